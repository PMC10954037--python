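# hetsilence

Statistical pipeline for studying **polyphosphate-directed bacterial
heterochromatin**: how the polyanion polyP steers the nucleoid-associated
protein Hfq onto AT-rich mobile genetic elements (MGEs) and silences
them.  The package is aimed at bacterial chromatin and regulatory
genomics researchers who need the bespoke statistics of this kind of
study as reusable, tested code: a Bayesian survival model for
dilution-plating assays, ChIP occupancy normalization and class
comparisons, condition-dependent binding-site classification with
permutation enrichment tests, expression-shift statistics, and FRAP
recovery fitting — all exercisable end to end on synthetic data with
known planted effects.

## The models at the core

**Survival (dilution plating).** Colony counts are Poisson with log10
structure

    untreated_i ~ Poisson(10^(υ_i + φ_i)),  treated_i ~ Poisson(10^(υ_i + δ + φ_i))

where υ_i is the log10 CFU/ml titer of replicate *i*, δ the log10-fold
survival change under treatment (one per genotype-stress combination)
and φ_i the known log10 dilution (φ = −6 ⇔ 10^6-fold).  With
Uniform(0,15) and Uniform(−10,10) priors, the joint posterior over
{υ_i}, δ is sampled by MCMC (emcee), checked by split-Rhat, and
summarized by equal-tailed credible intervals, directional posterior
probabilities P(δ_a > δ_b), and the log-additive double-mutant
prediction δ_a + δ_b − δ_wt.

**ChIP occupancy.** log2 ChIP/input tracks are standardized to robust z
scores, z = (x − median)/(1.4826·MAD); the untagged-control track is
subtracted with clamping, max(tagged − max(untagged, 0), 0), so only
positive occupancy remains.  Occupancy is compared between wild type and
the polyP-free (Δ*ppk*) condition across three genome classes —
background, EPODs without MGEs, EPODs covering MGEs — with Wilcoxon
rank-sum tests and Benjamini-Hochberg correction.

**Peaks and enrichment.** Binding sites present only with polyP
(*ppk*-dependent), in both conditions (*ppk*-independent), or only
without polyP (secondary) are scored for AT-content, H-NS and motif
enrichment as log2(class mean / genome mean), with permutation P values
from random re-placement of the class's intervals (add-one convention,
±inf conventions for empty rates).

**Imaging.** Nucleoid occupancy = DAPI area / cell area with percentile
bootstrap CIs; FRAP recoveries are reference-normalized and fit to the
one-phase association curve Y(t) = Y0 + (Plateau − Y0)(1 − e^(−kt)),
t1/2 = ln2/k.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Fit the survival model to one replicate: 200 colonies from a 10^5-fold
diluted untreated sample and 200 colonies from a 10^3-fold diluted
treated sample.  The dilution arithmetic pins the survival effect at
two orders of magnitude:

```python
from hetsilence.survival import PlatingObservation, SamplerConfig, fit_survival_model
from hetsilence.synthetic import copy_number_to_concentration

obs = [
    PlatingObservation("wt", "cisplatin", 1, "untreated", phi=-5, count=200),
    PlatingObservation("wt", "cisplatin", 1, "treated",   phi=-3, count=200),
]
post = fit_survival_model(obs, SamplerConfig(seed=1))
lo, hi = post.delta_ci()
print(f"delta mean {post.delta_mean:.3f}, 95% CI ({lo:.3f}, {hi:.3f}), "
      f"max Rhat {max(post.rhat.values()):.4f}")
print(f"Hfq concentration: {copy_number_to_concentration(55000, 1.0):.1f} uM")
```

prints

```
delta mean -2.000, 95% CI (-2.084, -1.915), max Rhat 1.0042
Hfq concentration: 91.3 uM
```

i.e. treatment reduced survival 100-fold (δ = −2.00, CI ±0.08), the
sampler converged (Rhat ≤ 1.01), and 55,000 Hfq molecules in a 1-fl cell
correspond to ~90 μM.

The whole synthetic study — genome generation through occupancy, peak
classes, survival fits, expression and imaging — runs from the CLI:

```sh
hetsilence reproduce --seed 1 --out run1
```

writing per-stage TSV/BED/bedGraph outputs plus a manifest with the
config hash; two runs with the same config are byte-identical.

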