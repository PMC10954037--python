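"""Bayesian Poisson model for dilution-plating survival assays.

Colony counts from a 10-fold dilution series are modelled as Poisson draws
whose rates combine an unknown per-replicate titer and a shared treatment
effect, all on the log10 scale:

    untreated_i ~ Poisson(10 ** (upsilon_i + phi_i))
    treated_i   ~ Poisson(10 ** (upsilon_i + delta + phi_i))

where ``upsilon_i`` is the log10 CFU/ml of replicate *i*, ``delta`` the
log10-fold survival change under treatment (shared within one
genotype-stress combination) and ``phi_i`` the known log10 dilution of the
counted plate (phi = -6 means a 10^6-fold dilution).  Priors are
Uniform(0, 15) on upsilon and Uniform(-10, 10) on delta.  One model is fit
per genotype-stress combination.

Sampling uses the emcee affine-invariant ensemble sampler; convergence is
assessed with the rank-normalized split-Rhat statistic (arviz) treating
walkers as chains.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

UPSILON_BOUNDS = (0.0, 15.0)
DELTA_BOUNDS = (-10.0, 10.0)
LN10 = np.log(10.0)

__all__ = [
    "PlatingObservation",
    "SamplerConfig",
    "SurvivalPosterior",
    "ConvergenceWarning",
    "fit_survival_model",
    "credible_interval",
    "prob_direction",
    "log_additive_prediction",
    "mutation_rate",
]


class ConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class PlatingObservation:
    """One counted plate/spot from a dilution series."""

    genotype: str
    stress: str
    replicate_id: int
    arm: str  # "treated" or "untreated"
    phi: float  # log10 dilution; -6 means a 10^6-fold dilution
    count: int

    def __post_init__(self) -> None:
        if self.arm not in ("treated", "untreated"):
            raise ValueError(f"arm must be 'treated' or 'untreated', got {self.arm!r}")
        if not np.isfinite(self.phi):
            raise ValueError("phi must be finite")
        if self.count < 0 or int(self.count) != self.count:
            raise ValueError("count must be a non-negative integer")


@dataclass(frozen=True)
class SamplerConfig:
    n_walkers: int = 48
    n_steps: int = 2000  # retained steps per walker after warm-up
    n_burn: int = 1000
    seed: int = 0
    rhat_threshold: float = 1.01


@dataclass
class SurvivalPosterior:
    """Posterior draws over per-replicate titers and the shared effect."""

    genotype: str
    stress: str
    replicate_ids: list[int]
    delta_samples: np.ndarray  # flat draws
    upsilon_samples: np.ndarray  # shape (n_replicates, n_draws)
    rhat: dict[str, float]
    converged: bool
    prior_bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"upsilon": UPSILON_BOUNDS, "delta": DELTA_BOUNDS}
    )
    sampler_meta: dict = field(default_factory=dict)

    @property
    def delta_mean(self) -> float:
        return float(np.mean(self.delta_samples))

    def delta_ci(self, level: float = 0.95) -> tuple[float, float]:
        return credible_interval(self.delta_samples, level)

    def summary(self, level: float = 0.95) -> dict:
        lo, hi = self.delta_ci(level)
        return {
            "genotype": self.genotype,
            "stress": self.stress,
            "delta_mean": self.delta_mean,
            "delta_ci_lo": lo,
            "delta_ci_hi": hi,
            "ci_level": level,
            "upsilon_mean": [float(m) for m in self.upsilon_samples.mean(axis=1)],
            "max_rhat": max(self.rhat.values()),
            "converged": self.converged,
        }


def _log_posterior(params: np.ndarray, obs_matrix: np.ndarray, n_rep: int) -> np.ndarray:
    """Vectorized log posterior; params shape (n_walkers, n_rep + 1).

    obs_matrix columns: replicate index, treated flag, phi, count, lgamma(count+1).
    """
    ups = params[:, :n_rep]
    delta = params[:, n_rep]
    ok = (
        np.all((ups >= UPSILON_BOUNDS[0]) & (ups <= UPSILON_BOUNDS[1]), axis=1)
        & (delta >= DELTA_BOUNDS[0])
        & (delta <= DELTA_BOUNDS[1])
    )
    out = np.full(params.shape[0], -np.inf)
    if not np.any(ok):
        return out
    rep = obs_matrix[:, 0].astype(int)
    treated = obs_matrix[:, 1]
    phi = obs_matrix[:, 2]
    count = obs_matrix[:, 3]
    lg = obs_matrix[:, 4]
    # exponent per (walker, observation)
    expo = ups[np.ix_(ok, rep)] + np.outer(delta[ok], treated) + phi[None, :]
    log_lam = expo * LN10
    lam = np.power(10.0, expo)
    out[ok] = np.sum(count[None, :] * log_lam - lam - lg[None, :], axis=1)
    return out


def fit_survival_model(
    observations: list[PlatingObservation],
    sampler_cfg: SamplerConfig | None = None,
) -> SurvivalPosterior:
    """Fit the Poisson dilution-series model for one genotype-stress pair.

    Raises ``ValueError`` if observations span multiple genotypes or
    stresses (the model is strictly per combination) or if either arm is
    missing; warns if all untreated counts are zero (titers weakly
    identified) or if Rhat exceeds the configured threshold.
    """
    import emcee

    cfg = sampler_cfg or SamplerConfig()
    if not observations:
        raise ValueError("no observations")
    genotypes = {o.genotype for o in observations}
    stresses = {o.stress for o in observations}
    if len(genotypes) > 1 or len(stresses) > 1:
        raise ValueError(
            "fit_survival_model is per genotype-stress combination; "
            f"got genotypes={sorted(genotypes)}, stresses={sorted(stresses)}"
        )
    rep_ids = sorted({o.replicate_id for o in observations})
    rep_index = {r: i for i, r in enumerate(rep_ids)}
    arms = {o.arm for o in observations}
    if arms != {"treated", "untreated"}:
        raise ValueError("need both treated and untreated observations")
    untreated = [o for o in observations if o.arm == "untreated"]
    if all(o.count == 0 for o in untreated):
        warnings.warn(
            "all untreated counts are zero: titers are weakly identified",
            ConvergenceWarning,
        )
    obs_matrix = np.array(
        [
            [
                rep_index[o.replicate_id],
                1.0 if o.arm == "treated" else 0.0,
                o.phi,
                float(o.count),
                gammaln(o.count + 1.0),
            ]
            for o in observations
        ]
    )
    n_rep = len(rep_ids)
    ndim = n_rep + 1
    rng = np.random.default_rng(cfg.seed)

    # crude moment-based start: invert the count model on each arm
    ups0 = np.zeros(n_rep)
    for o in untreated:
        i = rep_index[o.replicate_id]
        ups0[i] = np.log10(max(o.count, 0.5)) - o.phi
    d0 = []
    for o in observations:
        if o.arm == "treated":
            i = rep_index[o.replicate_id]
            d0.append(np.log10(max(o.count, 0.5)) - o.phi - ups0[i])
    delta0 = float(np.clip(np.mean(d0), DELTA_BOUNDS[0] + 0.5, DELTA_BOUNDS[1] - 0.5))
    ups0 = np.clip(ups0, UPSILON_BOUNDS[0] + 0.5, UPSILON_BOUNDS[1] - 0.5)
    p0 = np.concatenate([ups0, [delta0]])
    start = p0[None, :] + 0.05 * rng.standard_normal((cfg.n_walkers, ndim))
    start[:, :n_rep] = np.clip(start[:, :n_rep], *UPSILON_BOUNDS)
    start[:, n_rep] = np.clip(start[:, n_rep], *DELTA_BOUNDS)

    sampler = emcee.EnsembleSampler(
        cfg.n_walkers,
        ndim,
        _log_posterior,
        args=(obs_matrix, n_rep),
        vectorize=True,
        # differential-evolution moves mix much faster than the default
        # stretch move on this narrow, correlated (upsilon, delta) posterior
        moves=[
            (emcee.moves.DEMove(), 0.8),
            (emcee.moves.DESnookerMove(), 0.2),
        ],
    )
    sampler.random_state = np.random.RandomState(cfg.seed).get_state()
    sampler.run_mcmc(start, cfg.n_burn + cfg.n_steps, progress=False)
    chain = sampler.get_chain(discard=cfg.n_burn)  # (n_steps, n_walkers, ndim)
    chain = np.moveaxis(chain, 0, 1)  # (n_walkers, n_steps, ndim)

    rhat = _rhat(chain, n_rep)
    converged = max(rhat.values()) <= cfg.rhat_threshold
    if not converged:
        warnings.warn(
            f"max Rhat {max(rhat.values()):.4f} exceeds threshold "
            f"{cfg.rhat_threshold}; treat posterior with caution",
            ConvergenceWarning,
        )
    flat = chain.reshape(-1, ndim)
    return SurvivalPosterior(
        genotype=next(iter(genotypes)),
        stress=next(iter(stresses)),
        replicate_ids=rep_ids,
        delta_samples=flat[:, n_rep].copy(),
        upsilon_samples=flat[:, :n_rep].T.copy(),
        rhat=rhat,
        converged=converged,
        sampler_meta={
            "sampler": "emcee",
            "n_walkers": cfg.n_walkers,
            "n_steps": cfg.n_steps,
            "n_burn": cfg.n_burn,
            "seed": cfg.seed,
        },
    )


def _rhat(chain: np.ndarray, n_rep: int) -> dict[str, float]:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = {"delta": float(az.rhat(chain[:, :, n_rep]))}
        for i in range(n_rep):
            out[f"upsilon[{i}]"] = float(az.rhat(chain[:, :, i]))
    return out


def credible_interval(samples, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from posterior draws.

    Uses linear-interpolated quantiles; ``level=1.0`` returns (min, max).
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample array")
    if not (0.0 < level <= 1.0):
        raise ValueError("level must be in (0, 1]")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def _delta_draws(post) -> np.ndarray:
    if isinstance(post, SurvivalPosterior):
        return post.delta_samples
    return np.asarray(post, dtype=float)


def prob_direction(post_a, post_b, n: int = 100_000, seed: int | None = None) -> float:
    """Posterior probability of a difference in the observed direction.

    The observed direction is the sign of the difference of posterior
    means; the probability is estimated by pairing random draws from the
    two (independent) posteriors.  Significance tiers used in reporting:
    ``*`` for P > 0.95 and ``***`` for P > 0.999.
    """
    a = _delta_draws(post_a)
    b = _delta_draws(post_b)
    rng = np.random.default_rng(seed)
    da = a[rng.integers(0, a.size, n)]
    db = b[rng.integers(0, b.size, n)]
    direction = np.sign(a.mean() - b.mean())
    if direction == 0:
        direction = 1.0
    diff = (da - db) * direction
    return float(np.mean(diff > 0) + 0.5 * np.mean(diff == 0))


def log_additive_prediction(
    post_wt,
    post_a,
    post_b,
    n: int = 100_000,
    seed: int | None = None,
    level: float = 0.95,
):
    """Predicted double-mutant effect if single-mutant effects are log-additive.

    Samplewise ``delta_pred = delta_a + delta_b - delta_wt`` over paired
    random draws.  Returns ``(samples, (lo, hi))``.  Raises if the three
    posteriors come from different stresses.
    """
    posts = [post_wt, post_a, post_b]
    stresses = {p.stress for p in posts if isinstance(p, SurvivalPosterior)}
    if len(stresses) > 1:
        raise ValueError(f"posteriors span multiple stresses: {sorted(stresses)}")
    rng = np.random.default_rng(seed)
    draws = []
    for p in posts:
        d = _delta_draws(p)
        draws.append(d[rng.integers(0, d.size, n)])
    pred = draws[1] + draws[2] - draws[0]
    return pred, credible_interval(pred, level)


def mutation_rate(selective_cfu_per_ml: float, total_cfu_per_ml: float) -> float:
    """Mutation rate: CFU/ml on selective plates over total CFU/ml."""
    if total_cfu_per_ml <= 0:
        raise ValueError("total CFU/ml must be positive")
    if selective_cfu_per_ml < 0:
        raise ValueError("selective CFU/ml must be non-negative")
    return selective_cfu_per_ml / total_cfu_per_ml
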