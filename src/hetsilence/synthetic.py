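"""Synthetic-data generators emulating the study's inputs.

Every downstream stage of the pipeline is exercised on data produced
here: a circular bacterial genome (treated as linear for interval
placement) carrying AT-rich mobile-genetic-element islands inside a
subset of extended protein occupancy domains (EPODs), condition-dependent
Hfq affinity tracks, Poisson dilution-plating counts, per-gene expression
shifts, per-cell nucleoid measurements and noisy FRAP recovery traces.
Planted effect sizes are free parameters (the study does not quantify
them); defaults are documented in the methods note.  All generators are
deterministic for a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .imaging import CellMeasurement, FrapTrace
from .survival import PlatingObservation
from .tracks import Region, RegionSet, SignalTrack

CONDITIONS = ("wt", "dppk")

__all__ = [
    "CONDITIONS",
    "SyntheticGenomeSpec",
    "GenomeModel",
    "generate_genome",
    "generate_occupancy_tracks",
    "generate_plating_counts",
    "generate_expression_table",
    "generate_cell_measurements",
    "generate_frap_trace",
    "copy_number_to_concentration",
]


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Parameters of the synthetic genome and its planted structure.

    Affinity amplitudes are in robust-z-like units on the occupancy
    scale: ``affinity_mge`` is the wild-type-only Hfq elevation at MGE
    EPODs (lost without polyP), ``affinity_shared`` the polyP-independent
    elevation at non-MGE EPODs (present in both backgrounds), and
    ``affinity_secondary`` the smaller elevation planted at GC-rich
    non-EPOD "secondary" sites active only in the ppk deletion.
    """

    genome_length: int = 200_000
    n_epods: int = 16
    mge_fraction: float = 0.4
    at_mge: float = 0.65
    at_background: float = 0.50
    hns_mge_boost: float = 1.0
    epod_width_range: tuple[int, int] = (1_000, 2_500)
    seed: int = 0
    # planted structure beyond the EPODs themselves
    n_secondary: int = 6
    secondary_width: int = 800
    at_secondary: float = 0.35
    hns_baseline: float = 0.5
    affinity_mge: float = 6.0
    affinity_shared: float = 6.0
    affinity_secondary: float = 4.0
    min_separation: int = 1_000

    def validate(self) -> None:
        if not (0 < self.at_background < self.at_mge <= 1):
            raise ValueError("need 0 < at_background < at_mge <= 1")
        if self.n_epods < 1:
            raise ValueError("n_epods must be >= 1")
        if not (0 <= self.mge_fraction <= 1):
            raise ValueError("mge_fraction must lie in [0, 1]")
        lo, hi = self.epod_width_range
        if not (0 < lo <= hi):
            raise ValueError("invalid epod_width_range")
        if hi > self.genome_length:
            raise ValueError("EPOD widths must fit within genome_length")


@dataclass
class GenomeModel:
    """Synthetic genome with annotation and condition-dependent affinity."""

    sequence: str
    epods: RegionSet
    secondary_sites: RegionSet
    hns_track: SignalTrack
    affinity: dict[str, SignalTrack]
    spec: SyntheticGenomeSpec


def _place_intervals(
    rng: np.random.Generator,
    widths: list[int],
    genome_length: int,
    min_separation: int,
    occupied: list[tuple[int, int]],
    max_tries: int = 20_000,
) -> list[tuple[int, int]]:
    """Rejection-sample non-overlapping intervals >= min_separation apart."""
    need = sum(widths) + min_separation * (len(widths) + len(occupied))
    if need > genome_length:
        raise ValueError(
            f"infeasible packing: {len(widths)} intervals totalling {sum(widths)} bp "
            f"(+{min_separation} bp separation) exceed genome of {genome_length} bp"
        )
    placed = list(occupied)
    out = []
    for w in widths:
        for _ in range(max_tries):
            s = int(rng.integers(0, genome_length - w + 1))
            e = s + w
            if all(
                e + min_separation <= ps or s >= pe + min_separation
                for ps, pe in placed
            ):
                placed.append((s, e))
                out.append((s, e))
                break
        else:
            raise ValueError("infeasible packing: rejection sampling failed")
    return out


def _draw_sequence(rng: np.random.Generator, n: int, at_frac: np.ndarray) -> str:
    is_at = rng.random(n) < at_frac
    pick = rng.integers(0, 2, n)
    bases = np.empty(n, dtype="U1")
    bases[is_at & (pick == 0)] = "A"
    bases[is_at & (pick == 1)] = "T"
    bases[~is_at & (pick == 0)] = "G"
    bases[~is_at & (pick == 1)] = "C"
    return "".join(bases)


def generate_genome(spec: SyntheticGenomeSpec) -> GenomeModel:
    """Generate the genome, EPOD/MGE annotation, H-NS track and affinities.

    MGE EPODs are drawn with per-base P(A or T) = ``at_mge``, secondary
    sites with ``at_secondary`` (GC-rich), everything else with
    ``at_background``.  The H-NS track is ``hns_baseline`` plus
    ``hns_mge_boost`` inside MGE EPODs.  EPODs and secondary sites are
    placed by rejection sampling, non-overlapping and at least
    ``min_separation`` bp apart; the circular chromosome is treated as
    linear (no wrap-around intervals).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.epod_width_range
    widths = [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_epods)]
    epod_pos = _place_intervals(rng, widths, spec.genome_length, spec.min_separation, [])
    n_mge = int(round(spec.mge_fraction * spec.n_epods))
    mge_idx = set(rng.choice(spec.n_epods, size=n_mge, replace=False).tolist())
    epods = RegionSet(
        (
            Region(s, e, label=f"EPOD_{i:03d}", mge=i in mge_idx)
            for i, (s, e) in enumerate(sorted(epod_pos))
        ),
        spec.genome_length,
    )
    sec_pos = _place_intervals(
        rng,
        [spec.secondary_width] * spec.n_secondary,
        spec.genome_length,
        spec.min_separation,
        [(r.start, r.end) for r in epods],
    )
    secondary = RegionSet(
        (
            Region(s, e, label=f"SEC_{i:03d}")
            for i, (s, e) in enumerate(sorted(sec_pos))
        ),
        spec.genome_length,
    )

    at_frac = np.full(spec.genome_length, spec.at_background)
    for r in epods:
        if r.mge:
            at_frac[r.start : r.end] = spec.at_mge
    for r in secondary:
        at_frac[r.start : r.end] = spec.at_secondary
    sequence = _draw_sequence(rng, spec.genome_length, at_frac)

    hns = np.full(spec.genome_length, spec.hns_baseline)
    aff_wt = np.zeros(spec.genome_length)
    aff_dppk = np.zeros(spec.genome_length)
    for r in epods:
        if r.mge:
            hns[r.start : r.end] += spec.hns_mge_boost
            aff_wt[r.start : r.end] += spec.affinity_mge
        else:
            aff_wt[r.start : r.end] += spec.affinity_shared
            aff_dppk[r.start : r.end] += spec.affinity_shared
    for r in secondary:
        aff_dppk[r.start : r.end] += spec.affinity_secondary

    L = spec.genome_length
    return GenomeModel(
        sequence=sequence,
        epods=epods,
        secondary_sites=secondary,
        hns_track=SignalTrack(L, 1, hns),
        affinity={
            "wt": SignalTrack(L, 1, aff_wt),
            "dppk": SignalTrack(L, 1, aff_dppk),
        },
        spec=spec,
    )


def generate_occupancy_tracks(
    genome: GenomeModel, condition: str, noise_sd: float = 1.0, seed: int = 0
) -> tuple[SignalTrack, SignalTrack]:
    """Tagged and untagged ChIP log2-ratio-like tracks for one condition.

    tagged = true affinity + Gaussian noise; untagged (negative control)
    = Gaussian noise only.  Under "wt" the affinity is elevated at MGE
    EPODs; under "dppk" that elevation is absent and a smaller one sits
    at the GC-rich secondary sites.
    """
    if condition not in genome.affinity:
        raise ValueError(f"unknown condition {condition!r}; have {sorted(genome.affinity)}")
    rng = np.random.default_rng(seed)
    aff = genome.affinity[condition]
    tagged = aff.with_values(aff.values + noise_sd * rng.standard_normal(aff.n_bins))
    untagged = aff.with_values(noise_sd * rng.standard_normal(aff.n_bins))
    return tagged, untagged


def generate_plating_counts(
    upsilon_true,
    delta_true: float | None,
    phis,
    seed: int = 0,
    genotype: str = "wt",
    stress: str = "stress",
) -> list[PlatingObservation]:
    """Poisson colony counts from known titers, effect and dilutions.

    For each replicate *i* (entry of ``upsilon_true``) and each dilution
    ``phi`` in ``phis``, an untreated count ~ Poisson(10**(upsilon_i + phi))
    is drawn, and, when ``delta_true`` is given, a treated count
    ~ Poisson(10**(upsilon_i + delta_true + phi)).  Expected counts above
    10**9 raise with advice to dilute further.
    """
    ups = np.atleast_1d(np.asarray(upsilon_true, dtype=float))
    phis = np.atleast_1d(np.asarray(phis, dtype=float))
    rng = np.random.default_rng(seed)
    obs: list[PlatingObservation] = []
    for i, u in enumerate(ups, start=1):
        for phi in phis:
            arms = [("untreated", u + phi)]
            if delta_true is not None:
                arms.append(("treated", u + delta_true + phi))
            for arm, expo in arms:
                if expo > 9:
                    raise ValueError(
                        f"expected count 10^{expo:.1f} overflows; dilute further "
                        "(choose a more negative phi)"
                    )
                count = int(rng.poisson(10.0**expo))
                obs.append(
                    PlatingObservation(
                        genotype=genotype,
                        stress=stress,
                        replicate_id=i,
                        arm=arm,
                        phi=float(phi),
                        count=count,
                    )
                )
    return obs


def generate_expression_table(
    n_genes: int,
    mge_fraction: float,
    shift_mge: dict[str, float],
    noise_sd: float,
    seed: int = 0,
    gene_sd: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2FC table with an MGE-specific shift per contrast.

    ``shift_mge`` maps contrast name -> log2 upshift applied to MGE-class
    genes only; other genes are centred at zero.  Each gene carries a
    latent per-gene effect (sd ``gene_sd``) shared across all contrasts —
    this is what makes genotype-genotype rank correlations high — plus
    independent measurement noise with sd ``noise_sd`` per contrast.
    """
    if not (0 <= mge_fraction <= 1):
        raise ValueError("mge_fraction must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    n_mge = int(round(mge_fraction * n_genes))
    categories = np.array(["MGE"] * n_mge + ["other"] * (n_genes - n_mge))
    rng.shuffle(categories)
    df = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:05d}" for i in range(n_genes)],
            "category": categories,
        }
    )
    is_mge = categories == "MGE"
    latent = gene_sd * rng.standard_normal(n_genes)
    for contrast, shift in shift_mge.items():
        vals = latent + noise_sd * rng.standard_normal(n_genes)
        vals[is_mge] += shift
        df[contrast] = vals
    return df


def generate_cell_measurements(
    n_cells: int,
    occupancy_mean: float,
    occupancy_sd: float,
    seed: int = 0,
    genotype: str = "wt",
    cell_area_mean: float = 2.0,
    cell_area_sd: float = 0.3,
) -> list[CellMeasurement]:
    """Cell/DAPI area pairs whose ratio is ~ N(mean, sd) clipped to [0, 1]."""
    rng = np.random.default_rng(seed)
    areas = np.clip(
        rng.normal(cell_area_mean, cell_area_sd, n_cells), 0.2 * cell_area_mean, None
    )
    ratios = np.clip(rng.normal(occupancy_mean, occupancy_sd, n_cells), 0.0, 1.0)
    return [
        CellMeasurement(genotype=genotype, cell_area=float(a), dapi_area=float(a * r))
        for a, r in zip(areas, ratios)
    ]


def generate_frap_trace(
    y0: float,
    plateau: float,
    t_half: float,
    dt: float,
    duration: float,
    noise_cv: float,
    seed: int = 0,
    n_prebleach: int = 3,
) -> FrapTrace:
    """Noisy one-phase association recovery trace with a reference channel.

    Pre-bleach samples sit at intensity 1; post-bleach samples follow
    ``Y(t) = y0 + (plateau - y0)(1 - exp(-k t))`` with ``k = ln2/t_half``,
    multiplied by ``1 + noise_cv * N(0,1)`` noise.  The unbleached
    reference channel is constant.
    """
    if t_half <= 0 or dt <= 0:
        raise ValueError("t_half and dt must be positive")
    if duration < 4 * dt:
        raise ValueError("duration too short for a meaningful fit")
    rng = np.random.default_rng(seed)
    k = np.log(2.0) / t_half
    t_post = np.arange(0.0, duration + dt / 2, dt)
    y_post = y0 + (plateau - y0) * (1.0 - np.exp(-k * t_post))
    y = np.concatenate([np.ones(n_prebleach), y_post])
    if noise_cv > 0:
        y = y * (1.0 + noise_cv * rng.standard_normal(y.size))
    times = np.concatenate(
        [np.arange(n_prebleach) * dt, n_prebleach * dt + t_post]
    )
    return FrapTrace(
        times=times,
        roi_intensity=y,
        ref_intensity=np.ones_like(y),
        bleach_index=n_prebleach,
    )


def copy_number_to_concentration(n_molecules: float, volume_fl: float) -> float:
    """Convert a per-cell copy number to a concentration in micromolar.

    ``n / (Avogadro * volume)`` with the volume in femtoliters; e.g.
    55,000 molecules in a 1-fl cell is ~91 uM.
    """
    if n_molecules < 0:
        raise ValueError("n_molecules must be non-negative")
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    moles = n_molecules / Avogadro
    liters = volume_fl * 1e-15
    return moles / liters * 1e6
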