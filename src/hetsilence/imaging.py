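"""Per-cell chromosome-occupancy statistics and FRAP recovery fitting.

Chromosome occupancy is the fraction of each cell's area covered by the
DAPI-stained nucleoid (DAPI area / phase-contrast cell area).  FRAP traces
from half-bleached condensates are normalized against an unbleached
reference droplet and fit to a one-phase association curve

    Y(t) = Y0 + (Plateau - Y0) * (1 - exp(-k t)),   t_half = ln(2) / k.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CellMeasurement",
    "FrapTrace",
    "FrapFit",
    "FrapFitError",
    "chromosome_occupancy",
    "bootstrap_ci",
    "wilcoxon_vs_wt",
    "frap_normalize",
    "frap_fit",
    "fit_frap_trace",
]


@dataclass(frozen=True)
class CellMeasurement:
    """One segmented cell: total area and DAPI (nucleoid) area, same units."""

    genotype: str
    cell_area: float
    dapi_area: float

    def __post_init__(self) -> None:
        if self.cell_area <= 0:
            raise ValueError("cell_area must be positive")
        if not (0 <= self.dapi_area <= self.cell_area):
            raise ValueError("dapi_area must lie in [0, cell_area]")


@dataclass
class FrapTrace:
    """Raw FRAP time series: bleached-droplet ROI and unbleached reference."""

    times: np.ndarray
    roi_intensity: np.ndarray
    ref_intensity: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        self.ref_intensity = np.asarray(self.ref_intensity, dtype=float)
        n = self.times.size
        if self.roi_intensity.size != n or self.ref_intensity.size != n:
            raise ValueError("times, roi and ref series must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (0 < self.bleach_index < n):
            raise ValueError("bleach_index out of range")


@dataclass(frozen=True)
class FrapFit:
    """One-phase association fit: ``t_half = ln(2)/k`` holds by construction."""

    y0: float
    plateau: float
    k: float
    r2: float

    @property
    def t_half(self) -> float:
        return np.log(2.0) / self.k


class FrapFitError(RuntimeError):
    """Raised when the recovery rate is unidentifiable or the fit fails."""


def chromosome_occupancy(cells: list[CellMeasurement]):
    """Per-cell DAPI/cell area ratios and per-genotype mean occupancy.

    Returns
    -------
    (ratios, means) : (pandas.DataFrame, pandas.Series)
        ``ratios`` has columns genotype/cell_area/dapi_area/occupancy;
        ``means`` is the mean occupancy indexed by genotype.
    """
    import pandas as pd

    if not cells:
        raise ValueError("no cell measurements supplied")
    df = pd.DataFrame(
        {
            "genotype": [c.genotype for c in cells],
            "cell_area": [c.cell_area for c in cells],
            "dapi_area": [c.dapi_area for c in cells],
        }
    )
    df["occupancy"] = df["dapi_area"] / df["cell_area"]
    return df, df.groupby("genotype")["occupancy"].mean()


def bootstrap_ci(
    values,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the mean of ``values``."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def wilcoxon_vs_wt(values_geno, values_wt) -> float:
    """Two-sided Wilcoxon rank-sum P comparing a genotype against wild type."""
    a = np.asarray(values_geno, dtype=float)
    b = np.asarray(values_wt, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def frap_normalize(trace: FrapTrace) -> FrapTrace:
    """Divide ROI by the unbleached reference, then rescale so the
    pre-bleach mean is 1.  Corrects full-field photobleaching; invariant
    under rescaling of either channel by a positive constant."""
    if np.any(trace.ref_intensity <= 0):
        raise ValueError("reference intensity must be positive throughout")
    ratio = trace.roi_intensity / trace.ref_intensity
    pre = ratio[: trace.bleach_index]
    pre_mean = pre.mean()
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach mean")
    return FrapTrace(
        times=trace.times.copy(),
        roi_intensity=ratio / pre_mean,
        ref_intensity=np.ones_like(trace.ref_intensity),
        bleach_index=trace.bleach_index,
    )


def _one_phase(t, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * t))


def frap_fit(times, values) -> FrapFit:
    """Least-squares one-phase association fit to a post-bleach series.

    ``times`` are measured from the bleach step (first point at t=0).
    Initialization: Y0 from the first point, Plateau from the last, and k
    from a log-linear regression of the remaining fraction
    (Plateau - Y) / (Plateau - Y0).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise ValueError("times and values must have equal length")
    if t.size < 5:
        raise ValueError("need at least 5 post-bleach points")
    y0_init = float(y[0])
    plateau_init = float(y[-1])
    if abs(plateau_init - y0_init) < 1e-12 or np.ptp(y) < 1e-12:
        raise FrapFitError("flat trace: recovery rate is unidentifiable")
    frac = (plateau_init - y) / (plateau_init - y0_init)
    ok = (frac > 1e-9) & (t > 0)
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(frac[ok]), 1)[0]
        k_init = max(-slope, 1e-6)
    else:
        k_init = np.log(2.0) / max(t[-1] / 4.0, 1e-6)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                _one_phase,
                t,
                y,
                p0=[y0_init, plateau_init, k_init],
                bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
                maxfev=10_000,
            )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        raise FrapFitError(f"one-phase association fit failed: {exc}") from exc
    y0, plateau, k = (float(v) for v in popt)
    resid = y - _one_phase(t, y0, plateau, k)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if k <= 0 or not np.isfinite(k):
        raise FrapFitError("fitted rate constant is non-positive")
    return FrapFit(y0=y0, plateau=plateau, k=k, r2=r2)


def fit_frap_trace(trace: FrapTrace) -> FrapFit:
    """Normalize a raw trace and fit the post-bleach portion.

    Time is re-zeroed at the first post-bleach sample, matching a fit to
    the data points immediately following the bleach step.
    """
    norm = frap_normalize(trace)
    i = norm.bleach_index
    t = norm.times[i:] - norm.times[i]
    return frap_fit(t, norm.roi_intensity[i:])
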