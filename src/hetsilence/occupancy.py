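"""ChIP occupancy processing: robust z-scores, control subtraction and
class-level occupancy comparisons.

ChIP-vs-input log2 ratio tracks are standardized to robust z-scores
(median/MAD), the untagged-strain negative control is subtracted with
clamping so that apparent occupancy is never added, and the result is
clamped to zero so only positive occupancy remains.  Genome bins are then
partitioned into three classes — background (outside any EPOD), EPODs
without mobile genetic elements, and EPODs covering MGEs — and per-class
occupancy is compared between conditions with a Wilcoxon rank-sum test
and Benjamini-Hochberg correction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tracks import RegionSet, SignalTrack

#: Gaussian-consistency constant for the median absolute deviation.
MAD_SCALE = 1.4826

CLASS_LABELS = ("background", "epod_minus_mge", "epod_plus_mge")

__all__ = [
    "MAD_SCALE",
    "CLASS_LABELS",
    "OccupancyClassSummary",
    "robust_z",
    "control_subtract",
    "classify_bins",
    "compare_class_occupancy",
]


@dataclass(frozen=True)
class OccupancyClassSummary:
    """Per-class occupancy comparison between two conditions."""

    class_label: str
    mean_occupancy: dict  # condition -> mean over class bins
    n_bins: int
    p_wilcoxon: float
    q_bh: float


def robust_z(track: SignalTrack) -> SignalTrack:
    """Convert a log2-ratio track to robust z-scores.

    z = (x - median(x)) / (1.4826 * MAD(x)); affine-invariant, output
    median 0 and robust scale 1.  Raises on a degenerate track (MAD = 0).
    """
    x = track.values
    if np.unique(x).size < 2:
        raise ValueError("track needs at least 2 distinct values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ValueError("degenerate track: median absolute deviation is zero")
    return track.with_values((x - med) / (MAD_SCALE * mad))


def control_subtract(tagged_z: SignalTrack, untagged_z: SignalTrack) -> SignalTrack:
    """Background-subtract the untagged negative control, with clamping.

    Per bin: ``max(tagged - max(untagged, 0), 0)``.  Negative control
    values are clamped at zero first (so noise in the control never adds
    apparent occupancy), and the result is clamped at zero so only
    positive occupancy remains.
    """
    if not tagged_z.same_binning(untagged_z):
        raise ValueError("tagged and untagged tracks must share binning")
    sub = tagged_z.values - np.maximum(untagged_z.values, 0.0)
    return tagged_z.with_values(np.maximum(sub, 0.0))


def classify_bins(
    epods: RegionSet, genome_length: int, bin_size: int = 1
) -> np.ndarray:
    """Exhaustive 3-way class label per bin.

    A bin belongs to an EPOD class when its midpoint falls inside the
    EPOD interval; otherwise it is background.  Returns an array of
    strings from ``CLASS_LABELS``.
    """
    n_bins = SignalTrack.n_bins_for(genome_length, bin_size)
    labels = np.full(n_bins, "background", dtype=object)
    starts = np.arange(n_bins) * bin_size
    ends = np.minimum(starts + bin_size, genome_length)
    mids = (starts + ends) / 2.0
    for region in epods:
        cls = "epod_plus_mge" if region.mge else "epod_minus_mge"
        sel = (mids >= region.start) & (mids < region.end)
        labels[sel] = cls
    return labels


def compare_class_occupancy(
    occ_wt: SignalTrack,
    occ_dppk: SignalTrack,
    classes: np.ndarray,
    condition_names: tuple[str, str] = ("wt", "dppk"),
) -> list[OccupancyClassSummary]:
    """Mean occupancy per class and condition, with Wilcoxon + BH q-values.

    For each class the two conditions' bin-level occupancies are compared
    with a two-sided Wilcoxon rank-sum (Mann-Whitney) test; the three
    class-level P values form one BH family.  Bins (not regions) are the
    observations, matching a per-position average occupancy; spatial
    autocorrelation between neighbouring bins is not modelled.
    """
    if not occ_wt.same_binning(occ_dppk):
        raise ValueError("condition tracks must share binning")
    classes = np.asarray(classes)
    if classes.size != occ_wt.n_bins:
        raise ValueError("class labels must match track binning")
    name_a, name_b = condition_names
    summaries: list[tuple[str, dict, int, float]] = []
    for cls in CLASS_LABELS:
        sel = classes == cls
        n = int(sel.sum())
        if n == 0:
            continue
        if n < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 bins")
        a = occ_wt.values[sel]
        b = occ_dppk.values[sel]
        if np.all(a == b):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(b, a, alternative="two-sided").pvalue)
        summaries.append(
            (cls, {name_a: float(a.mean()), name_b: float(b.mean())}, n, p)
        )
    pvals = [s[3] for s in summaries]
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        OccupancyClassSummary(
            class_label=cls,
            mean_occupancy=means,
            n_bins=n,
            p_wilcoxon=p,
            q_bh=float(q),
        )
        for (cls, means, n, p), q in zip(summaries, qvals)
    ]
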