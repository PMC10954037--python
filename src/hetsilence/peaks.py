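"""Peak calling, condition-dependent classification and class-level
enrichment tests.

Binding sites are classified by their presence across the two genetic
backgrounds: *ppk*-dependent sites are bound only when polyphosphate can
be made (wild type), *ppk*-independent sites are bound in both
backgrounds, and *secondary* sites appear only in the ppk deletion.  Each
class is then scored for enrichment of genomic metrics (AT content, H-NS
binding, motif occurrence) as a log2 fold change against the genome-wide
average, with permutation-based P values obtained by re-placing the
class's intervals uniformly at random on the genome.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tracks import Region, RegionSet, SignalTrack

PEAK_CLASSES = ("ppk_dependent", "ppk_independent", "secondary")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

__all__ = [
    "PEAK_CLASSES",
    "Peak",
    "EnrichmentResult",
    "call_peaks",
    "classify_peaks",
    "rolling_mean",
    "at_content_track",
    "class_log2fc",
    "permutation_test",
    "scan_motif",
    "motif_log2_enrichment",
]


@dataclass(frozen=True)
class Peak:
    """A classified binding interval (0-based half-open)."""

    start: int
    end: int
    present_wt: bool
    present_dppk: bool

    @property
    def peak_class(self) -> str:
        if self.present_wt and self.present_dppk:
            return "ppk_independent"
        if self.present_wt:
            return "ppk_dependent"
        if self.present_dppk:
            return "secondary"
        raise ValueError("peak absent in both conditions")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class EnrichmentResult:
    class_label: str
    metric: str
    log2fc: float  # may be +/-inf per the zero-class conventions
    p_perm: float | None
    n_perm: int | None


def call_peaks(
    occ: SignalTrack,
    z_threshold: float = 2.0,
    min_width: int = 200,
    merge_gap: int = 100,
) -> RegionSet:
    """Threshold-and-merge peak calling on a background-subtracted z track.

    Maximal runs of bins with z >= threshold; runs separated by gaps
    <= ``merge_gap`` bp are merged; merged runs narrower than
    ``min_width`` bp are discarded.
    """
    if min_width <= 0 or merge_gap < 0:
        raise ValueError("min_width must be positive and merge_gap non-negative")
    above = occ.values >= z_threshold
    if not above.any():
        return RegionSet([], occ.genome_length)
    b = occ.bin_size
    padded = np.concatenate([[False], above, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    run_starts, run_ends = edges[::2], edges[1::2]
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        start_bp, end_bp = int(s) * b, min(int(e) * b, occ.genome_length)
        if merged and start_bp - merged[-1][1] <= merge_gap:
            merged[-1][1] = end_bp
        else:
            merged.append([start_bp, end_bp])
    regions = [
        Region(s, e, label="peak") for s, e in merged if e - s >= min_width
    ]
    return RegionSet(regions, occ.genome_length)


def classify_peaks(
    peaks_wt: RegionSet,
    peaks_dppk: RegionSet,
    min_overlap_frac: float = 0.5,
) -> list[Peak]:
    """Merge condition peak sets and classify each union interval.

    A union interval counts as present in a condition when it has
    reciprocal overlap >= ``min_overlap_frac`` with any peak called in
    that condition.  The three classes partition the output.
    """
    if not (0 < min_overlap_frac <= 1):
        raise ValueError("min_overlap_frac must be in (0, 1]")
    union = RegionSet.union([peaks_wt, peaks_dppk])

    def present(u: Region, cond: RegionSet) -> bool:
        return any(u.reciprocal_overlap(p) >= min_overlap_frac for p in cond)

    out = []
    for u in union:
        p_wt = present(u, peaks_wt)
        p_dppk = present(u, peaks_dppk)
        if p_wt or p_dppk:
            out.append(Peak(u.start, u.end, present_wt=p_wt, present_dppk=p_dppk))
    return out


def rolling_mean(track: SignalTrack, window: int = 500) -> SignalTrack:
    """Centered moving average over ``window`` bp; edges use truncated windows."""
    if window < track.bin_size:
        raise ValueError("window must be at least one bin wide")
    if window > track.genome_length:
        raise ValueError("window larger than genome")
    w = max(1, round(window / track.bin_size))
    kernel = np.ones(w)
    sums = np.convolve(track.values, kernel, mode="same")
    counts = np.convolve(np.ones(track.n_bins), kernel, mode="same")
    return track.with_values(sums / counts)


def at_content_track(sequence: str, window: int = 500, strict: bool = True) -> SignalTrack:
    """Per-position A/T indicator smoothed with a centered rolling mean.

    Non-ACGT characters raise by default; with ``strict=False`` they
    count as non-AT.
    """
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    if strict:
        bad = ~np.isin(arr, [b"A", b"C", b"G", b"T"])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-ACGT character {seq[i]!r} at position {i}")
    indicator = np.isin(arr, [b"A", b"T"]).astype(float)
    track = SignalTrack(len(seq), 1, indicator)
    return rolling_mean(track, window)


def _class_bin_indices(track: SignalTrack, intervals) -> np.ndarray:
    idx: list[np.ndarray] = []
    for r in intervals:
        idx.append(track.bins_in(r.start, r.end))
    if not idx:
        return np.array([], dtype=int)
    return np.unique(np.concatenate(idx))


def class_log2fc(smoothed: SignalTrack, peaks_of_class) -> float:
    """log2(class mean / genome mean) of a non-negative smoothed metric.

    Zero class mean over a positive genome mean gives ``-inf`` (the
    convention for a class with no members of the metric); an empty class
    gives ``nan``; a zero genome mean is an error.
    """
    genome_mean = float(smoothed.values.mean())
    if genome_mean == 0:
        raise ValueError("genome-wide mean is zero")
    idx = _class_bin_indices(smoothed, peaks_of_class)
    if idx.size == 0:
        return float("nan")
    class_mean = float(smoothed.values[idx].mean())
    if class_mean == 0:
        return float("-inf")
    return float(np.log2(class_mean / genome_mean))


def _interval_mean(values: np.ndarray, starts: np.ndarray, widths: np.ndarray) -> float:
    # mean of the track over a set of intervals given by start bins/widths
    total = 0.0
    n = 0
    for s, w in zip(starts, widths):
        total += values[s : s + w].sum()
        n += w
    return total / n


def permutation_test(
    peaks_of_class,
    smoothed: SignalTrack,
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Two-sided permutation P for a class-vs-genome mean difference.

    The null re-places the class's intervals (widths preserved) uniformly
    at random on the genome; the statistic is the class mean of the
    smoothed track.  P uses the add-one convention
    ``(1 + #{|null - genome mean| >= |obs - genome mean|}) / (n_perm + 1)``
    and is therefore floored at ``1/(n_perm+1)``.
    """
    intervals = list(peaks_of_class)
    if not intervals:
        raise ValueError("empty class")
    b = smoothed.bin_size
    widths = np.array(
        [max(1, round((r.end - r.start) / b)) for r in intervals], dtype=int
    )
    if np.any(widths > smoothed.n_bins):
        raise ValueError("interval wider than genome")
    obs_starts = np.array([r.start // b for r in intervals], dtype=int)
    genome_mean = float(smoothed.values.mean())
    obs = _interval_mean(smoothed.values, obs_starts, widths) - genome_mean

    rng = np.random.default_rng(seed)
    csum = np.concatenate([[0.0], np.cumsum(smoothed.values)])
    max_starts = smoothed.n_bins - widths + 1
    exceed = 0
    for _ in range(n_perm):
        starts = rng.integers(0, max_starts)
        total = np.sum(csum[starts + widths] - csum[starts])
        null = total / widths.sum() - genome_mean
        if abs(null) >= abs(obs) - 1e-12:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def scan_motif(sequence: str, consensus: str, both_strands: bool = True) -> RegionSet:
    """Exact IUPAC consensus matching; returns hit intervals.

    A bundled stand-in for externally supplied motif hits (de novo motif
    discovery is out of scope).
    """
    seq = sequence.upper()
    hits: set[tuple[int, int]] = set()

    def matches(sub: str, cons: str) -> bool:
        return all(c in IUPAC[m] for c, m in zip(sub, cons))

    patterns = [consensus.upper()]
    if both_strands:
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R",
                "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
                "D": "H", "H": "D", "N": "N"}
        patterns.append("".join(comp[c] for c in reversed(consensus.upper())))
    m = len(consensus)
    for pat in set(patterns):
        for i in range(len(seq) - m + 1):
            if matches(seq[i : i + m], pat):
                hits.add((i, i + m))
    merged: list[Region] = []
    for s, e in sorted(hits):
        if merged and s < merged[-1].end:
            prev = merged.pop()
            merged.append(Region(prev.start, max(prev.end, e), label="motif"))
        else:
            merged.append(Region(s, e, label="motif"))
    return RegionSet(merged, len(seq))


def _has_hit(peak, motif_hits: RegionSet) -> bool:
    r = Region(peak.start, peak.end)
    return any(r.overlap(h) > 0 for h in motif_hits)


def motif_log2_enrichment(
    peaks_by_class: dict[str, list],
    motif_hits: RegionSet,
    denominator: str = "others",
) -> list[EnrichmentResult]:
    """Per-class log2 enrichment of motif-bearing peak fractions.

    With ``denominator="others"`` (default) each class's hit-bearing peak
    fraction is compared against the pooled fraction across all other
    classes; with ``denominator="genome"`` against the pooled fraction of
    all peaks.  Zero rates produce +/-inf, matching the convention that
    infinities arise when one side has no members.
    """
    if denominator not in ("others", "genome"):
        raise ValueError("denominator must be 'others' or 'genome'")
    if not any(peaks_by_class.values()):
        raise ValueError("no peaks in any class")
    flags = {
        cls: np.array([_has_hit(p, motif_hits) for p in pk], dtype=bool)
        for cls, pk in peaks_by_class.items()
    }
    results = []
    for cls, f in flags.items():
        if f.size == 0:
            results.append(EnrichmentResult(cls, "motif", float("nan"), None, None))
            continue
        rate = f.mean()
        if denominator == "others":
            other = np.concatenate(
                [v for c, v in flags.items() if c != cls] or [np.array([], bool)]
            )
        else:
            other = np.concatenate(list(flags.values()))
        other_rate = other.mean() if other.size else np.nan
        if np.isnan(other_rate):
            fc = float("nan")
        elif rate == 0 and other_rate == 0:
            fc = float("nan")
        elif rate == 0:
            fc = float("-inf")
        elif other_rate == 0:
            fc = float("inf")
        else:
            fc = float(np.log2(rate / other_rate))
        results.append(EnrichmentResult(cls, "motif", fc, None, None))
    return results
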