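"""Core genomic containers: fixed-bin signal tracks and labelled interval sets.

All coordinates are 0-based, half-open ``[start, end)`` throughout the
package, matching BED/bedGraph conventions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["SignalTrack", "Region", "RegionSet"]


@dataclass
class SignalTrack:
    """A real-valued signal sampled on fixed-width genomic bins.

    Parameters
    ----------
    genome_length : int
        Chromosome length in bp.
    bin_size : int
        Width of each bin in bp; the last bin may be truncated.
    values : np.ndarray
        One value per bin, ``ceil(genome_length / bin_size)`` entries.
    """

    genome_length: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        expected = self.n_bins_for(self.genome_length, self.bin_size)
        if self.values.shape != (expected,):
            raise ValueError(
                f"expected {expected} bins for genome_length={self.genome_length}, "
                f"bin_size={self.bin_size}; got shape {self.values.shape}"
            )

    @staticmethod
    def n_bins_for(genome_length: int, bin_size: int) -> int:
        return -(-genome_length // bin_size)

    @property
    def n_bins(self) -> int:
        return self.values.size

    def bin_starts(self) -> np.ndarray:
        return np.arange(self.n_bins) * self.bin_size

    def bin_midpoints(self) -> np.ndarray:
        starts = self.bin_starts()
        ends = np.minimum(starts + self.bin_size, self.genome_length)
        return (starts + ends) / 2.0

    def same_binning(self, other: "SignalTrack") -> bool:
        return (
            self.genome_length == other.genome_length
            and self.bin_size == other.bin_size
        )

    def with_values(self, values: np.ndarray) -> "SignalTrack":
        return replace(self, values=np.asarray(values, dtype=float))

    def bins_in(self, start: int, end: int) -> np.ndarray:
        """Indices of bins whose midpoint lies in [start, end)."""
        mid = self.bin_midpoints()
        return np.nonzero((mid >= start) & (mid < end))[0]


@dataclass(frozen=True)
class Region:
    """A labelled genomic interval, 0-based half-open."""

    start: int
    end: int
    label: str = ""
    mge: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Region") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "Region") -> float:
        """min of the two overlap fractions; 1.0 for identical intervals."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / self.width, ov / other.width)


class RegionSet:
    """A sorted collection of non-overlapping labelled intervals on one genome."""

    def __init__(self, regions: Iterable[Region], genome_length: int | None = None):
        regs = sorted(regions, key=lambda r: (r.start, r.end))
        for a, b in zip(regs, regs[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals [{a.start},{a.end}) and [{b.start},{b.end})"
                )
        if genome_length is not None:
            for r in regs:
                if r.end > genome_length:
                    raise ValueError(
                        f"interval [{r.start},{r.end}) exceeds genome length {genome_length}"
                    )
        self.regions: list[Region] = regs
        self.genome_length = genome_length

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, i: int) -> Region:
        return self.regions[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        return self.regions == other.regions

    def total_width(self) -> int:
        return sum(r.width for r in self.regions)

    def subset(self, predicate) -> "RegionSet":
        return RegionSet(
            (r for r in self.regions if predicate(r)), self.genome_length
        )

    def mask(self, genome_length: int | None = None) -> np.ndarray:
        """Boolean per-bp coverage mask (1 bp resolution)."""
        L = genome_length if genome_length is not None else self.genome_length
        if L is None:
            raise ValueError("genome_length required to build a mask")
        m = np.zeros(L, dtype=bool)
        for r in self.regions:
            m[r.start : min(r.end, L)] = True
        return m

    @staticmethod
    def union(sets: Sequence["RegionSet"]) -> "RegionSet":
        """Merge intervals from several sets into maximal disjoint intervals."""
        allregs = sorted(
            (r for s in sets for r in s), key=lambda r: (r.start, r.end)
        )
        merged: list[Region] = []
        for r in allregs:
            if merged and r.start <= merged[-1].end:
                prev = merged[-1]
                merged[-1] = Region(prev.start, max(prev.end, r.end), prev.label, prev.mge)
            else:
                merged.append(Region(r.start, r.end))
        gl = next((s.genome_length for s in sets if s.genome_length is not None), None)
        return RegionSet(merged, gl)
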