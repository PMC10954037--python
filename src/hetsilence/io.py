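"""Readers and writers for the pipeline's standard formats.

FASTA goes through Biopython; BED6 and bedGraph are thin validated text
parsers (coordinates are 0-based half-open, and malformed records are
rejected with line numbers).  Tables are TSV with headers, read and
written via pandas.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .imaging import CellMeasurement, FrapTrace
from .survival import PlatingObservation
from .tracks import Region, RegionSet, SignalTrack

__all__ = [
    "write_fasta", "read_fasta",
    "write_bed", "read_bed",
    "write_bedgraph", "read_bedgraph",
    "write_plating_tsv", "read_plating_tsv",
    "write_cells_tsv", "read_cells_tsv",
    "write_frap_tsv", "read_frap_tsv",
    "write_json",
]

_MGE_TAG = "MGE"


def write_fasta(path, name: str, sequence: str) -> None:
    record = SeqRecord(Seq(sequence), id=name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path) -> tuple[str, str]:
    """Read a single-record FASTA; returns (name, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return records[0].id, str(records[0].seq)


def write_bed(path, regions: RegionSet, chrom: str = "chr") -> None:
    """BED6; the name field carries the label and an MGE flag (label;MGE=0/1)."""
    with open(path, "w") as fh:
        for r in regions:
            name = f"{r.label or 'region'};{_MGE_TAG}={int(r.mge)}"
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\n")


def read_bed(path, genome_length: int | None = None) -> RegionSet:
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED record needs >= 3 fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start coordinate")
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end; BED intervals are 0-based "
                    "half-open [start, end) — 1-based inclusive input is not accepted"
                )
            label, mge = "", False
            if len(fields) >= 4:
                name = fields[3]
                if f";{_MGE_TAG}=" in name:
                    label, tag = name.rsplit(f";{_MGE_TAG}=", 1)
                    mge = tag == "1"
                else:
                    label = name
            regions.append(Region(start, end, label=label, mge=mge))
    return RegionSet(regions, genome_length)


def write_bedgraph(path, track: SignalTrack, chrom: str = "chr") -> None:
    """Run-length-compressed bedGraph of a fixed-bin track."""
    vals = track.values
    change = np.flatnonzero(np.diff(vals)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [track.n_bins]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            bp_start = int(s) * track.bin_size
            bp_end = min(int(e) * track.bin_size, track.genome_length)
            fh.write(f"{chrom}\t{bp_start}\t{bp_end}\t{vals[s]:.6g}\n")


def read_bedgraph(path, genome_length: int, bin_size: int = 1) -> SignalTrack:
    """Parse a bedGraph into a fixed-bin track; gaps are zero-filled.

    Overlapping intervals and intervals not aligned to the bin grid are
    rejected with line numbers.
    """
    values = np.zeros(SignalTrack.n_bins_for(genome_length, bin_size))
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: bedGraph record needs 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed record") from exc
            if not (0 <= start < end <= genome_length):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) outside genome "
                    f"(0-based half-open, length {genome_length})"
                )
            if start % bin_size or (end % bin_size and end != genome_length):
                raise ValueError(
                    f"{path}:{lineno}: interval not aligned to {bin_size}-bp bins"
                )
            records.append((start, end, value, lineno))
    records.sort()
    prev_end, prev_line = -1, None
    for start, end, value, lineno in records:
        if start < prev_end:
            raise ValueError(
                f"{path}:{lineno}: interval overlaps record at line {prev_line}"
            )
        values[start // bin_size : -(-end // bin_size)] = value
        prev_end, prev_line = end, lineno
    return SignalTrack(genome_length, bin_size, values)


_PLATING_COLS = ["genotype", "stress", "replicate", "arm", "phi", "count"]


def write_plating_tsv(path, observations: list[PlatingObservation]) -> None:
    pd.DataFrame(
        [
            (o.genotype, o.stress, o.replicate_id, o.arm, o.phi, o.count)
            for o in observations
        ],
        columns=_PLATING_COLS,
    ).to_csv(path, sep="\t", index=False)


def read_plating_tsv(path) -> list[PlatingObservation]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_PLATING_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PlatingObservation(
            genotype=str(r.genotype),
            stress=str(r.stress),
            replicate_id=int(r.replicate),
            arm=str(r.arm),
            phi=float(r.phi),
            count=int(r.count),
        )
        for r in df.itertuples()
    ]


def write_cells_tsv(path, cells: list[CellMeasurement]) -> None:
    pd.DataFrame(
        [(c.genotype, c.cell_area, c.dapi_area) for c in cells],
        columns=["genotype", "cell_area", "dapi_area"],
    ).to_csv(path, sep="\t", index=False)


def read_cells_tsv(path) -> list[CellMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        CellMeasurement(str(r.genotype), float(r.cell_area), float(r.dapi_area))
        for r in df.itertuples()
    ]


def write_frap_tsv(path, trace: FrapTrace) -> None:
    phase = np.where(np.arange(trace.times.size) < trace.bleach_index, "pre", "post")
    pd.DataFrame(
        {
            "time": trace.times,
            "roi": trace.roi_intensity,
            "ref": trace.ref_intensity,
            "phase": phase,
        }
    ).to_csv(path, sep="\t", index=False)


def read_frap_tsv(path) -> FrapTrace:
    df = pd.read_csv(path, sep="\t")
    post = np.flatnonzero((df["phase"] == "post").to_numpy())
    if post.size == 0:
        raise ValueError(f"{path}: no post-bleach samples")
    return FrapTrace(
        times=df["time"].to_numpy(float),
        roi_intensity=df["roi"].to_numpy(float),
        ref_intensity=df["ref"].to_numpy(float),
        bleach_index=int(post[0]),
    )


def write_json(path, obj) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
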