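"""YAML-backed pipeline configuration with validation and hashing."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .survival import SamplerConfig
from .synthetic import SyntheticGenomeSpec

__all__ = [
    "OccupancyParams", "PeakParams", "EnrichmentParams", "SurvivalDesign",
    "ExpressionParams", "ImagingParams", "PipelineConfig",
]


def _from_dict(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list) and k in ("epod_width_range",):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


@dataclass(frozen=True)
class OccupancyParams:
    noise_sd: float = 1.0
    bin_size: int = 1

    def validate(self):
        if self.noise_sd < 0 or self.bin_size <= 0:
            raise ValueError("invalid occupancy parameters")


@dataclass(frozen=True)
class PeakParams:
    z_threshold: float = 2.0
    min_width: int = 200
    merge_gap: int = 100
    min_overlap_frac: float = 0.5
    # peaks are called on a rolling-mean-smoothed occupancy track: at 1-bp
    # bins and unit noise, raw threshold crossings are too dense to be
    # meaningful runs
    smooth_window: int = 100

    def validate(self):
        if self.min_width <= 0 or self.merge_gap < 0:
            raise ValueError("invalid peak-calling parameters")
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if not (0 < self.min_overlap_frac <= 1):
            raise ValueError("min_overlap_frac must be in (0, 1]")


@dataclass(frozen=True)
class EnrichmentParams:
    n_perm: int = 999
    window: int = 500
    motif_consensus: str = "AAAWWTWTT"  # AT-rich consensus for the bundled scanner

    def validate(self):
        if self.n_perm < 999:
            raise ValueError("n_perm must be >= 999")
        if self.window <= 0:
            raise ValueError("window must be positive")


@dataclass(frozen=True)
class SurvivalDesign:
    stress: str = "cisplatin"
    # true log10 survival effect per genotype
    delta_by_genotype: dict = field(
        default_factory=lambda: {"wt": -1.0, "dppk": -2.5, "dhfq": -2.5, "dhfq_dppk": -3.0}
    )
    upsilon: float = 8.0
    n_replicates: int = 3
    phi_untreated: float = -6.0
    phi_treated: float = -4.0

    def validate(self):
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        for g, d in self.delta_by_genotype.items():
            if not (-10 <= d <= 10):
                raise ValueError(f"delta for {g} outside prior support [-10, 10]")


@dataclass(frozen=True)
class ExpressionParams:
    n_genes: int = 2000
    mge_fraction: float = 0.2
    # contrast name -> MGE-specific log2 upshift
    shift_mge: dict = field(
        default_factory=lambda: {"dppk_vs_wt": 1.0, "dhfq_vs_wt": 1.0}
    )
    noise_sd: float = 0.5

    def validate(self):
        if self.n_genes < 10:
            raise ValueError("n_genes too small")
        if not (0 < self.mge_fraction < 1):
            raise ValueError("mge_fraction must be in (0, 1)")


@dataclass(frozen=True)
class ImagingParams:
    n_cells: int = 300
    occupancy_by_genotype: dict = field(
        default_factory=lambda: {"wt": 0.55, "dppk": 0.65, "dhfq": 0.65, "dhfq_dppk": 0.75}
    )
    occupancy_sd: float = 0.08
    frap_y0: float = 0.2
    frap_plateau: float = 0.9
    frap_t_half: float = 29.0
    frap_dt: float = 5.0
    frap_duration: float = 300.0
    frap_noise_cv: float = 0.02
    frap_n_traces: int = 3

    def validate(self):
        if self.frap_t_half <= 0 or self.frap_dt <= 0:
            raise ValueError("frap_t_half and frap_dt must be positive")
        if self.frap_n_traces < 1:
            raise ValueError("need at least one FRAP trace")


_DEFAULT_SEEDS = {
    "genome": 11, "occupancy": 12, "survival": 13,
    "expression": 14, "imaging": 15, "permutation": 16,
}


@dataclass(frozen=True)
class PipelineConfig:
    genome: SyntheticGenomeSpec = field(default_factory=SyntheticGenomeSpec)
    occupancy: OccupancyParams = field(default_factory=OccupancyParams)
    peaks: PeakParams = field(default_factory=PeakParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    survival: SurvivalDesign = field(default_factory=SurvivalDesign)
    expression: ExpressionParams = field(default_factory=ExpressionParams)
    imaging: ImagingParams = field(default_factory=ImagingParams)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    seeds: dict = field(default_factory=lambda: dict(_DEFAULT_SEEDS))
    output_dir: str = "hetsilence_run"

    def validate(self) -> "PipelineConfig":
        self.genome.validate()
        for section in (self.occupancy, self.peaks, self.enrichment,
                        self.survival, self.expression, self.imaging):
            section.validate()
        missing = set(_DEFAULT_SEEDS) - set(self.seeds)
        if missing:
            raise ValueError(f"missing seeds for stages: {sorted(missing)}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "genome": SyntheticGenomeSpec,
            "occupancy": OccupancyParams,
            "peaks": PeakParams,
            "enrichment": EnrichmentParams,
            "survival": SurvivalDesign,
            "expression": ExpressionParams,
            "imaging": ImagingParams,
            "sampler": SamplerConfig,
        }
        kwargs = {}
        for key, klass in sections.items():
            if key in data:
                kwargs[key] = _from_dict(klass, data.pop(key))
        if "seeds" in data:
            kwargs["seeds"] = {**_DEFAULT_SEEDS, **data.pop("seeds")}
        if "output_dir" in data:
            kwargs["output_dir"] = data.pop("output_dir")
        if data:
            raise ValueError(f"unknown config sections: {sorted(data)}")
        return cls(**kwargs).validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def reseed(self, base_seed: int) -> "PipelineConfig":
        """Derive all stage seeds deterministically from one base seed."""
        import dataclasses

        seeds = {
            name: int((base_seed * 1_000_003 + i * 97) % (2**31 - 1))
            for i, name in enumerate(sorted(_DEFAULT_SEEDS))
        }
        genome = dataclasses.replace(self.genome, seed=seeds["genome"])
        sampler = dataclasses.replace(self.sampler, seed=seeds["survival"])
        return dataclasses.replace(self, genome=genome, sampler=sampler, seeds=seeds)
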