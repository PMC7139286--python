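"""Simulation and pipeline configuration.

The simulator is parameterised by a single :class:`SimulationConfig`
whose fields mirror the observed quantities of the study design: a small
plant genome, bisulfite counts with planted differentially methylated
regions, binomial allelic counts, 24-nt siRNA read clusters, expression
fragment counts, and a natural population with known additive/dominant
trait effects.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

from .errors import ConfigurationError


def _check_prop(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class DmrSpec:
    """A planted differentially methylated region (treated minus control).

    ``contexts`` limits the shift to those cytosine contexts (a strong
    hypomethylation can only be planted where the baseline leaves room).
    """

    chrom: str
    start: int
    end: int
    delta_ml: float  # signed shift of the true methylation level in treated
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH")


@dataclass(frozen=True)
class AseSpec:
    """A planted allele-specific-expression locus."""

    chrom: str
    pos: int  # 1-based
    f_ctrl: float  # true alt-allele fraction, control
    f_treat: float
    depth: int


@dataclass(frozen=True)
class SirnaSpec:
    """A planted 24-nt siRNA cluster with per-library read counts."""

    chrom: str
    start: int
    end: int
    reads_ctrl: int
    reads_treat: int


@dataclass(frozen=True)
class ExpressionSpec:
    """A feature with a planted expression level and fold change."""

    feature_id: str
    feature_type: str  # "gene" or "lncRNA"
    length_bp: int
    base_fpkm: float  # control-group expression level
    fold_change: float  # treated / control


@dataclass(frozen=True)
class CausalEffect:
    snp_index: int
    a: float  # additive effect: half the homozygote mean difference
    d: float  # dominance effect: heterozygote deviation from the midpoint


@dataclass(frozen=True)
class PopulationConfig:
    n_individuals: int = 300
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    causal: tuple[CausalEffect, ...] = ()
    polygenic_var: float = 0.3
    residual_var: float = 0.7
    mu: float = 0.0

    def validate(self) -> None:
        if self.n_individuals < 50:
            raise ConfigurationError("n_individuals must be >= 50 for association tests")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        _check_prop("missing_rate", self.missing_rate)
        if self.polygenic_var < 0 or self.residual_var < 0:
            raise ConfigurationError("variance components must be non-negative")
        for c in self.causal:
            if not (0 <= c.snp_index < self.n_snps):
                raise ConfigurationError(f"causal snp_index {c.snp_index} out of range")


@dataclass
class SimulationConfig:
    """Every knob of the synthetic study, with defaults matching the
    study conditions the pipeline is exercised under."""

    seed: int = 0
    n_chrom: int = 1
    chrom_length_bp: int = 100_000
    gc_fraction: float = 0.34  # poplar-like genome-wide GC
    # per-context baseline methylation levels (plant leaf methylome scale)
    baseline_ml: dict = field(default_factory=lambda: {"CG": 0.40, "CHG": 0.20, "CHH": 0.05})
    conversion_rate: float = 0.995  # bisulfite conversion rate c; error rate r = 1 - c
    coverage_mean: float = 30.0
    n_replicates_per_group: int = 3
    dmr_specs: Sequence[DmrSpec] = field(default_factory=list)
    ase_specs: Sequence[AseSpec] = field(default_factory=list)
    sirna_specs: Sequence[SirnaSpec] = field(default_factory=list)
    sirna_background_reads: int = 0  # uniform 24-nt reads per library outside clusters
    expression_specs: Sequence[ExpressionSpec] = field(default_factory=list)
    expression_library_size: int = 2_000_000  # fragments per replicate library
    population: PopulationConfig = field(default_factory=PopulationConfig)

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def validate(self) -> None:
        if self.n_chrom < 1 or self.chrom_length_bp < 1000:
            raise ConfigurationError(
                "need n_chrom >= 1 and chrom_length_bp >= 1000, got "
                f"{self.n_chrom} x {self.chrom_length_bp}"
            )
        _check_prop("gc_fraction", self.gc_fraction)
        _check_prop("conversion_rate", self.conversion_rate)
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.n_replicates_per_group < 1:
            raise ConfigurationError("need at least one replicate per group")
        names = set(self.chrom_names())
        for ctx, ml in self.baseline_ml.items():
            _check_prop(f"baseline_ml[{ctx}]", ml)
        for spec in self.dmr_specs:
            if spec.chrom not in names:
                raise ConfigurationError(f"DMR chrom {spec.chrom!r} not in genome")
            if not (0 <= spec.start < spec.end <= self.chrom_length_bp):
                raise ConfigurationError(f"DMR interval {spec} outside chromosome bounds")
            for ctx in spec.contexts:
                if ctx not in self.baseline_ml:
                    raise ConfigurationError(f"unknown context {ctx!r} in DMR spec")
                ml = self.baseline_ml[ctx]
                if not (0.0 <= ml + spec.delta_ml <= 1.0):
                    raise ConfigurationError(
                        f"delta_ml {spec.delta_ml} pushes {ctx} level {ml} outside [0, 1]"
                    )
        for spec in self.ase_specs:
            if spec.depth < 1:
                raise ConfigurationError("ASE depth must be >= 1")
            _check_prop("f_ctrl", spec.f_ctrl)
            _check_prop("f_treat", spec.f_treat)
        for spec in self.sirna_specs:
            if spec.end - spec.start < 24:
                raise ConfigurationError(f"siRNA cluster {spec} shorter than one 24-nt read")
            if spec.chrom not in names:
                raise ConfigurationError(f"siRNA chrom {spec.chrom!r} not in genome")
        self.population.validate()

    # -- round-trip to a plain YAML mapping ---------------------------------

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        raw = dict(raw)
        raw["dmr_specs"] = [
            DmrSpec(**{**d, "contexts": tuple(d.get("contexts", ("CG", "CHG", "CHH")))})
            for d in raw.get("dmr_specs", [])
        ]
        raw["ase_specs"] = [AseSpec(**d) for d in raw.get("ase_specs", [])]
        raw["sirna_specs"] = [SirnaSpec(**d) for d in raw.get("sirna_specs", [])]
        raw["expression_specs"] = [ExpressionSpec(**d) for d in raw.get("expression_specs", [])]
        pop = dict(raw.get("population", {}))
        if "maf_range" in pop:
            pop["maf_range"] = tuple(pop["maf_range"])
        pop["causal"] = tuple(CausalEffect(**c) for c in pop.get("causal", []))
        raw["population"] = PopulationConfig(**pop)
        return cls(**raw)
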