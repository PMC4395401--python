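"""Configuration objects for the simulation and mapping pipeline.

All tunable parameters live in small frozen-ish dataclasses so that a run is
fully specified by (config, seed).  YAML round-tripping is provided for the
command-line pipeline; library users construct the dataclasses directly.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is inconsistent or out of range."""


#: Published linkage-group genetic lengths (cM) used as default chromosome sizes.
DEFAULT_CHROM_CM = (72.5, 87.1, 96.9, 104.7, 88.7, 87.0, 61.8)
#: Physical chromosome lengths (Mb) of the reference genome emulated here.
DEFAULT_CHROM_MB = (29.1, 23.2, 39.8, 23.4, 28.0, 29.1, 19.2)
#: Per-chromosome marker counts, ~2,000 markers allocated by physical length.
DEFAULT_N_MARKERS = (304, 242, 415, 244, 292, 303, 200)

#: Training hybridization design: parent A in six replicates, F1 and parent B
#: in five each, with expected calls AA / AB / BB respectively.
TRAINING_REPLICATES = {"AA": 6, "AB": 5, "BB": 5}

GENOTYPES = ("AA", "AB", "BB")
NC = "NC"


@dataclass
class SdrSpec:
    """A segregation-distortion region: viability weight favoring the A allele."""

    chrom: str
    start_mb: float
    end_mb: float
    weight: float = 3.0

    def validate(self) -> None:
        if self.weight <= 0:
            raise ConfigError(f"viability weight must be > 0, got {self.weight}")
        if not self.start_mb < self.end_mb:
            raise ConfigError("SDR interval must have start < end")


@dataclass
class Hotspot:
    """Local multiplier on recombination (cM per Mb) density."""

    chrom: str
    start_mb: float
    end_mb: float
    multiplier: float = 5.0


@dataclass
class DesignWorldConfig:
    """Toy genome / read-pileup world consumed by the probe-design stage.

    The pileup emulates summarized re-sequencing evidence: per-site allele
    depths, a minimum base quality on the PHRED scale, and a mapping-uniqueness
    flag.  Total depth is lognormal, parameterized so that ``central_mass`` of
    sites fall inside ``depth_range`` (the emulated array had 90% of loci
    covered by 8-39 reads).
    """

    n_chromosomes: int = 2
    chrom_length_bp: int = 50_000
    snp_spacing_bp: float = 700.0
    depth_range: tuple[int, int] = (8, 39)
    central_mass: float = 0.9
    qual_range: tuple[int, int] = (15, 45)
    unique_rate: float = 0.95
    gene_spacing_bp: int = 5_000
    gene_length_bp: int = 2_000


@dataclass
class SimConfig:
    """Parameters of the simulated RIL population and its array hybridization.

    The population is a set of recombinant inbred lines derived by selfing a
    single F1 of two fully homozygous parents for ``generations - 1`` rounds
    (``generations=7`` models an F7:8 population, for which the expected
    genotype probabilities are 63/128 AA, 2/128 AB, 63/128 BB).  Crossovers
    follow a no-interference (Haldane) model: Poisson counts with mean equal
    to the chromosome length in Morgans, positions uniform.

    Hybridization signals are bivariate (A-signal, B-signal) Gaussian clusters
    on the log2-intensity scale around ``cluster_centers``; emitted intensities
    are linear (2**x) and the processing pipeline log2-transforms them back.
    """

    n_chromosomes: int = 7
    chrom_length_cm: Sequence[float] | float = DEFAULT_CHROM_CM
    chrom_length_mb: Sequence[float] | float = DEFAULT_CHROM_MB
    n_markers: Sequence[int] | int = DEFAULT_N_MARKERS
    n_rils: int = 120
    generations: int = 7
    cluster_centers: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"AA": (12.0, 7.0), "AB": (10.5, 10.5), "BB": (7.0, 12.0)}
    )
    noise_sd: float = 0.3
    probe_effect_sd: float = 2.0
    array_effect_sd: float = 0.2
    miscluster_rate: float = 0.01
    missing_rate: float = 0.002
    spatial_defect_rate: float = 0.0
    sdr_spec: SdrSpec | None = None
    hotspots: Sequence[Hotspot] = ()
    design: DesignWorldConfig = field(default_factory=DesignWorldConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        n = int(self.n_chromosomes)
        self.chrom_length_cm = _per_chrom(self.chrom_length_cm, n, float)
        self.chrom_length_mb = _per_chrom(self.chrom_length_mb, n, float)
        self.n_markers = _per_chrom(self.n_markers, n, int)
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("need at least one chromosome")
        if any(l < 0 for l in self.chrom_length_cm):
            raise ConfigError("genetic lengths must be >= 0 cM")
        if any(l <= 0 for l in self.chrom_length_mb):
            raise ConfigError("physical lengths must be > 0 Mb")
        if any(m <= 0 for m in self.n_markers):
            raise ConfigError("marker counts must be positive")
        if self.n_rils <= 0:
            raise ConfigError("RIL count must be positive")
        if self.generations < 2:
            raise ConfigError("selfing-generation index t must be >= 2")
        for name in ("miscluster_rate", "missing_rate", "spatial_defect_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        centers = [tuple(v) for v in self.cluster_centers.values()]
        if sorted(self.cluster_centers) != sorted(GENOTYPES):
            raise ConfigError("cluster_centers must have exactly the keys AA, AB, BB")
        if len({c for c in centers}) != 3:
            raise ConfigError("cluster centers must be pairwise distinct")
        if self.sdr_spec is not None:
            self.sdr_spec.validate()

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class MapConfig:
    """Linkage-map construction parameters.

    ``grouping_p_cutoff``, ``missing_threshold``, the Haldane mapping function
    and the minimum group size mirror the map-building program invocation the
    pipeline emulates (cut_off_p_value 1e-10, missing_threshold 0.15,
    no_map_size 2).  ``no_map_dist`` and ``detect_bad_data`` are recorded for
    provenance only.
    """

    grouping_p_cutoff: float = 1e-10
    missing_threshold: float = 0.15
    mapping_function: str = "haldane"
    ril_correction: bool = True
    ril_generations: int | None = 7
    ordering: str = "greedy2opt"
    min_group_size: int = 2
    no_map_dist: float = 15.0
    detect_bad_data: bool = False
    min_informative: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.grouping_p_cutoff < 1.0:
            raise ConfigError("grouping_p_cutoff must be in (0, 1)")
        if self.mapping_function != "haldane":
            raise ConfigError("only the Haldane mapping function is supported")


@dataclass
class CallConfig:
    """Genotype-calling parameters (no-call threshold, covariance shrinkage)."""

    nc_threshold: float = 0.6
    shrinkage: float = 0.1


@dataclass
class FilterConfig:
    """Marker/sample filtering thresholds."""

    conf_cutoff: float = 0.6
    alpha: float = 0.05
    het_max: float = 0.2
    hom_min: float = 0.15
    max_nc_regions: int = 10


@dataclass
class RefineConfig:
    flank: int = 6
    region_len: int = 12


@dataclass
class ScanConfig:
    lowess_span: float = 0.1
    slope_window: int = 5
    alpha: float = 0.05
    min_run: int = 3


@dataclass
class PipelineConfig:
    """Top-level configuration: one section per pipeline stage."""

    sim: SimConfig = field(default_factory=SimConfig)
    call: CallConfig = field(default_factory=CallConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    map: MapConfig = field(default_factory=MapConfig)
    refine: RefineConfig = field(default_factory=RefineConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    probe_window_bp: int = 2000
    probe_min_qual: int = 25
    probe_target_tm: float = 80.0
    probe_ctx: float = 1e-7
    stages: Sequence[str] = (
        "simulate", "design", "normalize", "call", "filter", "map", "refine", "scan",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.sim.seed = self.seed


def _per_chrom(value, n: int, cast):
    if isinstance(value, (int, float)):
        return tuple(cast(value) for _ in range(n))
    out = tuple(cast(v) for v in value)
    if len(out) < n:
        raise ConfigError(f"expected {n} per-chromosome values, got {len(out)}")
    return out[:n]


# -- YAML round trip ------------------------------------------------------

def _from_dict(cls, data):
    if data is None:
        return cls()
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "sdr_spec" and isinstance(v, dict):
            v = SdrSpec(**v)
        elif f.name == "hotspots":
            v = tuple(Hotspot(**h) if isinstance(h, dict) else h for h in v)
        elif f.name == "design" and isinstance(v, dict):
            v = DesignWorldConfig(**{k: tuple(x) if isinstance(x, list) else x
                                     for k, x in v.items()})
        kwargs[f.name] = v
    return cls(**kwargs)


_SECTIONS = {
    "sim": SimConfig, "call": CallConfig, "filter": FilterConfig, "map": MapConfig,
    "refine": RefineConfig, "scan": ScanConfig,
}


def load_pipeline_config(path) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from YAML; absent keys keep defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    kwargs = {}
    for name, cls in _SECTIONS.items():
        kwargs[name] = _from_dict(cls, data.get(name))
    for key in ("probe_window_bp", "probe_min_qual", "probe_target_tm", "probe_ctx",
                "stages", "seed"):
        if key in data:
            kwargs[key] = data[key]
    return PipelineConfig(**kwargs)


def dump_pipeline_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
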