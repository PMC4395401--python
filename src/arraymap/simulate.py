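"""Synthetic RIL populations, array signals, read pileups, and annotations.

This module is the data-generating counterpart of the analysis pipeline: it
produces populations with the statistical structure the downstream stages
assume (Haldane crossovers, selfing-series genotype frequencies, bivariate
Gaussian signal clusters) together with the ground truth needed for
parameter-recovery tests.

Randomness is organized through :class:`numpy.random.SeedSequence` children of
``config.seed`` with a fixed child index per generator, so each output is
bit-reproducible and independent of whether other outputs were requested.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    GENOTYPES,
    NC,
    TRAINING_REPLICATES,
    ConfigError,
    SdrSpec,
    SimConfig,
)

# fixed SeedSequence child indices, one stream per generator
_STREAM_POPULATION = 0
_STREAM_SIGNALS = 1
_STREAM_DESIGN = 2
_STREAM_ACCESSIONS = 3
_STREAM_DISTORTION = 4

_CODE_TO_CALL = np.array(["AA", "AB", "BB"])


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[stream])


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

@dataclass
class TruthSet:
    """Simulation ground truth: true genotypes, marker order and positions."""

    genotypes: pd.DataFrame          # markers x RILs, values in {AA, AB, BB}
    markers: pd.DataFrame            # index marker_id; chrom, pos_mb, pos_cm

    def order_for(self, chrom: str) -> list[str]:
        sub = self.markers[self.markers["chrom"] == chrom]
        return list(sub.sort_values("pos_mb").index)

    def with_genotypes(self, genotypes: pd.DataFrame) -> "TruthSet":
        return TruthSet(genotypes=genotypes.copy(), markers=self.markers)


def _marker_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample marker positions: physical strictly increasing, genetic via the
    (piecewise-constant, hotspot-aware) recombination-density profile."""
    rows = []
    for ci, chrom in enumerate(config.chrom_names):
        n = config.n_markers[ci]
        l_mb = config.chrom_length_mb[ci]
        l_cm = config.chrom_length_cm[ci]
        pos_mb = np.sort(rng.uniform(0.0, l_mb, size=n))
        # enforce strict monotonicity in the (measure-zero) event of ties
        eps = l_mb * 1e-12
        pos_mb = np.maximum.accumulate(pos_mb + eps * np.arange(n))
        pos_cm = _genetic_positions(pos_mb, l_mb, l_cm, chrom, config.hotspots)
        for j in range(n):
            rows.append((f"{chrom}_m{j:04d}", chrom, pos_mb[j], pos_cm[j]))
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_mb", "pos_cm"])
    return df.set_index("marker_id")


def _genetic_positions(pos_mb, l_mb, l_cm, chrom, hotspots):
    spots = [h for h in hotspots if h.chrom == chrom]
    if not spots:
        return pos_mb / l_mb * l_cm
    # piecewise-constant rate profile, rescaled to keep the total length
    edges = sorted({0.0, l_mb, *(h.start_mb for h in spots), *(h.end_mb for h in spots)})
    edges = [e for e in edges if 0.0 <= e <= l_mb]
    rate = np.ones(len(edges) - 1)
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        mid = (a + b) / 2
        for h in spots:
            if h.start_mb <= mid < h.end_mb:
                rate[i] *= h.multiplier
    widths = np.diff(edges)
    cum = np.concatenate([[0.0], np.cumsum(rate * widths)])
    raw = np.interp(pos_mb, edges, cum)
    return raw / cum[-1] * l_cm


def _gamete(h0, h1, pos_cm, length_cm, rng):
    """One meiotic product under the Haldane (no-interference) model."""
    start = int(rng.integers(2))
    k = rng.poisson(length_cm / 100.0)
    if k == 0:
        return (h0 if start == 0 else h1).copy()
    xo = np.sort(rng.uniform(0.0, length_cm, size=k))
    phase = (start + np.searchsorted(xo, pos_cm, side="right")) % 2
    return np.where(phase == 0, h0, h1)


def simulate_ril_population(config: SimConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Simulate an F_t RIL population by selfing from a single F1.

    Returns ``(calls, truth)`` where ``calls`` is the markers x RILs genotype
    matrix (identical to ``truth.genotypes``; downstream noise is added by the
    signal simulator, not here) and ``truth`` carries positions and order.

    When ``config.sdr_spec`` is set, viability selection favoring the A
    allele acts at the marker closest to the interval midpoint in every
    selfing generation (offspring survive with relative weight w / sqrt(w) /
    1 for AA / AB / BB), so the distortion compounds over the series and
    spreads to linked markers by hitchhiking.
    """
    config.validate()
    rng = _rng(config, _STREAM_POPULATION)
    markers = _marker_table(config, rng)
    samples = [f"RIL{i + 1:03d}" for i in range(config.n_rils)]

    anchor_chrom, anchor_idx, weight = None, None, 1.0
    if config.sdr_spec is not None:
        spec = config.sdr_spec
        if spec.chrom not in config.chrom_names:
            raise ConfigError(f"SDR chromosome {spec.chrom!r} is not simulated")
        sub = markers[markers["chrom"] == spec.chrom]
        mid = (spec.start_mb + spec.end_mb) / 2.0
        anchor_chrom = spec.chrom
        anchor_idx = int((sub["pos_mb"] - mid).abs().to_numpy().argmin())
        weight = float(spec.weight)

    blocks = []
    for ci, chrom in enumerate(config.chrom_names):
        sub = markers[markers["chrom"] == chrom]
        pos_cm = sub["pos_cm"].to_numpy()
        l_cm = float(config.chrom_length_cm[ci])
        n = len(sub)
        homologs = np.zeros((config.n_rils, 2, n), dtype=np.uint8)
        homologs[:, 1, :] = 1  # F1: one parental haplotype of each type
        # viability weights by anchor genotype (AA, AB, BB); selection acts
        # each generation, so its effect compounds over the selfing series
        select = chrom == anchor_chrom and weight != 1.0
        w = np.array([weight, math.sqrt(weight), 1.0])
        w = w / w.max()
        for _gen in range(config.generations - 1):
            for i in range(config.n_rils):
                while True:
                    g1 = _gamete(homologs[i, 0], homologs[i, 1], pos_cm, l_cm, rng)
                    g2 = _gamete(homologs[i, 0], homologs[i, 1], pos_cm, l_cm, rng)
                    if not select:
                        break
                    geno = int(g1[anchor_idx]) + int(g2[anchor_idx])
                    if rng.random() < w[geno]:
                        break
                homologs[i, 0], homologs[i, 1] = g1, g2
        codes = homologs.sum(axis=1)  # RILs x markers, 0/1/2
        blocks.append(pd.DataFrame(
            _CODE_TO_CALL[codes.T], index=sub.index, columns=samples))
    genotypes = pd.concat(blocks)
    truth = TruthSet(genotypes=genotypes, markers=markers)
    return genotypes.copy(), truth


def apply_segregation_distortion(
    calls: pd.DataFrame,
    markers: pd.DataFrame,
    sdr_spec: SdrSpec,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Viability selection favoring the A allele at one anchor locus.

    Whole RILs are resampled (with replacement) with weight ``w`` for AA,
    ``sqrt(w)`` for AB and 1 for BB at the marker closest to the midpoint of
    the specified interval; linked markers are distorted through hitchhiking.
    Column names of the input are retained so the output is a drop-in
    population of the same size.
    """
    sdr_spec.validate()
    if sdr_spec.chrom not in set(markers["chrom"]):
        raise ConfigError(f"SDR chromosome {sdr_spec.chrom!r} is not simulated")
    if rng is None:
        rng = np.random.default_rng(seed)
    if sdr_spec.weight == 1.0:
        return calls.copy()
    mid = (sdr_spec.start_mb + sdr_spec.end_mb) / 2.0
    sub = markers[markers["chrom"] == sdr_spec.chrom]
    anchor = (sub["pos_mb"] - mid).abs().idxmin()
    geno = calls.loc[anchor].to_numpy()
    w = np.where(geno == "AA", sdr_spec.weight,
                 np.where(geno == "AB", math.sqrt(sdr_spec.weight), 1.0))
    p = w / w.sum()
    idx = rng.choice(len(p), size=len(p), replace=True, p=p)
    out = calls.iloc[:, idx]
    out.columns = calls.columns
    return out


# ---------------------------------------------------------------------------
# array signals
# ---------------------------------------------------------------------------

ALLELES = ("A", "B")
STRANDS = ("fwd", "rev")


@dataclass
class SignalTensor:
    """Probe intensities indexed by SNP x allele x strand-replicate x sample.

    ``values`` has shape (n_snps, 2, 2, n_samples) on the linear intensity
    scale; NaN marks a missing measurement.
    """

    snp_ids: list[str]
    samples: list[str]
    values: np.ndarray

    def to_long(self) -> pd.DataFrame:
        s, a, t, n = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.snp_ids, ALLELES, STRANDS, self.samples],
            names=["snp_id", "allele", "strand", "sample"])
        return pd.DataFrame({"intensity": self.values.reshape(-1)}, index=idx).reset_index()

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "SignalTensor":
        snps = list(pd.unique(df["snp_id"]))
        samples = list(pd.unique(df["sample"]))
        shape = (len(snps), 2, 2, len(samples))
        values = np.full(shape, np.nan)
        si = {v: i for i, v in enumerate(snps)}
        ai = {v: i for i, v in enumerate(ALLELES)}
        ti = {v: i for i, v in enumerate(STRANDS)}
        ni = {v: i for i, v in enumerate(samples)}
        values[
            df["snp_id"].map(si), df["allele"].map(ai),
            df["strand"].map(ti), df["sample"].map(ni)] = df["intensity"]
        return cls(snp_ids=snps, samples=samples, values=values)


@dataclass
class ArrayLayout:
    """Probe-to-grid assignment of the slide; one (row, col) per probe."""

    probe_ids: list[str]
    rows: np.ndarray
    cols: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return int(self.rows.max()) + 1, int(self.cols.max()) + 1


@dataclass
class ArraySignals:
    """Test-sample and training-hybridization signals plus the slide layout."""

    test: SignalTensor
    training: SignalTensor
    training_labels: list[str]
    layout: ArrayLayout
    defects: list = field(default_factory=list)
    nc_draws: list = field(default_factory=list)


def probe_ids_for(snp_ids) -> list[str]:
    return [f"{s}_{a}_{t}" for s in snp_ids for a in ALLELES for t in STRANDS]


def training_sample_names() -> tuple[list[str], list[str]]:
    """Names and expected labels of the 16 training hybridizations."""
    names, labels = [], []
    for label, count in TRAINING_REPLICATES.items():
        parent = {"AA": "parentA", "AB": "f1", "BB": "parentB"}[label]
        for r in range(count):
            names.append(f"{parent}_rep{r + 1}")
            labels.append(label)
    return names, labels


def simulate_array_signals(
    genotypes: pd.DataFrame, config: SimConfig,
    rng: np.random.Generator | None = None,
) -> ArraySignals:
    """Two-channel hybridization signals for test samples plus the 16-point
    training set (6 parent-A, 5 F1, 5 parent-B hybridizations).

    The log2 intensity of probe (snp, allele, strand) on array j is
    ``center[genotype, allele] + probe_effect + array_effect + noise`` with
    independent Gaussian noise of SD ``noise_sd``; ``miscluster_rate`` of
    training points are drawn around a wrong cluster center, and each
    intensity is missing independently with ``missing_rate``.
    """
    if rng is None:
        rng = _rng(config, _STREAM_SIGNALS)
    snp_ids = list(genotypes.index)
    samples = list(genotypes.columns)
    n_snps, n_test = len(snp_ids), len(samples)
    centers = np.array([config.cluster_centers[g] for g in GENOTYPES])  # (3, 2)

    code = np.full((n_snps, n_test), -1, dtype=np.int64)
    for gi, g in enumerate(GENOTYPES):
        code[genotypes.to_numpy() == g] = gi
    nc_draws = []
    nc_pos = np.argwhere(code < 0)
    for i, j in nc_pos:
        code[i, j] = rng.integers(3)
        nc_draws.append((snp_ids[i], samples[j]))

    train_names, train_labels = training_sample_names()
    n_train = len(train_names)
    tcode = np.tile(np.array([GENOTYPES.index(l) for l in train_labels]), (n_snps, 1))
    if config.miscluster_rate > 0:
        flip = rng.random((n_snps, n_train)) < config.miscluster_rate
        shift = rng.integers(1, 3, size=(n_snps, n_train))
        tcode = np.where(flip, (tcode + shift) % 3, tcode)

    probe_eff = rng.normal(0.0, config.probe_effect_sd, size=(n_snps, 2, 2))
    array_eff = rng.normal(0.0, config.array_effect_sd, size=n_test + n_train)

    def _emit(codes, arr_eff, n_arr):
        # centers[codes] -> (S, N, 2 alleles); reorder to (S, 2, 1, N)
        base = centers[codes].transpose(0, 2, 1)[:, :, None, :]
        log2 = (base + probe_eff[:, :, :, None] + arr_eff[None, None, None, :]
                + rng.normal(0.0, config.noise_sd, size=(n_snps, 2, 2, n_arr)))
        if config.missing_rate > 0:
            log2[rng.random(log2.shape) < config.missing_rate] = np.nan
        return np.exp2(log2)

    test_vals = _emit(code, array_eff[:n_test], n_test)
    train_vals = _emit(tcode, array_eff[n_test:], n_train)

    layout = _default_layout(snp_ids, rng)
    defects = []
    if config.spatial_defect_rate > 0:
        defects = _inject_defects(test_vals, layout, config, rng)

    return ArraySignals(
        test=SignalTensor(snp_ids, samples, test_vals),
        training=SignalTensor(snp_ids, train_names, train_vals),
        training_labels=train_labels,
        layout=layout,
        defects=defects,
        nc_draws=nc_draws,
    )


def _default_layout(snp_ids, rng) -> ArrayLayout:
    probe_ids = probe_ids_for(snp_ids)
    n = len(probe_ids)
    side = math.ceil(math.sqrt(n))
    perm = rng.permutation(side * side)[:n]  # random placement on the slide
    return ArrayLayout(probe_ids=probe_ids, rows=perm // side, cols=perm % side)


def _inject_defects(values, layout: ArrayLayout, config: SimConfig, rng):
    """Multiplicative blobs (bubbles/scratches) on randomly chosen arrays."""
    defects = []
    n_rows, n_cols = layout.shape
    flat = values.reshape(-1, values.shape[-1])
    for j in range(values.shape[-1]):
        if rng.random() >= config.spatial_defect_rate:
            continue
        cr, cc = rng.integers(n_rows), rng.integers(n_cols)
        radius = int(rng.integers(2, 6))
        factor = float(rng.choice([0.15, 4.0]))
        hit = (np.abs(layout.rows - cr) <= radius) & (np.abs(layout.cols - cc) <= radius)
        flat[hit, j] *= factor
        defects.append({"sample_index": j, "row": int(cr), "col": int(cc),
                        "radius": radius, "factor": factor})
    return defects


# ---------------------------------------------------------------------------
# probe-design toy world: reference, pileup, annotation
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class DesignWorld:
    reference: dict
    pileup: pd.DataFrame
    annotation_gff3: str


def simulate_design_world(config: SimConfig) -> DesignWorld:
    """Toy genome with a summarized read pileup and a GFF3 annotation.

    The world is self-contained (its own seed stream) and independent of the
    RIL-marker world: it exists to exercise the probe-design stage.
    """
    rng = _rng(config, _STREAM_DESIGN)
    dc = config.design
    reference = {}
    rows = []
    gff = ["##gff-version 3"]
    mu, sigma = _depth_lognormal_params(dc.depth_range, dc.central_mass)
    for ci in range(dc.n_chromosomes):
        chrom = f"toy{ci + 1}"
        seq = "".join(rng.choice(_BASES, size=dc.chrom_length_bp))
        reference[chrom] = seq
        gff.extend(_annotate_chrom(chrom, dc))
        pos = 0
        while True:
            pos += 1 + int(rng.exponential(dc.snp_spacing_bp))
            if pos > dc.chrom_length_bp:
                break
            ref = seq[pos - 1]
            alt = str(rng.choice(_BASES[_BASES != ref]))
            depth = max(2, int(round(float(rng.lognormal(mu, sigma)))))
            p_alt = rng.uniform(0.2, 0.8)
            depth_alt = int(np.clip(rng.binomial(depth, p_alt), 1, depth - 1))
            rows.append((chrom, pos, ref, alt, depth - depth_alt, depth_alt,
                         int(rng.integers(*dc.qual_range)),
                         bool(rng.random() < dc.unique_rate)))
    pileup = pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref", "alt", "depth_ref", "depth_alt", "min_qual", "unique"])
    return DesignWorld(reference=reference, pileup=pileup,
                       annotation_gff3="\n".join(gff) + "\n")


def _depth_lognormal_params(depth_range, central_mass):
    """Lognormal (mu, sigma) placing ``central_mass`` of rounded draws in range."""
    from scipy.stats import norm
    lo, hi = depth_range
    a, b = math.log(lo - 0.5), math.log(hi + 0.5)  # continuity-corrected bounds
    z = norm.ppf(0.5 + central_mass / 2.0)
    return (a + b) / 2.0, (b - a) / (2.0 * z)


def _annotate_chrom(chrom, dc):
    lines = []
    g = 0
    for start in range(500, dc.chrom_length_bp - dc.gene_length_bp, dc.gene_spacing_bp):
        g += 1
        end = start + dc.gene_length_bp - 1
        gid = f"{chrom}_g{g:03d}"
        lines.append(f"{chrom}\ttoy\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}")
        lines.append(f"{chrom}\ttoy\tmRNA\t{start}\t{end}\t.\t+\t.\t"
                     f"ID={gid}.t1;Parent={gid}")
        third = dc.gene_length_bp // 3
        for k, (a, b) in enumerate(((start, start + third - 1),
                                    (end - third + 1, end))):
            lines.append(f"{chrom}\ttoy\tCDS\t{a}\t{b}\t.\t+\t0\t"
                         f"ID={gid}.cds{k + 1};Parent={gid}.t1")
    return lines


def simulate_read_pileup(config: SimConfig) -> pd.DataFrame:
    """Summarized read pileup (chrom, pos, ref, alt, depths, quality, uniqueness)."""
    return simulate_design_world(config).pileup


# ---------------------------------------------------------------------------
# non-parental accessions (for bin-polymorphism coverage)
# ---------------------------------------------------------------------------

def simulate_accession_calls(
    markers: pd.DataFrame, n_accessions: int = 4, mono_rate: float = 0.40,
    config: SimConfig | None = None, seed: int | None = None,
) -> pd.DataFrame:
    """Genotype calls of unrelated inbred accessions on the array markers.

    A ``mono_rate`` fraction of markers is forced monomorphic (all accessions
    share one homozygous call); the rest draw independent homozygous calls,
    which leaves roughly half of all markers effectively polymorphic -- in
    line with arrays designed against only two founder lines.
    """
    if config is not None:
        rng = _rng(config, _STREAM_ACCESSIONS)
    else:
        rng = np.random.default_rng(seed)
    n = len(markers)
    cols = [f"ACC{i + 1}" for i in range(n_accessions)]
    mono = rng.random(n) < mono_rate
    shared = rng.choice(["AA", "BB"], size=n)
    draws = rng.choice(["AA", "BB"], size=(n, n_accessions))
    out = np.where(mono[:, None], shared[:, None], draws)
    return pd.DataFrame(out, index=markers.index, columns=cols)
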