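"""Probe design: window-based SNP selection, nearest-neighbor melting
temperatures, four-probe design per SNP, and genomic-context annotation.

SNP selection runs a non-overlapping 2-Kb window over a read pileup and keeps,
per window, the unique-mapping SNP with base quality >= 25 and the highest
minor-allele read depth.  Each selected SNP receives four probes -- one per
allele on each strand -- with the probe length (20-35 nt) chosen to bring the
SantaLucia nearest-neighbor melting temperature closest to the target.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Raised for malformed sequence or pileup input."""


# SantaLucia (1998) unified nearest-neighbor parameters.
# dH in kcal/mol, dS in cal/(mol*K), keyed by the 5'->3' top-strand dinucleotide.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation terms for terminal G:C / A:T pairs
_INIT = {"G": (0.1, -2.8), "C": (0.1, -2.8), "A": (2.3, 4.1), "T": (2.3, 4.1)}

_GAS_CONSTANT = 1.9872  # cal/(mol*K)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class ThermoParams:
    """Nearest-neighbor thermodynamic tables and the strand-concentration term."""

    dh_table: dict = field(default_factory=lambda: {k: v[0] for k, v in _NN.items()})
    ds_table: dict = field(default_factory=lambda: {k: v[1] for k, v in _NN.items()})
    dh_init: dict = field(default_factory=lambda: {k: v[0] for k, v in _INIT.items()})
    ds_init: dict = field(default_factory=lambda: {k: v[1] for k, v in _INIT.items()})
    gas_constant: float = _GAS_CONSTANT
    ctx: float = 1e-7
    include_initiation: bool = True

    def __post_init__(self):
        if self.ctx <= 0:
            raise InputError("Ctx must be > 0")
        missing = {a + b for a in "ACGT" for b in "ACGT"} - set(self.dh_table)
        if missing:
            raise InputError(f"dH table misses stacks: {sorted(missing)}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def stack_sums(sequence: str, params: ThermoParams) -> tuple[float, float]:
    """Total (dH [kcal/mol], dS [cal/(mol*K)]) over dinucleotide stacks,
    plus initiation terms when enabled."""
    seq = sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise InputError(f"non-ACGT character in sequence {sequence!r}")
    if len(seq) < 2:
        raise InputError("sequence must have length >= 2")
    dh = sum(params.dh_table[seq[i:i + 2]] for i in range(len(seq) - 1))
    ds = sum(params.ds_table[seq[i:i + 2]] for i in range(len(seq) - 1))
    if params.include_initiation:
        dh += params.dh_init[seq[0]] + params.dh_init[seq[-1]]
        ds += params.ds_init[seq[0]] + params.ds_init[seq[-1]]
    return dh, ds


def tm_from_sums(dh: float, ds: float, params: ThermoParams) -> float:
    """Tm (deg C) = dH*1000 / (dS + R ln Ctx) - 273.15 (dH kcal/mol, dS cal/mol/K)."""
    return dh * 1000.0 / (ds + params.gas_constant * np.log(params.ctx)) - 273.15


def compute_tm(sequence: str, params: ThermoParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature of ``sequence`` in deg C."""
    params = params or ThermoParams()
    dh, ds = stack_sums(sequence, params)
    return tm_from_sums(dh, ds, params)


# ---------------------------------------------------------------------------
# window selection
# ---------------------------------------------------------------------------

def select_window_snps(
    pileup: pd.DataFrame, window_bp: int = 2000, min_qual: int = 25,
) -> pd.DataFrame:
    """Best SNP per non-overlapping window: unique-mapping, quality >= min_qual,
    highest minor-allele depth (ties: higher quality, then lower position).

    Windows are half-open ``[start, start + window_bp)`` anchored at position 1
    of each chromosome.  The pileup must be sorted by (chrom, pos).
    """
    required = {"chrom", "pos", "depth_ref", "depth_alt", "min_qual", "unique"}
    if not required <= set(pileup.columns):
        raise InputError(f"pileup misses columns {sorted(required - set(pileup.columns))}")
    sorted_ok = (pileup.sort_values(["chrom", "pos"], kind="stable")
                 .reset_index(drop=True)[["chrom", "pos"]]
                 .equals(pileup.reset_index(drop=True)[["chrom", "pos"]]))
    if not sorted_ok:
        raise InputError("pileup must be sorted by (chrom, pos); sort it first")

    cand = pileup[(pileup["unique"]) & (pileup["min_qual"] >= min_qual)].copy()
    if cand.empty:
        return cand
    cand["minor_depth"] = cand[["depth_ref", "depth_alt"]].min(axis=1)
    cand["window"] = (cand["pos"] - 1) // window_bp
    # rank within window: max minor depth, then max quality, then min position
    cand = cand.sort_values(
        ["chrom", "window", "minor_depth", "min_qual", "pos"],
        ascending=[True, True, False, False, True], kind="stable")
    best = cand.groupby(["chrom", "window"], sort=True).head(1)
    return (best.sort_values(["chrom", "pos"])
            .drop(columns=["window"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# probe design
# ---------------------------------------------------------------------------

@dataclass
class ProbeRecord:
    allele: str       # "A" (reference) or "B" (alternate)
    strand: str       # "fwd" or "rev"
    sequence: str
    length: int
    tm: float


@dataclass
class SnpDesign:
    snp_id: str
    chrom: str
    pos: int
    alleles: tuple[str, str]
    context: str = "intergenic"
    probes: list[ProbeRecord] = field(default_factory=list)


MIN_PROBE_LEN = 20
MAX_PROBE_LEN = 35


def _centered_window(flank: str, center: int, length: int) -> tuple[int, int]:
    left = (length - 1) // 2
    start = center - left
    return start, start + length


def design_probes(
    snp: pd.Series | dict, flank_sequence: str, params: ThermoParams | None = None,
    target_tm: float = 80.0, snp_offset: int | None = None,
) -> SnpDesign:
    """Design the four probes (2 alleles x 2 strands) for one SNP.

    ``flank_sequence`` is genomic sequence containing the SNP position at
    ``snp_offset`` (default: the center of the string).  For each allele the
    probe is centered on the SNP and its length in [20, 35] minimizes
    ``|Tm - target_tm|`` (ties broken toward the shorter probe); the
    reverse-strand replicate is the reverse complement.
    """
    params = params or ThermoParams()
    flank = flank_sequence.upper()
    center = len(flank) // 2 if snp_offset is None else snp_offset
    need = (MAX_PROBE_LEN - 1) // 2
    if center < need or len(flank) - center - 1 < need:
        raise InputError(
            f"need >= {need} flanking bases on each side of the SNP, got "
            f"{center} left / {len(flank) - center - 1} right")
    ref, alt = str(snp["ref"]), str(snp["alt"])
    design = SnpDesign(
        snp_id=f"{snp['chrom']}:{int(snp['pos'])}",
        chrom=str(snp["chrom"]), pos=int(snp["pos"]), alleles=(ref, alt))
    for allele_name, base in (("A", ref), ("B", alt)):
        best = None
        for length in range(MIN_PROBE_LEN, MAX_PROBE_LEN + 1):
            start, stop = _centered_window(flank, center, length)
            seq = flank[start:center] + base + flank[center + 1:stop]
            tm = compute_tm(seq, params)
            key = (abs(tm - target_tm), length)
            if best is None or key < best[0]:
                best = (key, seq, length, tm)
        _, seq, length, tm = best
        design.probes.append(ProbeRecord(allele_name, "fwd", seq, length, tm))
        design.probes.append(
            ProbeRecord(allele_name, "rev", reverse_complement(seq), length, tm))
    return design


def designs_to_frame(designs: list[SnpDesign]) -> pd.DataFrame:
    rows = []
    for d in designs:
        for p in d.probes:
            rows.append((d.snp_id, d.chrom, d.pos, p.allele, p.strand,
                         p.sequence, p.length, p.tm, d.context))
    return pd.DataFrame(rows, columns=[
        "snp_id", "chrom", "pos", "allele", "strand", "probe_seq",
        "length", "tm", "context"])


# ---------------------------------------------------------------------------
# annotation context
# ---------------------------------------------------------------------------

def annotate_snp_context(snps: pd.DataFrame, gff3_path_or_text) -> list[str]:
    """Label each SNP (rows with chrom, pos) as CDS, mRNA, or intergenic.

    CDS takes precedence over mRNA; anything outside both is intergenic.
    GFF3 intervals are 1-based inclusive.
    """
    import gffutils

    text = str(gff3_path_or_text)
    if "\n" not in text:
        with open(text) as fh:
            text = fh.read()
    try:
        db = gffutils.create_db(
            text, ":memory:", from_string=True, merge_strategy="create_unique",
            keep_order=True)
    except Exception as exc:  # surface parse failures with context
        raise InputError(f"malformed GFF3: {exc}") from exc

    intervals: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for ftype in ("CDS", "mRNA"):
        for feat in db.features_of_type(ftype):
            intervals.setdefault(ftype, {}).setdefault(feat.seqid, []).append(
                (feat.start, feat.end))

    labels = []
    for _, row in snps.iterrows():
        chrom, pos = str(row["chrom"]), int(row["pos"])
        label = "intergenic"
        for ftype, name in (("CDS", "CDS"), ("mRNA", "mRNA")):
            if any(a <= pos <= b for a, b in intervals.get(ftype, {}).get(chrom, [])):
                label = name
                break
        labels.append(label)
    return labels
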