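"""TSV / GFF3 / FASTA / VCF readers and writers for the pipeline's artifacts.

All tabular artifacts are tab-separated text; genotype matrices carry three
marker-metadata columns (marker_id, chrom, pos_mb) ahead of the sample
columns.  Formats are deliberately plain so runs diff cleanly.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SignalTensor


def write_genotypes(path, calls: pd.DataFrame, markers: pd.DataFrame | None = None):
    out = calls.copy()
    out.insert(0, "marker_id", out.index)
    if markers is not None:
        meta = markers.reindex(calls.index)
        out.insert(1, "chrom", meta["chrom"].values)
        out.insert(2, "pos_mb", meta["pos_mb"].values)
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_genotypes(path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    df = df.set_index("marker_id")
    meta = None
    meta_cols = [c for c in ("chrom", "pos_mb") if c in df.columns]
    if meta_cols:
        meta = df[meta_cols].copy()
        df = df.drop(columns=meta_cols)
    return df, meta


def write_matrix(path, df: pd.DataFrame, index_name: str = "marker_id"):
    df.rename_axis(index_name).to_csv(path, sep="\t", float_format="%.6g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_signals(path, tensor: SignalTensor):
    tensor.to_long().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_signals(path) -> SignalTensor:
    return SignalTensor.from_long(pd.read_csv(path, sep="\t"))


def write_pileup(path, pileup: pd.DataFrame):
    pileup.to_csv(path, sep="\t", index=False)


def read_pileup(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def write_fasta(path, sequences: dict, width: int = 80):
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {k: "".join(v) for k, v in seqs.items()}


def write_map(path, linkage_map, markers: pd.DataFrame | None = None):
    tab = linkage_map.table.copy()
    tab.insert(0, "marker_id", tab.index)
    if markers is not None:
        meta = markers.reindex(linkage_map.table.index)
        tab["chrom_true"] = meta["chrom"].values
        tab["pos_mb"] = meta["pos_mb"].values
    tab.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_map(path):
    from .mapping import LinkageMap
    df = pd.read_csv(path, sep="\t").set_index("marker_id")
    return LinkageMap(table=df)


_GT_CODE = {"AA": "0/0", "AB": "0/1", "BB": "1/1", "NC": "./."}


def write_vcf(path, calls: pd.DataFrame, markers: pd.DataFrame,
              ref_allele: str = "A", alt_allele: str = "B"):
    """Minimal VCF export of called genotypes (GT only).

    The array world is biallelic by construction, so the A/B alleles map to
    REF/ALT; positions are the marker Mb positions scaled to integer bp.
    """
    meta = markers.reindex(calls.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(calls.columns) + "\n")
        for mid in calls.index:
            pos = int(round(float(meta.at[mid, "pos_mb"]) * 1_000_000)) + 1
            gts = "\t".join(_GT_CODE.get(v, "./.") for v in calls.loc[mid])
            fh.write(f"{meta.at[mid, 'chrom']}\t{pos}\t{mid}\t{ref_allele}\t"
                     f"{alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def write_json(path, obj):
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
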