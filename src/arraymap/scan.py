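"""Genome scans on the refined map: local recombination rate, segregation
distortion, map-genome collinearity, and bin-polymorphism coverage.

The recombination profile Lowess-smooths genetic (cM) against physical (Mb)
position (span 0.1) and reports the least-squares slope over a five-marker
sliding window, in cM/Mb and log10(cM/Mb).  The distortion scan tests
p(AA) = p(BB) per marker by chi-square, controls the FDR with the
Benjamini-Hochberg step-up rule, and reports runs of at least three
consecutive significant markers sharing a favored allele as segregation-
distortion regions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


# ---------------------------------------------------------------------------
# local recombination rate
# ---------------------------------------------------------------------------

@dataclass
class RecombProfile:
    table: pd.DataFrame  # linkage_group, anchor, mid_mb, mid_cm, rate, log10_rate


_RATE_FLOOR = 1e-6  # cM/Mb; keeps log10 defined on flat/noisy stretches


def consistent_order_subset(mb: np.ndarray, cm: np.ndarray) -> np.ndarray:
    """Indices of the largest marker subset whose genetic order matches the
    physical order (longest nondecreasing subsequence, after orienting the
    group by rank correlation)."""
    mb = np.asarray(mb, float)
    cm = np.asarray(cm, float)
    order = np.argsort(cm, kind="stable")
    seq = mb[order]
    rho = stats.spearmanr(cm, mb).statistic if len(mb) > 2 else 1.0
    if rho is not None and not np.isnan(rho) and rho < 0:
        seq = -seq
    keep = _longest_nondecreasing(seq)
    return np.sort(order[keep])


def _longest_nondecreasing(seq: np.ndarray) -> np.ndarray:
    import bisect
    n = len(seq)
    tails: list[float] = []
    tail_idx: list[int] = []
    prev = np.full(n, -1)
    for i, x in enumerate(seq):
        j = bisect.bisect_right(tails, x)
        if j == len(tails):
            tails.append(x)
            tail_idx.append(i)
        else:
            tails[j] = x
            tail_idx[j] = i
        prev[i] = tail_idx[j - 1] if j > 0 else -1
    out = []
    i = tail_idx[-1]
    while i >= 0:
        out.append(i)
        i = prev[i]
    return np.array(out[::-1])


def local_recomb_rate(
    map_table: pd.DataFrame, physical_mb: pd.Series,
    span: float = 0.1, window: int = 5,
) -> RecombProfile:
    """Sliding-window recombination-rate profile per linkage group.

    ``map_table`` is a LinkageMap table (index marker_id, columns
    linkage_group, cm); ``physical_mb`` maps marker_id -> Mb.  Markers whose
    genetic order contradicts the physical order are removed, the cM-vs-Mb
    relation is Lowess-smoothed with the given span, and the slope of each
    ``window``-marker sliding window is reported (clamped to a small positive
    floor before the log10 transform).  Groups with fewer than ``window``
    consistent markers yield no windows.
    """
    rows = []
    for lg, sub in map_table.groupby("linkage_group"):
        sub = sub.copy()
        sub["mb"] = physical_mb.reindex(sub.index)
        sub = sub.dropna(subset=["mb"]).sort_values("cm", kind="stable")
        if len(sub) < window:
            continue
        keep = consistent_order_subset(sub["mb"].to_numpy(), sub["cm"].to_numpy())
        sub = sub.iloc[keep]
        if len(sub) < window:
            continue
        mb = sub["mb"].to_numpy()
        cm = sub["cm"].to_numpy()
        if stats.spearmanr(cm, mb).statistic < 0:
            mb = mb.max() - mb  # orient so cM increases with Mb
        smoothed = sm.nonparametric.lowess(cm, mb, frac=span, return_sorted=False)
        ids = list(sub.index)
        for k in range(len(sub) - window + 1):
            w = slice(k, k + window)
            x, y = mb[w], smoothed[w]
            if np.ptp(x) <= 0:
                continue
            slope = np.polyfit(x, y, 1)[0]
            rate = max(slope, _RATE_FLOOR)
            rows.append((lg, ids[k + window // 2], float(x.mean()),
                         float(y.mean()), rate, np.log10(rate)))
    table = pd.DataFrame(rows, columns=["linkage_group", "anchor", "mid_mb",
                                        "mid_cm", "rate", "log10_rate"])
    return RecombProfile(table=table)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values, alpha: float = 0.05):
    """Step-up FDR control; returns (reject mask, monotone q-values)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    passed = np.flatnonzero(p[order] <= alpha * np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if len(passed):
        reject[order[: passed[-1] + 1]] = True
    return reject, q


# ---------------------------------------------------------------------------
# segregation-distortion scan
# ---------------------------------------------------------------------------

@dataclass
class DistortionScan:
    records: pd.DataFrame   # marker rows: nAA, nBB, delta, chi2_p, bh_q, significant
    intervals: pd.DataFrame  # chrom, start_mb, end_mb, start/end markers, favored allele
    smooth: pd.DataFrame     # chrom, mb, delta_smooth (reporting only)


def segregation_scan(
    calls: pd.DataFrame, markers: pd.DataFrame, alpha: float = 0.05,
    min_run: int = 3, smooth: bool = True,
) -> DistortionScan:
    """Scan for segregation-distortion regions.

    Per marker the homozygous proportions p(AA), p(BB) are compared by
    chi-square under the null of equality (heterozygotes are excluded);
    Benjamini-Hochberg controls the FDR at ``alpha``.  Runs of at least
    ``min_run`` consecutive significant markers (in physical order, per
    chromosome) with the same favored allele become SDR intervals.  A cubic
    smoothing spline of delta = p(AA) - p(BB) against position is attached
    for reporting (``smooth=False`` skips it in bulk simulations).
    """
    arr = calls.to_numpy()
    naa = (arr == "AA").sum(axis=1).astype(float)
    nbb = (arr == "BB").sum(axis=1).astype(float)
    n = naa + nbb
    keep = n > 0
    idx = calls.index[keep]
    naa, nbb, n = naa[keep], nbb[keep], n[keep]
    delta = (naa - nbb) / n
    chi2 = (naa - nbb) ** 2 / n
    p = stats.chi2.sf(chi2, df=1)
    reject, q = benjamini_hochberg(p, alpha)
    records = pd.DataFrame({
        "nAA": naa.astype(int), "nBB": nbb.astype(int), "delta": delta,
        "chi2_p": p, "bh_q": q, "significant": reject,
    }, index=idx)
    meta = markers.reindex(idx)
    records["chrom"] = meta["chrom"]
    records["pos_mb"] = meta["pos_mb"]

    intervals = _sdr_intervals(records, min_run)
    smooth_df = (_smooth_delta(records) if smooth
                 else pd.DataFrame(columns=["chrom", "mb", "delta_smooth"]))
    return DistortionScan(records=records, intervals=intervals, smooth=smooth_df)


def _sdr_intervals(records: pd.DataFrame, min_run: int) -> pd.DataFrame:
    rows = []
    for chrom, sub in records.dropna(subset=["pos_mb"]).groupby("chrom"):
        sub = sub.sort_values("pos_mb", kind="stable")
        sig = sub["significant"].to_numpy()
        sign = np.sign(sub["delta"].to_numpy())
        start = None

        def _flush(start, stop):
            if start is not None and stop - start >= min_run:
                seg = sub.iloc[start:stop]
                rows.append((chrom, float(seg["pos_mb"].iloc[0]),
                             float(seg["pos_mb"].iloc[-1]),
                             seg.index[0], seg.index[-1],
                             "A" if sign[start] > 0 else "B", stop - start))

        for i in range(len(sub)):
            active = sig[i] and sign[i] != 0
            if start is not None and (not active or sign[i] != sign[start]):
                _flush(start, i)
                start = None
            if active and start is None:
                start = i
        _flush(start, len(sub))
    return pd.DataFrame(rows, columns=[
        "chrom", "start_mb", "end_mb", "start_marker", "end_marker",
        "favored_allele", "n_markers"])


def _smooth_delta(records: pd.DataFrame) -> pd.DataFrame:
    from scipy.interpolate import make_smoothing_spline
    rows = []
    for chrom, sub in records.dropna(subset=["pos_mb"]).groupby("chrom"):
        sub = sub.sort_values("pos_mb", kind="stable")
        x = sub["pos_mb"].to_numpy()
        y = sub["delta"].to_numpy()
        ux, inv = np.unique(x, return_inverse=True)
        if len(ux) < 5:
            continue
        uy = np.bincount(inv, weights=y) / np.bincount(inv)
        try:
            spl = make_smoothing_spline(ux, uy)
            ys = spl(ux)
        except Exception:
            ys = uy
        rows.extend((chrom, float(a), float(b)) for a, b in zip(ux, ys))
    return pd.DataFrame(rows, columns=["chrom", "mb", "delta_smooth"])


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

def collinearity(map_table: pd.DataFrame, markers: pd.DataFrame) -> pd.DataFrame:
    """Per-linkage-group R^2 of cM on Mb, plus chromosome-assignment accuracy.

    Orientation is resolved by the sign of the rank correlation (R^2 of a
    linear fit is orientation-invariant; the sign is reported).  The majority
    true chromosome of the group's markers defines the match fraction.
    """
    rows = []
    for lg, sub in map_table.groupby("linkage_group"):
        meta = markers.reindex(sub.index)
        cm = sub["cm"].to_numpy(dtype=float)
        mb = meta["pos_mb"].to_numpy(dtype=float)
        chroms = meta["chrom"]
        majority = chroms.mode().iloc[0]
        match = float((chroms == majority).mean())
        ok = ~(np.isnan(cm) | np.isnan(mb))
        if ok.sum() >= 3 and np.ptp(mb[ok]) > 0 and np.ptp(cm[ok]) > 0:
            rho = stats.spearmanr(cm[ok], mb[ok]).statistic
            r = stats.pearsonr(mb[ok], cm[ok]).statistic
            r2 = float(r ** 2)
        else:
            rho, r2 = np.nan, np.nan
        rows.append((lg, majority, match, float(np.sign(rho)) if rho == rho else np.nan,
                     r2, int(ok.sum())))
    return pd.DataFrame(rows, columns=[
        "linkage_group", "chrom", "chrom_match_fraction", "orientation",
        "r_squared", "n_markers"])


# ---------------------------------------------------------------------------
# bin polymorphism in non-parental accessions
# ---------------------------------------------------------------------------

def bin_polymorphism(map_table: pd.DataFrame, accession_calls: pd.DataFrame) -> dict:
    """Coverage of the map by bins containing accession-polymorphic markers.

    A marker is polymorphic when the accessions carry at least two distinct
    non-NC genotypes; a bin is covered when any member marker is polymorphic.
    Also reported: among non-polymorphic markers, the fraction whose bin
    offers a polymorphic replacement.
    """
    acc = accession_calls.reindex(map_table.index)

    def _poly(row):
        vals = {v for v in row if v != "NC" and v == v}
        return len(vals) >= 2

    poly = acc.apply(_poly, axis=1)
    tab = map_table.assign(polymorphic=poly)
    per_bin = tab.groupby(["linkage_group", "bin_index"])["polymorphic"].any()
    coverage = float(per_bin.mean()) if len(per_bin) else 0.0
    nonpoly = tab[~tab["polymorphic"]]
    if len(nonpoly):
        bin_ok = per_bin.reindex(
            pd.MultiIndex.from_frame(nonpoly[["linkage_group", "bin_index"]]))
        replaceable = float(np.asarray(bin_ok).mean())
    else:
        replaceable = float("nan")
    return {
        "bin_coverage": coverage,
        "n_bins": int(len(per_bin)),
        "n_polymorphic_bins": int(per_bin.sum()),
        "replaceable_fraction": replaceable,
        "per_bin": per_bin.reset_index().rename(columns={"polymorphic": "covered"}),
        "per_marker": tab[["linkage_group", "bin_index", "polymorphic"]],
    }
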