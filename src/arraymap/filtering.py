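"""Marker and sample filtering ahead of map construction.

Order of application (it affects the counts, so it is explicit): redundancy
deduplication -> low-confidence filter -> segregation filter -> sample QC.
The expected genotype distribution in a selfing series (F7:8: 63/128 AA,
2/128 AB, 63/128 BB) drives the segregation chi-square test.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

from .config import NC, ConfigError
from .calling import TrainingModels


@dataclass
class SegregationModel:
    """Expected genotype probabilities for generation ``t`` of a selfing series."""

    t: int
    probs: tuple[float, float, float]  # (pAA, pAB, pBB)


@dataclass
class FilterReport:
    """Audit trail: per-rule removal counts, in application order."""

    markers_redundant: int = 0
    markers_low_confidence: int = 0
    markers_distorted: int = 0
    samples_excess_het: int = 0
    samples_uninformative: int = 0
    samples_excess_nc_regions: int = 0
    dedup_groups: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("dedup_groups")
        return d


def expected_ril_probs(t: int, exact: bool = False):
    """(pAA, pAB, pBB) after ``t - 1`` selfing rounds from a heterozygous F1.

    Per locus and generation, AB -> 1/4 AA + 1/2 AB + 1/4 BB and homozygotes
    breed true, so pAB(t) = (1/2)**(t-1).  ``exact=True`` returns Fractions
    (t=7 gives 63/128, 2/128, 63/128).
    """
    if t < 2:
        raise ConfigError("selfing-generation index t must be >= 2")
    paa, pab, pbb = Fraction(0), Fraction(1), Fraction(0)
    for _ in range(t - 1):
        paa, pab, pbb = paa + pab / 4, pab / 2, pbb + pab / 4
    if exact:
        return paa, pab, pbb
    return float(paa), float(pab), float(pbb)


def segregation_model(t: int) -> SegregationModel:
    return SegregationModel(t=t, probs=expected_ril_probs(t))


# ---------------------------------------------------------------------------
# Bhattacharyya distance
# ---------------------------------------------------------------------------

def bhattacharyya_distance(mean1, cov1, mean2, cov2) -> float:
    """Bhattacharyya distance between two Gaussians.

    D = 1/8 (mu1-mu2)' Sbar^-1 (mu1-mu2) + 1/2 ln(det Sbar / sqrt(det S1 det S2)),
    Sbar = (S1 + S2) / 2.  Identical Gaussians give 0; identity covariances
    with mean separation delta give delta**2 / 8.
    """
    m1, m2 = np.asarray(mean1, float), np.asarray(mean2, float)
    s1, s2 = np.asarray(cov1, float), np.asarray(cov2, float)
    sbar = (s1 + s2) / 2.0
    det_bar = np.linalg.det(sbar)
    det1, det2 = np.linalg.det(s1), np.linalg.det(s2)
    if det_bar <= 0 or det1 <= 0 or det2 <= 0:
        raise ValueError("covariances must be positive-definite (regularize upstream)")
    diff = m1 - m2
    quad = diff @ np.linalg.solve(sbar, diff) / 8.0
    return float(quad + 0.5 * np.log(det_bar / np.sqrt(det1 * det2)))


def min_pairwise_separation(models: TrainingModels) -> pd.Series:
    """Per SNP: minimum Bhattacharyya distance over the three cluster pairs."""
    out = {}
    for i, sid in enumerate(models.snp_ids):
        if np.isnan(models.means[i]).any():
            out[sid] = np.nan
            continue
        ds = []
        for a, b in ((0, 1), (1, 2), (0, 2)):
            ds.append(bhattacharyya_distance(models.means[i, a], models.covs[i, a],
                                             models.means[i, b], models.covs[i, b]))
        out[sid] = min(ds)
    return pd.Series(out, name="min_bhattacharyya")


# ---------------------------------------------------------------------------
# marker filters
# ---------------------------------------------------------------------------

def dedup_redundant(
    calls: pd.DataFrame, models: TrainingModels | pd.Series,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """One representative per group of markers with identical call vectors.

    Grouping is exact equality of the genotype-call vector across all samples
    (including the no-call pattern).  The representative maximizes the minimum
    pairwise Bhattacharyya cluster separation, i.e. the marker with the most
    distinct signal clusters; ties keep the lexicographically smallest id.
    Group membership is recorded in ``report.dedup_groups`` for bin expansion.
    """
    sep = models if isinstance(models, pd.Series) else min_pairwise_separation(models)
    key = calls.apply(lambda row: "|".join(row.values), axis=1)
    keep, groups = [], {}
    for _, idx in sorted(calls.groupby(key).groups.items()):
        members = sorted(idx)
        scores = sep.reindex(members).fillna(-np.inf)
        best = scores.max()
        rep = min(m for m in members if scores[m] == best)  # deterministic tie-break
        keep.append(rep)
        groups[rep] = members
    if report is not None:
        report.markers_redundant = len(calls) - len(keep)
        report.dedup_groups = groups
    return calls.loc[sorted(keep)]


def low_confidence_counts(confidences: pd.DataFrame, conf_cutoff: float = 0.6) -> pd.Series:
    return (confidences <= conf_cutoff).sum(axis=1)


def filter_low_confidence(
    calls: pd.DataFrame, confidences: pd.DataFrame, conf_cutoff: float = 0.6,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Drop SNPs whose low-confidence call count exceeds median + 1 MAD.

    MAD is the raw (unscaled) median absolute deviation of the per-SNP counts.
    """
    counts = low_confidence_counts(confidences.loc[calls.index], conf_cutoff)
    med = counts.median()
    mad = (counts - med).abs().median()
    kept = calls[counts <= med + mad]
    if report is not None:
        report.markers_low_confidence = len(calls) - len(kept)
    return kept


def genotype_counts(calls: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame({
        "nAA": (calls == "AA").sum(axis=1),
        "nAB": (calls == "AB").sum(axis=1),
        "nBB": (calls == "BB").sum(axis=1),
    })
    out["n"] = out.sum(axis=1)
    return out


def segregation_pvalues(calls: pd.DataFrame, model: SegregationModel) -> pd.Series:
    """Goodness-of-fit p-value of each SNP's genotype counts against the
    selfing-series expectation.

    With all expected cells >= 5 (Cochran's rule) a three-category chi-square
    is used.  Below that -- the usual situation for the tiny expected AB count
    in late selfing generations, where the chi-square tail is badly inflated
    -- the test splits into an AA-vs-BB chi-square plus an exact one-sided
    binomial test for heterozygote excess, Bonferroni-combined
    (p = 2 * min(p_hom, p_het)); both components have valid small-count
    behavior.
    """
    counts = genotype_counts(calls)
    paa, pab, pbb = model.probs
    n = counts["n"].to_numpy(dtype=float)
    naa = counts["nAA"].to_numpy(dtype=float)
    nab = counts["nAB"].to_numpy(dtype=float)
    nbb = counts["nBB"].to_numpy(dtype=float)
    p = np.ones(len(counts))
    ok = n >= 2
    three = ok & (n * min(model.probs) >= 5.0)
    if three.any():
        e = np.stack([n[three] * paa, n[three] * pab, n[three] * pbb], axis=1)
        o = np.stack([naa[three], nab[three], nbb[three]], axis=1)
        stat = ((o - e) ** 2 / e).sum(axis=1)
        p[three] = stats.chi2.sf(stat, df=2)
    two = ok & ~three
    if two.any():
        m = naa[two] + nbb[two]
        # pAA == pBB, so the two-category statistic reduces to (nAA - nBB)^2 / m
        stat = np.where(m > 0, (naa[two] - nbb[two]) ** 2 / np.maximum(m, 1.0), 0.0)
        p_hom = stats.chi2.sf(stat, df=1)
        p_het = stats.binom.sf(nab[two] - 1, n[two].astype(int), pab)
        p[two] = np.minimum(1.0, 2.0 * np.minimum(p_hom, p_het))
    return pd.Series(p, index=calls.index, name="segregation_p")


def filter_segregation(
    calls: pd.DataFrame, model: SegregationModel, alpha: float = 0.05,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Remove SNPs deviating from the expected distribution (chi-square,
    Bonferroni-corrected across the tested SNPs)."""
    p = segregation_pvalues(calls, model)
    m = len(p)
    kept = calls[p >= alpha / m]
    if report is not None:
        report.markers_distorted = len(calls) - len(kept)
    return kept


# ---------------------------------------------------------------------------
# sample QC
# ---------------------------------------------------------------------------

def sample_qc(
    calls: pd.DataFrame, het_max: float = 0.2, hom_min: float = 0.15,
    nc_regions: pd.Series | None = None, max_nc_regions: int = 10,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Drop unusable samples.

    A sample is removed when its heterozygous proportion (among non-NC calls)
    exceeds ``het_max``, when its homozygous calls make up less than
    ``hom_min`` of all markers (uninformative, typically NC-heavy), or -- when
    post-refinement region counts are supplied -- when it has more than
    ``max_nc_regions`` no-call regions.
    """
    arr = calls.to_numpy()
    n_markers = arr.shape[0]
    het = (arr == "AB").sum(axis=0)
    hom = ((arr == "AA") | (arr == "BB")).sum(axis=0)
    informative = het + hom
    with np.errstate(invalid="ignore"):
        het_prop = np.where(informative > 0, het / np.maximum(informative, 1), 0.0)
    hom_prop = hom / n_markers
    drop_het = het_prop > het_max
    drop_hom = (hom_prop < hom_min) & ~drop_het
    keep = ~(drop_het | drop_hom)
    if nc_regions is not None:
        ncr = nc_regions.reindex(calls.columns).fillna(0).to_numpy()
        drop_nc = (ncr > max_nc_regions) & keep
        keep &= ~drop_nc
        if report is not None:
            report.samples_excess_nc_regions = int(drop_nc.sum())
    if report is not None:
        report.samples_excess_het = int(drop_het.sum())
        report.samples_uninformative = int(drop_hom.sum())
    return calls.loc[:, calls.columns[keep]]
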