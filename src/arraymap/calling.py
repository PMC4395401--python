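"""Training-set-based genotype calling.

For each SNP the 16 training hybridizations (six parent-A, five F1, five
parent-B, expected AA/AB/BB) are partitioned by k-means (k=3, deterministic
initialization at the expected-label group means).  A SNP passes as a good
training set (GTS) when every training point lands in the cluster of its
expected label, or exactly one point is misclustered; otherwise the model is
rejected.  Test points are assigned the label of the nearest cluster by
Mahalanobis distance, with confidence d1/(d1 + d0) (d0 = distance to the
nearest cluster, d1 = distance to the nearest of the remaining clusters), and
become no-calls below the confidence threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GENOTYPES, NC
from .signal import SummarizedSignals

GTS_PERFECT = "GTS_perfect"
GTS_ONE_OFF = "GTS_one_off"
REJECTED = "rejected"

_LABELS = np.array(GENOTYPES)


@dataclass
class TrainingModels:
    """Per-SNP three-cluster Gaussian models in (signal_A, signal_B) space.

    Cluster index 0/1/2 corresponds to label AA/AB/BB after majority-label
    assignment; ``gts_status`` is GTS_perfect / GTS_one_off / rejected.
    """

    snp_ids: list[str]
    means: np.ndarray              # (S, 3, 2)
    covs: np.ndarray               # (S, 3, 2, 2)
    gts_status: np.ndarray         # (S,) str
    miscluster_count: np.ndarray   # (S,) int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for i, sid in enumerate(self.snp_ids):
            row = {"snp_id": sid, "gts_status": self.gts_status[i],
                   "miscluster_count": int(self.miscluster_count[i])}
            for gi, g in enumerate(GENOTYPES):
                row[f"mean_{g}_A"] = self.means[i, gi, 0]
                row[f"mean_{g}_B"] = self.means[i, gi, 1]
            rows.append(row)
        return pd.DataFrame(rows).set_index("snp_id")


@dataclass
class TrainingModel:
    """Single-SNP view of a training model."""

    means: np.ndarray              # (3, 2) in AA/AB/BB order
    covs: np.ndarray               # (3, 2, 2)
    gts_status: str
    miscluster_count: int


@dataclass
class GenotypeCall:
    call: str
    confidence: float
    d0: float
    d1: float


def _batched_kmeans(points, valid, init, max_iter=100):
    """Lloyd iterations run in parallel over SNPs.

    points: (S, P, 2); valid: (S, P) bool; init: (S, 3, 2).
    Returns assignments (S, P) with -1 for invalid points.
    """
    S, P, _ = points.shape
    centers = init.copy()
    pts = np.where(valid[:, :, None], points, 0.0)
    assign = np.full((S, P), -1, dtype=np.int64)
    for _ in range(max_iter):
        d2 = np.einsum("spkd,spkd->spk",
                       points[:, :, None, :] - centers[:, None, :, :],
                       points[:, :, None, :] - centers[:, None, :, :])
        new_assign = np.where(valid, np.nanargmin(np.where(np.isnan(d2), np.inf, d2),
                                                  axis=2), -1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for k in range(3):
            mk = (assign == k) & valid
            cnt = mk.sum(axis=1)
            sums = np.einsum("sp,spd->sd", mk, pts)
            nonempty = cnt > 0
            centers[nonempty, k] = sums[nonempty] / cnt[nonempty, None]
    return assign, centers


def fit_training_models(
    train: SummarizedSignals, expected_labels: list[str],
    shrinkage: float = 0.1, min_per_label: int = 3,
) -> TrainingModels:
    """Fit three-cluster models for every SNP from the training hybridizations.

    Cluster labels come from the expected-label majority of their members; a
    SNP is rejected when two clusters claim the same majority label, a cluster
    is empty, fewer than ``min_per_label`` points per expected label survive
    masking, or more than one point disagrees with its expected label.
    Covariances are shrunk toward the pooled diagonal (weight ``shrinkage``)
    to stay positive-definite with 5-6 points per cluster.
    """
    points = train.points()                       # (S, P, 2)
    S, P, _ = points.shape
    exp = np.array([GENOTYPES.index(l) for l in expected_labels])
    valid = ~np.isnan(points).any(axis=2)

    # deterministic init: expected-label group means
    init = np.empty((S, 3, 2))
    for k in range(3):
        mk = valid & (exp[None, :] == k)
        cnt = np.maximum(mk.sum(axis=1), 1)
        init[:, k, :] = np.einsum("sp,spd->sd", mk,
                                  np.where(valid[:, :, None], points, 0.0)) / cnt[:, None]
    assign, _centers = _batched_kmeans(points, valid, init)

    means = np.full((S, 3, 2), np.nan)
    covs = np.zeros((S, 3, 2, 2))
    status = np.full(S, REJECTED, dtype=object)
    miscount = np.zeros(S, dtype=np.int64)

    label_counts = np.stack([(valid & (exp[None, :] == k)).sum(axis=1)
                             for k in range(3)], axis=1)
    for i in range(S):
        if (label_counts[i] < min_per_label).any():
            continue
        ok, mis = _assign_cluster_labels(points[i], valid[i], assign[i], exp,
                                         means, covs, i, shrinkage)
        miscount[i] = mis
        if not ok:
            continue
        if mis == 0:
            status[i] = GTS_PERFECT
        elif mis == 1:
            status[i] = GTS_ONE_OFF
    return TrainingModels(snp_ids=list(train.snp_ids), means=means, covs=covs,
                          gts_status=status.astype(str), miscluster_count=miscount)


def _assign_cluster_labels(pts, valid, assign, exp, means, covs, i, shrinkage):
    """Majority-label the clusters of one SNP; fill means/covs in label order.

    Returns (labels_ok, miscluster_count); labels_ok is False when clusters
    are empty or two clusters share a majority label.
    """
    cluster_label = np.full(3, -1)
    for k in range(3):
        members = (assign == k) & valid
        if not members.any():
            return False, int((assign[valid] != exp[valid]).sum())
        votes = np.bincount(exp[members], minlength=3)
        winners = np.flatnonzero(votes == votes.max())
        cluster_label[k] = winners[0]  # ties: lowest label index, deterministic
    if len(set(cluster_label)) != 3:
        mis = int(sum(cluster_label[assign[p]] != exp[p]
                      for p in np.flatnonzero(valid)))
        return False, mis
    mis = int(sum(cluster_label[assign[p]] != exp[p] for p in np.flatnonzero(valid)))
    # pooled per-axis variance for shrinkage target
    pooled = np.zeros(2)
    total = 0
    for k in range(3):
        members = (assign == k) & valid
        d = pts[members] - pts[members].mean(axis=0)
        pooled += (d ** 2).sum(axis=0)
        total += members.sum() - 1
    pooled = pooled / max(total, 1)
    target = np.diag(np.maximum(pooled, 1e-12))
    for k in range(3):
        lab = cluster_label[k]
        members = (assign == k) & valid
        mean = pts[members].mean(axis=0)
        if members.sum() >= 2:
            cov = np.cov(pts[members].T, ddof=1)
        else:
            cov = target.copy()
        cov = (1.0 - shrinkage) * cov + shrinkage * target + 1e-9 * np.eye(2)
        means[i, lab] = mean
        covs[i, lab] = cov
    return True, mis


def fit_training_model(
    points: np.ndarray, expected_labels: list[str], shrinkage: float = 0.1,
) -> TrainingModel:
    """Fit the model for a single SNP from its training points ((P, 2) array)."""
    summ = SummarizedSignals(snp_ids=["snp"], samples=[f"t{i}" for i in
                                                       range(len(points))],
                             signal_a=np.asarray(points, float)[None, :, 0],
                             signal_b=np.asarray(points, float)[None, :, 1])
    models = fit_training_models(summ, expected_labels, shrinkage=shrinkage)
    return TrainingModel(means=models.means[0], covs=models.covs[0],
                         gts_status=str(models.gts_status[0]),
                         miscluster_count=int(models.miscluster_count[0]))


def classify_gts(model: TrainingModel | TrainingModels):
    """GTS status from the label-agreement rule: 0 disagreements = perfect,
    exactly 1 = one-off, otherwise rejected."""
    return model.gts_status


# ---------------------------------------------------------------------------
# Mahalanobis calling
# ---------------------------------------------------------------------------

def _mahalanobis_distances(x, means, covs):
    """x: (N, 2); means: (3, 2); covs: (3, 2, 2) -> distances (N, 3)."""
    inv = np.linalg.inv(covs)
    diff = x[:, None, :] - means[None, :, :]
    d2 = np.einsum("nkd,kde,nke->nk", diff, inv, diff)
    return np.sqrt(np.maximum(d2, 0.0))


def call_genotype(point, model: TrainingModel, nc_threshold: float = 0.6) -> GenotypeCall:
    """Call one (signal_A, signal_B) point against a fitted training model."""
    if model.gts_status == REJECTED:
        raise ValueError("cannot call genotypes against a rejected model")
    x = np.asarray(point, dtype=float)
    if np.isnan(x).any():
        return GenotypeCall(NC, 0.0, np.nan, np.nan)
    d = _mahalanobis_distances(x[None], model.means, model.covs)[0]
    order = np.argsort(d, kind="stable")
    d0, d1 = d[order[0]], d[order[1]]
    conf = 0.5 if (d0 + d1) == 0 else d1 / (d0 + d1)
    call = _LABELS[order[0]] if conf > nc_threshold else NC
    return GenotypeCall(str(call), float(conf), float(d0), float(d1))


def call_genotypes(
    test: SummarizedSignals, models: TrainingModels, nc_threshold: float = 0.6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call all samples for every non-rejected SNP.

    Returns ``(calls, confidences)`` DataFrames (markers x samples); SNPs with
    rejected models are omitted.
    """
    keep = np.flatnonzero(models.gts_status != REJECTED)
    S, N = len(keep), len(test.samples)
    calls = np.full((S, N), NC, dtype=object)
    confs = np.zeros((S, N))
    pts = test.points()
    for row, i in enumerate(keep):
        x = pts[i]
        good = ~np.isnan(x).any(axis=1)
        if not good.any():
            continue
        d = _mahalanobis_distances(x[good], models.means[i], models.covs[i])
        order = np.argsort(d, axis=1, kind="stable")
        d0 = np.take_along_axis(d, order[:, :1], axis=1)[:, 0]
        d1 = np.take_along_axis(d, order[:, 1:2], axis=1)[:, 0]
        tot = d0 + d1
        conf = np.where(tot > 0, d1 / np.where(tot > 0, tot, 1.0), 0.5)
        lab = _LABELS[order[:, 0]]
        calls[row, good] = np.where(conf > nc_threshold, lab, NC)
        confs[row, good] = conf
    snp_ids = [models.snp_ids[i] for i in keep]
    return (pd.DataFrame(calls, index=snp_ids, columns=test.samples),
            pd.DataFrame(confs, index=snp_ids, columns=test.samples))
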