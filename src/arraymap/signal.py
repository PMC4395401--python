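"""Two-channel signal preprocessing and probe-replicate summarization.

Pipeline order: log2 transform -> quantile normalization between arrays ->
per-probe centering (subtract the probe's median over arrays) -> spatial-defect
masking on the slide grid -> median polish of the replicates x arrays matrix
per (SNP, allele), whose fitted per-array value (overall + column effect) is
the summarized signal.  Quantile normalization and probe centering are
idempotent; masking only removes values, it never alters retained ones.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .simulate import ArrayLayout, ArraySignals, SignalTensor


class SignalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: np.ndarray) -> np.ndarray:
    """Map every column onto the mean of the per-column order statistics.

    Missing entries (NaN) are excluded from rank computation and restored as
    NaN; ties receive the mid-rank (average) value.  After normalization the
    sorted non-missing values of complete columns are identical across arrays.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise SignalError("expected a probes x arrays matrix")
    n, m = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=0).all():
        raise SignalError("a column is entirely missing; cannot normalize")
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    for j in range(m):
        v = np.sort(X[obs[:, j], j])
        if len(v) == 1:
            ref += v[0]
        elif len(v) == n:
            ref += v
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, len(v)), v)
    ref /= m
    out = np.full_like(X, np.nan)
    for j in range(m):
        col = X[obs[:, j], j]
        nj = len(col)
        if nj == 1:
            out[obs[:, j], j] = ref[(n - 1) // 2]
            continue
        p = (rankdata(col, method="average") - 1.0) / (nj - 1.0)
        out[obs[:, j], j] = np.interp(p, grid, ref)
    return out


def center_probes(matrix: np.ndarray) -> np.ndarray:
    """Subtract each probe's median over arrays (row medians become 0)."""
    X = np.asarray(matrix, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        med = np.nanmedian(X, axis=1, keepdims=True)
    med = np.where(np.isnan(med), 0.0, med)
    return X - med


# ---------------------------------------------------------------------------
# spatial-defect masking
# ---------------------------------------------------------------------------

def mask_spatial_defects(
    values: np.ndarray, layout: ArrayLayout, radius: int = 3, k: float = 5.0,
    min_cluster: int = 5,
) -> np.ndarray:
    """Mask probes deviating from a local spatial median surface.

    For one array, each probe's residual from the median of its
    ``(2*radius+1)^2`` grid neighborhood is compared against ``k`` times the
    local median absolute deviation of those residuals.  Because genuine slide
    defects (scratches, bubbles) are spatially contiguous while biologically
    extreme probes are scattered by the randomized layout, flagged probes only
    become masked when they form a 4-connected grid cluster of at least
    ``min_cluster`` cells.  Returns a boolean mask aligned with ``values``
    (True = defective).
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] != len(layout.probe_ids):
        raise SignalError("layout does not cover all probes")
    n_rows, n_cols = layout.shape
    grid = np.full((n_rows, n_cols), np.nan)
    grid[layout.rows, layout.cols] = v
    filled = grid.copy()
    nanmask = np.isnan(grid)
    if nanmask.all():
        return np.zeros(len(v), dtype=bool)
    fill_value = np.nanmedian(grid)
    filled[nanmask] = fill_value
    size = 2 * radius + 1
    local_med = ndimage.median_filter(filled, size=size, mode="nearest")
    resid = filled - local_med
    local_mad = ndimage.median_filter(np.abs(resid), size=size, mode="nearest")
    scale = max(abs(fill_value), 1.0)
    floor = 1e-9 * scale  # uniform surfaces (MAD 0, residual 0) stay unmasked
    bad = np.abs(resid) > np.maximum(k * local_mad, floor)
    bad[nanmask] = False
    if min_cluster > 1 and bad.any():
        labels, n = ndimage.label(bad)  # 4-connectivity
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < min_cluster)
        bad &= ~np.isin(labels, small)
    return bad[layout.rows, layout.cols]


# ---------------------------------------------------------------------------
# median polish
# ---------------------------------------------------------------------------

def median_polish_batch(
    X: np.ndarray, max_iter: int = 10, tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Tukey median polish on a batch of matrices, NaN-tolerant.

    ``X`` has shape (groups, rows, cols); returns ``(overall, row_effects,
    col_effects, residuals)`` with shapes (G,), (G, R), (G, C), (G, R, C).
    Convergence: total absolute residual change below ``tol`` (per batch).
    """
    Z = np.array(X, dtype=float)
    G, R, C = Z.shape
    overall = np.zeros(G)
    row_eff = np.zeros((G, R))
    col_eff = np.zeros((G, C))
    last = np.nansum(np.abs(Z))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(max_iter):
            rm = np.nanmedian(Z, axis=2)
            rm = np.where(np.isnan(rm), 0.0, rm)
            Z -= rm[:, :, None]
            row_eff += rm
            delta = np.nanmedian(col_eff, axis=1)
            col_eff -= delta[:, None]
            overall += delta
            cm = np.nanmedian(Z, axis=1)
            cm = np.where(np.isnan(cm), 0.0, cm)
            Z -= cm[:, None, :]
            col_eff += cm
            delta = np.nanmedian(row_eff, axis=1)
            row_eff -= delta[:, None]
            overall += delta
            total = np.nansum(np.abs(Z))
            if abs(last - total) < tol:
                break
            last = total
    return overall, row_eff, col_eff, Z


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-8):
    """Median polish of a single rows x cols matrix (see batch version)."""
    o, r, c, z = median_polish_batch(np.asarray(matrix, float)[None], max_iter, tol)
    return o[0], r[0], c[0], z[0]


# ---------------------------------------------------------------------------
# summarization
# ---------------------------------------------------------------------------

@dataclass
class SummarizedSignals:
    """Per-SNP, per-sample (A-signal, B-signal) pairs on the processed
    (log2, normalized) scale, with a mask of unusable entries."""

    snp_ids: list[str]
    samples: list[str]
    signal_a: np.ndarray   # (S, N)
    signal_b: np.ndarray   # (S, N)

    @property
    def mask(self) -> np.ndarray:
        return np.isnan(self.signal_a) | np.isnan(self.signal_b)

    def points(self) -> np.ndarray:
        """Stack to (S, N, 2) signal points."""
        return np.stack([self.signal_a, self.signal_b], axis=-1)


def summarize_replicates(
    log2_matrix: np.ndarray, snp_ids: list[str], samples: list[str],
    max_iter: int = 10, tol: float = 1e-8,
) -> SummarizedSignals:
    """Summarize strand replicates by median polish, removing the array effect.

    ``log2_matrix`` is the processed probes x arrays matrix with probes ordered
    (snp, allele, strand) as produced by :func:`tensor_to_matrix`.  For each
    (SNP, allele) the 2 x n_arrays replicate matrix is polished and the fitted
    per-array value (overall + column effect) becomes the summary; entries with
    no unmasked replicate are masked.
    """
    S, N = len(snp_ids), len(samples)
    X = np.asarray(log2_matrix, float).reshape(S * 2, 2, N)
    overall, _rows, cols, _resid = median_polish_batch(X, max_iter=max_iter, tol=tol)
    fitted = overall[:, None] + cols                      # (S*2, N)
    all_missing = np.isnan(X).all(axis=1)                 # (S*2, N)
    fitted[all_missing] = np.nan
    fitted = fitted.reshape(S, 2, N)
    return SummarizedSignals(snp_ids=list(snp_ids), samples=list(samples),
                             signal_a=fitted[:, 0, :], signal_b=fitted[:, 1, :])


# ---------------------------------------------------------------------------
# end-to-end preprocessing
# ---------------------------------------------------------------------------

def tensor_to_matrix(tensor: SignalTensor) -> np.ndarray:
    """Flatten (S, allele, strand, N) intensities to a probes x arrays matrix."""
    s, a, t, n = tensor.values.shape
    return tensor.values.reshape(s * a * t, n)


def preprocess(
    signals: ArraySignals, radius: int = 3, k: float = 5.0,
    spatial_filter: bool = True,
) -> tuple[SummarizedSignals, SummarizedSignals]:
    """Run the full preprocessing chain on training + test arrays jointly.

    Returns ``(test_summaries, training_summaries)``.
    """
    test_m = tensor_to_matrix(signals.test)
    train_m = tensor_to_matrix(signals.training)
    X = np.log2(np.concatenate([test_m, train_m], axis=1))
    X = quantile_normalize(X)
    X = center_probes(X)
    if spatial_filter and signals.layout is not None:
        for j in range(X.shape[1]):
            bad = mask_spatial_defects(X[:, j], signals.layout, radius=radius, k=k)
            X[bad, j] = np.nan
    n_test = len(signals.test.samples)
    test = summarize_replicates(X[:, :n_test], signals.test.snp_ids,
                                signals.test.samples)
    train = summarize_replicates(X[:, n_test:], signals.training.snp_ids,
                                 signals.training.samples)
    return test, train
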