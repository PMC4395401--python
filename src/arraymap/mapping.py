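"""Binned linkage-map construction from filtered genotype calls.

Stages: pairwise recombination-fraction estimation over homozygous call pairs
(with the selfed-RIL correction r = R / (2(1 - R))), single-linkage grouping by
two-locus independence tests, marker ordering (exact for small groups, greedy
chain + 2-opt otherwise), and binning of cosegregating markers with cumulative
Haldane centimorgan positions.
"""
from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .config import NC, MapConfig


# ---------------------------------------------------------------------------
# Haldane mapping function
# ---------------------------------------------------------------------------

def haldane_cm(r) -> np.ndarray | float:
    """Map distance d = -50 ln(1 - 2r) cM; r >= 0.5 maps to infinity."""
    r = np.asarray(r, dtype=float)
    safe = np.minimum(r, np.nextafter(0.5, 0.0))
    d = np.where(r >= 0.5, np.inf, -50.0 * np.log1p(-2.0 * safe))
    return float(d) if d.ndim == 0 else d


def haldane_r(d) -> np.ndarray | float:
    """Inverse Haldane: r = (1 - exp(-d / 50)) / 2."""
    d = np.asarray(d, dtype=float)
    r = (1.0 - np.exp(-d / 50.0)) / 2.0
    return float(r) if r.ndim == 0 else r


def ril_observed_fraction(r) -> np.ndarray | float:
    """Expected observed recombinant fraction among selfed RILs: R = 2r/(1+2r)."""
    r = np.asarray(r, dtype=float)
    R = 2.0 * r / (1.0 + 2.0 * r)
    return float(R) if R.ndim == 0 else R


def ril_corrected_r(R) -> np.ndarray | float:
    """Invert the selfed-RIL accumulation: r = R / (2 (1 - R)), clamped to [0, 0.5)."""
    R = np.asarray(R, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(R < 1.0, R / (2.0 * np.maximum(1.0 - R, 1e-300)), np.inf)
    r = np.clip(r, 0.0, np.nextafter(0.5, 0.0))
    return float(r) if r.ndim == 0 else r


@functools.lru_cache(maxsize=None)
def _ril_fraction_table(t: int, n_grid: int = 512):
    r_grid = np.linspace(0.0, 0.4999, n_grid)
    R_grid = np.array([_ril_fraction_exact(r, t) for r in r_grid])
    return r_grid, R_grid


def _ril_fraction_exact(r: float, t: int) -> float:
    """Exact P(discordant | both loci homozygous) at selfing generation t.

    Two-locus transfer-matrix recursion: an individual is an ordered pair of
    two-locus gametes (16 states); a meiosis emits the parental haplotype with
    probability (1-r)/2 each and a recombinant with probability r/2 each, and
    selfing draws two independent gametes from the same parent.  As t grows
    this converges to the Haldane-Waddington limit R = 2r/(1+2r).
    """
    q = np.zeros((16, 4))
    for u in range(4):
        u1, u2 = divmod(u, 2)
        for v in range(4):
            v1, v2 = divmod(v, 2)
            s = u * 4 + v
            for (a, b), pr in (((u1, u2), (1 - r) / 2), ((u1, v2), r / 2),
                               ((v1, v2), (1 - r) / 2), ((v1, u2), r / 2)):
                q[s, a * 2 + b] += pr
    dist = np.zeros(16)
    dist[0 * 4 + 3] = 1.0  # F1: one fully-0 and one fully-1 haplotype
    for _ in range(t - 1):
        dist = np.einsum("s,sa,sb->ab", dist, q, q).ravel()
    hom = np.array([dist[g * 4 + g] for g in range(4)])
    total = hom.sum()
    return float((hom[1] + hom[2]) / total) if total > 0 else 0.0


def ril_observed_fraction_t(r, t: int):
    """Expected observed recombinant fraction among homozygous pairs at
    finite selfing generation t (exact recursion; see _ril_fraction_exact)."""
    r_grid, R_grid = _ril_fraction_table(int(t))
    r = np.asarray(r, dtype=float)
    R = np.interp(r, r_grid, R_grid)
    return float(R) if R.ndim == 0 else R


def ril_corrected_r_t(R, t: int):
    """Generation-aware inversion of the observed fraction, clamped to [0, 0.5).

    Repeated selfing stops adding crossovers once loci fix, so at finite t the
    observed fraction falls short of the Haldane-Waddington limit; the exact
    R_t(r) curve is inverted on a dense grid.
    """
    r_grid, R_grid = _ril_fraction_table(int(t))
    R = np.asarray(R, dtype=float)
    r = np.interp(R, R_grid, r_grid, left=0.0, right=np.nextafter(0.5, 0.0))
    r = np.clip(r, 0.0, np.nextafter(0.5, 0.0))
    return float(r) if r.ndim == 0 else r


# ---------------------------------------------------------------------------
# pairwise statistics
# ---------------------------------------------------------------------------

@dataclass
class PairwiseStats:
    """All-pairs recombination evidence over homozygous call pairs."""

    marker_ids: list[str]
    n_informative: np.ndarray    # (M, M) homozygous-pair sample counts
    n_discordant: np.ndarray     # (M, M)
    R: np.ndarray                # observed recombinant fraction (NaN if too few)
    r: np.ndarray                # meiotic fraction after RIL correction
    p_independence: np.ndarray   # two-locus independence-test p-values


def encode_calls(calls: pd.DataFrame) -> np.ndarray:
    """AA -> +1, BB -> -1, AB/NC -> 0 (hets and no-calls are uninformative)."""
    arr = calls.to_numpy()
    return np.where(arr == "AA", 1.0, np.where(arr == "BB", -1.0, 0.0))


def pairwise_stats(
    calls: pd.DataFrame, config: MapConfig | None = None,
) -> PairwiseStats:
    """Recombination fractions and independence tests for every marker pair.

    The observed fraction is R = discordant / informative over samples where
    both markers have homozygous calls; with ``ril_correction`` the meiotic
    fraction r = R / (2(1 - R)) undoes the crossover accumulation of repeated
    selfing.  Independence: chi-square on the 2x2 homozygous table with
    Fisher's exact fallback when any expected cell is below 5.  Pairs with
    fewer than ``min_informative`` samples are flagged unlinked (p = 1).
    """
    config = config or MapConfig()
    X = encode_calls(calls)
    A = (X > 0).astype(float)
    B = (X < 0).astype(float)
    aa = A @ A.T
    ab = A @ B.T
    ba = B @ A.T
    bb = B @ B.T
    n = aa + ab + ba + bb
    concord = aa + bb
    discord = ab + ba
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where(n > 0, discord / np.maximum(n, 1), np.nan)
    if not config.ril_correction:
        r = np.clip(R, 0.0, np.nextafter(0.5, 0.0))
    elif config.ril_generations is not None:
        r = ril_corrected_r_t(np.where(np.isnan(R), 0.0, R), config.ril_generations)
    else:
        r = ril_corrected_r(R)
    r = np.where(np.isnan(R), np.nan, r)

    p = _independence_pvalues(aa, ab, ba, bb, n, config.grouping_p_cutoff)
    too_few = n < config.min_informative
    R = np.where(too_few, np.nan, R)
    r = np.where(too_few, np.nan, r)
    p = np.where(too_few, 1.0, p)
    np.fill_diagonal(p, 0.0)
    return PairwiseStats(marker_ids=list(calls.index), n_informative=n,
                         n_discordant=discord, R=R, r=r, p_independence=p)


def _independence_pvalues(aa, ab, ba, bb, n, cutoff: float = 1e-10):
    row1 = aa + ab
    row2 = ba + bb
    col1 = aa + ba
    col2 = ab + bb
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = row1 * row2 * col1 * col2
        stat = np.where(denom > 0, n * (aa * bb - ab * ba) ** 2 /
                        np.maximum(denom, 1), 0.0)
    p = stats.chi2.sf(stat, df=1)
    # Exact fallback where the chi-square approximation breaks down: small
    # expected cells, or a p-value near the grouping cutoff (the extreme
    # chi-square tail is too crude to decide linkage there).  Linked RIL
    # markers are in coupling phase, so the exact test is the one-sided
    # (positive-association) hypergeometric tail, which vectorizes.
    with np.errstate(divide="ignore", invalid="ignore"):
        emin = np.where(n > 0, np.minimum(np.minimum(row1 * col1, row1 * col2),
                                          np.minimum(row2 * col1, row2 * col2))
                        / np.maximum(n, 1), 0.0)
    near_cutoff = (p > cutoff * 1e-8) & (p < cutoff * 1e6)
    need = ((emin < 5.0) | near_cutoff) & (n > 0)
    if need.any():
        p[need] = stats.hypergeom.sf(aa[need] - 1, n[need].astype(int),
                                     row1[need].astype(int),
                                     col1[need].astype(int))
    return p


def pairwise_recfrac(m1, m2, config: MapConfig | None = None):
    """(R_observed, r_meiotic) for two genotype vectors.

    Returns (NaN, NaN) when fewer than ``min_informative`` samples carry
    homozygous calls at both markers (the pair is then treated as unlinked).
    """
    config = config or MapConfig()
    calls = pd.DataFrame([list(m1), list(m2)], index=["_m1", "_m2"])
    ps = pairwise_stats(calls, config)
    return float(ps.R[0, 1]), float(ps.r[0, 1])


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------

def group_markers(
    calls: pd.DataFrame, config: MapConfig | None = None,
    pairwise: PairwiseStats | None = None,
) -> tuple[list[list[str]], list[str], PairwiseStats]:
    """Linkage groups as connected components of the significant-linkage graph.

    Markers exceeding the missing-call threshold are excluded up front.  Two
    markers connect when their independence-test p-value is below the grouping
    cutoff; components smaller than ``min_group_size`` are set aside as
    unmapped.  Groups are ordered by size (largest first), ties by smallest
    member id.
    """
    config = config or MapConfig()
    missing_frac = (calls == NC).mean(axis=1)
    usable = calls[missing_frac <= config.missing_threshold]
    if pairwise is None or pairwise.marker_ids != list(usable.index):
        pairwise = pairwise_stats(usable, config)
    adj = sparse.csr_matrix(pairwise.p_independence < config.grouping_p_cutoff)
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    ids = np.array(pairwise.marker_ids)
    groups, unmapped = [], []
    for c in range(n_comp):
        members = sorted(ids[labels == c])
        if len(members) >= config.min_group_size:
            groups.append(members)
        else:
            unmapped.extend(members)
    groups.sort(key=lambda g: (-len(g), g[0]))
    unmapped.extend(sorted(set(calls.index) - set(usable.index)))
    return groups, sorted(unmapped), pairwise


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

_EXACT_LIMIT = 7


def _adjacent_cost(order, rmat):
    idx = np.asarray(order)
    vals = rmat[idx[:-1], idx[1:]]
    return float(np.where(np.isnan(vals), 0.5, vals).sum())


def order_markers(
    group: list[str], pairwise: PairwiseStats, config: MapConfig | None = None,
) -> list[str]:
    """Order a linkage group to minimize the sum of adjacent meiotic
    recombination fractions.

    Groups of up to seven markers are solved exactly by enumeration; larger
    groups use greedy chain construction over ascending pairwise r followed by
    2-opt segment reversals until no improvement.  Ties break by ascending
    marker id and the output orientation is canonical (first id < last id), so
    the result is invariant to input order.
    """
    group = sorted(group)
    m = len(group)
    if m == 1:
        return list(group)
    pos = {mid: i for i, mid in enumerate(pairwise.marker_ids)}
    idx = np.array([pos[mid] for mid in group])
    rmat = pairwise.r[np.ix_(idx, idx)]
    rmat = np.where(np.isnan(rmat), 0.5, rmat)

    if m <= _EXACT_LIMIT:
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(m)):
            if perm[0] > perm[-1]:
                continue  # skip mirror orientations
            cost = _adjacent_cost(perm, rmat)
            if cost < best_cost - 1e-15 or (
                    abs(cost - best_cost) <= 1e-15 and (best is None or perm < best)):
                best, best_cost = perm, cost
        order = list(best)
    else:
        order = _greedy_chain(rmat)
        order = _two_opt(order, rmat)
    if order[0] > order[-1]:
        order.reverse()
    return [group[i] for i in order]


def _greedy_chain(rmat: np.ndarray) -> list[int]:
    """Join cheapest edges whose endpoints have free degree, avoiding cycles."""
    m = rmat.shape[0]
    edges = sorted(
        ((rmat[i, j], i, j) for i in range(m) for j in range(i + 1, m)),
        key=lambda e: (e[0], e[1], e[2]))
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    degree = [0] * m
    adjacency = [[] for _ in range(m)]
    n_edges = 0
    for _, i, j in edges:
        if degree[i] >= 2 or degree[j] >= 2 or find(i) == find(j):
            continue
        parent[find(i)] = find(j)
        adjacency[i].append(j)
        adjacency[j].append(i)
        degree[i] += 1
        degree[j] += 1
        n_edges += 1
        if n_edges == m - 1:
            break
    start = min(i for i in range(m) if degree[i] <= 1)
    order, prev, cur = [], -1, start
    while True:
        order.append(cur)
        nxt = [x for x in adjacency[cur] if x != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
    return order


def _two_opt(order: list[int], rmat: np.ndarray, max_passes: int = 100) -> list[int]:
    order = list(order)
    m = len(order)
    for _ in range(max_passes):
        improved = False
        for i in range(m - 1):
            for j in range(i + 1, m):
                before = 0.0
                after = 0.0
                if i > 0:
                    before += rmat[order[i - 1], order[i]]
                    after += rmat[order[i - 1], order[j]]
                if j < m - 1:
                    before += rmat[order[j], order[j + 1]]
                    after += rmat[order[i], order[j + 1]]
                if after < before - 1e-12:
                    order[i:j + 1] = order[i:j + 1][::-1]
                    improved = True
        if not improved:
            break
    return order


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

@dataclass
class LinkageMap:
    """Ordered bins per linkage group with cM positions and member markers."""

    table: pd.DataFrame  # marker_id (index), linkage_group, bin_index, cm
    unmapped: list[str] = field(default_factory=list)

    @property
    def linkage_groups(self) -> list[int]:
        return sorted(self.table["linkage_group"].unique())

    def group_length(self, lg: int) -> float:
        sub = self.table[self.table["linkage_group"] == lg]
        return float(sub["cm"].max())

    def total_length(self) -> float:
        return float(sum(self.group_length(lg) for lg in self.linkage_groups))

    def n_bins(self, lg: int | None = None) -> int:
        sub = self.table if lg is None else self.table[self.table["linkage_group"] == lg]
        return int(sub.groupby(["linkage_group", "bin_index"]).ngroups)

    def bins_frame(self) -> pd.DataFrame:
        g = self.table.groupby(["linkage_group", "bin_index"])
        return pd.DataFrame({
            "cm": g["cm"].first(),
            "n_markers": g.size(),
            "markers": g.apply(lambda s: ",".join(s.index)),
        }).reset_index()


def bin_markers(
    ordered: list[str], pairwise: PairwiseStats, lg: int,
    dedup_groups: dict | None = None,
) -> pd.DataFrame:
    """Merge adjacent markers with zero observed recombinants into bins and
    assign cumulative Haldane positions.

    ``dedup_groups`` (representative -> members, from the redundancy filter)
    re-attaches collapsed markers to their representative's bin.
    """
    pos = {mid: i for i, mid in enumerate(pairwise.marker_ids)}
    bins = [0]
    cms = [0.0]
    for a, b in zip(ordered[:-1], ordered[1:]):
        i, j = pos[a], pos[b]
        disc = pairwise.n_discordant[i, j]
        r = pairwise.r[i, j]
        if np.isnan(r):
            r = np.nextafter(0.5, 0.0)
        if disc == 0:
            bins.append(bins[-1])
            cms.append(cms[-1])
        else:
            bins.append(bins[-1] + 1)
            cms.append(cms[-1] + haldane_cm(r))
    rows = []
    for mid, b, cm in zip(ordered, bins, cms):
        members = (dedup_groups or {}).get(mid, [mid])
        for member in members:
            rows.append((member, lg, b, cm))
    return pd.DataFrame(rows, columns=["marker_id", "linkage_group", "bin_index",
                                       "cm"]).set_index("marker_id")


def build_map(
    calls: pd.DataFrame, config: MapConfig | None = None,
    dedup_groups: dict | None = None,
) -> LinkageMap:
    """Group, order, and bin filtered calls into a linkage map."""
    config = config or MapConfig()
    groups, unmapped, pairwise = group_markers(calls, config)
    tables = []
    for lg, group in enumerate(groups, start=1):
        ordered = order_markers(group, pairwise, config)
        tables.append(bin_markers(ordered, pairwise, lg, dedup_groups))
    if tables:
        table = pd.concat(tables)
    else:
        table = pd.DataFrame(columns=["linkage_group", "bin_index", "cm"])
        table.index.name = "marker_id"
    return LinkageMap(table=table, unmapped=unmapped)
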