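"""Linkage-map construction: Haldane functions, recombination fractions,
grouping, ordering, binning."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arraymap import (
    MapConfig,
    SimConfig,
    build_map,
    group_markers,
    haldane_cm,
    haldane_r,
    order_markers,
    pairwise_recfrac,
    pairwise_stats,
    ril_corrected_r,
    ril_observed_fraction,
    simulate_ril_population,
)
from arraymap.mapping import (
    PairwiseStats,
    _greedy_chain,
    _two_opt,
    bin_markers,
    ril_corrected_r_t,
    ril_observed_fraction_t,
)


class TestHaldane:
    def test_zero_and_reference_value(self):
        assert haldane_cm(0.0) == 0.0
        assert haldane_cm(0.25) == pytest.approx(-50 * np.log(0.5), abs=1e-9)
        assert haldane_cm(0.25) == pytest.approx(34.657, abs=1e-3)

    def test_roundtrip_identity(self):
        r = np.linspace(0.0, 0.49, 200)
        np.testing.assert_allclose(haldane_r(haldane_cm(r)), r, atol=1e-12)

    def test_half_maps_to_infinity(self):
        assert np.isinf(haldane_cm(0.5))

    def test_ril_correction_inverts_observed_fraction(self):
        assert ril_corrected_r(1 / 3) == pytest.approx(0.25)
        r = np.linspace(0.0, 0.45, 50)
        np.testing.assert_allclose(ril_corrected_r(ril_observed_fraction(r)), r,
                                   atol=1e-12)

    def test_finite_generation_curve_and_limit(self):
        # generation-aware curve inverts itself and approaches the classic
        # Haldane-Waddington limit as t grows
        r = np.linspace(0.0, 0.45, 30)
        np.testing.assert_allclose(
            ril_corrected_r_t(ril_observed_fraction_t(r, 7), 7), r, atol=1e-6)
        np.testing.assert_allclose(ril_observed_fraction_t(r, 300),
                                   ril_observed_fraction(r), atol=1e-4)
        assert (ril_observed_fraction_t(r[1:], 7)
                < ril_observed_fraction(r[1:])).all()

    def test_finite_generation_curve_matches_independent_simulation(self):
        """Forward simulation of two-locus selfing, coded independently of the
        transfer-matrix recursion."""
        rng = np.random.default_rng(0)
        for r in (0.02, 0.0906, 0.25):
            n = 120_000
            H = np.zeros((n, 2, 2), dtype=np.int8)
            H[:, 1, :] = 1

            def gam(H):
                m = H.shape[0]
                start = rng.integers(2, size=m)
                sec = (start + (rng.random(m) < r)) % 2
                g = np.empty((m, 2), np.int8)
                g[:, 0] = H[np.arange(m), start, 0]
                g[:, 1] = H[np.arange(m), sec, 1]
                return g

            for _ in range(6):  # t = 7
                H = np.stack([gam(H), gam(H)], axis=1)
            geno = H.sum(axis=1)
            hom = ((geno == 0) | (geno == 2)).all(axis=1)
            loc = geno[hom] // 2
            got = (loc[:, 0] != loc[:, 1]).mean()
            exp = ril_observed_fraction_t(r, 7)
            se = np.sqrt(exp * (1 - exp) / hom.sum())
            assert abs(got - exp) < 4 * se


def _frame(rows, ids=None):
    ids = ids or [f"m{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids,
                        columns=[f"s{j}" for j in range(len(rows[0]))])


class TestPairwiseRecfrac:
    CFG = MapConfig(ril_generations=None)

    def test_identical_vectors(self):
        v = ["AA", "BB", "AA", "BB"] * 3
        R, r = pairwise_recfrac(v, v, self.CFG)
        assert R == 0.0 and r == 0.0

    def test_observed_third_corrects_to_quarter(self):
        a = ["AA"] * 12
        b = ["AA"] * 8 + ["BB"] * 4  # R = 4/12 = 1/3
        R, r = pairwise_recfrac(a, b, self.CFG)
        assert R == pytest.approx(1 / 3)
        assert r == pytest.approx(0.25)

    def test_hets_and_nc_excluded(self):
        a = ["AA"] * 10 + ["AB", "NC"]
        b = ["AA"] * 8 + ["BB"] * 2 + ["AA", "BB"]
        R, r = pairwise_recfrac(a, b, self.CFG)
        assert R == pytest.approx(0.2)

    def test_too_few_informative_flagged(self):
        a = ["AA"] * 5 + ["NC"] * 10
        b = ["AA"] * 5 + ["NC"] * 10
        R, r = pairwise_recfrac(a, b, self.CFG)
        assert np.isnan(R) and np.isnan(r)

    def test_independent_markers_near_half(self):
        rng = np.random.default_rng(1)
        a = rng.choice(["AA", "BB"], size=600)
        b = rng.choice(["AA", "BB"], size=600)
        R, r = pairwise_recfrac(a, b, self.CFG)
        assert abs(R - 0.5) < 3 * np.sqrt(0.25 / 600)


class TestGrouping:
    def test_two_chromosomes_two_groups(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(100, 80),
                        n_rils=100, seed=21)
        calls, truth = simulate_ril_population(cfg)
        groups, unmapped, _ = group_markers(calls)
        assert len(groups) == 2
        for g in groups:
            chroms = truth.markers.loc[g, "chrom"].unique()
            assert len(chroms) == 1
        got = {truth.markers.loc[g[0], "chrom"]: set(g) for g in groups}
        for chrom, members in got.items():
            expected = set(truth.markers[truth.markers["chrom"] == chrom].index)
            assert members == expected

    def test_cosegregating_markers_one_group(self):
        rng = np.random.default_rng(2)
        base = rng.choice(["AA", "BB"], size=40)
        calls = _frame([list(base)] * 6)
        groups, unmapped, _ = group_markers(calls)
        assert len(groups) == 1 and len(groups[0]) == 6

    def test_excess_missing_excluded_before_grouping(self):
        rng = np.random.default_rng(3)
        base = list(rng.choice(["AA", "BB"], size=40))
        noisy = list(base)
        noisy[:8] = ["NC"] * 8  # 20% missing
        calls = _frame([base, base, noisy])
        groups, unmapped, _ = group_markers(calls)
        assert "m2" in unmapped
        assert all("m2" not in g for g in groups)


class TestOrdering:
    @staticmethod
    def _stats(rmat, ids):
        m = len(ids)
        return PairwiseStats(marker_ids=list(ids), n_informative=np.full((m, m), 100),
                             n_discordant=np.ceil(rmat * 100), R=rmat, r=rmat,
                             p_independence=np.zeros((m, m)))

    @staticmethod
    def _brute_force(rmat):
        m = rmat.shape[0]
        best, best_cost = None, np.inf
        for perm in itertools.permutations(range(m)):
            cost = sum(rmat[perm[i], perm[i + 1]] for i in range(m - 1))
            if cost < best_cost:
                best, best_cost = perm, cost
        return best, best_cost

    @pytest.mark.parametrize("m", [2, 3, 4, 5, 6, 7])
    def test_small_groups_attain_enumeration_minimum(self, m):
        rng = np.random.default_rng(m)
        for _ in range(8):
            rmat = rng.uniform(0.0, 0.5, size=(m, m))
            rmat = (rmat + rmat.T) / 2
            np.fill_diagonal(rmat, 0.0)
            ids = [f"m{i}" for i in range(m)]
            ps = self._stats(rmat, ids)
            order = order_markers(ids, ps)
            idx = [ids.index(x) for x in order]
            cost = sum(rmat[idx[i], idx[i + 1]] for i in range(m - 1))
            _, best_cost = self._brute_force(rmat)
            assert cost == pytest.approx(best_cost, abs=1e-12)

    def test_heuristic_path_matches_enumeration_on_small_groups(self):
        """The greedy + 2-opt route (used above the exact-size limit) also
        attains the optimum on clean distance-like matrices."""
        rng = np.random.default_rng(17)
        for trial in range(10):
            m = 7
            pos = np.sort(rng.uniform(0, 50, size=m))
            rmat = haldane_r(np.abs(pos[:, None] - pos[None, :]))
            order = _two_opt(_greedy_chain(rmat), rmat)
            cost = sum(rmat[order[i], order[i + 1]] for i in range(m - 1))
            _, best_cost = self._brute_force(rmat)
            assert cost == pytest.approx(best_cost, abs=1e-12)

    def test_input_order_and_reversal_invariance(self):
        rng = np.random.default_rng(4)
        m = 9
        rmat = rng.uniform(0.0, 0.5, size=(m, m))
        rmat = (rmat + rmat.T) / 2
        np.fill_diagonal(rmat, 0.0)
        ids = [f"m{i}" for i in range(m)]
        ps = self._stats(rmat, ids)
        o1 = order_markers(ids, ps)
        o2 = order_markers(ids[::-1], ps)
        assert o1 == o2
        assert o1[0] < o1[-1]  # canonical orientation

    def test_simulated_order_recovered(self, map_config):
        calls, truth = simulate_ril_population(map_config)
        lmap = build_map(calls)
        tab = lmap.table[lmap.table["linkage_group"] == 1]
        true_cm = truth.markers["pos_cm"].reindex(tab.index)
        rho = stats.spearmanr(np.arange(len(tab)), true_cm).statistic
        assert abs(rho) >= 0.99


class TestBinning:
    def test_cosegregating_markers_single_bin(self):
        rng = np.random.default_rng(5)
        base = rng.choice(["AA", "BB"], size=30)
        calls = _frame([list(base)] * 4)
        ps = pairwise_stats(calls)
        bins = bin_markers(list(calls.index), ps, lg=1)
        assert bins["bin_index"].nunique() == 1
        assert (bins["cm"] == 0.0).all()

    def test_recombinant_markers_split_bins(self, map_config):
        calls, truth = simulate_ril_population(map_config)
        lmap = build_map(calls)
        bins = lmap.table.groupby("bin_index")["cm"].first()
        assert (np.diff(bins.sort_index().to_numpy()) > 0).all()
        # final position equals the accumulated inter-bin distances
        assert lmap.total_length() == pytest.approx(lmap.table["cm"].max())

    def test_dedup_members_reattached(self):
        rng = np.random.default_rng(6)
        base = rng.choice(["AA", "BB"], size=30)
        calls = _frame([list(base)] * 2, ids=["m0", "m1"])
        ps = pairwise_stats(calls)
        bins = bin_markers(["m0", "m1"], ps, lg=1,
                           dedup_groups={"m0": ["m0", "m9"], "m1": ["m1"]})
        assert "m9" in bins.index
        assert bins.at["m9", "bin_index"] == bins.at["m0", "bin_index"]


class TestMapRecovery:
    def test_length_recovered_on_average(self):
        # single-replicate lengths carry ~7% Monte-Carlo error from the
        # breakpoint-count randomness; average a few replicates
        ratios = []
        for seed in range(5, 10):
            cfg = SimConfig(n_chromosomes=1, chrom_length_cm=100.0,
                            chrom_length_mb=30.0, n_markers=200, n_rils=120,
                            seed=seed)
            calls, truth = simulate_ril_population(cfg)
            lmap = build_map(calls)
            assert len(lmap.linkage_groups) == 1
            span = truth.markers["pos_cm"].max() - truth.markers["pos_cm"].min()
            ratios.append(lmap.total_length() / span)
        assert abs(np.mean(ratios) - 1.0) < 0.15

    def test_length_invariant_under_allele_relabeling(self, map_config):
        calls, _ = simulate_ril_population(map_config)
        swapped = calls.replace({"AA": "BB", "BB": "AA"})
        l1 = build_map(calls).total_length()
        l2 = build_map(swapped).total_length()
        assert l1 == pytest.approx(l2)

    def test_correction_off_inflates_map(self, map_config):
        calls, _ = simulate_ril_population(map_config)
        on = build_map(calls, MapConfig()).total_length()
        off = build_map(calls, MapConfig(ril_correction=False)).total_length()
        assert off > on
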