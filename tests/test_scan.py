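"""Genome scans: recombination profile, distortion scan, BH, collinearity,
bin polymorphism."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from arraymap import (
    Hotspot,
    SdrSpec,
    SimConfig,
    benjamini_hochberg,
    bin_polymorphism,
    build_map,
    collinearity,
    local_recomb_rate,
    segregation_scan,
    simulate_ril_population,
)
from arraymap.scan import consistent_order_subset
from arraymap.simulate import simulate_accession_calls


class TestRecombProfile:
    def _table(self, cm, lg=1):
        idx = [f"m{i}" for i in range(len(cm))]
        return pd.DataFrame({"linkage_group": lg, "cm": cm}, index=idx)

    def test_linear_map_constant_rate(self):
        mb = pd.Series(np.linspace(0, 20, 40), index=[f"m{i}" for i in range(40)])
        table = self._table(3.0 * mb.to_numpy())
        prof = local_recomb_rate(table, mb)
        np.testing.assert_allclose(prof.table["rate"], 3.0, rtol=1e-6)
        np.testing.assert_allclose(prof.table["log10_rate"], np.log10(3.0),
                                   atol=1e-6)

    def test_too_few_markers_empty_profile(self):
        mb = pd.Series([0.0, 1.0, 2.0], index=["m0", "m1", "m2"])
        prof = local_recomb_rate(self._table([0.0, 1.0, 2.0]), mb)
        assert prof.table.empty

    def test_mean_window_rate_tracks_global_slope(self, map_config):
        calls, truth = simulate_ril_population(map_config)
        lmap = build_map(calls)
        prof = local_recomb_rate(lmap.table, truth.markers["pos_mb"])
        global_rate = lmap.total_length() / (
            truth.markers["pos_mb"].max() - truth.markers["pos_mb"].min())
        assert abs(prof.table["rate"].mean() - global_rate) / global_rate < 0.10

    def test_hotspot_found_at_peak(self):
        cfg = SimConfig(n_chromosomes=1, chrom_length_cm=100.0,
                        chrom_length_mb=30.0, n_markers=200, n_rils=120, seed=2,
                        hotspots=(Hotspot("chr1", 10.0, 14.0, 5.0),))
        calls, truth = simulate_ril_population(cfg)
        lmap = build_map(calls)
        prof = local_recomb_rate(lmap.table, truth.markers["pos_mb"])
        peak = prof.table.loc[prof.table["rate"].idxmax()]
        assert 10.0 <= peak["mid_mb"] <= 14.0

    def test_order_inconsistent_markers_removed(self):
        mb = np.array([0.0, 1.0, 2.0, 50.0, 3.0, 4.0, 5.0])
        cm = np.arange(7.0)
        keep = consistent_order_subset(mb, cm)
        assert 3 not in keep and len(keep) == 6


class TestBenjaminiHochberg:
    @staticmethod
    def brute_force(p, alpha):
        """Literal step-up rule, coded independently."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        k = 0
        for i, idx in enumerate(order, start=1):
            if p[idx] <= alpha * i / m:
                k = i
        reject = np.zeros(m, dtype=bool)
        reject[order[:k]] = True
        return reject

    def test_example_all_rejected(self):
        reject, q = benjamini_hochberg([0.01, 0.02, 0.04], alpha=0.05)
        assert reject.all()

    def test_all_ones_none_rejected(self):
        reject, _ = benjamini_hochberg(np.ones(10))
        assert not reject.any()

    def test_qvalue_thresholding_equals_step_up(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            reject, q = benjamini_hochberg(p, alpha=0.1)
            np.testing.assert_array_equal(reject, q <= 0.1)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            m = int(rng.integers(1, 30))
            p = np.round(rng.uniform(size=m), 3)  # ties occur
            reject, _ = benjamini_hochberg(p, alpha=0.05)
            np.testing.assert_array_equal(reject, self.brute_force(p, 0.05))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=500) ** 2
        reject, q = benjamini_hochberg(p, alpha=0.05)
        sm_rej, sm_q, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, sm_rej)
        np.testing.assert_allclose(q, sm_q, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])


class TestDistortionScan:
    def test_hand_computed_chi_square(self):
        calls = pd.DataFrame([["AA"] * 80 + ["BB"] * 30],
                             index=["m0"], columns=[f"s{i}" for i in range(110)])
        markers = pd.DataFrame({"chrom": ["chr1"], "pos_mb": [1.0]}, index=["m0"])
        scan = segregation_scan(calls, markers)
        rec = scan.records.iloc[0]
        assert rec["nAA"] == 80 and rec["nBB"] == 30
        stat = (80 - 30) ** 2 / 110  # = 2 * 25**2 / 55 ~ 22.7
        assert stat == pytest.approx(22.727, abs=1e-3)
        assert rec["chi2_p"] == pytest.approx(stats.chi2.sf(stat, 1))
        assert rec["delta"] == pytest.approx(50 / 110)

    def test_delta_sign_tracks_favored_allele(self):
        rng = np.random.default_rng(3)
        calls = pd.DataFrame(rng.choice(["AA", "BB"], p=[0.7, 0.3],
                                        size=(50, 100)),
                             index=[f"m{i}" for i in range(50)])
        markers = pd.DataFrame({"chrom": "chr1", "pos_mb": np.arange(50.0)},
                               index=calls.index)
        scan = segregation_scan(calls, markers)
        sig = scan.records[scan.records["significant"]]
        assert (np.sign(sig["delta"]) > 0).all()
        if len(scan.intervals):
            assert (scan.intervals["favored_allele"] == "A").all()

    def test_injected_sdr_interval_recovered(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(150, 150),
                        n_rils=120, seed=4,
                        sdr_spec=SdrSpec("chr1", 10.0, 12.0, 3.0))
        calls, truth = simulate_ril_population(cfg)
        scan = segregation_scan(calls, truth.markers)
        iv = scan.intervals
        hit = ((iv["chrom"] == "chr1") & (iv["start_mb"] <= 12.0)
               & (iv["end_mb"] >= 10.0) & (iv["favored_allele"] == "A"))
        assert hit.any()

    def test_distortion_free_population_yields_no_intervals(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(150, 150),
                        n_rils=120, seed=5)
        calls, truth = simulate_ril_population(cfg)
        scan = segregation_scan(calls, truth.markers)
        assert len(scan.intervals) == 0

    def test_all_nc_marker_excluded(self):
        calls = pd.DataFrame([["NC"] * 10, ["AA"] * 6 + ["BB"] * 4],
                             index=["m0", "m1"])
        markers = pd.DataFrame({"chrom": "chr1", "pos_mb": [1.0, 2.0]},
                               index=calls.index)
        scan = segregation_scan(calls, markers)
        assert list(scan.records.index) == ["m1"]


class TestCollinearity:
    def _map(self, cm, mb, lg=1, chrom="chr1"):
        idx = [f"m{i}" for i in range(len(cm))]
        table = pd.DataFrame({"linkage_group": lg, "bin_index": range(len(cm)),
                              "cm": cm}, index=idx)
        markers = pd.DataFrame({"chrom": chrom, "pos_mb": mb}, index=idx)
        return table, markers

    def test_perfectly_linear_map(self):
        mb = np.linspace(0, 25, 40)
        table, markers = self._map(3.0 * mb, mb)
        out = collinearity(table, markers)
        assert out["r_squared"].iloc[0] == pytest.approx(1.0)
        assert out["chrom_match_fraction"].iloc[0] == 1.0

    def test_reversed_orientation_still_r2_one(self):
        mb = np.linspace(0, 25, 40)
        table, markers = self._map(3.0 * (25 - mb), mb)
        out = collinearity(table, markers)
        assert out["r_squared"].iloc[0] == pytest.approx(1.0)
        assert out["orientation"].iloc[0] == -1.0

    def test_permuted_positions_r2_near_zero(self):
        rng = np.random.default_rng(6)
        mb = np.linspace(0, 25, 200)
        table, markers = self._map(3.0 * mb, rng.permutation(mb))
        out = collinearity(table, markers)
        assert out["r_squared"].iloc[0] < 0.05

    def test_noise_free_simulated_map_r2(self, map_config):
        calls, truth = simulate_ril_population(map_config)
        lmap = build_map(calls)
        out = collinearity(lmap.table, truth.markers)
        assert (out["r_squared"] >= 0.99).all()
        assert (out["chrom_match_fraction"] == 1.0).all()


class TestBinPolymorphism:
    def _map_table(self, bins):
        idx = [f"m{i}" for i in range(len(bins))]
        return pd.DataFrame({"linkage_group": 1, "bin_index": bins,
                             "cm": np.arange(len(bins), dtype=float)}, index=idx)

    def test_counting_example(self):
        # 10 bins, one marker each; 8 polymorphic
        table = self._map_table(list(range(10)))
        acc = pd.DataFrame("AA", index=table.index, columns=["a1", "a2"])
        acc.iloc[:8, 1] = "BB"
        out = bin_polymorphism(table, acc)
        assert out["bin_coverage"] == pytest.approx(0.8)

    def test_all_monomorphic_zero_coverage(self):
        table = self._map_table([0, 0, 1, 1])
        acc = pd.DataFrame("BB", index=table.index, columns=["a1", "a2", "a3"])
        out = bin_polymorphism(table, acc)
        assert out["bin_coverage"] == 0.0
        assert out["replaceable_fraction"] == 0.0

    def test_shared_bin_marker_is_replaceable(self):
        table = self._map_table([0, 0])
        acc = pd.DataFrame({"a1": ["AA", "AA"], "a2": ["AA", "BB"]},
                           index=table.index)  # m0 mono, m1 poly, same bin
        out = bin_polymorphism(table, acc)
        assert out["bin_coverage"] == 1.0
        assert out["replaceable_fraction"] == 1.0

    def test_simulated_accessions_coverage_reasonable(self, map_config):
        calls, truth = simulate_ril_population(map_config)
        lmap = build_map(calls)
        acc = simulate_accession_calls(truth.markers, config=map_config)
        out = bin_polymorphism(lmap.table, acc)
        assert 0.5 < out["bin_coverage"] <= 1.0
        assert out["replaceable_fraction"] >= out["bin_coverage"] - 0.5
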