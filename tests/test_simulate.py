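"""Synthetic-data generator: selfing-series genetics, signals, pileups."""
import numpy as np
import pandas as pd
import pytest

from arraymap import (
    ConfigError,
    SdrSpec,
    SimConfig,
    apply_segregation_distortion,
    simulate_array_signals,
    simulate_design_world,
    simulate_read_pileup,
    simulate_ril_population,
)
from arraymap.mapping import haldane_r, ril_observed_fraction_t
from arraymap.probes import select_window_snps
from arraymap.simulate import simulate_accession_calls


def test_zero_length_chromosome_has_no_recombinants():
    cfg = SimConfig(n_chromosomes=1, chrom_length_cm=0.0, chrom_length_mb=5.0,
                    n_markers=50, n_rils=40, seed=9)
    calls, _ = simulate_ril_population(cfg)
    for col in calls.columns:
        assert calls[col].nunique() == 1


def test_invalid_config_rejected():
    with pytest.raises(ConfigError):
        SimConfig(n_markers=0)
    with pytest.raises(ConfigError):
        SimConfig(n_rils=-1)
    with pytest.raises(ConfigError):
        SimConfig(generations=1)
    with pytest.raises(ConfigError):
        SimConfig(miscluster_rate=1.5)


def test_simulation_is_bit_reproducible(small_config):
    a1, t1 = simulate_ril_population(small_config)
    a2, t2 = simulate_ril_population(small_config)
    assert a1.equals(a2)
    assert t1.markers.equals(t2.markers)
    s1 = simulate_array_signals(a1, small_config)
    s2 = simulate_array_signals(a2, small_config)
    np.testing.assert_array_equal(s1.test.values, s2.test.values)
    p1 = simulate_read_pileup(small_config)
    p2 = simulate_read_pileup(small_config)
    assert p1.equals(p2)


def test_marker_positions_monotone(small_population):
    _, truth = small_population
    for _, sub in truth.markers.groupby("chrom"):
        assert (np.diff(sub["pos_mb"]) > 0).all()
        assert (np.diff(sub["pos_cm"]) >= 0).all()


@pytest.mark.parametrize("t", range(2, 9))
def test_heterozygosity_decays_by_halving(t):
    """Residual heterozygosity after t-1 selfing rounds is (1/2)**(t-1)."""
    cfg = SimConfig(n_chromosomes=4, chrom_length_cm=2000.0, chrom_length_mb=30.0,
                    n_markers=60, n_rils=150, generations=t, seed=20 + t)
    calls, _ = simulate_ril_population(cfg)
    het = (calls == "AB").to_numpy().mean()
    p = 0.5 ** (t - 1)
    se = np.sqrt(p * (1 - p) / calls.size)
    assert abs(het - p) < 3.5 * se


def test_pair_recombinant_fraction_matches_exact_recursion():
    """Observed RIL recombinant fraction agrees with the two-locus selfing
    recursion (and approaches 1/2 for distant loci)."""
    rng = np.random.default_rng(0)
    for d_cm, seed in ((10.0, 1), (40.0, 2)):
        disc = tot = 0
        for rep in range(6):
            cfg = SimConfig(n_chromosomes=1, chrom_length_cm=2 * d_cm,
                            chrom_length_mb=1.0, n_markers=2, n_rils=400,
                            seed=100 * seed + rep)
            calls, truth = simulate_ril_population(cfg)
            d_true = float(np.diff(truth.markers["pos_cm"])[0])
            r = haldane_r(d_true)
            X = calls.to_numpy()
            hom = np.isin(X, ["AA", "BB"]).all(axis=0)
            disc_rep = (X[0, hom] != X[1, hom]).sum()
            exp = ril_observed_fraction_t(r, 7)
            se = np.sqrt(exp * (1 - exp) / hom.sum())
            assert abs(disc_rep / hom.sum() - exp) < 4 * se
            disc += disc_rep
            tot += hom.sum()
    # very distant loci: observed fraction near 1/2
    cfg = SimConfig(n_chromosomes=1, chrom_length_cm=100000.0, chrom_length_mb=1.0,
                    n_markers=2, n_rils=500, seed=7)
    calls, _ = simulate_ril_population(cfg)
    X = calls.to_numpy()
    hom = np.isin(X, ["AA", "BB"]).all(axis=0)
    frac = (X[0, hom] != X[1, hom]).mean()
    assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / hom.sum())


class TestSegregationDistortion:
    def _population(self, seed=12):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(150, 100),
                        n_rils=150, seed=seed)
        return cfg, *simulate_ril_population(cfg)

    def test_neutral_weight_is_identity(self):
        _, calls, truth = self._population()
        out = apply_segregation_distortion(
            calls, truth.markers, SdrSpec("chr1", 10.0, 12.0, 1.0), seed=0)
        assert out.equals(calls)

    def test_invalid_weight_rejected(self):
        _, calls, truth = self._population()
        with pytest.raises(ConfigError):
            apply_segregation_distortion(
                calls, truth.markers, SdrSpec("chr1", 10.0, 12.0, -2.0), seed=0)

    def test_strong_selection_shifts_frequencies_inside_interval(self):
        _, calls, truth = self._population()
        out = apply_segregation_distortion(
            calls, truth.markers, SdrSpec("chr1", 10.0, 12.0, 3.0), seed=0)
        inside = truth.markers[(truth.markers["chrom"] == "chr1")
                               & truth.markers["pos_mb"].between(10.0, 12.0)].index
        sub = out.loc[inside].to_numpy()
        delta = (sub == "AA").mean() - (sub == "BB").mean()
        assert delta > 0.2

    def test_in_simulation_selection_compounds(self):
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(150, 100),
                        n_rils=150, seed=12,
                        sdr_spec=SdrSpec("chr1", 10.0, 12.0, 3.0))
        calls, truth = simulate_ril_population(cfg)
        inside = truth.markers[(truth.markers["chrom"] == "chr1")
                               & truth.markers["pos_mb"].between(10.0, 12.0)].index
        sub = calls.loc[inside].to_numpy()
        assert (sub == "AA").mean() - (sub == "BB").mean() > 0.2
        other = calls.loc[truth.markers["chrom"] == "chr2"].to_numpy()
        assert abs((other == "AA").mean() - (other == "BB").mean()) < 0.3

    def test_unlinked_markers_unaffected(self):
        _, calls, truth = self._population()
        out = apply_segregation_distortion(
            calls, truth.markers, SdrSpec("chr1", 10.0, 12.0, 3.0), seed=0)
        other = truth.markers[truth.markers["chrom"] == "chr2"].index
        sub = out.loc[other].to_numpy()
        delta = (sub == "AA").mean() - (sub == "BB").mean()
        # null sampling bound: delta has SE ~ sqrt(1/n_rils) per marker
        assert abs(delta) < 3.5 / np.sqrt(out.shape[1])


class TestArraySignals:
    def test_degenerate_noise_puts_signals_at_centers(self, small_population):
        calls, _ = small_population
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(120, 80),
                        n_rils=60, seed=3, noise_sd=0.0, probe_effect_sd=0.0,
                        array_effect_sd=0.0, miscluster_rate=0.0, missing_rate=0.0)
        sig = simulate_array_signals(calls, cfg)
        log2 = np.log2(sig.test.values)
        centers = cfg.cluster_centers
        for gi, g in enumerate(("AA", "AB", "BB")):
            mask = (calls.to_numpy() == g)
            for ai in range(2):
                vals = log2[:, ai, :, :].transpose(0, 2, 1)[mask]
                np.testing.assert_allclose(vals, centers[g][ai], atol=1e-9)

    def test_missing_rate_realized(self, small_population):
        calls, _ = small_population
        cfg = SimConfig(n_chromosomes=2, chrom_length_cm=(90.0, 80.0),
                        chrom_length_mb=(25.0, 20.0), n_markers=(120, 80),
                        n_rils=60, seed=3, missing_rate=0.1)
        sig = simulate_array_signals(calls, cfg)
        frac = np.isnan(sig.test.values).mean()
        se = np.sqrt(0.1 * 0.9 / sig.test.values.size)
        assert abs(frac - 0.1) < 3 * se

    def test_training_design_is_six_five_five(self, small_signals):
        labels = small_signals.training_labels
        assert labels.count("AA") == 6
        assert labels.count("AB") == 5
        assert labels.count("BB") == 5
        assert small_signals.training.values.shape[-1] == 16

    def test_signal_means_converge_to_centers(self):
        """Law of large numbers: per-genotype mean log2 signal ~ center."""
        cfg = SimConfig(n_chromosomes=1, chrom_length_cm=50.0, chrom_length_mb=10.0,
                        n_markers=300, n_rils=100, seed=8, probe_effect_sd=0.0,
                        array_effect_sd=0.0, missing_rate=0.0)
        calls, _ = simulate_ril_population(cfg)
        sig = simulate_array_signals(calls, cfg)
        log2 = np.log2(sig.test.values)
        for g in ("AA", "BB"):
            mask = calls.to_numpy() == g
            got = log2[:, 0, :, :].transpose(0, 2, 1)[mask].mean()
            se = cfg.noise_sd / np.sqrt(mask.sum() * 2)
            assert abs(got - cfg.cluster_centers[g][0]) < 4 * se


class TestPileup:
    def test_pileup_schema_and_determinism(self, small_config):
        p = simulate_read_pileup(small_config)
        assert list(p.columns) == ["chrom", "pos", "ref", "alt", "depth_ref",
                                   "depth_alt", "min_qual", "unique"]
        assert (p["pos"] >= 1).all()
        assert (p[["depth_ref", "depth_alt"]] >= 0).to_numpy().all()
        assert (p["ref"] != p["alt"]).all()
        assert p.equals(simulate_read_pileup(small_config))

    def test_depth_range_covers_central_mass(self):
        cfg = SimConfig(seed=13)
        cfg.design.chrom_length_bp = 200_000
        cfg.design.n_chromosomes = 4
        p = simulate_read_pileup(cfg)
        depth = p["depth_ref"] + p["depth_alt"]
        frac = depth.between(8, 39).mean()
        se = np.sqrt(0.9 * 0.1 / len(p))
        assert abs(frac - 0.9) < 3.5 * se

    def test_nonunique_rows_never_selected_by_probe_design(self, small_config):
        p = simulate_read_pileup(small_config)
        selected = select_window_snps(p)
        merged = selected.merge(p, on=["chrom", "pos"], suffixes=("", "_orig"))
        assert merged["unique"].all()


def test_accession_calls_shape_and_determinism(small_population):
    _, truth = small_population
    cfg = SimConfig(seed=2)
    a1 = simulate_accession_calls(truth.markers, config=cfg)
    a2 = simulate_accession_calls(truth.markers, config=cfg)
    assert a1.equals(a2)
    assert a1.shape == (len(truth.markers), 4)
    assert set(np.unique(a1.to_numpy())) <= {"AA", "BB"}
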