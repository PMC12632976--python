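"""Synthetic-data generators: determinism, limiting cases, calibration."""

import numpy as np
import pytest

from flymeio.cytology import summarize_foci
from flymeio.markers import MarkerMap
from flymeio.scoring import tally_classes
from flymeio.simulate import (
    FociCell,
    FociSimConfig,
    MeiosisSimConfig,
    NdjSimConfig,
    SpcSimConfig,
    simulate_class_counts,
    simulate_foci,
    simulate_ndj,
    simulate_progeny,
    simulate_spectral,
    stream,
)
from flymeio.tetrad import TetradDistribution, chromatid_class_probs, tetrad_mle


@pytest.fixture
def chr2_map():
    return MarkerMap("2L-2R", ("net", "dpp", "dpy", "b", "pr", "cn"))


def meiosis_config(E, n, seed=0, weights=None, mmap=None):
    mmap = mmap or MarkerMap("2L-2R", ("net", "dpp", "dpy", "b", "pr", "cn"))
    if weights is None:
        weights = tuple([1.0 / mmap.n_intervals] * mmap.n_intervals)
    return MeiosisSimConfig(
        E=TetradDistribution(E=np.asarray(E, float)),
        marker_map=mmap,
        interval_weights=weights,
        n_progeny=n,
        seed=seed,
    )


class TestStreams:
    def test_labelled_streams_are_independent_and_reproducible(self):
        a1 = stream(7, "progeny").random(4)
        a2 = stream(7, "progeny").random(4)
        b = stream(7, "ndj").random(4)
        np.testing.assert_array_equal(a1, a2)
        assert not np.allclose(a1, b)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            stream(1, "nope")


class TestSimulateProgeny:
    def test_rank_zero_tetrads_give_all_parental_phase(self, chr2_map):
        recs = simulate_progeny(meiosis_config([1.0], 50))
        for r in recs:
            vals = set(r.calls.values())
            assert len(vals) == 1  # no phase switch anywhere

    def test_bit_reproducible(self):
        a = simulate_progeny(meiosis_config([0.5, 0.5], 30, seed=3))
        b = simulate_progeny(meiosis_config([0.5, 0.5], 30, seed=3))
        assert [r.calls for r in a] == [r.calls for r in b]

    def test_rank_one_recombinant_fraction_half(self, chr2_map):
        n = 20_000
        recs = simulate_progeny(meiosis_config([0.0, 1.0], n, seed=1))
        counts = tally_classes(recs, chr2_map)
        frac_rec = 1 - counts.counts.get(0, 0) / counts.n
        se = np.sqrt(0.25 / n)
        assert abs(frac_rec - 0.5) < 3 * se

    def test_class_fractions_converge_to_forward_model(self, chr2_map):
        # equal interval weights keep the same-interval cancellation bias
        # well below the tolerance band
        E = np.array([0.09, 0.77, 0.14, 0.00])
        n = 100_000
        recs = simulate_progeny(meiosis_config(E, n, seed=12))
        counts = tally_classes(recs, chr2_map)
        obs = np.array(counts.fractions(4))
        exp = chromatid_class_probs(E)
        ks = np.max(np.abs(np.cumsum(obs) - np.cumsum(exp)))
        assert ks < 0.01

    def test_end_to_end_mle_recovery_control_like(self, chr2_map):
        E = np.array([0.09355, 0.76467, 0.13713, 0.00465])
        cm = np.array([4.8, 6.2, 30.3, 9.0, 2.4])
        recs = simulate_progeny(
            meiosis_config(E, 1721, seed=4, weights=tuple(cm / cm.sum()))
        )
        fit = tetrad_mle(tally_classes(recs, chr2_map), max_rank=3)
        # one dataset at the study's N: allow ~3 sampling SDs per rank
        assert np.abs(fit.E_hat.E - E).max() < 0.1


class TestSimulateClassCounts:
    def test_matches_forward_model_at_scale(self):
        E = TetradDistribution(E=np.array([0.2, 0.8]))
        cc = simulate_class_counts(E, 50_000, seed=2)
        assert abs(cc.counts[1] / cc.n - 0.4) < 3 * np.sqrt(0.24 / 50_000)


class TestSimulateNdj:
    def test_zero_rate_yields_no_exceptions(self):
        t = simulate_ndj(NdjSimConfig(p_ndj=0.0, n_females=10, mean_brood=50, seed=0))
        assert t.exceptional == 0

    def test_total_rate_yields_no_regulars(self):
        t = simulate_ndj(NdjSimConfig(p_ndj=1.0, n_females=10, mean_brood=50, seed=0))
        assert t.regular == 0
        assert t.adjusted_total == 2 * t.exceptional

    def test_estimator_recovers_rate(self):
        t = simulate_ndj(
            NdjSimConfig(p_ndj=0.05, n_females=200, mean_brood=100, seed=5)
        )
        p_hat = 2 * t.exceptional / t.adjusted_total
        se = np.sqrt(0.05 * 0.95 / 20_000) * 2  # conservative
        assert abs(p_hat - 0.05) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            NdjSimConfig(p_ndj=1.5, n_females=1, mean_brood=1)


class TestSimulateFoci:
    def test_zero_mean_gives_all_zeros(self):
        df = simulate_foci(FociSimConfig(
            cells=(FociCell("c", "3", 0.0, 0.0, 20),), seed=0))
        assert (df["count"] == 0).all()

    def test_moment_matching_negative_binomial(self):
        df = simulate_foci(FociSimConfig(
            cells=(FociCell("r", "3", 12.3, 4.7, 10_000),), seed=1))
        x = df["count"].to_numpy(float)
        assert abs(x.mean() - 12.3) / 12.3 < 0.02
        assert abs(x.std(ddof=1) - 4.7) / 4.7 < 0.02

    def test_underdispersed_falls_back_to_poisson_with_warning(self):
        cfg = FociSimConfig(cells=(FociCell("c", "2A", 5.0, 1.0, 500),), seed=2)
        with pytest.warns(UserWarning, match="Poisson"):
            df = simulate_foci(cfg)
        x = df["count"].to_numpy(float)
        assert abs(x.var(ddof=1) - 5.0) < 1.5  # Poisson variance = mean

    def test_calibrated_difference_detected_by_mann_whitney(self):
        # region-3 control (all zero) vs RNAi-like (mean 7.1, sd 5.3) at the
        # study sample sizes: detected at p < 0.01 in >= 95% of seeds
        from flymeio.cytology import mann_whitney

        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            df = simulate_foci(FociSimConfig(cells=(
                FociCell("control", "3", 0.0, 0.0, 17),
                FociCell("rnai", "3", 7.1, 5.3, 14),
            ), seed=s))
            a = df.loc[df.genotype == "control", "count"].to_numpy()
            b = df.loc[df.genotype == "rnai", "count"].to_numpy()
            hits += mann_whitney(a, b).p_value < 0.01
        assert hits >= 0.95 * n_seeds

    def test_summaries_track_calibration(self):
        df = simulate_foci(FociSimConfig(
            cells=(FociCell("rnai", "3", 7.1, 5.3, 14),), seed=9))
        row = summarize_foci(df).iloc[0]
        # within 3 SE of the generator's mean (SE = sd/sqrt(n))
        assert abs(row["mean"] - 7.1) < 3 * 5.3 / np.sqrt(14)


class TestSimulateSpectral:
    def test_reproducible_and_well_formed(self):
        t1, s1 = simulate_spectral(SpcSimConfig(n_background=50, n_spiked=5, seed=3))
        t2, s2 = simulate_spectral(SpcSimConfig(n_background=50, n_spiked=5, seed=3))
        assert s1 == s2
        assert t1.unique.equals(t2.unique)
        assert len(t1.protein_ids) == 55

    def test_null_fold_change_yields_no_enrichment(self):
        from flymeio.enrichment import compute_dnsaf, enrichment_call

        table, _ = simulate_spectral(
            SpcSimConfig(n_background=300, n_spiked=0, fold_change=1.0, seed=6)
        )
        d = compute_dnsaf(table)
        rec = enrichment_call(d[["exp1", "exp2"]], d[["ctrl1", "ctrl2"]])
        assert rec["enriched"].sum() <= 2

    def test_doubling_baseline_preserves_dnsaf_distribution(self):
        from flymeio.enrichment import compute_dnsaf

        means = []
        for rate in (40.0, 80.0):
            vals = []
            for s in range(5):
                t, _ = simulate_spectral(SpcSimConfig(
                    n_background=200, n_spiked=0, baseline_rate=rate, seed=s))
                vals.append(compute_dnsaf(t).to_numpy().std())
            means.append(np.mean(vals))
        # dNSAF spread is scale-free in expectation up to Poisson noise
        assert abs(means[0] - means[1]) / means[0] < 0.2
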