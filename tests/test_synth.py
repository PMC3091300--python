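"""Synthetic-data generator: Markov models, planting, read simulation."""

import numpy as np
import pytest
from scipy import stats

from bindshift.motifs import HREConfig, encode_sequence, scan_hre
from bindshift.synth import (
    GroundTruth,
    MarkovModel,
    SyntheticSpec,
    fit_markov_model,
    mouse_like_composition_model,
    plant_hre_sites,
    simulate_experiment_suite,
    simulate_genome,
    simulate_reads,
    simulate_sequence_matrix,
)


class TestFitMarkov:
    def test_order_zero_on_homopolymer(self):
        m = fit_markov_model(["AAAA"], order=0)
        assert m.transition[0, 0] > 0.8  # pseudocount-smoothed
        assert m.transition[0].sum() == pytest.approx(1.0)

    def test_order_one_alternating_sequence(self):
        seq = "AC" * 5_000
        m = fit_markov_model([seq], order=1)
        # context A -> C and C -> A nearly certain
        assert m.transition[0, 1] > 0.99  # P(C|A)
        assert m.transition[1, 0] > 0.99  # P(A|C)

    def test_order3_fit_then_simulate_matches_4mer_frequencies(self):
        rng = np.random.default_rng(0)
        base = simulate_genome(mouse_like_composition_model(), 200_000, 1, rng)
        m = fit_markov_model(base, order=3)
        sim = simulate_genome(m, 1_000_000, 1, seed=1)["chr1"]
        enc = encode_sequence(sim)
        n = enc.size - 3
        idx = enc[:-3] * 64 + enc[1:-2] * 16 + enc[2:-1] * 4 + enc[3:]
        counts = np.bincount(idx, minlength=256)
        # expected 4-mer rate: P(context) * P(next | context), both from the model
        ctx_idx = enc[:-3] * 16 + enc[1:-2] * 4 + enc[2:-1]
        ctx_freq = np.bincount(ctx_idx, minlength=64) / n
        for k in range(256):
            ctx, nxt = k // 4, k % 4
            p = ctx_freq[ctx] * m.transition[ctx, nxt]
            se = np.sqrt(max(p * (1 - p) * n, 1))
            assert abs(counts[k] - p * n) <= 3 * se + 3

    def test_n_positions_excluded(self):
        m = fit_markov_model(["ANANANAA"], order=1)
        # only A->A transitions countable; C/G/T rows are pure pseudocount
        assert m.transition[0, 0] > 0.5

    def test_errors(self):
        with pytest.raises(ValueError):
            fit_markov_model([], order=0)
        with pytest.raises(ValueError):
            fit_markov_model(["ACG"], order=5)


class TestMarkovModelInvariants:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            MarkovModel(0, np.array([[0.3, 0.3, 0.3, 0.3]]))

    def test_context_coverage(self):
        m = fit_markov_model(["ACGTACGT"], order=2)
        assert m.transition.shape == (16, 4)
        assert np.allclose(m.transition.sum(axis=1), 1.0)


class TestSimulateGenome:
    def test_uniform_base_frequencies(self):
        m = MarkovModel(0, np.full((1, 4), 0.25))
        g = simulate_genome(m, 1_000_000, 1, seed=2)["chr1"]
        enc = encode_sequence(g)
        freqs = np.bincount(enc, minlength=4)[:4] / enc.size
        assert np.all((freqs > 0.246) & (freqs < 0.254))

    def test_deterministic_under_seed(self):
        m = mouse_like_composition_model()
        assert simulate_genome(m, 10_000, 2, seed=3) == simulate_genome(m, 10_000, 2, seed=3)

    def test_chromosome_count_and_length(self):
        g = simulate_genome(mouse_like_composition_model(), 5_000, 3, seed=4)
        assert sorted(g) == ["chr1", "chr2", "chr3"]
        assert all(len(s) == 5_000 for s in g.values())

    def test_sequence_matrix_matches_model_marginals(self):
        m = fit_markov_model(["ACGT" * 2_000], order=1)
        rng = np.random.default_rng(5)
        mat = simulate_sequence_matrix(m, 5_000, 50, rng)
        assert mat.shape == (5_000, 50)
        # transitions inside the matrix follow the fitted near-deterministic cycle
        trans_ok = (mat[:, 1:] == (mat[:, :-1] + 1) % 4).mean()
        assert trans_ok > 0.98


class TestPlantHreSites:
    def test_zero_sites_is_identity(self, halfsite_pwm):
        g = simulate_genome(mouse_like_composition_model(), 5_000, 1, seed=6)
        g2, truth = plant_hre_sites(g, halfsite_pwm, [(HREConfig("DR", 5), 1.0)], 0)
        assert g2 == g and truth == []

    def test_scanner_recovers_all_planted_instances(self, halfsite_pwm):
        g = simulate_genome(mouse_like_composition_model(), 100_000, 1, seed=7)
        g2, truth = plant_hre_sites(g, halfsite_pwm, [(HREConfig("DR", 5), 1.0)], 50, seed=8)
        assert len(g2["chr1"]) == len(g["chr1"])
        matches = {(m.chrom, m.start) for m in scan_hre(g2, halfsite_pwm, HREConfig("DR", 5), 3.0)}
        for chrom, start, _, _ in truth:
            assert (chrom, start) in matches

    def test_mixture_counts_near_weights(self, halfsite_pwm):
        g = simulate_genome(mouse_like_composition_model(), 500_000, 1, seed=9)
        _, truth = plant_hre_sites(
            g, halfsite_pwm, [(HREConfig("DR", 2), 0.5), (HREConfig("DR", 5), 0.5)], 200, seed=10
        )
        n_dr2 = sum(1 for *_, name in truth if name == "DR2")
        sd = np.sqrt(200 * 0.25)
        assert abs(n_dr2 - 100) <= 3 * sd

    def test_too_small_genome_raises(self, halfsite_pwm):
        g = {"chr1": "ACGT" * 20}
        with pytest.raises(ValueError):
            plant_hre_sites(g, halfsite_pwm, [(HREConfig("DR", 5), 1.0)], 30, seed=11)


class TestSimulateReads:
    def test_background_total_near_poisson_mean(self):
        spec = SyntheticSpec(genome_length=1_000_000, background_rate=0.05,
                             n_shared=0, n_a_only=0, n_b_only=0)
        reads = simulate_reads(GroundTruth(), spec, "signal", "A", seed=12)
        mean = 0.05 * 1_000_000
        assert abs(reads.total - mean) <= 4 * np.sqrt(mean)

    def test_event_reads_concentrate_within_model_support(self):
        spec = SyntheticSpec(genome_length=100_000, background_rate=0.0,
                             event_strength=200.0)
        truth = GroundTruth(events=[("chr1", 50_000, 200.0, "shared")])
        ok = 0
        for s in range(100):
            reads = simulate_reads(truth, spec, "signal", "A", seed=1000 + s)
            pos = reads.positions["chr1"]
            near = np.sum(np.abs(pos - 50_000) <= spec.binding_model.half_width)
            ok += near >= 150
        assert ok >= 95

    def test_control_is_event_blind(self):
        spec = SyntheticSpec(genome_length=2_000_000, background_rate=0.05,
                             n_shared=500, n_a_only=0, n_b_only=0, min_event_gap=500)
        from bindshift.synth import _place_events
        truth = GroundTruth(events=_place_events(spec, np.random.default_rng(13)))
        ctl = simulate_reads(truth, spec, "control", "A", seed=14)
        pos = ctl.positions["chr1"]
        in_windows = 0
        window_bp = 0
        for _, p, _, _ in truth.events:
            in_windows += np.sum((pos >= p - 200) & (pos < p + 200))
            window_bp += 400
        rate_in = in_windows / window_bp
        rate_all = ctl.total / 2_000_000
        sd = np.sqrt(rate_all * window_bp) / window_bp
        assert abs(rate_in - rate_all) <= 3 * sd

    def test_strand_follows_offset_sign(self):
        spec = SyntheticSpec(genome_length=100_000, background_rate=0.0,
                             event_strength=500.0)
        truth = GroundTruth(events=[("chr1", 50_000, 500.0, "shared")])
        reads = simulate_reads(truth, spec, "signal", "A", seed=15)
        pos, strand = reads.subset("chr1")
        upstream = pos < 50_000
        assert (strand[upstream] == 1).all()
        assert (strand[(pos > 50_000)] == -1).all()

    def test_duplicate_rate_inflates_counts(self):
        spec = SyntheticSpec(genome_length=100_000, background_rate=0.05,
                             duplicate_rate=0.5, n_shared=0, n_a_only=0, n_b_only=0)
        reads = simulate_reads(GroundTruth(), spec, "control", "A", seed=16)
        base = 0.05 * 100_000
        assert reads.total > base * 1.3  # ~1.5x with duplicates

    def test_unknown_condition_label_rejected(self):
        spec = SyntheticSpec(genome_length=10_000)
        with pytest.raises(ValueError):
            simulate_reads(GroundTruth(), spec, "signal", "C", seed=17)


class TestBackgroundCalibration:
    def test_binned_background_passes_poisson_gof(self):
        """Chi-square GOF to Poisson in >= 95% of seeds at alpha=0.01."""
        passes = 0
        n_seeds = 40
        for s in range(n_seeds):
            spec = SyntheticSpec(genome_length=500_000, background_rate=0.02,
                                 n_shared=0, n_a_only=0, n_b_only=0)
            reads = simulate_reads(GroundTruth(), spec, "control", "A", seed=2000 + s)
            counts = np.bincount(reads.positions["chr1"] // 1000, minlength=500)
            lam = counts.mean()
            # pool tail bins so expected counts stay >= 5
            kmax = int(stats.poisson.ppf(0.999, lam))
            obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
            exp = stats.poisson.pmf(np.arange(kmax + 1), lam) * counts.size
            exp[kmax] += stats.poisson.sf(kmax, lam) * counts.size
            keep = exp >= 5
            chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
            dof = keep.sum() - 2  # lambda estimated from the data
            p = stats.chi2.sf(chi2, max(dof, 1))
            passes += p > 0.01
        assert passes >= 0.95 * n_seeds - 1


class TestExperimentSuite:
    def test_uninformative_tracks_show_no_enrichment(self):
        spec = SyntheticSpec(genome_length=1_000_000, n_shared=50, n_a_only=0, n_b_only=0,
                             n_aux_tracks=3, informativeness=0.0, seed=18)
        suite = simulate_experiment_suite(spec, make_genome=False)
        rng = np.random.default_rng(19)
        rand_pos = rng.integers(5_000, 995_000, 200)
        for k in range(3):
            pos = suite.datasets[f"aux_{k}"].positions["chr1"]
            at_true = np.mean([np.sum(np.abs(pos - p) <= 250) for _, p, _, _ in suite.truth.events])
            at_rand = np.mean([np.sum(np.abs(pos - p) <= 250) for p in rand_pos])
            sd = np.sqrt(max(at_rand, 1e-9) / len(suite.truth.events))
            assert abs(at_true - at_rand) <= 4 * sd + 0.5

    def test_fully_informative_tracks_strongly_enriched(self):
        spec = SyntheticSpec(genome_length=1_000_000, n_shared=50, n_a_only=0, n_b_only=0,
                             n_aux_tracks=5, informativeness=1.0, seed=20)
        suite = simulate_experiment_suite(spec, make_genome=False)
        for k in range(5):
            pos = suite.datasets[f"aux_{k}"].positions["chr1"]
            rng = np.random.default_rng(21 + k)
            rand_pos = rng.integers(5_000, 995_000, 200)
            at_true = np.mean([np.sum(np.abs(pos - p) <= 250) for _, p, _, _ in suite.truth.events])
            at_rand = max(np.mean([np.sum(np.abs(pos - p) <= 250) for p in rand_pos]), 1e-6)
            assert at_true >= 5 * at_rand

    def test_suite_deterministic_under_seed(self):
        spec = SyntheticSpec(genome_length=100_000, n_shared=5, n_a_only=2, n_b_only=2,
                             n_aux_tracks=2, seed=22)
        s1 = simulate_experiment_suite(spec, make_genome=True)
        s2 = simulate_experiment_suite(spec, make_genome=True)
        assert s1.genome == s2.genome
        assert s1.truth.events == s2.truth.events
        for k in s1.datasets:
            np.testing.assert_array_equal(
                s1.datasets[k].positions["chr1"], s2.datasets[k].positions["chr1"]
            )

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(informativeness=1.5)
        with pytest.raises(ValueError):
            SyntheticSpec(background_rate=-0.1)
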