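"""Two-pass event caller: background, scoring, merging, estimation."""

import numpy as np
import pytest
from scipy import stats

from bindshift.events import (
    BindingEvent,
    benjamini_hochberg,
    call_domains,
    call_events,
    candidate_bins,
    dynamic_lambda,
    estimate_binding_model,
    estimate_fdr_by_swap,
    estimate_scaling_factor,
    merge_and_correct,
    refine_peak_position,
    region_binomial_pvalue,
)
from bindshift.model import BindingModel, default_binding_model
from bindshift.reads import BinnedCounts, ReadDataset
from bindshift.synth import GroundTruth, SyntheticSpec, simulate_reads

from conftest import make_reads


def binned(counts, width=50, offset=25, L=None):
    arr = np.asarray(counts, dtype=float)
    return BinnedCounts(width, offset, {"chr1": arr}, {"chr1": L or arr.size * offset})


class TestDynamicLambda:
    def test_uniform_control_gives_genome_mean_everywhere(self):
        b = binned(np.full(1000, 0.7))
        lam = dynamic_lambda(b)["chr1"]
        np.testing.assert_allclose(lam, 0.7)

    def test_takes_max_of_three_directly_computed_means(self):
        counts = np.zeros(2000)
        counts[1000:1040] = 5.0  # local pileup
        b = binned(counts)
        lam = dynamic_lambda(b)["chr1"]
        i = 1020
        gm = counts.mean()
        for w in (5000, 10000):
            half = (w - 50) // 50
            local = counts[max(i - half, 0): i + half + 1].mean()
            gm = max(gm, local)
        assert lam[i] == pytest.approx(gm)

    def test_window_clipped_at_chromosome_start(self):
        counts = np.concatenate([np.full(50, 2.0), np.zeros(1950)])
        b = binned(counts)
        lam = dynamic_lambda(b)["chr1"]
        half5 = (5000 - 50) // 50
        expected = max(counts.mean(), counts[: half5 + 1].mean(),
                       counts[: (10000 - 50) // 50 + 1].mean())
        assert lam[0] == pytest.approx(expected)


class TestCandidateBins:
    def test_threshold_count_at_unit_lambda(self):
        # smallest s with P(X >= s) < 1e-9 at lambda=1 is 12
        counts = np.arange(0, 20)
        b = binned(counts)
        lam = {"chr1": np.ones(counts.size)}
        idx = candidate_bins(b, lam, 1e-9)["chr1"]
        assert counts[idx].min() == 12

    def test_all_zero_signal_yields_no_candidates(self):
        b = binned(np.zeros(100))
        assert candidate_bins(b, {"chr1": np.ones(100)}, 1e-9)["chr1"].size == 0

    def test_null_simulation_produces_no_false_candidates(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(2.0, size=10_000).astype(float)
        b = binned(counts)
        idx = candidate_bins(b, {"chr1": np.full(10_000, 2.0)}, 1e-9)["chr1"]
        assert idx.size == 0


class TestRegionBinomial:
    def test_signal_only_reads(self):
        assert region_binomial_pvalue(10, 0, 1.0) == pytest.approx(0.5**10)

    def test_zero_signal_is_never_significant(self):
        assert region_binomial_pvalue(0, 7, 1.0) == 1.0
        assert region_binomial_pvalue(0, 0, 2.0) == 1.0

    def test_matches_pmf_summation(self):
        # s=6, c=4, sigma=1: sum_{k=6..10} C(10,k) / 2^10 = 386/1024
        assert region_binomial_pvalue(6, 4, 1.0) == pytest.approx(386 / 1024)
        for s, c, sig in [(3, 9, 0.5), (12, 2, 2.0), (5, 5, 1.3)]:
            q = sig / (sig + 1)
            brute = sum(stats.binom.pmf(k, s + c, q) for k in range(s, s + c + 1))
            assert region_binomial_pvalue(s, c, sig) == pytest.approx(brute, rel=1e-9)

    def test_monotone_in_signal_count(self):
        prev = 1.0
        for s in range(0, 30):
            p = region_binomial_pvalue(s, 10, 1.0)
            assert p <= prev + 1e-12
            prev = p


class TestMergeAndCorrect:
    def test_bh_matches_naive_oracle(self):
        raw = np.array([2e-4, 1e-2, 3e-2, 4e-2])
        adj = benjamini_hochberg(raw)
        np.testing.assert_allclose(adj, [8e-4, 2e-2, 4e-2, 4e-2])
        # naive oracle on random p-values
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        m = p.size
        naive = np.empty(m)
        order = np.argsort(p)
        for rank, i in enumerate(order, 1):
            naive[i] = min(min(p[j] * m / (list(order).index(j) + 1)
                               for j in order[rank - 1:]), 1.0)
        np.testing.assert_allclose(benjamini_hochberg(p), naive)

    def test_single_region_uncorrected(self):
        regions = merge_and_correct(
            {"chr1": (np.array([4]), np.array([5e-4]))}, 50, 25, 0.001
        )
        assert len(regions) == 1
        assert regions[0].p_corrected == pytest.approx(5e-4)

    def test_abutting_bins_take_maximal_p(self):
        regions = merge_and_correct(
            {"chr1": (np.array([4, 5]), np.array([1e-6, 1e-4]))}, 50, 25, 0.001
        )
        assert len(regions) == 1
        assert regions[0].p_raw == pytest.approx(1e-4)
        assert (regions[0].start, regions[0].end) == (100, 175)

    def test_min_rule_switch(self):
        regions = merge_and_correct(
            {"chr1": (np.array([4, 5]), np.array([1e-6, 1e-4]))}, 50, 25, 0.001, "min"
        )
        assert regions[0].p_raw == pytest.approx(1e-6)

    def test_discards_above_corrected_threshold(self):
        per_bin = {"chr1": (np.array([0, 10, 20, 30]),
                            np.array([2e-4, 1e-2, 3e-2, 4e-2]))}
        kept = merge_and_correct(per_bin, 50, 25, 0.001)
        assert len(kept) == 1
        assert kept[0].start == 0

    def test_empty_input(self):
        assert merge_and_correct({}, 50, 25, 0.001) == []


class TestRefinePeak:
    def test_reads_at_model_mode_recover_event_position(self, triangular_model):
        x0 = 5_000
        pos = np.array([x0 - 3, x0 + 3, x0 - 10, x0 + 10, x0])
        strand = np.array([1, -1, 1, -1, 1], dtype=np.int8)
        peak = refine_peak_position(x0 - 100, x0 + 100, pos, strand, triangular_model)
        assert peak == x0

    def test_translation_equivariance(self, triangular_model):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.integers(4_900, 5_100, 40))
        strand = rng.choice(np.array([1, -1], dtype=np.int8), 40)
        p1 = refine_peak_position(4_900, 5_100, pos, strand, triangular_model)
        p2 = refine_peak_position(4_937, 5_137, pos + 37, strand, triangular_model)
        assert p2 == p1 + 37

    def test_tie_breaks_leftmost(self):
        m = BindingModel(np.full(21, 1 / 21))  # uniform: every position ties
        peak = refine_peak_position(100, 110, np.array([105]), np.array([1], dtype=np.int8), m)
        assert peak == 100

    def test_requires_reads(self, triangular_model):
        with pytest.raises(ValueError):
            refine_peak_position(0, 10, np.empty(0, dtype=int), np.empty(0, dtype=np.int8),
                                 triangular_model)


class TestScalingFactor:
    def test_exact_double_control(self):
        rng = np.random.default_rng(3)
        # control has exactly twice the signal reads in every window
        sig_pos = np.sort(rng.integers(0, 500_000, 5_000))
        ctl_pos = np.sort(np.concatenate([sig_pos, sig_pos]))
        sig = ReadDataset({"chr1": 500_000}, {"chr1": sig_pos},
                          {"chr1": np.ones(sig_pos.size, dtype=np.int8)})
        ctl = ReadDataset({"chr1": 500_000}, {"chr1": ctl_pos},
                          {"chr1": np.ones(ctl_pos.size, dtype=np.int8)})
        fit = estimate_scaling_factor(sig, ctl, exclude=[])
        assert fit.mode == "regression"
        assert fit.sigma == pytest.approx(0.5, abs=1e-9)

    def test_falls_back_to_total_ratio_when_few_windows(self):
        sig = make_reads({"chr1": 5_000}, [("chr1", 10, "+")] * 10)
        ctl = make_reads({"chr1": 5_000}, [("chr1", 20, "+")] * 20)
        with pytest.warns(UserWarning):
            fit = estimate_scaling_factor(sig, ctl, exclude=[])
        assert fit.mode == "total-ratio"
        assert fit.sigma == pytest.approx(0.5)

    def test_excluded_windows_are_ignored(self):
        rng = np.random.default_rng(4)
        n = 300_000
        sig_pos = np.sort(rng.integers(0, n, 3_000))
        ctl_pos = np.sort(rng.integers(0, n, 3_000))
        # contaminate one window heavily in the signal only
        sig_pos = np.sort(np.concatenate([sig_pos, np.full(5_000, 15_000)]))
        sig = ReadDataset({"chr1": n}, {"chr1": sig_pos},
                          {"chr1": np.ones(sig_pos.size, dtype=np.int8)})
        ctl = ReadDataset({"chr1": n}, {"chr1": ctl_pos},
                          {"chr1": np.ones(ctl_pos.size, dtype=np.int8)})
        fit = estimate_scaling_factor(sig, ctl, exclude=[("chr1", 14_900, 15_100)])
        assert 0.8 < fit.sigma < 1.2


class TestEstimateBindingModel:
    def _events_and_reads(self, model, n_events=200, reads_per=100, seed=5):
        L = 5_000_000
        rng = np.random.default_rng(seed)
        positions = np.sort(rng.choice(np.arange(1_000, L - 1_000, 2_000), n_events, replace=False))
        truth = GroundTruth(events=[("chr1", int(p), float(reads_per), "shared") for p in positions])
        spec = SyntheticSpec(genome_length=L, background_rate=0.0, event_strength=reads_per,
                             binding_model=model, n_shared=n_events, n_a_only=0, n_b_only=0)
        reads = simulate_reads(truth, spec, "signal", "A", seed=seed)
        W = model.half_width
        events = [
            BindingEvent("chr1", int(p), int(p) - 100, int(p) + 100,
                         reads_per, 0, 0.0, 1e-20, 1e-20, 100.0)
            for p in positions
        ]
        return events, reads

    def test_recovers_generating_model_within_tv(self, triangular_model):
        events, reads = self._events_and_reads(triangular_model)
        est = estimate_binding_model(events, reads, default_binding_model(half_width=200))
        assert est.total_variation(triangular_model) <= 0.05

    def test_too_few_events_returns_prior(self, triangular_model):
        prior = default_binding_model()
        est = estimate_binding_model([], ReadDataset({"chr1": 1000}), prior)
        assert est is prior


def null_pair(seed, L=200_000, rate=0.2):
    rng = np.random.default_rng(seed)
    def channel(r):
        n = r.poisson(rate * L)
        return ReadDataset({"chr1": L},
                           {"chr1": np.sort(r.integers(0, L, n))},
                           {"chr1": r.choice(np.array([1, -1], dtype=np.int8), n)})
    return channel(rng), channel(rng)


class TestCallEvents:
    def test_identical_channels_produce_no_events(self):
        sig, _ = null_pair(6)
        events, _, _ = call_events(sig, sig)
        assert events == []

    def test_planted_events_recovered_with_accurate_peaks(self):
        spec = SyntheticSpec(genome_length=1_000_000, n_shared=30, n_a_only=0, n_b_only=0,
                             event_strength=200.0, background_rate=0.05, seed=7)
        rng_truth = np.random.default_rng(7)
        from bindshift.synth import _place_events
        truth = GroundTruth(events=_place_events(spec, rng_truth))
        sig = simulate_reads(truth, spec, "signal", "A", seed=8)
        ctl = simulate_reads(truth, spec, "control", "A", seed=9)
        events, fit, _ = call_events(sig, ctl)
        truth_pos = [p for _, p, _, _ in truth.events]
        hits = 0
        for p in truth_pos:
            if any(abs(e.peak - p) <= 50 for e in events):
                hits += 1
        assert hits >= 0.95 * len(truth_pos)
        for e in events:
            assert min(abs(e.peak - p) for p in truth_pos) <= 500

    def test_control_depth_invariance(self):
        spec = SyntheticSpec(genome_length=500_000, n_shared=15, n_a_only=0, n_b_only=0,
                             event_strength=200.0, seed=10)
        from bindshift.synth import _place_events
        truth = GroundTruth(events=_place_events(spec, np.random.default_rng(10)))
        sig = simulate_reads(truth, spec, "signal", "A", seed=11)
        ctl = simulate_reads(truth, spec, "control", "A", seed=12)
        # double the control by unioning two independent draws of equal content
        ctl2_extra = simulate_reads(truth, spec, "control", "A", seed=13)
        ctl2 = ReadDataset(
            {"chr1": 500_000},
            {"chr1": np.concatenate([ctl.positions["chr1"], ctl2_extra.positions["chr1"]])},
            {"chr1": np.concatenate([ctl.strands["chr1"], ctl2_extra.strands["chr1"]])},
        )
        ev1, fit1, _ = call_events(sig, ctl)
        ev2, fit2, _ = call_events(sig, ctl2)
        assert fit2.sigma == pytest.approx(fit1.sigma / 2, rel=0.15)
        peaks1 = {e.peak for e in ev1}
        peaks2 = {e.peak for e in ev2}
        # same events up to a couple of borderline regions
        shared = sum(1 for p in peaks1 if any(abs(p - q) <= 50 for q in peaks2))
        assert shared >= 0.9 * len(peaks1)

    def test_empty_signal_returns_no_events(self):
        empty = ReadDataset({"chr1": 10_000})
        ctl = make_reads({"chr1": 10_000}, [("chr1", 100, "+")])
        events, _, _ = call_events(empty, ctl)
        assert events == []


class TestSwapFdr:
    def test_identical_channels_zero_both_ways(self):
        sig, _ = null_pair(14)
        out = estimate_fdr_by_swap(sig, sig)
        assert out["real_events"] == 0 and out["swap_events"] == 0
        assert out["fdr"] is None

    def test_strong_signal_gives_low_fdr(self):
        spec = SyntheticSpec(genome_length=1_000_000, n_shared=30, n_a_only=0, n_b_only=0,
                             event_strength=200.0, seed=15)
        from bindshift.synth import _place_events
        truth = GroundTruth(events=_place_events(spec, np.random.default_rng(15)))
        sig = simulate_reads(truth, spec, "signal", "A", seed=16)
        ctl = simulate_reads(truth, spec, "control", "A", seed=17)
        out = estimate_fdr_by_swap(sig, ctl)
        assert out["real_events"] >= 25
        assert out["fdr"] < 0.05


class TestCallDomains:
    def _block_pair(self, blocks, L=500_000, rate=0.05, boost=10.0, seed=18):
        rng = np.random.default_rng(seed)
        lam = np.full(L // 100, rate * 100)
        sig_parts, ctl_parts = [], []
        ctl_n = rng.poisson(rate * L)
        ctl_parts.append(np.sort(rng.integers(0, L, ctl_n)))
        base_n = rng.poisson(rate * L)
        sig_parts.append(rng.integers(0, L, base_n))
        for s, e in blocks:
            n = rng.poisson(rate * boost * (e - s))
            sig_parts.append(rng.integers(s, e, n))
        sig_pos = np.sort(np.concatenate(sig_parts))
        ctl_pos = np.concatenate(ctl_parts)
        mk = lambda pos: ReadDataset({"chr1": L}, {"chr1": pos},
                                     {"chr1": rng.choice(np.array([1, -1], dtype=np.int8), pos.size)})
        return mk(sig_pos), mk(ctl_pos)

    def test_single_block_recovered(self):
        sig, ctl = self._block_pair([(100_000, 105_000)])
        domains = call_domains(sig, ctl)
        assert len(domains) >= 1
        cover = sum(min(d.end, 105_000) - max(d.start, 100_000)
                    for d in domains if d.end > 100_000 and d.start < 105_000)
        assert cover >= 0.9 * 5_000

    def test_flat_channels_give_no_domains(self):
        sig, ctl = null_pair(19)
        assert call_domains(sig, ctl) == []

    def test_two_separated_blocks_stay_disjoint(self):
        sig, ctl = self._block_pair([(100_000, 105_000), (115_000, 120_000)])
        domains = call_domains(sig, ctl)
        in_gap = [d for d in domains if d.start > 106_000 and d.end < 114_000]
        assert not in_gap
        hits_first = any(d.start < 105_000 and d.end > 100_000 for d in domains)
        hits_second = any(d.start < 120_000 and d.end > 115_000 for d in domains)
        assert hits_first and hits_second
        for d in domains:
            assert not (d.start < 105_000 and d.end > 115_000), "blocks merged"
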