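"""Synthetic recording generator and hit/false-positive scoring."""

import numpy as np
import pytest

from autosort import (
    GroundTruth,
    SimConfig,
    match_events,
    score_solution,
    simulate_recording,
    template_bank,
)

FS = 24000.0


class TestSimulator:
    def test_noiseless_single_unit_is_exact_template_train(self):
        cfg = SimConfig(n_units=1, noise_sd=0.0, duration_s=10.0, seed=3)
        rec, gt = simulate_recording(cfg)
        x = rec.data[0]
        # at every true spike the trace holds the template exactly
        for t in gt.times:
            seg = x[t - 19:t + 45]
            assert np.abs(seg).max() == pytest.approx(1.0, abs=1e-12)
        # away from spikes the trace is exactly zero
        mask = np.ones(x.size, dtype=bool)
        for t in gt.times:
            mask[t - 19:t + 45] = False
        assert np.all(x[mask] == 0.0)

    def test_noise_sd_calibrated_within_two_percent(self):
        cfg = SimConfig(n_units=1, noise_sd=0.2, rate_hz=0.1,
                        duration_s=20.0, seed=4)
        rec, gt = simulate_recording(cfg)
        # mask out the few spikes; what remains is the noise floor
        mask = np.ones(rec.n_samples, dtype=bool)
        for t in gt.times:
            mask[max(t - 40, 0):t + 80] = False
        assert rec.data[0][mask].std() == pytest.approx(0.2, rel=0.02)

    def test_seed_reproducibility_is_bitwise(self):
        cfg = SimConfig(n_units=3, noise_sd=0.1, duration_s=5.0, seed=9)
        r1, g1 = simulate_recording(cfg)
        r2, g2 = simulate_recording(cfg)
        assert np.array_equal(r1.data, r2.data)
        assert np.array_equal(g1.times, g2.times)
        assert np.array_equal(g1.units, g2.units)

    def test_refractory_floor_respected(self):
        cfg = SimConfig(n_units=1, noise_sd=0.0, rate_hz=20.0,
                        duration_s=30.0, seed=5)
        _, gt = simulate_recording(cfg)
        isi_s = np.diff(gt.times) / FS
        assert isi_s.min() >= 0.002 - 1e-9

    def test_tetrode_shapes_and_gains(self):
        cfg = SimConfig(n_units=2, noise_sd=0.05, duration_s=5.0,
                        n_channels=4, seed=6)
        rec, gt = simulate_recording(cfg)
        assert rec.data.shape[0] == 4
        assert gt.channel_gains.shape == (2, 4)
        assert np.all(gt.channel_gains <= 1.0)
        assert np.all(gt.channel_gains >= 0.2)

    def test_multiunit_layer_present_and_flagged(self):
        cfg = SimConfig(n_units=2, noise_sd=0.05, duration_s=20.0,
                        multiunit_fraction=0.3, seed=7)
        _, gt = simulate_recording(cfg)
        assert gt.is_multiunit.sum() > 0
        frac = gt.is_multiunit.mean()
        assert 0.1 < frac < 0.5  # targets 0.3 of events

    def test_infeasible_multiunit_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_recording(SimConfig(n_units=20, rate_hz=3.0,
                                         duration_s=2.0,
                                         multiunit_fraction=0.95, seed=0))

    def test_template_bank_shapes_normalized_and_aligned(self):
        bank = template_bank(FS, 8)
        assert bank.shape == (8, 64)
        assert np.allclose(np.abs(bank).max(axis=1), 1.0)
        assert np.all(np.argmax(np.abs(bank), axis=1) == 19)


class TestMatchEvents:
    def test_one_to_one_within_tolerance(self):
        gt = np.array([1000, 2000, 3000])
        ev = np.array([1003, 1990, 5000])
        m = match_events(ev, gt, FS, tol_ms=1.0)
        assert list(m) == [0, 1, -1]

    def test_double_detection_claims_single_truth_once(self):
        gt = np.array([1000])
        ev = np.array([997, 1002])
        m = match_events(ev, gt, FS, tol_ms=1.0)
        assert sorted(m) == [-1, 0]
        assert m[1] == 0  # the closer event wins


def make_gt(times, units, n_units):
    return GroundTruth(times=np.asarray(times), units=np.asarray(units),
                       n_units=n_units, fs=FS)


class TestScoring:
    def test_perfect_labeling_of_three_units(self):
        times = np.arange(30) * 1000
        units = np.tile([0, 1, 2], 10)
        gt = make_gt(times, units, 3)
        rep = score_solution(units + 1, times, gt)
        assert (rep.hits, rep.false_positives, rep.misses) == (3, 0, 0)

    def test_majority_rule_and_missed_unit(self):
        # one cluster: 60 spikes of unit A + 40 of unit B; B has no cluster
        times = np.arange(100) * 1000
        units = np.r_[np.zeros(60, dtype=int), np.ones(40, dtype=int)]
        gt = make_gt(times, units, 2)
        rep = score_solution(np.ones(100, dtype=int), times, gt)
        assert rep.hits == 1
        assert rep.misses == 1
        assert rep.false_positives == 0

    def test_mostly_multiunit_cluster_is_not_a_false_positive(self):
        times = np.arange(100) * 1000
        units = np.r_[np.full(80, -1), np.zeros(20, dtype=int)]
        gt = make_gt(times, units, 1)
        rep = score_solution(np.ones(100, dtype=int), times, gt)
        assert rep.false_positives == 0
        assert rep.hits == 0

    def test_minority_multiunit_cluster_is_a_false_positive(self):
        # 40% multiunit, 30%/30% split between two units: no majority unit
        times = np.arange(100) * 1000
        units = np.r_[np.full(40, -1), np.zeros(30, dtype=int),
                      np.ones(30, dtype=int)]
        gt = make_gt(times, units, 2)
        rep = score_solution(np.ones(100, dtype=int), times, gt)
        assert rep.false_positives == 1

    def test_duplicate_clusters_for_one_unit_count_once(self):
        times = np.arange(100) * 1000
        units = np.zeros(100, dtype=int)
        labels = np.r_[np.ones(70, dtype=int), np.full(30, 2)]
        gt = make_gt(times, units, 1)
        rep = score_solution(labels, times, gt)
        assert rep.hits == 1
        assert rep.false_positives == 1  # the smaller duplicate

    def test_invariant_under_relabeling(self):
        rng = np.random.default_rng(8)
        times = np.sort(rng.choice(10**6, 300, replace=False))
        units = rng.integers(0, 3, 300)
        labels = units + 1
        gt = make_gt(times, units, 3)
        base = score_solution(labels, times, gt)
        # permute cluster ids
        perm = {1: 3, 2: 1, 3: 2, 0: 0}
        relabeled = np.array([perm[l] for l in labels])
        rep = score_solution(relabeled, times, gt)
        assert (rep.hits, rep.false_positives, rep.misses) == \
            (base.hits, base.false_positives, base.misses)

    def test_degradation_with_noise(self):
        """Mean hits at noise 0.3 do not exceed mean hits at noise 0.1."""
        from autosort import PipelineConfig, run_pipeline
        means = {}
        for noise in (0.1, 0.3):
            hits = []
            for seed in (1, 2, 3):
                rec, gt = simulate_recording(SimConfig(
                    n_units=3, noise_sd=noise, duration_s=30.0, seed=seed))
                out = run_pipeline(rec, PipelineConfig(seed=seed))
                hits.append(score_solution(out.result.labels,
                                           out.spikes.times, gt).hits)
            means[noise] = np.mean(hits)
        assert means[0.3] <= means[0.1]
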