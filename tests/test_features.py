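"""Haar decomposition, Lilliefors screening and knee-based selection."""

import numpy as np
import pytest
from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

from autosort import (
    SpikeSet,
    extract_features,
    haar_decompose,
    lilliefors_stat,
    select_coefficients,
)

FS = 24000.0


def haar_oracle_matrix(n=64, levels=4):
    """Independent orthonormal periodized Haar transform, built from the
    recursive pairwise average/difference definition (no wavelet library)."""
    h = np.eye(n)
    out_rows = []
    approx = h
    for _ in range(levels):
        m = approx.shape[0]
        avg = (approx[0::2] + approx[1::2]) / np.sqrt(2.0)
        det = (approx[0::2] - approx[1::2]) / np.sqrt(2.0)
        out_rows.insert(0, det)
        approx = avg
    out_rows.insert(0, approx)
    return np.vstack(out_rows)  # rows: a4, d4, d3, d2, d1


def spikeset(waveforms):
    w = np.atleast_2d(waveforms)
    return SpikeSet(waveforms=w, times=np.arange(w.shape[0]) * 100,
                    peak_channel=np.zeros(w.shape[0], dtype=int), fs=FS)


class TestHaar:
    def test_constant_waveform_has_no_detail(self):
        c = haar_decompose(np.full((1, 64), 3.0))[0]
        # approximation block (first 4 coefficients) carries all the energy
        assert np.allclose(c[4:], 0.0, atol=1e-12)
        assert np.sum(c**2) == pytest.approx(64 * 9.0, rel=1e-12)

    def test_energy_conservation(self):
        w = np.random.default_rng(0).standard_normal((200, 64))
        c = haar_decompose(w)
        assert np.allclose(np.sum(c**2, axis=1), np.sum(w**2, axis=1),
                           rtol=1e-8)

    @pytest.mark.parametrize("col", [0, 1, 17, 63])
    def test_matches_recursive_oracle(self, col):
        """Unit impulses and random vectors agree with the pairwise
        average/difference construction to machine precision."""
        oracle = haar_oracle_matrix()
        e = np.zeros((1, 64))
        e[0, col] = 1.0
        assert np.allclose(haar_decompose(e)[0], oracle @ e[0], atol=1e-12)
        w = np.random.default_rng(col).standard_normal(64)
        assert np.allclose(haar_decompose(w[None, :])[0], oracle @ w, atol=1e-10)

    def test_tetrode_blocks_transformed_independently(self):
        w = np.random.default_rng(1).standard_normal((5, 256))
        c = haar_decompose(w)
        single = np.hstack([haar_decompose(w[:, i*64:(i+1)*64]) for i in range(4)])
        assert np.array_equal(c, single)

    def test_bad_length_rejected(self):
        with pytest.raises(ValueError):
            haar_decompose(np.zeros((2, 60)))


class TestLilliefors:
    def test_normal_data_scores_low(self):
        x = np.random.default_rng(0).standard_normal(5000)
        assert lilliefors_stat(x) < 0.03

    def test_bimodal_data_scores_high(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(-5, 1, 2500), rng.normal(5, 1, 2500)])
        assert lilliefors_stat(x) > 0.10

    def test_constant_column_is_uninformative(self):
        assert lilliefors_stat(np.full(100, 2.5)) == 0.0

    def test_too_few_values_is_uninformative(self):
        assert lilliefors_stat(np.arange(5.0)) == 0.0

    @pytest.mark.parametrize("maker", [
        lambda rng: rng.uniform(-1, 1, 2000),
        lambda rng: np.concatenate([rng.uniform(-1, -0.5, 1000),
                                    rng.uniform(0.5, 1, 1000)]),
    ])
    def test_matches_reference_implementation(self, maker):
        """On bounded data (where 3-SD trimming is a no-op) the statistic
        equals the independent reference implementation exactly."""
        x = maker(np.random.default_rng(7))
        ours = lilliefors_stat(x)
        ref, _ = sm_lilliefors(x, dist="norm")
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_trimming_removes_far_outliers_once(self):
        x = np.concatenate([np.random.default_rng(3).standard_normal(1000),
                            [1e6]])
        # the huge outlier would otherwise dominate mean/SD and the statistic
        assert lilliefors_stat(x) < 0.05


class TestSelectCoefficients:
    def test_linear_sequence_falls_back_to_top10(self):
        m = 64
        s = np.arange(1, m + 1) / m
        sel = select_coefficients(s)
        assert sel.knee_index == -1
        assert sel.n_selected == 10
        assert set(sel.selected) == set(range(m - 10, m))

    def test_flat_then_rising_sequence_has_knee_in_rise(self):
        m = 64
        s = np.full(m, 0.01)
        s[50:] = np.linspace(0.01, 1.0, 15)[1:]
        sel = select_coefficients(s)
        assert 40 <= sel.knee_index <= 50  # 0-based: positions 41..51 1-based
        assert sel.n_selected <= 23
        assert np.all(sel.ks_stat[sel.selected] > sel.knee_value)

    def test_selection_strictly_above_knee_value(self):
        rng = np.random.default_rng(5)
        ks = np.concatenate([rng.uniform(0.0, 0.02, 50),
                             rng.uniform(0.3, 0.9, 14)])
        sel = select_coefficients(ks)
        assert sel.n_selected > 0
        assert np.all(sel.ks_stat[sel.selected] > sel.knee_value)

    def test_order_invariance(self):
        rng = np.random.default_rng(6)
        ks = rng.uniform(0, 1, 64) ** 4
        base = select_coefficients(ks)
        for _ in range(5):
            perm = rng.permutation(64)
            sel = select_coefficients(ks[perm])
            assert set(perm[sel.selected]) == set(base.selected)
            assert sel.knee_index == base.knee_index

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no informative"):
            select_coefficients(np.zeros(64))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            select_coefficients(np.ones(12))


class TestExtractFeatures:
    def test_modes_select_expected_counts(self, detected_3units):
        spikes, _ = detected_3units
        f_var, sel_var = extract_features(spikes, "variable")
        f_fix, sel_fix = extract_features(spikes, "fixed10")
        f_all, sel_all = extract_features(spikes, "all")
        assert sel_fix.n_selected == 10
        assert sel_all.n_selected == 64
        assert f_var.shape == (spikes.n_events, sel_var.n_selected)
        # every clustered feature column deviates from normality beyond the knee
        assert np.all(sel_var.ks_stat[sel_var.selected] > sel_var.knee_value)

    def test_selected_count_non_increasing_in_noise(self):
        """More background noise means fewer informative coefficients."""
        from autosort import (DetectionParams, SimConfig, bandpass_filter,
                              detect_spikes, estimate_threshold,
                              realign_spikes, simulate_recording)
        medians = []
        for noise in (0.05, 0.1, 0.15, 0.2):
            counts = []
            for seed in range(1, 6):
                rec, _ = simulate_recording(SimConfig(
                    n_units=3, noise_sd=noise, duration_s=30.0, seed=seed))
                p = DetectionParams()
                filt = bandpass_filter(rec, p)
                thr = np.array([estimate_threshold(ch) for ch in filt.data])
                s = realign_spikes(detect_spikes(filt, p, thr), p)
                counts.append(extract_features(s)[1].n_selected)
            medians.append(np.median(counts))
        assert all(a >= b for a, b in zip(medians, medians[1:]))
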