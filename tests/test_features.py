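"""QEEG feature families: summary statistics, asymmetry indices, spectral
band powers, RQA, and the full featurization with transposition symmetry.

Brute-force oracles: sort-based percentiles, a periodogram band-power
check, and a naive double-loop recurrence-matrix implementation.
"""

import numpy as np
import pytest

from szforecast.eeg_io import Recording
from szforecast.features import (
    FeatureSpec,
    asymmetry_index,
    augmented_feature_views,
    feature_names,
    featurize,
    rqa_features,
    spectral_features,
    summary_stats,
)
from szforecast.labeling import augment_transpositions, label_epochs


class TestSummaryStats:
    def test_normal_draws_match_moments(self, rng):
        x = rng.standard_normal(800)
        m, s, k, sk, p10, p90 = summary_stats(x)
        assert abs(m) < 0.15
        assert abs(s - 1) < 0.15
        assert abs(sk) < 0.3
        assert abs(k) < 0.6
        assert -1.6 < p10 < -1.0
        assert 1.0 < p90 < 1.6

    def test_constant_signal_degenerate_convention(self):
        np.testing.assert_array_equal(
            summary_stats(np.full(10, 5.0)), [5.0, 0.0, 0.0, 0.0, 5.0, 5.0]
        )

    def test_percentiles_match_sort_oracle(self):
        x = np.array([0.0] * 9 + [10.0])

        def sort_percentile(v, q):
            v = np.sort(v)
            pos = q / 100 * (len(v) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            hi = min(lo + 1, len(v) - 1)
            return v[lo] * (1 - frac) + v[hi] * frac

        stats = summary_stats(x)
        assert stats[4] == pytest.approx(sort_percentile(x, 10))
        assert stats[5] == pytest.approx(sort_percentile(x, 90))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            summary_stats(np.array([1.0]))


class TestAsymmetryIndex:
    def test_symmetric_inputs_give_zero(self):
        assert asymmetry_index(3.0, 3.0) == 0.0

    def test_extreme_asymmetry_saturates(self):
        assert asymmetry_index(2.0, 0.0) == pytest.approx(1.0, abs=1e-9)

    def test_antisymmetry_property(self, rng):
        for _ in range(1000):
            left, right = rng.normal(size=2) * rng.choice([0.01, 1, 100])
            a = asymmetry_index(left, right)
            assert a == pytest.approx(-asymmetry_index(right, left), abs=1e-12)
            assert -1.0 <= a <= 1.0


class TestSpectral:
    def test_pure_sinusoid_lands_in_its_band(self):
        fs = 40.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 6.0 * t)
        spec = FeatureSpec(spectral_mode="relative")
        rel = spectral_features(x, fs, spec)
        assert rel[1] >= 0.95  # 4-8 Hz band

    def test_white_noise_relative_power_tracks_bandwidth(self, rng):
        fs = 40.0
        x = rng.standard_normal(int(20 * fs))
        spec = FeatureSpec(spectral_mode="relative")
        rel = spectral_features(x, fs, spec)
        widths = np.array([3.5, 4.0, 5.0, 7.0])  # 0.5-4, 4-8, 8-13, 13-20
        expected = widths / widths.sum()
        assert np.all(np.abs(rel - expected) / expected < 0.2)

    def test_tiling_relative_powers_sum_to_one(self, rng):
        fs = 40.0
        x = rng.standard_normal(int(20 * fs))
        rel = spectral_features(x, fs, FeatureSpec(spectral_mode="relative"))
        assert rel.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_signal_uniform_relative(self):
        rel = spectral_features(np.zeros(800), 40.0, FeatureSpec(spectral_mode="relative"))
        np.testing.assert_allclose(rel, 0.25)

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            FeatureSpec(bands=((0.5, 8.0), (4.0, 13.0)))


def brute_force_rqa(x, m, tau, eps, line_min=2, downsample=1):
    """Naive double-loop RQA oracle."""
    y = x[::downsample]
    n_pts = len(y) - (m - 1) * tau
    V = np.array([[y[i + k * tau] for k in range(m)] for i in range(n_pts)])
    R = np.zeros((n_pts, n_pts), dtype=bool)
    for i in range(n_pts):
        for j in range(n_pts):
            if abs(i - j) >= 1:  # Theiler window 1
                R[i, j] = np.linalg.norm(V[i] - V[j]) <= eps
    n_rec = R.sum()
    rr = n_rec / (n_pts * (n_pts - 1))

    def runs(lines):
        pts = cnt = 0
        for line in lines:
            run = 0
            for v in list(line) + [0]:
                if v:
                    run += 1
                else:
                    if run >= line_min:
                        pts += run
                        cnt += 1
                    run = 0
        return pts, cnt

    diags = [np.diagonal(R, off) for off in range(-n_pts + 1, n_pts)]
    verts = [R[:, j] for j in range(n_pts)]
    p_diag, n_diag = runs(diags)
    p_vert, _ = runs(verts)
    det = p_diag / n_rec if n_rec else 0.0
    lam = p_vert / n_rec if n_rec else 0.0
    mean_len = p_diag / n_diag if n_diag else 0.0
    return np.array([rr, det, lam, mean_len])


class TestRqa:
    def test_constant_signal_convention(self):
        spec = FeatureSpec(rqa_downsample=4)
        rr, det, lam, _ = rqa_features(np.full(800, 2.5), spec)
        assert rr == 1.0 and det == 1.0 and lam == 1.0

    def test_periodic_signal_highly_deterministic(self):
        fs = 40.0
        t = np.arange(800) / fs
        x = np.sin(2 * np.pi * 4.0 * t)
        spec = FeatureSpec(rqa_downsample=2)
        rr, det, lam, mean_len = rqa_features(x, spec)
        assert det > 0.9

    @pytest.mark.parametrize("kind", ["sine", "noise"])
    def test_matches_brute_force_oracle(self, kind, rng):
        n = 410  # ~200 embedded points after downsample 2
        if kind == "sine":
            x = np.sin(2 * np.pi * 5.0 * np.arange(n) / 40.0)
        else:
            x = rng.standard_normal(n)
        spec = FeatureSpec(rqa_m=3, rqa_tau=1, rqa_radius_fraction=0.2,
                           rqa_downsample=2, rqa_line_min=2)
        got = rqa_features(x, spec)
        want = brute_force_rqa(x, 3, 1, 0.2 * x.std(), line_min=2, downsample=2)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_general_line_min_matches_oracle(self, rng):
        x = rng.standard_normal(300)
        spec = FeatureSpec(rqa_m=2, rqa_tau=2, rqa_radius_fraction=0.5,
                           rqa_downsample=1, rqa_line_min=3)
        got = rqa_features(x, spec)
        want = brute_force_rqa(x, 2, 2, 0.5 * x.std(), line_min=3, downsample=1)
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_noise_less_deterministic_than_sine(self, rng):
        spec = FeatureSpec(rqa_downsample=2, rqa_radius_fraction=0.1)
        t = np.arange(800) / 40.0
        det_sine = rqa_features(np.sin(2 * np.pi * 5 * t), spec)[1]
        det_noise = rqa_features(rng.standard_normal(800), spec)[1]
        assert det_noise < det_sine

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="50"):
            rqa_features(np.random.default_rng(0).normal(size=120),
                         FeatureSpec(rqa_downsample=4))


class TestFeaturize:
    @pytest.fixture(scope="class")
    def featurized(self, montage):
        rng = np.random.default_rng(21)
        fs = 40.0
        sig = rng.normal(0, 20, size=(8, int(600 * fs)))
        rec = Recording("f", montage.derivation_labels, fs, sig)
        epochs = label_epochs(rec, [])
        spec = FeatureSpec(rqa_downsample=4)
        return rec, epochs, spec, featurize(epochs, rec, montage, spec)

    def test_feature_count_arithmetic(self, montage, featurized):
        *_, fset = featurized
        # 4 LR pairs x 6 stats + 8 derivations x (2 kinds x 4 bands) + 8 x 4 RQA
        assert fset.X.shape[1] == 4 * 6 + 8 * 8 + 8 * 4 == 120
        assert fset.names == feature_names(montage, fset.spec)
        assert len(fset.names) == 120

    def test_all_features_finite(self, featurized):
        *_, fset = featurized
        assert np.isfinite(fset.X).all()

    def test_deterministic(self, montage, featurized):
        rec, epochs, spec, fset = featurized
        again = featurize(epochs, rec, montage, spec)
        np.testing.assert_array_equal(fset.X, again.X)

    def test_stride_local(self, montage, featurized):
        rec, epochs, spec, fset = featurized
        tampered = rec.copy()
        fs = rec.fs
        tampered.signal[:, int(100 * fs) : int(120 * fs)] *= 3.0  # epoch 5
        other = featurize(epochs, tampered, montage, spec)
        changed = np.any(fset.X != other.X, axis=1)
        assert changed[5]
        assert not changed[[0, 1, 2, 3, 4, 6, 10]].any()

    def test_epoch_past_record_end_rejected(self, montage, featurized):
        rec, epochs, spec, _ = featurized
        bad = epochs.copy()
        bad.loc[bad.index[-1], "start_s"] = rec.duration_s - 10.0
        with pytest.raises(ValueError, match="past the end"):
            featurize(bad, rec, montage, spec)

    @pytest.mark.parametrize("flip", [0, 1, 2], ids=["left-right", "front-back", "both"])
    def test_augmented_views_match_refeaturized_flips(self, montage, featurized, flip):
        rec, epochs, spec, fset = featurized
        flipped = augment_transpositions(rec, montage)[flip]
        direct = featurize(epochs, flipped, montage, spec)
        view = augmented_feature_views(fset)[flip]
        np.testing.assert_allclose(view, direct.X, rtol=1e-8, atol=1e-10)

    def test_left_right_flip_negates_asymmetry_columns(self, montage, featurized):
        *_, fset = featurized
        lr_view = augmented_feature_views(fset)[0]
        n_asym = 4 * 6
        np.testing.assert_allclose(
            lr_view[:, :n_asym], -fset.X[:, :n_asym], atol=1e-12
        )
        # spectral/RQA columns are permuted by the pair map, not altered
        assert np.allclose(np.sort(lr_view[:, n_asym:]), np.sort(fset.X[:, n_asym:]))
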