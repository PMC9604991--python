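"""Envelope extraction, static and time-resolved functional connectivity."""

import numpy as np
import pytest

from oanet.fc import (
    EnvelopeSet,
    alpha_envelope,
    fc_similarity,
    ks_distance,
    nodal_strength,
    static_fc,
    trfc_recurrence,
    upper_triangle,
)

FS = 1000.0


def tone(freq, dur=45.0, fs=FS, amp=1.0, phase=0.0):
    t = np.arange(0, dur, 1 / fs)
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestAlphaEnvelope:
    def test_in_band_tone_has_unit_envelope(self):
        # away from the edges (the slow low-pass leaves a short residual
        # transient beyond the fixed 1 s trim) the envelope is flat at 1
        env = alpha_envelope(tone(10.5), FS).env[:, 0]
        assert np.all(np.abs(env[10:-10] - 1.0) < 0.02)
        assert np.all(np.abs(env - 1.0) < 0.06)

    def test_out_of_band_tone_rejected(self):
        env = alpha_envelope(tone(40.0), FS).env[:, 0]
        assert np.all(env < 0.05)

    def test_zero_signal_zero_envelope(self):
        env = alpha_envelope(np.zeros(int(45 * FS)), FS).env
        assert np.allclose(env, 0.0)

    def test_amplitude_homogeneity(self):
        x = np.random.default_rng(0).standard_normal(int(20 * FS))
        e1 = alpha_envelope(x, FS).env
        e3 = alpha_envelope(3.0 * x, FS).env
        assert np.allclose(e3, 3.0 * e1, atol=1e-9)

    def test_output_rate_and_trim(self):
        # 47 s in -> 5 Hz envelope with 1 s trimmed at each end -> 225 samples
        env = alpha_envelope(np.random.default_rng(1).standard_normal((47_000, 2)), FS)
        assert env.fs_env == 5.0
        assert env.env.shape == (225, 2)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            alpha_envelope(np.zeros(1000), fs=20.0)


class TestStaticFC:
    def test_duplicated_regions_fully_correlated(self):
        e = np.random.default_rng(0).uniform(0.5, 1.5, size=(200, 1))
        env = EnvelopeSet(np.hstack([e, e]))
        assert np.isclose(static_fc(env)[0, 1], 1.0)

    def test_anticorrelated_regions(self):
        x = np.random.default_rng(1).uniform(-1, 1, size=200)
        fc = np.corrcoef(np.vstack([x, -x]))
        assert np.isclose(fc[0, 1], -1.0)
        # through the pipeline entry point (raw array form)
        m = static_fc(np.vstack([x + 2, -x + 2]).T)
        assert np.isclose(m[0, 1], -1.0)

    def test_independent_noise_nearly_uncorrelated(self):
        e = np.random.default_rng(2).uniform(0, 1, size=(500, 6))
        fc = static_fc(EnvelopeSet(e))
        assert np.max(np.abs(upper_triangle(fc))) < 0.15

    def test_zero_variance_region_named(self):
        e = np.random.default_rng(3).uniform(0, 1, size=(50, 3))
        e[:, 1] = 0.7
        with pytest.raises(ValueError, match="region 1"):
            static_fc(EnvelopeSet(e))

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            static_fc(EnvelopeSet(np.ones((5, 2))))


class TestFCSimilarity:
    def test_self_similarity_is_one(self):
        m = np.corrcoef(np.random.default_rng(0).standard_normal((4, 100)))
        assert np.isclose(fc_similarity(m, m), 1.0)

    def test_negation_gives_minus_one(self):
        rng = np.random.default_rng(1)
        m = np.corrcoef(rng.standard_normal((5, 100)))
        assert np.isclose(fc_similarity(m, -m), -1.0)

    def test_upper_triangle_count_for_68_regions(self):
        assert upper_triangle(np.zeros((68, 68))).size == 2278

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fc_similarity(np.eye(3), np.eye(4))


class TestRecurrence:
    def test_window_and_pair_counts_for_300s(self):
        # 300 s at 5 Hz, 15 s windows, 12 s overlap -> 96 windows, 4560 pairs
        rng = np.random.default_rng(4)
        env = EnvelopeSet(rng.uniform(0.1, 1.0, size=(1500, 5)))
        rec = trfc_recurrence(env)
        n_win = 96
        assert rec.values.size == n_win * (n_win - 1) // 2 == 4560

    def test_identical_windows_recur_perfectly(self):
        rng = np.random.default_rng(5)
        # a 3 s block (one window step at 5 Hz) tiled: every window sees the same data
        env = EnvelopeSet(np.tile(rng.uniform(0.1, 1.0, size=(15, 4)), (20, 1)))
        rec = trfc_recurrence(env)
        assert np.allclose(rec.values, 1.0)

    def test_single_window_rejected(self):
        env = EnvelopeSet(np.random.default_rng(6).uniform(0.1, 1, size=(80, 3)))
        with pytest.raises(ValueError, match="2 windows"):
            trfc_recurrence(env)


class TestKSDistance:
    def test_identical_samples(self):
        x = np.array([0.1, 0.5, 0.9])
        assert ks_distance(x, x) == 0.0

    def test_disjoint_supports(self):
        assert np.isclose(ks_distance(np.array([0.0, 0.1]), np.array([0.8, 0.9])), 1.0)

    def test_shifted_triplet(self):
        d = ks_distance(np.array([0.1, 0.2, 0.3]), np.array([0.2, 0.3, 0.4]))
        assert np.isclose(d, 1 / 3)

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(size=50), rng.uniform(size=80) ** 2
        assert np.isclose(ks_distance(a, b), ks_distance(b, a))
        assert 0.0 <= ks_distance(a, b) <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ks_distance(np.array([]), np.array([0.1]))


class TestDiscriminability:
    def test_same_regime_more_similar_than_different_regime(self, connectome16):
        """FC is more reproducible across seeds than across parameter regimes."""
        from oanet.fitness import run_batch
        from oanet.model import ModelParams

        def sfc(G, L, seed):
            p = ModelParams(G=G, L=L, v=3.5, t_total=40.0, t_transient=10.0)
            _, sfcs, _ = run_batch(p, connectome16, n_runs=2, seed_base=seed)
            return np.median(np.stack(sfcs), axis=0)

        a1 = sfc(7.0, 1.0, seed=10)
        a2 = sfc(7.0, 1.0, seed=20)
        b = sfc(10.0, 1.5, seed=10)
        assert fc_similarity(a1, a2) > fc_similarity(a1, b)


class TestNodalStrength:
    def test_uniform_half_correlations(self):
        fc = np.full((3, 3), 0.5)
        np.fill_diagonal(fc, 1.0)
        assert np.allclose(nodal_strength(fc), 1.0)

    def test_zero_offdiagonal(self):
        assert np.allclose(nodal_strength(np.eye(4)), 0.0)

    def test_row_column_agreement_on_symmetric_input(self):
        m = np.corrcoef(np.random.default_rng(8).standard_normal((5, 60)))
        assert np.allclose(nodal_strength(m), nodal_strength(m.T))
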