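"""Phase relations, GPR pooling, and the behavior correlations."""

import numpy as np
import pytest

from phasebehav.spectral import SpectralFrame, PowerSpectrum
from phasebehav.phase_behavior import (gpr_rt_correlation, gpr_series,
                                       phase_relations, power_rt_correlation,
                                       rotated_deviations, wrap_angle,
                                       rt_quintile_ppc_contrast,
                                       cross_cluster_gpr_correlation)


def _frame(phases_a, phases_b, freq=70.0, amp=1.0):
    coeff = np.stack([amp * np.exp(1j * np.asarray(phases_a)),
                      np.exp(1j * np.asarray(phases_b))])[:, None, :]
    return SpectralFrame(coeff, np.array([freq]))


class TestPhaseRelations:
    def test_constant_relation_rotates_to_zero(self):
        frame = _frame(np.full(6, np.pi / 3), np.zeros(6))
        rel = phase_relations(frame, (0, 1), 70.0)
        assert rel.mean_phase == pytest.approx(np.pi / 3)
        np.testing.assert_allclose(rel.phi, 0.0, atol=1e-12)
        assert rel.rotated

    def test_mean_resultant_angle_of_two_phases(self):
        frame = _frame([0.0, np.pi / 2], [0.0, 0.0])
        rel = phase_relations(frame, (0, 1), 70.0, rotate=False)
        assert rel.mean_phase == pytest.approx(np.pi / 4)

    def test_rotated_series_has_zero_circular_mean(self, rng):
        frame = _frame(rng.uniform(-np.pi, np.pi, 40), np.zeros(40))
        rel = phase_relations(frame, (0, 1), 70.0)
        resultant = np.exp(1j * rel.phi).mean()
        assert abs(np.angle(resultant)) < 1e-9

    def test_zero_amplitude_error_names_trial(self):
        coeff = np.ones((2, 1, 4), complex)
        coeff[1, 0, 2] = 0.0
        frame = SpectralFrame(coeff, np.array([70.0]))
        with pytest.raises(ValueError, match="trial 2"):
            phase_relations(frame, (0, 1), 70.0)

    def test_wrap_angle_range(self, rng):
        x = rng.uniform(-20, 20, 1000)
        w = wrap_angle(x)
        assert np.all((w > -np.pi) & (w <= np.pi))
        np.testing.assert_allclose(np.exp(1j * w), np.exp(1j * x), atol=1e-12)


class TestGPR:
    def test_cosine_endpoints(self):
        dev = np.array([[[0.0, np.pi]]])
        g = gpr_series(dev)
        np.testing.assert_allclose(g.gpr, [[1.0, -1.0]], atol=1e-12)

    def test_identical_members_pool_to_member_value(self, rng):
        dev = rng.uniform(-np.pi / 2, np.pi / 2, (1, 3, 20))
        stacked = np.repeat(dev, 5, axis=0)
        np.testing.assert_allclose(gpr_series(stacked, level="cluster").gpr,
                                   gpr_series(dev).gpr, atol=1e-12)

    def test_empty_member_set_rejected(self):
        with pytest.raises(ValueError):
            gpr_series(np.empty((0, 2, 5)))

    def test_pooling_reduces_noise_and_boosts_correlation(self, rng):
        """Shared deviation + independent member noise: pooled deviation
        variance shrinks ~1/M and the pooled GPR correlates more strongly
        with the shared signal."""
        n, m = 400, 8
        shared = rng.vonmises(0.0, 3.0, n)
        noise = rng.vonmises(0.0, 6.0, (m, 1, n))
        dev = wrap_angle(shared[None, None, :] + noise)
        pooled = gpr_series(dev, level="cluster").gpr[0]
        single = gpr_series(dev[:1]).gpr[0]
        # residual variance around the shared signal shrinks ~1/M
        resid_pooled = wrap_angle(dev.mean(axis=0)[0] - shared).var()
        resid_single = wrap_angle(dev[0, 0] - shared).var()
        assert resid_pooled / resid_single < 2.5 / m
        target = np.cos(shared)
        assert abs(np.corrcoef(pooled, target)[0, 1]) > \
            abs(np.corrcoef(single, target)[0, 1])


class TestGprRtCorrelation:
    def test_exact_linear_link_gives_minus_one(self, rng):
        dev = rng.uniform(-np.pi, np.pi, (1, 1, 50))
        g = gpr_series(dev)
        rt = 400.0 - 80.0 * g.gpr[0]
        r = gpr_rt_correlation(g, rt)
        np.testing.assert_allclose(r, -1.0, atol=1e-12)

    def test_no_link_within_sampling_noise(self, rng):
        dev = rng.uniform(-np.pi, np.pi, (1, 1, 2000))
        g = gpr_series(dev)
        r = gpr_rt_correlation(g, rng.normal(300, 30, 2000))
        assert abs(r[0]) < 3.0 / np.sqrt(2000)

    def test_matches_direct_pearson_implementation(self, rng):
        dev = rng.uniform(-np.pi, np.pi, (1, 4, 60))
        g = gpr_series(dev)
        rt = rng.normal(300, 30, 60)
        r = gpr_rt_correlation(g, rt)
        for f in range(4):
            direct = np.corrcoef(g.gpr[f], rt)[0, 1]
            assert abs(r[f] - direct) < 1e-12

    def test_constant_gpr_reported_missing(self):
        g = gpr_series(np.zeros((1, 2, 30)))
        r = gpr_rt_correlation(g, np.random.default_rng(0).normal(0, 1, 30))
        assert np.isnan(r).all()

    def test_too_few_trials_rejected(self):
        g = gpr_series(np.zeros((1, 1, 5)))
        with pytest.raises(ValueError):
            gpr_rt_correlation(g, np.arange(5.0))


class TestCrossClusterCorrelation:
    def test_identical_series_r_one(self, rng):
        g = rng.uniform(-1, 1, 80)
        cond = np.array(["IN", "OUT"] * 40)
        out = cross_cluster_gpr_correlation(g, g, cond, n_rand=200, rng=rng)
        assert out["IN"]["r"] == pytest.approx(1.0)
        assert out["OUT"]["r"] == pytest.approx(1.0)

    def test_independent_series_within_null(self, rng):
        a = rng.uniform(-1, 1, 400)
        b = rng.uniform(-1, 1, 400)
        cond = np.array(["IN"] * 200 + ["OUT"] * 200)
        out = cross_cluster_gpr_correlation(a, b, cond, n_rand=200, rng=rng)
        assert out["IN"]["p"] > 0.001
        assert abs(out["difference"]["z"]) < 4

    def test_shared_latent_only_in_condition_detected(self, rng):
        n = 300
        latent = rng.normal(0, 1, n)
        cond = np.array(["IN"] * n + ["OUT"] * n)
        a = np.concatenate([latent + rng.normal(0, 1, n),
                            rng.normal(0, np.sqrt(2), n)])
        b = np.concatenate([latent + rng.normal(0, 1, n),
                            rng.normal(0, np.sqrt(2), n)])
        out = cross_cluster_gpr_correlation(a, b, cond, n_rand=300, rng=rng)
        assert out["IN"]["r"] > 0.3 and out["IN"]["p"] < 1e-4
        assert out["difference"]["p"] < 0.05

    def test_trial_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cross_cluster_gpr_correlation(np.zeros(10), np.zeros(11),
                                          np.array(["IN"] * 10))


class TestPowerRtControl:
    def test_independent_power_within_null(self, rng):
        power = PowerSpectrum(power=np.abs(rng.normal(1, 0.2, (3, 10, 500))),
                              freqs=np.arange(1.0, 11.0))
        r = power_rt_correlation(power, rng.normal(300, 30, 500))
        assert np.all(np.abs(r) < 4.0 / np.sqrt(500))

    def test_linear_power_link_detected(self, rng):
        p = np.abs(rng.normal(1, 0.3, (2, 3, 200)))
        rt = 200.0 + 50.0 * p.mean(axis=(0, 1))
        power = PowerSpectrum(power=p, freqs=np.arange(1.0, 4.0))
        r = power_rt_correlation(power, rt)
        assert np.all(r > 0.3)


class TestQuintileContrast:
    def test_bin_sizes_and_remainder_drop(self, rng):
        n = 103
        frame = _frame(rng.uniform(-np.pi, np.pi, n), np.zeros(n))
        rt = rng.normal(300, 30, n)
        fast, slow, diff = rt_quintile_ppc_contrast(frame, rt, [(0, 1)])
        assert fast.n_trials == 20 and slow.n_trials == 20
        assert diff.shape == (1,)

    def test_no_link_gives_small_contrast(self, rng):
        n = 500
        frame = _frame(rng.uniform(-np.pi, np.pi, n), np.zeros(n))
        _, _, diff = rt_quintile_ppc_contrast(frame, rng.normal(300, 30, n),
                                              [(0, 1)])
        assert abs(diff[0]) < 0.2

    def test_phase_rt_link_raises_fast_bin_ppc(self, rng):
        """RT grows with phase deviation, so fast trials are phase-
        concentrated and slow trials dispersed."""
        n = 500
        dev = rng.vonmises(0.0, 1.0, n)
        rt = 300.0 + 120.0 * (1 - np.cos(dev)) + rng.normal(0, 10, n)
        frame = _frame(dev, np.zeros(n))
        fast, slow, diff = rt_quintile_ppc_contrast(frame, rt, [(0, 1)])
        assert diff[0] > 0.1

    def test_too_small_bins_rejected(self, rng):
        frame = _frame(rng.uniform(-np.pi, np.pi, 12), np.zeros(12))
        with pytest.raises(ValueError):
            rt_quintile_ppc_contrast(frame, rng.normal(0, 1, 12), [(0, 1)],
                                     n_bins=12)


class TestRotatedDeviations:
    def test_shapes_and_consistency_with_single_pair_path(self, rng):
        coeff = np.exp(1j * rng.uniform(-np.pi, np.pi, (3, 95, 30)))
        frame = SpectralFrame(coeff, np.arange(1.0, 96.0))
        dev, mean_phase = rotated_deviations(frame, [(0, 1), (1, 2)],
                                             np.array([10.0, 20.0]))
        assert dev.shape == (2, 2, 30)
        rel = phase_relations(frame, (0, 1), 10.0)
        np.testing.assert_allclose(dev[0, 0], rel.phi, atol=1e-12)
        assert mean_phase[0, 0] == pytest.approx(rel.mean_phase)
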