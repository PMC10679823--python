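"""PPC estimation, artifact/threshold selection, cluster formation, and peak
alignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phasebehav.spectral import SpectralFrame
from phasebehav.connectivity import (PPCSpectrum, define_clusters, peak_align,
                                     ppc_pairwise_bruteforce, ppc_spectrum,
                                     select_site_pairs, inter_areal_pairs)


def _frame_from_phases(phases_a, phases_b, freq=10.0):
    """Two-site single-frequency frame with prescribed per-trial phases."""
    coeff = np.stack([np.exp(1j * np.asarray(phases_a)),
                      np.exp(1j * np.asarray(phases_b))])[:, None, :]
    return SpectralFrame(coeff, np.array([freq]))


def _ppc_obj(values, areas=("X", "Y")):
    n_pairs, n_freq = values.shape
    meta = pd.DataFrame({"site_a": np.zeros(n_pairs, int),
                         "site_b": np.ones(n_pairs, int),
                         "area_a": [areas[0]] * n_pairs,
                         "area_b": [areas[1]] * n_pairs})
    return PPCSpectrum(ppc=values, freqs=np.arange(1.0, n_freq + 1.0),
                       pairs=[(0, i + 1) for i in range(n_pairs)],
                       pair_meta=meta, n_trials=50)


class TestPPC:
    def test_identical_relative_phases_give_one(self):
        frame = _frame_from_phases([0.3] * 8, [1.0] * 8)
        ppc = ppc_spectrum(frame, [(0, 1)])
        np.testing.assert_allclose(ppc.ppc, 1.0, atol=1e-12)

    def test_two_opposite_trials_give_minus_one(self):
        frame = _frame_from_phases([0.0, np.pi], [0.0, 0.0])
        ppc = ppc_spectrum(frame, [(0, 1)])
        np.testing.assert_allclose(ppc.ppc, -1.0, atol=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 5, 10, 20, 50])
    def test_identity_matches_bruteforce(self, n, rng):
        rel = rng.uniform(-np.pi, np.pi, n)
        frame = _frame_from_phases(rel, np.zeros(n))
        ppc = float(ppc_spectrum(frame, [(0, 1)]).ppc[0, 0])
        assert abs(ppc - ppc_pairwise_bruteforce(rel)) < 1e-12

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=30))
    def test_identity_matches_bruteforce_property(self, rel):
        rel = np.asarray(rel)
        frame = _frame_from_phases(rel, np.zeros(len(rel)))
        ppc = float(ppc_spectrum(frame, [(0, 1)]).ppc[0, 0])
        assert abs(ppc - ppc_pairwise_bruteforce(rel)) < 1e-9

    def test_invariant_to_global_phase_rotation(self, rng):
        a = rng.uniform(-np.pi, np.pi, 20)
        b = rng.uniform(-np.pi, np.pi, 20)
        p1 = ppc_spectrum(_frame_from_phases(a, b), [(0, 1)]).ppc
        p2 = ppc_spectrum(_frame_from_phases(a + 1.234, b), [(0, 1)]).ppc
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_unbiased_under_independent_phases(self, rng):
        """E[PPC] is 0 for independent uniform phases — the property that
        motivates PPC over the resultant-length estimator."""
        vals = []
        for _ in range(1000):
            frame = _frame_from_phases(rng.uniform(-np.pi, np.pi, 12),
                                       rng.uniform(-np.pi, np.pi, 12))
            vals.append(float(ppc_spectrum(frame, [(0, 1)]).ppc[0, 0]))
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_fewer_than_two_trials_rejected(self):
        frame = _frame_from_phases([0.1], [0.2])
        with pytest.raises(ValueError):
            ppc_spectrum(frame, [(0, 1)])

    def test_zero_amplitude_coefficient_rejected(self):
        coeff = np.ones((2, 1, 3), complex)
        coeff[0, 0, 1] = 0.0
        frame = SpectralFrame(coeff, np.array([10.0]))
        with pytest.raises(ValueError, match="zero-amplitude"):
            ppc_spectrum(frame, [(0, 1)])


class TestSelection:
    def test_supra_threshold_peak_selected_flat_not(self, rng):
        vals = rng.normal(0.0, 0.01, (30, 95))
        pooled_sd = vals.std()
        vals[4, 69] = vals.mean() + 6 * pooled_sd     # clear peak at 70 Hz
        high = np.abs(rng.normal(0.0, 0.01, (30, 100)))
        res = select_site_pairs(_ppc_obj(vals), _ppc_obj(high))
        assert res.selected[4]
        assert res.selected.sum() <= 3                # near-threshold strays only
        assert res.threshold_value == pytest.approx(
            res.stats[0] + 3 * res.stats[1])

    def test_high_frequency_bump_excludes_pair(self, rng):
        vals = rng.normal(0.0, 0.01, (30, 95))
        vals[2, 50] = 0.9                             # would be selected
        high = rng.normal(0.0, 0.01, (30, 100))
        high[2, 10] = high.mean() + 8 * high.std()    # >100 Hz artifact
        res = select_site_pairs(_ppc_obj(vals), _ppc_obj(high))
        assert res.artifact_excluded[2]
        assert not res.selected[2]

    def test_all_equal_values_degenerate_error(self):
        vals = np.full((5, 95), 0.3)
        high = np.full((5, 100), 0.0)
        with pytest.raises(ValueError, match="degenerate"):
            select_site_pairs(_ppc_obj(vals), _ppc_obj(high))

    def test_selection_monotone_in_ppc(self, rng):
        vals = rng.normal(0.0, 0.01, (30, 95))
        vals[7, 40] = 0.5
        high = rng.normal(0.0, 0.01, (30, 100))
        res1 = select_site_pairs(_ppc_obj(vals), _ppc_obj(high))
        raised = vals.copy()
        raised[7, 40] = 0.8                           # raising never deselects
        res2 = select_site_pairs(_ppc_obj(raised), _ppc_obj(high))
        assert res1.selected[7] and res2.selected[7]

    def test_mismatched_pair_sets_rejected(self, rng):
        a = _ppc_obj(rng.normal(0, 0.01, (3, 95)))
        b = _ppc_obj(rng.normal(0, 0.01, (4, 100)))
        with pytest.raises(ValueError):
            select_site_pairs(a, b)


class TestClusters:
    freqs = np.arange(1.0, 96.0)

    def _avg(self, coupled, peak_freq, n_areas=6, height=0.6, rng=None):
        areas = [f"A{i}" for i in range(n_areas)]
        pairs = [(a, b) for i, a in enumerate(areas) for b in areas[i + 1:]]
        vals = (rng.normal(0.0, 0.01, (len(pairs), 95)) if rng is not None
                else np.zeros((len(pairs), 95)))
        for k, p in enumerate(pairs):
            if p in coupled or (p[1], p[0]) in coupled:
                vals[k, int(peak_freq) - 1] = height
        return vals, pairs

    def test_single_gamma_cluster(self, rng):
        coupled = {("A0", "A1"), ("A0", "A2"), ("A1", "A2"), ("A2", "A3"),
                   ("A0", "A3"), ("A1", "A3")}
        vals, pairs = self._avg(coupled, 70, rng=rng)
        clusters = define_clusters(vals, pairs, self.freqs)
        assert len(clusters) == 1
        assert set(clusters[0].areas) == {"A0", "A1", "A2", "A3"}
        assert clusters[0].band == "gamma"

    def test_no_coupling_no_clusters(self):
        vals, pairs = self._avg(set(), 70)
        with pytest.warns(UserWarning, match="no supra-threshold"):
            assert define_clusters(vals, pairs, self.freqs) == []

    def test_two_disjoint_groups_give_two_clusters(self, rng):
        vals, pairs = self._avg({("A0", "A1")}, 70, rng=rng)
        vals2, _ = self._avg({("A3", "A4")}, 16, rng=rng)
        vals = vals + vals2
        clusters = define_clusters(vals, pairs, self.freqs)
        assert len(clusters) == 2
        members = [set(c.areas) for c in clusters]
        assert {"A0", "A1"} in members and {"A3", "A4"} in members
        assert not set.intersection(*members)
        bands = {tuple(sorted(c.areas)): c.band for c in clusters}
        assert bands[("A0", "A1")] == "gamma"
        assert bands[("A3", "A4")] == "beta"


class TestPeakAlign:
    freqs = np.arange(1.0, 96.0)

    def test_gamma_peak_at_74(self):
        spec = np.zeros(95)
        spec[73] = 0.5                                # 74 Hz bin
        pk = peak_align(spec, self.freqs, "gamma")
        assert pk.peak_freq == 74.0
        assert pk.halfwidth == 20.0
        np.testing.assert_array_equal(
            pk.aligned_freqs(), np.arange(54.0, 95.0))

    def test_tie_breaks_to_lower_frequency(self):
        spec = np.zeros(95)
        spec[[15, 17]] = 0.4                          # 16 and 18 Hz tie
        pk = peak_align(spec, self.freqs, "beta")
        assert pk.peak_freq == 16.0
        assert pk.halfwidth == 15.0

    def test_boundary_peak_warns(self):
        spec = np.zeros(95)
        spec[9] = 0.4                                 # 10 Hz = beta range edge
        with pytest.warns(UserWarning, match="boundary"):
            peak_align(spec, self.freqs, "beta")

    def test_alignment_window_clipped_to_analysis_range(self):
        spec = np.zeros(95)
        spec[89] = 0.5                                # 90 Hz gamma peak
        pk = peak_align(spec, self.freqs, "gamma")
        assert pk.aligned_freqs()[-1] == 95.0         # 110 Hz clipped to 95


class TestInterArealPairs:
    def test_counts_and_ordering(self):
        meta = pd.DataFrame({"area": ["A", "A", "B", "C"]})
        pairs = inter_areal_pairs(meta)
        assert all(i < j for i, j in pairs)
        assert len(pairs) == 5                        # 6 total minus 1 intra

    def test_group_restriction(self):
        meta = pd.DataFrame({"area": ["A", "B", "C"]})
        pairs = inter_areal_pairs(meta, areas_a={"A"}, areas_b={"C"})
        assert pairs == [(0, 2)]
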