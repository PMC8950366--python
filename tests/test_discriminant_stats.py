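"""Summaries, comparisons, detachment detection and discriminant calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hemedist import (
    DistanceSeries,
    OUParams,
    batch_means_se,
    call_substrate,
    call_variant_effect,
    compare,
    detect_detachment,
    simulate_distance_series,
    summarize,
)


def _series(values, dt=10.0, label=""):
    values = np.asarray(values, dtype=float)
    return DistanceSeries(times_ps=dt * np.arange(values.size), values_nm=values,
                          label=label)


class TestSummarize:
    def test_constant_series(self):
        s = summarize(_series([0.5] * 100))
        assert s.mean_nm == pytest.approx(0.5)
        assert s.se_nm == 0.0 and s.sd_nm == 0.0
        assert s.n_frames == 100

    def test_two_point_hand_formula(self):
        s = summarize(_series([0.4, 0.6]))
        assert s.mean_nm == pytest.approx(0.5)
        assert s.sd_nm == pytest.approx(math.sqrt(0.02), rel=1e-12)  # ≈0.1414
        assert s.se_nm == pytest.approx(0.1, rel=1e-12)

    def test_ou_mean_recovery_at_reported_scale(self):
        p = OUParams(mu_nm=0.501, theta_per_ps=0.05, sigma_nm_sqrtps=0.022361)
        s = simulate_distance_series(p, 5000, 10.0, seed=2)
        summ = summarize(s)
        se = batch_means_se(s.values_nm)
        assert abs(summ.mean_nm - 0.501) <= 3 * se

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            summarize(_series([0.5]))

    def test_ess_correction_enlarges_se_for_correlated_frames(self):
        p = OUParams(mu_nm=0.5, theta_per_ps=0.05, sigma_nm_sqrtps=0.0224)
        s = simulate_distance_series(p, 2000, 10.0, seed=5)
        naive = summarize(s)
        honest = summarize(s, ess_correction=True)
        assert honest.se_nm > 1.5 * naive.se_nm
        assert honest.mean_nm == naive.mean_nm

    @settings(derandomize=True, max_examples=40)
    @given(shift=st.floats(0.0, 2.0), seed=st.integers(0, 10**6))
    def test_shift_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        vals = 0.3 + 0.2 * rng.random(50)
        a, b = summarize(_series(vals)), summarize(_series(vals + shift))
        assert b.mean_nm == pytest.approx(a.mean_nm + shift, abs=1e-12)
        assert b.sd_nm == pytest.approx(a.sd_nm, abs=1e-12)
        assert b.se_nm == pytest.approx(a.se_nm, abs=1e-12)


def _pooled_t(x, y):
    """Independently coded textbook pooled-variance t-test."""
    nx, ny = len(x), len(y)
    sx2 = sum((v - sum(x) / nx) ** 2 for v in x) / (nx - 1)
    sy2 = sum((v - sum(y) / ny) ** 2 for v in y) / (ny - 1)
    sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / (nx + ny - 2)
    t = (sum(x) / nx - sum(y) / ny) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return t, nx + ny - 2


class TestCompare:
    def test_identical_series_not_significant(self):
        s = _series([0.4, 0.5, 0.45, 0.42])
        r = compare(s, s)
        assert r.t_stat == pytest.approx(0.0, abs=1e-12)
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant and r.direction == "none"

    def test_matches_textbook_pooled_formula(self, rng):
        x = 0.4 + 0.05 * rng.random(10)
        y = 0.5 + 0.05 * rng.random(10)
        r = compare(_series(x), _series(y))
        t, df = _pooled_t(list(x), list(y))
        assert r.t_stat == pytest.approx(t, abs=1e-10)
        assert r.df == df

    def test_welch_has_non_integer_df(self, rng):
        x = 0.4 + 0.01 * rng.random(8)
        y = 0.5 + 0.20 * rng.random(30)
        r = compare(_series(x), _series(y), mode="welch")
        assert r.df != int(r.df)
        assert r.significant and r.direction == "A_lower"

    def test_large_n_separation_detected(self):
        pa = OUParams(mu_nm=0.439, theta_per_ps=0.05, sigma_nm_sqrtps=0.026111)
        pb = OUParams(mu_nm=0.518, theta_per_ps=0.05, sigma_nm_sqrtps=0.033249)
        a = simulate_distance_series(pa, 5000, 10.0, seed=11)
        b = simulate_distance_series(pb, 5000, 10.0, seed=12)
        r = compare(a, b)
        assert r.significant and r.p_value < 1e-3 and r.direction == "A_lower"

    def test_symmetry_up_to_sign(self, rng):
        x = _series(0.4 + 0.05 * rng.random(20))
        y = _series(0.5 + 0.05 * rng.random(20))
        r1, r2 = compare(x, y), compare(y, x)
        assert r1.t_stat == pytest.approx(-r2.t_stat, abs=1e-12)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert {r1.direction, r2.direction} <= {"A_lower", "B_lower"}

    def test_degenerate_constant_series(self):
        r = compare(_series([0.5] * 10), _series([0.5] * 10))
        assert (r.t_stat, r.p_value) == (0.0, 1.0)
        r2 = compare(_series([0.4] * 10), _series([0.5] * 10))
        assert r2.p_value == 0.0 and r2.significant

    def test_type_one_error_bounded_under_mild_autocorrelation(self):
        # Null calibration: identical OU parameters, weak frame coupling
        # (theta 0.3/ps at dt 10 ps). The naive frame-wise test stays below
        # a 0.10 empirical size; under strong coupling it would not — that
        # regime is covered by the ESS-corrected check below.
        p = OUParams(mu_nm=0.5, theta_per_ps=0.3,
                     sigma_nm_sqrtps=0.07 * math.sqrt(0.6))
        rejections = 0
        for r in range(200):
            a = simulate_distance_series(p, 500, 10.0, seed=10000 + 2 * r)
            b = simulate_distance_series(p, 500, 10.0, seed=10001 + 2 * r)
            rejections += compare(a, b).significant
        assert rejections / 200 <= 0.10

    def test_ess_corrected_size_bounded_under_strong_autocorrelation(self):
        p = OUParams(mu_nm=0.5, theta_per_ps=0.05,
                     sigma_nm_sqrtps=0.07 * math.sqrt(0.1))
        rejections = 0
        for r in range(200):
            a = simulate_distance_series(p, 500, 10.0, seed=50000 + 2 * r)
            b = simulate_distance_series(p, 500, 10.0, seed=50001 + 2 * r)
            rejections += compare(a, b, ess_correction=True).significant
        assert rejections / 200 <= 0.10


class TestDetectDetachment:
    def test_stable_series_has_no_event(self):
        e = detect_detachment(_series([0.45] * 300))
        assert not e.detected

    def test_step_series_onset_at_step(self):
        vals = [0.45] * 100 + [0.80] * 400
        e = detect_detachment(_series(vals))  # dt 10 ps
        assert e.onset_ps == pytest.approx(1000.0)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            detect_detachment(_series([0.45] * 50), window_ps=1000.0)

    def test_excursion_shorter_than_window_ignored(self):
        vals = [0.45] * 100 + [0.80] * 50 + [0.45] * 200
        e = detect_detachment(_series(vals))
        assert not e.detected

    def test_truncation_idempotence(self):
        vals = [0.45] * 100 + [0.80] * 150 + [0.45] * 100
        full = _series(vals)
        e = detect_detachment(full)
        assert e.detected
        end_idx = 100 + 150
        truncated = DistanceSeries(full.times_ps[:end_idx], full.values_nm[:end_idx])
        assert detect_detachment(truncated).onset_ps == e.onset_ps

    def test_noisy_regime_switch_recovered(self):
        p = OUParams(mu_nm=0.501, theta_per_ps=0.05, sigma_nm_sqrtps=0.022361,
                     regime_switch=(5000.0, 1.0))
        s = simulate_distance_series(p, 5000, 10.0, seed=9)
        e = detect_detachment(s)
        assert e.detected
        assert abs(e.onset_ps - 5000.0) <= e.window_ps


class TestCallSubstrate:
    PROBES = [0.439, 0.407]

    def _summary(self, mean):
        return summarize(_series(np.full(100, mean)))

    def test_minor_substrate_at_reported_mean(self):
        call = call_substrate(self._summary(0.501), self.PROBES)
        assert call.label == "minor_substrate"
        assert call.probe_envelope_nm == pytest.approx(0.439)

    def test_poor_substrate_at_detached_mean(self):
        assert call_substrate(self._summary(1.157), self.PROBES).label == \
            "poor_or_non_substrate"

    def test_envelope_boundary_is_probe_like(self):
        assert call_substrate(self._summary(0.439), self.PROBES).label == "probe_like"

    def test_empty_probe_list_rejected(self):
        with pytest.raises(ValueError):
            call_substrate(self._summary(0.5), [])

    def test_labels_monotone_in_mean(self):
        order = {"probe_like": 0, "minor_substrate": 1, "poor_or_non_substrate": 2}
        ranks = [
            order[call_substrate(self._summary(m), self.PROBES).label]
            for m in np.linspace(0.3, 1.2, 60)
        ]
        assert ranks == sorted(ranks)


class TestCallVariantEffect:
    def _ou(self, mu, seed, sigma=0.022361):
        p = OUParams(mu_nm=mu, theta_per_ps=0.05, sigma_nm_sqrtps=sigma)
        return simulate_distance_series(p, 5000, 10.0, seed=seed)

    def test_lower_variant_mean_reads_as_enhanced(self):
        call = call_variant_effect(self._ou(0.448, 21), self._ou(0.501, 22))
        assert call.label == "likely_enhanced"
        assert call.delta_nm < 0 and call.comparison.significant

    def test_higher_variant_mean_reads_as_reduced(self):
        call = call_variant_effect(self._ou(0.628, 23), self._ou(0.501, 24))
        assert call.label == "likely_reduced"
        assert call.delta_nm > 0

    def test_identical_series_unchanged(self):
        s = self._ou(0.501, 25)
        call = call_variant_effect(s, s)
        assert call.label == "unchanged"
        assert not call.comparison.significant
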