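import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from circaqpcr.rhythm import (circular_mean_hours, circular_phase_difference,
                              cosinor_fit, harmonic_regression,
                              phase_relation)

ZT_GRID = np.repeat([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 5)


def cosine(t, mesor, amp, phi, period=24.0):
    return mesor + amp * np.cos(2 * np.pi * (np.asarray(t) - phi) / period)


class TestCosinorFit:
    def test_flat_profile_has_no_rhythm(self):
        t = np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0])
        fit = cosinor_fit(t, np.full(6, 5.0))
        assert fit.mesor == pytest.approx(5.0)
        assert fit.amplitude == 0.0
        assert fit.f_statistic == 0.0
        assert fit.p_zero_amplitude == 1.0

    def test_noiseless_cosine_inverted_exactly(self):
        t = np.tile([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 2)
        fit = cosinor_fit(t, cosine(t, 1.0, 0.5, 16.0))
        assert fit.degenerate
        assert fit.mesor == pytest.approx(1.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(0.5, abs=1e-10)
        assert fit.acrophase == pytest.approx(16.0, abs=1e-9)

    def test_fitted_curve_peaks_at_acrophase(self):
        rng = np.random.default_rng(21)
        y = cosine(ZT_GRID, 1.0, 0.4, 10.3) + rng.normal(0, 0.05, ZT_GRID.size)
        fit = cosinor_fit(ZT_GRID, y)
        assert fit.predict([fit.acrophase])[0] == pytest.approx(
            fit.mesor + fit.amplitude, abs=1e-10)
        grid = np.linspace(0, 24, 2001)
        assert np.max(fit.predict(grid)) <= fit.mesor + fit.amplitude + 1e-9

    def test_matches_independent_ols_solver(self):
        rng = np.random.default_rng(22)
        y = cosine(ZT_GRID, 2.0, 0.6, 7.0) + rng.normal(0, 0.2, ZT_GRID.size)
        fit = cosinor_fit(ZT_GRID, y)
        w = 2 * np.pi / 24.0
        X = sm.add_constant(np.column_stack(
            [np.cos(w * ZT_GRID), np.sin(w * ZT_GRID)]))
        ols = sm.OLS(y, X).fit()
        assert fit.coefficients == pytest.approx(tuple(ols.params), abs=1e-10)
        assert fit.f_statistic == pytest.approx(ols.fvalue, abs=1e-8)
        assert fit.p_zero_amplitude == pytest.approx(ols.f_pvalue, abs=1e-12)
        assert fit.ci_mesor == pytest.approx(
            tuple(ols.conf_int()[0]), abs=1e-10)

    @pytest.mark.parametrize("shift", [1.0, 6.5, 23.0, -4.0])
    def test_time_shift_equivariance(self, shift):
        rng = np.random.default_rng(23)
        y = cosine(ZT_GRID, 1.0, 0.3, 16.0) + rng.normal(0, 0.1, ZT_GRID.size)
        base = cosinor_fit(ZT_GRID, y)
        moved = cosinor_fit(ZT_GRID + shift, y)
        assert moved.acrophase == pytest.approx(
            (base.acrophase + shift) % 24.0, abs=1e-8)
        assert moved.amplitude == pytest.approx(base.amplitude, abs=1e-10)
        assert moved.mesor == pytest.approx(base.mesor, abs=1e-10)
        assert moved.p_zero_amplitude == pytest.approx(
            base.p_zero_amplitude, abs=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(min_value=0.01, max_value=50.0))
    def test_value_scale_equivariance(self, s):
        rng = np.random.default_rng(24)
        y = cosine(ZT_GRID, 1.0, 0.3, 5.0) + rng.normal(0, 0.1, ZT_GRID.size)
        base = cosinor_fit(ZT_GRID, y)
        scaled = cosinor_fit(ZT_GRID, y * s)
        assert scaled.mesor == pytest.approx(base.mesor * s, rel=1e-9)
        assert scaled.amplitude == pytest.approx(base.amplitude * s, rel=1e-9)
        assert scaled.acrophase == pytest.approx(base.acrophase, abs=1e-9)
        assert scaled.p_zero_amplitude == pytest.approx(
            base.p_zero_amplitude, rel=1e-9)

    def test_confidence_interval_coverage(self):
        # amplitude/noise = 3, n = 30: both 95% CIs should cover truth
        # in roughly 95% of simulated profiles
        rng = np.random.default_rng(7)
        amp, sig, phi = 0.3, 0.1, 16.0
        cov_amp = cov_phi = 0
        n_sim = 2000
        for _ in range(n_sim):
            y = cosine(ZT_GRID, 1.0, amp, phi) + rng.normal(0, sig, ZT_GRID.size)
            fit = cosinor_fit(ZT_GRID, y)
            cov_amp += fit.ci_amplitude[0] <= amp <= fit.ci_amplitude[1]
            half = (fit.ci_acrophase[1] - fit.ci_acrophase[0]) / 2.0
            cov_phi += abs(circular_phase_difference(phi, fit.acrophase)) <= half
        assert 0.93 <= cov_amp / n_sim <= 0.97
        assert 0.93 <= cov_phi / n_sim <= 0.97

    def test_input_contracts(self):
        with pytest.raises(ValueError):
            cosinor_fit([0, 4, 8], [1, 2, 3])              # n < 4
        with pytest.raises(ValueError):
            cosinor_fit([0, 0, 4, 4], [1, 2, 3, 4])        # < 3 distinct times


class TestHarmonicRegression:
    def test_constant_profile_retains_nothing(self):
        fit = harmonic_regression(ZT_GRID, np.full(ZT_GRID.size, 2.0))
        assert fit.retained_harmonics == []
        assert not fit.is_rhythmic
        assert fit.p_value == 1.0

    def test_pure_fundamental_retains_order_one(self):
        rng = np.random.default_rng(25)
        y = cosine(ZT_GRID, 1.0, 0.4, 16.0) + rng.normal(0, 0.05, ZT_GRID.size)
        fit = harmonic_regression(ZT_GRID, y)
        assert fit.retained_harmonics == [1]
        assert fit.is_rhythmic

    def test_composite_signal_recovers_both_harmonics(self):
        t = np.linspace(0, 24, 48, endpoint=False)
        rng = np.random.default_rng(26)
        hits = 0
        for _ in range(100):
            y = (cosine(t, 2.0, 1.0, 16.0) + cosine(t, 0.0, 0.5, 5.0, 12.0)
                 + rng.normal(0, 0.1, t.size))
            if harmonic_regression(t, y).retained_harmonics == [1, 2]:
                hits += 1
        assert hits >= 95

    def test_partial_f_matches_statsmodels(self):
        rng = np.random.default_rng(27)
        y = cosine(ZT_GRID, 1.0, 0.4, 9.0) + rng.normal(0, 0.1, ZT_GRID.size)
        fit = harmonic_regression(ZT_GRID, y)
        w = 2 * np.pi / 24.0
        X1 = sm.add_constant(np.column_stack(
            [np.cos(w * ZT_GRID), np.sin(w * ZT_GRID)]))
        X0 = np.ones((ZT_GRID.size, 1))
        f, p, _ = sm.OLS(y, X1).fit().compare_f_test(sm.OLS(y, X0).fit())
        assert fit.f_statistic == pytest.approx(f, abs=1e-8)
        assert fit.p_value == pytest.approx(p, abs=1e-12)


class TestPhaseRelations:
    def _fit(self, gene, phi):
        t = np.tile([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 2)
        return cosinor_fit(t, cosine(t, 1.0, 0.3, phi), gene=gene)

    def test_bmal1_to_cry2_difference(self):
        rel = phase_relation([self._fit("Bmal1", 2.0), self._fit("Cry2", 7.6)])
        assert rel["difference_h"].iloc[0] == pytest.approx(5.6, abs=1e-9)
        assert not rel["antiphase"].iloc[0]

    def test_exact_antiphase_flagged(self):
        rel = phase_relation([self._fit("a", 2.0), self._fit("b", 14.0)])
        assert rel["difference_h"].iloc[0] == pytest.approx(12.0)
        assert rel["antiphase"].iloc[0]

    def test_wraparound_difference(self):
        rel = phase_relation([self._fit("a", 23.0), self._fit("b", 1.0)])
        assert rel["difference_h"].iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_mixed_periods_rejected(self):
        a = self._fit("a", 2.0)
        b = self._fit("b", 3.0)
        b.period = 12.0
        with pytest.raises(ValueError):
            phase_relation([a, b])


def test_circular_mean_wraps_midnight():
    assert circular_mean_hours([23.0, 1.0]) == pytest.approx(0.0, abs=1e-9)
    assert circular_mean_hours([11.0, 13.0]) == pytest.approx(12.0, abs=1e-9)
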