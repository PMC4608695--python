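"""Rhythm detection on temporal expression profiles.

Single cosinor
--------------
With a fixed anticipated period (24 h for an entrained light:dark design),
the model

    y(t) = M + A cos(w (t - phi)),  w = 2 pi / period

is linear in (M, b, c) after expanding the cosine:
y = M + b cos(wt) + c sin(wt), with amplitude A = sqrt(b^2 + c^2) and
acrophase phi = atan2(c, b)/w (the clock time of the fitted maximum).  The
zero-amplitude (no-rhythm) test is the F test of the two harmonic
coefficients:

    F = ((TSS - RSS)/2) / (RSS/(n-3))  ~  F(2, n-3) under A = 0.

95% confidence intervals: a t interval for the mesor, and delta-method
propagation of cov(b, c) for amplitude and acrophase.

Harmonic regression
-------------------
A forward-selection fit adds harmonic pairs (cos, sin of order h; order 1 =
24 h, order 2 = 12 h, ...) while the added pair's partial F test is
significant, and declares a profile rhythmic when the final model beats the
flat model at level alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Relative tolerance below which a residual sum of squares is treated as an
#: exact fit (degenerate inference).
_DEGENERATE_RTOL = 1e-12
#: Reported p-value floor for degenerate (perfect) fits.
P_FLOOR = 2.2e-308


@dataclass
class CosinorFit:
    gene: str
    period: float
    mesor: float
    amplitude: float
    acrophase: float            # hours in [0, period), time of fitted max
    f_statistic: float
    p_zero_amplitude: float
    ci_mesor: tuple
    ci_amplitude: tuple
    ci_acrophase: tuple         # centred on acrophase; may extend past [0, 24)
    n: int
    degenerate: bool = False
    coefficients: tuple = (0.0, 0.0, 0.0)   # (mesor, b, c)
    residual_sd: float = 0.0

    @property
    def is_rhythmic(self) -> bool:
        return self.degenerate or self.p_zero_amplitude < 0.05

    def predict(self, t) -> np.ndarray:
        w = 2 * np.pi / self.period
        m, b, c = self.coefficients
        t = np.asarray(t, dtype=float)
        return m + b * np.cos(w * t) + c * np.sin(w * t)


@dataclass
class HarmonicFit:
    gene: str
    period: float
    retained_harmonics: list
    coefficients: np.ndarray    # [intercept, cos1, sin1, cos2, sin2, ...]
    f_statistic: float
    p_value: float
    is_rhythmic: bool
    alpha: float
    n: int
    degenerate: bool = False

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        X = _harmonic_design(t, self.period, self.retained_harmonics)
        return X @ self.coefficients


def _mod_period(hours: float, period: float) -> float:
    """Map to [0, period); a second mod guards against float h == period."""
    return float((hours % period) % period)


def _harmonic_design(t, period, orders):
    cols = [np.ones_like(t)]
    for h in orders:
        w = 2 * np.pi * h / period
        cols.extend([np.cos(w * t), np.sin(w * t)])
    return np.column_stack(cols)


def cosinor_fit(times, values, period: float = 24.0, gene: str = "") -> CosinorFit:
    """Least-squares single-cosinor fit with the zero-amplitude test.

    Requires >= 4 observations over >= 3 distinct time points.  A constant
    profile returns amplitude 0, F = 0, p = 1; a perfect (zero-residual)
    non-constant fit reports ``degenerate=True`` with the p floor instead
    of an exact zero.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-d arrays")
    n = len(y)
    if n < 4:
        raise ValueError("need >= 4 observations")
    if len(np.unique(t)) < 3:
        raise ValueError("need >= 3 distinct time points")

    w = 2 * np.pi / period
    X = np.column_stack([np.ones(n), np.cos(w * t), np.sin(w * t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    m, b, c = (float(v) for v in beta)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    dof = n - 3
    scale = max(tss, float(y @ y), 1.0)

    amplitude = float(np.hypot(b, c))
    acrophase = _mod_period(np.arctan2(c, b) / w, period)

    if tss <= _DEGENERATE_RTOL * scale:
        # constant profile: no rhythm by definition
        return CosinorFit(gene=gene, period=period, mesor=float(y.mean()),
                          amplitude=0.0, acrophase=0.0, f_statistic=0.0,
                          p_zero_amplitude=1.0,
                          ci_mesor=(float(y.mean()), float(y.mean())),
                          ci_amplitude=(0.0, 0.0), ci_acrophase=(0.0, 0.0),
                          n=n, degenerate=False,
                          coefficients=(float(y.mean()), 0.0, 0.0),
                          residual_sd=0.0)

    degenerate = rss <= _DEGENERATE_RTOL * scale
    if degenerate:
        f_stat = float("inf")
        p = P_FLOOR
        ci_m = (m, m)
        ci_a = (amplitude, amplitude)
        ci_phi = (acrophase, acrophase)
        sd = 0.0
    else:
        f_stat = ((tss - rss) / 2.0) / (rss / dof)
        p = float(stats.f.sf(f_stat, 2, dof))
        s2 = rss / dof
        sd = float(np.sqrt(s2))
        cov = s2 * np.linalg.inv(X.T @ X)
        tq = stats.t.ppf(0.975, dof)
        se_m = np.sqrt(cov[0, 0])
        ci_m = (m - tq * se_m, m + tq * se_m)
        # delta method on (b, c)
        cbc = cov[1:, 1:]
        if amplitude > 0:
            g_amp = np.array([b, c]) / amplitude
            se_amp = float(np.sqrt(g_amp @ cbc @ g_amp))
            g_phi = np.array([-c, b]) / (amplitude ** 2 * w)
            se_phi = float(np.sqrt(g_phi @ cbc @ g_phi))
        else:
            se_amp = float(np.sqrt(cbc.diagonal().mean()))
            se_phi = period / 4.0
        ci_a = (max(0.0, amplitude - tq * se_amp), amplitude + tq * se_amp)
        ci_phi = (acrophase - tq * se_phi, acrophase + tq * se_phi)

    return CosinorFit(gene=gene, period=period, mesor=m, amplitude=amplitude,
                      acrophase=acrophase, f_statistic=f_stat,
                      p_zero_amplitude=p, ci_mesor=ci_m, ci_amplitude=ci_a,
                      ci_acrophase=ci_phi, n=n, degenerate=degenerate,
                      coefficients=(m, b, c), residual_sd=sd)


def harmonic_regression(times, values, period: float = 24.0,
                        max_order: int = 3, alpha: float = 0.05,
                        gene: str = "") -> HarmonicFit:
    """Forward-selection harmonic regression with an overall rhythm F test.

    Harmonic pairs are added in increasing order while the partial F test
    of the added pair is significant at ``alpha``; the overall p-value
    compares the final model against the flat (intercept-only) model.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    n = len(y)
    if n < 2 * max_order + 2:
        raise ValueError("need n >= 2*max_order + 2 observations")

    tss = float(np.sum((y - y.mean()) ** 2))
    scale = max(tss, float(y @ y), 1.0)
    if tss <= _DEGENERATE_RTOL * scale:
        # constant profile: the flat model is exact, nothing to add
        return HarmonicFit(gene=gene, period=period, retained_harmonics=[],
                           coefficients=np.array([float(y.mean())]),
                           f_statistic=0.0, p_value=1.0, is_rhythmic=False,
                           alpha=alpha, n=n)
    retained: list = []
    rss_cur = tss
    degenerate = False
    beta = np.array([y.mean()])

    for h in range(1, max_order + 1):
        orders = retained + [h]
        X = _harmonic_design(t, period, orders)
        cand, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ cand
        rss_new = float(resid @ resid)
        dof_new = n - X.shape[1]
        if dof_new <= 0:
            break
        if rss_new <= _DEGENERATE_RTOL * scale:
            retained, beta, rss_cur, degenerate = orders, cand, rss_new, True
            break
        f_part = ((rss_cur - rss_new) / 2.0) / (rss_new / dof_new)
        p_part = float(stats.f.sf(f_part, 2, dof_new))
        if p_part < alpha:
            retained, beta, rss_cur = orders, cand, rss_new
        else:
            break

    if not retained:
        return HarmonicFit(gene=gene, period=period, retained_harmonics=[],
                           coefficients=np.array([float(y.mean())]),
                           f_statistic=0.0, p_value=1.0, is_rhythmic=False,
                           alpha=alpha, n=n)
    q = 2 * len(retained)
    dof = n - 1 - q
    if degenerate or rss_cur <= _DEGENERATE_RTOL * scale:
        f_stat, p = float("inf"), P_FLOOR
        degenerate = True
    else:
        f_stat = ((tss - rss_cur) / q) / (rss_cur / dof)
        p = float(stats.f.sf(f_stat, q, dof))
    return HarmonicFit(gene=gene, period=period, retained_harmonics=retained,
                       coefficients=beta, f_statistic=f_stat, p_value=p,
                       is_rhythmic=bool(degenerate or p < alpha), alpha=alpha,
                       n=n, degenerate=degenerate)


def circular_phase_difference(phi_a: float, phi_b: float,
                              period: float = 24.0) -> float:
    """Signed circular difference phi_a - phi_b, mapped into (-period/2, period/2]."""
    d = (phi_a - phi_b) % period
    if d > period / 2.0:
        d -= period
    return float(d)


def phase_relation(fits, antiphase_band=(10.0, 14.0)) -> pd.DataFrame:
    """Pairwise signed acrophase differences (hours) between cosinor fits.

    The ``difference_h`` column is gene_b's acrophase minus gene_a's, as a
    signed circular difference in (-12, 12]; ``antiphase`` flags pairs whose
    absolute difference falls in ``antiphase_band`` (default 12 +/- 2 h).
    """
    fits = list(fits)
    periods = {f.period for f in fits}
    if len(periods) > 1:
        raise ValueError("all fits must share the same period")
    period = fits[0].period if fits else 24.0
    rows = []
    for fa, fb in itertools.combinations(fits, 2):
        d = circular_phase_difference(fb.acrophase, fa.acrophase, period)
        rows.append({
            "gene_a": fa.gene, "gene_b": fb.gene,
            "acrophase_a": fa.acrophase, "acrophase_b": fb.acrophase,
            "difference_h": d,
            "antiphase": antiphase_band[0] <= abs(d) <= antiphase_band[1],
        })
    return pd.DataFrame(rows)


def circular_mean_hours(hours, period: float = 24.0) -> float:
    """Circular mean of clock times in hours, result in [0, period)."""
    ang = np.asarray(hours, dtype=float) * 2 * np.pi / period
    mean_ang = np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
    return _mod_period(mean_ang * period / (2 * np.pi), period)
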