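"""Standard-curve fitting and amplification-efficiency estimation.

A qPCR standard curve regresses Ct on log10 of relative template input over a
serial dilution (e.g. 1:20 ... 1:320 of pooled cDNA).  The slope gives the
per-cycle amplification efficiency

    E = 10^(-1/slope) - 1,

with E = 1 (100%) corresponding to perfect doubling, i.e. slope
-1/log10(2) = -3.3219.  Assays are conventionally accepted when E falls in a
90-110% window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DilutionSeries:
    """Serial-dilution Ct measurements for one primer pair.

    ``points`` is a sequence of ``(dilution_factor, ct)`` pairs; a dilution
    factor of 40 means a 1:40 dilution, i.e. relative input 1/40.  Replicate
    measurements at the same dilution are separate points.
    """

    gene: str
    points: tuple

    def __post_init__(self):
        if any(d <= 0 for d, _ in self.points):
            raise ValueError("dilution factors must be positive")
        if len({d for d, _ in self.points}) < 3:
            raise ValueError("need >= 3 distinct dilution factors")


@dataclass(frozen=True)
class StandardCurve:
    gene: str
    slope: float            # cycles per log10(relative input)
    intercept: float
    r_squared: float
    efficiency_percent: float  # NaN when the slope orientation is invalid

    @property
    def efficiency_valid(self) -> bool:
        return np.isfinite(self.efficiency_percent)


def slope_for_efficiency(efficiency_percent: float) -> float:
    """Inverse map: standard-curve slope implied by an efficiency in percent."""
    return -1.0 / np.log10(1.0 + efficiency_percent / 100.0)


def fit_standard_curve(series: DilutionSeries) -> StandardCurve:
    """OLS of Ct on log10(relative input) and the implied efficiency.

    Relative input is 1/dilution_factor, so a well-behaved assay has a
    negative slope.  A non-negative slope yields an invalid-efficiency
    sentinel (NaN) but the curve is still returned for inspection.
    """
    d = np.asarray([p[0] for p in series.points], dtype=float)
    ct = np.asarray([p[1] for p in series.points], dtype=float)
    x = np.log10(1.0 / d)
    res = stats.linregress(x, ct)
    slope = float(res.slope)
    if slope < 0:
        eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    else:
        eff = float("nan")
    return StandardCurve(gene=series.gene, slope=slope,
                         intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         efficiency_percent=eff)


def check_efficiency_window(curve: StandardCurve, lo: float = 90.0,
                            hi: float = 110.0):
    """Accept/reject an assay by its efficiency window (inclusive bounds)."""
    if not lo < hi:
        raise ValueError("lo must be < hi")
    if not curve.efficiency_valid:
        return False, (f"{curve.gene}: slope {curve.slope:.3f} is non-negative; "
                       "efficiency undefined")
    ok = lo <= curve.efficiency_percent <= hi
    verdict = "within" if ok else "outside"
    return ok, (f"{curve.gene}: efficiency {curve.efficiency_percent:.2f}% "
                f"{verdict} [{lo:g}, {hi:g}]%")


def read_dilution_series(path, decimal: str = ".", sep: str = ",") -> list:
    """Read a CSV with columns gene, dilution_factor, ct into DilutionSeries.

    Comma-decimal exports are accepted with ``decimal=","`` (typically
    together with ``sep=";"``).
    """
    df = pd.read_csv(path, decimal=decimal, sep=sep)
    for col in ("gene", "dilution_factor", "ct"):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found")
    out = []
    for gene, g in df.groupby("gene", sort=True):
        pts = tuple(zip(g["dilution_factor"].astype(float),
                        g["ct"].astype(float)))
        out.append(DilutionSeries(gene=gene, points=pts))
    return out
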