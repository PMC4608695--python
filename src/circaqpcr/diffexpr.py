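"""Zeitgeber-time-stratified differential expression and phase sensitivity.

The central methodological point: when a transcript oscillates over the day,
the outcome of an "epileptic vs control" comparison depends on which ZT the
control animals were sampled at.  Each epileptic group (one ZT) is compared
against every naive ZT separately with an unpaired Student's t test, and
each gene is then classified by whether the significant outcomes agree in
direction across all naive ZTs (``consistent_up``/``consistent_down``),
disagree (``phase_dependent``), or are absent (``null``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import RelQuantTable

LIGHT_ZTS = (0.0, 4.0, 8.0)
DARK_ZTS = (12.0, 16.0, 20.0)

CONSISTENT_UP = "consistent_up"
CONSISTENT_DOWN = "consistent_down"
PHASE_DEPENDENT = "phase_dependent"
NULL = "null"


@dataclass
class DEComparison:
    gene: str
    epileptic_zt: float
    naive_zt: object            # a ZT in hours, or a pool label "light"/"dark"/"all"
    t_statistic: float
    p_value: float
    direction: str              # "up", "down" or "none"
    n_epi: int
    n_naive: int
    mean_epi: float
    mean_naive: float


@dataclass
class PhaseSensitivityReport:
    labels: dict = field(default_factory=dict)       # (gene, epi_zt) -> label
    supporting: dict = field(default_factory=dict)   # (gene, epi_zt) -> comparisons


def _direction(mean_epi, mean_naive, p, alpha):
    if p >= alpha:
        return "none"
    return "up" if mean_epi > mean_naive else "down"


def zt_stratified_tests(q: RelQuantTable, epileptic_zt: float, naive_zts,
                        genes=None, alpha: float = 0.05,
                        pool_phases: bool = False, equal_var: bool = True,
                        bh: bool = False) -> list:
    """Unpaired t tests of epileptic (one ZT) vs naive at each ZT, per gene.

    ``equal_var=True`` is the classic pooled-variance Student test; Welch is
    available via ``equal_var=False``.  With ``pool_phases`` two extra
    comparisons per gene pool the naive light (ZT 0/4/8) and dark
    (ZT 12/16/20) phases.  ``bh=True`` applies Benjamini-Hochberg across all
    comparisons of this call before directions are assigned (the default
    reports raw p-values).
    """
    long = q.long()
    genes = list(genes) if genes is not None else list(q.genes)
    epi = long[(long["group"] == "epileptic") & (long["zt"] == epileptic_zt)]
    naive = long[long["group"] == "naive"]
    if not set(epi["sample_id"]).isdisjoint(naive["sample_id"]):
        raise ValueError("epileptic and naive samples must be disjoint")

    slots: list = [(zt, lambda d, zt=zt: d["zt"] == zt) for zt in naive_zts]
    if pool_phases:
        slots.append(("light", lambda d: d["zt"].isin(LIGHT_ZTS)))
        slots.append(("dark", lambda d: d["zt"].isin(DARK_ZTS)))

    comparisons = []
    for gene in genes:
        x = epi.loc[epi["gene"] == gene, "quantity"].to_numpy()
        for label, selector in slots:
            sub = naive[naive["gene"] == gene]
            yv = sub.loc[selector(sub), "quantity"].to_numpy()
            if len(x) < 2 or len(yv) < 2:
                warnings.warn(
                    f"{gene} vs naive {label}: fewer than 2 animals per "
                    "cell, comparison skipped")
                continue
            t, p = stats.ttest_ind(x, yv, equal_var=equal_var)
            comparisons.append(DEComparison(
                gene=gene, epileptic_zt=epileptic_zt, naive_zt=label,
                t_statistic=float(t), p_value=float(p), direction="",
                n_epi=len(x), n_naive=len(yv),
                mean_epi=float(x.mean()), mean_naive=float(yv.mean())))

    pvals = np.array([c.p_value for c in comparisons])
    effective = (multipletests(pvals, method="fdr_bh")[1]
                 if bh and len(pvals) else pvals)
    for c, p_eff in zip(comparisons, effective):
        c.p_value = float(p_eff)
        c.direction = _direction(c.mean_epi, c.mean_naive, p_eff, alpha)
    return comparisons


def classify_phase_sensitivity(comparisons) -> PhaseSensitivityReport:
    """Label each (gene, epileptic ZT) by cross-ZT consistency of outcomes.

    Only per-ZT comparisons enter the classification (phase pools are
    supplementary).  ``consistent_up``/``consistent_down``: significant in
    the same direction against every naive ZT; ``phase_dependent``: at least
    one significant comparison but outcomes differ; ``null``: nothing
    significant.
    """
    report = PhaseSensitivityReport()
    per_zt = [c for c in comparisons if not isinstance(c.naive_zt, str)]
    keys = sorted({(c.gene, c.epileptic_zt) for c in per_zt})
    for key in keys:
        comps = sorted((c for c in per_zt
                        if (c.gene, c.epileptic_zt) == key),
                       key=lambda c: c.naive_zt)
        if len({c.naive_zt for c in comps}) < 2:
            raise ValueError(f"{key}: need comparisons against >= 2 naive ZTs")
        directions = [c.direction for c in comps]
        significant = [d for d in directions if d != "none"]
        if not significant:
            label = NULL
        elif all(d == "up" for d in directions):
            label = CONSISTENT_UP
        elif all(d == "down" for d in directions):
            label = CONSISTENT_DOWN
        else:
            label = PHASE_DEPENDENT
        report.labels[key] = label
        report.supporting[key] = comps
    return report


def comparisons_frame(comparisons) -> pd.DataFrame:
    """Tabular view of a list of DEComparison (one row per comparison)."""
    return pd.DataFrame([{
        "gene": c.gene, "epileptic_zt": c.epileptic_zt, "naive_zt": c.naive_zt,
        "t": c.t_statistic, "p": c.p_value, "direction": c.direction,
        "n_epi": c.n_epi, "n_naive": c.n_naive,
        "mean_epi": c.mean_epi, "mean_naive": c.mean_naive,
    } for c in comparisons])
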