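"""Reference-gene stability ranking: geNorm and NormFinder.

geNorm scores a candidate reference gene j by

    M_j = mean over partners k != j of sd_i( log2(Q_ij / Q_ik) ),

the average standard deviation of its pairwise log-ratios across samples;
a lower M means the gene varies less relative to the rest of the panel.
Genes are ranked by iteratively removing the highest-M gene until two
remain (the best pair, which share the same final M by construction).  The
pairwise variation V_{n/n+1} between normalization factors built from the n
and n+1 most stable genes decides how many reference genes are needed: the
smallest n with V below a 0.15 cutoff.

NormFinder fits a variance-components model to sample-centred log
quantities: per group it estimates each gene's within-group variance (with
the bias correction that accounts for the centring, truncated at zero) and
its between-group deviation, shrinks the deviation toward zero by an
empirical-Bayes factor, and scores each gene by the average over groups of
|shrunk deviation| + the sampling error of the group mean.  Without groups
the score reduces to the bias-corrected residual standard deviation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import RelQuantTable

DEFAULT_V_CUTOFF = 0.15


def _quantity_frame(q) -> pd.DataFrame:
    df = q.quantities if isinstance(q, RelQuantTable) else pd.DataFrame(q)
    if (df.to_numpy() <= 0).any() or df.isna().any().any():
        raise ValueError("all quantities must be positive and determined")
    return df.astype(float)


@dataclass
class GenormResult:
    m_values: dict                 # gene -> M on the full panel
    ranking: list                  # most stable first; first two = best pair
    best_pair: tuple               # unordered (stored sorted)
    pairwise_variation: list       # [(n, V_{n/n+1})] for n = 2..k-1
    cutoff: float
    recommended_count: int


@dataclass
class NormfinderResult:
    stability: dict                # gene -> stability value
    best_gene: str
    best_pair: tuple
    groups_used: list = field(default_factory=list)


def genorm_m_values(q) -> pd.Series:
    """geNorm expression-stability measure M for every gene in the panel."""
    df = _quantity_frame(q)
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise ValueError("need >= 2 genes and >= 2 samples")
    logq = np.log2(df.to_numpy())
    genes = list(df.columns)
    k = len(genes)
    m = np.zeros(k)
    for j in range(k):
        sds = [np.std(logq[:, j] - logq[:, l], ddof=1)
               for l in range(k) if l != j]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=genes, name="M")


def genorm_rank(q) -> list:
    """Stability ranking by stepwise exclusion of the highest-M gene.

    Returns gene names most-stable first; the first two entries are the
    best pair and are mutually unordered (they share the same final M).
    Ties in the maximum M are broken by removing the lexicographically
    last gene.
    """
    df = _quantity_frame(q)
    if df.shape[1] < 3:
        raise ValueError("ranking needs >= 3 genes")
    remaining = df
    excluded = []
    while remaining.shape[1] > 2:
        m = genorm_m_values(remaining)
        worst = sorted(m.index[m == m.max()])[-1]
        excluded.append(worst)
        remaining = remaining.drop(columns=[worst])
    return sorted(remaining.columns) + excluded[::-1]


def genorm_pairwise_variation(q, ranking, cutoff: float = DEFAULT_V_CUTOFF):
    """Pairwise variation V_{n/n+1} of successive normalization factors.

    NF_n per sample is the geometric mean of the n most stable genes'
    quantities; V_{n/n+1} is the sample standard deviation of
    log2(NF_n / NF_{n+1}).  Returns ``(series, recommended_count)`` where
    ``recommended_count`` is the smallest n with V < cutoff (k-1 if none).
    """
    df = _quantity_frame(q)[list(ranking)]
    k = df.shape[1]
    if k < 3:
        raise ValueError("pairwise variation needs >= 3 ranked genes")
    logq = np.log2(df.to_numpy())
    series = []
    for n in range(2, k):
        nf_n = logq[:, :n].mean(axis=1)        # log2 geometric mean
        nf_n1 = logq[:, :n + 1].mean(axis=1)
        v = float(np.std(nf_n - nf_n1, ddof=1))
        series.append((n, v))
    recommended = recommended_gene_count(series, cutoff, k)
    return series, recommended


def recommended_gene_count(v_series, cutoff: float, n_genes: int) -> int:
    """Smallest n whose V_{n/n+1} is below cutoff; n_genes - 1 if none."""
    for n, v in v_series:
        if v < cutoff:
            return n
    return n_genes - 1


def genorm(q, cutoff: float = DEFAULT_V_CUTOFF) -> GenormResult:
    """Full geNorm analysis: M values, ranking, best pair and V series."""
    m = genorm_m_values(q)
    ranking = genorm_rank(q)
    v_series, rec = genorm_pairwise_variation(q, ranking, cutoff)
    return GenormResult(
        m_values=m.to_dict(), ranking=ranking,
        best_pair=tuple(sorted(ranking[:2])),
        pairwise_variation=v_series, cutoff=cutoff, recommended_count=rec,
    )


def _normfinder_group_estimates(z: np.ndarray):
    """Bias-corrected per-gene residual variances for one group.

    ``z`` is samples x genes, already sample-centred.  Under the
    variance-components model, var over samples of a centred gene is
    sigma_j^2 (1 - 2/k) + sum_l sigma_l^2 / k^2; solving gives the
    correction below.  Negative estimates are truncated at zero.
    """
    n, k = z.shape
    v = z.var(axis=0, ddof=1)
    total = v.sum() / (1.0 - 1.0 / k)
    sig2 = (v - total / k ** 2) / (1.0 - 2.0 / k)
    return np.maximum(sig2, 0.0)


def normfinder_stability(q, groups=None) -> NormfinderResult:
    """Model-based (NormFinder) stability values for a candidate panel.

    Parameters
    ----------
    q : RelQuantTable or DataFrame
        Positive relative quantities, samples x genes (>= 3 genes).
    groups : mapping/Series sample_id -> label, or None
        Grouping for the intra/inter-group decomposition (e.g. the ZT
        label in a diurnal design).  ``None`` scores genes by residual
        standard deviation alone.
    """
    df = _quantity_frame(q)
    genes = list(df.columns)
    n_samples, k = df.shape
    if k < 3:
        raise ValueError("NormFinder needs >= 3 genes")
    y = np.log2(df.to_numpy())
    y = y - y.mean(axis=1, keepdims=True)      # remove per-sample effect

    if groups is None:
        sig2 = _normfinder_group_estimates(y)
        stab = np.sqrt(sig2)
        groups_used = []
        dtil = np.zeros((1, k))
        sig2_g = sig2[None, :]
        n_g = np.array([n_samples])
    else:
        glab = pd.Series(groups).reindex(df.index)
        if glab.isna().any():
            missing = list(df.index[glab.isna()])
            raise ValueError(f"samples without group label: {missing}")
        groups_used = sorted(glab.unique())
        G = len(groups_used)
        counts = glab.value_counts()
        small = [g for g in groups_used if counts[g] < 2]
        if small:
            raise ValueError(f"group {small[0]!r} has < 2 samples")
        sig2_g = np.zeros((G, k))
        zbar = np.zeros((G, k))
        n_g = np.zeros(G, dtype=int)
        for gi, g in enumerate(groups_used):
            z = y[(glab == g).to_numpy()]
            n_g[gi] = z.shape[0]
            sig2_g[gi] = _normfinder_group_estimates(z)
            zbar[gi] = z.mean(axis=0)
        d = zbar - zbar.mean(axis=0, keepdims=True)   # inter-group deviation
        if G > 1:
            samp_var = float((sig2_g / n_g[:, None]).mean())
            raw_tau2 = float((d ** 2).sum() / ((G - 1) * (k - 1)))
            tau2 = max(0.0, raw_tau2 - samp_var)
        else:
            tau2 = 0.0
        denom = tau2 + sig2_g / n_g[:, None]
        with np.errstate(invalid="ignore"):
            shrink = np.where(denom > 0, tau2 / np.where(denom > 0, denom, 1.0), 0.0)
        dtil = d * shrink
        stab = (np.abs(dtil) + np.sqrt(sig2_g / n_g[:, None])).mean(axis=0)

    stability = pd.Series(stab, index=genes)
    best_gene = stability.sort_index().idxmin()

    # best pair: averaging two genes lets opposite group deviations cancel
    best_pair, best_val = None, np.inf
    for a, b in itertools.combinations(range(k), 2):
        pair_d = np.abs((dtil[:, a] + dtil[:, b]) / 2.0)
        pair_se = np.sqrt((sig2_g[:, a] + sig2_g[:, b]) / (4.0 * n_g))
        val = float((pair_d + pair_se).mean())
        if val < best_val - 1e-15:
            best_val = val
            best_pair = (genes[a], genes[b])
    return NormfinderResult(stability=stability.to_dict(),
                            best_gene=best_gene,
                            best_pair=tuple(sorted(best_pair)),
                            groups_used=list(groups_used))
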