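"""Relative quantification of Ct data.

Two normalizations are provided:

* ``delta_ct_quantities`` — per-gene relative quantities Q = 2^(minCt - Ct),
  referencing each gene to its lowest-Ct sample.  This is the input expected
  by the reference-gene stability algorithms (geNorm, NormFinder).
* ``ddct_normalize`` — the 2^-ddCt method against one or more reference
  genes and a calibrator sample:

      dCt_i  = Ct_target,i - mean(Ct_ref,i)
      ddCt_i = dCt_i - dCt_calibrator
      Q_i    = 2^(-ddCt_i)

  With multiple reference genes the arithmetic mean of reference Cts is
  used, which at perfect efficiency equals normalizing by the geometric mean
  of reference quantities.  An efficiency-corrected base (1+E) is available
  but the classic base-2 form is the default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class QuantificationError(ValueError):
    pass


@dataclass
class RelQuantTable:
    """Per-sample, per-gene relative quantities (> 0).

    ``quantities`` is wide (index sample_id, one column per gene);
    ``meta`` is indexed by sample_id with columns animal_id, group, zt.
    """

    quantities: pd.DataFrame
    meta: pd.DataFrame
    normalization: str
    reference_genes: tuple = ()
    calibrator_id: str | None = None

    @property
    def genes(self) -> list:
        return list(self.quantities.columns)

    def long(self) -> pd.DataFrame:
        out = (self.quantities.stack().rename("quantity").reset_index())
        out.columns = ["sample_id", "gene", "quantity"]
        meta = self.meta.rename_axis("sample_id").reset_index()
        return out.merge(meta, on="sample_id", how="left")

    def to_tsv(self, path) -> None:
        self.long().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, normalization: str = "ddCt",
                 reference_genes=(), calibrator_id=None) -> "RelQuantTable":
        df = pd.read_csv(path, sep="\t")
        q = df.pivot(index="sample_id", columns="gene", values="quantity")
        q.columns.name = None
        meta = (df.drop_duplicates("sample_id")
                  .set_index("sample_id")[["animal_id", "group", "zt"]])
        return cls(quantities=q, meta=meta.loc[q.index],
                   normalization=normalization,
                   reference_genes=tuple(reference_genes),
                   calibrator_id=calibrator_id)


def _pivot(agg: pd.DataFrame):
    ct = agg.pivot(index="sample_id", columns="gene", values="ct")
    ct.columns.name = None
    meta = (agg.drop_duplicates("sample_id")
               .set_index("sample_id")[["animal_id", "group", "zt"]])
    return ct, meta.loc[ct.index]


def delta_ct_quantities(agg: pd.DataFrame) -> RelQuantTable:
    """Relative quantities via the delta-Ct method, lowest-Ct sample = 1.

    Genes with fewer than two determined samples are excluded (warned).
    """
    ct, meta = _pivot(agg)
    keep = [g for g in ct.columns if ct[g].notna().sum() >= 2]
    dropped = sorted(set(ct.columns) - set(keep))
    if dropped:
        warnings.warn(f"genes with < 2 determined samples excluded: {dropped}")
    ct = ct[keep]
    q = np.power(2.0, ct.min(axis=0) - ct)
    return RelQuantTable(quantities=q, meta=meta, normalization="deltaCt_minCt")


def ddct_normalize(agg: pd.DataFrame, reference_genes, calibrator_id: str,
                   amplification_factor: float = 2.0) -> RelQuantTable:
    """2^-ddCt quantities normalized to reference genes and a calibrator.

    Reference genes are excluded from the output target set; samples missing
    any reference gene are dropped with a warning; a calibrator missing any
    target or reference gene is an error.  ``amplification_factor`` is 2 for
    the classic method, or 1+E for an efficiency-corrected variant.
    """
    reference_genes = list(reference_genes)
    if not reference_genes:
        raise QuantificationError("reference_genes must be nonempty")
    ct, meta = _pivot(agg)
    for g in reference_genes:
        if g not in ct.columns:
            raise QuantificationError(f"reference gene {g!r} not in table")
    if calibrator_id not in ct.index:
        raise QuantificationError(f"calibrator {calibrator_id!r} not in table")
    targets = [g for g in ct.columns if g not in reference_genes]

    missing_ref = ct[reference_genes].isna().any(axis=1)
    if missing_ref.loc[calibrator_id]:
        gene = next(g for g in reference_genes
                    if pd.isna(ct.loc[calibrator_id, g]))
        raise QuantificationError(f"calibrator missing gene {gene!r}")
    for g in targets:
        if pd.isna(ct.loc[calibrator_id, g]):
            raise QuantificationError(f"calibrator missing gene {g!r}")
    if missing_ref.any():
        dropped = list(ct.index[missing_ref])
        warnings.warn(f"samples missing a reference gene dropped: {dropped}")
        ct = ct.loc[~missing_ref]
        meta = meta.loc[ct.index]

    ref_ct = ct[reference_genes].mean(axis=1)
    dct = ct[targets].sub(ref_ct, axis=0)
    ddct = dct - dct.loc[calibrator_id]
    q = np.power(amplification_factor, -ddct)
    return RelQuantTable(quantities=q, meta=meta, normalization="ddCt",
                         reference_genes=tuple(reference_genes),
                         calibrator_id=calibrator_id)
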