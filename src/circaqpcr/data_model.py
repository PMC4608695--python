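"""Long-format Ct data model: CSV I/O, replicate aggregation and plate-level QC.

The raw observable of an RT-qPCR experiment is the cycle threshold (Ct): the
PCR cycle at which a well's fluorescence crosses the detection threshold.
Lower Ct means more starting template; one cycle corresponds to roughly a
two-fold difference at 100% amplification efficiency.  Data enter as a
long-format table with one row per technical replicate, carrying the sample
metadata needed downstream: animal, group, Zeitgeber time (ZT, hours since
lights-on in a 12:12 light:dark cycle) and plate.

Wells that never cross threshold are exported by instruments as a sentinel
token (``"Undetermined"`` by default) and are represented internally as NaN.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

#: Sentinel token used in CSV files for wells with no amplification signal.
UNDETERMINED_TOKEN = "Undetermined"

#: Canonical column order of the long-format Ct table.
REQUIRED_COLUMNS = (
    "sample_id", "animal_id", "group", "zt", "plate", "gene", "replicate", "ct",
)

#: Accepted group labels.  ``naive`` and ``epileptic`` are the biological
#: groups; ``calibrator`` marks the inter-plate calibrator pseudo-sample of
#: the ddCt workflow and ``ntc`` marks no-template control wells.
GROUP_LABELS = ("naive", "epileptic", "calibrator", "ntc")

#: Light phase of a 12:12 LD cycle is ZT in [0, 12); dark phase [12, 24).
LIGHTS_OFF_ZT = 12.0


class CtTableFormatError(ValueError):
    """The input file does not match the expected long-format layout."""


class CtRecordError(ValueError):
    """A single row could not be parsed (carries the offending line number)."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one biological sample (one animal at one ZT)."""

    sample_id: str
    animal_id: str
    group: str
    zt: float
    plate_id: str

    def __post_init__(self):
        if self.group not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group!r}")
        if not 0.0 <= self.zt < 24.0:
            raise ValueError(f"zt must be in [0, 24), got {self.zt}")


@dataclass
class QCReport:
    """Plate-level QC findings; QC is reported, never silently applied.

    flagged_triplicates
        ``(sample_id, gene, replicate_sd)`` for sample x gene cells whose
        technical-replicate standard deviation exceeded the threshold.  The
        cells are flagged but their mean is retained.
    ntc_failures
        ``(plate_id, gene, ct)`` for no-template control wells that produced
        a determined Ct (possible contamination).
    dropped_records
        Number of sample x gene cells dropped because no replicate was
        determined.
    """

    flagged_triplicates: list = field(default_factory=list)
    ntc_failures: list = field(default_factory=list)
    dropped_records: int = 0
    notes: list = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["flagged_triplicates"] = [list(t) for t in self.flagged_triplicates]
        d["ntc_failures"] = [list(t) for t in self.ntc_failures]
        return json.dumps(d, sort_keys=True, **kwargs)


@dataclass
class CtTable:
    """Replicate-level Ct measurements with sample metadata.

    ``data`` holds one row per technical replicate with columns
    ``sample_id, animal_id, group, zt, plate, gene, replicate, ct, is_ntc``;
    ``ct`` is float with NaN for undetermined wells.
    """

    data: pd.DataFrame
    notes: str = ""

    @property
    def genes(self) -> set:
        return set(self.data.loc[~self.data["is_ntc"], "gene"].unique())

    def sample_meta(self) -> pd.DataFrame:
        """One row per non-NTC sample: animal_id, group, zt, plate."""
        cols = ["sample_id", "animal_id", "group", "zt", "plate"]
        meta = (self.data.loc[~self.data["is_ntc"], cols]
                .drop_duplicates("sample_id")
                .set_index("sample_id"))
        return meta

    def __len__(self) -> int:
        return len(self.data)


def _parse_ct_column(raw: pd.Series, token: str, decimal: str) -> pd.Series:
    vals = raw.astype(str).str.strip()
    is_undet = vals.str.casefold() == token.casefold()
    if decimal != ".":
        vals = vals.str.replace(decimal, ".", regex=False)
    ct = pd.to_numeric(vals.where(~is_undet), errors="coerce")
    bad = ct.isna() & ~is_undet & vals.ne("") & vals.str.casefold().ne("nan")
    if bad.any():
        # +2: one for the header line, one for 0-based positional index
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise CtRecordError(
            f"line {row}: ct value {raw.iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
            f"is neither a number nor the token {token!r}"
        )
    return ct


def read_ct_table(path, columns: dict | None = None,
                  undetermined_token: str = UNDETERMINED_TOKEN,
                  decimal: str = ".") -> CtTable:
    """Read a long-format Ct CSV (one row per technical replicate).

    Parameters
    ----------
    path : path-like
        CSV with header columns ``sample_id, animal_id, group, zt, plate,
        gene, replicate, ct`` (names remappable via ``columns``, a mapping
        from canonical name to the file's column name).  An optional
        ``is_ntc`` column (true/false) marks no-template controls; rows whose
        ``group`` is ``"ntc"`` are treated as NTC as well.
    undetermined_token : str
        Token marking wells with no signal (case-insensitive).
    decimal : str
        Decimal separator of the ``ct`` column (``","`` accepts instrument
        exports from comma-decimal locales).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in REQUIRED_COLUMNS}
    if columns:
        colmap.update(columns)
    for canon, name in colmap.items():
        if name not in raw.columns:
            raise CtTableFormatError(f"column {canon!r} not found")
    df = pd.DataFrame({canon: raw[name] for canon, name in colmap.items()})
    df["ct"] = _parse_ct_column(df["ct"], undetermined_token, decimal)
    df["zt"] = pd.to_numeric(df["zt"].replace("", np.nan), errors="coerce")
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce").astype("Int64")
    if "is_ntc" in raw.columns:
        ntc = raw["is_ntc"].astype(str).str.strip().str.casefold().isin(
            ("true", "1", "yes"))
    else:
        ntc = pd.Series(False, index=df.index)
    df["is_ntc"] = (ntc | df["group"].astype(str).str.casefold().eq("ntc")).to_numpy()
    return CtTable(data=df.reset_index(drop=True))


def write_ct_table(table: CtTable, path,
                   undetermined_token: str = UNDETERMINED_TOKEN) -> None:
    """Write a CtTable back to the long-format CSV (inverse of read)."""
    out = table.data.copy()
    ct = out["ct"].map(lambda v: undetermined_token if pd.isna(v) else repr(float(v)))
    out["ct"] = ct
    out = out[[*REQUIRED_COLUMNS, "is_ntc"]]
    out.to_csv(path, index=False)


def aggregate_replicates(table: CtTable, sd_threshold: float = 0.5):
    """Average technical replicates per sample x gene; flag noisy triplicates.

    Undetermined replicates are excluded from the mean; a sample x gene cell
    with no determined replicate is dropped (and counted in the QC report).
    Cells whose replicate standard deviation (ddof=1) exceeds ``sd_threshold``
    cycles are flagged but retained, so the mean-of-triplicates convention is
    preserved for all analysable cells.

    Returns
    -------
    (pandas.DataFrame, QCReport)
        The frame has one row per sample x gene with columns ``sample_id,
        animal_id, group, zt, plate, gene, ct, n_replicates, replicate_sd``.
    """
    if sd_threshold <= 0:
        raise ValueError("sd_threshold must be > 0")
    rep = table.data.loc[~table.data["is_ntc"]]
    qc = QCReport()
    if rep.empty:
        qc.notes.append("no non-NTC records to aggregate")
        return rep.head(0).assign(n_replicates=0, replicate_sd=0.0), qc

    grouped = rep.groupby(["sample_id", "gene"], sort=True)
    rows = []
    for (sid, gene), g in grouped:
        det = g["ct"].dropna()
        if det.empty:
            qc.dropped_records += 1
            continue
        sd = float(det.std(ddof=1)) if len(det) > 1 else 0.0
        if sd > sd_threshold:
            qc.flagged_triplicates.append((sid, gene, sd))
        first = g.iloc[0]
        rows.append({
            "sample_id": sid, "animal_id": first["animal_id"],
            "group": first["group"], "zt": first["zt"], "plate": first["plate"],
            "gene": gene, "ct": float(det.mean()),
            "n_replicates": int(len(det)), "replicate_sd": sd,
        })
    agg = pd.DataFrame(rows)
    return agg, qc


def validate_ntc(table: CtTable, max_allowed_ct="any-signal") -> QCReport:
    """Check no-template control wells for contamination.

    Default policy ``"any-signal"``: any determined Ct in an NTC well is a
    failure.  A numeric ``max_allowed_ct`` instead flags only NTC wells with
    Ct below that bound (late stochastic signal tolerated).
    """
    qc = QCReport()
    ntc = table.data.loc[table.data["is_ntc"]]
    if ntc.empty:
        msg = "no NTC records present; contamination not checked"
        warnings.warn(msg)
        qc.notes.append(msg)
        return qc
    det = ntc.dropna(subset=["ct"])
    if max_allowed_ct != "any-signal":
        det = det.loc[det["ct"] < float(max_allowed_ct)]
    for _, r in det.iterrows():
        qc.ntc_failures.append((r["plate"], r["gene"], float(r["ct"])))
    return qc
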