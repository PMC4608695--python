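"""Seeded generator of replicate-level Ct panels with diurnal structure.

The generator emulates the design this package analyses: naive rats sampled
every 4 h over one LD cycle (ZT 0..20, five animals per time point),
epileptic rats at one or two ZTs, six hippocampal clock genes with cosine
diurnal profiles, eight candidate reference genes with graded stability, and
triplicate technical replicates per well.

Measurement model (noise lives on the Ct / log2 scale, where qPCR error is
approximately additive):

* target gene i, animal at time t:  true quantity
  ``Q = mesor_i + A_i cos(2 pi (t - phi_i)/24)`` (epileptic animals instead
  follow the gene's epileptic effect), and
  ``Ct = B_i - log2(Q) + e_sample`` with ``e_sample ~ N(0, biological_sd)``
  a per-animal offset shared by every gene of that sample (RNA input /
  RT-efficiency variation — exactly what reference-gene normalization
  removes);
* reference gene r: ``Ct = baseline_r + N(0, instability_sd_r) + e_sample``;
* every technical replicate adds ``N(0, technical_sd)``.

One calibrator pseudo-sample is emitted whose true quantity equals each
gene's mesor; it carries no noise (it is an exact anchor, not a physical
well), so ddCt-normalized quantities sit on the same natural scale as the
generating cosine parameters.  A truth record accompanies every panel for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_model import CtTable, REQUIRED_COLUMNS

FLATTEN_AT_MESOR = "flatten_at_mesor"
LOG2_SHIFT = "log2_shift"
NO_EFFECT = "none"

CALIBRATOR_ID = "CAL"

#: Candidate reference panel with graded instability (cycles), most stable
#: first.  The grading makes Tubb2a/Rplp1 the expected geNorm best pair --
#: the pair the downstream quantification normalizes to -- and Gusb the
#: least stable candidate.
DEFAULT_REFERENCE_PANEL = (
    ("Tubb2a", 20.0, 0.02),
    ("Rplp1", 18.5, 0.06),
    ("Ppia", 19.0, 0.10),
    ("Actb", 17.5, 0.14),
    ("B2m", 21.0, 0.18),
    ("Gapdh", 18.0, 0.22),
    ("Polr1a", 24.0, 0.26),
    ("Gusb", 25.0, 0.30),
)


class GeneratorConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSpec:
    """Cosine diurnal profile of one target gene on the relative-quantity scale."""

    name: str
    amplitude: float
    acrophase: float
    mesor: float = 1.0
    epileptic_effect: str = FLATTEN_AT_MESOR
    log2_shift: float = 0.0
    baseline_ct: float = 25.0

    def __post_init__(self):
        if self.mesor - self.amplitude <= 0:
            raise GeneratorConfigError(
                f"{self.name}: mesor - amplitude must be > 0")
        if not 0.0 <= self.acrophase < 24.0:
            raise GeneratorConfigError(f"{self.name}: acrophase not in [0, 24)")
        if self.epileptic_effect not in (FLATTEN_AT_MESOR, LOG2_SHIFT, NO_EFFECT):
            raise GeneratorConfigError(
                f"{self.name}: unknown epileptic effect {self.epileptic_effect!r}")

    def quantity(self, t: float) -> float:
        return self.mesor + self.amplitude * np.cos(
            2 * np.pi * (t - self.acrophase) / 24.0)

    def epileptic_quantity(self, t: float) -> float:
        if self.epileptic_effect == FLATTEN_AT_MESOR:
            return self.mesor
        if self.epileptic_effect == LOG2_SHIFT:
            return self.quantity(t) * 2.0 ** self.log2_shift
        return self.quantity(t)


@dataclass(frozen=True)
class RefGeneSpec:
    name: str
    baseline_ct: float
    instability_sd: float

    def __post_init__(self):
        if self.instability_sd < 0:
            raise GeneratorConfigError(f"{self.name}: instability_sd < 0")


@dataclass
class GeneratorConfig:
    genes: tuple
    reference_genes: tuple
    zt_grid: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_naive_per_zt: int = 5
    epileptic_zts: tuple = (8.0, 12.0)
    n_epileptic_per_zt: int = 4
    biological_noise_sd: float = 0.15
    technical_noise_sd: float = 0.05
    replicates: int = 3
    include_ntc: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 1:
            raise GeneratorConfigError("replicates must be >= 1")
        if self.biological_noise_sd < 0 or self.technical_noise_sd < 0:
            raise GeneratorConfigError("noise sds must be >= 0")
        if any(not 0.0 <= z < 24.0 for z in (*self.zt_grid, *self.epileptic_zts)):
            raise GeneratorConfigError("ZT values must lie in [0, 24)")
        names = [g.name for g in self.genes] + [r.name for r in self.reference_genes]
        if len(set(names)) != len(names):
            raise GeneratorConfigError("gene names must be unique")


@dataclass
class TruthRecord:
    """Generating parameters and per-sample true quantities of one panel."""

    genes: dict                     # name -> dict(mesor, amplitude, acrophase, effect)
    sample_quantities: pd.DataFrame  # index sample_id, one column per target gene

    def to_json(self, **kwargs) -> str:
        return json.dumps({
            "genes": self.genes,
            "sample_quantities": {
                sid: {g: float(v) for g, v in row.items()}
                for sid, row in self.sample_quantities.iterrows()},
        }, sort_keys=True, **kwargs)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Study-default generator configuration.

    The rhythmic genes carry the published hippocampal cosine parameters
    where available: Per1 (A 0.469, acrophase ZT16), Per3 (ZT14.8), Bmal1
    (ZT2), Cry1 (ZT17.6), Cry2 (A 0.201, ZT7.6), with amplitude 0.30 as a
    declared stand-in for the three genes whose amplitudes were never
    printed.  Clock is non-rhythmic (A 0) and, in epileptic animals, shifted
    down by 0.6 log2 units; all rhythmic genes are flattened at their mesor
    in epileptic animals.
    """
    genes = (
        GeneSpec("Per1", amplitude=0.469, acrophase=16.0, baseline_ct=24.0),
        GeneSpec("Per3", amplitude=0.30, acrophase=14.8, baseline_ct=26.0),
        GeneSpec("Bmal1", amplitude=0.30, acrophase=2.0, baseline_ct=23.0),
        GeneSpec("Cry1", amplitude=0.30, acrophase=17.6, baseline_ct=24.5),
        GeneSpec("Cry2", amplitude=0.201, acrophase=7.6, baseline_ct=25.0),
        GeneSpec("Clock", amplitude=0.0, acrophase=0.0, baseline_ct=23.5,
                 epileptic_effect=LOG2_SHIFT, log2_shift=-0.6),
    )
    refs = tuple(RefGeneSpec(n, b, s) for n, b, s in DEFAULT_REFERENCE_PANEL)
    cfg = GeneratorConfig(genes=genes, reference_genes=refs, seed=seed)
    for key, val in overrides.items():
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def _sample_plan(config: GeneratorConfig):
    """Fixed-order sample list: (sample_id, animal_id, group, zt)."""
    plan = []
    for zt in config.zt_grid:
        for a in range(1, config.n_naive_per_zt + 1):
            sid = f"N_ZT{int(zt):02d}_{a}"
            plan.append((sid, f"naive_{int(zt):02d}_{a}", "naive", float(zt)))
    for zt in config.epileptic_zts:
        for a in range(1, config.n_epileptic_per_zt + 1):
            sid = f"E_ZT{int(zt):02d}_{a}"
            plan.append((sid, f"epi_{int(zt):02d}_{a}", "epileptic", float(zt)))
    plan.append((CALIBRATOR_ID, CALIBRATOR_ID, "calibrator", 0.0))
    return plan


def simulate_panel(config: GeneratorConfig):
    """Simulate one replicate-level Ct panel; deterministic given the seed.

    Returns ``(CtTable, TruthRecord)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    plan = _sample_plan(config)
    plate = "P1"
    rows = []
    truth_rows = {}
    for sid, aid, group, zt in plan:
        is_cal = group == "calibrator"
        offset = 0.0 if is_cal else rng.normal(0.0, config.biological_noise_sd)
        truth_rows[sid] = {}
        for spec in config.genes:
            if is_cal:
                q = spec.mesor
            elif group == "epileptic":
                q = spec.epileptic_quantity(zt)
            else:
                q = spec.quantity(zt)
            truth_rows[sid][spec.name] = float(q)
            base = spec.baseline_ct - np.log2(q) + offset
            for rep in range(1, config.replicates + 1):
                # the calibrator is a noiseless pseudo-sample: an exact
                # anchor, not a physical well
                ct = base if is_cal else base + rng.normal(
                    0.0, config.technical_noise_sd)
                rows.append((sid, aid, group, zt, plate, spec.name, rep, ct, False))
        for ref in config.reference_genes:
            base = ref.baseline_ct + offset
            if not is_cal:
                base += rng.normal(0.0, ref.instability_sd)
            for rep in range(1, config.replicates + 1):
                ct = base if is_cal else base + rng.normal(
                    0.0, config.technical_noise_sd)
                rows.append((sid, aid, group, zt, plate, ref.name, rep, ct, False))
    if config.include_ntc:
        for name in ([g.name for g in config.genes]
                     + [r.name for r in config.reference_genes]):
            rows.append((f"NTC_{name}", "", "ntc", 0.0, plate, name, 1,
                         np.nan, True))

    data = pd.DataFrame(rows, columns=[*REQUIRED_COLUMNS, "is_ntc"])
    truth = TruthRecord(
        genes={g.name: {
            "mesor": g.mesor, "amplitude": g.amplitude,
            "acrophase": g.acrophase, "epileptic_effect": g.epileptic_effect,
            "log2_shift": g.log2_shift} for g in config.genes},
        sample_quantities=pd.DataFrame.from_dict(truth_rows, orient="index")
    )
    return CtTable(data=data, notes=f"simulated panel, seed={config.seed}"), truth
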