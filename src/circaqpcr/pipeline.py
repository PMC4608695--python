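"""End-to-end orchestration: qc -> quantify -> stability -> rhythm -> diffexp.

Each stage persists a TSV (with a JSON sidecar for structured results) so
any stage can be re-run from its predecessor's file, and the whole run is
reproducible byte-for-byte given the same configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_model, diffexpr, quantify, refstab, rhythm, synthetic

SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending context."""


@dataclass
class RunConfig:
    ct_table: data_model.CtTable = None
    ct_path: object = None
    candidate_reference_genes: tuple = tuple(
        n for n, _, _ in synthetic.DEFAULT_REFERENCE_PANEL)
    target_genes: tuple = ("Per1", "Per3", "Bmal1", "Clock", "Cry1", "Cry2")
    reference_genes: object = "auto"     # "auto" -> geNorm best pair
    calibrator_id: str = synthetic.CALIBRATOR_ID
    stability_groups: str = "zt"         # "zt" or "none"
    alpha: float = 0.05
    sd_threshold: float = 0.5
    epileptic_zts: tuple = (8.0, 12.0)
    naive_zts: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    pool_phases: bool = False
    bh: bool = False
    on_means: bool = False
    outdir: object = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ReportBundle:
    qc: data_model.QCReport
    ntc: data_model.QCReport
    genorm: refstab.GenormResult
    normfinder: refstab.NormfinderResult
    reference_genes: tuple
    quant: quantify.RelQuantTable
    cosinor: dict                         # gene -> CosinorFit
    harmonic: dict                        # gene -> HarmonicFit
    phase_relations: pd.DataFrame
    comparisons: list
    phase_sensitivity: diffexpr.PhaseSensitivityReport
    log: list = field(default_factory=list)

    def rhythm_table(self) -> pd.DataFrame:
        rows = []
        for gene, f in self.cosinor.items():
            h = self.harmonic[gene]
            rows.append({
                "gene": gene, "n": f.n, "mesor": f.mesor,
                "amplitude": f.amplitude, "acrophase": f.acrophase,
                "F": f.f_statistic, "p_zero_amplitude": f.p_zero_amplitude,
                "ci_mesor_lo": f.ci_mesor[0], "ci_mesor_hi": f.ci_mesor[1],
                "ci_amplitude_lo": f.ci_amplitude[0],
                "ci_amplitude_hi": f.ci_amplitude[1],
                "ci_acrophase_lo": f.ci_acrophase[0],
                "ci_acrophase_hi": f.ci_acrophase[1],
                "harmonics": ",".join(map(str, h.retained_harmonics)),
                "p_harmonic": h.p_value,
                "rhythmic": bool(f.degenerate or f.p_zero_amplitude < 0.05),
            })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        d = {
            "schema_version": SCHEMA_VERSION,
            "qc": json.loads(self.qc.to_json()),
            "ntc": json.loads(self.ntc.to_json()),
            "genorm": {
                "m_values": self.genorm.m_values,
                "ranking": self.genorm.ranking,
                "best_pair": list(self.genorm.best_pair),
                "pairwise_variation": [[n, v] for n, v
                                       in self.genorm.pairwise_variation],
                "recommended_count": self.genorm.recommended_count,
            },
            "normfinder": {
                "stability": self.normfinder.stability,
                "best_gene": self.normfinder.best_gene,
                "best_pair": list(self.normfinder.best_pair),
                "groups_used": [str(g) for g in self.normfinder.groups_used],
            },
            "reference_genes": list(self.reference_genes),
            "rhythm": self.rhythm_table().to_dict(orient="records"),
            "phase_relations": self.phase_relations.to_dict(orient="records"),
            "differential_expression": [dataclasses.asdict(c)
                                        for c in self.comparisons],
            "phase_sensitivity": {
                f"{gene}@ZT{zt:g}": label
                for (gene, zt), label in self.phase_sensitivity.labels.items()},
            "log": self.log,
        }
        return json.dumps(d, sort_keys=True, indent=1)


def _load_table(config: RunConfig) -> data_model.CtTable:
    if config.ct_table is not None:
        return config.ct_table
    if config.ct_path is not None:
        return data_model.read_ct_table(config.ct_path)
    raise PipelineError("input: neither ct_table nor ct_path given")


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute all stages in order and (optionally) persist the report."""
    log = []
    table = _load_table(config)

    try:
        agg, qc = data_model.aggregate_replicates(table, config.sd_threshold)
        ntc = data_model.validate_ntc(table)
    except Exception as e:      # pragma: no cover - defensive context wrap
        raise PipelineError(f"qc stage: {e}") from e
    log.append(f"qc: {len(agg)} sample x gene cells, "
               f"{len(qc.flagged_triplicates)} flagged, "
               f"{qc.dropped_records} dropped, "
               f"{len(ntc.ntc_failures)} NTC failures")

    try:
        candidates = [g for g in config.candidate_reference_genes
                      if g in set(agg["gene"])]
        dq = quantify.delta_ct_quantities(
            agg[agg["gene"].isin(candidates)])
        groups = (dq.meta["zt"] if config.stability_groups == "zt" else None)
        gn = refstab.genorm(dq)
        nf = refstab.normfinder_stability(dq, groups=groups)
    except Exception as e:
        raise PipelineError(f"stability stage: {e}") from e
    if config.reference_genes == "auto":
        refs = gn.best_pair
        log.append(f"stability: geNorm best pair {refs} selected; "
                   f"NormFinder alternative {nf.best_pair} "
                   f"(best single {nf.best_gene})")
    else:
        refs = tuple(config.reference_genes)
        log.append(f"stability: user-specified reference genes {refs}")

    try:
        keep = agg["gene"].isin([*refs, *config.target_genes])
        q = quantify.ddct_normalize(agg[keep], refs, config.calibrator_id)
    except Exception as e:
        raise PipelineError(f"quantify stage: {e}") from e

    try:
        cosinor_fits, harmonic_fits = {}, {}
        naive = q.meta["group"] == "naive"
        for gene in config.target_genes:
            t = q.meta.loc[naive, "zt"].to_numpy(dtype=float)
            yv = q.quantities.loc[naive, gene].to_numpy(dtype=float)
            if config.on_means:
                means = (pd.DataFrame({"zt": t, "q": yv})
                         .groupby("zt")["q"].mean())
                t, yv = means.index.to_numpy(), means.to_numpy()
            cosinor_fits[gene] = rhythm.cosinor_fit(t, yv, gene=gene)
            harmonic_fits[gene] = rhythm.harmonic_regression(
                t, yv, alpha=config.alpha, gene=gene)
        relations = rhythm.phase_relation(
            [f for f in cosinor_fits.values()
             if f.degenerate or f.p_zero_amplitude < config.alpha])
    except Exception as e:
        raise PipelineError(f"rhythm stage: {e}") from e
    n_rhythmic = sum(f.degenerate or f.p_zero_amplitude < config.alpha
                     for f in cosinor_fits.values())
    log.append(f"rhythm: {n_rhythmic}/{len(cosinor_fits)} genes rhythmic "
               f"at alpha={config.alpha:g}")

    comparisons = []
    try:
        present_epi_zts = sorted(
            set(q.meta.loc[q.meta["group"] == "epileptic", "zt"])
            & set(config.epileptic_zts))
        for ezt in present_epi_zts:
            comparisons.extend(diffexpr.zt_stratified_tests(
                q, ezt, config.naive_zts, genes=config.target_genes,
                alpha=config.alpha, pool_phases=config.pool_phases,
                bh=config.bh))
        sensitivity = (diffexpr.classify_phase_sensitivity(comparisons)
                       if comparisons else diffexpr.PhaseSensitivityReport())
    except Exception as e:
        raise PipelineError(f"diffexp stage: {e}") from e
    log.append(f"diffexp: {len(comparisons)} comparisons across "
               f"epileptic ZTs {present_epi_zts}")

    bundle = ReportBundle(qc=qc, ntc=ntc, genorm=gn, normfinder=nf,
                          reference_genes=refs, quant=q,
                          cosinor=cosinor_fits, harmonic=harmonic_fits,
                          phase_relations=relations, comparisons=comparisons,
                          phase_sensitivity=sensitivity, log=log)
    if config.outdir is not None:
        _persist(bundle, Path(config.outdir))
    return bundle


def _persist(bundle: ReportBundle, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.quant.to_tsv(outdir / "quantities.tsv")
    bundle.rhythm_table().to_csv(outdir / "rhythm.tsv", sep="\t", index=False)
    diffexpr.comparisons_frame(bundle.comparisons).to_csv(
        outdir / "differential_expression.tsv", sep="\t", index=False)
    (outdir / "report.json").write_text(bundle.to_json())


def estimate_rhythm_parameters(seed: int, config=None,
                               reference_genes=("Tubb2a", "Rplp1"),
                               on_means: bool = False) -> dict:
    """Simulate one naive panel and run it through to cosinor fits.

    The workhorse of the parameter-recovery studies: generates a
    study-default naive panel (no epileptic animals) with the given seed,
    aggregates replicates, ddCt-normalizes against ``reference_genes`` and
    the calibrator pseudo-sample, and fits a 24-h cosinor per target gene.
    Returns ``{gene: CosinorFit}``.
    """
    if config is None:
        config = synthetic.default_config(seed=seed, epileptic_zts=())
    else:
        config.seed = seed
    table, _ = synthetic.simulate_panel(config)
    agg, _ = data_model.aggregate_replicates(table)
    keep = agg["gene"].isin([*reference_genes,
                             *[g.name for g in config.genes]])
    q = quantify.ddct_normalize(agg[keep], reference_genes,
                                synthetic.CALIBRATOR_ID)
    naive = q.meta["group"] == "naive"
    fits = {}
    for spec in config.genes:
        t = q.meta.loc[naive, "zt"].to_numpy(dtype=float)
        yv = q.quantities.loc[naive, spec.name].to_numpy(dtype=float)
        if on_means:
            means = pd.DataFrame({"zt": t, "q": yv}).groupby("zt")["q"].mean()
            t, yv = means.index.to_numpy(), means.to_numpy()
        fits[spec.name] = rhythm.cosinor_fit(t, yv, gene=spec.name)
    return fits
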