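"""End-to-end orchestration: simulate/ingest -> build -> classify -> evaluate.

Each runner executes the full signature-development flow on a cohort (a
simulated :class:`~reosig.simulate.Cohort` or matrices + phenotype tables
read from disk), returns every intermediate in a result object, and records a
manifest with the configuration, per-stage input/output counts and the seed,
so that any number in the final report is recomputable from the persisted
intermediates. ``persist`` writes the intermediates as TSV/CSV/JSON next to
each other in an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Sequence

import pandas as pd

from . import diagnosis, rankcomp, relapse, reo, survival as surv
from .simulate import Cohort, SimulationConfig, simulate_cohort

__all__ = [
    "DiagnosisRun",
    "RelapseRun",
    "run_diagnosis_pipeline",
    "run_relapse_pipeline",
]


class PipelineError(RuntimeError):
    """Raised with the failing stage's name when a pipeline stage aborts."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage: {stage}] {message}")
        self.stage = stage


def _stage_samples(phenotype: pd.DataFrame, group: str, stage: str | None = None) -> list[str]:
    mask = phenotype["group"] == group
    if stage is not None:
        mask &= phenotype["stage"] == stage
    return phenotype.loc[mask, "sample_id"].tolist()


@dataclasses.dataclass
class DiagnosisRun:
    signature: diagnosis.DiagnosisSignature
    predictions: pd.DataFrame
    accuracy: pd.DataFrame
    manifest: dict


@dataclasses.dataclass
class RelapseRun:
    degs: pd.DataFrame
    candidates: pd.DataFrame
    signature: relapse.RelapseSignature
    selection_grid: pd.DataFrame
    predictions: pd.DataFrame
    survival_report: dict
    manifest: dict


def run_diagnosis_pipeline(
    cohort: Cohort | None = None,
    *,
    config: SimulationConfig | None = None,
    expression: pd.DataFrame | None = None,
    phenotype: pd.DataFrame | None = None,
    stable_threshold: float = 0.99,
    vote_cutoff: float = 0.60,
    training_stage: str | None = "I",
    max_genes: int = reo.DEFAULT_MAX_GENES,
    persist: str | None = None,
) -> DiagnosisRun:
    """Stable opposite pairs -> avgRD -> redundancy removal -> vote -> accuracy.

    Training cancer samples default to stage I (set ``training_stage=None``
    to train on every cancer sample); normals are the training contrast. The
    signature is then applied to every sample in the matrix.
    """
    if cohort is None and config is not None:
        cohort = simulate_cohort(config)
    if cohort is not None:
        expression, phenotype = cohort.expression, cohort.phenotype
    if expression is None or phenotype is None:
        raise PipelineError("ingest", "need a cohort or expression + phenotype tables")
    normals = _stage_samples(phenotype, "normal")
    cancers = _stage_samples(phenotype, "cancer", training_stage)
    if not normals or not cancers:
        raise PipelineError("ingest", "training requires normal and cancer samples")
    try:
        signature = diagnosis.build_diagnosis_signature(
            expression, cancers, expression, normals,
            stable_threshold=stable_threshold, vote_cutoff=vote_cutoff,
            max_genes=max_genes,
        )
    except ValueError as exc:
        raise PipelineError("build_signature", str(exc)) from exc
    predictions = diagnosis.classify_samples(expression, signature)
    accuracy = diagnosis.evaluate_accuracy(expression, phenotype, signature)
    manifest = {
        "pipeline": "diagnosis",
        "stable_threshold": stable_threshold,
        "vote_cutoff": vote_cutoff,
        "training_stage": training_stage,
        "n_training_cancer": len(cancers),
        "n_training_normal": len(normals),
        "n_candidate_pairs": signature.meta["n_candidates"],
        "n_signature_pairs": len(signature),
        "n_classified": len(predictions),
        "seed": cohort.config.seed if cohort is not None else None,
    }
    run = DiagnosisRun(signature, predictions, accuracy, manifest)
    if persist:
        _persist_diagnosis(run, persist)
    return run


def run_relapse_pipeline(
    cohort: Cohort | None = None,
    *,
    config: SimulationConfig | None = None,
    expression: pd.DataFrame | None = None,
    phenotype: pd.DataFrame | None = None,
    survival_table: pd.DataFrame | None = None,
    ff: pd.DataFrame | None = None,
    ffpe: pd.DataFrame | None = None,
    pairing: dict[str, str] | None = None,
    stable_fdr: float = 0.20,
    deg_fdr: float = 0.05,
    pair_fdr: float = 0.01,
    min_concordant: int = 10,
    block_base: int = 3500,
    block_step: int = 1000,
    cutoffs: Sequence[float] = (0.49, 0.50, 0.51),
    horizon: float | None = None,
    max_genes: int = reo.DEFAULT_MAX_GENES,
    persist: str | None = None,
) -> RelapseRun:
    """RankComp DEGs -> DEG-anchored reversed pairs -> FFPE filter -> C_IVI
    ranking -> partition -> selection -> relapse vote -> survival report.

    Stage I and IV tumours are the training contrast; the chosen signature is
    applied to stage II/III samples, whose follow-up (if available) feeds the
    Kaplan-Meier / log-rank / Cox / Schoenfeld report. ``horizon`` applies
    administrative censoring (months) before the survival analyses.
    """
    if cohort is None and config is not None:
        cohort = simulate_cohort(config)
    if cohort is not None:
        expression, phenotype = cohort.expression, cohort.phenotype
        survival_table = cohort.survival
        ff, ffpe, pairing = cohort.ff, cohort.ffpe, cohort.pairing
    if expression is None or phenotype is None:
        raise PipelineError("ingest", "need a cohort or expression + phenotype tables")
    stage_i = _stage_samples(phenotype, "cancer", "I")
    stage_iv = _stage_samples(phenotype, "cancer", "IV")
    if not stage_i or not stage_iv:
        raise PipelineError("ingest", "need stage I and stage IV training samples")

    try:
        degs = rankcomp.rankcomp_degs(
            expression, stage_i, expression, stage_iv,
            stable_fdr=stable_fdr, deg_fdr=deg_fdr, max_genes=max_genes,
        )
    except ValueError as exc:
        raise PipelineError("rankcomp_degs", str(exc)) from exc
    if degs.empty:
        raise PipelineError("rankcomp_degs", "no DEGs between stage I and stage IV")

    candidates = relapse.deg_anchored_opposite_pairs(
        expression, stage_i, expression, stage_iv,
        degs["gene"], fdr=pair_fdr, max_genes=max_genes,
    )
    n_anchored = len(candidates)
    if candidates.empty:
        raise PipelineError(
            "deg_anchored_pairs",
            f"no significant opposite pairs among {len(degs)} DEGs",
        )
    if ff is not None and ffpe is not None and pairing:
        candidates = relapse.paired_concordance_filter(
            candidates, ff, ffpe, pairing, min_concordant=min_concordant
        )
        if candidates.empty:
            raise PipelineError(
                "ffpe_filter",
                f"all {n_anchored} candidates failed the paired FF/FFPE filter",
            )
    candidates = relapse.coverage_difference(
        candidates, expression, stage_iv, expression, stage_i
    )
    ranked = relapse.sort_candidates(candidates)
    blocks = relapse.partition_candidates(ranked, base=block_base, step=block_step)
    signature, grid = relapse.select_relapse_signature(
        blocks, expression, stage_i, expression, stage_iv, cutoffs=cutoffs
    )

    targets = _stage_samples(phenotype, "cancer", "II") + _stage_samples(
        phenotype, "cancer", "III"
    )
    predictions = relapse.predict_samples(expression[targets], signature)

    survival_report: dict = {}
    if survival_table is not None and len(survival_table) > 0:
        # predicted risk replaces any latent risk column carried by the table
        records = survival_table.drop(columns=["risk_group"], errors="ignore").join(
            predictions["label"].rename("risk_group"), how="inner"
        )
        if horizon is not None:
            records = surv.truncate_followup(records, horizon)
        groups = records.groupby("risk_group")
        if records["risk_group"].nunique() == 2 and records["event"].sum() > 0:
            high = groups.get_group("high_risk")
            low = groups.get_group("low_risk")
            chi2, logrank_p = surv.logrank_test(high, low)
            cox = surv.cox_fit(records)
            survival_report = {
                "n_high_risk": int(len(high)),
                "n_low_risk": int(len(low)),
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
                "cox_converged": cox.converged,
            }
            if cox.converged:
                term = cox.summary.index[0]
                survival_report.update(
                    hazard_ratio=cox.hazard_ratio(term),
                    hr_ci=[float(cox.summary.loc[term, "ci_lower"]),
                           float(cox.summary.loc[term, "ci_upper"])],
                    cox_p=float(cox.summary.loc[term, "p"]),
                )
                if int(records["event"].sum()) >= 3:
                    survival_report["schoenfeld_p"] = surv.schoenfeld_test(cox)
            survival_report["km"] = {
                "high_risk": surv.km_curve(high).to_dict(orient="list"),
                "low_risk": surv.km_curve(low).to_dict(orient="list"),
            }
        else:
            survival_report = {"note": "risk groups or events insufficient for tests"}

    manifest = {
        "pipeline": "relapse",
        "stable_fdr": stable_fdr,
        "deg_fdr": deg_fdr,
        "pair_fdr": pair_fdr,
        "min_concordant": min_concordant,
        "block_base": block_base,
        "block_step": block_step,
        "cutoffs": list(cutoffs),
        "n_stage_i": len(stage_i),
        "n_stage_iv": len(stage_iv),
        "n_degs": len(degs),
        "n_deg_anchored_pairs": n_anchored,
        "n_after_ffpe_filter": len(candidates),
        "block_sizes": [len(b) for b in blocks],
        "selected_block": signature.block_index,
        "selected_cutoff": signature.vote_cutoff,
        "n_signature_pairs": len(signature),
        "seed": cohort.config.seed if cohort is not None else None,
    }
    run = RelapseRun(degs, candidates, signature, grid, predictions, survival_report, manifest)
    if persist:
        _persist_relapse(run, persist)
    return run


def _ensure_dir(path: str) -> None:
    os.makedirs(path, exist_ok=True)


def _persist_diagnosis(run: DiagnosisRun, outdir: str) -> None:
    _ensure_dir(outdir)
    run.signature.pairs.to_csv(os.path.join(outdir, "diagnosis_signature.tsv"),
                               sep="\t", index=False)
    run.predictions.to_csv(os.path.join(outdir, "diagnosis_predictions.csv"), index=False)
    run.accuracy.to_csv(os.path.join(outdir, "diagnosis_accuracy.csv"), index=False)
    with open(os.path.join(outdir, "diagnosis_manifest.json"), "w") as fh:
        json.dump(run.manifest, fh, indent=2)


def _persist_relapse(run: RelapseRun, outdir: str) -> None:
    _ensure_dir(outdir)
    run.degs.to_csv(os.path.join(outdir, "relapse_degs.tsv"), sep="\t", index=False)
    run.candidates.to_csv(os.path.join(outdir, "relapse_candidates.tsv"),
                          sep="\t", index=False)
    run.signature.pairs.to_csv(os.path.join(outdir, "relapse_signature.tsv"),
                               sep="\t", index=False)
    run.selection_grid.to_csv(os.path.join(outdir, "relapse_selection_grid.csv"), index=False)
    run.predictions.to_csv(os.path.join(outdir, "relapse_predictions.csv"), index=False)
    report = {k: v for k, v in run.survival_report.items() if k != "km"}
    with open(os.path.join(outdir, "relapse_manifest.json"), "w") as fh:
        json.dump({"manifest": run.manifest, "survival": report}, fh, indent=2)
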