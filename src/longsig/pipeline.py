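"""End-to-end orchestration: simulate/load -> QC -> match -> associate ->
risk model -> signatures, with seeded determinism and per-stage manifests.

Stage outputs are plain files (TSVs + a JSON manifest), so each stage can be
replayed and inspected in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, ancestry, association, qc, risk, signatures
from .io import StudyBundle, read_study, write_study
from .simulate import StudyConfig, generate_study
from .study import GenotypeStudy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "longsig_run"
    study_prefix: str | None = None        # load instead of simulating
    study_dialect: str = "internal_tsv"
    simulation: StudyConfig = field(default_factory=StudyConfig)
    qc_thresholds: qc.QcThresholds = field(default_factory=qc.QcThresholds)
    do_matching: bool = False
    match_target_ratio: float = 0.88
    match_k_range: tuple[int, int] = (2, 10)
    n_pcs: int = 10
    alpha: float = 2.0
    candidate_pool: int = 500
    prune_bf_pair: float = 100.0
    prune_bf_multi: float = 10.0
    model_size_cap: int = 400
    prior_el: float = 0.5
    select_tol: float = 0.02
    select_acc_min: float = 0.85
    min_cluster_size: int = 8
    seed: int = 0


def run_discovery(config: PipelineConfig) -> dict:
    """Execute the discovery flow and write all artifacts to ``out_dir``.

    Returns a dict of in-memory artifacts (study, association table, model
    set, profiles, clusters, reports) keyed by stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    if config.study_prefix is not None:
        bundle = StudyBundle(config.study_prefix, config.study_dialect)
        study = read_study(bundle)
        logger.info("loaded study: %d subjects x %d SNPs", study.n_subjects, study.n_snps)
    else:
        study = generate_study(config.simulation)
        write_study(study, StudyBundle(out / "study", "internal_tsv"))
        logger.info("simulated study: %d subjects x %d SNPs", study.n_subjects, study.n_snps)
    manifest["stages"]["input"] = _counts(study)

    study, sample_report = qc.apply_sample_qc(study, config.qc_thresholds)
    study, snp_report = qc.apply_snp_qc(study, config.qc_thresholds)
    sample_report.to_csv(out / "qc_samples.tsv", sep="\t", index=False)
    snp_report.to_csv(out / "qc_snps.tsv", sep="\t", index=False)
    manifest["stages"]["qc"] = _counts(study)
    logger.info("after QC: %d subjects x %d SNPs", study.n_subjects, study.n_snps)

    clustering = None
    if config.do_matching:
        pruned = ancestry.ld_prune(study)
        pcs = ancestry.compute_pcs(study, n_components=config.n_pcs, snp_ids=pruned)
        clustering = ancestry.cluster_ancestry(
            pcs, k_range=config.match_k_range, seed=config.seed,
            subject_ids=study.subject_ids,
        )
        case_ids = study.subject_ids[study.case_mask]
        pool = study.subject_ids[study.control_mask]
        selected, match_table = ancestry.match_controls(
            clustering, case_ids, pool, config.match_target_ratio, seed=config.seed,
        )
        match_table.to_csv(out / "matching.tsv", sep="\t", index=False)
        keep = study.case_mask | np.isin(study.subject_ids, selected)
        study = study.subset(subject_mask=keep)
        manifest["stages"]["matching"] = _counts(study)

    assoc = association.associate(study, alpha=config.alpha)
    assoc = assoc.sort_values("log10_mbf", ascending=False).reset_index(drop=True)
    assoc.to_csv(out / "association.tsv", sep="\t", index=False)
    lam = association.genomic_control_lambda(association.allelic_chi2(study))
    manifest["stages"]["association"] = {"genomic_control_lambda": lam}

    pool_ids = assoc["snp_id"].head(config.candidate_pool).tolist()
    pruned_ids = risk.prune_correlated(
        study, pool_ids, config.prune_bf_pair, config.prune_bf_multi,
        alpha=config.alpha,
    )[: config.model_size_cap]
    tags = dict(zip(assoc["snp_id"], assoc["best_model"]))
    model_set = risk.fit_nested(
        study, pruned_ids, best_models=tags, alpha=config.alpha,
        prior_el=config.prior_el,
    )
    model_set.save(out / "model.tsv")

    profiles = risk.risk_profiles(study, model_set)
    labels = study.subject_meta["phenotype"].to_numpy()
    sens, spec = risk.sens_spec_traces(profiles, labels)
    k_star, qualified = risk.select_k(
        sens, spec, tol=config.select_tol, acc_min=config.select_acc_min
    )
    scores = profiles.mean(axis=1)
    report = risk.evaluate(scores, labels)
    pd.DataFrame(
        {"k": np.arange(1, model_set.k + 1), "sensitivity": sens, "specificity": spec}
    ).to_csv(out / "traces.tsv", sep="\t", index=False)
    manifest["stages"]["risk_model"] = {
        "k_selected": k_star, "k_qualified": qualified,
        "sensitivity": report.sensitivity, "specificity": report.specificity,
        "auc": report.auc,
    }

    case_profiles = profiles[study.case_mask]
    case_ids = study.subject_ids[study.case_mask]
    clusters, sporadic = signatures.cluster_profiles(
        case_profiles, subject_ids=case_ids,
        min_report_size=config.min_cluster_size, seed=config.seed,
    )
    assignments = pd.DataFrame(
        [(m, c.cluster_id, c.stratum) for c in clusters for m in c.member_ids]
        + [(s, -1, "sporadic") for s in sporadic],
        columns=["subject_id", "cluster", "stratum"],
    )
    assignments.to_csv(out / "signatures.tsv", sep="\t", index=False)
    manifest["stages"]["signatures"] = {
        "n_clusters": len(clusters),
        "n_sporadic": len(sporadic),
        "fraction_clustered": 1 - len(sporadic) / max(len(case_ids), 1),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return {
        "study": study, "association": assoc, "model_set": model_set,
        "profiles": profiles, "clusters": clusters, "sporadic": sporadic,
        "clustering": clustering, "manifest": manifest,
        "eval_report": report, "k_selected": k_star,
    }


def run_replication(
    model_set: risk.NestedModelSet,
    study: GenotypeStudy,
    age_bins: list[float] | None = None,
) -> risk.EvalReport:
    """Evaluate a trained ensemble on an independent study without refitting.

    Predicts over the SNP intersection (absent SNPs are treated as missing
    genotypes and logged); reports overall and optional per-age-stratum
    sensitivity.
    """
    shared = set(study.snp_ids) & set(model_set.snp_ids)
    if not shared:
        raise ValueError("no SNP overlap between model and replication study")
    profiles = risk.risk_profiles(study, model_set)
    scores = profiles.mean(axis=1)
    return risk.evaluate(
        scores,
        study.subject_meta["phenotype"].to_numpy(),
        ages=study.subject_meta["age_years"].to_numpy() if age_bins else None,
        age_bins=age_bins,
    )


def _counts(study: GenotypeStudy) -> dict:
    return {
        "subjects": study.n_subjects,
        "cases": int(study.case_mask.sum()),
        "controls": int(study.control_mask.sum()),
        "snps": study.n_snps,
    }


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
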