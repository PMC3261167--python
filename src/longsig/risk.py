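"""Nested naive-Bayes genetic risk models and the ensemble predictor.

SNPs ranked by log10 maximum Bayes factor define nested sets
``S_1 c S_2 c ... c S_K``; the k-th classifier computes, for a subject with
genotypes g,

    p(EL | S_k) = p(EL) prod_i p(g_i|EL) /
                  [ p(EL) prod_i p(g_i|EL) + p(AL) prod_i p(g_i|AL) ]

with conditional genotype probabilities estimated by posterior means under
a Dirichlet prior, each SNP entering under the recoding of its best
single-SNP model. The subject's genetic risk profile is the vector
``(p(EL|S_1), ..., p(EL|S_K))``; the ensemble score is its mean, and the
classification rule is EL iff score >= 0.5 (with prior 0.5 the rule is
prior-independent). Missing genotypes contribute no factor
(missing-at-random).

A useful exact property: ``p(EL|S_{k+1}) > p(EL|S_k)`` iff the subject's
genotype at the (k+1)-th SNP is more probable in cases than in controls --
profiles literally trace the subject's enrichment for longevity-associated
variants.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .association import (
    DEFAULT_ALPHA,
    estimate_conditional_probs,
    log10_bayes_factor,
    max_bayes_factor,
    recode,
)
from .study import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)

#: genotype code (count of M) -> category index per model recoding
_N_CATEGORIES = {"genotypic": 3, "allelic": 3, "dominant": 2, "recessive": 2}


def _category_of(code: np.ndarray, model: str) -> np.ndarray:
    """Map genotype codes {2,1,0} to table-category indices; MISSING -> -1."""
    out = np.full(code.shape, -1, dtype=np.int8)
    valid = code != MISSING
    if model in ("genotypic", "allelic"):
        out[valid] = 2 - code[valid]          # MM, Mm, mm -> 0, 1, 2
    elif model == "dominant":
        out[valid] = (code[valid] == 0).astype(np.int8)   # carrier=0, mm=1
    elif model == "recessive":
        out[valid] = (code[valid] != 2).astype(np.int8)   # MM=0, other=1
    else:
        raise ValueError(model)
    return out


@dataclass
class SnpRiskModel:
    snp_id: str
    model: str                      # best single-SNP genetic model tag
    p_el: np.ndarray                # conditional category probabilities, cases
    p_al: np.ndarray                # conditional category probabilities, controls


@dataclass
class NestedModelSet:
    """Ordered per-SNP conditional tables defining the K nested classifiers."""

    snps: list[SnpRiskModel]
    prior_el: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.prior_el < 1:
            raise ValueError("prior must be in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    # -- serialization: TSV of tables + JSON header, human-diffable --------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        header = {"prior_el": self.prior_el, "k": self.k}
        rows = []
        for rank, s in enumerate(self.snps, start=1):
            for cat, (pe, pa) in enumerate(zip(s.p_el, s.p_al)):
                rows.append({"rank": rank, "snp_id": s.snp_id, "model": s.model,
                             "category": cat, "p_el": pe, "p_al": pa})
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header) + "\n")
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path: str | Path) -> "NestedModelSet":
        path = Path(path)
        with open(path) as fh:
            header = json.loads(fh.readline().lstrip("#"))
            table = pd.read_csv(fh, sep="\t")
        snps = []
        for (rank, snp_id, model), sub in table.groupby(
            ["rank", "snp_id", "model"], sort=False
        ):
            sub = sub.sort_values("category")
            snps.append(SnpRiskModel(str(snp_id), str(model),
                                     sub["p_el"].to_numpy(),
                                     sub["p_al"].to_numpy()))
        return cls(snps=snps, prior_el=float(header["prior_el"]))


@dataclass
class RiskProfile:
    subject_id: str
    posteriors: np.ndarray

    @property
    def ensemble(self) -> float:
        return float(self.posteriors.mean())

    @property
    def classification(self) -> str:
        return "EL" if self.ensemble >= 0.5 else "AL"


@dataclass
class EvalReport:
    sensitivity: float | None
    specificity: float | None
    auc: float | None
    tp: int
    fn: int
    tn: int
    fp: int
    by_age: pd.DataFrame | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_nested(
    study: GenotypeStudy,
    snp_ids: list[str],
    best_models: dict[str, str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    prior_el: float = 0.5,
) -> NestedModelSet:
    """Estimate the per-SNP conditional tables on a training study.

    ``snp_ids`` must already be ranked (decreasing log10 MBF). Each SNP's
    table is the posterior-mean genotype distribution per phenotype under
    its best single-SNP model's recoding; when the allelic model wins, the
    3-category genotype table is used for prediction, because a subject
    contributes one genotype, not two independent alleles.
    """
    if not (study.case_mask.any() and study.control_mask.any()):
        raise ValueError("training study needs both phenotypes")
    idx = study.snp_index(snp_ids)
    cases, controls = study.genotype_counts()
    snps = []
    for snp_id, j in zip(snp_ids, idx):
        counts = np.stack([cases[j], controls[j]])
        if best_models is not None and snp_id in best_models:
            model = best_models[snp_id]
        else:
            _, model, _ = max_bayes_factor(counts, alpha)
        table = counts if model in ("genotypic", "allelic") else recode(counts, model)
        probs = estimate_conditional_probs(table, alpha)
        snps.append(SnpRiskModel(str(snp_id), model, probs[0], probs[1]))
    return NestedModelSet(snps=snps, prior_el=prior_el)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _log_likelihood_ratios(
    study: GenotypeStudy, model_set: NestedModelSet
) -> np.ndarray:
    """(n_subjects, K) per-SNP log [p(g|EL)/p(g|AL)]; 0 where missing."""
    present = set(study.snp_ids)
    cols = np.zeros((study.n_subjects, model_set.k))
    for k, s in enumerate(model_set.snps):
        if s.snp_id not in present:
            logger.warning("SNP %s absent from study; treated as missing", s.snp_id)
            continue
        j = int(study.snp_index([s.snp_id])[0])
        cat = _category_of(study.genotypes[:, j], s.model)
        llr = np.log(s.p_el) - np.log(s.p_al)
        valid = cat >= 0
        cols[valid, k] = llr[cat[valid]]
    return cols


def risk_profiles(study: GenotypeStudy, model_set: NestedModelSet) -> np.ndarray:
    """Posterior p(EL|S_k) for every subject and every nested set.

    Computed in log space via cumulative log-likelihood-ratio sums, so K in
    the hundreds cannot underflow.
    """
    llr = _log_likelihood_ratios(study, model_set)
    cum = np.cumsum(llr, axis=1)
    prior_lo = np.log(model_set.prior_el) - np.log(1 - model_set.prior_el)
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-(cum + prior_lo)))


def posterior_el(
    genotypes: np.ndarray, model_set: NestedModelSet, k: int | None = None
) -> float:
    """p(EL | S_k) for a single subject's genotype vector (study SNP order
    must match the model-set SNP order; MISSING entries are skipped)."""
    k = model_set.k if k is None else k
    log_el = np.log(model_set.prior_el)
    log_al = np.log(1 - model_set.prior_el)
    for s, g in zip(model_set.snps[:k], genotypes[:k]):
        cat = int(_category_of(np.array([g], dtype=np.int8), s.model)[0])
        if cat < 0:
            continue
        log_el += np.log(s.p_el[cat])
        log_al += np.log(s.p_al[cat])
    return float(1.0 / (1.0 + np.exp(log_al - log_el)))


def ensemble_posterior(
    study: GenotypeStudy, model_set: NestedModelSet
) -> list[RiskProfile]:
    """Full risk profile (and hence ensemble score) per subject."""
    mat = risk_profiles(study, model_set)
    return [
        RiskProfile(subject_id=str(sid), posteriors=mat[i])
        for i, sid in enumerate(study.subject_ids)
    ]


# ---------------------------------------------------------------------------
# evaluation and model-size selection
# ---------------------------------------------------------------------------

def evaluate(
    scores: np.ndarray,
    labels: np.ndarray,
    ages: np.ndarray | None = None,
    age_bins: list[float] | None = None,
) -> EvalReport:
    """Sensitivity/specificity of the >= 0.5 rule plus AUC of the scores.

    ``labels`` are "EL"/"AL" strings or booleans (True = EL). With ``ages``
    and ``age_bins``, per-age-stratum sensitivities are attached.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    is_el = labels == "EL" if labels.dtype.kind in "OUS" else labels.astype(bool)
    pred_el = scores >= 0.5
    tp = int((pred_el & is_el).sum())
    fn = int((~pred_el & is_el).sum())
    tn = int((~pred_el & ~is_el).sum())
    fp = int((pred_el & ~is_el).sum())
    sens = tp / (tp + fn) if (tp + fn) else None
    spec = tn / (tn + fp) if (tn + fp) else None
    auc = float(roc_auc_score(is_el, scores)) if 0 < is_el.sum() < is_el.size else None
    by_age = None
    if ages is not None and age_bins is not None:
        rows = []
        ages = np.asarray(ages, dtype=float)
        for lo in age_bins:
            m = is_el & (ages >= lo)
            rows.append({"age_min": lo, "n": int(m.sum()),
                         "sensitivity": float(pred_el[m].mean()) if m.any() else np.nan})
        by_age = pd.DataFrame(rows)
    return EvalReport(sens, spec, auc, tp, fn, tn, fp, by_age)


def sens_spec_traces(
    profiles: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-k sensitivity and specificity of the nested classifiers."""
    is_el = np.asarray(labels) == "EL"
    pred = profiles >= 0.5
    sens = pred[is_el].mean(axis=0)
    spec = (~pred[~is_el]).mean(axis=0)
    return sens, spec


def select_k(
    sens: np.ndarray,
    spec: np.ndarray,
    plateau_window: int = 10,
    tol: float = 0.02,
    acc_min: float = 0.85,
) -> tuple[int, bool]:
    """Choose the nested-model size where the traces balance on a plateau.

    Qualifying k: accuracy (mean of sens/spec) > ``acc_min``, |sens - spec|
    < ``tol``, and the sensitivity trace locally flat (range over the
    trailing ``plateau_window`` below ``tol``). Returns the qualifying k
    (1-based) minimizing |sens - spec| (ties -> smallest k) and a flag for
    whether any k qualified; otherwise falls back to the global argmin of
    |sens - spec| with a warning.
    """
    sens = np.asarray(sens, dtype=float)
    spec = np.asarray(spec, dtype=float)
    if sens.shape != spec.shape:
        raise ValueError("traces must have equal length")
    gap = np.abs(sens - spec)
    acc = (sens + spec) / 2
    plateau = np.zeros(sens.size, dtype=bool)
    for i in range(sens.size):
        w = sens[max(0, i - plateau_window + 1): i + 1]
        plateau[i] = (w.max() - w.min()) <= tol
    ok = (acc > acc_min) & (gap < tol) & plateau
    if ok.any():
        cand = np.flatnonzero(ok)
        return int(cand[np.argmin(gap[cand])]) + 1, True
    warnings.warn("no k meets the plateau criterion; falling back to argmin |sens-spec|")
    return int(np.argmin(gap)) + 1, False


# ---------------------------------------------------------------------------
# SNP pruning (conditional-independence screen)
# ---------------------------------------------------------------------------

def prune_correlated(
    study: GenotypeStudy,
    ranked_snp_ids: list[str],
    bf_threshold_pair: float = 100.0,
    bf_threshold_multi: float = 10.0,
    min_stratum: int = 10,
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Drop candidates conditionally independent of phenotype given a
    better-ranked SNP.

    Walking the ranked list, each candidate's phenotype-association Bayes
    factor is recomputed within genotype strata of every retained
    higher-ranked SNP (summing per-stratum log10 BFs; strata smaller than
    ``min_stratum`` subjects are skipped). If the conditional BF against any
    retained SNP falls below ``bf_threshold_pair``, the candidate is
    dropped (two-way screen). Candidates surviving the two-way screen are
    additionally screened against the joint genotype strata of their two
    "closest" retained SNPs (the two with the lowest single conditional BF)
    at the laxer ``bf_threshold_multi``, catching multi-SNP dependencies.
    The output is a subsequence of the input.
    """
    case = study.case_mask
    g = study.genotypes
    idx_of = {s: int(j) for s, j in zip(study.snp_ids, range(study.n_snps))}
    retained: list[str] = []

    def cond_log10_bf(cand_j: int, strata: np.ndarray) -> float:
        total = 0.0
        used = 0
        for s in np.unique(strata[strata >= 0]):
            mask = strata == s
            if mask.sum() < min_stratum:
                continue
            sub = g[mask, cand_j]
            counts = np.stack([
                _codes3(sub[case[mask]]),
                _codes3(sub[~case[mask]]),
            ])
            total += log10_bayes_factor(counts, alpha)
            used += 1
        return total if used else np.inf

    for snp in ranked_snp_ids:
        j = idx_of[snp]
        singles = []
        keep = True
        for r in retained:
            strata = g[:, idx_of[r]].astype(int)
            bf = cond_log10_bf(j, strata)
            singles.append((bf, r))
            if bf < np.log10(bf_threshold_pair):
                keep = False
                break
        if keep and len(singles) >= 2:
            (bf1, r1), (bf2, r2) = sorted(singles)[:2]
            if np.isfinite(bf1) and np.isfinite(bf2):
                joint = g[:, idx_of[r1]].astype(int) * 4 + g[:, idx_of[r2]].astype(int)
                joint[(g[:, idx_of[r1]] < 0) | (g[:, idx_of[r2]] < 0)] = -1
                if cond_log10_bf(j, joint) < np.log10(bf_threshold_multi):
                    keep = False
        if keep:
            retained.append(snp)
    return retained


def _codes3(g: np.ndarray) -> np.ndarray:
    return np.array([(g == 2).sum(), (g == 1).sum(), (g == 0).sum()])


# ---------------------------------------------------------------------------
# validation procedures
# ---------------------------------------------------------------------------

def resample_validate(
    study: GenotypeStudy,
    ranked_snp_ids: list[str],
    n_reps: int = 1000,
    train_frac: float = 2 / 3,
    seed: int | None = None,
    tol: float = 0.02,
    acc_min: float = 0.85,
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Repeated 2/3-train / 1/3-test splits of the study.

    Each replicate refits the conditional tables on the training split (SNP
    order and model tags fixed from the full study) and evaluates the nested
    traces on the held-out third. Returns mean traces and the mean
    qualifying model size under the plateau criterion.
    """
    rng = np.random.default_rng(seed)
    is_el = study.case_mask
    n = study.n_subjects
    base = fit_nested(study, ranked_snp_ids, alpha=alpha)
    tags = {s.snp_id: s.model for s in base.snps}
    sens_sum = np.zeros(base.k)
    spec_sum = np.zeros(base.k)
    ks = []
    for _ in range(n_reps):
        train = np.zeros(n, dtype=bool)
        for mask in (is_el, ~is_el):
            members = np.flatnonzero(mask)
            take = rng.choice(members, size=int(round(train_frac * members.size)),
                              replace=False)
            train[take] = True
        fitted = fit_nested(study.subset(subject_mask=train), ranked_snp_ids,
                            best_models=tags, alpha=alpha)
        test = study.subset(subject_mask=~train)
        profiles = risk_profiles(test, fitted)
        sens, spec = sens_spec_traces(profiles, test.subject_meta["phenotype"])
        sens_sum += sens
        spec_sum += spec
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k_star, _ = select_k(sens, spec, tol=tol, acc_min=acc_min)
        ks.append(k_star)
    return {
        "mean_sensitivity": sens_sum / n_reps,
        "mean_specificity": spec_sum / n_reps,
        "mean_k": float(np.mean(ks)),
    }


def order_controls(
    study: GenotypeStudy,
    ranked_snp_ids: list[str],
    mode: str,
    n_model: int | None = None,
    m: int = 1700,
    seed: int | None = None,
    full_ranking: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[EvalReport, EvalReport]:
    """Negative-control orderings for the MBF-ranked ensemble.

    ``shuffle_top`` permutes the chosen top SNPs before the nested build;
    ``random_from_top_m`` draws the same number of SNPs uniformly from the
    top ``m`` of ``full_ranking``. Returns (baseline_report, control_report)
    evaluated on the same study.
    """
    rng = np.random.default_rng(seed)
    n_model = len(ranked_snp_ids) if n_model is None else n_model
    top = list(ranked_snp_ids[:n_model])
    if mode == "shuffle_top":
        alt = list(rng.permutation(top))
    elif mode == "random_from_top_m":
        pool = list((full_ranking or ranked_snp_ids)[:m])
        if len(pool) < n_model:
            raise ValueError("m smaller than the model size")
        alt = list(rng.choice(pool, size=n_model, replace=False))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    reports = []
    labels = study.subject_meta["phenotype"].to_numpy()
    for snp_list in (top, alt):
        fitted = fit_nested(study, snp_list, alpha=alpha)
        scores = risk_profiles(study, fitted).mean(axis=1)
        reports.append(evaluate(scores, labels))
    return reports[0], reports[1]
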