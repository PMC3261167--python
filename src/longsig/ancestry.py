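"""Genetic-ancestry clustering and ratio-preserving control matching.

Pipeline: LD-prune the SNP panel (sliding window, pairwise r^2), run PCA on
the standardized genotype matrix, select a k-means clustering over a range
of k by a quality index (mean silhouette x restart stability), then sample
controls cluster by cluster so the case/control ratio inside every
case-bearing ancestry cluster matches a target -- clusters without cases
contribute no controls. This removes stratification confounding without
discarding the case sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .study import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)


@dataclass
class AncestryClustering:
    pc_scores: np.ndarray          # subjects x components
    assignments: np.ndarray        # cluster id per subject
    k: int
    score_index: pd.DataFrame      # per-k quality table
    subject_ids: np.ndarray


# ---------------------------------------------------------------------------

def ld_prune(
    study: GenotypeStudy,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.30,
) -> list[str]:
    """Greedy sliding-window LD pruning.

    Within each window of ``window`` SNPs (advanced by ``step``), for every
    pair with squared genotype correlation strictly above ``r2_max`` the
    later-positioned SNP is dropped. Returns the retained SNP ids in map
    order. Missing genotypes are mean-imputed for the correlation.
    """
    removed = np.zeros(study.n_snps, dtype=bool)
    x = _standardized(study.genotypes)
    chroms = study.snp_meta["chrom"].to_numpy()
    for c in np.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        for start in range(0, len(idx), step):
            win = idx[start:start + window]
            live = win[~removed[win]]
            if live.size < 2:
                continue
            block = x[:, live]
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(block, rowvar=False)
            r2 = np.nan_to_num(r) ** 2
            for a in range(len(live)):
                if removed[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if not removed[live[b]] and r2[a, b] > r2_max:
                        removed[live[b]] = True
    kept = ~removed
    return [str(s) for s in study.snp_ids[kept]]


def _standardized(g: np.ndarray) -> np.ndarray:
    x = g.astype(float)
    x[x == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    mean = np.nan_to_num(mean)
    x = np.where(np.isnan(x), mean, x)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def compute_pcs(
    study: GenotypeStudy,
    n_components: int = 10,
    snp_ids: list[str] | None = None,
) -> np.ndarray:
    """Principal-component scores of the column-standardized genotype matrix.

    Missing genotypes are imputed to the SNP mean before standardization
    (EIGENSOFT-style). Components are ordered by explained variance.
    """
    if snp_ids is not None:
        sub = study.subset(snp_mask=np.isin(study.snp_ids, snp_ids))
    else:
        sub = study
    if sub.n_snps < n_components:
        raise ValueError("fewer SNPs than requested components")
    x = _standardized(sub.genotypes)
    return PCA(n_components=n_components, svd_solver="randomized",
               random_state=0).fit_transform(x)


def cluster_ancestry(
    pc_scores: np.ndarray,
    k_range: tuple[int, int] = (2, 30),
    n_restarts: int = 8,
    seed: int | None = None,
    subject_ids: np.ndarray | None = None,
) -> AncestryClustering:
    """Pick a k-means clustering of PC scores by a combined quality index.

    For each k the index is (mean silhouette of the best-inertia run) x
    (mean pairwise adjusted Rand index across restarts). The silhouette term
    rewards between-cluster separation; the stability term penalizes k at
    which k-means converges to different partitions from different starts.
    """
    x = np.asarray(pc_scores, dtype=float)
    n = x.shape[0]
    lo, hi = k_range
    hi = min(hi, n - 1)
    if lo < 2 or lo > hi:
        raise ValueError("k_range infeasible for this subject count")
    rng = np.random.default_rng(seed)
    rows = []
    best_overall = None
    for k in range(lo, hi + 1):
        labelings = []
        inertias = []
        for _ in range(n_restarts):
            km = KMeans(n_clusters=k, n_init=1,
                        random_state=int(rng.integers(2**31 - 1))).fit(x)
            labelings.append(km.labels_)
            inertias.append(km.inertia_)
        best = labelings[int(np.argmin(inertias))]
        sil = silhouette_score(x, best) if len(np.unique(best)) > 1 else -1.0
        aris = [
            adjusted_rand_score(labelings[a], labelings[b])
            for a in range(n_restarts) for b in range(a + 1, n_restarts)
        ]
        stability = float(np.mean(aris)) if aris else 1.0
        score = sil * max(stability, 0.0)
        rows.append({"k": k, "silhouette": sil, "stability": stability,
                     "score": score})
        if best_overall is None or score > best_overall[0]:
            best_overall = (score, k, best)
    score_index = pd.DataFrame(rows)
    _, k_star, labels = best_overall
    if subject_ids is None:
        subject_ids = np.arange(n)
    return AncestryClustering(
        pc_scores=x, assignments=labels, k=k_star,
        score_index=score_index, subject_ids=np.asarray(subject_ids),
    )


def match_controls(
    clustering: AncestryClustering,
    case_ids,
    control_pool_ids,
    target_ratio: float,
    seed: int | None = None,
    existing_control_ids=(),
) -> tuple[list, pd.DataFrame]:
    """Ratio-preserving control selection within ancestry clusters.

    Every existing control in a case-bearing cluster is kept; additional
    controls are sampled without replacement from the pool so the cluster's
    case/control ratio comes as close as possible to ``target_ratio``
    (target control count = cases / ratio, rounded, half-ties toward fewer
    controls). Clusters without cases contribute no controls. Returns the
    selected control ids and a per-cluster summary table.
    """
    ids = pd.Index(clustering.subject_ids)
    assign = pd.Series(clustering.assignments, index=ids)
    case_ids = pd.Index(case_ids)
    pool_ids = pd.Index(control_pool_ids)
    existing = pd.Index(existing_control_ids)
    rng = np.random.default_rng(seed)
    selected: list = []
    rows = []
    for cl in np.unique(clustering.assignments):
        members = ids[assign == cl]
        n_cases = int(case_ids.isin(members).sum())
        cl_existing = existing[existing.isin(members)]
        cl_pool = pool_ids[pool_ids.isin(members) & ~pool_ids.isin(existing)]
        if n_cases == 0:
            rows.append({"cluster": int(cl), "cases": 0, "existing_controls":
                         len(cl_existing), "sampled_controls": 0, "ratio": np.nan})
            continue
        x = n_cases / target_ratio
        target = int(np.floor(x)) + (1 if x - np.floor(x) > 0.5 else 0)
        n_extra = max(0, target - len(cl_existing))
        if n_extra > len(cl_pool):
            logger.warning(
                "cluster %s: pool exhausted (%d wanted, %d available)",
                cl, n_extra, len(cl_pool),
            )
            n_extra = len(cl_pool)
        sampled = rng.choice(cl_pool.to_numpy(), size=n_extra, replace=False) \
            if n_extra else np.array([], dtype=object)
        chosen = list(cl_existing) + list(sampled)
        selected.extend(chosen)
        rows.append(
            {
                "cluster": int(cl), "cases": n_cases,
                "existing_controls": len(cl_existing),
                "sampled_controls": int(n_extra),
                "ratio": n_cases / len(chosen) if chosen else np.nan,
            }
        )
    return selected, pd.DataFrame(rows)


def residual_stratification_check(
    study: GenotypeStudy,
    snp_ids,
    pc_scores: np.ndarray,
    n_pcs: int = 4,
) -> tuple[pd.DataFrame, float]:
    """Compare additive logistic association p-values with vs without PCs.

    Per SNP an additive (0/1/2 dosage) logistic model of case status is fit
    unadjusted and adjusted for the top ``n_pcs`` principal components; the
    returned correlation is over paired -log10 p-values. SNPs where either
    fit separates perfectly are flagged and excluded from the correlation.
    """
    snp_ids = list(snp_ids)
    if not snp_ids:
        raise ValueError("no SNPs supplied")
    idx = study.snp_index(snp_ids)
    y = study.case_mask.astype(float)
    x_all = _dosage(study.genotypes[:, idx])
    pcs = np.asarray(pc_scores)[:, :n_pcs]
    rows = []
    for j, snp in enumerate(snp_ids):
        g = x_all[:, j]
        p_un = _logit_p(y, g[:, None])
        p_ad = _logit_p(y, np.column_stack([g, pcs]))
        rows.append({"snp_id": snp, "p_unadjusted": p_un, "p_adjusted": p_ad,
                     "flagged": np.isnan(p_un) or np.isnan(p_ad)})
    table = pd.DataFrame(rows)
    ok = ~table["flagged"]
    lp1 = -np.log10(table.loc[ok, "p_unadjusted"].clip(lower=1e-300))
    lp2 = -np.log10(table.loc[ok, "p_adjusted"].clip(lower=1e-300))
    corr = float(np.corrcoef(lp1, lp2)[0, 1]) if ok.sum() > 1 else np.nan
    return table, corr


def _dosage(g: np.ndarray) -> np.ndarray:
    x = g.astype(float)
    x[x == MISSING] = np.nan
    mean = np.nanmean(x, axis=0)
    return np.where(np.isnan(x), np.nan_to_num(mean), x)


def _logit_p(y: np.ndarray, x: np.ndarray) -> float:
    """P-value of the first column's coefficient in a logistic fit."""
    design = sm.add_constant(x, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
        if not np.isfinite(fit.bse[1]) or fit.bse[1] > 1e3:
            return float("nan")
        return float(fit.pvalues[1])
    except Exception:
        return float("nan")
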