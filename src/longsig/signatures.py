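"""Clustering of genetic risk profiles into prototypical "signatures".

A risk profile is a curve: posterior probability of exceptional longevity
against the nested-model size k. Profiles are clustered by a Bayesian
model-based agglomeration that preserves the column (k) ordering: two
clusters merge when a single Bayesian polynomial regression (order <= 4,
conjugate normal-inverse-gamma prior, x rescaled to [0, 1]) explains their
pooled curves better than separate regressions -- i.e. the merge increases
the total log marginal likelihood. Greedy best-merge-first, then an
agglomerative post-pass over cluster mean profiles re-attempts merges under
the same score. Clusters below a reporting size are pooled as "sporadic".

Signatures are labeled by the strength of their mean final posterior
(Blue/Red/Orange/Green strata) and can be correlated with survival
(log-rank) and ancestry (chi-square).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy.spatial.distance import pdist
from scipy.special import gammaln
from scipy.stats import chi2_contingency

STRATA = ("Blue", "Red", "Orange", "Green")


def stratum_label(avg_posterior: float) -> str:
    """Color stratum of a signature by its average final posterior.

    Blue: p > 0.95; Red: 0.5 <= p <= 0.95; Orange: 0.2 < p < 0.5;
    Green: p <= 0.2. (Boundaries resolved so that exactly 0.5 is Red.)
    """
    p = float(avg_posterior)
    if not 0 <= p <= 1:
        raise ValueError("posterior outside [0, 1]")
    if p > 0.95:
        return "Blue"
    if p >= 0.5:
        return "Red"
    if p > 0.2:
        return "Orange"
    return "Green"


@dataclass
class SignatureCluster:
    cluster_id: int
    member_ids: list
    mean_profile: np.ndarray
    avg_posterior: float
    stratum: str

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class SurvivalRecord:
    subject_id: str
    age_years: float
    event: bool


# ---------------------------------------------------------------------------
# Bayesian polynomial evidence
# ---------------------------------------------------------------------------

class _CurveScore:
    """Marginal likelihood of a cluster of profiles under one shared
    polynomial curve.

    All profiles share the x grid (k/K in [0, 1]), so cluster sufficient
    statistics are additive: (size, sum of V'y, sum of y'y) with V the
    Vandermonde design of the maximal order. The evidence for order d uses
    prior beta ~ N(0, sigma^2 I), sigma^2 ~ InvGamma(a0, b0); the cluster
    score is the max over d <= max_order.
    """

    def __init__(self, n_points: int, max_order: int = 4,
                 a0: float = 1.0, b0: float = 0.1) -> None:
        if n_points < max_order + 1:
            raise ValueError("profile length must exceed the polynomial order")
        x = np.arange(1, n_points + 1) / n_points
        self.v = np.vander(x, max_order + 1, increasing=True)  # (K, d_max+1)
        self.gram = self.v.T @ self.v
        self.k = n_points
        self.max_order = max_order
        self.a0, self.b0 = a0, b0

    def stats(self, profiles: np.ndarray) -> tuple[int, np.ndarray, float]:
        """Sufficient statistics for a stack of profiles (m, K)."""
        profiles = np.atleast_2d(profiles)
        return (
            profiles.shape[0],
            self.v.T @ profiles.sum(axis=0),
            float((profiles**2).sum()),
        )

    @staticmethod
    def merge(s1, s2):
        return (s1[0] + s2[0], s1[1] + s2[1], s1[2] + s2[2])

    def log_evidence(self, stats) -> float:
        size, vty, yty = stats
        n = size * self.k
        best = -np.inf
        for d in range(self.max_order + 1):
            p = d + 1
            xtx = size * self.gram[:p, :p]
            xty = vty[:p]
            vn_inv = np.eye(p) + xtx
            chol = np.linalg.cholesky(vn_inv)
            beta_n = np.linalg.solve(vn_inv, xty)
            log_det_vn = -2 * np.log(np.diag(chol)).sum()
            b_n = self.b0 + 0.5 * (yty - xty @ beta_n)
            a_n = self.a0 + n / 2
            ev = (
                0.5 * log_det_vn
                + self.a0 * np.log(self.b0)
                - a_n * np.log(b_n)
                + gammaln(a_n)
                - gammaln(self.a0)
                - (n / 2) * np.log(2 * np.pi)
            )
            best = max(best, ev)
        return best


def cluster_profiles(
    profiles: np.ndarray,
    subject_ids=None,
    max_poly_order: int = 4,
    min_report_size: int = 8,
    seed: int | None = None,
    post_merge: bool = True,
) -> tuple[list[SignatureCluster], list]:
    """Cluster an N x K profile array into genetic signatures.

    Returns ``(clusters, sporadic_ids)``: reported clusters (size >=
    ``min_report_size``) sorted by decreasing average final posterior, and
    the subjects whose clusters were too small to report. Deterministic:
    greedy merges break ties by lowest cluster index (``seed`` only matters
    if downstream consumers subsample).
    """
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    n, k = profiles.shape
    if subject_ids is None:
        subject_ids = np.arange(n)
    subject_ids = np.asarray(subject_ids)
    scorer = _CurveScore(k, max_order=max_poly_order)

    stats = [scorer.stats(profiles[i]) for i in range(n)]
    evidence = [scorer.log_evidence(s) for s in stats]
    members: list[list[int] | None] = [[i] for i in range(n)]
    active = list(range(n))

    # pairwise merge gains; recomputed only for rows touched by a merge
    gain = np.full((n, n), -np.inf)

    def pair_gain(a: int, b: int) -> float:
        merged = scorer.merge(stats[a], stats[b])
        return scorer.log_evidence(merged) - evidence[a] - evidence[b]

    for ai in range(len(active)):
        for bi in range(ai + 1, len(active)):
            gain[active[ai], active[bi]] = pair_gain(active[ai], active[bi])

    while len(active) > 1:
        sub = gain[np.ix_(active, active)]
        best_flat = int(np.argmax(sub))
        ai, bi = divmod(best_flat, len(active))
        best = sub[ai, bi]
        if best <= 0:
            break
        a, b = active[ai], active[bi]
        if a > b:
            a, b = b, a
        stats[a] = scorer.merge(stats[a], stats[b])
        evidence[a] = scorer.log_evidence(stats[a])
        members[a] = members[a] + members[b]
        members[b] = None
        active.remove(b)
        for other in active:
            if other == a:
                continue
            lo, hi = (a, other) if a < other else (other, a)
            gain[lo, hi] = pair_gain(a, other)

    if post_merge and len(active) > 2:
        active = _hierarchical_post_merge(
            profiles, scorer, stats, evidence, members, active
        )

    clusters = []
    sporadic: list = []
    final = sorted(
        active,
        key=lambda c: -float(np.mean([profiles[i, -1] for i in members[c]])),
    )
    cid = 0
    for c in final:
        mem = members[c]
        mean_profile = profiles[mem].mean(axis=0)
        avg_post = float(np.mean(profiles[mem][:, -1]))
        if len(mem) >= min_report_size:
            cid += 1
            clusters.append(
                SignatureCluster(
                    cluster_id=cid,
                    member_ids=[subject_ids[i] for i in mem],
                    mean_profile=mean_profile,
                    avg_posterior=avg_post,
                    stratum=stratum_label(avg_post),
                )
            )
        else:
            sporadic.extend(subject_ids[i] for i in mem)
    return clusters, sporadic


def _hierarchical_post_merge(profiles, scorer, stats, evidence, members, active):
    """Hierarchical pass over cluster mean profiles: repeatedly propose the
    closest pair (Euclidean distance of means) and accept the merge only if
    it improves the Bayesian score; stop at the first rejection."""
    active = list(active)
    while len(active) > 1:
        means = np.stack([profiles[members[c]].mean(axis=0) for c in active])
        d = pdist(means)
        order = np.argsort(d, kind="stable")
        merged_any = False
        for flat in order[:1]:          # closest pair only, then re-evaluate
            ai, bi = _condensed_to_square(int(flat), len(active))
            a, b = sorted((active[ai], active[bi]))
            merged = scorer.merge(stats[a], stats[b])
            new_ev = scorer.log_evidence(merged)
            if new_ev > evidence[a] + evidence[b]:
                stats[a] = merged
                evidence[a] = new_ev
                members[a] = members[a] + members[b]
                members[b] = None
                active.remove(b)
                merged_any = True
        if not merged_any:
            break
    return active


def _condensed_to_square(flat: int, n: int) -> tuple[int, int]:
    """Index of a condensed pdist entry as a (row, col) pair."""
    i = 0
    while flat >= n - i - 1:
        flat -= n - i - 1
        i += 1
    return i, i + 1 + flat


# ---------------------------------------------------------------------------
# downstream comparisons
# ---------------------------------------------------------------------------

def compare_survival(
    clusters: list[SignatureCluster],
    survival: pd.DataFrame,
    pairs: list[tuple[int, int]],
) -> pd.DataFrame:
    """Pairwise log-rank tests of member survival between signatures.

    ``survival`` needs columns ``subject_id``, ``age_years``, ``event``
    (1 = death observed, 0 = censored at last contact). No multiplicity
    adjustment by default, matching single-comparison reporting; apply one
    downstream if needed.
    """
    by_id = {c.cluster_id: c for c in clusters}
    surv = survival.set_index("subject_id")
    rows = []
    for a, b in pairs:
        rec = []
        for cid in (a, b):
            mem = [m for m in by_id[cid].member_ids if m in surv.index]
            if len(mem) < 2:
                raise ValueError(f"cluster {cid} has fewer than 2 survival records")
            sub = surv.loc[mem]
            if not sub["event"].astype(bool).any():
                raise ValueError(f"cluster {cid} is fully censored")
            rec.append(sub)
        res = logrank_test(
            rec[0]["age_years"], rec[1]["age_years"],
            event_observed_A=rec[0]["event"], event_observed_B=rec[1]["event"],
        )
        rows.append(
            {
                "cluster_a": a, "cluster_b": b,
                "statistic": float(res.test_statistic),
                "p_value": float(res.p_value),
                "median_a": float(rec[0]["age_years"].median()),
                "median_b": float(rec[1]["age_years"].median()),
            }
        )
    return pd.DataFrame(rows)


def signature_ethnicity_association(
    cluster_assignments: pd.Series, ancestry_assignments: pd.Series
) -> tuple[float, float]:
    """Chi-square test of independence of signature vs ancestry cluster.

    Both series are indexed by subject id; only shared subjects enter.
    Returns (statistic, p).
    """
    joined = pd.concat(
        [cluster_assignments.rename("sig"), ancestry_assignments.rename("anc")],
        axis=1,
    ).dropna()
    table = pd.crosstab(joined["sig"], joined["anc"])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("both partitions need at least two levels")
    stat, p, _, _ = chi2_contingency(table)
    return float(stat), float(p)


def signature_summary(
    clusters: list[SignatureCluster],
    control_profiles: np.ndarray | None = None,
    thresholds: tuple[float, ...] = (0.95, 0.5, 0.2),
) -> pd.DataFrame:
    """Stratified fractions of subjects per cohort (pie-chart style).

    Rows are the four strata; columns are the case-signature fraction and,
    when control profiles are given, the fraction of control subjects whose
    final posterior falls in each stratum.
    """
    case_strat = []
    for c in clusters:
        case_strat.extend([c.stratum] * c.size)
    rows = []
    case_n = max(len(case_strat), 1)
    for s in STRATA:
        row = {"stratum": s, "case_fraction": case_strat.count(s) / case_n}
        if control_profiles is not None and len(control_profiles):
            finals = np.atleast_2d(control_profiles)[:, -1]
            labels = np.array([stratum_label(p) for p in finals])
            row["control_fraction"] = float((labels == s).mean())
        rows.append(row)
    return pd.DataFrame(rows)
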