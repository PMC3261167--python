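"""Single-SNP Bayesian and frequentist association testing.

Each SNP is tested under four genetic models derived from its 2x3
case/control genotype table (columns MM, Mm, mm where M is the
lexicographically first allele):

* ``genotypic`` -- the three genotype categories as-is;
* ``allelic``   -- 2N allele counts (2*MM + Mm vs Mm + 2*mm);
* ``dominant``  -- carriers of M (MM/Mm) vs mm;
* ``recessive`` -- MM vs Mm/mm.

The Bayesian score is the Bayes factor comparing H1 (genotype distributions
in cases and controls are independent multinomials with conjugate Dirichlet
priors, hyper-parameters ``alpha_jk``) against H0 (a single pooled
multinomial with column hyper-parameters ``alpha_.k = sum_j alpha_jk``).
Both marginal likelihoods are available in closed form, so the log10 Bayes
factor is a short sum of log-gamma terms:

    p(data | H1) = prod_j  G(a_j.)/G(a_j. + n_j.) prod_k G(a_jk + n_jk)/G(a_jk)
    p(data | H0) = G(a)/G(a + N) prod_k G(a_.k + n_.k)/G(a_.k)

The per-SNP significance measure is the maximum Bayes factor (MBF) over the
four models; its frequentist error rate under the null is calibrated by
simulation (:func:`simulate_mbf_error_rate`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import chi2 as chi2_dist
from scipy.stats import ttest_ind

from .study import GenotypeStudy

GENETIC_MODELS = ("genotypic", "allelic", "dominant", "recessive")

#: theoretical median of a 1-df chi-square, denominator of genomic control
CHI2_1DF_MEDIAN = float(chi2_dist.ppf(0.5, 1))

DEFAULT_ALPHA = 2.0


# ---------------------------------------------------------------------------
# contingency-table machinery
# ---------------------------------------------------------------------------

def recode(counts: np.ndarray, model: str) -> np.ndarray:
    """Collapse a 2x3 genotype-count table into the given genetic model.

    ``counts`` has rows (cases, controls) and columns (MM, Mm, mm).
    Returns a 2x3 table for the genotypic model and a 2x2 table otherwise.
    """
    counts = np.asarray(counts)
    if counts.shape != (2, 3):
        raise ValueError("expected a 2x3 genotype count table")
    if (counts < 0).any():
        raise ValueError("negative counts")
    mm_hom, het, mm_low = counts[:, 0], counts[:, 1], counts[:, 2]
    if model == "genotypic":
        return counts.copy()
    if model == "allelic":
        return np.stack([2 * mm_hom + het, het + 2 * mm_low], axis=1)
    if model == "dominant":
        return np.stack([mm_hom + het, mm_low], axis=1)
    if model == "recessive":
        return np.stack([mm_hom, het + mm_low], axis=1)
    raise ValueError(f"unknown genetic model: {model!r}")


def log10_bayes_factor(table: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Closed-form log10 Bayes factor for a 2xK contingency table.

    ``alpha`` is the (constant) Dirichlet hyper-parameter of every cell under
    H1; under H0 the pooled column hyper-parameters are the column sums of
    the H1 hyper-parameters. Computed entirely in log-gamma space.
    """
    if alpha <= 0:
        raise ValueError("Dirichlet hyper-parameters must be positive")
    n = np.asarray(table, dtype=float)
    if n.ndim != 2 or n.shape[0] != 2:
        raise ValueError("expected a 2xK table")
    if (n < 0).any():
        raise ValueError("negative counts")
    k = n.shape[1]
    row_tot = n.sum(axis=1)
    col_tot = n.sum(axis=0)
    grand = n.sum()
    a_row = alpha * k          # alpha_j.
    a_col = 2 * alpha          # alpha_.k for two rows
    a_all = 2 * alpha * k
    log_h1 = (
        2 * gammaln(a_row)
        - gammaln(a_row + row_tot).sum()
        + gammaln(alpha + n).sum()
        - 2 * k * gammaln(alpha)
    )
    log_h0 = (
        gammaln(a_all)
        - gammaln(a_all + grand)
        + gammaln(a_col + col_tot).sum()
        - k * gammaln(a_col)
    )
    return float((log_h1 - log_h0) / math.log(10))


def max_bayes_factor(
    counts: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> tuple[float, str, dict[str, float]]:
    """Log10 MBF over the four genetic models for one 2x3 genotype table.

    Returns ``(log10_mbf, best_model, per_model_log10_bf)``.
    """
    per_model = {
        m: log10_bayes_factor(recode(counts, m), alpha) for m in GENETIC_MODELS
    }
    best = max(per_model, key=lambda m: (per_model[m], m))
    return per_model[best], best, per_model


def chi2_and_or(table: np.ndarray) -> tuple[float, float, list[float]]:
    """Pearson chi-square (no continuity correction) and odds ratios.

    For 2-column models the single OR is ``n11*n02 / (n12*n01)``. For the
    genotypic model two ORs are reported for Mm and mm relative to the MM
    reference column. Undefined ORs (zero denominator) come back as NaN.
    """
    n = np.asarray(table, dtype=float)
    keep = n.sum(axis=0) > 0
    trimmed = n[:, keep]
    if trimmed.shape[1] < 2 or (trimmed.sum(axis=1) == 0).any():
        stat, p = 0.0, 1.0
    else:
        expected = np.outer(trimmed.sum(axis=1), trimmed.sum(axis=0)) / trimmed.sum()
        stat = float(((trimmed - expected) ** 2 / expected).sum())
        p = float(chi2_dist.sf(stat, trimmed.shape[1] - 1))

    def _or(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    if n.shape[1] == 2:
        ors = [_or(n[0, 0] * n[1, 1], n[0, 1] * n[1, 0])]
    else:
        ors = [
            _or(n[0, j] * n[1, 0], n[1, j] * n[0, 0]) for j in (1, 2)
        ]
    return stat, p, ors


def estimate_conditional_probs(
    table: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> np.ndarray:
    """Posterior-mean genotype probabilities per phenotype row.

    ``p_hat(g_k | row j) = (n_jk + alpha) / (n_j. + K * alpha)`` -- the mean
    of the conjugate Dirichlet posterior. Rows sum to one by construction and
    no probability is ever exactly zero.
    """
    n = np.asarray(table, dtype=float)
    k = n.shape[1]
    return (n + alpha) / (n.sum(axis=1, keepdims=True) + k * alpha)


def genomic_control_lambda(chi2_values: np.ndarray, df: int = 1) -> float:
    """Genomic control inflation factor: median statistic / null median."""
    vals = np.asarray(chi2_values, dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one statistic")
    return float(np.median(vals) / chi2_dist.ppf(0.5, df))


# ---------------------------------------------------------------------------
# study-level association scan
# ---------------------------------------------------------------------------

def associate(study: GenotypeStudy, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Run the four-model Bayesian + frequentist scan over every SNP.

    Returns one row per SNP with per-model log10 BF, the log10 MBF and best
    model, the chi-square p-value and OR under the best model, and the
    posterior-mean conditional genotype probabilities.
    """
    cases, controls = study.genotype_counts()
    bf = {
        m: _log10_bf_rows(
            _recode_rows(cases, m), _recode_rows(controls, m), alpha
        )
        for m in GENETIC_MODELS
    }
    bf_mat = np.stack([bf[m] for m in GENETIC_MODELS], axis=1)
    best_idx = bf_mat.argmax(axis=1)
    records = []
    for i, snp_id in enumerate(study.snp_ids):
        counts = np.stack([cases[i], controls[i]])
        best = GENETIC_MODELS[best_idx[i]]
        table = recode(counts, best)
        stat, p, ors = chi2_and_or(table)
        probs = estimate_conditional_probs(table, alpha)
        rec = {
            "snp_id": snp_id,
            "log10_mbf": bf_mat[i, best_idx[i]],
            "best_model": best,
            "chi2": stat,
            "p_value": p,
            "odds_ratio": ors[0],
            "p_cat1_el": probs[0, 0],
            "p_cat1_al": probs[1, 0],
        }
        for m in GENETIC_MODELS:
            rec[f"log10_bf_{m}"] = bf[m][i]
        records.append(rec)
    return pd.DataFrame.from_records(records)


def allelic_chi2(study: GenotypeStudy) -> np.ndarray:
    """Per-SNP 1-df allelic chi-square statistics (for genomic control).

    Uses the 2x2 closed form N*(ad - bc)^2 / (r1*r2*c1*c2); monomorphic
    SNPs get statistic 0.
    """
    case_counts, control_counts = study.genotype_counts()
    a_ = _recode_rows(case_counts, "allelic").astype(float)
    b_ = _recode_rows(control_counts, "allelic").astype(float)
    a, b = a_[:, 0], a_[:, 1]
    c, d = b_[:, 0], b_[:, 1]
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, stat, 0.0)


# ---------------------------------------------------------------------------
# vectorized kernel + null calibration of the MBF decision rule
# ---------------------------------------------------------------------------

def _recode_rows(counts3: np.ndarray, model: str) -> np.ndarray:
    """Vectorized recode of an (n, 3) block of one-phenotype genotype counts."""
    c1, c2, c3 = counts3[:, 0], counts3[:, 1], counts3[:, 2]
    if model == "genotypic":
        return counts3
    if model == "allelic":
        return np.stack([2 * c1 + c2, c2 + 2 * c3], axis=1)
    if model == "dominant":
        return np.stack([c1 + c2, c3], axis=1)
    if model == "recessive":
        return np.stack([c1, c2 + c3], axis=1)
    raise ValueError(model)


def _log10_bf_rows(
    cases: np.ndarray, controls: np.ndarray, alpha: float = DEFAULT_ALPHA
) -> np.ndarray:
    """Vectorized closed-form log10 BF for many 2xK tables.

    ``cases`` and ``controls`` are (n, K) count arrays. With integer counts
    and integer alpha the log-gamma terms are read from a precomputed lookup
    table, which makes million-table calibration sweeps cheap.
    """
    k = cases.shape[1]
    a_row, a_col, a_all = alpha * k, 2 * alpha, 2 * alpha * k
    row_c = cases.sum(axis=1)
    row_d = controls.sum(axis=1)
    col = cases + controls
    grand = row_c + row_d
    int_alpha = float(alpha).is_integer() and np.issubdtype(cases.dtype, np.integer)
    if int_alpha:
        top = int(grand.max()) + int(a_all) + 1
        gl = gammaln(np.arange(max(top, 2), dtype=float))

        def g(x, off):
            return gl[x + int(off)]
    else:
        def g(x, off):
            return gammaln(x + off)

    log_h1 = (
        2 * gammaln(np.array(a_row))
        - (g(row_c, a_row) + g(row_d, a_row))
        + g(cases, alpha).sum(axis=1)
        + g(controls, alpha).sum(axis=1)
        - 2 * k * gammaln(np.array(alpha))
    )
    log_h0 = (
        gammaln(np.array(a_all))
        - g(grand, a_all)
        + g(col, a_col).sum(axis=1)
        - k * gammaln(np.array(a_col))
    )
    return (log_h1 - log_h0) / math.log(10)


def _simulate_null_mbf(
    rng: np.random.Generator,
    n_reps: int,
    n_cases: int,
    n_controls: int,
    mafs: np.ndarray,
    alpha: float,
) -> np.ndarray:
    """Log10 MBF for ``n_reps`` null case/control datasets.

    Mirrors the calibration design: a pooled cohort of
    ``n_cases + n_controls`` subjects with HWE genotypes at the given allele
    frequency is randomly split into cases and controls, so any allele-
    frequency difference is pure sampling noise.
    """
    n_total = n_cases + n_controls
    p = np.asarray(mafs, dtype=float)
    probs = np.stack([p**2, 2 * p * (1 - p), (1 - p) ** 2], axis=1)
    totals = rng.multinomial(n_total, probs)
    # multivariate-hypergeometric split of the pooled genotype counts
    t1, t2 = totals[:, 0], totals[:, 1]
    c1 = rng.hypergeometric(t1, n_total - t1, n_cases)
    c2 = rng.hypergeometric(t2, n_total - t1 - t2, n_cases - c1)
    c3 = n_cases - c1 - c2
    cases = np.stack([c1, c2, c3], axis=1)
    controls = totals - cases
    mbf = np.full(n_reps, -np.inf)
    for model in GENETIC_MODELS:
        bf = _log10_bf_rows(
            _recode_rows(cases, model), _recode_rows(controls, model), alpha
        )
        np.maximum(mbf, bf, out=mbf)
    return mbf


@dataclass
class CalibrationResult:
    """Null false-positive rates of the MBF decision rule per threshold."""

    thresholds: np.ndarray          # on the BF (not log) scale
    n_exceed: np.ndarray
    n_reps: int

    @property
    def rate_per_100k(self) -> np.ndarray:
        return 1e5 * self.n_exceed / self.n_reps

    def credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Beta-posterior interval (uniform prior) on the per-100k rate."""
        lo = (1 - level) / 2
        a = self.n_exceed + 1
        b = self.n_reps - self.n_exceed + 1
        return 1e5 * np.stack(
            [beta_dist.ppf(lo, a, b), beta_dist.ppf(1 - lo, a, b)], axis=1
        )


def simulate_mbf_error_rate(
    n_cases: int = 800,
    n_controls: int = 950,
    maf_grid: np.ndarray | None = None,
    thresholds: tuple[float, ...] = (10, 100, 500, 1000, 1400, 1800),
    reps: int = 100_000,
    seed: int | None = None,
    alpha: float = DEFAULT_ALPHA,
    chunk: int = 250_000,
) -> CalibrationResult:
    """Estimate the null false-positive rate of ``MBF > threshold`` rules.

    ``reps`` null datasets are simulated in total, spread evenly over the
    allele-frequency grid (default 0.05, 0.10, ..., 0.50). Each dataset is a
    pooled HWE cohort split at random into cases and controls; a replicate
    counts against a threshold when the maximum of the four model Bayes
    factors exceeds it.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if maf_grid is None:
        maf_grid = np.round(np.arange(0.05, 0.501, 0.05), 2)
    thr = np.asarray(thresholds, dtype=float)
    log_thr = np.log10(thr)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(thr.size, dtype=np.int64)
    done = 0
    while done < reps:
        n = min(chunk, reps - done)
        mafs = rng.choice(maf_grid, size=n)
        mbf = _simulate_null_mbf(rng, n, n_cases, n_controls, mafs, alpha)
        exceed += (mbf[:, None] > log_thr[None, :]).sum(axis=0)
        done += n
    return CalibrationResult(thresholds=thr, n_exceed=exceed, n_reps=reps)


# ---------------------------------------------------------------------------
# secondary analyses
# ---------------------------------------------------------------------------

def gender_conditioned_test(
    counts_by_sex: dict[str, np.ndarray], alpha: float = DEFAULT_ALPHA
) -> tuple[float, bool]:
    """Test whether a SNP association survives conditioning on sex.

    ``counts_by_sex`` maps each sex label to a 2x3 case/control genotype
    table for that stratum. The per-stratum Dirichlet-multinomial Bayes
    factor compares phenotype dependence vs independence within the stratum;
    the conditional log10 BF is their sum. ``explained_away`` is True when
    the independence model wins (conditional BF < 1), i.e. the marginal
    association is attributable to sex imbalance.
    """
    total = 0.0
    used = 0
    for sex, table in counts_by_sex.items():
        table = np.asarray(table)
        if table.sum() == 0:
            continue
        total += log10_bayes_factor(table, alpha)
        used += 1
    if used == 0:
        raise ValueError("all sex strata are empty")
    return total, total < 0.0


def risk_allele_burden(
    study: GenotypeStudy, risk_allele_table: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject risk-allele carriage rates and case/control comparison.

    ``risk_allele_table`` needs columns ``snp_id``, ``risk_allele`` ("M" or
    "m"), ``category``. The per-subject rate within a category is the number
    of risk alleles carried over twice the number of typed category SNPs.
    Returns ``(rates, comparison)`` where comparison holds per-category mean
    rates and a two-sample t-test p-value.
    """
    known = set(study.snp_ids)
    usable = risk_allele_table[risk_allele_table["snp_id"].isin(known)]
    n_skipped = len(risk_allele_table) - len(usable)
    rates = pd.DataFrame({"subject_id": study.subject_ids})
    comparisons = []
    case = study.case_mask
    for category, sub in usable.groupby("category"):
        idx = study.snp_index(sub["snp_id"])
        g = study.genotypes[:, idx].astype(float)
        typed = g >= 0
        flip = (sub["risk_allele"] == "m").to_numpy()
        carried = np.where(flip[None, :], 2 - g, g)
        carried[~typed] = 0.0
        denom = 2 * typed.sum(axis=1)
        rate = np.divide(
            carried.sum(axis=1), denom, out=np.full(len(g), np.nan), where=denom > 0
        )
        rates[category] = rate
        stat, p = ttest_ind(
            rate[case & ~np.isnan(rate)], rate[~case & ~np.isnan(rate)]
        )
        comparisons.append(
            {
                "category": category,
                "mean_el": float(np.nanmean(rate[case])),
                "mean_al": float(np.nanmean(rate[~case])),
                "t_stat": float(stat),
                "p_value": float(p),
            }
        )
    comparison = pd.DataFrame(comparisons)
    comparison.attrs["n_skipped_snps"] = n_skipped
    return rates, comparison
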