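"""Sample- and SNP-level quality control.

Rules mirror a stringent multi-array GWAS cleaning protocol:

* samples: drop call rate < 96.5%, then re-admit dropped samples whose call
  rate (recomputed on the surviving SNP set) is >= 93% -- a genotype-space
  simplification of the re-clustering rescue used with raw intensity data;
* SNPs: call rate > 98% in every batch x phenotype stratum and overall,
  Hardy-Weinberg chi-square in controls < 50, max between-batch MAF
  difference < 0.2, heterozygosity-excess score within [-0.3, 0.3];
* duplicate / related samples flagged by genome-wide identity-by-state.

The intensity-based cluster-separation rule has no genotype-space analogue
and is a logged no-op.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .study import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)


@dataclass
class QcThresholds:
    sample_cr_primary: float = 0.965
    sample_cr_rescue: float = 0.93
    snp_cr: float = 0.98
    hwe_chi2_max: float = 50.0
    maf_diff_max: float = 0.2
    het_excess_range: tuple[float, float] = (-0.3, 0.3)

    def __post_init__(self) -> None:
        for f in (self.sample_cr_primary, self.sample_cr_rescue, self.snp_cr,
                  self.maf_diff_max):
            if not 0 <= f <= 1:
                raise ValueError("QC fractions must be in [0, 1]")
        if self.hwe_chi2_max <= 0:
            raise ValueError("hwe_chi2_max must be positive")


def apply_sample_qc(
    study: GenotypeStudy, thresholds: QcThresholds | None = None
) -> tuple[GenotypeStudy, pd.DataFrame]:
    """Two-pass sample call-rate filter with the rescue rule.

    Pass 1 drops samples with CR below the primary threshold. Pass 2 then
    recomputes the call rate of dropped samples on the SNPs that survive a
    provisional SNP call-rate screen in the retained samples, and re-admits
    those at or above the rescue threshold.
    """
    t = thresholds or QcThresholds()
    if study.n_subjects == 0 or study.n_snps == 0:
        raise ValueError("study is empty")
    cr1 = study.call_rate_subjects()
    keep = cr1 >= t.sample_cr_primary
    # provisional SNP screen on retained samples emulates re-clustering
    called = study.genotypes[keep] != MISSING
    snp_ok = called.mean(axis=0) > t.snp_cr if keep.any() else np.ones(study.n_snps, bool)
    cr2 = (study.genotypes[:, snp_ok] != MISSING).mean(axis=1) if snp_ok.any() else cr1
    rescued = (~keep) & (cr2 >= t.sample_cr_rescue)
    decision = np.where(keep, "retained", np.where(rescued, "rescued", "excluded"))
    report = pd.DataFrame(
        {
            "subject_id": study.subject_ids,
            "call_rate": cr1,
            "call_rate_rescreen": cr2,
            "decision": decision,
        }
    )
    return study.subset(subject_mask=keep | rescued), report


def _maf(counts3: np.ndarray) -> np.ndarray:
    """Minor-allele frequency from (m, 3) genotype counts (MM, Mm, mm)."""
    n = counts3.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts3[:, 0] + counts3[:, 1]) / (2 * n)
    return np.minimum(p, 1 - p)


def hwe_chi2(counts3: np.ndarray) -> np.ndarray:
    """1-df HWE chi-square from (m, 3) genotype counts; NaN if monomorphic."""
    counts3 = np.atleast_2d(counts3).astype(float)
    n = counts3.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts3[:, 0] + counts3[:, 1]) / (2 * n)
        exp = np.stack([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2], axis=1)
        stat = ((counts3 - exp) ** 2 / exp).sum(axis=1)
    stat[(p <= 0) | (p >= 1) | (n == 0)] = np.nan
    return stat


def het_excess(counts3: np.ndarray) -> np.ndarray:
    """F-hat = 1 - observed het / expected het under HWE (NaN if monomorphic)."""
    counts3 = np.atleast_2d(counts3).astype(float)
    n = counts3.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts3[:, 0] + counts3[:, 1]) / (2 * n)
        obs = counts3[:, 1] / n
        exp = 2 * p * (1 - p)
        f = 1 - obs / exp
    f[(p <= 0) | (p >= 1) | (n == 0)] = np.nan
    return f


def apply_snp_qc(
    study: GenotypeStudy, thresholds: QcThresholds | None = None
) -> tuple[GenotypeStudy, pd.DataFrame]:
    """SNP filter: stratified call rate, control HWE, batch MAF gap, F-hat.

    Returns the filtered study and a per-rule failure-count report (a SNP can
    fail several rules). Monomorphic SNPs skip the HWE test but are flagged.
    """
    t = thresholds or QcThresholds()
    g = study.genotypes
    called = g != MISSING
    batches = study.subject_meta["batch"].to_numpy()
    case = study.case_mask
    m = study.n_snps

    cr_fail = ~(called.mean(axis=0) > t.snp_cr)
    for b in np.unique(batches):
        for mask in (case & (batches == b), ~case & (batches == b)):
            if mask.any():
                cr_fail |= ~(called[mask].mean(axis=0) > t.snp_cr)

    control_counts = _phenotype_counts(study, case=False)
    hwe = hwe_chi2(control_counts)
    hwe_fail = hwe >= t.hwe_chi2_max  # NaN (monomorphic) compares False: skipped
    monomorphic = np.isnan(hwe)

    maf_fail = np.zeros(m, dtype=bool)
    batch_ids = np.unique(batches)
    if batch_ids.size > 1:
        mafs = []
        for b in batch_ids:
            mafs.append(_maf(_subset_counts(g, batches == b)))
        for a, b in itertools.combinations(range(len(mafs)), 2):
            diff = np.abs(mafs[a] - mafs[b])
            maf_fail |= np.nan_to_num(diff) >= t.maf_diff_max

    f_hat = het_excess(_subset_counts(g, np.ones(study.n_subjects, bool)))
    lo, hi = t.het_excess_range
    het_fail = ~np.isnan(f_hat) & ((f_hat < lo) | (f_hat > hi))

    logger.info("cluster-separation rule skipped: requires raw intensity data")
    fail = cr_fail | hwe_fail | maf_fail | het_fail
    report = pd.DataFrame(
        {
            "rule": ["call_rate", "hwe_controls", "batch_maf_diff", "het_excess",
                     "monomorphic_flagged", "total_removed"],
            "n_failed": [int(cr_fail.sum()), int(hwe_fail.sum()), int(maf_fail.sum()),
                         int(het_fail.sum()), int(monomorphic.sum()), int(fail.sum())],
        }
    )
    return study.subset(snp_mask=~fail), report


def _phenotype_counts(study: GenotypeStudy, case: bool) -> np.ndarray:
    mask = study.case_mask if case else study.control_mask
    return _subset_counts(study.genotypes, mask)


def _subset_counts(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sub = g[mask]
    return np.stack(
        [(sub == 2).sum(axis=0), (sub == 1).sum(axis=0), (sub == 0).sum(axis=0)],
        axis=1,
    )


def detect_duplicates(
    study: GenotypeStudy, ibs_threshold: float = 0.9
) -> pd.DataFrame:
    """Flag subject pairs with mean identity-by-state above the threshold.

    IBS for a pair at one SNP is ``1 - |g_i - g_j| / 2``; the genome-wide
    proportion is averaged over SNPs called in both subjects. A simple
    method-of-moments stand-in for full IBD estimation, adequate for
    duplicates and first-degree relatives.
    """
    if study.n_subjects < 2:
        raise ValueError("need at least two subjects")
    g = study.genotypes.astype(np.float64)
    mask = g != MISSING
    g_masked = np.where(mask, g, 0.0)
    n = study.n_subjects
    pairs = []
    for i in range(n - 1):
        both = mask[i] & mask[i + 1:]
        diff = np.abs(g_masked[i] - g_masked[i + 1:]) * both
        denom = both.sum(axis=1)
        with np.errstate(invalid="ignore"):
            ibs = 1 - (diff.sum(axis=1) / denom) / 2
        hits = np.flatnonzero((ibs > ibs_threshold) & (denom > 0))
        for h in hits:
            pairs.append(
                {
                    "subject_a": study.subject_ids[i],
                    "subject_b": study.subject_ids[i + 1 + h],
                    "ibs": float(ibs[h]),
                    "n_shared_snps": int(denom[h]),
                }
            )
    return pd.DataFrame(pairs, columns=["subject_a", "subject_b", "ibs", "n_shared_snps"])
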