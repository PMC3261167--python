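"""Core in-memory container for a case/control genotype study.

Genotypes are coded as the count of allele M, the lexicographically first of
the two SNP alleles (the TOP-strand convention of Illumina genotype calling),
so 2 = MM, 1 = Mm, 0 = mm, and :data:`MISSING` marks an uncalled genotype.
Phenotype labels are ``EL`` (exceptional longevity, case) and ``AL`` (average
longevity, control).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING: int = -1
PHENOTYPES = ("EL", "AL")

#: genotype-code order used for 3-column count tables: MM, Mm, mm
GENOTYPE_CODES = (2, 1, 0)


@dataclass
class GenotypeStudy:
    """Genotype matrix plus SNP and subject metadata.

    Attributes
    ----------
    genotypes:
        ``(n_subjects, n_snps)`` int8 array with values in {0, 1, 2, MISSING}.
    snp_meta:
        One row per SNP: ``id, chrom, pos, allele_m, allele_M`` (allele_M is
        the lexicographically first allele whose copies are counted) and any
        simulation ground-truth columns.
    subject_meta:
        One row per subject: ``id, phenotype, age_years, sex, batch, subpop,
        latent_group, event_flag``.
    """

    genotypes: np.ndarray
    snp_meta: pd.DataFrame
    subject_meta: pd.DataFrame
    lav_specs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        n_sub, n_snp = self.genotypes.shape
        if len(self.subject_meta) != n_sub:
            raise ValueError("subject_meta rows do not match genotype rows")
        if len(self.snp_meta) != n_snp:
            raise ValueError("snp_meta rows do not match genotype columns")

    # -- basic views ------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        return (self.subject_meta["phenotype"] == "EL").to_numpy()

    @property
    def control_mask(self) -> np.ndarray:
        return (self.subject_meta["phenotype"] == "AL").to_numpy()

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snp_meta["id"].to_numpy()

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subject_meta["id"].to_numpy()

    def validate(self) -> None:
        """Raise if the container violates its structural invariants."""
        g = self.genotypes
        ok = (g == MISSING) | ((g >= 0) & (g <= 2))
        if not ok.all():
            raise ValueError("genotype codes outside {0,1,2,missing}")
        bad = set(self.subject_meta["phenotype"].unique()) - set(PHENOTYPES)
        if bad:
            raise ValueError(f"unknown phenotype labels: {bad}")
        if self.subject_meta["id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        if self.snp_meta["id"].duplicated().any():
            raise ValueError("duplicate SNP ids")
        for _, sub in self.snp_meta.groupby("chrom"):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions not strictly increasing within chromosome")

    # -- count helpers ----------------------------------------------------

    def genotype_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP genotype counts (columns MM, Mm, mm) in cases and controls.

        Returns two ``(n_snps, 3)`` integer arrays; missing genotypes are not
        counted anywhere.
        """
        cases = _count_codes(self.genotypes[self.case_mask])
        controls = _count_codes(self.genotypes[self.control_mask])
        return cases, controls

    def subset(self, subject_mask=None, snp_mask=None) -> "GenotypeStudy":
        """Return a copy restricted to the selected subjects and/or SNPs."""
        g = self.genotypes
        subj = self.subject_meta
        snps = self.snp_meta
        if subject_mask is not None:
            g = g[subject_mask]
            subj = subj.loc[subject_mask].reset_index(drop=True)
        if snp_mask is not None:
            g = g[:, snp_mask]
            snps = snps.loc[snp_mask].reset_index(drop=True)
        return replace(self, genotypes=g.copy(), snp_meta=snps, subject_meta=subj)

    def snp_index(self, snp_ids) -> np.ndarray:
        """Column indices of the given SNP ids (order preserved)."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.snp_meta["id"])
        return lookup.loc[list(snp_ids)].to_numpy()

    def call_rate_subjects(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=1)

    def call_rate_snps(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)


def _count_codes(g: np.ndarray) -> np.ndarray:
    out = np.empty((g.shape[1], 3), dtype=np.int64)
    for col, code in enumerate(GENOTYPE_CODES):
        out[:, col] = (g == code).sum(axis=0)
    return out
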