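"""Read/write genotype studies: internal TSV bundle, VCF 4.2 (GT only),
and PLINK text .ped/.map.

All dialects map genotypes onto the count of the lexicographically first
allele (M); unresolvable calls (VCF ``./.``, PLINK ``0 0``) map to the
missing code. The internal TSV dialect is lossless; VCF and PLINK carry the
genotype matrix plus the SNP map and phenotype labels only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .study import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)

DIALECTS = ("internal_tsv", "vcf", "plink_text")


@dataclass
class StudyBundle:
    """File locations for one study under a given dialect.

    For ``internal_tsv``: ``<prefix>.genotypes.tsv``, ``<prefix>.subjects.tsv``,
    ``<prefix>.snps.tsv``. For ``vcf``: ``<prefix>.vcf``. For ``plink_text``:
    ``<prefix>.ped`` and ``<prefix>.map``.
    """

    prefix: str | Path
    dialect: str = "internal_tsv"

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect: {self.dialect!r}")
        self.prefix = Path(self.prefix)

    def paths(self) -> dict[str, Path]:
        p = self.prefix
        if self.dialect == "internal_tsv":
            return {
                "genotypes": p.with_suffix(".genotypes.tsv"),
                "subjects": p.with_suffix(".subjects.tsv"),
                "snps": p.with_suffix(".snps.tsv"),
            }
        if self.dialect == "vcf":
            return {"vcf": p.with_suffix(".vcf")}
        return {"ped": p.with_suffix(".ped"), "map": p.with_suffix(".map")}


def write_study(study: GenotypeStudy, bundle: StudyBundle) -> dict[str, Path]:
    paths = bundle.paths()
    if bundle.dialect == "internal_tsv":
        _write_internal(study, paths)
    elif bundle.dialect == "vcf":
        _write_vcf(study, paths["vcf"])
    else:
        _write_plink(study, paths)
    return paths


def read_study(bundle: StudyBundle) -> GenotypeStudy:
    paths = bundle.paths()
    for p in paths.values():
        if not p.exists():
            raise FileNotFoundError(p)
    if bundle.dialect == "internal_tsv":
        return _read_internal(paths)
    if bundle.dialect == "vcf":
        return _read_vcf(paths["vcf"])
    return _read_plink(paths)


# ---------------------------------------------------------------------------
# internal TSV: genotype matrix (subjects x SNPs) + two metadata tables
# ---------------------------------------------------------------------------

def _write_internal(study: GenotypeStudy, paths: dict[str, Path]) -> None:
    gdf = pd.DataFrame(
        study.genotypes, index=study.subject_ids, columns=study.snp_ids
    )
    gdf.to_csv(paths["genotypes"], sep="\t", index_label="subject_id")
    study.subject_meta.to_csv(paths["subjects"], sep="\t", index=False)
    study.snp_meta.to_csv(paths["snps"], sep="\t", index=False)


def _read_internal(paths: dict[str, Path]) -> GenotypeStudy:
    gdf = pd.read_csv(paths["genotypes"], sep="\t", index_col="subject_id")
    subjects = pd.read_csv(paths["subjects"], sep="\t")
    snps = pd.read_csv(paths["snps"], sep="\t")
    if subjects["id"].duplicated().any() or snps["id"].duplicated().any():
        raise ValueError("duplicate subject or SNP ids")
    gdf = gdf.loc[subjects["id"], [str(s) for s in snps["id"]]]
    study = GenotypeStudy(gdf.to_numpy(dtype=np.int8), snps, subjects)
    study.validate()
    return study


# ---------------------------------------------------------------------------
# VCF 4.2, sites + GT only
# ---------------------------------------------------------------------------

def _write_vcf(study: GenotypeStudy, path: Path) -> None:
    """Plain-text VCF with REF = allele M, so the ALT dosage is 2 - code."""
    subj = study.subject_ids
    order = np.lexsort((study.snp_meta["pos"], study.snp_meta["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in sorted(study.snp_meta["chrom"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(subj) + "\n"
        )
        gt_strings = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
        for j in order:
            row = study.snp_meta.iloc[j]
            calls = "\t".join(gt_strings[int(g)] for g in study.genotypes[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t"
                f"{row['allele_M']}\t{row['allele_m']}\t.\t.\t.\tGT\t{calls}\n"
            )


def _read_vcf(path: Path) -> GenotypeStudy:
    records = []
    genotypes = []
    n_skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                n_skipped += 1
                continue
            a, b = rec.ref, rec.alts[0]
            m_allele, other = (a, b) if a < b else (b, a)
            row = np.empty(len(samples), dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s]["GT"]
                if gt is None or any(x is None for x in gt):
                    row[i] = MISSING
                else:
                    # count copies of the lexicographically first allele
                    alleles = [a if x == 0 else b for x in gt]
                    row[i] = sum(al == m_allele for al in alleles)
            records.append(
                {
                    "id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": int(rec.chrom),
                    "pos": rec.pos,
                    "allele_M": m_allele,
                    "allele_m": other,
                }
            )
            genotypes.append(row)
    if n_skipped:
        logger.warning("skipped %d non-biallelic-SNP records", n_skipped)
    snp_meta = pd.DataFrame.from_records(records)
    g = np.stack(genotypes, axis=1) if genotypes else np.empty((len(samples), 0), np.int8)
    subject_meta = _default_subject_meta(samples)
    study = GenotypeStudy(g, snp_meta, subject_meta)
    study.snp_meta.attrs["n_skipped"] = n_skipped
    return study


# ---------------------------------------------------------------------------
# PLINK text .ped/.map
# ---------------------------------------------------------------------------

def _write_plink(study: GenotypeStudy, paths: dict[str, Path]) -> None:
    snp = study.snp_meta
    with open(paths["map"], "w") as fh:
        for _, row in snp.iterrows():
            fh.write(f"{row['chrom']}\t{row['id']}\t0\t{row['pos']}\n")
    pheno_code = {"EL": "2", "AL": "1"}
    sex_code = {"M": "1", "F": "2"}
    alleles = list(zip(snp["allele_M"], snp["allele_m"]))
    with open(paths["ped"], "w") as fh:
        for i, (_, srow) in enumerate(study.subject_meta.iterrows()):
            fields = [
                str(srow["id"]), str(srow["id"]), "0", "0",
                sex_code.get(srow.get("sex", "F"), "0"),
                pheno_code.get(srow["phenotype"], "0"),
            ]
            for j, g in enumerate(study.genotypes[i]):
                big, small = alleles[j]
                pair = {2: (big, big), 1: (big, small), 0: (small, small)}.get(
                    int(g), ("0", "0")
                )
                fields.extend(pair)
            fh.write(" ".join(fields) + "\n")


def _read_plink(paths: dict[str, Path]) -> GenotypeStudy:
    snp_meta = pd.read_csv(
        paths["map"], sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"],
    )[["id", "chrom", "pos"]]
    m = len(snp_meta)
    subj_rows, geno_rows = [], []
    allele_sets: list[set] = [set() for _ in range(m)]
    raw_calls = []
    with open(paths["ped"]) as fh:
        for line in fh:
            fields = line.split()
            fid, iid, _f, _m, sex, pheno = fields[:6]
            calls = fields[6:]
            if len(calls) != 2 * m:
                raise ValueError("ped line does not match map SNP count")
            pairs = [(calls[2 * j], calls[2 * j + 1]) for j in range(m)]
            for j, (a, b) in enumerate(pairs):
                allele_sets[j].update(x for x in (a, b) if x != "0")
            raw_calls.append(pairs)
            subj_rows.append(
                {
                    "id": iid,
                    "phenotype": {"2": "EL", "1": "AL"}.get(pheno, "AL"),
                    "sex": {"1": "M", "2": "F"}.get(sex, "F"),
                }
            )
    allele_M, allele_m = [], []
    for j, obs in enumerate(allele_sets):
        if len(obs) > 2:
            raise ValueError(f"SNP {snp_meta['id'][j]} has more than two alleles")
        srt = sorted(obs) + ["N"] * (2 - len(obs))
        allele_M.append(srt[0])
        allele_m.append(srt[1])
    for pairs in raw_calls:
        row = np.empty(m, dtype=np.int8)
        for j, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                row[j] = MISSING
            else:
                row[j] = (a == allele_M[j]) + (b == allele_M[j])
        geno_rows.append(row)
    subject_meta = pd.DataFrame(subj_rows)
    if subject_meta["id"].duplicated().any():
        raise ValueError("duplicate subject ids in .ped")
    for col, default in (("age_years", np.nan), ("batch", 0), ("subpop", 0),
                         ("latent_group", 0), ("event_flag", 1)):
        subject_meta[col] = default
    snp_meta = snp_meta.assign(allele_M=allele_M, allele_m=allele_m)
    return GenotypeStudy(np.stack(geno_rows), snp_meta, subject_meta)


def _default_subject_meta(ids) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": list(ids),
            "phenotype": "AL",
            "age_years": np.nan,
            "sex": "F",
            "batch": 0,
            "subpop": 0,
            "latent_group": 0,
            "event_flag": 1,
        }
    )
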