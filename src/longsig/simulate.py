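"""Synthetic case/control GWAS studies with the structure the analysis assumes.

The generator emulates a centenarian GWAS: ~800 exceptional-longevity (EL)
cases and ~900 average-longevity (AL) controls typed at biallelic SNPs, with

* null SNPs drawn under Hardy-Weinberg equilibrium from a shared allele
  frequency, optionally perturbed across latent subpopulations by the
  Balding-Nichols construction (one divergence parameter ``fst``);
* planted longevity-associated variants (LAVs) whose genotype distribution
  differs between phenotypes under a genotypic, allelic, dominant or
  recessive effect (e.g. carrier prevalence 0.15 in cases vs 0.26 in
  controls for a protective dominant allele);
* missing-completely-at-random genotype dropout, genotyping batches, and
* latent "signature" subgroups of cases enriched for distinct LAV subsets
  with shifted age-at-death distributions.

Everything is reproducible from ``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .study import MISSING, GenotypeStudy

_ALLELE_PAIR = ("A", "G")  # lexicographic: M = "A"


@dataclass(frozen=True)
class LavSpec:
    """One planted longevity-associated variant.

    ``model`` selects how ``case_freq``/``control_freq`` are interpreted:
    dominant/recessive -> carrier (resp. M-homozygote) prevalence, allelic ->
    frequency of allele M, genotypic -> 3-tuple of (MM, Mm, mm) frequencies.
    """

    model: str
    case_freq: float | tuple[float, float, float]
    control_freq: float | tuple[float, float, float]

    def genotype_probs(self, phenotype: str) -> np.ndarray:
        """(MM, Mm, mm) probabilities for the given phenotype."""
        f = self.case_freq if phenotype == "EL" else self.control_freq
        if self.model == "genotypic":
            p = np.asarray(f, dtype=float)
            if p.shape != (3,) or p.min() < 0 or abs(p.sum() - 1) > 1e-9:
                raise ValueError("genotypic LAV needs a 3-simplex of frequencies")
            return p
        f = float(f)
        if not 0 <= f <= 1:
            raise ValueError("LAV frequency outside [0, 1]")
        if self.model == "allelic":
            p = f
        elif self.model == "dominant":
            # carrier prevalence f => mm = 1 - f; HWE within: q_m = sqrt(1 - f)
            p = 1.0 - np.sqrt(1.0 - f)
        elif self.model == "recessive":
            # MM prevalence f => p_M = sqrt(f)
            p = np.sqrt(f)
        else:
            raise ValueError(f"unknown LAV model: {self.model!r}")
        return np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])


@dataclass
class StudyConfig:
    """Generator settings; defaults emulate the discovery-cohort design."""

    n_cases: int = 800
    n_controls: int = 900
    n_snps: int = 5000
    n_lavs: int = 0
    lav_models: Sequence[str] = ("dominant",)
    #: per-LAV (case, control) frequency pairs, cycled to length n_lavs
    lav_effect: Sequence[tuple] = ((0.15, 0.26),)
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_subpops: int = 1
    fst: float = 0.0
    missing_rate: float = 0.0
    n_batches: int = 1
    n_signature_groups: int = 1
    group_lav_overlap: float = 0.0
    #: per-group (mean, sd) of case age at death, years
    survival_params: Sequence[tuple[float, float]] = ((104.0, 3.0),)
    case_age_min: float = 95.0
    control_age: tuple[float, float] = (75.0, 7.0)
    #: adjacent duplicated SNP pairs (perfect LD), for exercising LD pruning
    n_duplicate_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lavs > self.n_snps:
            raise ValueError("n_lavs cannot exceed n_snps")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must be a probability")
        if not (0 <= self.group_lav_overlap <= 1):
            raise ValueError("group_lav_overlap must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (0 <= self.fst < 0.5):
            raise ValueError("fst must be in [0, 0.5)")

    def lav_specs(self) -> list[LavSpec]:
        models = list(self.lav_models) or ["dominant"]
        effects = list(self.lav_effect) or [(0.15, 0.26)]
        return [
            LavSpec(
                model=models[i % len(models)],
                case_freq=effects[i % len(effects)][0],
                control_freq=effects[i % len(effects)][1],
            )
            for i in range(self.n_lavs)
        ]

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("lav_effect", "survival_params"):
            if key in raw:
                raw[key] = [tuple(x) for x in raw[key]]
        for key in ("maf_range", "control_age"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _hwe_genotypes(rng: np.random.Generator, freqs: np.ndarray) -> np.ndarray:
    """Genotypes (count of M) from per-entry allele-M frequencies."""
    return rng.binomial(2, freqs).astype(np.int8)


def generate_study(config: StudyConfig) -> GenotypeStudy:
    """Simulate a full case/control study from the configuration.

    Null SNPs have identical genotype distributions in cases and controls
    (HWE at a shared, possibly subpopulation-perturbed allele frequency), so
    a study with ``n_lavs = 0`` and ``fst = 0`` is an exchangeable null on
    which association scans should show no inflation.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    m = config.n_snps
    specs = config.lav_specs()

    # SNP map: ~even split over 22 autosomes, increasing positions
    chrom = 1 + (np.arange(m) * 22) // max(m, 1)
    chrom = np.minimum(chrom, 22)
    pos = np.zeros(m, dtype=int)
    for c in np.unique(chrom):
        k = int((chrom == c).sum())
        pos[chrom == c] = np.cumsum(rng.integers(1, 50_000, size=k))

    ancestral = rng.uniform(*config.maf_range, size=m)
    subpop = rng.integers(config.n_subpops, size=n)
    if config.fst > 0 and config.n_subpops > 1:
        f = config.fst
        a = ancestral * (1 - f) / f
        b = (1 - ancestral) * (1 - f) / f
        pop_freq = rng.beta(a, b, size=(config.n_subpops, m))
        pop_freq = np.clip(pop_freq, 1e-4, 1 - 1e-4)
    else:
        pop_freq = np.broadcast_to(ancestral, (config.n_subpops, m))
    genotypes = _hwe_genotypes(rng, pop_freq[subpop, :])

    phenotype = np.array(["EL"] * config.n_cases + ["AL"] * config.n_controls)
    case_mask = phenotype == "EL"

    lav_idx = rng.choice(m, size=config.n_lavs, replace=False) if config.n_lavs else np.array([], int)
    lav_idx = np.sort(lav_idx)
    for j, spec in zip(lav_idx, specs):
        for label, mask in (("EL", case_mask), ("AL", ~case_mask)):
            probs = spec.genotype_probs(label)
            draws = rng.choice(np.array([2, 1, 0], np.int8), size=int(mask.sum()), p=probs)
            genotypes[mask, j] = draws

    if config.n_duplicate_pairs:
        same_chrom = np.flatnonzero(chrom[:-1] == chrom[1:])
        eligible = np.setdiff1d(same_chrom, np.union1d(lav_idx, lav_idx - 1))
        dup_src = rng.choice(eligible, size=config.n_duplicate_pairs, replace=False)
        for j in dup_src:
            genotypes[:, j + 1] = genotypes[:, j]

    if config.missing_rate > 0:
        miss = rng.random(genotypes.shape) < config.missing_rate
        genotypes[miss] = MISSING

    mean_c, sd_c = config.survival_params[0]
    ages = np.empty(n)
    ages[case_mask] = _truncated_normal(
        rng, mean_c, sd_c, config.case_age_min, int(case_mask.sum())
    )
    ages[~case_mask] = rng.normal(*config.control_age, size=int((~case_mask).sum()))

    subject_meta = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "phenotype": phenotype,
            "age_years": np.round(ages, 2),
            "sex": rng.choice(["F", "M"], size=n),
            "batch": rng.integers(config.n_batches, size=n),
            "subpop": subpop,
            "latent_group": np.zeros(n, dtype=int),
            "event_flag": np.ones(n, dtype=int),
        }
    )
    snp_meta = pd.DataFrame(
        {
            "id": [f"rs{j:07d}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "allele_M": _ALLELE_PAIR[0],
            "allele_m": _ALLELE_PAIR[1],
            "is_lav": np.isin(np.arange(m), lav_idx),
        }
    )
    study = GenotypeStudy(genotypes, snp_meta, subject_meta, lav_specs=list(specs))
    if config.n_signature_groups > 1:
        study = plant_signature_groups(study, config)
    return study


def plant_signature_groups(study: GenotypeStudy, config: StudyConfig) -> GenotypeStudy:
    """Partition cases into latent groups each enriched for its own LAV subset.

    Group ``g`` keeps the case-conditional genotype distribution only at its
    own LAVs; at the other groups' LAVs its members are re-drawn from the
    control distribution. A fraction ``group_lav_overlap`` of LAVs is shared
    by all groups. Case ages are re-drawn from the per-group survival
    parameters so that groups carry distinct survival signals.
    """
    n_groups = config.n_signature_groups
    if n_groups < 1:
        raise ValueError("need at least one signature group")
    case_idx = np.flatnonzero(study.case_mask)
    if n_groups > case_idx.size:
        raise ValueError("more signature groups than cases")
    if n_groups == 1:
        return study

    rng = np.random.default_rng(config.seed + 1)
    genotypes = study.genotypes.copy()
    subject_meta = study.subject_meta.copy()
    lav_idx = np.flatnonzero(study.snp_meta["is_lav"].to_numpy())
    specs = study.lav_specs

    n_shared = int(round(config.group_lav_overlap * lav_idx.size))
    shared = lav_idx[:n_shared]
    private = lav_idx[n_shared:]
    group_lavs = [
        np.concatenate([shared, private[g::n_groups]]) for g in range(n_groups)
    ]
    spec_of = dict(zip(lav_idx, specs))

    groups = rng.permutation(case_idx)
    assignment = np.array_split(groups, n_groups)
    latent = subject_meta["latent_group"].to_numpy().copy()
    ages = subject_meta["age_years"].to_numpy().copy()
    params = list(config.survival_params)
    for g, members in enumerate(assignment):
        latent[members] = g
        own = set(group_lavs[g].tolist())
        for j in lav_idx:
            label = "EL" if j in own else "AL"
            probs = spec_of[j].genotype_probs(label)
            genotypes[members, j] = rng.choice(
                np.array([2, 1, 0], np.int8), size=members.size, p=probs
            )
        mean, sd = params[g % len(params)]
        ages[members] = np.round(
            _truncated_normal(rng, mean, sd, config.case_age_min, members.size), 2
        )
    if config.missing_rate > 0:
        miss = rng.random((case_idx.size, lav_idx.size)) < config.missing_rate
        block = genotypes[np.ix_(case_idx, lav_idx)]
        block[miss] = MISSING
        genotypes[np.ix_(case_idx, lav_idx)] = block
    subject_meta["latent_group"] = latent
    subject_meta["age_years"] = ages
    return replace(
        study, genotypes=genotypes, subject_meta=subject_meta, snp_meta=study.snp_meta
    )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, size: int
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = out < lower
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.maximum(out, lower)
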