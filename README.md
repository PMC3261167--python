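# longsig

Bayesian case/control GWAS analysis of exceptional longevity: closed-form
Bayes-factor association testing over four genetic models, ancestry-matched
control selection, an ensemble of nested naïve-Bayes genetic risk models,
and clustering of per-subject risk profiles into "genetic signatures".

The package is aimed at statistical geneticists who want to reproduce, probe
or extend this style of analysis. Because centenarian cohorts of the kind
the method was designed for are not publicly deposited, `longsig` ships a
first-class synthetic-study generator that emulates their statistical
structure (planted longevity-associated variants, latent ancestry
subpopulations, genotyping batches, missingness, latent signature subgroups
with shifted survival), so every stage is testable end to end.

## The model

For each SNP with genotype counts n_jk (rows j = cases/controls, columns k
over the categories of a genetic model — genotypic, allelic, dominant or
recessive), association is scored by the Bayes factor

    BF = p(data | H1) / p(data | H0)

where under H1 the two rows are independent multinomials with conjugate
Dirichlet(α_jk) priors and under H0 a single pooled multinomial with column
hyper-parameters α_·k = Σ_j α_jk. Both marginal likelihoods are closed-form
Dirichlet-multinomial integrals, e.g.

    p(data|H1) = Π_j [Γ(α_j·)/Γ(α_j· + n_j·)] Π_k [Γ(α_jk + n_jk)/Γ(α_jk)]

with α_jk = 2 throughout. The per-SNP score is the maximum Bayes factor
(MBF) over the four models; its null false-positive rate is calibrated by
simulation. SNPs ranked by log10 MBF and pruned for conditional
independence define nested sets Σ_1 ⊂ … ⊂ Σ_K; the k-th naïve-Bayes
classifier computes

    p(EL | Σ_k) ∝ p(EL) Π_i p̂(g_i | EL)

with prior p(EL) = 0.5 (so classification is prior-free). A subject's
*risk profile* is the vector (p(EL|Σ_1), …, p(EL|Σ_K)); the ensemble score
is its mean. Profiles rise at SNP k+1 exactly when the subject's genotype
there is more common in cases — so the curve traces enrichment for
longevity-associated variants. Profiles are clustered by a Bayesian
model-based agglomeration (shared polynomial curves of order ≤ 4, conjugate
priors) into signatures, which are then compared on survival (log-rank) and
ancestry (χ²).

## Worked example

```python
import numpy as np
from longsig.simulate import StudyConfig, generate_study
from longsig import association, risk

study = generate_study(StudyConfig(
    n_cases=150, n_controls=160, n_snps=400, n_lavs=25,
    lav_models=("dominant",), lav_effect=((0.45, 0.20),), seed=100,
))
table = association.associate(study).sort_values("log10_mbf", ascending=False)
print(table.head(3)[["snp_id", "log10_mbf", "best_model", "odds_ratio"]])

model = risk.fit_nested(study, table["snp_id"].head(30).tolist())
scores = risk.risk_profiles(study, model).mean(axis=1)
report = risk.evaluate(scores, study.subject_meta["phenotype"].to_numpy())
print(f"sensitivity={report.sensitivity:.2f} specificity={report.specificity:.2f} "
      f"auc={report.auc:.3f}")
```

prints

```
        snp_id  log10_mbf best_model  odds_ratio
74   rs0000074   8.744618   dominant    5.666667
26   rs0000026   7.738379    allelic    4.290909
330  rs0000330   7.597406    allelic    3.786719
sensitivity=0.88 specificity=0.94 auc=0.974
```

The top hits are planted dominant variants (carrier prevalence 0.45 in
cases vs 0.20 in controls, so carrying the risk category multiplies the
odds of being a case several-fold); a 30-SNP ensemble separates the
cohorts far better than any single SNP can. The same flow is available
from the shell:

```sh
longsig simulate --seed 100 --out-prefix study
longsig assoc --in-prefix study --out assoc.tsv
longsig fit --in-prefix study --assoc-table assoc.tsv --out model.tsv
longsig predict --in-prefix study --model model.tsv --out scores.tsv
```

plus `qc`, `match`, `calibrate`, `validate`, `signatures`, `convert` and
`run-all` subcommands.

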