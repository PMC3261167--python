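"""Nested naive-Bayes risk models: posteriors, monotonicity, pruning,
selection, and validation procedures."""

import warnings

import numpy as np
import pytest

from conftest import make_study
from longsig import risk
from longsig.association import associate
from longsig.risk import (
    NestedModelSet,
    RiskProfile,
    SnpRiskModel,
    ensemble_posterior,
    evaluate,
    fit_nested,
    order_controls,
    posterior_el,
    prune_correlated,
    resample_validate,
    risk_profiles,
    select_k,
    sens_spec_traces,
)
from longsig.simulate import StudyConfig, generate_study
from longsig.study import MISSING


def _model(pairs, model="dominant", prior=0.5):
    snps = [
        SnpRiskModel(f"snp{i}", model, np.array([pe, 1 - pe]), np.array([pa, 1 - pa]))
        for i, (pe, pa) in enumerate(pairs)
    ]
    return NestedModelSet(snps=snps, prior_el=prior)


def test_posterior_hand_value():
    """Likelihood pairs (0.8, 0.2) and (0.6, 0.4) at prior 0.5 give 6/7."""
    ms = _model([(0.8, 0.2), (0.6, 0.4)])
    g = np.array([0, 0], dtype=np.int8)  # mm = category 0? no: dominant cat 0 = carrier
    # carriers (code 2 or 1) hit category 0 whose probabilities are (0.8, 0.6)
    g = np.array([2, 2], dtype=np.int8)
    assert posterior_el(g, ms) == pytest.approx(6 / 7)


def test_posterior_uninformative_snps():
    ms = _model([(0.5, 0.5)] * 10)
    g = np.full(10, 1, dtype=np.int8)
    assert posterior_el(g, ms) == pytest.approx(0.5)


def test_posterior_missing_contributes_nothing():
    ms = _model([(0.8, 0.2), (0.6, 0.4)])
    g = np.array([2, MISSING], dtype=np.int8)
    assert posterior_el(g, ms) == pytest.approx(0.8 / (0.8 + 0.2))


def test_classification_rule_and_tie():
    assert RiskProfile("a", np.array([0.51])).classification == "EL"
    assert RiskProfile("b", np.array([0.49])).classification == "AL"
    assert RiskProfile("c", np.array([0.5])).classification == "EL"  # tie -> EL


def test_ensemble_arithmetic():
    assert RiskProfile("x", np.array([0.2, 0.4, 0.9])).ensemble == pytest.approx(0.5)
    assert RiskProfile("y", np.full(7, 0.7)).ensemble == pytest.approx(0.7)


def test_log_space_matches_direct_product():
    """Log-space cumulative posteriors equal the direct product form."""
    rng = np.random.default_rng(0)
    k = 50
    pairs = [(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95)) for _ in range(k)]
    ms = _model(pairs)
    g = rng.choice([0, 1, 2], size=k).astype(np.int8)
    study = make_study(g[None, :].repeat(2, axis=0), ["EL", "AL"])
    study.snp_meta["id"] = [f"snp{i}" for i in range(k)]
    mat = risk_profiles(study, ms)
    num, den = np.log(ms.prior_el), np.log(1 - ms.prior_el)
    for kk in range(k):
        s = ms.snps[kk]
        cat = 0 if g[kk] >= 1 else 1
        num += np.log(s.p_el[cat])
        den += np.log(s.p_al[cat])
        direct = np.exp(num) / (np.exp(num) + np.exp(den))
        assert mat[0, kk] == pytest.approx(direct, abs=1e-12)


def test_profile_monotonicity_theorem():
    """p(EL|S_{k+1}) > p(EL|S_k) exactly when the (k+1)th genotype is more
    probable in cases than controls (equality when missing)."""
    rng = np.random.default_rng(1)
    n, k = 400, 25
    pairs = [(rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95)) for _ in range(k)]
    models = rng.choice(["genotypic", "dominant", "recessive"], size=k)
    snps = []
    for i, m in enumerate(models):
        ncat = 3 if m == "genotypic" else 2
        pe = rng.dirichlet([2] * ncat)
        pa = rng.dirichlet([2] * ncat)
        snps.append(SnpRiskModel(f"snp{i}", m, pe, pa))
    ms = NestedModelSet(snps=snps)
    g = rng.choice([0, 1, 2, MISSING], size=(n, k), p=[0.3, 0.3, 0.3, 0.1]).astype(np.int8)
    study = make_study(g, ["EL", "AL"] * (n // 2))
    study.snp_meta["id"] = [f"snp{i}" for i in range(k)]
    mat = risk_profiles(study, ms)
    from longsig.risk import _category_of

    for i in range(n):
        for kk in range(1, k):
            s = ms.snps[kk]
            cat = int(_category_of(g[i, kk:kk + 1], s.model)[0])
            if cat < 0:
                assert mat[i, kk] == pytest.approx(mat[i, kk - 1], abs=1e-12)
            elif s.p_el[cat] > s.p_al[cat]:
                assert mat[i, kk] > mat[i, kk - 1]
            elif s.p_el[cat] < s.p_al[cat]:
                assert mat[i, kk] < mat[i, kk - 1]


def test_prior_half_makes_classification_prior_free():
    rng = np.random.default_rng(2)
    pairs = [(rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9)) for _ in range(8)]
    ms = _model(pairs, prior=0.5)
    for _ in range(50):
        g = rng.choice([0, 1, 2], size=8).astype(np.int8)
        post = posterior_el(g, ms)
        cats = [0 if x >= 1 else 1 for x in g]
        lik_el = np.prod([s.p_el[c] for s, c in zip(ms.snps, cats)])
        lik_al = np.prod([s.p_al[c] for s, c in zip(ms.snps, cats)])
        assert (post >= 0.5) == (lik_el >= lik_al)


def test_fit_nested_tables_and_structure(lav_study):
    table = associate(lav_study).sort_values("log10_mbf", ascending=False)
    ranked = table["snp_id"].head(10).tolist()
    ms = fit_nested(lav_study, ranked)
    assert ms.snp_ids == ranked  # order preserved: S_k subset of S_{k+1}
    for s in ms.snps:
        assert np.all(s.p_el > 0) and np.all(s.p_al > 0)  # smoothing: never 0
        assert s.p_el.sum() == pytest.approx(1.0)
        assert s.p_al.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fit_nested(lav_study.subset(lav_study.case_mask), ranked)


def test_fit_nested_recovers_table1_probabilities():
    """Counts mirroring the carrier table: p(carrier|EL) ~ 0.152, |AL ~ 0.261."""
    rng = np.random.default_rng(3)
    g = np.zeros((801 + 914, 1), dtype=np.int8)
    g[:120, 0] = 1          # case carriers
    g[801:801 + 238, 0] = 1  # control carriers
    study = make_study(g, ["EL"] * 801 + ["AL"] * 914)
    ms = fit_nested(study, ["snp0"], best_models={"snp0": "dominant"})
    s = ms.snps[0]
    assert s.p_el[0] == pytest.approx(122 / 805, abs=1e-9)
    assert s.p_al[0] == pytest.approx(240 / 918, abs=1e-9)


def test_model_serialization_round_trip(tmp_path, lav_study):
    table = associate(lav_study).sort_values("log10_mbf", ascending=False)
    ms = fit_nested(lav_study, table["snp_id"].head(6).tolist())
    path = tmp_path / "model.tsv"
    ms.save(path)
    back = NestedModelSet.load(path)
    assert back.snp_ids == ms.snp_ids
    assert back.prior_el == ms.prior_el
    for a, b in zip(ms.snps, back.snps):
        np.testing.assert_allclose(a.p_el, b.p_el)
        assert a.model == b.model


def test_evaluate_report():
    scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1, 0.3])
    labels = np.array(["EL", "EL", "EL", "AL", "AL", "AL"])
    rep = evaluate(scores, labels)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0 and rep.auc == 1.0
    rep2 = evaluate(np.array([0.9] * 89 + [0.1] * 11 + [0.1] * 89 + [0.9] * 11),
                    np.array(["EL"] * 100 + ["AL"] * 100))
    assert rep2.sensitivity == pytest.approx(0.89)
    assert rep2.specificity == pytest.approx(0.89)
    rng = np.random.default_rng(4)
    rep3 = evaluate(rng.random(4000), np.array(["EL", "AL"] * 2000))
    assert rep3.auc == pytest.approx(0.5, abs=0.03)
    rep4 = evaluate(np.array([0.9, 0.8]), np.array(["EL", "EL"]))
    assert rep4.specificity is None and rep4.auc is None


def test_select_k_crossing_and_fallback():
    k = np.arange(1, 41)
    sens = np.clip(0.5 + k * 0.012, None, 0.95)
    spec = np.clip(1.0 - k * 0.0125, 0.4, None)
    # traces cross; pick the qualifying k with the smallest gap
    kk, ok = select_k(sens, spec, plateau_window=5, tol=0.05, acc_min=0.5)
    assert ok
    assert abs(sens[kk - 1] - spec[kk - 1]) == np.min(
        np.abs(sens - spec)[np.flatnonzero((np.abs(sens - spec) < 0.05))]
    )
    with pytest.warns(UserWarning):
        kk2, ok2 = select_k(np.full(10, 0.9), np.full(10, 0.2), tol=0.02)
    assert not ok2
    with pytest.raises(ValueError):
        select_k(np.zeros(3), np.zeros(4))


def test_prune_drops_duplicate_retains_independent(lav_study):
    table = associate(lav_study).sort_values("log10_mbf", ascending=False)
    top = table["snp_id"].iloc[0]
    # append an exact duplicate column of the top SNP
    j = int(lav_study.snp_index([top])[0])
    g = np.concatenate([lav_study.genotypes, lav_study.genotypes[:, [j]]], axis=1)
    snp_meta = lav_study.snp_meta.copy()
    import pandas as pd

    dup = snp_meta.iloc[[j]].assign(id="dup_top", pos=snp_meta["pos"].max() + 1)
    snp_meta = pd.concat([snp_meta, dup], ignore_index=True)
    from longsig.study import GenotypeStudy

    study2 = GenotypeStudy(g, snp_meta, lav_study.subject_meta)
    ranked = [top, "dup_top"] + table["snp_id"].iloc[1:8].tolist()
    # default thresholds: a perfect-LD copy carries no conditional signal
    pruned = prune_correlated(study2, ranked)
    assert top in pruned
    assert "dup_top" not in pruned
    # structural: output is a subsequence of the input
    it = iter(ranked)
    assert all(any(s == r for r in it) for s in pruned)


def test_prune_keeps_independent_strong_lavs():
    study = generate_study(
        StudyConfig(n_cases=400, n_controls=400, n_snps=40, n_lavs=2,
                    lav_effect=((0.7, 0.2),), seed=17)
    )
    lavs = [str(s) for s in study.snp_ids[study.snp_meta["is_lav"]]]
    pruned = prune_correlated(study, lavs, bf_threshold_pair=100)
    assert pruned == lavs


def test_resample_validate_null_and_deterministic(null_study):
    table = associate(null_study).sort_values("log10_mbf", ascending=False)
    ranked = table["snp_id"].head(10).tolist()
    res = resample_validate(null_study, ranked, n_reps=5, seed=1)
    # held-out accuracy on a null study hovers at chance
    assert abs(res["mean_sensitivity"][-1] - 0.5) < 0.25
    assert abs(res["mean_specificity"][-1] - 0.5) < 0.25

    # perfectly separable toy study: zero variance across replicates
    g = np.zeros((60, 3), dtype=np.int8)
    g[:30] = 2
    toy = make_study(g, ["EL"] * 30 + ["AL"] * 30)
    res2 = resample_validate(toy, ["snp0", "snp1", "snp2"], n_reps=4, seed=2)
    np.testing.assert_allclose(res2["mean_sensitivity"], 1.0)
    np.testing.assert_allclose(res2["mean_specificity"], 1.0)


def test_order_controls_modes(lav_study):
    table = associate(lav_study).sort_values("log10_mbf", ascending=False)
    ranked = table["snp_id"].head(30).tolist()
    base, shuf = order_controls(lav_study, ranked, "shuffle_top", n_model=1, seed=0)
    # permuting a single SNP is the identity: identical reports
    assert base.sensitivity == shuf.sensitivity
    assert base.specificity == shuf.specificity
    with pytest.raises(ValueError):
        order_controls(lav_study, ranked, "random_from_top_m", n_model=20, m=10)
    with pytest.raises(ValueError):
        order_controls(lav_study, ranked, "bogus")
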