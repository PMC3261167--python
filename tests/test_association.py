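"""Dirichlet-multinomial Bayes factors, frequentist companions, and the
null calibration machinery."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from longsig import association as assoc
from longsig.association import (
    chi2_and_or,
    estimate_conditional_probs,
    gender_conditioned_test,
    genomic_control_lambda,
    log10_bayes_factor,
    max_bayes_factor,
    recode,
    risk_allele_burden,
    simulate_mbf_error_rate,
)

BASE = np.array([[10, 20, 30], [5, 10, 15]])


@pytest.mark.parametrize(
    "model,expected",
    [
        ("genotypic", [[10, 20, 30], [5, 10, 15]]),
        ("allelic", [[40, 80], [20, 40]]),
        ("dominant", [[30, 30], [15, 15]]),
        ("recessive", [[10, 50], [5, 25]]),
    ],
)
def test_recode_arithmetic(model, expected):
    np.testing.assert_array_equal(recode(BASE, model), expected)


def test_recode_rejects_negative_counts():
    with pytest.raises(ValueError):
        recode(np.array([[1, -1, 0], [0, 0, 0]]), "allelic")


def test_bf_hand_value():
    # [[1,0],[0,1]] with alpha=2: H1 = 1/4, H0 = 16/72, BF = 1.125
    assert log10_bayes_factor(np.array([[1, 0], [0, 1]])) == pytest.approx(
        np.log10(1.125), abs=1e-12
    )


def test_bf_empty_table_is_zero():
    assert log10_bayes_factor(np.zeros((2, 3))) == 0.0
    assert log10_bayes_factor(np.zeros((2, 2))) == 0.0


def test_bf_row_swap_invariance():
    rng = np.random.default_rng(0)
    for _ in range(20):
        t = rng.integers(0, 40, size=(2, 3))
        assert log10_bayes_factor(t) == pytest.approx(
            log10_bayes_factor(t[::-1]), abs=1e-10
        )


def test_bf_negative_for_proportional_rows():
    """Tables with identical row proportions at large N favor H0."""
    for n in (100, 300, 1000):
        t = np.array([[n, 2 * n], [n, 2 * n]])
        assert log10_bayes_factor(t) < 0


def test_bf_monotone_under_balanced_dilution():
    """Adding identically distributed data to both rows drives the BF down."""
    base = np.array([[5, 3], [2, 6]])
    prev = log10_bayes_factor(base)
    for scale in (1, 2, 4, 8):
        extra = scale * np.array([[4, 4], [4, 4]])
        cur = log10_bayes_factor(base + extra)
        assert cur < prev
        prev = cur


def test_bf_rejects_bad_alpha():
    with pytest.raises(ValueError):
        log10_bayes_factor(BASE, alpha=0.0)


def _mc_log10_bf(table, alpha, rng, draws=200_000):
    """Monte-Carlo prior integration oracle for the closed form."""
    table = np.asarray(table, dtype=float)
    k = table.shape[1]

    def mean_lik(row_sets, prior_alpha):
        p = rng.dirichlet([prior_alpha] * k, draws)
        ll = sum((row * np.log(p)).sum(axis=1) for row in row_sets)
        vals = np.exp(ll)
        return vals.mean(), vals.std(ddof=1) / np.sqrt(draws)

    ev_case, se_case = mean_lik([table[0]], alpha)
    ev_ctrl, se_ctrl = mean_lik([table[1]], alpha)
    ev_null, se_null = mean_lik([table[0], table[1]], 2 * alpha)
    bf = ev_case * ev_ctrl / ev_null
    rel_se = np.sqrt(
        (se_case / ev_case) ** 2 + (se_ctrl / ev_ctrl) ** 2 + (se_null / ev_null) ** 2
    )
    return np.log10(bf), rel_se / np.log(10)


def test_bf_matches_monte_carlo_oracle():
    rng = np.random.default_rng(123)
    for _ in range(10):
        k = rng.choice([2, 3])
        t = rng.integers(0, 12, size=(2, k))
        mc, se = _mc_log10_bf(t, 2.0, rng)
        assert log10_bayes_factor(t) == pytest.approx(mc, abs=max(3 * se, 1e-3))


def test_mbf_is_max_and_null_tables_small():
    counts = np.array([[30, 60, 60], [30, 60, 60]])
    mbf, best, per_model = max_bayes_factor(counts)
    assert mbf == max(per_model.values())
    assert per_model[best] == mbf
    assert mbf < 0  # equal rows: every model favors no association


def test_mbf_planted_dominant_effect():
    """Carrier prevalence 0.15 vs 0.26 at n=801/914: the dominant model wins
    decisively (log10 MBF > 2)."""
    counts = np.array([[0, 120, 681], [0, 238, 676]])
    mbf, best, per_model = max_bayes_factor(counts)
    assert best == "dominant"
    assert mbf > 2


def test_mbf_degenerate_single_phenotype_row():
    counts = np.array([[10, 20, 30], [0, 0, 0]])
    mbf, _, _ = max_bayes_factor(counts)
    assert np.isfinite(mbf)


def test_chi2_and_or_reconstructed_discovery_table():
    """Carrier table rebuilt from printed prevalences: OR ~ 0.50, p ~ 1e-8."""
    stat, p, ors = chi2_and_or(np.array([[120, 681], [238, 676]]))
    assert ors[0] == pytest.approx(0.50, abs=0.01)
    assert 1e-10 < p < 1e-7


def test_chi2_identical_rows():
    stat, p, ors = chi2_and_or(np.array([[50, 50], [50, 50]]))
    assert stat == 0.0 and p == 1.0 and ors[0] == 1.0


def test_chi2_genotypic_two_ors_and_zero_margin():
    stat, p, ors = chi2_and_or(np.array([[10, 20, 30], [10, 20, 30]]))
    assert stat == pytest.approx(0.0, abs=1e-9)
    assert len(ors) == 2
    _, _, ors0 = chi2_and_or(np.array([[0, 5], [0, 7]]))
    assert np.isnan(ors0[0])


def test_conditional_probs():
    # empty row -> prior mean; counts row -> (n + 2)/(n_tot + 4)
    probs = estimate_conditional_probs(np.array([[0, 0], [120, 681]]))
    assert probs[0] == pytest.approx([0.5, 0.5])
    assert probs[1, 0] == pytest.approx(122 / 805)
    rng = np.random.default_rng(1)
    for _ in range(10):
        t = rng.integers(0, 50, size=(2, 3))
        np.testing.assert_allclose(estimate_conditional_probs(t).sum(axis=1), 1.0)


def test_genomic_control_definition_and_scale():
    assert genomic_control_lambda([assoc.CHI2_1DF_MEDIAN] * 5) == pytest.approx(1.0)
    vals = stats.chi2.rvs(1, size=20000, random_state=3)
    lam = genomic_control_lambda(vals)
    assert lam == pytest.approx(1.0, abs=0.05)
    assert genomic_control_lambda(2 * vals) == pytest.approx(2 * lam)
    with pytest.raises(ValueError):
        genomic_control_lambda([])


def test_calibration_rates_monotone_and_reproducible():
    res1 = simulate_mbf_error_rate(reps=20_000, seed=5, thresholds=(10, 100, 1e12))
    res2 = simulate_mbf_error_rate(reps=20_000, seed=5, thresholds=(10, 100, 1e12))
    np.testing.assert_array_equal(res1.n_exceed, res2.n_exceed)
    assert (np.diff(res1.n_exceed) <= 0).all()
    assert res1.n_exceed[-1] == 0  # unreachable threshold
    ci = res1.credible_interval()
    assert (ci[:, 0] <= ci[:, 1]).all()
    nonzero = res1.n_exceed > 0
    assert (ci[nonzero, 0] <= res1.rate_per_100k[nonzero]).all()
    assert (res1.rate_per_100k[nonzero] <= ci[nonzero, 1]).all()
    with pytest.raises(ValueError):
        simulate_mbf_error_rate(reps=0)


def test_null_pvalues_uniform(null_study):
    """Frequentist allelic p-values on a null study are uniform."""
    chi2 = assoc.allelic_chi2(null_study)
    p = stats.chi2.sf(chi2, 1)
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01


def test_gender_conditioning_resolves_confounding():
    # same case/control genotype distribution within each sex, but phenotype
    # imbalanced across sexes => marginal association explained away by sex
    females = np.array([[80, 40, 20], [8, 4, 2]])
    males = np.array([[5, 25, 30], [25, 125, 150]])
    marginal = females + males
    assert log10_bayes_factor(marginal) > 0
    _, explained = gender_conditioned_test({"F": females, "M": males})
    assert explained

    # genuine within-sex effect survives conditioning
    eff_f = np.array([[60, 30, 10], [20, 40, 40]])
    eff_m = np.array([[55, 35, 10], [22, 38, 40]])
    _, explained = gender_conditioned_test({"F": eff_f, "M": eff_m})
    assert not explained
    with pytest.raises(ValueError):
        gender_conditioned_test({"F": np.zeros((2, 3))})


def test_risk_allele_burden(null_study):
    import pandas as pd

    table = pd.DataFrame(
        {
            "snp_id": null_study.snp_ids[:50],
            "risk_allele": ["M"] * 50,
            "category": ["cat_a"] * 25 + ["cat_b"] * 25,
        }
    )
    rates, comparison = risk_allele_burden(null_study, table)
    assert set(comparison["category"]) == {"cat_a", "cat_b"}
    # no burden difference planted: comparisons are null
    assert (comparison["p_value"] > 0.001).all()

    # subject homozygous for every risk allele scores rate 1.0
    g = null_study.genotypes.copy()
    g[0, :] = 2
    hom = null_study.subset(np.ones(null_study.n_subjects, bool))
    hom.genotypes = g
    rates, _ = risk_allele_burden(hom, table)
    assert rates.loc[0, "cat_a"] == 1.0 and rates.loc[0, "cat_b"] == 1.0
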