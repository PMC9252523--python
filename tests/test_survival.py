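import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from adipohep.survival import (
    cox_score_test,
    cox_univariate,
    km_curve,
    median_split_survival,
    screen_protective,
    two_sample_test,
)
from adipohep.types import ValidationError
from tests.conftest import make_cohort


def exact_partial_loglik(beta, time, event, x):
    """Independent oracle: the defining product over event-time risk sets."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            ll += beta * x[i] - np.log(np.exp(beta * x[time >= time[i]]).sum())
    return ll


class TestCoxUnivariate:
    def test_constant_covariate_errors(self):
        with pytest.raises(ValidationError, match="non-identifiable"):
            cox_univariate([1, 2, 3], [1, 1, 1], [2.0, 2.0, 2.0])

    def test_no_events_errors(self):
        with pytest.raises(ValidationError, match="one event"):
            cox_univariate([1, 2], [0, 0], [0.0, 1.0])

    def test_two_subject_monotone_likelihood(self):
        # partial likelihood e^b/(e^b+1) has no interior maximum
        fit = cox_univariate([1.0, 2.0], [1, 1], [1.0, 0.0])
        assert fit.monotone_likelihood_flag
        assert not fit.converged

    def test_matches_golden_section_oracle(self):
        rng = np.random.default_rng(7)
        used = 0
        for _ in range(60):
            n = int(rng.integers(4, 9))
            t = rng.exponential(1.0, n)
            x = rng.normal(0, 1, n)
            e = (rng.random(n) > 0.2).astype(int)
            if e.sum() == 0:
                e[0] = 1
            fit = cox_univariate(t, e, x)
            if not fit.converged or abs(fit.beta) > 5:
                continue
            res = optimize.minimize_scalar(
                lambda b: -exact_partial_loglik(b, t, e, x),
                bounds=(-8, 8), method="bounded", options={"xatol": 1e-10})
            assert fit.beta == pytest.approx(res.x, abs=1e-6)
            used += 1
        assert used >= 30

    def test_matches_lifelines_with_ties(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        t = np.ceil(rng.exponential(5, 150)) + 1
        x = rng.normal(0, 1, 150)
        e = (rng.random(150) < 0.7).astype(int)
        fit = cox_univariate(t, e, x)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"t": t, "e": e, "x": x}), "t", "e")
        assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se_beta == pytest.approx(cph.standard_errors_["x"], abs=1e-5)

    def test_score_test_equals_logrank_chi2(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(8, 40))
            t = rng.exponential(1, n)
            e = (rng.random(n) < 0.8).astype(int)
            g = (rng.random(n) < 0.5).astype(int)
            if e.sum() == 0 or g.min() == g.max():
                continue
            chi_score = cox_score_test(t, e, g)
            chi_lr = two_sample_test(
                t, e, np.where(g == 1, "a", "b"), method="logrank").chi_square
            assert chi_score == pytest.approx(chi_lr, abs=1e-8)


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(1, 40)
        km = km_curve(t, np.ones(40, dtype=int))
        empirical = [(t > ti).mean() for ti in km.event_times]
        assert np.allclose(km.survival, empirical)

    def test_invariants(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1, 50)
        e = (rng.random(50) < 0.7).astype(int)
        km = km_curve(t, e)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(np.diff(km.at_risk) < 0)
        assert km.survival[0] <= 1.0

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(3)
        t = np.ceil(rng.exponential(4, 80))
        e = (rng.random(80) < 0.6).astype(int)
        km = km_curve(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(km.event_times).to_numpy()
        assert np.allclose(km.survival, ref)


def gehan_pairwise_oracle(time, event, in_a):
    """Gehan's pairwise scoring: +1 when the B member definitely dies first."""
    u = 0
    for i in np.flatnonzero(in_a):
        for j in np.flatnonzero(~in_a):
            if event[j] and time[i] > time[j]:
                u -= 1
            elif event[i] and time[j] > time[i]:
                u += 1
    return u


class TestTwoSampleTests:
    def _fixture(self, seed, n=8):
        rng = np.random.default_rng(seed)
        t = rng.exponential(1, n)
        e = (rng.random(n) < 0.7).astype(int)
        if e.sum() == 0:
            e[0] = 1
        g = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        return t, e, g

    def test_statistic_equals_pairwise_u_no_ties(self):
        checked = 0
        for seed in range(40):
            t, e, g = self._fixture(seed)
            try:
                res = two_sample_test(t, e, g)
            except ValidationError:
                continue
            u = gehan_pairwise_oracle(t, e, g == "a")
            assert res.statistic == pytest.approx(u, abs=1e-9)
            checked += 1
        assert checked >= 30

    def test_label_swap_antisymmetry(self):
        t, e, g = self._fixture(4)
        res = two_sample_test(t, e, g)
        swapped = np.where(g == "a", "b", "a")
        res2 = two_sample_test(t, e, swapped)
        assert res2.statistic == pytest.approx(-res.statistic, abs=1e-12)
        assert res2.p_value == pytest.approx(res.p_value)

    def test_exact_permutation_matches_bruteforce(self):
        from itertools import combinations

        t, e, g = self._fixture(6)
        res = two_sample_test(t, e, g, exact=True)
        n_a = int((g == "a").sum())
        obs = abs(res.statistic)
        count = total = 0
        for combo in combinations(range(len(t)), n_a):
            mask = np.zeros(len(t), dtype=bool)
            mask[list(combo)] = True
            u = gehan_pairwise_oracle(t, e, mask)
            total += 1
            count += abs(u) >= obs - 1e-12
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_early_separation_gehan_beats_logrank(self):
        # constructed fixture with a front-loaded group difference; the
        # n-at-risk weights make the Gehan chi-square exceed the log-rank one
        t = np.array([57.7, 10.6, 28.3, 22.5, 16.8, 31.2, 53.0, 26.0, 38.2, 57.4])
        e = np.array([1, 1, 1, 1, 1, 0, 1, 0, 1, 1])
        g = np.array(["a"] * 5 + ["b"] * 5)
        gehan = two_sample_test(t, e, g, method="gehan_wilcoxon")
        logrank = two_sample_test(t, e, g, method="logrank")
        assert gehan.chi_square == pytest.approx(3.4594594594594597)
        assert logrank.chi_square == pytest.approx(0.9901949061341627)
        assert gehan.chi_square >= logrank.chi_square

    def test_one_group_errors(self):
        with pytest.raises(ValidationError, match="two"):
            two_sample_test([1, 2], [1, 1], ["a", "a"])

    def test_no_events_errors(self):
        with pytest.raises(ValidationError, match="no events"):
            two_sample_test([1, 2], [0, 0], ["a", "b"])


class TestScreenProtective:
    def test_planted_protective_gene_retained(self, default_sim):
        _, expr, truth, surv = default_sim
        fem = np.array([c == "tumor" and s == "female"
                        for c, s in zip(expr.cohort, expr.sex)])
        ft = expr.subset_samples(fem)
        retained, fits = screen_protective(ft, surv, list(truth.planted_hits.genes))
        assert set(retained) == set(truth.planted_hits.genes)
        assert (fits["hr"] < 1).all()

    def test_harmful_decoys_not_retained(self, default_sim):
        _, expr, truth, surv = default_sim
        fem = np.array([c == "tumor" and s == "female"
                        for c, s in zip(expr.cohort, expr.sex)])
        ft = expr.subset_samples(fem)
        dec4 = [g for g, s in truth.decoy_primary.items() if s == "stage4"]
        retained, fits = screen_protective(ft, surv, dec4)
        assert retained == []
        assert (fits["hr"] > 1).all()

    def test_constant_gene_flagged_not_fatal(self, default_sim):
        _, expr, _, surv = default_sim
        tumor = expr.select_cohort("tumor")
        vals = tumor.values.copy()
        vals[0, :] = 3.0
        flat = make_cohort(vals, genes=tumor.gene_ids, samples=tumor.sample_ids,
                           cohort="tumor")
        retained, fits = screen_protective(flat, surv, [tumor.gene_ids[0]])
        assert retained == []
        assert fits.iloc[0]["flag"] == "constant_expression"

    def test_insufficient_overlap_errors(self, default_sim):
        _, expr, _, surv = default_sim
        ref = expr.select_cohort("ref_normal")  # no survival rows
        with pytest.raises(ValidationError, match="shared"):
            screen_protective(ref, surv)


class TestMedianSplit:
    def test_horizon_beyond_max_is_identity(self, default_sim):
        _, expr, truth, surv = default_sim
        tumor = expr.select_cohort("tumor")
        gene = truth.planted_hits.genes[0]
        a = median_split_survival(tumor, surv, gene, horizon_days=1e12)
        b = median_split_survival(tumor, surv, gene, horizon_days=float(surv.time.max()))
        assert a.chi_square == pytest.approx(b.chi_square)

    def test_protective_gene_high_group_survives_better(self, default_sim):
        _, expr, truth, surv = default_sim
        tumor = expr.select_cohort("tumor")
        gene = truth.planted_hits.genes[0]
        res = median_split_survival(tumor, surv, gene)
        # group a == "high"; fewer observed-than-expected deaths there
        assert res.group_a == "high"
        assert res.statistic < 0
        assert res.p_value < 0.05

    def test_constant_gene_errors(self, default_sim):
        _, expr, _, surv = default_sim
        tumor = expr.select_cohort("tumor")
        vals = tumor.values.copy()
        vals[0, :] = 1.0
        flat = make_cohort(vals, genes=tumor.gene_ids, samples=tumor.sample_ids,
                           cohort="tumor")
        with pytest.raises(ValidationError, match="constant"):
            median_split_survival(flat, surv, tumor.gene_ids[0])


def test_parameter_recovery_small():
    """Reduced-scale version of the recovery property (full scale in acceptance)."""
    rng = np.random.default_rng(0)
    betas = []
    for _ in range(20):
        n = 400
        x = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(0.5 * x))  # true beta = -0.5
        c = rng.uniform(0, np.quantile(t, 0.995) * 2.2, n)
        e = (t <= c).astype(int)
        betas.append(cox_univariate(np.minimum(t, c), e, x).beta)
    assert np.mean(betas) == pytest.approx(-0.5, abs=0.06)
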