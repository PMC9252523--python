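import numpy as np
import pandas as pd
import pytest

from adipohep.mr import HarmonizedInstruments, egger, harmonize, ivw, mr_stratified
from adipohep.simulate import SimulationConfig, simulate_gwas
from adipohep.types import GwasSummaryTable, ValidationError


def _gwas(rows):
    cols = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
    return GwasSummaryTable(pd.DataFrame(rows, columns=cols))


def _instruments(gamma, Gamma, se_y=None):
    n = len(gamma)
    return HarmonizedInstruments(pd.DataFrame({
        "snp_id": [f"rs{i}" for i in range(n)],
        "gamma": gamma, "se_x": [0.01] * n,
        "Gamma": Gamma, "se_y": se_y if se_y is not None else [1.0] * n,
        "dropped": [False] * n, "reason": [""] * n,
    }))


class TestHarmonize:
    def test_identical_orientation_unchanged(self):
        exp = _gwas([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs1", "A", "G", 0.2, 0.05, 0.02, 1e-3, 1000)])
        h = harmonize(exp, out)
        row = h.retained().iloc[0]
        assert row["Gamma"] == 0.05
        assert h.df["dropped"].sum() == 0

    def test_swapped_alleles_flip_sign(self):
        exp = _gwas([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs1", "G", "A", 0.8, 0.05, 0.02, 1e-3, 1000)])
        assert harmonize(exp, out).retained().iloc[0]["Gamma"] == -0.05

    def test_strand_flip_same_orientation(self):
        exp = _gwas([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs1", "T", "C", 0.2, 0.05, 0.02, 1e-3, 1000)])
        assert harmonize(exp, out).retained().iloc[0]["Gamma"] == 0.05

    def test_strand_flip_and_swap(self):
        exp = _gwas([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs1", "C", "T", 0.8, 0.05, 0.02, 1e-3, 1000)])
        assert harmonize(exp, out).retained().iloc[0]["Gamma"] == -0.05

    def test_mismatched_alleles_dropped(self):
        exp = _gwas([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs1", "A", "C", 0.2, 0.05, 0.02, 1e-3, 1000)])
        h = harmonize(exp, out)
        assert h.df.iloc[0]["reason"] == "allele_mismatch"

    def test_palindromic_ambiguous_dropped(self):
        exp = _gwas([("rs1", "A", "T", 0.5, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs1", "A", "T", 0.5, 0.05, 0.02, 1e-3, 1000)])
        h = harmonize(exp, out)
        assert h.df.iloc[0]["reason"] == "palindromic_ambiguous"
        assert h.n_retained == 0

    def test_palindromic_resolved_by_eaf(self):
        exp = _gwas([("rs1", "A", "T", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out_same = _gwas([("rs1", "A", "T", 0.25, 0.05, 0.02, 1e-3, 1000)])
        out_flip = _gwas([("rs1", "A", "T", 0.75, 0.05, 0.02, 1e-3, 1000)])
        assert harmonize(exp, out_same).retained().iloc[0]["Gamma"] == 0.05
        # eaf on opposite sides of 0.5 but one outside the window -> flip
        exp2 = _gwas([("rs1", "A", "T", 0.2, 0.1, 0.01, 1e-8, 1000)])
        h = harmonize(exp2, out_flip)
        assert h.df.iloc[0]["reason"] == "palindromic_ambiguous" or \
            h.retained().iloc[0]["Gamma"] == -0.05

    def test_no_shared_snps_errors(self):
        exp = _gwas([("rs1", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        out = _gwas([("rs2", "A", "G", 0.2, 0.1, 0.01, 1e-8, 1000)])
        with pytest.raises(ValidationError, match="share no SNP"):
            harmonize(exp, out)

    def test_simulator_flips_recovered_exactly(self):
        config = SimulationConfig(seed=3, n_snps=200, causal_beta=0.1,
                                  strand_flip_fraction=0.2,
                                  allele_swap_fraction=0.2)
        exp_tab, out_tab, truth = simulate_gwas(config)
        h = harmonize(exp_tab, out_tab)
        kept = h.retained().set_index("snp_id")
        assert h.df["dropped"].sum() == 0
        for i, snp in enumerate(exp_tab.df["snp_id"]):
            assert kept.loc[snp, "Gamma"] == pytest.approx(
                truth.outcome_effect_aligned[i], abs=1e-12)


class TestIvw:
    def test_exact_proportional_fit(self):
        res = ivw(_instruments([1, 2, 3], [0.5, 1.0, 1.5]))
        assert res.slope == pytest.approx(0.5)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-12)

    def test_single_instrument_is_wald_ratio(self):
        res = ivw(_instruments([2.0], [0.8], se_y=[0.1]))
        assert res.slope == pytest.approx(0.4)
        assert res.se_slope == pytest.approx(0.1 / 2.0)

    def test_all_gamma_zero_errors(self):
        with pytest.raises(ValidationError, match="undefined"):
            ivw(_instruments([0.0, 0.0], [0.1, 0.2]))

    def test_affine_points_biased_upward(self):
        # hand-solved normal equations: slope = 4.8 / 14
        g = [1.0, 2.0, 3.0]
        res = ivw(_instruments(g, [0.1 + 0.3 * x for x in g]))
        assert res.slope == pytest.approx(4.8 / 14)
        assert res.slope > 0.3


class TestEgger:
    def test_exact_affine_fit(self):
        g = [1.0, 2.0, 3.0]
        res = egger(_instruments(g, [0.1 + 0.3 * x for x in g]))
        assert res.slope == pytest.approx(0.3, abs=1e-12)
        assert res.intercept == pytest.approx(0.1, abs=1e-12)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-18)

    def test_too_few_instruments(self):
        with pytest.raises(ValidationError, match=">= 3"):
            egger(_instruments([1.0, 2.0], [0.1, 0.2]))

    def test_collinear_gamma_errors(self):
        with pytest.raises(ValidationError, match="collinear"):
            egger(_instruments([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))


class TestInvariances:
    def _random_instruments(self, seed=0, n=30):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, 0.1, n)
        G = 0.2 * g + rng.normal(0, 0.03, n)
        se = rng.uniform(0.02, 0.05, n)
        return g, G, se

    def test_allele_recoding_invariance(self):
        g, G, se = self._random_instruments()
        base_i = ivw(_instruments(g, G, se))
        base_e = egger(_instruments(g, G, se))
        g2, G2 = g.copy(), G.copy()
        g2[::3] *= -1
        G2[::3] *= -1
        assert ivw(_instruments(g2, G2, se)).slope == pytest.approx(base_i.slope)
        flipped = egger(_instruments(g2, G2, se))
        assert flipped.slope == pytest.approx(base_e.slope)
        assert flipped.intercept == pytest.approx(base_e.intercept)

    def test_outcome_scale_equivariance(self):
        g, G, se = self._random_instruments(1)
        c = 3.7
        base_i, base_e = ivw(_instruments(g, G, se)), egger(_instruments(g, G, se))
        sc_i = ivw(_instruments(g, c * G, c * se))
        sc_e = egger(_instruments(g, c * G, c * se))
        assert sc_i.slope == pytest.approx(c * base_i.slope)
        assert sc_i.p_slope == pytest.approx(base_i.p_slope)
        assert sc_e.slope == pytest.approx(c * base_e.slope)
        assert sc_e.intercept == pytest.approx(c * base_e.intercept)
        assert sc_e.p_intercept == pytest.approx(base_e.p_intercept)


class TestStratified:
    def test_identical_strata_identical_results(self):
        config = SimulationConfig(seed=5, n_snps=40, causal_beta=0.05)
        exp_tab, out_tab, _ = simulate_gwas(config)
        res = mr_stratified({"a": (exp_tab, out_tab), "b": (exp_tab, out_tab)})
        assert res["a"]["ivw"].slope == res["b"]["ivw"].slope
        assert res["a"]["egger"].p_intercept == res["b"]["egger"].p_intercept

    def test_failing_stratum_reported_not_fatal(self):
        config = SimulationConfig(seed=5, n_snps=40)
        exp_tab, out_tab, _ = simulate_gwas(config)
        other = GwasSummaryTable(exp_tab.df.assign(
            snp_id=["zz" + s for s in exp_tab.df["snp_id"]]))
        res = mr_stratified({"female": (exp_tab, out_tab), "male": (exp_tab, other)})
        assert res["female"]["available"]
        assert not res["male"]["available"]
        assert "share no SNP" in res["male"]["error"]

    def test_female_signal_male_null(self):
        config = SimulationConfig(seed=21, n_snps=150, outcome_se=0.02,
                                  causal_beta=0.0, causal_beta_female=-0.1,
                                  causal_beta_male=0.0)
        fem_sig = male_sig = 0
        reps = 10
        for rep in range(reps):
            cfg = SimulationConfig(**{**config.__dict__, "seed": 100 + rep})
            from adipohep.simulate import simulate_gwas_stratified

            strata = simulate_gwas_stratified(cfg)
            res = mr_stratified({
                s: (e, o) for s, (e, o, _) in strata.items()})
            f = res["female"]["ivw"]
            m = res["male"]["ivw"]
            fem_sig += (f.slope < 0) and (f.p_slope < 0.05)
            male_sig += m.p_slope < 0.05
        assert fem_sig >= 9
        assert male_sig <= 2
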