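"""Odds ratios, logistic IRLS, bootstrap, Bonferroni, interactions."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

import riskrules as rr
from riskrules.mining import MiningConfig
from riskrules.stats import (
    ContingencyTable,
    RankDeficiencyError,
    SeparationError,
    fit_logistic,
    fit_logistic_firth,
    multiplicative_interaction,
    reri_ap,
)

from conftest import random_incidence


class TestCrudeOddsRatio:
    def test_balanced_table_or_one(self):
        t = ContingencyTable(10, 10, 10, 10)
        assert rr.crude_odds_ratio(t).odds_ratio == pytest.approx(1.0)

    def test_printed_counts_closed_form(self):
        t = ContingencyTable(20, 1, 187, 178)
        res = rr.crude_odds_ratio(t, zero_cell="none")
        assert res.odds_ratio == pytest.approx((20 * 178) / (1 * 187))
        assert not res.corrected

    def test_transpose_symmetry(self):
        t = ContingencyTable(7, 3, 12, 44)
        swapped = ContingencyTable(7, 12, 3, 44)  # rows and columns swapped
        assert rr.crude_odds_ratio(t).odds_ratio == pytest.approx(
            rr.crude_odds_ratio(swapped).odds_ratio
        )

    def test_haldane_flagged(self):
        t = ContingencyTable(5, 0, 10, 20)
        res = rr.crude_odds_ratio(t, zero_cell="haldane")
        assert res.corrected
        assert math.isfinite(res.odds_ratio)

    def test_zero_cell_none_returns_flagged_infinity(self):
        t = ContingencyTable(5, 0, 10, 20)
        res = rr.crude_odds_ratio(t, zero_cell="none")
        assert res.degenerate
        assert res.odds_ratio == math.inf

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="margin"):
            rr.crude_odds_ratio(ContingencyTable(0, 0, 10, 20))


class TestRuleContingency:
    def test_printed_top_rule_cells(self, top_rule_fixture):
        rules = rr.mine_rules(top_rule_fixture, MiningConfig())
        triad = next(r for r in rules if r.lhs == ("A", "B", "C"))
        t = rr.rule_contingency(top_rule_fixture, triad)
        assert (t.a, t.b, t.c, t.d) == (20, 1, 187, 178)
        assert round(100 * t.case_carrier_frequency, 1) == 9.7
        assert round(100 * t.control_carrier_frequency, 1) == 0.6

    def test_all_carriers(self):
        I = rr.exact_fixture(3, 2, {(("q",), "case"): 3, (("q",), "control"): 2})
        r = rr.evaluate_itemset(I, ["q"], "MS")
        t = rr.rule_contingency(I, r)
        assert t.c == 0 and t.d == 0

    def test_matches_hand_tally(self, rng):
        I = random_incidence(rng, 25, 4)
        r = rr.evaluate_itemset(I, ["i0", "i1"], "MS")
        carrier = I.cells[:, 0] & I.cells[:, 1]
        case = I.cells[:, -1]
        t = rr.rule_contingency(I, r)
        assert t.a == int((carrier & case).sum())
        assert t.d == int((~carrier & ~case).sum())


class TestFitLogistic:
    def test_single_predictor_equals_crude_or(self, rng):
        x = (rng.random(200) < 0.4).astype(float)
        logit = -0.5 + 1.2 * x
        y = (rng.random(200) < 1 / (1 + np.exp(-logit))).astype(float)
        X = np.column_stack([np.ones(200), x])
        fit = fit_logistic(y, X)
        t = ContingencyTable(
            int(((x == 1) & (y == 1)).sum()), int(((x == 1) & (y == 0)).sum()),
            int(((x == 0) & (y == 1)).sum()), int(((x == 0) & (y == 0)).sum()),
        )
        crude = rr.crude_odds_ratio(t, zero_cell="none")
        assert math.exp(fit.coef[1]) == pytest.approx(crude.odds_ratio, abs=1e-6)

    def test_agrees_with_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 300
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.random(n) < 0.5])
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.3 + 0.8 * X[:, 1] - 0.5 * X[:, 2])))).astype(float)
        mine = fit_logistic(y, X)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(mine.coef, ref.params, atol=1e-6)
        np.testing.assert_allclose(np.sqrt(np.diag(mine.cov)), ref.bse, atol=1e-5)

    def test_separation_flagged(self):
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        x = y.copy()  # all carriers are cases: complete separation
        fit = fit_logistic(y, np.column_stack([np.ones(6), x]))
        assert fit.separated

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_logistic((rng.random(50) < 0.5).astype(float), X)

    def test_null_wald_p_uniform(self):
        """y independent of x: Wald p-values are uniform (KS at alpha=0.01)."""
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(200):
            x = rng.normal(size=120)
            y = (rng.random(120) < 0.5).astype(float)
            fit = fit_logistic(y, np.column_stack([np.ones(120), x]))
            ps.append(fit.wald_p(1))
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_firth_finite_under_separation(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=float)
        x = y.copy()
        fit = fit_logistic_firth(y, np.column_stack([np.ones(8), x]))
        assert np.all(np.isfinite(fit.coef))
        assert abs(fit.coef[1]) < 10


@pytest.fixture(scope="module")
def planted_cohort():
    cfg = rr.SyntheticCohortConfig(seed=0, n_substructure_dims=0,
                                   pattern_item_maf=0.30)
    cfg.patterns = [rr.PlantedPattern(
        items=tuple(cfg.variant_ids[:2]), joint_odds_ratio=5.0,
        marginal_odds_ratios=(1.0, 1.0))]
    c = rr.simulate_cohort(cfg)
    I = rr.encode_incidence(c.genotypes, c.phenotype)
    rule = rr.evaluate_itemset(I, ("v001", "v002"), "MS")
    return I, rule


class TestBootstrapAssociation:
    def test_point_estimate_is_full_data_fit(self, planted_cohort):
        I, rule = planted_cohort
        a1 = rr.bootstrap_association(I, rule, n_boot=50, seed=1)
        a2 = rr.bootstrap_association(I, rule, n_boot=50, seed=2)
        assert a1.or_adjusted == pytest.approx(a2.or_adjusted)
        assert a1.ci_low != a2.ci_low  # replicates differ with the seed

    def test_reproducible_given_seed(self, planted_cohort):
        I, rule = planted_cohort
        a1 = rr.bootstrap_association(I, rule, n_boot=80, seed=3)
        a2 = rr.bootstrap_association(I, rule, n_boot=80, seed=3)
        assert (a1.ci_low, a1.ci_high, a1.p_value) == (a2.ci_low, a2.ci_high, a2.p_value)

    def test_constant_predictor_fails_at_fit_stage(self):
        I = rr.exact_fixture(4, 4, {(("k",), "case"): 4, (("k",), "control"): 4})
        rule = rr.evaluate_itemset(I, ["k"], "MS")
        with pytest.raises((RankDeficiencyError, ValueError)):
            rr.bootstrap_association(I, rule, n_boot=10, seed=0)

    def test_separation_fallback_explicit(self):
        I = rr.exact_fixture(
            10, 10, {(("s",), "case"): 6, ((), "case"): 4, ((), "control"): 10}
        )
        rule = rr.evaluate_itemset(I, ["s"], "MS")
        with pytest.raises(SeparationError):
            rr.bootstrap_association(I, rule, n_boot=10, seed=0)
        a = rr.bootstrap_association(I, rule, n_boot=50, seed=0,
                                     on_separation="haldane_crude")
        assert a.separated
        assert math.isfinite(a.or_adjusted)


class TestBonferroni:
    def test_printed_threshold(self):
        thr, _ = rr.bonferroni([0.5] * 114, alpha=0.05)
        assert thr == pytest.approx(0.05 / 114)
        assert round(thr, 5) == round(4.4e-4, 5)

    def test_single_test_threshold_is_alpha(self):
        thr, flags = rr.bonferroni([0.03], alpha=0.05)
        assert thr == 0.05 and flags == [True]

    def test_flags_exact(self):
        ps = [0.0024, 0.0025, 0.0026] + [0.5] * 17  # family of 20 tests
        thr, flags = rr.bonferroni(ps, alpha=0.05)
        assert thr == pytest.approx(0.0025)
        assert flags[:3] == [True, True, False]
        assert not any(flags[3:])


class TestStratifiedORs:
    def hand_fixture(self):
        # profiles: reference 20/20; (1,1,1): 16 cases 4 controls; (1,0,0): 10/10
        cells = {
            ((), "case"): 20, ((), "control"): 20,
            (("a", "b", "c"), "case"): 16, (("a", "b", "c"), "control"): 4,
            (("a",), "case"): 10, (("a",), "control"): 10,
        }
        return rr.exact_fixture(46, 34, cells)

    def test_hand_computed_ors(self):
        I = self.hand_fixture()
        s = rr.stratified_ors(I, ("a", "b", "c"))
        assert s.odds_ratios[(0, 0, 0)].odds_ratio == 1.0
        assert s.odds_ratios[(1, 1, 1)].odds_ratio == pytest.approx((16 / 4) / (20 / 20))
        assert s.odds_ratios[(1, 0, 0)].odds_ratio == pytest.approx(1.0)
        assert s.counts[(1, 1, 1)] == (16, 4)

    def test_uniform_case_fraction_gives_or_one(self):
        cells = {
            ((), "case"): 10, ((), "control"): 10,
            (("a",), "case"): 5, (("a",), "control"): 5,
            (("a", "b", "c"), "case"): 5, (("a", "b", "c"), "control"): 5,
        }
        I = rr.exact_fixture(20, 20, cells)
        s = rr.stratified_ors(I, ("a", "b", "c"))
        for prof, res in s.odds_ratios.items():
            if s.counts[prof] != (0, 0):
                assert res.odds_ratio == pytest.approx(1.0)

    def test_empty_reference_is_error(self):
        cells = {(("a",), "case"): 5, (("a",), "control"): 5}
        I = rr.exact_fixture(5, 5, cells, items=["a", "b", "c"])
        # all subjects carry a -> reference (0,0,0) has no cases or controls
        with pytest.raises(ValueError, match="reference"):
            rr.stratified_ors(I, ("a", "b", "c"))

    def test_joint_only_effect_isolated_to_triple_stratum(self):
        cfg = rr.SyntheticCohortConfig(seed=4, n_substructure_dims=0,
                                       pattern_item_maf=0.35)
        cfg.patterns = [rr.PlantedPattern(
            items=tuple(cfg.variant_ids[:3]), joint_odds_ratio=12.0,
            marginal_odds_ratios=(1.0, 1.0, 1.0))]
        c = rr.simulate_cohort(cfg)
        I = rr.encode_incidence(c.genotypes, c.phenotype)
        s = rr.stratified_ors(I, ("v001", "v002", "v003"))
        assert s.odds_ratios[(1, 1, 1)].odds_ratio > 4
        singles = [s.odds_ratios[p].odds_ratio
                   for p in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        assert all(o < 3 for o in singles)


class TestAdditiveInteraction:
    def test_all_or_one_is_exact_null(self):
        ors = {p: 1.0 for p in [(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)]}
        reri, ap = reri_ap(ors)
        assert reri == 0.0 and ap == 0.0

    def test_constructed_additive_null(self):
        ors = {(0, 0, 0): 1.0, (1, 0, 0): 2.0, (0, 1, 0): 3.0, (0, 0, 1): 1.5,
               (1, 1, 0): 4.0, (1, 0, 1): 2.5, (0, 1, 1): 3.5}
        ors[(1, 1, 1)] = (ors[(1, 1, 0)] + ors[(1, 0, 1)] + ors[(0, 1, 1)]
                          - ors[(1, 0, 0)] - ors[(0, 1, 0)] - ors[(0, 0, 1)] + 1)
        reri, ap = reri_ap(ors)
        assert reri == pytest.approx(0.0)
        assert ap == pytest.approx(0.0)

    def test_multiplicative_ors_give_positive_reri(self):
        o1, o2, o3 = 1.5, 2.0, 1.8
        ors = {(0, 0, 0): 1.0, (1, 0, 0): o1, (0, 1, 0): o2, (0, 0, 1): o3,
               (1, 1, 0): o1 * o2, (1, 0, 1): o1 * o3, (0, 1, 1): o2 * o3,
               (1, 1, 1): o1 * o2 * o3}
        reri, ap = reri_ap(ors)
        assert reri > 0
        assert ap == pytest.approx(reri / (o1 * o2 * o3))

    def test_bootstrap_ap_p_small_for_strong_interaction(self):
        cfg = rr.SyntheticCohortConfig(seed=2, n_substructure_dims=0,
                                       pattern_item_maf=0.35)
        cfg.patterns = [rr.PlantedPattern(
            items=tuple(cfg.variant_ids[:3]), joint_odds_ratio=15.0,
            marginal_odds_ratios=(1.0, 1.0, 1.0))]
        c = rr.simulate_cohort(cfg)
        I = rr.encode_incidence(c.genotypes, c.phenotype)
        reri, ap, ap_p, draws = rr.additive_interaction(
            I, ("v001", "v002", "v003"), n_boot=300, seed=0)
        assert reri > 0
        assert 0 < ap <= 1
        assert ap_p < 0.05


class TestMultiplicativeInteraction:
    def test_recovers_planted_three_way_log_or(self):
        """Large-n design with a pure three-way term: the estimate's Wald CI
        covers log(5)."""
        rng = np.random.default_rng(0)
        n = 20000
        G = (rng.random((n, 3)) < 0.5).astype(float)
        three = G.prod(axis=1)
        logit = -1.0 + math.log(5.0) * three
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        or3, p, fit, firth = multiplicative_interaction(y, G)
        se = math.sqrt(fit.cov[7, 7])
        assert abs(math.log(or3) - math.log(5.0)) < 1.96 * se
        assert p < 0.05
        assert not firth

    def test_null_three_way_p_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(120):
            n = 400
            G = (rng.random((n, 3)) < 0.5).astype(float)
            logit = -0.3 + 0.4 * G[:, 0] + 0.3 * G[:, 1]  # no interaction
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            _, p, fit, _ = multiplicative_interaction(y, G)
            if fit.converged:
                ps.append(p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_item_is_rank_deficiency_error(self, rng):
        n = 100
        G = (rng.random((n, 3)) < 0.5).astype(float)
        G[:, 2] = 0.0
        y = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(RankDeficiencyError):
            multiplicative_interaction(y, G)
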