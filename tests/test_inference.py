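"""Treatment ANOVAs, pair interaction ANOVAs, FDR, Welch test, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import synergy_screen as ss
from synergy_screen import Trait
from synergy_screen.inference import (
    AnalysisError,
    fdr_adjust,
    nonlinearity_alignment,
    pair_interaction_anova,
    screen_interaction_anovas,
    single_dual_correlation,
    treatment_anova,
    welch_germination_test,
)

TRAIT = Trait.SHOOT_DRY_WEIGHT


# ---------------------------------------------------------------------------
# independent oracles


def lstsq_interaction_oracle(cells):
    """Interaction F for a 2x2 design via normal equations.

    ``cells`` maps (a, b) in {0,1}^2 to response arrays.  Solves the full
    and main-effects least-squares problems explicitly and forms the
    extra-sum-of-squares F with 1 numerator df.
    """
    order = [(0, 0), (1, 0), (0, 1), (1, 1)]
    y = np.concatenate([np.asarray(cells[k], float) for k in order])
    a = np.concatenate([np.full(len(cells[k]), k[0], float) for k in order])
    b = np.concatenate([np.full(len(cells[k]), k[1], float) for k in order])
    X = np.column_stack([np.ones_like(y), a, b, a * b])

    def rss(Xm):
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        r = y - Xm @ beta
        return float(r @ r)

    rss_full, rss_main = rss(X), rss(X[:, :3])
    df_den = len(y) - 4
    F = (rss_main - rss_full) / (rss_full / df_den)
    return F, float(scipy.stats.f.sf(F, 1, df_den))


def welch_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx + vy)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    p = 2 * scipy.stats.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Benjamini–Hochberg step-up by direct enumeration."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        q[i] = running_min
    return q


def _sg_from_cells(make_sg_frame, cells, round_ids=None):
    kinds = {(0, 0): ("control", ()), (1, 0): ("single", ("a",)), (0, 1): ("single", ("b",)), (1, 1): ("dual", ("a", "b"))}
    rows = []
    for key, values in cells.items():
        kind, iso = kinds[key]
        rid = (round_ids or {}).get(key, "R1")
        rows += [(kind, iso, rid, TRAIT.value, v) for v in values]
    return make_sg_frame(rows)


# ---------------------------------------------------------------------------


class TestTreatmentAnova:
    def test_two_group_hand_computed_sums_of_squares(self, make_sg_frame):
        sg = make_sg_frame(
            [("single", ("a",), "R1", TRAIT.value, v) for v in (1.0, 2.0, 3.0)]
            + [("single", ("b",), "R1", TRAIT.value, v) for v in (4.0, 5.0, 6.0)]
        )
        res = treatment_anova(sg, TRAIT, "single")
        assert res.F == pytest.approx(13.5)  # SSB 13.5, MSW 1
        assert (res.df_between, res.df_within) == (1, 4)

    def test_relabeling_groups_leaves_F_unchanged(self, make_sg_frame):
        values = {"a": (1.0, 2.0, 5.0), "b": (0.0, 3.0, 4.0), "c": (2.0, 2.5, 9.0)}
        sg1 = make_sg_frame(
            [("single", (k,), "R1", TRAIT.value, v) for k, vs in values.items() for v in vs]
        )
        relabel = {"a": "z", "b": "y", "c": "x"}
        sg2 = make_sg_frame(
            [("single", (relabel[k],), "R1", TRAIT.value, v) for k, vs in values.items() for v in vs]
        )
        assert treatment_anova(sg1, TRAIT, "single").F == pytest.approx(
            treatment_anova(sg2, TRAIT, "single").F
        )

    def test_single_replicate_group_rejected(self, make_sg_frame):
        sg = make_sg_frame(
            [("single", ("a",), "R1", TRAIT.value, v) for v in (1.0, 2.0)]
            + [("single", ("b",), "R1", TRAIT.value, 4.0)]
        )
        with pytest.raises(AnalysisError, match="replicate"):
            treatment_anova(sg, TRAIT, "single")

    def test_zero_within_group_variance_rejected(self, make_sg_frame):
        sg = make_sg_frame(
            [("single", ("a",), "R1", TRAIT.value, 1.0)] * 3
            + [("single", ("b",), "R1", TRAIT.value, 2.0)] * 3
        )
        with pytest.raises(AnalysisError, match="variance"):
            treatment_anova(sg, TRAIT, "single")

    def test_null_p_values_are_uniform(self, make_sg_frame):
        """Groups drawn from one normal distribution give U(0,1) p-values."""
        rng = np.random.default_rng(4)
        pvals = []
        for _ in range(400):
            sg = make_sg_frame(
                [("single", (k,), "R1", TRAIT.value, v)
                 for k in ("a", "b", "c")
                 for v in rng.normal(0, 1, 8)]
            )
            pvals.append(treatment_anova(sg, TRAIT, "single").p)
        assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_full_design_degrees_of_freedom(self, default_sg):
        single = treatment_anova(default_sg, TRAIT, "single")
        dual = treatment_anova(default_sg, TRAIT, "dual")
        assert single.df_between == 12
        assert dual.df_between == 77


class TestPairInteractionAnova:
    def test_exactly_additive_cell_means_give_zero_F(self, make_sg_frame):
        cells = {
            (0, 0): [0.0, 2.0],
            (1, 0): [2.0, 4.0],
            (0, 1): [3.0, 5.0],
            (1, 1): [5.0, 7.0],  # interaction contrast 6-3-4+1 = 0
        }
        sg = _sg_from_cells(make_sg_frame, cells)
        res = pair_interaction_anova(sg, ("a", "b"), TRAIT)
        assert res.F_interaction == pytest.approx(0.0, abs=1e-9)
        assert res.df_num == 1

    def test_agrees_with_least_squares_oracle_on_random_instances(self, make_sg_frame):
        rng = np.random.default_rng(8)
        for _ in range(30):
            cells = {
                k: rng.normal(rng.normal(0, 2), 1, rng.integers(2, 9))
                for k in [(0, 0), (1, 0), (0, 1), (1, 1)]
            }
            sg = _sg_from_cells(make_sg_frame, cells)
            res = pair_interaction_anova(sg, ("a", "b"), TRAIT)
            F, p = lstsq_interaction_oracle(cells)
            assert res.F_interaction == pytest.approx(F, abs=1e-8)
            assert res.p == pytest.approx(p, abs=1e-8)

    def test_agrees_with_statsmodels_type2_anova_table(self, make_sg_frame):
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        rng = np.random.default_rng(21)
        cells = {k: rng.normal(k[0] + 2 * k[1], 1, rng.integers(3, 10))
                 for k in [(0, 0), (1, 0), (0, 1), (1, 1)]}
        sg = _sg_from_cells(make_sg_frame, cells)
        res = pair_interaction_anova(sg, ("a", "b"), TRAIT)

        df = pd.DataFrame(
            [(k[0], k[1], v) for k, vs in cells.items() for v in vs],
            columns=["A", "B", "y"],
        )
        table = anova_lm(smf.ols("y ~ A * B", df).fit(), typ=2)
        assert res.F_interaction == pytest.approx(table.loc["A:B", "F"], rel=1e-8)

    def test_empty_cell_is_named(self, make_sg_frame):
        cells = {(0, 0): [0.0, 1.0], (1, 0): [1.0, 2.0], (0, 1): [1.0, 2.0], (1, 1): [2.0]}
        sg = _sg_from_cells(make_sg_frame, cells)
        with pytest.raises(AnalysisError, match="dual AB"):
            pair_interaction_anova(sg, ("a", "b"), TRAIT)

    def test_round_control_pool_restricts_baseline_cell(self, make_sg_frame):
        cells = {(1, 0): [1.0, 2.0], (0, 1): [1.0, 3.0], (1, 1): [2.0, 4.0]}
        round_ids = {(1, 0): "R1", (0, 1): "R1", (1, 1): "R1"}
        sg = _sg_from_cells(make_sg_frame, cells, round_ids)
        other = make_sg_frame(
            [("control", (), "R1", TRAIT.value, v) for v in (0.0, 1.0)]
            + [("control", (), "R9", TRAIT.value, v) for v in (50.0, 60.0, 70.0)]
        )
        sg = pd.concat([sg, other], ignore_index=True)
        res_round = pair_interaction_anova(sg, ("a", "b"), TRAIT, control_pool="round")
        res_all = pair_interaction_anova(sg, ("a", "b"), TRAIT, control_pool="all")
        assert res_round.df_den == 4  # 8 obs - 4 params
        assert res_all.df_den == 7  # 11 obs - 4 params
        assert res_round.F_interaction != pytest.approx(res_all.F_interaction)

    def test_known_nonadditive_pair_outscores_null_pairs(self, default_sg):
        """Screen-level sanity: interaction F ranks high for pairs whose
        dual response deviates most from the single midpoint."""
        anovas = screen_interaction_anovas(default_sg)
        idx = ss.screen_pair_indices(default_sg)
        rho, p = nonlinearity_alignment(idx, anovas, TRAIT)
        assert rho > 0
        assert p < 0.05


class TestFdrAdjust:
    def test_single_p_is_unchanged(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_applied_step_up(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_are_fixed_points(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_out_of_range_p_rejected(self):
        with pytest.raises(AnalysisError):
            fdr_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_enumeration_oracle_and_dominates_p(self, p):
        q = fdr_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestWelch:
    def test_identical_groups_give_t0_p1(self):
        res = welch_germination_test([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_applied_formulas_on_toy(self):
        res = welch_germination_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.t == pytest.approx(-1.2247, abs=1e-4)
        assert res.df == pytest.approx(4.0)

    def test_matches_hand_formula_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(0.6, 0.15, rng.integers(5, 30))
            y = rng.normal(0.8, 0.05, rng.integers(5, 30))
            res = welch_germination_test(x, y)
            t, df, p = welch_oracle(x, y)
            assert res.t == pytest.approx(t, abs=1e-9)
            assert res.df == pytest.approx(df, abs=1e-9)
            assert res.p == pytest.approx(p, abs=1e-9)

    def test_dual_higher_rates_give_negative_t(self, default_screen):
        g = default_screen.germination
        res = welch_germination_test(
            g[g["treatment_kind"] == "single"]["rate"],
            g[g["treatment_kind"] == "dual"]["rate"],
        )
        assert res.t < 0
        assert res.p < 0.05

    def test_degenerate_variances_rejected(self):
        with pytest.raises(AnalysisError):
            welch_germination_test([0.5, 0.5], [0.7, 0.7])


class TestCorrelation:
    def _sg(self, make_sg_frame, single_vals, dual_vals):
        rows = []
        for iso, v in single_vals.items():
            rows += [("single", (iso,), "R1", TRAIT.value, x) for x in (v, v)]
        for pair, v in dual_vals.items():
            rows += [("dual", tuple(pair), "R1", TRAIT.value, x) for x in (v, v)]
        return make_sg_frame(rows)

    def test_perfect_negative_linear_relation(self, make_sg_frame):
        # dual treatment means chosen so per-isolate dual averages are
        # (6, 4, 2) against single means (1, 2, 3): exact negative line
        sg = self._sg(
            make_sg_frame,
            {"a": 1.0, "b": 2.0, "c": 3.0},
            {("a", "b"): 8.0, ("a", "c"): 4.0, ("b", "c"): 0.0},
        )
        res = single_dual_correlation(sg, TRAIT)
        assert res.r == pytest.approx(-1.0)
        assert res.n == 3

    def test_identity_line_gives_r1(self, make_sg_frame):
        sg = self._sg(
            make_sg_frame,
            {"a": 1.0, "b": 2.0, "c": 3.0},
            {("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 4.0},
        )
        # dual averages: a:(1+2)/2=1.5, b:(1+4)/2=2.5, c:(2+4)/2=3
        res = single_dual_correlation(sg, TRAIT)
        assert res.r == pytest.approx(scipy.stats.pearsonr([1, 2, 3], [1.5, 2.5, 3.0])[0])

    def test_spearman_option(self, make_sg_frame):
        sg = self._sg(
            make_sg_frame,
            {"a": 1.0, "b": 2.0, "c": 3.0},
            {("a", "b"): 1.0, ("a", "c"): 2.0, ("b", "c"): 4.0},
        )
        res = single_dual_correlation(sg, TRAIT, method="spearman")
        assert res.method == "spearman"
        assert res.r == pytest.approx(1.0)

    def test_too_few_isolates_rejected(self, make_sg_frame):
        sg = self._sg(make_sg_frame, {"a": 1.0, "b": 2.0}, {("a", "b"): 1.0})
        with pytest.raises(AnalysisError, match="3 isolates"):
            single_dual_correlation(sg, TRAIT)

    def test_full_design_uses_all_13_isolates(self, default_sg):
        res = single_dual_correlation(default_sg, TRAIT)
        assert res.n == 13
        assert -1 <= res.r <= 1


class TestNonlinearityAlignment:
    def _tables(self, f_of_di):
        idx = pd.DataFrame(
            {
                "pair_a": ["a", "a", "b"],
                "pair_b": ["b", "c", "c"],
                "trait": TRAIT.value,
                "di_mean": [-2.0, 0.5, 1.0],
            }
        )
        anova = idx[["pair_a", "pair_b", "trait"]].copy()
        anova["F_interaction"] = [f_of_di(abs(d)) for d in idx["di_mean"]]
        return idx, anova

    def test_monotone_F_in_abs_di_gives_rho_1(self):
        idx, anova = self._tables(lambda d: d**2 + 1)
        rho, _ = nonlinearity_alignment(idx, anova, TRAIT)
        assert rho == pytest.approx(1.0)

    def test_mismatched_pair_sets_rejected(self):
        idx, anova = self._tables(lambda d: d)
        with pytest.raises(AnalysisError, match="pair sets"):
            nonlinearity_alignment(idx, anova.iloc[:-1], TRAIT)

    def test_constant_di_rejected(self):
        idx, anova = self._tables(lambda d: d)
        idx["di_mean"] = 1.0
        with pytest.raises(AnalysisError, match="rank variance"):
            nonlinearity_alignment(idx, anova, TRAIT)
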