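"""Loewe-additive predictions, interaction classification, power analysis."""

import math

import numpy as np
import pytest
from scipy import stats

from isobolo.isobole import (
    AdditivePrediction,
    MixtureDesign,
    additive_nonparallel,
    additive_parallel,
    compare_exp_vs_add,
    compromise_power,
    interaction_index,
    mixture_component_doses,
    therapeutic_index,
)

from conftest import make_fit


class TestAdditiveParallel:
    @pytest.mark.parametrize(
        "ed50_a, ed50_b, expected",
        [
            (72.12, 14.42, 43.27),  # GBP+LEV
            (31.66, 4.56, 18.11),  # PGB+LCM
            (31.66, 14.42, 23.04),  # PGB+LEV
            (14.42, 29.04, 21.73),  # LEV+RTG
        ],
    )
    def test_equieffective_mixture_ed50(self, ed50_a, ed50_b, expected):
        fa, fb = make_fit("a", ed50_a, 4.0), make_fit("b", ed50_b, 4.0)
        assert additive_parallel(fa, fb, 0.5).ed50_add == pytest.approx(
            expected, abs=0.005
        )

    def test_equal_potency_is_identity(self):
        fa, fb = make_fit("a", 10.0, 4.0), make_fit("b", 10.0, 4.0)
        assert additive_parallel(fa, fb, 0.5).ed50_add == pytest.approx(10.0)

    def test_sem_combines_in_quadrature(self):
        fa = make_fit("a", 40.0, 4.0, sem=3.0)
        fb = make_fit("b", 10.0, 4.0, sem=4.0)
        pred = additive_parallel(fa, fb, 0.5)
        assert pred.sem_add == pytest.approx(math.sqrt(0.25 * 9 + 0.25 * 16))

    def test_n_add_rule(self):
        fa = make_fit("a", 40.0, 4.0, n_effective=24)
        fb = make_fit("b", 10.0, 4.0, n_effective=24)
        assert additive_parallel(fa, fb).n_add == 44

    @pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
    def test_swap_symmetry(self, f):
        fa = make_fit("a", 40.0, 4.0, sem=3.0)
        fb = make_fit("b", 10.0, 4.0, sem=4.0)
        p1 = additive_parallel(fa, fb, f)
        p2 = additive_parallel(fb, fa, 1.0 - f)
        assert p1.ed50_add == pytest.approx(p2.ed50_add)
        assert p1.sem_add == pytest.approx(p2.sem_add)

    def test_prediction_between_single_ed50s(self):
        fa = make_fit("a", 40.0, 4.0)
        fb = make_fit("b", 10.0, 4.0)
        for f in (0.1, 0.5, 0.9):
            v = additive_parallel(fa, fb, f).ed50_add
            assert 10.0 < v < 40.0

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.3])
    def test_invalid_fraction(self, f):
        fa, fb = make_fit("a", 40.0, 4.0), make_fit("b", 10.0, 4.0)
        with pytest.raises(ValueError):
            additive_parallel(fa, fb, f)


class TestAdditiveNonparallel:
    def test_equal_slopes_degenerate_to_parallel(self):
        fa = make_fit("a", 72.11, 6.0)
        fb = make_fit("b", 4.57, 6.0)
        pred = additive_nonparallel(fa, fb, 0.5)
        parallel = 0.5 * (72.11 + 4.57)
        assert pred.lower_ed50_add == pytest.approx(parallel, abs=1e-8)
        assert pred.upper_ed50_add == pytest.approx(parallel, abs=1e-8)

    def test_midpoint_identity_at_equieffective_ratio(self):
        # at f = 0.5 the two dose-equivalence bounds are exactly symmetric
        # about the straight-line additive value, for any slope pair
        for slope_b in (1.8, 3.0, 9.0):
            fa = make_fit("a", 72.11, 6.0)
            fb = make_fit("b", 4.57, slope_b)
            pred = additive_nonparallel(fa, fb, 0.5)
            mid = 0.5 * (pred.lower_ed50_add + pred.upper_ed50_add)
            assert mid == pytest.approx(0.5 * (72.11 + 4.57), abs=1e-6)

    def test_bounds_bracket_parallel_value(self):
        fa = make_fit("a", 72.11, 6.0)
        fb = make_fit("b", 4.57, 1.8)
        pred = additive_nonparallel(fa, fb, 0.5)
        parallel = 0.5 * (72.11 + 4.57)
        assert pred.lower_ed50_add < parallel < pred.upper_ed50_add

    def test_bound_totals_satisfy_their_isobole_equations(self):
        fa = make_fit("a", 72.11, 6.0)
        fb = make_fit("b", 4.57, 1.8)
        pred = additive_nonparallel(fa, fb, 0.5)
        design = MixtureDesign("a", "b", 72.11, 4.57, 0.5)
        rho = 1.8 / 6.0
        for total, eq in (
            (pred.lower_ed50_add, lambda u, v: u + v**rho),
            (pred.upper_ed50_add, lambda u, v: u ** (1.0 / rho) + v),
        ):
            da, db = mixture_component_doses(design, total)
            vals = sorted(
                [eq(da / 72.11, db / 4.57), eq(db / 4.57, da / 72.11)]
            )
            # one orientation of the equation must be satisfied to ~1e-9
            assert min(abs(v - 1.0) for v in vals) < 1e-8

    def test_sems_positive_and_finite(self):
        fa = make_fit("a", 72.11, 6.0, sem=9.0)
        fb = make_fit("b", 4.57, 1.8, sem=1.5)
        pred = additive_nonparallel(fa, fb, 0.5)
        assert 0 < pred.sem_lower < math.inf
        assert 0 < pred.sem_upper < math.inf


class TestInteractionIndex:
    @pytest.mark.parametrize(
        "exp, add, expected",
        [(44.36, 51.88, 0.86), (8.17, 18.11, 0.45), (15.06, 43.27, 0.35)],
    )
    def test_parallel_reference(self, exp, add, expected):
        pred = AdditivePrediction("parallel", 36, ed50_add=add, sem_add=1.0)
        assert round(interaction_index(exp, pred), 2) == expected

    def test_nonparallel_uses_lower_bound(self):
        pred = AdditivePrediction(
            "nonparallel",
            52,
            lower_ed50_add=12.45,
            upper_ed50_add=21.15,
            sem_lower=4.22,
            sem_upper=4.82,
        )
        assert round(interaction_index(12.12, pred), 2) == 0.97

    def test_self_comparison_is_unity(self):
        pred = AdditivePrediction("parallel", 36, ed50_add=18.0, sem_add=1.0)
        assert interaction_index(18.0, pred) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        pred = AdditivePrediction("parallel", 36, ed50_add=0.0, sem_add=1.0)
        with pytest.raises(ValueError):
            interaction_index(10.0, pred)


class TestWelchComparison:
    def test_synergy_detected(self):
        # |43.27 - 15.06| / sqrt(6.47^2 + 5.03^2) = 3.44
        pred = AdditivePrediction("parallel", 44, ed50_add=43.27, sem_add=6.47)
        res = compare_exp_vs_add(15.06, 5.03, 16, pred)
        assert res.t_statistic == pytest.approx(3.442, abs=0.002)
        assert res.p_value < 0.01
        assert res.classification == "synergy"

    def test_welch_df_formula(self):
        pred = AdditivePrediction("parallel", 44, ed50_add=43.27, sem_add=6.47)
        res = compare_exp_vs_add(15.06, 5.03, 16, pred)
        se2 = 6.47**2 + 5.03**2
        df_expected = se2**2 / (5.03**4 / 15 + 6.47**4 / 43)
        assert res.df == pytest.approx(df_expected, rel=1e-12)
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(res.t_statistic, df_expected), rel=1e-12
        )

    def test_additivity_when_not_significant(self):
        pred = AdditivePrediction("parallel", 36, ed50_add=51.88, sem_add=9.09)
        res = compare_exp_vs_add(44.36, 5.51, 16, pred)
        assert res.p_value > 0.05
        assert res.classification == "additivity"

    def test_equal_estimates_give_t_zero(self):
        pred = AdditivePrediction("parallel", 36, ed50_add=20.0, sem_add=2.0)
        res = compare_exp_vs_add(20.0, 2.0, 16, pred)
        assert res.t_statistic == 0.0
        assert res.classification == "additivity"
        assert res.interaction_index == pytest.approx(1.0)

    def test_antagonism_branch(self):
        pred = AdditivePrediction("parallel", 36, ed50_add=20.0, sem_add=1.0)
        res = compare_exp_vs_add(40.0, 1.0, 16, pred)
        assert res.classification == "antagonism"

    def test_nonparallel_compares_against_lower_bound(self):
        pred = AdditivePrediction(
            "nonparallel",
            44,
            lower_ed50_add=7.26,
            upper_ed50_add=11.73,
            sem_lower=3.36,
            sem_upper=3.90,
        )
        res = compare_exp_vs_add(1.73, 0.26, 24, pred)
        assert res.t_statistic == pytest.approx(
            (7.26 - 1.73) / math.sqrt(3.36**2 + 0.26**2), rel=1e-9
        )

    @pytest.mark.parametrize("c", [0.1, 3.0, 250.0])
    def test_classification_invariant_to_dose_rescaling(self, c):
        pred = AdditivePrediction("parallel", 44, ed50_add=43.27, sem_add=6.47)
        pred_c = AdditivePrediction(
            "parallel", 44, ed50_add=c * 43.27, sem_add=c * 6.47
        )
        r = compare_exp_vs_add(15.06, 5.03, 16, pred)
        rc = compare_exp_vs_add(c * 15.06, c * 5.03, 16, pred_c)
        assert rc.t_statistic == pytest.approx(r.t_statistic, rel=1e-9)
        assert rc.classification == r.classification
        assert rc.interaction_index == pytest.approx(r.interaction_index)

    def test_degenerate_sem_rejected(self):
        pred = AdditivePrediction("parallel", 36, ed50_add=20.0, sem_add=0.0)
        with pytest.raises(ValueError):
            compare_exp_vs_add(18.0, 1.0, 16, pred)


class TestCompromisePower:
    def test_null_effect_symmetric_compromise(self):
        # d = 0, q = 1: alpha = beta = 0.5, power = alpha
        rep = compromise_power(20.0, 2.0, 16, 20.0, 2.0, 36, q=1.0)
        assert rep.effect_size_d == 0.0
        assert rep.implied_alpha == pytest.approx(0.5, abs=1e-9)
        assert rep.implied_power == pytest.approx(rep.implied_alpha, abs=1e-9)

    def test_matches_grid_search_oracle(self):
        # d = 1, n = 16/36, q = 1: brute-force the critical value on a
        # 1e-4 grid and compare
        n1, n2, df = 16, 36, 50
        ncp = 1.0 * math.sqrt(n1 * n2 / (n1 + n2))
        best = None
        for tc in np.arange(1.0, 3.0, 1e-4):
            alpha = 2 * stats.t.sf(tc, df)
            beta = stats.nct.cdf(tc, df, ncp) - stats.nct.cdf(-tc, df, ncp)
            gap = abs(beta - alpha)
            if best is None or gap < best[0]:
                best = (gap, tc, alpha, beta)
        # reconstruct sems that give exactly d = 1
        # pooled SD = 1 when both group SDs are 1
        rep = compromise_power(
            21.0, 1.0 / math.sqrt(n1), n1, 20.0, 1.0 / math.sqrt(n2), n2, q=1.0
        )
        assert rep.effect_size_d == pytest.approx(1.0, rel=1e-9)
        assert rep.critical_t == pytest.approx(best[1], abs=2e-4)
        assert rep.implied_alpha == pytest.approx(best[2], abs=1e-3)
        assert rep.implied_power == pytest.approx(1 - best[3], abs=1e-3)

    def test_power_increases_with_effect_size(self):
        powers = []
        for delta in (0.5, 1.0, 2.0, 4.0):
            rep = compromise_power(
                20.0 + delta, 0.25, 16, 20.0, 0.25, 36, q=1.0
            )
            powers.append(rep.implied_power)
        assert powers == sorted(powers)
        assert all(powers[i] < powers[i + 1] for i in range(len(powers) - 1))

    def test_beta_alpha_ratio_respected(self):
        rep = compromise_power(24.0, 1.0, 16, 20.0, 1.0, 36, q=4.0)
        beta = 1.0 - rep.implied_power
        assert beta / rep.implied_alpha == pytest.approx(4.0, rel=1e-6)

    def test_invalid_q(self):
        with pytest.raises(ValueError):
            compromise_power(20.0, 1.0, 16, 25.0, 1.0, 36, q=0.0)


class TestTherapeuticIndex:
    @pytest.mark.parametrize(
        "td50, ed50, expected",
        [(10.0, 10.0, 1.0), (100.0, 4.56, 100 / 4.56), (200.0, 72.12, 200 / 72.12)],
    )
    def test_ratio(self, td50, ed50, expected):
        assert therapeutic_index(td50, ed50) == pytest.approx(expected)

    def test_invalid(self):
        with pytest.raises(ValueError):
            therapeutic_index(10.0, 0.0)


class TestMixtureComponentDoses:
    def test_half_ed50_split_at_additive_total(self):
        design = MixtureDesign("GBP", "LEV", 72.12, 14.42, 0.5)
        da, db = mixture_component_doses(design, design.additive_total)
        assert da == pytest.approx(36.06, abs=0.005)
        assert db == pytest.approx(7.21, abs=0.005)

    def test_zero_total(self):
        design = MixtureDesign("a", "b", 10.0, 5.0)
        assert mixture_component_doses(design, 0.0) == (0.0, 0.0)

    @pytest.mark.parametrize("total", [0.5, 7.0, 123.4])
    def test_components_sum_to_total(self, total):
        design = MixtureDesign("a", "b", 10.0, 5.0, 0.3)
        da, db = mixture_component_doses(design, total)
        assert da + db == pytest.approx(total)
        # constant ratio along the ray
        assert da / db == pytest.approx(design.component_dose_ratio)

    def test_negative_total_rejected(self):
        design = MixtureDesign("a", "b", 10.0, 5.0)
        with pytest.raises(ValueError):
            mixture_component_doses(design, -1.0)
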