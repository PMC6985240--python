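import numpy as np
import pytest

import oracles
from conftest import make_panel
from qpop import (
    HillComboTruth,
    MedianEffectFit,
    combination_index,
    fit_4pl,
    fit_median_effect,
    fraction_affected,
    response_surface_map,
    simulate_combo_series,
)
from qpop.errors import ValidationError
from qpop.pharmacodynamics import four_pl, response_surface_map_from_grid
from qpop.surface import QuadraticSurface
from qpop.synthetic import simulate_dose_response


class TestFit4PL:
    def test_noise_free_recovery(self):
        doses = np.geomspace(1e-4, 10.0, 8)
        y = four_pl(doses, 1.0, 0.0, 0.02, 1.0)
        c = fit_4pl(doses, y)
        assert c.top == pytest.approx(1.0, rel=1e-6, abs=1e-6)
        assert c.bottom == pytest.approx(0.0, abs=1e-6)
        assert c.ic50 == pytest.approx(0.02, rel=1e-6)
        assert c.hill == pytest.approx(1.0, rel=1e-6)

    @pytest.mark.parametrize("ic50,hill", [(0.0216, 1.0), (0.000322, 1.5), (63.4, 0.8)])
    def test_noisy_recovery_within_10pct(self, ic50, hill):
        doses = np.geomspace(ic50 / 100, ic50 * 100, 8)
        d, y = simulate_dose_response(ic50, hill, doses, n_replicates=3,
                                      noise_sd=0.03, seed=11)
        c = fit_4pl(d, y)
        assert c.ic50 == pytest.approx(ic50, rel=0.10)

    def test_constant_responses_flagged(self):
        doses = np.geomspace(0.01, 10.0, 6)
        c = fit_4pl(doses, np.full(6, 0.98))
        assert c.no_dose_effect
        assert c.ic50 is None

    def test_dose_unit_rescaling(self):
        doses = np.geomspace(1e-3, 1.0, 9)
        y = four_pl(doses, 1.0, 0.1, 0.03, 1.4)
        a = fit_4pl(doses, y)
        b = fit_4pl(doses * 1000.0, y)  # e.g. uM -> nM
        assert b.ic50 == pytest.approx(a.ic50 * 1000.0, rel=1e-6)
        assert b.hill == pytest.approx(a.hill, rel=1e-6)

    def test_too_few_distinct_doses(self):
        with pytest.raises(ValidationError, match="5 distinct"):
            fit_4pl([1, 1, 2, 2, 3, 3], [1, 1, 0.5, 0.5, 0.1, 0.1])

    def test_nonpositive_dose(self):
        with pytest.raises(ValidationError, match="positive"):
            fit_4pl([0.0, 1, 2, 3, 4], [1, 0.9, 0.5, 0.2, 0.1])

    def test_increasing_response_curve(self):
        # fraction-affected style data: rising sigmoid needs negative hill
        doses = np.geomspace(1e-3, 1.0, 9)
        y = four_pl(doses, 0.95, 0.05, 0.03, -1.2)
        c = fit_4pl(doses, y)
        assert c.ic50 == pytest.approx(0.03, rel=1e-5)
        assert c.top > c.bottom


class TestMedianEffect:
    def test_exact_identity_curve(self):
        doses = np.geomspace(0.05, 20.0, 7)
        fa = (doses / 1.0) / (1.0 + doses / 1.0)  # Dm=1, m=1
        fit = fit_median_effect(doses, fa)
        assert fit.Dm == pytest.approx(1.0, rel=1e-10)
        assert fit.m == pytest.approx(1.0, rel=1e-10)
        assert fit.fa_at(fit.Dm) == pytest.approx(0.5)

    def test_matches_closed_form_regression_oracle(self):
        doses = np.geomspace(0.05, 5.0, 6)
        ratio = (doses / 0.5) ** 2.0
        fa = ratio / (1.0 + ratio)  # Dm=0.5, m=2
        fit = fit_median_effect(doses, fa)
        slope, intercept = oracles.linreg_closed_form(
            np.log(doses), np.log(fa / (1 - fa))
        )
        assert fit.m == pytest.approx(slope, rel=1e-12)
        assert fit.Dm == pytest.approx(np.exp(-intercept / slope), rel=1e-12)
        assert fit.Dm == pytest.approx(0.5, rel=1e-9)
        assert fit.m == pytest.approx(2.0, rel=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-9)

    def test_boundary_points_excluded_with_warning(self):
        doses = np.array([0.1, 0.5, 1.0, 2.0, 5.0])
        fa = np.array([0.0, 0.3, 0.5, 0.7, 1.0])
        with pytest.warns(UserWarning, match="excluding 2"):
            fit = fit_median_effect(doses, fa)
        assert fit.n_points == 3

    def test_too_few_interior_points(self):
        with pytest.warns(UserWarning, match="excluding"):
            with pytest.raises(ValidationError, match=">= 3"):
                fit_median_effect([1.0, 2.0, 3.0], [0.0, 0.5, 1.0])

    def test_saturated_constant_fa_unfittable(self):
        from qpop.errors import QpopError

        with pytest.raises(QpopError):
            fit_median_effect([1.0, 2.0, 4.0, 8.0], [0.999] * 4)


class TestCombinationIndex:
    def test_sham_self_combination_is_additive(self):
        me = MedianEffectFit(Dm=0.7, m=1.8, label="drug")
        fa = np.linspace(0.05, 0.95, 19)
        D = me.iso_effective_dose(fa)
        # drug "combined with itself": doses d and D-d
        doses = np.column_stack([0.35 * D, 0.65 * D])
        res = combination_index([me, me], doses, fa)
        assert np.max(np.abs(res.ci - 1.0)) <= 1e-9
        assert all(v == "additive" for v in res.verdicts)

    @pytest.mark.parametrize("alpha,side", [(0.5, "synergy"), (2.0, "antagonism")])
    def test_loewe_alpha_recovered(self, alpha, side):
        truth = HillComboTruth(labels=("a", "b"), ic50=(0.0216, 0.000322),
                               hill=(1.1, 0.9), loewe_alpha=alpha)
        s = simulate_combo_series(truth, n_points=9, seed=0)
        fits = [
            fit_median_effect(s.single_doses[i],
                              fraction_affected(s.single_viability[i]),
                              label=truth.labels[i])
            for i in (0, 1)
        ]
        res = combination_index(fits, s.combo_doses, 1.0 - s.combo_viability)
        interior = (res.fa > 0.1) & (res.fa < 0.9)
        assert np.allclose(res.ci[interior], alpha, rtol=1e-6)
        assert all(v == side for v, keep in zip(res.verdicts, interior) if keep)

    def test_matches_loewe_oracle(self):
        f1 = MedianEffectFit(Dm=1.0, m=1.0, label="a")
        f2 = MedianEffectFit(Dm=2.0, m=2.0, label="b")
        fa = np.array([0.25, 0.5, 0.75])
        doses = np.array([[0.3, 0.6], [1.0, 1.5], [2.0, 4.0]])
        res = combination_index([f1, f2], doses, fa)
        for row, f, c in zip(doses, fa, res.ci):
            assert c == pytest.approx(
                oracles.loewe_ci(row, [1.0, 2.0], [1.0, 2.0], f), rel=1e-12
            )

    def test_boundary_fa_skipped_with_warning(self):
        me = MedianEffectFit(Dm=1.0, m=1.0)
        fa = np.array([0.0, 0.5, 1.0])
        doses = np.ones((3, 2))
        with pytest.warns(UserWarning, match="skipping 2"):
            res = combination_index([me, me], doses, fa)
        assert res.n_skipped == 2
        assert res.fa.size == 1

    def test_nonexclusive_adds_cross_term(self):
        f1 = MedianEffectFit(Dm=1.0, m=1.0, label="a")
        f2 = MedianEffectFit(Dm=1.0, m=1.0, label="b")
        fa = np.array([0.5])
        doses = np.array([[0.5, 0.5]])
        excl = combination_index([f1, f2], doses, fa).ci[0]
        nonexcl = combination_index([f1, f2], doses, fa, form="nonexclusive").ci[0]
        assert nonexcl == pytest.approx(excl + 0.25)

    def test_ci_monotone_in_alpha(self):
        cis = []
        for alpha in (0.25, 0.5, 1.0, 2.0, 4.0):
            truth = HillComboTruth(labels=("a", "b"), ic50=(1.0, 0.1),
                                   hill=(1.0, 1.3), loewe_alpha=alpha)
            s = simulate_combo_series(truth, n_points=7, seed=0)
            fits = [
                fit_median_effect(s.single_doses[i],
                                  fraction_affected(s.single_viability[i]))
                for i in (0, 1)
            ]
            res = combination_index(fits, s.combo_doses, 1.0 - s.combo_viability)
            cis.append(float(np.median(res.ci)))
        assert all(a < b for a, b in zip(cis, cis[1:]))

    def test_left_shifted_combo_implies_synergy(self):
        # fixture shaped like the published follow-up: two agents whose
        # combined curve sits left of both singles -> CI < 1 everywhere tested
        truth = HillComboTruth(labels=("proteasome-i", "hdac-i"),
                               ic50=(0.0216, 0.000322), hill=(1.0, 1.0),
                               loewe_alpha=0.4)
        s = simulate_combo_series(truth, n_points=9, seed=5)
        # left shift probe: combo reaches fa=0.5 at lower total dose than singles
        combo_total_at_half = np.interp(0.5, 1 - s.combo_viability,
                                        s.combo_doses.sum(axis=1))
        assert combo_total_at_half < truth.ic50[0]
        fits = [
            fit_median_effect(s.single_doses[i],
                              fraction_affected(s.single_viability[i]))
            for i in (0, 1)
        ]
        res = combination_index(fits, s.combo_doses, 1.0 - s.combo_viability)
        assert np.all(res.ci < 1.0)

    def test_needs_two_components(self):
        with pytest.raises(ValidationError, match=">= 2"):
            combination_index([MedianEffectFit(Dm=1, m=1)], [[1.0]], [0.5])


class TestResponseSurfaceMap:
    def _surface(self, beta_int_01=0.0):
        panel = make_panel(3)
        b_int = np.zeros(3)
        b_int[0] = beta_int_01  # pair (d0, d1)
        return QuadraticSurface(panel=panel, beta0=1.0,
                                beta_lin=[-0.1, -0.2, 0.0],
                                beta_quad=np.zeros(3), beta_int=b_int)

    def test_negative_interaction_minimum_at_high_high(self):
        grid = response_surface_map(self._surface(-0.8), ("d0", "d1"), 15)
        i, j = np.unravel_index(np.argmin(grid.viability), grid.viability.shape)
        assert grid.dose_a[i] == 1.0 and grid.dose_b[j] == 1.0

    def test_additive_surface_has_zero_cross_difference(self):
        grid = response_surface_map(self._surface(0.0), ("d0", "d1"), 9)
        Z = grid.viability
        cross = Z[1:, 1:] - Z[:-1, 1:] - Z[1:, :-1] + Z[:-1, :-1]
        assert np.max(np.abs(cross)) < 1e-12

    def test_resolution_two_gives_corners(self):
        grid = response_surface_map(self._surface(-0.5), ("d0", "d1"), 2)
        assert grid.viability.shape == (2, 2)
        assert list(grid.dose_a) == [-1.0, 1.0]

    def test_unknown_pair(self):
        with pytest.raises(ValidationError, match="not in panel"):
            response_surface_map(self._surface(), ("d0", "zzz"), 5)

    def test_resolution_below_two(self):
        with pytest.raises(ValidationError, match=">= 2"):
            response_surface_map(self._surface(), ("d0", "d1"), 1)

    def test_measured_grid_bilinear_interpolation(self):
        da = np.array([0.0, 1.0, 2.0])
        db = np.array([0.0, 2.0])
        A, B = np.meshgrid(da, db, indexing="ij")
        Z = 1.0 - 0.1 * A - 0.2 * B  # bilinear: interpolation is exact
        grid = response_surface_map_from_grid(da, db, Z, ("a", "b"), 7)
        A2, B2 = np.meshgrid(grid.dose_a, grid.dose_b, indexing="ij")
        np.testing.assert_allclose(grid.viability, 1.0 - 0.1 * A2 - 0.2 * B2,
                                   atol=1e-12)
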