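"""Driver contributions, fitness differences, polymorphism criteria."""

import numpy as np
import pytest

from polydem import (classify_cells, driver_contribution, evaluate_surface,
                     fitness_difference, make_grid, overlay_ambient)
from polydem.kernel import build_kernel, dominant_eigen
from polydem.selection import _pin_driver
from polydem.surface import BootstrapEnsemble


def _ens(grid, draws, genotype):
    return BootstrapEnsemble(genotype=genotype, grid=grid,
                             draws=np.asarray(draws, float), seed=0)


@pytest.fixture(scope="module")
def tiny_grid():
    return make_grid(20.0, n_bins=2)  # 4 cells


class TestDriverContribution:
    def test_unretained_pair_is_structural_zero(self, truth_modelset_bb,
                                                mesh_small):
        grid = make_grid(20.0, n_bins=3)
        # g10 in the bundled truth has no herbivory term
        c = driver_contribution(truth_modelset_bb, grid, mesh_small,
                                "herbivory", "g10", reference=5.0)
        assert c == 0.0

    def test_environment_free_modelset_all_zero(self, env_free_modelset_bb,
                                                mesh_small):
        grid = make_grid(20.0, n_bins=2)
        for rate in ("s", "b0", "g00", "f"):
            for driver in ("moisture", "herbivory"):
                c = driver_contribution(env_free_modelset_bb, grid,
                                        mesh_small, driver, rate, 5.0)
                assert abs(c) < 1e-12

    def test_retained_pair_moves_lambda(self, truth_modelset_bb, mesh_small):
        grid = make_grid(20.0, n_bins=3)
        c = driver_contribution(truth_modelset_bb, grid, mesh_small,
                                "moisture", "s", reference=12.0)
        assert abs(c) > 1e-4

    def test_removing_driver_everywhere_equals_global_fix(
            self, truth_modelset_bb, mesh_small):
        """Pinning moisture at the reference in every vital rate reproduces,
        cell by cell, lambda evaluated with moisture fixed globally."""
        grid = make_grid(20.0, n_bins=4)
        ref = 11.0
        from polydem.vital_rates import RATE_KEYS
        pinned = _pin_driver(truth_modelset_bb, RATE_KEYS, "moisture", ref)
        via_pin = evaluate_surface(pinned, grid, mesh_small).values
        M, H = grid.cells()
        via_fix = np.array([
            dominant_eigen(build_kernel(truth_modelset_bb, (ref, h),
                                        mesh_small))
            for h in H])
        assert np.allclose(via_pin, via_fix, rtol=1e-10, atol=0)


class TestFitnessDifference:
    def test_identical_ensembles_never_significant(self, tiny_grid):
        draws = np.linspace(0.8, 1.2, 50)[:, None] * np.ones((1, 4))
        diff = fitness_difference(_ens(tiny_grid, draws, "MM"),
                                  _ens(tiny_grid, draws, "BB"))
        assert np.allclose(diff.median, 0.0)
        assert not diff.significant.any()

    def test_constant_shift_significant_everywhere(self, tiny_grid):
        rng = np.random.default_rng(1)
        base = 1.0 + 0.05 * rng.standard_normal((200, 4))
        diff = fitness_difference(_ens(tiny_grid, base + 0.5, "MM"),
                                  _ens(tiny_grid, base, "BB"))
        assert diff.significant.all()
        assert np.allclose(diff.median, 0.5)

    def test_antisymmetry(self, tiny_grid):
        rng = np.random.default_rng(2)
        a = 1.0 + 0.1 * rng.standard_normal((150, 4))
        b = 0.9 + 0.1 * rng.standard_normal((150, 4))
        d1 = fitness_difference(_ens(tiny_grid, a, "MM"),
                                _ens(tiny_grid, b, "BB"))
        d2 = fitness_difference(_ens(tiny_grid, b, "MM"),
                                _ens(tiny_grid, a, "BB"))
        assert np.allclose(d1.median, -d2.median)
        assert np.array_equal(d1.significant, d2.significant)

    def test_mismatched_ensembles_rejected(self, tiny_grid):
        other = make_grid(30.0, n_bins=2)
        with pytest.raises(ValueError, match="grid"):
            fitness_difference(
                _ens(tiny_grid, np.ones((10, 4)), "MM"),
                _ens(other, np.ones((10, 4)), "BB"))
        with pytest.raises(ValueError, match="bootstrap"):
            fitness_difference(
                _ens(tiny_grid, np.ones((10, 4)), "MM"),
                _ens(tiny_grid, np.ones((11, 4)), "BB"))


class TestClassification:
    def test_all_above_replacement_and_equal(self, tiny_grid):
        draws = np.full((40, 4), 1.2)
        pmap = classify_cells(_ens(tiny_grid, draws, "MM"),
                              _ens(tiny_grid, draws, "BB"))
        assert pmap.criterion1.all() and pmap.criterion2.all()
        assert pmap.criterion3.all()
        assert all(v == 1.0 for v in pmap.fractions.values())

    def test_all_below_replacement(self, tiny_grid):
        draws = np.full((40, 4), 0.5)
        pmap = classify_cells(_ens(tiny_grid, draws, "MM"),
                              _ens(tiny_grid, draws, "BB"))
        assert not pmap.criterion1.any()
        assert not pmap.criterion3.any()
        assert pmap.fractions["criterion1"] == 0.0

    def test_hand_built_toy_ensembles(self, tiny_grid):
        """4-cell toy case with known percentiles, enumerated by hand:
        cell 0: both persist, no difference      -> I, II, III
        cell 1: BB cannot persist, no difference -> II only
        cell 2: both persist, MM >> BB           -> I only
        cell 3: BB cannot persist and MM >> BB   -> neither."""
        B = 100
        jitter = np.linspace(-0.01, 0.01, B)[:, None]
        bb = np.column_stack([np.full(B, 1.1), np.full(B, 0.7),
                              np.full(B, 1.05), np.full(B, 0.6)]) + jitter
        mm = np.column_stack([np.full(B, 1.1), np.full(B, 0.72),
                              np.full(B, 1.6), np.full(B, 1.4)]) + jitter
        # cells 0 and 1: difference within jitter of 0 -> not significant
        mm[:, 0] = bb[:, 0] + np.linspace(-0.005, 0.005, B)
        mm[:, 1] = bb[:, 1] + np.linspace(-0.005, 0.005, B)
        pmap = classify_cells(_ens(tiny_grid, mm, "MM"),
                              _ens(tiny_grid, bb, "BB"))
        assert pmap.persist["BB"].tolist() == [True, False, True, False]
        assert pmap.persist["MM"].tolist() == [True, False, True, True]
        assert pmap.criterion1.tolist() == [True, False, True, False]
        assert pmap.criterion2.tolist() == [True, True, False, False]
        assert pmap.criterion3.tolist() == [True, False, False, False]
        assert pmap.fractions["criterion3"] == 0.25

    def test_criterion3_bounded_by_components(self, tiny_grid):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mm = 0.9 + 0.3 * rng.random((30, 4))
            bb = 0.9 + 0.3 * rng.random((30, 4))
            pmap = classify_cells(_ens(tiny_grid, mm, "MM"),
                                  _ens(tiny_grid, bb, "BB"))
            assert pmap.fractions["criterion3"] <= min(
                pmap.fractions["criterion1"], pmap.fractions["criterion2"])


class TestAmbientOverlay:
    def _pmap(self, crit3_grid):
        grid = make_grid(20.0, n_bins=crit3_grid.shape[0])
        flat = crit3_grid.ravel()
        ones = np.ones_like(flat, dtype=bool)
        from polydem.selection import PolymorphismMap
        return PolymorphismMap(grid=grid, persist={"BB": ones, "MM": ones},
                               criterion1=ones, criterion2=flat,
                               criterion3=flat,
                               fractions={"criterion3": float(flat.mean())})

    def test_point_inside_polymorphic_cell(self):
        crit3 = np.ones((4, 4), dtype=bool)
        pmap = self._pmap(crit3)
        rep = overlay_ambient(pmap, [{"year": 2017,
                                      "moisture_mean": 10.0,
                                      "herbivory_mean": 5.0}])
        assert bool(rep["inside_polymorphic"][0])
        assert not bool(rep["out_of_range"][0])

    def test_point_outside_grid_flagged(self):
        pmap = self._pmap(np.ones((4, 4), dtype=bool))
        rep = overlay_ambient(pmap, [{"year": 2018, "moisture_mean": 99.0,
                                      "herbivory_mean": 5.0}])
        assert bool(rep["out_of_range"][0])

    def test_distance_to_monomorphic_column(self):
        """One monomorphic moisture column: cell distance counted by hand."""
        crit3 = np.ones((5, 5), dtype=bool)
        crit3[0, :] = False  # driest column is monomorphic
        pmap = self._pmap(crit3)
        grid = pmap.grid
        rep = overlay_ambient(pmap, [{"year": 2019,
                                      "moisture_mean": float(grid.moisture[3]),
                                      "herbivory_mean": float(grid.herbivory[2])}])
        assert rep["dist_to_monomorphic_moisture_cells"][0] == 3.0
        assert np.isnan(rep["dist_to_monomorphic_herbivory_cells"][0])

    def test_empty_ambient_rejected(self):
        pmap = self._pmap(np.ones((3, 3), dtype=bool))
        with pytest.raises(ValueError):
            overlay_ambient(pmap, [])
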