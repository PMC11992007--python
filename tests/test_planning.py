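"""SOBP plan optimisation: basis selection, cost, solvers and objectives."""

import numpy as np
import pytest

import protonbeam as pb
from protonbeam.units import MEV_PER_G_TO_GY


class TestBasisSelection:
    def test_single_beam_energy(self, water):
        comps = pb.select_basis_energies(1, (3.0, 3.0), 1.0, water)
        assert len(comps) == 1
        assert comps[0].energy == pytest.approx(58.014284648193064, rel=1e-10)

    def test_two_beam_energies(self, water):
        comps = pb.select_basis_energies(2, (3.0, 6.25), 1.0, water)
        assert comps[0].energy == pytest.approx(58.014284648193064, rel=1e-10)
        assert comps[1].energy == pytest.approx(
            (6.25 / water.alpha) ** (1 / water.p), rel=1e-10)

    def test_ranges_roundtrip_to_linspace(self, water, example_basis):
        ranges = np.array(
            [water.range_from_energy(c.energy) for c in example_basis])
        assert np.allclose(ranges, np.linspace(3.0, 6.25, 30), rtol=1e-10)

    def test_unachievable_interval_rejected(self, water):
        with pytest.raises(ValueError):
            pb.select_basis_energies(3, (3.0, 500.0), 1.0, water,
                                     pb.EnergyWindow(0.1, 150.0))


class TestWeightFunction:
    def test_uniform_weights(self, tumour_regions):
        z = np.linspace(0.0, 8.0, 100)
        w = pb.build_weight_function(tumour_regions, 1.0, 1.0, 1.0, z)
        assert np.all(w == 1.0)

    def test_indicator_case(self, tumour_regions):
        z = np.linspace(0.0, 8.0, 801)
        w = pb.build_weight_function(tumour_regions, 1.0, 0.0, 0.0, z)
        assert np.all(w[(z >= 3.0) & (z <= 6.0)] == 1.0)
        assert np.all(w[(z < 3.0) | (z > 6.0)] == 0.0)

    def test_oar_priority_case(self):
        regions = pb.RegionPartition(tumour=(3.0, 6.0), oar=(6.0, 8.0))
        z = np.array([1.0, 4.0, 7.0])
        w = pb.build_weight_function(regions, 1.0, 10.0, 0.0, z)
        assert list(w) == [0.0, 1.0, 10.0]

    def test_negative_weight_rejected(self, tumour_regions):
        with pytest.raises(ValueError):
            pb.build_weight_function(tumour_regions, 1.0, -1.0, 0.0,
                                     np.linspace(0, 8, 10))


class TestRegions:
    def test_overlapping_regions_rejected(self):
        with pytest.raises(ValueError):
            pb.RegionPartition(tumour=(3.0, 6.0), oar=(5.0, 8.0))

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            pb.RegionPartition(tumour=(6.0, 3.0))


class TestCost:
    def test_zero_plan_cost_is_weighted_target_mass(self, example1_plan):
        # L(0) = sum 1/2 w T^2 dz, here ~ 1/2 * |tumour| = 1.5
        assert example1_plan.cost_zero() == pytest.approx(1.5, rel=2e-3)

    def test_exact_match_has_zero_cost(self, example1_plan):
        # synthetic weights whose dose is substituted as target
        rng = np.random.default_rng(0)
        y = rng.uniform(0.0, 0.1, example1_plan.n_beams)
        target = example1_plan.dose(y)
        plan = pb.TreatmentPlan(example1_plan.basis, example1_plan.regions,
                                example1_plan.medium,
                                target=lambda z: np.interp(z, example1_plan.grid,
                                                           target),
                                window=example1_plan.window)
        assert plan.cost(y) <= 1e-12 * plan.cost_zero()

    def test_quadratic_scaling(self, example1_plan):
        # doubling the deviation from target quadruples the cost
        y = np.zeros(example1_plan.n_beams)
        c1 = example1_plan.cost(y)  # deviation = T
        half = pb.TreatmentPlan(example1_plan.basis, example1_plan.regions,
                                example1_plan.medium, target=0.5,
                                window=example1_plan.window)
        c_half = half.cost(y)
        assert c1 == pytest.approx(4.0 * c_half, rel=1e-12)


class TestQuadraticOptimisation:
    def test_single_beam_exact_least_squares(self, water, window150):
        comp = pb.select_basis_energies(1, (4.0, 4.0), 1.0, water, window150)
        regions = pb.RegionPartition(tumour=(0.0, 6.0))
        base = pb.TreatmentPlan(comp, regions, water, target=1.0,
                                window=window150)
        profile = base.dose(np.array([1.0]))
        plan = pb.TreatmentPlan(
            comp, regions, water,
            target=lambda z: 2.5 * np.interp(z, base.grid, profile),
            weights=(1.0, 0.0, 1.0), window=window150)
        res = plan.fit("nnls")
        assert res.weights[0] == pytest.approx(2.5, rel=1e-8)

    def test_example1_relative_error(self, example1_results):
        assert example1_results.relative_error < 1e-5
        assert example1_results.converged

    def test_example1_uniform_coverage(self, example1_plan, example1_results):
        report = pb.evaluate_plan(example1_results)
        assert report["tumour_dose_min"] >= 0.99

    def test_solver_agreement(self, example1_plan, example2_plan):
        # bound-constrained quasi-Newton and the NNLS oracle minimise the
        # same convex quadratic; costs must agree tightly
        for plan in (example1_plan, example2_plan):
            c_qn = plan.fit("quasi_newton").cost
            c_nn = plan.fit("nnls").cost
            assert c_qn == pytest.approx(c_nn, rel=1e-6)

    def test_nnls_at_most_quasi_newton(self, example1_plan):
        c_qn = example1_plan.fit("quasi_newton").cost
        c_nn = example1_plan.fit("nnls").cost
        assert c_nn <= c_qn + 1e-9

    def test_weights_feasible(self, example1_results, example2_plan):
        assert np.all(example1_results.weights >= 0.0)
        res2 = example2_plan.fit("nnls")
        assert np.all(res2.weights >= 0.0)

    def test_upper_bound_respected(self, example1_plan):
        bounded = pb.TreatmentPlan(example1_plan.basis, example1_plan.regions,
                                   example1_plan.medium, target=1.0,
                                   window=example1_plan.window,
                                   upper_bound=0.02)
        res = bounded.fit("quasi_newton")
        assert np.all(res.weights <= 0.02 + 1e-12)
        assert np.all(res.weights >= 0.0)

    def test_hessian_positive_semidefinite(self, example1_plan):
        a, _ = example1_plan._quad_system()
        eigs = np.linalg.eigvalsh(a.T @ a)
        assert eigs.min() >= -1e-10 * eigs.max()

    def test_distal_margin_reduces_cost(self, water, window150, tumour_regions,
                                        example1_results):
        # beams confined to [z_prox, z_dist] oscillate at the distal edge;
        # the +1/4 cm extension achieves a strictly lower optimum
        basis = pb.select_basis_energies(30, (3.0, 6.0), 1.0, water, window150)
        plan = pb.TreatmentPlan(basis, tumour_regions, water, target=1.0,
                                window=window150)
        assert plan.fit("nnls").cost > example1_results.cost


class TestOARPlanning:
    def test_oar_penalty_reduces_oar_dose(self, example_basis, water,
                                          window150, example2_plan):
        regions = example2_plan.regions
        unpenalised = pb.TreatmentPlan(example_basis, regions, water,
                                       weights=(1.0, 0.0, 0.0),
                                       window=window150)
        r_free = unpenalised.fit("nnls")
        r_pen = example2_plan.fit("nnls")
        oar_free = pb.evaluate_plan(r_free)["oar_dose_mean"]
        oar_pen = pb.evaluate_plan(r_pen)["oar_dose_mean"]
        assert oar_pen < oar_free


@pytest.fixture(scope="module")
def bd_results(example_basis, tumour_regions, water, window150):
    plan = pb.TreatmentPlan(example_basis, tumour_regions, water,
                            objective="biological_dose",
                            cell=pb.get_cell_line("AG01522"),
                            window=window150)
    return plan.fit("nnls")


@pytest.fixture(scope="module")
def sf_setup(example_basis, tumour_regions, water, window150):
    # gigaproton-scale beams so unit weights deliver ~Gy doses
    basis = [pb.GaussianComponent(c.energy, c.sigma, 1e9)
             for c in example_basis]

    def make(target):
        return pb.TreatmentPlan(basis, tumour_regions, water,
                                objective="survival_fraction",
                                cell=pb.get_cell_line("AG01522"),
                                target=target,
                                dose_scale=MEV_PER_G_TO_GY,
                                window=window150)
    return make


class TestBiologicalDoseObjective:
    def test_distal_quarter_dose_tapered(self, bd_results, example1_results,
                                         example1_plan):
        grid = example1_plan.grid
        distal = (grid >= 5.25) & (grid <= 6.0)
        d_phys = example1_plan.dose(example1_results.weights)
        d_bd = bd_results.model.dose(bd_results.weights)
        assert d_bd[distal].mean() < d_phys[distal].mean()

    def test_bd_uniform_in_tumour(self, bd_results, tumour_regions):
        bd = bd_results.biological_dose_curve()
        tm = tumour_regions.tumour_mask(bd.z)
        assert np.all(np.abs(bd.values[tm] - 1.0) < 0.05)

    def test_requires_cell_line(self, example_basis, tumour_regions, water,
                                window150):
        with pytest.raises(ValueError, match="cell"):
            pb.TreatmentPlan(example_basis, tumour_regions, water,
                             objective="biological_dose", window=window150)


class TestSurvivalObjective:
    def test_unit_target_gives_zero_plan(self, sf_setup):
        res = sf_setup(1.0).fit()
        assert np.max(np.abs(res.weights)) == 0.0
        assert res.cost == 0.0

    def test_achieved_survival_tracks_target(self, sf_setup, tumour_regions):
        means = []
        for target in (0.5, 0.2, 0.05):
            plan = sf_setup(target)
            res = plan.fit()
            sf = plan.survival(res.weights)
            means.append(sf[tumour_regions.tumour_mask(plan.grid)].mean())
        assert means[0] > means[1] > means[2]
        assert means[1] == pytest.approx(0.2, abs=0.05)

    def test_excess_dose_barely_penalised(self, sf_setup):
        # where survival is already ~0, extra dose costs almost nothing --
        # the known pathology of survival-based objectives
        plan = sf_setup(0.01)
        res = plan.fit()
        bumped = res.weights.copy()
        i = int(np.argmax(bumped))
        bumped[i] *= 1.2
        assert abs(plan.cost(bumped) - plan.cost(res.weights)) < 1e-4

    def test_invalid_target_rejected(self, sf_setup):
        with pytest.raises(ValueError):
            sf_setup(0.0)


class TestResultsObject:
    def test_summary_contents(self, example1_results):
        text = example1_results.summary()
        assert "relative error" in text
        assert "E (MeV)" in text
        assert str(example1_results.model.n_beams) in text

    def test_curves_are_consistent(self, example1_results):
        d = example1_results.dose_curve()
        let = example1_results.dose_let_curve()
        assert d.z.shape == let.z.shape
        assert np.all(let.values >= 0.0)

    def test_evaluate_plan_report(self, example1_results):
        report = pb.evaluate_plan(example1_results,
                                  cell=pb.get_cell_line("U87"))
        assert report["tumour_dose_max"] >= report["tumour_dose_mean"] >= \
            report["tumour_dose_min"]
        assert report["tumour_bd_max"] >= report["tumour_bd_mean"]
        assert report["tumour_max_target_deviation"] < 0.01
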