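"""Axisymmetric contraction FE: mesh quality, linear-limit oracle, decay fits."""

import numpy as np
import pytest

from tendonscale.constitutive import FibrousMatrixParams
from tendonscale.contraction import (CellGeometry, DisplacementField,
                                     DisplacementProfile, MeshSpec, build_mesh,
                                     effective_decay, fit_power_law,
                                     linear_cavity_solution, radial_profile,
                                     solve_contraction,
                                     spherical_contraction_1d)

LINEAR = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=1e-8, lambda1=1.001,
                                         lambda2=1.05, n=5, m=10)
FIBROUS = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=30.0, lambda1=1.0,
                                          lambda2=1.005, n=2, m=10)
SPEC = MeshSpec(1.0, 6.0, 100.0)


@pytest.fixture(scope="module")
def sphere_cell():
    return CellGeometry(a=5.0)


@pytest.fixture(scope="module")
def sphere_mesh(sphere_cell):
    return build_mesh(sphere_cell, SPEC)


def eta_of(params, mesh, cell, increments=5):
    field = solve_contraction(mesh, params, cell, increments=increments)
    return fit_power_law(radial_profile(field)).eta


class TestMesh:
    def test_cavity_nodes_on_sphere(self, sphere_mesh, sphere_cell):
        r = np.linalg.norm(sphere_mesh.nodes[sphere_mesh.cavity_nodes], axis=1)
        assert np.abs(r - sphere_cell.a).max() < 1e-6 * sphere_cell.a

    def test_elliptical_cavity(self):
        cell = CellGeometry(a=5.0, aspect_ratio=3.0)
        mesh = build_mesh(cell, SPEC)
        xy = mesh.nodes[mesh.cavity_nodes]
        val = (xy[:, 0] / cell.semi_axis_r) ** 2 + (xy[:, 1] / cell.semi_axis_z) ** 2
        assert np.abs(val - 1.0).max() < 1e-6
        assert cell.semi_axis_z / cell.semi_axis_r == pytest.approx(3.0, rel=1e-9)

    def test_graded_sizing_monotone(self, sphere_mesh):
        # radial edge length grows monotonically along the equatorial ray
        mid = sphere_mesh.nodes[np.abs(sphere_mesh.nodes[:, 1]) < 1e-9]
        r = np.sort(mid[:, 0])
        dr = np.diff(r)
        assert np.all(np.diff(dr) > -1e-9)
        assert dr[0] < 1.2 * SPEC.near_size
        assert dr[-1] > 0.7 * SPEC.far_size

    def test_quality_floor(self, sphere_mesh):
        assert sphere_mesh.min_angle_deg >= 15.0

    def test_cell_validation(self):
        with pytest.raises(ValueError):
            CellGeometry(a=-1.0)
        with pytest.raises(ValueError):
            CellGeometry(a=5.0, contraction_volume_fraction=1.5)
        with pytest.raises(ValueError):
            build_mesh(CellGeometry(a=200.0), SPEC)


class TestSolve:
    def test_vanishing_contraction_gives_vanishing_field(self, sphere_mesh):
        cell = CellGeometry(a=5.0, contraction_volume_fraction=1e-9)
        field = solve_contraction(sphere_mesh, LINEAR, cell, increments=1)
        assert np.abs(field.u).max() < 1e-8

    def test_linear_limit_matches_cavity_closed_form(self, sphere_mesh):
        cell = CellGeometry(a=5.0, contraction_volume_fraction=0.001)
        field = solve_contraction(sphere_mesh, LINEAR, cell, increments=1)
        prof = radial_profile(field)
        u_a = 5.0 * (1 - 0.999 ** (1 / 3))
        ref = linear_cavity_solution(prof.r_center, 5.0, 100.0, u_a)
        m = (prof.r_center >= 10.0) & (prof.r_center <= 50.0)
        assert np.abs(prof.u[m] - ref[m]).max() / ref[m].max() < 0.05
        fit = fit_power_law(prof)
        assert 1.9 <= fit.eta <= 2.1

    def test_mesh_refinement_converged(self, sphere_cell):
        coarse = build_mesh(sphere_cell, SPEC)
        fine = build_mesh(sphere_cell, SPEC.refined(2.0))
        pc = radial_profile(solve_contraction(coarse, FIBROUS, sphere_cell))
        pf = radial_profile(solve_contraction(fine, FIBROUS, sphere_cell))
        ui = np.interp(pc.r_center, pf.r_center, pf.u)
        assert np.abs(pc.u - ui).max() / np.abs(pf.u).max() < 0.01

    def test_axial_polarization_breaks_isotropy(self, sphere_mesh):
        cell = CellGeometry(a=5.0, polarization="axial")
        field = solve_contraction(sphere_mesh, LINEAR, cell, increments=2)
        prof = radial_profile(field, ray_angles_deg=[5.0, 85.0])
        near = slice(0, 20)
        ratio = (np.nanmean(prof.per_ray_u[1][near])
                 / np.nanmean(prof.per_ray_u[0][near]))
        assert ratio > 1.5  # displacement concentrated along the axis


class TestSphericalOracle:
    def test_1d_reduction_matches_2d_fe(self, sphere_mesh, sphere_cell):
        field = solve_contraction(sphere_mesh, FIBROUS, sphere_cell)
        prof = radial_profile(field)
        Rg, u1d = spherical_contraction_1d(FIBROUS, 5.0, 100.0, n_elements=300)
        ui = np.interp(prof.r_center, Rg, np.abs(u1d))
        m = (prof.r_center >= 10.0) & (prof.r_center <= 50.0)
        assert np.abs(prof.u[m] - ui[m]).max() / ui[m].max() < 0.03

    def test_1d_linear_limit_closed_form(self):
        Rg, u = spherical_contraction_1d(LINEAR, 5.0, 100.0,
                                         contraction_volume_fraction=0.001,
                                         n_elements=400)
        u_a = 5.0 * (1 - 0.999 ** (1 / 3))
        ref = -linear_cavity_solution(Rg, 5.0, 100.0, u_a)
        m = (Rg >= 10.0) & (Rg <= 50.0)
        assert np.abs(u[m] - ref[m]).max() / np.abs(ref[m]).max() < 0.02


class TestProfilesAndDecay:
    def test_per_ray_isotropy_for_spherical_cell(self, sphere_mesh, sphere_cell):
        field = solve_contraction(sphere_mesh, LINEAR, sphere_cell, increments=2)
        prof = radial_profile(field)
        m = (prof.r_center >= 10.0) & (prof.r_center <= 50.0)
        spread = np.nanstd(prof.per_ray_u[:, m], axis=0) \
            / np.nanmean(prof.per_ray_u[:, m], axis=0)
        assert spread.max() < 0.02

    def test_profile_excludes_boundary_margin(self, sphere_mesh, sphere_cell):
        field = solve_contraction(sphere_mesh, LINEAR, sphere_cell, increments=1)
        prof = radial_profile(field)
        # one realized element clear of each boundary
        mesh = sphere_mesh
        near = np.median(np.linalg.norm(
            np.diff(mesh.nodes[mesh.cavity_nodes], axis=0), axis=1))
        far = np.median(np.linalg.norm(
            np.diff(mesh.nodes[mesh.outer_nodes], axis=0), axis=1))
        assert prof.r[0] >= 0.99 * near
        assert prof.r_center[-1] <= 100.0 - 0.99 * far

    def test_exact_power_law_recovered(self):
        r = np.geomspace(6.0, 60.0, 60)
        prof = DisplacementProfile(r=r - 5.0, r_center=r, u=3.0 * r ** -2.0,
                                   ray_angles_deg=np.array([45.0]),
                                   per_ray_u=(3.0 * r ** -2.0)[None, :],
                                   a=5.0, R_out=100.0)
        fit = fit_power_law(prof)
        assert fit.eta == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_power_law_within_tolerance(self, rng):
        r = np.geomspace(6.0, 60.0, 80)
        u = r ** -1.0 * (1.0 + 0.01 * rng.standard_normal(r.shape))
        prof = DisplacementProfile(r=r - 5.0, r_center=r, u=u,
                                   ray_angles_deg=np.array([45.0]),
                                   per_ray_u=u[None, :], a=5.0, R_out=100.0)
        assert fit_power_law(prof).eta == pytest.approx(1.0, abs=0.02)

    def test_angular_average_of_injected_field(self, sphere_cell):
        # synthetic r^-2 nodal field: angular averaging must preserve it
        # (fine mesh keeps linear-interpolation error below the 0.5% bound)
        mesh = build_mesh(sphere_cell, SPEC.refined(2.0))
        r_node = np.linalg.norm(mesh.nodes, axis=1)
        u = (mesh.nodes / r_node[:, None]) * (r_node ** -2.0)[:, None]
        field = DisplacementField(mesh=mesh, u=u, cell=sphere_cell,
                                  params=LINEAR)
        prof = radial_profile(field)
        m = (prof.r_center >= 10.0) & (prof.r_center <= 50.0)
        err = np.abs(prof.u[m] * prof.r_center[m] ** 2 - 1.0)
        assert err.max() < 0.005

    def test_insufficient_points_rejected(self):
        r = np.array([6.0, 7.0, 8.0])
        prof = DisplacementProfile(r=r - 5, r_center=r, u=r ** -2.0,
                                   ray_angles_deg=np.array([45.0]),
                                   per_ray_u=(r ** -2.0)[None, :],
                                   a=5.0, R_out=100.0)
        with pytest.raises(ValueError):
            fit_power_law(prof)


class TestMechanismOrdering:
    def test_eta_nonincreasing_in_fiber_ratio(self, sphere_mesh, sphere_cell):
        etas = []
        for ratio in (0.1, 1.0, 10.0, 100.0):
            p = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=ratio, lambda1=1.0,
                                                lambda2=1.005, n=2, m=10)
            etas.append(eta_of(p, sphere_mesh, sphere_cell))
        assert np.all(np.diff(etas) <= 1e-9)
        assert etas[-1] < etas[0] - 0.5  # strong fibers transmit much farther

    def test_healing_and_fatigue_decay_faster_than_baseline(self, sphere_mesh,
                                                            sphere_cell):
        eta_base = eta_of(FIBROUS, sphere_mesh, sphere_cell)
        healing = FibrousMatrixParams.from_youngs(E_b=0.5, E_f=1.5, lambda1=1.0,
                                                  lambda2=1.02, n=2, m=10)
        fatigue = FibrousMatrixParams.from_youngs(E_b=1.0, E_f=1.0, lambda1=1.01,
                                                  lambda2=1.06, n=2, m=10)
        assert eta_of(healing, sphere_mesh, sphere_cell) > eta_base
        assert eta_of(fatigue, sphere_mesh, sphere_cell) > eta_base

    def test_far_field_insensitivity(self, sphere_cell):
        eta1 = eta_of(FIBROUS, build_mesh(sphere_cell, SPEC), sphere_cell)
        big = MeshSpec(1.0, 6.0, 200.0)
        mesh2 = build_mesh(sphere_cell, big)
        field2 = solve_contraction(mesh2, FIBROUS, sphere_cell)
        # same absolute fit window as the small domain for comparability
        prof2 = radial_profile(field2)
        fit2 = fit_power_law(prof2, r_min_factor=1.2, r_max_factor=0.25)
        assert fit2.eta == pytest.approx(eta1, rel=0.03)


class TestEffectiveDecay:
    def test_reference_identity(self):
        assert effective_decay(2.0, 300.0, 300.0) == 2.0

    def test_quadruple_density_halves_eta(self):
        assert effective_decay(2.0, 1200.0, 300.0) == pytest.approx(1.0)

    def test_monotone_in_cellularity(self):
        vals = [effective_decay(2.0, c, 300.0) for c in (100, 300, 900, 2700)]
        assert np.all(np.diff(vals) < 0)

    def test_volumetric_exponent(self):
        assert effective_decay(2.0, 2400.0, 300.0, density="volumetric") \
            == pytest.approx(1.0)

    def test_invalid_cellularity(self):
        with pytest.raises(ValueError):
            effective_decay(2.0, -1.0, 300.0)
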