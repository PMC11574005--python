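"""Medial-curve fitting, radial thickness, and the discrepancy QC statistic."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from shapestage.errors import ParameterError
from shapestage.medial import MedialCurve, fit_medial_curve, medial_discrepancy, radial_thickness
from shapestage.mesh import SurfaceMesh, build_tube, build_uv_sphere


def test_sphere_centroids_lie_on_a_diameter():
    mesh = build_uv_sphere(20, 24)
    curve = fit_medial_curve(mesh, n_sections=8, smoothing=1.0)
    # section centroids of a sphere are on the central axis
    center = mesh.vertices.mean(axis=0)
    radial = np.linalg.norm(
        np.cross(curve.control_points - center, curve.section_axis), axis=1
    )
    assert radial.max() < 0.01  # < 1% of unit radius


def test_degenerate_curve_gives_unit_thickness_on_unit_sphere():
    mesh = build_uv_sphere(16, 20)
    curve = MedialCurve(np.zeros((1, 3)), None, degenerate=True)
    th = radial_thickness(mesh, curve)
    np.testing.assert_allclose(th, 1.0, atol=1e-9)


def test_cylinder_lateral_thickness_equals_radius():
    tube = build_tube(30.0, 2.0, rings=40, cols=24)
    curve = fit_medial_curve(tube, n_sections=10, smoothing=0.5)
    th = radial_thickness(tube, curve)
    lateral = np.abs(tube.vertices[:, 0]) < 10  # away from the caps
    np.testing.assert_allclose(th[lateral], 2.0, rtol=0.01)


def test_bent_tube_curve_tracks_analytic_centerline():
    bend, radius = 0.02, 1.5
    tube = build_tube(30.0, radius, rings=40, cols=24, bend=bend)
    curve = fit_medial_curve(tube, n_sections=12, smoothing=0.1)
    u = np.linspace(0.05, 0.95, 41)
    pts = curve.evaluate(u)
    # analytic centerline: y = bend * x^2, z = 0
    err = np.hypot(pts[:, 1] - bend * pts[:, 0] ** 2, pts[:, 2])
    assert err.max() < 0.05 * radius


def test_too_many_sections_raises_resolution_error():
    mesh = build_uv_sphere(5, 8)
    with pytest.raises(ParameterError, match="n_sections"):
        fit_medial_curve(mesh, n_sections=30)


def test_interpolating_spline_has_zero_discrepancy():
    tube = build_tube(30.0, 2.0, rings=30, cols=20, bend=0.03)
    curve = fit_medial_curve(tube, n_sections=8, smoothing=0.0)
    assert medial_discrepancy(tube, curve) < 1e-6


def test_sphere_discrepancy_tiny_for_any_smoothing():
    mesh = build_uv_sphere(20, 24)
    for s in (0.0, 1.0, 10.0):
        curve = fit_medial_curve(mesh, n_sections=8, smoothing=s)
        assert medial_discrepancy(mesh, curve) < 1e-6


def test_heavier_smoothing_increases_discrepancy_on_bent_tube():
    tube = build_tube(30.0, 2.0, rings=40, cols=24, bend=0.05)
    light = fit_medial_curve(tube, n_sections=10, smoothing=0.01)
    heavy = fit_medial_curve(tube, n_sections=10, smoothing=50.0)
    assert medial_discrepancy(tube, heavy) > medial_discrepancy(tube, light)


def test_thickness_invariant_under_rigid_motion(rng):
    tube = build_tube(20.0, 1.5, rings=25, cols=18, bend=0.04)
    curve = fit_medial_curve(tube, n_sections=8, smoothing=0.5)
    th = radial_thickness(tube, curve)
    R = Rotation.random(random_state=42).as_matrix()
    t = rng.normal(0, 10, 3)
    moved = SurfaceMesh(tube.vertices @ R.T + t, tube.faces)
    moved_curve = MedialCurve(
        curve.control_points @ R.T + t,
        _transform_tck(curve.tck, R, t),
        section_axis=curve.section_axis @ R.T,
    )
    th2 = radial_thickness(moved, moved_curve)
    np.testing.assert_allclose(th2, th, atol=1e-9)


def _transform_tck(tck, R, t):
    knots, coeffs, k = tck
    c = np.asarray(coeffs)  # (3, m)
    c2 = R @ c + np.asarray(t)[:, None]
    return (knots, [c2[0], c2[1], c2[2]], k)


def test_denser_sampling_never_increases_thickness():
    # pure grid evaluation: the finer uniform grid is a superset
    tube = build_tube(20.0, 1.5, rings=20, cols=16, bend=0.04)
    curve = fit_medial_curve(tube, n_sections=8, smoothing=0.5)
    th_coarse = radial_thickness(tube, curve, n_samples=256, refine=False)
    th_fine = radial_thickness(tube, curve, n_samples=512, refine=False)
    assert (th_fine <= th_coarse + 1e-12).all()


def test_ellipsoid_pole_thickness_matches_bruteforce_oracle():
    mesh = build_uv_sphere(16, 20)
    verts = mesh.vertices * np.array([2.0, 1.0, 1.0])
    ell = SurfaceMesh(verts[:, [2, 0, 1]].copy(), mesh.faces)  # long axis on x? keep default
    ell = SurfaceMesh(verts, mesh.faces)
    curve = fit_medial_curve(ell, n_sections=6, smoothing=0.5)
    th = radial_thickness(ell, curve)
    pole = np.argmax(ell.vertices[:, 0])
    dense = curve.evaluate(np.linspace(0, 1, 100_001))
    oracle = np.linalg.norm(dense - ell.vertices[pole], axis=1).min()
    assert th[pole] == pytest.approx(oracle, abs=1e-6)
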