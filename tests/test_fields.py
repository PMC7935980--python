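import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

from nlmsim.fields import (
    ArrayField,
    ExternalFieldSpec,
    compute_landscape,
    dipole_flux_density,
    prism_flux_density,
)
from nlmsim.geometry import ArraySpec, ShapeSpec, standard_array
from nlmsim.units import MU0, UM


def surface_charge_field(dims, magnetization, pt, n=64):
    """Quadrature oracle: magnetic surface charges ±M on the x-faces."""
    hx, hy, hz = [d / 2 for d in dims]
    yi, wy = leggauss(n)
    zi, wz = leggauss(n)
    Y, Z = np.meshgrid(yi * hy, zi * hz, indexing="ij")
    W = np.outer(wy * hy, wz * hz)
    B = np.zeros(3)
    for sgn, xf in ((+1, hx), (-1, -hx)):
        d = pt - np.stack([np.full_like(Y, xf), Y, Z], axis=-1)
        r = np.linalg.norm(d, axis=-1)
        B += (MU0 / (4 * np.pi)) * sgn * magnetization * np.sum(
            W[..., None] * d / r[..., None] ** 3, axis=(0, 1)
        )
    return B


# -- point dipole ----------------------------------------------------------

def test_dipole_axial_closed_form():
    B = dipole_flux_density(np.array([1e-14, 0, 0]), np.array([1e-6, 0, 0]))
    assert np.allclose(B, [2e-3, 0, 0], rtol=1e-12)


def test_dipole_equatorial_closed_form():
    B = dipole_flux_density(np.array([1e-14, 0, 0]), np.array([0, 1e-6, 0]))
    assert np.allclose(B, [-1e-3, 0, 0], rtol=1e-12)


def test_dipole_matches_vanishing_prism_quadrature():
    # a tiny prism of equal moment approaches the point dipole
    rng = np.random.default_rng(3)
    dims = (2e-8, 2e-8, 2e-8)
    M = 1e-14 / np.prod(dims)  # total moment 1e-14 A·m²
    for _ in range(5):
        pt = rng.uniform(2e-6, 6e-6, 3)
        Bd = dipole_flux_density(np.array([1e-14, 0, 0]), pt)
        Bq = surface_charge_field(dims, M, pt)
        assert np.linalg.norm(Bd - Bq) / np.linalg.norm(Bq) < 1e-3


def test_dipole_zero_displacement_rejected():
    with pytest.raises(ValueError, match="singular"):
        dipole_flux_density(np.array([1e-14, 0, 0]), np.zeros(3))


# -- analytic prism --------------------------------------------------------

def test_prism_matches_surface_charge_oracle():
    rng = np.random.default_rng(11)
    dims = (5e-6, 5e-6, 0.1e-6)
    for _ in range(10):
        pt = rng.uniform(-8e-6, 8e-6, 3)
        if abs(pt[0]) < 3e-6 and abs(pt[1]) < 3e-6 and abs(pt[2]) < 1e-6:
            pt[2] = 2e-6
        Ba = prism_flux_density(dims, 80e3, pt)
        Bq = surface_charge_field(dims, 80e3, pt)
        assert np.linalg.norm(Ba - Bq) / np.linalg.norm(Bq) < 5e-3


def test_prism_far_field_matches_equal_moment_dipole():
    dims = (5e-6, 5e-6, 0.1e-6)
    m = 80e3 * np.prod(dims)
    diag = np.linalg.norm(dims)
    pt = np.array([1.0, 0.7, 0.4])
    pt = pt / np.linalg.norm(pt) * 10 * diag
    Bp = prism_flux_density(dims, 80e3, pt)
    Bd = dipole_flux_density(np.array([m, 0, 0]), pt)
    assert np.linalg.norm(Bp - Bd) / np.linalg.norm(Bd) < 0.01


def test_prism_mirror_symmetry_in_y():
    dims = (5e-6, 5e-6, 0.1e-6)
    B1 = prism_flux_density(dims, 80e3, np.array([1e-6, 2e-6, 2e-6]))
    B2 = prism_flux_density(dims, 80e3, np.array([1e-6, -2e-6, 2e-6]))
    assert B1[0] == pytest.approx(B2[0], rel=1e-12)


def test_prism_interior_point_rejected():
    with pytest.raises(ValueError, match="inside"):
        prism_flux_density((5e-6, 5e-6, 1e-6), 80e3, np.zeros(3))


# -- raster lattice solver -------------------------------------------------

@pytest.fixture(scope="module")
def single_square():
    return ArraySpec(shape=ShapeSpec("square", (5.0,)), n_x=1, n_y=1)


def test_raster_matches_prism_oracle(single_square):
    """Dipole-raster solver vs analytic prism: < 1% at z >= 1 μm, 0.25 μm cells."""
    solver = ArrayField(single_square, cell_size_um=0.25)
    rng = np.random.default_rng(5)
    pts = np.column_stack(
        [rng.uniform(-6, 6, 30), rng.uniform(-6, 6, 30), rng.uniform(1, 5, 30)]
    ) * UM
    Br = solver.stray_field(pts)
    Bp = prism_flux_density(
        (5e-6, 5e-6, 0.1e-6), 80e3, pts, center_m=(0, 0, -0.05e-6)
    )
    rel = np.linalg.norm(Br - Bp, axis=1) / np.linalg.norm(Bp, axis=1)
    assert rel.max() < 0.01


def test_external_superposition_is_exact(single_square, ext):
    solver = ArrayField(single_square)
    pt = np.array([[1e-6, 0.5e-6, 2e-6]])
    total = solver.total_field(pt, ext, theta_deg=-45.0)
    stray = solver.stray_field(pt)
    assert np.allclose(total - stray, ext.vector(-45.0), atol=0)


def test_field_divergence_free(single_square, ext):
    # central-difference divergence on a 3-D stencil
    solver = ArrayField(single_square, cell_size_um=0.25)
    h = 0.05 * UM
    p0 = np.array([1.3e-6, -0.7e-6, 2.1e-6])
    div = 0.0
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = h
        bp = solver.total_field((p0 + e)[None], ext, 0.0)[0][axis]
        bm = solver.total_field((p0 - e)[None], ext, 0.0)[0][axis]
        div += (bp - bm) / (2 * h)
    bmag = np.linalg.norm(solver.total_field(p0[None], ext, 0.0)[0])
    assert abs(div) < 1e-3 * bmag / h


def test_lattice_periodicity_deep_inside(ext):
    arr = standard_array("C", n_x=15, n_y=15)
    solver = ArrayField(arr)
    c = 7 * 8.0
    p1 = np.array([[c * UM, c * UM, 2e-6]])
    p2 = np.array([[(c + 8.0) * UM, c * UM, 2e-6]])
    B1 = solver.stray_field(p1)[0]
    B2 = solver.stray_field(p2)[0]
    assert np.linalg.norm(B1 - B2) / np.linalg.norm(B1) < 0.005


def test_evaluation_below_magnet_plane_rejected(single_square):
    solver = ArrayField(single_square)
    with pytest.raises(ValueError, match="below the magnet plane"):
        solver.stray_field(np.array([[0.0, 0.0, -1e-6]]))


# -- landscapes ------------------------------------------------------------

def test_landscape_periodic_in_phase(ext):
    arr = standard_array("C", n_x=5, n_y=5)
    solver = ArrayField(arr, cell_size_um=0.5)
    cache = {}
    l0 = compute_landscape(arr, ext, 0.0, solver=solver, _stray_cache=cache)
    l360 = compute_landscape(arr, ext, -360.0, solver=solver, _stray_cache=cache)
    assert np.allclose(l0.b_mag, l360.b_mag, rtol=1e-12)


def test_landscape_gradient_consistent_with_b_squared(ext):
    arr = standard_array("C", n_x=5, n_y=5)
    solver = ArrayField(arr, cell_size_um=0.5)
    ls = compute_landscape(arr, ext, -90.0, solver=solver)
    b2 = ls.b_mag**2
    dx = np.gradient(b2, ls.x_um * UM, axis=1)
    inner = (slice(2, -2), slice(2, -2))
    scale = np.abs(ls.grad_b2[..., 0]).max()
    assert np.allclose(ls.grad_b2[inner + (0,)], dx[inner], atol=0.02 * scale)


def test_landscape_resolution_convergence(ext):
    arr = standard_array("C", n_x=5, n_y=5)
    solver = ArrayField(arr, cell_size_um=0.5)
    coarse = compute_landscape(arr, ext, 0.0, grid_step_um=0.2, solver=solver)
    fine = compute_landscape(arr, ext, 0.0, grid_step_um=0.1, solver=solver)
    assert abs(fine.b_mag.max() - coarse.b_mag.max()) / fine.b_mag.max() < 0.01


def test_coarse_grid_warns(ext):
    arr = standard_array("C", n_x=3, n_y=3)
    with pytest.warns(UserWarning, match="grid step"):
        compute_landscape(arr, ext, 0.0, grid_step_um=0.8, solver=ArrayField(arr, cell_size_um=0.5))


def test_external_field_vector_phases():
    ext = ExternalFieldSpec()
    assert np.allclose(ext.vector(0.0), [30e-4, 0, 0])
    assert np.allclose(ext.vector(-90.0), [0, 0, -35e-4], atol=1e-18)
    with pytest.raises(ValueError):
        ExternalFieldSpec(b_x_t=-1.0)
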