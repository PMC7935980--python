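import dataclasses
import math

import numpy as np
import pytest

from nlmsim.dynamics import (
    BeadSpec,
    DimerSpec,
    Stage,
    SeparationResult,
    drag_coefficient,
    design_schedule,
    magnetic_force,
    separation_protocol,
    simulate_transport,
    simulated_characteristics,
    velocity_vs_frequency,
    VelocityProfile,
)
from nlmsim.fields import FieldLandscape
from nlmsim.geometry import standard_array
from nlmsim.particles import Population
from nlmsim.transport import closed_form_velocity
from nlmsim.units import MU0, UM


# -- drag ------------------------------------------------------------------

def test_monomer_stokes_drag():
    gamma = drag_coefficient(BeadSpec(), "translation")
    assert gamma == pytest.approx(6 * math.pi * 1e-3 * 1.4e-6, rel=1e-12)
    assert gamma == pytest.approx(2.639e-8, rel=1e-3)


def test_dimer_drag_is_twice_monomer_at_unit_correction():
    g1 = drag_coefficient(BeadSpec(), "translation")
    g2 = drag_coefficient(DimerSpec(), "translation", c_drag=1.0)
    assert g2 == pytest.approx(2 * g1, rel=1e-12)


def test_drag_linear_in_viscosity():
    g = drag_coefficient(BeadSpec(), "translation", viscosity_pa_s=1e-3)
    g_half = drag_coefficient(BeadSpec(), "translation", viscosity_pa_s=0.5e-3)
    assert g_half == pytest.approx(g / 2, rel=1e-12)


def test_dimer_rotational_drag_two_sphere_estimate():
    r = 1.4e-6
    expected = 28 * math.pi * 1e-3 * r**3
    assert drag_coefficient(DimerSpec(), "rotation") == pytest.approx(expected, rel=1e-12)


# -- magnetic force --------------------------------------------------------

def _uniform_landscape(b=3e-3):
    x = np.linspace(0, 8, 41)
    y = np.linspace(0, 8, 41)
    return FieldLandscape(
        x_um=x, y_um=y, b_mag=np.full((41, 41), b),
        grad_b2=np.zeros((41, 41, 2)), theta_deg=0.0, z_um=2.0,
    )


def test_uniform_field_exerts_no_force():
    F = magnetic_force(BeadSpec(), _uniform_landscape(), np.array([4.0, 4.0]))
    assert np.allclose(F, 0.0)


def test_dimer_force_is_sum_of_bead_forces():
    x = np.linspace(0, 8, 81)
    y = np.linspace(0, 8, 81)
    rng = np.random.default_rng(2)
    grad = rng.normal(0, 1.0, (81, 81, 2))
    ls = FieldLandscape(x, y, np.full((81, 81), 3e-3), grad, 0.0, 2.0)
    dim = DimerSpec()
    F_dim = magnetic_force(dim, ls, np.array([4.0, 4.0]))
    c1, c2 = dim.bead_centers_m(np.array([4.0, 4.0]) * UM) / UM
    F_sum = magnetic_force(dim.bead, ls, c1) + magnetic_force(dim.bead, ls, c2)
    assert np.allclose(F_dim, F_sum, rtol=1e-12)


def test_force_matches_finite_difference_of_energy(ext, tables):
    # F_x = V χ ∂x(|B|²)/(2μ0) against a central difference of |B|² computed
    # independently from the periodic field table
    table = tables("C")
    bead = BeadSpec()
    b_ext = ext.vector(-45.0)
    p = np.array([[2.3e-6, 0.7e-6]])
    F = bead.volume_m3 * table.force_per_volume(p, b_ext, bead.susceptibility)[0]
    h = 5e-9
    for axis in range(2):
        e = np.zeros((1, 2))
        e[0, axis] = h
        b2p = table.b_squared(p + e, b_ext)[0]
        b2m = table.b_squared(p - e, b_ext)[0]
        F_fd = bead.volume_m3 * bead.susceptibility * (b2p - b2m) / (2 * h) / (2 * MU0)
        assert F[axis] == pytest.approx(F_fd, rel=0.01)


def test_force_outside_grid_rejected():
    with pytest.raises(ValueError, match="outside"):
        magnetic_force(BeadSpec(), _uniform_landscape(), np.array([100.0, 0.0]))


# -- trajectories ----------------------------------------------------------

def test_phase_locked_velocity_matches_f_times_d(ext, tables):
    arr = standard_array("C")
    traj = simulate_transport(BeadSpec(), arr, ext, 5.0, table=tables("C"))
    v = traj.mean_velocity_m_s()
    assert v == pytest.approx(5.0 * 8e-6, rel=0.02)


def test_reversed_sense_reverses_velocity(ext, tables):
    arr = standard_array("C")
    rev = dataclasses.replace(ext, sense=-1)
    v_fwd = simulate_transport(BeadSpec(), arr, ext, 5.0, table=tables("C")).mean_velocity_m_s()
    v_rev = simulate_transport(BeadSpec(), arr, rev, 5.0, table=tables("C")).mean_velocity_m_s()
    assert v_rev == pytest.approx(-v_fwd, rel=0.02)


def test_trajectory_determinism(ext, tables):
    arr = standard_array("C")
    t1 = simulate_transport(BeadSpec(), arr, ext, 10.0, table=tables("C"), seed=4)
    t2 = simulate_transport(BeadSpec(), arr, ext, 10.0, table=tables("C"), seed=4)
    assert np.array_equal(t1.position_um, t2.position_um)


def test_high_frequency_immobilizes_bead(ext, tables):
    arr = standard_array("C")
    traj = simulate_transport(BeadSpec(), arr, ext, 300.0, table=tables("C"))
    # far above the critical frequency: oscillation without net transport
    assert abs(traj.mean_velocity_m_s()) < 0.1 * 30.0 * 8e-6
    x = traj.position_um[:, 0]
    assert x.max() - x.min() < 8.0  # never completes a pitch


def test_coarse_time_step_rejected(ext, tables):
    with pytest.raises(ValueError, match="dt"):
        simulate_transport(
            BeadSpec(), standard_array("C"), ext, 10.0, dt_s=1.0, table=tables("C")
        )


def test_dimer_trajectory_records_orientation(ext, tables):
    arr = standard_array("C")
    traj = simulate_transport(DimerSpec(), arr, ext, 5.0, table=tables("C"), n_periods=4)
    assert traj.phi_rad is not None
    assert np.all(np.isfinite(traj.phi_rad))


# -- profiles and characteristics ------------------------------------------

def test_profile_determinism(ext, tables):
    arr = standard_array("C")
    f = np.array([5.0, 20.0])
    p1 = velocity_vs_frequency(BeadSpec(), arr, ext, f, table=tables("C"), record_stride=10)
    p2 = velocity_vs_frequency(BeadSpec(), arr, ext, f, table=tables("C"), record_stride=10)
    assert np.array_equal(p1.mean_velocity_m_s, p2.mean_velocity_m_s)


def test_characteristics_recovered_from_closed_form_profile():
    fc, d = 27.0, 8e-6
    f = np.arange(1.0, 200.0, 1.0)
    prof = VelocityProfile(
        frequencies_hz=f,
        mean_velocity_m_s=closed_form_velocity(f, fc, d),
        std_velocity_m_s=np.zeros_like(f),
        pitch_m=d,
    )
    ch, flags = simulated_characteristics(prof)
    assert flags["f_c_within_sweep"] and flags["f_i_within_sweep"]
    assert ch.f_c_hz == pytest.approx(fc, abs=1.0)
    assert ch.f_i_hz / ch.f_c_hz == pytest.approx(5.05, rel=0.02)


def test_flat_locked_profile_flags_fc_beyond_sweep():
    d = 8e-6
    f = np.arange(1.0, 20.0, 1.0)
    prof = VelocityProfile(f, f * d, np.zeros_like(f), d)
    ch, flags = simulated_characteristics(prof)
    assert not flags["f_c_within_sweep"]
    assert ch.f_c_hz == pytest.approx(19.0)


# -- separation protocol ---------------------------------------------------

def _mixed_population(n_mono, n_dim, array):
    species = ["monomer"] * n_mono + ["dimer"] * n_dim
    pos = np.zeros((n_mono + n_dim, 2))
    pos[:, 1] = array.pitch_y_um
    return Population(species=species, positions_um=pos)


@pytest.fixture(scope="module")
def s_chip(ext):
    array = standard_array("S", n_x=40, n_y=10)
    from nlmsim.dynamics import PeriodicLandscapeTable

    table = PeriodicLandscapeTable(array)
    stages, diag = design_schedule(array, ext, BeadSpec(), DimerSpec(), table=table)
    return array, table, stages, diag


def test_designed_schedule_is_separable(s_chip):
    _, _, stages, diag = s_chip
    assert diag["separable"]
    assert diag["f_c_dimer_hz"] < diag["f_hold_hz"] < diag["f_c_monomer_hz"]
    assert diag["dimer_travel_um"] < diag["monomer_travel_um"]


def test_all_monomer_population_clears(ext, s_chip):
    array, table, stages, _ = s_chip
    pop = _mixed_population(40, 0, array)
    res = separation_protocol(pop, array, ext, stages, seed=1, table=table)
    assert res.f_sb == pytest.approx(0.0)
    assert res.epsilon == pytest.approx(1.0)


def test_dimers_retained_then_reversed(ext, s_chip):
    array, table, stages, _ = s_chip
    pop = _mixed_population(20, 20, array)
    res = separation_protocol(pop, array, ext, stages, seed=1, table=table)
    assert res.f_agg == pytest.approx(0.0)
    assert res.f_sb == pytest.approx(0.0)
    assert all(
        fate == ("cleared" if sp == "monomer" else "retained")
        for fate, sp in zip(res.fates, pop.species)
    )


def test_sticking_probability_sets_expected_f_sb(ext, s_chip):
    array, table, stages, _ = s_chip
    cache: dict = {}
    vals = []
    for seed in range(30):
        pop = _mixed_population(50, 0, array)
        res = separation_protocol(
            pop, array, ext, stages, seed=seed, p_stick=0.05,
            table=table, velocity_cache=cache,
        )
        vals.append(res.f_sb)
    # binomial expectation: E[f_sb] = p_stick; 3σ band for 30×50 trials
    se = math.sqrt(0.05 * 0.95 / (30 * 50))
    assert np.mean(vals) == pytest.approx(0.05, abs=3 * se)


def test_efficiency_arithmetic():
    res = SeparationResult(f_sb=0.05, f_agg=0.02, fates=[], n_monomers=10, n_dimers=10)
    assert res.epsilon == pytest.approx(0.93)


def test_empty_population_rejected(ext, s_chip):
    array, table, stages, _ = s_chip
    with pytest.raises(ValueError, match="empty"):
        separation_protocol(
            Population(species=[], positions_um=np.zeros((0, 2))),
            array, ext, stages, table=table,
        )
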