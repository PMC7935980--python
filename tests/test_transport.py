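import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nlmsim.transport import (
    FrequencyCharacteristics,
    TransportParams,
    calibrate_coupling,
    closed_form_velocity,
    critical_frequency,
    estimate_critical_frequency,
    fit_critical_frequency,
    immobilization_frequency,
    omega_ratio,
    shape_factor,
)


# -- shape factor ----------------------------------------------------------

def test_shape_factor_vanishes_at_small_beta():
    assert shape_factor(1e-9) < 1e-15


def test_shape_factor_maximum_at_one_over_pi():
    # dg/dβ = 0 at 2πβ = 2: g(1/π) = 4 e⁻²
    assert shape_factor(1.0 / math.pi) == pytest.approx(4.0 * math.e**-2, rel=1e-12)
    eps = 1e-4
    assert shape_factor(1.0 / math.pi) > shape_factor(1.0 / math.pi + eps)
    assert shape_factor(1.0 / math.pi) > shape_factor(1.0 / math.pi - eps)


def test_shape_factor_reference_beads():
    # 1.4 μm bead on 8 μm pitch: direct arithmetic
    beta = 1.4 / 8.0
    expected = (2 * math.pi * beta) ** 2 * math.exp(-2 * math.pi * beta)
    assert shape_factor(beta) == pytest.approx(expected, rel=1e-12)
    assert shape_factor(beta) == pytest.approx(0.4023, abs=5e-4)


def test_shape_factor_rejects_nonpositive():
    with pytest.raises(ValueError):
        shape_factor(0.0)


# -- critical frequency and calibration ------------------------------------

def test_zero_coupling_gives_zero_critical_frequency():
    p = TransportParams(coupling_rad_s=0.0)
    assert critical_frequency(p) == 0.0


def test_uncalibrated_coupling_rejected():
    with pytest.raises(ValueError, match="calibrat"):
        critical_frequency(TransportParams())


def test_calibration_round_trip():
    beta = 1.4 / 8.0
    kappa = calibrate_coupling(27.0, beta)
    p = TransportParams(coupling_rad_s=kappa)
    assert p.beta == pytest.approx(beta)
    assert critical_frequency(p) == pytest.approx(27.0, rel=1e-12)


def test_calibration_linearity():
    beta = 0.2
    assert calibrate_coupling(54.0, beta) == pytest.approx(
        2 * calibrate_coupling(27.0, beta), rel=1e-12
    )


def test_species_specific_coupling_differs():
    # monomer vs dimer measured critical frequencies on the same chip give
    # species-specific couplings
    beta = 1.4 / 8.0
    k_mono = calibrate_coupling(27.0, beta)
    k_dim = calibrate_coupling(22.5, beta)
    assert k_dim < k_mono


def test_critical_frequency_maximal_at_beta_one_over_pi():
    kappa = 100.0
    fcs = [
        critical_frequency(
            TransportParams(bead_radius_m=b * 8e-6, pitch_m=8e-6, coupling_rad_s=kappa)
        )
        for b in (0.1, 1 / math.pi, 0.45)
    ]
    assert fcs[1] == max(fcs)


def test_beta_out_of_range_rejected():
    with pytest.raises(ValueError, match="beta"):
        TransportParams(bead_radius_m=5e-6, pitch_m=8e-6)


# -- closed-form velocity --------------------------------------------------

def test_phase_locked_velocity_product():
    # 10 Hz on 8 μm pitch, below f_c = 27: 80 μm/s
    assert closed_form_velocity(10.0, 27.0, 8e-6) == pytest.approx(80e-6, rel=1e-12)


def test_velocity_continuous_at_critical_frequency():
    fc, d = 27.0, 8e-6
    v_locked = fc * d
    v_below = closed_form_velocity(fc - 1e-9, fc, d)
    v_above = closed_form_velocity(fc + 1e-9, fc, d)
    assert v_below == pytest.approx(v_locked, rel=1e-6)
    assert v_above == pytest.approx(v_locked, rel=1e-4)


def test_velocity_at_twice_critical():
    fc, d = 27.0, 8e-6
    assert closed_form_velocity(2 * fc, fc, d) == pytest.approx(
        (2 - math.sqrt(3)) * fc * d, rel=1e-12
    )


def test_velocity_rejects_negative_frequency():
    with pytest.raises(ValueError):
        closed_form_velocity(-1.0, 27.0, 8e-6)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    fc=st.floats(1.0, 100.0),
    f1=st.floats(0.0, 500.0),
    f2=st.floats(0.0, 500.0),
)
def test_velocity_nonincreasing_above_critical(fc, f1, f2):
    lo, hi = sorted((max(f1, fc), max(f2, fc)))
    d = 8e-6
    assert closed_form_velocity(lo, fc, d) >= closed_form_velocity(hi, fc, d) - 1e-18


def test_velocity_vanishes_at_high_frequency():
    assert closed_form_velocity(1e6, 27.0, 8e-6) < 1e-2 * 27.0 * 8e-6


# -- immobilization frequency ----------------------------------------------

def test_immobilization_of_exact_closed_form_is_5_05():
    # solve f − sqrt(f² − f_c²) = 0.1 f_c: f = 5.05 f_c
    fc, d = 27.0, 8e-6
    f = np.linspace(0.5, 200.0, 4000)
    v = closed_form_velocity(f, fc, d)
    fi, crossed = immobilization_frequency(f, v)
    assert crossed
    assert fi / fc == pytest.approx(5.05, rel=1e-3)


def test_immobilization_fraction_one_returns_argmax():
    f = np.array([1.0, 2.0, 3.0, 4.0])
    v = np.array([1.0, 3.0, 2.0, 1.0])
    fi, crossed = immobilization_frequency(f, v, fraction=1.0)
    assert crossed and fi == 2.0


def test_immobilization_linear_interpolation():
    # synthetic monotone profile crossing 10% of max between samples
    f = np.array([1.0, 2.0, 3.0])
    v = np.array([1.0, 0.2, 0.05])
    fi, crossed = immobilization_frequency(f, v)
    # threshold 0.1 crossed between 2 and 3: t = (0.2-0.1)/(0.2-0.05)
    assert crossed and fi == pytest.approx(2.0 + 0.1 / 0.15, rel=1e-12)


def test_immobilization_never_crossing_flagged():
    f = np.array([1.0, 2.0, 3.0])
    v = np.array([1.0, 0.9, 0.8])
    fi, crossed = immobilization_frequency(f, v)
    assert not crossed and fi == 3.0


# -- omega ratio -----------------------------------------------------------

@pytest.mark.parametrize(
    "fc, fi, expected",
    [(22.5, 30.0, 0.75), (16.5, 25.0, 0.66), (27.0, 27.0, 1.0)],
)
def test_omega_ratio_worked_examples(fc, fi, expected):
    assert omega_ratio(fc, fi) == pytest.approx(expected, rel=1e-9)


def test_omega_ratio_rejects_inverted_characteristics():
    with pytest.raises(ValueError, match="inconsistent"):
        omega_ratio(30.0, 22.5)


def test_characteristics_invariants():
    ch = FrequencyCharacteristics(f_c_hz=27.0, f_i_hz=40.0)
    assert 0.0 < ch.omega <= 1.0


# -- estimation from profiles ----------------------------------------------

def test_divergence_estimator_recovers_fc_from_exact_profile():
    fc, d = 27.0, 8e-6
    f = np.arange(1.0, 60.0, 0.5)
    v = closed_form_velocity(f, fc, d)
    est, crossed = estimate_critical_frequency(f, v, d)
    assert crossed
    # the 95% rule fires just above the knee: within one grid step + bias
    assert est == pytest.approx(fc, abs=1.0)


def test_fit_recovers_fc_from_noisy_profile():
    fc, d = 27.0, 8e-6
    f = np.arange(1.0, 60.0, 1.0)
    rng = np.random.default_rng(0)
    v = closed_form_velocity(f, fc, d) * (1 + 0.05 * rng.standard_normal(f.size))
    est = fit_critical_frequency(f, v, d)
    assert est == pytest.approx(fc, rel=0.05)
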