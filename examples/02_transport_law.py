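"""The closed-form transport law: critical frequency, velocity, sharpness.

A bead on the array moves one pitch d per field rotation (v = f·d) until
the critical frequency f_c, where viscous drag overcomes the magnetic
restoring force; above f_c it slips periodically and the mean velocity
falls as v = [f − sqrt(f² − f_c²)]·d.  The geometry enters through
g(β) = (2πβ)²·exp(−2πβ) with β = r/d, and the remaining physics is bundled
in a coupling κ calibrated here from a measured critical frequency of
27 Hz (2.8 μm beads on the 8 μm-pitch circular array).
"""

import numpy as np

from nlmsim import (
    TransportParams,
    calibrate_coupling,
    closed_form_velocity,
    critical_frequency,
    immobilization_frequency,
    omega_ratio,
    shape_factor,
)

beta = 1.4 / 8.0  # 1.4 um bead radius on 8 um pitch
kappa = calibrate_coupling(27.0, beta)
params = TransportParams(coupling_rad_s=kappa)
print(f"beta = r/d = {beta:.4f},  g(beta) = {shape_factor(beta):.4f}")
print(f"calibrated coupling kappa = {kappa:.1f} rad/s")
print(f"critical frequency from the law: {critical_frequency(params):.2f} Hz")

d = 8e-6
print("\n f (Hz)   v (um/s)   regime")
for f in (10.0, 27.0, 40.0, 54.0):
    v = closed_form_velocity(f, 27.0, d)
    print(f"{f:7.1f} {v / 1e-6:10.1f}   {'phase-locked' if f <= 27 else 'phase-slipping'}")

f = np.linspace(0.5, 250.0, 5000)
fi, _ = immobilization_frequency(f, closed_form_velocity(f, 27.0, d))
print(f"\nimmobilization frequency (10% of max rule): {fi:.1f} Hz = {fi / 27:.2f} f_c")

print("\nSharpness ratio Omega = f_c/f_i from the chip's measured dimer frequencies:")
for name, fc, fi_meas in (
    ("circle", 22.5, 30.0), ("square", 23.5, 30.0),
    ("triangle", 16.5, 25.0), ("rectangle", 30.5, 40.0),
):
    print(f"  {name:10s} Omega = {omega_ratio(fc, fi_meas):.2f}")
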