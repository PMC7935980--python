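# nlmsim

A simulator and analysis toolkit for **nonlinear magnetophoresis (NLM)** —
the transport and separation of superparamagnetic (SPM) beads on chips
patterned with micromagnet arrays and driven by a rotating external
magnetic field. It is written for people designing or modelling such
lab-on-chip devices: it predicts the flux-density landscape a given magnet
geometry produces, how bead monomers and analyte-linked bead dimers move on
it, at which drive frequencies each species stalls, and how well a chip
separates the two — the readout underlying magnetic bead-assembly (MBA)
agglutination assays.

## The model

A rectilinear lattice (pitch *d*) of thin-film micromagnets (circle, square,
equilateral triangle or rectangle footprints; Co layer magnetized along +x)
is overlaid with a uniform field rotating in the *xz*-plane,
**B**ₑₓₜ(θ) = (Bₓ cos θ, 0, B_z sin θ). The total flux-density magnitude on
the bead-center plane forms maxima that advance one pitch in +x per field
rotation. An unsaturated SPM bead of volume *V* and effective volume
susceptibility χ feels

  **F** = V χ ∇|**B**|² / (2μ₀),

and moves inertialessly against Stokes drag γ = 6πηr. Below a critical
drive frequency the bead rides the travelling maximum ("phase-locked",
v = f·d); above it the drag exceeds the peak restoring force and the mean
velocity falls as

  v(f) = [f − √(f² − f_c²)]·d,  with  f_c = κ·(2πβ)² e^(−2πβ) / 2π,  β = r/d,

where κ = χμ₀σ₀(Hₑₓₜ)/(18η) bundles the experimentally calibrated field
parameter σ₀. The package implements both this closed form (with κ
calibration from one measured f_c) and a trajectory-level simulator: the
magnet array is rasterized into dipole cells (validated against the exact
closed-form field of a uniformly magnetized prism), its static stray field
is tabulated on a periodic lattice unit cell, and monomers or rigid
two-bead dimers are integrated on the travelling landscape. Dimers
straddling a small magnet overhang its edge, sample weaker field contrast,
and therefore slip at lower frequency than monomers — the geometric
mechanism that makes monomer/dimer separation possible on circle, square
and triangle arrays but not on tall rectangles. A counting-statistics layer
(binomial aggregate fractions with Wilson intervals, dose–response tables,
separation-efficiency summaries ε = 1 − f_sb − f_agg) covers the assay end.

## Worked example

`examples/03_simulated_critical_frequencies.py` simulates the critical
frequency of monomers and dimers on all four reference geometries (5 μm
magnets, 8 μm pitch, 2.8 μm beads, 30/35 G drive) and applies a single
calibration on the circle-array monomers:

```
geometry   monomer f_c (Hz)   dimer f_c (Hz)   gap (Hz)   [calibrated]
   C            27.0              24.5          2.5
   S            24.1              21.2          2.9
   T            20.1              14.6          5.4
   R            28.4              28.4          0.0
```

Triangles (smallest magnet volume, weakest field) stall earliest;
rectangles (largest) latest. The monomer–dimer gap is widest on the
triangle and vanishes on the rectangle, so C/S/T chips can separate the
species while R cannot — at the cost of R's faster transport. The other
examples print the travelling landscape maximum (one 8 μm pitch per
rotation), the closed-form law (immobilization at 5.05 f_c under the
10%-of-maximum rule, sharpness ratios Ω = f_c/f_i of 0.66–0.78 for dimers),
and a full separation run on a synthetic 30%-dimer population, which
recovers the generating fraction inside its Wilson interval with
ε ≈ 0.96 at 5% nonspecific monomer sticking.

A thin CLI mirrors the library (`nlmsim landscape|profile|simulate|
characteristics|separate|assay-stats`, YAML config via `--config`); outputs
embed seed and config hash.

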