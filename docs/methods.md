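# Methods

This note documents the physical model, numerical choices and limitations
of `nlmsim`, in the spirit of the model documentation of simulation
packages of this kind.

## Geometry and coordinates

Right-handed coordinates: x is the transport direction and the
magnetization axis, z the chip normal, z = 0 at the top surface of the
magnetic layer. The spin-on-glass planarization occupies z ∈ [0, 600 nm];
beads roll on the glass, so their centers sit at z = glass + r = 2.0 μm
for the default 2.8 μm beads. All computation is SI; interfaces take μm,
nm and gauss (1 G = 10⁻⁴ T).

Reference chips: circle (5 μm diameter), square (5 μm side), equilateral
triangle (5 μm side) and rectangle (5 × 12.5 μm) footprints of 100 nm Co,
magnetized uniformly at 80 kA/m along +x, on an 8 μm pitch lattice
(8 × 16 μm for the rectangle). The 80 kA/m figure is treated as the
authoritative effective magnetization input (it is well below Co
saturation and presumably encodes an effective remanence); it is exposed
in `ArraySpec`. The triangle's orientation is not fixed by the lattice
symmetry, so it is explicit: one side parallel to y, apex toward +x by
default (`triangle_apex_sign` flips it). Chromium adhesion/capping layers
are magnetically ignored.

## Magnetostatics

The magnetic layer is thin (100 nm) compared with the evaluation height
(≈2 μm), so each magnet is modelled as a single dipole layer at
mid-thickness (50 nm below z = 0). Footprints are rasterized into square
cells; each cell's volume is weighted by its fractional footprint coverage
(4 × 4 subsampling), which keeps the total rasterized moment within ~0.1%
of M·A·t for all four shapes and makes the solver shape-agnostic.
Lattice sums include every magnet within 5 lattice periods of the
evaluation region (fields decay at least as r⁻³; truncation error <0.5%);
magnets beyond 2 periods are collapsed to single equivalent dipoles of the
exact analytic moment (quadrupole-order error <1% at that distance), the
rest carry the full raster.

Accuracy is validated against the exact closed form for a uniformly
magnetized rectangular prism (log/arctan surface-charge solution,
implemented for z-magnetization and cyclically permuted to x), which is
itself cross-checked in the tests against Gauss–Legendre surface-charge
quadrature (agreement ~10⁻¹²). At 0.25 μm cells the raster solver matches
the prism oracle to better than 1% everywhere at z ≥ 1 μm (measured
maximum ≈0.2%). Dynamics tables use 0.5 μm cells: the dipole-spacing error
at 2 μm height is ≈0.5%, well below the other model uncertainties, at an
8-fold cost saving.

The external drive is uniform, elliptical in the xz-plane,
(Bₓ cos θ, 0, B_z sin θ) with defaults Bₓ = 3.0 mT (30 G), B_z = 3.5 mT
(35 G); θ advances by −360° per period for +x transport. No
self-consistent micromagnetics, hysteresis or eddy currents.

## Landscapes and their analysis

`compute_landscape` samples |B| and ∇|B|² on a rectangular grid at fixed
height; the array stray field is phase-independent and cached, so phase
sweeps cost one lattice sum. Gradients are central differences of |B|² on
the grid (the default 0.1 μm step resolves the ~1 μm feature scale; a
>0.5 μm step triggers a warning). Maxima are strict 8-neighbourhood
dominators with quadratic sub-grid refinement, excluding the window
border; a uniform landscape yields none (flatness tolerance 10⁻⁶
relative). Tracking associates peaks across phases by nearest neighbour
with a +x preference on ties and a maximum jump of d/2 per 30° of phase;
the tracking window spans ±2.5 pitches so the destination peak stays
interior after a full rotation.

Line profiles follow the construction used when reading flux maps: line
*a* along the monomer trajectory's y-center, line *b* along the
dimer-center trajectory (identical for a centred dimer; both retained),
line *c* offset +1.1 μm in y from *b*, through the outer half of a dimer's
second bead. Contrast is (max − min)/max over the sampled span — an
explicit metric chosen here because figure-derived magnitude comparisons
carry no stated metric. The asymmetry index is the L1 distance between a
profile and its periodic mirror about its peak, normalized by their
combined mass: 0 for even profiles, scale-invariant.

The dimer-overhang fraction integrates, per bead, the spherical column
volume 2√(r² − ρ²) over the part of the projected disk outside the magnet
footprint, on a 400 × 800 polar midpoint grid; a 1.2 × 10⁷-sample
Monte-Carlo volume integration (frozen in the tests) agrees to <0.1
percentage point. For the centred y-aligned dimer on the 5 μm circle the
fraction is 4.4% — the "few percent overhang" regime in which the dimer's
outer volume samples visibly weaker field contrast.

## Closed-form transport law

User-facing frequencies are cyclic (Hz) throughout — reported chip
characteristics (tens of Hz, 1–60 Hz sweeps) are cyclic — and the law is
implemented so that phase-locked velocity is v = f·d exactly:
f_c = κ·g(β)/2π with g(β) = (2πβ)²e^(−2πβ) and κ (rad/s) absorbing
χμ₀σ₀/(18η). σ₀ and χ are never needed separately: κ is identifiable from
a single measured f_c (`calibrate_coupling`, exact round trip). g peaks at
β = 1/π (g = 4e⁻²); the reference beads sit at β = 1.4/8 = 0.175,
g = 0.403. Above f_c, v = [f − √(f² − f_c²)]·d, continuous at the knee and
→ 0 as f → ∞. Under the operational 10%-of-maximum immobilization rule
this law gives f_i = 5.05·f_c exactly (0.2u = 1.01 with u = f_i/f_c).

Estimators for sampled profiles: f_c is the first frequency where mean
velocity drops below 95% of f·d ("onset of divergence" made operational;
threshold configurable), linearly interpolated; f_i is the interpolated
10%-of-maximum crossing, returning the sweep end with a flag when never
crossed. For noisy profiles a least-squares fit of the closed form
(`fit_critical_frequency`) is the recommended estimator: with 5%
multiplicative noise a threshold rule false-triggers early (≈16% chance
per pre-knee sample) whereas the fit recovers f_c to ~1%.

## Trajectory simulation

Overdamped (inertialess) dynamics — Reynolds and Stokes numbers are ≪1 at
these scales — with the vertical degree of freedom frozen at the
bead-center plane, matching the 2-D landscape analysis. Force
F = Vχ∇|B|²/(2μ₀) per bead (linear magnetization; the induced moment stays
~4× below the saturation cap of the default beads at these fields). Drag:
6πηr per bead, η = 1.0 mPa·s (aqueous buffer at room temperature; the
default is ours to set). Dimers are rigid touching pairs translating under
the summed per-bead forces with γ = 2·6πηr·c_drag and rotating in-plane
under their torque with the two-sphere rigid-rotor drag 28πηr³; c_drag
defaults to 1.0 (independent spheres — substrate-hydrodynamic wall
corrections exist in the literature but are deliberately out of scope, and
c_drag is the hook for them). Thermal noise is available but off by
default: the transport model is deterministic.

Integration: fixed-step explicit midpoint, dt = period/200, with a
stability guard aborting on any step larger than a quarter pitch. Because
the array field is static, the solver precomputes B_array and its in-plane
derivatives on one periodic lattice unit cell (0.1 μm grid, bilinear
lookup); a force evaluation is then a 9-channel table gather plus the
phase-dependent uniform field, making a full frequency sweep cheap. Beads
start at the landscape maximum of the initial phase; velocities are
averaged after a transient of ≥2 periods. Critical frequencies are found
by bisection on the phase-locked test (mean v ≥ 95% f·d over 10 periods)
to 1% relative tolerance.

With the default χ = 0.7 (typical effective susceptibility for 2.8 μm
streptavidin beads; calibratable) the simulated circle-array monomer f_c
is ≈30 Hz, within ~10% of the measured 27 Hz with no tuning. Since force
and hence f_c scale linearly in χ, a single calibration on circle-array
monomers rescales all geometries and species identically; only
calibrated ratios and orderings are treated as predictions. The simulated
orderings reproduce the measured mechanism: dimer f_c < monomer f_c on
C/S/T, near-zero gap on R (smallest of the four), monomer ordering
T < S ≈ C < R. Simulated C and S monomer f_c differ by ~12% (measured:
indistinguishable); the ≈ in the ordering assertion allows 15%.

The simulated velocity decay above f_c follows the closed-form law's slow
tail (Ω ≈ 0.2 under the 10% rule), whereas measured beads stop much more
sharply (Ω ≈ 0.5–0.8); the deterministic 2-D model omits the surface
interactions and out-of-plane effects responsible. Measured absolute f_i
values are therefore not reproduced — Ω worked examples use the measured
frequency pairs as inputs. One known inconsistency in those inputs: the
triangle-array monomer pair (21.5, 25) gives Ω = 0.86, not the 0.61
quoted alongside it; the package always reports the computed ratio.
Similarly the quoted dimer ratios "77%" (C/R) and "68%" (T/S) do not match
the quoted dimer frequencies (22.5/30.5 = 74%, 16.5/23.5 = 70%) and are
not used as targets.

## Separation protocol and assay statistics

`design_schedule` measures both species' f_c on the chip, gathers at
0.3·f_c(dimer), holds at f_c(dimer) + 0.8·[f_c(monomer) − f_c(dimer)]
(capped at 0.97·f_c(monomer)) — monomers stay phase-locked, dimers slip to
roughly half speed — for long enough (safety factor 1.3) that every
monomer clears the +x edge while dimers fall short, then reverses the
rotation sense to transport retained dimers back in −x. Because the
dynamics are deterministic, all particles of a species share one
representative simulated velocity per stage; fates are per-particle
kinematics plus seeded Bernoulli nonspecific effects: monomer sticking
(immobilization at protocol start, probability p_stick) and dimer loss
(p_loss_agg), the loss modes observed in practice. Efficiency is
ε = 1 − f_sb − f_agg with f_sb the fraction of monomers wrongly retained
and f_agg the fraction of dimers wrongly lost.

The synthetic-population generator draws species i.i.d. Bernoulli(dimer
fraction), places particles on magnet centers of the first two lattice
columns, and flags stuck monomers at generation time; identical seeds give
identical populations. The protocol's own random draws are decorrelated
from the generator's by construction (a derived seed sequence), so using
the same seed for both does not couple sticking to species. What the
generator does **not** emulate: higher-order clumps (unpredictable
out-of-plane motion; excluded from the model's scope), bead size
dispersion (3% CV in reality), aggregation kinetics or analyte chemistry —
dose–response handling is purely descriptive, and passing end-to-end tests
demonstrates the separation/counting pipeline, not assay chemistry.

Aggregate fractions are reported with Wilson 95% intervals
(statsmodels); dose–response tables impose no monotonicity (the hook
effect — signal suppression at high analyte concentration by binding-site
saturation — is a first-class shape); method comparison reports
per-condition percentage-point differences with Newcombe intervals and
score tests when raw counts are present. The bundled reference
dose–response CSV stores published point estimates with their printed ±
values verbatim as metadata (their type — SD, SEM or range — is unstated
and not reinterpreted).

## Problem sizes and defaults used in tests and the acceptance script

Landscape work uses 11 × 11 lattices with 0.5 μm raster cells and 0.1 μm
grids; dynamics use 10–12 drive periods per frequency probe and 1%
bisection tolerance; recovery studies use 100 seeded replicates of a
1–60 Hz sweep; coverage studies use 50 seeded populations of 100 particles
on a 40 × 10 square-magnet chip; the overhang quadrature uses a 400 × 800
polar grid. These sizes were chosen as the smallest at which the reported
quantities are stable to well within their assertion tolerances.

## Known limitations

No substrate hydrodynamics (wall-corrected drag), no bead–bead dipolar
interactions during transport, no vertical dynamics or out-of-plane dimer
rotation, no saturation of the bead moment, no FEM-grade near-field
accuracy inside the glass, and no chemistry. The simulator's velocity
decay above f_c is slower than measured; treat simulated f_i and Ω as
model quantities, not predictions of measured ones.
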