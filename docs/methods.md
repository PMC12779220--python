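# Methods

This note records the modelling assumptions, numerical choices and known
limitations behind `oxygel`, in the spirit of a model-description
appendix.

## Units and constants

All internal computation is SI (m, s, mol·m⁻³).  Diffusion coefficients
are accepted and reported in cm²·s⁻¹ at the API boundary because that is
how the field quotes them; lengths in mm.  Oxygen levels convert among
% air saturation, mmHg and mol·m⁻³ through a Henry-law solubility at the
37 °C set point.  The default solubility, 1.2×10⁻³ mol·m⁻³·mmHg⁻¹, is
chosen so that 25 mmHg corresponds to 0.03 mol·m⁻³, the working
correspondence for these systems; published 37 °C values span roughly
1.2–1.35×10⁻³ and the constant is configurable.  "% air saturation" is
defined against the dry-air O₂ fraction 0.2095 (standard optode
calibration), which is distinct from the incubator gas-mix fraction
(18.6% O₂ by default) used to compute the ambient dissolved
concentration; the ambient partial pressure assumes a humidified
atmosphere (total pressure minus 47 mmHg water vapor; set the vapor
pressure to 0 for dry gas).  Temperature-dependent solubility or
diffusivity correlations and salinity corrections are out of scope — the
package models a single 37 °C set point.

Default constants: D_water(37 °C) = 3.1×10⁻⁵ cm²·s⁻¹;
D_tissue = 1.24×10⁻⁵ cm²·s⁻¹; OCR(MIN6) = 0.129 mol·m⁻³·s⁻¹;
OCR(islet) = 0.034 mol·m⁻³·s⁻¹; critical pO₂ = 0.1 mmHg
(≈1.2×10⁻⁴ mol·m⁻³, effectively zero in the dimensionless formulas);
boundary dead time θ = 3 s and time constant τ = 23 s; default cell
volume 1.7 pL (a typical beta-cell scale) for converting cells·mL⁻¹ to
volume fraction — this conversion is a genuine free parameter of the
analysis and is always echoed in outputs.

## Transient solver

Geometry: z = 0 at the glass dish bottom, increasing upward; the probe
height is measured from the bottom (default 1.8 mm, the measured offset
of the sensing spot from the needle tip resting on the glass).  Two
presets mirror the measurement configurations: a single 4 mm liquid
layer, and 3.5 mm of gel under 1.5 mm of medium (medium at the water
diffusivity).  The liquid preset uses 4 mm as both the column height and
the Péclet length scale, while the slab analyses use the 3.5 mm gel
height as the reaction-diffusion length; both conventions are kept as
given rather than reconciled.

Discretization: vertex-centred finite volumes, uniform spacing within
each layer (default 20 µm) with a node pinned on the interface, so each
edge lies in one material and interface flux continuity holds by
construction (harmonic-mean transmissibility arises naturally; the
partition coefficient across the interface is fixed at 1).  Time
stepping is Crank–Nicolson (default 0.5 s), unconditionally stable over
1–2 h horizons.  The first four steps of every run use backward Euler
(Rannacher smoothing): a discontinuous ideal-step boundary otherwise
excites the undamped CN oscillation modes — at 10 µm spacing this
produced undershoots of −0.2·C0 before smoothing, and below the 10⁻⁶·C0
contract after.  Round-off negatives are clamped to zero; a clamp beyond
10⁻⁹·C0 triggers a warning.  At the default resolution the probe-height
solution changes by far less than 0.2% of C0 under a 2× grid/step
refinement, and matches the cosine-series single-layer solution within
0.5% of C0 for Fourier numbers above 0.005.

Time zero is the instant the gas step is applied at the inlet; the
boundary dead time is part of the FOPDT driver, never a shift applied to
data.  The solver optionally takes a masked zero-order sink (consumption
k_v wherever C exceeds C_crit, treated explicitly with a floor at
C_crit), used to verify that its long-time limit reproduces the steady
reaction–diffusion profile.  Advection, 2D/axisymmetric effects, moving
meshes and gel swelling are not modelled; the Péclet helper exists to
check (given a measured or simulated surface velocity) that the
measurement regime justifies the pure-diffusion assumption.  Stiff gels
can show an initial response delay relative to the 1D model (radial
effects); no correction is attempted.

## Diffusion-coefficient fitting

The objective is the mean absolute percent error between the modelled
and observed probe traces on a shared time grid, both normalized to the
observed initial concentration — normalization makes the fit invariant
to the logging unit, and which of normalized/absolute the percent error
is taken on is otherwise a free convention here.  Raw MAPE diverges as
readings approach zero during the purge, so (a) the fit window runs from
the step onset until the observed trace first drops below 1% of its
initial value, and (b) the denominator is floored at 2% of the initial
value.  Both fractions are configurable.

The optimizer is a deterministic bounded scalar minimization over
log₁₀(D) (golden-section/parabolic), default bounds 10⁻⁶–10⁻⁴ cm²·s⁻¹,
relative tolerance 10⁻³.  A result at a bound clears the `converged`
flag instead of failing silently.  When fitting the gel layer of a
two-layer stack the medium layer is held at the water diffusivity; joint
multi-parameter fitting (θ, τ and D together) is deliberately excluded.
The noise-free MAPE landscape is unimodal across the bounds (checked on
a log grid), so the scalar search is safe.  Replicate summaries use the
sample SD (n−1); with a single replicate the SD is reported as NaN.

## Steady zero-order reaction–diffusion

Depth x runs downward from the gel surface (x = 0 at the top), the
natural frame for penetration depths; the explicit flip to the transient
solver's z coordinate is tested.  Cells below the critical concentration
stop consuming (masked consumption), the classical zero-order obstacle
problem; the alternative — consumption to exhaustion — admits negative
concentrations and is rejected.  The closed-form profile is parabolic in
the viable zone with smooth pasting (value C_crit, zero slope) at the
front.  The default C_crit is the 0.1 mmHg equivalent; whether the
tabulated effectiveness factors used exactly zero or this threshold is
indistinguishable at two decimals, and both choices reproduce them.

The surface concentration under a top-up medium solves
C_s = C_amb − k_v·min(x_v(C_s), L)·h_med/D_med: the steady linear flux
across the quiescent medium balances the areal consumption of the viable
zone.  This 1D flux balance is this package's reconstruction of the
surface-tension/cell-fraction coupling (the tabulated Thiele ratios
between cell densities equal sqrt(10/1.2) to <0.5%, implying the
coupling's effect there was negligible, so the reconstruction is not
contradicted by the tabulated values); lateral losses are ignored.
Because the consumption is capped by the viable depth, the balance
always admits a solution above C_crit whenever the ambient concentration
exceeds C_crit — the "oxygen-starved" status therefore only arises when
the ambient level itself is at or below critical.  The root is found by
bracketed bisection/Brent iteration to 10⁻⁸ relative tolerance.  A
`couple_surface` flag switches between this coupling and a user-supplied
C_s.

Effectiveness-factor values are truncated — not rounded — to two
decimals when matching tabulated values, since that is the convention
the tabulation follows (rounding disagrees in two of six cells); full
precision is always available programmatically.  Michaelis–Menten
kinetics, sphere/cylinder geometries, 2D oxygen maps and time-dependent
death kinetics are out of scope.

## Synthetic data

The generator runs the forward solver at known parameters, samples the
probe height, and adds independent zero-mean Gaussian noise with SD a
fraction of the initial concentration (default 1% — an assumption, as
real optode noise is not characterized here; exposed as a parameter).
Seeds are mandatory and embedded in the trace metadata with the full
ground truth; identical spec and seed reproduce traces bit-identically.
What the noise model omits — drift, autocorrelation, probe response lag,
photobleaching, temperature fluctuation — bounds what passing recovery
tests demonstrate: they validate the inverse machinery under ideal read
noise, not robustness to structured experimental artifacts.  The
two-layer fixtures use placeholder gel diffusivities (1.5 and
1.0×10⁻⁵ cm²·s⁻¹, plausible for calcium-alginate) to exercise the
two-layer path; they are not measured material values.

## Problem sizes in the test suite

Fast property tests generate and fit traces at 0.05–0.1 mm spacing, 2 s
steps and 30 s sampling over 1 h — settings under which the solver is
still well within its convergence contract — while the recovery
acceptance tests use the default 20 µm/0.5 s resolution with 10 s
sampling over 1 h, and 20 noise seeds for the noisy-recovery average.
The steady-front cross-check sweeps 27 parameter combinations against a
pseudo-time finite-difference relaxation on a 351-node grid.  These
sizes were chosen to exercise every regime (front present/absent, one
and two layers, noise on/off) at comfortable runtimes.

## Known limitations

* Water-validation and gel measurements from the physical rig cannot be
  reproduced without the raw traces; parameter-recovery tests on
  synthetic data take their place.
* The headspace flow field is not simulated; the Péclet number takes the
  surface velocity as an input.
* The cells-to-volume-fraction conversion and the gel diffusivities for
  specific commercial alginates must be supplied by the user; design
  outputs echo all three so results are traceable.
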