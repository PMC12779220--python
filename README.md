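# oxygel

Oxygen transport modelling for cell-laden hydrogels: estimate oxygen
diffusion coefficients from low-cost probe measurements, and turn them
into viability predictions and encapsulation-device sizing rules.

## Who this is for

Labs that immobilize mammalian cells in hydrogels — alginate-encapsulated
pancreatic beta cells being the motivating case — need the oxygen
diffusion coefficient *D* of their actual material, not a literature
guess: small differences in gel formulation change *D* enough to move a
device from fully viable to hypoxic at its core.  A simple measurement
rig (a sealed Petri dish with a gas-controlled headspace and a needle
optode) produces oxygen-depletion traces during a nitrogen purge; this
package provides the modelling half of that platform.

## The models

**Forward transient model.**  In the sealed dish, transport is 1D along
the vertical axis.  Each layer (gel and/or overlaid medium) obeys Fick's
second law,

    ∂C/∂t = D ∂²C/∂z²,

with zero flux at the glass bottom (z = 0), concentration and flux
continuity at the gel/medium interface, and a gas-controlled top surface.
The surface follows either an ideal step or a measured
first-order-plus-dead-time (FOPDT) response to the inlet gas switch
(dead time θ = 3 s, time constant τ = 23 s by default); that boundary
settles to 1% of its initial value in under two minutes, negligible
against 1–2 h experiments.  The solver is Crank–Nicolson on a
finite-volume grid and is verified against the closed-form cosine-series
solution of the single-layer step problem.

**Inverse fit.**  *D* of the unknown layer is recovered by minimizing the
mean absolute percent error (MAPE) between the modelled and observed
probe trace, both normalized to the initial concentration, using a
bounded deterministic scalar search.  Noise-free synthetic traces refit
to within 1% of the generating *D*.

**Viability and design.**  Cells consume oxygen at a zero-order
volumetric rate k_v = X·OCR (X the cell volume fraction), valid because
concentrations stay far above the Michaelis–Menten constant.  With
surface concentration C_s and effective diffusivity
D_eff = X·D_tissue + (1 − X)·D_gel, oxygen penetrates to

    x_v = sqrt(2 · D_eff · (C_s − C_crit) / k_v),

below which cells fall under the critical concentration C_crit and die —
a sharp live/dead front.  Two dimensionless groups summarize the design
space: the Thiele modulus φ = L·sqrt(k_v/(D_eff·C_s)) and the
effectiveness factor

    η = 1                     for φ ≤ φ_crit = sqrt(2(1 − C_crit/C_s)),
    η = φ_crit / φ            otherwise,

which equals the viable fraction x_v/L of the slab.  Inverting these
gives the maximum slab thickness supporting a target effectiveness at a
given cell loading, optionally with C_s coupled to the cell fraction
through the diffusive resistance of the top-up medium layer.

## Worked example

Generate a synthetic water measurement (4 mm column at 37 °C,
D = 3.1×10⁻⁵ cm²·s⁻¹, probe at 1.8 mm, 1% read noise) and refit it:

```sh
oxygel synth --fixture water_37C --noise 0.01 --out water.csv
oxygel fit water.csv --preset water
```

prints

```json
{
  "D_hat_cm2_s": 3.106789475281966e-05,
  "mape_pct": 7.474305420318314,
  "converged": true,
  "window_s": [0.0, 7015.0]
}
```

(abridged): the fitted diffusion coefficient 3.11×10⁻⁵ cm²·s⁻¹ recovers
the generating value to 0.2% despite the noise; the MAPE of ~7% reflects
the 1% read noise amplified by the percent-error denominator as the
trace decays; the fit window ran from the purge onset until the trace
first fell below 1% of its initial value.

A viability analysis for a 3.5 mm slab of MIN6-laden gel
(1.2×10⁶ cells/mL, gel D = 1.35×10⁻⁵ cm²·s⁻¹, surface coupled through
1.5 mm of medium):

```sh
oxygel viability --cells-per-ml 1.2e6 --d-gel 1.35e-5
```

```json
{
  "C_s_mol_m3": 0.05964166161970452,
  "x_v_mm": 0.7813999314747553,
  "eta": 0.2232571232785015,
  "fully_viable": false
}
```

Consumption through the medium layer depresses the gel-surface oxygen
from the ambient 0.159 mol·m⁻³ to 0.060; oxygen then penetrates 0.78 mm
into the slab, so only 22% of its depth stays viable — the rest of the
cells sit below the critical tension.  `oxygel report --phi 2.31` prints
the effectiveness factor (0.61) for a known Thiele modulus, and
`oxygel design --d-gel 1.5e-5 --eta-target 0.9 --out curve.csv` writes
the thickness-vs-cell-density design curve.

The same pipeline is available as a library (`oxygel.solve_transient`,
`oxygel.fit_diffusion`, `oxygel.viable_depth`,
`oxygel.effectiveness_factor`, …); see the docstrings and
`docs/methods.md` for the modelling details.

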