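"""Steady-state zero-order reaction–diffusion in a cell-laden slab.

Immobilized cells consume oxygen at a concentration-independent
(zero-order) volumetric rate k_v = X·OCR, valid because oxygen levels in
these systems stay far above the Michaelis–Menten constant (~0.44 mmHg
for islets).  With the gel surface held at C_s and oxygen lost only to
consumption, the 1D steady profile is parabolic down to the depth x_v
where both the concentration reaches the critical level C_crit and the
flux vanishes (smooth pasting):

    x_v = sqrt(2 · D_eff · (C_s − C_crit) / k_v)

Cells deeper than x_v fall below C_crit, die, and stop consuming — the
classical zero-order obstacle problem, matching the sharp live/dead front
seen in stained slab cross-sections.  The viable fraction x_v/L equals
the zero-order slab effectiveness factor.

Depth x in this module runs *downward from the gel surface* (x = 0 at the
top), opposite to the transient module's z coordinate (z = 0 at the dish
bottom); the mapping is x = H_total − z.

The slab surface itself sits below a top-up medium layer: at steady state
the diffusive flux through the medium balances the areal consumption of
the viable zone, coupling the surface concentration C_s to the cell
fraction X:

    C_s = C_amb − k_v · min(x_v(C_s), L) · h_med / D_med
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .constants import DEFAULT_CONSTANTS
from .design import effective_diffusivity

__all__ = [
    "CellularSlab",
    "FrontResult",
    "SteadyProfile",
    "SurfaceResult",
    "viable_depth",
    "steady_profile",
    "surface_concentration",
    "predict_viable_fraction",
]

MM = 1e-3
CM2 = 1e-4

FrontStatus = Literal["front", "fully_viable", "starved"]


@dataclass(frozen=True)
class CellularSlab:
    """A cell-laden hydrogel slab.

    Attributes
    ----------
    L_mm
        Slab thickness (mm).
    X
        Cell volume fraction, 0 ≤ X < 1.
    OCR_mol_m3_s
        Volumetric oxygen consumption rate at X = 1.
    D_gel_cm2_s
        Oxygen diffusivity of the acellular gel.
    D_tissue_cm2_s
        Oxygen diffusivity of packed tissue; combined with the gel value
        through the cell-fraction-weighted mixture rule to give D_eff.
    C_crit_mol_m3
        Critical oxygen concentration below which cells die.  Defaults to
        the concentration equivalent of 0.1 mmHg, which is effectively
        zero in the effectiveness-factor formulas.
    """

    L_mm: float
    X: float
    OCR_mol_m3_s: float
    D_gel_cm2_s: float
    D_tissue_cm2_s: float = DEFAULT_CONSTANTS.D_tissue_cm2_s
    C_crit_mol_m3: float = (
        DEFAULT_CONSTANTS.pO2_crit_mmHg * DEFAULT_CONSTANTS.solubility_mol_m3_mmHg
    )

    def __post_init__(self) -> None:
        if self.L_mm <= 0:
            raise ValueError("slab thickness must be > 0")
        if not 0 <= self.X < 1:
            raise ValueError("cell fraction X must be in [0, 1)")
        if self.OCR_mol_m3_s <= 0:
            raise ValueError("OCR must be > 0")
        if self.D_gel_cm2_s <= 0 or self.D_tissue_cm2_s <= 0:
            raise ValueError("diffusivities must be > 0")
        if self.C_crit_mol_m3 < 0:
            raise ValueError("critical concentration must be >= 0")

    @property
    def k_v_mol_m3_s(self) -> float:
        """Volumetric consumption of the slab, k_v = X · OCR."""
        return self.X * self.OCR_mol_m3_s

    @property
    def D_eff_cm2_s(self) -> float:
        return effective_diffusivity(self.X, self.D_tissue_cm2_s, self.D_gel_cm2_s)

    @property
    def D_eff_m2_s(self) -> float:
        return self.D_eff_cm2_s * CM2


@dataclass(frozen=True)
class FrontResult:
    x_v_mm: float
    fully_viable: bool
    status: FrontStatus


@dataclass
class SteadyProfile:
    """Steady oxygen profile C(x), x measured downward from the gel surface."""

    depth_mm: np.ndarray
    C_mol_m3: np.ndarray
    x_v_mm: float
    eta: float
    fully_viable: bool
    status: FrontStatus
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SurfaceResult:
    C_s_mol_m3: float
    status: Literal["ok", "oxygen_starved"]


def viable_depth(C_s_mol_m3: float, slab: CellularSlab) -> FrontResult:
    """Depth of the viable zone under zero-order consumption.

    Returns the penetration depth x_v (capped at the slab thickness, with
    ``fully_viable`` set when the whole slab stays above C_crit).  A
    surface concentration at or below C_crit yields depth 0 with status
    ``"starved"`` rather than an exception.
    """
    if C_s_mol_m3 <= slab.C_crit_mol_m3:
        return FrontResult(0.0, False, "starved")
    k_v = slab.k_v_mol_m3_s
    if k_v == 0:
        return FrontResult(slab.L_mm, True, "fully_viable")
    x_v_m = np.sqrt(2.0 * slab.D_eff_m2_s * (C_s_mol_m3 - slab.C_crit_mol_m3) / k_v)
    x_v_mm = x_v_m / MM
    if x_v_mm >= slab.L_mm:
        return FrontResult(slab.L_mm, True, "fully_viable")
    return FrontResult(x_v_mm, False, "front")


def steady_profile(
    C_s_mol_m3: float, slab: CellularSlab, n_nodes: int = 201
) -> SteadyProfile:
    """Closed-form steady oxygen profile through the slab.

    Viable zone (x ≤ x_v):  C(x) = C_s − k_v/(2 D_eff) · x·(2 x_v − x),
    which satisfies C(x_v) = C_crit and dC/dx(x_v) = 0 when a front
    exists.  Dead zone (x > x_v): C = C_crit (no consumption, no flux).
    If the slab is fully viable the parabola instead has zero flux at the
    slab bottom x = L.
    """
    if n_nodes < 2:
        raise ValueError("profile needs at least 2 nodes")
    front = viable_depth(C_s_mol_m3, slab)
    x_mm = np.linspace(0.0, slab.L_mm, n_nodes)
    x_m = x_mm * MM
    k_v = slab.k_v_mol_m3_s
    D = slab.D_eff_m2_s
    if front.status == "starved":
        C = np.full_like(x_m, min(C_s_mol_m3, slab.C_crit_mol_m3))
        C[0] = C_s_mol_m3
        eta = 0.0
    elif k_v == 0:
        C = np.full_like(x_m, C_s_mol_m3)
        eta = 1.0
    elif front.fully_viable:
        L_m = slab.L_mm * MM
        C = C_s_mol_m3 - k_v / (2.0 * D) * x_m * (2.0 * L_m - x_m)
        eta = 1.0
    else:
        x_v_m = front.x_v_mm * MM
        C = np.where(
            x_m <= x_v_m,
            C_s_mol_m3 - k_v / (2.0 * D) * x_m * (2.0 * x_v_m - x_m),
            slab.C_crit_mol_m3,
        )
        eta = front.x_v_mm / slab.L_mm
    return SteadyProfile(
        depth_mm=x_mm,
        C_mol_m3=np.clip(C, 0.0, None),
        x_v_mm=front.x_v_mm,
        eta=eta,
        fully_viable=front.fully_viable,
        status=front.status,
        params={"C_s_mol_m3": C_s_mol_m3, "k_v_mol_m3_s": k_v, "D_eff_cm2_s": slab.D_eff_cm2_s},
    )


def surface_concentration(
    slab: CellularSlab,
    h_med_mm: float,
    D_med_cm2_s: float,
    C_amb_mol_m3: float,
    rel_tol: float = 1e-8,
) -> SurfaceResult:
    """Surface concentration coupled to consumption through the medium layer.

    Solves the fixed point C_s = C_amb − k_v·min(x_v(C_s), L)·h_med/D_med:
    at steady state the linear diffusive flux across the quiescent top-up
    medium equals the areal consumption of the viable zone.  Because the
    viable zone shrinks as C_s falls, the balance is monotone and a
    solution in (C_crit, C_amb] always exists when C_amb > C_crit; the
    root is located with a bracketed scalar solver to the requested
    relative tolerance.
    """
    if h_med_mm <= 0 or D_med_cm2_s <= 0:
        raise ValueError("medium thickness and diffusivity must be > 0")
    if C_amb_mol_m3 <= slab.C_crit_mol_m3:
        return SurfaceResult(min(C_amb_mol_m3, slab.C_crit_mol_m3), "oxygen_starved")
    if slab.k_v_mol_m3_s == 0:
        return SurfaceResult(C_amb_mol_m3, "ok")

    R_med = h_med_mm * MM / (D_med_cm2_s * CM2)  # medium transport resistance (s/m)

    def imbalance(C_s: float) -> float:
        depth_m = min(viable_depth(C_s, slab).x_v_mm, slab.L_mm) * MM
        return C_s - (C_amb_mol_m3 - slab.k_v_mol_m3_s * depth_m * R_med)

    lo = slab.C_crit_mol_m3 * (1 + 1e-12) + 1e-300
    if imbalance(C_amb_mol_m3) <= 0:
        return SurfaceResult(C_amb_mol_m3, "ok")
    C_s = brentq(
        imbalance, lo, C_amb_mol_m3, xtol=1e-300, rtol=max(rel_tol, 1e-15)
    )
    return SurfaceResult(float(C_s), "ok")


def predict_viable_fraction(
    slab: CellularSlab,
    h_med_mm: float,
    D_med_cm2_s: float,
    C_amb_mol_m3: float,
    couple_surface: bool = True,
    C_s_mol_m3: float | None = None,
) -> float:
    """Dimensionless viable length x_v/L of the slab (∈ [0, 1]).

    With ``couple_surface`` the surface concentration is computed from
    the medium-layer flux balance; otherwise ``C_s_mol_m3`` must be
    supplied directly.  Under zero-order kinetics this ratio equals the
    effectiveness factor.
    """
    if couple_surface:
        C_s = surface_concentration(slab, h_med_mm, D_med_cm2_s, C_amb_mol_m3).C_s_mol_m3
    else:
        if C_s_mol_m3 is None:
            raise ValueError("C_s_mol_m3 required when couple_surface is off")
        C_s = C_s_mol_m3
    front = viable_depth(C_s, slab)
    return min(1.0, front.x_v_mm / slab.L_mm)
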