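"""Dimensionless numbers and encapsulation design curves.

Three dimensionless groups organize the transport analysis:

* **Péclet number** Pe = uL/D — advective vs diffusive transport in the
  measurement headspace; Pe < 1 justifies the pure-diffusion model.
* **Thiele modulus** φ = L·sqrt(k_v / (D_eff·C_s)) with k_v = X·OCR — the
  zero-order reaction/diffusion balance of a cell-laden slab.
* **Effectiveness factor** η — the fraction of the slab's consumption
  capacity actually realized; for a zero-order slab with critical
  concentration ratio c = C_crit/C_s,

      φ_crit = sqrt(2(1 − c));   η = 1 for φ ≤ φ_crit,  else η = φ_crit/φ.

  η equals the viable fraction x_v/L, so it is directly comparable to
  measured dimensionless viable lengths.

The effective diffusivity is the cell-fraction-weighted average of tissue
and gel diffusivities.  The design functions invert the viable-depth
formula to give the slab thickness that achieves a target effectiveness
for a given cell loading (optionally coupling the surface concentration
to the cell fraction through the top-up medium).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_CONSTANTS

__all__ = [
    "DimensionlessReport",
    "DesignCurve",
    "peclet",
    "cells_to_fraction",
    "effective_diffusivity",
    "thiele_modulus",
    "effectiveness_factor",
    "critical_thiele",
    "truncate_two_decimals",
    "design_thickness",
    "design_curve",
]

MM = 1e-3
CM2 = 1e-4


def peclet(u_m_s: float, L_mm: float, D_cm2_s: float) -> float:
    """Péclet number Pe = uL/D for a surface speed u and length scale L."""
    if u_m_s < 0:
        raise ValueError("surface speed u must be >= 0")
    if L_mm <= 0 or D_cm2_s <= 0:
        raise ValueError("L and D must be > 0")
    return u_m_s * (L_mm * MM) / (D_cm2_s * CM2)


def cells_to_fraction(
    cells_per_mL: float, V_cell_pL: float = DEFAULT_CONSTANTS.cell_volume_pL
) -> float:
    """Cell volume fraction X from a concentration in cells·mL⁻¹.

    X = n · V_cell; rejects X ≥ 1 as unphysical packing.
    """
    if cells_per_mL < 0 or V_cell_pL < 0:
        raise ValueError("cell concentration and volume must be >= 0")
    X = cells_per_mL * V_cell_pL * 1e-9  # pL per mL = 1e-9
    if X >= 1:
        raise ValueError(f"cell fraction {X:.3g} >= 1 is unphysical")
    return X


def effective_diffusivity(X: float, D_tissue_cm2_s: float, D_material_cm2_s: float) -> float:
    """Cell-fraction-weighted diffusivity: X·D_tissue + (1 − X)·D_material."""
    if not 0 <= X <= 1:
        raise ValueError("cell fraction X must be in [0, 1]")
    return X * D_tissue_cm2_s + (1.0 - X) * D_material_cm2_s


def thiele_modulus(
    L_mm: float,
    X: float,
    OCR_mol_m3_s: float,
    D_eff_cm2_s: float,
    C_s_mol_m3: float,
) -> float:
    """Zero-order slab Thiele modulus φ = L·sqrt(X·OCR / (D_eff·C_s))."""
    if X < 0:
        raise ValueError("cell fraction X must be >= 0")
    if L_mm <= 0 or OCR_mol_m3_s <= 0 or D_eff_cm2_s <= 0:
        raise ValueError("L, OCR and D_eff must be > 0")
    if C_s_mol_m3 <= 0:
        raise ValueError("surface concentration C_s must be > 0")
    if X == 0:
        return 0.0
    k_v = X * OCR_mol_m3_s
    return (L_mm * MM) * math.sqrt(k_v / (D_eff_cm2_s * CM2 * C_s_mol_m3))


def critical_thiele(c_ratio: float = 0.0) -> float:
    """φ_crit = sqrt(2(1 − C_crit/C_s)): largest φ with a fully viable slab."""
    if not 0 <= c_ratio < 1:
        raise ValueError("c_ratio must be in [0, 1)")
    return math.sqrt(2.0 * (1.0 - c_ratio))


def effectiveness_factor(phi: float, c_ratio: float = 0.0) -> float:
    """Zero-order slab effectiveness factor.

    η = 1 for φ ≤ φ_crit, else η = sqrt(2(1 − c))/φ; continuous at
    φ_crit and identical to the viable fraction x_v/L.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    phi_crit = critical_thiele(c_ratio)
    if phi <= phi_crit:
        return 1.0
    return phi_crit / phi


def truncate_two_decimals(x: float) -> float:
    """Truncate (not round) toward zero at two decimals, e.g. 0.6122 -> 0.61."""
    return math.trunc(x * 100.0) / 100.0


@dataclass(frozen=True)
class DimensionlessReport:
    """Single-condition summary of the dimensionless groups."""

    phi: float
    phi_crit: float
    eta: float
    Pe: float | None = None
    inputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "phi": self.phi,
            "phi_crit": self.phi_crit,
            "eta": self.eta,
            "Pe": self.Pe,
            "inputs": dict(self.inputs),
        }


def dimensionless_report(
    L_mm: float,
    X: float,
    OCR_mol_m3_s: float,
    D_eff_cm2_s: float,
    C_s_mol_m3: float,
    C_crit_mol_m3: float = 0.0,
    u_m_s: float | None = None,
    D_flow_cm2_s: float | None = None,
) -> DimensionlessReport:
    """Compute φ, φ_crit, η (and Pe when a surface speed is supplied)."""
    phi = thiele_modulus(L_mm, X, OCR_mol_m3_s, D_eff_cm2_s, C_s_mol_m3)
    c_ratio = C_crit_mol_m3 / C_s_mol_m3
    pe = None
    if u_m_s is not None:
        pe = peclet(u_m_s, L_mm, D_flow_cm2_s if D_flow_cm2_s is not None else D_eff_cm2_s)
    return DimensionlessReport(
        phi=phi,
        phi_crit=critical_thiele(c_ratio),
        eta=effectiveness_factor(phi, c_ratio),
        Pe=pe,
        inputs={
            "L_mm": L_mm,
            "X": X,
            "OCR_mol_m3_s": OCR_mol_m3_s,
            "D_eff_cm2_s": D_eff_cm2_s,
            "C_s_mol_m3": C_s_mol_m3,
            "C_crit_mol_m3": C_crit_mol_m3,
            "u_m_s": u_m_s,
        },
    )


@dataclass
class DesignCurve:
    """Thickness-vs-cell-loading curve at a fixed target effectiveness."""

    cells_per_mL: np.ndarray
    X: np.ndarray
    C_s_mol_m3: np.ndarray
    phi: np.ndarray
    eta: np.ndarray
    L_mm: np.ndarray
    params: dict = field(default_factory=dict)


def design_thickness(
    X: float,
    eta_target: float,
    OCR_mol_m3_s: float,
    D_gel_cm2_s: float,
    C_amb_mol_m3: float,
    D_tissue_cm2_s: float = DEFAULT_CONSTANTS.D_tissue_cm2_s,
    C_crit_mol_m3: float = 0.0,
    couple_surface: bool = False,
    h_med_mm: float = 1.5,
    D_med_cm2_s: float = DEFAULT_CONSTANTS.D_water_37C_cm2_s,
) -> float:
    """Slab thickness L (mm) achieving a target effectiveness factor.

    L = x_v / η_target with x_v = sqrt(2·D_eff·(C_s − C_crit)/k_v).  With
    ``couple_surface`` the surface concentration is depressed below the
    ambient value by the flux balance across the top-up medium (the
    viable-zone depth, not the designed thickness, sets the consumption,
    so the coupling is independent of the L being solved for); otherwise
    C_s is taken as the ambient concentration itself.

    Raises a ``RuntimeError`` tagged oxygen-starved if the surface cannot
    stay above the critical concentration.
    """
    if not 0 < eta_target <= 1:
        raise ValueError("eta_target must be in (0, 1]")
    if X <= 0:
        raise ValueError("design thickness requires X > 0")
    k_v = X * OCR_mol_m3_s
    D_eff = effective_diffusivity(X, D_tissue_cm2_s, D_gel_cm2_s)
    if couple_surface:
        from .reaction import CellularSlab, surface_concentration

        # A slab much thicker than any feasible design: consumption is then
        # capped by the viable depth alone, as in the design identity above.
        probe_slab = CellularSlab(
            L_mm=1e6,
            X=X,
            OCR_mol_m3_s=OCR_mol_m3_s,
            D_gel_cm2_s=D_gel_cm2_s,
            D_tissue_cm2_s=D_tissue_cm2_s,
            C_crit_mol_m3=C_crit_mol_m3,
        )
        res = surface_concentration(probe_slab, h_med_mm, D_med_cm2_s, C_amb_mol_m3)
        if res.status != "ok":
            raise RuntimeError("oxygen-starved surface: C_s <= C_crit for this loading")
        C_s = res.C_s_mol_m3
    else:
        C_s = C_amb_mol_m3
    if C_s <= C_crit_mol_m3:
        raise RuntimeError("oxygen-starved surface: C_s <= C_crit for this loading")
    x_v_mm = math.sqrt(2.0 * D_eff * CM2 * (C_s - C_crit_mol_m3) / k_v) / MM
    return x_v_mm / eta_target


def design_curve(
    cells_per_mL,
    eta_target: float,
    OCR_mol_m3_s: float,
    D_gel_cm2_s: float,
    C_amb_mol_m3: float,
    V_cell_pL: float = DEFAULT_CONSTANTS.cell_volume_pL,
    D_tissue_cm2_s: float = DEFAULT_CONSTANTS.D_tissue_cm2_s,
    C_crit_mol_m3: float = 0.0,
    couple_surface: bool = False,
    h_med_mm: float = 1.5,
    D_med_cm2_s: float = DEFAULT_CONSTANTS.D_water_37C_cm2_s,
) -> DesignCurve:
    """Thickness-for-target-η curve over a grid of cell concentrations."""
    from .reaction import CellularSlab, surface_concentration

    cells = np.asarray(cells_per_mL, dtype=float)
    if cells.ndim != 1 or cells.size == 0 or np.any(cells <= 0):
        raise ValueError("cells_per_mL must be a 1D grid of positive values")
    X = np.array([cells_to_fraction(n, V_cell_pL) for n in cells])
    L = np.empty_like(X)
    C_s = np.empty_like(X)
    phi = np.empty_like(X)
    for i, x in enumerate(X):
        L[i] = design_thickness(
            x,
            eta_target,
            OCR_mol_m3_s,
            D_gel_cm2_s,
            C_amb_mol_m3,
            D_tissue_cm2_s=D_tissue_cm2_s,
            C_crit_mol_m3=C_crit_mol_m3,
            couple_surface=couple_surface,
            h_med_mm=h_med_mm,
            D_med_cm2_s=D_med_cm2_s,
        )
        if couple_surface:
            probe_slab = CellularSlab(
                L_mm=1e6,
                X=x,
                OCR_mol_m3_s=OCR_mol_m3_s,
                D_gel_cm2_s=D_gel_cm2_s,
                D_tissue_cm2_s=D_tissue_cm2_s,
                C_crit_mol_m3=C_crit_mol_m3,
            )
            C_s[i] = surface_concentration(
                probe_slab, h_med_mm, D_med_cm2_s, C_amb_mol_m3
            ).C_s_mol_m3
        else:
            C_s[i] = C_amb_mol_m3
        D_eff = effective_diffusivity(x, D_tissue_cm2_s, D_gel_cm2_s)
        phi[i] = thiele_modulus(L[i], x, OCR_mol_m3_s, D_eff, C_s[i])
    eta = np.array(
        [effectiveness_factor(p, C_crit_mol_m3 / c) for p, c in zip(phi, C_s)]
    )
    return DesignCurve(
        cells_per_mL=cells,
        X=X,
        C_s_mol_m3=C_s,
        phi=phi,
        eta=eta,
        L_mm=L,
        params={
            "eta_target": eta_target,
            "OCR_mol_m3_s": OCR_mol_m3_s,
            "D_gel_cm2_s": D_gel_cm2_s,
            "D_tissue_cm2_s": D_tissue_cm2_s,
            "C_amb_mol_m3": C_amb_mol_m3,
            "C_crit_mol_m3": C_crit_mol_m3,
            "V_cell_pL": V_cell_pL,
            "couple_surface": couple_surface,
            "h_med_mm": h_med_mm,
            "D_med_cm2_s": D_med_cm2_s,
        },
    )
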