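"""Inverse estimation of a layer's oxygen diffusion coefficient.

The diffusion coefficient of a liquid or hydrogel layer is recovered by
matching the forward transient model to an observed probe trace during a
nitrogen purge, minimizing the mean absolute percent error (MAPE) between
the two.  The optimization is a deterministic bounded scalar search over
log₁₀(D) — one unknown, no gradients required.

Both traces are normalized to the observed initial concentration before
comparison, so the fit is invariant to the unit the trace was logged in.
Because readings approach zero late in the purge, the MAPE denominator is
floored at a small fraction of the initial concentration and the fit
window ends when the observed trace first drops below 1% of it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .transient import (
    BoundaryDriver,
    LayerStack,
    ProbeTrace,
    SolverSettings,
    sample_probe,
    solve_transient,
)

__all__ = [
    "FitConfig",
    "DiffusionFitResult",
    "ReplicateSummary",
    "mape",
    "fit_diffusion",
    "aggregate_replicates",
]


@dataclass(frozen=True)
class FitConfig:
    """Settings for the one-parameter diffusion fit.

    Attributes
    ----------
    target_layer
        Index into the layer stack of the layer whose D is unknown (the
        other layer, if present, keeps its template diffusivity — for
        gels, medium held at the diffusivity of water).
    D_bounds_cm2_s
        Search interval for D; must bracket the minimum.
    rel_tol
        Relative convergence tolerance on D.
    fit_window_s
        Optional explicit (t_start, t_end) window; by default the window
        runs from the step onset (t = 0) until the observed trace first
        drops below ``cutoff_frac`` of its initial value.
    eps_frac
        Denominator floor for the MAPE, as a fraction of the observed
        initial concentration.
    """

    target_layer: int = 0
    D_bounds_cm2_s: tuple[float, float] = (1e-6, 1e-4)
    rel_tol: float = 1e-3
    fit_window_s: tuple[float, float] | None = None
    eps_frac: float = 0.02
    cutoff_frac: float = 0.01

    def __post_init__(self) -> None:
        lo, hi = self.D_bounds_cm2_s
        if not 0 < lo < hi:
            raise ValueError("D bounds must satisfy 0 < lower < upper")
        if not 0 < self.rel_tol < 1:
            raise ValueError("rel_tol must be in (0, 1)")
        if self.eps_frac <= 0:
            raise ValueError("eps_frac must be > 0")


@dataclass
class DiffusionFitResult:
    """Outcome of a diffusion-coefficient fit."""

    D_hat_cm2_s: float
    mape_pct: float
    iterations: int
    converged: bool
    residual: np.ndarray  # model − observed, normalized units, on the window
    window_s: tuple[float, float]
    settings: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: float
    sem: float
    n: int


def mape(model: ProbeTrace, observed: ProbeTrace, eps_frac: float = 0.02) -> float:
    """Mean absolute percent error of a model trace against observations.

    (100/N) Σ |mᵢ − oᵢ| / max(oᵢ, ε·C0) where C0 is the observed initial
    value.  Traces must share the same time grid and unit; zero iff they
    are identical.
    """
    if model.unit != observed.unit:
        raise ValueError(f"unit mismatch: model {model.unit!r} vs observed {observed.unit!r}")
    if model.times_s.size != observed.times_s.size or not np.allclose(
        model.times_s, observed.times_s, rtol=0, atol=1e-9
    ):
        raise ValueError("model and observed traces must share the same time grid")
    if observed.times_s.size == 0:
        raise ValueError("empty fit window")
    c0 = observed.values[0]
    if c0 <= 0:
        raise ValueError("observed initial concentration must be > 0")
    denom = np.maximum(observed.values, eps_frac * c0)
    return float(100.0 * np.mean(np.abs(model.values - observed.values) / denom))


def _fit_window_indices(observed: ProbeTrace, config: FitConfig) -> np.ndarray:
    t = observed.times_s
    if config.fit_window_s is not None:
        t0, t1 = config.fit_window_s
        idx = np.nonzero((t >= t0) & (t <= t1))[0]
        if idx.size < 2:
            raise ValueError("observed trace does not cover the requested fit window")
        return idx
    idx = np.nonzero(t >= 0)[0]
    if idx.size < 2:
        raise ValueError("observed trace has fewer than 2 samples at t >= 0")
    c0 = observed.values[idx[0]]
    below = np.nonzero(observed.values[idx] < config.cutoff_frac * c0)[0]
    if below.size:
        idx = idx[: below[0] + 1]
    if idx.size < 2:
        raise ValueError("fit window collapsed: trace starts below the cutoff")
    return idx


def fit_diffusion(
    observed: ProbeTrace,
    stack_template: LayerStack,
    driver: BoundaryDriver,
    config: FitConfig | None = None,
    settings: SolverSettings | None = None,
) -> DiffusionFitResult:
    """Estimate the target layer's D by bounded MAPE minimization.

    The observed trace is normalized by its initial value on the fit
    window and compared with the forward model run under a driver
    normalized the same way, so the result does not depend on the logging
    unit.  The optimizer works on log₁₀(D) with a golden-section /
    parabolic bounded search; hitting a bound clears the ``converged``
    flag rather than failing silently.
    """
    config = config or FitConfig()
    settings = settings or SolverSettings()
    if driver.C0 <= 0:
        raise ValueError("driver C0 must be > 0 to normalize the fit")
    if not 0 <= config.target_layer < len(stack_template.layers):
        raise ValueError("target_layer out of range for the stack")

    idx = _fit_window_indices(observed, config)
    t_win = observed.times_s[idx]
    obs_norm = observed.values[idx] / observed.values[idx[0]]
    obs_trace = ProbeTrace(t_win, obs_norm, unit=observed.unit)

    norm_driver = dataclasses.replace(
        driver, C0=1.0, C_final=driver.C_final / driver.C0
    )
    # solver output times must start at >= 0 and be increasing; t_win qualifies
    lo, hi = config.D_bounds_cm2_s

    def model_trace(D: float) -> ProbeTrace:
        stack = stack_template.with_layer_D(config.target_layer, D)
        fld = solve_transient(stack, norm_driver, t_win, settings)
        tr = sample_probe(fld, stack.probe_height_mm)
        return ProbeTrace(t_win, tr.values / tr.values[0], unit=observed.unit)

    def objective(log10_D: float) -> float:
        return mape(model_trace(10.0**log10_D), obs_trace, config.eps_frac)

    xatol = math.log10(1.0 + config.rel_tol)
    res = minimize_scalar(
        objective,
        bounds=(math.log10(lo), math.log10(hi)),
        method="bounded",
        options={"xatol": xatol},
    )
    D_hat = float(10.0**res.x)
    at_bound = (
        D_hat <= lo * (1 + 2 * config.rel_tol) or D_hat >= hi / (1 + 2 * config.rel_tol)
    )
    best = model_trace(D_hat)
    return DiffusionFitResult(
        D_hat_cm2_s=D_hat,
        mape_pct=float(res.fun),
        iterations=int(res.nfev),
        converged=bool(res.success) and not at_bound,
        residual=best.values - obs_norm,
        window_s=(float(t_win[0]), float(t_win[-1])),
        settings={
            "target_layer": config.target_layer,
            "D_bounds_cm2_s": list(config.D_bounds_cm2_s),
            "rel_tol": config.rel_tol,
            "eps_frac": config.eps_frac,
            "cutoff_frac": config.cutoff_frac,
            "dz_mm": settings.dz_mm,
            "dt_s": settings.dt_s,
        },
    )


def aggregate_replicates(results) -> ReplicateSummary:
    """Mean, sample SD (n−1) and SEM of replicate fitted D values.

    Accepts a list of :class:`DiffusionFitResult` or of plain numbers.
    With a single replicate the SD and SEM are NaN (undefined for n = 1).
    """
    values = np.asarray(
        [getattr(r, "D_hat_cm2_s", r) for r in results], dtype=float
    )
    if values.size == 0:
        raise ValueError("aggregate_replicates requires at least one result")
    n = int(values.size)
    mean = float(values.mean())
    if n == 1:
        return ReplicateSummary(mean, float("nan"), float("nan"), 1)
    sd = float(values.std(ddof=1))
    return ReplicateSummary(mean, sd, sd / math.sqrt(n), n)
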