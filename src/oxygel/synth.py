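"""Synthetic probe traces with known ground truth.

Emulates what the physical rig logs during a nitrogen purge: the forward
transient model is sampled at the probe height on a regular interval over
a 1–2 h horizon and optionally corrupted with independent Gaussian read
noise whose SD is a fraction of the initial concentration.  The
generating parameters (layer diffusivities, boundary driver, geometry,
seed) are embedded in the trace metadata, so fitting pipelines can be
exercised end-to-end and checked against the truth.

The noise model is deliberately the simplest plausible stand-in for
optode read noise: additive, white, zero-mean.  Drift, autocorrelation,
probe response lag and photobleaching are not simulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .constants import DEFAULT_CONSTANTS, MOL_PER_M3, ambient_concentration
from .transient import (
    BoundaryDriver,
    LayerStack,
    ProbeTrace,
    SolverSettings,
    gel_stack,
    sample_probe,
    solve_transient,
    water_stack,
)

__all__ = ["SyntheticSpec", "generate_trace", "make_fixture", "FIXTURE_NAMES"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic trace; the seed is mandatory."""

    stack: LayerStack
    driver: BoundaryDriver
    sampling_interval_s: float = 5.0
    duration_s: float = 7200.0
    noise_sd: float = 0.01  # fraction of C0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.duration_s < 10 * self.sampling_interval_s:
            raise ValueError("duration must be at least 10 sampling intervals")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def generate_trace(
    spec: SyntheticSpec, settings: SolverSettings | None = None
) -> ProbeTrace:
    """Forward-solve the spec and return the (optionally noisy) probe trace.

    Identical spec + seed gives a bit-identical trace.  Noise is drawn
    from ``numpy.random.default_rng(seed)`` with SD ``noise_sd · C0``.
    """
    times = np.arange(0.0, spec.duration_s + 1e-9, spec.sampling_interval_s)
    field = solve_transient(spec.stack, spec.driver, times, settings)
    trace = sample_probe(field, spec.stack.probe_height_mm)
    values = trace.values
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        values = values + rng.normal(
            0.0, spec.noise_sd * spec.driver.C0, size=values.shape
        )
        values = np.clip(values, 0.0, None)
    metadata = {
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "sampling_interval_s": spec.sampling_interval_s,
        "duration_s": spec.duration_s,
        "D_true_cm2_s": [layer.D_cm2_s for layer in spec.stack.layers],
        "thickness_mm": [layer.thickness_mm for layer in spec.stack.layers],
        "probe_height_mm": spec.stack.probe_height_mm,
        "driver_mode": spec.driver.mode,
        "C0_mol_m3": spec.driver.C0,
        "C_final_mol_m3": spec.driver.C_final,
        "theta_s": spec.driver.theta_s,
        "tau_s": spec.driver.tau_s,
        "source": "oxygel.synth",
    }
    return ProbeTrace(times, values, unit=MOL_PER_M3, metadata=metadata)


# Gel-layer diffusivities for the two-layer fixtures are placeholders on
# the right order of magnitude for calcium-alginate gels; they exist to
# exercise the two-layer solver/fitting path, not to represent measured
# material values.
_FIXTURES = {
    "water_37C": dict(kind="water", D=3.1e-5, seed=101),
    "gel_2pct": dict(kind="gel", D=1.5e-5, seed=102),
    "gel_5pct": dict(kind="gel", D=1.0e-5, seed=103),
}
FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(
    name: str,
    noise_sd: float = 0.01,
    seed: int | None = None,
) -> SyntheticSpec:
    """Named, seed-fixed synthetic specs mirroring the measurement geometries.

    ``water_37C``: single 4 mm liquid layer, D = 3.1e-5 cm²·s⁻¹, probe at
    1.8 mm, FOPDT boundary (θ = 3 s, τ = 23 s) stepping from the ambient
    dissolved concentration to 0 (N₂ purge).  ``gel_2pct`` / ``gel_5pct``:
    3.5 mm gel + 1.5 mm medium (medium at the diffusivity of water).
    """
    try:
        fx = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    if fx["kind"] == "water":
        stack = water_stack(D_cm2_s=fx["D"])
    else:
        stack = gel_stack(D_gel_cm2_s=fx["D"])
    C0 = ambient_concentration(DEFAULT_CONSTANTS).value
    driver = BoundaryDriver(
        "fopdt",
        C0=C0,
        C_final=0.0,
        theta_s=DEFAULT_CONSTANTS.theta_boundary_s,
        tau_s=DEFAULT_CONSTANTS.tau_boundary_s,
    )
    return SyntheticSpec(
        stack=stack,
        driver=driver,
        noise_sd=noise_sd,
        seed=fx["seed"] if seed is None else seed,
    )
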