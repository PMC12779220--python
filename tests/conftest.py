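"""Shared fixtures and independent numerical oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from oxygel.transient import SolverSettings


@pytest.fixture(scope="session")
def coarse_solver() -> SolverSettings:
    """Coarse but convergent discretization for fast property tests."""
    return SolverSettings(dz_mm=0.1, dt_s=2.0)


def fd_steady_masked(
    C_s: float,
    L_m: float,
    D_m2_s: float,
    k_v: float,
    C_crit: float,
    n_nodes: int = 351,
    dt_s: float = 20.0,
    tol: float = 1e-6,
    max_steps: int = 200_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force steady solver for the masked zero-order front problem.

    Pseudo-time relaxation on a plain finite-difference grid: implicit
    (backward Euler) diffusion, explicit consumption masked wherever
    C ≤ C_crit, floored at C_crit, marched until the profile stops
    changing.  C(0) = C_s (gel surface), mirror-ghost zero flux at x = L.
    Independent of the closed-form profile it is used to check.
    """
    from scipy.linalg import solve_banded

    x = np.linspace(0.0, L_m, n_nodes)
    h = x[1] - x[0]
    C = np.full(n_nodes, C_s)
    # The on/off consumption at the front node limit-cycles with amplitude
    # ~k_v·dt, so anneal dt: converge each stage to its cycle amplitude,
    # then shrink the step until the residual amplitude is negligible.
    # Stage 1 marches several diffusive equilibration times at the base dt;
    # later stages shrink dt so the on/off cycling of the front node (whose
    # amplitude is ~k_v·dt) relaxes to a negligible level.
    horizon_s = 8.0 * L_m * L_m / D_m2_s
    dt = dt_s
    stages = [(dt, int(np.ceil(horizon_s / dt)))]
    while k_v * dt > tol * C_s:
        dt /= 5.0
        stages.append((dt, 500))
    for dt, n_steps in stages:
        if n_steps > max_steps:
            raise RuntimeError("pseudo-time relaxation budget exceeded")
        r = D_m2_s * dt / (h * h)
        main = np.full(n_nodes, 1.0 + 2.0 * r)
        upper = np.full(n_nodes - 1, -r)
        lower = np.full(n_nodes - 1, -r)
        main[0] = 1.0
        upper[0] = 0.0
        lower[-1] = -2.0 * r  # mirror ghost at the far (no-flux) end
        ab = np.zeros((3, n_nodes))
        ab[0, 1:] = upper
        ab[1, :] = main
        ab[2, :-1] = lower
        for _ in range(n_steps):
            rhs = C - dt * k_v * (C > C_crit)
            rhs[0] = C_s
            C = np.maximum(solve_banded((1, 1), ab, rhs), C_crit)
    return x, C
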