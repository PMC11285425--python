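"""Atmospheric layer: advection-decay dynamics, the stochastic intermittent
vertical-exchange primitives, and the connectivity calibration of the
atmospheric decay rate.

The upper layer only transports and decays (no replication or predation):

    da/dt = -v da/dx - delta_a a   (periodic in x)

Vertical exchange between the two layers of one column is intermittent: each
window of length tau a column/species pair is active with probability p, and
while active biomass flows down the vertical density gradient at rate j0.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "draw_vertical_activity",
    "vertical_exchange_rates",
    "advect_decay_step",
    "delta_a_for_connectivity",
    "connectivity_from_delta_a",
]


def draw_vertical_activity(
    p: float, n_columns: int, n_species: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean activity mask of shape (n_species, n_columns).

    Each entry is independently active with probability ``p``: exchange is
    independent among species and columns, and of the system state in the
    previous window.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p out of [0,1]: {p}")
    if p == 0.0:
        return np.zeros((n_species, n_columns), dtype=bool)
    if p == 1.0:
        # still consume the draw so trajectories at p=1 and p<1 share streams
        rng.random((n_species, n_columns))
        return np.ones((n_species, n_columns), dtype=bool)
    return rng.random((n_species, n_columns)) < p


def vertical_exchange_rates(
    surface: np.ndarray, atmos: np.ndarray, j0: float, active: np.ndarray
) -> np.ndarray:
    """Net vertical flux j_n = j_up - j_down = j0 (surface - atmos) where
    active, zero elsewhere.

    The sign convention follows the surface equation: the net flux enters the
    surface ODE as ``-j_n`` and the atmosphere as ``+j_n``.
    """
    surface = np.asarray(surface, dtype=float)
    atmos = np.asarray(atmos, dtype=float)
    if np.any(surface < 0) or np.any(atmos < 0):
        raise ValueError("densities must be >= 0")
    return np.where(active, j0 * (surface - atmos), 0.0)


def advect_decay_step(
    field: np.ndarray,
    v: float,
    delta_a: float,
    dx: float,
    dt: float,
    mode: str = "shift",
) -> np.ndarray:
    """Advance a periodic 1D atmospheric field by dt: advect downstream by
    v*dt and decay by exp(-delta_a*dt).

    ``shift`` mode is an exact semi-Lagrangian step and requires v*dt to be an
    integer multiple of dx (no numerical diffusion, mass conserved exactly
    when delta_a=0). ``upwind`` is first-order and requires the CFL condition
    v*dt <= dx. The last axis is the spatial one.
    """
    field = np.asarray(field, dtype=float)
    if mode == "shift":
        c = v * dt / dx
        k = round(c)
        if abs(c - k) > 1e-9 * max(1.0, abs(c)):
            raise ValueError(f"shift mode requires v*dt an integer multiple of dx (v*dt/dx={c})")
        out = np.roll(field, k, axis=-1)
    elif mode == "upwind":
        c = v * dt / dx
        if c > 1.0 + 1e-12:
            raise ValueError(f"CFL violated in upwind mode: v*dt/dx = {c} > 1")
        out = (1.0 - c) * field + c * np.roll(field, 1, axis=-1)
    else:
        raise ValueError(f"unknown advection mode {mode!r}")
    if delta_a != 0.0:
        out = out * math.exp(-delta_a * dt)
    return out


def delta_a_for_connectivity(
    L: float, N: int, dx: float, v: float, rho_ext: float, K: float
) -> float:
    """Atmospheric decay rate delta_a giving connectivity length L.

    L is the fraction of the system length an emitted pulse of magnitude K
    travels before decaying below the extinction threshold rho_ext:
    x* = L N dx = -(v/delta_a) ln(rho_ext/K), hence
    delta_a = -v ln(rho_ext/K) / (L N dx).
    """
    if not 0.0 < rho_ext < K:
        raise ValueError("requires 0 < rho_ext < K")
    if L <= 0:
        raise ValueError("L must be > 0")
    if v <= 0 or N < 1 or dx <= 0:
        raise ValueError("v, N, dx must be positive")
    return v * math.log(K / rho_ext) / (L * N * dx)


def connectivity_from_delta_a(
    delta_a: float, N: int, dx: float, v: float, rho_ext: float, K: float
) -> float:
    """Inverse of :func:`delta_a_for_connectivity`."""
    if delta_a <= 0:
        raise ValueError("delta_a must be > 0")
    return v * math.log(K / rho_ext) / (delta_a * N * dx)
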