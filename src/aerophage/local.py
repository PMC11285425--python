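"""Deterministic single-habitat (one surface grid box) dynamics.

The local model is the classical Lotka-Volterra predator-prey system with
logistic host growth,

    dn_s/dt = g n_s (1 - n_s/K) - sum_i eta_i n_s m_i - r n_s
    dm_i/dt = (beta_i - 1) eta_i n_s m_i - delta_s_i m_i - r m_i

where ``r`` is an optional continuous loss rate: in the continuous-flux limit
of intermittent vertical transport a fraction ``p`` of the time is spent
losing biomass at rate ``j0``, so ``r = p * j0``.

This module provides the right-hand sides, the coexistence fixed point and
its classification, the linear-stability (spiral) analysis with the
perturbation-relaxation timescale ``tau_per``, an adaptive integrator, and
the critical-trajectory machinery: the deterministic separatrix in the
(n_s, m_s) plane outside of which a transient dips below the extinction
threshold before relaxing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import SpeciesParams

__all__ = [
    "FixedPointReport",
    "lv_rhs",
    "coexistence_fixed_point",
    "stability_report",
    "integrate_local",
    "critical_region_test",
    "critical_trajectory",
    "InfeasibleFixedPoint",
]

COEXISTENCE = "coexistence"
PHAGE_FREE = "phage_free"
DET_UNSTABLE = "deterministically_unstable"


class InfeasibleFixedPoint(ValueError):
    """Raised when a stability analysis is requested at an infeasible fixed point."""


@dataclass(frozen=True)
class FixedPointReport:
    """Coexistence fixed point, its linear stability and feasibility class.

    Attributes
    ----------
    ns_star, ms_star : float
        Host and phage densities at the coexistence fixed point (the values
        solve the loss-shifted right-hand sides; they may be non-positive when
        infeasible, in which case ``feasible`` says which regime applies).
    feasible : {'coexistence', 'phage_free', 'deterministically_unstable'}
        ``phage_free``: the phage cannot invade but a positive bacteria-only
        logistic equilibrium exists. ``deterministically_unstable``: the loss
        rate exceeds the maximum growth rate, so even a phage-free habitat is
        drained (loss_rate >= g).
    eigenvalues : tuple of complex or None
        Eigenvalues of the 2x2 Jacobian at the fixed point (filled by
        :func:`stability_report`).
    tau_per : float or None
        Relaxation timescale of small perturbations, -1/Re(lambda).
    spiral : bool or None
        True when the eigenvalues are a complex conjugate pair.
    ns_free : float or None
        The phage-free logistic equilibrium K (1 - loss_rate/g), when positive.
    """

    ns_star: float
    ms_star: float
    feasible: str
    loss_rate: float = 0.0
    eigenvalues: tuple | None = None
    tau_per: float | None = None
    spiral: bool | None = None
    ns_free: float | None = None


def _check_single_phage(phage: SpeciesParams) -> None:
    if phage.role != "phage":
        raise ValueError("expected a phage SpeciesParams")


def lv_rhs(
    ns: float,
    ms: Sequence[float] | np.ndarray,
    bact: SpeciesParams,
    phages: Sequence[SpeciesParams],
    loss_rate: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Right-hand side of the local dynamics for one host and any number of
    phage strains sharing it.

    Returns ``(dns_dt, dms_dt)`` with ``dms_dt`` an array over strains. The
    multi-strain host equation subtracts the additive predation load
    ``sum_i eta_i ns ms_i``.
    """
    ms = np.asarray(ms, dtype=float)
    if ms.ndim != 1 or len(ms) != len(phages):
        raise ValueError(f"ms has {ms.size} entries for {len(phages)} phage strains")
    if ns < 0 or np.any(ms < 0):
        raise ValueError("densities must be >= 0")
    if loss_rate < 0:
        raise ValueError("loss_rate must be >= 0")
    eta = np.array([ph.eta for ph in phages])
    beta = np.array([ph.beta for ph in phages])
    ds = np.array([ph.delta_s for ph in phages])
    dns = bact.g * ns * (1.0 - ns / bact.K) - ns * float(eta @ ms) - loss_rate * ns
    dms = (beta - 1.0) * eta * ns * ms - ds * ms - loss_rate * ms
    return dns, dms


def coexistence_fixed_point(
    bact: SpeciesParams, phage: SpeciesParams, loss_rate: float = 0.0
) -> FixedPointReport:
    """Fixed point of the single-phage loss-shifted system and its feasibility.

    The non-trivial root is

        ns* = (delta_s + r) / ((beta - 1) eta)
        ms* = (g (1 - ns*/K) - r) / eta

    classified as ``coexistence`` when both are positive, ``phage_free`` when
    only the logistic equilibrium K (1 - r/g) is positive, and
    ``deterministically_unstable`` when r >= g.
    """
    _check_single_phage(phage)
    if loss_rate < 0:
        raise ValueError("loss_rate must be >= 0")
    g, K = bact.g, bact.K
    r = loss_rate
    if g == 0 or r >= g:
        return FixedPointReport(0.0, 0.0, DET_UNSTABLE, loss_rate=r, ns_free=None)
    ns_free = K * (1.0 - r / g)
    denom = (phage.beta - 1.0) * phage.eta
    if denom <= 0 or phage.eta == 0:
        return FixedPointReport(ns_free, 0.0, PHAGE_FREE, loss_rate=r, ns_free=ns_free)
    ns_star = (phage.delta_s + r) / denom
    ms_star = (g * (1.0 - ns_star / K) - r) / phage.eta
    if ms_star <= 0 or ns_star >= ns_free:
        return FixedPointReport(ns_star, ms_star, PHAGE_FREE, loss_rate=r, ns_free=ns_free)
    return FixedPointReport(ns_star, ms_star, COEXISTENCE, loss_rate=r, ns_free=ns_free)


def jacobian(
    ns: float, ms: float, bact: SpeciesParams, phage: SpeciesParams, loss_rate: float = 0.0
) -> np.ndarray:
    """2x2 Jacobian of the loss-shifted single-phage system at (ns, ms)."""
    g, K = bact.g, bact.K
    eta, beta, ds = phage.eta, phage.beta, phage.delta_s
    return np.array(
        [
            [g * (1.0 - 2.0 * ns / K) - eta * ms - loss_rate, -eta * ns],
            [(beta - 1.0) * eta * ms, (beta - 1.0) * eta * ns - ds - loss_rate],
        ]
    )


def stability_report(
    bact: SpeciesParams, phage: SpeciesParams, loss_rate: float = 0.0
) -> FixedPointReport:
    """Fixed point with linear stability: eigenvalues, tau_per and spiral flag.

    At the coexistence fixed point the Jacobian reduces to
    [[-g ns*/K, -eta ns*], [(beta-1) eta ms*, 0]], a stable spiral whenever
    the discriminant is negative; the decay time of small perturbations is
    tau_per = -1/Re(lambda) = 2 K (beta-1) eta / (g delta_s) for the closed
    system, hence proportional to 1/delta_s.
    """
    rep = coexistence_fixed_point(bact, phage, loss_rate)
    if rep.feasible != COEXISTENCE:
        raise InfeasibleFixedPoint(
            f"stability analysis requires a feasible coexistence fixed point (got {rep.feasible})"
        )
    J = jacobian(rep.ns_star, rep.ms_star, bact, phage, loss_rate)
    lam = np.linalg.eigvals(J)
    lam = lam[np.argsort(-lam.real)]
    re = float(np.max(lam.real))
    tau_per = -1.0 / re if re < 0 else np.inf
    spiral = bool(np.any(np.abs(lam.imag) > 0))
    return FixedPointReport(
        rep.ns_star,
        rep.ms_star,
        rep.feasible,
        loss_rate=loss_rate,
        eigenvalues=(complex(lam[0]), complex(lam[1])),
        tau_per=tau_per,
        spiral=spiral,
        ns_free=rep.ns_free,
    )


def integrate_local(
    state0: tuple[float, Sequence[float]],
    bact: SpeciesParams,
    phages: Sequence[SpeciesParams],
    loss_rate: float,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
    method: str = "RK45",
):
    """Adaptive integration of the local dynamics.

    Returns the scipy ``OdeResult``; row 0 of ``sol.y`` is the host, the
    remaining rows the phage strains. Densities are clipped at zero on output
    (the flow never crosses zero from above, so any negative value is solver
    round-off).
    """
    ns0, ms0 = state0
    y0 = np.concatenate([[ns0], np.asarray(ms0, dtype=float)])
    if np.any(y0 < 0):
        raise ValueError("initial densities must be >= 0")
    eta = np.array([ph.eta for ph in phages])
    beta = np.array([ph.beta for ph in phages])
    ds = np.array([ph.delta_s for ph in phages])
    g, K = bact.g, bact.K

    def rhs(t, y):
        ns = y[0]
        ms = y[1:]
        dns = g * ns * (1.0 - ns / K) - ns * (eta @ ms) - loss_rate * ns
        dms = (beta - 1.0) * eta * ns * ms - ds * ms - loss_rate * ms
        return np.concatenate([[dns], dms])

    sol = solve_ivp(rhs, t_span, y0, t_eval=t_eval, rtol=rtol, atol=atol, method=method)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1]}: {sol.message}")
    np.clip(sol.y, 0.0, None, out=sol.y)
    return sol


def critical_region_test(
    state: tuple[float, float],
    bact: SpeciesParams,
    phage: SpeciesParams,
    loss_rate: float,
    rho_ext: float,
    horizon: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> tuple[str, str | None]:
    """Classify an initial (ns, ms) state as ``safe`` or ``doomed``.

    Forward-integrates the deterministic system and reports ``doomed`` if
    either species' density dips below ``rho_ext`` along the transient,
    together with which floor was crossed ('bacteria' or 'phage'). The default
    horizon is 20 tau_per, well past the spiral's decay.
    """
    ns0, ms0 = state
    if ns0 < 0 or ms0 < 0:
        raise ValueError("densities must be >= 0")
    if rho_ext <= 0:
        raise ValueError("rho_ext must be > 0")
    if ns0 < rho_ext:
        return "doomed", "bacteria"
    if ms0 < rho_ext:
        return "doomed", "phage"
    rep = stability_report(bact, phage, loss_rate)
    if horizon is None:
        horizon = 20.0 * rep.tau_per
    elif horizon < 5.0 * rep.tau_per:
        warnings.warn(
            "horizon shorter than 5 tau_per: safe/doomed classification may be premature",
            stacklevel=2,
        )

    g, K = bact.g, bact.K
    eta, beta, ds = phage.eta, phage.beta, phage.delta_s

    def rhs(t, y):
        ns, ms = y
        return (
            g * ns * (1.0 - ns / K) - eta * ns * ms - loss_rate * ns,
            (beta - 1.0) * eta * ns * ms - ds * ms - loss_rate * ms,
        )

    def host_floor(t, y):
        return y[0] - rho_ext

    def phage_floor(t, y):
        return y[1] - rho_ext

    host_floor.terminal = True
    host_floor.direction = -1
    phage_floor.terminal = True
    phage_floor.direction = -1
    sol = solve_ivp(
        rhs,
        (0.0, horizon),
        [ns0, ms0],
        events=[host_floor, phage_floor],
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed at t={sol.t[-1]}: {sol.message}")
    if len(sol.t_events[0]) > 0:
        return "doomed", "bacteria"
    if len(sol.t_events[1]) > 0:
        return "doomed", "phage"
    return "safe", None


def critical_trajectory(
    bact: SpeciesParams,
    phage: SpeciesParams,
    loss_rate: float,
    rho_ext: float,
    ns_grid: Sequence[float],
    ms_max: float | None = None,
    rel_tol: float = 1e-6,
    horizon: float | None = None,
) -> np.ndarray:
    """Largest safe phage density ms_crit(ns) along a grid of host densities.

    The safe set at fixed ns is an interval around the coexistence fixed
    point (a too-small dose blooms and crashes just like a too-large one), so
    the upper boundary is found by bisecting between a safe seed — located by
    probing a geometric grid around ms* — and ms_max. ms_crit is 0 where no
    safe phage density >= rho_ext exists at that ns (e.g. at the carrying
    capacity, where any migration dooms the habitat).
    """
    rep = stability_report(bact, phage, loss_rate)
    if ms_max is None:
        ms_max = 100.0 * rep.ms_star
    out = np.empty((len(ns_grid), 2))
    probes = rep.ms_star * np.array([1.0, 0.5, 2.0, 0.2, 5.0, 0.1, 10.0])
    for k, ns in enumerate(ns_grid):
        if not rho_ext < ns <= bact.K:
            raise ValueError("ns_grid entries must lie in (rho_ext, K]")
        lo = None
        for ms_try in probes:
            if ms_try < rho_ext:
                continue
            verdict, _ = critical_region_test(
                (ns, ms_try), bact, phage, loss_rate, rho_ext, horizon
            )
            if verdict == "safe":
                lo = ms_try
                break
        if lo is None:
            out[k] = (ns, 0.0)
            continue
        hi = ms_max
        verdict, _ = critical_region_test((ns, hi), bact, phage, loss_rate, rho_ext, horizon)
        if verdict == "safe":
            out[k] = (ns, np.inf)
            continue
        while (hi - lo) > rel_tol * hi:
            mid = 0.5 * (lo + hi)
            verdict, _ = critical_region_test((ns, mid), bact, phage, loss_rate, rho_ext, horizon)
            if verdict == "safe":
                lo = mid
            else:
                hi = mid
        out[k] = (ns, lo)
    return out
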