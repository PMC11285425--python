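"""The full coupled two-layer lattice: operator-split window stepping,
extinction thresholds, habitat classification and event logging.

Each window of length tau: (1) draw the per-species/per-column activity mask;
(2) jointly integrate every column's surface dynamics together with the
same-column atmospheric exchange (so the vertical flux conserves two-layer
mass exactly); (3) advect and decay the atmospheric fields; (4) apply the
extinction threshold in both layers; (5) log fluxes, depositions and habitat
transitions.

Habitat classes per column: C (host and at least one phage present on the
surface), F (host only), E (neither). An E->C label change within a single
window can only arise from simultaneous, independent bacterial and phage
deposition; it is decomposed into E->F + F->C records so that the event log
never contains a direct E->C transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import RunConfig
from .local import coexistence_fixed_point, COEXISTENCE
from .transport import draw_vertical_activity

__all__ = [
    "LatticeState",
    "LatticeSimulation",
    "SimResult",
    "run",
    "apply_extinction_threshold",
    "classify_habitats",
    "detect_transitions",
    "E",
    "F",
    "C",
]

E, F, C = 0, 1, 2
_LABEL_NAMES = {E: "E", F: "F", C: "C"}


@dataclass
class LatticeState:
    """Surface and atmosphere density fields, shape (n_species, N); species 0
    is the bacterium."""

    t: float
    surface: np.ndarray
    atmos: np.ndarray

    def copy(self) -> "LatticeState":
        return LatticeState(self.t, self.surface.copy(), self.atmos.copy())


def apply_extinction_threshold(state: LatticeState, rho_ext: float) -> LatticeState:
    """Zero every density strictly below rho_ext, in both layers (in place).

    A density exactly at rho_ext survives ('drops below' is strict). With
    rho_ext == 0 the threshold is disabled and the state is untouched.
    """
    if rho_ext > 0:
        state.surface[state.surface < rho_ext] = 0.0
        state.atmos[state.atmos < rho_ext] = 0.0
    return state


def classify_habitats(state: LatticeState, rho_ext: float = 0.0) -> np.ndarray:
    """Per-column habitat class from surface presence (density > 0 after
    thresholding): C host+phage, F host only, E neither."""
    present = state.surface > 0
    return _labels_from_presence(present)


def _labels_from_presence(present: np.ndarray) -> np.ndarray:
    host = present[0]
    phage_any = present[1:].any(axis=0)
    labels = np.zeros(present.shape[-1], dtype=np.uint8)
    labels[host & ~phage_any] = F
    labels[host & phage_any] = C
    return labels


def detect_transitions(
    labels_before: np.ndarray,
    labels_after: np.ndarray,
    deposited: np.ndarray,
    window: int,
    t: float,
) -> list[tuple]:
    """Emit one event row per column label change in a window.

    ``deposited`` is the (n_species, N) boolean mask of net-downward active
    exchange in this window. Rows are
    (window, t, column, before, after, dep_host, dep_phage); a same-window
    E->C change is decomposed into E->F followed by F->C.
    """
    rows: list[tuple] = []
    changed = np.nonzero(labels_before != labels_after)[0]
    dep_host = deposited[0]
    dep_phage = deposited[1:].any(axis=0)
    for col in changed:
        b, a = int(labels_before[col]), int(labels_after[col])
        dh, dp = bool(dep_host[col]), bool(dep_phage[col])
        if b == E and a == C:
            rows.append((window, t, int(col), "E", "F", dh, dp))
            rows.append((window, t, int(col), "F", "C", dh, dp))
        else:
            rows.append((window, t, int(col), _LABEL_NAMES[b], _LABEL_NAMES[a], dh, dp))
    return rows


@dataclass
class SimResult:
    """Trajectory summaries of one lattice run (reproducible per (config, seed))."""

    config: RunConfig
    seed: int
    times: np.ndarray  # (n_windows+1,) window-boundary times
    presence: np.ndarray  # (n_windows+1, n_species, N) surface presence
    events: pd.DataFrame
    depositions: pd.DataFrame
    final_state: LatticeState
    fluxes: pd.DataFrame | None = None

    @property
    def labels(self) -> np.ndarray:
        """(n_windows+1, N) habitat class per column over time."""
        host = self.presence[:, 0, :]
        phage_any = self.presence[:, 1:, :].any(axis=1)
        lab = np.zeros(host.shape, dtype=np.uint8)
        lab[host & ~phage_any] = F
        lab[host & phage_any] = C
        return lab

    def fractions(self, burn_in: float | None = None) -> pd.DataFrame:
        """Time series of C/F/E column fractions (rows sum to 1)."""
        lab = self.labels
        t = self.times
        if burn_in is not None:
            keep = t >= burn_in
            lab, t = lab[keep], t[keep]
        N = lab.shape[1]
        return pd.DataFrame(
            {
                "t": t,
                "C": (lab == C).sum(axis=1) / N,
                "F": (lab == F).sum(axis=1) / N,
                "E": (lab == E).sum(axis=1) / N,
            }
        )

    def extinction_times(self, species: int = 0) -> np.ndarray:
        """Per-column time of first absence of ``species`` (NaN if never)."""
        pres = self.presence[:, species, :]
        gone = ~pres
        first = np.argmax(gone, axis=0).astype(float)
        never = ~gone.any(axis=0)
        out = self.times[first.astype(int)]
        out = out.astype(float)
        out[never] = np.nan
        return out

    def occupancy(self, species: int, burn_in: float = 0.0) -> float:
        """Time-mean fraction of columns where ``species`` is present after
        burn-in."""
        keep = self.times >= burn_in
        return float(self.presence[keep, species, :].mean())


class LatticeSimulation:
    """Stochastic two-layer engine over N columns.

    All randomness (initialization and activity masks) comes from one Philox
    stream derived from the master seed, so same-seed runs are bit-identical.
    """

    def __init__(self, config: RunConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        self.rng = np.random.Generator(np.random.Philox(self.seed))
        cfg = config
        bact = cfg.bacterium
        self.N = cfg.lattice.N
        self.nsp = cfg.n_species
        self.g = bact.g
        self.K = bact.K
        self.eta = np.array([ph.eta for ph in cfg.phages])
        self.beta1 = np.array([ph.beta - 1.0 for ph in cfg.phages])
        self.ds = np.array([ph.delta_s for ph in cfg.phages])
        self.delta_a = np.array([sp.delta_a for sp in cfg.species])
        self.tau = cfg.transport.tau
        self.p = cfg.transport.p
        self.j0 = cfg.transport.j0
        self.rho_ext = cfg.resolved_rho_ext
        self.decay = np.exp(-self.delta_a * self.tau)[:, None]
        v, dx = cfg.transport.v, cfg.lattice.dx
        c = v * self.tau / dx
        if cfg.advection_mode == "shift":
            self.shift = round(c)
            if abs(c - self.shift) > 1e-9 * max(1.0, abs(c)):
                raise ValueError(
                    f"shift advection requires v*tau an integer multiple of dx (v*tau/dx={c})"
                )
        else:
            if c > 1 + 1e-12:
                raise ValueError(f"CFL violated: v*tau/dx={c} > 1")
            self.cfl = c
        self.state = self._initial_state()

    # -- initialization ----------------------------------------------------
    def _initial_state(self) -> LatticeState:
        cfg = self.config
        S = np.empty((self.nsp, self.N))
        if cfg.init == "fixed_point":
            rep = coexistence_fixed_point(
                cfg.bacterium, cfg.phages[0], loss_rate=self.p * self.j0
            )
            if rep.feasible != COEXISTENCE:
                rep = coexistence_fixed_point(cfg.bacterium, cfg.phages[0], loss_rate=0.0)
            S[0] = rep.ns_star
            S[1:] = rep.ms_star
        else:
            # host ~ U(0, K], each phage ~ U(0, factor * ms*]
            S[0] = self.K * (1.0 - self.rng.random(self.N))
            for i, ph in enumerate(cfg.phages):
                rep = coexistence_fixed_point(cfg.bacterium, ph, loss_rate=0.0)
                scale = rep.ms_star if rep.feasible == COEXISTENCE else self.K
                S[1 + i] = cfg.init_phage_factor * scale * (1.0 - self.rng.random(self.N))
            if cfg.init == "mosaic" and len(cfg.phages) > 1:
                # one strain per column: an assembled community in which the
                # strains meet through migration rather than starting mixed
                keep = self.rng.integers(0, len(cfg.phages), size=self.N)
                for i in range(len(cfg.phages)):
                    S[1 + i, keep != i] = 0.0
        A = np.zeros((self.nsp, self.N))
        return LatticeState(0.0, S, A)

    # -- dynamics ----------------------------------------------------------
    def _deriv(self, S: np.ndarray, A: np.ndarray, jmask: np.ndarray):
        nb = S[0]
        pred = self.eta[:, None] * S[1:]
        dS = np.empty_like(S)
        dS[0] = self.g * nb * (1.0 - nb / self.K) - nb * pred.sum(axis=0)
        dS[1:] = self.beta1[:, None] * pred * nb - self.ds[:, None] * S[1:]
        if self.config.disconnected:
            ex = jmask * S
            dA = None
        else:
            ex = jmask * (S - A)
            dA = ex
        dS -= ex
        return dS, dA

    def _integrate_window_rk4(self, S, A, jmask, duration):
        n = max(1, round(self.config.n_substeps * duration / self.tau))
        h = duration / n
        connected = not self.config.disconnected
        for _ in range(n):
            k1s, k1a = self._deriv(S, A, jmask)
            k2s, k2a = self._deriv(S + 0.5 * h * k1s, A + 0.5 * h * k1a if connected else A, jmask)
            k3s, k3a = self._deriv(S + 0.5 * h * k2s, A + 0.5 * h * k2a if connected else A, jmask)
            k4s, k4a = self._deriv(S + h * k3s, A + h * k3a if connected else A, jmask)
            S += (h / 6.0) * (k1s + 2.0 * k2s + 2.0 * k3s + k4s)
            np.clip(S, 0.0, None, out=S)
            if connected:
                A += (h / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
                np.clip(A, 0.0, None, out=A)
        return S, A

    def _integrate_window_adaptive(self, S, A, jmask, duration):
        cfg = self.config
        shape = S.shape
        connected = not cfg.disconnected

        def rhs(t, y):
            if connected:
                s = y[: S.size].reshape(shape)
                a = y[S.size :].reshape(shape)
            else:
                s = y.reshape(shape)
                a = A
            ds, da = self._deriv(np.clip(s, 0.0, None), np.clip(a, 0.0, None) if connected else a, jmask)
            if connected:
                return np.concatenate([ds.ravel(), da.ravel()])
            return ds.ravel()

        y0 = np.concatenate([S.ravel(), A.ravel()]) if connected else S.ravel()
        sol = solve_ivp(rhs, (0.0, duration), y0, rtol=cfg.rtol, atol=cfg.atol, method="DOP853")
        if not sol.success:
            raise RuntimeError(f"window integration failed: {sol.message}")
        y = sol.y[:, -1]
        if connected:
            S[:] = np.clip(y[: S.size].reshape(shape), 0.0, None)
            A[:] = np.clip(y[S.size :].reshape(shape), 0.0, None)
        else:
            S[:] = np.clip(y.reshape(shape), 0.0, None)
        return S, A

    def step_window(self, collect: bool = True):
        """Advance the lattice by one window of length tau.

        Returns (deposited_mask, flux_rows): ``deposited`` marks species/
        columns with active net-downward exchange at window start.
        """
        st = self.state
        S, A = st.surface, st.atmos
        mask = draw_vertical_activity(self.p, self.N, self.nsp, self.rng)
        jmask = np.where(mask, self.j0, 0.0)
        deposited = mask & (A > S) if not self.config.disconnected else np.zeros_like(mask)
        flux_rows = None
        if self.config.record_fluxes and collect:
            jup = np.where(mask, self.j0 * S, 0.0)
            jdown = np.where(mask, self.j0 * A, 0.0) if not self.config.disconnected else np.zeros_like(jup)
            sp_idx, col_idx = np.nonzero(mask)
            flux_rows = [
                (st.t, int(c), int(s), jup[s, c], jdown[s, c], jup[s, c] - jdown[s, c])
                for s, c in zip(sp_idx, col_idx)
            ]
        integrate = (
            self._integrate_window_adaptive
            if self.config.integrator == "adaptive"
            else self._integrate_window_rk4
        )
        if self.config.disconnected:
            integrate(S, A, jmask, self.tau)
            A[:] = 0.0
        elif self.config.advection_mode == "shift" and self.shift >= 1:
            # interleave exchange and advection so a plume passing several
            # columns per window can exchange with each of them en route:
            # the window is split into `shift` legs of one-column shifts
            sub = self.tau / self.shift
            decay_sub = np.exp(-self.delta_a * sub)[:, None]
            for _ in range(self.shift):
                deposited |= mask & (A > S)
                integrate(S, A, jmask, sub)
                A[:] = np.roll(A, 1, axis=-1)
                A *= decay_sub
        else:
            integrate(S, A, jmask, self.tau)
            if self.config.advection_mode == "shift":
                A *= self.decay
            else:
                A[:] = ((1.0 - self.cfl) * A + self.cfl * np.roll(A, 1, axis=-1)) * self.decay
        apply_extinction_threshold(st, self.rho_ext)
        st.t += self.tau
        return deposited, flux_rows

    # -- driver ------------------------------------------------------------
    def run(self, snapshot_path: str | None = None, snapshot_every: float | None = None) -> SimResult:
        cfg = self.config
        nw = cfg.n_windows
        presence = np.zeros((nw + 1, self.nsp, self.N), dtype=bool)
        times = np.arange(nw + 1) * self.tau
        apply_extinction_threshold(self.state, self.rho_ext)
        presence[0] = self.state.surface > 0
        labels = _labels_from_presence(presence[0])
        event_rows: list[tuple] = []
        dep_rows: list[tuple] = []
        flux_all: list[tuple] = []
        snaps: list[tuple[float, np.ndarray, np.ndarray]] = []
        next_snap = 0.0 if snapshot_every is not None else math.inf
        for w in range(nw):
            if self.state.t >= next_snap:
                snaps.append((self.state.t, self.state.surface.copy(), self.state.atmos.copy()))
                next_snap += snapshot_every
            deposited, flux_rows = self.step_window()
            if flux_rows:
                flux_all.extend(flux_rows)
            presence[w + 1] = self.state.surface > 0
            new_labels = _labels_from_presence(presence[w + 1])
            event_rows.extend(
                detect_transitions(labels, new_labels, deposited, w, self.state.t)
            )
            if deposited.any():
                sp_idx, col_idx = np.nonzero(deposited)
                est = presence[w + 1]
                for s, col in zip(sp_idx, col_idx):
                    dep_rows.append(
                        (
                            w,
                            self.state.t,
                            int(col),
                            int(s),
                            _LABEL_NAMES[int(labels[col])],
                            bool(est[s, col]),
                        )
                    )
            labels = new_labels
        events = pd.DataFrame(
            event_rows,
            columns=["window", "t", "column", "before", "after", "dep_host", "dep_phage"],
        )
        if not events.empty:
            events["transition"] = events["before"] + "->" + events["after"]
        else:
            events["transition"] = pd.Series(dtype=str)
        depositions = pd.DataFrame(
            dep_rows,
            columns=["window", "t", "column", "species", "label_before", "established"],
        )
        fluxes = (
            pd.DataFrame(flux_all, columns=["t", "column", "species", "jup", "jdown", "jn"])
            if cfg.record_fluxes
            else None
        )
        result = SimResult(
            config=cfg,
            seed=self.seed,
            times=times,
            presence=presence,
            events=events,
            depositions=depositions,
            final_state=self.state,
            fluxes=fluxes,
        )
        if snapshot_path is not None and snaps:
            _write_snapshots(snapshot_path, snaps)
        return result


def _write_snapshots(path: str, snaps: list[tuple[float, np.ndarray, np.ndarray]]) -> None:
    import h5py

    with h5py.File(path, "w") as fh:
        fh.create_dataset("t", data=np.array([s[0] for s in snaps]))
        # (time, layer, species, column); layer 0 = surface, 1 = atmosphere
        arr = np.stack([np.stack([s[1], s[2]]) for s in snaps])
        fh.create_dataset("density", data=arr)


def run(
    config: RunConfig,
    seed: int,
    snapshot_path: str | None = None,
    snapshot_every: float | None = None,
) -> SimResult:
    """Run one lattice simulation; reproducible given (config, seed)."""
    return LatticeSimulation(config, seed).run(snapshot_path, snapshot_every)
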