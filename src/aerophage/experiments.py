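"""Experiment drivers: EDL extinction ensembles, the (p, j0) phase diagram,
connectivity steady states, migration-outcome statistics and two-phage
competition sweeps.

All drivers are deterministic per (arguments, master seed): replicate and
pixel seeds are spawned from the master seed in a fixed order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig
from .lattice import E, SimResult, run
from .local import COEXISTENCE, coexistence_fixed_point
from .params import LatticeSpec, SpeciesParams, TransportParams

__all__ = [
    "fit_exponential_rate",
    "edl_ensemble",
    "phase_diagram",
    "steady_state_fractions",
    "migration_outcome_stats",
    "competition_sweep",
    "fitness_landscape",
    "CompetitionResult",
]


# ---------------------------------------------------------------------------
# extinction-time statistics
# ---------------------------------------------------------------------------

def fit_exponential_rate(times: np.ndarray, horizon: float) -> dict:
    """Maximum-likelihood exponential extinction rate with right-censoring.

    ``times`` holds one entry per replicate; NaN marks a replicate that had
    not gone extinct by ``horizon`` (censored). The MLE is
    rate = d / (sum of observed times + censored * horizon), with standard
    error rate/sqrt(d). With zero events only an upper bound (rule of three,
    95%) is reported.
    """
    times = np.asarray(times, dtype=float)
    obs = times[~np.isnan(times)]
    d = obs.size
    n_cens = times.size - d
    total_time = float(obs.sum()) + n_cens * horizon
    if d == 0:
        return {
            "rate": 0.0,
            "se": np.nan,
            "n_events": 0,
            "n_censored": n_cens,
            "rate_upper_95": 3.0 / total_time if total_time > 0 else np.nan,
        }
    rate = d / total_time
    return {
        "rate": rate,
        "se": rate / math.sqrt(d),
        "n_events": d,
        "n_censored": n_cens,
        "rate_upper_95": rate + 1.96 * rate / math.sqrt(d),
    }


def exponential_ks_test(times: np.ndarray) -> tuple[float, float]:
    """KS statistic and p-value of observed extinction times against an
    exponential with the fitted rate (estimated-parameter version, slightly
    conservative)."""
    obs = np.asarray(times, dtype=float)
    obs = obs[~np.isnan(obs)]
    lam = 1.0 / obs.mean()
    res = stats.kstest(obs, "expon", args=(0.0, 1.0 / lam))
    return float(res.statistic), float(res.pvalue)


def _single_column_config(
    bact: SpeciesParams,
    phage: SpeciesParams,
    lattice: LatticeSpec,
    p: float,
    j0: float,
    tau: float,
    horizon: float,
    init: str = "fixed_point",
    n_substeps: int = 40,
) -> RunConfig:
    """Ensemble of disconnected columns: N independent single habitats with
    pure aerosolization loss (j_down = 0)."""
    return RunConfig(
        species=(bact, phage),
        transport=TransportParams(v=0.0, p=p, j0=j0, tau=tau),
        lattice=lattice,
        horizon=horizon,
        disconnected=True,
        init=init,
        n_substeps=n_substeps,
    )


def edl_ensemble(
    p_values,
    pj0: float,
    tau: float,
    n_reps: int,
    horizon: float,
    bact: SpeciesParams,
    phage: SpeciesParams,
    V: float = 1.0,
    seed: int = 0,
    species: int = 0,
    init: str = "fixed_point",
    n_substeps: int = 40,
) -> tuple[pd.DataFrame, dict]:
    """Extinction-time ensembles along one equivalent deterministic line
    (p * j0 held fixed; tau fixed, so p * j0 * tau is fixed too).

    For each p, n_reps disconnected habitats are run and the time of first
    extinction of ``species`` (0 = host) is collected; an exponential rate is
    fitted with right-censoring. Returns a per-p summary frame and the raw
    extinction-time samples keyed by p.
    """
    p_values = list(p_values)
    ss = np.random.SeedSequence(seed)
    rows = []
    samples: dict[float, np.ndarray] = {}
    for p, child in zip(p_values, ss.spawn(len(p_values))):
        j0 = pj0 / p
        lattice = LatticeSpec(N=n_reps, dx=1.0, V=V)
        cfg = _single_column_config(
            bact, phage, lattice, p, j0, tau, horizon, init=init, n_substeps=n_substeps
        )
        res = run(cfg, int(child.generate_state(1)[0] % 2**31))
        t_ext = res.extinction_times(species=species)
        samples[p] = t_ext
        fit = fit_exponential_rate(t_ext, horizon)
        rows.append({"p": p, "j0": j0, "pj0": p * j0, "pj0tau": p * j0 * tau, **fit})
    return pd.DataFrame(rows), samples


# ---------------------------------------------------------------------------
# phase diagram
# ---------------------------------------------------------------------------

def phase_diagram(
    p_grid,
    j0_grid,
    n_reps: int,
    t_end: float,
    tau: float,
    bact: SpeciesParams,
    phage: SpeciesParams,
    V: float = 1.0,
    seed: int = 0,
    n_substeps: int = 40,
    init: str = "random",
) -> pd.DataFrame:
    """Ensemble-mean host density and deterministic feasibility class on a
    (p, j0) grid of disconnected habitats.

    The deterministic overlay classifies each pixel from the loss-shifted
    fixed point at r = p * j0: 'deterministically_unstable' (r >= g),
    'phage_free' or 'coexistence'.
    """
    p_grid, j0_grid = list(p_grid), list(j0_grid)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(p_grid) * len(j0_grid)))
    rows = []
    for p in p_grid:
        for j0 in j0_grid:
            rep = coexistence_fixed_point(bact, phage, loss_rate=p * j0)
            cfg = _single_column_config(
                bact,
                phage,
                LatticeSpec(N=n_reps, dx=1.0, V=V),
                p,
                j0,
                tau,
                t_end,
                init=init,
                n_substeps=n_substeps,
            )
            res = run(cfg, int(next(children).generate_state(1)[0] % 2**31))
            mean_ns = float(res.final_state.surface[0].mean())
            rows.append(
                {
                    "p": p,
                    "j0": j0,
                    "pj0": p * j0,
                    "mean_ns": mean_ns,
                    "det_class": rep.feasible,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# connectivity steady states
# ---------------------------------------------------------------------------

def mann_kendall_trend(series: np.ndarray, n_blocks: int = 12) -> float:
    """p-value of a Kendall rank correlation of block means against time,
    used as a stationarity check.

    Block averaging (default 12 blocks) suppresses the strong window-to-window
    autocorrelation of the fraction series, which would otherwise make a rank
    test on the raw series reject stationarity for any finite fluctuation."""
    series = np.asarray(series, dtype=float)
    if series.size > n_blocks:
        edges = np.linspace(0, series.size, n_blocks + 1).astype(int)
        series = np.array([series[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    if np.allclose(series, series[0]):
        return 1.0
    tau_stat, p = stats.kendalltau(np.arange(series.size), series)
    return float(p)


def steady_state_fractions(
    L_values,
    base_config: RunConfig,
    seed: int = 0,
    delta_s_factors=(1.0,),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Post-burn-in mean and sigma of the C/F/E column fractions versus
    connectivity L, optionally for rescaled phage surface decay rates.

    ``delta_s_factors`` multiplies the (single) phage's delta_s: 10.0 is the
    weaker phage, 0.1 the stronger, 1.0 the control. A Kendall trend test on
    the post-burn-in C-fraction series flags runs that have not reached a
    statistical steady state.
    """
    L_values = list(L_values)
    delta_s_factors = list(delta_s_factors)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(L_values) * len(delta_s_factors)))
    rows = []
    for L in L_values:
        for fac in delta_s_factors:
            phages = tuple(
                ph.with_(delta_s=ph.delta_s * fac, delta_a=0.0) for ph in base_config.phages
            )
            cfg = base_config.with_connectivity(L, species=(base_config.bacterium,) + phages)
            res = run(cfg, int(next(children).generate_state(1)[0] % 2**31))
            frac = res.fractions(burn_in=cfg.burn_in)
            row = {"L": L, "delta_s_factor": fac}
            for cls in ("C", "F", "E"):
                row[f"{cls}_mean"] = float(frac[cls].mean())
                row[f"{cls}_sigma"] = float(frac[cls].std())
            p_trend = mann_kendall_trend(frac["C"].to_numpy())
            row["trend_p"] = p_trend
            row["stationary"] = bool(p_trend > alpha)
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# migration outcome statistics
# ---------------------------------------------------------------------------

def migration_outcome_stats(
    result: SimResult,
    attribution_window: float,
    established_only: bool = True,
) -> dict:
    """Per-transition counts and the conditional extinction probability of
    phage migrations into phage-free habitats.

    A qualifying event is a window with active net-downward phage flux into a
    column labelled F at window start (by default only counting migrations
    whose phage population is present at window end, i.e. at least one
    individual arrived). The outcome is 'extinction' if the column reaches E
    within ``attribution_window`` after the event, the time for the
    deterministic post-migration transient to resolve.
    """
    labels = result.labels
    tau = result.config.transport.tau
    k = max(1, int(round(attribution_window / tau)))
    counts = result.events["transition"].value_counts().to_dict() if not result.events.empty else {}
    dep = result.depositions
    out = {"transition_counts": counts}
    if dep.empty:
        out.update(n_migrations=0, n_extinct=np.nan, fraction_extinct=np.nan)
        return out
    sel = (dep["species"] > 0) & (dep["label_before"] == "F")
    if established_only:
        sel &= dep["established"]
    events = dep[sel]
    n_windows = labels.shape[0] - 1
    n_ext = 0
    n_eval = 0
    for w, col in zip(events["window"].to_numpy(), events["column"].to_numpy()):
        stop = min(w + 1 + k, n_windows + 1)
        if stop <= w + 1:
            continue
        n_eval += 1
        if (labels[w + 1 : stop, col] == E).any():
            n_ext += 1
    out["n_migrations"] = int(n_eval)
    out["n_extinct"] = int(n_ext)
    if n_eval > 0:
        out["fraction_extinct"] = n_ext / n_eval
        ci = stats.binomtest(n_ext, n_eval).proportion_ci(confidence_level=0.99)
        out["ci99"] = (float(ci.low), float(ci.high))
    else:
        out["fraction_extinct"] = np.nan
    return out


# ---------------------------------------------------------------------------
# two-phage competition
# ---------------------------------------------------------------------------

@dataclass
class CompetitionResult:
    """Occupancy of the weaker strain across a delta_s ratio sweep."""

    table: pd.DataFrame  # per-ratio rows
    Cw_max: float
    optimal_ratio: float

    @property
    def nonmonotone(self) -> bool:
        cw = self.table["Cw"].to_numpy()
        i = int(np.argmax(cw))
        return 0 < i < len(cw) - 1 and cw[i] > cw[0] and cw[i] > cw[-1]


def feasibility_limit_ratio(bact: SpeciesParams, phage_strong: SpeciesParams) -> float:
    """Largest delta_s ratio for which the weak strain's local coexistence
    fixed point is still feasible: delta_s_w < (beta - 1) eta K."""
    return (phage_strong.beta - 1.0) * phage_strong.eta * bact.K / phage_strong.delta_s


def competition_sweep(
    ratio_grid,
    L: float,
    base_config: RunConfig,
    delta_s_strong: float,
    seed: int = 0,
) -> CompetitionResult:
    """Spatial steady-state occupancy Cw of the weaker phage strain for a grid
    of decay-rate ratios delta_s_w / delta_s_strong.

    ``base_config`` supplies the host, one template phage, transport and
    lattice; the sweep replaces the phage table with a (strong, weak) pair.
    Ratios beyond the deterministic feasibility limit are not simulated:
    the weak strain cannot even persist locally, so Cw is recorded as 0 and
    marked infeasible.
    """
    ratio_grid = list(ratio_grid)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(ratio_grid)))
    template = base_config.phages[0]
    strong = template.with_(delta_s=delta_s_strong, name="phage_strong")
    limit = feasibility_limit_ratio(base_config.bacterium, strong)
    rows = []
    for ratio in ratio_grid:
        child = next(children)
        weak = template.with_(delta_s=delta_s_strong * ratio, name="phage_weak")
        if ratio >= limit:
            rows.append(
                {"ratio": ratio, "Cw": 0.0, "Cstr": np.nan, "shared": np.nan, "feasible": False}
            )
            continue
        cfg = base_config.with_connectivity(L, species=(base_config.bacterium, strong, weak)).with_(init="mosaic")
        res = run(cfg, int(child.generate_state(1)[0] % 2**31))
        keep = res.times >= cfg.burn_in
        pres = res.presence[keep]
        cw = float(pres[:, 2, :].mean())
        cs = float(pres[:, 1, :].mean())
        shared = float((pres[:, 1, :] & pres[:, 2, :]).mean())
        rows.append({"ratio": ratio, "Cw": cw, "Cstr": cs, "shared": shared, "feasible": True})
    table = pd.DataFrame(rows)
    imax = int(table["Cw"].idxmax())
    return CompetitionResult(
        table=table,
        Cw_max=float(table["Cw"].max()),
        optimal_ratio=float(table.loc[imax, "ratio"]),
    )


def fitness_landscape(
    p_grid,
    j0_grid,
    L: float,
    ratio_grid,
    base_config: RunConfig,
    delta_s_strong: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Optimal weak-strain decay ratio and dominance indicator per (p, j0)
    pixel at fixed connectivity L.

    Pixels in the deterministically unstable region (p * j0 >= g) are masked.
    Dominance means the weaker strain occupies more habitats than the
    stronger at the optimum.
    """
    p_grid, j0_grid = list(p_grid), list(j0_grid)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(p_grid) * len(j0_grid)))
    g = base_config.bacterium.g
    rows = []
    for p in p_grid:
        for j0 in j0_grid:
            child = next(children)
            if p * j0 >= g:
                rows.append(
                    {
                        "p": p,
                        "j0": j0,
                        "masked": True,
                        "optimal_ratio": np.nan,
                        "Cw_max": np.nan,
                        "dominant": False,
                    }
                )
                continue
            cfg = base_config.with_(
                transport=TransportParams(
                    v=base_config.transport.v, p=p, j0=j0, tau=base_config.transport.tau
                )
            )
            comp = competition_sweep(
                ratio_grid, L, cfg, delta_s_strong, seed=int(child.generate_state(1)[0] % 2**31)
            )
            best = comp.table.loc[comp.table["Cw"].idxmax()]
            dominant = bool(
                comp.Cw_max > 0
                and np.isfinite(best["Cstr"])
                and best["Cw"] > best["Cstr"]
            )
            rows.append(
                {
                    "p": p,
                    "j0": j0,
                    "masked": False,
                    "optimal_ratio": comp.optimal_ratio,
                    "Cw_max": comp.Cw_max,
                    "dominant": dominant,
                }
            )
    return pd.DataFrame(rows)
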