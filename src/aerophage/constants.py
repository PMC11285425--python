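"""Canonical parameter sets and ready-made experiment fixtures.

Two scales are provided for every figure-class experiment:

``full``
    SI units (seconds, metres): p = 1e-4, j0 = 6e-3 s^-1, N = 1000, L = 0.5
    for the connected-mosaic run; (p, j0) = (0.1, 3.2)e-3 for the competition
    sweep; 150 / 350-year horizons; biological rates at field-realistic
    magnitudes (host generation time ~1 day, burst size 50, phage surface
    half-life ~20 days, K/rho_ext = 1e5).

``desk``
    An accelerated set for desktop-scale runs and the test suite. The time
    unit is one host generation (g = 1) and the exchange window tau is one
    time unit, which preserves the governing dimensionless ratios of the
    full-scale set (beta, K/rho_ext, delta_s/g, p, j0*tau, p*j0/g, L) while
    keeping window counts tractable. Desk lattices use N = 200.

All fixtures read from this module only; no numeric defaults are duplicated
elsewhere.
"""

from __future__ import annotations

from .config import RunConfig, validate_config
from .params import LatticeSpec, SpeciesParams, TransportParams

__all__ = ["YEAR", "FULL", "DESK", "make_fixture", "desk_bacterium", "desk_phage", "desk_lattice"]

#: seconds per (Julian) year, used to express full-scale horizons
YEAR = 3.15576e7

# ---------------------------------------------------------------------------
# full scale (SI)
# ---------------------------------------------------------------------------
FULL = {
    "g": 1.2e-5,  # s^-1, host generation ~ 1 day
    "K": 1.0e5,  # individuals per grid box (V = 1, rho_ext = 1)
    "V": 1.0,
    "beta": 50.0,
    "eta": 2.0e-12,  # box volume per second; (beta-1) eta K = 9.8e-6 s^-1
    "delta_s": 4.0e-7,  # s^-1, surface half-life ~ 20 days; ns*/K = 0.041
    "v": 1.0,  # m/s
    "dx": 10.0,  # m; v tau / dx = 60 columns per window
    "tau": 600.0,  # s, duration of one exchange window
    "N": 1000,
    "fig2": {"pj0tau": 1.6e-5, "p_stochastic": 1e-4, "horizon": 150 * YEAR},
    "fig3": {"n_reps": 1000, "t_end": 150 * YEAR},
    "fig4": {"p": 1e-4, "j0": 6e-3, "L": 0.5, "horizon": 350 * YEAR, "burn_in": 50 * YEAR},
    "fig5": {"L_values": [0.1, 0.25, 0.5, 1.0], "horizon": 350 * YEAR, "burn_in": 50 * YEAR},
    "fig6": {"p": 1e-4, "j0": 3.2e-3, "L": 0.1, "ratio_range": (1e1, 1e5)},
}

# ---------------------------------------------------------------------------
# desk scale (time unit = one host generation, g = 1)
# ---------------------------------------------------------------------------
# The desk set keeps the full-scale dimensionless ratios: beta = 50,
# K/rho_ext = 1e5, ns*/K = delta_s/((beta-1) eta K) = 0.04, kick size
# j0 tau = 3 (full: 3.6), deterministic loss p j0 / g = 0.03 (full: 0.05),
# exchange events per relaxation time p tau_per / tau = 0.5 (full: 0.68),
# and plume transit L N dx / (v tau) = 10 windows (full: 8.3).
DESK = {
    "g": 1.0,
    "K": 1.0e5,
    "V": 1.0,
    "beta": 50.0,
    # (beta - 1) * eta * K = 5, so ns* = delta_s K / 5 and the weak-strain
    # feasibility limit sits at delta_s = 5
    "eta": 5.0 / (49.0 * 1.0e5),
    "delta_s": 0.2,  # tau_per = 2 K (beta-1) eta / (g delta_s) = 50
    "v": 10.0,  # columns per window
    "dx": 1.0,
    "tau": 1.0,
    "N": 200,
    "fig2": {"pj0": 0.04, "p_values": [0.005, 0.01, 0.02, 1.0], "n_reps": 300, "horizon": 2500.0},
    "fig3": {"n_reps": 100, "t_end": 1000.0},
    "fig4": {"p": 0.01, "j0": 3.0, "L": 0.5, "horizon": 4000.0, "burn_in": 1500.0},
    "fig5": {"L_values": [0.1, 0.25, 0.5, 1.0], "horizon": 4000.0, "burn_in": 1500.0},
    "fig6": {
        "p": 0.01,
        "j0": 1.6,
        "L": 0.1,
        "delta_s_strong": 0.002,
        "ratios": [10.0, 31.6, 100.0, 316.0, 1000.0, 3162.0, 10000.0, 100000.0],
        "horizon": 3000.0,
        "burn_in": 1000.0,
        "N": 200,
    },
}


def desk_bacterium() -> SpeciesParams:
    return SpeciesParams.bacterium(g=DESK["g"], K=DESK["K"])


def desk_phage(delta_s: float | None = None, name: str = "phage") -> SpeciesParams:
    return SpeciesParams.phage(
        eta=DESK["eta"],
        beta=DESK["beta"],
        delta_s=DESK["delta_s"] if delta_s is None else delta_s,
        name=name,
    )


def desk_lattice(N: int | None = None) -> LatticeSpec:
    return LatticeSpec(N=DESK["N"] if N is None else N, dx=DESK["dx"], V=DESK["V"])


def _species_docs(c: dict, delta_s: float | None = None) -> list[dict]:
    return [
        {"role": "bacterium", "name": "bacteria", "g": c["g"], "K": c["K"]},
        {
            "role": "phage",
            "name": "phage",
            "eta": c["eta"],
            "beta": c["beta"],
            "delta_s": c["delta_s"] if delta_s is None else delta_s,
        },
    ]


def make_fixture(tag: str, scale: str = "desk") -> dict:
    """Ready-made configuration document for one figure-class experiment.

    Returns a dict with a ``config`` block (validating RunConfig document for
    the lattice run, where one applies) and a ``driver`` block with the sweep
    settings the corresponding experiment driver takes. ``scale`` is ``desk``
    or ``full``.
    """
    if scale not in ("desk", "full"):
        raise ValueError(f"unknown scale {scale!r}")
    c = FULL if scale == "full" else DESK
    if tag not in ("fig2", "fig3", "fig4", "fig5", "fig6"):
        raise ValueError(f"unknown experiment tag {tag!r}")
    sub = c[tag]
    if tag == "fig2":
        driver = dict(sub)
        driver["tau"] = c["tau"]
        if scale == "full":
            driver["pj0"] = sub["pj0tau"] / c["tau"]
            driver["p_values"] = [sub["p_stochastic"], 1.0]
            driver["n_reps"] = 1000
        return {
            "experiment": "fig2",
            "scale": scale,
            "species": _species_docs(c),
            "V": c["V"],
            "driver": driver,
        }
    if tag == "fig3":
        return {
            "experiment": "fig3",
            "scale": scale,
            "species": _species_docs(c),
            "V": c["V"],
            "driver": {**sub, "tau": c["tau"]},
        }
    if tag in ("fig4", "fig5"):
        N = c["N"]
        horizon, burn_in = sub["horizon"], sub["burn_in"]
        p = sub.get("p", c["fig4"]["p"])
        j0 = sub.get("j0", c["fig4"]["j0"])
        config = {
            "species": _species_docs(c),
            "transport": {"v": c["v"], "p": p, "j0": j0, "tau": c["tau"]},
            "lattice": {"N": N, "dx": c["dx"], "V": c["V"]},
            "horizon": horizon,
            "burn_in": burn_in,
            "experiment": tag,
        }
        if tag == "fig4":
            config["L"] = sub["L"]
            driver = {"attribution_tau_per": 20.0}
        else:
            driver = {"L_values": sub["L_values"], "delta_s_factors": [1.0, 10.0, 0.1]}
        validate_config(config)
        return {"experiment": tag, "scale": scale, "config": config, "driver": driver}
    # fig6
    N = sub.get("N", c["N"])
    config = {
        "species": _species_docs(c),
        "transport": {"v": c["v"], "p": sub["p"], "j0": sub["j0"], "tau": c["tau"]},
        "lattice": {"N": N, "dx": c["dx"], "V": c["V"]},
        "horizon": sub.get("horizon", c["fig4"]["horizon"]),
        "burn_in": sub.get("burn_in", c["fig4"]["burn_in"]),
        "experiment": "fig6",
    }
    validate_config(config)
    driver = {
        "L": sub["L"],
        "delta_s_strong": sub.get("delta_s_strong", c["delta_s"] * 1e-2),
        "ratios": list(sub.get("ratios", [])) or list(sub.get("ratio_range", [])),
    }
    return {"experiment": "fig6", "scale": scale, "config": config, "driver": driver}
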