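"""Run configuration: validation, canonical JSON round-trip and TOML reading.

A run is fully specified by (RunConfig, master seed). The connectivity L, when
given, overrides the per-species atmospheric decay rate via the pulse-travel
relation (see :func:`aerophage.transport.delta_a_for_connectivity`); supplying
both L and an explicit nonzero delta_a is a conflict.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import dataclass, replace

from .params import LatticeSpec, ParamError, SpeciesParams, TransportParams
from .transport import delta_a_for_connectivity

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Raised with the exhaustive list of config violations."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(self.errors))


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one lattice simulation.

    ``species`` lists exactly one bacterium first, then >= 1 phage strains.
    ``rho_ext`` defaults to 1/V; pass 0.0 to disable the extinction threshold
    (densities then stay continuous and C becomes absorbing).
    ``disconnected`` drops the deposition flux (j_down = 0) and empties the
    atmosphere each window: habitats become independent and vertical transport
    is a pure surface loss.
    """

    species: tuple[SpeciesParams, ...]
    transport: TransportParams
    lattice: LatticeSpec
    horizon: float
    L: float | None = None
    burn_in: float = 0.0
    rho_ext: float | None = None
    disconnected: bool = False
    n_substeps: int = 40
    integrator: str = "rk4"
    rtol: float = 1e-8
    atol: float = 1e-12
    advection_mode: str = "shift"
    init: str = "random"
    init_phage_factor: float = 2.0
    record_fluxes: bool = False
    experiment: str = ""

    def __post_init__(self) -> None:
        errs = _collect_errors(self)
        if errs:
            raise ConfigError(errs)
        if self.L is not None:
            bact = self.species[0]
            da = delta_a_for_connectivity(
                self.L,
                self.lattice.N,
                self.lattice.dx,
                self.transport.v,
                self.resolved_rho_ext if self.resolved_rho_ext > 0 else 1.0 / self.lattice.V,
                bact.K,
            )
            object.__setattr__(
                self, "species", tuple(sp.with_(delta_a=da) for sp in self.species)
            )

    @property
    def bacterium(self) -> SpeciesParams:
        return self.species[0]

    @property
    def phages(self) -> tuple[SpeciesParams, ...]:
        return self.species[1:]

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def resolved_rho_ext(self) -> float:
        return self.lattice.rho_ext if self.rho_ext is None else self.rho_ext

    @property
    def n_windows(self) -> int:
        return int(round(self.horizon / self.transport.tau))

    def with_(self, **kw) -> "RunConfig":
        new_L = kw.get("L", self.L)
        if new_L is not None and "species" not in kw:
            # species delta_a was derived from L; clear it so the new config
            # re-derives instead of flagging a conflict
            kw["species"] = tuple(sp.with_(delta_a=0.0) for sp in self.species)
        return replace(self, **kw)

    def with_connectivity(self, L: float, species: tuple[SpeciesParams, ...] | None = None) -> "RunConfig":
        """Copy with connectivity L (re-deriving delta_a), clearing any
        delta_a previously derived on the species table."""
        sp = tuple((species or self.species))
        sp = tuple(s.with_(delta_a=0.0) for s in sp)
        return replace(self, species=sp, L=L)

    def to_dict(self) -> dict:
        d = {
            "species": [sp.to_dict() for sp in self.species],
            "transport": self.transport.to_dict(),
            "lattice": self.lattice.to_dict(),
            "horizon": self.horizon,
            "burn_in": self.burn_in,
            "disconnected": self.disconnected,
            "n_substeps": self.n_substeps,
            "integrator": self.integrator,
            "rtol": self.rtol,
            "atol": self.atol,
            "advection_mode": self.advection_mode,
            "init": self.init,
            "init_phage_factor": self.init_phage_factor,
            "record_fluxes": self.record_fluxes,
            "experiment": self.experiment,
        }
        if self.L is not None:
            d["L"] = self.L
            # delta_a was derived from L; drop it from species so round-trip
            # re-derives identically
            for sp in d["species"]:
                sp.pop("delta_a", None)
        if self.rho_ext is not None:
            d["rho_ext"] = self.rho_ext
        return d


def _collect_errors(cfg: RunConfig) -> list[str]:
    errs: list[str] = []
    roles = [sp.role for sp in cfg.species]
    if roles.count("bacterium") != 1:
        errs.append(f"species: exactly one bacterium required, got {roles.count('bacterium')}")
    elif roles[0] != "bacterium":
        errs.append("species: the bacterium must be listed first")
    if roles.count("phage") < 1:
        errs.append("species: at least one phage strain required")
    if cfg.horizon <= 0:
        errs.append("horizon: must be > 0")
    if cfg.burn_in < 0 or cfg.burn_in >= cfg.horizon:
        errs.append("burn_in: must be in [0, horizon)")
    if cfg.rho_ext is not None and cfg.rho_ext < 0:
        errs.append("rho_ext: must be >= 0 (0 disables the threshold)")
    if cfg.L is not None:
        if cfg.L <= 0:
            errs.append("L: must be > 0")
        if any(sp.delta_a != 0.0 for sp in cfg.species):
            errs.append("L and explicit species delta_a both supplied: conflicting")
        if cfg.transport.v <= 0:
            errs.append("L: requires advection speed v > 0")
    if cfg.n_substeps < 1:
        errs.append("n_substeps: must be >= 1")
    if cfg.integrator not in ("rk4", "adaptive"):
        errs.append(f"integrator: unknown {cfg.integrator!r}")
    if cfg.advection_mode not in ("shift", "upwind"):
        errs.append(f"advection_mode: unknown {cfg.advection_mode!r}")
    if cfg.init not in ("random", "mosaic", "fixed_point"):
        errs.append(f"init: unknown {cfg.init!r}")
    return errs


def validate_config(doc: dict) -> RunConfig:
    """Build a RunConfig from a raw (already parsed) document, reporting every
    violated invariant with its field path."""
    errs: list[str] = []
    species: list[SpeciesParams] = []
    for i, raw in enumerate(doc.get("species", [])):
        try:
            species.append(SpeciesParams(**raw))
        except (ParamError, TypeError) as e:
            errs.append(f"species[{i}]: {e}")
    try:
        transport = TransportParams(**doc["transport"])
    except KeyError:
        errs.append("transport: missing")
        transport = None
    except (ParamError, TypeError) as e:
        errs.append(f"transport: {e}")
        transport = None
    try:
        lattice = LatticeSpec(**doc["lattice"])
    except KeyError:
        errs.append("lattice: missing")
        lattice = None
    except (ParamError, TypeError) as e:
        errs.append(f"lattice: {e}")
        lattice = None
    if "horizon" not in doc:
        errs.append("horizon: missing")
    if errs:
        raise ConfigError(errs)
    kw = {
        k: doc[k]
        for k in (
            "horizon",
            "L",
            "burn_in",
            "rho_ext",
            "disconnected",
            "n_substeps",
            "integrator",
            "rtol",
            "atol",
            "advection_mode",
            "init",
            "init_phage_factor",
            "record_fluxes",
            "experiment",
        )
        if k in doc
    }
    return RunConfig(species=tuple(species), transport=transport, lattice=lattice, **kw)


def dump_config(cfg: RunConfig) -> str:
    """Canonical JSON serialization (sorted keys, stable floats): writing,
    reading back and writing again is byte-identical."""
    return json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n"


def load_config(path) -> RunConfig:
    """Read a config document from a .json or .toml file."""
    path = str(path)
    if path.endswith(".toml"):
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    else:
        with open(path) as fh:
            doc = json.load(fh)
    return validate_config(doc)
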