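"""Parameter containers for species biology, vertical/horizontal transport and lattice
geometry.

Units: every rate is expressed per unit of the configuration's time unit (the
canonical full-scale set uses seconds; the desk-scale set uses one bacterial
generation time, ``1/g``). Densities are individuals per grid-box volume ``V``,
so the extinction threshold is ``rho_ext = 1/V``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

__all__ = ["SpeciesParams", "TransportParams", "LatticeSpec", "ParamError"]


class ParamError(ValueError):
    """Raised when a parameter container violates one of its invariants."""


@dataclass(frozen=True)
class SpeciesParams:
    """Biological rates of one bacterial or phage strain.

    Parameters
    ----------
    role : {'bacterium', 'phage'}
    name : str
        Identifier used in event logs and output tables.
    g : float, optional
        Maximum logistic growth rate (time^-1). Bacteria only.
    K : float, optional
        Carrying capacity (density). Bacteria only.
    eta : float, optional
        Adsorption rate (volume * time^-1), the mass-action kernel of
        phage-host encounter. Phage only.
    beta : float, optional
        Burst size (progeny per lysed cell), must be >= 2 so the net
        replication factor (beta - 1) is positive. Phage only.
    delta_s : float, optional
        Surface decay rate (time^-1). Phage only.
    delta_a : float
        Atmospheric decay rate (time^-1). Both roles. Usually overridden by
        the connectivity calibration (see
        :func:`aerophage.transport.delta_a_for_connectivity`).
    """

    role: str
    name: str = ""
    g: float | None = None
    K: float | None = None
    eta: float | None = None
    beta: float | None = None
    delta_s: float | None = None
    delta_a: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ("bacterium", "phage"):
            raise ParamError(f"role must be 'bacterium' or 'phage', got {self.role!r}")
        if self.delta_a < 0:
            raise ParamError("delta_a must be >= 0")
        if self.role == "bacterium":
            if self.g is None or self.K is None:
                raise ParamError("bacterium requires g and K")
            if self.g < 0:
                raise ParamError("g must be >= 0")
            if self.K <= 0:
                raise ParamError("K must be > 0")
            for f in ("eta", "beta", "delta_s"):
                if getattr(self, f) is not None:
                    raise ParamError(f"bacterium does not take {f}")
        else:
            if self.eta is None or self.beta is None or self.delta_s is None:
                raise ParamError("phage requires eta, beta and delta_s")
            if self.eta < 0:
                raise ParamError("eta must be >= 0")
            if self.beta < 2:
                raise ParamError("beta must be >= 2 so that (beta - 1) > 0")
            if self.delta_s < 0:
                raise ParamError("delta_s must be >= 0")
            for f in ("g", "K"):
                if getattr(self, f) is not None:
                    raise ParamError(f"phage does not take {f}")

    @classmethod
    def bacterium(cls, g: float, K: float, delta_a: float = 0.0, name: str = "bacteria") -> "SpeciesParams":
        return cls(role="bacterium", name=name, g=g, K=K, delta_a=delta_a)

    @classmethod
    def phage(
        cls,
        eta: float,
        beta: float,
        delta_s: float,
        delta_a: float = 0.0,
        name: str = "phage",
    ) -> "SpeciesParams":
        return cls(role="phage", name=name, eta=eta, beta=beta, delta_s=delta_s, delta_a=delta_a)

    def with_(self, **kw) -> "SpeciesParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kw)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None:
                out[f.name] = v
        return out


@dataclass(frozen=True)
class TransportParams:
    """Stochastic vertical-exchange regime and horizontal advection.

    ``p`` is the probability that a column exchanges biomass with the layer
    above during one window of duration ``tau``; when active, exchange runs at
    the density-proportional rate ``j0`` down the vertical gradient. ``v`` is
    the constant horizontal advection speed of the upper layer.
    """

    v: float
    p: float
    j0: float
    tau: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ParamError(f"p out of [0,1]: {self.p}")
        if self.j0 < 0:
            raise ParamError("j0 must be >= 0")
        if self.tau <= 0:
            raise ParamError("tau must be > 0")
        if self.v < 0:
            raise ParamError("v must be >= 0")

    def to_dict(self) -> dict:
        return {"v": self.v, "p": self.p, "j0": self.j0, "tau": self.tau}


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the quasi-1D, periodic two-layer lattice.

    ``N`` columns of width ``dx``; each grid box has volume ``V``, so one
    individual per box corresponds to the density ``rho_ext = 1/V``, which is
    the extinction threshold making populations effectively integer.
    """

    N: int
    dx: float
    V: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ParamError("N must be >= 1")
        if self.dx <= 0:
            raise ParamError("dx must be > 0")
        if self.V <= 0:
            raise ParamError("V must be > 0")

    @property
    def rho_ext(self) -> float:
        return 1.0 / self.V

    @property
    def length(self) -> float:
        return self.N * self.dx

    def to_dict(self) -> dict:
        return {"N": self.N, "dx": self.dx, "V": self.V}
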