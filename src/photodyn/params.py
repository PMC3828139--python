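"""Model parameters of the dynamical-adaptation (DA) photoreceptor model.

The model describes the photoreceptor response R(t) (membrane potential
relative to the dark resting potential, in mV) to a light intensity I(t)
via

    tau_r dR/dt = alpha_signed * y(t) - (1 + beta * z(t)) * R(t)

where y and z are versions of I filtered by two unit-area gamma kernels.
Vertebrate photoreceptors hyperpolarize in the light, so the effective
gain ``alpha_signed`` is negative; ``ModelParams.alpha`` stores its
magnitude, which lets the published parameter tables be used verbatim.

Canonical internal units are milliseconds and photons/um^2/ms.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Optional

_POSITIVE_FIELDS = ("beta", "gamma", "tau_r", "n_y", "tau_y", "n_z", "tau_z")


@dataclass(frozen=True)
class ModelParams:
    """The eight DA-model parameters.

    Attributes
    ----------
    alpha : float
        Response gain magnitude, mV * um^2 * ms / photon. The model applies
        the hyperpolarizing (negative) sign internally.
    beta : float
        Nonlinearity strength, (photons/um^2/ms)^-1. ``beta * z`` is the
        dimensionless divisive gain term; the steady response to constant
        light saturates at magnitude ``alpha / beta``.
    gamma : float
        Weight in [0, 1] of the fast component of the gain-control kernel
        Kz; the remaining 1 - gamma weights the slow gamma kernel.
    tau_r : float
        Relaxation time of the response, ms.
    n_y, tau_y : float
        Shape exponent (>= 0, possibly non-integer) and time constant (ms)
        of the drive kernel Ky ~ t^n_y exp(-t/tau_y); Ky peaks at
        n_y * tau_y.
    n_z, tau_z : float
        Same for the slow component of Kz.
    label : str
        Name of the parameter set.
    """

    alpha: float
    beta: float
    gamma: float
    tau_r: float
    n_y: float
    tau_y: float
    n_z: float
    tau_z: float
    label: str = ""
    units: str = "ms, photons/um^2/ms, mV"
    notes: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha is stored as a positive magnitude")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.gamma > 1:
            raise ValueError(f"gamma must be <= 1, got {self.gamma}")
        if self.tau_y <= 0 or self.tau_z <= 0 or self.tau_r <= 0:
            raise ValueError("time constants must be > 0")

    @property
    def alpha_signed(self) -> float:
        """Gain with the hyperpolarizing sign applied."""
        return -self.alpha

    @property
    def saturation_mv(self) -> float:
        """Magnitude of the steady response to infinitely bright light, mV."""
        return self.alpha / self.beta if self.beta > 0 else float("inf")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    # ----- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> Optional[str]:
        s = json.dumps(self.to_dict(), indent=2)
        if path is None:
            return s
        with open(path, "w") as fh:
            fh.write(s + "\n")
        return None

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    @classmethod
    def from_json(cls, source) -> "ModelParams":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))


def load_paramset(name: str) -> ModelParams:
    """Load one of the packaged published parameter sets.

    Available names: ``salamander``, ``bhl``, ``b``, ``dn`` (case
    insensitive; the labels refer to the data sources the sets were fitted
    to: salamander cone flicker recordings, and the turtle-cone experiments
    of Baylor/Hodgkin/Lamb, Burkhardt, and Daly/Normann).
    """
    key = name.strip().lower()
    fname = f"{key}.json"
    pkg = resources.files("photodyn") / "data"
    path = pkg / fname
    if not path.is_file():
        avail = sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))
        raise KeyError(f"unknown parameter set {name!r}; available: {avail}")
    return ModelParams.from_json(path.read_text())


def available_paramsets() -> list[str]:
    pkg = resources.files("photodyn") / "data"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".json"))
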