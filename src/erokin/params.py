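"""Parameter containers and formulation presets.

The degradation of a PLGA microsphere is summarised by four kinetic
constants: a lumped initial-degradation-rate parameter ``B0`` (day^-1), a
dimensionless acid-polymer affinity parameter ``psi``, an induction time
``t_ind`` (day) before measurable mass loss, and a first-order
molecular-weight decay constant ``k_deg`` (day^-1).  A fifth constant,
``alpha`` (day^-1), sets the sharpness of the smooth switch that turns
erosion on around ``t_ind``; it is a fixed model constant, not a fitted
quantity.

``B0`` and ``psi`` are composites of dimensional quantities (microsphere
volume and mass, molecular weights, Michaelis-type constant and initial
rate); :class:`PhysicalParams` holds those and :func:`derive_b0_psi`
performs the reduction.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

__all__ = [
    "ModelParams",
    "PhysicalParams",
    "Geometry",
    "Preset",
    "PRESETS",
    "derive_b0_psi",
    "get_preset",
    "load_presets",
    "dump_presets",
]

DEFAULT_ALPHA = 2.5  # day^-1, mollification sharpness of the induction switch


@dataclass(frozen=True)
class ModelParams:
    """Kinetic constants of one formulation.

    Parameters
    ----------
    b0 : float
        Initial degradation rate parameter, day^-1. Non-negative.
    psi : float
        Acid-polymer affinity parameter, dimensionless. Non-negative;
        small values mean a stable acid-polymer complex.
    t_ind : float
        Induction time, day. Non-negative.
    k_deg : float
        First-order molecular-weight decay constant, day^-1.
    alpha : float
        Sharpness of the mollified induction switch, day^-1. Positive.
    """

    b0: float
    psi: float
    t_ind: float
    k_deg: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.b0 < 0:
            raise ValueError(f"b0 must be >= 0, got {self.b0}")
        if self.psi < 0:
            raise ValueError(f"psi must be >= 0, got {self.psi}")
        if self.t_ind < 0:
            raise ValueError(f"t_ind must be >= 0, got {self.t_ind}")
        if self.k_deg < 0:
            raise ValueError(f"k_deg must be >= 0, got {self.k_deg}")
        if not self.alpha > 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "b0": self.b0,
            "psi": self.psi,
            "t_ind": self.t_ind,
            "k_deg": self.k_deg,
            "alpha": self.alpha,
        }


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional quantities from which ``b0`` and ``psi`` derive.

    All strictly positive.  ``K_M = (k_m1 + k2)/k1`` and ``R0 = k2*A0``
    may be given directly or derived from the elementary constants of the
    acid + polymer <-> complex -> acid + soluble-product scheme.
    """

    v_ms: float  # single-microsphere volume, length^3
    mw_s: float  # molecular weight of soluble products, mass/mol
    mw_p0: float  # initial number-average polymer molecular weight, mass/mol
    m_ms0: float  # initial single-microsphere mass, mass
    k_m: float | None = None  # composite constant, concentration
    r0: float | None = None  # initial reaction rate k2*[A]0, concentration/time
    k1: float | None = None
    k_m1: float | None = None
    k2: float | None = None
    a0: float | None = None  # initial acid concentration

    def __post_init__(self) -> None:
        for name in ("v_ms", "mw_s", "mw_p0", "m_ms0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        elem = (self.k1, self.k_m1, self.k2)
        if self.k_m is None:
            if any(v is None for v in elem):
                raise ValueError("either k_m or all of (k1, k_m1, k2) required")
            object.__setattr__(self, "k_m", (self.k_m1 + self.k2) / self.k1)
        elif all(v is not None for v in elem):
            km = (self.k_m1 + self.k2) / self.k1
            if abs(km - self.k_m) > 1e-12 * max(km, self.k_m):
                raise ValueError(
                    f"inconsistent k_m: supplied {self.k_m}, derived {km}"
                )
        if self.r0 is None:
            if self.k2 is None or self.a0 is None:
                raise ValueError("either r0 or both (k2, a0) required")
            object.__setattr__(self, "r0", self.k2 * self.a0)
        for name in ("k_m", "r0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class Geometry:
    """Microsphere geometry: mean radius and nondimensional radius r/R_MS."""

    r_ms: float  # formulation mean microsphere radius, length
    rho: float = 0.0  # nondimensional radius, in [0, 1]

    def __post_init__(self) -> None:
        if not self.r_ms > 0:
            raise ValueError("r_ms must be > 0")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")


def derive_b0_psi(phys: PhysicalParams) -> tuple[float, float]:
    """Reduce the dimensional quantities to the two lumped parameters.

    ``B0 = V_MS * MW_S * R0 / m_MS0`` and
    ``Psi = K_M * V_MS * MW_P0 / m_MS0``.
    """
    b0 = phys.v_ms * phys.mw_s * phys.r0 / phys.m_ms0
    psi = phys.k_m * phys.v_ms * phys.mw_p0 / phys.m_ms0
    return b0, psi


@dataclass(frozen=True)
class Preset:
    """A named formulation: kinetic constants plus mean microsphere radius."""

    name: str
    params: ModelParams
    r_ms_um: float = field(default=float("nan"))


# Best-fit constants for the three emulsion formulations (10/15/20 % w/v
# PLGA in the organic phase).  b0 and psi are the lumped parameters, t_ind
# the induction time, k_deg the independently fitted molecular-weight decay
# constant; r_ms_um is half the formulation's mean particle diameter.
PRESETS: Mapping[str, Preset] = {
    "PLGA10": Preset(
        "PLGA10",
        ModelParams(b0=2.48e-2, psi=2.69e-5, t_ind=3.42, k_deg=0.104),
        r_ms_um=24.3 / 2,
    ),
    "PLGA15": Preset(
        "PLGA15",
        ModelParams(b0=2.72e-2, psi=4.32e-5, t_ind=3.40, k_deg=0.0997),
        r_ms_um=23.0 / 2,
    ),
    "PLGA20": Preset(
        "PLGA20",
        ModelParams(b0=3.46e-2, psi=1.59e-5, t_ind=2.91, k_deg=0.1004),
        r_ms_um=24.1 / 2,
    ),
}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def dump_presets(presets: Mapping[str, Preset], stream=None) -> str | None:
    """Serialise presets to YAML (round-trips through :func:`load_presets`)."""
    doc = {
        name: {"params": p.params.to_dict(), "r_ms_um": p.r_ms_um}
        for name, p in presets.items()
    }
    return yaml.safe_dump(doc, stream, sort_keys=True)


def load_presets(source) -> dict[str, Preset]:
    """Read presets from a YAML path, stream, or string."""
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, str):
        doc = yaml.safe_load(io.StringIO(source))
    else:
        doc = yaml.safe_load(source)
    out = {}
    for name, entry in doc.items():
        out[name] = Preset(
            name=name,
            params=ModelParams(**entry["params"]),
            r_ms_um=float(entry.get("r_ms_um", float("nan"))),
        )
    return out
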