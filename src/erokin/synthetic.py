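"""Synthetic emulation of the two degradation assays.

Real studies of bulk-eroding microspheres produce two time series per
formulation: a gravimetric mass-loss series (residual polymer weighed after
solvent extraction, here expressed as the lost/soluble fraction ``mu_S``)
and a GPC molecular-weight series (number-average molecular weight
normalised to its initial value, ``omega_P``).  This module generates both
from a formulation preset with seeded additive Gaussian noise, so parameter
recovery can be exercised without raw laboratory data.

Noise defaults: sd 0.02 on mass fractions (gravimetric validation errors of
a few percent are typical for this assay) and 0.03 on ``omega_P``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .params import Preset

__all__ = [
    "TimeSeries",
    "KINDS",
    "DEFAULT_TIMES",
    "MASS_NOISE_SD",
    "MW_NOISE_SD",
    "generate_mass_loss",
    "generate_mw_series",
    "generate_front_series",
    "mass_to_front",
    "write_series",
    "read_series",
]

logger = logging.getLogger(__name__)

KINDS = ("mass-fraction", "nondim-MW", "front-radius")

# Sampling days covering the 0-6 week degradation window of the assays.
DEFAULT_TIMES = (0.0, 1.0, 3.0, 7.0, 10.0, 14.0, 21.0, 28.0, 35.0, 42.0)

MASS_NOISE_SD = 0.02
MW_NOISE_SD = 0.03
_MW_FLOOR = 1e-6  # noisy omega_P truncated below at this value


@dataclass(frozen=True)
class TimeSeries:
    """One observed or synthetic experiment.

    ``kind`` tags the measured quantity: ``mass-fraction`` (lost/soluble
    fraction mu_S), ``nondim-MW`` (omega_P) or ``front-radius`` (R_f).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    replicate_id: str = "rep0"
    formulation: str = "custom"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if t.size and (np.any(t < 0) or np.any(np.diff(t) <= 0)):
            raise ValueError("times must be non-negative and strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_day": self.times,
                "value": self.values,
                "kind": self.kind,
                "replicate_id": self.replicate_id,
                "formulation": self.formulation,
            }
        )


def _check_gen_args(times, noise_sd, n_replicates) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    return times


def generate_mass_loss(
    preset: Preset,
    times: Sequence[float] = DEFAULT_TIMES,
    noise_sd: float = MASS_NOISE_SD,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    view: str = "lost",
    dt: float = kinetics.DEFAULT_DT,
) -> list[TimeSeries]:
    """Emulate the gravimetric assay: noisy mass-fraction replicates.

    ``view="lost"`` emits the soluble fraction mu_S (mass lost relative to
    the initial microsphere mass); ``view="residual"`` emits mu_P = 1 - mu_S,
    the fraction the balance actually weighs.  Replicates share the model
    curve and differ only by their noise stream; output is reproducible
    given the seed.
    """
    if view not in ("lost", "residual"):
        raise ValueError(f"view must be 'lost' or 'residual', got {view!r}")
    times = _check_gen_args(times, noise_sd, n_replicates)
    mu_s = kinetics.simulate_mu_s(preset.params, times, dt)
    clean = mu_s if view == "lost" else 1.0 - mu_s
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=times.size)
        out.append(
            TimeSeries(
                times=times,
                values=np.clip(noisy, 0.0, 1.0),
                kind="mass-fraction",
                replicate_id=f"rep{r}",
                formulation=preset.name,
            )
        )
    return out


def generate_mw_series(
    preset: Preset,
    times: Sequence[float] = DEFAULT_TIMES,
    noise_sd: float = MW_NOISE_SD,
    n_replicates: int = 3,
    seed: int = 0,
) -> list[TimeSeries]:
    """Emulate GPC readouts: noisy nondimensional molecular-weight replicates.

    The clean curve is ``omega_P(t) = exp(-k_deg t)`` (unity at t = 0);
    noisy values are truncated below at 1e-6 so log-scale estimators remain
    defined.
    """
    times = _check_gen_args(times, noise_sd, n_replicates)
    clean = kinetics.omega_p(times, preset.params.k_deg)
    clean = np.atleast_1d(clean)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=times.size)
        out.append(
            TimeSeries(
                times=times,
                values=np.maximum(noisy, _MW_FLOOR),
                kind="nondim-MW",
                replicate_id=f"rep{r}",
                formulation=preset.name,
            )
        )
    return out


def generate_front_series(
    preset: Preset,
    times: Sequence[float] = DEFAULT_TIMES,
    noise_sd: float = MASS_NOISE_SD,
    n_replicates: int = 3,
    seed: int = 0,
    *,
    dt: float = kinetics.DEFAULT_DT,
) -> list[TimeSeries]:
    """Front-radius replicates with Gaussian noise applied on the R_f scale.

    Convenience for recovery studies that perturb the derived front radius
    directly rather than the weighed mass fraction; values are clipped to
    [0, 1].
    """
    times = _check_gen_args(times, noise_sd, n_replicates)
    clean = kinetics.simulate_front(preset.params, times, dt)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        noisy = clean + rng.normal(0.0, noise_sd, size=times.size)
        out.append(
            TimeSeries(
                times=times,
                values=np.clip(noisy, 0.0, 1.0),
                kind="front-radius",
                replicate_id=f"rep{r}",
                formulation=preset.name,
            )
        )
    return out


def mass_to_front(series: TimeSeries) -> TimeSeries:
    """Convert a lost-mass-fraction series to a degradation-front series.

    Pointwise ``R_f = mu_S**(1/3)`` from the shell-volume balance
    ``mu_P = 1 - R_f**3``.  Noisy values outside [0, 1] are clipped first
    (a count is logged).
    """
    if series.kind != "mass-fraction":
        raise ValueError(
            f"expected kind 'mass-fraction', got {series.kind!r}"
        )
    vals = series.values
    n_out = int(np.count_nonzero((vals < 0) | (vals > 1)))
    if n_out:
        logger.info("clipped %d out-of-range mass fractions to [0, 1]", n_out)
        vals = np.clip(vals, 0.0, 1.0)
    return replace(series, values=np.cbrt(vals), kind="front-radius")


# --- delimited-text I/O -------------------------------------------------

_COLUMNS = ["time_day", "value", "kind", "replicate_id", "formulation"]


def write_series(series: TimeSeries | Iterable[TimeSeries], path) -> None:
    """Write one or more series to CSV (17 significant digits, round-trip safe)."""
    if isinstance(series, TimeSeries):
        series = [series]
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_series(path) -> list[TimeSeries]:
    """Read CSV written by :func:`write_series`; one TimeSeries per
    (kind, replicate_id, formulation) group, in file order."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    out = []
    for (kind, rep, form), grp in frame.groupby(
        ["kind", "replicate_id", "formulation"], sort=False
    ):
        out.append(
            TimeSeries(
                times=grp["time_day"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                kind=str(kind),
                replicate_id=str(rep),
                formulation=str(form),
            )
        )
    return out
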