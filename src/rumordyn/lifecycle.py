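"""Rumor lifecycle statistics, trust-transfer efficiency, and the
corpus-level stage and hijack analyses.

A rumor-intensity series R(t) defines four landmarks by threshold
crossings relative to its maximum R_max:

    t_e = min{ t : R(t) > 0.1 R_max }           emergence
    t_p = argmax_t R(t)                         peak (earliest, under ties)
    t_d = min{ t > t_p : R(t) < 0.7 R_max }     onset of decline
    t_r = min{ t > t_d : R(t) < 0.2 R_max }     onset of dissipation

with stage durations (t_p - t_e, t_d - t_p, t_r - t_d, t_r - t_e) and
per-stage transition rates (intensity change per unit time).  Inequalities
are strict and landmarks are grid points; no interpolation is done unless
explicitly requested.  A landmark whose condition is never satisfied is an
*undefined* first-class result, not an exception — real series often never
decay below the thresholds within the observation window.

Trust-transfer efficiency quantifies how effectively trust propagates when
refutation is delayed:  T_trans = alpha * C_cred * exp(-beta * D_time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateFitError,
    DegenerateSeriesError,
    InputError,
    MissingStageError,
    PhaseDegenerateError,
)
from .records import CorpusLike, STAGE_ORDER, corpus_to_frame

__all__ = [
    "IntensitySeries",
    "LifecycleTimes",
    "LifecycleDurations",
    "TransitionRates",
    "TrustTransferParams",
    "detect_lifecycle_times",
    "compute_durations",
    "compute_transition_rates",
    "trust_transfer_efficiency",
    "stage_levels",
    "hijack_spread_relation",
    "HijackSpreadFit",
]


@dataclass(frozen=True)
class IntensitySeries:
    """A rumor-intensity time series R(t) on a strictly increasing grid."""

    t: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        r = np.asarray(self.R, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "R", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise InputError("t and R must be 1-D arrays of equal length")
        if t.size == 0:
            raise InputError("series must be non-empty")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError("t must be strictly increasing")
        if np.any(r < 0):
            raise InputError("R must be non-negative")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "R": self.R}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "IntensitySeries":
        frame = pd.read_csv(path)
        return cls(t=frame["t"].to_numpy(), R=frame["R"].to_numpy())


@dataclass(frozen=True)
class LifecycleTimes:
    """Lifecycle landmarks; a landmark is None when its condition is never met."""

    te: float | None
    tp: float | None
    td: float | None
    tr: float | None
    R_max: float

    @property
    def all_defined(self) -> bool:
        return None not in (self.te, self.tp, self.td, self.tr)

    @property
    def undefined(self) -> tuple[str, ...]:
        return tuple(
            name for name, v in (("te", self.te), ("tp", self.tp), ("td", self.td), ("tr", self.tr))
            if v is None
        )


@dataclass(frozen=True)
class LifecycleDurations:
    """Stage durations; None propagates from undefined landmarks."""

    d_emerge: float | None
    d_growthdecline: float | None
    d_decline: float | None
    d_total: float | None


@dataclass(frozen=True)
class TransitionRates:
    """Intensity change per unit time during the three phases."""

    r_eg: float
    r_gd: float
    r_dr: float


def detect_lifecycle_times(
    series: IntensitySeries,
    thresholds: tuple[float, float, float] = (0.1, 0.7, 0.2),
    interpolate: bool = False,
) -> LifecycleTimes:
    """Locate the four lifecycle landmarks of an intensity series.

    ``thresholds`` are the emergence, decline and dissipation fractions of
    R_max.  Comparisons are strict (``>`` for emergence, ``<`` for decline
    and dissipation) and landmarks are grid points; with
    ``interpolate=True`` the threshold crossings t_e, t_d, t_r are refined
    by linear interpolation between the bracketing grid points (t_p stays
    a grid point).
    """
    t, r = series.t, series.R
    r_max = float(r.max())
    if r_max == 0.0:
        raise DegenerateSeriesError("R is identically zero; relative thresholds undefined")
    thr_e, thr_d, thr_r = (th * r_max for th in thresholds)

    def first_cross(mask: np.ndarray, level: float, rising: bool) -> float | None:
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return None
        i = int(idx[0])
        if not interpolate or i == 0:
            return float(t[i])
        r0, r1 = r[i - 1], r[i]
        if r1 == r0:
            return float(t[i])
        frac = (level - r0) / (r1 - r0)
        return float(t[i - 1] + frac * (t[i] - t[i - 1]))

    te = first_cross(r > thr_e, thr_e, rising=True)
    ip = int(np.argmax(r))  # earliest index attaining the maximum
    tp = float(t[ip])
    after_peak = np.zeros_like(r, dtype=bool)
    after_peak[ip + 1 :] = True
    td = first_cross(after_peak & (r < thr_d), thr_d, rising=False)
    tr = None
    if td is not None:
        after_decline = t > (td if interpolate else td)
        tr = first_cross(after_decline & (r < thr_r), thr_r, rising=False)
    return LifecycleTimes(te=te, tp=tp, td=td, tr=tr, R_max=r_max)


def compute_durations(times: LifecycleTimes) -> LifecycleDurations:
    """Stage durations from the landmarks; undefined landmarks propagate."""

    def diff(a: float | None, b: float | None) -> float | None:
        return None if a is None or b is None else b - a

    return LifecycleDurations(
        d_emerge=diff(times.te, times.tp),
        d_growthdecline=diff(times.tp, times.td),
        d_decline=diff(times.td, times.tr),
        d_total=diff(times.te, times.tr),
    )


def _value_at(series: IntensitySeries, t0: float) -> float:
    i = int(np.argmin(np.abs(series.t - t0)))
    return float(np.interp(t0, series.t, series.R)) if series.t[i] != t0 else float(series.R[i])


def compute_transition_rates(series: IntensitySeries, times: LifecycleTimes) -> TransitionRates:
    """Per-phase intensity change rates (R(b) - R(a)) / (b - a)."""
    if not times.all_defined:
        raise InputError(f"landmarks undefined: {', '.join(times.undefined)}")
    pairs = (("emergence-growth", times.te, times.tp),
             ("growth-decline", times.tp, times.td),
             ("decline-dissipation", times.td, times.tr))
    rates = []
    for phase, a, b in pairs:
        if b - a <= 0:
            raise PhaseDegenerateError(phase)
        rates.append((_value_at(series, b) - _value_at(series, a)) / (b - a))
    return TransitionRates(r_eg=rates[0], r_gd=rates[1], r_dr=rates[2])


@dataclass(frozen=True)
class TrustTransferParams:
    """Parameters of the delay-discounted trust-transfer law."""

    alpha_tt: float = 0.8
    beta_tt: float = 0.5
    C_cred: float = 0.9
    D_time: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_tt < 0 or self.beta_tt < 0:
            raise InputError("alpha_tt and beta_tt must be >= 0")
        if not 0.0 <= self.C_cred <= 1.0:
            raise InputError("C_cred must lie in [0, 1]")
        if self.D_time < 0:
            raise InputError("D_time must be >= 0")


def trust_transfer_efficiency(p: TrustTransferParams) -> float:
    """Credibility-scaled, exponentially delay-discounted trust transfer:
    ``alpha * C_cred * exp(-beta * D_time)``."""
    return p.alpha_tt * p.C_cred * math.exp(-p.beta_tt * p.D_time)


def stage_levels(records: CorpusLike) -> pd.DataFrame:
    """Mean trust and rumor level per propagation stage (early, mid, late).

    Every stage must be present; otherwise :class:`MissingStageError`
    lists the absent ones.
    """
    frame = corpus_to_frame(records)
    stage_names = [s.value for s in STAGE_ORDER]
    present = set(frame["stage"].astype(str)) if len(frame) else set()
    missing = [s for s in stage_names if s not in present]
    if missing:
        raise MissingStageError(missing)
    grouped = frame.groupby("stage")[["trust_level", "rumor_level"]].mean()
    out = grouped.loc[stage_names]
    out.columns = ["mean_trust", "mean_rumor"]
    out.index.name = "stage"
    return out


@dataclass(frozen=True)
class HijackSpreadFit:
    """OLS fit of spread intensity on the trust-hijack index with a
    classical homoscedastic pointwise 95 % confidence band."""

    slope: float
    intercept: float
    correlation: float
    x_grid: np.ndarray
    fitted: np.ndarray
    band_low: np.ndarray
    band_high: np.ndarray
    n: int


def hijack_spread_relation(records: CorpusLike, n_grid: int = 100) -> HijackSpreadFit:
    """Fit spread_intensity ~ hijack_index by ordinary least squares."""
    frame = corpus_to_frame(records)
    x = frame["hijack_index"].to_numpy(dtype=float)
    y = frame["spread_intensity"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InputError("need at least 3 records with finite hijack and spread values")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("hijack_index has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    grid = np.linspace(x.min(), x.max(), n_grid)
    pred = model.get_prediction(sm.add_constant(grid)).summary_frame(alpha=0.05)
    sx, sy = np.std(x), np.std(y)
    corr = float(np.corrcoef(x, y)[0, 1]) if sy > 0 else 0.0
    return HijackSpreadFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        correlation=corr,
        x_grid=grid,
        fitted=pred["mean"].to_numpy(),
        band_low=pred["mean_ci_lower"].to_numpy(),
        band_high=pred["mean_ci_upper"].to_numpy(),
        n=int(x.size),
    )
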