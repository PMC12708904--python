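"""ODE models of rumor propagation and trust, plus the intervention
scenario engine.

Extended SIR rumor model
------------------------
Believers B, susceptibles S and immune I (B + S + I = N) evolve as

    dB/dt =  beta * S * B / N  -  delta * eta * B  -  lam * B
    dS/dt = -beta * S * B / N  +  lam * B          +  rho * I
    dI/dt =  delta * eta * B   -  rho * I

with rumor transmission rate beta, refutation intensity delta and
efficiency eta, forgetting rate lam (believers relapse to susceptible) and
reinfection rate rho (immunity wanes).  The right-hand sides sum to zero,
so the population is conserved exactly in real arithmetic (and by any
Runge-Kutta method, which preserves linear invariants).

Coupled trust-rumor model
-------------------------
Trust level T and rumor level R, with external intervention forcing E(t):

    dT/dt = alpha_T * (1 - T) + beta_T * E(t) - gamma_T * R * T
    dR/dt = -delta_R * R - eps_R * E(t) * R - zeta_R * T * R

Every dR/dt term is non-positive, so R is non-increasing whenever the
parameters and forcing are non-negative.  T is deliberately *not* clamped
to [0, 1]: the printed equations permit T > 1 for strong forcing, and
silent clamping would hide parameterisation errors.  Excursions are
flagged on the returned trajectory instead.

Scenario engine
---------------
The published intervention experiment compares believer/trust/panic
trajectories under trust enhancement (+30 %), panic reduction (-20 %),
strengthened debunking (+25 %) and their combination.  No equations are
published for that four-variable system, so the engine closes the stated
causal loops around the two models above:

    spread  = beta0 * (1 + k_P * P) * (1 - k_T * T) * S * B / N
    dP/dt   = a_P * spread / N - d_P * P
    dT/dt   = alpha_T (1 - T) + beta_T E(t) - gamma_T (B/N) T
    B, S, I follow the extended SIR system with beta replaced by the
    effective spread coefficient.

Panic amplifies transmission, trust throttles it, panic is fuelled by the
spread flux and decays on its own, and trust is damaged by believer
prevalence.  An optional health-literacy stock H (dH/dt = g_H (1 - H))
strengthens the trust throttle via k_T * (1 + c_H * H).  Multiplier
attachment points: trust enhancement scales the initial trust (capped at
1), panic reduction scales a_P, strengthened debunking scales delta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ConfigurationError, InputError, IntegrationError

__all__ = [
    "SIRState",
    "SIRParams",
    "TrustRumorState",
    "TrustRumorParams",
    "Trajectory",
    "ScenarioSpec",
    "ScenarioEngineConfig",
    "sir_derivatives",
    "integrate_sir",
    "trust_rumor_derivatives",
    "integrate_trust_rumor",
    "run_scenarios",
    "default_scenarios",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SIRState:
    """Stocks of the extended SIR rumor model; B + S + I must equal N."""

    B: float
    S: float
    I: float
    N: float

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise InputError(f"N must be > 0, got {self.N}")
        if min(self.B, self.S, self.I) < 0:
            raise InputError("stocks must be non-negative")
        if abs(self.B + self.S + self.I - self.N) > 1e-6 * self.N:
            raise InputError("B + S + I must equal N within 1e-6 * N")


@dataclass(frozen=True)
class SIRParams:
    """Rates of the extended SIR rumor model (all non-negative)."""

    beta: float = 0.3
    delta: float = 0.4
    eta: float = 0.5
    lam: float = 0.05
    rho: float = 0.02

    def __post_init__(self) -> None:
        if min(self.beta, self.delta, self.lam, self.rho) < 0:
            raise InputError("rates must be non-negative")
        if not 0.0 <= self.eta <= 1.0:
            raise InputError("eta must lie in [0, 1]")


def sir_derivatives(state: SIRState, params: SIRParams) -> tuple[float, float, float]:
    """Right-hand sides (dB, dS, dI); they sum to zero exactly."""
    contact = params.beta * state.S * state.B / state.N
    debunk = params.delta * params.eta * state.B
    forget = params.lam * state.B
    reinfect = params.rho * state.I
    dB = contact - debunk - forget
    dS = -contact + forget + reinfect
    dI = debunk - reinfect
    return dB, dS, dI


@dataclass(frozen=True)
class TrustRumorState:
    """Trust level T (unbounded) and rumor level R >= 0."""

    T: float
    R: float

    def __post_init__(self) -> None:
        if self.R < 0:
            raise InputError("R must be >= 0")


def _const_zero(t: float) -> float:
    return 0.0


@dataclass(frozen=True)
class TrustRumorParams:
    """Rate constants of the coupled trust-rumor model plus the
    intervention forcing function E(t) >= 0."""

    alpha_T: float = 0.2
    beta_T: float = 0.4
    gamma_T: float = 0.5
    delta_R: float = 0.1
    eps_R: float = 0.3
    zeta_R: float = 0.2
    E_fn: Callable[[float], float] = _const_zero

    def __post_init__(self) -> None:
        rates = (self.alpha_T, self.beta_T, self.gamma_T, self.delta_R, self.eps_R, self.zeta_R)
        if min(rates) < 0:
            raise InputError("rate constants must be non-negative")


def trust_rumor_derivatives(
    state: TrustRumorState, params: TrustRumorParams, t: float = 0.0
) -> tuple[float, float]:
    """Right-hand sides (dT, dR) of the coupled trust-rumor model."""
    E = params.E_fn(t)
    if E < 0:
        raise InputError(f"E(t) must be >= 0, got {E} at t={t}")
    dT = params.alpha_T * (1.0 - state.T) + params.beta_T * E - params.gamma_T * state.R * state.T
    dR = -params.delta_R * state.R - params.eps_R * E * state.R - params.zeta_R * state.T * state.R
    return dT, dR


@dataclass(frozen=True)
class Trajectory:
    """Named state trajectories on a common strictly increasing grid."""

    t: np.ndarray
    columns: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        object.__setattr__(self, "t", t)
        cols = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        object.__setattr__(self, "columns", cols)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InputError("t must be strictly increasing")
        for name, v in cols.items():
            if v.shape != t.shape:
                raise InputError(f"column {name!r} length does not match t")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.columns[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, **self.columns})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _rk4(f: Callable[[float, np.ndarray], np.ndarray], y0: np.ndarray, t_grid: np.ndarray) -> np.ndarray:
    """Classical fixed-step RK4 with the step equal to the grid spacing."""
    ys = np.empty((t_grid.size, y0.size))
    ys[0] = y0
    y = y0.astype(float)
    for i in range(t_grid.size - 1):
        t0, h = t_grid[i], t_grid[i + 1] - t_grid[i]
        k1 = f(t0, y)
        k2 = f(t0 + h / 2, y + h / 2 * k1)
        k3 = f(t0 + h / 2, y + h / 2 * k2)
        k4 = f(t0 + h, y + h * k3)
        y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(float(t_grid[i + 1]))
        ys[i + 1] = y
    return ys


def _integrate(
    f: Callable[[float, np.ndarray], np.ndarray],
    y0: np.ndarray,
    t_grid: np.ndarray,
    method: str,
) -> np.ndarray:
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise InputError("t_grid must be strictly increasing with at least 2 points")
    if method == "rk4":
        return _rk4(f, y0, t_grid)
    if method == "adaptive":
        sol = solve_ivp(
            f, (t_grid[0], t_grid[-1]), y0, t_eval=t_grid, method="RK45",
            rtol=1e-8, atol=1e-10,
        )
        if not sol.success:
            t_bad = float(sol.t[-1]) if sol.t.size else float(t_grid[0])
            raise IntegrationError(t_bad, f"adaptive integration failed: {sol.message}")
        return sol.y.T
    raise InputError(f"unknown method {method!r}; use 'rk4' or 'adaptive'")


def _clip_small_negatives(ys: np.ndarray, scale: float, what: str) -> np.ndarray:
    low = ys.min()
    if low < 0:
        if low < -1e-9 * scale:
            logger.warning("%s: stock fell to %.3g (< -1e-9 * scale); clipping to 0", what, low)
        ys = np.clip(ys, 0.0, None)
    return ys


def integrate_sir(
    state0: SIRState,
    params: SIRParams,
    t_grid: Sequence[float],
    method: str = "rk4",
) -> Trajectory:
    """Integrate the extended SIR rumor model on ``t_grid``.

    The returned stocks satisfy B + S + I = N to 1e-6 N at every point;
    tiny negative excursions are clipped to zero with a logged warning.
    """

    def f(t: float, y: np.ndarray) -> np.ndarray:
        contact = params.beta * y[1] * y[0] / state0.N
        debunk = params.delta * params.eta * y[0]
        forget = params.lam * y[0]
        reinfect = params.rho * y[2]
        return np.array([
            contact - debunk - forget,
            -contact + forget + reinfect,
            debunk - reinfect,
        ])

    y0 = np.array([state0.B, state0.S, state0.I])
    ys = _clip_small_negatives(_integrate(f, y0, np.asarray(t_grid, float), method), state0.N, "SIR")
    return Trajectory(
        t=np.asarray(t_grid, float),
        columns={"B": ys[:, 0], "S": ys[:, 1], "I": ys[:, 2]},
    )


def integrate_trust_rumor(
    state0: TrustRumorState,
    params: TrustRumorParams,
    t_grid: Sequence[float],
    method: str = "rk4",
) -> Trajectory:
    """Integrate the coupled trust-rumor model on ``t_grid``.

    R is clipped at tiny negative excursions; T is left unclamped (it may
    exceed 1 under strong forcing) and excursions above 1 are logged.
    """

    def f(t: float, y: np.ndarray) -> np.ndarray:
        E = params.E_fn(t)
        if E < 0:
            raise InputError(f"E(t) must be >= 0, got {E} at t={t}")
        T, R = y
        return np.array([
            params.alpha_T * (1.0 - T) + params.beta_T * E - params.gamma_T * R * T,
            -params.delta_R * R - params.eps_R * E * R - params.zeta_R * T * R,
        ])

    y0 = np.array([state0.T, state0.R])
    ys = _integrate(f, y0, np.asarray(t_grid, float), method)
    ys[:, 1] = _clip_small_negatives(ys[:, 1:2], max(state0.R, 1.0), "trust-rumor R")[:, 0]
    if ys[:, 0].max() > 1.0 + 1e-12:
        logger.info("trust exceeded 1 (max %.4f); left unclamped by design", ys[:, 0].max())
    return Trajectory(t=np.asarray(t_grid, float), columns={"T": ys[:, 0], "R": ys[:, 1]})


# --------------------------------------------------------------------------
# Scenario engine


@dataclass(frozen=True)
class ScenarioSpec:
    """A named intervention configuration as multiplicative tweaks on the
    baseline: initial trust x trust_multiplier (capped at 1), panic gain
    x panic_multiplier, refutation intensity x debunk_multiplier."""

    name: str
    trust_multiplier: float = 1.0
    panic_multiplier: float = 1.0
    debunk_multiplier: float = 1.0
    horizon: float | None = None
    literacy_enabled: bool = False

    def __post_init__(self) -> None:
        if min(self.trust_multiplier, self.panic_multiplier, self.debunk_multiplier) <= 0:
            raise ConfigurationError("multipliers must be > 0")

    @property
    def is_baseline(self) -> bool:
        return (
            self.trust_multiplier == 1.0
            and self.panic_multiplier == 1.0
            and self.debunk_multiplier == 1.0
        )


def default_scenarios(literacy_enabled: bool = False) -> list[ScenarioSpec]:
    """The published scenario set: baseline, the three single interventions
    at their stated strengths, and the comprehensive combination."""
    return [
        ScenarioSpec("baseline"),
        ScenarioSpec("trust_enhancement", trust_multiplier=1.3, literacy_enabled=literacy_enabled),
        ScenarioSpec("panic_reduction", panic_multiplier=0.8, literacy_enabled=literacy_enabled),
        ScenarioSpec("strengthened_debunking", debunk_multiplier=1.25, literacy_enabled=literacy_enabled),
        ScenarioSpec(
            "comprehensive",
            trust_multiplier=1.3,
            panic_multiplier=0.8,
            debunk_multiplier=1.25,
            literacy_enabled=literacy_enabled,
        ),
    ]


@dataclass(frozen=True)
class ScenarioEngineConfig:
    """Baseline parameters and closure constants of the believer-trust-panic
    system.

    The defaults put the system in a high-turnover regime (strong
    forgetting and reinfection, weak refutation efficiency, slow trust
    dynamics) in which believers rise to a plateau within the horizon,
    baseline trust stays in a low band, and the trust and panic levers act
    persistently while debunking alone has limited effect — the published
    qualitative behaviour.  Every constant is overridable.
    """

    N: float = 10_000.0
    B0: float = 100.0
    S0: float = 9_850.0
    I0: float = 50.0
    T0: float = 0.5
    P0: float = 0.05
    H0: float = 0.35
    beta0: float = 0.88
    k_P: float = 2.0
    k_T: float = 0.70
    delta: float = 0.25
    eta: float = 0.02
    lam: float = 0.30
    rho: float = 0.10
    a_P: float = 1.0
    d_P: float = 0.3
    alpha_T: float = 0.01
    beta_T: float = 0.01
    gamma_T: float = 0.05
    E_level: float = 0.2
    g_H: float = 0.05
    c_H: float = 0.5
    horizon: float = 30.0
    dt: float = 0.1
    method: str = "rk4"

    def __post_init__(self) -> None:
        if self.N <= 0 or self.horizon <= 0 or self.dt <= 0:
            raise ConfigurationError("N, horizon and dt must be > 0")
        if abs(self.B0 + self.S0 + self.I0 - self.N) > 1e-6 * self.N:
            raise ConfigurationError("B0 + S0 + I0 must equal N")

    def with_(self, **kwargs) -> "ScenarioEngineConfig":
        return replace(self, **kwargs)

    @property
    def t_grid(self) -> np.ndarray:
        n = int(round(self.horizon / self.dt))
        return np.linspace(0.0, self.horizon, n + 1)


def _simulate_scenario(base: ScenarioEngineConfig, spec: ScenarioSpec) -> Trajectory:
    N = base.N
    delta = base.delta * spec.debunk_multiplier
    a_P = base.a_P * spec.panic_multiplier
    T0 = min(1.0, base.T0 * spec.trust_multiplier)
    literacy = spec.literacy_enabled

    def f(t: float, y: np.ndarray) -> np.ndarray:
        B, S, I, T, P = y[:5]
        H = y[5] if literacy else 0.0
        k_T_eff = base.k_T * (1.0 + base.c_H * H) if literacy else base.k_T
        throttle = max(0.0, 1.0 - k_T_eff * T)
        spread = base.beta0 * (1.0 + base.k_P * P) * throttle * S * B / N
        debunk = delta * base.eta * B
        forget = base.lam * B
        reinfect = base.rho * I
        dB = spread - debunk - forget
        dS = -spread + forget + reinfect
        dI = debunk - reinfect
        dT = base.alpha_T * (1.0 - T) + base.beta_T * base.E_level - base.gamma_T * (B / N) * T
        dP = a_P * spread / N - base.d_P * P
        out = [dB, dS, dI, dT, dP]
        if literacy:
            out.append(base.g_H * (1.0 - H))
        return np.array(out)

    y0 = [base.B0, base.S0, base.I0, T0, base.P0]
    if literacy:
        y0.append(base.H0)
    t_grid = base.t_grid
    if spec.horizon is not None and spec.horizon != base.horizon:
        n = int(round(spec.horizon / base.dt))
        t_grid = np.linspace(0.0, spec.horizon, n + 1)
    ys = _integrate(f, np.array(y0, dtype=float), t_grid, base.method)
    ys[:, :3] = _clip_small_negatives(ys[:, :3], N, f"scenario {spec.name!r}")
    cols = {
        "believers": ys[:, 0],
        "susceptibles": ys[:, 1],
        "immune": ys[:, 2],
        "trust": ys[:, 3],
        "panic": ys[:, 4],
    }
    if literacy:
        cols["literacy"] = ys[:, 5]
    return Trajectory(t=t_grid, columns=cols)


def run_scenarios(
    base: ScenarioEngineConfig,
    specs: Sequence[ScenarioSpec] | None = None,
) -> dict[str, Trajectory]:
    """Integrate every scenario on the engine's grid, baseline first.

    If ``specs`` contains no baseline (all multipliers 1), one is
    prepended.  Duplicate scenario names are a configuration error.
    """
    specs = list(default_scenarios() if specs is None else specs)
    if not specs:
        raise ConfigurationError("specs must be non-empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate scenario names: {', '.join(dupes)}")
    baseline = next((s for s in specs if s.is_baseline), None)
    if baseline is None:
        baseline = ScenarioSpec("baseline")
        specs = [baseline] + specs
    else:
        specs = [baseline] + [s for s in specs if s is not baseline]
    return {s.name: _simulate_scenario(base, s) for s in specs}
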