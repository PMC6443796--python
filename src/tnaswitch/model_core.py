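"""Reduced and full ODE models of the tryptophanase operon pathway.

The reduced model tracks a single dimensionless protein level ``p`` (the
TnaA/TnaB level, identical after reduction) and the scaled intracellular
tryptophan concentration ``w``::

    p' = rho_G(G_e) * rho_W(w) - p
    w' = (1 + phi*p) * W_e - (theta + psi * rho_A(G_e, W_e) * p) * w

with three regulatory functions:

* ``rho_G`` -- repressing Hill function of external glucose (catabolite
  repression),
* ``rho_W`` -- activating Hill function of intracellular tryptophan
  (anti-termination),
* ``rho_A`` -- fraction of catalytically active (dispersed, non-focus)
  enzyme as a function of the combined external signal
  ``x = lam*G_e + W_e``.

The full three-variable mass-action model is kept for reduction-equivalence
checks only; all analysis runs on the reduced system.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "FullModelParams",
    "FullState",
    "ReducedParams",
    "ReducedState",
    "Environment",
    "DEFAULT_PARAMS",
    "rho_G",
    "rho_W",
    "rho_W_prime",
    "rho_A",
    "reduce_params",
    "rhs_reduced",
    "rhs_full",
    "integrate",
]


class DomainError(ValueError):
    """Raised when an argument lies outside the model's physical domain."""


@dataclass(frozen=True)
class FullModelParams:
    """Rate constants of the three-variable mass-action model.

    All rates are strictly positive.  ``k_A``/``k_B`` are maximal protein
    production rates, ``gamma_A``/``gamma_B`` protein degradation rates,
    ``mu`` the population growth rate, ``alpha`` the permease-independent
    tryptophan uptake rate, ``beta`` the per-permease uptake rate,
    ``delta`` the consumption rate in protein synthesis and ``epsilon``
    the per-enzyme catabolism rate.
    """

    k_A: float
    k_B: float
    gamma_A: float
    gamma_B: float
    mu: float
    alpha: float
    beta: float
    delta: float
    epsilon: float

    def __post_init__(self) -> None:
        for name in ("k_A", "k_B", "mu", "alpha", "beta", "delta", "epsilon"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")
        for name in ("gamma_A", "gamma_B"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FullState:
    """State (A, B, W) of the full model: enzyme, permease, tryptophan."""

    A: float
    B: float
    W: float

    def __post_init__(self) -> None:
        vals = (self.A, self.B, self.W)
        if not all(np.isfinite(vals)) or any(v < 0 for v in vals):
            raise DomainError("full state must be finite and non-negative")


@dataclass(frozen=True)
class ReducedParams:
    """Dimensionless parameters of the reduced model.

    ``phi`` is the uptake gain, ``psi`` the catabolism gain and ``theta``
    the dimensionless consumption rate (``theta >= 1``).  ``K_W``/``n_W``
    and ``K_G``/``n_G`` parameterize the two Hill functions; ``K1``,
    ``K2`` and ``lam`` parameterize the enzyme-activity function.
    """

    phi: float
    psi: float
    theta: float
    K_W: float = 60.0
    n_W: float = 4.0
    K_G: float = 11.0
    n_G: float = 4.0
    K1: float = 14.0
    K2: float = 9.0
    lam: float = 7.0

    def __post_init__(self) -> None:
        if not (self.phi > 0 and self.psi > 0):
            raise DomainError("phi and psi must be strictly positive")
        if self.theta < 1:
            raise DomainError("theta must be >= 1")
        if not (self.K_W > 0 and self.K_G > 0 and self.K1 > 0 and self.K2 > 0 and self.lam > 0):
            raise DomainError("K_W, K_G, K1, K2 and lam must be strictly positive")
        if self.n_W < 1 or self.n_G < 1:
            raise DomainError("Hill exponents must be >= 1")

    @classmethod
    def unchecked(cls, **kwargs: float) -> "ReducedParams":
        """Build a parameter set without invariant validation.

        Needed by the sensitivity sweep, whose uniform draws on
        ``[0, 2*ref]`` can legitimately produce e.g. ``theta < 1``; the
        steady-state equations remain well defined for any positive values.
        """
        obj = object.__new__(cls)
        defaults = {
            "K_W": 60.0, "n_W": 4.0, "K_G": 11.0, "n_G": 4.0,
            "K1": 14.0, "K2": 9.0, "lam": 7.0,
        }
        for name in ("phi", "psi", "theta", *defaults):
            value = kwargs.get(name, defaults.get(name))
            if value is None:
                raise TypeError(f"missing required parameter {name!r}")
            object.__setattr__(obj, name, float(value))
        return obj

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ReducedParams":
        return cls(**json.loads(Path(path).read_text()))

    def with_(self, **kwargs: float) -> "ReducedParams":
        return replace(self, **kwargs)


#: Reference parameter set used throughout the analysis.
DEFAULT_PARAMS = ReducedParams(
    phi=150.0, psi=0.1, theta=6.0,
    K_W=60.0, n_W=4.0, K_G=11.0, n_G=4.0,
    K1=14.0, K2=9.0, lam=7.0,
)


@dataclass(frozen=True)
class ReducedState:
    """Reduced-model state: protein level ``p`` and scaled tryptophan ``w``."""

    p: float
    w: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.p) and np.isfinite(self.w)):
            raise DomainError("state must be finite")
        if self.p < 0 or self.w < 0:
            raise DomainError("state must be non-negative")


@dataclass(frozen=True)
class Environment:
    """External condition: glucose ``G_e`` and tryptophan ``W_e`` in mM."""

    G_e: float
    W_e: float

    def __post_init__(self) -> None:
        vals = (self.G_e, self.W_e)
        if not all(np.isfinite(vals)) or any(v < 0 for v in vals):
            raise DomainError("environment concentrations must be finite and >= 0")


# ---------------------------------------------------------------------------
# Regulatory functions
# ---------------------------------------------------------------------------

def rho_G(G_e, params: ReducedParams = DEFAULT_PARAMS):
    """Catabolite-repression function: ``K_G^n / (K_G^n + G_e^n)``.

    Strictly decreasing in ``G_e``; equals 1 at zero glucose.  Accepts
    scalars or arrays.
    """
    G_e = np.asarray(G_e, dtype=float)
    if np.any(G_e < 0):
        raise DomainError("G_e must be >= 0")
    Kn = params.K_G ** params.n_G
    out = Kn / (Kn + G_e ** params.n_G)
    return float(out) if out.ndim == 0 else out


def rho_W(w, params: ReducedParams = DEFAULT_PARAMS):
    """Anti-termination function: ``w^n / (K_W^n + w^n)``.

    Strictly increasing in ``w``; 0 at ``w = 0`` with limit 1.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise DomainError("w must be >= 0")
    Kn = params.K_W ** params.n_W
    out = w ** params.n_W / (Kn + w ** params.n_W)
    return float(out) if out.ndim == 0 else out


def rho_W_prime(w, params: ReducedParams = DEFAULT_PARAMS):
    """Derivative of :func:`rho_W` with respect to ``w``."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise DomainError("w must be >= 0")
    n, Kn = params.n_W, params.K_W ** params.n_W
    wn = w ** n
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(w > 0, n * Kn * wn / (w * (Kn + wn) ** 2), 0.0 if n > 1 else np.nan)
    if n == 1:
        out = np.where(w > 0, out, 1.0 / params.K_W)
    return float(out) if out.ndim == 0 else out


def rho_A(env_or_Ge, W_e: float | None = None, params: ReducedParams = DEFAULT_PARAMS):
    """Active-enzyme fraction ``1 - (x/K1)^3 * exp(-x/K2)``, ``x = lam*G_e + W_e``.

    Equals 1 at ``x = 0``, returns to 1 as ``x -> inf`` and has a unique
    interior minimum at ``x = 3*K2``.  Not clamped: for nonstandard
    ``K1``/``K2`` the value can go negative, which triggers a warning
    instead of an error (the standard constants keep it positive).
    """
    if isinstance(env_or_Ge, Environment):
        G_e, W_e = env_or_Ge.G_e, env_or_Ge.W_e
    else:
        G_e = env_or_Ge
        if W_e is None:
            raise TypeError("rho_A requires an Environment or (G_e, W_e)")
    G_e = np.asarray(G_e, dtype=float)
    W_e = np.asarray(W_e, dtype=float)
    if np.any(G_e < 0) or np.any(W_e < 0):
        raise DomainError("G_e and W_e must be >= 0")
    x = params.lam * G_e + W_e
    out = 1.0 - (x / params.K1) ** 3 * np.exp(-x / params.K2)
    if np.any(out < 0):
        warnings.warn(
            "rho_A is negative for these K1/K2 values; result not clamped",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(out) if out.ndim == 0 else out


def reduce_params(full: FullModelParams) -> ReducedParams:
    """Map full-model rate constants onto (phi, psi, theta).

    phi = beta*mu / (k_B*alpha), theta = 1 + delta/mu, psi = epsilon/k_A.
    Hill and activity constants keep their defaults.
    """
    return ReducedParams(
        phi=full.beta * full.mu / (full.k_B * full.alpha),
        psi=full.epsilon / full.k_A,
        theta=1.0 + full.delta / full.mu,
    )


# ---------------------------------------------------------------------------
# Vector fields
# ---------------------------------------------------------------------------

def rhs_reduced(
    state: ReducedState | tuple[float, float],
    env: Environment,
    params: ReducedParams,
) -> tuple[float, float]:
    """Time derivatives (p', w') of the reduced system."""
    p, w = (state.p, state.w) if isinstance(state, ReducedState) else state
    rg = rho_G(env.G_e, params)
    ra = rho_A(env, params=params)
    dp = rg * rho_W(w, params) - p
    dw = (1.0 + params.phi * p) * env.W_e - (params.theta + params.psi * ra * p) * w
    return dp, dw


def rhs_full(
    state: FullState | tuple[float, float, float],
    env: Environment,
    full: FullModelParams,
    regs: ReducedParams = DEFAULT_PARAMS,
) -> tuple[float, float, float]:
    """Time derivatives (A', B', W') of the three-variable model.

    The regulatory inputs P_G, P_W, P_A are supplied through the reduced
    functions under the model's scaling: P_G = rho_G, P_W(W) = rho_W(W*mu/alpha)
    (so that rho_W(w) = P_W(w*alpha/mu)) and P_A = rho_A.
    """
    A, B, W = (state.A, state.B, state.W) if isinstance(state, FullState) else state
    PG = rho_G(env.G_e, regs)
    PW = rho_W(W * full.mu / full.alpha, regs)
    PA = rho_A(env, params=regs)
    dA = full.k_A * PG * PW - (full.gamma_A + full.mu) * A
    dB = full.k_B * PG * PW - (full.gamma_B + full.mu) * B
    dW = (full.alpha + full.beta * B) * env.W_e - (
        full.delta + full.epsilon * A * PA + full.mu
    ) * W
    return dA, dB, dW


def integrate(
    state0: ReducedState | tuple[float, float],
    env: Environment,
    params: ReducedParams,
    t_end: float,
    dt: float | None = None,
    rtol: float = 1e-7,
    atol: float = 1e-9,
):
    """Integrate the reduced system from ``state0`` to ``t_end``.

    Returns ``(t, y)`` with ``y`` of shape ``(n, 2)`` holding ``(p, w)``
    rows.  ``dt`` controls the output sampling only; the solver steps
    adaptively (LSODA, abs/rel tolerances 1e-9/1e-7 by default).
    """
    if not t_end > 0:
        raise DomainError("t_end must be positive")
    y0 = (state0.p, state0.w) if isinstance(state0, ReducedState) else tuple(state0)

    def fun(t: float, y: np.ndarray) -> list[float]:
        # the solver may probe marginally negative states near the origin
        dp, dw = rhs_reduced((max(y[0], 0.0), max(y[1], 0.0)), env, params)
        return [dp, dw]

    t_eval = None if dt is None else np.arange(0.0, t_end + 0.5 * dt, dt)
    sol = solve_ivp(
        fun, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise RuntimeError(f"integration failed: {sol.message}")
    return sol.t, sol.y.T


def trajectory_to_csv(t: np.ndarray, y: np.ndarray, path: str | Path) -> None:
    """Write a trajectory as CSV with header ``t,p,w``."""
    arr = np.column_stack([t, y])
    header = "t,p,w"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
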