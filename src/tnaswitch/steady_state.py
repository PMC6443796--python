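"""Enumeration and stability classification of reduced-model steady states.

Steady states satisfy ``p* = rho_G * rho_W(w*)`` together with the scalar
balance equation in ``w*``::

    (1 + phi*rho_G*rho_W(w*)) * W_e  =  (theta + psi*rho_G*rho_W(w*)*rho_A) * w*

Roots are located by sign-change bracketing on a dense mixed linear/log
grid over ``[0, w_max]`` and refined with the secant method.  Depending on
the environment there are one to three roots; with three, the outer pair
is stable and the middle one unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_core import (
    DomainError,
    Environment,
    ReducedParams,
    rho_A,
    rho_G,
    rho_W,
    rho_W_prime,
)

__all__ = [
    "SteadyState",
    "SteadyStateSet",
    "residual",
    "find_steady_states",
    "p_from_w",
    "count_roots_scan",
    "w_upper_bound",
]

# Bracketing grid sizes: roots can span three orders of magnitude, so a
# log-spaced grid is merged with a linear one.
_N_LOG = 2000
_N_LIN = 2000
_SECANT_TOL_W = 1e-9
_SECANT_TOL_F = 1e-8
_SECANT_MAXITER = 100


@dataclass(frozen=True)
class SteadyState:
    """One root of the steady-state equation with its stability label."""

    w_star: float
    p_star: float
    stable: bool
    eigenvalues: tuple[float, float]
    degenerate: bool = False


@dataclass(frozen=True)
class SteadyStateSet:
    """All steady states at one environmental condition, ascending in w."""

    env: Environment
    params: ReducedParams
    states: tuple[SteadyState, ...]

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    @property
    def n_roots(self) -> int:
        return len(self.states)

    @property
    def stable_states(self) -> tuple[SteadyState, ...]:
        return tuple(s for s in self.states if s.stable)


def p_from_w(w_star, env: Environment, params: ReducedParams):
    """Protein level at a steady state: ``rho_G(G_e) * rho_W(w*)``."""
    return rho_G(env.G_e, params) * rho_W(w_star, params)


def residual(w, env: Environment, params: ReducedParams):
    """Signed steady-state balance; zero exactly at a root.

    ``(1 + phi*rho_G*rho_W(w))*W_e - (theta + psi*rho_G*rho_W(w)*rho_A)*w``.
    Positive below a stable root approached from the left, tends to -inf as
    ``w -> inf`` (the right-hand side diverges linearly).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise DomainError("w must be >= 0")
    rg = rho_G(env.G_e, params)
    ra = rho_A(env, params=params)
    rw = rho_W(w, params)
    out = (1.0 + params.phi * rg * rw) * env.W_e - (
        params.theta + params.psi * rg * rw * ra
    ) * w
    return float(out) if out.ndim == 0 else out


def w_upper_bound(env: Environment, params: ReducedParams) -> float:
    """Analytic upper bound (with 5% margin) on any root.

    The left side of the balance is at most ``(1 + phi*rho_G)*W_e`` while
    the right side grows at least as ``theta*w``, so every root is below
    ``(1 + phi*rho_G)*W_e / theta``.
    """
    return 1.05 * (1.0 + params.phi * rho_G(env.G_e, params)) * env.W_e / params.theta


def _jacobian(w: float, env: Environment, params: ReducedParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the reduced system at (p_from_w(w), w)."""
    rg = rho_G(env.G_e, params)
    ra = rho_A(env, params=params)
    p = rg * rho_W(w, params)
    return np.array(
        [
            [-1.0, rg * rho_W_prime(w, params)],
            [params.phi * env.W_e - params.psi * ra * w, -(params.theta + params.psi * ra * p)],
        ]
    )


def _secant(f, x0: float, x1: float) -> float:
    """Secant iteration on the bracket [x0, x1]; falls back to bisection
    when an iterate escapes the bracket."""
    f0, f1 = f(x0), f(x1)
    lo, hi = (x0, x1) if f0 > 0 else (x1, x0)  # residual decreases through a root
    a, b, fa, fb = x0, x1, f0, f1
    for _ in range(_SECANT_MAXITER):
        if fb == fa:
            break
        x2 = b - fb * (b - a) / (fb - fa)
        if not (min(x0, x1) <= x2 <= max(x0, x1)) or not np.isfinite(x2):
            x2 = 0.5 * (lo + hi)
        f2 = f(x2)
        if abs(x2 - b) < _SECANT_TOL_W * max(1.0, abs(x2)) or abs(f2) < _SECANT_TOL_F:
            return x2
        if f2 > 0:
            lo = x2
        else:
            hi = x2
        a, b, fa, fb = b, x2, fb, f2
    raise RuntimeError(
        f"secant iteration failed to converge on bracket [{x0:.6g}, {x1:.6g}]"
    )


def _bracket_grid(w_max: float) -> np.ndarray:
    lin = np.linspace(0.0, w_max, _N_LIN)
    log = np.geomspace(max(w_max * 1e-9, 1e-12), w_max, _N_LOG)
    return np.unique(np.concatenate([lin, log]))


def find_steady_states(
    env: Environment,
    params: ReducedParams,
    classify_stability: bool = True,
) -> SteadyStateSet:
    """Locate all steady states at one condition.

    With ``W_e = 0`` the origin is the unique (stable) steady state and is
    returned exactly.  Otherwise roots are bracketed on a dense grid over
    ``(0, w_max]`` and refined by secant iteration; stability comes from
    the eigenvalues of the analytic Jacobian.  An even root count signals
    a tangency; the degenerate root is flagged, not dropped.
    """
    if env.W_e == 0.0:
        eig = np.linalg.eigvals(_jacobian(0.0, env, params))
        st = SteadyState(0.0, 0.0, True, (float(eig[0].real), float(eig[1].real)))
        return SteadyStateSet(env, params, (st,))

    w_max = w_upper_bound(env, params)
    grid = _bracket_grid(w_max)
    res = residual(grid, env, params)

    roots: list[float] = []
    sign = np.sign(res)
    # exact zeros on grid points count as roots directly
    zero_idx = np.nonzero(sign == 0)[0]
    for i in zero_idx:
        roots.append(float(grid[i]))
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    f = lambda w: residual(w, env, params)
    for i in flips:
        roots.append(_secant(f, float(grid[i]), float(grid[i + 1])))
    roots = sorted(set(roots))

    states: list[SteadyState] = []
    degenerate = len(roots) % 2 == 0 and len(roots) > 0
    for w_star in roots:
        J = _jacobian(w_star, env, params)
        eig = np.linalg.eigvals(J)
        re = (float(eig[0].real), float(eig[1].real))
        stable = max(re) < 0
        states.append(
            SteadyState(
                w_star=w_star,
                p_star=float(p_from_w(w_star, env, params)),
                stable=stable and not degenerate,
                eigenvalues=re,
                degenerate=degenerate,
            )
        )
    return SteadyStateSet(env, params, tuple(states))


def count_roots_bracket(env: Environment, params: ReducedParams) -> int:
    """Root count from sign changes on the standard bracketing grid,
    without secant refinement.  Matches ``len(find_steady_states(...))``
    for non-degenerate conditions and is the fast path for large sweeps."""
    if env.W_e == 0.0:
        return 1
    grid = _bracket_grid(w_upper_bound(env, params))
    s = np.sign(residual(grid, env, params))
    nz = s[s != 0]
    zeros = int(np.count_nonzero(s == 0))
    return int(np.count_nonzero(nz[:-1] != nz[1:])) + zeros


def count_roots_scan(
    env: Environment,
    params: ReducedParams,
    resolution: float = 1e-3,
    w_max: float | None = None,
) -> int:
    """Brute-force root count: sign changes of the residual on a uniform
    grid of the given step.  Independent of the bracketing/secant path;
    used as an oracle in tests and available for cross-checks."""
    if env.W_e == 0.0:
        return 1
    if w_max is None:
        w_max = w_upper_bound(env, params)
    n = int(np.ceil(w_max / resolution)) + 1
    # chunked to bound memory at fine resolutions
    count = 0
    prev_sign = None
    chunk = 2_000_000
    edges = np.arange(0, n, chunk)
    for start in edges:
        stop = min(start + chunk, n)
        w = np.arange(start, stop, dtype=float) * resolution
        if start == 0:
            w = w[1:]  # skip w=0 (positive residual trivially when W_e>0)
        s = np.sign(residual(w, env, params))
        s = s[s != 0]
        if s.size == 0:
            continue
        if prev_sign is not None and s[0] != prev_sign:
            count += 1
        count += int(np.count_nonzero(s[:-1] != s[1:]))
        prev_sign = s[-1]
    return count
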