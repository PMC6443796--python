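"""Gamma-mixture fits and modality statistics for single-cell fluorescence.

Single-cell fluorescence samples are modelled as one- or two-component
gamma mixtures ``omega*Gamma(x; a1, b1) + (1-omega)*Gamma(x; a2, b2)``
in the shape/scale parameterization (mean = shape*scale).  A sample is
called bimodal when the two-component fit is preferred by BIC *and* its
density shows two interior modes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special, stats

__all__ = [
    "MixtureFit",
    "ModalityVerdict",
    "ModalityLabel",
    "fit_gamma_mixture",
    "classify_modality",
    "dispersed_fraction_summary",
    "joint_density",
]

_EM_MAX_ITER = 500
_EM_TOL = 1e-8
_N_RANDOM_RESTARTS = 5
_MIN_SAMPLES = 50


class ModalityLabel(str, Enum):
    UNIMODAL = "UNIMODAL"
    BIMODAL = "BIMODAL"


@dataclass(frozen=True)
class MixtureFit:
    """Fitted mixture: weight, per-component shape/scale, log-likelihood."""

    omega: float
    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    loglik: float
    converged: bool
    n_components: int = 2
    loglik_trace: tuple[float, ...] = ()  # per-iteration log-likelihoods

    @property
    def n_free_params(self) -> int:
        return 2 if self.n_components == 1 else 5

    def bic(self, n: int) -> float:
        return self.n_free_params * np.log(n) - 2.0 * self.loglik

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p1 = stats.gamma.pdf(x, a=self.alpha1, scale=self.beta1)
        if self.n_components == 1 or self.omega == 1.0:
            return p1
        p2 = stats.gamma.pdf(x, a=self.alpha2, scale=self.beta2)
        return self.omega * p1 + (1.0 - self.omega) * p2


@dataclass(frozen=True)
class ModalityVerdict:
    label: ModalityLabel
    delta_bic: float
    n_modes: int
    fit1: MixtureFit
    fit2: MixtureFit


def _check_samples(samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} samples, got {x.size}")
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("samples must be strictly positive and finite")
    return x


def _gamma_mle(wbar: float, wlogbar: float) -> tuple[float, float]:
    """Weighted gamma MLE from sufficient statistics.

    Solves ``log(a) - digamma(a) = log(wbar) - wlogbar`` by Newton
    iteration from the standard Minka-style starting point, then sets
    ``scale = wbar / a``.
    """
    s = np.log(wbar) - wlogbar
    if s <= 0:  # numerically degenerate (near-constant data)
        s = 1e-10
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    for _ in range(100):
        g = np.log(a) - special.digamma(a) - s
        gp = 1.0 / a - special.polygamma(1, a)
        step = g / gp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * a:
            a = a_new
            break
        a = a_new
    return float(a), float(wbar / a)


def _fit_single(x: np.ndarray) -> MixtureFit:
    a, b = _gamma_mle(float(np.mean(x)), float(np.mean(np.log(x))))
    ll = float(np.sum(stats.gamma.logpdf(x, a=a, scale=b)))
    return MixtureFit(1.0, a, b, a, b, ll, True, n_components=1)


def _em_two(x: np.ndarray, init: tuple) -> MixtureFit:
    """One EM run from a given (omega, a1, b1, a2, b2) start."""
    omega, a1, b1, a2, b2 = init
    ll_prev = -np.inf
    converged = False
    trace: list[float] = []
    for _ in range(_EM_MAX_ITER):
        log_p1 = np.log(omega) + stats.gamma.logpdf(x, a=a1, scale=b1)
        log_p2 = np.log1p(-omega) + stats.gamma.logpdf(x, a=a2, scale=b2)
        log_tot = np.logaddexp(log_p1, log_p2)
        ll = float(np.sum(log_tot))
        trace.append(ll)
        r1 = np.exp(log_p1 - log_tot)
        if abs(ll - ll_prev) < _EM_TOL * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
        w1 = float(np.sum(r1))
        w2 = float(x.size - w1)
        if w1 < 1e-8 or w2 < 1e-8:  # component died; collapse to single fit
            break
        omega = w1 / x.size
        a1, b1 = _gamma_mle(float(np.dot(r1, x) / w1), float(np.dot(r1, np.log(x)) / w1))
        r2 = 1.0 - r1
        a2, b2 = _gamma_mle(float(np.dot(r2, x) / w2), float(np.dot(r2, np.log(x)) / w2))
    # component order: component 1 = smaller mean
    if a1 * b1 > a2 * b2:
        omega, a1, b1, a2, b2 = 1.0 - omega, a2, b2, a1, b1
    return MixtureFit(
        omega, a1, b1, a2, b2, ll, converged, n_components=2,
        loglik_trace=tuple(trace),
    )


def _quantile_init(x: np.ndarray) -> tuple:
    med = float(np.median(x))
    lo, hi = x[x <= med], x[x > med]
    a1, b1 = _gamma_mle(float(np.mean(lo)), float(np.mean(np.log(lo))))
    a2, b2 = _gamma_mle(float(np.mean(hi)), float(np.mean(np.log(hi))))
    return 0.5, a1, b1, a2, b2


def fit_gamma_mixture(samples, k: int = 2, seed: int = 0) -> MixtureFit:
    """Maximum-likelihood gamma-mixture fit by EM.

    ``k=1`` fits a single gamma (closed-form sufficient statistics plus a
    Newton solve for the shape) and returns ``omega = 1``.  ``k=2`` runs
    EM from a median-split initialization plus a handful of seeded random
    restarts, keeping the best log-likelihood.
    """
    x = _check_samples(samples)
    if k == 1:
        return _fit_single(x)
    if k != 2:
        raise ValueError("k must be 1 or 2")

    inits = [_quantile_init(x)]
    rng = np.random.default_rng(seed)
    for _ in range(_N_RANDOM_RESTARTS):
        q = rng.uniform(0.2, 0.8)
        split = float(np.quantile(x, q))
        lo, hi = x[x <= split], x[x > split]
        if lo.size < 5 or hi.size < 5:
            continue
        a1, b1 = _gamma_mle(float(np.mean(lo)), float(np.mean(np.log(lo))))
        a2, b2 = _gamma_mle(float(np.mean(hi)), float(np.mean(np.log(hi))))
        inits.append((float(rng.uniform(0.3, 0.7)), a1, b1, a2, b2))

    best: MixtureFit | None = None
    for init in inits:
        try:
            fit = _em_two(x, init)
        except (FloatingPointError, ValueError):
            continue
        if best is None or fit.loglik > best.loglik:
            best = fit
    if best is None:
        raise RuntimeError("all EM starts failed")
    return best


def _count_modes(fit: MixtureFit, x: np.ndarray, n_grid: int = 2000) -> int:
    """Count interior local maxima of the fitted density on a fine grid."""
    grid = np.linspace(max(1e-9, 0.5 * x.min()), 1.2 * x.max(), n_grid)
    dens = fit.pdf(grid)
    d = np.diff(dens)
    rising, falling = d > 0, d < 0
    modes = int(np.sum(rising[:-1] & falling[1:]))
    # a mode at the left boundary (e.g. shape < 1 spike at 0) counts too
    if dens.size > 1 and d[0] < 0:
        modes += 1
    return modes


def classify_modality(samples, seed: int = 0) -> ModalityVerdict:
    """Uni-/bimodality verdict: BIC preference for k=2 AND two modes.

    Both conditions are required; BIC preference alone (e.g. a heavy-tail
    correction by a second overlapping component) does not qualify.
    """
    x = _check_samples(samples)
    fit1 = fit_gamma_mixture(x, k=1)
    fit2 = fit_gamma_mixture(x, k=2, seed=seed)
    delta_bic = fit2.bic(x.size) - fit1.bic(x.size)
    n_modes = _count_modes(fit2, x)
    label = (
        ModalityLabel.BIMODAL
        if (delta_bic < 0 and n_modes == 2)
        else ModalityLabel.UNIMODAL
    )
    return ModalityVerdict(label, float(delta_bic), n_modes, fit1, fit2)


def dispersed_fraction_summary(cells) -> tuple[float, float] | None:
    """Mean dispersed and foci fluorescence fractions over a population.

    ``cells`` is an iterable of objects (or mapping rows) exposing
    ``dispersed_fluor`` and ``total_fluor``; cells with zero total are
    excluded (their fraction is undefined).  Returns ``None`` for an
    empty population; otherwise the two means sum to exactly 1.
    """
    fracs = []
    for c in cells:
        get = c.get if hasattr(c, "get") else lambda k, _c=c: getattr(_c, k)
        total = float(get("total_fluor"))
        if total <= 0:
            continue
        fracs.append(float(get("dispersed_fluor")) / total)
    if not fracs:
        return None
    mean_disp = float(np.mean(fracs))
    return mean_disp, 1.0 - mean_disp


def joint_density(
    cells,
    grid_size: int = 128,
    padding: float = 0.15,
):
    """Gaussian KDE of the joint (dispersed, foci) fluorescence density.

    Returns ``(xx, yy, density)`` with the density evaluated on a regular
    grid over the positive quadrant; the grid integral is ~1 (reflection
    about both axes keeps the on-quadrant mass).
    """
    pts = np.array(
        [
            (
                float(c["dispersed_fluor"] if hasattr(c, "__getitem__") else c.dispersed_fluor),
                float(c["foci_fluor"] if hasattr(c, "__getitem__") else c.foci_fluor),
            )
            for c in cells
        ]
    )
    if pts.shape[0] < 100:
        raise ValueError("joint_density needs at least 100 cells")
    if np.allclose(pts.std(axis=0), 0):
        raise ValueError("degenerate input: zero variance")
    # reflect about both axes so mass near the boundary is not lost
    jitter = None
    for col in range(2):
        if pts[:, col].std() == 0:
            jitter = pts.copy()
            rng = np.random.default_rng(0)
            jitter[:, col] += rng.normal(0, 1e-6 * max(1.0, pts.max()), pts.shape[0])
    data = (jitter if jitter is not None else pts).T
    reflected = np.hstack(
        [data, data * np.array([[-1], [1]]), data * np.array([[1], [-1]]),
         data * np.array([[-1], [-1]])]
    )
    kde = stats.gaussian_kde(reflected)
    hi = pts.max(axis=0) * (1.0 + padding)
    hi[hi == 0] = 1.0
    xs = np.linspace(0, hi[0], grid_size)
    ys = np.linspace(0, hi[1], grid_size)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    dens = 4.0 * kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return xx, yy, dens
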