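"""Monte-Carlo parameter-sensitivity screen of the bistability region.

Samples (phi, psi, theta, K_W, K_G) uniformly on [0, 2*reference] with the
Hill exponents held at 4, classifies the experimental 5x5 condition grid
for each draw, and accepts a draw when its bistable set matches the
experimentally observed bimodality pattern.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import Environment, ReducedParams
from .steady_state import count_roots_bracket

__all__ = [
    "SWEPT_NAMES",
    "BimodalityPattern",
    "SweepResult",
    "DEFAULT_PATTERN",
    "RELAXED_PATTERN",
    "sample_params",
    "agreement_test",
    "run_sweep",
    "summarize_sweep",
]

SWEPT_NAMES = ("phi", "psi", "theta", "K_W", "K_G")

WE_GRID = (0.0, 6.0, 12.0, 24.0, 48.0)
GE_GRID = (0.0, 3.75, 7.5, 15.0, 30.0)


@dataclass(frozen=True)
class BimodalityPattern:
    """Experimental verdicts on the 5x5 condition grid.

    ``bimodal_points`` and ``unimodal_points`` are disjoint sets of
    (W_e, G_e) tuples drawn from the experimental grid.
    """

    bimodal_points: frozenset[tuple[float, float]]
    unimodal_points: frozenset[tuple[float, float]]

    def __post_init__(self) -> None:
        grid = {(w, g) for w in WE_GRID for g in GE_GRID}
        if not (self.bimodal_points <= grid and self.unimodal_points <= grid):
            raise ValueError("pattern points must lie on the experimental grid")
        if self.bimodal_points & self.unimodal_points:
            raise ValueError("bimodal and unimodal point sets must be disjoint")

    @classmethod
    def from_json(cls, path: str | Path) -> "BimodalityPattern":
        obj = json.loads(Path(path).read_text())
        return cls(
            bimodal_points=frozenset(tuple(p) for p in obj["bimodal_points"]),
            unimodal_points=frozenset(tuple(p) for p in obj["unimodal_points"]),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "bimodal_points": sorted(self.bimodal_points),
                    "unimodal_points": sorted(self.unimodal_points),
                },
                indent=2,
            )
            + "\n"
        )


def _default_pattern() -> BimodalityPattern:
    # Bimodality observed for W_e in {6,...,48} at G_e <= 7.5 mM, plus the
    # single point (48, 15); everything else (all G_e = 30 and all W_e = 0)
    # unimodal.  W_e = 0 cannot be bistable in the model.
    bimodal = {(w, g) for w in (6.0, 12.0, 24.0, 48.0) for g in (0.0, 3.75, 7.5)}
    bimodal.add((48.0, 15.0))
    grid = {(w, g) for w in WE_GRID for g in GE_GRID}
    return BimodalityPattern(
        bimodal_points=frozenset(bimodal),
        unimodal_points=frozenset(grid - bimodal),
    )


DEFAULT_PATTERN = _default_pattern()

#: Screen variant that leaves the contested grid point (W_e=24, G_e=15)
#: unscored.  The reference parameter set classifies that point bistable
#: while the experiments saw a unimodal distribution there, so under the
#: literal pattern the reference set itself fails the screen; excluding
#: the single known model/experiment mismatch is the minimal relaxation
#: under which the reference set passes.
RELAXED_PATTERN = BimodalityPattern(
    bimodal_points=DEFAULT_PATTERN.bimodal_points,
    unimodal_points=DEFAULT_PATTERN.unimodal_points - {(24.0, 15.0)},
)


@dataclass(frozen=True)
class SweepResult:
    n_sampled: int
    accepted: list[tuple[float, float, float, float, float]]
    seed: int
    pattern: BimodalityPattern
    samples: np.ndarray = field(repr=False, default=None)  # (n, 5) draws
    accepted_mask: np.ndarray = field(repr=False, default=None)
    ref: ReducedParams = None

    @property
    def n_accepted(self) -> int:
        return len(self.accepted)

    @property
    def acceptance_fraction(self) -> float:
        return len(self.accepted) / self.n_sampled

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.samples, columns=list(SWEPT_NAMES))
        df["accepted"] = self.accepted_mask.astype(int)
        df.to_csv(path, index=False)


def sample_params(n: int, ref: ReducedParams, seed: int) -> list[ReducedParams]:
    """Draw ``n`` parameter sets, each swept field ~ Uniform(0, 2*ref).

    Hill exponents stay at the reference (n_W = n_G = 4 by default) and
    the activity constants K1, K2, lam are never varied.  Draws may break
    the physical invariants of :class:`ReducedParams` (e.g. theta < 1);
    they are built unvalidated on purpose.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    draws = _draw_matrix(n, ref, seed)
    return [_params_from_row(row, ref) for row in draws]


def _draw_matrix(n: int, ref: ReducedParams, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    highs = 2.0 * np.array([getattr(ref, name) for name in SWEPT_NAMES])
    return rng.uniform(0.0, highs, size=(n, 5))


def _params_from_row(row: np.ndarray, ref: ReducedParams) -> ReducedParams:
    return ReducedParams.unchecked(
        phi=row[0], psi=row[1], theta=row[2], K_W=row[3], K_G=row[4],
        n_W=ref.n_W, n_G=ref.n_G, K1=ref.K1, K2=ref.K2, lam=ref.lam,
    )


def _is_bistable(env: Environment, params: ReducedParams) -> bool:
    return count_roots_bracket(env, params) == 3


def agreement_test(
    params: ReducedParams,
    pattern: BimodalityPattern = DEFAULT_PATTERN,
    tolerance: int = 0,
) -> bool:
    """True when the predicted bistable set matches the bimodality pattern.

    Every bimodal point must classify bistable and every unimodal point
    non-bistable; ``tolerance`` allows up to that many mismatched points.
    """
    if params.theta <= 0 or params.phi < 0 or params.psi < 0:
        return len(pattern.bimodal_points) == 0 or tolerance >= len(pattern.bimodal_points)
    mismatches = 0
    # bimodal points first: random draws usually fail there, short-circuiting
    for w_e, g_e in sorted(pattern.bimodal_points):
        if not _is_bistable(Environment(G_e=g_e, W_e=w_e), params):
            mismatches += 1
            if mismatches > tolerance:
                return False
    for w_e, g_e in sorted(pattern.unimodal_points):
        if _is_bistable(Environment(G_e=g_e, W_e=w_e), params):
            mismatches += 1
            if mismatches > tolerance:
                return False
    return True


def run_sweep(
    n: int,
    ref: ReducedParams,
    pattern: BimodalityPattern = DEFAULT_PATTERN,
    seed: int = 0,
    tolerance: int = 0,
) -> SweepResult:
    """Sample ``n`` sets and screen each with :func:`agreement_test`.

    Deterministic for a given seed; the draws and the acceptance mask are
    retained for downstream summaries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    draws = _draw_matrix(n, ref, seed)
    mask = np.zeros(n, dtype=bool)
    for i, row in enumerate(draws):
        mask[i] = agreement_test(_params_from_row(row, ref), pattern, tolerance)
    accepted = [tuple(float(v) for v in row) for row in draws[mask]]
    return SweepResult(
        n_sampled=n, accepted=accepted, seed=seed, pattern=pattern,
        samples=draws, accepted_mask=mask, ref=ref,
    )


def summarize_sweep(result: SweepResult, n_bins: int = 30) -> dict:
    """Histograms per swept parameter and Pearson correlations per pair.

    Histogram bins are fixed on [0, 2*ref] for each parameter.  With an
    empty acceptance list, an explicit empty marker is returned; with
    zero-variance parameters the affected correlations are reported as NaN.
    """
    if not result.accepted:
        return {"empty": True, "n_accepted": 0, "histograms": {}, "correlations": {}}
    acc = np.array(result.accepted)
    histograms: dict[str, dict] = {}
    for k, name in enumerate(SWEPT_NAMES):
        high = 2.0 * getattr(result.ref, name)
        counts, edges = np.histogram(acc[:, k], bins=n_bins, range=(0.0, high))
        histograms[name] = {"counts": counts.tolist(), "edges": edges.tolist()}
    correlations: dict[tuple[str, str], float] = {}
    for (i, a), (j, b) in itertools.combinations(enumerate(SWEPT_NAMES), 2):
        sa, sb = acc[:, i], acc[:, j]
        if np.std(sa) == 0 or np.std(sb) == 0 or len(acc) < 2:
            correlations[(a, b)] = float("nan")
        else:
            correlations[(a, b)] = float(np.corrcoef(sa, sb)[0, 1])
    return {
        "empty": False,
        "n_accepted": len(result.accepted),
        "histograms": histograms,
        "correlations": correlations,
    }
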