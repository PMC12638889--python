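"""Gray-level histogram statistics and the multilevel Otsu objective.

Otsu's criterion picks thresholds ``T_1 < ... < T_Th`` that maximise the
between-class variance of the resulting intensity classes,

    sigma_B^2 = sum_k  w_k (mu_k - mu_I)^2,

where ``w_k`` and ``mu_k`` are the probability mass and mean gray level of
class ``k`` and ``mu_I`` is the global mean.  The class rule used throughout
the package is half-open: pixel ``g`` belongs to class ``k`` iff
``T_k <= g < T_{k+1}`` with sentinels ``T_0 = 0`` and ``T_{Th+1} = L``.

The equivalent "second moment" form ``sum_k w_k mu_k^2`` differs from
``sigma_B^2`` only by the constant ``mu_I^2`` and therefore shares its
argmax; both are provided.

Cumulative sums of ``p_i`` and ``i p_i`` are precomputed per histogram so a
single objective evaluation costs O(Th), not O(L) — this is what makes a
metaheuristic with thousands of evaluations cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Literal, Sequence

import numpy as np

from .optimizer import Bounds, OptResult, OptimizerConfig, run_coot, run_icoot

__all__ = [
    "Histogram",
    "ClassStats",
    "ThresholdResult",
    "compute_histogram",
    "global_mean",
    "class_stats",
    "between_class_variance",
    "between_class_variance_eq24",
    "decode_position",
    "exhaustive_otsu",
    "make_otsu_objective",
    "optimize_thresholds",
    "optimize_thresholds_from_histogram",
]


@dataclass(frozen=True)
class Histogram:
    """Per-gray-level pixel counts and probabilities over ``L`` bins."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size < 2:
            raise ValueError("counts must be a 1-D array with at least 2 bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("histogram must contain at least one pixel")
        object.__setattr__(self, "counts", counts)

    @property
    def levels(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @cached_property
    def probs(self) -> np.ndarray:
        return self.counts / self.total

    @cached_property
    def cum_p(self) -> np.ndarray:
        """``cum_p[j] = sum_{i < j} p_i`` (length L + 1)."""
        out = np.empty(self.levels + 1)
        out[0] = 0.0
        np.cumsum(self.probs, out=out[1:])
        return out

    @cached_property
    def cum_ip(self) -> np.ndarray:
        """``cum_ip[j] = sum_{i < j} i * p_i`` (length L + 1)."""
        out = np.empty(self.levels + 1)
        out[0] = 0.0
        np.cumsum(np.arange(self.levels) * self.probs, out=out[1:])
        return out


@dataclass(frozen=True)
class ClassStats:
    """Class weights/means induced by a threshold set, plus the global mean."""

    weights: np.ndarray
    means: np.ndarray
    global_mean: float


@dataclass(frozen=True)
class ThresholdResult:
    """Best thresholds found by an optimizer on one image/histogram."""

    thresholds: tuple[int, ...]
    fitness: float
    trace: np.ndarray
    seed: int
    algorithm: str


def compute_histogram(image: np.ndarray, levels: int = 256) -> Histogram:
    """Histogram of an integer gray image with intensities in ``[0, L-1]``."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("image must be non-empty")
    flat = image.reshape(-1)
    if np.any(flat < 0) or np.any(flat > levels - 1):
        raise ValueError(f"intensities must lie in [0, {levels - 1}]")
    counts = np.bincount(flat.astype(np.int64), minlength=levels)
    return Histogram(counts=counts)


def global_mean(hist: Histogram) -> float:
    """Mean gray level ``mu_I = sum_i i p_i``."""
    return float(hist.cum_ip[-1])


def _validate_thresholds(thresholds: Sequence[int], levels: int) -> tuple[int, ...]:
    t = tuple(int(v) for v in thresholds)
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {t}")
    if t and (t[0] < 1 or t[-1] > levels - 1):
        raise ValueError(f"thresholds must lie in [1, {levels - 1}], got {t}")
    return t


def _edges(thresholds: tuple[int, ...], levels: int) -> np.ndarray:
    return np.array((0, *thresholds, levels), dtype=np.int64)


def class_stats(hist: Histogram, thresholds: Sequence[int]) -> ClassStats:
    """Weights ``w_k`` and means ``mu_k`` of the classes cut by ``thresholds``.

    An empty class gets ``mu_k = 0`` and (since ``w_k = 0``) contributes
    nothing to the between-class variance.
    """
    t = _validate_thresholds(thresholds, hist.levels)
    e = _edges(t, hist.levels)
    w = hist.cum_p[e[1:]] - hist.cum_p[e[:-1]]
    s = hist.cum_ip[e[1:]] - hist.cum_ip[e[:-1]]
    means = np.divide(s, w, out=np.zeros_like(s), where=w > 0)
    return ClassStats(weights=w, means=means, global_mean=global_mean(hist))


def between_class_variance(hist: Histogram, thresholds: Sequence[int]) -> float:
    """Otsu's criterion ``sigma_B^2 = sum_k w_k (mu_k - mu_I)^2``."""
    st = class_stats(hist, thresholds)
    return float(np.sum(st.weights * (st.means - st.global_mean) ** 2))


def between_class_variance_eq24(hist: Histogram, thresholds: Sequence[int]) -> float:
    """Second-moment form ``sum_k w_k mu_k^2``; equals ``sigma_B^2 + mu_I^2``."""
    st = class_stats(hist, thresholds)
    return float(np.sum(st.weights * st.means**2))


def decode_position(
    position: np.ndarray, n_thresh: int, levels: int = 256
) -> tuple[int, ...]:
    """Decode a continuous agent position into strictly increasing thresholds.

    Coordinates are rounded to the nearest integer, clamped to
    ``[1, L-1]``, sorted ascending, and duplicates resolved by bumping the
    later duplicate up to the next free integer; if that overruns ``L-1``
    the excess cascades back downward so the result stays within range.
    """
    if n_thresh >= levels - 1:
        raise ValueError(
            f"cannot form {n_thresh} distinct thresholds in [1, {levels - 1}]"
        )
    position = np.asarray(position, dtype=float).reshape(-1)
    if position.size != n_thresh:
        raise ValueError(f"position length {position.size} != n_thresh {n_thresh}")
    t = np.clip(np.rint(position).astype(np.int64), 1, levels - 1)
    t.sort()
    for i in range(1, n_thresh):  # bump duplicates upward
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + 1
    if n_thresh and t[-1] > levels - 1:  # cascade any overflow back down
        t[-1] = levels - 1
        for i in range(n_thresh - 2, -1, -1):
            if t[i] >= t[i + 1]:
                t[i] = t[i + 1] - 1
    return tuple(int(v) for v in t)


def _batch_sigma_b2(hist: Histogram, combos: np.ndarray) -> np.ndarray:
    """Vectorised sigma_B^2 for a (C, n) array of threshold tuples."""
    c, n = combos.shape
    edges = np.empty((c, n + 2), dtype=np.int64)
    edges[:, 0] = 0
    edges[:, 1:-1] = combos
    edges[:, -1] = hist.levels
    w = hist.cum_p[edges[:, 1:]] - hist.cum_p[edges[:, :-1]]
    s = hist.cum_ip[edges[:, 1:]] - hist.cum_ip[edges[:, :-1]]
    mu = np.divide(s, w, out=np.zeros_like(s), where=w > 0)
    mu_i = global_mean(hist)
    return np.sum(w * (mu - mu_i) ** 2, axis=1)


def exhaustive_otsu(
    hist: Histogram, n_thresh: int, max_thresh: int = 3
) -> tuple[tuple[int, ...], float]:
    """Exact optimum by enumerating every strictly increasing threshold tuple.

    Returns the lexicographically smallest tuple attaining the maximal
    ``sigma_B^2``.  Refuses ``n_thresh > max_thresh`` (combinatorial guard,
    default 3); raise the guard explicitly for small ``L`` if needed.
    """
    if not (1 <= n_thresh <= max_thresh):
        raise ValueError(
            f"exhaustive search supports 1 <= n_thresh <= {max_thresh}, got {n_thresh}"
        )
    if n_thresh >= hist.levels - 1:
        raise ValueError("n_thresh too large for the number of gray levels")
    best_f = -np.inf
    best_t: tuple[int, ...] | None = None
    combos = itertools.combinations(range(1, hist.levels), n_thresh)
    while True:
        chunk = list(itertools.islice(combos, 65536))
        if not chunk:
            break
        arr = np.asarray(chunk, dtype=np.int64)
        f = _batch_sigma_b2(hist, arr)
        i = int(np.argmax(f))
        # combinations are generated in lexicographic order, so the first
        # strict improvement is the lexicographically smallest optimum
        if f[i] > best_f:
            best_f = float(f[i])
            best_t = tuple(int(v) for v in arr[i])
    assert best_t is not None
    return best_t, best_f


def make_otsu_objective(hist: Histogram, n_thresh: int):
    """Maximisation objective: decode a continuous position, score sigma_B^2."""

    def objective(x: np.ndarray) -> float:
        return between_class_variance(hist, decode_position(x, n_thresh, hist.levels))

    return objective


def optimize_thresholds_from_histogram(
    hist: Histogram,
    n_thresh: int,
    config: OptimizerConfig | None = None,
    algorithm: Literal["coot", "icoot"] = "icoot",
) -> ThresholdResult:
    """Maximise the Otsu criterion over ``[0, L-1]^Th`` with COOT or ICOOT."""
    if not (1 <= n_thresh <= 8):
        raise ValueError(f"n_thresh must be in 1..8, got {n_thresh}")
    config = OptimizerConfig() if config is None else config
    config = config.replace(mode="maximize")
    bounds = Bounds(lb=0.0, ub=float(hist.levels - 1), dim=n_thresh)
    runner = {"coot": run_coot, "icoot": run_icoot}.get(algorithm)
    if runner is None:
        raise ValueError(f"algorithm must be 'coot' or 'icoot', got {algorithm!r}")
    res: OptResult = runner(make_otsu_objective(hist, n_thresh), bounds, config)
    thresholds = decode_position(res.best_position, n_thresh, hist.levels)
    return ThresholdResult(
        thresholds=thresholds,
        fitness=between_class_variance(hist, thresholds),
        trace=res.trace,
        seed=config.seed,
        algorithm=algorithm,
    )


def optimize_thresholds(
    image: np.ndarray,
    n_thresh: int,
    config: OptimizerConfig | None = None,
    algorithm: Literal["coot", "icoot"] = "icoot",
    levels: int = 256,
) -> ThresholdResult:
    """Histogram an image once, then optimise its thresholds (seeded run)."""
    hist = compute_histogram(image, levels=levels)
    return optimize_thresholds_from_histogram(hist, n_thresh, config, algorithm)
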