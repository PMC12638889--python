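"""Synthetic grayscale fixtures and analytic optimizer test functions.

The image generators emulate the kind of material multilevel thresholding is
usually demonstrated on: 8-bit images whose gray-level histograms are
mixtures of a few well-separated modes (2-6), laid out as contiguous
horizontal bands so a segmentation can be judged by eye.  The two-delta
image has a closed-form histogram and a closed-form Otsu optimum, which
makes it an exact oracle fixture.

The analytic test functions (sphere, rastrigin, rosenbrock) have known
global minima and stand in for external benchmark suites when validating
the optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModeSpec",
    "DEFAULT_THREE_MODES",
    "synth_multimodal_image",
    "synth_two_delta_image",
    "test_function",
    "TEST_FUNCTION_BOUNDS",
    "make_fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class ModeSpec:
    """One Gaussian mode of a mixture histogram: mean/sd in gray levels."""

    mean: float
    sd: float
    weight: float


#: Default three-mode mixture: well-separated peaks at 60/128/200, sd 8,
#: equal thirds — a multimodal histogram typical of natural test images.
DEFAULT_THREE_MODES: tuple[ModeSpec, ...] = (
    ModeSpec(60.0, 8.0, 1.0 / 3.0),
    ModeSpec(128.0, 8.0, 1.0 / 3.0),
    ModeSpec(200.0, 8.0, 1.0 / 3.0),
)


def _validate_modes(modes: Sequence[ModeSpec], levels: int) -> None:
    if len(modes) < 1:
        raise ValueError("at least one mode is required")
    total = 0.0
    for m in modes:
        if not (0.0 <= m.mean <= levels - 1):
            raise ValueError(f"mode mean {m.mean} outside [0, {levels - 1}]")
        if m.sd < 0:
            raise ValueError("mode sd must be >= 0")
        if m.weight <= 0:
            raise ValueError("mode weights must be positive")
        total += m.weight
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mode weights must sum to 1, got {total}")


def synth_multimodal_image(
    modes: Sequence[ModeSpec] = DEFAULT_THREE_MODES,
    height: int = 128,
    width: int = 128,
    seed: int = 0,
    levels: int = 256,
) -> np.ndarray:
    """Banded Gaussian-mixture image (uint8), deterministic given the seed.

    Rows are split into contiguous horizontal bands, one per mode, with band
    heights proportional to the mode weights; each pixel draws from its
    band's normal distribution, rounded and clamped to ``[0, L-1]``.
    """
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    _validate_modes(modes, levels)
    rng = np.random.default_rng(seed)
    # cumulative-rounding band edges so heights track weights exactly
    cum = np.cumsum([m.weight for m in modes])
    edges = np.concatenate(([0], np.rint(cum * height).astype(int)))
    edges[-1] = height
    img = np.empty((height, width), dtype=np.uint8)
    for m, lo, hi in zip(modes, edges[:-1], edges[1:]):
        n = (hi - lo) * width
        if n <= 0:
            continue
        vals = rng.normal(m.mean, m.sd, size=n) if m.sd > 0 else np.full(n, m.mean)
        vals = np.clip(np.rint(vals), 0, levels - 1)
        img[lo:hi, :] = vals.reshape(hi - lo, width).astype(np.uint8)
    return img


def synth_two_delta_image(
    low: int = 0,
    high: int = 255,
    height: int = 64,
    width: int = 64,
    levels: int = 256,
) -> np.ndarray:
    """Two-valued image: first (top) half ``low``, second half ``high``.

    With an odd pixel count the top half receives the extra pixel.  The
    histogram is known exactly, and for equal halves the optimal bilevel
    between-class variance is ``(high - low)^2 / 4``.
    """
    if not (0 <= low < high <= levels - 1):
        raise ValueError(f"need 0 <= low < high <= {levels - 1}, got ({low}, {high})")
    if height < 1 or width < 1:
        raise ValueError("height and width must be >= 1")
    n = height * width
    flat = np.full(n, high, dtype=np.uint8)
    flat[: (n + 1) // 2] = low
    return flat.reshape(height, width)


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(np.asarray(x, float) ** 2))


def _rastrigin(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


_TEST_FUNCTIONS: dict[str, Callable[[np.ndarray], float]] = {
    "sphere": _sphere,
    "rastrigin": _rastrigin,
    "rosenbrock": _rosenbrock,
}

#: Conventional search boxes for the analytic functions.
TEST_FUNCTION_BOUNDS: dict[str, tuple[float, float]] = {
    "sphere": (-100.0, 100.0),
    "rastrigin": (-5.12, 5.12),
    "rosenbrock": (-5.0, 10.0),
}


def test_function(name: str, dim: int = 2) -> Callable[[np.ndarray], float]:
    """Analytic benchmark with known global minimum 0.

    ``sphere`` and ``rastrigin`` attain it at the origin, ``rosenbrock`` at
    the all-ones point.  ``dim`` is validated here; the returned callable
    accepts any vector of that length.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    try:
        return _TEST_FUNCTIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown test function {name!r}; choose from {sorted(_TEST_FUNCTIONS)}"
        ) from None


test_function.__test__ = False  # keep pytest from collecting the factory

FIXTURE_NAMES = ("two-delta", "three-mode")


def make_fixture(
    name: str, seed: int = 0, height: int = 256, width: int = 256
) -> np.ndarray:
    """Named fixture images used by the command-line interface."""
    if name == "two-delta":
        return synth_two_delta_image(0, 255, height, width)
    if name == "three-mode":
        return synth_multimodal_image(
            DEFAULT_THREE_MODES, height=height, width=width, seed=seed
        )
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
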