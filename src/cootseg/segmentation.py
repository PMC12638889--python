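"""Image I/O, threshold application, and the segment-and-evaluate pipeline.

A threshold set ``T_1 < ... < T_Th`` cuts the gray range into ``Th + 1``
classes under the half-open rule ``T_k <= g < T_{k+1}`` (``T_0 = 0``,
``T_{Th+1} = L``); a pixel's label is simply the number of thresholds at or
below its intensity.  The *rendered* segmentation replaces every pixel with
its class's representative intensity — the class mean (default) or the
class-interval midpoint — and is what the PSNR/SSIM/FSIM scores compare
against the original image.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .metrics import MetricReport, compute_metric_report
from .optimizer import OptimizerConfig
from .otsu import ThresholdResult, optimize_thresholds

__all__ = [
    "SegmentedImage",
    "SegmentationOutcome",
    "read_image",
    "write_image",
    "apply_thresholds",
    "segment_and_evaluate",
    "repeat_segment_and_evaluate",
]


@dataclass(frozen=True)
class SegmentedImage:
    """Class labels in [0, Th] and the rendered 8-bit image."""

    labels: np.ndarray
    rendered: np.ndarray


@dataclass(frozen=True)
class SegmentationOutcome:
    """One full segment-and-evaluate run."""

    result: ThresholdResult
    segmented: SegmentedImage
    metrics: MetricReport


def read_image(
    path,
    as_gray: bool = True,
    resize_to: int | None = None,
) -> np.ndarray:
    """Load an 8-bit grayscale image from PNG/TIFF/PGM/JPEG.

    Color inputs are converted with the standard luma transform; if
    ``resize_to`` is given the image is resampled (bilinear) to that square
    size before use.
    """
    import imageio.v3 as iio

    try:
        img = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # unreadable / unsupported content
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim == 3:
        if as_gray:
            from skimage.color import rgb2gray

            img = np.rint(rgb2gray(img[..., :3]) * 255.0)
        else:
            raise ValueError("color image given but as_gray=False")
    if img.ndim != 2:
        raise OSError(f"unsupported image layout with shape {img.shape}")
    img = np.clip(img, 0, 255).astype(np.uint8)
    if resize_to is not None:
        from skimage.transform import resize

        img = resize(
            img.astype(float),
            (resize_to, resize_to),
            order=1,
            anti_aliasing=True,
            preserve_range=True,
        )
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img


def write_image(path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale image (format chosen by file extension)."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def apply_thresholds(
    image: np.ndarray,
    thresholds: Sequence[int],
    render: Literal["class_mean", "midpoint"] = "class_mean",
    levels: int = 256,
) -> SegmentedImage:
    """Label each pixel by its intensity class and render the segmentation.

    ``class_mean`` replaces each pixel with the rounded mean intensity of
    its class (an empty class falls back to its interval midpoint);
    ``midpoint`` uses the midpoint of the class interval ``[T_k, T_{k+1})``.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    t = tuple(int(v) for v in thresholds)
    if any(b <= a for a, b in zip(t, t[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {t}")
    if t and (t[0] < 1 or t[-1] > levels - 1):
        raise ValueError(f"thresholds must lie in [1, {levels - 1}], got {t}")

    tarr = np.asarray(t, dtype=np.int64)
    labels = np.searchsorted(tarr, image.astype(np.int64), side="right")

    edges = np.concatenate(([0], tarr, [levels]))
    reps = np.empty(len(t) + 1, dtype=float)
    for k in range(len(t) + 1):
        lo, hi = edges[k], edges[k + 1]
        mid = (lo + hi - 1) / 2.0
        if render == "midpoint":
            reps[k] = mid
        elif render == "class_mean":
            mask = labels == k
            reps[k] = image[mask].mean() if mask.any() else mid
        else:
            raise ValueError(f"unknown render mode {render!r}")
    rendered = np.clip(np.rint(reps[labels]), 0, levels - 1).astype(np.uint8)
    return SegmentedImage(labels=labels.astype(np.int32), rendered=rendered)


def segment_and_evaluate(
    image: np.ndarray,
    n_thresh: int,
    config: OptimizerConfig | None = None,
    algorithm: Literal["coot", "icoot"] = "icoot",
    render: Literal["class_mean", "midpoint"] = "class_mean",
) -> SegmentationOutcome:
    """Optimise thresholds, apply them, and score the rendering.

    Deterministic given ``config.seed``: the same seed reproduces the same
    thresholds, rendering and metric values.
    """
    result = optimize_thresholds(image, n_thresh, config, algorithm)
    segmented = apply_thresholds(image, result.thresholds, render=render)
    metrics = compute_metric_report(image, segmented.rendered)
    return SegmentationOutcome(result=result, segmented=segmented, metrics=metrics)


def repeat_segment_and_evaluate(
    image: np.ndarray,
    n_thresh: int,
    base_config: OptimizerConfig | None = None,
    algorithm: Literal["coot", "icoot"] = "icoot",
    repeats: int = 1,
    render: Literal["class_mean", "midpoint"] = "class_mean",
):
    """Run ``repeats`` seeded replicates and summarise fitness and metrics.

    Replicate ``r`` uses seed ``base_config.seed + r``.  Returns
    ``(outcomes, summary)`` where ``summary`` is a pandas DataFrame with one
    row per run plus ``mean`` and ``std`` rows over fitness/PSNR/SSIM/FSIM.
    """
    import pandas as pd

    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    base_config = OptimizerConfig() if base_config is None else base_config
    outcomes: list[SegmentationOutcome] = []
    rows = []
    for r in range(repeats):
        cfg = base_config.replace(seed=base_config.seed + r)
        out = segment_and_evaluate(image, n_thresh, cfg, algorithm, render=render)
        outcomes.append(out)
        rows.append(
            {
                "run": r,
                "seed": cfg.seed,
                "fitness": out.result.fitness,
                "psnr": out.metrics.psnr,
                "ssim": out.metrics.ssim,
                "fsim": out.metrics.fsim,
                "thresholds": " ".join(str(v) for v in out.result.thresholds),
            }
        )
    df = pd.DataFrame(rows)
    numeric = df[["fitness", "psnr", "ssim", "fsim"]]
    summary = pd.DataFrame(
        [
            {"run": "mean", "seed": "", "thresholds": "", **numeric.mean().to_dict()},
            {"run": "std", "seed": "", "thresholds": "", **numeric.std(ddof=1).to_dict()}
            if repeats > 1
            else {"run": "std", "seed": "", "thresholds": "", "fitness": 0.0,
                  "psnr": 0.0, "ssim": 0.0, "fsim": 0.0},
        ]
    )
    return outcomes, pd.concat([df, summary], ignore_index=True)
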