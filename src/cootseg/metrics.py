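"""Image-quality metrics: RMSE/PSNR, SSIM and FSIM.

These score how faithfully a rendered segmentation reproduces the original
grayscale image.

* PSNR is ``20 log10(255 / RMSE)`` dB for 8-bit images, with an explicit
  ``+inf`` sentinel when the images are identical.
* SSIM is, by default, the *global-statistics* form — one luminance /
  contrast / covariance comparison over whole-image moments with stabilising
  constants ``C1 = 6.5025`` and ``C2 = 58.52252`` (``K1 = 0.01``,
  ``K2 = 0.03`` at dynamic range 255).  The familiar 11x11 sliding-window
  mean SSIM from the wider literature is available behind ``windowed=True``
  (delegated to scikit-image).
* FSIM weights the pointwise similarity of phase-congruency maps (``S_PC``)
  and gradient-magnitude maps (``S_G``) by the maximum phase congruency
  ``PC_m = max(PC_1, PC_2)``:

      FSIM = sum(S_PC * S_G * PC_m) / sum(PC_m).

  Phase congruency is computed with a log-Gabor filter bank (4 scales x 4
  orientations, Kovesi-style energy-over-amplitude formulation with a
  noise-floor estimate from the smallest-scale responses); gradients use the
  FSIM-standard Scharr/16 kernels so the conventional constants
  ``T1 = 0.85``, ``T2 = 160`` keep their usual scale.

All functions accept 2-D arrays of 8-bit gray intensities (any integer or
float dtype; values are interpreted on the 0-255 scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.fft import fft2, ifft2, ifftshift
from scipy import ndimage

__all__ = [
    "MetricReport",
    "rmse",
    "psnr",
    "ssim",
    "gradient_magnitude",
    "phase_congruency",
    "fsim",
    "compute_metric_report",
]

#: SSIM stabilising constants for 8-bit images (K1=0.01, K2=0.03, L=255).
DEFAULT_C1 = 6.5025
DEFAULT_C2 = 58.52252
#: standard FSIM constants
DEFAULT_T1 = 0.85
DEFAULT_T2 = 160.0


@dataclass(frozen=True)
class MetricReport:
    """PSNR/RMSE/SSIM/FSIM for one image pair, with the constants used."""

    psnr: float
    rmse: float
    ssim: float
    fsim: float
    constants_used: dict[str, float] = field(default_factory=dict)

    def to_jsonable(self) -> dict[str, Any]:
        """JSON-safe dict; an infinite PSNR becomes the string ``"inf"``."""
        return {
            "psnr": "inf" if math.isinf(self.psnr) else self.psnr,
            "rmse": self.rmse,
            "ssim": self.ssim,
            "fsim": None if math.isnan(self.fsim) else self.fsim,
            "constants_used": dict(self.constants_used),
        }


def _pair(ref: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, dtype=float)
    test = np.asarray(test, dtype=float)
    if ref.ndim != 2 or ref.size == 0:
        raise ValueError("images must be non-empty 2-D arrays")
    if ref.shape != test.shape:
        raise ValueError(f"image shapes differ: {ref.shape} vs {test.shape}")
    return ref, test


def rmse(ref: np.ndarray, test: np.ndarray) -> float:
    """Root-mean-square intensity error in gray levels."""
    ref, test = _pair(ref, test)
    return float(np.sqrt(np.mean((ref - test) ** 2)))


def psnr(ref: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio ``20 log10(255 / RMSE)`` in dB.

    Identical images give ``math.inf`` (never silently capped).
    """
    err = rmse(ref, test)
    if err == 0.0:
        return math.inf
    return float(20.0 * math.log10(255.0 / err))


def ssim(
    ref: np.ndarray,
    test: np.ndarray,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
    windowed: bool = False,
) -> float:
    """Structural similarity index.

    The default computes one SSIM from whole-image means, variances and the
    covariance; ``windowed=True`` instead averages local SSIM over an 11x11
    Gaussian window (scikit-image implementation) for comparability with the
    wider literature.
    """
    ref, test = _pair(ref, test)
    if windowed:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(
                ref,
                test,
                data_range=255.0,
                win_size=11,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
                K1=math.sqrt(c1) / 255.0,
                K2=math.sqrt(c2) / 255.0,
            )
        )
    mu_r, mu_t = ref.mean(), test.mean()
    # one arithmetic path for both variances and the covariance, so that
    # identical inputs give numerator == denominator bit-for-bit
    dr = ref - mu_r
    dt = test - mu_t
    var_r = (dr * dr).mean()
    var_t = (dt * dt).mean()
    cov = (dr * dt).mean()
    num = (2.0 * mu_r * mu_t + c1) * (2.0 * cov + c2)
    den = (mu_r**2 + mu_t**2 + c1) * (var_r + var_t + c2)
    return float(num / den)


_SCHARR_X = np.array([[3.0, 0.0, -3.0], [10.0, 0.0, -10.0], [3.0, 0.0, -3.0]]) / 16.0
_SCHARR_Y = _SCHARR_X.T


def gradient_magnitude(image: np.ndarray) -> np.ndarray:
    """Per-pixel gradient magnitude via the Scharr/16 kernels.

    The /16 normalisation is the convention under which the FSIM gradient
    constant ``T2 = 160`` was calibrated for 0-255 images.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    gx = ndimage.convolve(image, _SCHARR_X, mode="reflect")
    gy = ndimage.convolve(image, _SCHARR_Y, mode="reflect")
    return np.hypot(gx, gy)


def _lowpass(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15) -> np.ndarray:
    rows, cols = shape
    y = np.fft.fftfreq(rows)[:, None]
    x = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(x, y)
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(
    image: np.ndarray,
    nscale: int = 4,
    norient: int = 4,
    min_wavelength: float = 6.0,
    mult: float = 2.0,
    sigma_onf: float = 0.55,
    k: float = 2.0,
    eps: float = 1e-4,
) -> np.ndarray:
    """Phase-congruency map in [0, 1] via a log-Gabor filter bank.

    For each of ``norient`` orientations, even/odd responses at ``nscale``
    log-Gabor scales are combined into a local energy that measures how
    tightly the component phases agree; energy below a noise floor
    (estimated from the smallest-scale amplitude, Rayleigh model, ``k``
    standard deviations) is suppressed, and the result is normalised by the
    total filter amplitude.  A constant image has zero response at every
    filter (log-Gabors have no DC component) and so maps to ~0 everywhere.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    rows, cols = image.shape
    im_fft = fft2(image)

    y = np.fft.fftfreq(rows)[:, None]
    x = np.fft.fftfreq(cols)[None, :]
    radius = np.hypot(x, y)
    radius[0, 0] = 1.0  # avoid log(0); the DC gain is zeroed below
    theta = np.arctan2(-y, x)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpass((rows, cols))

    log_gabors = []
    for s in range(nscale):
        wavelength = min_wavelength * mult**s
        f0 = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / f0) ** 2) / (2.0 * np.log(sigma_onf) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    theta_sigma = math.pi / norient / 1.3
    total_energy = np.zeros((rows, cols))
    total_amplitude = np.zeros((rows, cols))

    for o in range(norient):
        angle = o * math.pi / norient
        ds = sintheta * math.cos(angle) - costheta * math.sin(angle)
        dc = costheta * math.cos(angle) + sintheta * math.sin(angle)
        dtheta = np.abs(np.arctan2(ds, dc))
        spread = np.exp(-(dtheta**2) / (2.0 * theta_sigma**2))

        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        tau = 0.0
        for s in range(nscale):
            eo = ifft2(im_fft * log_gabors[s] * spread)
            e, od = eo.real, eo.imag
            an = np.hypot(e, od)
            sum_e += e
            sum_o += od
            sum_an += an
            if s == 0:
                tau = float(np.median(an)) / math.sqrt(math.log(4.0))

        x_energy = np.hypot(sum_e, sum_o) + eps
        mean_e = sum_e / x_energy
        mean_o = sum_o / x_energy
        # re-accumulate the phase-deviation energy against the mean phase
        energy = np.zeros((rows, cols))
        for s in range(nscale):
            eo = ifft2(im_fft * log_gabors[s] * spread)
            e, od = eo.real, eo.imag
            energy += e * mean_e + od * mean_o - np.abs(e * mean_o - od * mean_e)

        # Rayleigh noise floor from the smallest-scale amplitude
        total_tau = tau * (1.0 - (1.0 / mult) ** nscale) / (1.0 - 1.0 / mult)
        noise_mean = total_tau * math.sqrt(math.pi / 2.0)
        noise_sigma = total_tau * math.sqrt((4.0 - math.pi) / 2.0)
        t_floor = noise_mean + k * noise_sigma
        energy = np.maximum(energy - t_floor, 0.0)

        total_energy += energy
        total_amplitude += sum_an

    pc = total_energy / (total_amplitude + eps)
    return np.clip(pc, 0.0, 1.0)


def fsim(
    ref: np.ndarray,
    test: np.ndarray,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
) -> float:
    """Feature similarity index in [0, 1].

    ``S_PC = (2 PC1 PC2 + T1) / (PC1^2 + PC2^2 + T1)``,
    ``S_G  = (2 G1 G2 + T2) / (G1^2 + G2^2 + T2)``, combined as
    ``S_L = S_PC * S_G`` and pooled with weights ``PC_m = max(PC1, PC2)``.

    Feature-free pairs (both phase-congruency maps ~0, e.g. two constant
    images) score 1 when the images are identical and raise otherwise.
    """
    ref, test = _pair(ref, test)
    pc1 = phase_congruency(ref)
    pc2 = phase_congruency(test)
    g1 = gradient_magnitude(ref)
    g2 = gradient_magnitude(test)
    s_pc = (2.0 * pc1 * pc2 + t1) / (pc1**2 + pc2**2 + t1)
    s_g = (2.0 * g1 * g2 + t2) / (g1**2 + g2**2 + t2)
    pc_m = np.maximum(pc1, pc2)
    denom = float(pc_m.sum())
    if denom <= 0.0:
        if np.array_equal(ref, test):
            return 1.0
        raise ValueError("neither image contains features (zero phase congruency)")
    return float(np.sum(s_pc * s_g * pc_m) / denom)


def compute_metric_report(
    ref: np.ndarray,
    test: np.ndarray,
    c1: float = DEFAULT_C1,
    c2: float = DEFAULT_C2,
    t1: float = DEFAULT_T1,
    t2: float = DEFAULT_T2,
    windowed_ssim: bool = False,
) -> MetricReport:
    """All four metrics for one (reference, test) pair.

    A pair on which FSIM is undefined (two different featureless images)
    records ``fsim = nan`` (serialised as null) rather than failing the
    whole report.
    """
    try:
        fsim_value = fsim(ref, test, t1=t1, t2=t2)
    except ValueError:
        fsim_value = math.nan
    return MetricReport(
        psnr=psnr(ref, test),
        rmse=rmse(ref, test),
        ssim=ssim(ref, test, c1=c1, c2=c2, windowed=windowed_ssim),
        fsim=fsim_value,
        constants_used={"C1": c1, "C2": c2, "T1": t1, "T2": t2},
    )
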