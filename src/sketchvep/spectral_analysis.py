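"""Spatial-frequency analysis of stimulus images.

Power spectral density by unnormalized 2-D FFT of a centered square
crop, radial averaging onto a cycles/degree axis, Kolmogorov-Smirnov
comparison of power-weighted frequency distributions across SNR levels,
and the theoretical frequency range of a square feature glyph.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import kolmogorov


def power_spectral_density(image: np.ndarray, region_px: int = 1080) -> np.ndarray:
    """2-D power spectrum of the centered square crop of an image.

    The crop side is ``min(region_px, largest centered square)``.  Power
    is the squared modulus of the unnormalized, fft-shifted discrete
    Fourier transform (no window), so Parseval reads
    ``psd.sum() == n**2 * (crop**2).sum()``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {img.shape}")
    n = min(region_px, *img.shape)
    if n < 1:
        raise ValueError("cannot take a square crop of the image")
    r0 = (img.shape[0] - n) // 2
    c0 = (img.shape[1] - n) // 2
    crop = img[r0 : r0 + n, c0 : c0 + n]
    return np.abs(np.fft.fftshift(np.fft.fft2(crop))) ** 2


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged power spectrum on a cycles/degree axis."""

    frequencies: np.ndarray  # cycles/degree, strictly increasing, >= 0
    power: np.ndarray  # mean power per radial bin
    pixel_angle_deg: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if (np.diff(f) <= 0).any() or (f < 0).any():
            raise ValueError("frequencies must be non-negative and increasing")
        if (np.asarray(self.power) < 0).any():
            raise ValueError("power must be non-negative")


def radial_average(
    psd: np.ndarray | list[np.ndarray], pixel_angle_deg: float
) -> RadialSpectrum:
    """Average a (stack of) square 2-D power spectra over radial bins.

    Bins group pixels by integer distance (rounded) from the DC bin; the
    frequency of radius r is ``r / (n * pixel_angle_deg)`` cycles/degree.
    Every pixel of the psd falls in exactly one bin.
    """
    stack = [np.asarray(p, dtype=float) for p in
             (psd if isinstance(psd, list) else [psd])]
    n = stack[0].shape[0]
    for p in stack:
        if p.shape != (n, n):
            raise ValueError("all spectra must be square with a common size")
    center = n // 2  # DC after fftshift
    yy, xx = np.indices((n, n))
    radius = np.rint(np.hypot(yy - center, xx - center)).astype(int)
    n_bins = radius.max() + 1
    counts = np.bincount(radius.ravel(), minlength=n_bins)
    mean_power = np.zeros(n_bins)
    for p in stack:
        mean_power += np.bincount(radius.ravel(), weights=p.ravel(),
                                  minlength=n_bins) / counts
    mean_power /= len(stack)
    freqs = np.arange(n_bins) / (n * pixel_angle_deg)
    return RadialSpectrum(freqs, mean_power, pixel_angle_deg)


def _power_cdf(spec: RadialSpectrum) -> np.ndarray:
    total = spec.power.sum()
    if total <= 0:
        raise ValueError("spectrum has no power")
    return np.cumsum(spec.power) / total


def compare_spectra(
    spectra: dict[int, RadialSpectrum]
) -> dict[tuple[int, int], dict[str, float]]:
    """Pairwise KS comparison of power-weighted frequency distributions.

    For each condition, power is normalized into a distribution over the
    common frequency grid; the KS statistic is the maximum absolute
    difference of the cumulative distributions, with the asymptotic
    two-sample p-value computed at an effective sample size of
    ``n_bins / 2`` per condition (documented approximation: bins are
    treated as the resolution elements of the distribution).
    """
    if len(spectra) < 2:
        raise ValueError("need at least two conditions")
    keys = sorted(spectra)
    grid = spectra[keys[0]].frequencies
    for k in keys[1:]:
        if not np.array_equal(spectra[k].frequencies, grid):
            raise ValueError("spectra are not on a common frequency grid")
    results = {}
    m = len(grid)
    n_eff = (m / 2 * m / 2) / (m / 2 + m / 2)  # = m/4
    for a, b in combinations(keys, 2):
        d = float(np.max(np.abs(_power_cdf(spectra[a]) - _power_cdf(spectra[b]))))
        p = float(min(1.0, kolmogorov(d * np.sqrt(n_eff)))) if d > 0 else 1.0
        results[(a, b)] = {"statistic": d, "p_value": p}
    return results


def low_frequency_fraction(spec: RadialSpectrum, cutoff_cpd: float = 4.0) -> float:
    """Fraction of total (non-DC) power below a cycles/degree cutoff."""
    mask = spec.frequencies > 0
    power = spec.power[mask]
    return float(power[spec.frequencies[mask] < cutoff_cpd].sum() / power.sum())


def theoretical_frequency_range(
    feature_px: int = 9, pixel_angle_deg: float = 0.0289
) -> tuple[float, float]:
    """Theoretical 1-D spatial-frequency range of a square feature glyph.

    The lower bound is one cycle per feature width, ``1 / (feature_px *
    pixel_angle_deg)``; the upper bound is one cycle per pattern cell
    (3 px), i.e. three times the lower bound.  At the printed pixel angle
    of 0.0289 deg a 9 px glyph spans 3.84-11.53 cycles/degree.
    """
    if feature_px <= 0 or pixel_angle_deg <= 0:
        raise ValueError("feature size and pixel angle must be positive")
    f_min = 1.0 / (feature_px * pixel_angle_deg)
    return f_min, 3.0 * f_min


def printed_frequency_range(
    feature_px: int = 9, pixel_angle_deg: float = 0.0289
) -> tuple[float, float]:
    """Frequency range rounded the way such bounds are usually printed.

    The lower bound is rounded to two decimals first and the upper bound
    is three times the rounded value (3.84 -> 11.52 at 0.0289 deg/px).
    """
    f_min, _ = theoretical_frequency_range(feature_px, pixel_angle_deg)
    f_min = round(f_min, 2)
    return f_min, round(3.0 * f_min, 2)
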