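"""Fourier ring correlation resolution estimation.

The localization set is randomly split into two statistically independent
halves; each half is rendered as a count histogram on the same grid
(zero-padded to a square power of two), and the normalized cross-correlation
of their discrete Fourier transforms is averaged over integer-radius
frequency rings:

    FRC(q) = Re sum_ring F1 conj(F2) / sqrt(sum_ring |F1|^2 sum_ring |F2|^2)

The image resolution is 1/q* where q* is the first ring at which the
(3-ring smoothed) curve falls below a fixed threshold, 1/7 by default.
The resolution-vs-integration-time analysis repeats this on random frame
subsets of increasing total exposure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from paintkit.render import render_histogram
from paintkit.table import LocalizationTable

DEFAULT_FRC_THRESHOLD = 1.0 / 7.0
DEFAULT_N_REPS = 3
SMOOTH_RINGS = 3


@dataclass
class FRCCurve:
    """Ring correlations with the derived threshold-crossing resolution."""

    frequencies: np.ndarray     # 1/nm, strictly increasing, <= Nyquist
    correlations: np.ndarray
    render_bin: float           # nm/px
    threshold: float = DEFAULT_FRC_THRESHOLD
    resolution: Optional[float] = None  # nm; None when no crossing

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.render_bin)


@dataclass
class ResolutionSeries:
    """FRC resolution vs integration time (mean and sd over replicates)."""

    times: np.ndarray           # s
    mean_resolution: np.ndarray  # nm
    sd_resolution: np.ndarray    # nm (NaN where < 2 defined replicates)
    n_reps: int
    replicates: Optional[np.ndarray] = None  # (n_times, n_reps), NaN = no crossing


def _pad_to_pow2_square(img: np.ndarray) -> np.ndarray:
    n = 1 << int(np.ceil(np.log2(max(img.shape))))
    out = np.zeros((n, n))
    out[: img.shape[0], : img.shape[1]] = img
    return out


def ring_correlation(img1: np.ndarray, img2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FRC numerator/denominator aggregated over integer-radius rings.

    Returns (ring radii in FFT pixels 1..n/2, correlation per ring). Every
    Fourier pixel up to Nyquist belongs to exactly one ring (radius rounded
    to nearest integer).
    """
    if img1.shape != img2.shape:
        raise ValueError("images must share a shape")
    f1 = np.fft.fftshift(np.fft.fft2(img1))
    f2 = np.fft.fftshift(np.fft.fft2(img2))
    n = img1.shape[0]
    center = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    radius = np.rint(np.hypot(xx - center, yy - center)).astype(int)
    n_rings = n // 2
    num = np.bincount(radius.ravel(), weights=(f1 * np.conj(f2)).real.ravel(),
                      minlength=n_rings + 1)[1 : n_rings + 1]
    d1 = np.bincount(radius.ravel(), weights=(np.abs(f1) ** 2).ravel(),
                     minlength=n_rings + 1)[1 : n_rings + 1]
    d2 = np.bincount(radius.ravel(), weights=(np.abs(f2) ** 2).ravel(),
                     minlength=n_rings + 1)[1 : n_rings + 1]
    denom = np.sqrt(d1 * d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where(denom > 0, num / denom, 0.0)
    return np.arange(1, n_rings + 1), frc


def split_table(table: LocalizationTable, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random equal-half partition of record indices."""
    n = len(table)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return perm[:half], perm[half:]

def frc_curve(
    table: LocalizationTable,
    render_bin: float = 10.0,
    split_seed: int = 0,
    threshold: float = DEFAULT_FRC_THRESHOLD,
) -> FRCCurve:
    """FRC of two random half-datasets rendered on a common grid."""
    if len(table) < 2:
        raise ValueError("need at least 2 localizations for an FRC split")
    idx1, idx2 = split_table(table, split_seed)
    mask1 = np.zeros(len(table), dtype=bool)
    mask1[idx1] = True
    img1 = render_histogram(table.select(mask1), render_bin).pixels
    img2 = render_histogram(table.select(~mask1), render_bin).pixels
    return frc_from_images(img1, img2, render_bin, threshold)


def frc_from_images(
    img1: np.ndarray,
    img2: np.ndarray,
    render_bin: float,
    threshold: float = DEFAULT_FRC_THRESHOLD,
) -> FRCCurve:
    """FRC curve and resolution from two pre-rendered half-images."""
    p1 = _pad_to_pow2_square(np.asarray(img1, dtype=float))
    p2 = _pad_to_pow2_square(np.asarray(img2, dtype=float))
    rings, corr = ring_correlation(p1, p2)
    n = p1.shape[0]
    freqs = rings / (n * render_bin)  # 1/nm
    curve = FRCCurve(freqs, corr, render_bin, threshold)
    curve.resolution = frc_resolution(curve, threshold)
    return curve


def frc_resolution(curve: FRCCurve, threshold: float = DEFAULT_FRC_THRESHOLD) -> Optional[float]:
    """Resolution (nm) = 1 / first smoothed-curve crossing below threshold.

    The curve is smoothed with a 3-ring moving average before crossing
    detection; the crossing frequency is linearly interpolated between the
    bracketing rings. Returns None when the curve never falls below the
    threshold before Nyquist.
    """
    corr = curve.correlations
    if corr.size < 2:
        return None
    kernel = np.ones(SMOOTH_RINGS) / SMOOTH_RINGS
    smoothed = np.convolve(corr, kernel, mode="same")
    # edges of 'same' convolution average fewer rings; renormalize
    counts = np.convolve(np.ones_like(corr), kernel, mode="same")
    smoothed = smoothed / counts
    below = smoothed < threshold
    if not below.any():
        return None
    i = int(np.argmax(below))
    if i == 0:
        q_star = curve.frequencies[0]
    else:
        f0, f1 = curve.frequencies[i - 1], curve.frequencies[i]
        c0, c1 = smoothed[i - 1], smoothed[i]
        q_star = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0) if c0 != c1 else f1
    return float(1.0 / q_star)


def sample_frame_subset(
    frames: np.ndarray, n_frames_wanted: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct frame indices sampled without replacement (scattered subset)."""
    unique = np.unique(frames)
    if n_frames_wanted > unique.size:
        raise ValueError("requested more frames than the acquisition contains")
    return rng.choice(unique, size=n_frames_wanted, replace=False)


def resolution_vs_integration(
    table: LocalizationTable,
    times: Sequence[float],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    render_bin: float = 10.0,
    threshold: float = DEFAULT_FRC_THRESHOLD,
) -> ResolutionSeries:
    """FRC resolution at increasing integration times on random frame subsets.

    For each integration time t, ``n_reps`` random subsets of
    ``t / exposure`` frames are drawn (without replacement, scattered across
    the acquisition); the per-subset FRC resolution's mean and sd are
    reported. A replicate without a threshold crossing contributes NaN.
    """
    frames = table.df["frame"].to_numpy(dtype=int)
    total_duration = frames.max() * table.exposure
    rng = np.random.default_rng(seed)
    means, sds, reps = [], [], []
    for t in times:
        if t > total_duration + 1e-9:
            raise ValueError(f"integration time {t} s exceeds acquisition {total_duration} s")
        n_sub = int(round(t / table.exposure))
        vals = []
        for _ in range(n_reps):
            chosen = sample_frame_subset(frames, n_sub, rng)
            sub = table.select(np.isin(frames, chosen))
            if len(sub) < 2:
                vals.append(np.nan)
                continue
            curve = frc_curve(sub, render_bin, split_seed=int(rng.integers(2**31)),
                              threshold=threshold)
            vals.append(np.nan if curve.resolution is None else curve.resolution)
        vals = np.array(vals, dtype=float)
        reps.append(vals)
        defined = vals[np.isfinite(vals)]
        means.append(defined.mean() if defined.size else np.nan)
        sds.append(defined.std(ddof=1) if defined.size >= 2 else np.nan)
    return ResolutionSeries(np.asarray(times, dtype=float), np.array(means),
                            np.array(sds), n_reps, np.array(reps))
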