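"""Spot detection and sub-pixel 2D Gaussian fitting of camera frames.

Implements a ThunderSTORM-style least-squares localization chain: a
difference-of-Gaussians band-pass with a robust (MAD-based) intensity
threshold proposes candidate pixels; each candidate is fit with an
integrated-intensity symmetric 2D Gaussian over a small window; the lateral
localization precision is estimated with the Thompson-style least-squares
formula; and a strict precision filter (< 30 nm by default) removes poor
fits.

Coordinate convention: x, y in nm, origin at the outer corner of pixel
(0, 0); a point at the center of pixel (row i, col j) maps to
``((j + 0.5) * a, (i + 0.5) * a)`` with pixel size ``a``. Frames are
1-based in output tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from paintkit.table import LocalizationTable

#: Default strict upper bound on lateral uncertainty (nm).
DEFAULT_PRECISION_THRESHOLD_NM = 30.0

DEFAULT_FIT_WINDOW = 7  # px, odd


class FitRejected(Exception):
    """Raised when a candidate cannot be fit to a credible single emitter."""


def detect_spots(
    frame_image: np.ndarray,
    band_sigmas_px: tuple[float, float] = (1.0, 2.5),
    peak_threshold: float = 5.0,
    window: int = DEFAULT_FIT_WINDOW,
) -> np.ndarray:
    """Candidate emitter pixels from a band-pass filtered frame.

    The frame is filtered with a difference of Gaussians (sigmas in px);
    strict local maxima of the filtered image exceeding
    ``peak_threshold x robust-sd`` (MAD estimate of the filtered background
    noise) are returned as (row, col) pairs. Candidates closer than half the
    fit window to an edge are dropped.
    """
    img = np.asarray(frame_image, dtype=float)
    if img.size == 0:
        return np.empty((0, 2), dtype=int)
    s1, s2 = band_sigmas_px
    band = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, s2)
    med = np.median(band)
    mad = np.median(np.abs(band - med))
    robust_sd = 1.4826 * mad
    if robust_sd == 0:
        robust_sd = np.finfo(float).tiny
    thresh = med + peak_threshold * robust_sd
    # strict local maxima on the band-passed image
    footprint = np.ones((3, 3), dtype=bool)
    maxima = (band == ndimage.maximum_filter(band, footprint=footprint)) & (band > thresh)
    # suppress plateau duplicates: keep one pixel per connected maximum
    labeled, n = ndimage.label(maxima)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    coords = np.array(
        ndimage.maximum_position(band, labeled, index=np.arange(1, n + 1)), dtype=int
    ).reshape(-1, 2)
    half = window // 2
    rows, cols = img.shape
    ok = (
        (coords[:, 0] >= half)
        & (coords[:, 0] < rows - half)
        & (coords[:, 1] >= half)
        & (coords[:, 1] < cols - half)
    )
    return coords[ok]


@dataclass
class GaussianFit:
    """Raw fit result in pixel units (converted to nm by the caller)."""

    x0_px: float  # column coordinate, pixel-center convention
    y0_px: float  # row coordinate
    sigma_px: float
    amplitude: float
    background: float
    photons: float
    bkg_sd: float


def _gaussian_model(params: np.ndarray, xx: np.ndarray, yy: np.ndarray) -> np.ndarray:
    b, A, x0, y0, s = params
    return b + A * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * s**2))


def fit_gaussian(
    frame_image: np.ndarray,
    candidate: tuple[int, int],
    window: int = DEFAULT_FIT_WINDOW,
    psf_sigma_px: float = 1.5,
) -> GaussianFit:
    """Least-squares symmetric 2D Gaussian fit around a candidate pixel.

    Fits ``b + A exp(-((x-x0)^2 + (y-y0)^2) / (2 s^2))`` over a
    ``window x window`` region. Photon count is ``N = 2 pi A s^2`` in pixel
    units. Raises :class:`FitRejected` on non-convergence, vanishing
    amplitude, or a fitted width outside ``[0.5, 3] x psf_sigma_px``.
    """
    img = np.asarray(frame_image, dtype=float)
    half = window // 2
    r, c = candidate
    if r - half < 0 or c - half < 0 or r + half >= img.shape[0] or c + half >= img.shape[1]:
        raise FitRejected("fit window extends beyond the frame")
    patch = img[r - half : r + half + 1, c - half : c + half + 1]
    yy, xx = np.mgrid[r - half : r + half + 1, c - half : c + half + 1].astype(float)

    b0 = float(patch.min())
    A0 = max(float(patch.max() - b0), 1e-3)
    p0 = np.array([b0, A0, float(c), float(r), psf_sigma_px])
    lb = [-np.inf, 1e-9, c - half, r - half, 0.25 * psf_sigma_px]
    ub = [np.inf, np.inf, c + half, r + half, 4.0 * psf_sigma_px]
    try:
        res = least_squares(
            lambda p: (_gaussian_model(p, xx, yy) - patch).ravel(),
            p0, bounds=(lb, ub), method="trf", max_nfev=200,
        )
    except Exception as exc:  # pragma: no cover - scipy internal failures
        raise FitRejected(str(exc)) from exc
    if not res.success:
        raise FitRejected("fit did not converge")
    b, A, x0, y0, s = res.x
    if not (0.5 * psf_sigma_px <= s <= 3.0 * psf_sigma_px):
        raise FitRejected(f"fitted sigma {s:.2f} px outside prior range")
    photons = 2.0 * np.pi * A * s**2
    if photons <= 0 or A < 1e-6:
        raise FitRejected("vanishing amplitude")
    resid = (_gaussian_model(res.x, xx, yy) - patch).ravel()
    bkg_sd = float(np.std(resid))
    return GaussianFit(x0, y0, s, A, b, photons, bkg_sd)


def estimate_precision(
    sigma_nm: float, photons: float, bkg_sd: float, pixel_size: float
) -> float:
    """Thompson-style least-squares lateral localization precision (nm).

    ``sigma_loc = sqrt((s^2 + a^2/12)/N + 8 pi s^4 b^2 / (a^2 N^2))`` with
    PSF sd ``s`` (nm), pixel size ``a`` (nm), photon count ``N`` and
    background sd per pixel ``b`` (photons).
    """
    if photons <= 0:
        raise ValueError("photon count must be positive")
    s2 = sigma_nm**2
    a2 = pixel_size**2
    var = (s2 + a2 / 12.0) / photons
    if pixel_size > 0:
        var += 8.0 * np.pi * s2**2 * bkg_sd**2 / (a2 * photons**2)
    return float(np.sqrt(var))


def localize_frame(
    frame_image: np.ndarray,
    frame_index: int,
    pixel_size: float,
    psf_sigma_px: float = 1.5,
    band_sigmas_px: tuple[float, float] = (1.0, 2.5),
    peak_threshold: float = 5.0,
    window: int = DEFAULT_FIT_WINDOW,
) -> list[dict]:
    """Detect and fit all emitters in one frame; returns record dicts.

    Duplicate fits landing within one fitted sigma of a brighter fit in the
    same frame are discarded (keep-the-brighter rule).
    """
    records: list[dict] = []
    for r, c in detect_spots(frame_image, band_sigmas_px, peak_threshold, window):
        try:
            fit = fit_gaussian(frame_image, (int(r), int(c)), window, psf_sigma_px)
        except FitRejected:
            continue
        x_nm = (fit.x0_px + 0.5) * pixel_size
        y_nm = (fit.y0_px + 0.5) * pixel_size
        s_nm = fit.sigma_px * pixel_size
        unc = estimate_precision(s_nm, fit.photons, fit.bkg_sd, pixel_size)
        records.append(
            dict(frame=frame_index, x=x_nm, y=y_nm, sigma=s_nm,
                 intensity=fit.photons, offset=fit.background,
                 bkgstd=fit.bkg_sd, uncertainty=unc)
        )
    # keep-the-brighter duplicate suppression
    records.sort(key=lambda rec: -rec["intensity"])
    kept: list[dict] = []
    for rec in records:
        dup = any(
            np.hypot(rec["x"] - k["x"], rec["y"] - k["y"]) < k["sigma"] for k in kept
        )
        if not dup:
            kept.append(rec)
    kept.sort(key=lambda rec: (rec["x"], rec["y"]))
    return kept


def localize_stack(
    stack: np.ndarray,
    pixel_size: float,
    exposure: float,
    psf_sigma_px: float = 1.5,
    band_sigmas_px: tuple[float, float] = (1.0, 2.5),
    peak_threshold: float = 5.0,
    window: int = DEFAULT_FIT_WINDOW,
    fov: Optional[tuple[float, float]] = None,
) -> LocalizationTable:
    """Localize every frame of a stack into a LocalizationTable (frames 1-based)."""
    all_records: list[dict] = []
    for k, frame in enumerate(stack):
        all_records.extend(
            localize_frame(frame, k + 1, pixel_size, psf_sigma_px,
                           band_sigmas_px, peak_threshold, window)
        )
    df = pd.DataFrame(
        all_records,
        columns=["frame", "x", "y", "sigma", "intensity", "offset", "bkgstd", "uncertainty"],
    )
    if fov is None:
        rows, cols = stack.shape[1], stack.shape[2]
        fov = (cols * pixel_size, rows * pixel_size)
    return LocalizationTable(df, pixel_size=pixel_size, exposure=exposure, fov=fov)


def filter_precision(
    table: LocalizationTable, max_uncertainty: float = DEFAULT_PRECISION_THRESHOLD_NM
) -> LocalizationTable:
    """Retain records with uncertainty strictly below the threshold (nm)."""
    unc = table.df["uncertainty"].to_numpy(dtype=float)
    return table.select(unc < max_uncertainty)
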