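"""Spot detection, center-of-mass fitting and localization filtering.

Raw camera frames are band-pass filtered (difference of Gaussians), local
maxima above a robust noise threshold become candidate windows, and each
window is fit by background-subtracted center of mass. Photometric and shape
descriptors (integrated intensity, RMS width sqrt(l1+l2), asymmetry
sqrt(l1/l2) from the second-moment matrix) feed the downstream threshold
filter that rejects dim, overlapping or aberrant spots.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidArgumentError
from .tables import make_table, validate_table

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterThresholds:
    """Intensity / asymmetry / width acceptance windows for localizations.

    Defaults select well-formed single emitters: at least 100 photons, an
    asymmetry below 1.5 (rejects overlapping/double emitters), and an RMS
    width between 0.5x and 2x the nominal PSF-derived width.
    """

    min_intensity: float = 100.0
    max_asymmetry: float = 1.5
    width_nm_range: tuple = (70.0, 283.0)  # [0.5, 2] x sqrt(2)*psf_sigma for a 100 nm PSF

    def __post_init__(self):
        lo, hi = self.width_nm_range
        if not lo < hi:
            raise InvalidArgumentError("width range must satisfy min < max")

    @classmethod
    def for_psf(cls, psf_sigma_nm: float, min_intensity: float = 100.0, max_asymmetry: float = 1.5):
        rms = np.sqrt(2.0) * psf_sigma_nm  # isotropic Gaussian: l1 = l2 = sigma^2
        return cls(min_intensity, max_asymmetry, (0.5 * rms, 2.0 * rms))


def detect_spots(
    frame: np.ndarray,
    detection_sigma_threshold: float = 5.0,
    window_px: int = 7,
    dog_sigmas: tuple = (1.0, 3.0),
):
    """Find candidate spot windows in one frame.

    The frame is band-passed with a difference of Gaussians, and local maxima
    exceeding median + threshold * robust noise sigma (1.4826 * MAD) are
    kept; maxima closer than one window are merged to the brighter one.
    Returns a list of ``(row, col)`` integer maxima positions.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise InvalidArgumentError("frame must be 2D")
    if frame.size == 0:
        return []
    bp = ndimage.gaussian_filter(frame, dog_sigmas[0]) - ndimage.gaussian_filter(frame, dog_sigmas[1])
    med = np.median(bp)
    sigma = 1.4826 * np.median(np.abs(bp - med))
    thresh = med + detection_sigma_threshold * max(sigma, 1e-12)
    # local maxima within a window_px neighborhood
    maxf = ndimage.maximum_filter(bp, size=window_px, mode="nearest")
    peaks = (bp >= maxf) & (bp > thresh)
    coords = np.argwhere(peaks)
    if len(coords) == 0:
        return []
    # merge residual close pairs (plateaus / adjacent maxima) keeping the brighter
    order = np.argsort(-bp[coords[:, 0], coords[:, 1]])
    coords = coords[order]
    kept = []
    for rc in coords:
        if all(max(abs(rc[0] - k[0]), abs(rc[1] - k[1])) >= window_px for k in kept):
            kept.append((int(rc[0]), int(rc[1])))
    return kept


def fit_com(window: np.ndarray, camera_pixel_nm: float = 100.0, origin_px=(0, 0)):
    """Background-subtracted center-of-mass fit of one spot window.

    Background is the mean of the window's border pixels; after subtraction,
    negative residuals are clipped to zero. Returns a dict with x_nm, y_nm,
    intensity_photons, sigma_nm (RMS size), asymmetry — or ``None`` when the
    residual has no mass (reject-window signal).
    """
    window = np.asarray(window, dtype=float)
    if window.ndim != 2 or window.shape[0] != window.shape[1] or window.shape[0] < 5:
        raise InvalidArgumentError("window must be square with side >= 5 pixels")
    border = np.concatenate([window[0], window[-1], window[1:-1, 0], window[1:-1, -1]])
    resid = np.clip(window - border.mean(), 0.0, None)
    total = resid.sum()
    if total <= 0:
        return None
    rows, cols = np.mgrid[0 : window.shape[0], 0 : window.shape[1]]
    cy = (rows * resid).sum() / total
    cx = (cols * resid).sum() / total
    dy = rows - cy
    dx = cols - cx
    mxx = (dx * dx * resid).sum() / total
    myy = (dy * dy * resid).sum() / total
    mxy = (dx * dy * resid).sum() / total
    tr, det = mxx + myy, mxx * myy - mxy * mxy
    disc = max(0.25 * tr * tr - det, 0.0)
    l1 = 0.5 * tr + np.sqrt(disc)
    l2 = max(0.5 * tr - np.sqrt(disc), 1e-12)
    r0, c0 = origin_px
    return {
        "x_nm": (c0 + cx + 0.5) * camera_pixel_nm,
        "y_nm": (r0 + cy + 0.5) * camera_pixel_nm,
        "intensity_photons": float(total),
        "sigma_nm": float(np.sqrt(l1 + l2)) * camera_pixel_nm,
        "asymmetry": float(np.sqrt(l1 / l2)),
    }


def localize_frames(
    frames,
    camera_pixel_nm: float = 100.0,
    detection_sigma_threshold: float = 5.0,
    window_px: int = 7,
) -> pd.DataFrame:
    """Detect and fit spots in every frame of a stack; returns a table."""
    rows = {k: [] for k in ("frame", "x_nm", "y_nm", "intensity_photons", "sigma_nm", "asymmetry")}
    half = window_px // 2
    for f, frame in enumerate(frames):
        h, w = frame.shape
        for (r, c) in detect_spots(frame, detection_sigma_threshold, window_px):
            r0, c0 = r - half, c - half
            r1, c1 = r0 + window_px, c0 + window_px
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                continue  # fitting window clipped by frame edge
            loc = fit_com(frame[r0:r1, c0:c1], camera_pixel_nm, origin_px=(r0, c0))
            if loc is None:
                continue
            rows["frame"].append(f)
            for k, v in loc.items():
                rows[k].append(v)
    return make_table(
        np.asarray(rows["x_nm"]),
        np.asarray(rows["y_nm"]),
        frame=np.asarray(rows["frame"], dtype=int),
        intensity_photons=np.asarray(rows["intensity_photons"]),
        sigma_nm=np.asarray(rows["sigma_nm"]),
        asymmetry=np.asarray(rows["asymmetry"]),
        channel="A",
    )


def filter_localizations(
    table: pd.DataFrame,
    thresholds: FilterThresholds,
    return_report: bool = False,
):
    """Apply the intensity / asymmetry / width acceptance filter.

    Row order is preserved. Per-criterion removal counts are logged; pass
    ``return_report=True`` to receive them as a dict alongside the table.
    """
    validate_table(table, require=["intensity_photons", "asymmetry", "sigma_nm"])
    inten = table["intensity_photons"].to_numpy(dtype=float)
    asym = table["asymmetry"].to_numpy(dtype=float)
    width = table["sigma_nm"].to_numpy(dtype=float)
    lo, hi = thresholds.width_nm_range
    ok_i = inten >= thresholds.min_intensity
    ok_a = asym <= thresholds.max_asymmetry
    ok_w = (width >= lo) & (width <= hi)
    keep = ok_i & ok_a & ok_w
    report = {
        "n_in": int(len(table)),
        "n_kept": int(keep.sum()),
        "removed_intensity": int((~ok_i).sum()),
        "removed_asymmetry": int((~ok_a).sum()),
        "removed_width": int((~ok_w).sum()),
    }
    log.info("filter_localizations: %s", report)
    out = table.loc[keep].reset_index(drop=True)
    return (out, report) if return_report else out
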