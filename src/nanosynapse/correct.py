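"""Lateral drift correction and two-channel registration.

Drift is estimated either by redundant cross-correlation (RCC: the stack is
split into temporal segments, every segment pair is aligned by sub-pixel
image cross-correlation, and the over-determined set of pairwise shifts is
combined by least squares) or, for PAINT-style acquisitions, by tracking
fiducial beads frame by frame. The chromatic offset between channels is a
global affine transform fit to matched bead positions by least squares.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.fft import irfft2, rfft2

from .errors import (
    DegenerateGeometryError,
    InsufficientDataError,
    InsufficientFiducialsError,
    InvalidArgumentError,
)
from .render import render

log = logging.getLogger(__name__)


@dataclass
class DriftTrajectory:
    """Per-frame lateral displacement (dx, dy) in nm relative to frame 0."""

    displacement_nm: np.ndarray  # (n_frames, 2)

    def __post_init__(self):
        self.displacement_nm = np.asarray(self.displacement_nm, dtype=float)
        if self.displacement_nm.ndim != 2 or self.displacement_nm.shape[1] != 2:
            raise InvalidArgumentError("displacement must be (n_frames, 2)")
        # trajectories are always expressed relative to frame 0
        self.displacement_nm = self.displacement_nm - self.displacement_nm[0]

    @property
    def n_frames(self) -> int:
        return len(self.displacement_nm)

    def at(self, frames) -> np.ndarray:
        frames = np.asarray(frames, dtype=int)
        if frames.size and (frames.min() < 0 or frames.max() >= self.n_frames):
            raise InvalidArgumentError("frame outside drift trajectory domain")
        return self.displacement_nm[frames]

    def negated(self) -> "DriftTrajectory":
        return DriftTrajectory(-self.displacement_nm)


@dataclass
class AffineTransform2D:
    """x' = A x + t, with the fit residual bookkeeping from the bead fit."""

    matrix: np.ndarray          # (2, 2)
    translation_nm: np.ndarray  # (2,)
    residual_rms_nm: float = 0.0
    n_beads: int = 0
    per_bead_residuals_nm: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.translation_nm = np.asarray(self.translation_nm, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise InvalidArgumentError("transform linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.matrix.T + self.translation_nm

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform2D(inv, -inv @ self.translation_nm)

    def to_json(self, path=None):
        payload = {
            "matrix": self.matrix.tolist(),
            "translation_nm": self.translation_nm.tolist(),
            "residual_rms_nm": float(self.residual_rms_nm),
            "n_beads": int(self.n_beads),
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AffineTransform2D":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["matrix"]), np.array(d["translation_nm"]),
                   d.get("residual_rms_nm", 0.0), d.get("n_beads", 0))


def fit_channel_transform(ref_beads, moving_beads) -> AffineTransform2D:
    """Least-squares affine mapping moving-channel bead positions onto the
    reference channel: minimizes sum ||A p_mov + t - p_ref||^2."""
    ref = np.atleast_2d(np.asarray(ref_beads, dtype=float))
    mov = np.atleast_2d(np.asarray(moving_beads, dtype=float))
    if len(ref) != len(mov):
        raise InvalidArgumentError("bead lists must have equal length")
    if len(ref) < 3:
        raise DegenerateGeometryError("need >= 3 matched bead pairs")
    design = np.column_stack([mov, np.ones(len(mov))])
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateGeometryError("bead positions are collinear")
    coef, *_ = np.linalg.lstsq(design, ref, rcond=None)
    matrix = coef[:2].T
    translation = coef[2]
    pred = design @ coef
    per_bead = np.linalg.norm(pred - ref, axis=1)
    # residual RMS per coordinate, directly comparable to the per-axis
    # localization noise of the bead positions
    return AffineTransform2D(
        matrix,
        translation,
        residual_rms_nm=float(np.sqrt(np.sum(per_bead**2) / (2 * len(ref)))),
        n_beads=len(ref),
        per_bead_residuals_nm=per_bead,
    )


def _quadratic_peak_offset(cm, c0, cp):
    """Sub-pixel offset of a parabola through three samples around a peak."""
    denom = cm - 2.0 * c0 + cp
    if denom >= 0:  # degenerate (flat or valley): no refinement
        return 0.0
    return float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))


def _correlation_shift_px(fft_i, fft_j, shape):
    """Displacement (drow, dcol) of segment j's image relative to segment i's.

    Peak of the circular cross-correlation computed from the cached FFTs,
    refined by quadratic interpolation through the peak's neighbors along
    each axis; shifts beyond half the image wrap around.
    """
    corr = irfft2(fft_j * np.conj(fft_i), s=shape)
    r, c = np.unravel_index(np.argmax(corr), corr.shape)
    nr, nc = corr.shape
    dr = r + _quadratic_peak_offset(
        corr[(r - 1) % nr, c], corr[r, c], corr[(r + 1) % nr, c]
    )
    dc = c + _quadratic_peak_offset(
        corr[r, (c - 1) % nc], corr[r, c], corr[r, (c + 1) % nc]
    )
    if dr > nr / 2:
        dr -= nr
    if dc > nc / 2:
        dc -= nc
    return dr, dc


def _interp_with_extrapolation(x, xp, fp):
    """Piecewise-linear interpolation continuing the end slopes outward."""
    y = np.interp(x, xp, fp)
    if len(xp) >= 2:
        left = x < xp[0]
        right = x > xp[-1]
        y[left] = fp[0] + (x[left] - xp[0]) * (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[right] = fp[-1] + (x[right] - xp[-1]) * (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
    return y


def estimate_drift_rcc(
    table: pd.DataFrame,
    n_frames: Optional[int] = None,
    n_segments: int = 10,
    bin_nm: float = 10.0,
    min_locs_per_segment: int = 10,
    smooth_px: float = 1.0,
) -> DriftTrajectory:
    """Redundant cross-correlation drift estimation.

    Frames are split into ``n_segments`` consecutive segments, each rendered
    at ``bin_nm`` on a common raster (lightly Gaussian-smoothed to stabilize
    the correlation peak); the displacement of every segment pair (i < j) is
    measured by cross-correlation with quadratic sub-pixel peak
    interpolation, and segment positions are solved from all pairwise
    measurements by least squares (the redundancy averages down individual
    correlation errors). Per-frame drift is interpolated linearly between
    segment midpoints, continuing the end slopes to the stack boundaries,
    and re-zeroed to frame 0.
    """
    if len(table) == 0:
        raise InsufficientDataError("empty localization table")
    frames = table["frame"].to_numpy(dtype=int)
    if n_frames is None:
        n_frames = int(frames.max()) + 1
    if n_segments < 2:
        raise InvalidArgumentError("need >= 2 segments")
    edges = np.linspace(0, n_frames, n_segments + 1)
    seg_of = np.clip(np.searchsorted(edges, frames, side="right") - 1, 0, n_segments - 1)

    x = table["x_nm"].to_numpy(dtype=float)
    y = table["y_nm"].to_numpy(dtype=float)
    pad = 5 * bin_nm
    bounds = (
        np.floor((x.min() - pad) / bin_nm) * bin_nm,
        np.floor((y.min() - pad) / bin_nm) * bin_nm,
        np.ceil((x.max() + pad) / bin_nm) * bin_nm,
        np.ceil((y.max() + pad) / bin_nm) * bin_nm,
    )
    ffts, usable, shape = [], [], None
    for s in range(n_segments):
        sub = table.loc[seg_of == s]
        if len(sub) < min_locs_per_segment:
            log.warning("RCC: segment %d has %d localizations; excluded", s, len(sub))
            continue
        img = render(sub, pixel_size_nm=bin_nm, weight_mode="unit", bounds_nm=bounds).data
        if smooth_px > 0:
            img = ndimage.gaussian_filter(img, smooth_px)
        shape = img.shape
        usable.append(s)
        ffts.append(rfft2(img.astype(np.float32)))
    if len(usable) < 2:
        raise InsufficientDataError("fewer than 2 usable segments for RCC")

    # redundant pairwise shifts -> least-squares segment positions
    rows, rhs = [], []
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            drow, dcol = _correlation_shift_px(ffts[a], ffts[b], shape)
            coeff = np.zeros(len(usable))
            coeff[b] = 1.0
            coeff[a] = -1.0
            rows.append(coeff)
            rhs.append([dcol * bin_nm, drow * bin_nm])  # col ~ x, row ~ y
    design = np.asarray(rows)
    rhs = np.asarray(rhs)
    # anchor the first usable segment at 0
    design = design[:, 1:]
    pos, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    positions = np.vstack([np.zeros(2), pos])

    mids = np.array([(edges[s] + edges[s + 1]) / 2.0 for s in usable])
    all_frames = np.arange(n_frames, dtype=float)
    disp = np.column_stack(
        [_interp_with_extrapolation(all_frames, mids, positions[:, k]) for k in range(2)]
    )
    return DriftTrajectory(disp)


def estimate_drift_beads(
    table: pd.DataFrame,
    bead_seed_positions,
    n_frames: Optional[int] = None,
    search_radius_nm: float = 500.0,
    smooth_window: int = 11,
) -> DriftTrajectory:
    """Fiducial-tracking drift estimation (PAINT-style).

    For each frame, each bead contributes (observed position - its own mean
    position); the per-frame mean over beads is median-smoothed with an
    ``smooth_window``-frame window, missing frames are linearly interpolated,
    and the trajectory is re-zeroed to frame 0. Beads localized in fewer than
    half the frames are dropped.
    """
    seeds = np.atleast_2d(np.asarray(bead_seed_positions, dtype=float))
    frames = table["frame"].to_numpy(dtype=int)
    if n_frames is None:
        n_frames = int(frames.max()) + 1
    xy = table[["x_nm", "y_nm"]].to_numpy(dtype=float)

    tracks = np.full((len(seeds), n_frames, 2), np.nan)
    for b, seed in enumerate(seeds):
        d2 = np.sum((xy - seed) ** 2, axis=1)
        near = d2 <= search_radius_nm**2
        if not near.any():
            continue
        sub = pd.DataFrame({"frame": frames[near], "x": xy[near, 0], "y": xy[near, 1]})
        g = sub.groupby("frame")[["x", "y"]].mean()
        tracks[b, g.index.to_numpy(), 0] = g["x"].to_numpy()
        tracks[b, g.index.to_numpy(), 1] = g["y"].to_numpy()

    found = ~np.isnan(tracks[:, :, 0])
    good = found.sum(axis=1) >= 0.5 * n_frames
    if not good.any():
        raise InsufficientFiducialsError(
            "no bead localized within the search radius in >= 50% of frames"
        )
    tracks = tracks[good]
    offsets = tracks - np.nanmean(tracks, axis=1, keepdims=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-NaN frames handled below
        disp = np.nanmean(offsets, axis=0)
    for k in range(2):
        col = disp[:, k]
        nan = np.isnan(col)
        if nan.all():
            raise InsufficientFiducialsError("no frame with any bead localization")
        if nan.any():
            col[nan] = np.interp(np.flatnonzero(nan), np.flatnonzero(~nan), col[~nan])
        disp[:, k] = ndimage.median_filter(col, size=smooth_window, mode="nearest")
    return DriftTrajectory(disp)


def apply_correction(
    table: pd.DataFrame,
    drift: Optional[DriftTrajectory] = None,
    transform: Optional[AffineTransform2D] = None,
    transform_channel: Optional[str] = None,
) -> pd.DataFrame:
    """Subtract drift and (optionally) apply the channel transform.

    The transform is applied after drift subtraction, to all rows or only to
    ``transform_channel``; every other column is left untouched.
    """
    out = table.copy()
    if drift is not None:
        shift = drift.at(out["frame"].to_numpy(dtype=int))
        out["x_nm"] = out["x_nm"].to_numpy(dtype=float) - shift[:, 0]
        out["y_nm"] = out["y_nm"].to_numpy(dtype=float) - shift[:, 1]
    if transform is not None:
        mask = (
            np.ones(len(out), dtype=bool)
            if transform_channel is None
            else (out["channel"].to_numpy() == transform_channel)
        )
        pts = out.loc[mask, ["x_nm", "y_nm"]].to_numpy(dtype=float)
        moved = transform.apply(pts)
        out.loc[mask, "x_nm"] = moved[:, 0]
        out.loc[mask, "y_nm"] = moved[:, 1]
    return out
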