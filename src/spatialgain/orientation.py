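"""Epimysium/fascicle orientation, ROI placement, and mean gray value.

The pennation angle alpha is the angle between the fascicles and the
epimysium they insert into; the fascicle probe angle (FPA) is the angle
between the fascicles and the probe face.  Because a probe tilt is
physically present in the image, the FPA is simply the fascicle
orientation in image coordinates, and alpha is the folded difference
between the fascicle and epimysium orientations — no gel-pad arithmetic
is needed at analysis time.

Both orientation estimators scan candidate angles by rotating the image
so that structures at the candidate angle become horizontal and reducing
each row to its mean: the epimysium is the strongest near-horizontal line
(maximum row mean), while the dominant fascicle orientation maximizes the
variance of the row-mean profile inside the ROI (a projection/Radon-style
orientation-energy scan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage, stats

from .frames import Frame, ROISpec

FINE_STEP_DEG = 0.25


class OrientationError(RuntimeError):
    """Raised when no reliable orientation can be extracted."""


class ROIError(ValueError):
    """Raised when a region of interest cannot be placed or evaluated."""


@dataclass(frozen=True)
class AngleMeasurement:
    """Orientation measurements for one frame, all in degrees."""

    epimysium_deg: float
    fascicle_deg: float
    alpha_deg: float
    fpa_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_deg < 90.0:
            raise ValueError("alpha must lie in [0, 90)")
        if not -90.0 < self.fpa_deg < 90.0:
            raise ValueError("FPA must lie in (-90, 90)")


@dataclass(frozen=True)
class HomogeneityReport:
    """Per-sweep trend screen of epimysium angle and MGV on frame index."""

    slope_epimysium_deg: float
    p_epimysium: float
    slope_mgv: float
    p_mgv: float
    p_threshold: float
    passed: bool


def rotate_image(image: np.ndarray, deg: float, cval: float = math.nan) -> np.ndarray:
    """Rotate the scene by ``deg`` (CCW on screen), bilinear, constant fill.

    A structure at orientation ``a`` appears at ``a + deg`` afterwards.
    """
    return ndimage.rotate(
        np.asarray(image, dtype=np.float64),
        deg,
        reshape=False,
        order=1,
        mode="constant",
        cval=cval,
    )


def _row_profile(rotated: np.ndarray, min_valid_fraction: float = 0.3) -> np.ndarray:
    """Row means of a rotated image, ignoring constant-fill NaNs."""
    valid = np.isfinite(rotated)
    counts = valid.sum(axis=1)
    sums = np.where(valid, rotated, 0.0).sum(axis=1)
    enough = counts >= max(3, int(min_valid_fraction * rotated.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = sums / counts
    return profile[enough]


def _profile_score(image: np.ndarray, angle: float, reducer) -> float:
    profile = _row_profile(rotate_image(image, -angle))
    if profile.size < 3:
        return -np.inf
    return float(reducer(profile))


def _scan_orientation(
    image: np.ndarray,
    lo: float,
    hi: float,
    reducer,
    coarse_step: float = 1.0,
) -> tuple[float, float, np.ndarray]:
    """Coarse-to-fine orientation scan; returns (angle, score, coarse scores)."""
    coarse = np.arange(lo, hi + 1e-9, coarse_step)
    scores = np.array([_profile_score(image, a, reducer) for a in coarse])
    best = coarse[int(np.argmax(scores))]
    fine = np.arange(
        max(lo, best - coarse_step), min(hi, best + coarse_step) + 1e-9, FINE_STEP_DEG
    )
    fscores = np.array([_profile_score(image, a, reducer) for a in fine])
    i = int(np.argmax(fscores))
    angle, score = float(fine[i]), float(fscores[i])
    # parabolic refinement on the fine grid
    if 0 < i < fine.size - 1:
        y0, y1, y2 = fscores[i - 1], fscores[i], fscores[i + 1]
        denom = y0 - 2 * y1 + y2
        if np.isfinite(denom) and denom < 0:
            angle += 0.5 * FINE_STEP_DEG * (y0 - y2) / denom
    return angle, score, scores


def estimate_epimysium_angle(
    frame: Frame | np.ndarray,
    search_halfwidth_deg: float = 30.0,
    top_fraction: float = 0.5,
    min_peak_ratio: float = 1.5,
) -> float:
    """Orientation (degrees) of the strongest near-horizontal bright line.

    Searches within ``+-search_halfwidth_deg`` of horizontal in the upper
    ``top_fraction`` of the frame.  Raises :class:`OrientationError` when
    the brightest aligned row does not exceed the background row mean by
    ``min_peak_ratio`` ("epimysium not found").
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    crop = pixels[: max(16, int(pixels.shape[0] * top_fraction))].astype(np.float64)
    angle, _, _ = _scan_orientation(
        crop, -search_halfwidth_deg, search_halfwidth_deg, np.max
    )
    profile = _row_profile(rotate_image(crop, -angle))
    peak, background = float(profile.max()), float(np.median(profile))
    if background <= 0 or peak / background < min_peak_ratio:
        raise OrientationError(
            "epimysium not found: no line exceeds background by "
            f"factor {min_peak_ratio} (peak ratio {peak / max(background, 1e-9):.2f})"
        )
    return angle


def estimate_fascicle_angle(
    frame: Frame | np.ndarray,
    roi: ROISpec,
    search_halfwidth_deg: float = 45.0,
    min_anisotropy: float = 2.0,
) -> float:
    """Dominant streak orientation (degrees) inside the ROI.

    Maximizes the variance of line-integral projections over the angle
    window in 0.25-degree steps.  Raises :class:`OrientationError` when
    the orientation energy is flat (anisotropy ratio below threshold).
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    if not roi.fits_in(pixels.shape):
        raise ROIError("ROI lies outside the frame")
    r0, r1, c0, c1 = roi.bounds()
    crop = pixels[r0:r1, c0:c1].astype(np.float64)
    angle, _, coarse_scores = _scan_orientation(
        crop, -search_halfwidth_deg, search_halfwidth_deg, np.var
    )
    finite = coarse_scores[np.isfinite(coarse_scores)]
    background = float(np.median(finite))
    ratio = float(finite.max()) / max(background, 1e-12)
    if ratio < min_anisotropy:
        raise OrientationError(
            f"no dominant fascicle orientation (anisotropy ratio {ratio:.2f} "
            f"< {min_anisotropy})"
        )
    return angle


def derive_angles(
    fascicle_deg: float,
    epimysium_deg: float,
    gel_pad_deg: float | None = None,
) -> AngleMeasurement:
    """Combine the two orientations into pennation angle and FPA.

    ``alpha = |fascicle - epimysium|`` folded into [0, 90); the FPA is the
    fascicle orientation itself, since the probe face is the image
    horizontal.  ``gel_pad_deg`` is accepted for bookkeeping only — it is
    already physically expressed in the image and enters no arithmetic
    (validation against phantoms uses FPA ~ alpha - GA).
    """
    if not (math.isfinite(fascicle_deg) and math.isfinite(epimysium_deg)):
        raise ValueError("orientations must be finite")
    alpha = abs(fascicle_deg - epimysium_deg) % 180.0
    if alpha >= 90.0:
        alpha = 180.0 - alpha
    return AngleMeasurement(
        epimysium_deg=float(epimysium_deg),
        fascicle_deg=float(fascicle_deg),
        alpha_deg=float(alpha),
        fpa_deg=float(fascicle_deg),
    )


def place_roi(
    frame: Frame | np.ndarray,
    template: ROISpec,
    offset_px: int = 80,
    epimysium_deg: float | None = None,
) -> ROISpec:
    """Place the study ROI a fixed offset below the detected epimysium.

    The frame is derotated by the epimysium angle (estimated unless
    passed in), the epimysium row is the brightest full-width row of the
    derotated image, and that row is mapped back to the original central
    column.  The ROI keeps the template's size and orientation and is
    centered ``offset_px + height/2`` below the detected row, recording
    ROICy.  Raises :class:`ROIError` instead of clipping when the ROI
    would leave the image.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    h, w = pixels.shape
    if template.width > w or template.height > h:
        raise ROIError("ROI template larger than frame")
    if epimysium_deg is None:
        epimysium_deg = estimate_epimysium_angle(frame)
    rotated = rotate_image(pixels.astype(np.float64), -epimysium_deg)
    valid = np.isfinite(rotated)
    counts = valid.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(valid, rotated, 0.0).sum(axis=1) / counts
    profile[counts < w // 2] = -np.inf
    row_derot = int(np.argmax(profile[: max(1, h * 3 // 4)]))
    # map the horizontal row back to the epimysium's crossing of the
    # central column in the original image
    cy = (h - 1) / 2.0
    epi_row = int(round(cy + (row_derot - cy) / math.cos(math.radians(epimysium_deg))))
    roi = template.recenter(w / 2.0, epi_row + offset_px + template.height / 2.0)
    if not roi.fits_in(pixels.shape):
        raise ROIError(
            f"ROI out of bounds: epimysium at row {epi_row}, "
            f"offset {offset_px}, height {template.height}"
        )
    return roi


def mean_gray_value(image: np.ndarray, roi: ROISpec) -> float:
    """Arithmetic mean of the pixels inside a (possibly rotated) rectangle."""
    image = np.asarray(image, dtype=np.float64)
    if not roi.fits_in(image.shape):
        raise ROIError("ROI lies outside the image")
    if roi.orientation_deg % 360 == 0:
        r0, r1, c0, c1 = roi.bounds()
        patch = image[r0:r1, c0:c1]
        if patch.size == 0:
            raise ROIError("empty ROI")
        return float(patch.mean())
    t = math.radians(roi.orientation_deg)
    y, x = np.mgrid[0 : image.shape[0], 0 : image.shape[1]].astype(np.float64)
    dx, dy = x - roi.center_x, y - roi.center_y
    u = dx * math.cos(t) - dy * math.sin(t)
    v = dx * math.sin(t) + dy * math.cos(t)
    mask = (np.abs(u) <= roi.width / 2.0) & (np.abs(v) <= roi.height / 2.0)
    if not mask.any():
        raise ROIError("empty ROI")
    return float(image[mask].mean())


def compute_mgv(frame: Frame, roi: ROISpec) -> float:
    """Mean gray value (MGV) of a frame inside the ROI, in [0, 255]."""
    return mean_gray_value(frame.pixels, roi)


def _trend(index: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """OLS slope and two-sided p of values on frame index; constant -> p=1."""
    if np.ptp(values) < 1e-12 or np.ptp(index) < 1e-12:
        return 0.0, 1.0
    res = stats.linregress(index, values)
    p = res.pvalue if math.isfinite(res.pvalue) else 1.0
    return float(res.slope), float(p)


def check_sweep_homogeneity(
    observations: Iterable[tuple[int, float, float]],
    p_threshold: float = 0.20,
) -> HomogeneityReport:
    """Screen a sweep for probe-translation artifacts.

    ``observations`` are (frame_index, epimysium_deg, MGV) triples from
    one sweep (or a whole specimen).  Each quantity is regressed on frame
    index by ordinary least squares; the sweep passes when both trend
    p-values exceed ``p_threshold`` (default 0.20, the bound observed for
    all real sweeps, adopted as a conservative screen).
    """
    rows = list(observations)
    if len(rows) < 3:
        raise ValueError("homogeneity check needs at least 3 frames")
    idx = np.array([r[0] for r in rows], dtype=float)
    epi = np.array([r[1] for r in rows], dtype=float)
    mgv = np.array([r[2] for r in rows], dtype=float)
    s_epi, p_epi = _trend(idx, epi)
    s_mgv, p_mgv = _trend(idx, mgv)
    return HomogeneityReport(
        slope_epimysium_deg=s_epi,
        p_epimysium=p_epi,
        slope_mgv=s_mgv,
        p_mgv=p_mgv,
        p_threshold=p_threshold,
        passed=(p_epi > p_threshold) and (p_mgv > p_threshold),
    )
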