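"""Synthetic B-mode sweeps and cross-section images with known ground truth.

No public image archive exists for gel-pad tilt sweeps of skeletal muscle,
so every downstream stage is validated against this generator.  A phantom
frame emulates the display-level appearance of a fascicle-aligned B-mode
scan: a smoothed-Gaussian speckle background, a bright epimysium line, and
parallel perimysial streaks at the pennation angle.  Probe tilt by a gel
pad of angle GA is simulated by rotating the whole scene by -GA about the
region-of-interest center, so the fascicle streaks appear at the fascicle
probe angle FPA = alpha - GA and the epimysium at -GA.

The streak brightness of each frame is calibrated analytically from the
streak area fraction inside the default ROI so that the noiseless ROI mean
equals the reflection-law target ``m(FPA) = b0 - (b1/2) sin(2|FPA|)``.
The generator works directly in display gray values; it does not model
wave propagation, attenuation, gel-pad absorption, or the scanner's
(unknown) log-compression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .fitting import linear_model, sine_model
from .frames import Frame, ROISpec, write_frame

DEFAULT_GEL_PAD_ANGLES = (-24.0, -12.0, 0.0, 12.0, 24.0)

#: muscle region starts this far (px) below the epimysium along its normal
MUSCLE_MARGIN_PX = 8.0
#: correlation length (px) of the smoothed-Gaussian speckle approximation
SPECKLE_SMOOTH_SIGMA = 1.2


class PhantomConfigError(ValueError):
    """Raised when a phantom configuration cannot render a valid image."""


@dataclass(frozen=True)
class PhantomConfig:
    """Ground-truth description of one synthetic sweep study.

    ``beta0_true`` is the target ROI mean gray value at FPA 0 and
    ``beta1_true`` the sine-model amplitude (gray values).  ``seed`` is
    mandatory: identical configurations render bit-identical images.
    """

    seed: int
    image_width: int = 512
    image_height: int = 512
    beta0_true: float = 80.0
    beta1_true: float = 33.5
    pennation_deg: float = 12.0
    epimysium_row: int = 60
    streak_spacing: float = 24.0
    streak_thickness: float = 3.0
    speckle_mean: float = 62.0
    speckle_sd: float = 6.0
    gel_pad_angles_deg: tuple[float, ...] = DEFAULT_GEL_PAD_ANGLES
    frames_per_sweep: int = 3
    translation_px_per_frame: float = 8.0
    epimysium_brightness: float = 245.0
    epimysium_thickness: float = 4.0
    roi_width: int = 400
    roi_height: int = 200
    roi_offset_px: int = 80

    def __post_init__(self) -> None:
        if self.seed is None:
            raise PhantomConfigError("a seed is mandatory (no silent default)")
        if not 0 < self.beta0_true <= 255:
            raise PhantomConfigError("beta0_true must lie in (0, 255]")
        if self.beta1_true < 0:
            raise PhantomConfigError("beta1_true must be non-negative")
        if abs(self.pennation_deg) >= 45:
            raise PhantomConfigError("|pennation_deg| must be < 45 degrees")
        if any(abs(a) > 30 for a in self.gel_pad_angles_deg):
            raise PhantomConfigError(
                "gel-pad angles must lie within [-30, 30] degrees"
            )
        if self.frames_per_sweep < 1:
            raise PhantomConfigError("frames_per_sweep must be >= 1")
        if not 0 <= self.speckle_mean <= 255:
            raise PhantomConfigError("speckle_mean must lie in [0, 255]")

    def rotation_center(self) -> tuple[float, float]:
        """Scene-rotation pivot: the pre-tilt default ROI center (x, y)."""
        return (
            self.image_width / 2.0,
            self.epimysium_row + self.roi_offset_px + self.roi_height / 2.0,
        )


@dataclass(frozen=True)
class FrameTruth:
    """Ground truth attached to one rendered frame."""

    specimen_id: str
    gel_pad_deg: float
    frame_index: int
    alpha_true_deg: float
    fpa_true_deg: float
    mgv_target: float
    epimysium_deg: float
    fascicle_deg: float
    streak_value: float
    roi: ROISpec


@dataclass(frozen=True)
class SweepSet:
    """All frames of one specimen across the gel-pad angles."""

    specimen_id: str
    config: PhantomConfig
    frames: tuple[Frame, ...]
    truths: tuple[FrameTruth, ...]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "specimen": t.specimen_id,
                "gel_pad_deg": t.gel_pad_deg,
                "frame": t.frame_index,
                "alpha_true_deg": t.alpha_true_deg,
                "fpa_true_deg": t.fpa_true_deg,
                "mgv_target": t.mgv_target,
            }
            for t in self.truths
        ]
        return pd.DataFrame(rows)


def _rotate_point(
    p: tuple[float, float], center: tuple[float, float], deg: float
) -> tuple[float, float]:
    """Rotate ``p`` about ``center`` by ``deg`` (CCW on screen, y down)."""
    t = math.radians(deg)
    dx, dy = p[0] - center[0], p[1] - center[1]
    return (
        center[0] + dx * math.cos(t) + dy * math.sin(t),
        center[1] - dx * math.sin(t) + dy * math.cos(t),
    )


def _frame_rng(config: PhantomConfig, gel_pad_deg: float, frame_index: int):
    ga_key = int(round((gel_pad_deg + 360.0) * 1000.0))
    return np.random.default_rng([int(config.seed), ga_key, int(frame_index)])


def default_roi(config: PhantomConfig, gel_pad_deg: float) -> ROISpec:
    """The axis-aligned analysis ROI for one gel-pad angle.

    Placed the configured offset below the point where the (tilted)
    epimysium crosses the central image column, mirroring what the
    analysis stage does with the detected epimysium.
    """
    theta = -gel_pad_deg
    cx = config.image_width / 2.0
    e = _rotate_point(
        (cx, float(config.epimysium_row)), config.rotation_center(), theta
    )
    t = math.radians(theta)
    # y where the epimysium line crosses x = cx
    s = (cx - e[0]) / math.cos(t)
    y_cross = e[1] - s * math.sin(t)
    center_y = round(y_cross) + config.roi_offset_px + config.roi_height / 2.0
    return ROISpec(
        center_x=cx,
        center_y=center_y,
        width=config.roi_width,
        height=config.roi_height,
    )


def _noiseless_scene(
    config: PhantomConfig, gel_pad_deg: float, frame_index: int
) -> tuple[np.ndarray, FrameTruth]:
    """Render the pre-noise float scene and its ground-truth record."""
    angles = [round(a, 6) for a in config.gel_pad_angles_deg]
    if round(gel_pad_deg, 6) not in angles:
        raise PhantomConfigError(
            f"gel-pad angle {gel_pad_deg} not in configured list {angles}"
        )
    if not 0 <= frame_index < config.frames_per_sweep:
        raise PhantomConfigError(
            f"frame_index {frame_index} outside 0..{config.frames_per_sweep - 1}"
        )

    theta = -gel_pad_deg  # scene rotation simulating the probe tilt
    fpa = config.pennation_deg - gel_pad_deg
    m = float(sine_model(fpa, config.beta0_true, config.beta1_true))
    if not 0.0 < m < 255.0:
        raise PhantomConfigError(
            f"model value {m:.1f} at FPA {fpa:.1f} deg lies outside (0, 255); "
            "reduce beta1_true or adjust beta0_true"
        )

    h, w = config.image_height, config.image_width
    cx = w / 2.0
    anchor = _rotate_point(
        (cx, float(config.epimysium_row)), config.rotation_center(), theta
    )
    te = math.radians(theta)
    tf = math.radians(fpa)

    # lateral probe translation: shift the scene along the epimysium line
    shift = config.translation_px_per_frame * frame_index
    vx, vy = shift * math.cos(te), -shift * math.sin(te)

    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    dx = x - anchor[0] - vx
    dy = y - anchor[1] - vy
    d_epi = dx * math.sin(te) + dy * math.cos(te)
    d_fas = dx * math.sin(tf) + dy * math.cos(tf)

    epi_mask = np.abs(d_epi) <= config.epimysium_thickness / 2.0
    muscle = d_epi > MUSCLE_MARGIN_PX
    stripes = (np.mod(d_fas, config.streak_spacing) < config.streak_thickness) & muscle

    scene = np.full((h, w), config.speckle_mean, dtype=np.float64)
    scene[epi_mask] = config.epimysium_brightness

    roi = default_roi(config, gel_pad_deg)
    if not roi.fits_in((h, w)):
        raise PhantomConfigError("default ROI does not fit inside the image")
    r0, r1, c0, c1 = roi.bounds()
    frac = float(stripes[r0:r1, c0:c1].mean())
    if frac <= 0:
        raise PhantomConfigError("no streak pixels inside the ROI")
    base_mean = float(scene[r0:r1, c0:c1].mean())
    amplitude = (m - base_mean) / frac
    streak_value = config.speckle_mean + amplitude
    if not 0.0 <= streak_value <= 255.0:
        raise PhantomConfigError(
            f"calibrated streak brightness {streak_value:.1f} falls outside "
            "[0, 255]; the ROI target cannot be rendered"
        )
    scene[stripes] = streak_value

    truth = FrameTruth(
        specimen_id="",
        gel_pad_deg=float(gel_pad_deg),
        frame_index=int(frame_index),
        alpha_true_deg=float(config.pennation_deg),
        fpa_true_deg=float(fpa),
        mgv_target=m,
        epimysium_deg=float(theta),
        fascicle_deg=float(fpa),
        streak_value=float(streak_value),
        roi=roi,
    )
    return scene, truth


def render_frame(
    config: PhantomConfig,
    gel_pad_deg: float,
    frame_index: int = 0,
    noise: bool = True,
    specimen_id: str = "phantom",
) -> tuple[Frame, FrameTruth]:
    """Render one frame plus its ground-truth record.

    With ``noise=False`` the smoothed-speckle noise is omitted, so the
    mean gray value inside the ground-truth ROI equals the reflection-law
    target to within rounding (< 0.1 gray value).
    """
    scene, truth = _noiseless_scene(config, gel_pad_deg, frame_index)
    if noise:
        rng = _frame_rng(config, gel_pad_deg, frame_index)
        nz = ndimage.gaussian_filter(
            rng.standard_normal(scene.shape), SPECKLE_SMOOTH_SIGMA
        )
        nz *= config.speckle_sd / nz.std()
        scene = scene + nz
    pixels = np.clip(np.round(scene), 0, 255).astype(np.uint8)
    frame = Frame(
        pixels=pixels,
        gel_pad_deg=float(gel_pad_deg),
        frame_index=int(frame_index),
        specimen_id=specimen_id,
    )
    truth = FrameTruth(**{**truth.__dict__, "specimen_id": specimen_id})
    return frame, truth


def render_sweepset(
    config: PhantomConfig,
    specimen_id: str = "phantom",
    noise: bool = True,
) -> SweepSet:
    """Render ``frames_per_sweep`` frames at every configured gel-pad angle."""
    frames: list[Frame] = []
    truths: list[FrameTruth] = []
    for ga in config.gel_pad_angles_deg:
        for k in range(config.frames_per_sweep):
            f, t = render_frame(
                config, ga, k, noise=noise, specimen_id=specimen_id
            )
            frames.append(f)
            truths.append(t)
    return SweepSet(
        specimen_id=specimen_id,
        config=config,
        frames=tuple(frames),
        truths=tuple(truths),
    )


def write_sweepset(
    sweepset: SweepSet, root: str | Path, image_format: str = "tif"
) -> Path:
    """Write frames as ``<specimen>/ga<angle>/frame<k>.<fmt>`` plus truth CSV.

    Returns the specimen directory.  The configuration is stored alongside
    as YAML for provenance.
    """
    root = Path(root)
    spec_dir = root / sweepset.specimen_id
    for frame, truth in zip(sweepset.frames, sweepset.truths, strict=True):
        ga_dir = spec_dir / f"ga{int(round(truth.gel_pad_deg))}"
        write_frame(frame, ga_dir / f"frame{truth.frame_index}.{image_format}")
    sweepset.truth_table().to_csv(spec_dir / "truth.csv", index=False)
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in sweepset.config.__dict__.items()
    }
    (spec_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return spec_dir


# ---------------------------------------------------------------------------
# observation-level simulators (no image rendering)


def simulate_mgv_observations(
    rng: np.random.Generator,
    beta0: float = 80.0,
    beta1: float = 33.5,
    fpa_grid_deg=DEFAULT_GEL_PAD_ANGLES,
    frames_per_angle: int = 3,
    noise_sd: float = 3.0,
    family: str = "sine",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (FPA, MGV) pairs from a model plus Gaussian ROI-level noise.

    This samples at the level the fits consume (one MGV per frame) and is
    used for Monte-Carlo parameter-recovery and model-selection studies,
    where rendering full images would add nothing but runtime.
    """
    fpa = np.repeat(np.asarray(fpa_grid_deg, dtype=float), frames_per_angle)
    model = sine_model if family == "sine" else linear_model
    mgv = model(fpa, beta0, beta1) + rng.normal(0.0, noise_sd, size=fpa.size)
    return fpa, np.clip(mgv, 0.0, 255.0)


def simulate_study_observations(
    rng: np.random.Generator,
    n_specimens: int = 51,
    gel_pad_angles_deg=DEFAULT_GEL_PAD_ANGLES,
    frames_per_angle: int = 3,
    noise_sd: float = 3.0,
    family: str = "sine",
) -> pd.DataFrame:
    """Simulate a whole-study ensemble of (specimen, FPA, MGV) observations.

    Per-specimen parameters emulate the spread reported for bovine muscles:
    pennation angle ~ N(11.5, 4.5^2) clipped to [1.5, 20] degrees, MGV_00
    ~ N(78, 9^2) clipped to [50, 110], and tilt echo gain ~ N(1.85, 0.3^2)
    clipped to [0.8, 3.0] %/degree.  The sine-family amplitude is derived
    from TEG via the small-angle relation b1_sine = b1_linear * 180/pi.
    """
    rows = []
    gas = np.asarray(gel_pad_angles_deg, dtype=float)
    for i in range(n_specimens):
        alpha = float(np.clip(rng.normal(11.5, 4.5), 1.5, 20.0))
        beta0 = float(np.clip(rng.normal(78.0, 9.0), 50.0, 110.0))
        teg = float(np.clip(rng.normal(1.85, 0.3), 0.8, 3.0))
        b1_lin = teg * beta0 / 100.0
        fpa = np.repeat(alpha - gas, frames_per_angle)
        if family == "sine":
            mean = sine_model(fpa, beta0, b1_lin * 180.0 / math.pi)
        else:
            mean = linear_model(fpa, beta0, b1_lin)
        mgv = np.clip(mean + rng.normal(0.0, noise_sd, fpa.size), 0.0, 255.0)
        for a, m in zip(fpa, mgv):
            rows.append(
                {"specimen": f"S{i:02d}", "fpa_deg": float(a), "mgv": float(m)}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross sections


@dataclass(frozen=True)
class CrossSectionConfig:
    """Synthetic muscle cross-section photograph with a known IMCT fraction.

    The connective-tissue network is a level-set band of a smooth random
    field: pixels whose field value lies in a central rank band form long,
    curved, connected septa whose area fraction equals
    ``imct_fraction_true`` percent by construction.
    """

    seed: int
    image_width: int = 512
    image_height: int = 512
    imct_fraction_true: float = 12.0
    septum_thickness: float = 6.0
    muscle_color: tuple[float, float, float] = (150.0, 62.0, 70.0)
    imct_color: tuple[float, float, float] = (228.0, 222.0, 210.0)
    color_noise_sd: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.imct_fraction_true <= 100.0:
            raise PhantomConfigError("imct_fraction_true must lie in [0, 100]")
        if self.septum_thickness <= 0:
            raise PhantomConfigError("septum_thickness must be positive")


def render_cross_section(
    config: CrossSectionConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Render an RGB cross-section photo and its ground-truth IMCT mask.

    Returns ``(image, mask)`` with ``image`` a (H, W, 3) uint8 array and
    ``mask`` boolean (True = IMCT).  The mask fraction matches
    ``imct_fraction_true`` to well within one percentage point.
    """
    rng = np.random.default_rng(int(config.seed))
    h, w = config.image_height, config.image_width
    field_ = ndimage.gaussian_filter(
        rng.standard_normal((h, w)), sigma=2.0 * config.septum_thickness
    )
    if config.imct_fraction_true <= 0:
        mask = np.zeros((h, w), dtype=bool)
    elif config.imct_fraction_true >= 100:
        mask = np.ones((h, w), dtype=bool)
    else:
        centered = np.abs(field_ - np.median(field_))
        cut = np.quantile(centered, config.imct_fraction_true / 100.0)
        mask = centered <= cut

    image = np.where(
        mask[..., None],
        np.asarray(config.imct_color),
        np.asarray(config.muscle_color),
    )
    image = image + rng.normal(0.0, config.color_noise_sd, size=image.shape)
    return np.clip(np.round(image), 0, 255).astype(np.uint8), mask
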