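"""Spatial-gain model fitting: MGV versus fascicle probe angle.

Echo intensity of fascicle-aligned muscle ultrasound drops as the probe
is tilted away from the fascicle direction, because specular reflections
at perimysial interfaces are deflected sideways by ``sin(2|FPA|)``.  Two
model families describe the mean gray value (MGV, 0-255) of a region of
interest as a function of the fascicle probe angle (FPA, degrees):

* sine family:    ``MGV = b0 - (b1/2) * sin(2|FPA|)``
* linear family:  ``MGV = b0 - b1 * |FPA|``

``b0`` is the expected gray value at FPA 0 (``MGV_00``), a
pennation-unbiased echo-intensity measure.  The tilt echo gain,
``TEG = 100 * b1 / b0`` of the *linear* family, is the percent decrease
in MGV per degree of probe tilt.  Both families are plain ordinary least
squares after transforming the regressor; degrees are the public unit and
radians are used only inside the trigonometric evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SINE = "sine"
LINEAR = "linear"


class FitError(ValueError):
    """Raised for degenerate fitting inputs (too few or collinear data)."""


@dataclass(frozen=True)
class MGVObservation:
    """One (FPA, MGV) pair, the atomic fitting datum.

    ``fpa_deg`` should lie within +-45 degrees; the method itself is
    recommended for |FPA| <= 30 degrees, where the linear approximation
    of the reflection law is accurate to ~25%.
    """

    fpa_deg: float
    mgv: float
    specimen_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mgv <= 255.0):
            raise ValueError(f"MGV must lie in [0, 255], got {self.mgv}")
        if abs(self.fpa_deg) > 45.0:
            raise ValueError(
                f"|FPA| must be <= 45 degrees for fitting, got {self.fpa_deg}"
            )


@dataclass(frozen=True)
class FitResult:
    """Ordinary-least-squares result for one model family on one specimen.

    ``beta1`` is family-specific: gray value per unit of ``sin(2|FPA|)/2``
    for the sine family, gray value per degree for the linear family.
    ``teg`` (percent per degree) is defined only for the linear family
    with a positive intercept.
    """

    model_family: str
    beta0: float
    beta1: float
    n: int
    rss: float
    tss: float
    adjusted_r2: float
    aic: float
    residuals: np.ndarray
    fitted: np.ndarray
    teg: float | None = None


@dataclass(frozen=True)
class ModelComparison:
    """Sine-minus-linear fit deltas; ``preferred`` has the lower AIC."""

    delta_adjusted_r2: float
    delta_aic: float
    preferred: str


# ---------------------------------------------------------------------------
# model evaluation


def sine_model(fpa_deg, beta0: float, beta1: float):
    """Evaluate ``b0 - (b1/2) sin(2|FPA|)`` (FPA in degrees)."""
    x = np.deg2rad(np.abs(np.asarray(fpa_deg, dtype=float)))
    return beta0 - (beta1 / 2.0) * np.sin(2.0 * x)


def linear_model(fpa_deg, beta0: float, beta1: float):
    """Evaluate ``b0 - b1 |FPA|`` (FPA in degrees)."""
    return beta0 - beta1 * np.abs(np.asarray(fpa_deg, dtype=float))


def predict_mgv(fit: FitResult, fpa_deg) -> np.ndarray | float:
    """Model value of a fit at ``fpa_deg``; returns ``beta0`` exactly at 0."""
    if fit.model_family == SINE:
        return sine_model(fpa_deg, fit.beta0, fit.beta1)
    return linear_model(fpa_deg, fit.beta0, fit.beta1)


# ---------------------------------------------------------------------------
# fitting


def _as_xy(observations) -> tuple[np.ndarray, np.ndarray]:
    obs = list(observations)
    if obs and isinstance(obs[0], MGVObservation):
        x = np.array([o.fpa_deg for o in obs], dtype=float)
        y = np.array([o.mgv for o in obs], dtype=float)
    else:
        x = np.array([o[0] for o in obs], dtype=float)
        y = np.array([o[1] for o in obs], dtype=float)
    return x, y


def observations_from_arrays(
    fpa_deg: Sequence[float], mgv: Sequence[float], specimen_id: str = ""
) -> list[MGVObservation]:
    return [
        MGVObservation(fpa_deg=float(a), mgv=float(m), specimen_id=specimen_id)
        for a, m in zip(fpa_deg, mgv, strict=True)
    ]


def _adjusted_r2(rss: float, tss: float, n: int, n_regressors: int = 1) -> float:
    if tss <= 0:
        return math.nan
    r2 = 1.0 - rss / tss
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_regressors - 1)


def gaussian_aic(rss: float, n: int, n_params: int = 3) -> float:
    """AIC of a Gaussian linear model from its residual sum of squares.

    Uses the full log-likelihood including the 2*pi term, and counts the
    error variance as a parameter (k = 3 for intercept + slope + sigma^2),
    matching R's ``AIC(lm(...))``.  Only AIC differences between models on
    the same data are meaningful.
    """
    if rss <= 1e-10:  # numerically perfect fit: likelihood unbounded
        return math.nan
    return n * math.log(2.0 * math.pi * rss / n) + n + 2.0 * n_params


def aic(fit: FitResult) -> float:
    """Gaussian-likelihood AIC of a fit (nan for a perfect fit)."""
    return gaussian_aic(fit.rss, fit.n)


def adjusted_r2(fit: FitResult) -> float:
    """Adjusted coefficient of determination, 1 - (1-r2)(n-1)/(n-2)."""
    if fit.n < 3:
        raise FitError("adjusted r2 requires n > p + 1")
    return _adjusted_r2(fit.rss, fit.tss, fit.n)


def _fit_family(x: np.ndarray, y: np.ndarray, family: str) -> FitResult:
    n = x.size
    if n < 3:
        raise FitError(f"need at least 3 observations, got {n}")
    if family == SINE:
        reg = np.sin(2.0 * np.deg2rad(np.abs(x))) / 2.0
    else:
        reg = np.abs(x)
    if np.ptp(reg) < 1e-12:
        raise FitError(
            "rank-deficient design: all observations share the same |FPA|"
        )
    design = np.column_stack([np.ones(n), reg])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    residuals = y - fitted
    rss = float(residuals @ residuals)
    tss = float(np.sum((y - y.mean()) ** 2))
    beta0 = float(coef[0])
    beta1 = float(-coef[1])  # models are written with a negative slope
    teg = None
    if family == LINEAR:
        teg = 100.0 * beta1 / beta0 if beta0 > 0 else None
    return FitResult(
        model_family=family,
        beta0=beta0,
        beta1=beta1,
        teg=teg,
        n=n,
        rss=rss,
        tss=tss,
        adjusted_r2=_adjusted_r2(rss, tss, n),
        aic=gaussian_aic(rss, n),
        residuals=residuals,
        fitted=fitted,
    )


def fit_sine(observations: Iterable) -> FitResult:
    """OLS of MGV on ``sin(2|FPA|)/2`` with intercept.

    ``beta0`` is MGV_00 and ``beta1`` the (negated) regressor coefficient,
    i.e. the amplitude of the reflection-law model.
    """
    x, y = _as_xy(observations)
    return _fit_family(x, y, SINE)


def fit_linear(observations: Iterable) -> FitResult:
    """OLS of MGV on ``|FPA|`` (degrees) with intercept.

    ``beta1`` is the gray-value drop per degree; ``teg = 100 * beta1/beta0``
    is reported in percent per degree (None when ``beta0 <= 0``).
    """
    x, y = _as_xy(observations)
    return _fit_family(x, y, LINEAR)


def compare_models(sine: FitResult, linear: FitResult) -> ModelComparison:
    """Compare the two families fitted to the same observations.

    The preferred family is the one with the lower AIC; an exact tie goes
    to the linear family, the more practical choice at small angles.
    """
    if sine.model_family != SINE or linear.model_family != LINEAR:
        raise ValueError("expected one sine and one linear fit, in that order")
    if sine.n != linear.n:
        raise ValueError(
            f"fits are based on different n ({sine.n} vs {linear.n})"
        )
    delta_aic = sine.aic - linear.aic
    preferred = SINE if sine.aic < linear.aic else LINEAR
    return ModelComparison(
        delta_adjusted_r2=sine.adjusted_r2 - linear.adjusted_r2,
        delta_aic=delta_aic,
        preferred=preferred,
    )


# ---------------------------------------------------------------------------
# analytic side results


def linearization_error(angle_deg: float) -> float:
    """Percent deviation of the linear from the sine reflection law.

    ``100 * (2x - sin 2x) / sin 2x`` with ``x`` the angle in radians;
    about 8.5% at 20 degrees, which is why clinical use of the linear fit
    is recommended only within |FPA| <= 30 degrees.
    """
    if not 0.0 < angle_deg < 90.0:
        raise ValueError("angle must lie strictly between 0 and 90 degrees")
    x = math.radians(angle_deg)
    s = math.sin(2.0 * x)
    return 100.0 * (2.0 * x - s) / s


def acoustic_wavelength(speed_m_per_s: float, frequency_hz: float) -> float:
    """Wavelength in micrometers, ``speed / frequency``.

    At 15 MHz in bovine muscle (c = 1580 m/s) this is ~105 um, which
    bounds what perimysial sheets (30-120 um) can echo back.
    """
    if speed_m_per_s <= 0 or frequency_hz <= 0:
        raise ValueError("speed and frequency must be positive")
    return speed_m_per_s / frequency_hz * 1e6


def axial_resolution(pulse_length_um: float) -> float:
    """Best axial resolution in micrometers: half the pulse length."""
    if pulse_length_um <= 0:
        raise ValueError("pulse length must be positive")
    return pulse_length_um / 2.0
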