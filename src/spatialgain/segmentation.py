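"""IMCT segmentation of muscle cross-section photographs.

Intramuscular connective tissue (IMCT — epi-, peri- and endomysium) is
pale against the red-brown muscle tissue in a fixed cross-section photo.
A transparent supervised per-channel threshold classifier, trained by
exhaustive scan on manually labeled pixels, separates the two classes;
the operative output is the percentage of IMCT pixels, which is then
regressed on the echo-intensity measure MGV_00.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

#: correlation magnitude bins on |r|, upper-edge inclusive
_MAGNITUDE_BINS = (
    (0.1, "trivial"),
    (0.3, "small"),
    (0.5, "moderate"),
    (0.7, "large"),
    (0.9, "very large"),
)


class SegmentationError(ValueError):
    """Raised for invalid training data or degenerate regression input."""


@dataclass(frozen=True)
class ThresholdClassifier:
    """A single-channel threshold: IMCT where value > (or <=) threshold."""

    channel: int
    threshold: float
    imct_above: bool
    training_error: float = math.nan

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Classify pixels; the last axis indexes channels (pass gray
        images as (H, W, 1) or use channel 0 with a 1-D vector)."""
        v = np.asarray(values, dtype=np.float64)
        if v.ndim < 2:
            if self.channel != 0:
                raise SegmentationError("1-D input has only channel 0")
            chan = v
        else:
            chan = v[..., self.channel]
        above = chan > self.threshold
        return above if self.imct_above else ~above

    def complement(self) -> "ThresholdClassifier":
        return ThresholdClassifier(
            channel=self.channel,
            threshold=self.threshold,
            imct_above=not self.imct_above,
            training_error=1.0 - self.training_error
            if math.isfinite(self.training_error)
            else math.nan,
        )


@dataclass(frozen=True)
class SegmentationResult:
    """Binary IMCT mask and pixel percentage for one cross-section image."""

    mask: np.ndarray
    imct_percent: float
    classifier: ThresholdClassifier

    def __post_init__(self) -> None:
        if not 0.0 <= self.imct_percent <= 100.0:
            raise ValueError("imct_percent must lie in [0, 100]")


@dataclass(frozen=True)
class RegressionReport:
    """OLS summary with the field's correlation-magnitude label."""

    slope: float
    intercept: float
    r: float
    adjusted_r2: float
    p_value: float
    n: int
    magnitude_label: str


def train_threshold(
    features: np.ndarray, labels: np.ndarray
) -> ThresholdClassifier:
    """Fit a per-channel threshold by exhaustive scan over candidate cuts.

    ``features`` is (N, C) with gray/color values, ``labels`` is boolean
    (True = IMCT).  Every midpoint between adjacent distinct values of
    every channel is tried with both polarities; the cut minimizing the
    training misclassification rate wins.  Raises on single-class input.
    """
    X = np.asarray(features, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=bool)
    if X.shape[0] != y.shape[0]:
        raise SegmentationError("features and labels disagree in length")
    if y.all() or (~y).all():
        raise SegmentationError("training data must contain both classes")

    best: ThresholdClassifier | None = None
    n = y.size
    for c in range(X.shape[1]):
        v = X[:, c]
        uniq = np.unique(v)
        cuts = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else uniq
        pred_above = v[None, :] > cuts[:, None]  # (n_cuts, N)
        err_above = (pred_above != y[None, :]).mean(axis=1)
        for err, above in ((err_above, True), (1.0 - err_above, False)):
            i = int(np.argmin(err))
            if best is None or err[i] < best.training_error:
                best = ThresholdClassifier(
                    channel=c,
                    threshold=float(cuts[i]),
                    imct_above=above,
                    training_error=float(err[i]),
                )
    assert best is not None
    return best


def segment(
    image: np.ndarray,
    classifier: ThresholdClassifier,
    foreground_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Classify every pixel and compute the IMCT percentage.

    By default the percentage is taken over the whole photograph; pass a
    boolean ``foreground_mask`` to restrict it to a muscle-only region.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    mask = classifier.predict(img)
    if foreground_mask is not None:
        fg = np.asarray(foreground_mask, dtype=bool)
        if fg.shape != mask.shape:
            raise SegmentationError("foreground mask shape mismatch")
        total = int(fg.sum())
        if total == 0:
            raise SegmentationError("empty foreground mask")
        percent = 100.0 * float((mask & fg).sum()) / total
        mask = mask & fg
    else:
        percent = 100.0 * float(mask.mean())
    return SegmentationResult(mask=mask, imct_percent=percent, classifier=classifier)


def correlation_magnitude_label(r: float) -> str:
    """Magnitude label of a correlation coefficient on standard |r| bins.

    trivial <= 0.1 < small <= 0.3 < moderate <= 0.5 < large <= 0.7
    < very large <= 0.9 < almost perfect.
    """
    a = abs(r)
    for upper, label in _MAGNITUDE_BINS:
        if a <= upper:
            return label
    return "almost perfect"


def regress_imct_on_mgv00(
    pairs: Iterable[tuple[float, float]]
) -> RegressionReport:
    """OLS of IMCT percentage on MGV_00 with a two-sided slope test.

    ``pairs`` are (imct_percent, mgv00) per specimen.  Returns slope,
    intercept, Pearson r, adjusted r^2, the slope p-value and the
    magnitude label of |r|.
    """
    data = list(pairs)
    if len(data) < 3:
        raise SegmentationError("regression needs at least 3 pairs")
    imct = np.array([p[0] for p in data], dtype=float)
    mgv00 = np.array([p[1] for p in data], dtype=float)
    if np.ptp(imct) < 1e-12 or np.ptp(mgv00) < 1e-12:
        raise SegmentationError("zero variance in IMCT or MGV_00")
    res = stats.linregress(mgv00, imct)
    n = imct.size
    r2 = res.rvalue**2
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return RegressionReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        adjusted_r2=float(adj),
        p_value=float(res.pvalue),
        n=n,
        magnitude_label=correlation_magnitude_label(res.rvalue),
    )
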