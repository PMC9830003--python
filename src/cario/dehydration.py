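"""Dehydration-curve statistics for SWIR reflectance and thermal image series.

A tooth surface is wetted, then dried with forced air while a camera records
one frame per second.  Water in the pores of a porous (active) lesion absorbs
shortwave-infrared light and cools the surface as it evaporates, so the rate
and magnitude of intensity/temperature change during drying indirectly measure
lesion permeability.  Two integral statistics summarise a region-of-interest
(ROI) time curve:

* SWIR intensity gain  ``delta_I = sum_t (I_t - I_min)``
* evaporative heat loss ``delta_Q = sum_t (T_max - T_t)``  (units K·s for 1-s frames)

Each lesion statistic is contrasted against a sound control ROI on the same
tooth as a difference (L−C) and a ratio (L/C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageStack",
    "RoiPair",
    "DehydrationResult",
    "roi_mean_curve",
    "delta_I",
    "delta_Q",
    "contrast_metrics",
    "integrated_heatmap",
    "analyze_stack",
]

MODALITIES = ("swir", "thermal")
#: physically plausible bounds for a thermal frame, kelvin
THERMAL_RANGE_K = (250.0, 350.0)


@dataclass
class ImageStack:
    """A T×H×W image time series with uniform frame spacing.

    ``frames`` holds arbitrary intensity units for SWIR and kelvin for
    thermal stacks.  Frame 0 is the first post-immersion frame; frame t is
    t·frame_interval_s seconds into drying.
    """

    frames: np.ndarray
    frame_interval_s: float = 1.0
    modality: str = "swir"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be T×H×W with T >= 2")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.modality == "thermal":
            lo, hi = THERMAL_RANGE_K
            if self.frames.min() < lo or self.frames.max() > hi:
                raise ValueError(
                    f"thermal frames outside plausible range [{lo}, {hi}] K"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class RoiPair:
    """Lesion and control masks on the stack's frame grid.

    The masks must be nonempty and disjoint; composite-restoration pixels
    (bright in SWIR, a false-positive hazard) are the caller's responsibility
    to exclude from both.
    """

    lesion_mask: np.ndarray
    control_mask: np.ndarray

    def __post_init__(self) -> None:
        self.lesion_mask = np.asarray(self.lesion_mask, dtype=bool)
        self.control_mask = np.asarray(self.control_mask, dtype=bool)
        if self.lesion_mask.shape != self.control_mask.shape:
            raise ValueError("lesion and control masks must share a shape")
        if not self.lesion_mask.any() or not self.control_mask.any():
            raise ValueError("ROI masks must be nonempty")
        if np.any(self.lesion_mask & self.control_mask):
            raise ValueError("lesion and control masks must be disjoint")


@dataclass
class DehydrationResult:
    """ΔI or ΔQ for both ROIs plus the L−C and L/C contrasts."""

    delta_lesion: float
    delta_control: float
    diff: float
    ratio: float  # NaN when the control delta is zero
    ratio_defined: bool
    curve_lesion: np.ndarray = field(repr=False)
    curve_control: np.ndarray = field(repr=False)
    modality: str = "swir"


def _validate_curve(curve: np.ndarray) -> np.ndarray:
    curve = np.asarray(curve, dtype=np.float64)
    if curve.ndim != 1 or curve.size < 2:
        raise ValueError("curve must be a 1-D vector with at least 2 samples")
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite values")
    return curve


def roi_mean_curve(stack: ImageStack, mask: np.ndarray) -> np.ndarray:
    """Mean intensity over the mask for each frame (length-T vector)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.image_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {stack.image_shape}"
        )
    if not mask.any():
        raise ValueError("mask is empty")
    return stack.frames[:, mask].mean(axis=1)


def delta_I(curve: np.ndarray) -> float:
    """Integrated SWIR intensity gain Σ_t (I_t − I_min).

    I_min is the global minimum over the recorded window, not the first
    frame: curves typically start at the minimum (wet surface) but are not
    guaranteed to.  Zero iff the curve is constant.
    """
    curve = _validate_curve(curve)
    # fsum: exactly rounded, order-independent summation
    return math.fsum(curve - curve.min())


def delta_Q(curve: np.ndarray) -> float:
    """Integrated evaporative-cooling area Σ_t (T_max − T_t), in K·s for 1-s frames."""
    curve = _validate_curve(curve)
    return math.fsum(curve.max() - curve)


def contrast_metrics(lesion_value: float, control_value: float) -> tuple[float, float, bool]:
    """L−C difference and L/C ratio of a lesion statistic against its control.

    Returns ``(diff, ratio, ratio_defined)``; a zero control leaves the ratio
    NaN with ``ratio_defined`` False (the difference is still meaningful).
    """
    diff = float(lesion_value - control_value)
    if control_value == 0:
        return diff, float("nan"), False
    return diff, float(lesion_value / control_value), True


def integrated_heatmap(stack: ImageStack) -> np.ndarray:
    """Per-pixel integrated change map used to designate ROIs.

    Pixel (i, j) holds delta_I (SWIR) or delta_Q (thermal) of that pixel's own
    time series.  Note this per-pixel-first estimator differs from computing
    the delta of an ROI-mean curve whenever per-pixel extrema occur at
    different frames; ROI-mean-first is the reporting default (see
    :func:`analyze_stack`), the heat map is a visualisation/ROI-picking aid.
    """
    frames = stack.frames
    if stack.modality == "thermal":
        return np.sum(frames.max(axis=0)[None] - frames, axis=0)
    return np.sum(frames - frames.min(axis=0)[None], axis=0)


def analyze_stack(stack: ImageStack, rois: RoiPair) -> DehydrationResult:
    """ROI-mean-first dehydration analysis of one stack.

    Aggregates each ROI to its mean time curve, applies delta_I or delta_Q
    according to the stack modality, and forms the L−C / L/C contrasts.  The
    sum runs over every available frame including frame 0, so truncated
    acquisitions remain analyzable.
    """
    if rois.lesion_mask.shape != stack.image_shape:
        raise ValueError("ROI masks do not match the stack's frame shape")
    curve_l = roi_mean_curve(stack, rois.lesion_mask)
    curve_c = roi_mean_curve(stack, rois.control_mask)
    stat = delta_Q if stack.modality == "thermal" else delta_I
    d_l, d_c = stat(curve_l), stat(curve_c)
    diff, ratio, ok = contrast_metrics(d_l, d_c)
    return DehydrationResult(
        delta_lesion=d_l,
        delta_control=d_c,
        diff=diff,
        ratio=ratio,
        ratio_defined=ok,
        curve_lesion=curve_l,
        curve_control=curve_c,
        modality=stack.modality,
    )
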