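"""OCT B-scan morphometry: lesion depth, integrated reflectivity, TSL.

A B-scan is a stack of axial reflectivity profiles (A-lines).  Demineralised
enamel scatters strongly and appears as a bright band; a remineralised
transparent surface layer (TSL) appears as a dark band between the surface
Fresnel peak and the lesion body.  OCT measures optical path length, so every
reported tissue length is the optical length divided by 1.6, the refractive
index of enamel.

The analysis chain is: :func:`detect_surface` → :func:`segment_lesion` →
:func:`lesion_depth` / :func:`integrated_reflectivity` / :func:`detect_tsl`,
or :func:`measure_bscan` for the whole chain at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "ENAMEL_RI",
    "BScan",
    "OctMorphometry",
    "detect_surface",
    "segment_lesion",
    "lesion_depth",
    "integrated_reflectivity",
    "detect_tsl",
    "measure_bscan",
]

#: refractive index of enamel; optical length ÷ 1.6 = tissue length
ENAMEL_RI = 1.6

#: a column's surface entry when no suprathreshold pixel exists
MISSING = -1

# TSL decision rule: a column's transparent run must stay below this fraction
# of that column's lesion-body peak, and the median run must span at least
# MIN_TSL_PIXELS axial pixels to count as detected.
TSL_BODY_FRACTION = 0.5
MIN_TSL_PIXELS = 2

# lesion-candidate foreground must average at least this fraction of the
# surface Fresnel peak; sound sub-surface scattering sits well below it
MIN_BODY_TO_SURFACE = 0.15
MIN_LESION_PIXELS = 10


@dataclass
class BScan:
    """A 2-D B-scan: axial rows × lateral columns, with the axial pixel
    pitch in *optical* micrometres per row."""

    image: np.ndarray
    axial_pitch_um_optical: float
    surface_row_per_col: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("image must be a nonempty 2-D array")
        if self.axial_pitch_um_optical <= 0:
            raise ValueError("axial pitch must be positive")
        if self.surface_row_per_col is not None:
            s = np.asarray(self.surface_row_per_col, dtype=int)
            if s.shape != (self.image.shape[1],):
                raise ValueError("surface vector length must equal the column count")
            if np.any((s != MISSING) & ((s < 0) | (s >= self.image.shape[0]))):
                raise ValueError("surface rows out of image bounds")
            self.surface_row_per_col = s


@dataclass
class OctMorphometry:
    """Per-B-scan lesion measurements, all lengths on the tissue scale (μm)."""

    lesion_depth_um: float
    delta_R: float
    tsl_thickness_um: float
    tsl_detected: bool
    lesion_present: bool

    def __post_init__(self) -> None:
        if self.lesion_depth_um < 0 or self.tsl_thickness_um < 0:
            raise ValueError("lengths must be nonnegative")
        if not self.tsl_detected and self.tsl_thickness_um != 0:
            raise ValueError("undetected TSL must report zero thickness")


def _surface(bscan: BScan) -> np.ndarray:
    if bscan.surface_row_per_col is None:
        bscan.surface_row_per_col = detect_surface(bscan)
    return bscan.surface_row_per_col


def detect_surface(bscan: BScan, air_rows: int = 5, median_width: int = 5) -> np.ndarray:
    """Air/enamel boundary per column.

    Threshold = mean + 3·sd of the top ``air_rows`` rows (assumed air); the
    surface is the first suprathreshold row in each column, median-filtered
    across columns.  Columns with no suprathreshold pixel are marked
    ``MISSING`` and excluded downstream.
    """
    img = bscan.image
    air = img[: min(air_rows, img.shape[0])]
    thresh = float(air.mean() + 3.0 * air.std())
    above = img > thresh
    has_any = above.any(axis=0)
    first = np.where(has_any, above.argmax(axis=0), MISSING)
    valid = first != MISSING
    if valid.any() and median_width > 1:
        smoothed = first.astype(float).copy()
        # fill missing with nearest valid before smoothing, restore after
        idx = np.arange(first.size)
        smoothed[~valid] = np.interp(idx[~valid], idx[valid], first[valid].astype(float))
        smoothed = median_filter(smoothed, size=median_width, mode="nearest")
        out = np.round(smoothed).astype(int)
        out[~valid] = MISSING
        return out
    return first.astype(int)


def segment_lesion(bscan: BScan, roi_cols: slice) -> np.ndarray:
    """Threshold segmentation of the lesion body below the surface.

    Otsu's threshold is computed on the below-surface pixels within
    ``roi_cols``; the mask is the largest connected suprathreshold component.
    Two guards make sound tissue yield an empty mask: the candidate must
    contain at least ``MIN_LESION_PIXELS`` pixels and its mean reflectivity
    must reach ``MIN_BODY_TO_SURFACE`` of the median surface-peak intensity
    (sound sub-surface scattering is far dimmer than the Fresnel peak).
    """
    img = bscan.image
    surface = _surface(bscan)
    n_rows, n_cols = img.shape
    cols = np.arange(n_cols)[roi_cols]
    if cols.size == 0 or cols.min() < 0 or cols.max() >= n_cols:
        raise ValueError("roi_cols out of bounds")

    below = np.zeros_like(img, dtype=bool)
    surf_vals = []
    for c in cols:
        s = surface[c]
        if s == MISSING:
            continue
        below[s + 1 :, c] = True
        surf_vals.append(img[s, c])
    empty = np.zeros_like(img, dtype=bool)
    if not below.any():
        return empty

    vals = img[below]
    if np.ptp(vals) == 0:
        return empty
    # Otsu-initialised intermeans iteration: plain Otsu can split the
    # heavy-tailed dark background (deep attenuated rows dominate the
    # histogram) instead of separating the bright lesion body
    thresh = float(threshold_otsu(vals))
    for _ in range(50):
        hi, lo = vals[vals > thresh], vals[vals <= thresh]
        if hi.size == 0 or lo.size == 0:
            break
        new = 0.5 * (hi.mean() + lo.mean())
        if abs(new - thresh) < 1e-6:
            break
        thresh = new
    cand = below & (img > thresh)
    if not cand.any():
        return empty

    labels = label(cand, connectivity=2)
    largest = np.argmax(np.bincount(labels[labels > 0]))
    mask = labels == largest
    if mask.sum() < MIN_LESION_PIXELS:
        return empty
    surface_peak = float(np.median(surf_vals)) if surf_vals else float(img.max())
    if img[mask].mean() < MIN_BODY_TO_SURFACE * surface_peak:
        return empty
    return mask


def lesion_depth(mask: np.ndarray, bscan: BScan) -> float:
    """Mean lesion depth in tissue μm.

    Per column carrying mask pixels: (deepest mask row − surface row) × pitch
    ÷ 1.6; the reported depth is the mean over those columns.  An empty mask
    returns 0 (absent lesion).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bscan.image.shape:
        raise ValueError("mask shape must match the B-scan")
    if not mask.any():
        return 0.0
    surface = _surface(bscan)
    depths_px = []
    for c in np.flatnonzero(mask.any(axis=0)):
        if surface[c] == MISSING:
            continue
        deepest = np.flatnonzero(mask[:, c]).max()
        depths_px.append(deepest - surface[c])
    if not depths_px:
        return 0.0
    return float(np.mean(depths_px) * bscan.axial_pitch_um_optical / ENAMEL_RI)


def integrated_reflectivity(bscan: BScan, mask: np.ndarray) -> float:
    """ΔR: mean reflectivity over the lesion ROI (arbitrary units)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != bscan.image.shape:
        raise ValueError("mask shape must match the B-scan")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(bscan.image[mask].mean())


def detect_tsl(
    bscan: BScan,
    roi_cols: slice,
    mask: np.ndarray | None = None,
) -> tuple[bool, float]:
    """Transparent-surface-layer detection and thickness (tissue μm).

    Per lesion column: the contiguous run of rows immediately above the first
    lesion-body row whose reflectivity stays below ``TSL_BODY_FRACTION`` of
    that column's body peak.  Thickness is the median run length × pitch
    ÷ 1.6; detected only when the median run spans at least
    ``MIN_TSL_PIXELS`` axial pixels.  Raises if no lesion body exists — a TSL
    is defined only relative to a lesion.
    """
    if mask is None:
        mask = segment_lesion(bscan, roi_cols)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("TSL is undefined without a segmented lesion body")
    surface = _surface(bscan)
    img = bscan.image

    runs = []
    for c in np.flatnonzero(mask.any(axis=0)):
        s = surface[c]
        if s == MISSING:
            continue
        body_rows = np.flatnonzero(mask[:, c])
        body_top = body_rows.min()
        body_peak = img[body_rows, c].max()
        run = 0
        for r in range(body_top - 1, s, -1):  # walk up from the body
            if img[r, c] < TSL_BODY_FRACTION * body_peak:
                run += 1
            else:
                break
        runs.append(run)
    if not runs:
        return False, 0.0
    median_px = float(np.median(runs))
    if median_px < MIN_TSL_PIXELS:
        return False, 0.0
    return True, float(median_px * bscan.axial_pitch_um_optical / ENAMEL_RI)


def measure_bscan(bscan: BScan, roi_cols: slice) -> OctMorphometry:
    """Full morphometry of one B-scan: segmentation, depth, ΔR, TSL."""
    mask = segment_lesion(bscan, roi_cols)
    if not mask.any():
        return OctMorphometry(
            lesion_depth_um=0.0,
            delta_R=0.0,
            tsl_thickness_um=0.0,
            tsl_detected=False,
            lesion_present=False,
        )
    ld = lesion_depth(mask, bscan)
    dr = integrated_reflectivity(bscan, mask)
    detected, tsl = detect_tsl(bscan, roi_cols, mask=mask)
    return OctMorphometry(
        lesion_depth_um=ld,
        delta_R=dr,
        tsl_thickness_um=tsl,
        tsl_detected=detected,
        lesion_present=True,
    )
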