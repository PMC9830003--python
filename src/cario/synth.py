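"""Synthetic lesion cohorts and forward models for every imaging modality.

No public dataset of extracted teeth with secondary caries exists, so the
analysis stages are exercised against a generator that emulates the
statistical structure the method assumes:

* a ground-truth lesion parameterisation (depth, transparent-surface-layer
  thickness, mineral loss, permeability, surface type, water pooling);
* SWIR reflectance stacks whose lesion ROI brightens sigmoidally during
  drying at a rate set by permeability;
* thermal stacks with an evaporative-cooling dip and recovery to ambient;
* OCT B-scans with a bright demineralised body optionally capped by a dark
  transparent surface layer (TSL), rendered in optical units (tissue length
  × refractive index 1.6);
* MicroCT slices with a high-mineral surface layer over a demineralised
  body, on a true spatial scale (no refractive correction).

The arrest physics is encoded in :func:`permeability_from_tsl`: a TSL of
70 μm or more leaves the lesion essentially impermeable, so dehydration
statistics saturate in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dehydration import ImageStack, RoiPair

__all__ = [
    "LesionTruth",
    "CohortConfig",
    "permeability_from_tsl",
    "sample_cohort",
    "render_swir_stack",
    "render_thermal_stack",
    "render_oct_bscan",
    "render_microct_slice",
    "default_roi_pair",
    "oct_lesion_cols",
    "microct_lesion_cols",
    "lesion_rng",
    "SURFACE_TYPES",
    "AMBIENT_K",
    "ENAMEL_RI",
    "ARREST_TSL_UM",
]

SURFACE_TYPES = ("occlusal", "smooth", "incisal")

#: ambient / air / water-bath temperature, kelvin
AMBIENT_K = 294.15
#: refractive index of enamel: tissue length × 1.6 = optical path length
ENAMEL_RI = 1.6

#: TSL thickness at which a lesion is considered fully arrested, μm
ARREST_TSL_UM = 70.0
#: residual permeability fraction in the arrest regime
ARREST_FRACTION = 0.05
_TAU_UM = ARREST_TSL_UM / np.log(1.0 / ARREST_FRACTION)  # 70 / ln 20

PERMEABILITY_BASELINE = 1.0

# ---------------------------------------------------------------------------
# forward-model constants (see docs/methods.md for rationale and units)
# ---------------------------------------------------------------------------
# SWIR (arbitrary intensity units)
SWIR_BASE = 40.0           # wet sound enamel reflectance
SWIR_SOUND_AMP = 2.0       # drying amplitude of sound enamel
SWIR_LESION_AMP = 80.0     # lesion plateau amplitude at full mineral-loss scale
SWIR_POOL_AMP = 15.0       # extra amplitude from crevice water pooling
SWIR_COMPOSITE = 180.0     # static composite-restoration reflectance
SWIR_RATE_PER_PERM = 0.45  # logistic rate k per unit permeability, 1/s
SWIR_SOUND_RATE = 0.15
SWIR_T50_S = 12.0          # logistic midpoint
SWIR_SOUND_T50_S = 8.0
SWIR_POOL_RATE = 0.30
SWIR_POOL_T50_S = 20.0

# thermal (kelvin)
THERMAL_CTRL_AMP = 0.12    # sound-surface evaporation amplitude
THERMAL_LESION_AMP = 3.0   # amplitude scale for mineral_loss_frac × permeability
THERMAL_POOL_AMP = 2.5     # amplitude per unit water_pool_frac
THERMAL_COMPOSITE_AMP = 0.8
THERMAL_TAU_FAST_S = 3.0
THERMAL_TAU_SLOW_S = 25.0

#: tooth-to-tooth lognormal sigma on the sound/control drying amplitude;
#: cancels in L−C but compresses the information in L/C ratios
TOOTH_AMP_SIGMA = 0.35

# OCT (arbitrary reflectivity units)
OCT_SURFACE_PEAK = 200.0   # Fresnel reflection at the air/enamel interface
OCT_BODY_MAX = 150.0       # lesion-body reflectivity at/above saturation
OCT_SATURATION_ML = 0.15   # mineral-loss fraction where scattering saturates
OCT_TSL_LEVEL = 8.0        # transparent surface layer reflectivity
OCT_SOUND_LEVEL = 10.0     # sound sub-surface scattering just below the surface
OCT_ATTEN_UM = 300.0       # optical attenuation length of the weak background
OCT_SURFACE_ROW = 24

# MicroCT (arbitrary gray values)
CT_AIR = 15.0
CT_SOUND = 120.0
CT_SL = 160.0              # high-mineral surface layer
CT_BODY_BASE = 90.0        # demineralised body gray at zero mineral loss
CT_BODY_ML_SLOPE = 80.0    # gray lost per unit mineral_loss_frac
CT_SURFACE_ROW = 20


@dataclass(frozen=True)
class LesionTruth:
    """Ground-truth parameters of one synthetic lesion.

    ``sl_thickness_um`` is the MicroCT-visible surface layer, distinct from
    the OCT transparent surface layer: nearly all lesions carry some
    high-mineral surface zone, but only sufficiently remineralised ones are
    transparent in OCT.
    """

    lesion_depth_um: float
    tsl_thickness_um: float
    mineral_loss_frac: float
    permeability: float
    surface_type: str
    has_composite: bool
    water_pool_frac: float
    sl_thickness_um: float = 0.0
    lesion_id: int = 0

    def __post_init__(self) -> None:
        if self.lesion_depth_um < 0 or self.tsl_thickness_um < 0 or self.sl_thickness_um < 0:
            raise ValueError("lengths must be nonnegative")
        for name in ("mineral_loss_frac", "water_pool_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.permeability < 0:
            raise ValueError("permeability must be nonnegative")
        if self.surface_type not in SURFACE_TYPES:
            raise ValueError(f"surface_type must be one of {SURFACE_TYPES}")


@dataclass(frozen=True)
class CohortConfig:
    """Sampling and rendering configuration for a synthetic cohort.

    The seed fully determines every draw: each lesion gets its own RNG stream
    spawned from (seed, lesion index, purpose), so cohorts are reproducible
    under reordering or partial rendering.
    """

    n_lesions: int = 100
    tsl_range_um: tuple[float, float] = (0.0, 100.0)
    depth_range_um: tuple[float, float] = (80.0, 320.0)
    noise_sd_swir: float = 2.0
    noise_sd_thermal: float = 0.05
    noise_sd_oct: float = 3.0
    noise_sd_microct: float = 3.0
    frame_count: int = 60
    frame_interval_s: float = 1.0
    seed: int = 0
    image_shape: tuple[int, int] = (128, 128)
    # occlusal / smooth / incisal mix observed clinically: smooth surfaces dominate
    surface_type_weights: tuple[float, float, float] = (0.13, 0.81, 0.06)
    p_no_tsl: float = 0.2
    p_composite: float = 0.8
    mineral_loss_range: tuple[float, float] = (0.05, 0.35)
    oct_axial_pitch_um_optical: float = 5.0
    microct_pitch_um: float = 10.0

    def __post_init__(self) -> None:
        if self.n_lesions < 1:
            raise ValueError("n_lesions must be >= 1")
        if self.frame_count < 2:
            raise ValueError("frame_count must be >= 2")
        for name in ("tsl_range_um", "depth_range_um", "mineral_loss_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} is empty: ({lo}, {hi})")
        if abs(sum(self.surface_type_weights) - 1.0) > 1e-9:
            raise ValueError("surface_type_weights must sum to 1")
        h, w = self.image_shape
        if h < 48 or w < 48:
            raise ValueError("image_shape must be at least 48×48 to place ROIs")


# purpose codes for per-lesion RNG streams
_STREAMS = {"cohort": 0, "swir": 1, "thermal": 2, "oct": 3, "microct": 4}


def lesion_rng(seed: int, lesion_index: int, purpose: str) -> np.random.Generator:
    """Counter-style RNG stream for one lesion and purpose.

    Derived from the cohort seed via ``SeedSequence`` spawn keys, so streams
    are independent and stable regardless of evaluation order.
    """
    key = (lesion_index, _STREAMS[purpose])
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def permeability_from_tsl(tsl_thickness_um: float, baseline: float = PERMEABILITY_BASELINE) -> float:
    """Lesion permeability as a function of transparent-surface-layer thickness.

    Exponential decay p₀·exp(−tsl·ln20/70) clamped below at its 70-μm value,
    5% of baseline: remineralisation beyond the arrest threshold no longer
    changes fluid transport appreciably, so the response saturates rather
    than decaying indefinitely.  Strictly positive, monotone nonincreasing,
    equal to baseline at zero TSL.
    """
    if tsl_thickness_um < 0:
        raise ValueError("tsl_thickness_um must be nonnegative")
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return float(baseline * max(np.exp(-tsl_thickness_um / _TAU_UM), ARREST_FRACTION))


def sample_cohort(config: CohortConfig) -> list[LesionTruth]:
    """Draw a deterministic cohort of ground-truth lesions.

    TSL is zero with probability ``p_no_tsl`` (lesions with no detectable
    transparent layer) and otherwise uniform over ``tsl_range_um``.  Lesion
    depth is uniform over ``depth_range_um`` but kept at least 40 μm deeper
    than the TSL so the transparent cap stays enclosed by the lesion.  Water
    pooling affects only occlusal and incisal surfaces, where crevices retain
    water.  The MicroCT surface layer is TSL plus a broad positive offset and
    noise: almost every lesion has one, and it correlates only loosely with
    the transparent layer.
    """
    cohort: list[LesionTruth] = []
    for i in range(config.n_lesions):
        rng = lesion_rng(config.seed, i, "cohort")
        surface = rng.choice(SURFACE_TYPES, p=config.surface_type_weights)
        if rng.random() < config.p_no_tsl:
            tsl = 0.0
        else:
            tsl = float(rng.uniform(*config.tsl_range_um))
        lo, hi = config.depth_range_um
        depth = float(rng.uniform(max(lo, tsl + 40.0), max(hi, tsl + 60.0)))
        ml = float(rng.uniform(*config.mineral_loss_range))
        pool = float(rng.uniform(0.0, 0.8)) if surface in ("occlusal", "incisal") else 0.0
        # surface layer over the body: positive, loosely tied to TSL, and
        # thinner than the lesion so a demineralised body band remains
        sl = float(np.clip(tsl + rng.uniform(0.0, 60.0) + rng.normal(0.0, 35.0), 0.0, depth - 30.0))
        cohort.append(
            LesionTruth(
                lesion_depth_um=depth,
                tsl_thickness_um=tsl,
                mineral_loss_frac=ml,
                permeability=permeability_from_tsl(tsl),
                surface_type=str(surface),
                has_composite=bool(rng.random() < config.p_composite),
                water_pool_frac=pool,
                sl_thickness_um=sl,
                lesion_id=i,
            )
        )
    return cohort


# ---------------------------------------------------------------------------
# ROI geometry
# ---------------------------------------------------------------------------

def _roi_rects(image_shape: tuple[int, int]):
    h, w = image_shape
    rows = slice(h // 3, h // 3 + max(h // 6, 4))
    lesion_cols = slice(w // 3, w // 3 + max(w // 6, 4))
    control_cols = slice(2 * w // 3, 2 * w // 3 + max(w // 6, 4))
    composite_cols = slice(w // 12, w // 12 + max(w // 6, 4))
    return rows, lesion_cols, control_cols, composite_cols


def default_roi_pair(image_shape: tuple[int, int]) -> RoiPair:
    """Disjoint rectangular lesion/control ROIs on the frame grid.

    The composite region (when rendered) sits left of the lesion and is part
    of neither mask, mirroring the operator practice of excluding bright
    restoration pixels from both ROIs.
    """
    rows, les, ctl, _ = _roi_rects(image_shape)
    lesion = np.zeros(image_shape, dtype=bool)
    control = np.zeros(image_shape, dtype=bool)
    lesion[rows, les] = True
    control[rows, ctl] = True
    return RoiPair(lesion_mask=lesion, control_mask=control)


def _logistic(t: np.ndarray, rate: float, t50: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rate * (t - t50)))


def render_swir_stack(
    truth: LesionTruth,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> tuple[ImageStack, RoiPair]:
    """Render a SWIR dehydration stack for one lesion.

    Every tooth pixel shares a weak sound-enamel drying sigmoid whose
    amplitude carries a per-tooth lognormal factor (surface texture and
    wetting vary tooth to tooth).  Lesion pixels add a logistic component
    with plateau ∝ mineral_loss_frac and rate ∝ permeability, plus a slow
    pooled-water term ∝ water_pool_frac.  Frame 0 is the curve minimum in
    the noise-free limit; noise is additive Gaussian.
    """
    if rng is None:
        rng = lesion_rng(config.seed, truth.lesion_id, "swir")
    if noise_sd is None:
        noise_sd = config.noise_sd_swir
    h, w = config.image_shape
    t = np.arange(config.frame_count, dtype=np.float64) * config.frame_interval_s
    rows, les, _, comp = _roi_rects(config.image_shape)

    tooth_factor = float(np.exp(rng.normal(0.0, TOOTH_AMP_SIGMA)))
    sound = SWIR_SOUND_AMP * tooth_factor * _logistic(t, SWIR_SOUND_RATE, SWIR_SOUND_T50_S)

    lesion_amp = SWIR_LESION_AMP * truth.mineral_loss_frac
    rate = SWIR_RATE_PER_PERM * truth.permeability
    lesion = lesion_amp * _logistic(t, rate, SWIR_T50_S)
    pool = SWIR_POOL_AMP * truth.water_pool_frac * _logistic(t, SWIR_POOL_RATE, SWIR_POOL_T50_S)

    frames = np.empty((config.frame_count, h, w), dtype=np.float64)
    frames[:] = (SWIR_BASE + sound)[:, None, None]
    frames[:, rows, les] += (lesion + pool)[:, None, None]
    if truth.has_composite:
        frames[:, rows, comp] = SWIR_COMPOSITE
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    stack = ImageStack(frames=frames, frame_interval_s=config.frame_interval_s, modality="swir")
    return stack, default_roi_pair(config.image_shape)


def _cooling_shape(t: np.ndarray) -> np.ndarray:
    """Drop-then-recover kernel: e^{−t/τ_slow} − e^{−t/τ_fast}, zero at t=0."""
    return np.exp(-t / THERMAL_TAU_SLOW_S) - np.exp(-t / THERMAL_TAU_FAST_S)


def render_thermal_stack(
    truth: LesionTruth,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> tuple[ImageStack, RoiPair]:
    """Render a thermal dehydration stack for one lesion.

    Surfaces start near ambient (294.15 K), dip as surface water evaporates
    and recover within the 60-s window.  The lesion dip amplitude scales with
    mineral_loss_frac × permeability (water escaping lesion pores) plus
    water_pool_frac (crevice pooling); control pixels carry only the small
    sound-surface evaporation shared by the whole tooth.
    """
    if rng is None:
        rng = lesion_rng(config.seed, truth.lesion_id, "thermal")
    if noise_sd is None:
        noise_sd = config.noise_sd_thermal
    h, w = config.image_shape
    t = np.arange(config.frame_count, dtype=np.float64) * config.frame_interval_s
    rows, les, _, comp = _roi_rects(config.image_shape)

    tooth_factor = float(np.exp(rng.normal(0.0, TOOTH_AMP_SIGMA)))
    shape = _cooling_shape(t)
    base_amp = THERMAL_CTRL_AMP * tooth_factor
    lesion_extra = (
        THERMAL_LESION_AMP * truth.mineral_loss_frac * truth.permeability
        + THERMAL_POOL_AMP * truth.water_pool_frac
    )

    frames = np.empty((config.frame_count, h, w), dtype=np.float64)
    frames[:] = (AMBIENT_K - base_amp * shape)[:, None, None]
    frames[:, rows, les] -= (lesion_extra * shape)[:, None, None]
    if truth.has_composite:
        frames[:, rows, comp] -= (THERMAL_COMPOSITE_AMP * shape)[:, None, None]
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)
    frames = np.clip(frames, 250.0, 350.0)
    stack = ImageStack(frames=frames, frame_interval_s=config.frame_interval_s, modality="thermal")
    return stack, default_roi_pair(config.image_shape)


# ---------------------------------------------------------------------------
# OCT B-scan rendering (optical axial units)
# ---------------------------------------------------------------------------

OCT_SHAPE = (220, 64)


def oct_lesion_cols(n_cols: int) -> slice:
    """Columns occupied by the lesion in a rendered B-scan (middle half)."""
    return slice(n_cols // 4, 3 * n_cols // 4)


def render_oct_bscan(
    truth: LesionTruth,
    axial_pitch_um_optical: float = 5.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = OCT_SHAPE,
    surface_row: int = OCT_SURFACE_ROW,
) -> np.ndarray:
    """Render a 2-D B-scan (axial rows × lateral columns) in optical units.

    Axial band boundaries are placed at tissue length × 1.6 ÷ pitch rows
    below the surface Fresnel peak: an (optional) dark transparent surface
    layer, then a bright lesion body whose reflectivity saturates at 15%
    mineral loss, then weak exponentially attenuated background.  Sound
    columns show only the surface peak and attenuated background.
    """
    if axial_pitch_um_optical <= 0:
        raise ValueError("axial pitch must be positive")
    n_rows, n_cols = shape
    if rng is None:
        rng = np.random.default_rng(0)

    depth_rows = np.arange(n_rows, dtype=np.float64) - surface_row
    atten = np.where(
        depth_rows > 0,
        OCT_SOUND_LEVEL * np.exp(-depth_rows * axial_pitch_um_optical / OCT_ATTEN_UM),
        0.0,
    )
    image = np.tile(atten[:, None], (1, n_cols))
    image[surface_row, :] = OCT_SURFACE_PEAK

    if truth.mineral_loss_frac > 0:
        cols = oct_lesion_cols(n_cols)
        n_tsl = int(round(truth.tsl_thickness_um * ENAMEL_RI / axial_pitch_um_optical))
        n_ld = int(round(truth.lesion_depth_um * ENAMEL_RI / axial_pitch_um_optical))
        body = OCT_BODY_MAX * min(truth.mineral_loss_frac, OCT_SATURATION_ML) / OCT_SATURATION_ML
        tsl_top = surface_row + 1
        body_top = min(tsl_top + n_tsl, n_rows)
        body_bottom = min(surface_row + n_ld + 1, n_rows)
        if n_tsl > 0:
            image[tsl_top:body_top, cols] = OCT_TSL_LEVEL
        image[body_top:body_bottom, cols] = body
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image


# ---------------------------------------------------------------------------
# MicroCT slice rendering (true spatial units)
# ---------------------------------------------------------------------------

CT_SHAPE = (120, 64)


def microct_lesion_cols(n_cols: int) -> slice:
    """Columns occupied by the lesion in a rendered MicroCT slice."""
    return slice(n_cols // 4, 3 * n_cols // 4)


def render_microct_slice(
    truth: LesionTruth,
    pitch_um: float = 10.0,
    sl_thickness_um: float | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    shape: tuple[int, int] = CT_SHAPE,
    surface_row: int = CT_SURFACE_ROW,
) -> np.ndarray:
    """Render a MicroCT slice: air, high-mineral surface layer, demineralised
    body down to the lesion depth, then sound mineral density.

    The depth axis is true μm (pitch_um per pixel, no optical correction).
    A zero mineral-loss truth renders flat sound tissue.  Gray ordering in
    the noise-free limit: body < sound < surface layer.
    """
    if pitch_um <= 0:
        raise ValueError("pitch must be positive")
    if sl_thickness_um is None:
        sl_thickness_um = truth.sl_thickness_um
    n_rows, n_cols = shape
    if rng is None:
        rng = np.random.default_rng(0)

    image = np.full(shape, CT_SOUND, dtype=np.float64)
    image[:surface_row, :] = CT_AIR

    if truth.mineral_loss_frac > 0:
        cols = microct_lesion_cols(n_cols)
        n_ld = int(round(truth.lesion_depth_um / pitch_um))
        # keep at least one body row below the surface layer
        n_sl = min(int(round(sl_thickness_um / pitch_um)), max(n_ld - 1, 0))
        body_gray = CT_BODY_BASE - CT_BODY_ML_SLOPE * truth.mineral_loss_frac
        sl_bottom = min(surface_row + n_sl, n_rows)
        ld_bottom = min(surface_row + n_ld, n_rows)
        image[surface_row:ld_bottom, cols] = body_gray
        image[surface_row:sl_bottom, cols] = CT_SL
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image
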