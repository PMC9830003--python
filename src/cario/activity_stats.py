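"""Cohort statistics: correlations, the 70-μm TSL split, and activity classes.

Joins per-lesion dehydration statistics (ΔI/ΔQ, as L−C differences and L/C
ratios), OCT morphometry (lesion depth, ΔR, TSL thickness) and MicroCT
morphometry (lesion depth, SL thickness) into one table, then asks the
questions that matter clinically: does the transparent surface layer predict
permeability (negative TSL-vs-dehydration correlations), does the effect
saturate at 70 μm (band analysis and between-band t-tests), and does surface
type modulate it (stratified correlations)?

Conventions: Pearson correlation with two-sided p-values throughout;
unpaired t-tests default to Welch's unequal-variance form; no
multiple-testing correction by default (a Benjamini–Hochberg helper is
available); lesions without a detectable TSL are excluded from TSL
correlations by default, with an option to keep them at thickness zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TSL_ARREST_CUT_UM",
    "DEHYDRATION_STATS",
    "LesionRecord",
    "CorrelationReport",
    "pearson",
    "unpaired_t",
    "tsl_band_analysis",
    "stratify_by_surface",
    "classify_activity",
    "benjamini_hochberg",
    "records_frame",
    "run_statistics",
]

#: TSL thickness (μm) at and above which a lesion is called arrested
TSL_ARREST_CUT_UM = 70.0

#: dehydration contrast columns correlated against TSL
DEHYDRATION_STATS = ("dI_diff", "dI_ratio", "dQ_diff", "dQ_ratio")

SURFACE_TYPES = ("occlusal", "smooth", "incisal")


@dataclass
class LesionRecord:
    """One joined per-lesion row; truth fields are present only for synthetic cohorts."""

    lesion_id: int
    surface_type: str
    dI_diff: float
    dI_ratio: float
    dQ_diff: float
    dQ_ratio: float
    ld_oct_um: float
    delta_R: float
    tsl_um: float
    tsl_detected: bool
    ld_ct_um: float
    sl_um: float
    truth_tsl_um: float = float("nan")
    truth_depth_um: float = float("nan")
    truth_mineral_loss: float = float("nan")
    truth_permeability: float = float("nan")

    def __post_init__(self) -> None:
        if self.surface_type not in SURFACE_TYPES:
            raise ValueError(f"surface_type must be one of {SURFACE_TYPES}")
        for name in ("ld_oct_um", "tsl_um", "ld_ct_um", "sl_um"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class CorrelationReport:
    """Pearson r for one variable pair within one stratum."""

    pair: tuple[str, str]
    r: float
    p: float
    n: int
    stratum: str = "cohort"
    computed: bool = True
    note: str = ""


def records_frame(records) -> pd.DataFrame:
    """Normalise a list of LesionRecords (or a DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([asdict(r) for r in records])


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value from the t transform.

    Requires equal lengths ≥ 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("pearson needs two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def unpaired_t(a: np.ndarray, b: np.ndarray, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test, Welch's unequal-variance form by default."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.std(a) == 0 and np.std(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def _tsl_table(frame: pd.DataFrame, include_undetected: bool) -> pd.DataFrame:
    if include_undetected:
        return frame
    return frame[frame["tsl_detected"].astype(bool)]


def _safe_corr(x, y, pair, stratum) -> CorrelationReport:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return CorrelationReport(pair=pair, r=float("nan"), p=float("nan"), n=int(x.size),
                                 stratum=stratum, computed=False,
                                 note="fewer than 3 points or zero variance")
    r, p = pearson(x, y)
    return CorrelationReport(pair=pair, r=r, p=p, n=int(x.size), stratum=stratum)


def tsl_band_analysis(
    records,
    cut_um: float = TSL_ARREST_CUT_UM,
    include_undetected: bool = False,
    equal_var: bool = False,
) -> dict:
    """Within-band TSL correlations and between-band t-tests at a TSL cut.

    Splits lesions at ``cut_um`` (below vs at-or-above), correlates TSL with
    each dehydration statistic inside each band, and t-tests each statistic
    between bands.  Sub-arrest lesions should show strong negative
    correlations that vanish in the arrest band, where further
    remineralisation no longer changes permeability.  Empty bands yield a
    partial report with ``computed`` flags rather than an error.
    """
    frame = _tsl_table(records_frame(records), include_undetected)
    below = frame[frame["tsl_um"] < cut_um]
    above = frame[frame["tsl_um"] >= cut_um]
    report: dict = {
        "cut_um": cut_um,
        "n_below": len(below),
        "n_above": len(above),
        "bands": {},
        "between": {},
    }
    for name, band in (("below", below), ("above", above)):
        report["bands"][name] = {
            stat: _safe_corr(band["tsl_um"], band[stat], ("tsl_um", stat), f"tsl-band-{name}")
            for stat in DEHYDRATION_STATS
        }
    for stat in DEHYDRATION_STATS:
        if len(below) >= 2 and len(above) >= 2:
            t, p = unpaired_t(below[stat], above[stat], equal_var=equal_var)
            report["between"][stat] = {"t": t, "p": p, "computed": True}
        else:
            report["between"][stat] = {"t": float("nan"), "p": float("nan"), "computed": False}
    return report


def stratify_by_surface(records, include_undetected: bool = False) -> dict[str, list[CorrelationReport]]:
    """TSL-vs-dehydration correlations computed separately per surface type.

    Strata with fewer than 3 lesions are flagged, not computed.  Occlusal and
    incisal surfaces pool water in pits and crevices, which inflates thermal
    (and to a lesser degree SWIR) statistics independently of lesion
    activity, so smooth surfaces are expected to correlate best.
    """
    frame = _tsl_table(records_frame(records), include_undetected)
    out: dict[str, list[CorrelationReport]] = {}
    for surface, group in frame.groupby("surface_type", sort=True):
        out[str(surface)] = [
            _safe_corr(group["tsl_um"], group[stat], ("tsl_um", stat), f"surface-{surface}")
            for stat in DEHYDRATION_STATS
        ]
    return out


def classify_activity(
    tsl_um: float, tsl_detected: bool, cut_um: float = TSL_ARREST_CUT_UM
) -> str:
    """Lesion activity class from the transparent surface layer.

    No detectable TSL → ``active`` (nothing impedes fluid exchange); a TSL
    thinner than the cut → ``partially-arrested``; at or above the cut →
    ``arrested``.  The boundary value itself is assigned to ``arrested``
    (inclusive convention, documented here once).
    """
    if tsl_um < 0:
        raise ValueError("tsl_um must be nonnegative")
    if not tsl_detected:
        return "active"
    if tsl_um >= cut_um:
        return "arrested"
    return "partially-arrested"


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (off by default everywhere)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return out


#: headline variable pairs reported for every cohort
_CORR_PAIRS = (
    ("ld_oct_um", "delta_R"),
    ("delta_R", "dQ_ratio"),
    ("tsl_um", "dI_diff"),
    ("tsl_um", "dI_ratio"),
    ("tsl_um", "dQ_diff"),
    ("tsl_um", "dQ_ratio"),
    ("tsl_um", "sl_um"),
)


def run_statistics(
    records,
    cut_um: float = TSL_ARREST_CUT_UM,
    include_undetected: bool = False,
    equal_var: bool = False,
) -> dict:
    """Full statistical report for a joined cohort table.

    Cohort-level correlations for the headline pairs (TSL pairs restricted to
    lesions with a detected TSL unless ``include_undetected``), the TSL band
    analysis at ``cut_um``, surface-type strata, and a per-lesion activity
    classification.
    """
    frame = records_frame(records)
    tsl_frame = _tsl_table(frame, include_undetected)
    correlations = []
    for xcol, ycol in _CORR_PAIRS:
        sub = tsl_frame if "tsl_um" in (xcol, ycol) else frame
        correlations.append(_safe_corr(sub[xcol], sub[ycol], (xcol, ycol), "cohort"))
    classes = [
        classify_activity(row.tsl_um, bool(row.tsl_detected), cut_um)
        for row in frame.itertuples()
    ]
    return {
        "correlations": correlations,
        "band_analysis": tsl_band_analysis(
            frame, cut_um, include_undetected=include_undetected, equal_var=equal_var
        ),
        "surface_strata": stratify_by_surface(frame, include_undetected=include_undetected),
        "activity_class": classes,
        "n_lesions": len(frame),
        "n_tsl_detected": int(frame["tsl_detected"].astype(bool).sum()),
    }
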