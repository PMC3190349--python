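"""Approximate bone-marrow-lesion (BML) volumetry and change classification.

A BML is an ill-defined high-signal region in subchondral bone on
fluid-sensitive MRI. Rather than segmenting each lesion slice by slice,
the pipeline approximates its volume as the product of three maximal
orthogonal linear dimensions — anterior–posterior (AP) and
superior–inferior (SI) read on sagittal images, medial–lateral (ML) on
coronal images — each taken as the greatest diameter across all slices.
Dimensions are in cm, volumes in cm³.

Lesion volumes are summed per knee region (index/non-index femur/tibia)
and the follow-up minus baseline difference is classified as
regression, no change, or progression against a smallest detectable
difference (SDD). The SDD is derived from test–retest reliability data:
for each lesion the difference between the first and repeated
volume-change reading is formed, and the SDD is the larger absolute
endpoint of the 95% confidence interval of the median of those
differences (order-statistic interval by default; a bootstrap
percentile interval is available as an alternative).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stats import MedianCi, median_ci

logger = logging.getLogger(__name__)

__all__ = [
    "Region",
    "Timepoint",
    "ChangeClass",
    "BmlMeasurement",
    "RegionalBmlRecord",
    "BmlChangeRecord",
    "SddEstimate",
    "approximate_volume",
    "regional_aggregate",
    "normalize_peak_signal",
    "regional_peak_signal",
    "volume_change",
    "derive_sdd",
    "bootstrap_sdd",
    "classify_change",
    "summarize_classifications",
    "whole_percent",
    "select_study_knee",
    "DEFAULT_THRESHOLD_CM3",
]

#: Change threshold (cm³) from the reference reliability analysis; any
#: SDD estimate derived from project-specific test–retest data overrides it.
DEFAULT_THRESHOLD_CM3 = 3.2


class InvalidMeasurementError(ValueError):
    """A lesion measurement violates its invariants."""


class AggregationError(ValueError):
    """Measurements from mixed knees/regions/timepoints were aggregated."""


class Region(str, enum.Enum):
    INDEX_FEMUR = "index_femur"
    INDEX_TIBIA = "index_tibia"
    NONINDEX_FEMUR = "nonindex_femur"
    NONINDEX_TIBIA = "nonindex_tibia"


class Timepoint(str, enum.Enum):
    BASELINE = "baseline"
    FOLLOWUP = "followup"


class ChangeClass(str, enum.Enum):
    REGRESSION = "regression"
    NO_CHANGE = "no_change"
    PROGRESSION = "progression"


@dataclass(frozen=True)
class BmlMeasurement:
    """One lesion's three maximal linear dimensions at one timepoint."""

    lesion_id: str
    knee_id: str
    region: Region
    timepoint: Timepoint
    ap_cm: float
    ml_cm: float
    si_cm: float
    peak_signal: float
    n_sagittal_slices: int = 0
    n_coronal_slices: int = 0
    reference_signal: float | None = None

    def __post_init__(self) -> None:
        for name in ("ap_cm", "ml_cm", "si_cm"):
            if not getattr(self, name) > 0:
                raise InvalidMeasurementError(
                    f"{name} must be > 0 for lesion {self.lesion_id}"
                )
        if self.peak_signal < 0:
            raise InvalidMeasurementError(
                f"peak_signal must be >= 0 for lesion {self.lesion_id}"
            )

    @property
    def is_valid_lesion(self) -> bool:
        """Visibility rule: present on >= 2 sagittal and/or >= 2 coronal slices."""
        return self.n_sagittal_slices >= 2 or self.n_coronal_slices >= 2

    @property
    def approx_volume_cm3(self) -> float:
        return approximate_volume(self.ap_cm, self.ml_cm, self.si_cm)


@dataclass(frozen=True)
class RegionalBmlRecord:
    """Summed approximate BML volume for one knee region at one timepoint."""

    knee_id: str
    region: Region
    timepoint: Timepoint
    approx_volume_cm3: float
    peak_signal_normalized: float | None
    n_lesions: int


@dataclass(frozen=True)
class BmlChangeRecord:
    """Follow-up minus baseline regional volume with its change class."""

    knee_id: str
    region: Region
    delta_cm3: float
    change_class: ChangeClass


@dataclass(frozen=True)
class SddEstimate:
    """Smallest detectable difference from test–retest change data."""

    median_diff_cm3: float
    ci_lo_cm3: float
    ci_hi_cm3: float
    threshold_cm3: float
    method: str
    n_lesions: int
    n_resamples: int = 0
    seed: int | None = None


def approximate_volume(ap_cm: float, ml_cm: float, si_cm: float) -> float:
    """Approximate lesion volume: product of the three maximal dimensions."""
    if not (ap_cm > 0 and ml_cm > 0 and si_cm > 0):
        raise InvalidMeasurementError("all three dimensions must be > 0")
    return ap_cm * ml_cm * si_cm


def normalize_peak_signal(peak_signal: float, reference_signal: float) -> float:
    """Peak lesion signal over normal bone-marrow reference signal.

    The reference is read in the posterior non-index femur, a region
    reliably free of lesions, to correct for acquisition-to-acquisition
    intensity variation.
    """
    if not reference_signal > 0:
        raise InvalidMeasurementError("reference_signal must be > 0")
    if peak_signal < 0:
        raise InvalidMeasurementError("peak_signal must be >= 0")
    return peak_signal / reference_signal


def regional_peak_signal(normalized_peaks: Sequence[float]) -> float | None:
    """Regional peak: the greatest normalized lesion signal, None if no lesions."""
    if len(normalized_peaks) == 0:
        return None
    return float(max(normalized_peaks))


def regional_aggregate(
    measurements: Sequence[BmlMeasurement],
    knee_id: str | None = None,
    region: Region | None = None,
    timepoint: Timepoint | None = None,
) -> RegionalBmlRecord:
    """Sum lesion volumes within one knee/region/timepoint.

    An empty list yields a zero-volume record, in which case the
    identifying fields must be supplied explicitly.
    """
    if not measurements:
        if knee_id is None or region is None or timepoint is None:
            raise AggregationError(
                "empty aggregate needs explicit knee_id, region and timepoint"
            )
        return RegionalBmlRecord(knee_id, region, timepoint, 0.0, None, 0)
    keys = {(m.knee_id, m.region, m.timepoint) for m in measurements}
    if len(keys) > 1:
        raise AggregationError(f"mixed knee/region/timepoint groups: {sorted(keys)}")
    k, r, t = keys.pop()
    if knee_id is not None and knee_id != k:
        raise AggregationError("knee_id does not match measurements")
    total = sum(m.approx_volume_cm3 for m in measurements)
    peaks = [
        normalize_peak_signal(m.peak_signal, m.reference_signal)
        for m in measurements
        if m.reference_signal is not None
    ]
    return RegionalBmlRecord(
        knee_id=k,
        region=r,
        timepoint=t,
        approx_volume_cm3=float(total),
        peak_signal_normalized=regional_peak_signal(peaks),
        n_lesions=len(measurements),
    )


def volume_change(
    baseline: RegionalBmlRecord | None, followup: RegionalBmlRecord | None
) -> float:
    """Regional volume change; a region absent at one timepoint counts as 0.

    Incident lesions (absent at baseline) and resolved lesions (absent
    at follow-up) thus enter the change analysis with their full volume.
    """
    if baseline is None and followup is None:
        raise ValueError("change undefined: no record at either timepoint")
    b = 0.0 if baseline is None else baseline.approx_volume_cm3
    f = 0.0 if followup is None else followup.approx_volume_cm3
    return f - b


def change_differences(
    test_retest: Sequence[tuple[tuple[float, float], tuple[float, float]]],
) -> np.ndarray:
    """Per-lesion difference of volume changes between test and retest.

    Each element is ``((baseline1, followup1), (baseline2, followup2))``;
    the returned difference is ``(followup1 - baseline1) - (followup2 -
    baseline2)``.
    """
    out = np.array(
        [(f1 - b1) - (f2 - b2) for (b1, f1), (b2, f2) in test_retest], dtype=float
    )
    return out


def derive_sdd(
    test_retest: Sequence[tuple[tuple[float, float], tuple[float, float]]],
    level: float = 0.95,
) -> SddEstimate:
    """Smallest detectable difference from test–retest change readings.

    The distribution-free order-statistic CI of the median
    difference-of-changes is computed and the SDD is the larger absolute
    endpoint — a conservative choice appropriate for the skewed,
    small-sample differences typical of this measurement.
    """
    diffs = change_differences(test_retest)
    ci: MedianCi = median_ci(diffs, level=level)
    threshold = max(abs(ci.ci_lo), abs(ci.ci_hi))
    return SddEstimate(
        median_diff_cm3=ci.median,
        ci_lo_cm3=ci.ci_lo,
        ci_hi_cm3=ci.ci_hi,
        threshold_cm3=float(threshold),
        method="median_order_statistic",
        n_lesions=int(diffs.size),
    )


def bootstrap_sdd(
    differences: Sequence[float],
    n_resamples: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> SddEstimate:
    """Bootstrap percentile CI of the median difference-of-changes.

    Reproducible for a fixed seed; offered as an alternative to the
    order-statistic interval for cross-checking the SDD.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size < 2:
        raise ValueError("bootstrap requires at least 2 observations")
    if n_resamples < 100:
        logger.warning(
            "bootstrap_sdd with n_resamples=%d (< 100) is unstable", n_resamples
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, diffs.size, size=(n_resamples, diffs.size))
    medians = np.median(diffs[idx], axis=1)
    alpha = 1.0 - level
    ci_lo, ci_hi = np.quantile(medians, [alpha / 2.0, 1.0 - alpha / 2.0])
    med = float(np.median(diffs))
    return SddEstimate(
        median_diff_cm3=med,
        ci_lo_cm3=float(ci_lo),
        ci_hi_cm3=float(ci_hi),
        threshold_cm3=float(max(abs(ci_lo), abs(ci_hi))),
        method="bootstrap_percentile",
        n_lesions=int(diffs.size),
        n_resamples=int(n_resamples),
        seed=seed,
    )


def classify_change(
    delta_cm3: float, threshold_cm3: float = DEFAULT_THRESHOLD_CM3
) -> ChangeClass:
    """Classify a regional volume change against the SDD threshold.

    Strictly below −threshold is regression, strictly above +threshold
    is progression; the closed interval [−threshold, +threshold] is no
    change.
    """
    if not threshold_cm3 > 0:
        raise ValueError("threshold_cm3 must be > 0")
    if delta_cm3 < -threshold_cm3:
        return ChangeClass.REGRESSION
    if delta_cm3 > threshold_cm3:
        return ChangeClass.PROGRESSION
    return ChangeClass.NO_CHANGE


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def whole_percent(count: int, total: int) -> int:
    """Whole-number percentage, rounded half away from zero."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return _round_half_away(100.0 * count / total)


def summarize_classifications(
    classes: Iterable[ChangeClass],
) -> Mapping[ChangeClass, tuple[int, int]]:
    """Counts and whole-number percentages per change class.

    Percentages are rounded half away from zero; counts always sum to
    the number of inputs.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("cannot summarize an empty classification list")
    total = len(classes)
    out: dict[ChangeClass, tuple[int, int]] = {}
    for cls in ChangeClass:
        count = sum(1 for c in classes if c is cls)
        out[cls] = (count, _round_half_away(100.0 * count / total))
    return out


def select_study_knee(
    womac_left: float,
    womac_right: float,
    kl_left: int,
    kl_right: int,
    rng_seed: int | None = None,
) -> str:
    """Pick the study knee: greater WOMAC pain, then greater KL grade,
    then a seeded random draw on a full tie."""
    if womac_left < 0 or womac_right < 0:
        raise ValueError("WOMAC pain scores must be >= 0")
    for kl in (kl_left, kl_right):
        if kl not in (0, 1, 2, 3, 4):
            raise ValueError("KL grades must be integers in 0..4")
    if womac_left != womac_right:
        return "left" if womac_left > womac_right else "right"
    if kl_left != kl_right:
        return "left" if kl_left > kl_right else "right"
    rng = np.random.default_rng(rng_seed)
    return "left" if rng.random() < 0.5 else "right"
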