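"""Synthetic inputs with known ground truth.

Clinical-trial knee MRI underlying this kind of analysis is not
publicly deposited, so every downstream module is validated against
generated data whose true values are known by construction:

* **Cartilage phantoms** — binary mask stacks shaped like cartilage
  plates: straight bands of known pixel thickness, or rasterized
  annulus sectors (curved plates) of known mid-thickness radius, with
  optional full-thickness gaps of known length. The ground-truth record
  carries the true thickness (mm), the true per-slice gap lengths (mm;
  arc length at the mid-thickness radius for sectors), and the exact
  foreground volume (mm³).
* **Test–retest BML measurement sets** — paired (baseline, follow-up)
  approximate-volume readings per lesion, each reading being the true
  volume plus independent additive Gaussian error, emulating a
  reliability study in which the same lesions are measured twice.
* **Bivariate cohorts** — tables of per-knee BML volume and
  full-thickness lesion-area percentage with a target Spearman rank
  correlation, built from a Gaussian copula (Pearson correlation of the
  normal scores set to ``2 sin(pi * rho_s / 6)``) with log-normal and
  scaled-Beta marginals.

All generators are pure functions of their spec, seed included:
re-running with the same spec reproduces byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "make_phantom",
    "make_test_retest",
    "make_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a synthetic cartilage plate.

    For ``shape="band"``: an axis-aligned rectangle ``thickness_px``
    tall and ``length_px`` wide, with rectangular full-thickness gaps
    given as ``(start_col_px, gap_px)`` offsets along the band.
    For ``shape="annulus_sector"``: a ring of mid radius ``radius_px``
    and radial thickness ``thickness_px`` over ``angular_extent_deg``,
    with angular gaps given as ``(center_deg, gap_deg)``.
    """

    shape: str = "band"  # "band" | "annulus_sector"
    thickness_px: int = 8
    length_px: int = 60
    radius_px: float = 40.0
    angular_extent_deg: float = 120.0
    gaps: tuple[tuple[float, float], ...] = ()
    pixel_spacing_mm: float = 0.3
    n_slices: int = 3
    slice_spacing_mm: float = 1.3
    margin_px: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("band", "annulus_sector"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.thickness_px < 2:
            raise ValueError("thickness_px must be >= 2")
        if self.pixel_spacing_mm <= 0 or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.shape == "band":
            for start, width in self.gaps:
                if width <= 0 or start < 0 or start + width > self.length_px:
                    raise ValueError(f"gap ({start}, {width}) outside the band")
        else:
            half = self.angular_extent_deg / 2.0
            for center, width in self.gaps:
                if width <= 0 or abs(center) + width / 2.0 > half:
                    raise ValueError(f"gap ({center}, {width}) outside the sector")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth of a generated phantom, in physical units."""

    thickness_mm: float
    gap_lengths_mm: tuple[float, ...]  # per gap, identical on every slice
    volume_mm3: float
    n_foreground_px_per_slice: int


def _band_slice(spec: PhantomSpec) -> np.ndarray:
    m, t, length = spec.margin_px, spec.thickness_px, spec.length_px
    rows = t + 2 * m
    cols = length + 2 * m
    grid = np.zeros((rows, cols), dtype=bool)
    grid[m : m + t, m : m + length] = True
    for start, width in spec.gaps:
        c0 = m + int(round(start))
        c1 = m + int(round(start + width))
        grid[:, c0:c1] = False
    return grid


def _annulus_slice(spec: PhantomSpec) -> np.ndarray:
    r_mid = spec.radius_px
    t = spec.thickness_px
    r_in, r_out = r_mid - t / 2.0, r_mid + t / 2.0
    half = math.radians(spec.angular_extent_deg) / 2.0
    size = int(math.ceil(2 * (r_out + spec.margin_px)))
    center = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - center
    dx = xx - center
    rr = np.hypot(dx, dy)
    # angle measured from the +x axis; sector symmetric about it
    theta = np.arctan2(dy, dx)
    inside = (rr >= r_in) & (rr <= r_out) & (np.abs(theta) <= half)
    for center_deg, width_deg in spec.gaps:
        t0 = math.radians(center_deg - width_deg / 2.0)
        t1 = math.radians(center_deg + width_deg / 2.0)
        inside &= ~((theta >= t0) & (theta <= t1))
    return inside


def make_phantom(spec: PhantomSpec) -> tuple[np.ndarray, PhantomTruth]:
    """Rasterize a phantom spec into a (slices, rows, cols) bool stack.

    A pixel is foreground iff its centre lies inside the continuous
    shape. The same slice is replicated ``n_slices`` times, so the
    phantom is a prism of the 2D shape.
    """
    if spec.shape == "band":
        grid = _band_slice(spec)
        gap_lengths = tuple(w * spec.pixel_spacing_mm for _, w in spec.gaps)
    else:
        grid = _annulus_slice(spec)
        gap_lengths = tuple(
            math.radians(w) * spec.radius_px * spec.pixel_spacing_mm
            for _, w in spec.gaps
        )
    stack = np.repeat(grid[None, :, :], spec.n_slices, axis=0)
    s = spec.pixel_spacing_mm
    truth = PhantomTruth(
        thickness_mm=spec.thickness_px * s,
        gap_lengths_mm=gap_lengths,
        volume_mm3=float(stack.sum()) * s * s * spec.slice_spacing_mm,
        n_foreground_px_per_slice=int(grid.sum()),
    )
    return stack, truth


def make_test_retest(
    n_lesions: int = 16,
    true_change_mean: float = 0.0,
    true_change_sd: float = 5.0,
    error_sd: float = 3.0,
    baseline_median_cm3: float = 4.0,
    baseline_sigma: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a test–retest reliability set of approximate BML volumes.

    Each lesion has a log-normal true baseline volume and a Gaussian
    true change; the four readings (baseline and follow-up, measured
    twice) are truth plus independent ``Normal(0, error_sd)`` noise, so
    the difference of changes has standard deviation ``2 * error_sd``.
    Defaults mirror a 16-lesion reliability set with a
    difference-of-changes SD of about 6 cm³.
    """
    if n_lesions < 6:
        raise ValueError("need at least 6 lesions for a usable reliability set")
    rng = np.random.default_rng(seed)
    base_true = baseline_median_cm3 * np.exp(
        rng.normal(0.0, baseline_sigma, n_lesions)
    )
    change_true = rng.normal(true_change_mean, true_change_sd, n_lesions)
    noise = rng.normal(0.0, error_sd, (4, n_lesions)) if error_sd > 0 else np.zeros(
        (4, n_lesions)
    )
    return pd.DataFrame(
        {
            "lesion_id": [f"L{i:03d}" for i in range(n_lesions)],
            "baseline_1": base_true + noise[0],
            "followup_1": base_true + change_true + noise[1],
            "baseline_2": base_true + noise[2],
            "followup_2": base_true + change_true + noise[3],
            "true_change_cm3": change_true,
        }
    )


@dataclass(frozen=True)
class CohortSpec:
    """A bivariate cohort with a target Spearman rank correlation.

    Marginals emulate the scale of an OA knee cohort: regional BML
    volume log-normal (median ``bml_median_cm3``, log-SD
    ``bml_sigma``), full-thickness lesion area as a Beta distribution
    scaled to 0–100% with the given mean and SD. ``measurement_error_sd``
    adds optional Gaussian noise to the BML volumes after the copula,
    attenuating the realized correlation the way re-measurement would.
    """

    n_knees: int = 44
    target_rho: float = 0.63
    bml_median_cm3: float = 8.8
    bml_sigma: float = 1.2
    lesion_pct_mean: float = 24.8
    lesion_pct_sd: float = 17.8
    measurement_error_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_rho <= 1.0:
            raise ValueError("target_rho must lie in [-1, 1]")
        if self.n_knees < 4:
            raise ValueError("n_knees must be >= 4")
        m, sd = self.lesion_pct_mean / 100.0, self.lesion_pct_sd / 100.0
        if not 0 < m < 1 or sd * sd >= m * (1 - m):
            raise ValueError("infeasible lesion-percentage mean/SD for a Beta")


def _beta_params(mean01: float, sd01: float) -> tuple[float, float]:
    nu = mean01 * (1 - mean01) / (sd01 * sd01) - 1.0
    return mean01 * nu, (1 - mean01) * nu


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table via a Gaussian copula at the target Spearman rho.

    The Pearson correlation of the latent normals is
    ``2 sin(pi * rho_s / 6)``, the exact normal-scores relation, so the
    population Spearman correlation equals ``target_rho``; marginals
    are applied by inverse-CDF and leave ranks untouched.
    """
    rng = np.random.default_rng(spec.seed)
    rho_p = 2.0 * math.sin(math.pi * spec.target_rho / 6.0)
    cov = np.array([[1.0, rho_p], [rho_p, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=spec.n_knees)
    u = sps.norm.cdf(z)
    bml = spec.bml_median_cm3 * np.exp(
        sps.norm.ppf(u[:, 0]) * spec.bml_sigma
    )
    a, b = _beta_params(spec.lesion_pct_mean / 100.0, spec.lesion_pct_sd / 100.0)
    lesion_pct = 100.0 * sps.beta.ppf(u[:, 1], a, b)
    if spec.measurement_error_sd > 0:
        bml = np.maximum(
            bml + rng.normal(0.0, spec.measurement_error_sd, spec.n_knees), 0.0
        )
    bml_change = rng.normal(0.5, 5.0, spec.n_knees)
    lesion_pct_change = rng.normal(2.0, 4.0, spec.n_knees)
    return pd.DataFrame(
        {
            "knee_id": [f"K{i:03d}" for i in range(spec.n_knees)],
            "region": "index_tibia",
            "baseline_bml_cm3": bml,
            "baseline_lesion_pct": lesion_pct,
            "bml_change_cm3": bml_change,
            "lesion_pct_change": lesion_pct_change,
        }
    )
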