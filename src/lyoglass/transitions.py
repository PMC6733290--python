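"""Three-region glass-transition analysis of alpha(1 THz) versus temperature.

Amorphous molecular solids probed by THz-TDS show three linear temperature
regimes in the absorption coefficient at 1 THz.  The lower transition,
Tg,beta, marks the onset of local (Johari-Goldstein beta-relaxation)
mobility and is defined as the intersection of the two low-temperature
best-fit lines; the upper transition, Tg,alpha, marks the onset of
large-scale cooperative (alpha-relaxation) mobility and is the intersection
of the two high-temperature lines.  Above Tg,alpha the slope either keeps
increasing (unconfined mobility, the usual small-molecule behaviour) or
drops and stays flat — the signature of the protein being confined in its
excipient matrix.

The segmentation is an exhaustive least-squares search over ordered
breakpoint pairs: every admissible split into three contiguous regions of at
least ``min_pts`` points is scored by the total (optionally 1/SD^2-weighted)
ordinary-least-squares error and the minimiser is kept.  Lines are fitted
independently per region — no continuity constraint — so the transition
temperatures come from line intersections, not from breakpoint grid
positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .config import TransitionSettings

__all__ = [
    "TemperatureSeries",
    "LinearFit",
    "PiecewiseFitResult",
    "HysteresisReport",
    "NoIntersectionError",
    "fit_three_regions",
    "intersect",
    "classify_mobility",
    "compare_cycles",
    "tabulate",
    "result_from_slopes",
]

MobilityClass = Literal["confined", "unconfined"]


class NoIntersectionError(ValueError):
    """Raised when two fitted lines are too close to parallel to intersect."""

    def __init__(self, slope_difference: float):
        self.slope_difference = slope_difference
        super().__init__(
            f"lines are near-parallel (slope difference {slope_difference:g})"
        )


# ---------------------------------------------------------------- containers

@dataclass
class TemperatureSeries:
    """alpha(1 THz) against temperature for one formulation.

    ``sd_cm`` holds the per-point standard error of the mean over replicate
    measurements (used as weights); it may be omitted for single sweeps.
    """

    temperature_k: np.ndarray
    absorption_cm: np.ndarray
    sd_cm: np.ndarray | None = None
    n_replicates: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature_k = np.asarray(self.temperature_k, dtype=float)
        self.absorption_cm = np.asarray(self.absorption_cm, dtype=float)
        if self.temperature_k.size != self.absorption_cm.size:
            raise ValueError("temperature and absorption must match in length")
        if np.any(np.diff(self.temperature_k) <= 0):
            raise ValueError("temperatures must be strictly increasing/unique")
        if self.sd_cm is not None:
            self.sd_cm = np.asarray(self.sd_cm, dtype=float)
            if self.sd_cm.size != self.temperature_k.size:
                raise ValueError("sd must match series length")

    def __len__(self) -> int:
        return self.temperature_k.size


@dataclass
class LinearFit:
    """One region's line y = m*x + c with standard errors."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    sse: float
    n_points: int


@dataclass
class PiecewiseFitResult:
    """Fitted three-region model with derived transition temperatures."""

    regions: tuple[LinearFit, LinearFit, LinearFit]
    break_indices: tuple[int, int]
    tg_beta_k: float
    tg_alpha_k: float
    sse: float
    mobility_class: MobilityClass
    weighted: bool = False
    label: str = ""

    @property
    def slopes(self) -> tuple[float, float, float]:
        return tuple(r.slope for r in self.regions)  # type: ignore[return-value]

    @property
    def slope_ses(self) -> tuple[float, float, float]:
        return tuple(r.slope_se for r in self.regions)  # type: ignore[return-value]

    @property
    def region_counts(self) -> tuple[int, int, int]:
        return tuple(r.n_points for r in self.regions)  # type: ignore[return-value]


def result_from_slopes(
    slopes: tuple[float, float, float],
    slope_ses: tuple[float, float, float] = (0.0, 0.0, 0.0),
    tg_beta_k: float = float("nan"),
    tg_alpha_k: float = float("nan"),
    label: str = "",
    settings: TransitionSettings | None = None,
) -> PiecewiseFitResult:
    """Build a result from externally tabulated slopes and standard errors.

    Lets published fit parameters (slope +/- SE tables) be classified with
    the same machinery as in-package fits.  Intercepts are synthesised so
    the three lines intersect at the stated transition temperatures.
    """
    m1, m2, m3 = slopes
    c1 = 0.0
    c2 = c1 + (m1 - m2) * tg_beta_k if np.isfinite(tg_beta_k) else 0.0
    c3 = c2 + (m2 - m3) * tg_alpha_k if np.isfinite(tg_alpha_k) else 0.0
    regions = tuple(
        LinearFit(m, c, se, 0.0, 0.0, 0)
        for m, c, se in zip(slopes, (c1, c2, c3), slope_ses)
    )
    result = PiecewiseFitResult(
        regions=regions,  # type: ignore[arg-type]
        break_indices=(0, 0),
        tg_beta_k=tg_beta_k,
        tg_alpha_k=tg_alpha_k,
        sse=0.0,
        mobility_class="unconfined",
        label=label,
    )
    result.mobility_class = classify_mobility(result, settings=settings)
    return result


# ------------------------------------------------------------- segmentation

def _segment_stats(prefix: np.ndarray, a: int, b: int) -> np.ndarray:
    return prefix[b] - prefix[a]


def _ols_from_sums(s: np.ndarray) -> tuple[float, float, float, float]:
    """(slope, intercept, sse, det) from weighted sums (w, wx, wy, wxx, wxy, wyy)."""
    s0, sx, sy, sxx, sxy, syy = s
    det = s0 * sxx - sx * sx
    if det <= 0:
        raise ZeroDivisionError("degenerate segment (no temperature spread)")
    slope = (s0 * sxy - sx * sy) / det
    intercept = (sy - slope * sx) / s0
    sse = syy - intercept * sy - slope * sxy
    return slope, intercept, max(sse, 0.0), det


def _fit_segment(
    sums: np.ndarray, weighted: bool, n_pts: int
) -> LinearFit:
    slope, intercept, sse, det = _ols_from_sums(sums)
    s0, _, _, sxx = sums[0], sums[1], sums[2], sums[3]
    if weighted:
        # covariance (X' W X)^-1 with known per-point variances
        var_slope = s0 / det
        var_intercept = sxx / det
    else:
        dof = max(n_pts - 2, 1)
        s2 = sse / dof
        var_slope = s2 * s0 / det
        var_intercept = s2 * sxx / det
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(np.sqrt(max(var_slope, 0.0))),
        intercept_se=float(np.sqrt(max(var_intercept, 0.0))),
        sse=float(sse),
        n_points=n_pts,
    )


def fit_three_regions(
    series: TemperatureSeries,
    min_pts: int = 3,
    settings: TransitionSettings | None = None,
) -> PiecewiseFitResult:
    """Exhaustive three-segment weighted-OLS fit of a temperature series.

    Every ordered breakpoint-index pair ``(i, j)`` (regions ``[0:i)``,
    ``[i:j)``, ``[j:n)``, each with at least ``min_pts`` points) is scored
    by total SSE; ties within numerical tolerance are broken toward the most
    balanced segmentation.  Weighted by 1/SD^2 when replicate SDs are
    available, plain OLS otherwise.
    """
    settings = settings or TransitionSettings()
    x = series.temperature_k
    y = series.absorption_cm
    n = x.size
    if n < 3 * min_pts:
        raise ValueError(f"need at least {3 * min_pts} points, got {n}")
    weighted = bool(series.sd_cm is not None and np.all(series.sd_cm > 0))
    w = 1.0 / series.sd_cm**2 if weighted else np.ones(n)

    cols = np.stack([w, w * x, w * y, w * x * x, w * x * y, w * y * y], axis=1)
    prefix = np.vstack([np.zeros(6), np.cumsum(cols, axis=0)])

    best: tuple[float, float, int, int] | None = None
    candidates: list[tuple[float, float, int, int]] = []
    for i in range(min_pts, n - 2 * min_pts + 1):
        s1 = _segment_stats(prefix, 0, i)
        _, _, sse1, _ = _ols_from_sums(s1)
        for j in range(i + min_pts, n - min_pts + 1):
            _, _, sse2, _ = _ols_from_sums(_segment_stats(prefix, i, j))
            _, _, sse3, _ = _ols_from_sums(_segment_stats(prefix, j, n))
            sse = sse1 + sse2 + sse3
            counts = (i, j - i, n - j)
            balance = float(np.var(counts))
            candidates.append((sse, balance, i, j))
            if best is None or sse < best[0]:
                best = (sse, balance, i, j)
    assert best is not None
    # tie tolerance: absolute floor scaled to the data's magnitude (sum of
    # weighted y^2) so that numerically-zero SSEs on noiseless data tie
    tol = 1e-12 * (1.0 + float(prefix[-1, 5])) + 1e-9 * abs(best[0])
    tied = [c for c in candidates if c[0] <= best[0] + tol]
    _, _, i, j = min(tied, key=lambda c: (c[1], c[2], c[3]))

    bounds = [(0, i), (i, j), (j, n)]
    regions = tuple(
        _fit_segment(_segment_stats(prefix, a, b), weighted, b - a)
        for a, b in bounds
    )
    # a degenerate (single-line) series has parallel region fits and hence
    # no defined transition; report NaN rather than failing the whole fit
    try:
        tg_beta = intersect(regions[0], regions[1], settings.parallel_rtol)
    except NoIntersectionError:
        tg_beta = float("nan")
    try:
        tg_alpha = intersect(regions[1], regions[2], settings.parallel_rtol)
    except NoIntersectionError:
        tg_alpha = float("nan")
    result = PiecewiseFitResult(
        regions=regions,  # type: ignore[arg-type]
        break_indices=(i, j),
        tg_beta_k=tg_beta,
        tg_alpha_k=tg_alpha,
        sse=float(sum(r.sse for r in regions)),
        mobility_class="unconfined",
        weighted=weighted,
        label=series.label,
    )
    result.mobility_class = classify_mobility(result, settings=settings)
    return result


def intersect(
    a: LinearFit, b: LinearFit, rtol: float = 1e-6, atol: float = 1e-8
) -> float:
    """Temperature where two fitted lines cross: (c_b - c_a)/(m_a - m_b)."""
    dm = a.slope - b.slope
    tol = max(atol, rtol * max(abs(a.slope), abs(b.slope)))
    if abs(dm) <= tol:
        raise NoIntersectionError(dm)
    return float((b.intercept - a.intercept) / dm)


def classify_mobility(
    result: PiecewiseFitResult,
    ratio_threshold: float = 1.0,
    settings: TransitionSettings | None = None,
) -> MobilityClass:
    """Confinement call from the region-2 vs region-3 slopes.

    Confined requires a strict slope decrease (``m3 < ratio_threshold*m2``)
    with statistical support: the decrease must exceed ``confinement_z``
    combined standard errors.  Region-3 slopes are frequently poorly
    determined, so the default threshold is deliberately conservative to
    avoid calling confinement on noise.
    """
    settings = settings or TransitionSettings()
    m2, m3 = result.regions[1].slope, result.regions[2].slope
    se = float(np.hypot(result.regions[1].slope_se, result.regions[2].slope_se))
    ratio = ratio_threshold if ratio_threshold is not None else settings.confinement_ratio
    if m3 < ratio * m2 and (m2 - m3) > settings.confinement_z * se:
        return "confined"
    return "unconfined"


@dataclass
class HysteresisReport:
    """Comparison of two heating cycles of the same sample."""

    cycle1: PiecewiseFitResult
    cycle2: PiecewiseFitResult
    delta_m3: float
    delta_m3_se: float
    hysteresis: bool


def compare_cycles(
    cycle1: TemperatureSeries,
    cycle2: TemperatureSeries,
    min_pts: int = 3,
    settings: TransitionSettings | None = None,
) -> HysteresisReport:
    """Fit both cycles independently and flag high-temperature hysteresis.

    Hysteresis is reported when the mobility classes differ or the region-3
    slope change exceeds ``hysteresis_z`` combined standard errors — the
    signature of a sample escaping its confined state on reheating.
    """
    settings = settings or TransitionSettings()
    r1 = fit_three_regions(cycle1, min_pts, settings)
    r2 = fit_three_regions(cycle2, min_pts, settings)
    delta = r2.regions[2].slope - r1.regions[2].slope
    se = float(np.hypot(r1.regions[2].slope_se, r2.regions[2].slope_se))
    hysteresis = (r1.mobility_class != r2.mobility_class) or (
        abs(delta) > settings.hysteresis_z * se
    )
    return HysteresisReport(r1, r2, float(delta), se, hysteresis)


def tabulate(results: list[PiecewiseFitResult]) -> pd.DataFrame:
    """Machine-readable summary table, one row per formulation."""
    if not results:
        raise ValueError("need at least one result")
    rows = []
    for k, r in enumerate(results):
        label = r.label or f"series_{k}"
        rows.append(
            {
                "label": label,
                "m1": r.regions[0].slope,
                "m1_se": r.regions[0].slope_se,
                "m2": r.regions[1].slope,
                "m2_se": r.regions[1].slope_se,
                "m3": r.regions[2].slope,
                "m3_se": r.regions[2].slope_se,
                "tg_beta_k": r.tg_beta_k,
                "tg_alpha_k": r.tg_alpha_k,
                "mobility_class": r.mobility_class,
            }
        )
    return pd.DataFrame(rows)
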