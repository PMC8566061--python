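"""Per-fixation spatial precision metrics and cohort summaries.

The classic precision estimate is the sample SD of the 500 position samples
of a fixation (per axis).  When the position distribution is multimodal the
SD mixes within-mode spread with between-mode separation and loses its
usual interpretation; the mixture-aware alternative (MaxCompSD) is the SD
of the maximum-weight component of the fitted normal mixture.  For
comparison the module also provides RMS-S2S (root-mean-square
sample-to-sample difference), the median/mean absolute deviation, the
bivariate contour ellipse area (BCEA), and the empirical +/-n SD coverage
that motivates the whole exercise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .multimodality import EVIDENCE_CATEGORIES, MixtureFit

__all__ = [
    "PrecisionResult",
    "CohortSummary",
    "classic_precision",
    "max_comp_sd",
    "rms_s2s",
    "mad_precision",
    "bcea",
    "sd_coverage",
    "normal_coverage",
    "summarize_cohort",
]


@dataclass
class PrecisionResult:
    """Precision metrics for one fixation and one axis (degrees)."""

    axis: str
    classic_precision: float
    max_comp_sd: float
    rms_s2s: float
    mad: float
    n_samples: int
    subject_id: str = ""
    session_id: str = ""
    trial_index: int = -1


@dataclass
class CohortSummary:
    """Cohort-level roll-up mirroring the per-direction results table.

    ``category_pct`` maps axis -> {category: percent}; percentages per axis
    sum to 100.  ``component_counts`` maps axis -> {K: frequency}.
    """

    n_events: dict[str, int]
    category_pct: dict[str, dict[str, float]]
    component_counts: dict[str, dict[int, int]]
    median_classic: dict[str, float]
    median_max_comp_sd: dict[str, float]
    median_ratio: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for axis in sorted(self.n_events):
            row = {"direction": axis, "n_events": self.n_events[axis]}
            for cat in EVIDENCE_CATEGORIES:
                row[f"pct_{cat}"] = self.category_pct[axis].get(cat, 0.0)
            row["median_classic_precision"] = self.median_classic[axis]
            row["median_max_comp_sd"] = self.median_max_comp_sd[axis]
            row["median_ratio_maxcomp_to_classic"] = self.median_ratio[axis]
            rows.append(row)
        return pd.DataFrame(rows)


def _values(values) -> np.ndarray:
    return np.asarray(getattr(values, "values", values), dtype=float).ravel()


def classic_precision(values) -> float:
    """Sample standard deviation (n-1 denominator) of the position samples."""
    y = _values(values)
    if len(y) < 2:
        raise ValueError("classic precision needs at least 2 samples")
    return float(np.std(y, ddof=1))


def max_comp_sd(fit: MixtureFit) -> float:
    """SD of the maximum-weight mixture component.

    Weight ties are broken toward the smaller SD (the conservative choice).
    """
    if not fit.components:
        raise ValueError("fit has no components")
    best = max(fit.components, key=lambda c: (c[2], -c[1]))
    return float(best[1])


def rms_s2s(values) -> float:
    """Root-mean-square of successive sample-to-sample differences."""
    y = _values(values)
    if len(y) < 2:
        raise ValueError("RMS-S2S needs at least 2 samples")
    return float(np.sqrt(np.mean(np.diff(y) ** 2)))


def mad_precision(values, flavor: str = "median_abs_dev") -> float:
    """Median (or mean) absolute deviation from the median (or mean).

    No normal-consistency scaling is applied: the statistic is reported in
    its raw, directly interpretable form.
    """
    y = _values(values)
    if len(y) < 1:
        raise ValueError("need at least 1 sample")
    if flavor == "median_abs_dev":
        return float(np.median(np.abs(y - np.median(y))))
    if flavor == "mean_abs_dev":
        return float(np.mean(np.abs(y - np.mean(y))))
    raise ValueError(f"unknown flavor {flavor!r}")


def bcea(x_values, y_values, p: float = 0.68) -> float:
    """Bivariate contour ellipse area, deg^2.

    BCEA = 2 k pi sigma_x sigma_y sqrt(1 - rho^2) with k = -ln(1 - p); the
    area of the ellipse expected to contain a fraction ``p`` of the samples
    under a bivariate normal model.  Provided for comparison only: the
    statistic assumes the joint distribution is unimodal and Gaussian,
    which the multimodality analysis shows is frequently false.
    """
    x, y = _values(x_values), _values(y_values)
    if len(x) != len(y):
        raise ValueError("x and y must be paired")
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    if sx == 0.0 or sy == 0.0:
        warnings.warn("degenerate variance; BCEA is 0", stacklevel=2)
        return 0.0
    rho = float(np.corrcoef(x, y)[0, 1])
    k = -math.log1p(-p)
    return float(2.0 * k * math.pi * sx * sy * math.sqrt(max(0.0, 1.0 - rho**2)))


def sd_coverage(values, n_sd: float = 1.0) -> float:
    """Fraction of samples within mean +/- n_sd * SD.

    For a normal distribution this approaches :func:`normal_coverage`; for
    a well-separated multimodal distribution it falls well below it, which
    is what makes the SD hard to interpret there.  Zero-SD input covers
    everything by convention.
    """
    y = _values(values)
    if len(y) < 2:
        raise ValueError("coverage needs at least 2 samples")
    mu, sd = np.mean(y), np.std(y, ddof=1)
    if sd == 0.0:
        return 1.0
    return float(np.mean(np.abs(y - mu) <= n_sd * sd))


def normal_coverage(n_sd: float) -> float:
    """Analytic +/- n_sd coverage of a normal distribution, 2 Phi(n_sd) - 1."""
    return float(norm.cdf(n_sd) - norm.cdf(-n_sd))


def compute_precision_result(sample_set, fit: MixtureFit) -> PrecisionResult:
    """Bundle all per-fixation metrics for one axis of one fixation."""
    y = _values(sample_set)
    return PrecisionResult(
        axis=getattr(sample_set, "axis", fit.axis),
        classic_precision=classic_precision(y),
        max_comp_sd=max_comp_sd(fit),
        rms_s2s=rms_s2s(y),
        mad=mad_precision(y),
        n_samples=len(y),
        subject_id=getattr(sample_set, "subject_id", ""),
        session_id=getattr(sample_set, "session_id", ""),
        trial_index=getattr(sample_set, "trial_index", -1),
    )


def summarize_cohort(
    fits: list[MixtureFit], results: list[PrecisionResult]
) -> CohortSummary:
    """Per-axis evidence-category percentages, component-count frequencies
    and metric medians over a cohort of fixations."""
    if not fits:
        raise ValueError("cohort is empty")
    axes = sorted({f.axis or "horizontal" for f in fits})
    n_events, category_pct, component_counts = {}, {}, {}
    median_classic, median_mcs, median_ratio = {}, {}, {}
    for axis in axes:
        af = [f for f in fits if (f.axis or "horizontal") == axis]
        ar = [r for r in results if r.axis == axis]
        n = len(af)
        n_events[axis] = n
        category_pct[axis] = {
            cat: 100.0 * sum(f.category == cat for f in af) / n
            for cat in EVIDENCE_CATEGORIES
        }
        counts: dict[int, int] = {}
        for f in af:
            counts[f.modal_k] = counts.get(f.modal_k, 0) + 1
        component_counts[axis] = dict(sorted(counts.items()))
        median_classic[axis] = float(np.median([r.classic_precision for r in ar])) if ar else math.nan
        median_mcs[axis] = float(np.median([r.max_comp_sd for r in ar])) if ar else math.nan
        ratios = [
            r.max_comp_sd / r.classic_precision for r in ar if r.classic_precision > 0
        ]
        median_ratio[axis] = float(np.median(ratios)) if ratios else math.nan
    return CohortSummary(
        n_events=n_events,
        category_pct=category_pct,
        component_counts=component_counts,
        median_classic=median_classic,
        median_max_comp_sd=median_mcs,
        median_ratio=median_ratio,
    )
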