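"""Prediction and summary surfaces for calibrated fire-rate estimates.

Applies a calibration model to new sites, summarizes historical PMFI/FR
collections overall and by group, bins rates into fixed-width histograms
with exceedance percentages, proxies old-forest status from the beginning
analysis year, and evaluates the low-severity fire-regime classifier with
its area-weighted landscape percentage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationModel

__all__ = [
    "PredictedSite",
    "GroupSummary",
    "HistogramResult",
    "DRY_FOREST_LANDSCAPES",
    "predict_pmfi_fr",
    "summarize",
    "compare_groups",
    "histogram",
    "exceedance_percent",
    "old_forest_proxy",
    "low_severity_classifier",
    "area_weighted_percentage",
]

logger = logging.getLogger(__name__)

#: Published GLO-survey and early aerial-photo reconstructions of eleven
#: western-USA dry-forest landscapes: (location, total area in ha, area
#: fitting the low-severity fire model in ha).
DRY_FOREST_LANDSCAPES: tuple[tuple[str, float, float], ...] = (
    ("Mogollon Plateau, AZ", 405_214, 252_854),
    ("Black Mesa, AZ", 151_080, 18_130),
    ("Front Range, CO", 65_525, 1_638),
    ("Blue Mountains, OR", 304_709, 122_798),
    ("North-E Cascades, OR", 146_555, 47_630),
    ("Central-E Cascades, OR", 147_502, 15_340),
    ("South-E Cascades, OR", 104_160, 30_623),
    ("Coconino Plateau, AZ", 41_214, 24_234),
    ("N. Sierra, CA", 115_766, 14_587),
    ("S. Sierra, CA", 187_085, 49_390),
    ("E. WA & E. OR", 112_115, 24_200),
)


@dataclass
class PredictedSite:
    """One site's calibrated or predicted PMFI/FR."""

    site_id: str
    weibull_mean_itfi: float | None
    pmfi_fr: float
    source: str = "predicted"  # or "calibration_case"
    state_code: str | None = None
    forest_type: str = "unknown"
    beginning_year: int | None = None

    def __post_init__(self) -> None:
        if self.pmfi_fr <= 0:
            raise ValueError("pmfi_fr must be positive")


@dataclass(frozen=True)
class GroupSummary:
    """Distributional summary of PMFI/FR for one group of sites (years)."""

    n: int
    mean: float
    ci95_mean: tuple[float, float] | None
    sd: float | None
    cv_percent: float | None
    min: float
    q1: float
    median: float
    ci95_median: tuple[float, float] | None
    q3: float
    max: float


def predict_pmfi_fr(
    suite_value: float,
    model: CalibrationModel,
    covariate_values: dict[str, float] | None = None,
) -> float:
    """PMFI/FR (years) predicted from an estimator value by a fitted model."""
    return model.predict(suite_value, covariate_values)


def _median_ci(sorted_vals: np.ndarray, level: float = 0.95) -> tuple[float, float] | None:
    """Distribution-free (order-statistic) confidence interval for the median.

    Ranks come from the binomial(n, 1/2) distribution; endpoints are
    interpolated between adjacent order statistics to approach the nominal
    level rather than rounding outward to the conservative integer ranks.
    """
    n = sorted_vals.size
    if n < 6:
        return None
    a = (1.0 - level) / 2.0
    lo_rank = stats.binom.ppf(a, n, 0.5)          # number of values below lo
    hi_rank = stats.binom.isf(a, n, 0.5)
    lo_f = max(lo_rank - 1, 0)
    hi_f = min(hi_rank, n - 1)

    def _interp(r: float) -> float:
        i = int(math.floor(r))
        frac = r - i
        if i >= n - 1:
            return float(sorted_vals[-1])
        return float(sorted_vals[i] * (1 - frac) + sorted_vals[i + 1] * frac)

    return (_interp(lo_f), _interp(hi_f))


def _summary_from_values(values: np.ndarray) -> GroupSummary:
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    mean = float(values.mean())
    if n >= 2:
        sd = float(values.std(ddof=1))
        cv = 100.0 * sd / mean if mean != 0 else None
        half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
        ci_mean = (mean - half, mean + half)
    else:
        sd = cv = ci_mean = None
    q1, med, q3 = (float(q) for q in np.percentile(values, [25, 50, 75]))
    return GroupSummary(
        n=n, mean=mean, ci95_mean=ci_mean, sd=sd, cv_percent=cv,
        min=float(values[0]), q1=q1, median=med,
        ci95_median=_median_ci(values), q3=q3, max=float(values[-1]),
    )


def summarize(
    sites: pd.DataFrame | list,
    group_by: str = "overall",
    value_col: str = "pmfi_fr",
) -> dict[str, GroupSummary]:
    """Group summaries of PMFI/FR across a site collection.

    ``sites`` is a DataFrame (or list of :class:`PredictedSite`) and
    ``group_by`` one of ``overall``, ``forest_type``, ``state``.  Empty
    groups are omitted with a log entry.
    """
    if not isinstance(sites, pd.DataFrame):
        sites = pd.DataFrame(
            {
                value_col: [s.pmfi_fr for s in sites],
                "forest_type": [s.forest_type for s in sites],
                "state": [s.state_code for s in sites],
            }
        )
    col = {"overall": None, "forest_type": "forest_type", "state": "state"}.get(
        group_by, group_by if group_by in sites.columns else None
    )
    if group_by != "overall" and col is None:
        raise ValueError(f"unknown grouping {group_by!r}")

    out: dict[str, GroupSummary] = {}
    if group_by == "overall":
        vals = sites[value_col].dropna().to_numpy()
        if vals.size:
            out["overall"] = _summary_from_values(vals)
        return out
    for key, sub in sites.groupby(col, dropna=True):
        vals = sub[value_col].dropna().to_numpy()
        if vals.size == 0:
            logger.info("group %r has no usable values; omitted", key)
            continue
        out[str(key)] = _summary_from_values(vals)
    return out


def compare_groups(values_a, values_b):
    """Welch two-sample t-test between two groups of PMFI/FR values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass(frozen=True)
class HistogramResult:
    """Fixed-width bins from zero, half-open at the top, with the percent
    of the distribution exceeding each bin's lower limit."""

    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    exceedance_pct: tuple[float, ...]


def exceedance_percent(values, threshold: float) -> float:
    """Percent of values strictly exceeding ``threshold``."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values")
    return float(100.0 * np.mean(values > threshold))


def histogram(values, bin_width: float = 15.0) -> HistogramResult:
    """Histogram of PMFI/FR values in fixed-width bins anchored at zero."""
    values = np.asarray(values, dtype=float)
    if values.size == 0 or np.any(values <= 0):
        raise ValueError("values must be positive and non-empty")
    top = bin_width * math.ceil(values.max() / bin_width + 1e-9)
    edges = np.arange(0.0, top + bin_width / 2, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    lowers = edges[:-1]
    exceed = tuple(exceedance_percent(values, lo) for lo in lowers)
    return HistogramResult(
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        exceedance_pct=exceed,
    )


def old_forest_proxy(beginning_year: int) -> str:
    """Old-forest age class proxied by a stand's beginning analysis year.

    Stands whose analysis begins before 1700 were generally >= 200 years
    old by 1900 (``"ge200"``), before 1750 generally >= 150 years old
    (``"ge150"``), otherwise ``"younger"``.
    """
    if beginning_year < 1700:
        return "ge200"
    if beginning_year < 1750:
        return "ge150"
    return "younger"


def low_severity_classifier(
    tree_density: float, pct_large: float, pct_small: float
) -> bool:
    """Calibrated structural classifier for a low-severity fire regime.

    Predicts a history of predominantly low-severity fire where historical
    tree density was < 178 trees/ha, the percentage of large trees was
    > 29.2%, and the percentage of small trees was < 46.9% (all strict).
    """
    if tree_density < 0 or not (0 <= pct_large <= 100) or not (0 <= pct_small <= 100):
        raise ValueError("density must be non-negative and percentages in [0, 100]")
    return tree_density < 178.0 and pct_large > 29.2 and pct_small < 46.9


def area_weighted_percentage(landscapes) -> float:
    """Area-weighted percent of landscape area fitting the low-severity model.

    ``landscapes`` is an iterable of ``(total_ha, fitting_ha)`` pairs;
    the result is ``100 * sum(fitting) / sum(total)``.
    """
    total = fitting = 0.0
    for t, f in landscapes:
        if f > t:
            raise ValueError(f"fitting area {f} exceeds total area {t}")
        total += t
        fitting += f
    if total <= 0:
        raise ValueError("zero total landscape area")
    return 100.0 * fitting / total
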