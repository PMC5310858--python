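"""Composite and individual-tree fire-interval estimators.

Fire-scar records underestimate fire occurrence at a point because the
scarring fraction is below one; compositing scar records across trees pools
fire years so the composite fire interval (CFI) tends to shorten as more
trees are pooled, while the individual-tree fire interval (ITFI) averages
each tree's own inter-scar intervals.  This module builds the restricted
analysis period, the composite fire-year lists under the all-fires / 10% /
25%-scarred filters, the interval statistics (mean, median, and the
two-parameter Weibull scale, mean and median), and assembles them, with
sample-size covariates, into the per-site estimator suite used by the
calibration stage.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (
    FireHistorySite,
    InsufficientIntervalsError,
    NoUsableRecordError,
    ShortRecordError,
)

__all__ = [
    "AnalysisWindow",
    "CompositeFilter",
    "WeibullFit",
    "ITFIResult",
    "EstimatorSuite",
    "ESTIMATOR_NAMES",
    "restrict_analysis_period",
    "composite_fire_years",
    "intervals",
    "itfi",
    "fit_weibull",
    "estimator_suite",
]

_FAMILIES = ("cfi_all", "cfi_10", "cfi_25", "itfi")
_MEASURES = ("mean", "median", "weibull_scale", "weibull_mean", "weibull_median")

#: Canonical names of the 20 CFI/ITFI estimators (the 21st, FR from
#: recorders, comes from :mod:`firecal.area_burned`).
ESTIMATOR_NAMES = tuple(f"{m}_{f}" for f in _FAMILIES for m in _MEASURES)


@dataclass(frozen=True)
class AnalysisWindow:
    """Restriction rules for the analysis period.

    The analysis period runs from the earliest fire to the latest fire
    within ``[start_year, end_year]`` (scar-to-scar, so the record starts
    and ends on fires); when ``min_samples_accumulated`` > 0 the first
    qualifying fire is the earliest fire at or after the year in which that
    many series are simultaneously alive.  Sites whose restricted span is
    shorter than ``min_record_years`` are rejected.
    """

    start_year: int = 1600
    end_year: int = 1900
    min_record_years: int = 50
    min_samples_accumulated: int = 10

    def __post_init__(self) -> None:
        if self.end_year <= self.start_year:
            raise ValueError("end_year must exceed start_year")


@dataclass(frozen=True)
class CompositeFilter:
    """Composite fire-year filter.

    ``mode`` is one of ``all_fires`` (every year with >= 1 scar), ``pct10``
    or ``pct25`` (years where the fraction of scarred-sample series alive
    that year that were scarred meets the threshold).  ``rule`` selects the
    threshold comparison: ``">="`` (a fire on exactly 25% of scarred
    samples qualifies under pct25, the default) or ``">"`` (strict).
    """

    mode: str = "all_fires"
    rule: str = ">="
    denominator: str = "scarred_samples"

    _THRESHOLDS = {"all_fires": 0.0, "pct10": 0.10, "pct25": 0.25}

    def __post_init__(self) -> None:
        if self.mode not in self._THRESHOLDS:
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if self.rule not in (">=", ">"):
            raise ValueError(f"unknown threshold rule {self.rule!r}")
        if self.denominator != "scarred_samples":
            raise ValueError(f"unknown denominator {self.denominator!r}")

    @property
    def threshold(self) -> float:
        return self._THRESHOLDS[self.mode]


@dataclass(frozen=True)
class WeibullFit:
    """Two-parameter Weibull fit of a fire-interval distribution.

    ``scale`` is the 63rd percentile of the distribution; the fitted mean
    is ``scale * gamma(1 + 1/shape)`` and the fitted median is
    ``scale * ln(2)**(1/shape)``.  The shift parameter is fixed at zero.
    """

    shape: float
    scale: float
    shift: float = 0.0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.scale * math.gamma(1.0 + 1.0 / self.shape)

    @property
    def median(self) -> float:
        return self.scale * math.log(2.0) ** (1.0 / self.shape)


@dataclass(frozen=True)
class ITFIResult:
    """Per-tree mean fire intervals and their grand mean/median."""

    tree_means: dict[str, float]
    pooled_intervals: tuple[int, ...]

    @property
    def grand_mean(self) -> float:
        return float(np.mean(list(self.tree_means.values())))

    @property
    def grand_median(self) -> float:
        return float(np.median(list(self.tree_means.values())))


@dataclass
class EstimatorSuite:
    """The 20 CFI/ITFI estimator values plus sample-size covariates.

    ``values`` maps canonical estimator names (``mean_cfi_all`` ...
    ``weibull_median_itfi``) to years; estimators that could not be
    computed (too few intervals, non-convergent fit) are ``None``,
    mirroring the variable estimator availability of real compilations.
    """

    site_id: str
    values: dict[str, float | None] = field(default_factory=dict)
    sample_area_ha: float | None = None
    total_scarred_trees: int | None = None

    @property
    def scarred_trees_per_100ha(self) -> float | None:
        if self.sample_area_ha and self.total_scarred_trees is not None:
            return 100.0 * self.total_scarred_trees / self.sample_area_ha
        return None

    def to_row(self) -> dict:
        row: dict = {"site_id": self.site_id}
        row.update({name: self.values.get(name) for name in ESTIMATOR_NAMES})
        row["sample_area_ha"] = self.sample_area_ha
        row["total_scarred_trees"] = self.total_scarred_trees
        row["scarred_trees_per_100ha"] = self.scarred_trees_per_100ha
        return row


# ---------------------------------------------------------------------------


def restrict_analysis_period(
    site: FireHistorySite, window: AnalysisWindow
) -> FireHistorySite:
    """Truncate a site to its scar-to-scar analysis period.

    Raises :class:`NoUsableRecordError` when no fire falls in the window
    (or none after the sample-depth year) and :class:`ShortRecordError`
    when the restricted span is below ``window.min_record_years``.
    """
    fires = [y for y in site.fire_years if window.start_year <= y <= window.end_year]
    if not fires:
        raise NoUsableRecordError(
            f"site {site.site_id!r}: no fire years in "
            f"[{window.start_year}, {window.end_year}] — no usable record"
        )

    first_fire = fires[0]
    if window.min_samples_accumulated > 0:
        depth_year = None
        for year in range(site.first_year, site.last_year + 1):
            if site.alive_count(year) >= window.min_samples_accumulated:
                depth_year = year
                break
        if depth_year is None:
            raise NoUsableRecordError(
                f"site {site.site_id!r}: never accumulates "
                f"{window.min_samples_accumulated} simultaneous samples"
            )
        after = [y for y in fires if y >= depth_year]
        if not after:
            raise NoUsableRecordError(
                f"site {site.site_id!r}: no fire at or after the sample-depth "
                f"year {depth_year}"
            )
        first_fire = after[0]

    last_fire = fires[-1]
    if last_fire < first_fire:
        raise NoUsableRecordError(
            f"site {site.site_id!r}: no fire remains after restriction"
        )
    span = last_fire - first_fire
    if span < window.min_record_years:
        raise ShortRecordError(
            f"site {site.site_id!r}: restricted record spans {span} years, "
            f"below the {window.min_record_years}-year minimum"
        )

    truncated = [
        t for t in (s.truncate(first_fire, last_fire) for s in site.series)
        if t is not None
    ]
    return site.with_series(truncated)


def composite_fire_years(
    site: FireHistorySite, filt: CompositeFilter = CompositeFilter()
) -> list[int]:
    """Pooled composite list of fire years under a percent-scarred filter.

    The filter denominator counts series that are alive in the fire year
    and scarred at least once during the analysis period.
    """
    scarred = site.scarred_series
    out = []
    for year in site.fire_years:
        n_scarred_now = sum(1 for s in scarred if (s.code_at(year) or "").isupper())
        if n_scarred_now < 1:
            continue
        if filt.mode == "all_fires":
            out.append(year)
            continue
        denom = sum(1 for s in scarred if s.is_alive(year))
        if denom == 0:
            continue
        frac = n_scarred_now / denom
        if (filt.rule == ">=" and frac >= filt.threshold) or (
            filt.rule == ">" and frac > filt.threshold
        ):
            out.append(year)
    return out


def intervals(years) -> np.ndarray:
    """Successive differences of an ordered fire-year list, in years."""
    years = np.asarray(sorted(years), dtype=float)
    if years.size < 2:
        raise InsufficientIntervalsError(
            f"{years.size} fire year(s): at least two are needed to form an interval"
        )
    return np.diff(years)


def itfi(site: FireHistorySite) -> ITFIResult:
    """Individual-tree fire intervals.

    Each tree with >= 2 scars contributes its own mean inter-scar interval;
    the grand mean is unweighted across qualifying trees.  The pooled
    per-tree intervals are retained for Weibull fitting.
    """
    tree_means: dict[str, float] = {}
    pooled: list[int] = []
    for s in site.series:
        scars = s.scar_years
        if len(scars) < 2:
            continue
        diffs = np.diff(scars)
        tree_means[s.series_id] = float(diffs.mean())
        pooled.extend(int(d) for d in diffs)
    if not tree_means:
        raise InsufficientIntervalsError(
            f"site {site.site_id!r}: no tree has two or more scars"
        )
    return ITFIResult(tree_means=tree_means, pooled_intervals=tuple(pooled))


def fit_weibull(interval_values) -> WeibullFit | None:
    """Two-parameter maximum-likelihood Weibull fit (shift fixed at 0).

    Returns ``None`` for fewer than three intervals, zero-variance
    (degenerate) interval sets, or non-convergent fits — the estimator is
    then simply unavailable for that site.
    """
    data = np.asarray(interval_values, dtype=float)
    if data.size < 3 or np.any(data <= 0):
        return None
    if np.ptp(data) == 0.0:
        return None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, _, scale = stats.weibull_min.fit(data, floc=0.0)
    except Exception:  # non-convergence is reported as missing
        return None
    if not (np.isfinite(shape) and np.isfinite(scale)) or shape <= 0 or scale <= 0:
        return None
    return WeibullFit(shape=float(shape), scale=float(scale))


def _interval_measures(interval_values) -> dict[str, float | None]:
    data = np.asarray(interval_values, dtype=float)
    out: dict[str, float | None] = {
        "mean": float(data.mean()),
        "median": float(np.median(data)),
        "weibull_scale": None,
        "weibull_mean": None,
        "weibull_median": None,
    }
    fit = fit_weibull(data)
    if fit is not None:
        out["weibull_scale"] = fit.scale
        out["weibull_mean"] = fit.mean
        out["weibull_median"] = fit.median
    return out


def estimator_suite(
    site: FireHistorySite,
    window: AnalysisWindow | None = None,
    threshold_rule: str = ">=",
) -> EstimatorSuite:
    """Assemble the 20 CFI/ITFI estimator values for one site.

    If ``window`` is given the site is restricted first.  Missing
    estimators (too few intervals, failed fits) are left ``None``.
    """
    if window is not None:
        site = restrict_analysis_period(site, window)

    suite = EstimatorSuite(
        site_id=site.site_id,
        sample_area_ha=site.area_ha,
        total_scarred_trees=len(site.scarred_series),
    )
    values: dict[str, float | None] = {name: None for name in ESTIMATOR_NAMES}

    for family, mode in (("cfi_all", "all_fires"), ("cfi_10", "pct10"), ("cfi_25", "pct25")):
        years = composite_fire_years(site, CompositeFilter(mode=mode, rule=threshold_rule))
        if len(years) >= 2:
            for measure, val in _interval_measures(intervals(years)).items():
                values[f"{measure}_{family}"] = val

    try:
        res = itfi(site)
    except InsufficientIntervalsError:
        res = None
    if res is not None:
        values["mean_itfi"] = res.grand_mean
        values["median_itfi"] = res.grand_median
        fit = fit_weibull(res.pooled_intervals)
        if fit is not None:
            values["weibull_scale_itfi"] = fit.scale
            values["weibull_mean_itfi"] = fit.mean
            values["weibull_median_itfi"] = fit.median

    suite.values = values
    return suite
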