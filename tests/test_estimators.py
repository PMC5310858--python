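"""Analysis-period restriction, composite/ITFI intervals, Weibull fits."""

import numpy as np
import pytest
from scipy import stats

from firecal import (
    AnalysisWindow,
    CompositeFilter,
    InsufficientIntervalsError,
    NoUsableRecordError,
    RegimeConfig,
    ShortRecordError,
    WeibullFit,
    composite_fire_years,
    estimator_suite,
    fit_weibull,
    intervals,
    itfi,
    restrict_analysis_period,
    simulate_regime,
)

from conftest import make_series, make_site


# --- restriction -----------------------------------------------------------


def test_restriction_spans_first_to_last_fire_inside_window():
    site = make_site(
        [make_series("A", 1580, 1920, scars=[1590, 1650, 1880, 1910])]
    )
    window = AnalysisWindow(1600, 1900, min_record_years=50, min_samples_accumulated=0)
    out = restrict_analysis_period(site, window)
    assert (out.first_year, out.last_year) == (1650, 1880)
    assert out.fire_years == (1650, 1880)


def test_short_record_is_flagged():
    site = make_site([make_series("A", 1700, 1800, scars=[1720, 1760])])
    window = AnalysisWindow(1600, 1900, min_record_years=50, min_samples_accumulated=0)
    with pytest.raises(ShortRecordError, match="40 years"):
        restrict_analysis_period(site, window)


def test_no_fires_in_window_signals_no_usable_record():
    site = make_site([make_series("A", 1700, 1800, scars=[1950])], site_id="X")
    site.series = [make_series("A", 1700, 1999, scars=[1950])]
    with pytest.raises(NoUsableRecordError, match="no fire"):
        restrict_analysis_period(site, AnalysisWindow(1600, 1900))


def test_sample_depth_rule_never_moves_start_earlier():
    for seed in range(5):
        site, truth = simulate_regime(
            RegimeConfig(years=200, n_trees=12, tree_lifespan=120, seed=seed)
        )
        if truth.degenerate:
            continue
        base = AnalysisWindow(1600, 1900, min_record_years=0, min_samples_accumulated=0)
        ruled = AnalysisWindow(1600, 1900, min_record_years=0, min_samples_accumulated=5)
        try:
            off = restrict_analysis_period(site, base)
            on = restrict_analysis_period(site, ruled)
        except NoUsableRecordError:
            continue
        assert on.first_year >= off.first_year


# --- composites ------------------------------------------------------------


def _ten_tree_site():
    # ten scarred trees alive throughout; 1750 scars only one of them
    series = [
        make_series(f"T{i}", 1700, 1800, scars=[1710, 1790]) for i in range(9)
    ]
    series.append(make_series("T9", 1700, 1800, scars=[1710, 1750, 1790]))
    return make_site(series)


def test_small_fire_included_all_fires_excluded_pct25():
    site = _ten_tree_site()
    assert 1750 in composite_fire_years(site, CompositeFilter("all_fires"))
    assert 1750 not in composite_fire_years(site, CompositeFilter("pct25"))


def test_threshold_rule_at_exactly_25_percent():
    # four scarred trees; 1750 scars exactly one (25%)
    series = [make_series(f"T{i}", 1700, 1800, scars=[1710, 1790]) for i in range(3)]
    series.append(make_series("T3", 1700, 1800, scars=[1710, 1750, 1790]))
    site = make_site(series)
    assert 1750 in composite_fire_years(site, CompositeFilter("pct25", rule=">="))
    assert 1750 not in composite_fire_years(site, CompositeFilter("pct25", rule=">"))


def test_filter_monotonicity_on_simulated_sites():
    for seed in range(6):
        site, truth = simulate_regime(RegimeConfig(years=250, seed=seed))
        if truth.degenerate:
            continue
        n_all = len(composite_fire_years(site, CompositeFilter("all_fires")))
        n_10 = len(composite_fire_years(site, CompositeFilter("pct10")))
        n_25 = len(composite_fire_years(site, CompositeFilter("pct25")))
        assert n_25 <= n_10 <= n_all


# --- intervals & ITFI ------------------------------------------------------


def test_intervals_and_conservation():
    iv = intervals([1700, 1710, 1725])
    assert iv.tolist() == [10.0, 15.0]
    assert iv.mean() == 12.5
    assert iv.sum() == 1725 - 1700


def test_single_fire_year_is_insufficient():
    with pytest.raises(InsufficientIntervalsError):
        intervals([1700])


def test_itfi_grand_mean_unweighted():
    site = make_site(
        [
            make_series("A", 1690, 1800, scars=[1700, 1710, 1720]),  # mean 10
            make_series("B", 1690, 1800, scars=[1700, 1730, 1760]),  # mean 30
            make_series("C", 1690, 1800, scars=[1795]),  # <2 scars: excluded
        ]
    )
    res = itfi(site)
    assert res.tree_means == {"A": 10.0, "B": 30.0}
    assert res.grand_mean == 20.0


def test_single_tree_itfi():
    site = make_site([make_series("A", 1690, 1800, scars=[1700, 1720, 1760])])
    assert itfi(site).tree_means["A"] == 30.0


def test_itfi_no_qualifying_tree():
    site = make_site([make_series("A", 1690, 1800, scars=[1700])])
    with pytest.raises(InsufficientIntervalsError):
        itfi(site)


def test_compositing_only_shortens_intervals():
    """Mean CFI-all <= grand mean ITFI wherever both are defined."""
    for seed in range(8):
        site, truth = simulate_regime(RegimeConfig(years=250, seed=seed))
        if truth.degenerate:
            continue
        years = composite_fire_years(site, CompositeFilter("all_fires"))
        if len(years) < 2:
            continue
        try:
            res = itfi(site)
        except InsufficientIntervalsError:
            continue
        assert intervals(years).mean() <= res.grand_mean + 1e-9


# --- Weibull ---------------------------------------------------------------


def test_weibull_mle_parameter_recovery():
    data = stats.weibull_min.rvs(2.0, scale=20.0, size=5000, random_state=42)
    fit = fit_weibull(data)
    assert fit.shape == pytest.approx(2.0, rel=0.05)
    assert fit.scale == pytest.approx(20.0, rel=0.05)


def test_weibull_exponential_identities():
    fit = WeibullFit(shape=1.0, scale=17.0)
    assert fit.mean == pytest.approx(17.0)
    assert fit.median == pytest.approx(17.0 * np.log(2))


def test_degenerate_and_tiny_interval_sets_are_missing():
    assert fit_weibull([10, 10, 10, 10]) is None
    assert fit_weibull([5, 9]) is None


# --- suite -----------------------------------------------------------------


def test_suite_basic_measures():
    site = make_site(
        [make_series("A", 1700, 1725, scars=[1700, 1710, 1725])], area_ha=200.0
    )
    suite = estimator_suite(site)
    assert suite.values["mean_cfi_all"] == 12.5
    assert suite.values["median_cfi_all"] == 12.5
    assert suite.total_scarred_trees == 1
    assert suite.scarred_trees_per_100ha == pytest.approx(0.5)


def test_suite_filter_monotonicity_of_means():
    checked = 0
    for seed in range(10):
        site, truth = simulate_regime(RegimeConfig(years=300, seed=seed))
        if truth.degenerate:
            continue
        v = estimator_suite(site).values
        trio = [v["mean_cfi_all"], v["mean_cfi_10"], v["mean_cfi_25"]]
        if any(t is None for t in trio):
            continue
        assert trio[0] <= trio[1] + 1e-9 <= trio[2] + 2e-9
        checked += 1
    assert checked >= 3
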