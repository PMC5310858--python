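"""Prediction, group summaries, histograms, and the low-severity surface."""

import numpy as np
import pandas as pd
import pytest

from firecal import (
    CalibrationModel,
    DRY_FOREST_LANDSCAPES,
    area_weighted_percentage,
    compare_groups,
    exceedance_percent,
    histogram,
    low_severity_classifier,
    old_forest_proxy,
    predict_pmfi_fr,
    summarize,
)


def _slope_model(slope=1.216):
    return CalibrationModel(
        predictor_name="weibull_mean_itfi", slope=slope, n=55, r2_adj=0.97
    )


def test_prediction_is_slope_times_value():
    assert predict_pmfi_fr(30.0, _slope_model()) == pytest.approx(36.48)


def test_prediction_is_linear_for_slope_only_models():
    m = _slope_model(1.5)
    assert predict_pmfi_fr(24.0, m) == pytest.approx(2 * predict_pmfi_fr(12.0, m))


def test_prediction_rejects_nonpositive_value():
    with pytest.raises(ValueError):
        predict_pmfi_fr(0.0, _slope_model())


def test_covariate_model_requires_covariates():
    m = CalibrationModel(
        predictor_name="mean_itfi", slope=1.178, n=65, r2_adj=0.95,
        covariates={"total_scarred_trees": -0.037},
    )
    got = predict_pmfi_fr(30.0, m, {"total_scarred_trees": 20.0})
    assert got == pytest.approx(1.178 * 30 - 0.037 * 20)
    with pytest.raises(ValueError, match="covariate"):
        predict_pmfi_fr(30.0, m)


# --- summaries -------------------------------------------------------------


def _sites_frame(seed=0, n=120):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "pmfi_fr": rng.lognormal(3.4, 0.55, n),
            "forest_type": rng.choice(["dry_pine", "dry_mixed_conifer"], n),
            "state": rng.choice(["AZ", "CO", "NM"], n),
        }
    )


def test_overall_summary_matches_direct_statistics():
    df = _sites_frame()
    s = summarize(df, "overall")["overall"]
    vals = df["pmfi_fr"].to_numpy()
    assert s.n == len(df)
    assert s.mean == pytest.approx(vals.mean())
    assert s.median == pytest.approx(np.median(vals))
    assert s.cv_percent == pytest.approx(100 * vals.std(ddof=1) / vals.mean())
    assert s.ci95_mean[0] < s.mean < s.ci95_mean[1]
    assert s.ci95_median[0] <= s.median <= s.ci95_median[1]
    assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


def test_group_ns_partition_overall():
    df = _sites_frame(3)
    by_state = summarize(df, "state")
    assert sum(g.n for g in by_state.values()) == len(df)


def test_summaries_permutation_invariant():
    df = _sites_frame(5)
    shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = summarize(df, "forest_type")
    b = summarize(shuffled, "forest_type")
    for key in a:
        assert a[key].mean == pytest.approx(b[key].mean)
        assert a[key].median == pytest.approx(b[key].median)


def test_single_member_group():
    df = pd.DataFrame({"pmfi_fr": [40.49], "state": ["BC"], "forest_type": ["dry_pine"]})
    s = summarize(df, "state")["BC"]
    assert s.mean == s.median == s.min == s.max == 40.49
    assert s.sd is None and s.cv_percent is None


def test_welch_comparison_detects_separation_and_identity():
    rng = np.random.default_rng(1)
    a = rng.normal(30, 5, 60)
    t_same, _ = compare_groups(a, a)
    assert t_same == pytest.approx(0.0)
    t_diff, p_diff = compare_groups(a, a + 20.0)
    assert p_diff < 1e-6 and t_diff < 0


# --- histograms ------------------------------------------------------------


def test_histogram_exceedance_examples():
    values = [10.0, 20.0, 30.0, 40.0]
    assert exceedance_percent(values, 25) == pytest.approx(50.0)
    assert exceedance_percent(values, 0) == pytest.approx(100.0)
    h = histogram(values, bin_width=15)
    assert h.bin_edges[:3] == (0.0, 15.0, 30.0)
    assert sum(h.counts) == 4
    assert h.exceedance_pct[0] == pytest.approx(100.0)


def test_histogram_counts_are_half_open():
    h = histogram([15.0, 29.9, 30.0], bin_width=15)
    assert h.counts[1] == 2 and h.counts[2] == 1


# --- old-forest proxy and low-severity model -------------------------------


@pytest.mark.parametrize(
    "year, cls", [(1650, "ge200"), (1699, "ge200"), (1749, "ge150"), (1800, "younger")]
)
def test_old_forest_proxy(year, cls):
    assert old_forest_proxy(year) == cls


@pytest.mark.parametrize(
    "args, expected",
    [
        ((100, 50, 20), True),
        ((200, 50, 20), False),
        ((100, 20, 20), False),
        ((100, 50, 60), False),
        ((178, 29.2, 46.9), False),  # thresholds are strict
    ],
)
def test_low_severity_classifier(args, expected):
    assert low_severity_classifier(*args) is expected


def test_area_weighted_percentage_single_and_bounds():
    assert area_weighted_percentage([(100.0, 50.0)]) == pytest.approx(50.0)
    pairs = [(t, f) for _, t, f in DRY_FOREST_LANDSCAPES]
    pct = area_weighted_percentage(pairs)
    per = [100 * f / t for t, f in pairs]
    assert min(per) <= pct <= max(per)


def test_area_weighted_percentage_rejects_bad_input():
    with pytest.raises(ValueError):
        area_weighted_percentage([(100.0, 150.0)])
    with pytest.raises(ValueError):
        area_weighted_percentage([])
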