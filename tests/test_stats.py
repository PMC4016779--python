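import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nailmorph.stats import (StatsError, build_stats_report, correlation,
                             holm_adjust, kruskal_wallis,
                             lilliefors_normality, mann_whitney_u,
                             shapiro_wilk)


def brute_force_mw(x, y, alternative="two_sided"):
    """Independent oracle: enumerate every labeling of the pooled values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n, nm = len(x), len(x) * len(y)

    def u_of(xs, ys):
        return float((xs[:, None] > ys[None, :]).sum()) \
            + 0.5 * float((xs[:, None] == ys[None, :]).sum())

    u_obs = u_of(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n):
        sel = np.zeros(len(pooled), bool)
        sel[list(combo)] = True
        us.append(u_of(pooled[sel], pooled[~sel]))
    us = np.asarray(us)
    if alternative == "two_sided":
        p = np.mean(np.abs(us - nm / 2) >= abs(u_obs - nm / 2) - 1e-9)
    elif alternative == "greater":
        p = np.mean(us >= u_obs - 1e-9)
    else:
        p = np.mean(us <= u_obs + 1e-9)
    return u_obs, float(p)


def test_mann_whitney_separated_samples():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(2 / 20)
    assert res.method == "exact"


def test_mann_whitney_interleaved_samples():
    res = mann_whitney_u([1, 3], [2, 4])
    assert res.statistic == 1.0
    assert res.p_value == pytest.approx(4 / 6)


def test_mann_whitney_identical_samples_with_ties():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.statistic == pytest.approx(4.5)  # nm/2
    assert res.p_value == pytest.approx(1.0)


def test_mann_whitney_exact_matches_enumeration_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(2, 6))
        m = int(rng.integers(2, 6))
        # mix of continuous and tied data
        if rng.random() < 0.5:
            x = rng.normal(size=n)
            y = rng.normal(size=m)
        else:
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=m).astype(float)
        for alt in ("two_sided", "greater", "less"):
            res = mann_whitney_u(x, y, alternative=alt, method="exact")
            u_ref, p_ref = brute_force_mw(x, y, alt)
            assert res.statistic == pytest.approx(u_ref)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)


def test_mann_whitney_exact_agrees_with_scipy_without_ties(rng):
    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        res = mann_whitney_u(x, y, method="exact")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_mann_whitney_asymptotic_close_to_scipy(rng):
    x = rng.normal(size=30)
    y = rng.normal(0.5, size=28)
    res = mann_whitney_u(x, y, method="asymptotic")
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_mann_whitney_empty_sample_is_an_error():
    with pytest.raises(StatsError):
        mann_whitney_u([], [1.0])


def test_kruskal_wallis_printed_toy_value():
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(32 / 7)


def test_kruskal_wallis_degenerate_and_errors():
    res = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0]])
    assert res.statistic == 0.0 and res.p_value == 1.0
    with pytest.raises(StatsError):
        kruskal_wallis([[1.0, 2.0]])
    with pytest.raises(StatsError):
        kruskal_wallis([[1.0], []])


def test_kruskal_two_groups_matches_mann_whitney_squared_z(rng):
    x = rng.normal(size=15)
    y = rng.normal(size=14)
    kw = kruskal_wallis([x, y])
    mw = mann_whitney_u(x, y, method="asymptotic", continuity=False)
    # H = z^2: the chi-square(1) tail equals the two-sided normal tail
    assert kw.p_value == pytest.approx(mw.p_value, abs=1e-10)
    mw_cc = mann_whitney_u(x, y, method="asymptotic")
    assert kw.p_value == pytest.approx(mw_cc.p_value, abs=0.05)


def test_correlation_examples():
    x = [1.0, 2.0, 3.0]
    assert correlation(x, x).statistic == pytest.approx(1.0)
    assert correlation(x, [3.0, 2.0, 1.0]).statistic == pytest.approx(-1.0)
    r = correlation(x, [1.0, 2.0, 4.0]).statistic
    assert r == pytest.approx(9 / np.sqrt(84), abs=1e-12)


def test_spearman_equals_pearson_on_ranks(rng):
    x = rng.normal(size=20)
    y = 0.5 * x + rng.normal(size=20)
    rs = correlation(x, y, kind="spearman").statistic
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    assert rs == pytest.approx(correlation(rx, ry).statistic, abs=1e-12)


def test_correlation_errors():
    with pytest.raises(StatsError):
        correlation([1, 2, 3], [1, 2])
    with pytest.raises(StatsError):
        correlation([1.0, 1.0, 1.0], [1, 2, 3])
    with pytest.raises(StatsError):
        correlation([1, 2], [1, 2])


def test_lilliefors_rejects_uniform_data():
    # at n=500 the test's power against Uniform(0,1) at the 0.01 level is
    # essentially 1 (at n=200 it is only ~0.7, so rejection there would be
    # a coin flip)
    x = np.random.default_rng(42).uniform(0, 1, size=500)
    res = lilliefors_normality(x, n_mc=500, seed=1)
    assert res.p_value < 0.01


def test_lilliefors_accepts_perfect_normal_quantiles():
    x = sps.norm.ppf((np.arange(1, 51) - 0.5) / 50)
    res = lilliefors_normality(x, n_mc=500, seed=1)
    assert res.p_value > 0.5


def test_lilliefors_statistic_matches_statsmodels(rng):
    from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

    x = rng.normal(size=40)
    d_sm, _ = sm_lilliefors(x, dist="norm")
    res = lilliefors_normality(x, n_mc=200, seed=0)
    assert res.statistic == pytest.approx(d_sm, abs=1e-10)


def test_lilliefors_small_sample_is_an_error():
    with pytest.raises(StatsError):
        lilliefors_normality([1.0, 2.0, 3.0])


def test_shapiro_wilk_wrapper(rng):
    res = shapiro_wilk(rng.normal(size=30))
    assert 0 <= res.p_value <= 1
    assert res.test_name == "shapiro_wilk"


def test_holm_adjustment_order():
    adj = holm_adjust({"a": 0.01, "b": 0.04, "c": 0.03})
    assert adj["a"] == pytest.approx(0.03)
    assert adj["a"] <= adj["c"] <= adj["b"]
    assert all(v <= 1 for v in adj.values())


# ---------------------------------------------------------------------------
# study-level report
# ---------------------------------------------------------------------------

def _toy_study(n_donors=5, unilateral=False, seed=0):
    rng = np.random.default_rng(seed)
    rows, manifest = [], []
    for i in range(n_donors):
        donor = f"d{i}"
        sides = ("left",) if (unilateral and i == 0) else ("left", "right")
        base = rng.uniform(0.1, 0.3)
        for side in sides:
            sid = f"{donor}_{side[0]}"
            manifest.append({"specimen_id": sid, "donor_id": donor,
                             "side": side, "sex": "m" if i % 2 else "f",
                             "age": 70, "volume_path": "",
                             "landmark_path": ""})
            for design in ("straight", "bent"):
                scale = 1.0 if design == "straight" else 0.5
                for j, region in enumerate(("all", "q1", "q2", "q3", "q4")):
                    rows.append({
                        "specimen_id": sid, "design": design,
                        "region": region,
                        "bvtv": scale * base * (1.2 - 0.2 * j)
                        + rng.normal(0, 0.005),
                    })
    return pd.DataFrame(rows), pd.DataFrame(manifest)


def test_stats_report_schema_counts():
    results, manifest = _toy_study()
    report = build_stats_report(results, manifest, n_mc=100)
    assert len(report.adjacent_quarter_tests) == 6  # 3 per design
    assert set(report.design_tests) == {"all", "q1", "q2", "q3", "q4"}
    assert set(report.side_test) == {"bent", "straight"}
    assert set(report.sex_test) == {"bent", "straight"}
    assert len(report.side_correlations) == 10  # 2 designs x 5 regions
    table = report.correlation_table()
    assert list(table["region"]) == ["all", "q1", "q2", "q3", "q4"]
    d = report.to_dict()
    assert "design_tests" in d and "side_correlations" in d


def test_stats_report_excludes_unilateral_specimen():
    results, manifest = _toy_study(unilateral=True)
    report = build_stats_report(results, manifest, n_mc=100)
    assert any("unpaired" in note for note in report.notes)
    tr = report.side_correlations[("straight", "all")]
    assert tr.n_per_group == (4,)  # 5 donors, one unilateral


def test_stats_report_invariant_to_row_order():
    results, manifest = _toy_study()
    r1 = build_stats_report(results, manifest, n_mc=50, seed=3)
    shuffled = results.sample(frac=1.0, random_state=9).reset_index(drop=True)
    r2 = build_stats_report(shuffled, manifest, n_mc=50, seed=3)
    for key in r1.design_tests:
        assert r1.design_tests[key].p_value == r2.design_tests[key].p_value
    for key in r1.side_correlations:
        a, b = r1.side_correlations[key], r2.side_correlations[key]
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)


def test_stats_report_all_one_side_has_empty_correlations():
    results, manifest = _toy_study()
    manifest = manifest[manifest["side"] == "left"]
    results = results[results["specimen_id"].isin(manifest["specimen_id"])]
    report = build_stats_report(results, manifest, n_mc=50)
    assert all(v is None for v in report.side_correlations.values())
    assert any("no complete pairs" in n for n in report.notes)


from hypothesis import given, settings, strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 5), min_size=1, max_size=5),
       st.lists(st.integers(0, 5), min_size=1, max_size=5))
def test_exact_p_matches_enumeration_property(x, y):
    """Exact Mann-Whitney p equals full enumeration for every small sample,
    ties included."""
    res = mann_whitney_u(x, y, method="exact")
    u_ref, p_ref = brute_force_mw(x, y)
    assert res.statistic == pytest.approx(u_ref)
    assert res.p_value == pytest.approx(p_ref, abs=1e-12)
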