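"""Paired t-test, summary tables, Monte-Carlo power and detectable change."""

import numpy as np
import pytest
from scipy import stats as sps

from dyno17 import (
    min_detectable_change,
    paired_t_test,
    power_curve,
    summary_table,
    t_tail_prob,
)
from dyno17.stats import DEFAULT_M0, default_effect_model

from oracles import t4_tail_closed_form

# printed per-participant maxima of the study data: PV-corrected (table 1)
# and plain relative evaluation (table 2), stimulated vs control
TABLE1 = list(zip((1.27, 1.36, 1.32, 1.35, 1.45), (1.54, 1.40, 1.21, 1.49, 1.46)))
TABLE2 = list(zip((1.32, 1.37, 1.25, 1.36, 1.40), (1.35, 1.34, 1.23, 1.39, 1.41)))


# --- tail probability ---------------------------------------------------------


def test_tail_at_zero_is_half():
    assert t_tail_prob(0.0, 4) == pytest.approx(0.5)


@pytest.mark.parametrize("t,expected", [(1.0946, 0.1676), (0.3202, 0.3824)])
def test_tail_matches_df4_closed_form_examples(t, expected):
    assert t_tail_prob(t, 4) == pytest.approx(expected, abs=5e-5)
    assert t_tail_prob(t, 4) == pytest.approx(t4_tail_closed_form(t), abs=1e-12)


def test_tail_matches_closed_form_across_range():
    ts = np.linspace(-10, 10, 401)
    ours = t_tail_prob(ts, 4)
    oracle = np.array([t4_tail_closed_form(t) for t in ts])
    assert np.max(np.abs(ours - oracle)) < 1e-9


@pytest.mark.parametrize("df", [1, 2, 5, 30])
def test_tail_cross_checked_against_scipy(df):
    ts = np.linspace(-6, 6, 121)
    assert np.max(np.abs(t_tail_prob(ts, df) - sps.t.sf(ts, df))) < 1e-12


def test_tail_rejects_bad_df():
    with pytest.raises(ValueError):
        t_tail_prob(1.0, 0)


# --- paired t-test ------------------------------------------------------------


def test_reproduces_published_pv_corrected_p_value():
    res = paired_t_test(*map(list, zip(*TABLE1)))
    assert round(res.p_one_tailed, 3) == 0.168
    assert res.df == 4
    assert res.mean_diff == pytest.approx(-0.07)


def test_reproduces_published_relative_signal_p_value():
    res = paired_t_test(*map(list, zip(*TABLE2)))
    assert round(res.p_one_tailed, 3) == 0.382


def test_directional_convention():
    x, y = map(list, zip(*TABLE1))
    magnitude = paired_t_test(x, y)  # P(T >= |t|)
    directional = paired_t_test(x, y, directional=True)  # P(T >= t), t < 0 here
    assert directional.p_one_tailed == pytest.approx(1.0 - magnitude.p_one_tailed)


def test_degenerate_differences_rejected():
    with pytest.raises(ValueError, match="identical"):
        paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])


def test_cross_check_against_scipy_paired_test():
    rng = np.random.default_rng(5)
    x, y = rng.normal(1.4, 0.1, 8), rng.normal(1.3, 0.1, 8)
    ours = paired_t_test(x, y)
    ref = sps.ttest_rel(x, y, alternative="two-sided")
    assert ours.t == pytest.approx(ref.statistic)
    assert ours.p_one_tailed == pytest.approx(ref.pvalue / 2)


# --- summary tables -----------------------------------------------------------


def test_summary_reproduces_table1():
    table = summary_table(TABLE1)
    assert round(table.mean_stimulated, 2) == 1.35
    assert round(table.mean_control, 2) == 1.42
    assert round(table.sd_stimulated, 2) == 0.07
    assert round(table.sd_control, 2) == 0.13
    frame = table.to_frame()
    assert frame.attrs["p_one_tailed"] == 0.168
    assert list(frame.loc["Mean"]) == [1.35, 1.42]


def test_summary_reproduces_table2():
    table = summary_table(TABLE2)
    assert round(table.mean_stimulated, 2) == 1.34
    assert round(table.mean_control, 2) == 1.34
    assert round(table.sd_stimulated, 2) == 0.06
    assert round(table.sd_control, 2) == 0.07
    assert round(table.ttest.p_one_tailed, 3) == 0.382


def test_summary_rejects_short_input():
    with pytest.raises(ValueError):
        summary_table([(1.0, 2.0)])


# --- Monte-Carlo power --------------------------------------------------------


def test_zero_effect_power_is_type_i_error():
    res = power_curve([0.0], noise_cv=0.10, n=5, alpha=0.05, reps=10_000, seed=1)
    se = np.sqrt(0.05 * 0.95 / 10_000)
    assert res.power[0] == pytest.approx(0.05, abs=2 * se)


def test_huge_effect_power_saturates():
    # mean shift 10x the noise sd of the difference
    sd_d = 0.10 * DEFAULT_M0 * np.sqrt(2)
    effect = 10 * sd_d / (DEFAULT_M0 - 1.0)
    res = power_curve([effect], noise_cv=0.10, n=5, reps=2_000, seed=2)
    assert res.power[0] > 0.99


def test_power_matches_noncentral_t_oracle():
    """Monte-Carlo power agrees with the analytic noncentral-t power of the
    directional paired test within 2 Monte-Carlo standard errors."""
    n, cv, alpha, reps = 5, 0.10, 0.05, 20_000
    for effect in (0.5, 1.0, 1.5):
        shift = default_effect_model(DEFAULT_M0, effect) - DEFAULT_M0
        sd_d = cv * DEFAULT_M0 * np.sqrt(2)
        nc = shift / sd_d * np.sqrt(n)
        t_crit = sps.t.ppf(1 - alpha, n - 1)
        analytic = sps.nct.sf(t_crit, n - 1, nc)
        mc = power_curve([effect], cv, n, alpha=alpha, reps=reps, seed=3).power[0]
        se = np.sqrt(max(analytic * (1 - analytic), 1e-6) / reps)
        assert mc == pytest.approx(analytic, abs=max(2 * se, 5e-3))


def test_power_monotone_in_effect_n_and_noise():
    effects = np.linspace(0, 1.5, 7)
    res = power_curve(effects, noise_cv=0.10, n=5, reps=4_000, seed=4)
    assert np.all(np.diff(res.power) >= 0)  # exact under common random numbers
    p_small_n = power_curve([0.8], 0.10, 3, reps=4_000, seed=4).power[0]
    p_large_n = power_curve([0.8], 0.10, 10, reps=4_000, seed=4).power[0]
    assert p_large_n > p_small_n
    p_low_noise = power_curve([0.8], 0.05, 5, reps=4_000, seed=4).power[0]
    p_high_noise = power_curve([0.8], 0.20, 5, reps=4_000, seed=4).power[0]
    assert p_low_noise > p_high_noise


def test_power_input_validation():
    with pytest.raises(ValueError):
        power_curve([0.1], noise_cv=0.1, n=5, alpha=1.5)
    with pytest.raises(ValueError):
        power_curve([0.1], noise_cv=0.1, n=5, reps=10)
    with pytest.raises(ValueError):
        power_curve([-0.1], noise_cv=0.1, n=5)


# --- minimal detectable change ------------------------------------------------


def test_mdc_near_zero_when_target_is_alpha():
    res = min_detectable_change(0.06, noise_cv=0.10, n=5, alpha=0.05,
                                reps=4_000, seed=5)
    assert res.change < 0.05


def test_mdc_matches_grid_scan_oracle():
    reps, seed = 4_000, 6
    res = min_detectable_change(0.8, noise_cv=0.10, n=5, reps=reps, seed=seed)
    grid = np.linspace(0, 2.0, 201)
    powers = power_curve(grid, 0.10, 5, reps=reps, seed=seed).power
    first = grid[np.argmax(powers >= 0.8)]
    assert abs(res.change - first) <= (grid[1] - grid[0])


def test_mdc_monotone_in_n_and_noise():
    kw = dict(alpha=0.05, reps=3_000, seed=7)
    small_n = min_detectable_change(0.8, noise_cv=0.10, n=4, **kw).change
    large_n = min_detectable_change(0.8, noise_cv=0.10, n=12, **kw).change
    assert large_n <= small_n
    low_noise = min_detectable_change(0.8, noise_cv=0.05, n=5, **kw).change
    high_noise = min_detectable_change(0.8, noise_cv=0.15, n=5, **kw).change
    assert low_noise <= high_noise


def test_mdc_unreachable_target_reported():
    with pytest.raises(ValueError, match="unreachable"):
        min_detectable_change(0.999, noise_cv=0.8, n=2, reps=1_000, seed=8,
                              effect_max=0.5)
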