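"""Uncertainty budget, trueness, ruggedness and mode robustness."""

import numpy as np
import pytest
from scipy import stats

from temsize.intra import (
    AnovaDecomposition,
    CrmReference,
    anova_decompose,
    budget_from_design,
    combine_budget,
    min_particles_for,
    mode_robustness,
    piecewise_loglog_fit,
    ruggedness_curve,
    trueness,
    variance_components,
)


def test_anova_all_equal_cells():
    d = anova_decompose(np.full((5, 3), 20.0))
    assert d.ms_within == 0 and d.ms_between == 0 and d.c_m == 20.0


def test_anova_hand_example():
    # 2 days x 3 reps, day means 10 and 12, no within-day spread
    d = anova_decompose([[10.0, 10, 10], [12, 12, 12]])
    assert d.ms_within == 0.0
    assert d.ms_between == pytest.approx(6.0)
    assert d.c_m == pytest.approx(11.0)
    assert d.nu_within == 4
    u_r, u_day = variance_components(d)
    assert u_r == 0.0
    assert u_day == pytest.approx(100 * np.sqrt(2.0) / 11.0)


def test_anova_matches_scipy_f_oneway():
    rng = np.random.default_rng(0)
    m = rng.normal(50, 3, size=(5, 3))
    d = anova_decompose(m)
    f_ref = stats.f_oneway(*m)  # groups = days
    assert d.ms_between / d.ms_within == pytest.approx(f_ref.statistic, rel=1e-12)


def test_anova_rejects_bad_designs():
    with pytest.raises(ValueError):
        anova_decompose(np.ones((1, 3)))
    with pytest.raises(ValueError):
        anova_decompose([[1.0, np.nan], [2.0, 3.0]])


def test_degenerate_branch_value_and_nonnegativity():
    d = AnovaDecomposition(c_m=100.0, sd=2.0, ms_within=4.0, ms_between=4.0,
                           nu_within=10, n_r=3, n_days=5)
    u_r, u_day = variance_components(d)
    assert u_r == pytest.approx(2.0)
    assert u_day == pytest.approx(100 * np.sqrt(4 / 3) * 0.2**0.25 / 100)
    # always real and >= 0, including MS_between < MS_within
    d2 = AnovaDecomposition(c_m=10.0, sd=1.0, ms_within=4.0, ms_between=1.0,
                            nu_within=8, n_r=2, n_days=5)
    _, u_day2 = variance_components(d2)
    assert u_day2 >= 0.0


def test_combine_budget_published_cells():
    b = combine_budget(1.5, 1.0, 1.0, u_t_crm=0.0)
    assert b.u_ip == pytest.approx(1.80, abs=5e-3)
    b2 = combine_budget(0.0, 0.0, 0.0, u_t_crm=0.0)
    assert b2.ucx == 0.0
    # printed chain: u_IP 7.4, u_t 8.0, u_cal 1.0 -> u_c 10.94 -> Ucx 21.9
    u_c = np.sqrt(7.4**2 + 8.0**2 + 1.0**2)
    assert u_c == pytest.approx(10.94, abs=5e-3)
    assert 2 * u_c == pytest.approx(21.9, abs=0.02)


def test_budget_invariants():
    b = combine_budget(2.0, 1.5, 0.5, u_t_crm=3.0)
    assert b.u_ip**2 == pytest.approx(b.u_r**2 + b.u_day**2)
    assert b.ucx == pytest.approx(2 * b.u_c)
    with pytest.raises(ValueError):
        combine_budget(-1.0, 0.0, 0.0)


def test_trueness_published_rows_and_identity():
    t = trueness(19.2, 0.9, CrmReference(19.4, 0.7))
    assert t.delta_m == pytest.approx(0.2)
    assert t.u_delta == pytest.approx(1.14, abs=5e-3)
    assert t.U_delta == pytest.approx(2.28, abs=5e-3)
    assert t.no_significant_bias
    t2 = trueness(24.9, 1.0, CrmReference(27.8, 0.8))
    assert t2.delta_m == pytest.approx(2.9)
    assert t2.u_delta == pytest.approx(1.28, abs=5e-3)
    assert t2.U_delta == pytest.approx(2.56, abs=5e-3)
    t3 = trueness(19.4, 0.8, CrmReference(19.4, 0.7))
    assert t3.delta_m == 0.0 and t3.no_significant_bias


def test_monte_carlo_expectations_of_mean_squares():
    """E[MS_within] = sigma_r^2 and E[MS_between] = sigma_r^2 + n_r sigma_day^2."""
    rng = np.random.default_rng(42)
    n_mc, s_day, s_r = 3000, 0.5, 0.3
    msw = np.empty(n_mc)
    msb = np.empty(n_mc)
    for k in range(n_mc):
        m = 20 + s_day * rng.standard_normal((5, 1)) + s_r * rng.standard_normal((5, 3))
        d = anova_decompose(m)
        msw[k], msb[k] = d.ms_within, d.ms_between
    assert msw.mean() == pytest.approx(s_r**2, abs=3 * msw.std() / np.sqrt(n_mc))
    assert msb.mean() == pytest.approx(
        s_r**2 + 3 * s_day**2, abs=3 * msb.std() / np.sqrt(n_mc)
    )


def _iid_pools(rng, mean=20.0, sd=2.0, pool=4000):
    return {
        (d, r): rng.normal(mean, sd, size=pool)
        for d in range(1, 6)
        for r in range(1, 4)
    }


def test_ruggedness_full_pool_single_draw_matches_direct():
    rng = np.random.default_rng(1)
    pools = {k: v[:200] for k, v in _iid_pools(rng).items()}
    curve = ruggedness_curve(pools, n_grid=[200], n_boot=1, seed=0)
    medians = np.array(
        [[np.median(pools[(d, r)]) for r in range(1, 4)] for d in range(1, 6)]
    )
    d = anova_decompose(medians)
    u_r, u_day = variance_components(d)
    assert curve.u_ip_pct.iloc[0] == pytest.approx(float(np.hypot(u_r, u_day)))


def test_ruggedness_slope_is_square_root_law():
    rng = np.random.default_rng(2)
    curve = ruggedness_curve(
        _iid_pools(rng), n_grid=[25, 50, 100, 200, 400, 800], n_boot=25, seed=3
    )
    fit = piecewise_loglog_fit(curve.n_particles, curve.u_ip_pct)
    for slope in fit["slopes"]:
        assert slope == pytest.approx(-0.5, abs=0.1)


def test_ruggedness_day_effect_creates_floor():
    rng = np.random.default_rng(4)
    pools = {
        (d, r): 20 + 1.0 * d + rng.normal(0, 1.0, size=4000)  # strong day effect
        for d in range(1, 6)
        for r in range(1, 4)
    }
    curve = ruggedness_curve(pools, n_grid=[25, 100, 400, 1600], n_boot=15, seed=5)
    # u_IP flattens at the day-effect floor instead of falling as N^-1/2
    assert curve.u_ip_pct.iloc[-1] > 0.5 * curve.u_ip_pct.iloc[0]
    assert curve.u_ip_pct.iloc[-1] > 3.0  # sd of day means ~1.4 nm on 22.5 nm


def test_ruggedness_grid_exceeding_pool_raises():
    rng = np.random.default_rng(6)
    pools = {k: v[:100] for k, v in _iid_pools(rng).items()}
    with pytest.raises(ValueError):
        ruggedness_curve(pools, n_grid=[200], n_boot=2, seed=0)


def test_min_particles_threshold_rule():
    import pandas as pd

    curve = pd.DataFrame({"n_particles": [25, 50, 100], "u_ip_pct": [8.0, 4.0, 2.0]})
    assert min_particles_for(curve, 5.0) == 50
    assert min_particles_for(curve, 1.0) is None


def test_mode_robustness_on_disk_scene(disk_scene):
    from temsize.detection import DetectionParams

    _, mg, truth = disk_scene
    params = {m: DetectionParams(mode=m) for m in
              ("default", "irregular_watershed", "ellipse_fitting", "single_particle")}
    table = mode_robustness(mg, params)
    assert set(table["mode"]) == set(params)
    assert table.attrs["max_pairwise_rel_diff"] < 0.05
    table2 = mode_robustness(mg, params)
    assert table.equals(table2)


def test_budget_from_design_uses_material_trueness_default():
    m = 20 + np.random.default_rng(0).normal(0, 0.3, size=(5, 3))
    b = budget_from_design(m, u_cal=1.0, material="NM-212")
    # materials without a CRM get the mean silica trueness component
    assert b.u_t == pytest.approx(np.hypot(3.0242, b.u_ip), abs=1e-3)
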