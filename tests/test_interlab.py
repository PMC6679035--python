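"""Interlaboratory outlier screening and ISO 5725-2 precision estimates."""

import numpy as np
import pandas as pd
import pytest

from temsize.interlab import (
    cochran_critical,
    cochran_test,
    double_grubbs_critical,
    grubbs_critical,
    grubbs_tests,
    iso_summary,
    outlier_workflow,
    table_from_dict,
)


def _labs_with_sds(sds, n_rep=3, mean=50.0):
    """Deterministic labs whose sample sds are exactly as requested."""
    rows = []
    for i, sd in enumerate(sds):
        for j, v in enumerate([-sd, 0.0, sd][:n_rep]):
            rows.append({"lab_id": f"L{i:02d}", "replicate": j, "value_nm": mean + v})
    return pd.DataFrame(rows)


def test_critical_values_match_published_tables():
    # Cochran 5%: k=3, n=2 -> 0.9669; k=10, n=3 -> 0.4450 (standard tables)
    assert cochran_critical(0.05, 3, 1) == pytest.approx(0.9669, abs=2e-3)
    assert cochran_critical(0.05, 10, 2) == pytest.approx(0.4450, abs=2e-3)
    # Grubbs 1% (two-sided): n=5 -> 1.764; n=10 -> 2.482
    assert grubbs_critical(0.01, 5) == pytest.approx(1.764, abs=2e-3)
    assert grubbs_critical(0.01, 10) == pytest.approx(2.482, abs=2e-3)
    # double-Grubbs: n=10 -> 0.1150 at 1%, 0.1864 at 5% (ISO 5725-2 table)
    assert double_grubbs_critical(0.01, 10) == pytest.approx(0.115, abs=4e-3)
    assert double_grubbs_critical(0.05, 10) == pytest.approx(0.1864, abs=4e-3)


def test_critical_values_are_monotone():
    assert grubbs_critical(0.01, 8) > grubbs_critical(0.05, 8)
    assert cochran_critical(0.01, 8, 2) > cochran_critical(0.05, 8, 2)


def test_cochran_homogeneous_and_dominant_variance():
    flags = cochran_test(_labs_with_sds([1.0] * 5))
    assert flags[0].statistic == pytest.approx(0.2)
    assert flags[0].classification == "ok"
    # variances {100, 1, ..., 1} over 9 labs: C = 100/108
    flags = cochran_test(_labs_with_sds([10.0] + [1.0] * 8))
    assert flags[0].statistic == pytest.approx(100.0 / 108.0)
    assert flags[0].classification == "outlier"
    assert flags[0].lab_id == "L00"


def test_cochran_never_flags_zero_variance_lab():
    flags = cochran_test(_labs_with_sds([0.0, 1.0, 1.0, 1.0, 1.0]))
    assert all(f.lab_id != "L00" for f in flags)


def test_grubbs_mean_flags_shifted_lab():
    tab = table_from_dict({f"L{i}": [v] * 3 for i, v in enumerate([10, 10, 10, 10, 100.0])})
    flags = [f for f in grubbs_tests(tab) if f.test == "grubbs_mean"]
    assert flags[0].statistic == pytest.approx(1.7889, abs=1e-3)
    assert flags[0].critical_1pct == pytest.approx(1.764, abs=2e-3)
    assert flags[0].classification == "outlier"


def test_grubbs_symmetric_small_sample_ok():
    tab = table_from_dict({"A": [1.0], "B": [2.0], "C": [3.0]})
    flags = [f for f in grubbs_tests(tab) if f.test == "grubbs_mean"]
    assert flags[0].statistic == pytest.approx(1.0)
    assert flags[0].classification == "ok"


def test_grubbs_internal_flags_single_replicate():
    rng = np.random.default_rng(0)
    data = {f"L{i:02d}": list(20 + 0.3 * rng.standard_normal(15)) for i in range(8)}
    data["L07"][4] = 35.0  # one gross replicate in one lab
    tab = table_from_dict(data)
    internal = [f for f in grubbs_tests(tab) if f.test == "grubbs_internal"]
    assert len(internal) == 1
    assert internal[0].lab_id == "L07" and internal[0].replicate == 4
    assert internal[0].classification == "outlier"
    cleaned, log = outlier_workflow(tab)
    # only that single replicate is removed, the lab itself is kept
    assert cleaned["lab_id"].nunique() == 8
    assert len(cleaned) == 8 * 15 - 1


def test_workflow_identity_without_anomalies():
    rng = np.random.default_rng(1)
    tab = table_from_dict({f"L{i:02d}": 20 + 0.5 * rng.standard_normal(10) for i in range(9)})
    cleaned, log = outlier_workflow(tab)
    assert len(cleaned) == len(tab)
    assert all(f.classification == "straggler" for f in log)


def test_workflow_excludes_variance_and_mean_outliers():
    rng = np.random.default_rng(2)
    data = {f"L{i:02d}": list(20 + 0.4 * rng.standard_normal(10)) for i in range(10)}
    data["L03"] = list(20 + 8.0 * rng.standard_normal(10))  # inflated variance
    data["L07"] = list(35 + 0.4 * rng.standard_normal(10))  # shifted mean
    tab = table_from_dict(data)
    cleaned, log = outlier_workflow(tab)
    removed = set(tab["lab_id"]) - set(cleaned["lab_id"])
    assert removed == {"L03", "L07"}
    tests_used = {f.test for f in log if f.classification == "outlier"}
    assert "cochran" in tests_used and "grubbs_mean" in tests_used


def test_workflow_nineteen_labs_two_outliers_seventeen_remain():
    rng = np.random.default_rng(3)
    data = {f"L{i:02d}": list(17.4 + 0.3 * rng.standard_normal(15)) for i in range(19)}
    data["L01"] = list(19.5 + 0.3 * rng.standard_normal(15))  # Grubbs-type
    data["L18"] = list(17.4 + 3.0 * rng.standard_normal(15))  # Cochran-type
    cleaned, log = outlier_workflow(table_from_dict(data))
    assert cleaned["lab_id"].nunique() == 17
    s = iso_summary(cleaned, exclusion_log=log)
    assert s.n_labs == 17 and len(s.exclusion_log) >= 2


def test_workflow_requires_three_labs():
    tab = table_from_dict({"A": [1, 1.1], "B": [1.2, 1.3]})
    with pytest.raises(ValueError):
        outlier_workflow(tab)


def test_iso_summary_limits_and_degenerate_table():
    rng = np.random.default_rng(4)
    tab = table_from_dict({f"L{i}": 20 + rng.standard_normal(5) for i in range(6)})
    s = iso_summary(tab)
    assert s.r == pytest.approx(2.8 * s.s_r)
    assert s.R == pytest.approx(2.8 * s.s_R)
    assert s.s_R >= s.s_r
    assert s.rsd_r == pytest.approx(100 * s.s_r / s.x_obs)
    const = table_from_dict({"A": [5.0] * 4, "B": [5.0] * 4, "C": [5.0] * 4})
    s0 = iso_summary(const)
    assert s0.s_r == 0 and s0.s_R == 0 and s0.rsd_R == 0


def test_iso_summary_recovers_variance_components():
    """sigma_r = 1, sigma_L = 2: S_r -> 1 and S_R -> sqrt(5) on average."""
    rng = np.random.default_rng(5)
    n_mc, p, n = 150, 15, 15
    s_rs, s_Rs = [], []
    for _ in range(n_mc):
        labs = {
            f"L{i:02d}": 50 + 2.0 * rng.standard_normal() + rng.standard_normal(n)
            for i in range(p)
        }
        s = iso_summary(table_from_dict(labs))
        s_rs.append(s.s_r)
        s_Rs.append(s.s_R)
    se_r = np.std(s_rs, ddof=1) / np.sqrt(n_mc)
    se_R = np.std(s_Rs, ddof=1) / np.sqrt(n_mc)
    assert np.mean(s_rs) == pytest.approx(1.0, abs=3 * se_r + 0.01)
    assert np.mean(s_Rs) == pytest.approx(np.sqrt(5.0), abs=3 * se_R + 0.03)


def test_exclusion_monotonicity_on_outlier_fixture():
    rng = np.random.default_rng(6)
    data = {f"L{i:02d}": list(20 + 0.4 * rng.standard_normal(10)) for i in range(9)}
    data["L05"] = list(30 + 0.4 * rng.standard_normal(10))
    tab = table_from_dict(data)
    before = iso_summary(tab)
    cleaned, _ = outlier_workflow(tab)
    after = iso_summary(cleaned)
    assert after.s_R <= before.s_R


def test_plot_interlab_writes_file(tmp_path):
    rng = np.random.default_rng(7)
    tab = table_from_dict({f"L{i}": 20 + rng.standard_normal(5) for i in range(5)})
    s = iso_summary(tab)
    out = tmp_path / "dots.png"
    from temsize.interlab import plot_interlab

    plot_interlab(tab, s, out)
    assert out.stat().st_size > 0
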