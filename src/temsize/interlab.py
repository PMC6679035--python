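"""Interlaboratory study evaluation following ISO 5725-2.

Input is a long table of replicate specimen medians per laboratory.
Outlier screening uses the standard battery: the Cochran test flags a
laboratory whose internal repeatability variance dominates the sum of
all reported variances; Grubbs tests flag an anomalous laboratory mean
(single), the two most extreme means jointly (double), or a single
replicate within a laboratory (internal).  Statistics are compared with
their critical values at the 5% level (straggler) and 1% level
(outlier); only outliers are excluded from the final treatment.

Precision follows from a one-way ANOVA with laboratory as the factor:
S_r^2 = MS_within is the repeatability variance, the between-laboratory
component S_L^2 = (MS_between - MS_within)/n_bar (floored at zero,
n_bar the effective replicate count for unbalanced data), and the
reproducibility variance S_R^2 = S_r^2 + S_L^2.  The repeatability and
reproducibility limits are r = 2.8 S_r and R = 2.8 S_R
(2.8 ~ 1.96 * sqrt(2): the 95% bound on the difference of two results).

Critical values are computed analytically — Grubbs from the Student-t
quantile closed form, Cochran from the F-quantile relation — except for
the double-Grubbs test, whose null distribution has no closed form and
is tabulated here once per group size by seeded Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierFlag",
    "InterlabSummary",
    "table_from_dict",
    "cochran_critical",
    "grubbs_critical",
    "double_grubbs_critical",
    "cochran_test",
    "grubbs_tests",
    "outlier_workflow",
    "iso_summary",
    "plot_interlab",
]

LIMIT_FACTOR = 2.8  # 1.96 * sqrt(2), 95% limit on |difference of two results|

REQUIRED_COLUMNS = ("lab_id", "replicate", "value_nm")


@dataclass
class OutlierFlag:
    """Outcome of one outlier test on one lab (or lab pair / replicate)."""

    lab_id: str
    test: str  # cochran | grubbs_mean | grubbs_double | grubbs_internal
    statistic: float
    critical_5pct: float
    critical_1pct: float
    classification: str  # ok | straggler | outlier
    replicate: int | None = None

    @staticmethod
    def classify(statistic, c5, c1, *, lower_tail=False) -> str:
        if lower_tail:  # double-Grubbs: small ratios are extreme
            if statistic < c1:
                return "outlier"
            if statistic < c5:
                return "straggler"
            return "ok"
        if statistic > c1:
            return "outlier"
        if statistic > c5:
            return "straggler"
        return "ok"


@dataclass
class InterlabSummary:
    """ISO 5725-2 precision estimates after outlier exclusion."""

    x_obs: float
    s_r: float
    r: float
    rsd_r: float
    s_R: float
    R: float
    rsd_R: float
    n_labs: int
    exclusion_log: list = field(default_factory=list)


def table_from_dict(values_by_lab: dict) -> pd.DataFrame:
    """Long-format table from {lab_id: iterable of replicate medians}."""
    rows = [
        {"lab_id": str(lab), "replicate": i, "value_nm": float(v)}
        for lab, vals in values_by_lab.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks columns {missing}")
    if table["lab_id"].nunique() < 3:
        raise ValueError("need at least 3 laboratories")
    return table


# ---------------------------------------------------------------------------
# critical values

def cochran_critical(alpha: float, n_labs: int, nu: int) -> float:
    """Critical value of Cochran's max-variance ratio.

    From the F-quantile relation for the largest of ``n_labs`` variance
    ratios, each with ``nu`` degrees of freedom:
    C = F / (F + n_labs - 1) with F the upper alpha/n_labs quantile of
    F(nu, (n_labs - 1) * nu).
    """
    if n_labs < 2 or nu < 1:
        raise ValueError("need at least 2 labs and 1 degree of freedom")
    f = stats.f.ppf(1.0 - alpha / n_labs, nu, (n_labs - 1) * nu)
    return float(f / (f + n_labs - 1))


def grubbs_critical(alpha: float, n: int) -> float:
    """Two-sided single-Grubbs critical value from the t-quantile form."""
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 values")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2)))


@lru_cache(maxsize=64)
def double_grubbs_critical(alpha: float, n: int, n_sim: int = 200_000) -> float:
    """Lower-tail critical value of the double-Grubbs SS ratio.

    Null distribution of the smaller of the two trimmed-sum-of-squares
    ratios (two highest removed / two lowest removed, each over the full
    SS) for n standard normals, by Monte Carlo with a seed derived from
    n — no closed form exists.  Small ratios indicate an outlying pair;
    taking the minimum over both pairs reproduces the published ISO
    5725-2 critical values.
    """
    if n < 5:
        raise ValueError("double-Grubbs test needs at least 5 values")
    rng = np.random.default_rng(977_000 + n)
    x = rng.standard_normal((n_sim, n))
    x.sort(axis=1)
    ss_all = ((x - x.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    hi = x[:, :-2]
    lo = x[:, 2:]
    r_hi = ((hi - hi.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / ss_all
    r_lo = ((lo - lo.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) / ss_all
    return float(np.quantile(np.minimum(r_hi, r_lo), alpha))


# ---------------------------------------------------------------------------
# statistics + tests

def _double_grubbs_ratio(values: np.ndarray, which: str) -> float:
    x = np.sort(np.asarray(values, dtype=float))
    ss_all = ((x - x.mean()) ** 2).sum()
    trimmed = x[:-2] if which == "high" else x[2:]
    ss_trim = ((trimmed - trimmed.mean()) ** 2).sum()
    return float(ss_trim / ss_all) if ss_all > 0 else 1.0


def cochran_test(
    table: pd.DataFrame, alphas: tuple[float, float] = (0.05, 0.01)
) -> list[OutlierFlag]:
    """Flag the laboratory with the largest internal variance."""
    table = _check_table(table)
    grouped = table.groupby("lab_id")["value_nm"]
    sizes = grouped.size()
    usable = sizes[sizes >= 2].index
    if len(usable) < 2:
        return []
    variances = grouped.var(ddof=1).loc[usable]
    total = variances.sum()
    if total == 0:
        return []
    lab = variances.idxmax()
    c = float(variances.max() / total)
    nu = int(round(sizes.loc[usable].mean())) - 1
    c5 = cochran_critical(alphas[0], len(usable), max(nu, 1))
    c1 = cochran_critical(alphas[1], len(usable), max(nu, 1))
    return [
        OutlierFlag(
            lab_id=str(lab),
            test="cochran",
            statistic=c,
            critical_5pct=c5,
            critical_1pct=c1,
            classification=OutlierFlag.classify(c, c5, c1),
        )
    ]


def grubbs_tests(
    table: pd.DataFrame, alphas: tuple[float, float] = (0.05, 0.01)
) -> list[OutlierFlag]:
    """Single-, double- and internal-Grubbs screening of one table."""
    table = _check_table(table)
    flags: list[OutlierFlag] = []
    means = table.groupby("lab_id")["value_nm"].mean()

    # single Grubbs on the laboratory means
    if len(means) >= 3:
        s = means.std(ddof=1)
        if s > 0:
            dev = (means - means.mean()).abs()
            lab = dev.idxmax()
            g = float(dev.max() / s)
            c5 = grubbs_critical(alphas[0], len(means))
            c1 = grubbs_critical(alphas[1], len(means))
            flags.append(
                OutlierFlag(
                    lab_id=str(lab),
                    test="grubbs_mean",
                    statistic=g,
                    critical_5pct=c5,
                    critical_1pct=c1,
                    classification=OutlierFlag.classify(g, c5, c1),
                )
            )

    # double Grubbs on the two most extreme laboratory means
    if len(means) >= 5:
        c5 = double_grubbs_critical(alphas[0], len(means))
        c1 = double_grubbs_critical(alphas[1], len(means))
        order = means.sort_values()
        for which, labs in (
            ("high", order.index[-2:]),
            ("low", order.index[:2]),
        ):
            g = _double_grubbs_ratio(means.to_numpy(), which)
            flags.append(
                OutlierFlag(
                    lab_id=",".join(map(str, labs)),
                    test="grubbs_double",
                    statistic=g,
                    critical_5pct=c5,
                    critical_1pct=c1,
                    classification=OutlierFlag.classify(g, c5, c1, lower_tail=True),
                )
            )

    # internal Grubbs within each laboratory's replicates
    for lab, grp in table.groupby("lab_id"):
        vals = grp["value_nm"].to_numpy(dtype=float)
        if len(vals) < 3:
            continue
        s = vals.std(ddof=1)
        if s == 0:
            continue
        dev = np.abs(vals - vals.mean())
        idx = int(np.argmax(dev))
        g = float(dev[idx] / s)
        c5 = grubbs_critical(alphas[0], len(vals))
        c1 = grubbs_critical(alphas[1], len(vals))
        cls = OutlierFlag.classify(g, c5, c1)
        if cls != "ok":
            flags.append(
                OutlierFlag(
                    lab_id=str(lab),
                    test="grubbs_internal",
                    statistic=g,
                    critical_5pct=c5,
                    critical_1pct=c1,
                    classification=cls,
                    replicate=int(grp["replicate"].iloc[idx]),
                )
            )
    return flags


def outlier_workflow(
    table: pd.DataFrame, max_removed_fraction: float = 2.0 / 9.0
) -> tuple[pd.DataFrame, list[OutlierFlag]]:
    """Iterative outlier exclusion with minimal data loss per step.

    Each pass runs the full battery (Cochran plus the three Grubbs
    variants) and removes at most one finding before re-testing, so
    exclusions never rest on already-discarded data.  When several tests
    flag outliers in the same pass, a single anomalous replicate
    (internal Grubbs) is removed before any whole laboratory — a gross
    replicate inflates its lab's variance and would otherwise cost the
    entire lab via Cochran.  Stragglers (5%) are logged but kept.
    Exclusion stops once the ISO practice bound of ``2/9`` of the
    laboratories has been removed.
    """
    table = _check_table(table).copy()
    n_labs_start = table["lab_id"].nunique()
    max_excluded = int(np.floor(max_removed_fraction * n_labs_start))
    log: list[OutlierFlag] = []
    excluded_labs: set[str] = set()

    while True:
        flags = cochran_test(table) + grubbs_tests(table)
        log.extend(f for f in flags if f.classification == "straggler")
        outliers = [f for f in flags if f.classification == "outlier"]
        if not outliers:
            break
        order = {"grubbs_internal": 0, "cochran": 1, "grubbs_mean": 2, "grubbs_double": 3}
        f = min(outliers, key=lambda fl: order[fl.test])
        if f.test == "grubbs_internal":
            table = table[
                ~((table["lab_id"] == f.lab_id) & (table["replicate"] == f.replicate))
            ]
        else:
            labs = set(f.lab_id.split(","))
            if len(excluded_labs | labs) > max_excluded:
                log.append(f)
                break
            excluded_labs |= labs
            table = table[~table["lab_id"].isin(labs)]
        log.append(f)
        if table["lab_id"].nunique() < 3:
            raise ValueError("fewer than 3 laboratories remain after exclusion")
    return table.reset_index(drop=True), log


def iso_summary(table: pd.DataFrame, exclusion_log=None) -> InterlabSummary:
    """Repeatability/reproducibility estimates from a cleaned table."""
    table = _check_table(table)
    grouped = table.groupby("lab_id")["value_nm"]
    sizes = grouped.size().to_numpy(dtype=float)
    means = grouped.mean().to_numpy(dtype=float)
    p = len(sizes)
    n_total = sizes.sum()
    x_obs = float(table["value_nm"].mean())
    # within-lab (repeatability) variance: pooled over labs
    ss_within = ((table["value_nm"] - grouped.transform("mean")) ** 2).sum()
    nu_within = n_total - p
    s_r2 = float(ss_within / nu_within) if nu_within > 0 else 0.0
    # between-lab component with the effective replicate count n_bar
    n_bar = (n_total - (sizes**2).sum() / n_total) / (p - 1)
    ss_between = (sizes * (means - x_obs) ** 2).sum()
    ms_between = float(ss_between / (p - 1))
    s_L2 = max(0.0, (ms_between - s_r2) / n_bar)
    s_r = float(np.sqrt(s_r2))
    s_R = float(np.sqrt(s_r2 + s_L2))  # floored at s_r by construction
    return InterlabSummary(
        x_obs=x_obs,
        s_r=s_r,
        r=LIMIT_FACTOR * s_r,
        rsd_r=100.0 * s_r / x_obs,
        s_R=s_R,
        R=LIMIT_FACTOR * s_R,
        rsd_R=100.0 * s_R / x_obs,
        n_labs=p,
        exclusion_log=list(exclusion_log or []),
    )


def plot_interlab(table: pd.DataFrame, summary: InterlabSummary, path) -> None:
    """Per-laboratory dot plot with the mean and X_obs +/- S_R band."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    labs = sorted(table["lab_id"].unique())
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(labs)), 4))
    for i, lab in enumerate(labs):
        vals = table.loc[table["lab_id"] == lab, "value_nm"]
        ax.plot([i] * len(vals), vals, "o", ms=3, color="tab:blue", alpha=0.7)
    ax.axhline(summary.x_obs, color="k", lw=1.2)
    for y in (summary.x_obs - summary.s_R, summary.x_obs + summary.s_R):
        ax.axhline(y, color="k", lw=0.8, ls="--")
    ax.set_xticks(range(len(labs)), labs, rotation=90, fontsize=7)
    ax.set_ylabel("median minimal Feret diameter (nm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
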