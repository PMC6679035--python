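"""Intra-laboratory validation calculus.

Top-down uncertainty budget of a day x replicate design of specimen
medians: a one-way ANOVA with day as the factor splits the variance
into a repeatability component u_r and a day-to-day component u_day,

    u_r   = 100 * sqrt(MS_within) / C_m
    u_day = 100 * sqrt((MS_between - MS_within) / n_r) / C_m      (MS_between > MS_within)
          = 100 * sqrt(MS_within / n_r) * (2 / nu)^(1/4) / C_m    (otherwise)

with nu = n_days * (n_r - 1) the within degrees of freedom.  The
degenerate branch is the standard upper estimate of an undetectable
between-day component (the MS_between <= MS_within case), so u_day is
always real and non-negative.  Components combine in quadrature:
u_IP = sqrt(u_r^2 + u_day^2), u_t = sqrt(u_t,CRM^2 + u_IP^2),
u_c = sqrt(u_IP^2 + u_t^2 + u_cal^2), and the expanded uncertainty
Ucx = 2 * u_c (coverage factor 2, ~95%).  All components are carried as
relative percentages; the trueness comparison runs in absolute nm:
Delta_m = |C_m - C_CRM| against U_Delta = 2 * sqrt(u_c^2 + u_CRM^2).

The module also provides the ruggedness-vs-particle-count curve
(subsample the per-specimen pools, recompute u_IP, fit a piecewise
log-log line) and the robustness-vs-analysis-mode table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .size_stats import median_min_feret
from .validation_tables import u_t_crm_pct

__all__ = [
    "AnovaDecomposition",
    "UncertaintyBudget",
    "CrmReference",
    "TruenessAssessment",
    "anova_decompose",
    "variance_components",
    "combine_budget",
    "budget_from_design",
    "trueness",
    "ruggedness_curve",
    "piecewise_loglog_fit",
    "min_particles_for",
    "mode_robustness",
]


@dataclass
class AnovaDecomposition:
    """One-way (day-factor) ANOVA of a balanced medians matrix."""

    c_m: float
    sd: float
    ms_within: float
    ms_between: float
    nu_within: int
    n_r: int
    n_days: int


@dataclass
class CrmReference:
    """Certified (or indicative) reference value with k=1 uncertainty."""

    value_nm: float
    u_nm: float
    u_t_crm_pct: float | None = None

    def __post_init__(self):
        if self.u_nm < 0:
            raise ValueError("u_nm must be >= 0")
        if self.u_t_crm_pct is None:
            self.u_t_crm_pct = 100.0 * self.u_nm / self.value_nm


@dataclass
class UncertaintyBudget:
    """Relative (%) uncertainty chain of one material/mode analysis."""

    u_r: float
    u_day: float
    u_ip: float
    u_cal: float
    u_t: float
    u_c: float
    ucx: float
    anova: AnovaDecomposition | None = None

    def absolute(self, c_m: float) -> dict:
        """Budget re-expressed in nm for a given mean value."""
        return {
            k: getattr(self, k) * c_m / 100.0
            for k in ("u_r", "u_day", "u_ip", "u_cal", "u_t", "u_c", "ucx")
        }


@dataclass
class TruenessAssessment:
    """Bias check of the measured mean against a reference value (nm)."""

    delta_m: float
    u_delta: float
    U_delta: float
    no_significant_bias: bool


def anova_decompose(medians: np.ndarray) -> AnovaDecomposition:
    """Grand mean and within/between-day mean squares of a medians matrix.

    ``medians`` has one row per day and one column per replicate; the
    design must be complete (no NaN) and at least 2 x 2.
    """
    m = np.asarray(medians, dtype=float)
    if m.ndim != 2:
        raise ValueError("medians must be a 2-D day x replicate matrix")
    n_days, n_r = m.shape
    if n_days < 2 or n_r < 2:
        raise ValueError("need at least 2 days and 2 replicates per day")
    if np.isnan(m).any():
        raise ValueError("balanced complete design required (missing cells found)")
    grand = m.mean()
    day_means = m.mean(axis=1)
    ss_within = ((m - day_means[:, None]) ** 2).sum()
    ss_between = n_r * ((day_means - grand) ** 2).sum()
    nu_within = n_days * (n_r - 1)
    return AnovaDecomposition(
        c_m=float(grand),
        sd=float(m.std(ddof=1)),
        ms_within=float(ss_within / nu_within),
        ms_between=float(ss_between / (n_days - 1)),
        nu_within=nu_within,
        n_r=n_r,
        n_days=n_days,
    )


def variance_components(decomp: AnovaDecomposition) -> tuple[float, float]:
    """Relative repeatability and day-to-day components (u_r %, u_day %)."""
    if decomp.c_m <= 0:
        raise ValueError("grand mean must be positive")
    u_r = 100.0 * np.sqrt(decomp.ms_within) / decomp.c_m
    if decomp.ms_between > decomp.ms_within:
        u_day = (
            100.0
            * np.sqrt((decomp.ms_between - decomp.ms_within) / decomp.n_r)
            / decomp.c_m
        )
    else:
        u_day = (
            100.0
            * np.sqrt(decomp.ms_within / decomp.n_r)
            * (2.0 / decomp.nu_within) ** 0.25
            / decomp.c_m
        )
    return float(u_r), float(u_day)


def combine_budget(
    u_r: float,
    u_day: float,
    u_cal: float,
    crm: CrmReference | None = None,
    *,
    u_t_crm: float | None = None,
    anova: AnovaDecomposition | None = None,
) -> UncertaintyBudget:
    """Quadrature combination of the relative (%) uncertainty chain."""
    for name, v in (("u_r", u_r), ("u_day", u_day), ("u_cal", u_cal)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    if u_t_crm is None:
        u_t_crm = crm.u_t_crm_pct if crm is not None else 0.0
    u_ip = float(np.hypot(u_r, u_day))
    u_t = float(np.hypot(u_t_crm, u_ip))
    u_c = float(np.sqrt(u_ip**2 + u_t**2 + u_cal**2))
    return UncertaintyBudget(
        u_r=float(u_r),
        u_day=float(u_day),
        u_ip=u_ip,
        u_cal=float(u_cal),
        u_t=u_t,
        u_c=u_c,
        ucx=2.0 * u_c,
        anova=anova,
    )


def budget_from_design(
    medians: np.ndarray,
    u_cal: float,
    crm: CrmReference | None = None,
    material: str | None = None,
) -> UncertaintyBudget:
    """Full chain from a day x replicate medians matrix to Ucx."""
    decomp = anova_decompose(medians)
    u_r, u_day = variance_components(decomp)
    if crm is None and material is not None:
        return combine_budget(
            u_r, u_day, u_cal, u_t_crm=u_t_crm_pct(material), anova=decomp
        )
    return combine_budget(u_r, u_day, u_cal, crm, anova=decomp)


def trueness(c_m: float, u_c_abs_nm: float, crm: CrmReference) -> TruenessAssessment:
    """Compare the measured mean with the reference value, in nm.

    No significant bias is concluded when the absolute difference
    Delta_m stays within the expanded combined uncertainty U_Delta of
    result and reference.
    """
    delta_m = abs(c_m - crm.value_nm)
    u_delta = float(np.hypot(u_c_abs_nm, crm.u_nm))
    U_delta = 2.0 * u_delta
    return TruenessAssessment(
        delta_m=float(delta_m),
        u_delta=u_delta,
        U_delta=U_delta,
        no_significant_bias=bool(delta_m <= U_delta),
    )


# ---------------------------------------------------------------------------
# ruggedness against the number of measured particles

def _u_ip_of_medians(medians: np.ndarray) -> float:
    decomp = anova_decompose(medians)
    u_r, u_day = variance_components(decomp)
    return float(np.hypot(u_r, u_day))


def ruggedness_curve(
    pools: dict[tuple[int, int], np.ndarray],
    n_grid: list[int],
    n_boot: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """u_IP as a function of the number of particles measured per specimen.

    ``pools`` maps (day, replicate) to that specimen's particle sizes.
    For each N in ``n_grid``, every pool is subsampled to N particles
    without replacement ``n_boot`` times; each draw gives a medians
    matrix and hence one u_IP, and the draws are averaged.
    """
    days = sorted({d for d, _ in pools})
    reps = sorted({r for _, r in pools})
    arrays = {k: np.asarray(v, dtype=float) for k, v in pools.items()}
    min_pool = min(len(v) for v in arrays.values())
    if max(n_grid) > min_pool:
        raise ValueError(
            f"n_grid maximum {max(n_grid)} exceeds smallest pool size {min_pool}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for n_sub in n_grid:
        u_ips = np.empty(n_boot)
        for b in range(n_boot):
            medians = np.empty((len(days), len(reps)))
            for i, d in enumerate(days):
                for j, r in enumerate(reps):
                    pool = arrays[(d, r)]
                    idx = rng.choice(len(pool), size=n_sub, replace=False)
                    medians[i, j] = median_min_feret(pool[idx])
            u_ips[b] = _u_ip_of_medians(medians)
        rows.append(
            {"n_particles": n_sub, "u_ip_pct": u_ips.mean(), "u_ip_sd": u_ips.std(ddof=1) if n_boot > 1 else 0.0}
        )
    return pd.DataFrame(rows)


def piecewise_loglog_fit(n_particles, u_ip_pct) -> dict:
    """Piecewise (one-breakpoint) linear fit in log10-log10 space.

    The breakpoint is the interior grid point minimising the total
    residual sum of squares of the two ordinary least-squares segments;
    a plain single line is reported when the grid is too short to split.
    """
    x = np.log10(np.asarray(n_particles, dtype=float))
    y = np.log10(np.asarray(u_ip_pct, dtype=float))

    def _ols(xs, ys):
        slope, intercept = np.polyfit(xs, ys, 1)
        resid = ys - (slope * xs + intercept)
        return slope, intercept, float((resid**2).sum())

    if len(x) < 6:
        s, i, r = _ols(x, y)
        return {"breakpoint_n": None, "slopes": (s,), "intercepts": (i,), "rss": r}
    best = None
    for k in range(2, len(x) - 2):
        s1, i1, r1 = _ols(x[: k + 1], y[: k + 1])
        s2, i2, r2 = _ols(x[k:], y[k:])
        if best is None or r1 + r2 < best["rss"]:
            best = {
                "breakpoint_n": float(10 ** x[k]),
                "slopes": (s1, s2),
                "intercepts": (i1, i2),
                "rss": r1 + r2,
            }
    return best


def min_particles_for(curve: pd.DataFrame, u_ip_threshold_pct: float = 5.0):
    """Smallest grid N whose mean u_IP falls below the threshold."""
    ok = curve[curve["u_ip_pct"] < u_ip_threshold_pct]
    return None if ok.empty else int(ok["n_particles"].min())


# ---------------------------------------------------------------------------
# robustness against the analysis mode

def mode_robustness(mg, params_by_mode: dict) -> pd.DataFrame:
    """Median minimal Feret per analysis mode on one micrograph.

    ``params_by_mode`` maps mode name to its DetectionParams; the same
    image is analysed once per mode and the per-mode medians plus the
    maximum pairwise relative difference are returned.
    """
    from .detection import analyze_micrograph

    rows = []
    for mode, params in params_by_mode.items():
        if params.mode != mode:
            raise ValueError(f"params for {mode!r} carry mode {params.mode!r}")
        retained, log = analyze_micrograph(mg, params)
        med = (
            median_min_feret(retained["min_feret_nm"].to_numpy())
            if len(retained)
            else np.nan
        )
        rows.append(
            {"mode": mode, "median_min_feret_nm": med, "n_particles": log["n_retained"]}
        )
    table = pd.DataFrame(rows)
    meds = table["median_min_feret_nm"].to_numpy()
    finite = meds[np.isfinite(meds)]
    if len(finite) >= 2:
        spread = (finite.max() - finite.min()) / np.mean(finite)
    else:
        spread = np.nan
    table.attrs["max_pairwise_rel_diff"] = float(spread)
    return table
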