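"""Exponential growth rates from OD600 curves and growth-rate-ratio tests.

The rate estimate is the ordinary least-squares slope of ln(OD) versus
time over the points in logarithmic phase (0.05 < OD600 < 0.5), in units
of 1/h (natural log, so the slope is the continuous growth rate; the
base only rescales rates and cancels in every ratio).  Condition effects
are expressed as the growth-rate ratio — the sup35 strain's
YPD-normalized rate over the wildtype strain's — and strain backgrounds
are compared per condition with Welch t-tests followed by Storey
q-value FDR estimation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

logger = logging.getLogger(__name__)

OD_LOWER, OD_UPPER = 0.05, 0.5
MIN_FIT_POINTS = 4
MIN_MEASUREMENTS = 8  # replication the assays report: >= 8 measurements,
MIN_BIOLOGICAL = 4    # including >= 4 biological replicates


@dataclass
class GrowthCurve:
    """OD600 time series for one well."""

    time_h: np.ndarray
    od: np.ndarray
    well: str = ""
    strain: str = ""
    genotype: str = ""
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.time_h.shape != self.od.shape:
            raise ValueError("time and OD must have equal length")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD must be >= 0")


@dataclass
class GrowthRate:
    """Fitted log-phase exponential rate with its valid-window metadata."""

    rate: float
    n_points: int
    t_start: float
    t_end: float
    r_squared: float
    ok: bool = True
    flag: str = ""

    @classmethod
    def failed(cls, reason: str) -> "GrowthRate":
        return cls(np.nan, 0, np.nan, np.nan, np.nan, ok=False, flag=reason)


def fit_growth_rate(
    curve: GrowthCurve,
    od_lower: float = OD_LOWER,
    od_upper: float = OD_UPPER,
    min_points: int = MIN_FIT_POINTS,
) -> GrowthRate:
    """OLS slope of ln(OD) vs time over points with od_lower < OD < od_upper.

    Returns a flagged failure (``rate = NaN``, ``ok = False``) when fewer
    than ``min_points`` readings fall in the log-phase window.
    """
    in_phase = (curve.od > od_lower) & (curve.od < od_upper)
    n = int(in_phase.sum())
    if n < min_points:
        return GrowthRate.failed(f"only {n} points with {od_lower} < OD < {od_upper}")
    t = curve.time_h[in_phase]
    y = np.log(curve.od[in_phase])
    res = stats.linregress(t, y)
    return GrowthRate(
        rate=float(res.slope),
        n_points=n,
        t_start=float(t[0]),
        t_end=float(t[-1]),
        r_squared=float(res.rvalue**2),
    )


def fit_rate_table(
    curves: list[GrowthCurve], **fit_kwargs
) -> pd.DataFrame:
    """Fit every curve; one row per well with labels and fit diagnostics."""
    rows = []
    for c in curves:
        g = fit_growth_rate(c, **fit_kwargs)
        rows.append(
            {
                "well": c.well,
                "strain": c.strain,
                "genotype": c.genotype,
                "condition": c.condition,
                "replicate": c.replicate,
                "rate": g.rate,
                "n_points": g.n_points,
                "r_squared": g.r_squared,
                "ok": g.ok,
                "flag": g.flag,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GrowthRateRatio:
    """sup35-over-wildtype growth-rate ratio after YPD normalization."""

    strain: str
    condition: str
    ratio: float
    sd: float
    n_measurements: int
    replicate_ratios: np.ndarray = field(default_factory=lambda: np.array([]))
    ok: bool = True
    flag: str = ""


def growth_rate_ratio(
    rates: pd.DataFrame,
    strain: str,
    condition: str,
    control_condition: str = "YPD",
    wildtype_label: str = "wildtype",
    mutant_label: str = "sup35",
) -> GrowthRateRatio:
    """Ratio of YPD-normalized mean rates, sup35 over wildtype.

    ``rates`` needs columns ``strain, genotype, condition, rate`` (one
    row per measurement).  Each genotype's condition rate is normalized
    by that genotype's mean rate in ``control_condition``; the ratio of
    the normalized means is reported.  Replicate-level ratios (each
    sup35 measurement over the wildtype mean) feed the strain
    comparisons; dispersion is propagated by the delta method from the
    replicate SDs of both genotypes.

    Fewer than 8 measurements flags the estimate; a zero or failed
    wildtype rate yields ``ok=False`` with ``ratio=NaN``.
    """
    def grab(genotype, cond):
        sel = rates[
            (rates["strain"] == strain)
            & (rates["genotype"] == genotype)
            & (rates["condition"] == cond)
        ]["rate"].to_numpy()
        return sel[np.isfinite(sel)]

    wt_cond, wt_ctrl = grab(wildtype_label, condition), grab(wildtype_label, control_condition)
    mu_cond, mu_ctrl = grab(mutant_label, condition), grab(mutant_label, control_condition)
    for name, arr in (
        ("wildtype condition", wt_cond),
        ("wildtype control", wt_ctrl),
        ("sup35 condition", mu_cond),
        ("sup35 control", mu_ctrl),
    ):
        if arr.size == 0:
            return GrowthRateRatio(
                strain, condition, np.nan, np.nan, 0, ok=False,
                flag=f"no {name} measurements",
            )
    wt_norm_mean = wt_cond.mean() / wt_ctrl.mean()
    if wt_norm_mean == 0 or not np.isfinite(wt_norm_mean):
        return GrowthRateRatio(
            strain, condition, np.nan, np.nan, 0, ok=False, flag="zero wildtype rate"
        )
    mu_norm = mu_cond / mu_ctrl.mean()
    ratio = mu_norm.mean() / wt_norm_mean
    rep_ratios = mu_norm / wt_norm_mean
    # Delta method: var(ratio)/ratio^2 = sum of squared relative SEs of
    # the four means entering the ratio of normalized means.
    rel = 0.0
    for arr in (mu_cond, mu_ctrl, wt_cond, wt_ctrl):
        if arr.size > 1 and arr.mean() != 0:
            rel += arr.var(ddof=1) / arr.size / arr.mean() ** 2
    sd = abs(ratio) * np.sqrt(rel)
    n = int(mu_cond.size)
    flag = ""
    if n < MIN_MEASUREMENTS:
        flag = f"fewer than {MIN_MEASUREMENTS} measurements (n={n})"
    return GrowthRateRatio(
        strain, condition, float(ratio), float(sd), n,
        replicate_ratios=rep_ratios, flag=flag,
    )


def compare_strain_ratios(
    ratios_by: dict[str, GrowthRateRatio],
    ratios_rm: dict[str, GrowthRateRatio],
) -> pd.DataFrame:
    """Welch t-test of BY vs RM replicate-level ratios per condition.

    ``ratios_by``/``ratios_rm`` map condition -> GrowthRateRatio.
    Conditions with fewer than two replicate ratios in either strain get
    ``p = NaN`` with a flag.  A ``q`` column (Storey) is appended when
    two or more conditions are testable.
    """
    rows = []
    for cond in sorted(set(ratios_by) & set(ratios_rm)):
        a = ratios_by[cond].replicate_ratios
        b = ratios_rm[cond].replicate_ratios
        if len(a) < 2 or len(b) < 2:
            rows.append((cond, np.nan, np.nan, np.nan, "fewer than 2 replicates"))
            continue
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            (cond, ratios_by[cond].ratio, ratios_rm[cond].ratio, p, "")
        )
    out = pd.DataFrame(rows, columns=["condition", "ratio_BY", "ratio_RM", "p", "flag"])
    testable = out["p"].notna()
    if testable.sum() >= 1:
        q, pi0 = storey_qvalues(out.loc[testable, "p"].to_numpy())
        out.loc[testable, "q"] = q
        out.attrs["pi0"] = pi0
    return out


def one_sample_ratio_test(ratio: GrowthRateRatio, null_value: float = 1.0) -> float:
    """p-value of the one-sample t-test of replicate ratios against 1."""
    r = ratio.replicate_ratios
    if len(r) < 2:
        return np.nan
    return float(stats.ttest_1samp(r, null_value).pvalue)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's smoother estimate of the null proportion pi0.

    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))`` on a lambda grid,
    smoothed with a cubic spline and read off at the largest lambda;
    clipped to (0, 1].  With fewer than ~20 p-values the smoother is
    unstable, so pi0 = 1 (conservative) is returned.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m < 20:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    pi0_lambda = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambdas])
    spline = UnivariateSpline(lambdas, pi0_lambda, k=3)
    pi0 = float(spline(lambdas[-1]))
    return float(np.clip(pi0, 1.0 / m, 1.0))


def storey_qvalues(
    pvalues: np.ndarray, pi0: float | None = None
) -> tuple[np.ndarray, float]:
    """Storey q-values: ``q(p_(i)) = min_{j>=i} pi0 * m * p_(j) / j``.

    Returns ``(qvalues, pi0)`` with q-values in the input order,
    monotone in p and capped at 1.  ``pi0=None`` estimates it with the
    spline smoother (forced to 1 for a single p-value).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy(), 1.0
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, float(pi0)
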