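"""Three-factor interaction model for growth rate.

Growth rate is modelled by ordinary least squares on the full 2x2x2
factorial of genetic background (BY vs RM), SUP35 allelic status
(wildtype vs the readthrough-elevating sup35 mutant) and SKY1 allelic
status (BY vs RM allele), with all two- and three-way interactions.
Treatment coding uses RM background, mutant SUP35 and RM SKY1 as
reference levels, so the reported contrasts are "BG (BY)", "SUP35 (WT)"
and "SKY1 (BY)".  An optional preliminary regression removes the SKY1
mRNA-level covariate and refits the factorial model on the residuals.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

FACTORS = {
    "background": ("RM", "BY"),   # (reference, contrast)
    "sup35": ("sup35", "WT"),
    "sky1": ("RM", "BY"),
}
COEF_NAMES = [
    "(Intercept)",
    "BG (BY)",
    "SUP35 (WT)",
    "SKY1 (BY)",
    "BG (BY): SUP35 (WT)",
    "BG (BY): SKY1 (BY)",
    "SUP35 (WT): SKY1 (BY)",
    "BG (BY): SUP35 (WT): SKY1 (BY)",
]
TABLE_COLUMNS = ["Estimate", "Std. Error", "t value", "Pr (>|t|)"]


def _indicator(df: pd.DataFrame, factor: str) -> np.ndarray:
    ref, alt = FACTORS[factor]
    vals = df[factor].astype(str)
    bad = set(vals) - {ref, alt}
    if bad:
        raise ValueError(f"unknown level(s) {bad} for factor {factor!r}")
    return (vals == alt).to_numpy(dtype=float)


def design_matrix(df: pd.DataFrame) -> np.ndarray:
    """Treatment-coded full-interaction design (8 columns, COEF_NAMES order)."""
    bg = _indicator(df, "background")
    su = _indicator(df, "sup35")
    sk = _indicator(df, "sky1")
    return np.column_stack(
        [np.ones(len(df)), bg, su, sk, bg * su, bg * sk, su * sk, bg * su * sk]
    )


def validate_table(df: pd.DataFrame, min_replicates: int = 1) -> None:
    """Check the 2x2x2 design is complete; name any missing cell."""
    for col in ("background", "sup35", "sky1", "rate"):
        if col not in df.columns:
            raise ValueError(f"table missing column {col!r}")
    for bg, su, sk in itertools.product(*(FACTORS[f] for f in FACTORS)):
        n = len(
            df[
                (df["background"].astype(str) == bg)
                & (df["sup35"].astype(str) == su)
                & (df["sky1"].astype(str) == sk)
            ]
        )
        if n < min_replicates:
            raise ValueError(
                f"design cell background={bg}, sup35={su}, sky1={sk} has "
                f"{n} rows (need >= {min_replicates})"
            )


class ThreeFactorModel:
    """OLS model of growth rate on BG x SUP35 x SKY1 with all interactions.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``background`` (BY|RM), ``sup35`` (WT|sup35), ``sky1``
        (BY|RM), ``rate`` (YPD-normalized growth rate) and optionally
        ``mrna`` (relative SKY1 mRNA level) and ``replicate``.
    residualize_mrna : bool
        Regress rate on the mRNA covariate first (intercept + slope) and
        fit the factorial model to the residuals.
    """

    def __init__(self, data: pd.DataFrame, residualize_mrna: bool = False):
        validate_table(data)
        self.data = data.reset_index(drop=True)
        self.residualize = residualize_mrna
        if residualize_mrna and "mrna" not in data.columns:
            raise ValueError("residualize_mrna=True requires an 'mrna' column")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ThreeFactorModel":
        return cls(data, **kwargs)

    def fit(self) -> "FactorialResults":
        df = self.data
        mrna_fit = None
        response = df["rate"].to_numpy(dtype=float)
        if self.residualize:
            df2, mrna_fit = residualize_mrna(df)
            response = df2["rate"].to_numpy(dtype=float)
        X = design_matrix(df)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        cells = df.groupby(["background", "sup35", "sky1"]).size()
        if (cells < 2).any():
            logger.warning(
                "cells with < 2 replicates: coefficient SEs are unreliable"
            )
        ols = sm.OLS(response, X).fit()
        return FactorialResults(model=self, sm_results=ols, mrna_fit=mrna_fit)


@dataclass
class FactorialResults:
    """Coefficient table, residuals and diagnostics of the factorial fit."""

    model: ThreeFactorModel
    sm_results: object
    mrna_fit: dict | None = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.sm_results.params, index=COEF_NAMES)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.sm_results.bse, index=COEF_NAMES)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.sm_results.pvalues, index=COEF_NAMES)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self.sm_results.resid)

    @property
    def fittedvalues(self) -> np.ndarray:
        return np.asarray(self.sm_results.fittedvalues)

    def coef_table(self) -> pd.DataFrame:
        """Four-column coefficient table (Estimate, SE, t, two-sided p)."""
        return pd.DataFrame(
            {
                "Estimate": self.sm_results.params,
                "Std. Error": self.sm_results.bse,
                "t value": self.sm_results.tvalues,
                "Pr (>|t|)": self.sm_results.pvalues,
            },
            index=COEF_NAMES,
        )

    def summary(self) -> str:
        header = "Growth rate ~ BG * SUP35 * SKY1"
        if self.model.residualize:
            header += "  (on residuals after removing the SKY1 mRNA covariate)"
        table = self.coef_table().to_string(float_format=lambda v: f"{v:.4g}")
        extra = (
            f"\nn = {int(self.sm_results.nobs)}, "
            f"residual df = {int(self.sm_results.df_resid)}, "
            f"R^2 = {self.sm_results.rsquared:.4f}"
        )
        return "\n".join([header, "=" * len(header), table, extra])


def residualize_mrna(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Replace rates by residuals of ``rate ~ 1 + mrna``.

    A constant mRNA covariate leaves the slope undefined; the rates are
    then centred only and the result flagged.
    """
    if "mrna" not in table.columns:
        raise ValueError("table has no 'mrna' column")
    if table["mrna"].isna().any():
        raise ValueError("mRNA level missing for some rows")
    out = table.copy()
    y = table["rate"].to_numpy(dtype=float)
    x = table["mrna"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        logger.warning("constant mRNA covariate: slope undefined, centering rates")
        out["rate"] = y - y.mean()
        return out, {"intercept": float(y.mean()), "slope": np.nan, "degenerate": True}
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    out["rate"] = y - X @ coef
    return out, {
        "intercept": float(coef[0]),
        "slope": float(coef[1]),
        "degenerate": False,
    }


def fit_three_factor(
    table: pd.DataFrame, residualize: bool = False
) -> FactorialResults:
    """Functional wrapper: build the model and fit in one call."""
    return ThreeFactorModel(table, residualize_mrna=residualize).fit()
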