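"""Trait construction: covariate screens, inverse-normal residuals, eGFR.

The GWAS screen operates on a covariate-adjusted, rank-normalized trait:
the raw phenotype is regressed on the chosen covariates by OLS and the
residuals are mapped to normal quantiles by rank (Blom offset).  The joint
linkage/association path can instead estimate covariates simultaneously
inside the mixed model; both modes are supported and the mode used is
recorded in scan metadata.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

log = logging.getLogger(__name__)


def egfr_mdrd(serum_creatinine, age, is_female=False, is_black=False):
    """Estimated GFR (ml/min/1.73 m^2) from the 4-variable MDRD equation.

    eGFR = 186 * SCr^-1.154 * age^-0.203 * (0.742 if female) * (1.210 if black)

    with serum creatinine in mg/dl and age in years.  Inputs broadcast.
    """
    scr = np.asarray(serum_creatinine, dtype=float)
    a = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(a <= 0):
        raise ValueError("serum creatinine and age must be positive")
    out = 186.0 * scr ** -1.154 * a ** -0.203
    out = out * np.where(np.asarray(is_female, dtype=bool), 0.742, 1.0)
    out = out * np.where(np.asarray(is_black, dtype=bool), 1.210, 1.0)
    return out if out.shape else float(out)


def add_derived_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Append age^2 and age x sex interaction columns when age/female exist."""
    out = table.copy()
    if "age" in out.columns:
        out["age2"] = out["age"] ** 2
        if "female" in out.columns:
            out["age_x_female"] = out["age"] * out["female"]
    return out


def residualize(
    trait: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
    columns: list[str] | None = None,
) -> tuple[pd.Series, sm.regression.linear_model.RegressionResultsWrapper | None]:
    """OLS residuals of the trait on an intercept plus selected covariates.

    Rows with any missing value are dropped (casewise deletion, logged).
    Returns (residuals indexed like the complete-case input, fitted OLS
    results or None when no covariates are given).

    Raises
    ------
    ValueError
        If the design matrix is rank deficient; the message names the
        collinear column(s).
    """
    y = pd.Series(np.asarray(trait, dtype=float))
    if covariates is None or (columns is not None and len(columns) == 0):
        resid = y - y.mean()
        resid = resid.dropna()
        return resid, None
    X = covariates[columns] if columns is not None else covariates
    X = X.reset_index(drop=True).astype(float)
    keep = (~y.isna()) & (~X.isna().any(axis=1))
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("residualize: dropping %d incomplete case(s)", n_drop)
    Xc = sm.add_constant(X[keep], has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        # identify columns whose removal restores full rank
        bad = []
        mat = Xc.to_numpy()
        for k, name in enumerate(Xc.columns):
            sub = np.delete(mat, k, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                bad.append(name)
        raise ValueError(f"design matrix is rank deficient; collinear column(s): {bad}")
    fit = sm.OLS(y[keep], Xc).fit()
    return pd.Series(fit.resid, index=y.index[keep]), fit


def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom offset.

    The value of rank r among n maps to Phi^-1((r - c) / (n - 2c + 1)) with
    c = 3/8 by default; tied values share their average rank, hence an
    identical transformed score.  Raises on constant input (the transform
    is undefined) and on missing values.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with at least two values")
    if np.isnan(x).any():
        raise ValueError("missing values not allowed; residualize first")
    if np.all(x == x[0]):
        raise ValueError("constant vector: inverse-normal transform undefined")
    r = rankdata(x, method="average")
    return norm.ppf((r - offset) / (x.size - 2.0 * offset + 1.0))


def prepare_trait(
    phenotypes: pd.DataFrame,
    trait: str,
    covariate_columns: list[str] | None = None,
    offset: float = 3.0 / 8.0,
) -> pd.DataFrame:
    """Residualize then inverse-normal transform one trait column.

    Returns a frame (iid, residual, transformed) restricted to complete
    cases, aligned for use against a pedigree.
    """
    resid, _ = residualize(
        phenotypes[trait],
        phenotypes if covariate_columns else None,
        covariate_columns,
    )
    z = inverse_normal(resid.to_numpy(), offset=offset)
    return pd.DataFrame(
        {
            "iid": phenotypes["iid"].to_numpy()[resid.index],
            "residual": resid.to_numpy(),
            "transformed": z,
        }
    )
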