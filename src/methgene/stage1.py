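"""Stage 1: kinship mixed model for the change in ln-triglycerides.

The trait is y = ln(follow-up TG) - ln(baseline TG), with each side
ln-transformed *before* averaging duplicate visit measurements.  It is
regressed on the covariates plus an additive polygenic random effect g with
cov(g) = 2 Phi sigma2_g, cov(e) = sigma2_e I, fitted by REML.  Because the
model has a single relationship kernel, one eigendecomposition of 2 Phi
reduces REML to a 1-D profile optimisation over the variance ratio
lambda = sigma2_g / sigma2_e.

The per-individual residual handed to stage 2 is r_i = yhat_i - y_i.  By
default yhat includes the BLUP of the polygenic effect ("conditional"
residuals), which removes the familial correlation and makes unrestricted
permutation of the residuals defensible; a "marginal" option (yhat = X
betahat only) is exposed.  Every downstream statistic is invariant to the
sign of r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .datatypes import KinshipMatrix

__all__ = ["Stage1Fit", "derive_phenotype", "fit_stage1", "reml_loglik_dense"]


@dataclass
class Stage1Fit:
    fixed_effects: np.ndarray
    fixed_effect_names: list[str]
    sigma2_g: float
    sigma2_e: float
    residuals: np.ndarray  # r_i = yhat_i - y_i
    loglik: float
    residual_type: str

    @property
    def variance_ratio(self) -> float:
        return self.sigma2_g / self.sigma2_e if self.sigma2_e > 0 else np.inf


def _ln_average(values: np.ndarray) -> np.ndarray:
    """ln-transform each available measurement, then average per row."""
    if (np.nan_to_num(values, nan=1.0) <= 0).any():
        raise ValueError("measurements must be strictly positive for the ln transform")
    with warnings.catch_warnings():
        # rows with no measurement at all legitimately yield NaN here and
        # are excluded downstream
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(np.log(values), axis=1)


def derive_phenotype(pheno: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Change score and stage-1 design covariates from the visit table.

    Returns ``(y, covariates)`` where y = mean(ln follow-up) - mean(ln
    baseline); baseline HDL and baseline TG covariates get the same
    ln-then-average rule.  Individuals with no measurement at baseline or
    follow-up are excluded (both outputs are index-aligned on the survivors).
    """
    tg_base = _ln_average(pheno[["tg_baseline_1", "tg_baseline_2"]].to_numpy())
    tg_follow = _ln_average(pheno[["tg_followup_1", "tg_followup_2"]].to_numpy())
    hdl = _ln_average(pheno[["hdl_1", "hdl_2"]].to_numpy())

    ok = np.isfinite(tg_base) & np.isfinite(tg_follow) & np.isfinite(hdl)
    y = pd.Series(tg_follow - tg_base, index=pheno.index, name="delta_ln_tg")[ok]
    cov = pd.DataFrame(
        {
            "age": pheno["age"],
            "center": pheno["center"],
            "smoking": pheno["smoking"],
            "msdx_score": pheno["msdx_score"],
            "fasting_time": pheno["fasting_time"],
            "ln_hdl_base": hdl,
            "ln_tg_base": tg_base,
        },
        index=pheno.index,
    )[ok]
    return y, cov


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    x = covariates.to_numpy(dtype=float)
    names = ["intercept", *covariates.columns]
    x = np.column_stack([np.ones(len(x)), x])
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(x)
        bad = [names[j] for j in range(x.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"design matrix is rank deficient (collinear: {bad})")
    return x, names


def reml_loglik_dense(
    y: np.ndarray, x: np.ndarray, k2: np.ndarray, sigma2_g: float, sigma2_e: float
) -> float:
    """Restricted log-likelihood evaluated with dense matrices.

    Brute-force reference used to validate the profiled eigendecomposition
    path; O(n^3) per call.
    """
    n, p = x.shape
    v = sigma2_g * k2 + sigma2_e * np.eye(n)
    sign, logdet_v = np.linalg.slogdet(v)
    vinv = np.linalg.inv(v)
    xtvx = x.T @ vinv @ x
    beta = np.linalg.solve(xtvx, x.T @ vinv @ y)
    resid = y - x @ beta
    _, logdet_x = np.linalg.slogdet(xtvx)
    return -0.5 * (logdet_v + logdet_x + resid @ vinv @ resid + (n - p) * np.log(2 * np.pi))


def fit_stage1(
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    kinship: KinshipMatrix,
    residual_type: str = "conditional",
) -> Stage1Fit:
    """REML fit of y = X beta + g + e with cov(g) = 2 Phi sigma2_g.

    The eigendecomposition 2 Phi = U D U' rotates the model to independent
    coordinates with variances sigma2_e (lambda d_i + 1); the restricted
    likelihood is profiled over lambda with a bounded scalar search (plus an
    explicit lambda = 0 boundary check).  Residuals are r = yhat - y with
    yhat = X betahat + BLUP(g) (conditional, default) or X betahat
    (marginal).
    """
    y = np.asarray(y, dtype=float)
    x, names = _design_matrix(covariates)
    n, p = x.shape
    if kinship.n != n:
        raise ValueError("kinship dimension does not match phenotype length")

    k2 = kinship.additive_relationship()
    d, u = np.linalg.eigh(k2)
    if d.min() < -1e-8 * max(1.0, d.max()):
        raise ValueError("kinship matrix is not positive semidefinite")
    d = np.clip(d, 0.0, None)
    yt = u.T @ y
    xt = u.T @ x

    def neg_restricted_ll(log10_lam: float) -> float:
        lam = 10.0**log10_lam
        w = lam * d + 1.0
        xtw = xt / w[:, None]
        xtwx = xt.T @ xtw
        beta = np.linalg.solve(xtwx, xtw.T @ yt)
        resid = yt - xt @ beta
        rss_w = float(resid @ (resid / w))
        sigma2_e = rss_w / (n - p)
        _, logdet_xtwx = np.linalg.slogdet(xtwx)
        ll = -0.5 * (
            (n - p) * np.log(sigma2_e)
            + np.sum(np.log(w))
            + logdet_xtwx
            + (n - p)
            + (n - p) * np.log(2 * np.pi)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-8.0, 4.0), method="bounded",
        options={"xatol": 1e-6},
    )
    candidates = [(res.fun, 10.0**res.x)]
    candidates.append((neg_restricted_ll(-12.0), 0.0))  # boundary sigma2_g = 0
    negll, lam = min(candidates, key=lambda t: t[0])

    w = lam * d + 1.0
    xtw = xt / w[:, None]
    xtwx = xt.T @ xtw
    beta = np.linalg.solve(xtwx, xtw.T @ yt)
    resid_rot = yt - xt @ beta
    sigma2_e = float(resid_rot @ (resid_rot / w)) / (n - p)
    sigma2_g = lam * sigma2_e

    if residual_type == "conditional":
        # e_hat = sigma2_e V^{-1} (y - X beta); r = yhat - y = -e_hat
        r = -(u @ (resid_rot / w))
    elif residual_type == "marginal":
        r = x @ beta - y
    else:
        raise ValueError("residual_type must be 'conditional' or 'marginal'")

    return Stage1Fit(
        fixed_effects=beta,
        fixed_effect_names=names,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        residuals=r,
        loglik=-negll,
        residual_type=residual_type,
    )
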