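"""Per-variant association models for detecting non-additive allelic effects.

Three models are fitted per variant, always with the same covariate
adjustment:

* dominance-deviation model — outcome ~ minor-allele count + heterozygote
  indicator (+ covariates); logistic for binary outcomes, linear for
  continuous ones;
* genotypic model — outcome ~ genotype category with the heterozygote as the
  reference class (+ covariates), reporting both homozygote-vs-heterozygote
  contrasts;
* additive-only model — the dominance-deviation model with the heterozygote
  term removed (used for conventional risk-score weights).

All p-values are two-sided Wald tests on a normal approximation,
``p = 2 * Phi(-|coef / se|)``.  Rows with a missing genotype are dropped for
the variant being tested only.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotypes import MISSING


@dataclasses.dataclass
class DomDevFit:
    """Additive + dominance-deviation coefficients for one variant."""

    variant_id: str
    beta: float
    gamma: float
    se_beta: float
    se_gamma: float
    p_beta: float
    p_gamma: float
    n_used: int
    model: str  # "logistic" or "linear"
    converged: bool = True
    message: str = ""
    loglik: float = float("nan")


@dataclasses.dataclass
class GenotypicFit:
    """Heterozygote-referenced genotype-class contrasts for one variant."""

    variant_id: str
    effect_AA_vs_AB: float
    effect_BB_vs_AB: float
    se_AA_vs_AB: float
    se_BB_vs_AB: float
    p_AB_AA: float
    p_AB_BB: float
    n_used: int
    model: str
    converged: bool = True
    message: str = ""
    loglik: float = float("nan")


def wald_p(coefficient: float, se: float) -> float:
    """Two-sided normal-approximation Wald p-value, ``2 * Phi(-|coef/se|)``."""
    if not se > 0:
        raise ValueError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(coefficient / se)))


def _design(columns: list[np.ndarray], covariates: pd.DataFrame | None,
            keep: np.ndarray) -> np.ndarray:
    parts = [np.ones(keep.sum())] + [c[keep].astype(float) for c in columns]
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float)[keep])
    return np.column_stack(parts)


def _fit(X: np.ndarray, y: np.ndarray, model: str):
    """Fit OLS or logistic; returns (params, bse, llf, converged, message)."""
    if model == "linear":
        res = sm.OLS(y, X).fit()
        return res.params, res.bse, res.llf, True, ""
    if model != "logistic":
        raise ValueError(f"unknown model {model!r}")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=False, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", False))
        finite = bool(np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)))
        msg = "" if (converged and finite) else "non-convergence or separation"
        return res.params, res.bse, res.llf, converged and finite, msg
    except Exception as exc:  # separation, singular Hessian, ...
        k = X.shape[1]
        nan = np.full(k, np.nan)
        return nan, nan, float("nan"), False, f"logistic fit failed: {exc}"


def _check_outcome(y: np.ndarray, model: str) -> None:
    if np.unique(y).size < 2:
        raise ValueError("outcome is degenerate (single value)")
    if model == "logistic" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("logistic model requires a 0/1 outcome")


def infer_model(outcome: np.ndarray) -> str:
    vals = np.unique(outcome[~np.isnan(outcome)])
    return "logistic" if set(vals) <= {0.0, 1.0} else "linear"


def fit_domdev(
    genotypes: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    model: str | None = None,
    variant_id: str = "",
    include_domdev: bool = True,
) -> DomDevFit:
    """Joint fit of additive count + heterozygote indicator (+ covariates).

    With ``include_domdev=False`` this is the conventional additive GWAS
    model (gamma reported as exactly 0 with undefined SE/p).
    """
    g = np.asarray(genotypes)
    y = np.asarray(outcome, dtype=float)
    keep = (g != MISSING) & ~np.isnan(y)
    if model is None:
        model = infer_model(y[keep])
    yk = y[keep]
    _check_outcome(yk, model)
    gk = g[keep]
    if np.unique(gk).size < 2:
        return DomDevFit(variant_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, int(keep.sum()), model, False,
                         "fewer than two genotype classes present")
    cols = [g, (g == 1).astype(float)] if include_domdev else [g]
    X = _design(cols, covariates, keep)
    params, bse, llf, converged, msg = _fit(X, yk, model)
    if converged:
        p_beta = wald_p(params[1], bse[1])
        if include_domdev:
            gamma, se_g = float(params[2]), float(bse[2])
            p_gamma = wald_p(params[2], bse[2])
        else:
            gamma, se_g, p_gamma = 0.0, float("nan"), float("nan")
        return DomDevFit(variant_id, float(params[1]), gamma, float(bse[1]),
                         se_g, p_beta, p_gamma, int(keep.sum()), model,
                         True, "", float(llf))
    return DomDevFit(variant_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                     np.nan, int(keep.sum()), model, False, msg)


def fit_genotypic(
    genotypes: np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    model: str | None = None,
    variant_id: str = "",
) -> GenotypicFit:
    """Genotype-category fit with the heterozygote as reference.

    Requires all three genotype classes among the analysed rows; otherwise
    the variant cannot be assessed for full dominance/recessiveness and a
    flagged (non-converged) fit is returned.
    """
    g = np.asarray(genotypes)
    y = np.asarray(outcome, dtype=float)
    keep = (g != MISSING) & ~np.isnan(y)
    if model is None:
        model = infer_model(y[keep])
    yk = y[keep]
    _check_outcome(yk, model)
    gk = g[keep]
    if np.unique(gk).size < 3:
        return GenotypicFit(variant_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, int(keep.sum()), model, False,
                            "absent genotype class: full dominance/recessive "
                            "action cannot be assessed")
    # indicator columns for AA and BB; AB is the reference category
    X = _design([(g == 0).astype(float), (g == 2).astype(float)],
                covariates, keep)
    params, bse, llf, converged, msg = _fit(X, yk, model)
    if converged:
        return GenotypicFit(variant_id, float(params[1]), float(params[2]),
                            float(bse[1]), float(bse[2]),
                            wald_p(params[1], bse[1]), wald_p(params[2], bse[2]),
                            int(keep.sum()), model, True, "", float(llf))
    return GenotypicFit(variant_id, np.nan, np.nan, np.nan, np.nan, np.nan,
                        np.nan, int(keep.sum()), model, False, msg)


def assoc_table(fits: list[DomDevFit],
                genotypic_fits: list[GenotypicFit] | None = None) -> pd.DataFrame:
    """Tab-separated-friendly association table (one row per variant)."""
    rows = []
    gmap = {f.variant_id: f for f in genotypic_fits or []}
    for f in fits:
        row = {
            "variant_id": f.variant_id,
            "model": f.model,
            "n": f.n_used,
            "beta_add": f.beta,
            "se_add": f.se_beta,
            "p_add": f.p_beta,
            "beta_domdev": f.gamma,
            "se_domdev": f.se_gamma,
            "p_domdev": f.p_gamma,
            "converged": f.converged,
        }
        gfit = gmap.get(f.variant_id)
        if gfit is not None:
            row["p_AB_AA"] = gfit.p_AB_AA
            row["p_AB_BB"] = gfit.p_AB_BB
        rows.append(row)
    return pd.DataFrame(rows)
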