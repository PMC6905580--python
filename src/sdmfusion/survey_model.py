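"""Confidence-weighted logistic regression for the survey-based models.

Two configurations mirror the study design: the base G model (ground-survey
records only) and the GT model (ground plus thermal-imagery records).  Each
record's confidence rating enters as a prior case weight multiplying its
log-likelihood contribution,

    l(beta) = sum_i w_i * [ y_i log p_i + (1 - y_i) log(1 - p_i) ],
    p_i = expit(x_i' beta),

so a half-confidence record contributes half as much information as a
certain one.  Standard errors come from the inverse of the weighted
observed information at the maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .data_model import COVARIATE_COLUMNS

__all__ = ["FittedModel", "SeparationError", "fit_weighted_logistic", "predict_probability", "design_matrix"]

#: Term names of the full design: intercept + the six habitat covariates.
TERMS: tuple[str, ...] = ("intercept",) + COVARIATE_COLUMNS


class SeparationError(RuntimeError):
    """Perfect separation: the weighted likelihood has no finite maximizer."""


@dataclass
class FittedModel:
    """A fitted regression from either family, as consumed by the fusion stage.

    Attributes
    ----------
    family : {"binomial", "beta"}
    terms : coefficient names, intercept first
    coef, se : point estimates and standard errors (beta_o/s_o or beta_e/s_e)
    vcov : coefficient covariance matrix
    residual_df : residual degrees of freedom (v_o or v_e) for the fused t
        interval
    n_obs : number of records used
    converged : optimizer convergence flag
    aux : family-specific extras (Beta precision phi, expert random-effect SD,
        effective df absorbed by the random intercepts)
    """

    family: str
    terms: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    residual_df: float
    n_obs: int
    converged: bool = True
    link: str = "logit"
    aux: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coef = np.asarray(self.coef, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if self.coef.shape != self.se.shape:
            raise ValueError("coef and se must have the same length")
        if self.converged and np.any(self.se <= 0):
            raise ValueError("standard errors must be positive in a converged fit")

    def term_df(self) -> np.ndarray:
        """Per-term degrees of freedom for Wald t intervals.

        Defaults to the residual df for every term; a mixed fit overrides
        the intercept with the between-cluster (containment) df, since an
        intercept confounded with cluster effects is replicated only at the
        cluster level."""
        df = np.full(len(self.coef), float(self.residual_df))
        override = self.aux.get("df_by_term")
        if override is not None:
            df = np.asarray(override, dtype=float)
        return df

    def confidence_intervals(self, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
        """Per-coefficient Wald t intervals at level 1 - alpha."""
        from scipy import stats

        half = stats.t.ppf(1.0 - alpha / 2.0, self.term_df()) * self.se
        return self.coef - half, self.coef + half

    def coef_table(self) -> pd.DataFrame:
        """Coefficient table (term, estimate, se, residual_df) — the CSV schema
        shared by all model outputs."""
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": self.coef,
                "se": self.se,
                "residual_df": self.residual_df,
            }
        )


def design_matrix(z: pd.DataFrame, terms: Sequence[str] = TERMS) -> np.ndarray:
    """Stack an intercept column onto the standardized covariates, in the
    fixed term order shared by every model."""
    covs = [t for t in terms if t != "intercept"]
    missing = [c for c in covs if c not in z.columns]
    if missing:
        raise ValueError(f"standardized table is missing covariates {missing}")
    X = np.column_stack([np.ones(len(z)), z[covs].to_numpy(dtype=float)])
    return X


def _check_rank(X: np.ndarray, terms: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [terms[j] for j in np.where(diag < 1e-8 * diag.max())[0]]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"collinear column(s): {bad or 'unidentified'}"
        )


def fit_weighted_logistic(
    z: pd.DataFrame,
    y: np.ndarray | pd.Series,
    weights: np.ndarray | pd.Series,
    terms: Sequence[str] = TERMS,
) -> FittedModel:
    """Maximize the confidence-weighted Bernoulli log-likelihood.

    Parameters
    ----------
    z : standardized covariate table (reference scaling already applied)
    y : binary presence/absence per record
    weights : per-record confidence in (0, 1]

    The fit is IRLS via statsmodels' binomial GLM with ``var_weights``, which
    implements exactly the prior-case-weight likelihood above; residual df is
    the nominal n - p with p = 7 (intercept + six covariates), matching the
    degrees-of-freedom bookkeeping of the combined-model t intervals.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    X = design_matrix(z, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more records ({n}) than parameters ({p})")
    if not (y.min() == 0 and y.max() == 1):
        raise ValueError("need at least one presence and one absence")
    if np.any(w <= 0) or np.any(w > 1.0 + 1e-12):
        raise ValueError("weights must lie in (0, 1]")
    _check_rank(X, terms)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer binomial totals are intended
        model = sm.GLM(y, X, family=sm.families.Binomial(), var_weights=w)
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"weighted logistic fit failed: {exc}") from exc

    coef = np.asarray(res.params)
    if not np.all(np.isfinite(coef)) or np.abs(coef).max() > 50:
        raise SeparationError(
            "coefficients diverged (|beta| > 50): data are (quasi-)separated; "
            f"largest estimate {np.abs(coef).max():.1f}"
        )
    vcov = np.asarray(res.cov_params())
    return FittedModel(
        family="binomial",
        terms=tuple(terms),
        coef=coef,
        se=np.sqrt(np.diag(vcov)),
        vcov=vcov,
        residual_df=float(n - p),
        n_obs=n,
        converged=bool(res.converged),
    )


def predict_probability(model: FittedModel, z: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predicted presence probability expit(x'beta) at standardized sites."""
    if not model.converged:
        raise ValueError("cannot predict from a non-converged model")
    X = z if isinstance(z, np.ndarray) else design_matrix(z, model.terms)
    if X.shape[1] != len(model.coef):
        raise ValueError(
            f"design has {X.shape[1]} columns but model has {len(model.coef)} coefficients"
        )
    return expit(X @ model.coef)
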