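"""Inverse-variance pooling of survey-model and expert-model coefficients.

Both parents model a probability through a logit-linked linear predictor on
identically standardized covariates, so their coefficient vectors are
estimates of commensurate quantities.  Elementwise, with observation-data
estimates (beta_o, s_o) and elicited-data estimates (beta_e, s_e):

    beta_c = (beta_o / s_o^2 + beta_e / s_e^2) / (1 / s_o^2 + 1 / s_e^2)
    s_c^2  = (s_o^-2 + s_e^-2)^-1

i.e. the minimum-variance convex combination, with precisions adding.  The
combined t interval uses v_c = v_o + v_e residual degrees of freedom:

    beta_c +/- t_{alpha/2, v_c} * s_c.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .survey_model import FittedModel, design_matrix

__all__ = ["CombinedModel", "combine_estimates", "combined_confidence_interval", "predict_combined"]


@dataclass
class CombinedModel:
    """Fused coefficients, their pooled SDs and combined residual df."""

    terms: tuple[str, ...]
    beta_c: np.ndarray
    s_c: np.ndarray
    v_c: float
    alpha: float = 0.05
    provenance: tuple[str, str] = ("observation", "elicitation")

    def coef_table(self) -> pd.DataFrame:
        lo, hi = combined_confidence_interval(self, self.alpha)
        return pd.DataFrame(
            {
                "term": list(self.terms),
                "estimate": self.beta_c,
                "se": self.s_c,
                "residual_df": self.v_c,
                "ci_lower": lo,
                "ci_upper": hi,
            }
        )


def combine_estimates(
    mo: FittedModel,
    me: FittedModel,
    alpha: float = 0.05,
    provenance: tuple[str, str] | None = None,
) -> CombinedModel:
    """Pool two fitted models elementwise by inverse-variance weighting.

    The parents must be converged fits sharing coefficient names and order
    (hence identical covariate standardization).  The operation is symmetric
    in its arguments.
    """
    if mo.terms != me.terms:
        raise ValueError(f"coefficient terms differ: {mo.terms} vs {me.terms}")
    if not (mo.converged and me.converged):
        raise ValueError("both parent models must have converged")
    so = np.asarray(mo.se, dtype=float)
    se = np.asarray(me.se, dtype=float)
    if np.any(so <= 0) or np.any(se <= 0):
        raise ValueError("standard errors must be strictly positive")
    prec_o = so**-2
    prec_e = se**-2
    s2_c = 1.0 / (prec_o + prec_e)
    beta_c = (mo.coef * prec_o + me.coef * prec_e) * s2_c
    return CombinedModel(
        terms=mo.terms,
        beta_c=beta_c,
        s_c=np.sqrt(s2_c),
        v_c=float(mo.residual_df + me.residual_df),
        alpha=alpha,
        provenance=provenance or (mo.family, me.family),
    )


def combined_confidence_interval(
    cm: CombinedModel, alpha: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient t interval beta_c +/- t_{alpha/2, v_c} s_c."""
    a = cm.alpha if alpha is None else alpha
    if not 0.0 < a < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {a}")
    if cm.v_c <= 0:
        raise ValueError(f"combined residual df must be positive, got {cm.v_c}")
    half = stats.t.ppf(1.0 - a / 2.0, cm.v_c) * cm.s_c
    return cm.beta_c - half, cm.beta_c + half


def predict_combined(cm: CombinedModel, z: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Presence probability expit(x' beta_c) at standardized sites."""
    X = z if isinstance(z, np.ndarray) else design_matrix(z, cm.terms)
    if X.shape[1] != len(cm.beta_c):
        raise ValueError(
            f"design has {X.shape[1]} columns but model has {len(cm.beta_c)} coefficients"
        )
    return expit(X @ cm.beta_c)
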