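"""Performance modelling on dyad-level features.

The scenario checklist score (CPT) is rescaled to 0-10; *high performance*
is a score strictly above 7.5.  Three model families mirror the analysis
plan: a binomial logistic regression of high performance on sympathetic
predictors (with log-likelihood, McFadden pseudo-R2, AIC and in-sample
accuracy), a linear baseline, and the concave quadratic in dyad-mean
Poincare SD1 whose vertex locates the optimal arousal window
(vertex_x = -b/(2a), vertex_y = c - b^2/(4a) when a < 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ValidationError

__all__ = [
    "QuadraticFit",
    "LinearFit",
    "LogisticFit",
    "scale_cpt",
    "label_high_performance",
    "build_dyad_features",
    "fit_logistic",
    "fit_quadratic",
    "fit_linear",
    "predict_quadratic",
]

HIGH_PERFORMANCE_CUT = 7.5


def scale_cpt(raw: float, max_raw: float) -> float:
    """Rescale a raw checklist score to the 0-10 performance scale."""
    if max_raw <= 0:
        raise ValidationError("max_raw must be positive")
    if not 0 <= raw <= max_raw:
        raise ValidationError(f"raw score {raw} outside [0, {max_raw}]")
    return raw / max_raw * 10.0


def label_high_performance(score: float) -> bool:
    """High performance is a 0-10 score strictly above 7.5."""
    if not 0 <= score <= 10:
        raise ValidationError(f"score {score} outside [0, 10]")
    return score > HIGH_PERFORMANCE_CUT


def build_dyad_features(
    cohort_table: pd.DataFrame, dyads: pd.DataFrame
) -> pd.DataFrame:
    """Assemble the dyad-level feature table the models consume.

    Per dyad: team-member and team-leader pre-phase tonic EDA, team-leader
    pre-phase SCR rate, the dyad-mean SD1 (arithmetic mean of the two
    members' windowed scenario-phase SD1, in seconds), and the 0-10 CPT
    score rescaled from the raw checklist columns.
    """
    def pick(role: str, phase: str, metric: str, name: str) -> pd.Series:
        s = cohort_table[
            (cohort_table.role == role)
            & (cohort_table.phase == phase)
            & (cohort_table.metric == metric)
        ]
        return s.set_index("dyad_id")["value"].rename(name)

    sd1 = (
        cohort_table[
            (cohort_table.phase == "Sim") & (cohort_table.metric == "sd1")
        ]
        .groupby("dyad_id")["value"]
        .mean()
        .rename("dyad_sd1")
    )
    feats = pd.concat(
        [
            pick("TM", "pre", "tonic_eda", "tm_eda_pre"),
            pick("TL", "pre", "tonic_eda", "tl_eda_pre"),
            pick("TL", "pre", "scr_rate", "tl_scr_pre"),
            sd1,
        ],
        axis=1,
    )
    d = dyads.set_index("dyad_id")
    feats["cpt_score"] = [
        scale_cpt(d.loc[i, "cpt_raw"], d.loc[i, "cpt_max_raw"]) for i in feats.index
    ]
    feats["high_performance"] = [
        label_high_performance(s) for s in feats.cpt_score
    ]
    return feats.reset_index()


@dataclass
class LogisticFit:
    predictors: list
    coefficients: dict          # name -> estimate (incl. "intercept")
    pvalues: dict
    log_likelihood: float
    null_log_likelihood: float
    mcfadden_r2: float
    aic: float
    accuracy: float             # in-sample, probability cutoff 0.5
    n: int
    separation: bool = False
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "predictors": self.predictors,
            "coefficients": self.coefficients,
            "pvalues": self.pvalues,
            "log_likelihood": self.log_likelihood,
            "null_log_likelihood": self.null_log_likelihood,
            "mcfadden_r2": self.mcfadden_r2,
            "aic": self.aic,
            "accuracy": self.accuracy,
            "n": self.n,
            "separation": self.separation,
            "converged": self.converged,
        }


def fit_logistic(
    features: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "high_performance",
    standardize: bool = False,
    penalized_fallback: bool = False,
) -> LogisticFit:
    """Maximum-likelihood binomial logistic regression (IRLS).

    Reports the fitted log-likelihood, the intercept-only null
    log-likelihood, McFadden pseudo-R2 = 1 - ll/ll_null, AIC = 2k - 2 ll
    with k counting the intercept, and in-sample accuracy at a 0.5
    probability cutoff.  Complete separation is detected and flagged; with
    ``penalized_fallback`` an L2-regularized refit is returned instead of
    the diverging MLE.
    """
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    y = features[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("outcome has a single class; logistic fit undefined")
    X = features[list(predictors)].astype(float)
    if standardize:
        X = (X - X.mean()) / X.std(ddof=0)
    X = sm.add_constant(X, has_constant="add")

    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.Logit(y, X)
        try:
            res = model.fit(disp=0, maxiter=200)
        except Exception:
            separation = True
            res = None
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            separation = True
    if res is not None and (not res.mle_retvals.get("converged", True)):
        separation = separation or bool(np.max(np.abs(res.params)) > 1e3)

    if (separation and penalized_fallback) or res is None:
        res = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)

    params = np.asarray(res.params, dtype=float)
    try:
        pvals = np.asarray(res.pvalues, dtype=float)
    except Exception:
        pvals = np.full_like(params, np.nan)
    names = ["intercept"] + list(predictors)
    ll = float(model.loglike(params))
    ll_null = float(
        sm.Logit(y, np.ones((len(y), 1))).fit(disp=0).llf
    )
    k = len(params)
    prob = model.predict(params)
    acc = float(np.mean((prob > 0.5) == (y > 0.5)))
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    return LogisticFit(
        predictors=list(predictors),
        coefficients=dict(zip(names, map(float, params))),
        pvalues=dict(zip(names, map(float, pvals))),
        log_likelihood=ll,
        null_log_likelihood=ll_null,
        mcfadden_r2=float(1.0 - ll / ll_null) if ll_null != 0 else np.nan,
        aic=float(2 * k - 2 * ll),
        accuracy=acc,
        n=len(y),
        separation=separation,
        converged=converged,
    )


@dataclass
class QuadraticFit:
    a: float
    b: float
    intercept: float
    r2: float
    pvalues: dict = field(default_factory=dict)  # keys a, b, intercept
    n: int = 0
    degenerate: bool = False

    @property
    def vertex_x(self) -> Optional[float]:
        """Maximizer -b/(2a); defined only for a concave parabola (a < 0)."""
        return -self.b / (2.0 * self.a) if self.a < 0 else None

    @property
    def vertex_y(self) -> Optional[float]:
        return (
            self.intercept - self.b**2 / (4.0 * self.a) if self.a < 0 else None
        )

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "intercept": self.intercept,
            "r2": self.r2, "pvalues": self.pvalues, "n": self.n,
            "vertex_x": self.vertex_x, "vertex_y": self.vertex_y,
            "degenerate": self.degenerate,
        }


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float
    slope_pvalue: float
    n: int


def fit_quadratic(x, y) -> QuadraticFit:
    """Ordinary least squares of y on [x^2, x, 1] with vertex analytics.

    Coefficient p-values come from classical OLS t statistics.  A constant
    y yields the a = b = 0, r2 = 0 convention (flagged degenerate).  The
    vertex is reported only when the parabola is concave (a < 0), where
    -b/(2a) is the unique maximizer.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if len(np.unique(x)) < 3:
        raise ValidationError("quadratic fit needs >= 3 distinct x values")
    if np.ptp(y) == 0:
        return QuadraticFit(
            0.0, 0.0, float(y[0]), 0.0,
            pvalues={"a": np.nan, "b": np.nan, "intercept": np.nan},
            n=len(y), degenerate=True,
        )
    X = sm.add_constant(np.column_stack([x, x**2]), has_constant="add")
    res = sm.OLS(y, X).fit()
    c0, b, a = map(float, res.params)
    pv = {"intercept": float(res.pvalues[0]), "b": float(res.pvalues[1]), "a": float(res.pvalues[2])}
    return QuadraticFit(a, b, c0, float(res.rsquared), pvalues=pv, n=len(y))


def fit_linear(x, y) -> LinearFit:
    """Simple linear regression baseline (slope, intercept, r2, slope p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    if len(np.unique(x)) < 2:
        raise ValidationError("linear fit needs >= 2 distinct x values")
    res = stats_linregress(x, y)
    return res


def stats_linregress(x, y) -> LinearFit:
    from scipy import stats as _st

    r = _st.linregress(x, y)
    return LinearFit(
        slope=float(r.slope),
        intercept=float(r.intercept),
        r2=float(r.rvalue**2),
        slope_pvalue=float(r.pvalue),
        n=len(x),
    )


def predict_quadratic(fit: QuadraticFit, x) -> np.ndarray | float:
    """Evaluate a*x^2 + b*x + intercept at x (scalar or array)."""
    x = np.asarray(x, dtype=float)
    out = fit.a * x**2 + fit.b * x + fit.intercept
    return float(out) if out.ndim == 0 else out
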