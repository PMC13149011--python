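"""Regression estimators of the COP -> IRR curve from TND samples.

Four specifications, all binomial-likelihood regressions of case status:

* ``TNDLogit(transform="none")``      — logit(p) = b0 + b1 * X
* ``TNDLogit(transform="log1m_x")``   — logit(p) = b0 + b1 * ln(1 - X)
* ``TNDGam(transform="none")``        — logit(p) = b0 + f(X)
* ``TNDGam(transform="log1m_x")``     — logit(p) = b0 + f(ln(1 - X))

with ``f`` a penalized spline smooth (basis dimension 5, data-driven
penalty).  With heterogeneous baseline risk, ``risk_adjust=True`` adds a
main effect b2 * I(R = 2).  Because the TND odds ratio estimates the
incidence rate ratio, the fitted linear predictor maps to an IRR curve
via ``IRR(x, r) = exp(eta(x, r) - eta(0, low-risk))``; for the
transformed logit this is ``(1 - x)^b1 * exp(b2 * I(r = 2))``, so b1 = 1
recovers the true linear protection curve exactly.  The squared/cubic
sensitivity transforms ``ln(1 - X^2)`` and ``ln(1 - X^3)`` play the same
role when protection is a power of the COP.

Estimators follow the scikit-learn protocol (``fit(X, y)``,
``get_params``/``set_params``, trailing-underscore fitted attributes) so
they compose with sklearn model selection; the module-level
:func:`fit`/:func:`predict_irr` helpers are thin wrappers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "TRANSFORMS",
    "ModelSpec",
    "transform_exposure",
    "TNDLogit",
    "TNDGam",
    "fit",
    "predict_irr",
]

TRANSFORMS = ("none", "log1m_x", "log1m_x2", "log1m_x3")

_TRANSFORM_POWER = {"log1m_x": 1, "log1m_x2": 2, "log1m_x3": 3}

#: default penalty grid searched when fitting a GAM
_ALPHA_GRID = np.logspace(-3, 9, 13)


@dataclass(frozen=True)
class ModelSpec:
    """Serializable description of one estimator specification."""

    family: str = "logit"  # "logit" | "gam"
    transform: str = "none"
    risk_adjust: bool = False
    basis_dim: int = 5
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.family not in ("logit", "gam"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.family == "gam" and self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3 for a GAM")

    def build(self) -> "TNDLogit | TNDGam":
        if self.family == "logit":
            return TNDLogit(
                transform=self.transform,
                risk_adjust=self.risk_adjust,
                epsilon=self.epsilon,
            )
        return TNDGam(
            transform=self.transform,
            risk_adjust=self.risk_adjust,
            basis_dim=self.basis_dim,
            epsilon=self.epsilon,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def transform_exposure(x, transform: str = "none", epsilon: float = 1e-6):
    """g(X): identity, or ln(1 - X^m) for m in {1, 2, 3}, floored at ln(eps).

    The epsilon floor keeps the covariate finite for agents boosted to
    exactly X = 1 on the sampling day.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("COP level must lie in [0, 1]")
    if transform == "none":
        return x if x.ndim else float(x)
    try:
        m = _TRANSFORM_POWER[transform]
    except KeyError:
        raise ValueError(f"unknown transform {transform!r}") from None
    out = np.log(np.maximum(epsilon, 1.0 - x**m))
    return out if out.ndim else float(out)


def _as_cop_risk(X) -> tuple[np.ndarray, np.ndarray]:
    """Accept (n,) cop, (n, 2) [cop, risk], or a DataFrame with cop/risk."""
    if isinstance(X, pd.DataFrame):
        cop = X["cop"].to_numpy(float)
        risk = (
            X["risk"].to_numpy(int) if "risk" in X else np.ones(len(X), dtype=int)
        )
        return cop, risk
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        return X, np.ones(X.size, dtype=int)
    if X.ndim == 2 and X.shape[1] in (1, 2):
        cop = X[:, 0]
        risk = X[:, 1].astype(int) if X.shape[1] == 2 else np.ones(len(X), int)
        return cop, risk
    raise ValueError("X must be cop levels, [cop, risk] columns, or a DataFrame")


class _BaseTNDEstimator(BaseEstimator):
    """Shared validation, design-matrix assembly, and IRR prediction."""

    def _validate(self, X, y):
        cop, risk = _as_cop_risk(X)
        y = np.asarray(y)
        if y.shape != cop.shape:
            raise ValueError("X and y have inconsistent lengths")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary case status")
        if y.min() == y.max():
            raise ValueError("need both cases and controls to fit")
        if np.any(cop < 0) or np.any(cop > 1):
            raise ValueError("COP level must lie in [0, 1]")
        g = transform_exposure(cop, self.transform, self.epsilon)
        if np.ptp(g) == 0:
            raise ValueError("exposure is constant; slope is unidentifiable")
        if self.risk_adjust and len(np.unique(risk)) < 2:
            raise ValueError("risk_adjust=True requires both risk groups")
        return cop, risk, g, y.astype(float)

    def _parametric_exog(self, risk: np.ndarray) -> np.ndarray:
        cols = [np.ones(risk.size)]
        if self.risk_adjust:
            cols.append((risk == 2).astype(float))
        return np.column_stack(cols)

    def linear_predictor(self, cop, risk=1):
        """eta(X, R) on the fitted model's log-odds scale."""
        check_is_fitted(self, "result_")
        cop = np.atleast_1d(np.asarray(cop, dtype=float))
        risk = np.broadcast_to(np.asarray(risk, dtype=int), cop.shape)
        return self._eta(cop, risk)

    def predict_irr(self, cop, risk=1):
        """IRR(X, R) relative to a low-risk agent with X = 0."""
        cop = np.atleast_1d(np.asarray(cop, dtype=float))
        eta = self.linear_predictor(cop, risk)
        eta0 = self.linear_predictor(np.zeros(1), 1)
        return np.exp(eta - eta0[0])

    def predict_shape(self, cop, risk=1):
        """Within-group protection shape: IRR relative to the *same*
        group's X = 0 baseline, so the risk-group main effect cancels."""
        cop = np.atleast_1d(np.asarray(cop, dtype=float))
        eta = self.linear_predictor(cop, risk)
        eta0 = self.linear_predictor(np.zeros(1), risk)
        return np.exp(eta - eta0[0])


class TNDLogit(_BaseTNDEstimator):
    """Binomial-likelihood logistic regression of case status on g(X).

    Parameters
    ----------
    transform : {"none", "log1m_x", "log1m_x2", "log1m_x3"}
        Exposure transform g; "none" fits the (misspecified, under
        power-law protection) linear-in-X log odds.
    risk_adjust : bool
        Add a high-risk-group main effect.
    epsilon : float
        Floor for 1 - X^m inside the log transform.

    Attributes
    ----------
    intercept_, coef_ : float
        b0 and the slope b1 on the transformed exposure.
    risk_coef_ : float
        b2 on I(R = 2); 0.0 when ``risk_adjust=False``.
    result_ : statsmodels GLMResults
    """

    def __init__(
        self,
        transform: str = "log1m_x",
        risk_adjust: bool = False,
        epsilon: float = 1e-6,
    ):
        self.transform = transform
        self.risk_adjust = risk_adjust
        self.epsilon = epsilon

    def fit(self, X, y):
        cop, risk, g, y = self._validate(X, y)
        exog = np.column_stack([self._parametric_exog(risk), g])
        model = sm.GLM(y, exog, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError("logistic fit did not converge (separation?)")
        self.result_ = res
        self.intercept_ = float(res.params[0])
        self.risk_coef_ = float(res.params[1]) if self.risk_adjust else 0.0
        self.coef_ = float(res.params[-1])
        return self

    def _eta(self, cop, risk):
        g = transform_exposure(cop, self.transform, self.epsilon)
        return (
            self.intercept_
            + self.coef_ * g
            + self.risk_coef_ * (np.asarray(risk) == 2)
        )

    def to_json(self) -> str:
        check_is_fitted(self, "result_")
        return json.dumps(
            {
                "family": "logit",
                "transform": self.transform,
                "risk_adjust": self.risk_adjust,
                "epsilon": self.epsilon,
                "intercept": self.intercept_,
                "coef": self.coef_,
                "risk_coef": self.risk_coef_,
            }
        )


class TNDGam(_BaseTNDEstimator):
    """Penalized-spline binomial GAM: logit(p) = b0 + f(g(X)) [+ b2 I(R=2)].

    The smooth ``f`` is a B-spline basis of dimension ``basis_dim`` with a
    second-derivative penalty whose weight is chosen by minimizing the
    UBRE/AIC score (deviance + 2 * edf) over a fixed log-spaced grid — a
    data-driven penalty with the property that as the penalty grows the
    fit collapses onto the straight line in g(X), i.e. onto the
    corresponding logistic model.

    The spline basis is anchored on the full evaluable COP range (0 to
    0.99) joined with the observed data range, so the predicted IRR curve
    is finite on the whole evaluation grid; covariate values beyond the
    anchored range (agents above COP 0.99 under a log transform) are
    clamped to the basis boundary.

    Attributes
    ----------
    alpha_ : float
        Selected penalty weight.
    edf_ : float
        Effective degrees of freedom of the selected fit.
    result_ : statsmodels GLMGamResults
    """

    #: upper edge of the COP evaluation range the basis must cover
    _GRID_MAX_COP = 0.99

    def __init__(
        self,
        transform: str = "log1m_x",
        risk_adjust: bool = False,
        basis_dim: int = 5,
        epsilon: float = 1e-6,
        alphas=None,
    ):
        self.transform = transform
        self.risk_adjust = risk_adjust
        self.basis_dim = basis_dim
        self.epsilon = epsilon
        self.alphas = alphas

    def _basis_bounds(self, g: np.ndarray) -> tuple[float, float]:
        grid_ends = transform_exposure(
            np.array([0.0, self._GRID_MAX_COP]), self.transform, self.epsilon
        )
        lo = min(float(g.min()), float(np.min(grid_ends)))
        hi = max(float(g.max()), float(np.max(grid_ends)))
        if self.transform != "none":
            # keep knots on the populated part of the log scale; rows from
            # agents above COP 0.99 are clamped to the boundary instead
            lo = max(lo, float(np.min(grid_ends)))
        return lo, hi

    def _make_smoother(self, g: np.ndarray) -> BSplines:
        lo, hi = self._bounds_
        g = np.clip(g, lo, hi)
        return BSplines(
            g[:, None],
            df=[self.basis_dim],
            degree=[3],
            include_intercept=False,
            knot_kwds=[{"lower_bound": lo - 1e-9, "upper_bound": hi + 1e-9}],
        )

    def fit(self, X, y):
        if self.basis_dim < 3:
            raise ValueError("basis_dim must be >= 3")
        cop, risk, g, y = self._validate(X, y)
        self._bounds_ = self._basis_bounds(g)
        smoother = self._make_smoother(g)
        exog = self._parametric_exog(risk)
        alphas = _ALPHA_GRID if self.alphas is None else np.asarray(self.alphas)

        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for alpha in alphas:
                model = GLMGam(
                    y,
                    exog=exog,
                    smoother=smoother,
                    family=sm.families.Binomial(),
                    alpha=[float(alpha)],
                )
                try:
                    res = model.fit()
                except Exception:
                    continue
                if not np.all(np.isfinite(res.params)):
                    continue
                edf = float(np.sum(res.edf))
                score = float(res.deviance + 2.0 * edf)
                if best is None or score < best[0]:
                    best = (score, float(alpha), res, edf)
        if best is None:
            raise RuntimeError("GAM fit failed for every penalty weight")
        _, self.alpha_, self.result_, self.edf_ = best
        return self

    def _eta(self, cop, risk):
        g = transform_exposure(cop, self.transform, self.epsilon)
        g = np.clip(np.atleast_1d(g), *self._bounds_)
        exog = self._parametric_exog(np.asarray(risk).ravel())
        return np.asarray(
            self.result_.predict(exog=exog, exog_smooth=g[:, None], which="linear")
        )

    def to_json(self) -> str:
        check_is_fitted(self, "result_")
        return json.dumps(
            {
                "family": "gam",
                "transform": self.transform,
                "risk_adjust": self.risk_adjust,
                "basis_dim": self.basis_dim,
                "epsilon": self.epsilon,
                "alpha": self.alpha_,
                "edf": self.edf_,
                "coefficients": list(map(float, self.result_.params)),
                "basis_bounds": list(self._bounds_),
            }
        )


def fit(data, spec: ModelSpec):
    """Fit a :class:`ModelSpec` to a TND dataset; returns the fitted estimator."""
    cop, risk, case = data.design()
    est = spec.build()
    return est.fit(np.column_stack([cop, risk]), case)


def predict_irr(model, grid, risk=1) -> np.ndarray:
    """Predicted IRR curve of a fitted estimator on COP levels ``grid``."""
    return model.predict_irr(grid, risk)
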