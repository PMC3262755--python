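"""Rolling-window logistic risk models.

For each analysis month a standard logistic regression is fitted on the prior
up-to-11 months of pooled statewide cases and applied to every case in the
current month, giving the predicted probability that feeds the RA-SPRT
weight.  The first study month has no training data and is never scored;
early months train on however many prior months exist (one to ten).  Months
whose training window contains no deaths or no survivors cannot be fitted and
are skipped, with their cases excluded from surveillance.

On separation or IRLS non-convergence the fit falls back to a lightly
ridge-penalised refit (flagged on the model) rather than failing: early
low-volume windows are known to produce unstable coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .registry import RiskFactorSchema, as_frame, default_schema

__all__ = [
    "RiskModel",
    "ModelSequence",
    "DegenerateWindowError",
    "fit_monthly_model",
    "predict_case",
    "build_model_sequence",
]

logger = logging.getLogger(__name__)

#: predicted probabilities are clipped into this open interval so that the
#: SPRT weight (which requires p < 1) and its log stay finite
PROB_CLIP = 1e-6

#: absolute coefficient magnitude beyond which a fit is treated as separated
_SEPARATION_COEF = 15.0

#: ridge penalty (per observation) used by the stabilised fallback refit
_RIDGE_LAMBDA = 1.0


class DegenerateWindowError(ValueError):
    """Training window empty or single-class: the month must be skipped."""


@dataclass(frozen=True)
class RiskModel:
    """A fitted monthly logistic model and its training-window metadata."""

    analysis_month: pd.Period
    training_window: tuple[pd.Period, pd.Period]
    coefficients: dict[str, float]          # "intercept" first, then design columns
    n_train: int
    converged: bool
    stabilized: bool                        # True when the ridge fallback was used
    calibration: tuple[float, float]        # (observed rate, mean predicted) on training data
    schema: RiskFactorSchema

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        x = self.schema.design_matrix(frame, add_intercept=True)
        beta = np.array(list(self.coefficients.values()))
        return x @ beta

    def predict(self, cases) -> np.ndarray:
        """Predicted outcome probabilities, clipped to (PROB_CLIP, 1 - PROB_CLIP)."""
        frame = as_frame(cases, self.schema)
        self._check_levels(frame)
        return np.clip(expit(self.linear_predictor(frame)), PROB_CLIP, 1.0 - PROB_CLIP)

    def _check_levels(self, frame: pd.DataFrame) -> None:
        for f in self.schema.factors:
            if f.kind == "categorical":
                bad = set(frame[f.name].astype(str)) - set(f.levels)
                if bad:
                    raise ValueError(f"unseen level(s) {sorted(bad)} for factor {f.name!r}")


def _ridge_logistic(x: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Newton solver for logistic regression with an L2 penalty.

    The intercept is unpenalised.  Deterministic: fixed start at zero, fixed
    iteration cap, convergence on the gradient norm.
    """
    n, k = x.shape
    beta = np.zeros(k)
    pen = np.full(k, lam)
    pen[0] = 0.0
    for _ in range(200):
        eta = x @ beta
        mu = expit(eta)
        grad = x.T @ (y - mu) - pen * beta
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        hess = (x * w[:, None]).T @ x + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(grad)) < 1e-8:
            break
    return beta


def fit_monthly_model(
    cases,
    analysis_month,
    schema: RiskFactorSchema | None = None,
    window_months: int = 11,
) -> RiskModel:
    """Fit the risk model for ``analysis_month`` on the prior-month window.

    The window covers the ``window_months`` months before the analysis month,
    truncated at the start of the available data; the analysis month itself is
    never included.  Raises :class:`DegenerateWindowError` when the window has
    no cases, no deaths or no survivors — the caller should skip the month.
    """
    schema = schema if schema is not None else default_schema()
    analysis_month = pd.Period(analysis_month, freq="M")
    frame = as_frame(cases, schema)
    months = frame["procedure_date"].dt.to_period("M")

    win_start = max(analysis_month - window_months, months.min())
    win_end = analysis_month - 1
    train = frame.loc[(months >= win_start) & (months <= win_end)]
    if train.empty:
        raise DegenerateWindowError(f"{analysis_month}: no training cases in window")
    y = train["outcome"].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise DegenerateWindowError(
            f"{analysis_month}: training window has a single outcome class; skip this month"
        )

    x = schema.design_matrix(train, add_intercept=True)
    names = ["intercept"] + schema.design_columns()

    converged, stabilized = True, False
    try:
        with np.errstate(all="ignore"):
            result = sm.GLM(y, x, family=sm.families.Binomial()).fit(maxiter=100)
        params = np.asarray(result.params)
        if (not np.all(np.isfinite(params))) or np.max(np.abs(params)) > _SEPARATION_COEF:
            raise np.linalg.LinAlgError("separation suspected")
        if not getattr(result, "converged", True):
            raise np.linalg.LinAlgError("IRLS did not converge")
    except Exception:
        params = _ridge_logistic(x, y, _RIDGE_LAMBDA)
        stabilized = True
        converged = bool(np.all(np.isfinite(params)))
        logger.warning("%s: logistic fit unstable; ridge-stabilised refit used", analysis_month)

    mean_pred = float(np.mean(np.clip(expit(x @ params), PROB_CLIP, 1 - PROB_CLIP)))
    return RiskModel(
        analysis_month=analysis_month,
        training_window=(win_start, win_end),
        coefficients=dict(zip(names, map(float, params))),
        n_train=len(train),
        converged=converged,
        stabilized=stabilized,
        calibration=(float(y.mean()), mean_pred),
        schema=schema,
    )


def predict_case(model: RiskModel, case) -> float:
    """Predicted probability for a single case (clipped into (0, 1))."""
    return float(model.predict([case])[0])


@dataclass
class ModelSequence:
    """Monthly models keyed by analysis month plus the skipped months."""

    models: dict
    skipped: dict            # month -> reason

    def get(self, month):
        return self.models.get(pd.Period(month, freq="M"))

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(sorted(self.models))

    def to_records(self) -> list[dict]:
        out = []
        for month in sorted(self.models):
            m = self.models[month]
            out.append(
                {
                    "analysis_month": str(month),
                    "training_window": [str(m.training_window[0]), str(m.training_window[1])],
                    "n_train": m.n_train,
                    "converged": m.converged,
                    "stabilized": m.stabilized,
                    "calibration": list(m.calibration),
                    "coefficients": m.coefficients,
                }
            )
        return out


def build_model_sequence(cases, schema: RiskFactorSchema | None = None, window_months: int = 11) -> ModelSequence:
    """One model per analysis month from the second study month onward.

    The first month is training-only (its cases are never scored).  Months
    whose fit is degenerate are recorded in ``skipped`` and their cases are
    excluded from surveillance downstream.
    """
    schema = schema if schema is not None else default_schema()
    frame = as_frame(cases, schema)
    if frame.empty:
        raise ValueError("no cases supplied")
    months = frame["procedure_date"].dt.to_period("M")
    all_months = pd.period_range(months.min(), months.max(), freq="M")
    if len(all_months) < 2:
        raise ValueError("need at least two months of data to build a model sequence")

    models: dict = {}
    skipped: dict = {str(all_months[0]): "first study month: training only"}
    for month in all_months[1:]:
        try:
            models[month] = fit_monthly_model(frame, month, schema, window_months)
        except DegenerateWindowError as exc:
            skipped[str(month)] = str(exc)
            logger.warning("skipping analysis month %s: %s", month, exc)
    return ModelSequence(models=models, skipped=skipped)
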