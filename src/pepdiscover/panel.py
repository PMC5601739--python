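"""Stepwise logistic diagnostic-panel construction and validation.

The panel is a multivariate binary logistic regression on reference-peak
intensities (case = 1, control = 0).  Variables enter by the
likelihood-ratio test (P < ``p_enter``, default 0.05) and leave by the
Wald test (P > ``p_remove``, default 0.10), the classic forward-stepwise-
with-elimination scheme of mainstream statistical packages.  A fitted
panel is frozen -- coefficients, intercept and probability cut-off -- and
applied unchanged to an external validation matrix, whose columns are
matched to the model's peaks by nearest reference m/z within the
alignment tolerance.

The maximum-likelihood fit is Newton-Raphson / iteratively reweighted
least squares with the standard errors taken from the inverse observed
information; complete or quasi-complete separation is detected by
monitoring the standardized coefficient magnitudes and reported as an
explicit error rather than silently diverging.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from math import sqrt
from pathlib import Path

import numpy as np
from scipy import stats

from pepdiscover.matrix import PeakMatrix
from pepdiscover.univariate import roc_auc

__all__ = [
    "PanelModel",
    "DiagnosticPerformance",
    "LogisticFit",
    "fit_logistic",
    "stepwise_select",
    "odds_ratios",
    "predict_prob",
    "evaluate",
    "external_validate",
]

Z975 = 1.96  # normal quantile used throughout for 95% intervals


class SeparationError(RuntimeError):
    """Perfect or quasi-complete separation: the MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


class ModelError(ValueError):
    pass


@dataclass
class LogisticFit:
    """Raw maximum-likelihood fit: coefficients ordered (intercept, columns...)."""

    params: np.ndarray
    se: np.ndarray
    loglik: float
    n_iter: int

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def beta(self) -> np.ndarray:
        return self.params[1:]

    def wald_p(self) -> np.ndarray:
        """Two-sided Wald P-values, same ordering as ``params``."""
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.params / self.se, np.inf)
        return 2.0 * stats.norm.sf(np.abs(z))


def _loglik(params: np.ndarray, X1: np.ndarray, y: np.ndarray) -> float:
    eta = X1 @ params
    # log(1 + e^eta) computed stably
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_threshold: float = 20.0,
) -> LogisticFit:
    """Binary logistic regression by iteratively reweighted least squares.

    ``X`` is the n x k predictor matrix (no intercept column; one is
    added), ``y`` the 0/1 outcome.  Iterations stop when the maximum
    absolute score (gradient) falls below ``tol``.  Standard errors come
    from the inverse observed information.  Separation is flagged when any
    coefficient exceeds ``separation_threshold`` on standardized columns.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    n, k = X.shape
    if len(y) != n:
        raise ModelError(f"X has {n} rows but y has {len(y)}")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ModelError("y must be coded 0/1")
    if y.sum() == 0 or y.sum() == n:
        raise ModelError("both outcome classes must be present")
    if n <= k + 1:
        raise ModelError(f"need n > k+1 observations, got n={n}, k={k}")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.nonzero(sd == 0)[0][0])
        raise ModelError(f"predictor column {j} is constant")

    X1 = np.column_stack([np.ones(n), X])
    scale = np.concatenate([[1.0], sd])
    params = np.zeros(k + 1)
    params[0] = np.log(y.mean() / (1 - y.mean()))

    for it in range(1, max_iter + 1):
        eta = X1 @ params
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        score = X1.T @ (y - mu)
        w = mu * (1.0 - mu)
        info = X1.T @ (X1 * w[:, None])
        if np.max(np.abs(params * scale)) > separation_threshold:
            raise SeparationError(
                "complete or quasi-complete separation detected "
                f"(standardized |coefficient| > {separation_threshold:g} at iteration {it})"
            )
        if np.max(np.abs(score)) < tol:
            cov = np.linalg.inv(info)
            return LogisticFit(params, np.sqrt(np.diag(cov)), _loglik(params, X1, y), it)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information matrix at iteration {it}") from exc
        # dampen oversized Newton steps for stability far from the optimum
        ll_old = _loglik(params, X1, y)
        damp = 1.0
        for _ in range(30):
            trial = params + damp * step
            if _loglik(trial, X1, y) >= ll_old - 1e-12:
                break
            damp /= 2.0
        params = params + damp * step

    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations "
        f"(last max|score| = {np.max(np.abs(score)):.3g})"
    )


@dataclass
class PanelModel:
    """Frozen logistic diagnostic panel.

    ``beta`` are log-odds per intensity unit for the peaks in
    ``peak_mzs``; ``cutoff`` is the predicted-probability threshold used
    for classification (0.5 by default, the standard classification-table
    convention).
    """

    peak_mzs: list[float]
    beta: np.ndarray
    intercept: float
    se: np.ndarray
    intercept_se: float
    loglik: float = float("nan")
    cutoff: float = 0.5
    feature_scale: float = 1.0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, float)
        self.se = np.asarray(self.se, float)
        if len(self.beta) != len(self.peak_mzs) or len(self.se) != len(self.peak_mzs):
            raise ModelError("beta/se length must match peak_mzs")

    @property
    def or_(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            return np.exp(self.beta)

    @property
    def or_ci(self) -> np.ndarray:
        with np.errstate(over="ignore"):
            lo = np.exp(self.beta - Z975 * self.se)
            hi = np.exp(self.beta + Z975 * self.se)
        return np.column_stack([lo, hi])

    @property
    def p_wald(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se > 0, self.beta / self.se, np.inf)
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_json(self, path: str | Path, provenance: dict | None = None) -> None:
        payload = {
            "peak_mzs": list(map(float, self.peak_mzs)),
            "beta": self.beta.tolist(),
            "intercept": self.intercept,
            "se": self.se.tolist(),
            "intercept_se": self.intercept_se,
            "loglik": self.loglik,
            "cutoff": self.cutoff,
            "feature_scale": self.feature_scale,
            "provenance": provenance or {},
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelModel":
        d = json.loads(Path(path).read_text())
        return cls(
            peak_mzs=d["peak_mzs"],
            beta=np.array(d["beta"]),
            intercept=d["intercept"],
            se=np.array(d["se"]),
            intercept_se=d["intercept_se"],
            loglik=d.get("loglik", float("nan")),
            cutoff=d.get("cutoff", 0.5),
            feature_scale=d.get("feature_scale", 1.0),
        )


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Confusion-matrix summary with 95% intervals (case = positive)."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy: float
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    auc: float = float("nan")
    auc_ci: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sens_ci": list(self.sens_ci),
            "spec_ci": list(self.spec_ci),
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
        }


def _wald_ci(p: float, n: int) -> tuple[float, float]:
    if n == 0:
        return (float("nan"), float("nan"))
    se = sqrt(p * (1.0 - p) / n)
    return (max(0.0, p - Z975 * se), min(1.0, p + Z975 * se))


def evaluate(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    scores: np.ndarray | None = None,
) -> DiagnosticPerformance:
    """Confusion-matrix metrics for predicted versus true case/control labels.

    Labels may be 0/1 or "case"/"control" strings (case = positive).
    When ``scores`` (e.g. predicted probabilities) are given, the panel
    ROC AUC and its interval are included.
    """
    def as01(a: np.ndarray) -> np.ndarray:
        a = np.asarray(a)
        return (a == 1).astype(int) if a.dtype.kind in "iufb" else (a == "case").astype(int)

    pred, truth = as01(pred_labels), as01(true_labels)
    if len(pred) != len(truth):
        raise ModelError(f"{len(pred)} predictions but {len(truth)} true labels")
    if truth.sum() == 0 or truth.sum() == len(truth):
        raise ModelError("true labels must contain both classes")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    n = tp + fn + tn + fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    auc, auc_ci = (float("nan"), (float("nan"), float("nan")))
    if scores is not None:
        auc, auc_ci = roc_auc(np.asarray(scores, float), truth)
    return DiagnosticPerformance(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy=(tp + tn) / n,
        sensitivity=sens,
        specificity=spec,
        sens_ci=_wald_ci(sens, tp + fn),
        spec_ci=_wald_ci(spec, tn + fp),
        auc=auc,
        auc_ci=auc_ci,
    )


def _matrix_Xy(m: PeakMatrix) -> tuple[np.ndarray, np.ndarray]:
    y = (np.asarray(m.labels) == "case").astype(int)
    return m.intensities, y


def stepwise_select(
    m: PeakMatrix,
    candidates: list[float],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    cutoff: float = 0.5,
    feature_scale: float = 1.0,
) -> PanelModel:
    """Forward-stepwise logistic panel with backward elimination.

    At each step the candidate whose likelihood-ratio test against the
    current model has the smallest P enters if that P < ``p_enter``
    (ties broken by ascending m/z); after every entry, included peaks
    whose Wald P exceeds ``p_remove`` are removed worst-first with
    refitting.  Terminates when neither an entry nor a removal changes the
    set, or when a previously visited set recurs.  Deterministic given the
    matrix.  Candidates whose addition makes the fit separable or
    non-identifiable are skipped at that step.

    ``feature_scale`` multiplies all intensities before fitting (the
    published coefficient scale of such panels depends on an in-house
    intensity unit; the scale is recorded on the model and applied
    identically at prediction time).
    """
    if not 0 < p_enter <= p_remove < 1:
        raise ModelError("need 0 < p_enter <= p_remove < 1")
    X_all, y = _matrix_Xy(m)
    X_all = X_all * feature_scale
    mz_refs = list(m.mz_refs)
    cand_idx: list[int] = []
    for mz in sorted(candidates):
        j = int(np.argmin(np.abs(np.array(mz_refs) - mz)))
        if abs(mz_refs[j] - mz) > 1e-6 * max(mz, 1.0):
            raise ModelError(f"candidate m/z {mz} not found among matrix columns")
        cand_idx.append(j)

    included: list[int] = []
    current_fit: LogisticFit | None = None
    current_ll = None
    seen: set[tuple[int, ...]] = set()

    def fit_subset(idx: list[int]) -> LogisticFit:
        return fit_logistic(X_all[:, idx], y)

    while True:
        key = tuple(sorted(included))
        if key in seen:
            break
        seen.add(key)
        changed = False

        if current_ll is None:
            p0 = y.mean()
            current_ll = float(y.sum() * np.log(p0) + (len(y) - y.sum()) * np.log(1 - p0))

        # --- entry: best likelihood-ratio candidate
        best: tuple[float, float, int, LogisticFit] | None = None
        for j in cand_idx:
            if j in included:
                continue
            try:
                trial = fit_subset(included + [j])
            except (SeparationError, ConvergenceError, ModelError):
                continue
            lr = 2.0 * (trial.loglik - current_ll)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            cand_key = (p, mz_refs[j])
            if best is None or cand_key < (best[0], best[1]):
                best = (p, mz_refs[j], j, trial)
        if best is not None and best[0] < p_enter:
            included.append(best[2])
            current_fit, current_ll = best[3], best[3].loglik
            changed = True

        # --- elimination: worst Wald P above the removal threshold
        while included:
            fit = current_fit if current_fit is not None else fit_subset(included)
            pw = fit.wald_p()[1:]  # skip intercept
            worst = int(np.argmax(pw))
            if pw[worst] > p_remove:
                del included[worst]
                changed = True
                current_fit = fit_subset(included) if included else None
                current_ll = current_fit.loglik if current_fit is not None else None
            else:
                current_fit = fit
                current_ll = fit.loglik
                break

        if not changed:
            break

    if not included:
        warnings.warn("no candidate passed the entry criterion; intercept-only model",
                      stacklevel=2)
        p0 = y.mean()
        return PanelModel(
            peak_mzs=[], beta=np.array([]), intercept=float(np.log(p0 / (1 - p0))),
            se=np.array([]), intercept_se=float(np.sqrt(1.0 / (len(y) * p0 * (1 - p0)))),
            loglik=float(y.sum() * np.log(p0) + (len(y) - y.sum()) * np.log(1 - p0)),
            cutoff=cutoff, feature_scale=feature_scale,
        )

    order = np.argsort([mz_refs[j] for j in included])
    included = [included[i] for i in order]
    fit = fit_subset(included)
    return PanelModel(
        peak_mzs=[mz_refs[j] for j in included],
        beta=fit.beta,
        intercept=fit.intercept,
        se=fit.se[1:],
        intercept_se=float(fit.se[0]),
        loglik=fit.loglik,
        cutoff=cutoff,
        feature_scale=feature_scale,
    )


def odds_ratios(model: PanelModel, decimals: int = 3):
    """Per-peak coefficient table: (mz, beta, OR, CI low, CI high, Wald P)."""
    import pandas as pd

    ci = model.or_ci
    return pd.DataFrame(
        {
            "mz": [round(mz, 1) for mz in model.peak_mzs],
            "beta": np.round(model.beta, decimals),
            "OR": np.round(model.or_, decimals),
            "ci_low": np.round(ci[:, 0], decimals),
            "ci_high": np.round(ci[:, 1], decimals),
            "p_value": model.p_wald,
        }
    )


def _model_columns(model: PanelModel, m: PeakMatrix, tol_rel: float = 0.001) -> np.ndarray:
    """Extract the model's peak columns, matching by nearest m/z within tolerance."""
    mzs = m.mz_refs
    cols = np.zeros((m.n_samples, len(model.peak_mzs)))
    for k, mz in enumerate(model.peak_mzs):
        if len(mzs) == 0:
            warnings.warn(f"model peak m/z {mz:.1f} missing from matrix; using zeros",
                          stacklevel=3)
            continue
        j = int(np.argmin(np.abs(mzs - mz)))
        if abs(mzs[j] - mz) <= tol_rel * mz:
            cols[:, k] = m.intensities[:, j]
        else:
            warnings.warn(f"model peak m/z {mz:.1f} missing from matrix; using zeros",
                          stacklevel=3)
    return cols


def predict_prob(model: PanelModel, m: PeakMatrix, tol_rel: float = 0.001) -> np.ndarray:
    """Predicted case probability per sample under the frozen panel."""
    X = _model_columns(model, m, tol_rel) * model.feature_scale
    eta = model.intercept + X @ model.beta if len(model.beta) else np.full(m.n_samples, model.intercept)
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))


def external_validate(
    model: PanelModel, m_val: PeakMatrix, tol_rel: float = 0.001
) -> DiagnosticPerformance:
    """Apply a frozen panel to an independent cohort and report performance.

    No refitting: predicted probabilities are thresholded at the model's
    stored cut-off and compared with the cohort's true labels; the panel
    ROC AUC on the validation probabilities is included.
    """
    probs = predict_prob(model, m_val, tol_rel)
    pred = (probs >= model.cutoff).astype(int)
    truth = (np.asarray(m_val.labels) == "case").astype(int)
    return evaluate(pred, truth, scores=probs)
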