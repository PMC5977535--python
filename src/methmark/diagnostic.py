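"""Logistic-regression diagnostic model on marker-panel beta values.

The model is fit by iteratively reweighted least squares on a
ridge-stabilized log-likelihood (a tiny quadratic penalty, default 1e-8,
on the coefficients but not the intercept — enough to make separable data
well-posed without noticeably shrinking estimates).  Beta values enter
untransformed.  Evaluation reports sensitivity, specificity, confusion
counts and AUC at a fixed decision threshold (default 0.5), plus the
cross-cancer false-positive profile: the fraction of each other-cancer
cohort a fitted model would call tumor-positive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import BetaMatrix
from .stats_core import roc_auc

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class DiagnosticModel:
    intercept: float
    coefficients: pd.Series  # probe id -> coefficient
    ridge: float = 1e-8
    decision_threshold: float = 0.5

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "intercept": self.intercept,
                    "coefficients": self.coefficients.to_dict(),
                    "ridge": self.ridge,
                    "decision_threshold": self.decision_threshold,
                },
                indent=1,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path) -> "DiagnosticModel":
        d = json.loads(Path(path).read_text())
        return cls(
            intercept=d["intercept"],
            coefficients=pd.Series(d["coefficients"]).sort_index(),
            ridge=d["ridge"],
            decision_threshold=d["decision_threshold"],
        )


def fit_logistic(
    X: pd.DataFrame,
    y,
    ridge: float = 1e-8,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> DiagnosticModel:
    """Penalized maximum-likelihood logistic regression via IRLS.

    ``X`` is samples x panel probes (no missing values), ``y`` binary
    (1 = tumor).  Convergence is declared when the largest coefficient
    change drops below ``tol``; non-convergence raises
    :class:`ConvergenceError` carrying the iteration trace.
    """
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.isnan(Xa).any():
        raise ValueError("fit_logistic requires complete beta values; impute first")
    if set(np.unique(ya)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(ya)) < 2:
        raise ValueError("both classes must be present for fitting")
    n, p = Xa.shape
    A = np.hstack([np.ones((n, 1)), Xa])
    penalty = np.diag([0.0] + [ridge] * p)
    beta = np.zeros(p + 1)
    trace: list[float] = []
    for _ in range(max_iter):
        eta = np.clip(A @ beta, -30, 30)
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (ya - mu) / w
        AtW = A.T * w
        beta_new = np.linalg.solve(AtW @ A + penalty, AtW @ z)
        step = float(np.max(np.abs(beta_new - beta)))
        trace.append(step)
        beta = beta_new
        if step < tol:
            return DiagnosticModel(
                intercept=float(beta[0]),
                coefficients=pd.Series(beta[1:], index=X.columns),
                ridge=ridge,
            )
    raise ConvergenceError(
        f"IRLS did not converge in {max_iter} iterations (last step {trace[-1]:.3g})",
        trace,
    )


def _design(model: DiagnosticModel, X: pd.DataFrame) -> np.ndarray:
    missing = [p for p in model.coefficients.index if p not in X.columns]
    if missing:
        raise ValueError(f"panel probes missing from input: {missing}")
    return X[model.coefficients.index].to_numpy(dtype=float)


def predict_score(model: DiagnosticModel, X: pd.DataFrame) -> np.ndarray:
    """Tumor probability: logistic of intercept + coefficients . beta."""
    return expit(model.intercept + _design(model, X) @ model.coefficients.to_numpy())


def classify(model: DiagnosticModel, X: pd.DataFrame) -> np.ndarray:
    return (predict_score(model, X) >= model.decision_threshold).astype(int)


@dataclass
class EvalResult:
    cohort_label: str
    sensitivity: float
    specificity: float
    auc: float  # NaN when only one class is present
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate(model: DiagnosticModel, X: pd.DataFrame, y, cohort_label: str = "") -> EvalResult:
    """Confusion counts at the decision threshold plus AUC.

    Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); either is NaN when
    its class is absent.  AUC needs both classes (NaN otherwise).
    """
    ya = np.asarray(y, dtype=int)
    scores = predict_score(model, X)
    pred = (scores >= model.decision_threshold).astype(int)
    tp = int(((pred == 1) & (ya == 1)).sum())
    fp = int(((pred == 1) & (ya == 0)).sum())
    tn = int(((pred == 0) & (ya == 0)).sum())
    fn = int(((pred == 0) & (ya == 1)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    auc = roc_auc(scores, ya) if len(np.unique(ya)) == 2 else float("nan")
    return EvalResult(cohort_label, sens, spec, auc, tp, fp, tn, fn)


def panel_matrix(bm: BetaMatrix, probes, fill: str = "mean") -> pd.DataFrame:
    """Samples x probes design matrix from a beta matrix.

    Missing cells are filled with the per-probe cohort mean (``fill="mean"``)
    or rejected (``fill="error"``).  A probe with no observed value at all is
    always an error.
    """
    missing = [p for p in probes if p not in bm.probe_ids]
    if missing:
        raise ValueError(f"panel probes absent from matrix: {missing}")
    sub = bm.values.loc[list(probes)].T  # samples x probes
    if sub.isna().any().any():
        if fill == "error":
            raise ValueError("missing beta values in panel columns; impute first")
        means = sub.mean(axis=0)
        if means.isna().any():
            bad = means.index[means.isna()].tolist()
            raise ValueError(f"panel probes with no observed values: {bad}")
        sub = sub.fillna(means)
    return sub


def training_frame(
    tumor: BetaMatrix, normal: BetaMatrix, probes
) -> tuple[pd.DataFrame, np.ndarray]:
    """Stack tumor and normal cohorts into (X, y) for fitting/evaluation."""
    Xt = panel_matrix(tumor, probes)
    Xn = panel_matrix(normal, probes)
    X = pd.concat([Xt, Xn], axis=0)
    y = np.concatenate([np.ones(len(Xt), dtype=int), np.zeros(len(Xn), dtype=int)])
    return X, y


def panel_size_sweep(
    ranked_probes,
    train: tuple[pd.DataFrame, np.ndarray],
    eval_sets: dict[str, tuple[pd.DataFrame, np.ndarray]],
    ridge: float = 1e-8,
) -> pd.DataFrame:
    """Refit with the top-1 ... top-k ranked probes and evaluate each panel
    size on every evaluation cohort."""
    X_tr, y_tr = train
    rows = []
    for size in range(1, len(ranked_probes) + 1):
        probes = list(ranked_probes[:size])
        model = fit_logistic(X_tr[probes], y_tr, ridge=ridge)
        for label, (X_ev, y_ev) in eval_sets.items():
            res = evaluate(model, X_ev[probes], y_ev, cohort_label=label)
            rows.append(
                {
                    "panel_size": size,
                    "cohort": label,
                    "auc": res.auc,
                    "sensitivity": res.sensitivity,
                    "specificity": res.specificity,
                }
            )
    return pd.DataFrame(rows)


def cross_cancer_specificity(
    model: DiagnosticModel, other_cancers: dict[str, dict[str, BetaMatrix]]
) -> pd.DataFrame:
    """Fraction of each other-cancer cohort predicted tumor-positive.

    Returns one row per (cancer type, tissue) cohort plus the overall and
    median summary; empty cohorts are excluded with a warning.
    """
    rows = []
    for t, cohorts in sorted(other_cancers.items()):
        for tissue, bm in sorted(cohorts.items()):
            if bm.n_samples == 0:
                logger.warning("cross_cancer_specificity: cohort %s/%s empty, skipped", t, tissue)
                continue
            X = panel_matrix(bm, model.coefficients.index)
            pred = classify(model, X)
            rows.append(
                {
                    "cancer_type": t,
                    "tissue": tissue,
                    "n": len(pred),
                    "n_positive": int(pred.sum()),
                    "frac_positive": float(pred.mean()),
                }
            )
    df = pd.DataFrame(rows)
    if len(df):
        df.attrs["median_frac_positive"] = float(df["frac_positive"].median())
        df.attrs["overall_frac_positive"] = float(df["n_positive"].sum() / df["n"].sum())
    return df
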