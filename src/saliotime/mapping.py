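"""Map accumulated salient-event counts to duration estimates in seconds.

Two routes, both trained on *presented* (clock-time) duration, never on
the human reports — any human-like bias that survives in the predictions
is therefore a property of the event counts, not of the fit target:

* epsilon-SVR with k-fold cross-validation (the neuroimaging route):
  every trial is predicted out-of-fold, with feature standardization
  fitted on the training folds only;
* in-sample multiple linear regression (the classification-network
  route).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR


@dataclass
class MappingConfig:
    method: str = "svr"
    n_folds: int = 10
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    kernel: str = "rbf"
    feature_scaling: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.svr_c <= 0 or self.svr_epsilon < 0:
            raise ValueError("svr_c must be > 0 and svr_epsilon >= 0")
        if self.method not in ("svr", "ols"):
            raise ValueError(f"unknown mapping method {self.method!r}")


@dataclass
class MappingResult:
    """Out-of-fold (or in-sample) predictions plus fit-quality summaries."""

    predictions: pd.DataFrame  # columns: duration_s, predicted_s, fold (+ keys)
    r_per_fold: Sequence[float]
    r_pooled: float
    r_mean: float  # Fisher-z average of the per-fold correlations
    coefficients: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _fisher_mean(rs: Sequence[float]) -> float:
    rs = np.clip(np.asarray(rs, float), -0.999999, 0.999999)
    return float(np.tanh(np.mean(np.arctanh(rs))))


def _feature_matrix(counts: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    cols = [c for c in counts.columns if c.startswith("layer")]
    if not cols:
        raise ValueError("counts table has no layer columns")
    return counts[cols].to_numpy(float), cols


def fit_predict_cv(
    counts: pd.DataFrame, durations: Sequence[float], cfg: MappingConfig
) -> MappingResult:
    """Cross-validated epsilon-SVR of duration on per-layer event counts.

    Fold assignment is randomized by ``cfg.seed``; feature scaling uses
    training-fold statistics only, so no test information leaks into the
    fit.
    """
    X, cols = _feature_matrix(counts)
    y = np.asarray(durations, float)
    if len(y) != len(X):
        raise ValueError("counts and durations length mismatch")
    if (y <= 0).any():
        raise ValueError("durations must be positive")
    if cfg.n_folds > len(y):
        raise ValueError(f"n_folds={cfg.n_folds} exceeds n_trials={len(y)}")

    kf = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    pred = np.full(len(y), np.nan)
    fold_id = np.full(len(y), -1)
    r_per_fold = []
    for f, (tr, te) in enumerate(kf.split(X)):
        steps = []
        if cfg.feature_scaling:
            steps.append(("scale", StandardScaler()))
        steps.append(
            ("svr", SVR(kernel=cfg.kernel, C=cfg.svr_c, epsilon=cfg.svr_epsilon))
        )
        model = Pipeline(steps)
        model.fit(X[tr], y[tr])
        pred[te] = model.predict(X[te])
        fold_id[te] = f
        if len(te) > 1 and np.std(pred[te]) > 0 and np.std(y[te]) > 0:
            r_per_fold.append(float(stats.pearsonr(y[te], pred[te])[0]))
        else:
            r_per_fold.append(np.nan)

    keys = counts[[c for c in ("participant", "trial", "scene") if c in counts]]
    out = keys.copy()
    out["duration_s"] = y
    out["predicted_s"] = pred
    out["fold"] = fold_id
    r_pooled = float(stats.pearsonr(y, pred)[0])
    return MappingResult(
        predictions=out,
        r_per_fold=r_per_fold,
        r_pooled=r_pooled,
        r_mean=_fisher_mean([r for r in r_per_fold if np.isfinite(r)]),
        extra={"feature_columns": cols},
    )


def fit_predict_ols(
    counts: pd.DataFrame, durations: Sequence[float]
) -> MappingResult:
    """In-sample least-squares fit of duration on per-layer counts."""
    X, cols = _feature_matrix(counts)
    y = np.asarray(durations, float)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"need more than {k + 1} trials for {k} layer regressors")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design: collinear or constant layer counts")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    pred = design @ beta

    keys = counts[[c for c in ("participant", "trial", "scene") if c in counts]]
    out = keys.copy()
    out["duration_s"] = y
    out["predicted_s"] = pred
    out["fold"] = -1
    r = float(stats.pearsonr(y, pred)[0]) if np.std(pred) > 0 else np.nan
    return MappingResult(
        predictions=out,
        r_per_fold=[r],
        r_pooled=r,
        r_mean=r,
        coefficients=beta,
        extra={"feature_columns": cols},
    )
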