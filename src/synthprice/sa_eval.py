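"""Evaluation: regression metrics, ES/HS threshold classification, PCA diagnostics.

The fine-tuned model is used as a binary synthetic-accessibility
classifier by thresholding its predicted log-price: molecules scoring
below the threshold are called easy-to-synthesize (ES), those at or above
it hard-to-synthesize (HS, the positive class).  The threshold is chosen
by exhaustive scan over the midpoints of consecutive sorted unique
scores, which exactly maximizes any step-wise objective such as MCC or
the F-score; ROC-AUC is threshold-free.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score, matthews_corrcoef, roc_auc_score

from .errors import ConfigError, DegenerateBatchError


@dataclasses.dataclass
class RegressionReport:
    mse: float
    r2: float
    spearman_rs: float
    n: int
    constant_target: bool = False


@dataclasses.dataclass
class ThresholdResult:
    threshold: float
    mcc: float
    f_score: float
    roc_auc: float
    objective: str


def regression_metrics(y: np.ndarray, yhat: np.ndarray) -> RegressionReport:
    """MSE, R² (against the evaluation set's own mean) and Spearman rank correlation.

    A constant target leaves R² undefined; the report flags it and carries
    ``nan`` rather than a silent zero.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ConfigError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if len(y) < 2:
        raise ConfigError("need at least 2 points for regression metrics")
    mse = float(np.mean((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    constant = ss_tot == 0.0
    if constant:
        warnings.warn("constant target: R^2 undefined", stacklevel=2)
        r2 = float("nan")
        rs = float("nan")
    else:
        r2 = 1.0 - float(np.sum((y - yhat) ** 2)) / ss_tot
        rs = float(sps.spearmanr(y, yhat).statistic)
    return RegressionReport(mse=mse, r2=r2, spearman_rs=rs, n=len(y), constant_target=constant)


def _as_hs_mask(labels) -> np.ndarray:
    labels = np.asarray(labels)
    mask = labels if labels.dtype == bool else labels == "HS"
    if mask.all() or not mask.any():
        raise DegenerateBatchError("both ES and HS labels are required")
    return mask


def optimize_threshold(
    scores: np.ndarray,
    labels,
    objective: str = "mcc",
) -> ThresholdResult:
    """Best price threshold for ES/HS classification.

    Rule: ``score >= threshold`` predicts HS.  Candidates are the midpoints
    between consecutive sorted unique scores plus -inf/+inf sentinels; ties
    in the objective break toward the lower threshold.
    """
    if objective not in ("mcc", "f_score"):
        raise ConfigError(f"unknown objective: {objective!r}")
    scores = np.asarray(scores, dtype=np.float64)
    is_hs = _as_hs_mask(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate(
        [[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else [], [np.inf]]
    )
    best_t, best_obj, best_mcc, best_f = np.nan, -np.inf, 0.0, 0.0
    for t in candidates:
        pred = scores >= t
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mcc = matthews_corrcoef(is_hs, pred)
            f = f1_score(is_hs, pred, zero_division=0.0)
        obj = mcc if objective == "mcc" else f
        if obj > best_obj:  # strict: ties keep the earlier (lower) threshold
            best_t, best_obj, best_mcc, best_f = t, obj, mcc, f
    auc = float(roc_auc_score(is_hs, scores))
    return ThresholdResult(
        threshold=float(best_t), mcc=float(best_mcc), f_score=float(best_f),
        roc_auc=auc, objective=objective,
    )


@dataclasses.dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray
    projections: np.ndarray  # n x n_components
    labels: np.ndarray


def latent_separation_pca(
    latents: np.ndarray,
    labels,
    n_components: int = 3,
) -> PCAResult:
    """PCA of the latent space with class labels, for separation diagnostics.

    Returns the full explained-variance-ratio spectrum (summing to 1) and
    the first ``n_components`` projections.  A fine-tuned model typically
    concentrates the ES/HS-discriminative variance in the first component.
    """
    latents = np.asarray(latents, dtype=np.float64)
    if latents.ndim != 2 or latents.shape[0] <= latents.shape[1]:
        raise ConfigError("need more rows than latent dimensions for PCA")
    if float(np.var(latents, axis=0).sum()) == 0.0:
        raise ConfigError("degenerate (zero-variance) latents")
    pca = PCA(n_components=latents.shape[1])
    proj = pca.fit_transform(latents)
    return PCAResult(
        explained_variance_ratio=pca.explained_variance_ratio_,
        projections=proj[:, :n_components],
        labels=np.asarray(labels),
    )
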