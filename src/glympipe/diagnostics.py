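"""Diagnostic modelling: per-marker ROC analysis, a combined logistic
nomogram, bootstrap optimism-corrected calibration, and decision-curve
analysis.

The ROC cut-off maximizes Youden's J (sensitivity + specificity - 1); the
AUC confidence interval uses DeLong's structural-components variance.
The combined model is an unregularized maximum-likelihood logistic
regression on the three imaging markers, rendered as a nomogram whose
largest feature contribution spans 0-100 points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError


class SeparationError(RuntimeError):
    """Raised when logistic maximum likelihood does not exist (complete
    or quasi-complete separation)."""


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    direction: str  # "greater": higher score predicts the positive class


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    n = x.size
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and xs[j] == xs[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from positive/negative-class scores.

    The AUC here is the Mann-Whitney probability that a random positive
    outscores a random negative, ties counted half.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # structural components of positives
    v10 = 1.0 - (tz[m:] - ty) / m    # and of negatives
    if m < 2 or n < 2:
        return float(auc), float("nan")
    var = np.var(v01, ddof=1) / m + np.var(v10, ddof=1) / n
    return float(auc), float(var)


def roc_analysis(scores, labels, direction: str = "auto") -> RocResult:
    """Empirical ROC curve, AUC with DeLong 95% CI, and Youden cut-off.

    ``direction="greater"`` treats higher scores as evidence for the
    positive class, ``"less"`` the reverse (e.g. a lower ALPS index
    indicating disease); ``"auto"`` picks the orientation with AUC >= 0.5.
    The cut-off is reported in the original score units; with
    ``direction="less"`` the positive call is ``score <= cutoff``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if scores.shape != y.shape:
        raise ValueError("scores and labels must have the same shape")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    if direction == "auto":
        auc_raw, _ = delong_auc_variance(scores[y], scores[~y])
        direction = "greater" if auc_raw >= 0.5 else "less"
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    oriented = scores if direction == "greater" else -scores

    auc, var = delong_auc_variance(oriented[y], oriented[~y])
    half = 1.959963984540054 * np.sqrt(var) if np.isfinite(var) else np.nan
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    fpr, tpr, thr = roc_curve(y, oriented)
    youden = tpr - fpr
    best = int(np.argmax(youden))
    cutoff_oriented = thr[best]
    cutoff = float(cutoff_oriented if direction == "greater" else -cutoff_oriented)

    return RocResult(
        thresholds=thr if direction == "greater" else -thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        ci95=ci,
        cutoff=cutoff,
        sens_at_cutoff=float(tpr[best]),
        spec_at_cutoff=float(1.0 - fpr[best]),
        direction=direction,
    )


@dataclass(frozen=True)
class DiagnosticModel:
    """Fitted logistic model: P(positive) = expit(intercept + X @ coef)."""

    feature_names: tuple[str, ...]
    intercept: float
    coef: np.ndarray
    fitted_probabilities: np.ndarray
    stderr: np.ndarray | None = None  # SEs of (intercept, *coef)

    def linear_predictor(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.intercept + X @ self.coef

    def predict_proba(self, X) -> np.ndarray:
        return expit(self.linear_predictor(X))


def _as_matrix(features) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(float), tuple(features.columns)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("features must be 1-D or 2-D")
    return X, tuple(f"x{i + 1}" for i in range(X.shape[1]))


def fit_logistic(features, labels) -> DiagnosticModel:
    """Unregularized maximum-likelihood logistic regression.

    Newton-Raphson (iteratively reweighted least squares) with a 1e-8
    log-likelihood convergence tolerance.  Complete separation is
    reported as :class:`SeparationError` rather than silently diverging;
    a rank-deficient design raises ``ValueError``.
    """
    X, names = _as_matrix(features)
    y = np.asarray(labels).astype(float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("features and labels length mismatch")
    if not (0 < y.sum() < n):
        raise ValueError("both classes must be present")
    if n <= p + 1:
        raise ValueError("need more observations than parameters")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise ValueError("rank-deficient design matrix")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, design).fit(method="newton", tol=1e-8,
                                          maxiter=200, disp=0)
    except (PerfectSeparationError, RuntimeWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed, likely separation: {exc}") from exc

    fitted = np.asarray(res.predict(design))
    eps = 1e-10
    if np.any(fitted < eps) or np.any(fitted > 1 - eps) or not np.all(np.isfinite(res.bse)):
        raise SeparationError("fitted probabilities at 0/1: complete separation")

    params = np.asarray(res.params)
    return DiagnosticModel(
        feature_names=names,
        intercept=float(params[0]),
        coef=params[1:],
        fitted_probabilities=fitted,
        stderr=np.asarray(res.bse),
    )


@dataclass(frozen=True)
class Nomogram:
    """Point-scale rendering of a logistic model.

    Each feature's points are an affine, non-negative function of its
    value over its stated range; the feature with the largest
    |coefficient x span| contribution spans exactly 0-100 points, and the
    total-points axis maps back to predicted probability through the
    reconstructed linear predictor.
    """

    feature_names: tuple[str, ...]
    anchors: np.ndarray       # feature value at 0 points
    point_slopes: np.ndarray  # points per unit of the feature
    max_points: np.ndarray    # points at the far end of the range
    base_lp: float            # linear predictor when all features sit at anchors
    points_to_lp: float       # linear-predictor units per total point

    def feature_points(self, name: str, value) -> np.ndarray:
        i = self.feature_names.index(name)
        return self.point_slopes[i] * (np.asarray(value, dtype=float) - self.anchors[i])

    def total_points(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.anchors) @ self.point_slopes

    def probability_from_points(self, total) -> np.ndarray:
        return expit(self.base_lp + self.points_to_lp * np.asarray(total, dtype=float))

    def table(self, n_rows: int = 21) -> pd.DataFrame:
        total_max = float(self.max_points.sum())
        totals = np.linspace(0.0, total_max, n_rows)
        return pd.DataFrame({
            "total_points": totals,
            "probability": self.probability_from_points(totals),
        })


def build_nomogram(model: DiagnosticModel,
                   feature_ranges: dict[str, tuple[float, float]]) -> Nomogram:
    """Construct the point mapping for a fitted logistic model.

    Each feature is anchored at the end of its range that minimizes its
    contribution (low end for positive coefficients, high end for
    negative), so points are always non-negative, and scaled so the
    largest |coefficient x span| equals 100 points.
    """
    names = model.feature_names
    missing = set(names) - set(feature_ranges)
    if missing:
        raise ValueError(f"missing ranges for features: {sorted(missing)}")

    lo = np.array([feature_ranges[n][0] for n in names], dtype=float)
    hi = np.array([feature_ranges[n][1] for n in names], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)) or np.any(hi <= lo):
        raise ValueError("feature ranges must be finite with high > low")

    span_contrib = np.abs(model.coef) * (hi - lo)
    max_contrib = span_contrib.max()
    if max_contrib == 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    scale = 100.0 / max_contrib  # points per unit of linear predictor

    anchors = np.where(model.coef >= 0, lo, hi)
    point_slopes = model.coef * scale
    base_lp = model.intercept + float(anchors @ model.coef)
    return Nomogram(
        feature_names=names,
        anchors=anchors,
        point_slopes=point_slopes,
        max_points=span_contrib * scale,
        base_lp=base_lp,
        points_to_lp=1.0 / scale,
    )


def calibration_curve(probabilities, labels, bin_edges) -> pd.DataFrame:
    """Mean predicted probability vs observed event rate per bin."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    idx = np.clip(np.searchsorted(bin_edges, p, side="right") - 1, 0,
                  len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        if not sel.any():
            rows.append({"bin": b, "n": 0, "mean_predicted": np.nan,
                         "observed": np.nan})
        else:
            rows.append({"bin": b, "n": int(sel.sum()),
                         "mean_predicted": float(p[sel].mean()),
                         "observed": float(y[sel].mean())})
    return pd.DataFrame(rows)


def _decile_edges(probabilities: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(probabilities, np.linspace(0, 1, n_bins + 1)))
    edges[0], edges[-1] = 0.0, 1.0
    if len(edges) < 3:
        raise ValueError("predicted probabilities too concentrated to bin")
    return edges


def calibration_bootstrap(model: DiagnosticModel, features, labels,
                          n_boot: int = 1000, n_bins: int = 10,
                          seed: int = 0) -> pd.DataFrame:
    """Optimism-corrected calibration curve by bootstrap refitting.

    The apparent curve bins the model's predictions on the original data
    into (by default) deciles.  For each bootstrap resample the model is
    refitted; the per-bin miscalibration (observed - predicted) on the
    resample minus that on the original data estimates the optimism, and
    the corrected observed rate is the apparent one minus the mean
    optimism.  Bins with fewer than 2 subjects are merged with their
    neighbor (with a warning).  Resamples with separation or a missing
    class are skipped.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X, _ = _as_matrix(features)
    y = np.asarray(labels, dtype=float).ravel()
    p_app = model.predict_proba(X)

    edges = _decile_edges(p_app, n_bins)
    # merge sparse bins with the left neighbor
    counts = np.histogram(p_app, bins=edges)[0]
    while np.any(counts < 2) and len(edges) > 2:
        b = int(np.argmin(counts))
        warnings.warn("merging calibration bin with < 2 subjects")
        drop = b + 1 if b + 1 < len(edges) - 1 else b
        edges = np.delete(edges, drop)
        counts = np.histogram(p_app, bins=edges)[0]

    apparent = calibration_curve(p_app, y, edges)
    miscal_app = apparent["observed"] - apparent["mean_predicted"]

    rng = np.random.default_rng(seed)
    optimism_draws = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(y), size=len(y))
        yb = y[idx]
        if yb.sum() in (0, len(yb)):
            skipped += 1
            continue
        try:
            mb = fit_logistic(X[idx], yb)
        except (SeparationError, ValueError):
            skipped += 1
            continue
        cb = calibration_curve(mb.predict_proba(X[idx]), yb, edges)
        co = calibration_curve(mb.predict_proba(X), y, edges)
        optimism_draws.append(
            (cb["observed"] - cb["mean_predicted"])
            - (co["observed"] - co["mean_predicted"])
        )
    if not optimism_draws:
        raise RuntimeError("all bootstrap resamples failed to refit")

    optimism = pd.concat(optimism_draws, axis=1).mean(axis=1, skipna=True)
    out = apparent.copy()
    out["optimism"] = optimism
    out["observed_corrected"] = miscal_app - optimism + out["mean_predicted"]
    out.attrs["n_boot_used"] = n_boot - skipped
    out.attrs["seed"] = seed
    return out


def decision_curve(probabilities, labels, thresholds) -> pd.DataFrame:
    """Net benefit of the model vs treat-all and treat-none strategies.

    At threshold probability pt, subjects with predicted probability
    >= pt are called positive and net benefit = TP/N - FP/N * pt/(1-pt).
    Treat-none is identically zero; treat-all tends to the prevalence as
    pt -> 0.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(bool)
    pt = np.asarray(thresholds, dtype=float)
    if pt.size == 0:
        raise ValueError("empty threshold grid")
    if np.any((pt <= 0) | (pt >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")

    n = y.size
    prevalence = y.mean()
    odds = pt / (1.0 - pt)
    rows = []
    for t, w in zip(pt, odds):
        called = p >= t
        tp = np.sum(called & y) / n
        fp = np.sum(called & ~y) / n
        rows.append({
            "threshold": float(t),
            "net_benefit_model": float(tp - fp * w),
            "net_benefit_all": float(prevalence - (1 - prevalence) * w),
            "net_benefit_none": 0.0,
        })
    return pd.DataFrame(rows)
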