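"""Performance statistics for the screening assay.

ROC/AUC (rank formulation with half-credit for ties), confusion-matrix
metrics at a threshold, logistic recalibration intercept/slope,
permutation feature importance as mean AUC decrease, paired-bootstrap F1
comparison, and the clinical subgroup reports (PSA grey zone 4-10 ng/mL,
per-stage sensitivity, per-grade score summaries).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "EvalMetrics",
    "CalibrationResult",
    "PermutationImportanceResult",
    "BootstrapComparison",
    "SubgroupReport",
    "roc_auc",
    "roc_points",
    "confusion_metrics",
    "f1_score",
    "calibration",
    "permutation_importance",
    "bootstrap_f1_comparison",
    "grey_zone_report",
    "per_stage_sensitivity",
    "grade_score_summary",
]

GREY_ZONE = (4.0, 10.0)  # ng/mL, both ends inclusive


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        return (labels == "cancer").astype(int)
    return labels.astype(int)


# ---------------------------------------------------------------------------
# ROC / AUC


def roc_auc(scores, labels) -> float:
    """AUC as P(score_cancer > score_noncancer) + 0.5 P(tie).

    The rank (Mann-Whitney) formulation; equals the trapezoidal area under
    the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute AUC")
    r = stats.rankdata(scores)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def roc_points(scores, labels) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold)."""
    from sklearn.metrics import roc_curve

    y = _as_binary(labels)
    fpr, tpr, thr = roc_curve(y, np.asarray(scores, dtype=float))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


# ---------------------------------------------------------------------------
# confusion metrics and F1


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity.

    F1 = 2 * precision * sensitivity / (precision + sensitivity); the
    (0, 0) corner is defined as 0 by the limit convention.
    """
    if not (0 <= precision <= 1 and 0 <= sensitivity <= 1):
        raise ValueError("precision and sensitivity must lie in [0, 1]")
    if precision == 0 and sensitivity == 0:
        warnings.warn("precision and sensitivity both zero; F1 defined as 0")
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


@dataclass(frozen=True)
class EvalMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else float("nan")

    @property
    def ppv(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def npv(self) -> float:
        d = self.tn + self.fn
        return self.tn / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    @property
    def f1(self) -> float:
        p, s = self.ppv, self.sensitivity
        if np.isnan(p) or np.isnan(s):
            return float("nan")
        return f1_score(p, s)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn, "n": self.n,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "npv": self.npv, "accuracy": self.accuracy, "f1": self.f1,
        }


def confusion_metrics(scores, labels, threshold: float) -> EvalMetrics:
    """2x2-table metrics with the rule: positive iff score >= threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    pred = scores >= threshold
    return EvalMetrics(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        tn=int((~pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
    )


# ---------------------------------------------------------------------------
# calibration


@dataclass(frozen=True)
class CalibrationResult:
    """Logistic recalibration of predicted probabilities.

    ``slope`` is the coefficient on logit(predicted) in the free-slope
    refit (ideal 1); ``intercept`` is calibration-in-the-large, i.e. the
    intercept of the refit with the slope fixed at 1 (ideal 0).  The
    intercept of the free-slope fit is kept as ``intercept_free``; the two
    intercept conventions coincide only when the slope is 1.
    """

    intercept: float
    slope: float
    intercept_free: float
    n: int


def calibration(predicted_probs, labels, clip: float = 1e-6) -> CalibrationResult:
    """Fit outcome ~ logit(predicted) by maximum likelihood."""
    p = np.clip(np.asarray(predicted_probs, dtype=float), clip, 1 - clip)
    y = _as_binary(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present for calibration")
    if np.ptp(p) == 0:
        raise ValueError("calibration undefined for constant predictions")
    lp = np.log(p / (1 - p))
    free = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
    fixed = sm.GLM(y, np.ones((len(y), 1)), offset=lp, family=sm.families.Binomial()).fit()
    return CalibrationResult(
        intercept=float(fixed.params[0]),
        slope=float(free.params[1]),
        intercept_free=float(free.params[0]),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# permutation importance


@dataclass(frozen=True)
class PermutationImportanceResult:
    delta_auc: dict[str, float]  # percentage points
    auc_original: float
    mean_auc_shuffled: dict[str, float]
    n_permutations: int
    seed: int


def permutation_importance(
    features: pd.DataFrame,
    labels,
    model,
    n_permutations: int = 2000,
    seed: int = 0,
) -> PermutationImportanceResult:
    """Mean AUC decrease when one input column is shuffled across samples.

    ``features`` must hold columns (cnv_score, fsc_score, psa) and
    ``model`` an integrated fit exposing ``predict(cnv, fsc, psa)``.  For
    each feature the column is shuffled ``n_permutations`` times with the
    other two untouched, the model re-scores the shuffled data, and
    dAUC = mean original AUC - mean shuffled AUC, in percentage points.
    The model itself stays fixed (no refitting).

    Shuffling commutes with any per-column monotone rescaling and AUC is
    rank-invariant, so standardizing features (with PSA log-transformed)
    beforehand would leave every dAUC unchanged; columns are therefore
    shuffled on their native scale.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    cols = ["cnv_score", "fsc_score", "psa"]
    X = features[cols].to_numpy(dtype=float)
    y = _as_binary(labels)
    auc0 = roc_auc(model.predict(X[:, 0], X[:, 1], X[:, 2]), y)
    rng = np.random.default_rng(seed)
    delta: dict[str, float] = {}
    mean_shuffled: dict[str, float] = {}
    for j, name in enumerate(cols):
        aucs = np.empty(n_permutations)
        for b in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            aucs[b] = roc_auc(model.predict(Xp[:, 0], Xp[:, 1], Xp[:, 2]), y)
        mean_shuffled[name] = float(aucs.mean())
        delta[name] = 100.0 * (auc0 - mean_shuffled[name])
    return PermutationImportanceResult(delta, auc0, mean_shuffled, n_permutations, seed)


# ---------------------------------------------------------------------------
# paired bootstrap F1 comparison


@dataclass(frozen=True)
class BootstrapComparison:
    f1_a: float
    f1_b: float
    diff_mean: float
    diff_ci: tuple[float, float]
    p_value: float
    n_boot: int
    n_skipped: int
    seed: int


def bootstrap_f1_comparison(
    scores_a, threshold_a: float,
    scores_b, threshold_b: float,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
) -> BootstrapComparison:
    """Paired bootstrap of the F1 difference between two assays.

    Samples are resampled with replacement; each replicate recomputes both
    F1 scores on the same resample.  Replicates without any positive label
    (F1 undefined) are skipped; more than 10% skipped is an error.  The
    two-sided p-value uses add-one smoothing, so it is never exactly 0.
    """
    a = np.asarray(scores_a, dtype=float) >= threshold_a
    b = np.asarray(scores_b, dtype=float) >= threshold_b
    y = _as_binary(labels).astype(bool)
    n = len(y)

    def f1_of(pred: np.ndarray, yy: np.ndarray) -> float:
        tp = int((pred & yy).sum())
        fp = int((pred & ~yy).sum())
        fn = int((~pred & yy).sum())
        prec = tp / (tp + fp) if tp + fp else 0.0
        sens = tp / (tp + fn) if tp + fn else 0.0
        if prec == 0 and sens == 0:
            return 0.0
        return 2 * prec * sens / (prec + sens)

    f1_a, f1_b = f1_of(a, y), f1_of(b, y)
    rng = np.random.default_rng(seed)
    diffs = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        yy = y[idx]
        if not yy.any():
            skipped += 1
            continue
        diffs.append(f1_of(a[idx], yy) - f1_of(b[idx], yy))
    if skipped > 0.1 * n_boot:
        raise ValueError(f"{skipped}/{n_boot} bootstrap replicates had no positives")
    diffs = np.asarray(diffs)
    m = len(diffs)
    p_le = (1 + int((diffs <= 0).sum())) / (m + 1)
    p_ge = (1 + int((diffs >= 0).sum())) / (m + 1)
    p = min(1.0, 2.0 * min(p_le, p_ge))
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return BootstrapComparison(
        f1_a, f1_b, float(diffs.mean()), (float(lo), float(hi)), p, n_boot, skipped, seed
    )


# ---------------------------------------------------------------------------
# subgroup reports


@dataclass(frozen=True)
class SubgroupReport:
    n: int
    assay: EvalMetrics | None
    psa_as_score: EvalMetrics | None
    auc_assay: float | None
    auc_psa: float | None


def grey_zone_report(
    scores, labels, psa, threshold: float,
    psa_threshold: float = 4.0,
    zone: tuple[float, float] = GREY_ZONE,
) -> SubgroupReport:
    """Assay vs PSA-alone performance among samples with PSA in [4, 10] ng/mL.

    Both zone ends are inclusive.  PSA is also used directly as a score
    (positive iff PSA >= ``psa_threshold``) for the side-by-side
    comparison the grey zone motivates.
    """
    scores = np.asarray(scores, dtype=float)
    psa = np.asarray(psa, dtype=float)
    y = _as_binary(labels)
    m = (psa >= zone[0]) & (psa <= zone[1])
    if not m.any():
        return SubgroupReport(0, None, None, None, None)
    sub_y = y[m]
    assay = confusion_metrics(scores[m], sub_y, threshold)
    psa_m = confusion_metrics(psa[m], sub_y, psa_threshold)
    both = sub_y.min() != sub_y.max()
    return SubgroupReport(
        int(m.sum()),
        assay,
        psa_m,
        roc_auc(scores[m], sub_y) if both else None,
        roc_auc(psa[m], sub_y) if both else None,
    )


def per_stage_sensitivity(scores, labels, stage, threshold: float) -> pd.DataFrame:
    """Detected / total / percent per disease stage among cancer samples.

    Stages with no members are omitted; percentages are reported to one
    decimal place.
    """
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    stage = np.asarray(stage, dtype=object)
    rows = []
    for st in ("I", "II", "III", "IV"):
        m = (y == 1) & (stage == st)
        total = int(m.sum())
        if total == 0:
            continue
        detected = int((scores[m] >= threshold).sum())
        rows.append({"stage": st, "detected": detected, "total": total,
                     "percent": round(100.0 * detected / total, 1)})
    return pd.DataFrame(rows, columns=["stage", "detected", "total", "percent"])


def grade_score_summary(scores, labels, grade) -> pd.DataFrame:
    """Median/IQR of scores per histological grade among cancer samples."""
    scores = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    grade = np.asarray(grade, dtype=object)
    rows = []
    for g in pd.unique(grade[(y == 1) & (grade != None) & (grade != "")]):  # noqa: E711
        m = (y == 1) & (grade == g)
        q1, q2, q3 = np.percentile(scores[m], [25, 50, 75])
        rows.append({"grade": g, "n": int(m.sum()), "median": q2, "q1": q1, "q3": q3})
    return pd.DataFrame(rows, columns=["grade", "n", "median", "q1", "q3"])
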