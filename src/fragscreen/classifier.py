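"""Stacked fragmentomic classifier and PSA-integrated model.

Architecture, mirroring the assay's training procedure:

1. per-feature two-sample t-test selection (p < 0.01, unadjusted) applied
   separately to the CNV and FSC matrices;
2. one gradient-boosted tree base learner per feature family, tuned by a
   seeded random search over predefined hyperparameter ranges with k-fold
   inner cross-validation on log-loss, emitting out-of-fold probabilities
   (cnv_score, fsc_score);
3. an elastic-net logistic stacker trained on the out-of-fold base scores,
   emitting the fragmentomic score;
4. an XGBoost integrated model on exactly (cnv_score, fsc_score, PSA) with
   fixed published hyperparameters, emitting the integrated score;
5. leave-one-out cross-validation that repeats steps 1-4 inside every
   fold, so no statistic of the held-out sample touches its fold's fit;
6. a decision threshold chosen as the smallest cut-point achieving a
   target specificity (98%) among non-cancer samples with PSA >= 4 ng/mL.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "FeatureSelectionConfig",
    "BaseLearnerConfig",
    "StackerConfig",
    "IntegratedModelConfig",
    "ThresholdPolicy",
    "ThresholdResult",
    "select_features",
    "train_base_learner",
    "train_stacker",
    "train_integrated",
    "train_full",
    "run_loocv",
    "choose_threshold",
]


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class FeatureSelectionConfig:
    alpha: float = 0.01
    equal_var: bool = False  # Welch by default; True restores the pooled form

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class BaseLearnerConfig:
    """Seeded random search over gradient-boosted tree hyperparameters."""

    n_configs: int = 20
    depth_range: tuple[int, int] = (2, 6)
    eta_range: tuple[float, float] = (0.01, 0.3)  # log-uniform
    rounds_range: tuple[int, int] = (50, 500)
    subsample_range: tuple[float, float] = (0.5, 1.0)
    colsample_range: tuple[float, float] = (0.5, 1.0)
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_configs < 1:
            raise ValueError("need at least one candidate configuration")
        if self.inner_folds < 2:
            raise ValueError("inner CV needs k >= 2")


@dataclass(frozen=True)
class StackerConfig:
    l1_ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambda: int = 8  # log-spaced inverse-penalty path 1e-2 .. 1e2
    inner_folds: int = 5
    seed: int = 0


@dataclass(frozen=True)
class IntegratedModelConfig:
    """Fixed published XGBoost hyperparameters for the PSA-integrated model."""

    max_depth: int = 3
    gamma: float = 1.0
    reg_alpha: float = 0.5
    subsample: float = 0.75
    colsample_bytree: float = 0.7
    eta: float = 0.01
    n_rounds: int = 1000
    early_stopping_rounds: int = 20
    holdout_fraction: float = 0.2
    seed: int = 0


@dataclass(frozen=True)
class ThresholdPolicy:
    target_specificity: float = 0.98
    psa_min: float = 4.0
    #: decision threshold the assay reported on its own training cohort;
    #: a constant of record, never asserted against synthetic data
    reported_reference_threshold: float = 0.7294

    def __post_init__(self) -> None:
        if not (0 < self.target_specificity < 1):
            raise ValueError("target specificity must lie in (0, 1)")


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    achieved_specificity: float
    n_subcohort: int


# ---------------------------------------------------------------------------
# feature selection


def select_features(
    X, y, config: FeatureSelectionConfig = FeatureSelectionConfig()
) -> np.ndarray:
    """Indices of features whose two-sided t-test p-value is < alpha.

    Features with zero variance in both groups are excluded before
    testing.  Deterministic given X and y.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if X[y].shape[0] < 2 or X[~y].shape[0] < 2:
        raise ValueError("each class needs >= 2 samples for the t-test")
    p = _welch_pvalues(X, y, config)
    return np.flatnonzero(p < config.alpha)


def _welch_pvalues(X: np.ndarray, y: np.ndarray, config: FeatureSelectionConfig) -> np.ndarray:
    """Per-feature two-sided t-test p-values; overall-constant features get 1.

    A feature with zero variance in both groups but differing means is a
    perfect separator: its p-value is set to 0 rather than left undefined.
    """
    var1, var0 = X[y].var(axis=0), X[~y].var(axis=0)
    mean1, mean0 = X[y].mean(axis=0), X[~y].mean(axis=0)
    zero_both = (var1 == 0) & (var0 == 0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(X[y], X[~y], axis=0, equal_var=config.equal_var)
    p = np.nan_to_num(p, nan=1.0)
    p[zero_both & (mean1 != mean0)] = 0.0
    p[zero_both & (mean1 == mean0)] = 1.0  # constant feature: untestable
    return p


def _selection_with_fallback(X, y, config: FeatureSelectionConfig) -> np.ndarray:
    """As select_features, but fall back to the single smallest-p feature.

    At p < 0.01 a null cohort can select nothing; the pipeline still needs
    a score, so the best-ranked feature is used (and carries no signal in
    that regime by construction).
    """
    idx = select_features(X, y, config)
    if len(idx) > 0:
        return idx
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    return np.array([int(np.argmin(_welch_pvalues(X, y, config)))])


# ---------------------------------------------------------------------------
# base learners


def _xgb_params(depth: int, eta: float, subsample: float, colsample: float, seed: int) -> dict:
    return {
        "objective": "binary:logistic",
        "eval_metric": "logloss",
        "tree_method": "hist",
        "max_bin": 128,
        "nthread": 1,
        "verbosity": 0,
        "max_depth": depth,
        "eta": eta,
        "subsample": subsample,
        "colsample_bytree": colsample,
        "seed": int(seed) % (2**31),
    }


@dataclass
class BaseLearnerFit:
    booster: xgb.Booster
    params: dict
    n_rounds: int
    oof_prob: np.ndarray
    cv_logloss: float

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.booster.predict(xgb.DMatrix(X, nthread=1))


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified folds whose training parts contain both classes.

    A degenerate single-class training part triggers one seeded redraw,
    then an error.
    """
    for attempt in (0, 1):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + attempt) % (2**31))
        folds = list(skf.split(np.zeros(len(y)), y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            return folds
    raise ValueError("cannot build folds with both classes in every training part")


def train_base_learner(
    X, y, config: BaseLearnerConfig = BaseLearnerConfig()
) -> BaseLearnerFit:
    """Random-search a gradient-boosted learner; return fit + out-of-fold scores.

    The best of ``n_configs`` random configurations by inner-CV log-loss is
    refit on the full data; out-of-fold probabilities come from that
    configuration's CV folds, so every training sample is scored by models
    that never saw it.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(config.seed)
    candidates = []
    for _ in range(config.n_configs):
        lo, hi = config.eta_range
        candidates.append(
            dict(
                depth=int(rng.integers(config.depth_range[0], config.depth_range[1] + 1)),
                eta=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                rounds=int(rng.integers(config.rounds_range[0], config.rounds_range[1] + 1)),
                subsample=float(rng.uniform(*config.subsample_range)),
                colsample=float(rng.uniform(*config.colsample_range)),
            )
        )
    folds = _stratified_folds(y, config.inner_folds, config.seed)
    fold_dm = [
        (
            xgb.DMatrix(X[tr], label=y[tr], nthread=1),
            xgb.DMatrix(X[te], nthread=1),
            te,
        )
        for tr, te in folds
    ]
    best = None
    for c in candidates:
        params = _xgb_params(c["depth"], c["eta"], c["subsample"], c["colsample"], config.seed)
        oof = np.empty(len(y))
        for dtr, dte, te in fold_dm:
            bst = xgb.train(params, dtr, num_boost_round=c["rounds"])
            oof[te] = bst.predict(dte)
        ll = log_loss(y, oof, labels=[0, 1])
        if best is None or ll < best[0]:
            best = (ll, c, oof)
    ll, c, oof = best
    params = _xgb_params(c["depth"], c["eta"], c["subsample"], c["colsample"], config.seed)
    booster = xgb.train(params, xgb.DMatrix(X, label=y, nthread=1), num_boost_round=c["rounds"])
    return BaseLearnerFit(booster, params, c["rounds"], oof, ll)


# ---------------------------------------------------------------------------
# stacker


@dataclass
class StackerFit:
    model: LogisticRegression
    l1_ratio: float
    C: float
    cv_logloss: float

    def predict(self, cnv_score, fsc_score) -> np.ndarray:
        Z = np.column_stack([np.atleast_1d(cnv_score), np.atleast_1d(fsc_score)])
        return self.model.predict_proba(Z)[:, 1]

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_.ravel()


def _fit_enet_logistic(Z, y, C: float, l1_ratio: float) -> LogisticRegression:
    m = LogisticRegression(
        penalty="elasticnet", solver="saga", C=C, l1_ratio=l1_ratio,
        max_iter=10_000, tol=1e-6, random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m.fit(Z, y)
    return m


def train_stacker(
    oof_cnv, oof_fsc, y, config: StackerConfig = StackerConfig()
) -> StackerFit:
    """Elastic-net logistic stacker over the two out-of-fold base scores.

    The (mixing, penalty) grid is scored by inner-CV log-loss; the winner
    is refit on all samples.
    """
    Z = np.column_stack([np.asarray(oof_cnv, float), np.asarray(oof_fsc, float)])
    y = np.asarray(y).astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 10:
        warnings.warn("fewer than 10 samples per class: stacker may be unstable")
    Cs = np.logspace(-2, 2, config.n_lambda)
    folds = _stratified_folds(y, config.inner_folds, config.seed)
    best = None
    for l1 in config.l1_ratios:
        for C in Cs:
            oof = np.empty(len(y))
            for tr, te in folds:
                m = _fit_enet_logistic(Z[tr], y[tr], C, l1)
                oof[te] = m.predict_proba(Z[te])[:, 1]
            ll = log_loss(y, oof, labels=[0, 1])
            if best is None or ll < best[0]:
                best = (ll, l1, C)
    ll, l1, C = best
    return StackerFit(_fit_enet_logistic(Z, y, C, l1), l1, C, ll)


# ---------------------------------------------------------------------------
# integrated model


@dataclass
class IntegratedFit:
    booster: xgb.Booster
    best_iteration: int

    def predict(self, cnv_score, fsc_score, psa) -> np.ndarray:
        X = np.column_stack(
            [np.atleast_1d(cnv_score), np.atleast_1d(fsc_score), np.atleast_1d(psa)]
        )
        return self.booster.predict(
            xgb.DMatrix(X, nthread=1), iteration_range=(0, self.best_iteration + 1)
        )


def train_integrated(
    cnv_score, fsc_score, psa, y, config: IntegratedModelConfig = IntegratedModelConfig()
) -> IntegratedFit:
    """Fit the XGBoost integrated model on exactly (cnv_score, fsc_score, psa).

    Hyperparameters are fixed (logloss, max_depth 3, gamma 1, alpha 0.5,
    subsample 0.75, colsample_bytree 0.7, eta 0.01, up to 1000 rounds,
    early-stopping patience 20 on a seeded 20% class-stratified holdout).
    PSA must be present for every sample; there is no imputation.
    """
    psa = np.asarray(psa, dtype=float)
    if np.any(~np.isfinite(psa)):
        raise ValueError("missing or non-finite PSA values")
    X = np.column_stack([np.asarray(cnv_score, float), np.asarray(fsc_score, float), psa])
    y = np.asarray(y).astype(int)
    idx_tr, idx_val = train_test_split(
        np.arange(len(y)), test_size=config.holdout_fraction,
        stratify=y, random_state=int(config.seed) % (2**31),
    )
    params = {
        "objective": "binary:logistic",
        "eval_metric": "logloss",
        "max_depth": config.max_depth,
        "gamma": config.gamma,
        "alpha": config.reg_alpha,
        "subsample": config.subsample,
        "colsample_bytree": config.colsample_bytree,
        "eta": config.eta,
        "tree_method": "hist",
        "nthread": 1,
        "verbosity": 0,
        "seed": int(config.seed) % (2**31),
    }
    dtr = xgb.DMatrix(X[idx_tr], label=y[idx_tr], nthread=1)
    dval = xgb.DMatrix(X[idx_val], label=y[idx_val], nthread=1)
    bst = xgb.train(
        params, dtr, num_boost_round=config.n_rounds,
        evals=[(dval, "holdout")],
        early_stopping_rounds=config.early_stopping_rounds,
        verbose_eval=False,
    )
    best_it = getattr(bst, "best_iteration", None)
    if best_it is None:
        best_it = config.n_rounds - 1
    return IntegratedFit(bst, int(best_it))


# ---------------------------------------------------------------------------
# full training and LOOCV


@dataclass
class AssayConfigs:
    selection: FeatureSelectionConfig = field(default_factory=FeatureSelectionConfig)
    base: BaseLearnerConfig = field(default_factory=BaseLearnerConfig)
    stacker: StackerConfig = field(default_factory=StackerConfig)
    integrated: IntegratedModelConfig = field(default_factory=IntegratedModelConfig)
    seed: int = 0

    def reseeded(self, *tokens: int) -> "AssayConfigs":
        """Derive per-component seeds deterministically from (seed, tokens)."""
        ss = np.random.SeedSequence([int(self.seed), *map(int, tokens)])
        s = [int(x) for x in ss.generate_state(4) % (2**31)]
        import dataclasses as dc

        return AssayConfigs(
            selection=self.selection,
            base=dc.replace(self.base, seed=s[0]),
            stacker=dc.replace(self.stacker, seed=s[1]),
            integrated=dc.replace(self.integrated, seed=s[2]),
            seed=self.seed,
        )


@dataclass
class FittedAssay:
    selected_cnv: np.ndarray
    selected_fsc: np.ndarray
    base_cnv: BaseLearnerFit
    base_fsc: BaseLearnerFit
    stacker: StackerFit
    integrated: IntegratedFit

    def score(self, cnv_X, fsc_X, psa, provenance: str = "external") -> pd.DataFrame:
        cnv_X = np.atleast_2d(np.asarray(cnv_X, float))
        fsc_X = np.atleast_2d(np.asarray(fsc_X, float))
        cnv_s = self.base_cnv.predict(cnv_X[:, self.selected_cnv])
        fsc_s = self.base_fsc.predict(fsc_X[:, self.selected_fsc])
        frag_s = self.stacker.predict(cnv_s, fsc_s)
        integ_s = self.integrated.predict(cnv_s, fsc_s, psa)
        return pd.DataFrame(
            {
                "cnv_score": cnv_s,
                "fsc_score": fsc_s,
                "fragmentomic_score": frag_s,
                "integrated_score": integ_s,
                "provenance": provenance,
            }
        )

    def save(self, out_dir) -> None:
        """Serialize the assay to a directory of JSON artifacts."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.base_cnv.booster.save_model(str(out / "base_cnv.json"))
        self.base_fsc.booster.save_model(str(out / "base_fsc.json"))
        self.integrated.booster.save_model(str(out / "integrated.json"))
        meta = {
            "selected_cnv": self.selected_cnv.tolist(),
            "selected_fsc": self.selected_fsc.tolist(),
            "stacker": {
                "coef": self.stacker.coef_.tolist(),
                "intercept": float(self.stacker.model.intercept_[0]),
                "l1_ratio": self.stacker.l1_ratio,
                "C": self.stacker.C,
            },
            "integrated_best_iteration": self.integrated.best_iteration,
            "base_cnv": {"params": self.base_cnv.params, "n_rounds": self.base_cnv.n_rounds},
            "base_fsc": {"params": self.base_fsc.params, "n_rounds": self.base_fsc.n_rounds},
        }
        (out / "assay.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, out_dir) -> "FittedAssay":
        import json
        from pathlib import Path

        out = Path(out_dir)
        meta = json.loads((out / "assay.json").read_text())

        def _load_booster(name: str) -> xgb.Booster:
            b = xgb.Booster()
            b.load_model(str(out / name))
            return b

        def _base(name: str, key: str) -> BaseLearnerFit:
            return BaseLearnerFit(
                _load_booster(name), meta[key]["params"], meta[key]["n_rounds"],
                oof_prob=np.empty(0), cv_logloss=float("nan"),
            )

        sk = meta["stacker"]
        lr = LogisticRegression(penalty="elasticnet", solver="saga",
                                C=sk["C"], l1_ratio=sk["l1_ratio"])
        lr.classes_ = np.array([0, 1])
        lr.coef_ = np.asarray([sk["coef"]], dtype=float)
        lr.intercept_ = np.asarray([sk["intercept"]], dtype=float)
        stacker = StackerFit(lr, sk["l1_ratio"], sk["C"], float("nan"))
        integrated = IntegratedFit(_load_booster("integrated.json"),
                                   meta["integrated_best_iteration"])
        return cls(
            np.asarray(meta["selected_cnv"], dtype=int),
            np.asarray(meta["selected_fsc"], dtype=int),
            _base("base_cnv.json", "base_cnv"),
            _base("base_fsc.json", "base_fsc"),
            stacker,
            integrated,
        )


def train_full(cnv_X, fsc_X, psa, y, configs: AssayConfigs = AssayConfigs()) -> FittedAssay:
    """Train the deployed assay on a full cohort.

    Selection runs once on the whole cohort; the stacker and the
    integrated model are trained on the base learners' out-of-fold scores
    (in-sample base scores would make them degenerate).
    """
    cnv_X = np.asarray(cnv_X, dtype=float)
    fsc_X = np.asarray(fsc_X, dtype=float)
    y = np.asarray(y).astype(int)
    cfg = configs.reseeded(0)
    sel_cnv = _selection_with_fallback(cnv_X, y, cfg.selection)
    sel_fsc = _selection_with_fallback(fsc_X, y, cfg.selection)
    import dataclasses as dc

    base_cnv = train_base_learner(cnv_X[:, sel_cnv], y, cfg.base)
    base_fsc = train_base_learner(
        fsc_X[:, sel_fsc], y, dc.replace(cfg.base, seed=(cfg.base.seed + 1) % 2**31)
    )
    stacker = train_stacker(base_cnv.oof_prob, base_fsc.oof_prob, y, cfg.stacker)
    integrated = train_integrated(base_cnv.oof_prob, base_fsc.oof_prob, psa, y, cfg.integrated)
    return FittedAssay(sel_cnv, sel_fsc, base_cnv, base_fsc, stacker, integrated)


def run_loocv(
    cnv_X, fsc_X, psa, y,
    configs: AssayConfigs = AssayConfigs(),
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Leave-one-out cross-validation with the full pipeline inside each fold.

    For every held-out sample the t-test selection, both base-learner
    searches, the stacker and the integrated model are trained on the
    remaining n-1 samples only; the held-out sample is then scored by that
    fold's models.  Returns out-of-sample scores, one row per sample.
    """
    cnv_X = np.asarray(cnv_X, dtype=float)
    fsc_X = np.asarray(fsc_X, dtype=float)
    psa = np.asarray(psa, dtype=float)
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs n >= 10")
    if (y == 1).sum() < 2 or (y == 0).sum() < 2:
        raise ValueError("each class needs >= 2 samples for LOOCV")
    rows = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        cfg = configs.reseeded(i + 1)
        fit = train_full(cnv_X[mask], fsc_X[mask], psa[mask], y[mask], cfg)
        rows.append(
            fit.score(cnv_X[i], fsc_X[i], np.array([psa[i]]), provenance="loocv").iloc[0]
        )
    out = pd.DataFrame(rows).reset_index(drop=True)
    out.insert(0, "sample_id", list(sample_ids) if sample_ids is not None else list(range(n)))
    return out


# ---------------------------------------------------------------------------
# thresholding


def choose_threshold(
    scores, labels, psa, policy: ThresholdPolicy = ThresholdPolicy()
) -> ThresholdResult:
    """Smallest cut-point achieving the target specificity in the subcohort.

    The subcohort is non-cancer samples with PSA >= ``policy.psa_min``.
    Candidate cut-points are the midpoints between adjacent distinct
    sorted subcohort scores plus a +inf sentinel; classification is
    positive iff score >= threshold, so subcohort specificity at t is the
    fraction of subcohort scores strictly below t.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    noncancer = (labels == 0) | (labels == "non-cancer")
    psa = np.asarray(psa, dtype=float)
    sub = scores[noncancer & (psa >= policy.psa_min)]
    if len(sub) == 0:
        raise ValueError("empty thresholding subcohort (non-cancer, PSA >= min)")
    s = np.unique(sub)
    candidates = np.concatenate([(s[:-1] + s[1:]) / 2.0, [np.inf]])
    for t in candidates:
        achieved = float(np.mean(sub < t))
        if achieved >= policy.target_specificity:
            return ThresholdResult(float(t), achieved, len(sub))
    raise AssertionError("unreachable: +inf sentinel always achieves specificity 1")
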