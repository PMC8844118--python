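"""Habitat suitability model fitting, evaluation, gating and ensembling.

Four learner families are wrapped behind one sklearn-style estimator,
:class:`HsmModel`: a binomial GLM with quadratic terms, a binomial GAM
(B-spline smooths with penalty chosen on a small AIC grid), boosted
classification trees, and a 500-tree random forest with probability
output. All predict a suitability in [0, 1], clipped away from the exact
bounds so downstream correlations stay defined.

Evaluation on spatially independent test folds uses RMSE, rank-based AUC
(probability that a random presence outscores a random absence, ties at
half weight) and the True Skill Statistic (sensitivity + specificity - 1,
maximized over a 0.01-step threshold grid). Models clearing AUC >= 0.7 and
TSS >= 0.4 are retained; multiple retained models for a sample form an
AUC-weighted ensemble (EM_wmean), a single one passes through unchanged
(HSM_unique). Variable importance is the permutation-based,
algorithm-independent score: 1 minus the correlation between original and
variable-permuted predictions, standardized to percentages summing to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "HsmModel",
    "WeightedEnsemble",
    "EvalMetrics",
    "fit_hsm",
    "rmse",
    "auc",
    "tss_best",
    "evaluate",
    "select_models",
    "ensemble_wmean",
    "permutation_importance",
]

ALGORITHMS = ("glm", "gam", "gbm", "rf")
PRED_CLIP = 1e-6


class HsmModel(BaseEstimator):
    """One habitat suitability learner behind a common fit/predict surface.

    Parameters
    ----------
    algorithm : {"glm", "gam", "gbm", "rf"}
        glm  - binomial GLM on standardized linear + quadratic terms;
        gam  - binomial additive model, B-spline smooth per variable,
               penalty weight picked from ``gam_alphas`` by AIC;
        gbm  - gradient-boosted trees, log-loss, fixed defaults;
        rf   - random forest, ``rf_trees`` trees, probability = fraction
               of trees voting presence.
    random_state : int
        Seed for the stochastic learners.

    Fitted attributes end in an underscore (``model_``, ``variables_``).
    """

    def __init__(
        self,
        algorithm: str = "glm",
        random_state: int = 0,
        rf_trees: int = 500,
        gbm_trees: int = 100,
        gam_df: int = 6,
        gam_alphas: Sequence[float] = (0.1, 1.0, 10.0),
    ):
        self.algorithm = algorithm
        self.random_state = random_state
        self.rf_trees = rf_trees
        self.gbm_trees = gbm_trees
        self.gam_df = gam_df
        self.gam_alphas = gam_alphas

    # -- helpers ---------------------------------------------------------

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        return pd.DataFrame(np.asarray(X, dtype=float))

    def _check_design(self, X: pd.DataFrame) -> None:
        """Flag exactly collinear / constant columns for the GLM path."""
        mat = X.to_numpy(dtype=float)
        sds = mat.std(axis=0)
        bad = [str(c) for c, s in zip(X.columns, sds) if s == 0]
        if bad:
            raise ValueError(f"constant variables in design: {bad}")
        std = (mat - mat.mean(axis=0)) / sds
        if np.linalg.matrix_rank(std) < std.shape[1]:
            offenders = []
            for j in range(std.shape[1]):
                others = np.delete(std, j, axis=1)
                coef, _, _, _ = np.linalg.lstsq(others, std[:, j], rcond=None)
                resid = std[:, j] - others @ coef
                if float(resid @ resid) < 1e-10 * len(std):
                    offenders.append(str(X.columns[j]))
            raise ValueError(f"singular design; collinear variables: {offenders}")

    def _glm_design(self, X: pd.DataFrame) -> np.ndarray:
        std = (X.to_numpy(dtype=float) - self._mean_) / self._sd_
        return sm.add_constant(np.column_stack([std, std**2]), has_constant="add")

    # -- estimator interface --------------------------------------------

    def fit(self, X, y) -> "HsmModel":
        X = self._as_frame(X)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != len(y):
            raise ValueError("X and y length mismatch")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        if X.shape[1] < 1:
            raise ValueError("need at least one predictor")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        self.variables_ = [str(c) for c in X.columns]

        if self.algorithm == "glm":
            self._check_design(X)
            self._mean_ = X.to_numpy(dtype=float).mean(axis=0)
            self._sd_ = X.to_numpy(dtype=float).std(axis=0)
            design = self._glm_design(X)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.model_ = sm.GLM(y, design, family=sm.families.Binomial()).fit(maxiter=100)
        elif self.algorithm == "gam":
            mat = X.to_numpy(dtype=float)
            self._mean_ = mat.mean(axis=0)
            self._sd_ = np.where(mat.std(axis=0) > 0, mat.std(axis=0), 1.0)
            std = (mat - self._mean_) / self._sd_
            p = std.shape[1]
            df = min(self.gam_df, max(4, len(y) // (3 * p)))
            self._smoother_ = BSplines(std, df=[df] * p, degree=[3] * p,
                                       include_intercept=False)
            best = None
            for alpha in self.gam_alphas:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = GLMGam(
                            y, np.ones((len(y), 1)), smoother=self._smoother_,
                            alpha=[alpha] * p, family=sm.families.Binomial(),
                        ).fit(maxiter=100)
                    if best is None or res.aic < best[0]:
                        best = (res.aic, res, alpha)
                except Exception:  # singular penalty/fit: try next alpha
                    continue
            if best is None:
                # separable or otherwise degenerate likelihood: fall back to a
                # ridge-penalized logistic fit on the same B-spline basis
                from sklearn.linear_model import LogisticRegression

                basis = self._smoother_.transform(std)
                self.model_ = LogisticRegression(C=1.0, max_iter=1000).fit(basis, y.astype(int))
                self._gam_mode_ = "ridge_basis"
                self.gam_alpha_ = None
            else:
                self.model_ = best[1]
                self._gam_mode_ = "glmgam"
                self.gam_alpha_ = best[2]
        elif self.algorithm == "gbm":
            self.model_ = GradientBoostingClassifier(
                n_estimators=self.gbm_trees,
                learning_rate=0.1,
                max_depth=3,
                random_state=self.random_state,
            ).fit(X.to_numpy(dtype=float), y.astype(int))
        else:  # rf
            self.model_ = RandomForestClassifier(
                n_estimators=self.rf_trees,
                random_state=self.random_state,
            ).fit(X.to_numpy(dtype=float), y.astype(int))
        return self

    def predict_suitability(self, X) -> np.ndarray:
        X = self._as_frame(X)
        if list(map(str, X.columns)) != self.variables_ and X.shape[1] != len(self.variables_):
            raise ValueError("prediction variables do not match training variables")
        if self.algorithm == "glm":
            with np.errstate(over="ignore"):
                pred = self.model_.predict(self._glm_design(X))
        elif self.algorithm == "gam":
            std = (X.to_numpy(dtype=float) - self._mean_) / self._sd_
            # clip to the spline support seen at training time
            std = np.clip(std, self._smoother_.x.min(axis=0), self._smoother_.x.max(axis=0))
            if self._gam_mode_ == "ridge_basis":
                pred = self.model_.predict_proba(self._smoother_.transform(std))[:, 1]
            else:
                pred = self.model_.predict(np.ones((len(std), 1)), exog_smooth=std)
        else:
            pred = self.model_.predict_proba(X.to_numpy(dtype=float))[:, 1]
        return np.clip(np.asarray(pred, dtype=float), PRED_CLIP, 1.0 - PRED_CLIP)

    # sklearn-compatible alias
    def predict(self, X) -> np.ndarray:
        return self.predict_suitability(X)


def fit_hsm(algorithm: str, X, y, random_state: int = 0, **kwargs) -> HsmModel:
    """Thin functional wrapper over :class:`HsmModel`."""
    return HsmModel(algorithm=algorithm, random_state=random_state, **kwargs).fit(X, y)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class EvalMetrics:
    rmse: float
    auc: float
    tss: float
    tss_threshold: float
    sensitivity: float
    specificity: float


def rmse(pred: np.ndarray, obs: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size == 0 or pred.shape != obs.shape:
        raise ValueError("pred and obs must be equal-length and non-empty")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def auc(pred: np.ndarray, obs: np.ndarray) -> float:
    """Rank-based AUC: fraction of (presence, absence) pairs where the
    presence outscores the absence, ties counted one half."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs)
    pos = pred[obs == 1]
    neg = pred[obs == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC needs at least one presence and one absence")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def tss_best(
    pred: np.ndarray, obs: np.ndarray, step: float = 0.01
) -> tuple[float, float, float, float]:
    """Max of sensitivity + specificity - 1 over a threshold grid.

    Binarization rule: presence predicted when score >= threshold. Ties on
    TSS resolve to the lowest threshold. Returns (tss, threshold,
    sensitivity, specificity)."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs)
    n_pos = int((obs == 1).sum())
    n_neg = int((obs == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("TSS needs at least one presence and one absence")
    thresholds = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    binarized = pred[None, :] >= thresholds[:, None]
    tp = (binarized & (obs == 1)[None, :]).sum(axis=1)
    tn = (~binarized & (obs == 0)[None, :]).sum(axis=1)
    sens = tp / n_pos
    spec = tn / n_neg
    tss = sens + spec - 1.0
    best = int(np.argmax(tss))  # argmax returns the first (lowest) on ties
    return float(tss[best]), float(thresholds[best]), float(sens[best]), float(spec[best])


def evaluate(pred: np.ndarray, obs: np.ndarray) -> EvalMetrics:
    t, thr, sens, spec = tss_best(pred, obs)
    return EvalMetrics(
        rmse=rmse(pred, obs),
        auc=auc(pred, obs),
        tss=t,
        tss_threshold=thr,
        sensitivity=sens,
        specificity=spec,
    )


def select_models(
    metrics: Mapping[object, EvalMetrics], auc_min: float = 0.7, tss_min: float = 0.4
) -> list:
    """Keys of the models clearing both discrimination gates (inclusive).
    An empty list is a legal outcome (no model enters projection)."""
    return [k for k, m in metrics.items() if m.auc >= auc_min and m.tss >= tss_min]


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------


class WeightedEnsemble(BaseEstimator):
    """AUC-weighted mean of member suitability predictions.

    Weight of member i is auc_i / sum(auc); a single member passes through
    with weight 1 and tag ``HSM_unique``.
    """

    def __init__(self, models: Sequence, aucs: Sequence[float]):
        if len(models) == 0:
            raise ValueError("ensemble needs at least one member")
        if len(models) != len(aucs):
            raise ValueError("one AUC per member required")
        self.models = list(models)
        self.aucs = [float(a) for a in aucs]
        total = sum(self.aucs)
        self.weights_ = np.array([a / total for a in self.aucs])
        self.tag_ = "HSM_unique" if len(self.models) == 1 else "EM_wmean"
        self.variables_ = getattr(self.models[0], "variables_", None)

    def predict_suitability(self, X) -> np.ndarray:
        preds = np.column_stack([m.predict_suitability(X) for m in self.models])
        return preds @ self.weights_

    def predict(self, X) -> np.ndarray:
        return self.predict_suitability(X)


def ensemble_wmean(models: Sequence, aucs: Sequence[float]) -> WeightedEnsemble:
    return WeightedEnsemble(models, aucs)


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model, X: pd.DataFrame, n_perm: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Standardized permutation importance (Std_Imp).

    For each variable: permute its column, importance = mean over
    ``n_perm`` permutations of 1 - Pearson r(pred_original, pred_permuted),
    negatives clipped to 0; scores are standardized to percentages summing
    to 100 (all zero stays all zero). If the original prediction vector is
    constant (correlation undefined), the mean absolute prediction
    difference is used instead and a warning is emitted.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        # degenerate but legal: a single variable carries all importance
        pass
    if X.shape[0] < 10:
        raise ValueError("need at least 10 rows for permutation importance")
    rng = np.random.default_rng(seed)
    pred0 = model.predict_suitability(X)
    constant = np.std(pred0) == 0
    if constant:
        warnings.warn(
            "constant prediction vector; falling back to mean-absolute-difference importance",
            stacklevel=2,
        )
    raw = {}
    for col in X.columns:
        scores = []
        for _ in range(n_perm):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            pred1 = model.predict_suitability(Xp)
            if constant or np.std(pred1) == 0:
                scores.append(float(np.mean(np.abs(pred0 - pred1))))
            else:
                r = float(np.corrcoef(pred0, pred1)[0, 1])
                scores.append(1.0 - r)
        raw[str(col)] = max(0.0, float(np.mean(scores)))
    total = sum(raw.values())
    std = {v: (100.0 * s / total if total > 0 else 0.0) for v, s in raw.items()}
    return pd.DataFrame(
        {
            "variable": list(raw),
            "importance": list(raw.values()),
            "std_imp": [std[v] for v in raw],
            "n_permutations": n_perm,
        }
    )
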