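"""RBF-SVM quality classifier with subject-stratified bootstrap cross-validation.

Training uses only good- and poor-quality segments. Hyperparameters (soft
margin C, kernel width sigma) come from a grid search with inner five-fold
cross-validation; performance is estimated by repeatedly splitting *subjects*
into five folds and, per fold, drawing a class-balanced bootstrap sample of
segments (60 per class by default). Features are z-scored with statistics of
the training side only. Sensitivity is the recall of the good class,
specificity the recall of the poor class; on balanced draws the fold accuracy
equals their mean.

A trained model carries a Platt-style logistic calibration of the SVM decision
value into P(good), and a data-derived probability threshold used to call the
good class; intermediate-quality segments (mostly clean / mostly noisy) are
evaluated against that threshold without retraining.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import gaussian_kde
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from dusqa.config import PipelineConfig
from dusqa.features import FEATURE_ORDER

logger = logging.getLogger(__name__)

GOOD, POOR = "good", "poor"


def rbf_kernel(x_i: np.ndarray, x_j: np.ndarray, sigma: float) -> float:
    """Gaussian RBF kernel ``exp(-|x_i - x_j|^2 / (2 sigma^2))``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x_i = np.asarray(x_i, dtype=np.float64)
    x_j = np.asarray(x_j, dtype=np.float64)
    if x_i.shape != x_j.shape:
        raise ValueError("vectors must have equal length")
    return float(np.exp(-np.sum((x_i - x_j) ** 2) / (2.0 * sigma**2)))


def _sigma_to_gamma(sigma: float) -> float:
    return 1.0 / (2.0 * sigma**2)


def _make_svc(C: float, sigma: float, seed: int | None = None) -> SVC:
    return SVC(C=C, kernel="rbf", gamma=_sigma_to_gamma(sigma),
               random_state=seed)


@dataclass
class _Scaler:
    """Per-feature z-scoring with training-data statistics only."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale


@dataclass
class TrainedClassifier:
    """A fitted RBF-SVM with scaler, Platt calibration and probability threshold."""

    C: float
    sigma: float
    svc: SVC | None
    scaler: _Scaler
    platt_a: float
    platt_b: float
    prob_threshold: float = 0.5
    feature_names: tuple[str, ...] = FEATURE_ORDER
    df_sign: float = 1.0  # orients the raw SVC decision toward the good class
    # flattened SVM state (filled on save/load for portability)
    support_vectors: np.ndarray | None = None
    dual_coef: np.ndarray | None = None
    intercept: float = 0.0

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        """Margin values oriented so larger means more good-like."""
        Z = self.scaler.transform(np.atleast_2d(X))
        if self.svc is not None:
            return self.df_sign * self.svc.decision_function(Z)
        # reconstruct sum_i alpha_i y_i k(x_i, x) + b from stored coefficients
        gamma = _sigma_to_gamma(self.sigma)
        d2 = ((Z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-gamma * d2) @ self.dual_coef + self.intercept

    def predict_proba_good(self, X: np.ndarray) -> np.ndarray:
        df = self.decision_values(X)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * df + self.platt_b)))


@dataclass
class CVResult:
    """Bootstrap cross-validation outcome over repetitions (percent units)."""

    accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    chosen_params: list[list[tuple[float, float]]]
    audit: list[dict] = field(default_factory=list)

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.accuracies))

    @property
    def median_sensitivity(self) -> float:
        return float(np.median(self.sensitivities))

    @property
    def median_specificity(self) -> float:
        return float(np.median(self.specificities))

    @property
    def most_common_params(self) -> tuple[float, float]:
        flat = [p for rep in self.chosen_params for p in rep]
        return Counter(flat).most_common(1)[0][0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "repetition": np.arange(self.accuracies.size),
            "accuracy_pct": self.accuracies,
            "sensitivity_pct": self.sensitivities,
            "specificity_pct": self.specificities,
        })


def split_train_test(good_counts: Mapping[str, int],
                     total_counts: Mapping[str, int] | None = None
                     ) -> tuple[list[str], list[str]]:
    """Ranked alternating subject split.

    Subjects are ranked by good-segment count in descending order (ties broken
    lexicographically by id) and assigned alternately to train and test; with
    an odd subject count, the last subject joins the side holding fewer total
    segments so far.
    """
    if len(good_counts) < 2:
        raise ValueError("need at least 2 subjects")
    totals = dict(total_counts) if total_counts is not None else dict(good_counts)
    ranked = sorted(good_counts, key=lambda s: (-good_counts[s], s))
    train: list[str] = []
    test: list[str] = []
    for k, subj in enumerate(ranked):
        if k == len(ranked) - 1 and len(ranked) % 2 == 1:
            n_train = sum(totals.get(s, 0) for s in train)
            n_test = sum(totals.get(s, 0) for s in test)
            (train if n_train <= n_test else test).append(subj)
        elif k % 2 == 0:
            train.append(subj)
        else:
            test.append(subj)
    return train, test


def grid_search(X: np.ndarray, y: np.ndarray, c_grid: Sequence[float],
                sigma_grid: Sequence[float], n_folds: int = 5,
                seed: int = 0) -> tuple[float, float]:
    """(C, sigma) maximising inner stratified k-fold CV accuracy.

    Ties resolve to the smallest C, then the largest sigma (simpler, smoother
    models). Features are z-scored inside each inner fold from its own
    training part.
    """
    if not len(c_grid) or not len(sigma_grid):
        raise ValueError("grids must be non-empty")
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    n_folds = min(n_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    if n_folds < 2:
        return min(c_grid), max(sigma_grid)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best = None
    for C, sigma in itertools.product(sorted(c_grid), sorted(sigma_grid, reverse=True)):
        accs = []
        for tr, te in splits:
            scaler = _Scaler.fit(X[tr])
            clf = _make_svc(C, sigma)
            clf.fit(scaler.transform(X[tr]), y[tr])
            accs.append(np.mean(clf.predict(scaler.transform(X[te])) == y[te]))
        score = float(np.mean(accs))
        if best is None or score > best[0] + 1e-12:
            best = (score, (C, sigma))
    return best[1]


def _platt_fit(df: np.ndarray, y_good: np.ndarray) -> tuple[float, float]:
    """Platt scaling: logistic fit p = sigmoid(a*df + b) of P(good).

    Uses Platt's regularised soft targets ((n+ + 1)/(n+ + 2) and 1/(n- + 2))
    so the fit stays finite on separable training data.
    """
    from scipy.optimize import minimize

    df = np.asarray(df, dtype=np.float64)
    n_pos = int(np.sum(y_good))
    n_neg = int(y_good.size - n_pos)
    t = np.where(y_good, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(params):
        a, b = params
        z = a * df + b
        # log(1+exp(z)) computed stably
        return float(np.sum(np.logaddexp(0.0, z) - t * z))

    res = minimize(nll, x0=np.array([1.0, 0.0]), method="Nelder-Mead")
    return float(res.x[0]), float(res.x[1])


def _derive_threshold(p_good: np.ndarray, y_good: np.ndarray) -> float:
    """Probability cut maximising balanced accuracy on the training data.

    Candidate cuts are midpoints between adjacent distinct probabilities; ties
    resolve to the cut closest to 0.5.
    """
    order = np.unique(p_good)
    if order.size < 2:
        return 0.5
    cuts = np.concatenate([[order[0] - 1e-9],
                           (order[:-1] + order[1:]) / 2.0,
                           [order[-1] + 1e-9]])
    best = (-1.0, 0.5)
    for c in cuts:
        pred = p_good >= c
        sens = np.mean(pred[y_good]) if y_good.any() else 0.0
        spec = np.mean(~pred[~y_good]) if (~y_good).any() else 0.0
        bal = (sens + spec) / 2.0
        if bal > best[0] + 1e-12 or (abs(bal - best[0]) <= 1e-12
                                     and abs(c - 0.5) < abs(best[1] - 0.5)):
            best = (bal, float(c))
    return best[1]


def train_classifier(X: np.ndarray, y: Sequence[str],
                     cfg: PipelineConfig | None = None, seed: int = 0,
                     C: float | None = None, sigma: float | None = None,
                     feature_names: Sequence[str] = FEATURE_ORDER) -> TrainedClassifier:
    """Fit the RBF-SVM on good/poor segments with grid-searched (C, sigma).

    The scaler, Platt calibration and probability threshold are all derived
    from the training data only.
    """
    cfg = cfg or PipelineConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if not set(np.unique(y)) <= {GOOD, POOR}:
        raise ValueError("labels must be 'good'/'poor' only")
    if C is None or sigma is None:
        C, sigma = grid_search(X, y, cfg.c_grid, cfg.sigma_grid,
                               cfg.cv_folds, seed)
    scaler = _Scaler.fit(X)
    svc = _make_svc(C, sigma, seed)
    svc.fit(scaler.transform(X), y)
    # decision_function is positive toward classes_[1]; orient toward 'good'
    sign = 1.0 if svc.classes_[1] == GOOD else -1.0
    df = sign * svc.decision_function(scaler.transform(X))
    y_good = y == GOOD
    a, b = _platt_fit(df, y_good)
    model = TrainedClassifier(C=C, sigma=sigma, svc=svc, scaler=scaler,
                              platt_a=a, platt_b=b, df_sign=sign,
                              feature_names=tuple(feature_names))
    p = model.predict_proba_good(X)
    model.prob_threshold = _derive_threshold(p, y_good)
    return model


def predict_with_probability(model: TrainedClassifier,
                             fv: np.ndarray) -> tuple[str, float]:
    """Class call and P(good) for one feature vector."""
    if model.svc is None and model.support_vectors is None:
        raise RuntimeError("model is not fitted")
    p = float(model.predict_proba_good(np.atleast_2d(fv))[0])
    return (GOOD if p >= model.prob_threshold else POOR), p


def _fold_subjects(subjects: np.ndarray, n_folds: int,
                   rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(subjects)
    return [perm[i::n_folds] for i in range(n_folds)]


def bootstrap_cv(features: pd.DataFrame, feature_names: Sequence[str] = FEATURE_ORDER,
                 n_folds: int = 5, per_class: int = 60, n_reps: int = 100,
                 seed: int = 0, c_grid: Sequence[float] | None = None,
                 sigma_grid: Sequence[float] | None = None,
                 fixed_params: tuple[float, float] | None = None,
                 collect_audit: bool = False) -> CVResult:
    """Subject-stratified five-fold bootstrap cross-validation.

    Per repetition, subjects are partitioned into ``n_folds`` folds (resampled
    when a fold lacks a class). Each fold draws ``per_class`` segments per
    class with replacement from its own subjects' segments; the classifier is
    fitted on the union of the other folds' draws (z-scored with training
    statistics; (C, sigma) by inner grid search unless ``fixed_params``) and
    evaluated on the fold's draw. The repetition's accuracy / sensitivity /
    specificity are medians over folds; the result holds all repetitions.

    ``features`` needs columns ``subject_id``, ``label`` (good/poor only) and
    the feature columns. Same seed, same result.
    """
    cfg = PipelineConfig()
    c_grid = list(c_grid) if c_grid is not None else cfg.c_grid
    sigma_grid = list(sigma_grid) if sigma_grid is not None else cfg.sigma_grid
    df = features[features["label"].isin([GOOD, POOR])].reset_index(drop=True)
    if df.empty or df["label"].nunique() < 2:
        raise ValueError("need good and poor segments")
    X_all = df[list(feature_names)].to_numpy(dtype=np.float64)
    y_all = df["label"].to_numpy()
    subj_all = df["subject_id"].to_numpy()
    subjects = np.unique(subj_all)

    accs, senss, specs = [], [], []
    chosen: list[list[tuple[float, float]]] = []
    audit: list[dict] = []
    master = np.random.SeedSequence([seed, 0xD05])
    rep_seeds = master.spawn(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(rep_seeds[rep])
        folds = None
        for _ in range(100):
            cand = _fold_subjects(subjects, n_folds, rng)
            ok = all(
                {GOOD, POOR} <= set(y_all[np.isin(subj_all, f)]) for f in cand)
            if ok:
                folds = cand
                break
            logger.info("repetition %d: fold missing a class, resampling", rep)
        if folds is None:
            raise RuntimeError("could not build folds with both classes present")
        # per-fold bootstrap draws (rows into df)
        draws = []
        for f in folds:
            rows = []
            for cls in (GOOD, POOR):
                pool = np.where(np.isin(subj_all, f) & (y_all == cls))[0]
                rows.append(rng.choice(pool, size=per_class, replace=True))
            draws.append(np.concatenate(rows))
        fold_acc, fold_sens, fold_spec, fold_params = [], [], [], []
        for k in range(n_folds):
            test_rows = draws[k]
            train_rows = np.concatenate([draws[j] for j in range(n_folds) if j != k])
            X_tr, y_tr = X_all[train_rows], y_all[train_rows]
            X_te, y_te = X_all[test_rows], y_all[test_rows]
            if fixed_params is not None:
                C, sigma = fixed_params
            else:
                C, sigma = grid_search(X_tr, y_tr, c_grid, sigma_grid,
                                       n_folds=5, seed=int(rng.integers(2**31)))
            scaler = _Scaler.fit(X_tr)
            clf = _make_svc(C, sigma)
            clf.fit(scaler.transform(X_tr), y_tr)
            pred = clf.predict(scaler.transform(X_te))
            good_te = y_te == GOOD
            sens = float(np.mean(pred[good_te] == GOOD))
            spec = float(np.mean(pred[~good_te] == POOR))
            fold_acc.append(float(np.mean(pred == y_te)) * 100.0)
            fold_sens.append(sens * 100.0)
            fold_spec.append(spec * 100.0)
            fold_params.append((C, sigma))
            if collect_audit:
                audit.append({
                    "repetition": rep, "fold": k,
                    "train_rows": train_rows.copy(), "test_rows": test_rows.copy(),
                    "train_subjects": frozenset(subj_all[train_rows]),
                    "test_subjects": frozenset(subj_all[test_rows]),
                    "scaler_mean": scaler.mean.copy(),
                    "scaler_scale": scaler.scale.copy(),
                    "acc_pct": fold_acc[-1],
                    "sens_pct": fold_sens[-1],
                    "spec_pct": fold_spec[-1],
                })
        accs.append(float(np.median(fold_acc)))
        senss.append(float(np.median(fold_sens)))
        specs.append(float(np.median(fold_spec)))
        chosen.append(fold_params)
    return CVResult(np.array(accs), np.array(senss), np.array(specs),
                    chosen, audit)


def evaluate_intermediate(model: TrainedClassifier,
                          class_features: Mapping[str, np.ndarray]) -> dict:
    """Fractions of P(good) above the model threshold per quality class.

    Also returns a smoothed (Gaussian-kernel) density summary of the
    probability distribution of each class, on a fixed [0, 1] grid. Empty
    classes are reported as missing (None).
    """
    grid = np.linspace(0.0, 1.0, 101)
    out: dict = {"threshold": model.prob_threshold, "fraction_above": {},
                 "density": {"grid": grid}}
    for cls, X in class_features.items():
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.size == 0:
            out["fraction_above"][cls] = None
            out["density"][cls] = None
            continue
        p = model.predict_proba_good(X)
        out["fraction_above"][cls] = float(np.mean(p >= model.prob_threshold))
        if np.std(p) > 0 and p.size > 1:
            out["density"][cls] = gaussian_kde(p)(grid)
        else:
            out["density"][cls] = None
    return out


def feature_subset_search(features: pd.DataFrame,
                          feature_names: Sequence[str] = FEATURE_ORDER,
                          n_reps: int = 20, seed: int = 0,
                          **cv_kwargs) -> pd.DataFrame:
    """Exhaustive sweep over the 2^6 - 1 non-empty feature subsets.

    Each subset is scored with :func:`bootstrap_cv`; rows are sorted by median
    accuracy, ties by median specificity (preferring fewer false-good calls).
    """
    rows = []
    for k in range(1, len(feature_names) + 1):
        for subset in itertools.combinations(feature_names, k):
            res = bootstrap_cv(features, feature_names=subset,
                               n_reps=n_reps, seed=seed, **cv_kwargs)
            rows.append({
                "features": "+".join(subset), "n_features": k,
                "median_accuracy": res.median_accuracy,
                "median_sensitivity": res.median_sensitivity,
                "median_specificity": res.median_specificity,
            })
    out = pd.DataFrame(rows)
    return out.sort_values(["median_accuracy", "median_specificity"],
                           ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model serialization (documented JSON schema)
# ---------------------------------------------------------------------------

def save_model(model: TrainedClassifier, path: str | Path,
               extra: Mapping | None = None) -> None:
    """Serialize a trained model to portable JSON.

    Schema: C, sigma, feature order, scaler mean/scale, the SVM dual
    representation oriented toward the good class (support vectors,
    alpha_i * y_i coefficients, intercept), Platt coefficients and the
    probability threshold.
    """
    svc = model.svc
    sign = model.df_sign  # store the dual representation good-oriented
    blob = {
        "schema": "dusqa-svm-v1",
        "C": model.C,
        "sigma": model.sigma,
        "feature_names": list(model.feature_names),
        "scaler_mean": model.scaler.mean.tolist(),
        "scaler_scale": model.scaler.scale.tolist(),
        "support_vectors": svc.support_vectors_.tolist(),
        "dual_coef": (sign * svc.dual_coef_[0]).tolist(),
        "intercept": float(sign * svc.intercept_[0]),
        "platt_a": model.platt_a,
        "platt_b": model.platt_b,
        "prob_threshold": model.prob_threshold,
    }
    if extra:
        blob["extra"] = dict(extra)
    Path(path).write_text(json.dumps(blob, indent=1))


def load_model(path: str | Path) -> TrainedClassifier:
    blob = json.loads(Path(path).read_text())
    if blob.get("schema") != "dusqa-svm-v1":
        raise ValueError("unrecognised model file")
    scaler = _Scaler(np.array(blob["scaler_mean"]), np.array(blob["scaler_scale"]))
    model = TrainedClassifier(
        C=blob["C"], sigma=blob["sigma"], svc=None, scaler=scaler,
        platt_a=blob["platt_a"], platt_b=blob["platt_b"],
        prob_threshold=blob["prob_threshold"],
        feature_names=tuple(blob["feature_names"]),
        support_vectors=np.array(blob["support_vectors"]),
        dual_coef=np.array(blob["dual_coef"]),
        intercept=blob["intercept"],
    )
    return model
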