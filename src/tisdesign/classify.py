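"""Reactive-vs-nonreactive classifiers on prereaction geometry.

Two model families predict whether a turnover attempt will succeed from
structural features in a sliding prereaction time window:

* LR: logistic regression; feature subsets of 5/10/20 are chosen by tuning an
  L1 (LASSO) regularization path until exactly k features survive (ties
  broken by coefficient magnitude, then schema order), then refit without
  regularization on the subset.
* NN: a single-hidden-layer perceptron (70 ReLU units, learning rate 0.001,
  L2 penalty alpha = 1e-4, batch size 200); subsets chosen by greedy forward
  selection on cross-validated AUROC.

Cross-validation is 5-fold with folds split by *unique path* (all frames of
a path share a fold) so that path multiplicity weighting cannot leak between
train and test.  Samples are weighted by TIS path counts; the NN trainer
realizes weights by row duplication (multiplicities are integers), which is
exactly equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score
from sklearn.model_selection import StratifiedGroupKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .geometry import FeatureDef, FeatureSchema, compute_feature_matrix
from .paths import PathEnsemble, WeightedFrames, sample_window_frames
from .systems import ModelSystem

__all__ = [
    "LabeledDataset",
    "TrainedModel",
    "default_schema_for",
    "build_dataset",
    "train_lr",
    "train_nn",
    "scan_windows",
    "reactive_fraction",
    "normalize_by_reference",
    "DEFAULT_WINDOW_WIDTH",
    "DEFAULT_WINDOW_STEP",
]

DEFAULT_WINDOW_WIDTH = 30.0  # fs
DEFAULT_WINDOW_STEP = 5.0    # fs
NN_HIDDEN = 70
NN_LEARNING_RATE = 0.001
NN_ALPHA = 1e-4              # L2 penalty weight
NN_BATCH = 200


class TrainingError(RuntimeError):
    pass


def default_schema_for(system: ModelSystem) -> FeatureSchema:
    """Distance/angle schema for a bundled surrogate system.

    For the migration mimic: the three core distances, the gate-to-M
    distance, one distance per distractor particle, and two angles.  The
    planted signal lives in ``d_gate_M``.
    """
    labels = system.metadata.get("particle_labels")
    if labels is None or labels[:3] != ["D", "M", "A"]:
        raise ValueError("no default schema for this system")
    feats = [
        FeatureDef("d_D_M", "distance", (0, 1)),
        FeatureDef("d_M_A", "distance", (1, 2)),
        FeatureDef("d_D_A", "distance", (0, 2)),
        FeatureDef("d_gate_M", "distance", (3, 1)),
    ]
    for i, lab in enumerate(labels[4:], start=4):
        feats.append(FeatureDef(f"d_{lab}_M", "distance", (i, 1)))
    feats.append(FeatureDef("a_D_M_A", "angle", (0, 1, 2)))
    feats.append(FeatureDef("a_gate_M_D", "angle", (3, 1, 0)))
    return FeatureSchema(feats)


@dataclass
class LabeledDataset:
    """Feature matrix with labels (1 = reactive), path weights and groups."""

    X: pd.DataFrame
    y: np.ndarray
    weights: np.ndarray
    groups: np.ndarray
    window: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.X)
        if not (len(self.y) == len(self.weights) == len(self.groups) == n):
            raise ValueError("rows, labels, weights, groups must align")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if self.X.isna().any().any():
            raise ValueError("missing feature values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def build_dataset(r_ensembles: list[PathEnsemble],
                  nr_ensembles: list[PathEnsemble],
                  schema: FeatureSchema,
                  window: tuple[float, float],
                  rng: np.random.Generator | None = None,
                  frames_per_path: int = 1) -> LabeledDataset:
    """One frame per unique path per window, weighted by path multiplicity.

    Ensembles must be time-aligned beforehand (see
    :func:`tisdesign.paths.align_time_zero`).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    wf_r = sample_window_frames(r_ensembles, window, frames_per_path, rng, "R")
    wf_nr = sample_window_frames(nr_ensembles, window, frames_per_path, rng, "NR")
    if len(wf_r) == 0 or len(wf_nr) == 0:
        raise TrainingError(f"window {window} has no frames for one class")
    Xr = compute_feature_matrix(wf_r.positions, schema)
    Xn = compute_feature_matrix(wf_nr.positions, schema)
    X = pd.DataFrame(np.vstack([Xr, Xn]), columns=schema.names)
    y = np.concatenate([np.ones(len(wf_r), dtype=int),
                        np.zeros(len(wf_nr), dtype=int)])
    w = np.concatenate([wf_r.weights, wf_nr.weights])
    groups = np.concatenate([wf_r.path_ids, -wf_nr.path_ids - 1])
    return LabeledDataset(X=X, y=y, weights=w, groups=groups, window=window)


@dataclass
class TrainedModel:
    kind: str                     # "LR" | "NN"
    features: list[str]
    pipeline: Pipeline
    window: tuple[float, float]
    cv_auroc: np.ndarray
    cv_accuracy: np.ndarray
    seed: int = 0

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(self.cv_auroc))

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.cv_accuracy))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """P(reactive) for rows of a feature DataFrame."""
        return self.pipeline.predict_proba(X[self.features].values)[:, 1]

    def predict_proba_frames(self, positions: np.ndarray,
                             schema: FeatureSchema) -> np.ndarray:
        X = pd.DataFrame(compute_feature_matrix(positions, schema),
                         columns=schema.names)
        return self.predict_proba(X)


def _check_two_classes(y):
    if len(np.unique(y)) < 2:
        raise TrainingError("both classes must be present")


def _expand_rows(X, y, w):
    """Integer-weight row duplication (exact weighting for estimators
    without sample_weight support)."""
    reps = np.asarray(np.round(w), dtype=int)
    if np.any(np.abs(reps - w) > 1e-9):
        raise TrainingError("row expansion requires integer weights")
    idx = np.repeat(np.arange(len(y)), reps)
    return X[idx], y[idx]


def _make_estimator(kind: str, seed: int):
    if kind == "LR":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(penalty=None, max_iter=2000)),
        ])
    return Pipeline([
        ("scale", StandardScaler()),
        ("clf", MLPClassifier(hidden_layer_sizes=(NN_HIDDEN,),
                              activation="relu", solver="adam",
                              learning_rate_init=NN_LEARNING_RATE,
                              alpha=NN_ALPHA, batch_size=NN_BATCH,
                              max_iter=400, random_state=seed)),
    ])


def _fit(pipe: Pipeline, X, y, w):
    if pipe.steps[-1][0] == "clf" and isinstance(pipe.steps[-1][1], MLPClassifier):
        Xe, ye = _expand_rows(X, y, w)
        pipe.fit(Xe, ye)
    else:
        # weight-aware scaling keeps the weighted fit identical to the
        # duplicated-row formulation
        pipe.fit(X, y, scale__sample_weight=w, clf__sample_weight=w)
    return pipe


def _cv_metrics(kind, X, y, w, groups, seed, n_folds=5):
    """Per-fold AUROC/accuracy; folds partition unique paths."""
    n_folds = min(n_folds, len(np.unique(groups)))
    cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aurocs, accs = [], []
    for tr, te in cv.split(X, y, groups):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
            continue
        pipe = _make_estimator(kind, seed)
        _fit(pipe, X[tr], y[tr], w[tr])
        p = pipe.predict_proba(X[te])[:, 1]
        aurocs.append(roc_auc_score(y[te], p, sample_weight=w[te]))
        accs.append(accuracy_score(y[te], p >= 0.5, sample_weight=w[te]))
    if not aurocs:
        raise TrainingError("no usable CV fold had both classes")
    return np.array(aurocs), np.array(accs)


# ---------------------------------------------------------------------------
# feature selection
# ---------------------------------------------------------------------------

def _lasso_select(X, y, w, names, k: int, seed: int) -> list[str]:
    """Exactly-k feature selection along an L1 logistic path.

    Bisects the regularization strength until k coefficients survive; when a
    sparsity plateau skips k, takes the top k by |coefficient| at the
    smallest strength with >= k survivors (ties: schema order, via stable
    sort)."""
    Xs = StandardScaler().fit(X, sample_weight=w).transform(X)

    def nnz_and_coefs(C):
        clf = LogisticRegression(penalty="l1", C=C, solver="liblinear",
                                 max_iter=2000, random_state=seed)
        clf.fit(Xs, y, sample_weight=w)
        coef = clf.coef_[0]
        return int(np.sum(coef != 0)), coef

    lo, hi = 1e-4, 1e4
    n_hi, coef_hi = nnz_and_coefs(hi)
    if n_hi < k:
        raise TrainingError(f"cannot select {k} features: only {n_hi} informative")
    best = (n_hi, coef_hi)
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        n_mid, coef_mid = nnz_and_coefs(mid)
        if n_mid >= k:
            best = (n_mid, coef_mid)
            hi = mid
            if n_mid == k:
                break
        else:
            lo = mid
    _, coef = best
    order = np.argsort(-np.abs(coef), kind="stable")
    return [names[i] for i in sorted(order[:k])]


def _greedy_select(X, y, w, groups, names, k: int, seed: int) -> list[str]:
    """Greedy forward selection by mean CV AUROC (ties: schema order)."""
    selected: list[int] = []
    remaining = list(range(len(names)))
    for _ in range(k):
        best_j, best_score = None, -np.inf
        for j in remaining:
            cols = selected + [j]
            au, _ = _cv_metrics("NN", X[:, cols], y, w, groups, seed)
            score = au.mean()
            if score > best_score + 1e-12:
                best_score, best_j = score, j
        selected.append(best_j)
        remaining.remove(best_j)
    return [names[i] for i in sorted(selected)]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _resolve_k(n_features, total):
    if n_features in (None, "all"):
        return total
    k = int(n_features)
    if not 1 <= k <= total:
        raise ValueError(f"n_features must be in [1, {total}]")
    return k


def train_lr(dataset: LabeledDataset, n_features="all", seed: int = 0) -> TrainedModel:
    """LASSO-select (when n_features < all), refit unregularized, 5-fold CV."""
    _check_two_classes(dataset.y)
    names = dataset.feature_names
    X = dataset.X.values
    k = _resolve_k(n_features, len(names))
    if k < len(names):
        feats = _lasso_select(X, dataset.y, dataset.weights, names, k, seed)
    else:
        feats = list(names)
    cols = [names.index(f) for f in feats]
    Xk = X[:, cols]
    au, acc = _cv_metrics("LR", Xk, dataset.y, dataset.weights,
                          dataset.groups, seed)
    pipe = _fit(_make_estimator("LR", seed), Xk, dataset.y, dataset.weights)
    return TrainedModel(kind="LR", features=feats, pipeline=pipe,
                        window=dataset.window, cv_auroc=au, cv_accuracy=acc,
                        seed=seed)


def train_nn(dataset: LabeledDataset, n_features="all", seed: int = 0) -> TrainedModel:
    """Greedy-select (when n_features < all), train the fixed NN, 5-fold CV."""
    _check_two_classes(dataset.y)
    names = dataset.feature_names
    X = dataset.X.values
    k = _resolve_k(n_features, len(names))
    if k < len(names):
        feats = _greedy_select(X, dataset.y, dataset.weights, dataset.groups,
                               names, k, seed)
    else:
        feats = list(names)
    cols = [names.index(f) for f in feats]
    Xk = X[:, cols]
    au, acc = _cv_metrics("NN", Xk, dataset.y, dataset.weights,
                          dataset.groups, seed)
    pipe = _fit(_make_estimator("NN", seed), Xk, dataset.y, dataset.weights)
    return TrainedModel(kind="NN", features=feats, pipeline=pipe,
                        window=dataset.window, cv_auroc=au, cv_accuracy=acc,
                        seed=seed)


_TRAINERS = {"LR": train_lr, "NN": train_nn}


def scan_windows(r_ensembles, nr_ensembles, schema,
                 t_range: tuple[float, float] = (-200.0, 0.0),
                 width: float = DEFAULT_WINDOW_WIDTH,
                 step: float = DEFAULT_WINDOW_STEP,
                 kinds=("LR", "NN"), feature_counts=("all",),
                 seed: int = 0,
                 rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Train one model per (window placement, kind, feature count).

    Window placements slide the ``width``-fs window in ``step``-fs increments
    across ``t_range``; windows with no frames for a class are recorded with
    NaN metrics.  Returns a tidy table (t_lo, t_hi, kind, n_features, auroc,
    accuracy, auroc_sd, n_rows).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    t0, t1 = t_range
    n_windows = int(np.floor((t1 - t0 - width) / step + 1e-9)) + 1
    rows = []
    for iw in range(n_windows):
        lo = t0 + iw * step
        window = (lo, lo + width)
        try:
            ds = build_dataset(r_ensembles, nr_ensembles, schema, window, rng)
        except TrainingError:
            ds = None
        for kind in kinds:
            for k in feature_counts:
                rec = {"t_lo": window[0], "t_hi": window[1], "kind": kind,
                       "n_features": k}
                if ds is None:
                    rec.update(auroc=np.nan, accuracy=np.nan,
                               auroc_sd=np.nan, n_rows=0)
                else:
                    model = _TRAINERS[kind](ds, n_features=k, seed=seed)
                    rec.update(auroc=model.mean_auroc,
                               accuracy=model.mean_accuracy,
                               auroc_sd=float(np.std(model.cv_auroc)),
                               n_rows=len(ds.y))
                rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# population tracking
# ---------------------------------------------------------------------------

def reactive_fraction(model: TrainedModel, frames: WeightedFrames,
                      schema: FeatureSchema, threshold: float = 0.5) -> float:
    """Weighted fraction of frames on the reactive side of the classifier."""
    if len(frames) == 0 or frames.weights.sum() == 0:
        raise ValueError("no weighted frames to classify")
    p = model.predict_proba_frames(frames.positions, schema)
    hits = p >= threshold
    return float(frames.weights[hits].sum() / frames.weights.sum())


def normalize_by_reference(fraction: float, ref_fraction: float) -> float:
    if ref_fraction <= 0:
        raise ValueError("reference fraction must be positive")
    return fraction / ref_fraction
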