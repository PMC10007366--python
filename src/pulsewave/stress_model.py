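"""Binary stress classification on ultra-short-term PRV features.

The classifier operates on the frozen 6-feature PRV vector and treats stress
detection as a binary problem (0 = no stress, 1 = stress).  Training follows
the standard imbalanced-classification recipe:

* minority oversampling (SMOTE) to counter the natural imbalance of stress
  windows, applied strictly inside training folds;
* one of three pipeline shapes — classifier alone, scaler + classifier, or
  scaler + PCA + classifier — with scaler/classifier families drawn from a
  fixed registry;
* stratified shuffle-split cross-validation with accuracy and F1, a
  most-frequent-label dummy baseline as the reference point, and exhaustive
  grid search over user-specified hyperparameters;
* subject-level holdout for the final evaluation (held-out subjects never
  contribute training rows).

The shipped default is a standard scaler + linear-kernel SVM, chosen for its
trivially flattenable inference: the fitted model reduces to four arrays
(w, c, u, p) so that a label costs 2d multiplications, 2d-1 additions and one
comparison — the same arithmetic an MCU port performs.  ``embedded_infer``
reproduces that path, optionally in single precision, and is required to
agree with the full scikit-learn pipeline away from the decision margin.

SMOTE is implemented here directly (minority-neighbor convex interpolation
with k nearest neighbors) with an explicit seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import (
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, RobustScaler, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LabeledDataset",
    "PipelineSpec",
    "LinearSVMParams",
    "EvalReport",
    "FittedModel",
    "SCALERS",
    "CLASSIFIERS",
    "DEFAULT_GRID",
    "smote",
    "oversample_minority",
    "dummy_baseline",
    "build_pipeline",
    "train_pipeline",
    "cross_validate",
    "grid_search",
    "evaluate",
    "export_linear_svm",
    "embedded_infer",
    "save_params",
    "load_params",
]

N_FEATURES = 6

SCALERS = ("none", "standard", "minmax", "robust")
CLASSIFIERS = (
    "lda",
    "knn",
    "svm",
    "linear_svm",
    "decision_tree",
    "naive_bayes",
    "bagging",
    "random_forest",
    "extra_trees",
    "gradient_boosting",
)

# Default hyperparameter grid for grid_search; users supply their own grids.
DEFAULT_GRID: dict[str, Sequence[Any]] = {
    "classifier_params.C": (0.1, 1.0, 10.0, 100.0),
}


@dataclass(frozen=True)
class LabeledDataset:
    """PRV feature rows with binary labels and a subject grouping key."""

    features: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        s = np.asarray(self.subject_ids)
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "subject_ids", s)
        if X.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if not (X.shape[0] == y.shape[0] == s.shape[0]):
            raise ValueError("features, labels and subject_ids must align")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary (0/1)")

    def __len__(self) -> int:
        return self.features.shape[0]

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[mask], self.labels[mask], self.subject_ids[mask]
        )


@dataclass(frozen=True)
class PipelineSpec:
    """One of the three experiment shapes: classifier alone, scaler +
    classifier, or scaler + PCA + classifier."""

    scaler: str = "standard"
    use_pca: bool = False
    n_components: int | None = None
    classifier: str = "linear_svm"
    classifier_params: tuple[tuple[str, Any], ...] = ()

    def __post_init__(self) -> None:
        if self.scaler not in SCALERS:
            raise ValueError(f"unknown scaler {self.scaler!r}; valid: {SCALERS}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(
                f"unknown classifier {self.classifier!r}; valid: {CLASSIFIERS}"
            )
        if self.use_pca and self.scaler == "none":
            raise ValueError(
                "PCA is only used in the scaler+PCA+classifier shape"
            )

    def params_dict(self) -> dict[str, Any]:
        return dict(self.classifier_params)

    def sort_key(self) -> tuple:
        return (
            self.scaler,
            self.use_pca,
            -1 if self.n_components is None else self.n_components,
            self.classifier,
            tuple(sorted((k, repr(v)) for k, v in self.classifier_params)),
        )


@dataclass(frozen=True)
class LinearSVMParams:
    """Flattened standard-scaler + linear-SVM model.

    ``w``: hyperplane coefficients; ``c``: the negative of the intercept;
    ``u``: per-feature training means; ``p``: inverse training standard
    deviations.  Inference: label 1 iff w . (p * (x - u)) > c.
    """

    w: np.ndarray
    c: float
    u: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        u = np.asarray(self.u, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "p", p)
        if not (w.shape == u.shape == p.shape) or w.ndim != 1:
            raise ValueError("w, u, p must be 1-D arrays of equal length")
        if np.any(p <= 0):
            raise ValueError("all inverse standard deviations must be positive")
        if not (
            np.all(np.isfinite(w))
            and np.all(np.isfinite(u))
            and np.all(np.isfinite(p))
            and np.isfinite(self.c)
        ):
            raise ValueError("parameters must be finite")

    @property
    def d(self) -> int:
        return self.w.size


@dataclass(frozen=True)
class EvalReport:
    accuracy: float
    f1: float
    tn: int
    fp: int
    fn: int
    tp: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
        }


@dataclass
class FittedModel:
    """A fitted pipeline plus the provenance needed for honest evaluation."""

    pipeline: Pipeline
    spec: PipelineSpec
    train_subjects: frozenset

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.pipeline.predict(np.asarray(X, dtype=float))


# ---------------------------------------------------------------------------
# Oversampling


def smote(
    X: np.ndarray,
    y: np.ndarray,
    seed: int,
    k_neighbors: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Minority Oversampling: balance classes by interpolating
    each synthetic point between a minority sample and one of its k nearest
    minority neighbors (uniform gap in [0, 1)).  Original rows are preserved;
    the result is deterministic for a given seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE requires exactly two classes present")
    minority = classes[np.argmin(counts)]
    n_needed = int(np.max(counts) - np.min(counts))
    if n_needed == 0:
        return X.copy(), y.copy()
    X_min = X[y == minority]
    if X_min.shape[0] < k_neighbors + 1:
        raise ValueError(
            f"minority class has {X_min.shape[0]} rows; SMOTE with "
            f"k={k_neighbors} needs at least {k_neighbors + 1}"
        )
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, neigh = nn.kneighbors(X_min)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, X_min.shape[0], size=n_needed)
    pick = rng.integers(1, k_neighbors + 1, size=n_needed)
    gap = rng.uniform(0.0, 1.0, size=n_needed)
    partner = neigh[base, pick]
    X_new = X_min[base] + gap[:, None] * (X_min[partner] - X_min[base])
    X_out = np.vstack([X, X_new])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=int)])
    return X_out, y_out


def oversample_minority(data: LabeledDataset, seed: int,
                        k_neighbors: int = 5) -> LabeledDataset:
    """SMOTE on a labeled dataset; synthetic rows inherit the subject id of
    their base minority sample (they remain within-subject interpolations
    only in feature space, so the id is a bookkeeping convention)."""
    X, y = data.features, data.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    n_before = len(data)
    X_out, y_out = smote(X, y, seed, k_neighbors)
    n_new = X_out.shape[0] - n_before
    rng = np.random.default_rng(seed)
    base = rng.integers(0, int(np.sum(y == minority)), size=n_new)
    min_subjects = data.subject_ids[y == minority]
    subj_out = np.concatenate([data.subject_ids, min_subjects[base]])
    return LabeledDataset(X_out, y_out, subj_out)


def dummy_baseline(labels_train: np.ndarray, labels_test: np.ndarray) -> float:
    """Accuracy of always predicting the training-majority label.

    Ties in the training counts resolve to the lower label (0).
    """
    yt = np.asarray(labels_train, dtype=int)
    ys = np.asarray(labels_test, dtype=int)
    if yt.size == 0 or ys.size == 0:
        raise ValueError("labels must be non-empty")
    n1 = int(np.sum(yt == 1))
    majority = 1 if n1 > yt.size - n1 else 0
    return float(np.mean(ys == majority))


# ---------------------------------------------------------------------------
# Pipeline construction and training


def _make_scaler(name: str):
    return {
        "standard": StandardScaler,
        "minmax": MinMaxScaler,
        "robust": RobustScaler,
    }[name]()


def _make_classifier(name: str, params: Mapping[str, Any], seed: int):
    p = dict(params)
    if name == "lda":
        return LinearDiscriminantAnalysis(**p)
    if name == "knn":
        return KNeighborsClassifier(**p)
    if name == "svm":
        return SVC(random_state=seed, **p)
    if name == "linear_svm":
        return SVC(kernel="linear", random_state=seed, **p)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **p)
    if name == "naive_bayes":
        return GaussianNB(**p)
    if name == "bagging":
        return BaggingClassifier(random_state=seed, **p)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed, **p)
    if name == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **p)
    if name == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **p)
    raise ValueError(f"unknown classifier {name!r}; valid: {CLASSIFIERS}")


def build_pipeline(spec: PipelineSpec, seed: int = 0) -> Pipeline:
    """Assemble the scikit-learn pipeline for one experiment shape.

    Scalers are fitted on training data only (the Pipeline contract);
    standard = (x-mean)/std, minmax = (x-min)/(max-min),
    robust = (x-median)/IQR.
    """
    steps = []
    if spec.scaler != "none":
        steps.append(("scaler", _make_scaler(spec.scaler)))
    if spec.use_pca:
        steps.append(("pca", PCA(n_components=spec.n_components,
                                 random_state=seed)))
    steps.append(
        ("classifier", _make_classifier(spec.classifier, spec.params_dict(), seed))
    )
    return Pipeline(steps)


def train_pipeline(
    data: LabeledDataset,
    spec: PipelineSpec = PipelineSpec(),
    seed: int = 0,
    oversample: bool = True,
) -> FittedModel:
    """Fit a pipeline on the full training dataset (optionally SMOTE-balanced)
    and record the training subjects for the holdout guard."""
    if oversample and len(set(np.unique(data.labels))) == 2:
        counts = np.bincount(data.labels, minlength=2)
        if counts[0] != counts[1]:
            data = oversample_minority(data, seed)
    pipe = build_pipeline(spec, seed)
    pipe.fit(data.features, data.labels)
    return FittedModel(pipe, spec, frozenset(np.unique(data.subject_ids).tolist()))


def cross_validate(
    data: LabeledDataset,
    spec: PipelineSpec,
    n_splits: int = 5,
    test_fraction: float = 0.25,
    seed: int = 0,
    oversample: bool = True,
) -> pd.DataFrame:
    """Stratified shuffle-split cross-validation.

    Folds preserve the class proportions; SMOTE (when enabled) and all
    fitting happen strictly inside each training fold, so no test row ever
    influences fitted statistics.  Returns one row per fold with accuracy
    and F1.
    """
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    rows = []
    for fold, (tr, te) in enumerate(
        splitter.split(data.features, data.labels)
    ):
        X_tr, y_tr = data.features[tr], data.labels[tr]
        if oversample and np.unique(y_tr).size == 2:
            counts = np.bincount(y_tr, minlength=2)
            if counts[0] != counts[1]:
                X_tr, y_tr = smote(X_tr, y_tr, seed=seed + fold)
        if np.unique(y_tr).size < 2 or np.unique(data.labels[te]).size < 1:
            raise ValueError(f"degenerate fold {fold}: a class is missing")
        pipe = build_pipeline(spec, seed)
        pipe.fit(X_tr, y_tr)
        pred = pipe.predict(data.features[te])
        rows.append(
            {
                "fold": fold,
                "accuracy": accuracy_score(data.labels[te], pred),
                "f1": f1_score(data.labels[te], pred, zero_division=0),
            }
        )
    return pd.DataFrame(rows)


def _expand_grid(grid: Mapping[str, Sequence[Any]]):
    keys = sorted(grid.keys())
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def _apply_grid_point(base: PipelineSpec, point: Mapping[str, Any]) -> PipelineSpec:
    spec = base
    params = dict(base.classifier_params)
    for key, value in point.items():
        if key.startswith("classifier_params."):
            params[key.split(".", 1)[1]] = value
        elif key in ("scaler", "use_pca", "n_components", "classifier"):
            spec = replace(spec, **{key: value})
        else:
            raise ValueError(f"unknown grid field {key!r}")
    return replace(spec, classifier_params=tuple(sorted(params.items())))


def grid_search(
    data: LabeledDataset,
    grid: Mapping[str, Sequence[Any]],
    base_spec: PipelineSpec = PipelineSpec(),
    n_splits: int = 5,
    test_fraction: float = 0.25,
    seed: int = 0,
) -> tuple[PipelineSpec, pd.DataFrame]:
    """Exhaustive search over a user-specified grid.

    Every combination is scored by cross_validate; the winner is the argmax
    of mean accuracy, ties broken by mean F1, then by lexicographic spec
    order (reproducible selection).  Returns (best spec, full score table).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    results = []
    for point in _expand_grid(grid):
        spec = _apply_grid_point(base_spec, point)
        scores = cross_validate(
            data, spec, n_splits=n_splits, test_fraction=test_fraction, seed=seed
        )
        results.append(
            {
                "spec": spec,
                **{f"param:{k}": v for k, v in point.items()},
                "mean_accuracy": float(scores["accuracy"].mean()),
                "mean_f1": float(scores["f1"].mean()),
            }
        )
    table = pd.DataFrame(results)
    order = sorted(
        range(len(results)),
        key=lambda i: (
            -results[i]["mean_accuracy"],
            -results[i]["mean_f1"],
            results[i]["spec"].sort_key(),
        ),
    )
    return results[order[0]]["spec"], table


def evaluate(model: FittedModel, held_out: LabeledDataset) -> EvalReport:
    """Accuracy, F1 and confusion counts on a subject-disjoint holdout."""
    overlap = model.train_subjects & set(np.unique(held_out.subject_ids).tolist())
    if overlap:
        raise ValueError(
            f"held-out subjects overlap training subjects: {sorted(overlap)}"
        )
    pred = model.predict(held_out.features)
    tn, fp, fn, tp = confusion_matrix(
        held_out.labels, pred, labels=[0, 1]
    ).ravel()
    return EvalReport(
        accuracy=float(accuracy_score(held_out.labels, pred)),
        f1=float(f1_score(held_out.labels, pred, zero_division=0)),
        tn=int(tn),
        fp=int(fp),
        fn=int(fn),
        tp=int(tp),
    )


# ---------------------------------------------------------------------------
# Flattened linear-SVM export and embedded-style inference


def export_linear_svm(model: FittedModel | Pipeline) -> LinearSVMParams:
    """Flatten a fitted standard-scaler + linear-SVM pipeline into the four
    arrays an embedded target stores: w (hyperplane), c (negative intercept),
    u (feature means), p (inverse standard deviations)."""
    pipe = model.pipeline if isinstance(model, FittedModel) else model
    names = [name for name, _ in pipe.steps]
    if names != ["scaler", "classifier"]:
        raise ValueError(
            "export requires exactly a scaler + classifier pipeline, got "
            f"steps {names}"
        )
    scaler = pipe.named_steps["scaler"]
    clf = pipe.named_steps["classifier"]
    if not isinstance(scaler, StandardScaler):
        raise ValueError("export requires a standard scaler")
    if not (isinstance(clf, SVC) and clf.kernel == "linear"):
        raise ValueError("export requires a linear-kernel SVM classifier")
    w = np.asarray(clf.coef_, dtype=float).ravel()
    c = -float(np.asarray(clf.intercept_).ravel()[0])
    u = np.asarray(scaler.mean_, dtype=float)
    p = 1.0 / np.asarray(scaler.scale_, dtype=float)
    return LinearSVMParams(w=w, c=c, u=u, p=p)


def embedded_infer(
    params: LinearSVMParams,
    x: np.ndarray,
    precision: str = "double",
) -> int:
    """Flat-array inference: x_bar[i] = p[i] * (x[i] - u[i]) then
    label = 1 if w . x_bar > c else 0.

    Exactly 2d multiplications, 2d-1 additions/subtractions, one comparison.
    ``precision='single'`` runs the whole computation in 32-bit floats, the
    arithmetic of a constrained microcontroller target.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (params.d,):
        raise ValueError(f"expected a length-{params.d} vector, got shape {x.shape}")
    if precision not in ("single", "double"):
        raise ValueError("precision must be 'single' or 'double'")
    dt = np.float32 if precision == "single" else np.float64
    w = params.w.astype(dt)
    u = params.u.astype(dt)
    p = params.p.astype(dt)
    c = dt(params.c)
    xv = x.astype(dt)
    score = dt(0.0)
    for i in range(params.d):  # d mults + d subs
        xbar = p[i] * (xv[i] - u[i])
        score = dt(score + w[i] * xbar)  # d mults + d-1 adds (first add is to 0)
    return 1 if score > c else 0


def save_params(params: LinearSVMParams, path, metadata: dict | None = None) -> None:
    """Persist the flattened model as JSON (the software twin of the MCU's
    flat-array export)."""
    payload = {
        "d": params.d,
        "w": params.w.tolist(),
        "c": params.c,
        "u": params.u.tolist(),
        "p": params.p.tolist(),
        "metadata": metadata or {},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_params(path) -> LinearSVMParams:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    params = LinearSVMParams(
        w=np.asarray(d["w"], dtype=float),
        c=float(d["c"]),
        u=np.asarray(d["u"], dtype=float),
        p=np.asarray(d["p"], dtype=float),
    )
    if params.d != d["d"]:
        raise ValueError("model file is inconsistent: d does not match arrays")
    return params
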