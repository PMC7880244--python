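"""Pixel-wise tissue classification of preprocessed Raman cubes.

The modeling pipeline is: L1-penalized linear SVM as a sparse feature
selector (channels with non-zero weight are kept), per-channel
standardization with training-set statistics, then a grid-searched
classifier (linear SVM, RBF SVM, or random forest) chosen by validation
accuracy.  Class confidences are Platt-scaled probabilities (a sigmoid over
the SVM decision value, fitted on out-of-fold decision values from a 5-fold
cross-validation of the training set); for random forests the confidence is
the fraction of trees voting for the predicted class.  Only spectral
features are used — no spatial context.

Convention: *adipose* is the positive class for sensitivity/specificity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC

from .errors import AssemblyError, ConfigurationError, ParameterError, SelectionError
from .preprocess import ProcessedCube

__all__ = [
    "LabeledDataset",
    "ClassifierConfig",
    "ClassifierBundle",
    "MarginMap",
    "MetricsReport",
    "assemble_datasets",
    "select_features_l1",
    "grid_search_train",
    "predict_with_probability",
    "compute_metrics",
    "pearson_diagnostics",
    "render_margin_map",
]

POSITIVE_CLASS = "adipose"


@dataclass
class LabeledDataset:
    """SNV spectra with labels and per-spectrum provenance."""

    features: np.ndarray  # (n_spectra, n_channels)
    labels: np.ndarray  # (n_spectra,) class-name strings
    provenance: np.ndarray  # (n_spectra, 3) object rows (image_id, x, y)
    role: str  # "train" or "validation"

    def __post_init__(self) -> None:
        if not (len(self.features) == len(self.labels) == len(self.provenance)):
            raise AssemblyError("features, labels and provenance lengths differ")
        if self.role not in ("train", "validation"):
            raise AssemblyError(f"unknown dataset role {self.role!r}")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class ClassifierConfig:
    """Hyperparameter grids and seeds for model development."""

    svm_C_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)
    svm_gamma_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0)
    svm_kernels: tuple[str, ...] = ("linear", "rbf")
    rf_n_estimators_grid: tuple[int, ...] = (100, 200, 300)
    rf_max_samples_grid: tuple[float, ...] = (0.6, 0.7, 0.8)
    l1_C: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for grid in (
            self.svm_C_grid,
            self.svm_gamma_grid,
            self.rf_n_estimators_grid,
            self.rf_max_samples_grid,
        ):
            if len(grid) == 0:
                raise ConfigurationError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.svm_C_grid) or any(g <= 0 for g in self.svm_gamma_grid):
            raise ConfigurationError("C and gamma must be > 0")
        if self.l1_C <= 0:
            raise ConfigurationError("l1_C must be > 0")


def _cube_records(cube: ProcessedCube, image_id: str, labels: np.ndarray, lines: slice):
    """Yield (feature row, label, provenance) for retained pixels of chosen lines."""
    feats, labs, prov = [], [], []
    for x in range(cube.n_lines)[lines]:
        for y in range(cube.n_y):
            if not cube.retained[x, y]:
                continue
            feats.append(cube.data[x, y])
            labs.append(str(labels[x, y]))
            prov.append((image_id, x, y))
    return feats, labs, prov


def assemble_datasets(
    pure_adipose: ProcessedCube,
    pure_muscle: ProcessedCube,
    margin: ProcessedCube | None,
    margin_truth: np.ndarray | None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Split pure-tissue images by scan line and add the margin image.

    Training set: the first half of the scan lines of each pure image.
    Validation set: the remaining halves plus every retained pixel of the
    margin image.  The split is always by whole scan line.
    """
    if margin is not None and margin_truth is None:
        raise AssemblyError("margin cube requires a per-pixel truth label grid")

    tr_f, tr_l, tr_p = [], [], []
    va_f, va_l, va_p = [], [], []
    for cube, image_id, name in (
        (pure_adipose, "pure_adipose", "adipose"),
        (pure_muscle, "pure_muscle", "muscle"),
    ):
        labels = np.full((cube.n_lines, cube.n_y), name, dtype=object)
        half = cube.n_lines // 2
        f, l, p = _cube_records(cube, image_id, labels, slice(0, half))
        tr_f += f
        tr_l += l
        tr_p += p
        f, l, p = _cube_records(cube, image_id, labels, slice(half, cube.n_lines))
        va_f += f
        va_l += l
        va_p += p
    if margin is not None:
        truth = np.asarray(margin_truth)
        if truth.shape != (margin.n_lines, margin.n_y):
            raise AssemblyError("margin truth grid shape does not match margin cube")
        f, l, p = _cube_records(margin, "margin", truth, slice(0, margin.n_lines))
        va_f += f
        va_l += l
        va_p += p

    seen = set(map(tuple, tr_p))
    overlap = [p for p in va_p if tuple(p) in seen]
    if overlap:
        raise AssemblyError(f"pixel {overlap[0]} appears in both roles")

    train = LabeledDataset(
        np.asarray(tr_f, dtype=float),
        np.asarray(tr_l, dtype=object).astype(str),
        np.asarray(tr_p, dtype=object),
        "train",
    )
    validation = LabeledDataset(
        np.asarray(va_f, dtype=float),
        np.asarray(va_l, dtype=object).astype(str),
        np.asarray(va_p, dtype=object),
        "validation",
    )
    return train, validation


def select_features_l1(
    train: LabeledDataset, l1_C: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Channels with non-zero weight in an L1-penalized linear SVM."""
    classes = np.unique(train.labels)
    if classes.size < 2:
        raise SelectionError("feature selection requires two classes")
    model = LinearSVC(
        penalty="l1", dual=False, C=l1_C, tol=1e-5, max_iter=20000, random_state=seed
    )
    model.fit(train.features, train.labels)
    selected = np.flatnonzero(np.abs(model.coef_[0]) > 1e-10)
    if selected.size == 0:
        raise SelectionError(
            "L1-SVM selected zero features; increase l1_C to weaken the penalty"
        )
    return selected


def _platt_fit(decision: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit Platt's sigmoid P(y=1|f) = 1 / (1 + exp(A f + B)).

    Uses the standard smoothed targets t+ = (N+ + 1)/(N+ + 2),
    t- = 1/(N- + 2) and minimizes the cross-entropy in (A, B).
    """
    f = np.asarray(decision, dtype=float)
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = y.size - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll(ab):
        a, b = ab
        z = a * f + b
        # stable log(1 + exp(z)) and z + log(1 + exp(-z))
        log1p_exp = np.where(z > 0, z + np.log1p(np.exp(-z)), np.log1p(np.exp(z)))
        return float(np.sum(t * log1p_exp + (1.0 - t) * (log1p_exp - z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    a, b = res.x
    return float(a), float(b)


def _platt_apply(decision: np.ndarray, a: float, b: float) -> np.ndarray:
    z = a * np.asarray(decision, dtype=float) + b
    return np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))


@dataclass
class ClassifierBundle:
    """Everything needed to classify new spectra reproducibly."""

    selected_channels: np.ndarray
    mean: np.ndarray  # training means of the selected channels
    scale: np.ndarray  # training sample stds of the selected channels
    model_kind: str  # "svm" or "rf"
    hyperparameters: dict
    classes: tuple[str, str]  # index 0/1 encoding used by the decision model
    model: object = field(default=None, repr=False)  # fitted sklearn estimator
    platt: tuple[float, float] | None = None  # (A, B) for SVM confidence
    rf_trees: list | None = field(default=None, repr=False)  # serialized forest

    def standardize(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.shape[1] == self.mean.size:
            sub = x
        else:
            sub = x[:, self.selected_channels]
        return (sub - self.mean) / self.scale

    # --- decision values -------------------------------------------------
    def decision_function(self, features: np.ndarray) -> np.ndarray:
        """Signed distance to the boundary (SVM only), positive for classes[1]."""
        if self.model_kind != "svm":
            raise ParameterError("decision_function is defined for SVM bundles")
        x = self.standardize(features)
        if self.model is not None:
            return self.model.decision_function(x)
        h = self.hyperparameters
        if h["kernel"] == "linear":
            w = np.asarray(h["coef"], dtype=float)
            return x @ w + h["intercept"]
        sv = np.asarray(h["support_vectors"], dtype=float)
        dual = np.asarray(h["dual_coef"], dtype=float)
        gamma = h["gamma_value"]
        d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-gamma * d2) @ dual + h["intercept"]

    def _rf_vote_fraction(self, features: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for classes[1]."""
        x = self.standardize(features)
        if self.model is not None:
            votes = np.stack(
                [est.predict(x) for est in self.model.estimators_], axis=0
            )
            # estimators_ predict encoded class indices 0/1
            return votes.mean(axis=0)
        votes = np.zeros(len(x))
        for tree in self.rf_trees:
            votes += _tree_predict(tree, x)
        return votes / len(self.rf_trees)

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """P(classes[1]) per spectrum."""
        if self.model_kind == "svm":
            if self.platt is None:
                raise ParameterError("SVM bundle lacks Platt parameters")
            return _platt_apply(self.decision_function(features), *self.platt)
        return self._rf_vote_fraction(features)

    # --- JSON round-trip --------------------------------------------------
    def to_json(self) -> str:
        h = dict(self.hyperparameters)
        if self.model_kind == "svm" and self.model is not None:
            if h["kernel"] == "linear":
                h["coef"] = self.model.coef_[0].tolist()
            else:
                h["support_vectors"] = self.model.support_vectors_.tolist()
                h["dual_coef"] = self.model.dual_coef_[0].tolist()
                h["gamma_value"] = float(self.model._gamma)
            h["intercept"] = float(self.model.intercept_[0])
        payload = {
            "selected_channels": self.selected_channels.tolist(),
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "model_kind": self.model_kind,
            "hyperparameters": _jsonable(h),
            "classes": list(self.classes),
            "platt": list(self.platt) if self.platt is not None else None,
            "rf_trees": self.rf_trees
            if self.rf_trees is not None
            else (_serialize_forest(self.model) if self.model_kind == "rf" and self.model is not None else None),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierBundle":
        d = json.loads(text)
        return cls(
            selected_channels=np.asarray(d["selected_channels"], dtype=int),
            mean=np.asarray(d["mean"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            model_kind=d["model_kind"],
            hyperparameters=d["hyperparameters"],
            classes=tuple(d["classes"]),
            model=None,
            platt=tuple(d["platt"]) if d["platt"] is not None else None,
            rf_trees=d["rf_trees"],
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _serialize_forest(model: RandomForestClassifier) -> list:
    trees = []
    for est in model.estimators_:
        t = est.tree_
        leaf_class = np.argmax(t.value[:, 0, :], axis=1)
        trees.append(
            {
                "children_left": t.children_left.tolist(),
                "children_right": t.children_right.tolist(),
                "feature": t.feature.tolist(),
                "threshold": t.threshold.tolist(),
                "leaf_class": leaf_class.tolist(),
            }
        )
    return trees


def _tree_predict(tree: dict, x: np.ndarray) -> np.ndarray:
    left = tree["children_left"]
    right = tree["children_right"]
    feat = tree["feature"]
    thr = tree["threshold"]
    leaf = tree["leaf_class"]
    out = np.empty(len(x))
    for i, row in enumerate(x):
        node = 0
        while left[node] != -1:
            node = left[node] if row[feat[node]] <= thr[node] else right[node]
        out[i] = leaf[node]
    return out


def _grid_points(config: ClassifierConfig):
    """Deterministic evaluation order: linear SVM, RBF SVM, then RF."""
    if "linear" in config.svm_kernels:
        for C in sorted(config.svm_C_grid):
            yield ("svm", {"kernel": "linear", "C": C})
    if "rbf" in config.svm_kernels:
        for C in sorted(config.svm_C_grid):
            for gamma in sorted(config.svm_gamma_grid):
                yield ("svm", {"kernel": "rbf", "C": C, "gamma": gamma})
    for n_est in sorted(config.rf_n_estimators_grid):
        for max_samples in sorted(config.rf_max_samples_grid):
            yield ("rf", {"n_estimators": n_est, "max_samples": max_samples})


def _fit_model(kind: str, params: dict, x: np.ndarray, y01: np.ndarray, seed: int):
    if kind == "svm":
        model = SVC(
            kernel=params["kernel"],
            C=params["C"],
            gamma=params.get("gamma", "scale"),
            random_state=seed,
        )
    else:
        model = RandomForestClassifier(
            n_estimators=params["n_estimators"],
            max_samples=params["max_samples"],
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
    model.fit(x, y01)
    return model


def grid_search_train(
    train: LabeledDataset,
    validation: LabeledDataset,
    config: ClassifierConfig = ClassifierConfig(),
) -> tuple[ClassifierBundle, list[dict]]:
    """Evaluate every grid point on the validation set; return the best bundle.

    The leaderboard lists every configuration with its validation accuracy in
    evaluation order.  Ties are broken by that order (SVMs before RF,
    ascending C, gamma, n_estimators, max_samples).  Feature selection,
    standardization and Platt calibration use the training set only.
    """
    selected = select_features_l1(train, config.l1_C, config.seed)
    xt_full = train.features[:, selected]
    mean = xt_full.mean(axis=0)
    scale = xt_full.std(axis=0, ddof=1)
    scale = np.where(scale == 0, 1.0, scale)
    xt = (xt_full - mean) / scale
    xv = (validation.features[:, selected] - mean) / scale

    classes = tuple(sorted(np.unique(train.labels)))
    if len(classes) != 2:
        raise SelectionError("training requires exactly two classes")
    yt = (train.labels == classes[1]).astype(int)
    yv = (validation.labels == classes[1]).astype(int)

    leaderboard: list[dict] = []
    best = None
    for order, (kind, params) in enumerate(_grid_points(config)):
        model = _fit_model(kind, params, xt, yt, config.seed)
        acc = float(np.mean(model.predict(xv) == yv))
        leaderboard.append(
            {"order": order, "model": kind, **params, "validation_accuracy": acc}
        )
        if best is None or acc > best[0]:
            best = (acc, order, kind, params, model)

    _, _, kind, params, model = best
    platt = None
    if kind == "svm":
        platt = _fit_platt_cv(xt, yt, kind, params, config.seed)
    bundle = ClassifierBundle(
        selected_channels=selected,
        mean=mean,
        scale=scale,
        model_kind=kind,
        hyperparameters=dict(params),
        classes=classes,
        model=model,
        platt=platt,
    )
    return bundle, leaderboard


def _fit_platt_cv(
    x: np.ndarray, y01: np.ndarray, kind: str, params: dict, seed: int
) -> tuple[float, float]:
    """Platt sigmoid on out-of-fold decision values (5-fold stratified CV)."""
    n_splits = min(5, int(np.min(np.bincount(y01))))
    if n_splits < 2:
        raise SelectionError("Platt calibration needs at least 2 samples per class")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    decisions = np.empty(len(y01))
    for tr_idx, te_idx in skf.split(x, y01):
        fold = _fit_model(kind, params, x[tr_idx], y01[tr_idx], seed)
        decisions[te_idx] = fold.decision_function(x[te_idx])
    return _platt_fit(decisions, y01)


def predict_with_probability(
    bundle: ClassifierBundle, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted labels and the probability of the predicted class.

    ``features`` are full-channel SNV spectra; the bundle restricts them to
    its selected channels and standardizes with training statistics.  The
    returned confidence is ``max(p, 1 - p)`` and therefore lies in
    [0.5, 1.0].
    """
    p1 = bundle.predict_proba(features)
    labels = np.where(p1 >= 0.5, bundle.classes[1], bundle.classes[0])
    confidence = np.maximum(p1, 1.0 - p1)
    return labels, confidence


@dataclass
class MetricsReport:
    """Binary classification metrics; adipose is the positive class."""

    accuracy: float
    sensitivity: float
    specificity: float
    confusion: np.ndarray  # [[TP, FN], [FP, TN]]
    pearson_r: float | None = None


def compute_metrics(
    predicted: Sequence[str], truth: Sequence[str], positive: str = POSITIVE_CLASS
) -> MetricsReport:
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ParameterError("predicted and truth lengths differ")
    tp = int(np.sum((pred == positive) & (true == positive)))
    fn = int(np.sum((pred != positive) & (true == positive)))
    fp = int(np.sum((pred == positive) & (true != positive)))
    tn = int(np.sum((pred != positive) & (true != positive)))
    total = tp + fn + fp + tn
    return MetricsReport(
        accuracy=(tp + tn) / total if total else float("nan"),
        sensitivity=tp / (tp + fn) if (tp + fn) else float("nan"),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        confusion=np.array([[tp, fn], [fp, tn]]),
    )


def pearson_diagnostics(mean_a: np.ndarray, mean_b: np.ndarray) -> float:
    """Pearson correlation between two mean spectra."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("spectra lengths differ")
    if a.std() == 0 or b.std() == 0:
        raise ParameterError("constant spectrum has no defined correlation")
    return float(pearsonr(a, b)[0])


@dataclass
class MarginMap:
    """Per-pixel class and confidence grids over a margin image."""

    class_map: np.ndarray  # (n_lines, n_y) class-name strings
    confidence_map: np.ndarray  # (n_lines, n_y) in [0.5, 1.0]
    mask: np.ndarray  # True = rejected / low illumination
    truth_line: int | None
    margin_column: float | None  # median per-row transition column
    low_confidence_width: float  # mean width (px) of the <0.90 band
    no_transition: bool = False


def _row_transition(labels01: np.ndarray) -> int | None:
    """Change-point of a 0/1 row: split minimizing step-function mismatch."""
    n = labels01.size
    if n == 0 or labels01.min() == labels01.max():
        return None
    cum = np.concatenate([[0], np.cumsum(labels01)])
    total = cum[-1]
    # step 0...0 1...1 with boundary at c: errors = ones left of c + zeros right
    errors = [cum[c] + ((n - c) - (total - cum[c])) for c in range(n + 1)]
    return int(np.argmin(errors))


def render_margin_map(
    bundle: ClassifierBundle,
    processed_margin: ProcessedCube,
    truth_line: int | None = None,
    low_confidence_threshold: float = 0.90,
) -> MarginMap:
    """Classify every retained pixel of a margin cube and locate the boundary.

    The margin column estimate is the median over scan rows (y) of the
    per-row class-transition location along x; the low-confidence width is
    the mean, over rows with a transition, of the length of the contiguous
    run of pixels with confidence below the threshold around the transition.
    """
    nx, ny = processed_margin.n_lines, processed_margin.n_y
    flat = processed_margin.data.reshape(-1, processed_margin.data.shape[-1])
    labels, conf = predict_with_probability(bundle, flat)
    class_map = labels.reshape(nx, ny)
    conf_map = conf.reshape(nx, ny)
    mask = ~processed_margin.retained

    transitions = []
    widths = []
    for y in range(ny):
        keep = ~mask[:, y]
        if keep.sum() < 2:
            continue
        xs = np.flatnonzero(keep)
        row01 = (class_map[xs, y] == bundle.classes[1]).astype(int)
        # orient so the majority of the left half is 0
        half = max(1, row01.size // 2)
        if row01[:half].mean() > 0.5:
            row01 = 1 - row01
        c = _row_transition(row01)
        if c is None or c == 0 or c == row01.size:
            continue
        transitions.append(float(xs[min(c, xs.size - 1)]))
        low = conf_map[xs, y] < low_confidence_threshold
        width = 0
        # contiguous low-confidence run touching the transition
        i = c
        while i < row01.size and low[i]:
            width += 1
            i += 1
        i = c - 1
        while i >= 0 and low[i]:
            width += 1
            i -= 1
        widths.append(width)

    no_transition = len(transitions) == 0
    return MarginMap(
        class_map=class_map,
        confidence_map=conf_map,
        mask=mask,
        truth_line=truth_line,
        margin_column=float(np.median(transitions)) if transitions else None,
        low_confidence_width=float(np.mean(widths)) if widths else 0.0,
        no_transition=no_transition,
    )
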