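"""Gear-of-origin classification from per-reading sensor feature vectors.

Each time instance of a preprocessed recording is one observation: a vector
of 35 standardized sensor variables labelled with the gear of the fish.
The module provides stratified 65/25/10 splits, a sensor-subset ladder, and
from-scratch implementations of the three model families that win the
ladder — random-subspace k-nearest-neighbour ensembles, kernel naive Bayes,
and random-subspace linear discriminant ensembles — plus Monte-Carlo Shapley
feature importances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import logsumexp, softmax

from .data import GearRecording, channels_for_modules

__all__ = [
    "FeatureTable",
    "SplitSpec",
    "ClassifierReport",
    "build_feature_table",
    "subset_sensors",
    "split",
    "SubspaceKNN",
    "KernelNaiveBayes",
    "SubspaceDiscriminant",
    "fit_subspace_knn",
    "fit_kernel_nb",
    "fit_subspace_discriminant",
    "evaluate",
    "shapley_importance",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """Observations = readings (rows), features = sensor variables."""

    features: np.ndarray  # [N x p]
    labels: np.ndarray  # [N]
    feature_names: list[str]
    group_ids: np.ndarray  # recording id per row

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.group_ids = np.asarray(self.group_ids)
        n, p = self.features.shape
        if len(self.labels) != n or len(self.group_ids) != n:
            raise ValueError("labels/group_ids length must match feature rows")
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must match feature columns")
        if np.isnan(self.features).any():
            raise ValueError("feature table must not contain missing entries")

    def __len__(self) -> int:
        return self.features.shape[0]

    def take(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            features=self.features[idx],
            labels=self.labels[idx],
            feature_names=list(self.feature_names),
            group_ids=self.group_ids[idx],
        )


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition design."""

    train_frac: float = 0.65
    val_frac: float = 0.25
    test_frac: float = 0.10
    seed: int = 0
    stratified: bool = True
    grouped: bool = False  # split whole recordings instead of single readings

    def __post_init__(self) -> None:
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1 (got {total})")
        if min(self.train_frac, self.val_frac, self.test_frac) < 0:
            raise ValueError("split fractions must be nonnegative")


@dataclass
class ClassifierReport:
    """Evaluation summary of one fitted model on validation and test sets."""

    model_name: str
    classes: list[str]
    accuracy_val: float  # percent
    accuracy_test: float
    confusion_val: np.ndarray  # [K x K], rows = true, cols = predicted
    confusion_test: np.ndarray
    per_class_val: dict[str, np.ndarray]  # precision / recall / f1
    per_class_test: dict[str, np.ndarray]
    macro_val: dict[str, float]
    macro_test: dict[str, float]
    importances: np.ndarray | None = None
    feature_names: list[str] | None = None

    def to_dict(self) -> dict:
        out = {
            "model_name": self.model_name,
            "classes": self.classes,
            "accuracy_val_pct": self.accuracy_val,
            "accuracy_test_pct": self.accuracy_test,
            "confusion_val": self.confusion_val.tolist(),
            "confusion_test": self.confusion_test.tolist(),
            "macro_val": self.macro_val,
            "macro_test": self.macro_test,
            "per_class_val": {k: v.tolist() for k, v in self.per_class_val.items()},
            "per_class_test": {k: v.tolist() for k, v in self.per_class_test.items()},
        }
        if self.importances is not None:
            out["importances"] = dict(
                zip(self.feature_names or [], map(float, self.importances))
            )
        return out

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "report.json").write_text(
            json.dumps(self.to_dict(), indent=2, sort_keys=True)
        )
        import pandas as pd

        for name, cm in (("val", self.confusion_val), ("test", self.confusion_test)):
            pd.DataFrame(cm, index=self.classes, columns=self.classes).to_csv(
                directory / f"confusion_{name}.csv"
            )


def build_feature_table(recordings: list[GearRecording]) -> FeatureTable:
    """Pool all readings: one row per time instance per recording."""
    if not recordings:
        raise ValueError("no recordings given")
    channels = recordings[0].channels
    for rec in recordings:
        if rec.channels != channels:
            raise ValueError("recordings have inconsistent channel lists")
        if np.isnan(rec.values).any():
            raise ValueError("preprocess recordings before building features")
    features = np.vstack([rec.values for rec in recordings])
    labels = np.concatenate(
        [np.repeat(rec.gear, rec.n_time) for rec in recordings]
    )
    group_ids = np.concatenate(
        [np.repeat(f"{rec.gear}__rep{rec.replicate}", rec.n_time) for rec in recordings]
    )
    return FeatureTable(
        features=features,
        labels=labels,
        feature_names=list(channels),
        group_ids=group_ids,
    )


def subset_sensors(table: FeatureTable, modules: list[str]) -> FeatureTable:
    """Keep only the analyte columns of the listed MQ modules (5 each),
    preserving the table's column order."""
    wanted = set(channels_for_modules(modules))
    keep = [j for j, name in enumerate(table.feature_names) if name in wanted]
    missing = wanted - {table.feature_names[j] for j in keep}
    if missing:
        raise ValueError(f"channels not present in table: {sorted(missing)}")
    return FeatureTable(
        features=table.features[:, keep],
        labels=table.labels,
        feature_names=[table.feature_names[j] for j in keep],
        group_ids=table.group_ids,
    )


def split(
    table: FeatureTable, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureTable, FeatureTable, FeatureTable]:
    """Deterministic stratified partition; rounding residue goes to train.

    With ``spec.grouped`` whole recordings are assigned to one partition
    (avoids temporal-autocorrelation leakage); default is reading-level.
    """
    rng = np.random.default_rng(spec.seed)
    n = len(table)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []

    def partition(units: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        units = units[rng.permutation(len(units))]
        n_val = int(np.floor(spec.val_frac * len(units)))
        n_test = int(np.floor(spec.test_frac * len(units)))
        return units[n_val + n_test :], units[:n_val], units[n_val : n_val + n_test]

    if spec.grouped:
        strata = (
            [np.unique(table.group_ids[table.labels == c]) for c in np.unique(table.labels)]
            if spec.stratified
            else [np.unique(table.group_ids)]
        )
        for groups in strata:
            tr_g, va_g, te_g = partition(groups)
            train_idx.append(np.flatnonzero(np.isin(table.group_ids, tr_g)))
            val_idx.append(np.flatnonzero(np.isin(table.group_ids, va_g)))
            test_idx.append(np.flatnonzero(np.isin(table.group_ids, te_g)))
    else:
        strata = (
            [np.flatnonzero(table.labels == c) for c in np.unique(table.labels)]
            if spec.stratified
            else [np.arange(n)]
        )
        for idx in strata:
            tr, va, te = partition(idx)
            train_idx.append(tr)
            val_idx.append(va)
            test_idx.append(te)

    pick = lambda parts: table.take(np.sort(np.concatenate(parts)))
    return pick(train_idx), pick(val_idx), pick(test_idx)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------


class _BaseClassifier:
    """Shared prediction plumbing: classes in a fixed configured order,
    argmax of class scores with ties broken toward the earlier class."""

    classes_: np.ndarray
    feature_names: list[str]
    name = "base"

    def predict_proba(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def predict(self, x: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(np.asarray(x, dtype=float))
        return self.classes_[np.argmax(proba, axis=1)]

    def _encode(self, labels: np.ndarray, class_order: list[str] | None) -> np.ndarray:
        if class_order is None:
            self.classes_ = np.unique(labels)
        else:
            self.classes_ = np.asarray(class_order)
            unknown = set(labels) - set(self.classes_)
            if unknown:
                raise ValueError(f"labels outside configured classes: {unknown}")
        lookup = {c: i for i, c in enumerate(self.classes_)}
        return np.array([lookup[c] for c in labels])


def _draw_subspaces(
    rng: np.random.Generator, p: int, dim: int, n_learners: int
) -> list[np.ndarray]:
    return [np.sort(rng.choice(p, size=dim, replace=False)) for _ in range(n_learners)]


class SubspaceKNN(_BaseClassifier):
    """Random-subspace ensemble of k-nearest-neighbour learners.

    Each learner sees an independently drawn feature subset; prediction is
    the majority vote over learners (vote shares double as class scores).
    """

    name = "subspace_knn"

    def __init__(self, n_learners: int = 30, subspace_dim: int | None = None,
                 k_neighbors: int = 1, seed: int = 0):
        if n_learners < 1 or k_neighbors < 1:
            raise ValueError("n_learners and k_neighbors must be positive")
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.k_neighbors = k_neighbors
        self.seed = seed

    def fit(self, table: FeatureTable, class_order: list[str] | None = None) -> "SubspaceKNN":
        y = self._encode(table.labels, class_order)
        x = table.features
        p = x.shape[1]
        dim = self.subspace_dim if self.subspace_dim is not None else int(np.ceil(p / 2))
        if not 1 <= dim <= p:
            raise ValueError(f"subspace_dim must be in [1, {p}]")
        if self.k_neighbors > len(table):
            raise ValueError("k_neighbors exceeds the training-set size")
        self.feature_names = list(table.feature_names)
        rng = np.random.default_rng(self.seed)
        self.subspaces_ = _draw_subspaces(rng, p, dim, self.n_learners)
        self.trees_ = [cKDTree(x[:, s]) for s in self.subspaces_]
        self.train_y_ = y
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n, k_classes = x.shape[0], len(self.classes_)
        votes = np.zeros((n, k_classes))
        for tree, sub in zip(self.trees_, self.subspaces_):
            _, nn = tree.query(x[:, sub], k=self.k_neighbors)
            nn = np.atleast_2d(nn.reshape(n, -1))
            neigh_labels = self.train_y_[nn]  # [n x k]
            counts = np.zeros((n, k_classes))
            for c in range(k_classes):
                counts[:, c] = (neigh_labels == c).sum(axis=1)
            votes[np.arange(n), np.argmax(counts, axis=1)] += 1.0
        return votes / self.n_learners


class KernelNaiveBayes(_BaseClassifier):
    """Naive Bayes with per-class, per-feature Gaussian kernel densities.

    Bandwidths follow the named rule (Silverman's rule of thumb by default);
    a zero-variance feature within a class gets a floored bandwidth.
    """

    name = "kernel_nb"

    def __init__(self, bandwidth_rule: str = "silverman"):
        if bandwidth_rule not in ("silverman", "scott"):
            raise ValueError("bandwidth_rule must be 'silverman' or 'scott'")
        self.bandwidth_rule = bandwidth_rule

    def _bandwidth(self, vals: np.ndarray) -> float:
        n = len(vals)
        sd = vals.std(ddof=1) if n > 1 else 0.0
        if self.bandwidth_rule == "silverman":
            iqr = np.subtract(*np.percentile(vals, [75, 25]))
            spread = min(sd, iqr / 1.34) if iqr > 0 else sd
            return 0.9 * spread * n ** (-1 / 5)
        return 1.06 * sd * n ** (-1 / 5)

    def fit(self, table: FeatureTable, class_order: list[str] | None = None) -> "KernelNaiveBayes":
        y = self._encode(table.labels, class_order)
        x = table.features
        self.feature_names = list(table.feature_names)
        counts = np.bincount(y, minlength=len(self.classes_))
        if np.any(counts < 2):
            raise ValueError("kernel naive Bayes needs >= 2 observations per class")
        self.log_priors_ = np.log(counts / counts.sum())
        global_sd = x.std(axis=0)
        self.values_: list[list[np.ndarray]] = []
        self.bandwidths_ = np.empty((len(self.classes_), x.shape[1]))
        for c in range(len(self.classes_)):
            rows = x[y == c]
            per_feature = []
            for j in range(x.shape[1]):
                vals = rows[:, j]
                h = self._bandwidth(vals)
                if h <= 0:
                    floor = 1e-6 * (global_sd[j] if global_sd[j] > 0 else 1.0)
                    logger.warning(
                        "zero-variance feature %s in class %s; flooring bandwidth",
                        self.feature_names[j], self.classes_[c],
                    )
                    h = floor
                per_feature.append(vals)
                self.bandwidths_[c, j] = h
            self.values_.append(per_feature)
        return self

    def _log_posteriors(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        n = x.shape[0]
        log_post = np.tile(self.log_priors_, (n, 1))
        for c in range(len(self.classes_)):
            for j in range(x.shape[1]):
                vals = self.values_[c][j]
                h = self.bandwidths_[c, j]
                z = (x[:, j, None] - vals[None, :]) / h
                log_k = -0.5 * z**2 - np.log(h * np.sqrt(2 * np.pi) * len(vals))
                log_post[:, c] += logsumexp(log_k, axis=1)
        return log_post

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self._log_posteriors(x), axis=1)


class SubspaceDiscriminant(_BaseClassifier):
    """Random-subspace ensemble of pooled-covariance linear discriminants,
    combined by averaging class posteriors."""

    name = "subspace_discriminant"

    def __init__(self, n_learners: int = 30, subspace_dim: int | None = None,
                 seed: int = 0, shrinkage: float = 1e-6):
        if n_learners < 1:
            raise ValueError("n_learners must be positive")
        self.n_learners = n_learners
        self.subspace_dim = subspace_dim
        self.seed = seed
        self.shrinkage = shrinkage

    def _fit_lda(self, x: np.ndarray, y: np.ndarray, k: int):
        n, d = x.shape
        means = np.vstack([x[y == c].mean(axis=0) for c in range(k)])
        centered = x - means[y]
        pooled = centered.T @ centered / max(n - k, 1)
        lam = self.shrinkage * max(np.trace(pooled) / d, 1e-30)
        for _ in range(8):
            try:
                reg = pooled + lam * np.eye(d)
                w = np.linalg.solve(reg, means.T)  # [d x K]
                if np.all(np.isfinite(w)):
                    break
            except np.linalg.LinAlgError:
                pass
            lam *= 1000.0
            logger.warning("singular pooled covariance; escalating shrinkage to %g", lam)
        intercept = -0.5 * np.sum(means * w.T, axis=1)
        return w, intercept

    def fit(self, table: FeatureTable, class_order: list[str] | None = None) -> "SubspaceDiscriminant":
        y = self._encode(table.labels, class_order)
        x = table.features
        p = x.shape[1]
        k = len(self.classes_)
        dim = self.subspace_dim if self.subspace_dim is not None else int(np.ceil(p / 2))
        if not 1 <= dim <= p:
            raise ValueError(f"subspace_dim must be in [1, {p}]")
        self.feature_names = list(table.feature_names)
        counts = np.bincount(y, minlength=k)
        self.log_priors_ = np.log(counts / counts.sum())
        rng = np.random.default_rng(self.seed)
        self.subspaces_ = _draw_subspaces(rng, p, dim, self.n_learners)
        self.learners_ = [
            self._fit_lda(x[:, s], y, k) for s in self.subspaces_
        ]
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        post = np.zeros((x.shape[0], len(self.classes_)))
        for sub, (w, intercept) in zip(self.subspaces_, self.learners_):
            scores = x[:, sub] @ w + intercept + self.log_priors_
            post += softmax(scores, axis=1)
        return post / self.n_learners


def fit_subspace_knn(
    train: FeatureTable,
    n_learners: int = 30,
    subspace_dim: int | None = None,
    k_neighbors: int = 1,
    seed: int = 0,
    class_order: list[str] | None = None,
) -> SubspaceKNN:
    return SubspaceKNN(n_learners, subspace_dim, k_neighbors, seed).fit(train, class_order)


def fit_kernel_nb(
    train: FeatureTable,
    bandwidth_rule: str = "silverman",
    class_order: list[str] | None = None,
) -> KernelNaiveBayes:
    return KernelNaiveBayes(bandwidth_rule).fit(train, class_order)


def fit_subspace_discriminant(
    train: FeatureTable,
    n_learners: int = 30,
    subspace_dim: int | None = None,
    seed: int = 0,
    class_order: list[str] | None = None,
) -> SubspaceDiscriminant:
    return SubspaceDiscriminant(n_learners, subspace_dim, seed).fit(train, class_order)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray, classes: np.ndarray) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[lookup[t], lookup[p]] += 1
    return cm


def _metrics(cm: np.ndarray) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    tp = np.diag(cm).astype(float)
    pred_tot = cm.sum(axis=0).astype(float)
    true_tot = cm.sum(axis=1).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(pred_tot > 0, tp / pred_tot, 0.0)
        recall = np.where(true_tot > 0, tp / true_tot, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    per_class = {"precision": precision, "recall": recall, "f1": f1}
    macro = {k: float(v.mean()) for k, v in per_class.items()}
    return per_class, macro


def evaluate(
    model: _BaseClassifier, val: FeatureTable, test: FeatureTable
) -> ClassifierReport:
    """Score a fitted model on validation and test partitions."""
    reports = {}
    for name, part in (("val", val), ("test", test)):
        if part.feature_names != model.feature_names:
            raise ValueError(f"{name} feature names do not match training")
        unknown = set(part.labels) - set(model.classes_)
        if unknown:
            raise ValueError(f"{name} labels outside training classes: {unknown}")
        pred = model.predict(part.features)
        cm = _confusion(part.labels, pred, model.classes_)
        acc = 100.0 * np.trace(cm) / max(len(part), 1)
        per_class, macro = _metrics(cm)
        reports[name] = (acc, cm, per_class, macro)
    return ClassifierReport(
        model_name=getattr(model, "name", type(model).__name__),
        classes=list(model.classes_),
        accuracy_val=reports["val"][0],
        accuracy_test=reports["test"][0],
        confusion_val=reports["val"][1],
        confusion_test=reports["test"][1],
        per_class_val=reports["val"][2],
        per_class_test=reports["test"][2],
        macro_val=reports["val"][3],
        macro_test=reports["test"][3],
        feature_names=list(model.feature_names),
    )


def shapley_importance(
    model: _BaseClassifier,
    data: FeatureTable,
    n_samples: int = 64,
    seed: int = 0,
    background_size: int = 100,
) -> np.ndarray:
    """Mean absolute Monte-Carlo Shapley value of each feature.

    For each observation, the value function is the model's score
    (probability / vote share) for that observation's predicted class; absent
    coalition features are marginalized by substituting values from a random
    background row.  Permutation sampling with ``n_samples`` permutations per
    observation; deterministic per seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    x = data.features
    n, p = x.shape
    bg_idx = rng.choice(n, size=min(background_size, n), replace=False)
    background = x[bg_idx]

    class_index = {c: i for i, c in enumerate(model.classes_)}
    target = np.array([class_index[c] for c in model.predict(x)])
    rows = np.arange(n)

    def score(w: np.ndarray) -> np.ndarray:
        return model.predict_proba(w)[rows, target]

    phi = np.zeros((n, p))
    for _ in range(n_samples):
        perm = rng.permutation(p)
        w = background[rng.integers(len(background), size=n)].copy()
        v_prev = score(w)
        for j in perm:
            w[:, j] = x[:, j]
            v = score(w)
            phi[:, j] += v - v_prev
            v_prev = v
    phi /= n_samples
    return np.abs(phi).mean(axis=0)
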