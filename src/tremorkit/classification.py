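"""Nested cross-validated disease classification and feature importance.

Three binary tasks are supported on the PD / DD / healthy label set:

* ``pd_vs_healthy``      -- PD (positive) against healthy controls,
* ``disease_vs_healthy`` -- any movement disorder (PD + DD, positive)
  against healthy controls,
* ``pd_vs_dd``           -- PD (positive) against differential diagnoses.

The estimation pipeline mirrors a standard imbalanced-tabular setup:
random undersampling of the majority class, feature standardization, PCA,
univariate percentile feature selection, then the estimator (RBF-SVM,
gradient-boosted trees, or a two-hidden-layer MLP).  Hyperparameters are
tuned by grid search on five inner folds using balanced accuracy; test
performance is measured on five stratified outer folds.  All sampling,
fold splitting and estimator seeds derive deterministically from a single
integer seed.

The module exposes a statsmodels-like surface: :class:`TremorClassifier`
is the model object, its :meth:`~TremorClassifier.fit` returns a
:class:`ClassificationResults` carrying per-fold metrics, the selected
hyperparameters, leakage-audit details and a ``summary()`` table.
:func:`nested_cv` and :func:`feature_importance` are thin functional
wrappers over those objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import f_classif, mutual_info_classif
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "TASKS",
    "TaskSpec",
    "TremorClassifier",
    "ClassificationResults",
    "BootstrapImportance",
    "ImportanceResult",
    "balanced_accuracy",
    "feature_importance",
    "nested_cv",
    "random_undersample",
]


# --------------------------------------------------------------------------
# tasks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskSpec:
    """Binary task definition over the PD / DD / healthy label set."""

    name: str
    positive_class: str
    class_mapping: dict  # label -> 0/1

    def encode(self, labels) -> tuple[np.ndarray, np.ndarray]:
        """Return (row mask of included labels, binary target vector)."""
        labels = np.asarray(labels)
        mask = np.isin(labels, list(self.class_mapping))
        y = np.array([self.class_mapping[v] for v in labels[mask]], dtype=int)
        return mask, y


TASKS: dict[str, TaskSpec] = {
    "pd_vs_healthy": TaskSpec(
        name="pd_vs_healthy",
        positive_class="PD",
        class_mapping={"PD": 1, "healthy": 0},
    ),
    "disease_vs_healthy": TaskSpec(
        name="disease_vs_healthy",
        positive_class="PD+DD",
        class_mapping={"PD": 1, "DD": 1, "healthy": 0},
    ),
    "pd_vs_dd": TaskSpec(
        name="pd_vs_dd",
        positive_class="PD",
        class_mapping={"PD": 1, "DD": 0},
    ),
}


def _resolve_task(task) -> TaskSpec:
    if isinstance(task, TaskSpec):
        return task
    try:
        return TASKS[task]
    except KeyError:
        raise ValidationError(
            f"unknown task {task!r}; expected one of {sorted(TASKS)}"
        ) from None


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def _undersample_indices(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices retaining the minority class and a random, equally sized
    subset of the majority class (without replacement)."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("undersampling requires at least two classes")
    n_min = counts.min()
    keep = []
    for c in classes:
        idx = np.nonzero(y == c)[0]
        if idx.size > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def random_undersample(features, labels, seed: int):
    """Balance classes by randomly discarding majority-class samples.

    Returns the subsampled ``(features, labels)`` pair; row order of the
    retained samples is preserved.  Works on DataFrames/Series and plain
    arrays alike.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    idx = _undersample_indices(y, rng)
    if isinstance(features, pd.DataFrame):
        X_out = features.iloc[idx]
    else:
        X_out = np.asarray(features)[idx]
    if isinstance(labels, pd.Series):
        y_out = labels.iloc[idx]
    else:
        y_out = y[idx]
    return X_out, y_out


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class recalls (chance level 0.5 for binary tasks)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have the same shape")
    classes = np.unique(y_true)
    if classes.size < 2:
        raise ValidationError("balanced accuracy needs both classes in y_true")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


# --------------------------------------------------------------------------
# hyperparameter grids (defaults)
# --------------------------------------------------------------------------

DEFAULT_PCA_VARIANCES: tuple[float, ...] = (0.80, 0.90, 0.95)
DEFAULT_SELECT_PERCENTILES: tuple[int, ...] = (25, 50, 75, 100)

DEFAULT_ESTIMATOR_GRIDS: dict[str, list[dict]] = {
    "svm_rbf": [
        {"C": c, "gamma": g}
        for c, g in product([0.1, 1.0, 10.0], ["auto", 0.01, 0.001])
    ],
    "boosted_trees": [
        {"max_depth": d, "n_estimators": n, "learning_rate": lr}
        for d, n, lr in product([4, 6], [200, 500], [0.03, 0.1])
    ],
    "mlp": [
        {"hidden_layer_sizes": h, "alpha": a}
        for h, a in product([(64, 32), (128, 64)], [1e-4, 1e-2])
    ],
}


def _make_estimator(family: str, params: dict, seed: int):
    if family == "svm_rbf":
        return SVC(kernel="rbf", **params)
    if family == "mlp":
        return MLPClassifier(
            max_iter=400, random_state=seed, **params
        )
    if family == "boosted_trees":
        from lightgbm import LGBMClassifier

        depth = params.get("max_depth", 6)
        return LGBMClassifier(
            num_leaves=min(31, 2 ** depth),
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            min_child_samples=5,
            **params,
        )
    raise ValidationError(
        f"unknown estimator family {family!r}; expected one of "
        f"{sorted(DEFAULT_ESTIMATOR_GRIDS)}"
    )


def _select_top_percentile(scores: np.ndarray, percentile: float) -> np.ndarray:
    """Boolean mask keeping the top-scoring ``percentile`` % of features.

    Deterministic tie-break: lower feature index wins (stable argsort)."""
    n = scores.size
    k = max(1, int(round(n * percentile / 100.0)))
    order = np.argsort(-scores, kind="stable")
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


# --------------------------------------------------------------------------
# model / results objects
# --------------------------------------------------------------------------

@dataclass
class FoldDetail:
    """Leakage-audit record of one outer fold."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    undersample_idx: np.ndarray  # absolute row indices used for the refit
    scaler_mean: np.ndarray
    chosen_params: dict


class ClassificationResults:
    """Per-fold test metrics of a nested cross-validation run."""

    _METRICS = ("accuracy", "balanced_accuracy", "precision", "recall", "f1")

    def __init__(
        self,
        task: TaskSpec,
        estimator: str,
        seed: int,
        fold_metrics: pd.DataFrame,
        fold_details: list[FoldDetail],
        n_samples: int,
        n_features: int,
    ) -> None:
        self.task = task
        self.estimator = estimator
        self.seed = seed
        self.fold_metrics = fold_metrics
        self.fold_details = fold_details
        self.n_samples = n_samples
        self.n_features = n_features

    @property
    def chosen_params(self) -> list[dict]:
        return [d.chosen_params for d in self.fold_details]

    def mean(self) -> pd.Series:
        return self.fold_metrics.mean()

    def sd(self) -> pd.Series:
        return self.fold_metrics.std(ddof=1)

    def to_dict(self) -> dict:
        return {
            "task": self.task.name,
            "estimator": self.estimator,
            "seed": self.seed,
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "folds": self.fold_metrics.to_dict(orient="records"),
            "mean": self.mean().to_dict(),
            "sd": self.sd().to_dict(),
            "chosen_params": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in p.items()}
                for p in self.chosen_params
            ],
        }

    def summary(self) -> str:
        lines = [
            f"Nested cross-validation: task={self.task.name} "
            f"estimator={self.estimator} seed={self.seed}",
            f"n={self.n_samples} samples, {self.n_features} features, "
            f"{len(self.fold_metrics)} outer folds",
            "",
            f"{'metric':<18}{'mean':>8}{'sd':>8}",
        ]
        means, sds = self.mean(), self.sd()
        for m in self._METRICS:
            lines.append(f"{m:<18}{means[m]:>8.3f}{sds[m]:>8.3f}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        bal = self.mean()["balanced_accuracy"]
        return (
            f"<ClassificationResults {self.task.name}/{self.estimator} "
            f"balanced_accuracy={bal:.3f}>"
        )


class TremorClassifier:
    """Nested cross-validated classifier over a feature table.

    Parameters
    ----------
    features
        Feature table (DataFrame or array), one row per participant.
    labels
        Class labels aligned with ``features`` rows.
    task
        Task name or :class:`TaskSpec`.
    estimator
        One of ``svm_rbf``, ``boosted_trees``, ``mlp``.
    pca_variances, select_percentiles, estimator_grid
        Hyperparameter grids; defaults are the module-level grids.
    selector
        Univariate selection score: ``"mutual_info"`` (default) or
        ``"anova"``.
    n_outer, n_inner
        Outer and inner stratified fold counts (default five and five).
    """

    def __init__(
        self,
        features,
        labels,
        task,
        estimator: str = "svm_rbf",
        pca_variances=DEFAULT_PCA_VARIANCES,
        select_percentiles=DEFAULT_SELECT_PERCENTILES,
        estimator_grid: list[dict] | None = None,
        selector: str = "mutual_info",
        n_outer: int = 5,
        n_inner: int = 5,
    ) -> None:
        self.task = _resolve_task(task)
        if estimator not in DEFAULT_ESTIMATOR_GRIDS:
            _make_estimator(estimator, {}, 0)  # raises with a helpful message
        self.estimator = estimator
        self.feature_names = (
            list(features.columns)
            if isinstance(features, pd.DataFrame)
            else [f"f{i}" for i in range(np.asarray(features).shape[1])]
        )
        X = np.asarray(features, dtype=float)
        mask, y = self.task.encode(labels)
        self.X = X[mask]
        self.y = y
        if self.X.shape[0] < 50:
            warnings.warn(
                "fewer than 50 samples; nested CV estimates will be unstable",
                stacklevel=2,
            )
        if np.unique(self.y).size < 2:
            raise ValidationError("both task classes must be present")
        self.pca_variances = tuple(pca_variances)
        self.select_percentiles = tuple(select_percentiles)
        self.estimator_grid = (
            estimator_grid
            if estimator_grid is not None
            else DEFAULT_ESTIMATOR_GRIDS[estimator]
        )
        if selector not in ("mutual_info", "anova"):
            raise ValidationError("selector must be 'mutual_info' or 'anova'")
        self.selector = selector
        self.n_outer = n_outer
        self.n_inner = n_inner

    # -- internal stages ---------------------------------------------------

    def _scores(self, X: np.ndarray, y: np.ndarray, seed: int) -> np.ndarray:
        if self.selector == "anova":
            scores, _ = f_classif(X, y)
            return np.nan_to_num(scores)
        return mutual_info_classif(X, y, random_state=seed)

    def _fit_transforms(self, X_train, y_train, pca_var, seed):
        scaler = StandardScaler().fit(X_train)
        Xs = scaler.transform(X_train)
        n_comp = min(pca_var, 1.0) if isinstance(pca_var, float) else pca_var
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
        Xp = pca.fit_transform(Xs)
        scores = self._scores(Xp, y_train, seed)
        return scaler, pca, scores, Xp

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int = 0) -> ClassificationResults:
        """Run the nested cross-validation and return the results object."""
        X, y = self.X, self.y
        configs = [
            {"pca": v, "percentile": p, "params": ep}
            for v, p, ep in product(
                self.pca_variances, self.select_percentiles, self.estimator_grid
            )
        ]
        outer = StratifiedKFold(self.n_outer, shuffle=True, random_state=seed)
        rows = []
        details = []
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=UserWarning)
            warnings.filterwarnings(
                "ignore", module="sklearn.neural_network"
            )
            for k, (tr, te) in enumerate(outer.split(X, y)):
                best = self._tune_fold(X[tr], y[tr], configs, seed, k)
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, k, 2**20])
                )
                us = _undersample_indices(y[tr], rng)
                scaler, pca, scores, Xp = self._fit_transforms(
                    X[tr][us], y[tr][us], best["pca"], seed
                )
                mask = _select_top_percentile(scores, best["percentile"])
                est = _make_estimator(self.estimator, best["params"], seed)
                est.fit(Xp[:, mask], y[tr][us])
                X_test = pca.transform(scaler.transform(X[te]))[:, mask]
                pred = est.predict(X_test)
                rows.append(self._metrics(y[te], pred))
                details.append(
                    FoldDetail(
                        train_idx=tr,
                        test_idx=te,
                        undersample_idx=tr[us],
                        scaler_mean=scaler.mean_.copy(),
                        chosen_params=dict(best),
                    )
                )
        fold_metrics = pd.DataFrame(rows)
        return ClassificationResults(
            task=self.task,
            estimator=self.estimator,
            seed=seed,
            fold_metrics=fold_metrics,
            fold_details=details,
            n_samples=X.shape[0],
            n_features=X.shape[1],
        )

    def _tune_fold(self, X_tr, y_tr, configs, seed, k) -> dict:
        inner = StratifiedKFold(
            self.n_inner, shuffle=True, random_state=seed * 1000 + k + 1
        )
        splits = list(inner.split(X_tr, y_tr))
        scores = np.zeros(len(configs))
        # cache transforms per (inner split, pca variance): the undersampler
        # is re-drawn per inner fit but, like a seeded sampler in a pipeline,
        # draws identically for identical fold data across the grid
        for j, (itr, ite) in enumerate(splits):
            rng = np.random.default_rng(np.random.SeedSequence([seed, k, j]))
            us = _undersample_indices(y_tr[itr], rng)
            Xu, yu = X_tr[itr][us], y_tr[itr][us]
            for pca_var in self.pca_variances:
                scaler, pca, mi, Xp = self._fit_transforms(Xu, yu, pca_var, seed)
                X_val = pca.transform(scaler.transform(X_tr[ite]))
                for ci, cfg in enumerate(configs):
                    if cfg["pca"] != pca_var:
                        continue
                    mask = _select_top_percentile(mi, cfg["percentile"])
                    est = _make_estimator(self.estimator, cfg["params"], seed)
                    est.fit(Xp[:, mask], yu)
                    scores[ci] += balanced_accuracy(
                        y_tr[ite], est.predict(X_val[:, mask])
                    )
        scores /= len(splits)
        return configs[int(np.argmax(scores))]  # ties: first config wins

    @staticmethod
    def _metrics(y_true, y_pred) -> dict:
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, pos_label=1, average="binary", zero_division=0
        )
        return {
            "accuracy": float(np.mean(y_true == y_pred)),
            "balanced_accuracy": balanced_accuracy(y_true, y_pred),
            "precision": float(precision),
            "recall": float(recall),
            "f1": float(f1),
        }


def nested_cv(
    features,
    labels,
    task,
    estimator_family: str = "svm_rbf",
    seed: int = 0,
    **kwargs,
) -> ClassificationResults:
    """Functional wrapper: build a :class:`TremorClassifier` and fit it."""
    model = TremorClassifier(
        features, labels, task, estimator=estimator_family, **kwargs
    )
    return model.fit(seed=seed)


# --------------------------------------------------------------------------
# bootstrap feature importance
# --------------------------------------------------------------------------

class ImportanceResult:
    """Bootstrap distribution of normalized split-gain importances."""

    def __init__(
        self,
        per_feature: pd.DataFrame,  # n_boot x n_features, rows sum to 1
        groups: dict[str, str],
    ) -> None:
        self.per_feature = per_feature
        self.groups = groups
        group_cols = {}
        for g in dict.fromkeys(groups.values()):
            members = [c for c in per_feature.columns if groups[c] == g]
            group_cols[g] = per_feature[members].sum(axis=1)
        self.per_group = pd.DataFrame(group_cols)

    def group_medians(self) -> pd.Series:
        return self.per_group.median().sort_values(ascending=False)

    def summary(self) -> str:
        med = self.group_medians()
        q1 = self.per_group.quantile(0.25)
        q3 = self.per_group.quantile(0.75)
        lines = [
            f"Bootstrap feature importance ({len(self.per_feature)} resamples)",
            f"{'group':<24}{'median':>8}{'IQR':>16}",
        ]
        for g, m in med.items():
            lines.append(f"{g:<24}{m:>8.3f}   [{q1[g]:.3f}, {q3[g]:.3f}]")
        return "\n".join(lines)


class BootstrapImportance:
    """Gradient-boosted-tree importance model over bootstrap resamples.

    For each resample the rows are drawn with replacement, the classes are
    balanced by undersampling, a boosted-tree classifier is fitted and its
    total split gain per feature, normalized to sum to one, is recorded.
    """

    def __init__(
        self,
        features,
        labels,
        task="disease_vs_healthy",
        groups: dict[str, str] | None = None,
        n_estimators: int = 150,
        max_depth: int = 4,
        learning_rate: float = 0.1,
    ) -> None:
        self.task = _resolve_task(task)
        if isinstance(features, pd.DataFrame):
            self.feature_names = list(features.columns)
        else:
            self.feature_names = [
                f"f{i}" for i in range(np.asarray(features).shape[1])
            ]
        X = np.asarray(features, dtype=float)
        mask, y = self.task.encode(labels)
        self.X, self.y = X[mask], y
        if groups is None:
            groups = {name: "features" for name in self.feature_names}
        self.groups = groups
        self.model_params = dict(
            n_estimators=n_estimators,
            max_depth=max_depth,
            learning_rate=learning_rate,
        )

    def fit(self, n_boot: int = 100, seed: int = 0) -> ImportanceResult:
        if n_boot < 2:
            raise ConfigurationError("n_boot must be at least 2")
        from lightgbm import LGBMClassifier

        n = self.X.shape[0]
        root = np.random.SeedSequence(seed)
        rows = np.zeros((n_boot, len(self.feature_names)))
        for b, child in enumerate(root.spawn(n_boot)):
            rng = np.random.default_rng(child)
            while True:  # re-draw degenerate single-class bootstraps
                idx = rng.integers(0, n, n)
                if np.unique(self.y[idx]).size == 2:
                    break
            us = _undersample_indices(self.y[idx], rng)
            Xb, yb = self.X[idx][us], self.y[idx][us]
            clf = LGBMClassifier(
                num_leaves=min(31, 2 ** self.model_params["max_depth"]),
                random_state=int(child.generate_state(1)[0] % (2**31 - 1)),
                n_jobs=1,
                verbose=-1,
                min_child_samples=5,
                **self.model_params,
            )
            clf.fit(Xb, yb)
            gains = clf.booster_.feature_importance(importance_type="gain")
            total = gains.sum()
            if total <= 0:
                warnings.warn(
                    "no informative splits in a bootstrap resample; "
                    "recording a uniform importance vector",
                    stacklevel=2,
                )
                rows[b] = 1.0 / len(self.feature_names)
            else:
                rows[b] = gains / total
        per_feature = pd.DataFrame(rows, columns=self.feature_names)
        return ImportanceResult(per_feature, self.groups)


def feature_importance(
    features,
    labels,
    n_boot: int = 100,
    seed: int = 0,
    task="disease_vs_healthy",
    groups: dict[str, str] | None = None,
    **model_params,
) -> ImportanceResult:
    """Functional wrapper over :class:`BootstrapImportance`."""
    model = BootstrapImportance(
        features, labels, task=task, groups=groups, **model_params
    )
    return model.fit(n_boot=n_boot, seed=seed)
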