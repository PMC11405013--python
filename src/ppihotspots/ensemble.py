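"""Stacked ensemble classifier with repeated k-fold bagging.

:class:`StackedEnsembleClassifier` is a scikit-learn estimator implementing
the multilayer-stacking recipe popularized by AutoML tabular frameworks:

* level-0 base learners are trained with repeated stratified k-fold bagging;
  their out-of-fold (OOF) predicted probabilities, averaged over repeats,
  become extra meta-features for the next layer;
* every higher layer repeats the scheme on ``[original features | previous
  OOF predictions]``;
* the output layer aggregates the last layer's learners by greedy forward
  ensemble selection (with replacement) maximizing the validation F1 score
  of hot-spot calls at the fixed probability threshold of 0.5.

Everything is deterministic per ``random_state``; predictions at inference
time average each learner's bagged fold models.  ``k_folds=1`` is the
degenerate no-bagging mode (each learner refit on all rows, in-sample OOF),
under which a single-learner single-layer configuration reduces exactly to
that learner.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from sklearn.utils.validation import check_is_fitted

HOTSPOT_THRESHOLD = 0.5  # calls are strictly greater-than

ID_COLUMNS = ("protein", "chain", "number", "icode")


def _make_learner(kind: str, seed: int, hyper: dict | None = None):
    hyper = hyper or {}
    if kind == "gradient-boosted-trees":
        return HistGradientBoostingClassifier(random_state=seed, **hyper)
    if kind == "random-forest":
        return RandomForestClassifier(n_estimators=120, random_state=seed, **hyper)
    if kind == "extremely-randomized-trees":
        return ExtraTreesClassifier(n_estimators=120, random_state=seed, **hyper)
    if kind == "k-nearest-neighbors":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(**(hyper or {"n_neighbors": 15})))
    if kind == "shallow-neural-net":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(32,), max_iter=500, random_state=seed, **hyper),
        )
    if kind == "logistic":
        return make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000, **hyper))
    raise ValueError(f"unknown learner kind {kind!r}")


LEARNER_KINDS = (
    "gradient-boosted-trees",
    "random-forest",
    "extremely-randomized-trees",
    "k-nearest-neighbors",
    "shallow-neural-net",
    "logistic",
)


@dataclass
class LearnerSpec:
    kind: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in LEARNER_KINDS:
            raise ValueError(f"learner kind {self.kind!r} not in registry {LEARNER_KINDS}")


@dataclass
class StackConfig:
    """Training-time knobs of the stack (selection metric is fixed: F1)."""

    layers: int = 2
    k_folds: int = 5
    repeats: int = 2
    seed: int = 0
    learners: tuple[str, ...] = LEARNER_KINDS

    def __post_init__(self):
        if self.layers < 1 or self.k_folds < 1 or self.repeats < 1:
            raise ValueError("layers, k_folds and repeats must be positive")


@dataclass
class CvReport:
    fold_f1: list[float]

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))


@dataclass
class ImportanceReport:
    """Permutation importance: mean F1 drop per feature, descending."""

    baseline_f1: float
    mean_drop: dict[str, float]
    sd_drop: dict[str, float]

    @property
    def ranking(self) -> list[str]:
        return sorted(self.mean_drop, key=lambda k: -self.mean_drop[k])


def _schema_hash(columns: list[str], dtypes: list[str]) -> str:
    payload = repr(list(zip(columns, dtypes))).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


class StackedEnsembleClassifier(BaseEstimator, ClassifierMixin):
    """Multilayer stacked ensemble for per-residue hot-spot classification.

    Parameters
    ----------
    learners : tuple of str
        Registry kinds of the base learners used at every layer.
    n_layers, k_folds, n_repeats : int
        Stack depth, folds per bagging pass and number of repeated k-fold
        passes.  ``k_folds=1`` disables bagging (degenerate mode).
    max_selection_rounds : int
        Cap on greedy forward-selection iterations in the output layer.
    random_state : int
        Master seed for fold shuffling and stochastic learners.
    """

    def __init__(
        self,
        learners: tuple[str, ...] = LEARNER_KINDS,
        n_layers: int = 2,
        k_folds: int = 5,
        n_repeats: int = 2,
        max_selection_rounds: int = 25,
        random_state: int = 0,
    ):
        self.learners = learners
        self.n_layers = n_layers
        self.k_folds = k_folds
        self.n_repeats = n_repeats
        self.max_selection_rounds = max_selection_rounds
        self.random_state = random_state

    # -- feature handling ---------------------------------------------------

    def _build_preprocessor(self, X: pd.DataFrame) -> ColumnTransformer:
        feat = [c for c in X.columns if c not in ID_COLUMNS]
        if not feat:
            raise ValueError("no feature columns after excluding identity columns")
        cat = [c for c in feat if X[c].dtype == object]
        num = [c for c in feat if c not in cat]
        return ColumnTransformer(
            [
                ("cat", OneHotEncoder(handle_unknown="ignore", sparse_output=False), cat),
                ("num", "passthrough", num),
            ]
        )

    def _validate_X(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X))
            X.columns = [str(c) for c in X.columns]
        return X

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        X = self._validate_X(X)
        y = np.asarray(y).astype(int).ravel()
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")
        if self.k_folds > 1 and len(y) < self.k_folds:
            raise ValueError(f"{len(y)} rows cannot be split into {self.k_folds} folds")
        for kind in self.learners:
            if kind not in LEARNER_KINDS:
                raise ValueError(f"unknown learner kind {kind!r}")
        self.classes_ = classes
        feat_cols = [c for c in X.columns if c not in ID_COLUMNS]
        self.feature_columns_ = feat_cols
        self.schema_hash_ = _schema_hash(feat_cols, [str(X[c].dtype) for c in feat_cols])

        self.preprocessor_ = self._build_preprocessor(X)
        Z0 = np.asarray(self.preprocessor_.fit_transform(X), dtype=float)
        Z = Z0
        self.layers_ = []
        for layer in range(self.n_layers):
            fitted_layer = {}
            oof_cols = []
            for li, kind in enumerate(self.learners):
                oof, models = self._bagged_oof(kind, Z, y, layer, li)
                fitted_layer[kind] = models
                oof_cols.append(oof)
            self.layers_.append(fitted_layer)
            oof_matrix = np.column_stack(oof_cols)
            if layer == self.n_layers - 1:
                self._select_ensemble(oof_matrix, y)
            Z = np.hstack([Z0, oof_matrix])
        return self

    def _bagged_oof(self, kind: str, Z: np.ndarray, y: np.ndarray, layer: int, li: int):
        """Out-of-fold probabilities (mean over repeats) and fitted models."""
        models = []
        if self.k_folds == 1:
            seed = self._seed_for(layer, li, 0)
            est = _make_learner(kind, seed)
            est.fit(Z, y)
            models.append(est)
            return self._proba1(est, Z), models
        oof_sum = np.zeros(len(y))
        for rep in range(self.n_repeats):
            skf = StratifiedKFold(
                n_splits=self.k_folds, shuffle=True,
                random_state=self._seed_for(layer, li, rep),
            )
            for tr, va in skf.split(Z, y):
                est = _make_learner(kind, self._seed_for(layer, li, rep))
                est.fit(Z[tr], y[tr])
                models.append(est)
                oof_sum[va] += self._proba1(est, Z[va])
        return oof_sum / self.n_repeats, models

    def _seed_for(self, layer: int, learner_idx: int, repeat: int) -> int:
        return (self.random_state * 9973 + layer * 389 + learner_idx * 53 + repeat * 7) % (2**31 - 1)

    @staticmethod
    def _proba1(est, Z: np.ndarray) -> np.ndarray:
        p = est.predict_proba(Z)
        idx = list(est.classes_).index(1)
        return p[:, idx]

    def _select_ensemble(self, oof: np.ndarray, y: np.ndarray) -> None:
        """Greedy forward selection with replacement (Caruana-style)."""

        def score(cols: list[int]) -> float:
            p = oof[:, cols].mean(axis=1)
            return f1_score(y, (p > HOTSPOT_THRESHOLD).astype(int), zero_division=0)

        singles = [score([j]) for j in range(oof.shape[1])]
        chosen = [int(np.argmax(singles))]
        best = singles[chosen[0]]
        for _ in range(self.max_selection_rounds - 1):
            cand = [score(chosen + [j]) for j in range(oof.shape[1])]
            j = int(np.argmax(cand))
            if cand[j] < best:
                break
            if cand[j] == best and all(c <= best for c in cand):
                break
            chosen.append(j)
            best = cand[j]
        counts = np.bincount(chosen, minlength=oof.shape[1]).astype(float)
        self.weights_ = counts / counts.sum()
        self.validation_f1_ = float(best)
        self.learner_validation_f1_ = dict(zip(self.learners, singles))

    # -- inference ----------------------------------------------------------

    def _meta_features(self, X: pd.DataFrame) -> np.ndarray:
        Z0 = np.asarray(self.preprocessor_.transform(X), dtype=float)
        Z = Z0
        for layer, fitted_layer in enumerate(self.layers_):
            cols = []
            for kind in self.learners:
                preds = [self._proba1(m, Z) for m in fitted_layer[kind]]
                cols.append(np.mean(preds, axis=0))
            last = np.column_stack(cols)
            Z = np.hstack([Z0, last])
        return last

    def _check_schema(self, X: pd.DataFrame) -> None:
        feat_cols = [c for c in X.columns if c not in ID_COLUMNS]
        h = _schema_hash(feat_cols, [str(X[c].dtype) for c in feat_cols])
        if h != self.schema_hash_:
            raise ValueError(
                f"feature schema mismatch: model expects {self.feature_columns_}, "
                f"got {feat_cols}"
            )

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "layers_")
        X = self._validate_X(X)
        self._check_schema(X)
        if len(X) == 0:
            return np.zeros((0, 2))
        last = self._meta_features(X)
        p1 = last @ self.weights_
        p1 = np.clip(p1, 0.0, 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        """Hot-spot call: probability strictly greater than 0.5."""
        p = self.predict_proba(X)
        if len(p) == 0:
            return np.zeros(0, dtype=int)
        return (p[:, 1] > HOTSPOT_THRESHOLD).astype(int)

    # -- persistence --------------------------------------------------------

    FORMAT_VERSION = 1

    def save(self, path: str) -> None:
        check_is_fitted(self, "layers_")
        payload = {
            "format": self.FORMAT_VERSION,
            "params": self.get_params(),
            "schema_hash": self.schema_hash_,
            "state": self.__dict__,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str) -> "StackedEnsembleClassifier":
        payload = joblib.load(path)
        if payload.get("format") != cls.FORMAT_VERSION:
            raise ValueError("unsupported model archive format")
        state = payload["state"]
        if payload["schema_hash"] != state.get("schema_hash_"):
            raise ValueError("schema hash mismatch in model archive")
        model = cls(**payload["params"])
        model.__dict__.update(state)
        return model


# ---------------------------------------------------------------------------
# functional wrappers


def train_stack(table: pd.DataFrame, labels, config: StackConfig | None = None) -> StackedEnsembleClassifier:
    config = config or StackConfig()
    model = StackedEnsembleClassifier(
        learners=tuple(config.learners),
        n_layers=config.layers,
        k_folds=config.k_folds,
        n_repeats=config.repeats,
        random_state=config.seed,
    )
    return model.fit(table, labels)


def predict_proba(model: StackedEnsembleClassifier, rows: pd.DataFrame) -> np.ndarray:
    return model.predict_proba(rows)[:, 1] if len(rows) else np.zeros(0)


def call_hotspots(model: StackedEnsembleClassifier, rows: pd.DataFrame) -> np.ndarray:
    return model.predict(rows)


def cross_validate(
    table: pd.DataFrame,
    labels,
    config: StackConfig | None = None,
    n_splits: int = 5,
    group_by_protein: bool = True,
) -> CvReport:
    """Stack-level cross-validation; folds never split a protein when
    grouping is enabled and a ``protein`` column is present."""
    config = config or StackConfig()
    y = np.asarray(labels).astype(int)
    if group_by_protein and "protein" in table.columns:
        splitter = GroupKFold(n_splits=n_splits)
        splits = splitter.split(table, y, groups=table["protein"])
    else:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=config.seed)
        splits = splitter.split(table, y)
    fold_f1 = []
    for tr, va in splits:
        model = train_stack(table.iloc[tr].reset_index(drop=True), y[tr], config)
        pred = model.predict(table.iloc[va].reset_index(drop=True))
        fold_f1.append(float(f1_score(y[va], pred, zero_division=0)))
    return CvReport(fold_f1=fold_f1)


def permutation_importance(
    model: StackedEnsembleClassifier,
    table: pd.DataFrame,
    labels,
    n_repeats: int = 5,
    seed: int = 0,
) -> ImportanceReport:
    """F1 drop when one feature column is shuffled across rows."""
    y = np.asarray(labels).astype(int)
    baseline = float(f1_score(y, model.predict(table), zero_division=0))
    rng = np.random.default_rng(seed)
    mean_drop, sd_drop = {}, {}
    for col in model.feature_columns_:
        drops = []
        for _ in range(n_repeats):
            shuffled = table.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            f1 = float(f1_score(y, model.predict(shuffled), zero_division=0))
            drops.append(baseline - f1)
        mean_drop[col] = float(np.mean(drops))
        sd_drop[col] = float(np.std(drops))
    return ImportanceReport(baseline_f1=baseline, mean_drop=mean_drop, sd_drop=sd_drop)
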