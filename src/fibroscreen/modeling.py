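"""Model construction: splitting, algorithm selection, iterative feature
elimination, final fitting and repositioning-score prediction.

The pipeline mirrors standard practice for screening models: 70% of the
QC-passed samples train the model, five candidate algorithms (logistic
regression with L1 and L2 penalties, decision tree, random forest,
gradient boosting) are compared by stratified 5-fold cross-validation, the
winner's feature set is pruned by iterative feature elimination (IFE), and
the final classifier — SPPM for structural features, BPPM for biological —
is validated on the held-out 30%.  A candidate's repositioning score is
the classifier's positive-class probability; scores at or above 0.5 are
labeled anti-fibrosis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupShuffleSplit, StratifiedKFold, StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    FibroscreenError,
    MissingFeatureError,
    ModalityError,
    StratificationError,
)
from .featurize import FeatureMatrix

__all__ = [
    "Dataset",
    "SplitConfig",
    "CandidateSpec",
    "CVResult",
    "FeatureRanking",
    "TrainedModel",
    "PredictionConfig",
    "ALGORITHMS",
    "default_candidate_specs",
    "split_train_test",
    "evaluate_candidates",
    "select_best",
    "iterative_feature_elimination",
    "fit_final",
    "evaluate_holdout",
    "predict_scores",
    "auc_score",
]

#: Fixed algorithm order; also the final tie-break in model selection.
ALGORITHMS = (
    "logistic_l1",
    "logistic_l2",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
)


@dataclass
class Dataset:
    """Aligned features, labels and optional per-sample group IDs."""

    X: pd.DataFrame
    y: pd.Series
    groups: Optional[pd.Series] = None

    def __post_init__(self):
        self.y = pd.Series(self.y)
        self.y.index = self.X.index
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            self.groups.index = self.X.index

    def __len__(self):
        return len(self.X)


@dataclass(frozen=True)
class SplitConfig:
    train_fraction: float = 0.70
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CandidateSpec:
    """One candidate algorithm with its (fixed, documented) hyperparameters."""

    algorithm: str
    hyperparameters: tuple = ()  # sorted (key, value) pairs; hashable
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    @property
    def params(self) -> dict:
        return dict(self.hyperparameters)


# Fixed defaults, sized for screening corpora of a few hundred to a few
# thousand samples.  The ensembles are kept small (50 trees; performance
# plateaus well before that on 166-bit fingerprints) and gradient boosting
# uses the stochastic variant (row subsampling + sqrt feature sampling),
# the common choice for high-dimensional fingerprint data; this also keeps
# the feature-elimination loop, which refits the model hundreds of times,
# affordable on one CPU.
_DEFAULTS: dict[str, dict] = {
    "logistic_l1": {"C": 1.0, "solver": "liblinear", "max_iter": 1000},
    "logistic_l2": {"C": 1.0, "solver": "liblinear", "max_iter": 1000},
    "decision_tree": {"max_depth": 5},
    "random_forest": {"n_estimators": 50, "min_samples_leaf": 5},
    "gradient_boosting": {
        "n_estimators": 50,
        "learning_rate": 0.2,
        "max_depth": 2,
        "subsample": 0.5,
        "max_features": "sqrt",
    },
}


def default_candidate_specs(seed: int = 0) -> list[CandidateSpec]:
    return [CandidateSpec(a, _DEFAULTS[a], seed=seed) for a in ALGORITHMS]


def build_estimator(spec: CandidateSpec):
    p = {**_DEFAULTS[spec.algorithm], **spec.params}
    if spec.algorithm == "logistic_l1":
        return LogisticRegression(l1_ratio=1.0, **p)
    if spec.algorithm == "logistic_l2":
        return LogisticRegression(l1_ratio=0.0, **p)
    if spec.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=spec.seed, **p)
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=spec.seed, **p)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=spec.seed, **p)
    raise ValueError(spec.algorithm)  # pragma: no cover


def _importances(estimator) -> np.ndarray:
    if hasattr(estimator, "coef_"):
        return np.abs(np.asarray(estimator.coef_)).ravel()
    return np.asarray(estimator.feature_importances_)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def auc_score(y_true, scores) -> float:
    """AUC as the Mann–Whitney pair statistic, ties counting one-half.

    Equals the probability that a uniformly random positive outscores a
    uniformly random negative, with ties worth 1/2.
    """
    y = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise FibroscreenError("AUC undefined: test set has a single class")
    r = stats.rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _threshold_metrics(y_true, scores, threshold=0.5):
    y = np.asarray(y_true).astype(int)
    pred = (np.asarray(scores) >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split_train_test(
    matrix, labels, config: SplitConfig = SplitConfig(), groups=None
) -> tuple[Dataset, Dataset]:
    """Split samples into train/test with stratification (and, when
    per-compound groups are given, keeping all samples of a compound on
    one side to avoid leakage).
    """
    X = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    y = pd.Series(labels)
    y.index = X.index
    if y.nunique() < 2 or y.value_counts().min() < 2:
        raise StratificationError("need >= 2 samples per class to split")
    n_train = int(round(config.train_fraction * len(X)))

    if groups is not None:
        g = pd.Series(groups)
        g.index = X.index
        for attempt in range(5):
            splitter = GroupShuffleSplit(
                n_splits=1,
                train_size=config.train_fraction,
                random_state=config.seed + attempt,
            )
            tr, te = next(splitter.split(X, y, g))
            if y.iloc[tr].nunique() == 2 and y.iloc[te].nunique() == 2:
                break
        else:
            raise StratificationError(
                "could not place both classes on both sides of a grouped split"
            )
    elif config.stratified:
        splitter = StratifiedShuffleSplit(
            n_splits=1, train_size=n_train, random_state=config.seed
        )
        try:
            tr, te = next(splitter.split(X, y))
        except ValueError as e:
            raise StratificationError(str(e)) from e
    else:
        rng = np.random.default_rng(config.seed)
        perm = rng.permutation(len(X))
        tr, te = perm[:n_train], perm[n_train:]
        if y.iloc[tr].nunique() < 2 or y.iloc[te].nunique() < 2:
            raise StratificationError("a class is absent from one side of the split")

    def subset(idx):
        return Dataset(
            X=X.iloc[idx],
            y=y.iloc[idx],
            groups=None if groups is None else pd.Series(groups, index=X.index).iloc[idx],
        )

    return subset(np.sort(tr)), subset(np.sort(te))


# ---------------------------------------------------------------------------
# Candidate evaluation and selection
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    spec: CandidateSpec
    precision: list[float]
    recall: list[float]
    auc: list[float]
    n_folds: int = 5

    @property
    def algorithm(self) -> str:
        return self.spec.algorithm

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.auc))

    @property
    def std_auc(self) -> float:
        return float(np.std(self.auc))

    @property
    def mean_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def mean_recall(self) -> float:
        return float(np.mean(self.recall))


def _make_folds(y: pd.Series, n_folds: int, seed: int):
    """Stratified folds; refolds with a new seed if a fold is single-class."""
    for attempt in range(5):
        kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed + attempt)
        folds = list(kf.split(np.zeros(len(y)), y))
        if all(
            y.iloc[tr].nunique() == 2 and y.iloc[te].nunique() == 2 for tr, te in folds
        ):
            return folds
    raise StratificationError("could not build folds with both classes present")


def _cv_fold_scores(X: np.ndarray, y: np.ndarray, spec: CandidateSpec, folds):
    """Fit on each fold; yield (auc, precision, recall, importances)."""
    for tr, te in folds:
        est = build_estimator(spec)
        est.fit(X[tr], y[tr])
        s = est.predict_proba(X[te])[:, 1]
        p, r = _threshold_metrics(y[te], s)
        yield auc_score(y[te], s), p, r, _importances(est)


def evaluate_candidates(
    train: Dataset,
    candidate_specs: Sequence[CandidateSpec] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> list[CVResult]:
    """Stratified k-fold CV of every candidate on the same fold partition."""
    specs = list(candidate_specs) if candidate_specs else default_candidate_specs(seed)
    y = _binarize(train.y)
    folds = _make_folds(y, n_folds, seed)
    Xa, ya = train.X.to_numpy(dtype=float), y.to_numpy()
    results = []
    for spec in specs:
        aucs, precs, recs = [], [], []
        for a, p, r, _ in _cv_fold_scores(Xa, ya, spec, folds):
            aucs.append(a)
            precs.append(p)
            recs.append(r)
        results.append(
            CVResult(spec=spec, precision=precs, recall=recs, auc=aucs, n_folds=n_folds)
        )
    return results


def select_best(cv_results: Sequence[CVResult]) -> CandidateSpec:
    """Pick the winner by mean CV AUC, then mean precision, then the fixed
    algorithm order."""
    if not cv_results:
        raise ValueError("no CV results to select from")
    ranked = sorted(
        cv_results,
        key=lambda r: (-r.mean_auc, -r.mean_precision, ALGORITHMS.index(r.algorithm)),
    )
    return ranked[0].spec


def _binarize(y: pd.Series) -> pd.Series:
    vals = sorted(pd.Series(y).unique().tolist())
    if set(vals) <= {0, 1}:
        return pd.Series(y).astype(int)
    if set(vals) == {"negative", "positive"}:
        return pd.Series(y).map({"negative": 0, "positive": 1})
    raise FibroscreenError(f"labels must be 0/1 or negative/positive, got {vals}")


# ---------------------------------------------------------------------------
# Iterative feature elimination
# ---------------------------------------------------------------------------


@dataclass
class FeatureRanking:
    elimination_order: list[str]          # first-eliminated first; survivor last
    cv_auc_by_subset_size: dict[int, float]
    optimal_subset: list[str]

    @property
    def max_cv_auc(self) -> float:
        return max(self.cv_auc_by_subset_size.values())


def _greedy_eliminate(X: np.ndarray, y: np.ndarray, spec: CandidateSpec,
                      eval_X=None, eval_y=None):
    """Greedy importance-guided elimination on one training set.

    Fits on (X, y) at every subset size, deletes the lowest-importance
    feature — absolute coefficient for logistic models, impurity
    importance for trees and ensembles.  Features with exactly zero
    importance are unused by the fitted model, so they are deleted
    together as tied lowest and the skipped sizes inherit the current
    score.  Returns (elimination order as column indices, {size: AUC}).
    AUC is scored on (eval_X, eval_y) when given (held-out fold), else
    it is not computed (scores dict stays empty).
    """
    n_features = X.shape[1]
    current = list(range(n_features))
    order: list[int] = []
    auc_by_size: dict[int, float] = {}

    while current:
        est = build_estimator(spec)
        est.fit(X[:, current], y)
        if eval_X is not None:
            s = est.predict_proba(eval_X[:, current])[:, 1]
            auc_by_size[len(current)] = auc_score(eval_y, s)
        if len(current) == 1:
            order.append(current[0])
            break
        imp = _importances(est)
        zero_idx = np.flatnonzero(imp == 0)
        if len(zero_idx) > 0:
            # drop all unused features at once; keep at least one feature
            drop_idx = list(zero_idx[: len(current) - 1])
            if eval_X is not None:
                cur_auc = auc_by_size[len(current)]
                for size in range(len(current) - 1, len(current) - len(drop_idx), -1):
                    auc_by_size[size] = cur_auc
        else:
            drop_idx = [int(np.argmin(imp))]
        for i in sorted(drop_idx, reverse=True):
            order.append(current[i])
            del current[i]

    return order, auc_by_size


def iterative_feature_elimination(
    train: Dataset,
    spec: CandidateSpec,
    n_folds: int = 5,
    seed: int = 0,
) -> FeatureRanking:
    """One-by-one feature deletion guided by model importance.

    The AUC-versus-subset-size curve is estimated with *nested* fold-wise
    elimination: each stratified fold runs its own greedy elimination
    using only that fold's training half and scores each subset size on
    its held-out half, and the curve is the fold average.  Deciding which
    features to drop strictly inside each fold keeps the curve honest —
    if the drop decisions saw the held-out samples, surviving features
    would be chance-correlated with them and the curve would drift above
    0.5 even on label-independent data (the classic feature-selection
    leak).  The optimal size is the smallest attaining the maximum of the
    averaged curve; the reported elimination order and optimal subset
    come from one further elimination pass on the full training set, so
    the final model uses all training information.
    """
    if train.X.shape[1] < 2:
        raise FibroscreenError("iterative feature elimination needs >= 2 features")
    y = _binarize(train.y)
    folds = _make_folds(y, n_folds, seed)
    Xa, ya = train.X.to_numpy(dtype=float), y.to_numpy()
    n_features = Xa.shape[1]

    fold_curves = []
    for tr, te in folds:
        _, curve = _greedy_eliminate(
            Xa[tr], ya[tr], spec, eval_X=Xa[te], eval_y=ya[te]
        )
        fold_curves.append(curve)
    auc_by_size = {
        size: float(np.mean([c[size] for c in fold_curves]))
        for size in range(1, n_features + 1)
    }

    order_idx, _ = _greedy_eliminate(Xa, ya, spec)
    order = [train.X.columns[i] for i in order_idx]

    best_auc = max(auc_by_size.values())
    best_size = min(s for s, a in auc_by_size.items() if a == best_auc)
    survivors = order[len(order) - best_size:]
    col_pos = {c: i for i, c in enumerate(train.X.columns)}
    optimal = sorted(survivors, key=col_pos.__getitem__)
    return FeatureRanking(
        elimination_order=order,
        cv_auc_by_subset_size=auc_by_size,
        optimal_subset=optimal,
    )


# ---------------------------------------------------------------------------
# Final model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionConfig:
    threshold: float = 0.5

    def __post_init__(self):
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class TrainedModel:
    """A fitted SPPM (structural) or BPPM (biological) repositioning model."""

    modality: str
    spec: CandidateSpec
    feature_ids: list[str]
    estimator: object
    metadata: dict = field(default_factory=dict)

    @property
    def name(self) -> str:
        return "SPPM" if self.modality == "structural" else "BPPM"

    # -- persistence -------------------------------------------------------
    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        joblib.dump(self.estimator, out / "estimator.joblib")
        (out / "features.txt").write_text("\n".join(self.feature_ids) + "\n")
        meta = {
            "modality": self.modality,
            "algorithm": self.spec.algorithm,
            "hyperparameters": self.spec.params,
            "seed": self.spec.seed,
            **self.metadata,
        }
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return out

    @classmethod
    def load(cls, model_dir) -> "TrainedModel":
        d = Path(model_dir)
        meta = json.loads((d / "metadata.json").read_text())
        spec = CandidateSpec(
            meta["algorithm"], meta["hyperparameters"], seed=meta.get("seed", 0)
        )
        features = (d / "features.txt").read_text().splitlines()
        extra = {
            k: v
            for k, v in meta.items()
            if k not in {"modality", "algorithm", "hyperparameters", "seed"}
        }
        return cls(
            modality=meta["modality"],
            spec=spec,
            feature_ids=[f for f in features if f],
            estimator=joblib.load(d / "estimator.joblib"),
            metadata=extra,
        )


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def fit_final(
    train: Dataset,
    spec: CandidateSpec,
    feature_subset: Sequence[str],
    modality: str = "structural",
    metadata: Optional[dict] = None,
) -> TrainedModel:
    """Fit the selected algorithm on the selected feature subset."""
    feature_subset = list(feature_subset)
    if not feature_subset:
        raise FibroscreenError("feature_subset must be nonempty")
    unknown = [f for f in feature_subset if f not in train.X.columns]
    if unknown:
        raise MissingFeatureError(unknown)
    y = _binarize(train.y)
    est = build_estimator(spec)
    est.fit(train.X[feature_subset].to_numpy(dtype=float), y.to_numpy())
    meta = dict(metadata or {})
    meta.setdefault("n_train", len(train))
    meta["config_hash"] = _config_hash(
        {
            "algorithm": spec.algorithm,
            "hyperparameters": spec.params,
            "seed": spec.seed,
            "features": feature_subset,
        }
    )
    return TrainedModel(
        modality=modality,
        spec=spec,
        feature_ids=feature_subset,
        estimator=est,
        metadata=meta,
    )


def evaluate_holdout(model: TrainedModel, test: Dataset, threshold: float = 0.5) -> dict:
    """AUC (Mann–Whitney, ties half), precision and recall on a holdout set."""
    y = _binarize(test.y)
    if y.nunique() < 2:
        raise FibroscreenError("AUC undefined: holdout set has a single class")
    s = model.estimator.predict_proba(
        test.X[model.feature_ids].to_numpy(dtype=float)
    )[:, 1]
    precision, recall = _threshold_metrics(y.to_numpy(), s, threshold)
    return {"auc": auc_score(y.to_numpy(), s), "precision": precision, "recall": recall}


def predict_scores(
    model: TrainedModel,
    features,
    config: PredictionConfig = PredictionConfig(),
) -> pd.DataFrame:
    """Score candidates with a trained model.

    Returns a DataFrame ``compound_id, score, label`` in input row order;
    a candidate is labeled ``anti_fibrosis`` when its repositioning score
    is at or above the threshold.
    """
    if isinstance(features, FeatureMatrix):
        if features.modality != model.modality:
            raise ModalityError(
                f"{features.modality} features given to a {model.modality} "
                f"model ({model.name})"
            )
        X = features.values
    else:
        X = features
    missing = [f for f in model.feature_ids if f not in X.columns]
    if missing:
        raise MissingFeatureError(missing)
    scores = model.estimator.predict_proba(
        X[model.feature_ids].to_numpy(dtype=float)
    )[:, 1]
    return pd.DataFrame(
        {
            "compound_id": list(X.index),
            "score": scores,
            "label": np.where(
                scores >= config.threshold, "anti_fibrosis", "non_anti_fibrosis"
            ),
        }
    )
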