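"""High-level modelling interface.

:class:`RepositioningModel` bundles the full training procedure — one-class
SVM quality control, stratified 70/30 split, 5-fold cross-validated
algorithm selection, iterative feature elimination, final fit — behind a
statsmodels-style ``Model.fit() -> Results`` pair.  The
:class:`RepositioningResults` object carries the trained SPPM/BPPM, the
cross-validation table, the feature-elimination curve and the holdout
metrics, and can score new candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .modeling import (
    CandidateSpec,
    CVResult,
    Dataset,
    FeatureRanking,
    PredictionConfig,
    SplitConfig,
    TrainedModel,
    default_candidate_specs,
    evaluate_candidates,
    evaluate_holdout,
    fit_final,
    iterative_feature_elimination,
    predict_scores,
    select_best,
    split_train_test,
)
from .qc import QCConfig, QCReport, ocsvm_filter

__all__ = ["RepositioningModel", "RepositioningResults"]


class RepositioningModel:
    """Anti-fibrosis repositioning classifier (SPPM or BPPM) to be fitted.

    Parameters
    ----------
    X : DataFrame
        Samples × features (MACCS bit columns or rank-transformed genes).
    y : sequence
        Binary labels (1/0 or "positive"/"negative"); positives are
        compounds present in the anti-fibrosis knowledge base.
    modality : "structural" | "biological"
    groups : optional per-sample compound IDs; when given, all profiles of
        one compound stay on the same side of the train/test split.
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        modality: str = "structural",
        groups=None,
        qc_config: Optional[QCConfig] = None,
        split_config: Optional[SplitConfig] = None,
        candidate_specs: Optional[Sequence[CandidateSpec]] = None,
        n_folds: int = 5,
        seed: int = 0,
    ):
        self.X = X
        self.y = pd.Series(y)
        self.y.index = X.index
        self.modality = modality
        self.groups = None if groups is None else pd.Series(groups, index=X.index)
        self.seed = seed
        self.qc_config = qc_config or QCConfig(seed=seed)
        self.split_config = split_config or SplitConfig(seed=seed)
        self.candidate_specs = (
            list(candidate_specs) if candidate_specs else default_candidate_specs(seed)
        )
        self.n_folds = n_folds

    @classmethod
    def from_corpus(cls, corpus, **kwargs) -> "RepositioningModel":
        """Build from a :class:`~fibroscreen.synthetic.SynthCorpus`."""
        return cls(
            X=corpus.matrix.values,
            y=corpus.labels,
            modality=corpus.matrix.modality,
            groups=corpus.groups,
            **kwargs,
        )

    def fit(self, run_ife: bool = True) -> "RepositioningResults":
        filtered, qc_report = ocsvm_filter(self.X, self.y, self.qc_config)
        y_kept = self.y.loc[filtered.index]
        g_kept = None if self.groups is None else self.groups.loc[filtered.index]
        train, test = split_train_test(filtered, y_kept, self.split_config, groups=g_kept)
        cv_results = evaluate_candidates(
            train, self.candidate_specs, n_folds=self.n_folds, seed=self.seed
        )
        best = select_best(cv_results)
        if run_ife:
            ranking = iterative_feature_elimination(
                train, best, n_folds=self.n_folds, seed=self.seed
            )
            subset = ranking.optimal_subset
        else:
            ranking = None
            subset = list(train.X.columns)
        model = fit_final(
            train,
            best,
            subset,
            modality=self.modality,
            metadata={"seed": self.seed, "n_features_input": self.X.shape[1]},
        )
        holdout = evaluate_holdout(model, test)
        return RepositioningResults(
            model=model,
            qc_report=qc_report,
            cv_results=cv_results,
            feature_ranking=ranking,
            holdout_metrics=holdout,
            train=train,
            test=test,
        )


@dataclass
class RepositioningResults:
    """Everything the fitting procedure produced, plus prediction."""

    model: TrainedModel
    qc_report: QCReport
    cv_results: list[CVResult]
    feature_ranking: Optional[FeatureRanking]
    holdout_metrics: dict
    train: Dataset
    test: Dataset
    prediction_config: PredictionConfig = field(default_factory=PredictionConfig)

    @property
    def holdout_auc(self) -> float:
        return self.holdout_metrics["auc"]

    def predict(self, features) -> pd.DataFrame:
        """Repositioning scores and anti-fibrosis labels for new candidates."""
        return predict_scores(self.model, features, self.prediction_config)

    def cv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "algorithm": r.algorithm,
                    "mean_auc": r.mean_auc,
                    "std_auc": r.std_auc,
                    "mean_precision": r.mean_precision,
                    "mean_recall": r.mean_recall,
                }
                for r in self.cv_results
            ]
        )

    def summary(self) -> str:
        lines = [
            f"{self.model.name} ({self.model.modality}) — "
            f"algorithm: {self.model.spec.algorithm}",
            f"QC removed fractions: "
            + ", ".join(
                f"{k}: {v:.3f}" for k, v in sorted(self.qc_report.removed_fraction.items())
            ),
            f"train/test sizes: {len(self.train)}/{len(self.test)}",
            "",
            "5-fold cross-validation (training set):",
            self.cv_table().to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
        ]
        if self.feature_ranking is not None:
            lines += [
                "",
                f"iterative feature elimination: optimal subset size "
                f"{len(self.feature_ranking.optimal_subset)} "
                f"(max CV AUC {self.feature_ranking.max_cv_auc:.3f})",
            ]
        h = self.holdout_metrics
        lines += [
            "",
            f"holdout: AUC {h['auc']:.3f}, precision {h['precision']:.3f}, "
            f"recall {h['recall']:.3f}",
        ]
        return "\n".join(lines)
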