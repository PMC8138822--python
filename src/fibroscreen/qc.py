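"""Sample quality control with a one-class support vector machine.

Before model construction, each labeled class is screened for outlying
samples with a one-class SVM (ν = 0.3 by default).  ν upper-bounds the
fraction of training samples that may fall outside the learned boundary,
so at most ~ν of each class is removed.  Fitting is per class by default:
a single boundary over both classes would conflate class structure with
sample quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .errors import QCError
from .featurize import FeatureMatrix

__all__ = ["QCConfig", "QCReport", "ocsvm_filter"]


@dataclass(frozen=True)
class QCConfig:
    """One-class SVM settings.

    The default radial-basis bandwidth is a *wide* variant of the median
    heuristic: gamma = 1/(10 x median squared pairwise distance).  A
    narrower kernel (e.g. the common 1/(d.Var) rule) leaves gross outliers
    many cloud-radii away sitting exactly on a self-supported boundary
    island with decision value 0, where they are not reliably flagged; the
    wide kernel keeps them in low-density territory.  Because the median
    distance scales with the data, the kept set is invariant to a uniform
    positive rescaling of the features.  ``gamma`` may also be "scale"
    (scikit-learn's 1/(d.Var)) or an explicit float.
    """

    nu: float = 0.3
    kernel: str = "rbf"
    gamma: object = "median-wide"
    bandwidth_factor: float = 10.0
    per_class: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.nu <= 1):
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")


def _median_wide_gamma(X: np.ndarray, factor: float, seed: int) -> float:
    """1 / (factor x median squared pairwise distance), on <= 200 rows."""
    from scipy.spatial.distance import pdist

    rng = np.random.default_rng(seed)
    idx = rng.choice(len(X), size=min(len(X), 200), replace=False)
    med = float(np.median(pdist(X[idx], "sqeuclidean")))
    return 1.0 / (factor * med) if med > 0 else 1.0


@dataclass
class QCReport:
    kept_ids: dict = field(default_factory=dict)      # class label -> list of sample IDs
    removed_ids: dict = field(default_factory=dict)   # class label -> list of sample IDs
    removed_fraction: dict = field(default_factory=dict)

    def all_kept(self) -> list:
        out = []
        for ids in self.kept_ids.values():
            out.extend(ids)
        return out

    def all_removed(self) -> list:
        out = []
        for ids in self.removed_ids.values():
            out.extend(ids)
        return out


_MIN_CLASS_SIZE = 10


def ocsvm_filter(matrix, labels, config: QCConfig = QCConfig()):
    """Remove outlier samples from each class with a one-class SVM.

    Parameters
    ----------
    matrix : FeatureMatrix or DataFrame
        Samples × features. Binary fingerprint rows are used as real
        vectors; rank profiles already live in [0, 1].
    labels : Series aligned with the matrix rows.
    config : QCConfig

    Returns
    -------
    (filtered, QCReport)
        ``filtered`` has the surviving rows in their original order; the
        report partitions every input sample into kept or removed.
    """
    df = matrix.values if isinstance(matrix, FeatureMatrix) else matrix
    y = pd.Series(labels)
    if len(y) != len(df):
        raise QCError(f"labels ({len(y)}) do not align with matrix rows ({len(df)})")
    y.index = df.index

    classes = sorted(y.unique().tolist())
    for cls in classes:
        n = int((y == cls).sum())
        if n < _MIN_CLASS_SIZE:
            raise QCError(
                f"class {cls!r} has {n} samples (< {_MIN_CLASS_SIZE}); "
                "outlier filtering would be unreliable"
            )

    report = QCReport()
    keep_mask = pd.Series(True, index=df.index)
    groups = [(cls, df[y == cls]) for cls in classes] if config.per_class else [
        ("all", df)
    ]
    for cls, sub in groups:
        arr = sub.to_numpy(dtype=float)
        gamma = (
            _median_wide_gamma(arr, config.bandwidth_factor, config.seed)
            if config.gamma == "median-wide"
            else config.gamma
        )
        model = OneClassSVM(nu=config.nu, kernel=config.kernel, gamma=gamma, tol=1e-8)
        pred = model.fit_predict(arr)
        inliers = pred == 1
        kept = list(sub.index[inliers])
        removed = list(sub.index[~inliers])
        report.kept_ids[cls] = kept
        report.removed_ids[cls] = removed
        report.removed_fraction[cls] = len(removed) / len(sub)
        keep_mask[removed] = False

    filtered_df = df[keep_mask]
    if isinstance(matrix, FeatureMatrix):
        filtered = FeatureMatrix(
            values=filtered_df,
            modality=matrix.modality,
            dropped_features=matrix.dropped_features,
        )
    else:
        filtered = filtered_df
    return filtered, report
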