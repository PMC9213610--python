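"""Sample-integrity checks: tissue clustering and out-of-bag classification.

Methylation profiles separate strongly by tissue (and species), so two
cheap checks catch platemap errors: average-linkage hierarchical clustering
on 1 − Pearson correlation distance, summarized as cluster purity, and a
random-forest out-of-bag error for tissue / sex labels.  On clean data both
should be near-perfect (purity ≈ 1, OOB error ≈ 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestClassifier

from .io_formats import MethylationMatrix


@dataclass
class QcReport:
    clustering_purity: dict[str, float] = field(default_factory=dict)
    oob_error: dict[str, float] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "clustering_purity": self.clustering_purity,
            "oob_error": self.oob_error,
            "parameters": self.parameters,
        }


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 − Pearson correlation between sample columns (probes × samples)."""
    ok = ~np.isnan(values).any(axis=1)
    corr = np.corrcoef(values[ok].T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


def cluster_purity(
    matrix: MethylationMatrix, labels, k: int | None = None
) -> float:
    """Purity of average-linkage correlation clustering cut at k clusters.

    purity = Σ_c max_label |cluster_c ∩ label| / n; 1.0 means every cluster
    is label-homogeneous.  k defaults to the number of distinct labels.
    """
    labels = list(labels)
    if len(labels) != matrix.n_samples:
        raise ValueError("one label per sample required")
    if k is None:
        k = len(set(labels))
    if matrix.n_samples < k:
        raise ValueError("fewer samples than clusters")
    if k == 1:
        return max(pd.Series(labels).value_counts()) / len(labels)
    dist = _correlation_distance(matrix.values)
    tree = linkage(squareform(dist, checks=False), method="average")
    assignment = fcluster(tree, t=k, criterion="maxclust")
    df = pd.DataFrame({"cluster": assignment, "label": labels})
    hits = df.groupby("cluster")["label"].agg(lambda s: s.value_counts().iloc[0]).sum()
    return float(hits) / len(labels)


def oob_classifier_error(
    matrix: MethylationMatrix, labels, n_trees: int = 500, seed: int = 0
) -> float:
    """Out-of-bag error of a random forest predicting the labels.

    Each tree is grown on a bootstrap sample; a sample's OOB prediction is
    the majority vote over trees whose bootstrap missed it.  Unrestricted
    depth, √p features per split.
    """
    labels = np.asarray(list(labels))
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 classes")
    if (counts < 3).any():
        small = counts[counts < 3].index.tolist()
        raise ValueError(f"class(es) with fewer than 3 samples: {small}")
    X = matrix.values.T
    keep = ~np.isnan(X).any(axis=0)
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, max_features="sqrt",
        bootstrap=True, random_state=seed, n_jobs=1,
    )
    clf.fit(X[:, keep], labels)
    return float(1.0 - clf.oob_score_)
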