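"""Nearest-neighbor prediction, jackknife evaluation and IFS.

The classifier is the plain nearest-neighbor algorithm (NNA) under the
cosine dissimilarity

    D(x, y) = 1 - <x, y> / (|x| * |y|),

which ranges over [0, 2]; a query takes the label of its closest
training sample, ties toward the lowest sample index.  Performance is
measured by jackknife (leave-one-out) cross-validation, summarized as
sensitivity, specificity, accuracy and Matthews correlation coefficient
(MCC).  Incremental feature selection (IFS) evaluates the jackknife on
growing prefixes of an mRMR-ranked feature list; the shortest prefix
attaining the maximum MCC is the optimal feature set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoder import FeatureMatrix, FeatureSchema
from .mrmr import RankedFeatures


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float


def nna_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine dissimilarity 1 - cos(a, b); raises on zero vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(1.0 - np.dot(a, b) / (na * nb))


def _cosine_distance_matrix(x: np.ndarray, q: np.ndarray | None = None) -> np.ndarray:
    """All-pairs cosine dissimilarity with a zero-norm convention.

    Rows with zero norm are assigned similarity 0 (distance 1) to every
    other row; this keeps batch evaluation defined when a small feature
    subset zeroes out a sample.
    """
    x = np.asarray(x, dtype=float)
    q = x if q is None else np.asarray(q, dtype=float)
    nx = np.linalg.norm(x, axis=1)
    nq = np.linalg.norm(q, axis=1)
    denom = np.outer(nq, nx)
    sim = q @ x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(denom > 0, sim / np.where(denom > 0, denom, 1.0), 0.0)
    return 1.0 - cos


def nna_predict(
    train: FeatureMatrix | np.ndarray,
    query: np.ndarray,
    labels: np.ndarray | None = None,
) -> int:
    """Label of the training sample nearest to ``query`` (ties: lowest index)."""
    if isinstance(train, FeatureMatrix):
        values, y = train.values, train.labels
    else:
        values = np.asarray(train, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        y = np.asarray(labels)
    if values.shape[0] == 0:
        raise ValueError("training set is empty")
    query = np.asarray(query, dtype=float)
    if query.shape != (values.shape[1],):
        raise ValueError(
            f"query dimension {query.shape} does not match "
            f"training dimension {values.shape[1]}"
        )
    dist = _cosine_distance_matrix(values, query[None, :])[0]
    return int(y[int(np.argmin(dist))])


def jackknife(
    matrix: FeatureMatrix | np.ndarray,
    feature_subset: np.ndarray | list[int],
    labels: np.ndarray | None = None,
) -> ConfusionCounts:
    """Leave-one-out NNA evaluation restricted to ``feature_subset``.

    Every sample is predicted by its nearest neighbor among all other
    samples; confusion counts are accumulated with the positive class
    coded 1.  Fully deterministic.
    """
    if isinstance(matrix, FeatureMatrix):
        values, y = matrix.values, matrix.labels
    else:
        values = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        y = np.asarray(labels)
    subset = np.asarray(feature_subset, dtype=np.int64)
    if subset.size == 0:
        raise ValueError("feature subset is empty")
    if values.shape[0] < 2:
        raise ValueError("jackknife needs at least 2 samples")
    x = values[:, subset]
    dist = _cosine_distance_matrix(x)
    np.fill_diagonal(dist, np.inf)
    pred = y[np.argmin(dist, axis=1)]
    return _confusion(y, pred)


def _confusion(y: np.ndarray, pred: np.ndarray) -> ConfusionCounts:
    y = np.asarray(y).astype(bool)
    pred = np.asarray(pred).astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & y)),
        tn=int(np.sum(~pred & ~y)),
        fp=int(np.sum(pred & ~y)),
        fn=int(np.sum(~pred & y)),
    )


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity, accuracy and MCC from confusion counts.

    Degenerate denominators follow the standard conventions: Sn (resp.
    Sp) is 0 when no positives (negatives) were evaluated; MCC is 0
    whenever any factor under the square root vanishes.
    """
    if c.total == 0:
        raise ValueError("no samples evaluated")
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    acc = (c.tp + c.tn) / c.total
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return Metrics(sn, sp, acc, mcc)


@dataclass
class IFSTable:
    """Jackknife metrics for each evaluated prefix of the ranking."""

    records: list[tuple[int, Metrics]]
    optimal_k: int

    @property
    def max_mcc(self) -> float:
        return max(m.mcc for _, m in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "k": k,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                    "mcc": m.mcc,
                }
                for k, m in self.records
            ]
        )


def ifs(
    matrix: FeatureMatrix | np.ndarray,
    ranked: RankedFeatures,
    labels: np.ndarray | None = None,
    stride: int = 1,
) -> IFSTable:
    """Incremental feature selection over an mRMR ranking.

    Prefix sizes k = stride, 2*stride, ... (always including the full
    set) are evaluated by jackknife NNA; ``optimal_k`` is the smallest
    evaluated k attaining the maximum MCC.  The Gram matrix of the
    growing prefix is updated incrementally, so a full stride-1 sweep
    costs O(N * n^2) rather than O(N^2 * n^2).
    """
    if isinstance(matrix, FeatureMatrix):
        values, y = matrix.values, matrix.labels
    else:
        values = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        y = np.asarray(labels)
    n_feat = values.shape[1]
    if len(ranked.order) != n_feat:
        raise ValueError(
            f"ranking covers {len(ranked.order)} features, matrix has {n_feat}"
        )
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ks = list(range(stride, n_feat + 1, stride))
    if not ks or ks[-1] != n_feat:
        ks.append(n_feat)

    yb = np.asarray(y).astype(bool)
    gram = np.zeros((values.shape[0], values.shape[0]))
    sq = np.zeros(values.shape[0])
    records: list[tuple[int, Metrics]] = []
    prev = 0
    for k in ks:
        cols = values[:, ranked.order[prev:k]]
        gram += cols @ cols.T
        sq += (cols * cols).sum(axis=1)
        prev = k
        norms = np.sqrt(sq)
        denom = np.outer(norms, norms)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, gram / np.where(denom > 0, denom, 1.0), 0.0)
        dist = 1.0 - cos
        np.fill_diagonal(dist, np.inf)
        pred = yb[np.argmin(dist, axis=1)]
        records.append((k, compute_metrics(_confusion(yb, pred))))
    best = max(m.mcc for _, m in records)
    optimal_k = next(k for k, m in records if m.mcc == best)
    return IFSTable(records, optimal_k)


@dataclass
class FeatureSetAnalysis:
    """Family-wise and site-wise composition of a feature subset."""

    counts_by_family: dict[str, int]
    counts_by_site: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts_by_family.values())


def analyze_feature_set(
    schema: FeatureSchema, subset: np.ndarray | list[int]
) -> FeatureSetAnalysis:
    """Count how a feature subset distributes over families and sites."""
    subset = np.asarray(subset, dtype=np.int64)
    if len(np.unique(subset)) != len(subset):
        raise ValueError("feature subset contains duplicate indices")
    if subset.size and (subset.min() < 0 or subset.max() >= len(schema)):
        raise ValueError("feature subset index out of schema range")
    from .encoder import FAMILIES  # late import to avoid cycle at module load

    by_family = {f: 0 for f in FAMILIES}
    by_site = {s: 0 for s in range(1, schema.window_length + 1)}
    for j in subset:
        d = schema[int(j)]
        by_family[d.family] += 1
        by_site[d.site] += 1
    return FeatureSetAnalysis(by_family, by_site)


# ---------------------------------------------------------------------------
# Serialization


def write_ifs_tsv(table: IFSTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_analysis_tsv(analysis: FeatureSetAnalysis, family_path, site_path) -> None:
    pd.DataFrame(
        {"family": list(analysis.counts_by_family),
         "count": list(analysis.counts_by_family.values())}
    ).to_csv(family_path, sep="\t", index=False)
    pd.DataFrame(
        {"site": list(analysis.counts_by_site),
         "count": list(analysis.counts_by_site.values())}
    ).to_csv(site_path, sep="\t", index=False)


def write_ranking_tsv(ranked: RankedFeatures, names: list[str], path) -> None:
    pd.DataFrame(
        {
            "round": np.arange(1, len(ranked.order) + 1),
            "feature": [names[j] for j in ranked.order],
            "column_index": ranked.order,
            "score": ranked.scores,
        }
    ).to_csv(path, sep="\t", index=False)
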