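"""Maximum-relevance minimum-redundancy (mRMR) feature ranking.

Features are ranked greedily: the first pick maximizes relevance, the
mutual information MI(f, c) between the (discretized) feature and the
class label; every later round picks the to-be-selected feature
maximizing

    MI(f, c) - (1/m) * sum over selected s of MI(f, s)      (difference form)

or MI(f, c) / ((1/m) * sum MI(f, s)) in the quotient variant.  The round
at which a feature is picked is its rank index h; a smaller h means a
better relevance/redundancy trade-off.

MI is the plug-in estimate over the empirical joint distribution, in
bits.  Continuous columns are discretized per column before estimation;
the default rule maps values below mean - k*sigma, within, and above
mean + k*sigma to three states (k = 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import FeatureMatrix

SCHEME_THREE_STATE = "three-state-mean-sigma"
SCHEME_EQUAL_FREQUENCY = "equal-frequency"
SCHEME_NONE = "none"

VARIANT_DIFFERENCE = "mid"
VARIANT_QUOTIENT = "miq"


@dataclass(frozen=True)
class DiscretizationRule:
    """Per-column discretization applied before MI estimation.

    ``three-state-mean-sigma``: thresholds at mean +/- parameter * sigma
    (default parameter 1.0).  ``equal-frequency``: parameter quantile
    bins.  ``none``: values are already categorical.
    """

    scheme: str = SCHEME_THREE_STATE
    parameter: float = 1.0

    def __post_init__(self) -> None:
        if self.scheme not in (
            SCHEME_THREE_STATE,
            SCHEME_EQUAL_FREQUENCY,
            SCHEME_NONE,
        ):
            raise ValueError(f"unknown discretization scheme {self.scheme!r}")


def discretize(column: np.ndarray, rule: DiscretizationRule) -> np.ndarray:
    """Map one feature column to small nonnegative integer categories."""
    x = np.asarray(column, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("column contains non-finite values")
    if rule.scheme == SCHEME_NONE:
        _, codes = np.unique(x, return_inverse=True)
        return codes.astype(np.int64)
    if rule.scheme == SCHEME_THREE_STATE:
        mu = x.mean()
        sigma = x.std()
        if sigma == 0.0:
            return np.zeros(len(x), dtype=np.int64)
        lo = mu - rule.parameter * sigma
        hi = mu + rule.parameter * sigma
        out = np.ones(len(x), dtype=np.int64)
        out[x <= lo] = 0
        out[x >= hi] = 2
        return out
    # equal-frequency
    k = int(rule.parameter)
    if k < 2:
        raise ValueError("equal-frequency needs parameter >= 2 bins")
    qs = np.quantile(x, np.linspace(0, 1, k + 1)[1:-1])
    return np.searchsorted(qs, x, side="left").astype(np.int64)


def entropy(x: np.ndarray) -> float:
    """Shannon entropy of a discrete vector, in bits."""
    _, counts = np.unique(np.asarray(x), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits.

    Symmetric and nonnegative; equals H(x) when y determines x.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(
            f"x and y must be equal-length 1-D vectors, got {x.shape} / {y.shape}"
        )
    n = len(x)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = xi.max() + 1
    ny = yi.max() + 1
    counts = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    joint = counts / n
    # marginals from integer counts: exact before the single division
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    mi = 0.0
    for a in range(nx):
        for b in range(ny):
            p = joint[a, b]
            if p > 0:
                mi += p * np.log2(p / (px[a] * py[b]))
    return float(max(mi, 0.0))


@dataclass
class RankedFeatures:
    """Full mRMR ordering of a feature set.

    ``order[h-1]`` is the column selected at round h; ``round_index[j]``
    is the round at which column j was selected (1-based); ``scores[h-1]``
    is the criterion value of the winning feature at round h.
    """

    order: np.ndarray
    round_index: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.int64)
        self.round_index = np.asarray(self.round_index, dtype=np.int64)
        self.scores = np.asarray(self.scores, dtype=float)
        n = len(self.order)
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValueError("order must be a permutation of all column indices")
        if sorted(self.round_index.tolist()) != list(range(1, n + 1)):
            raise ValueError("round_index must cover rounds 1..N exactly once")


def mrmr_rank(
    matrix: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    rule: DiscretizationRule = DiscretizationRule(),
    variant: str = VARIANT_DIFFERENCE,
) -> RankedFeatures:
    """Rank all features by greedy mRMR forward selection.

    Ties at any round are broken toward the lowest original column
    index.  The ordering is invariant to the row order of the input.
    """
    if isinstance(matrix, FeatureMatrix):
        values = matrix.values
        y = matrix.labels
    else:
        values = np.asarray(matrix, dtype=float)
        if labels is None:
            raise ValueError("labels required when passing a bare array")
        y = np.asarray(labels)
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 1:
        raise ValueError("need >= 2 samples and >= 1 feature")
    if len(np.unique(y)) < 2:
        raise ValueError("label vector is constant; relevance is undefined")
    if variant not in (VARIANT_DIFFERENCE, VARIANT_QUOTIENT):
        raise ValueError(f"unknown mRMR variant {variant!r}")

    n_feat = values.shape[1]
    disc = np.empty_like(values, dtype=np.int64)
    for j in range(n_feat):
        disc[:, j] = discretize(values[:, j], rule)

    relevance = np.array(
        [mutual_information(disc[:, j], y) for j in range(n_feat)]
    )
    redundancy_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    order: list[int] = []
    scores: list[float] = []
    for _round in range(n_feat):
        m = len(order)
        if m == 0:
            crit = relevance.copy()
        else:
            mean_red = redundancy_sum / m
            if variant == VARIANT_DIFFERENCE:
                crit = relevance - mean_red
            else:
                with np.errstate(divide="ignore"):
                    crit = np.where(
                        mean_red > 0, relevance / mean_red, np.inf
                    )
        crit = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit))  # argmax returns the first (lowest) index
        order.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        if remaining.any():
            sel = disc[:, best]
            for j in np.flatnonzero(remaining):
                redundancy_sum[j] += mutual_information(disc[:, j], sel)
    round_index = np.empty(n_feat, dtype=np.int64)
    for h, j in enumerate(order, start=1):
        round_index[j] = h
    return RankedFeatures(np.array(order), round_index, np.array(scores))
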