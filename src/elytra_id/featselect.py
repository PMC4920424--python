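"""Feature selection: mRMR ranking and correlation-based subset search.

Minimum-redundancy maximum-relevance (mRMR) greedily ranks features by
mutual information with the class label penalized (MID, difference) or
divided (MIQ, quotient) by mean mutual information with already selected
features.  Correlation-based feature selection (CFS) searches for a subset
maximizing the merit

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where k = |S|, r_cf is the mean feature-class correlation and r_ff the mean
feature-feature correlation, both measured as symmetric uncertainty on
discretized values.  Continuous features are discretized (default: ternary
z-threshold at +-1 sigma, the classic mRMR convention) before any
information measure is computed.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ANNConfig, loso_cv
from .datasets import SpecimenDataset

_EPS = 1e-12


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous features become discrete states.

    ``zscore`` maps each feature to three states (below -t*sigma, within,
    above +t*sigma); ``quantile`` uses equal-frequency bins.
    """

    method: str = "zscore"
    t: float = 1.0
    bins: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("zscore", "quantile"):
            raise ValueError("method must be 'zscore' or 'quantile'")
        if self.bins < 2:
            raise ValueError("need at least 2 states per feature")


def discretize(X: np.ndarray, spec: DiscretizationSpec | None = None) -> np.ndarray:
    """Column-wise discretization to small integer states."""
    if spec is None:
        spec = DiscretizationSpec()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    out = np.empty(X.shape, dtype=np.int64)
    if spec.method == "zscore":
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        lo = mu - spec.t * sd
        hi = mu + spec.t * sd
        out = (X > lo[None, :]).astype(np.int64) + (X > hi[None, :]).astype(np.int64)
    else:
        for j in range(X.shape[1]):
            qs = np.quantile(X[:, j], np.linspace(0, 1, spec.bins + 1)[1:-1])
            out[:, j] = np.searchsorted(qs, X[:, j], side="right")
    return out


def _encode(v: np.ndarray) -> tuple[np.ndarray, int]:
    _, codes = np.unique(v, return_inverse=True)
    return codes, int(codes.max()) + 1 if codes.size else 0


def mutual_information(x, y) -> float:
    """Mutual information (bits) of two discrete vectors.

    Computed exactly from the joint empirical distribution; always >= 0.
    """
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    if x.size == 0:
        return 0.0
    cx, nx = _encode(x)
    cy, ny = _encode(y)
    joint = np.bincount(cx * ny + cy, minlength=nx * ny).reshape(nx, ny).astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nzmask = joint > 0
    mi = (joint[nzmask] * np.log2(joint[nzmask] / (px @ py)[nzmask])).sum()
    return max(float(mi), 0.0)


def _entropy(codes: np.ndarray) -> float:
    p = np.bincount(codes).astype(float)
    p = p[p > 0] / codes.size
    return float(-(p * np.log2(p)).sum())


def symmetric_uncertainty(x, y) -> float:
    """SU(x, y) = 2 I(x; y) / (H(x) + H(y)), in [0, 1]."""
    cx, _ = _encode(np.asarray(x).ravel())
    cy, _ = _encode(np.asarray(y).ravel())
    hx, hy = _entropy(cx), _entropy(cy)
    if hx + hy == 0:
        return 0.0
    return 2.0 * mutual_information(cx, cy) / (hx + hy)


@dataclass
class SelectionResult:
    """Outcome of a selection run.

    For mRMR, ``features`` is the rank-ordered list of selected column
    names and ``scores`` the per-step criterion values; for CFS the list is
    an unordered subset and ``scores`` traces the best merit per step.
    """

    method: str
    features: list = field(default_factory=list)
    scores: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"method": self.method, "features": list(self.features),
                "scores": [float(s) for s in self.scores]}


def mrmr_select(
    matrix: pd.DataFrame,
    labels,
    k: int = 50,
    scheme: str = "MID",
    disc: DiscretizationSpec | None = None,
) -> SelectionResult:
    """Greedy mRMR ranking of ``k`` features.

    The first pick maximizes relevance I(f; c); subsequent picks maximize
    I(f; c) - mean_i I(f; f_i) (MID) or I(f; c) / mean_i I(f; f_i) (MIQ)
    over features f_i already selected.  Ties break toward the lower column
    index, so the ranking is deterministic given the discretized matrix.
    """
    scheme = scheme.upper()
    if scheme not in ("MID", "MIQ"):
        raise ValueError("scheme must be 'MID' or 'MIQ'")
    X = np.asarray(matrix, dtype=float)
    names = (list(matrix.columns) if hasattr(matrix, "columns")
             else list(range(X.shape[1])))
    n_feat = X.shape[1]
    if not 1 <= k <= n_feat:
        raise ValueError(f"k must lie in [1, {n_feat}]")
    D = discretize(X, disc)
    y = np.asarray(labels)

    relevance = np.array([mutual_information(D[:, j], y) for j in range(n_feat)])
    selected: list[int] = []
    scores: list[float] = []
    redundancy_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)

    first = int(np.argmax(relevance))
    selected.append(first)
    scores.append(float(relevance[first]))
    remaining[first] = False

    pair_mi = np.zeros((n_feat, n_feat))
    computed = np.zeros((n_feat, n_feat), dtype=bool)

    while len(selected) < k:
        last = selected[-1]
        idx = np.flatnonzero(remaining)
        for j in idx:
            if not computed[last, j]:
                pair_mi[last, j] = pair_mi[j, last] = mutual_information(D[:, last], D[:, j])
                computed[last, j] = computed[j, last] = True
        redundancy_sum[idx] += pair_mi[last, idx]
        mean_red = redundancy_sum[idx] / len(selected)
        if scheme == "MID":
            crit = relevance[idx] - mean_red
        else:
            crit = relevance[idx] / np.maximum(mean_red, _EPS)
        best = idx[int(np.argmax(crit))]
        selected.append(int(best))
        scores.append(float(crit[int(np.argmax(crit))]))
        remaining[best] = False

    return SelectionResult(method=f"mRMR-{scheme}",
                           features=[names[j] for j in selected],
                           scores=scores)


def cfs_merit(subset, su_fc: np.ndarray, su_ff: np.ndarray) -> float:
    """CFS merit of a feature subset from precomputed SU tables."""
    subset = list(subset)
    k = len(subset)
    if k == 0:
        return 0.0
    rcf = float(su_fc[subset].mean())
    if k == 1:
        return rcf
    pairs = [su_ff[i, j] for i, j in itertools.combinations(subset, 2)]
    rff = float(np.mean(pairs))
    return k * rcf / np.sqrt(k + k * (k - 1) * rff)


def cfs_select(
    matrix: pd.DataFrame,
    labels,
    direction: str = "forward",
    disc: DiscretizationSpec | None = None,
    stale_limit: int = 5,
) -> SelectionResult:
    """Correlation-based subset selection via best-first search.

    Forward search starts from the empty set and adds features; backward
    starts from the full set and removes them.  Expansion stops after
    ``stale_limit`` consecutive non-improving expansions.  The returned
    subset is unordered (reported in column order).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    X = np.asarray(matrix, dtype=float)
    names = (list(matrix.columns) if hasattr(matrix, "columns")
             else list(range(X.shape[1])))
    n_feat = X.shape[1]
    if n_feat < 1:
        raise ValueError("need at least one feature")
    D = discretize(X, disc)
    y = np.asarray(labels)

    su_fc = np.array([symmetric_uncertainty(D[:, j], y) for j in range(n_feat)])
    su_ff = np.zeros((n_feat, n_feat))
    for i, j in itertools.combinations(range(n_feat), 2):
        su_ff[i, j] = su_ff[j, i] = symmetric_uncertainty(D[:, i], D[:, j])

    start = frozenset() if direction == "forward" else frozenset(range(n_feat))
    start_merit = cfs_merit(start, su_fc, su_ff)
    best_subset, best_merit = start, start_merit
    frontier: list[tuple[float, int, frozenset]] = [(-start_merit, 0, start)]
    visited = {start}
    stale = 0
    counter = itertools.count(1)
    trace = [best_merit]

    while frontier and stale < stale_limit:
        _, _, subset = heapq.heappop(frontier)
        if direction == "forward":
            children = [subset | {j} for j in range(n_feat) if j not in subset]
        else:
            children = [subset - {j} for j in subset]
        improved = False
        for child in children:
            if child in visited or not child:
                continue
            visited.add(child)
            merit = cfs_merit(child, su_fc, su_ff)
            heapq.heappush(frontier, (-merit, next(counter), child))
            if merit > best_merit + _EPS:
                best_merit, best_subset = merit, child
                improved = True
        trace.append(best_merit)
        stale = 0 if improved else stale + 1

    subset_sorted = sorted(best_subset)
    return SelectionResult(method=f"CFS-{direction}",
                           features=[names[j] for j in subset_sorted],
                           scores=trace)


def topk_eval(
    dataset: SpecimenDataset,
    ranked: SelectionResult,
    ks=(5, 10, 15, 20, 25, 30, 35, 40, 45, 50),
    rounds: int = 10,
    cfg: ANNConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """LOSO-CV accuracy of the top-K ranked features for each K.

    Returns a DataFrame indexed by K with the CV mean and std, reusing the
    classification module's protocol on the restricted column set.
    """
    rows = {}
    for k in ks:
        cols = list(ranked.features[:k])
        sub = SpecimenDataset(features=dataset.features[cols],
                              labels=dataset.labels, groups=dataset.groups)
        res = loso_cv(sub, feature_set="all", rounds=rounds, cfg=cfg, seed=seed)
        rows[k] = {"accuracy_mean": res.overall_accuracy,
                   "accuracy_std": res.overall_std}
    out = pd.DataFrame(rows).T
    out.index.name = "k"
    return out
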