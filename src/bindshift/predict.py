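"""Predicting future TF occupancy at motif matches from prior-state data.

Given genome-wide motif matches and ChIP-seq read tracks collected in a
*preceding* cellular state, this module builds per-position feature
matrices (reads-per-million in 500-bp windows), rank-combines motif
similarity with prior-state occupancy, traces true-positive versus
additional-prediction curves, averages per-base conservation, and runs
a repeated-holdout RBF-kernel SVM harness reporting mean ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_auc_score
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .reads import ReadDataset

__all__ = [
    "FeatureMatrix",
    "Ranking",
    "CurvePoint",
    "ClassifierResult",
    "extract_features",
    "rank_by_collection",
    "combine_rankings",
    "tp_additional_curve",
    "average_conservation",
    "train_occupancy_classifier",
]


@dataclass
class FeatureMatrix:
    """Rows = genomic positions, columns = experiments (RPM in a window)."""

    positions: list[tuple[str, int]]
    values: pd.DataFrame  # index aligned with positions
    collections: dict[str, list[str]] = field(default_factory=dict)
    window: int = 500
    normalization: str = "reads-per-million"

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and value rows must align")
        if (self.values.values < 0).any():
            raise ValueError("feature values must be non-negative")

    def columns_for(self, collection: str) -> list[str]:
        if collection not in self.collections:
            raise ValueError(f"unknown collection {collection!r}")
        cols = self.collections[collection]
        if not cols:
            raise ValueError(f"collection {collection!r} is empty")
        return cols


def extract_features(
    positions: list[tuple[str, int]],
    datasets: dict[str, ReadDataset],
    window: int = 500,
    collections: dict[str, list[str]] | None = None,
) -> FeatureMatrix:
    """Reads-per-million counts in a window centred on each position.

    Counts reads whose 5' position falls in [pos - w/2, pos + w/2) and
    divides by (total mapped reads / 1e6) per experiment, so doubling
    an experiment's depth uniformly leaves its column unchanged.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    data: dict[str, np.ndarray] = {}
    for name, ds in datasets.items():
        col = np.zeros(len(positions))
        per_chrom = {c: ds.subset(c)[0] for c in ds.chroms()}
        scale = 1.0 if ds.total == 0 else 1e6 / ds.total
        for i, (chrom, pos) in enumerate(positions):
            arr = per_chrom.get(chrom)
            if arr is None:
                continue
            col[i] = (np.searchsorted(arr, pos + half) - np.searchsorted(arr, pos - half)) * scale
        data[name] = col
    values = pd.DataFrame(data, index=range(len(positions)))
    return FeatureMatrix(
        positions=list(positions),
        values=values,
        collections=collections or {"all": list(datasets)},
        window=window,
    )


@dataclass
class Ranking:
    """Rank-normalised scores in [0, 1] (1 = best), mean-rank ties."""

    positions: list[tuple[str, int]]
    scores: np.ndarray  # in [0, 1]
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.positions) != self.scores.size:
            raise ValueError("positions and scores must align")
        if self.scores.size and (self.scores.min() < -1e-12 or self.scores.max() > 1 + 1e-12):
            raise ValueError("rank scores must lie in [0, 1]")

    def order(self) -> np.ndarray:
        """Indices best-first; ties broken by original position order."""
        return np.lexsort((np.arange(self.scores.size), -self.scores))


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """(rank - 1) / (N - 1) with mean ranks for ties; single value -> 1."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n == 0:
        return values
    if n == 1:
        return np.ones(1)
    return (rankdata(values, method="average") - 1.0) / (n - 1.0)


def rank_by_collection(matrix: FeatureMatrix, collection: str) -> Ranking:
    """Rank positions by summed normalised counts over a collection."""
    cols = matrix.columns_for(collection)
    sums = matrix.values[cols].sum(axis=1).to_numpy()
    return Ranking(matrix.positions, rank_normalize(sums), raw=sums)


def combine_rankings(r1: Ranking, r2: Ranking) -> Ranking:
    """Multiply two rank scores per position and re-rank the product."""
    if r1.positions != r2.positions:
        raise ValueError("rankings must share a position list")
    product = r1.scores * r2.scores
    return Ranking(r1.positions, rank_normalize(product), raw=product)


@dataclass(frozen=True)
class CurvePoint:
    cutoff: int
    true_positives: int
    additional: int


def tp_additional_curve(
    ranking: Ranking, truth: set[tuple[str, int]]
) -> list[CurvePoint]:
    """Walk the ranking best-first, counting hits and additional calls.

    At cutoff k, ``true_positives`` is |top-k intersect truth| and
    ``additional`` = k - TP (predicted-bound positions not actually
    bound).
    """
    unknown = truth - set(ranking.positions)
    if unknown:
        raise ValueError("truth positions must be a subset of the ranking")
    order = ranking.order()
    is_true = np.array([ranking.positions[i] in truth for i in order])
    tp = np.cumsum(is_true)
    return [
        CurvePoint(k + 1, int(tp[k]), int(k + 1 - tp[k])) for k in range(order.size)
    ]


def additional_at_tp(curve: list[CurvePoint], tp_target: int) -> int | None:
    """Additional predictions at the first cutoff reaching ``tp_target``."""
    for pt in curve:
        if pt.true_positives >= tp_target:
            return pt.additional
    return None


def average_conservation(
    positions: list[tuple[str, int]],
    track: dict[str, np.ndarray],
    window: int = 20,
) -> np.ndarray:
    """Mean per-base conservation in [pos - w/2, pos + w/2); missing = 0."""
    half = window // 2
    out = np.zeros(len(positions))
    for i, (chrom, pos) in enumerate(positions):
        arr = track.get(chrom)
        if arr is None:
            continue
        lo, hi = pos - half, pos + half
        vals = np.zeros(hi - lo)
        a, b = max(lo, 0), min(hi, arr.size)
        if b > a:
            vals[a - lo : b - lo] = arr[a:b]
        out[i] = float(vals.mean())
    return out


@dataclass(frozen=True)
class ClassifierResult:
    mean_auc: float
    sd_auc: float
    repeats: int
    holdout_pos: int
    holdout_neg: int
    standardized: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def train_occupancy_classifier(
    features: FeatureMatrix,
    bound: list[tuple[str, int]],
    unbound: list[tuple[str, int]],
    n_pos: int = 500,
    n_neg: int = 10_000,
    holdout: tuple[int, int] = (50, 50),
    repeats: int = 100,
    seed: int = 0,
    standardize: bool = True,
) -> ClassifierResult:
    """Repeated-holdout RBF-kernel SVM bound/unbound classification.

    Per repeat, 50 bound and 50 unbound positions are held out, a
    C-classification SVM with RBF kernel (library defaults) is trained
    on the remainder — features standardised by training-set mean/SD —
    and held-out decision values are scored by ROC-AUC.  Reports mean
    and SD over ``repeats`` repeats, deterministic under the seed.
    """
    index = {p: i for i, p in enumerate(features.positions)}
    try:
        pos_idx = np.array([index[p] for p in bound])
        neg_idx = np.array([index[p] for p in unbound])
    except KeyError as exc:  # pragma: no cover - misuse guard
        raise ValueError(f"position {exc.args[0]} missing from the feature matrix") from exc
    rng = np.random.default_rng(seed)
    if pos_idx.size > n_pos:
        pos_idx = rng.choice(pos_idx, size=n_pos, replace=False)
    if neg_idx.size > n_neg:
        neg_idx = rng.choice(neg_idx, size=n_neg, replace=False)
    h_pos, h_neg = holdout
    if h_pos >= pos_idx.size or h_neg >= neg_idx.size:
        raise ValueError("holdout exceeds the available sites")
    X = features.values.to_numpy()
    aucs = np.empty(repeats)
    for r in range(repeats):
        test_pos = rng.choice(pos_idx, size=h_pos, replace=False)
        test_neg = rng.choice(neg_idx, size=h_neg, replace=False)
        train_pos = np.setdiff1d(pos_idx, test_pos)
        train_neg = np.setdiff1d(neg_idx, test_neg)
        Xtr = np.vstack([X[train_pos], X[train_neg]])
        ytr = np.concatenate([np.ones(train_pos.size), np.zeros(train_neg.size)])
        Xte = np.vstack([X[test_pos], X[test_neg]])
        yte = np.concatenate([np.ones(h_pos), np.zeros(h_neg)])
        if standardize:
            scaler = StandardScaler().fit(Xtr)
            Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
        clf = SVC(kernel="rbf").fit(Xtr, ytr)
        aucs[r] = roc_auc_score(yte, clf.decision_function(Xte))
    return ClassifierResult(
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if repeats > 1 else 0.0,
        repeats=repeats,
        holdout_pos=h_pos,
        holdout_neg=h_neg,
        standardized=standardize,
    )
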