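"""Consensus-score threshold calibration.

Negative examples are built by degree-preserving random rewiring (double-edge
swaps) of the gold-standard DDI edge set; positives and negatives that carry a
nonzero consensus score form the learning set.  The score threshold is then
chosen by 5-fold cross-validated F1 over a three-phase grid (coarse 0.01
steps over [0, 1], then 0.001 steps over [0, 0.04], then 0.0001 steps over
[0.01, 0.02]); the mean of the per-fold optima, T_m, filters the consensus
matrix: entries are kept iff score > T_m, strictly.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Set
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from .core import DDIKey
from .errors import CalibrationError

logger = logging.getLogger(__name__)


@dataclass
class LearningSet:
    positives: set[DDIKey]
    negatives: set[DDIKey]
    scores: dict[DDIKey, float]


@dataclass
class ThresholdResult:
    fold_thresholds: list[float]
    fold_f1s: list[float]
    t_m: float
    f1_train: float
    f1_test: float
    precision_test: float
    recall_test: float


def shuffle_negatives(positives: Set[DDIKey], seed: int,
                      max_tries: int = 100_000) -> set[DDIKey]:
    """Degree-preserving rewiring of the positive edge set.

    Repeated double-edge swaps preserve every domain's degree (a homo-DDI
    contributes 2 to its domain) while forbidding (a) edges identical to an
    original positive, (b) duplicate edges, and (c) newly created self-edges.
    Original edges that cannot be rewired within ``max_tries`` proposals are
    dropped from the output with a logged count.  Deterministic given ``seed``.
    """
    pos = set(positives)
    if len(pos) < 2:
        raise CalibrationError("degree-preserving shuffle needs at least 2 positive edges")
    rng = np.random.default_rng(seed)
    edges: list[DDIKey] = sorted(pos)
    current = set(edges)
    n = len(edges)

    def propose(i: int, j: int) -> bool:
        (a, b), (c, d) = edges[i], edges[j]
        # two swap orientations; try them in seeded random order
        options = [((a, c), (b, d)), ((a, d), (b, c))]
        if rng.random() < 0.5:
            options.reverse()
        for (p1, q1), (p2, q2) in options:
            e1: DDIKey = (p1, q1) if p1 <= q1 else (q1, p1)
            e2: DDIKey = (p2, q2) if p2 <= q2 else (q2, p2)
            # no new self-edges unless the swap recombines an existing self-edge
            if (e1[0] == e1[1] and a != b and c != d) or (e2[0] == e2[1] and a != b and c != d):
                continue
            if e1 == e2 or e1 in pos or e2 in pos:
                continue
            if e1 in current or e2 in current:
                continue
            current.discard(edges[i])
            current.discard(edges[j])
            edges[i], edges[j] = e1, e2
            current.add(e1)
            current.add(e2)
            return True
        return False

    tries = 0
    # mixing phase: uniform random swaps
    n_mix = 10 * n
    while tries < min(n_mix, max_tries):
        i, j = rng.integers(0, n, size=2)
        tries += 1
        if i != j:
            propose(int(i), int(j))
    # repair phase: target edges still identical to an original positive
    while tries < max_tries:
        stale = [i for i, e in enumerate(edges) if e in pos]
        if not stale:
            break
        i = int(rng.choice(stale))
        j = int(rng.integers(0, n))
        tries += 1
        if i != j:
            propose(i, j)
    result = {e for e in edges if e not in pos}
    n_dropped = n - len(result)
    if n_dropped:
        logger.warning("shuffle: dropped %d original edge(s) that could not be rewired",
                       n_dropped)
    if not result:
        raise CalibrationError("shuffle produced no valid negative edges")
    return result


def build_learning_set(positives: Set[DDIKey], shuffled: Set[DDIKey],
                       consensus: Mapping[DDIKey, float]) -> LearningSet:
    """Keep only positives/negatives that carry a nonzero consensus score."""
    if not shuffled:
        raise CalibrationError("empty shuffled negative set")
    neg = {k for k in shuffled if k not in positives and consensus.get(k, 0.0) > 0.0}
    pos = {k for k in positives if consensus.get(k, 0.0) > 0.0}
    if not pos:
        raise CalibrationError("no gold-standard positive has a nonzero consensus score")
    logger.info("learning set: %d/%d positives and %d/%d negatives scored",
                len(pos), len(positives), len(neg), len(shuffled))
    scores = {k: float(consensus[k]) for k in pos | neg}
    return LearningSet(positives=pos, negatives=neg, scores=scores)


def precision_recall_f1(labels: Mapping[DDIKey, str], scores: Mapping[DDIKey, float],
                        t: float) -> tuple[float, float, float]:
    """P/R/F1 when predicting positive iff score > t (strict)."""
    tp = fp = fn = 0
    for key, lab in labels.items():
        pred = scores[key] > t
        if lab == "pos":
            tp += pred
            fn += not pred
        else:
            fp += pred
    p = tp / (tp + fp) if (tp + fp) else 0.0
    r = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def threshold_grid() -> np.ndarray:
    """Sorted union of the three grid phases (in units of 1e-4 internally)."""
    ticks = set(range(0, 10001, 100))          # 0.00..1.00 step 0.01
    ticks.update(range(0, 401, 10))            # 0.00..0.04 step 0.001
    ticks.update(range(100, 201, 1))           # 0.01..0.02 step 0.0001
    return np.array(sorted(ticks)) / 10000.0


def _metrics_at(scores: np.ndarray, y: np.ndarray, t: float) -> tuple[float, float, float]:
    pred = scores > t
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    p = tp / (tp + fp) if (tp + fp) else 0.0
    r = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


def best_grid_threshold(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """F1-maximizing grid threshold; ties break toward the smallest threshold."""
    grid = threshold_grid()
    best_t, best_f1 = grid[0], -1.0
    for t in grid:
        f1 = _metrics_at(scores, y, float(t))[2]
        if f1 > best_f1:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


def select_threshold_cv(ls: LearningSet, k: int = 5, train_fraction: float = 2 / 3,
                        seed: int = 0) -> ThresholdResult:
    """Stratified Train/Test split + k-fold CV threshold selection.

    For each fold, the F1-optimal grid threshold is fit on the other k-1
    folds and verified on the held-out fold; the mean T_m of the per-fold
    optima is evaluated on the whole Training set and on the untouched Test
    set.  All randomness is driven by ``seed``.
    """
    keys = sorted(ls.scores)
    y = np.array([key in ls.positives for key in keys])
    if int(y.sum()) < k or int((~y).sum()) < k:
        raise CalibrationError(
            f"{k}-fold calibration needs >= {k} scored positives and negatives "
            f"(got {int(y.sum())} / {int((~y).sum())})")
    s = np.array([ls.scores[key] for key in keys])

    idx = np.arange(len(keys))
    train_idx, test_idx = train_test_split(
        idx, train_size=train_fraction, stratify=y, random_state=seed)
    s_train, y_train = s[train_idx], y[train_idx]
    s_test, y_test = s[test_idx], y[test_idx]
    if int(y_train.sum()) < k or int((~y_train).sum()) < k:
        raise CalibrationError(
            f"training subset too small to stratify into {k} folds "
            f"({int(y_train.sum())} positives / {int((~y_train).sum())} negatives)")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ts: list[float] = []
    fold_f1s: list[float] = []
    for fit_idx, val_idx in skf.split(s_train.reshape(-1, 1), y_train):
        t, _ = best_grid_threshold(s_train[fit_idx], y_train[fit_idx])
        fold_ts.append(t)
        fold_f1s.append(_metrics_at(s_train[val_idx], y_train[val_idx], t)[2])
    t_m = float(np.mean(fold_ts))
    f1_train = _metrics_at(s_train, y_train, t_m)[2]
    p_test, r_test, f1_test = _metrics_at(s_test, y_test, t_m)
    logger.info("calibration: fold thresholds %s -> T_m=%.5f, F1(train)=%.4f, "
                "F1(test)=%.4f", [f"{t:.4f}" for t in fold_ts], t_m, f1_train, f1_test)
    return ThresholdResult(fold_thresholds=fold_ts, fold_f1s=fold_f1s, t_m=t_m,
                           f1_train=f1_train, f1_test=f1_test,
                           precision_test=p_test, recall_test=r_test)


def select_threshold_simple(ls: LearningSet) -> ThresholdResult:
    """Single F1-optimal grid threshold on the whole learning set.

    Fallback for learning sets too small to cross-validate; the train and
    test metrics then both refer to the full set.
    """
    keys = sorted(ls.scores)
    y = np.array([key in ls.positives for key in keys])
    s = np.array([ls.scores[key] for key in keys])
    t, _ = best_grid_threshold(s, y)
    p, r, f1 = _metrics_at(s, y, t)
    return ThresholdResult(fold_thresholds=[t], fold_f1s=[f1], t_m=t, f1_train=f1,
                           f1_test=f1, precision_test=p, recall_test=r)


def filter_matrix(consensus: Mapping[DDIKey, float], t_m: float) -> dict[DDIKey, float]:
    """Keep consensus entries with score strictly greater than t_m."""
    return {k: v for k, v in consensus.items() if v > t_m}
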