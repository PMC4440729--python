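"""Tolerant-match evaluation of detected conversational groups.

A ground-truth group G of cardinality |G| counts as correctly detected
by a detected group D when at least ``ceil(T * |G|)`` of its members
are found and no more than ``ceil((1 - T) * |G|)`` false subjects are
included, for a tolerance threshold T in [1/2, 1].  T = 1 is exact set
equality; T = 2/3 is the customary "two thirds found, at most one
third false" regime.  Matching between truth and detected groups is
one-to-one.

From per-frame true positives / false positives / false negatives the
module derives micro-averaged precision, recall and F1, the Global
Tolerant Matching score (GTM: normalised area under the F1-vs-T curve
on the grid T in {1/2, 2/3, 5/6, 1}), and F1 stratified by group
cardinality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import GroupSet

__all__ = [
    "MatchResult",
    "GTM_GRID",
    "tolerant_match",
    "precision_recall_f1",
    "micro_scores",
    "gtm",
    "cardinality_f1",
    "cardinality_summary",
]

# "3 equal steps" from 1/2 to 1: step 1/6.
GTM_GRID: tuple[float, ...] = (1 / 2, 2 / 3, 5 / 6, 1.0)


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching detected against ground-truth groups."""

    T: float
    tp: int
    fp: int
    fn: int
    matched_pairs: tuple[tuple[frozenset, frozenset], ...] = ()


def _is_match(truth_group: frozenset, detected_group: frozenset, T: float) -> bool:
    found = len(truth_group & detected_group)
    false_subjects = len(detected_group - truth_group)
    need = math.ceil(T * len(truth_group))
    allowed_false = math.ceil((1.0 - T) * len(truth_group))
    return found >= need and false_subjects <= allowed_false


def _group_key(g: frozenset) -> list[str]:
    return sorted(repr(i) for i in g)


def tolerant_match(detected: GroupSet, truth: GroupSet, T: float) -> MatchResult:
    """Match detected groups to ground-truth groups at tolerance ``T``.

    Matching is one-to-one and greedy by descending intersection size
    (ties broken towards the lexicographically smallest truth group).
    Detected singletons are never candidate groups — ground truth only
    contains groups of cardinality >= 2.
    """
    if not (0.5 <= T <= 1.0):
        raise ValueError(f"tolerance T must lie in [1/2, 1], got {T}")
    truth_groups = sorted(truth.groups, key=_group_key)
    det_groups = sorted(detected.groups, key=_group_key)

    candidates = []
    for ti, tg in enumerate(truth_groups):
        for di, dg in enumerate(det_groups):
            if _is_match(tg, dg, T):
                candidates.append((-len(tg & dg), ti, di))
    candidates.sort()

    matched_t: set[int] = set()
    matched_d: set[int] = set()
    pairs: list[tuple[frozenset, frozenset]] = []
    for _, ti, di in candidates:
        if ti in matched_t or di in matched_d:
            continue
        matched_t.add(ti)
        matched_d.add(di)
        pairs.append((truth_groups[ti], det_groups[di]))

    tp = len(pairs)
    return MatchResult(
        T=T,
        tp=tp,
        fp=len(det_groups) - tp,
        fn=len(truth_groups) - tp,
        matched_pairs=tuple(pairs),
    )


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and F1 from match counts.

    Empty denominators follow the vacuous-truth convention: with no
    detected and no truth groups all three scores are 1, so empty
    frames are neutral under micro-averaging.
    """
    return _prf(m.tp, m.fp, m.fn)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    f1 = (
        2.0 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return precision, recall, f1


def micro_scores(
    detected_per_frame: Sequence[GroupSet],
    truth_per_frame: Sequence[GroupSet],
    T: float,
) -> tuple[float, float, float]:
    """Micro-averaged precision/recall/F1 over a list of frames.

    Counts are summed over frames before forming the ratios, so every
    group carries equal weight regardless of frame crowding.
    """
    if len(detected_per_frame) != len(truth_per_frame):
        raise ValueError("detected and truth frame lists differ in length")
    tp = fp = fn = 0
    for det, tru in zip(detected_per_frame, truth_per_frame):
        m = tolerant_match(det, tru, T)
        tp, fp, fn = tp + m.tp, fp + m.fp, fn + m.fn
    return _prf(tp, fp, fn)


def gtm(
    detected_per_frame: Sequence[GroupSet],
    truth_per_frame: Sequence[GroupSet],
) -> float:
    """Global Tolerant Matching score.

    Normalised area under the dataset-level F1-vs-T curve on the grid
    T in {1/2, 2/3, 5/6, 1} (trapezoidal rule over [1/2, 1], divided
    by the interval length 1/2), so a detector with constant F1 = c
    scores exactly c.
    """
    f1s = [
        micro_scores(detected_per_frame, truth_per_frame, T)[2] for T in GTM_GRID
    ]
    area = float(np.trapezoid(f1s, GTM_GRID))
    return area / (GTM_GRID[-1] - GTM_GRID[0])


def cardinality_f1(
    detected_per_frame: Sequence[GroupSet],
    truth_per_frame: Sequence[GroupSet],
    k: int,
    T: float,
) -> float | None:
    """F1 restricted to ground-truth groups of cardinality ``k``.

    True positives are matched truth groups of size k; false negatives
    the unmatched ones; false positives the detected groups of size k
    left unmatched by the global matching.  Returns ``None`` when no
    truth or detected group of size k exists (the stratum is absent).
    """
    if k < 2:
        raise ValueError("group cardinality is at least 2")
    if len(detected_per_frame) != len(truth_per_frame):
        raise ValueError("detected and truth frame lists differ in length")
    tp = fn = fp = 0
    present = False
    for det, tru in zip(detected_per_frame, truth_per_frame):
        m = tolerant_match(det, tru, T)
        matched_truth = {p[0] for p in m.matched_pairs}
        matched_det = {p[1] for p in m.matched_pairs}
        truth_k = [g for g in tru.groups if len(g) == k]
        det_k = [g for g in det.groups if len(g) == k]
        if truth_k or det_k:
            present = True
        tp += sum(1 for g in truth_k if g in matched_truth)
        fn += sum(1 for g in truth_k if g not in matched_truth)
        fp += sum(1 for g in det_k if g not in matched_det)
    if not present:
        return None
    return _prf(tp, fp, fn)[2]


def cardinality_summary(
    detected_per_frame: Sequence[GroupSet],
    truth_per_frame: Sequence[GroupSet],
    T: float,
) -> tuple[dict[int, float], float, float]:
    """Per-cardinality F1 plus mean and standard deviation.

    Considers every cardinality present in the ground truth; the
    mean/std are taken across the per-cardinality F1 values.
    """
    ks = sorted(
        {len(g) for tru in truth_per_frame for g in tru.groups}
        | {len(g) for det in detected_per_frame for g in det.groups}
    )
    per_k = {}
    for k in ks:
        f1 = cardinality_f1(detected_per_frame, truth_per_frame, k, T)
        if f1 is not None:
            per_k[k] = f1
    vals = np.array(list(per_k.values()), dtype=float)
    if vals.size == 0:
        return per_k, float("nan"), float("nan")
    return per_k, float(vals.mean()), float(vals.std(ddof=0))
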