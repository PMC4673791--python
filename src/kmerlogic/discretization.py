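"""Supervised discretization of k-mer frequencies into half-open intervals.

Rule learners operate on interval conditions such as ``lo <= f(W) < hi``.
The cut points defining those intervals come from recursive minimum
description length partitioning (MDLP): sort the values of one feature,
consider midpoints between adjacent distinct values at class boundaries,
take the cut minimizing the class-entropy of the split, and accept it only
when its information gain beats the MDL cost of encoding the split; recurse
into both sides. Features whose best cut fails the test get no cuts at all
and collapse to a single (uninformative) interval.

The interval convention is half-open everywhere: value v falls in interval
i iff ``cuts[i-1] <= v < cuts[i]``, so a value exactly equal to a cut
belongs to the interval above it.

An unsupervised equal-frequency splitter is provided for experiments on the
number of intervals; it is not used by the default pipeline.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .errors import ParameterError, ValidationError


def _entropy(label_counts: np.ndarray) -> float:
    n = label_counts.sum()
    if n == 0:
        return 0.0
    p = label_counts[label_counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdlp_accepts(
    total: np.ndarray, left: np.ndarray, right: np.ndarray
) -> bool:
    """Fayyad-Irani MDL stopping criterion for one candidate cut."""
    n = int(total.sum())
    e = _entropy(total)
    e1 = _entropy(left)
    e2 = _entropy(right)
    gain = e - (left.sum() / n) * e1 - (right.sum() / n) * e2
    c = int((total > 0).sum())
    c1 = int((left > 0).sum())
    c2 = int((right > 0).sum())
    delta = math.log2(3**c - 2) - (c * e - c1 * e1 - c2 * e2)
    threshold = (math.log2(n - 1) + delta) / n
    return gain > threshold


def _recurse(values: np.ndarray, labels: np.ndarray, n_classes: int, cuts: list[float]) -> None:
    """values sorted ascending; labels are integer codes aligned with values."""
    n = len(values)
    if n < 2:
        return
    # group by distinct value; candidate cuts sit between adjacent groups
    # whose pooled labels are not a single shared pure class (boundary points)
    distinct, starts = np.unique(values, return_index=True)
    if len(distinct) < 2:
        return
    bounds = list(starts[1:]) + [n]
    group_counts = []
    pos = 0
    for b in bounds:
        counts = np.bincount(labels[pos:b], minlength=n_classes)
        group_counts.append(counts)
        pos = b
    group_counts = np.array(group_counts)
    prefix = np.cumsum(group_counts, axis=0)
    total = prefix[-1]

    best = None  # (weighted entropy, cut value, split position, group index)
    for g in range(len(distinct) - 1):
        cg, cn = group_counts[g], group_counts[g + 1]
        # skip non-boundary midpoints: both groups pure with the same class
        if cg.sum() == cg.max() and cn.sum() == cn.max():
            if int(np.argmax(cg)) == int(np.argmax(cn)):
                continue
        left = prefix[g]
        right = total - left
        w = (left.sum() / n) * _entropy(left) + (right.sum() / n) * _entropy(right)
        cut = (float(distinct[g]) + float(distinct[g + 1])) / 2.0
        if best is None or w < best[0] - 1e-12 or (abs(w - best[0]) <= 1e-12 and cut < best[1]):
            best = (w, cut, int(bounds[g]), g)
    if best is None:
        return
    _, cut, split_at, g_best = best
    left_counts = prefix[g_best]
    right_counts = total - left_counts
    if not _mdlp_accepts(total, left_counts, right_counts):
        return
    cuts.append(cut)
    _recurse(values[:split_at], labels[:split_at], n_classes, cuts)
    _recurse(values[split_at:], labels[split_at:], n_classes, cuts)


def mdl_discretize(values: Sequence[float], labels: Sequence) -> list[float]:
    """MDLP cut points for one feature; possibly empty, strictly increasing.

    Candidate cuts are midpoints between consecutive distinct sorted values
    at class-boundary positions; the entropy-minimizing cut is accepted iff
    its information gain exceeds the MDL threshold, then both sides are
    partitioned recursively.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape[0] != labels.shape[0]:
        raise ValidationError(
            f"values ({values.shape[0]}) and labels ({labels.shape[0]}) differ in length"
        )
    if values.shape[0] == 0:
        return []
    _, label_codes = np.unique(labels, return_inverse=True)
    n_classes = int(label_codes.max()) + 1
    if n_classes < 2:
        return []
    order = np.argsort(values, kind="stable")
    cuts: list[float] = []
    _recurse(values[order], label_codes[order], n_classes, cuts)
    return sorted(cuts)


def equal_frequency_discretize(values: Sequence[float], n_intervals: int) -> list[float]:
    """Cut points at the 1/n .. (n-1)/n empirical quantiles, deduplicated.

    Cuts equal to or below the minimum (or above the maximum) value are
    dropped, so constant features yield no cuts.
    """
    if n_intervals < 2:
        raise ParameterError(f"n_intervals must be >= 2, got {n_intervals}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return []
    qs = np.arange(1, n_intervals) / n_intervals
    cuts = np.quantile(values, qs)
    vmin, vmax = float(values.min()), float(values.max())
    out: list[float] = []
    for c in cuts:
        c = float(c)
        if c <= vmin or c > vmax:
            continue
        if not out or c > out[-1]:
            out.append(c)
    return out


def apply_cutpoints(values, cuts: Sequence[float]):
    """Map value(s) to half-open interval indices: v in i iff cuts[i-1] <= v < cuts[i].

    Monotone: v1 <= v2 implies interval(v1) <= interval(v2); with empty cuts
    everything maps to interval 0.
    """
    cuts = np.asarray(list(cuts), dtype=float)
    scalar = np.isscalar(values) or getattr(values, "ndim", 1) == 0
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    idx = np.searchsorted(cuts, arr, side="right")
    return int(idx[0]) if scalar else idx


def fit_cutpoints(
    X: np.ndarray,
    labels: Sequence,
    method: str = "mdl",
    n_intervals: int = 3,
) -> list[list[float]]:
    """Per-feature cut points for a (n_features x n_samples) matrix slice."""
    if method == "mdl":
        return [mdl_discretize(X[i], labels) for i in range(X.shape[0])]
    if method == "equal_frequency":
        return [equal_frequency_discretize(X[i], n_intervals) for i in range(X.shape[0])]
    raise ParameterError(f"unknown discretizer {method!r}")
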