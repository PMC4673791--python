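"""PART-style rule extraction: repeated pruned decision trees to rules.

Builds a pruned C4.5-style decision tree on the training data, converts
its best leaf — the one covering the most samples — into a rule, removes
the covered samples, and repeats until no samples remain or the tree
degenerates to a single leaf. The result is an ordered decision list whose
default class is the majority of the residual samples.

Trees split binarily at the interval boundaries produced by supervised
(MDLP) discretization: each candidate split tests ``f(W) >= cut``.
Attributes are chosen by gain ratio; exact ties fall to the split with the
widest empty data gap around its cut (best expected generalization), then
to the lexicographically smaller k-mer. Trees are pruned by replacing
subtrees with leaves whenever the pessimistic error estimate (binomial
upper confidence bound, default confidence 0.25) does not get worse.
Features whose discretization produced no cuts can never be split on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .discretization import fit_cutpoints
from .errors import ParameterError, ValidationError
from .kmer_features import FeatureMatrix
from .ripper import _majority, attach_coverage
from .rules import INF, Literal, Rule, RuleModel


def _add_errs(n: float, e: float, cf: float) -> float:
    """Pessimistic additional errors for a leaf with n samples and e errors."""
    if cf >= 1.0:
        return 0.0
    if e == 0:
        return n * (1.0 - cf ** (1.0 / n))
    if e + 0.5 >= n:
        return max(n - e, 0.0)
    z = float(norm.ppf(1.0 - cf))
    f = (e + 0.5) / n
    r = (f + z * z / (2 * n) + z * np.sqrt(f / n - f * f / n + z * z / (4 * n * n))) / (
        1 + z * z / n
    )
    return r * n - e


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def cut_margins(values: np.ndarray, cuts: list[list[float]]) -> dict[tuple[int, int], float]:
    """Empty-gap width around each (feature, cut) on the training values."""
    margins: dict[tuple[int, int], float] = {}
    for fi, clist in enumerate(cuts):
        if not clist:
            continue
        v = np.sort(values[fi])
        for ci, c in enumerate(clist):
            below = v[v < c]
            above = v[v >= c]
            if len(below) and len(above):
                margins[(fi, ci)] = float(above[0] - below[-1])
            else:
                margins[(fi, ci)] = 0.0
    return margins


@dataclass
class _Node:
    counts: np.ndarray
    split: tuple[int, int] | None = None  # (feature, cut index); None -> leaf
    low: "_Node | None" = None
    high: "_Node | None" = None

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def majority(self) -> int:
        return int(np.argmax(self.counts))

    @property
    def errors(self) -> int:
        return self.n - int(self.counts.max())

    def to_leaf(self) -> None:
        self.split = None
        self.low = self.high = None


class _TreeContext:
    def __init__(self, values, y, cuts, margins, n_classes, min_leaf):
        self.values = values  # (n_features, n_samples) raw values
        self.y = y
        self.cuts = cuts
        self.margins = margins
        self.n_classes = n_classes
        self.min_leaf = min_leaf


def _build(ctx: _TreeContext, idx: np.ndarray, used: frozenset) -> _Node:
    counts = np.bincount(ctx.y[idx], minlength=ctx.n_classes)
    node = _Node(counts=counts)
    n = len(idx)
    if n < 2 * ctx.min_leaf or counts.max() == n:
        return node
    parent_entropy = _entropy(counts)
    best = None  # ((ratio, margin, -fi), (fi, ci), high_mask)
    for fi in range(ctx.values.shape[0]):
        clist = ctx.cuts[fi]
        if not clist:
            continue
        v = ctx.values[fi, idx]
        for ci, cut in enumerate(clist):
            if (fi, ci) in used:
                continue
            high = v >= cut
            n_high = int(high.sum())
            if n_high < ctx.min_leaf or n - n_high < ctx.min_leaf:
                continue
            c_high = np.bincount(ctx.y[idx[high]], minlength=ctx.n_classes)
            c_low = counts - c_high
            child = (n_high / n) * _entropy(c_high) + ((n - n_high) / n) * _entropy(c_low)
            gain = parent_entropy - child
            if gain <= 1e-9:
                continue
            split_info = _entropy(np.array([n_high, n - n_high]))
            if split_info <= 0:
                continue
            ratio = gain / split_info
            margin = ctx.margins.get((fi, ci), 0.0)
            if (
                best is None
                or ratio > best[0][0] + 1e-9
                or (
                    abs(ratio - best[0][0]) <= 1e-9
                    and (
                        margin > best[0][1] + 1e-15
                        or (abs(margin - best[0][1]) <= 1e-15 and -fi > best[0][2])
                    )
                )
            ):
                best = ((ratio, margin, -fi), (fi, ci), high)
    if best is None:
        return node
    _, (fi, ci), high = best
    node.split = (fi, ci)
    node.low = _build(ctx, idx[~high], used | {(fi, ci)})
    node.high = _build(ctx, idx[high], used | {(fi, ci)})
    return node


def _prune(node: _Node, cf: float) -> float:
    """Post-order subtree-replacement pruning; returns pessimistic errors."""
    if node.split is None:
        return node.errors + _add_errs(node.n, node.errors, cf)
    subtree_est = _prune(node.low, cf) + _prune(node.high, cf)
    leaf_est = node.errors + _add_errs(node.n, node.errors, cf)
    if leaf_est <= subtree_est + 0.1:
        node.to_leaf()
        return leaf_est
    return subtree_est


def _best_leaf(node: _Node, path: tuple):
    """Leaf maximizing coverage; ties -> fewer errors, more enrichment-side
    conditions, shallower, smaller path."""
    if node.split is None:
        n_high = sum(side for _, _, side in path)
        key = (node.n, -node.errors, n_high, -len(path), tuple((-f, -c, s) for f, c, s in path))
        return key, path, node
    fi, ci = node.split
    low = _best_leaf(node.low, path + ((fi, ci, 0),))
    high = _best_leaf(node.high, path + ((fi, ci, 1),))
    return max(low, high, key=lambda t: t[0])


def part_fit(
    matrix: FeatureMatrix,
    rank: str,
    confidence: float = 0.25,
    min_leaf: int = 2,
    seed: int = 0,
    cuts: list[list[float]] | None = None,
    discretizer: str = "mdl",
    n_intervals: int = 3,
) -> RuleModel:
    """Learn a decision list by repeated partial-tree extraction.

    ``cuts`` (per-feature, aligned with ``matrix.feature_order``) are fitted
    with ``discretizer`` when omitted. ``seed`` is recorded for provenance;
    the procedure itself is deterministic.
    """
    if discretizer not in ("mdl", "equal_frequency"):
        raise ParameterError("part_fit requires a discretizer ('mdl' or 'equal_frequency')")
    if rank not in matrix.labels:
        raise ValidationError(f"no labels at rank {rank!r}")
    if matrix.n_samples == 0:
        raise ValidationError("empty matrix")
    labels = matrix.labels[rank]
    usable = [j for j, lab in enumerate(labels) if lab is not None]
    if len(usable) < matrix.n_samples:
        warnings.warn(
            f"{matrix.n_samples - len(usable)} samples lack a label at {rank!r}; excluded",
            stacklevel=2,
        )
        matrix = matrix.subset_samples(usable)
        labels = matrix.labels[rank]
    if matrix.n_samples == 0:
        raise ValidationError(f"no labeled samples at rank {rank!r}")

    y_str = np.asarray(labels, dtype=object)
    classes, y = np.unique(y_str.astype(str), return_inverse=True)
    params = {"confidence": confidence, "min_leaf": min_leaf, "discretizer": discretizer}
    if len(classes) == 1:
        warnings.warn(f"single class {classes[0]!r} at rank {rank!r}; default-only model")
        return RuleModel(
            rules=[], default_class=str(classes[0]), rank=rank, learner="part",
            params=params, seed=seed, k=matrix.k,
        )

    if cuts is None:
        cuts = fit_cutpoints(matrix.values, y_str, method=discretizer, n_intervals=n_intervals)
    cuts = [list(map(float, c)) for c in cuts]
    margins = cut_margins(matrix.values, cuts)
    feature_names = matrix.feature_order
    ctx = _TreeContext(matrix.values, y, cuts, margins, len(classes), min_leaf)

    rules: list[Rule] = []
    remaining = np.arange(matrix.n_samples)
    while len(remaining) > 0:
        counts = np.bincount(y[remaining], minlength=len(classes))
        if counts.max() == len(remaining):
            break  # residual is pure; the default rule handles it
        tree = _build(ctx, remaining, frozenset())
        _prune(tree, confidence)
        if tree.split is None:
            break
        _, path, leaf = _best_leaf(tree, ())
        bounds: dict[int, tuple[float, float]] = {}
        order: list[int] = []
        mask = np.ones(len(remaining), dtype=bool)
        for fi, ci, side in path:
            cut = cuts[fi][ci]
            lo, hi = bounds.get(fi, (-INF, INF))
            if side:
                lo = max(lo, cut)
                mask &= ctx.values[fi, remaining] >= cut
            else:
                hi = min(hi, cut)
                mask &= ctx.values[fi, remaining] < cut
            if fi not in bounds:
                order.append(fi)
            bounds[fi] = (lo, hi)
        if not path or not mask.any():
            break
        literals = [Literal.interval(feature_names[fi], *bounds[fi]) for fi in order]
        rules.append(Rule(literals=literals, conclusion=str(classes[leaf.majority])))
        remaining = remaining[~mask]

    if len(remaining) > 0:
        default = _majority(y_str[remaining])
    else:
        default = _majority(y_str)
    model = RuleModel(
        rules=rules, default_class=default, rank=rank, learner="part",
        params=params, seed=seed, k=matrix.k,
    )
    attach_coverage(model, matrix, rank)
    return model
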