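"""RIPPER-style rule induction over k-mer frequency intervals.

Sequential covering with incremental reduced-error pruning and a
description-length stopping criterion:

* classes are processed in ascending prevalence order, each learned against
  all remaining classes (ordered one-vs-rest);
* each rule is GROWN on a fraction of the data by greedily adding the
  literal with the best FOIL information gain until no negatives are
  covered, then PRUNED on the held-out fraction by deleting a trailing
  suffix of literals to maximize (p - n) / (p + n);
* rule addition stops for a class when the total description length of the
  ruleset exceeds the best seen so far by a slack (default 64 bits), or
  when a rule misclassifies more than half of the pruning data it covers;
* a fixed number of optimization passes then revisits each rule, comparing
  it against a freshly grown replacement and a revision, keeping whichever
  gives the shortest description.

Literal bounds are taken from supervised (MDLP) discretization cut points
by default; with ``discretizer="raw"`` they are midpoints between
consecutive sorted feature values of the growing data. All tie-breaks are
deterministic (fewer negatives covered, then lexicographically smaller
k-mer) and all random splits are driven by the seed, so identical inputs
yield byte-identical models.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .discretization import fit_cutpoints
from .errors import ValidationError
from .kmer_features import FeatureMatrix
from .rules import INF, Literal, Rule, RuleModel


def _log2_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return 0.0
    return (
        math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    ) / math.log(2)


def _rule_bits(n_literals: int, n_conditions: int) -> float:
    n = max(n_conditions, n_literals, 1)
    return _log2_comb(n, n_literals) + n_literals


def _exception_bits(cov: int, fp: int, uncov: int, fn: int) -> float:
    t = cov + uncov
    return math.log2(t + 1) + _log2_comb(cov, fp) + _log2_comb(uncov, fn)


def _ruleset_dl(
    rule_masks: list[np.ndarray], pos: np.ndarray, n_conditions: int, n_literals: list[int]
) -> float:
    """Description length of a one-vs-rest ruleset on its full task data."""
    n = pos.size
    if rule_masks:
        covered = np.logical_or.reduce(rule_masks)
    else:
        covered = np.zeros(n, dtype=bool)
    cov = int(covered.sum())
    fp = int((covered & ~pos).sum())
    fn = int((~covered & pos).sum())
    theory = sum(_rule_bits(nl, n_conditions) for nl in n_literals)
    return theory + _exception_bits(cov, fp, n - cov, fn)


class _Task:
    """Shared state for learning the rules of one class."""

    def __init__(self, X, pos, thresholds, feature_names, rng, grow_fraction):
        self.X = X  # (n_samples, n_features)
        self.pos = pos  # bool mask: class members
        self.thresholds = thresholds  # list per feature (may be None -> raw)
        self.feature_names = feature_names
        self.rng = rng
        self.grow_fraction = grow_fraction
        if thresholds is not None:
            n_cond = sum(2 * len(t) for t in thresholds)
        else:
            n_cond = sum(
                2 * (len(np.unique(X[:, fi])) - 1) for fi in range(X.shape[1])
            )
        self.n_conditions = max(1, n_cond)

    def literal_mask(self, fi: int, lo: float, hi: float) -> np.ndarray:
        v = self.X[:, fi]
        return (v >= lo) & (v < hi)

    def rule_mask(self, lits: list[tuple[int, float, float]]) -> np.ndarray:
        m = np.ones(self.X.shape[0], dtype=bool)
        for fi, lo, hi in lits:
            m &= self.literal_mask(fi, lo, hi)
        return m


def _raw_thresholds(values: np.ndarray) -> list[float]:
    u = np.unique(values)
    if len(u) < 2:
        return []
    return [float((a + b) / 2.0) for a, b in zip(u[:-1], u[1:])]


def _grow(task: _Task, grow_idx: np.ndarray, start=None) -> list[tuple[int, float, float]]:
    X, pos = task.X, task.pos
    lits: list[tuple[int, float, float]] = list(start or [])
    cover = np.ones(len(grow_idx), dtype=bool)
    Xg = X[grow_idx]
    posg = pos[grow_idx]
    for fi, lo, hi in lits:
        cover &= (Xg[:, fi] >= lo) & (Xg[:, fi] < hi)
    if task.thresholds is not None:
        ths = task.thresholds
    else:
        ths = [_raw_thresholds(Xg[:, fi]) for fi in range(Xg.shape[1])]
    while True:
        p0 = int((cover & posg).sum())
        n0 = int((cover & ~posg).sum())
        if n0 == 0 or p0 == 0:
            break
        base = math.log2(p0 / (p0 + n0))
        best = None  # (gain, n1, margin, feature_name, lo, hi, mask)
        for fi in range(Xg.shape[1]):
            tlist = ths[fi]
            if not tlist:
                continue
            v = Xg[:, fi]
            name = task.feature_names[fi]
            for t in tlist:
                below = v < t
                if below.all() or not below.any():
                    continue
                margin = float(v[~below].min() - v[below].max())
                for lo, hi, cond in ((-INF, t, below), (t, INF, ~below)):
                    m = cover & cond
                    p1 = int((m & posg).sum())
                    if p1 == 0:
                        continue
                    n1 = int(m.sum()) - p1
                    gain = p1 * (math.log2(p1 / (p1 + n1)) - base)
                    if gain <= 1e-9:
                        continue
                    enriched = 1 if hi == INF else 0
                    cand = (gain, n1, enriched, margin, name, lo, hi)
                    if best is None or _better(cand, best[0]):
                        best = (cand, (fi, lo, hi), m)
        if best is None:
            break
        lits.append(best[1])
        cover = best[2]
    return lits


def _better(a, b) -> bool:
    """Candidate ordering on FOIL-gain ties: fewer negatives covered, then an
    enrichment condition (lower bound) over a depletion one — a signature is
    an over-representation — then the wider separation gap at the threshold,
    then the lexicographically smaller k-mer and bounds."""
    if a[0] > b[0] + 1e-9:
        return True
    if a[0] < b[0] - 1e-9:
        return False
    if a[1] != b[1]:
        return a[1] < b[1]
    if a[2] != b[2]:
        return a[2] > b[2]
    if abs(a[3] - b[3]) > 1e-15:
        return a[3] > b[3]
    return (a[4], a[5], a[6]) < (b[4], b[5], b[6])


def _prune(task: _Task, lits, prune_idx: np.ndarray):
    """Keep the literal prefix maximizing (p - n) / (p + n) on pruning data."""
    if len(prune_idx) == 0 or len(lits) <= 1:
        return lits
    Xp = task.X[prune_idx]
    posp = task.pos[prune_idx]
    cover = np.ones(len(prune_idx), dtype=bool)
    best_j, best_metric = len(lits), None
    for j, (fi, lo, hi) in enumerate(lits, start=1):
        cover &= (Xp[:, fi] >= lo) & (Xp[:, fi] < hi)
        p = int((cover & posp).sum())
        n = int(cover.sum()) - p
        metric = (p - n) / (p + n) if (p + n) else 0.0
        if best_metric is None or metric > best_metric + 1e-12:
            best_metric, best_j = metric, j
    return lits[:best_j]


def _split_grow_prune(task: _Task, idx: np.ndarray):
    """Stratified grow/prune split of the current example indices."""
    pos_idx = idx[task.pos[idx]]
    neg_idx = idx[~task.pos[idx]]
    out_grow, out_prune = [], []
    for part in (pos_idx, neg_idx):
        perm = part[task.rng.permutation(len(part))]
        n_grow = int(math.ceil(task.grow_fraction * len(part)))
        out_grow.append(perm[:n_grow])
        out_prune.append(perm[n_grow:])
    grow = np.sort(np.concatenate(out_grow))
    prune = np.sort(np.concatenate(out_prune))
    return grow, prune


def _rule_error_on(task: _Task, lits, idx: np.ndarray):
    if len(idx) == 0:
        return 0.0, 0
    m = task.rule_mask(lits)[idx]
    covered = int(m.sum())
    if covered == 0:
        return 0.0, 0
    p = int((m & task.pos[idx]).sum())
    return (covered - p) / covered, covered


def _learn_class(task: _Task, dl_slack_bits: float):
    """IREP* loop for one class; returns literal lists (internal form)."""
    n = task.X.shape[0]
    current = np.arange(n)
    rules: list[list[tuple[int, float, float]]] = []
    masks: list[np.ndarray] = []
    best_dl = _ruleset_dl([], task.pos, task.n_conditions, [])
    while task.pos[current].any():
        grow_idx, prune_idx = _split_grow_prune(task, current)
        if not task.pos[grow_idx].any():
            break
        lits = _grow(task, grow_idx)
        if not lits:
            break
        lits = _prune(task, lits, prune_idx)
        err, covered = _rule_error_on(task, lits, prune_idx)
        if covered and err > 0.5:
            break
        full_mask = task.rule_mask(lits)
        if not (full_mask[current] & task.pos[current]).any():
            break
        rules.append(lits)
        masks.append(full_mask)
        dl = _ruleset_dl(masks, task.pos, task.n_conditions, [len(r) for r in rules])
        if dl > best_dl + dl_slack_bits:
            rules.pop()
            masks.pop()
            break
        best_dl = min(best_dl, dl)
        current = current[~full_mask[current]]
        if len(current) == 0:
            break
    return rules


def _optimize(task: _Task, rules, passes: int, dl_slack_bits: float):
    """Cohen-style replacement/revision passes, judged by description length."""
    for _ in range(passes):
        for i in range(len(rules)):
            others = [r for j, r in enumerate(rules) if j != i]
            other_masks = [task.rule_mask(r) for r in others]
            if other_masks:
                residual = ~np.logical_or.reduce(other_masks)
            else:
                residual = np.ones(task.X.shape[0], dtype=bool)
            idx = np.where(residual)[0]
            if not task.pos[idx].any():
                variants = [rules[i]]
            else:
                grow_idx, prune_idx = _split_grow_prune(task, idx)
                replacement = _prune(task, _grow(task, grow_idx), prune_idx)
                revision = _prune(task, _grow(task, grow_idx, start=rules[i]), prune_idx)
                variants = [rules[i]]
                if replacement:
                    variants.append(replacement)
                if revision:
                    variants.append(revision)
            best_rule, best_dl = None, None
            for var in variants:
                cand = rules[:i] + [var] + rules[i + 1 :]
                dl = _ruleset_dl(
                    [task.rule_mask(r) for r in cand],
                    task.pos,
                    task.n_conditions,
                    [len(r) for r in cand],
                )
                if best_dl is None or dl < best_dl - 1e-9:
                    best_rule, best_dl = var, dl
            rules[i] = best_rule
    # drop rules whose removal shortens the description
    changed = True
    while changed and rules:
        changed = False
        full_dl = _ruleset_dl(
            [task.rule_mask(r) for r in rules],
            task.pos,
            task.n_conditions,
            [len(r) for r in rules],
        )
        for i in range(len(rules)):
            cand = rules[:i] + rules[i + 1 :]
            dl = _ruleset_dl(
                [task.rule_mask(r) for r in cand],
                task.pos,
                task.n_conditions,
                [len(r) for r in cand],
            )
            if dl < full_dl - 1e-9:
                rules.pop(i)
                changed = True
                break
    return rules


def _lits_to_rule(lits, feature_names, conclusion: str) -> Rule:
    merged: dict[int, tuple[float, float]] = {}
    order: list[int] = []
    for fi, lo, hi in lits:
        if fi in merged:
            plo, phi = merged[fi]
            merged[fi] = (max(plo, lo), min(phi, hi))
        else:
            merged[fi] = (lo, hi)
            order.append(fi)
    literals = [Literal.interval(feature_names[fi], *merged[fi]) for fi in order]
    return Rule(literals=literals, conclusion=conclusion)


def ripper_fit(
    matrix: FeatureMatrix,
    rank: str,
    grow_fraction: float = 2 / 3,
    optimization_passes: int = 2,
    dl_slack_bits: float = 64.0,
    seed: int = 0,
    cuts: list[list[float]] | None = None,
    discretizer: str = "mdl",
    n_intervals: int = 3,
) -> RuleModel:
    """Learn an ordered decision list for the classes at ``rank``.

    Parameters
    ----------
    matrix:
        Feature matrix with labels at ``rank``.
    cuts:
        Optional per-feature cut points (aligned with ``matrix.feature_order``).
        When omitted they are fitted with ``discretizer`` ("mdl",
        "equal_frequency", or "raw" for midpoint thresholds during growing).
    """
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

    y = np.asarray(labels, dtype=object)
    X = matrix.values.T  # samples x features
    feature_names = matrix.feature_order
    params = {
        "grow_fraction": grow_fraction,
        "optimization_passes": optimization_passes,
        "dl_slack_bits": dl_slack_bits,
        "discretizer": discretizer,
    }

    class_counts: dict[str, int] = {}
    for lab in y:
        class_counts[lab] = class_counts.get(lab, 0) + 1
    classes = sorted(class_counts, key=lambda c: (class_counts[c], c))
    if len(classes) == 1:
        warnings.warn(f"single class {classes[0]!r} at rank {rank!r}; default-only model")
        return RuleModel(
            rules=[], default_class=classes[0], rank=rank, learner="ripper",
            params=params, seed=seed, k=matrix.k,
        )

    if cuts is None and discretizer in ("mdl", "equal_frequency"):
        cuts = fit_cutpoints(matrix.values, y, method=discretizer, n_intervals=n_intervals)
    thresholds = cuts  # None -> raw midpoints inside _grow

    rng = np.random.default_rng(seed)
    all_rules: list[Rule] = []
    remaining = np.ones(len(y), dtype=bool)
    for cls in classes[:-1]:
        idx = np.where(remaining)[0]
        if len(idx) == 0 or not (y[idx] == cls).any():
            continue
        task = _Task(
            X[idx], y[idx] == cls, thresholds, feature_names, rng, grow_fraction
        )
        lits_list = _learn_class(task, dl_slack_bits)
        lits_list = _optimize(task, lits_list, optimization_passes, dl_slack_bits)
        class_rules = [_lits_to_rule(l, feature_names, cls) for l in lits_list]
        all_rules.extend(class_rules)
        covered_local = np.zeros(len(idx), dtype=bool)
        for l in lits_list:
            covered_local |= task.rule_mask(l)
        remaining[idx[covered_local]] = False
        remaining[y == cls] = False

    # default: majority among samples no rule covers, else global majority
    uncovered = np.ones(len(y), dtype=bool)
    fidx = matrix.feature_index()
    for rule in all_rules:
        m = np.ones(len(y), dtype=bool)
        for lit in rule.literals:
            v = X[:, fidx[lit.feature]]
            m &= (v >= lit.lo) & (v < lit.hi)
        uncovered &= ~m
    if uncovered.any():
        default = _majority(y[uncovered])
    else:
        default = classes[-1]

    model = RuleModel(
        rules=all_rules, default_class=default, rank=rank, learner="ripper",
        params=params, seed=seed, k=matrix.k,
    )
    attach_coverage(model, matrix, rank)
    return model


def _majority(labels: np.ndarray) -> str:
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    return max(sorted(counts), key=lambda c: counts[c])


def attach_coverage(model: RuleModel, matrix: FeatureMatrix, rank: str) -> None:
    """Record each rule's standalone (positives, negatives) on training data."""
    labels = np.asarray(matrix.labels[rank], dtype=object)
    X = matrix.values.T
    fidx = matrix.feature_index()
    for rule in model.rules:
        m = np.ones(matrix.n_samples, dtype=bool)
        for lit in rule.literals:
            v = X[:, fidx[lit.feature]]
            lm = np.zeros(matrix.n_samples, dtype=bool)
            for lo, hi in lit.intervals:
                lm |= (v >= lo) & (v < hi)
            m &= lm
        p = int((m & (labels == rule.conclusion)).sum())
        n = int(m.sum()) - p
        rule.coverage = (p, n)
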