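"""Noise-filtration scores: null-model expectations and relative-deviation z.

Raw k-mer frequencies mix taxon signal with the background character
composition of each genome. A classical correction replaces the empirical
probability p(W) of a word W with the relative deviation

    z(W) = (p(W) - p~(W)) / p~(W)

where p~(W) is the probability expected under a null model of the genome.
Three standard expectations are provided:

``markov_k2``
    Markov process of order k-2 (or smaller):
    p~(W) = p(W[1..k-1]) * p(W[2..k]) / p(W[2..k-1]).
``boundary``
    Independence of the first character, last character and interior:
    p~(W) = (f(W[1]) * f(W[2..k]) + f(W[1..k-1]) * f(W[k])) / 2.
``iid``
    Independent single-nucleotide frequencies: p~(W) = prod_i f(W[i]).

Probabilities at every word length use the same strand mode and the same
valid-window denominator as the k-mer counts, so the null model is
internally consistent with the observed frequencies. When p~(W) = 0 (which
only happens on short or heavily masked sequences) a policy decides whether
the feature scores 0 (default) or is dropped from the matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, ValidationError
from .kmer_features import FeatureMatrix, all_kmers, count_vector, kmer_to_index
from .sequence_io import RANKS, GenomeRecord, dust_mask

ESTIMATORS = ("none", "markov_k2", "boundary", "iid")
ZERO_POLICIES = ("score_zero", "drop_feature")


@dataclass
class ScoreConfig:
    """Choice of preprocessing applied to raw k-mer frequencies."""

    estimator: str = "none"
    mask_low_complexity: bool = False
    zero_expectation_policy: str = "score_zero"

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ParameterError(
                f"estimator must be one of {ESTIMATORS}, got {self.estimator!r}"
            )
        if self.zero_expectation_policy not in ZERO_POLICIES:
            raise ParameterError(
                f"zero_expectation_policy must be one of {ZERO_POLICIES}, "
                f"got {self.zero_expectation_policy!r}"
            )

    def required_lengths(self, k: int) -> list[int]:
        if self.estimator == "markov_k2":
            if k < 3:
                raise ParameterError("markov_k2 estimator requires k >= 3")
            return [k - 2, k - 1, k]
        if self.estimator == "boundary":
            return [1, k - 1, k]
        if self.estimator == "iid":
            return [1, k]
        return [k]


class SubwordStats:
    """Counts and probabilities of all words at several lengths of one genome.

    Shared backing store for the scalar estimator functions below; lengths
    are counted lazily with the same sequence and strand mode.
    """

    def __init__(self, sequence_or_record, strand_mode: str = "forward") -> None:
        if isinstance(sequence_or_record, GenomeRecord):
            self.sequence = sequence_or_record.sequence
        else:
            self.sequence = sequence_or_record
        self.strand_mode = strand_mode
        self._counts: dict[int, np.ndarray] = {}
        self._valid: dict[int, int] = {}

    def _ensure(self, length: int) -> None:
        if length not in self._counts:
            counts, valid = count_vector(self.sequence, length, self.strand_mode)
            self._counts[length] = counts
            self._valid[length] = valid

    def valid_windows(self, length: int) -> int:
        self._ensure(length)
        return self._valid[length]

    def count(self, word: str) -> int:
        self._ensure(len(word))
        return int(self._counts[len(word)][kmer_to_index(word)])

    def probability(self, word: str) -> float:
        """Empirical probability: occurrences over valid windows at |word|."""
        if not word:
            raise ValidationError("empty word")
        self._ensure(len(word))
        valid = self._valid[len(word)]
        if valid == 0:
            warnings.warn(
                f"no valid windows at length {len(word)}; probability set to 0",
                stacklevel=2,
            )
            return 0.0
        return self._counts[len(word)][kmer_to_index(word)] / valid


def empirical_probability(stats: SubwordStats, word: str) -> float:
    """p(W): occurrence count of W over the number of valid |W|-windows."""
    return stats.probability(word)


def markov_expectation(stats: SubwordStats, word: str) -> float:
    """Expected p(W) under a Markov source of order |W|-2 or smaller.

    p~(W) = p(prefix) * p(suffix) / p(interior); returns 0 when the interior
    word is absent (the caller applies its zero-expectation policy).
    """
    k = len(word)
    if k < 3:
        raise ParameterError(f"markov expectation requires |W| >= 3, got {k}")
    interior = stats.probability(word[1 : k - 1])
    if interior == 0.0:
        return 0.0
    return stats.probability(word[: k - 1]) * stats.probability(word[1:]) / interior


def boundary_expectation(stats: SubwordStats, word: str) -> float:
    """Expected p(W) assuming the interior and the two boundary characters
    occur independently: the symmetric average of the two factorizations
    f(W[1]) * f(W[2..k]) and f(W[1..k-1]) * f(W[k])."""
    k = len(word)
    if k < 2:
        raise ParameterError(f"boundary expectation requires |W| >= 2, got {k}")
    return (
        stats.probability(word[0]) * stats.probability(word[1:])
        + stats.probability(word[: k - 1]) * stats.probability(word[-1])
    ) / 2.0


def iid_expectation(stats: SubwordStats, word: str) -> float:
    """Expected p(W) from single-nucleotide frequencies: prod_i f(W[i]).

    Factors are multiplied in sorted order so the result is bit-identical
    for a word and its reverse complement under both-strand counting.
    """
    factors = sorted(stats.probability(c) for c in word)
    out = 1.0
    for f in factors:
        out *= f
    return out


def z_score(p: float, p_expected: float, policy: str = "score_zero") -> float:
    """Relative deviation (p - p~) / p~ of observed from expected probability.

    When the expectation is 0 the ``score_zero`` policy returns 0; the
    ``drop_feature`` policy is applied at the matrix level (the feature row
    is removed), so here it also returns 0.
    """
    if policy not in ZERO_POLICIES:
        raise ParameterError(f"unknown zero-expectation policy {policy!r}")
    if p_expected == 0.0:
        return 0.0
    return (p - p_expected) / p_expected


def _dense_probabilities(stats: SubwordStats, length: int) -> np.ndarray:
    stats._ensure(length)
    valid = stats._valid[length]
    if valid == 0:
        return np.zeros(4**length, dtype=float)
    return stats._counts[length] / valid


def score_vector(
    sequence_or_record,
    k: int,
    strand_mode: str = "forward",
    config: ScoreConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """z-scores of all 4^k words of one genome under ``config.estimator``.

    Returns ``(scores, zero_expectation_mask)`` in lexicographic k-mer
    order; the mask marks features whose expectation was 0 (candidates for
    dropping under the ``drop_feature`` policy).
    """
    config = config or ScoreConfig(estimator="markov_k2")
    if config.estimator == "none":
        raise ParameterError("score_vector requires a non-trivial estimator")
    seq = (
        sequence_or_record.sequence
        if isinstance(sequence_or_record, GenomeRecord)
        else sequence_or_record
    )
    if config.mask_low_complexity:
        seq = dust_mask(seq)
    stats = SubwordStats(seq, strand_mode)
    m = 4**k
    p = _dense_probabilities(stats, k)
    idx = np.arange(m, dtype=np.int64)
    if config.estimator == "markov_k2":
        if k < 3:
            raise ParameterError("markov_k2 estimator requires k >= 3")
        p_km1 = _dense_probabilities(stats, k - 1)
        p_km2 = _dense_probabilities(stats, k - 2)
        prefix = idx >> 2
        suffix = idx & (4 ** (k - 1) - 1)
        interior = prefix & (4 ** (k - 2) - 1)
        denom = p_km2[interior]
        with np.errstate(divide="ignore", invalid="ignore"):
            expected = np.where(denom > 0, p_km1[prefix] * p_km1[suffix] / denom, 0.0)
    elif config.estimator == "boundary":
        p1 = _dense_probabilities(stats, 1)
        p_km1 = _dense_probabilities(stats, k - 1)
        first = idx >> (2 * (k - 1))
        last = idx & 3
        prefix = idx >> 2
        suffix = idx & (4 ** (k - 1) - 1)
        expected = (p1[first] * p_km1[suffix] + p_km1[prefix] * p1[last]) / 2.0
    else:  # iid
        p1 = _dense_probabilities(stats, 1)
        factors = np.empty((m, k), dtype=float)
        for j in range(k):
            digit = (idx >> (2 * (k - 1 - j))) & 3
            factors[:, j] = p1[digit]
        factors.sort(axis=1)
        expected = np.ones(m, dtype=float)
        # ascending factor order: canonical, reverse-complement symmetric
        for j in range(k):
            expected *= factors[:, j]
    zero_mask = expected == 0.0
    scores = np.zeros(m, dtype=float)
    nz = ~zero_mask
    scores[nz] = (p[nz] - expected[nz]) / expected[nz]
    return scores, zero_mask


def transform_matrix(
    records,
    k: int,
    strand_mode: str,
    config: ScoreConfig,
) -> FeatureMatrix:
    """Build a feature matrix of per-genome z-scores instead of frequencies.

    Under ``drop_feature`` every feature whose expectation is 0 in any
    genome is removed from the matrix (feature order then shrinks below
    4^k); under ``score_zero`` such entries simply score 0.
    """
    if not records:
        raise ValidationError("cannot build a matrix from an empty record list")
    columns = []
    dropped = np.zeros(4**k, dtype=bool)
    for rec in records:
        scores, zero_mask = score_vector(rec, k, strand_mode, config)
        columns.append(scores)
        dropped |= zero_mask
    values = np.column_stack(columns)
    feature_order = all_kmers(k)
    if config.zero_expectation_policy == "drop_feature" and dropped.any():
        keep = ~dropped
        values = values[keep]
        feature_order = [f for f, keep_f in zip(feature_order, keep) if keep_f]
    ranks_present = [r for r in RANKS if any(r in rec.lineage for rec in records)]
    labels = {rank: [rec.lineage.get(rank) for rec in records] for rank in ranks_present}
    return FeatureMatrix(
        k=k,
        feature_order=feature_order,
        sample_ids=[rec.id for rec in records],
        values=values,
        labels=labels,
        transformed=config.estimator,
    )
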