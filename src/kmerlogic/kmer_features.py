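"""k-mer counting, relative frequency vectors, and the feature matrix.

A genome is represented by the vector of relative frequencies of all 4^k
words of length k, obtained by sliding a window over the sequence (and,
optionally, independently over its reverse complement). The feature matrix
stacks one frequency vector per genome, rows indexed by k-mers in
lexicographic order and columns by sequence ids, with class labels attached
per taxonomic rank — the standard input layout for the rule learners.

Counting notes:

* windows containing ``N`` are skipped and do not count toward the number of
  valid windows; frequencies are counts divided by valid windows, so masked
  or ambiguous stretches do not distort the distribution;
* with ``strand_mode="both"`` the forward and reverse-complement strands are
  scanned separately and the counts summed — windows never span the junction
  of a concatenation, and every k-mer ends up with the same frequency as its
  reverse complement;
* the full 4^k feature space is kept (no canonical-k-mer collapsing), so a
  word and its reverse complement are separate, redundant features.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParameterError, ValidationError
from .sequence_io import RANKS, GenomeRecord, reverse_complement

MAX_K = 12

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def all_kmers(k: int) -> list[str]:
    """All 4^k k-mers in lexicographic order over A < C < G < T."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_to_index(kmer: str) -> int:
    """Lexicographic index of a k-mer (A=0, C=1, G=2, T=3 digits, base 4)."""
    idx = 0
    for ch in kmer:
        code = _CODE[ord(ch)]
        if code < 0:
            raise ValidationError(f"invalid k-mer {kmer!r}")
        idx = idx * 4 + int(code)
    return idx


def index_to_kmer(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[index % 4])
        index //= 4
    return "".join(reversed(out))


def _encode(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _scan_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, int]:
    """Dense count array (length 4^k) and valid window count for one strand."""
    n = len(codes)
    m = 4**k
    if n < k:
        return np.zeros(m, dtype=np.int64), 0
    nwin = n - k + 1
    invalid = (codes < 0).astype(np.int64)
    bad = np.convolve(invalid, np.ones(k, dtype=np.int64), mode="valid") > 0
    safe = np.where(codes < 0, 0, codes).astype(np.int64)
    acc = np.zeros(nwin, dtype=np.int64)
    for j in range(k):
        acc = acc * 4 + safe[j : j + nwin]
    word_codes = acc[~bad]
    counts = np.bincount(word_codes, minlength=m)
    return counts, int(word_codes.size)


def count_vector(sequence: str, k: int, strand_mode: str = "forward") -> tuple[np.ndarray, int]:
    """Dense k-mer count vector (lexicographic order) and valid window count.

    Low-level numeric path shared by :func:`count_kmers`, the significance
    estimators and the matrix builder.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    if k > MAX_K:
        raise ParameterError(f"k must be <= {MAX_K}, got {k}")
    if strand_mode not in ("forward", "both"):
        raise ParameterError(f"strand_mode must be 'forward' or 'both', got {strand_mode!r}")
    if k > len(sequence):
        warnings.warn(
            f"k={k} exceeds sequence length {len(sequence)}; returning empty counts",
            stacklevel=2,
        )
        return np.zeros(4**k, dtype=np.int64), 0
    codes = _encode(sequence)
    counts, valid = _scan_codes(codes, k)
    if strand_mode == "both":
        rc_codes = _encode(reverse_complement(sequence))
        rc_counts, rc_valid = _scan_codes(rc_codes, k)
        counts = counts + rc_counts
        valid += rc_valid
    return counts, valid


@dataclass
class KmerCounts:
    """Occurrence counts of all observed k-mers of one genome.

    ``counts`` maps each observed k-mer (no ``N``) to its occurrence count;
    ``valid_windows`` is the number of window positions actually counted, so
    ``sum(counts.values()) == valid_windows`` always holds.
    """

    k: int
    counts: dict[str, int]
    valid_windows: int
    strand_mode: str = "forward"

    def dense(self) -> np.ndarray:
        """Counts as a dense vector in lexicographic k-mer order."""
        out = np.zeros(4**self.k, dtype=np.int64)
        for kmer, c in self.counts.items():
            out[kmer_to_index(kmer)] = c
        return out


def count_kmers(record: GenomeRecord | str, k: int, strand_mode: str = "forward") -> KmerCounts:
    """Count k-mers of a genome with a sliding window of length ``k``.

    Windows containing ``N`` are skipped. With ``strand_mode="both"`` the
    reverse complement is scanned independently and counts are summed.
    """
    sequence = record.sequence if isinstance(record, GenomeRecord) else record
    dense, valid = count_vector(sequence, k, strand_mode)
    nz = np.nonzero(dense)[0]
    counts = {index_to_kmer(int(i), k): int(dense[i]) for i in nz}
    return KmerCounts(k=k, counts=counts, valid_windows=valid, strand_mode=strand_mode)


@dataclass
class FrequencyVector:
    """Relative frequency (or significance score) per k-mer for one genome.

    When ``transformed == "none"`` the values are counts over valid windows:
    they lie in [0, 1] and sum to 1 whenever any window was valid. Absent
    k-mers have value 0 and are not stored.
    """

    k: int
    values: dict[str, float]
    transformed: str = "none"

    def get(self, kmer: str) -> float:
        return self.values.get(kmer, 0.0)

    def dense(self) -> np.ndarray:
        out = np.zeros(4**self.k, dtype=float)
        for kmer, v in self.values.items():
            out[kmer_to_index(kmer)] = v
        return out


def to_frequencies(counts: KmerCounts) -> FrequencyVector:
    """Convert counts to relative frequencies (count / valid windows)."""
    if counts.valid_windows == 0:
        warnings.warn(
            "no valid windows: frequency vector is all zeros (unusable record)",
            stacklevel=2,
        )
        return FrequencyVector(k=counts.k, values={})
    denom = counts.valid_windows
    values = {kmer: c / denom for kmer, c in counts.counts.items()}
    return FrequencyVector(k=counts.k, values=values)


@dataclass
class FeatureMatrix:
    """k-mers x sequences matrix with class labels per taxonomic rank.

    Rows correspond to k-mers (``feature_order``, lexicographic — the full
    4^k set unless features were dropped by a zero-expectation policy),
    columns to sequences (``sample_ids``). ``labels[rank][j]`` is the class
    of column ``j`` at ``rank`` (``None`` when the lineage lacks the rank).
    """

    k: int
    feature_order: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_features, n_samples)
    labels: dict[str, list[str | None]] = field(default_factory=dict)
    transformed: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_order), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_order)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_order)) != len(self.feature_order):
            raise ValidationError("duplicate features in feature_order")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_order)

    def feature_index(self) -> dict[str, int]:
        return {f: i for i, f in enumerate(self.feature_order)}

    def column(self, j: int) -> FrequencyVector:
        values = {
            f: float(v) for f, v in zip(self.feature_order, self.values[:, j]) if v != 0.0
        }
        return FrequencyVector(k=self.k, values=values, transformed=self.transformed)

    def subset_samples(self, indices: Sequence[int]) -> "FeatureMatrix":
        indices = list(indices)
        return FeatureMatrix(
            k=self.k,
            feature_order=list(self.feature_order),
            sample_ids=[self.sample_ids[j] for j in indices],
            values=self.values[:, indices].copy(),
            labels={r: [lab[j] for j in indices] for r, lab in self.labels.items()},
            transformed=self.transformed,
        )


def build_matrix(
    records: Sequence[GenomeRecord],
    k: int = 4,
    strand_mode: str = "both",
    score_config=None,
) -> FeatureMatrix:
    """Assemble the feature matrix from genome records.

    Each column is the record's frequency vector; when ``score_config``
    requests a significance estimator the frequencies are replaced by
    per-genome z-scores (see :mod:`kmerlogic.significance`). Labels are
    copied from the lineages for every rank present in any record.
    """
    if not records:
        raise ValidationError("cannot build a matrix from an empty record list")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate record ids")
    if score_config is not None and score_config.estimator != "none":
        from .significance import transform_matrix

        return transform_matrix(records, k, strand_mode, score_config)
    columns = []
    for rec in records:
        dense, valid = count_vector(rec.sequence, k, strand_mode)
        if valid == 0:
            warnings.warn(f"record {rec.id!r} has no valid windows at k={k}", stacklevel=2)
            columns.append(np.zeros(4**k, dtype=float))
        else:
            columns.append(dense / valid)
    values = np.column_stack(columns)
    ranks_present = [r for r in RANKS if any(r in rec.lineage for rec in records)]
    labels = {
        rank: [rec.lineage.get(rank) for rec in records] for rank in ranks_present
    }
    return FeatureMatrix(
        k=k,
        feature_order=all_kmers(k),
        sample_ids=ids,
        values=values,
        labels=labels,
    )


def filter_rare_classes(
    matrix: FeatureMatrix, rank: str, min_specimens: int = 9
) -> FeatureMatrix:
    """Drop columns whose class at ``rank`` has fewer than ``min_specimens``.

    Columns with no label at ``rank`` are dropped as well (they cannot be
    used for supervised training). Raises if nothing survives.
    """
    if rank not in matrix.labels:
        raise ValidationError(f"no labels at rank {rank!r}")
    labels = matrix.labels[rank]
    sizes: dict[str, int] = {}
    for lab in labels:
        if lab is not None:
            sizes[lab] = sizes.get(lab, 0) + 1
    keep = [
        j
        for j, lab in enumerate(labels)
        if lab is not None and sizes[lab] >= min_specimens
    ]
    if not keep:
        raise ValidationError(
            f"no classes with >= {min_specimens} specimens at rank {rank!r}"
        )
    if len(keep) == matrix.n_samples:
        return matrix
    return matrix.subset_samples(keep)


def write_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write the matrix as TSV: k-mer rows, sequence columns, label header lines.

    The first header line carries the sample ids; one additional ``#label:``
    line per rank carries the class labels. Values are printed with 12
    significant digits so a write/read round trip is bit-exact at that
    precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"#k\t{matrix.k}\n")
        fh.write(f"#transformed\t{matrix.transformed}\n")
        fh.write("#ids\t" + "\t".join(matrix.sample_ids) + "\n")
        for rank in RANKS:
            if rank in matrix.labels:
                cells = ["" if v is None else v for v in matrix.labels[rank]]
                fh.write(f"#label:{rank}\t" + "\t".join(cells) + "\n")
        for i, kmer in enumerate(matrix.feature_order):
            row = "\t".join(f"{v:.12g}" for v in matrix.values[i])
            fh.write(f"{kmer}\t{row}\n")


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a matrix written by :func:`write_matrix`."""
    path = Path(path)
    k = None
    transformed = "none"
    sample_ids: list[str] | None = None
    labels: dict[str, list[str | None]] = {}
    features: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            tag = cells[0]
            if tag == "#k":
                k = int(cells[1])
            elif tag == "#transformed":
                transformed = cells[1]
            elif tag == "#ids":
                sample_ids = cells[1:]
            elif tag.startswith("#label:"):
                rank = tag[len("#label:") :]
                labels[rank] = [c if c else None for c in cells[1:]]
            elif tag.startswith("#"):
                continue
            else:
                features.append(tag)
                rows.append([float(c) for c in cells[1:]])
    if k is None or sample_ids is None:
        raise ValidationError(f"{path} is not a kmerlogic matrix file")
    return FeatureMatrix(
        k=k,
        feature_order=features,
        sample_ids=sample_ids,
        values=np.array(rows, dtype=float),
        labels=labels,
        transformed=transformed,
    )
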