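"""Genome ingestion and elementary sequence operations.

Reads multi-FASTA genome files into :class:`GenomeRecord` objects, attaches
taxonomic lineages from a tab-separated table, and provides the two sequence
primitives the pipeline needs before any counting happens: reverse
complementation and DUST-style low-complexity masking.

Sequences are uppercased on ingest and every non-ACGT character is mapped to
the single sentinel ``N``; all downstream window logic treats ``N`` as
invalid, so one rule covers ambiguity codes, gaps and masked regions alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import FastaFormatError, ParameterError, ValidationError

#: Taxonomic ranks handled throughout the package, most to least specific.
RANKS = ("species", "genus", "order", "class", "phylum")

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_TO_N = {c: "N" for c in range(256)}
for _b in "ACGT":
    _TO_N[ord(_b)] = _b
_NORMALIZE = str.maketrans(_TO_N)


@dataclass
class GenomeRecord:
    """One labeled genome: identifier, nucleotide string, lineage by rank.

    ``lineage`` maps rank names from :data:`RANKS` to taxon names; partial
    lineages are permitted (missing ranks simply have no entry).
    """

    id: str
    sequence: str
    lineage: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("GenomeRecord id must be non-empty")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValidationError(
                f"sequence of {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def normalize_sequence(raw: str) -> str:
    """Uppercase ``raw`` and replace every non-ACGT character with ``N``."""
    return raw.upper().translate(_NORMALIZE)


def read_taxonomy(path: str | Path) -> dict[str, dict[str, str]]:
    """Read a taxonomy table mapping sequence id to a (partial) lineage.

    Expected format: TSV with header ``id<TAB>species<TAB>genus<TAB>order
    <TAB>class<TAB>phylum``; empty cells are allowed and yield no lineage
    entry for that rank.
    """
    path = Path(path)
    lineages: dict[str, dict[str, str]] = {}
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0].lstrip("#").strip().lower() != "id":
            raise ValidationError(
                f"taxonomy table {path} must start with an 'id' header column"
            )
        ranks = [h.strip().lower() for h in header[1:]]
        unknown = [r for r in ranks if r not in RANKS]
        if unknown:
            raise ValidationError(f"unknown taxonomy ranks in header: {unknown}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            rid = cells[0].strip()
            if not rid:
                raise ValidationError(f"{path}:{lineno}: empty sequence id")
            if rid in lineages:
                raise ValidationError(f"{path}:{lineno}: duplicate id {rid!r}")
            lineage = {
                rank: cell.strip()
                for rank, cell in zip(ranks, cells[1:])
                if cell.strip()
            }
            lineages[rid] = lineage
    return lineages


def _validate_fasta_layout(path: Path) -> None:
    # Bio.SeqIO silently ignores some malformed layouts; fail loudly instead,
    # naming the first offending line.
    seen_header = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                if len(stripped) == 1:
                    raise FastaFormatError(f"{path}:{lineno}: empty FASTA header")
                seen_header = True
            elif not seen_header:
                raise FastaFormatError(
                    f"{path}:{lineno}: sequence data before first '>' header"
                )
    if not seen_header:
        raise FastaFormatError(f"{path}: no FASTA records found")


def read_fasta(
    path: str | Path,
    taxonomy: Mapping[str, Mapping[str, str]] | str | Path | None = None,
) -> list[GenomeRecord]:
    """Read a multi-FASTA file into a list of :class:`GenomeRecord`.

    Parameters
    ----------
    path:
        FASTA file, one genome per record.
    taxonomy:
        Either a mapping ``id -> {rank: taxon}`` or the path of a taxonomy
        TSV (see :func:`read_taxonomy`). Records without an entry get an
        empty lineage.
    """
    path = Path(path)
    _validate_fasta_layout(path)
    if taxonomy is not None and not isinstance(taxonomy, Mapping):
        taxonomy = read_taxonomy(taxonomy)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        lineage = dict(taxonomy.get(rec.id, {})) if taxonomy else {}
        records.append(
            GenomeRecord(
                id=rec.id,
                sequence=normalize_sequence(str(rec.seq)),
                lineage=lineage,
            )
        )
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    """Write records as multi-FASTA with fixed line width (deterministic bytes)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_taxonomy(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write the lineages of ``records`` as the standard taxonomy TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(RANKS) + "\n")
        for rec in records:
            cells = [rec.lineage.get(rank, "") for rank in RANKS]
            fh.write(rec.id + "\t" + "\t".join(cells) + "\n")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}; N maps to N.

    Involution: ``reverse_complement(reverse_complement(s)) == s``.
    """
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValidationError(f"cannot complement characters: {sorted(bad)}")
    return sequence.translate(_COMPLEMENT)[::-1]


def dust_mask(sequence: str, window: int = 64, threshold: float = 2.0) -> str:
    """Mask low-complexity regions to ``N`` with the classic triplet score.

    Every window of length ``min(window, len(sequence))`` is scored by its
    overlapping-triplet counts ``c_t`` as ``sum_t c_t (c_t - 1) / 2`` divided
    by ``m - 1`` where ``m = L - 2`` is the number of triplet positions;
    windows scoring above ``threshold`` are masked entirely. Triplets that
    contain ``N`` are ignored (which makes the operation idempotent). Output
    length always equals input length.
    """
    if window < 4:
        raise ParameterError(f"dust window must be >= 4, got {window}")
    bad = set(sequence) - _ALPHABET
    if bad:
        raise ValidationError(f"invalid characters in sequence: {sorted(bad)}")
    n = len(sequence)
    L = min(window, n)
    if L < 4:
        return sequence
    m = L - 2  # triplet positions per window; m - 1 >= 1 since L >= 4

    # triplet code per start position; -1 when the triplet contains N
    code4 = {"A": 0, "C": 1, "G": 2, "T": 3}
    tri = []
    for i in range(n - 2):
        a, b, c = sequence[i], sequence[i + 1], sequence[i + 2]
        if "N" in (a, b, c):
            tri.append(-1)
        else:
            tri.append(16 * code4[a] + 4 * code4[b] + code4[c])

    counts = [0] * 64
    pair_sum = 0  # sum_t c_t (c_t - 1) / 2, maintained incrementally
    masked = bytearray(n)

    def add(t: int) -> None:
        nonlocal pair_sum
        if t >= 0:
            pair_sum += counts[t]
            counts[t] += 1

    def remove(t: int) -> None:
        nonlocal pair_sum
        if t >= 0:
            counts[t] -= 1
            pair_sum -= counts[t]

    for t in tri[:m]:
        add(t)
    for start in range(0, n - L + 1):
        if pair_sum / (m - 1) > threshold:
            for i in range(start, start + L):
                masked[i] = 1
        if start < n - L:
            remove(tri[start])
            add(tri[start + m])
    if not any(masked):
        return sequence
    chars = list(sequence)
    for i, flag in enumerate(masked):
        if flag:
            chars[i] = "N"
    return "".join(chars)
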