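"""Synthetic genomes with planted, rank-nested k-mer frequency biases.

Real bacterial genomes carry taxon-characteristic biases in their 4-mer
composition (the "genomic signature"); this module emulates exactly that
statistical structure so the whole pipeline can be exercised, and its rule
recovery scored against known ground truth, without any downloads.

A nested taxonomy (phylum down to species) is drawn first; every taxon that
has siblings is assigned signature k-mers disjoint from its siblings' (and,
in this implementation, from every other signature and its reverse
complement). Each genome is an i.i.d. background sequence into which
non-overlapping copies of every signature along its lineage are planted at
random positions until the signature's target frequency — ``bias`` times
its background expectation, capped at 0.05 — is reached up to sampling
noise. Taxa without siblings at their branching point carry no signal of
their own (none is needed: the partition they induce coincides with an
ancestor's), which also keeps the total planted mass within the
saturation guard.

Everything is a deterministic function of the SimSpec seed: identical
seeds give identical taxonomies, signatures and FASTA bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .kmer_features import FeatureMatrix, all_kmers, build_matrix
from .rules import RuleModel
from .sequence_io import RANKS, GenomeRecord, reverse_complement

#: ranks from root to leaf, the reverse of RANKS
_TOP_DOWN = tuple(reversed(RANKS))  # phylum, class, order, genus, species


@dataclass
class SimSpec:
    """Study conditions for the synthetic benchmark.

    The defaults describe the standard desk-scale benchmark: 4 species
    nested in 2 genera within 2 phyla, 10 genomes per species of 50 kb,
    uniform background, and signature 4-mers enriched 5-fold over their
    background expectation.
    """

    n_phyla: int = 2
    taxa_per_level: dict[str, int] = field(
        default_factory=lambda: {"class": 1, "order": 1, "genus": 1, "species": 2}
    )
    genomes_per_species: int = 10
    genome_length: int = 50_000
    k_sig: int = 4
    n_signatures_per_taxon: int = 2
    bias: float = 5.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    max_planted_fraction: float = 0.3
    max_signature_frequency: float = 0.05

    def __post_init__(self) -> None:
        if self.n_phyla < 1:
            raise ParameterError("n_phyla must be >= 1")
        for rank in ("class", "order", "genus", "species"):
            if self.taxa_per_level.get(rank, 1) < 1:
                raise ParameterError(f"branching at {rank!r} must be >= 1")
        if self.genomes_per_species < 1:
            raise ParameterError("genomes_per_species must be >= 1")
        if self.bias < 0:
            raise ParameterError("bias must be >= 0")
        if abs(sum(self.background) - 1.0) > 1e-9 or min(self.background) < 0:
            raise ParameterError("background must be a probability vector over ACGT")


@dataclass
class PlantedSignature:
    """Ground truth: signature k-mers and target frequencies per taxon."""

    k: int
    signatures: dict[str, list[tuple[str, float]]]  # taxon -> [(kmer, target f)]

    def kmers_of(self, taxon: str) -> set[str]:
        return {kmer for kmer, _ in self.signatures.get(taxon, [])}

    def lineage_kmers(self, lineage: dict[str, str]) -> set[str]:
        """All signature k-mers planted along a lineage, with reverse complements."""
        out: set[str] = set()
        for taxon in lineage.values():
            for kmer in self.kmers_of(taxon):
                out.add(kmer)
                out.add(reverse_complement(kmer))
        return out


def _background_expectation(kmer: str, background) -> float:
    p = 1.0
    for ch in kmer:
        p *= background["ACGT".index(ch)]
    return p


def simulate_taxonomy(spec: SimSpec) -> tuple[list[dict[str, str]], PlantedSignature]:
    """Nested lineages plus the planted-signature key, deterministic in seed.

    Signature k-mers are assigned only to taxa with at least one sibling;
    all assigned words are mutually distinct and no word is another's
    reverse complement, so signatures are unambiguous under both-strand
    counting.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x7A0]))
    pool = all_kmers(spec.k_sig)
    order = rng.permutation(len(pool))
    available = [pool[i] for i in order]
    used: set[str] = set()

    def draw_signature() -> str:
        while available:
            kmer = available.pop()
            if kmer in used or reverse_complement(kmer) in used:
                continue
            used.add(kmer)
            return kmer
        raise ParameterError(
            f"not enough distinct {spec.k_sig}-mers for the requested signatures"
        )

    signatures: dict[str, list[tuple[str, float]]] = {}

    def assign(taxon: str) -> None:
        sigs = []
        for _ in range(spec.n_signatures_per_taxon):
            kmer = draw_signature()
            target = min(
                spec.bias * _background_expectation(kmer, spec.background),
                spec.max_signature_frequency,
            )
            sigs.append((kmer, target))
        signatures[taxon] = sigs

    lineages: list[dict[str, str]] = []

    def expand(prefix: dict[str, str], rank_pos: int, name_prefix: str) -> None:
        if rank_pos == len(_TOP_DOWN):
            lineages.append(dict(prefix))
            return
        rank = _TOP_DOWN[rank_pos]
        n_children = (
            spec.n_phyla if rank == "phylum" else spec.taxa_per_level.get(rank, 1)
        )
        for i in range(1, n_children + 1):
            tag = f"{rank[0].upper()}{i}"
            taxon = f"{name_prefix}{tag}" if not name_prefix else f"{name_prefix}.{tag}"
            child = dict(prefix)
            child[rank] = taxon
            if n_children > 1:
                if taxon not in signatures:
                    assign(taxon)
            expand(child, rank_pos + 1, taxon)

    expand({}, 0, "")
    return lineages, PlantedSignature(k=spec.k_sig, signatures=signatures)


def _planted_copies(target_freq: float, kmer: str, spec: SimSpec) -> int:
    n_windows = spec.genome_length - spec.k_sig + 1
    expected_bg = _background_expectation(kmer, spec.background) * n_windows
    return max(0, int(round(target_freq * n_windows - expected_bg)))


def simulate_genome(
    lineage: dict[str, str],
    spec: SimSpec,
    signatures: PlantedSignature,
    genome_index: int = 0,
    record_id: str | None = None,
) -> GenomeRecord:
    """One labeled genome: i.i.d. background plus planted lineage signatures.

    Copies of each signature are placed at uniformly random positions,
    never overlapping another planted copy; overlap with chance background
    occurrences is allowed and simply adds to the measured frequency.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 0x6E0, int(genome_index)])
    )
    L = spec.genome_length
    k = spec.k_sig

    plan: list[tuple[str, int]] = []
    for rank in _TOP_DOWN:
        taxon = lineage.get(rank)
        if taxon is None:
            continue
        for kmer, target in signatures.signatures.get(taxon, []):
            n_copies = _planted_copies(target, kmer, spec)
            if n_copies:
                plan.append((kmer, n_copies))
    planted_bases = sum(n * k for _, n in plan)
    if planted_bases > spec.max_planted_fraction * L:
        raise ParameterError(
            f"planted signature mass {planted_bases} exceeds "
            f"{spec.max_planted_fraction:.0%} of genome length {L}; "
            "reduce bias, signatures, or taxonomy depth"
        )

    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = rng.choice(bases, size=L, p=list(spec.background)).astype(np.uint8)
    occupied = np.zeros(L, dtype=bool)
    for kmer, n_copies in plan:
        word = np.frombuffer(kmer.encode(), dtype=np.uint8)
        placed = 0
        attempts = 0
        max_attempts = 200 * n_copies + 1000
        while placed < n_copies:
            attempts += 1
            if attempts > max_attempts:
                raise ParameterError(
                    f"could not place {n_copies} non-overlapping copies of {kmer}"
                )
            p = int(rng.integers(0, L - k + 1))
            if occupied[p : p + k].any():
                continue
            seq[p : p + k] = word
            occupied[p : p + k] = True
            placed += 1

    rid = record_id or f"{lineage['species']}_g{genome_index}"
    return GenomeRecord(id=rid, sequence=seq.tobytes().decode("ascii"), lineage=dict(lineage))


def simulate_dataset(spec: SimSpec) -> tuple[list[GenomeRecord], PlantedSignature]:
    """All genomes of the benchmark plus the planted-signature ground truth."""
    lineages, signatures = simulate_taxonomy(spec)
    records: list[GenomeRecord] = []
    index = 0
    for lineage in lineages:
        for g in range(spec.genomes_per_species):
            records.append(
                simulate_genome(
                    lineage,
                    spec,
                    signatures,
                    genome_index=index,
                    record_id=f"{lineage['species']}_g{g + 1}",
                )
            )
            index += 1
    return records, signatures


def benchmark_suite(
    spec: SimSpec | None = None,
    strand_mode: str = "both",
    score_config=None,
) -> tuple[FeatureMatrix, PlantedSignature]:
    """Full pipeline input: simulated genomes counted into a labeled matrix."""
    spec = spec or SimSpec()
    records, signatures = simulate_dataset(spec)
    matrix = build_matrix(records, k=spec.k_sig, strand_mode=strand_mode, score_config=score_config)
    return matrix, signatures


def recovery_score(
    models: RuleModel | list[RuleModel],
    signatures: PlantedSignature,
    lineages_by_taxon: dict[str, dict[str, str]],
) -> float:
    """Fraction of learned-rule literals whose k-mer is a planted signature.

    A literal counts as recovered when its k-mer, or its reverse
    complement, was planted somewhere along the lineage of the taxon the
    rule concludes. Returns 0.0 for models without rules.
    """
    if isinstance(models, RuleModel):
        models = [models]
    hits = 0
    total = 0
    for model in models:
        for rule in model.rules:
            lineage = lineages_by_taxon.get(rule.conclusion)
            if lineage is None:
                raise ValidationError(f"unknown taxon {rule.conclusion!r} in rule")
            truth = signatures.lineage_kmers(lineage)
            for lit in rule.literals:
                total += 1
                if lit.feature in truth:
                    hits += 1
    return hits / total if total else 0.0


def lineage_index(records_or_lineages) -> dict[str, dict[str, str]]:
    """Map every taxon name to its (partial) lineage, for recovery scoring."""
    out: dict[str, dict[str, str]] = {}
    for item in records_or_lineages:
        lineage = item.lineage if isinstance(item, GenomeRecord) else item
        for rank in RANKS:
            taxon = lineage.get(rank)
            if taxon is None:
                continue
            idx = RANKS.index(rank)
            out[taxon] = {
                r: lineage[r] for r in RANKS[idx:] if r in lineage
            }
    return out
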