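"""The planted-signature genome simulator and its ground truth."""

import numpy as np
import pytest

import kmerlogic as kl
from kmerlogic.errors import ParameterError
from kmerlogic.kmer_features import kmer_to_index


class TestSimulateTaxonomy:
    def test_nested_and_distinct(self):
        spec = kl.SimSpec(seed=0)
        lineages, sigs = kl.simulate_taxonomy(spec)
        assert len(lineages) == 4  # 2 phyla x 2 species
        species = [l["species"] for l in lineages]
        assert len(set(species)) == 4
        for l in lineages:
            assert set(l) == set(kl.RANKS)

    def test_deterministic(self):
        a = kl.simulate_taxonomy(kl.SimSpec(seed=9))
        b = kl.simulate_taxonomy(kl.SimSpec(seed=9))
        assert a[0] == b[0]
        assert a[1].signatures == b[1].signatures

    def test_sibling_signatures_disjoint(self):
        spec = kl.SimSpec(
            seed=3, n_phyla=3, taxa_per_level={"class": 2, "order": 1, "genus": 2, "species": 3}
        )
        lineages, sigs = kl.simulate_taxonomy(spec)
        all_sig_words = [w for words in sigs.signatures.values() for w, _ in words]
        # stronger than sibling-disjointness: globally distinct, and no word
        # is another's reverse complement (unambiguous under both-strand
        # counting)
        assert len(all_sig_words) == len(set(all_sig_words))
        for w in all_sig_words:
            rc = kl.reverse_complement(w)
            assert rc == w or rc not in all_sig_words

    def test_signature_pool_exhaustion(self):
        spec = kl.SimSpec(
            seed=0, n_phyla=40, k_sig=3,
            taxa_per_level={"class": 1, "order": 1, "genus": 1, "species": 1},
            n_signatures_per_taxon=2, genome_length=5000, bias=1.0,
        )
        with pytest.raises(ParameterError, match="not enough distinct"):
            kl.simulate_taxonomy(spec)


class TestSimulateGenome:
    def test_deterministic_bytes(self):
        spec = kl.SimSpec(seed=5, genome_length=5000)
        lineages, sigs = kl.simulate_taxonomy(spec)
        g1 = kl.simulate_genome(lineages[0], spec, sigs, genome_index=0)
        g2 = kl.simulate_genome(lineages[0], spec, sigs, genome_index=0)
        assert g1.sequence == g2.sequence

    def test_planted_frequency_hits_target(self):
        # forward-strand frequency of each planted species signature should
        # show the full 5-fold enrichment over the 1/256 background
        spec = kl.SimSpec(seed=6)
        records, sigs = kl.simulate_dataset(spec)
        for rec in records[:5]:
            counts, valid = kl.count_vector(rec.sequence, 4, "forward")
            for taxon in (rec.lineage["species"], rec.lineage["phylum"]):
                for kmer, target in sigs.signatures[taxon]:
                    f = counts[kmer_to_index(kmer)] / valid
                    assert 4.0 <= f * 256 <= 6.0, (rec.id, kmer, f * 256)

    def test_planted_frequency_within_20pct_of_target(self):
        spec = kl.SimSpec(seed=8)
        records, sigs = kl.simulate_dataset(spec)
        for rec in records[:10]:
            counts, valid = kl.count_vector(rec.sequence, 4, "forward")
            for taxon in set(rec.lineage.values()) & set(sigs.signatures):
                for kmer, target in sigs.signatures[taxon]:
                    f = counts[kmer_to_index(kmer)] / valid
                    assert abs(f - target) <= 0.2 * target

    def test_bias_zero_plants_nothing(self):
        # with bias 0 every 4-mer count stays at its uniform-background
        # expectation: z-scores behave like a standard normal, so across
        # 20 genomes x 256 words at most a handful may exceed 4 binomial
        # standard deviations and none should approach 6
        spec = kl.SimSpec(seed=7, bias=0.0, genome_length=20_000)
        records, sigs = kl.simulate_dataset(spec)
        p = 1 / 256
        zs = []
        for rec in records[:20]:
            counts, valid = kl.count_vector(rec.sequence, 4, "forward")
            sd = np.sqrt(valid * p * (1 - p))
            zs.append((counts - valid * p) / sd)
        zs = np.abs(np.array(zs))
        assert (zs > 4).sum() <= 6  # null expectation ~0.3, generous ceiling
        assert zs.max() < 6
        assert zs.mean() < 1.2  # no systematic inflation

    def test_saturation_guard(self):
        spec = kl.SimSpec(seed=0, bias=30.0)
        lineages, sigs = kl.simulate_taxonomy(spec)
        with pytest.raises(ParameterError, match="planted signature mass"):
            kl.simulate_genome(lineages[0], spec, sigs, genome_index=0)


class TestBenchmarkSuite:
    def test_default_shape(self, default_benchmark):
        spec, records, sigs, matrix = default_benchmark
        assert matrix.values.shape == (256, 40)
        assert len({l for l in matrix.labels["species"]}) == 4
        assert len({l for l in matrix.labels["phylum"]}) == 2

    def test_fasta_bytes_reproducible(self, tmp_path):
        spec = kl.SimSpec(seed=12, genome_length=5000)
        for name in ("a.fa", "b.fa"):
            records, _ = kl.simulate_dataset(kl.SimSpec(seed=12, genome_length=5000))
            kl.write_fasta(records, tmp_path / name)
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_chance_recovery_with_random_rules(self, small_benchmark):
        # control: rules pointing at arbitrary k-mers recover ~n_sigs/4^k
        _, records, sigs, _ = small_benchmark
        lidx = kl.lineage_index(records)
        species = sorted({r.lineage["species"] for r in records})
        rng = np.random.default_rng(0)
        kmers = kl.all_kmers(4)
        rules = [
            kl.Rule([kl.Literal.interval(kmers[int(rng.integers(256))], 0, 1)], sp)
            for sp in species
            for _ in range(50)
        ]
        model = kl.RuleModel(rules=rules, default_class=species[0])
        score = kl.recovery_score(model, sigs, lidx)
        # 4 lineage signature words + reverse complements out of 256
        expected = 8 / 256
        assert score <= expected + 3 * np.sqrt(expected * (1 - expected) / len(rules))
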