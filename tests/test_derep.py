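import numpy as np
import pytest

from halocrust.config import DereplicationParams
from halocrust.derep import (
    GenomeBin,
    dereplicate,
    estimate_completeness,
    genome_shared_fraction,
    representative_score,
)
from halocrust.scg import ARCHAEAL_SCGS, BACTERIAL_SCGS, count_scg_cassettes, scg_cassette_sequence
from halocrust.seqio import SequenceRecord
from halocrust.simulate import SimulationConfig, generate_redundant_bins, generate_species_pool


def _bin(bin_id, seqs, domain="bacteria", scg_counts=None):
    return GenomeBin(
        bin_id=bin_id, sample_id="s",
        scaffolds=[SequenceRecord(id=f"{bin_id}_{i}", sequence=s)
                   for i, s in enumerate(seqs)],
        domain_tag=domain,
        scg_counts=scg_counts or {},
    )


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestCompleteness:
    def test_full_archaeal_set_is_100(self):
        counts = {name: 1 for name in ARCHAEAL_SCGS}
        bin = _bin("a", ["ACGT"], domain="archaea", scg_counts=counts)
        assert estimate_completeness(bin) == 100.0

    def test_36_of_51_bacterial_passes_70_floor(self):
        counts = {name: 1 for name in BACTERIAL_SCGS[:36]}
        bin = _bin("b", ["ACGT"], scg_counts=counts)
        assert estimate_completeness(bin) == pytest.approx(100 * 36 / 51)
        assert estimate_completeness(bin) >= 70.0

    def test_zero_scgs_is_zero_and_excluded(self):
        bin = _bin("z", ["ACGT"], scg_counts={})
        assert estimate_completeness(bin) == 0.0
        result = dereplicate([bin])
        assert result.clusters == []
        assert result.excluded == ["z"]

    def test_unknown_domain_rejected(self):
        bin = _bin("u", ["ACGT"], domain="virus")
        with pytest.raises(ValueError, match="domain"):
            estimate_completeness(bin)

    def test_cassette_scan_matches_planted_counts(self, rng):
        names = list(BACTERIAL_SCGS[:5])
        seq = _random_seq(rng, 500)
        for name in names:
            seq += scg_cassette_sequence(name) + _random_seq(rng, 50)
        seq += scg_cassette_sequence(names[0])  # one multi-copy gene
        counts = count_scg_cassettes([seq], "bacteria")
        assert counts[names[0]] == 2
        assert all(counts[n] == 1 for n in names[1:])


class TestRepresentativeScore:
    def test_printed_formula_48_minus_6(self):
        counts = {f"g{i}": 1 for i in range(45)}
        counts.update({f"m{i}": 2 for i in range(3)})  # 48 present, 3 multi
        bin = _bin("x", ["ACGT"], scg_counts=counts)
        assert representative_score(bin) == 48 - 2 * 3

    def test_zero_scgs_scores_zero(self):
        assert representative_score(_bin("x", ["ACGT"], scg_counts={})) == 0

    def test_all_multicopy_goes_negative(self):
        counts = {f"g{i}": 2 for i in range(38)}
        assert representative_score(_bin("x", ["A"], scg_counts=counts)) == -38


class TestSharedFraction:
    def test_self_identity(self, rng):
        bin = _bin("a", [_random_seq(rng, 5000), _random_seq(rng, 3000)])
        assert genome_shared_fraction(bin, bin) == pytest.approx(1.0)

    def test_disjoint_genomes_share_nothing(self, rng):
        a = _bin("a", [_random_seq(rng, 5000)])
        b = _bin("b", [_random_seq(rng, 5000)])
        assert genome_shared_fraction(a, b) == 0.0

    def test_symmetry(self, rng):
        seq = _random_seq(rng, 8000)
        a = _bin("a", [seq])
        mutated = list(seq)
        for pos in rng.choice(8000, 40, replace=False):
            mutated[pos] = "ACGT"[(("ACGT".index(mutated[pos])) + 1) % 4]
        b = _bin("b", ["".join(mutated)[:6000]])
        assert genome_shared_fraction(a, b) == genome_shared_fraction(b, a)

    def test_simulator_dropout_pair_bases(self, rng):
        """1% mutations plus 40% scaffold dropout from one copy.

        On the larger-genome basis the shared fraction is ~0.6; on the
        default smaller-genome basis the retained scaffolds are fully
        covered, so the fraction is ~1.
        """
        scaffolds = [_random_seq(rng, 4000) for _ in range(5)]
        a = _bin("a", scaffolds)
        kept = scaffolds[:3]  # drop 2 of 5 scaffolds = 40% of nucleotides
        mutated = []
        for seq in kept:
            chars = list(seq)
            for pos in rng.choice(len(chars), int(0.01 * len(chars)), replace=False):
                chars[pos] = "ACGT"[("ACGT".index(chars[pos]) + 1) % 4]
            mutated.append("".join(chars))
        b = _bin("b", mutated)
        assert genome_shared_fraction(a, b, basis="larger") == pytest.approx(0.60, abs=0.05)
        assert genome_shared_fraction(a, b) == pytest.approx(1.0, abs=0.05)


class TestDereplicate:
    def _scored_pair(self, rng, scores=(40, 42), lengths=(6000, 6000)):
        seq = _random_seq(rng, max(lengths))
        bins = []
        for i, (score, length) in enumerate(zip(scores, lengths)):
            counts = {f"g{j}": 1 for j in range(score)}
            bins.append(_bin(f"bin{i}", [seq[:length]], scg_counts=counts))
        return bins

    def test_higher_score_becomes_representative(self, rng):
        bins = self._scored_pair(rng)
        result = dereplicate(bins, enforce_completeness=False)
        assert result.n_clusters == 1
        assert result.representatives == ["bin1"]

    def test_score_tie_broken_by_length(self, rng):
        bins = self._scored_pair(rng, scores=(40, 40), lengths=(6000, 5000))
        result = dereplicate(bins, enforce_completeness=False)
        assert result.representatives == ["bin0"]

    def test_remaining_tie_broken_lexicographically(self, rng):
        bins = self._scored_pair(rng, scores=(40, 40), lengths=(6000, 6000))
        result = dereplicate(bins, enforce_completeness=False)
        assert result.representatives == ["bin0"]

    def test_result_invariant_under_input_order(self, rng):
        cfg = SimulationConfig(
            species_per_taxon=(("Halobacteriales", "archaea", 4),
                               ("Bacteroidetes", "bacteria", 3)),
            genome_size_range=(8_000, 12_000), scaffold_count_range=(2, 3),
            seed=21,
        )
        pool = generate_species_pool(cfg)
        bins, _ = generate_redundant_bins(pool)
        forward = dereplicate(bins)
        backward = dereplicate(bins[::-1])
        assert forward.clusters == backward.clusters
        assert forward.representatives == backward.representatives

    def test_cluster_count_nonincreasing_in_threshold(self, rng):
        cfg = SimulationConfig(
            species_per_taxon=(("Halobacteriales", "archaea", 5),),
            genome_size_range=(8_000, 12_000), scaffold_count_range=(2, 3),
            seed=8,
        )
        pool = generate_species_pool(cfg)
        bins, _ = generate_redundant_bins(pool)
        counts = []
        for thr in (0.9, 0.7, 0.3, 0.05):
            params = DereplicationParams(shared_fraction_threshold=thr)
            counts.append(dereplicate(bins, params).n_clusters)
        assert counts == sorted(counts, reverse=True)

    def test_recovers_true_partition_small_scale(self):
        cfg = SimulationConfig(
            species_per_taxon=(("Halobacteriales", "archaea", 6),
                               ("Bacteroidetes", "bacteria", 5)),
            genome_size_range=(10_000, 16_000), scaffold_count_range=(2, 4),
            seed=5,
        )
        pool = generate_species_pool(cfg)
        bins, truth = generate_redundant_bins(pool)
        result = dereplicate(bins)
        assert result.n_clusters == 11
        part = result.partition()
        truth_sets = {}
        for bin_id, species in truth.items():
            if bin_id in part:
                truth_sets.setdefault(species, set()).add(bin_id)
        pred_sets = {}
        for bin_id, c in part.items():
            pred_sets.setdefault(c, set()).add(bin_id)
        assert set(map(frozenset, truth_sets.values())) == set(
            map(frozenset, pred_sets.values())
        )

    def test_empty_input_gives_empty_result(self):
        result = dereplicate([])
        assert result.clusters == [] and result.representatives == []

    def test_fixed_multiplicity_two_gives_double_bins(self):
        cfg = SimulationConfig(
            species_per_taxon=(("Halobacteriales", "archaea", 10),),
            multiplicity_probs=(0.0, 1.0, 0.0),
            genome_size_range=(8_000, 12_000), scaffold_count_range=(2, 3),
            seed=3,
        )
        pool = generate_species_pool(cfg)
        bins, truth = generate_redundant_bins(pool)
        assert len(bins) == 20
        assert len(set(truth.values())) == 10
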