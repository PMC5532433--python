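import dataclasses

import numpy as np
import pytest
from Bio.Seq import Seq

from halocrust.config import CrisprParams
from halocrust.crispr import (
    CrisprArray,
    assign_locus_types,
    canonical_orientation,
    compare_arrays,
    detect_arrays,
)
from halocrust.seqio import SequenceRecord
from halocrust.simulate import (
    ancestral_crispr_array,
    array_sequence,
    build_figure4_fixture,
    evolve_array,
)


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _arr(spacers, repeat="A" + "CGT" * 9 + "AT", sample="s", scaffold="scf", start=0):
    return CrisprArray(
        sample_id=sample, scaffold_id=scaffold, repeat_consensus=repeat,
        spacers=tuple(spacers), start=start,
        end=start + len(repeat) * (len(spacers) + 1) + sum(map(len, spacers)),
    )


class TestDetect:
    def test_planted_array_recovered(self, rng):
        repeat = _random_seq(rng, 30)
        spacers = [_random_seq(rng, 35) for _ in range(3)]
        body = repeat + "".join(s + repeat for s in spacers)
        scaffold = SequenceRecord(
            id="scf", sequence=_random_seq(rng, 500) + body + _random_seq(rng, 500)
        )
        arrays = detect_arrays(scaffold)
        assert len(arrays) == 1
        assert arrays[0].spacers == tuple(spacers)
        assert arrays[0].repeat_consensus == repeat
        assert arrays[0].start == 500
        assert arrays[0].end == 500 + len(body)

    def test_tandem_repeat_rejected(self, rng):
        repeat = _random_seq(rng, 30)
        spacer = _random_seq(rng, 35)  # identical "spacers" => tandem repeat
        body = repeat + (spacer + repeat) * 3
        scaffold = SequenceRecord(
            id="scf", sequence=_random_seq(rng, 300) + body + _random_seq(rng, 300)
        )
        assert detect_arrays(scaffold) == []

    def test_too_few_repeats_not_reported(self, rng):
        repeat = _random_seq(rng, 30)
        body = repeat + _random_seq(rng, 35) + repeat  # only 2 copies
        scaffold = SequenceRecord(
            id="scf", sequence=_random_seq(rng, 300) + body + _random_seq(rng, 300)
        )
        assert detect_arrays(scaffold) == []

    def test_reverse_complement_scaffold_detects_canonically(self, rng):
        repeat = _random_seq(rng, 30)
        spacers = [_random_seq(rng, 35) for _ in range(4)]
        body = repeat + "".join(s + repeat for s in spacers)
        fwd = SequenceRecord(
            id="fwd", sequence=_random_seq(rng, 400) + body + _random_seq(rng, 400)
        )
        rev = SequenceRecord(
            id="rev", sequence=str(Seq(fwd.sequence).reverse_complement())
        )
        a = canonical_orientation(detect_arrays(fwd)[0])
        b = canonical_orientation(detect_arrays(rev)[0])
        assert a.repeat_consensus == b.repeat_consensus
        assert a.spacers == b.spacers


class TestOrientation:
    def test_idempotent(self, rng):
        arr = _arr([_random_seq(rng, 35) for _ in range(3)],
                   repeat=_random_seq(rng, 30))
        once = canonical_orientation(arr)
        assert canonical_orientation(once) == once

    def test_array_and_reverse_complement_agree(self, rng):
        repeat = _random_seq(rng, 30)
        spacers = [_random_seq(rng, 35) for _ in range(3)]
        arr = _arr(spacers, repeat=repeat)
        flipped = _arr(
            [str(Seq(s).reverse_complement()) for s in reversed(spacers)],
            repeat=str(Seq(repeat).reverse_complement()),
        )
        assert canonical_orientation(arr).spacers == canonical_orientation(flipped).spacers

    def test_palindromic_repeat_kept_forward(self, rng):
        repeat = "ACGT" * 5  # reverse complement of ACGT... is itself
        assert str(Seq(repeat).reverse_complement()) == repeat
        arr = _arr([_random_seq(rng, 35) for _ in range(3)], repeat=repeat)
        assert canonical_orientation(arr) == arr


class TestCompare:
    def test_identical_lists(self, rng):
        spacers = [_random_seq(rng, 35) for _ in range(4)]
        rel = compare_arrays(_arr(spacers), _arr(spacers))
        assert rel.relation == "identical"
        assert rel.terminal_gap == 0
        assert rel.shared_spacer_count == 4

    def test_three_missing_leader_spacers(self, rng):
        spacers = [_random_seq(rng, 35) for _ in range(7)]
        rel = compare_arrays(_arr(spacers), _arr(spacers[3:]))
        assert rel.relation == "terminal_variant"
        assert rel.terminal_gap == 3
        # symmetric with the same gap
        rel_rev = compare_arrays(_arr(spacers[3:]), _arr(spacers))
        assert rel_rev.relation == "terminal_variant"
        assert rel_rev.terminal_gap == 3

    def test_single_internal_shared_spacer_is_distinct(self, rng):
        shared = _random_seq(rng, 35)
        a = [_random_seq(rng, 35), shared, _random_seq(rng, 35)]
        b = [_random_seq(rng, 35), shared, _random_seq(rng, 35), _random_seq(rng, 35)]
        rel = compare_arrays(_arr(a), _arr(b))
        assert rel.relation == "distinct"
        assert rel.shared_spacer_count == 1

    def test_different_repeats_always_distinct(self, rng):
        spacers = [_random_seq(rng, 35) for _ in range(4)]
        rel = compare_arrays(
            _arr(spacers, repeat=_random_seq(rng, 30)),
            _arr(spacers, repeat=_random_seq(rng, 30)),
        )
        assert rel.relation == "distinct"
        assert rel.shared_spacer_count == 4

    def test_empty_spacer_list_rejected(self, rng):
        good = _arr([_random_seq(rng, 35)])
        with pytest.raises(ValueError):
            object.__setattr__(good, "spacers", ())
            compare_arrays(good, good)


class TestTyping:
    def test_fixture_types_and_variants(self):
        fx = build_figure4_fixture()
        arrays = fx.present_arrays()
        assert len(arrays) == 20
        assert len({a.repeat_consensus for a in arrays}) == 3
        assignment = assign_locus_types(arrays)
        assert assignment.n_types() == 12
        labels = {a.sample_id: assignment.label(a.array_id) for a in arrays}
        assert labels == fx.expected_labels

    def test_fixture_group1_relations(self):
        fx = build_figure4_fixture()
        # the identical cross-site pair
        rel = compare_arrays(fx.arrays["Sw1"], fx.arrays["Qh1"])
        assert rel.relation == "identical"
        # 1a and 1b differ by four leader-end spacers
        rel_ab = compare_arrays(fx.arrays["Sw2"], fx.arrays["Sw1"])
        assert rel_ab.relation == "terminal_variant"
        assert rel_ab.terminal_gap == 4
        # 1c lacks three terminal spacer-repeat sets relative to the pair
        rel_bc = compare_arrays(fx.arrays["Qh1"], fx.arrays["Qh2"])
        assert rel_bc.relation == "terminal_variant"
        assert rel_bc.terminal_gap == 3

    def test_fixture_detection_from_scaffolds(self):
        fx = build_figure4_fixture()
        detected = []
        with_arrays = 0
        for scaffold in fx.scaffolds():
            arrays = detect_arrays(scaffold)
            if arrays:
                with_arrays += 1
            sample = scaffold.id.replace("_cyano_scaffold", "")
            detected.extend(
                canonical_orientation(dataclasses.replace(a, sample_id=sample))
                for a in arrays
            )
        assert with_arrays == 20
        assignment = assign_locus_types(detected)
        assert assignment.n_types() == 12

    def test_partition_invariant_under_input_order(self):
        fx = build_figure4_fixture()
        arrays = fx.present_arrays()
        fwd = assign_locus_types(arrays)
        rev = assign_locus_types(arrays[::-1])

        def partition(assignment, arrays):
            groups = {}
            for a in arrays:
                groups.setdefault(assignment.assignments[a.array_id][0], set()).add(
                    a.array_id
                )
            return set(map(frozenset, groups.values()))

        assert partition(fwd, arrays) == partition(rev, arrays)

    def test_turnover_descendants_stay_one_type(self, rng):
        ancestor = ancestral_crispr_array(rng)
        descendants = [
            evolve_array(ancestor, n_gains=g, n_losses=l, rng=rng, sample_id=f"d{g}{l}")
            for g, l in [(0, 0), (2, 0), (0, 2), (3, 1)]
        ]
        assignment = assign_locus_types(descendants)
        assert assignment.n_types() == 1

    def test_detection_of_embedded_evolved_arrays(self, rng):
        ancestor = ancestral_crispr_array(rng)
        seqs = []
        for i, (g, l) in enumerate([(0, 0), (2, 0)]):
            arr = evolve_array(ancestor, g, l, rng, sample_id=f"s{i}")
            seqs.append(SequenceRecord(
                id=f"s{i}", sequence=_random_seq(rng, 300) + array_sequence(arr)
                + _random_seq(rng, 300)))
        detected = [canonical_orientation(detect_arrays(s)[0]) for s in seqs]
        assert assign_locus_types(detected).n_types() == 1
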