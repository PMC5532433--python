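"""CRISPR array detection and locus typing.

A CRISPR array is a run of at least ``min_repeats`` near-identical direct
repeats (23-55 bp) separated by unique spacers (25-60 bp).  Spacer content
records infection history: arrays with identical spacer lists descend from
one recently dispersed population, and arrays differing only by extra
spacers at the leader end diverged recently by new spacer acquisition.
Loci are grouped into types when they carry the same repeat sequence and
either share at least ``type_min_shared_spacers`` spacers or are related as
identical / leader-end (terminal) variants; within a type, exact spacer-list
classes are lettered a, b, c ... by decreasing spacer count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import edlib
from Bio.Seq import Seq

from .config import CrisprParams
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrisprArray:
    sample_id: str
    scaffold_id: str
    repeat_consensus: str
    spacers: tuple[str, ...]  # leader -> trailer
    start: int  # 0-based half-open on the forward strand
    end: int
    orientation: str = "+"
    cas_label: str | None = None

    @property
    def array_id(self) -> str:
        return f"{self.sample_id}:{self.scaffold_id}:{self.start}"

    def __post_init__(self) -> None:
        if len(self.spacers) < 1:
            raise ValueError("array must have at least one spacer")


@dataclass(frozen=True)
class ArrayRelation:
    relation: str  # identical | terminal_variant | distinct
    shared_spacer_count: int
    terminal_gap: int


@dataclass
class LocusTypeAssignment:
    assignments: dict[str, tuple[int, str]]  # array_id -> (type_number, letter)
    relations: dict[tuple[str, str], ArrayRelation] = field(default_factory=dict)

    def n_types(self) -> int:
        return len({t for t, _ in self.assignments.values()})

    def label(self, array_id: str) -> str:
        t, v = self.assignments[array_id]
        return f"{t}{v}"


def _distinct_spacers(spacers: list[str]) -> bool:
    """Spacers must differ by >= 2 edits pairwise, else the run is a tandem repeat."""
    for a, b in itertools.combinations(spacers, 2):
        if a == b:
            return False
        d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        if d < 2:
            return False
    return True


def detect_arrays(
    scaffold: SequenceRecord,
    params: CrisprParams = CrisprParams(),
    sample_id: str = "",
) -> list[CrisprArray]:
    """Find repeat-spacer arrays in a scaffold.

    Seeds are exact ``min_repeat_len``-mers recurring at legal periods; each
    chain is extended in both directions while repeat columns agree across
    copies, and accepted when repeats and spacers fall in their length
    windows, the run has >= ``min_repeats`` copies, every copy is within
    ``max_repeat_mismatches`` of the consensus, and spacers are mutually
    distinct.  Overlapping detections are reduced to the longest run.
    """
    seq = scaffold.sequence
    if scaffold.alphabet != "nucleotide":
        raise ValueError("detect_arrays requires a nucleotide scaffold")
    k = params.min_repeat_len
    L = len(seq)
    if L < params.min_repeats * (k + params.min_spacer_len):
        return []
    occurrences: dict[str, list[int]] = {}
    for i in range(L - k + 1):
        occurrences.setdefault(seq[i: i + k], []).append(i)

    min_period = k + params.min_spacer_len
    max_period = params.max_repeat_len + params.max_spacer_len
    candidates: list[tuple[int, list[int], int]] = []  # (repeat_len, starts, span)
    seen_chains: set[tuple[int, ...]] = set()
    for kmer, positions in occurrences.items():
        if len(positions) < params.min_repeats:
            continue
        # maximal chains of consecutive occurrences with legal periods
        chain = [positions[0]]
        chains = []
        for p in positions[1:]:
            if min_period <= p - chain[-1] <= max_period:
                chain.append(p)
            else:
                chains.append(chain)
                chain = [p]
        chains.append(chain)
        for chain in chains:
            if len(chain) < params.min_repeats:
                continue
            key = tuple(chain)
            if key in seen_chains:
                continue
            seen_chains.add(key)
            starts, rlen = _extend_chain(seq, chain, k, params)
            if starts is None:
                continue
            candidates.append((rlen, starts, starts[-1] + rlen - starts[0]))

    arrays: list[CrisprArray] = []
    taken: list[tuple[int, int]] = []
    for rlen, starts, _span in sorted(
        candidates, key=lambda c: (-len(c[1]), -c[2], c[1][0])
    ):
        a0, a1 = starts[0], starts[-1] + rlen
        if any(not (a1 <= t0 or a0 >= t1) for t0, t1 in taken):
            continue
        copies = [seq[s: s + rlen] for s in starts]
        consensus = _consensus(copies)
        if any(_hamming(c, consensus) > params.max_repeat_mismatches for c in copies):
            continue
        spacers = [seq[starts[i] + rlen: starts[i + 1]] for i in range(len(starts) - 1)]
        if not all(
            params.min_spacer_len <= len(s) <= params.max_spacer_len for s in spacers
        ):
            continue
        if not _distinct_spacers(spacers):
            continue
        taken.append((a0, a1))
        arrays.append(
            CrisprArray(
                sample_id=sample_id,
                scaffold_id=scaffold.id,
                repeat_consensus=consensus,
                spacers=tuple(spacers),
                start=a0,
                end=a1,
            )
        )
    arrays.sort(key=lambda a: a.start)
    return arrays


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _consensus(copies: list[str]) -> str:
    out = []
    for col in zip(*copies):
        out.append(max(sorted(set(col)), key=col.count))
    return "".join(out)


def _extend_chain(
    seq: str, chain: list[int], k: int, params: CrisprParams
) -> tuple[list[int] | None, int]:
    """Grow the seed repeat left/right while all copies agree on the column."""
    starts = list(chain)
    left, right = 0, k  # repeat = [start - left, start + right)
    periods = [starts[i + 1] - starts[i] for i in range(len(starts) - 1)]

    def column_ok(offset: int) -> bool:
        cols = []
        for s in starts:
            p = s + offset
            if p < 0 or p >= len(seq):
                return False
            cols.append(seq[p])
        return len(set(cols)) == 1

    while (
        right + left < params.max_repeat_len
        and min(periods) - (right + left) > params.min_spacer_len
        and column_ok(right)
    ):
        right += 1
    while (
        right + left < params.max_repeat_len
        and min(periods) - (right + left) > params.min_spacer_len
        and column_ok(-left - 1)
    ):
        left += 1
    rlen = right + left
    if not (params.min_repeat_len <= rlen <= params.max_repeat_len):
        return None, 0
    return [s - left for s in starts], rlen


def canonical_orientation(array: CrisprArray) -> CrisprArray:
    """Orient by the lexicographically smaller of repeat and its complement.

    When flipped, spacers are reverse-complemented and their order reversed;
    the operation is idempotent.  A palindromic repeat keeps the forward
    orientation (logged).
    """
    rc = str(Seq(array.repeat_consensus).reverse_complement())
    if array.repeat_consensus < rc:
        return array
    if array.repeat_consensus == rc:
        logger.warning("palindromic repeat on %s; keeping forward orientation",
                       array.scaffold_id)
        return array
    flipped = tuple(
        str(Seq(s).reverse_complement()) for s in reversed(array.spacers)
    )
    return replace(
        array,
        repeat_consensus=rc,
        spacers=flipped,
        orientation="-" if array.orientation == "+" else "+",
    )


def compare_arrays(a: CrisprArray, b: CrisprArray) -> ArrayRelation:
    """Classify the relation between two canonical arrays.

    identical: equal spacer lists.  terminal_variant: one list equals the
    other plus extra leader-end spacers, or both share a contiguous
    trailer-anchored block and differ only at the leader end; terminal_gap
    counts the leader spacers not in the shared block.  Everything else
    (including different repeat sequences) is distinct.
    """
    if not a.spacers or not b.spacers:
        raise ValueError("cannot compare an array with an empty spacer list")
    shared = len(set(a.spacers) & set(b.spacers))
    if a.repeat_consensus != b.repeat_consensus:
        return ArrayRelation("distinct", shared, 0)
    if a.spacers == b.spacers:
        return ArrayRelation("identical", shared, 0)
    # longest common trailer-anchored suffix
    s = 0
    while (
        s < len(a.spacers) and s < len(b.spacers)
        and a.spacers[-1 - s] == b.spacers[-1 - s]
    ):
        s += 1
    if s >= 1:
        gap = (len(a.spacers) - s) + (len(b.spacers) - s)
        # differences must be confined to the leader end: the non-shared
        # leader prefixes share no spacer with each other
        lead_a = set(a.spacers[: len(a.spacers) - s])
        lead_b = set(b.spacers[: len(b.spacers) - s])
        if not lead_a & lead_b:
            return ArrayRelation("terminal_variant", shared, gap)
    return ArrayRelation("distinct", shared, 0)


def assign_locus_types(
    arrays: list[CrisprArray],
    params: CrisprParams = CrisprParams(),
) -> LocusTypeAssignment:
    """Group canonical arrays into locus types and letter their variants.

    Two arrays are linked when they carry the same repeat consensus and are
    identical, terminal variants, or share >= ``type_min_shared_spacers``
    spacers; connected components are types, numbered 1..k by first
    appearance in the input.  Within a type, exact-spacer-list classes are
    lettered by decreasing spacer count (ties by spacer content, then id).
    Optional cas labels must agree within a type (warning otherwise).
    """
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate array ids")
    relations: dict[tuple[str, str], ArrayRelation] = {}
    parent = {i: i for i in range(len(arrays))}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(len(arrays)), 2):
        rel = compare_arrays(arrays[i], arrays[j])
        relations[(ids[i], ids[j])] = rel
        linked = (
            arrays[i].repeat_consensus == arrays[j].repeat_consensus
            and (
                rel.relation in ("identical", "terminal_variant")
                or rel.shared_spacer_count >= params.type_min_shared_spacers
            )
        )
        if linked:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

    components: dict[int, list[int]] = {}
    for i in range(len(arrays)):
        components.setdefault(find(i), []).append(i)
    # type numbers by first appearance
    ordered_roots = sorted(components, key=lambda r: min(components[r]))
    assignments: dict[str, tuple[int, str]] = {}
    for type_number, root in enumerate(ordered_roots, start=1):
        members = components[root]
        cas = {arrays[i].cas_label for i in members if arrays[i].cas_label}
        if len(cas) > 1:
            logger.warning("conflicting cas labels within type %d: %s", type_number, cas)
        classes: dict[tuple[str, ...], list[int]] = {}
        for i in members:
            classes.setdefault(arrays[i].spacers, []).append(i)
        ordered_classes = sorted(
            classes, key=lambda sp: (-len(sp), sp, min(ids[i] for i in classes[sp]))
        )
        for letter_idx, spacers in enumerate(ordered_classes):
            letter = _letter(letter_idx)
            for i in classes[spacers]:
                assignments[ids[i]] = (type_number, letter)
    return LocusTypeAssignment(assignments=assignments, relations=relations)


def _letter(idx: int) -> str:
    out = ""
    idx += 1
    while idx:
        idx, rem = divmod(idx - 1, 26)
        out = chr(ord("a") + rem) + out
    return out
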