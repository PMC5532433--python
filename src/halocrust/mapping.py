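"""Stringent end-to-end read mapping (Hamming placement, no indels).

A read counts toward a reference iff its best end-to-end placement, on either
strand, has at most floor(max_mismatch_fraction * read_length) mismatches —
three mismatches on a 100 bp read, i.e. 97% similarity to the template.
Seeding uses the pigeonhole principle: the read is split into
(max_mismatches + 1) chunks, at least one of which must match the reference
exactly for an acceptable placement, so the chunk index finds every candidate
and acceptance is exact, not heuristic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmers import encode, kmer_codes
from .config import MappingParams
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)


@dataclass
class CoverageResult:
    """Per-reference per-nucleotide depth for one sample's reads."""

    depths: dict[str, np.ndarray]
    total_reads: int
    mapped_reads: float = 0.0
    reference_lengths: dict[str, int] = field(default_factory=dict)

    def mean_depth(self, ref_id: str) -> float:
        d = self.depths[ref_id]
        return float(d.mean()) if len(d) else 0.0

    def breadth(self, ref_id: str) -> float:
        d = self.depths[ref_id]
        return float((d > 0).mean()) if len(d) else 0.0


class ReferenceIndex:
    """Sorted chunk-k-mer index over a set of reference sequences."""

    def __init__(self, references: list[SequenceRecord], chunk_len: int):
        self.chunk_len = chunk_len
        self.ref_ids = [r.id for r in references]
        self.arrays = {r.id: encode(r.sequence) for r in references}
        self.lengths = {r.id: len(r.sequence) for r in references}
        codes, refs, positions = [], [], []
        for idx, r in enumerate(references):
            c = kmer_codes(self.arrays[r.id], chunk_len)
            codes.append(c)
            refs.append(np.full(len(c), idx, dtype=np.int32))
            positions.append(np.arange(len(c), dtype=np.int32))
        self.codes = np.concatenate(codes) if codes else np.empty(0, np.uint64)
        self.refs = np.concatenate(refs) if refs else np.empty(0, np.int32)
        self.positions = (
            np.concatenate(positions) if positions else np.empty(0, np.int32)
        )
        order = np.argsort(self.codes, kind="stable")
        self.codes = self.codes[order]
        self.refs = self.refs[order]
        self.positions = self.positions[order]


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def _best_placements(
    read_arr: np.ndarray, index: ReferenceIndex, max_mm: int
) -> tuple[int, set[tuple[int, int]]]:
    """(best mismatch count, {(ref_idx, pos)}) over all candidate placements."""
    L = len(read_arr)
    c = index.chunk_len
    n_chunks = max_mm + 1
    best = max_mm + 1
    placements: set[tuple[int, int]] = set()
    seen: set[tuple[int, int]] = set()
    for chunk_idx in range(n_chunks):
        offset = chunk_idx * c
        if offset + c > L:
            break
        code = kmer_codes(read_arr[offset: offset + c], c)
        if not len(code):
            continue
        lo = np.searchsorted(index.codes, code[0], side="left")
        hi = np.searchsorted(index.codes, code[0], side="right")
        for j in range(lo, hi):
            ref_idx = int(index.refs[j])
            pos = int(index.positions[j]) - offset
            key = (ref_idx, pos)
            if key in seen:
                continue
            seen.add(key)
            ref_arr = index.arrays[index.ref_ids[ref_idx]]
            if pos < 0 or pos + L > len(ref_arr):
                continue
            mm = int((ref_arr[pos: pos + L] != read_arr).sum())
            if mm < best:
                best = mm
                placements = {key}
            elif mm == best:
                placements.add(key)
    return best, placements


def map_reads(
    reads: list[SequenceRecord],
    references: list[SequenceRecord],
    params: MappingParams = MappingParams(),
    index: ReferenceIndex | None = None,
) -> CoverageResult:
    """Map reads end-to-end and accumulate per-nucleotide depth.

    Mates of a pair are mapped independently.  A read with equal-best
    placements on several references is counted fractionally (1/k per
    reference) under the default policy, or dropped under ``discard``.
    Equal-best placements within one reference count once, at the smallest
    coordinate.  References shorter than a read are skipped for that read.
    """
    if not references:
        raise ValueError("no references")
    usable = references
    if reads:
        max_len = max(len(r) for r in reads)
        short = [r.id for r in references if len(r) < max_len]
        if short:
            logger.warning("references shorter than the longest read: %s", short)
    chunk_len = None
    for read in reads:
        n_chunks = params.max_mismatches(len(read)) + 1
        cl = len(read) // n_chunks
        chunk_len = cl if chunk_len is None else min(chunk_len, cl)
    if chunk_len is None:
        chunk_len = params.seed_kmer
    chunk_len = min(chunk_len, params.seed_kmer)
    if index is None or index.chunk_len != chunk_len:
        index = ReferenceIndex(usable, chunk_len)

    depths = {r.id: np.zeros(len(r), dtype=float) for r in usable}
    mapped = 0.0
    for read in reads:
        arr = encode(read.sequence)
        max_mm = params.max_mismatches(len(read))
        fwd_best, fwd_pl = _best_placements(arr, index, max_mm)
        rev_best, rev_pl = _best_placements(_revcomp_codes(arr), index, max_mm)
        if fwd_best < rev_best:
            best, placements, rc = fwd_best, fwd_pl, False
        elif rev_best < fwd_best:
            best, placements, rc = rev_best, rev_pl, True
        else:
            best, placements, rc = fwd_best, fwd_pl | rev_pl, None
        if best > max_mm or not placements:
            continue
        by_ref: dict[int, int] = {}
        for ref_idx, pos in placements:
            if ref_idx not in by_ref or pos < by_ref[ref_idx]:
                by_ref[ref_idx] = pos
        if len(by_ref) > 1 and params.ambiguous_policy == "discard":
            continue
        w = 1.0 / len(by_ref)
        for ref_idx, pos in by_ref.items():
            depths[index.ref_ids[ref_idx]][pos: pos + len(read)] += w
        mapped += 1.0
    return CoverageResult(
        depths=depths,
        total_reads=len(reads),
        mapped_reads=mapped,
        reference_lengths=dict(index.lengths),
    )
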