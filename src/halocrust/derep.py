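"""Species-level genome de-replication.

Bins whose scaffolds align at >= 98% nucleotide identity over more than 70%
of the smaller genome's nucleotides are grouped (single linkage, since the
pairwise grouping rule is transitive by construction), and one representative
per group is kept: the bin maximizing

    score = (number of single copy genes) - 2 * (number of multi-copy SCGs),

ties broken by greatest total length, then lexicographic bin id.  The
alignment engine is desk-scale: exact 15-mer anchors voted onto gapless
diagonals, with >= 98% identity required per aligned block (substitutions
only; the read simulator introduces no indels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._kmers import encode as _encode
from ._kmers import kmer_codes as _kmer_codes
from .config import DereplicationParams
from .scg import SCG_SETS, count_scg_cassettes
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

_BLOCK = 500  # identity is assessed per aligned block of this many bp


@dataclass
class GenomeBin:
    """A set of scaffolds with domain tag and SCG occurrence counts."""

    bin_id: str
    sample_id: str
    scaffolds: list[SequenceRecord]
    domain_tag: str
    scg_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.scg_counts.values()):
            raise ValueError("SCG counts must be >= 0")

    @property
    def total_length_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    def count_scgs(self) -> "GenomeBin":
        """Populate scg_counts by scanning scaffolds for the domain's cassettes."""
        self.scg_counts = count_scg_cassettes(
            [s.sequence for s in self.scaffolds], self.domain_tag
        )
        return self


@dataclass
class DereplicationResult:
    clusters: list[list[str]]  # bin_ids, one list per cluster
    representatives: list[str]  # aligned with clusters
    scores: dict[str, int]
    shared_fractions: dict[tuple[str, str], float]
    excluded: list[str]  # bins below the completeness floor

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def partition(self) -> dict[str, int]:
        """bin_id -> cluster index."""
        return {b: i for i, members in enumerate(self.clusters) for b in members}


def estimate_completeness(bin: GenomeBin) -> float:
    """Percent of the domain's SCG set present at least once."""
    if bin.domain_tag not in SCG_SETS:
        raise ValueError(f"unknown domain_tag {bin.domain_tag!r} for bin {bin.bin_id}")
    universe = SCG_SETS[bin.domain_tag]
    present = sum(1 for name in universe if bin.scg_counts.get(name, 0) >= 1)
    return 100.0 * present / len(universe)


def representative_score(bin: GenomeBin) -> int:
    """SCG presence count minus twice the multi-copy SCG count."""
    present = sum(1 for v in bin.scg_counts.values() if v >= 1)
    multi = sum(1 for v in bin.scg_counts.values() if v >= 2)
    return present - 2 * multi


class _BinIndex:
    """Sorted k-mer codes of all scaffolds of a bin, for anchor lookup."""

    def __init__(self, bin: GenomeBin, k: int):
        self.bin = bin
        self.k = k
        self.arrays = [_encode(s.sequence) for s in bin.scaffolds]
        codes, scafs, positions = [], [], []
        for idx, arr in enumerate(self.arrays):
            c = _kmer_codes(arr, k)
            codes.append(c)
            scafs.append(np.full(len(c), idx, dtype=np.int32))
            positions.append(np.arange(len(c), dtype=np.int32))
        self.codes = np.concatenate(codes) if codes else np.empty(0, dtype=np.uint64)
        self.scafs = np.concatenate(scafs) if scafs else np.empty(0, dtype=np.int32)
        self.positions = (
            np.concatenate(positions) if positions else np.empty(0, dtype=np.int32)
        )
        order = np.argsort(self.codes, kind="stable")
        self.codes = self.codes[order]
        self.scafs = self.scafs[order]
        self.positions = self.positions[order]

    def sketch(self, step: int = 16) -> set[int]:
        return set(self.codes[::step].tolist())


def _covered_blocks(qarr: np.ndarray, tarr: np.ndarray, diag: int,
                    identity_threshold: float, covered: np.ndarray) -> None:
    """Mark query positions covered by the gapless alignment on ``diag``.

    ``diag = qpos - tpos``.  The full overlap window is split into blocks of
    ~500 bp; a block is accepted (marked covered) iff its identity meets the
    threshold.
    """
    q0 = max(0, diag)
    q1 = min(len(qarr), len(tarr) + diag)
    if q1 - q0 < 1:
        return
    q = qarr[q0:q1]
    t = tarr[q0 - diag: q1 - diag]
    eq = q == t
    n = len(eq)
    n_blocks = max(1, round(n / _BLOCK))
    bounds = np.linspace(0, n, n_blocks + 1).astype(int)
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b > a and eq[a:b].mean() >= identity_threshold:
            covered[q0 + a: q0 + b] = True


def genome_shared_fraction(
    a: GenomeBin,
    b: GenomeBin,
    params: DereplicationParams = DereplicationParams(),
    basis: str = "smaller",
    _indices: dict | None = None,
) -> float:
    """Fraction of a bin's nucleotides aligned at >= 98% identity.

    Every scaffold of the smaller bin is aligned against the other bin via
    exact k-mer anchors grouped by gapless diagonal; accepted blocks mark
    coverage.  With the default ``basis="smaller"`` the fraction is
    covered / total over the smaller bin (tolerant of completeness
    differences between true replicates and symmetric by construction);
    ``basis="larger"`` divides by the larger bin instead.
    """
    small, large = (a, b) if a.total_length_bp <= b.total_length_bp else (b, a)
    if small.total_length_bp == 0 or large.total_length_bp == 0:
        raise ValueError("bins must be non-empty")
    k = params.anchor_k

    def get_index(bin: GenomeBin) -> _BinIndex:
        if _indices is None:
            return _BinIndex(bin, k)
        if bin.bin_id not in _indices:
            _indices[bin.bin_id] = _BinIndex(bin, k)
        return _indices[bin.bin_id]

    qidx = get_index(small)
    tidx = get_index(large)
    covered_total = 0
    for arr in qidx.arrays:
        covered = np.zeros(len(arr), dtype=bool)
        qcodes = _kmer_codes(arr, k)
        if len(qcodes):
            step = 4
            sub = qcodes[::step]
            qpos = np.arange(0, len(qcodes), step, dtype=np.int64)
            lo = np.searchsorted(tidx.codes, sub, side="left")
            hi = np.searchsorted(tidx.codes, sub, side="right")
            hits = hi > lo
            seen: set[tuple[int, int]] = set()
            for qp, l, h in zip(qpos[hits], lo[hits], hi[hits]):
                for j in range(l, min(h, l + 4)):  # cap repeated-kmer fanout
                    key = (int(tidx.scafs[j]), int(qp) - int(tidx.positions[j]))
                    if key in seen:
                        continue
                    seen.add(key)
                    _covered_blocks(
                        arr, tidx.arrays[key[0]], key[1],
                        params.identity_threshold, covered,
                    )
        covered_total += int(covered.sum())
    if basis == "smaller":
        return covered_total / small.total_length_bp
    if basis == "larger":
        return covered_total / large.total_length_bp
    raise ValueError(f"unknown basis {basis!r}")


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def dereplicate(
    bins: list[GenomeBin],
    params: DereplicationParams = DereplicationParams(),
    enforce_completeness: bool = True,
) -> DereplicationResult:
    """Group bins into species-level clusters and pick representatives.

    Single-linkage grouping on pairwise shared fraction strictly greater than
    ``shared_fraction_threshold``; candidate pairs are pre-filtered by shared
    k-mer sketches, so unrelated genomes are never aligned.  Deterministic and
    invariant under input-order permutation (clusters sorted by smallest
    member id).
    """
    if not bins:
        return DereplicationResult([], [], {}, {}, [])
    ids = [b.bin_id for b in bins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate bin ids")

    kept: list[GenomeBin] = []
    excluded: list[str] = []
    for bin in bins:
        if enforce_completeness and estimate_completeness(bin) < 100 * params.completeness_floor:
            excluded.append(bin.bin_id)
        else:
            kept.append(bin)
    if excluded:
        logger.info("excluded %d bins below completeness floor", len(excluded))
    if not kept:
        return DereplicationResult([], [], {}, {}, sorted(excluded))

    by_id = {b.bin_id: b for b in kept}
    indices: dict[str, _BinIndex] = {
        b.bin_id: _BinIndex(b, params.anchor_k) for b in kept
    }
    sketches = {bid: idx.sketch() for bid, idx in indices.items()}

    uf = _UnionFind(sorted(by_id))
    shared: dict[tuple[str, str], float] = {}
    ordered = sorted(by_id)
    for i, bi in enumerate(ordered):
        for bj in ordered[i + 1:]:
            if len(sketches[bi] & sketches[bj]) < 5:
                continue
            frac = genome_shared_fraction(by_id[bi], by_id[bj], params, _indices=indices)
            shared[(bi, bj)] = frac
            if frac > params.shared_fraction_threshold:
                uf.union(bi, bj)

    groups: dict[str, list[str]] = {}
    for bid in ordered:
        groups.setdefault(uf.find(bid), []).append(bid)
    clusters = [sorted(members) for _, members in sorted(groups.items())]

    scores = {b.bin_id: representative_score(b) for b in kept}
    representatives = []
    for members in clusters:
        best = min(
            members,
            key=lambda bid: (-scores[bid], -by_id[bid].total_length_bp, bid),
        )
        tied = [
            m for m in members
            if scores[m] == scores[best]
            and by_id[m].total_length_bp == by_id[best].total_length_bp
        ]
        if len(tied) > 1:
            logger.info("representative tie among %s resolved lexicographically", tied)
        representatives.append(best)
    return DereplicationResult(clusters, representatives, scores, shared, sorted(excluded))
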