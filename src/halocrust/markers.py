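"""Marker-gene profiling: ORF scanning, rpS3 hits, clustering, nif screen.

The rpS3 ribosomal protein is single-copy and universal, so the number of
distinct rpS3 sequences in an assembly estimates the number of community
members, and the coverage of the scaffold carrying each rpS3 gene estimates
that member's abundance.  Hits must fall in the 120-450 aa length window and
reach the per-domain bit-score cutoff (bacteria 111, archaea 172, eukaryotes
175); each ORF is assigned to the domain of its best-scoring profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from Bio.Seq import Seq

from .config import MarkerCutoffs
from .profile import ProfileModel, score_sequence
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

# tie-break priority when two domain profiles give equal bit scores
_DOMAIN_PRIORITY = {"bacteria": 0, "archaea": 1, "eukaryote": 2}


@dataclass(frozen=True)
class Orf:
    """A predicted open reading frame, 0-based half-open forward-strand coords."""

    scaffold_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    protein: str
    sample_id: str = ""


@dataclass
class MarkerHit:
    scaffold_id: str
    sample_id: str
    protein: str
    length_aa: int
    bit_score: float
    domain_tag: str
    scaffold_coverage: float


@dataclass
class MarkerCluster:
    cluster_id: str
    centroid: MarkerHit
    members: list[MarkerHit]

    def coverage_by_sample(self) -> dict[str, float]:
        cov: dict[str, float] = {}
        for hit in self.members:
            cov[hit.sample_id] = cov.get(hit.sample_id, 0.0) + hit.scaffold_coverage
        return cov


def find_orfs(
    scaffold: SequenceRecord, min_len_aa: int, sample_id: str = ""
) -> list[Orf]:
    """All maximal stop-to-stop reading frames on both strands.

    Frames are translated with the standard genetic code; segments between
    stops (including open-ended segments at frame boundaries) of at least
    ``min_len_aa`` residues are reported with 0-based half-open coordinates
    on the forward strand.
    """
    if scaffold.alphabet != "nucleotide":
        raise ValueError(f"scaffold {scaffold.id!r} is not nucleotide")
    seq = scaffold.sequence
    L = len(seq)
    orfs: list[Orf] = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            usable = (len(s) - frame) // 3 * 3
            if usable <= 0:
                continue
            protein = str(Seq(s[frame: frame + usable]).translate())
            pos = 0
            for segment in protein.split("*"):
                if len(segment) >= min_len_aa and "X" not in segment:
                    nt_start = frame + 3 * pos
                    nt_end = nt_start + 3 * len(segment)
                    if strand == "+":
                        start, end = nt_start, nt_end
                    else:
                        start, end = L - nt_end, L - nt_start
                    orfs.append(
                        Orf(scaffold.id, start, end, strand, segment, sample_id)
                    )
                pos += len(segment) + 1
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


class CoverageMissingError(KeyError):
    pass


def find_rps3(
    profiles: Mapping[str, ProfileModel],
    orfs: Iterable[Orf],
    cutoffs: MarkerCutoffs,
    scaffold_coverage: Mapping[tuple[str, str], float],
) -> list[MarkerHit]:
    """Score ORFs against the three domain profiles and apply the cutoffs.

    ``scaffold_coverage`` maps (scaffold_id, sample_id) to the fold coverage
    of the assembled scaffold, which becomes the hit's abundance proxy.
    A hit is kept iff its length is within the window and its best domain
    score reaches that domain's cutoff.
    """
    hits: list[MarkerHit] = []
    for orf in orfs:
        n = len(orf.protein)
        if not (cutoffs.min_len_aa <= n <= cutoffs.max_len_aa):
            continue
        scored = sorted(
            ((score_sequence(p, orf.protein), tag) for tag, p in profiles.items()),
            key=lambda t: (-t[0], _DOMAIN_PRIORITY.get(t[1], 99)),
        )
        best_score, best_tag = scored[0]
        if len(scored) > 1 and scored[1][0] == best_score:
            logger.warning(
                "domain tie for ORF on %s: %s kept by priority", orf.scaffold_id, best_tag
            )
        if best_score < cutoffs.score_cutoffs[best_tag]:
            continue
        key = (orf.scaffold_id, orf.sample_id)
        if key not in scaffold_coverage:
            raise CoverageMissingError(
                f"no coverage for scaffold {orf.scaffold_id!r} in sample {orf.sample_id!r}"
            )
        hits.append(
            MarkerHit(
                scaffold_id=orf.scaffold_id,
                sample_id=orf.sample_id,
                protein=orf.protein,
                length_aa=n,
                bit_score=float(best_score),
                domain_tag=best_tag,
                scaffold_coverage=float(scaffold_coverage[key]),
            )
        )
    return hits


def protein_identity(a: str, b: str) -> float:
    """Global (Needleman-Wunsch) identity: 1 - edit_distance / max(len)."""
    if a == b:
        return 1.0
    dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def cluster_markers(
    hits: Sequence[MarkerHit], identity_threshold: float = 0.99
) -> list[MarkerCluster]:
    """Greedy length-sorted centroid clustering (cluster_fast style).

    Hits are sorted by decreasing length (ties by scaffold then sample id);
    each joins the first existing centroid within ``identity_threshold``
    global identity, else founds a new cluster.  The centroid is therefore
    always the longest member.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity threshold must be in (0, 1], got {identity_threshold}")
    if not hits:
        raise ValueError("no hits to cluster")
    ordered = sorted(hits, key=lambda h: (-h.length_aa, h.scaffold_id, h.sample_id))
    clusters: list[MarkerCluster] = []
    for hit in ordered:
        for cluster in clusters:
            if protein_identity(hit.protein, cluster.centroid.protein) >= identity_threshold:
                cluster.members.append(hit)
                break
        else:
            clusters.append(
                MarkerCluster(
                    cluster_id=f"rps3_{len(clusters):04d}", centroid=hit, members=[hit]
                )
            )
    return clusters


def clusters_to_table(clusters: Sequence[MarkerCluster]) -> pd.DataFrame:
    rows = []
    for cluster in clusters:
        for hit in cluster.members:
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "sample_id": hit.sample_id,
                    "scaffold_id": hit.scaffold_id,
                    "length_aa": hit.length_aa,
                    "bit_score": round(hit.bit_score, 2),
                    "domain": hit.domain_tag,
                    "coverage": hit.scaffold_coverage,
                }
            )
    return pd.DataFrame(rows)


def screen_nitrogenase(
    nif_profiles: Sequence[ProfileModel],
    proteomes: Mapping[str, Sequence[str]],
    expected_profiles: int = 14,
) -> pd.DataFrame:
    """Screen per-sample proteomes against the nitrogenase profile set.

    Each profile applies its own noise cutoff (``score_cutoff_bits``).
    Returns a samples x profiles table of hit counts with a boolean
    ``any_nif`` column; an empty proteome map yields an empty table.
    """
    if len(nif_profiles) != expected_profiles:
        warnings.warn(
            f"expected {expected_profiles} nitrogenase profiles, got {len(nif_profiles)}",
            stacklevel=2,
        )
    rows = {}
    for sample_id, proteins in proteomes.items():
        counts = {}
        for prof in nif_profiles:
            counts[prof.name] = sum(
                1
                for protein in proteins
                if protein and score_sequence(prof, protein) >= prof.score_cutoff_bits
            )
        counts["any_nif"] = any(v > 0 for k, v in counts.items() if k != "any_nif")
        rows[sample_id] = counts
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df
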