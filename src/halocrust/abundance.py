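"""Relative abundance, presence/occupancy and rank-abundance statistics.

Mean per-nucleotide coverage of each representative genome is computed per
sample and then sum-normalized across samples using the total number of reads
used for the mapping: each sample's column is scaled by (reference sample
read count / own read count), where the reference is the deepest sample, so
sequencing-effort differences cancel while within-sample ratios are
preserved.  An organism is "present" in a sample when its normalized coverage
reaches the presence threshold (default 1.0 fold); sample-specific means
present in exactly one sample, site-specific in exactly one site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .manifest import SampleManifest
from .mapping import CoverageResult

logger = logging.getLogger(__name__)


@dataclass
class AbundanceMatrix:
    """Organisms x samples normalized coverage plus the read counts used."""

    values: pd.DataFrame  # index: organism ids, columns: sample ids
    total_reads: dict[str, int]

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("abundance entries must be >= 0")

    @property
    def organisms(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class OrganismOccupancy:
    organism_id: str
    n_samples: int
    n_sites: int
    sites: frozenset[str]


@dataclass
class OccupancyStats:
    per_organism: dict[str, OrganismOccupancy]
    fraction_sample_specific: float
    fraction_site_specific: float


def relative_abundance(
    coverage: Mapping[str, CoverageResult],
) -> AbundanceMatrix:
    """Build the normalized organisms x samples abundance matrix.

    ``coverage`` maps sample_id to that sample's mapping result.  Entry =
    mean per-nucleotide depth x (max sample read count / sample read count).
    Zero-read samples yield an all-zero column with a warning.
    """
    if not coverage:
        raise ValueError("no coverage results")
    samples = list(coverage)
    organisms = sorted({ref for cov in coverage.values() for ref in cov.depths})
    total_reads = {s: coverage[s].total_reads for s in samples}
    ref_total = max(total_reads.values())
    data = {}
    for s in samples:
        n = total_reads[s]
        if n == 0:
            logger.warning("sample %s has zero reads; abundance column is zero", s)
            data[s] = [0.0] * len(organisms)
            continue
        scale = ref_total / n
        data[s] = [
            coverage[s].mean_depth(org) * scale if org in coverage[s].depths else 0.0
            for org in organisms
        ]
    values = pd.DataFrame(data, index=organisms)
    return AbundanceMatrix(values=values, total_reads=total_reads)


def occupancy(
    matrix: AbundanceMatrix,
    manifest: SampleManifest,
    presence_min_coverage: float = 1.0,
) -> OccupancyStats:
    """Tally per-organism sample/site presence and aggregate specificity.

    Organisms absent from every sample are excluded from the aggregate
    fractions (with a warning); for any present organism one sample implies
    one site, so the sample-specific fraction never exceeds the site-specific
    fraction.
    """
    unknown = [s for s in matrix.samples if s not in manifest.sample_ids]
    if unknown:
        raise ValueError(f"samples not in manifest: {unknown}")
    per: dict[str, OrganismOccupancy] = {}
    absent = []
    for org in matrix.organisms:
        row = matrix.values.loc[org]
        present = [s for s in matrix.samples if row[s] >= presence_min_coverage]
        if not present:
            absent.append(org)
            continue
        sites = frozenset(manifest.site_of(s) for s in present)
        per[org] = OrganismOccupancy(
            organism_id=org,
            n_samples=len(present),
            n_sites=len(sites),
            sites=sites,
        )
    if absent:
        logger.warning("%d organisms present in no sample were excluded", len(absent))
    n = len(per)
    frac_sample = sum(1 for o in per.values() if o.n_samples == 1) / n if n else 0.0
    frac_site = sum(1 for o in per.values() if o.n_sites == 1) / n if n else 0.0
    return OccupancyStats(
        per_organism=per,
        fraction_sample_specific=frac_sample,
        fraction_site_specific=frac_site,
    )


def rank_abundance(
    matrix: AbundanceMatrix,
    site_id: str,
    manifest: SampleManifest,
) -> dict[str, pd.DataFrame]:
    """Per-sample rank-abundance tables for one site.

    Organisms are sorted by decreasing abundance (ties by organism id) and
    assigned ranks 1..n.
    """
    site_samples = [
        s.sample_id for s in manifest.samples
        if s.site_id == site_id and s.sample_id in matrix.samples
    ]
    if not site_samples:
        raise ValueError(f"no samples for site {site_id!r}")
    out = {}
    for sample in site_samples:
        col = matrix.values[sample]
        rows = sorted(
            ((org, float(col[org])) for org in matrix.organisms),
            key=lambda t: (-t[1], t[0]),
        )
        out[sample] = pd.DataFrame(
            {
                "rank": range(1, len(rows) + 1),
                "organism": [r[0] for r in rows],
                "abundance": [r[1] for r in rows],
            }
        )
    return out
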