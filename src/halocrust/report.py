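"""Occupancy summary tables in the style of the survey's taxon table.

The summary has one row per taxon and reports, as integer percentages
(rounded half-up, with exact zeros rendered as a dash): how many of the
taxon's populations are restricted to a single site, to a single sample, to
each individual site, shared by all sites, or shared by exactly one pair of
sites.  Every organism falls in exactly one site-combination category, so the
"only"/"all"/"pairwise" percentages of a row account for every population.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Mapping

import pandas as pd

from .manifest import SampleManifest


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties upward (0.5 -> 1, 1.5 -> 2)."""
    return int(math.floor(x + 0.5))


class TaxonomyError(ValueError):
    """Raised when organisms lack a taxon assignment."""


def summarize_taxon_table(
    occupancy: "OccupancyStats",
    taxonomy: Mapping[str, str],
    manifest: SampleManifest,
) -> pd.DataFrame:
    """Tabulate occupancy categories per taxon.

    Parameters
    ----------
    occupancy : OccupancyStats
        Per-organism presence tallies (see :mod:`halocrust.abundance`).
    taxonomy : mapping organism_id -> taxon label
        Must cover every organism present in the occupancy stats.
    manifest : SampleManifest
        Supplies the site roster; sites are ordered as in the manifest
        (wettest first in the bundled design).

    Returns
    -------
    DataFrame with integer percentage columns and a ``TOTAL`` row whose
    ``total_populations`` is the grand total of organisms.
    """
    organisms = list(occupancy.per_organism.keys())
    missing = [o for o in organisms if o not in taxonomy]
    if missing:
        raise TaxonomyError(f"organisms without taxon: {sorted(missing)}")

    site_ids = [s.site_id for s in manifest.sites]
    pairs = [
        (site_ids[i], site_ids[j])
        for i in range(len(site_ids))
        for j in range(i + 1, len(site_ids))
    ]

    taxa: dict[str, dict[str, int]] = {}
    for org in organisms:
        stats = occupancy.per_organism[org]
        taxon = taxonomy[org]
        row = taxa.setdefault(
            taxon,
            {key: 0 for key in (
                ["total", "site_specific", "sample_specific"]
                + [f"only_{s}" for s in site_ids]
                + ["all_sites"]
                + [f"pair_{a}_{b}" for a, b in pairs]
            )},
        )
        row["total"] += 1
        sites = stats.sites
        if len(sites) == 1:
            row["site_specific"] += 1
            row[f"only_{next(iter(sites))}"] += 1
        elif sites == set(site_ids):
            row["all_sites"] += 1
        else:
            for a, b in pairs:
                if sites == {a, b}:
                    row[f"pair_{a}_{b}"] += 1
                    break
        if stats.n_samples == 1:
            row["sample_specific"] += 1

    records = []
    for taxon in sorted(taxa, key=lambda t: -taxa[t]["total"]):
        row = taxa[taxon]
        n = row["total"]
        rec: dict[str, object] = {"taxonomy": taxon, "total_populations": n}
        for key, value in row.items():
            if key == "total":
                continue
            rec[f"{key}_pct"] = round_half_up(100.0 * value / n)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    totals: dict[str, object] = {"taxonomy": "TOTAL",
                                 "total_populations": int(df["total_populations"].sum())}
    grand = sum(taxa[t]["total"] for t in taxa)
    for key in df.columns:
        if key.endswith("_pct"):
            raw = key[:-4]
            count = sum(taxa[t][raw] for t in taxa)
            totals[key] = round_half_up(100.0 * count / grand) if grand else 0
    df = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    return df


def render_summary(df: pd.DataFrame) -> str:
    """TSV rendering with exact-zero percentages shown as a dash."""
    shown = df.copy()
    for col in shown.columns:
        if col.endswith("_pct"):
            shown[col] = shown[col].map(lambda v: "-" if v == 0 else str(int(v)))
    return shown.to_csv(sep="\t", index=False)


def load_reference_table() -> pd.DataFrame:
    """The bundled per-taxon reference table.

    Panel A covers the 115 de-replicated draft genomes, panel B the 198
    distinct rpS3 marker sequences; columns are integer percentages as
    printed (dashes stored as 0).
    """
    with resources.as_file(resources.files("halocrust.data") / "taxon_panels.tsv") as p:
        return pd.read_csv(p, sep="\t")


def table_specificity_aggregates(table: pd.DataFrame) -> tuple[int, int]:
    """Recompute aggregate sample-/site-specific percentages from a panel.

    Per-taxon organism counts are reconstructed from the printed percentages
    (count = round-half-up of pct * total / 100), summed, and expressed as a
    round-half-up percentage of the panel's grand total.

    Returns
    -------
    (sample_specific_pct, site_specific_pct) as integers.
    """
    grand = int(table["total_populations"].sum())
    sample_n = sum(
        round_half_up(r.sample_specific_pct * r.total_populations / 100.0)
        for r in table.itertuples()
    )
    site_n = sum(
        round_half_up(r.site_specific_pct * r.total_populations / 100.0)
        for r in table.itertuples()
    )
    return (
        round_half_up(100.0 * sample_n / grand),
        round_half_up(100.0 * site_n / grand),
    )
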