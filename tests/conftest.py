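import numpy as np
import pytest

from halocrust.manifest import default_manifest
from halocrust.simulate import SimulationConfig, generate_species_pool

SMALL_PANEL = (
    ("Halobacteriales", "archaea", 6),
    ("Bacteroidetes", "bacteria", 4),
    ("Parcubacteria (OD1)", "bacteria", 1),
    ("Actinobacteria", "bacteria", 1),
    ("Nanohaloarchaea", "archaea", 2),
    ("Cyanobacteria", "bacteria", 1),
    ("Thermoplasmatales", "archaea", 1),
    ("Proteobacteria", "bacteria", 1),
    ("Saccharibacteria (TM7)", "bacteria", 1),
)


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def small_config():
    """A desk-scale community with the full taxon roster (18 species)."""
    return SimulationConfig(
        species_per_taxon=SMALL_PANEL,
        genome_size_range=(8_000, 15_000),
        scaffold_count_range=(2, 4),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pool(small_config):
    return generate_species_pool(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def occupancy_from_panel(panel, manifest):
    """Reconstruct per-organism occupancy records from a reference panel.

    Integer per-taxon category counts are recovered from the printed
    percentages by round-half-up; rounding drift is padded into the
    wettest-only category, mirroring the simulator.  Returns
    (OccupancyStats, taxonomy) suitable for summarize_taxon_table.
    """
    from halocrust.abundance import OccupancyStats, OrganismOccupancy
    from halocrust.report import round_half_up

    site_ids = [s.site_id for s in manifest.sites]
    pairs = [(site_ids[0], site_ids[1]), (site_ids[1], site_ids[2]),
             (site_ids[2], site_ids[0])]
    per = {}
    taxonomy = {}
    counter = 0
    for row in panel.itertuples():
        n = int(row.total_populations)
        cats = (
            [("only", site_ids[0])] * round_half_up(row.wet_only_pct * n / 100)
            + [("only", site_ids[1])] * round_half_up(row.intermediate_only_pct * n / 100)
            + [("only", site_ids[2])] * round_half_up(row.dry_only_pct * n / 100)
            + [("all", None)] * round_half_up(row.all_sites_pct * n / 100)
            + [("pair", pairs[0])] * round_half_up(row.wet_intermediate_pct * n / 100)
            + [("pair", pairs[1])] * round_half_up(row.intermediate_dry_pct * n / 100)
            + [("pair", pairs[2])] * round_half_up(row.dry_wet_pct * n / 100)
        )
        while len(cats) < n:
            cats.append(("only", site_ids[0]))
        cats = cats[:n]
        n_sample_specific = round_half_up(row.sample_specific_pct * n / 100)
        single_idx = [i for i, c in enumerate(cats) if c[0] == "only"]
        sample_specific = set(single_idx[:n_sample_specific])
        for i, (kind, arg) in enumerate(cats):
            counter += 1
            org = f"org{counter:04d}"
            taxonomy[org] = row.taxonomy
            if kind == "only":
                sites = frozenset([arg])
                n_samples = 1 if i in sample_specific else 2
            elif kind == "all":
                sites = frozenset(site_ids)
                n_samples = 3
            else:
                sites = frozenset(arg)
                n_samples = 2
            per[org] = OrganismOccupancy(org, n_samples, len(sites), sites)
    n_total = len(per)
    stats = OccupancyStats(
        per_organism=per,
        fraction_sample_specific=sum(
            1 for o in per.values() if o.n_samples == 1) / n_total,
        fraction_site_specific=sum(
            1 for o in per.values() if o.n_sites == 1) / n_total,
    )
    return stats, taxonomy
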