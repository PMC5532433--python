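"""Synthetic salt-crust community generator.

Every downstream stage of the pipeline is exercised against communities
generated here, with full ground truth: a species pool with the taxon
structure of the survey (65 Halobacteriales, 31 Bacteroidetes, ... — 115
species in the genome panel; 198 in the marker panel), redundant genome bins
at >= 98% within-species identity, occupancy-structured abundance profiles
along the moisture gradient, CRISPR arrays related by leader-end spacer
turnover, and error-bearing 100 bp paired reads.

Genomes are i.i.d. uniform nucleotides with embedded cassettes: a
composition-neutral test bed.  Single-copy genes and the rpS3 locus are
protected from within-species mutation so that cassette recovery is exact;
everything else mutates.  All generators are pure functions of their
configuration (which carries the seed).
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd

from .abundance import AbundanceMatrix
from .crispr import CrisprArray, canonical_orientation
from .derep import GenomeBin
from .manifest import SampleManifest, default_manifest
from .profile import AMINO_ACIDS, ProfileModel, build_profile
from .report import load_reference_table, round_half_up
from .scg import SCG_SETS, scg_cassette_sequence
from .seqio import SequenceRecord

logger = logging.getLogger(__name__)

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)

# Taxon panels: (taxon, domain, n_species) following the survey's tallies
GENOME_PANEL: tuple[tuple[str, str, int], ...] = (
    ("Halobacteriales", "archaea", 65),
    ("Bacteroidetes", "bacteria", 31),
    ("Parcubacteria (OD1)", "bacteria", 4),
    ("Actinobacteria", "bacteria", 2),
    ("Nanohaloarchaea", "archaea", 5),
    ("Cyanobacteria", "bacteria", 3),
    ("Thermoplasmatales", "archaea", 1),
    ("Proteobacteria", "bacteria", 1),
    ("Saccharibacteria (TM7)", "bacteria", 3),
)
MARKER_PANEL: tuple[tuple[str, str, int], ...] = (
    ("Halobacteriales", "archaea", 148),
    ("Bacteroidetes", "bacteria", 23),
    ("Parcubacteria (OD1)", "bacteria", 10),
    ("Actinobacteria", "bacteria", 3),
    ("Nanohaloarchaea", "archaea", 6),
    ("Cyanobacteria", "bacteria", 3),
    ("Thermoplasmatales", "archaea", 1),
    ("Proteobacteria", "bacteria", 3),
    ("Saccharibacteria (TM7)", "bacteria", 1),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic community.

    Defaults encode the survey's design: 100 bp paired-end reads with a
    600-1000 bp library, within-species divergence well below the 2% species
    boundary, between-species divergence well above it, and the genome-panel
    taxon counts.
    """

    species_per_taxon: tuple[tuple[str, str, int], ...] = GENOME_PANEL
    multiplicity_probs: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    within_species_mutation_rate: float = 0.005
    between_species_divergence: float = 0.25
    marker_divergence_aa: float = 0.08
    scg_missing_rate: float = 0.05
    scaffold_dropout_max: float = 0.3
    genome_size_range: tuple[int, int] = (20_000, 50_000)
    scaffold_count_range: tuple[int, int] = (3, 8)
    occupancy_panel: str = "A"
    read_length: int = 100
    read_error_rate: float = 0.005
    insert_size_range: tuple[int, int] = (600, 1000)
    spacer_turnover_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_species_mutation_rate", "between_species_divergence",
            "marker_divergence_aa", "scg_missing_rate", "scaffold_dropout_max",
            "read_error_rate", "spacer_turnover_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.within_species_mutation_rate >= 0.02:
            raise ValueError(
                "within-species mutation rate must stay below the 2% species "
                f"identity boundary, got {self.within_species_mutation_rate}"
            )
        if self.read_length < 35:
            raise ValueError("read_length must be >= 35")
        if abs(sum(self.multiplicity_probs) - 1.0) > 1e-9:
            raise ValueError("multiplicity probabilities must sum to 1")


@dataclass
class Species:
    species_id: str
    taxon: str
    domain_tag: str
    scaffolds: list[SequenceRecord]
    embedded_markers: dict[str, tuple[str, int, int]]  # name -> (scaffold, start, end)
    rps3_protein: str
    scg_names: tuple[str, ...]
    protected: dict[str, list[tuple[int, int]]]  # scaffold -> protected intervals
    crispr_array: CrisprArray | None = None
    true_site_range: frozenset[str] | None = None

    @property
    def genome_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)


@dataclass
class SpeciesPool:
    species: list[Species]
    config: SimulationConfig

    def by_id(self, species_id: str) -> Species:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_NUC[rng.integers(0, 4, n)]).decode()


def _mutate_nt(seq: str, rate_or_n, rng: np.random.Generator,
               protect: list[tuple[int, int]] | None = None) -> str:
    """Substitute positions at the given rate, sparing protected intervals."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    mask = np.ones(len(arr), dtype=bool)
    for a, b in protect or []:
        mask[a:b] = False
    eligible = np.flatnonzero(mask)
    if isinstance(rate_or_n, float):
        n_mut = rng.binomial(len(eligible), rate_or_n)
    else:
        n_mut = min(int(rate_or_n), len(eligible))
    if n_mut == 0:
        return seq
    sites = rng.choice(eligible, size=n_mut, replace=False)
    cur = arr[sites]
    # draw a different base for every site
    shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
    code = np.zeros(256, dtype=np.uint8)
    for i, c in enumerate(b"ACGT"):
        code[c] = i
    arr[sites] = _NUC[(code[cur] + shift) % 4]
    return arr.tobytes().decode()


def _mutate_protein(protein: str, rate: float, rng: np.random.Generator) -> str:
    out = list(protein)
    n_mut = rng.binomial(len(out), rate)
    sites = rng.choice(len(out), size=n_mut, replace=False)
    for i in sites:
        choices = [a for a in AMINO_ACIDS if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


_CODONS: dict[str, list[str]] = {}


def _build_codon_table() -> None:
    from Bio.Seq import Seq

    bases = "ACGT"
    for a in bases:
        for b in bases:
            for c in bases:
                codon = a + b + c
                aa = str(Seq(codon).translate())
                _CODONS.setdefault(aa, []).append(codon)


def _encode_protein_nt(protein: str, rng: np.random.Generator) -> str:
    """Reverse-translate with uniformly chosen synonymous codons."""
    if not _CODONS:
        _build_codon_table()
    return "".join(
        _CODONS[a][rng.integers(0, len(_CODONS[a]))] for a in protein
    )


# ---------------------------------------------------------------------------
# marker profile inputs (bundled synthetic seed alignments)

_SEED_ALIGNMENT_SEED = 20170728  # fixed: seed alignments are bundled inputs
_PROFILE_SPECS = {
    "bacteria": (217, 111.0),
    "archaea": (212, 172.0),
    "eukaryote": (221, 175.0),
}
NIF_PROFILE_NAMES = (
    "nifH", "nifD", "nifK", "nifE", "nifN", "nifB", "nifQ",
    "nifV", "nifW", "nifZ", "nifT", "nifX", "nifU", "nifS",
)
NIF_NOISE_CUTOFF_BITS = 40.0


def _ancestor_protein(tag: str, length: int) -> str:
    rng = np.random.default_rng(
        (_SEED_ALIGNMENT_SEED + zlib.crc32(tag.encode())) % 2**31
    )
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, length))


def default_seed_alignments() -> dict[str, list[SequenceRecord]]:
    """Synthetic rpS3 seed alignments, one per domain (8 sequences each).

    Deterministic bundled inputs: each domain descends from an independent
    ancestral protein, members diverged ~10% (substitutions only, so the
    alignment is gap-free).
    """
    out = {}
    for tag, (length, _) in _PROFILE_SPECS.items():
        rng = np.random.default_rng(
            (_SEED_ALIGNMENT_SEED + zlib.crc32(f"aln::{tag}".encode())) % 2**31
        )
        ancestor = _ancestor_protein(f"rps3::{tag}", length)
        out[tag] = [
            SequenceRecord(
                id=f"rps3_{tag}_{i:02d}",
                sequence=_mutate_protein(ancestor, 0.10, rng),
                alphabet="protein",
            )
            for i in range(8)
        ]
    return out


def default_marker_profiles() -> dict[str, ProfileModel]:
    """rpS3 profiles for the three domains with the survey's score cutoffs."""
    profiles = {}
    for tag, records in default_seed_alignments().items():
        _, cutoff = _PROFILE_SPECS[tag]
        profiles[tag] = build_profile(records, tag, cutoff, name=f"rps3_{tag}")
    return profiles


def nif_profiles() -> list[ProfileModel]:
    """The 14 nitrogenase-pathway screening profiles with noise cutoffs."""
    out = []
    for name in NIF_PROFILE_NAMES:
        rng = np.random.default_rng(
            (_SEED_ALIGNMENT_SEED + zlib.crc32(f"nifaln::{name}".encode())) % 2**31
        )
        ancestor = _ancestor_protein(f"nif::{name}", 150)
        records = [
            SequenceRecord(
                id=f"{name}_{i:02d}",
                sequence=_mutate_protein(ancestor, 0.10, rng),
                alphabet="protein",
            )
            for i in range(6)
        ]
        out.append(
            build_profile(records, "bacteria", NIF_NOISE_CUTOFF_BITS, name=name)
        )
    return out


def nif_cassette_nt(name: str = "nifH", seed: int = 7) -> str:
    """Nucleotide cassette encoding a nif profile consensus (for planting)."""
    prof = next(p for p in nif_profiles() if p.name == name)
    rng = np.random.default_rng(seed)
    return "TAA" + _encode_protein_nt(prof.consensus(), rng) + "TAA"


# ---------------------------------------------------------------------------
# species pool

def generate_species_pool(config: SimulationConfig) -> SpeciesPool:
    """Generate the species pool for the configured taxon panel.

    Species of one taxon descend from a shared ancestral genome mutated at
    ``between_species_divergence`` per species, keeping pairwise identity far
    below the de-replication grouping threshold.  Each species carries
    exactly one rpS3 locus (a domain-consensus protein diverged
    ``marker_divergence_aa``, reverse-translated and stop-codon bounded) and
    its domain's single-copy-gene cassettes minus a random
    ``scg_missing_rate`` subset.
    """
    rng = np.random.default_rng(config.seed)
    profiles = default_marker_profiles()
    lo, hi = config.genome_size_range
    if hi < 5 * len(SCG_SETS["bacteria"]) * 60 // 4:
        raise ValueError("genome size range too small to host the cassette sets")
    species: list[Species] = []
    counter = 0
    for taxon, domain, n_species in config.species_per_taxon:
        n_scaf = int(rng.integers(config.scaffold_count_range[0],
                                  config.scaffold_count_range[1] + 1))
        total = int(rng.integers(lo, hi + 1))
        proportions = rng.dirichlet(np.full(n_scaf, 5.0))
        lengths = np.maximum((proportions * total).astype(int), 1200)
        ancestor = [_random_seq(rng, int(n)) for n in lengths]
        for _ in range(n_species):
            counter += 1
            sp = _make_species(
                f"sp{counter:03d}", taxon, domain, ancestor, profiles[domain],
                config, rng,
            )
            species.append(sp)
    # one cosmopolitan cyanobacterial species carries an ancestral CRISPR array
    for sp in species:
        if sp.taxon == "Cyanobacteria":
            _embed_crispr(sp, ancestral_crispr_array(rng))
            break
    return SpeciesPool(species=species, config=config)


def _embed_crispr(sp: Species, array: CrisprArray) -> None:
    """Plant an array's repeat-spacer sequence near the end of a scaffold."""
    body = array_sequence(array)
    idx = max(range(len(sp.scaffolds)), key=lambda i: len(sp.scaffolds[i]))
    rec = sp.scaffolds[idx]
    pos = len(rec.sequence) - len(body) - 50
    occupied = max((b for _, b in sp.protected.get(rec.id, [])), default=0)
    if pos <= occupied:
        raise ValueError(f"no room for CRISPR array in {sp.species_id}")
    sp.scaffolds[idx] = SequenceRecord(
        id=rec.id,
        sequence=rec.sequence[:pos] + body + rec.sequence[pos + len(body):],
    )
    sp.protected.setdefault(rec.id, []).append((pos, pos + len(body)))
    sp.crispr_array = _dc_replace(
        array, sample_id=sp.species_id, scaffold_id=rec.id,
        start=pos, end=pos + len(body),
    )


def _make_species(
    species_id: str,
    taxon: str,
    domain: str,
    ancestor: list[str],
    profile: ProfileModel,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Species:
    scaffolds = [
        _mutate_nt(seq, config.between_species_divergence, rng) for seq in ancestor
    ]
    n_scaf = len(scaffolds)
    protected: dict[str, list[tuple[int, int]]] = {}
    embedded: dict[str, tuple[str, int, int]] = {}
    scaffold_ids = [f"{species_id}_scf{i}" for i in range(n_scaf)]

    # per-scaffold write cursors so cassettes never overlap
    cursors = [20] * n_scaf

    def plant(cassette: str, scaffold_idx: int) -> tuple[int, int, int]:
        # fall through to the next scaffold with room if the target is full
        for attempt in range(n_scaf):
            idx = (scaffold_idx + attempt) % n_scaf
            pos = cursors[idx]
            seq = scaffolds[idx]
            if pos + len(cassette) + 20 <= len(seq):
                scaffolds[idx] = seq[:pos] + cassette + seq[pos + len(cassette):]
                cursors[idx] = pos + len(cassette) + int(rng.integers(20, 60))
                protected.setdefault(scaffold_ids[idx], []).append(
                    (pos, pos + len(cassette))
                )
                return idx, pos, pos + len(cassette)
        raise ValueError(f"genome too small to host cassettes ({species_id})")

    # rpS3 locus: one per species, stop-codon bounded so the ORF is exact
    rps3_protein = _mutate_protein(profile.consensus(), config.marker_divergence_aa, rng)
    rps3_nt = "TAA" + _encode_protein_nt(rps3_protein, rng) + "TAA"
    scf = int(rng.integers(0, n_scaf))
    idx, a, b = plant(rps3_nt, scf)
    embedded["rpS3"] = (scaffold_ids[idx], a, b)

    # single-copy-gene cassettes, spread round-robin across scaffolds
    keep = [
        name for name in SCG_SETS[domain]
        if rng.random() >= config.scg_missing_rate
    ]
    order = rng.permutation(n_scaf)
    for i, name in enumerate(keep):
        idx, a, b = plant(scg_cassette_sequence(name), int(order[i % n_scaf]))
        embedded[name] = (scaffold_ids[idx], a, b)

    records = [
        SequenceRecord(id=sid, sequence=seq)
        for sid, seq in zip(scaffold_ids, scaffolds)
    ]
    return Species(
        species_id=species_id,
        taxon=taxon,
        domain_tag=domain,
        scaffolds=records,
        embedded_markers=embedded,
        rps3_protein=rps3_protein,
        scg_names=tuple(keep),
        protected=protected,
    )


# ---------------------------------------------------------------------------
# redundant bins

def generate_redundant_bins(
    pool: SpeciesPool, config: SimulationConfig | None = None
) -> tuple[list[GenomeBin], dict[str, str]]:
    """Derive 1-3 redundant bins per species.

    The first bin of each species is the unmodified genome; further bins are
    mutated at the within-species rate (outside protected cassettes, so
    within-species identity stays >= 98%) and lose random scaffolds up to the
    dropout budget.  Returns (bins, truth) where truth maps bin_id ->
    species_id.
    """
    config = config or pool.config
    rng = np.random.default_rng((config.seed + 0x5EED) % 2**31)
    bins: list[GenomeBin] = []
    truth: dict[str, str] = {}
    for sp in pool.species:
        multiplicity = 1 + int(
            rng.choice(3, p=np.asarray(config.multiplicity_probs))
        )
        for j in range(multiplicity):
            bin_id = f"{sp.species_id}_bin{j}"
            if j == 0:
                scaffolds = [SequenceRecord(id=f"{bin_id}:{s.id}", sequence=s.sequence)
                             for s in sp.scaffolds]
                kept_names = set(sp.scg_names)
            else:
                keep_idx = _dropout_subset(sp, config, rng)
                scaffolds = []
                kept_scaffold_ids = set()
                for i in keep_idx:
                    s = sp.scaffolds[i]
                    kept_scaffold_ids.add(s.id)
                    mutated = _mutate_nt(
                        s.sequence,
                        config.within_species_mutation_rate,
                        rng,
                        protect=sp.protected.get(s.id, []),
                    )
                    scaffolds.append(
                        SequenceRecord(id=f"{bin_id}:{s.id}", sequence=mutated)
                    )
                kept_names = {
                    name for name in sp.scg_names
                    if sp.embedded_markers[name][0] in kept_scaffold_ids
                }
            bin = GenomeBin(
                bin_id=bin_id,
                sample_id="sim",
                scaffolds=scaffolds,
                domain_tag=sp.domain_tag,
                scg_counts={name: (1 if name in kept_names else 0)
                            for name in SCG_SETS[sp.domain_tag]},
            )
            bins.append(bin)
            truth[bin_id] = sp.species_id
    return bins, truth


def _dropout_subset(
    sp: Species, config: SimulationConfig, rng: np.random.Generator
) -> list[int]:
    """Indices of scaffolds to keep, dropping up to the length budget."""
    total = sp.genome_length
    budget = config.scaffold_dropout_max * total
    order = rng.permutation(len(sp.scaffolds))
    dropped_len = 0.0
    dropped: set[int] = set()
    for idx in order:
        L = len(sp.scaffolds[int(idx)])
        if len(dropped) < len(sp.scaffolds) - 1 and dropped_len + L <= budget \
                and rng.random() < 0.5:
            dropped.add(int(idx))
            dropped_len += L
    return [i for i in range(len(sp.scaffolds)) if i not in dropped]


# ---------------------------------------------------------------------------
# occupancy-structured abundance

def generate_abundance_profiles(
    pool: SpeciesPool,
    manifest: SampleManifest | None = None,
    config: SimulationConfig | None = None,
) -> AbundanceMatrix:
    """True abundance matrix with the configured occupancy structure.

    Per-taxon occupancy category counts (single-site per site, all-sites,
    site-pairs, and the sample-specific subset) are reconstructed from the
    configured reference panel's integer percentages by round-half-up, so the
    realized fractions match the panel within rounding.  Present cells draw
    a lognormal fold-coverage offset above the presence threshold, modulated
    by a per-organism moisture affinity acting on the site's standardized
    log wetness — the moisture-driven composition signal that the gradient
    statistics (Mantel, BioENV) are expected to detect.
    """
    manifest = manifest or default_manifest()
    config = config or pool.config
    rng = np.random.default_rng((config.seed + 0xAB1) % 2**31)
    table = load_reference_table()
    table = table[table["panel"] == config.occupancy_panel].set_index("taxonomy")
    site_ids = [s.site_id for s in manifest.sites]
    if len(site_ids) != 3:
        raise ValueError("occupancy panels assume the three-site design")
    pairs = [(site_ids[0], site_ids[1]), (site_ids[1], site_ids[2]),
             (site_ids[2], site_ids[0])]
    samples_by_site = {
        site: [s.sample_id for s in manifest.samples if s.site_id == site]
        for site in site_ids
    }
    values = pd.DataFrame(
        0.0, index=[sp.species_id for sp in pool.species],
        columns=manifest.sample_ids,
    )
    by_taxon: dict[str, list[Species]] = {}
    for sp in pool.species:
        by_taxon.setdefault(sp.taxon, []).append(sp)

    logw = np.log([manifest.site(site).wetness_hours for site in site_ids])
    z_wet = {
        site: float(z) for site, z in
        zip(site_ids, (logw - logw.mean()) / (logw.std() or 1.0))
    }

    for taxon, members in by_taxon.items():
        n = len(members)
        if taxon not in table.index:
            raise ValueError(f"taxon {taxon!r} missing from occupancy panel")
        row = table.loc[taxon]
        n_only = [round_half_up(row[f"{c}_pct"] * n / 100.0)
                  for c in ("wet_only", "intermediate_only", "dry_only")]
        n_all = round_half_up(row["all_sites_pct"] * n / 100.0)
        n_pair = [round_half_up(row[f"{c}_pct"] * n / 100.0)
                  for c in ("wet_intermediate", "intermediate_dry", "dry_wet")]
        cats: list[tuple[str, object]] = (
            [("only", site_ids[0])] * n_only[0]
            + [("only", site_ids[1])] * n_only[1]
            + [("only", site_ids[2])] * n_only[2]
            + [("all", None)] * n_all
            + [("pair", pairs[0])] * n_pair[0]
            + [("pair", pairs[1])] * n_pair[1]
            + [("pair", pairs[2])] * n_pair[2]
        )
        # rounding drift: pad with the wettest-site category, trim from the end
        while len(cats) < n:
            cats.append(("only", site_ids[0]))
        cats = cats[:n]
        n_sample_specific = round_half_up(row["sample_specific_pct"] * n / 100.0)
        single_site_idx = [i for i, c in enumerate(cats) if c[0] == "only"]
        sample_specific = set(single_site_idx[:n_sample_specific])

        for i, (sp, cat) in enumerate(zip(members, cats)):
            kind, arg = cat
            if kind == "only":
                site = str(arg)
                pool_samples = samples_by_site[site]
                if i in sample_specific or len(pool_samples) == 1:
                    chosen = [pool_samples[int(rng.integers(0, len(pool_samples)))]]
                else:
                    k = int(rng.integers(2, min(4, len(pool_samples)) + 1))
                    chosen = list(rng.choice(pool_samples, size=k, replace=False))
                sites = frozenset([site])
            elif kind == "all":
                chosen = list(manifest.sample_ids)
                sites = frozenset(site_ids)
            else:
                a, b = arg  # type: ignore[misc]
                chosen = []
                for site in (a, b):
                    k = int(rng.integers(1, min(3, len(samples_by_site[site])) + 1))
                    chosen.extend(rng.choice(samples_by_site[site], size=k,
                                             replace=False))
                sites = frozenset([a, b])
            sp.true_site_range = sites
            affinity = float(rng.normal(0.8, 0.4))
            site_of = {s.sample_id: s.site_id for s in manifest.samples}
            for sample in set(chosen):
                moisture = np.exp(affinity * z_wet[site_of[sample]])
                values.loc[sp.species_id, sample] = (
                    1.0 + float(rng.lognormal(mean=0.5, sigma=0.8)) * moisture
                )
    total_reads = {s: 0 for s in manifest.sample_ids}
    return AbundanceMatrix(values=values, total_reads=total_reads)


# ---------------------------------------------------------------------------
# reads

def simulate_reads(
    pool: SpeciesPool,
    matrix: AbundanceMatrix,
    config: SimulationConfig | None = None,
) -> dict[str, list[SequenceRecord]]:
    """Paired 100 bp reads per sample, counts proportional to coverage x length.

    The abundance entry is the target fold coverage: n_reads = round(coverage
    x genome_length / read_length), emitted as mate pairs from uniformly
    placed 600-1000 bp fragments with per-base substitution errors at the
    configured rate.  Deterministic given the config seed.
    """
    config = config or pool.config
    rng = np.random.default_rng((config.seed + 0x0EAD) % 2**31)
    L = config.read_length
    out: dict[str, list[SequenceRecord]] = {}
    for sample in matrix.samples:
        reads: list[SequenceRecord] = []
        col = matrix.values[sample]
        if float(col.sum()) == 0.0:
            warnings.warn(f"sample {sample} has zero total abundance; empty FASTQ",
                          stacklevel=2)
            out[sample] = []
            continue
        for sp in pool.species:
            cov = float(col.get(sp.species_id, 0.0))
            if cov <= 0:
                continue
            n_reads = int(round(cov * sp.genome_length / L))
            n_pairs = max(1, n_reads // 2)
            reads.extend(_species_read_pairs(sp, sample, n_pairs, config, rng))
        out[sample] = reads
    return out


def _species_read_pairs(
    sp: Species,
    sample: str,
    n_pairs: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[SequenceRecord]:
    from Bio.Seq import Seq

    L = config.read_length
    lengths = np.array([len(s) for s in sp.scaffolds], dtype=float)
    usable = lengths >= L
    if not usable.any():
        return []
    probs = np.where(usable, lengths, 0.0)
    probs /= probs.sum()
    reads = []
    for p in range(n_pairs):
        scf = int(rng.choice(len(sp.scaffolds), p=probs))
        seq = sp.scaffolds[scf].sequence
        insert = int(rng.integers(*config.insert_size_range))
        insert = min(insert, len(seq))
        start = int(rng.integers(0, len(seq) - insert + 1))
        frag = seq[start: start + insert]
        r1 = frag[:L]
        r2 = str(Seq(frag[-L:]).reverse_complement())
        for mate, template in ((1, r1), (2, r2)):
            read_seq = (
                _mutate_nt(template, config.read_error_rate, rng)
                if config.read_error_rate > 0 else template
            )
            reads.append(
                SequenceRecord(
                    id=f"{sample}:{sp.species_id}:{p}/{mate}",
                    sequence=read_seq,
                    quality=[40] * len(read_seq),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# CRISPR ground truth

def ancestral_crispr_array(rng: np.random.Generator, n_spacers: int = 8) -> CrisprArray:
    repeat = _random_seq(rng, 30)
    spacers = tuple(_random_seq(rng, 35) for _ in range(n_spacers))
    return CrisprArray(
        sample_id="ancestral", scaffold_id="ancestral",
        repeat_consensus=repeat, spacers=spacers, start=0,
        end=len(repeat) * (n_spacers + 1) + 35 * n_spacers,
    )


def evolve_array(
    ancestor: CrisprArray,
    n_gains: int,
    n_losses: int,
    rng: np.random.Generator,
    sample_id: str = "",
) -> CrisprArray:
    """Descend an array by leader-end spacer turnover.

    New spacers are acquired only at the leader end (index 0); losses also
    trim the leader end, matching the biology of spacer acquisition.
    """
    spacers = list(ancestor.spacers)
    spacers = spacers[n_losses:]
    for _ in range(n_gains):
        spacers.insert(0, _random_seq(rng, len(ancestor.spacers[0])))
    if not spacers:
        raise ValueError("turnover removed every spacer")
    return _dc_replace(
        ancestor,
        sample_id=sample_id or ancestor.sample_id,
        spacers=tuple(spacers),
    )


def array_sequence(array: CrisprArray) -> str:
    """Concrete repeat-spacer nucleotide sequence of an array."""
    parts = [array.repeat_consensus]
    for sp in array.spacers:
        parts.append(sp)
        parts.append(array.repeat_consensus)
    return "".join(parts)


@dataclass
class Figure4Fixture:
    """26 per-sample CRISPR records reproducing the survey's locus relations."""

    arrays: dict[str, CrisprArray | None]  # sample_id -> array (None = absent)
    expected_labels: dict[str, str]  # sample_id -> e.g. "1a"
    repeats: tuple[str, str, str]
    array_order: list[str]  # sample ids in canonical typing order

    def present_arrays(self) -> list[CrisprArray]:
        return [self.arrays[s] for s in self.array_order]  # type: ignore[misc]

    def scaffolds(self, flank: int = 400) -> list[SequenceRecord]:
        """One synthetic scaffold per sample; six carry no array.

        Arrays of the driest site are embedded in reverse complement to
        exercise orientation handling.
        """
        from Bio.Seq import Seq

        rng = np.random.default_rng(0xF16)
        out = []
        for sample in sorted(self.arrays):
            arr = self.arrays[sample]
            if arr is None:
                seq = _random_seq(rng, 2 * flank + 800)
            else:
                body = array_sequence(arr)
                if sample.startswith("Qs"):
                    body = str(Seq(body).reverse_complement())
                seq = _random_seq(rng, flank) + body + _random_seq(rng, flank)
            out.append(SequenceRecord(id=f"{sample}_cyano_scaffold", sequence=seq))
        return out


def build_figure4_fixture() -> Figure4Fixture:
    """The bundled 26-sample CRISPR fixture.

    20 arrays and 6 absences; 12 locus types on 3 repeat sequences.  Group 1
    holds the longest variant 1a, an identical wet/intermediate pair 1b
    (= 1a minus four leader spacers) and 1c (= 1b minus three leader
    spacer-repeat sets); groups 2 and 3 are cross-site with small leader-end
    differences; the remaining nine groups pairwise share at most one
    (internal) spacer.
    """
    rng = np.random.default_rng(0xF1640)
    repeats = []
    while len(repeats) < 3:
        r = _random_seq(rng, 30)
        from Bio.Seq import Seq

        if r < str(Seq(r).reverse_complement()):  # pre-canonical
            repeats.append(r)
    r1, r2, r3 = repeats

    def sp(n: int) -> tuple[str, ...]:
        return tuple(_random_seq(rng, 35) for _ in range(n))

    def arr(sample: str, repeat: str, spacers: tuple[str, ...]) -> CrisprArray:
        return CrisprArray(
            sample_id=sample, scaffold_id=f"{sample}_cyano_scaffold",
            repeat_consensus=repeat, spacers=spacers,
            start=0, end=len(repeat) * (len(spacers) + 1) + sum(map(len, spacers)),
        )

    s1 = sp(12)  # group 1 master list, leader -> trailer
    t = sp(6)    # group 2
    u = sp(7)    # group 3
    shared_internal = _random_seq(rng, 35)
    g4 = (sp(1) + (shared_internal,) + sp(2))        # 4 spacers
    g5 = (sp(2) + (shared_internal,) + sp(2))        # 5 spacers, shares 1 internal
    g6 = sp(5)
    g7 = sp(6)
    g8 = sp(4)
    g9, g10, g11, g12 = sp(5), sp(4), sp(6), sp(5)

    entries: list[tuple[str, str, str, tuple[str, ...]]] = [
        # (sample, label, repeat, spacers)
        ("Sw2", "1a", r1, s1),
        ("Sw1", "1b", r1, s1[4:]),
        ("Qh1", "1b", r1, s1[4:]),
        ("Qh2", "1c", r1, s1[7:]),
        ("Sw3", "2a", r1, t),
        ("Qh3", "2b", r1, t[1:]),
        ("Sw4", "3a", r2, u),
        ("Qs1", "3b", r2, u[2:]),
        ("Qs2", "4a", r3, g4),
        ("Qs5", "5a", r3, g5),
        ("Qs3", "6a", r2, g6),
        ("Qs4", "6a", r2, g6),
        ("Sw5", "7a", r1, g7),
        ("Sw6", "7a", r1, g7),
        ("Qh4", "8a", r3, g8),
        ("Qh5", "8a", r3, g8),
        ("Sw7", "9a", r1, g9),
        ("Sw8", "10a", r2, g10),
        ("Qh6", "11a", r3, g11),
        ("Qs6", "12a", r3, g12),
    ]
    arrays: dict[str, CrisprArray | None] = {
        s: None for s in
        [f"Sw{i}" for i in range(1, 10)]
        + [f"Qh{i}" for i in range(1, 9)]
        + [f"Qs{i}" for i in range(1, 10)]
    }
    labels = {}
    order = []
    for sample, label, repeat, spacers in entries:
        arrays[sample] = canonical_orientation(arr(sample, repeat, spacers))
        labels[sample] = label
        order.append(sample)
    return Figure4Fixture(
        arrays=arrays, expected_labels=labels,
        repeats=(r1, r2, r3), array_order=order,
    )
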