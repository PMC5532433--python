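"""Stage orchestration: file-level glue between the analysis modules.

Each stage reads and writes plain TSV/FASTA/FASTQ under a run directory so
stages can be re-run independently from the command line.  Every stage logs
its parameters and seed; tables are tab-delimited UTF-8 with a header row.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import simulate
from .abundance import AbundanceMatrix, occupancy, relative_abundance
from .config import PipelineConfig
from .crispr import assign_locus_types, canonical_orientation, detect_arrays
from .derep import GenomeBin, dereplicate, estimate_completeness
from .ecology import DistanceMatrix, bioenv, bray_curtis, mantel, mrpp, nmds, permanova
from .manifest import SampleManifest, default_manifest
from .mapping import map_reads
from .markers import (
    clusters_to_table,
    cluster_markers,
    find_orfs,
    find_rps3,
    screen_nitrogenase,
)
from .report import render_summary, summarize_taxon_table
from .seqio import SequenceRecord, read_sequences, write_sequences

logger = logging.getLogger(__name__)


def _log_stage(stage: str, config: PipelineConfig, inputs: dict[str, Path]) -> None:
    digests = {}
    for name, path in inputs.items():
        if path.exists():
            digests[name] = hashlib.sha256(path.read_bytes()).hexdigest()[:12]
    logger.info("stage=%s seed=%d inputs=%s", stage, config.seed, digests)


def run_simulate(config: PipelineConfig, outdir: Path,
                 sim_config: simulate.SimulationConfig | None = None) -> None:
    """Generate the synthetic community and write all ground truth."""
    outdir.mkdir(parents=True, exist_ok=True)
    sim = sim_config or simulate.SimulationConfig(seed=config.seed)
    _log_stage("simulate", config, {})
    manifest = default_manifest()
    pool = simulate.generate_species_pool(sim)
    bins, truth = simulate.generate_redundant_bins(pool, sim)
    matrix = simulate.generate_abundance_profiles(pool, manifest, sim)
    reads = simulate.simulate_reads(pool, matrix, sim)

    bins_dir = outdir / "bins"
    bins_dir.mkdir(exist_ok=True)
    rows = []
    for bin in bins:
        write_sequences(bin.scaffolds, bins_dir / f"{bin.bin_id}.fasta")
        rows.append({"bin_id": bin.bin_id, "sample_id": bin.sample_id,
                     "domain_tag": bin.domain_tag,
                     "true_species": truth[bin.bin_id]})
    pd.DataFrame(rows).to_csv(outdir / "bin_manifest.tsv", sep="\t", index=False)

    genomes_dir = outdir / "genomes"
    genomes_dir.mkdir(exist_ok=True)
    taxonomy = {}
    for sp in pool.species:
        write_sequences(sp.scaffolds, genomes_dir / f"{sp.species_id}.fasta")
        taxonomy[sp.species_id] = sp.taxon
    pd.Series(taxonomy, name="taxon").rename_axis("organism").reset_index().to_csv(
        outdir / "taxonomy.tsv", sep="\t", index=False
    )
    matrix.values.rename_axis("organism").to_csv(outdir / "true_abundance.tsv", sep="\t")

    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for sample, recs in reads.items():
        write_sequences(recs, reads_dir / f"{sample}.fastq", format="fastq")
    (outdir / "seed.json").write_text(json.dumps({"seed": sim.seed}))


def load_bins(outdir: Path) -> list[GenomeBin]:
    manifest = pd.read_csv(outdir / "bin_manifest.tsv", sep="\t")
    bins = []
    for row in manifest.itertuples():
        scaffolds = read_sequences(outdir / "bins" / f"{row.bin_id}.fasta")
        bin = GenomeBin(
            bin_id=row.bin_id, sample_id=row.sample_id,
            scaffolds=scaffolds, domain_tag=row.domain_tag,
        ).count_scgs()
        bins.append(bin)
    return bins


def run_derep(config: PipelineConfig, outdir: Path) -> None:
    """De-replicate the bin set and write the cluster table."""
    _log_stage("derep", config, {"bin_manifest": outdir / "bin_manifest.tsv"})
    bins = load_bins(outdir)
    result = dereplicate(bins, config.dereplication)
    rows = []
    for cluster_idx, (members, rep) in enumerate(
        zip(result.clusters, result.representatives)
    ):
        for bin_id in members:
            pair = (min(bin_id, rep), max(bin_id, rep))
            rows.append({
                "cluster_id": f"cluster_{cluster_idx:04d}",
                "bin_id": bin_id,
                "score": result.scores[bin_id],
                "representative": int(bin_id == rep),
                "shared_fraction_to_representative":
                    1.0 if bin_id == rep else round(result.shared_fractions.get(pair, 0.0), 4),
            })
    for bin_id in result.excluded:
        rows.append({"cluster_id": "excluded", "bin_id": bin_id, "score": 0,
                     "representative": 0, "shared_fraction_to_representative": 0.0})
    pd.DataFrame(rows).to_csv(outdir / "derep_clusters.tsv", sep="\t", index=False)


def run_rps3(config: PipelineConfig, outdir: Path) -> None:
    """Find and cluster rpS3 genes across per-species genome FASTAs.

    Scaffold coverage is taken from the true abundance table (the assembled
    scaffold's fold coverage in the pipeline's stand-in for assembly
    coverage); hits inherit it per sample.
    """
    _log_stage("rps3", config, {"taxonomy": outdir / "taxonomy.tsv"})
    profiles = simulate.default_marker_profiles()
    abundance = pd.read_csv(outdir / "true_abundance.tsv", sep="\t", index_col=0)
    genomes_dir = outdir / "genomes"
    all_hits = []
    for fasta in sorted(genomes_dir.glob("*.fasta")):
        species_id = fasta.stem
        row = abundance.loc[species_id]
        present = row[row > 0]
        if present.empty:
            continue
        sample_id = str(present.index[0])
        orfs = []
        coverage = {}
        for scaffold in read_sequences(fasta):
            orfs.extend(find_orfs(scaffold, config.marker_cutoffs.min_len_aa,
                                  sample_id=sample_id))
            coverage[(scaffold.id, sample_id)] = float(present.iloc[0])
        all_hits.extend(find_rps3(profiles, orfs, config.marker_cutoffs, coverage))
    clusters = cluster_markers(all_hits)
    clusters_to_table(clusters).to_csv(outdir / "rps3_clusters.tsv", sep="\t",
                                       index=False)


def run_abundance(config: PipelineConfig, outdir: Path,
                  manifest: SampleManifest | None = None) -> None:
    """Map reads to representative genomes; write abundance and occupancy."""
    manifest = manifest or default_manifest()
    _log_stage("abundance", config, {"derep": outdir / "derep_clusters.tsv"})
    clusters = pd.read_csv(outdir / "derep_clusters.tsv", sep="\t")
    reps = clusters[clusters["representative"] == 1]["bin_id"]
    bin_manifest = pd.read_csv(outdir / "bin_manifest.tsv", sep="\t").set_index("bin_id")
    references = []
    for bin_id in reps:
        species = bin_manifest.loc[bin_id, "true_species"]
        scaffolds = read_sequences(outdir / "bins" / f"{bin_id}.fasta")
        references.append(
            SequenceRecord(id=str(species),
                           sequence="".join(s.sequence for s in scaffolds))
        )
    coverage = {}
    for sample in manifest.sample_ids:
        fastq = outdir / "reads" / f"{sample}.fastq"
        reads = read_sequences(fastq, format="fastq") if fastq.exists() else []
        coverage[sample] = map_reads(reads, references, config.mapping)
    matrix = relative_abundance(coverage)
    matrix.values.rename_axis("organism").to_csv(outdir / "abundance.tsv", sep="\t")
    occ = occupancy(matrix, manifest, config.mapping.presence_min_coverage)
    rows = [
        {"organism": o.organism_id, "n_samples": o.n_samples,
         "n_sites": o.n_sites, "sites": ",".join(sorted(o.sites))}
        for o in occ.per_organism.values()
    ]
    pd.DataFrame(rows).to_csv(outdir / "occupancy.tsv", sep="\t", index=False)
    pd.DataFrame([{
        "fraction_sample_specific": occ.fraction_sample_specific,
        "fraction_site_specific": occ.fraction_site_specific,
    }]).to_csv(outdir / "occupancy_aggregate.tsv", sep="\t", index=False)


def run_crispr(config: PipelineConfig, outdir: Path) -> None:
    """Detect and type CRISPR arrays across the genome FASTAs."""
    _log_stage("crispr", config, {})
    genomes_dir = outdir / "genomes"
    arrays = []
    for fasta in sorted(genomes_dir.glob("*.fasta")):
        for scaffold in read_sequences(fasta):
            for arr in detect_arrays(scaffold, config.crispr, sample_id=fasta.stem):
                arrays.append(canonical_orientation(arr))
    rows = [
        {"sample": a.sample_id, "scaffold": a.scaffold_id, "start": a.start,
         "end": a.end, "repeat_consensus": a.repeat_consensus,
         "n_spacers": len(a.spacers)}
        for a in arrays
    ]
    pd.DataFrame(rows).to_csv(outdir / "crispr_arrays.tsv", sep="\t", index=False)
    if arrays:
        typing = assign_locus_types(arrays, config.crispr)
        trows = [
            {"sample": a.sample_id, "scaffold": a.scaffold_id,
             "locus_type": typing.assignments[a.array_id][0],
             "variant": typing.assignments[a.array_id][1]}
            for a in arrays
        ]
        pd.DataFrame(trows).to_csv(outdir / "crispr_types.tsv", sep="\t", index=False)


def run_nfix(config: PipelineConfig, outdir: Path) -> None:
    """Screen all genome proteomes for the 14 nitrogenase profiles."""
    _log_stage("nfix", config, {})
    profiles = simulate.nif_profiles()
    proteomes = {}
    for fasta in sorted((outdir / "genomes").glob("*.fasta")):
        proteins = []
        for scaffold in read_sequences(fasta):
            proteins.extend(
                o.protein for o in find_orfs(scaffold, 100)
            )
        proteomes[fasta.stem] = proteins
    table = screen_nitrogenase(profiles, proteomes)
    table.to_csv(outdir / "nif_screen.tsv", sep="\t")


def run_ecology(config: PipelineConfig, outdir: Path,
                manifest: SampleManifest | None = None) -> None:
    """Distance matrix, ordination, and the permutation-test battery."""
    manifest = manifest or default_manifest()
    _log_stage("ecology", config, {"abundance": outdir / "abundance.tsv"})
    table = pd.read_csv(outdir / "abundance.tsv", sep="\t", index_col=0)
    matrix = AbundanceMatrix(values=table, total_reads={c: 1 for c in table.columns})
    d = bray_curtis(matrix)
    d.to_frame().to_csv(outdir / "bray_curtis.tsv", sep="\t")
    groups = [manifest.site_of(s) for s in d.labels]
    seed = config.seed
    ord_res = nmds(d, config.ecology, seed=seed)
    coords = pd.DataFrame(ord_res.coordinates, index=d.labels,
                          columns=[f"NMDS{i+1}" for i in range(config.ecology.nmds_k)])
    coords.assign(stress=ord_res.stress).to_csv(outdir / "nmds.tsv", sep="\t")
    env = manifest.environment_table().loc[d.labels]
    geo = DistanceMatrix(
        labels=d.labels,
        values=squareform(pdist(env[["latitude", "longitude"]].to_numpy())),
    )
    results = []
    r = mrpp(d, groups, config.ecology, seed=seed)
    results.append(r)
    results.append(permanova(d, groups, config.ecology, seed=seed))
    results.append(mantel(d, geo, config.ecology, seed=seed))
    be = bioenv(d, env, config.ecology)
    rows = [
        {"statistic": t.statistic_name, "value": round(t.observed, 4),
         "permutations": t.n_permutations, "p_value": t.p_value, "seed": t.seed}
        for t in results
    ]
    rows.append({"statistic": "BioENV_rho", "value": round(be.correlation, 4),
                 "permutations": 0, "p_value": float("nan"), "seed": seed})
    pd.DataFrame(rows).to_csv(outdir / "ecology_tests.tsv", sep="\t", index=False)
    pd.DataFrame([{"best_subset": ",".join(be.best_subset)}]).to_csv(
        outdir / "bioenv_best_subset.tsv", sep="\t", index=False
    )


def run_report(config: PipelineConfig, outdir: Path,
               manifest: SampleManifest | None = None) -> None:
    """Taxon occupancy summary table from the abundance stage outputs."""
    manifest = manifest or default_manifest()
    _log_stage("report", config, {"abundance": outdir / "abundance.tsv"})
    table = pd.read_csv(outdir / "abundance.tsv", sep="\t", index_col=0)
    matrix = AbundanceMatrix(values=table, total_reads={c: 1 for c in table.columns})
    occ = occupancy(matrix, manifest, config.mapping.presence_min_coverage)
    taxonomy = pd.read_csv(outdir / "taxonomy.tsv", sep="\t").set_index("organism")[
        "taxon"].to_dict()
    summary = summarize_taxon_table(occ, taxonomy, manifest)
    (outdir / "taxon_summary.tsv").write_text(render_summary(summary))
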