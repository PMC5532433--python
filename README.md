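# halocrust

Genome-resolved community analysis for hypersaline salt-crust microbiomes.

Translucent halite crusts in hyperarid deserts host endolithic microbial
communities that are activated when the salt deliquesces under coastal fog.
`halocrust` implements the analysis pipeline used to characterize such
communities from shotgun metagenomes across a moisture gradient:

* **Species-level genome de-replication** — genome bins whose scaffolds align
  at ≥98% nucleotide identity over more than 70% of the smaller genome are
  grouped, and one representative per group is kept, chosen by
  `score = (#single-copy genes) − 2 × (#multi-copy single-copy genes)`,
  ties broken by genome length. Completeness is estimated from 51 bacterial /
  38 archaeal single-copy genes (SCGs) with a 70% floor.
* **rpS3 marker profiling** — ribosomal protein S3 genes are found with
  per-domain profile models (length window 120–450 aa; bit-score cutoffs:
  bacteria 111, archaea 172, eukaryotes 175) and clustered at 99% protein
  identity to enumerate community members; each marker's abundance is the
  coverage of its scaffold.
* **Stringent-mapping abundance** — reads count toward a reference only when
  their best end-to-end placement has ≤ ⌊0.03·L⌋ mismatches (3 per 100 bp,
  i.e. 97% identity); per-nucleotide coverage is sum-normalized across
  samples by sequencing effort. Occupancy statistics classify each organism
  as sample-specific (one sample) or site-specific (one site).
* **CRISPR locus typing** — repeat–spacer arrays are detected by grammar
  (23–55 bp repeats, 25–60 bp spacers, ≥3 near-identical copies), oriented
  canonically, and grouped into locus types by repeat sequence and shared
  spacers; variants differing only by leader-end ("terminal") spacers mark
  recently diverged, dispersing populations.
* **Community ecology** — Bray–Curtis dissimilarity
  `d(i,j) = Σ|x_ik − x_jk| / Σ(x_ik + x_jk)`, NMDS (Kruskal stress-1 with
  isotonic regression), MRPP (chance-corrected within-group agreement
  `A = 1 − δ_obs / E[δ]`), single-factor PERMANOVA, BioENV environmental
  subset matching, and the Mantel test, all with seeded permutation
  inference (add-one p-values).
* **Synthetic community generator** — a ground-truthed salt-crust community
  (115-species genome panel / 198-species marker panel with the survey's
  taxon structure, redundant bins, occupancy-structured abundance along the
  moisture gradient, CRISPR arrays with leader-end spacer turnover, and
  error-bearing 100 bp paired reads) against which every stage is tested.

It is intended for microbial ecologists studying extreme, low-diversity
communities who need the full chain from genome bins to biogeographic
statistics in a reproducible, desk-scale form.

## Worked example

```python
from halocrust import (
    SimulationConfig, generate_species_pool, generate_redundant_bins,
    generate_abundance_profiles, dereplicate, occupancy,
    bray_curtis, mrpp, default_manifest,
)

manifest = default_manifest()           # 26 samples: Sw:9, Qh:8, Qs:9
config = SimulationConfig(seed=42)      # 115-species genome panel
pool = generate_species_pool(config)
bins, truth = generate_redundant_bins(pool, config)
result = dereplicate(bins)
print(len(bins), result.n_clusters)

matrix = generate_abundance_profiles(pool, manifest, config)
occ = occupancy(matrix, manifest)
print(round(100 * occ.fraction_sample_specific), round(100 * occ.fraction_site_specific))

test = mrpp(bray_curtis(matrix), manifest.group_labels(), seed=1)
print(round(test.observed, 3), test.p_value)
```

prints

```
224 115
16 37
0.283 0.001
```

meaning: 224 redundant bins collapse back to exactly the 115 true species;
under the genome-panel occupancy structure 16% of organisms occur in a
single sample and 37% at a single site (the marker panel is far more
specific: 72% / 84%); and MRPP finds the within-site agreement (A = 0.283)
far beyond chance (p = 0.001 at 999 permutations).

A CLI mirrors the stages for shell use:
`halocrust simulate|derep|rps3|abundance|crispr|nfix|ecology|report`,
each accepting `--seed`, `--config`, `--outdir`.

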