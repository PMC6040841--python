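# epiallele

Tools for detecting metastable epialleles (MEs) — genomic regions with
systemic, cross-tissue interindividual variation in DNA methylation — from
multi-individual multi-tissue bisulfite sequencing data, and for
characterizing their methylation dynamics:

- **`epiallele.io`** — readers/writers for Bismark cytosine reports,
  count bedGraphs, BED, VCF (SNP positions only) and a per-read CpG call
  TSV. One internal convention: 0-based half-open coordinates, CpG dyads
  addressed by the plus-strand C, strand counts merged before depth
  filtering.
- **`epiallele.screen`** — the three-step ME screen (per-CpG
  interindividual ≥ 15% / intertissue ≤ ⅓-ratio criteria, SNP-proximity
  exclusion, 300 bp single-linkage clustering with ≥ 4 CpGs, 2:1 purity
  filter) plus control-cluster sampling matched on the joint
  (span, CpG count) distribution.
- **`epiallele.dynamics`** — stage-wise methylation summaries for
  developmental series (per-replicate CpG counting, intermediate-methylation
  fraction, stratified pre/post-stage transitions with bootstrap CIs,
  chi-squared two-proportion test).
- **`epiallele.readlevel`** — read-level methylation and the read
  homogeneity index (RHI): observed adjacent-call transition count versus
  the median over 1000 cluster-wide permutations of the call multiset,
  preserving read structure and uncalled positions.
- **`epiallele.enrichment`** — Fisher's exact test machinery over 1 kb
  genome tiles (proximal-feature enrichment at 10 kb, region-overlap
  enrichment), proximity profiles, chromHMM 15→8 state overlap, mQTL
  enrichment and variance-explained summaries.
- **`epiallele.simulate`** — fully deterministic synthetic data for every
  stage: cohorts with planted ME regions and SNPs, stage trajectories with
  post-gastrulation intermediate methylation, molecule-specific vs. mosaic
  read sets, and feature tracks with planted proximity enrichment.
- **`epiallele.pipeline` / `epiallele.cli`** — end-to-end orchestration
  from a flat key=value config and an input manifest, with structured
  logging and bit-identical reruns.

## CLI

Every subcommand accepts `--config` (flat `key=value` file; defaults are the
published analysis constants), `--manifest`, `--seed`, `--out`, and
stage-specific flag overrides.

```sh
# fully synthetic end-to-end run (writes inputs + manifest + all outputs)
epiallele run --demo --seed 7 --out out/demo

# just the synthetic inputs
epiallele simulate --out out/sim --seed 7

# individual stages against a manifest
epiallele screen   --manifest out/sim/inputs/manifest.txt --out out/screen
epiallele controls --manifest out/sim/inputs/manifest.txt --out out/controls
epiallele dynamics --manifest out/sim/inputs/manifest.txt --out out/dynamics
epiallele rhi      --demo --seed 7 --out out/rhi
epiallele enrich   --manifest out/sim/inputs/manifest.txt --out out/enrich
```

Outputs are TSV/BED only; each carries the config hash, and reruns with the
same inputs and seed are bit-identical.

### Manifest format

Flat `key=value` lines naming one input file per role:

```
dataset.D1.samples=path/to/D1.samples.tsv   # TSV: sample_id, individual, tissue, path
dataset.D1.snps=path/to/D1.vcf              # optional; skipping disables the SNP filter
stage.ICM.replicates=rep1.tsv,rep2.tsv      # per-stage CpG count files
features=features.bed
chrom_sizes=chrom_sizes.tsv
reads=reads.tsv                             # per-read CpG calls for RHI
regions=regions.bed                         # optional externally supplied regions
```

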