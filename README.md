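# mybkit

Gene-family mining toolkit built around MYB-style repeat proteins. It
detects ~52-residue repeat architectures in a proteome, classifies genes
into 1R/2R/3R/4R subfamilies, names members by chromosomal order, calls
tandem and segmental duplications, groups cross-subgenome homologs,
estimates Ka/Ks (Nei–Gojobori 1986 with Jukes–Cantor correction), builds
neighbor-joining trees with bootstrap support, and screens
stress-responsive genes from TPM expression matrices. A first-class
synthetic-data module generates genomes, diverged codon pairs and
expression matrices with machine-readable planted truth, which is what the
test suite validates against.

## Modules

| module | what it does |
|---|---|
| `mybkit.simulate` | synthetic genomes (planted repeats, tandem clusters, collinear blocks, homoeolog triads, promoter motifs), controlled Ka/Ks codon divergence, NB-noise TPM matrices |
| `mybkit.family` | PSSM repeat scan, HMMER domtblout ingest, hit merging, subfamily classification, systematic naming |
| `mybkit.annotation` | intron counts, average molecular weight, Bjellqvist isoelectric point, strand-aware promoter extraction, IUPAC motif scanning |
| `mybkit.duplication` | pairwise affine-gap alignment, BLAST outfmt-6 ingest, tandem cluster calling (coverage ≥ 0.8 of the longer gene, identity > 80%, E < 1e-10, no intervening gene), collinear segmental block chaining, reciprocal-best-hit homolog groups |
| `mybkit.evolution` | codon alignment back-translation, NG86 Ka/Ks with path-averaged difference counting, p-distances, neighbor joining, bootstrap bipartition support |
| `mybkit.expression` | per-gene z-scores of log2(TPM+1), Welch-test differential screening (\|log2FC\| > 1, p < 0.05), average-linkage correlation clustering, 2^-ΔΔCt |
| `mybkit.pipeline` / `mybkit.cli` | stage orchestration, YAML config, JSON + text run report |

## CLI

```bash
# full run on a simulated genome
mybkit run-all --outdir runs/demo --simulate --seed 1

# or stage by stage (each stage re-reads the run directory)
mybkit simulate --outdir runs/demo --seed 1
mybkit identify --outdir runs/demo
mybkit annotate --outdir runs/demo
mybkit dup      --outdir runs/demo --min-span 12000
mybkit kaks     --outdir runs/demo
mybkit tree     --outdir runs/demo --bootstraps 100
mybkit expr     --outdir runs/demo
mybkit ddct     --ct-tsv ct.tsv --out rel.tsv
```

Options can also come from a YAML config (`--config cfg.yaml`); explicit
flags win. Stage thresholds default to the standard criteria (tandem
coverage 0.8 / identity 80% / E-value 1e-10, segmental identity 90% /
span 600 kb, |log2FC| > 1 at p < 0.05, 1000 bootstrap replicates, 1500 bp
promoters). `min_span` is a knob so synthetic chromosomes can use scaled
values.

Outputs per run directory: `family.tsv`, `properties.tsv`,
`motif_hits.tsv`, `tandem.tsv`/`tandem.bed`, `segmental.tsv`/
`segmental.bed`, `homolog_groups.tsv`, `kaks.tsv`, `tree.nwk`,
`zscore.tsv`, `calls.tsv`, `cluster_labels.tsv`, `expression_summary.tsv`,
`report.json`, `report.txt`. Reruns with the same seed are byte-identical.

## Acceptance

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance criteria are property-based (recovery of planted truth,
oracle equality for NG86 counting, exact NJ reconstruction on additive
matrices, screening calibration); they live in `tests/test_acceptance.py`,
one test per criterion. The report script runs the pipeline end-to-end as
a smoke check and writes the (empty) target object.

`scripts/calibrate_threshold.py` reproduces the calibration behind the
default 40-bit repeat-scan threshold.
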