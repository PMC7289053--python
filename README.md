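# syntegraph

Micro-synteny network and phylogenetic analysis of multi-domain gene
families, bundled with a forward genome-evolution simulator so that every
stage of the pipeline can be benchmarked against known ground truth.

The pipeline traces how a two-domain gene family diversifies across a
clade of genomes: all-vs-all protein search, collinear-block detection by
anchor chaining, synteny-network construction with k-clique-percolation
communities (conserved loci), profile-based domain-architecture calls,
distance-based gene trees with bootstrap, segment-wise chimera (gene
fusion) testing, duplication-type classification (tandem / syntenic-WGD /
transposed / dispersed / singleton), and per-locus dosage profiling.

## Layout

| module | role |
|---|---|
| `syntegraph.simgenomes` | genome/protein evolution simulator: species tree, WGD/WGT, tandem + transposed duplications, losses, domain loss, chimeric fusions; emits FASTA+BED and a ground-truth event log |
| `syntegraph.seqio` | FASTA, BED6, GFF3, blast-tabular, schema'd TSV and Newick IO; genome reconciliation |
| `syntegraph.homology` | exact Smith–Waterman/Gotoh all-vs-all search (numba-accelerated when available), Karlin–Altschul e-values with optional shuffle calibration |
| `syntegraph.domains` | PSSM profiles from seed alignments, ungapped window scan with empirical shuffle e-values (inclusive 0.007 threshold), architecture calls, divergence pre-filter |
| `syntegraph.collinearity` | anchor chaining DP (both orientations, gap-bounded, best-score-first extraction), intra- and cross-genome scans |
| `syntegraph.network` | synteny network, 25-gene-window family subnetwork extraction, clique percolation communities, membership statistics |
| `syntegraph.phylo` | center-star MSA, occupancy column filter, Kimura-corrected distances, neighbour joining + bootstrap, exemplar-anchored clade assignment |
| `syntegraph.fusion_dosage` | before/domain/after segment split, rank-sum fusion test, conservation summaries, duplication classifier, locus dosage profiles |

Tree inference is deliberately distance-based (NJ + bootstrap) rather than
maximum likelihood: downstream analyses consume clades and supports, and
NJ is deterministic and exactly testable at desk scale.

## CLI

```bash
syntegraph simulate --out data/ --seed 7           # FASTA+BED+truth TSV
syntegraph search   --genomes data/ --out hits.tsv
syntegraph domains  --genomes data/ --profiles profiles/ --out domains.tsv
syntegraph network  --genomes data/ --hits hits.tsv --candidates cand.txt \
                    --out net/ --window 25 -k 3
syntegraph phylo    --fasta family.faa --mode full --bootstrap 100 \
                    --seed 7 --out tree.nwk
syntegraph fusion   --fasta family.faa --domains domains.tsv \
                    --groups groups.tsv --out verdicts.tsv
syntegraph run      --out results/ --seed 7        # full pipeline
```

`syntegraph run` simulates the default scenario (4 genomes, one
whole-genome duplication, recurring tandem/transposed duplications and
domain losses) and carries it through every stage, writing plain-text
outputs; the same configuration and seed reproduce byte-identical files.
Custom scenarios go in a YAML config (`--config`), covering the species
tree, event rates, WGD placement and all analysis thresholds.

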