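# rgascape

Genome-wide receptor-like kinase (RLK) / receptor-like protein (RLP)
landscape analysis for allopolyploid genomes, built as a reusable, tested
pipeline:

* **Classification** — similarity prescreen against a reference RGA database
  followed by domain-architecture rules (LRR / LysM ectodomains,
  transmembrane helix, serine/threonine kinase) partitioning every gene into
  `LRR_RLK`, `LYSM_RLK`, `RLK_OTHER`, `LRR_RLP`, `LYSM_RLP` or `NON_RGA`.
* **Genome landscape** — per-chromosome distribution accounting and
  positional gene-cluster detection (≥3 same-family genes chained at ≤200 kb
  consecutive gaps), with homogeneity labelling and span statistics.
* **Duplication analysis** — duplicate-pair calling from all-vs-all protein
  hits (≥70% identity and ≥70% coverage on both sequences), typed
  tandem (≤5 Mb, same chromosome) / segmental (>5 Mb, same chromosome) /
  dispersed, and scoped intra-A / intra-B / inter-genomic; separate
  E-value-only paralog calling; tandem-cluster labelling.
* **Comparative orthology** — cross-species ortholog calling
  (E < 1e-45, ≥70% similarity and coverage), conservation / gained / lost
  ledgers per sub-genome ↔ progenitor pairing, and chromosome-level
  collinearity chains via longest order-consistent anchor subsequences.
* **NJ phylogeny** — identity-derived distance matrices, deterministic
  Saitou–Nei neighbour joining, Newick I/O, and k-group tree cutting.
* **Synthetic genomes** — a seeded allotetraploid + two-progenitor world
  generator with planted ground truth (clusters, typed duplicate pairs,
  ortholog maps, synteny order), plus a deterministic fixture sized to a
  published survey's headline tallies.
* **Reporting** — deterministic TSV tables with auditable percentage
  arithmetic (half-up rounding; every percentage carries its numerator,
  denominator and denominator definition).

## CLI

The console script `rgascape` exposes one subcommand per stage:

```sh
# generate a synthetic world with planted ground truth
rgascape simulate --seed 1 --out world/

# classify the tetraploid proteome
rgascape classify --gff world/tetraploid.gff3 \
    --domains world/tetraploid.domains.tsv \
    --rga-hits world/tetraploid.rga_hits.tsv \
    --species tetraploid --out out/

# distribution + clusters, duplication typing
rgascape landscape --classification out/classification.tsv \
    --gff world/tetraploid.gff3 --out out/
rgascape duplication --classification out/classification.tsv \
    --gff world/tetraploid.gff3 \
    --selfhits world/tetraploid.self_hits.tsv --out out/

# NJ tree over pairwise identities
rgascape tree --hits world/tetraploid.self_hits.tsv \
    --labels labels.txt --out tree.nwk --groups 7
```

Inputs are plain text: GFF3 gene models, InterProScan-style domain TSVs and
BLAST tabular hits (`outfmt "6 std qlen slen"`). Thresholds live in a YAML
config mirroring `AnalysisConfig` (`--config`); every analysis constant
(E-value ceilings, identity/coverage floors, cluster and tandem distances)
is a config field with the published value as default.

## Scope notes

* External tools (BLAST, InterProScan, Phobius, the RGAugury pipeline) are
  not executed; their tabular outputs are the pipeline's inputs.
* Multiple sequence alignment and bootstrap support values are out of scope;
  the NJ module operates on hit-derived distance matrices.
* No plotting.
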