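# ampliscreen

In-silico screening of PCR primer pairs against panels of genomes.

Amplicon sequencing infers community composition from a PCR product of a
marker gene, most often a 16S rRNA region. Two biological facts limit what
an amplicon can tell you: a single genome usually carries several —
often different — alleles of the target (inflating apparent diversity),
and the same allele can occur in genomes of different species (blocking
species-level assignment). `ampliscreen` quantifies both effects for any
IUPAC-degenerate primer pair on any set of genomes (bacterial or not),
so you can pick primers that actually resolve the taxa you care about,
whether for short V3–V4 reads or long-read full-operon amplicons.

## What it computes

For a genome panel \(G\) and a primer pair \((F, R)\):

- **In-silico PCR.** Binding sites are windows where every primer
  position shares at least one nucleotide with the genome position
  (IUPAC set intersection), within a Hamming mismatch budget; no indels.
  Each forward site is paired with the nearest correctly oriented
  reverse site on the opposite strand; the product includes both primer
  sites.
- **Allele clusters.** Amplicons are clustered at an identity threshold
  \(t \in [0.7, 1.0]\) (default 1.0 = exact sequences, i.e. ASV
  granularity). Identity is computed from a Needleman–Wunsch global
  alignment (match +1, mismatch −1, gap −2, free terminal gaps) as
  matches / non-terminal-gap columns.
- **Amplification rate** \(= |\{g : g \text{ yields} \ge 1
  \text{ product}\}| / |G|\).
- **Multiplicity and divergence.** Per genome: amplicon count, distinct
  allele clusters, and mean pairwise identity of its amplicons.
- **Shannon diversity** \(\sum_k H_k\) with
  \(H_k = -\sum_{b \in \{A,C,G,T\}} p_{kb}\ln p_{kb}\) over the columns
  \(k\) of a center-star multiple alignment of all amplicons.
- **Species overlap.** A species overlaps when one of its amplicons sits
  in a cluster that also contains another species' amplicon; the
  overlap fraction divides by species with at least one amplicon.
- **Shared-allele network.** Genomes as nodes, an edge wherever two
  genomes hold amplicons in a common cluster, weighted by the number of
  shared clusters; rendered with isolated genomes excluded and edge
  width scaled by weight.

A synthetic-panel generator (`ampliscreen.fixtures`) plants primer
sites, 16S-like operons, copy numbers and cross-species allele sharing
with exact ground truth, so the whole pipeline is verifiable without
downloading a single genome.

## Worked example

Screen a planted synthetic panel (4 species × 3 genomes, 3 amplicon
copies per genome, one allele shared between the first two species):

```python
from ampliscreen import PlantedDesign, RunConfig, generate_panel, run_pipeline
from ampliscreen.fixtures import planted_primer_pair

panel, truth = generate_panel(PlantedDesign(seed=1))
config = RunConfig(genomes="", outdir="out", primers=[planted_primer_pair()],
                   mode="whole_genome", identity=1.0)
result = run_pipeline(config, panel=panel).results["planted"]
print(result.stats.amplification_rate)   # 1.0   — every genome amplifies
print(result.overlap.fraction)           # 0.5   — 2 of 4 species share an allele
print(len(result.clusters))              # 5     — distinct alleles across the panel
print(result.graph.number_of_edges())    # 21    — genome pairs sharing >=1 allele
```

`out/planted/` then holds the amplicon FASTA, cluster and per-genome
summary tables, the presence/absence matrix with its heatmap, the
shared-allele network as GraphML/edge list/PNG, and a plain-text
summary. The same analysis runs from the shell on any directory of
FASTA genomes:

```sh
ampliscreen --genomes my_genomes/ --primers primers.tsv -w -i 1.0 -o out/
```

Omitting `-w` restricts the search to 16S rRNA genes located by the
built-in anchored-motif extractor (or an external predictor's GFF3 via
the library API). Default V3–V4 / V1–V9 / operon-span 16S primer
definitions ship as an editable data file.

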