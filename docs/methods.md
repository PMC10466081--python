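# Methods

## Scope and model

`ampliscreen` evaluates a degenerate primer pair against a panel of
genome assemblies by exhaustive in-silico PCR, then summarises the
resulting amplicons as allele clusters, per-genome multiplicity and
divergence, a panel amplification rate, summed per-column Shannon
diversity, species-level overlap, and a shared-allele genome network.
It models primer annealing as pure sequence matching: no thermodynamics,
no primer dimers, no 3'-end weighting, and no indels inside a primer
site.

## Primer matching

Primers and genomes share one IUPAC alphabet (case-folded, U→T on
load). A primer position matches a genome position when the two codes'
nucleotide sets intersect; a genomic `N` therefore matches any primer
base rather than counting as a mismatch — the self-consistent extension
of degenerate-base semantics, isolated in `iupac_match`. A site is any
window, in either orientation of the plus-strand text, with at most
`max_mismatch` non-matching positions (default 2, per primer pair).
Matching is Hamming-only, which keeps an exact exhaustive-scan oracle
feasible; the test suite holds `find_sites` to that oracle over random
contigs and budgets 0–3.

## Product formation

A plus-orientation product pairs a forward site with a reverse-primer
site on the opposite physical strand, strictly downstream; the minus
orientation is the mirror image. For each forward site only the nearest
admissible reverse site is used — the dominant short product of real
PCR — and overlapping products from distinct forward sites are allowed.
Products span both primer sites inclusive (as physical PCR products
do), are bounded by a length window (default 50–6000 nt, wide enough
for full rRNA-operon spans of ≈5 kb), never cross contig boundaries,
and are reported oriented to begin with the forward primer. Internal
coordinates are 0-based half-open on the plus strand; all file outputs
print 1-based inclusive coordinates.

## 16S-restricted mode

The standard (non-whole-genome) run first extracts 16S rRNA genes and
amplifies within them. The built-in extractor anchors on near-universal
terminal motifs (27F-class `AGAGTTTGATCMTGGCTCAG`, 1492R-class
`TACGGYTACCTTGTTACGACTT`, ≤2 mismatches) and accepts products of
1200–1800 nt. Anchoring is deliberately simple and dependency-free; its
known blind spot is genes with degraded terminal motifs, so an adapter
hook accepts an external rRNA predictor's GFF3 instead, validated
against the same plausibility window with sequences re-extracted from
the genome. Whole-genome mode on the same data always yields a superset
of 16S-mode amplicons.

## Identity and clustering

Pairwise identity comes from a Needleman–Wunsch global alignment with
match +1, mismatch −1, linear gap −2 and free terminal gaps, scored as
matches divided by alignment columns excluding terminal-gap runs — so a
perfect substring scores by its overlap and length differences from
degenerate priming are not penalised. Tie-breaks are fixed (the end
cell nearest the matrix corner, last column before last row; traceback
prefers diagonal, then a gap in the second sequence), making results
deterministic; a consequence worth knowing is that for *dissimilar*
pairs the identity of the chosen optimal alignment need not be exactly
symmetric in its arguments, although the optimal score always is.

Clustering is greedy centroid assignment: amplicons sorted by
(descending length, sequence, accession) join the first centroid at or
above the threshold, else seed a new cluster. The threshold is
restricted to [0.7, 1.0]. At the default threshold of 1.0 membership is
exact string equality, which makes clustering coincide with
dereplication (ASV granularity); this is a deliberate definition, since
under overlap-identity a substring would otherwise score 1.0 against a
longer centroid. Exact partitioning guarantees hold only at 1.0; below
it the greedy partition is only guaranteed (and tested) to refine the
connected components of the ≥t pairwise-identity graph.

## Alignment profile and Shannon diversity

The amplicon multiple alignment is a center-star build: the longest
sequence (ties broken lexicographically) is the star, every other
sequence is aligned to it pairwise with the scoring above, and gap
patterns are merged once-a-gap-always-a-gap. This is deterministic and
oracle-checkable, and is adequate for the near-identical amplicon sets
the tool mostly sees; it degrades for highly divergent inputs (e.g.
heavily degenerate functional-gene primers), which is accepted and
documented rather than replaced by a heuristic progressive aligner.
Column entropy is Shannon's H in natural log over A/C/G/T frequencies
only; gaps and ambiguity codes are excluded from the distribution
(base-2 readers multiply by 1/ln 2). The panel statistic is the sum of
H over all columns, so it grows with both alignment length and
per-column diversity.

## Overlap and network

The presence matrix counts each genome's amplicons per cluster,
retaining all-zero rows for non-amplified genomes. A species overlaps
when ≥1 of its amplicons lies in a cluster that also contains another
species' amplicon; the overlap fraction divides by species with ≥1
amplicon (not the whole panel — non-amplified species are reported
separately so either convention is recoverable), and genomes labelled
`unknown` never enter the fraction. The network places an edge between
two genomes wherever both have nonzero cells in a common cluster,
weighted by the number of such clusters; rendering drops isolated nodes
and scales edge width monotonically with weight.

## Synthetic panels

The generator plants constructs `forward-site + insert +
revcomp(reverse-site)` (default insert 300 nt) at non-overlapping
random positions, on random strands, in uniform-random backgrounds
(default 20 kb per genome). Backgrounds are rejection-sampled until the
planted primers occur exactly the planted number of times at zero
mismatches, so at threshold 1.0 / mismatch 0 the design-implied
multiplicity, rate, overlap, matrix totals and edge weights are exact
ground truth. The default design — 4 species × 3 genomes × 3 copies
with one allele shared between the first two species — mirrors the
structure the statistics are meant to expose: multiplicity within
genomes, identical alleles across genomes of a species, and a planted
cross-species overlap of exactly half the species.

The 16S builder plants 1500-nt genes (terminal anchor motifs, internal
V3/V4-class sites at offsets giving a 461-nt V3–V4 product, copy-level
substitutions confined to the variable region) and can add
degraded-anchor copies that the extractor is *designed* to miss.

What the fixtures do not emulate: real base composition and repeats,
rRNA secondary-structure conservation, primer-site degeneracy in the
genome, contamination, or fragmented assemblies splitting operons.
Passing the planted-recovery suite therefore demonstrates algorithmic
correctness of the pipeline, not field performance of any primer on
real genomes — the latter depends on the genome inventory used and is
exactly what a user runs the tool to measure.

## Numerical and design choices

- Mismatch budget default 2; the matching rule for `N` is set
  intersection (above). Both are stated because published pipelines
  rarely print them.
- Threshold 1.0 means exact equality (see clustering).
- Mean intragenomic identity is undefined (reported `NA`) below two
  amplicons.
- Shannon entropy of an empty/ambiguous-only column is 0.
- Graph, table and GraphML artifacts are written in sorted order and
  are byte-reproducible for a fixed config and panel; figures may
  differ only in image metadata.
- Test and acceptance runs use 5–30 kb backgrounds and panels of 4–12
  genomes — sizes chosen so planted structure spans multiplicities
  {1,3,7} and sharing {0,1,2} while the full suite stays interactive.

## Limitations

- No indel-tolerant primer matching; a primer with an indel relative to
  the template is scored as multiple mismatches or missed.
- Anchored 16S extraction misses genes with degraded terminal motifs
  (use the GFF adapter with a dedicated predictor for real genomes).
- Greedy clustering below threshold 1.0 is order-canonical but not an
  exact optimum; centroids depend on the declared sort key.
- Center-star alignment quality degrades for highly divergent amplicon
  sets, inflating the Shannon sum's gap-adjacent columns.
- The NCBI download path is an adapter contract only; no network client
  ships with the package.
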