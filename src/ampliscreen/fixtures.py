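"""Synthetic genome panels with planted primer sites and known ground truth.

The generator emulates exactly the allele structure the pipeline
measures — per-genome copy number (multiplicity), within-genome allele
divergence, and cross-species allele sharing — by planting constructs
of the form ``forward-site + insert + revcomp(reverse-site)`` at
non-overlapping positions, on random strands, in uniform-random
backgrounds. Backgrounds are rejection-sampled against accidental
primer sites at zero mismatches, so at threshold 1.0 / mismatch 0 the
design-implied statistics are exact ground truth, not approximations.

A second builder plants full-length 16S-like genes: terminal anchor
motifs recognised by the built-in extractor, internal V3-V4 class
priming sites, and copy-level substitutions confined to a variable
region, so the 16S-restricted mode is testable end to end without any
real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DesignError
from .genome_io import Genome, GenomePanel, write_genome_fasta
from .insilico_pcr import PrimerPair, find_sites, revcomp
from .rrna_mode import ANCHOR_FORWARD, ANCHOR_REVERSE

# concrete planted primers for whole-genome designs
PLANT_FWD = "ATGGCTCAGACGAACGCTGG"
PLANT_REV = "CGGTTACCTTGTTACGACTT"

# concrete realizations of the degenerate 16S anchors (M->A, Y->C)
ANCHOR_FWD_SITE = "AGAGTTTGATCATGGCTCAG"
ANCHOR_REV_SITE = "TACGGCTACCTTGTTACGACTT"

# internal V3-V4 class priming sites planted inside fixture 16S genes
V3_FWD = "CCTACGGGAGGCAGCAG"
V4_REV = "GACTACCGGGGTATCTAATCC"

_NUCS = np.array(list("ACGT"))


def planted_primer_pair(max_mismatch: int = 0) -> PrimerPair:
    """The primer pair matching whole-genome planted constructs."""
    return PrimerPair("planted", PLANT_FWD, PLANT_REV, max_mismatch=max_mismatch)


def v3v4_fixture_pair(max_mismatch: int = 0) -> PrimerPair:
    """Primer pair matching the internal sites of fixture 16S genes."""
    return PrimerPair("V3V4-fixture", V3_FWD, V4_REV, max_mismatch=max_mismatch)


def v1v9_fixture_pair() -> PrimerPair:
    """Near-full-length pair: the extractor's own degenerate anchors."""
    return PrimerPair(
        "V1V9-fixture", ANCHOR_FORWARD, ANCHOR_REVERSE, max_mismatch=2
    )


@dataclass(frozen=True)
class PlantedDesign:
    """Declarative description of a synthetic panel.

    ``copies_per_genome`` may be a single int or one int per species;
    ``within_divergence`` substitutions separate successive private
    copies inside each genome; ``shared_alleles`` maps species-index
    pairs to the number of alleles planted identically in both.
    """

    n_species: int = 4
    genomes_per_species: int = 3
    copies_per_genome: int | tuple[int, ...] = 3
    within_divergence: int = 0
    shared_alleles: dict[tuple[int, int], int] = field(
        default_factory=lambda: {(0, 1): 1}
    )
    background_length: int = 20_000
    insert_length: int = 300
    seed: int = 0

    def copies(self, species_index: int) -> int:
        if isinstance(self.copies_per_genome, int):
            return self.copies_per_genome
        return self.copies_per_genome[species_index]


@dataclass
class GroundTruth:
    """Everything the design implies, computed by set algebra at build time."""

    design: PlantedDesign
    species_by_accession: dict[str, str]
    # expected oriented amplicon sequences per genome, in planted order
    amplicons_by_genome: dict[str, list[str]]
    gene_coords_by_genome: dict[str, list[tuple[str, int, int, str]]] = field(
        default_factory=dict
    )
    designed_misses: dict[str, list[tuple[str, int, int, str]]] = field(
        default_factory=dict
    )

    def multiplicity(self, accession: str) -> int:
        return len(self.amplicons_by_genome[accession])

    @property
    def total_amplicons(self) -> int:
        return sum(len(v) for v in self.amplicons_by_genome.values())

    @property
    def n_alleles(self) -> int:
        return len({s for v in self.amplicons_by_genome.values() for s in v})

    @property
    def amplification_rate(self) -> float:
        n = len(self.amplicons_by_genome)
        return sum(1 for v in self.amplicons_by_genome.values() if v) / n

    def alleles_of(self, accession: str) -> set[str]:
        return set(self.amplicons_by_genome[accession])

    @property
    def edge_weights(self) -> dict[tuple[str, str], int]:
        """Expected shared-allele network: distinct alleles shared per genome pair."""
        weights = {}
        for g1, g2 in combinations(sorted(self.amplicons_by_genome), 2):
            w = len(self.alleles_of(g1) & self.alleles_of(g2))
            if w:
                weights[(g1, g2)] = w
        return weights

    @property
    def species_pairs(self) -> dict[tuple[str, str], int]:
        """Expected shared-cluster counts between named species."""
        species_alleles: dict[str, set[str]] = {}
        for acc, seqs in self.amplicons_by_genome.items():
            sp = self.species_by_accession[acc]
            species_alleles.setdefault(sp, set()).update(seqs)
        pairs = {}
        for a, b in combinations(sorted(species_alleles), 2):
            shared = len(species_alleles[a] & species_alleles[b])
            if shared:
                pairs[(a, b)] = shared
        return pairs

    @property
    def overlap_fraction(self) -> float | None:
        amplified = {
            self.species_by_accession[acc]
            for acc, seqs in self.amplicons_by_genome.items()
            if seqs
        }
        if not amplified:
            return None
        overlapping = {sp for pair in self.species_pairs for sp in pair}
        return len(overlapping) / len(amplified)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NUCS, size=length))


def _mutate(seq: str, positions: Sequence[int], rng: np.random.Generator) -> str:
    chars = list(seq)
    for pos in positions:
        current = chars[pos]
        chars[pos] = rng.choice([n for n in "ACGT" if n != current])
    return "".join(chars)


def _species_inserts(
    design: PlantedDesign, rng: np.random.Generator
) -> list[list[str]]:
    """Insert sequences per species, honouring sharing and divergence."""
    shared_pool: dict[tuple[int, int], list[str]] = {}
    for pair, k in sorted(design.shared_alleles.items()):
        i, j = pair
        if not (0 <= i < j < design.n_species):
            raise DesignError(f"shared-allele pair {pair} out of range")
        shared_pool[pair] = [_random_seq(rng, design.insert_length) for _ in range(k)]

    inserts: list[list[str]] = []
    for s in range(design.n_species):
        copies = design.copies(s)
        shared_here = [
            seq
            for pair, seqs in sorted(shared_pool.items())
            if s in pair
            for seq in seqs
        ]
        if len(shared_here) > copies:
            raise DesignError(
                f"species {s}: {len(shared_here)} shared alleles exceed "
                f"{copies} copies per genome"
            )
        n_private = copies - len(shared_here)
        d = design.within_divergence
        if d * n_private > design.insert_length:
            raise DesignError("divergence edits exceed insert length")
        base = _random_seq(rng, design.insert_length)
        private = [
            base if (d == 0 or c == 0) else _mutate(base, range((c - 1) * d, c * d), rng)
            for c in range(n_private)
        ]
        inserts.append(shared_here + private)
    return inserts


def _plant_constructs(
    constructs: list[str],
    background_length: int,
    rng: np.random.Generator,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Interleave constructs (strand-randomized) with random background.

    Returns the contig and each construct's (start, end, strand) in
    planted order.
    """
    total_construct = sum(len(c) for c in constructs)
    if background_length < len(constructs) + 1:
        raise DesignError("background too short for the requested constructs")
    cuts = np.sort(rng.integers(0, background_length + 1, size=len(constructs)))
    chunk_sizes = np.diff(np.concatenate(([0], cuts, [background_length])))
    parts: list[str] = []
    coords: list[tuple[int, int, str]] = []
    offset = 0
    for k, construct in enumerate(constructs):
        gap = _random_seq(rng, int(chunk_sizes[k]))
        parts.append(gap)
        offset += len(gap)
        strand = "+" if rng.integers(2) == 0 else "-"
        planted = construct if strand == "+" else revcomp(construct)
        parts.append(planted)
        coords.append((offset, offset + len(planted), strand))
        offset += len(planted)
    parts.append(_random_seq(rng, int(chunk_sizes[-1])))
    return "".join(parts), coords


def _count_planted_sites(contig: str, primer: str, max_mismatch: int) -> int:
    return len(find_sites(primer, contig, max_mismatch))


def generate_panel(design: PlantedDesign) -> tuple[GenomePanel, GroundTruth]:
    """Build a panel of whole-genome fixtures with planted amplicon sites."""
    rng = np.random.default_rng(design.seed)
    inserts = _species_inserts(design, rng)

    genomes: list[Genome] = []
    species_by_accession: dict[str, str] = {}
    amplicons_by_genome: dict[str, list[str]] = {}
    for s in range(design.n_species):
        species = f"Synthetica sp{s + 1:02d}"
        constructs = [PLANT_FWD + ins + revcomp(PLANT_REV) for ins in inserts[s]]
        for g in range(design.genomes_per_species):
            accession = f"SYN{s + 1:02d}G{g + 1:02d}"
            contig = _build_clean_contig(
                constructs, design.background_length, rng,
                [(PLANT_FWD, 0, len(constructs)), (PLANT_REV, 0, len(constructs))],
            )[0]
            genomes.append(
                Genome(accession, species, "complete", [("chr1", contig)])
            )
            species_by_accession[accession] = species
            amplicons_by_genome[accession] = [
                PLANT_FWD + ins + revcomp(PLANT_REV) for ins in inserts[s]
            ]
    panel = GenomePanel(genus_label="Synthetica", genomes=genomes, source="local")
    truth = GroundTruth(
        design=design,
        species_by_accession=species_by_accession,
        amplicons_by_genome=amplicons_by_genome,
    )
    return panel, truth


def _build_clean_contig(
    constructs: list[str],
    background_length: int,
    rng: np.random.Generator,
    site_checks: list[tuple[str, int, int]],
    max_tries: int = 20,
) -> tuple[str, list[tuple[int, int, str]]]:
    """Plant constructs, rejecting backgrounds with spurious primer sites.

    ``site_checks`` lists (primer, max_mismatch, expected_site_count);
    a contig is accepted only when every primer is found exactly the
    planted number of times, which keeps ground truth exact.
    """
    for _ in range(max_tries):
        contig, coords = _plant_constructs(constructs, background_length, rng)
        if all(
            _count_planted_sites(contig, primer, mm) == expected
            for primer, mm, expected in site_checks
        ):
            return contig, coords
    raise DesignError("could not build a background free of spurious primer sites")


def generate_16s_panel(
    design: PlantedDesign, degraded_copies: int = 0
) -> tuple[GenomePanel, GroundTruth]:
    """Build a panel whose planted features are full-length 16S-like genes.

    Genes are 1500 nt: terminal anchor motifs recognised by the
    built-in extractor, internal V3/V4 priming sites, and copy-level
    substitutions confined to the variable region between them.
    ``degraded_copies`` extra genes per genome carry a 3-substitution
    forward anchor and are recorded as designed misses.
    """
    rng = np.random.default_rng(design.seed)

    # fixed template layout (offsets within the 1500 nt gene)
    body_a = _random_seq(rng, 300)
    mid = _random_seq(rng, 423)
    body_b = _random_seq(rng, 697)
    rev_v4 = revcomp(V4_REV)
    rev_anchor = revcomp(ANCHOR_REV_SITE)

    def gene_from_mid(mid_variant: str, degraded: bool = False) -> str:
        fwd = ANCHOR_FWD_SITE
        if degraded:
            fwd = _mutate(fwd, (3, 9, 15), rng)
        return (
            fwd + body_a + V3_FWD + mid_variant + rev_v4 + body_b + rev_anchor
        )

    # reuse the insert machinery on the variable region
    mid_design = PlantedDesign(
        n_species=design.n_species,
        genomes_per_species=design.genomes_per_species,
        copies_per_genome=design.copies_per_genome,
        within_divergence=design.within_divergence,
        shared_alleles=design.shared_alleles,
        background_length=design.background_length,
        insert_length=len(mid),
        seed=design.seed,
    )
    mids = _species_inserts(mid_design, rng)

    genomes: list[Genome] = []
    species_by_accession: dict[str, str] = {}
    amplicons_by_genome: dict[str, list[str]] = {}
    gene_coords: dict[str, list[tuple[str, int, int, str]]] = {}
    misses: dict[str, list[tuple[str, int, int, str]]] = {}
    for s in range(design.n_species):
        species = f"Synthetica sp{s + 1:02d}"
        gene_seqs = [gene_from_mid(m) for m in mids[s]]
        degraded_seqs = [gene_from_mid(mids[s][0] if mids[s] else mid, degraded=True)
                         for _ in range(degraded_copies)]
        constructs = gene_seqs + degraded_seqs
        n_intact = len(gene_seqs)
        for g in range(design.genomes_per_species):
            accession = f"SYN{s + 1:02d}G{g + 1:02d}"
            contig, coords = _build_clean_contig(
                constructs, design.background_length, rng,
                [(ANCHOR_FORWARD, 2, n_intact), (ANCHOR_REVERSE, 2, len(constructs)),
                 (V3_FWD, 0, len(constructs)), (V4_REV, 0, len(constructs))],
            )
            genomes.append(Genome(accession, species, "complete", [("chr1", contig)]))
            species_by_accession[accession] = species
            amplicons_by_genome[accession] = [
                V3_FWD + m + rev_v4 for m in mids[s]
            ]
            gene_coords[accession] = [
                ("chr1", start, end, strand)
                for (start, end, strand) in coords[:n_intact]
            ]
            misses[accession] = [
                ("chr1", start, end, strand)
                for (start, end, strand) in coords[n_intact:]
            ]
    panel = GenomePanel(genus_label="Synthetica", genomes=genomes, source="local")
    truth = GroundTruth(
        design=design,
        species_by_accession=species_by_accession,
        amplicons_by_genome=amplicons_by_genome,
        gene_coords_by_genome=gene_coords,
        designed_misses=misses,
    )
    return panel, truth


def write_panel(panel: GenomePanel, directory: str | Path) -> None:
    """Emit the panel in the exact formats the loader consumes."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "metadata.tsv", "w") as fh:
        fh.write("accession\tspecies\tlevel\n")
        for genome in panel.genomes:
            fh.write(f"{genome.accession}\t{genome.species}\t{genome.level}\n")
            write_genome_fasta(genome, directory / f"{genome.accession}.fasta")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tspecies\tplanted_amplicon_index\tsequence\n")
        for acc in sorted(truth.amplicons_by_genome):
            sp = truth.species_by_accession[acc]
            for idx, seq in enumerate(truth.amplicons_by_genome[acc]):
                fh.write(f"{acc}\t{sp}\t{idx}\t{seq}\n")
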