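"""16S rRNA gene extraction and the 16S-restricted analysis mode.

The standard run restricts amplification to 16S rRNA genes instead of
whole contigs. Genes are located by a built-in anchored-motif
extractor: the near-universal terminal priming motifs (27F/1492R-class
degenerate anchors) are matched with up to two mismatches through the
in-silico PCR machinery, and every product inside the 16S plausibility
window of 1200-1800 nt is reported as a gene. Real genes with degraded
terminal motifs will be missed by anchoring, so an adapter hook accepts
an external rRNA predictor's GFF3 instead; adapter calls are validated
against the same plausibility window and their sequences re-extracted
from the genome.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

from .errors import FormatError
from .genome_io import Genome, GenomePanel
from .insilico_pcr import Amplicon, PrimerPair, amplify_contig, amplify_genome, revcomp

# 27F / 1492R class terminal anchors (written 5'->3')
ANCHOR_FORWARD = "AGAGTTTGATCMTGGCTCAG"
ANCHOR_REVERSE = "TACGGYTACCTTGTTACGACTT"
ANCHOR_MAX_MISMATCH = 2

MIN_16S_LEN = 1200
MAX_16S_LEN = 1800


@dataclass(frozen=True)
class RrnaGene:
    """One 16S rRNA gene, oriented 5'->3' of the gene."""

    genome_accession: str
    contig_id: str
    start: int  # 0-based half-open on the plus strand
    end: int
    strand: Literal["+", "-"]
    sequence: str

    @property
    def gene_id(self) -> str:
        return f"{self.contig_id}:{self.start + 1}-{self.end}({self.strand})"


def _anchor_pair() -> PrimerPair:
    return PrimerPair(
        name="16S-anchor",
        forward=ANCHOR_FORWARD,
        reverse=ANCHOR_REVERSE,
        max_mismatch=ANCHOR_MAX_MISMATCH,
        min_len=MIN_16S_LEN,
        max_len=MAX_16S_LEN,
    )


def extract_16s(genome: Genome) -> list[RrnaGene]:
    """Anchored-motif 16S extraction; empty list means "no 16S detected"."""
    genes = []
    for amp in amplify_genome(genome, _anchor_pair()):
        genes.append(
            RrnaGene(
                genome_accession=genome.accession,
                contig_id=amp.contig_id,
                start=amp.start,
                end=amp.end,
                strand=amp.strand,
                sequence=amp.sequence,
            )
        )
    return genes


def genes_from_gff(genome: Genome, gff_path: str | Path) -> list[RrnaGene]:
    """Adapter hook: take 16S calls from an external predictor's GFF3.

    Rows with type ``rRNA`` whose attributes name a 16S product are
    re-extracted from the genome (reverse complemented for minus-strand
    rows) and validated against the 1200-1800 nt plausibility window;
    out-of-window calls are dropped like any other implausible gene.
    """
    contigs = dict(genome.contigs)
    genes: list[RrnaGene] = []
    for lineno, line in enumerate(Path(gff_path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(f"{gff_path}:{lineno}: GFF3 rows need 9 columns")
        seqid, _, ftype, start1, end1, _, strand, _, attrs = fields[:9]
        if ftype != "rRNA" or "16S" not in attrs:
            continue
        if seqid not in contigs:
            raise FormatError(f"{gff_path}:{lineno}: unknown contig {seqid!r}")
        start, end = int(start1) - 1, int(end1)
        if not MIN_16S_LEN <= end - start <= MAX_16S_LEN:
            continue
        seq = contigs[seqid][start:end]
        if strand == "-":
            seq = revcomp(seq)
        genes.append(
            RrnaGene(genome.accession, seqid, start, end, strand, seq)  # type: ignore[arg-type]
        )
    return genes


def run_16s_mode(
    panel: GenomePanel,
    primer_pair: PrimerPair,
    gff_by_accession: dict[str, str | Path] | None = None,
) -> tuple[dict[str, list[Amplicon]], dict[str, list[RrnaGene]]]:
    """Amplify against extracted 16S genes rather than whole contigs.

    Returns (amplicons per accession, genes per accession). A genome
    with zero extracted genes yields zero amplicons but is
    distinguishable from a primer non-match through its empty gene
    list. Amplicon ``contig_id`` carries the originating gene id so
    provenance maps back to genomic coordinates.
    """
    gff_by_accession = gff_by_accession or {}
    amplicons_by_genome: dict[str, list[Amplicon]] = {}
    genes_by_genome: dict[str, list[RrnaGene]] = {}
    for genome in panel.genomes:
        if genome.accession in gff_by_accession:
            genes = genes_from_gff(genome, gff_by_accession[genome.accession])
        else:
            genes = extract_16s(genome)
        genes_by_genome[genome.accession] = genes
        amplicons: list[Amplicon] = []
        for gene in genes:
            amplicons.extend(
                amplify_contig(gene.gene_id, gene.sequence, primer_pair, genome.accession)
            )
        amplicons_by_genome[genome.accession] = amplicons
    return amplicons_by_genome, genes_by_genome


def write_genes_fasta(genes: Iterable[RrnaGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            fh.write(f">{gene.genome_accession}|{gene.gene_id}\n{gene.sequence}\n")
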