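"""Per-genome and per-panel amplicon statistics.

Covers allele multiplicity (amplicon and distinct-allele counts per
genome), intragenomic divergence (mean pairwise identity of a genome's
amplicons), the panel amplification rate, and the summed per-column
Shannon diversity of a multiple alignment of all amplicons.

The multiple alignment is a deterministic center-star build: every
sequence is globally aligned to the longest input (ties broken
lexicographically) with the clustering module's scoring and merged
under the once-a-gap-always-a-gap rule. Entropy uses the natural
logarithm over A/C/G/T frequencies only — gaps and ambiguity symbols
are excluded from the column distribution (base-2 values are this
times 1/ln 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .clustering import AmpliconCluster, global_align, global_identity
from .errors import ValidationError
from .genome_io import Genome, GenomePanel
from .insilico_pcr import Amplicon

_NUCS = ("A", "C", "G", "T")


@dataclass
class GenomeSummary:
    accession: str
    species: str
    n_amplicons: int
    n_distinct_alleles: int
    mean_intragenomic_identity: float | None  # None when < 2 amplicons


@dataclass
class PanelStats:
    amplification_rate: float
    shannon_sum: float
    n_genomes: int
    n_amplified: int


@dataclass
class AlignmentProfile:
    """Per-column symbol counts of a multiple alignment.

    ``columns[k]`` maps A/C/G/T/other to counts among non-gap symbols;
    gaps are tracked separately in ``gap_counts`` so each column's
    grand total equals ``n_rows``.
    """

    columns: list[dict[str, int]]
    gap_counts: list[int]
    n_rows: int

    @property
    def width(self) -> int:
        return len(self.columns)


def amplification_rate(
    panel: GenomePanel, amplicons_by_genome: Mapping[str, Sequence[Amplicon]]
) -> float:
    """Fraction of panel genomes yielding at least one product."""
    if len(panel) == 0:
        raise ValidationError("empty panel")
    amplified = sum(
        1 for g in panel.genomes if amplicons_by_genome.get(g.accession)
    )
    return amplified / len(panel)


def align_amplicons(sequences: Sequence[str]) -> AlignmentProfile:
    """Center-star multiple alignment, returned as a column profile."""
    if not sequences:
        raise ValidationError("cannot align zero sequences")
    star = min(sequences, key=lambda s: (-len(s), s))
    rest = list(sequences)
    rest.remove(star)

    master = star  # star row with accumulated gaps
    rows: list[str] = [star]
    for seq in rest:
        pair_star, pair_seq, _, _ = global_align(star, seq)
        master, rows = _merge_into(master, rows, pair_star, pair_seq)
    return profile_from_rows(rows)


def _merge_into(
    master: str, rows: list[str], pair_star: str, pair_seq: str
) -> tuple[str, list[str]]:
    """Merge one pairwise alignment into the master (once a gap, always a gap)."""
    new_master: list[str] = []
    new_rows: list[list[str]] = [[] for _ in rows]
    new_seq: list[str] = []
    i = j = 0
    while i < len(master) or j < len(pair_star):
        mi = master[i] if i < len(master) else None
        pj = pair_star[j] if j < len(pair_star) else None
        if mi is not None and pj is not None and (mi == "-") == (pj == "-"):
            new_master.append(mi)
            for out, row in zip(new_rows, rows):
                out.append(row[i])
            new_seq.append(pair_seq[j])
            i += 1
            j += 1
        elif mi == "-" or pj is None:  # master-only gap column
            new_master.append("-")
            for out, row in zip(new_rows, rows):
                out.append(row[i])
            new_seq.append("-")
            i += 1
        else:  # pairwise-only gap column
            new_master.append("-")
            for out in new_rows:
                out.append("-")
            new_seq.append(pair_seq[j])
            j += 1
    merged_rows = ["".join(out) for out in new_rows] + ["".join(new_seq)]
    return "".join(new_master), merged_rows


def profile_from_rows(rows: Sequence[str]) -> AlignmentProfile:
    """Column counts from equal-length aligned rows ('-' marks a gap)."""
    if not rows:
        raise ValidationError("no alignment rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValidationError("alignment rows have unequal lengths")
    columns: list[dict[str, int]] = []
    gap_counts: list[int] = []
    for k in range(width):
        counts = {n: 0 for n in _NUCS}
        counts["other"] = 0
        gaps = 0
        for row in rows:
            char = row[k]
            if char == "-":
                gaps += 1
            elif char in counts:
                counts[char] += 1
            else:
                counts["other"] += 1
        columns.append(counts)
        gap_counts.append(gaps)
    return AlignmentProfile(columns=columns, gap_counts=gap_counts, n_rows=len(rows))


def shannon_column(counts: Mapping[str, int]) -> float:
    """Shannon entropy (nats) of one column's A/C/G/T frequencies.

    Zero when the column is unanimous or holds no admissible symbol.
    """
    nuc_counts = [counts.get(n, 0) for n in _NUCS]
    total = sum(nuc_counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in nuc_counts:
        if c > 0:
            p = c / total
            h -= p * math.log(p)
    return h


def shannon_sum(profile: AlignmentProfile) -> float:
    """Summed Shannon diversity across every alignment column."""
    if profile.width == 0:
        raise ValidationError("empty alignment profile")
    return sum(shannon_column(col) for col in profile.columns)


def genome_summary(
    genome: Genome,
    amplicons: Sequence[Amplicon],
    clusters: Sequence[AmpliconCluster],
) -> GenomeSummary:
    """Multiplicity and divergence of one genome's amplicons."""
    n_amp = len(amplicons)
    n_alleles = sum(1 for cl in clusters if genome.accession in cl.genomes)
    mean_identity: float | None = None
    if n_amp >= 2:
        idents = [
            global_identity(amplicons[i].sequence, amplicons[j].sequence)
            for i in range(n_amp)
            for j in range(i + 1, n_amp)
        ]
        mean_identity = sum(idents) / len(idents)
    return GenomeSummary(
        accession=genome.accession,
        species=genome.species,
        n_amplicons=n_amp,
        n_distinct_alleles=n_alleles,
        mean_intragenomic_identity=mean_identity,
    )


def panel_stats(
    panel: GenomePanel, amplicons_by_genome: Mapping[str, Sequence[Amplicon]]
) -> PanelStats:
    """Panel-level amplification rate and summed Shannon diversity."""
    sequences = [
        amp.sequence
        for genome in panel.genomes
        for amp in amplicons_by_genome.get(genome.accession, [])
    ]
    shannon = shannon_sum(align_amplicons(sequences)) if sequences else 0.0
    n_amplified = sum(
        1 for g in panel.genomes if amplicons_by_genome.get(g.accession)
    )
    return PanelStats(
        amplification_rate=n_amplified / len(panel),
        shannon_sum=shannon,
        n_genomes=len(panel),
        n_amplified=n_amplified,
    )


def write_genome_summaries(summaries: Iterable[GenomeSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "accession\tspecies\tn_amplicons\tn_distinct_alleles\tmean_intragenomic_identity\n"
        )
        for s in summaries:
            ident = "NA" if s.mean_intragenomic_identity is None else f"{s.mean_intragenomic_identity:.4f}"
            fh.write(
                f"{s.accession}\t{s.species}\t{s.n_amplicons}\t{s.n_distinct_alleles}\t{ident}\n"
            )


def write_panel_stats(
    rows: Iterable[tuple[str, str, PanelStats]], path: str | Path
) -> None:
    """One row per (primer name, target label, stats) — the screening table."""
    with open(path, "w") as fh:
        fh.write("primer\ttarget\tamplification_rate\tshannon_sum\tn_genomes\tn_amplified\n")
        for primer, target, stats in rows:
            fh.write(
                f"{primer}\t{target}\t{stats.amplification_rate:.3f}\t"
                f"{stats.shannon_sum:.2f}\t{stats.n_genomes}\t{stats.n_amplified}\n"
            )
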