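"""Genome and panel I/O.

Genomes arrive either from a local directory of FASTA files (optionally
with a ``metadata.tsv`` giving species and assembly level) or from a
download adapter keyed by genus name.  Sequences are case-folded to
uppercase and U is normalised to T on load so genomes and primers share
one alphabet; internal coordinates are 0-based half-open on the plus
strand throughout the package, while file outputs report 1-based
inclusive positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping

from Bio import SeqIO

from .errors import EmptyPanelError, FormatError, OfflineError
from .insilico_pcr import IUPAC_MASK

logger = logging.getLogger(__name__)

Level = Literal["complete", "chromosome", "fragmented"]
LEVELS: tuple[str, ...] = ("complete", "chromosome", "fragmented")

_FASTA_SUFFIXES = {".fa", ".fasta", ".fna"}


@dataclass
class Genome:
    """One assembly: ordered named contigs plus species and completeness."""

    accession: str
    species: str
    level: Level
    contigs: list[tuple[str, str]]


@dataclass
class GenomePanel:
    """A set of genomes analysed together, usually one genus."""

    genus_label: str
    genomes: list[Genome]
    source: Literal["local", "downloaded"] = "local"

    def __len__(self) -> int:
        return len(self.genomes)

    def __iter__(self):
        return iter(self.genomes)


def _normalize_sequence(raw: str, contig_id: str) -> str:
    seq = raw.upper().replace("U", "T")
    for pos, char in enumerate(seq):
        if char not in IUPAC_MASK:
            raise FormatError(
                f"contig {contig_id!r}: non-IUPAC character {char!r} at position {pos + 1}"
            )
    return seq


def _species_from_description(description: str) -> str:
    # description = "<id> <rest...>"; species = first two words of <rest>
    words = description.split()
    if len(words) >= 3:
        return f"{words[1]} {words[2]}"
    return "unknown"


def load_genome(
    fasta_path: str | Path,
    metadata_row: Mapping[str, str] | None = None,
) -> Genome:
    """Load one (multi-)FASTA assembly.

    Species resolution order: metadata table, then the first two
    whitespace-separated words after the accession token of the first
    header, else ``"unknown"``.  Level comes from metadata (default
    ``complete`` — FASTA carries no assembly level).
    """
    fasta_path = Path(fasta_path)
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"{fasta_path}: empty or unparseable FASTA")

    contigs = []
    for rec in records:
        if len(rec.seq) == 0:
            raise FormatError(f"{fasta_path}: contig {rec.id!r} has empty sequence")
        contigs.append((rec.id, _normalize_sequence(str(rec.seq), rec.id)))

    meta = dict(metadata_row or {})
    accession = meta.get("accession") or fasta_path.stem
    species = meta.get("species") or _species_from_description(records[0].description)
    level = meta.get("level") or "complete"
    if level not in LEVELS:
        raise FormatError(f"{fasta_path}: unknown assembly level {level!r}")
    return Genome(accession=accession, species=species, level=level, contigs=contigs)


def _read_metadata_table(path: Path) -> dict[str, dict[str, str]]:
    """Read 'accession<TAB>species<TAB>level' keyed by accession."""
    rows: dict[str, dict[str, str]] = {}
    lines = path.read_text().splitlines()
    if not lines:
        return rows
    header = lines[0].rstrip("\n").split("\t")
    for line in lines[1:]:
        if not line.strip():
            continue
        values = line.split("\t")
        row = dict(zip(header, values))
        if "accession" not in row:
            raise FormatError(f"{path}: metadata rows need an 'accession' column")
        rows[row["accession"]] = row
    return rows


def load_panel(
    directory_or_manifest: str | Path,
    frag_allowed: bool = False,
    genus_label: str = "local",
) -> GenomePanel:
    """Load every genome under a directory (or listed in a manifest TSV).

    Fragmented assemblies are excluded unless ``frag_allowed`` (each
    exclusion is logged with its reason); genomes are sorted by
    accession so the panel is independent of filesystem order.
    """
    src = Path(directory_or_manifest)
    entries: list[tuple[Path, Mapping[str, str] | None]] = []
    if src.is_dir():
        metadata: dict[str, dict[str, str]] = {}
        meta_path = src / "metadata.tsv"
        if meta_path.exists():
            metadata = _read_metadata_table(meta_path)
        for fasta in sorted(src.iterdir()):
            if fasta.suffix.lower() in _FASTA_SUFFIXES:
                entries.append((fasta, metadata.get(fasta.stem)))
    elif src.is_file():
        for row in _read_metadata_table(src).values():
            if "path" not in row:
                raise FormatError(f"{src}: manifest rows need a 'path' column")
            entries.append((src.parent / row["path"], row))
    else:
        raise FormatError(f"{src}: not a directory or manifest file")

    genomes: list[Genome] = []
    for fasta, row in entries:
        genome = load_genome(fasta, row)
        if genome.level == "fragmented" and not frag_allowed:
            logger.info(
                "excluding %s: fragmented assembly (enable frag mode to admit)",
                genome.accession,
            )
            continue
        genomes.append(genome)
    if not genomes:
        raise EmptyPanelError(f"{src}: no admissible genomes")
    genomes.sort(key=lambda g: g.accession)
    seen: set[str] = set()
    for g in genomes:
        if g.accession in seen:
            raise FormatError(f"duplicate accession {g.accession!r} in panel")
        seen.add(g.accession)
    return GenomePanel(genus_label=genus_label, genomes=genomes, source="local")


def fetch_genus(
    genus_name: str,
    level_policy: Literal["complete_only", "chromosome_or_better"] = "complete_only",
    adapter: Callable[[str], Iterable[Genome]] | None = None,
) -> GenomePanel:
    """Obtain a panel through a download adapter (contract only).

    The adapter is any callable mapping a genus name to Genome objects;
    this package ships no network client. ``complete_only`` admits only
    complete assemblies (the default for bacterial panels);
    ``chromosome_or_better`` also admits chromosome-level assemblies, as
    appropriate for non-bacterial targets where complete genomes are
    rare. Pipelines accept the returned panel interchangeably with
    :func:`load_panel` output.
    """
    if adapter is None:
        raise OfflineError(
            "no download adapter configured; run in local mode on a genome directory"
        )
    try:
        fetched = list(adapter(genus_name))
    except OfflineError:
        raise
    except Exception as exc:
        raise OfflineError(
            f"download adapter failed ({exc}); run in local mode on a genome directory"
        ) from exc
    admitted_levels = (
        {"complete"} if level_policy == "complete_only" else {"complete", "chromosome"}
    )
    genomes = sorted(
        (g for g in fetched if g.level in admitted_levels), key=lambda g: g.accession
    )
    if not genomes:
        raise EmptyPanelError(
            f"adapter returned no genomes at level policy {level_policy!r} for {genus_name!r}"
        )
    return GenomePanel(genus_label=genus_name, genomes=genomes, source="downloaded")


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    """Write normalized FASTA; round-trips contigs and their order."""
    with open(path, "w") as fh:
        for contig_id, seq in genome.contigs:
            fh.write(f">{contig_id} {genome.species}\n{seq}\n")


def write_panel_manifest(panel: GenomePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tspecies\tlevel\tn_contigs\ttotal_length\n")
        for g in panel.genomes:
            total = sum(len(seq) for _, seq in g.contigs)
            fh.write(f"{g.accession}\t{g.species}\t{g.level}\t{len(g.contigs)}\t{total}\n")
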