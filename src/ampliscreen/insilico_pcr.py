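"""In-silico PCR with IUPAC-degenerate primers.

Primer sites are located by exact window scanning under a Hamming
(no-indel) mismatch model: a primer position matches a genome position
when the two IUPAC codes share at least one concrete nucleotide, so a
genomic ``N`` matches any primer base and a primer ``W`` matches ``A``
or ``T`` but not ``C``/``G``.  Both orientations of each primer are
searched on the plus-strand text.  Products are formed by pairing a
forward-primer site with the *nearest* correctly oriented reverse-primer
site on the opposite physical strand (the dominant short product of real
PCR), and the emitted amplicon sequence *includes both primer sites*,
oriented 5'->3' starting at the forward site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from .errors import AlphabetError, FormatError, ValidationError

# 4-bit nucleotide-set encoding: A=1, C=2, G=4, T=8.
IUPAC_MASK: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMP_TABLE = str.maketrans(IUPAC_COMPLEMENT)

# mask lookup table indexed by ASCII code; 0 marks an invalid character
_MASK_LUT = np.zeros(128, dtype=np.uint8)
for _c, _m in IUPAC_MASK.items():
    _MASK_LUT[ord(_c)] = _m


def iupac_match(primer_base: str, genome_base: str) -> bool:
    """True iff the two IUPAC codes share at least one concrete nucleotide."""
    try:
        return (IUPAC_MASK[primer_base] & IUPAC_MASK[genome_base]) != 0
    except KeyError as exc:
        raise AlphabetError(f"non-IUPAC character {exc.args[0]!r}") from None


def revcomp(seq: str) -> str:
    """Reverse complement honouring degenerate complements (R<->Y, K<->M...)."""
    bad = set(seq) - IUPAC_MASK.keys()
    if bad:
        raise AlphabetError(f"non-IUPAC character(s) {sorted(bad)!r} in sequence")
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode an IUPAC string as an array of 4-bit nucleotide-set masks."""
    arr = _MASK_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 0).any():
        pos = int(np.argmax(arr == 0))
        raise AlphabetError(f"non-IUPAC character {seq[pos]!r} at position {pos}")
    return arr


@dataclass(frozen=True)
class PrimerPair:
    """A named forward/reverse degenerate primer pair, both written 5'->3'.

    ``max_mismatch`` bounds Hamming mismatches per primer site; the
    default product-length window [50, 6000] admits anything from a
    short tag up to a full rRNA-operon span.
    """

    name: str
    forward: str
    reverse: str
    max_mismatch: int = 2
    min_len: int = 50
    max_len: int = 6000

    def __post_init__(self) -> None:
        for label, oligo in (("forward", self.forward), ("reverse", self.reverse)):
            bad = set(oligo) - IUPAC_MASK.keys()
            if bad:
                raise ValidationError(
                    f"primer {self.name!r} {label}: non-IUPAC character(s) {sorted(bad)!r}"
                )
            if not 10 <= len(oligo) <= 60:
                raise ValidationError(
                    f"primer {self.name!r} {label}: length {len(oligo)} outside [10, 60]"
                )
        if self.max_mismatch < 0:
            raise ValidationError(f"primer {self.name!r}: max_mismatch must be >= 0")
        if not 0 < self.min_len < self.max_len:
            raise ValidationError(
                f"primer {self.name!r}: need 0 < min_len < max_len, "
                f"got [{self.min_len}, {self.max_len}]"
            )


@dataclass(frozen=True)
class PrimerSite:
    """One primer binding window on a contig (0-based half-open, plus-strand text)."""

    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    mismatches: int
    which: Literal["forward", "reverse"]


@dataclass(frozen=True)
class Amplicon:
    """An extracted product spanning both primer sites inclusive.

    ``start``/``end`` are 0-based half-open on the plus strand of the
    source contig; ``strand`` is the strand carrying the forward site;
    ``sequence`` is oriented to begin with the forward primer site.
    """

    genome_accession: str
    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    sequence: str

    def __len__(self) -> int:
        return self.end - self.start


def find_sites(
    primer: str,
    contig_seq: str,
    max_mismatch: int,
    contig_id: str = "",
    which: Literal["forward", "reverse"] = "forward",
) -> list[PrimerSite]:
    """All windows where the primer (either orientation) binds within budget.

    A ``+`` site means the primer as written matches the plus-strand
    text; a ``-`` site means its reverse complement does, i.e. the
    primer anneals to the minus strand. Sites are sorted by start, then
    strand. No indels are modelled.
    """
    m = len(primer)
    if len(contig_seq) < m:
        return []
    enc_contig = encode(contig_seq)
    sites: list[PrimerSite] = []
    for strand, oligo in (("+", primer), ("-", revcomp(primer))):
        counts = _window_mismatches(encode(oligo), enc_contig)
        for start in np.flatnonzero(counts <= max_mismatch):
            sites.append(
                PrimerSite(contig_id, int(start), int(start) + m, strand,
                           int(counts[start]), which)
            )
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _window_mismatches(enc_primer: np.ndarray, enc_contig: np.ndarray) -> np.ndarray:
    """Mismatch count of every length-m window against the primer masks."""
    m = len(enc_primer)
    n_win = len(enc_contig) - m + 1
    counts = np.zeros(n_win, dtype=np.int32)
    for j in range(m):
        counts += (enc_contig[j : j + n_win] & enc_primer[j]) == 0
    return counts


def pair_sites(
    forward_sites: Iterable[PrimerSite],
    reverse_sites: Iterable[PrimerSite],
    min_len: int,
    max_len: int,
    contig_seq: str,
    genome_accession: str = "",
) -> list[Amplicon]:
    """Pair forward with nearest admissible opposite-strand reverse sites.

    A plus-orientation product pairs a ``+`` forward site with a ``-``
    reverse site strictly downstream of it; a minus-orientation product
    is the mirror image and its sequence is reverse complemented so it
    begins with the forward primer. For each forward site only the
    shortest admissible product is emitted.
    """
    fwd = list(forward_sites)
    rev = list(reverse_sites)
    amplicons: list[Amplicon] = []

    rev_minus = sorted((s for s in rev if s.strand == "-"), key=lambda s: s.end)
    for f in (s for s in fwd if s.strand == "+"):
        best = None
        for r in rev_minus:  # sorted by end => first admissible is nearest
            if r.start >= f.end and min_len <= r.end - f.start <= max_len:
                best = r
                break
        if best is not None:
            seq = contig_seq[f.start : best.end]
            amplicons.append(
                Amplicon(genome_accession, f.contig_id, f.start, best.end, "+", seq)
            )

    rev_plus = sorted((s for s in rev if s.strand == "+"),
                      key=lambda s: s.start, reverse=True)
    for f in (s for s in fwd if s.strand == "-"):
        best = None
        for r in rev_plus:  # descending start => first admissible is nearest
            if r.end <= f.start and min_len <= f.end - r.start <= max_len:
                best = r
                break
        if best is not None:
            seq = revcomp(contig_seq[best.start : f.end])
            amplicons.append(
                Amplicon(genome_accession, f.contig_id, best.start, f.end, "-", seq)
            )

    amplicons.sort(key=lambda a: (a.start, a.strand))
    return amplicons


def amplify_contig(
    contig_id: str,
    contig_seq: str,
    pair: PrimerPair,
    genome_accession: str = "",
) -> list[Amplicon]:
    fwd = find_sites(pair.forward, contig_seq, pair.max_mismatch, contig_id, "forward")
    rev = find_sites(pair.reverse, contig_seq, pair.max_mismatch, contig_id, "reverse")
    return pair_sites(fwd, rev, pair.min_len, pair.max_len, contig_seq, genome_accession)


def amplify_genome(genome, pair: PrimerPair) -> list[Amplicon]:
    """All products across a genome's contigs, in contig order then start.

    Amplicons never span contig boundaries. A genome returning an empty
    list counts as non-amplified downstream.
    """
    amplicons: list[Amplicon] = []
    for contig_id, seq in genome.contigs:
        amplicons.extend(amplify_contig(contig_id, seq, pair, genome.accession))
    return amplicons


def read_primer_file(path: str | Path) -> list[PrimerPair]:
    """Parse a primer TSV: name, forward, reverse, optional max_mismatch.

    Lines starting with '#' and a header line beginning with 'name' are
    ignored, so the shipped defaults file is directly editable.
    """
    path = Path(path)
    pairs: list[PrimerPair] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0].lower() == "name":
            continue
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
        name, forward, reverse = fields[0], fields[1].upper(), fields[2].upper()
        kwargs = {}
        if len(fields) >= 4 and fields[3]:
            kwargs["max_mismatch"] = int(fields[3])
        pairs.append(PrimerPair(name, forward, reverse, **kwargs))
    if not pairs:
        raise FormatError(f"{path}: no primer pairs found")
    return pairs


def amplicon_header(amp: Amplicon) -> str:
    """FASTA header ``accession|contig|start|end|strand`` (1-based inclusive)."""
    return f"{amp.genome_accession}|{amp.contig_id}|{amp.start + 1}|{amp.end}|{amp.strand}"


def write_amplicons_fasta(amplicons: Iterable[Amplicon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for amp in amplicons:
            fh.write(f">{amplicon_header(amp)}\n{amp.sequence}\n")
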