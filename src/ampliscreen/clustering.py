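"""Amplicon allele clustering at a user identity threshold.

Identity between two amplicons is computed from a Needleman–Wunsch
global alignment (match +1, mismatch -1, gap -2) with *free terminal
gaps*, as matches divided by alignment columns excluding terminal-gap
columns — so a perfect substring scores by its overlap rather than
being penalised for length.

Clustering is greedy centroid assignment in the style of dereplication
tools: amplicons sorted by (descending length, sequence, accession) are
attached to the first existing centroid at or above the threshold, else
they seed a new cluster. At the default threshold of 1.0 membership is
exact string equality (ASV granularity), which makes ``cluster(x, 1.0)``
coincide with :func:`dereplicate` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .insilico_pcr import Amplicon, amplicon_header

MATCH = 1
MISMATCH = -1
GAP = -2


def validate_threshold(value: float) -> float:
    if not 0.7 <= value <= 1.0:
        raise ValidationError(f"identity threshold {value} outside [0.7, 1.0]")
    return float(value)


def _score_matrix(a: str, b: str) -> np.ndarray:
    """Fill the free-end-gap DP matrix, vectorised row by row.

    The left-dependency within a row is resolved as a prefix-max scan:
    S[i,j] = max_k<=j (T[k] - GAP_COST*(j-k)) with T the best of the
    diagonal/up moves, which equals cummax(T[k] - 2k reversed-sign)
    adjusted by the column index.
    """
    n, m = len(a), len(b)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    S = np.zeros((n + 1, m + 1), dtype=np.int32)
    cols = np.arange(1, m + 1, dtype=np.int32)
    for i in range(1, n + 1):
        sub = np.where(bv == av[i - 1], MATCH, MISMATCH).astype(np.int32)
        T = np.maximum(S[i - 1, :m] + sub, S[i - 1, 1:] + GAP)
        # include a gap chain entering from column 0 of this row (score 0 start
        # only at j=0 for free leading gaps handled via S[i,0]=0)
        T0 = np.empty(m + 1, dtype=np.int32)
        T0[0] = S[i, 0]  # = 0, free leading gaps in b
        T0[1:] = T
        U = T0 - GAP * np.concatenate(([np.int32(0)], cols))
        np.maximum.accumulate(U, out=U)
        S[i, 1:] = U[1:] + GAP * cols
    return S


def global_align(a: str, b: str) -> tuple[str, str, int, int]:
    """Align a against b; return (aligned_a, aligned_b, matches, core_cols).

    ``core_cols`` counts alignment columns excluding terminal-gap runs.
    Tie-breaks are fixed (end cell nearest the corner; traceback prefers
    diagonal, then a gap in ``b``) so results are deterministic.
    """
    if not a or not b:
        raise ValidationError("cannot align an empty sequence")
    if a == b:
        return a, b, len(a), len(a)
    n, m = len(a), len(b)
    S = _score_matrix(a, b)

    best = (np.iinfo(np.int32).min, -1, -1)
    for i in range(n, -1, -1):
        cand = (int(S[i, m]), i, m)
        if cand[0] > best[0]:
            best = cand
    for j in range(m, -1, -1):
        cand = (int(S[n, j]), n, j)
        if cand[0] > best[0]:
            best = cand
    _, ei, ej = best

    # terminal suffix: pad the shorter side with gaps down to the corner
    out_a: list[str] = list(a[ei:]) + ["-"] * (m - ej)
    out_b: list[str] = ["-"] * (n - ei) + list(b[ej:])
    out_a.reverse()
    out_b.reverse()

    matches = 0
    core = 0
    i, j = ei, ej
    while i > 0 and j > 0:
        s = S[i, j]
        sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
        if s == S[i - 1, j - 1] + sub:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif s == S[i - 1, j] + GAP:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        core += 1

    # terminal prefix
    out_a.extend(["-"] * j)
    out_a.extend(reversed(a[:i]))
    out_b.extend(reversed(b[:j]))
    out_b.extend(["-"] * i)
    return "".join(reversed(out_a)), "".join(reversed(out_b)), matches, core


def global_identity(a: str, b: str) -> float:
    """Fractional identity in [0, 1] under the free-terminal-gap alignment."""
    if not a or not b:
        raise ValidationError("cannot compute identity of an empty sequence")
    if a == b:
        return 1.0
    _, _, matches, core = global_align(a, b)
    if core == 0:
        return 0.0
    return matches / core


@dataclass
class AmpliconCluster:
    """A group of amplicons within the identity threshold of a centroid."""

    cluster_id: int
    centroid: Amplicon
    members: list[Amplicon]
    genomes: set[str]
    species: set[str]
    member_identities: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def _sort_key(amp: Amplicon):
    return (-len(amp.sequence), amp.sequence, amp.genome_accession,
            amp.contig_id, amp.start, amp.strand)


def cluster(
    amplicons: Sequence[Amplicon],
    threshold: float = 1.0,
    species_by_accession: Mapping[str, str] | None = None,
) -> list[AmpliconCluster]:
    """Greedy centroid clustering of oriented amplicon sequences."""
    threshold = validate_threshold(threshold)
    if not amplicons:
        raise ValidationError("cannot cluster an empty amplicon list")
    species_by_accession = species_by_accession or {}
    ordered = sorted(amplicons, key=_sort_key)

    clusters: list[AmpliconCluster] = []
    exact_index: dict[str, AmpliconCluster] = {}
    for amp in ordered:
        target: AmpliconCluster | None = None
        identity = 1.0
        if threshold == 1.0:
            target = exact_index.get(amp.sequence)
        else:
            for cl in clusters:
                ident = global_identity(amp.sequence, cl.centroid.sequence)
                if ident >= threshold:
                    target, identity = cl, ident
                    break
        if target is None:
            target = AmpliconCluster(len(clusters), amp, [], set(), set())
            clusters.append(target)
            exact_index[amp.sequence] = target
            identity = 1.0
        target.members.append(amp)
        target.member_identities.append(identity)
        target.genomes.add(amp.genome_accession)
        target.species.add(
            species_by_accession.get(amp.genome_accession, "unknown")
        )
    return clusters


def dereplicate(
    amplicons: Sequence[Amplicon],
    species_by_accession: Mapping[str, str] | None = None,
) -> list[AmpliconCluster]:
    """Exact-sequence grouping; equivalent to clustering at identity 1.0."""
    return cluster(amplicons, 1.0, species_by_accession)


def write_cluster_table(clusters: Iterable[AmpliconCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcentroid_header\tmember_header\tidentity_to_centroid\n")
        for cl in clusters:
            centroid = amplicon_header(cl.centroid)
            for amp, ident in zip(cl.members, cl.member_identities):
                fh.write(f"{cl.cluster_id}\t{centroid}\t{amplicon_header(amp)}\t{ident:.4f}\n")


def write_centroid_fasta(clusters: Iterable[AmpliconCluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for cl in clusters:
            fh.write(f">cluster_{cl.cluster_id}|{amplicon_header(cl.centroid)}\n"
                     f"{cl.centroid.sequence}\n")
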