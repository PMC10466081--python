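"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive results from first principles
(exhaustive window scans, plain-python dynamic programming, union-find,
set algebra) so they share no code path with the implementation they
check.
"""

from __future__ import annotations

import numpy as np
import pytest

from ampliscreen.insilico_pcr import Amplicon

# ---------------------------------------------------------------- oracles

# IUPAC nucleotide sets written out longhand, independent of the package's
# bitmask tables
IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": {"A", "C", "G", "T"},
}

ORACLE_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


def oracle_revcomp(seq: str) -> str:
    return "".join(ORACLE_COMPLEMENT[c] for c in reversed(seq))


def brute_force_sites(primer: str, contig: str, max_mismatch: int):
    """Exhaustive window scan over both orientations; (start, strand, mm)."""
    hits = []
    m = len(primer)
    for strand, oligo in (("+", primer), ("-", oracle_revcomp(primer))):
        for start in range(len(contig) - m + 1):
            mm = 0
            for p_char, g_char in zip(oligo, contig[start : start + m]):
                if not (IUPAC_SETS[p_char] & IUPAC_SETS[g_char]):
                    mm += 1
                    if mm > max_mismatch:
                        break
            else:
                hits.append((start, strand, mm))
    hits.sort()
    return hits


def nw_oracle(a: str, b: str) -> tuple[int, float]:
    """Plain-python free-end-gap global alignment: (score, identity).

    Match +1, mismatch -1, gap -2; terminal gaps free; identity is
    matches over non-terminal-gap alignment columns. Tie conventions
    match the declared ones (end cell nearest the corner in the last
    column first, traceback prefers diagonal, then a gap in b).
    """
    n, m = len(a), len(b)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = 1 if a[i - 1] == b[j - 1] else -1
            S[i][j] = max(S[i - 1][j - 1] + sub, S[i - 1][j] - 2, S[i][j - 1] - 2)
    best_score, ei, ej = S[n][m], n, m
    for i in range(n, -1, -1):
        if S[i][m] > best_score:
            best_score, ei, ej = S[i][m], i, m
    for j in range(m, -1, -1):
        if S[n][j] > best_score:
            best_score, ei, ej = S[n][j], n, j
    matches = cols = 0
    i, j = ei, ej
    while i > 0 and j > 0:
        sub = 1 if a[i - 1] == b[j - 1] else -1
        if S[i][j] == S[i - 1][j - 1] + sub:
            matches += a[i - 1] == b[j - 1]
            i -= 1
            j -= 1
        elif S[i][j] == S[i - 1][j] - 2:
            i -= 1
        else:
            j -= 1
        cols += 1
    return best_score, (matches / cols if cols else 0.0)


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        self.parent[self.find(x)] = self.find(y)

    def components(self):
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return list(groups.values())


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


# ---------------------------------------------------------------- fixtures


def make_amplicon(seq: str, accession: str = "G1", contig: str = "c1",
                  start: int = 0, strand: str = "+") -> Amplicon:
    return Amplicon(accession, contig, start, start + len(seq), strand, seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231)
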