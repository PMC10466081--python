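"""Allele sharing between genomes and species.

Builds the genomes x allele-clusters presence matrix, the species
overlap fraction (a species "overlaps" when at least one of its
amplicons sits in a cluster that also holds another species' amplicon),
and the shared-allele network: genomes as nodes, an edge wherever two
genomes hold amplicons in a common cluster, weighted by the number of
such shared clusters.

Genomes labelled ``"unknown"`` never enter the species-overlap
percentage; they are reported separately so local panels without
taxonomy still get genome-level results.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .clustering import AmpliconCluster
from .genome_io import GenomePanel


def presence_matrix(
    panel: GenomePanel, clusters: Sequence[AmpliconCluster]
) -> pd.DataFrame:
    """Genomes (rows, by accession) x cluster ids (columns): amplicon counts.

    Non-amplified genomes keep an all-zero row; row sums equal each
    genome's amplicon count and column sums equal cluster sizes.
    """
    accessions = sorted(g.accession for g in panel.genomes)
    cluster_ids = sorted(cl.cluster_id for cl in clusters)
    matrix = pd.DataFrame(0, index=accessions, columns=cluster_ids, dtype=int)
    for cl in clusters:
        for amp in cl.members:
            matrix.loc[amp.genome_accession, cl.cluster_id] += 1
    matrix.index.name = "accession"
    return matrix


@dataclass
class SpeciesOverlap:
    """Species-level allele-sharing report.

    ``fraction`` is overlapping species divided by species with at
    least one amplicon, or None when no named species amplified;
    ``pairs`` maps unordered species pairs to shared-cluster counts.
    """

    fraction: float | None
    overlapping_species: set[str]
    amplified_species: set[str]
    pairs: dict[tuple[str, str], int]
    n_unknown_genomes_amplified: int = 0


def species_overlap(
    clusters: Sequence[AmpliconCluster], panel: GenomePanel
) -> SpeciesOverlap:
    amplified = {sp for cl in clusters for sp in cl.species if sp != "unknown"}
    pairs: dict[tuple[str, str], int] = {}
    for cl in clusters:
        named = sorted(sp for sp in cl.species if sp != "unknown")
        for a, b in combinations(named, 2):
            pairs[(a, b)] = pairs.get((a, b), 0) + 1
    overlapping = {sp for pair in pairs for sp in pair}
    n_unknown = len(
        {amp.genome_accession for cl in clusters for amp in cl.members
         if "unknown" in cl.species}
        & {g.accession for g in panel.genomes if g.species == "unknown"}
    )
    fraction = len(overlapping) / len(amplified) if amplified else None
    return SpeciesOverlap(
        fraction=fraction,
        overlapping_species=overlapping,
        amplified_species=amplified,
        pairs=pairs,
        n_unknown_genomes_amplified=n_unknown,
    )


def build_graph(presence: pd.DataFrame) -> nx.Graph:
    """Shared-allele network from the presence matrix.

    Edge weight (g1, g2) = number of clusters where both genomes have a
    nonzero cell. Every genome is kept as a node (isolated ones are
    dropped only at rendering time).
    """
    graph = nx.Graph()
    graph.add_nodes_from(presence.index)
    occupied = presence > 0
    for g1, g2 in combinations(presence.index, 2):
        weight = int((occupied.loc[g1] & occupied.loc[g2]).sum())
        if weight >= 1:
            graph.add_edge(g1, g2, weight=weight)
    return graph


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Components among genomes with at least one edge, largest first."""
    connected = graph.subgraph([n for n, d in graph.degree() if d > 0])
    comps = [set(c) for c in nx.connected_components(connected)]
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def write_presence_matrix(presence: pd.DataFrame, path: str | Path) -> None:
    presence.to_csv(path, sep="\t")


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source\ttarget\tweight\n")
        for g1, g2 in sorted(graph.edges()):
            fh.write(f"{g1}\t{g2}\t{graph.edges[g1, g2]['weight']}\n")


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    # rebuild in sorted order so serialization is byte-deterministic
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes(data=True)))
    ordered.add_edges_from(
        (g1, g2, graph.edges[g1, g2]) for g1, g2 in sorted(graph.edges())
    )
    nx.write_graphml(ordered, str(path))


def write_overlap_report(
    clusters: Sequence[AmpliconCluster],
    overlap: SpeciesOverlap,
    path: str | Path,
) -> None:
    """Plain-text overlap report: per-cluster species, per-pair counts."""
    with open(path, "w") as fh:
        fh.write("# Species overlap report\n")
        if overlap.fraction is None:
            fh.write("overlap_fraction\tundefined (no amplified named species)\n")
        else:
            fh.write(f"overlap_fraction\t{overlap.fraction:.4f}\n")
        fh.write(f"amplified_species\t{len(overlap.amplified_species)}\n")
        fh.write(f"overlapping_species\t{len(overlap.overlapping_species)}\n")
        fh.write(f"unknown_genomes_amplified\t{overlap.n_unknown_genomes_amplified}\n")
        fh.write("\n# Cluster membership (cluster_id: species)\n")
        for cl in clusters:
            fh.write(f"cluster_{cl.cluster_id}\t{', '.join(sorted(cl.species))}\n")
        fh.write("\n# Species pairs sharing clusters (pair: n_shared_clusters)\n")
        for (a, b), count in sorted(overlap.pairs.items()):
            fh.write(f"{a} | {b}\t{count}\n")
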