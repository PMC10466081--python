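"""Presence matrix, species overlap, and the shared-allele network."""

import itertools

import numpy as np
import pytest

from ampliscreen.clustering import cluster
from ampliscreen.genome_io import Genome, GenomePanel
from ampliscreen.overlap import (
    build_graph,
    connected_components,
    presence_matrix,
    species_overlap,
)
from conftest import UnionFind, make_amplicon
import pandas as pd


def _panel(species_by_accession):
    genomes = [
        Genome(acc, sp, "complete", [("c", "ACGT")])
        for acc, sp in sorted(species_by_accession.items())
    ]
    return GenomePanel("Synthetica", genomes)


def _cluster_fixture(assignments, species_by_accession):
    """assignments: allele sequence -> list of accessions carrying it."""
    amps = [
        make_amplicon(seq, accession=acc)
        for seq, accs in assignments.items()
        for acc in accs
    ]
    return cluster(amps, 1.0, species_by_accession)


def test_presence_matrix_shared_cluster():
    species = {"G1": "Synthetica sp01", "G2": "Synthetica sp02"}
    clusters = _cluster_fixture({"ACGTACGTACGT" * 5: ["G1", "G2"]}, species)
    matrix = presence_matrix(_panel(species), clusters)
    assert matrix.shape == (2, 1)
    assert (matrix.values == 1).all()


def test_presence_matrix_multi_copy_cell():
    species = {"G1": "Synthetica sp01"}
    clusters = _cluster_fixture({"ACGTACGTACGT" * 5: ["G1", "G1", "G1"]}, species)
    matrix = presence_matrix(_panel(species), clusters)
    assert matrix.values.tolist() == [[3]]


def test_presence_matrix_keeps_zero_rows():
    species = {"G1": "Synthetica sp01", "G2": "Synthetica sp02"}
    clusters = _cluster_fixture({"ACGTACGTACGT" * 5: ["G1"]}, species)
    matrix = presence_matrix(_panel(species), clusters)
    assert matrix.loc["G2"].sum() == 0
    assert matrix.values.sum() == 1  # conservation


def test_presence_matrix_row_and_column_sums(rng):
    species = {f"G{i}": f"Synthetica sp{i:02d}" for i in range(4)}
    pool = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(3)]
    amps = []
    for acc in species:
        for _ in range(int(rng.integers(1, 5))):
            amps.append(make_amplicon(str(rng.choice(pool)), accession=acc))
    clusters = cluster(amps, 1.0, species)
    matrix = presence_matrix(_panel(species), clusters)
    per_genome = {acc: sum(1 for a in amps if a.genome_accession == acc)
                  for acc in species}
    for acc, total in per_genome.items():
        assert matrix.loc[acc].sum() == total
    for cl in clusters:
        assert matrix[cl.cluster_id].sum() == len(cl.members)


def test_species_overlap_half_of_four_species():
    species = {f"G{i}": f"Synthetica sp{i:02d}" for i in range(4)}
    shared = "ACGT" * 20
    assignments = {
        shared: ["G0", "G1"],
        "AAGT" * 20: ["G2"],
        "CCGT" * 20: ["G3"],
    }
    clusters = _cluster_fixture(assignments, species)
    result = species_overlap(clusters, _panel(species))
    assert result.fraction == pytest.approx(0.5)
    assert result.pairs == {("Synthetica sp00", "Synthetica sp01"): 1}


def test_species_overlap_all_unique_fully_resolving():
    species = {f"G{i}": f"Synthetica sp{i:02d}" for i in range(3)}
    assignments = {f"{nuc}CGT" * 20: [acc]
                   for nuc, acc in zip("ATG", sorted(species))}
    result = species_overlap(_cluster_fixture(assignments, species), _panel(species))
    assert result.fraction == 0.0
    assert result.pairs == {}


def test_species_overlap_unknown_excluded_from_fraction():
    species = {"G1": "Synthetica sp01", "G2": "unknown"}
    clusters = _cluster_fixture({"ACGT" * 20: ["G1", "G2"]}, species)
    result = species_overlap(clusters, _panel(species))
    assert result.fraction == 0.0  # 'unknown' cannot create overlap
    assert result.n_unknown_genomes_amplified == 1


def test_species_overlap_matches_set_algebra_oracle(rng):
    species = {f"G{i}": f"Synthetica sp{i % 4:02d}" for i in range(8)}
    pool = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(5)]
    amps = [
        make_amplicon(str(rng.choice(pool)), accession=acc)
        for acc in species
        for _ in range(int(rng.integers(1, 4)))
    ]
    clusters = cluster(amps, 1.0, species)
    result = species_overlap(clusters, _panel(species))

    # oracle: recompute from raw membership lists
    seq_species: dict[str, set] = {}
    for amp in amps:
        seq_species.setdefault(amp.sequence, set()).add(species[amp.genome_accession])
    overlapping = {
        sp for sps in seq_species.values() if len(sps) > 1 for sp in sps
    }
    amplified = {species[a.genome_accession] for a in amps}
    assert result.fraction == pytest.approx(len(overlapping) / len(amplified))
    expected_pairs = {}
    for sps in seq_species.values():
        for a, b in itertools.combinations(sorted(sps), 2):
            expected_pairs[(a, b)] = expected_pairs.get((a, b), 0) + 1
    assert result.pairs == expected_pairs


def test_species_overlap_invariant_to_cluster_renumbering(rng):
    species = {f"G{i}": f"Synthetica sp{i % 3:02d}" for i in range(6)}
    pool = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(4)]
    amps = [make_amplicon(str(rng.choice(pool)), accession=acc) for acc in species]
    clusters = cluster(amps, 1.0, species)
    renumbered = list(reversed(clusters))
    a = species_overlap(clusters, _panel(species))
    b = species_overlap(renumbered, _panel(species))
    assert a.fraction == b.fraction and a.pairs == b.pairs


def test_build_graph_edge_weight_counts_shared_clusters():
    species = {"G1": "s1", "G2": "s2"}
    clusters = _cluster_fixture(
        {"ACGT" * 20: ["G1", "G2"], "TTAA" * 20: ["G1", "G2"]}, species
    )
    graph = build_graph(presence_matrix(_panel(species), clusters))
    assert graph.number_of_edges() == 1
    assert graph.edges["G1", "G2"]["weight"] == 2


def test_build_graph_no_sharing_is_edgeless():
    species = {"G1": "s1", "G2": "s2"}
    clusters = _cluster_fixture({"ACGT" * 20: ["G1"], "TTAA" * 20: ["G2"]}, species)
    graph = build_graph(presence_matrix(_panel(species), clusters))
    assert graph.number_of_edges() == 0
    assert set(graph.nodes) == {"G1", "G2"}  # nodes retained in the object


def test_build_graph_matches_column_intersection_oracle(rng):
    accs = [f"G{i}" for i in range(8)]
    matrix = pd.DataFrame(
        rng.integers(0, 3, size=(8, 6)), index=accs, columns=range(6)
    )
    graph = build_graph(matrix)
    for g1, g2 in itertools.combinations(accs, 2):
        expected = sum(
            1 for c in matrix.columns
            if matrix.loc[g1, c] > 0 and matrix.loc[g2, c] > 0
        )
        if expected:
            assert graph.edges[g1, g2]["weight"] == expected
        else:
            assert not graph.has_edge(g1, g2)


def test_connected_components_examples():
    species = {f"G{i}": f"s{i}" for i in range(5)}
    clusters = _cluster_fixture(
        {"ACGT" * 20: ["G0", "G1"], "TTAA" * 20: ["G1", "G2"],
         "GGCC" * 20: ["G3", "G4"]},
        species,
    )
    graph = build_graph(presence_matrix(_panel(species), clusters))
    comps = connected_components(graph)
    assert sorted(map(sorted, comps)) == [["G0", "G1", "G2"], ["G3", "G4"]]


def test_connected_components_match_union_find_oracle(rng):
    accs = [f"G{i}" for i in range(10)]
    matrix = pd.DataFrame(
        (rng.random((10, 5)) < 0.3).astype(int), index=accs, columns=range(5)
    )
    graph = build_graph(matrix)
    comps = connected_components(graph)

    uf = UnionFind(accs)
    for g1, g2 in graph.edges():
        uf.union(g1, g2)
    linked = {n for n, d in graph.degree() if d > 0}
    expected = [c for c in uf.components() if c <= linked and len(c) >= 1 and c & linked]
    expected = [c for c in expected if any(n in linked for n in c)]
    assert sorted(map(sorted, comps)) == sorted(map(sorted, expected))
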