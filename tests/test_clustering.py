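"""Identity scoring and greedy centroid clustering."""

import itertools

import pytest
from Bio import Align

from ampliscreen.clustering import (
    cluster,
    dereplicate,
    global_align,
    global_identity,
    validate_threshold,
)
from ampliscreen.errors import ValidationError
from conftest import make_amplicon, nw_oracle, random_dna


def _biopython_score(a: str, b: str) -> float:
    """Independent optimal score under the same free-end-gap scoring."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_insertion_score = 0  # free terminal gaps on either side
    aligner.end_deletion_score = 0
    return aligner.score(a, b)


def test_identity_of_identical_sequences():
    seq = "ACGT" * 25
    assert global_identity(seq, seq) == 1.0


def test_identity_two_substitutions_in_100():
    a = "A" * 50 + "C" * 50
    b = a[:10] + "G" + a[11:80] + "T" + a[81:]
    assert global_identity(a, b) == pytest.approx(0.98)


def test_identity_perfect_substring_scores_by_overlap():
    assert global_identity("ACGTACGTAC", "TTACGTACGTACTT") == 1.0


def test_identity_rejects_empty():
    with pytest.raises(ValidationError):
        global_identity("", "ACGT")


def test_identity_bounded_and_score_symmetric(rng):
    """Identity stays in [0,1]; the optimal score itself is symmetric.

    (The identity value is tied to one deterministically chosen optimal
    alignment, so for dissimilar pairs it need not be exactly symmetric
    even though the score is.)
    """
    for _ in range(20):
        a = random_dna(rng, int(rng.integers(10, 50)))
        b = random_dna(rng, int(rng.integers(10, 50)))
        assert 0.0 <= global_identity(a, b) <= 1.0
        assert nw_oracle(a, b)[0] == nw_oracle(b, a)[0]


def test_identity_matches_independent_dp_oracle(rng):
    """Implementation vs a plain-python DP; oracle scores vs biopython."""
    for _ in range(80):
        a = random_dna(rng, int(rng.integers(5, 61)))
        b = random_dna(rng, int(rng.integers(5, 61)))
        score, identity = nw_oracle(a, b)
        assert score == _biopython_score(a, b)
        assert global_identity(a, b) == pytest.approx(identity)


def test_alignment_round_trip_preserves_sequences(rng):
    for _ in range(20):
        a = random_dna(rng, int(rng.integers(5, 40)))
        b = random_dna(rng, int(rng.integers(5, 40)))
        aa, bb, _, _ = global_align(a, b)
        assert len(aa) == len(bb)
        assert aa.replace("-", "") == a
        assert bb.replace("-", "") == b


@pytest.mark.parametrize("value", [0.69, 1.01, -1.0, 2.0])
def test_threshold_validation_rejects_out_of_range(value):
    with pytest.raises(ValidationError):
        validate_threshold(value)


def test_dereplicate_groups_exact_sequences():
    amps = [make_amplicon("ACGT" * 20, accession=f"G{i}") for i in range(3)]
    amps.append(make_amplicon("TTTT" * 20, accession="G9"))
    clusters = dereplicate(amps)
    assert sorted(len(c) for c in clusters) == [1, 3]


def test_dereplicate_all_unique_gives_singletons(rng):
    amps = [make_amplicon(random_dna(rng, 60), accession=f"G{i}") for i in range(6)]
    assert all(len(c) == 1 for c in dereplicate(amps))


def test_cluster_at_one_equals_dereplicate(rng):
    pool = [random_dna(rng, 60) for _ in range(4)]
    amps = [make_amplicon(str(rng.choice(pool)), accession=f"G{i}") for i in range(15)]
    derep = dereplicate(amps)
    clustered = cluster(amps, 1.0)
    as_sets = lambda cs: sorted(
        sorted((a.genome_accession, a.sequence) for a in c.members) for c in cs
    )
    assert as_sets(derep) == as_sets(clustered)


def test_threshold_splits_and_merges_near_identical_pair():
    a = "A" * 50 + "C" * 49 + "G"
    b = "A" * 50 + "C" * 49 + "T"  # 0.99 identity to a
    amps = [make_amplicon(a, accession="G1"), make_amplicon(b, accession="G2")]
    assert len(cluster(amps, 0.98)) == 1
    assert len(cluster(amps, 1.0)) == 2


def test_cluster_partitions_the_input(rng):
    amps = [make_amplicon(random_dna(rng, 40), accession=f"G{i}") for i in range(12)]
    clusters = cluster(amps, 0.9)
    members = sorted(a.sequence for c in clusters for a in c.members)
    assert members == sorted(a.sequence for a in amps)


def test_cluster_members_within_threshold_of_centroid(rng):
    base = random_dna(rng, 80)
    amps = []
    for i in range(10):
        pos = int(rng.integers(0, 80))
        mutated = base[:pos] + "ACGT"[int(rng.integers(4))] + base[pos + 1 :]
        amps.append(make_amplicon(mutated, accession=f"G{i}"))
    for cl in cluster(amps, 0.9):
        for amp in cl.members:
            assert global_identity(amp.sequence, cl.centroid.sequence) >= 0.9


def test_cluster_is_order_invariant(rng):
    amps = [make_amplicon(random_dna(rng, 50), accession=f"G{i}") for i in range(10)]
    reference = cluster(amps, 0.85)
    for perm_seed in range(3):
        shuffled = list(amps)
        rng2 = __import__("numpy").random.default_rng(perm_seed)
        rng2.shuffle(shuffled)
        permuted = cluster(shuffled, 0.85)
        key = lambda cs: [
            sorted((a.genome_accession, a.sequence) for a in c.members) for c in cs
        ]
        assert key(reference) == key(permuted)


def test_cluster_count_monotone_in_threshold(rng):
    base = random_dna(rng, 100)
    amps = []
    for i in range(10):
        seq = base
        for _ in range(int(rng.integers(0, 12))):
            pos = int(rng.integers(0, 100))
            seq = seq[:pos] + "ACGT"[int(rng.integers(4))] + seq[pos + 1 :]
        amps.append(make_amplicon(seq, accession=f"G{i}"))
    counts = [len(cluster(amps, t)) for t in (1.0, 0.95, 0.9, 0.8, 0.7)]
    assert counts == sorted(counts, reverse=True)


def test_clusters_refine_pairwise_identity_components(rng):
    """Every greedy cluster sits inside one component of the >=t graph."""
    base = random_dna(rng, 60)
    amps = []
    for i in range(10):
        seq = base
        for _ in range(int(rng.integers(0, 8))):
            pos = int(rng.integers(0, 60))
            seq = seq[:pos] + "ACGT"[int(rng.integers(4))] + seq[pos + 1 :]
        amps.append(make_amplicon(seq, accession=f"G{i}"))
    t = 0.9
    idx = {id(a): i for i, a in enumerate(amps)}
    from conftest import UnionFind

    uf = UnionFind(range(len(amps)))
    for i, j in itertools.combinations(range(len(amps)), 2):
        if global_identity(amps[i].sequence, amps[j].sequence) >= t:
            uf.union(i, j)
    components = uf.components()
    for cl in cluster(amps, t):
        roots = {uf.find(idx[id(a)]) for a in cl.members}
        assert len(roots) == 1


def test_species_sets_reflect_members():
    amps = [make_amplicon("ACGT" * 15, accession="G1"),
            make_amplicon("ACGT" * 15, accession="G2")]
    clusters = cluster(amps, 1.0, {"G1": "Synthetica sp01", "G2": "Synthetica sp02"})
    assert clusters[0].genomes == {"G1", "G2"}
    assert clusters[0].species == {"Synthetica sp01", "Synthetica sp02"}
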