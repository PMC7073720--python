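"""Greedy identity clustering against the brute-force oracle."""

import numpy as np
import pytest

import pgmine as pg
from pgmine.io import AMINO_ACIDS


def canonical(clusters):
    return sorted(
        (c.representative_id, tuple(sorted(c.member_ids))) for c in clusters
    )


def random_instance(rng, max_n=30):
    """Mixed instance: some mutated copy families, some random sequences."""
    n = int(rng.integers(2, max_n + 1))
    alphabet = AMINO_ACIDS if rng.random() < 0.5 else "ACDE"
    seqs = {}
    i = 0
    while len(seqs) < n:
        length = int(rng.integers(10, 61))
        base = "".join(alphabet[j] for j in rng.integers(len(alphabet), size=length))
        seqs[f"s{i:03d}"] = base
        i += 1
        # with probability 1/2 add a mutated relative of the sequence
        if len(seqs) < n and rng.random() < 0.5:
            seqs[f"s{i:03d}"] = pg.mutate_copy(base, float(rng.uniform(0.6, 1.0)), rng)
            i += 1
    return seqs


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("MKLV", "MKLV", 1.0),
        ("AAAA", "AAAT", 0.75),
        ("AAAA", "AAAAAA", 1.0),
        ("AC", "CA", 0.5),
    ],
)
def test_pairwise_identity_examples(a, b, expected):
    assert pg.pairwise_identity(a, b) == pytest.approx(expected)
    assert pg.pairwise_identity(b, a) == pytest.approx(expected)


def test_pairwise_identity_empty_is_error():
    with pytest.raises(ValueError):
        pg.pairwise_identity("", "MKLV")


def test_greedy_identical_pair_single_cluster():
    clusters = pg.greedy_cluster({"a": "MKLVH", "b": "MKLVH"}, 0.9)
    assert len(clusters) == 1
    assert sorted(clusters[0].member_ids) == ["a", "b"]
    assert clusters[0].representative_id == "a"  # length tie broken by id


def test_greedy_singleton():
    clusters = pg.greedy_cluster({"only": "MKLV"}, 0.9)
    assert canonical(clusters) == [("only", ("only",))]


def test_greedy_two_similar_one_unrelated():
    rng = np.random.default_rng(3)
    base = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=50))
    copy = pg.mutate_copy(base, 0.95, rng)
    other = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=50))
    seqs = {"base": base, "copy": copy, "other": other}
    clusters = pg.greedy_cluster(seqs, 0.9)
    assert len(clusters) == 2
    assert canonical(clusters) == canonical(pg.brute_force_cluster(seqs, 0.9))


def test_threshold_validation():
    with pytest.raises(ValueError):
        pg.greedy_cluster({"a": "MK"}, 0.0)
    with pytest.raises(ValueError):
        pg.greedy_cluster({}, 0.9)
    with pytest.raises(ValueError):
        pg.brute_force_cluster({f"s{i}": "MK" for i in range(51)}, 0.9)


def test_oracle_equivalence_random_instances():
    rng = np.random.default_rng(11)
    thresholds = [0.7, 0.8, 0.9, 0.95]
    for k in range(60):
        seqs = random_instance(rng)
        threshold = thresholds[k % len(thresholds)]
        assert canonical(pg.greedy_cluster(seqs, threshold)) == canonical(
            pg.brute_force_cluster(seqs, threshold)
        ), f"instance {k} at threshold {threshold}"


def test_partition_and_threshold_soundness():
    rng = np.random.default_rng(5)
    for _ in range(20):
        seqs = random_instance(rng)
        threshold = float(rng.choice([0.7, 0.9]))
        clusters = pg.greedy_cluster(seqs, threshold)
        members = [m for c in clusters for m in c.member_ids]
        assert sorted(members) == sorted(seqs)  # exact partition
        for c in clusters:
            rep = seqs[c.representative_id]
            assert c.representative_id in c.member_ids
            assert all(len(seqs[m]) <= len(rep) for m in c.member_ids)
            for m in c.member_ids:
                assert pg.pairwise_identity(seqs[m], rep) >= threshold


def test_cluster_count_monotone_in_threshold():
    rng = np.random.default_rng(23)
    for _ in range(20):
        seqs = random_instance(rng)
        counts = [
            len(pg.greedy_cluster(seqs, t)) for t in (0.5, 0.7, 0.8, 0.9, 0.95, 1.0)
        ]
        assert counts == sorted(counts)


def test_copy_groups_recovered_from_synthetic(default_sim):
    _, bundles, truth = default_sim
    peptides = {
        t.transcript_id: t.peptide_sequence
        for b in bundles
        for t in b.transcripts
        if t.peptide_sequence
    }
    for group_id, members in list(truth.copy_groups.items())[:4]:
        seqs = {m: peptides[m] for m in members}
        clusters = pg.brute_force_cluster(seqs, 0.9)
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == sorted(members)


def _assignment(tid, species, code):
    return pg.FunctionAssignment(tid, "X1", species, code, "Prostaglandin thing")


def test_cluster_by_function_report_collapse():
    rng = np.random.default_rng(1)
    base = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=80))
    peptides = {
        "a": base,
        "b": pg.mutate_copy(base, 0.95, rng),
        "c": pg.mutate_copy(base, 0.95, rng),
    }
    assignments = [_assignment(t, "Sp one", "PTGES2") for t in peptides]
    clusters, report = pg.cluster_by_function(assignments, peptides, 0.9)
    assert len(clusters) == 1
    row = report.iloc[0]
    assert (row.sp_count, row.cdhit_count) == (3, 1)


def test_cluster_by_function_groups_species_separately():
    peptides = {"a": "MKLVHGA", "b": "MKLVHGA"}
    assignments = [
        _assignment("a", "Sp one", "PTGR1"),
        _assignment("b", "Sp two", "PTGR1"),
    ]
    clusters, report = pg.cluster_by_function(assignments, peptides, 0.9)
    assert len(clusters) == 2  # identical sequences, but distinct species
    assert (report.cdhit_count <= report.sp_count).all()
    assert (report.sp_count == 1).all()


def test_cluster_by_function_missing_peptide_fatal():
    assignments = [_assignment("ghost", "Sp one", "PTGR1")]
    with pytest.raises(ValueError, match="ghost"):
        pg.cluster_by_function(assignments, {}, 0.9)


def test_cross_species_purity_pure_and_impure():
    rng = np.random.default_rng(9)
    sp_a = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=60))
    sp_b = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=60))
    seqs = {"a1": sp_a, "a2": pg.mutate_copy(sp_a, 0.96, rng), "b1": sp_b}
    clusters = pg.greedy_cluster(seqs, 0.9)
    species_of = {"a1": "A", "a2": "A", "b1": "B"}
    functions_of = {k: {"PTGR1"} for k in seqs}
    report = pg.cross_species_purity(clusters, species_of, functions_of)
    assert report.fraction_pure == 1.0

    # constructed impurity: identical sequences planted in two species
    clusters2 = pg.greedy_cluster({"x": "MKLVHGA", "y": "MKLVHGA"}, 0.9)
    report2 = pg.cross_species_purity(
        clusters2, {"x": "A", "y": "B"}, {"x": {"PTGR1"}, "y": {"PTGR1"}}
    )
    assert report2.fraction_pure is not None and report2.fraction_pure < 1.0
    assert report2.impure_cluster_ids == [0]


def test_cross_species_purity_empty():
    report = pg.cross_species_purity([], {}, {})
    assert report.n_clusters == 0
    assert report.fraction_pure is None


def test_write_clstr_format(tmp_path):
    rng = np.random.default_rng(2)
    base = "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=40))
    seqs = {"a": base, "b": pg.mutate_copy(base, 0.95, rng)}
    clusters = pg.greedy_cluster(seqs, 0.9)
    path = pg.clustering.write_clstr(clusters, seqs, tmp_path / "c.clstr")
    text = path.read_text()
    assert text.startswith(">Cluster 0")
    assert "*" in text and "at " in text
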