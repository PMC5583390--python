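"""Binary matrices, Jaccard index, clustering and distribution tables."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nrpairs import (
    RecordSet,
    build_binary_matrix,
    hierarchical_cluster,
    jaccard_index,
    jaccard_matrix,
    pec_vs_pop_distribution,
    pecs_for,
    pop_distribution,
    branch_distribution,
)
from nrpairs.exceptions import ConfigError, InputError
from nrpairs.fragmentation import PairMultiset
from nrpairs.similarity import GLOBAL_BRANCH, read_branch_assignments

from conftest import make_record


def _rs(*records):
    return RecordSet(records=list(records))


def test_binary_matrix_cluster_granularity():
    rs = _rs(
        make_record(["asp", "ser"], organism="Org A", cluster_index=1),
        make_record(["asp", "ser", "orn"], organism="Org A", cluster_index=2),
    )
    bm = build_binary_matrix(rs, granularity="cluster")
    assert bm.instance_ids == ["Org A-C1", "Org A-C2"]
    assert bm.attribute_ids == ["asp.ser", "orn.ser"]
    assert bm.values.tolist() == [[1, 0], [1, 1]]


def test_binary_matrix_organism_granularity_unions_clusters():
    rs = _rs(
        make_record(["asp", "ser"], organism="Org A", cluster_index=1),
        make_record(["asp", "ser", "orn"], organism="Org A", cluster_index=2),
    )
    bm = build_binary_matrix(rs, granularity="organism")
    assert bm.instance_ids == ["Org A"]
    assert bm.values.tolist() == [[1, 1]]
    # organism row support equals the union of its cluster-level supports
    cluster_bm = build_binary_matrix(rs, granularity="cluster")
    union = cluster_bm.row_support(0) | cluster_bm.row_support(1)
    assert bm.row_support(0) == union


def test_binary_matrix_flags_empty_instances():
    rs = _rs(
        make_record(["asp", "ser"], organism="Org A"),
        make_record([], organism="Org B"),
    )
    bm = build_binary_matrix(rs)
    assert bm.empty_instances == ["Org B-C1"]
    assert bm.values[1].sum() == 0


def test_binary_matrix_rejects_bad_granularity(record_set):
    with pytest.raises(ConfigError):
        build_binary_matrix(record_set, granularity="genus")


def test_jaccard_worked_examples():
    shared = {"asp.nrp", "asp.ser", "orn.ser"}
    assert jaccard_index(shared, set(shared)) == 1.0
    assert jaccard_index({"asp.ser"}, {"orn.thr"}) == 0.0
    assert jaccard_index({"a.b", "b.c"}, {"b.c", "c.d"}) == pytest.approx(1 / 3)
    assert jaccard_index(set(), set()) == 0.0


SETS = st.sets(st.sampled_from(["a.b", "b.c", "c.d", "d.e", "e.f"]), max_size=5)


@settings(deadline=None)
@given(SETS, SETS)
def test_jaccard_axioms(a, b):
    ji = jaccard_index(a, b)
    assert 0.0 <= ji <= 1.0
    assert ji == jaccard_index(b, a)
    if a or b:
        assert (ji == 1.0) == (a == b)
        assert (ji == 0.0) == (not a & b)


def test_jaccard_matrix_against_set_oracle():
    rng = np.random.default_rng(7)
    rows = [
        make_record(
            ["ser" if rng.random() < 0.5 else "gly",
             "thr" if rng.random() < 0.5 else "orn",
             "asp" if rng.random() < 0.5 else "arg"],
            organism=f"Org {i}",
        )
        for i in range(6)
    ]
    bm = build_binary_matrix(_rs(*rows))
    ji = jaccard_matrix(bm)
    supports = [bm.row_support(i) for i in range(len(bm.instance_ids))]
    for i, j in itertools.product(range(6), repeat=2):
        assert ji.values[i, j] == pytest.approx(jaccard_index(supports[i], supports[j]))
    assert np.allclose(ji.values, ji.values.T)
    assert np.allclose(np.diag(ji.values), 1.0)


def test_jaccard_matrix_identical_rows():
    rs = _rs(
        make_record(["orn", "ser"], organism="Org A"),
        make_record(["orn", "ser"], organism="Org B"),
    )
    ji = jaccard_matrix(build_binary_matrix(rs))
    assert ji.values[0, 1] == 1.0


def test_jaccard_matrix_single_row():
    ji = jaccard_matrix(build_binary_matrix(_rs(make_record(["orn", "ser"]))))
    assert ji.values.shape == (1, 1) and ji.values[0, 0] == 1.0


# ---------------------------------------------------------------------------
# hierarchical clustering


def _naive_average_linkage(points):
    """Independent UPGMA: average of pairwise Euclidean distances between
    all member pairs of two clusters; returns sorted merge heights."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([
                np.linalg.norm(points[i] - points[j])
                for i in clusters[a]
                for j in clusters[b]
            ])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


def test_identical_rows_merge_at_zero():
    rs = _rs(
        make_record(["orn", "ser"], organism="Org A"),
        make_record(["orn", "ser"], organism="Org B"),
    )
    dend = hierarchical_cluster(build_binary_matrix(rs))
    assert dend.merge_heights().tolist() == [0.0]


def test_disjoint_rows_merge_at_sqrt_two():
    rs = _rs(
        make_record(["orn", "ser"], organism="Org A"),
        make_record(["asp", "thr"], organism="Org B"),
    )
    dend = hierarchical_cluster(build_binary_matrix(rs))
    assert dend.merge_heights()[0] == pytest.approx(math.sqrt(2))


def test_average_linkage_matches_naive_oracle():
    rng = np.random.default_rng(11)
    values = (rng.random((5, 7)) < 0.4).astype(np.int8)
    from nrpairs.similarity import BinaryMatrix

    bm = BinaryMatrix(
        instance_ids=[f"I{i}" for i in range(5)],
        attribute_ids=[f"a{j}.b{j}" for j in range(7)],
        values=values,
    )
    dend = hierarchical_cluster(bm)
    expected = _naive_average_linkage(values.astype(float))
    assert np.allclose(sorted(dend.merge_heights()), expected)


def test_merge_heights_are_monotone():
    rng = np.random.default_rng(23)
    from nrpairs.similarity import BinaryMatrix

    values = (rng.random((8, 10)) < 0.5).astype(np.int8)
    bm = BinaryMatrix(
        instance_ids=[f"I{i}" for i in range(8)],
        attribute_ids=[f"a{j}.b{j}" for j in range(10)],
        values=values,
    )
    heights = hierarchical_cluster(bm).merge_heights()
    assert all(heights[i] <= heights[i + 1] + 1e-12 for i in range(len(heights) - 1))


def test_clustering_needs_two_rows():
    with pytest.raises(InputError):
        hierarchical_cluster(build_binary_matrix(_rs(make_record(["orn", "ser"]))))


def test_newick_export_parses(tmp_path):
    import dendropy

    rs = _rs(
        make_record(["orn", "ser"], organism="Org A"),
        make_record(["asp", "thr"], organism="Org B"),
        make_record(["orn", "ser", "asp"], organism="Org C"),
    )
    dend = hierarchical_cluster(build_binary_matrix(rs))
    tree = dendropy.Tree.get(data=dend.to_newick(), schema="newick")
    assert len(tree.leaf_nodes()) == 3
    assert sorted(dend.leaf_order) == ["Org A-C1", "Org B-C1", "Org C-C1"]


# ---------------------------------------------------------------------------
# distributions


def test_delftibactin_distribution_with_multiplicity(delftibactin_pecs):
    table = pop_distribution([delftibactin_pecs], with_multiplicity=True)
    assert table.iloc[0]["pair"] == "gly.thr"
    assert table.iloc[0]["percent"] == pytest.approx(25.0)  # 2 of 8
    assert table["percent"].sum() == pytest.approx(100.0, abs=1e-9)


def test_delftibactin_distribution_unique(delftibactin_pecs):
    table = pop_distribution([delftibactin_pecs], with_multiplicity=False)
    row = table.set_index("pair").loc["gly.thr"]
    assert row["percent"] == pytest.approx(100.0 / 7)


def test_single_pair_distribution():
    table = pop_distribution([PairMultiset(counts={"orn.ser": 1})])
    assert table["percent"].tolist() == [100.0]


def test_empty_group_rejected():
    with pytest.raises(InputError):
        pop_distribution([])


def test_pec_vs_pop_identity_case(library):
    rs = _rs(*(
        make_record(
            ["pk", "asp", "thr", "gly", "thr", "orn", "ser", "arg", "orn"],
            organism=f"Org {i}", identity=100.0,
        )
        for i in range(3)
    ))
    df = pec_vs_pop_distribution(rs, library)
    assert np.allclose(df["pec_percent"], df["pop_percent"])


def test_pec_vs_pop_detects_dropout(library):
    # predictions replace orn by nrp: orn.ser present only on the PEC side
    rs = _rs(
        make_record(
            ["pk", "asp", "thr", "gly", "thr", "nrp", "ser", "arg", "nrp"],
            identity=60.0,
        )
    )
    df = pec_vs_pop_distribution(rs, library).set_index("pair")
    assert df.loc["orn.ser", "pec_percent"] > 0
    assert df.loc["orn.ser", "pop_percent"] == 0.0


def test_pec_vs_pop_excludes_unresolvable(library):
    rs = _rs(
        make_record(["orn", "ser"], organism="Org A", identity=90.0),
        make_record(["orn", "ser"], organism="Org B", identity=90.0,
                    compound="Mystery", mibig=""),
    )
    df = pec_vs_pop_distribution(rs, library)
    assert df.attrs["excluded"] == ["Org B-C1"]


def test_branch_distribution_single_branch_equals_global():
    rs = _rs(
        make_record(["orn", "ser"], organism="Org A"),
        make_record(["asp", "ser"], organism="Org B"),
    )
    assignments = {"Org A-C1": "Branch_1", "Org B-C1": "Branch_1"}
    tables = branch_distribution(rs, assignments)
    assert set(tables) == {GLOBAL_BRANCH, "Branch_1"}
    assert tables["Branch_1"].equals(tables[GLOBAL_BRANCH])


def test_branch_distribution_pure_nrp_branch():
    rs = _rs(
        make_record(["nrp", "nrp"], organism="Org A"),
        make_record(["orn", "ser"], organism="Org B"),
    )
    tables = branch_distribution(
        rs, {"Org A-C1": "Branch_3", "Org B-C1": "Branch_1"}
    )
    b3 = tables["Branch_3"]
    assert b3["pair"].tolist() == ["nrp.nrp"]
    assert b3["percent"].tolist() == [100.0]


def test_branch_distribution_unknown_key_rejected(record_set):
    with pytest.raises(InputError, match="unknown cluster keys"):
        branch_distribution(record_set, {"Nobody-C1": "Branch_1"})


def test_read_branch_assignments(tmp_path):
    path = tmp_path / "branches.tsv"
    path.write_text(
        "cluster_key\tbranch\n# comment\nOrg A-C1\tBranch_2\n", encoding="utf-8"
    )
    assert read_branch_assignments(path) == {"Org A-C1": "Branch_2"}


def test_matrix_tsv_round_trip(tmp_path):
    import pandas as pd

    rs = _rs(
        make_record(["orn", "ser"], organism="Org A"),
        make_record(["asp", "ser"], organism="Org B"),
    )
    bm = build_binary_matrix(rs)
    path = tmp_path / "bm.tsv"
    bm.write_tsv(path)
    df = pd.read_csv(path, sep="\t", index_col="instance")
    assert df.values.tolist() == bm.values.tolist()
    ji_path = tmp_path / "ji.tsv"
    jaccard_matrix(bm).write_tsv(ji_path)
    ji = pd.read_csv(ji_path, sep="\t", index_col="instance")
    assert ji.shape == (2, 2)
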