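"""Haplotype collapsing, median-joining vs the exhaustive Steiner oracle, haplogroups."""

import itertools

import networkx as nx
import numpy as np
import pytest

from msynet.genotypes import GenotypeMatrix, Site
from msynet.haplotype_network import (
    HaplotypeTable,
    assign_haplogroups,
    collapse_haplotypes,
    median_joining,
    network_oracle,
    network_tables,
    network_from_tables,
)
from msynet.synthetic_data import TreeSpec, simulate_haplotypes, two_haplogroup_tree


def matrix_from_rows(rows, samples=None):
    rows = np.array(rows, dtype=np.int8)
    samples = samples or [f"S{i + 1}" for i in range(rows.shape[0])]
    sites = [Site("c", j + 1) for j in range(rows.shape[1])]
    return GenotypeMatrix(samples=samples, sites=sites, calls=rows)


def table_from_vectors(vectors):
    vectors = np.array(vectors, dtype=np.uint8)
    return HaplotypeTable(
        ids=[f"H{i + 1}" for i in range(len(vectors))],
        vectors=vectors,
        members=[(f"S{i + 1}",) for i in range(len(vectors))],
        sites=[Site("c", j + 1) for j in range(vectors.shape[1])],
    )


def random_tree_table(rng, n_tips, max_len=6):
    """Haplotypes from a random caterpillar-ish tree: tree-like by construction."""
    names = [f"T{i}" for i in range(n_tips)]
    parent = {"root": None}
    muts = {}
    tips = {}
    attach = ["root"]
    for i, t in enumerate(names):
        inner = f"I{i}"
        p = attach[int(rng.integers(len(attach)))]
        parent[inner] = p
        muts[inner] = int(rng.integers(0, max_len))
        parent[t] = inner
        muts[t] = int(rng.integers(1, max_len))
        tips[t] = (f"S{i}",)
        attach.append(inner)
    tree = TreeSpec(parent=parent, mutations=muts, tip_samples=tips)
    matrix, _ = simulate_haplotypes(tree, seed=int(rng.integers(1 << 16)))
    total = sum(muts.values())
    return matrix, total


# ---------------------------------------------------------------------------
# Collapse


def test_two_identical_rows_collapse_to_shared_haplotype():
    m = matrix_from_rows([[0, 1], [0, 1], [1, 0]])
    ht = collapse_haplotypes(m)
    assert ht.n_haplotypes == 2
    assert ("S1", "S2") in ht.members


def test_all_identical_rows_collapse_to_one_and_drop_all_sites():
    m = matrix_from_rows([[1, 1], [1, 1]])
    ht = collapse_haplotypes(m)
    assert ht.n_haplotypes == 1
    assert ht.n_constant_dropped == 2
    assert len(ht.sites) == 0


def test_pairwise_distinct_rows_stay_distinct():
    m = matrix_from_rows([[1, 0, 0], [0, 1, 0], [0, 0, 1]])
    assert collapse_haplotypes(m).n_haplotypes == 3


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        collapse_haplotypes(GenotypeMatrix(samples=[], sites=[], calls=np.zeros((0, 0))))


# ---------------------------------------------------------------------------
# Median joining


def test_two_haplotypes_give_single_edge_no_medians():
    ht = table_from_vectors([[0] * 5, [1] * 5])
    net = median_joining(ht)
    assert net.medians() == []
    assert net.graph.edges["H1", "H2"]["length"] == 5


def test_three_tip_star_resolves_to_steiner_median():
    matrix, _ = simulate_haplotypes(
        TreeSpec(
            parent={"r": None, "a": "r", "b": "r", "c": "r"},
            mutations={"a": 13, "b": 14, "c": 15},
            tip_samples={"a": ("A",), "b": ("B",), "c": ("C",)},
        ),
        seed=0,
    )
    ht = collapse_haplotypes(matrix)
    net = median_joining(ht)
    assert len(net.medians()) == 1
    mv = net.medians()[0]
    branch_lengths = sorted(net.graph.edges[mv, n]["length"] for n in net.observed())
    assert branch_lengths == [13, 14, 15]
    assert net.total_length() == 42
    # exhaustive check: no spanning network over any median subset is shorter
    oracle = network_oracle(ht)
    assert oracle.total_length() == 42


def test_reference_genealogy_reconstructed_exactly(reference_matrix):
    matrix, _ = reference_matrix
    ht = collapse_haplotypes(matrix)
    net = median_joining(ht)
    # tree-like data: one inferred median (the domestic basal node), a tree
    assert len(net.medians()) == 1
    assert nx.is_tree(net.graph)
    assert net.total_length() == 596
    # path lengths equal Hamming distances for every haplotype pair
    for i, j in itertools.combinations(range(ht.n_haplotypes), 2):
        ham = int((ht.vectors[i] != ht.vectors[j]).sum())
        assert net.path_length(ht.ids[i], ht.ids[j]) == ham
    wc305 = net.node_of_sample("WC305")
    assert net.path_length(wc305, net.medians()[0]) == 12


def test_median_joining_equals_oracle_on_tree_like_data():
    rng = np.random.default_rng(77)
    for _ in range(20):
        matrix, total = random_tree_table(rng, n_tips=int(rng.integers(3, 7)))
        ht = collapse_haplotypes(matrix)
        if len(ht.sites) > 64:
            continue
        net = median_joining(ht)
        oracle = network_oracle(ht)
        assert net.total_length() == oracle.total_length()


def test_oracle_never_longer_than_median_joining_on_random_instances():
    rng = np.random.default_rng(13)
    for _ in range(30):
        vecs = rng.integers(0, 2, size=(4, 12))
        vecs = np.unique(vecs, axis=0)
        if len(vecs) < 2:
            continue
        ht = table_from_vectors(vecs)
        assert network_oracle(ht).total_length() <= median_joining(ht).total_length()


def test_median_count_bounded_for_tree_like_data():
    rng = np.random.default_rng(3)
    for _ in range(10):
        matrix, _ = random_tree_table(rng, n_tips=5)
        ht = collapse_haplotypes(matrix)
        net = median_joining(ht)
        assert len(net.medians()) <= max(ht.n_haplotypes - 2, 0)


def test_relabeling_haplotypes_yields_isomorphic_network(reference_matrix):
    matrix, _ = reference_matrix
    perm = [3, 1, 7, 0, 6, 2, 5, 4]
    permuted = matrix.subset_samples([matrix.samples[i] for i in perm])
    net1 = median_joining(collapse_haplotypes(matrix))
    net2 = median_joining(collapse_haplotypes(permuted))
    assert nx.is_isomorphic(
        net1.graph,
        net2.graph,
        edge_match=lambda a, b: a["length"] == b["length"],
    )


def test_oracle_refuses_oversized_instances():
    ht = table_from_vectors(np.eye(13, dtype=np.uint8))
    with pytest.raises(ValueError):
        network_oracle(ht)


# ---------------------------------------------------------------------------
# Haplogroups


def test_two_node_network_splits_on_its_only_edge():
    ht = table_from_vectors([[0, 0], [1, 1]])
    net = median_joining(ht)
    part = assign_haplogroups(net, {"H1": "A", "H2": "B"})
    assert part.split_edge == ("H1", "H2")
    assert part.labels == {"H1": "A", "H2": "B"}


def test_wild_sampled_lineage_lands_in_domestic_haplogroup(reference_matrix):
    matrix, _ = reference_matrix
    net = median_joining(collapse_haplotypes(matrix))
    part = assign_haplogroups(
        net,
        {net.node_of_sample("DC101"): "D", net.node_of_sample("WC302"): "W"},
    )
    assert part.split_length == 536
    assert part.labels[net.node_of_sample("WC305")] == "D"
    d_side = [n for n, l in part.labels.items() if l == "D"]
    assert len(d_side) == 5  # 4 observed haplotypes + the basal median


def test_equal_edges_with_conflicting_seeds_is_tie_error():
    matrix, _ = simulate_haplotypes(
        TreeSpec(
            parent={"r": None, "a": "r", "b": "r", "c": "r"},
            mutations={"a": 4, "b": 4, "c": 4},
            tip_samples={"a": ("A",), "b": ("B",), "c": ("C",)},
        ),
        seed=0,
    )
    net = median_joining(collapse_haplotypes(matrix))
    seeds = {net.node_of_sample("A"): "X", net.node_of_sample("B"): "Y"}
    with pytest.raises(ValueError, match="tie"):
        assign_haplogroups(net, seeds)


def test_network_tables_round_trip(reference_matrix):
    matrix, _ = reference_matrix
    net = median_joining(collapse_haplotypes(matrix))
    nodes, edges = network_tables(net)
    back = network_from_tables(nodes, edges)
    assert set(back.graph.nodes) == set(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        assert back.graph.edges[u, v]["length"] == d["length"]
    assert back.graph.nodes[net.node_of_sample("WC214")]["multiplicity"] == 2
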