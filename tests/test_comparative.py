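"""Identity matrices, family rules, NJ trees, bootstrap, DDE motif."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from difhunter.comparative import (IdentityMatrix, bootstrap_consensus,
                                   cluster_by_identity, dde_motif_check,
                                   identity_matrix, isoform_check,
                                   multiple_align, nj_tree)
from difhunter.seqcore import Sequence

from conftest import mutate, random_dna


# --- identity matrix ------------------------------------------------------

def test_identity_matrix_matches_construction_truth(rng):
    """Substitution-only divergence at high gap cost: identity is exactly
    100*(1 - mutated/len)."""
    base = random_dna(rng, 60)
    seqs = [Sequence(id="a", residues=base),
            Sequence(id="b", residues=mutate(base, 6, rng)),
            Sequence(id="c", residues=mutate(base, 12, rng))]
    m = identity_matrix(seqs, kind="nt")
    assert m["a", "b"] == pytest.approx(100 * (1 - 6 / 60))
    assert m["a", "c"] == pytest.approx(100 * (1 - 12 / 60))
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 100.0)


def test_identity_matrix_rejects_duplicates_and_singletons(rng):
    s = Sequence(id="a", residues=random_dna(rng, 50))
    with pytest.raises(ValueError):
        identity_matrix([s], kind="nt")
    with pytest.raises(ValueError):
        identity_matrix([s, s], kind="nt")


def test_identical_pair_scores_100(rng):
    base = random_dna(rng, 80)
    m = identity_matrix([Sequence(id="x", residues=base),
                         Sequence(id="y", residues=base)], kind="nt")
    assert m["x", "y"] == 100.0


# --- family rules ---------------------------------------------------------

@pytest.mark.parametrize("id_nt,id_aa,expected", [
    (94.06, 97.0, False),  # two distinct named elements: both below threshold
    (96.0, 50.0, True),    # nucleotide rule
    (10.0, 99.0, True),    # amino-acid rule
    (95.0, 98.0, False),   # thresholds are strict inequalities
])
def test_isoform_rule(id_nt, id_aa, expected):
    assert isoform_check(id_nt, id_aa) is expected


def _block_matrix():
    """Synthetic 7-member aa-identity matrix with the two-cluster block
    structure of the Acinetobacter transposases (>=92.9 within, <=72
    across)."""
    labels = ["ISAjo2", "ISAba71", "ISAso2", "ISApi2",
              "ISAba32", "ISAba54", "ISAlw22"]
    n = len(labels)
    values = np.full((n, n), 70.0)
    for i, j in itertools.product(range(4), range(4)):
        values[i, j] = 93.0
    for i, j in itertools.product(range(4, 7), range(4, 7)):
        values[i, j] = 94.0
    np.fill_diagonal(values, 100.0)
    return IdentityMatrix(labels=labels, values=values, kind="aa")


def test_clustering_reproduces_the_two_clusters():
    parts = cluster_by_identity(_block_matrix(), threshold=90)
    assert parts == [{"ISAba32", "ISAba54", "ISAlw22"},
                     {"ISAjo2", "ISAba71", "ISAso2", "ISApi2"}]


def test_clustering_edge_cases():
    m = _block_matrix()
    assert cluster_by_identity(m, threshold=50) == [set(m.labels)]
    assert cluster_by_identity(m, threshold=100) == \
        [{lab} for lab in sorted(m.labels)]
    # output is a partition
    parts = cluster_by_identity(m, threshold=90)
    flat = [x for p in parts for x in p]
    assert sorted(flat) == sorted(m.labels)


# --- NJ trees -------------------------------------------------------------

def _random_topology(labels, rng):
    """A random unrooted binary topology as a set of splits, plus the
    additive distance matrix it generates under random branch lengths."""
    # build by random leaf insertion; represent as a dendropy-free edge list
    import networkx as nx
    g = nx.Graph()
    g.add_edge(labels[0], labels[1], w=float(rng.uniform(1, 5)))
    inner = 0
    for leaf in labels[2:]:
        u, v = list(g.edges())[rng.integers(0, g.number_of_edges())]
        w = g[u][v]["w"]
        g.remove_edge(u, v)
        node = f"_i{inner}"
        inner += 1
        a = float(rng.uniform(0.2, 0.8))
        g.add_edge(u, node, w=w * a)
        g.add_edge(node, v, w=w * (1 - a))
        g.add_edge(node, leaf, w=float(rng.uniform(1, 5)))
    n = len(labels)
    dist = np.zeros((n, n))
    paths = dict(nx.all_pairs_dijkstra_path_length(g, weight="w"))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            dist[i, j] = paths[a][b]
    splits = set()
    for u, v in g.edges():
        h = g.copy()
        h.remove_edge(u, v)
        side = frozenset(x for x in nx.node_connected_component(h, u)
                         if not x.startswith("_i"))
        if 1 < len(side) < n - 1:
            other = frozenset(labels) - side
            splits.add(min(side, other,
                           key=lambda s: (len(s), sorted(s))))
    return splits, dist


def _all_topologies(labels):
    """Every unrooted binary topology on the labels, as split sets."""
    if len(labels) == 3:
        yield frozenset()
        return
    # recursive leaf addition: attach the last label onto every edge of
    # every smaller topology (edges = internal splits + pendant edges)
    first = labels[:-1]
    leaf = labels[-1]
    full = frozenset(labels)
    for splits in _all_topologies(first):
        edges = set(splits) | {frozenset([x]) for x in first}
        for es in edges:
            # the new leaf joins, for each old split, the side holding the
            # attachment edge; the subdivided edge contributes its split
            out = {frozenset(s | {leaf}) if es <= s else frozenset(s)
                   for s in splits}
            out.add(frozenset(es))          # the two halves of the
            out.add(frozenset(es | {leaf}))  # subdivided edge
            norm = {min(s, full - s, key=lambda x: (len(x), sorted(x)))
                    for s in out}
            yield frozenset(s for s in norm if 1 < len(s) < len(labels) - 1)


def _ls_fit_error(splits, labels, dist):
    """Least-squares branch-length fit error of a topology to distances."""
    full = frozenset(labels)
    edges = [frozenset([x]) for x in labels] + [set(s) for s in splits]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dist[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for c, e in enumerate(edges):
            e = set(e)
            # edge separates i from j iff exactly one endpoint inside e
            ini, inj = labels[i] in e, labels[j] in e
            if ini != inj:
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


@pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (5, 2), (6, 3)])
def test_nj_matches_exhaustive_least_squares_oracle(n_taxa, seed):
    """On additive matrices NJ finds the same topology as enumerating all
    unrooted topologies and picking the best least-squares fit."""
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_taxa)]
    true_splits, dist = _random_topology(labels, rng)
    best = min(_all_topologies(labels),
               key=lambda sp: _ls_fit_error(sp, labels, dist))
    assert set(best) == true_splits
    values = np.clip(100.0 - dist, 0, 100)
    np.fill_diagonal(values, 100.0)
    m = IdentityMatrix(labels=labels, values=values, kind="aa")
    assert nj_tree(m).bipartitions() == true_splits


def test_nj_recovers_eight_taxon_additive_topology():
    rng = np.random.default_rng(9)
    labels = [f"t{i}" for i in range(8)]
    true_splits, dist = _random_topology(labels, rng)
    values = np.clip(100.0 - dist, 0, 100)
    np.fill_diagonal(values, 100.0)
    m = IdentityMatrix(labels=labels, values=values, kind="aa")
    assert nj_tree(m).bipartitions() == true_splits


def test_three_taxon_branch_lengths_closed_form():
    labels = ["a", "b", "c"]
    d = np.array([[0.0, 10.0, 16.0], [10.0, 0.0, 14.0], [16.0, 14.0, 0.0]])
    values = 100.0 - d
    np.fill_diagonal(values, 100.0)
    tree = nj_tree(IdentityMatrix(labels=labels, values=values, kind="aa"))
    lengths = {lf.taxon.label: lf.edge.length
               for lf in tree.dtree.leaf_node_iter()}
    # x+y=10, x+z=16, y+z=14 -> x=6, y=4, z=10
    assert lengths == pytest.approx({"a": 6.0, "b": 4.0, "c": 10.0})


def test_nj_requires_three_labels(rng):
    base = random_dna(rng, 40)
    m = identity_matrix([Sequence(id="a", residues=base),
                         Sequence(id="b", residues=mutate(base, 3, rng))],
                        kind="nt")
    with pytest.raises(ValueError):
        nj_tree(m)


# --- bootstrap consensus --------------------------------------------------

def _two_clade_proteins(rng, n_per_clade=3, length=120, within=2, between=40):
    base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    other = list(base)
    for p in rng.choice(length, size=between, replace=False):
        alt = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != other[p]]
        other[p] = rng.choice(alt)
    other = "".join(other)
    seqs = []
    for c, stem in enumerate((base, other)):
        for k in range(n_per_clade):
            chars = list(stem)
            for p in rng.choice(length, size=within, replace=False):
                alt = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a != chars[p]]
                chars[p] = rng.choice(alt)
            seqs.append(Sequence(id=f"c{c}_{k}", residues="".join(chars)))
    return seqs


@pytest.mark.parametrize("seed", range(3))
def test_deep_clades_get_high_support(seed):
    rng = np.random.default_rng(seed)
    seqs = _two_clade_proteins(rng)
    aligned = multiple_align(seqs)
    tree = bootstrap_consensus(aligned, n_resamples=200, seed=seed)
    clade = frozenset(s.id for s in seqs[:3])
    other = frozenset(s.id for s in seqs[3:])
    support = {tree.supports.get(clade, 0.0), tree.supports.get(other, 0.0)}
    assert max(support) >= 95.0


def test_single_resample_supports_are_all_or_nothing(rng):
    seqs = _two_clade_proteins(rng)
    aligned = multiple_align(seqs)
    tree = bootstrap_consensus(aligned, n_resamples=1, seed=0)
    assert set(tree.supports.values()) <= {0.0, 100.0}


def test_bootstrap_deterministic_for_fixed_seed(rng):
    seqs = _two_clade_proteins(rng)
    aligned = multiple_align(seqs)
    t1 = bootstrap_consensus(aligned, n_resamples=25, seed=42)
    t2 = bootstrap_consensus(aligned, n_resamples=25, seed=42)
    assert t1.newick() == t2.newick()
    assert t1.supports == t2.supports


def test_multiple_align_roundtrip(rng):
    seqs = _two_clade_proteins(rng)
    aligned = multiple_align(seqs)
    assert [s.id for s in aligned] == [s.id for s in seqs]
    for raw, al in zip(seqs, aligned):
        assert al.residues.replace("-", "") == raw.residues


# --- DDE motif ------------------------------------------------------------

def _synthetic_transposase():
    chars = ["A"] * 300
    chars[141], chars[202], chars[246] = "D", "D", "E"
    chars[253] = "Q"
    return "".join(chars)


def test_dde_motif_detected_on_synthetic_transposase():
    rep = dde_motif_check(_synthetic_transposase(), positions=(142, 203, 247))
    assert rep.residues == ("D", "D", "E")
    assert rep.residue_at_E_plus_7 == "Q"
    assert rep.motif_ok


def test_dde_motif_fails_on_polyalanine():
    rep = dde_motif_check("A" * 300, positions=(142, 203, 247))
    assert rep.residues == ("A", "A", "A")
    assert not rep.motif_ok


def test_dde_positions_beyond_length_error():
    with pytest.raises(ValueError):
        dde_motif_check("A" * 250, positions=(142, 203, 247))
    with pytest.raises(ValueError):
        dde_motif_check(_synthetic_transposase(), positions=(203, 142, 247))
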