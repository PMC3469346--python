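"""Distance models, neighbor joining, bootstrap, genome assignment."""

import math

import networkx as nx
import numpy as np
import pytest
import skbio

from gliascan.contig_assembly import Contig
from gliascan.phylo_assign import (
    DistanceMatrix,
    SATURATION_CAP,
    assign_genome,
    bipartitions,
    bootstrap_support,
    build_nj,
    compute_distances,
    group_distances,
    total_branch_length,
    LOCUS_BY_GENOME,
)
from gliascan.sequence_core import SequenceRecord


def seqs(*pairs):
    return [SequenceRecord(id=i, seq=s) for i, s in pairs]


class TestDistances:
    def test_identical_pair_zero_under_all_models(self):
        aln = seqs(("a", "ACGT" * 25), ("b", "ACGT" * 25))
        for model in ("p", "JC69", "K2P"):
            assert compute_distances(aln, model=model).d[0, 1] == 0.0

    def test_ten_transitions_closed_form(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90  # 10 transitions, 0 transversions
        aln = seqs(("a", a), ("b", b))
        assert compute_distances(aln, model="p").d[0, 1] == pytest.approx(0.10)
        assert compute_distances(aln, model="K2P").d[0, 1] == pytest.approx(
            0.5 * math.log(1 / 0.8), abs=1e-9
        )

    def test_jc69_at_least_p(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("ACGT"), 200))
        for k in (5, 20, 60, 120):
            other = list(base)
            for i in rng.choice(200, k, replace=False):
                other[i] = rng.choice([b for b in "ACGT" if b != other[i]])
            aln = seqs(("a", base), ("b", "".join(other)))
            p = compute_distances(aln, model="p").d[0, 1]
            jc = compute_distances(aln, model="JC69").d[0, 1]
            assert p < 0.75 and jc >= p

    def test_gap_modes(self):
        # gap column counted for neither pair under pairwise deletion, and
        # stripped for everyone under complete deletion
        aln = seqs(("a", "AAAA"), ("b", "A-AA"), ("c", "TAAA"))
        pd = compute_distances(aln, model="p", gap_mode="pairwise_deletion")
        assert pd.d[0, 1] == 0.0
        assert pd.d[0, 2] == pytest.approx(0.25)
        cd = compute_distances(aln, model="p", gap_mode="complete_deletion")
        assert cd.d[0, 2] == pytest.approx(1 / 3)

    def test_saturation_capped_with_warning(self):
        aln = seqs(("a", "ACAC" * 10), ("b", "CACA" * 10))
        with pytest.warns(UserWarning, match="saturated"):
            dm = compute_distances(aln, model="JC69")
        assert dm.d[0, 1] == SATURATION_CAP
        assert ("a", "b") in dm.saturated_pairs

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(2)
        aln = seqs(*((f"s{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(5)))
        dm = compute_distances(aln, model="K2P")
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0.0)


def random_additive_matrix(n, rng):
    """Distance matrix of a random binary tree with random branch lengths."""
    G = nx.Graph()
    nodes = [f"L{i}" for i in range(n)]
    free = list(nodes)
    k = 0
    while len(free) > 1:
        if len(free) > 2:
            i, j = rng.choice(len(free), 2, replace=False)
        else:
            i, j = 0, 1
        a, b = free.pop(int(max(i, j))), free.pop(int(min(i, j)))
        mid = f"I{k}"
        k += 1
        G.add_edge(a, mid, weight=float(rng.uniform(0.5, 3)))
        G.add_edge(b, mid, weight=float(rng.uniform(0.5, 3)))
        free.append(mid)
    lengths = dict(nx.all_pairs_dijkstra_path_length(G))
    d = np.zeros((n, n))
    for x in range(n):
        for y in range(n):
            d[x, y] = lengths[nodes[x]][nodes[y]]
    return nodes, (d + d.T) / 2, G


def tree_splits(G, leaves):
    """Bipartitions induced by the internal edges of the generating tree."""
    splits = set()
    leafset = frozenset(leaves)
    for u, v in G.edges:
        H = G.copy()
        H.remove_edge(u, v)
        comp = frozenset(x for x in nx.node_connected_component(H, u) if x in leafset)
        side = min(comp, leafset - comp, key=lambda s: tuple(sorted(s)))
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


class TestNeighborJoining:
    def test_four_taxon_additive_round_trip(self):
        # matrix of ((A:1,B:2):1,(C:3,D:4))
        labels = list("ABCD")
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = build_nj(DistanceMatrix(labels, d, "p"))
        assert bipartitions(tree) == {frozenset("AB")}
        assert total_branch_length(tree) == pytest.approx(11.0)
        lengths = {tip.name: tip.length for tip in tree.tips()}
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = build_nj(DistanceMatrix(list("ABC"), d, "p"))
        lengths = {c.name: c.length for c in tree.children}
        assert lengths == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})

    @pytest.mark.parametrize("trial", range(12))
    def test_recovers_generating_topology(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(4, 9))
        nodes, d, G = random_additive_matrix(n, rng)
        tree = build_nj(DistanceMatrix(nodes, d, "p"))
        assert bipartitions(tree) == tree_splits(G, nodes)

    def test_agrees_with_skbio_nj(self):
        rng = np.random.default_rng(3)
        nodes, d, _ = random_additive_matrix(7, rng)
        ours = build_nj(DistanceMatrix(nodes, d, "p"))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, nodes))
        assert ours.compare_rfd(theirs) == 0.0

    def test_rejects_nonfinite(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError):
            build_nj(DistanceMatrix(list("ABC"), d, "p"))


def _mutated(base, k, rng):
    s = list(base)
    for i in rng.choice(len(s), k, replace=False):
        s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


class TestBootstrap:
    def test_clear_split_is_strongly_supported(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 300))
        other = _mutated(base, 80, rng)
        aln = seqs(
            *[(f"x{i}", _mutated(base, 3, rng)) for i in range(3)],
            *[(f"y{i}", _mutated(other, 3, rng)) for i in range(3)],
        )
        tree = bootstrap_support(aln, n_reps=100, seed=1)
        split = {
            nd.support
            for nd in tree.non_tips(include_self=False)
            if {t.name for t in nd.tips()} in ({"x0", "x1", "x2"}, {"y0", "y1", "y2"})
        }
        assert split and min(split) >= 95

    def test_identical_sequences_support_100(self):
        rng = np.random.default_rng(6)
        base = "".join(rng.choice(list("ACGT"), 200))
        far = _mutated(base, 60, rng)
        aln = seqs(("a1", base), ("a2", base), ("b1", far), ("b2", _mutated(far, 2, rng)))
        tree = bootstrap_support(aln, n_reps=50, seed=3)
        sup = {
            frozenset(t.name for t in nd.tips()): nd.support
            for nd in tree.non_tips(include_self=False)
        }
        key = [k for k in sup if k in (frozenset({"a1", "a2"}), frozenset({"b1", "b2"}))]
        assert key and all(sup[k] == 100 for k in key)

    def test_same_seed_same_supports(self):
        rng = np.random.default_rng(7)
        aln = seqs(*((f"s{i}", "".join(rng.choice(list("ACGT"), 120))) for i in range(5)))
        t1 = bootstrap_support(aln, n_reps=30, seed=9)
        t2 = bootstrap_support(aln, n_reps=30, seed=9)
        assert str(t1) == str(t2)

    def test_rejects_zero_replicates(self):
        aln = seqs(("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT"))
        with pytest.raises(ValueError):
            bootstrap_support(aln, n_reps=0)


class TestGroupDistances:
    def test_identical_group_zero(self):
        aln = seqs(("a", "ACGT" * 10), ("b", "ACGT" * 10), ("c", "ACGT" * 10))
        dm = compute_distances(aln, model="p")
        within, _ = group_distances(dm, {"a": "g", "b": "g", "c": "g"})
        assert within["g"] == 0.0

    def test_mean_of_three_pairs(self):
        labels = list("abc")
        d = np.array([[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]])
        dm = DistanceMatrix(labels, d, "p")
        within, _ = group_distances(dm, {"a": "g", "b": "g", "c": "g"})
        assert within["g"] == pytest.approx(0.2)

    def test_singleton_group_absent_and_between_mean(self):
        labels = list("abc")
        d = np.array([[0, 0.1, 0.4], [0.1, 0, 0.2], [0.4, 0.2, 0]])
        dm = DistanceMatrix(labels, d, "p")
        within, between = group_distances(dm, {"a": "g1", "b": "g1", "c": "g2"})
        assert within["g2"] is None
        assert between[("g1", "g2")] == pytest.approx(0.3)

    def test_ungrouped_label_rejected(self):
        dm = DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p")
        with pytest.raises(ValueError):
            group_distances(dm, {"a": "g"})


class TestGenomeAssignment:
    def _refs(self):
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), 400))
        return {
            "A": _mutated(base, 60, rng),
            "S": _mutated(base, 60, rng),
            "D": _mutated(base, 60, rng),
        }

    def test_identical_to_d_reference(self):
        refs = self._refs()
        records = [SequenceRecord(id=g, seq=s, source=g) for g, s in refs.items()]
        contig = Contig(contig_id="c1", member_ids=["t1"], consensus=refs["D"])
        a = assign_genome(contig, records, model="p")
        assert a.locus == "Gli-D1" and a.margin > 0
        assert a.mean_distance_per_genome["D"] == 0.0

    def test_equidistant_contig_unassigned(self):
        # midpoint sequence: equally far from two references
        a = "A" * 200
        b = "G" * 100 + "A" * 100
        mid = "G" * 50 + "A" * 150
        records = [
            SequenceRecord(id="ra", seq=a, source="A"),
            SequenceRecord(id="rb", seq=b, source="D"),
        ]
        contig = Contig(contig_id="c1", member_ids=["t1"], consensus=mid)
        out = assign_genome(contig, records, model="p")
        assert out.locus == "unassigned"
        assert "margin" in out.reason

    def test_synthetic_assignment_accuracy(self, diverged_family):
        _, refs, transcripts, truth = diverged_family
        from gliascan.contig_assembly import ClusterParams, cluster_transcripts

        result = cluster_transcripts(transcripts, ClusterParams())
        gene_of = {r["id"]: r["gene_id"] for r in truth.transcripts}
        correct = 0
        for contig in result.contigs:
            got = assign_genome(contig, refs, model="K2P")
            want = LOCUS_BY_GENOME[truth.genes[gene_of[contig.member_ids[0]]].genome]
            correct += got.locus == want
        assert correct / len(result.contigs) >= 0.95
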