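"""Distance matrices, neighbor-joining trees with bootstrap, and genome-of-origin
assignment of contigs against diploid reference sequences.

Bread wheat is an allohexaploid (A, B and D subgenomes); a transcript contig
can be traced to its homoeologous locus (Gli-A1 / Gli-B1 / Gli-D1) by its
distance to γ-gliadin sequences cloned from the diploid relatives of each
subgenome.  Distances are nucleotide substitutions per site under the p,
JC69 or K2P model with pairwise or complete gap deletion; trees are built
with the Saitou–Nei neighbor-joining agglomeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import log
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import TreeNode

from .contig_assembly import Contig, _ALIGNER
from .sequence_core import SequenceRecord

__all__ = [
    "DistanceMatrix",
    "GenomeAssignment",
    "SATURATION_CAP",
    "LOCUS_BY_GENOME",
    "compute_distances",
    "build_nj",
    "total_branch_length",
    "bipartitions",
    "bootstrap_support",
    "group_distances",
    "assign_genome",
    "pairwise_model_distance",
]

#: distance (subs/site) assigned to saturated pairs (log argument ≤ 0)
SATURATION_CAP = 5.0

#: diploid genome label → homoeologous locus of bread wheat.  S-genome
#: relatives (Ae. speltoides and kin) stand in for the B genome.
LOCUS_BY_GENOME = {"A": "Gli-A1", "B": "Gli-B1", "S": "Gli-B1", "D": "Gli-D1"}

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_VALID = set("ACGT")


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero-diagonal, subs/site
    model: str = "K2P"
    gap_mode: str = "pairwise_deletion"
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.d[i, j])


@dataclass
class GenomeAssignment:
    contig_id: str
    locus: str  # Gli-A1 / Gli-B1 / Gli-D1 / unassigned
    mean_distance_per_genome: dict[str, float]
    margin: float
    depth: int = 1
    reason: str = ""


def _site_distance(pa: str, pb: str, model: str) -> tuple[float, bool]:
    """Model distance for one pre-filtered (ACGT-only) site pair string."""
    n = len(pa)
    if n == 0:
        raise ValueError("no comparable sites between sequence pair")
    diffs = ts = tv = 0
    for x, y in zip(pa, pb):
        if x != y:
            diffs += 1
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    p = diffs / n
    if model == "p":
        return p, False
    if model == "JC69":
        arg = 1.0 - 4.0 * p / 3.0
        if arg <= 0.0:
            return SATURATION_CAP, True
        return -0.75 * log(arg), False
    if model == "K2P":
        P, Q = ts / n, tv / n
        a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
        if a1 <= 0.0 or a2 <= 0.0:
            return SATURATION_CAP, True
        return 0.5 * log(1.0 / a1) + 0.25 * log(1.0 / a2), False
    raise ValueError(f"unknown model {model!r}")


def _comparable(x: str, y: str) -> bool:
    return x in _VALID and y in _VALID


def compute_distances(
    alignment: Sequence[SequenceRecord],
    model: str = "K2P",
    gap_mode: str = "pairwise_deletion",
) -> DistanceMatrix:
    """Pairwise substitutions/site over an alignment.

    ``pairwise_deletion`` drops gap/ambiguous columns per pair;
    ``complete_deletion`` drops them from the whole alignment first.
    Saturated pairs are capped at ``SATURATION_CAP`` and listed, with a
    warning, rather than emitted as infinities.
    """
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    length = len(alignment[0].seq)
    if any(len(r.seq) != length for r in alignment):
        raise ValueError("sequences are not aligned to a common length")
    if gap_mode not in ("pairwise_deletion", "complete_deletion"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")

    seqs = [r.seq for r in alignment]
    if gap_mode == "complete_deletion":
        keep = [c for c in range(length) if all(s[c] in _VALID for s in seqs)]
        seqs = ["".join(s[c] for c in keep) for s in seqs]

    n = len(seqs)
    d = np.zeros((n, n))
    saturated: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs[i], seqs[j]
            pa, pb = [], []
            for x, y in zip(a, b):
                if _comparable(x, y):
                    pa.append(x)
                    pb.append(y)
            dist, sat = _site_distance("".join(pa), "".join(pb), model)
            d[i, j] = d[j, i] = dist
            if sat:
                saturated.append((alignment[i].id, alignment[j].id))
    if saturated:
        warnings.warn(
            f"{len(saturated)} saturated pair(s) capped at {SATURATION_CAP} subs/site",
            stacklevel=2,
        )
    return DistanceMatrix([r.id for r in alignment], d, model, gap_mode, saturated)


def build_nj(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining; returns an unrooted (trifurcating-root) tree.

    Q-criterion ties break on the lowest (row, column) index pair in the
    current node ordering.  Negative branch lengths are clamped to zero with
    the deficit moved to the sister branch, preserving the path length
    between the joined pair.
    """
    if not np.all(np.isfinite(dm.d)):
        raise ValueError("distance matrix contains non-finite entries")
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least three taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        # new node reuses slot i
        for k in active:
            if k in (i, j):
                continue
            nd = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[i, k] = d[k, i] = max(nd, 0.0)
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    # three-point formulas for the final star
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        node.length = max(ln, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return root


def total_branch_length(tree: TreeNode) -> float:
    return sum(nd.length or 0.0 for nd in tree.traverse() if not nd.is_root())


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions (internal edges) as canonical leaf-name sets.

    Each internal edge splits the leaves in two; the split is represented by
    whichever side sorts first, so rootings do not matter.
    """
    leaves = frozenset(lf.name for lf in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(lf.name for lf in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return splits


def bootstrap_support(
    alignment: Sequence[SequenceRecord],
    model: str = "K2P",
    gap_mode: str = "pairwise_deletion",
    n_reps: int = 500,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with bootstrap supports (percent of replicates, 0–100).

    Alignment columns are resampled with replacement ``n_reps`` times; each
    internal bipartition of the original tree is scored by the percentage of
    replicate trees that contain it.  Supports are stored on internal nodes
    as ``node.support`` and mirrored into ``node.name``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    tree = build_nj(compute_distances(alignment, model, gap_mode))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    length = len(alignment[0].seq)
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        resampled = [
            SequenceRecord(id=r.id, seq="".join(r.seq[c] for c in cols))
            for r in alignment
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = build_nj(compute_distances(resampled, model, gap_mode))
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1

    leaves = frozenset(lf.name for lf in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(lf.name for lf in node.tips())
        key = min(side, leaves - side, key=lambda s: tuple(sorted(s)))
        if key in counts:
            node.support = 100.0 * counts[key] / n_reps
            node.name = f"{node.support:.0f}"
    return tree


def group_distances(
    dm: DistanceMatrix, groups: Mapping[str, str]
) -> tuple[dict[str, Optional[float]], dict[tuple[str, str], float]]:
    """Mean within-group and between-group distances.

    Within-group mean averages the unordered pairs inside each group
    (absent/None for singleton groups); between-group means average all
    cross pairs for each unordered group pair.
    """
    missing = [lab for lab in dm.labels if lab not in groups]
    if missing:
        raise ValueError(f"ungrouped labels: {missing[:5]}")
    names = sorted(set(groups[lab] for lab in dm.labels))
    idx = {g: [i for i, lab in enumerate(dm.labels) if groups[lab] == g] for g in names}

    within: dict[str, Optional[float]] = {}
    for g, members in idx.items():
        if len(members) < 2:
            within[g] = None
            continue
        vals = [dm.d[i, j] for ai, i in enumerate(members) for j in members[ai + 1 :]]
        within[g] = float(np.mean(vals))

    between: dict[tuple[str, str], float] = {}
    for gi in range(len(names)):
        for gj in range(gi + 1, len(names)):
            a, b = names[gi], names[gj]
            vals = [dm.d[i, j] for i in idx[a] for j in idx[b]]
            between[(a, b)] = float(np.mean(vals))
    return within, between


def pairwise_model_distance(a: str, b: str, model: str = "K2P") -> float:
    """Model distance from a fresh pairwise alignment of two unaligned sequences.

    Terminal gaps are free and excluded; internal gap/ambiguous columns are
    deleted pairwise.
    """
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    start, end = 0, len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    pa = "".join(x for x, y in zip(sa[start:end], sb[start:end]) if _comparable(x, y))
    pb = "".join(y for x, y in zip(sa[start:end], sb[start:end]) if _comparable(x, y))
    dist, _ = _site_distance(pa, pb, model)
    return dist


def assign_genome(
    contig: Contig,
    references: Sequence[SequenceRecord],
    model: str = "K2P",
    min_margin: float = 0.01,
    locus_by_genome: Mapping[str, str] | None = None,
) -> GenomeAssignment:
    """Assign a contig to the locus of the nearest reference genome.

    Each reference must carry a genome label in ``source``.  The contig
    consensus is aligned pairwise to every reference and the mean model
    distance per genome computed; the contig is assigned to the locus of
    the closest genome when the margin to the runner-up reaches
    ``min_margin`` subs/site, else left unassigned.
    """
    locus_by_genome = dict(locus_by_genome or LOCUS_BY_GENOME)
    genomes: dict[str, list[float]] = {}
    for ref in references:
        if not ref.source:
            raise ValueError(f"reference {ref.id} has no genome label")
        try:
            dist = pairwise_model_distance(contig.consensus, ref.seq, model)
        except ValueError:
            return GenomeAssignment(
                contig.contig_id, "unassigned", {}, 0.0, contig.depth,
                reason=f"alignment to {ref.id} has no comparable sites",
            )
        genomes.setdefault(ref.source, []).append(dist)
    if len(genomes) < 2:
        raise ValueError("references must cover at least two genomes")
    means = {g: float(np.mean(v)) for g, v in genomes.items()}
    ranked = sorted(means.items(), key=lambda kv: (kv[1], kv[0]))
    margin = ranked[1][1] - ranked[0][1]
    if margin >= min_margin:
        locus = locus_by_genome.get(ranked[0][0], ranked[0][0])
        return GenomeAssignment(contig.contig_id, locus, means, margin, contig.depth)
    return GenomeAssignment(
        contig.contig_id, "unassigned", means, margin, contig.depth,
        reason=f"margin {margin:.4f} below {min_margin}",
    )
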