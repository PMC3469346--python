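"""Cluster near-identical transcripts into contigs and call consensus sequences.

EST/cDNA collections of a multigene family are redundant: each expressed
gene is represented by many (partial) transcripts.  Contigs are built by
single-linkage clustering at a high identity threshold (default 98%), and a
consensus is called per contig; contigs below a minimum depth are set aside
in a "minor" bin, mirroring the usual ≥4-transcripts support rule for
calling an isoform real.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio import Align

from .sequence_core import ProteinRecord, SequenceRecord, translate_cds

__all__ = [
    "ClusterParams",
    "Contig",
    "ClusterResult",
    "pairwise_identity",
    "cluster_transcripts",
    "call_consensus",
    "star_align",
]


@dataclass
class ClusterParams:
    identity_threshold: float = 0.98
    min_members: int = 4
    min_overlap: int = 300  # nt; shortest credible shared region

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.min_members < 1:
            raise ValueError("min_members must be ≥ 1")


@dataclass
class Contig:
    contig_id: str
    member_ids: list[str]
    consensus: str
    deduced_protein: Optional[ProteinRecord] = None

    @property
    def depth(self) -> int:
        return len(self.member_ids)


@dataclass
class ClusterResult:
    contigs: list[Contig]
    minor: list[str] = field(default_factory=list)  # transcripts in under-depth clusters

    @property
    def n_clustered(self) -> int:
        return sum(c.depth for c in self.contigs)


#: terminal gaps are near-free so partial ESTs align against full-length
#: cDNAs, but cost slightly more than half a mismatch so the aligner never
#: shifts a sequence to clip a terminal mismatch into the overhangs
END_GAP_SCORE = -1.1


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_insertion_score = END_GAP_SCORE
    aligner.end_deletion_score = END_GAP_SCORE
    return aligner


_ALIGNER = _make_aligner()


def _aligned_columns(a: str, b: str) -> tuple[int, int, int]:
    """(matches, columns, overlap) of the optimal alignment, terminal gaps excluded.

    ``columns`` counts alignment columns inside the mutual overlap (mismatches
    and internal gaps included); ``overlap`` counts columns where both
    sequences have a base.
    """
    aln = _ALIGNER.align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    # trim terminal-gap columns
    start = 0
    while sa[start] == "-" or sb[start] == "-":
        start += 1
        if start == len(sa):
            return 0, 0, 0
    end = len(sa)
    while sa[end - 1] == "-" or sb[end - 1] == "-":
        end -= 1
    matches = cols = overlap = 0
    for x, y in zip(sa[start:end], sb[start:end]):
        cols += 1
        if x != "-" and y != "-":
            overlap += 1
            if x == y:
                matches += 1
    return matches, cols, overlap


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction identical over aligned columns, terminal gaps free/excluded."""
    if not a.seq or not b.seq:
        raise ValueError("sequences must be non-empty")
    matches, cols, _ = _aligned_columns(a.seq, b.seq)
    return matches / cols if cols else 0.0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def cluster_transcripts(
    records: Sequence[SequenceRecord],
    params: ClusterParams | None = None,
    translate: bool = True,
) -> ClusterResult:
    """Single-linkage clustering at ``identity_threshold`` with depth filtering.

    Edges join transcript pairs whose global-alignment identity reaches the
    threshold over an overlap of at least ``min_overlap`` nt.  Clusters with
    fewer than ``min_members`` transcripts go to the minor bin.  Contig ids
    are assigned by descending depth, ties by lexicographically smallest
    member id; output is deterministic for a given input order.
    """
    if not records:
        raise ValueError("no records to cluster")
    params = params or ClusterParams()

    # exact duplicates collapse first: identical sequences always co-cluster,
    # and EST sets are dominated by them
    by_seq: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_seq.setdefault(rec.seq, []).append(i)
    reps = [idxs[0] for idxs in by_seq.values()]

    uf = _UnionFind(len(records))
    for idxs in by_seq.values():
        for j in idxs[1:]:
            uf.union(idxs[0], j)
    for ai in range(len(reps)):
        for bi in range(ai + 1, len(reps)):
            i, j = reps[ai], reps[bi]
            matches, cols, overlap = _aligned_columns(records[i].seq, records[j].seq)
            if overlap >= params.min_overlap and cols and matches / cols >= params.identity_threshold:
                uf.union(i, j)

    clusters: dict[int, list[int]] = {}
    for i in range(len(records)):
        clusters.setdefault(uf.find(i), []).append(i)

    kept = [v for v in clusters.values() if len(v) >= params.min_members]
    minor = sorted(records[i].id for v in clusters.values() if len(v) < params.min_members for i in v)
    kept.sort(key=lambda v: (-len(v), min(records[i].id for i in v)))

    contigs: list[Contig] = []
    for k, member_idx in enumerate(kept, start=1):
        members = [records[i] for i in member_idx]
        consensus = call_consensus(members)
        cid = f"contig_{k:03d}"
        prot = None
        if translate:
            prot = translate_cds(SequenceRecord(id=cid, seq=consensus))
        contigs.append(
            Contig(
                contig_id=cid,
                member_ids=[m.id for m in members],
                consensus=consensus,
                deduced_protein=prot,
            )
        )
    return ClusterResult(contigs=contigs, minor=minor)


def star_align(members: Sequence[SequenceRecord]) -> list[str]:
    """Star multiple alignment: all members pairwise-aligned to the longest.

    Gaps inserted into the centre by any member are propagated to all rows.
    Adequate for the near-identical members of a contig; not a general MSA.
    """
    if not members:
        raise ValueError("no members")
    if len(members) == 1:
        return [members[0].seq]
    centre = max(members, key=lambda r: (len(r.seq), r.id))
    pairwise: list[tuple[str, str]] = []
    for m in members:
        if m is centre:
            pairwise.append((centre.seq, centre.seq))
            continue
        aln = _ALIGNER.align(centre.seq, m.seq)[0]
        pairwise.append((str(aln[0]), str(aln[1])))

    # merge insertion patterns relative to the centre
    def gap_runs(centre_row: str) -> list[int]:
        """number of gap columns in the centre before each centre base, plus tail"""
        runs = [0]
        for ch in centre_row:
            if ch == "-":
                runs[-1] += 1
            else:
                runs.append(0)
        return runs

    runs_per = [gap_runs(c) for c, _ in pairwise]
    n_bases = len(centre.seq)
    merged = [max(r[k] for r in runs_per) for k in range(n_bases + 1)]

    rows: list[str] = []
    for (crow, mrow), runs in zip(pairwise, runs_per):
        out: list[str] = []
        pos = 0  # index into crow/mrow
        for k in range(n_bases + 1):
            out.append("-" * (merged[k] - runs[k]))
            out.append(mrow[pos : pos + runs[k]])
            pos += runs[k]
            if k < n_bases:
                out.append(mrow[pos])
                pos += 1
        rows.append("".join(out))
    return rows


def call_consensus(members: Sequence[SequenceRecord]) -> str:
    """Strict per-column majority consensus over a star alignment.

    Ties break by fixed base order A<C<G<T (gap loses all ties); columns
    whose majority is a gap are dropped.
    """
    if not members:
        raise ValueError("no members")
    rows = star_align(members)
    length = len(rows[0])
    out: list[str] = []
    order = {b: i for i, b in enumerate("ACGTN")}
    for col in range(length):
        column = [r[col] for r in rows]
        counts: dict[str, int] = {}
        for ch in column:
            counts[ch] = counts.get(ch, 0) + 1
        # highest count wins; among tied bases prefer A<C<G<T order, never gap
        top = max(counts.values())
        tied = sorted([ch for ch, n in counts.items() if n == top], key=lambda c: order.get(c, 99))
        non_gap = [c for c in tied if c != "-"]
        if counts.get("-", 0) > sum(n for ch, n in counts.items() if ch != "-"):
            continue  # strict gap majority: drop column
        pick = non_gap[0] if non_gap else None
        if pick is None:
            continue
        out.append(pick)
    return "".join(out)
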