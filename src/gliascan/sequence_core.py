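"""Sequence I/O, translation, pseudogene detection and γ-gliadin domain segmentation.

γ-gliadins follow a conserved layout: a short signal peptide (S), a unique
N-terminal domain (I), a P/Q-rich repetitive domain R1 (II), a conserved
non-repetitive domain NR1 (III) carrying six cysteines and opening with the
NPC motif, a second repetitive domain R2 (IV), and a conserved C-terminal
domain NR2 (V) carrying two cysteines and ending in the MCN motif.  This
module segments deduced proteins into those domains and flags pseudogenes
(transcripts whose translation hits an in-frame stop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = [
    "SequenceRecord",
    "ProteinRecord",
    "DomainSegmentation",
    "DOMAIN_ORDER",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "detect_pseudogene",
    "segment_domains",
    "count_domain_cysteines",
    "segmentation_table",
]

#: canonical domain order: signal, unique N-terminal, repeat 1, non-repeat 1
#: (six cysteines, NPC anchor), repeat 2, non-repeat 2 (two cysteines, MCN).
DOMAIN_ORDER = ("S", "I", "R1", "NR1", "R2", "NR2")

_NUCLEOTIDES = set("ACGTN")
# IUPAC ambiguity codes tolerated on read; translated as X (except N-handling
# which Biopython already maps to X for untranslatable codons).
_IUPAC_EXTRA = set("RYSWKMBDHV")
_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}


@dataclass
class SequenceRecord:
    """A nucleotide sequence with identifier and optional genome/source label."""

    id: str
    seq: str
    source: Optional[str] = None
    depth_hint: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        self.seq = self.seq.upper()
        if len(self.seq) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.depth_hint < 1:
            raise ValueError("depth_hint must be a positive integer")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """An amino-acid sequence; ``truncated`` marks an internal stop (pseudogene).

    ``stop_position`` is the 0-based codon index of the first internal stop;
    it is present iff ``truncated`` is true, and ``aa`` ends just before the
    stop in that case.
    """

    id: str
    aa: str
    truncated: bool = False
    stop_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.truncated != (self.stop_position is not None):
            raise ValueError("truncated must be true iff stop_position is present")
        if not self.truncated and "*" in self.aa.rstrip("*"):
            raise ValueError(f"{self.id}: internal '*' but truncated is false")

    def __len__(self) -> int:
        return len(self.aa)


@dataclass
class DomainSegmentation:
    """Half-open protein-coordinate intervals per domain; absent domains are None."""

    intervals: dict[str, Optional[tuple[int, int]]] = field(default_factory=dict)
    anchors_found: set[str] = field(default_factory=set)

    def __getitem__(self, domain: str) -> Optional[tuple[int, int]]:
        return self.intervals.get(domain)

    def present(self) -> list[str]:
        return [d for d in DOMAIN_ORDER if self.intervals.get(d) is not None]


def read_fasta(path: str | Path, alignment: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (upper-cased, order preserved).

    Gap characters '-' are preserved only when ``alignment=True``; otherwise
    they are rejected. Duplicate ids raise a ValueError naming the id.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not alignment and "-" in seq:
            raise ValueError(
                f"{rec.id}: gap characters found; pass alignment=True for aligned FASTA"
            )
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [_BioRecord(Seq(r.seq), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def _validate_nucleotides(rec: SequenceRecord) -> None:
    bad = set(rec.seq) - _NUCLEOTIDES - _IUPAC_EXTRA - {"-"}
    if bad:
        raise ValueError(f"{rec.id}: non-nucleotide characters {sorted(bad)!r}")


def translate_cds(rec: SequenceRecord, frame: int = 0) -> ProteinRecord:
    """Translate a coding-strand sequence with the standard genetic code.

    The trailing partial codon is dropped. Codons containing N or another
    IUPAC ambiguity code translate to 'X' unless unambiguous. At the first
    internal stop the protein is cut: ``truncated=True`` and
    ``stop_position`` records the 0-based codon index of the stop.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    _validate_nucleotides(rec)
    seq = rec.seq.replace("-", "")
    coding = seq[frame:]
    if len(coding) < 3:
        raise ValueError(f"{rec.id}: fewer than one codon in frame {frame}")
    coding = coding[: len(coding) - (len(coding) % 3)]
    aa = str(Seq(coding).translate())
    # terminal stop is not an internal stop
    had_terminal_stop = aa.endswith("*")
    body = aa[:-1] if had_terminal_stop else aa
    stop_idx = body.find("*")
    if stop_idx >= 0:
        return ProteinRecord(rec.id, body[:stop_idx], truncated=True, stop_position=stop_idx)
    return ProteinRecord(rec.id, body)


def detect_pseudogene(prot: ProteinRecord) -> tuple[bool, dict]:
    """Flag a pseudogene (internal stop) and report its context.

    Returns (is_pseudogene, report); the report carries the stop's codon
    index and the up-to-12 residues preceding it.
    """
    if not prot.truncated:
        return False, {}
    start = max(0, len(prot.aa) - 12)
    return True, {
        "stop_position": prot.stop_position,
        "preceding_12mer": prot.aa[start:],
    }


def _repeat_onset(aa: str, begin: int, end: int, window: int = 8, frac: float = 0.5) -> Optional[int]:
    """Onset of repeat (P/Q-rich) content in [begin, end).

    Finds the first position at/after ``begin`` where an 8-residue window is
    ≥50% {P,Q}, then snaps forward to the first P or Q residue of that
    window, so that a rich window straddling a non-repetitive tail does not
    pull the boundary into the preceding domain.
    """
    for i in range(begin, min(end, len(aa) - window + 1)):
        w = aa[i : i + window]
        if sum(c in "PQ" for c in w) / window >= frac:
            for j in range(i, i + window):
                if aa[j] in "PQ":
                    return j if j < end else None
            return i
    return None


def segment_domains(
    prot: ProteinRecord,
    signal_length: int = 19,
    full_length: bool = True,
    nr2_length: int = 33,
) -> DomainSegmentation:
    """Segment a deduced γ-gliadin protein into S/I/R1/NR1/R2/NR2.

    NR1 is anchored at the first "NPC" occurrence and NR2 ends after the last
    "MCN".  The signal peptide is a fixed-length prefix (default 19) for
    full-length proteins.  The I/R1 boundary is the repeat-content onset
    (first ≥50% P/Q 8-residue window, snapped to its first P/Q residue)
    after the signal; the NR1/R2 boundary is the repeat onset after the
    sixth cysteine of NR1.  NR2 is a fixed-length region ending at the MCN
    anchor (no compositional rule separates R2 from NR2, so a length
    convention is used).  Domains that cannot be located are marked absent;
    the function never raises on a conforming protein.
    """
    aa = prot.aa
    if len(aa) < 20:
        raise ValueError("protein too short to segment (need ≥20 residues)")

    seg = DomainSegmentation({d: None for d in DOMAIN_ORDER})
    npc = aa.find("NPC")
    mcn = aa.rfind("MCN")
    if npc >= 0:
        seg.anchors_found.add("NPC")
    if mcn >= 0 and (npc < 0 or mcn > npc):
        seg.anchors_found.add("MCN")
    else:
        mcn = -1

    sig_end = min(signal_length, len(aa)) if full_length else 0
    if full_length:
        seg.intervals["S"] = (0, sig_end)

    if npc < 0:
        # no anchor: only S and I can be delimited
        seg.intervals["I"] = (sig_end, len(aa)) if sig_end < len(aa) else None
        return seg

    r1_start = _repeat_onset(aa, sig_end, npc)
    if r1_start is None:
        r1_start = npc  # no repeat content: all of it is domain I
    if r1_start > sig_end:
        seg.intervals["I"] = (sig_end, r1_start)
    if r1_start < npc:
        seg.intervals["R1"] = (r1_start, npc)

    # NR2 is anchored on MCN alone so a degraded repeat region cannot move it
    if mcn >= 0:
        nr2_end = mcn + 3
        nr2_start = max(npc + 3, nr2_end - nr2_length)
        seg.intervals["NR2"] = (nr2_start, nr2_end)
    else:
        nr2_start = len(aa)

    # NR1 runs from NPC up to the repeat onset after its 6th cysteine
    cys = [i for i, c in enumerate(aa) if c == "C" and npc <= i < nr2_start]
    sixth_c = cys[5] if len(cys) >= 6 else None
    r2_start = None
    if sixth_c is not None and sixth_c < nr2_start:
        r2_start = _repeat_onset(aa, sixth_c + 1, nr2_start)
    if r2_start is None:
        seg.intervals["NR1"] = (npc, nr2_start)
    else:
        seg.intervals["NR1"] = (npc, r2_start)
        if r2_start < nr2_start:
            seg.intervals["R2"] = (r2_start, nr2_start)
    return seg


def count_domain_cysteines(
    prot: ProteinRecord, seg: DomainSegmentation
) -> tuple[dict[str, int], list[str]]:
    """Per-domain cysteine counts with QC flags.

    Conforming γ-gliadins carry six conserved cysteines in NR1 and two in
    NR2; a QC flag is raised when a populated NR1/NR2 deviates.
    """
    counts: dict[str, int] = {}
    flags: list[str] = []
    for dom in DOMAIN_ORDER:
        iv = seg.intervals.get(dom)
        if iv is None:
            continue
        counts[dom] = prot.aa[iv[0] : iv[1]].count("C")
    if "NR1" in counts and counts["NR1"] != 6:
        flags.append(f"NR1 has {counts['NR1']} cysteines, expected 6")
    if "NR2" in counts and counts["NR2"] != 2:
        flags.append(f"NR2 has {counts['NR2']} cysteines, expected 2")
    return counts, flags


def segmentation_table(prots_segs: Iterable[tuple[ProteinRecord, DomainSegmentation]]):
    """Segmentation report rows: id, domain, start, end, anchor flags."""
    rows = []
    for prot, seg in prots_segs:
        anchors = "+".join(sorted(seg.anchors_found)) or "none"
        for dom in DOMAIN_ORDER:
            iv = seg.intervals.get(dom)
            if iv is not None:
                rows.append(
                    {"id": prot.id, "domain": dom, "start": iv[0], "end": iv[1], "anchors": anchors}
                )
    return rows
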