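"""Celiac-disease 9-mer epitope scanning, TG2 deamidation annotation, and
in-silico protease digestion.

The T-cell epitopes of γ-gliadins are 9-residue cores presented by
HLA-DQ2/8 after tissue transglutaminase (TG2) converts specific glutamines
to glutamate.  Matching is exact (a census counts literal cores, overlaps
included); deamidation targets follow the QxP rule plus a curated list of
moderate sites; protease sites follow PeptideCutter-style rules for
trypsin and chymotrypsin, whose absence inside the P/Q-rich repeats marks
proteolysis-resistant, epitope-dense fragments.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

from .sequence_core import ProteinRecord

__all__ = [
    "EpitopeDefinition",
    "EpitopeMatch",
    "DeamidationProfile",
    "CleavageSite",
    "ResistantFragment",
    "DEFAULT_ENZYME_RULES",
    "default_epitope_registry",
    "load_registry",
    "load_moderate_sites",
    "scan_epitopes",
    "count_distinct_epitopes",
    "count_instances",
    "annotate_deamidation",
    "deamidate",
    "predict_cleavage",
    "find_resistant_fragments",
    "extract_epitope_context",
    "render_markup",
]

_AA = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass(frozen=True)
class EpitopeDefinition:
    label: str
    core: str
    alt_label: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.core) != 9:
            raise ValueError(f"{self.label}: core must be exactly 9 residues")


@dataclass(frozen=True)
class EpitopeMatch:
    label: str
    start: int  # 0-based
    matched: str
    flank_left: str = ""
    flank_right: str = ""

    @property
    def end(self) -> int:
        return self.start + 9


@dataclass
class DeamidationProfile:
    """Classification of every Q in a peptide: primary / moderate / none."""

    peptide: str
    classes: dict[int, str] = field(default_factory=dict)  # Q position → class
    rules: dict[int, str] = field(default_factory=dict)  # Q position → rule id

    def positions(self, cls: str) -> list[int]:
        return sorted(p for p, c in self.classes.items() if c == cls)


@dataclass(frozen=True)
class CleavageSite:
    enzyme: str
    position: int  # cleavage occurs after this 0-based residue


@dataclass
class ResistantFragment:
    start: int
    end: int  # half-open
    matches: list[EpitopeMatch]
    enzymes: tuple[str, ...]


def _data_rows(filename: str) -> list[dict[str, str]]:
    ref = resources.files("gliascan.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def default_epitope_registry() -> list[EpitopeDefinition]:
    """The nine canonical γ-gliadin CD-epitope cores, with both nomenclatures."""
    out = []
    for row in _data_rows("epitope_registry.tsv"):
        out.append(
            EpitopeDefinition(
                label=row["label"], core=row["core"], alt_label=row["alt_label"] or None
            )
        )
    return out


def load_registry(path: str) -> list[EpitopeDefinition]:
    """Read a user registry TSV (columns: label, alt_label, core)."""
    out = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["label"] in seen:
                raise ValueError(f"duplicate epitope label {row['label']!r}")
            seen.add(row["label"])
            out.append(
                EpitopeDefinition(
                    label=row["label"], core=row["core"], alt_label=row.get("alt_label") or None
                )
            )
    return out


def load_moderate_sites() -> dict[str, frozenset[int]]:
    """Curated moderate TG2 target sites: peptide → 0-based Q positions.

    Position-specific by necessity: identical local Q contexts can differ in
    annotation, so no sequence rule can replace the curated table.
    """
    table: dict[str, frozenset[int]] = {}
    for row in _data_rows("tg2_moderate_sites.tsv"):
        pos = row["moderate_positions"].strip()
        table[row["peptide"]] = frozenset(int(p) for p in pos.split(",")) if pos else frozenset()
    return table


def scan_epitopes(
    prot: ProteinRecord | str,
    registry: Sequence[EpitopeDefinition] | None = None,
    region: Optional[tuple[int, int]] = None,
    flank: int = 4,
) -> list[EpitopeMatch]:
    """All exact (overlapping) occurrences of registry cores, sorted by (start, label).

    ``region`` restricts matches to those fully inside the half-open interval.
    """
    aa = prot if isinstance(prot, str) else prot.aa
    registry = registry if registry is not None else default_epitope_registry()
    lo, hi = region if region is not None else (0, len(aa))
    matches: list[EpitopeMatch] = []
    for ep in registry:
        start = aa.find(ep.core, lo)
        while start >= 0 and start + 9 <= hi:
            matches.append(
                EpitopeMatch(
                    label=ep.label,
                    start=start,
                    matched=ep.core,
                    flank_left=aa[max(0, start - flank) : start],
                    flank_right=aa[start + 9 : start + 9 + flank],
                )
            )
            start = aa.find(ep.core, start + 1)
    matches.sort(key=lambda m: (m.start, m.label))
    return matches


def count_distinct_epitopes(matches: Iterable[EpitopeMatch]) -> int:
    return len({m.label for m in matches})


def count_instances(matches: Iterable[EpitopeMatch]) -> int:
    return sum(1 for _ in matches)


def annotate_deamidation(
    peptide: str, moderate_sites: dict[str, frozenset[int]] | None = None
) -> DeamidationProfile:
    """Classify each glutamine as a primary, moderate or non-target of TG2.

    Default rule table, applied in order at each Q position i:

    - R1 (primary): residue i+2 is P and residue i+1 is not P (QxP motif);
    - R2 (none): residue i+1 is P (QP is never deamidated);
    - R3 (moderate): (peptide, i) is in the curated moderate-site table;
    - otherwise: none.
    """
    if not peptide:
        raise ValueError("empty peptide")
    bad = set(peptide) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters {sorted(bad)!r}")
    moderate_sites = moderate_sites if moderate_sites is not None else load_moderate_sites()
    curated = moderate_sites.get(peptide, frozenset())
    prof = DeamidationProfile(peptide)
    for i, ch in enumerate(peptide):
        if ch != "Q":
            continue
        nxt = peptide[i + 1] if i + 1 < len(peptide) else ""
        nxt2 = peptide[i + 2] if i + 2 < len(peptide) else ""
        if nxt2 == "P" and nxt != "P":
            prof.classes[i], prof.rules[i] = "primary", "R1"
        elif nxt == "P":
            prof.classes[i], prof.rules[i] = "none", "R2"
        elif i in curated:
            prof.classes[i], prof.rules[i] = "moderate", "R3"
        else:
            prof.classes[i], prof.rules[i] = "none", "default"
    return prof


def deamidate(peptide: str, include_moderate: bool = False,
              moderate_sites: dict[str, frozenset[int]] | None = None) -> str:
    """Q→E substitution at primary (optionally also moderate) TG2 targets."""
    prof = annotate_deamidation(peptide, moderate_sites)
    take = set(prof.positions("primary"))
    if include_moderate:
        take |= set(prof.positions("moderate"))
    return "".join("E" if i in take else c for i, c in enumerate(peptide))


def render_markup(peptide: str, moderate_sites: dict[str, frozenset[int]] | None = None) -> str:
    """Text proxy for the usual bold/italic deamidation markup.

    Primary-target glutamines are underlined ("Q" + combining low line),
    moderate targets are lower-case ("q"), everything else is plain
    upper-case — so ``QPQ̲QPqQSF…`` reads like the printed annotation.
    """
    prof = annotate_deamidation(peptide, moderate_sites)
    out = []
    for i, ch in enumerate(peptide):
        cls = prof.classes.get(i)
        if cls == "primary":
            out.append("Q̲")
        elif cls == "moderate":
            out.append("q")
        else:
            out.append(ch)
    return "".join(out)


#: enzyme → (residues cleaved after, blocking exceptions).  Cleavage occurs
#: C-terminal of the listed residue unless the next residue is P; for
#: chymotrypsin-low an H site is additionally blocked before M or W.
DEFAULT_ENZYME_RULES: dict[str, dict] = {
    "trypsin": {"after": set("KR"), "block_next": {"P"}},
    "chymotrypsin_high": {"after": set("FYW"), "block_next": {"P"}},
    "chymotrypsin_low": {
        "after": set("FLMWYH"),
        "block_next": {"P"},
        "extra_block": {"H": {"M", "W"}},
    },
}


def predict_cleavage(
    prot: ProteinRecord | str,
    enzymes: Sequence[str] = ("trypsin",),
    rules: dict[str, dict] | None = None,
) -> list[CleavageSite]:
    """Protease cleavage sites under PeptideCutter-style rules (overridable)."""
    aa = prot if isinstance(prot, str) else prot.aa
    if len(aa) < 2:
        raise ValueError("protein too short to digest")
    rules = rules or DEFAULT_ENZYME_RULES
    sites: list[CleavageSite] = []
    for enz in enzymes:
        rule = rules[enz]
        for i in range(len(aa) - 1):
            if aa[i] not in rule["after"]:
                continue
            nxt = aa[i + 1]
            if nxt in rule.get("block_next", set()):
                continue
            if nxt in rule.get("extra_block", {}).get(aa[i], set()):
                continue
            sites.append(CleavageSite(enzyme=enz, position=i))
    sites.sort(key=lambda s: (s.position, s.enzyme))
    return sites


def find_resistant_fragments(
    prot: ProteinRecord | str,
    enzymes: Sequence[str] = ("trypsin", "chymotrypsin_high"),
    min_epitope_instances: int = 1,
    registry: Sequence[EpitopeDefinition] | None = None,
    rules: dict[str, dict] | None = None,
) -> list[ResistantFragment]:
    """Maximal uncleaved intervals holding ≥ ``min_epitope_instances`` matches.

    The considered enzymes' sites partition the protein; each fragment between
    consecutive sites (or protein ends) is returned when enough epitope
    matches lie fully inside it.
    """
    aa = prot if isinstance(prot, str) else prot.aa
    sites = predict_cleavage(aa, enzymes, rules)
    cuts = sorted({s.position + 1 for s in sites})
    bounds = [0] + cuts + [len(aa)]
    matches = scan_epitopes(aa, registry)
    out: list[ResistantFragment] = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if lo >= hi:
            continue
        inside = [m for m in matches if m.start >= lo and m.end <= hi]
        if len(inside) >= min_epitope_instances:
            out.append(ResistantFragment(lo, hi, inside, tuple(enzymes)))
    return out


def extract_epitope_context(
    prot: ProteinRecord | str,
    epitope_label: str,
    flank: int = 4,
    registry: Sequence[EpitopeDefinition] | None = None,
) -> list[str]:
    """Flanked peptides (core ± up to ``flank`` residues) for one epitope.

    Deduplicating these over a transcriptome yields natural-variant tables of
    an epitope in its flanking context.
    """
    if flank < 0:
        raise ValueError("flank must be ≥ 0")
    aa = prot if isinstance(prot, str) else prot.aa
    matches = scan_epitopes(aa, registry, flank=flank)
    return [
        m.flank_left + m.matched + m.flank_right for m in matches if m.label == epitope_label
    ]
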