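"""Per-locus CD-epitope census tables.

The census weights each contig's deduced-protein epitope matches by contig
depth (every member transcript carries the consensus protein's epitopes),
aggregates over assignment groups and homoeologous loci, and reports
epitopes-per-transcript frequencies and percentage shares.  A second entry
point aggregates an already-counted epitope × group matrix, so published
count tables can be re-derived without the raw transcript data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .contig_assembly import Contig
from .epitope_screen import EpitopeDefinition, default_epitope_registry, scan_epitopes
from .phylo_assign import GenomeAssignment

__all__ = [
    "EpitopeCensusTable",
    "LocusAggregate",
    "census",
    "aggregate_printed_counts",
    "render_report",
    "parse_report",
    "load_printed_counts",
    "load_printed_layout",
    "round_half_up",
]


def round_half_up(value, ndigits: int = 0) -> float:
    """Decimal rounding, ties away from zero (so 8.45 → 8.5, 58.5 → 59)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_UP))


def _ratio(num: int, den: int, ndigits: int) -> float:
    return float((Decimal(num) / Decimal(den)).quantize(
        Decimal(1).scaleb(-ndigits), rounding=ROUND_HALF_UP))


@dataclass
class LocusAggregate:
    locus: str
    n_epitopes: int
    n_transcripts: int
    frequency: Optional[float]  # epitope cores per transcript, 1 decimal
    epitope_share_pct: Optional[int]
    transcript_share_pct: Optional[int]


@dataclass
class EpitopeCensusTable:
    counts: pd.DataFrame  # epitope × group, instance counts × depth
    n_transcripts: dict[str, int]  # per group
    group_to_locus: dict[str, str]
    distinct: pd.DataFrame | None = None  # epitope × group, 0/1 presence
    excluded_pseudogenes: int = 0
    notes: list[str] = field(default_factory=list)

    @property
    def group_totals(self) -> dict[str, int]:
        return {g: int(self.counts[g].sum()) for g in self.counts.columns}

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def group_frequency(self, group: str) -> Optional[float]:
        n = self.n_transcripts.get(group, 0)
        if n == 0:
            return None
        return _ratio(self.group_totals[group], n, 1)

    def locus_aggregates(self) -> list[LocusAggregate]:
        loci: dict[str, list[str]] = {}
        for g in self.counts.columns:
            loci.setdefault(self.group_to_locus.get(g, g), []).append(g)
        grand = self.grand_total
        all_tx = sum(self.n_transcripts.values())
        out = []
        for locus in sorted(loci):
            total = sum(self.group_totals[g] for g in loci[locus])
            tx = sum(self.n_transcripts[g] for g in loci[locus])
            out.append(
                LocusAggregate(
                    locus=locus,
                    n_epitopes=total,
                    n_transcripts=tx,
                    frequency=_ratio(total, tx, 1) if tx else None,
                    epitope_share_pct=int(_ratio(100 * total, grand, 0)) if grand else None,
                    transcript_share_pct=int(_ratio(100 * tx, all_tx, 0)) if all_tx else None,
                )
            )
        return out

    def to_json(self) -> str:
        payload = {
            agg.locus: {
                "n_transcripts": agg.n_transcripts,
                "n_epitopes": agg.n_epitopes,
                "frequency": agg.frequency,
                "epitope_share_pct": agg.epitope_share_pct,
                "transcript_share_pct": agg.transcript_share_pct,
            }
            for agg in self.locus_aggregates()
        }
        payload["_meta"] = {
            "grand_total": self.grand_total,
            "total_transcripts": sum(self.n_transcripts.values()),
            "excluded_pseudogenes": self.excluded_pseudogenes,
            "notes": self.notes,
        }
        return json.dumps(payload, indent=2, ensure_ascii=False)


def census(
    contigs: Sequence[Contig],
    assignments: Sequence[GenomeAssignment],
    registry: Sequence[EpitopeDefinition] | None = None,
    include_pseudogenes: bool = False,
    region: Optional[dict[str, tuple[int, int]]] = None,
) -> EpitopeCensusTable:
    """Depth-weighted epitope × group census over assigned contigs.

    Groups are assignment loci (``unassigned`` is its own group).  Contigs
    whose deduced protein is truncated by an internal stop are pseudogenes
    and excluded unless ``include_pseudogenes``; the exclusion count is
    noted on the table.  ``region`` optionally restricts scanning per contig
    to a protein interval (e.g. the repeat domains only).
    """
    registry = registry if registry is not None else default_epitope_registry()
    locus_of = {a.contig_id: a.locus for a in assignments}
    labels = [ep.label for ep in registry]
    cells: dict[str, dict[str, int]] = {}
    distinct: dict[str, dict[str, set]] = {}
    n_tx: dict[str, int] = {}
    excluded = 0
    for contig in contigs:
        prot = contig.deduced_protein
        if prot is None:
            raise ValueError(f"{contig.contig_id} has no deduced protein")
        if prot.truncated and not include_pseudogenes:
            excluded += 1
            continue
        group = locus_of.get(contig.contig_id, "unassigned")
        n_tx[group] = n_tx.get(group, 0) + contig.depth
        reg = region.get(contig.contig_id) if region else None
        matches = scan_epitopes(prot, registry, region=reg)
        col = cells.setdefault(group, {lab: 0 for lab in labels})
        dcol = distinct.setdefault(group, {lab: set() for lab in labels})
        for m in matches:
            col[m.label] += contig.depth
            dcol[m.label].add(contig.contig_id)
    groups = sorted(cells)
    counts = pd.DataFrame(
        {g: [cells[g][lab] for lab in labels] for g in groups}, index=labels, dtype=int
    )
    dmat = pd.DataFrame(
        {g: [len(distinct[g][lab]) for lab in labels] for g in groups}, index=labels, dtype=int
    )
    notes = []
    if excluded:
        notes.append(f"{excluded} pseudogene contig(s) excluded from the census")
    return EpitopeCensusTable(
        counts=counts,
        n_transcripts=n_tx,
        group_to_locus={g: g for g in groups},
        distinct=dmat,
        excluded_pseudogenes=excluded,
        notes=notes,
    )


def aggregate_printed_counts(
    count_matrix: pd.DataFrame,
    transcripts_per_group: Mapping[str, int],
    group_to_locus: Mapping[str, str],
    printed_row_sums: Mapping[str, int] | None = None,
    printed_grand_total: Optional[int] = None,
) -> tuple[EpitopeCensusTable, list[str]]:
    """Aggregate an epitope × group count matrix into locus totals and shares.

    All sums are recomputed from the cells; when printed marginal sums are
    supplied, disagreements are flagged (returned as messages) rather than
    arbitrated — the cells are taken as the authoritative input.
    """
    if (count_matrix.to_numpy() < 0).any():
        raise ValueError("count matrix must be non-negative")
    table = EpitopeCensusTable(
        counts=count_matrix.astype(int),
        n_transcripts={g: int(transcripts_per_group[g]) for g in count_matrix.columns},
        group_to_locus=dict(group_to_locus),
    )
    flags: list[str] = []
    if printed_row_sums is not None:
        for epitope, printed in printed_row_sums.items():
            recomputed = int(count_matrix.loc[epitope].sum())
            if recomputed != int(printed):
                flags.append(
                    f"{epitope}: recomputed row sum {recomputed} ≠ printed {printed}"
                )
    if printed_grand_total is not None and table.grand_total != int(printed_grand_total):
        flags.append(
            f"grand total: recomputed {table.grand_total} ≠ printed {printed_grand_total}"
        )
    table.notes.extend(flags)
    return table, flags


def render_report(table: EpitopeCensusTable) -> str:
    """Deterministic TSV rendering: epitopes ordered by descending grand total
    (ties lexicographic), a sum row, and per-group/locus aggregate rows."""
    order = sorted(
        table.counts.index, key=lambda lab: (-int(table.counts.loc[lab].sum()), lab)
    )
    counts = table.counts.loc[order]
    lines = ["epitope\t" + "\t".join(counts.columns) + "\ttotal"]
    for lab in order:
        row = counts.loc[lab]
        lines.append(lab + "\t" + "\t".join(str(int(v)) for v in row) + f"\t{int(row.sum())}")
    totals = [str(table.group_totals[g]) for g in counts.columns]
    lines.append("N_epitopes\t" + "\t".join(totals) + f"\t{table.grand_total}")
    lines.append(
        "N_transcripts\t"
        + "\t".join(str(table.n_transcripts.get(g, 0)) for g in counts.columns)
        + f"\t{sum(table.n_transcripts.values())}"
    )
    freqs = []
    for g in counts.columns:
        f = table.group_frequency(g)
        freqs.append("NA" if f is None else f"{f:.1f}")
    lines.append("frequency\t" + "\t".join(freqs) + "\t")
    for agg in table.locus_aggregates():
        lines.append(
            f"#locus\t{agg.locus}\t{agg.n_epitopes}\t{agg.n_transcripts}\t"
            f"{'NA' if agg.frequency is None else f'{agg.frequency:.1f}'}\t"
            f"{agg.epitope_share_pct}\t{agg.transcript_share_pct}"
        )
    for note in table.notes:
        lines.append(f"#note\t{note}")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> pd.DataFrame:
    """Parse the epitope count block of a rendered report back to a DataFrame."""
    rows = [ln.split("\t") for ln in text.strip().splitlines() if not ln.startswith("#")]
    header = rows[0]
    body = [r for r in rows[1:] if r[0] not in ("N_epitopes", "N_transcripts", "frequency")]
    df = pd.DataFrame(
        {g: [int(r[1 + i]) for r in body] for i, g in enumerate(header[1:-1])},
        index=[r[0] for r in body],
        dtype=int,
    )
    return df


def load_printed_counts() -> tuple[pd.DataFrame, dict[str, int]]:
    """Published epitope × topology-group count matrix plus its printed row sums."""
    ref = resources.files("gliascan.data").joinpath("printed_epitope_counts.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    groups = [k for k in rows[0] if k not in ("epitope", "printed_sum")]
    df = pd.DataFrame(
        {g: [int(r[g]) for r in rows] for g in groups},
        index=[r["epitope"] for r in rows],
        dtype=int,
    )
    printed = {r["epitope"]: int(r["printed_sum"]) for r in rows}
    return df, printed


def load_printed_layout() -> pd.DataFrame:
    """Published topology-group → locus map with per-group transcript counts."""
    ref = resources.files("gliascan.data").joinpath("printed_group_layout.tsv")
    with ref.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    return pd.DataFrame(rows).astype({"n_transcripts": int}).set_index("group")
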