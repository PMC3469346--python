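"""Synthetic γ-gliadin gene families with ground truth.

Emulates the data a prolamin transcriptome study works with, so every
pipeline stage is testable without downloads: a multigene family with the
canonical domain layout (signal, unique N-terminal domain, repetitive R1,
conserved NR1 opening with NPC and carrying six cysteines, repetitive R2,
conserved NR2 with two cysteines ending in MCN), three genome groups (A, S,
D — the diploid relatives of bread wheat's subgenomes) with tunable
within- and between-genome divergence, heavily skewed transcript depth per
gene, and pseudogenes created by C→T transitions that put an in-frame stop
in R1.

Divergence semantics: ``between_genome_divergence`` is the expected pairwise
p-distance between genome founders, ``within_genome_divergence`` between
genes of one genome.  Substitutions are drawn per site with a 2:1
transition:transversion bias; the per-branch substitution probability is
solved from the target pairwise distance (two independent branches from a
common source otherwise undershoot the target).  Substitutions never create
stop codons and never touch the anchor/cysteine codons, so domain anchors
survive divergence; everything else drifts freely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import sqrt
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sequence_core import SequenceRecord, translate_cds, write_fasta

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "GeneTruth",
    "DEFAULT_GRAMMARS",
    "generate_reference_genes",
    "sample_transcripts",
    "emit",
    "branch_probability",
]

# ---------------------------------------------------------------------------
# protein architecture templates (ancestor).  The non-repetitive templates are
# deliberately P/Q-poor so the segmenter's repeat-content heuristic has an
# unambiguous truth to recover; real γ-gliadin conserved domains are more
# Q-rich than this.
SIGNAL = "MKTLLILTILAMAITIGTA"  # 19 aa, fixed-length signal peptide
DOMAIN_I = "NIDVGSGEVESRLTKHW"  # unique N-terminal domain, no P/Q
NR1_TEMPLATE = "NPCKNILLERCKVSVDSLWSTIWDSNEATAVRHECARELAKIDRVSDCISKHECARVLKDTAC"
NR2_TEMPLATE = "LVQGQGIIQPQQPAQLEAIRSLVLQCLPTWMCN"  # 33 aa, ends in MCN

#: per-genome weighted repeat-unit grammars.  Units plant the canonical
#: epitope cores with genome-specific composition: the D grammar carries the
#: VIIb/VI/γ2a 17-mer repeat and the proteolysis-resistant 26-mer, A carries
#: the 17-mer and a DQ2-γ-I context, S carries VIIa and a divergent γ-I
#: context — echoing the unequal epitope load of the three homoeologous loci.
DEFAULT_GRAMMARS: dict[str, list[tuple[str, float]]] = {
    "D": [
        ("QQPQQPFPQQPQQPFPQ", 3.0),  # VIIb ×2 / VI / γ2a repeat
        ("FLQPQQPFPQQPQQPYPQQPQQPFPQ", 1.0),  # 26-mer: VI, III, γ2b, VIIb
        ("QPQQPQQSFPQQQQPLI", 1.0),  # DQ2-γ-I in its variant-1 context
    ],
    "A": [
        ("QQPQQPFPQQPQQPFPQ", 2.0),
        ("QQPQQPFPQ", 2.0),  # lone VIIb unit
        ("QPQQPQQSFPQQQQPAI", 1.0),  # DQ2-γ-I, variant-4 context
    ],
    "S": [
        ("PQPQQQFPQ", 2.0),  # VIIa
        ("QQPQQQLPQ", 2.0),  # spacer unit, matches no core
        ("QPQQPQQSFPQQQPSLI", 1.0),  # DQ2-γ-I, variant-5 context
    ],
}

#: fixed reverse-translation codon table (one frequent wheat codon per aa);
#: Q = CAA so a single C→T transition yields the TAA stop used for
#: pseudogene injection.
CODON = {
    "A": "GCA", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAG", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCA", "Q": "CAA", "R": "AGG", "S": "AGC", "T": "ACT", "V": "GTG",
    "W": "TGG", "Y": "TAT",
}
_STOPS = {"TAA", "TAG", "TGA"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@dataclass
class SyntheticConfig:
    genome_labels: tuple[str, ...] = ("A", "S", "D")
    genes_per_genome: int = 4
    r1_repeats: tuple[int, int] = (3, 5)  # units, inclusive range
    r2_repeats: tuple[int, int] = (1, 2)
    within_genome_divergence: float = 0.216  # subs/site, D-genome paralog scale
    between_genome_divergence: float = 0.43
    depth_range: tuple[int, int] = (4, 220)  # log-uniform (skewed) per gene
    pseudogene_rate: float = 0.1  # per-gene probability of an injected stop
    error_rate: float = 0.0  # per-base transcript error
    truncate_prob: float = 0.0  # probability a transcript is 5'-truncated
    min_overlap: int = 300  # nt of the 3' region every truncated copy keeps
    seed: int = 0
    grammars: Optional[dict[str, list[tuple[str, float]]]] = None  # None = per-genome defaults
    shared_grammar: bool = False  # True: all genomes inherit the ancestor's repeats

    def __post_init__(self) -> None:
        for name in ("within_genome_divergence", "between_genome_divergence"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.8):
                raise ValueError(f"{name} must be in [0, 0.8]")
        if self.genes_per_genome < 1 or self.depth_range[0] < 1:
            raise ValueError("counts must be positive")


@dataclass
class GeneTruth:
    gene_id: str
    genome: str
    protein: str
    nt: str
    domains: dict[str, tuple[int, int]]  # aa coordinates, half-open
    epitope_counts: dict[str, int]
    pseudogene: bool = False
    stop_codon_index: Optional[int] = None


@dataclass
class SyntheticTruth:
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    transcripts: list[dict] = field(default_factory=list)  # id, gene_id, genome, pseudogene
    config: Optional[SyntheticConfig] = None


def branch_probability(target_pairwise: float) -> float:
    """Per-branch substitution probability for a target pairwise p-distance.

    Two lineages mutated independently from a common source differ at a site
    with probability 2q(1−q) + 0.625·q² (0.625 = chance two 2:1
    transition-biased substitutions of the same base disagree); invert for q.
    """
    d = target_pairwise
    if d <= 0.0:
        return 0.0
    disc = 4.0 - 5.5 * d
    if disc < 0.0:
        raise ValueError(f"pairwise divergence {d} not reachable")
    return (2.0 - sqrt(disc)) / 2.75


_CYS_CODONS = {"TGC", "TGT"}


def _mutate(nt: str, q: float, rng: np.random.Generator, protected: set[int]) -> str:
    """Substitute each unprotected site with probability q (ts:tv = 2:1).

    Substitutions are redrawn when they would create an in-frame stop (only
    deliberate pseudogene injection makes stops) or a new cysteine codon
    (the family's conserved cysteine skeleton is held fixed; existing Cys
    codons are protected separately).
    """
    if q <= 0.0:
        return nt
    seq = list(nt)
    hits = np.nonzero(rng.random(len(seq)) < q)[0]
    for i in hits:
        if int(i) in protected:
            continue
        old = seq[i]
        if old not in "ACGT":
            continue
        choices = [_TRANSITION[old]] + [b for b in "ACGT" if b != old and b != _TRANSITION[old]]
        weights = [0.5, 0.25, 0.25]
        order = list(rng.choice(len(choices), size=3, replace=False, p=weights))
        codon_start = (i // 3) * 3
        was_cys = "".join(seq[codon_start : codon_start + 3]) in _CYS_CODONS
        for k in order:
            seq[i] = choices[k]
            codon = "".join(seq[codon_start : codon_start + 3])
            if codon not in _STOPS and (was_cys or codon not in _CYS_CODONS):
                break
        else:
            seq[i] = old  # no admissible substitution exists; leave the site
    return "".join(seq)


def _naive_epitope_counts(aa: str, cores: dict[str, str]) -> dict[str, int]:
    """Brute-force window count of each core (overlaps included)."""
    out = {}
    for label, core in cores.items():
        out[label] = sum(1 for i in range(len(aa) - 8) if aa[i : i + 9] == core)
    return out


def _registry_cores() -> dict[str, str]:
    from .epitope_screen import default_epitope_registry

    return {ep.label: ep.core for ep in default_epitope_registry()}


def _sample_units(
    grammar: list[tuple[str, float]], n: int, rng: np.random.Generator
) -> list[str]:
    """Draw n weighted repeat units; the first unit of a region must open
    with P or Q so the repeat-content boundary is well defined."""
    units = [u for u, _ in grammar]
    w = np.array([wt for _, wt in grammar], dtype=float)
    w /= w.sum()
    out = [units[int(k)] for k in rng.choice(len(units), size=n, p=w)]
    if out and out[0][0] not in "PQ":
        starters = [i for i, u in enumerate(units) if u[0] in "PQ"]
        if not starters:
            raise ValueError("grammar needs at least one P/Q-initial unit")
        ws = w[starters] / w[starters].sum()
        out[0] = units[int(rng.choice(starters, p=ws))]
    return out


def _architecture(r1_units: Sequence[str], r2_units: Sequence[str]):
    """Assemble the ancestor protein and its domain intervals."""
    parts = [SIGNAL, DOMAIN_I, "".join(r1_units), NR1_TEMPLATE, "".join(r2_units), NR2_TEMPLATE]
    names = ["S", "I", "R1", "NR1", "R2", "NR2"]
    domains: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, part in zip(names, parts):
        domains[name] = (pos, pos + len(part))
        pos += len(part)
    return "".join(parts), domains


def _protected_sites(aa: str, domains: dict[str, tuple[int, int]]) -> set[int]:
    """nt positions whose codons must survive: start codon, NPC/MCN anchors,
    and the conserved cysteines of NR1/NR2."""
    aa_pos: set[int] = {0}
    nr1, nr2 = domains["NR1"], domains["NR2"]
    aa_pos.update(range(nr1[0], nr1[0] + 3))  # NPC
    aa_pos.update(range(nr2[1] - 3, nr2[1]))  # MCN
    for lo, hi in (nr1, nr2):
        aa_pos.update(i for i in range(lo, hi) if aa[i] == "C")
    nt_pos: set[int] = set()
    for p in aa_pos:
        nt_pos.update(range(3 * p, 3 * p + 3))
    return nt_pos


def generate_reference_genes(cfg: SyntheticConfig) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Reference gene set: per genome, ``genes_per_genome`` full-length genes.

    The ancestor's architecture (repeat counts) is sampled once; each genome
    founder resamples its repeat units from its own grammar (unless
    ``shared_grammar``) and diverges by substitution, then genes diverge
    within the genome.  Records carry the genome label in ``source``.
    """
    rng = np.random.default_rng(cfg.seed)
    grammars = cfg.grammars or DEFAULT_GRAMMARS
    n_r1 = int(rng.integers(cfg.r1_repeats[0], cfg.r1_repeats[1] + 1))
    n_r2 = int(rng.integers(cfg.r2_repeats[0], cfg.r2_repeats[1] + 1))

    anc_grammar = grammars[cfg.genome_labels[0]] if cfg.shared_grammar else None
    if cfg.shared_grammar:
        anc_r1 = _sample_units(anc_grammar, n_r1, rng)
        anc_r2 = _sample_units(anc_grammar, n_r2, rng)

    q_between = branch_probability(cfg.between_genome_divergence)
    q_within = branch_probability(cfg.within_genome_divergence)
    cores = _registry_cores()

    records: list[SequenceRecord] = []
    truth = SyntheticTruth(config=cfg)
    for genome in cfg.genome_labels:
        grammar = grammars.get(genome) or next(iter(grammars.values()))
        if cfg.shared_grammar:
            r1_units, r2_units = anc_r1, anc_r2
        else:
            r1_units = _sample_units(grammar, n_r1, rng)
            r2_units = _sample_units(grammar, n_r2, rng)
        aa, domains = _architecture(r1_units, r2_units)
        anc_nt = "".join(CODON[c] for c in aa)
        protected = _protected_sites(aa, domains)
        founder = _mutate(anc_nt, q_between, rng, protected)
        for g in range(1, cfg.genes_per_genome + 1):
            gene_nt = _mutate(founder, q_within, rng, protected)
            gene_id = f"{genome}_g{g}"
            prot = translate_cds(SequenceRecord(id=gene_id, seq=gene_nt))
            if prot.truncated:  # cannot happen: mutations are stop-free
                raise AssertionError("unexpected internal stop in generated gene")
            records.append(SequenceRecord(id=gene_id, seq=gene_nt, source=genome))
            truth.genes[gene_id] = GeneTruth(
                gene_id=gene_id,
                genome=genome,
                protein=prot.aa,
                nt=gene_nt,
                domains=dict(domains),
                epitope_counts=_naive_epitope_counts(prot.aa, cores),
            )
    return records, truth


def sample_transcripts(
    genes: Sequence[SequenceRecord],
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
) -> tuple[list[SequenceRecord], SyntheticTruth]:
    """Skewed-depth transcript sets per gene, with optional truncation, error
    and per-gene pseudogene injection (C→T of a CAA codon in R1 → TAA stop).

    The truth object is updated in place (gene pseudogene flags, transcript
    table) and returned.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    lo, hi = cfg.depth_range
    out: list[SequenceRecord] = []
    for gene in genes:
        gt = truth.genes[gene.id]
        depth = int(round(float(np.exp(rng.uniform(np.log(lo), np.log(hi)))))) if hi > lo else lo
        depth = max(lo, min(depth, hi))
        nt = gene.seq
        if cfg.pseudogene_rate > 0 and rng.random() < cfg.pseudogene_rate:
            r1 = gt.domains["R1"]
            q_codons = [
                p for p in range(r1[0], r1[1])
                if nt[3 * p : 3 * p + 3] == "CAA" and 3 * p + 3 < len(nt)
            ]
            if q_codons:
                p = int(rng.choice(q_codons))
                nt = nt[: 3 * p] + "TAA" + nt[3 * p + 3 :]
                gt.pseudogene = True
                gt.stop_codon_index = p
        for t in range(1, depth + 1):
            seq = nt
            if cfg.truncate_prob > 0 and rng.random() < cfg.truncate_prob:
                max_cut = max(0, len(seq) - cfg.min_overlap)
                nr1_start_nt = 3 * gt.domains["NR1"][0]
                cut = int(rng.integers(0, min(max_cut, nr1_start_nt) + 1))
                seq = seq[cut:]
            if cfg.error_rate > 0:
                seq = _mutate(seq, cfg.error_rate, rng, protected=set())
            tid = f"{gene.id}_t{t:03d}"
            out.append(SequenceRecord(id=tid, seq=seq, source=gt.genome))
            truth.transcripts.append(
                {"id": tid, "gene_id": gene.id, "genome": gt.genome, "pseudogene": gt.pseudogene}
            )
    return out, truth


def emit(
    references: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    truth: SyntheticTruth,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write FASTA files and truth tables; byte-deterministic for a given seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "references": outdir / "references.fasta",
        "transcripts": outdir / "transcripts.fasta",
        "truth_transcripts": outdir / "truth_transcripts.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "config": outdir / "config.json",
    }
    write_fasta(references, paths["references"])
    write_fasta(transcripts, paths["transcripts"])
    with open(paths["truth_transcripts"], "w", encoding="utf-8") as fh:
        fh.write("id\tgene_id\tgenome\tpseudogene\n")
        for row in truth.transcripts:
            fh.write(f"{row['id']}\t{row['gene_id']}\t{row['genome']}\t{int(row['pseudogene'])}\n")
    with open(paths["truth_genes"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tgenome\tpseudogene\tstop_codon_index\tdomains\tepitope_counts\tprotein\n")
        for gt in truth.genes.values():
            fh.write(
                f"{gt.gene_id}\t{gt.genome}\t{int(gt.pseudogene)}\t"
                f"{'' if gt.stop_codon_index is None else gt.stop_codon_index}\t"
                f"{json.dumps(gt.domains, sort_keys=True)}\t"
                f"{json.dumps(gt.epitope_counts, sort_keys=True)}\t{gt.protein}\n"
            )
    if truth.config is not None:
        with open(paths["config"], "w", encoding="utf-8") as fh:
            json.dump(asdict(truth.config), fh, indent=2, default=list)
    return paths
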