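"""End-to-end orchestration: read → cluster → translate → assign → scan → census.

The stages communicate through the modules' FASTA/TSV interfaces so any
stage can be rerun or replaced independently; ``run_all`` chains them and
writes a manifest (seed, parameter hash) so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .census_report import census, render_report
from .contig_assembly import ClusterParams, cluster_transcripts
from .epitope_screen import default_epitope_registry, load_registry
from .phylo_assign import assign_genome
from .sequence_core import read_fasta, segment_domains, write_fasta, SequenceRecord

log = logging.getLogger("gliascan")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    transcripts: str
    references: str
    outdir: str
    registry: Optional[str] = None  # TSV; None = canonical nine cores
    cluster: ClusterParams = field(default_factory=ClusterParams)
    model: str = "K2P"
    gap_mode: str = "pairwise_deletion"
    min_margin: float = 0.01
    include_pseudogenes: bool = False
    restrict_region: bool = False  # census over domains III–V only
    seed: int = 0

    def validate(self) -> None:
        for name in ("transcripts", "references"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name} file not found: {p}")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "cluster"}
        d["cluster"] = self.cluster.__dict__
        return d


def _param_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(cfg: PipelineConfig) -> Path:
    """Run the whole analysis; returns the output directory.

    Outputs: contigs.fasta, proteins.fasta, membership.tsv, assignments.tsv,
    matches.tsv, census.tsv, census.json, manifest.json.  Partial outputs are
    retained on stage failure (the manifest records the last completed stage).
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed, "param_hash": _param_hash(cfg),
                "config": cfg.to_dict(), "stage": "start"}

    def checkpoint(stage: str) -> None:
        manifest["stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        transcripts = read_fasta(cfg.transcripts)
        references = read_fasta(cfg.references)
        ref_labels = _genome_labels(references)
        checkpoint("read")

        result = cluster_transcripts(transcripts, cfg.cluster)
        log.info("clustered %d transcripts into %d contigs (%d minor)",
                 len(transcripts), len(result.contigs), len(result.minor))
        write_fasta(
            [SequenceRecord(id=c.contig_id, seq=c.consensus) for c in result.contigs],
            outdir / "contigs.fasta",
        )
        with open(outdir / "membership.tsv", "w") as fh:
            fh.write("transcript_id\tcontig_id\n")
            for c in result.contigs:
                for m in c.member_ids:
                    fh.write(f"{m}\t{c.contig_id}\n")
            for m in result.minor:
                fh.write(f"{m}\tminor\n")
        checkpoint("cluster")

        prots = [c.deduced_protein for c in result.contigs]
        with open(outdir / "proteins.fasta", "w") as fh:
            for p in prots:
                fh.write(f">{p.id}{' pseudogene' if p.truncated else ''}\n{p.aa}\n")
        checkpoint("translate")

        assignments = [
            assign_genome(c, ref_labels, model=cfg.model, min_margin=cfg.min_margin)
            for c in result.contigs
        ]
        with open(outdir / "assignments.tsv", "w") as fh:
            fh.write("contig_id\tlocus\tmargin\tdepth\tmeans\n")
            for a in assignments:
                means = ";".join(f"{g}={v:.4f}" for g, v in sorted(a.mean_distance_per_genome.items()))
                fh.write(f"{a.contig_id}\t{a.locus}\t{a.margin:.4f}\t{a.depth}\t{means}\n")
        checkpoint("assign")

        registry = load_registry(cfg.registry) if cfg.registry else default_epitope_registry()
        region = None
        if cfg.restrict_region:
            region = {}
            for c in result.contigs:
                seg = segment_domains(c.deduced_protein) if len(c.deduced_protein.aa) >= 20 else None
                iv = seg.intervals.get("NR1") if seg else None
                end = seg.intervals.get("NR2") if seg else None
                if iv and end:
                    region[c.contig_id] = (iv[0], end[1])
        table = census(
            result.contigs, assignments, registry,
            include_pseudogenes=cfg.include_pseudogenes, region=region,
        )
        (outdir / "census.tsv").write_text(render_report(table))
        (outdir / "census.json").write_text(table.to_json())
        checkpoint("done")
    except Exception:
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    return outdir


def _genome_labels(references) -> list:
    """References carry their genome as an id suffix ``id|genome`` or in source."""
    out = []
    for r in references:
        if r.source:
            out.append(r)
        elif "|" in r.id:
            rid, genome = r.id.rsplit("|", 1)
            out.append(SequenceRecord(id=rid, seq=r.seq, source=genome))
        else:
            raise ValueError(
                f"reference {r.id}: no genome label (use 'id|genome' FASTA ids)"
            )
    return out
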