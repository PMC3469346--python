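import pytest

from gliascan.synthetic_data import (
    SyntheticConfig,
    generate_reference_genes,
    sample_transcripts,
)


@pytest.fixture
def make_fasta(tmp_path):
    """Write entries to a FASTA file and return its path."""

    def _write(entries, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in entries:
                fh.write(f">{header}\n{seq}\n")
        return path

    return _write


@pytest.fixture
def clean_family():
    """Small zero-divergence family: truth is exactly the emitted sequences."""
    cfg = SyntheticConfig(
        seed=11,
        within_genome_divergence=0.0,
        between_genome_divergence=0.0,
        genes_per_genome=2,
        pseudogene_rate=0.0,
        depth_range=(4, 6),
    )
    refs, truth = generate_reference_genes(cfg)
    transcripts, truth = sample_transcripts(refs, truth, cfg)
    return cfg, refs, transcripts, truth


@pytest.fixture
def diverged_family():
    """Three genomes at a 3:1 between:within divergence ratio."""
    cfg = SyntheticConfig(
        seed=7,
        within_genome_divergence=0.08,
        between_genome_divergence=0.24,
        genes_per_genome=3,
        pseudogene_rate=0.0,
        depth_range=(4, 20),
    )
    refs, truth = generate_reference_genes(cfg)
    transcripts, truth = sample_transcripts(refs, truth, cfg)
    return cfg, refs, transcripts, truth
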