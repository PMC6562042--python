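from __future__ import annotations

import numpy as np
import pytest

from synmic.curation import TranscriptModel
from synmic.synthetic_data import (
    SyntheticConfig,
    generate_mutations,
    generate_reference_tables,
    generate_transcriptome,
)


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=10,
        n_samples=20,
        load_distribution=(30, 300),
        duplicate_fraction=0.02,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    tx = generate_transcriptome(small_config)
    muts = generate_mutations(small_config, tx)
    refs = generate_reference_tables(small_config, tx, muts)
    return small_config, tx, muts, refs


def make_transcript(
    sequence: str,
    exons,
    strand: str = "+",
    cds_start: int = 0,
    cds_end: int | None = None,
    transcript_id: str = "TX1",
    gene: str = "G1",
    chrom: str = "chr1",
    code_table: str = "standard",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=transcript_id,
        gene=gene,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_start=cds_start,
        cds_end=len(sequence) if cds_end is None else cds_end,
        sequence=sequence,
        code_table=code_table,
    )


@pytest.fixture()
def monoexonic_transcript():
    seq = "ATGAAACCCGGGTTTTAA"  # 18 nt CDS incl. stop
    return make_transcript(seq, [(100, 100 + len(seq))])


@pytest.fixture()
def three_exon_minus_transcript():
    """Minus-strand transcript: genomic exons ascending, transcript order
    reversed.  30-nt CDS spanning all three exons."""
    rng = np.random.default_rng(0)
    seq = "ATG" + "".join(rng.choice(list("ACGT"), size=24)) + "TAA"
    # transcript length 30; exons of 10 each; genomically leftmost = last exon
    return make_transcript(
        seq, [(100, 110), (200, 210), (300, 310)], strand="-"
    )
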