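"""Worked-example sequences.

``KRAS_CDS_75NT`` is the first 75 nucleotides (25 codons) of the human
KRAS-4B coding sequence, the fragment used throughout this package's worked
examples of consequence classification: the recurrent somatic change
c.30 A>C turns codon 10 GGA into GGC (both glycine, synonymous), c.36 T>C
turns codon 12 GGT into GGC (synonymous), while c.35 G>A turns codon 12 into
GAT (aspartate, the classic G12D missense change).
"""

from __future__ import annotations

from .curation import TranscriptModel

__all__ = ["KRAS_CDS_75NT", "kras_cassette_transcript"]

KRAS_CDS_75NT = (
    "ATGACTGAATATAAACTTGTGGTAGTTGGAGCTGGTGGCGTAGGCAAGAGTGCCTTGACGATACAGCTAATTCAG"
)


def kras_cassette_transcript() -> TranscriptModel:
    """The 75-nt KRAS CDS fragment as a monoexonic transcript model.

    The fragment has no stop codon and is used only for codon-level
    consequence classification, so the CDS spans the whole sequence.
    """
    return TranscriptModel(
        transcript_id="KRAS_cassette",
        gene="KRAS",
        chrom="cassette",
        strand="+",
        exons=[(0, len(KRAS_CDS_75NT))],
        cds_start=0,
        cds_end=len(KRAS_CDS_75NT),
        sequence=KRAS_CDS_75NT,
    )
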