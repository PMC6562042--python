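"""Curation of somatic mutation catalogs.

Raw pan-cancer mutation tables aggregate calls from many studies and carry
systematic annotation problems: the same variant in the same patient sample is
listed once per transcript it maps to, mitochondrial variants are sometimes
classified under the standard (nuclear) genetic code, and consequence labels
occasionally disagree with the transcript sequence.  This module re-derives
every consequence from sequence, recomputes mitochondrial consequences under
NCBI translation table 2, collapses per-sample duplicates onto a canonical
transcript, and standardizes tumor annotations into a three-tier
Organ System-Site-Histology label.

Coordinate conventions (used package-wide):

* CDS positions are 1-based (HGVS ``c.`` style).
* Transcript offsets are 0-based.
* Genomic intervals are 0-based half-open (BED convention).
* ``ref``/``alt`` alleles are always stored on the coding (transcript) strand;
  genomic-strand alleles of minus-strand transcripts are reverse-complemented
  on ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "TranscriptModel",
    "CurationError",
    "CoordinateError",
    "classify_consequence",
    "apply_code_table_correction",
    "deduplicate",
    "categorize_tumor",
    "split_tier",
    "curate_table",
    "revcomp",
    "translate_codon",
    "CODE_TABLES",
]

NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: NCBI translation tables used in this pipeline.  "standard" is table 1,
#: "vertebrate_mitochondrial" is table 2 (TGA=Trp, AGA/AGG=stop, ATA=Met).
CODE_TABLES = {
    "standard": CodonTable.unambiguous_dna_by_id[1],
    "vertebrate_mitochondrial": CodonTable.unambiguous_dna_by_id[2],
}


class CurationError(ValueError):
    """A record violates a curation precondition (e.g. reference mismatch)."""


class CoordinateError(ValueError):
    """A position falls outside the coordinate system it claims to use."""


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str, code_table: str = "standard") -> str:
    """Translate a codon to a one-letter amino acid, ``*`` for stop.

    Uses the NCBI translation table named by *code_table* ("standard" or
    "vertebrate_mitochondrial").
    """
    if code_table not in CODE_TABLES:
        raise CurationError(f"unknown code table: {code_table!r}")
    table = CODE_TABLES[code_table]
    codon = codon.upper()
    if codon in table.stop_codons:
        return "*"
    return table.forward_table[codon]


@dataclass
class TranscriptModel:
    """A transcript with exon structure, CDS boundaries and sequence.

    Parameters
    ----------
    transcript_id, gene
        Identifiers.  ``gene`` is the symbol shared by sibling transcripts.
    chrom, strand, exons
        Genomic placement.  ``exons`` are 0-based half-open intervals in
        ascending genomic order regardless of strand.
    cds_start, cds_end
        CDS boundaries as 0-based half-open *transcript* offsets
        (5'→3' in transcript orientation).
    sequence
        Full transcript sequence on the coding strand.
    code_table
        Genetic code used for this transcript ("standard" or
        "vertebrate_mitochondrial").
    """

    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    sequence: str
    code_table: str = "standard"

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise CurationError(f"bad strand {self.strand!r}")
        if self.code_table not in CODE_TABLES:
            raise CurationError(f"unknown code table {self.code_table!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        exon_len = sum(e - s for s, e in self.exons)
        if exon_len != len(self.sequence):
            raise CurationError(
                f"{self.transcript_id}: exon lengths sum to {exon_len}, "
                f"sequence is {len(self.sequence)} nt"
            )
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise CurationError(f"{self.transcript_id}: CDS length not a multiple of 3")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise CurationError(f"{self.transcript_id}: overlapping exons")

    # -- derived geometry -------------------------------------------------

    @property
    def transcript_length(self) -> int:
        return len(self.sequence)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def cds_sequence(self) -> str:
        return self.sequence[self.cds_start : self.cds_end]

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exons_in_transcript_order(self) -> list[tuple[int, int]]:
        """Exon intervals ordered 5'→3' along the transcript."""
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def cds_pos_to_transcript_offset(self, cds_pos: int) -> int:
        """1-based CDS position → 0-based transcript offset."""
        if not 1 <= cds_pos <= self.cds_length:
            raise CoordinateError(
                f"{self.transcript_id}: cds_pos {cds_pos} outside [1, {self.cds_length}]"
            )
        return self.cds_start + cds_pos - 1

    def transcript_offset_to_genomic(self, offset: int) -> int:
        """0-based transcript offset → 0-based genomic position."""
        if not 0 <= offset < self.transcript_length:
            raise CoordinateError(f"{self.transcript_id}: offset {offset} out of range")
        remaining = offset
        for start, end in self.exons_in_transcript_order():
            length = end - start
            if remaining < length:
                if self.strand == "+":
                    return start + remaining
                return end - 1 - remaining
            remaining -= length
        raise AssertionError("unreachable")

    def genomic_to_transcript_offset(self, gpos: int) -> int:
        """0-based genomic position → 0-based transcript offset.

        Raises :class:`CoordinateError` if the position is not exonic.
        """
        walked = 0
        for start, end in self.exons_in_transcript_order():
            if start <= gpos < end:
                if self.strand == "+":
                    return walked + (gpos - start)
                return walked + (end - 1 - gpos)
            walked += end - start
        raise CoordinateError(
            f"{self.transcript_id}: genomic position {gpos} is not exonic"
        )

    def codon_at(self, cds_pos: int) -> tuple[str, int]:
        """Return (codon, 0-based offset of cds_pos within the codon)."""
        off = self.cds_pos_to_transcript_offset(cds_pos)
        within = (cds_pos - 1) % 3
        start = off - within
        return self.sequence[start : start + 3], within


def classify_consequence(
    transcript: TranscriptModel, cds_pos: int, ref: str, alt: str
) -> str:
    """Classify a single-base coding change from sequence.

    Returns one of ``synonymous``, ``missense``, ``nonsense``, ``other``.
    A change is synonymous iff the reference and mutated codons translate to
    the same amino acid under the transcript's genetic code; nonsense iff the
    mutated codon is a stop while the reference codon is not.  Stop-loss
    (reference codon is a stop, mutant is sense) is labeled ``other``;
    stop-retained changes are synonymous.

    Raises
    ------
    CurationError
        If *ref* does not match the transcript sequence at *cds_pos*, or
        ref == alt, or an allele is not a single A/C/G/T base.
    CoordinateError
        If *cds_pos* is outside ``[1, CDS length]``.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in NUCLEOTIDES or alt not in NUCLEOTIDES:
        raise CurationError(f"alleles must be single bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise CurationError(f"ref and alt are identical ({ref})")
    codon, within = transcript.codon_at(cds_pos)
    if codon[within] != ref:
        raise CurationError(
            f"{transcript.transcript_id}: reference mismatch at c.{cds_pos} "
            f"(expected {codon[within]}, record says {ref})"
        )
    mut_codon = codon[:within] + alt + codon[within + 1 :]
    aa_ref = translate_codon(codon, transcript.code_table)
    aa_alt = translate_codon(mut_codon, transcript.code_table)
    if aa_ref == aa_alt:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    if aa_ref == "*":
        return "other"
    return "missense"


def apply_code_table_correction(
    record: dict, transcript: TranscriptModel
) -> tuple[dict, bool]:
    """Recompute a record's consequence under the transcript's genetic code.

    For mitochondrial transcripts the vertebrate mitochondrial table (NCBI
    table 2) differs from the standard code (TGA encodes Trp, ATA encodes
    Met, AGA/AGG are stops), so consequences derived under the standard code
    can be wrong.  Nuclear transcripts are returned unchanged.

    Returns the (possibly updated) record and a flag telling whether the
    consequence class changed.
    """
    new = dict(record)
    correct = classify_consequence(
        transcript, record["cds_pos"], record["ref"], record["alt"]
    )
    changed = correct != record.get("consequence")
    new["consequence"] = correct
    return new, changed


def categorize_tumor(organ_system: str, site: str, histology: str) -> str:
    """Build the three-tier tumor label ``Organ System-Site-Histology``.

    Blank or missing fields map to ``NS`` (not specified), e.g.
    ``("Respiratory System", "Lung", "Adenocarcinoma")`` →
    ``"Respiratory System-Lung-Adenocarcinoma"`` and all-blank input →
    ``"NS-NS-NS"``.
    """

    def norm(x) -> str:
        if x is None or (isinstance(x, float) and math.isnan(x)):
            return "NS"
        x = str(x).strip()
        return x if x else "NS"

    return "-".join(norm(x) for x in (organ_system, site, histology))


def split_tier(label: str) -> tuple[str, str, str]:
    """Inverse of :func:`categorize_tumor` for well-formed labels."""
    parts = label.split("-")
    if len(parts) != 3:
        raise CurationError(f"not a three-tier label: {label!r}")
    return tuple(parts)  # type: ignore[return-value]


VARIANT_KEY = ["chrom", "pos", "ref_genomic", "alt_genomic"]


def _canonical_rank(transcripts: dict[str, TranscriptModel]) -> dict[str, tuple]:
    # longest CDS wins; ties broken lexicographically by transcript_id
    return {
        tid: (-t.cds_length, tid) for tid, t in transcripts.items()
    }


def deduplicate(
    records: pd.DataFrame, transcripts: dict[str, TranscriptModel] | None = None
) -> pd.DataFrame:
    """Collapse duplicate (variant, sample) rows onto one transcript mapping.

    A variant is identified by its genomic locus and genomic-strand alleles;
    the same variant in the same sample mapped to several transcripts of a
    gene is kept once, on the canonical transcript (longest CDS, ties broken
    lexicographically by transcript id).  Idempotent and order-insensitive in
    the set of retained (variant, sample) identities.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    if transcripts:
        rank = _canonical_rank(transcripts)
        order = df["transcript_id"].map(
            lambda t: rank.get(t, (0, t))
        )
    else:
        order = df["transcript_id"]
    df = df.assign(_rank=order)
    df = df.sort_values("_rank", kind="mergesort")
    df = df.drop_duplicates(subset=VARIANT_KEY + ["sample_id"], keep="first")
    return df.drop(columns="_rank").sort_index().reset_index(drop=True)


def curate_table(
    mutations: pd.DataFrame,
    transcripts: dict[str, TranscriptModel],
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the full curation stage on a raw COSMIC-like mutation table.

    Steps, in order: re-derive every SNV consequence from sequence under the
    transcript's genetic code (fixing both misclassified consequences and
    standard-code misuse on mitochondrial transcripts); quarantine records
    whose reference allele does not match the transcript sequence or whose
    transcript is unknown; label non-SNV rows ``other``; remove per-sample
    duplicate variant mappings; standardize tumor tiers.

    Returns ``(curated, rejected, log)`` where *rejected* carries a
    ``reject_reason`` column and *log* is a dict of row-count bookkeeping
    (every input row is accounted for as kept, corrected, or quarantined).
    """
    df = mutations.copy()
    n_in = len(df)
    keep_rows: list[int] = []
    reject_rows: list[tuple[int, str]] = []
    consequences: dict[int, str] = {}
    corrected = 0

    for idx, row in df.iterrows():
        tid = row["transcript_id"]
        tr = transcripts.get(tid)
        if tr is None:
            reject_rows.append((idx, f"unknown transcript {tid}"))
            continue
        ref, alt = str(row["ref"]), str(row["alt"])
        if len(ref) != 1 or len(alt) != 1 or not {ref, alt} <= NUCLEOTIDES:
            # indels / MNVs pass through as "other", excluded from SNV analyses
            keep_rows.append(idx)
            consequences[idx] = "other"
            continue
        try:
            cons = classify_consequence(tr, int(row["cds_pos"]), ref, alt)
        except (CurationError, CoordinateError) as exc:
            reject_rows.append((idx, str(exc)))
            continue
        if cons != row.get("consequence"):
            corrected += 1
        consequences[idx] = cons
        keep_rows.append(idx)

    kept = df.loc[keep_rows].copy()
    kept["consequence"] = [consequences[i] for i in keep_rows]
    if {"organ_system", "site", "histology"} <= set(kept.columns):
        kept["tumor_tier"] = [
            categorize_tumor(r.organ_system, r.site, r.histology)
            for r in kept.itertuples()
        ]
    n_before_dedup = len(kept)
    kept = deduplicate(kept, transcripts)

    rejected = df.loc[[i for i, _ in reject_rows]].copy()
    rejected["reject_reason"] = [r for _, r in reject_rows]

    log = {
        "input_rows": n_in,
        "rejected_rows": len(rejected),
        "consequence_corrected": corrected,
        "duplicates_removed": n_before_dedup - len(kept),
        "curated_rows": len(kept),
    }
    assert log["curated_rows"] + log["rejected_rows"] + log["duplicates_removed"] == n_in
    return kept.reset_index(drop=True), rejected.reset_index(drop=True), log


# -- transcript model I/O (BED12 + FASTA) ---------------------------------


def write_bed12(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcript models as 12-column BED (0-based half-open,
    blockStarts relative to chromStart)."""
    lines = []
    for t in transcripts:
        chrom_start = t.exons[0][0]
        chrom_end = t.exons[-1][1]
        # genomic CDS span from transcript CDS offsets
        g = sorted(
            (
                t.transcript_offset_to_genomic(t.cds_start),
                t.transcript_offset_to_genomic(t.cds_end - 1),
            )
        )
        sizes = ",".join(str(e - s) for s, e in t.exons)
        starts = ",".join(str(s - chrom_start) for s, _ in t.exons)
        lines.append(
            "\t".join(
                str(x)
                for x in (
                    t.chrom,
                    chrom_start,
                    chrom_end,
                    t.transcript_id,
                    0,
                    t.strand,
                    g[0],
                    g[1] + 1,
                    0,
                    t.n_exons,
                    sizes,
                    starts,
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_bed12(
    path: str | Path,
    transcript_sequences: dict[str, str],
    genes: dict[str, str] | None = None,
    code_tables: dict[str, str] | None = None,
) -> dict[str, TranscriptModel]:
    """Read BED12 transcript models, attaching sequences (and optionally gene
    symbols and per-transcript genetic codes) by transcript id."""
    out: dict[str, TranscriptModel] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        seq = transcript_sequences[name]
        tmp = TranscriptModel(
            transcript_id=name,
            gene=(genes or {}).get(name, name),
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=0,
            cds_end=0,
            sequence=seq,
            code_table=(code_tables or {}).get(name, "standard"),
        )
        # thickStart/thickEnd are genomic; convert back to transcript offsets
        a = tmp.genomic_to_transcript_offset(thick_start)
        b = tmp.genomic_to_transcript_offset(thick_end - 1)
        tmp.cds_start, tmp.cds_end = min(a, b), max(a, b) + 1
        if tmp.cds_length % 3 != 0:
            raise CurationError(f"{name}: CDS length not a multiple of 3")
        out[name] = tmp
    return out
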