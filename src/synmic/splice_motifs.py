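"""Exonic splicing enhancer/silencer (ESE/ESS) motif curation and
per-mutation gain/loss scanning.

A motif catalog merges entries (possibly degenerate IUPAC sequences, with
U mapped to T on ingest) from one or more sources; sequences listed under
both ESE and ESS annotations are flagged ``both``.  For each mutation, the
wildtype and mutant local sequence windows (default ±100 nt, truncated at
transcript boundaries) are scanned for every motif, counting occurrences at
every offset (overlapping matches allowed, only occurrences fully contained
in the window).  A nonzero count difference is a motif gain (positive) or
loss (negative).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .curation import TranscriptModel

__all__ = [
    "Motif",
    "MotifCatalog",
    "MotifDiff",
    "curate_catalog",
    "read_catalog_tsv",
    "extract_window",
    "count_occurrences",
    "scan_gain_loss",
    "scan_table",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Motif:
    sequence: str            # DNA alphabet, possibly degenerate IUPAC
    role: str                # "ESE", "ESS" or "both"
    sources: str             # concatenated source annotations


@dataclass
class MotifCatalog:
    motifs: list[Motif]
    source_name: str = ""

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def n_dual_role(self) -> int:
        return sum(m.role == "both" for m in self.motifs)


def _normalize_sequence(seq: str) -> str:
    seq = seq.strip().upper().replace("U", "T")
    if not seq or any(b not in IUPAC for b in seq):
        raise ValueError(f"invalid motif sequence {seq!r}")
    return seq


def curate_catalog(
    entries: Iterable[tuple[str, str, str]], source_name: str = ""
) -> MotifCatalog:
    """Merge raw (sequence, role, annotation) entries into a catalog.

    Duplicate sequences are merged with their annotations concatenated
    (``;``-joined, in first-seen order); a sequence annotated as both ESE and
    ESS gets role ``both``.  U is mapped to T; empty or non-IUPAC sequences
    raise ``ValueError``.
    """
    roles: dict[str, set[str]] = {}
    annos: dict[str, list[str]] = {}
    order: list[str] = []
    for seq, role, anno in entries:
        seq = _normalize_sequence(seq)
        role = role.strip()
        if role not in {"ESE", "ESS"}:
            raise ValueError(f"motif role must be ESE or ESS, got {role!r}")
        if seq not in roles:
            roles[seq] = set()
            annos[seq] = []
            order.append(seq)
        roles[seq].add(role)
        if anno and anno not in annos[seq]:
            annos[seq].append(anno)
    motifs = [
        Motif(
            sequence=s,
            role="both" if roles[s] == {"ESE", "ESS"} else next(iter(roles[s])),
            sources=";".join(annos[s]),
        )
        for s in order
    ]
    return MotifCatalog(motifs, source_name)


def read_catalog_tsv(path, source_name: str = "") -> MotifCatalog:
    """Read a motif catalog from TSV with columns sequence, role, annotation."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return curate_catalog(
        list(df[["sequence", "role", "annotation"]].itertuples(index=False, name=None)),
        source_name,
    )


def extract_window(
    transcript: TranscriptModel, position: int, flank: int
) -> tuple[str, int]:
    """Sequence window of ±*flank* nt around a 0-based transcript offset.

    Truncated at transcript boundaries.  Returns ``(window, offset)`` where
    *offset* is the 0-based position of the focal base within the window.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    if not 0 <= position < transcript.transcript_length:
        raise ValueError(f"position {position} outside transcript")
    start = max(0, position - flank)
    end = min(transcript.transcript_length, position + flank + 1)
    return transcript.sequence[start:end], position - start


def _motif_pattern(sequence: str) -> re.Pattern:
    body = "".join(
        b if len(IUPAC[b]) == 1 else f"[{IUPAC[b]}]" for b in sequence
    )
    return re.compile(f"(?={body})")  # lookahead → overlapping occurrences


def count_occurrences(window: str, motif_sequence: str) -> int:
    """Number of (possibly overlapping) occurrences fully contained in the
    window; degenerate IUPAC positions match their base set."""
    return sum(1 for _ in _motif_pattern(motif_sequence).finditer(window.upper()))


@dataclass(frozen=True)
class MotifDiff:
    motif: str
    role: str
    delta: int  # occurrences in mutant window − occurrences in wildtype window


def scan_gain_loss(
    wt_window: str, mut_window: str, catalog: MotifCatalog
) -> list[MotifDiff]:
    """Per-motif occurrence-count difference between mutant and wildtype
    windows; only nonzero deltas are emitted.

    The windows must be equal-length and differ at exactly one offset.
    """
    if len(wt_window) != len(mut_window):
        raise ValueError("windows differ in length")
    diffs = [i for i, (a, b) in enumerate(zip(wt_window, mut_window)) if a != b]
    if len(diffs) != 1:
        raise ValueError(f"windows differ at {len(diffs)} positions, expected 1")
    out = []
    for m in catalog.motifs:
        delta = count_occurrences(mut_window, m.sequence) - count_occurrences(
            wt_window, m.sequence
        )
        if delta:
            out.append(MotifDiff(m.sequence, m.role, delta))
    return out


def scan_table(
    annotated: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    catalog: MotifCatalog,
    flank: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan every SNV row of an annotated table for motif gains and losses.

    Returns ``(summary, long)``: *summary* has one row per scanned mutation
    with an any-change flag and gain/loss counts; *long* has one row per
    (mutation, motif) with a nonzero delta.
    """
    seen: set[str] = set()
    summary_rows, long_rows = [], []
    for row in annotated.itertuples():
        mid = row.mutation_id
        if mid in seen or row.consequence not in {"synonymous", "missense", "nonsense"}:
            continue
        seen.add(mid)
        tr = transcripts[row.transcript_id]
        offset = tr.cds_pos_to_transcript_offset(int(row.cds_pos))
        wt, o = extract_window(tr, offset, flank)
        mut = wt[:o] + row.alt + wt[o + 1 :]
        diffs = scan_gain_loss(wt, mut, catalog)
        summary_rows.append(
            {
                "mutation_id": mid,
                "any_motif_change": bool(diffs),
                "n_gained": sum(d.delta > 0 for d in diffs),
                "n_lost": sum(d.delta < 0 for d in diffs),
            }
        )
        for d in diffs:
            long_rows.append(
                {"mutation_id": mid, "motif": d.motif, "role": d.role, "delta": d.delta}
            )
    summary = pd.DataFrame(
        summary_rows,
        columns=["mutation_id", "any_motif_change", "n_gained", "n_lost"],
    )
    long = pd.DataFrame(long_rows, columns=["mutation_id", "motif", "role", "delta"])
    return summary, long
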