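"""Per-mutation annotation: recurrence, signature normalization, mutation
load, coding-sequence and exon positional features, alternative-event
overlap, and joins against external reference tables.

The annotated flat table produced by :func:`annotate_table` is the working
container for every downstream analysis (motif scanning, structure ranking,
composite scoring, cohort distributions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .curation import (
    CoordinateError,
    CurationError,
    TranscriptModel,
    VARIANT_KEY,
    revcomp,
    translate_codon,
)

__all__ = [
    "SignatureModel",
    "SUBSTITUTION_CLASSES",
    "substitution_class",
    "signature_normalized_frequency",
    "compute_frequency",
    "mutation_load",
    "cds_position_features",
    "exon_context",
    "alt_event_overlap",
    "external_joins",
    "annotate_table",
]

#: The six strand-symmetric single-base substitution classes, written with a
#: pyrimidine reference base (the standard signature convention): a change and
#: its reverse complement belong to the same class.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_PURINE_TO_PYRIMIDINE = {"G": "C", "A": "T"}


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a single-base change into its strand-symmetric class.

    ``substitution_class("G", "A") == "C>T"`` — reciprocal changes on either
    strand map to one of the six classes in :data:`SUBSTITUTION_CLASSES`.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise ValueError(f"invalid substitution {ref!r}>{alt!r}")
    if ref in _PURINE_TO_PYRIMIDINE:
        ref, alt = revcomp(ref), revcomp(alt)
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SignatureModel:
    """Probabilities of the six strand-symmetric substitution classes.

    Emulates the ubiquitous aging-associated signature (dominant C>T/G>A
    fraction) collapsed from trinucleotide channels to the six classes.
    A 96-channel signature is collapsed with :meth:`from_channels` by summing
    context channels within each class.
    """

    class_probabilities: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(SUBSTITUTION_CLASSES) - set(self.class_probabilities)
        if missing:
            raise ValueError(f"signature missing classes: {sorted(missing)}")
        probs = [self.class_probabilities[c] for c in SUBSTITUTION_CLASSES]
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("class probabilities must be non-negative and sum to 1")

    def p(self, ref: str, alt: str) -> float:
        """Probability of the class containing the change ref>alt."""
        return self.class_probabilities[substitution_class(ref, alt)]

    @classmethod
    def from_channels(cls, channel_probabilities: Mapping[str, float]) -> "SignatureModel":
        """Collapse context-resolved channels (keys like ``A[C>T]G``) by
        summing within each of the six classes."""
        agg = {c: 0.0 for c in SUBSTITUTION_CLASSES}
        for key, p in channel_probabilities.items():
            core = key[key.index("[") + 1 : key.index("]")] if "[" in key else key
            agg[substitution_class(core[0], core[2])] += p
        total = sum(agg.values())
        return cls({c: v / total for c, v in agg.items()})

    @classmethod
    def default(cls) -> "SignatureModel":
        """Six-class signature used as the study condition: C>T/G>A carries
        67% of the mass, T>C/A>G is the second-largest class."""
        return cls(
            {
                "C>A": 0.06,
                "C>G": 0.05,
                "C>T": 0.67,
                "T>A": 0.05,
                "T>C": 0.12,
                "T>G": 0.05,
            }
        )


def signature_normalized_frequency(frequency, p):
    """Down-weight recurrence by mutational bias: ``frequency × (1 − p)``.

    *p* is the signature probability of the mutation's substitution class, so
    changes that are common under the mutational process (e.g. C>T) are
    discounted relative to rare ones.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("signature probability outside [0, 1]")
    return frequency * (1.0 - p_arr)


def compute_frequency(curated: pd.DataFrame) -> pd.DataFrame:
    """Attach per-variant recurrence to a deduplicated table.

    ``frequency`` is the number of distinct samples carrying the identical
    genomic variant across all tumor entities; ``recurrent`` is true iff
    frequency > 1.
    """
    df = curated.copy()
    freq = df.groupby(VARIANT_KEY)["sample_id"].transform("nunique")
    df["frequency"] = freq.astype(int)
    df["recurrent"] = df["frequency"] > 1
    return df


def mutation_load(curated: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample mutation burden and per-mutation carrier-average burden.

    The load of a sample is its total number of curated mutations (all
    consequence classes — the cohort is genome-wide, so totals are
    comparable).  ``avg_mutation_load`` of a variant is the mean load over
    the samples that carry it.
    """
    loads = curated.groupby("sample_id").size().rename("mutation_load")
    df = curated.copy()
    df["_load"] = df["sample_id"].map(loads)
    df["avg_mutation_load"] = df.groupby(VARIANT_KEY)["_load"].transform("mean")
    return loads, df.drop(columns="_load")


def cds_position_features(transcript: TranscriptModel, cds_pos: int) -> dict:
    """Positional features of a CDS coordinate.

    Returns ``cds_fraction`` (position / CDS length, in (0, 1]),
    ``cds_decile`` (= ceil(10 × pos / length), clamped to [1, 10]; boundary
    positions go to the lower-indexed bin), ``codon_index`` (1-based),
    ``amino_acid`` (one-letter, of the reference codon), and, only for CDS
    longer than 600 nt (> 200 codons), ``first200_bin``: the codon's bin of
    20 codons within the first 200 (null beyond codon 200).
    """
    length = transcript.cds_length
    if not 1 <= cds_pos <= length:
        raise CoordinateError(f"cds_pos {cds_pos} outside [1, {length}]")
    decile = min(10, max(1, -(-10 * cds_pos // length)))
    codon_index = -(-cds_pos // 3)
    codon, _ = transcript.codon_at(cds_pos)
    feat = {
        "cds_fraction": cds_pos / length,
        "cds_decile": int(decile),
        "codon_index": int(codon_index),
        "amino_acid": translate_codon(codon, transcript.code_table),
        "first200_bin": None,
    }
    if length > 600 and codon_index <= 200:
        feat["first200_bin"] = int(-(-codon_index // 20))
    return feat


def exon_context(transcript: TranscriptModel, genomic_pos: int) -> dict:
    """Exon-level context of a genomic position on a transcript.

    ``exon_context`` is one of ``first``/``internal``/``last``/``monoexonic``
    in transcription order (strand-aware: on a minus-strand transcript the
    genomically leftmost exon is the *last* exon).  For internal exons,
    ``internal_exon_decile`` bins the position within the exon in 5'→3'
    transcript orientation; ``boundary_distance`` is the distance in
    nucleotides to the nearer end of the containing exon (0 at an edge).
    """
    exons_tx = transcript.exons_in_transcript_order()
    for i, (start, end) in enumerate(exons_tx):
        if start <= genomic_pos < end:
            break
    else:
        raise CoordinateError(
            f"{transcript.transcript_id}: position {genomic_pos} is not exonic"
        )
    n = len(exons_tx)
    if n == 1:
        label = "monoexonic"
    elif i == 0:
        label = "first"
    elif i == n - 1:
        label = "last"
    else:
        label = "internal"
    length = end - start
    if transcript.strand == "+":
        within = genomic_pos - start  # 0-based from the exon's 5' end
    else:
        within = end - 1 - genomic_pos
    decile = None
    if label == "internal":
        decile = int(min(10, max(1, -(-10 * (within + 1) // length))))
    return {
        "exon_context": label,
        "internal_exon_decile": decile,
        "boundary_distance": int(min(within, length - 1 - within)),
    }


def alt_event_overlap(
    chrom: str, pos: int, events: pd.DataFrame
) -> set[str]:
    """Labels of all alternative-event intervals containing a genomic locus.

    *events* is a BED-like frame with columns ``chrom``, ``start``, ``end``
    (0-based half-open) and ``event`` (cassetteExon, retainedIntron,
    altPromoter, ...).  Returns the (possibly empty) set of event labels.
    """
    if events.empty:
        return set()
    hit = (
        (events["chrom"] == chrom)
        & (events["start"] <= pos)
        & (pos < events["end"])
    )
    return set(events.loc[hit, "event"])


def _check_unique(ref: pd.DataFrame, keys: list[str], name: str) -> None:
    dup = ref.duplicated(subset=keys)
    if dup.any():
        bad = ref.loc[dup, keys].iloc[0].tolist()
        raise ValueError(f"duplicate key in {name} reference table: {bad}")


def external_joins(
    table: pd.DataFrame,
    conservation: pd.DataFrame | None = None,
    cancer_genes: Iterable[str] | None = None,
    snps: pd.DataFrame | None = None,
    fathmm: pd.DataFrame | None = None,
    cadd: pd.DataFrame | None = None,
    clinvar: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Left-join external reference annotations onto the mutation table.

    Variant-level tables (*snps*, *fathmm*, *cadd*, *clinvar*) are keyed on
    (chrom, pos, ref_genomic, alt_genomic) — a match requires identical
    genomic position *and* nucleotide change.  *conservation* is keyed on
    (chrom, pos); *cancer_genes* is a gene-symbol list.  Missing joins yield
    nulls (or false flags), never row loss.  ClinVar rows whose phenotype
    list contains "cancer" or "tumor" (case-insensitive) set
    ``clinvar_cancer_related``.
    """
    df = table.copy()
    if conservation is not None:
        _check_unique(conservation, ["chrom", "pos"], "conservation")
        df = df.merge(
            conservation[["chrom", "pos", "phastcons"]], on=["chrom", "pos"], how="left"
        )
    if cancer_genes is not None:
        genes = set(cancer_genes)
        df["cancer_gene"] = df["gene"].isin(genes)
    if snps is not None:
        _check_unique(snps, VARIANT_KEY, "snps")
        s = snps[VARIANT_KEY].copy()
        s["snp_flag"] = True
        df = df.drop(columns=[c for c in ("snp_flag",) if c in df], errors="ignore")
        df = df.merge(s, on=VARIANT_KEY, how="left")
        df["snp_flag"] = df["snp_flag"].eq(True)
    for name, ref in (("fathmm", fathmm), ("cadd_raw", cadd)):
        if ref is None:
            continue
        _check_unique(ref, VARIANT_KEY, name)
        score_col = [c for c in ref.columns if c not in VARIANT_KEY][0]
        df = df.merge(
            ref[VARIANT_KEY + [score_col]].rename(columns={score_col: name}),
            on=VARIANT_KEY,
            how="left",
        )
    if clinvar is not None:
        _check_unique(clinvar, VARIANT_KEY, "clinvar")
        cv = clinvar[VARIANT_KEY + ["phenotype_list"]].rename(
            columns={"phenotype_list": "clinvar_match"}
        )
        df = df.merge(cv, on=VARIANT_KEY, how="left")
        pheno = df["clinvar_match"].fillna("").str.lower()
        df["clinvar_cancer_related"] = pheno.str.contains("cancer") | pheno.str.contains(
            "tumor"
        )
    return df


def annotate_table(
    curated: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    signature: SignatureModel,
    alt_events: pd.DataFrame | None = None,
    **references,
) -> pd.DataFrame:
    """Build the full annotated table from a curated mutation table.

    Adds recurrence, signature-normalized frequency, per-mutation average
    load, substitution class, CDS and exon positional features, alternative
    events, and any external reference joins passed through *references*
    (see :func:`external_joins`).  Positional features are computed for SNV
    rows only; ``other`` rows carry nulls.
    """
    _, df = mutation_load(compute_frequency(curated))
    snv = df["consequence"].isin(["synonymous", "missense", "nonsense"])

    cls, p = [], []
    feats: list[dict] = []
    for row in df.itertuples():
        if not snv.loc[row.Index]:
            cls.append(None)
            p.append(np.nan)
            feats.append({})
            continue
        cls.append(substitution_class(row.ref, row.alt))
        p.append(signature.p(row.ref, row.alt))
        tr = transcripts[row.transcript_id]
        f = cds_position_features(tr, int(row.cds_pos))
        gpos = tr.transcript_offset_to_genomic(
            tr.cds_pos_to_transcript_offset(int(row.cds_pos))
        )
        f.update(exon_context(tr, gpos))
        f["genomic_pos0"] = gpos
        if alt_events is not None:
            f["alt_events"] = ";".join(
                sorted(alt_event_overlap(tr.chrom, gpos, alt_events))
            )
        feats.append(f)

    df["substitution_class"] = cls
    df["signature_p"] = p
    df["signature_normalized_frequency"] = np.where(
        np.isnan(p), np.nan, df["frequency"] * (1.0 - np.asarray(p))
    )
    feat_df = pd.DataFrame(feats, index=df.index)
    df = pd.concat([df, feat_df], axis=1)
    return external_joins(df, **references)
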