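"""Synthetic transcriptomes and COSMIC-like somatic mutation catalogs.

Every downstream stage of the pipeline is exercised against generated data
with *known, injectable* statistical structure:

* toy transcript models (multi-exon, both strands, UTRs, start/stop-bounded
  CDS) laid out on toy contigs, writable as FASTA + BED12;
* a per-sample mutation-load distribution (log-uniform, spanning the orders
  of magnitude seen in genome-wide tumor cohorts);
* a six-class substitution signature driving the choice of nucleotide change
  (dominated by C>T/G>A, as in the ubiquitous aging signature);
* controllable positional depletion — a multiplicative thinning weight for
  the first 10% of the coding sequence and for the outer deciles of internal
  exons — implemented by weighting otherwise-uniform positions, so the
  closed-form expectation of any bin fraction is available for tests;
* heavy-tailed per-site recurrence (Pareto-distributed site rates), so a
  controllable fraction of mutations is recurrent;
* reference tables (conservation, cancer genes, SNPs, FATHMM-MKL-like and
  CADD-like scores, ClinVar-like phenotypes, alternative-event intervals,
  RNA-structure scores) generated as independent uniforms unless a
  correlation knob couples the structure score to mutation load.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import SUBSTITUTION_CLASSES, SignatureModel, substitution_class
from .curation import TranscriptModel, classify_consequence, revcomp, write_bed12

__all__ = [
    "SyntheticConfig",
    "ToyTranscriptome",
    "generate_transcriptome",
    "generate_mutations",
    "generate_reference_tables",
    "generate_structure_scores",
    "write_fasta",
]

_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
]

# toy tumor-entity vocabulary for the three-tier labels
_ENTITIES = [
    ("Respiratory System", "Lung", "Adenocarcinoma"),
    ("Digestive System", "Colon", "Adenocarcinoma"),
    ("Digestive System", "Liver", "Hepatocellular carcinoma"),
    ("Skin", "Skin", "Malignant melanoma"),
    ("Urinary System", "Kidney", "Clear cell carcinoma"),
    ("Reproductive System", "Ovary", "Serous carcinoma"),
    ("Digestive System", "Stomach", "Adenocarcinoma"),
    ("Digestive System", "Pancreas", "Ductal adenocarcinoma"),
]


class ConfigurationError(ValueError):
    """The synthetic configuration is internally inconsistent."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults are the conditions the pipeline is characterized under; see the
    methods note for rationale.  All randomness flows from ``seed`` (each
    generation stage derives its stream from it deterministically), so a
    fixed seed gives byte-identical outputs.
    """

    n_genes: int = 60
    n_samples: int = 60
    cds_length_range: tuple[int, int] = (300, 1500)
    exon_count_range: tuple[int, int] = (1, 8)
    utr5_range: tuple[int, int] = (20, 200)
    utr3_range: tuple[int, int] = (20, 300)
    signature: SignatureModel = field(default_factory=SignatureModel.default)
    depletion_first_decile: float = 1.0
    depletion_exon_edges: float = 1.0
    cancer_gene_fraction: float = 0.1
    snp_fraction: float = 0.08
    load_distribution: tuple[float, float] = (20.0, 200.0)
    recurrence_shape: float | None = 1.5
    n_studies: int = 12
    duplicate_fraction: float = 0.0
    structure_load_correlation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depletion_first_decile", "depletion_exon_edges",
                     "cancer_gene_fraction", "snp_fraction", "duplicate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        lo, hi = self.cds_length_range
        if lo % 3 or hi % 3 or lo < 9 or hi < lo:
            raise ConfigurationError(
                f"cds_length_range {self.cds_length_range} must be multiples of 3, ≥9"
            )
        elo, ehi = self.exon_count_range
        if elo < 1 or ehi < elo:
            raise ConfigurationError(f"bad exon_count_range {self.exon_count_range}")
        # every exon needs at least one base of the shortest possible transcript
        min_tx = lo + self.utr5_range[0] + self.utr3_range[0]
        if ehi > min_tx:
            raise ConfigurationError(
                f"exon count up to {ehi} impossible for transcripts of {min_tx} nt"
            )
        if self.load_distribution[0] < 1 or self.load_distribution[1] < self.load_distribution[0]:
            raise ConfigurationError(f"bad load_distribution {self.load_distribution}")
        if self.recurrence_shape is not None and self.recurrence_shape <= 1.0:
            raise ConfigurationError("recurrence_shape must exceed 1 (finite mean)")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from ``seed``."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stage]))

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["signature"] = dict(self.signature.class_probabilities)
        Path(path).write_text(json.dumps(d, indent=2, default=list) + "\n")


@dataclass
class ToyTranscriptome:
    """Generated transcript models plus the toy contig sequences."""

    transcripts: list[TranscriptModel]
    genome: dict[str, str]

    def by_id(self) -> dict[str, TranscriptModel]:
        return {t.transcript_id: t for t in self.transcripts}

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write contig FASTA, transcript FASTA and BED12 models."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome_fasta": out / "genome.fa",
            "transcripts_fasta": out / "transcripts.fa",
            "bed12": out / "transcripts.bed12",
        }
        write_fasta(self.genome, paths["genome_fasta"])
        write_fasta(
            {t.transcript_id: t.sequence for t in self.transcripts},
            paths["transcripts_fasta"],
        )
        write_bed12(self.transcripts, paths["bed12"])
        return paths


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """ATG + random non-stop codons + one stop codon; no internal stops."""
    n_codons = length // 3
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = _STOPS[rng.integers(len(_STOPS))]
    return "ATG" + "".join(body) + stop


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_transcriptome(config: SyntheticConfig) -> ToyTranscriptome:
    """Generate a toy transcriptome per the configuration.

    One gene per contig; strands alternate deterministically so both are
    always represented.  Exon boundaries are uniform random cut points of the
    transcript; introns are 60–400 nt.
    """
    rng = config.rng(0)
    transcripts: list[TranscriptModel] = []
    genome: dict[str, str] = {}
    lo, hi = config.cds_length_range
    for i in range(config.n_genes):
        cds_len = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        utr5 = int(rng.integers(*config.utr5_range)) if config.utr5_range[1] else 0
        utr3 = int(rng.integers(*config.utr3_range)) if config.utr3_range[1] else 0
        seq = _random_seq(rng, utr5) + _random_cds(rng, cds_len) + _random_seq(rng, utr3)
        tx_len = len(seq)
        n_exons = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
        if n_exons > tx_len:
            raise ConfigurationError(f"{n_exons} exons exceed transcript of {tx_len} nt")
        cuts = np.sort(rng.choice(np.arange(1, tx_len), size=n_exons - 1, replace=False))
        bounds = [0, *cuts.tolist(), tx_len]
        exon_lens = [b - a for a, b in zip(bounds, bounds[1:])]
        strand = "+" if i % 2 == 0 else "-"
        flank = 100
        # lay exons out 5'→3' with random introns, then flip for minus strand
        layout_parts, layout_intervals, cur = [], [], 0
        tx_exons = []
        offset = 0
        for j, el in enumerate(exon_lens):
            layout_parts.append(seq[offset : offset + el])
            layout_intervals.append((cur, cur + el))
            cur += el
            offset += el
            if j < n_exons - 1:
                intron = _random_seq(rng, int(rng.integers(60, 400)))
                layout_parts.append(intron)
                cur += len(intron)
        layout_seq = "".join(layout_parts)
        M = len(layout_seq)
        if strand == "+":
            contig_core = layout_seq
            exons = [(flank + s, flank + e) for s, e in layout_intervals]
        else:
            contig_core = revcomp(layout_seq)
            exons = [(flank + M - e, flank + M - s) for s, e in layout_intervals]
        chrom = f"ctg{i:03d}"
        genome[chrom] = _random_seq(rng, flank) + contig_core + _random_seq(rng, flank)
        transcripts.append(
            TranscriptModel(
                transcript_id=f"TX{i:04d}.1",
                gene=f"GENE{i:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_start=utr5,
                cds_end=utr5 + cds_len,
                sequence=seq,
            )
        )
    return ToyTranscriptome(transcripts, genome)


def _site_table(config: SyntheticConfig, transcriptome: ToyTranscriptome) -> pd.DataFrame:
    """Enumerate every CDS position with its sampling weight and a fixed
    alternate allele.

    The depletion weight of a site is ``depletion_first_decile`` if it lies
    in the first 10% of the CDS, times ``depletion_exon_edges`` if it lies in
    the outer deciles (1 or 10) of an internal exon; otherwise 1.  Sampling
    sites proportional to these weights is equivalent to drawing uniform
    positions and rejection-thinning.  The weight is further multiplied by
    the signature mass compatible with the site's reference base (C/G sites
    carry the C>* classes, A/T sites the T>* classes), and each site gets one
    fixed alternate allele drawn from the compatible classes renormalized —
    so recurrent hits are the identical variant and the marginal class
    frequencies match the signature (up to base-composition noise).
    """
    rng = config.rng(4)
    sig = config.signature.class_probabilities
    mass_c = sig["C>A"] + sig["C>G"] + sig["C>T"]
    mass_t = sig["T>A"] + sig["T>C"] + sig["T>G"]

    frames = []
    for t in transcriptome.transcripts:
        L = t.cds_length
        pos = np.arange(1, L + 1)
        off = t.cds_start + pos - 1
        seq_arr = np.frombuffer(t.sequence.encode(), dtype="S1").astype("U1")
        refs = seq_arr[off]
        # genomic coordinate of every transcript offset, transcript order
        segs = []
        for s, e in t.exons_in_transcript_order():
            segs.append(np.arange(s, e) if t.strand == "+" else np.arange(e - 1, s - 1, -1))
        tx2g = np.concatenate(segs)
        w = np.ones(L)
        w[10 * pos <= L] *= config.depletion_first_decile
        exon_lens = np.array([e - s for s, e in t.exons_in_transcript_order()])
        bounds = np.concatenate([[0], np.cumsum(exon_lens)])
        ei = np.searchsorted(bounds, off, side="right") - 1
        within = off - bounds[ei]
        decile = np.minimum(10, np.maximum(1, -(-10 * (within + 1) // exon_lens[ei])))
        edge = (ei > 0) & (ei < len(exon_lens) - 1) & np.isin(decile, (1, 10))
        w[edge] *= config.depletion_exon_edges
        frames.append(
            pd.DataFrame(
                {
                    "transcript_id": t.transcript_id,
                    "cds_pos": pos,
                    "ref": refs,
                    "gpos0": tx2g[off],
                    "depletion_weight": w,
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)

    ref = sites["ref"].to_numpy()
    is_cg = np.isin(ref, ("C", "G"))
    weight = sites["depletion_weight"].to_numpy() * np.where(is_cg, mass_c, mass_t)

    # fixed per-site alternate allele from the compatible classes
    alt = np.empty(len(sites), dtype="U1")
    for base, classes, m in (
        ("C", ("C>A", "C>G", "C>T"), mass_c),
        ("G", ("C>A", "C>G", "C>T"), mass_c),
        ("T", ("T>A", "T>C", "T>G"), mass_t),
        ("A", ("T>A", "T>C", "T>G"), mass_t),
    ):
        idx = np.flatnonzero(ref == base)
        if not len(idx):
            continue
        probs = np.array([sig[c] for c in classes])
        probs = probs / probs.sum() if m > 0 else np.full(3, 1 / 3)
        pick = rng.choice(3, size=len(idx), p=probs)
        targets = np.array([c[2] for c in classes], dtype="U1")
        chosen = targets[pick]
        if base in ("G", "A"):  # purine reference: complement the target base
            chosen = np.array([revcomp(b) for b in chosen], dtype="U1")
        alt[idx] = chosen
    sites["alt"] = alt
    sites["weight"] = weight
    return sites


def generate_mutations(
    config: SyntheticConfig, transcriptome: ToyTranscriptome
) -> pd.DataFrame:
    """Generate a COSMIC-like somatic SNV table.

    Per-sample totals are log-uniform over ``load_distribution``; sites are
    drawn with probability proportional to (depletion weight × compatible
    signature mass × Pareto site rate), the Pareto mixture (tail index
    ``recurrence_shape``) producing heavy-tailed recurrence; each site
    carries one fixed alternate allele drawn from the signature, so
    recurrent hits are the identical variant.  Within-sample repeats of a
    site are dropped.
    """
    rng = config.rng(1)
    sites = _site_table(config, transcriptome)
    tmap = transcriptome.by_id()
    n_sites = len(sites)

    rates = sites["weight"].to_numpy(float).copy()
    if config.recurrence_shape is not None:
        rates *= 1.0 + rng.pareto(config.recurrence_shape, size=n_sites)
    if rates.sum() <= 0:
        raise ConfigurationError("all site weights are zero")
    p_sites = rates / rates.sum()

    lo, hi = config.load_distribution
    loads = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_samples))
    loads = np.maximum(1, np.round(loads)).astype(int)

    site_snp = rng.random(n_sites) < config.snp_fraction
    study_of_sample = rng.integers(0, config.n_studies, size=config.n_samples)
    entity_of_study = [
        _ENTITIES[int(k)] for k in rng.integers(0, len(_ENTITIES), size=config.n_studies)
    ]

    # per-site constant columns (consequence from the fixed alternate allele)
    site_cons = np.empty(n_sites, dtype=object)
    tx_ids = sites["transcript_id"].to_numpy()
    cds_pos_arr = sites["cds_pos"].to_numpy()
    ref_arr = sites["ref"].to_numpy()
    alt_arr = sites["alt"].to_numpy()
    for k in range(n_sites):
        site_cons[k] = classify_consequence(
            tmap[tx_ids[k]], int(cds_pos_arr[k]), ref_arr[k], alt_arr[k]
        )
    minus = np.array([tmap[t].strand == "-" for t in tx_ids])
    refg = np.where(minus, [revcomp(b) for b in ref_arr], ref_arr)
    altg = np.where(minus, [revcomp(b) for b in alt_arr], alt_arr)

    all_events = rng.choice(n_sites, size=int(loads.sum()), p=p_sites)
    slices = np.concatenate([[0], np.cumsum(loads)])
    chosen_parts, sample_parts = [], []
    for s_idx in range(config.n_samples):
        chunk = pd.unique(all_events[slices[s_idx] : slices[s_idx + 1]])
        chosen_parts.append(chunk)
        sample_parts.append(np.full(len(chunk), s_idx))
    site_idx = np.concatenate(chosen_parts)
    samp_idx = np.concatenate(sample_parts)

    tiers = np.array(entity_of_study, dtype=object)[study_of_sample[samp_idx]]
    tr_of = np.array([tmap[t].strand for t in tx_ids])
    chrom_of = np.array([tmap[t].chrom for t in tx_ids])
    gene_of = np.array([tmap[t].gene for t in tx_ids])

    df = pd.DataFrame(
        {
            "gene": gene_of[site_idx],
            "transcript_id": tx_ids[site_idx],
            "sample_id": [f"SAMP{i:04d}" for i in samp_idx],
            "study_id": [f"STUDY{k:02d}" for k in study_of_sample[samp_idx]],
            "chrom": chrom_of[site_idx],
            "pos": sites["gpos0"].to_numpy()[site_idx] + 1,  # 1-based, COSMIC style
            "strand": tr_of[site_idx],
            "cds_pos": cds_pos_arr[site_idx],
            "ref": ref_arr[site_idx],
            "alt": alt_arr[site_idx],
            "ref_genomic": refg[site_idx],
            "alt_genomic": altg[site_idx],
            "consequence": site_cons[site_idx],
            "organ_system": tiers[:, 0],
            "site": tiers[:, 1],
            "histology": tiers[:, 2],
            "snp_flag": site_snp[site_idx],
        }
    )
    df["cds_change"] = (
        "c." + df["cds_pos"].astype(str) + df["ref"] + ">" + df["alt"]
    )
    if config.duplicate_fraction > 0 and len(df):
        n_dup = int(round(config.duplicate_fraction * len(df)))
        dup = df.iloc[rng.choice(len(df), size=n_dup, replace=False)]
        df = pd.concat([df, dup], ignore_index=True)
    df.insert(0, "mutation_id", _mutation_ids(df))
    return df


def _mutation_ids(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(str)
        + ":"
        + df["ref_genomic"]
        + ">"
        + df["alt_genomic"]
    )


def generate_reference_tables(
    config: SyntheticConfig,
    transcriptome: ToyTranscriptome,
    mutations: pd.DataFrame,
) -> dict[str, pd.DataFrame | list[str]]:
    """Generate the external reference tables for the annotation joins.

    Conservation, FATHMM-MKL-like and CADD-like scores are independent
    uniforms per locus/variant; the cancer-gene list and SNP list sample the
    configured fractions; a small ClinVar-like table covers a subset of
    variants with phenotype strings, some cancer/tumor-related;
    alternative-event intervals are random sub-intervals of exons with
    cassette exons the most common type.
    """
    rng = config.rng(2)
    variants = mutations.drop_duplicates(
        subset=["chrom", "pos", "ref_genomic", "alt_genomic"]
    )[["chrom", "pos", "ref_genomic", "alt_genomic"]].reset_index(drop=True)
    loci = variants[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)

    conservation = loci.copy()  # keyed on (chrom, pos), 1-based like the table
    conservation["phastcons"] = rng.random(len(conservation))

    genes = sorted({t.gene for t in transcriptome.transcripts})
    n_cg = int(round(config.cancer_gene_fraction * len(genes)))
    cancer_genes = sorted(rng.choice(genes, size=n_cg, replace=False).tolist())

    snps = variants.iloc[
        np.flatnonzero(rng.random(len(variants)) < config.snp_fraction)
    ].reset_index(drop=True)

    fathmm = variants.copy()
    fathmm["fathmm_score"] = rng.random(len(variants))
    cadd = variants.copy()
    cadd["cadd_raw"] = rng.normal(0.0, 1.0, size=len(variants))

    n_cv = max(1, len(variants) // 20)
    cv = variants.iloc[
        rng.choice(len(variants), size=min(n_cv, len(variants)), replace=False)
    ].copy()
    phenos = np.where(
        rng.random(len(cv)) < 0.3,
        "Hereditary cancer-predisposing syndrome",
        "Cardiomyopathy, familial",
    )
    cv["phenotype_list"] = phenos

    event_types = np.array(
        ["cassetteExon"] * 6
        + ["retainedIntron", "altPromoter", "altFinish", "bleedingExon",
           "altThreePrime", "altFivePrime", "atacIntron", "strangeSplice"]
    )
    ev_rows = []
    for t in transcriptome.transcripts:
        for s, e in t.exons:
            if rng.random() < 0.3:
                a = int(rng.integers(s, e))
                b = int(rng.integers(a + 1, e + 1))
                ev_rows.append(
                    (t.chrom, a, b, str(event_types[rng.integers(len(event_types))]))
                )
    alt_events = pd.DataFrame(ev_rows, columns=["chrom", "start", "end", "event"])

    return {
        "conservation": conservation.rename(columns={"pos": "pos"}),
        "cancer_genes": cancer_genes,
        "snps": snps,
        "fathmm": fathmm,
        "cadd": cadd,
        "clinvar": cv.reset_index(drop=True),
        "alt_events": alt_events,
    }


def generate_structure_scores(
    config: SyntheticConfig,
    mutations: pd.DataFrame,
    context: int = 200,
    avg_loads: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Null-model RNA-structure scores in the two ingestible tool dialects.

    Scores are i.i.d. (entropy ~ exponential, p-values ~ uniform) unless
    ``structure_load_correlation`` is nonzero, in which case the remuRNA-like
    relative entropy is shifted by that coefficient times the z-scored log
    average load of the variant (negative values couple high structural
    impact to low-burden samples).
    """
    rng = config.rng(3)
    ids = pd.unique(mutations["mutation_id"])
    n = len(ids)
    entropy = rng.exponential(1.0, size=n)
    if config.structure_load_correlation and avg_loads is not None:
        z = np.log(avg_loads.reindex(ids).to_numpy(float))
        z = (z - np.nanmean(z)) / (np.nanstd(z) or 1.0)
        entropy = entropy + config.structure_load_correlation * z
    mfe_wt = rng.normal(-60.0, 10.0, size=n)
    remurna = pd.DataFrame(
        {
            "mutation_id": ids,
            "context": context,
            "relative_entropy": entropy,
            "mfe_wt": mfe_wt,
            "mfe_mut": mfe_wt + rng.normal(0.0, 1.5, size=n),
            "gc_content": rng.uniform(0.3, 0.7, size=n),
        }
    )
    d_max = rng.exponential(0.1, size=n)
    start = rng.integers(0, 2 * context - 50, size=n)
    rnasnp = pd.DataFrame(
        {
            "mutation_id": ids,
            "context": context,
            "d_max": d_max,
            "p_value": rng.uniform(0.0, 1.0, size=n),
            "interval_start": start,
            "interval_end": start + rng.integers(50, 120, size=n),
        }
    )
    return remurna, rnasnp
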