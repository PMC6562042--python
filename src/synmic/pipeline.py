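"""End-to-end orchestration: simulate → curate → annotate → motifs →
structure → score → distributions, with one config, uniform logging and a
final database-style flat table export.

Everything is plain TSV/JSON on disk; the run log records the serialized
config, the seed and per-stage row counts, so a run is reproducible from the
log alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import SignatureModel, annotate_table
from .curation import curate_table
from .distributions import (
    metric_by_bin,
    per_study_stratification,
    positional_distribution,
)
from .scoring import score_table, write_threshold_summary
from .splice_motifs import MotifCatalog, curate_catalog, read_catalog_tsv, scan_table
from .structure_rank import export_windows, ingest_scores, write_windows_fasta
from .synthetic_data import (
    SyntheticConfig,
    generate_mutations,
    generate_reference_tables,
    generate_structure_scores,
    generate_transcriptome,
)

__all__ = ["PipelineConfig", "run_pipeline", "export_database_table", "DEFAULT_MOTIFS"]

logger = logging.getLogger("synmic")

# a small built-in ESE/ESS catalog (classic SR-protein and hnRNP-associated
# hexamer-class motifs) so the pipeline runs without external files
DEFAULT_MOTIFS = [
    ("GAAGAA", "ESE", "SRSF1-like"),
    ("GAAGGA", "ESE", "SRSF1-like"),
    ("TGAAGA", "ESE", "SRSF5-like"),
    ("GGAGGA", "ESE", "SRp-like"),
    ("AAGAAG", "ESE", "SR-rich"),
    ("GAAGAT", "ESE", "SR-like"),
    ("CTCTTC", "ESS", "hnRNP-like"),
    ("TAGGGT", "ESS", "hnRNPA1-like"),
    ("TTCTCC", "ESS", "silencer-class"),
    ("GGGTGG", "ESS", "G-run"),
    ("GGGGGG", "ESS", "G-run"),
    ("TAGACT", "ESS", "silencer-class"),
    ("GAAGAA", "ESS", "dual-annotated"),  # dual-role example
]


@dataclass
class PipelineConfig:
    """Run configuration; fully serialized into the run log."""

    out_dir: str = "synmic_run"
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    motif_catalog_path: str | None = None
    flank_motifs: int = 100
    flank_structure: int = 200
    percentile_levels: tuple[float, ...] = (50, 10, 1, 0.1, 0.01)
    stages: tuple[str, ...] = (
        "simulate",
        "curate",
        "annotate",
        "motifs",
        "structure",
        "score",
        "distributions",
    )
    log_level: str = "INFO"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["synthetic"]["signature"] = dict(
            self.synthetic.signature.class_probabilities
        )
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        syn = d.pop("synthetic", {})
        sig = syn.pop("signature", None)
        for k in ("cds_length_range", "exon_count_range", "utr5_range",
                  "utr3_range", "load_distribution"):
            if k in syn:
                syn[k] = tuple(syn[k])
        syn_cfg = SyntheticConfig(
            **syn, signature=SignatureModel(sig) if sig else SignatureModel.default()
        )
        for k in ("percentile_levels", "stages"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(synthetic=syn_cfg, **d)


DATABASE_COLUMNS = {
    "mutation_id": "genomic variant identifier chrom:pos:ref>alt",
    "gene": "gene symbol",
    "transcript_id": "canonical transcript the variant is reported on",
    "cds_change": "HGVS-like c. notation on the coding strand",
    "consequence": "synonymous/missense/nonsense/other, derived from sequence",
    "tumor_tier": "Organ System-Site-Histology three-tier label",
    "frequency": "number of distinct carrier samples (recurrence)",
    "recurrent": "frequency > 1",
    "signature_normalized_frequency": "frequency × (1 − signature probability)",
    "avg_mutation_load": "mean total mutation count of carrier samples",
    "substitution_class": "one of the six strand-symmetric change classes",
    "cds_decile": "position decile along the coding sequence (1–10, 5'→3')",
    "exon_context": "first/internal/last/monoexonic",
    "internal_exon_decile": "decile within internal exon, transcript orientation",
    "boundary_distance": "nt to the nearest end of the containing exon",
    "alt_events": "overlapping alternative-event labels (';'-joined)",
    "phastcons": "per-nucleotide conservation probability [0,1]",
    "cancer_gene": "gene is in the supplied cancer-gene list",
    "snp_flag": "variant matches a known SNP",
    "fathmm": "FATHMM-MKL-like score [0,1]",
    "cadd_qrank": "cohort quantile rank of the CADD-like score",
    "structure_qrank": "cohort quantile rank of the structure-impact score",
    "any_motif_change": "mutation gains or loses ≥1 ESE/ESS motif",
    "synmicdb_score": "the composite prioritization score",
    "score_percentile": "cohort quantile rank of the score",
}


def export_database_table(scored: pd.DataFrame, out_dir: Path) -> Path:
    """Write the database-style flat table (synonymous rows, one per
    mutation occurrence) plus a machine-readable column dictionary."""
    syn = scored[scored["consequence"] == "synonymous"].copy()
    cols = [c for c in DATABASE_COLUMNS if c in syn.columns]
    extra = [c for c in syn.columns if c.startswith("loo_")]
    path = out_dir / "database_table.tsv"
    syn[cols + extra].to_csv(path, sep="\t", index=False)
    (out_dir / "database_columns.json").write_text(
        json.dumps({c: DATABASE_COLUMNS[c] for c in cols}, indent=2) + "\n"
    )
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages in dependency order.

    Returns the run directory.  Any stage failure raises with the stage
    named; outputs of completed stages are retained.  Row counts of every
    stage are logged to ``run.log`` alongside the full configuration.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level)
    logger.info("synmic %s", __version__)
    logger.info("config:\n%s", config.to_json())
    (out / "config.json").write_text(config.to_json() + "\n")

    state: dict = {}
    try:
        for stage in config.stages:
            logger.info("stage %s: start", stage)
            _STAGES[stage](config, out, state)
            logger.info("stage %s: done", stage)
    except Exception:
        logger.exception("pipeline aborted")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> None:
    tx = generate_transcriptome(config.synthetic)
    tx.write(out)
    muts = generate_mutations(config.synthetic, tx)
    muts.to_csv(out / "mutations_raw.tsv", sep="\t", index=False)
    refs = generate_reference_tables(config.synthetic, tx, muts)
    state.update(transcriptome=tx, mutations_raw=muts, references=refs)
    logger.info("simulated %d transcripts, %d mutation rows", len(tx.transcripts), len(muts))


def _stage_curate(config: PipelineConfig, out: Path, state: dict) -> None:
    tmap = state["transcriptome"].by_id()
    curated, rejected, log = curate_table(state["mutations_raw"], tmap)
    curated.to_csv(out / "mutations_curated.tsv", sep="\t", index=False)
    rejected.to_csv(out / "mutations_rejected.tsv", sep="\t", index=False)
    state["curated"] = curated
    logger.info("curation: %s", log)


def _stage_annotate(config: PipelineConfig, out: Path, state: dict) -> None:
    tmap = state["transcriptome"].by_id()
    refs = state["references"]
    ann = annotate_table(
        state["curated"],
        tmap,
        config.synthetic.signature,
        alt_events=refs["alt_events"],
        conservation=refs["conservation"],
        cancer_genes=refs["cancer_genes"],
        snps=refs["snps"],
        fathmm=refs["fathmm"],
        cadd=refs["cadd"],
        clinvar=refs["clinvar"],
    )
    ann.to_csv(out / "mutations_annotated.tsv", sep="\t", index=False)
    state["annotated"] = ann
    logger.info("annotated %d rows", len(ann))


def _stage_motifs(config: PipelineConfig, out: Path, state: dict) -> None:
    if config.motif_catalog_path:
        catalog = read_catalog_tsv(config.motif_catalog_path)
    else:
        catalog = curate_catalog(DEFAULT_MOTIFS, "builtin")
    tmap = state["transcriptome"].by_id()
    summary, long = scan_table(
        state["annotated"], tmap, catalog, flank=config.flank_motifs
    )
    summary.to_csv(out / "motif_summary.tsv", sep="\t", index=False)
    long.to_csv(out / "motif_diffs.tsv", sep="\t", index=False)
    ann = state["annotated"].merge(summary, on="mutation_id", how="left")
    ann["any_motif_change"] = ann["any_motif_change"].eq(True)
    state["annotated"] = ann
    logger.info(
        "motif scan: %d mutations, %.1f%% with ≥1 motif change",
        len(summary),
        100 * summary["any_motif_change"].mean() if len(summary) else 0.0,
    )


def _stage_structure(config: PipelineConfig, out: Path, state: dict) -> None:
    tmap = state["transcriptome"].by_id()
    windows = export_windows(state["annotated"], tmap, flank=config.flank_structure)
    write_windows_fasta(windows, out / "structure_windows.fa")
    loads = (
        state["annotated"]
        .drop_duplicates("mutation_id")
        .set_index("mutation_id")["avg_mutation_load"]
    )
    remurna, rnasnp = generate_structure_scores(
        config.synthetic,
        state["annotated"],
        context=config.flank_structure,
        avg_loads=loads,
    )
    scores = ingest_scores(remurna, rnasnp)
    scores.to_csv(out / "structure_scores.tsv", sep="\t", index=False)
    ann = state["annotated"].merge(
        scores.drop(columns=["context"]), on="mutation_id", how="left"
    )
    state["annotated"] = ann
    state["windows"] = windows
    logger.info("structure: %d windows (%d truncated), %d score rows",
                len(windows), int(windows["truncated"].sum()), len(scores))


def _stage_score(config: PipelineConfig, out: Path, state: dict) -> None:
    scored = score_table(state["annotated"])
    scored.to_csv(out / "mutations_scored.tsv", sep="\t", index=False)
    syn_scores = scored.loc[
        scored["consequence"] == "synonymous", "synmicdb_score"
    ]
    write_threshold_summary(syn_scores, out / "score_thresholds.json")
    state["scored"] = scored
    export_database_table(scored, out)
    logger.info("scored %d rows", len(scored))


def _stage_distributions(config: PipelineConfig, out: Path, state: dict) -> None:
    scored = state["scored"]
    syn = scored[scored["consequence"] == "synonymous"]
    frames = []
    for by in ("cds", "internal_exon"):
        for dist in positional_distribution(syn, by=by, stratify_by="substitution_class"):
            f = dist.to_frame()
            f.insert(0, "analysis", by)
            frames.append(f)
        f = positional_distribution(syn, by=by)[0].to_frame()
        f.insert(0, "analysis", by)
        f["stratum"] = "all"
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(
        out / "positional_distributions.tsv", sep="\t", index=False
    )
    metric_by_bin(syn, "synmicdb_score", by="cds").to_csv(
        out / "score_by_cds_bin.tsv", sep="\t", index=False
    )
    strat = per_study_stratification(scored, metric="synmicdb_score")
    (out / "per_study_selection.json").write_text(
        json.dumps(
            {
                "selected_studies": strat["selected_studies"],
                "syn_counts": strat["syn_counts"],
                "sample_counts": strat["sample_counts"],
            },
            indent=2,
        )
        + "\n"
    )
    logger.info("distributions written")


_STAGES = {
    "simulate": _stage_simulate,
    "curate": _stage_curate,
    "annotate": _stage_annotate,
    "motifs": _stage_motifs,
    "structure": _stage_structure,
    "score": _stage_score,
    "distributions": _stage_distributions,
}
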