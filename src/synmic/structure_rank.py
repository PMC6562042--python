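"""RNA-structure score export, ingestion and ranking analyses.

Folding itself is out of process: this module writes per-mutation sequence
windows for external structure-aberration tools (remuRNA-style relative
entropy, RNAsnp-style base-pair-probability distance with a GC/length
normalized empirical p-value), ingests their tabular outputs under a strict
TSV contract, and runs the ranking analyses — cohort-wide quantile ranks,
Spearman correlations between metrics, per-decile top-percentile fractions,
per-decile window GC/MFE summaries, and score-vs-mutation-load comparisons.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curation import TranscriptModel

__all__ = [
    "export_windows",
    "write_windows_fasta",
    "ingest_scores",
    "quantile_rank",
    "rank_correlation",
    "top_percentile_by_bin",
    "window_summaries",
    "score_by_load_bins",
    "gc_content",
]

REMURNA_COLUMNS = {
    "mutation_id",
    "context",
    "relative_entropy",
    "mfe_wt",
    "mfe_mut",
    "gc_content",
}
RNASNP_COLUMNS = {
    "mutation_id",
    "context",
    "d_max",
    "p_value",
    "interval_start",
    "interval_end",
}


def export_windows(
    annotated: pd.DataFrame,
    transcripts: Mapping[str, TranscriptModel],
    flank: int = 200,
) -> pd.DataFrame:
    """One sequence window per unique mutation, for external folding tools.

    The window spans ±*flank* nt around the mutated base on the transcript,
    truncated at transcript boundaries; windows shorter than ``2×flank+1``
    are flagged ``truncated`` so length-sensitive analyses can drop them.
    Columns: mutation_id, window, offset (0-based within window), ref, alt,
    truncated.
    """
    rows, seen = [], set()
    for row in annotated.itertuples():
        mid = row.mutation_id
        if mid in seen or row.consequence not in {
            "synonymous",
            "missense",
            "nonsense",
        }:
            continue
        seen.add(mid)
        tr = transcripts[row.transcript_id]
        pos = tr.cds_pos_to_transcript_offset(int(row.cds_pos))
        start = max(0, pos - flank)
        end = min(tr.transcript_length, pos + flank + 1)
        window = tr.sequence[start:end]
        offset = pos - start
        if window[offset] != row.ref:
            raise ValueError(
                f"{mid}: window base {window[offset]} does not match ref {row.ref}"
            )
        rows.append(
            {
                "mutation_id": mid,
                "window": window,
                "offset": offset,
                "ref": row.ref,
                "alt": row.alt,
                "truncated": len(window) < 2 * flank + 1,
            }
        )
    return pd.DataFrame(
        rows, columns=["mutation_id", "window", "offset", "ref", "alt", "truncated"]
    )


def write_windows_fasta(windows: pd.DataFrame, path) -> None:
    """Write windows as FASTA with variant-tagged headers
    ``>mutation_id|offset|ref>alt``."""
    with open(path, "w") as fh:
        for r in windows.itertuples():
            fh.write(f">{r.mutation_id}|{r.offset}|{r.ref}>{r.alt}\n{r.window}\n")


def _validate_tool_table(
    df: pd.DataFrame, required: set[str], name: str
) -> pd.DataFrame:
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["mutation_id", "context"])
    if dup.any():
        raise ValueError(
            f"duplicate mutation_id in {name} table: "
            f"{df.loc[dup, 'mutation_id'].iloc[0]}"
        )
    return df


def ingest_scores(
    remurna: pd.DataFrame | None = None, rnasnp: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Join tool outputs into one structure-score table.

    One row per (mutation_id, context length); a mutation present in only one
    tool's output keeps its row with nulls for the other tool's columns.
    Duplicate (mutation_id, context) keys in either input are an error.
    """
    if remurna is None and rnasnp is None:
        raise ValueError("at least one tool table is required")
    parts = []
    if remurna is not None:
        parts.append(_validate_tool_table(remurna, REMURNA_COLUMNS, "remuRNA"))
    if rnasnp is not None:
        parts.append(_validate_tool_table(rnasnp, RNASNP_COLUMNS, "RNAsnp"))
    if len(parts) == 1:
        return parts[0].copy()
    return parts[0].merge(parts[1], on=["mutation_id", "context"], how="outer")


def quantile_rank(values) -> np.ndarray:
    """Empirical quantile rank in (0, 1]: ``rank_i = #{values ≤ value_i}/n``
    with tied values sharing the mean of their positional ranks.

    A unique maximum gets rank 1.0 (tied maxima share the averaged rank);
    nulls are passed through as nulls and excluded from *n*.  All-null input
    is an error.
    """
    arr = np.asarray(values, dtype=float)
    finite = np.isfinite(arr)
    n = int(finite.sum())
    if n == 0:
        raise ValueError("quantile_rank needs at least one finite value")
    out = np.full(arr.shape, np.nan)
    out[finite] = stats.rankdata(arr[finite], method="average") / n
    return out


def rank_correlation(score_a, score_b) -> float:
    """Spearman rank correlation over pairwise-complete observations."""
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("rank_correlation needs at least 3 complete pairs")
    rho, _ = stats.spearmanr(a[ok], b[ok])
    return float(rho)


def top_percentile_by_bin(
    scores, bins, percentile: float = 5.0
) -> pd.DataFrame:
    """Per-bin fraction of mutations in the cohort-wide top score percentile.

    The top set is the ``round(percentile/100 × n)`` highest scores (ties
    broken deterministically by position).  For each bin the fraction is
    (top-set members in bin) / (bin size); empty bins yield a null fraction.
    Bin-count-weighted fractions average to |top set|/n, i.e. percentile/100
    up to the integer rounding of the top-set size.
    """
    s = np.asarray(scores, dtype=float)
    b = np.asarray(bins)
    if len(s) != len(b):
        raise ValueError("scores and bins must align")
    ok = np.isfinite(s)
    k = int(round(percentile / 100.0 * ok.sum()))
    top = np.zeros(len(s), dtype=bool)
    if k > 0:
        order = np.argsort(-np.where(ok, s, -np.inf), kind="stable")
        top[order[:k]] = True
    rows = []
    for label in sorted(pd.unique(b[ok])):
        in_bin = ok & (b == label)
        n_bin = int(in_bin.sum())
        rows.append(
            {
                "bin": label,
                "n": n_bin,
                "n_top": int((top & in_bin).sum()),
                "fraction": (top & in_bin).sum() / n_bin if n_bin else np.nan,
            }
        )
    return pd.DataFrame(rows)


def gc_content(seq: str) -> float:
    """Fraction of G/C bases in a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def window_summaries(
    windows: pd.DataFrame,
    deciles,
    mfe: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Per-CDS-decile mean GC content of the windows (and mean ingested MFE
    when supplied), with standard errors."""
    gc = windows["window"].map(gc_content).to_numpy(float)
    d = np.asarray(deciles)
    df = pd.DataFrame({"decile": d, "gc": gc})
    if mfe is not None:
        df["mfe"] = np.asarray(mfe, dtype=float)
    out = []
    for label, grp in df.groupby("decile"):
        row = {"decile": label, "n": len(grp), "gc_mean": grp["gc"].mean(),
               "gc_sem": stats.sem(grp["gc"]) if len(grp) > 1 else np.nan}
        if "mfe" in grp:
            row["mfe_mean"] = grp["mfe"].mean()
            row["mfe_sem"] = stats.sem(grp["mfe"]) if len(grp) > 1 else np.nan
        out.append(row)
    return pd.DataFrame(out)


def score_by_load_bins(
    scores, loads, bin_edges: Sequence[float]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Structure score binned by average mutation load.

    Returns ``(bins, tests)``: per-bin mean/SEM of the score, and Welch
    two-sample t-tests between adjacent bins (skipped and flagged when a bin
    has fewer than two values).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    s = np.asarray(scores, dtype=float)
    l = np.asarray(loads, dtype=float)
    ok = np.isfinite(s) & np.isfinite(l)
    idx = np.digitize(l[ok], edges)  # 1..len(edges)-1 inside range
    groups = {}
    rows = []
    for b in range(1, len(edges)):
        vals = s[ok][idx == b]
        groups[b] = vals
        rows.append(
            {
                "bin": b,
                "lo": edges[b - 1],
                "hi": edges[b],
                "n": len(vals),
                "mean": vals.mean() if len(vals) else np.nan,
                "sem": stats.sem(vals) if len(vals) > 1 else np.nan,
            }
        )
    tests = []
    for b in range(1, len(edges) - 1):
        a, c = groups[b], groups[b + 1]
        if len(a) < 2 or len(c) < 2:
            tests.append({"bin_a": b, "bin_b": b + 1, "t": np.nan, "p": np.nan,
                          "skipped": True})
            continue
        t, p = stats.ttest_ind(a, c, equal_var=False)
        tests.append({"bin_a": b, "bin_b": b + 1, "t": float(t), "p": float(p),
                      "skipped": False})
    return pd.DataFrame(rows), pd.DataFrame(tests)
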