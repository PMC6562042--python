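"""The composite prioritization score for synonymous mutations.

Nine parameters enter the score: recurrence (frequency) corrected for
mutational bias by the signature factor (1 − p), the average mutation load of
the carrier samples (low burden up-weights), cancer-gene membership,
per-nucleotide conservation, absence from known SNPs, a FATHMM-MKL score, and
cohort-wide quantile ranks of the CADD score and of the RNA-structure impact
score:

    S = (log2(f) + 1) · (1 − p) − log10(L)
        + g + c + s + m + qC + qR

with f ≥ 1 the sample frequency, p ∈ [0, 1] the signature probability of the
substitution class, L ≥ 1 the average mutation load, g ∈ {0, 2} the
cancer-gene term, c ∈ [0, 1] conservation, s ∈ {0, 1} the SNP term (1 when
the variant is *not* a known SNP), m ∈ [0, 1] FATHMM-MKL, and qC, qR ∈ [0, 1]
the CADD and structure quantile ranks.  Higher scores indicate a higher
likelihood of functional impact.

A leave-one-out variant of the score removes one parameter at a time
(the (1 − p) multiplier is replaced by 1 when the signature correction is
left out; the whole frequency term, or the −log10 L term, or an additive
term is dropped otherwise), which quantifies how much each parameter shapes
the top of the ranking.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .structure_rank import quantile_rank

__all__ = [
    "ScoreComponents",
    "ScoreResult",
    "synmicdb_score",
    "leave_one_out",
    "LOO_PARAMETERS",
    "top_decile_retention",
    "percentile_thresholds",
    "score_table",
]

#: The nine leave-one-out parameters (frequency and its signature correction
#: count separately).
LOO_PARAMETERS = (
    "frequency",
    "signature",
    "mutation_load",
    "cancer_gene",
    "conservation",
    "snp",
    "fathmm",
    "cadd",
    "structure",
)


@dataclass(frozen=True)
class ScoreComponents:
    """The nine inputs of the composite score (see module docstring)."""

    frequency: float          # f ≥ 1, distinct carrier samples
    signature_p: float        # p ∈ [0, 1]
    avg_mutation_load: float  # L ≥ 1
    cgc_score: float = 0.0    # g, 2 for Cancer Gene Census genes else 0
    phastcons: float = 0.0    # c ∈ [0, 1]
    snp_score: float = 1.0    # s, 1 when NOT a known SNP
    fathmm: float = 0.0       # m ∈ [0, 1]
    cadd_qrank: float = 0.0   # qC ∈ [0, 1]
    structure_qrank: float = 0.0  # qR ∈ [0, 1]

    def __post_init__(self) -> None:
        if self.frequency < 1:
            raise ValueError(f"frequency must be ≥ 1, got {self.frequency}")
        if self.avg_mutation_load < 1:
            raise ValueError(f"avg_mutation_load must be ≥ 1, got {self.avg_mutation_load}")
        for name, lo, hi in (
            ("signature_p", 0, 1),
            ("phastcons", 0, 1),
            ("snp_score", 0, 1),
            ("fathmm", 0, 1),
            ("cadd_qrank", 0, 1),
            ("structure_qrank", 0, 1),
            ("cgc_score", 0, 2),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")


def synmicdb_score(comp: ScoreComponents) -> float:
    """Evaluate the composite score for one mutation."""
    return (
        (math.log2(comp.frequency) + 1.0) * (1.0 - comp.signature_p)
        - math.log10(comp.avg_mutation_load)
        + comp.cgc_score
        + comp.phastcons
        + comp.snp_score
        + comp.fathmm
        + comp.cadd_qrank
        + comp.structure_qrank
    )


def leave_one_out(comp: ScoreComponents) -> dict[str, float]:
    """Score with each of the nine parameters removed in turn.

    Removing ``frequency`` drops the whole (log2 f + 1)(1 − p) term; removing
    ``signature`` replaces the (1 − p) multiplier by 1; removing
    ``mutation_load`` drops the −log10 L term; removing an additive parameter
    drops its term.
    """
    freq_term = (math.log2(comp.frequency) + 1.0) * (1.0 - comp.signature_p)
    full = synmicdb_score(comp)
    return {
        "frequency": full - freq_term,
        "signature": full - freq_term + (math.log2(comp.frequency) + 1.0),
        "mutation_load": full + math.log10(comp.avg_mutation_load),
        "cancer_gene": full - comp.cgc_score,
        "conservation": full - comp.phastcons,
        "snp": full - comp.snp_score,
        "fathmm": full - comp.fathmm,
        "cadd": full - comp.cadd_qrank,
        "structure": full - comp.structure_qrank,
    }


@dataclass
class ScoreResult:
    score: float
    components: ScoreComponents
    loo_scores: dict[str, float] = field(default_factory=dict)
    percentile: float | None = None


def top_decile_retention(full_scores, loo_scores) -> float:
    """Fraction of the full-score top 10% retained in the leave-one-out
    top 10% (rank sets of equal size, ties broken by position)."""
    a = np.asarray(full_scores, dtype=float)
    b = np.asarray(loo_scores, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must align")
    n = len(a)
    k = max(1, int(round(0.1 * n)))
    top_a = set(np.argsort(-a, kind="stable")[:k].tolist())
    top_b = set(np.argsort(-b, kind="stable")[:k].tolist())
    return len(top_a & top_b) / k


def percentile_thresholds(
    scores, levels: Sequence[float] = (50, 10, 1, 0.1, 0.01)
) -> dict[float, float]:
    """Empirical score thresholds for the top *levels* percent of the cohort.

    ``thresholds[10]`` is the score quantile above which the top 10% of
    mutations lie; thresholds are non-decreasing as the level shrinks.
    """
    arr = np.asarray(scores, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("percentile_thresholds needs at least one score")
    return {
        float(lv): float(np.quantile(arr, 1.0 - lv / 100.0)) for lv in levels
    }


_IMPUTED_ZERO = ("phastcons", "fathmm", "cadd_qrank", "structure_qrank")


def score_table(
    annotated: pd.DataFrame,
    structure_score_col: str = "relative_entropy",
    cgc_value: float = 2.0,
) -> pd.DataFrame:
    """Score every row of an annotated synonymous-mutation table.

    Quantile ranks for CADD and the structure score are computed cohort-wide
    first; missing conservation, FATHMM, CADD or structure values impute to 0
    (absence of evidence contributes nothing) and are flagged in
    ``imputed_components``.  Adds the score, the nine leave-one-out score
    columns (``loo_<parameter>``) and the cohort percentile of the score.
    Rows without the mandatory components (non-SNV rows such as indels or
    stop-loss variants carry no substitution class, hence no signature
    probability) pass through with null scores.
    """
    df = annotated.copy()
    if "cadd_raw" in df and df["cadd_raw"].notna().any():
        df["cadd_qrank"] = quantile_rank(df["cadd_raw"])
    else:
        df["cadd_qrank"] = np.nan
    if structure_score_col in df and df[structure_score_col].notna().any():
        df["structure_qrank"] = quantile_rank(df[structure_score_col])
    else:
        df["structure_qrank"] = np.nan

    scores, loos, flags = [], [], []
    for row in df.itertuples():
        p = float(getattr(row, "signature_p", np.nan))
        if not (math.isfinite(p) and math.isfinite(float(row.frequency))):
            scores.append(np.nan)
            loos.append({name: np.nan for name in LOO_PARAMETERS})
            flags.append("unscored")
            continue
        imputed = []
        vals = {}
        for name, col in (
            ("phastcons", "phastcons"),
            ("fathmm", "fathmm"),
            ("cadd_qrank", "cadd_qrank"),
            ("structure_qrank", "structure_qrank"),
        ):
            v = getattr(row, col, np.nan)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                vals[name] = 0.0
                imputed.append(name)
            else:
                vals[name] = float(v)
        comp = ScoreComponents(
            frequency=float(row.frequency),
            signature_p=float(row.signature_p),
            avg_mutation_load=max(1.0, float(row.avg_mutation_load)),
            cgc_score=cgc_value if bool(getattr(row, "cancer_gene", False)) else 0.0,
            snp_score=0.0 if bool(getattr(row, "snp_flag", False)) else 1.0,
            **vals,
        )
        scores.append(synmicdb_score(comp))
        loos.append(leave_one_out(comp))
        flags.append(";".join(imputed))
    df["synmicdb_score"] = scores
    df["imputed_components"] = flags
    loo_df = pd.DataFrame(loos, index=df.index).add_prefix("loo_")
    df = pd.concat([df, loo_df], axis=1)
    df["score_percentile"] = quantile_rank(df["synmicdb_score"])
    return df


def write_threshold_summary(scores, path: str | Path) -> dict[float, float]:
    th = percentile_thresholds(scores)
    Path(path).write_text(
        json.dumps({f"top_{k}pct": v for k, v in th.items()}, indent=2) + "\n"
    )
    return th
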