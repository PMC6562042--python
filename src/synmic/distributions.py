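"""Cohort-level distribution statistics.

Positional decile distributions (along the coding sequence, along internal
exons, and within the first 200 codons of long CDS), optionally stratified by
substitution class or study; per-bin means of any numeric metric with SEM and
bin-vs-rest t-tests; observed and expected amino-acid distributions of the
mutated codons; group comparisons with an F-test-guided choice of pooled vs
Welch t-test; and per-study stratification over the largest studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import SUBSTITUTION_CLASSES, SignatureModel, substitution_class
from .curation import TranscriptModel, translate_codon

__all__ = [
    "BinnedDistribution",
    "positional_distribution",
    "metric_by_bin",
    "amino_acid_distribution",
    "expected_aa_distribution",
    "codon_usage_from_transcripts",
    "group_compare",
    "per_study_stratification",
    "CODONS_PER_AA",
]

_BIN_COLUMN = {
    "cds": "cds_decile",
    "internal_exon": "internal_exon_decile",
    "first_200_codons": "first200_bin",
}

#: Number of sense codons per amino acid under the standard genetic code.
CODONS_PER_AA: dict[str, int] = {}
for _a in "ACGT":
    for _b in "ACGT":
        for _c in "ACGT":
            _aa = translate_codon(_a + _b + _c)
            if _aa != "*":
                CODONS_PER_AA[_aa] = CODONS_PER_AA.get(_aa, 0) + 1


@dataclass
class BinnedDistribution:
    """Counts and fractions over the 10 positional bins, per stratum."""

    bin_labels: list[int]
    counts: np.ndarray
    fractions: np.ndarray
    stratum: str | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stratum": self.stratum,
                "bin": self.bin_labels,
                "count": self.counts,
                "fraction": self.fractions,
            }
        )


def _one_distribution(bins: pd.Series, stratum: str | None) -> BinnedDistribution:
    labels = list(range(1, 11))
    counts = bins.value_counts().reindex(labels, fill_value=0).to_numpy()
    total = counts.sum()
    return BinnedDistribution(
        labels, counts, counts / total if total else counts * np.nan, stratum
    )


def positional_distribution(
    annotated: pd.DataFrame,
    by: str = "cds",
    stratify_by: str | None = None,
) -> list[BinnedDistribution]:
    """Decile distributions of mutation positions.

    *by* selects the coordinate system: ``cds`` (deciles of the coding
    sequence), ``internal_exon`` (deciles of internal exons only), or
    ``first_200_codons`` (bins of 20 codons, restricted to CDS > 200 codons).
    With *stratify_by* (e.g. ``substitution_class`` or ``study_id``) one
    distribution per stratum is returned; empty strata are omitted.
    """
    col = _BIN_COLUMN[by]
    df = annotated.dropna(subset=[col])
    bins = df[col].astype(int)
    if stratify_by is None:
        return [_one_distribution(bins, None)]
    out = []
    for label, grp in df.groupby(stratify_by, observed=True):
        if len(grp):
            out.append(_one_distribution(grp[col].astype(int), str(label)))
    return out


def metric_by_bin(
    annotated: pd.DataFrame, metric: str, by: str = "cds"
) -> pd.DataFrame:
    """Per-decile mean of a numeric column with SEM, difference from the
    grand average, and a two-sample t-test of each bin against the rest."""
    col = _BIN_COLUMN[by]
    df = annotated.dropna(subset=[col, metric])
    vals = df[metric].astype(float)
    grand = vals.mean()
    rows = []
    for b in range(1, 11):
        in_bin = df[col].astype(int) == b
        x = vals[in_bin]
        rest = vals[~in_bin]
        t = p = np.nan
        if len(x) >= 2 and len(rest) >= 2:
            t, p = group_compare(x, rest)[:2]
        rows.append(
            {
                "bin": b,
                "n": int(len(x)),
                "mean": x.mean() if len(x) else np.nan,
                "sem": stats.sem(x) if len(x) > 1 else np.nan,
                "diff_from_average": (x.mean() - grand) if len(x) else np.nan,
                "t": t,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def amino_acid_distribution(
    annotated: pd.DataFrame, consequence: str = "synonymous"
) -> pd.Series:
    """Observed per-amino-acid mutation share, degeneracy-corrected.

    Raw counts of mutations whose reference codon encodes each amino acid are
    divided by the number of codons for that amino acid under the standard
    genetic code (so six-codon Leu is not trivially over-represented), then
    renormalized to sum to 1.  Stop codons are excluded.
    """
    df = annotated[annotated["consequence"] == consequence]
    counts = df["amino_acid"].value_counts()
    counts = counts[counts.index != "*"]
    corrected = counts / counts.index.map(CODONS_PER_AA)
    out = corrected / corrected.sum()
    return out.reindex(sorted(CODONS_PER_AA), fill_value=0.0)


def codon_usage_from_transcripts(
    transcripts: Mapping[str, TranscriptModel] | Sequence[TranscriptModel],
) -> pd.Series:
    """Relative frequency of each sense codon over the CDS set."""
    if isinstance(transcripts, Mapping):
        transcripts = list(transcripts.values())
    counts: dict[str, int] = {}
    for t in transcripts:
        cds = t.cds_sequence
        for i in range(0, len(cds) - 2, 3):
            codon = cds[i : i + 3]
            if translate_codon(codon, t.code_table) != "*":
                counts[codon] = counts.get(codon, 0) + 1
    s = pd.Series(counts, dtype=float)
    return s / s.sum()


def expected_aa_distribution(
    codon_usage: pd.Series, signature: SignatureModel
) -> pd.Series:
    """Expected per-amino-acid share of synonymous mutations.

    For each sense codon, its nine single-base substitutions are enumerated;
    the signature probabilities of the synonymous ones are summed to give the
    codon's synonymous-change likelihood, which is multiplied by the codon's
    usage frequency, aggregated to the amino-acid level, and normalized to 1.
    Amino acids with no synonymous single-base route (Trp, Met) get share 0.
    """
    missing = [c for c in codon_usage.index if translate_codon(c) == "*"]
    if missing:
        raise ValueError(f"codon usage contains stop codons: {missing}")
    if len(codon_usage) != len(CODONS_PER_AA) and len(codon_usage) != 61:
        missing_codons = (
            {c for c in _all_sense_codons()} - set(codon_usage.index)
        )
        if missing_codons:
            raise ValueError(f"codon usage missing codons: {sorted(missing_codons)[:5]}...")
    expected: dict[str, float] = {aa: 0.0 for aa in CODONS_PER_AA}
    for codon, usage in codon_usage.items():
        aa = translate_codon(codon)
        syn_mass = 0.0
        for i in range(3):
            for alt in "ACGT":
                if alt == codon[i]:
                    continue
                mut = codon[:i] + alt + codon[i + 1 :]
                if translate_codon(mut) == aa:
                    syn_mass += signature.p(codon[i], alt)
        expected[aa] += usage * syn_mass
    s = pd.Series(expected)
    return s / s.sum()


def _all_sense_codons():
    return (
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if translate_codon(a + b + c) != "*"
    )


def group_compare(values_a, values_b) -> tuple[float, float, float]:
    """Two-sided two-sample t-test with F-test-guided variance handling.

    An F-test of variance equality at α = 0.05 selects the pooled (Student)
    t-test when variances are compatible and Welch's otherwise.  Returns
    ``(t, p, relative_difference)`` with the relative difference in percent,
    ``100 × (mean_a − mean_b) / mean_b``.  Two zero-variance groups with
    equal means return p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    rel = 100.0 * (a.mean() - b.mean()) / b.mean() if b.mean() != 0 else np.inf
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, rel
        return np.inf, 0.0, rel
    if va == 0 or vb == 0:
        equal_var = False
    else:
        f = va / vb
        dfa, dfb = len(a) - 1, len(b) - 1
        p_f = 2 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
        equal_var = p_f >= 0.05
    with warnings.catch_warnings():
        # a zero-variance group is a legitimate degenerate input here; scipy
        # warns about precision loss on near-identical data
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), rel


def per_study_stratification(
    annotated: pd.DataFrame, metric: str | None = None
) -> dict:
    """Distributions for the largest studies.

    Selects the union of the five studies with the most synonymous mutations
    and the five with the most distinct samples (all studies when fewer than
    ten exist).  Returns the selection plus, per selected study, the CDS and
    internal-exon positional distributions (and per-bin means of *metric*
    when given).
    """
    syn = annotated[annotated["consequence"] == "synonymous"]
    by_mut = syn.groupby("study_id").size().sort_values(ascending=False)
    by_samples = (
        annotated.groupby("study_id")["sample_id"].nunique().sort_values(ascending=False)
    )
    all_studies = sorted(set(annotated["study_id"]))
    if len(all_studies) < 10:
        selected = all_studies
    else:
        selected = sorted(set(by_mut.index[:5]) | set(by_samples.index[:5]))
    out = {
        "selected_studies": selected,
        "syn_counts": by_mut.to_dict(),
        "sample_counts": by_samples.to_dict(),
        "per_study": {},
    }
    for study in selected:
        sub = syn[syn["study_id"] == study]
        entry = {
            "cds": positional_distribution(sub, by="cds"),
            "internal_exon": positional_distribution(sub, by="internal_exon"),
        }
        if metric is not None and metric in sub:
            entry["metric_by_bin"] = metric_by_bin(sub, metric, by="cds")
        out["per_study"][study] = entry
    return out
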