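"""Cohort distribution statistics: positional bins, amino-acid observed vs
expected, group comparisons, per-study stratification."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from synmic.annotation import SignatureModel
from synmic.distributions import (
    CODONS_PER_AA,
    amino_acid_distribution,
    codon_usage_from_transcripts,
    expected_aa_distribution,
    group_compare,
    metric_by_bin,
    per_study_stratification,
    positional_distribution,
)
from synmic.synthetic_data import (
    SyntheticConfig,
    generate_mutations,
    generate_transcriptome,
)

from oracles import oracle_translate, sense_codons


def _frame(deciles, **extra):
    df = pd.DataFrame({"cds_decile": deciles})
    df["internal_exon_decile"] = np.nan
    for k, v in extra.items():
        df[k] = v
    return df


class TestPositionalDistribution:
    def test_point_mass_in_bin_one(self):
        dists = positional_distribution(_frame(np.ones(50, dtype=int)))
        (d,) = dists
        assert d.fractions[0] == 1.0
        assert d.counts.sum() == 50

    def test_uniform_positions_give_about_ten_percent(self):
        rng = np.random.default_rng(1)
        (d,) = positional_distribution(_frame(rng.integers(1, 11, size=50_000)))
        assert np.allclose(d.fractions, 0.1, atol=0.01)
        assert d.fractions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_stratified_counts_recombine_to_unstratified(self):
        rng = np.random.default_rng(2)
        df = _frame(
            rng.integers(1, 11, size=5000),
            substitution_class=rng.choice(["C>T", "T>A", "C>G"], size=5000),
        )
        total = positional_distribution(df)[0].counts
        parts = positional_distribution(df, stratify_by="substitution_class")
        assert np.array_equal(sum(p.counts for p in parts), total)


class TestMetricByBin:
    def test_constant_metric_all_bins_equal(self):
        rng = np.random.default_rng(3)
        df = _frame(rng.integers(1, 11, size=500), score=1.7)
        out = metric_by_bin(df, "score")
        assert np.allclose(out["mean"], 1.7)
        assert np.allclose(out["diff_from_average"], 0.0)

    def test_monotone_fixture_gives_increasing_means(self):
        deciles = np.repeat(np.arange(1, 11), 20)
        df = _frame(deciles, score=deciles.astype(float))
        out = metric_by_bin(df, "score")
        assert np.all(np.diff(out["mean"]) > 0)

    def test_sem_agrees_with_bootstrap_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(3.0, 2.0, size=4000)
        df = _frame(np.ones(4000, dtype=int), score=vals)
        out = metric_by_bin(df, "score")
        sem = out.loc[out["bin"] == 1, "sem"].iloc[0]
        boot = np.std(
            [rng.choice(vals, size=len(vals)).mean() for _ in range(500)], ddof=1
        )
        assert abs(sem - boot) / boot < 0.10


class TestAminoAcidDistribution:
    def test_single_amino_acid_point_mass(self):
        df = pd.DataFrame({"consequence": ["synonymous"] * 5, "amino_acid": ["M"] * 5})
        out = amino_acid_distribution(df)
        assert out["M"] == 1.0

    def test_degeneracy_correction_leu_vs_met(self):
        df = pd.DataFrame(
            {
                "consequence": ["synonymous"] * 12,
                "amino_acid": ["L"] * 6 + ["M"] * 6,
            }
        )
        out = amino_acid_distribution(df)
        # equal raw counts: Met (1 codon) outweighs Leu (6 codons) 6:1
        assert out["M"] / out["L"] == pytest.approx(6.0)
        assert out.sum() == pytest.approx(1.0)


class TestExpectedAminoAcids:
    @staticmethod
    def _oracle(usage: pd.Series, signature: SignatureModel) -> pd.Series:
        """Independent brute force: explicit loop over 61 codons × 9 changes
        using the textbook codon table."""
        agg: dict[str, float] = {}
        for codon in sense_codons():
            aa = oracle_translate(codon)
            mass = 0.0
            for i in range(3):
                for alt in "ACGT":
                    if alt == codon[i]:
                        continue
                    mut = codon[:i] + alt + codon[i + 1 :]
                    if oracle_translate(mut) == aa:
                        mass += signature.class_probabilities[
                            _cls(codon[i], alt)
                        ]
            agg[aa] = agg.get(aa, 0.0) + usage[codon] * mass
        s = pd.Series(agg)
        return (s / s.sum()).sort_index()

    def test_matches_bruteforce_to_1e12(self):
        rng = np.random.default_rng(7)
        usage = pd.Series(rng.random(61), index=sense_codons())
        usage /= usage.sum()
        sig = SignatureModel.default()
        got = expected_aa_distribution(usage, sig).sort_index()
        want = self._oracle(usage, sig).reindex(got.index, fill_value=0.0)
        assert np.allclose(got, want, atol=1e-12)

    def test_tryptophan_expected_share_is_zero(self):
        usage = pd.Series(1 / 61, index=sense_codons())
        out = expected_aa_distribution(usage, SignatureModel.default())
        assert out["W"] == 0.0
        assert out["M"] == 0.0  # ATG likewise has no synonymous route
        assert out.sum() == pytest.approx(1.0)

    def test_uniform_usage_uniform_signature_proportional_to_routes(self):
        usage = pd.Series(1 / 61, index=sense_codons())
        sig = SignatureModel({c: 1 / 6 for c in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")})
        out = expected_aa_distribution(usage, sig)
        routes: dict[str, int] = {}
        for codon in sense_codons():
            aa = oracle_translate(codon)
            for i in range(3):
                for alt in "ACGT":
                    if alt != codon[i] and oracle_translate(
                        codon[:i] + alt + codon[i + 1 :]
                    ) == aa:
                        routes[aa] = routes.get(aa, 0) + 1
        want = pd.Series(routes, dtype=float)
        want = (want / want.sum()).reindex(out.index, fill_value=0.0)
        assert np.allclose(out, want, atol=1e-12)

    def test_usage_missing_codons_rejected(self):
        usage = pd.Series(1 / 10, index=sense_codons()[:10])
        with pytest.raises(ValueError):
            expected_aa_distribution(usage, SignatureModel.default())

    def test_codon_usage_from_transcripts_sums_to_one(self, small_cohort):
        _, tx, _, _ = small_cohort
        usage = codon_usage_from_transcripts(tx.transcripts)
        assert usage.sum() == pytest.approx(1.0)
        assert all(oracle_translate(c) != "*" for c in usage.index)


def _cls(ref, alt):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if ref in "AG":
        ref, alt = comp[ref], comp[alt]
    return f"{ref}>{alt}"


class TestGroupCompare:
    def test_identical_groups(self):
        t, p, rel = group_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rel == 0.0
        assert p == pytest.approx(1.0)

    def test_relative_difference_of_doubled_mean(self):
        _, _, rel = group_compare([2.0, 2.0], [1.0, 1.0])
        assert rel == pytest.approx(100.0)

    def test_textbook_three_vs_three_fixture(self):
        # a=[1,2,3], b=[2,4,6]: F=0.25 (p=0.4 ⇒ pooled); t = −2/√(5/3)
        t, p, rel = group_compare([1, 2, 3], [2, 4, 6])
        assert t == pytest.approx(-1.5491933384829668)
        assert p == pytest.approx(0.1963, abs=1e-4)
        assert rel == pytest.approx(-50.0)

    def test_null_pvalues_are_uniform(self):
        """KS test on 1,000 simulated null comparisons at alpha=0.01."""
        rng = np.random.default_rng(41)
        ps = [
            group_compare(rng.normal(size=10), rng.normal(size=10))[1]
            for _ in range(1000)
        ]
        _, p_ks = stats.kstest(ps, "uniform")
        assert p_ks > 0.01

    def test_zero_variance_conventions(self):
        t, p, _ = group_compare([1.0, 1.0], [1.0, 1.0])
        assert p == 1.0
        t2, p2, _ = group_compare([1.0, 1.0], [2.0, 2.0])
        assert p2 == 0.0


class TestPerStudyStratification:
    @staticmethod
    def _cohort(n_studies, seed=51):
        cfg = SyntheticConfig(
            n_genes=8, n_samples=40, load_distribution=(20, 200),
            n_studies=n_studies, seed=seed,
        )
        tx = generate_transcriptome(cfg)
        muts = generate_mutations(cfg, tx)
        muts["cds_decile"] = 1  # positional features not needed here
        muts["internal_exon_decile"] = np.nan
        return muts

    def test_fewer_than_ten_studies_selects_all(self):
        muts = self._cohort(3)
        out = per_study_stratification(muts)
        assert set(out["selected_studies"]) == set(muts["study_id"])

    def test_ranking_agrees_with_sort_oracle_and_union_bounded(self):
        muts = self._cohort(14)
        out = per_study_stratification(muts)
        syn = muts[muts["consequence"] == "synonymous"]
        top_mut = sorted(
            syn["study_id"].value_counts().items(), key=lambda kv: -kv[1]
        )[:5]
        for study, _ in top_mut:
            assert study in out["selected_studies"]
        assert len(out["selected_studies"]) <= 10
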