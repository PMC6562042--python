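"""Recurrence, signature normalization, load, positional features, events
and external joins."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from synmic.annotation import (
    SUBSTITUTION_CLASSES,
    SignatureModel,
    alt_event_overlap,
    annotate_table,
    cds_position_features,
    compute_frequency,
    exon_context,
    external_joins,
    mutation_load,
    signature_normalized_frequency,
    substitution_class,
)
from synmic.curation import CoordinateError, curate_table, revcomp
from synmic.examples import kras_cassette_transcript

from conftest import make_transcript


class TestSubstitutionClass:
    def test_twelve_changes_collapse_to_exactly_six_classes(self):
        classes = {
            substitution_class(r, a)
            for r, a in itertools.permutations("ACGT", 2)
        }
        assert classes == set(SUBSTITUTION_CLASSES)
        assert len(classes) == 6

    def test_reverse_complement_invariance_all_cases(self):
        for r, a in itertools.permutations("ACGT", 2):
            assert substitution_class(r, a) == substitution_class(revcomp(r), revcomp(a))

    def test_g_to_a_equals_c_to_t(self):
        assert substitution_class("G", "A") == "C>T"

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            substitution_class("N", "A")


class TestSignatureNormalizedFrequency:
    def test_direct_formula(self):
        assert signature_normalized_frequency(10, 0.3) == pytest.approx(7.0)

    def test_limits(self):
        assert signature_normalized_frequency(5, 0.0) == 5
        assert signature_normalized_frequency(123, 1.0) == 0

    def test_p_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            signature_normalized_frequency(1, 1.5)

    def test_never_exceeds_frequency(self):
        rng = np.random.default_rng(0)
        f = rng.integers(1, 100, size=50)
        p = rng.random(50)
        assert np.all(signature_normalized_frequency(f, p) <= f)


def _table(rows):
    cols = ["chrom", "pos", "ref_genomic", "alt_genomic", "sample_id"]
    return pd.DataFrame(rows, columns=cols)


class TestFrequencyAndLoad:
    def test_shared_and_private_variants(self):
        df = _table(
            [("c", 1, "A", "G", s) for s in ("S1", "S2", "S3")]
            + [("c", 9, "C", "T", "S1")]
        )
        out = compute_frequency(df)
        assert set(out.loc[out["pos"] == 1, "frequency"]) == {3}
        assert set(out.loc[out["pos"] == 9, "frequency"]) == {1}
        assert out.loc[out["pos"] == 1, "recurrent"].all()
        assert not out.loc[out["pos"] == 9, "recurrent"].any()

    def test_per_sample_load_and_carrier_average(self):
        rows = [("c", i, "A", "G", "S1") for i in range(100)]
        rows += [("c", i, "A", "G", "S2") for i in range(300)]
        df = _table(rows)
        loads, out = mutation_load(df)
        assert loads["S1"] == 100 and loads["S2"] == 300
        shared = out[(out["pos"] < 100)]
        assert shared["avg_mutation_load"].unique().tolist() == [200.0]

    def test_load_invariant_under_row_permutation(self):
        df = _table([("c", i % 7, "A", "G", f"S{i % 3}") for i in range(40)])
        l1, _ = mutation_load(df)
        l2, _ = mutation_load(df.sample(frac=1, random_state=5))
        assert l1.sort_index().equals(l2.sort_index())


class TestCdsPositionFeatures:
    def test_boundaries_of_300nt_cds(self):
        tr = make_transcript("ATG" + "GCT" * 98 + "TAA", [(0, 300)])
        f1 = cds_position_features(tr, 1)
        assert (f1["cds_decile"], f1["codon_index"]) == (1, 1)
        f300 = cds_position_features(tr, 300)
        assert (f300["cds_decile"], f300["codon_index"]) == (10, 100)

    def test_kras_c36_is_codon12_glycine(self):
        f = cds_position_features(kras_cassette_transcript(), 36)
        assert f["codon_index"] == 12
        assert f["amino_acid"] == "G"

    def test_first200_bin_only_for_long_cds(self):
        short = make_transcript("ATG" + "GCT" * 98 + "TAA", [(0, 300)])
        assert cds_position_features(short, 150)["first200_bin"] is None
        long = make_transcript("ATG" + "GCT" * 299 + "TAA", [(0, 903)])
        assert cds_position_features(long, 1)["first200_bin"] == 1
        assert cds_position_features(long, 598)["first200_bin"] == 10  # codon 200
        assert cds_position_features(long, 601)["first200_bin"] is None  # codon 201

    def test_decile_partition_sums_to_total(self, small_cohort):
        _, tx, muts, _ = small_cohort
        tmap = tx.by_id()
        for tid, grp in muts.groupby("transcript_id"):
            decs = [
                cds_position_features(tmap[tid], int(p))["cds_decile"]
                for p in grp["cds_pos"]
            ]
            assert len(decs) == len(grp)
            assert all(1 <= d <= 10 for d in decs)


class TestExonContext:
    def test_monoexonic(self, monoexonic_transcript):
        ctx = exon_context(monoexonic_transcript, 105)
        assert ctx["exon_context"] == "monoexonic"
        assert ctx["internal_exon_decile"] is None

    def test_internal_exon_first_base(self):
        tr = make_transcript("A" * 30, [(0, 10), (20, 30), (40, 50)], cds_end=30)
        ctx = exon_context(tr, 20)
        assert ctx["exon_context"] == "internal"
        assert ctx["internal_exon_decile"] == 1
        assert ctx["boundary_distance"] == 0

    def test_minus_strand_leftmost_exon_is_last(self, three_exon_minus_transcript):
        tr = three_exon_minus_transcript
        assert exon_context(tr, 105)["exon_context"] == "last"
        assert exon_context(tr, 305)["exon_context"] == "first"
        assert exon_context(tr, 205)["exon_context"] == "internal"
        # 5'-most base of the internal exon is genomically rightmost
        assert exon_context(tr, 209)["internal_exon_decile"] == 1

    def test_non_exonic_position_rejected(self, three_exon_minus_transcript):
        with pytest.raises(CoordinateError):
            exon_context(three_exon_minus_transcript, 150)

    def test_context_counts_partition_exonic_mutations(self, small_cohort):
        _, tx, muts, _ = small_cohort
        tmap = tx.by_id()
        labels = []
        for row in muts.itertuples():
            tr = tmap[row.transcript_id]
            labels.append(exon_context(tr, int(row.pos) - 1)["exon_context"])
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == len(muts)
        assert set(counts.index) <= {"first", "internal", "last", "monoexonic"}


class TestAltEvents:
    EVENTS = pd.DataFrame(
        {
            "chrom": ["c", "c", "c"],
            "start": [10, 15, 100],
            "end": [20, 25, 110],
            "event": ["cassetteExon", "retainedIntron", "altPromoter"],
        }
    )

    def test_single_containment(self):
        assert alt_event_overlap("c", 12, self.EVENTS) == {"cassetteExon"}

    def test_no_containment(self):
        assert alt_event_overlap("c", 50, self.EVENTS) == set()

    def test_overlapping_intervals_give_both_labels(self):
        assert alt_event_overlap("c", 17, self.EVENTS) == {
            "cassetteExon",
            "retainedIntron",
        }


class TestExternalJoins:
    def _base(self):
        return pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "pos": [5, 6],
                "ref_genomic": ["A", "C"],
                "alt_genomic": ["G", "T"],
                "gene": ["G1", "G2"],
            }
        )

    def test_absent_snp_gives_false_flag_and_no_row_loss(self):
        snps = pd.DataFrame(
            {"chrom": ["c"], "pos": [5], "ref_genomic": ["A"], "alt_genomic": ["G"]}
        )
        out = external_joins(self._base(), snps=snps)
        assert len(out) == 2
        assert out["snp_flag"].tolist() == [True, False]

    def test_cancer_gene_membership(self):
        out = external_joins(self._base(), cancer_genes=["G2"])
        assert out["cancer_gene"].tolist() == [False, True]

    def test_clinvar_cancer_phenotype_substring(self):
        cv = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "pos": [5, 6],
                "ref_genomic": ["A", "C"],
                "alt_genomic": ["G", "T"],
                "phenotype_list": [
                    "Hereditary cancer-predisposing syndrome",
                    "Cardiomyopathy",
                ],
            }
        )
        out = external_joins(self._base(), clinvar=cv)
        assert out["clinvar_cancer_related"].tolist() == [True, False]

    def test_duplicate_reference_key_raises(self):
        snps = pd.DataFrame(
            {
                "chrom": ["c", "c"],
                "pos": [5, 5],
                "ref_genomic": ["A", "A"],
                "alt_genomic": ["G", "G"],
            }
        )
        with pytest.raises(ValueError, match="duplicate key"):
            external_joins(self._base(), snps=snps)


def test_annotate_table_end_to_end(small_cohort):
    cfg, tx, muts, refs = small_cohort
    curated, _, _ = curate_table(muts, tx.by_id())
    ann = annotate_table(
        curated,
        tx.by_id(),
        cfg.signature,
        alt_events=refs["alt_events"],
        conservation=refs["conservation"],
        cancer_genes=refs["cancer_genes"],
        snps=refs["snps"],
        fathmm=refs["fathmm"],
        cadd=refs["cadd"],
        clinvar=refs["clinvar"],
    )
    assert len(ann) == len(curated)
    snv = ann[ann["substitution_class"].notna()]
    assert (snv["signature_normalized_frequency"] <= snv["frequency"]).all()
    expected_snf = snv["frequency"] * (1 - snv["signature_p"])
    assert np.allclose(snv["signature_normalized_frequency"], expected_snf)
    assert (snv["boundary_distance"] >= 0).all()
    assert snv["phastcons"].between(0, 1).all()
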