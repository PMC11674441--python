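import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neovax import somatic_calling as sc
from neovax import synthetic_data as sd
from conftest import hypergeom_oracle_p


def make_site(t_alt=20, t_ref=80, n_alt=0, n_ref=100, **kw):
    row = dict(chrom="chr1", pos=1000, ref="A", alt="T",
               t_ref=t_ref, t_alt=t_alt, n_ref=n_ref, n_alt=n_alt)
    row.update(kw)
    return pd.DataFrame([row])


class TestFisherExactP:
    def test_no_association_gives_one(self):
        assert sc.fisher_exact_p(0, 20, 0, 20) == 1.0

    def test_matches_enumeration_oracle(self):
        p = sc.fisher_exact_p(10, 10, 0, 20)
        assert p == pytest.approx(hypergeom_oracle_p(10, 10, 0, 20), rel=1e-12)
        # frozen oracle value: exact fraction 1/2294 from integer enumeration
        assert p == pytest.approx(1 / 2294, rel=1e-9)

    def test_row_swap_symmetry(self):
        assert sc.fisher_exact_p(12, 3, 2, 9) == pytest.approx(
            sc.fisher_exact_p(2, 9, 12, 3), rel=1e-12)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            sc.fisher_exact_p(-1, 5, 5, 5)

    def test_all_zero_table_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert sc.fisher_exact_p(0, 0, 0, 0) == 1.0

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25), st.integers(0, 25))
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_agrees_with_oracle_on_random_tables(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert sc.fisher_exact_p(a, b, c, d) == pytest.approx(
            hypergeom_oracle_p(a, b, c, d), rel=1e-12)


class TestCallVariants:
    def test_variant_depth_below_four_rejected(self):
        sites = make_site(t_alt=3, t_ref=10)  # VAF 23%, depth 13: only t_alt fails
        assert sc.call_variants(sites).empty

    def test_normal_vaf_bound_is_exclusive(self):
        rejected = make_site(n_alt=5, n_ref=95)  # exactly 5%
        assert sc.call_variants(rejected).empty
        boundary = make_site(n_alt=2, n_ref=98)  # exactly 2%
        assert sc.call_variants(boundary).empty
        below = make_site(n_alt=1, n_ref=99)
        assert len(sc.call_variants(below)) == 1

    def test_tumour_vaf_bound_is_inclusive(self):
        site = make_site(t_alt=10, t_ref=90, n_alt=0, n_ref=100)  # exactly 10%
        calls = sc.call_variants(site)
        # emitted iff its Fisher p clears the gate; p is far below 0.05 here
        assert sc.fisher_exact_p(10, 90, 0, 100) < 0.05
        assert len(calls) == 1
        assert calls.iloc[0]["tumour_vaf"] == pytest.approx(0.10)

    def test_p_value_bound_is_exclusive(self):
        # shallow counts: passes count filters but p-value too large
        site = make_site(t_alt=4, t_ref=6, n_alt=0, n_ref=10)
        p = sc.fisher_exact_p(4, 6, 0, 10)
        assert p >= 0.05
        assert sc.call_variants(site).empty

    def test_depth_criteria(self):
        assert sc.call_variants(make_site(t_alt=4, t_ref=5)).empty  # tumour depth 9
        assert sc.call_variants(make_site(n_alt=0, n_ref=9)).empty  # normal depth 9

    def test_base_quality_prefilter(self):
        site = make_site(mean_base_quality=10.0)
        assert sc.call_variants(site).empty
        site = make_site(mean_base_quality=15.0)
        assert len(sc.call_variants(site)) == 1

    def test_empty_input_gives_empty_output(self):
        out = sc.call_variants(pd.DataFrame(columns=sd.PILEUP_COLUMNS))
        assert out.empty and list(out.columns) == sc.CALL_COLUMNS

    def test_emitted_calls_sorted_by_position(self, counts_and_truth):
        sites, _ = counts_and_truth
        calls = sc.call_variants(sites)
        assert calls["pos"].is_monotonic_increasing

    @pytest.mark.parametrize("param,tighter", [
        ("min_variant_depth", 8), ("min_tumour_vaf", 0.2),
        ("max_normal_vaf", 0.01), ("max_p", 0.01), ("min_depth", 50),
    ])
    def test_tightening_thresholds_is_monotone(self, counts_and_truth, param, tighter):
        sites, _ = counts_and_truth
        loose = sc.call_variants(sites, sc.CallerParams())
        tight = sc.call_variants(sites, sc.CallerParams(**{param: tighter}))
        assert len(tight) <= len(loose)
        assert set(tight["pos"]) <= set(loose["pos"])

    def test_every_emitted_call_satisfies_all_criteria(self, counts_and_truth):
        sites, _ = counts_and_truth
        calls = sc.call_variants(sites)
        assert len(calls) > 0
        t_depth = calls["t_ref"] + calls["t_alt"]
        n_depth = calls["n_ref"] + calls["n_alt"]
        assert (t_depth >= 10).all()
        assert (n_depth >= 10).all()
        assert (calls["t_alt"] >= 4).all()
        assert (calls["tumour_vaf"] >= 0.10).all()
        assert (calls["normal_vaf"] < 0.02).all()
        assert (calls["p_value"] < 0.05).all()
        for r in calls.itertuples(index=False):
            assert r.p_value == pytest.approx(
                hypergeom_oracle_p(r.t_alt, r.t_ref, r.n_alt, r.n_ref), rel=1e-12)


def _toy_transcriptome():
    """Two handmade transcripts: plus strand and minus strand."""
    # plus strand: protein M D V..., CDS at chr1:101..
    # codon 542 is GAT (D); genomic pos of its middle base: 101 + 3*541 + 1
    protein_codons = ["ATG"] + ["GCT"] * 600
    protein_codons[541] = "GAT"  # D at protein position 542
    seq_plus = "".join(protein_codons)
    # minus strand transcript on chr3: CDS TTG GAT TGG -> L D W
    seq_minus = "TTGGATTGG"
    annotation = pd.DataFrame([
        ("TXP", "NEK9", "chr1", 101, 101 + len(seq_plus) - 1, "+"),
        ("TXM", "MINUS", "chr3", 2001, 2009, "-"),
    ], columns=sd.ANNOTATION_COLUMNS)
    return {"TXP": seq_plus, "TXM": seq_minus}, annotation


class TestAnnotateVariants:
    def test_missense_codon_substitution_plus_strand(self):
        cds, annotation = _toy_transcriptome()
        # GAT->GTT: middle base A->T at pos 101 + 3*541 + 1
        call = make_site(pos=101 + 3 * 541 + 1, ref="A", alt="T")
        out = sc.annotate_variants(call, annotation, cds)
        assert out.iloc[0]["aa_change"] == "D542V"
        assert out.iloc[0]["effect"] == "missense"
        assert out.iloc[0]["gene"] == "NEK9"

    def test_synonymous_codon_substitution(self):
        cds, annotation = _toy_transcriptome()
        # codon 2 GCT->GCC (third base, pos 101+5)
        call = make_site(pos=106, ref="T", alt="C")
        out = sc.annotate_variants(call, annotation, cds)
        assert out.iloc[0]["effect"] == "synonymous"
        assert out.iloc[0]["aa_change"] == ""

    def test_minus_strand_substitution(self):
        cds, annotation = _toy_transcriptome()
        # CDS offset 4 (codon 2 middle base, GAT->GTT) maps to genomic
        # pos = cds_end - 4 = 2005; CDS base A = complement of genome ref T
        call = make_site(chrom="chr3", pos=2005, ref="T", alt="A")
        out = sc.annotate_variants(call, annotation, cds)
        assert out.iloc[0]["aa_change"] == "D2V"
        assert out.iloc[0]["effect"] == "missense"

    def test_adjacent_snvs_merge_into_multi_residue_change(self):
        # codons: ATG ATT CTA -> M I L; three adjacent SNVs hit codon 2
        # twice (ATT->AGG, I->R) and codon 3 once (CTA->ATA, L->I)
        seq = "ATGATTCTA"
        annotation = pd.DataFrame(
            [("TX1", "LRBA", "chr9", 501, 509, "+")], columns=sd.ANNOTATION_COLUMNS)
        calls = pd.DataFrame([
            dict(chrom="chr9", pos=505, ref="T", alt="G"),  # ATT->AGT
            dict(chrom="chr9", pos=506, ref="T", alt="G"),  # ->AGG (I2R)
            dict(chrom="chr9", pos=507, ref="C", alt="A"),
        ])
        calls["t_ref"], calls["t_alt"], calls["n_ref"], calls["n_alt"] = 80, 20, 100, 0
        out = sc.annotate_variants(calls, annotation, {"TX1": seq})
        assert len(out) == 1
        assert out.iloc[0]["aa_change"] == "I2R L3I"
        assert out.iloc[0]["effect"] == "missense"

    def test_stop_gain(self):
        seq = "ATGTGGGCT"  # M W A
        annotation = pd.DataFrame(
            [("TX1", "G", "chr9", 1, 9, "+")], columns=sd.ANNOTATION_COLUMNS)
        call = make_site(chrom="chr9", pos=5, ref="G", alt="A")  # TGG->TAG = stop
        out = sc.annotate_variants(call, annotation, {"TX1": seq})
        assert out.iloc[0]["effect"] == "stop_gain"
        assert out.iloc[0]["aa_change"] == "W2*"

    def test_position_outside_transcripts_is_non_coding(self):
        cds, annotation = _toy_transcriptome()
        out = sc.annotate_variants(make_site(pos=50), annotation, cds)
        assert out.iloc[0]["effect"] == "non_coding"

    def test_cds_not_divisible_by_three_raises_naming_transcript(self):
        annotation = pd.DataFrame(
            [("TXBAD", "G", "chr9", 1, 8, "+")], columns=sd.ANNOTATION_COLUMNS)
        with pytest.raises(sc.AnnotationError, match="TXBAD"):
            sc.annotate_variants(make_site(chrom="chr9", pos=2, ref="T", alt="A"),
                                 annotation, {"TXBAD": "ATGTGGGC"})

    def test_synthetic_truth_sites_annotate_as_coding(self, counts_and_truth, transcriptome):
        sites, truth = counts_and_truth
        cds, annotation, _ = transcriptome
        calls = sc.call_variants(sites)
        out = sc.annotate_variants(calls, annotation, cds)
        truth_pos = set(truth["pos"])
        coding = out[out["pos"].isin(truth_pos)]
        assert (coding["effect"] != "non_coding").all()
        assert (coding["effect"] == "missense").mean() > 0.9


class TestRnaSupport:
    def test_absent_site_not_expressed(self):
        calls = make_site()
        rna = pd.DataFrame(columns=sd.RNA_COLUMNS)
        out = sc.rna_support(calls, rna)
        assert out.iloc[0]["rna_mut_reads"] == 0
        assert not out.iloc[0]["expressed"]

    def test_min_mut_reads_threshold(self):
        calls = make_site()
        rna = pd.DataFrame([("chr1", 1000, 34, 3)], columns=sd.RNA_COLUMNS)
        out = sc.rna_support(calls, rna, min_mut_reads=1)
        assert out.iloc[0]["expressed"]
        assert out.iloc[0]["rna_mut_reads"] == 3
        assert out.iloc[0]["rna_total_reads"] == 37
        out = sc.rna_support(calls, rna, min_mut_reads=4)
        assert not out.iloc[0]["expressed"]


class TestVcfOutput:
    def test_vcf_round_trips_through_pysam(self, tmp_path, counts_and_truth, transcriptome):
        pysam = pytest.importorskip("pysam")
        sites, _ = counts_and_truth
        cds, annotation, rna = transcriptome
        calls = sc.rna_support(
            sc.annotate_variants(sc.call_variants(sites), annotation, cds), rna)
        path = tmp_path / "calls.vcf"
        sc.write_vcf(calls, path)
        with pysam.VariantFile(str(path)) as vf:
            records = list(vf)
        assert len(records) == len(calls)
        assert records[0].pos == int(calls.iloc[0]["pos"])
        assert records[0].info["TVAF"] == pytest.approx(calls.iloc[0]["tumour_vaf"], abs=1e-4)
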