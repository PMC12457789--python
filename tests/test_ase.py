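"""Trimming, TPM, variant detection/classification, ratios and summaries."""

import numpy as np
import pytest

from rutinseq.ase import (
    AlleleExpressionModel,
    annotate_amino_acid_change,
    classify_pattern,
    compute_tpm,
    detect_pollen_allele,
    detect_variants,
    expression_filter,
    pollen_allele_ratio,
    present_alleles,
    summarize_locus,
    trim_ends,
)
from rutinseq.simulate import simulate_ase
from rutinseq.types import (
    PATTERN_I,
    PATTERN_II,
    PATTERN_UNINFORMATIVE,
    ExpressionRecord,
    LocusInfo,
    PileupColumn,
    RunConfig,
    VariantCall,
)
from conftest import make_ase_spec


def col(pos, ref, cross_type="outcross", sample="s", locus="L1", **counts):
    base = dict.fromkeys("ACGT", 0)
    base.update(counts)
    return PileupColumn(sample, cross_type, locus, pos, ref, base)


class TestTrimEnds:
    def test_retained_window(self):
        cols = [col(p, "A", A=5) for p in range(1, 101)]
        kept = trim_ends(cols, locus_length=100, trim_bases=6)
        assert [c.pos for c in kept] == list(range(7, 95))
        assert len(kept) == 88

    def test_too_short_locus_empty(self):
        cols = [col(p, "A", A=5) for p in range(1, 13)]
        assert trim_ends(cols, locus_length=12, trim_bases=6) == []

    def test_boundary_length_13(self):
        cols = [col(p, "A", A=5) for p in range(1, 14)]
        kept = trim_ends(cols, locus_length=13, trim_bases=6)
        assert [c.pos for c in kept] == [7]


class TestTpm:
    def test_single_locus_is_one_million(self):
        r = [ExpressionRecord("s", "L1", 17.0, 100.0)]
        assert compute_tpm(r)[0].tpm == pytest.approx(1e6)

    def test_hand_evaluated_two_loci(self):
        rs = [ExpressionRecord("s", "L1", 10.0, 100.0),
              ExpressionRecord("s", "L2", 10.0, 200.0)]
        compute_tpm(rs)
        assert rs[0].tpm == pytest.approx(666666.67, abs=0.01)
        assert rs[1].tpm == pytest.approx(333333.33, abs=0.01)
        assert rs[0].tpm + rs[1].tpm == pytest.approx(1e6)

    def test_all_zero_counts(self):
        rs = [ExpressionRecord("s", "L1", 0.0, 100.0),
              ExpressionRecord("s", "L2", 0.0, 200.0)]
        compute_tpm(rs)
        assert rs[0].tpm == 0.0 and rs[1].tpm == 0.0

    def test_threshold_is_strict(self):
        rs = [ExpressionRecord("s", "L1", 1.0, 1.0),
              ExpressionRecord("s", "L2", 1.0, 1.0)]
        rs[0].tpm, rs[1].tpm = 1.0, 1.01
        flags = expression_filter(rs, tpm_threshold=1.0)
        assert flags[("s", "L1")] is False  # TPM exactly 1.0: not expressed
        assert flags[("s", "L2")] is True

    def test_62_locus_fixture_counts_22_expressed(self):
        rs = [ExpressionRecord("s", f"L{i}", 50_000.0 if i < 22 else 1.0, 1.0)
              for i in range(62)]
        compute_tpm(rs)
        flags = expression_filter(rs, tpm_threshold=1.0)
        assert sum(flags.values()) == 22


class TestVariantDetection:
    def test_worked_example_configuration(self):
        """Self-cross all C, outcross C+G at a G reference position."""
        self_cols = [col(10, "G", cross_type="self_cross", C=30)]
        out_cols = [col(10, "G", C=20, G=10)]
        calls = detect_variants(self_cols, out_cols, 3, 0.10)
        assert len(calls) == 1
        v = calls[0]
        assert v.alleles_self == {"C"} and v.alleles_out == {"C", "G"}
        assert v.pattern == PATTERN_II
        assert v.pollen_ratio == pytest.approx(100 * 10 / 30)

    def test_all_reference_not_a_variant(self):
        self_cols = [col(10, "G", cross_type="self_cross", G=30)]
        out_cols = [col(10, "G", G=25)]
        assert detect_variants(self_cols, out_cols, 3, 0.10) == []

    def test_below_fraction_threshold_not_a_variant(self):
        self_cols = [col(10, "G", cross_type="self_cross", G=99, A=1)]
        out_cols = [col(10, "G", G=100)]
        assert detect_variants(self_cols, out_cols, 3, 0.10) == []

    def test_zero_depth_position_skipped(self):
        self_cols = [col(10, "G", cross_type="self_cross")]
        out_cols = [col(10, "G")]
        assert detect_variants(self_cols, out_cols, 3, 0.10) == []

    def test_present_alleles_thresholds(self):
        c = col(1, "G", G=90, C=9, A=1)
        assert present_alleles(c, 3, 0.10) == {"G"}
        assert present_alleles(c, 3, 0.05) == {"G", "C"}
        assert present_alleles(c, 1, 0.0) == {"G", "C", "A"}


class TestPatternClassification:
    def test_pattern_ii(self):
        assert classify_pattern(frozenset("C"), frozenset("CG"), "G") == PATTERN_II

    def test_pattern_i(self):
        assert classify_pattern(frozenset("CG"), frozenset("CG"), "G") == PATTERN_I

    def test_uninformative_when_pollen_allele_unseen(self):
        assert (classify_pattern(frozenset("C"), frozenset("C"), "G")
                == PATTERN_UNINFORMATIVE)

    def test_multiallelic_site_is_pattern_ii(self):
        assert classify_pattern(frozenset("CT"), frozenset("CTG"), "G") == PATTERN_II


class TestPollenRatio:
    def test_direct_arithmetic(self):
        assert pollen_allele_ratio(col(1, "G", C=20, G=10), "G") == pytest.approx(33.3333, abs=1e-3)

    def test_endpoints(self):
        assert pollen_allele_ratio(col(1, "G", C=30), "G") == 0.0
        assert pollen_allele_ratio(col(1, "G", G=30), "G") == 100.0

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError, match="depth"):
            pollen_allele_ratio(col(1, "G"), "G")

    def test_denominator_restricted_to_present_alleles(self):
        c = col(1, "G", C=18, G=10, T=2)  # T below presence thresholds
        assert pollen_allele_ratio(c, "G", frozenset("CG")) == pytest.approx(100 * 10 / 28)


def call(pos, pattern, ratio=None):
    return VariantCall("s", "L1", pos, "G", frozenset("C"),
                       frozenset("CG") if pattern == PATTERN_II else frozenset("C"),
                       pattern if pattern != PATTERN_I else PATTERN_I,
                       ratio)


class TestSummaries:
    locus = LocusInfo("L1", "4CL", 1654)

    def test_single_pattern_ii_mean_without_se(self):
        calls = [VariantCall("s", "L1", 10, "G", frozenset("C"), frozenset("CG"),
                             PATTERN_II, 38.5)]
        s = summarize_locus(calls, "s", self.locus, 1642)
        assert s.n_pattern_ii == 1
        assert s.mean_ratio == pytest.approx(38.5)
        assert s.se_ratio is None  # the dash convention

    def test_two_equal_ratios_zero_se(self):
        calls = [VariantCall("s", "L1", p, "G", frozenset("C"), frozenset("CG"),
                             PATTERN_II, 50.0) for p in (10, 20)]
        s = summarize_locus(calls, "s", self.locus, 1642)
        assert s.mean_ratio == 50.0 and s.se_ratio == 0.0

    def test_closed_form_se(self):
        calls = [VariantCall("s", "L1", p, "G", frozenset("C"), frozenset("CG"),
                             PATTERN_II, r) for p, r in ((1, 28.0), (2, 30.0), (3, 32.0))]
        s = summarize_locus(calls, "s", self.locus, 1642)
        assert s.mean_ratio == pytest.approx(30.0)
        assert s.se_ratio == pytest.approx(2 / np.sqrt(3))

    def test_pattern_i_only_detected_without_ratio(self):
        calls = [VariantCall("s", "L1", p, "G", frozenset("CG"), frozenset("CG"),
                             PATTERN_I) for p in range(10, 21)]
        s = summarize_locus(calls, "s", self.locus, 760)
        assert s.n_pattern_i == 11 and s.n_pattern_ii == 0
        assert s.mean_ratio is None and s.se_ratio is None
        assert detect_pollen_allele([s]) == {"L1": True}

    def test_no_variants_not_detected(self):
        s = summarize_locus([], "s", self.locus, 1642)
        assert detect_pollen_allele([s]) == {"L1": False}


class TestAminoAcidAnnotation:
    seq = "NNN" + "ATGGCTTAA"  # CDS starts at position 4: ATG GCT TAA

    def test_nonsynonymous(self):
        # ATG -> ACG is M -> T
        assert annotate_amino_acid_change(self.seq, 4, 5, "T", "C") == "nonsynonymous"

    def test_synonymous(self):
        # GCT -> GCC is A -> A
        assert annotate_amino_acid_change(self.seq, 4, 9, "T", "C") == "synonymous"

    def test_upstream_is_noncoding(self):
        assert annotate_amino_acid_change(self.seq, 4, 2, "N", "A") == "noncoding"

    def test_incomplete_terminal_codon(self):
        seq = "ATGGC"
        assert annotate_amino_acid_change(seq, 1, 5, "C", "T") == "noncoding"


class TestModelEndToEnd:
    def test_pattern_labels_match_generator_truth(self, noise_free_config):
        """Classifier agrees with truth labels at >= 99% of variant sites."""
        from rutinseq.simulate import random_sequences

        loci = [LocusInfo("L1", "PAL", 1500), LocusInfo("L2", "CHS", 1200)]
        seqs = random_sequences({"L1": 1500, "L2": 1200}, seed=31)
        spec = make_ase_spec(loci, seqs, pi=0.3, depth=200, seed=32,
                             maternal_het_rate=0.05,
                             maternal_hom_alt_rate=0.03,
                             multiallelic_rate=0.01)
        pileups, truth = simulate_ase(spec)
        res = AlleleExpressionModel(pileups, loci, config=noise_free_config).fit()
        tb = truth.by_position()
        checked = matched = 0
        for v in res.variants:
            site = tb.get((v.locus_id, v.pos))
            if site is None:
                continue
            checked += 1
            matched += site.expected_pattern == v.pattern
        assert checked > 100
        assert matched / checked >= 0.99

    def test_variants_never_inside_trimmed_ends(self, hom_alt_locus):
        loci, seqs = hom_alt_locus
        pileups, _ = simulate_ase(make_ase_spec(loci, seqs, pi=0.3))
        res = AlleleExpressionModel(
            pileups, loci, config=RunConfig(min_allele_count=1,
                                            min_allele_fraction=0.0)).fit()
        assert res.variants
        for v in res.variants:
            assert 6 < v.pos <= 62 - 6

    def test_mean_ratio_monotone_in_pi(self, hom_alt_locus, noise_free_config):
        loci, seqs = hom_alt_locus
        means = []
        for pi in (0.1, 0.3, 0.5):
            pileups, _ = simulate_ase(make_ase_spec(loci, seqs, pi=pi, seed=41))
            res = AlleleExpressionModel(pileups, loci,
                                        config=noise_free_config).fit()
            means.append(res.locus_summaries[0].mean_ratio)
        assert means[0] < means[1] < means[2]

    def test_per_snp_ratio_matches_read_log_tally(self, hom_alt_locus,
                                                  noise_free_config):
        """Each reported ratio equals a naive per-read re-tally."""
        loci, seqs = hom_alt_locus
        spec = make_ase_spec(loci, seqs, pi=0.4, depth=80, seed=43)
        pileups, _, log = simulate_ase(spec, read_log=True)
        res = AlleleExpressionModel(pileups, loci, config=noise_free_config).fit()
        assert any(v.pattern == PATTERN_II for v in res.variants)
        for v in res.variants:
            if v.pattern != PATTERN_II:
                continue
            reads = [obs for ct, loc, pos, _o, _t, obs in log
                     if ct == "outcross" and loc == v.locus_id and pos == v.pos
                     and obs in v.alleles_out]
            naive = 100 * sum(b == v.ref_base for b in reads) / len(reads)
            assert v.pollen_ratio == pytest.approx(naive)

    def test_unexpressed_locus_excluded(self, hom_alt_locus):
        loci, seqs = hom_alt_locus
        pileups, _ = simulate_ase(make_ase_spec(loci, seqs, pi=0.3))
        expression = [ExpressionRecord("plant-A", "L1", 0.0, 62.0),
                      ExpressionRecord("plant-A", "HK", 1e6, 1000.0)]
        loci_all = loci + [LocusInfo("HK", "GTR", 1000)]
        res = AlleleExpressionModel(pileups, loci_all, expression).fit()
        l1 = [s for s in res.locus_summaries if s.locus_id == "L1"][0]
        assert l1.expressed is False
        assert l1.n_pattern_i == 0 and l1.n_pattern_ii == 0
        assert res.pollen_detected().get("L1", False) is False

    def test_maternal_all_reference_yields_no_detection(self, noise_free_config):
        from rutinseq.simulate import random_sequences

        loci = [LocusInfo("L1", "FLS", 200)]
        seqs = random_sequences({"L1": 200}, seed=51)
        spec = make_ase_spec(loci, seqs, pi=0.4, seed=52,
                             maternal_het_rate=0.0, maternal_hom_alt_rate=0.0)
        pileups, truth = simulate_ase(spec)
        assert truth.sites == []
        res = AlleleExpressionModel(pileups, loci, config=noise_free_config).fit()
        assert res.variants == []
        assert res.pollen_detected() == {"L1": False}

    def test_write_uses_dash_for_absent(self, tmp_path, hom_alt_locus,
                                        noise_free_config):
        loci, seqs = hom_alt_locus
        pileups, _ = simulate_ase(make_ase_spec(loci, seqs, pi=0.3))
        res = AlleleExpressionModel(pileups, loci, config=noise_free_config).fit()
        res.write(tmp_path)
        text = (tmp_path / "ase_summary.tsv").read_text()
        assert "tpm" in text.splitlines()[0]
        assert "\t-" in text  # tpm column absent without expression data
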