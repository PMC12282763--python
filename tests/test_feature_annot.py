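"""Consequence annotation, context features, resources, feature assembly.

Codon-level consequences are cross-checked with standard-codon-table
translation of hand-built toy transcripts; the strand-bias phred is checked
against a direct hypergeometric (Fisher-exact) computation.
"""

import math

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq
from scipy import stats

from chipcall.feature_annot import (
    Consequence,
    GeneModel,
    INDEL_FEATURES,
    ResourceTables,
    SNV_FEATURES,
    Transcript,
    build_feature_vector,
    classify_consequence,
    context_features,
    functional_filter,
    schema_hash,
    strand_bias_phred,
)
from chipcall.meta_caller import merge_callsets
from chipcall.spike_sim import make_reference
from chipcall.variant_model import GenomicVariant, VariantKey
from chipcall.vartracker import CallRecord

# toy gene: single exon, CDS "ATG CAG TGC CAT TAA" at positions 11-25 of a
# 40 bp contig; codon 2 is CAG (Gln)
_CDS = "ATGCAGTGCCATTAA"
TOY_SEQ = {"t": "AAAAAAAAAA" + _CDS + "AAAAAAAAAACCCCC"}
TOY_GM = GeneModel(
    [Transcript("tx1", "GENE1", "t", "+", ((11, 25),), 11, 25)]
)


class TestConsequence:
    def test_synonymous_third_position(self):
        # CAG -> CAA both encode Gln
        v = GenomicVariant("t", 16, "G", "A")
        assert classify_consequence(v, TOY_GM, TOY_SEQ) is Consequence.SYNONYMOUS

    def test_nonsense_cag_to_tag(self):
        v = GenomicVariant("t", 14, "C", "T")
        ref_codon, alt_codon = "CAG", "TAG"
        assert str(Seq(alt_codon).translate()) == "*"  # oracle
        assert classify_consequence(v, TOY_GM, TOY_SEQ) is Consequence.NONSENSE

    def test_missense(self):
        # TGC (Cys) -> TGG? pos 19 third base C->G gives TGG (Trp)
        v = GenomicVariant("t", 19, "C", "G")
        assert classify_consequence(v, TOY_GM, TOY_SEQ) is Consequence.MISSENSE

    def test_start_and_stop_loss(self):
        assert classify_consequence(
            GenomicVariant("t", 11, "A", "G"), TOY_GM, TOY_SEQ
        ) is Consequence.START_LOSS
        assert classify_consequence(
            GenomicVariant("t", 23, "T", "C"), TOY_GM, TOY_SEQ
        ) is Consequence.STOP_LOSS

    def test_frameshift_vs_inframe(self):
        seq = TOY_SEQ["t"]
        two_bp = GenomicVariant("t", 14, seq[13:16], seq[13])
        three_bp = GenomicVariant("t", 13, seq[12:16], seq[12])
        assert classify_consequence(two_bp, TOY_GM, TOY_SEQ) is Consequence.FRAMESHIFT
        assert classify_consequence(three_bp, TOY_GM, TOY_SEQ) is Consequence.INFRAME_INDEL

    def test_intergenic_is_noncoding(self):
        v = GenomicVariant("t", 3, "A", "G")
        assert classify_consequence(v, TOY_GM, TOY_SEQ) is Consequence.NONCODING

    def test_essential_splice_window(self):
        # two-exon transcript with intron 21-110
        seq = {"s": "A" * 10 + "ATGCAG" + "G" * 90 + "TGCCATTAA" + "A" * 10}
        gm = GeneModel(
            [Transcript("tx2", "GENE2", "s", "+", ((11, 16), (107, 115)), 11, 115)]
        )
        base = seq["s"][16]  # first intronic base (pos 17)
        alt = "A" if base != "A" else "C"
        assert classify_consequence(
            GenomicVariant("s", 17, base, alt), gm, seq
        ) is Consequence.ESSENTIAL_SPLICE
        mid = seq["s"][60]
        assert classify_consequence(
            GenomicVariant("s", 61, mid, "A" if mid != "A" else "C"), gm, seq
        ) is Consequence.NONCODING

    def test_minus_strand_uses_reverse_complement(self, sim_ref):
        """Simulated minus-strand gene: disrupting its genomic stop-codon
        complement is recognized through reverse-complement translation."""
        t = next(t for t in sim_ref.gene_model.transcripts if t.strand == "-")
        # genomic start of a minus-strand gene holds the reversed stop codon
        pos = t.cds_start
        base = sim_ref.seqs[t.chrom][pos - 1]
        alt = next(b for b in "ACGT" if b != base)
        cq = classify_consequence(
            GenomicVariant(t.chrom, pos, base, alt), sim_ref.gene_model, sim_ref.seqs
        )
        assert cq in (Consequence.STOP_LOSS, Consequence.SYNONYMOUS)

    def test_functional_filter_membership_and_order(self):
        items = [
            ("a", Consequence.MISSENSE),
            ("b", Consequence.SYNONYMOUS),
            ("c", Consequence.FRAMESHIFT),
            ("d", Consequence.NONCODING),
            ("e", Consequence.ESSENTIAL_SPLICE),
        ]
        kept = functional_filter(items)
        assert [k for k, _ in kept] == ["a", "c", "e"]


class TestContextFeatures:
    def test_homopolymer_adjacent_run(self):
        seq = {"c": "GCGC" + "AAAAAA" + "GCGCGATC"}
        v = GenomicVariant("c", 4, "C", "T")  # immediately left of the A run
        hp, _, _, _ = context_features(v, seq)
        assert hp == 6

    def test_nonrepetitive_context(self):
        seq = {"c": "ACGTAGCTAGGATCCGATCA"}
        hp, in_str, _, _ = context_features(GenomicVariant("c", 10, "G", "T"), seq)
        assert hp <= 2 and not in_str

    def test_tandem_repeat_detected(self):
        seq = {"c": "GATC" + "TG" * 5 + "CATG"}
        v = GenomicVariant("c", 7, "G", "A")  # inside the TG x5 tract
        _, in_str, _, _ = context_features(v, seq)
        assert in_str

    def test_gc_boundary_all_gc(self):
        seq = {"c": "GC" * 60}
        *_, gc = context_features(GenomicVariant("c", 60, "C", "A"), seq)
        assert gc == 1.0

    def test_interval_flags(self):
        seq = {"c": "ACGT" * 30}
        v = GenomicVariant("c", 50, "T", "A")
        _, in_str, in_lc, _ = context_features(
            v, seq, str_intervals=[("c", 40, 60)], low_complexity_intervals=[("c", 49, 51)]
        )
        assert in_str and in_lc


class TestStrandBias:
    @pytest.mark.parametrize(
        "table", [(5, 5, 50, 50), (10, 0, 30, 40), (1, 9, 48, 52), (0, 0, 10, 10)]
    )
    def test_matches_fisher_oracle(self, table):
        af, ar, rf, rr = table
        _, p = stats.fisher_exact([[af, ar], [rf, rr]])
        expected = min(200.0, -10 * math.log10(p)) if p > 0 else 200.0
        assert strand_bias_phred(af, ar, rf, rr) == pytest.approx(expected)

    def test_balanced_counts_score_low(self):
        assert strand_bias_phred(5, 5, 50, 50) < 3.0


class TestSchemaAndVector:
    def test_schema_sizes_and_hash_stability(self):
        assert len(SNV_FEATURES) == 26
        assert len(INDEL_FEATURES) == 24
        assert schema_hash("SNV") == schema_hash("SNV")
        assert schema_hash("SNV") != schema_hash("INDEL")

    def _merged(self, ref_seqs, pos=20, callers=3):
        ids = ["TRACKER", "CALLER_A", "CALLER_B"][:callers]
        base = ref_seqs["chr1"][pos - 1]
        alt = next(b for b in "ACGT" if b != base)
        callsets = [
            (
                cid,
                [
                    CallRecord(
                        variant=GenomicVariant("chr1", pos, base, alt),
                        caller_id=cid,
                        alt_count=5,
                        depth=100,
                    )
                ],
            )
            for cid in ids
        ]
        merged, _ = merge_callsets(callsets, ref_seqs)
        return merged[0]

    def test_full_status_and_flags(self, sim_ref):
        mc = self._merged(sim_ref.seqs, pos=200, callers=3)
        vec = build_feature_vector(
            mc, None, Consequence.MISSENSE, ResourceTables(), sim_ref.seqs
        )
        assert len(vec) == 26
        assert vec["status_meta"] == 3
        assert (
            vec["called_by_tracker"] == vec["called_by_caller_a"] == vec["called_by_caller_b"] == 1
        )
        assert vec["vaf"] == pytest.approx(0.05)

    def test_absent_resources_encode_zero(self, sim_ref):
        mc = self._merged(sim_ref.seqs, pos=200, callers=1)
        vec = build_feature_vector(
            mc, None, Consequence.MISSENSE, ResourceTables(), sim_ref.seqs
        )
        for col in ("maf_db1", "maf_db2", "maf_db3", "maf_db4", "max_germline_maf",
                    "cosmic_match", "cosmic_freq"):
            assert vec[col] == 0.0

    def test_resource_lookup_and_max_maf(self, sim_ref):
        mc = self._merged(sim_ref.seqs, pos=300, callers=2)
        key = mc.key
        rt = ResourceTables(
            germline_mafs=({key: 0.01}, {}, {key: 0.2}, {}),
            cosmic={key: 42},
        )
        vec = build_feature_vector(mc, None, Consequence.MISSENSE, rt, sim_ref.seqs)
        assert vec["maf_db1"] == 0.01
        assert vec["maf_db3"] == 0.2
        assert vec["max_germline_maf"] == 0.2
        assert vec["cosmic_match"] == 1 and vec["cosmic_freq"] == 42

    def test_indel_vector_has_signed_length(self, sim_ref):
        seq = sim_ref.seqs["chr1"]
        pos = 400
        callsets = [
            (
                "TRACKER",
                [
                    CallRecord(
                        variant=GenomicVariant("chr1", pos, seq[pos - 1 : pos + 2], seq[pos - 1]),
                        caller_id="TRACKER",
                        alt_count=8,
                        depth=90,
                    )
                ],
            )
        ]
        merged, _ = merge_callsets(callsets, sim_ref.seqs)
        vec = build_feature_vector(
            merged[0], None, Consequence.FRAMESHIFT, ResourceTables(), sim_ref.seqs
        )
        assert len(vec) == 24
        assert vec["indel_length"] == -2.0
        assert "is_transition" not in vec.index


class TestResourceTables:
    def test_from_files_roundtrip(self, tmp_path):
        def tsv(name, rows, cols):
            p = tmp_path / name
            pd.DataFrame(rows, columns=cols).to_csv(p, sep="\t", index=False)
            return str(p)

        key_cols = ["chrom", "pos", "ref", "alt"]
        maf_paths = [
            tsv(f"maf{i}.tsv", [["chr1", 100, "A", "G", 0.1 * (i + 1)]], key_cols + ["maf"])
            for i in range(4)
        ]
        cosmic = tsv("cosmic.tsv", [["chr1", 100, "A", "G", 7]], key_cols + ["sample_count"])
        chip = tsv("chip.tsv", [["chr1", 100, "A", "G"]], key_cols)
        bed = tmp_path / "lc.bed"
        bed.write_text("chr1\t90\t110\n")
        rt = ResourceTables.from_files(
            maf_paths, cosmic, chip, low_complexity_bed=str(bed)
        )
        key = VariantKey("chr1", 100, "A", "G")
        assert rt.max_germline_maf(key) == pytest.approx(0.4)
        assert rt.cosmic[key] == 7
        assert key in rt.known_chip
        assert rt.low_complexity == [("chr1", 91, 110)]

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            ResourceTables(germline_mafs=({VariantKey("c", 1, "A", "G"): 1.5}, {}, {}, {}))
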