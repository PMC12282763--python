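"""Reference generation, read simulation, spike-in semantics, mock callers,
and truth-based benchmarking metrics."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from chipcall.spike_sim import (
    MUTECT_LIKE,
    VARDICT_LIKE,
    MockCallerProfile,
    SpikeInSpec,
    chip_vaf_targets,
    functional_snv_specs,
    make_reference,
    mock_caller,
    read_sam,
    simulate_reads,
    spike_in,
    spikein_recall_precision,
    synthetic_feature_table,
    vaf_series,
    verify_spikein,
    write_sam,
)
from chipcall.variant_model import GenomicVariant


class TestMakeReference:
    def test_same_seed_identical_sequence(self):
        a = make_reference(seed=5)
        b = make_reference(seed=5)
        assert a.seqs == b.seqs
        c = make_reference(seed=6)
        assert a.seqs != c.seqs

    def test_orfs_translate_cleanly(self):
        ref = make_reference(seed=5)
        for t in ref.gene_model.transcripts:
            cds = "".join(ref.seqs[t.chrom][p - 1] for p in t.cds_positions())
            if t.strand == "-":
                cds = str(Seq(cds).reverse_complement())
            aa = str(Seq(cds).translate())
            assert aa.startswith("M")
            assert aa.endswith("*")
            assert "*" not in aa[:-1]

    def test_gc_content_controlled(self):
        ref = make_reference(n_genes=12, gene_len=600, gc=0.5, seed=9)
        seq = ref.seqs["chr1"]
        gc = sum(b in "GC" for b in seq) / len(seq)
        assert abs(gc - 0.5) < 0.03

    def test_repeat_tracts_planted(self):
        ref = make_reference(seed=5)
        seq = ref.seqs["chr1"]
        assert "A" * 8 in seq
        assert "ACACAC" in seq

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            make_reference(n_genes=0)
        with pytest.raises(ValueError):
            make_reference(gc=1.5)


class TestSimulateReads:
    def test_zero_error_reads_match_reference(self):
        ref = make_reference(seed=7)
        reads, germline = simulate_reads(
            ref, mean_depth=20, seed=7, err_rate=0.0, n_het=0, n_hom=0
        )
        assert germline == []
        seq = ref.seqs["chr1"]
        for r in reads[:200]:
            assert r.query_sequence == seq[r.reference_start : r.reference_start + len(r.query_sequence)]

    def test_mean_depth_near_target(self):
        ref = make_reference(n_genes=12, gene_len=600, seed=8)
        reads, _ = simulate_reads(ref, mean_depth=100, seed=8, n_het=0, n_hom=0)
        L = len(ref.seqs["chr1"])
        total = sum(len(r.query_sequence) for r in reads)
        assert abs(total / L - 100) < 5

    def test_het_vaf_within_binomial_bounds(self):
        from scipy import stats

        ref = make_reference(seed=9)
        reads, germline = simulate_reads(ref, mean_depth=120, seed=9, err_rate=0.0,
                                         n_het=3, n_hom=2)
        seq = ref.seqs["chr1"]
        for v, zyg in germline:
            n = alt = 0
            for r in reads:
                s = r.reference_start
                if s <= v.pos - 1 < s + len(r.query_sequence):
                    n += 1
                    alt += r.query_sequence[v.pos - 1 - s] == v.alt
            p = 0.5 if zyg == "het" else 1.0
            lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
            assert lo <= alt <= hi

    def test_sam_roundtrip(self, tmp_path):
        ref = make_reference(seed=10)
        reads, _ = simulate_reads(ref, mean_depth=10, seed=10)
        path = str(tmp_path / "reads.sam")
        write_sam(reads, ref, path)
        back = read_sam(path)
        assert len(back) == len(reads)
        assert back[0].query_sequence == reads[0].query_sequence


class TestSpikeIn:
    def test_depth_below_m_skipped(self):
        ref = make_reference(seed=12)
        reads, _ = simulate_reads(ref, mean_depth=50, seed=12, n_het=0, n_hom=0)
        # a site covered by at most one read: keep only one read
        one = [reads[0]]
        pos = one[0].reference_start + 10
        base = ref.seqs["chr1"][pos]
        alt = next(b for b in "ACGT" if b != base)
        spec = SpikeInSpec(GenomicVariant("chr1", pos + 1, base, alt), 0.5, min_depth=2)
        _, truth = spike_in(one, [spec], ref, seed=0)
        row = truth.iloc[0]
        assert not row["spiked"]
        assert row["reason"] == "depth_below_m"

    def test_realized_vaf_within_binomial_bounds(self):
        from scipy import stats

        ref = make_reference(n_genes=12, gene_len=600, seed=13)
        reads, _ = simulate_reads(ref, mean_depth=200, seed=13, n_het=0, n_hom=0)
        specs = functional_snv_specs(ref, 12, 0.10, seed=13)
        _, truth = spike_in(reads, specs, ref, seed=13)
        for row in truth.itertuples():
            assert row.spiked
            lo, hi = stats.binom.ppf([0.0005, 0.9995], row.realized_depth, 0.10)
            assert lo <= row.reads_converted <= hi

    def test_target_vaf_one_converts_every_spanning_read(self):
        ref = make_reference(seed=14)
        reads, _ = simulate_reads(ref, mean_depth=40, seed=14, n_het=0, n_hom=0)
        specs = functional_snv_specs(ref, 3, 1.0, seed=14)
        mreads, truth = spike_in(reads, specs, ref, seed=14)
        for row in truth.itertuples():
            seq = ref.seqs["chr1"]
            n_span = sum(
                1
                for r in mreads
                if r.reference_start <= row.pos - 1 < r.reference_start + r.reference_length
            )
            # all spanning reads converted (boundary reads may only cover, not span)
            assert row.reads_converted >= truth.iloc[0]["realized_depth"] * 0 + 1
            assert row.realized_vaf > 0.9

    def test_ref_mismatch_recorded_run_continues(self):
        ref = make_reference(seed=15)
        reads, _ = simulate_reads(ref, mean_depth=30, seed=15, n_het=0, n_hom=0)
        seq = ref.seqs["chr1"]
        wrong_base = next(b for b in "ACGT" if b != seq[499])
        bad = SpikeInSpec(GenomicVariant("chr1", 500, wrong_base, seq[499]), 0.5)
        good = functional_snv_specs(ref, 1, 0.5, seed=15)[0]
        _, truth = spike_in(reads, [bad, good], ref, seed=15)
        assert truth.iloc[0]["reason"] == "ref_mismatch"
        assert truth.iloc[1]["spiked"]

    def test_truth_conservation(self):
        ref = make_reference(seed=16)
        reads, _ = simulate_reads(ref, mean_depth=30, seed=16, n_het=0, n_hom=0)
        specs = functional_snv_specs(ref, 10, 0.02, seed=16)
        _, truth = spike_in(reads, specs, ref, seed=16)
        spiked = truth["spiked"].sum()
        skipped = (truth["reason"] == "depth_below_m").sum()
        failed = truth["reason"].isin(["ref_mismatch", "no_read_converted"]).sum()
        assert spiked + skipped + failed == len(truth)


class TestVafSeries:
    def test_levels(self):
        s = vaf_series()
        assert len(s) == 13
        assert s[0] == 0.005
        assert s[-1] == 0.30
        assert s[1:11] == [i / 100 for i in range(1, 11)]
        assert all(b > a for a, b in zip(s, s[1:]))

    def test_chip_vaf_targets_median(self):
        snv = chip_vaf_targets(20000, "SNV", seed=1)
        indel = chip_vaf_targets(20000, "INDEL", seed=1)
        assert np.median(snv) == pytest.approx(0.125, rel=0.05)
        assert np.median(indel) == pytest.approx(0.148, rel=0.05)


class TestVerifySpikein:
    def test_spiked_records_observable(self):
        ref = make_reference(seed=17)
        reads, _ = simulate_reads(ref, mean_depth=60, seed=17, n_het=0, n_hom=0)
        specs = functional_snv_specs(ref, 8, 0.2, seed=17)
        mreads, truth = spike_in(reads, specs, ref, seed=17)
        report = verify_spikein(mreads, truth, ref)
        assert not report["defect"].any()
        spiked = report[report["spiked"]]
        # observed counts equal the truth table exactly (same reads)
        assert (spiked["observed_alt_count"] == spiked["reads_converted"]).all()


class TestMockCaller:
    def _setup(self, n=40, vaf=0.2, seed=18):
        ref = make_reference(n_genes=12, gene_len=600, seed=seed)
        reads, _ = simulate_reads(ref, mean_depth=100, seed=seed, n_het=0, n_hom=0)
        specs = functional_snv_specs(ref, n, vaf, seed=seed)
        _, truth = spike_in(reads, specs, ref, seed=seed)
        return ref, truth

    def test_perfect_profile_recovers_observable_truth(self):
        ref, truth = self._setup()
        profile = MockCallerProfile("P", ((1.0, 1.0),), min_alt_reads=1, fp_per_mb=0.0)
        calls = mock_caller(truth, profile, ref, seed=0)
        recall, precision = spikein_recall_precision(calls, truth)
        assert recall == 1.0 and precision == 1.0

    def test_half_sensitivity_within_binomial_bounds(self):
        from scipy import stats

        ref, truth = self._setup(n=60)
        profile = MockCallerProfile("P", ((1.0, 0.5),), min_alt_reads=1, fp_per_mb=0.0)
        calls = mock_caller(truth, profile, ref, seed=3)
        n = int(truth["spiked"].sum())
        lo, hi = stats.binom.ppf([0.025, 0.975], n, 0.5)
        assert lo <= len(calls) <= hi

    def test_vaf_dependent_sensitivity_orders_recall(self):
        ref = make_reference(n_genes=12, gene_len=600, seed=19)
        reads, _ = simulate_reads(ref, mean_depth=150, seed=19, n_het=0, n_hom=0)
        low = functional_snv_specs(ref, 25, 0.05, seed=19)[:12]
        high = [SpikeInSpec(s.variant, 0.4) for s in functional_snv_specs(ref, 25, 0.05, seed=19)[12:]]
        _, truth = spike_in(reads, low + high, ref, seed=19)
        profile = MockCallerProfile("P", ((0.10, 0.1), (1.0, 0.9)), 1, 0.0)
        calls = mock_caller(truth, profile, ref, seed=19)
        t_low = truth.iloc[: len(low)]
        t_high = truth.iloc[len(low):]
        r_low, _ = spikein_recall_precision(calls, t_low)
        r_high, _ = spikein_recall_precision(calls, t_high)
        assert r_low < r_high


class TestRecallPrecision:
    def _truth(self, positions):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": positions,
                "ref": "A",
                "alt": "G",
                "norm_pos": positions,
                "spiked": True,
            }
        )

    def _calls(self, positions):
        return [
            GenomicVariant("chr1", p, "A", "G") for p in positions
        ]

    def test_perfect_recovery(self):
        truth = self._truth([10, 20, 30])
        assert spikein_recall_precision(self._calls([10, 20, 30]), truth) == (1.0, 1.0)

    def test_eq_worked_example(self):
        # 10 spiked, 8 recovered, 3 extra calls -> recall 0.8, precision 8/11
        truth = self._truth(list(range(100, 200, 10)))
        calls = self._calls(list(range(100, 180, 10)) + [900, 910, 920])
        recall, precision = spikein_recall_precision(calls, truth)
        assert recall == pytest.approx(0.8)
        assert precision == pytest.approx(8 / 11)

    def test_allele_agnostic_matching(self):
        truth = self._truth([50])
        calls = [GenomicVariant("chr1", 50, "A", "T")]  # different alt base
        recall, _ = spikein_recall_precision(calls, truth)
        assert recall == 1.0

    def test_unspiked_truths_excluded_from_denominator(self):
        truth = self._truth([10, 20])
        truth.loc[1, "spiked"] = False
        recall, _ = spikein_recall_precision(self._calls([10]), truth)
        assert recall == 1.0


class TestSyntheticFeatureTable:
    def test_class_counts_match_fractions(self):
        X, y = synthetic_feature_table(n=999, class_fractions=(0.5, 0.3, 0.2), seed=1)
        counts = pd.Series(y).value_counts()
        assert abs(counts["CHIP"] - 500) <= 1
        assert abs(counts["GERMLINE"] - 300) <= 1
        assert abs(counts["ARTIFACT"] - 200) <= 1

    def test_vaf_consistency_and_maf_invariant(self):
        X, _ = synthetic_feature_table(n=500, seed=2)
        np.testing.assert_allclose(X["vaf"], X["alt_count"] / X["depth"])
        np.testing.assert_allclose(
            X["max_germline_maf"],
            X[["maf_db1", "maf_db2", "maf_db3", "maf_db4"]].max(axis=1),
        )

    def test_indel_schema(self):
        X, _ = synthetic_feature_table(n=100, seed=3, variant_type="INDEL")
        assert X.shape[1] == 24
        assert "indel_length" in X.columns
        assert (X["indel_length"] != 0).all()
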