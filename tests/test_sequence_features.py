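import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from crypticburden.io_formats import GenomicJunction, IntervalSet, SequenceStore
from crypticburden.sequence_features import (
    HEXAMER_CLASSES,
    bh_adjust,
    binding_fraction_profile,
    count_motif_windows,
    donor_downstream_ppm,
    enrichment_table,
    fisher_enrichment,
    fraction_bound_within,
    hexamer_class_freq,
    ingest_splice_scores,
    merge_intervals,
    sample_background_exons,
    ug_density,
)


def brute_motif_count(seq, motif, mm):
    m = len(motif)
    return sum(
        sum(a != b for a, b in zip(seq[i : i + m], motif)) <= mm
        for i in range(len(seq) - m + 1)
    )


dna = st.text(alphabet="ACGTN", min_size=6, max_size=200)


class TestUgDensity:
    @pytest.mark.parametrize(
        "seq, count",
        [("TGTGTG", 1), ("TGTGAG", 1), ("TGTGTGTG", 2), ("AAAAAA", 0)],
    )
    def test_hand_counts(self, seq, count):
        assert ug_density(seq) == pytest.approx(count / len(seq))

    def test_short_sequence_warns_zero(self):
        with pytest.warns(UserWarning):
            assert ug_density("ACG") == 0.0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(seq=dna, mm=st.integers(0, 2))
    def test_matches_brute_force(self, seq, mm):
        assert count_motif_windows(seq, "TGTGTG", mm) == brute_motif_count(
            seq, "TGTGTG", mm
        )

    @pytest.mark.parametrize("k", [5, 10, 50, 200])
    def test_perfect_tg_repeat_closed_form(self, k):
        seq = "TG" * k
        assert count_motif_windows(seq, "TGTGTG", 1) == k - 2
        assert ug_density(seq) == pytest.approx((k - 2) / (2 * k))


class TestHexamerClasses:
    def test_classes_disjoint_hexamers(self):
        all_members = [h for c in HEXAMER_CLASSES.values() for h in c]
        assert len(all_members) == len(set(all_members))
        assert all(len(h) == 6 and set(h) <= set("ACGT") for h in all_members)

    @pytest.mark.parametrize(
        "seq, cls, freq",
        [
            ("TGTGTG", "YG", 1000 / 6),
            ("AAAAAA", "YG", 0.0),
            ("TTGAAT", "AA", 1000 / 6),
        ],
    )
    def test_per_kb_frequency(self, seq, cls, freq):
        out = hexamer_class_freq(seq)
        assert out[cls] == pytest.approx(freq)

    def test_ttgaat_only_in_aa(self):
        out = hexamer_class_freq("TTGAAT")
        assert out["YG"] == 0.0 and out["YA"] == 0.0 and out["AA"] > 0


def fisher_oracle(a, b, c, d):
    """Two-sided p via full hypergeometric enumeration."""
    n1, N, K = a + b, a + b + c + d, a + c
    support = np.arange(max(0, n1 + K - N), min(n1, K) + 1)
    pmf = hypergeom.pmf(support, N, K, n1)
    obs = hypergeom.pmf(a, N, K, n1)
    return float(pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected_p",
        [
            ((3, 1, 1, 3), 34 / 70),
            ((5, 0, 0, 5), 2 / 252),
            ((2, 2, 2, 2), 1.0),
        ],
    )
    def test_hand_enumerated(self, table, expected_p):
        _, p = fisher_enrichment(*table)
        assert p == pytest.approx(expected_p)

    def test_odds_ratio_inf_allowed(self):
        odds, _ = fisher_enrichment(5, 0, 0, 5)
        assert odds == np.inf

    def test_zero_margin(self):
        odds, p = fisher_enrichment(0, 0, 3, 4)
        assert p == 1.0 and np.isnan(odds)

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10)))
    def test_matches_enumeration(self, table):
        a, b, c, d = table
        if a + b + c + d == 0 or a + b == 0 or c + d == 0 \
                or a + c == 0 or b + d == 0:
            return
        _, p = fisher_enrichment(a, b, c, d)
        assert p == pytest.approx(fisher_oracle(a, b, c, d), rel=1e-9)


def bh_oracle(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    best = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, pvals[i] * m / rank)
        adj[i] = best
    return adj


class TestBH:
    def test_hand_computed(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_unit(self):
        assert bh_adjust([0.4])[0] == pytest.approx(0.4)
        assert np.allclose(bh_adjust([1.0, 1.0]), 1.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_oracle(pvals))

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


class TestMergeIntervals:
    def test_overlap_and_adjacency(self):
        merged = merge_intervals(IntervalSet([("chr1", 10, 20), ("chr1", 15, 25)]))
        assert [(r[1], r[2]) for r in merged] == [(10, 25)]
        merged = merge_intervals(IntervalSet([("chr1", 10, 20), ("chr1", 20, 30)]))
        assert [(r[1], r[2]) for r in merged] == [(10, 30)]

    def test_disjoint_untouched(self):
        merged = merge_intervals(IntervalSet([("chr1", 10, 20), ("chr1", 30, 40)]))
        assert len(merged) == 2

    def test_idempotent_and_base_preserving(self):
        rng = np.random.default_rng(1)
        ivs = IntervalSet([
            ("chr%d" % rng.integers(1, 3), int(s), int(s + rng.integers(1, 50)))
            for s in rng.integers(0, 500, size=100)
        ])
        m1 = merge_intervals(ivs)
        m2 = merge_intervals(m1)
        assert list(m1) == list(m2)
        assert m1.covered_bases() == ivs.covered_bases()

    def test_strand_separation(self):
        merged = merge_intervals(
            IntervalSet([("chr1", 10, 20, "+"), ("chr1", 15, 25, "-")]))
        assert len(merged) == 2


class TestBindingProfiles:
    def test_full_coverage_and_empty(self):
        js = [GenomicJunction("chr1", 1000, 2000, "+")]
        peaks = merge_intervals(IntervalSet([("chr1", 0, 5000)]))
        prof = binding_fraction_profile(js, peaks, "donor", window=50)
        assert (prof.values == 1.0).all()
        prof0 = binding_fraction_profile(js, IntervalSet([]), "donor", window=50)
        assert (prof0.values == 0.0).all()

    def test_partial_coverage_fraction(self):
        js = [GenomicJunction("chr1", 1000, 2000, "+"),
              GenomicJunction("chr1", 5000, 6000, "+")]
        # peak covering +100 (donor-relative, into the intron) for the first only
        peaks = merge_intervals(IntervalSet([("chr1", 1100, 1101)]))
        prof = binding_fraction_profile(js, peaks, "donor", window=500)
        assert prof.loc[100] == 0.5
        assert prof.loc[99] == 0.0

    def test_minus_strand_offsets_flip(self):
        js = [GenomicJunction("chr1", 1000, 2000, "-")]
        # donor of a minus-strand intron is at end-1 = 1999; +10 into the
        # intron means genomic position 1989
        peaks = merge_intervals(IntervalSet([("chr1", 1989, 1990)]))
        prof = binding_fraction_profile(js, peaks, "donor", window=20)
        assert prof.loc[10] == 1.0
        assert prof.loc[-10] == 0.0

    def test_unknown_strand_excluded(self):
        js = [GenomicJunction("chr1", 1000, 2000, ".")]
        prof = binding_fraction_profile(js, IntervalSet([("chr1", 0, 5000)]),
                                        "donor", window=10)
        assert (prof.values == 0.0).all()


class TestFractionBound:
    def test_peak_at_site(self):
        js = [GenomicJunction("chr1", 1000, 2000, "+")]
        assert fraction_bound_within(js, IntervalSet([("chr1", 1000, 1001)])) == 1.0

    def test_peak_just_outside_radius(self):
        js = [GenomicJunction("chr1", 1000, 2000, "+")]
        # [site-250, site+250) = [750, 1250); peak at 1250 misses
        assert fraction_bound_within(js, IntervalSet([("chr1", 1250, 1260)])) == 0.0
        assert fraction_bound_within(js, IntervalSet([("chr1", 1249, 1260)])) == 1.0

    def test_empty_peaks(self):
        js = [GenomicJunction("chr1", 1000, 2000, "+")]
        assert fraction_bound_within(js, IntervalSet([])) == 0.0


class TestDonorPpm:
    def test_identical_sequences(self):
        store = SequenceStore({"c1": "A" * 100 + "ACGT" * 30, "c2": "A" * 100 + "ACGT" * 30})
        js = [GenomicJunction("c1", 100, 200, "+"),
              GenomicJunction("c2", 100, 200, "+")]
        ppm = donor_downstream_ppm(js, store, length=8)
        for pos, base in enumerate("ACGTACGT"):
            assert ppm.loc[pos, base] == 1.0

    def test_split_position(self):
        store = SequenceStore({"c1": "A" * 20, "c2": "C" + "A" * 19})
        js = [GenomicJunction("c1", 0, 20, "+"), GenomicJunction("c2", 0, 20, "+")]
        ppm = donor_downstream_ppm(js, store, length=5)
        assert ppm.loc[0, "A"] == 0.5 and ppm.loc[0, "C"] == 0.5

    def test_minus_strand_reverse_complement(self):
        # minus-strand donor at end: downstream intron = revcomp of the
        # final bases
        store = SequenceStore({"c1": "A" * 15 + "TTTTT"})
        js = [GenomicJunction("c1", 0, 20, "-")]
        ppm = donor_downstream_ppm(js, store, length=5)
        assert (ppm["A"].values == 1.0).all()

    def test_columns_sum_to_one_and_ns_excluded(self):
        store = SequenceStore({"c1": "NNACG" + "A" * 20})
        js = [GenomicJunction("c1", 0, 20, "+")]
        ppm = donor_downstream_ppm(js, store, length=5)
        assert ppm.iloc[0].sum() == 0.0  # all-N position has no denominator
        assert np.allclose(ppm.iloc[2:].sum(axis=1), 1.0)

    def test_truncated_flank_skipped(self):
        store = SequenceStore({"c1": "ACGT"})
        js = [GenomicJunction("c1", 0, 4, "+")]
        ppm = donor_downstream_ppm(js, store, length=50)
        assert (ppm.values == 0).all()


class TestBackgroundExons:
    def test_deterministic_sampling(self, mini_annotation):
        s1 = sample_background_exons(mini_annotation, n=2, seed=11)
        s2 = sample_background_exons(mini_annotation, n=2, seed=11)
        assert s1 == s2

    def test_internal_exons_only(self, mini_annotation):
        with pytest.warns(UserWarning):
            all_internal = sample_background_exons(mini_annotation, n=100, seed=0)
        # gA and gB each contribute their middle exon; two-exon genes none
        assert ("chr1", 300, 400, "+") in all_internal
        assert ("chr1", 2300, 2400, "-") in all_internal
        assert len(all_internal) == 2


class TestIngestScores:
    def test_join_and_missing_flag(self):
        js = [GenomicJunction("chr1", 10, 20, "+"),
              GenomicJunction("chr1", 30, 40, "+")]
        scores = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10], "end": [20], "score": [0.9]})
        out = ingest_splice_scores(scores, js)
        assert out.loc["chr1:10:20:+", "score"] == 0.9
        assert bool(out.loc["chr1:30:40:+", "missing"])

    def test_out_of_range_score_errors(self):
        scores = pd.DataFrame(
            {"chrom": ["chr1"], "start": [10], "end": [20], "score": [1.2]})
        with pytest.raises(ValueError):
            ingest_splice_scores(scores, [])


class TestEnrichmentTable:
    def test_planted_contrast_detected(self):
        late = ["GTGTGAATGAATGAATGTGT" * 3] * 8
        early = ["TGTGTGTGTGTGTGTGTGTG" * 3] * 8
        table = enrichment_table(late, early).set_index("class")
        assert table.loc["AA", "freq_per_kb_a"] > table.loc["AA", "freq_per_kb_b"]
        assert table.loc["YG", "freq_per_kb_a"] < table.loc["YG", "freq_per_kb_b"]
        assert (table["p_adj"] >= table["p"] - 1e-12).all()
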