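import numpy as np
import pandas as pd
import pytest

from crypticburden.io_formats import CohortDesign, GenomicJunction, JunctionTable
from crypticburden.splicing_core import (
    call_cryptic_events,
    classify_junction,
    classify_junctions,
    compute_psi,
    events_to_frame,
    filter_cluster_junctions,
    normalize_median_of_ratios,
)

from conftest import make_psi_matrix


def _table(cluster_counts, sample_ids=("s1",)):
    """cluster_counts: {cluster: [count, ...]} with one sample."""
    junctions, clusters, rows = [], [], []
    pos = 0
    for cid, counts in cluster_counts.items():
        for c in counts:
            junctions.append(GenomicJunction("chr1", pos * 1000 + 10,
                                             pos * 1000 + 200, "+"))
            clusters.append(cid)
            rows.append([c] * len(sample_ids))
            pos += 1
    return JunctionTable(junctions, clusters, np.array(rows), list(sample_ids))


class TestClusterFilter:
    def test_at_threshold_kept(self):
        t = filter_cluster_junctions(_table({"c1": [9999, 1]}), 1e-4)
        assert t.n_junctions == 2  # 1e-4 fraction is kept (>=)

    def test_below_threshold_removed(self):
        t = filter_cluster_junctions(_table({"c1": [1_000_000, 5]}), 1e-4)
        assert t.n_junctions == 1

    def test_zero_fraction_is_identity(self, simple_table):
        assert filter_cluster_junctions(simple_table, 0.0) is simple_table


class TestComputePsi:
    def test_basic_ratio(self):
        psi = compute_psi(_table({"c1": [30, 70]}), min_cluster_reads=10)
        assert np.allclose(psi.psi.iloc[:, 0].values, [0.3, 0.7])

    def test_low_coverage_missing(self):
        psi = compute_psi(_table({"c1": [1, 2]}), min_cluster_reads=10)
        assert psi.psi.iloc[:, 0].isna().all()

    def test_single_junction_cluster(self):
        psi = compute_psi(_table({"c1": [50]}), min_cluster_reads=10)
        assert psi.psi.iloc[0, 0] == 1.0

    def test_cluster_psi_sums_to_one(self, simple_table):
        psi = compute_psi(simple_table, min_cluster_reads=10)
        clusters = pd.Series(simple_table.cluster_ids, index=psi.psi.index)
        sums = psi.psi.groupby(clusters).sum(min_count=1)
        covered = sums.notna()
        assert np.allclose(sums.values[covered.values], 1.0, atol=1e-9)


def _splice_site_oracle(j, ann):
    """Independent re-derivation of the category from raw annotation sets."""
    hits = [
        g for g, (chrom, strand, gs, ge) in ann.genes.items()
        if chrom == j.chrom and gs < j.end and ge > j.start
        and (j.strand == "." or strand == j.strand)
    ]
    if not hits:
        return "none"
    if len(hits) > 1:
        owning = [
            g for g in hits
            if j.start in (ann.gene_donors[g] | ann.gene_acceptors[g])
            or j.end in (ann.gene_donors[g] | ann.gene_acceptors[g])
        ]
        if len(owning) != 1:
            return "ambig_gene"
        hits = owning
    g = hits[0]
    strand = ann.genes[g][1]
    if (j.start, j.end) in ann.gene_introns[g]:
        return "annotated"
    donor = j.end if strand == "-" else j.start
    acceptor = j.start if strand == "-" else j.end
    dk = donor in ann.gene_donors[g]
    ak = acceptor in ann.gene_acceptors[g]
    if dk and not ak:
        return "novel_acceptor"
    if ak and not dk:
        return "novel_donor"
    if dk and ak:
        if any(j.start < s and e < j.end for s, e in ann.gene_exons[g]):
            return "novel_exon_skip"
        return "novel_combo"
    return "novel_combo"


class TestClassifyJunction:
    @pytest.mark.parametrize(
        "junction, expected",
        [
            (("chr1", 200, 300, "+"), "annotated"),
            (("chr1", 400, 500, "+"), "annotated"),
            # donor matches gA's exon1 end, acceptor 120 bp into the intron
            (("chr1", 200, 320, "+"), "novel_acceptor"),
            # acceptor matches, donor novel
            (("chr1", 220, 300, "+"), "novel_donor"),
            # exon1 donor to exon3 acceptor skips exon2 entirely
            (("chr1", 200, 500, "+"), "novel_exon_skip"),
            # both ends novel within gA
            (("chr1", 210, 330, "+"), "novel_combo"),
            # no gene here
            (("chr1", 5000, 5200, "+"), "none"),
            # minus-strand gene gB: its intron, then a novel acceptor
            (("chr1", 2100, 2300, "-"), "annotated"),
            (("chr1", 2150, 2300, "-"), "novel_acceptor"),
            # overlapping genes gD/gE with neither end a known site
            (("chr3", 430, 580, "+"), "ambig_gene"),
        ],
    )
    def test_categories(self, mini_annotation, junction, expected):
        j = GenomicJunction(*junction)
        assert classify_junction(j, mini_annotation) == expected

    def test_matches_brute_force_oracle(self, mini_annotation):
        rng = np.random.default_rng(42)
        sites = sorted(
            {100, 200, 300, 400, 500, 600, 2000, 2100, 2300, 2400, 2500, 2600}
        )
        junctions = []
        for _ in range(300):
            chrom = rng.choice(["chr1", "chr2", "chr3"])
            a, b = sorted(rng.choice(
                sites + list(rng.integers(50, 3000, size=4)), size=2,
                replace=False))
            if a == b:
                continue
            strand = rng.choice(["+", "-", "."])
            junctions.append(GenomicJunction(str(chrom), int(a), int(b), str(strand)))
        for j in junctions:
            assert classify_junction(j, mini_annotation) == _splice_site_oracle(
                j, mini_annotation
            ), j.id

    def test_every_junction_gets_one_category(self, mini_annotation):
        js = [GenomicJunction("chr1", s, s + 150, ".") for s in range(0, 3000, 97)]
        cats = classify_junctions(js, mini_annotation)
        from crypticburden.splicing_core import JUNCTION_CATEGORIES

        assert cats.isin(JUNCTION_CATEGORIES).all()


class TestCallCrypticEvents:
    def _run(self, control, kd, category="novel_acceptor", **kw):
        psi = make_psi_matrix([[kd, control]], ["kd1", "ctrl1"])
        design = CohortDesign(
            pd.DataFrame({"sample_id": ["kd1", "ctrl1"],
                          "class": ["KD", "control"]})
        )
        cats = pd.Series([category], index=psi.junction_ids)
        return call_cryptic_events(psi, design, cats, **kw)

    def test_event_called_above_thresholds(self):
        events = self._run(0.02, 0.15)
        assert len(events) == 1
        assert events[0].dpsi == pytest.approx(0.13)

    def test_control_psi_gate(self):
        assert self._run(0.06, 0.40) == []

    def test_dpsi_gate(self):
        assert self._run(0.00, 0.08) == []

    def test_annotated_never_called(self):
        assert self._run(0.0, 0.9, category="annotated") == []

    def test_monotone_in_min_dpsi(self):
        loose = self._run(0.01, 0.30, min_dpsi=0.10)
        tight = self._run(0.01, 0.30, min_dpsi=0.40)
        assert len(tight) <= len(loose)

    def test_cassette_pairing(self, mini_annotation):
        # two junctions flanking an unannotated exon inside gA's intron 1:
        # [200,240) ends at exon start 240; [260,300) starts at exon end 260
        psi = make_psi_matrix(
            [[0.3, 0.0], [0.28, 0.0]], ["kd1", "ctrl1"],
            cluster_ids=["cA", "cB"],
        )
        psi.junctions[0] = GenomicJunction("chr1", 200, 240, "+")
        psi.junctions[1] = GenomicJunction("chr1", 260, 300, "+")
        psi.psi.index = [j.id for j in psi.junctions]
        psi.cluster_totals.index = psi.psi.index
        design = CohortDesign(
            pd.DataFrame({"sample_id": ["kd1", "ctrl1"],
                          "class": ["KD", "control"]})
        )
        cats = pd.Series(["novel_acceptor", "novel_donor"],
                         index=psi.junction_ids)
        events = call_cryptic_events(psi, design, cats,
                                     annotation=mini_annotation)
        assert len(events) == 1
        assert not events[0].single_junction
        assert events[0].partner is not None

    def test_unpairable_events_flagged_single(self):
        events = self._run(0.0, 0.5)
        assert events[0].single_junction

    def test_frame_serialisation(self):
        df = events_to_frame(self._run(0.0, 0.5))
        assert df.loc[0, "dpsi"] == pytest.approx(0.5)


class TestMedianOfRatios:
    def test_identical_columns(self):
        sf, norm = normalize_median_of_ratios(
            pd.DataFrame({"a": [10, 20], "b": [10, 20]})
        )
        assert np.allclose(sf.values, 1.0)
        assert np.allclose(norm.values, [[10, 10], [20, 20]])

    def test_proportional_columns(self):
        counts = pd.DataFrame({"a": [10, 100, 7], "b": [20, 200, 14]})
        sf, _ = normalize_median_of_ratios(counts)
        assert np.allclose(sf.values, [1 / np.sqrt(2), np.sqrt(2)])

    def test_single_gene_hand_computed(self):
        sf, _ = normalize_median_of_ratios(pd.DataFrame({"a": [4], "b": [9]}))
        assert np.allclose(sf.values, [4 / 6, 9 / 6])

    def test_no_all_positive_gene_errors(self):
        with pytest.raises(ValueError, match="positive"):
            normalize_median_of_ratios(pd.DataFrame({"a": [0, 5], "b": [3, 0]}))
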