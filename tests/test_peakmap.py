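import numpy as np
import pytest

from setsig.genesets import GeneSet, GeneSetLibrary
from setsig.peakmap import (
    BedParseError,
    GeneModel,
    GeneRecord,
    Peak,
    PeakSet,
    cobound_anchor_fraction,
    overlap_conditioned_enrichment,
    overlap_peaks,
    peaks_to_genes,
    read_bed,
    read_narrowpeak,
    read_genes_bed6,
    venn_counts,
    write_bed,
)
from setsig.synthetic_data import PlantedDesign, make_peaks


def brute_force_overlap(a: PeakSet, b: PeakSet) -> list[Peak]:
    """All-pairs half-open overlap scan; the independent oracle."""
    kept = []
    for p in a:
        for q in b:
            if p.chrom == q.chrom and p.start < q.end and q.start < p.end:
                kept.append(p)
                break
    return kept


def random_peakset(rng, name, n, chroms=("chr1", "chr2"), span=10_000):
    peaks = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        peaks.append(
            Peak(str(rng.choice(chroms)), start, start + int(rng.integers(1, 300)))
        )
    return PeakSet(name=name, peaks=peaks)


class TestBedIO:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t50\t150\nchr1\t100\t200\tpeakA\n")
        ps = read_bed(p)
        assert [(pk.chrom, pk.start, pk.end) for pk in ps] == [
            ("chr1", 100, 200),
            ("chr2", 50, 150),
        ]  # sorted on read
        out = tmp_path / "y.bed"
        write_bed(ps, out)
        assert read_bed(out).peaks == ps.peaks

    def test_inverted_coordinates_error(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":1"):
            read_bed(p)

    def test_non_integer_coordinates_error(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\tabc\t100\n")
        with pytest.raises(BedParseError):
            read_bed(p)

    def test_narrowpeak_requires_ten_columns(self, tmp_path):
        p = tmp_path / "x.narrowPeak"
        p.write_text("chr1\t1\t100\tp1\t0\t.\t5.0\n")
        with pytest.raises(BedParseError):
            read_narrowpeak(p)
        p.write_text("chr1\t1\t100\tp1\t0\t.\t5.0\t3.0\t2.0\t50\n")
        ps = read_narrowpeak(p)
        assert len(ps) == 1 and ps.peaks[0].extra[0] == "p1"

    def test_gene_model_bed6(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t1000\t2000\tg1\t0\t+\nchr1\t5000\t6000\tg2\t0\t-\n")
        gm = read_genes_bed6(p)
        assert len(gm) == 2
        assert gm.records[1].tss == 6000


class TestOverlapPeaks:
    def test_self_overlap_complete(self):
        rng = np.random.default_rng(1)
        a = random_peakset(rng, "a", 50)
        res = overlap_peaks(a, a)
        assert res.fraction_overlapping == 1.0

    def test_disjoint_chromosomes(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        b = PeakSet("b", [Peak("chr2", 0, 100)])
        assert len(overlap_peaks(a, b).kept) == 0

    def test_half_open_bookended(self):
        a = PeakSet("a", [Peak("chr1", 100, 200)])
        touching = PeakSet("b", [Peak("chr1", 199, 300)])
        bookended = PeakSet("c", [Peak("chr1", 200, 300)])
        assert len(overlap_peaks(a, touching).kept) == 1
        assert len(overlap_peaks(a, bookended).kept) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            a = random_peakset(rng, "a", 120)
            b = random_peakset(rng, "b", 120)
            fast = overlap_peaks(a, b).kept.peaks
            assert sorted(fast) == sorted(brute_force_overlap(a, b))

    def test_monotone_as_b_grows(self):
        rng = np.random.default_rng(3)
        a = random_peakset(rng, "a", 100)
        b = random_peakset(rng, "b", 60)
        grown = PeakSet(
            "b2", [Peak(p.chrom, max(0, p.start - 50), p.end + 50) for p in b]
        )
        assert len(overlap_peaks(a, grown).kept) >= len(overlap_peaks(a, b).kept)


class TestVennCounts:
    def test_identical_sets_single_signature(self):
        peaks = [Peak("chr1", i * 1000, i * 1000 + 100) for i in range(5)]
        a, b = PeakSet("a", list(peaks)), PeakSet("b", list(peaks))
        counts = venn_counts([a, b])
        assert set(counts) == {("a", "b")}
        assert counts[("a", "b")] == 10  # 5 peaks from each set

    def test_disjoint_sets_singletons(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        b = PeakSet("b", [Peak("chr1", 1000, 1100)])
        counts = venn_counts([a, b])
        assert counts == {("a",): 1, ("b",): 1}

    def test_planted_colocalization_recovered(self, small_design):
        a, b, _, truth = make_peaks(small_design, n_peaks=400, n_genes=2000)
        counts = venn_counts([a, b])
        # each colocalized pair contributes one ("a","b") signature per source
        n_cobound_sigs = sum(
            n for sig, n in counts.items() if {"FACTOR_A_SYN", "FACTOR_B_SYN"} <= set(sig)
        )
        frac = n_cobound_sigs / 2 / len(a)
        assert frac == pytest.approx(truth["colocalization_fraction"], abs=0.05)

    def test_cobound_anchor_fraction(self):
        shared = [Peak("chr1", 0, 100), Peak("chr1", 1000, 1100)]
        s1, s2 = PeakSet("s1", list(shared)), PeakSet("s2", list(shared))
        anchor = PeakSet("anchor", [Peak("chr1", 0, 100)])
        assert cobound_anchor_fraction([s1, s2], anchor) == pytest.approx(0.5)


PROMOTER_GENES = GeneModel(
    records=[
        GeneRecord("chr1", 5000, 8000, "PLUSGENE", "+"),
        GeneRecord("chr1", 2000, 3000, "MINUSGENE", "-"),
    ]
)


class TestPeaksToGenes:
    def test_plus_strand_promoter_window(self):
        # promoter [4000, 5500): peak [4100, 4200) hits
        ps = PeakSet("p", [Peak("chr1", 4100, 4200)])
        assert peaks_to_genes(ps, PROMOTER_GENES) == {"PLUSGENE"}

    def test_minus_strand_promoter_window(self):
        # TSS 3000, promoter [2500, 4000): peak [3200, 3300) hits
        ps = PeakSet("p", [Peak("chr1", 3200, 3300)])
        assert peaks_to_genes(ps, PROMOTER_GENES) == {"MINUSGENE"}

    def test_far_peak_maps_nothing_even_with_body(self):
        ps = PeakSet("p", [Peak("chr1", 50_000, 50_100)])
        assert peaks_to_genes(ps, PROMOTER_GENES, include_body=True) == frozenset()

    def test_body_only_hit_requires_flag(self):
        ps = PeakSet("p", [Peak("chr1", 7000, 7100)])  # inside PLUSGENE body
        assert peaks_to_genes(ps, PROMOTER_GENES) == frozenset()
        assert peaks_to_genes(ps, PROMOTER_GENES, include_body=True) == {"PLUSGENE"}

    def test_invariant_to_peak_order_and_splitting(self):
        whole = PeakSet("p", [Peak("chr1", 4100, 4300)])
        halves = PeakSet(
            "p", [Peak("chr1", 4200, 4300), Peak("chr1", 4100, 4200)]
        )
        assert peaks_to_genes(whole, PROMOTER_GENES) == peaks_to_genes(
            halves, PROMOTER_GENES
        )


class TestConditionedEnrichment:
    def test_b_equals_a_gives_identical_arms(self, small_design):
        a, b, genes, _ = make_peaks(small_design, n_peaks=200, n_genes=1500)
        lib = GeneSetLibrary(
            "L", [GeneSet.from_symbols("q", [g.name for g in genes][:100])]
        )
        uncond, cond = overlap_conditioned_enrichment(
            a, a, genes, lib, small_design.universe_size
        )
        assert uncond[0].table == cond[0].table

    def test_planted_colocalization_boosts_conditioned_or(self, small_design):
        a, b, genes, truth = make_peaks(small_design, n_peaks=400, n_genes=2000)
        disease = GeneSet.from_symbols("disease", truth["disease_genes_in_model"])
        lib = GeneSetLibrary("L", [disease])
        uncond, cond = overlap_conditioned_enrichment(
            a, b, genes, lib, small_design.universe_size
        )
        assert cond[0].odds_ratio > uncond[0].odds_ratio

    def test_empty_overlap_conditioned_arm_p_one(self):
        a = PeakSet("a", [Peak("chr1", 4100, 4200)])
        b = PeakSet("b", [Peak("chr2", 0, 100)])
        lib = GeneSetLibrary("L", [GeneSet.from_symbols("q", ["PLUSGENE"])])
        _, cond = overlap_conditioned_enrichment(a, b, PROMOTER_GENES, lib, 1000)
        assert cond[0].p == 1.0
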