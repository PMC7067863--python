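"""Consensus building: occurrence filter, merge/recentre, annotation, motifs."""

import numpy as np
import pytest

from meripseq import consensus as cns
from meripseq.detectors import DetectionResult
from meripseq.genomic_io import ConsensusPeak, CoverageTrack, GeneModel
from meripseq.windows import Window


def result(wid, tech="fisher", sample="s1", passed=True):
    return DetectionResult(wid, tech, sample, 0.0, passed)


class TestOccurrenceFilter:
    def results(self, support_by_window, n_samples=6):
        res = []
        for s in range(1, n_samples + 1):
            for wid, samples in support_by_window.items():
                res.append(result(wid, sample=f"s{s}", passed=f"s{s}" in samples))
        return res

    def test_three_of_six_kept(self):
        res = self.results({"w1": {"s1", "s2", "s3"}, "w2": {"s1", "s2"}})
        kept = cns.occurrence_filter(res, min_samples=3)
        assert kept["fisher"] == {"w1"}

    def test_min_one_is_union_of_passes(self):
        res = self.results({"w1": {"s1"}, "w2": set()})
        kept = cns.occurrence_filter(res, min_samples=1)
        assert kept["fisher"] == {"w1"}

    def test_too_few_samples_raises(self):
        res = [result("w1", sample="s1"), result("w1", sample="s2")]
        with pytest.raises(ValueError, match="min_samples"):
            cns.occurrence_filter(res, min_samples=3)


def flat_cov(values, chrom="chr1"):
    return {chrom: np.asarray(values, dtype=float)}


class TestMergeAndRecenter:
    def windows(self, spans):
        return [Window(f"w{i}", "g", "chr1", s, e) for i, (s, e) in enumerate(spans)]

    def test_overlapping_windows_merged(self):
        ws = self.windows([(0, 100), (50, 150)])
        merged = cns.merge_intervals([(w.chrom, w.start, w.end) for w in ws])
        assert merged == [("chr1", 0, 150)]

    def test_book_ended_windows_merged_disjoint_kept(self):
        merged = cns.merge_intervals([("chr1", 0, 100), ("chr1", 100, 200),
                                      ("chr1", 300, 400)])
        assert merged == [("chr1", 0, 200), ("chr1", 300, 400)]

    def test_merge_equals_per_base_union_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(1, 12))
            ivs = []
            for _ in range(n):
                s = int(rng.integers(0, 900))
                ivs.append(("chr1", s, s + int(rng.integers(1, 100))))
            merged = cns.merge_intervals(ivs)
            # oracle: mark covered bases, read off maximal runs
            mask = np.zeros(1000, dtype=bool)
            for _, s, e in ivs:
                mask[s:e] = True
            runs = []
            in_run = False
            for i, v in enumerate(mask):
                if v and not in_run:
                    start, in_run = i, True
                elif not v and in_run:
                    runs.append(("chr1", start, i))
                    in_run = False
            if in_run:
                runs.append(("chr1", start, 1000))
            assert merged == runs

    def test_recenter_at_max_median_coverage(self):
        cov = np.zeros(600)
        cov[200:320] = 1
        cov[260] = 9
        kept = {"fisher": {"w0", "w1"}}
        ws = self.windows([(200, 300), (250, 320)])
        sites = cns.merge_and_recenter(kept, ws, flat_cov(cov))
        (site,) = sites["fisher"]
        assert (site.start, site.end, site.max_cov_pos) == (185, 335, 260)

    def test_tie_breaks_leftmost(self):
        cov = np.zeros(600)
        cov[200:320] = 1
        cov[260] = 9
        cov[280] = 9
        kept = {"fisher": {"w0"}}
        ws = self.windows([(200, 320)])
        (site,) = cns.merge_and_recenter(kept, ws, flat_cov(cov))["fisher"]
        assert site.max_cov_pos == 260 and (site.start, site.end) == (185, 335)

    def test_all_zero_coverage_uses_region_centre(self):
        kept = {"fisher": {"w0"}}
        ws = self.windows([(200, 320)])
        with pytest.warns(UserWarning, match="all-zero"):
            (site,) = cns.merge_and_recenter(kept, ws, flat_cov(np.zeros(600)))["fisher"]
        assert site.max_cov_pos == 260


def site(tech, start, end, chrom="chr1"):
    return cns.CandidateSite(tech, chrom, start, end, 3, (start + end) // 2)


class TestCombineTechniques:
    def test_three_of_four_required(self):
        cov = flat_cov(np.ones(600))
        three = {t: [site(t, 100, 250)] for t in ("fisher", "rpmf", "poi")}
        three["macs2like"] = []
        peaks = cns.combine_techniques(three, cov)
        assert len(peaks) == 1 and peaks[0].n_techniques == 3
        two = {t: [site(t, 100, 250)] for t in ("fisher", "rpmf")}
        two.update({"poi": [], "macs2like": []})
        assert cns.combine_techniques(two, cov) == []

    def test_idempotent_on_identical_sites(self):
        cov = flat_cov(np.ones(600))
        four = {t: [site(t, 100, 250)] for t in
                ("fisher", "rpmf", "poi", "macs2like")}
        peaks = cns.combine_techniques(four, cov)
        assert len(peaks) == 1
        p = peaks[0]
        assert p.end - p.start == 150 and p.n_techniques == 4

    def test_order_invariance(self):
        cov = flat_cov(np.ones(1000))
        sites_a = {
            "fisher": [site("fisher", 100, 250), site("fisher", 500, 650)],
            "rpmf": [site("rpmf", 120, 270)],
            "poi": [site("poi", 90, 240), site("poi", 510, 660)],
            "macs2like": [site("macs2like", 500, 650)],
        }
        sites_b = dict(reversed(list(sites_a.items())))
        pa = cns.combine_techniques(sites_a, cov)
        pb = cns.combine_techniques(sites_b, cov)
        assert [(p.chrom, p.start, p.end) for p in pa] == \
               [(p.chrom, p.start, p.end) for p in pb]

    def test_empty_input(self):
        assert cns.combine_techniques({t: [] for t in ("a", "b", "c")},
                                      flat_cov(np.ones(10))) == []

    def test_clipping_at_chromosome_edge(self):
        cov = flat_cov(np.ones(300))
        four = {t: [site(t, 0, 60)] for t in ("fisher", "rpmf", "poi")}
        peaks = cns.combine_techniques(four, cov, chrom_lengths={"chr1": 300})
        (p,) = peaks
        assert p.start == 0 and p.clipped


@pytest.fixture
def annotated_gene():
    # +strand gene: 5UTR [0,100), CDS [100,400), 3UTR [400,500)
    return GeneModel("g", "chr1", "+", [(0, 500)], cds=[(100, 400)],
                     utr5=[(0, 100)], utr3=[(400, 500)])


class TestRegionAnnotation:
    def peak(self, start, end):
        return ConsensusPeak("chr1", start, end, "g")

    def test_cds_interior(self, annotated_gene):
        assert cns.annotate_region(self.peak(150, 300), annotated_gene) == "CDS"

    def test_precedence_at_cds_3utr_junction(self, annotated_gene):
        assert cns.annotate_region(self.peak(350, 450), annotated_gene) == "3UTR"

    def test_precedence_5utr_over_cds(self, annotated_gene):
        assert cns.annotate_region(self.peak(50, 150), annotated_gene) == "5UTR"

    def test_intronic_peak(self):
        g = GeneModel("g", "chr1", "+", [(0, 100), (400, 500)], cds=[(0, 100)])
        assert cns.annotate_region(self.peak(150, 300), g) == "intron"

    def test_no_overlap_is_intergenic_with_warning(self, annotated_gene):
        with pytest.warns(UserWarning, match="no gene"):
            assert cns.annotate_region(self.peak(900, 1050), annotated_gene) == "intergenic"


class TestMotifScore:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("TTTGGACTTTT", 8),
            ("TTGAACATTGGACATT", 5),
            ("AAAAAAAAAA", 0),
            ("GGACT", 8),
            ("GGAC", 0),  # shorter than any motif's full match
        ],
    )
    def test_weighted_counts(self, seq, expected):
        assert cns.motif_score(seq) == expected

    def test_overlapping_occurrences_counted(self):
        # GAACT starting at 0; GGACT nowhere; GAACA at? sequence GAACTGAACT
        assert cns.motif_score("GAACTGAACT") == 10

    def test_rgacw_flag(self):
        assert cns.rgacw_present("TTGAACTTT")
        assert not cns.rgacw_present("TTTTTTT")

    def test_minus_strand_sequence_is_reverse_complemented(self):
        genome = {"chr1": "A" * 10 + cns.reverse_complement("GGACT") + "A" * 10}
        peak = ConsensusPeak("chr1", 0, 25, "g")
        assert cns.motif_score(cns.peak_sequence(peak, genome, "-")) == 8
        assert cns.motif_score(cns.peak_sequence(peak, genome, "+")) == 0


class TestReferenceOverlap:
    def test_partial_overlap_counts(self):
        peaks = [ConsensusPeak("chr1", 185, 335, "g")]
        frac, flags = cns.reference_overlap(peaks, [("chr1", 300, 400)])
        assert flags == [True] and frac == 1.0

    def test_identical_sets_give_one(self):
        peaks = [ConsensusPeak("chr1", 0, 150, "g"), ConsensusPeak("chr1", 300, 450, "g")]
        frac, _ = cns.reference_overlap(peaks, [("chr1", 0, 150), ("chr1", 300, 450)])
        assert frac == 1.0

    def test_empty_reference_gives_zero(self):
        peaks = [ConsensusPeak("chr1", 0, 150, "g")]
        frac, flags = cns.reference_overlap(peaks, [])
        assert frac == 0.0 and flags == [False]


class TestMetagene:
    @pytest.fixture
    def gene(self):
        return GeneModel("g", "chr1", "+", [(0, 500)], cds=[(100, 400)],
                         utr5=[(0, 100)], utr3=[(400, 500)])

    def test_cds_start_maps_to_one(self, gene):
        peak = ConsensusPeak("chr1", 25, 175, "g")  # midpoint 100 = CDS start
        assert cns.metagene_position(peak, gene) == pytest.approx(1.0)

    def test_middle_of_3utr_maps_to_two_and_a_half(self, gene):
        peak = ConsensusPeak("chr1", 375, 525, "g")  # midpoint 450
        assert cns.metagene_position(peak, gene) == pytest.approx(2.5)

    def test_minus_strand_rightmost_5utr_base_near_zero(self):
        g = GeneModel("g", "chr1", "-", [(0, 500)], cds=[(100, 400)],
                      utr5=[(400, 500)], utr3=[(0, 100)])
        peak = ConsensusPeak("chr1", 424, 574, "g")  # midpoint 499, transcript 5' end
        assert cns.metagene_position(peak, g) == pytest.approx(0.0)

    def test_gene_without_cds_excluded(self):
        g = GeneModel("g", "chr1", "+", [(0, 500)])
        peak = ConsensusPeak("chr1", 100, 250, "g")
        assert cns.metagene_position(peak, g) is None

    def test_positions_in_unit_range(self, default_study, called_peaks):
        _, txm, _ = default_study
        peaks, _ = called_peaks
        pos = cns.metagene_positions(peaks, txm.genes)
        assert len(pos) > 0
        assert all(0.0 <= v < 3.0 for v in pos.values())
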