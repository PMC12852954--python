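"""Fragment-terminus extraction, windowing, anchors and normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ngdscan.fragments import (
    AlignmentRecord,
    alignments_from_bed,
    compute_coverage_anchors,
    extract_fragment_termini,
    filter_alignments,
    gene_end_table,
    normalize_read_ends,
    restrict_to_window,
)
from ngdscan.reference import GeneWindow


def test_flag_filter_keeps_only_primary_mapped():
    recs = [
        AlignmentRecord("c", 0, 10, "+", flags=0),      # primary mapped
        AlignmentRecord("c", 0, 10, "+", flags=256),    # secondary
        AlignmentRecord("c", 0, 10, "+", flags=2048),   # supplementary
        AlignmentRecord("c", 0, 10, "+", flags=1024),   # duplicate
        AlignmentRecord("c", 0, 10, "+", flags=512),    # QC fail
        AlignmentRecord("c", 0, 10, "-", flags=16),     # reverse, primary
    ]
    kept = filter_alignments(recs)
    assert [r.flags for r in kept] == [0, 16]


class TestTerminusExtraction:
    """Background-dependent strand logic for fragment termini."""

    read_plus = AlignmentRecord("c", 100, 400, "+")
    read_minus = AlignmentRecord("c", 100, 400, "-")

    @pytest.mark.parametrize(
        "background,gene_strand,read,expected",
        [
            # + gene: 5'-fragment 3' terminus is the rightmost aligned base
            ("ski2_deficient", "+", read_plus, 399),   # sense read 3' end
            ("ski2_deficient", "+", read_minus, 399),  # antisense read 5' end
            ("xrn1_deficient", "+", read_plus, 100),   # sense read 5' end
            ("xrn1_deficient", "+", read_minus, 100),  # antisense read 3' end
            # - gene: orientations swap but the same cDNA maps the same end
            ("ski2_deficient", "-", read_minus, 100),
            ("ski2_deficient", "-", read_plus, 100),
            ("xrn1_deficient", "-", read_minus, 399),
            ("xrn1_deficient", "-", read_plus, 399),
        ],
    )
    def test_background_by_strand_cases(self, background, gene_strand, read, expected):
        assert extract_fragment_termini([read], gene_strand, background) == [expected]

    def test_sense_antisense_partitions_agree(self, small_study):
        """Both cDNA strands of the same fragments give identical profiles."""
        ref = small_study.reference
        windows = {w.gene_id: w for w in ref.windows}
        bg = "ski2_deficient"
        bed = small_study.fragments[bg]["ko_rep1"]
        truth = small_study.fragment_truth.query(
            "background == @bg and sample == 'ko_rep1'"
        )
        checked = 0
        for gene_id, tt in truth.groupby("gene_id"):
            w = windows[gene_id]
            # rebuild the two cDNA strands of every fragment of this gene
            frags = bed[bed["name"].str.startswith(f"{gene_id}_frag")]
            sense, anti = [], []
            for _, row in frags.iterrows():
                for container, strand in ((sense, w.strand),
                                          (anti, "-" if w.strand == "+" else "+")):
                    container.append(
                        AlignmentRecord(row["chrom"], row["start"], row["end"], strand)
                    )
            p_sense = restrict_to_window(
                extract_fragment_termini(sense, w.strand, bg), w, bg
            )
            p_anti = restrict_to_window(
                extract_fragment_termini(anti, w.strand, bg), w, bg
            )
            assert p_sense.counts == p_anti.counts
            checked += 1
            if checked >= 10:
                break

    def test_unknown_background_rejected(self):
        with pytest.raises(ValueError):
            extract_fragment_termini([self.read_plus], "+", "dom34_deficient")


class TestWindowRestriction:
    window = GeneWindow("g", "c", "+", 0, 1000)  # window = [700, 1000)

    def test_inside_counted_outside_discarded(self):
        # relative -150 -> genomic 850; -301 -> 699 (outside); +5 in UTR -> 1004
        profile = restrict_to_window([850, 699, 1004], self.window)
        assert profile.counts == {-150: 1}
        assert profile.total_ends == 1

    def test_boundary_at_minus_300_inclusive(self):
        profile = restrict_to_window([700], self.window)
        assert profile.counts == {-300: 1}

    def test_total_invariant_under_permutation(self):
        termini = [850, 999, 850, 700, 980]
        a = restrict_to_window(termini, self.window)
        b = restrict_to_window(termini[::-1], self.window)
        assert a.counts == b.counts


class TestCoverageAnchors:
    def test_uniform_depth(self):
        w = GeneWindow("g", "c", "+", 100, 400)
        recs = [AlignmentRecord("c", 50, 450, "+") for _ in range(10)]
        anchors = compute_coverage_anchors(recs, w)
        assert anchors.cov_start == anchors.cov_stop == anchors.cov_cds == 10

    def test_no_reads_gives_zero(self):
        w = GeneWindow("g", "c", "+", 100, 400)
        anchors = compute_coverage_anchors([], w)
        assert anchors.cov_start == anchors.cov_stop == anchors.cov_cds == 0

    def test_partial_start_codon_coverage(self):
        # 2 reads cover all 3 start-codon bases, 1 covers only the first:
        # per-base depths 3,2,2 -> mean 7/3
        w = GeneWindow("g", "c", "+", 100, 400)
        recs = [
            AlignmentRecord("c", 100, 400, "+"),
            AlignmentRecord("c", 100, 400, "+"),
            AlignmentRecord("c", 100, 101, "+"),
        ]
        anchors = compute_coverage_anchors(recs, w)
        assert anchors.cov_start == pytest.approx(7 / 3)

    def test_minus_strand_start_codon_at_right_edge(self):
        w = GeneWindow("g", "c", "-", 100, 400)
        recs = [AlignmentRecord("c", 397, 400, "+")]  # covers start codon only
        anchors = compute_coverage_anchors(recs, w)
        assert anchors.cov_start == 1
        assert anchors.cov_stop == 0


class TestNormalization:
    window = GeneWindow("g", "c", "+", 0, 1000)

    def _profile(self, n_ends):
        termini = [999] * n_ends
        return restrict_to_window(termini, self.window, "ski2_deficient")

    def _anchors(self, value):
        recs = [AlignmentRecord("c", 0, 1000, "+") for _ in range(value)]
        return compute_coverage_anchors(recs, self.window)

    def test_normalized_total(self):
        norm = normalize_read_ends(self._profile(20), self._anchors(40))
        assert norm.total_norm_ends == pytest.approx(0.5)
        assert norm.anchor_used == "cov_start"

    def test_twenty_percent_boundary(self):
        norm = normalize_read_ends(self._profile(10), self._anchors(50))
        assert norm.total_norm_ends == pytest.approx(0.2)

    def test_zero_anchor_undefined(self, caplog):
        with caplog.at_level("WARNING"):
            norm = normalize_read_ends(self._profile(5), self._anchors(0))
        assert norm is None
        assert "anchor is 0" in caplog.text

    def test_xrn1_uses_stop_anchor(self):
        profile = restrict_to_window([999] * 10, self.window, "xrn1_deficient")
        recs = [AlignmentRecord("c", 997, 1000, "+") for _ in range(4)]
        anchors = compute_coverage_anchors(recs, self.window)
        norm = normalize_read_ends(profile, anchors)
        assert norm.anchor_used == "cov_stop"
        assert norm.total_norm_ends == pytest.approx(10 / 4)


def test_extraction_matches_simulated_ground_truth(small_study):
    """Extracted termini equal the simulator's cleavage coordinates exactly
    (multiset equality) for every gene, both backgrounds."""
    ref = small_study.reference
    windows = {w.gene_id: w for w in ref.windows}
    for bg in ("ski2_deficient", "xrn1_deficient"):
        bed = small_study.fragments[bg]["ko_rep1"]
        aln = alignments_from_bed(bed)
        truth = small_study.fragment_truth.query(
            "background == @bg and sample == 'ko_rep1'"
        )
        table = gene_end_table(aln, ref.windows, bg)
        for gene_id, tt in truth.groupby("gene_id"):
            w = windows[gene_id]
            sub = [a for a in aln if a.start < w.cds_end and a.end > w.cds_start]
            profile = restrict_to_window(
                extract_fragment_termini(sub, w.strand, bg), w, bg
            )
            expected = (
                tt["terminus_genomic"].map(w.genomic_to_relative).value_counts()
            )
            assert profile.counts == expected.to_dict()
            assert table.loc[gene_id, "total_ends"] == len(tt)


@settings(deadline=None, max_examples=40)
@given(
    ends=st.lists(st.integers(700, 999), min_size=0, max_size=50),
    anchor=st.integers(1, 60),
)
def test_normalized_total_scales_linearly(ends, anchor):
    window = GeneWindow("g", "c", "+", 0, 1000)
    profile = restrict_to_window(ends, window)
    recs = [AlignmentRecord("c", 0, 1000, "+") for _ in range(anchor)]
    anchors = compute_coverage_anchors(recs, window)
    norm = normalize_read_ends(profile, anchors)
    assert norm.total_norm_ends == pytest.approx(len(ends) / anchor)
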