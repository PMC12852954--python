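"""Synthetic-study generator: determinism, geometry and ground truth."""

import numpy as np
import pandas as pd
import pytest

from ngdscan import fragments as fr
from ngdscan.calling import cleavage_score
from ngdscan.simulate import (
    SimConfig,
    simulate_5pseq,
    simulate_fragment_library,
    simulate_reference,
    simulate_study,
    write_study,
)


class TestSimConfig:
    def test_class_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(class_mix=(0.5, 0.5, 0.5))

    def test_fold_excess_floor(self):
        with pytest.raises(ValueError):
            SimConfig(fold_excess=0.5)

    def test_queue_must_fit_window(self):
        with pytest.raises(ValueError):
            SimConfig(footprint_nt=60, max_queue=5)

    def test_rqt_deficiency_shifts_offset_weights(self):
        assert SimConfig(rqt_deficient=True).offset_weights == (0.1, 0.9)
        assert SimConfig().offset_weights == (0.5, 0.5)


class TestReference:
    def test_exact_class_allocation(self):
        ref = simulate_reference(SimConfig(n_genes=100, class_mix=(0.3, 0.3, 0.4)))
        counts = ref.genes["class"].value_counts()
        assert counts["strong"] == 30
        assert counts["mild"] == 30
        assert counts["not"] == 40

    def test_strong_genes_have_strong_terminal_codons(self):
        ref = simulate_reference(SimConfig(n_genes=60))
        strong = ref.genes[ref.genes["class"] == "strong"]
        assert set(strong["terminal_codon"]) <= {"AAA", "AGG", "CGT"}

    def test_targets_only_among_strong(self):
        ref = simulate_reference(SimConfig(n_genes=60))
        assert (ref.genes.loc[ref.genes["is_target"], "class"] == "strong").all()

    def test_annotation_consistent_with_genome(self):
        ref = simulate_reference(SimConfig(n_genes=20, seed=4))
        comp = str.maketrans("ACGT", "TGCA")
        for (gid, chrom, s, e, strand), rec in zip(ref.cds_annotation, ref.records):
            genomic = ref.genome[chrom][s:e]
            if strand == "-":
                genomic = genomic.translate(comp)[::-1]
            assert genomic == rec.sequence

    def test_same_seed_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            write_study(simulate_study(SimConfig(n_genes=15, depth=30, seed=5)),
                        tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seeds_differ(self):
        a = simulate_reference(SimConfig(n_genes=15, seed=1))
        b = simulate_reference(SimConfig(n_genes=15, seed=2))
        assert a.genome != b.genome


class TestFragmentLibrary:
    def test_zero_depth_errors(self):
        cfg = SimConfig(n_genes=10, depth=0)
        ref = simulate_reference(cfg)
        with pytest.raises(ValueError):
            simulate_fragment_library(cfg, ref, "ski2_deficient")

    def test_single_site_no_noise_forces_terminus(self):
        """With one ribosome and one anchor every fragment ends at the
        configured cleavage site."""
        cfg = SimConfig(
            n_genes=8, depth=40, max_queue=1,
            cleavage_offset_model=(1.0, 0.0), seed=3,
        )
        ref = simulate_reference(cfg)
        samples, truth = simulate_fragment_library(cfg, ref, "ski2_deficient")
        # j is always 1, anchor always near-E-site: site = -9 - footprint
        expected = -9 - cfg.footprint_nt
        assert (truth["cleavage_rel"] == expected).all()
        windows = {w.gene_id: w for w in ref.windows}
        for _, row in truth.iterrows():
            w = windows[row["gene_id"]]
            assert w.genomic_to_relative(row["terminus_genomic"]) == expected

    def test_every_emitted_terminus_in_truth(self, small_study):
        """Extraction recovers exactly the multiset of true termini."""
        ref = small_study.reference
        for bg in ("ski2_deficient", "xrn1_deficient"):
            for sample in ("ko_rep1", "ctrl_rep2"):
                bed = small_study.fragments[bg][sample]
                truth = small_study.fragment_truth.query(
                    "background == @bg and sample == @sample"
                )
                table = fr.gene_end_table(
                    fr.alignments_from_bed(bed), ref.windows, bg
                )
                expected = truth.groupby("gene_id").size()
                got = table["total_ends"]
                assert got.sum() == len(truth)
                assert (expected.reindex(got.index).fillna(0) == got).all()

    def test_fold_excess_three_gives_score_near_three_quarters(self):
        """A 3-fold fragment excess yields cleavage scores within 0.05 of
        the binomial expectation 0.75 at >= 200 fragments per gene."""
        cfg = SimConfig(
            n_genes=30, depth=700, fold_excess=3.0, target_fraction=1.0, seed=13,
        )
        ref = simulate_reference(cfg)
        samples, _ = simulate_fragment_library(cfg, ref, "ski2_deficient")
        bg = "ski2_deficient"
        ko = fr.gene_end_table(
            fr.alignments_from_bed(samples["ko_rep1"]), ref.windows, bg
        )
        ctrl = fr.gene_end_table(
            fr.alignments_from_bed(samples["ctrl_rep1"]), ref.windows, bg
        )
        targets = ref.genes.index[ref.genes["is_target"]]
        assert ko.loc[targets, "total_ends"].mean() >= 200
        scores = np.array(
            [
                cleavage_score(ko.loc[g, "sum_norm_ends"], ctrl.loc[g, "sum_norm_ends"])
                for g in targets
            ]
        )
        assert np.all(np.abs(scores - 0.75) <= 0.05)
        non_targets = ref.genes.index[~ref.genes["is_target"]]
        if len(non_targets):
            nt_scores = np.array(
                [
                    cleavage_score(
                        ko.loc[g, "sum_norm_ends"], ctrl.loc[g, "sum_norm_ends"]
                    )
                    for g in non_targets
                ]
            )
            # equal rates: expected score 0.5 for the non-target group
            assert abs(nt_scores.mean() - 0.5) <= 0.05

    def test_xrn1_trim_noise_moves_termini_downstream_only(self):
        cfg = SimConfig(n_genes=10, depth=60, trim_noise_sd=4.0, seed=8)
        ref = simulate_reference(cfg)
        _, truth = simulate_fragment_library(cfg, ref, "xrn1_deficient")
        windows = {w.gene_id: w for w in ref.windows}
        shifts = []
        for _, row in truth.iterrows():
            w = windows[row["gene_id"]]
            rel = w.genomic_to_relative(row["terminus_genomic"])
            if rel is None:  # trimmed past the stop codon
                continue
            shifts.append(rel - row["cleavage_rel"])
        shifts = np.array(shifts)
        assert (shifts >= 0).all()  # trimming is 5'->3' only
        assert shifts.max() > 0  # and actually happens at sd=4


class TestFivePSeq:
    def test_strong_gene_comb_spacing(self, small_study):
        cfg = small_study.config
        mat = small_study.fivepseq["new1d"]
        strong = small_study.reference.genes.query("`class` == 'strong'").index
        pooled = mat.loc[strong].sum(axis=0)
        peaks = pooled[pooled > 0].index.to_numpy()
        assert set(np.diff(sorted(peaks))) <= {cfg.footprint_nt}
        assert -17 in peaks

    def test_not_class_single_terminating_peak(self, small_study):
        mat = small_study.fivepseq["new1d"]
        not_genes = small_study.reference.genes.query("`class` == 'not'").index
        pooled = mat.loc[not_genes].sum(axis=0)
        assert pooled[pooled > 0].index.tolist() == [-17]

    def test_wildtype_mostly_terminating(self, small_study):
        mat = small_study.fivepseq["wt"]
        pooled = mat.sum(axis=0)
        assert pooled[-17] / pooled.sum() > 0.9


def test_wig_roundtrip_preserves_counts(tmp_path, small_study):
    from ngdscan.simulate import read_wig, write_wig

    counts = small_study.fivepseq["new1d"]
    windows = small_study.reference.windows
    path = tmp_path / "t.wig"
    write_wig(counts, windows, path)
    back = read_wig(path, windows)
    assert np.allclose(back.loc[counts.index], counts)


def test_study_writer_emits_expected_files(tmp_path, small_config):
    from ngdscan.simulate import SimConfig

    study = simulate_study(SimConfig(n_genes=10, depth=30, seed=21))
    write_study(study, tmp_path)
    names = {p.name for p in tmp_path.iterdir()}
    expected = {
        "genome.fa", "cds.fasta", "cds.bed", "utr3.bed", "annotation.gff3",
        "manifest.yaml", "truth_genes.tsv", "truth_fragments.tsv", "pars.tsv",
        "crac.ko.bedgraph", "crac.wt.bedgraph",
        "fivepseq.new1d.wig", "fivepseq.wt.wig",
    }
    assert expected <= names
    beds = [n for n in names if n.endswith(".bed") and "deficient" in n]
    assert len(beds) == 8  # 2 backgrounds x (ko, ctrl) x 2 replicates
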