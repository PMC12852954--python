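"""Seeded synthetic study generator with known ground truth.

Generates everything the pipeline consumes — a reference genome with
annotated CDS and 3'-UTRs, long-read alignments containing decay
fragments whose termini are drawn from collided-ribosome geometry, 5PSeq
5'-end tracks with footprint-spaced combs, paired CRAC coverage tracks
with configurable 3'-UTR enrichment, and PARS-like per-nucleotide scores
with a structure bump upstream of the stop codon — so every stage is
testable without external downloads.

Collision geometry
------------------
The stalled ribosome holds the stop codon (positions -3..-1) in its
A-site; the 5' boundary of its footprint sits near -17.  Collided
ribosome ``j`` (j = 1.. queue length) adds one footprint (default 30 nt)
upstream.  Cleavage on a given transcript happens within collided
ribosome ``j`` either a few nucleotides 5' of that ribosome's E-site
(``-9 - j*footprint``) or at its footprint 5'-end (``-17 - j*footprint``);
the mixture shifts toward footprint 5'-ends when the RQT-deficient flag is
set, as splitting-dependent within-ribosome cleavage is lost.

Cleavage converts transcripts into fragments rather than adding reads, so
coverage anchors count full-length transcripts plus fragments and the
expected cleavage score of a target with a k-fold fragment excess is
exactly k/(k+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .pars import ParsTrack
from .reference import (
    STOP_CODONS,
    CODON_CLASSES,
    CdsRecord,
    GeneWindow,
    build_last300_windows,
)

CLASS_ORDER = ("strong", "mild", "not")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults model a New1-deficient yeast experiment: two replicates per
    strain, 200 sequenced transcripts per gene per sample, a 30-nt
    ribosome footprint with queues of up to five collided ribosomes, a 10%
    baseline cleavage rate and a 4-fold fragment excess on target genes in
    the knockout.
    """

    n_genes: int = 200
    #: proportions of strong/mild/not terminal-codon classes
    class_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    #: share of strong-class genes simulated as NGD targets
    target_fraction: float = 0.5
    footprint_nt: int = 30
    max_queue: int = 5
    #: mixture weights over (near-E-site, footprint 5'-end) cleavage anchors
    cleavage_offset_model: tuple[float, float] = (0.5, 0.5)
    #: RQT-deficient strains lose within-ribosome cleavage: weights shift
    #: toward footprint 5'-ends
    rqt_deficient: bool = False
    #: knockout/control fragment-rate ratio for targets
    fold_excess: float = 4.0
    #: transcripts sequenced per gene per sample (full-length + fragments)
    depth: int = 200
    #: per-transcript cleavage probability in control samples
    base_cleave_prob: float = 0.1
    n_replicates: int = 2
    #: share of reads from second-strand (sense) cDNA
    sense_fraction: float = 0.5
    #: sd (nt) of Dxo1-like 5'-trimming of 3'-fragments (xrn1 background)
    trim_noise_sd: float = 0.0
    #: CRAC 3'-UTR coverage fold in the knockout for strong-class genes
    utr_enrichment: float = 4.0
    #: PARS score offset added for targets inside pars_bump_window
    pars_bump: float = 0.5
    pars_bump_window: tuple[int, int] = (-17, -11)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if self.footprint_nt < 15:
            raise ValueError("footprint_nt must be >= 15")
        if self.fold_excess < 1:
            raise ValueError("fold_excess must be >= 1")
        if 17 + self.max_queue * self.footprint_nt > 300:
            raise ValueError("queue geometry exceeds the 300 nt window")

    def cleavage_site(self, ribosome_j: int, anchor: int) -> int:
        """Stop-relative cleavage position within collided ribosome j for
        anchor 0 (near E-site) or 1 (footprint 5'-end)."""
        base = -9 if anchor == 0 else -17
        return base - ribosome_j * self.footprint_nt

    @property
    def offset_weights(self) -> tuple[float, float]:
        return (0.1, 0.9) if self.rqt_deficient else self.cleavage_offset_model


def _allocate_classes(n_genes: int, mix: tuple[float, float, float]) -> list[str]:
    """Largest-remainder allocation: exact class counts for exact mixes."""
    raw = [n_genes * p for p in mix]
    counts = [int(math.floor(x)) for x in raw]
    short = n_genes - sum(counts)
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:short]:
        counts[i] += 1
    labels = []
    for cls, n in zip(CLASS_ORDER, counts):
        labels.extend([cls] * n)
    return labels


@dataclass
class SimReference:
    """Synthetic genome, annotation and per-gene ground truth."""

    genome: dict[str, str]
    cds_annotation: list[tuple]
    utr3_annotation: list[tuple]
    tx_annotation: list[tuple]
    records: list[CdsRecord]
    genes: pd.DataFrame

    @property
    def windows(self) -> list[GeneWindow]:
        return build_last300_windows(self.cds_annotation)


_SENSE = sorted(set().union(*CODON_CLASSES.values()))
_NONSTOP_BY_CLASS = {c: sorted(m) for c, m in CODON_CLASSES.items()}


def simulate_reference(config: SimConfig) -> SimReference:
    """Generate genes with configured terminal-codon classes on one
    synthetic chromosome; deterministic under the config seed."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    labels = _allocate_classes(config.n_genes, config.class_mix)
    strong_ids = [i for i, c in enumerate(labels) if c == "strong"]
    n_targets = int(round(config.target_fraction * len(strong_ids)))
    target_ids = set(
        rng.choice(strong_ids, size=n_targets, replace=False).tolist()
        if n_targets
        else []
    )

    chrom = "chrS"
    pieces: list[str] = []
    pos = 0
    cds_ann, utr3_ann, tx_ann = [], [], []
    records, rows = [], []
    stops = sorted(STOP_CODONS)
    for i, cls in enumerate(labels):
        gene_id = f"G{i + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_codons = int(rng.integers(160, 421))  # 480..1263 nt incl. stop
        terminal = _NONSTOP_BY_CLASS[cls][
            int(rng.integers(len(_NONSTOP_BY_CLASS[cls])))
        ]
        stop = stops[int(rng.integers(3))]
        internal = rng.choice(_SENSE, size=n_codons - 3).tolist()
        cds_seq = "ATG" + "".join(internal) + terminal + stop
        utr5 = "".join(rng.choice(list("ACGT"), size=30))
        utr3_len = int(rng.integers(50, 301))
        utr3 = "".join(rng.choice(list("ACGT"), size=utr3_len))
        gap = "".join(rng.choice(list("ACGT"), size=100))

        tx_fwd = utr5 + cds_seq + utr3  # transcript in its own 5'->3' sense
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            tx_genomic = tx_fwd.translate(comp)[::-1]
        else:
            tx_genomic = tx_fwd
        tx_start = pos
        tx_end = pos + len(tx_fwd)
        if strand == "+":
            cds_start = tx_start + 30
            cds_end = tx_end - utr3_len
            utr3_iv = (cds_end, tx_end)
        else:
            cds_start = tx_start + utr3_len
            cds_end = tx_end - 30
            utr3_iv = (tx_start, cds_start)
        pieces.append(tx_genomic + gap)
        pos = tx_end + 100

        cds_ann.append((gene_id, chrom, cds_start, cds_end, strand))
        utr3_ann.append((gene_id, chrom, utr3_iv[0], utr3_iv[1], strand))
        tx_ann.append((gene_id, chrom, tx_start, tx_end, strand))
        records.append(CdsRecord(gene_id, cds_seq, status="verified"))
        rows.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "is_target": i in target_ids,
                "terminal_codon": terminal,
                "stop_codon": stop,
                "strand": strand,
                "cds_len": len(cds_seq),
                "utr3_len": utr3_len,
            }
        )
    genome = {chrom: "".join(pieces)}
    genes = pd.DataFrame(rows).set_index("gene_id")
    return SimReference(genome, cds_ann, utr3_ann, tx_ann, records, genes)


def _draw_queue_position(rng, max_queue: int, p_stop: float = 0.45) -> int:
    """Truncated geometric draw of the collided-ribosome index j >= 1."""
    j = 1
    while j < max_queue and rng.random() > p_stop:
        j += 1
    return j


def simulate_fragment_library(
    config: SimConfig,
    ref: SimReference,
    background: str,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Aligned reads (BED-like frames) for knockout and control samples.

    Per gene and sample, ``depth`` transcripts are sequenced; each is
    cleaved with probability ``base_cleave_prob`` (times ``fold_excess``
    for targets in knockout samples).  The ski2 background stabilises
    5'-fragments (terminus = cleavage site, at the fragment's 3' end), the
    xrn1 background 3'-fragments (terminus at the 5' end, with optional
    Gaussian trimming toward 3').  Reads are emitted as sense or antisense
    cDNA per ``sense_fraction``.

    Returns ``(alignments_by_sample, truth_fragments)`` where the truth
    table records every fragment's gene, sample, intended stop-relative
    cleavage site and realised genomic terminus.
    """
    if background not in ("ski2_deficient", "xrn1_deficient"):
        raise ValueError(f"unknown background {background!r}")
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    bg_tag = 1 if background == "ski2_deficient" else 2
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, bg_tag]))
    windows = {w.gene_id: w for w in ref.windows}
    tx_iv = {g: (s, e) for g, _, s, e, _ in ref.tx_annotation}
    w_e, w_f = config.offset_weights
    p_e = w_e / (w_e + w_f)

    samples: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for cond in ("ko", "ctrl"):
        for rep in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{rep}"
            rows = []
            for gene_id, g in ref.genes.iterrows():
                w = windows[gene_id]
                tx_start, tx_end = tx_iv[gene_id]
                p = config.base_cleave_prob * (
                    config.fold_excess if (g["is_target"] and cond == "ko") else 1.0
                )
                n_frag = int(rng.binomial(config.depth, min(p, 1.0)))
                n_full = config.depth - n_frag
                strand = g["strand"]
                for k in range(n_frag):
                    j = _draw_queue_position(rng, config.max_queue)
                    anchor = 0 if rng.random() < p_e else 1
                    rel = config.cleavage_site(j, anchor)
                    gpos = w.relative_to_genomic(rel)
                    if background == "ski2_deficient":
                        # 5'-fragment: transcript 5' end .. cleavage site
                        if strand == "+":
                            start, end = tx_start, gpos + 1
                        else:
                            start, end = gpos, tx_end
                        terminus = gpos
                    else:
                        # 3'-fragment: cleavage site .. transcript 3' end
                        trim = 0
                        if config.trim_noise_sd > 0:
                            trim = int(abs(rng.normal(0, config.trim_noise_sd)))
                        if strand == "+":
                            start, end = gpos + trim, tx_end
                            start = min(start, end - 1)
                            terminus = start
                        else:
                            start, end = tx_start, gpos + 1 - trim
                            end = max(end, start + 1)
                            terminus = end - 1
                    sense = rng.random() < config.sense_fraction
                    align_strand = strand if sense else ("-" if strand == "+" else "+")
                    rows.append(
                        (w.chrom, start, end, f"{gene_id}_frag{k}", 0, align_strand)
                    )
                    truth_rows.append(
                        {
                            "background": background,
                            "sample": sample,
                            "gene_id": gene_id,
                            "ribosome_j": j,
                            "cleavage_rel": rel,
                            "terminus_genomic": terminus,
                            "sense": sense,
                        }
                    )
                for k in range(n_full):
                    sense = rng.random() < config.sense_fraction
                    align_strand = strand if sense else ("-" if strand == "+" else "+")
                    rows.append(
                        (w.chrom, tx_start, tx_end, f"{gene_id}_full{k}", 0, align_strand)
                    )
            samples[sample] = pd.DataFrame(
                rows, columns=["chrom", "start", "end", "name", "score", "strand"]
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "background", "sample", "gene_id", "ribosome_j",
            "cleavage_rel", "terminus_genomic", "sense",
        ],
    )
    return samples, truth


# queue-propensity by class: probability that a 5PSeq read reports a
# collided (j >= 1) rather than terminating ribosome, and the geometric
# continuation probability of the queue
_QUEUE_BY_CLASS = {
    "strong": (0.75, 0.65),
    "mild": (0.40, 0.25),
    "not": (0.0, 0.0),
}


def simulate_5pseq(
    config: SimConfig, ref: SimReference
) -> dict[str, pd.DataFrame]:
    """5PSeq 5'-end count matrices (genes x positions -300..-1) for a
    New1-lacking and a wildtype sample.

    5' ends fall at ``-17 - j*footprint_nt`` for ribosome j; queue lengths
    are geometric with class-dependent propensity (strong > mild > not) in
    the knockout, and collapse to the terminating ribosome in wildtype.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    positions = list(range(-300, 0))
    out = {}
    for sample in ("new1d", "wt"):
        mat = np.zeros((len(ref.genes), 300))
        for gi, (gene_id, g) in enumerate(ref.genes.iterrows()):
            p_collide, p_cont = _QUEUE_BY_CLASS[g["class"]]
            if sample == "wt":
                p_collide = 0.02
                p_cont = 0.0
            for _ in range(config.depth):
                if rng.random() < p_collide:
                    j = 1
                    while j < config.max_queue and rng.random() < p_cont:
                        j += 1
                else:
                    j = 0
                rel = -17 - j * config.footprint_nt
                mat[gi, rel + 300] += 1
        out[sample] = pd.DataFrame(
            mat, index=ref.genes.index, columns=positions
        )
    return out


def simulate_crac_coverage(
    config: SimConfig, ref: SimReference
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Paired (knockout, wildtype) CRAC coverage tracks with Poisson noise.

    Strong-class genes get ``utr_enrichment``-fold elevated 3'-UTR
    coverage in the knockout track.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    chrom = next(iter(ref.genome))
    n = len(ref.genome[chrom])
    cov_ko = {chrom: np.zeros(n)}
    cov_wt = {chrom: np.zeros(n)}
    utr_iv = {g: (s, e) for g, _, s, e, _ in ref.utr3_annotation}
    for (gene_id, _, tx_s, tx_e, _), (_, g) in zip(
        ref.tx_annotation, ref.genes.iterrows()
    ):
        lam = rng.uniform(5.0, 30.0)
        u_s, u_e = utr_iv[gene_id]
        base_wt = rng.poisson(lam, size=tx_e - tx_s).astype(float)
        base_ko = rng.poisson(lam, size=tx_e - tx_s).astype(float)
        cov_wt[chrom][tx_s:tx_e] += base_wt
        cov_ko[chrom][tx_s:tx_e] += base_ko
        if g["class"] == "strong" and config.utr_enrichment != 1.0:
            extra = rng.poisson(
                lam * (config.utr_enrichment - 1.0), size=u_e - u_s
            ).astype(float)
            cov_ko[chrom][u_s:u_e] += extra
    return cov_ko, cov_wt


def simulate_pars_track(
    config: SimConfig, ref: SimReference
) -> list[ParsTrack]:
    """Gaussian-baseline PARS-like scores per gene; targets get a
    ``pars_bump`` offset inside ``pars_bump_window`` (UTR-relative
    coordinates, -1 = last CDS nucleotide)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    lo, hi = config.pars_bump_window
    tracks = []
    for gene_id, g in ref.genes.iterrows():
        cds_positions = range(-min(300, int(g["cds_len"])), 0)
        utr_positions = range(1, min(21, int(g["utr3_len"]) + 1))
        scores = {}
        for p in list(cds_positions) + list(utr_positions):
            v = rng.normal(0.0, 1.0)
            if g["is_target"] and lo <= p <= hi:
                v += config.pars_bump
            scores[p] = v
        tracks.append(ParsTrack(gene_id, scores))
    return tracks


@dataclass
class SimStudy:
    """A complete in-memory synthetic study."""

    config: SimConfig
    reference: SimReference
    fragments: dict[str, dict[str, pd.DataFrame]]  # background -> sample -> BED
    fragment_truth: pd.DataFrame
    fivepseq: dict[str, pd.DataFrame]
    crac_ko: dict[str, np.ndarray]
    crac_wt: dict[str, np.ndarray]
    pars_tracks: list = field(default_factory=list)


def simulate_study(config: SimConfig) -> SimStudy:
    """Run every generator with seeds derived from the config seed."""
    ref = simulate_reference(config)
    fragments = {}
    truths = []
    for background in ("ski2_deficient", "xrn1_deficient"):
        samples, truth = simulate_fragment_library(config, ref, background)
        fragments[background] = samples
        truths.append(truth)
    fivepseq = simulate_5pseq(config, ref)
    crac_ko, crac_wt = simulate_crac_coverage(config, ref)
    pars_tracks = simulate_pars_track(config, ref)
    return SimStudy(
        config=config,
        reference=ref,
        fragments=fragments,
        fragment_truth=pd.concat(truths, ignore_index=True),
        fivepseq=fivepseq,
        crac_ko=crac_ko,
        crac_wt=crac_wt,
        pars_tracks=pars_tracks,
    )


def write_wig(counts: pd.DataFrame, windows, path) -> None:
    """Write a stop-relative 5'-end count matrix as a genomic WIG track."""
    by_gene = {w.gene_id: w for w in windows}
    values: dict[str, dict[int, float]] = {}
    for gene_id, row in counts.iterrows():
        w = by_gene[gene_id]
        for rel, v in row.items():
            if v and -w.length <= rel <= -1:
                g = w.relative_to_genomic(int(rel))
                values.setdefault(w.chrom, {})[g + 1] = (
                    values.get(w.chrom, {}).get(g + 1, 0.0) + float(v)
                )
    with open(path, "w") as fh:
        for chrom in sorted(values):
            fh.write(f"variableStep chrom={chrom}\n")
            for gpos in sorted(values[chrom]):
                fh.write(f"{gpos}\t{values[chrom][gpos]:g}\n")


def read_wig(path, windows, window_nt: int = 300) -> pd.DataFrame:
    """Read a WIG 5'-end track back into a stop-relative count matrix."""
    tracks: dict[str, dict[int, float]] = {}
    chrom = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("variableStep"):
                chrom = dict(
                    kv.split("=") for kv in line.split()[1:]
                )["chrom"]
            elif line and chrom is not None:
                p, v = line.split("\t")
                tracks.setdefault(chrom, {})[int(p) - 1] = float(v)
    mat = {}
    for w in windows:
        vec = np.zeros(window_nt)
        for g, v in tracks.get(w.chrom, {}).items():
            rel = w.genomic_to_relative(g)
            if rel is not None:
                vec[rel + window_nt] += v
        mat[w.gene_id] = vec
    return pd.DataFrame.from_dict(
        mat, orient="index", columns=range(-window_nt, 0)
    )


def write_bed(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", header=False, index=False)


def write_bam(frame: pd.DataFrame, genome: Mapping[str, str], path,
              decoys: int = 3) -> None:
    """Write alignments as BAM, injecting flagged decoy records
    (secondary, supplementary, duplicate) that flag filtering must drop."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    refid = {c: i for i, c in enumerate(genome)}
    frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, row in frame.iterrows():
            a = pysam.AlignedSegment()
            a.query_name = str(row["name"])
            a.reference_id = refid[row["chrom"]]
            a.reference_start = int(row["start"])
            a.cigarstring = f"{int(row['end']) - int(row['start'])}M"
            a.flag = 16 if row["strand"] == "-" else 0
            a.mapping_quality = 60
            bam.write(a)
            if i < decoys:
                for extra_flag in (256, 2048, 1024):
                    d = pysam.AlignedSegment()
                    d.query_name = f"{row['name']}_decoy{extra_flag}"
                    d.reference_id = a.reference_id
                    d.reference_start = a.reference_start
                    d.cigarstring = a.cigarstring
                    d.flag = a.flag | extra_flag
                    d.mapping_quality = 0
                    bam.write(d)
    pysam.index(str(path))


def write_study(study: SimStudy, outdir) -> None:
    """Write the full study as plain-text files plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ref = study.reference
    with open(out / "genome.fa", "w") as fh:
        for chrom, seq in ref.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(out / "cds.fasta", "w") as fh:
        for rec in ref.records:
            fh.write(f">{rec.gene_id} {rec.status.capitalize()} ORF\n")
            fh.write(rec.sequence + "\n")
    pd.DataFrame(
        [(c, s, e, g, 0, st) for g, c, s, e, st in ref.cds_annotation]
    ).to_csv(out / "cds.bed", sep="\t", header=False, index=False)
    pd.DataFrame(
        [(c, s, e, g, 0, st) for g, c, s, e, st in ref.utr3_annotation]
    ).to_csv(out / "utr3.bed", sep="\t", header=False, index=False)
    with open(out / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for g, c, s, e, st in ref.cds_annotation:
            fh.write(
                f"{c}\tngdscan-sim\tCDS\t{s + 1}\t{e}\t.\t{st}\t0\tID={g}\n"
            )
    manifest: dict = {"seed": study.config.seed, "samples": {}}
    for background, samples in study.fragments.items():
        for sample, frame in samples.items():
            name = f"{background}.{sample}.bed"
            write_bed(frame, out / name)
            manifest["samples"][name] = {
                "background": background,
                "condition": "knockout" if sample.startswith("ko") else "control",
                "replicate": int(sample.rsplit("rep", 1)[1]),
            }
    windows = ref.windows
    for sample, counts in study.fivepseq.items():
        write_wig(counts, windows, out / f"fivepseq.{sample}.wig")
    from .crac import write_bedgraph

    write_bedgraph(study.crac_ko, out / "crac.ko.bedgraph")
    write_bedgraph(study.crac_wt, out / "crac.wt.bedgraph")
    from .pars import write_pars_tsv

    write_pars_tsv(study.pars_tracks, out / "pars.tsv")
    ref.genes.to_csv(out / "truth_genes.tsv", sep="\t")
    study.fragment_truth.to_csv(out / "truth_fragments.tsv", sep="\t", index=False)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
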