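"""Candidate endonucleolytic fragment termini from aligned long reads.

Decay intermediates of no-go decay are sequenced as cDNA from both strands,
so the biologically meaningful fragment terminus maps to a different read
end depending on (a) which exonuclease background stabilised the fragment
and (b) the alignment orientation relative to the gene:

* ``ski2_deficient`` — the 5'-fragment is stabilised and its 3' terminus is
  the cleavage site: take the 3'-end of sense reads (second-strand cDNA)
  and the 5'-end of antisense reads (first-strand cDNA).
* ``xrn1_deficient`` — the 3'-fragment is stabilised and its 5' terminus is
  the cleavage site: take the 5'-end of sense reads and the 3'-end of
  antisense reads.

"Read 5'/3' end" is in the read's own orientation mapped to the genome; the
terminus coordinate is the last aligned base itself (0-based), not
one-past-the-end.  Termini are then restricted to the stop-anchored window
and normalised by a coverage anchor approximating per-gene mRNA abundance
(start-codon coverage in the ski2 background, stop-codon coverage in xrn1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .reference import GeneWindow

logger = logging.getLogger(__name__)

BACKGROUNDS = ("ski2_deficient", "xrn1_deficient")

# unmapped / secondary / QC-fail / duplicate / supplementary
EXCLUDE_FLAG_MASK = 3844


@dataclass(frozen=True)
class AlignmentRecord:
    """A minimal aligned-read record (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    align_strand: str
    flags: int = 0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("alignment interval must satisfy start < end")
        if self.align_strand not in ("+", "-"):
            raise ValueError("align_strand must be '+' or '-'")

    @property
    def five_prime(self) -> int:
        """Genomic coordinate of the read's own 5' end (last/first aligned base)."""
        return self.start if self.align_strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the read's own 3' end."""
        return self.end - 1 if self.align_strand == "+" else self.start


@dataclass
class FragmentEndProfile:
    """Per-gene counts of candidate fragment termini at stop-relative
    positions ``-L..-1``."""

    gene_id: str
    background: str
    counts: dict[int, int]
    window_length: int

    @property
    def total_ends(self) -> int:
        return int(sum(self.counts.values()))

    def as_vector(self, window_nt: int = 300) -> np.ndarray:
        """Dense vector over positions -window_nt..-1 (index 0 = -window_nt)."""
        vec = np.zeros(window_nt, dtype=float)
        for rel, n in self.counts.items():
            vec[rel + window_nt] = n
        return vec


@dataclass(frozen=True)
class CoverageAnchors:
    """Mean per-base depths over start codon, stop codon and whole CDS."""

    gene_id: str
    cov_start: float
    cov_stop: float
    cov_cds: float


@dataclass
class NormalizedEndProfile:
    """Fragment-end counts divided by the background's coverage anchor."""

    gene_id: str
    background: str
    norm_counts: dict[int, float]
    anchor_used: str
    anchor_value: float

    @property
    def total_norm_ends(self) -> float:
        return float(sum(self.norm_counts.values()))


def filter_alignments(
    records: Iterable[AlignmentRecord],
) -> list[AlignmentRecord]:
    """Drop unmapped, secondary, supplementary, duplicate and QC-fail
    records (flag mask 3844); primary mapped records pass."""
    return [r for r in records if not (r.flags & EXCLUDE_FLAG_MASK)]


def extract_fragment_termini(
    records: Iterable[AlignmentRecord],
    gene_strand: str,
    background: str,
) -> list[int]:
    """Genomic fragment-terminus position for each alignment.

    In the ski2 background the fragment's 3' terminus is returned, in the
    xrn1 background its 5' terminus; both strands of the same cDNA map the
    same fragment end to the same genomic coordinate.
    """
    if background not in BACKGROUNDS:
        raise ValueError(f"unknown background {background!r}")
    if gene_strand not in ("+", "-"):
        raise ValueError("gene_strand must be '+' or '-'")
    termini = []
    for rec in records:
        sense = rec.align_strand == gene_strand
        if background == "ski2_deficient":
            # fragment 3' terminus
            pos = rec.three_prime if sense else rec.five_prime
        else:
            # fragment 5' terminus
            pos = rec.five_prime if sense else rec.three_prime
        termini.append(pos)
    return termini


def restrict_to_window(
    termini: Sequence[int], window: GeneWindow, background: str = "ski2_deficient"
) -> FragmentEndProfile:
    """Keep termini falling inside the stop-anchored window and count them
    at stop-relative positions; everything else (including the 3'-UTR and
    positions 5' of the window) is discarded."""
    counts: dict[int, int] = {}
    for pos in termini:
        rel = window.genomic_to_relative(pos)
        if rel is not None:
            counts[rel] = counts.get(rel, 0) + 1
    return FragmentEndProfile(
        gene_id=window.gene_id,
        background=background,
        counts=counts,
        window_length=window.length,
    )


def per_base_depth(
    records: Iterable[AlignmentRecord], start: int, end: int
) -> np.ndarray:
    """Per-base read depth over [start, end) from aligned spans."""
    depth = np.zeros(end - start, dtype=float)
    for rec in records:
        lo = max(rec.start, start)
        hi = min(rec.end, end)
        if lo < hi:
            depth[lo - start : hi - start] += 1.0
    return depth


def compute_coverage_anchors(
    records: Iterable[AlignmentRecord], window: GeneWindow
) -> CoverageAnchors:
    """Mean per-base depth over the start codon, stop codon and CDS.

    Reads should already be flag-filtered.  Zero coverage yields zero
    anchors; the exclusion of such genes is handled by the caller.
    """
    records = [r for r in records if r.chrom == window.chrom]
    depth = per_base_depth(records, window.cds_start, window.cds_end)
    if window.strand == "+":
        start_codon = depth[:3]
        stop_codon = depth[-3:]
    else:
        start_codon = depth[-3:]
        stop_codon = depth[:3]
    return CoverageAnchors(
        gene_id=window.gene_id,
        cov_start=float(start_codon.mean()),
        cov_stop=float(stop_codon.mean()),
        cov_cds=float(depth.mean()),
    )


def anchor_for_background(anchors: CoverageAnchors, background: str) -> float:
    if background == "ski2_deficient":
        return anchors.cov_start
    if background == "xrn1_deficient":
        return anchors.cov_stop
    raise ValueError(f"unknown background {background!r}")


def normalize_read_ends(
    profile: FragmentEndProfile,
    anchors: CoverageAnchors,
    background: str | None = None,
) -> NormalizedEndProfile | None:
    """Divide end counts by the background's coverage anchor.

    Returns None (and logs) when the anchor is zero: the gene carries no
    abundance estimate and is excluded from scoring.
    """
    background = background or profile.background
    anchor = anchor_for_background(anchors, background)
    name = "cov_start" if background == "ski2_deficient" else "cov_stop"
    if anchor <= 0:
        logger.warning(
            "%s: %s anchor is 0, normalized profile undefined", profile.gene_id, name
        )
        return None
    return NormalizedEndProfile(
        gene_id=profile.gene_id,
        background=background,
        norm_counts={p: n / anchor for p, n in profile.counts.items()},
        anchor_used=name,
        anchor_value=anchor,
    )


def alignments_from_bed(path_or_df) -> list[AlignmentRecord]:
    """Read a 6-column BED of alignments (flags implied 0: primary mapped)."""
    if isinstance(path_or_df, pd.DataFrame):
        bed = path_or_df
    else:
        bed = pd.read_csv(
            path_or_df, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "name", "score", "strand"],
            usecols=range(6),
        )
    return [
        AlignmentRecord(c, int(s), int(e), st)
        for c, s, e, st in bed[["chrom", "start", "end", "strand"]].itertuples(
            index=False, name=None
        )
    ]


def alignments_from_bam(path, chrom=None, start=None, end=None) -> list[AlignmentRecord]:
    """Read alignments from a (optionally indexed) BAM via pysam, carrying
    the raw flag field so :func:`filter_alignments` can act on it."""
    import pysam

    out = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        it = bam.fetch(chrom, start, end) if chrom is not None else bam
        for aln in it:
            if aln.is_unmapped or aln.reference_end is None:
                continue
            out.append(
                AlignmentRecord(
                    chrom=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    align_strand="-" if aln.is_reverse else "+",
                    flags=aln.flag,
                )
            )
    return out


class _ChromIndex:
    """Per-chromosome alignment arrays for fast CDS-overlap queries."""

    def __init__(self, records: Sequence[AlignmentRecord]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        grouped: dict[str, list[AlignmentRecord]] = {}
        for r in records:
            grouped.setdefault(r.chrom, []).append(r)
        for chrom, recs in grouped.items():
            starts = np.fromiter((r.start for r in recs), dtype=np.int64, count=len(recs))
            ends = np.fromiter((r.end for r in recs), dtype=np.int64, count=len(recs))
            self.by_chrom[chrom] = (starts, ends, recs)

    def overlapping(self, window: GeneWindow) -> list[AlignmentRecord]:
        entry = self.by_chrom.get(window.chrom)
        if entry is None:
            return []
        starts, ends, recs = entry
        mask = (starts < window.cds_end) & (ends > window.cds_start)
        return [recs[i] for i in np.flatnonzero(mask)]


def gene_end_table(
    alignments: Iterable[AlignmentRecord],
    windows: Iterable[GeneWindow],
    background: str,
) -> pd.DataFrame:
    """Per-gene summary over one sample: raw end totals, anchors and
    normalized end totals (NaN when the anchor is zero).

    Alignments are assigned to a gene when they overlap its CDS interval.
    """
    index = _ChromIndex(filter_alignments(alignments))
    rows = []
    for w in windows:
        overlapping = index.overlapping(w)
        termini = extract_fragment_termini(overlapping, w.strand, background)
        profile = restrict_to_window(termini, w, background)
        anchors = compute_coverage_anchors(overlapping, w)
        norm = normalize_read_ends(profile, anchors, background)
        rows.append(
            {
                "gene_id": w.gene_id,
                "background": background,
                "total_ends": profile.total_ends,
                "cov_start": anchors.cov_start,
                "cov_stop": anchors.cov_stop,
                "cov_cds": anchors.cov_cds,
                "anchor": anchor_for_background(anchors, background),
                "sum_norm_ends": norm.total_norm_ends if norm else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def gene_end_vectors(
    alignments: Iterable[AlignmentRecord],
    windows: Iterable[GeneWindow],
    background: str,
    window_nt: int = 300,
) -> pd.DataFrame:
    """Dense per-gene stop-relative end-count matrix (genes x positions
    ``-window_nt..-1``) for metaprofile construction."""
    index = _ChromIndex(filter_alignments(alignments))
    mat = {}
    for w in windows:
        overlapping = index.overlapping(w)
        termini = extract_fragment_termini(overlapping, w.strand, background)
        profile = restrict_to_window(termini, w, background)
        mat[w.gene_id] = profile.as_vector(window_nt)
    return pd.DataFrame.from_dict(
        mat, orient="index", columns=range(-window_nt, 0)
    )
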