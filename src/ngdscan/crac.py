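"""3'-UTR crosslinking enrichment from CRAC coverage tracks.

Each annotated 3'-UTR is rescaled to five equal bins (balanced integer
partition of its length); the per-gene statistic is the sum of the five
bin means.  For a knockout/wildtype sample pair the enrichment ratio is

    raw_ratio = (sum5_ko + 1) / (sum5_wt + 1)

with a pseudo-count of 1 guarding against division by zero, except that a
gene with no 3'-UTR reads in either sample is set to N/A (and excluded
from the median).  Ratios are then normalised to the median of all defined
ratios for the pair — by construction the median normalised ratio is 1 —
and summarised per gene group (terminal-codon class, NGD status, ...).

Coverage tracks are accepted unscaled; the median normalisation is the
sole cross-sample correction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_BINS = 5


def balanced_partition(length: int, n_bins: int = N_BINS) -> list[int]:
    """Partition ``length`` into ``n_bins`` integer segment lengths that
    differ by at most one, longer segments first (37 -> 8+8+7+7+7)."""
    q, r = divmod(length, n_bins)
    return [q + 1] * r + [q] * (n_bins - r)


def utr_bin_sums(
    coverage: Mapping[str, np.ndarray],
    utr_annotation: Iterable[tuple],
    n_bins: int = N_BINS,
) -> pd.DataFrame:
    """Per-gene 5-bin mean coverages over each 3'-UTR and their sum.

    ``coverage`` maps chromosome to a per-base depth array;
    ``utr_annotation`` yields ``(gene_id, chrom, start, end, strand)``
    tuples (0-based half-open).  Bins run 5'->3' along the UTR
    (strand-aware).  UTRs shorter than ``n_bins`` nucleotides are excluded
    with a log message.
    """
    rows = []
    for gene_id, chrom, start, end, strand in utr_annotation:
        length = end - start
        if length < n_bins:
            logger.info("%s: 3'-UTR of %d nt too short, excluded", gene_id, length)
            continue
        track = coverage.get(chrom)
        if track is None:
            logger.info("%s: no coverage for chromosome %s", gene_id, chrom)
            continue
        depth = np.asarray(track[start:end], dtype=float)
        if strand == "-":
            depth = depth[::-1]
        bins = []
        offset = 0
        for seg in balanced_partition(length, n_bins):
            bins.append(float(depth[offset : offset + seg].mean()))
            offset += seg
        rows.append(
            {"gene_id": gene_id, **{f"bin{i + 1}": b for i, b in enumerate(bins)},
             "sum5": float(sum(bins))}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def utr_ratios(
    sums_ko: pd.Series | pd.DataFrame,
    sums_wt: pd.Series | pd.DataFrame,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene raw and median-normalised knockout/wildtype UTR ratios.

    Genes with zero summed coverage in *both* samples are N/A and excluded
    from the median.  Errors when no defined ratio remains.
    """
    if isinstance(sums_ko, pd.DataFrame):
        sums_ko = sums_ko["sum5"]
    if isinstance(sums_wt, pd.DataFrame):
        sums_wt = sums_wt["sum5"]
    genes = sums_ko.index.union(sums_wt.index)
    a = sums_ko.reindex(genes).fillna(0.0)
    b = sums_wt.reindex(genes).fillna(0.0)
    raw = (a + pseudocount) / (b + pseudocount)
    undefined = (a == 0) & (b == 0)
    raw = raw.where(~undefined)
    defined = raw.dropna()
    if defined.empty:
        raise ValueError("no gene with 3'-UTR reads in either sample")
    med = float(defined.median())
    return pd.DataFrame(
        {"raw_ratio": raw, "norm_ratio": raw / med}, index=genes
    )


def group_ratio_distributions(
    ratios: pd.DataFrame | pd.Series,
    gene_classes: Mapping[str, str],
    valid_labels: Sequence[str] | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Split defined normalised ratios by gene-group label.

    ``gene_classes`` maps gene_id to a label ("strong"/"mild"/"not",
    "strong NGD"/"strong other", ...).  When ``valid_labels`` is given, an
    unknown label raises.  Returns the per-group value arrays (boxplot
    export) and a summary table (n, median, quartiles; NaN for empty
    groups).
    """
    if isinstance(ratios, pd.DataFrame):
        ratios = ratios["norm_ratio"]
    labels = pd.Series(gene_classes)
    if valid_labels is not None:
        bad = set(labels.unique()) - set(valid_labels)
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
    values: dict[str, np.ndarray] = {}
    rows = []
    for label in dict.fromkeys(labels.values):  # preserve first-seen order
        genes = labels.index[labels == label]
        vals = ratios.reindex(genes).dropna().to_numpy()
        values[label] = vals
        if len(vals):
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
        else:
            q25 = med = q75 = np.nan
        rows.append(
            {"group": label, "n": len(vals), "median": med, "q25": q25, "q75": q75}
        )
    return values, pd.DataFrame(rows).set_index("group")


def read_bedgraph(path, chrom_sizes: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Expand a bedGraph file into per-base depth arrays."""
    cov = {c: np.zeros(n, dtype=float) for c, n in chrom_sizes.items()}
    bg = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
    )
    for chrom, start, end, value in bg.itertuples(index=False, name=None):
        if chrom in cov:
            cov[chrom][int(start) : int(end)] += float(value)
    return cov


def write_bedgraph(coverage: Mapping[str, np.ndarray], path) -> None:
    """Write per-base depth arrays as a run-length-encoded bedGraph."""
    with open(path, "w") as fh:
        for chrom in sorted(coverage):
            vals = np.asarray(coverage[chrom])
            if len(vals) == 0:
                continue
            breaks = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate([[0], breaks])
            ends = np.concatenate([breaks, [len(vals)]])
            for s, e in zip(starts, ends):
                v = vals[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")
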