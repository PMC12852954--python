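"""Normalized metaprofiles over gene groups and cleavage periodicity.

Four profile flavours are built, each matching a different normalisation:

* coverage — per gene min-subtracted and amplitude-scaled to [0, 1],
  averaged over genes then replicates, finally rescaled to max 1 / min 0;
* read ends — per gene divided by the gene maximum, averaged over genes
  then replicates, finally multiplied by the group's mean total end count;
* 5PSeq 5'-ends — CPM-normalised, pooled over replicates, per gene divided
  by the gene maximum, group-summed and divided by group size, optionally
  smoothed with a centered 5-nt rolling mean;
* readthrough — CPM-normalised 5' ends (or P-sites) in a -200..+200 window
  around the stop, per gene divided by the gene's window total, averaged.

Collided ribosomes space cleavage signals at the ~30 nt footprint period;
:func:`estimate_periodicity` quantifies that spacing from the
mean-subtracted autocorrelation of a profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MetaProfile:
    """A per-position aggregate over a gene group."""

    group_label: str
    positions: np.ndarray
    values: np.ndarray
    n_genes: int
    scaling: str
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"position": self.positions, "value": self.values}
        ).set_index("position")


def _as_matrix(gene_vectors: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(gene_vectors, pd.DataFrame):
        raise TypeError("gene vectors must be a genes x positions DataFrame")
    return gene_vectors.astype(float)


def _mean_over_replicate_groups(
    per_sample: Mapping[str, pd.Series],
    replicate_grouping: Mapping[str, Sequence[str]] | None,
) -> dict[str, pd.Series]:
    """Average per-sample mean profiles over replicates per strain (group)."""
    if replicate_grouping is None:
        replicate_grouping = {s: [s] for s in per_sample}
    out = {}
    for strain, samples in replicate_grouping.items():
        missing = [s for s in samples if s not in per_sample]
        if missing:
            raise KeyError(f"samples {missing} not provided for group {strain!r}")
        out[strain] = pd.concat([per_sample[s] for s in samples], axis=1).mean(axis=1)
    return out


def coverage_metaplot(
    gene_vectors_by_sample: Mapping[str, pd.DataFrame],
    replicate_grouping: Mapping[str, Sequence[str]] | None = None,
    group_label: str = "all",
) -> MetaProfile:
    """Amplitude-normalised coverage metaprofile over the last-300-nt window.

    Per gene the minimum depth is subtracted and values are divided by the
    amplitude (max - min); flat genes (amplitude 0) are excluded and
    counted.  Gene means per sample are then averaged over replicates (and
    over strain groups when ``replicate_grouping`` maps one label to many
    samples), and the final profile is rescaled so its max is 1 and min 0.
    """
    per_sample: dict[str, pd.Series] = {}
    n_genes = 0
    n_excluded = 0
    positions = None
    for sample, mat in gene_vectors_by_sample.items():
        mat = _as_matrix(mat)
        positions = mat.columns if positions is None else positions
        amp = mat.max(axis=1) - mat.min(axis=1)
        flat = amp <= 0
        if flat.any():
            n_excluded += int(flat.sum())
            logger.info("%s: excluding %d amplitude-0 genes", sample, int(flat.sum()))
        kept = mat.loc[~flat]
        if kept.empty:
            raise ValueError(f"sample {sample!r}: no gene with nonzero amplitude")
        scaled = kept.sub(kept.min(axis=1), axis=0).div(
            amp.loc[~flat], axis=0
        )
        per_sample[sample] = scaled.mean(axis=0)
        n_genes = max(n_genes, len(kept))
    merged = _mean_over_replicate_groups(per_sample, replicate_grouping)
    mean = pd.concat(list(merged.values()), axis=1).mean(axis=1)
    lo, hi = mean.min(), mean.max()
    final = (mean - lo) / (hi - lo) if hi > lo else mean * 0.0
    return MetaProfile(
        group_label=group_label,
        positions=np.asarray(positions),
        values=final.to_numpy(),
        n_genes=n_genes,
        scaling="per-gene amplitude, group mean rescaled to [0,1]",
        n_excluded=n_excluded,
    )


def readend_metaplot(
    gene_end_vectors_by_sample: Mapping[str, pd.DataFrame],
    replicate_grouping: Mapping[str, Sequence[str]] | None = None,
    group_label: str = "all",
) -> MetaProfile:
    """Read-end metaprofile: per gene max-scaled, averaged, then multiplied
    by the mean total end count over all genes from all replicates."""
    if not gene_end_vectors_by_sample:
        raise ValueError("no samples provided")
    per_sample: dict[str, pd.Series] = {}
    totals: list[float] = []
    n_genes = 0
    n_excluded = 0
    positions = None
    for sample, mat in gene_end_vectors_by_sample.items():
        mat = _as_matrix(mat)
        positions = mat.columns if positions is None else positions
        gene_max = mat.max(axis=1)
        zero = gene_max <= 0
        if zero.any():
            n_excluded += int(zero.sum())
            logger.info("%s: excluding %d zero-end genes", sample, int(zero.sum()))
        kept = mat.loc[~zero]
        if kept.empty:
            raise ValueError(f"sample {sample!r}: every gene has zero read ends")
        per_sample[sample] = kept.div(gene_max.loc[~zero], axis=0).mean(axis=0)
        totals.extend(kept.sum(axis=1).tolist())
        n_genes = max(n_genes, len(kept))
    merged = _mean_over_replicate_groups(per_sample, replicate_grouping)
    mean = pd.concat(list(merged.values()), axis=1).mean(axis=1)
    multiplier = float(np.mean(totals))
    return MetaProfile(
        group_label=group_label,
        positions=np.asarray(positions),
        values=(mean * multiplier).to_numpy(),
        n_genes=n_genes,
        scaling=f"per-gene max=1, scaled by mean total ends {multiplier:.3g}",
        n_excluded=n_excluded,
    )


def rolling_mean(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered rolling mean, truncated at the edges."""
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def cpm(counts: pd.DataFrame, library_size: float | None = None) -> pd.DataFrame:
    """Counts-per-million normalisation; by default the library size is the
    total count in the table."""
    total = float(counts.to_numpy().sum()) if library_size is None else library_size
    if total <= 0:
        raise ValueError("library size must be positive")
    return counts * (1e6 / total)


def fivepseq_group_metaplot(
    five_prime_counts_by_replicate: Sequence[pd.DataFrame],
    groups: Mapping[str, Sequence[str]],
    library_sizes: Sequence[float] | None = None,
    smooth: bool = False,
) -> dict[str, MetaProfile]:
    """5PSeq 5'-end metaprofiles per gene group.

    Replicate count tables (genes x positions, last 300 nt) are
    CPM-normalised and pooled (summed), each gene is divided by its maximum
    (relative values per position), group values are summed and divided by
    group size, and optionally smoothed with a centered 5-nt rolling mean.
    Empty groups are skipped.
    """
    if not five_prime_counts_by_replicate:
        raise ValueError("no replicates provided")
    pooled = None
    for i, mat in enumerate(five_prime_counts_by_replicate):
        lib = library_sizes[i] if library_sizes is not None else None
        mat = cpm(_as_matrix(mat), lib)
        pooled = mat if pooled is None else pooled.add(mat, fill_value=0.0)
    gene_max = pooled.max(axis=1)
    relative = pooled.loc[gene_max > 0].div(gene_max[gene_max > 0], axis=0)
    out: dict[str, MetaProfile] = {}
    for label, genes in groups.items():
        members = [g for g in genes if g in relative.index]
        if not members:
            logger.info("group %r empty after filtering; skipped", label)
            continue
        values = relative.loc[members].sum(axis=0) / len(members)
        vec = values.to_numpy()
        if smooth:
            vec = rolling_mean(vec, 5)
        out[label] = MetaProfile(
            group_label=label,
            positions=np.asarray(relative.columns),
            values=vec,
            n_genes=len(members),
            scaling="CPM-pooled, per-gene max=1, group mean"
            + (", 5 nt rolling mean" if smooth else ""),
        )
    return out


def readthrough_profile(
    counts_by_replicate: Sequence[pd.DataFrame],
    group_label: str = "all",
) -> MetaProfile:
    """Stop-codon readthrough window profile (positions -200..+200).

    5'-end (or P-site) count tables are CPM-normalised, pooled over
    replicates, each gene is divided by its total within the window, and
    gene profiles are averaged.  Genes with zero counts in the window are
    excluded.
    """
    pooled = None
    for mat in counts_by_replicate:
        mat = cpm(_as_matrix(mat))
        pooled = mat if pooled is None else pooled.add(mat, fill_value=0.0)
    totals = pooled.sum(axis=1)
    kept = pooled.loc[totals > 0].div(totals[totals > 0], axis=0)
    if kept.empty:
        raise ValueError("no gene with counts inside the readthrough window")
    return MetaProfile(
        group_label=group_label,
        positions=np.asarray(pooled.columns),
        values=kept.mean(axis=0).to_numpy(),
        n_genes=len(kept),
        scaling="CPM-pooled, per-gene sum=1, gene mean",
        n_excluded=int((totals <= 0).sum()),
    )


def autocorrelation(values: np.ndarray, max_lag: int) -> np.ndarray:
    """Mean-subtracted Pearson autocovariance, normalised by lag-0."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    c0 = float(np.dot(x, x))
    if c0 == 0:
        return np.zeros(max_lag + 1)
    return np.array(
        [np.dot(x[: len(x) - lag], x[lag:]) / c0 for lag in range(max_lag + 1)]
    )


def estimate_periodicity(
    profile,
    lag_range: tuple[int, int] = (15, 60),
    prominence_floor: float = 0.1,
) -> int | None:
    """Dominant spacing (nt) of a profile's autocorrelation within
    ``lag_range``, or None when no peak reaches ``prominence_floor``.

    Accepts a :class:`MetaProfile` or a plain value array on a uniform
    1-nt grid.  Errors when the profile is shorter than twice the maximum
    lag.
    """
    values = profile.values if isinstance(profile, MetaProfile) else np.asarray(profile, float)
    lo, hi = lag_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid lag range")
    if len(values) < 2 * hi:
        raise ValueError(
            f"profile of length {len(values)} too short for max lag {hi}"
        )
    ac = autocorrelation(values, hi)
    lags = np.arange(lo, hi + 1)
    peak = lags[int(np.argmax(ac[lo : hi + 1]))]
    if ac[peak] < prominence_floor:
        return None
    return int(peak)
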