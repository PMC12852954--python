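"""Cleavage scoring and NGD target calling.

The cleavage score of a gene compares summed, coverage-normalised fragment
end counts between a New1-lacking sample and its matched control:

    score = sum_norm_ends(knockout) / (sum_norm_ends(knockout) + sum_norm_ends(control))

summed over stop-relative positions -300..-1.  0.5 means equal normalised
end counts; 0.75 corresponds to a 3-fold excess in the knockout.  A gene is
called an NGD target when three criteria hold jointly:

(i)   mean cleavage score over matched replicate pairs >= 0.75,
(ii)  mean raw end count over knockout replicates >= 10 (ski2 background)
      or >= 15 (xrn1 background),
(iii) that mean raw end count is >= 20% of the mean coverage anchor
      (start-codon coverage for ski2, stop-codon coverage for xrn1).

These are plain thresholds, not statistical tests; no multiplicity
correction applies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    score_min: float = 0.75
    min_ends_ski2: float = 10.0
    min_ends_xrn1: float = 15.0
    min_fraction: float = 0.20
    window_nt: int = 300

    def min_ends(self, background: str) -> float:
        return (
            self.min_ends_ski2
            if background == "ski2_deficient"
            else self.min_ends_xrn1
        )


def cleavage_score(
    sum_norm_ends_ko: float, sum_norm_ends_ctrl: float
) -> float:
    """Knockout share of normalised read ends, in [0, 1].

    NaN when both sums are zero (no evidence); negative input is an error.
    """
    if sum_norm_ends_ko < 0 or sum_norm_ends_ctrl < 0:
        raise ValueError("normalized end sums must be nonnegative")
    total = sum_norm_ends_ko + sum_norm_ends_ctrl
    if total == 0:
        return math.nan
    return sum_norm_ends_ko / total


def aggregate_scores(pair_scores: Sequence[float]) -> float:
    """Arithmetic mean over defined (non-NaN) per-replicate-pair scores;
    NaN when no pair is defined."""
    defined = [s for s in pair_scores if not math.isnan(s)]
    if not defined:
        return math.nan
    return float(np.mean(defined))


def score_genes(
    ko_tables: Sequence[pd.DataFrame],
    ctrl_tables: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Per-gene cleavage scores from per-replicate gene-end tables.

    ``ko_tables[i]`` is paired with ``ctrl_tables[i]`` (matched replicate
    index); with unequal replicate counts, pairs up to the minimum with a
    warning.  Each table is a :func:`ngdscan.fragments.gene_end_table`
    output indexed by gene.  Returns per-gene pair scores, their mean, and
    knockout replicate means of raw end totals and anchors.
    """
    if not ko_tables or not ctrl_tables:
        raise ValueError("at least one knockout and one control table required")
    n_pairs = min(len(ko_tables), len(ctrl_tables))
    if len(ko_tables) != len(ctrl_tables):
        logger.warning(
            "unequal replicate counts (%d knockout, %d control); pairing "
            "first %d", len(ko_tables), len(ctrl_tables), n_pairs,
        )
    genes = ko_tables[0].index
    pair_cols = {}
    for i in range(n_pairs):
        ko = ko_tables[i].reindex(genes)
        ctrl = ctrl_tables[i].reindex(genes)
        scores = [
            cleavage_score(k, c) if not (np.isnan(k) or np.isnan(c)) else math.nan
            for k, c in zip(ko["sum_norm_ends"], ctrl["sum_norm_ends"])
        ]
        pair_cols[f"score_pair{i + 1}"] = scores
    result = pd.DataFrame(pair_cols, index=genes)
    result["mean_score"] = result.apply(
        lambda row: aggregate_scores(list(row)), axis=1
    )
    ko_ends = np.mean([t.reindex(genes)["total_ends"] for t in ko_tables[:n_pairs]], axis=0)
    ko_anchor = np.mean([t.reindex(genes)["anchor"] for t in ko_tables[:n_pairs]], axis=0)
    ko_anchor_defined = np.all(
        [t.reindex(genes)["anchor"] > 0 for t in ko_tables[:n_pairs]], axis=0
    )
    result["mean_ko_ends"] = ko_ends
    result["mean_ko_anchor"] = ko_anchor
    result["anchor_defined"] = ko_anchor_defined
    return result


def call_ngd_targets(
    scores: pd.DataFrame,
    background: str,
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Apply the three target-calling criteria to a :func:`score_genes`
    table.

    Genes with an undefined anchor in any knockout replicate are excluded
    from calling (is_target False, ``excluded`` True); they are reported so
    a QC table can be written.
    """
    mean_score = scores["mean_score"]
    score_ok = (mean_score >= thresholds.score_min).fillna(False)
    count_ok = scores["mean_ko_ends"] >= thresholds.min_ends(background)
    fraction_ok = (
        scores["mean_ko_ends"]
        >= thresholds.min_fraction * scores["mean_ko_anchor"]
    )
    excluded = ~scores["anchor_defined"].astype(bool)
    calls = pd.DataFrame(
        {
            "background": background,
            "mean_score": mean_score,
            "score_ok": score_ok & ~excluded,
            "count_ok": count_ok & ~excluded,
            "fraction_ok": fraction_ok & ~excluded,
            "excluded": excluded,
        },
        index=scores.index,
    )
    calls["is_target"] = (
        calls["score_ok"] & calls["count_ok"] & calls["fraction_ok"]
    )
    return calls
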