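"""Positional summaries of PARS folding-propensity scores.

PARS scores are per-nucleotide measures of double-strandedness from
parallel nuclease probing; higher means more structured.  Positions are
expressed relative to the 3'-UTR start: the last CDS nucleotide is -1, the
first 3'-UTR nucleotide is +1 (there is no position 0).  Gene groups
(NGD targets, other strongly affected, mild, not) are compared per
position by mean and a 95% confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_95 = 1.959963984540054


@dataclass
class ParsTrack:
    """Per-nucleotide PARS scores for one gene, keyed by UTR-relative
    position (CDS negative, 3'-UTR positive; missing positions absent or
    NaN)."""

    gene_id: str
    scores: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if 0 in self.scores:
            raise ValueError("position 0 does not exist (-1 = last CDS nt, "
                             "+1 = first 3'-UTR nt)")
        self.scores = {
            int(p): float(v) for p, v in self.scores.items()
            if v is not None and not math.isnan(float(v))
        }

    def cds_values(self) -> np.ndarray:
        return np.array([v for p, v in self.scores.items() if p < 0])


def cds_mean_pars(track: ParsTrack) -> float:
    """CDS-wide average PARS score over defined CDS positions (NaN when the
    track has none)."""
    vals = track.cds_values()
    if len(vals) == 0:
        return math.nan
    return float(vals.mean())


def positional_pars_profile(
    tracks: Iterable[ParsTrack],
    groups: Mapping[str, Sequence[str]],
    window: tuple[int, int] = (-25, 20),
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Per-group, per-position mean PARS score with a 95% CI.

    ``window=(-25, 20)`` covers the last 25 CDS nt and the first 20 3'-UTR
    nt.  The CI is mean +/- 1.96 * sd / sqrt(n) (normal approximation) or
    t-based with ``ci_method='t'``; positions with n < 2 report the mean
    with an undefined (NaN) interval.
    """
    if ci_method not in ("normal", "t"):
        raise ValueError("ci_method must be 'normal' or 't'")
    by_gene = {t.gene_id: t for t in tracks}
    lo, hi = window
    positions = [p for p in range(lo, hi + 1) if p != 0]
    rows = []
    for label, genes in groups.items():
        members = [by_gene[g] for g in genes if g in by_gene]
        for pos in positions:
            vals = np.array(
                [t.scores[pos] for t in members if pos in t.scores]
            )
            n = len(vals)
            mean = float(vals.mean()) if n else math.nan
            if n >= 2:
                sd = float(vals.std(ddof=1))
                crit = Z_95 if ci_method == "normal" else float(
                    stats.t.ppf(0.975, n - 1)
                )
                half = crit * sd / math.sqrt(n)
                ci_low, ci_high = mean - half, mean + half
            else:
                ci_low = ci_high = math.nan
            rows.append(
                {
                    "group": label,
                    "position": pos,
                    "mean": mean,
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "n": n,
                }
            )
    return pd.DataFrame(rows).set_index(["group", "position"])


def read_pars_tsv(path) -> list[ParsTrack]:
    """Read a long-format TSV (gene_id, position, score) into tracks."""
    df = pd.read_csv(path, sep="\t")
    tracks = []
    for gid, grp in df.groupby("gene_id", sort=False):
        tracks.append(
            ParsTrack(gid, dict(zip(grp["position"], grp["score"])))
        )
    return tracks


def write_pars_tsv(tracks: Iterable[ParsTrack], path) -> None:
    rows = [
        {"gene_id": t.gene_id, "position": p, "score": v}
        for t in tracks
        for p, v in sorted(t.scores.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
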