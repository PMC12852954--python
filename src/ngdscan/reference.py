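"""Coding-sequence reference model.

Loads yeast-style coding sequences (one contiguous CDS per gene, stop codon
included), classifies terminal sense codons into the collision-prone classes
observed in New1-deficient cells, tabulates codon usage at the C-terminus
versus the gene body, scans stop-codon contexts, and builds stop-anchored
coordinate windows used by every downstream read-end analysis.

Coordinate conventions
----------------------
All genomic intervals are 0-based half-open internally.  Stop-relative
positions run ``-L..-1`` where ``-1`` is the 3'-most nucleotide of the stop
codon and ``L = min(300, CDS length incl. stop)``.  Sequences are normalised
to DNA (T) internally; user-facing tables report codons in RNA notation (U).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
SENSE_CODONS = frozenset(standard_dna_table.forward_table)  # 61 codons

#: Terminal codons whose presence at the C-terminus causes strong ribosome
#: queuing and Hel2 recruitment when New1 is absent: K(AAA), R(AGG), R(CGU).
STRONG_CODONS = frozenset({"AAA", "AGG", "CGT"})

#: Mildly affected terminal codons: all Cys, Asn and Ser codons plus the
#: arginine codons CGA, CGC and CGG.
MILD_CODONS = frozenset(
    c for c, aa in standard_dna_table.forward_table.items() if aa in "CNS"
) | {"CGA", "CGC", "CGG"}

#: Every remaining sense codon.
NOT_CODONS = SENSE_CODONS - STRONG_CODONS - MILD_CODONS

CODON_CLASSES: Mapping[str, frozenset] = {
    "strong": STRONG_CODONS,
    "mild": MILD_CODONS,
    "not": NOT_CODONS,
}

_STATUS_TOKENS = ("verified", "uncharacterized", "dubious", "pseudogene")


def normalize_codon(codon: str) -> str:
    """Uppercase a 3-mer and map RNA (U) onto DNA (T)."""
    return codon.upper().replace("U", "T")


def to_rna(codon: str) -> str:
    """Display form of a codon, RNA notation."""
    return codon.upper().replace("T", "U")


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence with its annotation status and terminal codons.

    ``terminal_sense_codon`` is the codon immediately 5' of the stop codon;
    ``stop_codon`` is ``None`` when the sequence does not end in TAA/TAG/TGA.
    """

    gene_id: str
    sequence: str
    status: str = "unknown"
    terminal_sense_codon: str = field(init=False)
    stop_codon: str | None = field(init=False)

    def __post_init__(self):
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) % 3:
            raise ValueError(
                f"{self.gene_id}: CDS length {len(seq)} not divisible by 3"
            )
        if len(seq) < 6:
            raise ValueError(f"{self.gene_id}: CDS shorter than two codons")
        last = seq[-3:]
        if last in STOP_CODONS:
            object.__setattr__(self, "stop_codon", last)
            object.__setattr__(self, "terminal_sense_codon", seq[-6:-3])
        else:
            object.__setattr__(self, "stop_codon", None)
            object.__setattr__(self, "terminal_sense_codon", last)

    @property
    def codons(self) -> list[str]:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]


def parse_status(header: str) -> str:
    """Extract an SGD-style ORF status token from a FASTA header.

    Tokens ("Verified", "Dubious", ...) are matched case-insensitively
    anywhere in the header; absent token -> "unknown".
    """
    lowered = header.lower()
    for token in _STATUS_TOKENS:
        if token in lowered:
            return token
    return "unknown"


def load_coding_sequences(
    fasta_source,
    exclusion_statuses: Iterable[str] = ("dubious", "pseudogene"),
) -> list[CdsRecord]:
    """Read CDS records from FASTA, dropping excluded annotation statuses.

    Records whose length is not a multiple of 3 are skipped with a warning.
    An empty FASTA raises ``ValueError``.
    """
    excluded = {s.lower() for s in exclusion_statuses}
    records: list[CdsRecord] = []
    n_seen = 0
    for rec in SeqIO.parse(fasta_source, "fasta"):
        n_seen += 1
        status = parse_status(rec.description)
        if status in excluded:
            continue
        seq = str(rec.seq)
        if len(seq) % 3 or len(seq) < 6:
            logger.warning(
                "skipping %s: CDS length %d not usable (not divisible by 3 "
                "or too short)", rec.id, len(seq),
            )
            continue
        records.append(CdsRecord(gene_id=rec.id, sequence=seq, status=status))
    if n_seen == 0:
        raise ValueError("empty FASTA: no sequences found")
    return records


def classify_terminal_codon(codon: str) -> str:
    """Return the collision-propensity class ("strong"/"mild"/"not") of a
    sense codon.  U and T are equivalent; stop codons are rejected."""
    c = normalize_codon(codon)
    if c in STOP_CODONS:
        raise ValueError(f"{codon} is a stop codon, not a sense codon")
    if c not in SENSE_CODONS:
        raise ValueError(f"{codon!r} is not a valid sense codon")
    for label, members in CODON_CLASSES.items():
        if c in members:
            return label
    raise AssertionError("unreachable: codon classes partition sense codons")


def codon_usage_table(records: Iterable[CdsRecord]) -> pd.DataFrame:
    """Tabulate sense-codon usage across gene bodies versus C-termini.

    Returns one row per sense codon (RNA notation) with the amino acid,
    total in-frame occurrences across all CDS (``cds_count``), occurrences
    as the terminal sense codon (``cterm_count``), the percentages each
    represents within its amino acid's codon family, and the
    C-terminal/CDS percentage ratio (NaN where the family has no
    C-terminal occurrences).
    """
    records = list(records)
    if not records:
        raise ValueError("codon_usage_table requires at least one record")
    cds_counts = {c: 0 for c in SENSE_CODONS}
    cterm_counts = {c: 0 for c in SENSE_CODONS}
    for rec in records:
        for codon in rec.codons:
            if codon in SENSE_CODONS:
                cds_counts[codon] += 1
        cterm_counts[rec.terminal_sense_codon] += 1

    rows = []
    for codon in sorted(SENSE_CODONS):
        aa = standard_dna_table.forward_table[codon]
        rows.append(
            {
                "codon": to_rna(codon),
                "amino_acid": aa,
                "class": classify_terminal_codon(codon),
                "cds_count": cds_counts[codon],
                "cterm_count": cterm_counts[codon],
            }
        )
    table = pd.DataFrame(rows).set_index("codon")
    fam_cds = table.groupby("amino_acid")["cds_count"].transform("sum")
    fam_cterm = table.groupby("amino_acid")["cterm_count"].transform("sum")
    table["pct_within_amino_acid_cds"] = (
        100.0 * table["cds_count"] / fam_cds.where(fam_cds > 0)
    ).fillna(0.0)
    pct_cterm = 100.0 * table["cterm_count"] / fam_cterm.where(fam_cterm > 0)
    table["pct_within_amino_acid_cterm"] = pct_cterm.fillna(0.0)
    # ratio undefined (NaN) when the family has no C-terminal occurrences
    table["ratio"] = (
        table["pct_within_amino_acid_cterm"]
        / table["pct_within_amino_acid_cds"].where(fam_cterm > 0)
    )
    return table


def stop_context_scan(
    records: Iterable[CdsRecord],
    plus_one_nt: Mapping[str, str],
) -> pd.DataFrame:
    """Scan stop-codon contexts for the readthrough-permissive pattern.

    ``plus_one_nt`` maps gene_id to the strand-aware nucleotide immediately
    3' of the stop codon (use :func:`plus_one_nucleotides` to build it from
    a genome and CDS intervals); missing genes get 'N'.  ``pattern_match``
    is true iff the terminal codon class is strong AND the stop codon is
    UGA AND the +1 nucleotide is C.
    """
    rows = []
    for rec in records:
        nt = normalize_codon(plus_one_nt.get(rec.gene_id, "N")[:1] or "N")
        nt = nt if nt in "ACGT" else "N"
        cls = classify_terminal_codon(rec.terminal_sense_codon)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "terminal_codon": to_rna(rec.terminal_sense_codon),
                "class": cls,
                "stop_codon": to_rna(rec.stop_codon) if rec.stop_codon else None,
                "plus_one_nt": nt,
                "pattern_match": bool(
                    cls == "strong" and rec.stop_codon == "TGA" and nt == "C"
                ),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def plus_one_nucleotides(
    genome: Mapping[str, str],
    cds_intervals: Iterable["GeneWindow | tuple"],
) -> dict[str, str]:
    """Read the strand-aware nucleotide immediately 3' of each CDS.

    ``cds_intervals`` yields :class:`GeneWindow` objects or
    ``(gene_id, chrom, start, end, strand)`` tuples over the *full* CDS.
    Genes at a chromosome edge get 'N'.
    """
    comp = str.maketrans("ACGT", "TGCA")
    out: dict[str, str] = {}
    for iv in cds_intervals:
        if isinstance(iv, GeneWindow):
            gene_id, chrom, start, end, strand = (
                iv.gene_id, iv.chrom, iv.cds_start, iv.cds_end, iv.strand,
            )
        else:
            gene_id, chrom, start, end, strand = iv
        seq = genome.get(chrom)
        if seq is None:
            out[gene_id] = "N"
            continue
        if strand == "+":
            out[gene_id] = seq[end].upper() if end < len(seq) else "N"
        else:
            out[gene_id] = (
                seq[start - 1].upper().translate(comp) if start >= 1 else "N"
            )
    return out


@dataclass(frozen=True)
class GeneWindow:
    """Stop-anchored window over the terminal ``min(300, CDS length)`` nt.

    Maps genomic positions bijectively onto stop-relative coordinates
    ``-L..-1`` (the stop codon occupies ``-3..-1``).  ``cds_start/cds_end``
    hold the full CDS interval, 0-based half-open.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    window_nt: int = 300

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.cds_end <= self.cds_start:
            raise ValueError(f"{self.gene_id}: empty CDS interval")

    @property
    def length(self) -> int:
        """Window length L = min(window_nt, CDS length)."""
        return min(self.window_nt, self.cds_end - self.cds_start)

    @property
    def genomic_interval(self) -> tuple[int, int]:
        """Genomic span of the window, 0-based half-open."""
        if self.strand == "+":
            return self.cds_end - self.length, self.cds_end
        return self.cds_start, self.cds_start + self.length

    def genomic_to_relative(self, pos: int) -> int | None:
        """Map a genomic position into -L..-1, or None if outside."""
        lo, hi = self.genomic_interval
        if not lo <= pos < hi:
            return None
        if self.strand == "+":
            return pos - self.cds_end
        return self.cds_start - pos - 1

    def relative_to_genomic(self, rel: int) -> int:
        if not -self.length <= rel <= -1:
            raise ValueError(f"relative position {rel} outside -{self.length}..-1")
        if self.strand == "+":
            return self.cds_end + rel
        return self.cds_start - rel - 1


def build_last300_windows(
    annotations: Iterable[tuple], window_nt: int = 300
) -> list[GeneWindow]:
    """Build stop-anchored windows from CDS annotation tuples
    ``(gene_id, chrom, start, end, strand)`` (0-based half-open)."""
    windows = []
    for gene_id, chrom, start, end, strand in annotations:
        windows.append(
            GeneWindow(gene_id, chrom, strand, int(start), int(end), window_nt)
        )
    return windows


def read_cds_bed(path) -> list[tuple]:
    """Read a 6-column BED of coding sequences into annotation tuples."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return list(
        bed[["name", "chrom", "start", "end", "strand"]].itertuples(
            index=False, name=None
        )
    )


def read_cds_gff3(path, feature: str = "CDS") -> list[tuple]:
    """Read contiguous CDS intervals from a GFF3 file.

    Yeast CDS are treated as contiguous: multiple CDS lines sharing a
    parent are merged to their outer span.  GFF3 1-based closed
    coordinates are converted to 0-based half-open.
    """
    cols = ["chrom", "source", "type", "start", "end",
            "score", "strand", "phase", "attributes"]
    gff = pd.read_csv(path, sep="\t", header=None, comment="#", names=cols)
    gff = gff[gff["type"] == feature].copy()

    def _gene_id(attrs: str) -> str:
        for key in ("Parent=", "ID=", "gene_id="):
            for fieldv in attrs.split(";"):
                if fieldv.startswith(key):
                    return fieldv[len(key):].split(",")[0].strip('"')
        return attrs

    gff["gene_id"] = gff["attributes"].map(_gene_id)
    out = []
    for gid, grp in gff.groupby("gene_id", sort=False):
        out.append(
            (
                gid,
                grp["chrom"].iloc[0],
                int(grp["start"].min()) - 1,
                int(grp["end"].max()),
                grp["strand"].iloc[0],
            )
        )
    return out
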