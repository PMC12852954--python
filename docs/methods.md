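# Methods

## Coordinate and sequence conventions

All genomic intervals are 0-based half-open internally; BED input/output
uses the same convention and GFF3 is converted from 1-based closed on
read.  Stop-relative positions run −L..−1 with −1 the 3′-most nucleotide
of the stop codon and L = min(300, CDS length including the stop); genes
shorter than 300 nt use their full CDS as the window, and the window
length is carried so downstream normalisations are unaffected.  Sequence
logic normalises U to T internally; user-facing tables print codons in
RNA notation.  Yeast CDS are treated as contiguous (multi-part GFF3 CDS
features are merged to their outer span); splice-aware reconstruction is
out of scope.

## Terminal-codon classes

The three collision-propensity classes partition the 61 sense codons:
strong = {AAA, AGG, CGU}; mild = all Cys, Asn, Ser codons plus CGA, CGC,
CGG (13 codons); not = the remaining 45.  SGD-style status tokens
(Verified/Uncharacterized/Dubious/Pseudogene) are matched
case-insensitively anywhere in a FASTA header; records without a token
are retained with status `unknown`, since only dubious and pseudogene
entries are filtered.  Codon-family percentages in the usage table are
computed within each amino acid's codon family; a family with no
C-terminal occurrence reports 0% and an undefined (NaN) ratio.

## Fragment-terminus extraction

Alignments are filtered with the standard flag mask 3844 (unmapped,
secondary, supplementary, duplicate, QC-fail).  The fragment terminus is
the position of the last aligned base itself (not one-past-the-end),
chosen so read ends land on the −300..−1 nucleotide grid; soft-clipped
bases are ignored — the aligned span defines the ends.  First- versus
second-strand cDNA is distinguished solely by alignment orientation
relative to the gene: in the *ski2Δ* background the fragment 3′ terminus
is the 3′ end of sense reads and the 5′ end of antisense reads; in
*xrn1Δ* the fragment 5′ terminus is the 5′ end of sense reads and the 3′
end of antisense reads.  Both strands of one cDNA therefore map the same
fragment end to the same coordinate, which the tests assert.  The window
boundary at −300 is inclusive.

Coverage anchors are mean per-base depths over the start codon's 3 nt,
the stop codon's 3 nt, and the whole CDS; the mean is robust to
off-by-one edge effects.  Normalised profiles are undefined when the
anchor is zero; such genes are excluded from scoring and surfaced for QC.

## Scoring and calling

The cleavage score is the knockout share of summed normalised read ends,
ko/(ko+ctrl), undefined when both sums are zero.  Replicates are paired
by index (matched samples); with unequal replicate counts the pairing
truncates to the minimum with a warning.  The replicate mean excludes
undefined pairs.  Criteria (ii) and (iii) use raw (unnormalised) end
counts averaged over the knockout replicates, and criterion (iii)'s
denominator is the same replicate-averaged anchor — (ii) is phrased in
reads, (iii) as a fraction of coverage.  The procedure is a set of
thresholds, not a hypothesis test, so no multiple-testing correction
exists anywhere in the pipeline.

## Metaprofiles

Coverage metaprofiles: per gene, subtract the minimum and divide by the
amplitude; amplitude-zero genes are excluded (and counted) rather than
zero-filled; average over genes, then over replicates (and optionally
strain groups); finally rescale the group profile to max 1 / min 0.
Read-end metaprofiles: per gene divide by the gene maximum, average the
same way, then multiply by the mean total end count over all genes from
all replicates of the group.  5PSeq metaprofiles: counts-per-million,
pooled over replicates, per-gene division by the gene maximum (the same
"relative values" rule as read-end profiles, its nearest antecedent),
group sum divided by group size; smoothing is an off-by-default flag
implemented as a centered 5-nt rolling mean truncated at the edges.
Readthrough profiles use a −200..+200 stop-anchored grid with per-gene
self-normalisation to the window total.

Periodicity is estimated as the lag in 15..60 nt maximising the
mean-subtracted Pearson autocovariance (normalised by lag 0); a peak
below a prominence floor of 0.1 (configurable plumbing, not biology)
returns "none".  Larger multiples of a true period score lower because
fewer terms overlap at larger lags, so the base period wins on even
combs.

## CRAC 3′-UTR enrichment

Each annotated 3′-UTR is rescaled to five bins by a balanced integer
partition of its length (37 → 8+8+7+7+7), bin value = mean per-base
depth, mirroring the gene-body scaling of standard matrix tools; UTRs
shorter than 5 nt are excluded.  Ratios are knockout/wildtype with a
pseudo-count of 1 in numerator and denominator; a gene with zero summed
coverage in both samples is N/A — the explicit N/A rule wins over the
pseudo-count (which would otherwise report 1) because "no reads in either
sample" carries no evidence.  Ratios are divided by the median of all
defined ratios of the pair, the sole cross-sample correction (tracks are
accepted unscaled); by construction the normalised median is exactly 1.

## PARS structure context

Positions are UTR-relative: −1 is the last CDS nucleotide, +1 the first
3′-UTR nucleotide, no position 0.  The positional profile reports, per
group and position, the mean over genes and a 95% confidence interval,
mean ± 1.96·sd/√n by default (the normal approximation matching common
spreadsheet behaviour), with a t-based option; positions with n < 2
report the mean with an undefined interval.  External PARS data are an
optional input; synthetic tracks make the module fully testable offline.

## The synthetic study generator

The generator emulates the geometry of stop-codon collisions.  The
stalled ribosome holds the stop codon (−3..−1) in its A-site with its
footprint 5′ boundary near −17; collided ribosome j adds one footprint
(default 30 nt) upstream.  Per cleaved transcript, the collided-ribosome
index j ≥ 1 is a truncated geometric draw (up to `max_queue` = 5), and
the cleavage site is a mixture of "a few nt 5′ of ribosome j's E-site"
(−9 − j·30) and "ribosome j's footprint 5′-end" (−17 − j·30), with equal
default weights shifting to (0.1, 0.9) under the RQT-deficient flag —
within-ribosome cleavage requires splitting activity.  Both site families
are 30 nt-periodic, so read-end profiles carry the footprint period.

Cleavage converts transcripts into fragments rather than adding reads: a
gene's `depth` (default 200) transcripts per sample are each cleaved with
probability `base_cleave_prob` (default 0.1; times `fold_excess` for
targets in knockout samples) or sequenced full-length.  Coverage anchors
therefore count full-length transcripts plus fragments — the anchor is an
abundance proxy — and the expected cleavage score of a target with a
k-fold excess is exactly k/(k+1).  `fold_excess` defaults to 4: a 3-fold
excess places the expected score exactly on the ≥ 0.75 calling boundary,
where sampling noise alone drops half the targets below threshold, so the
generator models targets the way identified targets behave — comfortably
above the boundary — while the k = 3 limit case remains exercised in
tests with `fold_excess=3` passed explicitly.  The depth default of 200
comes from a power calculation (per-pair score sd ≈ 0.52/√depth; at depth
200 the per-target call probability is ≈ 0.97), i.e. deep coverage of
abundant mRNAs.

Class proportions use largest-remainder allocation, so exact mixes give
exact counts.  Targets are drawn only among strong-class genes
(`target_fraction` = 0.5 of them by default).  Genes are 480–1263 nt CDS
with 30-nt 5′-UTRs and 50–300 nt 3′-UTRs on one synthetic chromosome,
random strands, 100-nt spacers.  3′-fragment 5′ termini can optionally be
trimmed toward 3′ by a truncated Gaussian (`trim_noise_sd`, default 0),
modelling Dxo1-like shortening; with the default off, extraction recovers
the ground-truth terminus multiset exactly, which the tests assert.
5PSeq tracks place 5′ ends at −17 − j·footprint with class-dependent
queue propensity (strong > mild > not; wildtype collapses to the
terminating ribosome).  CRAC tracks are per-base Poisson draws around a
per-gene rate, with strong-class genes' 3′-UTRs multiplied by
`utr_enrichment` (default 4) in the knockout.  PARS tracks are standard
normal baselines with a +0.5 bump at −17..−11 for targets.  Every
generator derives an independent child seed from the config seed, so
outputs are byte-identical under a fixed seed and each data type is
reproducible in isolation.

What the generator does not model: nanopore error profiles and
basecalling artifacts, poly(A) length, library-preparation length bias
against short fragments, transcriptional compensation, or overlapping
genes.  Passing tests therefore demonstrate correctness of the
computational pipeline on data with known truth, not robustness to every
artefact of real libraries.

## Problem sizes

The test suite runs cohorts of 15–400 genes at 30–700 transcripts per
gene; the acceptance script simulates 200 genes (100 targets) at 500
transcripts per gene, giving ~200 fragments per target gene per sample.
These sizes make every analysis statistically well-powered while keeping
a full run in seconds.

## Known limitations

Criterion-style calling has no error control beyond the thresholds
themselves; anchors assume fragments retain the anchor codon (true for
the modelled backgrounds, not for doubly-trimmed species); the CRAC
module accepts bedGraph/in-memory tracks (bigWig is a binary container
carrying the same information); and the Table-1-scale codon counts
require the real S288C coding FASTA, which is not redistributed — the
drop-in path is documented in the README.
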