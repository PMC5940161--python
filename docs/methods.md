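# Methods

## Model and scope

The package models knockout by cytidine deamination: a base editor
guided by a 20-nt protospacer adjacent to an NGG PAM converts C:G base
pairs to T:A within a *deamination window* of protospacer positions
(numbered 1..20 from the PAM-distal end). A coding-sequence position is
a *knockout site* when the edit converts an in-frame codon into a
premature stop codon.

Enumerating all 64 codons against every non-empty subset of same-strand
C→T edits (sense-strand Cs for a plus-strand protospacer, sense-strand
Gs — i.e. antisense Cs — for a minus-strand protospacer) shows that
exactly four codons admit such a route: CAA→TAA, CAG→TAG, CGA→TGA
(single edit at codon position 1, plus strand) and TGG→TAG/TGA/TAA
(one or both of codon positions 2 and 3, minus strand). Codons that
already are stops are excluded — TGA→TAA and TAG→TAA are formally C→T
routes between stop codons, but not knockouts. `stop_codon_conversions`
implements this enumeration directly rather than a lookup table, so the
four-codon rule is derived, not asserted.

## Design scan

`scan_cds` enumerates every NGG protospacer on both strands of a
frame-valid CDS, every in-frame codon, and every conversion route, and
keeps the combinations whose **required edited positions** all fall
inside the window as Cs on the protospacer strand. This is the
functional reading of window membership; a strict mode additionally
requires the whole codon inside the window, for a more conservative
count. TGG yields up to three routes per protospacer; all are reported,
but genome summaries count a unique (gene, codon, protospacer) place
once — a site is somewhere you can target, not a route.

Window defaults: (1, 13), the widest range at which effective
substitutions have been observed for this editor class in insect cells;
(4, 8) is the canonical in-vitro window and is available as
`CANONICAL_WINDOW`. Widening the window never removes a site (verified
as a property test).

Per-gene summaries compute the median number of sites over *targetable*
genes only (genes with ≥1 site), and the percent of targetable genes
over all supplied genes. Relative codon positions (codon index / total
codons) are binned into deciles per codon class.

Scanning operates on the supplied CDS sequence only; protospacers
spanning beyond CDS ends (e.g. across splice junctions) are not
searched. This is a documented limitation, not an error.

Reverse-complement behaviour: the scan is verified against the
exhaustive oracle on reverse-complemented inputs as well. Note that
knockout sites themselves are **not** mirror-symmetric — the stop-codon
set is not closed under reverse complement (the mirror image of CAA is
TTG, which has no C→T route to a stop) — so only protospacer discovery,
not the site set, mirrors under strand swap.

## Quantification

**Trimming.** Leading/trailing bases with quality below 3 are removed;
then scanning 5'→3', the read is cut at the start of the first 4-base
window with mean quality below 15; reads shorter than 50 nt are
discarded. These defaults follow the common Trimmomatic-style recipe
(LEADING:3 TRAILING:3 SLIDINGWINDOW:4:15 MINLEN:50) used for amplicon
quality control. An independent step-by-step oracle in the test suite
checks the window rule on random quality vectors.

**Demultiplexing.** Exact joint match of a (left prefix, right suffix)
barcode pair, zero mismatches; ambiguous or unmatched reads are counted
as unassigned. Exactness is conservative and deterministic; with
typical barcode edit distances, one sequencing error in a barcode sends
the read to the unassigned pool rather than to the wrong sample.

**Alignment.** Each read is aligned to its known amplicon reference
with a global affine-gap aligner (Biopython `PairwiseAligner`): match
+2, mismatch −3, gap open −5, gap extend −2, with *free end gaps on the
read*, so partial coverage of the amplicon is not penalized. Tie-breaks
follow the aligner's leftmost-first enumeration; with these scores an
isolated substitution always out-scores a gapped explanation.

**Classification.** A read is *edited* iff ≥1 protospacer-strand C of
the 20-bp target shows a C→T conversion (read base T at a sense C for
plus-strand sites, read base A at a sense G for minus-strand sites).
Substitutions other than C→T at a targeted C never make a read edited.
Reads whose alignment does not place a base at all 20 protospacer
positions are *not covering* and are excluded from per-position
numerators while remaining in the clean-read denominator. Efficiency is
`100 × n_edited / n_clean`, reported to one decimal (round half up).

Clone-count percentages (`clone_efficiency`) are instead *truncated* to
one decimal, matching the reporting convention for clone counts
(3/11 → 27.2).

**Editing-window profile.** Over a gRNA panel, position n gets
`P(substitution at Cn) = #gRNAs edited at Cn / #gRNAs designed with a C
at n`. A gRNA "shows" a substitution when its per-position fraction
reaches `max(0.5%, 3 × control rate at n)` — the 0.5% floor separates
signal from sequencing error at typical amplicon error rates, and the
control multiplier adapts the threshold when a no-editor control sample
is available. Both components are configurable; no single threshold is
canonical.

**Multiplex counting.** For pooled panels, k per read is the number of
*distinct* targeted C positions (union over sites) converted; shared
positions of overlapping sites count once. Under independent
per-position editing the histogram of k is binomial, which the test
suite checks by chi-square goodness of fit.

**Indel calling.** A read is an indel read iff its best alignment
contains ≥1 gap strictly inside the aligned span. Terminal gaps reflect
read length and coverage, not editing outcomes, and are never counted.
Consequences worth knowing:

* an indel within ~15 nt of a read end is absorbed into a free terminal
  gap and is undetectable — by any caller under this gap model;
* with substitution errors present, two clustered errors that mimic a
  one-base shift can legitimately score better as a gap (−5) plus a
  free terminal gap than as two mismatches (−6), giving a small
  false-positive rate (about 1 in 10⁴ reads at a 0.5% error rate). This
  mirrors the nonzero "indel" background that control samples show in
  real amplicon data. On reads whose only differences from the
  reference are isolated substitutions (editing without sequencing
  error), the caller is exactly zero.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated.

`generate_cds_set` emits frame-valid CDSs (ATG start, one terminal
stop, no internal stops, 100–150 codons by default, 40% GC background)
with planted target codons positioned so a chosen protospacer position
carries the editable C, plus the NGG (or CCN on the sense strand for
minus-strand protospacers) PAM bases. Planted constructs sit ≥10 codons
apart and away from the termini; planting retries against the
no-internal-stop constraint and fails loudly if infeasible. Incidental
sites arising from the random background are expected and allowed;
oracle comparisons use full enumeration, never the truth table alone.

`simulate_amplicon_reads` emits reads from an amplicon reference:
editing events are independent across targeted positions and reads
(consistent with the qualitative observation that reads with more
simultaneous substitutions are rarer); at most one contiguous indel per
read (lengths 1–10, uniform); uniform substitution errors; constant
Q35 qualities (a 3'-degradation option exists to exercise trimming);
fixed barcode pairs attached to both ends. Indel events are placed
≥15 nt from read ends because terminal indels are unresolvable under
free-end-gap alignment (see above): uniform placement would make a
planted indel rate unrecoverable *by construction* rather than by
estimator error. Deep-sequencing runs of this kind produce on the order
of 1e5 reads per sample; tests and the acceptance script run at 10,000
reads, which keeps three-binomial-SE recovery checks meaningful at a
few seconds of runtime.

What the simulations do not emulate: PCR duplicates and chimeras,
position-dependent error profiles, linkage between editing events,
multi-indel reads, and real barcode cross-talk. Passing recovery tests
therefore demonstrates estimator correctness under the stated model,
not robustness to every artifact of real libraries.

## Numerical and reporting conventions

* Coordinates: 0-based half-open internally, 1-based inclusive in all
  user-facing tables; protospacer positions always 1..20 PAM-distal.
* Percentages reported to 1 d.p., round half up — except clone counts,
  which truncate (above).
* Ambiguity codes other than N are rejected at parse time; protospacers
  containing N are discarded; codons containing N are untargetable.
* Quality encoding is fixed Phred+33; no auto-detection.
* Empty or frame-broken CDS records are flagged
  (`CdsRecord.is_frame_valid`), never silently dropped; `scan_cds`
  raises on them, batch scanning skips and reports them.
* All randomness flows from a single integer seed per generator spec;
  identical seeds give byte-identical FASTA/FASTQ output.

## Known limitations

* Genome-scale published totals depend on the specific CDS release they
  were computed from and on window-membership and multiplicity
  conventions; this package exposes both window readings (functional
  and strict) and both site multiplicities (places vs routes) but makes
  no claim to reproduce release-specific totals.
* Single-amplicon global alignment replaces read mapping; this is exact
  for targeted amplicon designs but unsuitable for genome-wide data.
* Paired-end reads are accepted only pre-merged; merging and adapter
  trimming are out of scope.
* No off-target scoring or gRNA activity prediction.
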