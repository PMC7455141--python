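# Methods

This note records the models, conventions, parameter defaults and design
choices behind `primsite`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Integration model and junction signature

SB100x-class transposases insert an IR/DR-flanked cargo exclusively at TA
dinucleotides and duplicate the target site, so after integration both
vector-chromosome junctions read TA.  `construct_integrated_sequence`
reproduces this exactly: for an event at T-index *p*,

    genome[:p+2] + left_end + cargo + right_end + genome[p:]

(the insert, including cargo, is reverse-complemented for minus-orientation
events — the two ends swap and flip, and inverse-PCR primer geometry inside
the cargo inverts with them).  All coordinates are 0-based half-open
internally; BED output is 0-based half-open and GFF3 1-based closed, per
those standards.  A "unique insertion" is a deduplicated
(chromosome, T-index) locus: because the TA is duplicated, the left- and
right-junction reads of one event canonicalize to the same T-index (a
plus-strand-mapped genomic fragment begins at the TA, a minus-strand one
ends at it), so both sides merge into one site.  Orientation conflicts at
one position (possible only under sequencing errors) keep the majority
vote, tie broken to "+", with a warning.

## Junction calling

Per read: (1) end detection — the read prefix is compared against the two
junction-proximal 20 bp end signatures with at most 1 mismatch (ties break
toward fewer mismatches, then the left end); (2) trimming; (3) mapping of
the genomic remainder against both strands by exact substring search, with
one round of single-mismatch rescue (pigeonhole on the two fragment
halves) when no exact hit exists.  Exactly one hit → mapped; two or more →
discarded as ambiguous (the conservative standard for integration-site
work); fragments under 20 bp are rejected.  (4) TA validation against the
*reference* dinucleotide at the canonical position — sequencing errors in
the read cannot shift the coordinate, only fail detection or mapping.
Every read is accounted for: reads in = supporting reads of emitted sites
+ rejections by reason (no_end / ambiguous / unmapped / no_TA /
too_short), asserted at run time.

The mapper is built in rather than delegated to an external aligner: the
genomes the pipeline targets (simulated, tens of Mb) make exact search
with mismatch rescue both sufficient and exactly analysable, and the
calling contract stays free of external binaries.  Exact-position
deduplication is the default; a `merge_window` parameter exists because
the appropriate dedup radius for noisy real data is a judgement call.

## PRIM — the windowed Poisson regression insertion model

Windows tile each chromosome from 0 in steps of `width` (default
**20 000 bp**); the final short window is kept and flagged.  TA counts per
window come from a sorted TA index via binary range counting
(overlapping occurrences counted, e.g. "TATA" → 2).  A site on a window
boundary belongs to the right-hand window (half-open convention).

The model is the canonical Poisson GLM with log link:
intercept + categorical chromosome effect (first chromosome in genome
order is the reference) + coefficient on log(TA count).  The TA-
proportional null is the testable special case coefficient = 1, and the
coefficient can be fixed (offset) for that purpose.  Fitting is IRLS,
converged when the relative log-likelihood change drops below 1e-10
(cap 100 iterations); at the optimum the intercept score equation forces
Σ fitted = Σ observed (checked to 1e-6 relative).  Windows with zero TA
count cannot receive TA-targeted insertions; they are excluded from
fitting and testing and reported as untested.  A chromosome with zero
insertions is completely separated in the likelihood; its effect is fixed
at −20 (fitted mean ≈ 2·10⁻⁹ per window) rather than dropped, so expected
counts stay defined everywhere, with a warning.

Per-window P values are one-sided upper tails P(Y ≥ y | μ̂) at the fitted
mean, ignoring estimation uncertainty — enrichment is the safety question;
depletion testing exists behind a flag.  The survival function uses the
regularized incomplete-gamma formulation (scipy), stable to k ≈ 10⁶.
Bonferroni multiplies by the number of *tested* windows (not all genomic
windows) and caps at 1; enriched ⇔ adjusted p < α (default 0.05).  Because
the Poisson tail is discrete, raw null p-values are stochastically larger
than uniform and the family-wise error rate runs below nominal — measured
≈ 0.02–0.06 at α = 0.05 over 50 replicates of 300 insertions in 500
windows, with a 50×-weighted hotspot window (~10 % of insertions) flagged
in 100 % of replicates at ≤ 0.02 false windows per replicate (recomputed
by `scripts/acceptance.py`).

The randomized null is a set of uniformly drawn reference fragments
(default 60 bp, one per observed insertion) required to contain a TA,
mapped back to the genome; each uniquely mapping fragment contributes one
site at the first TA it covers.  Observed and null per-chromosome count
vectors feed a chi-square homogeneity test, and a per-window overlay table
supports plotting.  The fragment count and length are not dictated by any
external convention; both are configuration parameters chosen once at
read-length scale.

## Inverse PCR

Restriction digestion is motif + cut-offset (SacI = GAGCT^C; overhang
chemistry is not modelled because intramolecular religation restores the
site regardless of where the offset splits the motif).  Linear digestion
of k sites yields k+1 fragments, circular k fragments.  Each fragment
circularizes (only intramolecular ligation; no concatemers); a primer pair
amplifies a circle iff the forward core and the reverse complement of the
reverse core each anneal exactly once (either strand of the circle), the
product being the arc from forward start to reverse end; a primer
annealing twice is an ambiguous-product error.  Nested mode re-amplifies
the first-round product linearly with the inner pair.  Primer matching is
exact after removing the 16 bp cloning tails of the shipped EF1α/3′HS1
nested sets; mismatch-tolerant annealing is out of scope.  Junction
extraction locates a 20 bp junction-proximal IR/DR segment (either end,
either strand) in the amplicon, maps the adjoining ≥ 20 bp genomic run
with the junction caller's mapper, validates the TA, and reports the
event; an amplicon implying two distinct junctions is ambiguous, never
guessed.  End-to-end recovery caps the genomic window per event at 50 kb —
a proxy for the circle sizes PCR traverses efficiently, since the real
efficiency-versus-size relationship is not modelled — and events whose
nearest restriction site lies beyond it are reported unrecoverable.  For
simulation, `build_ipcr_ready_transposon` embeds the two nested primer
cassettes (with flanking restriction sites) at the cargo ends, mirroring
how the real vector carries its primer landing sites.

## Feature annotation

Categories: cds, utr5, utr3, intron, upstream_1kb, downstream_1kb,
intergenic — exhaustive and mutually exclusive under the precedence
cds > utr5 > utr3 > intron > upstream_1kb > downstream_1kb > intergenic.
Genic membership uses the transcript span; introns are the within-span
gaps between exonic (CDS ∪ UTR) intervals.  Flanks (default 1 000 bp) are
strand-aware: upstream means 5′ of the TSS on the gene's own strand, and
"1 kb downstream" is measured from the annotated transcript 3′ end.  The
precedence order (genic before flank, coding before UTR before intron)
follows common annotation-tool convention; it is not externally dictated
and is configurable.  One transcript per gene is assumed.  One category
label in circulating figure legends for this assay family reads "3′UTR of
exons" alongside a separate 3′UTR class; that is internally inconsistent
and is encoded here as the 5′UTR category.  Percentages are over unique
sites (read support ignored).  Sites on chromosomes absent from the gene
model classify intergenic with a warning.

## Synthetic-data generator

Defaults describe the reference study condition: 4 chromosomes × 2.5 Mb
(500 windows of 20 kb), i.i.d. bases at GC 0.42 (mouse-like), 100
single-transcript genes (1–4 CDS exons, optional UTRs, introns 0.2–1.5 kb,
nonoverlapping unless a fraction of overlapping pairs is requested for
precedence tests), 200 integrations sampled without replacement uniformly
over TA sites (hotspots multiply per-TA weights; sampling is exact
weighted-without-replacement via Gumbel-top-k), fair-coin orientation,
3 reads per junction side, 80 bp reads carrying a 20 bp end signature,
substitution errors i.i.d. at a configurable rate (default 0), constant
"I" qualities.  The default transposon totals 32 400 bp (11 800 bp
preset also provided) with 160 bp pseudo-random IR/DR ends checked to be
absent from the simulated genome, and pseudo-random non-genomic cargo so
reads never multimap into cargo.  All streams derive from one seed through
tagged child generators, so identical configurations give byte-identical
FASTA/FASTQ/GFF3/BED outputs regardless of call order.

What the generator does *not* emulate — and therefore what green tests do
not certify about real data: base-quality structure, indels, PCR
duplicates and chimeras, restriction/sonication bias of real LAM-PCR,
repetitive or low-complexity genome content (multimapping is rare by
construction), isoform complexity, and chromatin-driven integration
preferences.  Round-trip recall of 100 % is a property of clean reads on
a repeat-free genome; the error-robustness tests (recall ≥ 95 % at 0.5 %
substitution rate) probe the rescue path, not real error spectra.

## Numerical choices and degenerate inputs

IRLS linear algebra solves the weighted normal equations with an lstsq
fallback on singularity; linear predictors are clipped to [−500, 30]
before exponentiation during iteration.  The log-likelihood uses the
gammaln formulation.  Tail probabilities below the subnormal range
(~1e−290) are reported as computed but compared only in absolute terms.
Zero observed insertions overall is a degenerate-fit error; an empty site
table from calling is a warning plus empty outputs, not an error.  Gene
placement retries 200 positions before raising a density error.  In
coefficient-recovery checks the intercept is assessed at the mean
covariate value (equivalently, after centering log TA): the raw intercept
trades off against the TA slope through mean(log TA) ≈ 6.5 and is not
separately identifiable to tight tolerance at a few thousand events.

## Problem sizes used in tests and the acceptance script

Round-trip recovery runs 200 events on the 10 Mb genome; PRIM error/power
run 50 replicates × 300 insertions × 500 windows; GLM oracle equivalence
runs 20 small instances (≤ 6 windows) against an iteratively refined
QR-orthogonalized grid search plus 3 × 500-window recovery simulations at
~2 000 insertions; the inverse-PCR oracle covers 100 (tests) / 40
(script) random 40 kb constructs; annotation agreement covers 1 000 sites
against 60 genes with 25 % forced overlaps; occupancy uses 10 seeds of
100 insertions over 500 windows, where a multinomial Monte-Carlo oracle
puts P(max ≤ 3) ≥ 0.9.  These sizes make the whole suite run in well
under a minute of statistics plus ~20 s of read mapping.

## Known limitations

Single-transcript gene models; no proto-oncogene proximity annotation (a
curated gene list is deliberately out of scope); no overdispersion
(negative-binomial) option — PRIM assumes Poisson counts, adequate for
sparse integration data but not for clonally expanded samples where one
clone inflates a window; Bonferroni only (FDR alternatives would be
trivial to add but are not the contract); no plot rendering — the
per-window and overlay tables are written for external plotting.
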