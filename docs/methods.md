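# Methods

This note documents the models, rules and numerical choices behind
`ribopause`, in the order the pipeline runs.

## Simulated libraries

The simulator exists so that every statistic the pipeline computes can be
checked as a parameter-recovery experiment. A `SimSpec` describes one
library; the defaults are the package's study conditions.

**Transcriptome.** Each primary transcript is 5′UTR + CDS + 3′UTR with
uniform random lengths (defaults: UTRs 60–120 nt, CDS 120–300 sense codons).
The CDS starts with ATG, ends with a random stop codon, and encodes a
uniform random peptide into uniformly chosen synonymous codons. A configured
number of tripeptide motifs (default one PPP per transcript) is planted at
random positions with ≥ 5 flanking codons and ≥ 10 codons between
occurrences; a repair loop mutates background residues until a
translate-and-scan finds *exactly* the planted set, so the truth table is
authoritative. A small second-species transcriptome (`spike|`-prefixed IDs,
default 20 transcripts) is generated the same way without motifs.

**Footprints.** Each footprint's P-site codon is drawn from a categorical
distribution over CDS codons with weight λ per codon, multiplied by the
start enrichment *s* at codon 0 and the pause multiplier *m* at motif
codons. Read length follows a categorical over 26–35 nt with its mass on the
gel-selected 27–30 nt range; the 5′ end sits o(L) nt upstream of the P-site
codon, with planted offsets rising monotonically from 11 nt (26-mers) to
15 nt (35-mers) around the canonical ≈ 12 nt for 28-mers. Placements that
would run off the transcript are resampled and counted (with the default
geometry this is never triggered).

**Read classes.** A multinomial split assigns each of `depth` reads to
footprint / low-quality (default 2%) / contaminant (5%) / spike-in (15%)
classes. The spike-in default follows the experimental design of mixing
primary and foreign-species lysate at a fixed ratio whose RNA yield is about
5:1; the read-level fraction is not knowable in advance, so 0.15 is a
realistic round figure, not a fit. Contaminant reads are uniform substrings
of a bundled *synthetic* rRNA-like FASTA (generated GC-biased random
sequences — stand-ins, not real rRNA). Low-quality reads get Phred 10
qualities, everything else Phred 40. The full adapter
(`ATCTCGTATGCCGTCTTCTGCTTG`) is appended to every read.

**No-go decay.** With probability `nogo_drop`, a read whose P-site lies in a
motif codon is discarded before output — the footprint-level consequence of
degrading mRNAs that carry severely stalled ribosomes. Dropped reads are
counted, so class accounting stays exact.

**Exact-trimming guarantee.** The generator removes every occurrence of the
adapter's seed heptamer from transcripts and contaminants (synonymous-codon
resampling inside CDSs, free base changes in UTRs). Without this, chance
seed matches inside inserts would truncate a handful of reads per 10⁵ and
break the exact read-for-read correspondence between kept alignments and
truth. Reads are error-free by default (`read_error_rate` is a knob) so that
exact-match alignment is complete and the analysis layer is tested in
isolation.

**What the simulator does not emulate:** sequencing errors beyond uniform
substitutions, UMI structure, spliced genomes, reverse-strand reads, codon-
level dwell-time variation beyond the planted multipliers, and biological
variability between transcripts (λ is shared). Passing recovery tests
therefore demonstrates correctness of the analysis arithmetic under the
stated generative model, not robustness to every artifact of real libraries.

## Preprocessing

Order: adapter trimming → quality filter → contaminant depletion →
alignment → length filter. Each read lands in exactly one ledger category
and `input = Σ categories` is asserted after every run.

* **Trimming** locates the leftmost exact match of the adapter's first 8 nt;
  the insert is everything before it. No match, or an insert < 20 nt, is a
  discard (20 nt sits safely below the shortest calibratable footprint).
  Mismatch-tolerant trimming is out of scope — the simulator writes exact
  adapters.
* **Quality**: keep iff mean per-base Phred ≥ 20 (the boundary keeps);
  a per-base-minimum mode is available for stricter use.
* **Depletion**: a read is removed iff it is an exact substring of a
  contaminant sequence (newline-joined haystack, so matches cannot span
  sequences).
* **Alignment** is an exact-substring search over a 20-mer index of the
  sense strand. Exactly one match → one alignment; zero → unaligned; more
  than one (across or within transcripts) → multimapped and dropped, which
  keeps counts deterministic. This is a self-contained substitute for a
  short-read aligner, valid because simulated reads are error-free and
  essentially always unique at ≥ 26 nt. A SAM import path (primary,
  forward-strand, gapless records only) accepts externally aligned reads.
* **Length filter**: closed range, default [26, 35] nt.

## P-site calibration

For each read length L, the 5′-end histogram in a [−40, +20] nt window
around start codons (wide enough for initiating-ribosome geometry at every
length in range) peaks at −o(L), because initiating ribosomes place the
start codon in their P-site. o(L) = −(modal position); ties break toward the
smaller offset; lengths with window support < 100 reads (default) are left
uncalibrated and their reads skipped and counted rather than imputed from
neighbouring lengths — imputation is possible behind a flag but silently
biases position estimates when the mode is wrong. The canonical expectation
o(28) ≈ 12 nt is documentation, never a hard-coded value.

Coverage is stored over the whole transcript in the CDS reading frame
(codon index ⌊(p − cds_start)/3⌋, negative in the 5′UTR), so landmark
windows that reach into UTRs stay well defined; sub-codon phase is ignored
at assignment since no frame-filtering rule is part of the method.
Conservation — Σ codon counts + out-of-CDS + skipped = kept alignments — is
a tested invariant.

## Metagenes

Per transcript (or motif occurrence), window counts are normalized by the
row's own window mean, making profiles depth-independent and comparable
across libraries; raw-count mode exists behind a flag. Rows with zero signal
in the window are excluded *before any other filter*. Columns are averaged
after removing values strictly above the nearest-rank (1 − f) quantile and
strictly below the f quantile (f = 0.001 by default). Nearest-rank with
strict comparisons is chosen for reproducible integer semantics: for
n ≥ 1/f it removes the extreme 0.1% tails, for n < 1/f it degrades to a
no-op rather than deleting the minimum and maximum. Default windows are
[−20, +100] codons around the start and [−100, +20] around the stop;
both are configurable.

## Pause analysis

Occurrences come from in-frame translation and an overlap-permitting scan
(PPPP yields two PPPs); each needs ≥ 5 flanking codons. The scalar score
averages the three motif codons rather than singling out one, because the
P-site vs A-site registration of the stall is a property worth inspecting,
not assuming — the per-offset motif metagene (window [−5, +7] codons,
flank-mean normalized) exposes the registration. The background is the mean
over codons 5–50 codons away on each side, excluding other occurrences'
codons and the first/last 5 CDS codons (initiation/termination ramps);
occurrences with background below 0.5 reads/codon are flagged unusable and
never divide by zero. The library aggregate is the median (robust to the
heavy right tail of ratio statistics); the mean is available behind a flag.

Conditions are compared by the ratio of aggregate scores with a seeded
percentile bootstrap (default 1000 resamples) over occurrences, refusing to
run with fewer than 10 usable occurrences per side. A CI is reported rather
than a named test because the scientific claim at stake — "treatment did
not further increase occupancy" — is a statement about effect size, not
significance. In the no-go-decay scenario, parity between a baseline
multiplier m and a doubled multiplier 2m requires motif-read loss of
probability 0.5, since observed occupancy scales as m·(1 − p); the
simulator's `nogo_drop` is that probability.

## Pipeline and normalization

`run_pipeline` executes simulate/load → preprocess → spike-in accounting →
calibration → coverage → metagenes → pause analysis in fixed order, writes
every intermediate as text (FASTA/FASTQ/SAM/TSV/JSON), and emits a report
with per-library ledgers, offset tables, timings, and the hash of the
resolved configuration. All randomness derives from the single run seed, so
identical config + seed reproduce byte-identical tables.

Spike-in factors are geometric-mean centered (factor_i = spike_i /
gmean(spike)): symmetric across libraries, no designated reference, and the
factors of a run multiply to 1. Species are assigned by transcript-ID prefix,
mirroring a concatenated-genome design without any taxonomy machinery.
Whether to normalize coverage by spike-in factors at all is experiment-
dependent (a spike-in can also serve purely as a bench-side RNA accounting
control), so normalization is provided but off by default.

## Problem sizes

The recovery experiments run at 200 transcripts with 2 × 10⁵ footprints for
offset calibration (≈ 16k reads land in the calibration window, 500+ for
every length carrying ≥ 2% of the mass) and 5 × 10⁵ for pause scoring
(≈ 8–10 reads/codon background, comfortably above the 0.5 usability floor).
These sizes put Poisson noise on the recovered quantities near or below 1%,
an order of magnitude inside the asserted tolerances. The toy pipeline
fixture (5 transcripts, 2000 reads) exercises every stage end-to-end in a
few seconds with a lowered calibration support threshold of 10.

## Known limitations

* Exact-match alignment cannot place reads with sequencing errors; real
  libraries need an external aligner plus the SAM import path.
* Offsets are global per length; no per-transcript or frame-aware
  refinement, no A-site model, no initiation-site discovery.
* Pause scores assume a locally flat background; strong nearby features
  other than planted motifs would bias the denominator.
* The start-codon accumulation signature can be inflated by cycloheximide
  artifacts in real experiments; nothing in this package corrects for that.
* No-go decay is modelled only as footprint loss at motif codons, not as
  transcript-level degradation kinetics.
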