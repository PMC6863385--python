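# ribopause

Ribosome-profiling analysis for translational pausing: P-site offset
calibration per read length, outlier-trimmed metagene profiles, spike-in
normalization, and tripeptide-motif pause scoring — together with a footprint
simulator that plants every one of those quantities as a known ground truth.

## The problem

Ribosome profiling sequences the ~26–35 nt mRNA fragments protected by
translating ribosomes. Turning those fragments into codon-resolution
occupancy requires a chain of small, error-prone steps: trimming the 3′
adapter, discarding low-quality reads, depleting rRNA contaminants, aligning
to the transcriptome, and — crucially — assigning each read to the codon in
the ribosome's P-site, which sits a read-length-dependent offset o(L)
downstream of the read's 5′ end. Once coverage is codon-indexed, two
signatures of impaired elongation become measurable: accumulation of
ribosomes at the start codon, and stalling at polyproline-type motifs
(PPP, SPP, PPV — the sites whose smooth translation requires hypusinated
eIF5A). A complication is no-go decay: mRNAs carrying severely stalled
ribosomes are degraded, so a *stronger* stall can paradoxically show *no
increase* in footprint occupancy.

Because real libraries come with no ground truth, every statistic here is
validated by parameter recovery on simulated data: the simulator plants
offsets, enrichments and pause multipliers; the pipeline must recover them.

## The statistics

* **Offset calibration.** For each read length L, pool the 5′-end positions
  of reads in a window (default [−40, +20] nt) around annotated start
  codons. The modal position is −o(L); ties break toward the smaller offset;
  lengths with fewer than `min_support` window reads stay uncalibrated and
  are excluded. The P-site codon of a read is then
  ⌊(5′ + o(L) − cds_start)/3⌋.
* **Metagene profiles.** Per transcript, window counts are normalized by the
  transcript's window mean; transcripts with zero reads in the window are
  excluded before any other filter; at each position the highest and lowest
  0.1% of signals (nearest-rank quantiles) are removed before averaging.
* **Pause score.** For a motif occurrence at codon i, score =
  mean count over the motif codons ÷ mean count over flanking codons
  (5–50 codons away, excluding other occurrences and the CDS edges). 1.0
  means no pausing; the library aggregate is the median over usable
  occurrences.
* **Condition comparison.** ratio = median(B)/median(A) with a seeded
  percentile-bootstrap 95% CI over occurrences.
* **Spike-in normalization.** With a foreign-species spike-in,
  factor_i = spike_i / geometric-mean(spike); coverage divides by the
  factor, so factors of a run multiply to 1.

## Worked example

```python
import ribopause as rp

# plant a 4x pause at one PPP motif per transcript
spec = rp.SimSpec(n_transcripts=200, depth=500_000, pause_multiplier=4.0, seed=1)
transcripts, truth = rp.generate_transcriptome(spec)
alignments, truth = rp.simulate_alignments(transcripts, truth, spec)

offsets = rp.calibrate_offsets(alignments, transcripts)
print(offsets.to_frame().to_string(index=False))

coverage = rp.psite_coverage(alignments, offsets, transcripts)
occurrences = rp.scan_motifs(transcripts, "PPP")
scores = rp.pause_score_table(coverage, occurrences)
print(f"median pause score: {scores.aggregate_score():.3f}")
```

prints

```
 length  offset  support  sharpness
     26      11     1564   0.343990
     27      11     6502   0.328976
     28      12     9638   0.332745
     29      13     8553   0.314393
     30      13     4149   0.313087
     31      13     1387   0.317952
     32      14      704   0.312500
     33      14      358   0.254190
     34      15      180   0.277778
     35      15      150   0.293333
median pause score: 3.961
```

The planted offsets (11, 11, 12, 13, 13, 13, 14, 14, 15, 15 for lengths
26–35) are recovered at every length, `support` counts the reads in each
length's start-codon window, and `sharpness` is the fraction of window reads
in the modal bin. The median pause score 3.961 recovers the planted 4×
multiplier to 1%. The motif metagene around the same occurrences shows the
stall directly — ~1.0 everywhere except ~4 at the three motif codons:

```
offset from motif:  -5   -4   -3   -2   -1    0    1    2    3    4    5    6    7
occupancy:        1.01 0.96 1.07 0.98 0.98 4.17 4.11 4.04 0.99 1.00 1.01 1.00 0.99
```

The same workflow is available from the shell:

```bash
ribopause simulate --out sim/ --seed 1
ribopause preprocess --reads sim/reads.fastq --transcriptome sim/transcriptome.fa \
    --annotation sim/annotation.tsv --out pre/
ribopause psite --alignments pre/alignments.sam --transcriptome sim/transcriptome.fa \
    --annotation sim/annotation.tsv --out ps/
ribopause run --config cfg.yaml   # full pipeline + report.json
```

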