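"""Independent oracles and small builders used across the test suite.

Everything here is deliberately written as naive, brute-force code that does
not share logic with the package implementation it checks.
"""
from __future__ import annotations

import math
import re

import numpy as np
from Bio.Seq import Seq

from ribopause.io import TranscriptRecord
from ribopause.psite import CodonCoverage


def translate_scan_oracle(transcripts, motif):
    """Find motif occurrences by translating each CDS and regex-scanning
    with an overlap-permitting lookahead. Returns {(tid, codon_index)}."""
    found = set()
    pattern = re.compile(f"(?={re.escape(motif)})")
    for tid, rec in transcripts.items():
        if rec.species != "primary":
            continue
        aa = str(Seq(rec.cds).translate())
        for m in pattern.finditer(aa):
            found.add((tid, m.start()))
    return found


def trimmed_kept_oracle(values, trim_frac):
    """Sort-and-slice: the values surviving the trim — everything between the
    nearest-rank f and 1-f quantiles inclusive (strict drops outside)."""
    v = sorted(float(x) for x in values)
    n = len(v)
    if trim_frac == 0:
        return v
    lo_rank = min(max(math.ceil(trim_frac * n), 1), n)
    hi_rank = min(max(math.ceil((1 - trim_frac) * n), 1), n)
    lo, hi = v[lo_rank - 1], v[hi_rank - 1]
    return [x for x in v if lo <= x <= hi]


def trimmed_mean_oracle(values, trim_frac):
    """Brute-force trimmed mean via :func:`trimmed_kept_oracle`."""
    kept = trimmed_kept_oracle(values, trim_frac)
    return sum(kept) / len(kept)


def naive_metagene(coverage, landmark, window, species="primary"):
    """Double-loop metagene with window-mean normalization and no trimming."""
    a, b = window
    rows = []
    for tid, rec in coverage.annotation.items():
        if rec.species != species:
            continue
        c0 = 0 if landmark == "start" else rec.n_codons - 1
        win = coverage.window(tid, c0 + a, c0 + b)
        if win is None or win.sum() == 0:
            continue
        rows.append(win / win.mean())
    out = []
    for j in range(b - a + 1):
        out.append(sum(r[j] for r in rows) / len(rows))
    return np.array(out)


def toy_transcript(tid, utr5, codon_aas, utr3, species="primary", rng=None):
    """Build a transcript from explicit UTR sequences and a peptide; codons
    are the alphabetically first synonymous codon of each residue."""
    from ribopause.synthetic import CODONS_BY_AA

    codons = [CODONS_BY_AA[a][0] for a in codon_aas]
    cds = "".join(codons) + "TAA"
    seq = utr5 + cds + utr3
    return TranscriptRecord(tid, seq, len(utr5), len(utr5) + len(cds), species)


def toy_config(outdir, seed=5):
    """The bundled toy fixture: 5 transcripts, 2000 reads, one library."""
    import ribopause as rp

    return rp.RunConfig(
        outdir=str(outdir),
        seed=seed,
        sim={
            "n_transcripts": 5,
            "n_spike_transcripts": 2,
            "depth": 2000,
            "cds_codons": [120, 160],
        },
        libraries=[rp.LibraryConfig("A")],
        min_support=10,
        n_boot=200,
        compare=False,
    )


def coverage_with_counts(transcripts, counts_by_tid):
    """CodonCoverage with CDS counts set directly (UTRs left at zero)."""
    cov = CodonCoverage(transcripts)
    for tid, counts in counts_by_tid.items():
        arr = cov.cds_counts(tid)
        arr[:] = np.asarray(counts, dtype=float)
    return cov
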