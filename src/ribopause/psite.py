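"""P-site offset calibration and codon-level coverage.

The offset o(L) for each read length L is read off the start-codon metagene:
pooled across transcripts, the 5'-ends of initiating-ribosome footprints of
length L pile up o(L) nt upstream of the first nucleotide of the start codon,
so the modal position of the 5'-end histogram in a window around the start
codon determines the offset. Calibrated offsets convert alignments into
per-transcript codon-indexed P-site counts.

Coverage is stored over the whole transcript in the CDS reading frame
(codon index ``q = floor((p - cds_start) / 3)``, negative in the 5'UTR,
``>= n_codons`` in the 3'UTR) so that landmark windows extending into the
UTRs remain well defined; counts outside ``[0, n_codons)`` are reported as
out-of-CDS.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AlignmentRecord, TranscriptRecord

#: default 5'-end histogram window around the start codon, nt (closed)
DEFAULT_CALIBRATION_WINDOW = (-40, 20)
#: default minimum reads in the window for a length to be calibrated
DEFAULT_MIN_SUPPORT = 100


@dataclass(frozen=True)
class FivePrimeHistogram:
    """5'-end counts relative to the first nt of the start codon."""

    length: int
    rel_positions: np.ndarray  # window positions a..b (closed)
    counts: np.ndarray
    flagged_empty: bool

    @property
    def support(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class OffsetEntry:
    offset: int | None  # None == uncalibrated
    support: int
    sharpness: float  # fraction of window reads in the modal bin

    @property
    def calibrated(self) -> bool:
        return self.offset is not None


@dataclass
class PSiteOffsetTable:
    """Calibrated 5'-end -> P-site offsets per read length."""

    entries: dict[int, OffsetEntry] = field(default_factory=dict)

    def offset(self, length: int) -> int | None:
        e = self.entries.get(length)
        return e.offset if e else None

    def calibrated_lengths(self) -> list[int]:
        return sorted(L for L, e in self.entries.items() if e.calibrated)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (L, e.offset if e.calibrated else "uncalibrated", e.support, e.sharpness)
            for L, e in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["length", "offset", "support", "sharpness"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_offsets(cls, offsets: Mapping[int, int], support: int = 0) -> "PSiteOffsetTable":
        """Build a table from known offsets (e.g. a simulator's truth)."""
        return cls({int(L): OffsetEntry(int(o), support, 1.0) for L, o in offsets.items()})


def five_prime_histogram(
    alignments: Iterable[AlignmentRecord],
    annotation: Mapping[str, TranscriptRecord],
    length: int,
    window: tuple[int, int] = DEFAULT_CALIBRATION_WINDOW,
) -> FivePrimeHistogram:
    """Histogram of 5'-end positions relative to the start codon, pooled
    across transcripts, for reads of one length."""
    a, b = window
    rel = np.arange(a, b + 1)
    if b < a:
        return FivePrimeHistogram(length, rel, np.zeros(0, dtype=int), True)
    counts = np.zeros(b - a + 1, dtype=int)
    for aln in alignments:
        if aln.length != length:
            continue
        rec = annotation.get(aln.transcript_id)
        if rec is None:
            raise KeyError(f"no annotation for transcript {aln.transcript_id}")
        r = aln.five_prime_pos - rec.cds_start
        if a <= r <= b:
            counts[r - a] += 1
    return FivePrimeHistogram(length, rel, counts, counts.sum() == 0)


def calibrate_offsets(
    alignments: Sequence[AlignmentRecord],
    annotation: Mapping[str, TranscriptRecord],
    lengths: Iterable[int] = range(26, 36),
    window: tuple[int, int] = DEFAULT_CALIBRATION_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> PSiteOffsetTable:
    """Determine o(L) per read length from start-codon metagene modes.

    o(L) is minus the modal relative 5'-end position; ties are broken toward
    the smaller offset. Lengths with window support below ``min_support`` (or
    a mode that implies an offset outside [0, L]) are marked uncalibrated and
    excluded downstream. Raises if no length is calibratable.
    """
    table = PSiteOffsetTable()
    for L in lengths:
        hist = five_prime_histogram(alignments, annotation, L, window)
        support = hist.support
        if support < min_support:
            table.entries[L] = OffsetEntry(None, support, 0.0)
            continue
        top = hist.counts.max()
        # ties toward the smaller offset == the larger relative position
        mode_rel = int(hist.rel_positions[hist.counts == top].max())
        offset = -mode_rel
        sharpness = float(top / support)
        if 0 <= offset <= L:
            table.entries[L] = OffsetEntry(offset, support, sharpness)
        else:
            table.entries[L] = OffsetEntry(None, support, sharpness)
    if not table.calibrated_lengths():
        raise RuntimeError(
            "no read length could be calibrated; the library is too shallow "
            "in the start-codon window (try lowering min_support or sequencing deeper)"
        )
    return table


class CodonCoverage:
    """Per-transcript codon-indexed P-site counts in the CDS reading frame.

    ``cds_counts(tid)`` gives the counts for codons ``0..n_codons-1``;
    positions outside the CDS are kept (for UTR-reaching metagene windows)
    and summarized by ``out_of_cds``. Conservation invariant::

        sum(cds counts) + out_of_cds + skipped_uncalibrated == alignments in
    """

    def __init__(self, annotation: Mapping[str, TranscriptRecord]):
        self.annotation = dict(annotation)
        self._qmin: dict[str, int] = {}
        self._arr: dict[str, np.ndarray] = {}
        for tid, rec in self.annotation.items():
            qmin = (0 - rec.cds_start) // 3  # floor division: first frame index
            qmax = (len(rec.sequence) - 1 - rec.cds_start) // 3
            self._qmin[tid] = qmin
            self._arr[tid] = np.zeros(qmax - qmin + 1)
        self.skipped_uncalibrated = 0
        self.n_assigned = 0

    # -- accessors ---------------------------------------------------------

    def frame_counts(self, tid: str) -> tuple[np.ndarray, int]:
        """Full frame array and its first codon index (negative in 5'UTR)."""
        return self._arr[tid], self._qmin[tid]

    def cds_counts(self, tid: str) -> np.ndarray:
        arr, qmin = self._arr[tid], self._qmin[tid]
        n = self.annotation[tid].n_codons
        return arr[-qmin:-qmin + n]

    def out_of_cds(self, tid: str) -> float:
        arr, qmin = self._arr[tid], self._qmin[tid]
        n = self.annotation[tid].n_codons
        return float(arr[:-qmin].sum() + arr[-qmin + n:].sum())

    def out_of_cds_total(self) -> float:
        return sum(self.out_of_cds(tid) for tid in self._arr)

    def total_assigned(self, tid: str) -> float:
        return float(self._arr[tid].sum())

    def window(self, tid: str, lo: int, hi: int) -> np.ndarray | None:
        """Counts for codon-frame positions lo..hi (closed), or None if the
        window does not fit inside the transcript."""
        rec = self.annotation[tid]
        if rec.cds_start + 3 * lo < 0 or rec.cds_start + 3 * (hi + 1) > len(rec.sequence):
            return None
        arr, qmin = self._arr[tid], self._qmin[tid]
        return arr[lo - qmin:hi - qmin + 1]

    # -- mutation / bookkeeping --------------------------------------------

    def conservation_total(self) -> float:
        in_cds = sum(self.cds_counts(t).sum() for t in self._arr)
        return float(in_cds + self.out_of_cds_total() + self.skipped_uncalibrated)

    def scale(self, factor: float) -> "CodonCoverage":
        """Return a copy with all counts divided by ``factor`` (spike-in
        normalization). Bookkeeping counters stay in read units."""
        out = CodonCoverage(self.annotation)
        for tid in self._arr:
            out._arr[tid] = self._arr[tid] / factor
        out.skipped_uncalibrated = self.skipped_uncalibrated
        out.n_assigned = self.n_assigned
        return out

    def to_frame(self, species: str | None = None) -> pd.DataFrame:
        """CDS codon counts as a tidy (transcript_id, codon_index, count) table."""
        rows = []
        for tid, rec in self.annotation.items():
            if species is not None and rec.species != species:
                continue
            counts = self.cds_counts(tid)
            rows.append(pd.DataFrame({
                "transcript_id": tid,
                "codon_index": np.arange(rec.n_codons),
                "count": counts,
            }))
        return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
            columns=["transcript_id", "codon_index", "count"]
        )


def psite_coverage(
    alignments: Sequence[AlignmentRecord],
    offsets: PSiteOffsetTable,
    annotation: Mapping[str, TranscriptRecord],
) -> CodonCoverage:
    """Apply calibrated offsets to alignments and count P-sites per codon.

    The P-site nucleotide is ``five_prime_pos + o(L)``; its codon index is
    ``floor((p - cds_start)/3)`` regardless of sub-codon phase. Reads of
    uncalibrated lengths are skipped and counted. Raises KeyError naming the
    transcript if an aligned transcript is missing from the annotation.
    """
    cov = CodonCoverage(annotation)
    if not alignments:
        return cov
    tids = [a.transcript_id for a in alignments]
    for tid in set(tids):
        if tid not in annotation:
            raise KeyError(f"no annotation for transcript {tid}")
    tid_codes, tid_names = pd.factorize(np.asarray(tids, dtype=object))
    fives = np.fromiter((a.five_prime_pos for a in alignments), dtype=np.int64, count=len(alignments))
    lens = np.fromiter((a.length for a in alignments), dtype=np.int64, count=len(alignments))

    max_len = int(lens.max())
    off_lut = np.full(max_len + 1, -1, dtype=np.int64)
    for L, e in offsets.entries.items():
        if e.calibrated and L <= max_len:
            off_lut[L] = e.offset
    calibrated = off_lut[lens] >= 0
    cov.skipped_uncalibrated = int((~calibrated).sum())

    cds_start = np.array([annotation[t].cds_start for t in tid_names])
    p = fives[calibrated] + off_lut[lens[calibrated]]
    tc = tid_codes[calibrated]
    q = np.floor_divide(p - cds_start[tc], 3)
    cov.n_assigned = int(len(p))
    for code, tid in enumerate(tid_names):
        mask = tc == code
        if not mask.any():
            continue
        qmin = cov._qmin[tid]
        idx = q[mask] - qmin
        np.add.at(cov._arr[tid], idx, 1)
    return cov
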