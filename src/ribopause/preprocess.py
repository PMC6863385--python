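"""Read preprocessing: adapter trimming, quality and contaminant filtering,
and exact-match transcriptome alignment with full bookkeeping.

Every input read ends up in exactly one :class:`FilterLedger` category, so
``input == adapter_discarded + quality_discarded + contaminant + unaligned +
multimapped + length_excluded + kept`` holds after every run. Alignment is an
exact-substring search over a k-mer index of the sense strand; reads with
exactly one match are kept, multimappers are dropped deterministically.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

from .io import AlignmentRecord, ReadRecord, TranscriptRecord

# re-exported record types (they live with the file formats)
__all__ = [
    "ReadRecord",
    "AlignmentRecord",
    "FilterLedger",
    "trim_adapter",
    "quality_filter",
    "deplete_contaminants",
    "TranscriptomeIndex",
    "align_to_transcriptome",
    "length_filter",
    "run_preprocess",
]

#: adapter-locator seed length (exact match, no mismatches)
ADAPTER_SEED_LEN = 8
#: shortest insert kept after trimming, in nt
MIN_INSERT = 20


@dataclass
class FilterLedger:
    """Per-library read accounting; ``input`` must equal the partition sum."""

    input: int = 0
    adapter_discarded: int = 0
    quality_discarded: int = 0
    contaminant: int = 0
    unaligned: int = 0
    multimapped: int = 0
    length_excluded: int = 0
    kept: int = 0

    def partition_sum(self) -> int:
        return (
            self.adapter_discarded + self.quality_discarded + self.contaminant
            + self.unaligned + self.multimapped + self.length_excluded + self.kept
        )

    def check(self) -> None:
        if self.input != self.partition_sum():
            raise AssertionError(
                f"ledger does not conserve reads: input={self.input}, "
                f"partition sum={self.partition_sum()}"
            )

    def to_dict(self) -> dict[str, int]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def trim_adapter(
    read: ReadRecord,
    adapter: str,
    min_insert: int = MIN_INSERT,
    seed_len: int = ADAPTER_SEED_LEN,
) -> tuple[ReadRecord | None, str]:
    """Trim the 3' adapter off a read by exact seed match.

    The insert is everything before the leftmost exact occurrence of the
    adapter's first ``seed_len`` nt; qualities are trimmed in step. Returns
    ``(trimmed_read, "ok")`` or ``(None, code)`` with code one of ``"empty"``,
    ``"no_adapter"``, ``"short_insert"``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not read.sequence:
        return None, "empty"
    pos = read.sequence.find(adapter[:seed_len])
    if pos == -1:
        return None, "no_adapter"
    if pos < min_insert:
        return None, "short_insert"
    return ReadRecord(read.id, read.sequence[:pos], read.quality[:pos]), "ok"


def quality_filter(
    read: ReadRecord, min_mean_phred: float = 20.0, per_base: bool = False
) -> bool:
    """Keep a read iff its mean per-base Phred score reaches the threshold.

    ``per_base=True`` switches to requiring every base to reach the
    threshold (the stricter reading of a per-read quality cut-off).
    """
    if per_base:
        return read.min_phred() >= min_mean_phred
    return read.mean_phred() >= min_mean_phred


def deplete_contaminants(
    reads: Sequence[ReadRecord], contaminants: Mapping[str, str]
) -> tuple[list[ReadRecord], int]:
    """Remove reads occurring as exact substrings of any contaminant sequence.

    Survivors are returned unchanged and in input order. An empty contaminant
    set is an identity pass-through with a warning.
    """
    if not contaminants:
        warnings.warn("empty contaminant set: depletion is a no-op")
        return list(reads), 0
    # newline-joined haystack: reads are ACGTN, so matches never span sequences
    haystack = "\n".join(contaminants.values())
    survivors = [r for r in reads if r.sequence not in haystack]
    return survivors, len(reads) - len(survivors)


class TranscriptomeIndex:
    """K-mer index over transcript sense strands for exact substring lookup.

    Every full-read match starts with the read's first k nt, so the postings
    list of that k-mer covers all candidate start positions; candidates are
    verified by direct string comparison.
    """

    def __init__(self, transcripts: Mapping[str, TranscriptRecord] | Sequence[TranscriptRecord], k: int = 20):
        if not isinstance(transcripts, Mapping):
            transcripts = {t.id: t for t in transcripts}
            if len(transcripts) != len(set(t.id for t in transcripts.values())):
                raise ValueError("duplicate transcript IDs")
        self.k = k
        self.transcripts = dict(transcripts)
        self._index: dict[str, list[tuple[str, int]]] = {}
        for tid, rec in self.transcripts.items():
            seq = rec.sequence
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos:pos + k], []).append((tid, pos))

    def matches(self, sequence: str) -> list[tuple[str, int]]:
        """All (transcript_id, position) exact full-length matches."""
        if len(sequence) < self.k:
            return []
        out = []
        for tid, pos in self._index.get(sequence[:self.k], ()):
            if self.transcripts[tid].sequence[pos:pos + len(sequence)] == sequence:
                out.append((tid, pos))
        return out


def _check_unique_ids(transcripts: Mapping[str, TranscriptRecord]) -> None:
    # a Mapping can't hold duplicates; guard list-of-records inputs upstream
    if len(set(transcripts)) != len(transcripts):
        raise ValueError("duplicate transcript IDs")


def align_to_transcriptome(
    reads: Sequence[ReadRecord],
    transcripts: Mapping[str, TranscriptRecord] | TranscriptomeIndex,
    k: int = 20,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Place reads on the transcriptome by unique exact match (sense strand).

    Reads with exactly one match produce one :class:`AlignmentRecord`; zero
    matches are counted ``unaligned`` and >1 matches (across or within
    transcripts) are counted ``multimapped`` and dropped. Output order is
    input read order.
    """
    index = transcripts if isinstance(transcripts, TranscriptomeIndex) else TranscriptomeIndex(transcripts, k=k)
    alignments: list[AlignmentRecord] = []
    counts = {"unaligned": 0, "multimapped": 0}
    for read in reads:
        hits = index.matches(read.sequence)
        if len(hits) == 1:
            tid, pos = hits[0]
            alignments.append(AlignmentRecord(read.id, tid, pos, len(read.sequence)))
        elif not hits:
            counts["unaligned"] += 1
        else:
            counts["multimapped"] += 1
    return alignments, counts


def length_filter(
    alignments: Iterable[AlignmentRecord],
    min_len: int = 26,
    max_len: int = 35,
) -> tuple[list[AlignmentRecord], int]:
    """Keep alignments whose read length lies in the closed range."""
    if min_len > max_len:
        raise ValueError(f"inverted length range [{min_len}, {max_len}]")
    kept, excluded = [], 0
    for a in alignments:
        if min_len <= a.length <= max_len:
            kept.append(a)
        else:
            excluded += 1
    return kept, excluded


def run_preprocess(
    reads: Sequence[ReadRecord],
    transcripts: Mapping[str, TranscriptRecord],
    contaminants: Mapping[str, str],
    adapter: str,
    min_mean_phred: float = 20.0,
    min_len: int = 26,
    max_len: int = 35,
    min_insert: int = MIN_INSERT,
    per_base_quality: bool = False,
    index: TranscriptomeIndex | None = None,
) -> tuple[list[AlignmentRecord], FilterLedger]:
    """Run the full preprocessing chain, one ledger category per read.

    Order of operations: adapter trimming -> quality filter -> contaminant
    depletion -> exact-match alignment -> length filter. Output alignment
    order is input read order.
    """
    if min_len > max_len:
        raise ValueError(f"inverted length range [{min_len}, {max_len}]")
    ledger = FilterLedger(input=len(reads))

    trimmed: list[ReadRecord] = []
    for read in reads:
        t, code = trim_adapter(read, adapter, min_insert=min_insert)
        if t is None:
            ledger.adapter_discarded += 1
        else:
            trimmed.append(t)

    passed = []
    for read in trimmed:
        if quality_filter(read, min_mean_phred, per_base=per_base_quality):
            passed.append(read)
        else:
            ledger.quality_discarded += 1

    survivors, removed = deplete_contaminants(passed, contaminants)
    ledger.contaminant = removed

    if index is None:
        index = TranscriptomeIndex(transcripts)
    aligned, counts = align_to_transcriptome(survivors, index)
    ledger.unaligned = counts["unaligned"]
    ledger.multimapped = counts["multimapped"]

    kept, excluded = length_filter(aligned, min_len, max_len)
    ledger.length_excluded = excluded
    ledger.kept = len(kept)
    ledger.check()
    return kept, ledger
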