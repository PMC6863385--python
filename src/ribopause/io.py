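"""Shared record types and file I/O for the ribosome-profiling pipeline.

Everything downstream works in transcript coordinates: 0-based, half-open,
with the coding interval given as ``[cds_start, cds_end)`` in nucleotides and
codon *i* occupying nucleotides ``[cds_start + 3i, cds_start + 3i + 3)``.

Standard formats go through the standard libraries: FASTA/FASTQ via Biopython,
SAM via pysam, tab-separated tables via pandas.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam
from Bio import SeqIO

#: transcript-ID prefix marking spike-in (foreign-species) transcripts
SPIKE_PREFIX = "spike|"

#: Sanger/Illumina 1.8+ Phred offset used for all FASTQ quality strings
PHRED_OFFSET = 33


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript sequence with its coding interval and species tag.

    Parameters
    ----------
    id : str
        Unique transcript identifier. Spike-in transcripts carry the
        ``"spike|"`` prefix so species assignment needs no taxonomy machinery.
    sequence : str
        Nucleotide sequence (ACGT), 5'->3'.
    cds_start, cds_end : int
        Coding interval ``[cds_start, cds_end)`` in 0-based nt coordinates.
        The interval includes the stop codon.
    species : str
        ``"primary"`` or ``"spike"``; derived data are split on this tag.
    """

    id: str
    sequence: str
    cds_start: int
    cds_end: int
    species: str = "primary"

    def __post_init__(self) -> None:
        if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
            raise ValueError(
                f"{self.id}: CDS [{self.cds_start}, {self.cds_end}) outside "
                f"transcript of length {len(self.sequence)}"
            )
        if (self.cds_end - self.cds_start) % 3:
            raise ValueError(f"{self.id}: CDS length not a multiple of 3")

    @property
    def n_codons(self) -> int:
        """Number of CDS codons (stop codon included)."""
        return (self.cds_end - self.cds_start) // 3

    @property
    def cds(self) -> str:
        return self.sequence[self.cds_start:self.cds_end]

    def codon(self, i: int) -> str:
        start = self.cds_start + 3 * i
        return self.sequence[start:start + 3]


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: identifier, bases and per-base Phred string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")

    def mean_phred(self) -> float:
        if not self.quality:
            return 0.0
        q = self.quality.encode("ascii")
        return sum(q) / len(q) - PHRED_OFFSET

    def min_phred(self) -> int:
        if not self.quality:
            return 0
        return min(self.quality.encode("ascii")) - PHRED_OFFSET


@dataclass(frozen=True)
class AlignmentRecord:
    """A footprint placed on a transcript: 5' end position and length."""

    read_id: str
    transcript_id: str
    five_prime_pos: int
    length: int

    def __post_init__(self) -> None:
        if self.five_prime_pos < 0 or self.length <= 0:
            raise ValueError(f"{self.read_id}: invalid placement")


# ---------------------------------------------------------------------------
# FASTA / annotation
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict.

    Duplicate identifiers are a hard error: downstream alignment and
    bookkeeping key everything by transcript ID.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence ID in {path}: {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


ANNOTATION_COLUMNS = ["transcript_id", "cds_start", "cds_end", "species"]


def write_annotation(transcripts: Mapping[str, TranscriptRecord], path: str | Path) -> None:
    """Write the CDS annotation as a 4-column TSV."""
    df = pd.DataFrame(
        [(t.id, t.cds_start, t.cds_end, t.species) for t in transcripts.values()],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_transcriptome(
    fasta_path: str | Path, annotation_path: str | Path
) -> dict[str, TranscriptRecord]:
    """Combine a transcript FASTA with its CDS annotation TSV."""
    seqs = read_fasta(fasta_path)
    ann = pd.read_csv(annotation_path, sep="\t")
    missing = set(ann["transcript_id"]) - set(seqs)
    if missing:
        raise ValueError(f"annotation refers to transcripts absent from FASTA: {sorted(missing)[:5]}")
    out: dict[str, TranscriptRecord] = {}
    for row in ann.itertuples(index=False):
        out[row.transcript_id] = TranscriptRecord(
            id=row.transcript_id,
            sequence=seqs[row.transcript_id],
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            species=str(getattr(row, "species", "primary")),
        )
    return out


def write_transcriptome(
    transcripts: Mapping[str, TranscriptRecord],
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    write_fasta({t.id: t.sequence for t in transcripts.values()}, fasta_path)
    write_annotation(transcripts, annotation_path)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[ReadRecord]:
    """Read a Phred+33 FASTQ file into ReadRecords (order preserved)."""
    reads: list[ReadRecord] = []
    with open(path) as fh:
        for title, seq, qual in SeqIO.QualityIO.FastqGeneralIterator(fh):
            reads.append(ReadRecord(title.split()[0], seq.upper(), qual))
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# ---------------------------------------------------------------------------
# SAM import / export
# ---------------------------------------------------------------------------

def write_sam(
    alignments: Iterable[AlignmentRecord],
    transcripts: Mapping[str, TranscriptRecord],
    path: str | Path,
) -> None:
    """Write alignments as a headered, text-mode SAM file.

    Footprints are single-end, forward-strand, gapless matches, so the CIGAR
    is always ``<len>M``; sequence and quality are omitted (``*``).
    """
    header = pysam.AlignmentHeader.from_references(
        [t.id for t in transcripts.values()],
        [len(t.sequence) for t in transcripts.values()],
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.reference_name = a.transcript_id
            seg.reference_start = a.five_prime_pos
            seg.cigarstring = f"{a.length}M"
            seg.mapping_quality = 255
            seg.flag = 0
            fh.write(seg)


def read_sam(path: str | Path) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Import alignments from SAM for interoperability with external aligners.

    Only primary, mapped, forward-strand, gapless (pure-match CIGAR) records
    are accepted; everything else is counted and dropped. Returns the
    alignments in file order plus a ``{reason: count}`` dict of drops.
    """
    kept: list[AlignmentRecord] = []
    dropped = {"unmapped": 0, "secondary_or_supplementary": 0, "reverse_strand": 0, "gapped_or_clipped": 0}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                dropped["unmapped"] += 1
            elif seg.is_secondary or seg.is_supplementary:
                dropped["secondary_or_supplementary"] += 1
            elif seg.is_reverse:
                dropped["reverse_strand"] += 1
            elif len(seg.cigartuples or []) != 1 or seg.cigartuples[0][0] not in (0, 7):
                dropped["gapped_or_clipped"] += 1
            else:
                kept.append(
                    AlignmentRecord(
                        read_id=seg.query_name,
                        transcript_id=seg.reference_name,
                        five_prime_pos=seg.reference_start,
                        length=seg.cigartuples[0][1],
                    )
                )
    return kept, dropped


# ---------------------------------------------------------------------------
# bundled synthetic contaminant set
# ---------------------------------------------------------------------------

def default_contaminants() -> dict[str, str]:
    """Load the bundled *synthetic* rRNA-like contaminant FASTA.

    These sequences are generated, GC-biased random nucleotide strings that
    stand in for an rRNA depletion reference; they share no provenance with
    any real rRNA sequence.
    """
    path = Path(__file__).parent / "data" / "synthetic_rrna.fa"
    return read_fasta(path)


def load_contaminants(path: str | Path | None = None) -> dict[str, str]:
    if path is None:
        return default_contaminants()
    seqs = read_fasta(path)
    if not seqs:
        warnings.warn(f"contaminant FASTA {path} is empty; depletion is a no-op")
    return seqs
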