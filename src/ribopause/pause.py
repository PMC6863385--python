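"""Tripeptide-motif pause analysis: occurrence scanning, motif metagenes,
scalar pause scores and between-condition comparison.

Polyproline (PPP) and related motifs (SPP, PPV; the SPPPVP context combines
all three) stall elongating ribosomes when hypusinated eIF5A is limiting.
The pause score of one motif occurrence is the mean P-site count over its
codons divided by a flanking-background mean; 1.0 means no pausing. Scores
are ratios, so they are invariant to sequencing depth and library scaling.
Conditions are compared by the ratio of aggregate (median) scores with a
seeded percentile-bootstrap confidence interval over occurrences.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import TranscriptRecord
from .metagene import DEFAULT_TRIM_FRAC, MetageneProfile, metagene_profile
from .psite import CodonCoverage

#: flanking codons required on each side for an occurrence to be reported
DEFAULT_FLANK_REQUIREMENT = 5
#: background flank: codons at distance 5..50 on each side of the motif
DEFAULT_FLANK_RANGE = (5, 50)
#: minimum background mean (reads/codon) for an occurrence to be usable
DEFAULT_BACKGROUND_FLOOR = 0.5
#: motif metagene window in codons around the first motif codon
DEFAULT_MOTIF_WINDOW = (-5, 7)
#: CDS edge codons excluded from backgrounds (initiation/termination ramps)
_EDGE_EXCLUDE = 5


@dataclass(frozen=True)
class MotifOccurrence:
    """One tripeptide occurrence inside a CDS, with its local context."""

    transcript_id: str
    tripeptide: str
    codon_index: int  # codon of the first residue
    context: str  # +/- 5 codons as amino acids

    @property
    def n_codons(self) -> int:
        return len(self.tripeptide)


def translate_cds(record: TranscriptRecord) -> str:
    """In-frame translation of the CDS, including a trailing '*' if present."""
    return str(Seq(record.cds).translate())


def scan_motifs(
    transcripts: Mapping[str, TranscriptRecord],
    tripeptide: str,
    flank: int = DEFAULT_FLANK_REQUIREMENT,
    species: str | None = "primary",
) -> list[MotifOccurrence]:
    """Find every in-frame occurrence of a tripeptide motif.

    Overlapping occurrences (PPPP contains two PPPs) are all reported.
    Occurrences need ``flank`` codons of CDS on each side; transcripts with
    an internal stop codon are skipped with a warning.
    """
    occurrences: list[MotifOccurrence] = []
    for tid, rec in transcripts.items():
        if species is not None and rec.species != species:
            continue
        aa = translate_cds(rec)
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            warnings.warn(f"{tid}: internal stop codon; transcript skipped")
            continue
        i = aa.find(tripeptide)
        while i != -1:
            if i >= flank and i + len(tripeptide) + flank <= len(aa):
                occurrences.append(
                    MotifOccurrence(
                        tid, tripeptide, i, aa[i - 5:i + len(tripeptide) + 5]
                    )
                )
            i = aa.find(tripeptide, i + 1)
    return occurrences


@dataclass(frozen=True)
class PauseScore:
    occurrence: MotifOccurrence
    score: float  # NaN when unusable
    background: float
    usable: bool


@dataclass
class PauseScoreTable:
    """Per-occurrence pause scores plus the aggregate for one library."""

    scores: list[PauseScore]
    aggregate: str = "median"

    def usable_scores(self) -> np.ndarray:
        return np.array([s.score for s in self.scores if s.usable])

    @property
    def n_usable(self) -> int:
        return sum(1 for s in self.scores if s.usable)

    def aggregate_score(self) -> float:
        v = self.usable_scores()
        if v.size == 0:
            return float("nan")
        return float(np.median(v) if self.aggregate == "median" else v.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    s.occurrence.transcript_id,
                    s.occurrence.tripeptide,
                    s.occurrence.codon_index,
                    s.score,
                    s.background,
                    s.usable,
                )
                for s in self.scores
            ],
            columns=["transcript_id", "tripeptide", "codon_index", "score", "background", "usable"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _background_codons(
    occurrence: MotifOccurrence,
    n_codons: int,
    flank_range: tuple[int, int],
    blocked: frozenset[int],
) -> np.ndarray:
    """Flank codon indices at distance flank_range from the occurrence,
    clipped to the CDS interior and excluding other occurrences' codons."""
    near, far = flank_range
    i, m = occurrence.codon_index, occurrence.n_codons
    left = np.arange(i - far, i - near + 1)
    right = np.arange(i + m - 1 + near, i + m - 1 + far + 1)
    idx = np.concatenate([left, right])
    idx = idx[(idx >= _EDGE_EXCLUDE) & (idx < n_codons - _EDGE_EXCLUDE)]
    if blocked:
        idx = np.array([j for j in idx if j not in blocked], dtype=int)
    return idx


def pause_score(
    coverage: CodonCoverage,
    occurrence: MotifOccurrence,
    flank_range: tuple[int, int] = DEFAULT_FLANK_RANGE,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
    other_occurrences: Iterable[MotifOccurrence] = (),
) -> PauseScore:
    """Score one occurrence: motif-codon mean over flanking-background mean.

    The background excludes codons belonging to other occurrences and the
    first/last 5 CDS codons. Occurrences whose background is empty or below
    ``background_floor`` are flagged unusable (score NaN, never a division
    by zero).
    """
    rec = coverage.annotation[occurrence.transcript_id]
    counts = coverage.cds_counts(occurrence.transcript_id)
    i, m = occurrence.codon_index, occurrence.n_codons
    blocked = frozenset(
        j
        for o in other_occurrences
        if o.transcript_id == occurrence.transcript_id and o.codon_index != i
        for j in range(o.codon_index, o.codon_index + o.n_codons)
    )
    bg_idx = _background_codons(occurrence, rec.n_codons, flank_range, blocked)
    if bg_idx.size == 0:
        return PauseScore(occurrence, float("nan"), 0.0, False)
    background = float(counts[bg_idx].mean())
    if background < background_floor or background == 0.0:
        return PauseScore(occurrence, float("nan"), background, False)
    motif_mean = float(counts[i:i + m].mean())
    return PauseScore(occurrence, motif_mean / background, background, True)


def pause_score_table(
    coverage: CodonCoverage,
    occurrences: Sequence[MotifOccurrence],
    flank_range: tuple[int, int] = DEFAULT_FLANK_RANGE,
    background_floor: float = DEFAULT_BACKGROUND_FLOOR,
    aggregate: str = "median",
) -> PauseScoreTable:
    """Score every occurrence of a library (shared exclusion bookkeeping)."""
    scores = [
        pause_score(coverage, occ, flank_range, background_floor, other_occurrences=occurrences)
        for occ in occurrences
    ]
    return PauseScoreTable(scores, aggregate=aggregate)


def motif_metagene(
    coverage: CodonCoverage,
    occurrences: Sequence[MotifOccurrence],
    window: tuple[int, int] = DEFAULT_MOTIF_WINDOW,
    trim_frac: float = DEFAULT_TRIM_FRAC,
) -> MetageneProfile:
    """Per-offset occupancy profile around motif occurrences.

    Delegates to the metagene machinery with one row per occurrence,
    anchored at the first motif codon and normalized by each occurrence's
    flank mean (window positions outside the motif codons).
    """
    if not occurrences:
        a, b = window
        width = b - a + 1
        return MetageneProfile(
            "motif", window, np.arange(a, b + 1), np.full(width, np.nan),
            np.zeros(width, dtype=int), 0, 0, 0, flagged_empty=True,
        )
    m = occurrences[0].n_codons
    return metagene_profile(
        coverage,
        landmark="motif",
        window=window,
        trim_frac=trim_frac,
        normalize="flank_mean",
        norm_exclude=(0, m - 1),
        anchors=[(o.transcript_id, o.codon_index) for o in occurrences],
    )


@dataclass(frozen=True)
class ConditionComparison:
    """Ratio of aggregate pause scores between two libraries, with a seeded
    percentile-bootstrap confidence interval over occurrences."""

    ratio: float  # aggregate(B) / aggregate(A)
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    n_boot: int
    seed: int
    ci_level: float = 0.95

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high

    def to_dict(self) -> dict:
        return {
            "ratio": self.ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_level": self.ci_level,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_boot": self.n_boot,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare_conditions(
    table_a: PauseScoreTable,
    table_b: PauseScoreTable,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
    min_usable: int = 10,
) -> ConditionComparison:
    """Compare pause scores of condition B against condition A.

    The statistic is ``median(B scores) / median(A scores)``; both score sets
    are resampled with replacement ``n_boot`` times and the CI is the
    percentile interval of the bootstrap ratios. Deterministic given
    ``seed``. Refuses to compare when either table has fewer than
    ``min_usable`` usable occurrences.
    """
    a = table_a.usable_scores()
    b = table_b.usable_scores()
    if a.size < min_usable or b.size < min_usable:
        raise ValueError(
            f"too few usable occurrences to compare (A={a.size}, B={b.size}, "
            f"need >= {min_usable})"
        )
    ratio = float(np.median(b) / np.median(a))
    rng = np.random.default_rng(seed)
    med_a = np.median(a[rng.integers(0, a.size, size=(n_boot, a.size))], axis=1)
    med_b = np.median(b[rng.integers(0, b.size, size=(n_boot, b.size))], axis=1)
    boots = med_b / med_a
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return ConditionComparison(
        ratio, float(lo), float(hi), int(a.size), int(b.size), n_boot, seed, ci_level
    )
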