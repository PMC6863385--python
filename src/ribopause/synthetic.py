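"""Synthetic ribosome-profiling data with a known ground truth.

This module generates transcriptomes and footprint libraries in which every
quantity the analysis pipeline later estimates is planted by construction:
read-length-specific 5'-end-to-P-site offsets, start-codon enrichment,
multiplicative pausing at tripeptide motifs (PPP and friends), adapter-tagged
reads, low-quality reads, rRNA-like contaminants, and spike-in reads from a
second species. A :class:`TruthTable` records the planted values so that
calibration, metagene and pause-score code can be tested as parameter-recovery
experiments.

The library model: each footprint's P-site codon is drawn from a categorical
distribution over CDS codons with weight ``lambda`` per codon, multiplied by
``start_enrichment`` at the start codon and by ``pause_multiplier`` at planted
motif codons. The read's 5' end is then placed ``offset_map[L]`` nt upstream
of the P-site codon for a read length ``L`` drawn from ``length_weights``.
Optionally, a read whose P-site falls in a motif codon is discarded with
probability ``nogo_drop`` before output — the footprint-level consequence of
no-go decay of mRNAs carrying severely stalled ribosomes.

Reads are error-free by default so that exact-match alignment is complete, and
the adapter is always appended in full. The generator additionally guarantees
that the adapter's seed heptamer never occurs inside any simulated transcript
or contaminant, which makes adapter trimming exact and keeps the kept-read /
truth-footprint correspondence a bijection.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .io import (
    SPIKE_PREFIX,
    AlignmentRecord,
    ReadRecord,
    TranscriptRecord,
    default_contaminants,
)

# --- genetic code -----------------------------------------------------------

_CODE = unambiguous_dna_by_id[1]
STOP_CODONS: tuple[str, ...] = tuple(sorted(_CODE.stop_codons))
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_CODE.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] += (_codon,)
AMINO_ACIDS: tuple[str, ...] = tuple(sorted(CODONS_BY_AA))

# --- library-design defaults ------------------------------------------------

#: 3' sequencing adapter appended to every simulated read
DEFAULT_ADAPTER = "ATCTCGTATGCCGTCTTCTGCTTG"

#: planted 5'-end -> P-site offsets per read length (nt); monotone around the
#: canonical ~12 nt for 28-mers
DEFAULT_OFFSET_MAP: dict[int, int] = {
    26: 11, 27: 11, 28: 12, 29: 13, 30: 13,
    31: 13, 32: 14, 33: 14, 34: 15, 35: 15,
}

#: read-length distribution over 26-35 nt, mass concentrated on the
#: gel-selected 27-30 nt range
DEFAULT_LENGTH_WEIGHTS: dict[int, float] = {
    26: 0.05, 27: 0.20, 28: 0.30, 29: 0.25, 30: 0.12,
    31: 0.04, 32: 0.02, 33: 0.01, 34: 0.005, 35: 0.005,
}

#: minimum codon gap between planted motif occurrence starts
_MIN_MOTIF_GAP = 10
#: flanking codons required on each side of a planted occurrence
_MOTIF_FLANK = 5

_BASES = np.array(list("ACGT"))
READ_CLASSES = ("footprint", "lowq", "spikein", "contaminant")


@dataclass
class SimSpec:
    """Parameters of a simulated footprint library.

    ``base_density`` sets the relative sampling weight per codon; with
    ``depth`` fixed, only its ratios to ``start_enrichment`` and
    ``pause_multiplier`` matter.
    """

    n_transcripts: int = 200
    n_spike_transcripts: int = 20
    utr5_len: tuple[int, int] = (60, 120)
    cds_codons: tuple[int, int] = (120, 300)
    utr3_len: tuple[int, int] = (60, 120)
    planted_motifs: list[tuple[str, int]] = field(default_factory=lambda: [("PPP", 1)])
    base_density: float = 1.0
    start_enrichment: float = 5.0
    pause_multiplier: float = 1.0
    offset_map: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_OFFSET_MAP))
    length_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS))
    depth: int = 100_000
    adapter: str = DEFAULT_ADAPTER
    frac_lowq: float = 0.02
    frac_contaminant: float = 0.05
    frac_spikein: float = 0.15
    nogo_drop: float = 0.0
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_transcripts < 1 or self.depth < 1:
            raise ValueError("n_transcripts and depth must be positive")
        if min(self.base_density, self.start_enrichment, self.pause_multiplier) <= 0:
            raise ValueError("base_density, start_enrichment, pause_multiplier must be > 0")
        for name in ("frac_lowq", "frac_contaminant", "frac_spikein", "nogo_drop", "read_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_lowq + self.frac_contaminant + self.frac_spikein > 1.0 + 1e-12:
            raise ValueError("class fractions sum to more than 1")
        total = sum(self.length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"length_weights sum to {total}, expected 1")
        support = {L for L, w in self.length_weights.items() if w > 0}
        if set(self.offset_map) != support:
            raise ValueError("offset_map keys must be exactly the support of length_weights")
        for L, o in self.offset_map.items():
            if not 0 <= o <= L:
                raise ValueError(f"offset {o} for length {L} outside [0, {L}]")
        for lo, hi in (self.utr5_len, self.cds_codons, self.utr3_len):
            if lo > hi or lo < 0:
                raise ValueError("length ranges must be (min, max) with min <= max >= 0")
        for motif, count in self.planted_motifs:
            if count < 0 or not motif or any(a not in CODONS_BY_AA for a in motif):
                raise ValueError(f"bad planted motif {(motif, count)}")
        # every transcript must be able to hold all requested occurrences
        need = 2 * _MOTIF_FLANK + sum(
            c * (len(m) + _MIN_MOTIF_GAP) for m, c in self.planted_motifs
        )
        if self.cds_codons[0] < need:
            raise ValueError(
                f"cds_codons min {self.cds_codons[0]} too short for planted motifs (need >= {need})"
            )
        if not self.adapter:
            raise ValueError("adapter must be non-empty")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["planted_motifs"] = [list(x) for x in self.planted_motifs]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimSpec":
        kw = dict(d)
        if "planted_motifs" in kw:
            kw["planted_motifs"] = [tuple(x) for x in kw["planted_motifs"]]
        for key in ("utr5_len", "cds_codons", "utr3_len"):
            if key in kw:
                kw[key] = tuple(kw[key])
        for key in ("offset_map", "length_weights"):
            if key in kw:
                kw[key] = {int(k): v for k, v in kw[key].items()}
        return cls(**kw)


@dataclass
class TruthTable:
    """Ground truth of a simulated transcriptome and (optionally) library.

    ``occurrences`` maps transcript ID to the planted ``(tripeptide,
    codon_index)`` list; ``reads`` (once a library has been simulated) holds
    one row per emitted read: read_id, cls, transcript, psite_codon, length,
    five_prime. ``psite_codon`` and ``five_prime`` are -1 / the contaminant
    start for non-footprint classes.
    """

    occurrences: dict[str, list[tuple[str, int]]]
    offset_map: dict[int, int]
    start_enrichment: float
    pause_multiplier: float
    base_density: float
    nogo_drop: float = 0.0
    reads: pd.DataFrame | None = None
    class_counts: dict[str, int] = field(default_factory=dict)
    resampled: int = 0
    nogo_dropped: int = 0

    def occurrence_frame(self) -> pd.DataFrame:
        rows = [
            (tid, motif, idx)
            for tid, occs in self.occurrences.items()
            for motif, idx in occs
        ]
        return pd.DataFrame(rows, columns=["transcript_id", "tripeptide", "codon_index"])

    def footprint_reads(self) -> pd.DataFrame:
        """Rows of classes that survive preprocessing (footprint + spikein)."""
        if self.reads is None:
            raise ValueError("no library simulated yet")
        return self.reads[self.reads["cls"].isin(("footprint", "spikein"))]

    def psite_codon_histogram(self, transcript_id: str, n_codons: int) -> np.ndarray:
        """True per-codon P-site counts for footprint/spikein reads."""
        sub = self.footprint_reads()
        sub = sub[sub["transcript"] == transcript_id]
        return np.bincount(sub["psite_codon"].to_numpy(), minlength=n_codons)


# ---------------------------------------------------------------------------
# transcriptome generation
# ---------------------------------------------------------------------------

def _random_utr(n: int, rng: np.random.Generator) -> list[str]:
    return list(_BASES[rng.integers(0, 4, size=n)])


def _scan_peptide(aa: str, motif: str) -> list[int]:
    """All (overlapping) occurrence start indices of ``motif`` in ``aa``."""
    out, i = [], aa.find(motif)
    while i != -1:
        out.append(i)
        i = aa.find(motif, i + 1)
    return out


def _place_motifs(
    n_sense: int, planted: Sequence[tuple[str, int]], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Choose non-interacting occurrence start codons inside the CDS."""
    chosen: list[tuple[str, int]] = []
    taken: list[tuple[int, int]] = []  # (start, end) codon spans incl. gap
    for motif, count in planted:
        lo, hi = _MOTIF_FLANK, n_sense - len(motif) - _MOTIF_FLANK
        if hi < lo:
            raise ValueError("CDS too short for motif and flank requirements")
        for _ in range(count):
            for _attempt in range(200):
                s = int(rng.integers(lo, hi + 1))
                if all(
                    s + len(motif) + _MIN_MOTIF_GAP <= a or b + _MIN_MOTIF_GAP <= s
                    for a, b in taken
                ):
                    taken.append((s, s + len(motif)))
                    chosen.append((motif, s))
                    break
            else:
                raise ValueError("could not place all motif occurrences; CDS too crowded")
    return sorted(chosen, key=lambda x: x[1])


def _repair_spurious(
    aa: list[str],
    occs: list[tuple[str, int]],
    motifs: Sequence[str],
    fixed: set[int],
    rng: np.random.Generator,
) -> None:
    """Mutate background residues until each motif occurs only where planted."""
    safe = [a for a in AMINO_ACIDS if a not in set("".join(motifs))]
    planted = {(m, s) for m, s in occs}
    for _ in range(100):
        dirty = False
        s_aa = "".join(aa)
        for motif in motifs:
            for s in _scan_peptide(s_aa, motif):
                if (motif, s) in planted:
                    continue
                free = [i for i in range(s, s + len(motif)) if i not in fixed]
                if not free:  # cannot happen with the placement gap
                    raise RuntimeError("spurious motif occurrence inside fixed residues")
                aa[free[len(free) // 2]] = safe[int(rng.integers(len(safe)))]
                dirty = True
        if not dirty:
            return
    raise RuntimeError("motif repair did not converge")


def _codons_for(aa: Sequence[str], rng: np.random.Generator) -> list[str]:
    out = []
    for a in aa:
        options = CODONS_BY_AA[a]
        out.append(options[int(rng.integers(len(options)))])
    return out


def _purge_seed(
    utr5: list[str],
    codons: list[str],
    aa: Sequence[str],
    utr3: list[str],
    seed7: str,
    rng: np.random.Generator,
) -> str:
    """Remove every occurrence of the adapter seed heptamer from the
    assembled transcript, preserving the encoded peptide (synonymous codon
    resampling inside the CDS, free base substitution in the UTRs)."""
    n5 = len(utr5)
    for _ in range(200):
        cds = "".join(codons)
        seq = "".join(utr5) + cds + "".join(utr3)
        hits = _scan_peptide(seq, seed7)  # generic overlapping substring scan
        if not hits:
            return seq
        s = hits[0]
        span = range(s, s + len(seed7))
        utr_pos = [p for p in span if p < n5 or p >= n5 + len(cds)]
        if utr_pos:
            p = utr_pos[len(utr_pos) // 2]
            old = seq[p]
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            if p < n5:
                utr5[p] = new
            else:
                utr3[p - n5 - len(cds)] = new
        else:
            c_lo = (s - n5) // 3
            c_hi = (s + len(seed7) - 1 - n5) // 3
            for ci in range(c_lo, c_hi + 1):
                options = CODONS_BY_AA.get(aa[ci], (codons[ci],))
                codons[ci] = options[int(rng.integers(len(options)))]
    raise RuntimeError("adapter-seed purge did not converge")


def _make_transcript(
    tid: str,
    species: str,
    spec: SimSpec,
    planted: Sequence[tuple[str, int]],
    rng: np.random.Generator,
) -> tuple[TranscriptRecord, list[tuple[str, int]]]:
    n5 = int(rng.integers(spec.utr5_len[0], spec.utr5_len[1] + 1))
    n_sense = int(rng.integers(spec.cds_codons[0], spec.cds_codons[1] + 1))
    n3 = int(rng.integers(spec.utr3_len[0], spec.utr3_len[1] + 1))

    occs = _place_motifs(n_sense, planted, rng) if planted else []
    aa = ["M"] + [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), size=n_sense - 1)]
    fixed = {0}
    for motif, s in occs:
        for j, res in enumerate(motif):
            aa[s + j] = res
            fixed.add(s + j)
    motifs = sorted({m for m, _ in planted})
    if motifs:
        _repair_spurious(aa, occs, motifs, fixed, rng)

    codons = _codons_for(aa, rng)
    codons[0] = "ATG"
    stop = STOP_CODONS[int(rng.integers(len(STOP_CODONS)))]
    codons.append(stop)
    aa_full = list(aa) + ["*"]

    utr5 = _random_utr(n5, rng)
    utr3 = _random_utr(n3, rng)
    seed7 = spec.adapter[:7]
    seq = _purge_seed(utr5, codons, aa_full, utr3, seed7, rng)

    rec = TranscriptRecord(
        id=tid, sequence=seq, cds_start=n5, cds_end=n5 + 3 * len(codons), species=species
    )
    return rec, occs


def generate_transcriptome(spec: SimSpec) -> tuple[dict[str, TranscriptRecord], TruthTable]:
    """Generate primary + spike-in transcripts with planted motif occurrences.

    Returns the transcript dict (primary first, then ``spike|``-prefixed
    spike-in transcripts) and a :class:`TruthTable` holding the planted motif
    positions and simulation parameters. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng([int(spec.seed), 101])
    transcripts: dict[str, TranscriptRecord] = {}
    occurrences: dict[str, list[tuple[str, int]]] = {}
    for i in range(spec.n_transcripts):
        tid = f"t{i:04d}"
        rec, occs = _make_transcript(tid, "primary", spec, spec.planted_motifs, rng)
        transcripts[tid] = rec
        occurrences[tid] = occs
    for i in range(spec.n_spike_transcripts):
        tid = f"{SPIKE_PREFIX}s{i:03d}"
        rec, _ = _make_transcript(tid, "spike", spec, [], rng)
        transcripts[tid] = rec
        occurrences[tid] = []
    truth = TruthTable(
        occurrences=occurrences,
        offset_map=dict(spec.offset_map),
        start_enrichment=spec.start_enrichment,
        pause_multiplier=spec.pause_multiplier,
        base_density=spec.base_density,
        nogo_drop=spec.nogo_drop,
    )
    return transcripts, truth


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

class _CodonSpace:
    """Flattened (transcript, codon) sampling space for one species."""

    def __init__(
        self,
        transcripts: Sequence[TranscriptRecord],
        truth: TruthTable,
        spec: SimSpec,
        pause: bool,
    ) -> None:
        tids, codon_idx, weight, is_motif = [], [], [], []
        self.records = list(transcripts)
        for ti, rec in enumerate(self.records):
            n = rec.n_codons
            w = np.full(n, spec.base_density)
            w[0] *= spec.start_enrichment
            motif_mask = np.zeros(n, bool)
            if pause:
                for motif, s in truth.occurrences.get(rec.id, []):
                    motif_mask[s:s + len(motif)] = True
                w[motif_mask] *= spec.pause_multiplier
            tids.append(np.full(n, ti))
            codon_idx.append(np.arange(n))
            weight.append(w)
            is_motif.append(motif_mask)
        self.tid = np.concatenate(tids)
        self.codon = np.concatenate(codon_idx)
        self.is_motif = np.concatenate(is_motif)
        self.p = np.concatenate(weight)
        self.p /= self.p.sum()
        self.cds_start = np.array([r.cds_start for r in self.records])
        self.tlen = np.array([len(r.sequence) for r in self.records])

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(len(self.p), size=n, p=self.p)


def _draw_placed(
    space: _CodonSpace,
    n: int,
    spec: SimSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """Draw n footprints (transcript index, codon, length, 5' position),
    resampling any placement that would run off the transcript."""
    lengths_arr = np.array(sorted(spec.length_weights))
    lw = np.array([spec.length_weights[L] for L in lengths_arr])
    lw = lw / lw.sum()
    offs = np.array([spec.offset_map.get(int(L), 0) for L in lengths_arr])

    flat = space.draw(n, rng)
    li = rng.choice(len(lengths_arr), size=n, p=lw)
    resampled = 0
    for _ in range(100):
        tid = space.tid[flat]
        five = space.cds_start[tid] + 3 * space.codon[flat] - offs[li]
        bad = (five < 0) | (five + lengths_arr[li] > space.tlen[tid])
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        resampled += n_bad
        flat[bad] = space.draw(n_bad, rng)
        li[bad] = rng.choice(len(lengths_arr), size=n_bad, p=lw)
    else:
        raise RuntimeError("footprint placement kept running off transcripts")
    return flat, lengths_arr[li], five, space.is_motif[flat], resampled


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hit:
        old = arr[i].decode()
        arr[i] = rng.choice([b for b in "ACGT" if b != old]).encode()
    return arr.tobytes().decode()


def simulate_library(
    transcripts: Mapping[str, TranscriptRecord],
    truth: TruthTable,
    spec: SimSpec,
    emit_reads: bool = True,
    contaminants: Mapping[str, str] | None = None,
) -> tuple[list[ReadRecord], TruthTable]:
    """Simulate one footprint library over a generated transcriptome.

    Returns the FASTQ-ready reads (adapter appended, Phred 40 except the
    low-quality class at Phred 10) and a new :class:`TruthTable` whose
    ``reads`` frame is the per-read truth in emission order. With
    ``emit_reads=False`` no sequences are synthesised (``reads`` list is
    empty) but the truth table is identical — the fast entry point for
    analysis-layer experiments via :func:`true_alignments`.

    Pause multiplier, no-go drop and seed are taken from ``spec``, so several
    conditions can be simulated over one shared transcriptome by passing the
    same ``(transcripts, truth)`` with different specs.
    """
    rng = np.random.default_rng([int(spec.seed), 211])
    if contaminants is None:
        contaminants = default_contaminants()

    primary = [t for t in transcripts.values() if t.species == "primary"]
    spike = [t for t in transcripts.values() if t.species == "spike"]
    if spec.frac_spikein > 0 and not spike:
        raise ValueError("frac_spikein > 0 but transcriptome has no spike-in transcripts")

    fracs = [spec.frac_contaminant, spec.frac_spikein, spec.frac_lowq]
    n_cont, n_spike, n_lowq, n_fp = rng.multinomial(
        spec.depth, fracs + [1.0 - sum(fracs)]
    )

    p_space = _CodonSpace(primary, truth, spec, pause=True)
    cols: dict[str, list[np.ndarray]] = {k: [] for k in ("cls", "ti", "codon", "length", "five")}
    spaces: list[_CodonSpace | None] = []
    resampled = 0
    nogo_dropped = 0

    def _add(cls: str, space: _CodonSpace, n: int, nogo: bool) -> None:
        nonlocal resampled, nogo_dropped
        if n == 0:
            return
        flat, lens, five, motif, res = _draw_placed(space, n, spec, rng)
        resampled += res
        keep = np.ones(n, bool)
        if nogo and spec.nogo_drop > 0:
            drop = motif & (rng.random(n) < spec.nogo_drop)
            nogo_dropped += int(drop.sum())
            keep = ~drop
        cols["cls"].append(np.full(int(keep.sum()), cls, dtype=object))
        cols["ti"].append(space.tid[flat[keep]])
        cols["codon"].append(space.codon[flat[keep]])
        cols["length"].append(lens[keep])
        cols["five"].append(five[keep])
        spaces.append(space)

    _add("footprint", p_space, int(n_fp), nogo=True)
    _add("lowq", p_space, int(n_lowq), nogo=True)
    if n_spike:
        s_space = _CodonSpace(spike, truth, spec, pause=False)
        _add("spikein", s_space, int(n_spike), nogo=False)
    else:
        s_space = None

    # contaminant reads: uniform substrings of the contaminant set
    cont_ids = list(contaminants)
    if n_cont:
        lengths_arr = np.array(sorted(spec.length_weights))
        lw = np.array([spec.length_weights[L] for L in lengths_arr])
        ci = rng.integers(0, len(cont_ids), size=n_cont)
        cl = lengths_arr[rng.choice(len(lengths_arr), size=n_cont, p=lw / lw.sum())]
        starts = np.array(
            [rng.integers(0, len(contaminants[cont_ids[i]]) - L + 1) for i, L in zip(ci, cl)]
        )
        cols["cls"].append(np.full(n_cont, "contaminant", dtype=object))
        cols["ti"].append(ci)
        cols["codon"].append(np.full(n_cont, -1))
        cols["length"].append(cl)
        cols["five"].append(starts)

    cls = np.concatenate(cols["cls"])
    ti = np.concatenate(cols["ti"])
    codon = np.concatenate(cols["codon"])
    length = np.concatenate(cols["length"])
    five = np.concatenate(cols["five"])

    order = rng.permutation(len(cls))
    cls, ti, codon, length, five = cls[order], ti[order], codon[order], length[order], five[order]

    # resolve transcript names per class
    p_names = np.array([r.id for r in p_space.records], dtype=object)
    s_names = np.array([r.id for r in s_space.records], dtype=object) if s_space else None
    names = np.empty(len(cls), dtype=object)
    pm = (cls == "footprint") | (cls == "lowq")
    names[pm] = p_names[ti[pm]]
    sm = cls == "spikein"
    if sm.any():
        names[sm] = s_names[ti[sm]]
    cm = cls == "contaminant"
    if cm.any():
        names[cm] = np.array(cont_ids, dtype=object)[ti[cm]]

    read_ids = np.array([f"r{i:07d}" for i in range(len(cls))], dtype=object)
    reads_df = pd.DataFrame(
        {
            "read_id": read_ids,
            "cls": cls,
            "transcript": names,
            "psite_codon": codon,
            "length": length,
            "five_prime": five,
        }
    )
    counts = {k: int((cls == k).sum()) for k in READ_CLASSES}

    reads: list[ReadRecord] = []
    if emit_reads:
        seq_by_name = {t.id: t.sequence for t in transcripts.values()}
        seq_by_name.update(contaminants)
        adapter = spec.adapter
        hi_q, lo_q = chr(33 + 40), chr(33 + 10)
        err = spec.read_error_rate
        for rid, c, name, L, f in zip(read_ids, cls, names, length, five):
            insert = seq_by_name[name][f:f + L]
            s = insert + adapter
            if err > 0:
                s = _apply_errors(s, err, rng)
            q = (lo_q if c == "lowq" else hi_q) * len(s)
            reads.append(ReadRecord(str(rid), s, q))

    truth2 = dataclasses.replace(
        truth,
        pause_multiplier=spec.pause_multiplier,
        start_enrichment=spec.start_enrichment,
        nogo_drop=spec.nogo_drop,
        reads=reads_df,
        class_counts=counts,
        resampled=resampled,
        nogo_dropped=nogo_dropped,
    )
    return reads, truth2


def true_alignments(truth: TruthTable) -> list[AlignmentRecord]:
    """The alignments an exact aligner recovers from an error-free library:
    one record per footprint/spike-in read at its true 5' position."""
    sub = truth.footprint_reads()
    return [
        AlignmentRecord(rid, tname, int(f), int(L))
        for rid, tname, f, L in zip(
            sub["read_id"], sub["transcript"], sub["five_prime"], sub["length"]
        )
    ]


def simulate_alignments(
    transcripts: Mapping[str, TranscriptRecord],
    truth: TruthTable,
    spec: SimSpec,
) -> tuple[list[AlignmentRecord], TruthTable]:
    """Simulate a library and return its true alignment records directly,
    bypassing read synthesis. Equivalent to running the error-free library
    through trimming/filtering/alignment (see tests for the cross-check)."""
    _, truth2 = simulate_library(transcripts, truth, spec, emit_reads=False)
    return true_alignments(truth2), truth2
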