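"""End-to-end orchestration: simulate -> preprocess -> calibrate -> metagene
-> pause, with optional spike-in normalization and a machine-readable report.

A run is described by a :class:`RunConfig` (YAML-loadable; the library-design
constants — adapter sequence, Phred 20 cut-off, 26-35 nt length range, 0.1%
metagene trim — are defaults and all overridable). Every stochastic step
derives its generator from the single run seed, so identical config + seed
reproduce byte-identical output tables.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from . import io as rio
from .io import SPIKE_PREFIX, AlignmentRecord, TranscriptRecord
from .metagene import (
    DEFAULT_START_WINDOW,
    DEFAULT_STOP_WINDOW,
    DEFAULT_TRIM_FRAC,
    metagene_profile,
)
from .pause import (
    DEFAULT_BACKGROUND_FLOOR,
    DEFAULT_FLANK_RANGE,
    DEFAULT_MOTIF_WINDOW,
    compare_conditions,
    motif_metagene,
    pause_score_table,
    scan_motifs,
)
from .preprocess import FilterLedger, run_preprocess
from .psite import (
    DEFAULT_CALIBRATION_WINDOW,
    DEFAULT_MIN_SUPPORT,
    CodonCoverage,
    calibrate_offsets,
    psite_coverage,
)
from .synthetic import DEFAULT_ADAPTER, SimSpec, generate_transcriptome, simulate_library

__version__ = "0.1.0"

logger = logging.getLogger("ribopause")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("[%(name)s] %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class LibraryConfig:
    """One footprint library: either a FASTQ/SAM path or simulation overrides."""

    name: str
    reads: str | None = None  # FASTQ path (mutually exclusive with sam)
    sam: str | None = None  # pre-aligned SAM path
    pause_multiplier: float | None = None
    nogo_drop: float | None = None
    depth: int | None = None


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "ribopause_run"
    seed: int = 0
    # inputs: simulate (default) or load from paths
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimSpec overrides
    transcriptome: str | None = None
    annotation: str | None = None
    contaminants: str | None = None  # None -> bundled synthetic set
    libraries: list[LibraryConfig] = field(default_factory=lambda: [LibraryConfig("A")])
    # preprocessing
    adapter: str = DEFAULT_ADAPTER
    min_mean_phred: float = 20.0
    min_len: int = 26
    max_len: int = 35
    # calibration
    calibration_window: tuple[int, int] = DEFAULT_CALIBRATION_WINDOW
    min_support: int = DEFAULT_MIN_SUPPORT
    # metagenes
    start_window: tuple[int, int] = DEFAULT_START_WINDOW
    stop_window: tuple[int, int] = DEFAULT_STOP_WINDOW
    trim_frac: float = DEFAULT_TRIM_FRAC
    # pause analysis
    motifs: list[str] = field(default_factory=lambda: ["PPP"])
    motif_window: tuple[int, int] = DEFAULT_MOTIF_WINDOW
    flank_range: tuple[int, int] = DEFAULT_FLANK_RANGE
    background_floor: float = DEFAULT_BACKGROUND_FLOOR
    n_boot: int = 1000
    compare: bool = True
    spike_normalize: bool = False

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"inverted length range [{self.min_len}, {self.max_len}]")
        if not 0.0 <= self.trim_frac < 0.5:
            raise ValueError(f"trim_frac {self.trim_frac} outside [0, 0.5)")
        for name in ("calibration_window", "start_window", "stop_window", "motif_window", "flank_range"):
            a, b = getattr(self, name)
            if a > b:
                raise ValueError(f"inverted {name} ({a}, {b})")
        if self.min_support < 1 or self.n_boot < 1:
            raise ValueError("min_support and n_boot must be >= 1")
        if not self.libraries:
            raise ValueError("at least one library required")
        if len({lib.name for lib in self.libraries}) != len(self.libraries):
            raise ValueError("library names must be unique")
        if not self.simulate:
            if self.transcriptome is None or self.annotation is None:
                raise ValueError("non-simulated runs need transcriptome and annotation paths")
            for lib in self.libraries:
                if lib.reads is None and lib.sam is None:
                    raise ValueError(f"library {lib.name}: needs a reads or sam path")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("calibration_window", "start_window", "stop_window", "motif_window", "flank_range"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        kw = dict(d)
        if "libraries" in kw:
            kw["libraries"] = [
                lib if isinstance(lib, LibraryConfig) else LibraryConfig(**lib)
                for lib in kw["libraries"]
            ]
        for key in ("calibration_window", "start_window", "stop_window", "motif_window", "flank_range"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class SpikeinSummary:
    """Per-library primary/spike-in read counts and normalization factors.

    Factors are geometric-mean centered: ``factor_i = spike_i / gmean(spike)``,
    so the factors of a run multiply to 1 and no library is a designated
    reference. Downstream coverage is divided by the factor.
    """

    primary_counts: dict[str, int]
    spike_counts: dict[str, int]
    factors: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "primary_counts": self.primary_counts,
            "spike_counts": self.spike_counts,
            "factors": self.factors,
        }


def spikein_factors(counts: Mapping[str, tuple[int, int]]) -> SpikeinSummary:
    """Compute spike-in normalization factors from per-library species counts.

    ``counts`` maps library name to ``(primary_reads, spike_reads)``. Every
    library must have spike-in reads; otherwise normalization is impossible
    and a hard error is raised.
    """
    if not counts:
        raise ValueError("no libraries given")
    spikes = {name: s for name, (_, s) in counts.items()}
    zero = [name for name, s in spikes.items() if s <= 0]
    if zero:
        raise ValueError(f"zero spike-in reads in libraries {zero}: normalization impossible")
    gmean = float(np.exp(np.mean([np.log(s) for s in spikes.values()])))
    factors = {name: s / gmean for name, s in spikes.items()}
    return SpikeinSummary(
        primary_counts={name: p for name, (p, _) in counts.items()},
        spike_counts=spikes,
        factors=factors,
    )


def species_counts(alignments: list[AlignmentRecord]) -> tuple[int, int]:
    """(primary, spike) read counts, assigned by transcript-ID prefix."""
    spike = sum(1 for a in alignments if a.transcript_id.startswith(SPIKE_PREFIX))
    return len(alignments) - spike, spike


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    config_hash: str
    seed: int
    version: str
    ledgers: dict[str, dict]
    offsets: dict[str, dict]
    spikein: dict | None
    files: dict[str, str]
    comparisons: dict[str, dict]
    timings: dict[str, float]
    error: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages in fixed order and write every intermediate.

    Stage order: simulate (optional) -> preprocess -> spike-in accounting ->
    P-site calibration -> coverage -> metagenes -> pause analysis ->
    comparison -> report. Any stage failure aborts with the stage name after
    writing a partial report.
    """
    t0 = time.time()
    timings: dict[str, float] = {}
    files: dict[str, str] = {}
    report = RunReport(
        config={}, config_hash="", seed=0, version=__version__,
        ledgers={}, offsets={}, spikein=None, files=files, comparisons={}, timings=timings,
    )
    outdir = Path(config.outdir)

    def stage(name):
        def wrap(fn):
            t = time.time()
            try:
                result = fn()
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate with stage name
                report.error = f"{name}: {exc}"
                try:
                    report.write(outdir / "report.json")
                except OSError:
                    pass
                raise PipelineError(name, str(exc)) from exc
            timings[name] = round(time.time() - t, 3)
            logger.info("stage %-11s done in %.2fs", name, timings[name])
            return result

        return wrap

    # -- config ------------------------------------------------------------
    config.validate()  # must fail before any I/O
    outdir.mkdir(parents=True, exist_ok=True)
    report.config = config.to_dict()
    report.config_hash = config.config_hash()
    report.seed = config.seed

    # -- inputs / simulation ------------------------------------------------
    def _inputs():
        contaminants = rio.load_contaminants(config.contaminants)
        reads_by_lib = {}
        if config.simulate:
            base = SimSpec.from_dict({**config.sim, "seed": config.seed, "adapter": config.adapter})
            transcripts, truth0 = generate_transcriptome(base)
            rio.write_transcriptome(transcripts, outdir / "transcriptome.fa", outdir / "annotation.tsv")
            files["transcriptome"] = str(outdir / "transcriptome.fa")
            files["annotation"] = str(outdir / "annotation.tsv")
            truth0.occurrence_frame().to_csv(outdir / "truth_occurrences.tsv", sep="\t", index=False)
            files["truth_occurrences"] = str(outdir / "truth_occurrences.tsv")
            for i, lib in enumerate(config.libraries):
                spec = dataclasses.replace(
                    base,
                    seed=config.seed + 1 + i,
                    pause_multiplier=lib.pause_multiplier if lib.pause_multiplier is not None else base.pause_multiplier,
                    nogo_drop=lib.nogo_drop if lib.nogo_drop is not None else base.nogo_drop,
                    depth=lib.depth if lib.depth is not None else base.depth,
                )
                reads, truth = simulate_library(transcripts, truth0, spec, contaminants=contaminants)
                fq = outdir / f"{lib.name}.fastq"
                rio.write_fastq(reads, fq)
                files[f"reads:{lib.name}"] = str(fq)
                truth.reads.to_csv(outdir / f"truth_reads_{lib.name}.tsv", sep="\t", index=False)
                reads_by_lib[lib.name] = reads
        else:
            transcripts = rio.load_transcriptome(config.transcriptome, config.annotation)
            for lib in config.libraries:
                if lib.reads is not None:
                    reads_by_lib[lib.name] = rio.read_fastq(lib.reads)
        return transcripts, contaminants, reads_by_lib

    transcripts, contaminants, reads_by_lib = stage("simulate" if config.simulate else "load")(_inputs)

    # -- preprocess ----------------------------------------------------------
    def _preprocess():
        alignments_by_lib: dict[str, list[AlignmentRecord]] = {}
        for lib in config.libraries:
            if not config.simulate and lib.sam is not None:
                alns, dropped = rio.read_sam(lib.sam)
                alns, excluded = _length_filter(alns, config.min_len, config.max_len)
                # antisense and gapped records are unusable on the sense
                # transcriptome, so they are pooled with the unaligned count
                ledger = FilterLedger(
                    input=len(alns) + sum(dropped.values()) + excluded,
                    unaligned=dropped["unmapped"] + dropped["reverse_strand"] + dropped["gapped_or_clipped"],
                    multimapped=dropped["secondary_or_supplementary"],
                    length_excluded=excluded,
                    kept=len(alns),
                )
            else:
                alns, ledger = run_preprocess(
                    reads_by_lib[lib.name], transcripts, contaminants,
                    adapter=config.adapter, min_mean_phred=config.min_mean_phred,
                    min_len=config.min_len, max_len=config.max_len,
                )
            ledger.check()
            report.ledgers[lib.name] = ledger.to_dict()
            sam = outdir / f"alignments_{lib.name}.sam"
            rio.write_sam(alns, transcripts, sam)
            files[f"alignments:{lib.name}"] = str(sam)
            alignments_by_lib[lib.name] = alns
        return alignments_by_lib

    alignments_by_lib = stage("preprocess")(_preprocess)

    # -- spike-in accounting -------------------------------------------------
    def _spike():
        counts = {name: species_counts(alns) for name, alns in alignments_by_lib.items()}
        if config.spike_normalize:
            summary = spikein_factors(counts)
        else:
            summary = SpikeinSummary(
                primary_counts={n: p for n, (p, _) in counts.items()},
                spike_counts={n: s for n, (_, s) in counts.items()},
                factors={n: 1.0 for n in counts},
            )
        report.spikein = summary.to_dict()
        return summary

    spike_summary = stage("spikein")(_spike)

    # -- calibration + coverage ----------------------------------------------
    def _psite():
        coverage_by_lib: dict[str, CodonCoverage] = {}
        for lib in config.libraries:
            alns = alignments_by_lib[lib.name]
            table = calibrate_offsets(
                alns, transcripts,
                lengths=range(config.min_len, config.max_len + 1),
                window=config.calibration_window, min_support=config.min_support,
            )
            path = outdir / f"offsets_{lib.name}.tsv"
            table.write_tsv(path)
            files[f"offsets:{lib.name}"] = str(path)
            report.offsets[lib.name] = {
                str(L): (e.offset if e.calibrated else "uncalibrated")
                for L, e in sorted(table.entries.items())
            }
            cov = psite_coverage(alns, table, transcripts)
            factor = spike_summary.factors[lib.name]
            if factor != 1.0:
                cov = cov.scale(factor)
            cov_path = outdir / f"coverage_{lib.name}.tsv"
            cov.to_frame(species="primary").to_csv(cov_path, sep="\t", index=False, float_format="%.6g")
            files[f"coverage:{lib.name}"] = str(cov_path)
            coverage_by_lib[lib.name] = cov
        return coverage_by_lib

    coverage_by_lib = stage("psite")(_psite)

    # -- metagenes ------------------------------------------------------------
    def _metagene():
        for lib in config.libraries:
            cov = coverage_by_lib[lib.name]
            for landmark, window in (("start", config.start_window), ("stop", config.stop_window)):
                prof = metagene_profile(
                    cov, landmark=landmark, window=window, trim_frac=config.trim_frac
                )
                path = outdir / f"metagene_{landmark}_{lib.name}.tsv"
                prof.write_tsv(path)
                files[f"metagene_{landmark}:{lib.name}"] = str(path)

    stage("metagene")(_metagene)

    # -- pause analysis --------------------------------------------------------
    def _pause():
        tables: dict[tuple[str, str], object] = {}
        for motif in config.motifs:
            occurrences = scan_motifs(transcripts, motif)
            for lib in config.libraries:
                cov = coverage_by_lib[lib.name]
                table = pause_score_table(
                    cov, occurrences,
                    flank_range=config.flank_range,
                    background_floor=config.background_floor,
                )
                path = outdir / f"pause_{motif}_{lib.name}.tsv"
                table.write_tsv(path)
                files[f"pause_{motif}:{lib.name}"] = str(path)
                prof = motif_metagene(cov, occurrences, window=config.motif_window,
                                      trim_frac=config.trim_frac)
                mpath = outdir / f"motif_metagene_{motif}_{lib.name}.tsv"
                prof.write_tsv(mpath)
                files[f"motif_metagene_{motif}:{lib.name}"] = str(mpath)
                tables[(motif, lib.name)] = table
            if config.compare and len(config.libraries) >= 2:
                a, b = config.libraries[0].name, config.libraries[1].name
                cmp = compare_conditions(
                    tables[(motif, a)], tables[(motif, b)],
                    n_boot=config.n_boot, seed=config.seed,
                )
                cpath = outdir / f"comparison_{motif}.json"
                cmp.to_json(cpath)
                files[f"comparison_{motif}"] = str(cpath)
                report.comparisons[motif] = cmp.to_dict()

    stage("pause")(_pause)

    timings["total"] = round(time.time() - t0, 3)
    report.write(outdir / "report.json")
    files["report"] = str(outdir / "report.json")
    return report


def _length_filter(alignments, min_len, max_len):
    from .preprocess import length_filter

    return length_filter(alignments, min_len, max_len)
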