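"""Landmark-anchored metagene profiles with outlier-trimmed column means.

A metagene averages codon-level P-site signal across transcripts (or motif
occurrences) after anchoring each at a common landmark. Two rules shape the
averaging:

* transcripts with no reads within the window of interest are excluded
  before any other filter;
* at each window position, the highest and lowest ``trim_frac`` (default
  0.1%) of signals are removed before taking the column mean.

"Signal" is each transcript's window counts normalized by its own window
mean, which makes profiles depth-independent; raw-count averaging is
available behind ``normalize=None``.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import TranscriptRecord
from .psite import CodonCoverage

#: default landmark windows in codons (closed), start- and stop-anchored
DEFAULT_START_WINDOW = (-20, 100)
DEFAULT_STOP_WINDOW = (-100, 20)
#: default per-position outlier trim fraction
DEFAULT_TRIM_FRAC = 0.001


def trimmed_column_mean(values: Sequence[float] | np.ndarray, trim_frac: float = DEFAULT_TRIM_FRAC) -> float:
    """Mean after removing the highest and lowest ``trim_frac`` of values.

    Cut points are nearest-rank empirical quantiles and the comparisons are
    strict, so with ``n < 1/trim_frac`` nothing is dropped and the result is
    the plain mean. ``trim_frac`` must lie in ``[0, 0.5)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("trimmed_column_mean of empty input")
    if not 0.0 <= trim_frac < 0.5:
        raise ValueError(f"trim_frac {trim_frac} outside [0, 0.5)")
    if trim_frac == 0.0:
        return float(v.mean())
    kept = _trim(v, trim_frac)
    return float(kept.mean())


def _nearest_rank(sorted_v: np.ndarray, f: float) -> float:
    """Nearest-rank quantile: the value at rank ceil(f*n) (1-based)."""
    n = sorted_v.size
    rank = min(max(math.ceil(f * n), 1), n)
    return float(sorted_v[rank - 1])


def _trim(v: np.ndarray, trim_frac: float) -> np.ndarray:
    s = np.sort(v)
    lo = _nearest_rank(s, trim_frac)
    hi = _nearest_rank(s, 1.0 - trim_frac)
    return v[(v >= lo) & (v <= hi)]


@dataclass
class MetageneProfile:
    """Per-position trimmed-mean signal around a landmark."""

    landmark: str  # "start" | "stop" | "motif"
    window: tuple[int, int]
    positions: np.ndarray  # codon offsets a..b (closed)
    mean: np.ndarray  # trimmed column means
    n: np.ndarray  # rows contributing per position after trimming
    transcripts_used: int
    transcripts_excluded: int  # zero signal in window
    window_unfit: int  # window does not fit inside the transcript
    flagged_empty: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.positions, "mean": self.mean, "n": self.n})

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def value_at(self, position: int) -> float:
        a = self.window[0]
        return float(self.mean[position - a])

    def plot(self, ax=None):
        """Step plot of the profile (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3))
        ax.step(self.positions, self.mean, where="mid")
        ax.set_xlabel(f"codon offset from {self.landmark}")
        ax.set_ylabel("normalized occupancy")
        return ax


def _profile_from_rows(
    rows: list[np.ndarray],
    landmark: str,
    window: tuple[int, int],
    trim_frac: float,
    excluded: int,
    unfit: int,
) -> MetageneProfile:
    a, b = window
    positions = np.arange(a, b + 1)
    if not rows:
        width = b - a + 1
        return MetageneProfile(
            landmark, window, positions, np.full(width, np.nan),
            np.zeros(width, dtype=int), 0, excluded, unfit, flagged_empty=True,
        )
    mat = np.vstack(rows)
    means = np.empty(mat.shape[1])
    ns = np.empty(mat.shape[1], dtype=int)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        kept = _trim(col, trim_frac) if trim_frac > 0 else col
        means[j] = kept.mean()
        ns[j] = kept.size
    return MetageneProfile(landmark, window, positions, means, ns, mat.shape[0], excluded, unfit)


def metagene_profile(
    coverage: CodonCoverage,
    annotation: Mapping[str, TranscriptRecord] | None = None,
    landmark: str = "start",
    window: tuple[int, int] | None = None,
    trim_frac: float = DEFAULT_TRIM_FRAC,
    normalize: str | None = "window_mean",
    anchors: Iterable[tuple[str, int]] | None = None,
    species: str = "primary",
    norm_exclude: tuple[int, int] | None = None,
) -> MetageneProfile:
    """Build a landmark-anchored metagene profile from codon coverage.

    ``landmark`` is ``"start"`` (anchor codon 0), ``"stop"`` (anchor at the
    stop codon) or ``"motif"`` (anchors supplied explicitly as
    ``(transcript_id, codon_index)`` pairs, one row per occurrence).

    Per row, window counts are normalized by the row's window mean
    (``normalize="window_mean"``), by the mean over window positions outside
    ``norm_exclude`` (``"flank_mean"``, used by motif metagenes via
    :func:`ribopause.pause.motif_metagene`), or left raw (``None``). Rows
    whose window signal is all zero are excluded before any other filter;
    rows whose window does not fit inside the transcript are counted
    separately. Columns are averaged with :func:`trimmed_column_mean`.
    """
    if window is None:
        window = DEFAULT_START_WINDOW if landmark == "start" else DEFAULT_STOP_WINDOW
    a, b = window
    if a > b:
        raise ValueError(f"inverted window {window}")
    ann = coverage.annotation if annotation is None else annotation

    if landmark in ("start", "stop"):
        anchor_list = []
        for tid, rec in ann.items():
            if species is not None and rec.species != species:
                continue
            anchor_list.append((tid, 0 if landmark == "start" else rec.n_codons - 1))
    elif landmark == "motif":
        if anchors is None:
            raise ValueError("landmark='motif' requires anchors")
        anchor_list = list(anchors)
    else:
        raise ValueError(f"unknown landmark {landmark!r}")

    rows: list[np.ndarray] = []
    excluded = unfit = 0
    for tid, c0 in anchor_list:
        win = coverage.window(tid, c0 + a, c0 + b)
        if win is None:
            unfit += 1
            continue
        total = win.sum()
        if total == 0:
            excluded += 1  # excluded before applying any other filter
            continue
        if normalize == "window_mean":
            rows.append(win / win.mean())
        elif normalize == "flank_mean":
            if norm_exclude is None:
                raise ValueError("flank_mean normalization requires norm_exclude")
            positions = np.arange(a, b + 1)
            flank = win[(positions < norm_exclude[0]) | (positions > norm_exclude[1])]
            if flank.size == 0 or flank.mean() == 0:
                excluded += 1
                continue
            rows.append(win / flank.mean())
        elif normalize is None:
            rows.append(win.astype(float))
        else:
            raise ValueError(f"unknown normalization {normalize!r}")
    return _profile_from_rows(rows, landmark, window, trim_frac, excluded, unfit)
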