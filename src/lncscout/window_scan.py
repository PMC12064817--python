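"""Genome-wide sliding-window coverage scan and outlier window selection.

The scan tiles every chromosome with fixed-length windows (default 500 bp,
250 bp step), summarizes each window as mean per-base RPM per sample, and
selects windows whose top- or bottom-quintile samples deviate from the
cohort median by more than ``min_abs_diff`` RPM *and* more than
``min_log2fc`` in log2 fold change.  Selected windows overlapping known
genes are discarded and the survivors are merged into candidate regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import AnnotationSet, GenomicInterval

DEFAULT_WINDOW = 500
DEFAULT_STEP = 250
MIN_SAMPLES = 5  # the 20% quantile must contain at least one sample


@dataclass
class CoverageMatrix:
    """Windows x samples matrix of mean per-base RPM coverage."""

    windows: list[GenomicInterval]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.windows), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.windows)} windows x {len(self.samples)} samples"
            )
        if np.any(self.values < 0):
            raise ValueError("coverage values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{w.chrom}:{w.start}-{w.end}" for w in self.windows]
        return pd.DataFrame(self.values, index=idx, columns=self.samples)


@dataclass(frozen=True)
class WindowStat:
    """Cohort summary of one window under the outlier selection rule."""

    window: GenomicInterval
    median: float
    top_mean: float
    bottom_mean: float
    abs_diff: float
    log2fc: float
    selected: bool


def make_windows(
    chrom_lengths: Mapping[str, int],
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> list[GenomicInterval]:
    """Tile chromosomes with ``[i*step, i*step + window)`` windows.

    After the last full window, one partial window is appended when it
    extends past the covered end and is at least ``step`` long (so a short
    chromosome tail is still scanned but no redundant sub-window is made).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not (0 < step <= window):
        raise ValueError("need 0 < step <= window")
    out: list[GenomicInterval] = []
    for chrom, length in chrom_lengths.items():
        covered = 0
        for start in range(0, length, step):
            end = start + window
            if end <= length:
                out.append(GenomicInterval(chrom, start, end))
                covered = end
            else:
                if length - start >= step and length > covered:
                    out.append(GenomicInterval(chrom, start, length))
                break
    return out


def build_matrix(samples: Sequence, windows: Sequence[GenomicInterval]) -> CoverageMatrix:
    """Mean per-base RPM coverage for every window x sample.

    ``samples`` are :class:`~lncscout.genome_io.SampleAlignment` or
    :class:`~lncscout.genome_io.SampleCoverage` objects.  Per chromosome the
    full depth track is fetched once per sample and window means are taken
    via a cumulative sum.
    """
    if len(samples) < MIN_SAMPLES:
        raise ValueError(
            f"need >= {MIN_SAMPLES} samples so the 20% quantile contains at "
            f"least one sample; got {len(samples)}"
        )
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    values = np.zeros((len(windows), len(samples)))
    for j, sample in enumerate(samples):
        scale = 1e6 / sample.mapped_reads if sample.mapped_reads > 0 else 0.0
        for chrom, idxs in by_chrom.items():
            span_start = min(windows[i].start for i in idxs)
            span_end = max(windows[i].end for i in idxs)
            depth = sample.per_base_depth(
                GenomicInterval(chrom, span_start, span_end)
            )
            csum = np.concatenate([[0.0], np.cumsum(depth, dtype=float)])
            for i in idxs:
                w = windows[i]
                raw_mean = (csum[w.end - span_start] - csum[w.start - span_start]) / len(w)
                values[i, j] = raw_mean * scale
    return CoverageMatrix(list(windows), [s.sample_id for s in samples], values)


def window_statistics(
    matrix: CoverageMatrix,
    pseudocount: float = 0.1,
    min_abs_diff: float = 1.0,
    min_log2fc: float = 1.0,
) -> list[WindowStat]:
    """Apply the outlier rule to every window of the matrix.

    Per window the sample values are sorted; the top (bottom) group is the
    ``ceil(0.2 * n)`` highest (lowest) values and its mean is compared to
    the cohort median.  A window is selected when either comparison exceeds
    both the absolute-difference threshold (RPM units) and the |log2 fold
    change| threshold; the fold change uses a pseudocount on numerator and
    denominator so an all-zero median is well defined.
    """
    n = len(matrix.samples)
    if n < MIN_SAMPLES:
        raise ValueError(f"need >= {MIN_SAMPLES} samples, got {n}")
    k = math.ceil(0.2 * n)
    vals = np.sort(matrix.values, axis=1)
    median = np.median(vals, axis=1)
    top = vals[:, -k:].mean(axis=1)
    bottom = vals[:, :k].mean(axis=1)
    d_top = np.abs(top - median)
    d_bottom = np.abs(bottom - median)
    fc_top = np.abs(np.log2((top + pseudocount) / (median + pseudocount)))
    fc_bottom = np.abs(np.log2((bottom + pseudocount) / (median + pseudocount)))
    selected = ((d_top > min_abs_diff) & (fc_top > min_log2fc)) | (
        (d_bottom > min_abs_diff) & (fc_bottom > min_log2fc)
    )
    return [
        WindowStat(
            window=w,
            median=float(median[i]),
            top_mean=float(top[i]),
            bottom_mean=float(bottom[i]),
            abs_diff=float(max(d_top[i], d_bottom[i])),
            log2fc=float(max(fc_top[i], fc_bottom[i])),
            selected=bool(selected[i]),
        )
        for i, w in enumerate(matrix.windows)
    ]


def filter_known(stats: Iterable[WindowStat], annotation: AnnotationSet) -> list[WindowStat]:
    """Drop every window overlapping (>= 1 base, strand-agnostic) a gene span."""
    return [s for s in stats if not annotation.overlaps(s.window)]


def merge_windows(selected: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Coalesce overlapping or book-ended windows into maximal regions.

    Output is sorted and pairwise disjoint; adjacent 250 bp-step windows
    covering one transcript form a single region.
    """
    ivs = sorted(selected, key=lambda w: (w.chrom, w.start, w.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def stats_to_frame(stats: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [s.window.chrom for s in stats],
            "start": [s.window.start for s in stats],
            "end": [s.window.end for s in stats],
            "median": [s.median for s in stats],
            "top_mean": [s.top_mean for s in stats],
            "bottom_mean": [s.bottom_mean for s in stats],
            "abs_diff": [s.abs_diff for s in stats],
            "log2fc": [s.log2fc for s in stats],
            "selected": [s.selected for s in stats],
        }
    )


def write_window_stats(stats: Sequence[WindowStat], path: str | Path) -> None:
    stats_to_frame(stats).to_csv(path, sep="\t", index=False, float_format="%.6g")
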