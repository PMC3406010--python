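"""Pairwise nucleotide divergence and GC content, whole-region and windowed.

Divergence is the plain fraction of differing sites among sites where both
samples have an unambiguous base (``A/C/G/T``); no multiple-hit correction is
applied because the divergences of interest are small (<5%).  Sites with
``N`` (or, defensively, ``-``) in either sample are excluded from both the
numerator and the denominator.  All scans run in trimmed coordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import GAP, MISSING, GenomeAlignment


@dataclass
class ScanConfig:
    """Sliding-window settings.

    ``window``/``step`` default to the 500 kb / 100 kb divergence scan;
    GC scans conventionally use 100 kb / 20 kb.  ``min_sites`` flags windows
    with too few compared sites as undefined rather than reporting a noisy
    value.
    """

    window: int = 500_000
    step: int = 100_000
    min_sites: int = 1_000

    def __post_init__(self) -> None:
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")


@dataclass
class WindowStat:
    """One window's statistic (divergence between a pair, or one sample's GC)."""

    chromosome: str
    start: int
    end: int
    label: str
    n_compared: int
    n_diff: int
    value: float  # NaN when undefined
    defined: bool = True


def _pair_masks(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    valid = (x != MISSING) & (y != MISSING) & (x != GAP) & (y != GAP)
    diff = valid & (x != y)
    return valid, diff


def pairwise_divergence(
    aln: GenomeAlignment,
    chrom: str,
    sample_x: str,
    sample_y: str,
    interval: tuple[int, int] | None = None,
    min_sites: int = 1,
) -> WindowStat:
    """Fraction of differing sites between two samples over an interval."""
    x = aln.sequence(chrom, sample_x)
    y = aln.sequence(chrom, sample_y)
    length = aln.length(chrom)
    start, end = interval if interval is not None else (0, length)
    if not (0 <= start <= end <= length):
        raise IndexError(f"interval [{start}, {end}) out of bounds on {chrom!r}")
    valid, diff = _pair_masks(x[start:end], y[start:end])
    n_compared = int(valid.sum())
    n_diff = int(diff.sum())
    defined = n_compared >= max(min_sites, 1)
    value = n_diff / n_compared if defined else float("nan")
    return WindowStat(
        chrom, start, end, f"{sample_x}-{sample_y}", n_compared, n_diff, value, defined
    )


def window_starts(length: int, step: int) -> np.ndarray:
    """Window start positions 0, S, 2S, ... strictly below the chromosome end."""
    return np.arange(0, max(length, 1), step, dtype=np.int64)


def _windowed_counts(
    valid: np.ndarray, diff: np.ndarray, window: int, step: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    length = valid.shape[0]
    cum_valid = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
    cum_diff = np.concatenate(([0], np.cumsum(diff, dtype=np.int64)))
    starts = window_starts(length, step)
    ends = np.minimum(starts + window, length)
    return starts, ends, cum_valid[ends] - cum_valid[starts], cum_diff[ends] - cum_diff[starts]


def sliding_divergence(
    aln: GenomeAlignment,
    chrom: str,
    sample_x: str,
    sample_y: str,
    config: ScanConfig | None = None,
) -> list[WindowStat]:
    """Sliding-window divergence; the final window is truncated at the end."""
    config = config or ScanConfig()
    x = aln.sequence(chrom, sample_x)
    y = aln.sequence(chrom, sample_y)
    valid, diff = _pair_masks(x, y)
    starts, ends, n_comp, n_diff = _windowed_counts(
        valid, diff, config.window, config.step
    )
    label = f"{sample_x}-{sample_y}"
    out = []
    for s, e, nc, nd in zip(starts, ends, n_comp, n_diff):
        defined = nc >= config.min_sites
        out.append(
            WindowStat(
                chrom, int(s), int(e), label, int(nc), int(nd),
                nd / nc if defined else float("nan"), bool(defined),
            )
        )
    return out


def gc_content_windows(
    aln: GenomeAlignment,
    chrom: str,
    sample: str,
    config: ScanConfig | None = None,
) -> list[WindowStat]:
    """Windowed GC fraction (#G+#C over #A+#C+#G+#T); N excluded."""
    config = config or ScanConfig(window=100_000, step=20_000)
    seq = aln.sequence(chrom, sample)
    counted = (seq != MISSING) & (seq != GAP)
    gc = (seq == ord("G")) | (seq == ord("C"))
    starts, ends, n_counted, n_gc = _windowed_counts(
        counted, gc & counted, config.window, config.step
    )
    out = []
    for s, e, nc, ng in zip(starts, ends, n_counted, n_gc):
        defined = nc >= config.min_sites
        out.append(
            WindowStat(
                chrom, int(s), int(e), sample, int(nc), int(ng),
                ng / nc if defined else float("nan"), bool(defined),
            )
        )
    return out


def region_divergence_table(
    aln: GenomeAlignment,
    pairs: list[tuple[str, str]],
    regions: dict[str, tuple[str, int, int]],
    min_sites: int = 1,
) -> pd.DataFrame:
    """Per-(pair, region) divergence summary.

    ``regions`` maps a region label to ``(chromosome, start, end)``.  Returns a
    DataFrame with columns region, chromosome, start, end, pair, n_compared,
    n_diff, value.
    """
    rows = []
    for region, (chrom, start, end) in regions.items():
        for sx, sy in pairs:
            ws = pairwise_divergence(aln, chrom, sx, sy, (start, end), min_sites)
            rows.append(
                {
                    "region": region,
                    "chromosome": chrom,
                    "start": start,
                    "end": end,
                    "pair": ws.label,
                    "n_compared": ws.n_compared,
                    "n_diff": ws.n_diff,
                    "value": ws.value,
                }
            )
    return pd.DataFrame(rows)


def windows_to_frame(windows: list[WindowStat]) -> pd.DataFrame:
    """Long-format table of window statistics (one row per window)."""
    return pd.DataFrame(
        {
            "chromosome": [w.chromosome for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "pair": [w.label for w in windows],
            "n_compared": [w.n_compared for w in windows],
            "n_diff": [w.n_diff for w in windows],
            "value": [w.value for w in windows],
            "defined": [w.defined for w in windows],
        }
    )
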