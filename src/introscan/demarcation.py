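"""Stepwise demarcation of pseudoautosomal vs elevated-divergence regions and
introgression-tract boundaries.

The procedure mirrors the coarse-to-fine scheme used for recombination-
suppressed fungal mating-type chromosomes: the chromosome is tiled into
non-overlapping 100 kb sections and each section's percent nucleotide
difference is compared against a 1% cutoff; the longest contiguous run of
sections above the cutoff is the region of elevated divergence (the central,
non-recombining region), and its two boundary sections are re-scanned at
10 kb resolution to pin the borders.  Introgression tracts are found with the
same stepwise scheme but a relative criterion: a section is introgressed when
the putatively introgressed allele is closer to a non-introgressed reference
genome than its partner allele is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .alignment import GenomeAlignment
from .divergence import _pair_masks


@dataclass
class DemarcationConfig:
    coarse_section: int = 100_000
    fine_section: int = 10_000
    cutoff: float = 0.01
    #: minimum divergence difference for the closest-relative tract criterion;
    #: 0 means strict inequality
    introgression_margin: float = 0.0
    min_sites: int = 1_000

    def __post_init__(self) -> None:
        if self.coarse_section % self.fine_section != 0:
            raise ValueError("fine_section must divide coarse_section")
        if not (0 < self.cutoff < 1):
            raise ValueError("cutoff must be in (0, 1)")
        if self.introgression_margin < 0:
            raise ValueError("introgression_margin must be >= 0")


@dataclass
class RegionCall:
    """A labelled interval in trimmed coordinates with its evidence."""

    chromosome: str
    start: int
    end: int
    label: str  # PA1 | central | PA2 | tract
    evidence: dict[str, Any] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.end <= self.start


def _tile(start: int, end: int, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping tiling of [start, end); the last section is truncated."""
    starts = np.arange(start, end, size, dtype=np.int64)
    ends = np.minimum(starts + size, end)
    return starts, ends


def _section_counts(
    x: np.ndarray, y: np.ndarray, start: int, end: int, size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    valid, diff = _pair_masks(x[start:end], y[start:end])
    cum_v = np.concatenate(([0], np.cumsum(valid, dtype=np.int64)))
    cum_d = np.concatenate(([0], np.cumsum(diff, dtype=np.int64)))
    starts, ends = _tile(start, end, size)
    lo, hi = starts - start, ends - start
    return starts, ends, cum_v[hi] - cum_v[lo], cum_d[hi] - cum_d[lo]


def section_divergences(
    aln: GenomeAlignment,
    chrom: str,
    sample_x: str,
    sample_y: str,
    section_size: int,
    interval: tuple[int, int] | None = None,
) -> dict[str, np.ndarray]:
    """Per-section divergence over a non-overlapping tiling (from 0 or an interval).

    Returns arrays ``start``, ``end``, ``n_compared``, ``n_diff``, ``value``
    (NaN where no site is comparable).
    """
    if section_size < 1:
        raise ValueError("section_size must be >= 1")
    start, end = interval if interval is not None else (0, aln.length(chrom))
    x = aln.sequence(chrom, sample_x)
    y = aln.sequence(chrom, sample_y)
    starts, ends, n_comp, n_diff = _section_counts(x, y, start, end, section_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        value = np.where(n_comp > 0, n_diff / np.maximum(n_comp, 1), np.nan)
    return {
        "start": starts,
        "end": ends,
        "n_compared": n_comp,
        "n_diff": n_diff,
        "value": value,
    }


def _inherit_undefined(state: np.ndarray, defined: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Sections with too few compared sites inherit the preceding section's state."""
    out = state.copy()
    inherited = []
    prev = False  # an undefined leading section defaults to not-elevated
    for i in range(out.shape[0]):
        if not defined[i]:
            out[i] = prev
            inherited.append(i)
        prev = out[i]
    return out, inherited


def _longest_true_run(mask: np.ndarray) -> tuple[int, int]:
    """Indices [i, j) of the longest contiguous run of True (first on ties)."""
    best = (0, 0)
    i = 0
    n = mask.shape[0]
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def _refine_boundary(
    crit_values: np.ndarray, fine_starts: np.ndarray, fine_ends: np.ndarray,
    passes: np.ndarray, side: str, fallback: int,
) -> int:
    """Scan a boundary section's fine sections from the outside inward.

    ``side`` is which side of the run the section sits on: for "left" the scan
    runs left-to-right and the boundary is the start of the first passing fine
    section; for "right" it runs right-to-left and the boundary is the end of
    the first passing fine section.  If none passes, the boundary collapses to
    ``fallback`` (the inner edge of the section).
    """
    order = range(passes.shape[0]) if side == "left" else range(passes.shape[0] - 1, -1, -1)
    for i in order:
        if passes[i]:
            return int(fine_starts[i]) if side == "left" else int(fine_ends[i])
    return fallback


def demarcate_elevated_region(
    aln: GenomeAlignment,
    chrom: str,
    sample_x: str,
    sample_y: str,
    config: DemarcationConfig | None = None,
) -> tuple[RegionCall, RegionCall, RegionCall]:
    """Partition a chromosome into (PA1, central, PA2) for one allele pair.

    The central region is the longest contiguous run of coarse sections whose
    divergence strictly exceeds the cutoff (ties at the cutoff count as not
    elevated); its borders are refined at fine resolution.  All three calls
    are returned even when the central region is empty (then the whole
    chromosome is pseudoautosomal and the calls are flagged).
    """
    config = config or DemarcationConfig()
    length = aln.length(chrom)
    pair = f"{sample_x}-{sample_y}"
    sec = section_divergences(aln, chrom, sample_x, sample_y, config.coarse_section)
    defined = sec["n_compared"] >= config.min_sites
    elevated = np.where(defined, sec["value"] > config.cutoff, False)
    elevated, inherited = _inherit_undefined(elevated, defined)
    i0, i1 = _longest_true_run(elevated)

    flags = [f"section_{i}_undefined_inherited" for i in inherited]
    if i0 == i1:  # nothing above the cutoff
        pa1 = RegionCall(chrom, 0, length, "PA1",
                         {"pair": pair, "mean_divergence": float(np.nanmean(sec["value"]))},
                         flags + ["no_elevated_region"])
        central = RegionCall(chrom, length, length, "central", {"pair": pair},
                             ["no_elevated_region"])
        pa2 = RegionCall(chrom, length, length, "PA2", {"pair": pair},
                         ["no_elevated_region"])
        return pa1, central, pa2

    x = aln.sequence(chrom, sample_x)
    y = aln.sequence(chrom, sample_y)

    def fine_pass(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        fs, fe, n_c, n_d = _section_counts(x, y, lo, hi, config.fine_section)
        with np.errstate(invalid="ignore"):
            val = np.where(n_c > 0, n_d / np.maximum(n_c, 1), np.nan)
        ok = (n_c > 0) & (val > config.cutoff)
        return fs, fe, ok

    # left boundary: refine the run's first coarse section
    lo = int(sec["start"][i0])
    hi = int(sec["end"][i0])
    fs, fe, ok = fine_pass(lo, hi)
    start = _refine_boundary(None, fs, fe, ok, "left", hi)
    # right boundary: refine the run's last coarse section
    lo2 = int(sec["start"][i1 - 1])
    hi2 = int(sec["end"][i1 - 1])
    fs, fe, ok = fine_pass(lo2, hi2)
    end = _refine_boundary(None, fs, fe, ok, "right", lo2)
    if end < start:  # degenerate single-section run with no passing fine section
        start = end = lo

    outliers = [
        int(i) for i in np.flatnonzero(elevated) if not (i0 <= i < i1)
    ]
    run_values = sec["value"][i0:i1]
    evidence = {
        "pair": pair,
        "cutoff": config.cutoff,
        "coarse_run": [int(sec["start"][i0]), int(sec["end"][i1 - 1])],
        "mean_divergence": float(np.nanmean(run_values)),
        "outlier_sections": outliers,
    }
    central = RegionCall(chrom, start, end, "central", evidence, flags)
    pa1 = RegionCall(
        chrom, 0, start, "PA1",
        {"pair": pair, "mean_divergence": _interval_divergence(x, y, 0, start)},
        flags,
    )
    pa2 = RegionCall(
        chrom, end, length, "PA2",
        {"pair": pair, "mean_divergence": _interval_divergence(x, y, end, length)},
        flags,
    )
    return pa1, central, pa2


def _interval_divergence(x: np.ndarray, y: np.ndarray, start: int, end: int) -> float:
    if end <= start:
        return float("nan")
    valid, diff = _pair_masks(x[start:end], y[start:end])
    n = int(valid.sum())
    return float(diff.sum() / n) if n else float("nan")


def call_introgression_tract(
    aln: GenomeAlignment,
    chrom: str,
    query: str,
    partner: str,
    reference: str,
    central: RegionCall,
    config: DemarcationConfig | None = None,
) -> RegionCall:
    """Locate the introgression tract on the query allele within the central region.

    A coarse section is introgressed when
    ``divergence(query, reference) + margin < divergence(partner, reference)``;
    the tract is the longest contiguous run of such sections, with borders
    refined at fine resolution by the same criterion.  Sections are tiled from
    the central region's start so the tract nests inside it.
    """
    config = config or DemarcationConfig()
    if len({query, partner, reference}) != 3:
        raise ValueError("query, partner and reference must be distinct samples")
    if central.empty:
        raise ValueError("central region is empty; no tract can be called")

    interval = (central.start, central.end)
    sq = section_divergences(aln, chrom, query, reference, config.coarse_section, interval)
    sp = section_divergences(aln, chrom, partner, reference, config.coarse_section, interval)
    defined = (sq["n_compared"] >= config.min_sites) & (sp["n_compared"] >= config.min_sites)
    with np.errstate(invalid="ignore"):
        intro = np.where(
            defined, sq["value"] + config.introgression_margin < sp["value"], False
        )
    intro, inherited = _inherit_undefined(intro, defined)
    i0, i1 = _longest_true_run(intro)
    flags = [f"section_{i}_undefined_inherited" for i in inherited]
    pair_info = {
        "query_pair": f"{query}-{reference}",
        "partner_pair": f"{partner}-{reference}",
        "margin": config.introgression_margin,
    }
    if i0 == i1:
        return RegionCall(chrom, central.start, central.start, "tract",
                          pair_info, flags + ["no_tract"])

    xq = aln.sequence(chrom, query)
    xp = aln.sequence(chrom, partner)
    xr = aln.sequence(chrom, reference)

    def fine_pass(lo: int, hi: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        fs, fe, ncq, ndq = _section_counts(xq, xr, lo, hi, config.fine_section)
        _, _, ncp, ndp = _section_counts(xp, xr, lo, hi, config.fine_section)
        with np.errstate(invalid="ignore"):
            vq = np.where(ncq > 0, ndq / np.maximum(ncq, 1), np.nan)
            vp = np.where(ncp > 0, ndp / np.maximum(ncp, 1), np.nan)
        ok = (ncq > 0) & (ncp > 0) & (vq + config.introgression_margin < vp)
        return fs, fe, ok

    lo, hi = int(sq["start"][i0]), int(sq["end"][i0])
    fs, fe, ok = fine_pass(lo, hi)
    start = _refine_boundary(None, fs, fe, ok, "left", hi)
    lo2, hi2 = int(sq["start"][i1 - 1]), int(sq["end"][i1 - 1])
    fs, fe, ok = fine_pass(lo2, hi2)
    end = _refine_boundary(None, fs, fe, ok, "right", lo2)
    if end < start:
        start = end = lo

    evidence = dict(pair_info)
    evidence.update(
        {
            "coarse_run": [lo, hi2],
            "mean_query_divergence": _interval_divergence(xq, xr, start, end),
            "mean_partner_divergence": _interval_divergence(xp, xr, start, end),
        }
    )
    return RegionCall(chrom, start, end, "tract", evidence, flags)


def region_calls_to_bed(calls: list[RegionCall]) -> str:
    """BED (trimmed space) text for a list of region calls."""
    lines = []
    for c in calls:
        lines.append(f"{c.chromosome}\t{c.start}\t{c.end}\t{c.label}\t0\t+")
    return "\n".join(lines) + "\n"
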