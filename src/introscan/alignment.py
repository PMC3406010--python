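"""Multi-genome alignment container, gap-column trimming and coordinate maps.

The alignment holds one equal-length sequence per haploid genome for each
chromosome, in reference coordinates ("original" space).  Removing every
column that contains at least one alignment gap yields the "trimmed" space in
which all downstream statistics are computed; a :class:`ColumnMap` records the
strictly increasing mapping from trimmed to original column indices so that
results can be reported in either coordinate system.

Sequences are stored as 2-D ``uint8`` arrays of ASCII codes over the alphabet
``{A, C, G, T, N, -}``.  ``N`` marks missing consensus data (uncovered
reference positions) and is *not* a gap: columns containing ``N`` are kept by
trimming and handled at the divergence stage instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = ord("-")
MISSING = ord("N")
_ALLOWED = np.frombuffer(b"ACGTN-", dtype=np.uint8)

# byte translation table: lowercase acgtn -> uppercase, everything else kept
_UPPER = np.arange(256, dtype=np.uint8)
for _c in b"acgtn":
    _UPPER[_c] = _c - 32
del _c


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment input (length mismatch, bad characters)."""


@dataclass
class GenomeAlignment:
    """Equal-length aligned haploid genome sequences over named chromosomes.

    Parameters
    ----------
    sample_ids
        Ordered, unique genome names (e.g. ``NC, L1A, L1a, ...``).
    chromosomes
        Mapping chromosome name -> ``(n_samples, length)`` uint8 array of
        ASCII codes.
    coordinate_space
        ``"original"`` for raw input, ``"trimmed"`` after gap-column removal.
    """

    sample_ids: list[str]
    chromosomes: dict[str, np.ndarray]
    coordinate_space: str = "original"

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentFormatError("sample ids must be unique")
        if self.coordinate_space not in ("original", "trimmed"):
            raise ValueError(f"unknown coordinate space {self.coordinate_space!r}")
        n = len(self.sample_ids)
        for chrom, arr in self.chromosomes.items():
            if arr.ndim != 2 or arr.shape[0] != n:
                raise AlignmentFormatError(
                    f"chromosome {chrom!r}: expected {n} rows, got shape {arr.shape}"
                )

    @property
    def chromosome_names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, chrom: str) -> int:
        return int(self.chromosomes[chrom].shape[1])

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def sequence(self, chrom: str, sample: str) -> np.ndarray:
        """Return a (read-only view of) one sample's sequence on a chromosome."""
        return self.chromosomes[chrom][self.sample_index(sample)]


@dataclass
class ColumnMap:
    """Per-chromosome strictly increasing map trimmed index -> original index."""

    maps: dict[str, np.ndarray] = field(default_factory=dict)

    def trimmed_length(self, chrom: str) -> int:
        return int(self.maps[chrom].shape[0])


def _validate_sequence(arr: np.ndarray, chrom: str, sample: str) -> None:
    bad = ~np.isin(arr, _ALLOWED)
    if bad.any():
        pos = int(np.argmax(bad))
        raise AlignmentFormatError(
            f"chromosome {chrom!r}, sample {sample!r}: invalid character "
            f"{chr(arr[pos])!r} at position {pos}"
        )


def seq_to_array(seq: str | bytes) -> np.ndarray:
    """Encode a sequence string to an upper-cased uint8 ASCII array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _UPPER[np.frombuffer(seq, dtype=np.uint8)]


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def read_alignment(
    fasta_paths: Mapping[str, str | Path],
    samples: Sequence[str] | None = None,
) -> GenomeAlignment:
    """Read a per-chromosome set of aligned FASTA files.

    Each file must contain one record per sample, all of identical length.
    Lowercase bases are normalised to uppercase.  If ``samples`` is given it
    acts as a manifest: every listed sample must be present on every
    chromosome, and rows are ordered accordingly; otherwise the record order
    of the first chromosome is used.
    """
    chromosomes: dict[str, np.ndarray] = {}
    sample_order: list[str] | None = list(samples) if samples is not None else None
    for chrom, path in fasta_paths.items():
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise AlignmentFormatError(f"no records in {path}")
        if sample_order is None:
            sample_order = list(records)
        missing = [s for s in sample_order if s not in records]
        if missing:
            raise AlignmentFormatError(
                f"chromosome {chrom!r}: missing samples {missing}"
            )
        lengths = {s: len(records[s]) for s in sample_order}
        if len(set(lengths.values())) != 1:
            raise AlignmentFormatError(
                f"chromosome {chrom!r}: unequal sequence lengths {lengths}"
            )
        arr = np.empty((len(sample_order), len(records[sample_order[0]])), dtype=np.uint8)
        for i, s in enumerate(sample_order):
            row = seq_to_array(records[s])
            _validate_sequence(row, chrom, s)
            arr[i] = row
        chromosomes[chrom] = arr
    assert sample_order is not None
    return GenomeAlignment(sample_order, chromosomes, coordinate_space="original")


def write_alignment(
    aln: GenomeAlignment, outdir: str | Path, line_width: int = 70
) -> dict[str, Path]:
    """Write one aligned FASTA per chromosome; returns chromosome -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for chrom, arr in aln.chromosomes.items():
        path = outdir / f"{chrom}.fasta"
        records = [
            SeqRecord(Seq(array_to_seq(arr[i])), id=sid, description="")
            for i, sid in enumerate(aln.sample_ids)
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
            writer.write_file(records)
        paths[chrom] = path
    return paths


def remove_gap_columns(aln: GenomeAlignment) -> tuple[GenomeAlignment, ColumnMap]:
    """Drop every column containing at least one ``-`` in any sample.

    Returns the trimmed alignment plus the trimmed->original column map.
    Columns containing only ``N`` (missing data) are retained.  Idempotent:
    applying it to an already gap-free alignment returns an identical copy
    with an identity map.
    """
    if aln.coordinate_space != "original":
        raise ValueError("remove_gap_columns expects an original-space alignment")
    trimmed: dict[str, np.ndarray] = {}
    cmap = ColumnMap()
    for chrom, arr in aln.chromosomes.items():
        keep = ~(arr == GAP).any(axis=0)
        idx = np.flatnonzero(keep).astype(np.int64)
        trimmed[chrom] = np.ascontiguousarray(arr[:, idx])
        cmap.maps[chrom] = idx
    out = GenomeAlignment(list(aln.sample_ids), trimmed, coordinate_space="trimmed")
    return out, cmap


def map_to_original(
    interval: tuple[int, int], cmap: ColumnMap, chrom: str
) -> tuple[int, int]:
    """Map a 0-based half-open trimmed-space interval to original coordinates.

    The result is ``[map(start), map(end - 1) + 1)``; an empty interval maps
    to an empty interval anchored at ``map(start)``.
    """
    start, end = interval
    idx = cmap.maps[chrom]
    n = idx.shape[0]
    if not (0 <= start <= end <= n):
        raise IndexError(
            f"interval [{start}, {end}) out of trimmed bounds [0, {n}) on {chrom!r}"
        )
    if start == end:
        orig = int(idx[start]) if start < n else (int(idx[-1]) + 1 if n else 0)
        return orig, orig
    return int(idx[start]), int(idx[end - 1]) + 1


def write_column_map(cmap: ColumnMap, path: str | Path) -> None:
    """Serialise as run-length compressed JSON.

    Runs of consecutive original columns are stored as
    ``[trimmed_start, original_start, length]`` triples.
    """
    payload = {}
    for chrom, idx in cmap.maps.items():
        runs = []
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) != 1) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [idx.size]))
            for s, e in zip(starts, ends):
                runs.append([int(s), int(idx[s]), int(e - s)])
        payload[chrom] = runs
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_column_map(path: str | Path) -> ColumnMap:
    with open(path) as fh:
        payload = json.load(fh)
    cmap = ColumnMap()
    for chrom, runs in payload.items():
        parts = [np.arange(o, o + n, dtype=np.int64) for _, o, n in runs]
        cmap.maps[chrom] = (
            np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
        )
    return cmap
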