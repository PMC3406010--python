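"""Preferred/non-preferred codon-switch degeneration analysis.

Codon usage bias assigns each degenerate amino-acid family a preferred (PR)
codon; relaxed selection in non-recombining regions shows up as a net excess
of synonymous switches away from preferred codons.  Switches are polarised
against an outgroup genome (here *N. crassa*, NC): for each aligned codon the
PR/NPR status triple (NC, mat a, mat A) is inspected and a switch is
attributed to one allele only when the partner allele retains the outgroup
state, e.g. (PR, NPR, PR) is a mat a PR->NPR switch.  Codons whose three
translations are not identical carry a nonsynonymous change and are excluded;
so are codons with missing data.  Per allele, the excess
``E = n(PR->NPR) - n(NPR->PR)`` and the frequency ``F = E / T * 1000`` (T =
total analysed codons) summarise the degeneration, and exact binomial sign
tests assess the excess within and between alleles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .alignment import GenomeAlignment
from .shared_sites import SignTestResult, binomial_sign_test

PR = "PR"
NPR = "NPR"

_BASES = "ACGT"
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _BASE_INDEX[ord(_b)] = _i
del _i, _b

_COMPLEMENT = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN-", b"TGCAN-"):
    _COMPLEMENT[_a] = _b
del _a, _b

SENSE_CODONS = sorted(standard_dna_table.forward_table)
STOP_CODONS = sorted(standard_dna_table.stop_codons)
GENETIC_CODE = dict(standard_dna_table.forward_table)

_AA_LIST = sorted(set(GENETIC_CODE.values()))
_AA_ID = {aa: i for i, aa in enumerate(_AA_LIST)}


class CodonTableError(ValueError):
    """Raised for invalid or inconsistent preferred-codon tables."""


def codon_id(codon: str) -> int:
    b = [_BASE_INDEX[ord(c)] for c in codon]
    return b[0] * 16 + b[1] * 4 + b[2]


@dataclass
class PreferredCodonTable:
    """Mapping of the 61 sense codons to PR/NPR status and amino acid."""

    status: dict[str, str]
    amino_acid: dict[str, str]
    # 64-entry lookup arrays indexed by codon id; 255 = stop codon
    _aa_lut: np.ndarray = field(repr=False, default=None)
    _pr_lut: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        missing = [c for c in SENSE_CODONS if c not in self.status]
        if missing:
            raise CodonTableError(f"table missing sense codon(s): {missing[:5]}")
        for codon, aa in self.amino_acid.items():
            if codon in GENETIC_CODE and GENETIC_CODE[codon] != aa:
                raise CodonTableError(
                    f"codon {codon} assigned to {aa} but encodes {GENETIC_CODE[codon]}"
                )
            if codon in STOP_CODONS:
                raise CodonTableError(f"stop codon {codon} must not appear in the table")
        for codon, st in self.status.items():
            if st not in (PR, NPR):
                raise CodonTableError(f"codon {codon}: status must be PR or NPR, got {st!r}")
        # every degenerate family needs at least one preferred codon
        by_aa: dict[str, list[str]] = {}
        for codon in SENSE_CODONS:
            by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
        for aa, codons in by_aa.items():
            if len(codons) >= 2 and not any(self.status[c] == PR for c in codons):
                raise CodonTableError(f"amino acid {aa} has no preferred codon")
        aa_lut = np.full(64, 255, dtype=np.uint8)
        pr_lut = np.full(64, 255, dtype=np.uint8)
        for codon in SENSE_CODONS:
            cid = codon_id(codon)
            aa_lut[cid] = _AA_ID[GENETIC_CODE[codon]]
            pr_lut[cid] = 1 if self.status[codon] == PR else 0
        object.__setattr__(self, "_aa_lut", aa_lut)
        object.__setattr__(self, "_pr_lut", pr_lut)

    def preferred_codons(self) -> list[str]:
        return [c for c in SENSE_CODONS if self.status[c] == PR]

    def synonyms(self, codon: str, status: str) -> list[str]:
        aa = GENETIC_CODE[codon]
        return [
            c for c in SENSE_CODONS
            if GENETIC_CODE[c] == aa and self.status[c] == status
        ]


def load_preferred_table(path: str | Path) -> PreferredCodonTable:
    """Load a TSV with columns codon, amino_acid, status (PR/NPR)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"codon", "amino_acid", "status"}
    if not required.issubset(df.columns):
        raise CodonTableError(f"table must have columns {sorted(required)}")
    status = dict(zip(df["codon"].str.upper(), df["status"].str.upper()))
    amino = dict(zip(df["codon"].str.upper(), df["amino_acid"]))
    return PreferredCodonTable(status, amino)


def write_preferred_table(table: PreferredCodonTable, path: str | Path) -> None:
    rows = [
        {"codon": c, "amino_acid": GENETIC_CODE[c], "status": table.status[c]}
        for c in SENSE_CODONS
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_preferred_table() -> PreferredCodonTable:
    """Synthetic preferred-codon table used by the simulator.

    One preferred codon per degenerate family, chosen as the alphabetically
    first C-ending codon of the family (else the first codon); single-codon
    amino acids (Met, Trp) are preferred by convention.  This mimics the
    C-ending preference of highly expressed Neurospora genes but is a
    synthetic stand-in, not the organism's measured table; real analyses
    should supply their own table.
    """
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
    status: dict[str, str] = {}
    for aa, codons in sorted(by_aa.items()):
        if len(codons) == 1:
            status[codons[0]] = PR
            continue
        c_ending = [c for c in codons if c.endswith("C")]
        preferred = c_ending[0] if c_ending else codons[0]
        for c in codons:
            status[c] = PR if c == preferred else NPR
    amino = {c: GENETIC_CODE[c] for c in SENSE_CODONS}
    return PreferredCodonTable(status, amino)


# ---------------------------------------------------------------------------
# gene annotations and coding-sequence extraction


@dataclass
class Gene:
    chromosome: str
    start: int
    end: int
    name: str
    strand: str = "+"


def read_genes_bed(path: str | Path) -> list[Gene]:
    """Read a BED6 gene file (0-based half-open intervals)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"gene_{start}"
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(Gene(chrom, start, end, name, strand))
    return genes


def write_genes_bed(genes: list[Gene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n")


@dataclass
class CodingAlignment:
    """Concatenated in-frame coding sequences for a set of samples.

    ``codons[sample]`` is a ``(n_codons, 3)`` uint8 array of base indices
    (0-3).  Bookkeeping counts how many genes were dropped and why.
    """

    codons: dict[str, np.ndarray]
    gene_names: list[str]
    n_genes_considered: int
    n_excluded_outside: int
    n_excluded_incomplete: int
    n_excluded_frame: int

    @property
    def n_codons(self) -> int:
        first = next(iter(self.codons.values()))
        return int(first.shape[0])


def extract_coding_alignment(
    aln: GenomeAlignment,
    genes: list[Gene],
    region: tuple[str, int, int],
    samples: list[str] | None = None,
) -> CodingAlignment:
    """Concatenate, in coordinate order, the genes fully inside ``region`` that
    are complete (no N, no gap) in every sample.

    Reverse-strand genes are reverse-complemented into reading frame.  Genes
    whose length is not divisible by 3 are excluded and counted.
    """
    chrom, rstart, rend = region
    samples = samples if samples is not None else list(aln.sample_ids)
    seqs = {s: aln.sequence(chrom, s) for s in samples}

    kept: list[Gene] = []
    n_outside = n_incomplete = n_frame = 0
    candidates = [g for g in genes if g.chromosome == chrom]
    for g in sorted(candidates, key=lambda g: g.start):
        if g.start < rstart or g.end > rend:
            n_outside += 1
            continue
        if (g.end - g.start) % 3 != 0:
            n_frame += 1
            continue
        complete = True
        for s in samples:
            piece = seqs[s][g.start:g.end]
            if (_BASE_INDEX[piece] == 255).any():
                complete = False
                break
        if not complete:
            n_incomplete += 1
            continue
        kept.append(g)

    codons: dict[str, np.ndarray] = {}
    for s in samples:
        parts = []
        for g in kept:
            piece = seqs[s][g.start:g.end]
            if g.strand == "-":
                piece = _COMPLEMENT[piece][::-1]
            parts.append(_BASE_INDEX[piece])
        concat = np.concatenate(parts) if parts else np.empty(0, dtype=np.uint8)
        codons[s] = concat.reshape(-1, 3)
    return CodingAlignment(
        codons, [g.name for g in kept], len(candidates),
        n_outside, n_incomplete, n_frame,
    )


# ---------------------------------------------------------------------------
# switch classification


@dataclass
class CodonSwitchTable:
    """Per-allele PR<->NPR switch counts for one lineage (machine-readable
    form of a degeneration summary table row group)."""

    n_pr_to_npr: dict[str, int]  # allele -> count
    n_npr_to_pr: dict[str, int]
    total_codons: int  # all codons in the coding alignment
    n_excluded_missing: int
    n_excluded_nonsyn: int
    n_uninformative: int
    excess: dict[str, int] = field(default_factory=dict)
    frequency: dict[str, float] = field(default_factory=dict)

    @property
    def n_analyzed(self) -> int:
        """T: codons entering classification (total minus exclusions)."""
        return self.total_codons - self.n_excluded_missing - self.n_excluded_nonsyn


def _codon_ids(codons: np.ndarray) -> np.ndarray:
    """(n, 3) base-index array -> codon ids; 255 where any base is ambiguous."""
    valid = (codons < 4).all(axis=1)
    ids = (
        codons[:, 0].astype(np.int16) * 16
        + codons[:, 1].astype(np.int16) * 4
        + codons[:, 2].astype(np.int16)
    )
    ids[~valid] = 255
    return ids


def classify_codon_switches(
    nc: np.ndarray,
    mat_a: np.ndarray,
    mat_A: np.ndarray,
    table: PreferredCodonTable,
) -> CodonSwitchTable:
    """Classify allele-specific PR<->NPR switches against the outgroup state.

    Inputs are ``(n, 3)`` base-index codon arrays for the outgroup (NC) and
    the two alleles.  Codons with missing data in any sequence are excluded
    first, then codons whose three translations are not identical (or that
    contain a stop codon); the remainder are classified by the PR/NPR status
    triple.  A switch is attributed to an allele only when the partner allele
    retains the outgroup status; all other configurations (including
    both-derived states) are uninformative.
    """
    if not (nc.shape == mat_a.shape == mat_A.shape):
        raise ValueError("codon arrays must have equal shapes")
    n_total = nc.shape[0]
    ids = [_codon_ids(c) for c in (nc, mat_a, mat_A)]
    present = (ids[0] != 255) & (ids[1] != 255) & (ids[2] != 255)
    n_missing = int(n_total - present.sum())

    aa = [np.where(present, table._aa_lut[np.minimum(i, 63)], 255) for i in ids]
    stop_or_diff = present & (
        (aa[0] == 255) | (aa[1] == 255) | (aa[2] == 255)
        | (aa[0] != aa[1]) | (aa[0] != aa[2])
    )
    n_nonsyn = int(stop_or_diff.sum())
    analyzed = present & ~stop_or_diff

    st = [np.where(analyzed, table._pr_lut[np.minimum(i, 63)], 255) for i in ids]
    s_nc, s_a, s_A = st
    a_pr_to_npr = int((analyzed & (s_nc == 1) & (s_a == 0) & (s_A == 1)).sum())
    a_npr_to_pr = int((analyzed & (s_nc == 0) & (s_a == 1) & (s_A == 0)).sum())
    A_pr_to_npr = int((analyzed & (s_nc == 1) & (s_a == 1) & (s_A == 0)).sum())
    A_npr_to_pr = int((analyzed & (s_nc == 0) & (s_a == 0) & (s_A == 1)).sum())
    n_analyzed = int(analyzed.sum())
    n_uninformative = n_analyzed - (a_pr_to_npr + a_npr_to_pr + A_pr_to_npr + A_npr_to_pr)
    return CodonSwitchTable(
        n_pr_to_npr={"mat_a": a_pr_to_npr, "mat_A": A_pr_to_npr},
        n_npr_to_pr={"mat_a": a_npr_to_pr, "mat_A": A_npr_to_pr},
        total_codons=n_total,
        n_excluded_missing=n_missing,
        n_excluded_nonsyn=n_nonsyn,
        n_uninformative=n_uninformative,
    )


def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -ndigits, rounding=ROUND_HALF_UP))


def excess_and_frequency(
    tbl: CodonSwitchTable, total_codons: int | None = None
) -> CodonSwitchTable:
    """Fill per-allele excess E and per-1000-codon frequency F (2 decimals).

    ``total_codons`` overrides the denominator, for recomputing published
    summary rows from their printed counts and footnote totals.
    """
    T = total_codons if total_codons is not None else tbl.n_analyzed
    if T < 1:
        raise ValueError("total codon count must be >= 1")
    for allele in tbl.n_pr_to_npr:
        e = tbl.n_pr_to_npr[allele] - tbl.n_npr_to_pr[allele]
        tbl.excess[allele] = e
        tbl.frequency[allele] = round_half_up(e / T * 1000, 2)
    return tbl


def degeneration_sign_tests(tbl: CodonSwitchTable) -> dict[str, SignTestResult]:
    """Exact sign tests for net NPR accumulation per allele and between alleles.

    Per allele: k = n(PR->NPR) out of all switches.  Between alleles: the two
    excesses are compared (k = E(mat_A) out of E(mat_A) + E(mat_a)), defined
    only when both excesses are non-negative and not both zero.
    """
    if not tbl.excess:
        excess_and_frequency(tbl)
    results: dict[str, SignTestResult] = {}
    for allele in tbl.n_pr_to_npr:
        k = tbl.n_pr_to_npr[allele]
        n = k + tbl.n_npr_to_pr[allele]
        results[f"net_{allele}"] = (
            binomial_sign_test(k, n) if n else SignTestResult(0, 0, float("nan"), False)
        )
    e_A, e_a = tbl.excess["mat_A"], tbl.excess["mat_a"]
    if e_A >= 0 and e_a >= 0 and e_A + e_a > 0:
        results["between_alleles"] = binomial_sign_test(e_A, e_A + e_a)
    else:
        results["between_alleles"] = SignTestResult(0, 0, float("nan"), False)
    return results


def load_reference_switch_counts() -> pd.DataFrame:
    """Published allele-specific switch counts for the three *N. tetrasperma*
    lineages relative to *N. crassa* (introgressed-region 543-gene set),
    with the per-lineage analysed codon totals."""
    path = resources.files("introscan.data") / "tetrasperma_switch_counts.tsv"
    return pd.read_csv(str(path), sep="\t")


def switch_table_frame(tables: dict[str, CodonSwitchTable]) -> pd.DataFrame:
    """Degeneration-summary-shaped long table: one row per (lineage, allele)."""
    rows = []
    for lineage, tbl in tables.items():
        if not tbl.excess:
            excess_and_frequency(tbl)
        for allele in ("mat_a", "mat_A"):
            rows.append(
                {
                    "lineage": lineage,
                    "allele": allele,
                    "n_pr_to_npr": tbl.n_pr_to_npr[allele],
                    "n_npr_to_pr": tbl.n_npr_to_pr[allele],
                    "excess": tbl.excess[allele],
                    "frequency_per_1000": tbl.frequency[allele],
                    "total_codons": tbl.n_analyzed,
                }
            )
    return pd.DataFrame(rows)
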