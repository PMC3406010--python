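"""Sequence-evolution simulator for aligned haploid genomes with a known
introgression tract.

The generator emulates the data regime the analysis pipeline is built for:
seven aligned haploid genomes in reference coordinates — an outgroup (NC) and
three lineages x two mating types (L1A, L1a, L4A, L4a, L9A, L9a) — with

* near-identical intra-lineage autosomes (~0.45% observed divergence),
* a mating-type chromosome whose central region shows elevated intra-lineage
  divergence (the two alleles evolve independently from the lineage ancestor
  there, modelling suppressed recombination),
* a donor-derived introgression tract copied over the mat-a allele after
  evolution (modelling backcross replacement),
* a low-GC centromeric segment carrying missing data (``N``),
* in-frame coding genes with controlled synonymous codon-preference switch
  rates, and
* planted alignment gap columns to exercise trimming.

Substitutions follow a Jukes–Cantor-like per-site model (each site mutates to
one of the three alternative bases with equal probability); no multiple-hit
correction is applied downstream, so for divergence-calibrated pairs the two
branch lengths are solved from the composition ``D = d1 + d2 - (4/3) d1 d2``
so the *observed* pairwise divergence matches the configured value in
expectation.

Coordinate convention: all configured intervals (central region, tract,
centromere, genes) live in the gap-free core space — exactly the space that
gap-column trimming recovers — and the emitted truth intervals equal the
configured intervals in trimmed coordinates.  Planted gap columns inflate the
emitted original-space alignment.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .alignment import GenomeAlignment, write_alignment
from .codons import (
    GENETIC_CODE,
    NPR,
    PR,
    SENSE_CODONS,
    Gene,
    PreferredCodonTable,
    default_preferred_table,
    write_genes_bed,
    write_preferred_table,
)

SAMPLES = ["NC", "L1A", "L1a", "L4A", "L4a", "L9A", "L9a"]
LINEAGES = ["L1", "L4", "L9"]

_IDX_TO_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)
_N_IDX = 4


class ConfigError(ValueError):
    """Raised for invalid simulation configurations."""


def compose_divergence(d1: float, d2: float) -> float:
    """Observed divergence across two independent branches d1, d2."""
    return d1 + d2 - (4.0 / 3.0) * d1 * d2


def split_branch(total: float) -> float:
    """Branch length d such that two independent branches of length d give an
    observed divergence of ``total`` (inverse of :func:`compose_divergence`)."""
    if not (0 <= total < 0.75):
        raise ConfigError(f"cannot split divergence {total}")
    return (3.0 - math.sqrt(9.0 - 12.0 * total)) / 4.0


def residual_branch(total: float, d: float) -> float:
    """Branch length g with compose_divergence(g, d) == total."""
    g = (total - d) / (1.0 - (4.0 / 3.0) * d)
    if g < 0:
        raise ConfigError(f"divergence {total} unreachable past branch {d}")
    return g


@dataclass
class SwitchRates:
    """Per-allele synonymous codon-preference switch probabilities per codon,
    loosely calibrated to the observed per-1000-codon excess of 2-3."""

    mat_A_pr_to_npr: float = 0.0054
    mat_A_npr_to_pr: float = 0.0028
    mat_a_pr_to_npr: float = 0.0046
    mat_a_npr_to_pr: float = 0.0028

    def for_allele(self, allele: str) -> tuple[float, float]:
        if allele == "mat_A":
            return self.mat_A_pr_to_npr, self.mat_A_npr_to_pr
        if allele == "mat_a":
            return self.mat_a_pr_to_npr, self.mat_a_npr_to_pr
        raise KeyError(allele)


@dataclass
class LineageTree:
    """Rooted topology (outgroup, (L1, L4, L9)) with expected substitutions
    per site on each branch; allele branches are derived from the configured
    intra-lineage divergence."""

    outgroup: float = 0.016
    stem: float = 0.0158
    lineages: dict[str, float] = field(
        default_factory=lambda: {"L1": 0.0085, "L4": 0.0095, "L9": 0.0082}
    )


@dataclass
class Centromere:
    start: int = 7_050_000
    end: int = 7_350_000
    gc_level: float = 0.46
    missing_fraction: float = 0.10


@dataclass
class SimulationConfig:
    """All generator knobs; defaults reproduce the study-like scenario:
    an 8 Mbp mat chromosome whose central ~75% is elevated and ~72% is an
    introgression tract, plus a 1 Mbp autosome."""

    seed: int = 0
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {"LGI": 8_000_000, "LGII": 1_000_000}
    )
    mat_chromosome: str = "LGI"
    lineage_tree: LineageTree = field(default_factory=LineageTree)
    intra_lineage_autosome_divergence: float = 0.0045
    central_region: tuple[int, int] = (900_000, 6_900_000)
    central_divergence: float = 0.024
    #: observed divergence of each (non-introgressed) allele to the outgroup
    #: inside the central region
    central_reference_divergence: float = 0.034
    tract: tuple[int, int] = (1_100_000, 6_900_000)
    donor_branch_length: float = 0.027
    centromere: Centromere = field(default_factory=Centromere)
    background_gc: float = 0.52
    gap_fraction: float = 0.2
    n_genes: int = 543
    n_autosome_genes: int = 50
    gene_length_codons: int = 520
    preferred_fraction: float = 0.65
    switch_rates: SwitchRates = field(default_factory=SwitchRates)
    nonsyn_rate: float = 0.003

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    def validate(self) -> None:
        for chrom, length in self.chromosome_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {chrom!r} has non-positive length")
        if self.mat_chromosome not in self.chromosome_lengths:
            raise ConfigError(f"mat chromosome {self.mat_chromosome!r} undeclared")
        mat_len = self.chromosome_lengths[self.mat_chromosome]
        c0, c1 = self.central_region
        t0, t1 = self.tract
        if not (0 <= c0 <= c1 <= mat_len):
            raise ConfigError("central_region outside the mat chromosome")
        if not (c0 <= t0 <= t1 <= c1):
            raise ConfigError("tract must nest inside central_region")
        if not (0 <= self.centromere.start <= self.centromere.end <= mat_len):
            raise ConfigError("centromere outside the mat chromosome")
        rates = [
            self.intra_lineage_autosome_divergence,
            self.central_divergence,
            self.central_reference_divergence,
            self.donor_branch_length,
            self.gap_fraction,
            self.preferred_fraction,
            self.nonsyn_rate,
            self.centromere.gc_level,
            self.centromere.missing_fraction,
            self.background_gc,
            *vars(self.switch_rates).values(),
            self.lineage_tree.outgroup,
            self.lineage_tree.stem,
            *self.lineage_tree.lineages.values(),
        ]
        for r in rates:
            if not (0.0 <= r <= 1.0):
                raise ConfigError(f"rate {r} outside [0, 1]")
        if self.gap_fraction >= 1.0:
            raise ConfigError("gap_fraction must be < 1")
        if self.n_genes < 0 or self.n_autosome_genes < 0 or self.gene_length_codons < 1:
            raise ConfigError("gene counts must be >= 0 and gene length >= 1 codon")


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated dataset."""

    regions: dict[str, tuple[int, int]]  # PA1 / central / PA2 / tract (trimmed bp)
    realized_divergences: dict[str, dict[str, float]]
    codon_switch_counts: dict[str, dict]
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "regions": {k: list(v) for k, v in self.regions.items()},
            "realized_divergences": self.realized_divergences,
            "codon_switch_counts": self.codon_switch_counts,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {k: tuple(v) for k, v in payload["regions"].items()},
            payload["realized_divergences"],
            payload["codon_switch_counts"],
            payload["seed"],
        )


@dataclass
class SimulatedDataset:
    alignment: GenomeAlignment  # original space, gap columns planted
    core_alignment: GenomeAlignment  # trimmed space (gap-free)
    genes: list[Gene]  # trimmed-space coordinates
    codon_table: PreferredCodonTable
    truth: TruthSet
    config: SimulationConfig


# ---------------------------------------------------------------------------
# low-level helpers (base-index space: A=0 C=1 G=2 T=3, N=4)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _mutate(rng: np.random.Generator, seq: np.ndarray, d: float) -> np.ndarray:
    """Independently substitute each site with probability d (to a uniformly
    chosen different base); returns a new array."""
    out = seq.copy()
    if d <= 0:
        return out
    hit = np.flatnonzero(rng.random(seq.shape[0]) < d)
    out[hit] = (out[hit] + rng.integers(1, 4, size=hit.shape[0], dtype=np.uint8)) % 4
    return out


def _codon_bases(codon: str) -> list[int]:
    return ["ACGT".index(c) for c in codon]


class _CodonSampler:
    """Samples outgroup codons and applies per-allele switch/nonsyn events."""

    def __init__(self, table: PreferredCodonTable):
        self.table = table
        self.by_aa: dict[str, list[str]] = {}
        for codon in SENSE_CODONS:
            self.by_aa.setdefault(GENETIC_CODE[codon], []).append(codon)
        self.aas = sorted(self.by_aa)
        self.pr = {aa: [c for c in cs if table.status[c] == PR] for aa, cs in self.by_aa.items()}
        self.npr = {aa: [c for c in cs if table.status[c] == NPR] for aa, cs in self.by_aa.items()}
        self.other_aa_codons = {
            aa: [c for c in SENSE_CODONS if GENETIC_CODE[c] != aa] for aa in self.aas
        }

    def sample_outgroup(
        self, rng: np.random.Generator, n: int, preferred_fraction: float
    ) -> list[str]:
        aa_idx = rng.integers(0, len(self.aas), size=n)
        prefer = rng.random(n) < preferred_fraction
        choice = rng.random(n)
        out = np.empty(n, dtype="<U3")
        for a, aa in enumerate(self.aas):
            mask = aa_idx == a
            use_pr = mask & (prefer | (len(self.npr[aa]) == 0))
            for pool, sel in ((self.pr[aa], use_pr), (self.npr[aa], mask & ~use_pr)):
                if pool and sel.any():
                    idx = (choice[sel] * len(pool)).astype(int)
                    out[sel] = np.asarray(pool, dtype="<U3")[idx]
        return out.tolist()

    def derive_allele(
        self,
        rng: np.random.Generator,
        outgroup: list[str],
        pr_to_npr: float,
        npr_to_pr: float,
        nonsyn_rate: float,
    ) -> list[str]:
        """Apply nonsynonymous and synonymous-switch events to a copy of the
        outgroup codon sequence (events are mutually exclusive per codon)."""
        n = len(outgroup)
        u = rng.random(n)
        pick = rng.random(n)
        out = list(outgroup)
        # events are rare; only visit codons whose draw can trigger one
        thresh = nonsyn_rate + max(pr_to_npr, npr_to_pr)
        for i in np.flatnonzero(u < thresh):
            codon = outgroup[i]
            aa = GENETIC_CODE.get(codon)
            if aa is None:  # background evolution can create a stop codon
                continue
            if u[i] < nonsyn_rate:
                pool = self.other_aa_codons[aa]
                out[i] = pool[int(pick[i] * len(pool))]
                continue
            if self.table.status[codon] == PR:
                pool = self.npr[aa]
                rate = pr_to_npr
            else:
                pool = self.pr[aa]
                rate = npr_to_pr
            if pool and u[i] < nonsyn_rate + rate:
                out[i] = pool[int(pick[i] * len(pool))]
        return out


def count_codon_patterns(
    nc: list[str], mat_a: list[str], mat_A: list[str], table: PreferredCodonTable
) -> dict:
    """Straightforward per-codon pattern bookkeeping over codon strings.

    This is the generator-side truth accounting (dictionary lookups over codon
    strings), deliberately a separate code path from the vectorised
    classifier in :mod:`introscan.codons`.
    """
    counts = {
        "mat_a": {"pr_to_npr": 0, "npr_to_pr": 0},
        "mat_A": {"pr_to_npr": 0, "npr_to_pr": 0},
        "n_excluded_missing": 0,
        "n_excluded_nonsyn": 0,
        "n_uninformative": 0,
        "total_codons": len(nc),
    }
    # amino acid per codon; '*' marks stops, absence marks ambiguous bases
    aa_of = dict(GENETIC_CODE)
    for stop in ("TAA", "TAG", "TGA"):
        aa_of[stop] = "*"
    patterns: dict[str, int] = {}
    for c_nc, c_a, c_A in zip(nc, mat_a, mat_A):
        a0, a1, a2 = aa_of.get(c_nc), aa_of.get(c_a), aa_of.get(c_A)
        if a0 is None or a1 is None or a2 is None:
            counts["n_excluded_missing"] += 1
            continue
        if "*" in (a0, a1, a2) or a0 != a1 or a0 != a2:
            counts["n_excluded_nonsyn"] += 1
            key = "nonsyn"
        else:
            sts = [table.status[c_nc], table.status[c_a], table.status[c_A]]
            key = "/".join(sts)
            if sts == [PR, NPR, PR]:
                counts["mat_a"]["pr_to_npr"] += 1
            elif sts == [NPR, PR, NPR]:
                counts["mat_a"]["npr_to_pr"] += 1
            elif sts == [PR, PR, NPR]:
                counts["mat_A"]["pr_to_npr"] += 1
            elif sts == [NPR, NPR, PR]:
                counts["mat_A"]["npr_to_pr"] += 1
            else:
                counts["n_uninformative"] += 1
        patterns[key] = patterns.get(key, 0) + 1
    counts["patterns"] = patterns
    counts["n_analyzed"] = (
        counts["total_codons"] - counts["n_excluded_missing"] - counts["n_excluded_nonsyn"]
    )
    return counts


def _codons_to_idx(codons: list[str]) -> np.ndarray:
    flat = "".join(codons)
    arr = np.frombuffer(flat.encode(), dtype=np.uint8)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    return lut[arr].reshape(-1, 3)


def simulate_codon_alignment(
    config: SimulationConfig, table: PreferredCodonTable | None = None
) -> tuple[dict[str, np.ndarray], dict]:
    """Simulate the outgroup/mat_A/mat_a codon alignment alone.

    Returns ``(codons, truth)`` where ``codons`` maps ``NC``, ``mat_A`` and
    ``mat_a`` to ``(n, 3)`` base-index arrays and ``truth`` records the
    per-pattern counts of the emitted codons (summing to
    ``n_genes * gene_length_codons``).
    """
    config.validate()
    table = table or default_preferred_table()
    rng = np.random.default_rng(config.seed)
    sampler = _CodonSampler(table)
    n = config.n_genes * config.gene_length_codons
    nc = sampler.sample_outgroup(rng, n, config.preferred_fraction)
    a_rates = config.switch_rates.for_allele("mat_a")
    A_rates = config.switch_rates.for_allele("mat_A")
    mat_a = sampler.derive_allele(rng, nc, *a_rates, config.nonsyn_rate)
    mat_A = sampler.derive_allele(rng, nc, *A_rates, config.nonsyn_rate)
    truth = count_codon_patterns(nc, mat_a, mat_A, table)
    codons = {
        "NC": _codons_to_idx(nc),
        "mat_a": _codons_to_idx(mat_a),
        "mat_A": _codons_to_idx(mat_A),
    }
    return codons, truth


# ---------------------------------------------------------------------------
# gene placement


def _place_genes(
    rng: np.random.Generator,
    chrom: str,
    interval: tuple[int, int],
    n_genes: int,
    span: int,
    prefix: str,
    pad: int = 20_000,
) -> list[Gene]:
    """Place non-overlapping forward-strand genes inside an interval, evenly
    slotted with random jitter; padded away from the interval ends so gene
    content does not sit on region boundaries."""
    if n_genes == 0:
        return []
    lo, hi = interval[0] + pad, interval[1] - pad
    slot = (hi - lo) // n_genes
    if slot < span:
        raise ConfigError(
            f"cannot place {n_genes} genes of {span} bp in [{lo}, {hi})"
        )
    genes = []
    jitter = rng.integers(0, slot - span + 1, size=n_genes)
    for i in range(n_genes):
        start = lo + i * slot + int(jitter[i])
        genes.append(Gene(chrom, start, start + span, f"{prefix}{i:04d}", "+"))
    return genes


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(
    config: SimulationConfig, table: PreferredCodonTable | None = None
) -> SimulatedDataset:
    """Generate the seven-genome alignment, gene annotations and truth set."""
    config.validate()
    table = table or default_preferred_table()
    rng = np.random.default_rng(config.seed)
    tree = config.lineage_tree
    mat = config.mat_chromosome
    c0, c1 = config.central_region
    t0, t1 = config.tract

    # gene layout + outgroup codon content (planted into the root ancestor)
    span = 3 * config.gene_length_codons
    genes = _place_genes(rng, mat, (t0, t1), config.n_genes, span, "tract_g")
    autosomes = [c for c in config.chromosome_lengths if c != mat]
    if autosomes and config.n_autosome_genes:
        genes += _place_genes(
            rng, autosomes[0], (0, config.chromosome_lengths[autosomes[0]]),
            config.n_autosome_genes, span, "auto_g",
        )
    sampler = _CodonSampler(table)

    d_auto = split_branch(config.intra_lineage_autosome_divergence)
    d_central = split_branch(config.central_divergence)
    g_central = residual_branch(config.central_reference_divergence, d_central)

    # root ancestors with GC structure and planted gene content
    roots: dict[str, np.ndarray] = {}
    for chrom, length in config.chromosome_lengths.items():
        root = _random_sequence(rng, length, config.background_gc)
        if chrom == mat and config.centromere.end > config.centromere.start:
            cen = config.centromere
            root[cen.start:cen.end] = _random_sequence(
                rng, cen.end - cen.start, cen.gc_level
            )
        roots[chrom] = root
    gene_outgroup_codons: dict[str, list[str]] = {}
    for gene in genes:
        codons = sampler.sample_outgroup(
            rng, config.gene_length_codons, config.preferred_fraction
        )
        gene_outgroup_codons[gene.name] = codons
        roots[gene.chromosome][gene.start:gene.end] = _codons_to_idx(codons).reshape(-1)

    # branch evolution
    seqs: dict[str, dict[str, np.ndarray]] = {s: {} for s in SAMPLES}
    for chrom, root in roots.items():
        nc = _mutate(rng, root, tree.outgroup)
        anc = _mutate(rng, root, tree.stem)
        seqs["NC"][chrom] = nc
        for lineage in LINEAGES:
            lin = _mutate(rng, anc, tree.lineages[lineage])
            seqs[f"{lineage}A"][chrom] = _mutate(rng, lin, d_auto)
            seqs[f"{lineage}a"][chrom] = _mutate(rng, lin, d_auto)

    # central region: independent allele evolution from a lineage-specific
    # ancestor placed at the configured distance from the outgroup
    nc_central = seqs["NC"][mat][c0:c1]
    for lineage in LINEAGES:
        central_anc = _mutate(rng, nc_central, g_central)
        seqs[f"{lineage}A"][mat][c0:c1] = _mutate(rng, central_anc, d_central)
        seqs[f"{lineage}a"][mat][c0:c1] = _mutate(rng, central_anc, d_central)

    # introgression: copy a donor-derived segment over each mat-a tract
    nc_tract = seqs["NC"][mat][t0:t1]
    for lineage in LINEAGES:
        donor = _mutate(rng, nc_tract, config.donor_branch_length)
        seqs[f"{lineage}a"][mat][t0:t1] = donor

    # allele-specific codon switches in tract genes, relative to the emitted
    # outgroup state; truth patterns are recounted from the final codons
    tract_genes = [g for g in genes if g.chromosome == mat]
    switch_counts: dict[str, dict] = {}
    for lineage in LINEAGES:
        final = {"NC": [], "mat_a": [], "mat_A": []}
        for gene in tract_genes:
            nc_codons = _idx_to_codons(seqs["NC"][mat][gene.start:gene.end])
            for allele, sample in (("mat_A", f"{lineage}A"), ("mat_a", f"{lineage}a")):
                p_sw, p_bk = config.switch_rates.for_allele(allele)
                derived = sampler.derive_allele(
                    rng, nc_codons, p_sw, p_bk, config.nonsyn_rate
                )
                # overlay events on top of the evolved background: switched
                # codons replace the background codon, untouched codons keep it
                bg = _idx_to_codons(seqs[sample][mat][gene.start:gene.end])
                emitted = [d if d != o else b for d, o, b in zip(derived, nc_codons, bg)]
                seqs[sample][mat][gene.start:gene.end] = _codons_to_idx(emitted).reshape(-1)
                final[allele].extend(emitted)
            final["NC"].extend(nc_codons)
        if tract_genes:
            switch_counts[lineage] = count_codon_patterns(
                final["NC"], final["mat_a"], final["mat_A"], table
            )

    # missing data in the centromere of the six ingroup genomes
    cen = config.centromere
    if cen.end > cen.start and cen.missing_fraction > 0:
        for sample in SAMPLES[1:]:
            seg = seqs[sample][mat][cen.start:cen.end]
            seg[rng.random(seg.shape[0]) < cen.missing_fraction] = _N_IDX

    # core (trimmed-space) alignment in ASCII
    core = GenomeAlignment(
        list(SAMPLES),
        {
            chrom: np.stack([_IDX_TO_ASCII[seqs[s][chrom]] for s in SAMPLES])
            for chrom in config.chromosome_lengths
        },
        coordinate_space="trimmed",
    )

    truth = TruthSet(
        regions={
            "PA1": (0, c0),
            "central": (c0, c1),
            "PA2": (c1, config.chromosome_lengths[mat]),
            "tract": (t0, t1),
        },
        realized_divergences=_realized_divergences(core, config),
        codon_switch_counts=switch_counts,
        seed=config.seed,
    )

    original = _plant_gap_columns(rng, core, config.gap_fraction, config.background_gc)
    return SimulatedDataset(original, core, genes, table, truth, config)


def _idx_to_codons(idx: np.ndarray) -> list[str]:
    s = _IDX_TO_ASCII[idx].tobytes().decode()
    return [s[i:i + 3] for i in range(0, len(s), 3)]


def _realized_divergences(
    core: GenomeAlignment, config: SimulationConfig
) -> dict[str, dict[str, float]]:
    from .divergence import pairwise_divergence

    mat = config.mat_chromosome
    out: dict[str, dict[str, float]] = {}
    intra_pairs = [(f"{l}A", f"{l}a") for l in LINEAGES]
    for chrom in core.chromosome_names:
        d = {}
        for x, y in intra_pairs:
            d[f"{x}-{y}"] = pairwise_divergence(core, chrom, x, y).value
        out[chrom] = d
    regions = {
        "central": config.central_region,
        "tract": config.tract,
        "PA1": (0, config.central_region[0]),
        "PA2": (config.central_region[1], core.length(mat)),
    }
    reg = {}
    for name, (s, e) in regions.items():
        if e <= s:
            continue
        for x, y in intra_pairs:
            reg[f"{name}:{x}-{y}"] = pairwise_divergence(core, mat, x, y, (s, e)).value
        for l in LINEAGES:
            reg[f"{name}:{l}a-NC"] = pairwise_divergence(core, mat, f"{l}a", "NC", (s, e)).value
            reg[f"{name}:{l}A-NC"] = pairwise_divergence(core, mat, f"{l}A", "NC", (s, e)).value
    out[f"{mat}:regions"] = reg
    return out


def _plant_gap_columns(
    rng: np.random.Generator, core: GenomeAlignment, fraction: float, gc: float
) -> GenomeAlignment:
    """Insert gap columns so they make up ``fraction`` of the emitted original
    alignment; each gap column gets '-' in one random sample and random bases
    elsewhere, so trimming removes exactly the planted columns."""
    n_samples = len(core.sample_ids)
    chroms: dict[str, np.ndarray] = {}
    for chrom, arr in core.chromosomes.items():
        L = arr.shape[1]
        if fraction <= 0:
            chroms[chrom] = arr.copy()
            continue
        n_gap = int(round(L * fraction / (1.0 - fraction)))
        total = L + n_gap
        gap_pos = np.sort(rng.choice(total, size=n_gap, replace=False))
        keep = np.ones(total, dtype=bool)
        keep[gap_pos] = False
        out = np.empty((n_samples, total), dtype=np.uint8)
        out[:, keep] = arr
        filler = np.stack(
            [_IDX_TO_ASCII[_random_sequence(rng, n_gap, gc)] for _ in range(n_samples)]
        )
        out[:, gap_pos] = filler
        which = rng.integers(0, n_samples, size=n_gap)
        out[which, gap_pos] = ord("-")
        chroms[chrom] = out
    return GenomeAlignment(list(core.sample_ids), chroms, coordinate_space="original")


def replicate_config(seed: int, base: SimulationConfig | None = None) -> SimulationConfig:
    """Study-condition replicate: the default scenario with per-seed truth
    boundaries jittered on the 10 kb fine grid (0-40 kb into the boundary
    coarse section, same offset on both the central and tract boundary of
    each side, so boundaries stay on the coarse tiling used by the stepwise
    caller — change points deeper inside a coarse section are unresolvable by
    the refinement procedure by construction)."""
    base = base or SimulationConfig()
    rng = np.random.default_rng(seed)
    left = 10_000 * int(rng.integers(0, 5))
    right = 10_000 * int(rng.integers(0, 5))
    c0, c1 = base.central_region
    t0, t1 = base.tract
    return replace(
        base,
        seed=seed,
        central_region=(c0 + left, c1 - right),
        tract=(t0 + left, t1 - right),
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA (original space), gene BED, codon table TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = write_alignment(ds.alignment, outdir)
    bed = outdir / "genes.bed"
    write_genes_bed(ds.genes, bed)
    tab = outdir / "preferred_codons.tsv"
    write_preferred_table(ds.codon_table, tab)
    truth = outdir / "truth.json"
    ds.truth.to_json(truth)
    paths.update({"genes": bed, "codon_table": tab, "truth": truth})
    return paths
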