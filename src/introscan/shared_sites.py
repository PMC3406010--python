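"""Shared-nucleotide test: site-pattern counts for genome triples and the
exact binomial sign test.

For an ordered triple (X, Y, Z) the informative patterns are the sites where
X uniquely matches Z (``X = Z != Y``) versus where Y uniquely matches Z
(``Y = Z != X``).  Under a shared history the two counts are symmetric; an
excess of one pattern inside a region indicates that the corresponding genome
is closer to Z there, as expected after introgression from (a relative of) Z.
Significance is assessed with a two-sided exact binomial test at p = 0.5,
two-sidedness by the minimum-likelihood rule (summing all outcomes whose
probability does not exceed the observed outcome's).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import binomtest

from .alignment import GAP, MISSING, GenomeAlignment


@dataclass
class SharedSiteCounts:
    triple: tuple[str, str, str]  # (X, Y, Z)
    chromosome: str
    start: int
    end: int
    n_xz: int  # sites with X = Z != Y
    n_yz: int  # sites with Y = Z != X
    n_informative_other: int  # differing sites matching neither pattern
    n_compared: int  # sites unambiguous in all three samples
    identity_xz: float
    identity_yz: float


@dataclass
class SignTestResult:
    k: int
    n: int
    p_value: float
    defined: bool = True


def count_shared_patterns(
    aln: GenomeAlignment,
    sample_x: str,
    sample_y: str,
    sample_z: str,
    chrom: str,
    region: tuple[int, int] | None = None,
) -> SharedSiteCounts:
    """Count uniquely-shared-nucleotide site patterns for (X, Y, Z) in a region.

    Sites with ``N`` (or a residual gap) in any of the three samples are
    excluded from every count.  Identities are computed over all compared
    sites: ``identity_xz = 1 - divergence(X, Z)`` on the three-way-comparable
    sites.
    """
    if len({sample_x, sample_y, sample_z}) != 3:
        raise ValueError("the three samples must be distinct")
    start, end = region if region is not None else (0, aln.length(chrom))
    if not (0 <= start <= end <= aln.length(chrom)):
        raise IndexError(f"region [{start}, {end}) out of bounds on {chrom!r}")
    x = aln.sequence(chrom, sample_x)[start:end]
    y = aln.sequence(chrom, sample_y)[start:end]
    z = aln.sequence(chrom, sample_z)[start:end]

    valid = (
        (x != MISSING) & (y != MISSING) & (z != MISSING)
        & (x != GAP) & (y != GAP) & (z != GAP)
    )
    xz = valid & (x == z) & (x != y)
    yz = valid & (y == z) & (y != x)
    any_diff = valid & ~((x == y) & (y == z))
    other = any_diff & ~xz & ~yz

    n_compared = int(valid.sum())
    n_xz_diff = int((valid & (x != z)).sum())
    n_yz_diff = int((valid & (y != z)).sum())
    identity_xz = 1.0 - n_xz_diff / n_compared if n_compared else float("nan")
    identity_yz = 1.0 - n_yz_diff / n_compared if n_compared else float("nan")
    return SharedSiteCounts(
        (sample_x, sample_y, sample_z), chrom, start, end,
        int(xz.sum()), int(yz.sum()), int(other.sum()), n_compared,
        identity_xz, identity_yz,
    )


def binomial_sign_test(k: int, n: int) -> SignTestResult:
    """Two-sided exact binomial sign test of k successes in n trials at p = 0.5."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    p = binomtest(k, n, p=0.5, alternative="two-sided").pvalue
    return SignTestResult(k, n, min(float(p), 1.0))


def shared_site_test(counts: SharedSiteCounts) -> SignTestResult:
    """Sign test of the two uniquely-shared pattern counts against symmetry."""
    n = counts.n_xz + counts.n_yz
    if n == 0:
        return SignTestResult(0, 0, float("nan"), defined=False)
    return binomial_sign_test(counts.n_xz, n)
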