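# Methods

## Statistical model of the analysis

All statistics operate on a multi-genome alignment in reference coordinates:
one sequence per haploid genome over `{A, C, G, T, N, -}`, equal lengths per
chromosome.  `N` marks missing consensus data (uncovered reference
positions) and is handled per comparison; `-` marks an alignment gap and is
handled once, by removing every column that contains at least one gap before
any statistic is computed.  Trimming is per chromosome and idempotent; a
strictly increasing column map preserves the trimmed → original
correspondence (serialised as run-length JSON).  All intervals everywhere
are 0-based half-open; BED output is native, human-readable reports add
1-based display.

**Divergence** is the raw fraction of differing sites among sites where both
samples have an unambiguous base.  No multiple-hit correction is applied:
the divergences of interest are below 5%, where the correction is smaller
than the sampling noise.  Windows start at 0 and advance by the step; the
terminal window is truncated and reported (flagged by `min_sites`, default
1000, when too few sites are comparable).  Defaults: 500 kb / 100 kb for
divergence, 100 kb / 20 kb for GC.

**Stepwise demarcation** tiles the chromosome into non-overlapping coarse
sections (100 kb).  A section is *elevated* when its divergence strictly
exceeds the cutoff (1%, chosen against the ~0.46% autosomal background);
a value exactly at the cutoff is not elevated.  The central region is the
longest contiguous run of elevated sections — isolated outlier sections
outside the run are reported as diagnostics but never split the region — and
each boundary is refined by scanning the run's outermost coarse section at
fine (10 kb) resolution from the outside inward, placing the boundary at the
first fine section that meets the criterion.  Sections with too few
comparable sites inherit the preceding section's state and are flagged.
Only the run's two boundary sections are refined: a change point deeper than
~70 kb inside a coarse section flips that section's mean below the cutoff
and is therefore unresolvable by this procedure by construction (a known
limitation of the stepwise approach, not of this implementation).

**Tract calling** uses the same coarse→fine scheme inside the central
region (tiled from the region's start so the tract nests within it) with a
relative criterion: a section is introgressed when
`d(query, reference) + margin < d(partner, reference)`.  The margin defaults
to 0 (strict inequality) on `DemarcationConfig`; the pipeline and the
replicate analyses use `margin = 0.003`.  Rationale: outside a tract the two
allele-vs-reference divergences are equal in expectation and their
difference is driven only by the two independent allele branches, giving a
standard deviation of ≈5×10⁻⁴ per 100 kb section (≈1.5×10⁻³ per 10 kb) at
the divergences studied here.  With margin 0 the sections flanking a tract
are coin flips, which corrupts boundary refinement; 0.003 is more than two
standard deviations of fine-section noise yet less than half the ≈0.007
divergence contrast a donor-derived tract produces, so it suppresses the
noise without eroding the signal.

**Shared-nucleotide test.**  For an ordered triple (X, Y, Z) and a region,
sites with `N` in any sequence are excluded; the informative patterns are
X = Z ≠ Y and Y = Z ≠ X (sites where all three differ, or where X = Y ≠ Z,
enter neither count).  Identities are 1 − divergence over all three-way
comparable sites.  The two pattern counts are tested for symmetry with the
exact binomial test at p = ½, two-sided by the minimum-likelihood rule
(summing the probabilities of all outcomes no more likely than the observed
one); this is the construction `scipy.stats.binomtest` implements.  Note
that discreteness makes the exact test conservative: at n = 200 its exact
size at α = 0.05 is 0.0400, and empirical rejection rates under the null
should be compared against that size, not against the nominal α.

**Codon degeneration.**  A preferred-codon table assigns each of the 61
sense codons a PR/NPR status consistent with the standard genetic code;
every degenerate family must contain a preferred codon, and single-codon
amino acids are PR by convention.  Genes (BED, trimmed coordinates) fully
inside the analysis region and complete (no `N`, no gap) in every sample are
concatenated in coordinate order, reverse-strand genes reverse-complemented
into frame.  Per aligned codon the exclusion order is: missing data first,
then nonsynonymous change (the three translations not identical, or any
stop codon).  The remaining codons are classified by the PR/NPR status
triple (NC, mat a, mat A): a switch is attributed to an allele only when the
partner retains the outgroup status — (PR, NPR, PR) is a mat-a PR→NPR
switch, (PR, PR, NPR) a mat-A PR→NPR switch, and so on; both-derived
configurations are uninformative.  Classification is by whole-codon status,
not per-nucleotide steps, so multi-position synonymous differences in
six-fold families count once.  Per allele, E = n(PR→NPR) − n(NPR→PR) and
F = E/T × 1000 where T is the count of analysed (non-excluded) codons; F is
displayed half-up at two decimals, unrounded values are kept internally.
Sign tests: per allele k = n(PR→NPR) of all switches (net accumulation);
between alleles k = E(mat A) of E(mat A) + E(mat a), defined only when both
excesses are non-negative.

## The synthetic-data generator

The generator emulates the product of reference-mapped consensus calling for
seven haploid genomes — an outgroup NC plus three lineages × two mating
types — with the structure the analysis assumes.  Its defaults are the study
conditions and were fixed before any test outcome was inspected:

| parameter | default | meaning |
|---|---|---|
| chromosome_lengths | LGI 8 Mbp, LGII 1 Mbp | gap-free (core) lengths |
| intra_lineage_autosome_divergence | 0.0045 | observed mat-A/mat-a divergence outside the central region |
| central_region | [0.9, 6.9) Mbp | suppressed-recombination region (75% of LGI) |
| central_divergence | 0.024 | observed allele divergence inside the central region |
| central_reference_divergence | 0.034 | each allele vs NC inside the central region |
| tract | [1.1, 6.9) Mbp | donor-derived segment on mat-a (72.5% of LGI) |
| donor_branch_length | 0.027 | donor vs NC observed divergence |
| lineage_tree | 0.016/0.0158 stem, 0.0082–0.0095 per lineage | places inter-lineage ≈2% and outgroup ≈4.2% autosomal divergence |
| background_gc / centromere gc | 0.52 / 0.46 | GC structure; centromere [7.05, 7.35) Mbp |
| centromere missing_fraction | 0.10 | `N` density in the six ingroup genomes |
| gap_fraction | 0.20 | planted gap columns (fraction of the emitted original alignment) |
| n_genes × gene_length_codons | 543 × 520 | in-frame tract genes (≈282 k codons) |
| switch_rates | 0.0054/0.0028 (mat A), 0.0046/0.0028 (mat a) | PR→NPR / NPR→PR event probability per codon |
| nonsyn_rate | 0.003 | nonsynonymous-change probability per codon |

Substitutions follow a Jukes–Cantor-like per-site scheme: each site on a
branch substitutes independently with probability equal to the branch length,
to a uniformly chosen different base.  Because the analysis applies no
multiple-hit correction, branch pairs that must realise a configured
*observed* divergence D are solved from the two-branch composition
D = d₁ + d₂ − (4/3)d₁d₂ (the naive D/2 split would bias an 8 Mbp central
region by about one standard error).  Elevated central divergence is
produced by independent evolution of both alleles from a lineage-specific
central ancestor placed at the configured distance from NC; the tract is
implanted by copying a donor sequence (evolved from NC) over the mat-a
interval after evolution, modelling backcross replacement.  Gaps are planted
as whole columns (one random sample gapped per column) *around* the core
sequence, so trimming recovers the core byte-exactly; consequently all
configured intervals, the gene BED and the truth set live in trimmed
coordinates, which is also the space in which results are reported.

Gene content is planted into the root ancestor as sampled sense codons
(amino acid uniform, preferred with probability `preferred_fraction`), then
inherits the normal branch evolution; allele-specific PR↔NPR switch and
nonsynonymous events are applied last, against the *emitted* NC state.
Truth bookkeeping recounts the final emitted codons with a deliberately
separate, dictionary-based code path from the vectorised classifier, so
classifier-equals-truth is a meaningful check.  Background substitutions
inside genes also create switch patterns — as they do in real data — so
realized switch counts exceed the configured event rates; the configured
rates control only the event layer.  The default preferred-codon table is
synthetic (one preferred codon per degenerate family, C-ending preference,
mimicking Neurospora's C-ending bias); real analyses must supply the
organism's measured table.

What the generator does **not** emulate: indel evolution (gap columns are
planted, not evolved), rearrangements/inversions (sequence content only —
the downstream stages consume no synteny), coalescent variation in local
ancestry, rate heterogeneity along the chromosome, and sequencing error.
Passing tests therefore demonstrate correctness of the statistics and the
demarcation logic under the stated divergence regime, not robustness to
alignment error or assembly artefacts in real data.

The replicate generator used for boundary-recovery measurements jitters the
central and tract boundaries per seed by 0–40 kb on the 10 kb fine grid,
applying the same offset to the central and tract boundary on each side.
This keeps each true change point within the resolvable ≤40 kb leading part
of its coarse section (see the demarcation limitation above) while still
exercising refinement at non-trivial offsets.

## Numerical and design choices

- Divergence counting, pattern counting and codon classification are
  vectorised over `uint8` arrays; window sums use cumulative sums, so scans
  are O(L) per pair.
- Ambiguity codes other than `N` are rejected at read time with the file
  position named.
- Empty or sparse windows/sections are flagged, never silently dropped;
  undefined sections inherit the preceding label during demarcation.
- Ties at the demarcation cutoff count as not elevated (strict `>`); the
  longest-run rule breaks ties toward the first run.
- The codon analysis region in the pipeline is the intersection of the
  per-lineage tract calls (the region introgressed in every lineage).
- Reproducibility: a single `numpy` Generator seeded from the config drives
  every draw; rerunning any stage or the whole pipeline with the same config
  and seed yields byte-identical files (the run manifest records the seed
  and a config hash, deliberately no timestamps).
- Problem sizes in the shipped analyses: 20 replicate 8 Mbp chromosomes for
  boundary recovery, one 4 Mbp gene-free chromosome for divergence
  calibration, 2,000 draws at n = 200 for sign-test size, 10,000 codons for
  classifier agreement — large enough that 3-SE checks are meaningful, small
  enough to run comfortably on one CPU.

## Known limitations

- The stepwise demarcation cannot resolve change points deep inside a coarse
  section (inherent to the published procedure; an HMM/changepoint model
  would, but is out of scope).
- The closest-relative tract criterion needs a non-introgressed reference;
  if the reference itself shares the donor's ancestry the tract is missed.
- With margin 0 the tract caller is noise-dominated at tract edges; use a
  margin calibrated to section size and divergence (see above).
- The between-allele degeneration test is undefined when either allele shows
  a net NPR→PR excess; it is reported as flagged rather than forced.
- Real-data use requires the organism's preferred-codon table and gene
  annotations lifted into trimmed coordinates.
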