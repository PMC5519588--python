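# Methods

## Per-locus delimitation (haplowebs)

Each locus is an alignment of phased alleles: every individual present
carries exactly two sequences (alleles 0 and 1). Identical sequences are
collapsed into haplotypes by **exact string equality** — `N` and `-` are
literal characters, so sequences differing only at missing or gap positions
are distinct haplotypes. The alternative (treating `N` as a wildcard and
grouping by compatibility) is deliberately not the default: wildcard
merging is order-dependent and irreproducible unless cliques are resolved,
whereas exact matching is deterministic and errs on the side of splitting,
which only ever weakens, never fabricates, a conspecificity vote.

The haploweb graph has the haplotypes as nodes and one edge per
heterozygous individual between its two haplotypes; homozygotes contribute
no edge but anchor the carrier sets. Allele pools are the connected
components (isolated haplotypes form singleton pools). Both alleles of any
individual necessarily fall in one component — a heterozygote contributes
the very edge that joins them — and this contract is asserted at run time.
Pool ids are dense integers ordered by the smallest haplotype id contained,
so a locus delimitation is a pure function of the alignment.

Loci with a single present individual yield a one-individual pool and cast
no pairwise votes.

## Matrix condensation

For each locus and each unordered pair of co-present individuals: same pool
→ +1, different pools → −1. Scores and co-presence counts accumulate over
loci into the conspecificity matrix `C` with `|C_ij| ≤ copresent_ij` and
`C_ij + copresent_ij` even; both identities are validated on every
construction. Pairs never co-present keep `C = 0` rather than a missing
marker — this is exactly the "near zero against everyone" behaviour of
high-missingness libraries, and it keeps the matrix fully populated for
clustering. The diagonal stores each individual's presence count, a QC
quantity that is excluded from clustering distances.

Invariant loci (whose haploweb has a single pool) vote +1 for all present
pairs by default, matching the matrix-wide accounting of the source
procedure; `--min-pools 2` excludes such loci from both votes and
co-presence counts, as a sensitivity analysis. A `--vote-log` flag writes
the full per-(locus, pair) event stream so any cell can be recounted by
hand.

`--normalize per-pair` divides `C_ij` by `copresent_ij` (range [−1, 1],
NaN where undefined). It is reported alongside, never silently substituted:
the raw signed score is the statistic of record.

## Clustering and partition

The score is a similarity; distances are its min-max complement over
off-diagonal entries, `d_ij = (C_max − C_ij) / (C_max − C_min)`, which is
monotone decreasing in `C` and maps the most conspecific pair to 0 and the
least to 1. A constant off-diagonal (no signal) collapses to all-zero
distances.

Agglomerative clustering is implemented directly rather than delegated:
the published procedure only names a heatmap package whose defaults vary
across versions, so this package fixes its own dialect — UPGMA average
linkage (size-weighted), with ties in merge distance broken by the
lexicographically smallest individual **label** in the candidate clusters.
Label-based (not index-based) tie-breaking is what makes the induced
partition invariant to input row/column permutation; an index-based rule
cannot be, since indices move with the permutation. Complete and single
linkage are available behind `--linkage` for comparison with other heatmap
dialects, and every run records linkage and distance mode in its manifest
and heatmap sidecar. The implementation is cross-checked in the tests
against the UPGMA defining property (each merge height equals the mean raw
distance between the merged leaf sets) and against SciPy's linkage on
distance matrices with unique entries.

Species partitions are obtained by undoing the last `k − 1` merges. `k` is
user-supplied (the reference analysis read groups off the heatmap by eye);
no automatic selection is attempted. Partitions are compared by the
adjusted Rand index (scikit-learn's pair-counting implementation, verified
exhaustively against a brute-force oracle on all partitions of 5 elements)
plus an exact-match flag.

The heatmap reorders the matrix by the dendrogram leaf order, uses a
diverging colour scale symmetric about zero, masks the diagonal (presence
counts would distort the scale), draws the dendrogram on the top margin and
optional per-group boxes along the diagonal, and writes a JSON sidecar with
the plotted leaf order so figure claims are machine-checkable.

## Synthetic data

The generator emulates the statistical structure the analysis assumes in
RAD-seq data from diploid species, not the sequencing process itself. Per
locus: a uniform random ancestral sequence; independent species backbones
(star phylogeny) with Poisson(`d · L`) private substitutions; `a` pool
haplotypes per species, each adding Poisson(`θ · L`) private substitutions;
each individual draws two alleles uniformly with replacement from its
species pool. With probability `ρ` an individual of the designated sister
pair (species 0 and 1) carries one allele drawn from the sister's pool —
the cross-pool heterozygote that merges haploweb pools, i.e. the mechanism
behind an off-diagonal introgression signal. With probability `m` (globally
or per individual) the individual is absent from the locus; absence
overrides introgression. All draws come from one seeded NumPy generator in
a fixed order (locus → species backbones → pool haplotypes → individuals),
so identical config + seed reproduce output byte for byte.

Defaults: `d = 0.03`, `θ = 0.005`, `a = 3`, `L = 120`. At these settings
two species' pools essentially never share a haplotype (each backbone
carries ~3.6 private substitutions on average), while within-species
heterozygosity is common, which is the regime the method expects. The
generator makes no attempt at coalescent realism: no shared tree structure,
no recombination, no indels, no sequencing error. Passing recovery tests
therefore show that the statistic and the pipeline behave correctly when
the data match the method's assumptions; they say nothing about upstream
assembly or phasing quality in real libraries.

The study-shaped preset (`emulate-study`) mirrors the reference design's
shape: 13 individuals in 7 species with sizes (3, 2, 2, 2, 2, 1, 1), 500
loci of 120 bp, 10% missingness, and two designated individuals — the first
member of species 2 and of species 3, both two-member species so congruent
placement is testable — at 95% missingness, standing in for libraries with
very little data.

## Problem sizes and numerical choices

The verification experiments use desk-scale sizes chosen to give the
checks statistical teeth while staying interactive: 1000 random loci for
the delimitation oracle, 200 random datasets for the condensation oracle,
20 seeds for species recovery (15 individuals × 200 loci), 10 seeds each
for the missing-data preset and for the three introgression rates. At
these sizes within-species and cross-species scores differ by hundreds of
votes, so recovery outcomes are far from threshold effects.

Degenerate inputs are handled explicitly: empty files parse to empty
datasets; a matrix with a constant off-diagonal clusters at distance zero;
`normalize per-pair` yields NaN (flagged, not invented) where a pair is
never co-present; clustering requires at least two individuals and says so.
Individuals with a single allele line are an error by default — the votes
assume diploid phasing — and are duplicated only under the explicit
`--tolerate-haploid` flag.

## Known limitations

* Exact-match haplotype identity means alignment errors or unmasked
  ambiguity codes split haplotypes and bias votes toward heterospecificity.
* The signed score is unnormalised by default, so individuals with very
  different presence counts live on different scales; the per-pair
  normalisation is provided but changes the clustering geometry.
* The simulator's star phylogeny cannot produce nested species structure,
  so dendrogram topology above the species level is not a test target.
* `k` must be supplied; the package does not decide how many species exist.
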