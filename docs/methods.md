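# Methods

## The identification model

Cultivated mushroom strains are propagated clonally, so two samples of the
same cultivar should be genomically identical up to assay noise, while
distinct cultivars bred within one lineage differ by a modest number of
substitutions and wild strains differ by far more. mnpkit operationalizes
this with MNP markers: 130-bp windows whose joint SNP haplotype is read as
a single multi-allelic genotype. Compared with single SNPs, a window
containing several SNPs has many more alleles and therefore far more
discriminating power per locus; requiring **two or more** differing SNPs
within the window before a strain pair counts as distinguished also makes a
single sequencing error unable to flip a comparison.

### Discriminative power

For a window and `N` strains, `DP = t / C(N, 2)` with `t` the number of
unordered pairs distinguished by the window. "Dispersed" SNPs are
interpreted as two distinct differing positions at least `min_separation`
bp apart; the default `min_separation = 1` is the weakest reading (any two
distinct positions) and the knob lets users demand wider spacing. Missing
calls never count toward a difference; a pair with fewer than two usable
differing sites contributes false, with no imputation.

The panel is chosen greedily: windows with `DP` strictly above the 0.4
threshold, visited in order of descending DP (ties: ascending start, then
contig), each kept only if it does not overlap an already-kept window.
Published work with this marker system reports a panel without stating an
overlap-resolution rule; greedy highest-DP selection was chosen for
determinism, and marker ids are assigned in genomic order after selection.

The scan uses a per-SNP pairwise-difference matrix with prefix sums, so
each window costs O(1) per pair at the default separation; non-default
separations fall back to a direct per-window count. Both paths are checked
against a brute-force all-pairs oracle in the tests.

### Detection and core markers

A marker is *detected* in a strain when its consensus slice contains no
ambiguous base (`n_max = 1`, i.e. any `N` masks the call) and, when depth
information is supplied, its fold coverage is at least `min_depth = 10`.
Detection is not defined quantitatively in the underlying assay
description, so this operationalization is the package's own; both knobs
are exposed. Core markers are those detected in every strain — GS is only
computed over loci where no strain has missing data, which keeps the
statistic a simple exact fraction `k/M`.

### Genetic similarity and thresholds

`GS = k/M` with `k` the count of core markers whose haplotype strings are
byte-identical (IUPAC ambiguity codes, representing dikaryon
heterozygosity, are legal characters and compare by exact symbol). The
pair-classification thresholds are θ_ped = 0.60 and θ_cv = 0.986, with the
boundary conventions: GS exactly 0.60 means different pedigrees ("less
than or equal to" separates), GS exactly 0.986 still means two cultivars,
and anything strictly above 0.986 is called the same cultivar. Values in
(0.986, 1.0) carry a `near_identity` flag because the interval between the
cultivar ceiling and exact identity is empirically ambiguous; the flag
surfaces such calls instead of hiding them.

Pedigree membership uses single linkage — connected components of the
graph with an edge wherever GS > θ_ped — because the threshold statement
is pairwise, and component closure is the minimal grouping consistent with
it. A complete-linkage mode is provided for users who want every
within-pedigree pair above threshold; on chained similarity structures the
two modes differ, and the choice is reported in the run parameters.
Pedigree labels (G1, G2, ...) order groups by descending size, then by
lexicographically smallest member, so labels are deterministic.

### Neighbor joining

The NJ agglomeration is the classical Saitou–Nei procedure with the
standard two-point branch-length formulas, reduction
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`, and negative branch lengths clamped
to zero (a common convention; the clamp only fires on non-additive
inputs). Ties in the Q criterion break to the lexicographically smallest
index pair in the current node ordering, making the output deterministic.
On additive matrices the tree's path-length matrix reproduces the input to
1e−9 (property-tested against randomly generated trees, and cross-checked
against an independent NJ implementation).

Two distances are offered: `pdist` (default) — per-site mismatch fraction
over concatenated core haplotypes, the closest analogue of building the
tree from the marker sequences — and `gs` (1 − GS), since GS is the
headline statistic. The tree is left unrooted (represented with a
trifurcating root) and serialized as Newick with 6-decimal branch lengths.

`tree_cut_partition(tree, k)` provides the alternative, tree-based route
to pedigrees: branches are removed longest-first to yield `k` leaf
clusters. Internal branches are consumed before pendant branches, and a
cut that would strand a leafless fragment is skipped; pendant branches
must participate because an unrooted binary tree has only `n − 3` internal
edges, which cannot produce `n` singleton clusters. Agreement or
disagreement between the GS-threshold partition and a tree cut at the same
k is surfaced to the user rather than reconciled silently.

## The synthetic cohort generator

`simulate_cohort` emulates the statistical structure the analysis assumes:

| parameter | default | meaning |
|---|---|---|
| `genome_length` | 200,000 bp | one contig; large enough for ~20k windows |
| `n_pedigrees × strains_per_pedigree` | 3 × 4 | cultivar lineages around founders |
| `n_wild` | 5 | independent divergent strains |
| `snp_rate_between_pedigrees` | 8×10⁻³ /bp | founder vs ancestor divergence |
| `snp_rate_within_pedigree` | 5×10⁻⁴ /bp | cultivar vs founder divergence |
| `wild_rate` | 1.2×10⁻² /bp | wild vs ancestor divergence |
| `n_clone_pairs` | 1 | planted same-genome, different-name duplicates |
| `marker_dropout_prob` | 0.05 | per-cell detection failure (non-exempt markers) |

Rates were set so that, per 130-bp window, a within-pedigree pair carries
~0.13 expected differences (haplotype-identity probability ≈ 0.88) while
between-pedigree and wild pairs carry ≥ 2 expected differences (identity
probability ≤ 0.13). Aggregated over dozens to hundreds of core markers
this puts within-pedigree GS far above 0.60 and between-pedigree GS far
below, reproducing the separation regime the thresholds assume — with
enough margin that the planted partition is recovered deterministically at
the default sizes. The rates are configuration, not truth: they emulate a
near-clonal crop with diverse wild relatives, not any particular measured
genome.

Evolution is substitution-only (no indels, no recombination, no
transition/transversion bias), positions drawn without replacement,
alternate bases uniform. This keeps coordinates shared across samples, so
consensus genomes stay length-aligned with the reference — matching the
SNP-centric marker model and the assumption, also made during genotyping,
that consensus sequences are length-preserving. Consequences: simulated
data cannot exercise indel robustness, alignment error, reference bias, or
read-level noise (the generator produces consensus genomes, not reads).
Passing tests therefore validate the statistical pipeline — screening,
genotyping logic, GS arithmetic, clustering, tree building — not upstream
read processing, which the toolkit deliberately consumes from standard
VCF/FASTA produced by external callers.

Marker dropout is modelled as i.i.d. per-cell failure with an exempt
subset (`designate_exempt_markers`, by default the first 40% of the panel
in genomic order) emulating loci whose primers amplify robustly in every
strain; the expected core size is then
`exempt + (1 − p)^n_samples · non_exempt`, verified by Monte Carlo in the
tests. The two-platform mode genotypes the identical consensus genomes
twice — noiseless by construction, so concordance is exactly 1 — with an
optional per-cell substitution error rate for robustness testing.

All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical configs give byte-identical output
files, and the pipeline report records parameters and output checksums so
a rerun can be verified.

## Numerical and degenerate-input choices

- Percent columns in the metadata tables are stored as fractions and
  formatted back to one decimal for comparison with printed values; table
  summary means use exact (`math.fsum`) summation so they are invariant to
  row order. The bundled tables are transcribed as printed, including one
  duplicated strain row, which is dropped at load time (first occurrence
  kept). The per-strain detected-marker column of the targeted-assay table
  is internally inconsistent with its own printed summary (recomputed
  mean 141.2 / total 9740 vs printed 138.9 / 9583); the summary reports
  the recomputed values and pins no check to them.
- QC-filter inequalities are strict as worded ("more than 10%", "over
  50%"); boundary reads are kept. Adapter matching is exact substring; a
  mismatch-tolerant trimmer is out of scope.
- Heterozygous diploid VCF calls map to IUPAC ambiguity bases by default
  (`het_policy="iupac"`), the faithful representation for dikaryotic
  strains genotyped as consensus sequences; `"major"` takes the first
  allele.
- Multiallelic and indel VCF records are skipped (counted, reported).
  The simulator may emit multiallelic records when two samples hit one
  position with different alternate bases; the few sites lost to the skip
  only affect window scoring, never genotyping, which slices consensus
  genomes directly.
- `window_dp` with `N < 2`, empty core sets, out-of-range GS, and
  non-symmetric or negative distance matrices raise errors rather than
  guessing; an empty marker panel is allowed with a warning.

## Problem sizes

Defaults were chosen so the full pipeline (200-kb genome, 18 strains,
~20k windows) completes in a few seconds and the whole validation suite in
well under a minute, while still containing hundreds of markers — enough
for the GS distributions to concentrate and the planted structure to be
recovered with wide margins.

## Known limitations

- No read-level simulation (quality profiles, chimeras) and no BAM/SAM
  handling; alignment and variant calling are upstream of this toolkit.
- Indels are out of scope end to end; consensus genomes must be
  length-preserving relative to the reference.
- Whether published pedigree counts for real cohorts derive from GS
  thresholds alone or from tree cuts is not reconstructable; both routes
  are implemented and may disagree on chained structures.
- GS carries no statistical confidence interval; with M core markers the
  granularity is 1/M.
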