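# Methods

`polyqtl` simulates and analyses autotetraploid multiparental populations
to compare biallelic and multiallelic QTL models under controlled genetic
diversity. This note documents the models, the simulator, the numerical
choices, and what the defaults do and do not represent.

## The mixed model

Each tested locus is scored with the unified ("Q + K") mixed model

    y = X β + Q v + u + ε,    Var(u) = K σ_G²,    Var(ε) = R σ_ε²

where `y` are the phenotypes, `X` the locus incidence matrix, `Q` optional
structure covariates (off by default — the kinship term carries the
structure correction), `u` the polygenic effect with realized-relationship
covariance `K`, and `R` a diagonal weight matrix (identity by default:
one observation per genotype, as in the simulated design).

Three incidence parametrizations are compared:

* **snp** (biallelic): `X = [1 | d]` with `d` the 0..ploidy dosage of the
  B allele. One effect per marker; purely additive.
* **ibd** (ancestral multiallelic): one dosage column per founder allele
  observed at the locus, except a reference allele; effects are relative
  to the reference. We drop the most frequent allele (ties: smallest
  label) so the retained columns carry maximal information.
* **hap** (haplotype multiallelic): identical to `ibd` but alleles are the
  distinct SNP-state strings of a sliding window (6 SNPs, overlap 4 —
  blocks start every 2 SNPs, never span chromosomes, trailing partial
  windows are dropped). A 6-SNP block tags at most 2⁶ = 64 alleles. The
  block position is the mean position of its member SNPs. True phase from
  the simulator is used; no statistical phasing is modelled, so the
  haplotype model performs at its real-data upper bound.

### Kinship

`K = DDᵀ/Δ` with `D` column-centered dosages and `Δ` the mean diagonal of
`DDᵀ`, so `mean(diag K) = 1` exactly. `D` is matched to the marker system
under test: SNP dosages for `snp`, concatenated per-allele dosage columns
(all alleles of every locus) for `ibd` and `hap`. To mitigate
marker-density bias, `D` uses one locus per cM: per chromosome, the
nearest locus to each integer cM gridpoint (deduplicated). No
leave-one-chromosome-out correction is applied.

### Estimation and testing

Variance components are estimated once per (population, model) by REML on
the no-marker null model and recycled at every locus (the EMMAX/P3D
approximation). The implementation eigendecomposes `K` once and maximizes
the profiled restricted likelihood over log(σ_G²/σ_ε²) ∈ [−10, 10]
(100-point coarse grid, then bounded refinement to 1e-8; boundary optima
are accepted). Each locus is then tested by generalized least squares
under `V = K σ_G² + R σ_ε²`: an F-test of the joint null that all tested
columns are zero, with numerator df the post-projection rank of the
tested columns (singular values below 1e-10 of the largest are treated as
zero) and denominator df `n − rank(full design)`. Monomorphic or fully
confounded loci get p = 1 and a `degenerate` flag. Because the rotation
of the locus design depends only on `K`, it is precomputed once and
reused across permutations; loci are grouped by column count and tested
in batched linear algebra.

Known property of P3D recycling: near a strong QTL the null-estimated
σ_G² partially absorbs the QTL signal, so recycled-component p-values are
conservative relative to per-locus exact REML there. Under the null the
two agree closely (asserted in the tests within 0.3 −log10 units).

### Significance thresholds

Genome-wide thresholds are empirical permutation quantiles: the phenotype
vector is permuted across individuals, variance components are
re-estimated under each permuted null (the conservative choice), the
genome-wide maximum −log10 p is
recorded, and the (1 − α) empirical quantile over permutations is the
threshold. Defaults: 100 permutations, α = 0.05, computed on one
population per (diversity, model) cell and reused across replicates,
since thresholds change little between populations.

## QTL intervals and power scoring

A QTL interval is a maximal chain of significant markers on one
chromosome in which adjacent significant markers are strictly less than
the linking distance `l` apart; intervening non-significant markers do
not break a chain; single-marker chains are discarded. The peak is the
most significant member (leftmost on ties). Cross-chromosome distances
are "unlinked" and never chain.

Scoring against the simulated truth (the three major QTLs only — the
polygenic loci are background, not targets):

* an interval is a true positive iff its [start, end] range contains a
  true QTL position; detection power = covered truths / all truths
  (multiple covering intervals count once);
* false-positive **rate** = significant markers (isolated ones included)
  outside ±5 cM truth windows, divided by all markers outside the
  windows;
* QTL/marker **precision** use interval labels: true-positive intervals
  (or their member markers) over all detected intervals (or members);
* peak accuracy = mean |peak − truth| cM over true-positive intervals.

Undefined metrics (no detections, no true negatives) are reported as
missing, never as zero, and are excluded from averages.

## The simulator

**Meiosis.** Bivalent-only autotetraploid meiosis with random pairing:
per chromosome a uniformly random perfect matching of the four
homologues, one meiotic product per bivalent drawn directly as a
two-state Markov walk along the markers with switch probability
`haldane_r(d) = (1 − exp(−2d/100))/2` per interval (no crossover or
chromatid interference). Four-chromatid bookkeeping is not carried: only
the marginal gamete law matters downstream, and that law is exact here.
SNP states and founder (IBD) labels recombine together.

**Map.** The default synthetic map has the summary shape of a dense
tetraploid potato linkage map: five chromosomes
(lengths 110/95/90/105/85 cM, 485 cM total, chosen so every default QTL
position fits its chromosome), 3509 markers allocated proportionally to
length, evenly spread with small uniform jitter. Desk-scale runs keep
full marker density but drop chromosomes.

**Populations.** Ten ancestral groups (AGs): 10 tetraploid founders each
with fair-coin SNP states and 40 globally unique founder labels, drifted
50 generations of random non-self mating (uniform ordered pairs of
distinct parents, redrawn per offspring) at constant size 100. A NAM
population is one central parent crossed to nine peripheral parents, 50
offspring per cross, 460 individuals including the parents. Diversity
level k draws the 10 parents from k AGs with counts as equal as possible;
the central parent comes from the AG providing most parents (ties: lowest
AG index). Replicates share one AG pool and differ through the seed
stream.

**Phenotypes.** At each major QTL (defaults: chr1 67.88, chr2 61.2,
chr4 100.49 cM, snapped to the nearest marker) every AG contributing
alleles receives a mean ~ N(0, σ_ag²) and each founder allele an effect
~ N(AG mean, σ_within²); 50 polygenic loci placed uniformly on the map
get per-allele effects ~ N(0, σ_poly²). The phenotype is the sum of the
four carried allele effects at every effect locus plus N(0, σ_ε²) noise —
purely additive.

Defaults: σ_ag = 0.5, σ_within = 1.5, σ_poly = 0.18, and σ_ε calibrated
from the realized genotypic variance for broad-sense h² = 0.85. These
are the package's own effect-sampling constants, fixed by two design
considerations. First, in a NAM, AG-mean
differences (σ_ag) are expressed almost entirely *between* families and
are therefore absorbed by the kinship term; the within-AG spread
(σ_within) is what segregates inside crosses and carries the detectable
signal, so σ_within must dominate — with the ratio reversed no model
detects anything at any diversity, contradicting the benchmark regime
this simulator exists to emulate. Second, within that constraint the
scale of signal against noise was set so the benchmark regime is
reproduced (near-complete detection by every model at low diversity,
with the biallelic model degrading as diversity grows). The polygenic
loci contribute roughly a quarter to a third of genetic variance. These
are configuration knobs (`PhenotypeParams`), not estimates of any real
trait.

**What the simulator does not emulate.** Real marker ascertainment and
non-uniform map density; genotyping and phasing error (true phase and
true IBD are used, so the `hap` and `ibd` results are upper bounds for
real data); quadrivalent pairing, preferential pairing and double
reduction; selection, migration and mutation during drift; dominance,
epistasis and QTL×E. Passing tests therefore certify the statistical
machinery and the simulated-design conclusions, not performance on real
potato data.

## Problem sizes

Full-scale defaults mirror the study grid: 4 diversity levels × 11
replicates × 3 models, 100 permutations, l from 0 to 10 cM in 0.5 steps.
The packaged acceptance run uses the desk-scale configuration the package
treats as first-class: two chromosomes at full density (~1480 markers,
two major QTLs on-map), 11 replicates per diversity level, 50
permutations, l ∈ {1.5, …, 10}; the drift statistic uses 3 AGs on a
five-chromosome 485 cM map with 900 markers. Reported summaries are
unweighted means over replicate populations (and over the l grid where a
metric is averaged over l > 1).

Two desk-scale effects are worth knowing. A two-chromosome genome halves
the number of kinship markers the one-per-cM thinning retains (~205 vs
485), so the structure correction is noisier and the biallelic model
keeps more long-range "shadow" intervals than at full scale — its
QTL-level precision reads roughly 0.2 below the full-scale benchmark.
And the genome-wide permutation threshold is lower (fewer tests), which
nudges detection power upward, most visibly for the haplotype model at
the highest diversity.

## Numerical and degenerate-input choices

* Cross-chromosome distance is a distinguished "unlinked" value that
  compares greater than any finite l (chains can never bridge
  chromosomes).
* Markers at identical positions chain at any l > 0 (d = 0 < l).
* d = l exactly does not chain (strict inequality).
* Peak and reference-allele ties break to the leftmost / smallest label.
* Kinship requires Δ > 0; an all-constant dosage matrix is rejected.
* K must be PSD within 1e-8 (relative); small negative eigenvalues are
  clipped to zero after the check.
* Rare haplotype alleles are *not* merged before testing (a configurable
  merge threshold exists but defaults off).
* All randomness flows from a single seed through named seed-sequence
  spawns; identical configurations are bit-reproducible.
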