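# polyqtl

Multiallelic mixed-model QTL mapping for autopolyploid multiparental
populations — with the simulation and power-evaluation machinery to ask
*when a multiallelic model beats the standard biallelic SNP model*.

## The problem

In a biparental diploid cross, two QTL alleles segregate and a biallelic
SNP regression describes them well. In genetically diverse material —
multiparental populations (MPPs), polyploids, or both — each locus can
carry up to `ploidy × founders` functional alleles, and a single SNP can
no longer tag them: each SNP allele groups several functional alleles of
different effect, which weakens and displaces association signals. This
package implements and compares three marker systems for an
autotetraploid nested association mapping (NAM) design:

* **snp** — biallelic dosage regression (one column, dosage 0..4);
* **ibd** — ancestral multiallelic model: one effect per founder allele
  (identity-by-descent label), relative to a reference allele;
* **hap** — multiallelic haplotype blocks from a sliding window of 6
  SNPs (overlap 4), tagging up to 2⁶ = 64 alleles per block.

All three are scored with the unified mixed model

    y = Xβ + Qv + u + ε,   Var(u) = K σ_G²,   Var(ε) = R σ_ε²

where `K = DDᵀ/Δ` is the realized-relationship kinship on one marker per
cM (matched to the marker system: SNP dosages or concatenated
allele-dosage columns) and variance components are estimated once by
REML and recycled at every locus (EMMAX/P3D), testing each locus with a
GLS F-test. Genome-wide significance uses Churchill–Doerge permutation
thresholds; significant markers are chained into QTL intervals when
adjacent significant markers are closer than a linking distance `l`, and
intervals are scored against the simulated truth (detection power,
false-positive rate, QTL/marker precision, peak accuracy).

The simulator provides the full study design: bivalent-only tetraploid
meiosis under the Haldane mapping function, ten ancestral groups of 10
founders (40 founder alleles each) drifted 50 generations at size 100,
and NAM populations of 460 individuals whose 10 parents span a
configurable number of ancestral groups — the genetic-diversity dial of
the whole experiment. See `docs/methods.md` for the model details and
design choices.

## Worked example

```python
import numpy as np
from polyqtl import (
    GenomeScanner, LinkingParams, QTLSpec, assign_effects, build_nam,
    call_intervals, kinship_for_model, phenotype, simulate_ag_pool,
    synthetic_map,
)
from polyqtl.power import encode_loci, evaluate_scan

# 1. simulate: map, ancestral groups, one NAM population spanning 3 AGs
gmap = synthetic_map(n_chromosomes=2, rng=np.random.default_rng(0))
rng = np.random.default_rng(3)
ags = simulate_ag_pool(gmap, rng=rng)                  # 10 AGs, 50 generations
nam = build_nam(ags, diversity_k=3, rng=rng)           # 460 individuals
effects = assign_effects(nam, QTLSpec(), rng=rng)
trait = phenotype(nam, effects, rng=rng)

# 2. scan with the ancestral multiallelic (ibd) model
loci = encode_loci(nam.population, "ibd")
K = kinship_for_model(nam.population, "ibd")
scanner = GenomeScanner(loci, K)
threshold = scanner.permutation_threshold(trait.values, n_perm=50,
                                          rng=np.random.default_rng(2))
result = scanner.scan(trait.values)

# 3. call QTL intervals at linking distance l = 3 cM
intervals = call_intervals(result, LinkingParams(l=3.0, threshold=threshold))
print(f"permutation threshold: {threshold:.2f} (-log10 p)")
for iv in intervals:
    print(f"chr {iv.chromosome}: [{iv.start:.1f}, {iv.end:.1f}] cM, "
          f"{iv.n_markers} markers, peak {iv.peak_position:.1f} cM "
          f"(-log10 p = {iv.peak_neglog10p:.1f})")

# 4. score against the simulated truth
truth = [(c, gmap.positions[gmap.nearest_marker(c, p)])
         for c, p in QTLSpec().on_map(gmap).major_qtls]
report = evaluate_scan(result, truth, l=3.0, threshold=threshold)
print(f"detection power: {report.detection_power:.2f}, "
      f"QTL precision: {report.qtl_precision:.2f}, "
      f"peak accuracy: {report.peak_accuracy_cM:.2f} cM")
```

Output:

```
permutation threshold: 3.15 (-log10 p)
chr 1: [64.6, 68.9] cM, 32 markers, peak 67.8 cM (-log10 p = 11.2)
chr 2: [58.1, 64.7] cM, 43 markers, peak 60.7 cM (-log10 p = 12.8)
detection power: 1.00, QTL precision: 1.00, peak accuracy: 0.32 cM
```

Both simulated QTLs (chr1 67.9 cM, chr2 61.2 cM) are recovered as single
intervals whose peaks sit a fraction of a centiMorgan from the truth:
the ancestral model assigns one effect per founder allele, so markers at
the QTL separate the allelic effects cleanly and significance decays
quickly with distance.

The same pipeline is available from the shell:

```bash
polyqtl simulate --diversity 3 --replicates 1 --seed 7 --out run/
polyqtl scan --genotypes run/pop_d3_r0.csv --map run/map.csv \
             --phenotypes run/pheno_d3_r0.csv --model ibd --out run/scan.csv
polyqtl threshold --genotypes run/pop_d3_r0.csv --map run/map.csv \
             --phenotypes run/pheno_d3_r0.csv --model ibd --n-perm 100 \
             --seed 7 --out run/thr.csv
polyqtl call --scan run/scan.csv --threshold 3.3 --linking-distance 3 \
             --out run/intervals.csv
polyqtl power --config config.yaml --out power/     # the full grid
```

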