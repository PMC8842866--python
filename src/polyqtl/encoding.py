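"""Marker systems: SNP dosages, true-IBD ancestral alleles, haploblocks.

Three encodings of the same phased population are compared throughout:

* ``snp`` — the biallelic model; each marker is summarised by the dosage
  (0..ploidy) of its B allele and tested with a single regression column.
* ``ibd`` — the ancestral multiallelic model; the alleles of a locus are
  the founder labels observed there, each with its own dosage column.
* ``hap`` — multiallelic haplotype blocks built by sliding a window of
  consecutive SNPs along each chromosome; a block's alleles are the
  distinct SNP-state strings observed on homologues. A window of w SNPs
  can tag at most 2^w alleles.

Incidence matrices follow the additive parametrization: an intercept plus
one dosage column per allele — except one reference allele in the
multiallelic case, whose effect all others are estimated relative to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .population import PhasedPopulation

__all__ = [
    "MultiallelicLocus",
    "IncidenceMatrix",
    "LocusSet",
    "snp_dosages",
    "ibd_loci",
    "build_haploblocks",
    "incidence_biallelic",
    "incidence_multiallelic",
    "haploblock_map",
]


@dataclass
class MultiallelicLocus:
    """One multiallelic locus: allele labels and per-individual allele dosages.

    ``dosages`` is an (n_individuals, n_alleles) integer array whose rows
    sum exactly to the ploidy.
    """

    name: str
    chromosome: str
    position: float
    alleles: list
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.alleles):
            raise ValueError("dosages must be (n_individuals, n_alleles)")
        if len(self.alleles) < 1:
            raise ValueError("a locus needs at least one allele")

    @property
    def n_alleles(self) -> int:
        return len(self.alleles)


@dataclass
class IncidenceMatrix:
    """Fixed-effect design for one tested locus: intercept + dosage columns."""

    X: np.ndarray
    allele_labels: list  # labels of the dosage columns (reference excluded)
    reference: object | None  # dropped reference allele, None for biallelic
    testable: bool  # False when no polymorphic dosage column exists

    @property
    def n_tested_columns(self) -> int:
        return self.X.shape[1] - 1


def snp_dosages(pop: PhasedPopulation) -> np.ndarray:
    """Per-marker B-allele dosages, (n_individuals, n_markers) in 0..ploidy."""
    if np.any(pop.snp > 1):
        raise ValueError("SNP states must be binary (0=A, 1=B)")
    return pop.snp.sum(axis=1, dtype=np.int16)


def _dosage_locus(codes: np.ndarray, name, chrom, position, allele_namer) -> MultiallelicLocus:
    """Build a MultiallelicLocus from per-homologue integer codes (n, ploidy)."""
    uniq, inv = np.unique(codes, return_inverse=True)
    inv = inv.reshape(codes.shape)
    n, ploidy = codes.shape
    dos = np.zeros((n, uniq.size), dtype=np.int16)
    np.add.at(dos, (np.repeat(np.arange(n), ploidy), inv.ravel()), 1)
    return MultiallelicLocus(
        name=name,
        chromosome=chrom,
        position=float(position),
        alleles=[allele_namer(u) for u in uniq],
        dosages=dos,
    )


def ibd_loci(pop: PhasedPopulation) -> list[MultiallelicLocus]:
    """True-IBD encoding: one multiallelic locus per marker, founder labels as alleles."""
    gmap = pop.gmap
    out = []
    for m in range(gmap.n_markers):
        out.append(
            _dosage_locus(
                pop.labels[:, :, m],
                name=gmap.names[m],
                chrom=str(gmap.chromosomes[m]),
                position=gmap.positions[m],
                allele_namer=int,
            )
        )
    return out


def build_haploblocks(
    pop: PhasedPopulation, window: int = 6, overlap: int = 4
) -> list[MultiallelicLocus]:
    """Sliding-window haploblocks per chromosome.

    Blocks start at SNP 1, 1+step, 1+2*step, ... with step = window -
    overlap (default 6/4 so consecutive blocks share 4 SNPs); trailing SNPs
    that cannot fill a window are dropped; windows never span chromosomes.
    A block's position is the mean cM position of its member SNPs and its
    alleles are the distinct window-length SNP-state strings observed.
    """
    if window <= overlap:
        raise ValueError("window must exceed overlap")
    if np.any(pop.snp > 1):
        raise ValueError("SNP states must be binary (0=A, 1=B)")
    step = window - overlap
    gmap = pop.gmap
    powers = (1 << np.arange(window)).astype(np.int64)
    out = []
    for chrom in gmap.chrom_names:
        sl = gmap.chrom_slice(chrom)
        n_chrom = sl.stop - sl.start
        bi = 0
        for start in range(0, n_chrom - window + 1, step):
            cols = slice(sl.start + start, sl.start + start + window)
            codes = pop.snp[:, :, cols].astype(np.int64) @ powers
            bi += 1
            out.append(
                _dosage_locus(
                    codes,
                    name=f"c{chrom}_hb{bi}",
                    chrom=chrom,
                    position=float(np.mean(gmap.positions[cols])),
                    allele_namer=lambda u, w=window: format(int(u), f"0{w}b")[::-1],
                )
            )
    return out


def haploblock_map(blocks: list[MultiallelicLocus]) -> GeneticMap:
    """Genetic map over haploblock positions (for thinning and scan output)."""
    return GeneticMap(
        [b.name for b in blocks],
        [b.chromosome for b in blocks],
        [b.position for b in blocks],
    )


def incidence_biallelic(dosages: np.ndarray) -> IncidenceMatrix:
    """Biallelic additive design: intercept and one SNP-dosage column."""
    d = np.asarray(dosages, dtype=float)
    X = np.column_stack([np.ones(d.size), d])
    polymorphic = bool(np.ptp(d) > 0)
    return IncidenceMatrix(X=X, allele_labels=["B"], reference=None, testable=polymorphic)


def incidence_multiallelic(locus: MultiallelicLocus, merge_rare_below: int = 0) -> IncidenceMatrix:
    """Multiallelic additive design: intercept + dosages of all non-reference alleles.

    The reference allele is the most frequent one (ties broken by the
    smallest allele label); its column is dropped, so estimated effects
    are relative to the reference. A single-allele locus yields an
    intercept-only design flagged untestable. ``merge_rare_below`` folds
    alleles observed on fewer than that many homologues into the
    reference (off by default: every observed allele gets a column).
    """
    totals = locus.dosages.sum(axis=0)
    order = sorted(range(locus.n_alleles), key=lambda i: (-totals[i], locus.alleles[i]))
    ref = order[0]
    keep = [i for i in range(locus.n_alleles) if i != ref and totals[i] >= merge_rare_below]
    n = locus.dosages.shape[0]
    X = np.column_stack([np.ones(n)] + [locus.dosages[:, i].astype(float) for i in keep])
    return IncidenceMatrix(
        X=X,
        allele_labels=[locus.alleles[i] for i in keep],
        reference=locus.alleles[ref],
        testable=len(keep) > 0,
    )


class LocusSet:
    """A genome's worth of tested loci in one concatenated design block.

    Stores every locus's non-intercept design columns side by side in one
    (n_individuals, total_columns) matrix with per-locus column slices —
    the layout the genome scanner rotates once and reuses across
    permutations. Build with :meth:`from_snp` or :meth:`from_multiallelic`.
    """

    def __init__(self, names, chromosomes, positions, X_all, col_slices, model: str):
        self.names = list(names)
        self.chromosomes = [str(c) for c in chromosomes]
        self.positions = np.asarray(positions, dtype=float)
        self.X_all = X_all
        self.col_slices = col_slices
        self.model = model

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_individuals(self) -> int:
        return self.X_all.shape[0]

    def locus_columns(self, j: int) -> np.ndarray:
        return self.X_all[:, self.col_slices[j][0] : self.col_slices[j][1]]

    @classmethod
    def from_snp(cls, pop: PhasedPopulation) -> "LocusSet":
        d = snp_dosages(pop).astype(float)
        gmap = pop.gmap
        slices = [(j, j + 1) for j in range(gmap.n_markers)]
        return cls(gmap.names, gmap.chromosomes, gmap.positions, d, slices, "snp")

    @classmethod
    def from_multiallelic(cls, loci: list[MultiallelicLocus], model: str) -> "LocusSet":
        mats, slices, start = [], [], 0
        for loc in loci:
            inc = incidence_multiallelic(loc)
            cols = inc.X[:, 1:]
            mats.append(cols)
            slices.append((start, start + cols.shape[1]))
            start += cols.shape[1]
        X_all = np.concatenate(mats, axis=1) if mats else np.empty((0, 0))
        return cls(
            [l.name for l in loci],
            [l.chromosome for l in loci],
            [l.position for l in loci],
            X_all,
            slices,
            model,
        )
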