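"""Ancestral groups by random-mating drift, and NAM population assembly.

The study design is two-stage. First, ten ancestral groups (AGs) are each
founded by 10 tetraploid ancestors with random SNP states; every founder
homologue carries a globally unique founder label, so 40 identity-by-
descent (IBD) alleles segregate per AG. Each AG is drifted for 50
generations of random non-self mating at constant size 100, eroding allele
counts per locus by drift. Second, NAM (nested association mapping)
populations are assembled: one central parent crossed to nine peripheral
parents, 50 offspring per cross, 460 individuals in total including the
parents. Drawing the 10 parents from k different AGs (k in {1,3,7,10})
tunes the genetic diversity of the NAM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap
from .meiosis import Genotype, batch_gametes

__all__ = [
    "PhasedPopulation",
    "AncestralGroup",
    "NAMPopulation",
    "simulate_founders",
    "drift_generations",
    "build_nam",
    "distinct_alleles_per_locus",
]


@dataclass
class PhasedPopulation:
    """A set of individuals with fully phased two-track genotypes on one map.

    ``snp`` and ``labels`` are (n_individuals, ploidy, n_markers) arrays;
    see :class:`polyqtl.meiosis.Genotype` for the track semantics.
    """

    snp: np.ndarray
    labels: np.ndarray
    names: list[str]
    gmap: GeneticMap

    def __post_init__(self):
        self.snp = np.asarray(self.snp, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.snp.shape != self.labels.shape or self.snp.ndim != 3:
            raise ValueError("snp and labels must be matching (n, ploidy, n_markers) arrays")
        if self.snp.shape[0] != len(self.names):
            raise ValueError("one name per individual required")
        if self.snp.shape[2] != self.gmap.n_markers:
            raise ValueError("population and map disagree on marker count")

    @property
    def n_individuals(self) -> int:
        return self.snp.shape[0]

    @property
    def ploidy(self) -> int:
        return self.snp.shape[1]

    def genotype(self, i: int) -> Genotype:
        return Genotype(self.snp[i], self.labels[i])


@dataclass
class AncestralGroup:
    """Final generation of one drifted random-mating population."""

    population: PhasedPopulation
    n_founders: int
    generations: int
    size: int
    founder_label_universe: np.ndarray  # all labels the founders carried

    @property
    def n_labels(self) -> int:
        return self.founder_label_universe.size


@dataclass
class NAMPopulation:
    """One central parent x nine peripheral parents, plus their offspring.

    ``population`` holds parents first (central parent at index 0, then the
    peripherals) followed by the offspring; ``family`` is -1 for parents and
    the 0-based cross index for offspring.
    """

    population: PhasedPopulation
    diversity_k: int
    central_parent: int  # index into population (always 0)
    peripheral_parents: list[int]
    family: np.ndarray
    parent_ag: list[int]  # AG index each parent came from (central first)

    @property
    def n_individuals(self) -> int:
        return self.population.n_individuals


def simulate_founders(
    n_founders: int,
    gmap: GeneticMap,
    ploidy: int = 4,
    rng: np.random.Generator | None = None,
    label_offset: int = 0,
) -> PhasedPopulation:
    """Generate unrelated founders with fair-coin SNP states and unique labels.

    Every founder homologue receives an independent Bernoulli(1/2) SNP state
    at each marker and one globally unique founder label, constant along the
    homologue, numbered from ``label_offset``.
    """
    if rng is None:
        rng = np.random.default_rng()
    M = gmap.n_markers
    snp = rng.integers(0, 2, size=(n_founders, ploidy, M), dtype=np.uint8)
    hom_labels = label_offset + np.arange(n_founders * ploidy, dtype=np.int32)
    labels = np.broadcast_to(
        hom_labels.reshape(n_founders, ploidy, 1), (n_founders, ploidy, M)
    ).copy()
    names = [f"F{label_offset // ploidy + i}" for i in range(n_founders)]
    return PhasedPopulation(snp, labels, names, gmap)


def _random_distinct_pairs(n_parents: int, n_offspring: int, rng: np.random.Generator):
    """Uniform ordered pairs of distinct parents, redrawn per offspring."""
    mothers = rng.integers(0, n_parents, size=n_offspring)
    fathers = (mothers + 1 + rng.integers(0, n_parents - 1, size=n_offspring)) % n_parents
    return mothers, fathers


def _mate_generation(
    pop: PhasedPopulation, size: int, rng: np.random.Generator, name_prefix: str
) -> PhasedPopulation:
    mothers, fathers = _random_distinct_pairs(pop.n_individuals, size, rng)
    ms, ml = batch_gametes(pop.snp, pop.labels, mothers, pop.gmap, rng)
    fs, fl = batch_gametes(pop.snp, pop.labels, fathers, pop.gmap, rng)
    snp = np.concatenate([ms, fs], axis=1)
    labels = np.concatenate([ml, fl], axis=1)
    names = [f"{name_prefix}_{i}" for i in range(size)]
    return PhasedPopulation(snp, labels, names, pop.gmap)


def drift_generations(
    founders: PhasedPopulation,
    generations: int = 50,
    size: int = 100,
    rng: np.random.Generator | None = None,
) -> AncestralGroup:
    """Random non-self mating at constant size; returns the final generation.

    ``generations = 0`` returns the founders unchanged. Parent pairs are
    uniform over ordered pairs of distinct individuals, redrawn per
    offspring (no monogamy constraint, no selection/migration/mutation).
    """
    if founders.n_individuals < 2:
        raise ValueError("drift needs at least 2 founders")
    if rng is None:
        rng = np.random.default_rng()
    universe = np.unique(founders.labels)
    pop = founders
    for g in range(1, generations + 1):
        pop = _mate_generation(pop, size, rng, f"G{g}")
    return AncestralGroup(
        population=pop,
        n_founders=founders.n_individuals,
        generations=generations,
        size=pop.n_individuals,
        founder_label_universe=universe,
    )


def distinct_alleles_per_locus(pop: PhasedPopulation) -> np.ndarray:
    """Number of distinct founder labels segregating at each marker."""
    n, ploidy, M = pop.labels.shape
    flat = pop.labels.reshape(n * ploidy, M)
    counts = np.empty(M, dtype=np.int64)
    for m in range(M):
        counts[m] = np.unique(flat[:, m]).size
    return counts


def _parent_counts(diversity_k: int, n_parents: int) -> list[int]:
    """Per-AG parent counts, as equal as possible, remainder to the first AGs."""
    base, rem = divmod(n_parents, diversity_k)
    return [base + (1 if i < rem else 0) for i in range(diversity_k)]


def build_nam(
    ags: list[AncestralGroup],
    diversity_k: int,
    n_peripheral: int = 9,
    offspring_per_cross: int = 50,
    rng: np.random.Generator | None = None,
) -> NAMPopulation:
    """Assemble a NAM population whose parents span ``diversity_k`` AGs.

    The 10 parents (1 central + ``n_peripheral``) are sampled without
    replacement from ``diversity_k`` AGs drawn from the pool, with per-AG
    counts as equal as possible; the central parent comes from the AG
    providing the most parents (ties broken by lowest AG index). Parents
    are part of the analysed population, so the default design yields
    10 + 9 x 50 = 460 individuals.
    """
    if diversity_k < 1 or diversity_k > len(ags):
        raise ValueError(f"diversity_k must be in 1..{len(ags)}")
    if rng is None:
        rng = np.random.default_rng()
    n_parents = n_peripheral + 1
    chosen = sorted(rng.choice(len(ags), size=diversity_k, replace=False).tolist())
    counts = _parent_counts(diversity_k, n_parents)
    # AG providing the most parents hosts the central parent; counts are
    # assigned in ascending AG order so ties resolve to the lowest AG index.
    central_ag_pos = int(np.argmax(counts))
    parent_snp, parent_lab, parent_ag = [], [], []
    for pos, (ag_idx, cnt) in enumerate(zip(chosen, counts)):
        pop = ags[ag_idx].population
        picks = rng.choice(pop.n_individuals, size=cnt, replace=False)
        for j in picks:
            parent_snp.append(pop.snp[j])
            parent_lab.append(pop.labels[j])
            parent_ag.append(ag_idx)
    # reorder so the central parent (first pick of the central AG) is index 0
    first_of_central = sum(counts[:central_ag_pos])
    order = [first_of_central] + [i for i in range(n_parents) if i != first_of_central]
    parent_snp = [parent_snp[i] for i in order]
    parent_lab = [parent_lab[i] for i in order]
    parent_ag = [parent_ag[i] for i in order]

    gmap = ags[0].population.gmap
    psnp = np.stack(parent_snp)
    plab = np.stack(parent_lab)
    n_off = n_peripheral * offspring_per_cross
    mothers = np.zeros(n_off, dtype=np.int64)  # central parent is index 0
    fathers = np.repeat(np.arange(1, n_parents), offspring_per_cross)
    ms, ml = batch_gametes(psnp, plab, mothers, gmap, rng)
    fs, fl = batch_gametes(psnp, plab, fathers, gmap, rng)
    snp = np.concatenate([psnp, np.concatenate([ms, fs], axis=1)])
    labels = np.concatenate([plab, np.concatenate([ml, fl], axis=1)])
    names = ["P0_central"] + [f"P{i}" for i in range(1, n_parents)]
    names += [
        f"X{f}_{o}" for f in range(1, n_parents) for o in range(offspring_per_cross)
    ]
    family = np.concatenate(
        [np.full(n_parents, -1), np.repeat(np.arange(n_peripheral), offspring_per_cross)]
    )
    pop = PhasedPopulation(snp, labels, names, gmap)
    return NAMPopulation(
        population=pop,
        diversity_k=diversity_k,
        central_parent=0,
        peripheral_parents=list(range(1, n_parents)),
        family=family,
        parent_ag=parent_ag,
    )


def simulate_ag_pool(
    gmap: GeneticMap,
    n_ags: int = 10,
    n_founders: int = 10,
    generations: int = 50,
    size: int = 100,
    ploidy: int = 4,
    rng: np.random.Generator | None = None,
) -> list[AncestralGroup]:
    """Simulate the standard pool of ancestral groups with disjoint label ranges."""
    if rng is None:
        rng = np.random.default_rng()
    ags = []
    for g in range(n_ags):
        founders = simulate_founders(
            n_founders, gmap, ploidy=ploidy, rng=rng, label_offset=g * n_founders * ploidy
        )
        ags.append(drift_generations(founders, generations, size, rng))
    return ags
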