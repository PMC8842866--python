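"""Autotetraploid (any even ploidy) meiosis: bivalent pairing and Haldane recombination.

Only bivalents with fully random pairing are modelled, the configuration
used for all simulations here. One meiotic product is drawn per bivalent
directly as a two-state Markov walk along the chromosome: the first
marker's source homologue is uniform over the pair and between adjacent
markers at distance d the source switches with probability
``haldane_r(d)`` independently per interval (no crossover or chromatid
interference). This reproduces the marginal gamete distribution of
bivalent meiosis under the Haldane mapping function; four-chromatid
bookkeeping is deliberately not carried.

Genotypes carry two parallel tracks per homologue: the biallelic SNP state
(0/1 for A/B) and the founder label, an identity-by-descent tag naming the
founder homologue each segment descends from. Both recombine together, so
founder labels are propagated segment-wise with the SNP states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genmap import GeneticMap, haldane_r

__all__ = ["Genotype", "pair_bivalents", "recombinant_chromatid", "make_gamete", "cross"]


@dataclass
class Genotype:
    """One individual: ``ploidy`` homologue tracks of SNP states and founder labels.

    ``snp`` and ``labels`` are (ploidy, n_markers) arrays; snp entries are
    0 (allele A) or 1 (allele B), labels are integer founder-homologue tags.
    """

    snp: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.snp = np.asarray(self.snp, dtype=np.uint8)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.snp.shape != self.labels.shape or self.snp.ndim != 2:
            raise ValueError("snp and labels must be matching (ploidy, n_markers) arrays")
        if self.ploidy % 2 != 0 or self.ploidy < 2:
            raise ValueError(f"ploidy must be even and >= 2, got {self.ploidy}")

    @property
    def ploidy(self) -> int:
        return self.snp.shape[0]

    @property
    def n_markers(self) -> int:
        return self.snp.shape[1]


def pair_bivalents(ploidy: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Draw a uniformly random partition of homologues into bivalent pairs.

    A uniform permutation paired off consecutively gives every perfect
    matching of the ``ploidy`` indices equal probability (each matching is
    produced by exactly ``(ploidy/2)! * 2^(ploidy/2)`` orderings).
    """
    if ploidy % 2 != 0 or ploidy < 2:
        raise ValueError(f"ploidy must be even and >= 2, got {ploidy}")
    perm = rng.permutation(ploidy)
    return [tuple(sorted((int(perm[i]), int(perm[i + 1])))) for i in range(0, ploidy, 2)]


def _walk_states(r: np.ndarray, n_walks: int, rng: np.random.Generator) -> np.ndarray:
    """(n_walks, n_markers) 0/1 source-homologue states of independent Markov walks.

    ``r`` holds the recombination fractions between adjacent markers
    (length n_markers - 1).
    """
    start = rng.integers(0, 2, size=(n_walks, 1), dtype=np.int8)
    if r.size:
        switches = (rng.random((n_walks, r.size)) < r[None, :]).astype(np.int8)
        steps = np.concatenate([start, switches], axis=1)
    else:
        steps = start
    return np.cumsum(steps, axis=1, dtype=np.int32) & 1


def recombinant_chromatid(
    parent: Genotype,
    bivalent: tuple[int, int],
    gmap: GeneticMap,
    chrom: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One meiotic product of a bivalent restricted to one chromosome.

    Returns (snp, labels) arrays over the chromosome's markers.
    """
    a, b = bivalent
    if not (0 <= a < parent.ploidy and 0 <= b < parent.ploidy and a != b):
        raise ValueError(f"invalid bivalent {bivalent!r} for ploidy {parent.ploidy}")
    sl = gmap.chrom_slice(chrom)
    pos = gmap.positions[sl]
    r = haldane_r(np.diff(pos))
    state = _walk_states(np.atleast_1d(r), 1, rng)[0]
    src = np.where(state == 0, a, b)
    cols = np.arange(sl.start, sl.stop)
    return parent.snp[src, cols], parent.labels[src, cols]


def make_gamete(parent: Genotype, gmap: GeneticMap, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One gamete: ploidy/2 homologue tracks across all chromosomes.

    Bivalent pairing is redrawn independently for every chromosome, and one
    recombinant chromatid is produced per bivalent.
    """
    if parent.n_markers != gmap.n_markers:
        raise ValueError("parent genotype and map disagree on marker count")
    half = parent.ploidy // 2
    snp = np.empty((half, gmap.n_markers), dtype=np.uint8)
    labels = np.empty((half, gmap.n_markers), dtype=np.int32)
    for chrom in gmap.chrom_names:
        sl = gmap.chrom_slice(chrom)
        pairs = pair_bivalents(parent.ploidy, rng)
        for k, pair in enumerate(pairs):
            s, lab = recombinant_chromatid(parent, pair, gmap, chrom, rng)
            snp[k, sl] = s
            labels[k, sl] = lab
    return snp, labels


def cross(mother: Genotype, father: Genotype, gmap: GeneticMap, rng: np.random.Generator) -> Genotype:
    """Offspring genotype: union of one gamete from each parent.

    Selfing is not forbidden here (``cross(x, x)`` is mechanically valid);
    callers that model outbreeders are responsible for avoiding it.
    """
    if mother.ploidy != father.ploidy:
        raise ValueError("parents must share ploidy")
    ms, ml = make_gamete(mother, gmap, rng)
    fs, fl = make_gamete(father, gmap, rng)
    return Genotype(np.vstack([ms, fs]), np.vstack([ml, fl]))


# ---------------------------------------------------------------------------
# Batched engine (same marginal law as make_gamete, vectorized across gametes)
# ---------------------------------------------------------------------------

#: The three perfect matchings of four homologues, as (bivalent, member) pairs.
_MATCHINGS_4 = np.array(
    [[[0, 1], [2, 3]], [[0, 2], [1, 3]], [[0, 3], [1, 2]]], dtype=np.int64
)


def _batch_matchings(ploidy: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, ploidy/2, 2) uniformly random bivalent pairings."""
    if ploidy == 4:
        return _MATCHINGS_4[rng.integers(0, 3, size=n)]
    perms = np.argsort(rng.random((n, ploidy)), axis=1)
    return perms.reshape(n, ploidy // 2, 2)


def batch_gametes(
    snp: np.ndarray,
    labels: np.ndarray,
    parent_idx: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce one gamete per entry of ``parent_idx`` from a population array.

    ``snp``/``labels`` are (n_individuals, ploidy, n_markers) stacks; the
    return value is a pair of (n_gametes, ploidy/2, n_markers) arrays.
    Statistically identical to calling :func:`make_gamete` per parent, but
    draws all Markov walks of a chromosome in one vectorized step.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.int64)
    n_gam = parent_idx.size
    ploidy = snp.shape[1]
    half = ploidy // 2
    out_snp = np.empty((n_gam, half, gmap.n_markers), dtype=np.uint8)
    out_lab = np.empty((n_gam, half, gmap.n_markers), dtype=np.int32)
    for chrom in gmap.chrom_names:
        sl = gmap.chrom_slice(chrom)
        cols = np.arange(sl.start, sl.stop)
        r = haldane_r(np.diff(gmap.positions[sl]))
        pairings = _batch_matchings(ploidy, n_gam, rng)  # (n_gam, half, 2)
        for k in range(half):
            a = pairings[:, k, 0]
            b = pairings[:, k, 1]
            state = _walk_states(np.atleast_1d(r), n_gam, rng)  # (n_gam, n_chrom_markers)
            src = np.where(state == 0, a[:, None], b[:, None])
            pidx = parent_idx[:, None]
            out_snp[:, k, sl] = snp[pidx, src, cols[None, :]]
            out_lab[:, k, sl] = labels[pidx, src, cols[None, :]]
    return out_snp, out_lab
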