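"""Genetic maps, mapping-function mathematics and shared QTL-scan parameters.

All genome coordinates in this package are centiMorgan (cM) positions on a
named chromosome; no physical (bp) coordinates exist anywhere. Distances
between markers on different chromosomes are the distinguished value
:data:`UNLINKED`, which compares greater than any finite linking distance,
so interval chaining can never bridge chromosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "UNLINKED",
    "GeneticMap",
    "QTLSpec",
    "LinkingParams",
    "haldane_r",
    "marker_distance",
    "synthetic_map",
    "PAPER_MAP_SPEC",
]


class _Unlinked(float):
    """Distance between markers on different chromosomes.

    Behaves as +infinity in comparisons (``UNLINKED < l`` is False for every
    finite ``l``) but prints as ``'unlinked'`` and is a distinct sentinel type.
    """

    def __new__(cls):
        return float.__new__(cls, math.inf)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "unlinked"


#: Singleton returned by :func:`marker_distance` for cross-chromosome pairs.
UNLINKED = _Unlinked()


def haldane_r(d):
    """Haldane map distance -> recombination fraction, r = (1 - exp(-2d/100)) / 2.

    Parameters
    ----------
    d : float or array-like
        Map distance in centiMorgan, finite and >= 0.

    Returns
    -------
    float or ndarray
        Recombination fraction in [0, 0.5); assumes no crossover
        interference.
    """
    arr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr < 0):
        raise ValueError(f"map distance must be finite and >= 0, got {d!r}")
    r = 0.5 * (1.0 - np.exp(-2.0 * arr / 100.0))
    if np.isscalar(d) or arr.ndim == 0:
        return float(r)
    return r


class GeneticMap:
    """Ordered markers with chromosome assignment and cM positions.

    Markers are stored in map order: grouped by chromosome (in order of first
    appearance), non-decreasing position within a chromosome. Duplicate
    positions are allowed (co-segregating markers); the given order of tied
    markers is preserved. Marker names must be unique.
    """

    def __init__(self, names: Sequence[str], chromosomes: Sequence[str], positions: Sequence[float]):
        names = list(map(str, names))
        chroms = np.asarray([str(c) for c in chromosomes], dtype=object)
        pos = np.asarray(positions, dtype=float)
        if not (len(names) == len(chroms) == len(pos)):
            raise ValueError("names, chromosomes and positions must have equal length")
        if len(names) == 0:
            raise ValueError("a genetic map needs at least one marker")
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")
        if np.any(~np.isfinite(pos)) or np.any(pos < 0):
            raise ValueError("positions must be finite and >= 0")
        # stable sort by (chromosome first-appearance, position)
        order_of_chrom = {}
        for c in chroms:
            order_of_chrom.setdefault(c, len(order_of_chrom))
        key = np.array([order_of_chrom[c] for c in chroms])
        idx = np.lexsort((np.arange(len(pos)), pos, key))
        self.names = [names[i] for i in idx]
        self.chromosomes = chroms[idx]
        self.positions = pos[idx]
        self._index = {n: i for i, n in enumerate(self.names)}
        self._chrom_order = list(order_of_chrom)
        self._slices = {}
        for c in self._chrom_order:
            where = np.flatnonzero(self.chromosomes == c)
            self._slices[c] = slice(int(where[0]), int(where[-1]) + 1)

    # -- basic queries -------------------------------------------------
    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_markers(self) -> int:
        return len(self.names)

    @property
    def chrom_names(self) -> list[str]:
        """Chromosome identifiers in map order."""
        return list(self._chrom_order)

    def chrom_slice(self, chrom: str) -> slice:
        """Contiguous index range of one chromosome's markers."""
        return self._slices[str(chrom)]

    def chrom_length(self, chrom: str) -> float:
        """Length of a chromosome, taken as its last marker's position."""
        return float(self.positions[self.chrom_slice(chrom)].max())

    @property
    def total_length(self) -> float:
        return float(sum(self.chrom_length(c) for c in self.chrom_names))

    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown marker {name!r}") from None

    def nearest_marker(self, chrom: str, position: float) -> int:
        """Index of the marker on `chrom` closest to `position` (leftmost on ties)."""
        sl = self.chrom_slice(chrom)
        pos = self.positions[sl]
        return sl.start + int(np.argmin(np.abs(pos - position)))

    def subset(self, indices: Sequence[int]) -> "GeneticMap":
        idx = list(indices)
        return GeneticMap(
            [self.names[i] for i in idx],
            [self.chromosomes[i] for i in idx],
            [self.positions[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker": self.names, "chromosome": self.chromosomes, "position_cM": self.positions}
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GeneticMap({self.n_markers} markers, {len(self.chrom_names)} chromosomes, "
            f"{self.total_length:.1f} cM)"
        )


def marker_distance(gmap: GeneticMap, a: str, b: str):
    """cM distance between two markers, or UNLINKED across chromosomes.

    Symmetric; satisfies the triangle inequality within a chromosome.
    """
    ia, ib = gmap.index_of(a), gmap.index_of(b)
    if gmap.chromosomes[ia] != gmap.chromosomes[ib]:
        return UNLINKED
    return float(abs(gmap.positions[ia] - gmap.positions[ib]))


@dataclass(frozen=True)
class QTLSpec:
    """True QTL architecture used by the phenotype simulator and power scoring.

    Only ``major_qtls`` count as true positions in power evaluation; the
    polygenic loci model background genetic variance.
    """

    major_qtls: tuple = ((("1", 67.88)), ("2", 61.2), ("4", 100.49))
    n_polygenic: int = 50

    def __post_init__(self):
        object.__setattr__(
            self, "major_qtls", tuple((str(c), float(p)) for c, p in self.major_qtls)
        )

    def on_map(self, gmap: GeneticMap) -> "QTLSpec":
        """Restrict major QTLs to chromosomes present on `gmap` (scaled maps)."""
        chroms = set(gmap.chrom_names)
        kept = [
            (c, p) for c, p in self.major_qtls if c in chroms and p <= gmap.chrom_length(c)
        ]
        if not kept:
            raise ValueError("no major QTL lies on the provided map")
        return QTLSpec(major_qtls=tuple(kept), n_polygenic=self.n_polygenic)


@dataclass(frozen=True)
class LinkingParams:
    """Linking distance l (cM) and significance cutoff on the -log10 p scale."""

    l: float
    threshold: float

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("linking distance l must be >= 0")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")


#: Shape of the five-chromosome map used throughout the simulation study:
#: chromosome lengths in cM (sum 485) and total marker count 3509. Lengths
#: are chosen so every default major-QTL position fits its chromosome.
PAPER_MAP_SPEC = {
    "chrom_lengths": (110.0, 95.0, 90.0, 105.0, 85.0),
    "n_markers": 3509,
}


def synthetic_map(
    n_chromosomes: int = 5,
    n_markers: int | None = None,
    chrom_lengths: Sequence[float] | None = None,
    jitter: float = 0.3,
    rng: np.random.Generator | None = None,
) -> GeneticMap:
    """Generate a dense SNP map with the summary shape of a tetraploid crop map.

    Defaults reproduce the five-chromosome, 3509-marker, 485 cM layout used
    by the simulation study. Markers are evenly spread along each chromosome
    with small uniform jitter so inter-marker distances are irregular, as on
    a real map; the first and last markers sit at 0 and the chromosome end.

    Parameters
    ----------
    n_chromosomes:
        Number of chromosomes; defaults use the first `n_chromosomes`
        entries of the five standard lengths.
    n_markers:
        Total marker count, allocated to chromosomes proportionally to
        length. Default scales 3509 by the fraction of total length kept.
    jitter:
        Fraction of the local marker spacing used as uniform positional
        noise (0 disables; deterministic without an rng).
    """
    if chrom_lengths is None:
        base = PAPER_MAP_SPEC["chrom_lengths"]
        if not 1 <= n_chromosomes <= len(base):
            raise ValueError(f"n_chromosomes must be in 1..{len(base)}")
        chrom_lengths = base[:n_chromosomes]
    chrom_lengths = [float(x) for x in chrom_lengths]
    if n_markers is None:
        frac = sum(chrom_lengths) / sum(PAPER_MAP_SPEC["chrom_lengths"])
        n_markers = int(round(PAPER_MAP_SPEC["n_markers"] * frac))
    if n_markers < 2 * len(chrom_lengths):
        raise ValueError("need at least two markers per chromosome")
    if rng is None:
        rng = np.random.default_rng(0)
    total = sum(chrom_lengths)
    # proportional allocation, remainders to the longest chromosomes
    raw = [n_markers * L / total for L in chrom_lengths]
    counts = [int(math.floor(x)) for x in raw]
    for i in np.argsort([c - r for c, r in zip(counts, raw)]):
        if sum(counts) == n_markers:
            break
        counts[i] += 1
    names, chroms, pos = [], [], []
    for ci, (L, m) in enumerate(zip(chrom_lengths, counts), start=1):
        grid = np.linspace(0.0, L, m)
        if jitter > 0 and m > 2:
            step = L / (m - 1)
            noise = rng.uniform(-jitter * step, jitter * step, size=m)
            noise[0] = noise[-1] = 0.0
            grid = np.sort(np.clip(grid + noise, 0.0, L))
        names.extend(f"c{ci}_m{j + 1}" for j in range(m))
        chroms.extend([str(ci)] * m)
        pos.extend(grid.tolist())
    return GeneticMap(names, chroms, pos)
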