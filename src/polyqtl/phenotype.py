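"""Additive phenotypes from effects on ancestral (founder) alleles.

Genetic effects are attached to founder labels, not to SNP states: at each
major QTL, every ancestral group (AG) contributing alleles receives a
random allelic mean, and each founder allele's effect is drawn around its
AG mean, so diverged AGs carry systematically different allele effects. A
configurable number of small-effect polygenic loci, placed uniformly on
the map, adds background genetic variance. The phenotype of an individual
is the sum of the effects of the four alleles it carries at every effect
locus, plus Gaussian noise — purely additive, no dominance or epistasis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genmap import GeneticMap, QTLSpec
from .population import NAMPopulation

__all__ = ["PhenotypeParams", "EffectModel", "TraitVector", "assign_effects", "phenotype"]


@dataclass(frozen=True)
class PhenotypeParams:
    """Variance knobs of the additive phenotype simulator.

    sigma_ag:
        SD of the per-AG allelic means at each major QTL (trait units).
        AG-mean differences are heavily confounded with family structure
        in a NAM, so this component is largely absorbed by the kinship
        term of the scan model.
    sigma_within:
        SD of founder-allele effects around their AG mean. This is the
        component that segregates within crosses and therefore carries
        the detectable QTL signal; the default makes major QTLs clearly
        detectable at low diversity, as in the study conditions this
        simulator emulates.
    sigma_poly:
        SD of founder-allele effects at each polygenic locus (no AG
        structure; the default makes the polygenic loci jointly contribute
        roughly a quarter to a third of genetic variance under the
        standard design).
    sigma_e:
        Residual SD. ``None`` (default) calibrates the noise from the
        realized genotypic variance so broad-sense heritability equals
        ``h2_target``.
    """

    sigma_ag: float = 0.5
    sigma_within: float = 1.5
    sigma_poly: float = 0.18
    sigma_e: float | None = None
    h2_target: float = 0.85

    def __post_init__(self):
        if min(self.sigma_ag, self.sigma_within, self.sigma_poly) < 0:
            raise ValueError("variance parameters must be >= 0")
        if self.sigma_e is not None and self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")
        if not 0 < self.h2_target < 1:
            raise ValueError("h2_target must be in (0, 1)")


@dataclass
class EffectModel:
    """Founder-label effects at every effect locus (majors + polygenic).

    ``effects[j]`` maps founder label -> additive effect at the locus whose
    marker index is ``marker_idx[j]``; the first ``n_major`` loci are the
    major QTLs in map order.
    """

    marker_idx: list[int]
    effects: list[dict[int, float]]
    n_major: int
    params: PhenotypeParams
    ag_means: list[dict[int, float]] = field(default_factory=list)

    @property
    def major_marker_idx(self) -> list[int]:
        return self.marker_idx[: self.n_major]


@dataclass
class TraitVector:
    """Phenotype values aligned to a population's individuals."""

    values: np.ndarray
    names: list[str]
    genotypic: np.ndarray | None = None
    sigma_e: float | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size != len(self.names):
            raise ValueError("one finite value per individual required")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotypes must be finite")


def _ag_of_labels(labels: np.ndarray, labels_per_ag: int) -> np.ndarray:
    """AG index of each founder label (labels are numbered in AG blocks)."""
    return np.asarray(labels) // labels_per_ag


def assign_effects(
    nam: NAMPopulation,
    qtls: QTLSpec,
    params: PhenotypeParams = PhenotypeParams(),
    rng: np.random.Generator | None = None,
    labels_per_ag: int = 40,
) -> EffectModel:
    """Draw founder-allele effects at the major QTLs and polygenic loci.

    Major QTL positions are snapped to the nearest map marker. For each
    major QTL, each AG with alleles segregating in ``nam`` gets a mean
    ~ N(0, sigma_ag^2) and each of its labels an effect
    ~ N(mean, sigma_within^2). Each polygenic locus (position uniform on
    the map) gets independent per-label effects ~ N(0, sigma_poly^2).
    """
    if rng is None:
        rng = np.random.default_rng()
    gmap = nam.population.gmap
    qtls = qtls.on_map(gmap)
    marker_idx: list[int] = []
    for chrom, pos in qtls.major_qtls:
        marker_idx.append(gmap.nearest_marker(chrom, pos))
    n_major = len(marker_idx)
    # polygenic positions: uniform over the map's total length
    chrom_lens = np.array([gmap.chrom_length(c) for c in gmap.chrom_names])
    probs = chrom_lens / chrom_lens.sum()
    for _ in range(qtls.n_polygenic):
        ci = rng.choice(len(chrom_lens), p=probs)
        pos = rng.uniform(0.0, chrom_lens[ci])
        marker_idx.append(gmap.nearest_marker(gmap.chrom_names[ci], pos))

    effects: list[dict[int, float]] = []
    ag_means: list[dict[int, float]] = []
    lab3d = nam.population.labels
    for j, m in enumerate(marker_idx):
        present = np.unique(lab3d[:, :, m])
        eff: dict[int, float] = {}
        means: dict[int, float] = {}
        if j < n_major:
            for ag in np.unique(_ag_of_labels(present, labels_per_ag)):
                means[int(ag)] = rng.normal(0.0, params.sigma_ag)
            for lab in present:
                mu = means[int(lab) // labels_per_ag]
                eff[int(lab)] = mu + rng.normal(0.0, params.sigma_within)
        else:
            for lab in present:
                eff[int(lab)] = rng.normal(0.0, params.sigma_poly)
        effects.append(eff)
        ag_means.append(means)
    return EffectModel(
        marker_idx=marker_idx,
        effects=effects,
        n_major=n_major,
        params=params,
        ag_means=ag_means,
    )


def genotypic_values(nam: NAMPopulation, model: EffectModel) -> np.ndarray:
    """Sum of carried-allele effects over all effect loci, per individual."""
    lab3d = nam.population.labels
    n = lab3d.shape[0]
    g = np.zeros(n)
    for m, eff in zip(model.marker_idx, model.effects):
        carried = lab3d[:, :, m]  # (n, ploidy)
        lut_keys = np.array(sorted(eff))
        lut_vals = np.array([eff[k] for k in sorted(eff)])
        idx = np.clip(np.searchsorted(lut_keys, carried), 0, lut_keys.size - 1)
        if np.any(lut_keys[idx] != carried):
            missing = set(np.unique(carried).tolist()) - set(eff)
            raise KeyError(
                f"no effect assigned for carried labels {sorted(missing)} at marker {m}"
            )
        g += lut_vals[idx].sum(axis=1)
    return g


def phenotype(
    nam: NAMPopulation,
    model: EffectModel,
    rng: np.random.Generator | None = None,
) -> TraitVector:
    """Emit phenotypes: genotypic value plus N(0, sigma_e^2) noise.

    With ``sigma_e=None`` the residual SD is calibrated from the realized
    genotypic variance: sigma_e^2 = Var(g) * (1 - h2) / h2, so the design
    heritability holds for this population in expectation.
    """
    if rng is None:
        rng = np.random.default_rng()
    g = genotypic_values(nam, model)
    p = model.params
    if p.sigma_e is None:
        var_g = float(np.var(g))
        sigma_e = float(np.sqrt(var_g * (1.0 - p.h2_target) / p.h2_target))
    else:
        sigma_e = p.sigma_e
    y = g + rng.normal(0.0, sigma_e, size=g.size) if sigma_e > 0 else g.copy()
    return TraitVector(values=y, names=list(nam.population.names), genotypic=g, sigma_e=sigma_e)
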