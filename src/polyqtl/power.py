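"""Power evaluation: score called intervals against the simulated truth.

Two notions of false positive coexist, mirroring how the evaluation
metrics are defined:

* the *rate* counts significant markers (isolated ones included) outside a
  +/- 5 cM window around each true QTL position, divided by the number of
  markers outside every window (the true negatives N);
* the *precisions* label whole intervals — an interval is a true positive
  iff its [start, end] range contains a true QTL position; all member
  markers of a true-positive interval are true-positive markers, members
  of other intervals are false positives, and isolated significant
  markers are ignored.

Undefined metrics (no detected interval, N = 0) are reported as missing
values, never as 0, so averages over populations stay honest.

:func:`run_experiment` orchestrates the full simulation grid: one shared
pool of ancestral groups, NAM populations at each diversity level,
per-model permutation thresholds (computed on the first replicate of each
(diversity, model) cell and reused), genome scans, and a sweep of the
linking distance l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .encoding import LocusSet, build_haploblocks, ibd_loci
from .genmap import GeneticMap, LinkingParams, QTLSpec, synthetic_map
from .intervals import QTLInterval, call_intervals
from .mixedmodel import GenomeScanner, ScanResult, kinship_for_model
from .phenotype import PhenotypeParams, assign_effects, phenotype
from .population import NAMPopulation, PhasedPopulation, build_nam, simulate_ag_pool

__all__ = [
    "Classification",
    "PowerReport",
    "ExperimentConfig",
    "classify",
    "detection_power",
    "false_positive_rate",
    "precisions",
    "peak_accuracy",
    "evaluate_scan",
    "run_experiment",
    "summarize",
]

TRUTH_WINDOW_CM = 5.0


@dataclass
class Classification:
    """Interval and marker labels for one (scan, threshold, l) evaluation."""

    truth: list[tuple[str, float]]
    intervals: list[QTLInterval]
    is_true_positive: list[bool]
    covered_truths: list[bool]
    n_true_negative_markers: int  # N: markers outside every truth window
    n_fp_markers_outside_windows: int  # significant markers outside the windows
    n_interval_markers: int  # significant markers belonging to any interval
    n_tp_interval_markers: int  # ... belonging to a true-positive interval


def classify(
    intervals: list[QTLInterval],
    scan: ScanResult,
    truth: list[tuple[str, float]],
    threshold: float,
    window: float = TRUTH_WINDOW_CM,
) -> Classification:
    """Label intervals and markers as true/false positives against the truth."""
    truth = [(str(c), float(p)) for c, p in truth]
    is_tp = [
        any(iv.chromosome == c and iv.contains(p) for c, p in truth) for iv in intervals
    ]
    covered = [
        any(tp and iv.chromosome == c and iv.contains(p) for iv, tp in zip(intervals, is_tp))
        for c, p in truth
    ]
    t = scan.table
    chroms = t["chromosome"].to_numpy()
    pos = t["position_cM"].to_numpy()
    in_window = np.zeros(len(t), dtype=bool)
    for c, p in truth:
        in_window |= (chroms == c) & (np.abs(pos - p) < window)
    sig = t["neglog10p"].to_numpy() > threshold
    n_tn = int((~in_window).sum())
    n_fp_rate = int((sig & ~in_window).sum())
    n_members = sum(iv.n_markers for iv in intervals)
    n_tp_members = sum(iv.n_markers for iv, tp in zip(intervals, is_tp) if tp)
    return Classification(
        truth=truth,
        intervals=intervals,
        is_true_positive=is_tp,
        covered_truths=covered,
        n_true_negative_markers=n_tn,
        n_fp_markers_outside_windows=n_fp_rate,
        n_interval_markers=n_members,
        n_tp_interval_markers=n_tp_members,
    )


def detection_power(cls: Classification) -> float:
    """Proportion of true QTLs covered by at least one true-positive interval.

    A truth covered by several intervals counts once.
    """
    return sum(cls.covered_truths) / len(cls.truth)


def false_positive_rate(cls: Classification) -> float | None:
    """FP / N on the marker-window definition; None when N = 0."""
    if cls.n_true_negative_markers == 0:
        return None
    return cls.n_fp_markers_outside_windows / cls.n_true_negative_markers


def precisions(cls: Classification) -> tuple[float | None, float | None]:
    """(qtl_precision, marker_precision); None when nothing was detected."""
    n_iv = len(cls.intervals)
    qtl_p = sum(cls.is_true_positive) / n_iv if n_iv else None
    marker_p = (
        cls.n_tp_interval_markers / cls.n_interval_markers if cls.n_interval_markers else None
    )
    return qtl_p, marker_p


def peak_accuracy(cls: Classification) -> float | None:
    """Mean |peak - true position| (cM) over true-positive intervals; None if none."""
    dists = []
    for iv, tp in zip(cls.intervals, cls.is_true_positive):
        if not tp:
            continue
        contained = [p for c, p in cls.truth if c == iv.chromosome and iv.contains(p)]
        dists.append(min(abs(iv.peak_position - p) for p in contained))
    return float(np.mean(dists)) if dists else None


@dataclass
class PowerReport:
    """All power metrics for one (population, model, l) combination."""

    detection_power: float
    false_positive_rate: float | None
    qtl_precision: float | None
    marker_precision: float | None
    peak_accuracy_cM: float | None
    n_intervals: int
    diversity: int | None = None
    replicate: int | None = None
    model: str | None = None
    l: float | None = None
    threshold: float | None = None


def evaluate_scan(
    scan: ScanResult,
    truth: list[tuple[str, float]],
    l: float,
    threshold: float,
    window: float = TRUTH_WINDOW_CM,
) -> PowerReport:
    """Call intervals at (l, threshold) and compute every power metric."""
    params = LinkingParams(l=l, threshold=threshold)
    intervals = call_intervals(scan, params)
    cls = classify(intervals, scan, truth, threshold, window=window)
    qtl_p, marker_p = precisions(cls)
    return PowerReport(
        detection_power=detection_power(cls),
        false_positive_rate=false_positive_rate(cls),
        qtl_precision=qtl_p,
        marker_precision=marker_p,
        peak_accuracy_cM=peak_accuracy(cls),
        n_intervals=len(intervals),
        model=scan.model,
        l=l,
        threshold=threshold,
    )


@dataclass(frozen=True)
class ExperimentConfig:
    """Full simulation-and-evaluation grid.

    Defaults are the standard study conditions: a 5-chromosome 485 cM /
    3509-marker map, 10 ancestral groups of 10 founders drifted 50
    generations at size 100, NAM populations of 460 individuals, 11
    replicate populations per diversity level, 100 permutations, and a
    linking-distance grid of 0..10 cM in 0.5 steps.
    """

    diversity_levels: tuple[int, ...] = (1, 3, 7, 10)
    replicates: int = 11
    models: tuple[str, ...] = ("snp", "ibd", "hap")
    l_grid: tuple[float, ...] = tuple(np.arange(0.0, 10.5, 0.5).tolist())
    n_perm: int = 100
    alpha: float = 0.05
    window: int = 6
    overlap: int = 4
    n_ags: int = 10
    n_founders: int = 10
    generations: int = 50
    ag_size: int = 100
    ploidy: int = 4
    n_peripheral: int = 9
    offspring_per_cross: int = 50
    n_chromosomes: int = 5
    n_markers: int | None = None
    phenotype: PhenotypeParams = field(default_factory=PhenotypeParams)
    qtls: QTLSpec = field(default_factory=QTLSpec)
    seed: int = 1

    def scaled(self, scale: float) -> "ExperimentConfig":
        """Shrink chromosome count, replicates and permutations for desk runs."""
        if not 0 < scale <= 1:
            raise ValueError("scale must be in (0, 1]")
        return replace(
            self,
            n_chromosomes=max(1, math.ceil(self.n_chromosomes * scale)),
            replicates=max(1, round(self.replicates * scale)),
            n_perm=max(20, round(self.n_perm * scale)),
        )


def encode_loci(
    pop: PhasedPopulation, model: str, window: int = 6, overlap: int = 4
) -> LocusSet:
    """Build the tested-locus design block for one marker system."""
    if model == "snp":
        return LocusSet.from_snp(pop)
    if model == "ibd":
        return LocusSet.from_multiallelic(ibd_loci(pop), "ibd")
    if model == "hap":
        return LocusSet.from_multiallelic(
            build_haploblocks(pop, window=window, overlap=overlap), "hap"
        )
    raise ValueError(f"unknown model {model!r}; expected snp, ibd or hap")


def run_experiment(
    config: ExperimentConfig,
    gmap: GeneticMap | None = None,
    ags=None,
    progress: bool = False,
) -> pd.DataFrame:
    """Run the full grid and return one tidy row per (diversity, replicate, model, l).

    All randomness derives from ``config.seed`` through a seed sequence, so
    identical configs reproduce identical tables. Replicate populations
    share one pool of ancestral groups. The permutation threshold for each
    (diversity, model) cell is computed on its first replicate and reused.
    Failures inside one (diversity, replicate) cell are recorded in the
    ``error`` column and the run continues.
    """
    root = np.random.SeedSequence(config.seed)
    ss_map, ss_ags, ss_pops = root.spawn(3)
    if gmap is None:
        gmap = synthetic_map(
            n_chromosomes=config.n_chromosomes,
            n_markers=config.n_markers,
            rng=np.random.default_rng(ss_map),
        )
    if ags is None:
        ags = simulate_ag_pool(
            gmap,
            n_ags=config.n_ags,
            n_founders=config.n_founders,
            generations=config.generations,
            size=config.ag_size,
            ploidy=config.ploidy,
            rng=np.random.default_rng(ss_ags),
        )
    # truth = where the simulated effects actually sit: major QTL positions
    # snapped to their nearest map marker (QTLs are marker-coincident)
    truth_spec = config.qtls.on_map(gmap)
    truth = [
        (c, float(gmap.positions[gmap.nearest_marker(c, p)]))
        for c, p in truth_spec.major_qtls
    ]
    rows = []
    for ki, k in enumerate(config.diversity_levels):
        thresholds: dict[str, float] = {}
        for rep in range(config.replicates):
            cell = f"diversity={k} replicate={rep}"
            ss_cell = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(1000 + ki, rep)
            )
            rng = np.random.default_rng(ss_cell)
            try:
                nam = build_nam(
                    ags,
                    diversity_k=k,
                    n_peripheral=config.n_peripheral,
                    offspring_per_cross=config.offspring_per_cross,
                    rng=rng,
                )
                effects = assign_effects(
                    nam,
                    config.qtls,
                    params=config.phenotype,
                    rng=rng,
                    labels_per_ag=config.n_founders * config.ploidy,
                )
                y = phenotype(nam, effects, rng=rng).values
                for model in config.models:
                    loci = encode_loci(
                        nam.population, model, window=config.window, overlap=config.overlap
                    )
                    K = kinship_for_model(
                        nam.population, model, window=config.window, overlap=config.overlap
                    )
                    scanner = GenomeScanner(loci, K)
                    if model not in thresholds:
                        thresholds[model] = scanner.permutation_threshold(
                            y, n_perm=config.n_perm, alpha=config.alpha, rng=rng
                        )
                    res = scanner.scan(y)
                    for l in config.l_grid:
                        rep_row = evaluate_scan(res, truth, l, thresholds[model])
                        rows.append(
                            {
                                "diversity": k,
                                "replicate": rep,
                                "model": model,
                                "l": l,
                                "threshold": thresholds[model],
                                "detection_power": rep_row.detection_power,
                                "false_positive_rate": rep_row.false_positive_rate,
                                "qtl_precision": rep_row.qtl_precision,
                                "marker_precision": rep_row.marker_precision,
                                "peak_accuracy_cM": rep_row.peak_accuracy_cM,
                                "n_intervals": rep_row.n_intervals,
                                "error": "",
                            }
                        )
                    if progress:  # pragma: no cover - console feedback
                        print(f"[run_experiment] {cell} model={model} done", flush=True)
            except Exception as exc:  # noqa: BLE001 - record and continue
                rows.append(
                    {
                        "diversity": k,
                        "replicate": rep,
                        "model": None,
                        "l": None,
                        "threshold": None,
                        "detection_power": None,
                        "false_positive_rate": None,
                        "qtl_precision": None,
                        "marker_precision": None,
                        "peak_accuracy_cM": None,
                        "n_intervals": None,
                        "error": f"{type(exc).__name__}: {exc}",
                    }
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Unweighted per-(diversity, model, l) means over replicate populations.

    Missing metric values (undefined in a replicate) are excluded from
    their mean rather than treated as zero.
    """
    ok = results[results["error"] == ""]
    metrics = [
        "detection_power",
        "false_positive_rate",
        "qtl_precision",
        "marker_precision",
        "peak_accuracy_cM",
    ]
    return (
        ok.groupby(["diversity", "model", "l"], sort=True)[metrics]
        .mean()
        .reset_index()
    )
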