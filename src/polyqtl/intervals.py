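"""QTL interval calling: the linking-distance chain rule.

A QTL interval is a maximal chain of significant markers on one
chromosome in which every pair of adjacent *significant* markers is less
than the linking distance l apart (strict inequality; non-significant
markers in between do not break a chain). Chains of a single marker are
discarded — isolated significant markers are ignored — and each interval's
peak is its most significant member (leftmost on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genmap import LinkingParams
from .mixedmodel import ScanResult

__all__ = ["QTLInterval", "call_intervals", "peak_of"]


@dataclass
class QTLInterval:
    """A chain of >= 2 significant markers on one chromosome."""

    chromosome: str
    markers: list[str]
    positions: np.ndarray
    neglog10p: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.neglog10p = np.asarray(self.neglog10p, dtype=float)
        if len(self.markers) < 2:
            raise ValueError("a QTL interval needs at least 2 member markers")

    @property
    def start(self) -> float:
        return float(self.positions[0])

    @property
    def end(self) -> float:
        return float(self.positions[-1])

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def contains(self, position: float) -> bool:
        return self.start <= position <= self.end

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.neglog10p))

    @property
    def peak_marker(self) -> str:
        return self.markers[self.peak_index]

    @property
    def peak_position(self) -> float:
        return float(self.positions[self.peak_index])

    @property
    def peak_neglog10p(self) -> float:
        return float(self.neglog10p[self.peak_index])


def peak_of(interval: QTLInterval) -> tuple[str, float]:
    """Most significant member marker and its position (leftmost on ties)."""
    return interval.peak_marker, interval.peak_position


def call_intervals(scan: ScanResult, params: LinkingParams) -> list[QTLInterval]:
    """Partition significant markers into QTL intervals by the chain rule.

    Adjacent significant markers (adjacent within the significant subset of
    one chromosome) closer than ``params.l`` cM are chained; maximal chains
    of at least two markers become intervals. With l = 0 no pair chains
    (d < l is strict) and no interval is called.
    """
    t = scan.table
    intervals: list[QTLInterval] = []
    for chrom, sub in t.groupby("chromosome", sort=False):
        sub = sub.sort_values("position_cM", kind="stable")
        sig = sub[sub["neglog10p"] > params.threshold]
        if sig.empty:
            continue
        pos = sig["position_cM"].to_numpy()
        gaps = np.diff(pos)
        breaks = np.flatnonzero(~(gaps < params.l))
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [pos.size]])
        for s, e in zip(starts, ends):
            if e - s < 2:
                continue
            chunk = sig.iloc[s:e]
            intervals.append(
                QTLInterval(
                    chromosome=str(chrom),
                    markers=chunk["locus"].tolist(),
                    positions=chunk["position_cM"].to_numpy(),
                    neglog10p=chunk["neglog10p"].to_numpy(),
                )
            )
    return intervals


def intervals_frame(intervals: list[QTLInterval], params: LinkingParams) -> pd.DataFrame:
    """Tidy table of called intervals (one row per interval)."""
    rows = [
        {
            "chromosome": iv.chromosome,
            "start_cM": iv.start,
            "end_cM": iv.end,
            "n_markers": iv.n_markers,
            "peak_marker": iv.peak_marker,
            "peak_cM": iv.peak_position,
            "peak_neglog10p": iv.peak_neglog10p,
            "l": params.l,
            "threshold": params.threshold,
        }
        for iv in intervals
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "start_cM",
            "end_cM",
            "n_markers",
            "peak_marker",
            "peak_cM",
            "peak_neglog10p",
            "l",
            "threshold",
        ],
    )
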