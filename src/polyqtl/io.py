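"""Delimited-text readers and writers for every artifact format.

All tables are plain text with a header row; comma is the default
delimiter and tab is accepted on input. Lines starting with ``#`` are
comments; every writer can embed the producing command and seed as a
comment header, so outputs are self-describing. Read/write pairs are
inverses on valid files, and malformed rows are reported with their line
number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .population import PhasedPopulation

__all__ = [
    "read_map",
    "write_map",
    "read_phased",
    "write_phased",
    "read_dosage",
    "write_dosage",
    "read_phenotype",
    "write_phenotype",
    "write_scan",
    "read_scan",
    "write_intervals",
    "write_report",
    "read_report",
]

_STATE_CHARS = {"A": 0, "B": 1}
_STATE_NAMES = {0: "A", 1: "B"}


class FileFormatError(ValueError):
    """A schema violation in an input file, with the offending line number."""


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    raise FileFormatError(f"{path}: empty file")


def _read_table(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing required columns {missing}")
    return df


def _write_table(df: pd.DataFrame, path, header_comment: str | None = None, float_format=None):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format=float_format)


# -- genetic map -------------------------------------------------------------

def read_map(path) -> GeneticMap:
    df = _read_table(path, ["marker", "chromosome", "position_cM"])
    try:
        pos = df["position_cM"].astype(float)
    except ValueError as exc:
        raise FileFormatError(f"{path}: non-numeric position ({exc})") from None
    return GeneticMap(df["marker"].tolist(), df["chromosome"].tolist(), pos.tolist())


def write_map(gmap: GeneticMap, path, header_comment: str | None = None) -> None:
    _write_table(gmap.to_frame(), path, header_comment)


# -- phased populations ------------------------------------------------------

def write_phased(pop: PhasedPopulation, path, header_comment: str | None = None) -> None:
    """Long format: one row per (individual, marker), ``state:founder_label`` tokens."""
    n, ploidy, M = pop.snp.shape
    cols = {"individual": np.repeat(pop.names, M), "marker": np.tile(pop.gmap.names, n)}
    for h in range(ploidy):
        states = pop.snp[:, h, :].ravel()
        labels = pop.labels[:, h, :].ravel()
        cols[f"hom{h + 1}"] = [
            f"{_STATE_NAMES[int(s)]}:{int(l)}" for s, l in zip(states, labels)
        ]
    _write_table(pd.DataFrame(cols), path, header_comment)


def read_phased(path, gmap: GeneticMap, ploidy: int = 4) -> PhasedPopulation:
    hom_cols = [f"hom{h + 1}" for h in range(ploidy)]
    df = _read_table(path, ["individual", "marker"] + hom_cols)
    names = list(dict.fromkeys(df["individual"]))
    name_idx = {x: i for i, x in enumerate(names)}
    M = gmap.n_markers
    snp = np.zeros((len(names), ploidy, M), dtype=np.uint8)
    labels = np.zeros((len(names), ploidy, M), dtype=np.int32)
    seen = np.zeros((len(names), M), dtype=bool)
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            i = name_idx[row.individual]
            m = gmap.index_of(row.marker)
            for h, col in enumerate(hom_cols):
                token = getattr(row, col)
                state, label = token.split(":")
                snp[i, h, m] = _STATE_CHARS[state]
                labels[i, h, m] = int(label)
            seen[i, m] = True
        except (KeyError, ValueError, AttributeError) as exc:
            raise FileFormatError(
                f"{path}: malformed row {row_no} ({type(exc).__name__}: {exc})"
            ) from None
    if not seen.all():
        i, m = np.argwhere(~seen)[0]
        raise FileFormatError(
            f"{path}: missing genotype for individual {names[i]!r} at marker "
            f"{gmap.names[m]!r}"
        )
    return PhasedPopulation(snp, labels, names, gmap)


# -- dosage matrices ---------------------------------------------------------

def write_dosage(
    dosages: np.ndarray,
    names: list[str],
    gmap: GeneticMap,
    path,
    header_comment: str | None = None,
) -> None:
    """Wide individual x marker integer matrix (0..ploidy)."""
    df = pd.DataFrame(np.asarray(dosages), index=pd.Index(names, name="individual"),
                      columns=gmap.names)
    _write_table(df.reset_index(), path, header_comment)


def read_dosage(path, ploidy: int = 4) -> tuple[np.ndarray, list[str], list[str]]:
    df = _read_table(path, ["individual"])
    names = df["individual"].tolist()
    markers = [c for c in df.columns if c != "individual"]
    try:
        mat = df[markers].astype(int).to_numpy()
    except ValueError as exc:
        raise FileFormatError(f"{path}: non-integer dosage ({exc})") from None
    bad = np.argwhere((mat < 0) | (mat > ploidy))
    if bad.size:
        i, j = bad[0]
        raise FileFormatError(
            f"{path}: row {i + 2}: dosage {mat[i, j]} outside [0, {ploidy}] "
            f"for individual {names[i]!r} at marker {markers[j]!r}"
        )
    return mat, names, markers


# -- phenotypes --------------------------------------------------------------

def write_phenotype(values: np.ndarray, names: list[str], path, header_comment=None) -> None:
    _write_table(pd.DataFrame({"individual": names, "value": values}), path, header_comment)


def read_phenotype(path, individuals: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Read phenotypes; with ``individuals`` given, align and require completeness."""
    df = _read_table(path, ["individual", "value"])
    try:
        vals = df["value"].astype(float)
    except ValueError as exc:
        raise FileFormatError(f"{path}: non-numeric phenotype ({exc})") from None
    series = pd.Series(vals.to_numpy(), index=df["individual"])
    if individuals is None:
        return series.to_numpy(), df["individual"].tolist()
    missing = [x for x in individuals if x not in series.index]
    if missing:
        raise FileFormatError(f"{path}: missing phenotype for individuals {missing[:10]}")
    return series.loc[individuals].to_numpy(), list(individuals)


# -- scans, intervals, reports ----------------------------------------------

def write_scan(result, path, header_comment=None) -> None:
    tab = result.table.copy()
    tab["model"] = result.model
    _write_table(tab, path, header_comment)


def read_scan(path):
    from .mixedmodel import ScanResult, VarianceComponents

    df = _read_table(path, ["locus", "chromosome", "position_cM", "neglog10p"])
    for col in ("position_cM", "F", "neglog10p"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "df1" in df.columns:
        df["df1"] = df["df1"].astype(float).astype(int)
    model = df["model"].iloc[0] if "model" in df.columns else "unknown"
    tab = df.drop(columns=[c for c in ("model",) if c in df.columns])
    return ScanResult(table=tab, model=str(model), vc=VarianceComponents(0.0, 1.0))


def write_intervals(intervals, params, path, header_comment=None) -> None:
    from .intervals import intervals_frame

    _write_table(intervals_frame(intervals, params), path, header_comment)


def write_report(df: pd.DataFrame, path, header_comment=None) -> None:
    _write_table(df, path, header_comment)


def read_report(path) -> pd.DataFrame:
    df = _read_table(path, [])
    for col in df.columns:
        if col in ("model", "error"):
            continue
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            pass
    return df


def write_effects(model, path, header_comment=None) -> None:
    """Audit dump of an effect model: one row per (locus, founder allele)."""
    rows = [
        {
            "locus_index": j,
            "marker_index": m,
            "kind": "major" if j < model.n_major else "polygenic",
            "allele": lab,
            "effect": eff,
        }
        for j, (m, d) in enumerate(zip(model.marker_idx, model.effects))
        for lab, eff in sorted(d.items())
    ]
    _write_table(pd.DataFrame(rows), path, header_comment)


def write_multiallelic(loci, path, header_comment=None, individuals=None) -> None:
    """Long-format export of multiallelic loci: locus,position,individual,allele,dosage."""
    rows = []
    for loc in loci:
        n = loc.dosages.shape[0]
        names = individuals if individuals is not None else [f"i{j}" for j in range(n)]
        for i in range(n):
            for a, allele in enumerate(loc.alleles):
                rows.append(
                    {
                        "locus": loc.name,
                        "position": loc.position,
                        "individual": names[i],
                        "allele": allele,
                        "dosage": int(loc.dosages[i, a]),
                    }
                )
    _write_table(pd.DataFrame(rows), path, header_comment)
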