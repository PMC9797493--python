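"""Readers, writers and configuration.

All tabular formats are header-bearing, tab-delimited, UTF-8, '.' decimal.
Deletion calls are written BED-like with 0-based half-open coordinates.
Readers raise line-numbered errors on malformed rows; every writer's
output re-reads to an identical in-memory table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .dosage import DeletionCall, RRDTable
from .genome import GenomeLayout, GenomicInterval

__all__ = [
    "PipelineConfig",
    "read_layout",
    "write_layout",
    "read_depth_table",
    "read_bin_table",
    "write_bin_table",
    "write_rrd_table",
    "read_rrd_table",
    "read_ct_table",
    "write_ct_table",
    "read_counts_table",
    "write_counts_table",
    "read_survival_table",
    "write_survival_table",
    "write_calls_bed",
]


class TableFormatError(ValueError):
    """A malformed row or header in a tabular input."""


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings; all defaults overridable."""

    layout_path: str | None = None
    bin_size: int = 100_000
    rrd_threshold: float = 0.8
    min_bins: int = 3
    gap: int = 0
    refine_boundaries: bool = True
    gene_lengths: dict[str, int] = field(
        default_factory=lambda: {"TT4": 1789, "TT8": 4643}
    )
    control_sample: str = "control"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise TableFormatError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------- layout

def read_layout(path: str | Path) -> GenomeLayout:
    """Genome layout from YAML: ``chromosomes`` (name/length rows) plus
    optional ``loci`` and ``amplicon_targets`` interval maps."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        chroms = [(str(c["name"]), int(c["length"])) for c in data["chromosomes"]]
    except (KeyError, TypeError) as exc:
        raise TableFormatError(f"{path}: bad chromosomes section: {exc}") from exc

    def intervals(key: str) -> dict[str, GenomicInterval]:
        out = {}
        for name, iv in (data.get(key) or {}).items():
            try:
                out[name] = GenomicInterval(
                    str(iv["chrom"]), int(iv["start"]), int(iv["end"])
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise TableFormatError(
                    f"{path}: bad {key} entry {name!r}: {exc}"
                ) from exc
        return out

    return GenomeLayout(
        chromosomes=chroms,
        loci=intervals("loci"),
        amplicon_targets=intervals("amplicon_targets"),
    )


def write_layout(layout: GenomeLayout, path: str | Path) -> None:
    data = {
        "chromosomes": [
            {"name": n, "length": int(ln)} for n, ln in layout.chromosomes
        ],
        "loci": {
            k: {"chrom": v.chrom, "start": v.start, "end": v.end}
            for k, v in layout.loci.items()
        },
        "amplicon_targets": {
            k: {"chrom": v.chrom, "start": v.start, "end": v.end}
            for k, v in layout.amplicon_targets.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------- tables

def _read_tsv(path: str | Path, columns: dict[str, type]) -> pd.DataFrame:
    """Strict TSV reader: exact header, typed columns, line-numbered errors."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise TableFormatError(f"{path}: cannot parse TSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    for col, typ in columns.items():
        if typ is str:
            continue
        for i, raw in enumerate(df[col]):
            try:
                typ(raw)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}, line {i + 2}: bad value {raw!r} in column {col!r}"
                ) from None
        df[col] = df[col].astype(typ)
    return df


def read_depth_table(path: str | Path, one_based: bool = True) -> pd.DataFrame:
    """Per-base depth TSV (``chrom, pos, depth``).  Positions are 1-based
    by default (the convention of common depth tools) and converted to
    0-based on read."""
    df = _read_tsv(path, {"chrom": str, "pos": int, "depth": float})
    if one_based:
        if (df["pos"] < 1).any():
            raise TableFormatError(f"{path}: 1-based positions must be >= 1")
        df["pos"] = df["pos"] - 1
    return df


def read_bin_table(path: str | Path) -> pd.DataFrame:
    """Pre-binned depth TSV (``chrom, start, end, mean_depth``),
    0-based half-open."""
    df = _read_tsv(
        path, {"chrom": str, "start": int, "end": int, "mean_depth": float}
    )
    if (df["end"] <= df["start"]).any():
        bad = int((df["end"] <= df["start"]).idxmax()) + 2
        raise TableFormatError(f"{path}, line {bad}: bin end must exceed start")
    return df


def read_depth_or_bins(path: str | Path) -> tuple[pd.DataFrame, bool]:
    """Auto-detect per-base (3-column) vs pre-binned (4-column) depth input.

    Returns ``(table, is_binned)``.
    """
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    if len(header) >= 4 and "mean_depth" in header:
        return read_bin_table(path), True
    return read_depth_table(path), False


def write_bin_table(bins: pd.DataFrame, path: str | Path) -> None:
    bins.to_csv(path, sep="\t", index=False)


def write_rrd_table(rrd: RRDTable, path: str | Path) -> None:
    out = rrd.bins.copy()
    out["normalization_constant"] = rrd.normalization_constant
    out.to_csv(path, sep="\t", index=False)


def read_rrd_table(path: str | Path) -> RRDTable:
    df = _read_tsv(
        path,
        {
            "chrom": str,
            "start": int,
            "end": int,
            "mean_depth": float,
            "rrd": float,
            "normalization_constant": float,
        },
    )
    norm = float(df["normalization_constant"].iloc[0])
    return RRDTable(
        bins=df.drop(columns=["normalization_constant"]),
        normalization_constant=norm,
    )


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path, {"sample": str, "target": str, "replicate": int, "ct": float}
    )
    if (df["ct"] <= 0).any():
        bad = int((df["ct"] <= 0).idxmax()) + 2
        raise TableFormatError(f"{path}, line {bad}: Ct must be positive")
    return df


def write_ct_table(cts: pd.DataFrame, path: str | Path) -> None:
    cts.to_csv(path, sep="\t", index=False)


def read_counts_table(path: str | Path) -> pd.DataFrame:
    """Screening counts TSV: one row per group
    (``group, n_observed, n_mutant, n_tt4, n_tt8``)."""
    return _read_tsv(
        path,
        {
            "group": str,
            "n_observed": int,
            "n_mutant": int,
            "n_tt4": int,
            "n_tt8": int,
        },
    )


def write_counts_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_survival_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(
        path, {"dose_gy": float, "n_total": int, "n_survived": int}
    )
    if (df["n_survived"] > df["n_total"]).any():
        bad = int((df["n_survived"] > df["n_total"]).idxmax()) + 2
        raise TableFormatError(
            f"{path}, line {bad}: n_survived exceeds n_total"
        )
    return df


def write_survival_table(data: pd.DataFrame, path: str | Path) -> None:
    data.to_csv(path, sep="\t", index=False)


def write_calls_bed(calls: list[DeletionCall], path: str | Path) -> None:
    """Deletion calls as BED-like TSV:
    ``chrom, start, end, name, mean_rrd, mutant_fraction_est``."""
    rows = [
        {
            "chrom": c.interval.chrom,
            "start": c.interval.start,
            "end": c.interval.end,
            "name": f"del_{c.interval.chrom}_{c.interval.start}",
            "mean_rrd": c.mean_rrd,
            "mutant_fraction_est": c.mutant_fraction_est,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "mean_rrd", "mutant_fraction_est"],
    ).to_csv(path, sep="\t", index=False)
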