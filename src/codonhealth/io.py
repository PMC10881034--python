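"""Readers/writers for the delimited table formats the toolkit consumes.

All tables are plain delimited text with headers; codons are uppercase DNA
(T, not U). Sequence I/O lives in :mod:`codonhealth.sequences`.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .bias import WeightTable
from .chi import FitnessRecord
from .plates import PlateTimeseries


def _read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; have {list(df.columns)}")
    if "codon" in df.columns:
        df["codon"] = df["codon"].str.strip().str.upper().str.replace("U", "T")
    return df


def read_weight_table(path: str | Path, label: str | None = None) -> WeightTable:
    """Read a ``codon,w`` delimited file into a :class:`WeightTable`."""
    df = _read_table(path, ["codon", "w"])
    if df["codon"].duplicated().any():
        dups = df.loc[df["codon"].duplicated(), "codon"].tolist()
        raise ValueError(f"{path}: duplicate codon rows {dups}")
    return WeightTable(
        weights=dict(zip(df["codon"], df["w"].astype(float))),
        label=label or Path(path).stem,
    )


def write_weight_table(w: WeightTable, path: str | Path) -> None:
    pd.DataFrame(
        {"codon": sorted(w.weights), "W": [w.weights[c] for c in sorted(w.weights)]}
    ).to_csv(path, index=False)


def read_frequency_table(path: str | Path) -> dict[str, float]:
    """Read a ``codon,freq`` delimited file (genomic codon frequencies)."""
    df = _read_table(path, ["codon", "freq"])
    return dict(zip(df["codon"], df["freq"].astype(float)))


def read_codon_times(path: str | Path) -> dict[str, float]:
    """Read a ``codon,time`` elongation-time table (time units per codon)."""
    df = _read_table(path, ["codon", "time"])
    return dict(zip(df["codon"], df["time"].astype(float)))


def read_fitness_table(path: str | Path) -> list[FitnessRecord]:
    """Read per-codon Co-Expression Fitness pairs ``codon,c,m[,is_parent]``."""
    df = _read_table(path, ["codon", "c", "m"])
    has_parent = "is_parent" in df.columns
    return [
        FitnessRecord(
            codon=row.codon,
            c=float(row.c),
            m=float(row.m),
            is_parent=bool(getattr(row, "is_parent", False)) if has_parent else False,
        )
        for row in df.itertuples()
    ]


def write_fitness_table(records: list[FitnessRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "codon": [r.codon for r in records],
            "c": [r.c for r in records],
            "m": [r.m for r in records],
            "is_parent": [int(r.is_parent) for r in records],
        }
    ).to_csv(path, index=False)


def read_operon_membership(path: str | Path) -> dict[str, list[str]]:
    """Read ``operon_id,gene_id`` rows into operon → ordered gene ids."""
    df = _read_table(path, ["operon_id", "gene_id"])
    out: dict[str, list[str]] = {}
    for row in df.itertuples():
        out.setdefault(str(row.operon_id), []).append(str(row.gene_id))
    return out


def read_plate_long(
    path: str | Path, meta_path: str | Path | None = None
) -> dict[tuple[str, str], PlateTimeseries]:
    """Read long-format plate data ``well,condition,channel,time,value``.

    Returns a map (well, condition) → :class:`PlateTimeseries`. The
    optional JSON metadata file supplies per-channel ``background`` and
    ``upper_limit`` scalars applied to every series.
    """
    df = _read_table(path, ["well", "condition", "channel", "time", "value"])
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    background = meta.get("background", {})
    upper_limit = meta.get("upper_limit", {})
    out: dict[tuple[str, str], PlateTimeseries] = {}
    for (well, cond), grp in df.groupby(["well", "condition"], sort=True):
        signals = {}
        time = None
        for ch, sub in grp.groupby("channel"):
            sub = sub.sort_values("time")
            if time is None:
                time = sub["time"].to_numpy()
            signals[ch] = sub["value"].to_numpy()
        out[(str(well), str(cond))] = PlateTimeseries(
            time=time,
            signals=signals,
            condition=str(cond),
            background=background,
            upper_limit=upper_limit,
        )
    return out


def write_plate_long(
    series: dict[tuple[str, str], PlateTimeseries], path: str | Path
) -> None:
    rows = []
    for (well, cond), ts in series.items():
        for ch, y in ts.signals.items():
            for t, v in zip(ts.time, y):
                rows.append((well, cond, ch, t, v))
    pd.DataFrame(
        rows, columns=["well", "condition", "channel", "time", "value"]
    ).to_csv(path, index=False)
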