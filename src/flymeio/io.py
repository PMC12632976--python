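"""Readers and writers for the tab-separated dialects of each assay.

All tabular files are UTF-8 TSV with a single header row.  Schema
violations raise :class:`~flymeio.markers.SchemaError` naming the file
and offending column/value.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .enrichment import SpectralCountTable
from .markers import (
    MISSING,
    CrossoverClassCounts,
    MarkerMap,
    ProgenyRecord,
    SchemaError,
)
from .ndj import NdjTally

__all__ = [
    "read_marker_map",
    "read_progeny_tsv",
    "write_progeny_tsv",
    "read_class_counts",
    "write_class_counts",
    "read_ndj_tallies",
    "read_germaria_tsv",
    "read_foci_tsv",
    "read_spectral_tsv",
    "write_spectral_tsv",
]


def read_marker_map(path: str | Path) -> MarkerMap:
    """Marker-map config: YAML or JSON with chromosome label + locus list."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return MarkerMap(
            chromosome_label=str(data["chromosome_label"]),
            loci=tuple(data["loci"]),
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: invalid marker map config ({exc})") from exc


def read_progeny_tsv(path: str | Path, marker_map: MarkerMap) -> list[ProgenyRecord]:
    """Progeny TSV: progeny_id, sex, then one P/R/NA column per locus."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna(MISSING)
    needed = ["progeny_id", "sex", *marker_map.loci]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = set(df.columns) - set(needed)
    if extra:
        raise SchemaError(
            f"{path}: unknown locus columns {sorted(extra)} "
            f"(map defines {list(marker_map.loci)})"
        )
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ProgenyRecord(
                    progeny_id=row["progeny_id"],
                    sex=row["sex"],
                    calls={l: row[l] for l in marker_map.loci},
                )
            )
        except SchemaError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from exc
    return records


def write_progeny_tsv(
    records: Sequence[ProgenyRecord], marker_map: MarkerMap, path: str | Path
) -> None:
    rows = [
        {"progeny_id": r.progeny_id, "sex": r.sex,
         **{l: r.calls.get(l, MISSING) for l in marker_map.loci}}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_class_counts(path: str | Path) -> CrossoverClassCounts:
    """Class-count TSV with columns k, count."""
    df = pd.read_csv(path, sep="\t")
    if not {"k", "count"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns k, count")
    return CrossoverClassCounts(dict(zip(df["k"].astype(int), df["count"].astype(int))))


def write_class_counts(counts: CrossoverClassCounts, path: str | Path) -> None:
    ks = sorted(range(counts.max_class + 1))
    pd.DataFrame(
        {"k": ks, "count": [counts.counts.get(k, 0) for k in ks]}
    ).to_csv(path, sep="\t", index=False)


def read_ndj_tallies(path: str | Path) -> dict[str, NdjTally]:
    """NDJ tally TSV keyed by genotype."""
    df = pd.read_csv(path, sep="\t")
    need = {"genotype", "regular_females", "regular_males", "diplo_X",
            "nullo_X", "n_parent_females"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(need)}")
    out = {}
    for _, row in df.iterrows():
        out[str(row["genotype"])] = NdjTally(
            regular_females=int(row["regular_females"]),
            regular_males=int(row["regular_males"]),
            diplo_X=int(row["diplo_X"]),
            nullo_X=int(row["nullo_X"]),
            n_parent_females=int(row["n_parent_females"]),
        )
    return out


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def read_germaria_tsv(path: str | Path):
    """Germarium TSV: germarium_id plus boolean flag columns (blank = NA)."""
    from .cytology import GermariumObservation

    df = pd.read_csv(path, sep="\t", dtype=str)
    if "germarium_id" not in df.columns:
        raise SchemaError(f"{path}: missing column germarium_id")
    flags = [
        "full_length_SC_2A", "SC_maintained_region3",
        "gH2Av_present_2A", "gH2Av_present_region3", "underdeveloped",
    ]
    obs = []
    for i, row in df.iterrows():
        kw = {}
        for f in flags:
            if f not in df.columns:
                continue
            v = row[f]
            if pd.isna(v) or v == "" or v.upper() == "NA":
                kw[f] = None
            elif v.lower() in _BOOL:
                kw[f] = _BOOL[v.lower()]
            else:
                raise SchemaError(f"{path}: line {i + 2}: column {f}: "
                                  f"invalid boolean {v!r}")
        obs.append(GermariumObservation(germarium_id=row["germarium_id"], **kw))
    return obs


def read_foci_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"genotype", "region", "count"}
    if not need <= set(df.columns):
        raise SchemaError(f"{path}: expected columns {sorted(need)}")
    df["region"] = df["region"].astype(str)
    df["count"] = df["count"].astype(int)
    return df


def read_spectral_tsv(path: str | Path) -> SpectralCountTable:
    """Spectral-count TSV.

    Columns: ``protein_id``, ``length``, per-sample unique counts
    ``u_<sample>``, and optional shared counts ``s_<sample>:<group>``
    together with a ``shared_group`` membership column (group id or
    blank).  Shared counts for one group must be identical across its
    member rows (they are stored per group).
    """
    df = pd.read_csv(path, sep="\t")
    if not {"protein_id", "length"} <= set(df.columns):
        raise SchemaError(f"{path}: expected columns protein_id, length")
    df = df.set_index("protein_id")
    u_cols = [c for c in df.columns if c.startswith("u_")]
    if not u_cols:
        raise SchemaError(f"{path}: no unique-count columns (u_<sample>)")
    samples = [c[2:] for c in u_cols]
    unique = df[u_cols].astype(int)
    unique.columns = samples

    groups: dict[str, tuple[str, ...]] = {}
    shared_counts = None
    if "shared_group" in df.columns:
        gser = df["shared_group"].dropna()
        gser = gser[gser.astype(str) != ""]
        if len(gser):
            groups = {
                str(g): tuple(members.index)
                for g, members in gser.groupby(gser)
            }
            rows = {}
            for g, members in groups.items():
                row = {}
                for s in samples:
                    col = f"s_{s}"
                    if col not in df.columns:
                        raise SchemaError(f"{path}: shared groups present but "
                                          f"column {col} missing")
                    vals = df.loc[list(members), col].astype(float)
                    if vals.nunique() > 1:
                        raise SchemaError(
                            f"{path}: group {g} has inconsistent shared "
                            f"counts in {col}"
                        )
                    row[s] = int(vals.iloc[0])
                rows[g] = row
            shared_counts = pd.DataFrame.from_dict(rows, orient="index")[samples]
    return SpectralCountTable(
        lengths=df["length"].astype(int),
        unique=unique,
        shared_groups=groups,
        shared_counts=shared_counts,
    )


def write_spectral_tsv(table: SpectralCountTable, path: str | Path) -> None:
    df = pd.DataFrame({"length": table.lengths})
    for s in table.samples:
        df[f"u_{s}"] = table.unique[s]
    if table.shared_groups:
        member_of = {}
        for g, members in table.shared_groups.items():
            for m in members:
                member_of[m] = g
        df["shared_group"] = pd.Series(member_of).reindex(df.index)
        for s in table.samples:
            col = pd.Series(0, index=df.index)
            for g, members in table.shared_groups.items():
                col.loc[list(members)] = int(table.shared_counts.loc[g, s])
            df[f"s_{s}"] = col
    df.index.name = "protein_id"
    df.reset_index().to_csv(path, sep="\t", index=False)
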