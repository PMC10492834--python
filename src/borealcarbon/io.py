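"""Typed CSV round-tripping for the survey tables.

Each table has a declared schema (mandatory columns and dtypes). Unknown
columns pass through untouched; schema violations are reported with the
offending column (and row, for value errors) named.
"""
from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError
from .records import CarbonPools, PlotSurvey, SoilProfileRecord, TreeRecord

PLOTS_SCHEMA = {
    "plot_id": str,
    "x": float,
    "y": float,
    "radius": float,
    "moisture_class": "Int64",
    "stand_age": float,
    "wetness": float,
}
PROFILES_SCHEMA = {
    "plot_id": str,
    "organic_thickness": float,
    "organic_core_dry_mass": float,
    "organic_core_c_conc": float,
    "organic_sampled_area": float,
    "c_conc_0_10": float,
    "c_conc_10_20": float,
    "c_conc_55_65": float,
    # penetration_1 .. penetration_12 appended programmatically
}
TREES_SCHEMA = {
    "plot_id": str,
    "species": str,
    "dbh": float,
    "height": float,  # blank when not measured
    "height_measured": bool,
}
SOIL_POOLS_SCHEMA = {
    "plot_id": str,
    "organic": float,
    "mineral": float,
    "total_soc": float,
    "is_peat": bool,
}
TREE_POOLS_SCHEMA = {
    "plot_id": str,
    "tree_above": float,
    "tree_below": float,
    "tree_total": float,
}
ALS_POINTS_SCHEMA = {"cell_id": str, "height": float}

_PEN_COLS = [f"penetration_{i}" for i in range(1, 13)]


def read_table(path, schema: Dict[str, type]) -> pd.DataFrame:
    """Read a comma-delimited UTF-8 table and validate it against a schema."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    for col, typ in schema.items():
        if typ is str:
            continue
        raw = df[col]
        blank = raw.str.strip() == ""
        if typ is bool:
            bad = ~blank & ~raw.str.lower().isin(["true", "false", "0", "1"])
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
                raise SchemaError(f"{path}: non-boolean value in column '{col}' at line {row}")
            df[col] = raw.str.lower().isin(["true", "1"]) & ~blank
            continue
        converted = pd.to_numeric(raw.where(~blank, None), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2
            raise SchemaError(
                f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column '{col}' at line {row}"
            )
        df[col] = converted.astype("Int64" if typ == "Int64" else float)
    return df


def write_table(df: pd.DataFrame, path, schema: Optional[Dict[str, type]] = None) -> None:
    if schema is not None:
        missing = [c for c in schema if c not in df.columns]
        if missing:
            raise SchemaError(f"refusing to write {path}: missing column(s) {missing}")
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# record <-> frame conversion


def plots_to_frame(plots: Sequence[PlotSurvey]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "x": [p.x for p in plots],
            "y": [p.y for p in plots],
            "radius": [p.radius for p in plots],
            "moisture_class": pd.array([p.moisture_class for p in plots], dtype="Int64"),
            "stand_age": [p.stand_age for p in plots],
            "wetness": [p.wetness for p in plots],
        }
    )


def frame_to_plots(df: pd.DataFrame) -> List[PlotSurvey]:
    out = []
    for row in df.itertuples(index=False):
        mc = getattr(row, "moisture_class", None)
        out.append(
            PlotSurvey(
                plot_id=row.plot_id,
                x=row.x,
                y=row.y,
                radius=row.radius,
                moisture_class=None if pd.isna(mc) else int(mc),
                stand_age=None if pd.isna(row.stand_age) else float(row.stand_age),
                wetness=None if pd.isna(row.wetness) else float(row.wetness),
            )
        )
    return out


def profiles_to_frame(profiles: Sequence[SoilProfileRecord]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        layers = {(t, b): c for t, b, c in p.mineral_layers}
        row = {
            "plot_id": p.plot_id,
            "organic_thickness": p.organic_thickness,
            "organic_core_dry_mass": p.organic_core_dry_mass,
            "organic_core_c_conc": p.organic_core_c_conc,
            "organic_sampled_area": p.organic_sampled_area,
            "c_conc_0_10": layers.get((0.0, 10.0), math.nan),
            "c_conc_10_20": layers.get((10.0, 20.0), math.nan),
            "c_conc_55_65": layers.get((55.0, 65.0), math.nan),
        }
        for i, col in enumerate(_PEN_COLS):
            row[col] = p.penetration_depths[i] if i < len(p.penetration_depths) else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_profiles(df: pd.DataFrame) -> List[SoilProfileRecord]:
    out = []
    for row in df.itertuples(index=False):
        layers = []
        for (t, b), col in [
            ((0.0, 10.0), "c_conc_0_10"),
            ((10.0, 20.0), "c_conc_10_20"),
            ((55.0, 65.0), "c_conc_55_65"),
        ]:
            val = getattr(row, col)
            if not pd.isna(val):
                layers.append((t, b, float(val)))
        pens = tuple(
            float(getattr(row, col)) for col in _PEN_COLS if not pd.isna(getattr(row, col))
        )
        out.append(
            SoilProfileRecord(
                plot_id=row.plot_id,
                organic_thickness=float(row.organic_thickness),
                organic_core_dry_mass=float(row.organic_core_dry_mass),
                organic_core_c_conc=float(row.organic_core_c_conc),
                organic_sampled_area=float(row.organic_sampled_area),
                mineral_layers=layers,
                penetration_depths=pens,
            )
        )
    return out


def trees_to_frame(trees: Sequence[TreeRecord], measured_heights_only: bool = True) -> pd.DataFrame:
    """Tree list to table. With ``measured_heights_only`` (the survey
    convention) only field-measured heights are written; the rest are left
    blank for the imputation stage."""
    heights = []
    for t in trees:
        if t.height is None or (measured_heights_only and not t.height_measured):
            heights.append(math.nan)
        else:
            heights.append(t.height)
    return pd.DataFrame(
        {
            "plot_id": [t.plot_id for t in trees],
            "species": [t.species for t in trees],
            "dbh": [t.dbh for t in trees],
            "height": heights,
            "height_measured": [t.height_measured for t in trees],
        }
    )


def frame_to_trees(df: pd.DataFrame) -> List[TreeRecord]:
    out = []
    for row in df.itertuples(index=False):
        h = None if pd.isna(row.height) else float(row.height)
        out.append(
            TreeRecord(
                plot_id=row.plot_id,
                species=row.species,
                dbh=float(row.dbh),
                height=h,
                height_measured=bool(row.height_measured),
            )
        )
    return out


def als_points_to_frame(points: Dict[str, np.ndarray]) -> pd.DataFrame:
    cells, heights = [], []
    for cid, arr in points.items():
        cells.extend([cid] * len(arr))
        heights.extend(map(float, arr))
    return pd.DataFrame({"cell_id": cells, "height": heights})


def frame_to_als_points(df: pd.DataFrame) -> Dict[str, np.ndarray]:
    return {
        str(cid): grp["height"].to_numpy(float) for cid, grp in df.groupby("cell_id", sort=True)
    }


def pools_to_frame(pools: Sequence[CarbonPools]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in pools],
            "organic": [p.organic for p in pools],
            "mineral": [p.mineral for p in pools],
            "total_soc": [p.total_soc for p in pools],
            "tree_above": [p.tree_above for p in pools],
            "tree_below": [p.tree_below for p in pools],
            "tree_total": [p.tree_total for p in pools],
            "is_peat": [p.is_peat for p in pools],
        }
    )
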