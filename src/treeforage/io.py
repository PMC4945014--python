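"""Readers and writers for the pipeline's tabular formats.

All tables are plain CSV. The supplementary-style tree table ("s2
dialect") has columns ``PSRI`` (untransformed senescence index),
``Tree.stage`` (0 unused, 1 foraging, 2 other behaviour), ``Time`` (step
along the route) and ``Route``; it may arrive as CSV or XLSX.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

TREE_REQUIRED = ["tree_id", "x", "y", "di", "species", "dbh", "height"]
ROUTE_REQUIRED = [
    "route_id", "woodpecker_id", "step", "tree_id",
    "arrival_min", "departure_min", "behavior", "family_size",
]
S2_REQUIRED = ["PSRI", "Tree.stage", "Time", "Route"]


class TableParseError(ValueError):
    """A required column is missing or a value violates the table contract."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")


def read_trees(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TREE_REQUIRED, path)
    for col in ("x", "y", "di", "dbh", "height"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise TableParseError(f"{path}: non-numeric value in column {col!r} row {row}")
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise TableParseError(f"{path}: missing value in column {col!r} row {row}")
        df[col] = vals
    if not np.isfinite(df[["x", "y", "di"]].to_numpy()).all():
        raise TableParseError(f"{path}: non-finite coordinate or decay index")
    if (df[["dbh", "height"]] <= 0).any().any():
        raise TableParseError(f"{path}: dbh and height must be positive")
    if df["tree_id"].duplicated().any():
        dup = df.loc[df["tree_id"].duplicated(), "tree_id"].iloc[0]
        raise TableParseError(f"{path}: duplicate tree_id {dup}")
    return df


def read_routes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ROUTE_REQUIRED, path)
    if "censored" not in df.columns:
        df["censored"] = False
    dup = df.duplicated(subset=["route_id", "step"])
    if dup.any():
        r = df.loc[dup, ["route_id", "step"]].iloc[0]
        raise TableParseError(
            f"{path}: duplicate (route_id, step) = ({r['route_id']}, {r['step']})")
    bad_t = df["departure_min"] < df["arrival_min"]
    if bad_t.any():
        raise TableParseError(f"{path}: departure before arrival at row {int(bad_t.idxmax())}")
    bad_b = ~df["behavior"].isin(["F", "O"])
    if bad_b.any():
        raise TableParseError(f"{path}: behavior must be F or O at row {int(bad_b.idxmax())}")
    for route_id, grp in df.groupby("route_id"):
        steps = np.sort(grp["step"].to_numpy())
        if not np.array_equal(steps, np.arange(1, len(steps) + 1)):
            raise TableParseError(f"{path}: route {route_id} has non-contiguous steps")
        ordered = grp.sort_values("step")["tree_id"].to_numpy()
        same = ordered[1:] == ordered[:-1]
        if same.any():
            raise TableParseError(
                f"{path}: route {route_id} reuses a tree on consecutive steps")
    return df


def read_s2(path) -> pd.DataFrame:
    """Read a supplementary-style tree table (CSV or XLSX)."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    _require_columns(df, S2_REQUIRED, path)
    stage = pd.to_numeric(df["Tree.stage"], errors="coerce")
    bad = ~stage.isin([0, 1, 2])
    if bad.any():
        raise TableParseError(
            f"{path}: Tree.stage must be 0, 1 or 2 (row {int(bad.idxmax())})")
    df["Tree.stage"] = stage.astype(int)
    return df


def s2_counts(df: pd.DataFrame) -> dict:
    """Summary counts of a supplementary-style tree table."""
    used = df["Tree.stage"].isin([1, 2])
    per_route_used = df.loc[used].groupby("Route")["Tree.stage"].size()
    return {
        "n_total": int(len(df)),
        "n_used": int(used.sum()),
        "n_foraging": int((df["Tree.stage"] == 1).sum()),
        "n_routes": int(df["Route"].nunique()),
        "max_route_used": int(per_route_used.max()) if len(per_route_used) else 0,
    }


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
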