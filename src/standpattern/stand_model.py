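"""Domain types and plain-text I/O for stem maps, plot metadata and result tables.

A *stem map* is a per-tree table of plot-local coordinates (metres, origin at
the lower-left corner of the plot window) together with the three biometric
marks used throughout the package: tree height TH (m), diameter at breast
height DBH (cm) and crown diameter CD (m).  Plots are axis-aligned rectangular
windows, by default 50 m x 50 m, grouped into three river transects
(upper / middle / lower) at increasing distance from the river channel.

All files are comma-separated UTF-8 text with a mandatory header row and "."
as decimal separator; plot metadata is YAML.  Every reader validates fully
before returning: a malformed input raises a typed error, never a partial
silent load.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "StandModelError",
    "SchemaError",
    "ValidationError",
    "ParseError",
    "Window",
    "TreeRecord",
    "PlotData",
    "TRANSECTS",
    "transect_from_plot_id",
    "read_tree_table",
    "write_tree_table",
    "read_plot_metadata",
    "write_plot_metadata",
    "attach_trees",
    "write_results",
    "read_results",
    "TREE_TABLE_COLUMNS",
]


class StandModelError(Exception):
    """Base class for stem-map input errors."""


class SchemaError(StandModelError):
    """A required column or key is missing."""


class ValidationError(StandModelError):
    """A value violates a domain invariant (range, uniqueness, window)."""


class ParseError(StandModelError):
    """A cell could not be parsed as the expected type."""


TRANSECTS = ("upper", "middle", "lower")
_TRANSECT_PREFIX = {"U": "upper", "M": "middle", "L": "lower"}

ABIOTIC_KEYS = ("gd", "sm", "sc", "ph")


@dataclass(frozen=True)
class Window:
    """Axis-aligned rectangular plot window, coordinates in metres.

    The window is closed: points exactly on the boundary belong to it.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValidationError(
                f"degenerate window [{self.x_min}, {self.x_max}] x "
                f"[{self.y_min}, {self.y_max}]"
            )

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        """Window area in square metres."""
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        """Window area in hectares."""
        return self.area / 10_000.0

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max


#: Default 50 m x 50 m quadrat.
DEFAULT_WINDOW = Window(0.0, 50.0, 0.0, 50.0)


@dataclass(frozen=True)
class TreeRecord:
    """One stem: plot-local position plus biometric marks.

    th
        tree height (m), > 0 (the survey detects trees taller than 1.5 m,
        but the type only enforces positivity).
    dbh
        diameter at breast height (cm), > 0.
    cd
        crown diameter (m), >= 0 (0 = unknown / no measurable crown).
    """

    tree_id: str
    x: float
    y: float
    th: float
    dbh: float
    cd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("x", "y", "th", "dbh", "cd"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v)):
                raise ValidationError(f"tree {self.tree_id}: {name}={v!r} not finite")
        if self.dbh <= 0:
            raise ValidationError(f"tree {self.tree_id}: dbh must be > 0, got {self.dbh}")
        if self.th <= 0:
            raise ValidationError(f"tree {self.tree_id}: th must be > 0, got {self.th}")
        if self.cd < 0:
            raise ValidationError(f"tree {self.tree_id}: cd must be >= 0, got {self.cd}")


@dataclass
class PlotData:
    """A plot: window, trees and abiotic covariates.

    ``abiotic`` maps gd (groundwater depth, m), sm (soil moisture),
    sc (soil conductance) and ph to floats; a missing measurement is an
    explicit ``None``, never a silent zero.
    """

    plot_id: str
    transect: str
    distance_from_river: float
    altitude: float | None = None
    window: Window = DEFAULT_WINDOW
    trees: list[TreeRecord] = field(default_factory=list)
    abiotic: dict[str, float | None] = field(
        default_factory=lambda: {k: None for k in ABIOTIC_KEYS}
    )

    def __post_init__(self) -> None:
        if self.transect not in TRANSECTS:
            raise ValidationError(
                f"plot {self.plot_id}: unknown transect {self.transect!r} "
                f"(expected one of {TRANSECTS})"
            )
        for k in ABIOTIC_KEYS:
            self.abiotic.setdefault(k, None)
        self.validate_trees()

    @property
    def n(self) -> int:
        return len(self.trees)

    def validate_trees(self) -> None:
        seen: set[str] = set()
        for t in self.trees:
            if t.tree_id in seen:
                raise ValidationError(
                    f"plot {self.plot_id}: duplicate tree_id {t.tree_id!r}"
                )
            seen.add(t.tree_id)
            if not self.window.contains(t.x, t.y):
                raise ValidationError(
                    f"plot {self.plot_id}, tree {t.tree_id}: position "
                    f"({t.x}, {t.y}) outside window"
                )

    def coords(self):
        """Tree positions as an (n, 2) float array."""
        import numpy as np

        if not self.trees:
            return np.empty((0, 2))
        return np.array([[t.x, t.y] for t in self.trees], dtype=float)


def transect_from_plot_id(plot_id: str) -> str:
    """Infer the transect from a plot id like ``U3`` / ``M1`` / ``L6``."""
    prefix = plot_id[:1].upper()
    try:
        return _TRANSECT_PREFIX[prefix]
    except KeyError:
        raise ValidationError(
            f"cannot infer transect from plot_id {plot_id!r}; expected a "
            "U/M/L prefix or an explicit 'transect' entry"
        ) from None


TREE_TABLE_COLUMNS = ("plot_id", "tree_id", "x_m", "y_m", "th_m", "dbh_cm", "cd_m")
_NUMERIC_TREE_COLUMNS = ("x_m", "y_m", "th_m", "dbh_cm", "cd_m")


def read_tree_table(path: str | Path, window: Window = DEFAULT_WINDOW) -> dict[str, list[TreeRecord]]:
    """Read a stem-table CSV into TreeRecords grouped by plot id.

    Record order within each plot is preserved.  Raises :class:`SchemaError`
    for a missing column, :class:`ParseError` (with 1-based data line number)
    for a non-numeric biometric cell and :class:`ValidationError` for a
    coordinate outside ``window`` or an invariant violation.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TREE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")

    numeric: dict[str, pd.Series] = {}
    for col in _NUMERIC_TREE_COLUMNS:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}, line {row + 2}: column {col} value "
                f"{df[col].iloc[row]!r} is not numeric"
            )
        numeric[col] = parsed

    grouped: dict[str, list[TreeRecord]] = {}
    for i in range(len(df)):
        plot_id = df["plot_id"].iloc[i]
        rec = TreeRecord(
            tree_id=df["tree_id"].iloc[i],
            x=float(numeric["x_m"].iloc[i]),
            y=float(numeric["y_m"].iloc[i]),
            th=float(numeric["th_m"].iloc[i]),
            dbh=float(numeric["dbh_cm"].iloc[i]),
            cd=float(numeric["cd_m"].iloc[i]),
        )
        if not window.contains(rec.x, rec.y):
            raise ValidationError(
                f"{path}: plot {plot_id}, tree {rec.tree_id}: position "
                f"({rec.x}, {rec.y}) outside window "
                f"[{window.x_min}, {window.x_max}] x [{window.y_min}, {window.y_max}]"
            )
        grouped.setdefault(plot_id, []).append(rec)

    for plot_id, trees in grouped.items():
        ids = [t.tree_id for t in trees]
        if len(set(ids)) != len(ids):
            dup = next(t for t in ids if ids.count(t) > 1)
            raise ValidationError(f"{path}: plot {plot_id}: duplicate tree_id {dup!r}")
    return grouped


def write_tree_table(trees_by_plot: Mapping[str, Sequence[TreeRecord]], path: str | Path) -> Path:
    """Write TreeRecords grouped by plot to a stem-table CSV (inverse of the reader)."""
    path = Path(path)
    rows = []
    for plot_id, trees in trees_by_plot.items():
        for t in trees:
            rows.append((plot_id, t.tree_id, t.x, t.y, t.th, t.dbh, t.cd))
    df = pd.DataFrame(rows, columns=list(TREE_TABLE_COLUMNS))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_plot_metadata(path: str | Path) -> list[PlotData]:
    """Read plot metadata YAML into PlotData shells (no trees attached).

    The file holds a list of plot entries (optionally under a top-level
    ``plots`` key) with keys plot_id, transect (optional, inferred from the
    U/M/L id prefix if absent), distance_from_river_m, altitude_m and the
    abiotic measurements gd_m, sm, sc, ph (missing -> explicit None).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if raw is None:
        logger.warning("%s: empty plot metadata file, returning empty study", path)
        return []
    entries = raw.get("plots", raw) if isinstance(raw, dict) else raw
    if not isinstance(entries, list):
        raise SchemaError(f"{path}: expected a list of plot entries")

    plots: list[PlotData] = []
    seen: set[str] = set()
    for entry in entries:
        if "plot_id" not in entry:
            raise SchemaError(f"{path}: plot entry without plot_id: {entry!r}")
        plot_id = str(entry["plot_id"])
        if plot_id in seen:
            raise ValidationError(f"{path}: duplicate plot_id {plot_id!r}")
        seen.add(plot_id)
        transect = entry.get("transect") or transect_from_plot_id(plot_id)
        if transect not in TRANSECTS:
            raise ValidationError(
                f"{path}: plot {plot_id}: unknown transect {transect!r}"
            )
        if "distance_from_river_m" not in entry:
            raise SchemaError(f"{path}: plot {plot_id}: missing distance_from_river_m")
        abiotic = {
            "gd": _opt_float(entry.get("gd_m")),
            "sm": _opt_float(entry.get("sm")),
            "sc": _opt_float(entry.get("sc")),
            "ph": _opt_float(entry.get("ph")),
        }
        plots.append(
            PlotData(
                plot_id=plot_id,
                transect=transect,
                distance_from_river=float(entry["distance_from_river_m"]),
                altitude=_opt_float(entry.get("altitude_m")),
                window=DEFAULT_WINDOW,
                trees=[],
                abiotic=abiotic,
            )
        )
    return plots


def _opt_float(v) -> float | None:
    return None if v is None else float(v)


def write_plot_metadata(plots: Sequence[PlotData], path: str | Path) -> Path:
    """Write PlotData metadata (no trees) to YAML, inverse of the reader."""
    path = Path(path)
    entries = []
    for p in plots:
        entry: dict = {
            "plot_id": p.plot_id,
            "transect": p.transect,
            "distance_from_river_m": float(p.distance_from_river),
        }
        if p.altitude is not None:
            entry["altitude_m"] = float(p.altitude)
        for key, col in (("gd", "gd_m"), ("sm", "sm"), ("sc", "sc"), ("ph", "ph")):
            v = p.abiotic.get(key)
            entry[col] = None if v is None else float(v)
        entries.append(entry)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump({"plots": entries}, sort_keys=False), encoding="utf-8")
    return path


def attach_trees(
    shells: Sequence[PlotData], trees_by_plot: Mapping[str, Sequence[TreeRecord]]
) -> list[PlotData]:
    """Join metadata shells with a read stem table; validates each plot."""
    known = {p.plot_id for p in shells}
    orphans = set(trees_by_plot) - known
    if orphans:
        raise ValidationError(
            f"stem table references unknown plot(s): {sorted(orphans)}"
        )
    out = []
    for p in shells:
        out.append(
            PlotData(
                plot_id=p.plot_id,
                transect=p.transect,
                distance_from_river=p.distance_from_river,
                altitude=p.altitude,
                window=p.window,
                trees=list(trees_by_plot.get(p.plot_id, [])),
                abiotic=dict(p.abiotic),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

#: Default rounding (decimal places) applied by the writer, by column suffix.
#: Indices are reported to 2 d.p., percentages to 1 d.p., counts as integers.


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    decimals: Mapping[str, int] | None = None,
) -> dict[str, Path]:
    """Write each result table as ``<name>.csv`` under ``out_dir``.

    ``decimals`` maps column name -> decimal places; matching columns are
    rounded before writing so that write -> read -> write is byte-identical.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise StandModelError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        df = df.copy()
        if decimals:
            for col, nd in decimals.items():
                if col in df.columns:
                    df[col] = pd.to_numeric(df[col]).round(nd)
        target = out_dir / f"{name}.csv"
        df.to_csv(target, index=False)
        paths[name] = target
    return paths


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a result table written by :func:`write_results`."""
    return pd.read_csv(path)
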