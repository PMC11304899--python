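"""Typed tabular data model for remeasured regeneration-indicator inventories.

The interchange format is a set of UTF-8 CSV tables (see ``schema.yaml``):
``plots``, ``subplots``, ``conditions``, ``trees``, ``seedlings``,
``saplings``.  A plot carries exactly four subplots, each with one microplot
in which seedlings are tallied over six ordered height classes and sapling
presence is recorded at two measurement times.  Site attributes live on
mapped *conditions*, each covering a stated proportion of the plot.

This module provides readers/writers with invariant validation, the
plot-selection filters used to restrict analysis to fully surveyed,
undisturbed-by-harvest plots, condition-to-plot assignment, and plot-level
carbon aggregation (live by species, standing dead, downed woody material).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, IntegrityError, SchemaError

HEIGHT_CLASS_COLUMNS = tuple(f"count_class{i}" for i in range(1, 7))
N_HEIGHT_CLASSES = 6
N_SUBPLOTS = 4
TABLE_NAMES = ("plots", "subplots", "conditions", "trees", "seedlings", "saplings")

_BOOL_MAP = {"True": True, "False": False, "true": True, "false": False,
             "1": True, "0": False, True: True, False: False}


@functools.lru_cache(maxsize=1)
def load_schema() -> dict:
    """Load the packaged machine-readable table schema."""
    path = Path(__file__).with_name("schema.yaml")
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plot:
    plot_id: str
    latitude: float
    longitude: float
    elevation: float
    subplot_ids: tuple[int, ...]
    time1: float
    time2: float

    @property
    def interval_years(self) -> float:
        return self.time2 - self.time1


@dataclass(frozen=True)
class Condition:
    condition_id: str
    plot_id: str
    proportion: float
    forest_type_group: str
    forest_type: str
    stand_age: float
    physiographic_class: str
    slope: float
    aspect: float
    ownership: str
    disturbance: str
    at_plot_center: bool
    accessible_forest: bool
    artificial_regeneration: bool
    dwm_sampled: bool
    dwm_carbon: float


@dataclass(frozen=True)
class SeedlingTally:
    plot_id: str
    subplot: int
    species: str
    time: int
    counts: tuple[int, ...]

    def __post_init__(self):
        if len(self.counts) != N_HEIGHT_CLASSES:
            raise DataError(f"seedling tally needs {N_HEIGHT_CLASSES} height classes")
        if any(c < 0 for c in self.counts):
            raise DataError("negative seedling count")


@dataclass(frozen=True)
class PlotCarbon:
    """Plot-level aboveground carbon pools, Mg C per hectare."""
    plot_id: str
    time: int
    live_by_species: dict[str, float] = field(default_factory=dict)
    snag_total: float = 0.0
    dwm_total: float = 0.0

    @property
    def live_total(self) -> float:
        return float(sum(self.live_by_species.values()))

    @property
    def grand_total(self) -> float:
        return self.live_total + self.snag_total + self.dwm_total


# ---------------------------------------------------------------------------
# Tables container + validation
# ---------------------------------------------------------------------------

@dataclass
class InventoryTables:
    plots: pd.DataFrame
    subplots: pd.DataFrame
    conditions: pd.DataFrame
    trees: pd.DataFrame
    seedlings: pd.DataFrame
    saplings: pd.DataFrame

    def __getitem__(self, name: str) -> pd.DataFrame:
        return getattr(self, name)

    def copy(self) -> "InventoryTables":
        return InventoryTables(**{n: self[n].copy() for n in TABLE_NAMES})

    def validate(self) -> list[str]:
        """Collect invariant violations; each message carries table + row."""
        return _collect_issues(self)


def _require_columns(df: pd.DataFrame, table: str) -> None:
    spec = load_schema()["tables"][table]["columns"]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{table}' missing column(s): {', '.join(missing)}")


def _coerce(df: pd.DataFrame, table: str) -> pd.DataFrame:
    spec = load_schema()["tables"][table]["columns"]
    out = df.copy()
    for col, meta in spec.items():
        dtype = meta["dtype"]
        try:
            if dtype == "bool":
                out[col] = out[col].map(_BOOL_MAP).astype(bool)
            elif dtype == "int":
                out[col] = out[col].astype(np.int64)
            elif dtype == "float":
                out[col] = out[col].astype(float)
            else:
                out[col] = out[col].astype(str)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"table '{table}', column '{col}': {exc}") from exc
    return out


def _collect_issues(tables: InventoryTables) -> list[str]:
    issues: list[str] = []

    def flag(table: str, rows: Iterable[int], msg: str) -> None:
        for r in rows:
            issues.append(f"{table} row {r}: {msg}")

    plots, subplots, conditions = tables.plots, tables.subplots, tables.conditions
    trees, seedlings, saplings = tables.trees, tables.seedlings, tables.saplings

    if plots.plot_id.duplicated().any():
        flag("plots", plots.index[plots.plot_id.duplicated()], "duplicate plot_id")
    bad = plots.index[plots.interval_years <= 0]
    flag("plots", bad, "interval_years must be > 0")
    bad = plots.index[~np.isclose(plots.time2 - plots.time1, plots.interval_years, atol=1e-6)]
    flag("plots", bad, "interval_years inconsistent with time1/time2")

    counts = subplots.groupby("plot_id").size()
    for pid in counts.index[counts != N_SUBPLOTS]:
        flag("subplots", subplots.index[subplots.plot_id == pid][:1],
             f"plot {pid} has {counts[pid]} subplots, expected {N_SUBPLOTS}")

    sums = conditions.groupby("plot_id")["proportion"].sum()
    for pid in sums.index[~np.isclose(sums, 1.0, atol=1e-6)]:
        flag("conditions", conditions.index[conditions.plot_id == pid][:1],
             f"plot {pid} condition proportions sum to {sums[pid]:.6f}, expected 1")
    centers = conditions.groupby("plot_id")["at_plot_center"].sum()
    for pid in centers.index[centers != 1]:
        flag("conditions", conditions.index[conditions.plot_id == pid][:1],
             f"plot {pid} has {centers[pid]} plot-center conditions, expected 1")

    flag("trees", trees.index[trees.dbh < 12.7], "subplot tree dbh below 12.7 cm")
    flag("trees", trees.index[trees.agc_kg < 0], "negative aboveground carbon")
    flag("trees", trees.index[~trees.time.isin([1, 2])], "time must be 1 or 2")
    flag("trees", trees.index[~trees.status.isin(["live", "standing_dead", "cut"])],
         "unknown tree status")

    for col in HEIGHT_CLASS_COLUMNS:
        flag("seedlings", seedlings.index[seedlings[col] < 0], f"negative {col}")
    flag("seedlings", seedlings.index[~seedlings.time.isin([1, 2])], "time must be 1 or 2")

    t2 = saplings[saplings.time == 2]
    flag("saplings", t2.index[t2.newly_recruited & ~t2.present],
         "newly_recruited implies present at time 2")
    t1 = saplings[saplings.time == 1]
    flag("saplings", t1.index[t1.newly_recruited],
         "newly_recruited is only defined at time 2")

    return issues


def read_inventory(source: str | Path | Mapping[str, Path]) -> InventoryTables:
    """Read and validate the six inventory CSVs.

    ``source`` is a directory containing the schema's file names, or a
    mapping table name -> path.  Schema violations (missing columns, bad
    dtypes) raise :class:`SchemaError`; cross-row invariant violations raise
    :class:`IntegrityError` listing every offending row.
    """
    schema = load_schema()["tables"]
    frames = {}
    for name in TABLE_NAMES:
        if isinstance(source, Mapping):
            path = Path(source[name])
        else:
            path = Path(source) / schema[name]["file"]
        if not path.exists():
            raise SchemaError(f"missing inventory file: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _require_columns(df, name)
        frames[name] = _coerce(df, name)
    tables = InventoryTables(**frames)
    issues = tables.validate()
    if issues:
        raise IntegrityError("inventory invariant violations:\n" + "\n".join(issues))
    return tables


def write_inventory(tables: InventoryTables, directory: str | Path) -> dict[str, Path]:
    """Write the six tables as CSV; returns table name -> path.

    Floats are formatted with ``%.10g`` so identical tables produce
    byte-identical files.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    schema = load_schema()["tables"]
    paths = {}
    for name in TABLE_NAMES:
        path = directory / schema[name]["file"]
        cols = list(schema[name]["columns"])
        tables[name].to_csv(path, index=False, columns=cols, float_format="%.10g")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# Plot selection
# ---------------------------------------------------------------------------

def filter_plots(tables: InventoryTables) -> set[str]:
    """Plots meeting all five selection criteria.

    (1) regeneration-indicator seedling surveys on all four subplots at both
    times; (2) every condition on accessible forest land; (3) no artificial
    regeneration; (4) downed-woody-material sampling complete on every
    condition; (5) no trees cut and removed in the most recent measurement.
    An empty result is allowed.
    """
    sp = tables.subplots
    ok_survey = (
        sp.groupby("plot_id")
        .apply(lambda g: len(g) == N_SUBPLOTS
               and bool(g.ri_surveyed_time1.all() and g.ri_surveyed_time2.all()),
               include_groups=False)
    )
    surveyed = set(ok_survey.index[ok_survey])

    cond = tables.conditions.groupby("plot_id").agg(
        accessible=("accessible_forest", "all"),
        artificial=("artificial_regeneration", "any"),
        dwm=("dwm_sampled", "all"),
    )
    ok_cond = set(cond.index[cond.accessible & ~cond.artificial & cond.dwm])

    cut_t2 = set(tables.trees.loc[
        (tables.trees.status == "cut") & (tables.trees.time == 2), "plot_id"])

    return (set(tables.plots.plot_id) & surveyed & ok_cond) - cut_t2


def assign_plot_condition(plot_id: str, conditions: pd.DataFrame) -> pd.Series:
    """The condition representing the plot: largest proportion, plot-center
    condition on an exact tie."""
    sub = conditions[conditions.plot_id == plot_id]
    if sub.empty:
        raise DataError(f"plot {plot_id} has no conditions")
    best = sub.proportion.max()
    top = sub[np.abs(sub.proportion - best) < 1e-12]
    if len(top) > 1 and top.at_plot_center.any():
        top = top[top.at_plot_center]
    return top.iloc[0]


def plot_condition_table(tables: InventoryTables,
                         plot_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Per-plot site covariates: plot columns joined with the assigned
    condition's attributes.  Indexed by plot_id."""
    plots = tables.plots
    if plot_ids is not None:
        keep = set(plot_ids)
        plots = plots[plots.plot_id.isin(keep)]
    rows = []
    for _, p in plots.iterrows():
        c = assign_plot_condition(p.plot_id, tables.conditions)
        rows.append({
            "plot_id": p.plot_id, "latitude": p.latitude, "longitude": p.longitude,
            "elevation": p.elevation, "interval_years": p.interval_years,
            "mat_c": p.mat_c, "map_mm": p.map_mm, "vpd_hpa": p.vpd_hpa,
            "forest_type_group": c.forest_type_group, "forest_type": c.forest_type,
            "stand_age": c.stand_age, "physiographic_class": c.physiographic_class,
            "slope": c.slope, "aspect": c.aspect, "ownership": c.ownership,
            "disturbance": c.disturbance,
        })
    return pd.DataFrame(rows).set_index("plot_id")


# ---------------------------------------------------------------------------
# Carbon aggregation
# ---------------------------------------------------------------------------

def plot_carbon(tables: InventoryTables, plot_id: str, time: int) -> PlotCarbon:
    """Aggregate per-stem carbon to the plot, in Mg C per hectare.

    Live carbon is summed by species as agc * expansion (kg/ha -> Mg/ha);
    standing-dead stems use the same expansion logic; downed woody material
    is the proportion-weighted mean of condition-level values.
    """
    trees = tables.trees
    sub = trees[(trees.plot_id == plot_id) & (trees.time == time)]
    if (sub.agc_kg < 0).any():
        raise DataError(f"plot {plot_id}: negative per-stem carbon")
    mg_ha = sub.agc_kg * sub.expansion / 1000.0
    live = sub[sub.status == "live"]
    live_by_species = (mg_ha[live.index].groupby(live.species).sum()).to_dict()
    snag_total = float(mg_ha[sub.index[sub.status == "standing_dead"]].sum())

    cond = tables.conditions[tables.conditions.plot_id == plot_id]
    dwm_total = float((cond.dwm_carbon * cond.proportion).sum())
    return PlotCarbon(plot_id=plot_id, time=time,
                      live_by_species={k: float(v) for k, v in live_by_species.items()},
                      snag_total=snag_total, dwm_total=dwm_total)


def plot_carbon_table(tables: InventoryTables, time: int,
                      plot_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Plot-level carbon pools for many plots (Mg C/ha), indexed by plot_id."""
    ids = list(plot_ids) if plot_ids is not None else list(tables.plots.plot_id)
    rows = []
    for pid in ids:
        pc = plot_carbon(tables, pid, time)
        rows.append({"plot_id": pid, "live_total": pc.live_total,
                     "snag_total": pc.snag_total, "dwm_total": pc.dwm_total,
                     "grand_total": pc.grand_total})
    return pd.DataFrame(rows).set_index("plot_id")


def live_species_carbon(tables: InventoryTables, time: int,
                        plot_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Long table (plot_id, species, mg_ha) of live aboveground carbon."""
    trees = tables.trees
    sub = trees[(trees.time == time) & (trees.status == "live")]
    if plot_ids is not None:
        sub = sub[sub.plot_id.isin(set(plot_ids))]
    mg = (sub.agc_kg * sub.expansion / 1000.0).rename("mg_ha")
    out = (pd.concat([sub[["plot_id", "species"]], mg], axis=1)
           .groupby(["plot_id", "species"], as_index=False)["mg_ha"].sum())
    return out


def carbon_change_rate(c1: PlotCarbon, c2: PlotCarbon, interval_years: float) -> float:
    """Live-carbon change rate (Mg C/ha/yr) between two measurements."""
    if interval_years <= 0:
        raise DataError("remeasurement interval must be positive")
    return (c2.live_total - c1.live_total) / interval_years
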