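"""Landscape-scale indicators from categorical land-cover partitions.

Land cover follows a broad EUNIS-style classification with land-use
intensity qualifiers:

====== ==============================================
code   class
====== ==============================================
J      settlement
H      barren land
C      water
G      forest
D      wetland
E_int  intensive grassland (mown/grazed > 3×/year)
E_ext  extensive grassland, flower strips, fallows
I      crops
FB     shrub plantation
O_int  intensive (low-stem) orchard
O_hs   high-stem orchard (traditional silvopastoral)
====== ==============================================

Agricultural area comprises {E_int, E_ext, I, FB, O_int, O_hs};
intensively used agricultural land {I, E_int, O_int}; semi-natural
habitat {D, E_ext, O_hs, G}.  Spatial overlay is out of scope: paired
partitions must already share a tessellation (unit_id join); field
polygons may group several tessellation units via ``field_id``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_ORDER = ("J", "H", "C", "G", "D", "E_int", "E_ext", "I", "FB", "O_int", "O_hs")

AGRI_CLASSES = frozenset({"E_int", "E_ext", "I", "FB", "O_int", "O_hs"})
INTENSIVE_CLASSES = frozenset({"I", "E_int", "O_int"})
SEMI_NATURAL_CLASSES = frozenset({"D", "E_ext", "O_hs", "G"})

#: mapping protocol's minimal areal unit, ha (25 m²)
MIN_UNIT_HA = 25e-4


@dataclass
class LandCoverPartition:
    """Labeled areal units (class, area) for one snapshot.

    Parameters
    ----------
    units : DataFrame
        Columns ``unit_id``, ``class_code``, ``area_ha`` and optionally
        ``field_id`` (polygon membership for field-size statistics;
        defaults to unit_id).
    period : str
        Snapshot label (e.g. a year).
    total_study_area : float
        Total landscape area in ha; unit areas must not exceed it.
    """

    units: pd.DataFrame
    period: str
    total_study_area: float

    def __post_init__(self) -> None:
        df = self.units.copy()
        required = {"unit_id", "class_code", "area_ha"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"land cover table missing columns: {sorted(missing)}")
        unknown = sorted(set(df["class_code"]) - set(CLASS_ORDER))
        if unknown:
            raise ValueError(f"unknown land cover classes: {unknown}")
        if (df["area_ha"] < 0).any():
            raise ValueError("negative unit areas")
        if df["unit_id"].duplicated().any():
            raise ValueError("duplicate unit_ids")
        if "field_id" not in df.columns:
            df["field_id"] = df["unit_id"]
        total = df["area_ha"].sum()
        if total > self.total_study_area * (1 + 1e-9):
            raise ValueError(
                f"mapped area {total:.1f} ha exceeds study area {self.total_study_area} ha"
            )
        tiny = df["area_ha"] < MIN_UNIT_HA
        if tiny.any():
            warnings.warn(
                f"{int(tiny.sum())} areal units below the 25 m² minimal mapping unit",
                stacklevel=2,
            )
        self.units = df.reset_index(drop=True)

    def class_areas(self) -> pd.Series:
        areas = self.units.groupby("class_code")["area_ha"].sum()
        return areas.reindex(CLASS_ORDER, fill_value=0.0)

    def area_of(self, classes) -> float:
        sub = self.units[self.units["class_code"].isin(set(classes))]
        return float(sub["area_ha"].sum())


@dataclass
class TreeInventory:
    """Point inventory of field trees for one snapshot.

    Trees carry a size class: ``small`` (2–5 m canopy diameter) or
    ``large`` (> 5 m).
    """

    trees: pd.DataFrame  # columns tree_id, size_class [, parcel_id]
    period: str

    SIZE_CLASSES = ("small", "large")

    def __post_init__(self) -> None:
        df = self.trees.copy()
        required = {"tree_id", "size_class"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"tree table missing columns: {sorted(missing)}")
        bad = sorted(set(df["size_class"]) - set(self.SIZE_CLASSES))
        if bad:
            raise ValueError(f"unknown tree size classes: {bad}")
        if df["tree_id"].duplicated().any():
            raise ValueError("duplicate tree_ids")
        self.trees = df.reset_index(drop=True)

    def counts(self) -> dict[str, int]:
        by_class = self.trees["size_class"].value_counts()
        out = {c: int(by_class.get(c, 0)) for c in self.SIZE_CLASSES}
        out["total"] = len(self.trees)
        return out


@dataclass(frozen=True)
class TransitionMatrix:
    """Class × class area cross-tabulation between two snapshots."""

    table: pd.DataFrame  # rows: class at t0, columns: class at t1, ha

    def __post_init__(self) -> None:
        if (self.table.to_numpy() < -1e-9).any():
            raise ValueError("negative transition areas")

    @property
    def total_area(self) -> float:
        return float(self.table.to_numpy().sum())

    def persistent_area(self) -> float:
        return float(np.trace(self.table.to_numpy()))

    def row_sums(self) -> pd.Series:
        return self.table.sum(axis=1)

    def col_sums(self) -> pd.Series:
        return self.table.sum(axis=0)

    def to_csv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf)


def transition_matrix(map_t0: LandCoverPartition, map_t1: LandCoverPartition) -> TransitionMatrix:
    """Cross-tabulate area by (class at t0, class at t1) over shared units.

    Row sums equal class areas at t0, column sums class areas at t1, and
    the total equals the shared mapped area (area conservation).
    """
    u0 = map_t0.units.set_index("unit_id")
    u1 = map_t1.units.set_index("unit_id")
    sym_diff = set(u0.index).symmetric_difference(u1.index)
    if sym_diff:
        raise ValueError(
            f"partitions do not share a tessellation; mismatched unit_ids: "
            f"{sorted(sym_diff)[:10]}{'...' if len(sym_diff) > 10 else ''}"
        )
    mismatch = (u0["area_ha"] - u1.loc[u0.index, "area_ha"]).abs()
    if (mismatch > 1e-6).any():
        raise ValueError("shared units must cover the same area in both periods")
    joined = pd.DataFrame(
        {
            "from": u0["class_code"],
            "to": u1.loc[u0.index, "class_code"],
            "area_ha": u0["area_ha"],
        }
    )
    table = joined.pivot_table(
        index="from", columns="to", values="area_ha", aggfunc="sum", fill_value=0.0
    ).reindex(index=CLASS_ORDER, columns=CLASS_ORDER, fill_value=0.0)
    table.index.name = "from"
    table.columns.name = "to"
    return TransitionMatrix(table)


def mean_intensive_field_size(partition: LandCoverPartition) -> float:
    """Arithmetic mean polygon size (ha) of crops, intensive grassland and
    intensive orchards; NaN when the map has no such polygon."""
    sub = partition.units[partition.units["class_code"].isin(INTENSIVE_CLASSES)]
    if sub.empty:
        return float("nan")
    fields = sub.groupby("field_id")["area_ha"].sum()
    return float(fields.mean())


def proportion_intensive(partition: LandCoverPartition, denominator: str = "agricultural") -> float:
    """Percentage of intensively used agricultural land.

    ``denominator="agricultural"`` (default) relates the intensive area to
    the total agricultural area, matching the printed landscape series;
    ``denominator="study_area"`` relates it to the total study area.
    """
    intensive = partition.area_of(INTENSIVE_CLASSES)
    if denominator == "agricultural":
        agri = partition.area_of(AGRI_CLASSES)
        return 100.0 * intensive / agri if agri > 0 else 0.0
    if denominator == "study_area":
        if partition.total_study_area <= 0:
            raise ValueError("total_study_area must be positive")
        return 100.0 * intensive / partition.total_study_area
    raise ValueError(f"unknown denominator {denominator!r}")


def semi_natural_share(partition: LandCoverPartition) -> float:
    """Percentage of the study area covered by semi-natural habitat
    (wetlands, extensively managed land, high-stem orchards, forest)."""
    if partition.total_study_area <= 0:
        raise ValueError("total_study_area must be positive")
    return 100.0 * partition.area_of(SEMI_NATURAL_CLASSES) / partition.total_study_area


def classify_high_stem_orchard(parcel_area: float, field_tree_count: int) -> bool:
    """High-stem orchard rule: at least 3 field trees and a density
    strictly above 20 trees per hectare."""
    if parcel_area <= 0:
        raise ValueError("parcel_area must be positive")
    return field_tree_count >= 3 and field_tree_count / parcel_area > 20.0


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def tree_count_change(inv_t0: TreeInventory, inv_t1: TreeInventory) -> pd.DataFrame:
    """Per-size-class and total tree counts with integer percent change
    (rounded half away from zero); percent change is NaN from an empty
    baseline."""
    c0, c1 = inv_t0.counts(), inv_t1.counts()
    rows = []
    for key in ("small", "large", "total"):
        n0, n1 = c0[key], c1[key]
        pct = _round_half_away(100.0 * (n1 - n0) / n0) if n0 > 0 else float("nan")
        rows.append({"size_class": key, "n_t0": n0, "n_t1": n1, "pct_change": pct})
    return pd.DataFrame(rows).set_index("size_class")


def landscape_indicator_series(
    maps: tuple[LandCoverPartition, LandCoverPartition],
    trees: tuple[TreeInventory, TreeInventory] | None = None,
) -> dict[str, tuple[float, float]]:
    """Landscape indicator values (v0, v1) feeding the observed-change
    matrix: total agricultural area, average intensive field size,
    proportion intensive, semi-natural share."""
    m0, m1 = maps
    series = {
        "total_agri_area": (m0.area_of(AGRI_CLASSES), m1.area_of(AGRI_CLASSES)),
        "avg_field_size": (mean_intensive_field_size(m0), mean_intensive_field_size(m1)),
        "prop_intensive": (proportion_intensive(m0), proportion_intensive(m1)),
        "semi_natural": (semi_natural_share(m0), semi_natural_share(m1)),
    }
    if series["total_agri_area"] == (0.0, 0.0):
        warnings.warn("maps contain no agricultural classes; all-zero series", stacklevel=2)
    return series
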