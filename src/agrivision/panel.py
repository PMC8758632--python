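"""Farm indicator panel: long-format farm × indicator × period values.

A :class:`FarmPanel` holds one record per (farm, indicator, period) where
period is ``t0``/``t1`` for quantitative indicators and ``trend`` for
Likert-trend indicators (value coded −1/0/+1).  One-time indicators are
stored as a single ``t1`` record.  Missingness is allowed everywhere and
must propagate — a farm without both periods yields no change code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .registry import BOUNDED_PERCENT, NONNEGATIVE, REGISTRY, IndicatorRegistry

PERIODS = ("t0", "t1", "trend")
LIKERT_CODES = (-1, 0, 1)


class PanelValidationError(ValueError):
    """Raised when a panel violates the schema or indicator constraints."""


class FarmPanel:
    """Long-format panel of indicator values for a farm cohort.

    Parameters
    ----------
    records : DataFrame
        Columns ``farm_id``, ``indicator_id``, ``period``, ``value``.
    registry : IndicatorRegistry, optional
        Indicator definitions used for validation; defaults to the bundled
        registry.
    """

    def __init__(self, records: pd.DataFrame, registry: IndicatorRegistry | None = None):
        self.registry = registry if registry is not None else REGISTRY
        required = {"farm_id", "indicator_id", "period", "value"}
        missing = required - set(records.columns)
        if missing:
            raise PanelValidationError(f"panel missing columns: {sorted(missing)}")
        df = records.loc[:, ["farm_id", "indicator_id", "period", "value"]].copy()
        df["farm_id"] = df["farm_id"].astype(str)
        df["indicator_id"] = df["indicator_id"].astype(str)
        df["period"] = df["period"].astype(str)
        df["value"] = pd.to_numeric(df["value"], errors="coerce")
        df = df.dropna(subset=["value"]).reset_index(drop=True)
        self.records = df
        self._validate()

    # -- validation ----------------------------------------------------

    def _validate(self) -> None:
        df = self.records
        unknown = sorted(set(df["indicator_id"]) - set(self.registry.ids))
        if unknown:
            raise PanelValidationError(f"unknown indicator ids in panel: {unknown}")
        bad_period = sorted(set(df["period"]) - set(PERIODS))
        if bad_period:
            raise PanelValidationError(f"unknown periods: {bad_period}")

        dup = df.duplicated(subset=["farm_id", "indicator_id", "period"])
        if dup.any():
            rows = df.loc[dup, ["farm_id", "indicator_id", "period"]].head()
            raise PanelValidationError(f"duplicate (farm, indicator, period) records:\n{rows}")

        for ind_id, sub in df.groupby("indicator_id"):
            kind = self.registry[ind_id].kind
            if kind == "quantitative":
                if (sub["period"] == "trend").any():
                    raise PanelValidationError(
                        f"quantitative indicator {ind_id} has trend records"
                    )
            elif kind == "likert_trend":
                if (sub["period"] != "trend").any():
                    raise PanelValidationError(
                        f"likert indicator {ind_id} has non-trend records"
                    )
                if not sub["value"].isin(LIKERT_CODES).all():
                    raise PanelValidationError(
                        f"likert indicator {ind_id} has values outside {{-1,0,+1}}"
                    )
            else:  # one_time
                if (sub["period"] != "t1").any():
                    raise PanelValidationError(
                        f"one_time indicator {ind_id} must carry only t1 records"
                    )
            if ind_id in NONNEGATIVE and (sub["value"] < 0).any():
                raise PanelValidationError(f"negative values for {ind_id}")
            if ind_id in BOUNDED_PERCENT and (sub["value"] > 100).any():
                raise PanelValidationError(f"percentage values above 100 for {ind_id}")

    # -- accessors -----------------------------------------------------

    @property
    def farm_ids(self) -> list[str]:
        return sorted(self.records["farm_id"].unique())

    @property
    def n_farms(self) -> int:
        return self.records["farm_id"].nunique()

    def wide(self, indicator_id: str) -> pd.DataFrame:
        """Farm-indexed t0/t1 table for one quantitative indicator."""
        sub = self.records[self.records["indicator_id"] == indicator_id]
        return sub.pivot(index="farm_id", columns="period", values="value")

    def trend_codes(self, indicator_id: str) -> pd.Series:
        sub = self.records[
            (self.records["indicator_id"] == indicator_id)
            & (self.records["period"] == "trend")
        ]
        return sub.set_index("farm_id")["value"].astype(int)

    # -- I/O -----------------------------------------------------------

    def to_csv(self, path_or_buf=None):
        return self.records.to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, source, registry: IndicatorRegistry | None = None) -> "FarmPanel":
        return cls(pd.read_csv(source), registry=registry)


# ---------------------------------------------------------------------
# Derived indicators
# ---------------------------------------------------------------------

class DegenerateInputError(ValueError):
    """Raised when a raw farm record makes a derived indicator undefined."""


def derive_indicators(raw: dict, farm_id: str = "farm", period: str = "t0") -> list[dict]:
    """Compute derived indicators from raw interview answers for one period.

    Parameters
    ----------
    raw : dict
        May contain ``area_ha``, ``livestock_units``, ``crop_list``,
        ``livestock_list``, ``feed_pct``.
    Returns
    -------
    list of panel record dicts (farm_id, indicator_id, period, value).

    livestock_density = livestock_units / area_ha; crop and livestock
    diversity are counts of distinct entries.
    """
    rows: list[dict] = []

    def add(ind, value):
        rows.append({"farm_id": farm_id, "indicator_id": ind, "period": period, "value": value})

    if "area_ha" in raw:
        add("farm_area", float(raw["area_ha"]))
    if "livestock_units" in raw:
        add("livestock_units", float(raw["livestock_units"]))
    if "crop_list" in raw:
        add("crop_diversity", len(set(raw["crop_list"])))
    if "livestock_list" in raw:
        add("livestock_diversity", len(set(raw["livestock_list"])))
    if "feed_pct" in raw:
        add("feed_import", float(raw["feed_pct"]))
    if "area_ha" in raw and "livestock_units" in raw:
        area = float(raw["area_ha"])
        lu = float(raw["livestock_units"])
        if area <= 0:
            if lu != 0:
                raise DegenerateInputError(
                    f"farm {farm_id!r}: zero agricultural area with {lu} livestock units"
                )
            add("livestock_density", 0.0)
        else:
            add("livestock_density", lu / area)
    return rows


# ---------------------------------------------------------------------
# Panel summary (Table-2-style)
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class PanelSummary:
    """Per-indicator means, sample SDs (n−1 denominator), test p-value, n."""

    table: pd.DataFrame

    def row(self, indicator_id: str) -> pd.Series:
        return self.table.loc[indicator_id]


def summarize_panel(panel: FarmPanel) -> PanelSummary:
    """Summarize a panel per indicator: mean/SD per period, paired test, n.

    * quantitative indicators: mean ± sample SD at t0 and t1 over farms with
      data, paired Wilcoxon signed-rank p-value over farms with both
      periods, n = farms with both periods;
    * likert indicators: n = farms with a trend record and the share of
      −1/0/+1 answers;
    * indicators with zero observations get a row flagged missing.
    """
    from .changes import paired_wilcoxon  # local import; changes imports panel

    rows = []
    for d in panel.registry:
        rec = panel.records[panel.records["indicator_id"] == d.id]
        row = {
            "indicator_id": d.id,
            "mean_t0": np.nan,
            "sd_t0": np.nan,
            "mean_t1": np.nan,
            "sd_t1": np.nan,
            "p_value": np.nan,
            "n": 0,
            "missing": rec.empty,
        }
        if d.kind == "quantitative" and not rec.empty:
            wide = panel.wide(d.id)
            if "t0" in wide:
                row["mean_t0"] = wide["t0"].mean()
                row["sd_t0"] = wide["t0"].std(ddof=1)
            if "t1" in wide:
                row["mean_t1"] = wide["t1"].mean()
                row["sd_t1"] = wide["t1"].std(ddof=1)
            if {"t0", "t1"} <= set(wide.columns):
                paired = wide.dropna(subset=["t0", "t1"])
                row["n"] = len(paired)
                if len(paired) >= 5:
                    try:
                        row["p_value"] = paired_wilcoxon(
                            paired["t0"].to_numpy(), paired["t1"].to_numpy()
                        ).p_value
                    except ValueError:
                        pass
        elif d.kind == "likert_trend" and not rec.empty:
            codes = panel.trend_codes(d.id)
            row["n"] = len(codes)
            for code, label in ((-1, "share_decrease"), (0, "share_same"), (1, "share_increase")):
                row[label] = float((codes == code).mean()) if len(codes) else np.nan
        elif d.kind == "one_time" and not rec.empty:
            row["mean_t1"] = rec["value"].mean()
            row["n"] = rec["farm_id"].nunique()
        rows.append(row)
    table = pd.DataFrame(rows).set_index("indicator_id")
    return PanelSummary(table)
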