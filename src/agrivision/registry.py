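"""Indicator registry.

Agricultural development is tracked through 22 indicators spanning five
categories (farm-scale development, landscape-scale development, social,
economic, environmental) and two spatial scales (farm, landscape).  Three
measurement kinds occur:

``quantitative``
    a real value recorded at two time points (t0, t1);
``likert_trend``
    a single ordinal trend answer coded −1 (deteriorated), 0 (same),
    +1 (improved) — there is no underlying magnitude;
``one_time``
    a value recorded once (t1 only); its direction of change cannot be
    derived from the panel and must be supplied externally.

The bundled registry is loaded from ``data/indicators.csv`` and is the
single source of truth for indicator ids used by panels and vision
matrices.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import pandas as pd

CATEGORIES = ("farm_dev", "landscape_dev", "social", "economic", "environmental")
SCALES = ("farm", "landscape")
KINDS = ("quantitative", "likert_trend", "one_time")

#: share-type percentage indicators, bounded to [0, 100].  price_trend and
#: production_trend are index values relative to t0 (=100) and may exceed 100.
BOUNDED_PERCENT = frozenset(
    {
        "feed_import",
        "prop_intensive",
        "frac_over_50",
        "successor",
        "frac_owned_land",
        "off_farm_work",
        "ecological_focus_area",
        "semi_natural",
    }
)

#: indicators whose values are physically nonnegative (areas, counts,
#: percentages, densities).
NONNEGATIVE = frozenset(
    {
        "farm_area",
        "livestock_units",
        "crop_diversity",
        "livestock_diversity",
        "avg_field_size",
        "total_agri_area",
        "n_intensity",
        "pesticide_use",
        "livestock_density",
        "price_trend",
        "production_trend",
    }
    | BOUNDED_PERCENT
)


@dataclass(frozen=True)
class IndicatorDef:
    """Definition of one development indicator."""

    id: str
    name: str
    unit: str
    category: str
    scale: str
    kind: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for {self.id}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r} for {self.id}")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r} for {self.id}")


class IndicatorRegistry:
    """Ordered, id-indexed collection of :class:`IndicatorDef`."""

    def __init__(self, definitions: list[IndicatorDef]):
        ids = [d.id for d in definitions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate indicator ids: {dupes}")
        self._defs = list(definitions)
        self._by_id = {d.id: d for d in definitions}

    def __iter__(self):
        return iter(self._defs)

    def __len__(self) -> int:
        return len(self._defs)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def __getitem__(self, indicator_id: str) -> IndicatorDef:
        return self._by_id[indicator_id]

    @property
    def ids(self) -> list[str]:
        return [d.id for d in self._defs]

    def of_kind(self, kind: str) -> list[str]:
        return [d.id for d in self._defs if d.kind == kind]

    def of_category(self, category: str) -> list[str]:
        return [d.id for d in self._defs if d.category == category]

    def of_scale(self, scale: str) -> list[str]:
        return [d.id for d in self._defs if d.scale == scale]

    @property
    def landscape_ids(self) -> list[str]:
        return self.of_scale("landscape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": d.id,
                    "name": d.name,
                    "unit": d.unit,
                    "category": d.category,
                    "scale": d.scale,
                    "kind": d.kind,
                }
                for d in self._defs
            ]
        )

    def to_csv(self, path_or_buf=None):
        return self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_csv(cls, source) -> "IndicatorRegistry":
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, dtype=str)
        required = {"id", "name", "unit", "category", "scale", "kind"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"registry CSV missing columns: {sorted(missing)}")
        return cls([IndicatorDef(**row) for row in df[list(
            ["id", "name", "unit", "category", "scale", "kind"])].to_dict("records")])


def build_indicator_registry() -> IndicatorRegistry:
    """Return the bundled registry of the 22 development indicators.

    Categories partition the indicators 5/3/5/4/5 (farm development /
    landscape development / social / economic / environmental).
    """
    with resources.files("agrivision.data").joinpath("indicators.csv").open("r", encoding="utf-8") as fh:
        return IndicatorRegistry.from_csv(fh)


# module-level singleton; the registry is immutable in practice
REGISTRY = build_indicator_registry()
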