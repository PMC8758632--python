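"""Stakeholder visions: desired-change matrix and weights.

A vision assigns to every indicator a *desired change set* — a nonempty
subset of {−1, 0, +1} — and an importance weight in {0, 1, 2}.  Weight 2
marks changes central to the vision, weight 1 mentioned-or-implied, and
weight 0 not-applicable (the indicator plays no role for that
stakeholder; the desired set is then empty).  Set-valued desires encode
ambivalence: an "any" entry ({−1, 0, +1}) is compatible with every
outcome, and "0|+1" with stability or increase.

The bundled matrix (``data/visions.csv``) covers the three Swiss
stakeholder visions: AS (Avenir Suisse, market-liberal), SBV (Swiss
Farmers' Association, conservative) and LmZ (Landwirtschaft mit Zukunft,
agroecological).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .registry import REGISTRY, IndicatorRegistry

#: admissible desired-change sets (as sorted tuples)
_ALLOWED_SETS = {
    (-1,),
    (0,),
    (1,),
    (0, 1),
    (-1, 0, 1),
}

_DESIRED_TOKENS = {
    "+1": (1,),
    "1": (1,),
    "0": (0,),
    "-1": (-1,),
    "any": (-1, 0, 1),
    "-1/0/+1": (-1, 0, 1),
    "0|+1": (0, 1),
    "0/+1": (0, 1),
    "na": (),
    "": (),
}


def parse_desired(token: str) -> tuple[int, ...]:
    key = str(token).strip().replace(" ", "")
    if key not in _DESIRED_TOKENS:
        raise ValueError(f"unparseable desired-change token {token!r}")
    return _DESIRED_TOKENS[key]


def format_desired(desired: tuple[int, ...]) -> str:
    if not desired:
        return "na"
    if desired == (-1, 0, 1):
        return "any"
    if desired == (0, 1):
        return "0|+1"
    return {1: "+1", 0: "0", -1: "-1"}[desired[0]]


@dataclass
class VisionSpec:
    """One vision: per-indicator desired change set and weight."""

    vision_id: str
    desired: dict[str, tuple[int, ...]] = field(default_factory=dict)
    weights: dict[str, int] = field(default_factory=dict)
    registry: IndicatorRegistry = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.registry is None:
            self.registry = REGISTRY
        self.validate()

    def validate(self) -> None:
        ids = set(self.registry.ids)
        extra = sorted(set(self.desired) - ids)
        if extra:
            raise ValueError(f"vision {self.vision_id}: unknown indicators {extra}")
        missing = sorted(ids - set(self.desired))
        if missing:
            raise ValueError(f"vision {self.vision_id}: indicators without entry {missing}")
        for ind in self.registry.ids:
            w = self.weights.get(ind)
            d = tuple(sorted(self.desired[ind]))
            if w not in (0, 1, 2):
                raise ValueError(
                    f"vision {self.vision_id}, indicator {ind}: weight must be 0, 1 or 2, got {w}"
                )
            if w == 0:
                if d:
                    raise ValueError(
                        f"vision {self.vision_id}, indicator {ind}: weight 0 requires "
                        f"a not-applicable desired set"
                    )
            else:
                if not d:
                    raise ValueError(
                        f"vision {self.vision_id}, indicator {ind}: positive weight "
                        f"with empty desired set"
                    )
                if d not in _ALLOWED_SETS:
                    raise ValueError(
                        f"vision {self.vision_id}, indicator {ind}: desired set {d} "
                        f"not admissible"
                    )

    def applicable(self, indicator_id: str) -> bool:
        return self.weights.get(indicator_id, 0) > 0

    def reweighted(self, weight: int = 1) -> "VisionSpec":
        """Copy with every positive weight replaced (not-applicable stays 0)."""
        return VisionSpec(
            vision_id=self.vision_id,
            desired=dict(self.desired),
            weights={k: (weight if w > 0 else 0) for k, w in self.weights.items()},
            registry=self.registry,
        )

    def scaled(self, factor: int) -> "VisionSpec":
        """Copy with every weight multiplied by a positive integer factor.

        Only used to assert the weight-scale invariance of the agreement
        statistic; bypasses the {0,1,2} admissibility check.
        """
        out = VisionSpec.__new__(VisionSpec)
        out.vision_id = self.vision_id
        out.desired = dict(self.desired)
        out.weights = {k: w * factor for k, w in self.weights.items()}
        out.registry = self.registry
        return out


def potential_agreement(vision: VisionSpec, indicators=None) -> float:
    """Maximum achievable weighted distance: 2 × the sum of weights."""
    inds = vision.registry.ids if indicators is None else list(indicators)
    return 2.0 * sum(vision.weights.get(i, 0) for i in inds)


def weights_profile(vision: VisionSpec, dimensions=("social", "economic", "environmental")) -> dict:
    """Proportion of vision weight falling on each requested category.

    Defaults to the three sustainability outcome dimensions; a zero total
    weight over the requested dimensions yields ``None`` for every entry
    (undefined profile).
    """
    dims = list(dimensions)
    if not dims:
        raise ValueError("dimensions must be nonempty")
    sums = {
        c: float(sum(vision.weights.get(i, 0) for i in vision.registry.of_category(c)))
        for c in dims
    }
    total = sum(sums.values())
    if total == 0:
        return {c: None for c in dims}
    return {c: s / total for c, s in sums.items()}


def load_vision_matrix(source=None, registry: IndicatorRegistry | None = None) -> dict[str, VisionSpec]:
    """Load visions from a CSV (indicator_id,vision_id,desired,weight).

    With no source, loads the bundled three-vision matrix.  Returns a dict
    keyed by vision_id preserving first-appearance order.
    """
    registry = registry if registry is not None else REGISTRY
    if source is None:
        with resources.files("agrivision.data").joinpath("visions.csv").open(
            "r", encoding="utf-8"
        ) as fh:
            df = pd.read_csv(fh, dtype=str)
    else:
        if isinstance(source, str) and "\n" in source:
            source = io.StringIO(source)
        df = pd.read_csv(source, dtype=str)
    required = {"indicator_id", "vision_id", "desired", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"vision CSV missing columns: {sorted(missing)}")

    visions: dict[str, VisionSpec] = {}
    for vid in df["vision_id"].drop_duplicates():
        sub = df[df["vision_id"] == vid]
        desired: dict[str, tuple[int, ...]] = {}
        weights: dict[str, int] = {}
        for _, row in sub.iterrows():
            ind = row["indicator_id"]
            if ind in desired:
                raise ValueError(f"vision {vid}: duplicate row for indicator {ind}")
            try:
                weight = int(row["weight"])
            except (TypeError, ValueError):
                raise ValueError(
                    f"vision {vid}, indicator {ind}: unparseable weight {row['weight']!r}"
                ) from None
            desired[ind] = parse_desired(row["desired"])
            weights[ind] = weight
        visions[vid] = VisionSpec(vision_id=vid, desired=desired, weights=weights, registry=registry)
    return visions
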