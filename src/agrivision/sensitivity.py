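"""Sensitivity of agreement to the two key analysis assumptions.

The agreement statistic rests on (a) the no-change threshold used to
reclassify quantitative changes and (b) the importance weights of the
desired-change matrix.  The analysis re-runs the full pipeline while
(i) varying the threshold from 0 to 10% in 1% increments, (ii) setting
all positive weights to 1, and (iii) combining both, and asks whether
the per-vision median agreements — and above all their rank order —
are affected.

Medians use the midpoint convention (average of the two central order
statistics for even n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agreement import score_matrix
from .changes import build_observed_change_matrix
from .panel import FarmPanel
from .visions import VisionSpec

DEFAULT_GRID = tuple(np.round(np.arange(0.0, 0.101, 0.01), 3))


def _median_agreement(
    panel: FarmPanel,
    landscape_values,
    visions: dict[str, VisionSpec],
    threshold: float,
    one_time_codes=None,
) -> dict[str, float]:
    observed = build_observed_change_matrix(
        panel, landscape_values, threshold, one_time_codes=one_time_codes
    )
    scores = score_matrix(observed, visions)
    return {
        v: float(np.median(scores.loc[scores["vision_id"] == v, "agreement_pct"].dropna()))
        for v in visions
    }


@dataclass
class SensitivityResult:
    """Threshold sweep and equal-weights re-run of the agreement analysis.

    ``medians``: tidy frame (threshold, weights ∈ {baseline, equal},
    vision, median_agreement).  ``equal_weight_delta``: equal-weight minus
    baseline median at the baseline threshold, percentage points.
    """

    threshold_grid: tuple
    medians: pd.DataFrame
    baseline_threshold: float
    equal_weight_delta: dict

    def __post_init__(self) -> None:
        grid = np.asarray(self.threshold_grid, dtype=float)
        if len(grid) == 0:
            raise ValueError("threshold grid must be nonempty")
        if not (np.diff(grid) > 0).all():
            raise ValueError("threshold grid must be strictly increasing")

    def medians_at(self, threshold: float, weights: str = "baseline") -> dict[str, float]:
        sub = self.medians[
            (np.isclose(self.medians["threshold"], threshold))
            & (self.medians["weights"] == weights)
        ]
        return dict(zip(sub["vision_id"], sub["median_agreement"]))

    @property
    def rank_stable(self) -> bool:
        return rank_stability(self)[0]

    @property
    def ordering(self):
        return rank_stability(self)[1]


def _weak_order(medians: dict[str, float], tol: float = 1e-9):
    """Visions grouped by median, best first; ties form one group."""
    ordered = sorted(medians, key=lambda v: (-medians[v], v))
    groups: list[tuple[str, ...]] = []
    current: list[str] = []
    last = None
    for v in ordered:
        if last is not None and abs(medians[v] - last) > tol:
            groups.append(tuple(current))
            current = []
        current.append(v)
        last = medians[v]
    groups.append(tuple(current))
    return tuple(groups)


def threshold_sweep(
    panel: FarmPanel,
    landscape_values,
    visions: dict[str, VisionSpec],
    grid=DEFAULT_GRID,
    one_time_codes=None,
    baseline_threshold: float = 0.05,
    include_equal_weights: bool = True,
) -> SensitivityResult:
    """Re-run the observed-change matrix and all agreements at every grid
    threshold, under baseline and (optionally) equal weights."""
    grid = tuple(float(t) for t in grid)
    if len(grid) == 0:
        raise ValueError("threshold grid must be nonempty")
    if min(grid) < 0 or max(grid) > 0.5:
        raise ValueError("grid thresholds must lie in [0, 0.5]")
    schemes = {"baseline": visions}
    if include_equal_weights:
        schemes["equal"] = {v: spec.reweighted(1) for v, spec in visions.items()}
    rows = []
    for label, vis in schemes.items():
        for t in grid:
            med = _median_agreement(panel, landscape_values, vis, t, one_time_codes)
            for v, m in med.items():
                rows.append(
                    {"threshold": t, "weights": label, "vision_id": v, "median_agreement": m}
                )
    medians = pd.DataFrame(rows)

    delta = {}
    if include_equal_weights:
        base = _median_agreement(panel, landscape_values, visions, baseline_threshold, one_time_codes)
        equal = _median_agreement(
            panel, landscape_values, schemes["equal"], baseline_threshold, one_time_codes
        )
        delta = {v: equal[v] - base[v] for v in visions}
    return SensitivityResult(
        threshold_grid=grid,
        medians=medians,
        baseline_threshold=baseline_threshold,
        equal_weight_delta=delta,
    )


def equal_weights_rerun(
    panel: FarmPanel,
    landscape_values,
    visions: dict[str, VisionSpec],
    threshold: float = 0.05,
    one_time_codes=None,
) -> dict[str, float]:
    """Delta of per-vision median agreement when every positive weight is
    set to 1 (not-applicable entries stay 0), in percentage points."""
    base = _median_agreement(panel, landscape_values, visions, threshold, one_time_codes)
    equal_visions = {v: spec.reweighted(1) for v, spec in visions.items()}
    equal = _median_agreement(panel, landscape_values, equal_visions, threshold, one_time_codes)
    return {v: equal[v] - base[v] for v in visions}


def rank_stability(result: SensitivityResult):
    """True iff the (weak) ordering of visions by median agreement is the
    same at every grid point and under every weight scheme; also returns
    the baseline ordering (ties grouped)."""
    orders = set()
    baseline_order = None
    for (t, label), sub in result.medians.groupby(["threshold", "weights"]):
        med = dict(zip(sub["vision_id"], sub["median_agreement"]))
        order = _weak_order(med)
        orders.add(order)
        if label == "baseline" and np.isclose(t, result.baseline_threshold):
            baseline_order = order
    return (len(orders) == 1, baseline_order)
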