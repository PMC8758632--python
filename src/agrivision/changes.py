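"""Observed-change assessment.

Turns a two-timepoint panel into a reclassified observed-change matrix:
each (farm, indicator) cell is coded +1 (increase), 0 (no change) or −1
(decrease), where a quantitative indicator counts as unchanged when its
relative change does not exceed the no-change threshold (default 5%).
The threshold applies to *relative* change so that one rule covers
hectares, livestock units, counts and percentages alike.  Likert trend
answers are already direction codes and pass through untouched; landscape
indicators are reclassified once from landscape-level values and
broadcast identically to every farm.

Also houses the descriptive significance tests: paired Wilcoxon
signed-rank for interview indicators and the unpaired rank-sum test for
field-size distributions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import FarmPanel

#: sentinel relative change for appearance from a zero baseline; exceeds
#: any admissible threshold (thresholds are capped at 0.5)
ZERO_BASELINE_SENTINEL = math.inf


@dataclass(frozen=True)
class ChangeThreshold:
    """No-change threshold on the magnitude of relative change."""

    value: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 0.5):
            raise ValueError(f"threshold must lie in [0, 0.5], got {self.value}")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    paired: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def relative_change(v0: float, v1: float) -> float:
    """Relative change (v1 − v0)/v0 with a signed sentinel at zero baseline.

    v0 = v1 = 0 → 0; v0 = 0, v1 ≠ 0 → ±inf (any appearance from nothing is
    a change and exceeds every threshold).
    """
    if not (math.isfinite(v0) and math.isfinite(v1)):
        raise ValueError(f"non-finite inputs to relative_change: {v0}, {v1}")
    if v0 == 0:
        if v1 == 0:
            return 0.0
        return math.copysign(ZERO_BASELINE_SENTINEL, v1)
    return (v1 - v0) / v0


def reclassify_change(v0: float, v1: float, threshold: ChangeThreshold | float = ChangeThreshold()) -> int:
    """Code a change as −1/0/+1 under the no-change threshold."""
    if not isinstance(threshold, ChangeThreshold):
        threshold = ChangeThreshold(float(threshold))
    rel = relative_change(v0, v1)
    # epsilon guards exact-boundary cases (e.g. 2.0 → 2.1 at 5%)
    if abs(rel) <= threshold.value + 1e-12:
        return 0
    return 1 if v1 > v0 else -1


class ObservedChangeMatrix:
    """Farm × indicator matrix of observed change codes.

    Cells hold −1/0/+1 or NaN (missing).  Landscape-scale indicators carry
    the identical code for every farm.
    """

    def __init__(self, frame: pd.DataFrame, registry=None):
        from .registry import REGISTRY

        self.registry = registry if registry is not None else REGISTRY
        values = frame.to_numpy(dtype=float)
        valid = np.isnan(values) | np.isin(values, (-1.0, 0.0, 1.0))
        if not valid.all():
            raise ValueError("observed change codes must be -1, 0, +1 or missing")
        self.frame = frame.astype(float)
        for ind in self.registry.landscape_ids:
            if ind in self.frame.columns:
                col = self.frame[ind].dropna()
                if col.nunique() > 1:
                    raise ValueError(f"landscape indicator {ind} varies across farms")

    @property
    def farm_ids(self) -> list[str]:
        return list(self.frame.index)

    def row(self, farm_id: str) -> pd.Series:
        return self.frame.loc[farm_id]

    def n_no_change(self) -> int:
        """Number of cells coded 0 (grows monotonically with the threshold)."""
        return int((self.frame == 0).sum().sum())


def build_observed_change_matrix(
    panel: FarmPanel,
    landscape_values: dict | None = None,
    threshold: ChangeThreshold | float = ChangeThreshold(),
    one_time_codes: dict | None = None,
) -> ObservedChangeMatrix:
    """Reclassify a panel into the observed-change matrix.

    Parameters
    ----------
    panel : FarmPanel
    landscape_values : mapping indicator_id -> (v0, v1) or code
        Landscape-level indicator values; the resulting single code is
        broadcast to every farm.
    threshold : ChangeThreshold or float
    one_time_codes : mapping indicator_id -> code, optional
        Externally supplied codes for one-time indicators; indicators
        without a supplied code stay missing.
    """
    if not isinstance(threshold, ChangeThreshold):
        threshold = ChangeThreshold(float(threshold))
    registry = panel.registry
    landscape_values = dict(landscape_values or {})
    one_time_codes = dict(one_time_codes or {})
    for source, name in ((landscape_values, "landscape_values"), (one_time_codes, "one_time_codes")):
        unknown = sorted(set(source) - set(registry.ids))
        if unknown:
            raise ValueError(f"unknown indicator ids in {name}: {unknown}")

    farms = panel.farm_ids
    matrix = pd.DataFrame(np.nan, index=pd.Index(farms, name="farm_id"), columns=registry.ids)

    for d in registry:
        if d.kind == "one_time":
            if d.id in one_time_codes:
                matrix[d.id] = float(one_time_codes[d.id])
            continue
        if d.scale == "landscape":
            if d.id in landscape_values:
                val = landscape_values[d.id]
                if isinstance(val, (tuple, list)):
                    code = reclassify_change(float(val[0]), float(val[1]), threshold)
                else:
                    code = int(val)
                matrix[d.id] = float(code)
            continue
        if d.kind == "likert_trend":
            codes = panel.trend_codes(d.id)
            matrix.loc[codes.index, d.id] = codes.astype(float)
        else:
            wide = panel.wide(d.id)
            if not {"t0", "t1"} <= set(wide.columns):
                continue
            both = wide.dropna(subset=["t0", "t1"])
            for farm, row in both.iterrows():
                matrix.loc[farm, d.id] = float(
                    reclassify_change(row["t0"], row["t1"], threshold)
                )
    return ObservedChangeMatrix(matrix, registry=registry)


# ---------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------

def paired_wilcoxon(values_t0, values_t1) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Pairs with any missing value are dropped; zero differences are dropped
    (Wilcoxon's original treatment).  Exact permutation null for n ≤ 10
    (valid under ties), tie-corrected normal approximation otherwise.
    """
    x = np.asarray(values_t0, dtype=float)
    y = np.asarray(values_t1, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise ValueError(f"need at least 5 complete pairs, got {len(x)}")
    d = y - x
    nonzero = d != 0
    if not nonzero.any():
        warnings.warn("all paired differences are zero; p-value set to 1", stacklevel=2)
        return TestResult(statistic=0.0, p_value=1.0, n=len(x), paired=True)
    if nonzero.sum() <= 10:
        method = stats.PermutationMethod(n_resamples=200_000)
    else:
        method = "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), n=len(x), paired=True)


def unpaired_wilcoxon(sample_a, sample_b) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test for unpaired samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 3 or len(b) < 3:
        raise ValueError("both samples need at least 3 observations")
    if np.array_equal(np.sort(a), np.sort(b)):
        return TestResult(statistic=float(len(a) * len(b) / 2), p_value=1.0,
                          n=len(a) + len(b), paired=False)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      n=len(a) + len(b), paired=False)
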