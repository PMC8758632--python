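"""Vision benchmarking model: fit observed development against visions.

`VisionBenchmark` bundles the inputs of the analysis — a two-timepoint
farm panel, the vision matrix, landscape-level indicator values and
optional one-time codes.  ``fit(threshold=0.05)`` reclassifies observed
changes and scores every farm against every vision, returning a
`VisionBenchmarkResults` that carries the per-farm agreements, their
medians and spreads, the cross-vision rank tests, the best-vision
shares, and lazy sensitivity analyses.  The pattern follows the familiar
model/results split of statistical modelling libraries.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from .agreement import VisionComparison, best_vision_shares, compare_visions, score_matrix
from .changes import ChangeThreshold, ObservedChangeMatrix, build_observed_change_matrix
from .panel import FarmPanel, summarize_panel
from .registry import CATEGORIES
from .sensitivity import DEFAULT_GRID, SensitivityResult, equal_weights_rerun, threshold_sweep
from .visions import VisionSpec, load_vision_matrix

#: default codes for the one-time social indicators (no change observed);
#: pass an empty dict to leave them missing instead
DEFAULT_ONE_TIME_CODES = {"frac_over_50": 0, "successor": 0}


def load_default_landscape_values() -> dict[str, tuple[float, float]]:
    """Bundled landscape indicator series (v0, v1) of the study landscape."""
    with resources.files("agrivision.data").joinpath("landscape_values.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        df = pd.read_csv(fh)
    return {row["indicator_id"]: (row["v_t0"], row["v_t1"]) for _, row in df.iterrows()}


class VisionBenchmark:
    """Benchmark observed farm/landscape development against stakeholder
    visions.

    Parameters
    ----------
    panel : FarmPanel
    visions : dict of VisionSpec, optional
        Defaults to the bundled three-vision matrix (AS, SBV, LmZ).
    landscape_values : mapping indicator -> (v0, v1) or code, optional
        Defaults to the bundled landscape series.
    one_time_codes : mapping indicator -> code, optional
        Defaults to 0 for both one-time social indicators.
    """

    def __init__(
        self,
        panel: FarmPanel,
        visions: dict[str, VisionSpec] | None = None,
        landscape_values: dict | None = None,
        one_time_codes: dict | None = None,
    ):
        self.panel = panel
        self.visions = visions if visions is not None else load_vision_matrix()
        self.landscape_values = (
            landscape_values if landscape_values is not None else load_default_landscape_values()
        )
        self.one_time_codes = (
            one_time_codes if one_time_codes is not None else dict(DEFAULT_ONE_TIME_CODES)
        )

    @classmethod
    def from_csv(
        cls,
        panel_csv,
        visions_csv=None,
        landscape_values_csv=None,
        one_time_codes_csv=None,
    ) -> "VisionBenchmark":
        panel = FarmPanel.from_csv(panel_csv)
        visions = load_vision_matrix(visions_csv) if visions_csv else None
        landscape_values = None
        if landscape_values_csv:
            df = pd.read_csv(landscape_values_csv)
            landscape_values = {
                r["indicator_id"]: (r["v_t0"], r["v_t1"]) for _, r in df.iterrows()
            }
        one_time = None
        if one_time_codes_csv:
            df = pd.read_csv(one_time_codes_csv)
            one_time = {r["indicator_id"]: int(r["code"]) for _, r in df.iterrows()}
        return cls(panel, visions, landscape_values, one_time)

    @classmethod
    def from_synthetic(cls, seed: int = 0, config=None, **kwargs) -> "VisionBenchmark":
        """Build the model on a synthetic cohort and landscape pair."""
        from .landscape import landscape_indicator_series
        from .simulate import GeneratorConfig, generate_farm_panel, generate_landscape_pair

        if config is None:
            config = GeneratorConfig(seed=seed)
        panel = generate_farm_panel(config)
        maps, _trees = generate_landscape_pair(config)
        return cls(panel, landscape_values=landscape_indicator_series(maps), **kwargs)

    def fit(self, threshold: float | ChangeThreshold = 0.05) -> "VisionBenchmarkResults":
        if not isinstance(threshold, ChangeThreshold):
            threshold = ChangeThreshold(float(threshold))
        observed = build_observed_change_matrix(
            self.panel, self.landscape_values, threshold, self.one_time_codes
        )
        scores = score_matrix(observed, self.visions)
        return VisionBenchmarkResults(self, threshold, observed, scores)


class VisionBenchmarkResults:
    """Fitted agreement results for one farm cohort."""

    def __init__(
        self,
        model: VisionBenchmark,
        threshold: ChangeThreshold,
        observed: ObservedChangeMatrix,
        scores: pd.DataFrame,
    ):
        self.model = model
        self.threshold = threshold
        self.observed = observed
        self.scores = scores
        self._comparison: VisionComparison | None = None

    # -- headline statistics -------------------------------------------

    @property
    def vision_ids(self) -> list[str]:
        return list(self.model.visions)

    def median_agreement(self) -> dict[str, float]:
        out = {}
        for v in self.vision_ids:
            vals = self.scores.loc[
                self.scores["vision_id"] == v, "agreement_pct"
            ].dropna()
            out[v] = float(np.median(vals)) if len(vals) else float("nan")
        return out

    def category_median_agreement(self) -> pd.DataFrame:
        """Median per-category agreement per vision; NaN where a vision has
        no scorable indicators in a category."""
        rows = {}
        for v in self.vision_ids:
            sub = self.scores[self.scores["vision_id"] == v]
            rows[v] = {
                c: float(np.nanmedian(sub[f"agreement_{c}"]))
                if not sub[f"agreement_{c}"].dropna().empty
                else float("nan")
                for c in CATEGORIES
            }
        return pd.DataFrame(rows).T

    def best_vision_shares(self) -> dict[str, float]:
        return best_vision_shares(self.scores)

    @property
    def comparison(self) -> VisionComparison:
        if self._comparison is None:
            self._comparison = compare_visions(self.scores)
        return self._comparison

    # -- sensitivity ----------------------------------------------------

    def sensitivity(self, grid=DEFAULT_GRID) -> SensitivityResult:
        return threshold_sweep(
            self.model.panel,
            self.model.landscape_values,
            self.model.visions,
            grid=grid,
            one_time_codes=self.model.one_time_codes,
            baseline_threshold=self.threshold.value,
        )

    def equal_weights_delta(self) -> dict[str, float]:
        return equal_weights_rerun(
            self.model.panel,
            self.model.landscape_values,
            self.model.visions,
            threshold=self.threshold.value,
            one_time_codes=self.model.one_time_codes,
        )

    # -- reporting ------------------------------------------------------

    def panel_summary(self):
        return summarize_panel(self.model.panel)

    def to_report(self, with_comparison: bool = True) -> dict:
        """Canonical machine-readable report (JSON-serializable)."""

        def clean(x):
            if isinstance(x, float) and np.isnan(x):
                return None
            return x

        per_farm = [
            {k: clean(v) for k, v in row.items()}
            for row in self.scores.sort_values(["farm_id", "vision_id"]).to_dict("records")
        ]
        report = {
            "threshold": self.threshold.value,
            "n_farms": int(self.scores["farm_id"].nunique()),
            "visions": self.vision_ids,
            "median_agreement": {k: clean(v) for k, v in self.median_agreement().items()},
            "category_median_agreement": {
                v: {c: clean(x) for c, x in row.items()}
                for v, row in self.category_median_agreement().iterrows()
            },
            "best_vision_shares": self.best_vision_shares(),
            "per_farm": per_farm,
        }
        if with_comparison and self.scores["farm_id"].nunique() >= 5:
            comp = self.comparison
            report["comparison"] = {
                "kw_statistic": comp.kw_statistic,
                "kw_p": comp.kw_p,
                "pairwise_p": {f"{a}-{b}": p for (a, b), p in comp.pairwise_p.items()},
            }
        return report

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_report(**kwargs), sort_keys=True, indent=2)

    def summary(self) -> str:
        """Human-readable summary of the fitted benchmark."""
        lines = []
        n_farms = self.scores["farm_id"].nunique()
        lines.append("Vision agreement benchmark")
        lines.append("=" * 60)
        lines.append(
            f"farms: {n_farms}    visions: {', '.join(self.vision_ids)}    "
            f"no-change threshold: {self.threshold.value:.0%}"
        )
        if n_farms == 0:
            lines.append("no farms in panel — nothing to score")
            return "\n".join(lines)
        med = self.median_agreement()
        order = sorted(med, key=lambda v: -med[v])
        lines.append("")
        lines.append("median agreement [%] (best first)")
        for v in order:
            lines.append(f"  {v:<6} {med[v]:6.1f}")
        lines.append("")
        lines.append("median agreement by category [%]")
        cat = self.category_median_agreement()
        lines.append("  " + " " * 7 + " ".join(f"{c:>14}" for c in cat.columns))
        for v, row in cat.iterrows():
            cells = " ".join(
                f"{('—' if np.isnan(x) else format(x, '.1f')):>14}" for x in row
            )
            lines.append(f"  {v:<7}{cells}")
        lines.append("")
        shares = self.best_vision_shares()
        lines.append(
            "best-vision shares: "
            + ", ".join(f"{v}: {100 * s:.0f}%" for v, s in shares.items())
        )
        if n_farms >= 5:
            comp = self.comparison
            lines.append(
                f"Kruskal–Wallis H = {comp.kw_statistic:.2f}, p = {comp.kw_p:.3g}"
            )
            for (a, b), p in comp.pairwise_p.items():
                lines.append(f"  Dunn {a}–{b}: BH-adjusted p = {p:.3g}")
        return "\n".join(lines)
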