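"""Workflow assembly: run the full assessment from a run configuration
and render a human-readable report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import VisionBenchmark
from .sensitivity import DEFAULT_GRID

logger = logging.getLogger("agrivision")


@dataclass
class RunConfig:
    """Paths and parameters of one assessment run."""

    panel_csv: str
    visions_csv: str | None = None
    landscape_values_csv: str | None = None
    one_time_codes_csv: str | None = None
    threshold: float = 0.05
    grid: tuple = DEFAULT_GRID
    out_dir: str | None = None
    seed: int = 0
    verbose: bool = False

    def __post_init__(self) -> None:
        if not Path(self.panel_csv).exists():
            raise FileNotFoundError(f"panel CSV not found: {self.panel_csv}")
        for p in (self.visions_csv, self.landscape_values_csv, self.one_time_codes_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        grid = np.asarray(self.grid, dtype=float)
        if len(grid) == 0 or not (np.diff(grid) > 0).all():
            raise ValueError("grid must parse to a strictly increasing sequence")


def run_assess(config: RunConfig) -> dict:
    """Load inputs, fit the benchmark, and return the JSON-ready report.

    Writes the canonical JSON report and tidy per-farm CSV into
    ``config.out_dir`` when set.
    """
    logger.info(
        "assess: threshold=%s one_time_codes_csv=%s",
        config.threshold,
        config.one_time_codes_csv,
    )
    model = VisionBenchmark.from_csv(
        config.panel_csv,
        visions_csv=config.visions_csv,
        landscape_values_csv=config.landscape_values_csv,
        one_time_codes_csv=config.one_time_codes_csv,
    )
    results = model.fit(threshold=config.threshold)
    n_farms = results.scores["farm_id"].nunique()
    report = results.to_report(with_comparison=n_farms >= 5)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "agreement_report.json").write_text(results.to_json(
            with_comparison=n_farms >= 5))
        results.scores.to_csv(out / "agreement_per_farm.csv", index=False)
        logger.info("wrote %s", out / "agreement_report.json")
    return report


def render_report(report: dict) -> str:
    """Markdown summary: medians, category table, shares, tests."""
    lines = ["# Vision agreement report", ""]
    if report["n_farms"] == 0:
        lines.append("No farms in the panel — nothing was scored.")
        return "\n".join(lines)
    lines.append(f"Farms scored: **{report['n_farms']}**; "
                 f"no-change threshold: **{report['threshold']:.0%}**")
    lines.append("")
    lines.append("## Median agreement")
    lines.append("")
    med = report["median_agreement"]
    for v in sorted(med, key=lambda v: -(med[v] if med[v] is not None else -1)):
        val = "—" if med[v] is None else f"{med[v]:.1f}%"
        lines.append(f"- **{v}**: {val}")
    lines.append("")
    lines.append("## Agreement by category (median %)")
    lines.append("")
    cats = list(next(iter(report["category_median_agreement"].values())).keys())
    lines.append("| vision | " + " | ".join(cats) + " |")
    lines.append("|" + "---|" * (len(cats) + 1))
    for v, row in report["category_median_agreement"].items():
        cells = " | ".join("—" if row[c] is None else f"{row[c]:.1f}" for c in cats)
        lines.append(f"| {v} | {cells} |")
    lines.append("")
    shares = report["best_vision_shares"]
    lines.append(
        "Best-vision shares: "
        + ", ".join(f"{v} {100 * s:.0f}%" for v, s in shares.items())
    )
    if "comparison" in report:
        comp = report["comparison"]
        lines.append("")
        lines.append(
            f"Kruskal–Wallis H = {comp['kw_statistic']:.2f} (p = {comp['kw_p']:.3g}); "
            "Dunn/BH pairwise p: "
            + ", ".join(f"{k}: {p:.3g}" for k, p in comp["pairwise_p"].items())
        )
    return "\n".join(lines)
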