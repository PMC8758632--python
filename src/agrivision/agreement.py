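"""Agreement between observed and desired change.

For one farm and one vision, the weighted distance between observed and
desired change is

    difference = Σ_i  w_i · min_{d ∈ D_i} |o_i − d|

over the scorable indicators i (weight > 0 and observed code present),
with D_i the desired-change set.  The normalizer is the potential
agreement Σ_i 2·w_i over the same indicators, and

    agreement% = 100 · (potential − difference) / potential.

100% means every observed change is compatible with the vision; 0% means
every observed change is maximally opposed.  Missing observed codes are
excluded from both sums (per-farm renormalization) so non-response is
not mistaken for disagreement.

Cross-vision statistics: Kruskal–Wallis over per-farm agreements grouped
by vision, Dunn's post-hoc mean-rank z-tests with tie correction and
Benjamini–Hochberg adjustment, and the best-vision assignment with
fractional tie-splitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .changes import ObservedChangeMatrix
from .registry import CATEGORIES
from .visions import VisionSpec


def indicator_difference(o, desired: tuple[int, ...], w: int) -> tuple[float, float]:
    """Contribution of one indicator to (difference, potential).

    Weight 0 or a missing observed code excludes the indicator from both
    sums → (0, 0).  Otherwise the contribution is w·min_{d∈desired}|o−d|
    and the potential contribution 2w.
    """
    if w == 0 or o is None or (isinstance(o, float) and math.isnan(o)):
        return (0.0, 0.0)
    o = int(o)
    if o not in (-1, 0, 1):
        raise ValueError(f"observed code must be -1, 0 or +1, got {o}")
    if not desired:
        return (0.0, 0.0)
    return (w * min(abs(o - d) for d in desired), 2.0 * w)


@dataclass(frozen=True)
class AgreementResult:
    """Agreement of one farm with one vision (overall or per category)."""

    farm_id: str
    vision_id: str
    difference: float
    potential: float
    n_used: int
    category_agreement: dict = field(default_factory=dict)

    @property
    def defined(self) -> bool:
        return self.potential > 0

    @property
    def agreement_pct(self) -> float:
        """Eq.-3 statistic in percent; NaN when no indicator is scorable."""
        if not self.defined:
            return float("nan")
        return 100.0 * (self.potential - self.difference) / self.potential


def score_farm(
    observed_row,
    vision: VisionSpec,
    category_filter=None,
    with_categories: bool = True,
) -> AgreementResult:
    """Score one farm's observed codes against a vision.

    Parameters
    ----------
    observed_row : mapping indicator_id -> code or NaN
        A row of an :class:`ObservedChangeMatrix`.
    category_filter : iterable of categories, optional
        Restrict scoring to indicators of these categories.
    with_categories : bool
        Also compute per-category agreement (NaN where the category has
        zero scorable potential, e.g. a vision without social components).
    """
    registry = vision.registry
    cats = set(category_filter) if category_filter is not None else None
    farm_id = getattr(observed_row, "name", "farm")

    difference = potential = 0.0
    n_used = 0
    per_cat: dict[str, list[float]] = {c: [0.0, 0.0] for c in CATEGORIES}
    for d in registry:
        if cats is not None and d.category not in cats:
            continue
        o = observed_row.get(d.id) if hasattr(observed_row, "get") else observed_row[d.id]
        contrib, pot = indicator_difference(o, vision.desired[d.id], vision.weights[d.id])
        if pot > 0:
            n_used += 1
            difference += contrib
            potential += pot
            per_cat[d.category][0] += contrib
            per_cat[d.category][1] += pot

    category_agreement = {}
    if with_categories:
        for c in CATEGORIES:
            if cats is not None and c not in cats:
                continue
            cdiff, cpot = per_cat[c]
            category_agreement[c] = (
                100.0 * (cpot - cdiff) / cpot if cpot > 0 else float("nan")
            )
    return AgreementResult(
        farm_id=str(farm_id),
        vision_id=vision.vision_id,
        difference=difference,
        potential=potential,
        n_used=n_used,
        category_agreement=category_agreement,
    )


def score_matrix(observed: ObservedChangeMatrix, visions: dict[str, VisionSpec]) -> pd.DataFrame:
    """Score every farm against every vision.

    Returns a tidy DataFrame with one row per (farm, vision) carrying the
    overall agreement and one ``agreement_<category>`` column per
    indicator category.
    """
    base_cols = ["farm_id", "vision_id", "difference", "potential", "n_used",
                 "agreement_pct"] + [f"agreement_{c}" for c in CATEGORIES]
    rows = []
    for farm_id in observed.farm_ids:
        obs_row = observed.row(farm_id)
        for vid, vision in visions.items():
            res = score_farm(obs_row, vision)
            row = {
                "farm_id": farm_id,
                "vision_id": vid,
                "difference": res.difference,
                "potential": res.potential,
                "n_used": res.n_used,
                "agreement_pct": res.agreement_pct,
            }
            for c, val in res.category_agreement.items():
                row[f"agreement_{c}"] = val
            rows.append(row)
    if not rows:
        return pd.DataFrame(columns=base_cols)
    return pd.DataFrame(rows)


def best_vision_shares(scores: pd.DataFrame) -> dict[str, float]:
    """Share of farms whose agreement is highest with each vision.

    Ties split fractionally among the tied visions, so shares sum to 1.
    Farms with no defined agreement for any vision are excluded with a
    warning.
    """
    vision_ids = list(scores["vision_id"].drop_duplicates())
    shares = {v: 0.0 for v in vision_ids}
    wide = scores.pivot(index="farm_id", columns="vision_id", values="agreement_pct")
    n_counted = 0
    for farm_id, row in wide.iterrows():
        defined = row.dropna()
        if defined.empty:
            warnings.warn(f"farm {farm_id}: no defined agreement; excluded from shares",
                          stacklevel=2)
            continue
        n_counted += 1
        best = defined.max()
        tied = defined[defined == best].index
        for v in tied:
            shares[v] += 1.0 / len(tied)
    if n_counted:
        shares = {v: s / n_counted for v, s in shares.items()}
    return shares


# ---------------------------------------------------------------------
# Cross-vision statistics
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class VisionComparison:
    kw_statistic: float
    kw_p: float
    pairwise_p: dict            # (vision_a, vision_b) -> BH-adjusted p
    pairwise_z: dict            # (vision_a, vision_b) -> Dunn z statistic
    best_vision_shares: dict    # vision -> fraction of farms


def dunn_test(groups: dict[str, np.ndarray]) -> tuple[dict, dict]:
    """Dunn's post-hoc test: pairwise mean-rank z statistics with tie
    correction, Benjamini–Hochberg adjusted over all pairs.

    Returns (adjusted p-values, z statistics), keyed by vision pair.
    """
    labels = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in labels])
    sizes = {g: len(groups[g]) for g in labels}
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in labels:
        mean_ranks[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]

    # tie correction: Σ(t³ − t) / (12(N − 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(combinations(labels, 2))
    z_stats, raw_p = {}, []
    for a, b in pairs:
        se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        if se == 0:  # fully degenerate (all values identical)
            z = 0.0
            p = 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
        z_stats[(a, b)] = z
        raw_p.append(min(p, 1.0))
    _, adj, _, _ = multipletests(raw_p, method="fdr_bh")
    pairwise_p = {pair: float(p) for pair, p in zip(pairs, adj)}
    return pairwise_p, z_stats


def compare_visions(scores: pd.DataFrame) -> VisionComparison:
    """Kruskal–Wallis across per-farm agreements grouped by vision, with
    Dunn/BH post-hoc pairwise tests and best-vision shares."""
    vision_ids = list(scores["vision_id"].drop_duplicates())
    if len(vision_ids) < 2:
        raise ValueError("need at least 2 visions to compare")
    groups = {
        v: scores.loc[scores["vision_id"] == v, "agreement_pct"].dropna().to_numpy()
        for v in vision_ids
    }
    if min(len(g) for g in groups.values()) < 5:
        raise ValueError("need at least 5 farms per vision")

    pooled = np.concatenate(list(groups.values()))
    if np.allclose(pooled, pooled[0]):
        pairs = list(combinations(vision_ids, 2))
        return VisionComparison(
            kw_statistic=0.0,
            kw_p=1.0,
            pairwise_p={p: 1.0 for p in pairs},
            pairwise_z={p: 0.0 for p in pairs},
            best_vision_shares=best_vision_shares(scores),
        )
    kw = stats.kruskal(*groups.values())
    pairwise_p, pairwise_z = dunn_test(groups)
    return VisionComparison(
        kw_statistic=float(kw.statistic),
        kw_p=float(kw.pvalue),
        pairwise_p=pairwise_p,
        pairwise_z=pairwise_z,
        best_vision_shares=best_vision_shares(scores),
    )
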