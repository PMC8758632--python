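"""Synthetic farm cohorts and landscape snapshot pairs.

The generator emulates the statistical structure of a 20-farm interview
panel and a paired landscape mapping of a 2500 ha lowland agricultural
study area over two decades:

* quantitative indicators draw t0 values from lognormal (strictly
  positive quantities) or clipped-normal (percentages, counts) marginals
  and t1 values as rank-correlated draws (default within-farm
  correlation ρ = 0.7 on the latent scale), with an indicator-specific
  point mass of exact "no change" responses — survey answers are coarse
  and stable farms report identical values;
* the cohort mixes farm types (8 dairy / 10 mixed / 2 arable of 20) and
  development trajectories (14 growth-oriented / 5 persistent / 1
  greening of 20): growers expand area, livestock and production volume
  while specializing; persistent farms change little and report stable
  or improving satisfaction and economics; the greening farm extensifies
  (less livestock, fertilizer and pesticide, more ecological focus
  area).  Milk-price decline hits dairy farms; non-dairy prices are
  nearly stable;
* qualitative trend answers follow the printed shares (61% perceived a
  drop in societal valuation; satisfaction balanced; the economic
  situation worsened for ~50% of dairy vs ~25% of other farms; 82%
  increased production volumes);
* per-indicator missingness reproduces the varying interview sample
  sizes (n = 14–20);
* the landscape pair realizes an exact class-level flow budget
  (intensive land to settlement, extensive grassland and wetland;
  shrinking high-stem orchards) on a shared tessellation, hitting the
  landscape indicator series (total agricultural area 1781→1737 ha,
  mean intensive field size 1.35→1.81 ha, proportion intensive 93→90%,
  semi-natural share 19.8→22.2%) and the field-tree inventory
  (1631 large + 598 small → −23% / −6%).

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landscape import LandCoverPartition, TreeInventory
from .panel import FarmPanel

# ---------------------------------------------------------------------
# Calibration tables (study conditions)
# ---------------------------------------------------------------------

#: per-indicator marginals: family, mean/sd at both periods, interview n of 20
MARGINALS: dict[str, dict] = {
    "farm_area":             dict(family="lognormal", m0=23.9, s0=7.9, m1=37.7, s1=27.0, n_obs=20, round_step=1.0),
    "livestock_units":       dict(family="lognormal", m0=42.3, s0=24.5, m1=69.2, s1=51.0, n_obs=20, round_step=1.0),
    "crop_diversity":        dict(family="count",     m0=3.2,  s0=1.2,  m1=3.0,  s1=1.8,  n_obs=18, round_step=1.0),
    "livestock_diversity":   dict(family="count",     m0=5.1,  s0=1.8,  m1=3.7,  s1=1.8,  n_obs=19, round_step=1.0),
    "feed_import":           dict(family="percent",   m0=20.0, s0=21.0, m1=26.0, s1=24.0, n_obs=16, round_step=5.0),
    "frac_owned_land":       dict(family="percent",   m0=68.0, s0=24.0, m1=57.0, s1=25.0, n_obs=20, round_step=5.0),
    "ecological_focus_area": dict(family="percent",   m0=12.0, s0=7.0,  m1=18.0, s1=10.0, n_obs=18, round_step=1.0),
    "n_intensity":           dict(family="truncnorm", m0=132.0, s0=21.0, m1=133.0, s1=21.0, n_obs=14, round_step=10.0),
    "pesticide_use":         dict(family="count",     m0=2.0,  s0=1.9,  m1=2.1,  s1=2.3,  n_obs=20, round_step=1.0),
}

#: trajectory modulation: (stay probability, multiplier on the t1 mean)
TRAJECTORY: dict[str, dict[str, tuple[float, float]]] = {
    "farm_area":             {"grower": (0.05, 1.15), "persistent": (0.90, 1.00), "greening": (0.30, 0.70)},
    "livestock_units":       {"grower": (0.05, 1.15), "persistent": (0.90, 1.00), "greening": (0.20, 0.60)},
    "crop_diversity":        {"grower": (0.35, 0.95), "persistent": (0.80, 1.05), "greening": (0.30, 1.30)},
    "livestock_diversity":   {"grower": (0.10, 0.95), "persistent": (0.85, 1.35), "greening": (0.30, 1.30)},
    "feed_import":           {"grower": (0.30, 1.20), "persistent": (0.80, 0.77), "greening": (0.20, 0.30)},
    "frac_owned_land":       {"grower": (0.30, 0.92), "persistent": (0.85, 1.19), "greening": (0.60, 1.00)},
    "ecological_focus_area": {"grower": (0.25, 1.00), "persistent": (0.70, 0.67), "greening": (0.05, 1.60)},
    "n_intensity":           {"grower": (0.55, 1.00), "persistent": (0.85, 1.00), "greening": (0.10, 0.60)},
    "pesticide_use":         {"grower": (0.50, 1.00), "persistent": (0.85, 1.00), "greening": (0.10, 0.40)},
}

#: Likert trend shares (p_decrease, p_same, p_increase) per trajectory
LIKERT_SHARES: dict[str, dict[str, tuple[float, float, float]]] = {
    "farmer_satisfaction": {
        "grower": (0.33, 0.40, 0.27),
        "persistent": (0.05, 0.45, 0.50),
        "greening": (0.20, 0.40, 0.40),
    },
    "societal_valuation": {
        "grower": (0.75, 0.17, 0.08),
        "persistent": (0.30, 0.45, 0.25),
        "greening": (0.20, 0.40, 0.40),
    },
}

#: economic-situation shares, keyed (is_dairy, trajectory)
ECON_SHARES: dict[tuple[bool, str], tuple[float, float, float]] = {
    (True, "grower"): (0.55, 0.30, 0.15),
    (True, "persistent"): (0.20, 0.45, 0.35),
    (True, "greening"): (0.30, 0.40, 0.30),
    (False, "grower"): (0.30, 0.40, 0.30),
    (False, "persistent"): (0.05, 0.45, 0.50),
    (False, "greening"): (0.20, 0.40, 0.40),
}

LIKERT_N_OBS = {"farmer_satisfaction": 18, "societal_valuation": 18, "econ_situation": 20}

#: price index at t1 (t0 = 100): (mean, sd), keyed (is_dairy, trajectory)
PRICE_INDEX: dict[tuple[bool, str], tuple[float, float]] = {
    (True, "grower"): (74.0, 10.0),
    (True, "persistent"): (92.0, 8.0),
    (True, "greening"): (95.0, 8.0),
    (False, "grower"): (93.0, 8.0),
    (False, "persistent"): (100.0, 5.0),
    (False, "greening"): (103.0, 7.0),
}

#: production volume at t1 (t0 = 100): probability of an increase per
#: trajectory; increase magnitudes are lognormal with mean 250 / sd 280,
#: floored at 106 (above the 5% no-change band); maintainers report 100.
PRODUCTION_P_INCREASE = {"grower": 0.95, "persistent": 0.50, "greening": 0.50}
PRODUCTION_INCREASE = dict(mean=250.0, sd=280.0, floor=106.0)

#: off-farm work: zero-inflated percentages (many farmers are full-time)
OFF_FARM = dict(
    p_zero_t0=0.5,
    nonzero=dict(m0=27.0, s0=26.0, m1=40.0, s1=30.0),
    p_start={"grower": 0.15, "persistent": 0.05, "greening": 0.10},
    stay={"grower": 0.30, "persistent": 0.80, "greening": 0.50},
    adj={"grower": 1.00, "persistent": 0.70, "greening": 1.00},
    n_obs=19,
)

ONE_TIME_VALUES = {"frac_over_50": 35.0, "successor": 67.0}

FARM_TYPE_SHARES = {"dairy": 8 / 20, "mixed": 10 / 20, "arable": 2 / 20}
TRAJECTORY_SHARES = {"grower": 14 / 20, "persistent": 5 / 20, "greening": 1 / 20}

# -- landscape calibration --------------------------------------------

STUDY_AREA_HA = 2500.0

#: class areas at t0 (ha); sum = 2500
LANDSCAPE_T0 = {
    "J": 300.0, "H": 8.0, "C": 36.0, "G": 218.4, "D": 156.6,
    "E_int": 821.2, "E_ext": 92.0, "I": 830.0, "FB": 5.0,
    "O_int": 4.8, "O_hs": 28.0,
}

#: class-level area flows t0 → t1 (ha).  Net effect: agricultural area
#: 1781 → 1737, intensive share 93 → 90%, semi-natural 19.8 → 22.2%,
#: settlement +37.1, wetland +8, extensive grassland +60.6, high-stem
#: orchards −7.5.  The symmetric E_int↔I churn mimics crop rotation.
LANDSCAPE_FLOWS = [
    ("E_int", "J", 20.0),
    ("I", "J", 17.1),
    ("E_int", "D", 8.0),
    ("E_int", "E_ext", 30.0),
    ("I", "E_ext", 25.1),
    ("O_hs", "E_int", 7.5),
    ("FB", "E_ext", 4.4),
    ("G", "E_ext", 1.1),
    ("E_int", "I", 60.0),
    ("I", "E_int", 60.0),
]

FIELD_SIZE = dict(mean_t0=1.35, sd_t0=1.25, mean_t1=1.81)

#: units per non-field class (fields get one unit each)
NON_FIELD_UNITS = {"J": 25, "H": 2, "C": 3, "G": 10, "D": 5, "E_ext": 46, "FB": 2, "O_hs": 14}

#: field-tree inventory; jointly consistent with the printed totals and
#: rounded percent changes (2229 → 1818 overall, −23% large, −6% small)
TREES = dict(large_t0=1631, small_t0=598, large_t1=1256, small_t1=562)


# ---------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------

class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Configuration for the synthetic cohort and landscape generator.

    ``sd_scale`` multiplies every marginal SD (0 gives a deterministic
    cohort at the marginal means); ``homogeneous`` disables the
    trajectory/type mixture (no stay point mass, no modulation).
    ``change_scale`` scales the landscape flow budget and tree removals
    (0 gives two identical snapshots).
    """

    n_farms: int = 20
    seed: int = 0
    rho: float = 0.7
    sd_scale: float = 1.0
    homogeneous: bool = False
    reporting_precision: bool = True
    change_scale: float = 1.0
    marginals: dict = field(default_factory=lambda: {k: dict(v) for k, v in MARGINALS.items()})
    trajectory: dict = field(default_factory=lambda: {k: dict(v) for k, v in TRAJECTORY.items()})
    farm_type_shares: dict = field(default_factory=lambda: dict(FARM_TYPE_SHARES))
    trajectory_shares: dict = field(default_factory=lambda: dict(TRAJECTORY_SHARES))
    one_time_values: dict = field(default_factory=lambda: dict(ONE_TIME_VALUES))

    def __post_init__(self) -> None:
        if self.n_farms < 1:
            raise ConfigError("n_farms must be >= 1")
        if not (-1.0 <= self.rho <= 1.0):
            raise ConfigError("rho must lie in [-1, 1]")
        if self.sd_scale < 0:
            raise ConfigError("sd_scale must be >= 0")
        for ind, m in self.marginals.items():
            if m["s0"] < 0 or m["s1"] < 0:
                raise ConfigError(f"negative SD for {ind}")
            if m["m0"] <= 0 and m["family"] == "lognormal":
                raise ConfigError(f"lognormal marginal for {ind} needs a positive mean")
        for shares in (self.farm_type_shares, self.trajectory_shares):
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ConfigError("shares must sum to 1")

    def deterministic(self) -> "GeneratorConfig":
        """Degenerate copy: sd 0, ρ = 1, homogeneous cohort, exact values."""
        return replace(self, sd_scale=0.0, rho=1.0, homogeneous=True,
                       reporting_precision=False)


def _allocate(n: int, shares: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n farms to named groups."""
    raw = {k: n * s for k, s in shares.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    left = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:left]:
        counts[k] += 1
    return counts


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _from_latent(z: np.ndarray, family: str, mean: float, sd: float) -> np.ndarray:
    """Map standard-normal latents to the marginal family."""
    if family == "lognormal":
        mu, sigma = _lognormal_params(mean, sd)
        return np.exp(mu + sigma * z)
    v = mean + sd * z
    if family in ("percent",):
        return np.clip(v, 0.0, 100.0)
    if family == "truncnorm":
        return np.clip(v, 0.0, None)
    if family == "count":
        return np.round(np.clip(v, 0.0, None))
    raise ConfigError(f"unknown family {family!r}")


def _report(v, step: float):
    """Survey answers are coarse: round reported values to the indicator's
    reporting precision (whole hectares/LU, multiples of 5%, ~10 kg N)."""
    if step <= 0:
        return v
    return np.round(np.asarray(v, dtype=float) / step) * step


# ---------------------------------------------------------------------
# Farm panel generation
# ---------------------------------------------------------------------

def generate_farm_panel(config: GeneratorConfig) -> FarmPanel:
    """Generate a synthetic two-timepoint farm panel.

    The returned panel carries the per-farm metadata (type, trajectory)
    in its ``meta`` attribute.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_farms
    farm_ids = [f"F{i + 1:03d}" for i in range(n)]

    # farm type and trajectory assignment (fixed cohort composition)
    type_counts = _allocate(n, config.farm_type_shares)
    types = rng.permutation(
        [t for t, c in type_counts.items() for _ in range(c)]
    )
    if config.homogeneous:
        trajectories = np.array(["grower"] * n)
    else:
        traj_counts = _allocate(n, config.trajectory_shares)
        trajectories = rng.permutation(
            [t for t, c in traj_counts.items() for _ in range(c)]
        )
    meta = pd.DataFrame(
        {"farm_id": farm_ids, "farm_type": types, "trajectory": trajectories}
    ).set_index("farm_id")

    rho = config.rho
    ss = config.sd_scale
    records: list[dict] = []

    def add(farm, ind, period, value):
        records.append(
            {"farm_id": farm, "indicator_id": ind, "period": period, "value": value}
        )

    def missing_mask(n_obs_20: int) -> np.ndarray:
        """True where the indicator is observed for the farm."""
        n_missing = round(n * (1.0 - n_obs_20 / 20.0))
        mask = np.ones(n, dtype=bool)
        if n_missing > 0:
            mask[rng.choice(n, size=n_missing, replace=False)] = False
        return mask

    values: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- standard quantitative indicators -----------------------------
    for ind, m in config.marginals.items():
        z0 = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        z1 = rho * z0 + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
        v0 = _from_latent(z0, m["family"], m["m0"], m["s0"] * ss)
        stay_draw = rng.random(n)
        v1 = np.empty(n)
        for i, farm in enumerate(farm_ids):
            traj = meta.loc[farm, "trajectory"]
            if config.homogeneous:
                stay, adj = 0.0, 1.0
            else:
                stay, adj = config.trajectory[ind][traj]
            if stay_draw[i] < stay:
                v1[i] = v0[i]
            else:
                v1[i] = _from_latent(
                    np.array([z1[i]]), m["family"], m["m1"] * adj, m["s1"] * ss
                )[0]
        step = m.get("round_step", 0.0) if config.reporting_precision else 0.0
        values[ind] = (_report(v0, step), _report(v1, step))

    # -- structural zeros for arable farms ----------------------------
    arable = meta["farm_type"].to_numpy() == "arable"
    for ind in ("livestock_units", "livestock_diversity"):
        if ind in values:
            v0, v1 = values[ind]
            v0[arable] = 0.0
            v1[arable] = 0.0

    # -- price index (t0 = 100) ---------------------------------------
    price1 = np.empty(n)
    for i, farm in enumerate(farm_ids):
        if config.homogeneous:
            mean, sd = 85.7, 13.5  # cohort-level printed change −14.3 ± 13.5
        else:
            is_dairy = meta.loc[farm, "farm_type"] == "dairy"
            mean, sd = PRICE_INDEX[(is_dairy, meta.loc[farm, "trajectory"])]
        price1[i] = max(0.0, mean + sd * ss * rng.standard_normal())
    price_step = 5.0 if config.reporting_precision else 0.0
    values["price_trend"] = (np.full(n, 100.0), _report(price1, price_step))

    # -- production volume index (t0 = 100) ---------------------------
    prod1 = np.empty(n)
    mu, sigma = _lognormal_params(PRODUCTION_INCREASE["mean"], PRODUCTION_INCREASE["sd"])
    for i, farm in enumerate(farm_ids):
        if config.homogeneous:
            prod1[i] = max(0.0, 223.0 + 283.0 * ss * rng.standard_normal())
            continue
        p_inc = PRODUCTION_P_INCREASE[meta.loc[farm, "trajectory"]]
        if rng.random() < p_inc:
            draw = math.exp(mu + sigma * ss * rng.standard_normal())
            prod1[i] = max(PRODUCTION_INCREASE["floor"], draw)
        else:
            prod1[i] = 100.0
    prod_step = 10.0 if config.reporting_precision else 0.0
    values["production_trend"] = (np.full(n, 100.0), _report(prod1, prod_step))

    # -- off-farm work (zero-inflated) --------------------------------
    off = OFF_FARM
    off0 = np.empty(n)
    off1 = np.empty(n)
    for i, farm in enumerate(farm_ids):
        traj = meta.loc[farm, "trajectory"] if not config.homogeneous else "grower"
        nz = off["nonzero"]
        if rng.random() < off["p_zero_t0"] and not config.homogeneous:
            off0[i] = 0.0
            if rng.random() < off["p_start"][traj]:
                off1[i] = float(np.clip(nz["m1"] + nz["s1"] * ss * rng.standard_normal(), 0, 100))
            else:
                off1[i] = 0.0
        else:
            z0 = rng.standard_normal()
            off0[i] = float(np.clip(nz["m0"] + nz["s0"] * ss * z0, 0, 100))
            if not config.homogeneous and rng.random() < off["stay"][traj]:
                off1[i] = off0[i]
            else:
                z1 = rho * z0 + math.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal()
                adj = off["adj"][traj] if not config.homogeneous else 1.0
                off1[i] = float(np.clip(nz["m1"] * adj + nz["s1"] * ss * z1, 0, 100))
    off_step = 5.0 if config.reporting_precision else 0.0
    values["off_farm_work"] = (_report(off0, off_step), _report(off1, off_step))

    # -- derived: livestock density -----------------------------------
    fa0, fa1 = values["farm_area"]
    lu0, lu1 = values["livestock_units"]
    values["livestock_density"] = (lu0 / fa0, lu1 / fa1)

    # -- emit quantitative records with missingness -------------------
    n_obs_map = {ind: m["n_obs"] for ind, m in config.marginals.items()}
    n_obs_map.update(price_trend=20, production_trend=20,
                     off_farm_work=off["n_obs"], livestock_density=20)
    for ind, (v0, v1) in values.items():
        observed = missing_mask(n_obs_map[ind])
        if ind == "feed_import":
            observed = observed & ~arable  # no livestock, no feed question
        for i, farm in enumerate(farm_ids):
            if not observed[i]:
                continue
            add(farm, ind, "t0", float(v0[i]))
            add(farm, ind, "t1", float(v1[i]))

    # -- Likert trend indicators --------------------------------------
    def draw_code(p: tuple[float, float, float]) -> int:
        return int(rng.choice((-1, 0, 1), p=p))

    for ind in ("farmer_satisfaction", "societal_valuation"):
        observed = missing_mask(LIKERT_N_OBS[ind])
        for i, farm in enumerate(farm_ids):
            if not observed[i]:
                continue
            traj = meta.loc[farm, "trajectory"] if not config.homogeneous else "grower"
            add(farm, ind, "trend", draw_code(LIKERT_SHARES[ind][traj]))
    observed = missing_mask(LIKERT_N_OBS["econ_situation"])
    for i, farm in enumerate(farm_ids):
        if not observed[i]:
            continue
        is_dairy = meta.loc[farm, "farm_type"] == "dairy"
        traj = meta.loc[farm, "trajectory"] if not config.homogeneous else "grower"
        add(farm, "econ_situation", "trend", draw_code(ECON_SHARES[(is_dairy, traj)]))

    panel = FarmPanel(pd.DataFrame.from_records(records))
    panel.meta = meta
    return panel


# ---------------------------------------------------------------------
# Landscape pair generation
# ---------------------------------------------------------------------

def generate_landscape_pair(
    config: GeneratorConfig,
) -> tuple[tuple[LandCoverPartition, LandCoverPartition], tuple[TreeInventory, TreeInventory]]:
    """Generate paired land-cover partitions on a shared tessellation and
    the matching field-tree inventories."""
    rng = np.random.default_rng(config.seed + 10_000_019)
    scale = config.change_scale

    field_cfg = FIELD_SIZE
    intensive_area = LANDSCAPE_T0["I"] + LANDSCAPE_T0["E_int"] + LANDSCAPE_T0["O_int"]
    n_fields = int(round(intensive_area / field_cfg["mean_t0"]))
    mu, sigma = _lognormal_params(field_cfg["mean_t0"], field_cfg["sd_t0"])
    sizes = np.exp(mu + sigma * rng.standard_normal(n_fields))
    sizes *= intensive_area / sizes.sum()  # hit the class total exactly

    units: list[dict] = []  # unit_id, field_id, class_t0, area
    uid = 0

    def push(class_t0: str, area: float, field_id: str | None = None):
        nonlocal uid
        uid += 1
        unit_id = f"U{uid:05d}"
        units.append(
            {
                "unit_id": unit_id,
                "field_id": field_id if field_id is not None else unit_id,
                "class_t0": class_t0,
                "area_ha": float(area),
            }
        )

    # assign intensive field classes by cumulative area, splitting at borders
    order = rng.permutation(n_fields)
    targets = [("I", LANDSCAPE_T0["I"]), ("E_int", LANDSCAPE_T0["E_int"]),
               ("O_int", LANDSCAPE_T0["O_int"])]
    ti = 0
    remaining = targets[ti][1]
    for k in order:
        area = float(sizes[k])
        fid = f"P{k + 1:05d}"
        while area > remaining + 1e-9 and ti < len(targets) - 1:
            if remaining > 25e-4:  # never emit sub-25 m² splinters
                push(targets[ti][0], remaining, fid)
                area -= remaining
            ti += 1
            remaining = targets[ti][1]
        pushed = min(area, remaining)
        if pushed > 25e-4:
            push(targets[ti][0], pushed, fid)
        remaining -= pushed

    for cls, n_units in NON_FIELD_UNITS.items():
        areas = np.full(n_units, LANDSCAPE_T0[cls] / n_units)
        areas = areas * (1.0 + 0.2 * rng.standard_normal(n_units)).clip(0.3)
        areas *= LANDSCAPE_T0[cls] / areas.sum()
        for a in areas:
            push(cls, a)

    df = pd.DataFrame(units)
    df["class_t1"] = df["class_t0"]

    # realize the class-level flow budget unit by unit; intensive sources
    # convert their smallest fields first (consolidation removes small
    # fields), other sources convert random units; border units split so
    # each flow area is met exactly
    for src, dst, flow in LANDSCAPE_FLOWS:
        need = flow * scale
        if need <= 0:
            continue
        cand = df[(df["class_t0"] == src) & (df["class_t1"] == src)]
        if src in ("I", "E_int", "O_int"):
            cand = cand.sort_values("area_ha")
        else:
            cand = cand.sample(frac=1.0, random_state=int(rng.integers(2**31)))
        for idx, row in cand.iterrows():
            if need <= 1e-9:
                break
            if row["area_ha"] <= need + 25e-4:
                # convert whole units rather than leave sub-25 m² splinters
                df.at[idx, "class_t1"] = dst
                need -= row["area_ha"]
            elif need < 25e-4:
                break
            else:
                # split the unit; the converted piece gets a new unit_id
                uid += 1
                piece = {
                    "unit_id": f"U{uid:05d}",
                    "field_id": row["field_id"],
                    "class_t0": src,
                    "area_ha": need,
                    "class_t1": dst,
                }
                df.at[idx, "area_ha"] = row["area_ha"] - need
                df = pd.concat([df, pd.DataFrame([piece])], ignore_index=True)
                need = 0.0

    # t1 field grouping: consolidation merges remaining intensive units
    # into fewer, larger fields at the target mean size
    intensive_t1 = df["class_t1"].isin(("I", "E_int", "O_int"))
    area_t1 = df.loc[intensive_t1, "area_ha"].sum()
    n_fields_t1 = int(round(area_t1 / field_cfg["mean_t1"])) if scale > 0 else None
    field_t1 = df["unit_id"].copy()
    if n_fields_t1:
        idx = df.index[intensive_t1]
        perm = rng.permutation(len(idx))
        groups = np.arange(len(idx)) % max(1, min(n_fields_t1, len(idx)))
        field_t1.loc[idx[perm]] = [f"Q{g + 1:05d}" for g in groups]
    else:
        field_t1 = df["field_id"].copy()

    part0 = LandCoverPartition(
        units=df.rename(columns={"class_t0": "class_code"})[
            ["unit_id", "class_code", "area_ha", "field_id"]
        ],
        period="t0",
        total_study_area=STUDY_AREA_HA,
    )
    df1 = df.rename(columns={"class_t1": "class_code"})[["unit_id", "class_code", "area_ha"]]
    df1["field_id"] = field_t1.to_numpy()
    part1 = LandCoverPartition(units=df1, period="t1", total_study_area=STUDY_AREA_HA)

    # -- tree inventories ---------------------------------------------
    n_large0, n_small0 = TREES["large_t0"], TREES["small_t0"]
    tree_rows = [
        {"tree_id": f"T{i + 1:04d}", "size_class": "large"} for i in range(n_large0)
    ] + [
        {"tree_id": f"T{n_large0 + i + 1:04d}", "size_class": "small"}
        for i in range(n_small0)
    ]
    trees0 = pd.DataFrame(tree_rows)
    drop_large = int(round((n_large0 - TREES["large_t1"]) * scale))
    drop_small = int(round((n_small0 - TREES["small_t1"]) * scale))
    large_ids = trees0.loc[trees0["size_class"] == "large", "tree_id"].to_numpy()
    small_ids = trees0.loc[trees0["size_class"] == "small", "tree_id"].to_numpy()
    removed = set(rng.choice(large_ids, size=drop_large, replace=False)) | set(
        rng.choice(small_ids, size=drop_small, replace=False)
    )
    trees1 = trees0[~trees0["tree_id"].isin(removed)].reset_index(drop=True)

    inv0 = TreeInventory(trees=trees0, period="t0")
    inv1 = TreeInventory(trees=trees1, period="t1")
    return (part0, part1), (inv0, inv1)
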