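# Methods

## The benchmarking procedure

`agrivision` quantifies how well the observed development of a farming
landscape matches what different stakeholder groups *wanted* to happen.
The pipeline has four stages.

**1. Observed change.** Each indicator is measured at two time points
(here: a two-decade interval) per farm, or once per landscape. The
change is reclassified into three ordinal codes: −1 (decrease), 0 (no
change), +1 (increase). For quantitative indicators the code is 0 when
the magnitude of relative change, (v₁ − v₀)/v₀, is at most the
no-change threshold; otherwise it is the sign of v₁ − v₀. The threshold
applies to relative change because that is the only reading that is
unit-free across hectares, livestock units, counts and percentages. A
zero baseline with a nonzero follow-up is always a change (signed
sentinel). Likert-trend answers (satisfaction, valuation, economic
situation) are already direction codes and bypass the threshold; there
is no underlying magnitude to threshold. Landscape-scale indicators are
reclassified once from landscape-level values and broadcast identically
to every farm. One-time indicators (farmer age structure, succession)
have no computable change; their codes must be supplied externally and
default to 0 in the bundled pipeline (a configuration choice, exposed
as `one_time_codes`).

**2. Desired change.** A vision assigns each indicator a desired-change
set D ⊆ {−1, 0, +1} and an integer weight w ∈ {0, 1, 2}; w = 0 means
the indicator plays no role for that stakeholder. Set-valued desires
express ambivalence: "0|+1" accepts stability or growth, "any" accepts
every outcome. The scalar absolute difference |o − d| generalizes to
min over the set, so an ambivalent entry contributes zero difference
but still contributes 2w to the potential. A consequence worth knowing:
a category whose only weighted entries are fully ambivalent scores a
trivial 100%, not "undefined"; the undefined flag appears only when a
scored subset has zero total weight.

**3. Agreement.** Per farm and vision, difference = Σ w·min|o − d| over
indicators with w > 0 and a non-missing code, potential = Σ 2w over the
same indicators, agreement% = 100·(potential − difference)/potential.
Missing codes are excluded from both sums (per-farm renormalization)
rather than counted as disagreement, because interview non-response
varies by indicator and a fixed denominator would punish it. Agreement
is invariant under positive rescaling of a vision's weights, bounded in
[0, 100], and equals 100 exactly when every scorable code lies in its
desired set (asserted as properties).

**4. Comparison and robustness.** Per-farm agreements grouped by vision
are compared with the Kruskal–Wallis test followed by Dunn's pairwise
mean-rank z-tests with tie correction, Benjamini–Hochberg-adjusted over
the vision pairs. Each farm is assigned to its arg-max vision; ties
split fractionally so shares sum to one. Two sensitivity analyses
re-run everything: a threshold sweep (0 to 10% in 1% steps) and an
equal-weights re-run (every positive weight set to 1, zeros preserved),
plus their combination; the headline robustness output is whether the
weak ordering of visions by median agreement survives every
perturbation.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| no-change threshold | 0.05 | fraction of v₀ | survey answers and mapping are noisy; 5% separates noise from signal; admissible range [0, 0.5] |
| vision weights | bundled matrix | {0,1,2} | 2 = central demand, 1 = mentioned/implied, 0 = absent from the vision documents |
| sensitivity grid | 0.00–0.10 step 0.01 | fraction | brackets the plausible reading of "changed" for survey data |
| within-farm correlation ρ | 0.7 | — | generator assumption (see below); exposed because agreement medians depend on it |
| significance level | 0.05 | — | conventional; BH adjustment over the 3 vision pairs |

Medians use the midpoint convention (mean of the two central order
statistics for even n), so runs are comparable across tools.

## Statistical tests

Paired changes in interview indicators use the Wilcoxon signed-rank
test (two-sided, zero differences dropped); with ≤10 nonzero
differences the null is evaluated by exact permutation (valid under
ties), otherwise by the tie-corrected normal approximation. Field-size
distributions between snapshot years are compared with the unpaired
rank-sum test, since polygons are not paired across maps. Both are
verified in the test suite against brute-force enumeration oracles at
small n, and the Dunn z-statistic against a label-permutation null.

## Landscape metrics

Land cover uses a broad EUNIS-style legend with intensity qualifiers
(11 classes). Agricultural area = {crops, intensive and extensive
grassland, shrub plantations, intensive and high-stem orchards};
intensive agricultural land = {crops, intensive grassland, intensive
orchards}; semi-natural habitat = {wetland, extensive grassland,
high-stem orchards, forest}. The proportion of intensively used
agricultural land is reported relative to total *agricultural* area by
default: the landscape series of the study region (93% → 90% against
1781 → 1737 ha) is arithmetically consistent only with that
denominator, the 2500 ha study area being impossible (0.93·2500 >
1781). A `study_area` denominator is exposed for the alternative
definition. The semi-natural share uses the total study area.

Transition matrices cross-tabulate area over a shared tessellation
(unit-id join); spatial overlay is deliberately out of scope — inputs
must already be expressed on common units, with an optional `field_id`
grouping units into field polygons for the mean-field-size statistic.
High-stem orchards are parcels with ≥3 field trees at a density
strictly above 20 trees ha⁻¹. Tree-loss percentages are rounded half
away from zero to integer percent for reporting.

## What the synthetic generator emulates

The generator stands in for a 20-farm structured-interview panel and a
paired orthophoto interpretation of a 2500 ha lowland landscape. It is
calibrated to the study conditions:

* **Marginals.** Strictly positive quantities (areas, livestock units)
  are lognormal; percentages are clipped normals on [0, 100]; counts
  are rounded nonnegative normals. Means and SDs at both time points
  follow the published cohort table (e.g. farm area 23.9 ± 7.9 →
  37.7 ± 27.0 ha). Untruncated normals are ruled out by SDs comparable
  to means. Price and production trends are stored as index values
  (t0 = 100) so the uniform threshold rule applies.
* **Within-farm dependence.** t₁ latents correlate with t₀ latents at
  ρ = 0.7 — an assumption, since no within-farm correlation was
  published — plus an indicator-specific probability of reporting
  exactly no change. Survey answers are also coarse, so reported values
  are rounded to realistic precision (whole hectares and LU, multiples
  of 5 percentage points, ~10 kg N). Both mechanisms produce the exact
  zeros real interview data contain.
* **Cohort structure.** Farm types are fixed at 8 dairy / 10 mixed / 2
  arable (arable farms carry structural zeros for livestock and skip
  the feed question). Development trajectories are fixed at 14
  growth-oriented / 5 persistent / 1 greening, mirroring the reported
  farm-trajectory heterogeneity; trajectories modulate stay
  probabilities, growth ratios, and the Likert shares (61% perceived
  declining societal valuation overall; economic situation worse for
  ~50% of dairy vs ~25% of other farms; 82% increased production).
  Livestock density is derived as LU/area, never drawn.
* **Missingness.** Per-indicator interview n (14–20 of 20) is imposed
  by blanking farms at random; missingness propagates, it is never
  imputed.
* **Landscape.** A field tessellation (lognormal field sizes, mean
  1.35 ha) plus coarse non-field units realizes an exact class-level
  flow budget: intensive land to settlement (+37 ha), extensive
  grassland (+60.6 ha) and wetland (+8 ha), shrinking high-stem
  orchards (−7.5 ha), with a symmetric crop↔grassland churn mimicking
  rotation. Conversions take the smallest fields first and remaining
  intensive units merge into fewer, larger fields — consolidation — so
  the derived series hits total agricultural area 1781 → 1737 ha,
  mean field size 1.35 → 1.81 ha, intensive share 93 → 90%,
  semi-natural share 19.8 → 22.2% within 1%. Tree inventories are
  1631 large + 598 small → 1256 + 562, the unique integer solution
  consistent with the published totals and rounded percent changes.

**What it does not emulate.** Joint dependence across indicators beyond
the trajectory mixture (a farm's feed import and its area growth are
conditionally independent); real spatial geometry (areas on a
tessellation, no polygons); reporting biases of retrospective
interviews; multi-decade dynamics. Passing tests therefore show the
pipeline arithmetic and its statistical behavior are right under
realistic marginals and cohort structure — not that the generator
reproduces any particular real landscape. One knock-on effect is
visible in the bundled results: because every synthetic farm faces the
same landscape codes, the cohort-wide valuation decline and zero-coded
one-time indicators, agreement with the conservative vision has a hard
ceiling near 72% even for a fully persistent farm, which pulls its
median and best-vision share below the study's values while leaving
the vision ranking intact.

## Numerical and degenerate-input choices

Sample SDs use the n−1 denominator. The no-change comparison uses an
absolute epsilon (1e-12) so exact-boundary cases (2.0 → 2.1 at 5%)
classify as no change. All-zero paired differences give p = 1 with a
warning, not an exception. Zero-potential agreement is NaN-flagged, and
farms with no defined agreement are excluded from best-vision shares
with a warning. Identical unpaired samples short-circuit to p = 1.
Empty panels produce an explicit "no farms" report. All randomness
flows from a single integer seed; identical configurations produce
byte-identical JSON reports (sorted keys, fixed row order).

## Known limitations

* The agreement statistic treats the ordinal codes as equally spaced
  (|+1 − (−1)| = 2); no attempt is made to weight strong versus weak
  changes.
* Ambivalent vision entries inflate agreement (they can only add to the
  potential, never to the difference); comparisons between visions with
  different numbers of ambivalent entries inherit that asymmetry.
* Landscape indicators give every farm the same code, so with 6 of 22
  indicators landscape-driven, per-farm agreement differences are
  compressed.
* The equal-weights sensitivity delta is a difference of medians of a
  bounded score; for a vision whose double-weighted entries balance
  between agreement and disagreement its sign is unstable at cohort
  size 20.
* Problem sizes in the bundled analyses — 20 farms, 50 generator seeds
  for grand statistics, 12 seeds for the sensitivity sweep — are the
  package's desk-scale defaults; all loops scale linearly if larger
  cohorts are wanted.
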