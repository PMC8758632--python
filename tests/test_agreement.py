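"""Agreement statistic, best-vision assignment, and cross-vision tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from agrivision import (
    IndicatorDef,
    IndicatorRegistry,
    VisionSpec,
    best_vision_shares,
    compare_visions,
    dunn_test,
    score_farm,
    score_matrix,
)


def mini_registry(n):
    return IndicatorRegistry(
        [
            IndicatorDef(id=f"i{k}", name=f"i{k}", unit="", category="economic",
                         scale="farm", kind="quantitative")
            for k in range(n)
        ]
    )


def mini_vision(desired, weights, registry):
    return VisionSpec(
        vision_id="v",
        desired={f"i{k}": d for k, d in enumerate(desired)},
        weights={f"i{k}": w for k, w in enumerate(weights)},
        registry=registry,
    )


def eq_score(observed, desired, weights):
    """Independent inline evaluation of the agreement formula."""
    diff = pot = 0.0
    for o, d, w in zip(observed, desired, weights):
        if w == 0 or o is None:
            continue
        diff += w * min(abs(o - x) for x in d)
        pot += 2 * w
    return 100.0 * (pot - diff) / pot if pot else None


class TestScoreFarm:
    def test_full_agreement(self):
        reg = mini_registry(3)
        vision = mini_vision([(1,), (-1,), (0,)], [1, 2, 1], reg)
        row = pd.Series({"i0": 1, "i1": -1, "i2": 0})
        res = score_farm(row, vision)
        assert res.agreement_pct == 100.0
        assert res.difference == 0.0

    def test_full_disagreement(self):
        reg = mini_registry(2)
        vision = mini_vision([(1,), (-1,)], [1, 2], reg)
        row = pd.Series({"i0": -1, "i1": 1})
        res = score_farm(row, vision)
        assert res.agreement_pct == 0.0
        assert res.difference == res.potential == 6.0

    def test_hand_worked_example(self):
        """w = (1,2,1), desired = ({+1},{−1},{0}), observed all +1 →
        difference 5, potential 8, agreement 37.5%."""
        reg = mini_registry(3)
        vision = mini_vision([(1,), (-1,), (0,)], [1, 2, 1], reg)
        res = score_farm(pd.Series({"i0": 1, "i1": 1, "i2": 1}), vision)
        assert (res.difference, res.potential) == (5.0, 8.0)
        assert res.agreement_pct == pytest.approx(37.5)

    def test_zero_potential_flagged_undefined(self):
        reg = mini_registry(2)
        vision = mini_vision([(), ()], [0, 0], reg)
        res = score_farm(pd.Series({"i0": 1, "i1": 0}), vision)
        assert not res.defined
        assert np.isnan(res.agreement_pct)

    def test_matches_exhaustive_enumeration(self):
        """Oracle equivalence over every observed vector in {−1,0,+1}^n."""
        reg = mini_registry(4)
        desired = [(1,), (-1, 0, 1), (0, 1), (-1,)]
        weights = [2, 1, 1, 2]
        vision = mini_vision(desired, weights, reg)
        for obs in product((-1, 0, 1), repeat=4):
            res = score_farm(pd.Series(dict(zip(reg.ids, obs))), vision)
            assert res.agreement_pct == pytest.approx(eq_score(obs, desired, weights))

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_scale_invariance(self, data):
        n = data.draw(st.integers(2, 6))
        reg = mini_registry(n)
        sets = [(1,), (0,), (-1,), (0, 1), (-1, 0, 1)]
        desired = [data.draw(st.sampled_from(sets)) for _ in range(n)]
        weights = [data.draw(st.integers(1, 2)) for _ in range(n)]
        obs = [data.draw(st.sampled_from([-1, 0, 1, None])) for _ in range(n)]
        vision = mini_vision(desired, weights, reg)
        row = pd.Series(dict(zip(reg.ids, obs)), dtype=object)
        res = score_farm(row, vision)
        if res.defined:
            assert 0.0 <= res.agreement_pct <= 100.0
            scaled = score_farm(row, vision.scaled(3))
            assert scaled.agreement_pct == pytest.approx(res.agreement_pct)

    def test_all_missing_indicator_leaves_score_invariant(self):
        reg_small = mini_registry(2)
        v_small = mini_vision([(1,), (0,)], [2, 1], reg_small)
        base = score_farm(pd.Series({"i0": 1, "i1": -1}), v_small)
        reg_big = mini_registry(3)
        v_big = mini_vision([(1,), (0,), (-1,)], [2, 1, 2], reg_big)
        extended = score_farm(
            pd.Series({"i0": 1, "i1": -1, "i2": None}, dtype=object), v_big
        )
        assert extended.agreement_pct == pytest.approx(base.agreement_pct)

    def test_monotone_damage(self):
        """Moving one observed code away from a singleton desired value
        never increases agreement."""
        reg = mini_registry(3)
        vision = mini_vision([(1,), (0,), (-1,)], [1, 2, 1], reg)
        for start, worse in (((1, 0, -1), (0, 0, -1)), ((0, 0, -1), (-1, 0, -1)),
                             ((1, 0, -1), (1, 1, -1)), ((1, 0, -1), (1, 0, 0))):
            a = score_farm(pd.Series(dict(zip(reg.ids, start))), vision)
            b = score_farm(pd.Series(dict(zip(reg.ids, worse))), vision)
            assert b.agreement_pct <= a.agreement_pct

    def test_category_filter_restricts_scoring(self, visions, default_results):
        row = default_results.observed.row("F001")
        full = score_farm(row, visions["SBV"])
        social = score_farm(row, visions["SBV"], category_filter={"social"})
        assert social.potential <= full.potential
        assert social.agreement_pct == pytest.approx(
            full.category_agreement["social"], nan_ok=True
        )


class TestBestVisionShares:
    def scores_frame(self, rows):
        return pd.DataFrame(rows, columns=["farm_id", "vision_id", "agreement_pct"])

    def test_strict_maximum(self):
        scores = self.scores_frame(
            [("f", "AS", 80.0), ("f", "SBV", 70.0), ("f", "LmZ", 50.0)]
        )
        assert best_vision_shares(scores) == {"AS": 1.0, "SBV": 0.0, "LmZ": 0.0}

    def test_ties_split_fractionally(self):
        scores = self.scores_frame(
            [("f", "AS", 70.0), ("f", "SBV", 70.0), ("f", "LmZ", 50.0)]
        )
        shares = best_vision_shares(scores)
        assert shares == {"AS": 0.5, "SBV": 0.5, "LmZ": 0.0}

    def test_undefined_farm_excluded_with_warning(self):
        scores = self.scores_frame(
            [("f", "AS", np.nan), ("f", "SBV", np.nan),
             ("g", "AS", 60.0), ("g", "SBV", 50.0)]
        )
        with pytest.warns(UserWarning, match="no defined agreement"):
            shares = best_vision_shares(scores)
        assert shares == {"AS": 1.0, "SBV": 0.0}

    def test_shares_sum_to_one(self, default_results):
        assert sum(default_results.best_vision_shares().values()) == pytest.approx(1.0)


class TestCompareVisions:
    def scores_frame(self, groups):
        rows = []
        for vid, vals in groups.items():
            for i, v in enumerate(vals):
                rows.append((f"f{i}", vid, float(v)))
        return pd.DataFrame(rows, columns=["farm_id", "vision_id", "agreement_pct"])

    def test_identical_groups_degenerate(self):
        scores = self.scores_frame({v: [50.0] * 6 for v in ("A", "B", "C")})
        comp = compare_visions(scores)
        assert comp.kw_statistic == 0.0
        assert comp.kw_p == 1.0
        assert all(p == 1.0 for p in comp.pairwise_p.values())

    def test_separated_groups_all_significant(self):
        scores = self.scores_frame(
            {"A": range(1, 11), "B": range(11, 21), "C": range(21, 31)}
        )
        comp = compare_visions(scores)
        assert comp.kw_p < 0.001
        assert all(p < 0.05 for p in comp.pairwise_p.values())

    def test_dunn_z_matches_permutation_oracle(self):
        """Normal-approximation Dunn p agrees with a label-permutation
        null of the mean-rank difference at n = 10 per group."""
        rng = np.random.default_rng(3)
        groups = {
            "A": rng.normal(0.0, 1.0, 10),
            "B": rng.normal(0.8, 1.0, 10),
            "C": rng.normal(1.6, 1.0, 10),
        }
        _, z_stats = dunn_test(groups)
        pooled = np.concatenate(list(groups.values()))
        labels = np.repeat([0, 1, 2], 10)
        pair_index = {("A", "B"): (0, 1), ("A", "C"): (0, 2), ("B", "C"): (1, 2)}
        n_perm = 4000
        for pair, (ga, gb) in pair_index.items():
            obs = abs(z_stats[pair])
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(labels)
                ranks = stats.rankdata(pooled)
                ra = ranks[perm == ga].mean()
                rb = ranks[perm == gb].mean()
                # same standardization as the Dunn statistic
                n_tot = len(pooled)
                se = np.sqrt((n_tot * (n_tot + 1) / 12) * (1 / 10 + 1 / 10))
                count += abs((ra - rb) / se) >= obs
            p_perm = count / n_perm
            p_norm = 2 * stats.norm.sf(obs)
            assert p_perm == pytest.approx(p_norm, abs=0.03)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="2 visions"):
            compare_visions(self.scores_frame({"A": range(6)}))
        with pytest.raises(ValueError, match="5 farms"):
            compare_visions(self.scores_frame({"A": [1, 2], "B": [3, 4]}))

    def test_default_cohort_lmz_separated(self, default_results):
        """The agroecological vision disagrees most with observed
        development: both contrasts against it are significant."""
        comp = default_results.comparison
        assert comp.kw_p < 0.001
        assert comp.pairwise_p[("AS", "LmZ")] < 0.05
        assert comp.pairwise_p[("SBV", "LmZ")] < 0.05


def test_score_matrix_cardinality(default_results):
    scores = default_results.scores
    assert len(scores) == 20 * 3
    assert scores["agreement_pct"].between(0, 100).all()
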