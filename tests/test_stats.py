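"""Friedman gate, Wilcoxon signed-rank, Bonferroni tiers and effect sizes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from hapticlab.stats import (
    ALPHA_TIERS,
    ComparisonPlan,
    DegenerateTestError,
    bonferroni_alpha_tiers,
    bonferroni_tier,
    cohen_d,
    friedman_gate,
    run_battery,
    wilcoxon_pairwise,
)


def enumeration_wilcoxon_p(a, b):
    """Independent oracle: exact two-sided p by enumerating all 2^n sign
    assignments on the Pratt-ranked absolute differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    ranks = sps.rankdata(np.abs(d))
    nz = d != 0
    r = ranks[nz]
    w_obs = ranks[nz & (d > 0)].sum()
    ws = [
        np.sum(np.array(signs) * r)
        for signs in itertools.product((0, 1), repeat=len(r))
    ]
    ws = np.asarray(ws)
    eps = 1e-9
    p_le = np.mean(ws <= w_obs + eps)
    p_ge = np.mean(ws >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestFriedman:
    def test_degenerate_blocks(self):
        stat, p = friedman_gate(np.tile([[3.0, 3.0, 3.0]], (6, 1)))
        assert stat == 0.0 and p == 1.0

    def test_uniform_shift_detected(self, rng):
        x = rng.normal(0, 1, (9, 3))
        x[:, 0] += 10.0
        _, p = friedman_gate(x)
        assert p < 0.05

    def test_label_permutation_invariance(self, rng):
        x = rng.normal(0, 1, (8, 3))
        _, p1 = friedman_gate(x)
        _, p2 = friedman_gate(x[:, [2, 0, 1]])
        assert p1 == pytest.approx(p2)

    def test_missing_cells_rejected(self):
        x = np.ones((5, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            friedman_gate(x)


class TestWilcoxon:
    def test_all_positive_differences_exact(self):
        a = np.arange(1.0, 10.0)
        p = wilcoxon_pairwise(a, np.zeros(9))
        assert p == pytest.approx(2 / 2**9, abs=1e-15)

    def test_symmetric_null_large_p(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        b = a + np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        assert wilcoxon_pairwise(a, b) > 0.5

    def test_matches_enumeration_on_random_fixtures(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 11))
            a = np.round(rng.normal(0, 1, n), 2)
            b = np.round(rng.normal(0, 1, n), 2)
            if np.all(a == b):
                continue
            assert wilcoxon_pairwise(a, b) == pytest.approx(
                enumeration_wilcoxon_p(a, b), abs=1e-12
            )

    def test_zeros_handled_pratt(self):
        a = np.array([1.0, 2, 3, 4, 5, 6, 7])
        b = a.copy()
        b[:3] -= 1.0  # 4 zero differences remain
        p = wilcoxon_pairwise(a, b)
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(enumeration_wilcoxon_p(a, b), abs=1e-12)

    def test_degenerate_signalled(self):
        with pytest.raises(DegenerateTestError):
            wilcoxon_pairwise(np.ones(6), np.ones(6))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_pairwise(np.ones(3), np.zeros(3))


class TestBonferroni:
    def test_tier_arithmetic(self):
        assert bonferroni_alpha_tiers() == (0.017, 0.003, 0.0003)

    @pytest.mark.parametrize(
        "p,stars",
        [(0.002, 2), (0.05, 0), (0.0003, 3), (0.017, 1), (0.0031, 1), (0.5, 0)],
    )
    def test_tier_assignment(self, p, stars):
        assert bonferroni_tier(p) == stars

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_p(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert bonferroni_tier(lo) >= bonferroni_tier(hi)

    def test_plan_validation(self):
        with pytest.raises(ValueError):
            ComparisonPlan("grasp", ("GV", "NH"))
        with pytest.raises(ValueError):
            ComparisonPlan("grasp", ("GV", "GC", "NH"),
                           alpha_tiers=(0.003, 0.017, 0.0003))


class TestCohenD:
    def test_identical_samples(self):
        assert cohen_d([1.0, 2, 3], [1.0, 2, 3]) == pytest.approx(0.0)

    def test_unit_effect(self, rng):
        a = rng.normal(1.0, 1.0, 100000)
        b = rng.normal(0.0, 1.0, 100000)
        assert cohen_d(a, b) == pytest.approx(1.0, abs=0.05)

    def test_hand_computation(self):
        assert cohen_d([2.0, 4, 6], [1.0, 2, 3]) == pytest.approx(1.265, abs=1e-3)

    def test_dz_variant(self):
        a = np.array([2.0, 3.0, 4.0])
        d = a - np.array([1.0, 1.5, 2.0])
        assert cohen_d(a, a - d, variant="dz") == pytest.approx(
            np.mean(d) / np.std(d, ddof=1)
        )

    def test_degenerate(self):
        with pytest.raises(DegenerateTestError):
            cohen_d([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


def _tidy(values_by_condition, metric="pose_mean", channel="grasp_ratio", phase=3):
    rows = []
    for cond, vals in values_by_condition.items():
        for s, v in enumerate(vals, start=1):
            rows.append(
                dict(subject=s, condition=cond, phase=phase, metric=metric,
                     channel=channel, value=v)
            )
    return pd.DataFrame(rows)


class TestBattery:
    def test_identical_conditions_no_pairwise(self, rng):
        base = rng.normal(0, 1, 9)
        table = _tidy({c: base for c in ("GV", "GC", "NH")})
        report = run_battery(table)
        assert len(report.pairwise) == 0

    def test_gate_discipline(self, rng):
        """Pairwise rows appear only for gated Friedman cells."""
        table = pd.concat(
            [
                _tidy({c: rng.normal(0, 1, 9) for c in ("GV", "GC", "NH")},
                      phase=p)
                for p in (1, 2, 3)
            ]
        )
        report = run_battery(table)
        gated = set(
            map(tuple, report.friedman.query("gated")[
                ["family", "metric", "channel", "phase"]
            ].to_numpy())
        )
        for row in report.pairwise.itertuples():
            assert (row.family, row.metric, row.channel, row.phase) in gated

    def test_row_bookkeeping(self, rng):
        """One Friedman row per family x metric x channel x phase cell."""
        conds = {c: rng.normal(0, 1, 9) for c in ("GV", "GC", "NH", "RV", "RC")}
        table = pd.concat(
            [
                _tidy(conds, metric=m, phase=p)
                for m in ("pose_mean", "emg_rms")
                for p in (1, 2)
            ]
        )
        report = run_battery(table)
        assert len(report.friedman) == 2 * 2 * 2  # families x metrics x phases

    def test_strong_effect_detected(self, rng):
        table = _tidy(
            {
                "GV": rng.normal(0.5, 0.03, 9),
                "GC": rng.normal(0.6, 0.06, 9),
                "NH": rng.normal(0.7, 0.1, 9),
            }
        )
        report = run_battery(table)
        assert report.friedman["gated"].all()
        gv_nh = report.pairwise.query("pair == 'GV-NH'")
        assert len(gv_nh) == 1 and gv_nh["stars"].iloc[0] >= 1
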