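"""Nonparametric repeated-measures battery.

Within each three-condition family (grasp: GV, GC, NH; pronosupination:
RV, RC, NH), every metric x channel x phase cell is gated by a Friedman
test across conditions; only when the gate passes (p < 0.05) are the three
pairwise Wilcoxon signed-rank tests run, with Bonferroni-tiered
significance levels for three paired tests: alpha = 0.017 (*), 0.003 (**)
and 0.0003 (***).  Effect sizes are Cohen's d (pooled-SD by default) and
descriptives carry Student-t 95% confidence intervals.  No correction is
applied across metrics or phases; the correction spans only the three
pairwise tests of a family.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import descriptives

__all__ = [
    "FAMILIES",
    "ALPHA_TIERS",
    "ComparisonPlan",
    "StatReport",
    "DegenerateTestError",
    "friedman_gate",
    "wilcoxon_pairwise",
    "bonferroni_alpha_tiers",
    "bonferroni_tier",
    "cohen_d",
    "run_battery",
]

#: the two pre-registered three-condition comparisons
FAMILIES = {
    "grasp": ("GV", "GC", "NH"),
    "pronosupination": ("RV", "RC", "NH"),
}

#: significance thresholds for one, two and three asterisks
ALPHA_TIERS = (0.017, 0.003, 0.0003)


class DegenerateTestError(ValueError):
    """Raised when a test statistic is undefined (e.g. all-zero differences)."""


@dataclass(frozen=True)
class ComparisonPlan:
    """A three-condition family and its Bonferroni tier thresholds."""

    family: str
    conditions: tuple
    alpha_tiers: tuple = ALPHA_TIERS

    def __post_init__(self) -> None:
        if len(self.conditions) != 3:
            raise ValueError("a comparison family contains exactly 3 conditions")
        if list(self.alpha_tiers) != sorted(self.alpha_tiers, reverse=True):
            raise ValueError("alpha tiers must be strictly decreasing")

    @property
    def pairs(self):
        return list(itertools.combinations(self.conditions, 2))


def default_plans() -> list:
    return [ComparisonPlan(name, conds) for name, conds in FAMILIES.items()]


# ---------------------------------------------------------------------------
# primitive tests


def friedman_gate(values: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test on a subjects x conditions block.

    Returns ``(statistic, p)``.  Ties use mid-ranks with the chi-square
    tie correction; a fully degenerate block (identical values within every
    subject) has statistic 0 and p = 1.  Missing cells are an error --
    the design is complete-blocks, nothing is imputed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("values must be subjects x (>=3) conditions")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    if not np.isfinite(x).all():
        raise ValueError("missing cells in a complete-blocks design")
    if all(np.ptp(row) == 0 for row in x):
        return 0.0, 1.0
    stat, p = sps.friedmanchisquare(*(x[:, j] for j in range(x.shape[1])))
    if not math.isfinite(p):  # tie correction can degenerate
        return 0.0, 1.0
    return float(stat), float(p)


def _signed_rank_exact_p(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p via a generating-function convolution.

    Zeros are handled by the Pratt method: ranked with the rest, then
    dropped from the statistic.  Midranks (from tied magnitudes) are
    doubled to keep the distribution support on integers.
    """
    ranks = sps.rankdata(np.abs(diffs))
    nonzero = diffs != 0
    r2 = np.rint(2.0 * ranks[nonzero]).astype(int)
    w_obs = int(np.rint(2.0 * np.sum(ranks[nonzero & (diffs > 0)])))
    total = int(r2.sum())
    # distribution of W+ (doubled) over equiprobable sign assignments
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    p_le = counts[: w_obs + 1].sum()
    p_ge = counts[w_obs:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_pairwise(
    values_a,
    values_b,
    exact_max_n: int = 12,
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Exact (full null distribution, Pratt zero handling) for n <=
    ``exact_max_n``; normal approximation beyond.  All-zero differences
    raise :class:`DegenerateTestError`.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    if np.all(d == 0):
        raise DegenerateTestError("all paired differences are zero")
    if len(d) <= exact_max_n:
        return _signed_rank_exact_p(d)
    res = sps.wilcoxon(a, b, zero_method="pratt", correction=True,
                       alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def bonferroni_alpha_tiers(
    base_levels=(0.05, 0.01, 0.001), n_tests: int = 3
) -> tuple:
    """Tiered significance thresholds for ``n_tests`` paired comparisons.

    Each base level is divided by the number of tests and rounded to the
    precision at which such thresholds are conventionally reported (3
    decimals, or 4 when the corrected level drops below 0.001):
    (0.05, 0.01, 0.001) / 3 -> (0.017, 0.003, 0.0003).
    """
    tiers = []
    for level in base_levels:
        corrected = level / n_tests
        decimals = 3 if corrected >= 0.001 else 4
        tiers.append(round(corrected, decimals))
    return tuple(tiers)


def bonferroni_tier(p: float, tiers=ALPHA_TIERS) -> int:
    """Number of asterisks (0-3) for a pairwise p-value."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    stars = 0
    for threshold in sorted(tiers, reverse=True):
        if p <= threshold:
            stars += 1
    return stars


def cohen_d(values_a, values_b, variant: str = "pooled") -> float:
    """Cohen's d effect size for paired condition samples.

    ``"pooled"`` (default): difference of means over the pooled sample SD;
    ``"dz"``: mean of the paired differences over their SD.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if variant == "pooled":
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if va == 0 and vb == 0:
            if np.mean(a) == np.mean(b):
                return 0.0
            raise DegenerateTestError("zero variance in both samples")
        return float((np.mean(a) - np.mean(b)) / math.sqrt((va + vb) / 2.0))
    if variant == "dz":
        d = a - b
        sd = np.std(d, ddof=1)
        if sd == 0:
            if np.all(d == 0):
                return 0.0
            raise DegenerateTestError("zero variance of paired differences")
        return float(np.mean(d) / sd)
    raise ValueError(f"unknown Cohen's d variant {variant!r}")


# ---------------------------------------------------------------------------
# battery


@dataclass
class StatReport:
    """Friedman gates, gated pairwise results and descriptives."""

    friedman: pd.DataFrame
    pairwise: pd.DataFrame
    descriptive: pd.DataFrame
    notes: list = field(default_factory=list)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.friedman.to_csv(out / "stat_friedman.csv", index=False,
                             float_format="%.9g")
        self.pairwise.to_csv(out / "stat_pairwise.csv", index=False,
                             float_format="%.9g")
        self.descriptive.to_csv(out / "stat_descriptives.csv", index=False,
                                float_format="%.9g")

    def summary_json(self) -> dict:
        sig = self.pairwise[self.pairwise["stars"] > 0] if len(self.pairwise) else self.pairwise
        return {
            "n_families_tested": int(len(self.friedman)),
            "n_families_gated": int(self.friedman["gated"].sum()) if len(self.friedman) else 0,
            "n_pairwise": int(len(self.pairwise)),
            "n_significant_pairwise": int(len(sig)),
            "notes": self.notes,
        }


def run_battery(
    metrics: pd.DataFrame,
    plans: list | None = None,
    gate_alpha: float = 0.05,
    effect_variant: str = "pooled",
) -> StatReport:
    """Run the full Friedman -> Wilcoxon -> Bonferroni battery.

    ``metrics`` is the tidy subject-level table (columns subject,
    condition, phase, metric, channel, value).  Pairwise rows exist only
    for cells whose Friedman gate passed.
    """
    plans = plans if plans is not None else default_plans()
    friedman_rows, pairwise_rows, notes = [], [], []

    for plan in plans:
        sub = metrics[metrics["condition"].isin(plan.conditions)]
        for (metric, channel, phase), cell in sub.groupby(
            ["metric", "channel", "phase"]
        ):
            pivot = cell.pivot_table(
                index="subject", columns="condition", values="value"
            )
            if pivot.shape[1] < 3 or pivot.isna().any().any() or len(pivot) < 3:
                continue
            block = pivot[list(plan.conditions)].to_numpy()
            stat, p = friedman_gate(block)
            gated = p < gate_alpha
            friedman_rows.append(
                {
                    "family": plan.family, "metric": metric, "channel": channel,
                    "phase": phase, "statistic": stat, "p": p, "gated": gated,
                }
            )
            if not gated:
                continue
            for cond_a, cond_b in plan.pairs:
                va = pivot[cond_a].to_numpy()
                vb = pivot[cond_b].to_numpy()
                try:
                    p_w = wilcoxon_pairwise(va, vb)
                    d = cohen_d(va, vb, effect_variant)
                except DegenerateTestError as exc:
                    notes.append(
                        f"{plan.family}/{metric}/{channel}/phase{phase} "
                        f"{cond_a}-{cond_b}: {exc}"
                    )
                    continue
                pairwise_rows.append(
                    {
                        "family": plan.family, "metric": metric,
                        "channel": channel, "phase": phase,
                        "pair": f"{cond_a}-{cond_b}", "wilcoxon_p": p_w,
                        "cohen_d": d,
                        "stars": bonferroni_tier(p_w, plan.alpha_tiers),
                    }
                )

    friedman_df = pd.DataFrame(
        friedman_rows,
        columns=["family", "metric", "channel", "phase", "statistic", "p", "gated"],
    )
    pairwise_df = pd.DataFrame(
        pairwise_rows,
        columns=["family", "metric", "channel", "phase", "pair", "wilcoxon_p",
                 "cohen_d", "stars"],
    )
    desc = descriptives(metrics)
    return StatReport(friedman_df, pairwise_df, desc, notes)
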