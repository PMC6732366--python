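"""Rank-change evaluation statistics.

Summaries of per-gene rank shifts, the Wilcoxon rank-sum test for comparing
shift distributions between gene groups, and a permutation "nested ranks"
test that compares two conditions across several modules while permuting
only within modules (a light-weight analogue of a mixed-effects rank test).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .rerank import RankChange

logger = logging.getLogger(__name__)

ALTERNATIVES = ("TWO_SIDED", "GREATER", "LESS")
_SCIPY_ALT = {"TWO_SIDED": "two-sided", "GREATER": "greater", "LESS": "less"}

#: sample-size ceiling for the exact Wilcoxon enumeration path
EXACT_MAX_N = 12


@dataclass(frozen=True)
class RankShiftSummary:
    n_up: int
    n_down: int
    n_same: int
    max_up: int
    max_down: int

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down + self.n_same


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str  # WILCOXON_RANK_SUM | NESTED_RANKS_PERM
    alternative: str
    n_perm: int | None = None
    seed: int | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "statistic": self.statistic,
                "p_value": self.p_value,
                "method": self.method,
                "alternative": self.alternative,
                "n_perm": self.n_perm,
                "seed": self.seed,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload


def rank_shift_summary(changes: Sequence[RankChange]) -> RankShiftSummary:
    """Counts of improved / worsened / unchanged genes plus extreme moves."""
    deltas = [c.delta for c in changes]
    ups = [d for d in deltas if d > 0]
    downs = [d for d in deltas if d < 0]
    return RankShiftSummary(
        n_up=len(ups),
        n_down=len(downs),
        n_same=len(deltas) - len(ups) - len(downs),
        max_up=max(ups, default=0),
        max_down=max((-d for d in downs), default=0),
    )


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], alternative: str = "TWO_SIDED"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with mid-ranks for ties.

    Small tie-free samples (total n <= 12) take the exact enumeration path;
    otherwise the normal approximation with tie and continuity correction is
    used.  The reported statistic is the rank-sum W of ``x``.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")

    combined = np.concatenate([x, y])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (tie_free and combined.size <= EXACT_MAX_N) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=_SCIPY_ALT[alternative], method=method, use_continuity=True
    )
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U1 -> rank-sum of x
    return TestResult(
        statistic=w,
        p_value=float(min(res.pvalue, 1.0)),
        method="WILCOXON_RANK_SUM",
        alternative=alternative,
    )


def _group_z(ranks: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """Mean and sd of the rank-sum of the masked condition under within-group
    permutation, with tie correction; returns (W, mu, sigma)."""
    n = ranks.size
    n1 = int(mask.sum())
    n0 = n - n1
    w = float(ranks[mask].sum())
    mu = n1 * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    var = n0 * n1 / 12.0 * ((n + 1) - tie_term)
    return w, mu, math.sqrt(max(var, 0.0))


def nested_ranks_test(
    values: Sequence[float],
    groups: Sequence,
    condition: Sequence[int],
    n_perm: int = 1999,
    seed: int | None = None,
    alternative: str = "TWO_SIDED",
) -> TestResult:
    """Permutation test of a condition effect on ``values`` stratified by
    group (module).

    The observed statistic is the group-size-weighted mean of within-group
    rank-sum Z scores for condition 1; the null distribution permutes
    condition labels *within* each group, preserving group structure.  The
    one-sided p-value uses the add-one estimator (1 + #{perm >= obs}) /
    (1 + n_perm); the two-sided p doubles the smaller tail and caps at 1.

    Groups containing a single condition (or all-tied values) carry no
    information and are dropped with a warning.
    """
    if alternative not in ALTERNATIVES:
        raise ValidationError(f"unknown alternative {alternative!r}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    condition = np.asarray(condition, dtype=int)
    if not (values.size == groups.size == condition.size):
        raise ValidationError("values, groups and condition must have equal length")
    if not set(np.unique(condition)) <= {0, 1}:
        raise ValidationError("condition labels must be binary 0/1")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")

    rng = np.random.default_rng(seed)
    usable = []
    for g in sorted(set(groups.tolist()), key=str):
        idx = np.flatnonzero(groups == g)
        cond = condition[idx]
        if cond.min() == cond.max():
            logger.warning("group %r has a single condition; dropped", g)
            continue
        ranks = sps.rankdata(values[idx])
        w, mu, sigma = _group_z(ranks, cond.astype(bool))
        if sigma == 0.0:
            logger.warning("group %r has zero rank variance; dropped", g)
            continue
        usable.append((idx.size, np.sort(ranks), int(cond.sum()), w, mu, sigma))
    if not usable:
        raise ValidationError("no group contains both conditions")
    # consume the permutation stream in an order keyed by group content, so
    # p-values are invariant to group renaming and within-group reordering
    usable.sort(key=lambda u: (u[0], u[2], tuple(u[1])))

    total = sum(n for n, *_ in usable)
    weights = np.array([n / total for n, *_ in usable])
    observed = float(
        np.sum(weights * np.array([(w - mu) / sigma for _, _, _, w, mu, sigma in usable]))
    )

    perm_stats = np.zeros(n_perm)
    for (n, sorted_ranks, n1, _, mu, sigma), w_g in zip(usable, weights):
        # permute labels within the group: each row of random keys induces a
        # uniform draw of n1 ranks without replacement
        order = np.argsort(rng.random((n_perm, n)), axis=1)[:, :n1]
        perm_w = sorted_ranks[order].sum(axis=1)
        perm_stats += w_g * (perm_w - mu) / sigma

    p_ge = (1 + int(np.sum(perm_stats >= observed))) / (1 + n_perm)
    p_le = (1 + int(np.sum(perm_stats <= observed))) / (1 + n_perm)
    if alternative == "GREATER":
        p = p_ge
    elif alternative == "LESS":
        p = p_le
    else:
        p = min(1.0, 2.0 * min(p_ge, p_le))
    return TestResult(
        statistic=observed,
        p_value=p,
        method="NESTED_RANKS_PERM",
        alternative=alternative,
        n_perm=n_perm,
        seed=seed,
    )


def export_rank_change_table(
    changes: Sequence[RankChange], path: str | Path
) -> pd.DataFrame:
    """Plot-ready TSV of rank deltas: direction color and log10 |delta|
    (the transform is for display only; tests operate on raw deltas)."""
    rows = []
    for c in changes:
        color = "green" if c.delta > 0 else ("red" if c.delta < 0 else "grey")
        log_abs = math.log10(abs(c.delta)) if c.delta != 0 else float("nan")
        rows.append((c.gene, c.rank_before, c.rank_after, c.delta, log_abs, color))
    df = pd.DataFrame(
        rows, columns=["gene", "rank_before", "rank_after", "delta", "log10_abs_delta", "color"]
    )
    df.to_csv(path, sep="\t", index=False)
    return df
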