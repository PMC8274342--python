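"""Friedman omnibus test, Nemenyi post-hoc critical difference, and
CD-diagram grouping of conditions."""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats

__all__ = ["RankingResult", "friedman_rank", "cd_diagram_data", "nemenyi_cd"]


@dataclass
class RankingResult:
    conditions: list[str]
    n_blocks: int
    mean_ranks: dict[str, float]
    statistic: float
    p_value: float
    critical_difference: float
    groups: list[frozenset[str]]
    direction: str = "higher"

    def top_group(self) -> frozenset[str]:
        """The not-significantly-different group containing the best-ranked
        condition (highest mean rank)."""
        best = max(self.mean_ranks, key=self.mean_ranks.get)
        for g in self.groups:
            if best in g:
                return g
        return frozenset([best])


@lru_cache(maxsize=None)
def _q_alpha(k: int, alpha: float = 0.05) -> float:
    """Nemenyi constant: upper-alpha Studentized range quantile at infinite
    degrees of freedom, divided by sqrt(2)."""
    if k < 2:
        raise ValueError("need k >= 2 conditions")
    return float(stats.studentized_range.ppf(1 - alpha, k, 1e7) / np.sqrt(2.0))


def nemenyi_cd(k: int, n_blocks: int, alpha: float = 0.05) -> float:
    """Critical difference of mean ranks: q_alpha * sqrt(k(k+1)/(6N))."""
    return _q_alpha(k, alpha) * np.sqrt(k * (k + 1) / (6.0 * n_blocks))


def _rank_blocks(scores: np.ndarray, direction: str) -> np.ndarray:
    # higher-is-better: the best condition in a block gets rank k
    signed = scores if direction == "higher" else -scores
    return np.apply_along_axis(stats.rankdata, 1, signed)


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from a (N, k) rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    numer = (k - 1) * np.sum((col_sums - n * (k + 1) / 2.0) ** 2)
    denom = np.sum(ranks * ranks) - n * k * (k + 1) ** 2 / 4.0
    if denom == 0:
        return 0.0
    return float(numer / denom)


def _exact_p(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p by enumerating within-block rank orderings."""
    n, k = ranks.shape
    perms = list(permutations(range(k)))
    count = 0
    total = len(perms) ** n

    def recurse(block: int, current: np.ndarray) -> int:
        if block == n:
            return int(_friedman_statistic(current) >= observed - 1e-12)
        c = 0
        for p in perms:
            current[block] = ranks[block, list(p)]
            c += recurse(block + 1, current)
        return c

    count = recurse(0, ranks.copy())
    return count / total


def friedman_rank(
    scores: np.ndarray,
    condition_names: list[str] | None = None,
    direction: str = "higher",
    alpha: float = 0.05,
    method: str = "chisq",
) -> RankingResult:
    """Rank conditions across blocks and test for differences.

    ``scores`` is (n_blocks, k). With ``direction='higher'`` larger scores
    get larger ranks (the best condition has mean rank near k). Groups are
    chains of conditions whose mean-rank span is at most the Nemenyi CD.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be 2-D (blocks x conditions)")
    n, k = scores.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if n < 2:
        raise ValueError("need at least 2 blocks")
    if np.isnan(scores).any():
        keep = ~np.isnan(scores).any(axis=1)
        scores = scores[keep]
        n = scores.shape[0]
        if n < 2:
            raise ValueError("fewer than 2 complete blocks after deletion")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    if condition_names is None:
        condition_names = [f"c{i}" for i in range(k)]
    if len(condition_names) != k:
        raise ValueError("condition_names length mismatch")

    ranks = _rank_blocks(scores, direction)
    mean_ranks = ranks.mean(axis=0)
    statistic = _friedman_statistic(ranks)
    if statistic == 0.0:
        p = 1.0
    elif method == "exact":
        p = _exact_p(ranks, statistic)
    else:
        p = float(stats.chi2.sf(statistic, k - 1))

    cd = nemenyi_cd(k, n, alpha)
    order = np.argsort(-mean_ranks)
    groups: list[frozenset[str]] = []
    for i in range(k):
        members = [condition_names[order[j]] for j in range(i, k)
                   if mean_ranks[order[i]] - mean_ranks[order[j]] <= cd]
        g = frozenset(members)
        if not any(g <= existing for existing in groups):
            groups.append(g)

    return RankingResult(
        conditions=list(condition_names),
        n_blocks=n,
        mean_ranks={c: float(m) for c, m in zip(condition_names, mean_ranks)},
        statistic=statistic,
        p_value=p,
        critical_difference=float(cd),
        groups=groups,
        direction=direction,
    )


def cd_diagram_data(result: RankingResult) -> dict:
    """Plot-ready layout: conditions ordered by mean rank (best first) with
    group bars as (lo_rank, hi_rank) spans."""
    ordered = sorted(result.conditions, key=lambda c: -result.mean_ranks[c])
    bars = []
    for g in result.groups:
        rs = [result.mean_ranks[c] for c in g]
        bars.append({"members": sorted(g), "lo": min(rs), "hi": max(rs)})
    for b in bars:
        if b["hi"] - b["lo"] > result.critical_difference + 1e-9:
            raise AssertionError("group bar wider than the critical difference")
    return {
        "conditions": ordered,
        "mean_ranks": [result.mean_ranks[c] for c in ordered],
        "critical_difference": result.critical_difference,
        "bars": bars,
    }


def render_cd_diagram(result: RankingResult, path: str) -> None:
    """Minimal SVG rendering of the CD diagram (optional output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = cd_diagram_data(result)
    k = len(data["conditions"])
    fig, ax = plt.subplots(figsize=(8, 0.5 * k + 2))
    ys = np.arange(k)
    ax.scatter(data["mean_ranks"], ys, zorder=3)
    for y, (c, r) in enumerate(zip(data["conditions"], data["mean_ranks"])):
        ax.annotate(f"{c} ({r:.2f})", (r, y), textcoords="offset points",
                    xytext=(6, 4), fontsize=8)
    for i, b in enumerate(data["bars"]):
        ax.plot([b["lo"], b["hi"]], [k + 0.3 + 0.3 * i] * 2, lw=3)
    ax.set_xlabel("mean rank (higher is better)")
    ax.set_yticks([])
    ax.set_title(f"CD = {result.critical_difference:.3f}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
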