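"""Vertex-wise within-/inter-subject correlations, the t-to-r conversion,
and optimal early-window selection by cortical surface area."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .preproc import FrameWindow

__all__ = [
    "InterSubjectStat",
    "WindowSelection",
    "within_subject_corr",
    "t_to_r",
    "inter_subject_corr",
    "area_fraction_of_extremum",
    "select_optimal_window",
]


def within_subject_corr(
    map_a: np.ndarray, map_b: np.ndarray, include: np.ndarray | None = None
) -> float:
    """Pearson correlation of two surface maps over the included vertices.

    Returns NaN (with a warning) when either map has zero variance.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if include is not None:
        a, b = a[include], b[include]
    if a.size < 3:
        raise ValueError("need at least 3 included vertices")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        warnings.warn("zero variance; correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.clip((a * b).sum() / denom, -1.0, 1.0))


def t_to_r(t: np.ndarray | float, n_obs: int, rank_m: int) -> np.ndarray | float:
    """Correlation coefficient from a Student t statistic:

        r = sign(t) * sqrt(t^2 / (N - rank(M) + t^2))
    """
    if n_obs <= rank_m:
        raise ValueError("need N > rank(M)")
    t = np.asarray(t, dtype=float)
    r = np.sign(t) * np.sqrt(t * t / (n_obs - rank_m + t * t))
    return float(r) if r.ndim == 0 else r


@dataclass
class InterSubjectStat:
    """Per-vertex regression of modality B on modality A across subjects."""

    t: np.ndarray
    r: np.ndarray
    n_obs: int
    rank_m: int
    p: np.ndarray | None = None         # permutation p, two-sided
    valid: np.ndarray | None = None     # False where a regressor was constant


def inter_subject_corr(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    n_permutations: int = 0,
    rng: np.random.Generator | int | None = None,
) -> InterSubjectStat:
    """Vertex-wise across-subject correlation of two modalities.

    ``maps_a``/``maps_b`` are (n_subjects, n_vertices) with matched rows.
    t comes from regressing B on A with an intercept; r via :func:`t_to_r`.
    Optional permutation p-values shuffle the subject pairing (two-sided).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("modality arrays must have matching shape")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")

    def t_stats(a_c: np.ndarray, b_c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        saa = (a_c * a_c).sum(axis=0)
        sbb = (b_c * b_c).sum(axis=0)
        sab = (a_c * b_c).sum(axis=0)
        ok = (saa > 0) & (sbb > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sab / saa
            rss = sbb - slope * sab
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / (n - 2) / saa)
            t = np.where(se > 0, slope / se,
                         np.sign(slope) * np.inf * (np.abs(slope) > 0))
        t = np.where(ok, t, np.nan)
        return t, ok

    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    t_obs, valid = t_stats(a_c, b_c)
    r = np.full_like(t_obs, np.nan)
    finite = np.isfinite(t_obs)
    r[finite] = t_to_r(t_obs[finite], n, 2)
    r[np.isposinf(t_obs)] = 1.0
    r[np.isneginf(t_obs)] = -1.0

    p = None
    if n_permutations > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        abs_obs = np.abs(t_obs)
        exceed = np.zeros(a.shape[1])
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            t_perm, _ = t_stats(a_c[perm], b_c)
            exceed += np.abs(t_perm) >= abs_obs
        p = (1.0 + exceed) / (n_permutations + 1.0)
        p = np.where(valid, p, np.nan)

    return InterSubjectStat(t=t_obs, r=r, n_obs=n, rank_m=2, p=p, valid=valid)


def area_fraction_of_extremum(
    r_per_window: dict[FrameWindow, np.ndarray],
    areas: np.ndarray,
    include: np.ndarray,
    mode: str = "max",
) -> dict[FrameWindow, float]:
    """Fraction of included cortical area where each window attains the
    per-vertex extremum of r; exact per-vertex ties split the vertex's area
    equally among the tied windows."""
    windows = sorted(r_per_window)
    stack = np.stack([r_per_window[w] for w in windows])  # (W, V)
    stack = stack[:, include]
    a = areas[include]
    good = np.all(np.isfinite(stack), axis=0)
    stack, a = stack[:, good], a[good]
    ext = stack.max(axis=0) if mode == "max" else stack.min(axis=0)
    is_ext = stack == ext[None, :]
    n_tied = is_ext.sum(axis=0)
    share = a / n_tied
    total = a.sum()
    return {w: float((share * is_ext[k]).sum() / total) for k, w in enumerate(windows)}


@dataclass
class WindowSelection:
    candidates: list[FrameWindow]
    fdg_area_fraction: dict[FrameWindow, float]
    lav_area_fraction: dict[FrameWindow, float]
    selected: FrameWindow
    tied: bool = False


def select_optimal_window(
    fdg_r: dict[FrameWindow, np.ndarray],
    lav_r: dict[FrameWindow, np.ndarray],
    areas: np.ndarray,
    include: np.ndarray,
    lav_tolerance: float = 0.70,
) -> WindowSelection:
    """Pick the window that maximizes the cortical area of highest
    eAV45~FDG inter-subject r, restricted to windows whose area of lowest
    eAV45~lAV45 r is within tolerance of the best such area.

    ``lav_tolerance`` is relative: a window stays eligible while its
    minimum-correlation area is at least ``(1 - lav_tolerance)`` times the
    best window's. The second criterion thereby acts as a veto on
    binding-contaminated windows (whose share collapses toward zero) rather
    than as a noisy tie-break among clean ones."""
    candidates = sorted(fdg_r)
    if len(candidates) < 2:
        if not candidates:
            raise ValueError("no candidate windows")
        only = candidates[0]
        return WindowSelection([only], {only: 1.0}, {only: 1.0}, only)
    if sorted(lav_r) != candidates:
        raise ValueError("candidate sets differ between criteria")

    fdg_frac = area_fraction_of_extremum(fdg_r, areas, include, mode="max")
    lav_frac = area_fraction_of_extremum(lav_r, areas, include, mode="min")

    best_lav = max(lav_frac.values())
    eligible = [w for w in candidates if lav_frac[w] >= best_lav * (1.0 - lav_tolerance)]
    best_fdg = max(fdg_frac[w] for w in eligible)
    winners = [w for w in eligible if fdg_frac[w] == best_fdg]
    tied = len(winners) > 1
    if tied:
        warnings.warn("tie among candidate windows; selecting lexicographically "
                      "earliest", stacklevel=2)
    return WindowSelection(candidates, fdg_frac, lav_frac, min(winners), tied)
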