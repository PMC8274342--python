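"""Permutation GLM with Freedman-Lane nuisance handling, surface TFCE,
max-statistic FWE correction, and balanced-accuracy pattern overlap swept
over FWE thresholds."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .mesh import Mesh
from .ranking import RankingResult, friedman_rank

__all__ = [
    "TfceParams",
    "OverlapResult",
    "GlmResult",
    "tfce_transform",
    "permutation_glm_tfce",
    "pattern_overlap",
    "threshold_sweep",
    "sweep_and_rank",
]


@dataclass
class TfceParams:
    height_exponent: float = 2.0
    extent_exponent: float = 1.0
    n_steps: int = 100              # dh = max-stat / n_steps

    def __post_init__(self) -> None:
        if self.height_exponent < 0 or self.extent_exponent < 0:
            raise ValueError("TFCE exponents must be >= 0")
        if self.n_steps < 1:
            raise ValueError("need at least one integration step")


def tfce_transform(
    stat: np.ndarray,
    mesh: Mesh,
    params: TfceParams | None = None,
    include: np.ndarray | None = None,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a vertex statistic map.

    TFCE(v) = sum over heights h of [area of the supra-threshold component
    containing v at h]^E * h^H * dh, components taken on the mesh edge
    graph. Only the positive tail is enhanced (one-sided contrasts).
    Non-finite statistics are treated as zero.
    """
    if params is None:
        params = TfceParams()
    if include is None:
        include = mesh.included
    s = np.asarray(stat, dtype=float).copy()
    s[~np.isfinite(s)] = 0.0
    s[~include] = 0.0
    out = np.zeros_like(s)
    smax = s.max()
    if smax <= 0:
        return out
    if dh is None:
        dh = smax / params.n_steps
    areas = mesh.vertex_areas
    adj = mesh.adjacency
    heights = np.arange(dh, smax + dh / 2, dh)
    e, h_exp = params.extent_exponent, params.height_exponent
    for h in heights:
        mask = s >= h
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            break
        sub = adj[np.ix_(idx, idx)]
        n_comp, labels = connected_components(sub, directed=False)
        comp_area = np.bincount(labels, weights=areas[idx], minlength=n_comp)
        out[idx] += (comp_area[labels] ** e) * (h ** h_exp) * dh
    return out


@dataclass
class GlmResult:
    t: np.ndarray
    tfce: np.ndarray
    p_fwe: np.ndarray
    max_null: np.ndarray
    valid: np.ndarray


def _check_design(design: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = []
        for c in range(design.shape[1]):
            others = np.delete(design, c, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[c])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _glm_t(y: np.ndarray, design: np.ndarray, col: int) -> np.ndarray:
    """t statistics for one design column, vectorized over map columns."""
    n, p = design.shape
    pinv = np.linalg.pinv(design)
    beta = pinv @ y
    resid = y - design @ beta
    dof = n - p
    sigma2 = (resid * resid).sum(axis=0) / dof
    xtx_inv_cc = np.linalg.inv(design.T @ design)[col, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[col] / np.sqrt(sigma2 * xtx_inv_cc)
    return t


def permutation_glm_tfce(
    response: np.ndarray,
    predictor: np.ndarray,
    nuisance: np.ndarray | None,
    mesh: Mesh,
    n_permutations: int = 1000,
    tfce: TfceParams | None = None,
    rng: np.random.Generator | int | None = None,
    include: np.ndarray | None = None,
) -> GlmResult:
    """One-sided permutation inference with TFCE and max-statistic FWE.

    Fits response = b0 + predictor + nuisance per vertex and enhances the
    predictor's positive t map with TFCE. Null distribution by
    Freedman-Lane: residuals of the nuisance-only model are permuted,
    re-added to the nuisance fit, and the full model is re-estimated.
    FWE p(v) = (1 + #{perm max TFCE >= TFCE(v)}) / (P + 1).
    """
    if tfce is None:
        tfce = TfceParams()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if include is None:
        include = mesh.included
    y = np.asarray(response, dtype=float)
    x = np.asarray(predictor, dtype=float).reshape(-1, 1)
    n = y.shape[0]
    ones = np.ones((n, 1))
    if nuisance is not None and np.asarray(nuisance).size:
        z = np.asarray(nuisance, dtype=float).reshape(n, -1)
    else:
        z = np.zeros((n, 0))
    design = np.hstack([ones, z, x])
    names = ["intercept"] + [f"nuisance_{i}" for i in range(z.shape[1])] + ["predictor"]
    if n <= design.shape[1]:
        raise ValueError("more design columns than subjects")
    _check_design(design, names)
    col = design.shape[1] - 1

    # flag vertices with constant response (t undefined there)
    valid = y.std(axis=0) > 0
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} constant-response vertices flagged "
                      "missing", stacklevel=2)

    t_obs = _glm_t(y, design, col)
    t_obs[~valid] = np.nan
    # dh rule (own max / n_steps) is applied uniformly to the observed and
    # every permuted map, preserving exchangeability
    tfce_obs = tfce_transform(t_obs, mesh, tfce, include)

    reduced = np.hstack([ones, z])
    pinv_red = np.linalg.pinv(reduced)
    fitted_red = reduced @ (pinv_red @ y)
    resid_red = y - fitted_red

    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        y_star = fitted_red + resid_red[perm]
        t_perm = _glm_t(y_star, design, col)
        tfce_perm = tfce_transform(t_perm, mesh, tfce, include)
        max_null[b] = tfce_perm.max()

    p = np.ones(y.shape[1])
    inc = include & valid
    counts = (max_null[None, :] >= tfce_obs[inc, None]).sum(axis=1)
    p[inc] = (1.0 + counts) / (n_permutations + 1.0)
    p[~inc] = np.nan
    return GlmResult(t=t_obs, tfce=tfce_obs, p_fwe=p, max_null=max_null, valid=valid)


@dataclass
class OverlapResult:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)

    @property
    def valid(self) -> bool:
        return (self.tp + self.fn) > 0 and (self.tn + self.fp) > 0


def pattern_overlap(
    p_true: np.ndarray,
    p_pred: np.ndarray,
    threshold: float,
    include: np.ndarray | None = None,
) -> OverlapResult:
    """Confusion of the binarized (p < threshold) predicted pattern against
    the true pattern over included vertices."""
    p_true = np.asarray(p_true, dtype=float)
    p_pred = np.asarray(p_pred, dtype=float)
    if p_true.shape != p_pred.shape:
        raise ValueError("pattern maps must share one vertex set")
    mask = np.isfinite(p_true) & np.isfinite(p_pred)
    if include is not None:
        mask &= include
    t = p_true[mask] < threshold
    p = p_pred[mask] < threshold
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    res = OverlapResult(threshold, tp, fp, tn, fn)
    if not res.valid:
        warnings.warn(f"degenerate pattern at threshold {threshold:g}; "
                      "BACC undefined", stacklevel=2)
    return res


def threshold_sweep(n: int = 91, top: float = 0.05, bottom: float = 0.001) -> np.ndarray:
    """The FWE threshold grid: evenly spaced p-values from 0.05 down to
    0.001 inclusive."""
    return np.linspace(top, bottom, n)


def sweep_and_rank(
    p_maps: dict[str, tuple[np.ndarray, np.ndarray]],
    thresholds: np.ndarray | None = None,
    include: np.ndarray | None = None,
    alpha: float = 0.05,
) -> tuple[np.ndarray, RankingResult]:
    """Rank reference regions by pattern-overlap BACC across thresholds.

    ``p_maps`` maps region name -> (true FWE p-map from FDG, predicted FWE
    p-map from eAV45). Returns the (thresholds x regions) BACC table and
    the Friedman/Nemenyi ranking with thresholds as blocks (higher BACC
    better). Thresholds where any region's true pattern is degenerate are
    dropped listwise with a warning.
    """
    if len(p_maps) < 2:
        raise ValueError("need at least 2 reference regions")
    if thresholds is None:
        thresholds = threshold_sweep()
    regions = list(p_maps)
    table = np.full((len(thresholds), len(regions)), np.nan)
    for j, region in enumerate(regions):
        p_true, p_pred = p_maps[region]
        for i, thr in enumerate(thresholds):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = pattern_overlap(p_true, p_pred, thr, include)
            if res.valid:
                table[i, j] = res.balanced_accuracy
    bad = np.isnan(table).any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} thresholds with degenerate "
                      "patterns", stacklevel=2)
    ranking = friedman_rank(table[~bad], regions, direction="higher", alpha=alpha)
    return table, ranking
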