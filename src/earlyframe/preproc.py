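"""Early-window averaging, reference-region intensity scaling and
amyloid-status calling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from .mesh import Mesh, erode_patch
from .synthetic import DynamicSeries, N_FRAMES

__all__ = [
    "FrameWindow",
    "ReferenceRegionSpec",
    "AmyloidCutoff",
    "REFERENCE_REGIONS",
    "enumerate_windows",
    "window_mean",
    "scale_surface_map",
    "scale_volume",
    "call_amyloid_status",
    "neocortical_mask",
]

GLOBAL_REFERENCE_VALUE = 6.5  # mg/100 mL/min, proportional-scaling target


@dataclass(frozen=True, order=True)
class FrameWindow:
    """Half-open early window [t1, t2) minutes; averages frames t1..t2-1."""

    t1: int
    t2: int

    def __post_init__(self) -> None:
        if not 0 <= self.t1 < self.t2 <= N_FRAMES:
            raise ValueError(f"invalid window [{self.t1}, {self.t2}]")

    @property
    def label(self) -> str:
        return f"{self.t1}-{self.t2}"


@dataclass
class ReferenceRegionSpec:
    """How to build one scaling reference: a named mask, optionally eroded
    and tissue-masked, or the whole-brain 'global' proportional scaling."""

    name: str
    patch_names: tuple[str, ...] = ()
    tissue: str = "GM+WM"          # GM, WM or GM+WM (volume path only)
    tissue_threshold: float = 0.5
    erosion_mm: float = 4.0
    global_reference_value: float = GLOBAL_REFERENCE_VALUE

    def __post_init__(self) -> None:
        if not 0.0 < self.tissue_threshold < 1.0:
            raise ValueError("tissue threshold must be in (0, 1)")
        if self.erosion_mm < 0:
            raise ValueError("erosion radius must be >= 0")
        if self.name != "global" and not self.patch_names:
            raise ValueError("non-global reference needs at least one patch")


# the seven scaling schemes compared throughout the pipeline
REFERENCE_REGIONS: dict[str, ReferenceRegionSpec] = {
    "cerebellum": ReferenceRegionSpec("cerebellum", ("cerebellum",), "GM+WM"),
    "cerebellar_GM": ReferenceRegionSpec("cerebellar_GM", ("cerebellar_GM",), "GM"),
    "global": ReferenceRegionSpec("global"),
    "pons": ReferenceRegionSpec("pons", ("pons",), "GM+WM"),
    "pons+cerebellum": ReferenceRegionSpec(
        "pons+cerebellum", ("pons", "cerebellum"), "GM+WM"),
    "pons+cerebellar_GM": ReferenceRegionSpec(
        "pons+cerebellar_GM", ("pons", "cerebellar_GM"), "GM"),
    "cerebral_WM": ReferenceRegionSpec("cerebral_WM", ("cerebral_WM",), "WM"),
}


@dataclass
class AmyloidCutoff:
    """Neocortical-mean SUVR threshold for amyloid positivity."""

    threshold: float = 1.22
    exclude_patches: tuple[str, ...] = ("medial_wall", "pons", "cerebellum",
                                        "cerebellar_GM", "cerebral_WM")

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("cutoff must be positive")


def enumerate_windows(
    t1_values: tuple[int, ...] = (0, 1, 2, 3),
    t2_max: int = N_FRAMES,
) -> list[FrameWindow]:
    """All (t1, t2) windows with t2 in {1..t2_max}, t2 > t1, lexicographic."""
    return [
        FrameWindow(t1, t2)
        for t1 in sorted(t1_values)
        for t2 in range(1, t2_max + 1)
        if t2 > t1
    ]


def window_mean(series: DynamicSeries, window: FrameWindow) -> np.ndarray:
    """Arithmetic mean of frames t1..t2-1; the acquisition grid is unchanged."""
    if window.t2 > series.frames.shape[0]:
        raise ValueError("window extends past the acquired frames")
    return series.frames[window.t1: window.t2].mean(axis=0)


def _reference_mask_surface(mesh: Mesh, spec: ReferenceRegionSpec) -> np.ndarray:
    mask = np.zeros(mesh.n_vertices, dtype=bool)
    for patch in spec.patch_names:
        mask |= mesh.patch_mask(patch)
    eroded = erode_patch(mesh, mask, spec.erosion_mm)
    if not eroded.any():
        raise ValueError(
            f"reference region {spec.name!r} vanished after {spec.erosion_mm} mm erosion")
    return eroded


def scale_surface_map(
    values: np.ndarray, mesh: Mesh, spec: ReferenceRegionSpec
) -> tuple[np.ndarray, float]:
    """Intensity-normalize a surface map.

    Region scaling divides by the area-weighted mean over the eroded
    reference patch; 'global' applies proportional scaling so the
    brain-wide (included-vertex) mean equals the physiological reference
    value. Returns the scaled map and the reference mean.
    """
    values = np.asarray(values, dtype=float)
    areas = mesh.vertex_areas
    if spec.name == "global":
        mask = mesh.included
        ref_mean = float(np.average(values[mask], weights=areas[mask]))
        if ref_mean <= 0:
            raise ValueError("non-positive global mean")
        return values * (spec.global_reference_value / ref_mean), ref_mean
    mask = _reference_mask_surface(mesh, spec)
    ref_mean = float(np.average(values[mask], weights=areas[mask]))
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean in {spec.name!r}")
    return values / ref_mean, ref_mean


def _ball(radius_mm: float, voxel_mm: float) -> np.ndarray:
    r_vox = int(np.floor(radius_mm / voxel_mm))
    if r_vox < 1:
        return np.ones((1, 1, 1), dtype=bool)
    g = np.arange(-r_vox, r_vox + 1) * voxel_mm
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    return x * x + y * y + z * z <= radius_mm * radius_mm


def scale_volume(
    volume: np.ndarray,
    spec: ReferenceRegionSpec,
    region_mask: np.ndarray | None,
    tissue_probs: dict[str, np.ndarray],
    voxel_mm: float,
    brain_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Volume counterpart of :func:`scale_surface_map`.

    The reference mask is eroded by a discrete ball of the spec's radius
    then intersected with the thresholded tissue probability map of the
    spec's tissue class.
    """
    volume = np.asarray(volume, dtype=float)
    if spec.name == "global":
        if brain_mask is None:
            brain_mask = (tissue_probs["gm"] + tissue_probs["wm"]) > spec.tissue_threshold
        ref_mean = float(volume[brain_mask].mean())
        if ref_mean <= 0:
            raise ValueError("non-positive global mean")
        return volume * (spec.global_reference_value / ref_mean), ref_mean

    if region_mask is None:
        raise ValueError("region scaling requires a mask")
    mask = np.asarray(region_mask, dtype=bool)
    if spec.erosion_mm > 0:
        mask = binary_erosion(mask, structure=_ball(spec.erosion_mm, voxel_mm))
    if spec.tissue == "GM":
        tissue = tissue_probs["gm"]
    elif spec.tissue == "WM":
        tissue = tissue_probs["wm"]
    else:
        tissue = tissue_probs["gm"] + tissue_probs["wm"]
    mask &= tissue > spec.tissue_threshold
    if not mask.any():
        raise ValueError(
            f"reference region {spec.name!r} vanished after erosion/tissue masking")
    ref_mean = float(volume[mask].mean())
    if ref_mean <= 0:
        raise ValueError(f"non-positive reference mean in {spec.name!r}")
    return volume / ref_mean, ref_mean


def neocortical_mask(mesh: Mesh, cutoff: AmyloidCutoff) -> np.ndarray:
    """Included cortex minus the cutoff's excluded patches."""
    mask = mesh.included.copy()
    for name in cutoff.exclude_patches:
        if name in mesh.patches:
            mask &= ~mesh.patches[name]
    return mask


def call_amyloid_status(
    late_scaled: np.ndarray, mesh: Mesh, cutoff: AmyloidCutoff | None = None
) -> str:
    """'high' iff the area-weighted neocortical mean SUVR strictly exceeds
    the cutoff (the map must already be cerebellar-GM scaled)."""
    if cutoff is None:
        cutoff = AmyloidCutoff()
    mask = neocortical_mask(mesh, cutoff)
    if not mask.any():
        raise ValueError("empty neocortical mask")
    areas = mesh.vertex_areas
    mean = float(np.average(np.asarray(late_scaled, float)[mask], weights=areas[mask]))
    return "high" if mean > cutoff.threshold else "low"
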