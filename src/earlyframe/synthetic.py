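"""Synthetic dynamic-PET cohorts and volumetric phantoms with known truth.

The cohort generator produces, per subject, ten 1-minute early frames whose
signal is a perfusion-weighted delivery curve plus a late-onset
amyloid-binding term, a late-phase amyloid map, a metabolism (FDG-like)
map coupled to perfusion, and cognition scores driven by the
neurodegeneration burden in a vulnerable patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .mesh import Mesh, icosphere, build_cohort_mesh

__all__ = [
    "CohortConfig",
    "SubjectTable",
    "DynamicSeries",
    "Cohort",
    "VolumePhantom",
    "generate_cohort",
    "generate_phantom",
]

GROUPS = ("yHC", "eHC", "aMCI", "AD-d")

N_FRAMES = 10

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort, with desk-scale defaults."""

    n_yhc: int = 4
    n_ehc: int = 16
    n_amci: int = 10
    n_add: int = 10
    # delivery curve: gamma-variate peaking before the binding onset; the
    # small shape parameter (decay_rate * time_to_peak) gives the fast
    # initial influx expected of a flow tracer
    time_to_peak_min: float = 2.5
    decay_rate_per_min: float = 0.2
    # amyloid binding: zero until onset, then linear in time (the rate is a
    # free parameter; no kinetic model is implied)
    binding_onset_min: float = 4.0
    binding_slope_per_min: float = 0.3
    # perfusion-metabolism coupling (correlation of latent fields)
    coupling_r: float = 0.85
    # effect sizes: fractional signal loss in the vulnerable patch;
    # hypoperfusion is the weaker, noisier echo of hypometabolism
    hypoperfusion_effect: dict[str, float] = field(
        default_factory=lambda: {"yHC": 0.0, "eHC": 0.0, "aMCI": 0.09, "AD-d": 0.18}
    )
    hypometabolism_effect: dict[str, float] = field(
        default_factory=lambda: {"yHC": 0.0, "eHC": 0.0, "aMCI": 0.11, "AD-d": 0.30}
    )
    # amyloid load (specific binding relative to nonspecific background)
    amyloid_high_load: float = 0.6
    amyloid_low_load: float = 0.12
    amyloid_positivity_rate: dict[str, float] = field(
        default_factory=lambda: {"yHC": 0.125, "eHC": 0.51, "aMCI": 0.867, "AD-d": 0.933}
    )
    # diffuse (whole-cortex) deficit applied to patients when the global
    # mean is declared disease-affected
    diffuse_deficit: float = 0.05
    disease_affected_refs: tuple[str, ...] = ("global", "cerebellum", "cerebral_WM")
    # fractional patient signal loss inside disease-affected reference patches
    ref_deficit: float = 0.10
    between_subject_sd: float = 0.12
    # geodesic FWHM of the latent between-subject fields; 0 = iid vertices
    spatial_noise_fwhm_mm: float = 15.0
    # per-frame measurement noise; high per-frame counts noise is what makes
    # longer early windows pay off
    noise_sd: float = 6.0
    # static acquisitions integrate far longer than 1-minute frames
    fdg_noise_sd: float = 1.5
    late_noise_sd: float = 0.05
    cognition_noise_sd: float = 1.0
    base_perfusion: float = 50.0
    base_metabolism: float = 30.0
    seed: int = 0

    def group_sizes(self) -> dict[str, int]:
        return {"yHC": self.n_yhc, "eHC": self.n_ehc,
                "aMCI": self.n_amci, "AD-d": self.n_add}

    def validate(self) -> None:
        sizes = self.group_sizes()
        if any(n < 0 for n in sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if sum(sizes.values()) == 0:
            raise ValueError("cohort has zero subjects")
        if not -1.0 <= self.coupling_r <= 1.0:
            raise ValueError("coupling_r must lie in [-1, 1]")
        if self.noise_sd < 0 or self.cognition_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.time_to_peak_min <= 0:
            raise ValueError("time_to_peak_min must be positive")


@dataclass
class SubjectTable:
    """Per-subject phenotype table plus ground-truth maps (synthetic only)."""

    data: pd.DataFrame
    truth: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data["id"].duplicated().any():
            raise ValueError("subject ids must be unique")
        mmse = self.data["mmse"]
        if ((mmse < 0) | (mmse > 30)).any():
            raise ValueError("MMSE out of [0, 30]")
        tr = self.data["total_recall"]
        if ((tr < 0) | (tr > 16)).any():
            raise ValueError("Total Recall out of [0, 16]")

    @property
    def ids(self) -> list[str]:
        return list(self.data["id"])


@dataclass
class DynamicSeries:
    """Ten 1-minute frames for one subject; frame k covers minute [k, k+1)."""

    subject_id: str
    frames: np.ndarray  # (10, n_points)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.shape[0] != N_FRAMES:
            raise ValueError(f"expected {N_FRAMES} frames, got {self.frames.shape[0]}")


@dataclass
class Cohort:
    table: SubjectTable
    dynamic: dict[str, DynamicSeries]
    late: dict[str, np.ndarray]
    fdg: dict[str, np.ndarray]
    mesh: Mesh
    config: CohortConfig

    def stack(self, which: str) -> np.ndarray:
        """(n_subjects, n_vertices) array in table order for 'late'/'fdg'."""
        src = getattr(self, which)
        return np.stack([src[i] for i in self.table.ids])


def delivery_curve(tau: np.ndarray, time_to_peak: float, decay_rate: float) -> np.ndarray:
    """Gamma-variate delivery, normalized to peak 1 at ``time_to_peak``."""
    tau = np.asarray(tau, dtype=float)
    alpha = decay_rate * time_to_peak
    x = np.clip(tau / time_to_peak, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(x > 0, np.power(x, alpha) * np.exp(alpha * (1.0 - x)), 0.0)
    return d


def binding_curve(tau: np.ndarray, onset: float, slope: float) -> np.ndarray:
    """Amyloid-binding contamination: zero before onset, then linear."""
    return slope * np.clip(np.asarray(tau, dtype=float) - onset, 0.0, None)


def _sample_covariates(rng: np.random.Generator, group: str) -> tuple[str, float, float]:
    if group == "yHC":
        age = rng.normal(40.0, 8.0)
    else:
        age = rng.normal(71.0, 6.0)
    sex = "F" if rng.random() < 0.5 else "M"
    education = float(np.clip(rng.normal(12.6, 3.0), 5, 22))
    return sex, float(np.clip(age, 20, 95)), education


def generate_cohort(config: CohortConfig, mesh: Mesh | None = None) -> Cohort:
    """Generate a full synthetic cohort on ``mesh`` (built if omitted).

    Signal model at vertex v and frame midpoint tau:

        frame(v, tau) = perfusion(v) * D(tau) + P0 * amyloid(v) * B(tau) + noise

    with D a gamma-variate delivery curve peaking before the binding onset
    and B zero until onset then linear. Metabolism is a latent field
    correlated with perfusion at ``coupling_r``; patient maps are depressed
    in the vulnerable patch; cognition decreases with the vulnerable-patch
    metabolic deficit.
    """
    config.validate()
    if mesh is None:
        mesh = build_cohort_mesh()
    if "vulnerable" not in mesh.patches:
        raise ValueError("mesh lacks a 'vulnerable' patch")
    rng = np.random.default_rng(config.seed)
    nv = mesh.n_vertices

    if config.spatial_noise_fwhm_mm > 0:
        from .pvc import SmoothingParams, smooth_surface

        _sp = SmoothingParams(fwhm_mm=config.spatial_noise_fwhm_mm)
        _all = np.ones(nv, dtype=bool)

        def latent_field(z: np.ndarray) -> np.ndarray:
            f = smooth_surface(z, mesh, _sp, include=_all)
            sd = f.std()
            return f / sd if sd > 0 else f
    else:
        def latent_field(z: np.ndarray) -> np.ndarray:
            return z
    vuln = mesh.patches["vulnerable"].astype(float)
    included = mesh.included.astype(float)

    # amyloid spatial profile: cortical, sparing reference patches
    amyl_profile = included.copy()
    for ref in ("pons", "cerebellum", "cerebellar_GM", "cerebral_WM"):
        if ref in mesh.patches:
            amyl_profile[mesh.patches[ref]] = 0.1

    tau = np.arange(N_FRAMES) + 0.5
    d_curve = delivery_curve(tau, config.time_to_peak_min, config.decay_rate_per_min)
    b_curve = binding_curve(tau, config.binding_onset_min, config.binding_slope_per_min)

    rows = []
    truth_perf = np.empty((0, nv))
    perf_list, met_list, amyl_list = [], [], []
    dynamic: dict[str, DynamicSeries] = {}
    late: dict[str, np.ndarray] = {}
    fdg: dict[str, np.ndarray] = {}

    p0, m0 = config.base_perfusion, config.base_metabolism
    r = config.coupling_r
    diffuse_on = "global" in config.disease_affected_refs

    sid = 0
    for group in GROUPS:
        for _ in range(config.group_sizes()[group]):
            subject_id = f"sub-{sid:03d}"
            sid += 1
            is_patient = group in ("aMCI", "AD-d")

            z1 = latent_field(rng.standard_normal(nv))
            z2 = latent_field(rng.standard_normal(nv))
            zm = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2

            perf_eff = config.hypoperfusion_effect[group] * (1 + 0.15 * rng.standard_normal())
            met_eff = config.hypometabolism_effect[group] * (1 + 0.15 * rng.standard_normal())
            perf_eff, met_eff = max(0.0, perf_eff), max(0.0, met_eff)
            diffuse = config.diffuse_deficit if (is_patient and diffuse_on) else 0.0

            deficit_perf = perf_eff * vuln + diffuse * included
            deficit_met = diffuse * included + met_eff * vuln
            # reference patches declared disease-affected lose signal too
            for ref in config.disease_affected_refs:
                if ref != "global" and ref in mesh.patches and is_patient:
                    deficit_perf = deficit_perf + config.ref_deficit * mesh.patches[ref]
                    deficit_met = deficit_met + config.ref_deficit * mesh.patches[ref]

            perfusion = p0 * (1.0 + config.between_subject_sd * z1 - deficit_perf)
            metabolism = m0 * (1.0 + config.between_subject_sd * zm - deficit_met)

            amyl_high = rng.random() < config.amyloid_positivity_rate[group]
            load = config.amyloid_high_load if amyl_high else config.amyloid_low_load
            amyloid = load * amyl_profile * (1 + 0.1 * rng.standard_normal())

            frames = (
                perfusion[None, :] * d_curve[:, None]
                + p0 * amyloid[None, :] * b_curve[:, None]
                + config.noise_sd * rng.standard_normal((N_FRAMES, nv))
            )
            late_map = 1.0 + amyloid + config.late_noise_sd * rng.standard_normal(nv)
            fdg_map = metabolism + config.fdg_noise_sd * rng.standard_normal(nv)

            # cognition: decreasing in the vulnerable-patch metabolic deficit
            vuln_idx = vuln > 0
            burden = 1.0 - metabolism[vuln_idx].mean() / m0
            mmse = 29.0 - 36.0 * max(0.0, burden) + config.cognition_noise_sd * rng.standard_normal()
            recall = 15.0 - 40.0 * max(0.0, burden) + config.cognition_noise_sd * rng.standard_normal()
            sex, age, education = _sample_covariates(rng, group)

            rows.append({
                "id": subject_id,
                "group": group,
                "amyloid_status": "high" if amyl_high else "low",
                "sex": sex,
                "age": round(age, 1),
                "education": round(education, 1),
                "mmse": float(np.clip(round(mmse), 0, 30)),
                "total_recall": float(np.clip(round(recall), 0, 16)),
            })
            perf_list.append(perfusion)
            met_list.append(metabolism)
            amyl_list.append(amyloid)
            dynamic[subject_id] = DynamicSeries(subject_id, frames)
            late[subject_id] = late_map
            fdg[subject_id] = fdg_map

    table = SubjectTable(
        pd.DataFrame(rows),
        truth={
            "perfusion": np.stack(perf_list),
            "metabolism": np.stack(met_list),
            "amyloid": np.stack(amyl_list),
        },
    )
    return Cohort(table, dynamic, late, fdg, mesh, config)


@dataclass
class VolumePhantom:
    """Concentric-shell phantom: WM core, GM shell, CSF rim, background 0."""

    activity: np.ndarray          # observed (PSF-blurred) grid
    truth: np.ndarray             # piecewise-constant true activity
    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray
    voxel_mm: float
    psf_fwhm_mm: float
    compartment_activities: dict[str, float]
    mesh: Mesh                    # embedded mid-GM surface, physical coords

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be positive")
        total = self.gm + self.wm + self.csf
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("tissue probabilities exceed 1")


def generate_phantom(
    shape: tuple[int, int, int] = (48, 48, 48),
    voxel_mm: float = 2.0,
    psf_fwhm_mm: float = 6.0,
    compartment_activities: dict[str, float] | None = None,
    wm_radius_mm: float = 16.0,
    gm_thickness_mm: float = 6.0,
    csf_thickness_mm: float = 4.0,
) -> VolumePhantom:
    """Spherical-shell phantom blurred by an isotropic Gaussian PSF."""
    if compartment_activities is None:
        compartment_activities = {"gm": 4.0, "wm": 1.0, "csf": 0.0}
    if any(v < 0 for v in compartment_activities.values()):
        raise ValueError("compartment activities must be >= 0")
    if psf_fwhm_mm < 0:
        raise ValueError("psf_fwhm_mm must be >= 0")

    r_gm_outer = wm_radius_mm + gm_thickness_mm
    r_csf_outer = r_gm_outer + csf_thickness_mm
    half_extent = min(shape) * voxel_mm / 2.0
    if half_extent < r_csf_outer + 2 * voxel_mm:
        raise ValueError("grid shape too small to contain the shells")

    center = (np.array(shape) - 1) / 2.0 * voxel_mm
    coords = np.stack(
        np.meshgrid(*[np.arange(s) * voxel_mm for s in shape], indexing="ij"), axis=-1
    )
    radius = np.linalg.norm(coords - center, axis=-1)

    wm = (radius <= wm_radius_mm).astype(float)
    gm = ((radius > wm_radius_mm) & (radius <= r_gm_outer)).astype(float)
    csf = ((radius > r_gm_outer) & (radius <= r_csf_outer)).astype(float)

    truth = (
        compartment_activities["gm"] * gm
        + compartment_activities["wm"] * wm
        + compartment_activities["csf"] * csf
    )
    if psf_fwhm_mm > 0:
        sigma_vox = psf_fwhm_mm * _FWHM_TO_SIGMA / voxel_mm
        observed = gaussian_filter(truth, sigma_vox, mode="constant")
    else:
        observed = truth.copy()

    verts, faces = icosphere(3, wm_radius_mm + gm_thickness_mm / 2.0)
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    mesh = Mesh(verts + center, faces, normals,
                np.full(len(verts), gm_thickness_mm), {})

    return VolumePhantom(observed, truth, gm, wm, csf, voxel_mm,
                         psf_fwhm_mm, dict(compartment_activities), mesh)


def config_to_dict(config: CohortConfig) -> dict:
    d = asdict(config)
    d["disease_affected_refs"] = list(d["disease_affected_refs"])
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    if "disease_affected_refs" in d:
        d["disease_affected_refs"] = tuple(d["disease_affected_refs"])
    return CohortConfig(**d)
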