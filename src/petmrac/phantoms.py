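"""Procedural head/neck phantoms and degraded attenuation maps.

A phantom is a stack of axial slices holding an elliptical body with a
subcutaneous fat rim, a posterior bone column (spine-like, with an inner
canal carrying the spinal cord / brain stem), an anterior bone arc
(mandible-like) in the cranial slices, an anterior air channel
(trachea/larynx-like), an oral air pocket, an esophagus between air channel
and bone column, optional lung tissue at the caudal end, and spherical
hot lesions.  Only the topological relations that drive the attenuation
metrics are modeled — bone adjacent to the cord, air inside larynx and
trachea, esophagus sandwiched between air and bone — not anatomical realism.

Two degradation models emulate MRI-derived attenuation maps:

``atlas_like``
    Segmentation-plus-bone-atlas behavior: bone collapses to soft tissue
    except an optionally retained "major bone" subset (e.g. the spine
    column), a random subset of connected air cavities is misclassified as
    soft tissue (the trachea-not-air failure), and an optional fat-water
    swap.

``deep_like``
    CNN-prediction behavior: each bone structure's HU is shifted by one draw
    from Normal(-199, 60^2) — a systematic per-structure underestimation of
    bone density — followed by a mild Gaussian blur restricted to a band
    around bone boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .attenuation import AttenuationMap, hu_to_lac


class Tissue(IntEnum):
    BACKGROUND = 0
    SOFT_TISSUE = 1
    FAT = 2
    BONE = 3
    AIR_CAVITY = 4
    LUNG = 5
    LESION_BASE = 10  # lesion k is coded LESION_BASE + k


DEFAULT_TISSUE_HU = {
    Tissue.BACKGROUND: -1000.0,
    Tissue.SOFT_TISSUE: 40.0,
    Tissue.FAT: -100.0,
    Tissue.BONE: 700.0,
    Tissue.AIR_CAVITY: -1000.0,
    Tissue.LUNG: -700.0,
}


@dataclass(frozen=True)
class LesionSpec:
    """A spherical hot lesion: center in mm relative to the body center
    (x, y) and fractional axial position z in [0, 1]."""

    center_mm: tuple[float, float, float] = (-22.0, 16.0, 0.5)
    diameter_mm: float = 16.0
    suv: float = 5.0


@dataclass(frozen=True)
class AnatomyConfig:
    """Geometric and intensity parameters of the procedural anatomy.

    Distances are mm in the axial plane; the +y direction is posterior.
    ``jitter`` scales the seeded per-subject variation of sizes and
    positions (0 disables it).
    """

    body_semiaxes_mm: tuple[float, float] = (80.0, 62.0)
    fat_rim_mm: float = 6.0
    spine_center_mm: tuple[float, float] = (0.0, 35.0)
    spine_outer_radius_mm: float = 14.0
    spine_canal_radius_mm: float = 6.0
    cord_radius_mm: float = 4.5
    mandible_radius_mm: float = 34.0
    mandible_thickness_mm: float = 6.0
    mandible_center_mm: tuple[float, float] = (0.0, 5.0)
    trachea_center_mm: tuple[float, float] = (0.0, -20.0)
    trachea_radius_mm: float = 7.0
    esophagus_center_mm: tuple[float, float] = (0.0, 10.0)
    esophagus_radius_mm: float = 4.0
    oral_center_mm: tuple[float, float] = (0.0, -14.0)
    oral_radius_mm: float = 7.0
    include_lung: bool = True
    lung_slices: int = 2
    lesions: tuple[LesionSpec, ...] = (LesionSpec(),)
    tissue_hu: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))
    hu_noise_sd: float = 0.0
    body_suv: float = 1.0
    air_suv: float | None = None  # None: air cavities carry the body SUV
    lung_suv: float | None = None
    jitter: float = 1.0


@dataclass(frozen=True)
class Phantom:
    """Aligned label / HU / activity volumes with ROI masks.

    Axis order is (x, y, z) with z axial; ``rois`` maps region names to
    boolean masks and ``structures`` holds the named bone structures used by
    the degradation models.
    """

    labels: np.ndarray
    hu: np.ndarray
    activity: np.ndarray
    spacing: tuple[float, float, float]
    rois: dict[str, np.ndarray]
    structures: dict[str, np.ndarray]
    seed: int

    @property
    def body(self) -> np.ndarray:
        return self.labels != Tissue.BACKGROUND

    @property
    def lung(self) -> np.ndarray:
        return self.labels == Tissue.LUNG

    def validate(self) -> None:
        if not (self.labels.shape == self.hu.shape == self.activity.shape):
            raise ValueError("labels, hu and activity must share one shape")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if self.activity.min() < 0:
            raise ValueError("activity must be nonnegative")
        body = self.body
        for name, mask in self.rois.items():
            if np.any(mask & ~body):
                raise ValueError(f"roi {name!r} extends outside the body")


@dataclass(frozen=True)
class DegradationConfig:
    """Parameters of the attenuation-map degradation models."""

    mode: str = "atlas_like"  # or "deep_like"
    bone_to_soft: bool = True
    retain_structures: tuple[str, ...] = ()
    air_cavity_to_soft_fraction: float = 0.5
    fat_water_swap: bool = False
    bone_hu_bias_mean: float = -199.0
    bone_hu_bias_sd: float = 60.0
    boundary_blur_fwhm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("atlas_like", "deep_like"):
            raise ValueError(f"unknown degradation mode {self.mode!r}")
        if not 0.0 <= self.air_cavity_to_soft_fraction <= 1.0:
            raise ValueError("air_cavity_to_soft_fraction must be in [0, 1]")
        if self.boundary_blur_fwhm < 0:
            raise ValueError("boundary_blur_fwhm must be >= 0")
        if self.bone_hu_bias_sd < 0:
            raise ValueError("bone_hu_bias_sd must be >= 0")


IDENTITY_ATLAS = DegradationConfig(
    mode="atlas_like", bone_to_soft=False, air_cavity_to_soft_fraction=0.0
)
IDENTITY_DEEP = DegradationConfig(
    mode="deep_like", bone_hu_bias_mean=0.0, bone_hu_bias_sd=0.0, boundary_blur_fwhm=0.0
)


def _plane_coords(shape, spacing):
    nx, ny = shape[0], shape[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * spacing[0]
    y = (np.arange(ny) - (ny - 1) / 2.0) * spacing[1]
    return np.meshgrid(x, y, indexing="ij")


def _jittered(cfg: AnatomyConfig, rng: np.random.Generator) -> AnatomyConfig:
    """Seeded per-subject variation of the anatomy (sizes +/-8%, positions
    +/-3 mm, lesion position +/-4 mm; lesion diameters are left exact)."""
    j = cfg.jitter
    if j == 0:
        return cfg

    def scale(v):
        return v * (1.0 + j * rng.uniform(-0.08, 0.08))

    def shift(p, amount=3.0):
        return tuple(v + j * rng.uniform(-amount, amount) for v in p)

    lesions = tuple(
        replace(
            les,
            center_mm=(
                les.center_mm[0] + j * rng.uniform(-4, 4),
                les.center_mm[1] + j * rng.uniform(-4, 4),
                float(np.clip(les.center_mm[2] + j * rng.uniform(-0.08, 0.08), 0.15, 0.85)),
            ),
        )
        for les in cfg.lesions
    )
    return replace(
        cfg,
        body_semiaxes_mm=(scale(cfg.body_semiaxes_mm[0]), scale(cfg.body_semiaxes_mm[1])),
        spine_center_mm=shift(cfg.spine_center_mm),
        spine_outer_radius_mm=scale(cfg.spine_outer_radius_mm),
        trachea_center_mm=shift(cfg.trachea_center_mm, 2.0),
        trachea_radius_mm=scale(cfg.trachea_radius_mm),
        mandible_radius_mm=scale(cfg.mandible_radius_mm),
        lesions=lesions,
    )


def make_phantom(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    anatomy: AnatomyConfig | None = None,
    seed: int = 0,
) -> Phantom:
    """Generate a seeded synthetic head/neck phantom.

    Parameters
    ----------
    shape : (nx, ny, nz)
        Volume size in voxels; at least (32, 32, 8).
    spacing : (dx, dy, dz)
        Voxel spacing in mm.
    anatomy : AnatomyConfig, optional
        Anatomy parameters; defaults emulate a neck cross-section of roughly
        16 x 12 cm with one 16 mm lesion at 5x contrast.
    seed : int
        Drives the per-subject anatomical jitter and optional HU noise.

    Returns
    -------
    Phantom
        With ROIs spinal_cord, brain_stem, larynx, mandible, oral_cavity,
        esophagus, spine and lesion_1..k.
    """
    if any(n < m for n, m in zip(shape, (32, 32, 8))):
        raise ValueError(f"shape {shape} too small; need at least (32, 32, 8)")
    if anatomy is None:
        anatomy = AnatomyConfig()
    rng = np.random.default_rng(seed)
    cfg = _jittered(anatomy, rng)

    nx, ny, nz = shape
    X, Y = _plane_coords(shape, spacing)
    labels = np.zeros(shape, dtype=np.int16)
    rois: dict[str, np.ndarray] = {}
    structures: dict[str, np.ndarray] = {}

    ax, ay = cfg.body_semiaxes_mm
    body2d = (X / ax) ** 2 + (Y / ay) ** 2 <= 1.0
    fat2d = body2d & ~(
        (X / max(ax - cfg.fat_rim_mm, 1.0)) ** 2 + (Y / max(ay - cfg.fat_rim_mm, 1.0)) ** 2
        <= 1.0
    )
    labels = np.where(
        np.broadcast_to(body2d[:, :, None], shape), Tissue.SOFT_TISSUE, Tissue.BACKGROUND
    ).astype(np.int16)
    labels[fat2d[:, :, None] & (labels == Tissue.SOFT_TISSUE)] = Tissue.FAT

    z_idx = np.arange(nz)
    # the air channel ends at least two slices below the cranial block so the
    # trachea and the oral pocket are always separate connected components
    z_tr_end = int(np.floor(nz * 0.6))
    z_top_start = max(z_tr_end + 2, int(np.ceil(nz * 0.7)))
    z_top = z_idx >= z_top_start
    z_lung = z_idx < (cfg.lung_slices if cfg.include_lung else 0)

    def tube(center, radius):
        cx, cy = center
        return (X - cx) ** 2 + (Y - cy) ** 2 <= radius**2

    # posterior bone column with interior canal, full z extent
    spine2d = tube(cfg.spine_center_mm, cfg.spine_outer_radius_mm)
    canal2d = tube(cfg.spine_center_mm, cfg.spine_canal_radius_mm)
    cord2d = tube(cfg.spine_center_mm, cfg.cord_radius_mm)
    spine3d = (spine2d & ~canal2d)[:, :, None] & np.ones(nz, bool)[None, None, :]
    labels[spine3d & (labels > 0)] = Tissue.BONE
    structures["spine"] = spine3d & (labels == Tissue.BONE)

    # anterior bone arc in cranial slices (mandible-like)
    mx, my = cfg.mandible_center_mm
    r = np.hypot(X - mx, Y - my)
    ring = (r >= cfg.mandible_radius_mm - cfg.mandible_thickness_mm) & (
        r <= cfg.mandible_radius_mm
    )
    anterior = (Y - my) < -0.3 * cfg.mandible_radius_mm
    mand3d = (ring & anterior)[:, :, None] & z_top[None, None, :]
    mand3d &= labels > 0
    mand3d &= ~spine3d
    labels[mand3d] = Tissue.BONE
    structures["mandible"] = mand3d.copy()

    # anterior air channel (trachea/larynx) from the caudal end upward
    z_trachea = z_idx <= z_tr_end
    trach3d = tube(cfg.trachea_center_mm, cfg.trachea_radius_mm)[:, :, None] & z_trachea[
        None, None, :
    ]
    trach3d &= labels > 0
    trach3d &= labels != Tissue.BONE
    labels[trach3d] = Tissue.AIR_CAVITY

    # oral air pocket in cranial slices
    oral3d = tube(cfg.oral_center_mm, cfg.oral_radius_mm)[:, :, None] & z_top[None, None, :]
    oral3d &= (labels > 0) & (labels != Tissue.BONE)
    labels[oral3d] = Tissue.AIR_CAVITY

    # esophagus: soft-tissue tube between the air channel and the bone column
    eso3d = tube(cfg.esophagus_center_mm, cfg.esophagus_radius_mm)[:, :, None] & z_trachea[
        None, None, :
    ]
    eso3d &= labels == Tissue.SOFT_TISSUE

    # caudal lung
    if cfg.include_lung:
        lung2d = body2d & (np.abs(X) > 0.25 * ax) & (Y > -0.5 * ay) & (Y < 0.6 * ay)
        lung3d = lung2d[:, :, None] & z_lung[None, None, :]
        lung3d &= (labels == Tissue.SOFT_TISSUE) | (labels == Tissue.FAT)
        labels[lung3d] = Tissue.LUNG

    # lesions: spheres of soft tissue with elevated uptake
    dz = spacing[2]
    zc_mm = (np.arange(nz) - (nz - 1) / 2.0) * dz
    for k, les in enumerate(cfg.lesions, start=1):
        cx, cy, fz = les.center_mm
        cz = (fz - 0.5) * (nz - 1) * dz
        R = les.diameter_mm / 2.0
        d2 = (X[:, :, None] - cx) ** 2 + (Y[:, :, None] - cy) ** 2 + (
            zc_mm[None, None, :] - cz
        ) ** 2
        sphere = d2 <= R**2
        if not sphere.any():
            raise ValueError(f"lesion {k} has no voxels at this resolution")
        if np.any(sphere & (labels == Tissue.BACKGROUND)):
            raise ValueError(f"lesion {k} placed outside the body")
        place = sphere & np.isin(labels, (Tissue.SOFT_TISSUE, Tissue.FAT))
        labels[place] = Tissue.LESION_BASE + k
        rois[f"lesion_{k}"] = place

    # ROIs
    cord3d = cord2d[:, :, None] & np.ones(nz, bool)[None, None, :]
    cord3d &= labels == Tissue.SOFT_TISSUE
    n_bs = max(2, nz // 8)
    rois["brain_stem"] = cord3d & (z_idx >= nz - n_bs)[None, None, :]
    rois["spinal_cord"] = cord3d & (z_idx < nz - n_bs)[None, None, :]
    z_larynx = (z_idx >= int(nz * 0.45)) & (z_idx <= z_tr_end)
    larynx = tube(cfg.trachea_center_mm, cfg.trachea_radius_mm + 3.0)[:, :, None] & z_larynx[
        None, None, :
    ]
    rois["larynx"] = larynx & (labels > 0) & (labels != Tissue.BONE)
    rois["mandible"] = structures["mandible"]
    rois["oral_cavity"] = (
        tube(cfg.oral_center_mm, cfg.oral_radius_mm + 2.0)[:, :, None]
        & z_top[None, None, :]
        & (labels > 0)
        & (labels != Tissue.BONE)
    )
    rois["esophagus"] = eso3d
    rois["spine"] = structures["spine"]

    # intensity volumes
    hu = np.full(shape, cfg.tissue_hu[Tissue.BACKGROUND], dtype=np.float64)
    for t in (Tissue.SOFT_TISSUE, Tissue.FAT, Tissue.BONE, Tissue.AIR_CAVITY, Tissue.LUNG):
        hu[labels == t] = cfg.tissue_hu[t]
    hu[labels >= Tissue.LESION_BASE] = cfg.tissue_hu[Tissue.SOFT_TISSUE]
    if cfg.hu_noise_sd > 0:
        hu += rng.normal(0.0, cfg.hu_noise_sd, size=shape)

    activity = np.zeros(shape, dtype=np.float64)
    activity[labels > 0] = cfg.body_suv
    if cfg.air_suv is not None:
        activity[labels == Tissue.AIR_CAVITY] = cfg.air_suv
    if cfg.lung_suv is not None:
        activity[labels == Tissue.LUNG] = cfg.lung_suv
    for k, les in enumerate(cfg.lesions, start=1):
        if les.suv <= cfg.body_suv:
            raise ValueError("lesion SUV must exceed the body background SUV")
        activity[rois[f"lesion_{k}"]] = les.suv

    phantom = Phantom(
        labels=labels,
        hu=hu,
        activity=activity,
        spacing=tuple(float(s) for s in spacing),
        rois=rois,
        structures=structures,
        seed=seed,
    )
    phantom.validate()
    return phantom


def reference_attenuation_map(phantom: Phantom, kvp: int = 120) -> AttenuationMap:
    """CT-like reference attenuation map: voxelwise bilinear HU -> LAC."""
    return AttenuationMap(lac=hu_to_lac(phantom.hu, kvp=kvp), spacing=phantom.spacing)


def _soft_tissue_lac(phantom: Phantom, kvp: int) -> float:
    hu_soft = DEFAULT_TISSUE_HU[Tissue.SOFT_TISSUE]
    soft = phantom.labels == Tissue.SOFT_TISSUE
    if soft.any():
        hu_soft = float(np.median(phantom.hu[soft]))
    return float(hu_to_lac(np.array([hu_soft]), kvp=kvp)[0])


def degrade_map(
    phantom: Phantom,
    reference: AttenuationMap,
    config: DegradationConfig,
    kvp: int = 120,
) -> AttenuationMap:
    """Apply an MR-AC-like degradation to the reference attenuation map.

    See the module docstring for the two models.  The output is deterministic
    for a fixed ``config.seed``, and voxels outside the modified scope are
    bitwise equal to the reference.
    """
    if reference.lac.shape != phantom.labels.shape:
        raise ValueError("reference map is not aligned with the phantom")
    rng = np.random.default_rng(config.seed)
    lac = reference.lac.copy()

    if config.mode == "atlas_like":
        soft_lac = _soft_tissue_lac(phantom, kvp)
        bone = phantom.labels == Tissue.BONE
        if config.bone_to_soft:
            retained = np.zeros_like(bone)
            for name in config.retain_structures:
                if name in phantom.structures:
                    retained |= phantom.structures[name]
            lac[bone & ~retained] = soft_lac
        if config.air_cavity_to_soft_fraction > 0:
            air = phantom.labels == Tissue.AIR_CAVITY
            comps, n = ndimage.label(air)
            if n:
                # a seeded random subset holding the requested fraction of
                # connected cavities is misclassified as soft tissue
                k = int(round(config.air_cavity_to_soft_fraction * n))
                picked = rng.choice(n, size=k, replace=False)
                for i in picked:
                    lac[comps == i + 1] = soft_lac
        if config.fat_water_swap:
            fat = phantom.labels == Tissue.FAT
            soft = phantom.labels == Tissue.SOFT_TISSUE
            fat_lac_val = float(np.median(reference.lac[fat])) if fat.any() else soft_lac
            lac[fat] = soft_lac
            lac[soft] = fat_lac_val
        return AttenuationMap(lac=np.clip(lac, 0.0, None), spacing=reference.spacing)

    # deep_like: per-structure bone HU bias, then boundary-band blur
    hu = phantom.hu.copy()
    bone = phantom.labels == Tissue.BONE
    covered = np.zeros_like(bone)
    for name in sorted(phantom.structures):
        mask = phantom.structures[name] & bone
        if not mask.any():
            continue
        bias = rng.normal(config.bone_hu_bias_mean, config.bone_hu_bias_sd)
        hu[mask] += bias
        covered |= mask
    stray = bone & ~covered
    if stray.any():
        hu[stray] += rng.normal(config.bone_hu_bias_mean, config.bone_hu_bias_sd)
    lac = hu_to_lac(hu, kvp=kvp)

    if config.boundary_blur_fwhm > 0 and bone.any():
        sigma_mm = config.boundary_blur_fwhm / 2.3548
        sigma_vox = [sigma_mm / s for s in reference.spacing]
        halo = int(np.ceil(2 * max(sigma_vox))) + 1
        band = ndimage.binary_dilation(bone, iterations=halo) & ~ndimage.binary_erosion(
            bone, iterations=halo, border_value=0
        )
        blurred = ndimage.gaussian_filter(lac, sigma=sigma_vox)
        lac = np.where(band, blurred, lac)
    return AttenuationMap(lac=np.clip(lac, 0.0, None), spacing=reference.spacing)
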