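"""HU to 511 keV linear attenuation coefficients and compartment segmentation.

CT intensities (Hounsfield units) are mapped to linear attenuation
coefficients (LAC, cm^-1) at the PET annihilation-photon energy with the
standard bilinear scaling: a water-like slope up to a soft-tissue/bone
breakpoint and a flatter bone slope above it.  Bone and air compartments are
then defined by fixed LAC thresholds (bone strictly above 0.11 cm^-1, air
strictly below 0.007 cm^-1) inside the patient's body contour, with lung
excluded from the air compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

WATER_LAC = 0.096  # cm^-1 at 511 keV
AIR_LAC_THRESHOLD = 0.007  # cm^-1, voxels strictly below are "air"
BONE_LAC_THRESHOLD = 0.11  # cm^-1, voxels strictly above are "bone"

# Bilinear HU -> LAC(511 keV) parameters per CT tube voltage:
# (breakpoint HU, bone-segment slope cm^-1 per HU).  Below the breakpoint the
# water slope 9.6e-5 applies; the bone-segment intercept is derived from
# continuity at the breakpoint, which reproduces the published intercepts to
# their printed precision.
WATER_SLOPE = 9.6e-5
BILINEAR_PARAMS: dict[int, tuple[float, float]] = {
    100: (52.0, 4.43e-5),
    120: (47.0, 5.10e-5),
}


@dataclass(frozen=True)
class AttenuationMap:
    """Volume of 511 keV linear attenuation coefficients.

    Parameters
    ----------
    lac : ndarray
        Nonnegative LAC volume, cm^-1.
    spacing : tuple of float
        Voxel spacing (dx, dy, dz) in mm; axis order of ``lac`` is (x, y, z)
        with z the axial (slice) direction.
    """

    lac: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        lac = np.asarray(self.lac, dtype=np.float64)
        if not np.all(np.isfinite(lac)):
            raise ValueError("LAC volume must be finite")
        if lac.min() < 0:
            raise ValueError("LAC volume must be nonnegative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        object.__setattr__(self, "lac", lac)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))


@dataclass(frozen=True)
class CompartmentMasks:
    """Bone/air/lung masks inside the body contour.

    Invariants: bone and air lie inside body, are disjoint, and air excludes
    lung tissue.
    """

    body: np.ndarray
    bone: np.ndarray
    air: np.ndarray
    lung: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        lung = self.lung if self.lung is not None else np.zeros_like(self.body)
        object.__setattr__(self, "lung", np.asarray(lung, dtype=bool))
        for name in ("body", "bone", "air"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.bone[~self.body].sum() == 0 and self.air[~self.body].sum() == 0):
            raise ValueError("bone and air must lie inside body")
        if np.any(self.bone & self.air):
            raise ValueError("bone and air must be disjoint")
        if np.any(self.air & self.lung):
            raise ValueError("air must exclude lung")


def bilinear_intercept(kvp: int) -> float:
    """Bone-segment intercept implied by continuity at the breakpoint."""
    breakpoint_hu, slope = BILINEAR_PARAMS[kvp]
    return (WATER_SLOPE - slope) * (breakpoint_hu + 1000.0)


def hu_to_lac(hu: np.ndarray, kvp: int = 120) -> AttenuationMap | np.ndarray:
    """Convert HU to 511 keV LAC with the bilinear scaling.

    LAC = 9.6e-5 * (HU + 1000) up to the tube-voltage-specific breakpoint and
    a * (HU + 1000) + b above it, clipped at zero.  The map is continuous and
    nondecreasing; HU = -1000 gives 0 (air) and HU = 0 gives 0.096 cm^-1
    (water).

    Parameters
    ----------
    hu : array_like
        Hounsfield-unit volume (finite).
    kvp : int
        CT tube voltage; one of 100, 120.

    Returns
    -------
    ndarray
        LAC volume in cm^-1, same shape as ``hu``.
    """
    if kvp not in BILINEAR_PARAMS:
        raise ValueError(f"unsupported kvp {kvp}; supported: {sorted(BILINEAR_PARAMS)}")
    hu = np.asarray(hu, dtype=np.float64)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU input contains non-finite values")
    breakpoint_hu, slope = BILINEAR_PARAMS[kvp]
    intercept = bilinear_intercept(kvp)
    lac = np.where(
        hu <= breakpoint_hu,
        WATER_SLOPE * (hu + 1000.0),
        slope * (hu + 1000.0) + intercept,
    )
    return np.clip(lac, 0.0, None)


def body_contour(attn: AttenuationMap) -> np.ndarray:
    """Extract the patient body mask, internal air cavities included.

    Thresholds the map at the air LAC threshold, applies a morphological
    closing, fills holes slice-by-slice (so air channels open to the volume
    ends, e.g. a trachea, are still interior), and keeps the largest 3D
    connected component.

    Raises
    ------
    ValueError
        If no voxel exceeds the air threshold (empty body).
    """
    fg = attn.lac > AIR_LAC_THRESHOLD
    if not fg.any():
        raise ValueError("body contour undefined: no voxel above air threshold")
    fg = ndimage.binary_closing(fg, structure=np.ones((3, 3, 1), dtype=bool))
    filled = np.empty_like(fg)
    for z in range(fg.shape[2]):
        filled[:, :, z] = ndimage.binary_fill_holes(fg[:, :, z])
    labeled, n = ndimage.label(filled)
    if n == 0:
        raise ValueError("body contour undefined: empty foreground after closing")
    sizes = ndimage.sum_labels(filled, labeled, index=np.arange(1, n + 1))
    return labeled == (1 + int(np.argmax(sizes)))


def segment_compartments(
    attn: AttenuationMap,
    body: np.ndarray,
    lung: np.ndarray | None = None,
) -> CompartmentMasks:
    """Threshold the attenuation map into bone and air compartments.

    Bone is strictly above 0.11 cm^-1 within the body; air is strictly below
    0.007 cm^-1 within the body and outside lung.  Boundary values belong to
    neither compartment.
    """
    body = np.asarray(body, dtype=bool)
    if body.shape != attn.lac.shape:
        raise ValueError("body mask shape does not match attenuation map")
    if lung is None:
        lung = np.zeros_like(body)
    lung = np.asarray(lung, dtype=bool)
    if lung.shape != attn.lac.shape:
        raise ValueError("lung mask shape does not match attenuation map")
    bone = (attn.lac > BONE_LAC_THRESHOLD) & body
    air = (attn.lac < AIR_LAC_THRESHOLD) & body & ~lung
    return CompartmentMasks(body=body, bone=bone, air=air, lung=lung)
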