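"""Quantitative comparison of PET reconstructions under different
attenuation maps.

Implements the evaluation battery used to characterize MRI-based attenuation
correction against a CT-based reference: voxelwise relative differences and
their summary statistics, joint-histogram R^2, Dice overlap of bone/air
compartments, distance-resolved SUV_mean error profiles (2D in-plane
distance to the nearest bone or air voxel, 3 mm bins), and regional / lesion
SUV_mean errors, with across-subject quartile aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .attenuation import CompartmentMasks
from .pet_sim import PETImage

DEFAULT_THRESHOLDS = (5.0, 10.0, 20.0)
DEFAULT_BIN_WIDTH_MM = 3.0
DEFAULT_MIN_BIN_VOXELS = 10


@dataclass(frozen=True)
class DiffMap:
    """Voxelwise relative difference (percent) of a test PET vs reference."""

    rel_error: np.ndarray
    valid: np.ndarray
    reference_id: str = "reference"
    test_id: str = "test"

    def values(self) -> np.ndarray:
        return self.rel_error[self.valid]


@dataclass(frozen=True)
class DistanceProfile:
    """Per-distance-bin SUV_mean errors, per subject and aggregated.

    ``per_subject`` maps subject id -> DataFrame with columns
    [bin, lo_mm, hi_mm, n_voxels, error_pct]; ``aggregate`` has columns
    [bin, lo_mm, hi_mm, n_subjects, lq, median, uq].
    """

    compartment: str
    bin_width_mm: float
    per_subject: dict[str, pd.DataFrame]
    aggregate: pd.DataFrame


@dataclass(frozen=True)
class ErrorReport:
    """Metric bundle for one subject (or the pooled cohort)."""

    mean_error: float
    sd_error: float
    r2: float
    frac_within: dict[float, float]
    dice_bone: float
    dice_air: float
    regional_errors: dict[str, float] = field(default_factory=dict)
    scope: str = "subject"

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "mean_error_pct": self.mean_error,
            "sd_error_pct": self.sd_error,
            "r2": self.r2,
            "frac_within": {f"{t:g}": v for t, v in sorted(self.frac_within.items())},
            "dice_bone": self.dice_bone,
            "dice_air": self.dice_air,
            "regional_errors_pct": dict(sorted(self.regional_errors.items())),
        }


def _suv(img) -> np.ndarray:
    return img.suv if isinstance(img, PETImage) else np.asarray(img, dtype=np.float64)


def relative_difference(test, reference, body: np.ndarray) -> DiffMap:
    """100*(test - reference)/reference on body voxels with reference > 0."""
    t, r = _suv(test), _suv(reference)
    body = np.asarray(body, dtype=bool)
    if not (t.shape == r.shape == body.shape):
        raise ValueError("images and body mask are not aligned")
    valid = body & (r > 0)
    if not valid.any():
        raise ValueError("no valid voxels: empty body or zero reference")
    rel = np.zeros_like(r)
    np.divide(t - r, r, out=rel, where=valid)
    return DiffMap(rel_error=100.0 * rel, valid=valid)


def error_summary(
    diff: DiffMap, thresholds=DEFAULT_THRESHOLDS
) -> tuple[float, float, dict[float, float]]:
    """Mean, population SD, and fraction of voxels with |error| < t for each
    threshold t (percent)."""
    v = diff.values()
    if v.size == 0:
        raise ValueError("empty diff map")
    frac = {float(t): float(np.mean(np.abs(v) < t)) for t in thresholds}
    return float(v.mean()), float(v.std()), frac


def joint_r2(test, reference, mask: np.ndarray) -> float:
    """Squared Pearson correlation of paired voxel values on the mask."""
    mask = np.asarray(mask, dtype=bool)
    t, r = _suv(test)[mask], _suv(reference)[mask]
    if t.size < 2:
        raise ValueError("need at least 2 voxels")
    if t.std() == 0 or r.std() == 0:
        raise ValueError("zero variance in joint histogram")
    return float(np.corrcoef(t, r)[0, 1] ** 2)


def pooled_r2(stats: list[tuple[int, float, float, float, float, float]]) -> float:
    """R^2 from accumulated (n, sum_x, sum_y, sum_xx, sum_yy, sum_xy)."""
    n = sum(s[0] for s in stats)
    sx, sy, sxx, syy, sxy = (sum(s[i] for s in stats) for i in range(1, 6))
    cov = sxy - sx * sy / n
    vx = sxx - sx**2 / n
    vy = syy - sy**2 / n
    if vx <= 0 or vy <= 0:
        raise ValueError("zero variance in pooled joint histogram")
    return float(cov**2 / (vx * vy))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a&b|/(|a|+|b|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks are not aligned")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def distance_maps(
    compartments: CompartmentMasks, spacing
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Per-slice 2D Euclidean distance (mm) to the nearest bone/air voxel.

    Returns ((dist_to_bone, valid_bone), (dist_to_air, valid_air)).  The
    valid mask of the bone map excludes voxels outside the body, inside
    lung, and strictly closer to air than to bone — and vice versa for the
    air map; equidistant voxels are retained in both.  Slices lacking a
    compartment get infinite distance there (excluded from any finite bin);
    if a compartment is empty on every slice the profile is undefined.
    """
    bone, air = compartments.bone, compartments.air
    if not bone.any() or not air.any():
        raise ValueError("bone and air must each be nonempty somewhere")
    sampling = (spacing[0], spacing[1])
    nz = bone.shape[2]
    d_bone = np.full(bone.shape, np.inf)
    d_air = np.full(bone.shape, np.inf)
    for z in range(nz):
        if bone[:, :, z].any():
            d_bone[:, :, z] = ndimage.distance_transform_edt(
                ~bone[:, :, z], sampling=sampling
            )
        if air[:, :, z].any():
            d_air[:, :, z] = ndimage.distance_transform_edt(
                ~air[:, :, z], sampling=sampling
            )
    base = compartments.body & ~compartments.lung
    valid_bone = base & ~(d_air < d_bone)
    valid_air = base & ~(d_bone < d_air)
    return (d_bone, valid_bone), (d_air, valid_air)


def distance_profile(
    test,
    reference,
    dist: np.ndarray,
    valid: np.ndarray,
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
    min_voxels: int = DEFAULT_MIN_BIN_VOXELS,
) -> pd.DataFrame:
    """SUV_mean error per distance bin for one subject.

    Bin 0 holds voxels at distance exactly 0 (inside the compartment); bin
    k >= 1 holds distances in (w*(k-1), w*k].  The error of a bin is the
    ratio-of-means 100*(mean test - mean ref)/mean ref; bins with fewer than
    ``min_voxels`` voxels or zero reference mean are reported as missing
    (NaN).
    """
    t, r = _suv(test), _suv(reference)
    if not (t.shape == r.shape == dist.shape == valid.shape):
        raise ValueError("inputs are not aligned")
    d = dist[valid]
    tv, rv = t[valid], r[valid]
    finite = np.isfinite(d)
    d, tv, rv = d[finite], tv[finite], rv[finite]
    if d.size == 0:
        return pd.DataFrame(columns=["bin", "lo_mm", "hi_mm", "n_voxels", "error_pct"])
    k = np.where(d == 0, 0, np.ceil(d / bin_width_mm).astype(np.int64))
    n_bins = int(k.max()) + 1
    rows = []
    for b in range(n_bins):
        sel = k == b
        n = int(sel.sum())
        lo = 0.0 if b == 0 else bin_width_mm * (b - 1)
        hi = 0.0 if b == 0 else bin_width_mm * b
        if n < min_voxels or rv[sel].sum() <= 0:
            err = np.nan
        else:
            mref = rv[sel].mean()
            err = 100.0 * (tv[sel].mean() - mref) / mref
        rows.append((b, lo, hi, n, err))
    return pd.DataFrame(rows, columns=["bin", "lo_mm", "hi_mm", "n_voxels", "error_pct"])


def aggregate_profiles(
    profiles: dict[str, pd.DataFrame],
    compartment: str = "",
    bin_width_mm: float = DEFAULT_BIN_WIDTH_MM,
) -> DistanceProfile:
    """Across-subject quartiles (linear interpolation) per distance bin.

    Bins missing for a subject are skipped for that subject; a bin no
    subject has is absent from the aggregate.
    """
    if not profiles:
        raise ValueError("need at least one subject profile")
    rows = []
    all_bins = sorted({int(b) for df in profiles.values() for b in df["bin"]})
    for b in all_bins:
        vals = []
        lo = hi = None
        for df in profiles.values():
            hit = df[df["bin"] == b]
            if len(hit) and np.isfinite(hit["error_pct"].iloc[0]):
                vals.append(float(hit["error_pct"].iloc[0]))
                lo, hi = float(hit["lo_mm"].iloc[0]), float(hit["hi_mm"].iloc[0])
        if not vals:
            continue
        lq, med, uq = np.percentile(vals, [25, 50, 75])
        rows.append((b, lo, hi, len(vals), lq, med, uq))
    agg = pd.DataFrame(
        rows, columns=["bin", "lo_mm", "hi_mm", "n_subjects", "lq", "median", "uq"]
    )
    return DistanceProfile(
        compartment=compartment,
        bin_width_mm=bin_width_mm,
        per_subject=dict(profiles),
        aggregate=agg,
    )


def regional_errors(test, reference, rois: dict[str, np.ndarray]) -> dict[str, float]:
    """SUV_mean error (ratio of means, percent) per named region.

    Empty regions are reported as NaN rather than raising.
    """
    t, r = _suv(test), _suv(reference)
    out: dict[str, float] = {}
    for name, mask in rois.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != t.shape:
            raise ValueError(f"roi {name!r} is not aligned with the images")
        if not mask.any() or r[mask].mean() <= 0:
            out[name] = float("nan")
            continue
        mref = r[mask].mean()
        out[name] = float(100.0 * (t[mask].mean() - mref) / mref)
    return out
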