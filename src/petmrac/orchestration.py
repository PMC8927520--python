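"""Cohort experiment driver.

Runs the full study design on N synthetic subjects: for each subject a
phantom is generated, the reference (CT-like) attenuation map and the two
degraded maps (atlas-like, deep-like) are derived, one sinogram is simulated
with the REFERENCE attenuation (the true physics), and three reconstructions
are made, each corrected with its own map — so the reconstructions differ
only through the attenuation-correction error, mirroring a
PET_CT / PET_Atlas / PET_Deep comparison.  Per-subject metrics and cohort
aggregates (pooled voxel statistics, Dice mean +/- SD, distance-profile
quartiles, regional error tables) are computed and optionally written to
disk as JSON/CSV.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation as ev
from .attenuation import segment_compartments
from .pet_sim import Geometry, add_poisson, forward_project, osem_reconstruct, postfilter
from .phantoms import (
    AnatomyConfig,
    DegradationConfig,
    LesionSpec,
    Phantom,
    degrade_map,
    make_phantom,
    reference_attenuation_map,
)

log = logging.getLogger(__name__)

METHODS = ("atlas", "deep")


@dataclass(frozen=True)
class ExperimentConfig:
    """Full cohort-experiment configuration.

    Defaults echo the study design: 11 subjects, three reconstructions per
    subject with OSEM 4 iterations / 21 subsets / 3 mm FWHM post-filter, and
    noiseless projections as the primary analysis surface (Poisson noise is
    available via ``noiseless=False``).
    """

    n_subjects: int = 11
    shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    anatomy: AnatomyConfig = field(default_factory=AnatomyConfig)
    atlas: DegradationConfig = field(default_factory=lambda: DegradationConfig(mode="atlas_like"))
    deep: DegradationConfig = field(default_factory=lambda: DegradationConfig(mode="deep_like"))
    n_angles: int = 84
    iterations: int = 4
    subsets: int = 21
    postfilter_fwhm_mm: float = 3.0
    noiseless: bool = True
    counts_scale: float = 2.0e4
    kvp: int = 120
    thresholds: tuple[float, ...] = (5.0, 10.0, 20.0)
    bin_width_mm: float = 3.0
    min_bin_voxels: int = 10
    master_seed: int = 1234

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @staticmethod
    def from_yaml(path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, cls in (("anatomy", AnatomyConfig), ("atlas", DegradationConfig), ("deep", DegradationConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub = raw[key]
                if cls is AnatomyConfig and "lesions" in sub:
                    sub["lesions"] = tuple(LesionSpec(**l) for l in sub["lesions"])
                raw[key] = cls(**sub)
        for key in ("shape", "spacing", "thresholds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return ExperimentConfig(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anatomy"]["tissue_hu"] = {int(k): v for k, v in d["anatomy"]["tissue_hu"].items()}
        return d


def subject_seed(master_seed: int, index: int, stream: int = 0) -> int:
    """Deterministic, order-independent per-subject seed below 2^31."""
    ss = np.random.SeedSequence(entropy=(int(master_seed), int(index), int(stream)))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class SubjectResult:
    subject: str
    phantom: Phantom
    reports: dict[str, ev.ErrorReport]
    profiles: dict[tuple[str, str], pd.DataFrame]  # (method, compartment) -> bins
    joint_stats: dict[str, tuple]
    voxel_errors: dict[str, np.ndarray]


def run_subject(config: ExperimentConfig, index: int) -> SubjectResult:
    """Run the three-reconstruction experiment for one synthetic subject."""
    sid = f"subject_{index + 1:02d}"
    seed = subject_seed(config.master_seed, index)
    phantom = make_phantom(config.shape, config.spacing, config.anatomy, seed=seed)
    ref_map = reference_attenuation_map(phantom, kvp=config.kvp)
    maps = {
        "reference": ref_map,
        "atlas": degrade_map(
            phantom, ref_map, replace(config.atlas, seed=subject_seed(config.master_seed, index, 1)),
            kvp=config.kvp,
        ),
        "deep": degrade_map(
            phantom, ref_map, replace(config.deep, seed=subject_seed(config.master_seed, index, 2)),
            kvp=config.kvp,
        ),
    }

    geom = Geometry(
        nx=config.shape[0], ny=config.shape[1], pixel_mm=config.spacing[0],
        n_angles=config.n_angles,
    )
    sino = forward_project(phantom.activity, ref_map, geom)
    if not config.noiseless:
        sino = add_poisson(sino, config.counts_scale, seed=subject_seed(config.master_seed, index, 3))

    recon = {}
    for name, ac in maps.items():
        img = osem_reconstruct(
            sino, ac, geom, iterations=config.iterations, subsets=config.subsets
        )
        recon[name] = postfilter(img, config.postfilter_fwhm_mm)

    body, lung = phantom.body, phantom.lung
    ref_cm = segment_compartments(ref_map, body, lung)
    (d_bone, v_bone), (d_air, v_air) = ev.distance_maps(ref_cm, phantom.spacing)

    rois = {name: m for name, m in phantom.rois.items() if name != "spine"}
    reports: dict[str, ev.ErrorReport] = {}
    profiles: dict[tuple[str, str], pd.DataFrame] = {}
    joint_stats: dict[str, tuple] = {}
    voxel_errors: dict[str, np.ndarray] = {}
    for method in METHODS:
        diff = ev.relative_difference(recon[method], recon["reference"], body)
        mean, sd, frac = ev.error_summary(diff, config.thresholds)
        r2 = ev.joint_r2(recon[method], recon["reference"], body)
        test_cm = segment_compartments(maps[method], body, lung)
        reports[method] = ev.ErrorReport(
            mean_error=mean,
            sd_error=sd,
            r2=r2,
            frac_within=frac,
            dice_bone=ev.dice(test_cm.bone, ref_cm.bone),
            dice_air=ev.dice(test_cm.air, ref_cm.air),
            regional_errors=ev.regional_errors(recon[method], recon["reference"], rois),
            scope=sid,
        )
        for comp, (dist, valid) in (("bone", (d_bone, v_bone)), ("air", (d_air, v_air))):
            profiles[(method, comp)] = ev.distance_profile(
                recon[method], recon["reference"], dist, valid,
                bin_width_mm=config.bin_width_mm, min_voxels=config.min_bin_voxels,
            )
        t = recon[method].suv[body]
        r = recon["reference"].suv[body]
        joint_stats[method] = (
            t.size, float(t.sum()), float(r.sum()),
            float((t * t).sum()), float((r * r).sum()), float((t * r).sum()),
        )
        voxel_errors[method] = diff.values()
    return SubjectResult(
        subject=sid, phantom=phantom, reports=reports, profiles=profiles,
        joint_stats=joint_stats, voxel_errors=voxel_errors,
    )


@dataclass
class CohortResult:
    config: ExperimentConfig
    subjects: list[SubjectResult]
    failed: list[str]
    cohort_reports: dict[str, ev.ErrorReport]
    distance_profiles: dict[tuple[str, str], ev.DistanceProfile]
    regional_table: pd.DataFrame

    @property
    def n_completed(self) -> int:
        return len(self.subjects)


def _cohort_report(method: str, subjects: list[SubjectResult], thresholds) -> ev.ErrorReport:
    pooled = np.concatenate([s.voxel_errors[method] for s in subjects])
    frac = {float(t): float(np.mean(np.abs(pooled) < t)) for t in thresholds}
    r2 = ev.pooled_r2([s.joint_stats[method] for s in subjects])
    regional: dict[str, float] = {}
    names = sorted({n for s in subjects for n in s.reports[method].regional_errors})
    for name in names:
        vals = [
            s.reports[method].regional_errors[name]
            for s in subjects
            if np.isfinite(s.reports[method].regional_errors.get(name, np.nan))
        ]
        regional[name] = float(np.median(vals)) if vals else float("nan")
    return ev.ErrorReport(
        mean_error=float(pooled.mean()),
        sd_error=float(pooled.std()),
        r2=r2,
        frac_within=frac,
        dice_bone=float(np.mean([s.reports[method].dice_bone for s in subjects])),
        dice_air=float(np.mean([s.reports[method].dice_air for s in subjects])),
        regional_errors=regional,
        scope="cohort",
    )


def run_experiment(config: ExperimentConfig, outdir=None) -> CohortResult:
    """Run the cohort experiment; optionally persist reports under ``outdir``.

    A failing subject is logged and skipped; the cohort continues with the
    completed subjects.
    """
    subjects: list[SubjectResult] = []
    failed: list[str] = []
    for i in range(config.n_subjects):
        try:
            subjects.append(run_subject(config, i))
        except Exception:  # noqa: BLE001 - cohort must survive one bad subject
            log.exception("subject %d failed; continuing cohort", i + 1)
            failed.append(f"subject_{i + 1:02d}")
    if not subjects:
        raise RuntimeError("no subject completed")

    cohort_reports = {m: _cohort_report(m, subjects, config.thresholds) for m in METHODS}
    dist_profiles = {}
    for method in METHODS:
        for comp in ("bone", "air"):
            per_subj = {s.subject: s.profiles[(method, comp)] for s in subjects}
            dist_profiles[(method, comp)] = ev.aggregate_profiles(
                per_subj, compartment=comp, bin_width_mm=config.bin_width_mm
            )

    rows = []
    for s in subjects:
        for method in METHODS:
            for name, err in sorted(s.reports[method].regional_errors.items()):
                rows.append((s.subject, method, name, err))
    regional_table = pd.DataFrame(rows, columns=["subject", "method", "region", "error_pct"])

    result = CohortResult(
        config=config, subjects=subjects, failed=failed,
        cohort_reports=cohort_reports, distance_profiles=dist_profiles,
        regional_table=regional_table,
    )
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: CohortResult, outdir) -> None:
    """Persist cohort report, profiles, regional table and run manifest.

    Output is deterministic for a fixed config/seed (no timestamps), so two
    runs of the same experiment are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report = {
        "n_subjects_requested": result.config.n_subjects,
        "n_subjects_completed": result.n_completed,
        "failed_subjects": result.failed,
        "cohort": {m: r.to_dict() for m, r in result.cohort_reports.items()},
        "per_subject": {
            s.subject: {m: s.reports[m].to_dict() for m in METHODS} for s in result.subjects
        },
    }
    (outdir / "cohort_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))

    rows = []
    for s in result.subjects:
        for (method, comp), df in sorted(s.profiles.items()):
            for _, r in df.iterrows():
                rows.append(
                    (s.subject, method, comp, int(r["bin"]), r["lo_mm"], r["hi_mm"],
                     int(r["n_voxels"]), r["error_pct"])
                )
    pd.DataFrame(
        rows,
        columns=["subject", "method", "compartment", "bin", "lo_mm", "hi_mm",
                 "n_voxels", "error_pct"],
    ).to_csv(outdir / "profiles.csv", index=False)

    agg_rows = []
    for (method, comp), prof in sorted(result.distance_profiles.items()):
        for _, r in prof.aggregate.iterrows():
            agg_rows.append(
                (method, comp, int(r["bin"]), r["lo_mm"], r["hi_mm"],
                 int(r["n_subjects"]), r["lq"], r["median"], r["uq"])
            )
    pd.DataFrame(
        agg_rows,
        columns=["method", "compartment", "bin", "lo_mm", "hi_mm", "n_subjects",
                 "lq", "median", "uq"],
    ).to_csv(outdir / "profiles_aggregate.csv", index=False)

    result.regional_table.to_csv(outdir / "regional_errors.csv", index=False)

    manifest = {
        "config": result.config.to_dict(),
        "subject_seeds": {
            f"subject_{i + 1:02d}": subject_seed(result.config.master_seed, i)
            for i in range(result.config.n_subjects)
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
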