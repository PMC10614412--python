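"""Synthetic pre-school diffusion cohorts with age-dependent structure.

Generates, entirely in skeleton space, the statistical structure the
pipeline is designed to detect in 4-7 year-old children:

* typically developing (TD) children whose white-matter metrics drift
  linearly with age (FA rising; MD, RD and AD falling);
* autistic (ASD) children with a flattened trajectory (slope attenuation)
  and two latent developmental subgroups — a younger "overgrowth" subgroup
  whose affected bundles look older than their age (FA up, diffusivities
  down) and an older "delayed" subgroup with the opposite offset;
* subgroup membership drifting with age through a logistic boundary, higher
  ADOS social scores in the delayed subgroup, and a group difference in
  relative head motion.

Everything is deterministic given the spec seed; each subject draws from a
hierarchical child stream, so enlarging the cohort never reshuffles the
subjects already generated.

Diffusivities are expressed in um^2/ms so typical MD values sit near
0.8-1.0 and all arithmetic stays O(1).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "METRICS",
    "CohortSpec",
    "SubjectRecord",
    "MetricVolumeSet",
    "ConfigurationError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

METRICS = ("FA", "MD", "RD", "AD")

#: Per-metric baseline value at age 0 (extrapolated; FA dimensionless,
#: diffusivities in um^2/ms).
_BASELINES = {"FA": 0.35, "MD": 1.00, "RD": 0.82, "AD": 1.42}

PHENO_COLUMNS = (
    "subject_id", "group", "age", "sex", "handedness",
    "head_motion", "ados_total", "ados_social", "true_subgroup",
)


class ConfigurationError(ValueError):
    """Invalid cohort specification; the message names the offending field."""


def _metric_dict(fa, md, rd, ad):
    return {"FA": fa, "MD": md, "RD": rd, "AD": ad}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the discovery-cohort conditions the pipeline targets:
    68 ASD / 54 TD children aged 4-7 y, TD metric trajectories with the
    maturational sign pattern (FA +0.012/y; MD −0.020, RD −0.022,
    AD −0.018 um^2/ms per year), ASD slopes attenuated to 50% and pivoting
    at the age-range center (so the groups coincide in overall mean), and
    two latent ASD subgroups split by a soft logistic boundary at 5.5 y
    whose affected bundles (6 of 8, mirroring the handful of implicated
    tracts) carry opposite-signed regional offsets.
    """

    n_td: int = 54
    n_asd: int = 68
    age_range: tuple[float, float] = (4.0, 7.0)
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    n_bundles: int = 8
    td_slopes: dict = field(default_factory=lambda: _metric_dict(0.012, -0.020, -0.022, -0.018))
    asd_slope_attenuation: float = 0.5
    subgroup_effect: dict = field(default_factory=lambda: _metric_dict(0.015, 0.022, 0.022, 0.022))
    affected_bundles: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    subgroup_boundary_age: float = 5.5
    subgroup_boundary_scale: float = 0.20
    noise_sd: dict = field(default_factory=lambda: _metric_dict(0.040, 0.050, 0.050, 0.050))
    subject_sd: dict = field(default_factory=lambda: _metric_dict(0.003, 0.004, 0.004, 0.004))
    motion_params: dict = field(default_factory=lambda: {
        "ASD": (0.24, 0.05), "TD": (0.35, 0.12)})
    ados_params: dict = field(default_factory=lambda: {
        1: {"total": (17.5, 4.0), "social": (7.5, 1.8)},
        2: {"total": (19.5, 4.0), "social": (9.5, 1.8)}})
    ados_missing_fraction: float = 8 / 68
    sex_p_male: dict = field(default_factory=lambda: {"ASD": 47 / 68, "TD": 33 / 54})
    handedness_p: dict = field(default_factory=lambda: {
        "ASD": (59 / 68, 3 / 68, 6 / 68), "TD": (48 / 54, 1 / 54, 5 / 54)})
    seed: int = 0

    def validate(self) -> None:
        if self.n_td <= 0:
            raise ConfigurationError("n_td must be positive")
        if self.n_asd <= 0:
            raise ConfigurationError("n_asd must be positive")
        if not self.age_range[0] < self.age_range[1]:
            raise ConfigurationError("age_range must satisfy low < high")
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ConfigurationError("grid_shape must be three dimensions >= 2")
        if self.n_bundles < 1:
            raise ConfigurationError("n_bundles must be >= 1")
        if not 0.0 <= self.asd_slope_attenuation <= 1.0:
            raise ConfigurationError("asd_slope_attenuation must lie in [0, 1]")
        for m in METRICS:
            if self.noise_sd[m] <= 0:
                raise ConfigurationError(f"noise_sd[{m}] must be positive")
            if self.subject_sd[m] < 0:
                raise ConfigurationError(f"subject_sd[{m}] must be nonnegative")
        if self.td_slopes["FA"] <= 0:
            raise ConfigurationError("td_slopes[FA] must be positive (FA rises with age)")
        for m in ("MD", "RD", "AD"):
            if self.td_slopes[m] >= 0:
                raise ConfigurationError(f"td_slopes[{m}] must be negative "
                                         "(diffusivities fall with age)")
        if self.subgroup_boundary_scale <= 0:
            raise ConfigurationError("subgroup_boundary_scale must be positive")
        if not 0.0 <= self.ados_missing_fraction < 1.0:
            raise ConfigurationError("ados_missing_fraction must lie in [0, 1)")
        if any(b < 1 or b > self.n_bundles for b in self.affected_bundles):
            raise ConfigurationError("affected_bundles must be valid bundle labels")


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str                      # "TD" | "ASD"
    age: float                      # years (the true age Omega)
    sex: str                        # "M" | "F"
    handedness: str                 # "R" | "L" | "M" (mixed)
    head_motion: float              # relative head motion, mm
    ados_total: float | None = None
    ados_social: float | None = None
    true_subgroup: int | None = None  # latent, ASD only: 1 young / 2 old

    def __post_init__(self) -> None:
        if self.group not in ("TD", "ASD"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.head_motion <= 0:
            raise ValueError("head_motion must be positive")
        if (self.true_subgroup is None) != (self.group == "TD"):
            raise ValueError("true_subgroup must be set iff group is ASD")


@dataclass
class MetricVolumeSet:
    """One subject's FA/MD/RD/AD maps plus the shared skeleton geometry."""

    subject_id: str
    metric_maps: dict            # metric -> 3-D float array
    skeleton_mask: np.ndarray    # binary, same grid
    bundle_labels: np.ndarray    # int labels, 0 = background

    def validate(self) -> None:
        shape = self.skeleton_mask.shape
        for m, vol in self.metric_maps.items():
            if vol.shape != shape:
                raise ValueError(f"{m} map shape {vol.shape} != grid {shape}")
        sk = self.skeleton_mask.astype(bool)
        fa = self.metric_maps["FA"]
        if fa.min() < 0 or fa.max() > 1:
            raise ValueError("FA outside [0, 1]")
        for m in ("MD", "RD", "AD"):
            if np.any(self.metric_maps[m][sk] <= 0):
                raise ValueError(f"{m} not strictly positive on the skeleton")
        if np.any((self.bundle_labels != 0) & ~sk):
            raise ValueError("bundle labels extend beyond the skeleton")


# --- geometry -------------------------------------------------------------

def make_skeleton(grid_shape, n_bundles) -> tuple[np.ndarray, np.ndarray]:
    """A one-voxel-thick axial sheet split into contiguous bundle blocks.

    Real TBSS skeletons are sparse sheets at tract centers; a mid-grid plane
    partitioned into rectangular blocks keeps every bundle spatially
    contiguous so cluster-based statistics behave realistically.
    """
    nx, ny, nz = grid_shape
    z0 = nz // 2
    mask = np.zeros(grid_shape, dtype=np.uint8)
    mask[:, :, z0] = 1
    labels = np.zeros(grid_shape, dtype=np.int32)
    # split the sheet into n_bundles near-equal x-strips, alternating y halves
    # for n_bundles > nx strips is not supported at the default scale
    n_cols = int(np.ceil(n_bundles / 2)) if n_bundles > 1 else 1
    n_rows = 2 if n_bundles > 1 else 1
    x_edges = np.linspace(0, nx, n_cols + 1).astype(int)
    y_edges = np.linspace(0, ny, n_rows + 1).astype(int)
    label = 1
    for i in range(n_cols):
        for j in range(n_rows):
            if label > n_bundles:
                break
            labels[x_edges[i]:x_edges[i + 1], y_edges[j]:y_edges[j + 1], z0] = label
            label += 1
    # any leftover sheet voxels (odd splits) fold into the last bundle
    leftover = (mask == 1) & (labels == 0)
    labels[leftover] = n_bundles
    return mask, labels


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


# --- generation -----------------------------------------------------------

def _draw_subject(spec: CohortSpec, rng: np.random.Generator, idx: int,
                  group: str) -> SubjectRecord:
    lo, hi = spec.age_range
    age = float(rng.uniform(lo, hi))
    sex = "M" if rng.random() < spec.sex_p_male[group] else "F"
    handedness = str(rng.choice(["R", "L", "M"], p=np.asarray(spec.handedness_p[group])
                                / np.sum(spec.handedness_p[group])))
    mu, sd = spec.motion_params[group]
    motion = float(np.clip(rng.normal(mu, sd), 0.02, None))
    subgroup = None
    ados_total = ados_social = None
    if group == "ASD":
        p2 = _sigmoid((age - spec.subgroup_boundary_age) / spec.subgroup_boundary_scale)
        subgroup = 2 if rng.random() < p2 else 1
        if rng.random() >= spec.ados_missing_fraction:
            pt = spec.ados_params[subgroup]
            ados_total = float(np.clip(rng.normal(*pt["total"]), 0, 30))
            ados_social = float(np.clip(rng.normal(*pt["social"]), 0, 14))
    prefix = "td" if group == "TD" else "asd"
    return SubjectRecord(
        subject_id=f"{prefix}{idx:03d}", group=group, age=age, sex=sex,
        handedness=handedness, head_motion=motion,
        ados_total=ados_total, ados_social=ados_social, true_subgroup=subgroup,
    )


def _subject_maps(spec: CohortSpec, rng: np.random.Generator,
                  record: SubjectRecord, mask: np.ndarray,
                  labels: np.ndarray) -> MetricVolumeSet:
    affected = np.isin(labels, spec.affected_bundles)
    pivot = 0.5 * (spec.age_range[0] + spec.age_range[1])
    maps = {}
    for m in METRICS:
        slope = spec.td_slopes[m]
        vol = np.zeros(spec.grid_shape, dtype=np.float64)
        if record.group == "ASD":
            # flattened trajectory pivoting at the cohort age center, so the
            # two groups coincide in overall mean and the case-control test
            # on global means is null by construction
            a = spec.asd_slope_attenuation
            mean = (_BASELINES[m] + slope * pivot
                    + a * slope * (record.age - pivot))
        else:
            mean = _BASELINES[m] + slope * record.age
        vol[mask.astype(bool)] = mean
        if record.true_subgroup is not None and spec.subgroup_effect[m] != 0:
            # overgrowth subgroup looks older: FA up, diffusivities down;
            # delayed subgroup is the mirror image
            direction = 1.0 if record.true_subgroup == 1 else -1.0
            if m != "FA":
                direction *= -1.0
            vol[affected] += direction * spec.subgroup_effect[m]
        vol[mask.astype(bool)] += rng.normal(0.0, spec.subject_sd[m])
        vol[mask.astype(bool)] += rng.normal(0.0, spec.noise_sd[m],
                                             size=int(mask.sum()))
        if m == "FA":
            np.clip(vol, 0.0, 1.0, out=vol)
        else:
            on = mask.astype(bool)
            vol[on] = np.clip(vol[on], 1e-3, None)
        maps[m] = vol
    return MetricVolumeSet(record.subject_id, maps, mask.copy(), labels.copy())


def generate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecord], list[MetricVolumeSet]]:
    """Generate phenotypes and skeleton-space metric volumes.

    TD voxel means follow baseline + slope*age; ASD means use the attenuated
    slope plus the latent-subgroup offset on the affected bundles. All draws
    run off per-subject child streams of the spec seed.
    """
    spec.validate()
    mask, labels = make_skeleton(spec.grid_shape, spec.n_bundles)
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_td + spec.n_asd)
    records: list[SubjectRecord] = []
    volumes: list[MetricVolumeSet] = []
    for i in range(spec.n_td + spec.n_asd):
        group = "TD" if i < spec.n_td else "ASD"
        idx = i if group == "TD" else i - spec.n_td
        rng = np.random.default_rng(children[i])
        rec = _draw_subject(spec, rng, idx, group)
        records.append(rec)
        vols = _subject_maps(spec, rng, rec, mask, labels)
        vols.validate()
        volumes.append(vols)
    return records, volumes


# --- I/O ------------------------------------------------------------------

_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])  # RAS+, 2 mm isotropic


def _fmt(v) -> str:
    return "" if v is None else f"{v:.10g}"


def write_cohort(records, volumes, out_dir) -> Path:
    """Write phenotype CSV, per-subject metric NIfTIs, shared masks, manifest.

    Returns the manifest path; the manifest lists every written file
    relative to ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in records")
    by_id = {v.subject_id: v for v in volumes}
    if set(by_id) != set(ids):
        raise ValueError("records and volumes disagree on subject ids")

    paths = []
    pheno = out / "phenotype.csv"
    with pheno.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PHENO_COLUMNS)
        for r in records:
            w.writerow([
                r.subject_id, r.group, _fmt(r.age), r.sex, r.handedness,
                _fmt(r.head_motion), _fmt(r.ados_total), _fmt(r.ados_social),
                "" if r.true_subgroup is None else r.true_subgroup,
            ])
    paths.append(pheno.name)

    first = volumes[0]
    for name, arr in (("skeleton_mask", first.skeleton_mask),
                      ("bundle_labels", first.bundle_labels)):
        p = out / f"{name}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.int16), _AFFINE), p)
        paths.append(p.name)

    vol_dir = out / "volumes"
    vol_dir.mkdir(exist_ok=True)
    for r in records:
        for m in METRICS:
            p = vol_dir / f"{r.subject_id}_{m}.nii.gz"
            nib.save(nib.Nifti1Image(by_id[r.subject_id].metric_maps[m].astype(
                np.float32), _AFFINE), p)
            paths.append(str(p.relative_to(out)))

    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"files": paths}, indent=1))
    return manifest


def _parse_opt_float(s: str) -> float | None:
    return None if s == "" else float(s)


def read_pheno(path) -> list[SubjectRecord]:
    records = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            sg = row.get("true_subgroup", "")
            records.append(SubjectRecord(
                subject_id=row["subject_id"], group=row["group"],
                age=float(row["age"]), sex=row["sex"],
                handedness=row["handedness"],
                head_motion=float(row["head_motion"]),
                ados_total=_parse_opt_float(row["ados_total"]),
                ados_social=_parse_opt_float(row["ados_social"]),
                true_subgroup=None if sg in ("", None) else int(sg),
            ))
    return records


def read_cohort(in_dir) -> tuple[list[SubjectRecord], list[MetricVolumeSet]]:
    """Round-trip reader for :func:`write_cohort` output."""
    src = Path(in_dir)
    records = read_pheno(src / "phenotype.csv")
    mask = np.asarray(nib.load(src / "skeleton_mask.nii.gz").dataobj, dtype=np.uint8)
    labels = np.asarray(nib.load(src / "bundle_labels.nii.gz").dataobj, dtype=np.int32)
    volumes = []
    for r in records:
        maps = {}
        for m in METRICS:
            p = src / "volumes" / f"{r.subject_id}_{m}.nii.gz"
            maps[m] = np.asarray(nib.load(p).dataobj, dtype=np.float64)
        volumes.append(MetricVolumeSet(r.subject_id, maps, mask.copy(), labels.copy()))
    return records, volumes


def null_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A no-group-effect configuration: full TD slopes for ASD, zero subgroup
    offsets. Used for type-I calibration."""
    base = CohortSpec(seed=seed, asd_slope_attenuation=1.0,
                      subgroup_effect=_metric_dict(0.0, 0.0, 0.0, 0.0))
    return replace(base, **overrides) if overrides else base
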