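"""Synthetic cohort generator for the three airway age groups.

No imaging data ship with this package; instead the generator emulates the
reference cohort the models were fitted on — 7 children (ages 4–14),
6 adolescents/young adults (AYA, 15–39) and 7 adults (40–75) — using the
published per-group means and standard deviations of the twelve airway
parameters (three branch lengths, six angles, three diameters).

Each synthetic patient has:

* *true* spherical parameters drawn independently per parameter from
  normal distributions truncated to validity ranges,
* a noisy landmark set: the exact model landmarks plus isotropic Gaussian
  measurement noise on x and z (the slice axis y is read off the scanner
  grid and carries no noise),
* a per-slice centerline table sampled on a regular slice grid along each
  branch, again with Gaussian noise on x and z, plus per-slice diameters
  with their own noise.

The carina slice (y = 0) is emitted noise-free at (0, 0): the carina
landmark defines the coordinate origin, so its center has zero measurement
error by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import (
    BRANCHES,
    LEFT,
    RIGHT,
    TRACHEA,
    BranchPolar,
    DiameterSet,
    LandmarkSet,
    Point3,
    PolarParameters,
    branch_endpoint,
    DEFAULT_Y_SIGNS,
    params_to_dict,
)

__all__ = [
    "GroupDistribution",
    "STUDY_GROUPS",
    "CohortConfig",
    "SyntheticPatient",
    "Cohort",
    "sample_patient",
    "generate_cohort",
]

PARAM_KEYS = (
    "r1", "r2", "r3",
    "theta1", "theta2", "theta3",
    "phi1", "phi2", "phi3",
    "d1", "d2", "d3",
)

# Truncation bounds keeping sampled parameters anatomically valid.
_R_MIN = 0.5       # cm
_ANGLE_MIN = 5.0   # deg
_ANGLE_MAX = 175.0 # deg
_D_MIN = 0.2       # cm


@dataclass(frozen=True)
class GroupDistribution:
    """Sampling distribution of one age group: per-parameter mean and SD,
    the group's age range (years, metadata only) and its default size."""

    group: str
    n: int
    age_range: tuple[float, float]
    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        for key in PARAM_KEYS:
            if key not in self.mean or key not in self.sd:
                raise ValueError(f"group {self.group!r}: missing parameter {key!r}")
            if self.mean[key] <= 0:
                raise ValueError(f"group {self.group!r}: mean {key} must be positive")
            if self.sd[key] < 0:
                raise ValueError(f"group {self.group!r}: SD {key} must be >= 0")
        if self.n < 1:
            raise ValueError("group size must be >= 1")

    def zero_sd(self) -> "GroupDistribution":
        """Degenerate (noise-free) copy with every parameter SD set to zero;
        each sampled patient then carries exactly the group means."""
        return dataclasses.replace(self, sd={k: 0.0 for k in PARAM_KEYS})


def _group(group, n, ages, stats) -> GroupDistribution:
    mean = {k: m for k, (m, _) in stats.items()}
    sd = {k: s for k, (_, s) in stats.items()}
    return GroupDistribution(group=group, n=n, age_range=ages, mean=mean, sd=sd)


#: Reference-cohort parameter statistics (mean, SD) per age group:
#: lengths and diameters in cm, angles in degrees.
STUDY_GROUPS: Mapping[str, GroupDistribution] = {
    "children": _group("children", 7, (4.0, 14.0), {
        "r1": (8.08, 0.95), "r2": (2.02, 0.57), "r3": (3.10, 0.43),
        "theta1": (69.12, 5.69), "theta2": (105.35, 6.59), "theta3": (101.50, 5.08),
        "phi1": (88.03, 2.89), "phi2": (126.63, 6.95), "phi3": (42.31, 6.04),
        "d1": (1.04, 0.13), "d2": (0.95, 0.19), "d3": (0.99, 0.12),
    }),
    "aya": _group("aya", 6, (15.0, 39.0), {
        "r1": (11.75, 1.14), "r2": (2.93, 0.95), "r3": (4.19, 1.05),
        "theta1": (71.46, 1.82), "theta2": (101.97, 1.82), "theta3": (98.86, 7.21),
        "phi1": (87.10, 1.27), "phi2": (124.30, 2.62), "phi3": (45.36, 5.22),
        "d1": (1.58, 0.12), "d2": (1.40, 0.19), "d3": (1.35, 0.17),
    }),
    "adult": _group("adult", 7, (40.0, 75.0), {
        "r1": (11.69, 1.88), "r2": (3.30, 1.03), "r3": (4.25, 0.78),
        "theta1": (72.75, 3.90), "theta2": (108.82, 3.10), "theta3": (105.20, 4.02),
        "phi1": (86.10, 4.10), "phi2": (127.65, 6.36), "phi3": (38.00, 3.90),
        "d1": (1.64, 0.19), "d2": (1.49, 0.16), "d3": (1.49, 0.17),
    }),
}


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings. Defaults reproduce the reference-cohort
    structure (7/6/7 patients) and realistic planning-CT measurement noise.

    ``slice_spacing_cm``
        Regular slice grid spacing, default 0.25 cm (typical planning-CT
        slice thickness).
    ``landmark_noise_cm`` / ``slice_noise_cm``
        Gaussian SD of the x/z digitization error of landmarks and
        per-slice centers (default 0.15 cm).
    ``diameter_noise_cm``
        Gaussian SD of per-slice diameter reads (default 0.05 cm).
    """

    seed: int
    group_sizes: Mapping[str, int] | None = None
    slice_spacing_cm: float = 0.25
    landmark_noise_cm: float = 0.15
    slice_noise_cm: float = 0.15
    diameter_noise_cm: float = 0.05

    def __post_init__(self) -> None:
        if self.slice_spacing_cm <= 0:
            raise ValueError("slice_spacing_cm must be positive")
        for name in ("landmark_noise_cm", "slice_noise_cm", "diameter_noise_cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        sizes = self.sizes()
        if any(n < 0 for n in sizes.values()):
            raise ValueError("group sizes must be non-negative")
        if sum(sizes.values()) < 1:
            raise ValueError("cohort must contain at least one patient")

    def sizes(self) -> dict[str, int]:
        if self.group_sizes is None:
            return {g: d.n for g, d in STUDY_GROUPS.items()}
        return dict(self.group_sizes)

    def noise_free(self) -> "CohortConfig":
        """Copy with all measurement-noise SDs set to zero."""
        return dataclasses.replace(
            self, landmark_noise_cm=0.0, slice_noise_cm=0.0, diameter_noise_cm=0.0
        )


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    group: str
    age: float
    params: PolarParameters      # ground-truth spherical parameters
    diameters: DiameterSet       # ground-truth branch diameters
    landmarks: LandmarkSet       # noisy, carina-normalized frame
    slices: pd.DataFrame         # columns branch, y_cm, x_cm, z_cm, diameter_cm

    def truth_dict(self) -> dict[str, float]:
        return params_to_dict(self.params, self.diameters)


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    patients: tuple[SyntheticPatient, ...]

    def landmarks_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            for name, pt in p.landmarks.points().items():
                rows.append((p.patient_id, p.group, name, pt.x, pt.y, pt.z))
        return pd.DataFrame(rows, columns=["patient_id", "group", "point", "x_cm", "y_cm", "z_cm"])

    def slices_frame(self) -> pd.DataFrame:
        parts = []
        for p in self.patients:
            df = p.slices.copy()
            df.insert(0, "group", p.group)
            df.insert(0, "patient_id", p.patient_id)
            parts.append(df)
        return pd.concat(parts, ignore_index=True)

    def truth(self) -> dict[str, dict]:
        return {
            p.patient_id: {"group": p.group, "age": p.age, **p.truth_dict()}
            for p in self.patients
        }

    def write(self, out_dir) -> dict[str, Path]:
        """Write landmarks.csv, slices.csv and truth.json; returns the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "landmarks": out / "landmarks.csv",
            "slices": out / "slices.csv",
            "truth": out / "truth.json",
        }
        self.landmarks_frame().to_csv(paths["landmarks"], index=False)
        self.slices_frame().to_csv(paths["slices"], index=False)
        paths["truth"].write_text(json.dumps(self.truth(), indent=1, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# Sampling


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float) -> float:
    """Rejection-sampled truncated normal; degenerate at the mean for sd=0."""
    if sd == 0.0:
        if not (low < mean < high):
            raise ValueError(f"degenerate mean {mean} outside bounds ({low}, {high})")
        return mean
    for _ in range(10_000):
        v = rng.normal(mean, sd)
        if low < v < high:
            return v
    raise RuntimeError(
        f"truncated-normal rejection failed for mean={mean}, sd={sd} in ({low}, {high})"
    )


_BOUNDS = {
    "r": (_R_MIN, np.inf),
    "angle": (_ANGLE_MIN, _ANGLE_MAX),
    "d": (_D_MIN, np.inf),
}


def _draw_truth(dist: GroupDistribution, rng: np.random.Generator
                ) -> tuple[PolarParameters, DiameterSet]:
    v = {}
    for key in PARAM_KEYS:
        kind = "r" if key.startswith("r") else ("d" if key.startswith("d") else "angle")
        low, high = _BOUNDS[kind]
        v[key] = _truncated_normal(rng, dist.mean[key], dist.sd[key], low, high)
    params = PolarParameters(
        trachea=BranchPolar(v["r1"], v["theta1"], v["phi1"]),
        right_bronchus=BranchPolar(v["r2"], v["theta2"], v["phi2"]),
        left_bronchus=BranchPolar(v["r3"], v["theta3"], v["phi3"]),
    )
    return params, DiameterSet(v["d1"], v["d2"], v["d3"])


def _branch_slices(branch: str, params: PolarParameters, diameter: float,
                   config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Sample one branch's per-slice centerline table on the regular y grid."""
    ex, ey, ez = branch_endpoint(params.branch(branch), DEFAULT_Y_SIGNS[branch])
    s = config.slice_spacing_cm
    n_inner = int(np.floor(abs(ey) / s + 1e-9))
    if branch == TRACHEA:
        # carina slice y=0 owned by the trachea; ascending grid
        ys = np.arange(0, n_inner + 1) * s
    else:
        ys = -np.arange(1, n_inner + 1) * s  # descending, y < 0
    frac = ys / ey
    x = frac * ex
    z = frac * ez
    if config.slice_noise_cm > 0:
        x = x + rng.normal(0.0, config.slice_noise_cm, size=ys.size)
        z = z + rng.normal(0.0, config.slice_noise_cm, size=ys.size)
    d = np.full(ys.size, diameter)
    if config.diameter_noise_cm > 0:
        d = d + rng.normal(0.0, config.diameter_noise_cm, size=ys.size)
        d = np.clip(d, 0.05, None)  # a measured lumen is never <= 0
    if branch == TRACHEA and ys.size > 0:
        # carina defines the frame origin: its center is exact by construction
        x[0] = 0.0
        z[0] = 0.0
    return pd.DataFrame({
        "branch": branch, "y_cm": ys, "x_cm": x, "z_cm": z, "diameter_cm": d,
    })


def sample_patient(
    dist: GroupDistribution,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str,
) -> SyntheticPatient:
    """Draw one synthetic patient: truth parameters, noisy landmarks and a
    noisy per-slice centerline table. Bit-reproducible for a given rng state."""
    params, diameters = _draw_truth(dist, rng)
    age = float(rng.uniform(*dist.age_range))

    exact = {b: branch_endpoint(params.branch(b), DEFAULT_Y_SIGNS[b]) for b in BRANCHES}
    noisy = {}
    for b in BRANCHES:
        ex, ey, ez = exact[b]
        if config.landmark_noise_cm > 0:
            ex += rng.normal(0.0, config.landmark_noise_cm)
            ez += rng.normal(0.0, config.landmark_noise_cm)
        noisy[b] = Point3(ex, ey, ez)
    landmarks = LandmarkSet(
        P=noisy[TRACHEA], Q=Point3(0.0, 0.0, 0.0), R=noisy[RIGHT], S=noisy[LEFT],
        frame="normalized",
    )

    slices = pd.concat(
        [
            _branch_slices(b, params, diameters.branch(b), config, rng)
            for b in BRANCHES
        ],
        ignore_index=True,
    )
    return SyntheticPatient(
        patient_id=patient_id, group=dist.group, age=age,
        params=params, diameters=diameters, landmarks=landmarks, slices=slices,
    )


def generate_cohort(
    config: CohortConfig,
    distributions: Mapping[str, GroupDistribution] | None = None,
) -> Cohort:
    """Generate the full cohort (fixed group order children, aya, adult).

    ``distributions`` overrides the per-group sampling distributions, e.g.
    ``{g: d.zero_sd() for g, d in STUDY_GROUPS.items()}`` for a degenerate
    cohort pinned at the group means.
    """
    dists = dict(STUDY_GROUPS if distributions is None else distributions)
    rng = np.random.default_rng(config.seed)
    sizes = config.sizes()
    patients = []
    for group in ("children", "aya", "adult"):
        n = sizes.get(group, 0)
        if n == 0:
            continue
        if group not in dists:
            raise ValueError(f"no distribution provided for group {group!r}")
        for i in range(n):
            pid = f"{group}-{i + 1:02d}"
            patients.append(sample_patient(dists[group], config, rng, pid))
    return Cohort(config=config, patients=tuple(patients))
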