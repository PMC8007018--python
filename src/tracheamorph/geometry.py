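"""Coordinate frames and the Cartesian <-> spherical branch parameterization.

The tracheobronchial tree is reduced to four labelled landmarks measured on
supine planning CT:

* ``P`` — cranial end of the measured trachea,
* ``Q`` — tracheal carina (the bifurcation ridge),
* ``R`` — end of the right main bronchus,
* ``S`` — end of the left main bronchus.

Axes follow the anatomical convention used throughout this package:
``x`` runs left–right (patient-left positive), ``y`` runs superior–inferior
(superior positive; this is the CT slice axis), and ``z`` runs
anterior–posterior (anterior positive). All distances are centimetres and
all angles degrees.

After translating the frame so that the carina sits at the origin, each
branch (carina -> P, carina -> R, carina -> S) is summarised by spherical
parameters ``(r, theta, phi)``: ``r`` is the branch length, ``theta`` the
polar angle from the anterior–posterior (z) axis, and ``phi`` the azimuth
from the left–right (x) axis within the x–y plane.

Because ``theta`` and ``phi`` are recovered by arccos they live in
[0, 180] degrees, which makes ``y = r sin(theta) sin(phi)`` non-negative:
the spherical form does not retain which side of the carina a branch lies
on. Reconstruction therefore takes explicit per-branch y-signs (trachea
superior ``+1``, bronchi inferior ``-1`` by default), and extraction is
insensitive to the sign of the y-offset (y enters only squared).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TRACHEA",
    "RIGHT",
    "LEFT",
    "BRANCHES",
    "DEFAULT_Y_SIGNS",
    "Point3",
    "LandmarkSet",
    "BranchPolar",
    "PolarParameters",
    "DiameterSet",
    "normalize_landmarks",
    "branch_polar_from_vector",
    "cart_to_polar",
    "branch_endpoint",
    "polar_to_cart",
    "point_on_branch_at_y",
    "bed_angle",
    "params_to_dict",
    "params_from_dict",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

TRACHEA = "trachea"
RIGHT = "right"
LEFT = "left"
BRANCHES = (TRACHEA, RIGHT, LEFT)

#: Default superior/inferior signs used when rebuilding Cartesian landmarks:
#: the trachea rises above the carina, both main bronchi descend below it.
DEFAULT_Y_SIGNS: Mapping[str, float] = {TRACHEA: 1.0, RIGHT: -1.0, LEFT: -1.0}

_FRAMES = ("raw", "normalized", "model")


@dataclass(frozen=True)
class Point3:
    """A 3-D point in the anatomical frame (cm).

    ``x``: left–right (patient-left positive); ``y``: superior–inferior
    (superior positive, the slice axis); ``z``: anterior–posterior
    (anterior positive).
    """

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"Point3.{name} must be finite, got {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def __sub__(self, other: "Point3") -> "Point3":
        return Point3(self.x - other.x, self.y - other.y, self.z - other.z)


class LandmarkOrderError(ValueError):
    """A landmark set violates the superior/inferior ordering about the carina."""


@dataclass(frozen=True)
class LandmarkSet:
    """The four airway landmarks P, Q, R, S in one of three frames.

    ``raw`` — as digitized on the CT; ``normalized`` — translated so the
    carina Q is exactly at the origin; ``model`` — ideal landmarks
    reconstructed from spherical parameters (bronchi below the carina).
    """

    P: Point3
    Q: Point3
    R: Point3
    S: Point3
    frame: str = "raw"

    def __post_init__(self) -> None:
        if self.frame not in _FRAMES:
            raise ValueError(f"frame must be one of {_FRAMES}, got {self.frame!r}")
        if self.frame in ("normalized", "model"):
            if (self.Q.x, self.Q.y, self.Q.z) != (0.0, 0.0, 0.0):
                raise ValueError(
                    f"{self.frame} frame requires Q at the origin, got {self.Q}"
                )

    def validate_ordering(self) -> None:
        """Check the anatomical ordering: P superior to Q, R and S inferior.

        Applies to measured frames (raw/normalized). Raises
        :class:`LandmarkOrderError` naming the offending point.
        """
        if self.frame == "model":
            return
        if not self.P.y > self.Q.y:
            raise LandmarkOrderError(
                f"point P must lie superior to the carina Q "
                f"(P.y={self.P.y} <= Q.y={self.Q.y})"
            )
        for name in ("R", "S"):
            pt: Point3 = getattr(self, name)
            if not pt.y < self.Q.y:
                raise LandmarkOrderError(
                    f"point {name} must lie inferior to the carina Q "
                    f"({name}.y={pt.y} >= Q.y={self.Q.y})"
                )

    def points(self) -> dict[str, Point3]:
        return {"P": self.P, "Q": self.Q, "R": self.R, "S": self.S}


@dataclass(frozen=True)
class BranchPolar:
    """Spherical parameters of a single branch: length ``r`` (cm), polar
    angle ``theta`` from the A–P axis and azimuth ``phi`` from the L–R axis
    (both degrees, in [0, 180])."""

    r: float
    theta: float
    phi: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.r) and self.r > 0):
            raise ValueError(f"branch length r must be positive, got {self.r!r}")
        for name in ("theta", "phi"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 180.0):
                raise ValueError(f"{name} must lie in [0, 180] deg, got {v!r}")


@dataclass(frozen=True)
class PolarParameters:
    """The nine geometric model parameters of one airway: (r, theta, phi)
    for the trachea, the right main bronchus and the left main bronchus."""

    trachea: BranchPolar
    right_bronchus: BranchPolar
    left_bronchus: BranchPolar

    def __post_init__(self) -> None:
        # Anatomically the trachea is the longest segment; implausible sets
        # are flagged but not rejected (they can occur in noisy data).
        if not (self.trachea.r > self.right_bronchus.r and self.trachea.r > self.left_bronchus.r):
            warnings.warn(
                "implausible anatomy: trachea length r1 is not the largest "
                f"(r1={self.trachea.r}, r2={self.right_bronchus.r}, "
                f"r3={self.left_bronchus.r})",
                stacklevel=2,
            )

    def branch(self, name: str) -> BranchPolar:
        return {TRACHEA: self.trachea, RIGHT: self.right_bronchus, LEFT: self.left_bronchus}[name]


@dataclass(frozen=True)
class DiameterSet:
    """Mean lumen diameters (cm): ``d1`` trachea, ``d2`` right main
    bronchus, ``d3`` left main bronchus."""

    d1: float
    d2: float
    d3: float

    def __post_init__(self) -> None:
        for name in ("d1", "d2", "d3"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"diameter {name} must be positive, got {v!r}")

    def branch(self, name: str) -> float:
        return {TRACHEA: self.d1, RIGHT: self.d2, LEFT: self.d3}[name]


# ---------------------------------------------------------------------------
# Frame normalization


def normalize_landmarks(landmarks: LandmarkSet) -> LandmarkSet:
    """Translate a landmark set so the carina Q sits exactly at the origin.

    Accepts ``raw`` or already-``normalized`` input (the operation is
    idempotent); rejects ``model`` frames and sets violating the
    superior/inferior ordering about the carina.
    """
    if landmarks.frame == "model":
        raise ValueError("cannot normalize a model-frame landmark set")
    landmarks.validate_ordering()
    q = landmarks.Q
    return LandmarkSet(
        P=landmarks.P - q,
        Q=Point3(0.0, 0.0, 0.0),
        R=landmarks.R - q,
        S=landmarks.S - q,
        frame="normalized",
    )


# ---------------------------------------------------------------------------
# Cartesian -> spherical (extraction)


def branch_polar_from_vector(x: float, y: float, z: float) -> BranchPolar:
    """Spherical parameters of one carina-to-endpoint branch vector (cm).

    ``r`` is the Euclidean norm, ``theta = arccos(z / r)``,
    ``phi = arccos(x / sqrt(x^2 + y^2))``, both in degrees. The sign of the
    superior–inferior offset ``y`` does not affect the result.

    Raises ``ValueError`` for a zero-length vector, and for a vector on the
    A–P (z) axis where the azimuth is undefined.
    """
    r = math.sqrt(x * x + y * y + z * z)
    if r == 0.0:
        raise ValueError("zero-length branch vector: landmark coincides with the carina")
    planar = math.hypot(x, y)
    if planar == 0.0:
        raise ValueError(
            "branch vector lies on the anterior-posterior (z) axis; "
            "the azimuth phi is undefined"
        )
    theta = math.degrees(math.acos(min(1.0, max(-1.0, z / r))))
    phi = math.degrees(math.acos(min(1.0, max(-1.0, x / planar))))
    return BranchPolar(r=r, theta=theta, phi=phi)


def cart_to_polar(normalized: LandmarkSet) -> PolarParameters:
    """Extract (r, theta, phi) per branch from carina-centred landmarks.

    Requires ``frame == "normalized"``; the branch vectors are simply the
    coordinates of P, R and S.
    """
    if normalized.frame != "normalized":
        raise ValueError(
            f"cart_to_polar requires a normalized landmark set, got frame={normalized.frame!r}"
        )
    return PolarParameters(
        trachea=branch_polar_from_vector(normalized.P.x, normalized.P.y, normalized.P.z),
        right_bronchus=branch_polar_from_vector(normalized.R.x, normalized.R.y, normalized.R.z),
        left_bronchus=branch_polar_from_vector(normalized.S.x, normalized.S.y, normalized.S.z),
    )


# ---------------------------------------------------------------------------
# Spherical -> Cartesian (reconstruction)


def branch_endpoint(branch: BranchPolar, y_sign: float = 1.0) -> tuple[float, float, float]:
    """Cartesian endpoint of a branch from the carina:
    ``(r sin(theta) cos(phi), y_sign * r sin(theta) sin(phi), r cos(theta))``."""
    th = math.radians(branch.theta)
    ph = math.radians(branch.phi)
    st = math.sin(th)
    return (
        branch.r * st * math.cos(ph),
        y_sign * branch.r * st * math.sin(ph),
        branch.r * math.cos(th),
    )


def polar_to_cart(
    params: PolarParameters,
    y_signs: Mapping[str, float] | None = None,
) -> LandmarkSet:
    """Rebuild ideal model landmarks P, Q, R, S from spherical parameters.

    ``y_signs`` restores the superior/inferior side per branch (default:
    trachea +1, both bronchi -1). The carina Q is the origin; the returned
    frame is ``model``.
    """
    signs = DEFAULT_Y_SIGNS if y_signs is None else {**DEFAULT_Y_SIGNS, **y_signs}
    p = branch_endpoint(params.trachea, signs[TRACHEA])
    r = branch_endpoint(params.right_bronchus, signs[RIGHT])
    s = branch_endpoint(params.left_bronchus, signs[LEFT])
    return LandmarkSet(
        P=Point3(*p), Q=Point3(0.0, 0.0, 0.0), R=Point3(*r), S=Point3(*s), frame="model"
    )


def point_on_branch_at_y(
    params: PolarParameters,
    branch: str,
    y: float,
    y_signs: Mapping[str, float] | None = None,
) -> tuple[float, float]:
    """Centerline position (x, z) of a straight branch at slice height ``y``.

    Linear interpolation between the carina (origin) and the branch
    endpoint; ``y`` must lie between 0 and the endpoint's y (inclusive,
    sign-aware). At the carina (y = 0) this is exactly (0, 0).
    """
    signs = DEFAULT_Y_SIGNS if y_signs is None else {**DEFAULT_Y_SIGNS, **y_signs}
    ex, ey, ez = branch_endpoint(params.branch(branch), signs[branch])
    if ey == 0.0:
        raise ValueError(f"branch {branch!r} has zero superior-inferior extent")
    frac = y / ey
    if frac < -1e-12 or frac > 1.0 + 1e-12:
        raise ValueError(
            f"slice y={y} cm lies outside branch {branch!r} "
            f"(model extent 0 to {ey:.4f} cm)"
        )
    frac = min(1.0, max(0.0, frac))
    return (frac * ex, frac * ez)


def bed_angle(params: PolarParameters) -> float:
    """Inclination of the trachea axis out of the couch (x–y) plane, degrees.

    Returns ``90 - theta1``. Note the complementary reading: the trachea
    polar angle ``theta1`` itself (available as ``params.trachea.theta``)
    measures the same geometry from the A–P axis, so a supine trachea
    inclined ~20 deg out of the bed plane has ``theta1`` ~70 deg.
    """
    return 90.0 - params.trachea.theta


# ---------------------------------------------------------------------------
# Serialization contracts

_PARAM_ORDER = (
    "r1", "r2", "r3",
    "theta1", "theta2", "theta3",
    "phi1", "phi2", "phi3",
    "d1", "d2", "d3",
)


def params_to_dict(params: PolarParameters, diameters: DiameterSet | None = None) -> dict[str, float]:
    """Flatten parameters to the JSON contract keys
    ``r1..r3, theta1..theta3, phi1..phi3`` (+ ``d1..d3`` when given)."""
    out = {
        "r1": params.trachea.r, "theta1": params.trachea.theta, "phi1": params.trachea.phi,
        "r2": params.right_bronchus.r, "theta2": params.right_bronchus.theta,
        "phi2": params.right_bronchus.phi,
        "r3": params.left_bronchus.r, "theta3": params.left_bronchus.theta,
        "phi3": params.left_bronchus.phi,
    }
    if diameters is not None:
        out.update({"d1": diameters.d1, "d2": diameters.d2, "d3": diameters.d3})
    return {k: float(out[k]) for k in _PARAM_ORDER if k in out}


def params_from_dict(d: Mapping[str, float]) -> tuple[PolarParameters, DiameterSet | None]:
    """Inverse of :func:`params_to_dict`."""
    params = PolarParameters(
        trachea=BranchPolar(d["r1"], d["theta1"], d["phi1"]),
        right_bronchus=BranchPolar(d["r2"], d["theta2"], d["phi2"]),
        left_bronchus=BranchPolar(d["r3"], d["theta3"], d["phi3"]),
    )
    diam = None
    if all(k in d for k in ("d1", "d2", "d3")):
        diam = DiameterSet(d["d1"], d["d2"], d["d3"])
    return params, diam


# ---------------------------------------------------------------------------
# Landmark CSV contract
#
# Columns: patient_id, group, point in {P,Q,R,S}, x_cm, y_cm, z_cm; four rows
# per patient, header mandatory. The frame is not stored: a set whose Q is
# exactly at the origin reads back as normalized, anything else as raw.

_LANDMARK_COLUMNS = ["patient_id", "group", "point", "x_cm", "y_cm", "z_cm"]


def write_landmarks_csv(
    records: Iterable[tuple[str, str, LandmarkSet]], path
) -> None:
    """Write ``(patient_id, group, LandmarkSet)`` records to the landmark CSV."""
    rows = []
    for patient_id, group, lms in records:
        for name, pt in lms.points().items():
            rows.append((patient_id, group, name, pt.x, pt.y, pt.z))
    pd.DataFrame(rows, columns=_LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks_csv(path) -> list[tuple[str, str, LandmarkSet]]:
    """Read the landmark CSV back into ``(patient_id, group, LandmarkSet)``."""
    df = pd.read_csv(path)
    missing = set(_LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV is missing columns: {sorted(missing)}")
    out = []
    for (pid, group), sub in df.groupby(["patient_id", "group"], sort=False):
        pts = {}
        for _, row in sub.iterrows():
            pts[row["point"]] = Point3(float(row.x_cm), float(row.y_cm), float(row.z_cm))
        missing_pts = {"P", "Q", "R", "S"} - set(pts)
        if missing_pts:
            raise ValueError(f"patient {pid!r}: missing landmark(s) {sorted(missing_pts)}")
        q = pts["Q"]
        frame = "normalized" if (q.x, q.y, q.z) == (0.0, 0.0, 0.0) else "raw"
        out.append((str(pid), str(group), LandmarkSet(pts["P"], q, pts["R"], pts["S"], frame=frame)))
    return out
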