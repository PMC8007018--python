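"""Slice-wise agreement between a phantom model and measured centerlines.

A group model is a triple of straight branches through the carina. For
every CT slice of a patient (carina-normalized, so the patient's own Q is
the origin) whose slice position y falls inside the model branch's
superior–inferior extent, the model predicts a centerline position by
linear interpolation along the branch; the signed difference
``model − measured`` is taken separately in the left–right (x) and
anterior–posterior (z) directions. The y component of every difference is
identically zero because slices are matched on y, and at the carina the
difference is the zero vector by construction.

Differences are summarized as mean ± SD of absolute differences per
branch segment (QP = trachea, QR = right, QS = left) and direction
(LR, AP), and as Bland-Altman agreement statistics with 95% limits
``mean ± 1.96·SD``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import (
    BRANCHES,
    DEFAULT_Y_SIGNS,
    PolarParameters,
    branch_endpoint,
)
from .pipeline import TracheaModelSpec

__all__ = [
    "SEGMENT_LABELS",
    "BlandAltmanResult",
    "slice_differences",
    "summarize_absolute",
    "grand_mean_abs",
    "bland_altman",
    "bland_altman_by_cell",
    "plot_bland_altman",
]

#: Branch -> carina-anchored segment label used in reports.
SEGMENT_LABELS: Mapping[str, str] = {"trachea": "QP", "right": "QR", "left": "QS"}

_DIFF_COLUMNS = ["patient_id", "branch", "y_cm", "x_model_cm", "z_model_cm",
                 "x_meas_cm", "z_meas_cm", "dx_cm", "dz_cm"]


def _model_params(model) -> PolarParameters:
    if isinstance(model, TracheaModelSpec):
        return model.polar()
    if isinstance(model, PolarParameters):
        return model
    raise TypeError(f"model must be TracheaModelSpec or PolarParameters, got {type(model)}")


def slice_differences(
    model,
    slices: pd.DataFrame,
    y_signs: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Signed per-slice differences (model − measured) in x and z.

    ``slices`` must be carina-normalized with columns ``branch, y_cm, x_cm,
    z_cm`` (an optional ``patient_id`` column is carried through). Slices
    whose y lies outside the model branch's extent are excluded — the model
    cannot be extrapolated past its endpoint — and counted per branch in
    the returned mapping.
    """
    params = _model_params(model)
    signs = DEFAULT_Y_SIGNS if y_signs is None else {**DEFAULT_Y_SIGNS, **y_signs}
    has_pid = "patient_id" in slices.columns
    rows = []
    excluded: dict[str, int] = {}
    for b in BRANCHES:
        sub = slices[slices["branch"] == b]
        if sub.empty:
            continue
        ex, ey, ez = branch_endpoint(params.branch(b), signs[b])
        y = sub["y_cm"].to_numpy(dtype=float)
        frac = y / ey
        inside = (frac >= -1e-9) & (frac <= 1.0 + 1e-9)
        excluded[b] = int((~inside).sum())
        if not inside.any():
            warnings.warn(
                f"branch {b!r}: no slice overlaps the model extent "
                f"(0 to {ey:.3f} cm); empty difference list",
                stacklevel=2,
            )
            continue
        f = np.clip(frac[inside], 0.0, 1.0)
        xm = f * ex
        zm = f * ez
        x_meas = sub["x_cm"].to_numpy(dtype=float)[inside]
        z_meas = sub["z_cm"].to_numpy(dtype=float)[inside]
        part = pd.DataFrame({
            "patient_id": sub["patient_id"].to_numpy()[inside] if has_pid else "",
            "branch": b,
            "y_cm": y[inside],
            "x_model_cm": xm, "z_model_cm": zm,
            "x_meas_cm": x_meas, "z_meas_cm": z_meas,
            "dx_cm": xm - x_meas, "dz_cm": zm - z_meas,
        })
        rows.append(part)
    if rows:
        diffs = pd.concat(rows, ignore_index=True)[_DIFF_COLUMNS]
    else:
        diffs = pd.DataFrame(columns=_DIFF_COLUMNS)
    return diffs, excluded


def summarize_absolute(diffs: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of absolute differences per segment x direction.

    Returns a tidy frame with columns ``branch`` (QP/QR/QS), ``direction``
    (LR for x, AP for z), ``mean_abs_cm``, ``sd_abs_cm``, ``n_slices``.
    """
    if diffs.empty:
        raise ValueError("cannot summarize an empty difference list")
    rows = []
    for b, seg in SEGMENT_LABELS.items():
        sub = diffs[diffs["branch"] == b]
        if sub.empty:
            continue
        for direction, col in (("LR", "dx_cm"), ("AP", "dz_cm")):
            vals = sub[col].abs().to_numpy(dtype=float)
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            rows.append((seg, direction, float(vals.mean()), sd, int(vals.size)))
    return pd.DataFrame(
        rows, columns=["branch", "direction", "mean_abs_cm", "sd_abs_cm", "n_slices"]
    )


def grand_mean_abs(summary: pd.DataFrame) -> float:
    """Unweighted mean of the per-cell mean absolute differences (the
    headline single-number accuracy of a model)."""
    return float(summary["mean_abs_cm"].mean())


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement statistics for paired model/measurement series: mean
    difference, SD of differences and 95% limits of agreement."""

    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    n: int
    pair_means: np.ndarray
    differences: np.ndarray

    def __post_init__(self) -> None:
        if not (self.loa_lower <= self.mean_diff <= self.loa_upper):
            raise ValueError("limits of agreement must bracket the mean difference")


def bland_altman(
    model_values: Sequence[float], measured_values: Sequence[float]
) -> BlandAltmanResult:
    """Bland-Altman statistics of model − measured differences.

    Limits of agreement are ``mean ± 1.96·SD`` with the sample SD (n−1).
    Also returns the (pair mean, difference) series for plotting.
    """
    m = np.asarray(model_values, dtype=float)
    a = np.asarray(measured_values, dtype=float)
    if m.shape != a.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {a.shape}")
    if m.size < 2:
        raise ValueError("Bland-Altman needs at least two pairs")
    d = m - a
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n=int(d.size),
        pair_means=(m + a) / 2.0,
        differences=d,
    )


def bland_altman_by_cell(diffs: pd.DataFrame) -> dict[tuple[str, str], BlandAltmanResult]:
    """Bland-Altman per segment x direction, pooled over whatever patients
    are present in ``diffs``."""
    out = {}
    for b, seg in SEGMENT_LABELS.items():
        sub = diffs[diffs["branch"] == b]
        if len(sub) < 2:
            continue
        out[(seg, "LR")] = bland_altman(sub["x_model_cm"], sub["x_meas_cm"])
        out[(seg, "AP")] = bland_altman(sub["z_model_cm"], sub["z_meas_cm"])
    return out


def plot_bland_altman(
    results: Mapping[tuple[str, str], BlandAltmanResult], path
) -> None:
    """Write a panel figure (one axes per segment x direction) of the
    Bland-Altman scatters with mean line and 95% limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = list(results)
    ncols = 2
    nrows = max(1, (len(keys) + 1) // 2)
    fig, axes = plt.subplots(nrows, ncols, figsize=(9, 3 * nrows), squeeze=False)
    for ax in axes.flat:
        ax.set_visible(False)
    for ax, key in zip(axes.flat, keys):
        res = results[key]
        ax.set_visible(True)
        ax.scatter(res.pair_means, res.differences, s=8, alpha=0.6)
        ax.axhline(res.mean_diff, color="red")
        for lim in (res.loa_lower, res.loa_upper):
            ax.axhline(lim, color="black", linestyle="--")
        ax.set_title(f"{key[0]} {key[1]}")
        ax.set_xlabel("mean of model and measurement [cm]")
        ax.set_ylabel("model - measurement [cm]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
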