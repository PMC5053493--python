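"""Per-acquisition quantification and monthly clustering.

The retinal thickness of an acquisition is the mean over a circumpapillary
annulus centered at the ONH (inner radius 125 px ≈ 250 µm, outer 225 px ≈
450 µm at 2 µm/px), reported only when at least 75% of the annulus pixels
are covered.  Lesion spacing is summarized by the mean pairwise and mean
nearest-neighbour Euclidean distance in the en-face plane.  Depolarizing
deposits are binned into 20 equally spaced slabs between the ILM and the
RPE.  Longitudinal records are clustered per calendar-like month (30.44
days), keeping the latest measurement per eye and month.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import EnFaceMap, SurfaceSet

DAYS_PER_MONTH = 30.44


@dataclass
class AnnulusSpec:
    """Circumpapillary evaluation annulus around the ONH center."""

    center: tuple[float, float]          # (x, y) px
    inner_radius_px: float = 125.0
    outer_radius_px: float = 225.0
    min_coverage: float = 0.75
    pixel_size_um: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius_px < self.outer_radius_px:
            raise ValueError("need 0 < inner radius < outer radius")
        if not 0 < self.min_coverage <= 1:
            raise ValueError("coverage minimum must lie in (0, 1]")


@dataclass
class SeedAnnotations:
    """Manually placed seed points of one acquisition."""

    onh: tuple[float, float]                       # (x, y)
    lesions: list[tuple[float, float, float]]      # (z, x, y)
    deposits: list[tuple[float, float, float]]     # (z, x, y)


def annulus_pixel_count(spec: AnnulusSpec) -> int:
    """Number of integer pixel centers with inner ≤ d < outer from the center."""
    cx, cy = spec.center
    r = int(math.ceil(spec.outer_radius_px)) + 1
    xs = np.arange(math.floor(cx) - r, math.ceil(cx) + r + 1)
    ys = np.arange(math.floor(cy) - r, math.ceil(cy) + r + 1)
    d = np.hypot(xs[:, None] - cx, ys[None, :] - cy)
    return int(((d >= spec.inner_radius_px) & (d < spec.outer_radius_px)).sum())


def annulus_mean_thickness(
    enface: EnFaceMap, spec: AnnulusSpec
) -> tuple[float | None, str]:
    """Mean map value over the annulus, or ``(None, reason)`` when undefined.

    Annulus pixels outside the acquired field of view count as uncovered, so
    an off-center ONH can push the coverage below the 75% minimum.
    """
    cx, cy = spec.center
    nx, ny = enface.values.shape
    r = int(math.ceil(spec.outer_radius_px)) + 1
    xs = np.arange(math.floor(cx) - r, math.ceil(cx) + r + 1)
    ys = np.arange(math.floor(cy) - r, math.ceil(cy) + r + 1)
    d = np.hypot(xs[:, None] - cx, ys[None, :] - cy)
    in_ring = (d >= spec.inner_radius_px) & (d < spec.outer_radius_px)
    total = int(in_ring.sum())
    inside = (
        (xs[:, None] >= 0) & (xs[:, None] < nx)
        & (ys[None, :] >= 0) & (ys[None, :] < ny)
    )
    ring_inside = in_ring & inside
    if not ring_inside.any():
        return None, "annulus fully outside the acquired map"
    xi = np.broadcast_to(xs[:, None], d.shape)[ring_inside].astype(int)
    yi = np.broadcast_to(ys[None, :], d.shape)[ring_inside].astype(int)
    covered = enface.mask[xi, yi] & np.isfinite(enface.values[xi, yi])
    coverage = covered.sum() / total
    if coverage < spec.min_coverage:
        return None, (
            f"coverage {coverage:.2f} below minimum {spec.min_coverage:.2f}"
        )
    return float(enface.values[xi[covered], yi[covered]].mean()), "ok"


def lesion_spacing_stats(
    points: list[tuple[float, float]], pixel_size_um: float = 2.0
) -> tuple[float, float]:
    """Mean pairwise and mean nearest-neighbour distance (µm) of lesion seeds."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("spacing statistics need at least two lesions")
    d = pdist(pts) * pixel_size_um
    mean_pairwise = float(d.mean())
    dm = squareform(d)
    np.fill_diagonal(dm, np.inf)
    mean_nn = float(dm.min(axis=1).mean())
    return mean_pairwise, mean_nn


def deposit_depth_histogram(
    deposits: list[tuple[float, float, float]],
    surfaces: SurfaceSet,
    bins: int = 20,
) -> np.ndarray:
    """Relative histogram of normalized deposit depths in ILM..RPE slabs.

    Depth fraction ``f = (z − ILM)/(RPE − ILM)`` is evaluated at the
    deposit's own (x, y) column; bin index ``floor(f·bins)`` with ``f = 1``
    assigned to the last (posterior-most) bin.  Index 0 of the returned array
    is the ILM-side slab.  Deposits outside the band are clamped with a
    warning; an empty input yields an all-zero histogram.
    """
    hist = np.zeros(bins)
    if not deposits:
        return hist
    ilm, rpe = surfaces["ilm"], surfaces["rpe"]
    nx, ny = ilm.shape
    for (z, x, y) in deposits:
        ix = int(np.clip(round(x), 0, nx - 1))
        iy = int(np.clip(round(y), 0, ny - 1))
        f = (z - ilm[ix, iy]) / (rpe[ix, iy] - ilm[ix, iy])
        if f < 0 or f > 1:
            warnings.warn(
                f"deposit at (z={z}, x={x}, y={y}) outside ILM..RPE; clamped"
            )
            f = min(max(f, 0.0), 1.0)
        idx = min(int(np.floor(f * bins)), bins - 1)
        hist[idx] += 1
    return hist / hist.sum()


def month_bin(postnatal_day: float) -> int:
    """Calendar-like month bin, months of 30.44 days; P1..P30 → month 1."""
    return int(math.ceil(postnatal_day / DAYS_PER_MONTH))


def cluster_monthly(
    records: pd.DataFrame, metrics: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly clustering of longitudinal records.

    ``records`` needs columns ``mouse``, ``eye``, ``postnatal_day`` plus
    metric columns.  Each (mouse, eye) is one observation; when an eye has
    several measurements within a month, the latest is kept.  Returns the
    per-(eye, month) table and the per-month summary (eye count, mean and
    sample σ per metric; σ is NaN for a single eye).
    """
    df = records.copy()
    if metrics is None:
        metrics = [
            c for c in df.columns
            if c not in ("mouse", "eye", "postnatal_day", "month", "acquisition_id",
                         "quality")
            and pd.api.types.is_numeric_dtype(df[c])
        ]
    df["month"] = df["postnatal_day"].map(month_bin)
    latest = (
        df.sort_values("postnatal_day")
        .groupby(["mouse", "eye", "month"], as_index=False)
        .last()
    )
    rows = []
    for month, grp in latest.groupby("month"):
        row = {"month": month, "n_eyes": len(grp)}
        for mcol in metrics:
            vals = grp[mcol].dropna()
            row[f"{mcol}_total"] = vals.sum()
            row[f"{mcol}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{mcol}_sd"] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows.append(row)
    summary = pd.DataFrame(rows).sort_values("month").reset_index(drop=True)
    return latest, summary
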