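"""Graph-based retinal layer segmentation.

Each pixel of a B-scan is a node; a boundary is the minimum-cost
left-to-right path through a cost image derived from the signed axial
gradient (low cost along edges of the requested polarity), with the vertical
step between adjacent columns limited.  The shortest path is computed by
dynamic programming over the left-to-right DAG, which is exactly the
single-source shortest path on this graph.  Layers are found iteratively —
ILM and RPE first, then the remaining interfaces inside bands bounded by the
surfaces already found — followed by an across-B-scan 3D refinement that
removes outliers and re-enforces the anterior→posterior ordering.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, median_filter

from .core import SURFACE_NAMES, SurfaceSet
from .preprocess import PolySurface, fit_retina_surface

#: Edge polarity, gradient scale and smoothing of each boundary in standard
#: OCT reflectivity images.  High-dynamic-range transitions (vitreous→retina,
#: ONL→RPE, choroid→sclera) are detected on the log-scaled image where their
#: contrast dwarfs any intraretinal structure; the weaker intraretinal
#: interfaces separate best on the linear scale and benefit from a larger
#: smoothing kernel against speckle.
BOUNDARY_RULES = {
    "ilm": ("dark_to_bright", "log", (2.0, 5.0)),
    "ipl_inl": ("bright_to_dark", "linear", (4.0, 9.0)),
    "inl_opl": ("dark_to_bright", "linear", (4.0, 9.0)),
    "opl_onl": ("bright_to_dark", "linear", (4.0, 9.0)),
    "rpe": ("dark_to_bright", "log", (2.0, 5.0)),
    "ch": ("bright_to_dark", "log", (2.0, 5.0)),
}


class InfeasibleBandError(ValueError):
    """The search band and slope constraint admit no path."""


def _signed_axial_gradient(
    bscan: np.ndarray,
    polarity: str,
    smooth_sigma: tuple[float, float],
    scale: str,
) -> np.ndarray:
    """Axial backward difference, signed for the polarity, optionally on the
    log-scaled image."""
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    img = np.asarray(bscan, dtype=float)
    if scale == "log":
        positive = img[img > 0]
        floor = 1e-4 * positive.mean() if positive.size else 1.0
        img = np.log10(np.maximum(img, floor))
    elif scale != "linear":
        raise ValueError(f"unknown gradient scale {scale!r}")
    if any(s > 0 for s in smooth_sigma):
        img = gaussian_filter(img, sigma=smooth_sigma, mode="nearest")
    grad = np.empty_like(img)
    grad[1:] = img[1:] - img[:-1]
    grad[0] = 0.0
    if polarity == "bright_to_dark":
        grad = -grad
    return grad


def boundary_cost(
    bscan: np.ndarray,
    polarity: str,
    smooth_sigma: tuple[float, float] = (1.0, 2.0),
    eps: float = 1e-3,
    scale: str = "linear",
) -> np.ndarray:
    """Cost image in [eps, 1], low along edges of the given polarity.

    The cost is ``1 − (1 − eps) · g⁺/max(g⁺)`` where ``g`` is the axial
    backward difference of the (lightly Gaussian-smoothed) B-scan, signed for
    the polarity: positive for ``dark_to_bright`` rises, negated for
    ``bright_to_dark`` falls; negative responses are clipped.
    """
    grad = _signed_axial_gradient(bscan, polarity, smooth_sigma, scale)
    gmax = grad.max()
    if gmax <= 0:
        return np.ones_like(grad)
    return 1.0 - (1.0 - eps) * np.clip(grad / gmax, 0.0, 1.0)


#: Predecessor offsets in tie-preference order: flat first, then smaller z.
def _offsets(max_step: int) -> list[int]:
    offs = [0]
    for s in range(1, max_step + 1):
        offs.extend([-s, s])
    return offs


def _dp_batch(
    cost: np.ndarray, max_step: int
) -> tuple[np.ndarray, np.ndarray]:
    """Batched DP over (nz, nx, nB) cost; returns paths (nx, nB) and totals.

    Infeasible nodes carry infinite cost.  Ties are broken toward the
    flattest step and then the smallest z, so a constant cost image yields
    the flat path at z = 0.
    """
    nz, nx, nb = cost.shape
    offs = _offsets(max_step)
    ptr = np.zeros((nz, nx, nb), dtype=np.int8)
    dist = cost[:, 0, :].copy()
    dists = [dist]
    for ix in range(1, nx):
        cand = np.full((len(offs), nz, nb), np.inf)
        for k, off in enumerate(offs):
            # predecessor z' = z + off in the previous column
            if off == 0:
                cand[k] = dist
            elif off > 0:
                cand[k, : nz - off] = dist[off:]
            else:
                cand[k, -off:] = dist[:off]
        best = np.argmin(cand, axis=0)                  # first index wins ties
        ptr[:, ix, :] = best
        dist = cost[:, ix, :] + np.take_along_axis(cand, best[None], axis=0)[0]
        dists.append(dist)
    paths = np.zeros((nx, nb), dtype=int)
    total = np.empty(nb)
    offs_arr = np.array(offs)
    for ib in range(nb):
        if not np.isfinite(dist[:, ib]).any():
            raise InfeasibleBandError("no feasible path through the search band")
        zc = int(np.argmin(dist[:, ib]))                # smallest z on ties
        total[ib] = dist[zc, ib]
        for ix in range(nx - 1, -1, -1):
            paths[ix, ib] = zc
            if ix > 0:
                zc = zc + int(offs_arr[ptr[zc, ix, ib]])
    return paths, total


def segment_boundary(
    cost: np.ndarray,
    band: tuple[np.ndarray, np.ndarray] | None = None,
    max_step: int = 3,
) -> np.ndarray:
    """Minimum-cost left-to-right path z(x) through one cost image.

    ``band`` optionally restricts each column x to ``z_min(x) ≤ z < z_max(x)``
    (scalars broadcast).  Raises :class:`InfeasibleBandError` when the band
    and slope constraint admit no path.
    """
    cost = np.asarray(cost, dtype=float)
    nz, nx = cost.shape
    work = cost.copy()
    if band is not None:
        z_min = np.broadcast_to(np.asarray(band[0]), (nx,)).astype(int)
        z_max = np.broadcast_to(np.asarray(band[1]), (nx,)).astype(int)
        if np.any(np.clip(z_max, 0, nz) <= np.clip(z_min, 0, nz)):
            raise InfeasibleBandError("empty search band in at least one column")
        z = np.arange(nz)[:, None]
        work[(z < z_min[None, :]) | (z >= z_max[None, :])] = np.inf
    paths, _ = _dp_batch(work[:, :, None], max_step)
    return paths[:, 0]


def segment_all_layers(
    volume: np.ndarray,
    max_step: int = 3,
    ch_offset: int = 40,
    rpe_band: tuple[int, int] = (55, 15),
    margin: int = 5,
) -> SurfaceSet:
    """Segment all six boundaries of an averaged, flattened (z, x, y) volume.

    Search order and bands: ILM over the full depth; then the posterior CH
    boundary (the strongest bright→dark edge) at least ``ch_offset`` below
    the ILM; the anterior RPE inside a band ``rpe_band = (above, below)``
    pixels anterior to the CH — anchoring on the CH keeps bright intraretinal
    structures (vessels, lesions) out of the RPE search; finally the inner
    interfaces between the surfaces already found, separated by ``margin``
    pixels.  B-scans whose paths violate the anterior→posterior ordering are
    marked invalid for the affected surfaces.
    """
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("expected an averaged (z, x, y) volume")
    nz, nx, ny = vol.shape
    vol = np.nan_to_num(vol, nan=0.0)

    grads = {}
    for pol, scale, sigma in set(BOUNDARY_RULES.values()):
        g = np.empty_like(vol)
        for iy in range(ny):
            g[:, :, iy] = _signed_axial_gradient(vol[:, :, iy], pol, sigma, scale)
        grads[(pol, scale, sigma)] = g

    eps = 1e-3

    def run(name, z_min, z_max):
        grad = grads[BOUNDARY_RULES[name]]
        z = np.arange(nz)[:, None, None]
        zmin = np.clip(np.broadcast_to(np.asarray(z_min), (nx, ny)), 0, nz - 1)
        zmax = np.clip(np.broadcast_to(np.asarray(z_max), (nx, ny)), 1, nz)
        # a collapsed band degenerates to riding its anterior limit
        zmax = np.maximum(zmax, zmin + 1)
        in_band = (z >= zmin[None]) & (z < zmax[None])
        work = np.where(in_band, grad, 0.0)
        # per-column normalization over the band only, so a strong edge
        # elsewhere in the image cannot deflate this boundary's contrast
        gmax = work.max(axis=0, keepdims=True)
        gmax = np.where(gmax <= 0, 1.0, gmax)
        work = 1.0 - (1.0 - eps) * np.clip(work / gmax, 0.0, 1.0)
        work[~in_band] = np.inf
        paths, _ = _dp_batch(work, max_step)
        return paths.astype(float)                      # (nx, ny)

    ilm = run("ilm", 0, nz)
    ch = run("ch", ilm + ch_offset, nz)
    rpe = run("rpe", ch - rpe_band[0], ch - rpe_band[1])
    ipl_inl = run("ipl_inl", ilm + margin, rpe - margin)
    opl_onl = run("opl_onl", ipl_inl + margin, rpe - margin)
    inl_opl = run("inl_opl", ipl_inl + margin, opl_onl - margin + 1)

    # the backward difference localizes an edge between two pixels: report
    # boundary depths at the half-pixel edge position
    surfaces = SurfaceSet(
        surfaces={
            "ilm": ilm - 0.5, "ipl_inl": ipl_inl - 0.5,
            "inl_opl": inl_opl - 0.5, "opl_onl": opl_onl - 0.5,
            "rpe": rpe - 0.5, "ch": ch - 0.5,
        }
    )
    bad = surfaces.ordering_violations()
    if bad.any():
        bad_scans = bad.any(axis=0)
        for name in SURFACE_NAMES:
            surfaces.valid[name][:, bad_scans] = ~bad[:, bad_scans]
    return surfaces


def refine_3d(
    surfaces: SurfaceSet,
    window: int = 5,
    max_dev: float = 10.0,
) -> SurfaceSet:
    """Across-B-scan 3D refinement of the per-B-scan segmentation.

    Each surface is median-filtered across the slow axis (``window`` B-scans);
    points deviating more than ``max_dev`` pixels are replaced by the filtered
    value and marked in ``interpolated``.  Ordering is re-enforced by
    projecting onto the feasible (monotone) set.
    """
    refined: dict[str, np.ndarray] = {}
    interp: dict[str, np.ndarray] = {}
    for name in SURFACE_NAMES:
        surf = surfaces[name]
        filt = median_filter(surf, size=(1, window), mode="nearest")
        dev = np.abs(surf - filt)
        out = np.where(dev > max_dev, filt, surf)
        refined[name] = out
        interp[name] = dev > max_dev
    prev = None
    for name in SURFACE_NAMES:
        if prev is not None:
            refined[name] = np.maximum(refined[name], refined[prev])
        prev = name
    return SurfaceSet(
        surfaces=refined,
        valid={name: surfaces.valid[name].copy() for name in SURFACE_NAMES},
        interpolated=interp,
    )


def fit_reference_surface(
    rpe: np.ndarray, ch: np.ndarray, degree: int = 2
) -> np.ndarray:
    """Robust polynomial reference plane between the RPE and the CH.

    Fits the midline (RPE + CH)/2 with a low-order polynomial surface (with
    outlier down-weighting, so lesions and large choroidal vessels do not
    drag the fit) and clamps the result between the two surfaces.
    """
    rpe = np.asarray(rpe, dtype=float)
    ch = np.asarray(ch, dtype=float)
    valid = np.isfinite(rpe) & np.isfinite(ch)
    if valid.mean() < 0.5:
        raise ValueError("reference fit needs both surfaces on ≥50% of the grid")
    mid = np.where(valid, (rpe + ch) / 2.0, np.nan)
    surface: PolySurface = fit_retina_surface(mid, degree=degree)
    ref = surface.grid(*rpe.shape)
    return np.clip(ref, rpe, ch)
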