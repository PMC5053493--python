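"""Contrast-specific en-face projections for lesion screening.

Four maps summarize a processed acquisition: the reflectivity variance of a
50-pixel slab above the RPE–CH reference (lesions raise the axial intensity
variance), total/inner/outer retinal thickness from the segmented surfaces,
the minimum DOPU between the ILM and the RPE (intraretinal melanin deposits
depress it), and a depth-color-coded angiography maximum projection between
the ILM and the RPE.
"""

from __future__ import annotations

import numpy as np

from .core import EnFaceMap, SurfaceSet
from .octa import AngioVolume
from .pscontrast import DopuVolume


def _column_gather(volume: np.ndarray, z_start: np.ndarray, depth: int) -> np.ndarray:
    """Stack of ``depth`` voxels starting at z_start(x, y): (depth, nx, ny)."""
    nz, nx, ny = volume.shape
    offs = np.arange(depth)[:, None, None]
    idx = np.clip(z_start[None, :, :].astype(int) + offs, 0, nz - 1)
    ix = np.arange(nx)[None, :, None]
    iy = np.arange(ny)[None, None, :]
    return volume[idx, ix, iy]


def outer_retina_variance_map(
    reflectivity: np.ndarray,
    reference_surface: np.ndarray,
    slab_px: int = 50,
    pixel_size_um: float = 2.0,
) -> EnFaceMap:
    """Axial intensity variance in the slab above the RPE–CH reference fit.

    Per (x, y), the variance of the averaged reflectivity over the
    ``slab_px`` voxels immediately anterior to the reference surface.  Slabs
    truncated by the volume top are flagged in the mask.
    """
    vol = np.asarray(reflectivity, dtype=float)
    ref = np.asarray(reference_surface, dtype=float)
    start = np.rint(ref).astype(int) - slab_px
    truncated = start < 0
    slab = _column_gather(vol, np.maximum(start, 0), slab_px)
    values = np.nanvar(slab, axis=0)
    mask = np.isfinite(values) & ~truncated & np.isfinite(ref)
    values = np.where(np.isfinite(values), values, np.nan)
    return EnFaceMap(values=values, mask=mask, units="a.u.^2",
                     pixel_size_um=pixel_size_um)


def thickness_map(
    surfaces: SurfaceSet,
    which: str = "TR",
    pixel_size_axial_um: float = 2.0,
    pixel_size_lateral_um: float = 2.0,
) -> EnFaceMap:
    """Retinal thickness in µm: TR (ILM→RPE), IR (ILM→OPL/ONL), OR (TR − IR)."""
    which = which.upper()
    ilm, opl, rpe = surfaces["ilm"], surfaces["opl_onl"], surfaces["rpe"]
    if which == "TR":
        px = rpe - ilm
        valid = surfaces.joint_valid(("ilm", "rpe"))
    elif which == "IR":
        px = opl - ilm
        valid = surfaces.joint_valid(("ilm", "opl_onl"))
    elif which == "OR":
        px = (rpe - ilm) - (opl - ilm)
        valid = surfaces.joint_valid(("ilm", "opl_onl", "rpe"))
    else:
        raise ValueError(f"unknown thickness kind {which!r}; use TR, IR or OR")
    values = np.where(valid, px * pixel_size_axial_um, np.nan)
    return EnFaceMap(values=values, mask=valid, units="um",
                     pixel_size_um=pixel_size_lateral_um)


def min_dopu_map(
    dopu: DopuVolume,
    surfaces: SurfaceSet,
    rpe_margin: int = 5,
    pixel_size_um: float = 2.0,
) -> EnFaceMap:
    """Minimum valid DOPU between the ILM and a margin anterior to the RPE.

    The band excludes the RPE itself (by ``rpe_margin`` pixels) so the
    physiologic RPE depolarization does not mask intraretinal deposits.
    Columns with no valid DOPU value are missing.
    """
    vol = dopu.dopu
    nz = vol.shape[0]
    z = np.arange(nz)[:, None, None]
    band = (z >= surfaces["ilm"][None]) & (z < (surfaces["rpe"] - rpe_margin)[None])
    masked = np.where(band & np.isfinite(vol), vol, np.inf)
    values = masked.min(axis=0)
    missing = ~np.isfinite(values)
    values[missing] = np.nan
    return EnFaceMap(values=values, mask=~missing, units="DOPU",
                     pixel_size_um=pixel_size_um)


def depth_coded_angio_map(
    angio: AngioVolume,
    surfaces: SurfaceSet,
    pixel_size_um: float = 2.0,
) -> EnFaceMap:
    """Maximum angiography signal between ILM and RPE with its depth fraction.

    The depth fraction is 0 at the ILM and 1 at the RPE; rendering maps it to
    a green→red color scale.  Columns without signal get value 0 and an
    undefined depth.
    """
    vol = np.asarray(angio.signal, dtype=float)
    nz = vol.shape[0]
    ilm, rpe = surfaces["ilm"], surfaces["rpe"]
    z = np.arange(nz)[:, None, None]
    band = (z >= ilm[None]) & (z <= rpe[None])
    masked = np.where(band & np.isfinite(vol), vol, -np.inf)
    zmax = masked.argmax(axis=0)
    vmax = np.take_along_axis(masked, zmax[None], axis=0)[0]
    has_signal = np.isfinite(vmax) & (vmax > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (zmax - ilm) / (rpe - ilm)
    depth = np.where(has_signal, np.clip(frac, 0.0, 1.0), np.nan)
    values = np.where(np.isfinite(vmax) & (vmax > -np.inf), np.maximum(vmax, 0.0), 0.0)
    values = np.where(vmax == -np.inf, 0.0, values)
    mask = band.any(axis=0) & np.isfinite(vol).any(axis=0)
    return EnFaceMap(values=values, mask=mask, units="a.u.",
                     pixel_size_um=pixel_size_um, depth=depth)


def render_depth_coded(enface: EnFaceMap) -> np.ndarray:
    """8-bit RGB rendering of a depth-coded map (green at ILM → red at RPE)."""
    vals = enface.values
    vmax = np.nanmax(vals) if np.isfinite(vals).any() else 1.0
    brightness = np.clip(vals / vmax if vmax > 0 else vals, 0.0, 1.0)
    frac = np.nan_to_num(enface.depth if enface.depth is not None else 0.5 * np.ones_like(vals))
    rgb = np.zeros(vals.shape + (3,))
    rgb[..., 0] = frac                     # red grows toward the RPE
    rgb[..., 1] = 1.0 - 0.7 * frac         # green at the ILM
    rgb *= brightness[..., None]
    return (255 * rgb).astype(np.uint8)
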