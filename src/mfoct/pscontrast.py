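"""Stokes vectors and degree-of-polarization-uniformity (DOPU).

DOPU measures the uniformity of the polarization state in a small
spatio-temporal neighbourhood: the per-pixel normalized Stokes components
(q, u, v) = (Q, U, V)/I of sufficiently bright pixels are averaged inside a
``z × x × t`` window (default 3 × 9 × 5) and the magnitude of that mean is
the DOPU value, 1 for polarization-preserving tissue and → 0 for
depolarizing tissue such as melanin.  A window is evaluated only when more
than 80% of its pixels exceed the vitreous background threshold
``mean + 3·σ``; otherwise the voxel is marked invalid (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter

from .core import DualChannelVolume
from .preprocess import ReflectivityVolume


@dataclass
class StokesVolume:
    """Per-voxel Stokes components on the (z, x, y, t) grid."""

    i: np.ndarray
    q: np.ndarray
    u: np.ndarray
    v: np.ndarray

    @property
    def shape(self):
        return self.i.shape

    def normalized(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(q, u, v)/I where I > 0, zero elsewhere."""
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(self.i > 0, 1.0 / self.i, 0.0)
        return self.q * inv, self.u * inv, self.v * inv


@dataclass
class BackgroundStats:
    """Vitreous background intensity statistics and derived threshold."""

    mean: float
    sd: float
    region: str = "vitreous slab above ILM"

    @property
    def threshold(self) -> float:
        return self.mean + 3.0 * self.sd


@dataclass
class DopuVolume:
    """DOPU per voxel, one B-scan per repeated B-scan set; NaN = invalid."""

    dopu: np.ndarray                      # (z, x, y)
    window: tuple[int, int, int] = (3, 9, 5)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.dopu.shape


def compute_stokes(volume: DualChannelVolume) -> StokesVolume:
    """Stokes vector of each sample point from the two polarization channels.

    Convention: ``I = |S_H|² + |S_V|²``, ``Q = |S_H|² − |S_V|²``,
    ``U = 2·Re(S_H·S_V*)``, ``V = 2·Im(S_H·S_V*)``.  DOPU is independent of
    the sign conventions.
    """
    sh, sv = volume.sh, volume.sv
    ah2 = (sh.real**2 + sh.imag**2).astype(np.float32)
    av2 = (sv.real**2 + sv.imag**2).astype(np.float32)
    cross = sh * np.conj(sv)
    return StokesVolume(
        i=ah2 + av2,
        q=ah2 - av2,
        u=(2.0 * cross.real).astype(np.float32),
        v=(2.0 * cross.imag).astype(np.float32),
    )


def estimate_background(
    reflectivity: ReflectivityVolume | np.ndarray,
    ilm_surface: np.ndarray,
    margin: int = 20,
) -> BackgroundStats:
    """Mean and sample σ of the intensity in the vitreous above the ILM.

    Samples voxels at least ``margin`` pixels anterior to the (provisional)
    ILM surface, over all lateral positions and repeats.
    """
    I = reflectivity.intensity if isinstance(reflectivity, ReflectivityVolume) else reflectivity
    I = np.asarray(I)
    if I.ndim == 3:
        I = I[..., None]
    nz, nx, ny, nt = I.shape
    ilm = np.broadcast_to(np.asarray(ilm_surface, dtype=float), (nx, ny))
    z = np.arange(nz)[:, None, None, None]
    mask = z < (ilm[None, :, :, None] - margin)
    vals = I[np.broadcast_to(mask, I.shape)]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty vitreous region: ILM too close to the volume top")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return BackgroundStats(mean=mean, sd=sd)


def compute_dopu(
    stokes: StokesVolume,
    background: BackgroundStats,
    window: tuple[int, int, int] = (3, 9, 5),
    min_fraction: float = 0.8,
) -> DopuVolume:
    """Windowed DOPU on repeat-resolved Stokes data.

    The window spans ``window = (n_z, n_x, n_t)`` pixels of one repeated
    B-scan set (computed before any repeat averaging).  At volume edges the
    window is truncated and the >80% intensity rule applies to the truncated
    size.  Output is one DOPU B-scan per set, clipped to [0, 1].
    """
    wz, wx, wt = window
    nz, nx, ny, nt = stokes.shape
    if wz > nz or wx > nx or wt > nt:
        raise ValueError(f"window {window} larger than volume {(nz, nx, nt)}")
    qn, un, vn = stokes.normalized()
    bright = (stokes.i > background.threshold).astype(np.float32)

    size = (wz, wx, 1, wt)

    def wsum(arr):
        return uniform_filter(arr, size=size, mode="constant", cval=0.0)

    # uniform_filter returns window means over the full (zero-padded) window;
    # the common factor wz*wx*wt cancels in every ratio below.
    count = wsum(bright)
    full = wsum(np.ones_like(bright))
    with np.errstate(divide="ignore", invalid="ignore"):
        mq = wsum(qn * bright) / count
        mu = wsum(un * bright) / count
        mv = wsum(vn * bright) / count
    dopu = np.sqrt(mq**2 + mu**2 + mv**2)
    dopu = np.clip(dopu, 0.0, 1.0)
    valid = count > min_fraction * full
    dopu[~valid] = np.nan

    t_center = nt // 2
    return DopuVolume(
        dopu=dopu[:, :, :, t_center].astype(np.float32),
        window=window,
        meta={"threshold": background.threshold, "min_fraction": min_fraction},
    )
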