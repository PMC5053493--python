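"""OCT angiography by complex differencing of repeated B-scans.

The motion contrast of a B-scan set is the averaged magnitude of the complex
differences between consecutive repeats, after (i) removal of repeats with
severe residual motion and (ii) compensation of the bulk phase — a single
global phase offset per repeat pair caused by sub-wavelength axial bulk
motion.  With two detection channels the difference magnitude is taken over
the channel pair, ``|ΔC| = sqrt(|ΔS_V|² + |ΔS_H|²)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DualChannelVolume


@dataclass
class AngioVolume:
    """Non-negative flow signal (z, x, y); NaN columns mark missing B-scans."""

    signal: np.ndarray
    retained: list[list[int]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self):
        return self.signal.shape


def compensate_bulk_phase(
    sv: np.ndarray, sh: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align the global phase of consecutive repeats of one B-scan set.

    ``sv``/``sh`` are (z, x, m) complex stacks of the retained repeats.  For
    each consecutive pair the offset ``φ̂ = arg Σ C_{i+1}·C_i*`` (summed over
    both channels and all pixels, with the earlier frame already aligned) is
    removed from the later frame, so every frame ends up aligned to the
    first.  Returns the aligned stacks and the recovered offsets, which are
    cumulative (frame i+1 relative to frame 0); consecutive pairwise offsets
    are their wrapped differences.
    """
    if sv.shape != sh.shape:
        raise ValueError("channel shapes differ")
    m = sv.shape[2]
    if m < 2:
        raise ValueError("bulk-phase compensation needs at least two repeats")
    sv = sv.copy()
    sh = sh.copy()
    phases = np.zeros(m - 1)
    for i in range(m - 1):
        inner = np.vdot(sv[:, :, i], sv[:, :, i + 1]) + np.vdot(
            sh[:, :, i], sh[:, :, i + 1]
        )
        if inner == 0:
            warnings.warn(f"zero-energy repeat pair ({i}, {i + 1}); phase skipped")
            continue
        phi = np.angle(inner)
        phases[i] = phi
        factor = np.exp(-1j * phi).astype(sv.dtype)
        sv[:, :, i + 1] *= factor
        sh[:, :, i + 1] *= factor
    return sv, sh, phases


def reject_severe_motion(
    amplitude: np.ndarray,
    max_shift: int = 5,
    min_corr: float = 0.5,
    search: int = 25,
) -> list[int]:
    """Indices of repeats without severe residual motion.

    ``amplitude`` is a (z, x, m) stack.  The axial shift of each repeat vs
    the set median frame is located by cross-correlating mean A-line
    profiles; a repeat is removed when that shift exceeds ``max_shift``
    pixels or when the normalized 2-D correlation of the (shift-aligned)
    amplitude image with the median frame falls below ``min_corr`` — the 2-D
    check catches repeats whose speckle is decorrelated even though their
    mean profile matches.
    """
    nz, nx, m = amplitude.shape
    median_frame = np.median(amplitude, axis=2)
    ref2d = median_frame - median_frame.mean()
    ref2d_norm = np.linalg.norm(ref2d)
    profile_ref = median_frame.mean(axis=1)
    profile_ref = profile_ref - profile_ref.mean()
    ref_norm = np.linalg.norm(profile_ref)
    retained = []
    lags = np.arange(-search, search + 1)
    for i in range(m):
        p = amplitude[:, :, i].mean(axis=1)
        p = p - p.mean()
        denom = np.linalg.norm(p) * ref_norm
        if denom == 0:
            continue
        scores = np.array(
            [np.dot(np.roll(p, -lag), profile_ref) for lag in lags]
        )
        lag = int(lags[int(np.argmax(scores))])
        if abs(lag) > max_shift:
            continue
        frame = np.roll(amplitude[:, :, i], -lag, axis=0)
        frame = frame - frame.mean()
        denom2d = np.linalg.norm(frame) * ref2d_norm
        if denom2d == 0:
            continue
        if float((frame * ref2d).sum()) / denom2d >= min_corr:
            retained.append(i)
    return retained


def compute_angio(sv: np.ndarray, sh: np.ndarray) -> np.ndarray:
    """Averaged magnitude of complex differences of consecutive repeats.

    ``signal(z, x) = 1/(m−1) · Σ_i sqrt(|ΔS_V|² + |ΔS_H|²)`` over the m−1
    consecutive pairs of the (z, x, m) stacks.
    """
    if sv.shape[2] < 2:
        raise ValueError("angiography needs at least two retained repeats")
    dv = np.diff(sv, axis=2)
    dh = np.diff(sh, axis=2)
    mag = np.sqrt(np.abs(dv) ** 2 + np.abs(dh) ** 2)
    return mag.mean(axis=2)


def compute_angio_volume(
    volume: DualChannelVolume,
    max_shift: int = 5,
    min_corr: float = 0.5,
) -> AngioVolume:
    """Full angiography volume: rejection, phase alignment, differencing.

    Operates on the motion-compensated, flattened volume; B-scans with fewer
    than two retained repeats are marked missing (NaN).
    """
    nz, nx, ny, nt = volume.shape
    signal = np.full((nz, nx, ny), np.nan, dtype=np.float32)
    retained_lists: list[list[int]] = []
    for iy in range(ny):
        sv = volume.sv[:, :, iy, :]
        sh = volume.sh[:, :, iy, :]
        amp = np.sqrt(np.abs(sv) ** 2 + np.abs(sh) ** 2)
        retained = reject_severe_motion(amp, max_shift=max_shift, min_corr=min_corr)
        retained_lists.append(retained)
        if len(retained) < 2:
            continue
        sv_r, sh_r, _ = compensate_bulk_phase(
            sv[:, :, retained], sh[:, :, retained]
        )
        signal[:, :, iy] = compute_angio(sv_r, sh_r)
    return AngioVolume(signal=signal, retained=retained_lists)
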