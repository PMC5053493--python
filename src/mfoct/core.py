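"""Core in-memory containers shared by all pipeline stages.

Axes convention throughout the package: volumes are indexed ``(z, x, y, t)``
with ``z`` the axial (depth) direction, ``x`` the fast scan direction within a
B-scan, ``y`` the slow scan direction (B-scan position) and ``t`` the repeat
index of the repeated B-scan protocol.  En-face maps are indexed ``(x, y)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boundary names, anterior to posterior.
SURFACE_NAMES = ("ilm", "ipl_inl", "inl_opl", "opl_onl", "rpe", "ch")


class FormatError(ValueError):
    """A file or object does not conform to the documented layout."""


@dataclass
class DualChannelVolume:
    """Complex tomogram of the two orthogonal polarization channels.

    ``sv`` and ``sh`` hold the vertically and horizontally polarized complex
    OCT signals :math:`S_V, S_H = A e^{j\\varphi}` on a ``(z, x, y, t)`` grid.
    """

    sv: np.ndarray
    sh: np.ndarray
    pixel_size_axial_um: float = 2.0
    pixel_size_lateral_um: float = 2.0
    bscan_period_s: float = 0.0075
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv)
        self.sh = np.asarray(self.sh)
        if self.sv.shape != self.sh.shape:
            raise ValueError(
                f"channel shapes differ: {self.sv.shape} vs {self.sh.shape}"
            )
        if self.sv.ndim != 4:
            raise ValueError(f"expected a (z, x, y, t) volume, got {self.sv.ndim}D")
        if not np.iscomplexobj(self.sv) or not np.iscomplexobj(self.sh):
            raise TypeError("channel data must be complex")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.sv.shape

    @property
    def n_repeats(self) -> int:
        return self.sv.shape[3]

    @property
    def angiography_available(self) -> bool:
        """Complex-difference angiography needs at least two repeats."""
        return self.n_repeats >= 2


@dataclass
class SurfaceSet:
    """Depth maps ``z(x, y)`` of the six retinal boundaries plus a reference.

    ``surfaces`` maps a name from :data:`SURFACE_NAMES` (and optionally
    ``"ref"``, the RPE–CH reference fit) to a float array of shape ``(nx, ny)``.
    ``valid`` marks pixels where the segmentation is trusted.
    """

    surfaces: dict[str, np.ndarray]
    valid: dict[str, np.ndarray] = field(default_factory=dict)
    interpolated: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {np.asarray(s).shape for s in self.surfaces.values()}
        if len(shapes) > 1:
            raise ValueError(f"surface grids differ in shape: {shapes}")
        for name, surf in self.surfaces.items():
            self.surfaces[name] = np.asarray(surf, dtype=float)
            if name not in self.valid:
                self.valid[name] = np.ones(self.surfaces[name].shape, dtype=bool)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.surfaces[name]

    def __contains__(self, name: str) -> bool:
        return name in self.surfaces

    @property
    def grid_shape(self) -> tuple[int, int]:
        return next(iter(self.surfaces.values())).shape

    def joint_valid(self, names=SURFACE_NAMES) -> np.ndarray:
        mask = np.ones(self.grid_shape, dtype=bool)
        for name in names:
            mask &= self.valid[name]
        return mask

    def ordering_violations(self, names=SURFACE_NAMES) -> np.ndarray:
        """Boolean (nx, ny) map of pixels violating the anterior→posterior order."""
        bad = np.zeros(self.grid_shape, dtype=bool)
        for a, b in zip(names[:-1], names[1:]):
            if a in self.surfaces and b in self.surfaces:
                bad |= self.surfaces[a] > self.surfaces[b]
        return bad


@dataclass
class EnFaceMap:
    """Scalar ``(x, y)`` en-face projection with a missing-data mask.

    For depth-coded angiography maps, ``depth`` holds the normalized depth
    fraction (0 at the ILM, 1 at the RPE) of the reported value.
    """

    values: np.ndarray
    mask: np.ndarray = None
    units: str = ""
    pixel_size_um: float = 2.0
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values")
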