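"""Synthetic dual-channel PS-OCT retina phantom with full ground truth.

The phantom emulates the statistical structure every downstream stage of the
pipeline assumes:

* fully developed speckle — per-voxel circular complex Gaussian fields whose
  amplitude follows a piecewise-constant layer reflectivity template, shared
  across repeats for static tissue and decorrelated for flow voxels;
* a polarization state that is constant within polarization-preserving tissue
  (one pure Stokes state per B-scan) and randomly scrambled inside the RPE–CH
  complex and inside spherical intraretinal melanin deposits;
* respiration-like axial motion: a ~1 Hz sinusoidal axial shift sampled at the
  B-scan period and applied per B-scan as an integer-pixel roll;
* a random global (bulk) phase per B-scan, as caused by sub-wavelength axial
  motion between repeats;
* hyperreflective lesions of the outer retina and vessel tubes whose speckle
  decorrelates between repeats (flow).

All randomness flows from a single :class:`numpy.random.Generator`, so an
identical ``(spec, seed)`` pair reproduces the volume bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import SURFACE_NAMES, DualChannelVolume, SurfaceSet

DAYS_PER_MONTH = 30.44

#: Relative reflectivity of each region of the piecewise-constant template.
DEFAULT_LAYER_REFLECTIVITY = {
    "vitreous": 0.01,
    "nfl_ipl": 1.3,   # ILM .. IPL/INL : bright inner retina
    "inl": 0.45,
    "opl": 0.85,
    "onl": 0.35,
    "rpe_ch": 1.4,    # anterior RPE .. posterior CH complex
    "sclera": 0.05,   # below the posterior CH boundary
}


class PhantomValidationError(ValueError):
    """The phantom specification violates one of its invariants."""


@dataclass
class Deposit:
    """Spherical depolarizing melanin deposit."""

    center: tuple[float, float, float]  # (z, x, y) px
    radius: float = 6.0                 # px
    dopu_target: float = 0.3            # expected DOPU inside the sphere
    reflectivity_gain: float = 1.5


@dataclass
class Lesion:
    """Hyperreflective subretinal lesion with optional ONL disruption.

    Modeled as a saturated bright sphere (reflectivity well above the RPE-CH
    complex, as neovascular lesions appear in reflectivity B-scans)."""

    center: tuple[float, float, float]  # (z, x, y) px
    radius: float = 8.0
    reflectivity: float = 5.0           # absolute
    onl_disruption_px: float = 0.0      # depth of reduced-reflectivity ONL above


@dataclass
class Vessel:
    """Flow tube running along the slow axis at fixed normalized depth.

    The tube axis is parallel to y (it crosses every B-scan as a small disc
    in the (z, x) plane, like a real vessel crossing the raster)."""

    depth_fraction: float               # 0 at ILM, 1 at anterior RPE
    x: float                            # fast-axis position (px)
    radius: float = 3.0
    reflectivity: float = 2.0           # absolute (blood scattering)


@dataclass
class PhantomSpec:
    """Scene and acquisition parameters of the synthetic retina.

    Defaults mirror the emulated acquisition: 512 A-scans per B-scan, 400
    B-scan positions, 5 repeats, 1536 axial pixels at 2 µm/px, ~1 Hz axial
    respiratory motion of 30 px amplitude.  ``boundaries`` holds the base
    depth (px) of each surface in :data:`~mfoct.core.SURFACE_NAMES`; a gentle
    parabolic bowl of ``curvature_px`` sag is added to all of them.
    """

    dims: tuple[int, int, int, int] = (1536, 512, 400, 5)
    pixel_size_axial_um: float = 2.0
    pixel_size_lateral_um: float = 2.0
    boundaries: dict[str, float] = None
    curvature_px: float = 4.0
    layer_reflectivity: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_REFLECTIVITY)
    )
    snr_db: float = 20.0
    rpe_scramble: float = 0.85
    deposits: list[Deposit] = field(default_factory=list)
    lesions: list[Lesion] = field(default_factory=list)
    vessels: list[Vessel] = field(default_factory=list)
    flow_decorrelation: float = 1.0
    motion_amplitude_px: float = 30.0
    motion_freq_hz: float = 1.0
    bscan_period_s: float = 0.0075
    bulk_phase: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.boundaries is None:
            self.boundaries = default_boundaries(self.dims[0])

    def validate(self) -> None:
        if len(self.dims) != 4 or any(int(d) <= 0 for d in self.dims):
            raise PhantomValidationError(f"dims must be four positive ints: {self.dims}")
        depths = [self.boundaries[name] for name in SURFACE_NAMES]
        if any(b >= a for b, a in zip(depths[:-1], depths[1:])):
            raise PhantomValidationError(
                "boundary depths must increase strictly anterior→posterior: "
                f"{dict(zip(SURFACE_NAMES, depths))}"
            )
        if depths[-1] + self.curvature_px >= self.dims[0]:
            raise PhantomValidationError("posterior CH boundary exceeds volume depth")
        for dep in self.deposits:
            if not 0.0 <= dep.dopu_target <= 1.0:
                raise PhantomValidationError(
                    f"deposit DOPU target {dep.dopu_target} outside [0, 1]"
                )
        if not 0.0 <= self.rpe_scramble <= 1.0:
            raise PhantomValidationError("rpe_scramble must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Everything the generator knows about the scene it drew."""

    surfaces: SurfaceSet
    flow_mask: np.ndarray           # bool (z, x, y)
    deposit_mask: np.ndarray        # bool (z, x, y)
    lesion_mask: np.ndarray         # bool (z, x, y)
    lesion_coords: list[tuple[float, float, float]]
    deposit_coords: list[tuple[float, float, float]]
    shifts: np.ndarray              # int (ny, nt) applied axial shift per B-scan
    bulk_phases: np.ndarray         # float (ny, nt)
    stokes: np.ndarray              # float32 (z, x, y, 3) true normalized (q, u, v)
    template: np.ndarray            # float32 (z, x, y) noise-free reflectivity

    @property
    def or_thickness_um(self) -> float:
        """Mean programmed outer-retina (OPL/ONL→RPE) thickness in µm."""
        d = self.surfaces["rpe"] - self.surfaces["opl_onl"]
        return float(d.mean()) * self._axial_scale

    _axial_scale: float = 2.0


def default_boundaries(n_z: int) -> dict[str, float]:
    """Flat base depths scaled to a mouse retina at 2 µm/px."""
    ilm = max(40.0, round(n_z * 0.25))
    return {
        "ilm": ilm,
        "ipl_inl": ilm + 25.0,
        "inl_opl": ilm + 40.0,
        "opl_onl": ilm + 60.0,
        "rpe": ilm + 105.0,
        "ch": ilm + 150.0,
    }


def default_scene(
    dims: tuple[int, int, int, int] = (256, 128, 64, 5), **kwargs
) -> PhantomSpec:
    """A reduced-scale spec with vessels, deposits and a lesion placed
    proportionally to the field of view — the scene used by the analysis
    drivers and most tests."""
    nz, nx, ny, nt = dims
    # keep the full protocol's ~15 s duration (≈15 respiratory cycles) so the
    # motion statistics stay representative at reduced B-scan counts
    kwargs.setdefault("bscan_period_s", 15.0 / (ny * nt))
    spec = PhantomSpec(dims=dims, **kwargs)
    b = spec.boundaries
    spec.vessels = [
        Vessel(depth_fraction=0.1, x=nx * 0.3, radius=3.0, reflectivity=2.0),
        Vessel(depth_fraction=0.1, x=nx * 0.7, radius=3.0, reflectivity=2.0),
        Vessel(depth_fraction=0.47, x=nx * 0.45, radius=1.5, reflectivity=0.85),
        Vessel(depth_fraction=0.9, x=nx * 0.6, radius=2.0, reflectivity=2.0),
    ]
    dep_z = b["opl_onl"] + 0.7 * (b["rpe"] - b["opl_onl"])
    spec.deposits = [
        Deposit(center=(dep_z, nx * 0.25, ny * 0.25), radius=7.0, dopu_target=0.3),
        Deposit(center=(dep_z, nx * 0.7, ny * 0.6), radius=7.0, dopu_target=0.3),
    ]
    spec.lesions = [
        Lesion(center=(b["rpe"] - 8.0, nx * 0.5, ny * 0.5), radius=7.0,
               reflectivity=5.0)
    ]
    return spec


def control_scene(
    dims: tuple[int, int, int, int] = (256, 128, 64, 5), **kwargs
) -> PhantomSpec:
    """A healthy-retina spec: physiological vascular plexuses only, no
    lesions, deposits or outer-retinal sprouts — the recovery testbed
    (mirrors the control animals)."""
    nz, nx, ny, nt = dims
    kwargs.setdefault("bscan_period_s", 15.0 / (ny * nt))
    spec = PhantomSpec(dims=dims, **kwargs)
    spec.vessels = [
        Vessel(depth_fraction=0.1, x=nx * 0.3, radius=3.0, reflectivity=2.0),
        Vessel(depth_fraction=0.1, x=nx * 0.7, radius=3.0, reflectivity=2.0),
        Vessel(depth_fraction=0.47, x=nx * 0.5, radius=1.5, reflectivity=0.85),
    ]
    return spec


def _bowl(nx: int, ny: int, sag: float) -> np.ndarray:
    """Parabolic depth offset (0 at center, ``sag`` at the field corner)."""
    x = np.linspace(-1.0, 1.0, nx)[:, None]
    y = np.linspace(-1.0, 1.0, ny)[None, :]
    return sag * (x**2 + y**2) / 2.0


def _jones_from_stokes(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit Jones pair (J_H, J_V) realizing a unit Stokes direction (q, u, v).

    Convention (matching :func:`mfoct.pscontrast.compute_stokes`):
    ``Q = |H|^2 - |V|^2``, ``U = 2 Re(H V*)``, ``V = 2 Im(H V*)``.
    """
    q, u, v = direction[..., 0], direction[..., 1], direction[..., 2]
    a = np.sqrt(np.clip((1.0 + q) / 2.0, 0.0, 1.0))
    b = np.sqrt(np.clip((1.0 - q) / 2.0, 0.0, 1.0))
    psi = np.arctan2(v, u)
    return a.astype(np.complex64), (b * np.exp(-1j * psi)).astype(np.complex64)


def _random_unit_vectors(rng: np.random.Generator, shape) -> np.ndarray:
    vec = rng.standard_normal(shape + (3,), dtype=np.float32)
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    norm[norm == 0] = 1.0
    return vec / norm


def _complex_gaussian(rng: np.random.Generator, shape) -> np.ndarray:
    """Circular complex Gaussian with E|g|^2 = 1."""
    re = rng.standard_normal(shape, dtype=np.float32)
    im = rng.standard_normal(shape, dtype=np.float32)
    return ((re + 1j * im) / np.sqrt(2.0)).astype(np.complex64)


def build_surfaces(spec: PhantomSpec) -> SurfaceSet:
    nz, nx, ny, _ = spec.dims
    bowl = _bowl(nx, ny, spec.curvature_px)
    return SurfaceSet(
        surfaces={name: spec.boundaries[name] + bowl for name in SURFACE_NAMES}
    )


def build_template(spec: PhantomSpec, surfaces: SurfaceSet) -> np.ndarray:
    """Noise-free reflectivity template (z, x, y), lesions applied."""
    nz, nx, ny, _ = spec.dims
    z = np.arange(nz, dtype=np.float32)[:, None, None]
    refl = spec.layer_reflectivity
    layer_vals = [
        refl["vitreous"], refl["nfl_ipl"], refl["inl"], refl["opl"],
        refl["onl"], refl["rpe_ch"], refl["sclera"],
    ]
    bounds = [surfaces[name][None, :, :] for name in SURFACE_NAMES]
    template = np.full((nz, nx, ny), layer_vals[0], dtype=np.float32)
    for bound, val in zip(bounds, layer_vals[1:]):
        template = np.where(z >= bound, np.float32(val), template)

    zz = np.arange(nz, dtype=np.float32)[:, None, None]
    xx = np.arange(nx, dtype=np.float32)[None, :, None]
    yy = np.arange(ny, dtype=np.float32)[None, None, :]
    for les in spec.lesions:
        cz, cx, cy = les.center
        d2 = (zz - cz) ** 2 + (xx - cx) ** 2 + (yy - cy) ** 2
        inside = d2 <= les.radius**2
        template[inside] = les.reflectivity
        if les.onl_disruption_px > 0:
            lateral = (xx - cx) ** 2 + (yy - cy) ** 2 <= les.radius**2
            above = (zz < cz) & (zz >= cz - les.onl_disruption_px)
            template[lateral & above] *= 0.6
    return template


def _sphere_mask(dims, centers_radii) -> np.ndarray:
    nz, nx, ny = dims
    zz = np.arange(nz, dtype=np.float32)[:, None, None]
    xx = np.arange(nx, dtype=np.float32)[None, :, None]
    yy = np.arange(ny, dtype=np.float32)[None, None, :]
    mask = np.zeros((nz, nx, ny), dtype=bool)
    for (cz, cx, cy), r in centers_radii:
        mask |= (zz - cz) ** 2 + (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
    return mask


def build_flow_mask(spec: PhantomSpec, surfaces: SurfaceSet) -> np.ndarray:
    nz, nx, ny, _ = spec.dims
    mask = np.zeros((nz, nx, ny), dtype=bool)
    zz = np.arange(nz, dtype=np.float32)[:, None, None]
    xx = np.arange(nx, dtype=np.float32)[None, :, None]
    ilm, rpe = surfaces["ilm"], surfaces["rpe"]
    for ves in spec.vessels:
        z0 = (ilm + ves.depth_fraction * (rpe - ilm))[None, :, :]
        mask |= (zz - z0) ** 2 + (xx - ves.x) ** 2 <= ves.radius**2
    return mask


def make_phantom(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[DualChannelVolume, GroundTruth]:
    """Generate a seeded synthetic dual-channel tomogram with ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    nz, nx, ny, nt = spec.dims

    surfaces = build_surfaces(spec)
    template = build_template(spec, surfaces)
    flow_mask = build_flow_mask(spec, surfaces)
    deposit_mask = _sphere_mask(
        (nz, nx, ny), [(d.center, d.radius) for d in spec.deposits]
    )
    lesion_mask = _sphere_mask(
        (nz, nx, ny), [(l.center, l.radius) for l in spec.lesions]
    )
    for dep in spec.deposits:
        dm = _sphere_mask((nz, nx, ny), [(dep.center, dep.radius)])
        template[dm] *= dep.reflectivity_gain
    for ves in spec.vessels:
        vm = build_flow_mask(dataclasses.replace(spec, vessels=[ves]), surfaces)
        template[vm] = ves.reflectivity

    # --- polarization state per voxel -------------------------------------
    base_state = _random_unit_vectors(rng, (ny,))          # one state per B-scan
    stokes = np.broadcast_to(
        base_state[None, None, :, :], (nz, nx, ny, 3)
    ).copy()
    scramble = np.zeros((nz, nx, ny), dtype=np.float32)
    z = np.arange(nz, dtype=np.float32)[:, None, None]
    in_rpe_ch = (z >= surfaces["rpe"][None]) & (z < surfaces["ch"][None])
    scramble[in_rpe_ch] = spec.rpe_scramble
    for dep in spec.deposits:
        dm = _sphere_mask((nz, nx, ny), [(dep.center, dep.radius)])
        scramble[dm] = 1.0 - dep.dopu_target
    pick = rng.random((nz, nx, ny), dtype=np.float32) < scramble
    random_states = _random_unit_vectors(rng, (nz, nx, ny))
    stokes[pick] = random_states[pick]

    jones_h, jones_v = _jones_from_stokes(stokes)

    # --- speckle fields ----------------------------------------------------
    amplitude = np.sqrt(template)
    noise_free = np.isinf(spec.snr_db)
    if noise_free:
        g = np.broadcast_to(
            amplitude[..., None].astype(np.complex64), (nz, nx, ny, nt)
        ).copy()
    else:
        g_static = _complex_gaussian(rng, (nz, nx, ny))
        g = np.repeat(g_static[..., None], nt, axis=3)
        if flow_mask.any() and spec.flow_decorrelation > 0:
            beta = float(spec.flow_decorrelation)
            n_flow = int(flow_mask.sum())
            fresh = _complex_gaussian(rng, (n_flow, nt))
            mixed = (
                np.sqrt(1.0 - beta**2) * g_static[flow_mask][:, None] + beta * fresh
            )
            g[flow_mask] = mixed.astype(np.complex64)
        g *= amplitude[..., None]

    sh = g * jones_h[..., None]
    sv = g * jones_v[..., None]

    # --- axial respiratory motion (shifts the tissue, not the noise) ------
    shifts = np.zeros((ny, nt), dtype=int)
    if spec.motion_amplitude_px > 0:
        phi0 = rng.uniform(0.0, 2.0 * np.pi)
        m = np.arange(ny * nt, dtype=float)
        t_acq = m * spec.bscan_period_s
        s = spec.motion_amplitude_px * np.sin(
            2.0 * np.pi * spec.motion_freq_hz * t_acq + phi0
        )
        shifts = np.rint(s).astype(int).reshape(ny, nt)
        for iy in range(ny):
            for it in range(nt):
                sft = shifts[iy, it]
                if sft:
                    sh[:, :, iy, it] = _axial_shift(sh[:, :, iy, it], sft)
                    sv[:, :, iy, it] = _axial_shift(sv[:, :, iy, it], sft)

    if not noise_free:
        noise_i = 10.0 ** (-spec.snr_db / 10.0)       # total background intensity
        sigma = np.float32(np.sqrt(noise_i / 2.0))    # per-channel E|n|^2
        sh = sh + sigma * _complex_gaussian(rng, (nz, nx, ny, nt))
        sv = sv + sigma * _complex_gaussian(rng, (nz, nx, ny, nt))

    # --- bulk phase (sub-wavelength axial motion between repeats) ---------
    if spec.bulk_phase:
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(ny, nt)).astype(np.float32)
    else:
        phases = np.zeros((ny, nt), dtype=np.float32)
    phase_factor = np.exp(1j * phases)[None, None, :, :].astype(np.complex64)
    sh = sh * phase_factor
    sv = sv * phase_factor

    volume = DualChannelVolume(
        sv=sv,
        sh=sh,
        pixel_size_axial_um=spec.pixel_size_axial_um,
        pixel_size_lateral_um=spec.pixel_size_lateral_um,
        bscan_period_s=spec.bscan_period_s,
        meta={"snr_db": spec.snr_db, "phantom": True},
    )
    truth = GroundTruth(
        surfaces=surfaces,
        flow_mask=flow_mask,
        deposit_mask=deposit_mask,
        lesion_mask=lesion_mask,
        lesion_coords=[l.center for l in spec.lesions],
        deposit_coords=[d.center for d in spec.deposits],
        shifts=shifts,
        bulk_phases=phases,
        stokes=stokes.astype(np.float32),
        template=template,
        _axial_scale=spec.pixel_size_axial_um,
    )
    return volume, truth


def _axial_shift(bscan: np.ndarray, shift: int) -> np.ndarray:
    """Integer axial shift with zero fill (positive = content moves deeper)."""
    out = np.zeros_like(bscan)
    if shift > 0:
        out[shift:] = bscan[:-shift]
    elif shift < 0:
        out[:shift] = bscan[-shift:]
    else:
        out[:] = bscan
    return out


def make_longitudinal_series(
    spec: PhantomSpec,
    timepoints_days: list[float],
    or_thinning_rate_um_per_month: float,
    seed: int = 0,
) -> list[tuple[DualChannelVolume, GroundTruth]]:
    """Generate one phantom per postnatal-day timepoint with linear OR thinning.

    The OPL/ONL→RPE distance in the ground truth decreases linearly at the
    stated rate (µm/month, months of :data:`DAYS_PER_MONTH` days); the RPE and
    CH boundaries move anteriorly while the inner boundaries stay fixed, so
    the total retina thins by the same amount.  Each timepoint is generated
    from an independent child seed of ``seed``.
    """
    days = list(timepoints_days)
    if any(b <= a for a, b in zip(days[:-1], days[1:])):
        raise PhantomValidationError("timepoints must be strictly increasing")
    months = [(d - days[0]) / DAYS_PER_MONTH for d in days]
    shrink_px_last = (
        or_thinning_rate_um_per_month * months[-1] / spec.pixel_size_axial_um
    )
    or_px = spec.boundaries["rpe"] - spec.boundaries["opl_onl"]
    if shrink_px_last >= or_px:
        raise PhantomValidationError(
            "thinning rate leaves non-positive OR thickness at the last timepoint"
        )
    children = np.random.SeedSequence(seed).spawn(len(days))
    series = []
    for month, child in zip(months, children):
        shrink = (
            or_thinning_rate_um_per_month * month / spec.pixel_size_axial_um
        )
        boundaries = dict(spec.boundaries)
        boundaries["rpe"] -= shrink
        boundaries["ch"] -= shrink
        tp_spec = dataclasses.replace(spec, boundaries=boundaries)
        tp_seed = int(child.generate_state(1)[0] % (2**31))
        series.append(make_phantom(tp_spec, seed=tp_seed))
    return series
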