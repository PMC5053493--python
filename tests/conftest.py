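"""Shared phantom fixtures.

Two reduced-scale phantoms are processed once per session: a healthy-retina
"control" scene for recovery checks and a "pathology" scene (lesion, melanin
deposits, outer-retinal neovascular sprout) at the full repeat count for the
contrast stages.  All stages run with default parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from mfoct import phantom, preprocess, pscontrast, octa, segmentation


@dataclass
class ProcessedPhantom:
    spec: object
    volume: object
    truth: object
    motion: object
    flat: object            # flattened DualChannelVolume
    averaged: object        # averaged ReflectivityVolume
    surfaces: object        # refined SurfaceSet
    offsets: np.ndarray     # flattening offset grid (int)

    def true_surface(self, name: str) -> np.ndarray:
        """Ground-truth surface mapped into the flattened frame."""
        return self.truth.surfaces[name] + self.offsets

    def flatten_mask(self, mask: np.ndarray) -> np.ndarray:
        return preprocess.apply_flattening_3d(
            mask.astype(np.uint8), self.motion
        ).astype(bool)


def _process(spec, seed):
    volume, truth = phantom.make_phantom(spec, seed=seed)
    refl = preprocess.compute_reflectivity(volume)
    motion = preprocess.build_motion_model(refl)
    flat = preprocess.compensate_and_flatten(volume, motion)
    averaged = preprocess.average_repeats(
        preprocess.compute_reflectivity(flat), exclude=motion.severe
    )
    surfaces = segmentation.refine_3d(
        segmentation.segment_all_layers(averaged.intensity)
    )
    nx, ny = averaged.intensity.shape[1:3]
    offsets = np.rint(motion.target_depth - motion.surface.grid(nx, ny)).astype(int)
    return ProcessedPhantom(
        spec=spec, volume=volume, truth=truth, motion=motion, flat=flat,
        averaged=averaged, surfaces=surfaces, offsets=offsets,
    )


@pytest.fixture(scope="session")
def processed_control():
    spec = phantom.control_scene((256, 96, 48, 3))
    return _process(spec, seed=7)


@pytest.fixture(scope="session")
def processed_pathology():
    spec = phantom.default_scene((256, 128, 64, 5))
    return _process(spec, seed=5)


@pytest.fixture(scope="session")
def pathology_contrast(processed_pathology):
    """DOPU and angiography volumes of the pathology phantom."""
    p = processed_pathology
    refl_flat = preprocess.compute_reflectivity(p.flat)
    nx, ny = refl_flat.shape[1:3]
    ilm_prov = np.full((nx, ny), float(p.motion.target_depth))
    background = pscontrast.estimate_background(refl_flat, ilm_prov)
    stokes = pscontrast.compute_stokes(p.flat)
    dopu = pscontrast.compute_dopu(stokes, background)
    angio = octa.compute_angio_volume(p.flat)
    return {"background": background, "dopu": dopu, "angio": angio}
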