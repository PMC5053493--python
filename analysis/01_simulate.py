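"""Generate the synthetic study data: one pathology acquisition, one control
acquisition, and seed annotations.

Writes HDF5 tomograms (documented layout) and JSON annotations under
``results/phantom/``.  The pathology scene carries a hyperreflective lesion,
two depolarizing melanin deposits and an outer-retinal neovascular sprout;
the control scene has physiological vasculature only.

Usage:  python analysis/01_simulate.py [--seed 1] [--outdir results/phantom]
"""

import argparse
from pathlib import Path

from mfoct import pipeline_io as pio
from mfoct.evaluation import SeedAnnotations
from mfoct.phantom import control_scene, default_scene, make_phantom


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--dims", type=int, nargs=4,
                        default=(256, 128, 64, 5), metavar=("NZ", "NX", "NY", "NT"))
    parser.add_argument("--outdir", type=Path, default=Path("results/phantom"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    dims = tuple(args.dims)

    for name, factory in (("pathology", default_scene), ("control", control_scene)):
        spec = factory(dims)
        volume, truth = make_phantom(spec, seed=args.seed)
        pio.write_volume(args.outdir / f"{name}.h5", volume)
        ann = SeedAnnotations(
            onh=(dims[1] / 2.0, dims[2] / 2.0),
            lesions=list(truth.lesion_coords),
            deposits=list(truth.deposit_coords),
        )
        pio.write_annotations(args.outdir / f"{name}_annotations.json", ann)
        print(f"{name}: volume {volume.shape} -> {args.outdir / (name + '.h5')}")
        print(f"  lesions: {len(truth.lesion_coords)}, deposits: "
              f"{len(truth.deposit_coords)}, flow voxels: {int(truth.flow_mask.sum())}")


if __name__ == "__main__":
    main()
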