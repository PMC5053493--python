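"""Longitudinal quantification: monthly clustering and thinning recovery.

Two parts:

1. Aggregates the printed monthly lesion/deposit counts (``data/``) through
   the same clustering code the pipeline uses, reproducing the per-eye means
   (e.g. 3.79 deposits/eye at month 3).
2. Simulates a 5-timepoint longitudinal series with a programmed outer-retina
   (OR) thinning of 4 µm/month, runs the full thickness pipeline per
   timepoint and recovers the rate by linear regression.

Writes ``results/longitudinal_summary.csv`` and
``results/thinning_recovery.csv``.

Usage:  python analysis/03_longitudinal.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mfoct import evaluation as ev
from mfoct import preprocess as pp
from mfoct import projections as proj
from mfoct import segmentation as seg
from mfoct.phantom import control_scene, make_longitudinal_series

REPO = Path(__file__).resolve().parents[1]


def monthly_aggregation(outdir, rng):
    table = pd.read_csv(REPO / "data" / "longitudinal_counts.csv", comment="#")
    rows = []
    for _, r in table.iterrows():
        n_eyes, total = int(r["n_eyes"]), int(r["deposits_total"])
        counts = rng.multinomial(total, np.ones(n_eyes) / n_eyes)
        day0 = int(np.ceil((r["month"] - 1) * ev.DAYS_PER_MONTH)) + 1
        for k, c in enumerate(counts):
            rows.append({"mouse": f"m{k // 2}", "eye": ("left", "right")[k % 2],
                         "postnatal_day": day0 + k % 3, "deposits": int(c)})
    _, summary = ev.cluster_monthly(pd.DataFrame(rows))
    summary.to_csv(outdir / "longitudinal_summary.csv", index=False)
    print("deposits per eye by month (recomputed from printed totals):")
    for _, row in summary.iterrows():
        print(f"  month {int(row['month']):2d}: {row['deposits_mean']:.2f} "
              f"(n={int(row['n_eyes'])} eyes)")


def thinning_recovery(outdir, seed):
    spec = control_scene((256, 96, 48, 3))
    days = [30, 60, 90, 120, 150]
    rate = 4.0
    series = make_longitudinal_series(spec, days, rate, seed=seed)
    rows = []
    for day, (volume, truth) in zip(days, series):
        refl = pp.compute_reflectivity(volume)
        motion = pp.build_motion_model(refl)
        flat = pp.compensate_and_flatten(volume, motion)
        averaged = pp.average_repeats(pp.compute_reflectivity(flat),
                                      exclude=motion.severe)
        surfaces = seg.refine_3d(seg.segment_all_layers(averaged.intensity))
        or_map = proj.thickness_map(surfaces, "OR")
        rows.append({
            "postnatal_day": day,
            "month": (day - days[0]) / ev.DAYS_PER_MONTH,
            "or_estimated_um": float(np.nanmean(or_map.values)),
            "or_true_um": truth.or_thickness_um,
        })
    frame = pd.DataFrame(rows)
    frame.to_csv(outdir / "thinning_recovery.csv", index=False)
    slope = np.polyfit(frame["month"], frame["or_estimated_um"], 1)[0]
    print(f"\nprogrammed OR thinning: {rate:.2f} um/month")
    print(f"recovered OR thinning:  {-slope:.2f} um/month "
          f"(|error| = {abs(-slope - rate):.2f})")
    for _, row in frame.iterrows():
        print(f"  P{int(row['postnatal_day']):3d}: estimated "
              f"{row['or_estimated_um']:6.2f} um, true {row['or_true_um']:6.2f} um")


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    monthly_aggregation(args.outdir, np.random.default_rng(args.seed))
    thinning_recovery(args.outdir, args.seed)


if __name__ == "__main__":
    main()
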