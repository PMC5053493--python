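"""Longitudinal statistics on a synthetic per-eye cohort.

The raw per-eye measurements behind the printed monthly thickness summaries
are not available, so this driver simulates a cohort whose monthly means and
spreads match the printed table (``data/thickness_by_month.csv``), applies
the missing-data rules (eliminate months and eyes missing >25%, impute the
rest by a linear local trend), and runs the full statistical battery:
repeated-measures ANOVA with Bonferroni post hoc vs the baseline month,
Mann-Whitney U mutant-vs-control comparisons, and the Pearson correlation
between total-retina (TR) and outer-retina (OR) thickness decrease.

Writes ``results/stats_report.txt`` and ``results/stats.json``.

Usage:  python analysis/04_statistics.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mfoct import stats as ms

REPO = Path(__file__).resolve().parents[1]
N_EYES = 16
MISSING_FRACTION = 0.12


def simulate_cohort(table, rng, metric):
    """Per-eye monthly values drawn to match the printed means and sds,
    with a consistent per-eye offset (repeated measures) and random gaps."""
    months = table["month"].tolist()
    mean = table[f"{metric}_mean"].to_numpy()
    sd = table[f"{metric}_sd"].to_numpy()
    eye_offset = rng.normal(0.0, 0.6, size=N_EYES)
    data = np.empty((N_EYES, len(months)))
    for j in range(len(months)):
        data[:, j] = mean[j] + sd[j] * (
            0.8 * eye_offset + 0.6 * rng.standard_normal(N_EYES)
        )
    gaps = rng.random(data.shape) < MISSING_FRACTION
    data[gaps] = np.nan
    return pd.DataFrame(data, columns=months,
                        index=[f"eye{k}" for k in range(N_EYES)])


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(args.seed)

    table = pd.read_csv(REPO / "data" / "thickness_by_month.csv", comment="#")
    mutant = table[table["group"] == "mutant"]
    control = table[table["group"] == "control"]

    results, payload = [], {}

    # --- repeated-measures ANOVA on TR thickness over months --------------
    cohort = simulate_cohort(mutant, rng, "tr")
    matrix = ms.prepare_matrix(cohort, baseline=2)
    anova = ms.rm_anova_bonferroni(matrix)
    results.append(anova)
    payload["rm_anova"] = {
        "F": anova.statistic, "df": anova.df, "p": anova.p_value,
        "eliminated_months": matrix.dropped_columns,
        "eliminated_eyes": matrix.dropped_rows,
        "imputed_cells": int(matrix.imputed.to_numpy().sum()),
        "post_hoc_bonferroni": anova.adjusted,
    }

    # --- Mann-Whitney U: mutant vs control OR thickness per month ---------
    payload["mann_whitney_or"] = {}
    for _, ctrl_row in control.iterrows():
        month = int(ctrl_row["month"])
        mut_row = mutant[mutant["month"] == month].iloc[0]
        a = mut_row["or_mean"] + mut_row["or_sd"] * rng.standard_normal(
            int(mut_row["n_eyes"]))
        b = ctrl_row["or_mean"] + ctrl_row["or_sd"] * rng.standard_normal(
            int(ctrl_row["n_eyes"]))
        mwu = ms.mann_whitney_u(a, b)
        mwu.name = f"Mann-Whitney U, OR mutant vs control, month {month}"
        results.append(mwu)
        payload["mann_whitney_or"][month] = {
            "U": mwu.statistic, "p": mwu.p_value,
        }

    # --- Pearson correlation of TR vs OR decrease -------------------------
    tr = simulate_cohort(mutant, rng, "tr")
    orr = simulate_cohort(mutant, rng, "or")
    tr_m = ms.prepare_matrix(tr, baseline=2).data
    or_m = ms.prepare_matrix(orr, baseline=2).data
    shared = [c for c in tr_m.columns if c in or_m.columns and c != 2]
    rows = tr_m.index.intersection(or_m.index)
    tr_dec = (tr_m.loc[rows, 2].to_numpy()[:, None]
              - tr_m.loc[rows, shared].to_numpy()).ravel()
    or_dec = (or_m.loc[rows, 2].to_numpy()[:, None]
              - or_m.loc[rows, shared].to_numpy()).ravel()
    pearson = ms.pearson_r(tr_dec, or_dec)
    pearson.name = "Pearson correlation, TR decrease vs OR decrease"
    results.append(pearson)
    payload["pearson_tr_or_decrease"] = {
        "rho": pearson.statistic, "p": pearson.p_value, "n": int(tr_dec.size),
    }

    report = ms.report(results)
    (args.outdir / "stats_report.txt").write_text(report + "\n")
    (args.outdir / "stats.json").write_text(json.dumps(payload, indent=2,
                                                       default=str))
    print(report)


if __name__ == "__main__":
    main()
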