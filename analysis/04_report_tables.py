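#!/usr/bin/env python
"""Assemble the cohort tables and regressions from the fitted statistics.

Reads the per-ROI statistics written by 02 (relaxometry) and 03 (histology),
builds the viable-vs-necrotic percent-difference tables, runs the OD
time-course regressions (week 6 excluded: no histological necrosis) and the
pooled relaxation-vs-OD regression, and compares everything against the
published tables recomputed from their printed means.
"""

import numpy as np
import pandas as pd

from qcart import datasets
from qcart.cohort_stats import (
    SpecimenRecord,
    build_difference_table,
    build_relaxation_table,
    mri_vs_od_regression,
    od_time_regressions,
    percent_difference,
)
from qcart.io import write_report
from qcart.pipeline import published_difference_table

relax = pd.read_csv("results/relaxation_roi_stats.csv")
od = pd.read_csv("results/od_roi_stats.csv")

records = []
for week, grp in relax.groupby("week"):
    rec = SpecimenRecord(
        week=int(week),
        lesion_class=grp.lesion_class.iloc[0],
        stats={(r.parameter, r.roi): (r.mean, r.sd) for r in grp.itertuples()},
        od_stats={r.roi: (r.mean, r.sd) for r in od[od.week == week].itertuples()},
        histological_necrosis=int(week) != datasets.WEEK_WITHOUT_NECROSIS,
    )
    records.append(rec)

relax_table = build_relaxation_table(records)
diff_table = build_difference_table(relax_table)

od_rows = []
for rec in records:
    v, n = rec.od_stats["viable"], rec.od_stats["necrotic"]
    od_rows.append({"week": rec.week, "viable_mean": v[0], "viable_sd": v[1],
                    "necrotic_mean": n[0], "necrotic_sd": n[1],
                    "pct_difference": percent_difference(v[0], n[0])})
od_table = pd.DataFrame(od_rows).set_index("week")

regs = od_time_regressions(records)
od_by_week = {int(w): float(r.pct_difference) for w, r in od_table.iterrows()}
pooled, points = mri_vs_od_regression(diff_table, od_by_week)
all_regs = {f"od_{k}_vs_week": v for k, v in regs.items()}
all_regs["relaxation_vs_od"] = pooled

write_report(relax_table, diff_table, od_table, all_regs, "results",
             config={"seed": 1, "shape": [96, 96], "noise_sigma": 20.0})

published = published_difference_table()
delta = (diff_table - published).abs()
print("percent-difference table recovered under noise (pp deviation from the")
print("values recomputed from the published means):")
print(f"  median {np.nanmedian(delta.values):.2f} pp, max {np.nanmax(delta.values):.2f} pp")
print(f"week-3 T2 cell null: {bool(np.isnan(diff_table.loc[3, 'T2']))}")
print(f"viable-OD-vs-week R^2:      {regs['viable'].r_squared:.3f}  (published 0.129)")
print(f"necrotic-OD-vs-week R^2:    {regs['necrotic'].r_squared:.3f}")
print(f"OD-%-difference-vs-week R^2: {regs['pct_diff'].r_squared:.3f}")
print(f"pooled relaxation-vs-OD slope: {pooled.slope:.3f} over {pooled.n_points} pairs "
      f"(published 0.21)")
print("wrote results/relaxation_stats.csv, relaxation_differences.csv, "
      "od_stats.csv, regressions.json")
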