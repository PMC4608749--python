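#!/usr/bin/env python
"""Fit all relaxation maps of the synthetic cohort under realistic noise.

Simulates every preparation of every specimen with Rician noise at
sigma = A/50 (2% of the frame amplitude, chosen so per-pixel scatter in the
fitted times lands in the few-percent range of the published ROI standard
deviations), fits the maps pixel by pixel, and writes per-ROI statistics.
"""

import time

import numpy as np
import pandas as pd

from qcart.relaxometry import fit_series
from qcart.synthetic import LABELS, make_cohort, simulate_series

SEED = 1
SHAPE = (96, 96)
NOISE_SIGMA = 20.0  # amplitude is 1000

cohort = make_cohort(seed=SEED, shape=SHAPE, noise_sigma=NOISE_SIGMA)
ss = np.random.SeedSequence(SEED)
spec_seeds = ss.generate_state(len(cohort))

rows = []
t0 = time.time()
for sp, s in zip(cohort, spec_seeds):
    child = np.random.SeedSequence(int(s % (2**31))).generate_state(len(sp.protocols))
    for (name, proto), cs in zip(sorted(sp.protocols.items()), child):
        series = simulate_series(sp.phantom, proto, seed=int(cs % (2**31)))
        pmap = fit_series(series, mask=sp.phantom.labels > 0)
        for roi in ("articular", "viable", "necrotic"):
            mean, sd, n = pmap.roi_summary(sp.phantom.labels, LABELS[roi])
            if name == "T1":
                mean, sd = mean / 1000.0, sd / 1000.0  # report T1 in seconds
            rows.append({"week": sp.week, "lesion_class": sp.lesion_class,
                         "parameter": name, "roi": roi,
                         "mean": mean, "sd": sd, "n_pixels": n})
    print(f"week {sp.week:2d}: fitted {len(sp.protocols)} maps")

stats = pd.DataFrame(rows)
stats.to_csv("results/relaxation_roi_stats.csv", index=False)

truth = pd.read_csv("results/cohort_truth.csv")
merged = stats.merge(truth[truth.parameter != "OD"], on=["week", "lesion_class", "parameter", "roi"])
rel_err = 100 * (merged["mean"] - merged["truth"]).abs() / merged["truth"]
print(f"\nfitted {len(stats)} ROI statistics in {time.time() - t0:.0f}s "
      f"(sigma = {NOISE_SIGMA}, i.e. A/50)")
print(f"ROI-mean recovery error vs truth: median {rel_err.median():.2f}%, "
      f"max {rel_err.max():.2f}%")
print("wrote results/relaxation_roi_stats.csv")
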