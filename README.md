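# qcart

Quantitative MRI relaxometry and safranin-O optical-density analysis of
ischemic necrosis in epiphyseal growth cartilage (osteochondrosis).

Osteochondrosis begins as a focal area of necrotic epiphyseal cartilage after
failure of its cartilage-canal blood supply, long before anything is visible
radiographically. `qcart` implements the analysis used to show that
multiparametric MRI detects these lesions: pixel-wise mapping of five
relaxation parameters (T₁, T₂, T₁ρ, adiabatic T₁ρ, T_RAFF), transmission
densitometry of safranin-O–stained sections as a proteoglycan reference, and
the cohort statistics that tie the two together. Because no imaging data were
deposited with the study, the package ships a synthetic condyle-phantom
cohort whose ground truth is the published per-ROI means, so the entire
pipeline is testable end to end.

## Models

**Relaxometry.** Each magnetization preparation yields a frame series
S(t) over preparation times t (inversion time TI, echo time TE, spin-lock
duration, or pulse-train duration = pulse count × per-pulse length). Per
masked pixel the package fits, by nonlinear least squares,

* inversion recovery (T₁): S(TI) = A·(1 − 2e^(−TI/T₁)), fitted by default as
  its magnitude |A·(1 − 2e^(−TI/T₁))| since acquisitions are magnitude-valued
  (optional polarity-restoration mode fits the signed model);
* mono-exponential decay (T₂, T₁ρ, adiabatic T₁ρ, T_RAFF): S(t) = A·e^(−t/T).

Outputs are per-pixel maps of T, A, R² and a validity flag.

**Histology.** Sample and reference (blank-glass) transmission images are
background-subtracted, normalized to counts/s (cancelling exposure
differences), divided to give transmittance, and converted to optical
density OD = −log₁₀(T), which is proportional to safranin-O binding and
hence proteoglycan content.

**Cohort statistics.** Viable-vs-necrotic contrast is the symmetric percent
difference 100·(a − b)/((a + b)/2); OD means and differences are regressed
on weeks post-surgery (the week-6 specimen, which had no histologically
evident necrosis, is excluded by default), and all relaxation percent
differences are pooled against the OD percent difference in an ordinary
least-squares fit.

## Worked example

Fit the spin-lock T₁ρ map of a noisy week-5 phantom (Rician σ = A/50) and
summarize it over the phantom's ROI labels:

```python
from qcart import datasets, percent_difference
from qcart.relaxometry import fit_series
from qcart.synthetic import LABELS, PhantomSpec, make_phantom, simulate_series

proto = datasets.cohort_protocols()["T1RHO"]
phantom = make_phantom(PhantomSpec.for_week(5, shape=(96, 96), noise_sigma=20.0, seed=7))
series = simulate_series(phantom, proto)
pmap = fit_series(series, mask=phantom.labels > 0)
for roi in ("articular", "viable", "necrotic"):
    mean, sd, n = pmap.roi_summary(phantom.labels, LABELS[roi])
    print(f"{roi:9s} T1rho = {mean:6.1f} +/- {sd:4.1f} ms  (n={n})")
```

```
articular T1rho =  124.4 +/-  7.8 ms  (n=589)
viable    T1rho =   88.1 +/-  4.5 ms  (n=2130)
necrotic  T1rho =  206.6 +/- 16.8 ms  (n=263)
```

The generating values were 123.7 / 88.0 / 205.3 ms (the published week-5
means); the viable-vs-necrotic percent difference of the fitted means is
80.4%, against 80.0% printed for that specimen. Necrotic epiphyseal
cartilage relaxes much more slowly than viable — that contrast is what makes
the lesions visible.

The numbered scripts under `analysis/` run the same study cohort-wide:
`01_simulate_cohort.py` builds the six phantoms, `02_fit_relaxometry.py`
fits all 29 maps under noise, `03_histology_od.py` runs the densitometry,
and `04_report_tables.py` assembles the difference tables and regressions
under `results/`.

There is also a CLI for running the steps on files:

```sh
qcart simulate --week 5 --size 96 --out sim/
qcart fit --series sim/T1RHO_series.tif --protocol sim/T1RHO_protocol.json \
          --mask sim/labels.tif --out maps/
qcart od  --sample sim/histology_sample.tif --reference sim/histology_reference.tif \
          --meta sim/histology_meta.json --roi sim/labels.tif --out od/
qcart report --stats stats.csv --out report/
```

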