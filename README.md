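# diveo2

Blood O2 transport modelling for diving birds: pH-dependent
O2–hemoglobin dissociation curves, conversion of dive PO2/depth time
series into Hb-saturation profiles, blood and total-body O2 store
accounting, post-dive recovery-time extraction, and the blood-chemistry
regressions used to bound blood pH — together with a seeded synthetic
data generator so the whole pipeline is testable without field data.

## Modules

| module | purpose |
| --- | --- |
| `diveo2.oxy_dissociation` | Hill-form dissociation curves, Bohr shift (pH → P50), PO2 ↔ saturation, built-in giant-fulmar comparison curve |
| `diveo2.blood_chem` | blood-sample panels, lactate-based group partitioning, random-intercept pH regressions (marginal/conditional r²), AIC candidate selection, lower pH bound |
| `diveo2.o2_accounting` | blood O2 content, arterial/venous compartment stores, per-dive net depletion and DMR contributions, distributional summaries, Wilcoxon comparisons |
| `diveo2.dive_profiles` | dive/surface segmentation, saturation profiles at a chosen pH or curve, depth-dependent respiratory PO2, recovery times to saturation baselines |
| `diveo2.body_budget` | five-compartment total-body O2 budget by dive-duration class (exact rational arithmetic), remaining-store percentages, replenishment rates |
| `diveo2.synthetic_data` | seeded generators for blood panels (linear mixed-model structure) and dive records (phenomenological depth/PO2 templates) |

All literature constants live in one versioned parameter file,
`src/diveo2/data/printed_constants.yaml`; operations never hard-code
them.

## CLI

The console script `diveo2` exposes the pipeline stages:

```bash
# generate synthetic inputs from key-value spec files
diveo2 simulate --panel panel.yaml --dives dives.yaml --out data/

# random-intercept regression of pH on PCO2 or lactate
diveo2 fit-ph --input data/samples.csv --predictor pco2 --report fit.json

# per-dive blood O2 store accounting from endpoint PO2 values
diveo2 budget --endpoints endpoints.csv --ph-final 7.3 --ph-initial 7.5

# convert dive PO2 profiles to saturation profiles
diveo2 convert --profiles data/dives.csv --ph 7.5 --ph 7.3 --out sat.csv
diveo2 convert --profiles data/dives.csv --curve fulmar --out sat_fulmar.csv

# total-body O2 budget table for a dive-duration class
diveo2 report --class short
```

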