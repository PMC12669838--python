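# Versioned parameter file: every literature constant used by the package
# lives here, never hard-coded inside operations.
version: 1

dissociation:
  # (pH, P50 mmHg) anchor points for the high-affinity (emperor) blood.
  emperor_anchors:
    - [7.2, 37.0]
    - [7.3, 35.0]
    - [7.4, 31.0]
    - [7.5, 28.0]
  # Whole-blood cooperativity assumed for the emperor curves (not published
  # per pH; typical avian whole-blood value, configurable per curve).
  default_hill_n: 3.0
  # Hill-plot fit of the giant fulmar curve:
  # log10[S/(1-S)] = hill_n * log10(PO2) - hill_intercept
  fulmar:
    hill_n: 2.74683
    hill_intercept: 4.52219

blood:
  hb_conc_g_dl: 18.3
  o2_capacity_ml_g: 1.34
  solubility_ml_dl_mmhg: 0.003
  blood_volume_ml_kg: 100.0
  arterial_fraction: 0.33
  venous_fraction: 0.67

pressure:
  surface_mmhg: 760.0          # 1 ATA
  ata_per_10m: 1.0             # +1 ATA per 10 m of seawater
  water_vapor_mmhg: 47.0

thresholds:
  lactate_split_mmol_l: 1.5        # dive vs surface sample groups
  lactate_reg_pco2_max_mmhg: 70.0  # lactate regression keeps PCO2 < this
  pco2_exclude_mmhg: 93.0          # implausible PCO2, dropped before bounding
  anesthesia_pco2_exclude_mmhg: 70.0
  arterial_baseline_sat: 0.90
  venous_baseline_sat: 0.80
  ph_upper_bound: 7.5
  ph_lower_bound: 7.3

# Median blood O2 store contribution to metabolic rate (ml O2 kg-1 min-1),
# by compartment and end-of-dive pH, over all recorded dives.
table1_dmr_medians:
  arterial: {"7.4": 0.4, "7.3": 0.5}
  venous: {"7.4": 0.7, "7.3": 0.9}

# Non-blood depletion-rate contributions used alongside the all-dive medians.
other_dmr_rates:
  respiratory: 1.5
  muscle: 3.6

# Per-compartment initial stores (ml O2 kg-1) and depletion rates
# (ml O2 kg-1 min-1) for the two dive-duration classes.
budget:
  short:
    label: "5-6 min dives"
    representative_duration_min: 6.0
    compartments:
      arterial: {initial: 7.3, rate: 0.4}
      venous: {initial: 13.1, rate: 1.4}
      respiratory: {initial: 12.2, rate: 1.6}
      muscle_chest: {initial: 21.4, rate: 3.1}
      muscle_legs: {initial: 3.0, rate: 0.5}
  long:
    label: "10-12 min dives"
    representative_duration_min: 10.0
    compartments:
      arterial: {initial: 8.0, rate: 0.4}
      venous: {initial: 11.9, rate: 1.0}
      respiratory: {initial: 12.2, rate: 0.9}
      muscle_chest: {initial: 21.4, rate: 2.0}
      muscle_legs: {initial: 3.0, rate: 0.3}

myoglobin:
  chest_store_ml_kg: 21.4
  desat_rate_pct_min: {short: 14.4, long: 9.8}
  stated_chest_rate: {short: 3.1, long: 2.3}

respiratory_air_ml_kg: 70.0
replenishment_window_min: 2.0
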