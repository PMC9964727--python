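# Default synthetic study: two salts, four runs each (three calibration
# solid concentrations + one test concentration), all tunable constants of
# the generative model in one place.
#
# The additive detector noise is constant in counts while the Raman signal
# scales linearly with solid concentration (alpha = 1), so the lowest
# concentration run carries the worst signal-to-noise ratio — the mechanism
# behind the degradation of single-run calibrations built at 12.5 mg/mL.

seed: 20230
duration_min: 450.0
cadence_min: 2.0
cal_concs: [50.0, 25.0, 12.5]
test_conc: 16.7
procedures: [baseline, cp, cp_conc]
lv_max: 6
truncation: [100.0, 1761.0]
noise_sd: 0.02          # additive Gaussian SD, counts
baseline_coeffs: [0.2, 0.00023, -0.000000065]  # ascending powers of Raman shift
baseline_jitter_sd: 0.1       # per-spectrum fluorescence amplitude fluctuation
fluor_conversion_coupling: 1.0  # background doubles over a full conversion
fluor_density_exponent: 1.0     # background vs signal grows as ref_conc/conc
ref_rel_sd: 0.04        # relative SD of the XRPD reference fractions

salts:
  hcl:
    library:
      kind: hcl
      alpha: 0.3               # sublinear intensity response of the suspension
      shift_per_conc: 0.0     # HCl-like: intensity offsets only
    kinetics:
      kind: hcl               # salt -> I -> II -> V first-order cascade
    run_overrides:
      "50.0":
        kinetics:
          kind: hcl
          include_form_I: false   # form I too transient to observe at 50 mg/mL
    recipes: [mean_center, snv_auto]   # candidates for the pooled procedure
    xrpd_times:
      "50.0": [2, 6, 10, 16, 24, 40, 70, 150, 300]
      "25.0": [2, 4, 6, 10, 14, 20, 28, 40, 60, 90, 130, 160, 200, 250, 300, 380, 450]
      "12.5": [2, 4, 6, 8, 12, 16, 22, 30, 40, 60, 90, 130, 200, 300, 450]
      "16.7": [2, 6, 10, 16, 24, 40, 60, 80, 100, 150, 200, 250, 300, 350, 450]
  maleate:
    library:
      kind: maleate
      alpha: 0.3
      shift_per_conc: 0.03    # maleate-like: additional peak shifts, cm⁻¹ per mg/mL
    kinetics:
      kind: maleate           # slow partial conversion, terminal salt pool 0.81
    recipes: [mean_center, snv_auto]
    xrpd_times:
      "50.0": [10, 40, 80, 130, 190, 250, 310, 370, 450]
      "25.0": [10, 30, 50, 70, 100, 130, 160, 190, 220, 260, 300, 340, 380, 420, 450]
      "12.5": [10, 40, 70, 100, 130, 160, 190, 220, 250, 280, 310, 350, 390, 420, 450]
      "16.7": [10, 50, 90, 130, 170, 210, 250, 290, 310, 330, 370, 410, 450]
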