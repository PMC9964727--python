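# Methods

This note documents the models, numerical choices and limitations behind
`polymon`: a pipeline that calibrates in-line Raman spectroscopy against
sparse offline XRPD reference measurements to quantify a pharmaceutical
salt and up to three freebase polymorphs during disproportionation, and
then ranks candidate salts by conversion kinetics.

## The monitoring problem

A salt suspended in water at solid concentration *c* (mg/mL) converts to
freebase polymorphs; the mass fractions of all solid forms close to one at
every instant. In-line Raman spectra are acquired every other minute over
~450 min; offline XRPD samples (9–17 per run) provide reference mass
fractions. Calibration must cope with two interferences: the polymorph
fingerprints overlap heavily, and the solid concentration changes both
peak intensities and (for some salts) peak positions.

## Spectral model and preprocessing

Raman intensity of a suspension is modelled as linear in the solid mass
fractions (an expanded Beer–Lambert reading): the spectrum is a weighted
sum of pure-form profiles, times a concentration gain, plus a smooth
background and detector noise. Preprocessing follows that structure:

* **Truncation** to 100–1761 cm⁻¹ (inclusive bounds) keeps the
  form-indicating fingerprint region and discards the noise-dominated
  high-shift range. Truncation happens first, so row-wise statistics are
  not polluted by the discarded region.
* **SNV** (standard normal variate) subtracts each spectrum's mean
  intensity and divides by its standard deviation — suppressing baseline
  offsets and the global intensity scale. SNV is row-wise and therefore
  stateless; it is idempotent and always precedes column scaling.
* **Column scaling** (mean centering or autoscaling) is fitted on
  calibration spectra only and applied with stored statistics to test
  data. Autoscaling drops zero-variance channels with a logged warning
  instead of dividing by zero. The sample standard deviation (n−1
  denominator) is used everywhere, SNV included.

Two named recipes cover the cases used in practice: `mean_center`
(truncate → mean-center) and `snv_auto` (truncate → SNV → autoscale).

## Calibration model

Each freebase polymorph gets a **single-response PLS model** fitted with
SIMPLS. X and y are mean-centered inside the fit; the y offset is restored
at prediction. SIMPLS is deterministic, order-invariant in the training
rows, and coincides with ordinary least squares at full rank — both
properties are tested against independent oracles (pseudoinverse OLS;
scikit-learn's NIPALS PLS as a cross-check, since single-response NIPALS
and SIMPLS span the same space). The salt never gets its own model: its
fraction is the closure remainder, 1 − Σ freebase fractions.

Latent-variable counts (1–6 by default) are selected per form by
minimising the procedure's figure of merit, with ties (within 1e-6)
resolved toward the smallest count:

* `baseline` — models built on the test run itself; figure of merit is
  RMSECV from **venetian-blinds** cross-validation with 10 splits (sample
  *i*, in acquisition order, validates in fold *i* mod 10 — interleaving
  early and late process states of the kinetic series; single samples, not
  blocks).
* `cp` — one calibration run at a different solid concentration; figure of
  merit is RMSEP on the test run.
* `cp_conc` — reference-matched spectra pooled over all three calibration
  concentrations; RMSEP on the test run. When several recipes are offered,
  the recipe minimising the mean RMSEP across modeled forms is kept for
  the whole set.

Selecting LV counts on the test run mirrors the original optimisation
workflow but is optimistic — the test run steers model choice. A
conservative `selection="cv"` mode (select by RMSECV within calibration,
report test RMSEP once) is provided for honest error estimation.

References are paired to the nearest-in-time spectrum within a 2-min
tolerance (one cadence step); ties go to the earlier spectrum and each
spectrum is used at most once. A form with fewer than three distinct
reference values in calibration is flagged *unmodelable* and reported as
`N/A`, never silently dropped. Predictions are kept raw (unclipped) for
all error computations; only the reported composition clips freebase
fractions to [0, 1] and renormalises if their sum exceeds one, so every
reported composition closes exactly.

## XRPD reference quantitation

Each form has ≥ 2 signature peaks whose integration windows (± 2 FWHM)
must not overlap across forms — validated at library construction. Peak
areas are trapezoidal above a straight baseline between the window
endpoints, floored at zero. Binary physical mixtures (0–100% in 10%
steps) give a least-squares line of composition on summed signature area
per form. For a process sample, each form's calibration lines are
evaluated on its signature areas, estimates averaged over the covering
curves, negatives floored, and the result normalised to closure (which
also cancels any global intensity scale). When three or more forms
co-exist, this per-form-window reading of "relative amounts of all binary
pairs" is the implemented rule; it is isolated in one function so a
pairwise-ratio alternative could be swapped in.

## Kinetics

The zero-order conversion rate is the negative slope of a least-squares
line over the declining segment of the salt time course: from the first
point below 0.95 down to max(terminal + 0.05, 0.05), where the terminal
fraction is the mean of the final 5% of points. At least three points are
required; otherwise (or if the slope is non-negative, or the decline is
too shallow for the window to exist) the estimate is flagged no-decline
with rate 0. Rates are reported in fraction/min and %/min. Salts are
ranked by ascending rate (ties: higher terminal salt fraction is more
stable) with the fastest/slowest rate ratio attached. The window rule is
one defensible reading of "zero-order rate" for a process whose decline
is only piecewise linear; it is configurable.

## Synthetic-data generator

The generator is first-class, tested code and the ground-truth oracle for
every recovery test.

* **Kinetics**: conversion networks with first-order (exponential) and/or
  zero-order (linear, stopping at a floor) edges, integrated with LSODA at
  rtol 1e-10 in smooth segments; zero-order floor crossings are handled as
  terminal events with edge deactivation/reactivation. Accuracy is checked
  against the analytic exponential (1e-8) and the two-species Bateman
  solution (1e-6). The initial form may keep a terminal unconverted pool
  (partial disproportionation). Defaults: HCl-like salt → I → II → V
  first-order cascade (form I transient); maleate-like salt → II → V with
  a 0.81 terminal salt pool. Whether real conversions are first- or
  zero-order upstream of the zero-order summary is left open: both edge
  types are exposed rather than choosing.
* **Raman spectra**: pseudo-Voigt peaks (fixed 0.5 Gaussian/Lorentzian
  mix), intensity gain (c/c_ref)^α with α configurable (default 1,
  linear), peak centers displaced by (shift coefficient × c) — zero for
  HCl-like, nonzero for maleate-like salts — plus a polynomial baseline
  and additive Gaussian detector noise, constant in counts, so
  signal-to-noise falls with solid concentration.
* **Fluorescence background**: the baseline amplitude can (i) scale as
  max(1, c_ref/c)^q — the background grows relative to the solid signal
  only below a suspension-density threshold, (ii) grow with conversion
  (the dissolved freebase fluoresces), and (iii) jitter spectrum to
  spectrum. This term is what makes a low-concentration calibration
  genuinely unreliable: its background correlates with composition during
  calibration but scales differently on the test run, producing a bias
  that no latent-variable choice can remove. A pure intensity-scale
  concentration effect cannot reproduce that failure mode — test-run LV
  selection simply shrinks the overshoot away.
* **References**: true fractions times (1 + N(0, σ_rel)), clipped at
  zero and renormalised to closure; σ_rel defaults to 4%.
* **XRPD patterns**: weighted sums of per-form Gaussian signature peaks
  (Gaussian rather than pseudo-Voigt so windowed areas are exactly
  form-specific) with multiplicative relative noise.
* **RNG**: one seeded generator threads through all stochastic steps; the
  derived per-run seed is recorded in the run metadata and the study
  report.

## The default study

`config/default_study.yaml` holds every tuning constant of the packaged
study: two salts × four runs (50.0 / 25.0 / 12.5 mg/mL calibration,
16.7 mg/mL test), 450 min at 2-min cadence (226 spectra per run),
9–17 references per run placed early for the fast HCl-like conversion and
spread out for the slow maleate-like one; the HCl-like 50 mg/mL run omits
the transient form I (too short-lived to observe at that concentration),
so single-run calibration from that run reports form I as `N/A`.
Study-level constants: α = 0.3 (sublinear intensity response), detector
noise SD 0.02 counts, quadratic baseline [0.2, 2.3e-4, −6.5e-8],
fluorescence coupling 1.0, density exponent q = 1.0, baseline jitter SD
0.1, reference noise 4%, maleate peak-shift coefficient 0.03 cm⁻¹ per
mg/mL. These values were fixed once so that the two qualitative phenomena
the pipeline must expose — degradation of the 12.5 mg/mL single-run
calibration and uniform accuracy of the pooled calibration — emerge
reproducibly across seeds, and were then frozen.

What the generator does *not* emulate: fluorescence photobleaching,
particle-size and detector-response effects, cosmic-ray spikes,
crystal-structure-based diffraction intensities, or nonlinearities beyond
the concentration gain and baseline terms. Passing tests therefore show
that the calibration logic is correct under the stated generative model,
not that any particular real system satisfies that model.

## Numerical conventions and degenerate inputs

Sample SD (n−1) throughout; truncation bounds inclusive; SNV of a
constant spectrum, autoscaling a zero-variance channel (dropped with a
warning), empty truncation windows, unmatched references, LV counts beyond
min(n−1, p), fewer than two CV splits, and all-zero XRPD amounts each
raise a specific exception. PCA sign is fixed by making the
largest-magnitude loading element positive, so repeated fits are
bit-identical. Trajectories are renormalised to exact closure after
integration and validated to 1e-9.

## Testing strategy and problem sizes

The interference-free comparison of single-run and pooled calibrations
equalises the sampling plan across runs (15 references at common times,
no form-I omission, reference noise off) so the ratio measures the
concentration effect rather than reference-count differences; pooled
calibration retains an irreducible √n advantage of roughly 1.7× per form,
and the two procedures agree within 2× on form-averaged error. The
benchmark-vs-single-run ordering (baseline RMSECV ≤ CP RMSEP) is likewise
asserted on form-averaged errors: per form it can invert for the
easy two-polymorph salt. Tests and the acceptance script run the study at
full size (226 spectra/run, 1662 channels after truncation) — about four
seconds per study on one CPU; orchestration tests use a shortened 240-min
variant.
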