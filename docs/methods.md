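# Methods

## Model

A 1-D ¹H-NMR spectrum of serum/plasma is treated, within the lipid methyl
window 0.72–1.02 ppm, as an additive superposition of component lineshapes:
lipoprotein subclass envelopes (VLDL, LDL, HDL), one broad protein
background, and — when abnormal particles are present — the LP-X and LP-Z
methyl resonances. Writing the window intensities as a vector `y` and the
unit-area component profiles as columns of `P`, the working model is

    y = P a + ε,   a ≥ 0,

and the fit is the non-negative least squares (NNLS) solution
`â = argmin_{a≥0} ‖P a − y‖₂`, computed with the Lawson–Hanson active-set
solver (`scipy.optimize.nnls`). Optimality is verifiable through the KKT
conditions (zero gradient on the active components, nonnegative gradient on
the zero components); the test suite checks them on every class of fit, and
cross-checks the solver against an exhaustive support-set enumeration on
small instances.

Because the profiles are normalised to unit *area* (trapezoid rule on the
grid) rather than unit height, each amplitude is the integrated signal area
of its component — the quantity proportional to the amount of resonating
lipid, and hence to concentration.

### Two-pass analysis

Pass 1 fits the **standard model** (subclasses + protein background only).
The mismatch is summarised by the scale-free residual metric

    R = Σ|y − ŷ| / Σ|y|

over the window. `R` is dilution-invariant, so one threshold serves all
sample concentrations. If `R` strictly exceeds `flag_threshold` the sample
is declared to contain an abnormal lipoprotein, and pass 2 refits the
**modified model** — all standard components plus LP-X and (by default)
LP-Z, simultaneously. Unflagged samples report LP-X as not detected and are
not refit.

LP-X concentration is reported in mg/dL cholesterol units through an affine
calibration `mg/dL = f·a + b` fit from a spiking series; the default fit is
through the origin (`b = 0`), because a blank pool carries essentially zero
LP-X amplitude. Reported concentrations are floored at 0 and rounded to one
decimal.

## The synthetic component library

Measured lineshape libraries for clinical analysers are proprietary, so the
packaged default is parametric: every component is a Lorentzian
`(γ/π)/((δ−c)² + γ²)` sampled on the default grid (uniform, 0.72–1.02 ppm,
512 points ≈ 0.0006 ppm spacing) and renormalised to unit trapezoid area.

| component | centers (ppm) | FWHM (ppm) |
|---|---|---|
| VLDL large/medium/small | 0.875 / 0.865 / 0.855 | 0.025 |
| LDL large/medium/small | 0.845 / 0.835 / 0.825 | 0.020 |
| HDL large/medium/small | 0.805 / 0.795 / 0.785 | 0.015 |
| protein background | 0.850 | 0.300 |
| LP-X | 0.840 | 0.006 |
| LP-Z | 0.810 | 0.006 |

The subclass stagger and widths create the heavy overlap that makes the
deconvolution genuinely non-trivial (adjacent subclasses are separated by
well under one linewidth), while the full 10-column standard design matrix
remains numerically full-rank, so noise-free normal mixtures have a unique
nonnegative representation.

The LP-X/LP-Z centers (0.84 and 0.81 ppm, each ±0.01 ppm, enforced as
invariants) are the literature chemical shifts. Their widths are a design
choice that deserves explanation. Each *subclass* component is itself an
envelope of many particle species and is therefore intrinsically broad; the
abnormal-particle references model single, well-defined species and are
represented as much narrower lines. This separation of width scales is what
makes LP-X spectroscopically distinguishable here: quantitatively, the
standard model can absorb ~94 % of the area of a 0.020 ppm-wide Lorentzian
placed at 0.84 ppm (its NNLS projection residual is ~6 %, and the flag would
never fire at any realistic spike), but only ~10 % of the 0.006 ppm
reference, leaving a residual signature an order of magnitude above the
noise floor. With these defaults at SNR 100, normal spectra produce
`R ≈ 0.024` (never above ~0.035 in 500-sample populations), while an LP-X
spike of 70 mg/dL equivalent gives `R ≈ 0.06` — hence the default
`flag_threshold = 0.05` separates the two cleanly. The synthetic assay's
effective detection limit is ≈ 55–60 mg/dL; levels below that report 0.
Users injecting measured lineshapes should re-derive the threshold for
their library.

All library content is overridable via a JSON library file (schema
version 1) holding the grid specification plus per-component records
(name, category, center, FWHM, and either an explicit profile vector or
parameters to rebuild one).

## Synthetic data generation

`simulate_spectrum` draws `y = Σ aₖ pₖ + N(0, σ²)` i.i.d. per grid point,
deterministic under its seed. Conventions:

- **Serum background**: fixed mean amplitudes (LDL-dominated envelope,
  protein background ≈ 25 % of total area) with log-normal inter-sample
  variation (σ = 0.3) in population simulations.
- **Noise**: σ is referenced to the *unspiked* serum envelope maximum via
  `SNR = max(envelope)/σ`, default SNR 100. Acquisition noise does not grow
  with the analyte, which is what produces the characteristic precision
  profile (CV falling with concentration).
- **Concentration scale**: the simulators use a nominal conversion factor
  of 100 mg/dL per amplitude unit, making the 247 mg/dL interference-pool
  level ≈ 18 % of window signal area — commensurate with LP-X carrying
  cholesterol of the same order as the whole normal lipoprotein complement.
- **Screening populations**: LP-X spikes are log-normal (μ = 0, σ = 0.6 in
  amplitude units, median ≈ 100 mg/dL) applied with a stated prevalence.

What the simulator does *not* emulate: baseline drift and phasing errors,
chemical-shift jitter of component centers with sample matrix, lineshape
changes with temperature/field, and any chemistry of freeze–thaw damage or
interferents (interference simulations are purely spectral perturbations).
Passing tests therefore demonstrate correctness of the algorithmic chain
under the stated generative model, not instrument-grade performance on
patient sera.

## Validation statistics

- **Imprecision**: sample SD with the n−1 denominator (clinical-lab
  convention); %CV = 100·SD/mean, reported to one decimal.
- **LOB**: grand mean of all blank replicates by default; a parametric
  mean + 1.645·SD estimator is available.
- **LLOQ**: the concentration where the precision profile crosses a target
  CV (default 20 %). Pools are sorted by concentration and the crossing is
  located by log-log linear interpolation between the bracketing pools —
  exact for power-law profiles (CV ∝ 1/c), which is the shape constant
  absolute noise produces. A dense-grid crossing scan guards this choice in
  the tests.
- **Deming regression**: closed form with error-variance ratio λ
  (default 1): `slope = [s_yy − λ s_xx + √((s_yy − λ s_xx)² + 4λ s_xy²)]
  / (2 s_xy)`, `intercept = ȳ − slope·x̄`; verified against a numerical
  orthogonal-distance minimizer.
- **Linearity**: Deming fit of measured on expected; points deviating from
  the fitted line by more than a tolerance (default 10 %) are flagged, and
  the linear range is the widest contiguous unflagged span.
- **Stability**: percent bias of each timepoint against baseline; stability
  is claimed through the last point before the first run of **two or more
  consecutive** points with |bias| > 10 %. A single isolated excursion does
  not break the claim. Bias thresholds use absolute value — observed
  failures in practice are decreases, but the rule is two-sided.
- **Interference**: lowest interferent concentration whose mean result
  deviates from control by more than 10 % (absolute), else "no interference
  up to" the highest level tested.
- **Detection frequency**: 100·flagged/total, reported to two decimals.

Reporting precision mirrors clinical tables (CV one decimal, refrigerated
bias one decimal, freeze–thaw bias integer, frequency two decimals); all
internal arithmetic is full precision.

## Numerical choices and degenerate inputs

- ppm axes are normalised to descending order on input; ascending files are
  accepted and flipped with their pairing preserved.
- Resampling is piecewise-linear and never extrapolates; the fit grid is the
  intersection of the library grid, the analysis window, and the measured
  span.
- The flag comparison is strict (`R > threshold`).
- A numerically rank-deficient design matrix triggers a warning and returns
  the solver's feasible optimum (the default library never does this).
- An all-zero spectrum fits to all-zero amplitudes; the residual metric is
  undefined (error) for an all-zero measured signal.
- JCAMP-DX support covers single-block 1-D spectra with `(X++(Y..Y))` data
  in AFFN or SQZ/DIF/DUP packed form, ppm or Hz abscissae (Hz requires the
  observe frequency); NTUPLES/multi-block files are rejected.

## Problem sizes

Default test and acceptance runs use the 512-point grid, 500-spectrum
normal populations for flag specificity, 10 replicates for spike recovery,
9-level linearity series, 7-pool precision profiles with 6 replicates, and
1000 random 5-component instances for the solver/oracle comparison. These
sizes give stable statistics (Monte-Carlo error well inside the asserted
tolerances) while keeping a full run in seconds.

## Known limitations

- The default library is synthetic; absolute residual-metric levels, the
  flag threshold, and the detection limit all shift with the library and
  should be re-derived for measured lineshapes.
- The conversion factor is nominal; real deployments must calibrate against
  chemically measured cholesterol.
- Amplitude bias at very high LP-X (> ~2000 mg/dL equivalent) has not been
  characterised beyond the linearity series range.
- No FID-domain processing (apodization, phasing, baseline correction): the
  input is assumed to be a processed frequency-domain spectrum.
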