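# lpxnmr

Detection and quantification of the abnormal lipoproteins **LP-X** and
**LP-Z** from 1-D ¹H-NMR spectra of serum or plasma, by two-pass
non-negative least squares (NNLS) lineshape deconvolution of the lipid
methyl signal envelope, together with the clinical assay-validation
statistics used to characterise such a test and a synthetic-spectrum
simulator with known ground truth.

LP-X is a multilamellar, phospholipid/free-cholesterol-rich vesicular
particle that accumulates in cholestatic liver disease and familial LCAT
deficiency; LP-Z is a triglyceride- and free-cholesterol-enriched LDL-sized
particle seen in alcoholic hepatitis. Neither is accounted for by the normal
lipoprotein subclasses, so a spectrum containing them cannot be reproduced
by a standard lipoprotein deconvolution model — and that failure is itself
the detection signal. The package is aimed at clinical-chemistry and
metabolomics developers who want a transparent, testable implementation of
this idea.

## Method

The methyl resonance region (0.72–1.02 ppm) of a serum spectrum is modelled
as a nonnegative combination of unit-area component lineshapes
(VLDL/LDL/HDL subclasses, a broad protein background, and optionally LP-X at
0.84 ppm and LP-Z at 0.81 ppm):

    y(δ) ≈ Σₖ aₖ pₖ(δ),   aₖ ≥ 0,

with amplitudes `a` estimated by NNLS, `min ‖P a − y‖₂ s.t. a ≥ 0`.

1. **Pass 1** fits the *standard* model (normal components only) and
   computes a scale-free residual metric `R = Σ|y − ŷ| / Σ|y|` over the
   window. If `R` exceeds a threshold (default 0.05), the sample is flagged
   as containing an abnormal lipoprotein.
2. **Pass 2** refits flagged samples with the *modified* model (standard
   components + LP-X + LP-Z). The LP-X amplitude is converted to mg/dL
   cholesterol units via an empirically calibrated conversion factor
   (`mg/dL = f · a_LPX`, fit from a spiking series).

Validation statistics included: replicate imprecision (mean, SD, %CV),
limit of blank, lower limit of quantitation at the 20 %-CV point of the
precision profile (log-log interpolation), closed-form Deming regression
and linearity assessment, refrigerated/freeze–thaw stability under the
"two consecutive time points with |bias| > 10 %" rule, interference
screening, and screening detection frequency.

The packaged component library is synthetic and parametric (Lorentzians,
documented in `docs/methods.md`); measured lineshapes can be supplied as a
JSON library file.

## Worked example

Simulate a serum spectrum spiked with LP-X equivalent to 247 mg/dL
cholesterol, then analyse it:

```sh
lpx simulate spectrum --seed 42 --out demo --lpx-mgdl 247
lpx analyze --spectra demo/spectrum.csv --calibration 100 --out demo_out
```

prints the cohort summary

```json
{
  "n_analyzed": 1,
  "n_flagged": 1,
  "n_unreadable": 0,
  "detection_frequency_percent": 100.0,
  "config": {"flag_threshold": 0.05, "include_lpz": true}
}
```

and `demo_out/spectrum.report.json` contains, for this seed, a
standard-model residual metric of 0.163 (far above the 0.05 flag threshold:
the normal-lipoprotein model cannot absorb the LP-X resonance), a
modified-model residual metric of 0.062, and `"lpx_mgdl": 248.9` — the
spiked 247 mg/dL recovered within 1 %, with LP-Z amplitude 0 as expected.

The same pipeline is available as a library:

```python
import lpxnmr as lpx

lib = lpx.build_default_library()
spec = lpx.read_spectrum_csv("demo/spectrum.csv")   # or read_jcampdx(...)
std, mod = lpx.analyze(spec, lib)
if std.flagged:
    cal = lpx.CalibrationModel(conversion_factor=100.0)
    print(lpx.amplitude_to_cholesterol(mod.amplitudes["lpx"], cal))
```

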