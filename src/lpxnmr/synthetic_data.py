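"""Synthetic methyl-envelope spectra with known ground truth.

The generative model is exactly the assay's working assumption: a measured
envelope is the nonnegative sum of library lineshapes plus i.i.d. additive
Gaussian noise on intensity (frequency-domain NMR noise is approximately
Gaussian).  Everything downstream — deconvolution, calibration, the full
validation battery — can therefore be exercised with known truth and a
stated signal-to-noise ratio, defined as (max envelope intensity)/noise_sd.

Defaults describe a plausible normal serum: fixed mean subclass amplitudes
with log-normal inter-sample variation, optional LP-X/LP-Z spikes, and a
package conversion factor of 100 mg/dL cholesterol units per amplitude unit
linking spike sizes to the concentration scale of the assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calibration import CalibrationModel, amplitude_to_cholesterol
from .deconvolution import AnalysisConfig, analyze, fit_model
from .lineshape_library import ComponentLibrary, modified_model
from .spectra_io import Spectrum

__all__ = [
    "SimTruth",
    "DEFAULT_SERUM_AMPLITUDES",
    "DEFAULT_CONVERSION_FACTOR",
    "DEFAULT_SNR",
    "noise_sd_for_snr",
    "simulate_spectrum",
    "simulate_population",
    "simulate_calibration_series",
    "simulate_precision_pools",
]

#: Mean normal-serum amplitudes (area units) for the default library
#: components.  Chosen to give a realistic broad envelope: LDL dominates,
#: VLDL/HDL contribute comparably, and the protein background underlies
#: everything.
DEFAULT_SERUM_AMPLITUDES: dict[str, float] = {
    "vldl_large": 0.6,
    "vldl_medium": 0.8,
    "vldl_small": 0.7,
    "ldl_large": 1.2,
    "ldl_medium": 1.5,
    "ldl_small": 1.0,
    "hdl_large": 0.9,
    "hdl_medium": 1.1,
    "hdl_small": 0.8,
    "protein": 3.0,
}

#: mg/dL cholesterol units per LP-X amplitude unit used by the simulators.
#: At this scale the 247 mg/dL interference-pool level is ~18 % of window
#: signal area, commensurate with LP-X carrying cholesterol of the same
#: order as the normal lipoprotein complement.
DEFAULT_CONVERSION_FACTOR = 100.0

#: Instrument-like signal-to-noise ratio: (max normal-serum envelope
#: intensity)/noise_sd.  Noise is a property of the acquisition, so the
#: simulators reference it to the serum background envelope, not to any
#: abnormal-particle spike.
DEFAULT_SNR = 100.0

#: Log-normal sigma of inter-sample variation of serum amplitudes.
_POPULATION_SIGMA = 0.3

#: Log-normal parameters of spiked LP-X amplitudes in screening populations
#: (median e^0 = 1 amplitude unit ≈ 100 mg/dL, broad spread).
_LPX_SPIKE_MU = 0.0
_LPX_SPIKE_SIGMA = 0.6


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of one simulated spectrum."""

    amplitudes: Mapping[str, float]
    noise_sd: float
    seed: int
    lpx_mgdl_equivalent: float = 0.0  # under DEFAULT_CONVERSION_FACTOR

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("true amplitudes must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "amplitudes", dict(self.amplitudes))

    @property
    def has_lpx(self) -> bool:
        return self.amplitudes.get("lpx", 0.0) > 0


def noise_sd_for_snr(lib: ComponentLibrary, amplitudes: Mapping[str, float], snr: float) -> float:
    """Noise SD giving the stated SNR for this envelope."""
    env = _envelope(lib, amplitudes)
    return float(env.max() / snr)


def _envelope(lib: ComponentLibrary, amplitudes: Mapping[str, float]) -> np.ndarray:
    y = np.zeros_like(lib.grid)
    for name, amp in amplitudes.items():
        y = y + amp * lib[name].profile  # KeyError on unknown component
    return y


def simulate_spectrum(
    lib: ComponentLibrary, truth: SimTruth, sample_id: str = "sim"
) -> tuple[Spectrum, SimTruth]:
    """Σ amplitude·profile plus seeded i.i.d. Gaussian noise per grid point."""
    try:
        y = _envelope(lib, truth.amplitudes)
    except KeyError as exc:
        raise ValueError(f"unknown component name {exc} in truth") from exc
    if truth.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=y.size)
    return Spectrum(lib.grid, y, sample_id=sample_id), truth


def _normal_serum_truth(rng: np.random.Generator) -> dict[str, float]:
    draw = rng.lognormal(0.0, _POPULATION_SIGMA, size=len(DEFAULT_SERUM_AMPLITUDES))
    return {
        name: base * d
        for (name, base), d in zip(DEFAULT_SERUM_AMPLITUDES.items(), draw)
    }


def simulate_population(
    lib: ComponentLibrary,
    n: int,
    lpx_prevalence: float,
    seed: int,
    snr: float = DEFAULT_SNR,
    lpx_spike_lognormal: tuple[float, float] = (_LPX_SPIKE_MU, _LPX_SPIKE_SIGMA),
) -> list[tuple[Spectrum, SimTruth]]:
    """A screening cohort: normal sera, LP-X spiked with given prevalence.

    Serum amplitudes vary log-normally around the package defaults; each
    sample independently receives an LP-X spike (amplitude log-normal with
    the given parameters) with probability ``lpx_prevalence``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 <= lpx_prevalence <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    mu, sigma = lpx_spike_lognormal
    for i in range(n):
        amps = _normal_serum_truth(rng)
        lpx_amp = 0.0
        background = dict(amps)
        if rng.random() < lpx_prevalence:
            lpx_amp = float(rng.lognormal(mu, sigma))
            amps["lpx"] = lpx_amp
        noise_sd = noise_sd_for_snr(lib, background, snr)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        truth = SimTruth(
            amplitudes=amps,
            noise_sd=noise_sd,
            seed=sub_seed,
            lpx_mgdl_equivalent=lpx_amp * DEFAULT_CONVERSION_FACTOR,
        )
        out.append(simulate_spectrum(lib, truth, sample_id=f"sim{i:05d}"))
    return out


def simulate_calibration_series(
    lib: ComponentLibrary,
    factor: float = DEFAULT_CONVERSION_FACTOR,
    levels: Sequence[float] = (0, 50, 100, 200, 400, 800, 1600),
    noise_sd: float | None = None,
    seed: int = 0,
    snr: float = DEFAULT_SNR,
) -> list[tuple[float, float]]:
    """Spiking series on a fixed serum background → (fitted amplitude, level).

    Each level (mg/dL) is spiked as amplitude = level/factor; the modified
    model is fit and the recovered LP-X amplitude paired with the level, ready
    for :func:`lpxnmr.calibration.fit_conversion`.
    """
    if factor <= 0:
        raise ValueError("conversion factor must be positive")
    if any(l < 0 for l in levels):
        raise ValueError("levels must be nonnegative")
    rng = np.random.default_rng(seed)
    model = modified_model(lib)
    cfg = AnalysisConfig()
    pairs = []
    for level in levels:
        amps = dict(DEFAULT_SERUM_AMPLITUDES)
        if level > 0:
            amps["lpx"] = level / factor
        # noise referenced to the unspiked serum envelope: acquisition noise
        # does not grow with the analyte
        sd = noise_sd if noise_sd is not None else noise_sd_for_snr(
            lib, DEFAULT_SERUM_AMPLITUDES, snr)
        truth = SimTruth(amps, sd, int(rng.integers(0, 2**31 - 1)), float(level))
        spec, _ = simulate_spectrum(lib, truth)
        res = fit_model(spec, model, cfg)
        pairs.append((res.lpx_amplitude, float(level)))
    return pairs


def simulate_precision_pools(
    lib: ComponentLibrary,
    pool_mgdl: Sequence[float],
    replicates_per_pool: int,
    noise_sd: float | None = None,
    seed: int = 0,
    snr: float = DEFAULT_SNR,
    calibration: CalibrationModel | None = None,
) -> dict[float, list[float]]:
    """Replicate measurements per pool through the full pipeline.

    Each replicate simulates a spectrum of a fixed pool (serum background +
    LP-X at the pool level), runs the two-pass analysis, and converts the
    recovered amplitude to mg/dL (unflagged replicates report 0).  The
    per-pool value lists feed ``precision_summary`` and
    ``lloq_from_profile``.
    """
    if replicates_per_pool < 2:
        raise ValueError("need ≥ 2 replicates per pool")
    cal = calibration or CalibrationModel(conversion_factor=DEFAULT_CONVERSION_FACTOR)
    rng = np.random.default_rng(seed)
    cfg = AnalysisConfig()
    out: dict[float, list[float]] = {}
    for level in pool_mgdl:
        amps = dict(DEFAULT_SERUM_AMPLITUDES)
        if level > 0:
            amps["lpx"] = level / cal.conversion_factor
        sd = noise_sd if noise_sd is not None else noise_sd_for_snr(
            lib, DEFAULT_SERUM_AMPLITUDES, snr)
        values = []
        for _ in range(replicates_per_pool):
            truth = SimTruth(amps, sd, int(rng.integers(0, 2**31 - 1)), float(level))
            spec, _ = simulate_spectrum(lib, truth)
            _, mod = analyze(spec, lib, cfg)
            amp = mod.lpx_amplitude if mod is not None else 0.0
            values.append(amplitude_to_cholesterol(amp, cal))
        out[float(level)] = values
    return out
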