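"""Conversion of LP-X NMR amplitude to cholesterol concentration (mg/dL).

The deconvolved LP-X amplitude is an area in arbitrary signal units; a
spiking series (pooled serum plus known amounts of synthetic LP-X, with
chemically measured cholesterol) fixes the empirical conversion factor.
A blank pool carries essentially zero LP-X amplitude, so the default fit is
through the origin; an intercept can be estimated for matrix-effect
exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "CalibrationModel",
    "fit_conversion",
    "amplitude_to_cholesterol",
    "read_calibration_csv",
]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map amplitude → mg/dL cholesterol units."""

    conversion_factor: float  # mg/dL per amplitude unit
    intercept: float = 0.0  # mg/dL
    n_points: int = 0
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if not self.conversion_factor > 0:
            raise ValueError("conversion_factor must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


def fit_conversion(
    amplitudes: np.ndarray,
    cholesterol: np.ndarray,
    through_origin: bool = True,
) -> CalibrationModel:
    """Least squares of cholesterol (mg/dL) on LP-X amplitude.

    ``through_origin=True`` (default, matching a pure spiking design) forces
    a zero intercept; otherwise an ordinary straight-line fit is used
    (requires ≥ 3 points and non-constant amplitudes).
    """
    a = np.asarray(amplitudes, dtype=float)
    c = np.asarray(cholesterol, dtype=float)
    if a.shape != c.shape or a.ndim != 1:
        raise ValueError("amplitudes and cholesterol must be equal-length vectors")
    if np.any(a < 0):
        raise ValueError("amplitudes must be nonnegative")
    n = a.size
    if through_origin:
        if n < 1 or not np.any(a > 0):
            raise ValueError("degenerate fit: need at least one positive amplitude")
        factor = float(np.dot(a, c) / np.dot(a, a))
        intercept = 0.0
    else:
        if n < 3:
            raise ValueError("need ≥ 3 points to fit slope and intercept")
        if np.ptp(a) == 0:
            raise ValueError("degenerate fit: all amplitudes identical")
        factor, intercept = (float(v) for v in np.polyfit(a, c, 1))
        if factor <= 0:
            raise ValueError(f"fitted conversion factor {factor:.4g} is not positive")
    pred = factor * a + intercept
    ss_res = float(np.sum((c - pred) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return CalibrationModel(
        conversion_factor=factor,
        intercept=float(intercept),
        n_points=n,
        r_squared=float(min(max(r2, 0.0), 1.0)),
    )


def amplitude_to_cholesterol(amplitude: float, model: CalibrationModel) -> float:
    """LP-X amplitude → mg/dL cholesterol units, floored at 0, 1-decimal report."""
    if amplitude < 0:
        raise ValueError(f"amplitude must be nonnegative, got {amplitude}")
    mgdl = model.conversion_factor * amplitude + model.intercept
    return round(max(mgdl, 0.0), 1)


def read_calibration_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read an (amplitude, cholesterol_mgdl) series from CSV."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    try:
        a = df[cols["amplitude"]].to_numpy(dtype=float)
        c = df[cols["cholesterol_mgdl"]].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(
            f"{path}: calibration CSV needs columns 'amplitude' and "
            f"'cholesterol_mgdl' (found {list(df.columns)})"
        ) from exc
    return a, c
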