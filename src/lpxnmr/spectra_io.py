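"""Reading, writing, windowing and resampling of 1-D :sup:`1`\\ H-NMR spectra.

A :class:`Spectrum` is a plain (ppm, intensity) pair with metadata.  Chemical
shifts are normalized to *descending* ppm internally — the universal NMR
display convention — regardless of the order in the source file.  The serum
methyl region analysed by the LP-X assay is the :class:`AnalysisWindow`
0.72–1.02 ppm.

Two file formats are supported: JCAMP-DX (the standard NMR exchange format;
1-D spectra with a ppm or Hz abscissa, AFFN or SQZ/DIF/DUP packed ordinates)
and a two-column ``ppm,intensity`` CSV.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

__all__ = [
    "Spectrum",
    "AnalysisWindow",
    "SpectrumFormatError",
    "EmptyWindowError",
    "read_jcampdx",
    "write_jcampdx",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "extract_window",
    "resample_to_grid",
    "default_grid",
]


class SpectrumFormatError(ValueError):
    """A spectrum file could not be parsed or violates format invariants."""


class EmptyWindowError(ValueError):
    """An analysis window contains no spectrum points."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Spectrum:
    """One 1-D NMR spectrum: chemical-shift axis plus intensities.

    Parameters
    ----------
    ppm
        Chemical shifts in ppm, strictly monotonic.  Stored descending
        (high field → low field left to right, as spectra are displayed).
    intensity
        Signal amplitudes (arbitrary units), same length as ``ppm``.
    sample_id
        Free-text sample identifier.
    metadata
        Header records (field strength, temperature, ...) as text.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D")
        if ppm.size != intensity.size:
            raise ValueError(
                f"ppm and intensity differ in length ({ppm.size} vs {intensity.size})"
            )
        if ppm.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(ppm)
        if np.all(d > 0):  # ascending input → flip to display order
            ppm = ppm[::-1].copy()
            intensity = intensity[::-1].copy()
        elif not np.all(d < 0):
            raise ValueError("ppm axis must be strictly monotonic")
        if not np.all(np.isfinite(ppm)) or not np.all(np.isfinite(intensity)):
            raise ValueError("ppm and intensity must be finite")
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def n_points(self) -> int:
        return int(self.ppm.size)


@dataclass(frozen=True)
class AnalysisWindow:
    """A closed ppm interval; defaults to the lipid methyl region."""

    ppm_lo: float = 0.72
    ppm_hi: float = 1.02

    def __post_init__(self) -> None:
        if not self.ppm_lo < self.ppm_hi:
            raise ValueError(f"require ppm_lo < ppm_hi, got [{self.ppm_lo}, {self.ppm_hi}]")


def default_grid(window: AnalysisWindow | None = None, n_points: int = 512) -> np.ndarray:
    """Uniform descending ppm grid over *window* (default 0.72–1.02, 512 pts).

    ~0.0006 ppm spacing, far finer than the 0.01 ppm component-center
    tolerances, while keeping least-squares systems small.
    """
    w = window or AnalysisWindow()
    return np.linspace(w.ppm_hi, w.ppm_lo, n_points)


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

def read_spectrum_csv(path: str | Path) -> Spectrum:
    """Read a two-column header CSV (``ppm,intensity``) into a Spectrum."""
    import pandas as pd

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - surfacing as format error
        raise SpectrumFormatError(f"{path}: not a readable CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: expected two columns (ppm, intensity)")
    ppm = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    inten = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.isnan(ppm).any() or np.isnan(inten).any():
        raise SpectrumFormatError(f"{path}: non-numeric cells")
    if np.unique(ppm).size != ppm.size:
        raise SpectrumFormatError(f"{path}: duplicate ppm values")
    try:
        return Spectrum(ppm, inten, sample_id=path.stem)
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("ppm,intensity\n")
        for p, y in zip(s.ppm, s.intensity):
            fh.write(f"{p:.10g},{y:.10g}\n")


# ---------------------------------------------------------------------------
# JCAMP-DX
# ---------------------------------------------------------------------------
# A deliberately small dialect: single-block 1-D spectra, XYDATA=(X++(Y..Y)),
# AFFN or packed ASDF ordinates (SQZ @A-I/a-i, DIF %J-R/j-r, DUP S-Zs).
# NTUPLES / multi-block files are rejected.

_SQZ = {c: v for v, c in zip(range(10), "@ABCDEFGHI")}
_SQZ.update({c: -v for v, c in zip(range(1, 10), "abcdefghi")})
_DIF = {c: v for v, c in zip(range(10), "%JKLMNOPQR")}
_DIF.update({c: -v for v, c in zip(range(1, 10), "jklmnopqr")})
_DUP = {c: v for v, c in zip(range(1, 10), "STUVWXYZ")}
_DUP["s"] = 9

_TOKEN = re.compile(r"[@A-Za-z%][0-9.]*|[+-]?[0-9.]+(?:[eE][+-]?[0-9]+)?")


def _decode_asdf_line(line: str, last_y: float | None):
    """Decode one XYDATA line → (x_start, [y...], last_y, in_dif_mode)."""
    toks = _TOKEN.findall(line)
    if not toks:
        return None
    x_start = float(toks[0])
    ys: list[float] = []
    y = last_y
    dif_mode = False
    i = 1
    while i < len(toks):
        t = toks[i]
        c = t[0]
        if c in _SQZ:
            digits = t[1:]
            mag = _SQZ[c]
            sign = -1 if mag < 0 else 1
            y = sign * float(f"{abs(mag)}{digits}") if digits else float(mag)
            ys.append(y)
            dif_mode = False
        elif c in _DIF:
            digits = t[1:]
            mag = _DIF[c]
            if digits:
                delta = float(f"{mag}{digits}") if mag >= 0 else -float(f"{-mag}{digits}")
            else:
                delta = float(mag)
            if y is None:
                raise SpectrumFormatError("DIF ordinate with no preceding value")
            y = y + delta
            ys.append(y)
            dif_mode = True
        elif c in _DUP:
            digits = t[1:]
            count = int(f"{_DUP[c]}{digits}") if digits else _DUP[c]
            if not ys:
                raise SpectrumFormatError("DUP with no preceding ordinate")
            # repeat the previous *token*: in DIF mode repeat the delta
            if dif_mode and len(ys) >= 2:
                delta = ys[-1] - ys[-2]
                for _ in range(count - 1):
                    y = y + delta
                    ys.append(y)
            else:
                for _ in range(count - 1):
                    ys.append(ys[-1])
        else:  # plain AFFN number
            y = float(t)
            ys.append(y)
            dif_mode = False
        i += 1
    return x_start, ys, y, dif_mode


def read_jcampdx(path: str | Path) -> Spectrum:
    """Read a 1-D JCAMP-DX spectrum with a chemical-shift abscissa.

    Accepts ppm abscissae directly, or Hz when ``##.OBSERVE FREQUENCY`` is
    present (converted to ppm).  Multi-block and NTUPLES files are rejected.
    """
    path = Path(path)
    text = path.read_text()
    if text.count("##TITLE") > 1:
        raise SpectrumFormatError(f"{path}: multi-block JCAMP-DX not supported")
    if "##NTUPLES" in text.upper():
        raise SpectrumFormatError(f"{path}: NTUPLES/2-D JCAMP-DX not supported")

    header: dict[str, str] = {}
    data_lines: list[str] = []
    in_data = False
    for raw in text.splitlines():
        line = raw.split("$$")[0].rstrip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper()
            val = val.strip()
            if key == "XYDATA":
                if "X++(Y..Y)" not in val.replace(" ", ""):
                    raise SpectrumFormatError(f"{path}: unsupported XYDATA form {val!r}")
                in_data = True
                continue
            if key == "END":
                in_data = False
                continue
            header[key] = val
        elif in_data:
            data_lines.append(line)

    if not data_lines:
        raise SpectrumFormatError(f"{path}: no XYDATA block")

    xunits = header.get("XUNITS", "").upper()
    if xunits not in {"PPM", "HZ"}:
        raise SpectrumFormatError(f"{path}: unsupported or missing XUNITS {xunits!r}")
    try:
        xfactor = float(header.get("XFACTOR", "1"))
        yfactor = float(header.get("YFACTOR", "1"))
        npoints = int(float(header["NPOINTS"]))
        firstx = float(header["FIRSTX"])
        lastx = float(header["LASTX"])
    except KeyError as exc:
        raise SpectrumFormatError(f"{path}: missing header record {exc}") from exc

    ys: list[float] = []
    last_y: float | None = None
    prev_dif = False
    for line in data_lines:
        decoded = _decode_asdf_line(line, last_y)
        if decoded is None:
            continue
        _, line_ys, last_y, end_dif = decoded
        if prev_dif and line_ys:
            # after a DIF-mode line, the next line opens with a Y check value
            # that duplicates the previous line's final ordinate
            line_ys = line_ys[1:]
        ys.extend(line_ys)
        prev_dif = end_dif

    y = np.asarray(ys, dtype=float) * yfactor
    if y.size != npoints:
        raise SpectrumFormatError(f"{path}: ordinate count {y.size} != NPOINTS {npoints}")

    x = np.linspace(firstx, lastx, npoints) * xfactor
    if xunits == "HZ":
        try:
            freq_mhz = float(header[".OBSERVE FREQUENCY"])
        except KeyError as exc:
            raise SpectrumFormatError(
                f"{path}: Hz abscissa without ##.OBSERVE FREQUENCY"
            ) from exc
        x = x / freq_mhz

    meta = {
        k.lower(): v
        for k, v in header.items()
        if k not in {"XYDATA", "NPOINTS", "FIRSTX", "LASTX", "XFACTOR", "YFACTOR"}
    }
    sample_id = header.get("TITLE", path.stem)
    try:
        return Spectrum(x, y, sample_id=sample_id, metadata=meta)
    except ValueError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from exc


def write_jcampdx(s: Spectrum, path: str | Path, title: str | None = None) -> None:
    """Write a Spectrum as a minimal AFFN JCAMP-DX file (ppm abscissa)."""
    path = Path(path)
    n = s.n_points
    lines = [
        f"##TITLE={title or s.sample_id or path.stem}",
        "##JCAMP-DX=5.01",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={s.ppm[0]:.12g}",
        f"##LASTX={s.ppm[-1]:.12g}",
        f"##NPOINTS={n}",
        f"##FIRSTY={s.intensity[0]:.12g}",
        "##XYDATA=(X++(Y..Y))",
    ]
    per_line = 6
    for i in range(0, n, per_line):
        chunk = s.intensity[i : i + per_line]
        lines.append(
            f"{s.ppm[i]:.12g} " + " ".join(f"{y:.12g}" for y in chunk)
        )
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Windowing and resampling
# ---------------------------------------------------------------------------

def extract_window(s: Spectrum, w: AnalysisWindow | None = None) -> Spectrum:
    """Restrict a spectrum to ``ppm_lo ≤ ppm ≤ ppm_hi`` (order preserved)."""
    w = w or AnalysisWindow()
    mask = (s.ppm >= w.ppm_lo) & (s.ppm <= w.ppm_hi)
    if mask.sum() < 2:
        raise EmptyWindowError(
            f"window [{w.ppm_lo}, {w.ppm_hi}] contains {int(mask.sum())} spectrum point(s)"
        )
    return Spectrum(s.ppm[mask], s.intensity[mask], s.sample_id, s.metadata)


def resample_to_grid(s: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linearly interpolate a spectrum's intensity onto *grid* (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lo, hi = s.ppm[-1], s.ppm[0]  # descending storage
    if grid.min() < lo - 1e-12 or grid.max() > hi + 1e-12:
        raise ValueError(
            f"grid [{grid.min():.4f}, {grid.max():.4f}] extends beyond spectrum "
            f"span [{lo:.4f}, {hi:.4f}]; extrapolation is not supported"
        )
    # np.interp wants ascending abscissa
    y = np.interp(grid[::-1] if grid[0] > grid[-1] else grid, s.ppm[::-1], s.intensity[::-1])
    if grid[0] > grid[-1]:
        y = y[::-1]
    return Spectrum(grid, y, s.sample_id, s.metadata)
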