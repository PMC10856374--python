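"""Component lineshape libraries for methyl-envelope deconvolution.

The serum lipid methyl envelope (0.72–1.02 ppm) is modelled as a nonnegative
combination of unit-area component lineshapes: lipoprotein subclass envelopes
(VLDL, LDL, HDL), a broad protein background, and — in the *modified* model —
reference resonances for the abnormal particles LP-X (0.84 ppm) and LP-Z
(0.81 ppm).

The packaged default library is synthetic and parametric (Lorentzians).  Each
subclass component stands for an envelope of many particle species and is
therefore broad; the LP-X/LP-Z references model single well-defined species
and are substantially narrower, which is what renders them spectroscopically
distinguishable from the normal-lipoprotein span.  Users with measured
lineshapes can load them from a JSON library file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra_io import AnalysisWindow, default_grid

__all__ = [
    "CATEGORIES",
    "LineshapeComponent",
    "ComponentLibrary",
    "LibraryFormatError",
    "lorentzian_profile",
    "build_default_library",
    "standard_model",
    "modified_model",
    "save_library",
    "load_library",
    "LPX_CENTER",
    "LPZ_CENTER",
]

LIBRARY_SCHEMA_VERSION = 1

CATEGORIES = (
    "vldl_subclass",
    "ldl_subclass",
    "hdl_subclass",
    "protein_background",
    "lpx",
    "lpz",
)
_ABNORMAL = ("lpx", "lpz")

#: Chemical shifts of the abnormal-particle methyl resonances (ppm),
#: each quoted to ±0.01 ppm.
LPX_CENTER = 0.84
LPZ_CENTER = 0.81
_CENTER_TOL = 0.01

_AREA_TOL = 1e-9


class LibraryFormatError(ValueError):
    """A library file could not be parsed or violates library invariants."""


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def _trapz(y: np.ndarray, grid: np.ndarray) -> float:
    # grid is descending; integrate on the ascending copy
    return float(np.trapezoid(y[::-1], grid[::-1]))


def lorentzian_profile(center: float, fwhm: float, grid: np.ndarray) -> np.ndarray:
    """Unit-area Lorentzian sampled on *grid* and renormalized.

    The continuous Lorentzian ``(1/π)·γ / ((x−c)² + γ²)`` with half width
    ``γ = fwhm/2`` is sampled at the grid points, then rescaled so its
    trapezoid integral over the grid is exactly 1.
    """
    grid = np.asarray(grid, dtype=float)
    if fwhm <= 0:
        raise ValueError(f"fwhm must be positive, got {fwhm}")
    lo, hi = float(grid.min()), float(grid.max())
    if not lo <= center <= hi:
        raise ValueError(f"center {center} outside grid span [{lo}, {hi}]")
    gamma = fwhm / 2.0
    y = (gamma / np.pi) / ((grid - center) ** 2 + gamma**2)
    return y / _trapz(y, grid)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineshapeComponent:
    """A named unit-area lineshape on the library grid."""

    name: str
    category: str
    center: float
    width: float  # FWHM, ppm
    profile: np.ndarray

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        profile = np.asarray(self.profile, dtype=float)
        if np.any(profile < 0):
            raise ValueError(f"component {self.name!r}: profile has negative entries")
        object.__setattr__(self, "profile", profile)
        if self.category == "lpx" and abs(self.center - LPX_CENTER) > _CENTER_TOL:
            raise ValueError(
                f"LP-X center {self.center} outside {LPX_CENTER} ± {_CENTER_TOL} ppm"
            )
        if self.category == "lpz" and abs(self.center - LPZ_CENTER) > _CENTER_TOL:
            raise ValueError(
                f"LP-Z center {self.center} outside {LPZ_CENTER} ± {_CENTER_TOL} ppm"
            )


@dataclass(frozen=True)
class ComponentLibrary:
    """An ordered set of components sharing one descending ppm grid."""

    grid: np.ndarray
    components: tuple[LineshapeComponent, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        comps = tuple(self.components)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "components", comps)
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        for c in comps:
            if c.profile.size != grid.size:
                raise ValueError(
                    f"component {c.name!r}: profile length {c.profile.size} "
                    f"!= grid length {grid.size}"
                )
            area = _trapz(c.profile, grid)
            if abs(area - 1.0) > _AREA_TOL:
                raise ValueError(f"component {c.name!r}: area {area} is not 1")

    # -- access ------------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, name: str) -> LineshapeComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def design_matrix(self) -> np.ndarray:
        """Profiles as columns, in component order (n_grid × n_components)."""
        return np.column_stack([c.profile for c in self.components])

    def categories(self) -> list[str]:
        return [c.category for c in self.components]

    def validate_composition(self) -> None:
        """Check the library carries a full standard model.

        Requires ≥1 of each lipoprotein subclass category and exactly one
        protein background; LP-X/LP-Z components are optional.
        """
        cats = self.categories()
        for needed in ("vldl_subclass", "ldl_subclass", "hdl_subclass"):
            if cats.count(needed) < 1:
                raise ValueError(f"library has no {needed} component")
        if cats.count("protein_background") != 1:
            raise ValueError("library must contain exactly one protein_background")


# ---------------------------------------------------------------------------
# Default library
# ---------------------------------------------------------------------------

#: (name, category, center ppm, FWHM ppm) for the packaged synthetic default.
#: Subclass centers are staggered across 0.78–0.89 ppm with widths that make
#: neighbouring components overlap heavily; the protein background is a single
#: very broad resonance; the LP-X/LP-Z references are narrow single-species
#: lines at the literature chemical shifts.
DEFAULT_COMPONENT_SPECS: tuple[tuple[str, str, float, float], ...] = (
    ("vldl_large", "vldl_subclass", 0.875, 0.025),
    ("vldl_medium", "vldl_subclass", 0.865, 0.025),
    ("vldl_small", "vldl_subclass", 0.855, 0.025),
    ("ldl_large", "ldl_subclass", 0.845, 0.020),
    ("ldl_medium", "ldl_subclass", 0.835, 0.020),
    ("ldl_small", "ldl_subclass", 0.825, 0.020),
    ("hdl_large", "hdl_subclass", 0.805, 0.015),
    ("hdl_medium", "hdl_subclass", 0.795, 0.015),
    ("hdl_small", "hdl_subclass", 0.785, 0.015),
    ("protein", "protein_background", 0.850, 0.300),
    ("lpx", "lpx", LPX_CENTER, 0.006),
    ("lpz", "lpz", LPZ_CENTER, 0.006),
)


def build_default_library(grid: np.ndarray | None = None) -> ComponentLibrary:
    """Build the packaged synthetic default library on *grid*.

    3 VLDL + 3 LDL + 3 HDL subclass Lorentzians, one broad protein
    background, and narrow LP-X / LP-Z reference lines — 12 components.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    w = AnalysisWindow()
    if grid.max() < w.ppm_hi - 1e-9 or grid.min() > w.ppm_lo + 1e-9:
        raise ValueError("grid must cover the 0.72–1.02 ppm analysis window")
    comps = [
        LineshapeComponent(name, cat, center, fwhm, lorentzian_profile(center, fwhm, grid))
        for name, cat, center, fwhm in DEFAULT_COMPONENT_SPECS
    ]
    lib = ComponentLibrary(grid, tuple(comps))
    lib.validate_composition()
    return lib


def standard_model(lib: ComponentLibrary) -> ComponentLibrary:
    """The normal-lipoprotein model: all components except LP-X/LP-Z."""
    keep = tuple(c for c in lib.components if c.category not in _ABNORMAL)
    return ComponentLibrary(lib.grid, keep)


def modified_model(lib: ComponentLibrary, include_lpz: bool = True) -> ComponentLibrary:
    """The abnormal-lipoprotein model: standard components plus LP-X (and LP-Z).

    Raises ``ValueError`` if the library carries no LP-X component.
    """
    cats = lib.categories()
    if "lpx" not in cats:
        raise ValueError("library has no LP-X component; cannot build modified model")
    drop = () if include_lpz else ("lpz",)
    keep = tuple(c for c in lib.components if c.category not in drop)
    return ComponentLibrary(lib.grid, keep)


# ---------------------------------------------------------------------------
# Persistence (JSON, schema-versioned)
# ---------------------------------------------------------------------------

def save_library(lib: ComponentLibrary, path: str | Path) -> None:
    doc = {
        "schema_version": LIBRARY_SCHEMA_VERSION,
        "grid": {
            "ppm_hi": float(lib.grid[0]),
            "ppm_lo": float(lib.grid[-1]),
            "n_points": int(lib.grid.size),
        },
        "components": [
            {
                "name": c.name,
                "category": c.category,
                "center_ppm": c.center,
                "fwhm_ppm": c.width,
                "profile": [float(v) for v in c.profile],
            }
            for c in lib.components
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_library(path: str | Path) -> ComponentLibrary:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LibraryFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(doc, dict) or "components" not in doc or "grid" not in doc:
        raise LibraryFormatError(f"{path}: missing 'grid' or 'components'")
    if doc.get("schema_version") != LIBRARY_SCHEMA_VERSION:
        raise LibraryFormatError(
            f"{path}: unsupported schema_version {doc.get('schema_version')!r}"
        )
    g = doc["grid"]
    try:
        grid = np.linspace(float(g["ppm_hi"]), float(g["ppm_lo"]), int(g["n_points"]))
        comps = []
        for rec in doc["components"]:
            if "profile" in rec and rec["profile"] is not None:
                profile = np.asarray(rec["profile"], dtype=float)
            else:  # parametric record: rebuild the Lorentzian on the grid
                profile = lorentzian_profile(
                    float(rec["center_ppm"]), float(rec["fwhm_ppm"]), grid
                )
            comps.append(
                LineshapeComponent(
                    rec["name"],
                    rec["category"],
                    float(rec["center_ppm"]),
                    float(rec["fwhm_ppm"]),
                    profile,
                )
            )
        return ComponentLibrary(grid, tuple(comps))
    except (KeyError, TypeError, ValueError) as exc:
        raise LibraryFormatError(f"{path}: {exc}") from exc
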