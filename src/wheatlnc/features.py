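"""Spectral features: vegetation indices, continuum removal, band positions.

Three families of per-sample spectral features are computed from a canopy
ROI-mean reflectance spectrum restricted to the 400-1000 nm analysis window:

* 26 **vegetation indices** (VIs) — fixed combinations of reflectance at
  single wavelengths (R_lambda, linearly interpolated) and broadband roles
  (NIR/R/G/B, which default to 800/670/550/450 nm).
* 12 **continuum-removal parameters** — each of two absorption regions
  (557-754, 900-1000 nm) and two reflection regions (500-721, 753-959 nm)
  yields Depth, Area and their ratio ND. For absorption the continuum is the
  upper convex hull of the region; the removed curve is R/hull, the depth is
  1 - removed at its minimum, and the area is the trapezoidal integral of
  (hull - R). Reflection regions use the mirrored construction (lower convex
  chord, removed = hull/R, area of (R - hull)).
* 13 **band-position parameters** — first-derivative edge amplitudes and
  positions (blue 490-530, yellow 560-640, red 680-760 nm), green-peak and
  red-valley extrema (510-560, 650-690 nm), and edge derivative sums.

Together the last two families form the 25 "position features" (PFs).
Feature names carry the conventional field spellings (including ``A_Aear``
for the absorption area, as these parameters are usually labelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .io import Spectrum, reflectance_at

__all__ = [
    "FeatureConfig",
    "VIDefinition",
    "VI_DEFINITIONS",
    "UndefinedFeatureError",
    "compute_vi",
    "compute_all_vis",
    "ContinuumRegion",
    "continuum_remove",
    "absorption_params",
    "reflection_params",
    "band_position_params",
    "position_feature_set",
    "vi_table",
    "position_table",
]


class UndefinedFeatureError(ValueError):
    """A feature is mathematically undefined on this spectrum (e.g. 0/0)."""


@dataclass(frozen=True)
class FeatureConfig:
    """Tunables of the spectral feature extractors.

    Broadband roles (``nir``/``red``/``green``/``blue``) are the wavelengths
    substituted for RNIR/RR/RG/RB in the index formulas. Region bounds are
    the continuum-removal windows; the second absorption region is clipped
    to the 400-1000 nm analysis window. The first derivative defaults to a
    Savitzky-Golay filter (window 7, order 2) because plain differences are
    noise-sensitive at ~1.28 nm sampling; ``derivative="central"`` switches
    to central differences.
    """

    nir: float = 800.0
    red: float = 670.0
    green: float = 550.0
    blue: float = 450.0
    absorption_regions: tuple = ((557.0, 754.0), (900.0, 1000.0))
    reflection_regions: tuple = ((500.0, 721.0), (753.0, 959.0))
    derivative: str = "savgol"  # "savgol" | "central"
    sg_window: int = 7
    sg_order: int = 2
    lookup_mode: str = "linear"  # "linear" | "nearest"

    def to_dict(self) -> dict:
        return {
            "nir": self.nir, "red": self.red, "green": self.green,
            "blue": self.blue,
            "absorption_regions": [list(r) for r in self.absorption_regions],
            "reflection_regions": [list(r) for r in self.reflection_regions],
            "derivative": self.derivative, "sg_window": self.sg_window,
            "sg_order": self.sg_order, "lookup_mode": self.lookup_mode,
        }


@dataclass(frozen=True)
class VIDefinition:
    """One vegetation index: a name, the wavelengths it reads, a formula."""

    name: str
    formula: str
    func: Callable = field(repr=False, default=None)


def _make_vi_definitions() -> dict[str, VIDefinition]:
    """The 26-index library. ``R`` is the single-wavelength lookup; ``nir``,
    ``r``, ``g``, ``b`` are the configured broadband reflectances."""
    defs = [
        ("NDVIg-b#", "(R573-R440)/(R573+R440)",
         lambda R, nir, r, g, b: (R(573) - R(440)) / (R(573) + R(440))),
        ("DCNI#", "(R720-R700)/(R700-R670)/(R720-R670+0.03)",
         lambda R, nir, r, g, b:
         (R(720) - R(700)) / (R(700) - R(670)) / (R(720) - R(670) + 0.03)),
        ("NDVI I", "(R800-R670)/(R800+R670)",
         lambda R, nir, r, g, b: (R(800) - R(670)) / (R(800) + R(670))),
        ("RVI I", "R800/R670",
         lambda R, nir, r, g, b: R(800) / R(670)),
        ("DVI I", "R800-R670",
         lambda R, nir, r, g, b: R(800) - R(670)),
        ("SAVI I", "1.5*(R800-R670)/(R800+R670+0.5)",
         lambda R, nir, r, g, b:
         1.5 * (R(800) - R(670)) / (R(800) + R(670) + 0.5)),
        ("NDRE", "(R790-R720)/(R790+R720)",
         lambda R, nir, r, g, b: (R(790) - R(720)) / (R(790) + R(720))),
        ("DVI II", "RNIR-RR",
         lambda R, nir, r, g, b: nir - r),
        # As commonly printed the EVI numerator/denominator division bar is
        # implied; the standard form is used.
        ("EVI", "2.5*(RNIR-RR)/(RNIR+6*RR-7.5*RB+1)",
         lambda R, nir, r, g, b: 2.5 * (nir - r) / (nir + 6 * r - 7.5 * b + 1)),
        ("NDVI II", "(RNIR-RR)/(RNIR+RR)",
         lambda R, nir, r, g, b: (nir - r) / (nir + r)),
        ("MSAVI2", "(2*RNIR+1-sqrt((2*RNIR+1)^2-8*(RNIR-RR)))/2",
         lambda R, nir, r, g, b:
         (2 * nir + 1 - math.sqrt((2 * nir + 1) ** 2 - 8 * (nir - r))) / 2),
        ("OSAVI", "(1+0.16)*(RNIR-RR)/(RNIR+RR+0.16)",
         lambda R, nir, r, g, b: 1.16 * (nir - r) / (nir + r + 0.16)),
        ("RVI II", "RNIR/RR",
         lambda R, nir, r, g, b: nir / r),
        ("SAVI II", "1.5*(RNIR-RR)/(RNIR+RR+0.5)",
         lambda R, nir, r, g, b: 1.5 * (nir - r) / (nir + r + 0.5)),
        ("TVI", "60*(RNIR-RG)-100*(RR-RG)",
         lambda R, nir, r, g, b: 60 * (nir - g) - 100 * (r - g)),
        # Standard MTVI2; the usually-printed string drops the sqrt bars.
        ("MTVI2",
         "1.5*(1.2*(RNIR-RG)-2.5*(RR-RG))/sqrt((2*RNIR+1)^2-(6*RNIR-5*sqrt(RR))-0.5)",
         lambda R, nir, r, g, b:
         1.5 * (1.2 * (nir - g) - 2.5 * (r - g))
         / math.sqrt((2 * nir + 1) ** 2 - (6 * nir - 5 * math.sqrt(r)) - 0.5)),
        # GNDVI as conventionally tabulated alongside this VI set shares the
        # NDVI II formula (broadband NIR/R); a green-band variant exists as
        # gndvi_green() but is not part of the 26-index set.
        ("GNDVI", "(RNIR-RR)/(RNIR+RR)",
         lambda R, nir, r, g, b: (nir - r) / (nir + r)),
        # MSR here is the ratio form without the customary sqrt, implemented
        # exactly as tabulated.
        ("MSR", "(RNIR/RR-1)/(RNIR/RR+1)",
         lambda R, nir, r, g, b: (nir / r - 1) / (nir / r + 1)),
        # Standard atmospheric-resistant form with gamma = 1.
        ("ARVI", "(RNIR-(2*RR-RB))/(RNIR+(2*RR-RB))",
         lambda R, nir, r, g, b:
         (nir - (2 * r - b)) / (nir + (2 * r - b))),
        ("VOG1", "R740/R720",
         lambda R, nir, r, g, b: R(740) / R(720)),
        ("VOG2", "(R734-R747)/(R715+R726)",
         lambda R, nir, r, g, b: (R(734) - R(747)) / (R(715) + R(726))),
        ("VOG3", "(R734-R747)/(R715+R720)",
         lambda R, nir, r, g, b: (R(734) - R(747)) / (R(715) + R(720))),
        # PRI with the asymmetric 531/530 numerator/denominator wavelengths,
        # implemented exactly as tabulated.
        ("PRI", "(R531-R570)/(R530+R570)",
         lambda R, nir, r, g, b: (R(531) - R(570)) / (R(530) + R(570))),
        ("NPCI", "(R680-R430)/(R680+R430)",
         lambda R, nir, r, g, b: (R(680) - R(430)) / (R(680) + R(430))),
        ("SIPI", "(R800-R445)/(R800-R680)",
         lambda R, nir, r, g, b: (R(800) - R(445)) / (R(800) - R(680))),
        ("PSRI", "(R680-R500)/R750",
         lambda R, nir, r, g, b: (R(680) - R(500)) / R(750)),
    ]
    return {name: VIDefinition(name, formula, func)
            for name, formula, func in defs}


VI_DEFINITIONS: dict[str, VIDefinition] = _make_vi_definitions()
assert len(VI_DEFINITIONS) == 26

VI_NAMES: tuple[str, ...] = tuple(VI_DEFINITIONS)


def gndvi_green(spectrum: Spectrum, config: FeatureConfig = FeatureConfig()) -> float:
    """Green normalized-difference variant (RNIR-RG)/(RNIR+RG); not part of
    the 26-index set."""
    nir = reflectance_at(spectrum, config.nir, config.lookup_mode)
    g = reflectance_at(spectrum, config.green, config.lookup_mode)
    return (nir - g) / (nir + g)


def compute_vi(spectrum: Spectrum, name: str,
               config: FeatureConfig = FeatureConfig()) -> float:
    """Evaluate one vegetation index on *spectrum*.

    Raises :class:`UndefinedFeatureError` when a denominator vanishes and
    ``ValueError`` when a required wavelength is outside the spectrum.
    """
    try:
        definition = VI_DEFINITIONS[name]
    except KeyError:
        raise KeyError(f"unknown vegetation index {name!r}; "
                       f"known: {sorted(VI_DEFINITIONS)}") from None
    R = lambda lam: reflectance_at(spectrum, lam, config.lookup_mode)

    def _broadband(lam):
        # indices that never read this broadband must not require it, so a
        # missing broadband becomes NaN and only fails formulas that use it
        try:
            return R(lam)
        except ValueError:
            return float("nan")

    nir = _broadband(config.nir)
    r = _broadband(config.red)
    g = _broadband(config.green)
    b = _broadband(config.blue)
    try:
        with np.errstate(divide="raise", invalid="raise"):
            value = float(definition.func(R, nir, r, g, b))
    except (ZeroDivisionError, FloatingPointError) as exc:
        raise UndefinedFeatureError(
            f"{name} undefined on this spectrum: {exc}") from None
    if not np.isfinite(value):
        raise UndefinedFeatureError(f"{name} evaluated to {value}")
    return value


def compute_all_vis(spectrum: Spectrum,
                    config: FeatureConfig = FeatureConfig(),
                    errors: dict | None = None) -> dict[str, float]:
    """All 26 indices as an ordered name->value dict.

    Indices that are undefined on this spectrum are reported as NaN, with
    the reason stored in *errors* (if a dict is supplied) — they are never
    silently dropped.
    """
    out: dict[str, float] = {}
    for name in VI_DEFINITIONS:
        try:
            out[name] = compute_vi(spectrum, name, config)
        except (UndefinedFeatureError, ValueError) as exc:
            out[name] = float("nan")
            if errors is not None:
                errors[name] = str(exc)
    return out


# ---------------------------------------------------------------------------
# Continuum removal
# ---------------------------------------------------------------------------

@dataclass
class ContinuumRegion:
    """A continuum-removed spectral region.

    For ``kind="absorption"`` the hull is the upper convex hull of the
    region (hull >= spectrum, equality at the endpoints) and
    ``removed = reflectance / hull`` lies in (0, 1]. For
    ``kind="reflection"`` the hull is the lower convex chord
    (hull <= spectrum) and ``removed = hull / reflectance``.
    """

    kind: str
    wavelengths: np.ndarray
    reflectance: np.ndarray
    hull: np.ndarray
    removed: np.ndarray


def _lower_hull_indices(x: np.ndarray, y: np.ndarray) -> list[int]:
    """Monotone-chain lower convex hull indices of ((x_i, y_i)) (x sorted)."""
    stack: list[int] = []
    for i in range(len(x)):
        while len(stack) >= 2:
            o, a = stack[-2], stack[-1]
            cross = ((x[a] - x[o]) * (y[i] - y[o])
                     - (y[a] - y[o]) * (x[i] - x[o]))
            if cross <= 0:
                stack.pop()
            else:
                break
        stack.append(i)
    return stack


def continuum_remove(spectrum: Spectrum, region: tuple[float, float],
                     kind: str = "absorption") -> ContinuumRegion:
    """Continuum-remove *spectrum* on ``region = (lambda_start, lambda_end)``.

    A degenerate region (all-equal reflectance) returns ``removed`` == 1
    everywhere. Requires at least 3 bands inside the region.
    """
    if kind not in ("absorption", "reflection"):
        raise ValueError("kind must be 'absorption' or 'reflection'")
    lo, hi = region
    keep = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if keep.sum() < 3:
        raise ValueError(
            f"region [{lo}, {hi}] nm covers only {int(keep.sum())} bands "
            "(need >= 3)"
        )
    wl = spectrum.wavelengths[keep]
    r = spectrum.reflectance[keep]
    if np.ptp(r) == 0.0:
        hull = r.copy()
        removed = np.ones_like(r)
        return ContinuumRegion(kind, wl, r, hull, removed)
    if kind == "absorption":
        idx = _lower_hull_indices(wl, -r)  # upper hull = lower hull of -y
    else:
        idx = _lower_hull_indices(wl, r)
    hull = np.interp(wl, wl[idx], r[idx])
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "absorption":
            removed = np.where(hull > 0, r / hull, 1.0)
        else:
            removed = np.where(r > 0, hull / r, 1.0)
    removed = np.clip(removed, 0.0, 1.0)
    return ContinuumRegion(kind, wl, r, hull, removed)


def absorption_params(region: ContinuumRegion) -> tuple[float, float, float]:
    """(Depth, Area, ND) of an absorption region.

    Depth = 1 - R(lmin)/Rc(lmin) at the band minimising the removed curve;
    Area = trapezoidal integral of (hull - R) over the region (nm *
    reflectance); ND = Depth/Area, NaN (undefined) when Area = 0.
    """
    if region.kind != "absorption":
        raise ValueError("absorption_params requires an absorption region")
    i = int(np.argmin(region.removed))
    depth = float(1.0 - region.removed[i])
    area = float(np.trapezoid(region.hull - region.reflectance,
                              region.wavelengths))
    nd = depth / area if area > 0 else float("nan")
    return depth, area, nd


def reflection_params(region: ContinuumRegion) -> tuple[float, float, float]:
    """(Depth, Area, ND) of a reflection region (mirrored construction).

    Depth = 1 - Rc(lmax)/R(lmax) at the band where the spectrum most exceeds
    its lower chord; Area = trapezoidal integral of (R - hull).
    """
    if region.kind != "reflection":
        raise ValueError("reflection_params requires a reflection region")
    i = int(np.argmin(region.removed))
    depth = float(1.0 - region.removed[i])
    area = float(np.trapezoid(region.reflectance - region.hull,
                              region.wavelengths))
    nd = depth / area if area > 0 else float("nan")
    return depth, area, nd


# ---------------------------------------------------------------------------
# Band-position parameters
# ---------------------------------------------------------------------------

#: Wavelength windows (nm) of the edge/extremum parameters.
EDGE_WINDOWS = {
    "blue": (490.0, 530.0),
    "yellow": (560.0, 640.0),
    "red": (680.0, 760.0),
    "green_peak": (510.0, 560.0),
    "red_valley": (650.0, 690.0),
}

BAND_POSITION_NAMES = ("Db", "lambda_b", "Dy", "lambda_y", "Dr", "lambda_r",
                       "Rg", "lambda_g", "Ro", "lambda_o",
                       "SDb", "SDy", "SDr")


def first_derivative(spectrum: Spectrum,
                     config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    """First derivative of reflectance w.r.t. wavelength (per nm)."""
    wl, r = spectrum.wavelengths, spectrum.reflectance
    if config.derivative == "central":
        return np.gradient(r, wl)
    if config.derivative != "savgol":
        raise ValueError(f"unknown derivative scheme {config.derivative!r}")
    steps = np.diff(wl)
    if r.size < config.sg_window or np.ptp(steps) > 1e-6 * steps.mean():
        # short or non-uniform grid: fall back to central differences
        return np.gradient(r, wl)
    return savgol_filter(r, config.sg_window, config.sg_order, deriv=1,
                         delta=float(steps.mean()))


def band_position_params(spectrum: Spectrum,
                         config: FeatureConfig = FeatureConfig()) -> dict[str, float]:
    """The 13 waveband-position parameters.

    Db/Dy/Dr: maximum first derivative within the blue/yellow/red edge;
    lambda_b/y/r: the wavelength of that maximum; Rg/lambda_g: green-peak
    maximum reflectance and position (510-560 nm); Ro/lambda_o: red-valley
    minimum reflectance and position (650-690 nm); SDb/SDy/SDr: sum of
    first-derivative values within each edge window.
    """
    wl = spectrum.wavelengths
    if wl[0] > EDGE_WINDOWS["blue"][0] or wl[-1] < EDGE_WINDOWS["red"][1]:
        raise ValueError(
            f"spectrum ({wl[0]:.0f}-{wl[-1]:.0f} nm) does not cover "
            "the 490-760 nm edge windows"
        )
    deriv = first_derivative(spectrum, config)
    out: dict[str, float] = {}
    for edge, key in (("blue", "b"), ("yellow", "y"), ("red", "r")):
        lo, hi = EDGE_WINDOWS[edge]
        win = (wl >= lo) & (wl <= hi)
        d = deriv[win]
        i = int(np.argmax(d))
        out[f"D{key}"] = float(d[i])
        out[f"lambda_{key}"] = float(wl[win][i])
    lo, hi = EDGE_WINDOWS["green_peak"]
    win = (wl >= lo) & (wl <= hi)
    i = int(np.argmax(spectrum.reflectance[win]))
    out["Rg"] = float(spectrum.reflectance[win][i])
    out["lambda_g"] = float(wl[win][i])
    lo, hi = EDGE_WINDOWS["red_valley"]
    win = (wl >= lo) & (wl <= hi)
    i = int(np.argmin(spectrum.reflectance[win]))
    out["Ro"] = float(spectrum.reflectance[win][i])
    out["lambda_o"] = float(wl[win][i])
    for edge, key in (("blue", "b"), ("yellow", "y"), ("red", "r")):
        lo, hi = EDGE_WINDOWS[edge]
        win = (wl >= lo) & (wl <= hi)
        out[f"SD{key}"] = float(deriv[win].sum())
    return {name: out[name] for name in BAND_POSITION_NAMES}


def position_feature_set(spectrum: Spectrum,
                         config: FeatureConfig = FeatureConfig(),
                         errors: dict | None = None) -> dict[str, float]:
    """The 25 position features: 12 continuum-removal parameters (2
    absorption + 2 reflection regions x Depth/Area/ND) followed by the 13
    band-position parameters. Region failures are reported as NaN entries
    with the reason in *errors* (if supplied), never dropped."""
    out: dict[str, float] = {}
    for prefix, regions, kind, params_fn in (
        ("A", config.absorption_regions, "absorption", absorption_params),
        ("R", config.reflection_regions, "reflection", reflection_params),
    ):
        for i, bounds in enumerate(regions, start=1):
            names = (f"{prefix}_Depth{i}", f"{prefix}_Aear{i}", f"{prefix}_ND{i}")
            try:
                cr = continuum_remove(spectrum, bounds, kind)
                depth, area, nd = params_fn(cr)
                out[names[0]], out[names[1]], out[names[2]] = depth, area, nd
            except ValueError as exc:
                for n in names:
                    out[n] = float("nan")
                if errors is not None:
                    errors[f"{prefix}{i}"] = str(exc)
    try:
        out.update(band_position_params(spectrum, config))
    except ValueError as exc:
        for n in BAND_POSITION_NAMES:
            out[n] = float("nan")
        if errors is not None:
            errors["band_position"] = str(exc)
    return out


POSITION_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"A_{p}{i}" for i in (1, 2) for p in ("Depth", "Aear", "ND")]
    + [f"R_{p}{i}" for i in (1, 2) for p in ("Depth", "Aear", "ND")]
    + list(BAND_POSITION_NAMES)
)
assert len(POSITION_FEATURE_NAMES) == 25


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def vi_table(spectra: list[Spectrum],
             config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """26-column VI table indexed by sample_id."""
    rows = {s.sample_id or str(i): compute_all_vis(s, config)
            for i, s in enumerate(spectra)}
    return pd.DataFrame.from_dict(rows, orient="index")


def position_table(spectra: list[Spectrum],
                   config: FeatureConfig = FeatureConfig()) -> pd.DataFrame:
    """25-column position-feature table indexed by sample_id."""
    rows = {s.sample_id or str(i): position_feature_set(s, config)
            for i, s in enumerate(spectra)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[list(POSITION_FEATURE_NAMES)]
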