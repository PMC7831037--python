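"""Synthetic hyperspectral wheat-canopy generator with known leaf N content.

Field reflectance data for this kind of canopy study are rarely shareable, so
the package ships a generator that emulates the imaging setup the analysis
assumes: a pushbroom VNIR sensor delivering 520 bands on 360-1025 nm, canopy
plots viewed against soil background, and a leaf nitrogen content (LNC, % dry
mass) that expresses itself in the spectrum through two monotone links:

* the chlorophyll absorption well at 670 nm deepens with LNC, and
* the red-edge inflection (680-760 nm) shifts to longer wavelengths with LNC.

A canopy spectrum is composed of a low visible baseline, a Gaussian green
peak near 550 nm, a multiplicative Gaussian chlorophyll well at 670 nm, a
logistic red-edge rise onto a NIR plateau, and a Gaussian water dip near
970 nm. Soil is a linear ramp (dark blue end, brighter NIR). Cube patches mix
canopy and soil pixels; per-pixel brightness jitter and additive Gaussian
sensor noise are applied on top. Nuisance variation that is *not* driven by
LNC (per-sample illumination scaling, NIR plateau level, soil fraction)
ensures no single index determines LNC exactly, which is the regime in which
feature fusion is worth testing.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Spectrum, SpectralCube, write_envi

__all__ = [
    "SENSOR_BANDS",
    "SENSOR_RANGE_NM",
    "SENSOR_FRAME",
    "sensor_grid",
    "CanopyParams",
    "SyntheticSample",
    "params_from_lnc",
    "canopy_spectrum",
    "soil_spectrum",
    "make_sample",
    "make_dataset",
    "write_dataset",
    "load_dataset",
]

SENSOR_BANDS = 520
SENSOR_RANGE_NM = (360.0, 1025.0)
#: full sensor frame (rows, cols); desk-scale patches are the default
SENSOR_FRAME = (1040, 1392)
#: Sensor FWHM in nm. The sampling step implied by 520 bands over 360-1025 nm
#: is ~1.281 nm; 2.8 nm is treated as the optical resolution, not the step.
SENSOR_FWHM_NM = 2.8

DEFAULT_LNC_RANGE = (1.0, 5.0)  # % dry mass, typical wheat leaf N


def sensor_grid() -> np.ndarray:
    """The sensor's wavelength grid: 520 evenly spaced bands, 360-1025 nm."""
    return np.linspace(SENSOR_RANGE_NM[0], SENSOR_RANGE_NM[1], SENSOR_BANDS)


@dataclass(frozen=True)
class CanopyParams:
    """Endmember parameters for one canopy sample.

    ``chl_depth`` and ``red_edge_infl`` are the two LNC-linked parameters;
    see :func:`params_from_lnc` for the link functions. ``brightness`` is a
    per-sample illumination scaling (nuisance).
    """

    lnc: float = 3.0                 # % dry mass
    chl_depth: float = 0.6          # fractional 670 nm well depth, [0, 1]
    red_edge_infl: float = 712.0    # nm, logistic inflection in [680, 760]
    nir_plateau: float = 0.44       # reflectance, [0, 1]
    water_depth: float = 0.17       # fractional 970 nm dip depth, [0, 1]
    soil_fraction: float = 0.3      # fraction of soil pixels, [0, 1]
    noise_sd: float = 0.005         # additive sensor noise, reflectance units
    brightness: float = 1.0         # multiplicative illumination factor
    seed: int = 0

    def validate(self) -> None:
        for name in ("chl_depth", "nir_plateau", "water_depth", "soil_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 680.0 <= self.red_edge_infl <= 760.0:
            raise ValueError(
                f"red_edge_infl={self.red_edge_infl} outside [680, 760] nm"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")


@dataclass
class SyntheticSample:
    """One generated plot: cube patch, its canopy-mean spectrum, and truth."""

    cube: SpectralCube
    spectrum: Spectrum
    lnc_true: float
    year_tag: str  # "calibration" | "validation"
    canopy_mask: np.ndarray = field(repr=False, default=None)
    sample_id: str = ""


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def params_from_lnc(lnc: float, rng: np.random.Generator | None = None,
                    soil_fraction: float = 0.3, noise_sd: float = 0.005,
                    seed: int = 0) -> CanopyParams:
    """Map an LNC value to canopy parameters.

    The LNC-driven links are deterministic and monotone non-decreasing:

    * ``chl_depth = 0.35 + 0.60 * (1 - exp(-0.55 * (lnc - 1)))`` — a
      *saturating* link (0.35 at 1% N, 0.75 at 3% N, 0.88 at 5% N):
      chlorophyll absorption flattens out in dense, well-fertilised
      canopies, which is why purely chlorophyll-driven indices lose
      discrimination at high N,
    * ``red_edge_infl = clip(700 + 6 * (lnc - 1), 680, 745)``
      (700 nm at 1% N up to 724 nm at 5% N; the red edge does not
      saturate),
    * ``water_depth = clip(0.08 + 0.03 * lnc, 0, 0.5)`` (denser, wetter
      canopy at high N),
    * ``soil_fraction = clip(base + 0.18 - 0.06 * (lnc - 1), 0.05, 0.9)`` —
      nitrogen-starved wheat tillers less and covers the ground more
      sparsely, so ground cover rises with LNC. This is a *spatial* trait:
      it never enters the canopy ROI-mean spectrum (computed over canopy
      pixels only) but is plainly visible to the image-based deep features,
      which is exactly the complementary-information regime feature fusion
      is meant to exploit.

    If *rng* is given, biological/scene scatter is added around the links —
    the regime real canopies are in, where no single spectral feature
    determines LNC exactly: chl_depth jittered by U(-0.10, 0.10), the
    red-edge inflection by U(-6, 6) nm, water depth by U(-0.03, 0.03) and
    ground cover by U(-0.03, 0.03), plus LNC-independent nuisance draws
    (NIR plateau U(0.39, 0.49), illumination brightness U(0.92, 1.08)).
    The scatter magnitudes are chosen so that, as canopy N studies report,
    every single feature family is noticeably imperfect and carries partly
    complementary information, so fusing the families beats any one of them.
    """
    chl_depth = float(np.clip(
        0.35 + 0.60 * (1.0 - np.exp(-0.55 * (lnc - 1.0))), 0.0, 0.95))
    red_edge = float(np.clip(700.0 + 6.0 * (lnc - 1.0), 680.0, 745.0))
    water = float(np.clip(0.08 + 0.03 * lnc, 0.0, 0.5))
    soil_fraction = soil_fraction + 0.18 - 0.06 * (lnc - 1.0)
    nir = 0.44
    brightness = 1.0
    if rng is not None:
        chl_depth = float(np.clip(chl_depth + rng.uniform(-0.10, 0.10),
                                  0.0, 0.95))
        red_edge = float(np.clip(red_edge + rng.uniform(-6.0, 6.0),
                                 680.0, 745.0))
        water = float(np.clip(water + rng.uniform(-0.03, 0.03), 0.0, 0.5))
        nir = float(rng.uniform(0.39, 0.49))
        brightness = float(rng.uniform(0.92, 1.08))
        soil_fraction = soil_fraction + rng.uniform(-0.03, 0.03)
    soil_fraction = float(np.clip(soil_fraction, 0.05, 0.9))
    return CanopyParams(lnc=lnc, chl_depth=chl_depth, red_edge_infl=red_edge,
                        nir_plateau=nir, water_depth=water,
                        soil_fraction=soil_fraction, noise_sd=noise_sd,
                        brightness=brightness, seed=seed)


def canopy_spectrum(params: CanopyParams,
                    wavelengths: np.ndarray | None = None) -> Spectrum:
    """Deterministic canopy endmember spectrum for *params* (no pixel noise).

    With ``chl_depth = 0`` the 670 nm band equals the local baseline (no
    well); reflectance is clipped to [0, 1].
    """
    params.validate()
    wl = sensor_grid() if wavelengths is None else np.asarray(wavelengths, float)
    vis = 0.05 + 0.055 * _gauss(wl, 550.0, 18.0)
    blend = 1.0 / (1.0 + np.exp(-(wl - params.red_edge_infl) / 10.0))
    base = (1.0 - blend) * vis + blend * params.nir_plateau
    r = base * (1.0 - params.chl_depth * _gauss(wl, 670.0, 28.0))
    r = r * (1.0 - params.water_depth * _gauss(wl, 970.0, 22.0))
    r = np.clip(params.brightness * r, 0.0, 1.0)
    return Spectrum(wavelengths=wl, reflectance=r)


def soil_spectrum(wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Soil endmember: a linear ramp from 0.12 (blue) to 0.32 (NIR)."""
    wl = sensor_grid() if wavelengths is None else np.asarray(wavelengths, float)
    lo, hi = SENSOR_RANGE_NM
    return 0.12 + 0.20 * (wl - lo) / (hi - lo)


def make_sample(params: CanopyParams, patch_size=32,
                year_tag: str = "calibration",
                sample_id: str = "") -> SyntheticSample:
    """Render a cube patch for *params* and its canopy ROI-mean spectrum.

    ``patch_size`` is an int (square patch) or a (rows, cols) pair — pass
    :data:`SENSOR_FRAME` for a full 1040 x 1392 sensor frame.

    Pixels are canopy or soil (Bernoulli with ``soil_fraction``). About 30%
    of canopy pixels are self-shaded (illumination factor 0.5) — the third
    grey level that lets per-channel min-max normalised false-colour images
    retain canopy/soil contrast information. Canopy pixels additionally get
    multiplicative N(1, 0.03) brightness jitter and every pixel gets
    additive N(0, noise_sd) band noise. The sample's spectrum is the mean
    over the canopy-labelled pixels of the rendered (noisy) cube, so it is
    exactly what ROI extraction would recover.
    """
    params.validate()
    rows, cols = ((patch_size, patch_size) if np.isscalar(patch_size)
                  else tuple(patch_size))
    rng = np.random.default_rng(params.seed)
    wl = sensor_grid()
    canopy = canopy_spectrum(params).reflectance
    soil = soil_spectrum()
    mask = rng.random((rows, cols)) >= params.soil_fraction
    if not mask.any():  # guarantee at least one canopy pixel
        mask[rows // 2, cols // 2] = True
    # float32: the sensor's dynamic range is far below float32 precision,
    # and full-frame cubes would be prohibitive in float64
    values = np.empty((rows, cols, wl.size), dtype=np.float32)
    values[~mask] = soil
    n_canopy = int(mask.sum())
    shade = np.where(rng.random(n_canopy) < 0.3, 0.5, 1.0)
    jitter = shade[:, None] * rng.normal(1.0, 0.03, size=(n_canopy, 1))
    values[mask] = jitter * canopy
    if params.noise_sd > 0:
        values += rng.normal(0.0, params.noise_sd,
                             size=values.shape).astype(np.float32)
    values = np.clip(values, 0.0, 1.0)
    cube = SpectralCube(values=values, wavelengths=wl,
                        meta={"lnc_true": params.lnc, "seed": params.seed})
    spectrum = Spectrum(wavelengths=wl, reflectance=values[mask].mean(axis=0),
                        sample_id=sample_id)
    return SyntheticSample(cube=cube, spectrum=spectrum, lnc_true=params.lnc,
                           year_tag=year_tag, canopy_mask=mask,
                           sample_id=sample_id)


def make_dataset(n: int = 200, split: float = 0.7, noise_sd: float = 0.005,
                 seed: int = 0, lnc_range: tuple[float, float] = DEFAULT_LNC_RANGE,
                 soil_fraction: float = 0.3, patch_size=32,
                 nuisance: bool = True) -> list[SyntheticSample]:
    """Generate *n* samples, tagged calibration/validation by *split*.

    LNC is drawn uniformly from *lnc_range*; the first ``round(split * n)``
    samples are the calibration set (the stand-in for a first field season)
    and the rest the validation set (the second season). ``nuisance=False``
    disables all LNC-independent variation, giving noiseless deterministic
    links (plus sensor noise if ``noise_sd > 0``).
    """
    if n < 4:
        raise ValueError("need n >= 4 to populate both splits")
    if not 0.0 < split < 1.0:
        raise ValueError("split must be in (0, 1)")
    n_cal = int(round(split * n))
    if n_cal < 1 or n - n_cal < 1:
        raise ValueError(f"split {split} leaves an empty set for n={n}")
    rng = np.random.default_rng(seed)
    lnc_values = rng.uniform(lnc_range[0], lnc_range[1], size=n)
    sample_seeds = rng.integers(0, 2**31 - 1, size=n)
    samples = []
    for i in range(n):
        params = params_from_lnc(
            float(lnc_values[i]), rng=rng if nuisance else None,
            soil_fraction=soil_fraction, noise_sd=noise_sd,
            seed=int(sample_seeds[i]),
        )
        tag = "calibration" if i < n_cal else "validation"
        samples.append(make_sample(params, patch_size=patch_size, year_tag=tag,
                                   sample_id=f"S{i:04d}"))
    return samples


def write_dataset(samples: list[SyntheticSample], out_dir: str | Path) -> Path:
    """Write ENVI cubes plus a ground-truth table (sample_id, lnc_true, split)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        write_envi(s.cube, out_dir / f"{s.sample_id}.hdr")
        rows.append({"sample_id": s.sample_id, "lnc_true": s.lnc_true,
                     "split": s.year_tag})
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "ground_truth.tsv", sep="\t", index=False,
                 float_format="%.8g")
    return out_dir


def load_dataset(in_dir: str | Path) -> list[SyntheticSample]:
    """Reload a dataset written by :func:`write_dataset` (or real data laid
    out the same way: one ENVI cube per sample plus ground_truth.tsv)."""
    from .io import read_envi, roi_mean_spectrum

    in_dir = Path(in_dir)
    truth_path = in_dir / "ground_truth.tsv"
    if not truth_path.exists():
        raise FileNotFoundError(f"no ground_truth.tsv in {in_dir}")
    truth = pd.read_csv(truth_path, sep="\t")
    samples = []
    for _, row in truth.iterrows():
        hdr = in_dir / f"{row['sample_id']}.hdr"
        if not hdr.exists():
            raise FileNotFoundError(f"missing cube {hdr}")
        cube = read_envi(hdr)
        spectrum = roi_mean_spectrum(cube, sample_id=str(row["sample_id"]))
        samples.append(SyntheticSample(
            cube=cube, spectrum=spectrum, lnc_true=float(row["lnc_true"]),
            year_tag=str(row["split"]), canopy_mask=None,
            sample_id=str(row["sample_id"]),
        ))
    return samples
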