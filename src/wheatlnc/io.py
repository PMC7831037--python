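"""Hyperspectral cube and spectrum containers with ENVI-format I/O.

The analysis operates on two in-memory objects: a :class:`SpectralCube`
(rows x cols x bands reflectance with a per-band wavelength grid) and a
:class:`Spectrum` (the canopy region-of-interest mean of one sample's cube).
Cubes travel on disk in the ENVI convention — a plain-text ``.hdr`` header
next to a raw binary file whose band/line/pixel ordering is declared by the
header's ``interleave`` keyword (bsq, bil or bip). Spectra travel as a
delimited table with a wavelength column followed by one column per sample.

Wavelengths are always nanometres in memory; headers declaring micrometres
are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralCube",
    "read_envi",
    "write_envi",
    "roi_mean_spectrum",
    "ndvi_mask",
    "restrict",
    "reflectance_at",
    "read_mask",
    "read_spectra_table",
    "write_spectra_table",
]

# ENVI "data type" codes -> numpy dtypes (the subset this package reads/writes)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}

_INTERLEAVES = ("bsq", "bil", "bip")


@dataclass
class Spectrum:
    """One sample's reflectance curve on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.ndim != 1 or self.reflectance.ndim != 1:
            raise ValueError("wavelengths and reflectance must be 1-D")
        if self.wavelengths.size != self.reflectance.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.reflectance.size} reflectance values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass
class SpectralCube:
    """Reflectance cube (rows, cols, bands) with per-band wavelengths in nm.

    Negative reflectances are physically suspect but can arise from upstream
    calibration; they are flagged in ``meta['n_negative']`` rather than
    silently clipped.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    interleave: str = "bsq"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (rows, cols, bands)")
        if self.wavelengths.size != self.values.shape[2]:
            raise ValueError(
                f"{self.wavelengths.size} wavelengths for "
                f"{self.values.shape[2]} bands"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.interleave not in _INTERLEAVES:
            raise ValueError(f"interleave must be one of {_INTERLEAVES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube contains non-finite values")
        n_neg = int(np.count_nonzero(self.values < 0))
        if n_neg:
            self.meta.setdefault("n_negative", n_neg)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def _axes_for(interleave: str) -> tuple[int, int, int]:
    """Axis order (from (rows, cols, bands)) of the on-disk layout."""
    return {
        "bsq": (2, 0, 1),  # band, line, pixel
        "bil": (0, 2, 1),  # line, band, pixel
        "bip": (0, 1, 2),  # line, pixel, band
    }[interleave]


def write_envi(cube: SpectralCube, header_path: str | Path,
               data_path: str | Path | None = None) -> Path:
    """Write *cube* as an ENVI text header plus raw binary; returns header path."""
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".raw")
    data_path = Path(data_path)
    rows, cols, bands = cube.shape
    arr = np.ascontiguousarray(
        np.transpose(cube.values.astype(np.float32), _axes_for(cube.interleave))
    )
    arr.tofile(data_path)
    wl = ",\n".join(
        " , ".join(f"{w:.6f}" for w in cube.wavelengths[i:i + 8])
        for i in range(0, len(cube.wavelengths), 8)
    )
    lines = [
        "ENVI",
        "description = {wheatlnc synthetic reflectance cube}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(np.float32)]}",
        f"interleave = {cube.interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {",
        wl,
        "}",
    ]
    header_path.write_text("\n".join(lines) + "\n")
    return header_path


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    in_block = False
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper() == "ENVI":
            continue
        if in_block:
            buf.append(line)
            if line.endswith("}"):
                fields[key] = " ".join(buf).rstrip("}").strip()
                in_block = False
            continue
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        key = key.strip().lower()
        val = val.strip()
        if val.startswith("{") and not val.endswith("}"):
            in_block = True
            buf = [val.lstrip("{").strip()]
        else:
            fields[key] = val.strip("{}").strip()
    return fields


def read_envi(header_path: str | Path,
              data_path: str | Path | None = None) -> SpectralCube:
    """Read an ENVI header/binary pair into a :class:`SpectralCube`.

    Raises if the header lacks a wavelength block or if the binary's byte
    count disagrees with the declared dimensions.
    """
    header_path = Path(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        cols = int(fields["samples"])
        rows = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:  # pragma: no cover - malformed header
        raise ValueError(f"ENVI header missing dimension key: {exc}") from exc
    interleave = fields.get("interleave", "bsq").lower()
    if interleave not in _INTERLEAVES:
        raise ValueError(f"unsupported interleave {interleave!r}")
    dtype_code = int(fields.get("data type", 4))
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    if "wavelength" not in fields:
        raise ValueError("ENVI header has no wavelength block")
    wavelengths = np.array(
        [float(tok) for tok in fields["wavelength"].replace(",", " ").split()]
    )
    units = fields.get("wavelength units", "nanometers").lower()
    if units.startswith("micro") or (wavelengths.size and wavelengths.max() < 100):
        wavelengths = wavelengths * 1000.0
    if data_path is None:
        for suffix in (".raw", ".img", ".dat", ".bsq", ".bil", ".bip", ""):
            cand = header_path.with_suffix(suffix)
            if cand != header_path and cand.exists():
                data_path = cand
                break
        else:
            raise FileNotFoundError(f"no binary found next to {header_path}")
    data_path = Path(data_path)
    offset = int(fields.get("header offset", 0))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = rows * cols * bands
    if raw.size != expected:
        raise ValueError(
            f"{data_path.name}: {raw.size} values on disk but header declares "
            f"{rows}x{cols}x{bands} = {expected}"
        )
    disk_shapes = {
        "bsq": (bands, rows, cols),
        "bil": (rows, bands, cols),
        "bip": (rows, cols, bands),
    }
    arr = raw.reshape(disk_shapes[interleave])
    inverse = np.argsort(_axes_for(interleave))
    values = np.transpose(arr, inverse).astype(np.float64)
    return SpectralCube(values=values, wavelengths=wavelengths,
                        interleave=interleave, meta={"source": str(header_path)})


def ndvi_mask(cube: SpectralCube, threshold: float = 0.3,
              nir: float = 800.0, red: float = 670.0) -> np.ndarray:
    """Boolean canopy mask from per-pixel NDVI > *threshold*.

    The default threshold 0.3 separates green canopy from soil background;
    NDVI uses linearly interpolated per-pixel reflectance at the NIR and red
    wavelengths.
    """
    r_nir = _plane_at(cube, nir)
    r_red = _plane_at(cube, red)
    denom = r_nir + r_red
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(denom != 0, (r_nir - r_red) / denom, 0.0)
    return ndvi > threshold


def _plane_at(cube: SpectralCube, target: float) -> np.ndarray:
    """Per-pixel reflectance image at *target* nm (linear band interpolation)."""
    wl = cube.wavelengths
    if not (wl[0] <= target <= wl[-1]):
        raise ValueError(f"wavelength {target} nm outside cube range "
                         f"[{wl[0]}, {wl[-1]}]")
    hi = int(np.searchsorted(wl, target))
    if wl[hi] == target:
        return cube.values[:, :, hi]
    lo = hi - 1
    t = (target - wl[lo]) / (wl[hi] - wl[lo])
    return (1 - t) * cube.values[:, :, lo] + t * cube.values[:, :, hi]


def roi_mean_spectrum(cube: SpectralCube, mask: np.ndarray | None = None,
                      sample_id: str = "") -> Spectrum:
    """Per-band arithmetic mean over masked pixels.

    With no mask supplied, an NDVI > 0.3 canopy mask is used (the package's
    stated convention for delineating canopy against soil background).
    """
    if mask is None:
        mask = ndvi_mask(cube)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.values.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} != cube spatial shape "
            f"{cube.values.shape[:2]}"
        )
    if not mask.any():
        raise ValueError("ROI mask selects no pixels")
    mean = cube.values[mask].mean(axis=0)
    return Spectrum(wavelengths=cube.wavelengths.copy(), reflectance=mean,
                    sample_id=sample_id)


def restrict(spectrum: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep bands with lo <= wavelength <= hi, preserving order."""
    if lo >= hi:
        raise ValueError(f"invalid window [{lo}, {hi}]")
    keep = (spectrum.wavelengths >= lo) & (spectrum.wavelengths <= hi)
    if not keep.any():
        raise ValueError(
            f"window [{lo}, {hi}] nm contains no bands of the spectrum "
            f"({spectrum.wavelengths[0]}-{spectrum.wavelengths[-1]} nm)"
        )
    return Spectrum(wavelengths=spectrum.wavelengths[keep],
                    reflectance=spectrum.reflectance[keep],
                    sample_id=spectrum.sample_id)


def reflectance_at(spectrum: Spectrum, target: float,
                   mode: str = "linear") -> float:
    """Reflectance at *target* nm by linear interpolation (default) or
    nearest band. An exact band hit returns that band's value either way."""
    wl = spectrum.wavelengths
    if not (wl[0] <= target <= wl[-1]):
        raise ValueError(
            f"wavelength {target} nm outside spectrum range [{wl[0]}, {wl[-1]}]"
        )
    if mode == "nearest":
        return float(spectrum.reflectance[int(np.argmin(np.abs(wl - target)))])
    if mode != "linear":
        raise ValueError(f"unknown lookup mode {mode!r}")
    return float(np.interp(target, wl, spectrum.reflectance))


def read_mask(path: str | Path) -> np.ndarray:
    """Load an ROI mask: a delimited 0/1 grid (.txt/.tsv/.csv) or an image
    file (e.g. PNG, any nonzero pixel is in the ROI)."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".tsv", ".csv", ".dat"):
        delim = "," if path.suffix.lower() == ".csv" else None
        return np.loadtxt(path, delimiter=delim) != 0
    from skimage.io import imread

    img = imread(path)
    if img.ndim == 3:
        img = img[..., :3].max(axis=-1)
    return np.asarray(img) != 0


def write_spectra_table(spectra: list[Spectrum], path: str | Path,
                        sep: str = "\t") -> Path:
    """Delimited table: first column wavelength_nm, one column per sample."""
    if not spectra:
        raise ValueError("no spectra to write")
    wl = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, wl):
            raise ValueError("spectra are not on a common wavelength grid")
    df = pd.DataFrame({"wavelength_nm": wl})
    for i, s in enumerate(spectra):
        df[s.sample_id or f"sample_{i:04d}"] = s.reflectance
    path = Path(path)
    df.to_csv(path, sep=sep, index=False, float_format="%.8g")
    return path


def read_spectra_table(path: str | Path, sep: str = "\t") -> list[Spectrum]:
    df = pd.read_csv(path, sep=sep)
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"sample {col!r} has missing reflectance values")
        out.append(Spectrum(wavelengths=wl, reflectance=vals, sample_id=str(col)))
    return out
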