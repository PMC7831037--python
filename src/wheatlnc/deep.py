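"""Deep features: a 256-dim CNN descriptor of a false-colour canopy image.

Each sample's hyperspectral cube is rendered to a 3-channel false-colour
image (default bands 800/670/550 nm -> NIR/red/green channels, per-channel
min-max normalised, bilinearly resized to 224 x 224) and pushed through an
AlexNet-shaped network: five convolutional layers, three max-pooling layers
and a two-layer fully connected head whose second layer (FC2) is 256 wide.
The FC2 activations are the sample's deep feature vector DF_000..DF_255.

The forward pass is pure numpy (im2col convolutions), so extraction is a
deterministic function of (image, weights, architecture). Weights are
pluggable: a file of trained convolutional weights can be loaded, and with
none supplied a documented seeded He-normal initialisation is used — i.e.
the extractor acts as a structured random projection of the image, which
still transports the monotone LNC signal present in the band intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _resize

from .io import SpectralCube, _plane_at

__all__ = [
    "CnnSpec",
    "AlexNetFeatureExtractor",
    "cube_to_image",
    "deep_feature_table",
    "DEEP_FEATURE_NAMES",
]

DEEP_FEATURE_DIM = 256
DEEP_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"DF_{i:03d}" for i in range(DEEP_FEATURE_DIM)
)


@dataclass(frozen=True)
class CnnSpec:
    """Architecture of the extractor.

    ``conv`` rows are (out_channels, kernel, stride, pad); ``pool_after``
    lists the conv indices followed by a 3x3 stride-2 max pool. The trunk is
    AlexNet's (5 conv + 3 pool); the head is two fully connected layers with
    the second fixed at 256 outputs. FC1 width 1024 is a package choice (the
    canonical 4096-wide head is replaced by this two-layer 256-out head).
    """

    input_size: int = 224
    in_channels: int = 3
    conv: tuple = (
        (96, 11, 4, 2),
        (256, 5, 1, 2),
        (384, 3, 1, 1),
        (384, 3, 1, 1),
        (256, 3, 1, 1),
    )
    pool_after: tuple = (0, 1, 4)
    fc: tuple = (1024, DEEP_FEATURE_DIM)

    def layer_counts(self) -> dict[str, int]:
        return {"conv": len(self.conv), "pool": len(self.pool_after),
                "fc": len(self.fc)}

    def flat_dim(self) -> int:
        """Flattened feature-map size entering FC1."""
        s = self.input_size
        c = self.in_channels
        for i, (out_c, k, stride, pad) in enumerate(self.conv):
            s = (s + 2 * pad - k) // stride + 1
            c = out_c
            if i in self.pool_after:
                s = (s - 3) // 2 + 1
        return c * s * s


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray,
            stride: int, pad: int) -> np.ndarray:
    """x: (C, H, W); w: (O, C, k, k) -> (O, H', W') via im2col matmul."""
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    k = w.shape[2]
    win = sliding_window_view(x, (k, k), axis=(1, 2))  # (C, H-k+1, W-k+1, k, k)
    win = win[:, ::stride, ::stride]
    _, ho, wo, _, _ = win.shape
    cols = win.transpose(1, 2, 0, 3, 4).reshape(ho * wo, -1)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(ho, wo, w.shape[0]).transpose(2, 0, 1)


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2) -> np.ndarray:
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(-1, -2))


class AlexNetFeatureExtractor:
    """Forward-only CNN feature extractor with pluggable weights.

    Parameters
    ----------
    spec : CnnSpec
        Architecture; defaults to the 5-conv/3-pool/2-FC shape with a
        256-wide FC2.
    weights : dict | None
        Mapping ``conv{i}_w/conv{i}_b/fc{i}_w/fc{i}_b`` -> arrays. When
        None, He-normal random weights are drawn from *seed*.
    seed : int
        Seed of the random initialisation (ignored when weights are given).
    """

    def __init__(self, spec: CnnSpec = CnnSpec(),
                 weights: dict | None = None, seed: int = 0):
        self.spec = spec
        if weights is None:
            weights = self._random_weights(spec, seed)
            self.extractor_id = f"alexnet-fc256/random-seed{seed}"
        else:
            digest = sum(int(np.abs(v).sum() * 1e3) for v in weights.values())
            self.extractor_id = f"alexnet-fc256/weights-{digest % 10**8:08d}"
        self._check_weights(weights)
        self.weights = weights

    @staticmethod
    def _random_weights(spec: CnnSpec, seed: int) -> dict:
        rng = np.random.default_rng(seed)
        w: dict[str, np.ndarray] = {}
        c_in = spec.in_channels
        for i, (c_out, k, _, _) in enumerate(spec.conv):
            fan_in = c_in * k * k
            w[f"conv{i}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k)
            ).astype(np.float32)
            w[f"conv{i}_b"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        d_in = spec.flat_dim()
        for i, d_out in enumerate(spec.fc):
            w[f"fc{i}_w"] = rng.normal(
                0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)
            ).astype(np.float32)
            w[f"fc{i}_b"] = np.zeros(d_out, dtype=np.float32)
            d_in = d_out
        return w

    def _check_weights(self, weights: dict) -> None:
        c_in = self.spec.in_channels
        for i, (c_out, k, _, _) in enumerate(self.spec.conv):
            expect = (c_out, c_in, k, k)
            got = weights[f"conv{i}_w"].shape
            if got != expect:
                raise ValueError(f"conv{i}_w shape {got}, expected {expect}")
            c_in = c_out
        d_in = self.spec.flat_dim()
        for i, d_out in enumerate(self.spec.fc):
            expect = (d_out, d_in)
            got = weights[f"fc{i}_w"].shape
            if got != expect:
                raise ValueError(f"fc{i}_w shape {got}, expected {expect}")
            d_in = d_out

    @classmethod
    def from_npz(cls, path: str | Path, spec: CnnSpec = CnnSpec()
                 ) -> "AlexNetFeatureExtractor":
        """Load weights from a portable .npz container with named layer keys."""
        with np.load(path) as data:
            weights = {k: data[k] for k in data.files}
        return cls(spec=spec, weights=weights)

    def save_npz(self, path: str | Path) -> Path:
        path = Path(path)
        np.savez(path, **self.weights)
        return path

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return self.extract(image)

    def extract(self, image: np.ndarray) -> np.ndarray:
        """FC2 activations (length 256, float64) of one (3, H, W) image."""
        image = np.asarray(image, dtype=np.float32)
        expected = (self.spec.in_channels, self.spec.input_size,
                    self.spec.input_size)
        if image.shape != expected:
            raise ValueError(f"image shape {image.shape}, expected {expected}")
        x = image
        for i, (_, k, stride, pad) in enumerate(self.spec.conv):
            x = _conv2d(x, self.weights[f"conv{i}_w"],
                        self.weights[f"conv{i}_b"], stride, pad)
            np.maximum(x, 0.0, out=x)  # ReLU
            if i in self.spec.pool_after:
                x = _maxpool(x)
        x = x.reshape(-1)
        n_fc = len(self.spec.fc)
        for i in range(n_fc):
            x = self.weights[f"fc{i}_w"] @ x + self.weights[f"fc{i}_b"]
            if i < n_fc - 1:
                np.maximum(x, 0.0, out=x)  # ReLU on FC1; FC2 output is linear
        out = x.astype(np.float64)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite deep features")
        return out


def cube_to_image(cube: SpectralCube,
                  band_triplet: tuple[float, float, float] = (800.0, 670.0, 550.0),
                  size: int = 224) -> np.ndarray:
    """False-colour (3, size, size) image of *cube*.

    Each channel is the cube's reflectance plane at the requested wavelength
    (linear band interpolation), min-max normalised to [0, 1] (a zero-range
    channel maps to all zeros), and bilinearly resized; a cube already at the
    target spatial size is passed through unresampled.
    """
    channels = []
    for lam in band_triplet:
        plane = _plane_at(cube, lam)
        rng_ = plane.max() - plane.min()
        plane = (plane - plane.min()) / rng_ if rng_ > 0 else np.zeros_like(plane)
        if plane.shape != (size, size):
            plane = _resize(plane, (size, size), order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
        channels.append(plane.astype(np.float32))
    return np.stack(channels, axis=0)


def deep_feature_table(cubes: list[SpectralCube],
                       extractor: AlexNetFeatureExtractor,
                       sample_ids: list[str] | None = None,
                       band_triplet: tuple[float, float, float] = (800.0, 670.0, 550.0),
                       ) -> pd.DataFrame:
    """256-column DF table (DF_000..DF_255) indexed by sample_id."""
    if sample_ids is None:
        sample_ids = [f"sample_{i:04d}" for i in range(len(cubes))]
    rows = []
    for cube in cubes:
        image = cube_to_image(cube, band_triplet, extractor.spec.input_size)
        rows.append(extractor.extract(image))
    return pd.DataFrame(np.asarray(rows), index=sample_ids,
                        columns=list(DEEP_FEATURE_NAMES))
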