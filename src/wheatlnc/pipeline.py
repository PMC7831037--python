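"""End-to-end orchestration: synth -> features -> selection -> models -> report.

A :class:`RunConfig` captures every tunable of a run (generator settings,
analysis window, region bounds, broadband wavelengths, derivative scheme,
CNN triplet and weights path, selection rules, model hyperparameters, seed).
:func:`run` executes the stages in order, persists every intermediate table
under the output directory, and writes a ``manifest.json`` recording the
full resolved configuration — rerunning with the same config and seed
reproduces all outputs bit for bit.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .deep import AlexNetFeatureExtractor
from .features import FeatureConfig
from .model import LncModel, LncResults, SelectionConfig, build_feature_table
from .regression import ModelConfig
from .synthetic import DEFAULT_LNC_RANGE, load_dataset, make_dataset, write_dataset

__all__ = ["RunConfig", "run", "demo"]


@dataclass
class RunConfig:
    """Fully serialisable configuration of one pipeline run."""

    # input: synthetic generator (default) or a cube directory in real-data mode
    input_dir: str | None = None
    n: int = 200
    split: float = 0.7
    noise_sd: float = 0.005
    lnc_range: tuple = DEFAULT_LNC_RANGE
    soil_fraction: float = 0.3
    patch_size: int = 32
    nuisance: bool = True
    # analysis
    analysis_window: tuple = (400.0, 1000.0)
    nir: float = 800.0
    red: float = 670.0
    green: float = 550.0
    blue: float = 450.0
    absorption_regions: tuple = ((557.0, 754.0), (900.0, 1000.0))
    reflection_regions: tuple = ((500.0, 721.0), (753.0, 959.0))
    derivative: str = "savgol"
    # deep features
    cnn_triplet: tuple = (800.0, 670.0, 550.0)
    cnn_weights: str | None = None
    # selection
    vi_fraction: float = 0.3
    pf_fraction: float = 0.3
    df_threshold: float = 0.45
    df_cap: int = 20
    df_fallback_top_k: bool = True
    rf_trees: int = 500
    # models
    pls_components: int = 5
    svr_c: float = 10.0
    svr_gamma: str | float = "auto"
    gbdt_learning_rate: float = 0.1
    gbdt_estimators: int = 300
    gbdt_depth: int = 3
    seed: int = 0

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(nir=self.nir, red=self.red, green=self.green,
                             blue=self.blue,
                             absorption_regions=tuple(
                                 tuple(r) for r in self.absorption_regions),
                             reflection_regions=tuple(
                                 tuple(r) for r in self.reflection_regions),
                             derivative=self.derivative)

    def selection_config(self) -> SelectionConfig:
        return SelectionConfig(vi_fraction=self.vi_fraction,
                               pf_fraction=self.pf_fraction,
                               df_threshold=self.df_threshold,
                               df_cap=self.df_cap,
                               df_fallback_top_k=self.df_fallback_top_k,
                               rf_trees=self.rf_trees)

    def model_configs(self) -> dict[str, ModelConfig]:
        return {
            "PLS": ModelConfig("pls", {"n_components": self.pls_components},
                               seed=self.seed),
            "SVR": ModelConfig("svr", {"kernel": "rbf", "C": self.svr_c,
                                       "gamma": self.svr_gamma,
                                       }, seed=self.seed),
            "GBDT": ModelConfig("gbdt",
                                {"learning_rate": self.gbdt_learning_rate,
                                 "n_estimators": self.gbdt_estimators,
                                 "max_depth": self.gbdt_depth},
                                seed=self.seed),
        }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("lnc_range", "analysis_window", "cnn_triplet",
                    "absorption_regions", "reflection_regions"):
            if key in data and data[key] is not None:
                data[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v
                    for v in data[key])
        return cls(**data)


def _log(msg: str, log_file=None) -> None:
    print(f"[wheatlnc] {msg}", file=sys.stderr)
    if log_file is not None:
        log_file.write(msg + "\n")


def run(config: RunConfig, out_dir: str | Path,
        save_cubes: bool = False) -> LncResults:
    """Execute the full pipeline; artifacts land under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    with log_path.open("w") as log_file:
        if config.input_dir is not None:
            in_dir = Path(config.input_dir)
            if not in_dir.is_dir():
                raise FileNotFoundError(
                    f"input_dir {in_dir} does not exist (real-data mode)")
            _log(f"loading dataset from {in_dir}", log_file)
            samples = load_dataset(in_dir)
        else:
            _log(f"generating synthetic dataset n={config.n} "
                 f"noise_sd={config.noise_sd} seed={config.seed}", log_file)
            samples = make_dataset(n=config.n, split=config.split,
                                   noise_sd=config.noise_sd, seed=config.seed,
                                   lnc_range=tuple(config.lnc_range),
                                   soil_fraction=config.soil_fraction,
                                   patch_size=config.patch_size,
                                   nuisance=config.nuisance)
            if save_cubes:
                write_dataset(samples, out_dir / "cubes")
        if config.cnn_weights is not None:
            extractor = AlexNetFeatureExtractor.from_npz(config.cnn_weights)
        else:
            extractor = AlexNetFeatureExtractor(seed=config.seed)
        _log(f"extracting features (extractor {extractor.extractor_id})",
             log_file)
        table = build_feature_table(
            samples, config.feature_config(), extractor,
            band_triplet=tuple(config.cnn_triplet),
            analysis_window=tuple(config.analysis_window))
        table.to_csv(out_dir / "features.tsv", sep="\t",
                     float_format="%.10g")
        _write_feature_meta(out_dir, config, extractor)
        _log("ranking and selecting features", log_file)
        model = LncModel.from_dataframe(
            table, selection=config.selection_config(),
            model_configs=config.model_configs(), seed=config.seed)
        results = model.fit()
        _log("fitting model grid and writing report", log_file)
        results.save(out_dir)
        manifest = {
            "package": "wheatlnc",
            "version": __version__,
            "config": config.to_dict(),
            "extractor_id": extractor.extractor_id,
            "n_samples": len(samples),
            "n_variables": results.n_variables(),
        }
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=list) + "\n")
        # path goes to stderr only: the log file's content must not depend
        # on where the run directory lives (bit-reproducibility)
        print(f"[wheatlnc] done; artifacts in {out_dir}", file=sys.stderr)
        log_file.write("done\n")
    return results


def _write_feature_meta(out_dir: Path, config: RunConfig,
                        extractor: AlexNetFeatureExtractor) -> None:
    """Sidecar metadata: feature class per column and the exact extraction
    config."""
    from .deep import DEEP_FEATURE_NAMES
    from .features import POSITION_FEATURE_NAMES, VI_NAMES

    classes = {name: "VI" for name in VI_NAMES}
    classes.update({name: "PF" for name in POSITION_FEATURE_NAMES})
    classes.update({name: "DF" for name in DEEP_FEATURE_NAMES})
    meta = {
        "feature_classes": classes,
        "feature_config": config.feature_config().to_dict(),
        "cnn_triplet": list(config.cnn_triplet),
        "extractor_id": extractor.extractor_id,
        "analysis_window": list(config.analysis_window),
    }
    (out_dir / "features.meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def demo(out_dir: str | Path, seed: int = 0, n: int = 200) -> LncResults:
    """Single-command synthetic experiment with all defaults."""
    return run(RunConfig(n=n, seed=seed), out_dir)
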