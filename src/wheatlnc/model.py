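"""Top-level modelling objects: :class:`LncModel` and :class:`LncResults`.

This is the package's statsmodels-style front door. An :class:`LncModel` is
built from a per-sample feature table (vegetation indices + position
features + deep features), the measured leaf nitrogen content, and the
calibration/validation split tags. ``fit()`` runs feature selection on the
calibration samples (RF importance for VIs and DFs, |Pearson r| for PFs),
fuses the retained sets, fits the PLS/SVR/GBDT grid on the four feature
sets, and returns an :class:`LncResults` carrying the selections, the
fusion set, the evaluation grid and per-sample predictions, with a
``summary()`` text table.

>>> model = LncModel.from_samples(samples)      # samples from make_dataset
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .deep import AlexNetFeatureExtractor, DEEP_FEATURE_NAMES, deep_feature_table
from .features import (FeatureConfig, POSITION_FEATURE_NAMES, VI_NAMES,
                       position_table, vi_table)
from .io import restrict
from .regression import (EvalReport, ModelConfig, compare,
                         default_model_configs)
from .selection import (FusionSet, SelectionResult, fuse, select_by_correlation,
                        select_by_importance, select_deep, rf_importance,
                        rank_features)

__all__ = ["SelectionConfig", "LncModel", "LncResults", "build_feature_table"]

ANALYSIS_WINDOW_NM = (400.0, 1000.0)


@dataclass(frozen=True)
class SelectionConfig:
    """Retention rules for the three feature families."""

    vi_fraction: float = 0.3
    pf_fraction: float = 0.3
    df_threshold: float = 0.45
    df_cap: int = 20
    df_fallback_top_k: bool = True
    rf_trees: int = 500

    def to_dict(self) -> dict:
        return {"vi_fraction": self.vi_fraction,
                "pf_fraction": self.pf_fraction,
                "df_threshold": self.df_threshold, "df_cap": self.df_cap,
                "df_fallback_top_k": self.df_fallback_top_k,
                "rf_trees": self.rf_trees}


def build_feature_table(samples, feature_config: FeatureConfig | None = None,
                        extractor: AlexNetFeatureExtractor | None = None,
                        band_triplet=(800.0, 670.0, 550.0),
                        analysis_window=ANALYSIS_WINDOW_NM,
                        with_deep: bool = True) -> pd.DataFrame:
    """Per-sample feature table (26 VIs + 25 PFs [+ 256 DFs]) with ``lnc``
    and ``split`` columns, from a list of synthetic or loaded samples."""
    feature_config = feature_config or FeatureConfig()
    spectra = [restrict(s.spectrum, *analysis_window) for s in samples]
    for sp, s in zip(spectra, samples):
        sp.sample_id = s.sample_id
    vis = vi_table(spectra, feature_config)
    pfs = position_table(spectra, feature_config)
    parts = [vis, pfs]
    if with_deep:
        extractor = extractor or AlexNetFeatureExtractor(seed=0)
        dfs = deep_feature_table([s.cube for s in samples], extractor,
                                 sample_ids=[s.sample_id for s in samples],
                                 band_triplet=band_triplet)
        parts.append(dfs)
    table = pd.concat(parts, axis=1)
    table.insert(0, "lnc", [s.lnc_true for s in samples])
    table.insert(1, "split", [s.year_tag for s in samples])
    table.index.name = "sample_id"
    return table


class LncModel:
    """LNC estimation model over a fused spectral + deep feature table.

    Parameters
    ----------
    features : DataFrame
        Samples x features; any subset of the known VI/PF/DF columns.
    lnc : array-like
        Measured leaf nitrogen content (% dry mass) per sample.
    split : array-like of str
        "calibration" / "validation" tag per sample.
    selection : SelectionConfig
    model_configs : dict[str, ModelConfig], optional
        Defaults to the PLS/SVR/GBDT trio.
    seed : int
        Seeds the RF importance ranker and GBDT.
    """

    def __init__(self, features: pd.DataFrame, lnc, split,
                 selection: SelectionConfig = SelectionConfig(),
                 model_configs: dict[str, ModelConfig] | None = None,
                 seed: int = 0):
        self.features = features
        self.lnc = np.asarray(lnc, dtype=float)
        self.split = np.asarray(split, dtype=object)
        if len(self.features) != len(self.lnc) or len(self.lnc) != len(self.split):
            raise ValueError("features, lnc and split must have equal length")
        tags = set(self.split)
        if not tags <= {"calibration", "validation"}:
            raise ValueError(f"unknown split tags: {tags}")
        if "calibration" not in tags or "validation" not in tags:
            raise ValueError("need both calibration and validation samples")
        self.selection = selection
        self.model_configs = model_configs or default_model_configs(seed)
        self.seed = seed
        self.vi_columns = [c for c in features.columns if c in set(VI_NAMES)]
        self.pf_columns = [c for c in features.columns
                           if c in set(POSITION_FEATURE_NAMES)]
        self.df_columns = [c for c in features.columns
                           if c in set(DEEP_FEATURE_NAMES)]

    @classmethod
    def from_samples(cls, samples, feature_config: FeatureConfig | None = None,
                     extractor: AlexNetFeatureExtractor | None = None,
                     selection: SelectionConfig = SelectionConfig(),
                     model_configs: dict[str, ModelConfig] | None = None,
                     seed: int = 0, **feature_kwargs) -> "LncModel":
        """Build the model straight from generated/loaded samples."""
        if extractor is None:
            extractor = AlexNetFeatureExtractor(seed=seed)
        table = build_feature_table(samples, feature_config, extractor,
                                    **feature_kwargs)
        return cls.from_dataframe(table, selection=selection,
                                  model_configs=model_configs, seed=seed)

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "LncModel":
        """From a table holding ``lnc`` and ``split`` columns plus features."""
        for col in ("lnc", "split"):
            if col not in table.columns:
                raise ValueError(f"table lacks required column {col!r}")
        feats = table.drop(columns=["lnc", "split"])
        return cls(feats, table["lnc"], table["split"], **kwargs)

    @property
    def cal_mask(self) -> np.ndarray:
        return self.split == "calibration"

    def fit(self) -> "LncResults":
        """Select, fuse, fit the model grid; returns :class:`LncResults`."""
        cal = self.cal_mask
        y_cal = self.lnc[cal]
        y_val = self.lnc[~cal]
        sel = self.selection
        selections: dict[str, SelectionResult] = {}
        if self.vi_columns:
            selections["VIs"] = select_by_importance(
                self.features.loc[cal, self.vi_columns], y_cal,
                fraction=sel.vi_fraction, n_trees=sel.rf_trees, seed=self.seed)
        if self.pf_columns:
            selections["PFs"] = select_by_correlation(
                self.features.loc[cal, self.pf_columns], y_cal,
                fraction=sel.pf_fraction)
        if self.df_columns:
            df_scores = rf_importance(self.features.loc[cal, self.df_columns],
                                      y_cal, n_trees=sel.rf_trees,
                                      seed=self.seed)
            retained = select_deep(df_scores, threshold=sel.df_threshold,
                                   cap=sel.df_cap,
                                   fallback_top_k=sel.df_fallback_top_k)
            selections["DFs"] = SelectionResult(
                "rf_importance", df_scores, rank_features(df_scores), retained,
                rule=f"threshold({sel.df_threshold})+cap({sel.df_cap})"
                     + ("+top_k_fallback" if sel.df_fallback_top_k else ""))
        fusion = fuse(selections["VIs"].retained if "VIs" in selections else [],
                      selections["PFs"].retained if "PFs" in selections else [],
                      selections["DFs"].retained if "DFs" in selections else [])
        feature_sets = {}
        for label in ("VIs", "PFs", "DFs"):
            if label in selections:
                cols = selections[label].retained
                feature_sets[label] = (self.features.loc[cal, cols],
                                      self.features.loc[~cal, cols])
        feature_sets["FFs"] = (self.features.loc[cal, fusion.features],
                               self.features.loc[~cal, fusion.features])
        report = compare(feature_sets, y_cal, y_val, self.model_configs)
        return LncResults(model=self, selections=selections, fusion=fusion,
                          report=report)


@dataclass
class LncResults:
    """Fitted selections, fusion set, and the model x feature-set grid."""

    model: LncModel
    selections: dict
    fusion: FusionSet
    report: EvalReport
    extras: dict = field(default_factory=dict)

    @property
    def table(self) -> pd.DataFrame:
        return self.report.table

    def n_variables(self) -> dict[str, int]:
        """Retained feature counts per set (the Preferred Variables column)."""
        out = {label: len(sel.retained) for label, sel in self.selections.items()}
        out["FFs"] = len(self.fusion)
        return out

    def summary(self) -> str:
        counts = self.n_variables()
        lines = [
            "Wheat LNC estimation — feature selection and model comparison",
            "=" * 62,
            "Retained features: "
            + ", ".join(f"{k}={v}" for k, v in counts.items()),
            "",
            self.report.to_text(),
            "",
            "R2 = 1 - SS_res/SS_tot; RMSE in % dry-mass LNC.",
            "Selection fitted on calibration samples only.",
        ]
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> Path:
        """Persist selections, report and predictions as delimited text."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for label, sel in self.selections.items():
            sel.save(out_dir / f"selection_{label}.tsv")
        self.report.table.to_csv(out_dir / "report.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        preds = []
        for (model_name, set_name), df in self.report.predictions.items():
            df = df.copy()
            df.insert(0, "model", model_name)
            df.insert(1, "feature_set", set_name)
            preds.append(df)
        if preds:
            pd.concat(preds, ignore_index=True).to_csv(
                out_dir / "predictions.tsv", sep="\t", index=False,
                float_format="%.10g")
        (out_dir / "summary.txt").write_text(self.summary() + "\n")
        return out_dir

    def plot_predictions(self, model_name: str = "GBDT",
                         feature_set: str = "FFs", ax=None):
        """Observed-vs-predicted scatter for one grid cell (matplotlib)."""
        import matplotlib.pyplot as plt

        df = self.report.predictions[(model_name, feature_set)]
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        for split, marker in (("calibration", "o"), ("validation", "s")):
            sub = df[df["split"] == split]
            ax.scatter(sub["lnc_obs"], sub["lnc_pred"], s=12, marker=marker,
                       label=split, alpha=0.7)
        lims = [df[["lnc_obs", "lnc_pred"]].min().min(),
                df[["lnc_obs", "lnc_pred"]].max().max()]
        ax.plot(lims, lims, "k--", lw=0.8)
        ax.set_xlabel("measured LNC (%)")
        ax.set_ylabel("estimated LNC (%)")
        ax.set_title(f"{model_name} / {feature_set}")
        ax.legend(frameon=False, fontsize=8)
        return ax
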