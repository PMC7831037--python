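"""Feature ranking, retention rules, and fusion.

Two rankers are used, matched to the feature family:

* **Random-forest permutation importance** (VIs and deep features): each
  tree of a seeded regression forest is fitted on a bootstrap sample; the
  increase in out-of-bag (OOB) mean squared error when one feature's OOB
  column is permuted, averaged over trees, is that feature's raw importance.
  Negative raw importances are floored at 0 and scores are normalised to
  max = 1 ("relative importance").
* **Absolute Pearson correlation** |r| with LNC (position features), with r
  computed from the textbook product-moment formula.

Retention rules: ``top 30%`` with round-half-down (26 -> 8, 25 -> 7), and a
threshold-with-cap rule for deep features (relative importance > 0.45, at
most the first 20; a top-k fallback guarantees the cap binds on data where
the absolute threshold is meaningless). Retained sets are fused by ordered
concatenation VI -> PF -> DF.

Selection always operates on calibration samples only.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

__all__ = [
    "SelectionResult",
    "FusionSet",
    "pearson_r",
    "rf_importance",
    "rank_features",
    "select_top_fraction",
    "select_deep",
    "select_by_importance",
    "select_by_correlation",
    "fuse",
]


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined (a zero-variance input)."""


def pearson_r(x, y) -> float:
    """Product-moment correlation r = sum((X-Xbar)(Y-Ybar)) /
    sqrt(sum((X-Xbar)^2) * sum((Y-Ybar)^2)), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("zero-variance input")
    r = float(xc @ yc) / math.sqrt(sxx * syy)
    return float(np.clip(r, -1.0, 1.0))


def rf_importance(X, y, n_trees: int = 500, seed: int = 0,
                  max_features: float | None = None, min_samples_leaf: int = 3,
                  normalize: bool = True) -> pd.Series:
    """OOB permutation importance of each feature for a regression target.

    For each of *n_trees* bootstrap trees, the OOB mean squared error is
    measured before and after permuting each feature's OOB values (one
    shared permutation per tree, so scores are exactly equivariant under
    column reordering); the mean error increase over trees is the raw
    importance. Raw importances are floored at 0 and (by default)
    normalised so the largest equals 1. Trees consider all features at each
    split (the library default for regression forests); set *max_features*
    to subsample split candidates.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xv = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if names is None:
        names = [f"f{j}" for j in range(p)]
    if n < 10:
        raise ValueError(f"need >= 10 samples, got {n}")
    if p < 2:
        raise ValueError("need >= 2 features")
    if np.ptp(yv) == 0.0:
        raise ValueError("constant target")
    if not np.all(np.isfinite(Xv)):
        raise ValueError("feature table contains non-finite values")
    rng = np.random.default_rng(seed)
    imp = np.zeros(p)
    used = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        inbag = np.zeros(n, dtype=bool)
        inbag[boot] = True
        oob = np.flatnonzero(~inbag)
        tree_seed = int(rng.integers(0, 2**31 - 1))
        if oob.size < 2:
            continue
        tree = DecisionTreeRegressor(max_features=max_features,
                                     min_samples_leaf=min_samples_leaf,
                                     random_state=tree_seed)
        tree.fit(Xv[boot], yv[boot])
        Xo = Xv[oob]
        m = oob.size
        # one predict call per tree: rows [0:m] unpermuted, then one block
        # per feature with that feature's column permuted
        perm = rng.permutation(m)
        big = np.tile(Xo, (p + 1, 1))
        for j in range(p):
            big[(j + 1) * m:(j + 2) * m, j] = Xo[perm, j]
        preds = tree.predict(big).reshape(p + 1, m)
        errs = ((preds - yv[oob]) ** 2).mean(axis=1)
        imp += errs[1:] - errs[0]
        used += 1
    if used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    imp = np.maximum(imp / used, 0.0)
    if normalize and imp.max() > 0:
        imp = imp / imp.max()
    return pd.Series(imp, index=names)


def rank_features(scores: pd.Series) -> list[str]:
    """Feature names by descending score; ties broken lexicographically."""
    return sorted(scores.index, key=lambda f: (-float(scores[f]), str(f)))


def select_top_fraction(ranked: list[str], fraction: float) -> list[str]:
    """Retain the top round-half-down(fraction * n) features (at least 1).

    Round-half-down reproduces the conventional counts for these libraries:
    0.3 x 26 = 7.8 -> 8 and 0.3 x 25 = 7.5 -> 7.
    """
    if not ranked:
        raise ValueError("empty ranking")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    k = max(1, math.ceil(fraction * len(ranked) - 0.5))
    return list(ranked[:k])


def select_deep(scores: pd.Series, threshold: float = 0.45, cap: int = 20,
                fallback_top_k: bool = True) -> list[str]:
    """Deep-feature retention: relative importance > *threshold*, keeping at
    most the first *cap* by rank.

    With ``fallback_top_k`` (the default), fewer than *cap* features above
    the threshold fall back to the plain top-*cap* by rank, so the cap binds
    on data whose importance distribution never crosses the threshold. With
    the fallback off, an empty result is allowed (with a warning).
    """
    mx = float(scores.max())
    if mx > 0 and abs(mx - 1.0) > 1e-9:
        scores = scores / mx  # defensive renormalisation to max = 1
    ranked = rank_features(scores)
    above = [f for f in ranked if float(scores[f]) > threshold]
    retained = above[:cap]
    if fallback_top_k and len(retained) < cap:
        retained = ranked[:cap]
    if not retained:
        warnings.warn("deep-feature selection retained zero features",
                      stacklevel=2)
    return retained


@dataclass
class SelectionResult:
    """Ranked scores and the retained subset of one feature family."""

    method: str  # "rf_importance" | "pearson_abs_r"
    scores: pd.Series
    ranked: list[str]
    retained: list[str]
    rule: str

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.ranked,
                           "score": [float(self.scores[f]) for f in self.ranked]})
        df["retained"] = df["feature"].isin(set(self.retained))
        return df

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")
        manifest = {"method": self.method, "rule": self.rule,
                    "retained": list(self.retained)}
        path.with_suffix(".json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def select_by_importance(X: pd.DataFrame, y, fraction: float = 0.3,
                         n_trees: int = 500, seed: int = 0) -> SelectionResult:
    """Rank by RF permutation importance, keep the top *fraction*."""
    scores = rf_importance(X, y, n_trees=n_trees, seed=seed)
    ranked = rank_features(scores)
    retained = select_top_fraction(ranked, fraction)
    return SelectionResult("rf_importance", scores, ranked, retained,
                           rule=f"top_fraction({fraction})")


def select_by_correlation(X: pd.DataFrame, y, fraction: float = 0.3
                          ) -> SelectionResult:
    """Rank by |Pearson r| with the target, keep the top *fraction*.

    Zero-variance features score 0 (with a warning) rather than aborting the
    whole family."""
    yv = np.asarray(y, dtype=float)
    scores = {}
    for col in X.columns:
        try:
            scores[col] = abs(pearson_r(X[col].to_numpy(), yv))
        except UndefinedCorrelationError:
            warnings.warn(f"feature {col!r} has zero variance; |r| set to 0",
                          stacklevel=2)
            scores[col] = 0.0
    scores = pd.Series(scores)
    ranked = rank_features(scores)
    retained = select_top_fraction(ranked, fraction)
    return SelectionResult("pearson_abs_r", scores, ranked, retained,
                           rule=f"top_fraction({fraction})")


@dataclass
class FusionSet:
    """Ordered union of the retained VIs, PFs and DFs, with provenance."""

    features: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)


def fuse(vi_retained: list[str], pf_retained: list[str],
         df_retained: list[str]) -> FusionSet:
    """Concatenate the retained families in VI -> PF -> DF order.

    Duplicate names across families are an error (the name spaces must be
    disjoint for downstream column addressing)."""
    features = list(vi_retained) + list(pf_retained) + list(df_retained)
    if len(set(features)) != len(features):
        seen, dups = set(), set()
        for f in features:
            (dups if f in seen else seen).add(f)
        raise ValueError(f"duplicate feature names across families: {sorted(dups)}")
    provenance = {f: "VI" for f in vi_retained}
    provenance.update({f: "PF" for f in pf_retained})
    provenance.update({f: "DF" for f in df_retained})
    return FusionSet(features=features, provenance=provenance)
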