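"""Boosted-regression-tree sub-models and the 25-member ensemble.

Each sub-model is stagewise additive logistic boosting (Bernoulli deviance):
shallow regression trees of depth <= ``tree_complexity`` are fit to the
negative deviance gradient on a ``bag_fraction`` subsample and added with
shrinkage ``learning_rate``; the number of trees is selected by stratified
ten-fold cross-validation on the held-out deviance, following the standard
ecological BRT protocol. LightGBM provides the boosting engine (all the
controls above map one-to-one onto its parameters, with single-threaded
deterministic training); tree-count selection, ensemble aggregation, AUC,
relative influence, and partial dependence are implemented here.

Fitting is a pure function of the training *set*: rows are canonically
ordered (lexicographic over features and label) before any seeded operation,
so shuffling input rows cannot change the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .raster import CovariateStack, Raster, SuitabilityMap
from .sampling import BackgroundDraw, PresenceCells


@dataclass(frozen=True)
class BRTConfig:
    """Boosting hyper-parameters (ecological-BRT defaults)."""

    learning_rate: float = 0.005
    tree_complexity: int = 4
    bag_fraction: float = 0.75
    n_folds: int = 10
    step_size: int = 50
    max_trees: int = 10_000
    min_obs_in_leaf: int = 10
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate > 0:
            raise ValidationError("learning_rate must be > 0")
        if self.tree_complexity < 1:
            raise ValidationError("tree_complexity must be >= 1")
        if not 0 < self.bag_fraction <= 1:
            raise ValidationError("bag_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.step_size > self.max_trees:
            raise ValidationError("step_size must not exceed max_trees")

    def lgb_params(self, seed: int) -> dict:
        return dict(objective="binary", learning_rate=self.learning_rate,
                    max_depth=self.tree_complexity,
                    num_leaves=2 ** self.tree_complexity,
                    bagging_fraction=self.bag_fraction, bagging_freq=1,
                    min_data_in_leaf=self.min_obs_in_leaf,
                    feature_fraction=1.0, deterministic=True,
                    force_row_wise=True, num_threads=1, verbose=-1,
                    seed=int(seed) % (2 ** 31))


@dataclass
class SubModel:
    """One fitted boosted-tree sub-model plus its training context."""

    booster: lgb.Booster | None
    feature_names: list[str]
    categorical_features: list[str]
    n_trees: int
    learning_rate: float
    intercept: float  # log-odds of training prevalence
    train_X: pd.DataFrame | None = None
    train_y: np.ndarray | None = None
    draw_index: int | None = None
    seed: int | None = None
    cv_deviance: pd.DataFrame | None = None
    fold_auc: list[float] = field(default_factory=list)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Suitability scores in [0, 1] for a feature table."""
        if self.booster is None or self.n_trees == 0:
            p = 1.0 / (1.0 + np.exp(-self.intercept))
            return np.full(len(X), p)
        missing = [f for f in self.feature_names if f not in X.columns]
        if missing:
            raise ValidationError(f"feature table lacks layers: {missing}")
        return self.booster.predict(X[self.feature_names],
                                    num_iteration=self.n_trees)


def _canonical_order(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    """Permutation sorting rows lexicographically by (features..., label)."""
    keys = [np.asarray(y)] + [X[c].to_numpy() for c in reversed(X.columns)]
    return np.lexsort(keys)


def assemble_training(presences: PresenceCells, draw: BackgroundDraw,
                      stack: CovariateStack):
    """Feature table + binary labels for one presence/background pairing.

    Returns ``(X, y, cells)``: one row per cell (presences labelled 1, the
    draw's background cells 0), features looked up from every stack layer.
    """
    cells = np.vstack([presences.cells, draw.cells])
    y = np.concatenate([np.ones(len(presences), dtype=int),
                        np.zeros(len(draw), dtype=int)])
    valid = stack.joint_valid()
    if not valid[cells[:, 0], cells[:, 1]].all():
        bad = cells[~valid[cells[:, 0], cells[:, 1]]][:3]
        raise ValidationError(f"training cells on nodata, e.g. {bad.tolist()}")
    data = {}
    for name, layer in stack.layers.items():
        vals = layer.values[cells[:, 0], cells[:, 1]]
        if name in stack.categorical_layers:
            vals = vals.astype(np.int32)
        data[name] = vals
    X = pd.DataFrame(data)
    return X, y, cells


def fit_brt(X: pd.DataFrame, y: np.ndarray, config: BRTConfig, n_trees: int,
            seed: int, categorical: list[str] | None = None) -> SubModel:
    """Fit one sub-model with a fixed tree count. Deterministic given seed."""
    y = np.asarray(y)
    if n_trees < 1:
        raise ValidationError("n_trees must be >= 1")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    if categorical is None:
        categorical = [c for c in X.columns
                       if isinstance(X[c].dtype, pd.CategoricalDtype)
                       or X[c].dtype.kind in "iu" and c == "soil_class"]
    order = _canonical_order(X, y)
    Xs, ys = X.iloc[order].reset_index(drop=True), y[order]
    dset = lgb.Dataset(Xs, label=ys,
                       categorical_feature=categorical or "auto",
                       free_raw_data=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        booster = lgb.train(config.lgb_params(seed), dset,
                            num_boost_round=n_trees)
    prev = ys.mean()
    intercept = float(np.log(prev / (1 - prev)))
    return SubModel(booster, list(X.columns), list(categorical),
                    n_trees, config.learning_rate, intercept,
                    train_X=Xs, train_y=ys, seed=seed)


@dataclass
class TreeSelection:
    """CV tree-count selection result."""

    n_trees: int
    steps: np.ndarray
    cv_deviance: np.ndarray  # mean held-out Bernoulli deviance at each step
    fold_auc: list[float]    # held-out AUC per fold at the selected count

    @property
    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({"n_trees": self.steps,
                             "cv_deviance": self.cv_deviance})


def select_n_trees(X: pd.DataFrame, y: np.ndarray, config: BRTConfig,
                   seed: int, categorical: list[str] | None = None
                   ) -> tuple[int, TreeSelection]:
    """Pick the tree count minimizing mean held-out deviance over CV folds.

    Trees are evaluated at ``step_size`` increments up to ``max_trees``; ties
    break toward the smallest count, and a minimum sitting at the boundary
    triggers a warning (more trees might still help).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("labels contain a single class")
    if categorical is None:
        categorical = [c for c in X.columns if c == "soil_class"]
    order = _canonical_order(X, y)
    Xs, ys = X.iloc[order].reset_index(drop=True), y[order]
    if min(np.bincount(ys)) < config.n_folds:
        raise ValidationError(
            f"cannot stratify {config.n_folds} folds: minority class has "
            f"{min(np.bincount(ys))} rows")
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=int(seed) % (2 ** 31))
    steps = np.arange(config.step_size, config.max_trees + 1, config.step_size)
    if steps[-1] != config.max_trees:
        steps = np.append(steps, config.max_trees)
    fold_models, fold_valid, traces = [], [], []
    params = config.lgb_params(seed)
    for tr_idx, va_idx in skf.split(Xs, ys):
        dtr = lgb.Dataset(Xs.iloc[tr_idx], label=ys[tr_idx],
                          categorical_feature=categorical or "auto",
                          free_raw_data=False)
        dva = lgb.Dataset(Xs.iloc[va_idx], label=ys[va_idx], reference=dtr)
        ev: dict = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=UserWarning)
            booster = lgb.train(params, dtr, num_boost_round=config.max_trees,
                                valid_sets=[dva], valid_names=["held_out"],
                                callbacks=[lgb.record_evaluation(ev)])
        # Bernoulli deviance = 2 x mean negative log-likelihood
        traces.append(2.0 * np.asarray(ev["held_out"]["binary_logloss"]))
        fold_models.append(booster)
        fold_valid.append(va_idx)
    mean_dev = np.mean(traces, axis=0)[steps - 1]
    best = int(steps[int(np.argmin(mean_dev))])
    if best == int(steps[-1]):
        warnings.warn("CV deviance minimum at max_trees; the optimum may lie "
                      "beyond the search range", stacklevel=2)
    fold_auc = []
    for booster, va_idx in zip(fold_models, fold_valid):
        scores = booster.predict(Xs.iloc[va_idx], num_iteration=best)
        fold_auc.append(roc_auc(ys[va_idx], scores))
    return best, TreeSelection(best, steps, mean_dev, fold_auc)


def predict_map(sub: SubModel, stack: CovariateStack) -> SuitabilityMap:
    """Per-cell suitability over the stack's joint-valid domain."""
    missing = [f for f in sub.feature_names if f not in stack.layers]
    if missing:
        raise ValidationError(f"stack lacks model layers: {missing}")
    valid = stack.joint_valid()
    rows, cols = np.nonzero(valid)
    X = pd.DataFrame({name: stack.layers[name].values[rows, cols]
                      for name in sub.feature_names})
    scores = sub.predict(X)
    out = np.zeros(stack.grid.shape)
    out[rows, cols] = scores
    return SuitabilityMap(Raster(stack.grid, out, ~valid))


def roc_auc(labels, scores) -> float:
    """Rank-based AUC: P(random positive outscores random negative), ties 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def relative_influence(sub: SubModel) -> pd.Series:
    """Per-variable relative contribution (%) from accumulated split gains.

    Each split's improvement in the boosting objective is credited to its
    split variable; totals are normalized to sum to 100.
    """
    if sub.booster is None or sub.n_trees == 0:
        raise ValidationError("relative influence needs a fitted model with "
                              ">= 1 tree")
    gains = np.asarray(
        sub.booster.feature_importance(importance_type="gain",
                                       iteration=sub.n_trees), dtype=float)
    total = gains.sum()
    if total <= 0:
        raise ValidationError("model contains no splits")
    return pd.Series(100.0 * gains / total, index=sub.booster.feature_name())


@dataclass
class EffectCurve:
    """Marginal (partial-dependence) effect of one variable, suitability scale."""

    variable: str
    grid_values: np.ndarray
    mean_response: np.ndarray
    per_model: np.ndarray | None = None  # (B, n_points)


def partial_dependence(sub: SubModel, variable: str, n_points: int = 100,
                       grid_values: np.ndarray | None = None) -> EffectCurve:
    """Clamp-and-average marginal effect over the sub-model's training table.

    The evaluation grid spans the variable's 1st-99th training percentiles;
    the response at each grid value is the mean prediction with the variable
    clamped there, on the suitability (probability) scale.
    """
    if variable not in sub.feature_names:
        raise ValidationError(f"unknown variable {variable!r}")
    if variable in sub.categorical_features:
        raise ValidationError("partial dependence is defined for continuous "
                              "variables; categorical effects are tabulated "
                              "per class instead")
    if sub.train_X is None:
        raise ValidationError("sub-model carries no training table")
    if grid_values is None:
        col = sub.train_X[variable].to_numpy(float)
        lo, hi = np.percentile(col, [1, 99])
        grid_values = np.linspace(lo, hi, n_points)
    grid_values = np.asarray(grid_values, dtype=float)
    arr = sub.train_X[sub.feature_names].to_numpy(dtype=float)
    n = len(arr)
    if sub.booster is None or sub.n_trees == 0:
        p = 1.0 / (1.0 + np.exp(-sub.intercept))
        return EffectCurve(variable, grid_values,
                           np.full(len(grid_values), p))
    # one batched prediction over the table tiled once per grid value
    tiled = np.tile(arr, (len(grid_values), 1))
    tiled[:, sub.feature_names.index(variable)] = np.repeat(grid_values, n)
    preds = sub.booster.predict(tiled, num_iteration=sub.n_trees)
    responses = preds.reshape(len(grid_values), n).mean(axis=1)
    return EffectCurve(variable, grid_values, responses)


@dataclass
class RCTable:
    """Ensemble relative contributions with 95% confidence intervals."""

    table: pd.DataFrame      # variable, mean_pct, ci_low, ci_high
    per_model: pd.DataFrame  # one row per sub-model, one column per variable


@dataclass
class EnsembleModel:
    """B seeded sub-models integrated into one ensemble."""

    submodels: list[SubModel]
    config: BRTConfig
    presences: PresenceCells | None = None
    draws: list[BackgroundDraw] | None = None

    @property
    def B(self) -> int:
        return len(self.submodels)

    @property
    def feature_names(self) -> list[str]:
        return self.submodels[0].feature_names

    def cv_auc_summary(self) -> dict:
        """Mean +/- SD of held-out AUC, across all folds and across sub-models."""
        per_model = [np.mean(s.fold_auc) for s in self.submodels if s.fold_auc]
        all_folds = [a for s in self.submodels for a in s.fold_auc]
        out = {}
        if all_folds:
            out["across_folds"] = (float(np.mean(all_folds)),
                                   float(np.std(all_folds)))
        if per_model:
            out["across_submodels"] = (float(np.mean(per_model)),
                                       float(np.std(per_model)))
        out["formatted"] = {k: f"{m:.3f} ± {s:.3f}" for k, (m, s) in out.items()
                            if k != "formatted"}
        return out


def fit_ensemble(presences: PresenceCells, draws: list[BackgroundDraw],
                 stack: CovariateStack, config: BRTConfig) -> EnsembleModel:
    """Fit one sub-model per background draw, seeded ``base_seed + index``."""
    submodels = []
    for draw in draws:
        seed = config.base_seed + draw.index
        try:
            X, y, _ = assemble_training(presences, draw, stack)
            cat = [c for c in X.columns if c in stack.categorical_layers]
            n_trees, sel = select_n_trees(X, y, config, seed=seed,
                                          categorical=cat)
            sub = fit_brt(X, y, config, n_trees=n_trees, seed=seed,
                          categorical=cat)
        except Exception as exc:
            raise type(exc)(f"draw {draw.index}: {exc}") from exc
        sub.draw_index = draw.index
        sub.cv_deviance = sel.trace
        sub.fold_auc = sel.fold_auc
        submodels.append(sub)
    return EnsembleModel(submodels, config, presences, draws)


def ensemble_predict(ens: EnsembleModel, stack: CovariateStack) -> SuitabilityMap:
    """Per-cell mean and population SD over the B sub-model maps."""
    maps = np.stack([predict_map(s, stack).mean.values for s in ens.submodels])
    valid = stack.joint_valid()
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=0)
    mean[~valid] = 0.0
    sd[~valid] = 0.0
    return SuitabilityMap(Raster(stack.grid, mean, ~valid),
                          Raster(stack.grid, sd, ~valid))


def ensemble_rc(ens: EnsembleModel, ci: str = "normal",
                min_pct: float | None = None) -> RCTable:
    """Mean relative contribution per variable across sub-models, with 95% CI.

    ``ci='normal'`` uses mean +/- 1.96*SD/sqrt(B); ``ci='percentile'`` the
    empirical 2.5/97.5 percentiles. ``min_pct`` filters the report (not the
    per-model table) to variables whose mean exceeds it.
    """
    per = pd.DataFrame([relative_influence(s) for s in ens.submodels])
    mean = per.mean(axis=0)
    if ci == "normal":
        half = 1.96 * per.std(axis=0, ddof=1).fillna(0.0) / np.sqrt(len(per))
        lo, hi = mean - half, mean + half
    elif ci == "percentile":
        lo = per.quantile(0.025, axis=0)
        hi = per.quantile(0.975, axis=0)
    else:
        raise ValidationError(f"unknown CI method {ci!r}")
    table = pd.DataFrame({"variable": mean.index, "mean_pct": mean.values,
                          "ci_low": lo.values, "ci_high": hi.values})
    table = table.sort_values("mean_pct", ascending=False,
                              ignore_index=True)
    if min_pct is not None:
        table = table[table["mean_pct"] > min_pct].reset_index(drop=True)
    return RCTable(table, per)


def ensemble_curves(ens: EnsembleModel, variables: list[str],
                    n_points: int = 100) -> list[EffectCurve]:
    """Pointwise-averaged marginal effect curves on a shared evaluation grid."""
    curves = []
    for var in variables:
        pooled = np.concatenate([s.train_X[var].to_numpy(float)
                                 for s in ens.submodels])
        lo, hi = np.percentile(pooled, [1, 99])
        grid_values = np.linspace(lo, hi, n_points)
        per = np.stack([partial_dependence(s, var, grid_values=grid_values)
                        .mean_response for s in ens.submodels])
        curves.append(EffectCurve(var, grid_values, per.mean(axis=0), per))
    return curves


def save_ensemble(ens: EnsembleModel, path) -> None:
    """Serialize the ensemble to a JSON container (trees as model strings)."""
    doc = {
        "config": asdict(ens.config),
        "presences": None if ens.presences is None else {
            "cells": ens.presences.cells.tolist(),
            "n_source_points": ens.presences.n_source_points,
            "n_dropped": ens.presences.n_dropped},
        "draws": None if ens.draws is None else [
            {"index": d.index, "seed": d.seed, "cells": d.cells.tolist()}
            for d in ens.draws],
        "submodels": [{
            "model": s.booster.model_to_string(),
            "feature_names": s.feature_names,
            "categorical_features": s.categorical_features,
            "n_trees": s.n_trees, "intercept": s.intercept,
            "draw_index": s.draw_index, "seed": s.seed,
            "fold_auc": list(map(float, s.fold_auc)),
        } for s in ens.submodels],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_ensemble(path, stack: CovariateStack | None = None) -> EnsembleModel:
    """Load a saved ensemble; pass the stack to rebuild training tables
    (needed for partial dependence)."""
    with open(path) as fh:
        doc = json.load(fh)
    config = BRTConfig(**doc["config"])
    presences = None
    if doc["presences"] is not None:
        presences = PresenceCells(np.asarray(doc["presences"]["cells"]),
                                  doc["presences"]["n_source_points"],
                                  doc["presences"]["n_dropped"])
    draws = None
    if doc["draws"] is not None:
        draws = [BackgroundDraw(d["index"], d["seed"], np.asarray(d["cells"]))
                 for d in doc["draws"]]
    submodels = []
    for i, sd in enumerate(doc["submodels"]):
        booster = lgb.Booster(model_str=sd["model"])
        sub = SubModel(booster, sd["feature_names"],
                       sd["categorical_features"], sd["n_trees"],
                       config.learning_rate, sd["intercept"],
                       draw_index=sd["draw_index"], seed=sd["seed"],
                       fold_auc=sd["fold_auc"])
        if stack is not None and presences is not None and draws is not None:
            X, y, _ = assemble_training(presences, draws[i], stack)
            order = _canonical_order(X, y)
            sub.train_X = X.iloc[order].reset_index(drop=True)
            sub.train_y = np.asarray(y)[order]
        submodels.append(sub)
    return EnsembleModel(submodels, config, presences, draws)
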