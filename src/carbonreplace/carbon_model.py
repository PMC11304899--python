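"""Random-forest models linking composition scores and site covariates to
aboveground carbon stocks.

The response is plot-level live (or total) aboveground carbon at the most
recent measurement; predictors are the four ordination axis scores of the
plot's tree-carbon composition plus stand age, terrain, location (or
climate normals) and disturbance/ownership factors.  Model accuracy is the
out-of-bag pseudo-r2, 1 - MSE_oob / Var(y).  Variable importance is the
randomization importance of the original forest formulation: the mean
increase in out-of-bag MSE when a predictor is permuted, normalized by its
standard deviation over trees.  One-hot blocks (and the sin/cos pair that
encodes circular aspect) are permuted jointly so a factor gets one score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.ensemble._forest import (_generate_unsampled_indices,
                                      _get_n_samples_bootstrap)

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

AXIS_PREDICTORS = ["axis1", "axis2", "axis3", "axis4"]
LATLON = ["latitude", "longitude"]
CLIMATE = ["mat_c", "map_mm", "vpd_hpa"]
CATEGORICAL = ["physiographic_class", "forest_type_group", "ownership", "disturbance"]


def default_predictors(covariate_set: str = "latlon") -> list[str]:
    location = LATLON if covariate_set == "latlon" else CLIMATE
    return (AXIS_PREDICTORS + ["stand_age", "physiographic_class",
                               "forest_type_group", "elevation", "slope", "aspect",
                               "ownership", "disturbance"] + location)


@dataclass
class CarbonModelSpec:
    response: str = "live_c"            # live_c | total_c
    predictors: list[str] = field(default_factory=default_predictors)
    n_trees: int = 1000
    seed: int = 0
    aspect_mode: str = "sincos"         # sincos | raw


@dataclass
class FittedCarbonModel:
    spec: CarbonModelSpec
    model: RandomForestRegressor
    oob_pseudo_r2: float
    feature_names: list[str]
    feature_groups: dict[str, list[int]]    # predictor -> design column indices
    categories: dict[str, list[str]]        # recorded one-hot encodings
    X: np.ndarray                           # training design (rows follow table)
    y: np.ndarray
    numeric_ranges: dict[str, tuple[float, float]]


def build_design(table: pd.DataFrame, spec: CarbonModelSpec,
                 categories: dict[str, list[str]] | None = None
                 ) -> tuple[np.ndarray, list[str], dict[str, list[int]],
                            dict[str, list[str]]]:
    """Design matrix with recorded categorical encodings.

    When ``categories`` is given (prediction time), unseen levels map to the
    all-zero reference encoding and are logged.
    """
    fit_time = categories is None
    categories = dict(categories or {})
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: dict[str, list[int]] = {}
    for pred in spec.predictors:
        start = len(names)
        if pred == "aspect" and spec.aspect_mode == "sincos":
            rad = np.deg2rad(table["aspect"].to_numpy(dtype=float))
            cols += [np.sin(rad), np.cos(rad)]
            names += ["aspect_sin", "aspect_cos"]
        elif pred in CATEGORICAL:
            vals = table[pred].astype(str)
            if fit_time:
                categories[pred] = sorted(vals.unique())
            levels = categories[pred]
            unseen = set(vals.unique()) - set(levels)
            if unseen:
                logger.warning("predictor %s: unseen level(s) %s mapped to reference",
                               pred, sorted(unseen))
            for lv in levels:
                cols.append((vals == lv).to_numpy(dtype=float))
                names.append(f"{pred}={lv}")
        else:
            cols.append(table[pred].to_numpy(dtype=float))
            names.append(pred)
        groups[pred] = list(range(start, len(names)))
    X = np.column_stack(cols)
    return X, names, groups, categories


def fit_carbon_model(table: pd.DataFrame, spec: CarbonModelSpec) -> FittedCarbonModel:
    """Fit the regression forest (1000 trees by default, p/3 features per
    split, bootstrap resampling) and score it out of bag."""
    if len(table) < 30:
        raise DataError(f"only {len(table)} rows; at least 30 required")
    if table[spec.response].isna().any():
        raise DataError("missing response values")
    table = table.sort_index()  # bootstrap draws see a canonical row order
    X, names, groups, categories = build_design(table, spec)
    y = table[spec.response].to_numpy(dtype=float)
    model = RandomForestRegressor(
        n_estimators=spec.n_trees, max_features=1.0 / 3.0, min_samples_leaf=5,
        bootstrap=True, oob_score=True, random_state=spec.seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # rows never OOB on tiny data
        model.fit(X, y)
    mse_oob = float(np.mean((y - model.oob_prediction_) ** 2))
    oob_r2 = 1.0 - mse_oob / float(np.var(y))
    ranges = {nm: (float(X[:, j].min()), float(X[:, j].max()))
              for nm, j in zip(names, range(X.shape[1]))}
    return FittedCarbonModel(spec=spec, model=model, oob_pseudo_r2=oob_r2,
                             feature_names=names, feature_groups=groups,
                             categories=categories, X=X, y=y,
                             numeric_ranges=ranges)


def predict(fitted: FittedCarbonModel, table: pd.DataFrame) -> np.ndarray:
    X, _, _, _ = build_design(table, fitted.spec, categories=fitted.categories)
    return fitted.model.predict(X)


# ---------------------------------------------------------------------------
# Permutation importance (out of bag, per tree)
# ---------------------------------------------------------------------------

def permutation_importance(fitted: FittedCarbonModel, seed: int = 0) -> pd.Series:
    """Per-predictor importance: mean over trees of the out-of-bag MSE
    increase under within-predictor permutation, divided by its standard
    deviation over trees.  Multi-column predictors are permuted jointly."""
    model = fitted.model
    X = np.ascontiguousarray(fitted.X, dtype=np.float32)
    y = fitted.y
    n = X.shape[0]
    n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)
    rng = np.random.default_rng(seed)
    groups = fitted.feature_groups
    increases = {g: [] for g in groups}
    for est in model.estimators_:
        oob = _generate_unsampled_indices(est.random_state, n, n_boot, None)
        if len(oob) < 2:
            continue
        Xo = X[oob]
        yo = y[oob]
        base = np.mean((est.tree_.predict(Xo)[:, 0] - yo) ** 2)
        perm = rng.permutation(len(oob))
        for g, cols in groups.items():
            Xp = Xo.copy()
            Xp[:, cols] = Xo[perm][:, cols]
            mse = np.mean((est.tree_.predict(Xp)[:, 0] - yo) ** 2)
            increases[g].append(mse - base)
    scores = {}
    for g, inc in increases.items():
        inc = np.asarray(inc)
        sd = inc.std(ddof=1) if len(inc) > 1 else 0.0
        scores[g] = float(inc.mean() / sd) if sd > 0 else 0.0
    return pd.Series(scores).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# Partial dependence
# ---------------------------------------------------------------------------

def partial_dependence(fitted: FittedCarbonModel, predictors: list[str],
                       grid: list[np.ndarray] | None = None,
                       grid_resolution: int = 20) -> pd.DataFrame:
    """Brute-force partial dependence for one or two numeric predictors.

    The marginal prediction at each grid point averages model output over
    the training distribution of all remaining predictors.  Grid values
    outside the observed range are clamped with a warning.
    """
    if not 1 <= len(predictors) <= 2:
        raise ConfigError("partial dependence supports 1 or 2 predictors")
    cols = []
    for p in predictors:
        idx = fitted.feature_groups.get(p, [])
        if len(idx) != 1:
            raise ConfigError(f"partial dependence needs a single-column predictor: {p}")
        cols.append(idx[0])
    axes = []
    for p, j in zip(predictors, cols):
        lo, hi = fitted.X[:, j].min(), fitted.X[:, j].max()
        if grid is None:
            vals = np.linspace(lo, hi, grid_resolution)
        else:
            vals = np.asarray(grid[len(axes)], dtype=float)
            if (vals < lo).any() or (vals > hi).any():
                warnings.warn(f"grid for {p} outside observed range; clamping")
                vals = np.clip(vals, lo, hi)
        axes.append(vals)
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([m.ravel() for m in mesh])
    out = np.empty(len(points))
    Xw = fitted.X.copy()
    for i, pt in enumerate(points):
        for j, v in zip(cols, pt):
            Xw[:, j] = v
        out[i] = float(fitted.model.predict(Xw).mean())
    data = {p: points[:, i] for i, p in enumerate(predictors)}
    data["partial_dependence"] = out
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Covariate-set comparison
# ---------------------------------------------------------------------------

def compare_covariate_sets(table: pd.DataFrame,
                           spec: CarbonModelSpec | None = None) -> dict:
    """Fit location (latitude/longitude) vs climate-normal covariate sets
    and select the one with the higher out-of-bag pseudo-r2."""
    spec = spec or CarbonModelSpec()
    report = {}
    fits = {}
    for name in ("latlon", "climate"):
        s = CarbonModelSpec(response=spec.response,
                            predictors=default_predictors(name),
                            n_trees=spec.n_trees, seed=spec.seed,
                            aspect_mode=spec.aspect_mode)
        fits[name] = fit_carbon_model(table, s)
        report[f"oob_pseudo_r2_{name}"] = fits[name].oob_pseudo_r2
    selected = max(fits, key=lambda k: fits[k].oob_pseudo_r2)
    report["selected"] = selected
    report["model"] = fits[selected]
    return report
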