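"""Counterfactual carbon-replacement indicator.

For each plot, the fitted live-carbon forest is evaluated twice at a fixed
reference stand age (100 years by default): once with the plot's
tree-carbon composition ordination scores and once with its recruitment
composition scores, every other covariate held at its observed value.  The
difference (recruitment minus tree) is the replacement delta; plots are
classified as poised for carbon *loss* (delta < -5 Mg/ha), *replacement*
(|delta| <= 5) or *gain* (delta > +5).  Plots lacking either composition
row (no live carbon, or no seedlings anywhere) are flagged not assessable
and excluded from category tallies.

Category differences in site and stand variables are screened with
Kruskal-Wallis (continuous) and chi-square (categorical) tests under a
single Holm-Bonferroni family.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .carbon_model import FittedCarbonModel, build_design
from .errors import DataError

CATEGORIES = ("loss", "replacement", "gain")
DEFAULT_SENSITIVITY_AGES = (60.0, 80.0, 100.0, 120.0, 140.0)

#: variable -> test family used for category comparisons
DEFAULT_TEST_VARIABLES = {
    "latitude": "kruskal", "longitude": "kruskal", "elevation": "kruskal",
    "slope": "kruskal", "aspect": "kruskal", "live_c": "kruskal",
    "snag_c": "kruskal", "cwm_c": "kruskal", "live_c_change": "kruskal",
    "mat_c": "kruskal", "map_mm": "kruskal", "vpd_hpa": "kruskal",
    "ownership": "chi2", "physiographic_class": "chi2",
    "disturbance": "chi2", "forest_type_group": "chi2",
}


def categorize(delta: float, threshold: float = 5.0) -> str:
    """loss / replacement / gain classification of a replacement delta."""
    if not math.isfinite(delta):
        raise DataError(f"non-finite replacement delta: {delta}")
    if delta < -threshold:
        return "loss"
    if delta > threshold:
        return "gain"
    return "replacement"


def counterfactual_predictions(model: FittedCarbonModel, plot_table: pd.DataFrame,
                               scores: pd.DataFrame, reference_age: float = 100.0,
                               threshold: float = 5.0) -> pd.DataFrame:
    """Composition-swap predictions for every plot in ``plot_table``.

    ``scores`` is the ordination score table indexed by (plot_id, source).
    Returns one row per plot with pred_treec, pred_recruitment, delta,
    category and an ``assessable`` flag (False when either composition row
    is missing, e.g. the plot had no regeneration).
    """
    axis_cols = [c for c in scores.columns if c.startswith("axis")]
    have = {src: {pid for pid, s in scores.index if s == src}
            for src in ("treeC", "recruitment")}
    assessable = [pid for pid in plot_table.index
                  if pid in have["treeC"] and pid in have["recruitment"]]

    out = pd.DataFrame(index=plot_table.index)
    out.index.name = "plot_id"
    out["pred_treec"] = np.nan
    out["pred_recruitment"] = np.nan
    if assessable:
        base = plot_table.loc[assessable].copy()
        base["stand_age"] = reference_age
        for src, col in (("treeC", "pred_treec"),
                         ("recruitment", "pred_recruitment")):
            frame = base.copy()
            idx = pd.MultiIndex.from_product([assessable, [src]])
            for ax in axis_cols:
                frame[ax] = scores.loc[idx, ax].to_numpy()
            X, _, _, _ = build_design(frame, model.spec,
                                      categories=model.categories)
            out.loc[assessable, col] = model.model.predict(X)
    out["delta"] = out.pred_recruitment - out.pred_treec
    out["category"] = [categorize(d, threshold) if math.isfinite(d) else ""
                       for d in out.delta]
    out["reference_age"] = reference_age
    out["assessable"] = out.index.isin(assessable)
    return out


def sensitivity_sweep(model: FittedCarbonModel, plot_table: pd.DataFrame,
                      scores: pd.DataFrame,
                      ages=DEFAULT_SENSITIVITY_AGES,
                      threshold: float = 5.0) -> tuple[pd.DataFrame, float]:
    """Re-run the indicator across reference ages.

    Returns (one row per plot x age, stability), stability being the
    fraction of assessable plots whose category is constant across ages.
    """
    frames = []
    for age in ages:
        res = counterfactual_predictions(model, plot_table, scores,
                                         reference_age=age, threshold=threshold)
        frames.append(res.reset_index())
    table = pd.concat(frames, ignore_index=True)
    assessable = table[table.assessable]
    n_cat = assessable.groupby("plot_id")["category"].nunique()
    stability = float((n_cat == 1).mean()) if len(n_cat) else float("nan")
    return table, stability


def group_comparisons(results: pd.DataFrame, variables_table: pd.DataFrame,
                      variables: dict[str, str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis / chi-square screening of variables across the three
    replacement categories, Holm-Bonferroni corrected as one family.

    ``variables`` maps variable name -> "kruskal" or "chi2"; only variables
    present in ``variables_table`` are tested.  Categories with no plots
    are dropped with a warning.  Returns columns (variable, test, raw_p,
    holm_p, reported).
    """
    variables = variables or DEFAULT_TEST_VARIABLES
    res = results[results.assessable]
    joined = res.join(variables_table, how="inner")
    present = [c for c in CATEGORIES if (joined.category == c).any()]
    if len(present) < len(CATEGORIES):
        warnings.warn(f"empty categories dropped: "
                      f"{sorted(set(CATEGORIES) - set(present))}")
    if len(present) < 2:
        raise DataError("need at least two non-empty categories to test")

    rows = []
    for var, test in variables.items():
        if var not in joined.columns:
            continue
        if test == "kruskal":
            samples = [joined.loc[joined.category == c, var].dropna().to_numpy()
                       for c in present]
            samples = [s for s in samples if len(s)]
            try:
                p = float(stats.kruskal(*samples).pvalue) if len(samples) > 1 else np.nan
            except ValueError:  # all values identical
                p = 1.0
        else:
            contingency = pd.crosstab(joined.category, joined[var].astype(str))
            contingency = contingency.loc[[c for c in present
                                           if c in contingency.index]]
            contingency = contingency.loc[:, contingency.sum(axis=0) > 0]
            if contingency.shape[0] < 2 or contingency.shape[1] < 2:
                p = np.nan
            else:
                chi = stats.chi2_contingency(contingency.to_numpy(),
                                             correction=False)
                if (chi.expected_freq < 5).any():
                    warnings.warn(f"chi-square for {var}: expected cell count "
                                  "below 5; p-value may be fragile")
                p = float(chi.pvalue)
        rows.append({"variable": var, "test": test, "raw_p": p})
    table = pd.DataFrame(rows)
    table["holm_p"] = np.nan
    ok = table.raw_p.notna()
    if ok.any():
        table.loc[ok, "holm_p"] = multipletests(table.loc[ok, "raw_p"],
                                                method="holm")[1]
    table["reported"] = table.holm_p < alpha
    return table


def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm adjustment (monotone, capped at 1)."""
    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]


def summarize_categories(results: pd.DataFrame,
                         threshold: float = 5.0) -> dict:
    """Category proportions and delta moments over assessable plots."""
    res = results[results.assessable]
    if res.empty:
        raise DataError("no assessable plots")
    n = len(res)
    props = {c: float((res.category == c).mean()) for c in CATEGORIES}
    delta = res.delta.to_numpy(dtype=float)
    return {
        "n_assessable": int(n),
        "n_total": int(len(results)),
        "proportions": props,
        "mean_delta": float(delta.mean()),
        "sd_delta": float(delta.std(ddof=1)) if n > 1 else 0.0,
        "threshold": float(threshold),
    }
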