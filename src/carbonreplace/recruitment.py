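"""Sapling-recruitment likelihood from six-height-class seedling tallies.

Boosted classification trees predict whether a species recruits a new
sapling in a subplot between two measurements, from its time-1 seedling
tally per height class plus terrain/site covariates.  Species with enough
recruitment events get their own model; everything else is served by a
general model that carries species identity as a feature.  Predicted
probabilities at time 2 are averaged over a plot's four subplots and
relativized across species into a *recruitment composition* that sums to
one — the regeneration-side analogue of tree-carbon composition.

A species with no seedlings in a microplot is assigned recruitment
probability zero (the "zero rule"); consequently only subplot x species
combinations with time-1 seedlings enter the training table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import DataError
from .inventory import (HEIGHT_CLASS_COLUMNS, InventoryTables, N_SUBPLOTS,
                        plot_condition_table)

logger = logging.getLogger(__name__)

NUMERIC_FEATURES = ["elevation", "slope", "aspect_sin", "aspect_cos",
                    "latitude", "longitude", "stand_age"]
CATEGORICAL_FEATURES = ["forest_type_group", "physiographic_class"]


@dataclass
class BRTSettings:
    """Canonical ecological boosted-tree recipe: slow learning rate, shallow
    trees, 50% bagging, tree count chosen by cross-validated deviance."""
    learning_rate: float = 0.01
    max_depth: int = 3
    subsample: float = 0.5
    max_trees: int = 5000
    cv_folds: int = 10
    min_trees: int = 50
    seed: int = 0


@dataclass
class FeatureSpec:
    numeric: list[str]
    categorical_levels: dict[str, list[str]]
    species_levels: list[str]

    def columns(self, include_species: bool) -> list[str]:
        cols = list(HEIGHT_CLASS_COLUMNS) + list(self.numeric)
        for feat, levels in self.categorical_levels.items():
            cols += [f"{feat}={lv}" for lv in levels]
        if include_species:
            cols += [f"species={lv}" for lv in self.species_levels]
        return cols


@dataclass
class RecruitmentModelSet:
    species_models: dict[str, GradientBoostingClassifier]
    general_model: GradientBoostingClassifier
    species_threshold: int
    feature_spec: FeatureSpec
    settings: BRTSettings


@dataclass
class RecruitmentComposition:
    plot_id: str
    scores: dict[str, float]

    @property
    def no_regeneration(self) -> bool:
        return not self.scores


# ---------------------------------------------------------------------------
# Feature table construction
# ---------------------------------------------------------------------------

def build_training_table(tables: InventoryTables,
                         plot_ids=None, time: int = 1) -> pd.DataFrame:
    """One row per subplot x species with seedlings present at ``time``.

    Columns: identifiers, microplot-aggregated height-class counts,
    site covariates, and (for time 1) the label ``newly_recruited`` taken
    from the time-2 sapling records.  Missing covariates are imputed with
    the column median and logged.
    """
    seeds = tables.seedlings
    seeds = seeds[seeds.time == time]
    if plot_ids is not None:
        seeds = seeds[seeds.plot_id.isin(set(plot_ids))]
    counts = (seeds.groupby(["plot_id", "subplot", "species"])[list(HEIGHT_CLASS_COLUMNS)]
              .sum().reset_index())
    counts = counts[counts[list(HEIGHT_CLASS_COLUMNS)].sum(axis=1) > 0]

    cov = plot_condition_table(tables, plot_ids)
    cov = cov.assign(aspect_sin=np.sin(np.deg2rad(cov.aspect)),
                     aspect_cos=np.cos(np.deg2rad(cov.aspect)))
    table = counts.merge(
        cov[NUMERIC_FEATURES + CATEGORICAL_FEATURES].reset_index(),
        on="plot_id", how="left")

    for col in NUMERIC_FEATURES:
        if table[col].isna().any():
            med = float(table[col].median())
            n = int(table[col].isna().sum())
            logger.warning("imputing %d missing values of %s with median %.3g",
                           n, col, med)
            table[col] = table[col].fillna(med)

    if time == 1:
        sap = tables.saplings
        newly = sap[(sap.time == 2) & sap.newly_recruited]
        key = ["plot_id", "subplot", "species"]
        recruited = set(map(tuple, newly[key].itertuples(index=False)))
        table["newly_recruited"] = [
            tuple(r) in recruited for r in table[key].itertuples(index=False)]
    return table.reset_index(drop=True)


def build_feature_spec(table: pd.DataFrame) -> FeatureSpec:
    return FeatureSpec(
        numeric=list(NUMERIC_FEATURES),
        categorical_levels={c: sorted(table[c].astype(str).unique())
                            for c in CATEGORICAL_FEATURES},
        species_levels=sorted(table.species.astype(str).unique()),
    )


def encode_features(table: pd.DataFrame, spec: FeatureSpec,
                    include_species: bool) -> np.ndarray:
    """Dense design matrix; categorical levels unseen at fit time map to the
    all-zero reference encoding (logged)."""
    n = len(table)
    blocks = [table[list(HEIGHT_CLASS_COLUMNS)].to_numpy(dtype=float),
              table[spec.numeric].to_numpy(dtype=float)]
    cats = dict(spec.categorical_levels)
    if include_species:
        cats["species"] = spec.species_levels
    for feat, levels in cats.items():
        vals = table[feat].astype(str)
        unseen = set(vals.unique()) - set(levels)
        if unseen:
            logger.warning("feature %s: unseen level(s) %s mapped to reference",
                           feat, sorted(unseen))
        block = np.zeros((n, len(levels)))
        index = {lv: j for j, lv in enumerate(levels)}
        for i, v in enumerate(vals):
            j = index.get(v)
            if j is not None:
                block[i, j] = 1.0
        blocks.append(block)
    return np.hstack(blocks)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def _new_brt(settings: BRTSettings, n_trees: int, seed: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        learning_rate=settings.learning_rate, max_depth=settings.max_depth,
        subsample=settings.subsample, n_estimators=n_trees, random_state=seed)


def _cv_select(X: np.ndarray, y: np.ndarray, settings: BRTSettings,
               seed: int) -> tuple[int, np.ndarray]:
    """Tree count minimizing K-fold cross-validated binomial deviance along
    the boosting path (capped at ``settings.max_trees``), plus the
    out-of-fold probabilities at that tree count."""
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    folds = max(2, min(settings.cv_folds, n_pos, n_neg))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    losses = np.zeros(settings.max_trees)
    counts = np.zeros(settings.max_trees)
    models = []
    for tr, va in splits:
        model = _new_brt(settings, settings.max_trees, seed).fit(X[tr], y[tr])
        models.append(model)
        for stage, proba in enumerate(model.staged_predict_proba(X[va])):
            losses[stage] += log_loss(y[va], proba[:, 1], labels=[False, True])
            counts[stage] += 1
    mean = losses / np.maximum(counts, 1)
    best = int(np.argmin(mean[settings.min_trees - 1:])) + settings.min_trees
    best = min(best, settings.max_trees)
    oof = np.empty(len(y))
    for model, (tr, va) in zip(models, splits):
        for stage, proba in enumerate(model.staged_predict_proba(X[va]), start=1):
            if stage == best:
                oof[va] = proba[:, 1]
                break
    return best, oof


def select_n_trees(X: np.ndarray, y: np.ndarray, settings: BRTSettings,
                   seed: int) -> int:
    """Cross-validated boosting-path tree-count selection."""
    return _cv_select(X, y, settings, seed)[0]


def fit_recruitment_models(table: pd.DataFrame, threshold: int = 30,
                           settings: BRTSettings | None = None,
                           validate_species_models: bool = True,
                           validation_margin: float = 0.0) -> RecruitmentModelSet:
    """Fit per-species models for species with more than ``threshold``
    recruitment-positive subplots, plus a pooled general model.

    When ``validate_species_models`` is on, a candidate species model is
    retained only if its out-of-fold binomial deviance beats the general
    model's on the same rows (up to ``validation_margin``) — otherwise the
    pooled model, which borrows strength across species, serves that
    species too.  Deviance is the same criterion that selects tree counts.
    """
    if table.empty:
        raise DataError("empty training table")
    settings = settings or BRTSettings()
    spec = build_feature_spec(table)
    y_all = table.newly_recruited.to_numpy(dtype=bool)

    X_gen = encode_features(table, spec, include_species=True)
    n_gen, oof_gen = _cv_select(X_gen, y_all, settings, settings.seed)
    general = _new_brt(settings, n_gen, settings.seed).fit(X_gen, y_all)

    species_models: dict[str, GradientBoostingClassifier] = {}
    positives = table[table.newly_recruited].groupby("species").size()
    for rank, sp in enumerate(sorted(positives.index[positives > threshold])):
        mask = (table.species == sp).to_numpy()
        sub = table[mask]
        y = sub.newly_recruited.to_numpy(dtype=bool)
        if y.all() or not y.any():
            logger.warning("species %s has a single label class; using general model", sp)
            continue
        X = encode_features(sub, spec, include_species=False)
        seed = settings.seed + 1 + rank
        n, oof_sp = _cv_select(X, y, settings, seed)
        if validate_species_models:
            dev_sp = log_loss(y, oof_sp, labels=[False, True])
            dev_gen = log_loss(y, oof_gen[mask], labels=[False, True])
            if dev_sp > dev_gen + validation_margin:
                logger.info("species %s model (deviance %.4f) behind general "
                            "model (%.4f); using general model", sp, dev_sp, dev_gen)
                continue
        species_models[sp] = _new_brt(settings, n, seed).fit(X, y)
    return RecruitmentModelSet(species_models=species_models, general_model=general,
                               species_threshold=threshold, feature_spec=spec,
                               settings=settings)


def predict_recruitment(model_set: RecruitmentModelSet, tables: InventoryTables,
                        plot_ids=None, time: int = 2) -> pd.DataFrame:
    """Per-subplot recruitment probabilities from seedling tallies at
    ``time``.  Species without seedlings in a microplot are omitted (their
    probability is zero by the zero rule)."""
    feats = build_training_table(tables, plot_ids=plot_ids, time=time)
    if feats.empty:
        return pd.DataFrame(columns=["plot_id", "subplot", "species", "probability"])
    prob = np.empty(len(feats))
    spec = model_set.feature_spec
    general_rows = np.ones(len(feats), dtype=bool)
    for sp, model in model_set.species_models.items():
        mask = (feats.species == sp).to_numpy()
        if mask.any():
            prob[mask] = model.predict_proba(
                encode_features(feats[mask], spec, include_species=False))[:, 1]
            general_rows &= ~mask
    if general_rows.any():
        prob[general_rows] = model_set.general_model.predict_proba(
            encode_features(feats[general_rows], spec, include_species=True))[:, 1]
    out = feats[["plot_id", "subplot", "species"]].copy()
    out["probability"] = prob
    return out


# ---------------------------------------------------------------------------
# Recruitment composition
# ---------------------------------------------------------------------------

def relativize(scores: dict[str, float]) -> dict[str, float]:
    """Divide by the sum so the scores become proportions summing to one."""
    total = float(sum(scores.values()))
    if total <= 0:
        return {}
    return {sp: v / total for sp, v in scores.items()}


def plot_recruitment_composition(probabilities: pd.DataFrame, plot_id: str,
                                 n_subplots: int = N_SUBPLOTS) -> RecruitmentComposition:
    """Average a plot's subplot probabilities per species (subplots without
    the species count as zero) and relativize across species.

    A plot with no positive probability for any species is flagged as
    having no regeneration and is excluded from ordination rows downstream.
    """
    sub = probabilities[probabilities.plot_id == plot_id]
    means = (sub.groupby("species")["probability"].sum() / n_subplots).to_dict()
    return RecruitmentComposition(plot_id=plot_id, scores=relativize(means))


def recruitment_composition_table(probabilities: pd.DataFrame,
                                  plot_ids) -> tuple[pd.DataFrame, list[str]]:
    """Long table (plot_id, species, score) plus list of no-regeneration
    plots."""
    rows, empty = [], []
    for pid in plot_ids:
        comp = plot_recruitment_composition(probabilities, pid)
        if comp.no_regeneration:
            empty.append(pid)
            continue
        rows.extend({"plot_id": pid, "species": sp, "score": v}
                    for sp, v in sorted(comp.scores.items()))
    cols = ["plot_id", "species", "score"]
    return (pd.DataFrame(rows, columns=cols), empty)


def general_model_cv_auc(table: pd.DataFrame, settings: BRTSettings | None = None,
                         n_splits: int = 5) -> float:
    """Cross-validated AUC of the pooled model; model-accuracy diagnostic."""
    settings = settings or BRTSettings()
    spec = build_feature_spec(table)
    X = encode_features(table, spec, include_species=True)
    y = table.newly_recruited.to_numpy(dtype=bool)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=settings.seed)
    aucs = []
    for tr, va in skf.split(X, y):
        n = select_n_trees(X[tr], y[tr], settings, settings.seed)
        model = _new_brt(settings, n, settings.seed).fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[va], model.predict_proba(X[va])[:, 1]))
    return float(np.mean(aucs))
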