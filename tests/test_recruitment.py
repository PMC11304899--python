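"""Recruitment models: zero rule, relativization, threshold logic,
probability behaviour on generated data."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from carbonreplace.errors import DataError
from carbonreplace.inventory import HEIGHT_CLASS_COLUMNS, filter_plots
from carbonreplace.recruitment import (build_training_table, encode_features,
                                       fit_recruitment_models,
                                       general_model_cv_auc,
                                       plot_recruitment_composition,
                                       predict_recruitment,
                                       recruitment_composition_table, relativize)
from tests.conftest import FAST_BRT


def probs_frame(entries):
    return pd.DataFrame(entries, columns=["plot_id", "subplot", "species",
                                          "probability"])


class TestRelativization:
    def test_worked_example(self):
        """Plot-level probabilities 0.8/0.7/0.5 relativize to 0.4/0.35/0.25."""
        scores = relativize({"ACSA": 0.8, "FAGR": 0.7, "BEAL": 0.5})
        assert scores == pytest.approx({"ACSA": 0.4, "FAGR": 0.35, "BEAL": 0.25})

    def test_single_species_normalizes_to_one(self):
        assert relativize({"ABBA": 0.3}) == pytest.approx({"ABBA": 1.0})

    def test_already_normalized_is_unchanged(self):
        s = {"A": 0.2, "B": 0.2, "C": 0.6}
        assert relativize(s) == pytest.approx(s)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, k):
        base = {"A": 0.8, "B": 0.7, "C": 0.5}
        scaled = {sp: v * k for sp, v in base.items()}
        a, b = relativize(base), relativize(scaled)
        assert all(abs(a[sp] - b[sp]) < 1e-9 for sp in base)

    def test_subplot_average_then_relativize(self):
        # one species seen on 2 of 4 subplots at 0.8 -> mean 0.4
        frame = probs_frame([("P", 1, "ACSA", 0.8), ("P", 2, "ACSA", 0.8),
                             ("P", 1, "QURU", 0.4)])
        comp = plot_recruitment_composition(frame, "P")
        assert comp.scores == pytest.approx({"ACSA": 0.4 / 0.5, "QURU": 0.1 / 0.5})
        assert sum(comp.scores.values()) == pytest.approx(1.0)

    def test_no_regeneration_flagged_and_excluded(self):
        comp = plot_recruitment_composition(probs_frame([]), "P")
        assert comp.no_regeneration
        table, empty = recruitment_composition_table(
            probs_frame([("Q", 1, "ACSA", 0.5)]), ["P", "Q"])
        assert empty == ["P"]
        assert set(table.plot_id) == {"Q"}


class TestTrainingTable:
    def test_row_per_subplot_species_with_seedlings(self, mini_tables):
        table = build_training_table(mini_tables)
        # hand count of time-1 (subplot, species) pairs with seedlings
        expected = {("A", 1, "ACSA"), ("A", 1, "FAGR"), ("A", 2, "ACSA"),
                    ("B", 1, "ABBA"), ("C", 4, "QURU")}
        got = set(map(tuple, table[["plot_id", "subplot", "species"]]
                      .itertuples(index=False)))
        assert got == expected

    def test_zero_seedling_species_are_excluded(self, mini_tables):
        table = build_training_table(mini_tables)
        assert not ((table.plot_id == "C") & (table.species == "QUAL")).any()

    def test_labels_follow_time2_sapling_records(self, mini_tables):
        table = build_training_table(mini_tables).set_index(
            ["plot_id", "subplot", "species"])
        assert bool(table.loc[("A", 1, "ACSA"), "newly_recruited"])
        assert not bool(table.loc[("B", 1, "ABBA"), "newly_recruited"])

    def test_counts_conserve_raw_tallies(self, mini_tables):
        table = build_training_table(mini_tables).set_index(
            ["plot_id", "subplot", "species"])
        raw = mini_tables.seedlings.query("plot_id=='B' and time==1")
        assert (table.loc[("B", 1, "ABBA"), list(HEIGHT_CLASS_COLUMNS)].to_numpy()
                == raw[list(HEIGHT_CLASS_COLUMNS)].to_numpy()[0]).all()


@pytest.fixture(scope="module")
def fitted(small_cohort):
    tables, truth = small_cohort
    training = build_training_table(tables, plot_ids=filter_plots(tables))
    model_set = fit_recruitment_models(training, threshold=30, settings=FAST_BRT)
    return tables, truth, training, model_set


class TestModelSet:
    def test_species_threshold_rule(self, fitted):
        _, _, training, model_set = fitted
        positives = training[training.newly_recruited].groupby("species").size()
        for sp in model_set.species_models:
            assert positives[sp] > 30
        below = set(positives.index[positives <= 30])
        assert not below & set(model_set.species_models)

    def test_probabilities_are_valid_and_deterministic(self, fitted):
        tables, _, _, model_set = fitted
        probs = predict_recruitment(model_set, tables, time=2)
        assert probs.probability.between(0, 1).all()
        again = predict_recruitment(model_set, tables, time=2)
        assert np.array_equal(probs.probability, again.probability)

    def test_zero_rule_at_prediction(self, fitted):
        """Species absent from a microplot's time-2 tally get no row, i.e.
        zero probability."""
        tables, _, _, model_set = fitted
        probs = predict_recruitment(model_set, tables, time=2)
        t2 = tables.seedlings[tables.seedlings.time == 2]
        tallied = set(map(tuple, t2[["plot_id", "subplot", "species"]]
                          .itertuples(index=False)))
        assert all(tuple(r) in tallied
                   for r in probs[["plot_id", "subplot", "species"]]
                   .itertuples(index=False))

    def test_more_tall_seedlings_rarely_lowers_probability(self, fitted):
        """The generator's recruitment law is monotone in the tallest class;
        fitted models should agree on >=95% of probe rows."""
        tables, _, training, model_set = fitted
        probe = training.head(100).copy()
        spec = model_set.feature_spec
        X = encode_features(probe, spec, include_species=True)
        bumped = probe.copy()
        bumped["count_class6"] = bumped["count_class6"] + 4
        Xb = encode_features(bumped, spec, include_species=True)
        p0 = model_set.general_model.predict_proba(X)[:, 1]
        p1 = model_set.general_model.predict_proba(Xb)[:, 1]
        assert (p1 >= p0 - 1e-12).mean() >= 0.95

    def test_unseen_categorical_level_maps_to_reference(self, fitted, caplog):
        tables, _, training, model_set = fitted
        probe = training.head(5).copy()
        probe["forest_type_group"] = "martian_forest"
        import logging
        with caplog.at_level(logging.WARNING, logger="carbonreplace.recruitment"):
            X = encode_features(probe, model_set.feature_spec, include_species=True)
        assert "unseen" in caplog.text
        cols = [i for i, c in enumerate(model_set.feature_spec.columns(True))
                if c.startswith("forest_type_group=")]
        assert X[:, cols].sum() == 0


def test_general_model_is_competitive_with_species_models(fitted):
    """On held-out data the pooled model's discrimination stays within 0.1
    AUC of the best per-species model (validation gate off, so candidate
    species models are all retained for the comparison)."""
    from sklearn.metrics import roc_auc_score
    from carbonreplace.synthetic import GeneratorConfig, generate_inventory

    _, _, training, _ = fitted
    model_set = fit_recruitment_models(training, threshold=30, settings=FAST_BRT,
                                       validate_species_models=False)
    fresh, _ = generate_inventory(GeneratorConfig(n_plots=250, seed=8))
    eval_table = build_training_table(fresh)
    spec = model_set.feature_spec
    best_auc, best_rows = -np.inf, None
    for sp, model in model_set.species_models.items():
        rows = eval_table[eval_table.species == sp]
        y = rows.newly_recruited.to_numpy(dtype=bool)
        if y.sum() < 30 or (~y).sum() < 30:
            continue
        auc = roc_auc_score(y, model.predict_proba(
            encode_features(rows, spec, include_species=False))[:, 1])
        if auc > best_auc:
            best_auc, best_rows = auc, rows
    assert best_rows is not None
    general_auc = roc_auc_score(
        best_rows.newly_recruited.to_numpy(dtype=bool),
        model_set.general_model.predict_proba(
            encode_features(best_rows, spec, include_species=True))[:, 1])
    assert general_auc > best_auc - 0.1


def test_null_labels_give_chance_level_auc(small_cohort):
    """Shuffled labels -> cross-validated AUC near 0.5."""
    tables, _ = small_cohort
    training = build_training_table(tables)
    rng = np.random.default_rng(0)
    null = training.copy()
    null["newly_recruited"] = rng.permutation(null.newly_recruited.to_numpy())
    auc = general_model_cv_auc(null, settings=FAST_BRT, n_splits=4)
    assert 0.45 <= auc <= 0.55


def test_empty_training_table_rejected():
    with pytest.raises(DataError):
        fit_recruitment_models(pd.DataFrame())
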