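"""Shared fixtures: hand-built miniature inventories and generated cohorts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from carbonreplace.inventory import HEIGHT_CLASS_COLUMNS, InventoryTables
from carbonreplace.recruitment import BRTSettings
from carbonreplace.synthetic import GeneratorConfig, generate_inventory

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

#: light boosted-tree profile used throughout the tests
FAST_BRT = BRTSettings(learning_rate=0.05, max_trees=150, cv_folds=3, seed=0)


def mini_inventory() -> InventoryTables:
    """Three clean hand-built plots with known numbers."""
    plots = pd.DataFrame({
        "plot_id": ["A", "B", "C"],
        "latitude": [44.0, 45.5, 42.2], "longitude": [-72.0, -88.1, -75.3],
        "elevation": [300.0, 410.0, 150.0],
        "time1": [2014.0, 2015.2, 2013.5], "time2": [2020.0, 2021.0, 2020.0],
        "interval_years": [6.0, 5.8, 6.5],
        "mat_c": [11.0, 9.5, 12.8], "map_mm": [1050.0, 900.0, 1100.0],
        "vpd_hpa": [8.9, 8.1, 9.6],
    })
    subplots = pd.DataFrame(
        [{"plot_id": p, "subplot": s, "ri_surveyed_time1": True,
          "ri_surveyed_time2": True} for p in "ABC" for s in range(1, 5)])
    conditions = pd.DataFrame([
        dict(condition_id="A1", plot_id="A", proportion=1.0,
             forest_type_group="maple_beech_birch", forest_type="maple beech birch",
             stand_age=80.0, physiographic_class="hillslope", slope=12.0,
             aspect=180.0, ownership="private", disturbance="none",
             at_plot_center=True, accessible_forest=True,
             artificial_regeneration=False, dwm_sampled=True, dwm_carbon=10.0),
        dict(condition_id="B1", plot_id="B", proportion=0.5,
             forest_type_group="spruce_fir", forest_type="spruce fir",
             stand_age=60.0, physiographic_class="flatwoods", slope=3.0,
             aspect=90.0, ownership="state_local", disturbance="none",
             at_plot_center=False, accessible_forest=True,
             artificial_regeneration=False, dwm_sampled=True, dwm_carbon=10.0),
        dict(condition_id="B2", plot_id="B", proportion=0.5,
             forest_type_group="spruce_fir", forest_type="spruce fir",
             stand_age=55.0, physiographic_class="flatwoods", slope=4.0,
             aspect=100.0, ownership="state_local", disturbance="none",
             at_plot_center=True, accessible_forest=True,
             artificial_regeneration=False, dwm_sampled=True, dwm_carbon=20.0),
        dict(condition_id="C1", plot_id="C", proportion=0.6,
             forest_type_group="oak_hickory", forest_type="oak hickory",
             stand_age=95.0, physiographic_class="rolling_upland", slope=20.0,
             aspect=270.0, ownership="private", disturbance="weather",
             at_plot_center=True, accessible_forest=True,
             artificial_regeneration=False, dwm_sampled=True, dwm_carbon=5.0),
        dict(condition_id="C2", plot_id="C", proportion=0.4,
             forest_type_group="oak_hickory", forest_type="oak hickory",
             stand_age=90.0, physiographic_class="rolling_upland", slope=18.0,
             aspect=260.0, ownership="private", disturbance="none",
             at_plot_center=False, accessible_forest=True,
             artificial_regeneration=False, dwm_sampled=True, dwm_carbon=15.0),
    ])
    trees = pd.DataFrame([
        # plot A, time 2: live 3 stems, one snag
        dict(tree_id="A-1", plot_id="A", subplot=1, species="ACSA", dbh=30.0,
             status="live", agc_kg=200.0, time=2, expansion=10.0),
        dict(tree_id="A-2", plot_id="A", subplot=2, species="ACSA", dbh=25.0,
             status="live", agc_kg=150.0, time=2, expansion=10.0),
        dict(tree_id="A-3", plot_id="A", subplot=3, species="FAGR", dbh=40.0,
             status="live", agc_kg=500.0, time=2, expansion=10.0),
        dict(tree_id="A-4", plot_id="A", subplot=4, species="ACSA", dbh=35.0,
             status="standing_dead", agc_kg=100.0, time=2, expansion=10.0),
        dict(tree_id="A-5", plot_id="A", subplot=1, species="ACSA", dbh=28.0,
             status="live", agc_kg=300.0, time=1, expansion=10.0),
        # plot B: live only
        dict(tree_id="B-1", plot_id="B", subplot=1, species="ABBA", dbh=20.0,
             status="live", agc_kg=120.0, time=2, expansion=10.0),
        dict(tree_id="B-2", plot_id="B", subplot=1, species="ABBA", dbh=18.0,
             status="live", agc_kg=100.0, time=1, expansion=10.0),
        # plot C: cut at time 1 only (still passes selection)
        dict(tree_id="C-1", plot_id="C", subplot=2, species="QURU", dbh=45.0,
             status="live", agc_kg=600.0, time=2, expansion=10.0),
        dict(tree_id="C-2", plot_id="C", subplot=3, species="QUAL", dbh=30.0,
             status="cut", agc_kg=250.0, time=1, expansion=10.0),
        dict(tree_id="C-3", plot_id="C", subplot=2, species="QURU", dbh=44.0,
             status="live", agc_kg=550.0, time=1, expansion=10.0),
    ])
    seedlings = pd.DataFrame([
        dict(plot_id=p, subplot=s, species=sp, time=t,
             **{c: v for c, v in zip(HEIGHT_CLASS_COLUMNS, counts)})
        for p, s, sp, t, counts in [
            ("A", 1, "ACSA", 1, (4, 2, 1, 0, 0, 0)),
            ("A", 1, "FAGR", 1, (1, 1, 0, 0, 1, 0)),
            ("A", 2, "ACSA", 1, (2, 0, 0, 1, 0, 0)),
            ("A", 1, "ACSA", 2, (3, 2, 0, 0, 0, 0)),
            ("B", 1, "ABBA", 1, (5, 3, 2, 1, 0, 0)),
            ("B", 1, "ABBA", 2, (6, 2, 1, 0, 0, 0)),
            ("C", 4, "QURU", 1, (2, 1, 0, 0, 0, 0)),
            ("C", 4, "ACRU", 2, (1, 0, 0, 0, 0, 0)),
        ]])
    saplings = pd.DataFrame([
        dict(plot_id="A", subplot=1, species="ACSA", time=2,
             present=True, newly_recruited=True),
        dict(plot_id="B", subplot=1, species="ABBA", time=1,
             present=True, newly_recruited=False),
        dict(plot_id="B", subplot=1, species="ABBA", time=2,
             present=True, newly_recruited=False),
    ])
    return InventoryTables(plots=plots, subplots=subplots, conditions=conditions,
                           trees=trees, seedlings=seedlings, saplings=saplings)


@pytest.fixture()
def mini_tables() -> InventoryTables:
    return mini_inventory()


@pytest.fixture(scope="session")
def small_cohort():
    """150 generated plots shared by model-level tests."""
    tables, truth = generate_inventory(GeneratorConfig(n_plots=150, seed=7))
    return tables, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
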