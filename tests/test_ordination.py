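"""Composition matrix construction and nonmetric MDS behaviour."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import pdist, squareform

from carbonreplace.errors import DataError
from carbonreplace.inventory import PlotCarbon
from carbonreplace.ordination import (CompositionMatrix, bray_curtis,
                                      collapse_rare_species, filter_groups,
                                      nmds, run_nmds, species_centroids,
                                      tree_c_composition,
                                      _stress_and_disparities)


class TestBrayCurtis:
    @pytest.mark.parametrize("u,v,expected", [
        ((0.2, 0.3, 0.5), (0.2, 0.3, 0.5), 0.0),
        ((1.0, 0.0), (0.0, 1.0), 1.0),           # disjoint supports
        ((0.5, 0.5, 0.0), (0.0, 0.5, 0.5), 0.5),
    ])
    def test_hand_values(self, u, v, expected):
        assert bray_curtis(u, v) == pytest.approx(expected)

    def test_two_zero_rows_are_undefined(self):
        with pytest.raises(DataError):
            bray_curtis((0.0, 0.0), (0.0, 0.0))

    @given(st.lists(st.floats(min_value=0.01, max_value=1), min_size=3, max_size=6),
           st.lists(st.floats(min_value=0.01, max_value=1), min_size=3, max_size=6))
    def test_equals_half_l1_on_relativized_rows(self, a, b):
        n = min(len(a), len(b))
        u = np.array(a[:n]) / np.sum(a[:n])
        v = np.array(b[:n]) / np.sum(b[:n])
        assert bray_curtis(u, v) == pytest.approx(0.5 * np.abs(u - v).sum())


class TestTreeCComposition:
    @pytest.mark.parametrize("live,expected", [
        ({"A": 30.0, "B": 30.0}, {"A": 0.5, "B": 0.5}),
        ({"S": 12.0}, {"S": 1.0}),
        ({"A": 50.0, "B": 25.0, "C": 25.0}, {"A": 0.5, "B": 0.25, "C": 0.25}),
    ])
    def test_shares(self, live, expected):
        pc = PlotCarbon("p", 2, live)
        assert tree_c_composition(pc) == pytest.approx(expected)

    def test_zero_live_carbon_rejected(self):
        with pytest.raises(DataError):
            tree_c_composition(PlotCarbon("p", 2, {}))


def _long(df, value):
    return df.rename_axis("plot_id").reset_index().melt(
        id_vars="plot_id", var_name="species", value_name=value)


class TestCollapseRareSpecies:
    def make_matrix(self, rng=None):
        rng = rng or np.random.default_rng(0)
        plots = [f"p{i}" for i in range(12)]
        species = list("ABCDEFGH")
        live = pd.DataFrame(rng.gamma(1.0, 10.0, size=(12, 8)),
                            index=plots, columns=species)
        recr = pd.DataFrame(rng.dirichlet(np.ones(8), size=12),
                            index=plots, columns=species)
        return _long(live, "mg_ha"), _long(recr, "score")

    def test_either_criterion_retains(self):
        live = pd.DataFrame({"plot_id": ["p1", "p1"], "species": ["A", "B"],
                             "mg_ha": [98.0, 2.0]})   # B: 2% of C
        recr = pd.DataFrame({"plot_id": ["p1"], "species": ["A"],
                             "score": [1.0]})          # B: 0% of recruitment
        matrix = collapse_rare_species(live, recr, cutoff=0.01)
        assert "B" in matrix.retained_species

    def test_rare_on_both_is_collapsed(self):
        live = pd.DataFrame({"plot_id": ["p1", "p1"], "species": ["A", "B"],
                             "mg_ha": [99.5, 0.5]})
        recr = pd.DataFrame({"plot_id": ["p1", "p1"], "species": ["A", "B"],
                             "score": [0.995, 0.005]})
        matrix = collapse_rare_species(live, recr, cutoff=0.01)
        assert "B" not in matrix.retained_species
        assert matrix.values.loc[("p1", "treeC"), "other"] == pytest.approx(0.005)

    def test_row_sums_preserved(self):
        live, recr = self.make_matrix()
        matrix = collapse_rare_species(live, recr, cutoff=0.2)  # aggressive
        sums = matrix.values.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestFilterGroups:
    def test_boundary_at_twenty_plots(self):
        groups = pd.Series(["g1"] * 19 + ["g2"] * 20,
                           index=[f"p{i}" for i in range(39)])
        types = pd.Series("t", index=groups.index)
        kept = filter_groups(groups, types)
        assert kept == set(groups.index[19:])

    def test_representative_group_sizes_all_pass(self):
        sizes = {"aspen_birch": 113, "elm_ash_cottonwood": 74,
                 "maple_beech_birch": 304, "oak_hickory": 317, "oak_pine": 34,
                 "white_red_jack_pine": 36, "spruce_fir": 198}
        idx, vals = [], []
        for g, n in sizes.items():
            idx += [f"{g}{i}" for i in range(n)]
            vals += [g] * n
        groups = pd.Series(vals, index=idx)
        types = pd.Series("t", index=idx)
        assert filter_groups(groups, types) == set(idx)

    def test_excluded_forest_types_removed(self):
        groups = pd.Series(["pine"] * 25, index=[f"p{i}" for i in range(25)])
        types = pd.Series(["red pine"] * 3 + ["white pine"] * 22,
                          index=groups.index)
        kept = filter_groups(groups, types)
        assert kept == set(groups.index[3:])


def composition_matrix(values, plots=None, source="treeC"):
    values = np.asarray(values, dtype=float)
    plots = plots or [f"p{i}" for i in range(len(values))]
    idx = pd.MultiIndex.from_tuples([(p, source) for p in plots],
                                    names=["plot_id", "source"])
    cols = [f"s{j}" for j in range(values.shape[1])]
    return CompositionMatrix(values=pd.DataFrame(values, index=idx, columns=cols),
                             retained_species=cols)


class TestNmds:
    def test_embeddable_configuration_reaches_near_zero_stress(self, rng):
        X = rng.normal(size=(10, 2))
        D = squareform(pdist(X)) ** 1.5     # monotone transform
        _, stress, _, _ = nmds(D, k=2, n_starts=20, max_iter=500, seed=0)
        assert stress < 0.01

    def test_duplicate_rows_share_scores_exactly(self, rng):
        vals = rng.dirichlet(np.ones(5), size=9)
        vals = np.vstack([vals, vals[0]])   # exact duplicate
        result = run_nmds(composition_matrix(vals), k=2, n_starts=3,
                          max_iter=200, seed=1)
        assert np.array_equal(result.scores.iloc[0].to_numpy(),
                              result.scores.iloc[9].to_numpy())

    def test_identical_rows_are_degenerate(self):
        vals = np.tile([0.5, 0.5, 0.0], (8, 1))
        with pytest.raises(DataError, match="zero-variance"):
            run_nmds(composition_matrix(vals), k=2, n_starts=2)

    def test_reported_stress_is_best_of_starts(self, rng):
        vals = rng.dirichlet(np.ones(6) * 0.7, size=25)
        result = run_nmds(composition_matrix(vals), k=3, n_starts=6,
                          max_iter=200, seed=5)
        assert result.stress == pytest.approx(result.start_stresses.min())

    def test_more_starts_never_increase_stress(self, rng):
        """With a shared seed the first starts are identical, so the best of
        10 starts is at least as good as the best of 3."""
        vals = rng.dirichlet(np.ones(6) * 0.7, size=25)
        m = composition_matrix(vals)
        few = run_nmds(m, k=3, n_starts=3, max_iter=200, seed=5)
        many = run_nmds(m, k=3, n_starts=10, max_iter=200, seed=5)
        assert many.stress <= few.stress + 1e-12
        assert np.allclose(many.start_stresses[:4], few.start_stresses)

    def test_determinism(self, rng):
        vals = rng.dirichlet(np.ones(5), size=20)
        a = run_nmds(composition_matrix(vals), k=2, n_starts=3, seed=9,
                     max_iter=150)
        b = run_nmds(composition_matrix(vals), k=2, n_starts=3, seed=9,
                     max_iter=150)
        assert np.array_equal(a.scores.to_numpy(), b.scores.to_numpy())
        assert a.stress == b.stress

    def test_stress_depends_only_on_distances(self, rng):
        """Kruskal stress-1 is invariant under orthogonal transforms of the
        configuration."""
        vals = rng.dirichlet(np.ones(5), size=15)
        dis = pdist(vals, metric="braycurtis")
        X = rng.normal(size=(15, 3))
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        s1, _ = _stress_and_disparities(dis, pdist(X))
        s2, _ = _stress_and_disparities(dis, pdist(X @ Q))
        assert s1 == pytest.approx(s2, abs=1e-9)


class TestSpeciesCentroids:
    def test_matches_brute_force(self, rng):
        vals = rng.dirichlet(np.ones(5), size=15)
        m = composition_matrix(vals)
        result = run_nmds(m, k=2, n_starts=2, max_iter=150, seed=0)
        cents = species_centroids(result, m)
        W = m.values.to_numpy()
        S = result.scores.to_numpy()
        for j, sp in enumerate(m.values.columns):
            expected = (W[:, j] @ S) / W[:, j].sum()
            assert cents.loc[sp].to_numpy() == pytest.approx(expected)

    def test_single_row_species_takes_that_rows_scores(self):
        vals = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0],
                         [0.0, 1.0], [0.0, 1.0], [0.5, 0.5],
                         [0.3, 0.7], [0.8, 0.2]])
        m = composition_matrix(vals)
        result = run_nmds(m, k=2, n_starts=2, max_iter=150, seed=0)
        scores = pd.DataFrame(result.scores)
        only = np.array([[1.0, 0.0]])
        # species s0 appears with weight 1 only in row 0 among rows {0}
        cents = species_centroids(result, m)
        w = m.values["s0"].to_numpy()
        expected = (w @ result.scores.to_numpy()) / w.sum()
        assert cents.loc["s0"].to_numpy() == pytest.approx(expected)


def test_stress_agrees_with_vegan_monomds(tmp_path, rng):
    """Independent oracle: vegan's monoMDS on the same Bray-Curtis matrix
    reaches a similar minimum stress."""
    vals = rng.dirichlet(np.ones(6) * 0.8, size=24)
    m = composition_matrix(vals)
    ours = run_nmds(m, k=3, n_starts=20, max_iter=400, seed=0)
    csv = tmp_path / "comm.csv"
    pd.DataFrame(vals).to_csv(csv, index=False)
    script = tmp_path / "nmds.R"
    script.write_text(textwrap.dedent("""
        suppressMessages(library(vegan))
        comm <- as.matrix(read.csv("%s"))
        d <- vegdist(comm, method="bray")
        set.seed(1)
        best <- Inf
        for (i in 1:20) {
          fit <- monoMDS(d, k=3, maxit=400)
          best <- min(best, fit$stress)
        }
        cat(best)
    """ % csv))
    out = subprocess.run(["Rscript", str(script)], capture_output=True,
                         text=True, check=True)
    vegan_stress = float(out.stdout.strip().split()[-1])
    assert abs(ours.stress - vegan_stress) < 0.03
    assert ours.stress < 0.2 and vegan_stress < 0.2
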