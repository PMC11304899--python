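"""Joint composition matrix and nonmetric multidimensional scaling.

Tree-carbon composition rows (per-plot species shares of live aboveground
carbon) and recruitment composition rows (relativized sapling-recruitment
likelihoods) are stacked into one matrix over a common species list, after
collapsing species rare on *both* measures into an "other" column and
dropping plots from uncommon forest-type groups.  The matrix is ordinated
with multi-start nonmetric MDS on Bray-Curtis dissimilarities, so both
composition sources live in a shared low-dimensional space.

The NMDS optimizer is a Kruskal-style SMACOF iteration: distances are fit
to dissimilarity ranks by isotonic regression (primary tie handling — ties
do not constrain each other) and the configuration is updated by the
Guttman transform.  Stress is Kruskal's stress-1.  The best of many random
starts (plus one classical-scaling start) is reported, centered and rotated
to principal axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform

from .errors import DataError
from .inventory import PlotCarbon

OTHER = "other"


@dataclass
class CompositionMatrix:
    """Rows indexed by (plot_id, source in {treeC, recruitment}); columns are
    retained species plus "other"; every row sums to one."""
    values: pd.DataFrame
    retained_species: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.values)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame          # same index as the matrix, columns axis1..axis4
    stress: float
    n_starts: int
    converged: bool
    start_stresses: np.ndarray    # stress of every retained start


# ---------------------------------------------------------------------------
# Composition rows
# ---------------------------------------------------------------------------

def tree_c_composition(plot_carbon: PlotCarbon) -> dict[str, float]:
    """Species shares of live aboveground carbon, summing to one."""
    total = plot_carbon.live_total
    if total <= 0:
        raise DataError(f"plot {plot_carbon.plot_id} has no live carbon")
    return {sp: v / total for sp, v in plot_carbon.live_by_species.items() if v > 0}


def collapse_rare_species(live_c: pd.DataFrame, recruitment: pd.DataFrame,
                          cutoff: float = 0.01) -> CompositionMatrix:
    """Stack tree-carbon and recruitment rows, collapsing rare species.

    ``live_c``: long table (plot_id, species, mg_ha) of *absolute* live
    carbon; ``recruitment``: long table (plot_id, species, score) of
    relativized recruitment scores.  A species is retained iff its share of
    summed live carbon or its share of summed recruitment scores reaches
    ``cutoff``; all others are summed into the "other" column.  Row sums
    are preserved exactly.
    """
    c_share = live_c.groupby("species")["mg_ha"].sum()
    c_share = c_share / c_share.sum()
    r_share = recruitment.groupby("species")["score"].sum()
    r_share = r_share / r_share.sum() if len(r_share) else r_share
    species = sorted(set(c_share.index) | set(r_share.index))
    retained = sorted(s for s in species
                      if c_share.get(s, 0.0) >= cutoff or r_share.get(s, 0.0) >= cutoff)

    def _pivot(long: pd.DataFrame, value: str, source: str) -> pd.DataFrame:
        wide = long.pivot_table(index="plot_id", columns="species", values=value,
                                aggfunc="sum", fill_value=0.0)
        wide = wide[wide.sum(axis=1) > 0]
        rel = wide.div(wide.sum(axis=1), axis=0)
        out = pd.DataFrame(0.0, index=rel.index, columns=retained + [OTHER])
        for sp in rel.columns:
            col = sp if sp in retained else OTHER
            out[col] += rel[sp]
        out.index = pd.MultiIndex.from_product([out.index, [source]],
                                               names=["plot_id", "source"])
        return out

    rows = pd.concat([_pivot(live_c, "mg_ha", "treeC"),
                      _pivot(recruitment, "score", "recruitment")])
    return CompositionMatrix(values=rows, retained_species=retained)


def filter_groups(plot_groups: pd.Series, plot_forest_types: pd.Series,
                  min_plots: int = 20,
                  excluded_forest_types: frozenset[str] | set[str] = frozenset(
                      {"red pine", "jack pine"})) -> set[str]:
    """Plots belonging to forest-type groups with at least ``min_plots``
    members, after removing plots of the excluded forest types."""
    keep = plot_groups[~plot_forest_types.reindex(plot_groups.index)
                       .isin(set(excluded_forest_types))]
    sizes = keep.groupby(keep).transform("size")
    return set(keep.index[sizes >= min_plots])


# ---------------------------------------------------------------------------
# Bray-Curtis + NMDS
# ---------------------------------------------------------------------------

def bray_curtis(u, v) -> float:
    """Sum|u-v| / Sum(u+v) for non-negative abundance rows."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DataError("rows must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise DataError("negative abundances")
    denom = (u + v).sum()
    if denom == 0:
        raise DataError("Bray-Curtis undefined for two all-zero rows")
    return float(np.abs(u - v).sum() / denom)


def _stress_and_disparities(dis: np.ndarray, d: np.ndarray) -> tuple[float, np.ndarray]:
    order = np.lexsort((d, dis))
    fit = isotonic_regression(d[order]).x
    dhat = np.empty_like(d)
    dhat[order] = fit
    ssd = (d ** 2).sum()
    if ssd == 0:
        return np.inf, dhat
    dhat = dhat * np.sqrt(ssd / max((dhat ** 2).sum(), 1e-300))
    stress = np.sqrt(((d - dhat) ** 2).sum() / ssd)
    return float(stress), dhat


def _nmds_single(D: np.ndarray, k: int, init: np.ndarray,
                 max_iter: int, eps: float) -> tuple[np.ndarray, float]:
    n = D.shape[0]
    dis = squareform(D, checks=False)
    X = init - init.mean(axis=0)
    last = np.inf
    stress = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        stress, dhat = _stress_and_disparities(dis, d)
        if last - stress < eps:
            break
        last = stress
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, dhat / d, 0.0)
        B = -squareform(ratio, checks=False)
        np.fill_diagonal(B, squareform(ratio, checks=False).sum(axis=1))
        X = B @ X / n
        X -= X.mean(axis=0)
    return X, stress


def _pcoa_init(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - 1.0 / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:k]
    return V[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))


def _principal_axes(X: np.ndarray) -> np.ndarray:
    """Center, rotate to principal axes, deterministic axis signs."""
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for j in range(X.shape[1]):
        if X[np.argmax(np.abs(X[:, j])), j] < 0:
            X[:, j] = -X[:, j]
    return X


def nmds(D: np.ndarray, k: int = 4, n_starts: int = 250, max_iter: int = 999,
         seed: int = 0, eps: float = 1e-7
         ) -> tuple[np.ndarray, float, np.ndarray, np.ndarray | None]:
    """Best-of-starts nonmetric MDS on a precomputed dissimilarity matrix.

    Start 0 is a classical-scaling (principal coordinates) configuration;
    the remaining ``n_starts`` starts are random.  Returns (scores, stress,
    per-start stresses, runner-up configuration); scores are centered and
    rotated to principal axes with a deterministic sign convention.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < k + 2:
        raise DataError(f"need at least {k + 2} rows for a {k}-d ordination")
    if squareform(D, checks=False).max() == 0:
        raise DataError("zero-variance configuration")
    rng = np.random.default_rng(seed)
    inits = [_pcoa_init(D, k)]
    inits += [rng.normal(size=(n, k)) for _ in range(n_starts)]
    stresses = np.empty(len(inits))
    configs = []
    for i, init in enumerate(inits):
        X, s = _nmds_single(D, k, init, max_iter, eps)
        stresses[i] = s
        configs.append(X)
    order = np.argsort(stresses, kind="stable")
    best = configs[order[0]]
    runner_up = configs[order[1]] if len(configs) > 1 else None
    return _principal_axes(best), float(stresses[order[0]]), stresses, runner_up


def run_nmds(matrix: CompositionMatrix, k: int = 4, n_starts: int = 250,
             max_iter: int = 999, seed: int = 0, eps: float = 1e-7,
             converged_rms: float = 1e-3) -> OrdinationResult:
    """Ordinate a composition matrix with Bray-Curtis dissimilarities.

    Exactly duplicated rows are embedded once and share scores (their
    dissimilarity of zero is preserved by construction).  The two
    lowest-stress starts are compared by Procrustes RMS difference to call
    convergence.
    """
    values = matrix.values.to_numpy(dtype=float)
    if (values.sum(axis=1) == 0).any():
        raise DataError("all-zero composition row")
    if len(values) < k + 2:
        raise DataError(f"need at least {k + 2} rows for a {k}-d ordination")
    uniq, inverse = np.unique(values, axis=0, return_inverse=True)
    if len(uniq) == 1:
        raise DataError("zero-variance configuration")
    D = squareform(pdist(uniq, metric="braycurtis"))
    X, stress, stresses, runner_up = nmds(D, k=k, n_starts=n_starts,
                                          max_iter=max_iter, seed=seed, eps=eps)
    converged = False
    if runner_up is not None:
        try:
            _, _, disparity = procrustes(X, runner_up)
            converged = bool(np.sqrt(disparity) < converged_rms)
        except ValueError:
            converged = False
    scores = pd.DataFrame(X[inverse], index=matrix.values.index,
                          columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult(scores=scores, stress=stress, n_starts=n_starts,
                            converged=converged, start_stresses=stresses)


def species_centroids(result: OrdinationResult,
                      matrix: CompositionMatrix) -> pd.DataFrame:
    """Abundance-weighted mean row score per species (for biplot arrows)."""
    W = matrix.values.to_numpy(dtype=float)          # rows x species
    S = result.scores.to_numpy(dtype=float)          # rows x axes
    totals = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = (W.T @ S) / totals[:, None]
    return pd.DataFrame(C, index=matrix.values.columns,
                        columns=result.scores.columns)
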