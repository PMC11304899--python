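# Methods

`carbonreplace` implements a plot-level indicator of whether the species
composition of current tree regeneration is consistent with maintaining
aboveground live-tree carbon: each remeasured inventory plot is classified
as poised for carbon **loss**, **replacement**, or **gain**.

## Pipeline

1. **Data model.** Plots carry four subplots, each with one 13.5 m²
   microplot where seedlings (< 2.5 cm DBH) are tallied in six ordered
   height classes and sapling (2.5–12.6 cm) presence is recorded at two
   measurement times ~5–8 years apart. Trees ≥ 12.7 cm DBH are recorded per
   subplot with per-stem aboveground carbon (an input column — allometry is
   upstream of this package) and a per-hectare expansion factor. Site
   attributes live on mapped *conditions* with plot-area proportions;
   a plot takes the attributes of its largest condition (plot-center
   condition on ties). Analysis plots must have complete regeneration
   surveys on all four subplots at both times, lie entirely on accessible
   forest land, have no artificial regeneration, complete downed-wood
   sampling, and no harvest in the latest measurement.
2. **Recruitment likelihood.** For every subplot × species with seedlings
   at time 1, a boosted-tree classifier predicts whether a new sapling of
   that species recruits by time 2, from the six height-class counts plus
   elevation, slope, aspect (sin/cos), latitude, longitude, stand age,
   forest type group and physiographic class. Species with more than 30
   recruitment-positive subplots get their own model; a pooled general
   model (species identity one-hot encoded) serves the rest. A species
   with no seedlings has recruitment probability zero by assumption, so
   such rows never enter training or prediction. Time-2 probabilities are
   averaged over the four subplots (absences count as zero) and divided by
   their sum: the **recruitment composition**, which sums to 1.
3. **Ordination.** Tree-carbon composition rows (species shares of live
   carbon) and recruitment composition rows are stacked into one matrix.
   Species below 1 % of *both* total live carbon and total recruitment
   score are collapsed into "other"; plots from forest-type groups with
   < 20 plots, and red/jack pine forest types, are removed first (the
   order is configurable). The matrix is ordinated by nonmetric MDS on
   Bray–Curtis dissimilarities in 4 dimensions, so both composition
   sources share one space.
4. **Carbon models.** A 1000-tree regression forest predicts live (and
   total = live + snag + downed-wood) carbon from the four tree-carbon
   axis scores plus stand age, physiographic class, forest type group,
   elevation, slope, aspect, ownership, disturbance, and either
   latitude/longitude or three climate normals (the better out-of-bag set
   is selectable). Accuracy is OOB pseudo-r² = 1 − MSE_oob/Var(y).
5. **Replacement indicator.** The live-carbon model is evaluated twice per
   plot at stand age 100, once with the plot's tree-carbon axis scores and
   once with its recruitment scores, all other covariates at observed
   values. delta = pred(recruitment) − pred(treeC); |delta| ≤ 5 Mg C ha⁻¹
   is *replacement*, below −5 *loss*, above +5 *gain*. A sensitivity sweep
   repeats this at ages 60–140 (20-year steps; the range's endpoints and
   midpoints bracket it cheaply). Category differences in 16 site/stand
   variables are screened with Kruskal–Wallis (continuous) or chi-square
   (categorical) tests under a single Holm–Bonferroni family.

## Nonmetric MDS implementation

The optimizer is a Kruskal-style SMACOF iteration written here: at each
step, disparities are the isotonic (monotone) regression of configuration
distances on dissimilarity order — ties handled by the *primary* rule, so
tied dissimilarities do not constrain each other — rescaled to the
distances' sum of squares, and the configuration is updated by the Guttman
transform. Stress is Kruskal's stress-1. A run takes the best of many
starts (default 250 random starts, 999 iterations, convergence when stress
improves by < 1e-7), with one extra classical-scaling (PCoA) start;
convergence of the reported solution is declared when the two best starts
agree to Procrustes RMS < 1e-3. Scores are centered, rotated to principal
axes, and sign-fixed deterministically. Exactly duplicated rows are
embedded once and share scores. This component is hand-written because the
general-purpose nonmetric MDS available in the Python stack converges to
degenerate high-stress solutions on composition matrices; the test suite
cross-checks stress against vegan's `monoMDS` in R on a small matrix.

A practical note on degeneracy: when a large share of Bray–Curtis values
is exactly 1 (plots with disjoint species lists), nonmetric scaling can
collapse to a near-perfect one-dimensional "cluster" solution. The
synthetic generator avoids this regime the same way real regional
inventories do — cosmopolitan species (e.g. red maple) appear across
forest-type groups, keeping compositions connected.

## Boosted-tree settings

The canonical ecological recipe is the library default: learning rate
0.01, tree depth 3, 50 % bag fraction, tree count chosen by 10-fold
cross-validated binomial deviance along the boosting path, capped at 5000.
The pipeline profile ships a cheaper variant (learning rate 0.05, 3 folds,
cap 250) chosen once for the synthetic study sizes used here; both are
plain `BRTSettings` and either can be selected in the run config.

Per-species models are *candidates* once a species exceeds the
30-positive-subplot threshold, but a candidate is retained only if its
out-of-fold binomial deviance matches or beats the general model's on the
same rows (`validate_species_models` toggles this gate; deviance is the
same criterion that selects tree counts). Rationale: on a few hundred
subplots a species-specific model cannot out-learn a pooled model that
borrows strength across species unless recruitment really is
species-idiosyncratic; validating the candidates decides this from the
data rather than assuming it. The out-of-fold probabilities come free from
the tree-count cross-validation, so the gate costs nothing.

## Random-forest settings

1000 trees, p/3 features per split, bootstrap resampling, minimum leaf
size 5 (the regression-forest defaults of the reference R
implementation). Categorical predictors are one-hot encoded with the
encoding recorded in the fitted model; circular aspect enters as
sin/cos (configurable to raw degrees). Variable importance is the mean
per-tree out-of-bag MSE increase under within-predictor permutation
divided by its standard deviation over trees; one-hot blocks and the
sin/cos pair are permuted jointly so each predictor gets one score.
Partial dependence is brute-force marginal averaging over the training
distribution; grids outside the observed range are clamped with a
warning. Fitting canonicalizes row order (sorts by plot id), so
predictions do not depend on input row order. Models of carbon-stock
*change* are deliberately not implemented: their explanatory power is too
low to support an indicator.

## Synthetic inventory generator

The generator defines the study conditions for all tests; defaults:

| Parameter | Default | Meaning |
|---|---|---|
| group weights | 113/74/304/317/34/36/198 | plot counts by forest-type group, mirroring a representative regional inventory |
| stand age | uniform 15–140 yr | time-2 condition age |
| remeasurement interval | uniform 4.7–8.1 yr | per plot |
| live C curve | 95 Mg ha⁻¹ × c_pot × (1−e^(−0.025·age))^1.3 | Chapman-Richards-shaped; c_pot is the composition-weighted species carbon potential (0.55–1.40) |
| latitude effect | −2.5 %/° north of 43° | togglable asymptote multiplier |
| live C noise | SD 8 Mg ha⁻¹ | plot-level |
| downed wood | gamma, mean 8, SD 6 Mg ha⁻¹ | per condition; noisier than live C so the total-C model scores lower, as in real inventories |
| seedling tallies | negative-binomial (shape 1.5), declining height profile (0.35…0.05) | per microplot × species × class |
| recruitment law | logit p = −2.5 + Σ c_k·log1p(n_k) + 0.004·(age−70) − 0.004·slope, c = (0.2, 0.3, 0.45, 0.6, 0.8, 1.0) | monotone in every height class, taller classes weighted more |
| regeneration mix | Dirichlet(30 · center), center = 0.4·pool + 0.6·overstory mix | couples regeneration to the local stand |

Overstory mixes are Dirichlet draws (concentration 8) around group-level
species weights; per-stem carbon is allocated so plot totals match the
target curve exactly, making the composition→carbon link recoverable.
*Shifted cohorts* reweight the regeneration pool toward low- or
high-carbon-potential species with magnitude m ∈ (0, 1] (m = 1
concentrates all regeneration mass on the extreme species and removes the
overstory coupling), giving cohorts whose true replacement direction is
known. What the generator does **not** emulate: spatial autocorrelation,
browsing or disturbance-driven regeneration failure, demographic dynamics
beyond two measurements, and realistic climate surfaces (climate normals
are noisy functions of location). Passing tests therefore demonstrate
that the pipeline recovers a known composition–carbon signal under
realistic sampling noise — not that any particular real landscape behaves
this way.

## Problem sizes and numerical choices

The shipped tests and the acceptance script run the full study on cohorts
of 250–500 plots with 2–6 random NMDS starts (plus the PCoA start),
max 150–300 iterations at tolerance 1e-6, and the cheap boosted-tree
profile — sizes chosen for quick, deterministic desk runs; all are plain
config fields. Determinism: one top-level seed spawns per-stage seeds via
`numpy.random.SeedSequence`; CSV floats are written with `%.10g`, so
rerunning a config reproduces artifacts byte-for-byte. Degenerate inputs:
two all-zero composition rows make Bray–Curtis undefined (error); an
all-identical composition matrix is a zero-variance configuration (error);
plots with no live carbon contribute no tree-carbon row, plots with no
seedlings anywhere contribute no recruitment row, and plots missing either
row are flagged not assessable and excluded from category proportions.

## Known limitations

* The indicator is a composition-swap counterfactual, not a projection of
  future carbon; it inherits the carbon model's attenuation, so extreme
  true deltas are pulled toward "replacement".
* Recruitment probabilities are per-species and independent; competitive
  interactions among recruits are ignored.
* Height-class bounds are protocol metadata, not modelled quantities; the
  classes act as ordered features only.
* Snag carbon uses the same expansion logic as live trees (the protocol
  does not say otherwise).
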