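"""Synthetic remeasured regeneration-indicator inventories with known truth.

Real regeneration-indicator plot data carry restricted coordinates and
cannot be redistributed, so every downstream stage of the pipeline is
exercised against inventories drawn from a generator with an explicit
ground truth:

* stand live carbon follows a saturating (Chapman-Richards-shaped) age
  curve whose asymptote is scaled by the composition-weighted carbon
  potential of the species mix and (optionally) decreases with latitude;
* seedling tallies are negative-binomial per height class with a declining
  height profile, centred on a per-plot regeneration mix;
* sapling recruitment outcomes are independent Bernoulli draws whose
  probability comes from a known logistic law over the six time-1
  height-class tallies and site covariates.

The regeneration mix of each plot is a Dirichlet draw centred on a blend of
the plot's own overstory mix and the pool-level regeneration weights; a
*shifted cohort* reweights the pool toward low- or high-carbon-potential
species, giving cohorts whose intended replacement direction is known.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .inventory import HEIGHT_CLASS_COLUMNS, InventoryTables, N_SUBPLOTS

EXPANSION = 14.88  # stems/ha represented by one subplot stem (4 x 168 m2)


@dataclass(frozen=True)
class SpeciesParams:
    code: str
    overstory_weight: float
    regen_weight: float
    c_potential: float  # relative asymptote multiplier, >= 0


@dataclass(frozen=True)
class RecruitmentLaw:
    """Logistic law: logit p = intercept + sum_c class_coefs[c]*log1p(n_c)
    + age_coef*(stand_age-70) + slope_coef*slope.  Monotone in every height
    class because all class coefficients are positive, with taller classes
    weighted more heavily (taller advance regeneration recruits more)."""
    intercept: float = -2.5
    class_coefs: tuple[float, ...] = (0.20, 0.30, 0.45, 0.60, 0.80, 1.00)
    age_coef: float = 0.004
    slope_coef: float = -0.004

    def probability(self, counts, stand_age, slope) -> np.ndarray:
        counts = np.asarray(counts, dtype=float)
        z = (self.intercept
             + np.log1p(counts) @ np.asarray(self.class_coefs)
             + self.age_coef * (np.asarray(stand_age, dtype=float) - 70.0)
             + self.slope_coef * np.asarray(slope, dtype=float))
        return 1.0 / (1.0 + np.exp(-z))


def default_species_pool() -> dict[str, list[SpeciesParams]]:
    """Species pools per forest type group, northeastern/midwestern USA.

    Carbon potentials roughly track the capacity of each species to
    accumulate stand-level aboveground carbon (shade-tolerant northern
    hardwoods and white pine high; black spruce and tamarack low).
    """
    def sp(code, w, c):
        return SpeciesParams(code, w, w, c)

    return {
        "aspen_birch": [sp("POTR", .40, .85), sp("BEPA", .25, .80),
                        sp("ACRU", .12, 1.00), sp("ABBA", .08, .70),
                        sp("PIST", .05, 1.40), sp("ACSA", .05, 1.35),
                        sp("PIRU", .05, .95)],
        "elm_ash_cottonwood": [sp("ULAM", .30, .90), sp("FRAM", .30, 1.00),
                               sp("ACRU", .15, 1.00), sp("ACSA", .10, 1.35),
                               sp("QURU", .08, 1.25), sp("POTR", .07, .85)],
        "maple_beech_birch": [sp("ACSA", .35, 1.35), sp("FAGR", .18, 1.20),
                              sp("BEAL", .12, 1.15), sp("ACRU", .12, 1.00),
                              sp("TSCA", .08, 1.30), sp("BEPA", .05, .80),
                              sp("FRAM", .05, 1.00), sp("QURU", .05, 1.25)],
        "oak_hickory": [sp("QURU", .30, 1.25), sp("QUAL", .20, 1.20),
                        sp("CAGL", .12, 1.05), sp("ACRU", .15, 1.00),
                        sp("PIST", .08, 1.40), sp("FRAM", .08, 1.00),
                        sp("ACSA", .07, 1.35)],
        "oak_pine": [sp("PIST", .30, 1.40), sp("QURU", .25, 1.25),
                     sp("QUAL", .12, 1.20), sp("ACRU", .18, 1.00),
                     sp("CAGL", .08, 1.05), sp("POTR", .07, .85)],
        "white_red_jack_pine": [sp("PIST", .50, 1.40), sp("TSCA", .12, 1.30),
                                sp("ACRU", .15, 1.00), sp("PIRU", .08, .95),
                                sp("BEPA", .08, .80), sp("QURU", .07, 1.25)],
        "spruce_fir": [sp("ABBA", .28, .70), sp("PIRU", .22, .95),
                       sp("PIMA", .15, .60), sp("LALA", .08, .55),
                       sp("THOC", .12, .75), sp("BEPA", .08, .80),
                       sp("ACRU", .07, 1.00)],
    }


#: plot counts by forest type group in a representative regional inventory
DEFAULT_GROUP_WEIGHTS = {
    "aspen_birch": 113, "elm_ash_cottonwood": 74, "maple_beech_birch": 304,
    "oak_hickory": 317, "oak_pine": 34, "white_red_jack_pine": 36,
    "spruce_fir": 198,
}

_EXCLUDED_PINE_TYPES = ("red pine", "jack pine")


@dataclass
class GeneratorConfig:
    n_plots: int = 200
    seed: int = 0
    forest_type_group_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS))
    species_pool: dict[str, list[SpeciesParams]] = field(
        default_factory=default_species_pool)
    stand_age_range: tuple[float, float] = (15.0, 140.0)
    remeasurement_interval_range: tuple[float, float] = (4.7, 8.1)
    recruitment_law: RecruitmentLaw = field(default_factory=RecruitmentLaw)

    # carbon model: asymptote_base * c_potential * lat_mult * (1-exp(-k*age))^shape
    asymptote_base: float = 95.0    # Mg C/ha at c_potential 1, latitude 43
    curve_rate: float = 0.025       # 1/yr
    curve_shape: float = 1.3
    noise_sd: float = 8.0           # Mg C/ha, live carbon
    latitude_effect: bool = True
    latitude_slope: float = 0.025   # fractional asymptote loss per degree north of 43

    dwm_mean: float = 8.0           # Mg C/ha, condition-level downed wood
    dwm_sd: float = 6.0             # deliberately noisier than live carbon
    snag_rate: float = 2.0          # expected snags per plot

    # regeneration mix: Dirichlet centred on
    # (1-coupling)*pool_regen + coupling*overstory_mix
    regen_coupling: float = 0.6
    overstory_concentration: float = 8.0
    regen_concentration: float = 30.0
    seedling_intensity: float = 8.0      # expected seedlings per microplot
    seedling_dispersion: float = 1.5     # negative-binomial shape
    height_profile: tuple[float, ...] = (0.35, 0.25, 0.16, 0.11, 0.08, 0.05)
    sapling_presence_rate: float = 0.12  # time-1 sapling presence

    # fraction of white/red/jack pine plots typed as red or jack pine
    excluded_pine_type_rate: float = 0.0
    p_two_conditions: float = 0.15

    # flag-injection rates (clean plots by default); each violates exactly
    # one plot-selection criterion
    p_unsurveyed: float = 0.0
    p_inaccessible: float = 0.0
    p_artificial: float = 0.0
    p_dwm_unsampled: float = 0.0
    p_cut: float = 0.0

    # cohort shift bookkeeping (set by make_shifted_cohort)
    shift_direction: str = "neutral"   # neutral | loss | gain
    reference_age: float = 100.0

    def validate(self) -> None:
        if self.n_plots <= 0:
            raise ConfigError("n_plots must be positive")
        if not self.forest_type_group_weights:
            raise ConfigError("forest_type_group_weights is empty")
        if any(w < 0 for w in self.forest_type_group_weights.values()):
            raise ConfigError("group weights must be non-negative")
        for g in self.forest_type_group_weights:
            pool = self.species_pool.get(g, [])
            if not pool:
                raise ConfigError(f"species pool for group '{g}' is empty")
            if any(s.c_potential < 0 or s.overstory_weight < 0 or s.regen_weight < 0
                   for s in pool):
                raise ConfigError(f"negative weight in species pool '{g}'")
        if len(self.height_profile) != 6:
            raise ConfigError("height_profile needs 6 classes")


@dataclass
class GroundTruth:
    """What the generator knows that the pipeline must recover."""
    recruitment: pd.DataFrame   # plot_id, subplot, species, true_p
    plots: pd.DataFrame         # plot_id, true_c_tree, true_c_regen, direction
    reference_age: float


def expected_live_carbon(cfg: GeneratorConfig, age, c_potential, latitude) -> np.ndarray:
    """Noise-free live carbon (Mg/ha) of the generator's age curve."""
    lat_mult = 1.0
    if cfg.latitude_effect:
        lat_mult = 1.0 - cfg.latitude_slope * (np.asarray(latitude, dtype=float) - 43.0)
    curve = (1.0 - np.exp(-cfg.curve_rate * np.asarray(age, dtype=float))) ** cfg.curve_shape
    return cfg.asymptote_base * np.asarray(c_potential, dtype=float) * lat_mult * curve


def make_shifted_cohort(config: GeneratorConfig, shift: str,
                        magnitude: float) -> GeneratorConfig:
    """Config whose regeneration pool is reweighted toward low- or
    high-carbon-potential species; overstory weights untouched.

    ``magnitude`` in (0, 1]: at 1 the regeneration mass of each group is
    concentrated on its extreme-carbon-potential species, and the per-plot
    coupling to the local overstory is removed.
    """
    if shift not in ("toward_low_c", "toward_high_c"):
        raise ConfigError(f"unknown shift '{shift}'")
    if not (0.0 < magnitude <= 1.0):
        raise ConfigError("magnitude must be in (0, 1]")
    sign = -1.0 if shift == "toward_low_c" else 1.0
    pool = {}
    for group, species in config.species_pool.items():
        cpot = np.array([s.c_potential for s in species])
        lo, hi = cpot.min(), cpot.max()
        z = (cpot - lo) / (hi - lo) if hi > lo else np.zeros_like(cpot)
        temp = 0.3 * (1.0 - magnitude) + 1e-9
        target = np.exp(sign * z / temp)
        target /= target.sum()
        regen = np.array([s.regen_weight for s in species])
        regen = regen / regen.sum()
        new = (1.0 - magnitude) * regen + magnitude * target
        pool[group] = [dataclasses.replace(s, regen_weight=float(w))
                       for s, w in zip(species, new)]
    return dataclasses.replace(
        config,
        species_pool=pool,
        regen_coupling=config.regen_coupling * (1.0 - magnitude),
        shift_direction="loss" if sign < 0 else "gain",
    )


def _neg_binomial(rng: np.random.Generator, mean: np.ndarray, shape: float) -> np.ndarray:
    """Gamma-Poisson mixture; elementwise means, shared dispersion."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) / shape)
    return rng.poisson(lam)


def generate_inventory(config: GeneratorConfig) -> tuple[InventoryTables, GroundTruth]:
    """Draw a full remeasured inventory plus its ground truth.

    Identical config (including seed) yields identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    groups = sorted(config.forest_type_group_weights)
    gw = np.array([config.forest_type_group_weights[g] for g in groups], dtype=float)
    gw /= gw.sum()

    plot_rows, subplot_rows, cond_rows = [], [], []
    tree_rows, seedling_rows, sapling_rows = [], [], []
    gt_recr_rows, gt_plot_rows = [], []

    for i in range(config.n_plots):
        pid = f"P{i:05d}"
        group = groups[rng.choice(len(groups), p=gw)]
        pool = config.species_pool[group]
        codes = [s.code for s in pool]
        cpot = np.array([s.c_potential for s in pool])
        over_w = np.array([s.overstory_weight for s in pool])
        over_w = over_w / over_w.sum()
        regen_w = np.array([s.regen_weight for s in pool])
        regen_w = regen_w / regen_w.sum()

        latitude = rng.uniform(38.0, 48.0)
        longitude = rng.uniform(-97.0, -67.0)
        elevation = max(0.0, rng.normal(350.0, 200.0))
        interval = rng.uniform(*config.remeasurement_interval_range)
        time2 = 2020.0 + rng.uniform(0.0, 3.0)
        time1 = time2 - interval
        mat_c = 12.0 - 0.7 * (latitude - 43.0) + rng.normal(0.0, 0.8)
        map_mm = 1000.0 + 6.0 * (longitude + 82.0) + rng.normal(0.0, 80.0)
        vpd_hpa = 9.0 + 0.5 * (mat_c - 12.0) + rng.normal(0.0, 0.6)
        plot_rows.append(dict(plot_id=pid, latitude=latitude, longitude=longitude,
                              elevation=elevation, time1=time1, time2=time2,
                              interval_years=interval, mat_c=mat_c,
                              map_mm=map_mm, vpd_hpa=vpd_hpa))

        unsurveyed = rng.random() < config.p_unsurveyed
        for sub in range(1, N_SUBPLOTS + 1):
            ok = not (unsurveyed and sub == 1)
            subplot_rows.append(dict(plot_id=pid, subplot=sub,
                                     ri_surveyed_time1=ok, ri_surveyed_time2=True))

        # --- conditions -------------------------------------------------
        stand_age = float(rng.integers(int(config.stand_age_range[0]),
                                       int(config.stand_age_range[1]) + 1))
        forest_type = group.replace("_", " ")
        if (group == "white_red_jack_pine"
                and rng.random() < config.excluded_pine_type_rate):
            forest_type = _EXCLUDED_PINE_TYPES[int(rng.integers(2))]
        two = rng.random() < config.p_two_conditions
        props = (0.6, 0.4) if two else (1.0,)
        phys = rng.choice(["hillslope", "rolling_upland", "flatwoods", "floodplain",
                           "dry_slope", "ridge", "deep_sand", "swamp"],
                          p=[.25, .25, .1, .1, .1, .08, .06, .06])
        own = rng.choice(["private", "national_forest", "other_federal", "state_local"],
                         p=[.6, .2, .05, .15])
        dist = rng.choice(["none", "insects", "disease", "fire", "animals",
                           "weather", "vegetation", "human", "unknown"],
                          p=[.62, .08, .05, .04, .06, .07, .03, .03, .02])
        slope = abs(rng.normal(8.0, 8.0))
        aspect = rng.uniform(0.0, 360.0)
        inaccessible = rng.random() < config.p_inaccessible
        artificial = rng.random() < config.p_artificial
        dwm_unsampled = rng.random() < config.p_dwm_unsampled
        for j, prop in enumerate(props):
            dwm_shape = (config.dwm_mean / config.dwm_sd) ** 2
            dwm_c = rng.gamma(dwm_shape, config.dwm_mean / dwm_shape)
            cond_rows.append(dict(
                condition_id=f"{pid}C{j + 1}", plot_id=pid, proportion=prop,
                forest_type_group=group, forest_type=forest_type,
                stand_age=stand_age if j == 0 else max(config.stand_age_range[0],
                                                       stand_age - 10.0),
                physiographic_class=phys, slope=slope, aspect=aspect,
                ownership=own, disturbance=dist, at_plot_center=(j == 0),
                accessible_forest=not (inaccessible and j == len(props) - 1),
                artificial_regeneration=artificial and j == 0,
                dwm_sampled=not (dwm_unsampled and j == 0), dwm_carbon=dwm_c))

        # --- overstory mix and live carbon ------------------------------
        over_mix = rng.dirichlet(config.overstory_concentration * over_w + 1e-3)
        cpot_tree = float(over_mix @ cpot)
        plot_noise = rng.normal(0.0, config.noise_sd)
        tree_count = 0
        for t, age_t in ((1, stand_age - interval), (2, stand_age)):
            target = expected_live_carbon(config, age_t, cpot_tree, latitude)
            target = max(3.0, float(target) + plot_noise + rng.normal(0.0, 2.0))
            n_stems = int(rng.poisson(22)) + 4
            stems = rng.multinomial(n_stems, over_mix)
            stems = np.where((over_mix > 1e-9) & (stems == 0), 1, stems)
            share = target * over_mix / max(over_mix.sum(), 1e-12)
            for k, code in enumerate(codes):
                if stems[k] == 0:
                    continue
                agc = share[k] * 1000.0 / (EXPANSION * stems[k])
                for _ in range(int(stems[k])):
                    tree_count += 1
                    tree_rows.append(dict(
                        tree_id=f"{pid}T{tree_count}", plot_id=pid,
                        subplot=int(rng.integers(1, N_SUBPLOTS + 1)), species=code,
                        dbh=max(12.7, float(rng.lognormal(3.3, 0.3))),
                        status="live", agc_kg=agc, time=t, expansion=EXPANSION))
            for _ in range(rng.poisson(config.snag_rate)):
                tree_count += 1
                tree_rows.append(dict(
                    tree_id=f"{pid}T{tree_count}", plot_id=pid,
                    subplot=int(rng.integers(1, N_SUBPLOTS + 1)),
                    species=codes[int(rng.choice(len(codes), p=over_mix))],
                    dbh=max(12.7, float(rng.lognormal(3.2, 0.3))),
                    status="standing_dead",
                    agc_kg=float(rng.gamma(2.0, 60.0)), time=t, expansion=EXPANSION))
            if t == 2 and rng.random() < config.p_cut:
                tree_count += 1
                tree_rows.append(dict(
                    tree_id=f"{pid}T{tree_count}", plot_id=pid, subplot=1,
                    species=codes[0], dbh=20.0, status="cut", agc_kg=0.0,
                    time=2, expansion=EXPANSION))

        # --- regeneration mix, seedlings, saplings ----------------------
        center = ((1.0 - config.regen_coupling) * regen_w
                  + config.regen_coupling * over_mix)
        regen_mix = rng.dirichlet(config.regen_concentration * center + 1e-3)
        cpot_regen = float(regen_mix @ cpot)

        profile = np.asarray(config.height_profile)
        profile = profile / profile.sum()
        tallies: dict[tuple[int, int], dict[str, np.ndarray]] = {}
        for t in (1, 2):
            for sub in range(1, N_SUBPLOTS + 1):
                lam_total = rng.lognormal(np.log(config.seedling_intensity), 0.5)
                for k, code in enumerate(codes):
                    mean = lam_total * regen_mix[k] * profile
                    counts = _neg_binomial(rng, mean, config.seedling_dispersion)
                    if counts.sum() == 0:
                        continue
                    tallies.setdefault((t, sub), {})[code] = counts
                    seedling_rows.append(dict(
                        plot_id=pid, subplot=sub, species=code, time=t,
                        **{c: int(v) for c, v in zip(HEIGHT_CLASS_COLUMNS, counts)}))

        for sub in range(1, N_SUBPLOTS + 1):
            t1 = tallies.get((1, sub), {})
            for code in codes:
                present_t1 = (code in t1) and rng.random() < config.sapling_presence_rate
                if present_t1:
                    sapling_rows.append(dict(plot_id=pid, subplot=sub, species=code,
                                             time=1, present=True,
                                             newly_recruited=False))
                newly = False
                if code in t1:
                    p = float(config.recruitment_law.probability(
                        t1[code], stand_age, slope))
                    newly = bool(rng.random() < p)
                    gt_recr_rows.append(dict(plot_id=pid, subplot=sub,
                                             species=code, true_p=p))
                if newly or present_t1:
                    sapling_rows.append(dict(plot_id=pid, subplot=sub, species=code,
                                             time=2, present=True,
                                             newly_recruited=newly))

        ref = config.reference_age
        gt_plot_rows.append(dict(
            plot_id=pid,
            true_c_tree=float(expected_live_carbon(config, ref, cpot_tree, latitude)),
            true_c_regen=float(expected_live_carbon(config, ref, cpot_regen, latitude)),
            direction=config.shift_direction))

    tables = InventoryTables(
        plots=pd.DataFrame(plot_rows),
        subplots=pd.DataFrame(subplot_rows),
        conditions=pd.DataFrame(cond_rows),
        trees=pd.DataFrame(tree_rows),
        seedlings=pd.DataFrame(seedling_rows),
        saplings=pd.DataFrame(sapling_rows),
    )
    truth = GroundTruth(recruitment=pd.DataFrame(gt_recr_rows),
                        plots=pd.DataFrame(gt_plot_rows),
                        reference_age=config.reference_age)
    return tables, truth
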