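"""Synthetic FFQ-cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
two-factor latent structure in the energy-adjusted nutrient densities, a
six-cluster mixture of participants in factor-score space, Dirichlet
food-group energy composition, and consistent diet-quality index inputs.
Every stage of the pipeline is therefore testable without any external
data set.

The latent model for participant *i* in cluster *c* is

    f_i ~ Normal(centroid_c, I_2)                       (factor scores)
    x_i = Λ f_i + ε_i,  ε_i ~ Normal(0, diag(u^2))      (standardized densities)
    d_iv = a_v (1 + s x_iv)                             (positive density scale)
    raw_iv = d_iv × energy_i / 1000                     (daily amounts)

where Λ holds the planted loadings, u the per-variable residual SDs and
a_v the target mean density of variable v. The affine map (a_v, s) is
recorded in the metadata so tests can invert it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    EXTRA_NUTRIENTS,
    FOOD_GROUPS,
    GROUP_PREFIX,
    HEI_PREFIX,
    MEDDIET_PREFIX,
    N_CARB_ITEMS,
    PATTERN_VARIABLES,
    RATIO_VARIABLES,
)

# Planted two-factor loading pattern over the 18 pattern variables:
# block 1 loads on the "plant-origin" factor, block 2 on "animal-origin".
DEFAULT_LOADINGS = np.array([
    # plant  animal
    [0.858, 0.0],    # folate
    [0.789, 0.0],    # magnesium
    [0.718, 0.0],    # potassium
    [-0.707, 0.0],   # carbohydrate/fiber ratio
    [0.698, 0.0],    # thiamin
    [0.613, 0.0],    # vitamin B-6
    [0.584, 0.0],    # copper
    [0.545, 0.0],    # niacin
    [0.527, 0.0],    # vitamin C
    [0.0, 0.813],    # phosphorus
    [0.0, 0.811],    # vitamin B-12
    [0.0, 0.772],    # animal/plant protein ratio
    [0.0, 0.753],    # calcium
    [0.0, 0.726],    # riboflavin
    [0.0, 0.652],    # zinc
    [0.0, -0.622],   # (MUFA+PUFA)/SFA ratio
    [0.0, 0.597],    # selenium
    [0.0, 0.581],    # cholesterol
])

# Default six-cluster centroids on the (plant, animal) factor planes; the
# sign pattern mirrors clusters that score positively on the plant factor
# (C1, C5, C6) and on the animal factor (C1, C2, C3).
DEFAULT_CENTROIDS = np.array([
    [1.3, 1.3],
    [-2.0, 2.6],
    [-1.0, 1.0],
    [-2.3, -2.0],
    [1.0, -1.0],
    [2.9, -0.7],
])

DEFAULT_N_PER_CLUSTER = (179, 33, 142, 67, 127, 60)

# Target mean densities per 1000 kcal (ratios unit-free), chosen so that at
# typical pregnancy energies (~1900 kcal/d) raw intakes sit in a realistic
# relation to the pregnancy DRIs: mostly adequate micronutrients, marginal
# magnesium/zinc, low fiber.
TARGET_DENSITY = {
    "folate": 300.0,            # µg/1000 kcal
    "magnesium": 150.0,         # mg
    "potassium": 1.6,           # g
    "carb_fiber_ratio": 12.0,
    "thiamin": 0.75,            # mg
    "vitamin_b6": 0.9,          # mg
    "copper": 700.0,            # µg
    "niacin": 9.0,              # mg
    "vitamin_c": 60.0,          # mg
    "phosphorus": 650.0,        # mg
    "vitamin_b12": 2.5,         # µg
    "animal_plant_protein_ratio": 1.8,
    "calcium": 550.0,           # mg
    "riboflavin": 1.0,          # mg
    "zinc": 5.5,                # mg
    "unsat_sat_ratio": 1.6,
    "selenium": 55.0,           # µg
    "cholesterol": 140.0,       # mg
}

# Relative amplitude of the standardized latent signal on the density scale.
DENSITY_REL_SCALE = 0.10

# Base Dirichlet weights for the 19 food-group energy shares (global diet
# composition; per-cluster tilts applied on top).
_BASE_GROUP_ALPHA = np.array([
    10.0,  # white breads & cereals
    4.0,   # whole breads & cereals
    7.0,   # pasta, rice, potatoes
    3.0,   # vegetables
    8.0,   # fruits & juices
    1.5,   # nuts
    3.5,   # low-fat dairy
    2.5,   # full-fat dairy
    5.0,   # white cheese
    2.0,   # yellow cheese
    4.0,   # red meat
    0.5,   # meat products
    2.0,   # poultry
    0.5,   # egg
    2.0,   # seafood
    3.0,   # legumes
    5.5,   # sweets
    0.5,   # soft drinks
    1.5,   # ready-to-eat
])

# Multiplicative per-cluster tilts (rows: clusters, keyed by group index).
_CLUSTER_TILTS = {
    0: {1: 1.4, 4: 1.2, 6: 1.5},               # mixed, dairy-leaning
    1: {7: 2.0, 9: 1.5, 10: 1.3, 16: 1.3},     # full-fat dairy / meat
    2: {0: 1.4, 16: 1.4, 10: 1.1},             # refined grains / sweets
    3: {0: 1.5, 16: 1.7, 17: 2.0, 18: 1.5},    # energy-dense, low quality
    4: {3: 1.4, 15: 1.3, 4: 1.1},              # vegetables / legumes
    5: {1: 2.2, 4: 1.4, 5: 2.0, 15: 1.3},      # Mediterranean-leaning
}

# Fraction of daily energy covered by the 19 groups.
GROUP_ENERGY_COVERAGE = 0.85

MEDDIET_COMPONENTS = (
    "nonrefined_cereals", "potatoes", "fruits", "vegetables", "legumes",
    "fish", "olive_oil", "dairy", "red_meat_products", "poultry",
)
# Base monthly consumption frequencies and the factor effects applied to them
# (plant score raises protective plant foods, animal score raises meats).
_MEDDIET_BASE = np.array([14.0, 10.0, 20.0, 22.0, 8.0, 8.0, 24.0, 18.0, 10.0, 8.0])
_MEDDIET_PLANT_EFF = np.array([3.0, 0.5, 3.0, 3.0, 2.0, 0.5, 2.0, 0.5, -1.5, -0.5])
_MEDDIET_ANIMAL_EFF = np.array([-1.0, 0.0, -1.0, -0.5, -1.0, 1.0, -0.5, 1.5, 2.5, 1.5])

HEI_COMPONENTS = (
    "total_fruit", "whole_fruit", "total_vegetables", "greens_beans",
    "whole_grains", "dairy", "total_protein", "seafood_plant_protein",
    "fatty_acid_ratio", "refined_grains", "sodium", "empty_calories",
)
# Density units per 1000 kcal (cup/oz eq, ratio, g, % energy).
_HEI_BASE = np.array([0.7, 0.35, 0.9, 0.15, 0.9, 1.0, 2.4, 0.6, 1.9, 2.4, 1.5, 26.0])
_HEI_PLANT_EFF = np.array([0.08, 0.05, 0.12, 0.04, 0.25, 0.02, 0.05, 0.06, 0.15, -0.35, -0.10, -3.0])
_HEI_ANIMAL_EFF = np.array([-0.03, -0.02, -0.03, -0.01, -0.08, 0.08, 0.12, 0.0, -0.10, 0.05, 0.08, 0.8])
_HEI_NOISE = np.array([0.10, 0.06, 0.12, 0.04, 0.15, 0.12, 0.25, 0.10, 0.20, 0.30, 0.15, 4.0])

# (name, GI on the white-bread scale) of the carbohydrate-bearing items.
CARB_ITEM_GI = np.array([100.0, 65.0, 52.0, 84.0])  # white bread, pasta, fruit, sweets
_CARB_W_BASE = np.array([0.30, 0.25, 0.25, 0.20])
_CARB_W_PLANT = np.array([-0.05, 0.0, 0.06, -0.01])
_CARB_W_ANIMAL = np.array([0.02, 0.0, -0.03, 0.01])


@dataclass
class SyntheticConfig:
    """Generating parameters of a synthetic FFQ cohort.

    Defaults reproduce the study conditions the analysis is designed for: a
    608-participant cohort split 179/33/142/67/127/60 over six clusters,
    with the planted two-factor loading structure of the 18 energy-adjusted
    nutrient variables.
    """

    n_per_cluster: tuple[int, ...] = DEFAULT_N_PER_CLUSTER
    centroids: np.ndarray = field(default_factory=lambda: DEFAULT_CENTROIDS.copy())
    loadings_true: np.ndarray = field(default_factory=lambda: DEFAULT_LOADINGS.copy())
    uniqueness: np.ndarray | None = None  # default: sqrt(1 - communality)
    energy_log_mean: float = float(np.log(1900.0))
    energy_log_sd: float = 0.20
    group_concentration: np.ndarray | None = None  # k x 19 Dirichlet params
    dri_margin: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.loadings_true = np.asarray(self.loadings_true, dtype=float)
        k = len(self.n_per_cluster)
        if any(int(n) <= 0 for n in self.n_per_cluster):
            raise ValueError("n_per_cluster entries must be positive")
        if self.centroids.shape != (k, self.loadings_true.shape[1]):
            raise ValueError(
                f"centroids shape {self.centroids.shape} does not conform to "
                f"k={k} clusters and m={self.loadings_true.shape[1]} factors"
            )
        if self.uniqueness is None:
            communality = np.minimum((self.loadings_true ** 2).sum(axis=1), 1.0)
            self.uniqueness = np.sqrt(1.0 - communality)
        self.uniqueness = np.asarray(self.uniqueness, dtype=float)
        if self.uniqueness.shape != (self.loadings_true.shape[0],):
            raise ValueError("uniqueness must have one entry per variable")
        if np.any(self.uniqueness < 0):
            raise ValueError("uniqueness values must be >= 0")
        if self.group_concentration is None:
            self.group_concentration = _default_group_concentration(k)
        self.group_concentration = np.asarray(self.group_concentration, dtype=float)
        if self.group_concentration.shape != (k, len(FOOD_GROUPS)):
            raise ValueError(
                f"group_concentration must be k x {len(FOOD_GROUPS)}"
            )
        if np.any(self.group_concentration <= 0):
            raise ValueError("Dirichlet parameters must be > 0")

    @property
    def n_total(self) -> int:
        return int(sum(self.n_per_cluster))

    @property
    def k(self) -> int:
        return len(self.n_per_cluster)


def _default_group_concentration(k: int) -> np.ndarray:
    alpha = np.tile(_BASE_GROUP_ALPHA, (k, 1))
    for c in range(k):
        for g, mult in _CLUSTER_TILTS.get(c, {}).items():
            alpha[c, g] *= mult
    return alpha


def generate_cohort(config: SyntheticConfig) -> CohortTable:
    """Draw a full synthetic cohort from the latent two-factor mixture.

    Deterministic for a fixed ``config.seed``: a single pseudo-random stream
    is consumed in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_total
    p, m = config.loadings_true.shape
    if p != len(PATTERN_VARIABLES):
        raise ValueError(
            f"loadings_true must have {len(PATTERN_VARIABLES)} rows "
            "(one per pattern variable)"
        )

    labels = np.repeat(np.arange(config.k), config.n_per_cluster)

    # Latent factor scores and standardized densities (fixed draw order).
    f = config.centroids[labels] + rng.standard_normal((n, m))
    eps = rng.standard_normal((n, p)) * config.uniqueness
    x = f @ config.loadings_true.T + eps

    # Positive density scale: d = a (1 + s x), a = target mean x DRI margin.
    a = np.array([
        TARGET_DENSITY[v] * config.dri_margin.get(v, 1.0) for v in PATTERN_VARIABLES
    ])
    density = np.maximum(a * (1.0 + DENSITY_REL_SCALE * x), 0.0)

    energy = rng.lognormal(config.energy_log_mean, config.energy_log_sd, size=n)

    data: dict[str, np.ndarray] = {
        "participant_id": np.arange(1, n + 1),
        "cluster_truth": labels + 1,
        "energy_kcal": energy,
    }
    for j, v in enumerate(PATTERN_VARIABLES):
        if v in RATIO_VARIABLES:
            data[v] = density[:, j]  # unit-free, stored as-is
        else:
            data[v] = density[:, j] * energy / 1000.0

    # Macronutrients for the adequacy stage; fiber is tied to the generated
    # carbohydrate/fiber ratio so derive_ratios() round-trips.
    protein_density = 40.0 * config.dri_margin.get("protein", 1.0) * (
        1.0 + 0.08 * rng.standard_normal(n))
    carb_density = 120.0 * config.dri_margin.get("carbohydrate", 1.0) * (
        1.0 + 0.08 * rng.standard_normal(n))
    protein_density = np.maximum(protein_density, 1.0)
    carb_density = np.maximum(carb_density, 1.0)
    data["protein"] = protein_density * energy / 1000.0
    data["carbohydrate"] = carb_density * energy / 1000.0
    ratio = np.maximum(data["carb_fiber_ratio"], 1e-6)
    data["fiber"] = data["carbohydrate"] / ratio

    # Food-group energies: Dirichlet composition per cluster x coverage.
    shares = np.empty((n, len(FOOD_GROUPS)))
    for c in range(config.k):
        idx = labels == c
        shares[idx] = rng.dirichlet(config.group_concentration[c], size=int(idx.sum()))
    group_energy = shares * (GROUP_ENERGY_COVERAGE * energy)[:, None]
    for g, name in enumerate(FOOD_GROUPS):
        data[GROUP_PREFIX + name] = group_energy[:, g]

    # MedDiet component consumptions (servings/month).
    plant = f[:, 0]
    animal = f[:, 1] if m > 1 else np.zeros(n)
    med = (
        _MEDDIET_BASE
        + np.outer(plant, _MEDDIET_PLANT_EFF)
        + np.outer(animal, _MEDDIET_ANIMAL_EFF)
        + 2.0 * rng.standard_normal((n, len(MEDDIET_COMPONENTS)))
    )
    med = np.maximum(med, 0.0)
    for j, comp in enumerate(MEDDIET_COMPONENTS):
        data[MEDDIET_PREFIX + comp] = med[:, j]

    # HEI-2010 component densities.
    hei = (
        _HEI_BASE
        + np.outer(plant, _HEI_PLANT_EFF)
        + np.outer(animal, _HEI_ANIMAL_EFF)
        + rng.standard_normal((n, len(HEI_COMPONENTS))) * _HEI_NOISE
    )
    hei = np.maximum(hei, 0.0)
    for j, comp in enumerate(HEI_COMPONENTS):
        data[HEI_PREFIX + comp] = hei[:, j]

    # Carbohydrate items for the dietary GI: 65% of total carbohydrate split
    # over four GI-bearing foods with factor-dependent weights.
    w = (
        _CARB_W_BASE
        + np.outer(plant, _CARB_W_PLANT)
        + np.outer(animal, _CARB_W_ANIMAL)
    )
    w = np.maximum(w, 0.01)
    w /= w.sum(axis=1, keepdims=True)
    avail = 0.65 * data["carbohydrate"]
    for i in range(N_CARB_ITEMS):
        data[f"carb{i + 1}_g"] = w[:, i] * avail
        data[f"carb{i + 1}_gi"] = np.full(n, CARB_ITEM_GI[i])

    df = pd.DataFrame(data)
    meta = {
        "generator": "nutripatterns.synthetic",
        "seed": int(config.seed),
        "n_per_cluster": [int(v) for v in config.n_per_cluster],
        "centroids": config.centroids,
        "loadings_true": config.loadings_true,
        "uniqueness": config.uniqueness,
        "density_affine": {
            "intercept": a,
            "slope": a * DENSITY_REL_SCALE,
            "variables": list(PATTERN_VARIABLES),
        },
        "factor_scores_true": f,
        "units": {"energy_kcal": "kcal/d"},
    }
    return CohortTable(df, meta)


def inject_overconsumers(cohort: CohortTable, count: int, seed: int = 0) -> CohortTable:
    """Rescale ``count`` random participants above 3500 kcal/d.

    Raw nutrient amounts, food-group energies and carbohydrate items are
    rescaled proportionally, so densities are unchanged; used to exercise
    the exclusion stage.
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    if count > len(cohort):
        raise ValueError("count exceeds cohort size")
    out = cohort.copy()
    if count == 0:
        return out
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(out.df), size=count, replace=False)
    old = out.df["energy_kcal"].to_numpy(float).copy()
    new = rng.uniform(3600.0, 4500.0, size=count)
    factor = new / old[idx]

    scale_cols = [
        c for c in out.df.columns
        if (c in set(PATTERN_VARIABLES) - set(RATIO_VARIABLES))
        or c in EXTRA_NUTRIENTS
        or c.startswith(GROUP_PREFIX)
        or (c.startswith("carb") and c.endswith("_g"))
    ]
    rows = out.df.index[idx]
    out.df.loc[rows, "energy_kcal"] = new
    for c in scale_cols:
        out.df.loc[rows, c] = out.df.loc[rows, c].to_numpy(float) * factor
    out.meta["injected_overconsumers"] = sorted(int(i) for i in out.df.loc[rows, "participant_id"])
    return out
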