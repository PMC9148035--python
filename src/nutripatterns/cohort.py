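"""Cohort container and the canonical variable/group vocabularies.

A :class:`CohortTable` wraps one participant-per-row table holding daily
energy, raw nutrient intakes (natural units per day), food-group energies
(kcal/d), the inputs of the diet-quality indexes and the per-item available
carbohydrate/GI pairs, together with a metadata sidecar (generating
parameters, column units, truth labels for synthetic cohorts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# The 18 energy-adjusted input variables of the pattern stage: 15 nutrient
# densities plus three derived ratios treated as input variables in their
# own right.
PATTERN_VARIABLES: tuple[str, ...] = (
    "folate",
    "magnesium",
    "potassium",
    "carb_fiber_ratio",
    "thiamin",
    "vitamin_b6",
    "copper",
    "niacin",
    "vitamin_c",
    "phosphorus",
    "vitamin_b12",
    "animal_plant_protein_ratio",
    "calcium",
    "riboflavin",
    "zinc",
    "unsat_sat_ratio",
    "selenium",
    "cholesterol",
)

# Unit-free quotients: stored as-is, never divided by energy.
RATIO_VARIABLES: tuple[str, ...] = (
    "carb_fiber_ratio",
    "animal_plant_protein_ratio",
    "unsat_sat_ratio",
)

# Extra raw nutrients carried for the adequacy stage (not pattern inputs).
EXTRA_NUTRIENTS: tuple[str, ...] = ("protein", "carbohydrate", "fiber")

# The 19 food groups used for energy-share profiling.
FOOD_GROUPS: tuple[str, ...] = (
    "white_breads_cereals",
    "whole_breads_cereals",
    "pasta_rice_potatoes",
    "vegetables",
    "fruits_juices",
    "nuts",
    "low_fat_dairy",
    "full_fat_dairy",
    "white_cheese",
    "yellow_cheese",
    "red_meat",
    "meat_products",
    "poultry",
    "egg",
    "seafood",
    "legumes",
    "sweets",
    "soft_drinks",
    "ready_to_eat",
)

GROUP_PREFIX = "grp_"
MEDDIET_PREFIX = "med_"
HEI_PREFIX = "hei_"
N_CARB_ITEMS = 4


@dataclass
class CohortTable:
    """Participant-level intake table plus generating/mapping metadata.

    Parameters
    ----------
    df : pandas.DataFrame
        One row per participant. Required columns: ``participant_id``,
        ``energy_kcal``; nutrient columns carry raw daily amounts except the
        ratio variables, which are unit-free.
    meta : dict
        Free-form metadata (units, generator parameters, affine transform
        used to place densities on a positive scale, truth labels).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "energy_kcal" not in self.df.columns:
            raise ValueError("cohort table requires an 'energy_kcal' column")
        energy = self.df["energy_kcal"].to_numpy()
        if not np.all(energy > 0):
            raise ValueError("energy_kcal must be strictly positive")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def energy(self) -> pd.Series:
        return self.df["energy_kcal"]

    @property
    def nutrient_columns(self) -> list[str]:
        known = set(PATTERN_VARIABLES) | set(EXTRA_NUTRIENTS)
        return [c for c in self.df.columns if c in known]

    @property
    def group_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith(GROUP_PREFIX)]

    def group_energy(self) -> pd.DataFrame:
        """Food-group energies (kcal/d), columns in FOOD_GROUPS order."""
        cols = [GROUP_PREFIX + g for g in FOOD_GROUPS if GROUP_PREFIX + g in self.df.columns]
        out = self.df[cols].copy()
        out.columns = [c[len(GROUP_PREFIX):] for c in cols]
        return out

    def carb_items(self) -> list[np.ndarray]:
        """Per-participant (available carb g/d, gi) pairs as two arrays.

        Returns [carbs (n, k), gis (n, k)].
        """
        carb_cols = sorted(c for c in self.df.columns if c.startswith("carb") and c.endswith("_g"))
        gi_cols = [c[:-2] + "_gi" for c in carb_cols]
        return [self.df[carb_cols].to_numpy(float), self.df[gi_cols].to_numpy(float)]

    def copy(self) -> "CohortTable":
        return CohortTable(self.df.copy(), dict(self.meta))

    # ---- I/O: delimited table + structured-text sidecar -------------------
    def write(self, path: str | Path, sep: str = ",") -> None:
        path = Path(path)
        self.df.to_csv(path, sep=sep, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        with open(sidecar, "w") as fh:
            json.dump(self.meta, fh, indent=2, default=_jsonify)

    @classmethod
    def read(cls, path: str | Path, sep: str = ",") -> "CohortTable":
        path = Path(path)
        df = pd.read_csv(path, sep=sep)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = {}
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
        return cls(df, meta)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
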