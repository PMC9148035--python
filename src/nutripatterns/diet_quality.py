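"""Food-group energy shares and the a priori diet-quality indexes.

Three complementary views of overall diet quality:

* the share of daily energy contributed by each of 19 food groups;
* the pregnancy-modified MedDiet Score (10 components, 0-5 points each,
  total 0-50; dairy protective, alcohol excluded);
* the HEI-2010 total (12 density-based components, 0-100); and
* the dietary glycemic index, the available-carbohydrate-weighted mean GI
  of consumed foods on the white-bread reference scale.

Component standards ship as structured-text configs (see ``data/``) and can
be overridden by the user.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable, HEI_PREFIX, MEDDIET_PREFIX

GLUCOSE_TO_WHITE_BREAD = 100.0 / 70.0


@dataclass
class IndexStandards:
    """Scoring standards for the MedDiet Score, HEI-2010 and dietary GI."""

    meddiet: dict
    hei2010: dict
    gi_table: dict

    def __post_init__(self) -> None:
        comps = self.meddiet["components"]
        if len(comps) != 10:
            raise ValueError("pregnancy MedDiet Score requires exactly 10 components")
        total = sum(c["max_points"] for c in self.hei2010["components"])
        if total != 100:
            raise ValueError(f"HEI-2010 max points must sum to 100, got {total}")


def _load_yaml(name_or_path) -> dict:
    p = Path(name_or_path)
    if p.exists():
        with open(p) as fh:
            return yaml.safe_load(fh)
    ref = resources.files("nutripatterns").joinpath("data", str(name_or_path))
    with ref.open() as fh:
        return yaml.safe_load(fh)


def load_default_standards(
    meddiet: str = "meddiet_standards.yaml",
    hei2010: str = "hei2010_standards.yaml",
    gi_table: str = "gi_table.yaml",
) -> IndexStandards:
    """Load the shipped (or user-overridden) standards files."""
    return IndexStandards(
        meddiet=_load_yaml(meddiet),
        hei2010=_load_yaml(hei2010),
        gi_table=_load_yaml(gi_table),
    )


def group_energy_shares(cohort: CohortTable) -> pd.DataFrame:
    """Per-participant food-group energies as percentages of total energy."""
    ge = cohort.group_energy()
    energy = cohort.df["energy_kcal"].to_numpy(float)
    if np.any(energy <= 0):
        raise ValueError("total energy must be positive for share computation")
    shares = 100.0 * ge.to_numpy(float) / energy[:, None]
    out = pd.DataFrame(shares, columns=ge.columns,
                       index=cohort.df["participant_id"].to_numpy())
    out.index.name = "participant_id"
    if (out.to_numpy().sum(axis=1) > 100 + 1e-9).any():
        raise ValueError("food-group energies exceed total energy for some rows")
    return out


def _meddiet_component_score(x: float, thresholds, direction: str) -> int:
    # protective: boundary consumption moves to the higher-scoring band;
    # adverse: to the lower-scoring band (same >= count, subtracted from 5)
    count = int(np.sum(np.asarray(thresholds, dtype=float) <= x))
    if direction == "protective":
        return count
    if direction == "adverse":
        return 5 - count
    raise ValueError(f"unknown component direction: {direction}")


def meddiet_score(consumptions: dict, standards: IndexStandards) -> int:
    """Pregnancy-modified MedDiet Score (integer, 0-50).

    ``consumptions`` maps each of the 10 component names to a monthly
    consumption frequency. Protective components score 0-5 with increasing
    consumption; adverse components are reverse-scored.
    """
    total = 0
    for comp in standards.meddiet["components"]:
        name = comp["name"]
        if name not in consumptions:
            raise ValueError(f"missing MedDiet component: {name}")
        x = float(consumptions[name])
        if x < 0:
            raise ValueError(f"negative consumption for {name}")
        total += _meddiet_component_score(x, comp["thresholds"], comp["direction"])
    return int(total)


def meddiet_component_scores(consumptions: dict, standards: IndexStandards) -> dict:
    """Per-component MedDiet points (for auditing a total score)."""
    return {
        comp["name"]: _meddiet_component_score(
            float(consumptions[comp["name"]]), comp["thresholds"], comp["direction"])
        for comp in standards.meddiet["components"]
    }


def hei2010_score(component_densities: dict, energy: float,
                  standards: IndexStandards) -> float:
    """HEI-2010 total score (0-100) from component densities.

    Each component is scored by linear interpolation between its
    zero-score and maximum-score standards, truncated to [0, max points];
    moderation components (zero standard above max standard) are thereby
    reverse-scored. Densities are per 1000 kcal (or unitless/%-energy as
    configured), so the total is invariant to proportional energy scaling.
    """
    if energy <= 0:
        raise ValueError("energy must be positive")
    total = 0.0
    for comp in standards.hei2010["components"]:
        name = comp["name"]
        if name not in component_densities:
            raise ValueError(f"missing HEI-2010 component: {name}")
        x = float(component_densities[name])
        if x < 0:
            raise ValueError(f"negative density for {name}")
        mx, zero, pts = comp["max_standard"], comp["zero_standard"], comp["max_points"]
        score = pts * (x - zero) / (mx - zero)
        total += float(np.clip(score, 0.0, pts))
    return total


def dietary_gi(carb_items, gi_scale: str = "white_bread") -> float:
    """Dietary glycemic index: carb-weighted mean GI of consumed foods.

    ``carb_items`` is a sequence of (available carbohydrate g/d, gi) pairs.
    ``gi_scale='glucose'`` converts item GIs from the glucose scale to the
    white-bread reference (x 100/70).
    """
    items = [(float(c), float(g)) for c, g in carb_items]
    carbs = np.array([c for c, _ in items])
    gis = np.array([g for _, g in items])
    if np.any(carbs < 0):
        raise ValueError("negative carbohydrate amount")
    total = carbs.sum()
    if total <= 0:
        raise ValueError("total available carbohydrate must be positive")
    if gi_scale == "glucose":
        gis = gis * GLUCOSE_TO_WHITE_BREAD
    elif gi_scale != "white_bread":
        raise ValueError("gi_scale must be 'white_bread' or 'glucose'")
    return float((gis * carbs).sum() / total)


def score_cohort(cohort: CohortTable, standards: IndexStandards) -> pd.DataFrame:
    """All three index scores for every participant of a cohort.

    Expects MedDiet inputs in ``med_*`` columns (servings/month), HEI-2010
    component densities in ``hei_*`` columns, and carbohydrate items in
    ``carb{i}_g`` / ``carb{i}_gi`` columns.
    """
    med_cols = {c[len(MEDDIET_PREFIX):]: c for c in cohort.df.columns
                if c.startswith(MEDDIET_PREFIX)}
    hei_cols = {c[len(HEI_PREFIX):]: c for c in cohort.df.columns
                if c.startswith(HEI_PREFIX)}
    carbs, gis = cohort.carb_items()
    energy = cohort.df["energy_kcal"].to_numpy(float)

    rows = []
    for i in range(len(cohort.df)):
        med_in = {name: cohort.df[col].iat[i] for name, col in med_cols.items()}
        hei_in = {name: cohort.df[col].iat[i] for name, col in hei_cols.items()}
        rows.append({
            "meddiet": meddiet_score(med_in, standards),
            "hei2010": hei2010_score(hei_in, energy[i], standards),
            "dietary_gi": dietary_gi(list(zip(carbs[i], gis[i]))),
        })
    out = pd.DataFrame(rows, index=cohort.df["participant_id"].to_numpy())
    out.index.name = "participant_id"
    return out


def cluster_index_table(scores: pd.DataFrame, labels) -> pd.DataFrame:
    """Median, mean and SD of each index per cluster (report layout)."""
    df = scores.copy()
    df["cluster"] = np.asarray(labels)
    agg = df.groupby("cluster").agg(["median", "mean", "std"])
    agg.columns = [f"{idx}_{stat}" for idx, stat in agg.columns]
    return agg
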