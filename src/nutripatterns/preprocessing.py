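"""Exclusion filtering, energy adjustment and derived nutrient ratios.

Implausible energy reporters (default: above 3500 kcal/d) are removed,
raw daily intakes are converted to nutrient densities (amount per
1000 kcal), and the three unit-free ratios used as pattern inputs are
derived. Densities are deliberately NOT standardized here: the pattern
stage operates on the correlation matrix, which standardizes implicitly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortTable, PATTERN_VARIABLES, RATIO_VARIABLES

DEFAULT_ENERGY_CAP = 3500.0  # kcal/d


class RatioDenominatorError(ValueError):
    """A ratio denominator is zero (or negative) for at least one record."""


def apply_exclusions(
    cohort: CohortTable, energy_cap: float = DEFAULT_ENERGY_CAP
) -> tuple[CohortTable, list]:
    """Drop participants with energy intake strictly above ``energy_cap``.

    The boundary value (exactly ``energy_cap`` kcal/d) is retained. Row
    order is preserved. Returns the filtered cohort and the excluded
    participant ids. Idempotent.
    """
    if energy_cap <= 0:
        raise ValueError("energy_cap must be positive")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    energy = cohort.df["energy_kcal"].to_numpy(float)
    keep = energy <= energy_cap
    excluded = cohort.df.loc[~keep, "participant_id"].tolist()
    kept_df = cohort.df.loc[keep].reset_index(drop=True)
    meta = dict(cohort.meta)
    meta["excluded_ids"] = [int(i) for i in excluded]
    meta["energy_cap_kcal"] = float(energy_cap)
    if kept_df.empty:
        # an all-excluded cohort is a legitimate (if degenerate) outcome;
        # bypass the CohortTable energy validation on the empty frame
        out = CohortTable.__new__(CohortTable)
        out.df = kept_df
        out.meta = meta
        return out, excluded
    return CohortTable(kept_df, meta), excluded


def energy_adjust(raw_amount, energy):
    """Nutrient density: amount per 1000 kcal of energy intake.

    Scale-equivariant: doubling amount and energy together leaves the
    density unchanged. Accepts scalars or aligned arrays.
    """
    energy_arr = np.asarray(energy, dtype=float)
    if np.any(energy_arr <= 0):
        raise ValueError("energy must be strictly positive for density adjustment")
    result = np.asarray(raw_amount, dtype=float) * 1000.0 / energy_arr
    if result.ndim == 0:
        return float(result)
    return result


def derive_ratios(
    raw_nutrients: pd.DataFrame | dict,
    zero_floor: float | None = None,
) -> pd.DataFrame:
    """Derive carb/fiber, animal/plant protein and (MUFA+PUFA)/SFA ratios.

    Expects columns/keys ``carbohydrate``, ``fiber``, ``animal_protein``,
    ``plant_protein``, ``mufa``, ``pufa``, ``sfa`` (daily amounts, any
    consistent units). A zero denominator raises
    :class:`RatioDenominatorError` unless ``zero_floor`` (a strictly
    positive replacement for zero denominators, intended for synthetic
    stress tests) is given.
    """
    df = pd.DataFrame(raw_nutrients)
    needed = ["carbohydrate", "fiber", "animal_protein", "plant_protein", "mufa", "pufa", "sfa"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"missing component nutrients: {missing}")

    def _den(name: str) -> np.ndarray:
        d = df[name].to_numpy(float)
        bad = d <= 0
        if bad.any():
            if zero_floor is None:
                rows = np.nonzero(bad)[0].tolist()
                raise RatioDenominatorError(
                    f"non-positive denominator '{name}' at rows {rows}"
                )
            if zero_floor <= 0:
                raise ValueError("zero_floor must be strictly positive")
            d = np.where(bad, zero_floor, d)
        return d

    out = pd.DataFrame(index=df.index)
    out["carb_fiber_ratio"] = df["carbohydrate"].to_numpy(float) / _den("fiber")
    out["animal_plant_protein_ratio"] = (
        df["animal_protein"].to_numpy(float) / _den("plant_protein")
    )
    out["unsat_sat_ratio"] = (
        (df["mufa"].to_numpy(float) + df["pufa"].to_numpy(float)) / _den("sfa")
    )
    return out


def build_density_matrix(
    cohort: CohortTable, variables: tuple[str, ...] = PATTERN_VARIABLES
) -> pd.DataFrame:
    """Assemble the n x p matrix of energy-adjusted pattern variables.

    Nutrient columns are converted to densities (per 1000 kcal); the
    unit-free ratio variables are passed through unadjusted. Raises if any
    value is missing or any density is negative.
    """
    missing = [v for v in variables if v not in cohort.df.columns]
    if missing:
        raise ValueError(f"cohort lacks pattern variables: {missing}")
    energy = cohort.df["energy_kcal"].to_numpy(float)
    cols = {}
    for v in variables:
        raw = cohort.df[v].to_numpy(float)
        cols[v] = raw if v in RATIO_VARIABLES else energy_adjust(raw, energy)
    out = pd.DataFrame(cols, index=cohort.df["participant_id"].to_numpy())
    out.index.name = "participant_id"
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values in density matrix columns {bad}")
    if (out.to_numpy() < 0).any():
        bad = out.columns[(out < 0).any()].tolist()
        raise ValueError(f"negative densities in columns {bad}")
    return out
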