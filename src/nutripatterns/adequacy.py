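"""Nutritional-adequacy appraisal per cluster.

Two complementary estimators of the prevalence of adequate intake:

* **Probability approach** (Beaton): for nutrients with an established EAR
  and SD of requirement, each individual's probability of adequacy is
  Phi((intake - EAR)/SD) and the cluster estimate is the mean individual
  probability, expressed as a percentage.
* **EAR cut-point method**: for nutrients with only an AI (fiber,
  potassium) or an EAR without an SD (calcium), the cluster estimate is the
  percentage of individuals whose intake - rounded to the precision of the
  reference value - is at or above it.

Point estimates carry 95% BCa bootstrap confidence intervals (bootstrap over
individuals, default 500 resamples) and a P10/P25/P50/P75/P90 percentile
row of the individual probabilities (probability nutrients) or usual
intakes (cut-point nutrients).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

DEFAULT_B = 500
DEFAULT_PERCENTILES = (10, 25, 50, 75, 90)


@dataclass(frozen=True)
class DRIReference:
    """Per-nutrient reference values and assessment route.

    ``method`` is ``probability`` (requires ``ear`` and ``sd``) or
    ``cutpoint`` (requires exactly one of ``ai`` or ``ear``). ``decimals``
    is the rounding precision applied to intakes before the cut-point
    comparison.
    """

    name: str
    method: str
    ear: float | None = None
    sd: float | None = None
    ai: float | None = None
    units: str = ""
    decimals: int = 0

    def __post_init__(self) -> None:
        if self.method == "probability":
            if not (self.ear and self.ear > 0 and self.sd and self.sd > 0):
                raise ValueError(
                    f"{self.name}: probability method needs ear > 0 and sd > 0")
        elif self.method == "cutpoint":
            if (self.ai is None) == (self.ear is None):
                raise ValueError(
                    f"{self.name}: cutpoint method needs exactly one of ai or ear")
        else:
            raise ValueError(f"{self.name}: unknown method {self.method!r}")

    @property
    def cutoff(self) -> float:
        if self.method != "cutpoint":
            raise ValueError("cutoff defined only for the cut-point method")
        return float(self.ai if self.ai is not None else self.ear)


def load_dri_table(path: str | Path | None = None) -> dict[str, DRIReference]:
    """Load the DRI config (shipped pregnancy defaults if no path given)."""
    if path is None:
        ref = resources.files("nutripatterns").joinpath("data", "dri_pregnancy.yaml")
        with ref.open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table = {}
    for item in raw["nutrients"]:
        sd = item.get("sd")
        if sd is None and item.get("cv") is not None:
            sd = float(item["cv"]) * float(item["ear"])
        table[item["name"]] = DRIReference(
            name=item["name"],
            method=item["method"],
            ear=item.get("ear"),
            sd=sd,
            ai=item.get("ai"),
            units=item.get("units", ""),
            decimals=int(item.get("decimals", 0)),
        )
    return table


def probability_of_adequacy(intake, ref: DRIReference):
    """Individual probability of adequacy: Phi((intake - EAR)/SD)."""
    if ref.method != "probability":
        raise ValueError(f"{ref.name} is not a probability-approach nutrient")
    return stats.norm.cdf((np.asarray(intake, dtype=float) - ref.ear) / ref.sd)


def cluster_probability_adequacy(intakes, ref: DRIReference) -> float:
    """Cluster prevalence of adequacy (%): mean individual probability x 100."""
    intakes = np.asarray(intakes, dtype=float)
    if intakes.size == 0:
        raise ValueError("empty cluster")
    return float(100.0 * probability_of_adequacy(intakes, ref).mean())


def cutpoint_adequacy(intakes, ref: DRIReference) -> float:
    """Percentage of individuals at/above the AI (or EAR), after rounding.

    Intakes are rounded to the reference precision before comparison; an
    intake exactly at the reference value counts as adequate.
    """
    if ref.method != "cutpoint":
        raise ValueError(f"{ref.name} is not a cut-point nutrient")
    intakes = np.asarray(intakes, dtype=float)
    if intakes.size == 0:
        raise ValueError("empty cluster")
    # half-up rounding (with a tie guard against binary representation of
    # decimal fractions), matching conventional spreadsheet rounding
    f = 10.0 ** ref.decimals
    rounded = np.floor(intakes * f + 0.5 + 1e-9) / f
    return float(100.0 * np.mean(rounded >= ref.cutoff))


def percentile_rows(values, percentiles=DEFAULT_PERCENTILES) -> np.ndarray:
    """Percentile row (inclusive linear interpolation of order statistics)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty vector")
    return np.percentile(values, list(percentiles), method="linear")


def bca_interval(data, statistic, B: int = DEFAULT_B, level: float = 95,
                 seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """95% (or ``level``%) BCa bootstrap interval for ``statistic(data)``.

    Bias correction z0 comes from the (midrank-tied) fraction of bootstrap
    replicates below the point estimate; acceleration from jackknife
    skewness. Degenerate data (constant statistic) yield a zero-width
    interval at the point estimate.
    """
    data = np.asarray(data, dtype=float)
    n = data.size
    if n < 2:
        raise ValueError("BCa interval needs at least two observations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    point = float(statistic(data))

    idx = rng.integers(0, n, size=(B, n))
    boot = np.array([statistic(data[row]) for row in idx], dtype=float)
    if np.all(boot == point):
        return point, point

    # z0 with midrank handling of ties at the point estimate
    prop = (np.sum(boot < point) + 0.5 * np.sum(boot == point)) / B
    prop = min(max(prop, 0.5 / B), 1 - 0.5 / B)
    z0 = stats.norm.ppf(prop)

    # acceleration from the jackknife
    jack = np.array([
        statistic(np.delete(data, i)) for i in range(n)
    ], dtype=float)
    d = jack.mean() - jack
    denom = (d ** 2).sum() ** 1.5
    a = (d ** 3).sum() / (6.0 * denom) if denom > 0 else 0.0

    alpha = (1 - level / 100.0) / 2.0
    lo_hi = []
    for z_alpha in (stats.norm.ppf(alpha), stats.norm.ppf(1 - alpha)):
        adj = z0 + (z0 + z_alpha) / (1 - a * (z0 + z_alpha))
        q = stats.norm.cdf(adj)
        lo_hi.append(float(np.percentile(boot, 100 * q, method="linear")))
    return lo_hi[0], lo_hi[1]


@dataclass
class AdequacyResults:
    """Cluster x nutrient adequacy report."""

    report: pd.DataFrame      # tidy: cluster, nutrient, method, point, ci, percentiles
    dri_table: dict
    B: int
    level: float

    def table(self, nutrient: str) -> pd.DataFrame:
        """One nutrient's block: percentile rows plus point estimate and CI."""
        sub = self.report[self.report["nutrient"] == nutrient].set_index("cluster")
        return sub.drop(columns=["nutrient"])

    def point_estimates(self) -> pd.DataFrame:
        """Cluster x nutrient matrix of adequacy point estimates (%)."""
        return self.report.pivot(index="cluster", columns="nutrient", values="point")

    def summary(self) -> str:
        lines = [
            f"Nutritional adequacy ({len(self.dri_table)} nutrients; "
            f"{self.level:.0f}% BCa bootstrap, B = {self.B})",
        ]
        pt = self.point_estimates().round(1)
        lines.append(pt.to_string())
        return "\n".join(lines)


class AdequacyModel:
    """Adequacy appraisal of raw nutrient intakes within clusters.

    Parameters
    ----------
    intakes : DataFrame
        Raw daily intakes (columns include every nutrient in the DRI table).
    labels : array-like
        Cluster membership per row of ``intakes``.
    dri_table : dict[str, DRIReference], optional
        Defaults to the shipped pregnancy references (17 nutrients).
    """

    def __init__(self, intakes: pd.DataFrame, labels, dri_table=None):
        self.intakes = pd.DataFrame(intakes)
        self.labels = np.asarray(labels)
        if len(self.labels) != len(self.intakes):
            raise ValueError("labels must align with intake rows")
        self.dri_table = dri_table if dri_table is not None else load_dri_table()
        missing = [n for n in self.dri_table if n not in self.intakes.columns]
        if missing:
            raise ValueError(f"intake table lacks DRI nutrients: {missing}")

    def fit(self, B: int = DEFAULT_B, level: float = 95,
            seed: int = 0) -> AdequacyResults:
        rng = np.random.default_rng(seed)
        pct_names = [f"P{p}" for p in DEFAULT_PERCENTILES]
        rows = []
        for cluster in np.unique(self.labels):
            mask = self.labels == cluster
            for name, ref in self.dri_table.items():
                x = self.intakes.loc[mask, name].to_numpy(float)
                if ref.method == "probability":
                    stat = lambda d, r=ref: cluster_probability_adequacy(d, r)
                    dist = 100.0 * probability_of_adequacy(x, ref)
                else:
                    stat = lambda d, r=ref: cutpoint_adequacy(d, r)
                    dist = x
                point = stat(x)
                lo, hi = bca_interval(x, stat, B=B, level=level, seed=rng)
                # the reported interval always brackets the point estimate
                lo, hi = min(lo, point), max(hi, point)
                row = {
                    "cluster": cluster, "nutrient": name, "method": ref.method,
                    "n": int(mask.sum()), "point": point,
                    "ci_low": lo, "ci_high": hi,
                }
                row.update(dict(zip(pct_names, percentile_rows(dist))))
                rows.append(row)
        report = pd.DataFrame(rows)
        return AdequacyResults(report, self.dri_table, B, level)


def build_adequacy_report(cohort, labels, dri_table=None, B: int = DEFAULT_B,
                          level: float = 95, seed: int = 0) -> AdequacyResults:
    """Adequacy report straight from a cohort table and cluster labels."""
    dri_table = dri_table if dri_table is not None else load_dri_table()
    cols = list(dri_table)
    missing = [n for n in cols if n not in cohort.df.columns]
    if missing:
        raise ValueError(f"cohort lacks adequacy nutrients: {missing}")
    intakes = cohort.df[cols]
    model = AdequacyModel(intakes, labels, dri_table)
    return model.fit(B=B, level=level, seed=seed)
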