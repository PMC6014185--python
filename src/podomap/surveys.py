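"""Community survey tables and their descriptive summary.

A survey table has one row per surveyed community (cluster) with columns
``community_id, x_km, y_km, n_screened, n_cases``.  The summary reproduces
the descriptive statistics podoconiosis mapping studies report: pooled
prevalence with binomial confidence intervals, the share of zero-case
clusters, and screening-effort statistics.  Regional summary tables
(one row per region with cluster/screened/case totals) use the same
summary on their column sums.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "SurveySummary",
    "load_surveys",
    "save_surveys",
    "summarize_surveys",
    "summarize_regional_totals",
    "load_regional_survey_table",
]

SURVEY_COLUMNS = ["community_id", "x_km", "y_km", "n_screened", "n_cases"]


def validate_surveys(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ("n_screened", "n_cases") if c not in table.columns]
    if missing:
        raise ValueError(f"survey table lacks columns {missing}")
    if (table["n_cases"] > table["n_screened"]).any():
        bad = table.loc[table["n_cases"] > table["n_screened"], "community_id"]
        raise ValueError(f"cases exceed screened for communities {list(bad)[:5]}")
    if (table["n_screened"] < 0).any() or (table["n_cases"] < 0).any():
        raise ValueError("negative counts in survey table")
    return table


def load_surveys(path: str | Path) -> pd.DataFrame:
    return validate_surveys(pd.read_csv(path))


def save_surveys(table: pd.DataFrame, path: str | Path) -> None:
    validate_surveys(table).to_csv(path, index=False)


@dataclass
class SurveySummary:
    """Pooled descriptive statistics of a community survey collection.

    Prevalence and CI bounds are percentages; both a Wald (normal) and a
    Clopper–Pearson (exact) interval are reported since at national sample
    sizes they agree to the printed precision.
    """

    n_clusters: int
    total_screened: int
    total_cases: int
    prevalence_pct: float
    ci_wald_pct: tuple[float, float]
    ci_exact_pct: tuple[float, float]
    zero_case_clusters: int
    zero_case_share_pct: float
    mean_screened_per_cluster: float
    share_clusters_ge_100_pct: float

    def as_dict(self) -> dict:
        return asdict(self)


def _summary_from_counts(
    cluster_counts: np.ndarray,
    cluster_cases: np.ndarray,
) -> SurveySummary:
    n_clusters = len(cluster_counts)
    total_screened = int(cluster_counts.sum())
    total_cases = int(cluster_cases.sum())
    if total_screened == 0:
        raise ValueError("no individuals screened")
    prev = total_cases / total_screened
    wald = proportion_confint(total_cases, total_screened, alpha=0.05, method="normal")
    exact = proportion_confint(total_cases, total_screened, alpha=0.05, method="beta")
    zero = int((cluster_cases == 0).sum())
    return SurveySummary(
        n_clusters=n_clusters,
        total_screened=total_screened,
        total_cases=total_cases,
        prevalence_pct=100.0 * prev,
        ci_wald_pct=(100.0 * wald[0], 100.0 * wald[1]),
        ci_exact_pct=(100.0 * exact[0], 100.0 * exact[1]),
        zero_case_clusters=zero,
        zero_case_share_pct=100.0 * zero / n_clusters,
        mean_screened_per_cluster=total_screened / n_clusters,
        share_clusters_ge_100_pct=100.0 * float((cluster_counts >= 100).mean()),
    )


def summarize_surveys(table: pd.DataFrame) -> SurveySummary:
    """Summary of a community-level survey table (one row per cluster)."""
    validate_surveys(table)
    return _summary_from_counts(
        table["n_screened"].to_numpy(float), table["n_cases"].to_numpy(float)
    )


def summarize_regional_totals(table: pd.DataFrame) -> SurveySummary:
    """Summary of a regional totals table (columns: region, clusters,
    total_screened, cases).

    Totals are column sums; the zero-case statistics cannot be derived from
    regional totals alone, so a ``zero_case_clusters`` column is honoured if
    present and reported as NaN otherwise.  Mean screening effort is
    screened / clusters; the ≥100 share is likewise NaN without
    cluster-level data.
    """
    n_clusters = int(table["clusters"].sum())
    total_screened = int(table["total_screened"].sum())
    total_cases = int(table["cases"].sum())
    prev = total_cases / total_screened
    wald = proportion_confint(total_cases, total_screened, alpha=0.05, method="normal")
    exact = proportion_confint(total_cases, total_screened, alpha=0.05, method="beta")
    if "zero_case_clusters" in table.columns:
        zero = int(table["zero_case_clusters"].sum())
        zero_share = 100.0 * zero / n_clusters
    else:
        zero, zero_share = -1, float("nan")
    return SurveySummary(
        n_clusters=n_clusters,
        total_screened=total_screened,
        total_cases=total_cases,
        prevalence_pct=100.0 * prev,
        ci_wald_pct=(100.0 * wald[0], 100.0 * wald[1]),
        ci_exact_pct=(100.0 * exact[0], 100.0 * exact[1]),
        zero_case_clusters=zero,
        zero_case_share_pct=zero_share,
        mean_screened_per_cluster=total_screened / n_clusters,
        share_clusters_ge_100_pct=float("nan"),
    )


def load_regional_survey_table() -> pd.DataFrame:
    """The packaged regional totals of the two Cameroon podoconiosis surveys
    (2014 North-West census-style screening + 2017 nationwide sample)."""
    with resources.files("podomap.data").joinpath("cameroon_survey_regional_totals.csv").open() as fh:
        return pd.read_csv(fh)
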