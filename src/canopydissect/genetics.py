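"""Variance components, broad-sense heritability and trait correlations.

Heritability of a trait measured on r replicate plants per genotype is

    H2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / r)

with the genotypic and residual variances estimated by a one-way
random-effects method-of-moments (ANOVA) decomposition: sigma_e^2 is the
pooled within-genotype mean square and sigma_G^2 = max(0, (MS_between -
MS_within) / r_bar) with r_bar the harmonic-mean replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeritabilityResult",
    "variance_components",
    "heritability",
    "trait_correlations",
    "heritability_timecourse",
]


@dataclass(frozen=True)
class HeritabilityResult:
    sigma_g2: float
    sigma_e2: float
    r: float
    h2: float


def variance_components(values, genotypes) -> tuple[float, float]:
    """(sigma_G^2, sigma_e^2) by one-way ANOVA method of moments.

    Requires at least 2 genotypes and at least one genotype with 2 or more
    replicates.  A negative between-genotype estimate is truncated at 0.
    """
    y = np.asarray(values, float)
    g = np.asarray(genotypes)
    df = pd.DataFrame({"y": y, "g": g}).dropna()
    groups = df.groupby("g")["y"]
    k = groups.ngroups
    if k < 2:
        raise ValueError("need at least 2 genotypes")
    n_i = groups.count().to_numpy(float)
    if (n_i >= 2).sum() < 1:
        raise ValueError("need at least one genotype with >= 2 replicates")
    N = n_i.sum()
    means = groups.mean().to_numpy(float)
    grand = df["y"].mean()
    ss_between = float(np.sum(n_i * (means - grand) ** 2))
    ss_within = float(((df["y"] - groups.transform("mean")) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k) if N > k else 0.0
    r_bar = k / np.sum(1.0 / n_i)  # harmonic mean replicate count
    sigma_g2 = max(0.0, (ms_between - ms_within) / r_bar)
    return sigma_g2, ms_within


def heritability(sigma_g2: float, sigma_e2: float, r: float = 3) -> float:
    """Broad-sense H2 = sigma_G^2 / (sigma_G^2 + sigma_e^2 / r), in [0, 1]."""
    if sigma_g2 < 0 or sigma_e2 < 0:
        raise ValueError("variances must be >= 0")
    denom = sigma_g2 + sigma_e2 / r
    if denom <= 0:
        raise ValueError("total variance is zero; H2 undefined")
    return sigma_g2 / denom


def trait_correlations(genotype_means: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix between genotypic trait means.

    Constant traits give NaN against every other trait (undefined
    correlation), matching pandas' convention; the diagonal is forced to 1
    wherever the trait is non-degenerate.
    """
    if len(genotype_means) < 3:
        raise ValueError("need at least 3 genotypes")
    return genotype_means.corr(method="pearson")


def heritability_timecourse(
    daily: pd.DataFrame,
    traits: list[str],
    genotype_col: str = "genotype_id",
    day_col: str = "day",
    r: float | None = None,
) -> pd.DataFrame:
    """Per-day broad-sense heritability of each trait.

    ``daily`` is a tidy per-plant-day table.  ``r`` defaults to the
    harmonic-mean replicate count of each day.  Returns a long table with
    columns trait, day, sigma_g2, sigma_e2, r, h2.
    """
    rows = []
    for day, g in daily.groupby(day_col, sort=True):
        counts = g.groupby(genotype_col).size().to_numpy(float)
        r_day = r if r is not None else len(counts) / np.sum(1.0 / counts)
        for trait in traits:
            sg2, se2 = variance_components(g[trait], g[genotype_col])
            h2 = heritability(sg2, se2, r_day) if sg2 + se2 / r_day > 0 else np.nan
            rows.append(
                {
                    "trait": trait,
                    "day": day,
                    "sigma_g2": sg2,
                    "sigma_e2": se2,
                    "r": r_day,
                    "h2": h2,
                }
            )
    return pd.DataFrame(rows)
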