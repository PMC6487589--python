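"""Per-plant dissection of light interception and radiation use efficiency.

Biomass accumulation of an individual plant in a multi-genotype canopy is
written multiplicatively as

    dBM/dt = R_i * RIE_plant * RUE / D
           = R_i * (LA * CI / CP) * (exp(eps_RUE) * exp(a*R_leaf + b)) / D

where

* ``RIE_plant = R_plant * D / R_i`` is the plant-level radiation
  interception efficiency (unitless; may exceed 1 for strong competitors),
* ``CP = LA_c / RIE_c`` is the canopy competition pressure, an environmental
  index computed over a moving window of the k nearest plants (default 15,
  focal included): local mean leaf area over local mean RIE_plant,
* ``CI = (RIE_plant / LA) / (RIE_c / LA_c)`` is the competitiveness index, 1
  for a plant that intercepts the same light per unit leaf area as its
  neighbourhood,
* ``RUE`` (g fresh weight per mol photons) is dissected through the
  log-linear light response ``ln RUE = a * R_leaf + b + eps_RUE`` with
  ``R_leaf`` the mean intercepted flux per unit leaf area (umol m-2 s-1) and
  ``eps_RUE`` the genotypic residual.

The module offers both the individual operations and a statsmodels-style
pair :class:`CanopyDissection` / :class:`CanopyDissectionResults` that runs
the full dissection on a tidy per-plant-day table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.spatial import cKDTree
from scipy.stats import linregress

__all__ = [
    "WindowSummary",
    "RUEModelFit",
    "rie_plant",
    "neighbourhood",
    "competition_pressure",
    "competitiveness_index",
    "r_leaf",
    "estimate_rue",
    "fit_rue_response",
    "rue_predict",
    "biomass_increment",
    "dissect_day",
    "CanopyDissection",
    "CanopyDissectionResults",
]

DEFAULT_WINDOW = 15
DEFAULT_PHOTOPERIOD_H = 12.0
DEFAULT_RUE_INTERVAL = (30.0, 50.0)


@dataclass(frozen=True)
class WindowSummary:
    """Moving-window neighbourhood of a focal plant (focal included)."""

    focal_id: str
    member_ids: tuple[str, ...]
    la_c: float  # mean leaf area over members, m2 plant-1
    rie_c: float  # mean RIE_plant over members, unitless


def rie_plant(r_plant: float, density: float, r_i: float) -> float:
    """Plant-level radiation interception efficiency R_plant * D / R_i."""
    if r_i <= 0:
        raise ValueError("incident flux R_i must be > 0")
    if density <= 0:
        raise ValueError("plant density must be > 0")
    return r_plant * density / r_i


def neighbourhood(
    layout: pd.DataFrame, focal: str, k: int = DEFAULT_WINDOW
) -> WindowSummary:
    """The k-plant moving window centred on ``focal``.

    ``layout`` needs columns plant_id, x, y, leaf_area, rie_plant.  Members
    are the focal plant plus its k-1 nearest neighbours by x-y Euclidean
    distance; ties are broken by plant_id order.  LA_c and RIE_c are
    unweighted means over the members.
    """
    if len(layout) < k:
        raise ValueError(f"layout has {len(layout)} plants, window needs {k}")
    ids = layout["plant_id"].to_numpy()
    xy = layout[["x", "y"]].to_numpy(float)
    focal_idx = np.flatnonzero(ids == focal)
    if len(focal_idx) == 0:
        raise KeyError(f"focal plant {focal!r} not in layout")
    d = np.hypot(*(xy - xy[focal_idx[0]]).T)
    order = np.lexsort((ids, d))[:k]
    members = layout.iloc[order]
    return WindowSummary(
        focal_id=focal,
        member_ids=tuple(members["plant_id"]),
        la_c=float(members["leaf_area"].mean()),
        rie_c=float(members["rie_plant"].mean()),
    )


def competition_pressure(window: WindowSummary) -> float:
    """CP = LA_c / RIE_c (m2 leaf area per plant); low at canopy borders."""
    if window.rie_c <= 0:
        raise ValueError("window mean RIE must be > 0")
    return window.la_c / window.rie_c


def competitiveness_index(
    rie_plant_i: float, leaf_area_i: float, window: WindowSummary
) -> float:
    """CI = (RIE_plant,i / LA_i) / (RIE_c / LA_c); 1 = neutral competitor."""
    if leaf_area_i <= 0:
        raise ValueError("focal leaf area must be > 0")
    if window.rie_c <= 0 or window.la_c <= 0:
        raise ValueError("window means must be > 0")
    return (rie_plant_i / leaf_area_i) / (window.rie_c / window.la_c)


def r_leaf(
    r_plant: float, leaf_area: float, photoperiod_h: float = DEFAULT_PHOTOPERIOD_H
) -> float:
    """Mean intercepted flux per unit leaf area, umol m-2 s-1.

    Converts the daily integral (mol plant-1 d-1) to a mean rate over the
    photoperiod, then divides by leaf area.
    """
    if leaf_area <= 0:
        raise ValueError("leaf area must be > 0")
    return r_plant * 1e6 / (photoperiod_h * 3600.0) / leaf_area


def estimate_rue(
    thermal_time: np.ndarray,
    biomass: np.ndarray,
    cum_intercepted: np.ndarray,
    interval: tuple[float, float] = DEFAULT_RUE_INTERVAL,
) -> float:
    """RUE as the OLS slope of biomass on cumulative intercepted radiation.

    Only days with thermal time inside ``interval`` (default 30-50 d20)
    enter the regression; g fresh weight per mol photons.
    """
    t = np.asarray(thermal_time, float)
    sel = (t >= interval[0]) & (t <= interval[1])
    if sel.sum() < 3:
        raise ValueError("need at least 3 days inside the RUE interval")
    x = np.asarray(cum_intercepted, float)[sel]
    y = np.asarray(biomass, float)[sel]
    return float(linregress(x, y).slope)


@dataclass
class RUEModelFit:
    """OLS fit of ln RUE on R_leaf plus genotypic residual means."""

    a: float  # slope, per (umol m-2 s-1); expected negative
    b: float  # intercept, ln(g FW mol-1)
    a_se: float
    b_se: float
    r_squared: float
    nobs: int
    residuals: pd.Series  # per plant, index = plant_id
    eps_rue: pd.Series  # per genotype, mean residual
    sm_results: object = None

    def predict(self, r_leaf_value, eps: float = 0.0):
        return rue_predict(self.a, self.b, r_leaf_value, eps)


def fit_rue_response(records: pd.DataFrame) -> RUEModelFit:
    """Fit ``ln RUE = a * R_leaf + b`` across a panel's plants.

    ``records`` needs columns plant_id, genotype_id, rue, r_leaf.  The
    per-genotype eps_RUE is the mean of that genotype's plant residuals.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 plants to fit the RUE response")
    rue = records["rue"].to_numpy(float)
    if np.any(rue <= 0):
        bad = records.loc[rue <= 0, "plant_id"].tolist()[:5]
        raise ValueError(f"RUE must be > 0 for all plants (offenders: {bad})")
    y = np.log(rue)
    X = sm.add_constant(records["r_leaf"].to_numpy(float))
    res = sm.OLS(y, X).fit()
    resid = pd.Series(res.resid, index=records["plant_id"].to_numpy(), name="resid")
    eps = (
        pd.DataFrame(
            {"genotype_id": records["genotype_id"].to_numpy(), "resid": res.resid}
        )
        .groupby("genotype_id")["resid"]
        .mean()
        .rename("eps_rue")
    )
    return RUEModelFit(
        a=float(res.params[1]),
        b=float(res.params[0]),
        a_se=float(res.bse[1]),
        b_se=float(res.bse[0]),
        r_squared=float(res.rsquared),
        nobs=int(res.nobs),
        residuals=resid,
        eps_rue=eps,
        sm_results=res,
    )


def rue_predict(a: float, b: float, r_leaf_value, eps=0.0):
    """RUE = exp(eps) * exp(a * R_leaf + b), g FW per mol photons."""
    return np.exp(eps) * np.exp(a * np.asarray(r_leaf_value, float) + b)


def biomass_increment(
    r_i: float,
    leaf_area: float,
    ci: float,
    cp: float,
    a: float,
    b: float,
    eps: float,
    density: float,
    photoperiod_h: float = DEFAULT_PHOTOPERIOD_H,
) -> float:
    """Daily biomass increase, g FW plant-1 d-1, from the revised Monteith form.

    dBM = R_i * (LA * CI / CP) * exp(eps) * exp(a * R_leaf + b) / D, where
    RIE_plant = LA * CI / CP, R_plant = RIE_plant * R_i / D and R_leaf is
    derived from that implied R_plant.  Algebraically identical to
    R_plant * RUE.
    """
    if cp <= 0:
        raise ValueError("competition pressure CP must be > 0")
    if density <= 0:
        raise ValueError("density must be > 0")
    rie = leaf_area * ci / cp
    r_plant = rie * r_i / density
    rl = r_leaf(r_plant, leaf_area, photoperiod_h)
    return r_i * (leaf_area * ci / cp) * rue_predict(a, b, rl, eps) / density


def dissect_day(
    day_table: pd.DataFrame,
    density: float,
    k: int = DEFAULT_WINDOW,
    photoperiod_h: float = DEFAULT_PHOTOPERIOD_H,
) -> pd.DataFrame:
    """Compute RIE_plant, CP, CI and R_leaf for every plant of one day.

    ``day_table`` needs columns plant_id, x, y, leaf_area, r_i, r_plant.
    Returns the table with rie_plant, la_c, rie_c, cp, ci, r_leaf appended.
    """
    t = day_table.copy()
    t["rie_plant"] = [
        rie_plant(rp, density, ri) for rp, ri in zip(t["r_plant"], t["r_i"])
    ]
    # KDTree accelerates the k-NN query; exact tie-breaking is re-done per
    # focal plant on the (distance, plant_id) key.
    xy = t[["x", "y"]].to_numpy(float)
    tree = cKDTree(xy)
    kq = min(len(t), k + 4)  # headroom for ties
    dist, idx = tree.query(xy, k=kq)
    ids = t["plant_id"].to_numpy()
    la = t["leaf_area"].to_numpy(float)
    rie = t["rie_plant"].to_numpy(float)
    la_c = np.empty(len(t))
    rie_c = np.empty(len(t))
    for i in range(len(t)):
        cand = idx[i]
        order = np.lexsort((ids[cand], dist[i]))[:k]
        sel = cand[order]
        la_c[i] = la[sel].mean()
        rie_c[i] = rie[sel].mean()
    t["la_c"] = la_c
    t["rie_c"] = rie_c
    t["cp"] = t["la_c"] / t["rie_c"]
    t["ci"] = (t["rie_plant"] / t["leaf_area"]) / (t["rie_c"] / t["la_c"])
    t["r_leaf"] = [
        r_leaf(rp, a_, photoperiod_h) for rp, a_ in zip(t["r_plant"], t["leaf_area"])
    ]
    return t


class CanopyDissection:
    """Model object: the revised Monteith dissection of a canopy experiment.

    Parameters
    ----------
    data : DataFrame
        Tidy per-plant-day table with columns plant_id, genotype_id, day
        (thermal time, d20), x, y (m), leaf_area (m2), r_i (mol m-2 d-1),
        r_plant (mol plant-1 d-1) and, if RUE is to be estimated, biomass
        (g FW).
    density : float
        Plant density D, plants m-2.
    window_size : int
        Moving-window size k (focal plant plus k-1 nearest neighbours).
    photoperiod_h, rue_interval
        Photoperiod used for the R_leaf unit conversion and the thermal-time
        interval of the RUE regression.
    """

    REQUIRED = ["plant_id", "genotype_id", "day", "x", "y", "leaf_area", "r_i", "r_plant"]

    def __init__(
        self,
        data: pd.DataFrame,
        density: float,
        window_size: int = DEFAULT_WINDOW,
        photoperiod_h: float = DEFAULT_PHOTOPERIOD_H,
        rue_interval: tuple[float, float] = DEFAULT_RUE_INTERVAL,
    ):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"data is missing columns: {missing}")
        if density <= 0:
            raise ValueError("density must be > 0")
        self.data = data.reset_index(drop=True)
        self.density = float(density)
        self.window_size = int(window_size)
        self.photoperiod_h = float(photoperiod_h)
        self.rue_interval = tuple(rue_interval)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "CanopyDissection":
        return cls(data, **kwargs)

    def fit(self) -> "CanopyDissectionResults":
        parts = [
            dissect_day(g, self.density, self.window_size, self.photoperiod_h)
            for _, g in self.data.groupby("day", sort=True)
        ]
        records = pd.concat(parts, ignore_index=True)

        rue_table = None
        rue_fit = None
        if "biomass" in self.data.columns:
            rows = []
            for pid, g in records.groupby("plant_id", sort=True):
                g = g.sort_values("day")
                # daily R_plant integrated to cumulative intercepted light
                days = g["day"].to_numpy(float)
                dt = np.diff(days, prepend=days[0])
                dt[0] = dt[1] if len(dt) > 1 else 1.0
                cum = np.cumsum(g["r_plant"].to_numpy(float) * dt)
                t0, t1 = self.rue_interval
                sel = (days >= t0) & (days <= t1)
                if sel.sum() < 3:
                    continue
                rue_val = estimate_rue(
                    days, g["biomass"].to_numpy(float), cum, self.rue_interval
                )
                rows.append(
                    {
                        "plant_id": pid,
                        "genotype_id": g["genotype_id"].iloc[0],
                        "rue": rue_val,
                        "r_leaf": float(g.loc[sel, "r_leaf"].mean()),
                    }
                )
            if rows:
                rue_table = pd.DataFrame(rows)
                if (rue_table["rue"] > 0).all() and len(rue_table) >= 3:
                    rue_fit = fit_rue_response(rue_table)
        return CanopyDissectionResults(self, records, rue_table, rue_fit)


class CanopyDissectionResults:
    """Fitted dissection: per-plant-day records and the panel RUE response."""

    def __init__(self, model, records, rue_table=None, rue_fit=None):
        self.model = model
        self.records = records
        self.rue_table = rue_table
        self.rue_fit = rue_fit

    def genotype_means(self, day: float | None = None) -> pd.DataFrame:
        """Genotypic means (arithmetic over replicates) of the indices."""
        r = self.records
        if day is not None:
            r = r[r["day"] == day]
        cols = ["leaf_area", "rie_plant", "cp", "ci", "r_leaf"]
        out = r.groupby("genotype_id")[cols].mean()
        if self.rue_fit is not None:
            out = out.join(self.rue_fit.eps_rue)
            out = out.join(
                self.rue_table.groupby("genotype_id")["rue"].mean().rename("rue")
            )
        return out

    def summary(self) -> str:
        lines = ["Revised Monteith dissection", "=" * 42]
        r = self.records
        lines.append(f"plants: {r['plant_id'].nunique()}  "
                     f"genotypes: {r['genotype_id'].nunique()}  "
                     f"days: {r['day'].nunique()}")
        last = r[r["day"] == r["day"].max()]
        for col, name in [("rie_plant", "RIE_plant"), ("cp", "CP"), ("ci", "CI")]:
            v = last[col]
            lines.append(
                f"{name:>10} (final day): mean {v.mean():7.3f}  "
                f"range [{v.min():.3f}, {v.max():.3f}]"
            )
        if self.rue_fit is not None:
            f = self.rue_fit
            lines.append(
                f"RUE response: ln RUE = {f.a:+.5f} * R_leaf + {f.b:.3f}  "
                f"(r2 = {f.r_squared:.3f}, n = {f.nobs})"
            )
            lines.append(
                f"eps_RUE range: [{f.eps_rue.min():+.4f}, {f.eps_rue.max():+.4f}]"
            )
        return "\n".join(lines)

    def plot_rue_response(self, ax=None):
        """Scatter of ln RUE vs R_leaf with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.rue_table
        ax.scatter(t["r_leaf"], np.log(t["rue"]), s=8, alpha=0.5)
        xs = np.linspace(t["r_leaf"].min(), t["r_leaf"].max(), 50)
        f = self.rue_fit
        ax.plot(xs, f.a * xs + f.b, "k-")
        ax.set_xlabel("R_leaf (umol m-2 s-1)")
        ax.set_ylabel("ln RUE (g FW mol-1)")
        return ax
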