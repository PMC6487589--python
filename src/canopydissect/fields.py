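"""Virtual multi-genotype fields and the competitiveness-bias analysis.

Four canopy archetypes of increasing heterogeneity are simulated:

* A — large single-genotype plot (the farmer's-field reference),
* B — micro-plots of four contiguous rows per genotype,
* C — one genotype per row (early breeding generations),
* D — genotypes assigned at random (first-generation breeding field or a
  phenotyping platform); "Dall" is D over a whole panel.

The daily growth loop rebuilds every plant's mesh at the current thermal
time, voxelizes the canopy, traces light interception, converts each
plant's interception into R_leaf, evaluates RUE through the fitted
log-linear light response with the genotype's eps_RUE, and accumulates
dBM = R_plant * RUE.  Comparing a genotype's biomass in a mixed canopy with
its single-genotype reference quantifies the competitiveness bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import dissection as dx
from .light import (
    DEFAULT_CELL_SIZE,
    LightConfig,
    LightEnvironment,
    SkyModel,
    build_sky,
    trace_interception,
    voxelize,
)
from .synthetic import GenotypePanel, build_plant_mesh

__all__ = [
    "CanopyLayout",
    "GrowthTrajectory",
    "layout",
    "simulate",
    "relative_biomass",
    "competitiveness_bias",
]

CANOPY_TYPES = ("A", "B", "C", "D", "Dall")


@dataclass
class CanopyLayout:
    """Plant positions, genotype assignment and plot geometry."""

    type: str
    positions: np.ndarray  # (n, 2) m
    genotype_assignment: list[str]
    row_spacing: float
    plant_spacing: float
    bounds: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        if self.type not in CANOPY_TYPES:
            raise ValueError(f"canopy type must be one of {CANOPY_TYPES}")
        if len(self.positions) != len(self.genotype_assignment):
            raise ValueError("positions and genotype_assignment length mismatch")

    @property
    def n_plants(self) -> int:
        return len(self.positions)

    @property
    def plot_area(self) -> float:
        (x0, x1), (y0, y1) = self.bounds
        return (x1 - x0) * (y1 - y0)

    @property
    def density(self) -> float:
        """Plants per m2 of soil surface."""
        return self.n_plants / self.plot_area

    @property
    def plant_ids(self) -> list[str]:
        return [f"p{i:04d}" for i in range(self.n_plants)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plant_id": self.plant_ids,
                "genotype_id": self.genotype_assignment,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )


def layout(
    type: str,
    genotypes: list[str],
    n_rows: int = 20,
    plants_per_row: int = 20,
    row_spacing: float = 0.4,
    plant_spacing: float = 0.2,
    seed: int = 0,
) -> CanopyLayout:
    """Build a canopy layout of the given archetype.

    Rows run along y; row index maps to x.  Type A needs exactly one
    genotype; B needs n_rows divisible into 4-row blocks matching the
    genotype count; C cycles one genotype per row; D (and Dall) assigns
    genotypes at random, balanced to within one plant.
    """
    n = n_rows * plants_per_row
    rows = np.repeat(np.arange(n_rows), plants_per_row)
    cols = np.tile(np.arange(plants_per_row), n_rows)
    x = (rows + 0.5) * row_spacing
    y = (cols + 0.5) * plant_spacing
    positions = np.column_stack([x, y])
    bounds = ((0.0, n_rows * row_spacing), (0.0, plants_per_row * plant_spacing))
    g = list(genotypes)

    if type == "A":
        if len(g) != 1:
            raise ValueError("canopy A takes exactly one genotype")
        assign = g * n
    elif type == "B":
        if n_rows != 4 * len(g):
            raise ValueError(
                f"canopy B needs n_rows = 4 * n_genotypes ({4 * len(g)}), got {n_rows}"
            )
        assign = [g[r // 4] for r in rows]
    elif type == "C":
        if n_rows % len(g) != 0:
            raise ValueError("canopy C needs n_rows divisible by the genotype count")
        assign = [g[r % len(g)] for r in rows]
    elif type in ("D", "Dall"):
        rng = np.random.default_rng(seed)
        reps = -(-n // len(g))  # ceil
        pool = (g * reps)[:n]
        assign = list(np.array(pool)[rng.permutation(n)])
    else:
        raise ValueError(f"unknown canopy type {type!r}")

    return CanopyLayout(
        type=type,
        positions=positions,
        genotype_assignment=assign,
        row_spacing=row_spacing,
        plant_spacing=plant_spacing,
        bounds=bounds,
    )


@dataclass
class GrowthTrajectory:
    """Per-plant per-step simulation records plus canopy-level summaries."""

    records: pd.DataFrame  # plant_id, genotype_id, day, leaf_area, r_plant,
    #                        r_leaf, rue, dbm, biomass
    layout: CanopyLayout

    @property
    def final_biomass(self) -> pd.Series:
        """Final cumulative biomass per plant, g FW."""
        last = self.records[self.records["day"] == self.records["day"].max()]
        return last.set_index("plant_id")["biomass"]

    def genotype_biomass(self) -> pd.Series:
        """Mean final biomass per genotype, g FW plant-1."""
        last = self.records[self.records["day"] == self.records["day"].max()]
        return last.groupby("genotype_id")["biomass"].mean()

    @property
    def canopy_biomass_kg_m2(self) -> float:
        """Whole-canopy biomass per unit soil area, kg FW m-2."""
        return float(self.final_biomass.sum() / self.layout.plot_area / 1000.0)


def simulate(
    canopy: CanopyLayout,
    panel: GenotypePanel,
    env: LightEnvironment,
    rue_coeffs: tuple[float, float],
    t_range: tuple[float, float] = (15.0, 50.0),
    step: float = 1.0,
    replicate_noise: float = 0.0,
    seed: int = 0,
    cell_size=DEFAULT_CELL_SIZE,
    sky: SkyModel | None = None,
    light_cfg: LightConfig = LightConfig(),
    photoperiod_h: float = dx.DEFAULT_PHOTOPERIOD_H,
) -> GrowthTrajectory:
    """Run the daily growth loop over ``t_range`` (thermal time, d20).

    ``rue_coeffs`` is the panel-level (a, b) of the log-linear RUE light
    response; each genotype contributes its own eps_RUE.  Replicate noise
    perturbs leaf area and height per plant (constant through time).
    """
    missing = set(canopy.genotype_assignment) - set(panel.genotype_ids)
    if missing:
        raise ValueError(f"genotypes missing from panel: {sorted(missing)}")
    a, b = rue_coeffs
    sky = sky or build_sky()
    specs = {s.genotype_id: s for s in panel.specs}
    ids = canopy.plant_ids
    eps = np.array([specs[g].eps_rue for g in canopy.genotype_assignment])
    density = canopy.density

    days = np.arange(t_range[0], t_range[1] + 1e-9, step)
    biomass = np.zeros(canopy.n_plants)
    rows = []
    for day in days:
        plants = [
            build_plant_mesh(
                specs[g],
                day,
                tuple(pos),
                replicate_noise=replicate_noise,
                seed=seed,
                plant_id=pid,
            )
            for pid, g, pos in zip(ids, canopy.genotype_assignment, canopy.positions)
        ]
        grid = voxelize(plants, cell_size=cell_size, bounds=canopy.bounds)
        res = trace_interception(
            grid,
            sky,
            env,
            light_cfg,
            plant_positions={p.plant_id: p.position for p in plants},
        )
        la = np.array([p.leaf_area for p in plants])
        rp = np.array([res.r_plant[pid] for pid in ids])
        rl = rp * 1e6 / (photoperiod_h * 3600.0) / la
        rue = dx.rue_predict(a, b, rl, eps)
        dbm = rp * rue * step
        biomass = biomass + dbm
        rows.append(
            pd.DataFrame(
                {
                    "plant_id": ids,
                    "genotype_id": canopy.genotype_assignment,
                    "day": day,
                    "leaf_area": la,
                    "r_plant": rp,
                    "r_leaf": rl,
                    "rue": rue,
                    "dbm": dbm,
                    "biomass": biomass.copy(),
                    "r_i": [
                        env.daily_incident * env.tau(*p.position)
                        + env.lamp_supplement
                        for p in plants
                    ],
                    "x": canopy.positions[:, 0],
                    "y": canopy.positions[:, 1],
                }
            )
        )
    return GrowthTrajectory(records=pd.concat(rows, ignore_index=True), layout=canopy)


def relative_biomass(
    trajectories: dict[str, GrowthTrajectory],
    reference: dict[str, float] | pd.Series,
) -> pd.DataFrame:
    """Final-biomass ratios of each genotype in each canopy vs its reference.

    ``reference`` maps genotype -> final biomass in its single-genotype
    canopy A.  Returns a long table (canopy, genotype_id, biomass,
    reference, ratio); the ratio is 1 for canopy A by construction.
    """
    ref = pd.Series(reference, dtype=float)
    if (ref <= 0).any():
        raise ValueError("reference biomasses must be > 0")
    rows = []
    for name, traj in trajectories.items():
        gb = traj.genotype_biomass()
        for g, v in gb.items():
            if g not in ref.index:
                raise KeyError(f"genotype {g!r} has no canopy-A reference")
            rows.append(
                {
                    "canopy": name,
                    "genotype_id": g,
                    "biomass": v,
                    "reference": ref[g],
                    "ratio": v / ref[g],
                }
            )
    return pd.DataFrame(rows)


def competitiveness_bias(ratios: pd.Series, ci: pd.Series):
    """OLS of mixed-vs-pure biomass ratio on genotypic CI.

    Returns (slope, r_squared, intercept).  A positive slope means strong
    competitors are overrated in mixed canopies relative to pure stands.
    """
    common = ratios.index.intersection(ci.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genotypes present in both series")
    x = ci.loc[common].to_numpy(float)
    y = ratios.loc[common].to_numpy(float)
    if np.allclose(x, x[0]):
        raise ValueError("CI is constant across genotypes; bias undefined")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2), float(fit.intercept)
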