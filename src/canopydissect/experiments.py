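"""Canned in-silico experiments used for validation and reproduction.

Each function wires the synthetic generator, the voxel light model and the
dissection into one named experiment at desk scale:

* :func:`uniform_canopy_ci` — a uniform periodic canopy of identical plants,
  where the competitiveness index of every interior plant must be 1;
* :func:`heritability_experiment` — a randomized platform-like canopy with
  genotype-dependent height, contrasting the heritability of the
  environmental (CP) and genetic (CI) indices over time;
* :func:`bias_experiment` — canopies A-D for a nine-genotype panel,
  quantifying how canopy heterogeneity biases genotype comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fields
from .dissection import CanopyDissection, dissect_day
from .genetics import heritability_timecourse
from .light import LightConfig, LightEnvironment, build_sky, trace_interception, voxelize
from .synthetic import build_plant_mesh, generate_panel

__all__ = ["uniform_canopy_ci", "heritability_experiment", "bias_experiment"]

ZERO_VARIABILITY = {
    "final_leaf_area": 0.0,
    "max_height": 0.0,
    "n_leaves": 0.0,
    "leaf_angle_mode_sd": 0.0,
    "expansion_midpoint": 0.0,
    "expansion_rate": 0.0,
    "eps_rue_sd": 0.0,
}

#: Genotype variation in stature only: heights (and implicitly leaf angles
#: through the default angle s.d.) differ between genotypes while the leaf
#: area trajectory is common, so competition signals are architectural.
HEIGHT_VARIABILITY = {"final_leaf_area": 0.0}


def uniform_canopy_ci(
    seed: int = 0,
    n: int = 15,
    spacing: float = 0.4,
    thermal_time: float = 45.0,
    daily_incident: float = 40.0,
    margin: int = 3,
):
    """CI of interior plants in a uniform single-genotype periodic canopy.

    An ``n x n`` regular grid of identical plants (zero genotypic and
    replicate variability) is traced under the default 46-direction sky with
    periodic boundaries; CI is computed with 15-plant moving windows and
    averaged over plants at least ``margin`` rows/columns from the plot
    edge, whose windows are fully interior.  Returns a dict with the mean
    interior CI, the number of interior plants, and the per-plant records.
    """
    panel = generate_panel(1, variability=ZERO_VARIABILITY, seed=seed)
    spec = panel.specs[0]
    plants = [
        build_plant_mesh(
            spec,
            thermal_time,
            ((i + 0.5) * spacing, (j + 0.5) * spacing),
            replicate_noise=0.0,
            seed=seed,
            plant_id=f"p{i:02d}_{j:02d}",
        )
        for i in range(n)
        for j in range(n)
    ]
    bounds = ((0.0, n * spacing), (0.0, n * spacing))
    grid = voxelize(plants, bounds=bounds)
    res = trace_interception(grid, build_sky(46), LightEnvironment(daily_incident))
    density = 1.0 / spacing**2
    table = pd.DataFrame(
        {
            "plant_id": [p.plant_id for p in plants],
            "x": [p.position[0] for p in plants],
            "y": [p.position[1] for p in plants],
            "leaf_area": [p.leaf_area for p in plants],
            "r_i": daily_incident,
            "r_plant": [res.r_plant[p.plant_id] for p in plants],
        }
    )
    records = dissect_day(table, density)
    ij = np.array([(i, j) for i in range(n) for j in range(n)])
    interior = ((ij >= margin) & (ij <= n - 1 - margin)).all(axis=1)
    return {
        "mean_ci": float(records.loc[interior, "ci"].mean()),
        "n_interior": int(interior.sum()),
        "records": records,
        "interior": interior,
    }


def heritability_experiment(
    seed: int = 11,
    n_genotypes: int = 60,
    reps: int = 3,
    n_rows: int = 12,
    plants_per_row: int = 15,
    spacing: float = 0.2,
    days: tuple[float, ...] = (15.0, 25.0, 35.0, 45.0),
    replicate_noise: float = 0.08,
    daily_incident: float = 40.0,
):
    """Heritability time course of CP, CI, RIE_plant and leaf area.

    Genotypes differ in height (and leaf angle); plant positions are fully
    randomized, replicated ``reps`` times, in a finite platform-like canopy
    (absorbing lateral boundaries, so borders receive extra light as in a
    real greenhouse).  Returns a dict with the long per-day heritability
    table and the per-plant-day dissection records.
    """
    if n_genotypes * reps != n_rows * plants_per_row:
        raise ValueError("grid size must equal n_genotypes * reps")
    panel = generate_panel(n_genotypes, variability=HEIGHT_VARIABILITY, seed=seed)
    rng = np.random.default_rng(seed)
    assign = rng.permutation(np.repeat(np.arange(n_genotypes), reps))
    positions = [
        ((i + 0.5) * spacing, (j + 0.5) * spacing)
        for i in range(n_rows)
        for j in range(plants_per_row)
    ]
    bounds = ((0.0, n_rows * spacing), (0.0, plants_per_row * spacing))
    density = len(positions) / (bounds[0][1] * bounds[1][1])
    sky = build_sky(46)
    env = LightEnvironment(daily_incident)
    cfg = LightConfig(boundary="absorb")
    out = []
    for day in days:
        plants = [
            build_plant_mesh(
                panel.specs[g],
                day,
                pos,
                replicate_noise=replicate_noise,
                seed=seed,
                plant_id=f"p{k:03d}",
            )
            for k, (g, pos) in enumerate(zip(assign, positions))
        ]
        grid = voxelize(plants, bounds=bounds)
        res = trace_interception(grid, sky, env, cfg)
        table = pd.DataFrame(
            {
                "plant_id": [p.plant_id for p in plants],
                "genotype_id": [p.genotype_id for p in plants],
                "x": [p.position[0] for p in plants],
                "y": [p.position[1] for p in plants],
                "leaf_area": [p.leaf_area for p in plants],
                "r_i": daily_incident,
                "r_plant": [res.r_plant[p.plant_id] for p in plants],
            }
        )
        rec = dissect_day(table, density)
        rec["day"] = day
        out.append(rec)
    records = pd.concat(out, ignore_index=True)
    h2 = heritability_timecourse(
        records, ["cp", "ci", "rie_plant", "leaf_area"], r=reps
    )
    return {"h2": h2, "records": records, "panel": panel}


def bias_experiment(
    seed: int = 5,
    rue_coeffs: tuple[float, float] = (-0.0025, 3.2),
    t_range: tuple[float, float] = (20.0, 50.0),
    step: float = 10.0,
    replicate_noise: float = 0.05,
    spacing: float = 0.2,
    daily_incident: float = 40.0,
):
    """Canopies A-D for nine height-differentiated genotypes.

    Each genotype's single-genotype canopy A (8 x 8 plants, periodic) is the
    reference; canopies B (four rows per genotype), C (one row per genotype,
    two cycles) and D (random mixture, 12 x 12) are compared against it.
    Returns relative biomasses, genotypic CI measured in canopy D at the
    final step, and the OLS of the D/A ratio on CI.
    """
    panel = generate_panel(9, variability=HEIGHT_VARIABILITY, seed=seed)
    gids = panel.genotype_ids
    env = LightEnvironment(daily_incident)
    sky = build_sky(46)
    kw = dict(
        t_range=t_range,
        step=step,
        replicate_noise=replicate_noise,
        seed=seed,
        sky=sky,
    )
    geom = dict(row_spacing=spacing, plant_spacing=spacing)

    reference = {}
    for g in gids:
        lay = fields.layout("A", [g], n_rows=8, plants_per_row=8, **geom)
        traj = fields.simulate(lay, panel, env, rue_coeffs, **kw)
        reference[g] = float(traj.genotype_biomass().iloc[0])

    layouts = {
        "B": fields.layout("B", gids, n_rows=36, plants_per_row=8, seed=seed, **geom),
        "C": fields.layout("C", gids, n_rows=18, plants_per_row=8, seed=seed, **geom),
        "D": fields.layout("D", gids, n_rows=12, plants_per_row=12, seed=seed, **geom),
    }
    trajectories = {
        k: fields.simulate(lay, panel, env, rue_coeffs, **kw)
        for k, lay in layouts.items()
    }
    relative = fields.relative_biomass(trajectories, reference)

    traj_d = trajectories["D"]
    last = traj_d.records[traj_d.records["day"] == traj_d.records["day"].max()]
    ci = (
        CanopyDissection(last, density=traj_d.layout.density)
        .fit()
        .records.groupby("genotype_id")["ci"]
        .mean()
    )
    ratios_d = relative[relative["canopy"] == "D"].set_index("genotype_id")["ratio"]
    slope, r2, intercept = fields.competitiveness_bias(ratios_d, ci)
    return {
        "panel": panel,
        "reference": reference,
        "relative": relative,
        "ci": ci,
        "slope": slope,
        "r_squared": r2,
        "intercept": intercept,
        "trajectories": trajectories,
    }
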