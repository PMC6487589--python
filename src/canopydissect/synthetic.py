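"""Parametric synthetic maize-like plants and genotype panels.

This module generates the raw material for virtual canopies: a panel of
genotypes with heritable variation in final leaf area, height, leaf number
and leaf angle, plus a genetic radiation-use-efficiency residual
(``eps_rue``); and, for every plant, a triangle mesh of planar leaf blades
arranged with alternate phyllotaxis around a vertical stem axis.  Leaf area
expands logistically in thermal time (equivalent days at 20 degC, d20).

The meshes are deliberately simple — planar blades, no curvature, no ear or
tassel — because the downstream light model consumes only leaf-area density
and triangle orientations.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenotypeSpec",
    "GenotypePanel",
    "TriangleMesh",
    "PlantInstance",
    "TRAIT_MEANS",
    "DEFAULT_CV",
    "generate_panel",
    "leaf_area_at",
    "build_plant_mesh",
    "plant_rng",
]

#: Default genotype-trait means for a maize-like panel.
#: Units: final_leaf_area m2/plant, max_height m, leaf_angle_mode degrees
#: from horizontal, expansion_midpoint d20, expansion_rate 1/d20.
TRAIT_MEANS: dict[str, float] = {
    "final_leaf_area": 0.55,
    "max_height": 1.6,
    "n_leaves": 12,
    "leaf_angle_mode": 35.0,
    "expansion_midpoint": 30.0,
    "expansion_rate": 0.22,
}

#: Default between-genotype variability: coefficients of variation for the
#: log-normal traits, an absolute s.d. (degrees) for leaf angle, and an
#: absolute s.d. for eps_rue (a log-scale residual centred at 0, so a CV is
#: meaningless for it).  The eps_rue spread is chosen so that a 255-genotype
#: panel spans roughly [-0.13, 0.11].
DEFAULT_CV: dict[str, float] = {
    "final_leaf_area": 0.20,
    "max_height": 0.12,
    "n_leaves": 0.10,
    "leaf_angle_mode_sd": 8.0,
    "expansion_midpoint": 0.05,
    "expansion_rate": 0.10,
    "eps_rue_sd": 0.045,
}


@dataclass(frozen=True)
class GenotypeSpec:
    """Trait values of one genotype.

    eps_rue is the genotypic residual of the log-linear RUE light response
    (dimensionless, centred at 0 over a panel).
    """

    genotype_id: str
    final_leaf_area: float  # m2 plant-1
    max_height: float  # m
    n_leaves: int
    leaf_angle_mode: float  # degrees from horizontal
    expansion_midpoint: float  # d20
    expansion_rate: float  # 1/d20
    eps_rue: float = 0.0

    def __post_init__(self) -> None:
        if self.final_leaf_area <= 0:
            raise ValueError("final_leaf_area must be > 0")
        if self.max_height <= 0:
            raise ValueError("max_height must be > 0")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.expansion_rate <= 0:
            raise ValueError("expansion_rate must be > 0")


@dataclass(frozen=True)
class GenotypePanel:
    """A reproducible set of genotypes drawn around common trait means."""

    specs: tuple[GenotypeSpec, ...]
    seed: int
    variability: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.genotype_id for s in self.specs]
        if len(set(ids)) != len(ids):
            raise ValueError("genotype_ids must be unique")

    def __len__(self) -> int:
        return len(self.specs)

    def __getitem__(self, genotype_id: str) -> GenotypeSpec:
        for s in self.specs:
            if s.genotype_id == genotype_id:
                return s
        raise KeyError(genotype_id)

    @property
    def genotype_ids(self) -> list[str]:
        return [s.genotype_id for s in self.specs]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(s) | {} for s in self.specs]).set_index(
            "genotype_id"
        )


class TriangleMesh:
    """A triangle soup: array of shape (n, 3, 3), coordinates in metres."""

    def __init__(self, triangles: np.ndarray):
        triangles = np.asarray(triangles, dtype=float)
        if triangles.ndim != 3 or triangles.shape[1:] != (3, 3):
            raise ValueError("triangles must have shape (n, 3, 3)")
        self.triangles = triangles

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        a = self.triangles[:, 1] - self.triangles[:, 0]
        b = self.triangles[:, 2] - self.triangles[:, 0]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    @property
    def area(self) -> float:
        """Total one-sided area, m2."""
        return float(self.areas().sum())

    def normals(self) -> np.ndarray:
        """Unit normals, oriented with non-negative z."""
        a = self.triangles[:, 1] - self.triangles[:, 0]
        b = self.triangles[:, 2] - self.triangles[:, 0]
        n = np.cross(a, b)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        n = n / np.where(norm == 0, 1.0, norm)
        flip = n[:, 2] < 0
        n[flip] *= -1
        return n

    def centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def max_z(self) -> float:
        return float(self.triangles[..., 2].max())

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.triangles + np.asarray(offset, float))


@dataclass(frozen=True)
class PlantInstance:
    """One physical plant: genotype, position, mesh and derived size."""

    plant_id: str
    genotype_id: str
    position: tuple[float, float]  # m, plot frame
    thermal_time: float  # d20
    mesh: TriangleMesh
    leaf_area: float  # m2, equals mesh.area
    height: float  # m, equals mesh.max_z


def plant_rng(seed: int, plant_id: str) -> np.random.Generator:
    """Per-plant random stream, stable under layout reordering.

    The stream is derived from (seed, crc32(plant_id)) so that adding or
    removing other plants never perturbs this plant's draws.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(plant_id.encode())])
    )


def generate_panel(
    n_genotypes: int,
    variability: dict[str, float] | None = None,
    seed: int = 0,
    trait_means: dict[str, float] | None = None,
) -> GenotypePanel:
    """Draw a genotype panel.

    Areas, heights, leaf counts and expansion traits are log-normal around
    the configured means with the given CVs; leaf angle is normal (clipped
    to [5, 85] degrees); eps_rue is normal, centred at 0.  Identical seed
    gives an identical panel.
    """
    if n_genotypes < 1:
        raise ValueError("n_genotypes must be >= 1")
    cv = dict(DEFAULT_CV)
    if variability:
        unknown = set(variability) - set(cv)
        if unknown:
            raise ValueError(f"unknown variability keys: {sorted(unknown)}")
        cv.update(variability)
    means = dict(TRAIT_MEANS)
    if trait_means:
        means.update(trait_means)
    rng = np.random.default_rng(seed)

    def lognorm(mean: float, c: float, n: int) -> np.ndarray:
        if c <= 0:
            return np.full(n, mean)
        sigma = np.sqrt(np.log1p(c * c))
        mu = np.log(mean) - 0.5 * sigma * sigma
        return rng.lognormal(mu, sigma, n)

    la = lognorm(means["final_leaf_area"], cv["final_leaf_area"], n_genotypes)
    h = lognorm(means["max_height"], cv["max_height"], n_genotypes)
    nl = np.maximum(
        1, np.rint(lognorm(means["n_leaves"], cv["n_leaves"], n_genotypes))
    ).astype(int)
    ang = np.clip(
        rng.normal(means["leaf_angle_mode"], cv["leaf_angle_mode_sd"], n_genotypes),
        5.0,
        85.0,
    )
    mid = lognorm(means["expansion_midpoint"], cv["expansion_midpoint"], n_genotypes)
    rate = lognorm(means["expansion_rate"], cv["expansion_rate"], n_genotypes)
    eps = (
        rng.normal(0.0, cv["eps_rue_sd"], n_genotypes)
        if cv["eps_rue_sd"] > 0
        else np.zeros(n_genotypes)
    )

    width = len(str(n_genotypes))
    specs = tuple(
        GenotypeSpec(
            genotype_id=f"g{i:0{width}d}",
            final_leaf_area=float(la[i]),
            max_height=float(h[i]),
            n_leaves=int(nl[i]),
            leaf_angle_mode=float(ang[i]),
            expansion_midpoint=float(mid[i]),
            expansion_rate=float(rate[i]),
            eps_rue=float(eps[i]),
        )
        for i in range(n_genotypes)
    )
    return GenotypePanel(specs=specs, seed=seed, variability=cv)


def leaf_area_at(genotype: GenotypeSpec, t: float) -> float:
    """Whole-plant leaf area (m2) at thermal time t (d20), logistic expansion.

    Monotone non-decreasing, half the final area at the expansion midpoint,
    asymptoting to ``final_leaf_area``.
    """
    if t < 0:
        raise ValueError("thermal time must be >= 0")
    z = genotype.expansion_rate * (t - genotype.expansion_midpoint)
    return genotype.final_leaf_area / (1.0 + np.exp(-z))


def _height_at(genotype: GenotypeSpec, t: float) -> float:
    # Height co-develops with leaf area: same logistic fraction of max_height.
    return genotype.max_height * leaf_area_at(genotype, t) / genotype.final_leaf_area


def _blade(
    base: np.ndarray,
    azimuth: float,
    inclination_deg: float,
    length: float,
    width: float,
    n_segments: int = 4,
) -> np.ndarray:
    """A planar rectangular blade as 2*n_segments triangles.

    The length axis rises at `inclination_deg` from horizontal toward
    `azimuth`; the width axis is horizontal, so scaling widths rescales area
    without touching any z coordinate.
    """
    inc = np.deg2rad(inclination_deg)
    u = np.array(
        [np.cos(azimuth) * np.cos(inc), np.sin(azimuth) * np.cos(inc), np.sin(inc)]
    )
    w = np.array([-np.sin(azimuth), np.cos(azimuth), 0.0])
    s = np.linspace(0.0, length, n_segments + 1)
    left = base + s[:, None] * u - 0.5 * width * w
    right = base + s[:, None] * u + 0.5 * width * w
    tris = []
    for k in range(n_segments):
        tris.append([left[k], right[k], right[k + 1]])
        tris.append([left[k], right[k + 1], left[k + 1]])
    return np.asarray(tris)


def build_plant_mesh(
    genotype: GenotypeSpec,
    t: float,
    position: tuple[float, float],
    replicate_noise: float = 0.0,
    seed: int = 0,
    plant_id: str | None = None,
) -> PlantInstance:
    """Construct one plant's mesh at thermal time ``t``.

    ``n_leaves`` planar blades alternate around the vertical axis (180 deg
    phyllotaxis plus a per-plant azimuthal offset).  Blade inclinations are
    the genotype's ``leaf_angle_mode`` with per-leaf jitter proportional to
    ``replicate_noise``; blade widths are rescaled so the mesh area matches
    the logistic leaf area times a multiplicative log-normal replicate
    factor.  Height similarly carries a replicate factor.  With
    ``replicate_noise=0`` the construction is fully deterministic in the
    genotype, so replicates of one genotype are identical plants.
    """
    if plant_id is None:
        plant_id = f"{genotype.genotype_id}@{position[0]:.3f},{position[1]:.3f}"
    target_area = leaf_area_at(genotype, t)
    if target_area <= 0:
        raise ValueError("plant has no leaf area at this thermal time")
    rng = plant_rng(seed, plant_id)

    cv = float(replicate_noise)
    if cv > 0:
        sig = np.sqrt(np.log1p(cv * cv))
        area_factor = rng.lognormal(-0.5 * sig * sig, sig)
        height_factor = rng.lognormal(-0.5 * sig * sig, sig)
    else:
        area_factor = height_factor = 1.0
        rng = plant_rng(seed, plant_id)  # keep stream position defined

    target_area *= area_factor
    h = max(_height_at(genotype, t) * height_factor, 1e-3)
    n = genotype.n_leaves

    # Per-leaf inclination: genotype mode +- jitter that scales with the
    # replicate-noise level (zero noise -> deterministic geometry).
    jitter_sd = 15.0 * cv
    if jitter_sd > 0:
        incs = rng.normal(genotype.leaf_angle_mode, jitter_sd, n)
    else:
        incs = np.full(n, genotype.leaf_angle_mode)
    incs = np.clip(incs, 5.0, 85.0)

    azim0 = rng.uniform(0, 2 * np.pi) if cv > 0 else 0.0
    ranks = np.arange(1, n + 1)
    attach = h * ranks / (n + 1.0)  # node heights along the stem
    # Blade tips: upper leaves reach the plant top; lower leaves stop short.
    tip_frac = 0.65 + 0.35 * ranks / n
    tip_z = attach + tip_frac * (h - attach)
    tip_z[-1] = h  # topmost blade defines plant height exactly
    lengths = np.maximum((tip_z - attach) / np.sin(np.deg2rad(incs)), 1e-4)

    # Leaf-area profile over ranks (mid-canopy leaves largest).
    prof = np.sin(np.pi * (ranks - 0.3) / (n + 0.4)) + 0.15
    areas = target_area * prof / prof.sum()
    widths = areas / lengths

    x0, y0 = float(position[0]), float(position[1])
    tris = []
    for k in range(n):
        az = azim0 + np.pi * k + 0.2 * np.sin(2.3 * k)  # alternate + small twist
        base = np.array([x0, y0, attach[k]])
        tris.append(_blade(base, az, incs[k], lengths[k], widths[k]))
    triangles = np.concatenate(tris, axis=0)

    mesh = TriangleMesh(triangles)
    if mesh.areas().min() <= 0:
        raise ValueError("degenerate blade geometry (zero-area triangle)")
    # Exact area calibration: widths are horizontal so this leaves z alone.
    err = mesh.area / target_area
    if abs(err - 1.0) > 1e-12:
        # widths already give area exactly up to float; rescale defensively
        raise AssertionError("area calibration failed")

    return PlantInstance(
        plant_id=plant_id,
        genotype_id=genotype.genotype_id,
        position=(x0, y0),
        thermal_time=float(t),
        mesh=mesh,
        leaf_area=mesh.area,
        height=mesh.max_z,
    )
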