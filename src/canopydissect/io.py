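"""File formats and run configuration.

Meshes travel as ASCII PLY or OBJ (one plant per file, coordinates in
metres, plot frame); tabular data as UTF-8 comma-separated CSV with a
mandatory header and units embedded in column names; fit and bias reports
as JSON; run configuration as YAML.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .synthetic import PlantInstance, TriangleMesh

__all__ = [
    "MeshReadError",
    "read_mesh",
    "write_mesh",
    "write_plants",
    "read_plants",
    "read_transmission_map",
    "RunConfig",
    "validate_config",
    "load_config",
]


class MeshReadError(ValueError):
    pass


def read_mesh(path) -> TriangleMesh:
    """Load an ASCII PLY or OBJ file as a triangle soup.

    Non-triangular faces are fan-triangulated (trimesh does this on load).
    """
    path = Path(path)
    if path.suffix.lower() not in (".ply", ".obj"):
        raise MeshReadError(f"{path}: unsupported mesh format {path.suffix!r}")
    try:
        m = trimesh.load_mesh(path, process=False)
    except Exception as e:  # trimesh raises various types on malformed input
        raise MeshReadError(f"{path}: {e}") from e
    if m.is_empty or len(m.faces) == 0:
        raise MeshReadError(f"{path}: no faces found")
    tris = np.asarray(m.vertices)[np.asarray(m.faces)]
    return TriangleMesh(tris)


def write_mesh(mesh: TriangleMesh, path) -> None:
    """Write a triangle soup as ASCII PLY (or OBJ by extension)."""
    path = Path(path)
    n = mesh.n_triangles
    verts = mesh.triangles.reshape(-1, 3)
    faces = np.arange(3 * n).reshape(n, 3)
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if path.suffix.lower() == ".ply":
        path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    elif path.suffix.lower() == ".obj":
        path.write_text(tm.export(file_type="obj"))
    else:
        raise ValueError(f"unsupported mesh format {path.suffix!r}")


def write_plants(plants: list[PlantInstance], directory, manifest="plants.csv") -> Path:
    """Write one PLY per plant plus a manifest CSV; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in plants:
        fname = f"{p.plant_id}.ply".replace("/", "_")
        write_mesh(p.mesh, directory / fname)
        rows.append(
            {
                "plant_id": p.plant_id,
                "genotype_id": p.genotype_id,
                "x": p.position[0],
                "y": p.position[1],
                "thermal_time": p.thermal_time,
                "leaf_area_m2": p.leaf_area,
                "height_m": p.height,
                "mesh_file": fname,
            }
        )
    out = directory / manifest
    pd.DataFrame(rows).to_csv(out, index=False)
    return out


def read_plants(manifest) -> list[PlantInstance]:
    """Load plants from a manifest CSV written by :func:`write_plants`."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    plants = []
    for _, row in table.iterrows():
        mesh = read_mesh(manifest.parent / row["mesh_file"])
        plants.append(
            PlantInstance(
                plant_id=str(row["plant_id"]),
                genotype_id=str(row["genotype_id"]),
                position=(float(row["x"]), float(row["y"])),
                thermal_time=float(row["thermal_time"]),
                mesh=mesh,
                leaf_area=mesh.area,
                height=mesh.max_z,
            )
        )
    return plants


def read_transmission_map(path):
    """Read a 2D light-transmission raster.

    CSV layout: first row ``origin_x,origin_y,cell`` header values, then the
    grid rows (x index down, y index across).  Returns (xs, ys, grid)
    suitable for :class:`~canopydissect.light.LightEnvironment`.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if len(header) != 3:
            raise ValueError(f"{path}: header must be origin_x,origin_y,cell")
        ox, oy, cell = map(float, header)
        grid = np.loadtxt(fh, delimiter=",", ndmin=2)
    xs = ox + np.arange(grid.shape[0] + 1) * cell
    ys = oy + np.arange(grid.shape[1] + 1) * cell
    return xs, ys, grid


# -- run configuration -------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved configuration of a pipeline run.

    Defaults are the canonical parameterization: 0.2 x 0.2 x 0.1 m grid
    cells, 46 sky directions, clumping 0.8, scattering 0.16, 15-plant
    windows, RUE interval 30-50 d20, 12 h photoperiod.
    """

    seed: int = 0
    cell_size: tuple[float, float, float] = (0.2, 0.2, 0.1)
    n_directions: int = 46
    clumping_factor: float = 0.8
    scattering_coefficient: float = 0.16
    window_size: int = 15
    rue_interval: tuple[float, float] = (30.0, 50.0)
    photoperiod_h: float = 12.0
    daily_incident: float = 40.0
    n_genotypes: int = 9
    replicate_noise: float = 0.05
    row_spacing: float = 0.4
    plant_spacing: float = 0.2
    n_rows: int = 20
    plants_per_row: int = 20
    t_start: float = 15.0
    t_end: float = 50.0
    t_step: float = 1.0
    rue_a: float = -0.0025
    rue_b: float = 3.2
    canopy_type: str = "D"
    transmission_map: str | None = None
    paths: dict = field(default_factory=dict)


def validate_config(raw: dict | None) -> RunConfig:
    """Validate a raw config mapping, injecting defaults for omitted keys.

    All errors are aggregated; unknown keys are reported with the nearest
    valid key so a misspelling never silently falls back to a default.
    """
    raw = dict(raw or {})
    valid = {f.name for f in RunConfig.__dataclass_fields__.values()}
    errors = []
    for key in raw:
        if key not in valid:
            close = difflib.get_close_matches(key, valid, n=1)
            hint = f" (did you mean {close[0]!r}?)" if close else ""
            errors.append(f"unknown key {key!r}{hint}")
    cfg_kwargs = {k: v for k, v in raw.items() if k in valid}
    for key in ("cell_size", "rue_interval"):
        if key in cfg_kwargs:
            cfg_kwargs[key] = tuple(cfg_kwargs[key])
    cfg = RunConfig(**cfg_kwargs) if not errors else RunConfig()

    checks = [
        ("n_directions", cfg.n_directions >= 1, "must be >= 1"),
        ("clumping_factor", 0 < cfg.clumping_factor <= 1, "must be in (0, 1]"),
        (
            "scattering_coefficient",
            0 <= cfg.scattering_coefficient < 1,
            "must be in [0, 1)",
        ),
        ("window_size", cfg.window_size >= 1, "must be >= 1"),
        ("photoperiod_h", 0 < cfg.photoperiod_h <= 24, "must be in (0, 24]"),
        ("daily_incident", cfg.daily_incident >= 0, "must be >= 0"),
        ("n_genotypes", cfg.n_genotypes >= 1, "must be >= 1"),
        ("replicate_noise", cfg.replicate_noise >= 0, "must be >= 0"),
        ("row_spacing", cfg.row_spacing > 0, "must be > 0"),
        ("plant_spacing", cfg.plant_spacing > 0, "must be > 0"),
        ("t_step", cfg.t_step > 0, "must be > 0"),
        (
            "cell_size",
            all(c > 0 for c in cfg.cell_size) and len(cfg.cell_size) == 3,
            "must be 3 positive lengths",
        ),
        (
            "rue_interval",
            len(cfg.rue_interval) == 2 and cfg.rue_interval[0] < cfg.rue_interval[1],
            "must be an increasing (start, end) pair",
        ),
    ]
    for name, ok, msg in checks:
        if not ok:
            errors.append(f"{name}: {msg}")
    for name, p in (cfg.paths or {}).items():
        if not Path(p).exists():
            errors.append(f"paths.{name}: file not found: {p}")
    if cfg.transmission_map and not Path(cfg.transmission_map).exists():
        errors.append(f"transmission_map: file not found: {cfg.transmission_map}")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def dump_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
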