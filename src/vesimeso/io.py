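"""Configuration, trajectory and mesh I/O, result tables, test fixtures.

Configs are YAML mappings validated against a key schema (unknown keys are
rejected, errors name the offending key); all physical quantities are in
reduced units unless suffixed ``_physical``.  Trajectories are written as
extended XYZ, meshes as legacy-VTK polydata with an optional per-face scalar
(e.g. elastic energy density) or as OBJ.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .dpd import DPDPairParams, table1_pairs
from .meshgen import TriMesh, gv_mesh_preset, icosphere

_SCHEMA = {
    "units": {"preset", "r_c_nm", "f_scale", "T0_K"},
    "dpd": {"pairs", "box", "dt", "seed", "density"},
    "mesh": {"kind", "subdivisions", "R", "L_cyl", "n_ring", "ring_spacing",
             "cone_ring_sizes", "cone_height"},
    "material": {"model", "Ka", "mu", "muL", "c", "kappa", "nu",
                 "E_l", "E_t", "nu_lt", "G", "E2d", "h", "f_scale_applied"},
    "fsi": {"k_fsi", "auto_gamma", "a_ow"},
    "gas": {"pressure_compensation"},
    "obmd": {"buffer_fraction", "tau_B", "alpha_B", "P_xx", "P_yx"},
    "protocol": {"name", "F_values", "p_values", "twist", "gamma_dot",
                 "n_steps", "a_end", "t_ramp", "n_modes", "a_values",
                 "sample_every"},
    "output": {"directory", "prefix", "stride"},
    "seed": None,
}

_PAIR_KEYS = {"ww", "wg", "gg", "ow", "og", "oo"}


@dataclass
class RunConfig:
    """Validated run configuration with defaults applied."""

    units: dict = field(default_factory=dict)
    dpd: dict = field(default_factory=dict)
    mesh: dict = field(default_factory=dict)
    material: dict = field(default_factory=dict)
    fsi: dict = field(default_factory=dict)
    gas: dict = field(default_factory=dict)
    obmd: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)
    seed: int = 0

    def hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in _SCHEMA}, sort_keys=True,
            default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def pair_params(self) -> dict:
        """DPD pair dict from the preset, with per-pair overrides applied."""
        preset = self.units.get("preset", "emb")
        pairs = table1_pairs(preset)
        species = {"w": 0, "g": 1, "o": 2}
        for key, override in self.dpd.get("pairs", {}).items():
            if key not in _PAIR_KEYS:
                raise ValueError(f"unknown pair key 'dpd.pairs.{key}'")
            si, sj = species[key[0]], species[key[1]]
            cur = pairs[(si, sj)] if (si, sj) in pairs else pairs[(sj, si)]
            new = DPDPairParams(
                a=override.get("a", cur.a),
                gamma=override.get("gamma", cur.gamma),
                k=override.get("k", cur.k))
            pairs.pop((si, sj), None)
            pairs.pop((sj, si), None)
            pairs[(si, sj)] = new
        return pairs

    def build_mesh(self) -> TriMesh:
        kind = self.mesh.get("kind", "icosphere")
        if kind == "icosphere":
            return icosphere(self.mesh.get("subdivisions", 3),
                             self.mesh.get("R", 2.0))
        if kind == "gv":
            if set(self.mesh) <= {"kind", "R", "L_cyl"}:
                return gv_mesh_preset(self.mesh.get("R", 2.0),
                                      self.mesh.get("L_cyl", 12.0))
            from .meshgen import gv_capsule
            return gv_capsule(
                self.mesh.get("R", 2.0), self.mesh.get("L_cyl", 12.0),
                self.mesh.get("n_ring", 36),
                self.mesh.get("ring_spacing",
                              self.mesh.get("L_cyl", 12.0) / 36.0),
                cone_height=self.mesh.get("cone_height"),
                cone_ring_sizes=tuple(self.mesh.get("cone_ring_sizes",
                                                    (20, 10, 5))))
        raise ValueError(f"unknown mesh kind {kind!r}")

    def build_material(self):
        from . import elasticity as el
        m = self.material
        model = m.get("model", "isotropic")
        if model == "isotropic":
            if "E2d" in m:
                return el.emb_material(m["E2d"], m.get("nu", 1.0 / 3.0),
                                       m.get("h", 0.1))
            return el.MembraneMaterial(Ka=m["Ka"], mu=m["mu"],
                                       kappa=m["kappa"],
                                       nu=m.get("nu", 1.0 / 3.0))
        if model == "orthotropic":
            eng = el.OrthotropicEngineering(
                E_l=m["E_l"], E_t=m["E_t"], nu_lt=m["nu_lt"], G=m["G"],
                h=m["h"])
            return el.gv_material(eng)
        raise ValueError(f"unknown material model {model!r}")


def _validate(section: str, mapping: dict) -> None:
    allowed = _SCHEMA[section]
    for key in mapping:
        if key not in allowed:
            raise ValueError(f"unknown config key '{section}.{key}'")


def load_config(source) -> RunConfig:
    """Load and validate a YAML config file (path or mapping)."""
    if isinstance(source, dict):
        data = source
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    for section, value in data.items():
        if section not in _SCHEMA:
            raise ValueError(f"unknown config section '{section}'")
        if section == "seed":
            cfg.seed = int(value)
            continue
        if not isinstance(value, dict):
            raise ValueError(f"section '{section}' must be a mapping")
        _validate(section, value)
        setattr(cfg, section, value)
    # required keys with defaults applied via preset
    preset = cfg.units.get("preset")
    if preset is not None and preset not in ("emb", "gv"):
        raise ValueError(f"unknown units.preset {preset!r}")
    return cfg


def preset_config(name: str) -> RunConfig:
    """Full default configuration for the 'emb' or 'gv' model system."""
    if name == "emb":
        return load_config({
            "units": {"preset": "emb", "r_c_nm": 500.0, "f_scale": 1e-4,
                      "T0_K": 300.0},
            "mesh": {"kind": "icosphere", "subdivisions": 4, "R": 2.0},
            "material": {"model": "isotropic", "E2d": 1.21e5,
                         "nu": 1.0 / 3.0, "h": 0.04, "f_scale_applied": True},
            "fsi": {"k_fsi": 0.5, "auto_gamma": False, "a_ow": 40.0},
            "dpd": {"density": 3.0, "dt": 1e-4},
        })
    if name == "gv":
        return load_config({
            "units": {"preset": "gv", "r_c_nm": 35.0, "f_scale": 0.079,
                      "T0_K": 300.0},
            "mesh": {"kind": "gv", "R": 2.0, "L_cyl": 12.0},
            "material": {"model": "orthotropic", "E_l": 9.6e4, "E_t": 4.8e4,
                         "nu_lt": 0.2, "G": 1.8e4, "h": 0.0571,
                         "f_scale_applied": True},
            "fsi": {"k_fsi": 0.5, "auto_gamma": False, "a_ow": 40.0},
            "dpd": {"density": 3.0, "dt": 1e-4},
        })
    raise ValueError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# Extended XYZ
# ---------------------------------------------------------------------------

_SPECIES_NAMES = {0: "W", 1: "G", 2: "O"}
_SPECIES_CODES = {v: k for k, v in _SPECIES_NAMES.items()}


def write_xyz(frames, path, box=None, times=None) -> None:
    """Write extended-XYZ: species, position and velocity columns.

    ``frames`` is a list of (positions, velocities, species) triples.
    """
    with open(path, "w") as fh:
        for k, (pos, vel, species) in enumerate(frames):
            if len(pos) != len(vel) or len(pos) != len(species):
                raise ValueError("inconsistent frame arrays")
            fh.write(f"{len(pos)}\n")
            parts = ['Properties=species:S:1:pos:R:3:vel:R:3']
            if box is not None:
                b = np.asarray(box, dtype=float)
                parts.append(
                    f'Lattice="{b[0]} 0 0 0 {b[1]} 0 0 0 {b[2]}"')
            if times is not None:
                parts.append(f"Time={times[k]}")
            fh.write(" ".join(parts) + "\n")
            for s, p, v in zip(species, pos, vel):
                name = _SPECIES_NAMES.get(int(s), "X")
                fh.write(f"{name} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g} "
                         f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}\n")


def read_xyz(path):
    """Read frames written by :func:`write_xyz`."""
    frames = []
    with open(path) as fh:
        while True:
            line = fh.readline()
            if not line.strip():
                break
            n = int(line)
            fh.readline()  # comment
            pos = np.empty((n, 3))
            vel = np.empty((n, 3))
            species = np.empty(n, dtype=np.int8)
            for i in range(n):
                tok = fh.readline().split()
                species[i] = _SPECIES_CODES.get(tok[0], -1)
                pos[i] = [float(t) for t in tok[1:4]]
                vel[i] = [float(t) for t in tok[4:7]]
            frames.append((pos, vel, species))
    return frames


def write_vtk(mesh: TriMesh, path, face_scalar=None,
              scalar_name: str = "energy_density") -> None:
    """Legacy-VTK polydata mesh snapshot with optional per-face scalar."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"vesimeso mesh ({__version__})\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
        if face_scalar is not None:
            fh.write(f"CELL_DATA {mesh.n_faces}\n")
            fh.write(f"SCALARS {scalar_name} double 1\nLOOKUP_TABLE default\n")
            for v in face_scalar:
                fh.write(f"{v:.12g}\n")


def read_vtk_mesh(path) -> tuple[TriMesh, np.ndarray | None]:
    """Read back a polydata file written by :func:`write_vtk`."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POINTS"))
    n = int(lines[i].split()[1])
    verts = np.array([[float(t) for t in lines[i + 1 + j].split()]
                      for j in range(n)])
    i = next(k for k, ln in enumerate(lines) if ln.startswith("POLYGONS"))
    nf = int(lines[i].split()[1])
    faces = np.array([[int(t) for t in lines[i + 1 + j].split()[1:]]
                      for j in range(nf)])
    scalar = None
    for k, ln in enumerate(lines):
        if ln.startswith("LOOKUP_TABLE"):
            scalar = np.array([float(lines[k + 1 + j]) for j in range(nf)])
            break
    return TriMesh(verts, faces), scalar


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_table(df, path, config: RunConfig | None = None,
                seed: int | None = None) -> None:
    """CSV with a provenance header (# version, config hash, seed)."""
    with open(path, "w") as fh:
        fh.write(f"# vesimeso {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config.hash()}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        df.to_csv(fh, index=False)


def read_table(path):
    import pandas as pd
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            tok = line[1:].split()
            if len(tok) >= 2:
                meta[tok[0]] = tok[1]
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def make_fixture(name: str, seed: int = 0):
    """Deterministic small systems for tests.

    small_water_box: rho = 3 fluid in a 5^3 box; tiny_emb: 162-vertex
    icosphere; tiny_gv: 128-vertex capsule.  Returns the in-memory object.
    """
    from .dpd import fill_box
    from .meshgen import gv_capsule
    rng = np.random.default_rng(seed)
    if name == "small_water_box":
        return fill_box(np.array([5.0, 5.0, 5.0]), 3.0, rng)
    if name == "tiny_emb":
        return icosphere(2, 2.0)
    if name == "tiny_gv":
        return gv_capsule(1.2, 4.0, n_ring=12, ring_spacing=0.5,
                          cone_ring_sizes=(6, 3))
    raise ValueError(f"unknown fixture {name!r}")
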