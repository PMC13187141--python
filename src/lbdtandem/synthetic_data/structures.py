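"""Toy ligand/linker structure fixtures with ground-truth embedding labels.

Ligand shapes:

* ``slab`` — atoms filling a plate of thickness 8 A centered on the
  origin with its normal along x; a *threading* path crosses it.
* ``shell`` — atoms on a sphere of configurable radius; a *wrapping*
  path circles outside it.
* ``two-lobe`` — two balls mimicking a dimer, with a gap at the origin.

Truth labels come from a deliberately naive per-atom/per-octant oracle
(`brute_force_octant_counts`), kept independent of the vectorized
classifier in :mod:`lbdtandem.linker_geometry`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..linker_geometry import (
    Atom,
    EmbeddingParams,
    LinkerSpan,
    ResidueRec,
    StructureModel,
)

LIGAND_SHAPES = ("slab", "shell", "two-lobe")
LINKER_MODES = ("threading", "wrapping")


@dataclass(frozen=True)
class StructureSimSpec:
    ligand_atom_count: int
    ligand_shape: str
    linker_length: int
    linker_mode: str
    ca_spacing: float = 3.8
    shell_radius: float = 20.0
    wrap_radius: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ligand_atom_count < 0:
            raise ValueError(f"ligand_atom_count must be >= 0, got {self.ligand_atom_count}")
        if self.ligand_shape not in LIGAND_SHAPES:
            raise ValueError(f"ligand_shape must be one of {LIGAND_SHAPES}, got {self.ligand_shape!r}")
        if self.linker_length < 1:
            raise ValueError(f"linker_length must be >= 1, got {self.linker_length}")
        if self.linker_mode not in LINKER_MODES:
            raise ValueError(f"linker_mode must be one of {LINKER_MODES}, got {self.linker_mode!r}")
        if not (self.ca_spacing > 0):
            raise ValueError(f"ca_spacing must be > 0, got {self.ca_spacing}")


class GenerationError(RuntimeError):
    """Requested geometry is impossible (e.g. wrapping path hits the hull)."""


def _ligand_coords(spec: StructureSimSpec, rng: np.random.Generator) -> np.ndarray:
    n = spec.ligand_atom_count
    if n == 0:
        return np.zeros((0, 3))
    if spec.ligand_shape == "slab":
        xs = rng.uniform(-4.0, 4.0, size=n)
        ys = rng.uniform(-15.0, 15.0, size=n)
        zs = rng.uniform(-15.0, 15.0, size=n)
        return np.column_stack([xs, ys, zs])
    if spec.ligand_shape == "shell":
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = rng.uniform(spec.shell_radius - 1.0, spec.shell_radius + 1.0, size=n)
        return directions * radii[:, None]
    # two-lobe dimer: balls of radius 8 centered at x = +/- 11
    centers = np.where(rng.random(n) < 0.5, -11.0, 11.0)
    points = rng.normal(size=(n, 3))
    points /= np.linalg.norm(points, axis=1, keepdims=True)
    points *= (rng.uniform(0.0, 1.0, size=n) ** (1 / 3) * 8.0)[:, None]
    points[:, 0] += centers
    return points


def _linker_path(spec: StructureSimSpec) -> np.ndarray:
    n = spec.linker_length
    if spec.linker_mode == "threading":
        offsets = (np.arange(n) - (n - 1) / 2.0) * spec.ca_spacing
        return np.column_stack([offsets, np.zeros(n), np.zeros(n)])
    # wrapping: arc on a circle in the x-y plane, outside the ligand
    r = spec.wrap_radius
    dtheta = spec.ca_spacing / r
    thetas = (np.arange(n) - (n - 1) / 2.0) * dtheta
    return np.column_stack([r * np.cos(thetas), r * np.sin(thetas), np.zeros(n)])


def _path_hits_hull(path: np.ndarray, ligand: np.ndarray) -> bool:
    if len(ligand) < 4:
        return False
    from scipy.spatial import Delaunay, QhullError

    try:
        hull = Delaunay(ligand)
    except QhullError:
        return False
    return bool(np.any(hull.find_simplex(path) >= 0))


def brute_force_octant_counts(
    ligand_coords: np.ndarray,
    ca_coord,
    radius: float = 5.0,
) -> int:
    """Naive octant-occupancy count: explicit loops, no vectorization.

    Serves as the independent oracle for the vectorized classifier.
    Ties: an atom on an octant plane belongs to the positive side.
    """
    occupied = set()
    cx, cy, cz = float(ca_coord[0]), float(ca_coord[1]), float(ca_coord[2])
    for atom in ligand_coords:
        dx = float(atom[0]) - cx
        dy = float(atom[1]) - cy
        dz = float(atom[2]) - cz
        if math.sqrt(dx * dx + dy * dy + dz * dz) > radius:
            continue
        occupied.add((dx >= 0, dy >= 0, dz >= 0))
    return len(occupied)


def make_linker_structure(
    spec: StructureSimSpec,
    params: EmbeddingParams | None = None,
) -> tuple[StructureModel, dict]:
    """Build a ligand + linker model and its ground-truth embedding labels."""
    params = params or EmbeddingParams()
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    ligand = _ligand_coords(spec, rng)
    path = _linker_path(spec)

    if spec.linker_mode == "wrapping" and _path_hits_hull(path, ligand):
        raise GenerationError(
            "wrapping path intersects the ligand convex hull; "
            "increase wrap_radius or shrink the ligand"
        )

    lig_residues = tuple(
        ResidueRec(
            resseq=i + 1,
            resname="LIG",
            atoms=(Atom(name="C", element="C", coord=tuple(c)),),
        )
        for i, c in enumerate(ligand)
    )
    rec_residues = tuple(
        ResidueRec(
            resseq=i + 1,
            resname="GLY",
            atoms=(Atom(name="CA", element="C", coord=tuple(c)),),
        )
        for i, c in enumerate(path)
    )
    model = StructureModel(
        model_id=f"synthetic_{spec.ligand_shape}_{spec.linker_mode}_s{spec.seed}",
        chains={"L": lig_residues, "R": rec_residues},
        ligand_chains=("L",),
        receptor_chain="R",
    )

    counts = [
        brute_force_octant_counts(ligand, ca, radius=params.radius) for ca in path
    ]
    truth = {
        "octant_counts": counts,
        "embedded": [c >= params.min_octants for c in counts],
        "n_embedded": sum(c >= params.min_octants for c in counts),
        "span": LinkerSpan(start=0, end=spec.linker_length, how="explicit"),
        "params": params,
    }
    return model, truth
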