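"""Octant spatial-embedding metric for inter-domain linkers.

For each linker residue the space around its C-alpha is split into eight
octants; the residue is *embedded* in the ligand when ligand heavy atoms
within ``radius`` angstroms (default 5) occupy at least ``min_octants``
of the eight (default 5).  A model series over increasing linker lengths
yields the minimal length whose top-ranked models show zero embedded
residues — the bivalency cutoff.

Frame caveat: octants are axis-aligned in the model's global frame by
default, so joint rotation of a model can change counts (translation
cannot).  A ligand-PCA frame is available for rotation covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DEFAULT_LINKER_CORE = "SESVNNDMIVTDNNGAVKFP"

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}
_HYDROGEN_ELEMENTS = {"H", "D"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS


@dataclass(frozen=True)
class ResidueRec:
    resseq: int
    resname: str
    atoms: tuple[Atom, ...]

    @property
    def ca(self) -> Atom | None:
        for atom in self.atoms:
            if atom.name.strip() == "CA":
                return atom
        return None

    @property
    def one_letter(self) -> str:
        return _THREE_TO_ONE.get(self.resname.upper(), "X")


@dataclass(frozen=True)
class StructureModel:
    """One structural model with designated ligand and receptor chains."""

    model_id: str
    chains: Mapping[str, tuple[ResidueRec, ...]]
    ligand_chains: tuple[str, ...] = ("L",)
    receptor_chain: str = "R"
    rank: int = 0

    def __post_init__(self) -> None:
        for cid in (*self.ligand_chains, self.receptor_chain):
            if cid not in self.chains:
                raise ValueError(
                    f"model {self.model_id!r}: chain {cid!r} not present; "
                    f"chains found: {sorted(self.chains)}"
                )
        for chain in self.chains.values():
            for res in chain:
                for atom in res.atoms:
                    if not all(math.isfinite(c) for c in atom.coord):
                        raise ValueError(
                            f"model {self.model_id!r}: non-finite coordinate "
                            f"in residue {res.resseq}"
                        )

    def ligand_heavy_coords(self) -> np.ndarray:
        """(N, 3) coordinates of non-hydrogen, non-water ligand atoms."""
        coords = [
            atom.coord
            for cid in self.ligand_chains
            for res in self.chains[cid]
            if res.resname.upper() not in _WATER_RESNAMES
            for atom in res.atoms
            if not atom.is_hydrogen
        ]
        return np.asarray(coords, dtype=float).reshape(-1, 3)

    def receptor_residues(self) -> tuple[ResidueRec, ...]:
        return self.chains[self.receptor_chain]

    def receptor_sequence(self) -> str:
        return "".join(res.one_letter for res in self.receptor_residues())

    def translated(self, vector) -> "StructureModel":
        v = np.asarray(vector, dtype=float)
        new_chains = {
            cid: tuple(
                ResidueRec(
                    resseq=res.resseq,
                    resname=res.resname,
                    atoms=tuple(
                        Atom(a.name, a.element, tuple(np.asarray(a.coord) + v))
                        for a in res.atoms
                    ),
                )
                for res in chain
            )
            for cid, chain in self.chains.items()
        }
        return replace(self, chains=new_chains)


def read_pdb(
    path: str | Path,
    ligand_chains: Sequence[str] = ("L",),
    receptor_chain: str = "R",
    model_id: str | None = None,
    rank: int = 0,
) -> StructureModel:
    """Parse the first model of a PDB file into a StructureModel.

    Altloc duplicates are resolved to the highest-occupancy conformer
    (Bio.PDB's selection rule).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(model_id or Path(path).stem, str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError(f"{path}: no models found") from None

    chains: dict[str, tuple[ResidueRec, ...]] = {}
    for chain in model:
        residues = []
        for res in chain:
            atoms = []
            for atom in res:
                # DisorderedAtom delegates to its highest-occupancy child
                element = (atom.element or "").strip() or atom.get_name().strip()[:1]
                atoms.append(
                    Atom(
                        name=atom.get_name(),
                        element=element,
                        coord=tuple(float(x) for x in atom.coord),
                    )
                )
            residues.append(
                ResidueRec(resseq=res.id[1], resname=res.get_resname(), atoms=tuple(atoms))
            )
        chains[chain.id] = tuple(residues)

    return StructureModel(
        model_id=model_id or Path(path).stem,
        chains=chains,
        ligand_chains=tuple(ligand_chains),
        receptor_chain=receptor_chain,
        rank=rank,
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialize a StructureModel as plain ATOM records (one MODEL)."""
    serial = 0
    lines = []
    for cid in sorted(model.chains):
        for res in model.chains[cid]:
            for atom in res.atoms:
                serial += 1
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                x, y, z = atom.coord
                lines.append(
                    f"ATOM  {serial:5d} {name:<4s} {res.resname:<3s} {cid}"
                    f"{res.resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
                )
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EmbeddingParams:
    radius: float = 5.0
    min_octants: int = 5
    frame: str = "global"  # or "pca"

    def __post_init__(self) -> None:
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if not (1 <= self.min_octants <= 8):
            raise ValueError(f"min_octants must be in [1, 8], got {self.min_octants}")
        if self.frame not in ("global", "pca"):
            raise ValueError(f"frame must be 'global' or 'pca', got {self.frame!r}")


@dataclass(frozen=True)
class LinkerSpan:
    """Contiguous 0-based half-open index range on the receptor chain."""

    start: int
    end: int
    how: str = "explicit"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("linker span must be non-empty")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ResidueEmbedding:
    resseq: int
    octant_count: int
    embedded: bool


@dataclass(frozen=True)
class EmbeddingProfile:
    model_id: str
    rank: int
    linker_length: int
    residues: tuple[ResidueEmbedding, ...]

    def __post_init__(self) -> None:
        for r in self.residues:
            if not (0 <= r.octant_count <= 8):
                raise ValueError(f"octant count out of range: {r.octant_count}")

    @property
    def n_embedded(self) -> int:
        return sum(r.embedded for r in self.residues)


def find_linker(
    receptor_sequence: str,
    core: str = DEFAULT_LINKER_CORE,
    flank_residues: str = "GS",
) -> LinkerSpan:
    """Locate the linker by exact core match plus flanking-run extension.

    The core must occur exactly once; the span is then grown outward
    through maximal contiguous runs of the flanking letters (G/S by
    default) on both sides.
    """
    if not core:
        raise ValueError("core sequence must be non-empty")
    seq = receptor_sequence.upper()
    core = core.upper()
    first = seq.find(core)
    if first < 0:
        raise ValueError("linker core sequence not found in receptor sequence")
    if seq.find(core, first + 1) >= 0:
        raise ValueError("linker core sequence is ambiguous (multiple matches)")
    start, end = first, first + len(core)
    flank = set(flank_residues.upper())
    while start > 0 and seq[start - 1] in flank:
        start -= 1
    while end < len(seq) and seq[end] in flank:
        end += 1
    return LinkerSpan(start=start, end=end, how="motif")


def _frame_axes(ligand_coords: np.ndarray, frame: str) -> np.ndarray:
    if frame == "global" or len(ligand_coords) < 2:
        return np.eye(3)
    centered = ligand_coords - ligand_coords.mean(axis=0)
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    axes = eigvecs[:, ::-1].T  # rows = axes, descending variance
    # deterministic sign: largest-magnitude component positive
    for i in range(3):
        j = int(np.argmax(np.abs(axes[i])))
        if axes[i, j] < 0:
            axes[i] = -axes[i]
    return axes


def octant_counts(
    model: StructureModel,
    span: LinkerSpan,
    params: EmbeddingParams | None = None,
) -> EmbeddingProfile:
    """Per-residue octant occupancy for the linker span of a model.

    An atom exactly on the radius is inside; an atom on an octant plane
    is assigned to the positive half-space for that axis.
    """
    params = params or EmbeddingParams()
    residues = model.receptor_residues()
    if span.end > len(residues):
        raise ValueError(
            f"span [{span.start}, {span.end}) exceeds receptor chain "
            f"length {len(residues)}"
        )
    linker = residues[span.start:span.end]
    missing = [res.resseq for res in linker if res.ca is None]
    if missing:
        raise ValueError(f"linker residues missing CA atoms: {missing}")

    ligand = model.ligand_heavy_coords()
    axes = _frame_axes(ligand, params.frame)

    entries = []
    for res in linker:
        count = 0
        if len(ligand):
            rel = (ligand - np.asarray(res.ca.coord)) @ axes.T
            near = rel[np.linalg.norm(rel, axis=1) <= params.radius]
            if len(near):
                signs = (near >= 0).astype(np.int8)
                octant_ids = signs[:, 0] * 4 + signs[:, 1] * 2 + signs[:, 2]
                count = len(np.unique(octant_ids))
        entries.append(
            ResidueEmbedding(
                resseq=res.resseq,
                octant_count=count,
                embedded=count >= params.min_octants,
            )
        )
    return EmbeddingProfile(
        model_id=model.model_id,
        rank=model.rank,
        linker_length=span.length,
        residues=tuple(entries),
    )


@dataclass(frozen=True)
class PlacementSite:
    """Canonical docking site of one receptor LBD on the ligand."""

    lbd_name: str
    receptor_start: int  # resseq, inclusive
    receptor_end: int    # resseq, inclusive
    epitope: tuple[tuple[str, int], ...]  # (ligand chain, resseq)


@dataclass(frozen=True)
class PlacementExclusion:
    model_id: str
    lbd_name: str
    min_distance: float


def _residue_coords(model: StructureModel, chain_id: str, resseqs: set[int]) -> np.ndarray:
    chain = model.chains.get(chain_id)
    if chain is None:
        raise ValueError(f"model {model.model_id!r}: chain {chain_id!r} absent")
    found = {res.resseq for res in chain} & resseqs
    missing = resseqs - found
    if missing:
        raise ValueError(
            f"model {model.model_id!r}: chain {chain_id!r} lacks residue(s) "
            f"{sorted(missing)}"
        )
    coords = [
        atom.coord
        for res in chain
        if res.resseq in resseqs
        for atom in res.atoms
        if not atom.is_hydrogen
    ]
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def filter_misplaced_models(
    models: Iterable[StructureModel],
    placement_spec: Sequence[PlacementSite],
    max_dist: float = 8.0,
) -> tuple[list[StructureModel], list[PlacementExclusion]]:
    """Drop models whose LBDs sit away from their canonical ligand sites.

    A model is kept iff for every placement site the minimum heavy-atom
    distance between the LBD span and its epitope residues is <= max_dist.
    """
    kept: list[StructureModel] = []
    excluded: list[PlacementExclusion] = []
    for model in models:
        violation = None
        for site in placement_spec:
            span = set(range(site.receptor_start, site.receptor_end + 1))
            lbd = _residue_coords(model, model.receptor_chain, span)
            epitope_by_chain: dict[str, set[int]] = {}
            for chain_id, resseq in site.epitope:
                epitope_by_chain.setdefault(chain_id, set()).add(resseq)
            epi = np.vstack([
                _residue_coords(model, cid, rs) for cid, rs in epitope_by_chain.items()
            ])
            dmin = float(np.min(np.linalg.norm(lbd[:, None, :] - epi[None, :, :], axis=2)))
            if dmin > max_dist:
                violation = PlacementExclusion(model.model_id, site.lbd_name, dmin)
                break
        if violation is None:
            kept.append(model)
        else:
            excluded.append(violation)
    return kept, excluded


@dataclass(frozen=True)
class CutoffResult:
    length: int | None
    status: str
    warnings: tuple[str, ...] = ()

    @property
    def present(self) -> bool:
        return self.length is not None


def min_bivalent_linker(
    profiles_by_length: Mapping[int, Sequence[EmbeddingProfile]],
    top_n: int = 3,
) -> CutoffResult:
    """Smallest linker length whose top-n ranked models are all unembedded.

    Model ranking is taken from the profiles' ``rank`` attribute (input
    order / predictor rank), never recomputed.  Lengths with fewer than
    ``top_n`` profiles are skipped with a warning.
    """
    warnings = []
    for length in sorted(profiles_by_length):
        profiles = sorted(profiles_by_length[length], key=lambda p: p.rank)
        if len(profiles) < top_n:
            warnings.append(
                f"length {length}: only {len(profiles)} model(s), "
                f"need {top_n}; skipped"
            )
            continue
        if all(p.n_embedded == 0 for p in profiles[:top_n]):
            return CutoffResult(length=length, status="ok", warnings=tuple(warnings))
    return CutoffResult(
        length=None,
        status="absent: no linker length has all top-ranked models unembedded",
        warnings=tuple(warnings),
    )


def compare_to_cutoff(lengths: Mapping[str, int] | pd.DataFrame, cutoff: int) -> pd.DataFrame:
    """Classify species linker lengths against the bivalency cutoff.

    Feasibility is inclusive: a linker of exactly the cutoff length is
    classified as bivalency-feasible.
    """
    if isinstance(lengths, pd.DataFrame):
        if not {"species", "linker_length"} <= set(lengths.columns):
            raise ValueError("need columns: species, linker_length")
        items = list(zip(lengths["species"], lengths["linker_length"]))
    else:
        items = sorted(lengths.items())
    rows = []
    for species, length in items:
        if length < 0:
            raise ValueError(f"{species}: linker length must be >= 0, got {length}")
        rows.append(
            {
                "species": species,
                "linker_length": int(length),
                "bivalency_feasible": bool(length >= cutoff),
            }
        )
    return pd.DataFrame(rows, columns=["species", "linker_length", "bivalency_feasible"])


def profiles_to_tsv(profiles: Sequence[EmbeddingProfile]) -> str:
    lines = ["model\tlinker_len\tresidue\toctant_count\tembedded"]
    for p in profiles:
        for r in p.residues:
            lines.append(
                f"{p.model_id}\t{p.linker_length}\t{r.resseq}\t"
                f"{r.octant_count}\t{int(r.embedded)}"
            )
    return "\n".join(lines) + "\n"


def rotation_sensitivity(
    model: StructureModel,
    span: LinkerSpan,
    params: EmbeddingParams | None = None,
    n_rotations: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """n_embedded under random joint rotations (frame-sensitivity report)."""
    from scipy.spatial.transform import Rotation

    params = params or EmbeddingParams()
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_rotations):
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = _rotate_model(model, rot)
        profile = octant_counts(rotated, span, params)
        rows.append({"rotation": i, "n_embedded": profile.n_embedded})
    return pd.DataFrame(rows)


def _rotate_model(model: StructureModel, rot: np.ndarray) -> StructureModel:
    new_chains = {
        cid: tuple(
            ResidueRec(
                resseq=res.resseq,
                resname=res.resname,
                atoms=tuple(
                    Atom(a.name, a.element, tuple(rot @ np.asarray(a.coord)))
                    for a in res.atoms
                ),
            )
            for res in chain
        )
        for cid, chain in model.chains.items()
    }
    return replace(model, chains=new_chains)
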