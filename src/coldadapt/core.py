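"""Domain types for structures and conformational ensembles, PDB I/O and
least-squares superposition.

Coordinates are stored in nanometres throughout the package; PDB files (which
use angstroms) are converted on read and write.  Residues are indexed by a
0-based internal ordinal; user-facing output goes through
:attr:`StructureModel.numbering_map`, which defaults to the PDB residue number
(plus insertion code) so that results can be reported in a reference numbering
convention such as the one used for homolog comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "StructureModel",
    "Ensemble",
    "ReplicateSet",
    "ParseError",
    "ValidationError",
    "EmptyStructureError",
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "superpose_frames",
    "kabsch_transform",
    "fitted_rmsd",
    "resolve_selection",
]

ANGSTROM_PER_NM = 10.0

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
#: hetero residues accepted by default (metal/ion cofactors and water)
DEFAULT_HETERO = {"MG", "CL", "HOH", "NA", "ZN", "CA"}

BACKBONE_ATOMS = {"N", "CA", "C", "O"}

#: atomic masses (u) for the elements that occur in protein + ion systems
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "MG": 24.305, "CL": 35.45, "NA": 22.990, "K": 39.098,
    "ZN": 65.38, "CA": 40.078, "FE": 55.845,
}


class ParseError(ValueError):
    """File does not conform to the expected format."""


class ValidationError(ValueError):
    """Parsed content violates a structural invariant."""


class EmptyStructureError(ValidationError):
    """A structure file contained no ATOM records."""


@dataclass(frozen=True)
class Atom:
    """A single atom of a structure topology.

    ``coords`` are the reference coordinates in nm; ensemble frames carry
    their own coordinate arrays in the same atom order.
    """

    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: tuple[float, float, float]
    is_backbone: bool
    is_hydrogen: bool

    @property
    def mass(self) -> float:
        return ATOMIC_MASSES.get(self.element.upper(), 12.011)


def _element_from_name(name: str, element_field: str = "") -> str:
    el = element_field.strip()
    if el:
        return el.upper()
    # fall back to the atom-name convention: digits stripped, first letter(s)
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "C"
    if stripped[:2].upper() in ATOMIC_MASSES and len(stripped) > 1 and not stripped[0].isdigit():
        # two-letter elements only for ions (MG, CL, NA, ZN, FE)
        two = stripped[:2].upper()
        if two in {"MG", "CL", "NA", "ZN", "FE"}:
            return two
    return stripped[0].upper()


@dataclass
class StructureModel:
    """An ordered atom list plus residue bookkeeping for one topology.

    ``residues`` lists ``(residue_index, residue_name, chain_id)`` in order;
    ``numbering_map`` maps the internal 0-based residue ordinal to the
    user-facing residue label (PDB number + insertion code by default).
    """

    atoms: list[Atom]
    residues: list[tuple[int, str, str]]
    numbering_map: dict[int, str] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        keys = {(idx, ch) for idx, _name, ch in self.residues}
        for atom in self.atoms:
            if (atom.residue_index, atom.chain_id) not in keys:
                raise ValidationError(
                    f"atom {atom.name} references residue "
                    f"{atom.residue_index}/{atom.chain_id} not in residue list"
                )
            if not np.all(np.isfinite(atom.coords)):
                raise ValidationError(f"non-finite coordinates on atom {atom.name}")
        per_chain: dict[str, int] = {}
        for idx, _name, ch in self.residues:
            if ch in per_chain and idx <= per_chain[ch]:
                raise ValidationError(
                    f"residue ordinals not strictly increasing in chain {ch!r}"
                )
            per_chain[ch] = idx
        if self.numbering_map is not None:
            labels = list(self.numbering_map.values())
            if len(labels) != len(set(labels)):
                raise ValidationError("numbering_map is not injective")

    # -- derived views ------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.asarray([a.coords for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.asarray([a.mass for a in self.atoms], dtype=float)

    def residue_label(self, ordinal: int) -> str:
        if self.numbering_map is not None and ordinal in self.numbering_map:
            return self.numbering_map[ordinal]
        return str(self.residues[ordinal][0])

    def residue_ordinal_of_atom(self, atom_index: int) -> int:
        atom = self.atoms[atom_index]
        key = (atom.residue_index, atom.chain_id)
        if not hasattr(self, "_ordinal_cache"):
            self._ordinal_cache = {
                (idx, ch): k for k, (idx, _n, ch) in enumerate(self.residues)
            }
        return self._ordinal_cache[key]

    def atom_indices_of_residue(self, ordinal: int) -> list[int]:
        idx, _name, ch = self.residues[ordinal]
        return [
            k for k, a in enumerate(self.atoms)
            if a.residue_index == idx and a.chain_id == ch
        ]

    def select(self, predicate: Callable[[Atom], bool]) -> np.ndarray:
        return np.asarray(
            [i for i, a in enumerate(self.atoms) if predicate(a)], dtype=int
        )

    def calpha_indices(self) -> np.ndarray:
        return self.select(lambda a: a.name == "CA" and not a.is_hydrogen
                           and a.residue_name in STANDARD_RESIDUES)

    def mainchain_indices(self) -> np.ndarray:
        return self.select(lambda a: a.is_backbone)

    def heavy_indices(self) -> np.ndarray:
        return self.select(lambda a: not a.is_hydrogen)


NAMED_SELECTIONS = {
    "calpha": StructureModel.calpha_indices,
    "mainchain": StructureModel.mainchain_indices,
    "all-heavy": StructureModel.heavy_indices,
    "heavy": StructureModel.heavy_indices,
}


def resolve_selection(topology: StructureModel, selection) -> np.ndarray:
    """Resolve a selection (named string, predicate, mask or index array) to
    atom indices."""
    if selection is None or selection == "all":
        return np.arange(topology.n_atoms)
    if isinstance(selection, str):
        try:
            return NAMED_SELECTIONS[selection](topology)
        except KeyError:
            raise ValueError(
                f"unknown selection {selection!r}; expected one of "
                f"{sorted(NAMED_SELECTIONS)} or 'all'"
            ) from None
    if callable(selection):
        return topology.select(selection)
    arr = np.asarray(selection)
    if arr.dtype == bool:
        return np.flatnonzero(arr)
    return arr.astype(int)


@dataclass
class Ensemble:
    """Ordered coordinate frames over a fixed topology.

    ``frames`` has shape ``(n_frames, n_atoms, 3)`` in nm and
    ``frame_interval`` is the time between stored frames in ns.
    """

    topology: StructureModel
    frames: np.ndarray
    frame_interval: float
    replicate_id: str = "r1"
    system_id: str = "system"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValidationError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValidationError("an ensemble needs at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValidationError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if not self.frame_interval > 0:
            raise ValidationError("frame_interval must be positive (ns)")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.frames.shape[1])

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def with_frames(self, frames: np.ndarray) -> "Ensemble":
        return Ensemble(self.topology, frames, self.frame_interval,
                        self.replicate_id, self.system_id)


@dataclass
class ReplicateSet:
    """Independent replicate ensembles of one simulated system."""

    system_id: str
    ensembles: list[Ensemble]

    def __post_init__(self) -> None:
        if not self.ensembles:
            raise ValidationError("a ReplicateSet needs at least one ensemble")
        first = self.ensembles[0]
        for e in self.ensembles[1:]:
            if e.n_atoms != first.n_atoms:
                raise ValidationError("replicates differ in atom count")
            if e.topology.residues != first.topology.residues:
                raise ValidationError("replicates differ in residue list")
        ids = [e.replicate_id for e in self.ensembles]
        if len(ids) != len(set(ids)):
            raise ValidationError("replicate_ids are not unique")


# ---------------------------------------------------------------------------
# PDB reading (Bio.PDB parse engine + contract validation)
# ---------------------------------------------------------------------------

def _biopdb_parse(path: str | Path):
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(PERMISSIVE=0, QUIET=True)
    try:
        return parser.get_structure("s", str(path))
    except PDBConstructionException as exc:
        raise ValidationError(f"invalid PDB content in {path}: {exc}") from exc
    except (ValueError, IndexError) as exc:
        raise ValidationError(f"malformed PDB record in {path}: {exc}") from exc


def _model_to_atoms(model, hetero_allowed: set[str], path) -> tuple[list[Atom], list, dict]:
    atoms: list[Atom] = []
    residues: list[tuple[int, str, str]] = []
    numbering: dict[int, str] = {}
    seen_keys: set = set()
    dropped_altloc = False
    for chain in model:
        for residue in chain:
            hetflag, resseq, icode = residue.id
            resname = residue.get_resname().strip()
            if resname not in STANDARD_RESIDUES and resname not in hetero_allowed:
                raise ValidationError(
                    f"residue {resname} {resseq}{icode.strip()} in {path} is neither "
                    f"a standard amino acid nor in the accepted hetero set"
                )
            ordinal = len(residues)
            residues.append((ordinal, resname, chain.id))
            numbering[ordinal] = f"{resseq}{icode.strip()}"
            res_seen: set[str] = set()
            for atom in residue.get_unpacked_list():
                altloc = atom.get_altloc()
                if altloc not in (" ", "", "A"):
                    dropped_altloc = True
                    continue
                name = atom.get_name()
                if name in res_seen:
                    raise ValidationError(
                        f"duplicate atom {name} in residue {resname} "
                        f"{resseq}{icode.strip()} of {path}"
                    )
                res_seen.add(name)
                el = _element_from_name(name, atom.element or "")
                xyz = atom.get_coord() / ANGSTROM_PER_NM
                atoms.append(Atom(
                    name=name,
                    element=el,
                    residue_index=ordinal,
                    residue_name=resname,
                    chain_id=chain.id,
                    coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    is_backbone=(name in BACKBONE_ATOMS
                                 and resname in STANDARD_RESIDUES),
                    is_hydrogen=(el == "H"),
                ))
    if dropped_altloc:
        warnings.warn(f"{path}: alternate locations other than 'A' were dropped")
    return atoms, residues, numbering


def read_structure(path: str | Path, format: str = "pdb",
                   hetero_allowed: Iterable[str] = DEFAULT_HETERO) -> StructureModel:
    """Read a single-model PDB file into a :class:`StructureModel`.

    Hetero ions are retained as single-atom residues; backbone and hydrogen
    flags are derived from atom names; insertion codes are preserved in the
    numbering map.  Alternate locations other than 'A'/blank are dropped with
    a warning.
    """
    if format != "pdb":
        raise ValueError(f"unsupported structure format {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    structure = _biopdb_parse(path)
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    atoms, residues, numbering = _model_to_atoms(models[0], set(hetero_allowed), path)
    if not atoms:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    return StructureModel(atoms=atoms, residues=residues, numbering_map=numbering)


def read_ensemble(path: str | Path, format: str = "multi-model-pdb",
                  frame_interval: float = 0.02,
                  hetero_allowed: Iterable[str] = DEFAULT_HETERO,
                  replicate_id: str | None = None,
                  system_id: str = "system") -> Ensemble:
    """Read a multi-model PDB file as an :class:`Ensemble` (one MODEL = one
    frame).  A single un-modeled PDB counts as one frame.

    ``frame_interval`` is the time between stored frames in ns (default
    0.02 ns, i.e. one frame per 20 ps).
    """
    if format not in ("multi-model-pdb", "pdb"):
        raise ValueError(f"unsupported ensemble format {format!r}")
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    text_models = 0
    text_endmdl = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("MODEL"):
                text_models += 1
            elif line.startswith("ENDMDL"):
                text_endmdl += 1
    if text_models != text_endmdl:
        raise ParseError(
            f"{path}: {text_models} MODEL records but {text_endmdl} ENDMDL records"
        )
    structure = _biopdb_parse(path)
    models = list(structure)
    if not models:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    hetset = set(hetero_allowed)
    atoms, residues, numbering = _model_to_atoms(models[0], hetset, path)
    if not atoms:
        raise EmptyStructureError(f"{path} contains no ATOM records")
    topology = StructureModel(atoms=atoms, residues=residues, numbering_map=numbering)
    ref_sig = [(a.name, a.residue_index, a.chain_id) for a in atoms]
    frames = np.empty((len(models), len(atoms), 3))
    frames[0] = topology.coords
    for k, model in enumerate(models[1:], start=2):
        m_atoms, _r, _n = _model_to_atoms(model, hetset, path)
        if len(m_atoms) != len(atoms):
            raise ValidationError(
                f"{path}: model {k} has {len(m_atoms)} atoms, expected {len(atoms)}"
            )
        sig = [(a.name, a.residue_index, a.chain_id) for a in m_atoms]
        if sig != ref_sig:
            raise ValidationError(f"{path}: atom order differs in model {k}")
        frames[k - 1] = [a.coords for a in m_atoms]
    return Ensemble(
        topology=topology, frames=frames, frame_interval=frame_interval,
        replicate_id=replicate_id or path.stem, system_id=system_id,
    )


# ---------------------------------------------------------------------------
# PDB writing
# ---------------------------------------------------------------------------

def _format_atom_line(serial: int, atom: Atom, xyz: np.ndarray,
                      resseq: int, icode: str, hetero: bool) -> str:
    record = "HETATM" if hetero else "ATOM  "
    name = atom.name
    # PDB column convention: 1-3 char names start in column 14
    if len(name) < 4 and len(atom.element) < 2:
        name_field = f" {name:<3s}"
    else:
        name_field = f"{name:<4s}"
    x, y, z = (np.asarray(xyz) * ANGSTROM_PER_NM).tolist()
    return (
        f"{record}{serial:>5d} {name_field} {atom.residue_name:<3s} "
        f"{atom.chain_id:1s}{resseq:>4d}{icode:1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{atom.element:>2s}\n"
    )


def _split_label(label: str) -> tuple[int, str]:
    digits = label
    icode = " "
    if label and not label[-1].isdigit():
        digits, icode = label[:-1], label[-1]
    return int(digits) if digits.lstrip("-").isdigit() else 0, icode


def _write_model(fh, topology: StructureModel, coords: np.ndarray) -> None:
    serial = 0
    for i, atom in enumerate(topology.atoms):
        serial += 1
        ordinal = topology.residue_ordinal_of_atom(i)
        label = topology.residue_label(ordinal)
        resseq, icode = _split_label(label)
        hetero = atom.residue_name not in STANDARD_RESIDUES
        fh.write(_format_atom_line(serial, atom, coords[i], resseq, icode, hetero))
    fh.write("TER\n")


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a single-model PDB (coordinates converted nm -> angstrom)."""
    with open(path, "w") as fh:
        _write_model(fh, model, model.coords)
        fh.write("END\n")


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB, one MODEL block per frame."""
    with open(path, "w") as fh:
        for k in range(ensemble.n_frames):
            fh.write(f"MODEL {k + 1:>8d}\n")
            _write_model(fh, ensemble.topology, ensemble.frames[k])
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Superposition (Kabsch)
# ---------------------------------------------------------------------------

class DegenerateFitError(ValueError):
    """Selection has fewer than 3 atoms or is collinear."""


def _check_selection_rank(points: np.ndarray) -> None:
    if points.shape[0] < 3:
        raise DegenerateFitError(
            f"superposition needs >=3 selected atoms, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1e-12):
        raise DegenerateFitError("selected atoms are collinear; fit is degenerate")


def kabsch_transform(mobile: np.ndarray, target: np.ndarray,
                     check: bool = True) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid-body fit of ``mobile`` onto ``target``.

    Returns ``(R, mobile_centroid, target_centroid)`` such that the fitted
    coordinates of any point x are ``R @ (x - mobile_centroid) + target_centroid``.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape:
        raise ValueError("mobile and target shapes differ")
    if check:
        _check_selection_rank(mobile)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on exact fits
        rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.as_matrix(), mc, tc


def fitted_rmsd(mobile: np.ndarray, target: np.ndarray,
                check: bool = False) -> float:
    """RMSD (nm) between two coordinate sets after optimal rigid-body fit."""
    R, mc, tc = kabsch_transform(mobile, target, check=check)
    moved = (mobile - mc) @ R.T + tc
    return float(np.sqrt(np.mean(np.sum((moved - target) ** 2, axis=1))))


def superpose_frames(ensemble: Ensemble, reference: np.ndarray | None = None,
                     selection="calpha") -> Ensemble:
    """Rigid-body fit every frame onto ``reference`` over ``selection``.

    ``reference`` defaults to the first frame.  The transform minimises the
    selection RMSD and is applied to all atoms, so intra-frame geometry is
    unchanged.  Idempotent: re-fitting an already fitted ensemble is a no-op
    up to numerical precision.
    """
    idx = resolve_selection(ensemble.topology, selection)
    if idx.size == 0:
        raise DegenerateFitError("selection matches no atoms")
    if reference is None:
        reference = ensemble.frames[0]
    reference = np.asarray(reference, float)
    if reference.shape[0] != ensemble.n_atoms:
        raise ValidationError(
            f"reference has {reference.shape[0]} atoms, ensemble has "
            f"{ensemble.n_atoms}"
        )
    _check_selection_rank(reference[idx])
    out = np.empty_like(ensemble.frames)
    for k in range(ensemble.n_frames):
        R, mc, tc = kabsch_transform(ensemble.frames[k][idx], reference[idx],
                                     check=False)
        out[k] = (ensemble.frames[k] - mc) @ R.T + tc
    return ensemble.with_frames(out)
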