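"""Synthetic conformational ensembles, toy contact peptides and labeled
alignments with known ground truth.

These generators define controlled study conditions for every analysis stage:
Gaussian fluctuations with a prescribed low-rank covariance (flexibility and
PCA recovery), multi-basin mixtures with prescribed weights and separation
(ensemble-similarity endpoints), toy peptides with interactions planted at an
exact persistence (structure-network recovery), and labeled alignments with
planted adaptation-candidate columns (substitution classification recovery).

Every generator is a pure function of its spec and seed; draws use one named
:func:`numpy.random.default_rng` stream per call, never global state.
Generated objects can be written to standard multi-model PDB / FASTA so the
pipeline consumes them through the same readers as real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import (
    Atom,
    Ensemble,
    StructureModel,
    ValidationError,
)
from .seqadapt import LabeledAlignment

__all__ = [
    "HarmonicSpec",
    "BasinSpec",
    "make_calpha_chain",
    "make_basin_references",
    "gen_harmonic_ensemble",
    "gen_basin_mixture",
    "basin_assignments",
    "gen_contact_peptide",
    "gen_labeled_alignment",
]


def make_calpha_chain(n_residues: int, spacing: float = 0.38,
                      wobble: float = 0.1) -> StructureModel:
    """A toy C-alpha-only chain laid out on a gentle 3D curve (non-collinear,
    so it can serve as a superposition reference)."""
    atoms = []
    residues = []
    numbering = {}
    for i in range(n_residues):
        residues.append((i, "ALA", "A"))
        numbering[i] = str(i + 1)
        coords = (spacing * i, wobble * np.sin(0.9 * i), wobble * np.cos(0.9 * i))
        atoms.append(Atom(
            name="CA", element="C", residue_index=i, residue_name="ALA",
            chain_id="A", coords=coords, is_backbone=True, is_hydrogen=False,
        ))
    return StructureModel(atoms=atoms, residues=residues, numbering_map=numbering)


# ---------------------------------------------------------------------------
# Harmonic (Gaussian) ensembles
# ---------------------------------------------------------------------------

@dataclass
class HarmonicSpec:
    """Gaussian fluctuations about a reference along orthonormal modes.

    Frame k is ``reference + sum_m a_m z_km v_m + isotropic noise`` with
    ``z ~ N(0,1)``; the expected per-residue RMSF follows in closed form from
    the amplitudes, mode shapes and ``isotropic_sigma``.
    """

    reference: StructureModel
    mode_vectors: np.ndarray = field(default_factory=lambda: np.zeros((0, 0)))
    mode_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    isotropic_sigma: float = 0.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode_vectors = np.atleast_2d(np.asarray(self.mode_vectors, float))
        self.mode_amplitudes = np.atleast_1d(np.asarray(self.mode_amplitudes, float))
        n3 = 3 * self.reference.n_atoms
        if self.mode_vectors.size == 0:
            self.mode_vectors = np.zeros((0, n3))
        if self.mode_vectors.shape[0] != self.mode_amplitudes.shape[0]:
            raise ValidationError("one amplitude per mode vector required")
        if self.mode_vectors.shape[0] and self.mode_vectors.shape[1] != n3:
            raise ValidationError(f"mode vectors must have length 3N = {n3}")
        if np.any(self.mode_amplitudes < 0):
            raise ValidationError("mode amplitudes must be >= 0")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if self.mode_vectors.shape[0]:
            gram = self.mode_vectors @ self.mode_vectors.T
            if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
                raise ValidationError("mode vectors must be mutually orthonormal")


def gen_harmonic_ensemble(spec: HarmonicSpec, frame_interval: float = 0.02,
                          replicate_id: str = "r1",
                          system_id: str = "harmonic") -> Ensemble:
    """Draw an ensemble from a :class:`HarmonicSpec` (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.reference.n_atoms
    ref = spec.reference.coords.reshape(-1)
    n_modes = spec.mode_vectors.shape[0]
    frames = np.tile(ref, (spec.n_frames, 1))
    if n_modes:
        z = rng.standard_normal((spec.n_frames, n_modes))
        frames += (z * spec.mode_amplitudes) @ spec.mode_vectors
    if spec.isotropic_sigma > 0:
        frames += rng.normal(0.0, spec.isotropic_sigma, size=frames.shape)
    return Ensemble(
        topology=spec.reference,
        frames=frames.reshape(spec.n_frames, n_atoms, 3),
        frame_interval=frame_interval,
        replicate_id=replicate_id,
        system_id=system_id,
    )


# ---------------------------------------------------------------------------
# Multi-basin mixtures
# ---------------------------------------------------------------------------

def make_basin_references(n_basins: int, n_residues: int, separation: float,
                          seed: int = 0) -> list[StructureModel]:
    """Basin reference structures that differ in *internal* geometry.

    Each basin after the first is the base chain plus an isotropic random
    displacement rescaled so the superposition-invariant (fitted) RMSD to
    the base equals ``separation`` — a rigid-body translation would be
    removed by the least-squares fitting every similarity stage performs,
    so separation must live in the shape."""
    from .core import fitted_rmsd

    base = make_calpha_chain(n_residues)
    refs = [base]
    rng = np.random.default_rng(seed)
    for b in range(1, n_basins):
        for _attempt in range(20):
            disp = rng.normal(0.0, 1.0, size=(n_residues, 3))
            coords = base.coords + disp
            d = fitted_rmsd(coords, base.coords)
            coords = base.coords + disp * (separation / d)
            if all(fitted_rmsd(coords, r.coords) >= 0.8 * separation
                   for r in refs):
                break
        atoms = [
            replace(a, coords=(float(c[0]), float(c[1]), float(c[2])))
            for a, c in zip(base.atoms, coords)
        ]
        refs.append(StructureModel(atoms=atoms, residues=list(base.residues),
                                   numbering_map=dict(base.numbering_map)))
    return refs


def _direct_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


@dataclass
class BasinSpec:
    """Mixture of well-separated conformational basins with per-ensemble
    mixture weights; emulates ensembles with controlled overlap, from
    identical (expected divergence 0) to non-overlapping (ln 2)."""

    basin_references: list
    weights_per_ensemble: list
    intra_basin_sigma: float = 0.05
    min_separation: float = 1.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        refs = self.basin_references
        if len(refs) < 1:
            raise ValidationError("at least one basin reference required")
        n_atoms = refs[0].n_atoms
        for r in refs[1:]:
            if r.n_atoms != n_atoms:
                raise ValidationError("basin references must share topology")
        from .core import fitted_rmsd

        for i in range(len(refs)):
            for j in range(i + 1, len(refs)):
                # fitted RMSD: separation must survive rigid-body fitting
                d = fitted_rmsd(refs[i].coords, refs[j].coords)
                if d < self.min_separation:
                    raise ValidationError(
                        f"basins {i} and {j} are separated by RMSD {d:.3f} nm, "
                        f"below min_separation {self.min_separation} nm"
                    )
        self.weights_per_ensemble = [
            np.asarray(w, float) for w in self.weights_per_ensemble
        ]
        for w in self.weights_per_ensemble:
            if w.shape != (len(refs),):
                raise ValidationError("one weight per basin required")
            if np.any(w < 0):
                raise ValidationError("weights must be >= 0")
            if abs(float(w.sum()) - 1.0) > 1e-9:
                raise ValidationError("weights must sum to 1 within 1e-9")
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")


def gen_basin_mixture(spec: BasinSpec, ensemble_index: int,
                      frame_interval: float = 0.02,
                      system_id: str = "basins") -> Ensemble:
    """Draw ensemble ``ensemble_index`` of a :class:`BasinSpec`: each frame
    picks a basin with that ensemble's weights, then adds isotropic
    intra-basin jitter."""
    if ensemble_index >= len(spec.weights_per_ensemble):
        raise ValidationError(
            f"ensemble_index {ensemble_index} out of range "
            f"({len(spec.weights_per_ensemble)} weight vectors)"
        )
    rng = np.random.default_rng([spec.seed, ensemble_index])
    weights = spec.weights_per_ensemble[ensemble_index]
    ref_coords = np.stack([r.coords for r in spec.basin_references])
    choice = rng.choice(len(spec.basin_references), size=spec.n_frames, p=weights)
    frames = ref_coords[choice]
    if spec.intra_basin_sigma > 0:
        frames = frames + rng.normal(0.0, spec.intra_basin_sigma, frames.shape)
    return Ensemble(
        topology=spec.basin_references[0],
        frames=frames,
        frame_interval=frame_interval,
        replicate_id=f"e{ensemble_index}",
        system_id=system_id,
    )


def basin_assignments(ensemble: Ensemble, spec: BasinSpec) -> np.ndarray:
    """Assign each frame to its nearest basin reference (direct RMSD)."""
    refs = np.stack([r.coords for r in spec.basin_references])
    d2 = ((ensemble.frames[:, None, :, :] - refs[None]) ** 2).sum(axis=(2, 3))
    return np.argmin(d2, axis=1)


# ---------------------------------------------------------------------------
# Contact peptides with exact planted persistence
# ---------------------------------------------------------------------------

def _backbone(residue_ordinal: int, resname: str, with_h: bool) -> list[Atom]:
    x = 0.5 * residue_ordinal
    z = 0.05 * (residue_ordinal % 2)
    atoms = [
        Atom("N", "N", residue_ordinal, resname, "A", (x, 0.0, z), True, False),
        Atom("CA", "C", residue_ordinal, resname, "A", (x + 0.15, 0.05, 0.0), True, False),
        Atom("C", "C", residue_ordinal, resname, "A", (x + 0.30, 0.0, 0.0), True, False),
        Atom("O", "O", residue_ordinal, resname, "A", (x + 0.30, -0.12, 0.0), True, False),
    ]
    if with_h:
        atoms.insert(1, Atom("H", "H", residue_ordinal, resname, "A",
                             (x, 0.1, z), False, True))
    return atoms


def _sidechain_atoms(contact_type: str, ordinal: int, center: np.ndarray) -> list[Atom]:
    c = np.asarray(center, float)

    def at(name, el, off):
        p = c + np.asarray(off)
        return Atom(name, el, ordinal, RESNAMES[contact_type][0 if ordinal == 0 else 1],
                    "A", (float(p[0]), float(p[1]), float(p[2])), False, el == "H")

    if contact_type == "hydrophobic":
        # four equal-mass carbons symmetric about the center: COM == center
        return [at("CB", "C", (0.04, 0, 0)), at("CG", "C", (-0.04, 0, 0)),
                at("CD1", "C", (0, 0.04, 0)), at("CD2", "C", (0, -0.04, 0))]
    if contact_type == "saltbridge":
        if ordinal == 0:      # LYS ammonium: single-atom charged group
            return [at("NZ", "N", (0, 0, 0))]
        # GLU carboxylate; offsets chosen so the mass-weighted COM == center
        a = 0.05
        b = -a * 12.011 / (2 * 15.999)
        return [at("CD", "C", (a, 0, 0)), at("OE1", "O", (b, 0.04, 0)),
                at("OE2", "O", (b, -0.04, 0))]
    if contact_type == "hbond":
        if ordinal == 0:      # SER hydroxyl donor with explicit hydrogen
            return [at("OG", "O", (0, 0, 0)), at("HG", "H", (0.10, 0, 0))]
        # GLU acceptor group; OE1 is the atom that satisfies the criterion
        return [at("OE1", "O", (0, 0, 0)), at("OE2", "O", (0.06, 0.10, 0)),
                at("CD", "C", (0.06, -0.10, 0))]
    raise ValidationError(f"unknown contact_type {contact_type!r}")


RESNAMES = {
    "hydrophobic": ("LEU", "LEU"),
    "saltbridge": ("LYS", "GLU"),
    "hbond": ("SER", "GLU"),
}

#: in-criterion / out-of-criterion separations of the partner group (nm)
_ON_OFF = {
    "hydrophobic": (0.60, 0.95),   # COM cutoff 0.65
    "saltbridge": (0.40, 0.85),    # group-COM cutoff 0.45
    "hbond": (0.30, 0.80),         # donor-acceptor cutoff 0.35
}


def gen_contact_peptide(contact_type: str, persistence_target: float,
                        n_frames: int, seed: int = 0,
                        frame_interval: float = 0.02,
                        jitter: float = 0.0005) -> Ensemble:
    """A four-residue toy peptide in which the named interaction's geometric
    criterion holds in exactly ``round(persistence_target * n_frames)`` frames.

    Residues 0 and 3 carry the interacting groups (sequence separation 3, so
    the nearest-neighbour exclusion never interferes); in the remaining
    frames the partner group of residue 3 is displaced beyond the cutoff.
    The first frames are the satisfying ones; a sub-angstrom jitter keeps the
    frames distinct without ever crossing a cutoff.
    """
    if contact_type not in RESNAMES:
        raise ValidationError(
            f"unknown contact_type {contact_type!r}; expected one of "
            f"{sorted(RESNAMES)}"
        )
    if not 0.0 <= persistence_target <= 1.0:
        raise ValidationError("persistence_target must be in [0, 1]")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")

    with_h = contact_type == "hbond"
    resname_a, resname_b = RESNAMES[contact_type]
    names = [resname_a, "GLY", "GLY", resname_b]
    atoms: list[Atom] = []
    residues = []
    numbering = {}
    anchor = np.array([0.2, 0.6, 0.0])
    d_on, d_off = _ON_OFF[contact_type]
    partner_on = anchor + np.array([d_on, 0.0, 0.0])
    partner_atom_names: list[str] = []
    for i, rn in enumerate(names):
        residues.append((i, rn, "A"))
        numbering[i] = str(i + 1)
        atoms.extend(_backbone(i, rn, with_h))
        if i == 0:
            atoms.extend(_sidechain_atoms(contact_type, 0, anchor))
        elif i == 3:
            side = _sidechain_atoms(contact_type, 3, partner_on)
            partner_atom_names = [a.name for a in side]
            atoms.extend(side)
    topology = StructureModel(atoms=atoms, residues=residues, numbering_map=numbering)

    base = topology.coords
    partner_idx = np.asarray([
        k for k, a in enumerate(topology.atoms)
        if a.residue_index == 3 and a.name in partner_atom_names
    ])
    n_on = int(round(persistence_target * n_frames))
    rng = np.random.default_rng(seed)
    frames = np.tile(base, (n_frames, 1, 1))
    frames[n_on:, partner_idx, 0] += d_off - d_on
    if jitter > 0:
        frames += rng.normal(0.0, jitter, frames.shape)
    return Ensemble(
        topology=topology, frames=frames, frame_interval=frame_interval,
        replicate_id="r1", system_id=f"contact-{contact_type}",
    )


# ---------------------------------------------------------------------------
# Labeled alignments with planted candidate/drift columns
# ---------------------------------------------------------------------------

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


def gen_labeled_alignment(n_psychro: int, n_meso: int, length: int,
                          planted_candidate_columns=(),
                          planted_drift_columns=(),
                          seed: int = 0) -> LabeledAlignment:
    """A temperature-labeled alignment with planted ground truth.

    Candidate columns fix one residue across the whole cold
    (psychrophilic + psychrotolerant) group and a different residue across
    the whole mesophilic group.  Drift columns make the two target sequences
    differ while the mesophilic group is internally heterogeneous.  All other
    columns are identical across every sequence.  The first cold and first
    mesophilic sequences are the designated comparison targets.
    """
    cand = sorted(int(c) for c in planted_candidate_columns)
    drift = sorted(int(c) for c in planted_drift_columns)
    if set(cand) & set(drift):
        raise ValidationError("planted candidate and drift column sets overlap")
    for c in cand + drift:
        if not 0 <= c < length:
            raise ValidationError(f"planted column {c} outside alignment length")
    if n_psychro < 1 or n_meso < 1:
        raise ValidationError("need at least one sequence per group")

    rng = np.random.default_rng(seed)
    background = rng.choice(list(_ALPHABET), size=length)
    cols = np.tile(background, (n_psychro + n_meso, 1))
    cold_rows = np.arange(n_psychro)
    meso_rows = np.arange(n_psychro, n_psychro + n_meso)

    for c in cand:
        cold_res, meso_res = rng.choice(list(_ALPHABET), size=2, replace=False)
        cols[cold_rows, c] = cold_res
        cols[meso_rows, c] = meso_res
    for c in drift:
        picks = rng.choice(list(_ALPHABET), size=3, replace=False)
        cold_res, meso_res_1, meso_res_2 = picks
        cols[cold_rows, c] = cold_res
        # alternate two residues in the mesophilic group -> heterogeneous
        for j, row in enumerate(meso_rows):
            cols[row, c] = meso_res_1 if j % 2 == 0 else meso_res_2

    sequences = ["".join(row) for row in cols]
    ids = [f"psy_{i + 1}" for i in range(n_psychro)] + \
          [f"mes_{i + 1}" for i in range(n_meso)]
    labels = {}
    for i in range(n_psychro):
        # flag the last cold sequence as psychrotolerant when the group has >2
        if n_psychro > 2 and i == n_psychro - 1:
            labels[ids[i]] = "psychrotolerant"
        else:
            labels[ids[i]] = "psychrophilic"
    for i in range(n_meso):
        labels[ids[n_psychro + i]] = "mesophilic"
    return LabeledAlignment(
        sequences=sequences, ids=ids, labels=labels,
        target_a=ids[0], target_b=ids[n_psychro],
    )
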