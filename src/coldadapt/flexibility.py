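"""Time-series structural descriptors and windowed, replicate-averaged
per-residue fluctuation (RMSF) profiles.

The flexibility comparison follows the standard protocol for replicated MD
analysis: per-frame fitted RMSD and radius of gyration as stability checks,
Cα RMSF over non-overlapping time windows (default 10 ns, first 10 ns
excluded) averaged within each trajectory and then across replicates, and
the trace of the Cα coordinate covariance matrix as a scalar overall
flexibility metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    Ensemble,
    StructureModel,
    ValidationError,
    fitted_rmsd,
    kabsch_transform,
    resolve_selection,
)

__all__ = [
    "TimeSeries",
    "FlexibilityProfile",
    "ProfileDifference",
    "rmsd_series",
    "radius_of_gyration_series",
    "distance_monitor",
    "windowed_rmsf",
    "average_profiles",
    "rmsf_difference",
    "covariance_trace",
]


@dataclass
class TimeSeries:
    """A labelled scalar series over trajectory time (ns)."""

    times: np.ndarray
    values: np.ndarray
    label: str
    replicate_id: str = ""
    system_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValidationError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, self.label: self.values})


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF mean ± spread with window/replicate provenance."""

    residue_labels: list[str]
    rmsf_mean: np.ndarray
    rmsf_sd: np.ndarray
    window_ns: float
    n_windows: int
    n_replicates: int = 1
    system_id: str = ""

    def __post_init__(self) -> None:
        self.rmsf_mean = np.asarray(self.rmsf_mean, float)
        self.rmsf_sd = np.asarray(self.rmsf_sd, float)
        n = len(self.residue_labels)
        if self.rmsf_mean.shape != (n,) or self.rmsf_sd.shape != (n,):
            raise ValidationError("profile arrays must match residue labels")
        if np.any(self.rmsf_mean < 0) or np.any(self.rmsf_sd < 0):
            raise ValidationError("RMSF mean and sd must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "residue": self.residue_labels,
            "rmsf_nm": self.rmsf_mean,
            "sd_nm": self.rmsf_sd,
        })


def rmsd_series(ensemble: Ensemble, reference: np.ndarray | None = None,
                selection: str = "mainchain") -> TimeSeries:
    """Per-frame least-squares-fitted RMSD (nm) over the selection, against
    the starting structure by default."""
    idx = resolve_selection(ensemble.topology, selection)
    if idx.size == 0:
        raise ValidationError(f"selection {selection!r} matches no atoms")
    if reference is None:
        reference = ensemble.frames[0]
    ref_sel = np.asarray(reference, float)[idx]
    values = np.array([
        fitted_rmsd(ensemble.frames[k][idx], ref_sel)
        for k in range(ensemble.n_frames)
    ])
    return TimeSeries(ensemble.times, values, f"rmsd_{selection}_nm",
                      ensemble.replicate_id, ensemble.system_id)


def radius_of_gyration_series(ensemble: Ensemble) -> TimeSeries:
    """Mass-weighted radius of gyration (nm) per frame."""
    if ensemble.n_atoms < 1:
        raise ValidationError("ensemble has no atoms")
    masses = ensemble.topology.masses
    total = masses.sum()
    com = np.einsum("kij,i->kj", ensemble.frames, masses) / total
    d2 = np.sum((ensemble.frames - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt((d2 * masses).sum(axis=1) / total)
    return TimeSeries(ensemble.times, rg, "rg_nm",
                      ensemble.replicate_id, ensemble.system_id)


def _select_single(topology: StructureModel, selector) -> int:
    """Resolve an atom selector to exactly one atom index.

    Selectors: an integer atom index, or a string ``"NAME"`` /
    ``"RESLABEL/NAME"`` (residue label per the numbering map).
    """
    if isinstance(selector, (int, np.integer)):
        return int(selector)
    sel = str(selector)
    if "/" in sel:
        res_label, name = sel.split("/", 1)
    else:
        res_label, name = None, sel
    matches = []
    for i, atom in enumerate(topology.atoms):
        if atom.name != name:
            continue
        if res_label is not None:
            ordinal = topology.residue_ordinal_of_atom(i)
            if topology.residue_label(ordinal) != res_label:
                continue
        matches.append(i)
    if len(matches) != 1:
        desc = [
            f"{topology.atoms[i].residue_name}"
            f"{topology.residue_label(topology.residue_ordinal_of_atom(i))}/"
            f"{topology.atoms[i].name}" for i in matches
        ]
        raise ValidationError(
            f"selector {selector!r} matched {len(matches)} atoms: {desc}"
        )
    return matches[0]


def distance_monitor(ensemble: Ensemble, atom_a, atom_b) -> TimeSeries:
    """Euclidean distance (nm) between two uniquely selected atoms per frame,
    e.g. an ion and its coordinating residue atom."""
    ia = _select_single(ensemble.topology, atom_a)
    ib = _select_single(ensemble.topology, atom_b)
    d = np.linalg.norm(ensemble.frames[:, ia] - ensemble.frames[:, ib], axis=1)
    return TimeSeries(ensemble.times, d, f"dist_{atom_a}_{atom_b}_nm",
                      ensemble.replicate_id, ensemble.system_id)


def _window_rmsf(coords: np.ndarray) -> np.ndarray:
    """Per-atom RMSF of one window: fit frames to the window mean (one
    iteration), then fluctuate about the refitted mean."""
    mean = coords.mean(axis=0)
    fitted = np.empty_like(coords)
    for k in range(coords.shape[0]):
        R, mc, tc = kabsch_transform(coords[k], mean, check=False)
        fitted[k] = (coords[k] - mc) @ R.T + tc
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def windowed_rmsf(ensemble: Ensemble, window_ns: float = 10.0,
                  exclude_initial_ns: float = 10.0,
                  selection: str = "calpha") -> FlexibilityProfile:
    """Cα RMSF over non-overlapping time windows, averaged across windows.

    Each window's frames are fitted to that window's mean structure before
    computing fluctuations; the trailing partial window is discarded.
    ``rmsf_sd`` is the across-window standard deviation.  Defaults follow
    the 10 ns window / 10 ns equilibration-exclusion convention.
    """
    idx = resolve_selection(ensemble.topology, selection)
    if idx.size == 0:
        raise ValidationError(f"selection {selection!r} matches no atoms")
    frames_per_window = int(np.floor(window_ns / ensemble.frame_interval))
    n_skip = int(np.floor(exclude_initial_ns / ensemble.frame_interval))
    usable = ensemble.n_frames - n_skip
    if frames_per_window < 1 or usable < frames_per_window:
        needed = (n_skip + max(frames_per_window, 1)) * ensemble.frame_interval
        raise ValidationError(
            f"trajectory too short: {ensemble.n_frames * ensemble.frame_interval:g} ns "
            f"with {exclude_initial_ns:g} ns excluded leaves no complete "
            f"{window_ns:g} ns window (needs >= {needed:g} ns)"
        )
    n_windows = usable // frames_per_window
    sel = ensemble.frames[:, idx]
    per_window = np.empty((n_windows, idx.size))
    for w in range(n_windows):
        lo = n_skip + w * frames_per_window
        per_window[w] = _window_rmsf(sel[lo:lo + frames_per_window])
    labels = [
        ensemble.topology.residue_label(
            ensemble.topology.residue_ordinal_of_atom(i))
        for i in idx
    ]
    return FlexibilityProfile(
        residue_labels=labels,
        rmsf_mean=per_window.mean(axis=0),
        rmsf_sd=per_window.std(axis=0, ddof=1) if n_windows > 1
        else np.zeros(idx.size),
        window_ns=window_ns,
        n_windows=int(n_windows),
        n_replicates=1,
        system_id=ensemble.system_id,
    )


def average_profiles(profiles: list[FlexibilityProfile]) -> FlexibilityProfile:
    """Average RMSF profiles across replicates; ``rmsf_sd`` becomes the
    across-replicate standard deviation (sample sd, the shaded-band
    convention)."""
    if not profiles:
        raise ValidationError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if p.residue_labels != first.residue_labels:
            diff = next(
                (a for a, b in zip(p.residue_labels, first.residue_labels) if a != b),
                "<length mismatch>")
            raise ValidationError(
                f"profiles disagree on residue labels (first difference: {diff})"
            )
    stack = np.stack([p.rmsf_mean for p in profiles])
    n = len(profiles)
    return FlexibilityProfile(
        residue_labels=list(first.residue_labels),
        rmsf_mean=stack.mean(axis=0),
        rmsf_sd=stack.std(axis=0, ddof=1) if n > 1 else np.zeros(stack.shape[1]),
        window_ns=first.window_ns,
        n_windows=first.n_windows,
        n_replicates=n,
        system_id=first.system_id,
    )


@dataclass
class ProfileDifference:
    """Per-residue RMSF difference a − b over a residue mapping; positions
    present in one profile but unmapped are reported as gaps, never
    dropped."""

    labels_a: list[str]
    labels_b: list[str]
    delta: np.ndarray               # NaN marks gap rows
    gaps_a: list[str]
    gaps_b: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame({
            "residue_a": self.labels_a, "residue_b": self.labels_b,
            "delta_nm": self.delta,
        })
        gap_rows = pd.DataFrame(
            [{"residue_a": g, "residue_b": "-", "delta_nm": np.nan}
             for g in self.gaps_a]
            + [{"residue_a": "-", "residue_b": g, "delta_nm": np.nan}
               for g in self.gaps_b])
        return pd.concat([rows, gap_rows], ignore_index=True)


def rmsf_difference(profile_a: FlexibilityProfile,
                    profile_b: FlexibilityProfile,
                    residue_map: dict[str, str] | None = None) -> ProfileDifference:
    """Difference a − b per mapped residue (identity mapping on labels by
    default).  Unmapped positions on either side — e.g. an insertion present
    in only one homolog — appear in the gap lists."""
    if residue_map is None:
        shared = set(profile_a.residue_labels) & set(profile_b.residue_labels)
        residue_map = {lab: lab for lab in profile_a.residue_labels
                       if lab in shared}
    if not residue_map:
        raise ValidationError("residue map is empty")
    index_b = {lab: i for i, lab in enumerate(profile_b.residue_labels)}
    labels_a, labels_b, delta = [], [], []
    gaps_a = []
    mapped_b: set[str] = set()
    for i, lab in enumerate(profile_a.residue_labels):
        target = residue_map.get(lab)
        if target is None or target not in index_b:
            gaps_a.append(lab)
            continue
        labels_a.append(lab)
        labels_b.append(target)
        mapped_b.add(target)
        delta.append(profile_a.rmsf_mean[i] - profile_b.rmsf_mean[index_b[target]])
    gaps_b = [lab for lab in profile_b.residue_labels if lab not in mapped_b]
    return ProfileDifference(labels_a, labels_b, np.asarray(delta),
                             gaps_a, gaps_b)


def covariance_trace(ensemble: Ensemble, selection: str = "calpha") -> float:
    """Trace of the 3N×3N coordinate covariance matrix (nm²) over the
    selection — a basis-invariant scalar equal to the sum of the PCA
    eigenvalues.  Frames are expected to be superposed on a common
    reference beforehand."""
    idx = resolve_selection(ensemble.topology, selection)
    if idx.size == 0:
        raise ValidationError(f"selection {selection!r} matches no atoms")
    if ensemble.n_frames < 2:
        raise ValidationError("covariance undefined for a single frame")
    X = ensemble.frames[:, idx].reshape(ensemble.n_frames, -1)
    return float(np.sum(X.var(axis=0, ddof=1)))
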