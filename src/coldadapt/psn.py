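"""Persistence-weighted protein structure networks (PSN) from conformational
ensembles.

Residues are nodes; noncovalent interactions are typed edges (hydrophobic,
hydrogen bond, salt bridge) detected per frame from geometric criteria:

* hydrophobic — side-chain heavy-atom center-of-mass distance < 0.65 nm
  between residues of the hydrophobic set;
* hydrogen bond — donor–acceptor distance ≤ 0.35 nm and
  donor–hydrogen–acceptor angle > 120°;
* salt bridge — center-of-mass distance between oppositely charged groups
  < 0.45 nm.

An edge's weight is its *persistence*: the fraction of frames in which the
criterion holds.  Hubs are nodes connected by more than four edges
(degree ≥ 5); clusters are connected components; two systems are compared by
partitioning their mapped edges into shared / only-in-a / only-in-b.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core import Ensemble, StructureModel, ValidationError

__all__ = [
    "InteractionEdge",
    "PSNGraph",
    "NetworkDiff",
    "detect_frame_interactions",
    "build_psn",
    "find_hubs",
    "find_clusters",
    "diff_networks",
    "HYDROPHOBIC_RESIDUES",
]

EDGE_CLASSES = ("hydrophobic", "hbond", "saltbridge")

#: conventional hydrophobic set for residue-COM contacts (configurable)
HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"}

#: charged side-chain groups: residue -> (atom names, sign); HIS excluded by
#: default because its protonation state is not known from coordinates
CHARGED_GROUPS = {
    "ASP": (("CG", "OD1", "OD2"), -1),
    "GLU": (("CD", "OE1", "OE2"), -1),
    "LYS": (("NZ",), +1),
    "ARG": (("CZ", "NH1", "NH2", "NE"), +1),
}

#: hydrogen-bond donor heavy atoms and the hydrogen names that may sit on
#: them; the backbone amide N applies to every residue
SIDECHAIN_DONORS = {
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {"NE": ("HE",), "NH1": ("HH11", "HH12"), "NH2": ("HH21", "HH22")},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "TRP": {"NE1": ("HE1",)},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
}
BACKBONE_DONOR = {"N": ("H", "HN", "H1", "H2", "H3")}

SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}
BACKBONE_ACCEPTOR = ("O", "OXT")

#: distance cutoffs in nm; "below"/"lower than" are strict (<), the H-bond
#: donor-acceptor distance is inclusive (≤)
DEFAULT_CUTOFFS = {"hydrophobic": 0.65, "hbond": 0.35, "saltbridge": 0.45}
HBOND_MIN_ANGLE_DEG = 120.0


@dataclass(frozen=True)
class InteractionEdge:
    residue_a: str
    residue_b: str
    edge_class: str
    persistence: float
    subtype: str | None = None      # hbond: mm | ms | ss

    def __post_init__(self) -> None:
        if self.residue_a == self.residue_b:
            raise ValidationError("self-edges are not allowed")
        if not 0.0 <= self.persistence <= 1.0:
            raise ValidationError("persistence must be in [0, 1]")

    @property
    def pair(self) -> frozenset:
        return frozenset((self.residue_a, self.residue_b))


@dataclass
class PSNGraph:
    nodes: list[str]
    edges: list[InteractionEdge]
    edge_class: str
    persistence_threshold: float
    system_id: str = ""

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for e in self.edges:
            if e.residue_a not in nodeset or e.residue_b not in nodeset:
                raise ValidationError(f"edge endpoint not among nodes: {e}")
            if e.persistence < self.persistence_threshold:
                raise ValidationError(
                    "edge persistence below the graph threshold")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.residue_a, e.residue_b, weight=e.persistence,
                       edge_class=e.edge_class, subtype=e.subtype or "")
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))

    def edges_to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "residue_a": e.residue_a, "residue_b": e.residue_b,
            "class": e.edge_class, "persistence": e.persistence,
            "subtype": e.subtype or "",
        } for e in self.edges])


# ---------------------------------------------------------------------------
# Per-frame detection
# ---------------------------------------------------------------------------

def _group_com(frame: np.ndarray, indices: list[int], masses: np.ndarray) -> np.ndarray:
    m = masses[indices]
    return (frame[indices] * m[:, None]).sum(axis=0) / m.sum()


class _Topology:
    """Precomputed per-residue atom tables reused across frames."""

    def __init__(self, topology: StructureModel, edge_class: str,
                 hydrophobic_set, hydrophobic_com: str,
                 infer_hydrogens: bool):
        if edge_class not in EDGE_CLASSES:
            raise ValidationError(
                f"unknown edge class {edge_class!r}; expected one of {EDGE_CLASSES}")
        self.topology = topology
        self.masses = topology.masses
        self.edge_class = edge_class
        by_res: dict[int, dict[str, int]] = {}
        for i, atom in enumerate(topology.atoms):
            ordinal = topology.residue_ordinal_of_atom(i)
            by_res.setdefault(ordinal, {})[atom.name] = i
        self.by_res = by_res
        self.chains = {k: topology.residues[k][2]
                       for k in range(topology.n_residues)}
        self.resnames = {k: topology.residues[k][1]
                         for k in range(topology.n_residues)}

        if edge_class == "hydrophobic":
            self.com_groups = {}
            for k, atoms in by_res.items():
                if self.resnames[k] not in hydrophobic_set:
                    continue
                if hydrophobic_com == "sidechain":
                    idx = [i for name, i in atoms.items()
                           if name not in ("N", "CA", "C", "O", "OXT")
                           and not topology.atoms[i].is_hydrogen]
                else:
                    idx = [i for i in atoms.values()
                           if not topology.atoms[i].is_hydrogen]
                if idx:
                    self.com_groups[k] = idx
        elif edge_class == "saltbridge":
            self.charge_groups = []
            for k, atoms in by_res.items():
                spec = CHARGED_GROUPS.get(self.resnames[k])
                if spec is None:
                    continue
                names, sign = spec
                idx = [atoms[nm] for nm in names if nm in atoms]
                if idx:
                    self.charge_groups.append((k, idx, sign))
        else:
            has_h = any(a.is_hydrogen for a in topology.atoms)
            if not has_h and not infer_hydrogens:
                raise ValidationError(
                    "hydrogen-bond detection needs explicit hydrogens; none "
                    "found — pass infer_hydrogens=True to place backbone "
                    "amide hydrogens geometrically"
                )
            self.infer = infer_hydrogens and not has_h
            if self.infer:
                warnings.warn("hydrogen positions inferred geometrically for "
                              "backbone amide donors")
            self.donors = []            # (ordinal, donor_idx, [h_idx] | 'infer')
            self.acceptors = []         # (ordinal, idx, is_backbone)
            sorted_res = sorted(by_res)
            for k in sorted_res:
                atoms = by_res[k]
                rn = self.resnames[k]
                for dname, hnames in BACKBONE_DONOR.items():
                    if dname in atoms and rn != "PRO":
                        hs = [atoms[h] for h in hnames if h in atoms]
                        if hs:
                            self.donors.append((k, atoms[dname], hs, True))
                        elif self.infer:
                            self.donors.append((k, atoms[dname], "infer", True))
                for dname, hnames in SIDECHAIN_DONORS.get(rn, {}).items():
                    if dname in atoms:
                        hs = [atoms[h] for h in hnames if h in atoms]
                        if hs:
                            self.donors.append((k, atoms[dname], hs, False))
                for aname in BACKBONE_ACCEPTOR:
                    if aname in atoms:
                        self.acceptors.append((k, atoms[aname], True))
                for aname in SIDECHAIN_ACCEPTORS.get(rn, ()):
                    if aname in atoms:
                        self.acceptors.append((k, atoms[aname], False))

    def infer_backbone_h(self, frame: np.ndarray, ordinal: int,
                         n_idx: int) -> np.ndarray | None:
        """Place the amide hydrogen 0.1 nm from N along the direction
        opposite the bisector of N-CA and N-C(prev)."""
        atoms = self.by_res[ordinal]
        ca = atoms.get("CA")
        prev = self.by_res.get(ordinal - 1, {})
        c_prev = prev.get("C") if self.chains.get(ordinal - 1) == self.chains[ordinal] else None
        n = frame[n_idx]
        dirs = []
        if ca is not None:
            dirs.append(n - frame[ca])
        if c_prev is not None:
            dirs.append(n - frame[c_prev])
        if not dirs:
            return None
        v = np.sum([d / np.linalg.norm(d) for d in dirs], axis=0)
        norm = np.linalg.norm(v)
        if norm < 1e-9:
            return None
        return n + 0.1 * v / norm


def _adjacent(tab: _Topology, i: int, j: int, min_sep: int) -> bool:
    return tab.chains[i] == tab.chains[j] and abs(i - j) < min_sep


def _frame_pairs(frame: np.ndarray, tab: _Topology,
                 cutoffs: dict, min_sequence_separation: int
                 ) -> tuple[set, dict]:
    """One frame's interacting residue-ordinal pairs (i < j) and, for
    hydrogen bonds, the subtype seen for each pair."""
    cls = tab.edge_class
    pairs: set[tuple[int, int]] = set()
    subtypes: dict[tuple[int, int], str] = {}
    if cls == "hydrophobic":
        cutoff = cutoffs["hydrophobic"]
        keys = sorted(tab.com_groups)
        coms = {k: _group_com(frame, tab.com_groups[k], tab.masses) for k in keys}
        for i, j in itertools.combinations(keys, 2):
            if _adjacent(tab, i, j, min_sequence_separation):
                continue
            if np.linalg.norm(coms[i] - coms[j]) < cutoff:
                pairs.add((i, j))
    elif cls == "saltbridge":
        cutoff = cutoffs["saltbridge"]
        groups = [(k, _group_com(frame, idx, tab.masses), sign)
                  for k, idx, sign in tab.charge_groups]
        for (i, ci, si), (j, cj, sj) in itertools.combinations(groups, 2):
            if i == j or si == sj:
                continue
            if _adjacent(tab, i, j, min_sequence_separation):
                continue
            if np.linalg.norm(ci - cj) < cutoff:
                pairs.add((min(i, j), max(i, j)))
    else:
        cutoff = cutoffs["hbond"]
        cos_max = np.cos(np.deg2rad(HBOND_MIN_ANGLE_DEG))
        for (di, d_idx, hs, d_bb) in tab.donors:
            d_pos = frame[d_idx]
            if hs == "infer":
                h_positions = [tab.infer_backbone_h(frame, di, d_idx)]
                h_positions = [h for h in h_positions if h is not None]
            else:
                h_positions = [frame[h] for h in hs]
            if not h_positions:
                continue
            for (aj, a_idx, a_bb) in tab.acceptors:
                if aj == di or a_idx == d_idx:
                    continue
                if _adjacent(tab, di, aj, min_sequence_separation):
                    continue
                a_pos = frame[a_idx]
                if np.linalg.norm(d_pos - a_pos) > cutoff:
                    continue
                for h_pos in h_positions:
                    v1 = d_pos - h_pos
                    v2 = a_pos - h_pos
                    denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                    if denom < 1e-12:
                        continue
                    cos_angle = float(np.dot(v1, v2)) / denom
                    # angle > 120° <=> cos(angle) < cos(120°)
                    if cos_angle < cos_max:
                        key = (min(di, aj), max(di, aj))
                        pairs.add(key)
                        st = ("mainchain" if d_bb else "sidechain") + "-" + \
                             ("mainchain" if a_bb else "sidechain")
                        subtypes.setdefault(key, st)
                        break
    return pairs, subtypes


def detect_frame_interactions(frame: np.ndarray, topology: StructureModel,
                              edge_class: str,
                              cutoffs: dict | None = None,
                              min_sequence_separation: int = 2,
                              hydrophobic_set=HYDROPHOBIC_RESIDUES,
                              hydrophobic_com: str = "sidechain",
                              infer_hydrogens: bool = False) -> set:
    """Residue-ordinal pairs whose interaction criterion holds in one frame."""
    tab = _Topology(topology, edge_class, hydrophobic_set, hydrophobic_com,
                    infer_hydrogens)
    cut = dict(DEFAULT_CUTOFFS)
    cut.update(cutoffs or {})
    pairs, _subtypes = _frame_pairs(np.asarray(frame, float), tab, cut,
                                    min_sequence_separation)
    return pairs


# ---------------------------------------------------------------------------
# Network construction and analysis
# ---------------------------------------------------------------------------

def build_psn(ensemble: Ensemble, edge_class: str,
              persistence_threshold: float = 0.2,
              cutoffs: dict | None = None,
              min_sequence_separation: int = 2,
              hydrophobic_set=HYDROPHOBIC_RESIDUES,
              hydrophobic_com: str = "sidechain",
              infer_hydrogens: bool = False) -> PSNGraph:
    """Build a persistence-weighted network: an edge's persistence is the
    fraction of frames in which the geometric criterion holds; edges with
    persistence ≥ threshold are retained with the persistence as weight."""
    if not 0.0 <= persistence_threshold <= 1.0:
        raise ValidationError("persistence_threshold must be in [0, 1]")
    tab = _Topology(ensemble.topology, edge_class, hydrophobic_set,
                    hydrophobic_com, infer_hydrogens)
    cut = dict(DEFAULT_CUTOFFS)
    cut.update(cutoffs or {})
    counts: dict[tuple[int, int], int] = {}
    subtype_counts: dict[tuple[int, int], dict[str, int]] = {}
    for k in range(ensemble.n_frames):
        pairs, frame_subtypes = _frame_pairs(ensemble.frames[k], tab, cut,
                                             min_sequence_separation)
        for p in pairs:
            counts[p] = counts.get(p, 0) + 1
            if edge_class == "hbond":
                st = frame_subtypes.get(p)
                if st:
                    d = subtype_counts.setdefault(p, {})
                    d[st] = d.get(st, 0) + 1
    label = ensemble.topology.residue_label
    edges = []
    for (i, j), c in sorted(counts.items()):
        persistence = c / ensemble.n_frames
        if persistence < persistence_threshold:
            continue
        subtype = None
        if edge_class == "hbond" and (i, j) in subtype_counts:
            subtype = max(subtype_counts[(i, j)].items(), key=lambda kv: kv[1])[0]
        edges.append(InteractionEdge(label(i), label(j), edge_class,
                                     persistence, subtype))
    nodes = [label(k) for k in range(ensemble.topology.n_residues)]
    return PSNGraph(nodes=nodes, edges=edges, edge_class=edge_class,
                    persistence_threshold=persistence_threshold,
                    system_id=ensemble.system_id)


def find_hubs(graph: PSNGraph, min_degree: int = 5) -> list[tuple[str, int]]:
    """Residues connected by ``min_degree`` or more edges (default: more
    than four, the hub convention), sorted by degree descending then
    label."""
    degree: dict[str, int] = {}
    for e in graph.edges:
        degree[e.residue_a] = degree.get(e.residue_a, 0) + 1
        degree[e.residue_b] = degree.get(e.residue_b, 0) + 1
    hubs = [(r, d) for r, d in degree.items() if d >= min_degree]
    return sorted(hubs, key=lambda rd: (-rd[1], rd[0]))


def find_clusters(graph: PSNGraph, include_isolated: bool = True) -> list[list[str]]:
    """Connected components of the persistence-filtered graph, each as a
    sorted residue list, ordered by size descending (ties by first
    residue)."""
    g = graph.to_networkx()
    if not include_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: (-len(c), c[0] if c else ""))


@dataclass
class NetworkDiff:
    """Edge-level comparison of two same-class networks over a residue
    mapping.  ``shared`` pairs each common edge with both persistences;
    edges touching unmapped residues are reported, never dropped."""

    only_in_a: list[InteractionEdge]
    only_in_b: list[InteractionEdge]
    shared: list[tuple[InteractionEdge, InteractionEdge]]
    unmapped_a: list[InteractionEdge] = field(default_factory=list)
    unmapped_b: list[InteractionEdge] = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def diff_networks(graph_a: PSNGraph, graph_b: PSNGraph,
                  residue_map: dict[str, str] | None = None,
                  exclude_mainchain_hbonds: bool = False) -> NetworkDiff:
    """Partition the union of mapped edges into only-in-a / only-in-b /
    shared.  ``residue_map`` maps a-labels to b-labels (identity by
    default); hydrogen-bond edges can exclude the mainchain-mainchain
    subtype before counting, matching the usual polar+electrostatics
    bookkeeping."""
    if graph_a.edge_class != graph_b.edge_class:
        raise ValidationError(
            f"cannot diff networks of different classes "
            f"({graph_a.edge_class} vs {graph_b.edge_class})"
        )

    def keep(e: InteractionEdge) -> bool:
        return not (exclude_mainchain_hbonds and e.edge_class == "hbond"
                    and e.subtype == "mainchain-mainchain")

    edges_a = [e for e in graph_a.edges if keep(e)]
    edges_b = [e for e in graph_b.edges if keep(e)]
    if residue_map is None:
        residue_map = {n: n for n in graph_a.nodes}

    mapped_a: dict[frozenset, InteractionEdge] = {}
    unmapped_a = []
    for e in edges_a:
        if e.residue_a in residue_map and e.residue_b in residue_map:
            key = frozenset((residue_map[e.residue_a], residue_map[e.residue_b]))
            mapped_a[key] = e
        else:
            unmapped_a.append(e)
    mapped_b: dict[frozenset, InteractionEdge] = {}
    unmapped_b = []
    mapped_b_labels = set(residue_map.values())
    for e in edges_b:
        if e.residue_a in mapped_b_labels and e.residue_b in mapped_b_labels:
            mapped_b[e.pair] = e
        else:
            unmapped_b.append(e)

    shared_keys = set(mapped_a) & set(mapped_b)
    only_a = [mapped_a[k] for k in sorted(set(mapped_a) - shared_keys,
                                          key=sorted)]
    only_b = [mapped_b[k] for k in sorted(set(mapped_b) - shared_keys,
                                          key=sorted)]
    shared = [(mapped_a[k], mapped_b[k]) for k in sorted(shared_keys, key=sorted)]
    counts = {
        "class": graph_a.edge_class,
        "edges_a": len(edges_a), "edges_b": len(edges_b),
        "only_in_a": len(only_a), "only_in_b": len(only_b),
        "shared": len(shared),
        "unmapped_a": len(unmapped_a), "unmapped_b": len(unmapped_b),
    }
    return NetworkDiff(only_in_a=only_a, only_in_b=only_b, shared=shared,
                       unmapped_a=unmapped_a, unmapped_b=unmapped_b,
                       counts=counts)
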