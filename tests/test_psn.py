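"""Geometric interaction criteria, persistence networks, hubs, clusters
and network comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import coldadapt as ca
from coldadapt.core import Atom, Ensemble, StructureModel, ValidationError
from coldadapt.psn import InteractionEdge, PSNGraph, find_clusters, find_hubs


def make_topology(residue_atoms):
    """residue_atoms: list of (resname, [(atom_name, element, xyz), ...])."""
    atoms, residues, numbering = [], [], {}
    for k, (resname, atom_list) in enumerate(residue_atoms):
        residues.append((k, resname, "A"))
        numbering[k] = str(k + 1)
        for name, element, xyz in atom_list:
            atoms.append(Atom(name, element, k, resname, "A", tuple(xyz),
                              name in ("N", "CA", "C", "O"), element == "H"))
    return StructureModel(atoms=atoms, residues=residues,
                          numbering_map=numbering)


def leu_sidechain(center):
    c = np.asarray(center)
    return [("CB", "C", c + [0.04, 0, 0]), ("CG", "C", c + [-0.04, 0, 0]),
            ("CD1", "C", c + [0, 0.04, 0]), ("CD2", "C", c + [0, -0.04, 0])]


def backbone(x):
    return [("N", "N", [x, 0, 0]), ("CA", "C", [x + 0.15, 0.05, 0]),
            ("C", "C", [x + 0.3, 0, 0]), ("O", "O", [x + 0.3, -0.12, 0])]


def hydrophobic_pair_topology(com_distance):
    return make_topology([
        ("LEU", backbone(0.0) + leu_sidechain([0.2, 3.0, 0.0])),
        ("GLY", backbone(3.0)),
        ("GLY", backbone(6.0)),
        ("LEU", backbone(9.0) + leu_sidechain([0.2 + com_distance, 3.0, 0.0])),
    ])


def saltbridge_topology(com_distance):
    glu_off = -0.05 * 12.011 / (2 * 15.999)
    c = np.array([0.2 + com_distance, 3.0, 0.0])
    return make_topology([
        ("LYS", backbone(0.0) + [("NZ", "N", [0.2, 3.0, 0.0])]),
        ("GLY", backbone(3.0)),
        ("GLY", backbone(6.0)),
        ("GLU", backbone(9.0) + [("CD", "C", c + [0.05, 0, 0]),
                                 ("OE1", "O", c + [glu_off, 0.04, 0]),
                                 ("OE2", "O", c + [glu_off, -0.04, 0])]),
    ])


def hbond_topology(da_distance, angle_deg):
    """SER OG-HG donor, GLU OE1 acceptor, with the D-H-A angle planted."""
    d = np.array([0.2, 3.0, 0.0])
    h = d + [0.1, 0.0, 0.0]
    theta = np.deg2rad(180.0 - angle_deg)
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # choose |H->A| so that |D-A| equals da_distance
    lo, hi = 0.0, 5.0
    for _ in range(60):
        r = 0.5 * (lo + hi)
        if np.linalg.norm(h + r * direction - d) < da_distance:
            lo = r
        else:
            hi = r
    a = h + 0.5 * (lo + hi) * direction
    return make_topology([
        ("SER", backbone(0.0) + [("OG", "O", d), ("HG", "H", h)]),
        ("GLY", backbone(3.0)),
        ("GLY", backbone(6.0)),
        ("GLU", backbone(9.0) + [("OE1", "O", a)]),
    ])


def detect(topology, edge_class, **kw):
    return ca.detect_frame_interactions(topology.coords, topology,
                                        edge_class, **kw)


class TestGeometricCriteria:
    def test_hydrophobic_cutoff_is_strict_065(self):
        assert (0, 3) in detect(hydrophobic_pair_topology(0.60), "hydrophobic")
        assert detect(hydrophobic_pair_topology(0.70), "hydrophobic") == set()

    def test_saltbridge_cutoff_is_strict_045(self):
        assert (0, 3) in detect(saltbridge_topology(0.40), "saltbridge")
        assert detect(saltbridge_topology(0.50), "saltbridge") == set()

    def test_hbond_requires_distance_and_angle(self):
        assert (0, 3) in detect(hbond_topology(0.34, 150.0), "hbond")
        assert detect(hbond_topology(0.34, 119.0), "hbond") == set()
        assert detect(hbond_topology(0.36, 150.0), "hbond") == set()

    def test_sequence_neighbours_excluded(self):
        top = make_topology([
            ("LEU", backbone(0.0) + leu_sidechain([0.2, 0.5, 0.0])),
            ("LEU", backbone(0.5) + leu_sidechain([0.5, 0.5, 0.0])),
        ])
        assert detect(top, "hydrophobic") == set()

    def test_hbond_without_hydrogens_instructs_inference_flag(self):
        top = hydrophobic_pair_topology(0.6)   # no H anywhere
        with pytest.raises(ValidationError, match="infer_hydrogens"):
            detect(top, "hbond")
        # with the flag, detection runs on inferred backbone amides
        detect(top, "hbond", infer_hydrogens=True)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError, match="edge class"):
            detect(hydrophobic_pair_topology(0.6), "cation-pi")


class TestBuildPsn:
    def test_planted_persistence_recovered_exactly(self):
        ens = ca.gen_contact_peptide("saltbridge", 0.35, 100, seed=0)
        g = ca.build_psn(ens, "saltbridge", persistence_threshold=0.2)
        assert len(g.edges) == 1
        assert g.edges[0].persistence == pytest.approx(0.35)
        # brute-force per-frame recount with the public single-frame API
        recount = sum(
            bool(ca.detect_frame_interactions(ens.frames[k], ens.topology,
                                              "saltbridge"))
            for k in range(ens.n_frames))
        assert recount == 35

    def test_threshold_drops_edge(self):
        ens = ca.gen_contact_peptide("saltbridge", 0.35, 100, seed=0)
        assert ca.build_psn(ens, "saltbridge", 0.5).edges == []

    def test_always_present_interaction_has_persistence_one(self):
        ens = ca.gen_contact_peptide("hbond", 1.0, 20, seed=1)
        g = ca.build_psn(ens, "hbond", 0.9)
        assert g.edges[0].persistence == 1.0
        assert g.edges[0].subtype == "sidechain-sidechain"

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_raising_threshold_never_adds_edges(self, p_target, thr):
        ens = ca.gen_contact_peptide("hydrophobic", round(p_target, 2), 20,
                                     seed=3)
        lo = {e.pair for e in ca.build_psn(ens, "hydrophobic", 0.0).edges}
        hi = {e.pair for e in ca.build_psn(ens, "hydrophobic",
                                           round(thr, 2)).edges}
        assert hi <= lo

    def test_invariant_under_global_rigid_motion(self):
        ens = ca.gen_contact_peptide("saltbridge", 0.6, 30, seed=5)
        R = Rotation.from_euler("zyx", [15, 75, 140], degrees=True).as_matrix()
        moved = Ensemble(ens.topology, ens.frames @ R.T + 4.0,
                         ens.frame_interval)
        g1 = ca.build_psn(ens, "saltbridge", 0.2)
        g2 = ca.build_psn(moved, "saltbridge", 0.2)
        assert [(e.pair, e.persistence) for e in g1.edges] == \
            [(e.pair, e.persistence) for e in g2.edges]

    def test_bad_threshold_rejected(self):
        ens = ca.gen_contact_peptide("hbond", 0.5, 10, seed=0)
        with pytest.raises(ValidationError):
            ca.build_psn(ens, "hbond", persistence_threshold=1.5)


def graph_from_pairs(pairs, nodes):
    edges = [InteractionEdge(a, b, "hydrophobic", 1.0) for a, b in pairs]
    return PSNGraph(nodes=list(nodes), edges=edges, edge_class="hydrophobic",
                    persistence_threshold=0.5)


class TestHubsAndClusters:
    def test_degree_five_is_hub_degree_four_is_not(self):
        spokes5 = [("H", f"s{i}") for i in range(5)]
        g = graph_from_pairs(spokes5, ["H"] + [f"s{i}" for i in range(5)])
        assert find_hubs(g) == [("H", 5)]
        spokes4 = spokes5[:4]
        g4 = graph_from_pairs(spokes4, ["H"] + [f"s{i}" for i in range(4)])
        assert find_hubs(g4) == []

    def test_min_degree_one_returns_every_connected_node(self):
        g = graph_from_pairs([("a", "b")], ["a", "b", "isolated"])
        assert {r for r, _d in find_hubs(g, min_degree=1)} == {"a", "b"}

    def test_empty_graph(self):
        g = graph_from_pairs([], [])
        assert find_hubs(g) == []
        assert find_clusters(g) == []

    def test_two_triangles(self):
        pairs = [("a", "b"), ("b", "c"), ("c", "a"),
                 ("x", "y"), ("y", "z"), ("z", "x")]
        g = graph_from_pairs(pairs, list("abcxyz"))
        comps = find_clusters(g)
        assert sorted(map(len, comps)) == [3, 3]

    def test_component_sizes_match_brute_force_reachability(self):
        nodes = list("abcdefg")
        pairs = [("a", "b"), ("b", "c"), ("c", "d"), ("e", "f")]
        g = graph_from_pairs(pairs, nodes)
        comps = find_clusters(g)
        assert [len(c) for c in comps] == [4, 2, 1]
        # brute-force transitive closure oracle
        adj = {n: set() for n in nodes}
        for a, b in pairs:
            adj[a].add(b)
            adj[b].add(a)

        def reach(start):
            seen, stack = {start}, [start]
            while stack:
                for m in adj[stack.pop()]:
                    if m not in seen:
                        seen.add(m)
                        stack.append(m)
            return seen

        expected = {frozenset(reach(n)) for n in nodes}
        assert {frozenset(c) for c in comps} == expected


class TestDiffNetworks:
    def test_identical_graphs_all_shared(self):
        g = graph_from_pairs([("1", "2"), ("2", "3")], ["1", "2", "3"])
        diff = ca.diff_networks(g, g)
        assert diff.only_in_a == [] and diff.only_in_b == []
        assert len(diff.shared) == 2

    def test_set_arithmetic(self):
        a = graph_from_pairs([("1", "2"), ("2", "3")], ["1", "2", "3", "4"])
        b = graph_from_pairs([("2", "3"), ("3", "4")], ["1", "2", "3", "4"])
        diff = ca.diff_networks(a, b)
        assert [(e.residue_a, e.residue_b) for e in diff.only_in_a] == [("1", "2")]
        assert [(e.residue_a, e.residue_b) for e in diff.only_in_b] == [("3", "4")]
        assert [(p[0].residue_a, p[0].residue_b) for p in diff.shared] == [("2", "3")]
        assert diff.counts["only_in_a"] == 1

    def test_unmapped_edges_reported_not_dropped(self):
        a = graph_from_pairs([("1", "2"), ("2", "52A")], ["1", "2", "52A"])
        b = graph_from_pairs([("1", "2")], ["1", "2"])
        residue_map = {"1": "1", "2": "2"}   # insertion 52A unmapped
        diff = ca.diff_networks(a, b, residue_map)
        assert len(diff.unmapped_a) == 1
        assert diff.unmapped_a[0].pair == frozenset({"2", "52A"})

    def test_class_mismatch_rejected(self):
        a = graph_from_pairs([], ["1"])
        b = PSNGraph(["1"], [], "hbond", 0.5)
        with pytest.raises(ValidationError, match="class"):
            ca.diff_networks(a, b)

    def test_backbone_hbond_exclusion(self):
        edges = [InteractionEdge("1", "3", "hbond", 0.9, "mainchain-mainchain"),
                 InteractionEdge("2", "4", "hbond", 0.8, "sidechain-sidechain")]
        g = PSNGraph(["1", "2", "3", "4"], edges, "hbond", 0.5)
        diff = ca.diff_networks(g, g, exclude_mainchain_hbonds=True)
        assert diff.counts["edges_a"] == 1
        assert diff.shared[0][0].subtype == "sidechain-sidechain"


class TestGraphOutput:
    def test_graphml_roundtrip(self, tmp_path):
        ens = ca.gen_contact_peptide("hydrophobic", 0.8, 10, seed=2)
        g = ca.build_psn(ens, "hydrophobic", 0.2)
        path = tmp_path / "g.graphml"
        g.write_graphml(path)
        import networkx as nx
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == len(g.nodes)
        (u, v, data), = back.edges(data=True)
        assert data["weight"] == pytest.approx(0.8)
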