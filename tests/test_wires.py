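"""Wire-graph construction, segment classification and the steric probe test,
checked against brute-force oracles."""

import numpy as np
import pytest

from qwire import oracles
from qwire.errors import ConfigurationError
from qwire.structure import MacromolecularModel, ResidueRef
from qwire.synthetic import BLOCKER_ELEMENT, WireFixtureSpec, make_wire_fixture, random_rotation
from qwire.wires import (
    PathwayDefinition,
    SegmentSpec,
    analyse_pathway,
    bridge_path_gaps,
    build_wire_graph,
    classify_gap,
    classify_segment,
    collect_wire_nodes,
    detect_hbonds,
    hydration_number,
    segment_connectivity,
)

from conftest import atom, model_of, water


# -- node collection -------------------------------------------------------


def test_collect_nodes_sidechains_and_waters():
    m = model_of(
        atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0)),
        atom(2, "CD1", "C", "LEU", "A", 2, (3, 0, 0)),
        water(3, 100, (6, 0, 0)),
        water(4, 101, (9, 0, 0)),
    )
    nodes = collect_wire_nodes(m)
    assert len(nodes) == 3
    assert sorted(n.kind for n in nodes) == ["sidechain", "water", "water"]


def test_histidine_contributes_two_nodes():
    m = model_of(
        atom(1, "ND1", "N", "HIS", "A", 1, (0, 0, 0)),
        atom(2, "NE2", "N", "HIS", "A", 1, (2, 0, 0)),
        atom(3, "CG", "C", "HIS", "A", 1, (1, 1, 0)),
    )
    assert len(collect_wire_nodes(m)) == 2


def test_seven_residue_types_give_ten_nodes():
    """ASP(2) + GLU(2) + HIS(2) + LYS + SER + THR + TYR = 10 wire atoms."""
    spec_atoms = [
        ("ASP", ["OD1", "OD2"]), ("GLU", ["OE1", "OE2"]), ("HIS", ["ND1", "NE2"]),
        ("LYS", ["NZ"]), ("SER", ["OG"]), ("THR", ["OG1"]), ("TYR", ["OH"]),
    ]
    atoms, serial = [], 0
    for i, (resname, names) in enumerate(spec_atoms):
        for name in names + ["CB"]:  # CB must not contribute
            serial += 1
            element = name[0]
            atoms.append(atom(serial, name, element, resname, "A", i + 1, (i * 10.0, 0, 0)))
    assert len(collect_wire_nodes(model_of(*atoms))) == 10


def test_ligand_polar_atoms_only_when_requested():
    m = model_of(
        atom(1, "O1", "O", "U10", "Q", 1, (0, 0, 0), hetero=True),
        atom(2, "C1", "C", "U10", "Q", 1, (1.4, 0, 0), hetero=True),
    )
    assert len(collect_wire_nodes(m)) == 0
    nodes = collect_wire_nodes(m, include_ligand_polar=True)
    assert [n.kind for n in nodes] == ["ligand"]


# -- graph build -----------------------------------------------------------


def _water_chain_model(xs):
    return model_of(*[water(i + 1, 100 + i, (x, 0, 0)) for i, x in enumerate(xs)])


def test_cutoff_boundary_inclusive():
    for d, n_edges in ((3.99, 1), (4.0, 1), (4.01, 0)):
        nodes = collect_wire_nodes(_water_chain_model([0.0, d]))
        g = build_wire_graph(nodes, 4.0)
        assert len(g.edges()) == n_edges, d


def test_water_chain_is_path_graph():
    nodes = collect_wire_nodes(_water_chain_model(np.arange(6) * 2.8))
    g = build_wire_graph(nodes)
    assert len(g.edges()) == 5


@pytest.mark.parametrize("seed", range(8))
def test_edges_equal_bruteforce_on_random_clouds(seed):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(0, 12, size=(50, 3))
    m = model_of(*[water(i + 1, 100 + i, p) for i, p in enumerate(pts)])
    nodes = collect_wire_nodes(m)
    g = build_wire_graph(nodes, 4.0)
    got = {(min(u, v), max(u, v)) for u, v, _ in g.edges()}
    assert got == oracles.brute_force_edges(nodes, 4.0)


# -- connectivity ----------------------------------------------------------


def _segment_model(gap_positions=(), blocker=None, n=6, spacing=2.8):
    """TYR anchor, water chain, GLU anchor along x; optional gaps/blocker."""
    xs = [0.0]
    for i in range(n):
        step = spacing
        if i in gap_positions:
            step = 5.5
        xs.append(xs[-1] + step)
    atoms = [atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0), subunit="S")]
    for i, x in enumerate(xs[1:-1]):
        atoms.append(water(2 + i, 100 + i, (x, 0, 0), subunit="S"))
    atoms.append(atom(len(atoms) + 1, "OE1", "O", "GLU", "A", 2, (xs[-1], 0, 0), subunit="S"))
    if blocker is not None:
        atoms.append(
            atom(len(atoms) + 1, "SE", BLOCKER_ELEMENT, "BLK", "A", 900, blocker, hetero=True,
                 subunit="S")
        )
    m = model_of(*atoms)
    spec = SegmentSpec(
        code="T",
        A=(ResidueRef("S", 1, "TYR"),),
        B=(ResidueRef("S", 2, "GLU"),),
    )
    return m, spec


def test_bridged_segment_connected_with_witness():
    m, spec = _segment_model(n=4)
    g = build_wire_graph(collect_wire_nodes(m))
    connected, witness = segment_connectivity(g, spec)
    assert connected
    assert witness[0].resname == "TYR" and witness[-1].resname == "GLU"
    # witness path steps all within cutoff
    for a, b in zip(witness, witness[1:]):
        assert np.linalg.norm(a.position - b.position) <= 4.0


def test_distant_anchors_without_waters_not_connected():
    m = model_of(
        atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0), subunit="S"),
        atom(2, "OE1", "O", "GLU", "A", 2, (6, 0, 0), subunit="S"),
    )
    g = build_wire_graph(collect_wire_nodes(m))
    spec = SegmentSpec("T", (ResidueRef("S", 1, "TYR"),), (ResidueRef("S", 2, "GLU"),))
    assert segment_connectivity(g, spec) == (False, [])


def test_missing_anchor_is_configuration_error():
    m, _ = _segment_model(n=3)
    g = build_wire_graph(collect_wire_nodes(m))
    spec = SegmentSpec("T", (ResidueRef("S", 9, "LYS"),), (ResidueRef("S", 2, "GLU"),))
    with pytest.raises(ConfigurationError):
        segment_connectivity(g, spec)


@pytest.mark.parametrize("seed", range(10))
def test_reachability_equals_matrix_power_oracle(seed):
    rng = np.random.default_rng(100 + seed)
    n = int(rng.integers(5, 30))
    pts = rng.uniform(0, 10, size=(n, 3))
    atoms = [atom(1, "OH", "O", "TYR", "A", 1, pts[0], subunit="S")]
    atoms += [water(2 + i, 100 + i, p, subunit="S") for i, p in enumerate(pts[1:-1])]
    atoms.append(atom(n, "OE1", "O", "GLU", "A", 2, pts[-1], subunit="S"))
    m = model_of(*atoms)
    nodes = collect_wire_nodes(m)
    g = build_wire_graph(nodes, 4.0)
    spec = SegmentSpec("T", (ResidueRef("S", 1, "TYR"),), (ResidueRef("S", 2, "GLU"),))
    connected, _ = segment_connectivity(g, spec)
    adj = np.zeros((len(nodes), len(nodes)), dtype=bool)
    for u, v, _ in g.edges():
        adj[u, v] = adj[v, u] = True
    a_idx = [i for i, nd in enumerate(nodes) if nd.resname == "TYR"]
    b_idx = [i for i, nd in enumerate(nodes) if nd.resname == "GLU"]
    assert connected == oracles.reachable_bruteforce(adj, a_idx, b_idx)


# -- gap routes ------------------------------------------------------------


def test_single_break_yields_one_gap_between_flanking_waters():
    m, spec = _segment_model(gap_positions=(3,))
    g = build_wire_graph(collect_wire_nodes(m))
    gaps = bridge_path_gaps(g, spec)
    assert len(gaps) == 1
    assert gaps[0].distance == pytest.approx(5.5)
    assert gaps[0].u.kind == "water" and gaps[0].v.kind == "water"


def test_two_breaks_in_series_returned_in_chain_order():
    m, spec = _segment_model(gap_positions=(2, 4), n=7)
    g = build_wire_graph(collect_wire_nodes(m))
    gaps = bridge_path_gaps(g, spec)
    assert len(gaps) == 2
    assert gaps[0].u.position[0] < gaps[1].u.position[0]


def test_parallel_routes_choose_minimum_total_gap():
    """Two bridging routes: one 5 A gap vs a 4.5+4.5 A double gap."""
    atoms = [atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0), subunit="S")]
    # short route (upper): single 5.0 A gap
    atoms.append(water(2, 100, (2.8, 2, 0), subunit="S"))
    atoms.append(water(3, 101, (7.8, 2, 0), subunit="S"))
    # long route (lower): two gaps 4.5 each
    atoms.append(water(4, 102, (2.0, -4, 0), subunit="S"))
    atoms.append(water(5, 103, (6.5, -4, 0), subunit="S"))
    atoms.append(water(6, 104, (11.0, -4, 0), subunit="S"))
    atoms.append(atom(7, "OE1", "O", "GLU", "A", 2, (9.5, 1, 0), subunit="S"))
    m = model_of(*atoms)
    g = build_wire_graph(collect_wire_nodes(m))
    spec = SegmentSpec("T", (ResidueRef("S", 1, "TYR"),), (ResidueRef("S", 2, "GLU"),))
    gaps = bridge_path_gaps(g, spec)
    # oracle: exhaustive route enumeration on the condensation
    import networkx as nx

    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(g.graph)):
        for node in comp:
            comp_of[node] = ci
    nodes = g.nodes
    a_comps = {comp_of[i] for i, n in enumerate(nodes) if n.resname == "TYR"}
    b_comps = {comp_of[i] for i, n in enumerate(nodes) if n.resname == "GLU"}
    best_total, best_gaps = oracles.min_total_gap_routes(
        g.positions, [comp_of[i] for i in range(len(nodes))], a_comps, b_comps
    )
    assert sum(gp.distance for gp in gaps) == pytest.approx(best_total)
    got = {(gp.u.atom_index, gp.v.atom_index) for gp in gaps}
    want = {(nodes[i].atom_index, nodes[j].atom_index) for i, j in best_gaps}
    assert got == want


# -- probe test ------------------------------------------------------------


def _gap_nodes(extra_atoms=()):
    atoms = [water(1, 100, (0, 0, 0)), water(2, 101, (5.5, 0, 0))]
    atoms += list(extra_atoms)
    m = model_of(*atoms)
    nodes = collect_wire_nodes(m)
    u = next(n for n in nodes if n.resnum == 100)
    v = next(n for n in nodes if n.resnum == 101)
    return m, u, v


def test_gap_in_empty_space_is_open():
    m, u, v = _gap_nodes()
    rec = classify_gap(m, u, v)
    assert rec.verdict == "open" and rec.blockers == []


def test_blocker_on_midpoint_obstructs_and_is_reported():
    blk = atom(3, "SE", BLOCKER_ELEMENT, "BLK", "B", 900, (2.75, 0, 0), hetero=True)
    m, u, v = _gap_nodes([blk])
    rec = classify_gap(m, u, v)
    assert rec.verdict == "obstructed"
    assert any(b.residue_name == "BLK" for b in rec.blockers)


def test_waters_never_block():
    w = water(3, 102, (2.75, 0.5, 0))
    m, u, v = _gap_nodes([w])
    assert classify_gap(m, u, v).verdict == "open"


def test_probe_verdicts_match_grid_oracle():
    """Randomised blocker placements: production verdict vs dense-grid oracle."""
    rng = np.random.default_rng(0)
    agree = 0
    trials = 200
    for _ in range(trials):
        n_blockers = int(rng.integers(1, 4))
        extras = []
        for k in range(n_blockers):
            pos = np.array([rng.uniform(0.5, 5.0), rng.uniform(-3, 3), rng.uniform(-3, 3)])
            element = rng.choice(["C", "N", "O", "S", "SE"])
            extras.append(
                atom(10 + k, element if len(element) > 1 else "X" + element, element, "BLK",
                     "B", 900 + k, pos, hetero=True)
            )
        m, u, v = _gap_nodes(extras)
        got = classify_gap(m, u, v).verdict
        want = oracles.probe_verdict_grid(m, u, v)
        agree += got == want
    assert agree / trials >= 0.99


# -- classification --------------------------------------------------------


def test_three_state_row(three_state_fixture):
    model, pathway, truth = three_state_fixture
    results = analyse_pathway(model, pathway)
    assert [r.state for r in results] == truth
    obstructed = results[truth.index("obstructed_gap")]
    assert any(g.verdict == "obstructed" and g.blockers for g in obstructed.gaps)


def test_connected_segment_has_valid_witness(three_state_fixture):
    model, pathway, _ = three_state_fixture
    results = analyse_pathway(model, pathway)
    w = results[0].witness
    assert len(w) >= 2
    for a, b in zip(w, w[1:]):
        assert np.linalg.norm(a.position - b.position) <= 4.0


def test_classification_rigid_motion_invariant():
    spec = WireFixtureSpec(states=("connected", "open_gap", "obstructed_gap"), seed=21)
    model, pathway, truth = make_wire_fixture(spec)
    rng = np.random.default_rng(99)
    moved = model.transformed(random_rotation(rng), rng.uniform(-30, 30, 3))
    results = analyse_pathway(moved, pathway)
    assert [r.state for r in results] == truth


def test_cutoff_monotonicity_and_water_deletion():
    model, pathway, truth = make_wire_fixture(
        WireFixtureSpec(states=("connected", "open_gap"), seed=31)
    )
    # larger cutoff keeps connected segments connected
    bigger = analyse_pathway(model, pathway, r_c=5.0)
    assert bigger[0].state == "connected"
    # deleting waters never creates connectivity
    no_waters = MacromolecularModel(
        [a for a in model.atoms if a.residue_name != "HOH"], name="dry"
    )
    dry = analyse_pathway(no_waters, pathway)
    assert dry[1].state != "connected"


def test_pathway_purity_and_empty():
    model, pathway, _ = make_wire_fixture(WireFixtureSpec(states=("connected",), seed=41))
    doubled = PathwayDefinition(name="x", segments=pathway.segments * 2)
    results = analyse_pathway(model, doubled)
    assert results[0].state == results[1].state == "connected"
    assert analyse_pathway(model, PathwayDefinition(name="empty", segments=[])) == []


def test_segment_error_collected_not_fatal():
    model, pathway, _ = make_wire_fixture(WireFixtureSpec(states=("connected",), seed=51))
    bad = SegmentSpec("B", (ResidueRef("NOPE", 1, "TYR"),), (ResidueRef("SEG1", 2, "GLU"),))
    results = analyse_pathway(model, PathwayDefinition(name="x", segments=[bad] + pathway.segments))
    assert results[0].state == "error" and results[0].error
    assert results[1].state == "connected"


# -- hydration and hydrogen bonds ------------------------------------------


def test_hydration_number_cutoff():
    tyr = atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0), subunit="S")
    ws = [water(2 + i, 100 + i, (3.0, 0, 0) if i < 3 else (3.6, 0, 0)) for i in range(4)]
    for i, w in enumerate(ws[:3]):
        object.__setattr__(w, "position", np.array([3.0 * np.cos(i), 3.0 * np.sin(i), 0.0]))
    m = model_of(tyr, *ws)
    assert hydration_number(m, ResidueRef("S", 1, "TYR"), ["OH"]) == 3
    assert hydration_number(model_of(tyr), ResidueRef("S", 1, "TYR"), ["OH"]) == 0


@pytest.mark.parametrize("seed", range(5))
def test_hydration_number_matches_bruteforce(seed):
    rng = np.random.default_rng(seed)
    tyr = atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0), subunit="S")
    ws = [water(2 + i, 100 + i, rng.uniform(-5, 5, 3)) for i in range(30)]
    m = model_of(tyr, *ws)
    got = hydration_number(m, ResidueRef("S", 1, "TYR"), ["OH"], cutoff=3.4)
    want = sum(1 for w in ws if np.linalg.norm(w.position) <= 3.4)
    assert got == want


def test_hbond_distance_window_and_angle():
    a = water(1, 100, (0, 0, 0))
    close = water(2, 101, (2.0, 0, 0))
    good = water(3, 102, (2.8, 0, 0))
    m = model_of(a, close, good)
    pairs = detect_hbonds(m, m.atoms)
    ds = [round(d, 2) for _, _, d in pairs]
    assert 2.0 not in ds
    assert 2.8 in ds

    # angle gate: two tyrosine hydroxyls whose CZ antecedents put both
    # donor-assignment angles below 90 degrees -> pair rejected
    oh1 = atom(1, "OH", "O", "TYR", "A", 1, (0, 0, 0), subunit="S1")
    cz1 = atom(2, "CZ", "C", "TYR", "A", 1, (1.0, -1.0, 0), subunit="S1")
    oh2 = atom(3, "OH", "O", "TYR", "B", 1, (2.8, 0, 0), subunit="S2")
    cz2 = atom(4, "CZ", "C", "TYR", "B", 1, (1.8, -1.0, 0), subunit="S2")
    m2 = model_of(oh1, cz1, oh2, cz2)
    assert detect_hbonds(m2, m2.atoms) == []
    # same pair with antecedents behind the donors (angle 90/180) -> accepted
    cz1b = atom(2, "CZ", "C", "TYR", "A", 1, (-1.4, 0, 0), subunit="S1")
    cz2b = atom(4, "CZ", "C", "TYR", "B", 1, (4.2, 0, 0), subunit="S2")
    m3 = model_of(oh1, cz1b, oh2, cz2b)
    assert len(detect_hbonds(m3, m3.atoms)) == 1


def test_hbond_fixture_enumeration():
    """Quinol O4 - Tyr OH - adjacent water triangle: hand-enumerated pairs."""
    o4 = atom(1, "O4", "O", "U10", "Q", 1, (0, 0, 0), hetero=True)
    oh = atom(2, "OH", "O", "TYR", "A", 108, (2.8, 0, 0), subunit="NDUFS2")
    cz = atom(3, "CZ", "C", "TYR", "A", 108, (4.2, 0, 0), subunit="NDUFS2")
    w = water(4, 500, (0.0, 3.0, 0))
    m = model_of(o4, oh, cz, w)
    pairs = detect_hbonds(m, m.atoms)
    names = {frozenset((p[0].name, p[1].name)) for p in pairs}
    assert names == {frozenset(("O4", "OH")), frozenset(("O4", "O"))}
    assert [round(p[2], 1) for p in pairs] == [2.8, 3.0]
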