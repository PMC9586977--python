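"""Superposition, helix axes, Zn coordination, and interface contacts."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from foldkit.struct_geom import (
    GeometryError,
    HYDROPHOBIC_RESIDUES,
    Atom,
    Residue,
    StructureModel,
    helix_axis,
    interface_contacts,
    interhelix_angle,
    kabsch_superpose,
    load_structure,
    superpose_modules,
    zn_coordination,
)
from foldkit.synthetic_data import (
    gen_helix_pair,
    gen_ideal_helix,
    gen_zn_site,
    rotation_about_axis,
)


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def test_identity_superposition():
    rng = np.random.default_rng(0)
    P = rng.normal(size=(10, 3))
    sup = kabsch_superpose(P, P)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(sup.rotation, np.eye(3), atol=1e-10)


def test_known_rotation_recovered_exactly():
    rng = np.random.default_rng(1)
    P = rng.normal(size=(12, 3))
    R = rotation_about_axis([1.0, -2.0, 0.5], 73.0)
    t = np.array([4.0, -1.0, 2.5])
    Q = (P - t) @ R  # so that R @ Q + t = P
    sup = kabsch_superpose(P, Q)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-9)
    assert np.allclose(sup.rotation, R, atol=1e-8)


def _rmsd_oracle(P, Q):
    """Brute-force minimum RMSD: numerical optimization over rotation
    vectors, independent of the SVD solution path."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)

    def cost(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((Qc @ R.T - Pc) ** 2).sum() / len(P))

    best = np.inf
    for x0 in ([0.1, 0.0, 0.0], [1.5, 1.5, 0.0], [0.0, -2.0, 1.0], [2.0, 2.0, 2.0]):
        res = minimize(cost, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
        best = min(best, res.fun)
    return best


def test_noisy_rmsd_matches_numerical_minimizer():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(15, 3)) * 5.0
    R = rotation_about_axis([0.3, 1.0, -0.7], 41.0)
    Q = (P @ R.T) + rng.normal(0.0, 0.5, P.shape)
    sup = kabsch_superpose(P, Q)
    assert sup.rmsd == pytest.approx(_rmsd_oracle(P, Q), abs=1e-6)


def test_rmsd_symmetric_and_rigid_motion_invariant():
    rng = np.random.default_rng(3)
    P = rng.normal(size=(20, 3)) * 3.0
    Q = P + rng.normal(0.0, 0.8, P.shape)
    r_pq = kabsch_superpose(P, Q).rmsd
    assert kabsch_superpose(Q, P).rmsd == pytest.approx(r_pq, abs=1e-10)
    # joint rigid motion of both sets leaves the RMSD unchanged
    R = rotation_about_axis([1, 1, 1], 30.0)
    t = np.array([10.0, -5.0, 2.0])
    assert kabsch_superpose(P @ R.T + t, Q @ R.T + t).rmsd == pytest.approx(
        r_pq, abs=1e-9
    )


def test_degenerate_inputs_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(GeometryError, match="collinear"):
        kabsch_superpose(line, line)
    with pytest.raises(GeometryError, match="at least 3"):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


def test_proper_rotation_enforced_on_mirrored_set():
    # a reflected point cloud must still yield det(R) = +1
    rng = np.random.default_rng(4)
    P = rng.normal(size=(10, 3))
    Q = P * np.array([-1.0, 1.0, 1.0])
    sup = kabsch_superpose(P, Q)
    assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# Helix axes and tilts
# ---------------------------------------------------------------------------

def test_ideal_helix_axis_within_one_degree():
    coords, _ = gen_ideal_helix(0, n_res=12)
    ax = helix_axis(coords)
    angle = math.degrees(math.acos(abs(float(ax.direction @ [0, 0, 1.0]))))
    assert angle < 1.0


def test_axis_equivariant_under_rotation():
    R = rotation_about_axis([2.0, 1.0, 0.3], 57.0)
    coords, truth = gen_ideal_helix(0, n_res=12, rotation=R)
    ax = helix_axis(coords)
    assert float(ax.direction @ truth.truth["axis"]) == pytest.approx(1.0, abs=1e-6)


def test_reversed_trace_negates_direction():
    coords, _ = gen_ideal_helix(1, n_res=10)
    fwd = helix_axis(coords).direction
    rev = helix_axis(coords[::-1]).direction
    assert float(fwd @ rev) == pytest.approx(-1.0, abs=1e-9)


def test_short_trace_rejected():
    coords, _ = gen_ideal_helix(0, n_res=12)
    with pytest.raises(GeometryError):
        helix_axis(coords[:4])


@pytest.mark.parametrize("angle", [0.0, 26.0, 42.0, 90.0])
def test_planted_interhelix_angle_recovered(angle):
    a, b, _ = gen_helix_pair(5, angle, n_res=10)
    got = interhelix_angle(helix_axis(a), helix_axis(b))
    assert got == pytest.approx(angle, abs=1.0)


def test_interhelix_angle_symmetric_and_bounded():
    rng = np.random.default_rng(6)
    for _ in range(20):
        angle = float(rng.uniform(0.0, 180.0))
        a, b, _ = gen_helix_pair(7, angle, n_res=10)
        ax_a, ax_b = helix_axis(a), helix_axis(b)
        t1 = interhelix_angle(ax_a, ax_b)
        assert interhelix_angle(ax_b, ax_a) == pytest.approx(t1, abs=1e-9)
        assert 0.0 <= t1 <= 90.0
        signed = interhelix_angle(ax_a, ax_b, signed=True)
        assert signed == pytest.approx(min(angle, 360 - angle), abs=1.0)


# ---------------------------------------------------------------------------
# Module superposition
# ---------------------------------------------------------------------------

def _helix_model(coords, chain="A", start=1, name="ALA"):
    residues = [
        Residue(chain=chain, seqid=start + i, icode="", name=name,
                atoms=[Atom("CA", "C", xyz)])
        for i, xyz in enumerate(coords)
    ]
    return StructureModel(name="helix", residues=residues)


def test_self_superposition_zero_rmsd_and_tilts():
    coords, _ = gen_ideal_helix(0, n_res=16)
    model = _helix_model(coords)
    pairing = [(i, i) for i in range(1, 17)]
    sup, tilts = superpose_modules(
        model, model, pairing, helix_map=[((1, 16), (1, 16))]
    )
    assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
    assert tilts[0] == pytest.approx(0.0, abs=1e-6)


def test_planted_tilt_survives_superposition_frame():
    """A mobile copy rigidly moved away and carrying a 42°-tilted second
    helix reports that tilt after superposition on the first helix."""
    h1, _ = gen_ideal_helix(0, n_res=16)
    R42 = rotation_about_axis([1.0, 0.0, 0.0], 42.0)
    h2_ref, _ = gen_ideal_helix(1, n_res=12, translation=np.array([12.0, 0, 0]))
    h2_mov, _ = gen_ideal_helix(
        1, n_res=12, rotation=R42, translation=np.array([12.0, 0, 0])
    )
    ref = _helix_model(np.vstack([h1, h2_ref]))
    # rigidly move the whole mobile structure
    Rm = rotation_about_axis([0.2, 1.0, 0.5], 105.0)
    tm = np.array([30.0, -8.0, 14.0])
    mov = _helix_model(np.vstack([h1, h2_mov]) @ Rm.T + tm)
    pairing = [(i, i) for i in range(1, 17)]  # superpose on helix 1 only
    sup, tilts = superpose_modules(
        ref, mov, pairing, helix_map=[((17, 28), (17, 28))]
    )
    assert sup.rmsd == pytest.approx(0.0, abs=1e-8)
    assert tilts[0] == pytest.approx(42.0, abs=1.0)


def test_missing_ca_pairs_dropped_then_rejected():
    coords, _ = gen_ideal_helix(0, n_res=8)
    model = _helix_model(coords)
    pairing = [(1, 1), (2, 2), (3, 3), (99, 99)]
    sup, _ = superpose_modules(model, model, pairing)
    assert sup.n_pairs == 3
    with pytest.raises(GeometryError, match="usable"):
        superpose_modules(model, model, [(1, 1), (2, 2), (99, 99)])


# ---------------------------------------------------------------------------
# Zn coordination
# ---------------------------------------------------------------------------

def test_tetrahedral_site_reports_four_ligands():
    model, _ = gen_zn_site(0, distances=2.3)
    sites = zn_coordination(model)
    assert len(sites) == 1
    assert len(sites[0].ligands) == 4
    for _, _, _, _, dist in sites[0].ligands:
        assert dist == pytest.approx(2.3, abs=1e-9)


def test_displaced_donor_leaves_cutoff():
    model, _ = gen_zn_site(0, distances=(2.3, 2.3, 2.3, 3.5))
    sites = zn_coordination(model)
    assert len(sites[0].ligands) == 3


def test_jittered_sites_stay_tetrahedral():
    for seed in range(100):
        model, _ = gen_zn_site(seed, distances=2.3, jitter=0.05)
        assert len(zn_coordination(model)[0].ligands) == 4


def test_zn_coordination_rigid_motion_invariant():
    model, _ = gen_zn_site(3, distances=(2.25, 2.30, 2.35, 2.40))
    R = rotation_about_axis([1.0, 2.0, -1.0], 77.0)
    t = np.array([15.0, -3.0, 8.0])
    before = zn_coordination(model)[0]
    after = zn_coordination(model.transformed(R, t))[0]
    assert [l[:4] for l in before.ligands] == [l[:4] for l in after.ligands]
    for (_, _, _, _, d0), (_, _, _, _, d1) in zip(before.ligands, after.ligands):
        assert d1 == pytest.approx(d0, abs=1e-9)


def test_structure_without_zn_yields_empty_list():
    coords, _ = gen_ideal_helix(0, n_res=6)
    assert zn_coordination(_helix_model(coords)) == []


# ---------------------------------------------------------------------------
# Interface contacts
# ---------------------------------------------------------------------------

def _two_span_model(gap):
    """Two 5-residue stretches along x, the second offset by `gap` Å in y."""
    residues = []
    for i in range(5):
        residues.append(
            Residue(chain="A", seqid=i + 1, icode="", name="LEU",
                    atoms=[Atom("CA", "C", np.array([i * 3.8, 0.0, 0.0])),
                           Atom("CB", "C", np.array([i * 3.8, 1.5, 0.0]))])
        )
    for i in range(5):
        residues.append(
            Residue(chain="A", seqid=i + 11, icode="", name="SER",
                    atoms=[Atom("CA", "C", np.array([i * 3.8, gap, 0.0]))])
        )
    return StructureModel(name="spans", residues=residues)


def test_distant_spans_have_no_contacts():
    model = _two_span_model(gap=30.0)
    assert interface_contacts(model, (1, 5), (11, 15)) == []


def test_contacts_match_brute_force_scan():
    rng = np.random.default_rng(8)
    residues = []
    for i in range(12):
        n_at = int(rng.integers(1, 5))
        atoms = [
            Atom(f"C{j}", "C", rng.uniform(-8, 8, 3)) for j in range(n_at)
        ]
        name = "LEU" if i % 3 == 0 else "SER"
        residues.append(Residue("A", i + 1, "", name, atoms))
    model = StructureModel(name="rand", residues=residues)
    got = {
        (c.res_a[1], c.res_b[1]): c.min_distance
        for c in interface_contacts(model, (1, 6), (7, 12), cutoff=4.5)
    }
    # brute force over all atom pairs
    expected = {}
    for ra in residues[:6]:
        for rb in residues[6:]:
            dmin = min(
                float(np.linalg.norm(a.xyz - b.xyz))
                for a in ra.atoms
                for b in rb.atoms
            )
            if dmin <= 4.5:
                expected[(ra.seqid, rb.seqid)] = dmin
    assert set(got) == set(expected)
    for key in got:
        assert got[key] == pytest.approx(expected[key], abs=1e-9)


def test_contact_cutoff_monotonicity():
    model = _two_span_model(gap=4.2)
    tight = {(c.res_a[1], c.res_b[1]) for c in interface_contacts(model, (1, 5), (11, 15), cutoff=4.0)}
    loose = {(c.res_a[1], c.res_b[1]) for c in interface_contacts(model, (1, 5), (11, 15), cutoff=4.5)}
    assert tight <= loose


def test_overlapping_spans_rejected():
    model = _two_span_model(gap=5.0)
    with pytest.raises(GeometryError, match="overlap"):
        interface_contacts(model, (1, 12), (5, 15))


def test_hydrophobic_flags_follow_residue_identity():
    model = _two_span_model(gap=2.5)
    contacts = interface_contacts(model, (1, 5), (11, 15))
    assert contacts, "expected contacts at 2.5 Å separation"
    for c in contacts:
        assert c.hydrophobic_a is ("LEU" in HYDROPHOBIC_RESIDUES)
        assert c.hydrophobic_b is False  # SER is not hydrophobic


# ---------------------------------------------------------------------------
# Structure loading
# ---------------------------------------------------------------------------

_MINI_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  0.30 10.00           C
HETATM    4 ZN    ZN A  90       5.000   5.000   5.000  1.00 20.00          ZN
HETATM    5  O   HOH A  91       8.000   8.000   8.000  1.00 30.00           O
END
"""


def test_minimal_pdb_roundtrip(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(_MINI_PDB)
    model = load_structure(path)
    assert len(model.residues) == 1          # waters dropped
    assert model.residues[0].name == "ALA"
    assert len(model.metals) == 1
    assert model.metals[0][2].upper() == "ZN"
    low_occ = [a for a in model.residues[0].atoms if a.low_occupancy]
    assert [a.name for a in low_occ] == ["C"]  # occ 0.30 retained but flagged
    # write and re-read
    out = tmp_path / "out.pdb"
    model.write_pdb(out)
    again = load_structure(out)
    assert len(again.residues) == 1
    assert len(again.metals) == 1


def test_missing_file_rejected(tmp_path):
    with pytest.raises(GeometryError, match="no such file"):
        load_structure(tmp_path / "absent.pdb")


def test_synthetic_zn_site_survives_pdb_roundtrip(tmp_path):
    model, _ = gen_zn_site(11, distances=2.3)
    path = tmp_path / "zn.pdb"
    model.write_pdb(path)
    again = load_structure(path)
    assert len(zn_coordination(again)[0].ligands) == 4
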