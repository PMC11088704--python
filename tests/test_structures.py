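"""Coordinate model, PDB I/O, superposition, Rg and Ramachandran checks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import premodel as pm
from premodel.structures import classify_phi_psi, phi_psi


def _random_model(rng, n=10, chain="A"):
    coords = rng.normal(size=(n, 3)) * 5.0
    return pm.StructureModel([chain] * n, np.arange(1, n + 1), ["ALA"] * n,
                             ["CA"] * n, ["C"] * n, coords)


# ---------------------------------------------------------------------------
# PDB round trip
# ---------------------------------------------------------------------------

def test_pdb_round_trip_two_models(tmp_path, rng):
    m1 = _random_model(rng)
    m2 = m1.copy()
    m2.coords = m1.coords + rng.normal(size=m1.coords.shape)
    m2.model_id = 2
    ens = pm.Ensemble([m1, m2])
    path = tmp_path / "toy.pdb"
    pm.write_structure(ens, path)
    back = pm.read_structure(path)
    assert len(back) == 2
    for orig, rt in zip(ens, back):
        assert np.allclose(orig.coords, rt.coords, atol=1e-3)
        assert orig.atom_key() == rt.atom_key()


def test_dna_phosphates_survive_round_trip(tmp_path):
    from premodel.modeling import build_bform_dna

    dna = build_bform_dna(6)
    path = tmp_path / "dna.pdb"
    pm.write_structure(pm.Ensemble([dna]), path)
    back = pm.read_structure(path)[0]
    assert np.all(back.atom_names == "P")
    assert np.allclose(back.coords, dna.coords, atol=1e-3)


def test_empty_ensemble_rejected():
    with pytest.raises(ValueError):
        pm.Ensemble([])


def test_missing_file_and_no_atoms(tmp_path):
    with pytest.raises(FileNotFoundError):
        pm.read_structure(tmp_path / "absent.pdb")
    empty = tmp_path / "empty.pdb"
    empty.write_text("HEADER    NOTHING\nEND\n")
    with pytest.raises(ValueError):
        pm.read_structure(empty)


def test_inconsistent_models_rejected(tmp_path):
    lines = ["MODEL        1"]
    for i, name in enumerate(["N", "CA", "C"], 1):
        lines.append(f"ATOM  {i:>5} {name:<4}ALA A   1    "
                     f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           "
                     f"{name[0]}")
    lines += ["ENDMDL", "MODEL        2"]
    for i, name in enumerate(["N", "CA"], 1):  # model 2 misses the C atom
        lines.append(f"ATOM  {i:>5} {name:<4}ALA A   1    "
                     f"{float(i):8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           "
                     f"{name[0]}")
    lines += ["ENDMDL", "END"]
    path = tmp_path / "ragged.pdb"
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValueError, match="inconsistent"):
        pm.read_structure(path)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

def test_selection_mini_language(truth_model):
    ca_b = truth_model.select("B::CA")
    assert np.all(truth_model.atom_names[ca_b] == "CA")
    assert np.all(truth_model.chain_ids[ca_b] == "B")
    seg = truth_model.select("B:51-55:CA")
    assert sorted(truth_model.residue_numbers[seg]) == [51, 52, 53, 54, 55]
    mixed = truth_model.select("B:46,48,50-52:N,CA")
    assert set(truth_model.residue_numbers[mixed]) == {46, 48, 50, 51, 52}
    union = truth_model.select("A::CA B::CA")
    assert len(union) == len(truth_model.select("A::CA")) + len(ca_b)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def test_superpose_recovers_rigid_motion(rng):
    ref = _random_model(rng)
    mobile = ref.copy()
    mobile.coords = ref.coords + np.array([5.0, 0.0, 0.0])
    tf, rmsd = pm.superpose(mobile, ref)
    assert rmsd < 1e-9
    assert np.allclose(tf.apply(mobile.coords), ref.coords, atol=1e-9)

    rot = Rotation.from_euler("xyz", [20, -35, 110], degrees=True)
    mobile.coords = rot.apply(ref.coords) + np.array([1.0, -2.0, 3.0])
    _, rmsd = pm.superpose(mobile, ref)
    assert rmsd < 1e-9


def test_superpose_invariant_under_prior_rigid_motion(rng):
    ref = _random_model(rng)
    mobile = ref.copy()
    mobile.coords = ref.coords + rng.normal(size=ref.coords.shape) * 0.7
    _, rmsd0 = pm.superpose(mobile, ref)
    for seed in range(3):
        r2 = np.random.default_rng(seed)
        rot = Rotation.random(random_state=np.random.RandomState(seed))
        moved = mobile.copy()
        moved.coords = rot.apply(mobile.coords) + r2.normal(size=3) * 10
        _, rmsd = pm.superpose(moved, ref)
        assert rmsd == pytest.approx(rmsd0, abs=1e-9)


def test_superpose_matches_dense_rotation_search(rng):
    """Kabsch result equals a brute-force search over many random rotations."""
    ref = _random_model(rng, n=8)
    mobile = ref.copy()
    mobile.coords = ref.coords + rng.normal(size=ref.coords.shape) * 1.0
    _, rmsd_kabsch = pm.superpose(mobile, ref)

    xm = mobile.coords - mobile.coords.mean(axis=0)
    xr = ref.coords - ref.coords.mean(axis=0)
    rots = Rotation.random(40_000, random_state=np.random.RandomState(7))
    best = np.inf
    for chunk in range(0, 40_000, 5000):
        rr = rots[chunk:chunk + 5000]
        rotated = np.einsum("rij,nj->rni", rr.as_matrix(), xm)
        rmsds = np.sqrt(np.mean(np.sum((rotated - xr) ** 2, axis=2), axis=1))
        best = min(best, float(rmsds.min()))
    assert rmsd_kabsch <= best + 1e-9
    assert best - rmsd_kabsch < 0.05


def test_superpose_degenerate_inputs(rng):
    ref = _random_model(rng, n=2)
    with pytest.raises(ValueError):
        pm.superpose(ref, ref)  # < 3 atoms
    n = 5
    coords = np.outer(np.arange(n), np.array([1.0, 0.0, 0.0]))
    line = pm.StructureModel(["A"] * n, np.arange(1, n + 1), ["ALA"] * n,
                             ["CA"] * n, ["C"] * n, coords)
    with pytest.raises(ValueError, match="collinear"):
        pm.superpose(line, line)


# ---------------------------------------------------------------------------
# pairwise RMSD
# ---------------------------------------------------------------------------

def _independent_kabsch_rmsd(x, y):
    """Oracle: SVD-based Kabsch, written independently of the library path."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    u, s, vt = np.linalg.svd(xc.T @ yc)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return float(np.sqrt(np.mean(np.sum((xc @ rot.T - yc) ** 2, axis=1))))


def test_pairwise_rmsd_identical_models(rng):
    m = _random_model(rng)
    models = []
    for i in range(3):
        c = m.copy()
        c.model_id = i + 1
        models.append(c)
    mean, sd, mat = pm.pairwise_rmsd(pm.Ensemble(models))
    assert mean == pytest.approx(0.0, abs=1e-9)
    assert sd == pytest.approx(0.0, abs=1e-9)


def test_pairwise_rmsd_matches_pair_enumeration(rng):
    models = []
    base = _random_model(rng)
    for i in range(3):
        m = base.copy()
        m.coords = base.coords + rng.normal(size=base.coords.shape)
        m.model_id = i + 1
        models.append(m)
    mean, sd, mat = pm.pairwise_rmsd(pm.Ensemble(models))
    oracle = [_independent_kabsch_rmsd(models[i].coords, models[j].coords)
              for i in range(3) for j in range(i + 1, 3)]
    assert mean == pytest.approx(np.mean(oracle), abs=1e-9)
    assert mat[0, 1] == pytest.approx(oracle[0], abs=1e-9)
    # symmetric under model reordering
    mean_r, _, _ = pm.pairwise_rmsd(pm.Ensemble(models[::-1]))
    assert mean_r == pytest.approx(mean, abs=1e-12)


# ---------------------------------------------------------------------------
# radius of gyration
# ---------------------------------------------------------------------------

def test_radius_of_gyration_closed_forms(rng):
    single = _random_model(rng, n=1)
    assert pm.radius_of_gyration(single) == pytest.approx(0.0)
    two = pm.StructureModel(["A", "A"], [1, 2], ["ALA"] * 2, ["CA", "CB"],
                            ["C", "C"], [[0, 0, 0], [0, 0, 6.0]])
    assert pm.radius_of_gyration(two) == pytest.approx(3.0)


def test_radius_of_gyration_direct_summation(rng):
    m = _random_model(rng, n=50)
    w = rng.uniform(0.5, 2.0, size=50)
    got = pm.radius_of_gyration(m, None, weights=w)
    centroid = (m.coords * w[:, None]).sum(axis=0) / w.sum()
    expect = np.sqrt((w * ((m.coords - centroid) ** 2).sum(axis=1)).sum() / w.sum())
    assert got == pytest.approx(expect, rel=1e-10)


def test_radius_of_gyration_scales_linearly(rng):
    m = _random_model(rng, n=20)
    rg = pm.radius_of_gyration(m)
    m2 = m.copy()
    m2.coords = m.coords * 2.5
    assert pm.radius_of_gyration(m2) == pytest.approx(2.5 * rg, rel=1e-12)


# ---------------------------------------------------------------------------
# Ramachandran
# ---------------------------------------------------------------------------

def _chain_from_torsions(phi, psi):
    from premodel.structures import build_backbone

    bb = build_backbone(phi, psi)
    n = len(phi)
    rows = {k: [] for k in ("chain", "res", "name", "atom", "el", "xyz")}
    for i in range(n):
        for atom in ("N", "CA", "C"):
            rows["chain"].append("A")
            rows["res"].append(i + 1)
            rows["name"].append("ALA")
            rows["atom"].append(atom)
            rows["el"].append(atom[0])
            rows["xyz"].append(bb[atom][i])
    return pm.StructureModel(rows["chain"], rows["res"], rows["name"],
                             rows["atom"], rows["el"], np.array(rows["xyz"]))


def test_ideal_helix_is_most_favored():
    m = _chain_from_torsions([-57.0] * 8, [-47.0] * 8)
    stats = pm.ramachandran_stats(pm.Ensemble([m]), "A")
    assert stats["most_favored"] == pytest.approx(1.0)


def test_forbidden_torsions_not_favored():
    m = _chain_from_torsions([170.0] * 8, [170.0] * 8)
    stats = pm.ramachandran_stats(pm.Ensemble([m]), "A")
    assert stats["most_favored"] == 0.0


def test_mixed_chain_matches_per_residue_lookup(rng):
    phi = rng.uniform(-180, 180, size=12)
    psi = rng.uniform(-180, 180, size=12)
    m = _chain_from_torsions(phi, psi)
    stats = pm.ramachandran_stats(pm.Ensemble([m]), "A")
    # oracle: classify each measured (phi, psi) individually
    measured = phi_psi(m, "A")
    classes = [classify_phi_psi(p, s) for _, p, s in measured]
    for cls in ("most_favored", "additional_allowed", "generously_allowed",
                "disallowed"):
        assert stats[cls] == pytest.approx(classes.count(cls) / len(classes))
    assert sum(stats.values()) == pytest.approx(1.0, abs=1e-12)
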