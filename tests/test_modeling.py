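"""Energy terms, Metropolis sampling and the ternary protocol."""

import numpy as np
import pytest

import premodel as pm
from premodel.modeling import (DEFAULT_RADII, RestraintPotential, _System,
                               build_bform_dna, build_ternary_start,
                               hbond_energy, merge_models, sample_ternary)
from premodel.pre_analysis import DistanceRestraint
from premodel.structures import radius_of_gyration


def _restraint(lower, upper, target=None):
    return DistanceRestraint(site=None, anchor_atoms=(("A", 1, "CA"),),
                             chain_id="B", residue_number=1, atom_name="CA",
                             target=target or (lower + upper) / 2,
                             lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# flat-bottom restraint energy
# ---------------------------------------------------------------------------

def test_flat_bottom_exact_values():
    # the mutagenesis-style restraint: 12.5 ± 0.5 Å, k = 2.0 kcal/mol/Å²
    rst = _restraint(12.0, 13.0, target=12.5)
    pot = RestraintPotential(flat_width=1.0, k=2.0)
    assert pm.restraint_energy(12.7, rst, pot) == 0.0
    assert pm.restraint_energy(12.0, rst, pot) == 0.0
    assert pm.restraint_energy(14.0, rst, pot) == pytest.approx(2.0)
    assert pm.restraint_energy(11.0, rst, pot) == pytest.approx(2.0)


def test_flat_bottom_continuity_at_boundary():
    rst = _restraint(10.0, 12.0)
    pot = RestraintPotential()
    eps = 1e-7
    assert pm.restraint_energy(12.0 + eps, rst, pot) < 1e-10
    assert pm.restraint_energy(10.0 - eps, rst, pot) < 1e-10


def test_flat_bottom_convex_outside(rng):
    rst = _restraint(10.0, 12.0)
    pot = RestraintPotential()
    d = np.sort(rng.uniform(12.0, 20.0, size=20))
    e = np.array([pm.restraint_energy(x, rst, pot) for x in d])
    assert np.all(np.diff(e) >= 0)  # monotone beyond the upper bound
    assert all(pm.restraint_energy(x, rst, pot) == 0.0
               for x in rng.uniform(10.0, 12.0, size=10))


# ---------------------------------------------------------------------------
# clash energy
# ---------------------------------------------------------------------------

def _two_atom_model(d, elements=("C", "C")):
    return pm.StructureModel(["A", "B"], [1, 1], ["ALA", "ALA"], ["CA", "CA"],
                             list(elements), [[0, 0, 0], [d, 0, 0]])


def test_clash_energy_boundary():
    rsum = 2 * DEFAULT_RADII["C"] * 0.85
    assert pm.clash_energy(_two_atom_model(rsum + 1e-9)) == 0.0
    assert pm.clash_energy(_two_atom_model(rsum - 0.2)) == \
        pytest.approx(0.2 ** 2, rel=1e-6)


def test_clash_energy_well_separated_chains(toy_complex):
    receptor, truth, free = toy_complex
    shifted = free.copy()
    shifted.coords = free.coords + 500.0
    assert pm.clash_energy(merge_models(receptor, shifted),
                           rigid_chains=("A",)) == 0.0


def test_clash_energy_matches_brute_force(rng):
    n = 30
    model = pm.StructureModel(
        ["A"] * 15 + ["B"] * 15, list(range(1, 16)) + list(range(1, 16)),
        ["ALA"] * n, ["CA"] * n, ["C"] * n, rng.normal(size=(n, 3)) * 4.0)
    got = pm.clash_energy(model, k_rep=1.3, scale=0.9)
    expect = 0.0
    radii = {el: DEFAULT_RADII[el] * 0.9 for el in ("C",)}
    for i in range(n):
        for j in range(i + 1, n):
            if (model.chain_ids[i] == model.chain_ids[j]
                    and abs(int(model.residue_numbers[i])
                            - int(model.residue_numbers[j])) <= 1):
                continue
            d = np.linalg.norm(model.coords[i] - model.coords[j])
            rsum = radii["C"] * 2
            if d < rsum:
                expect += 1.3 * (rsum - d) ** 2
    assert got == pytest.approx(expect, rel=1e-10)


# ---------------------------------------------------------------------------
# collapse + H-bond terms, additivity
# ---------------------------------------------------------------------------

def test_rg_collapse_one_sided(truth_model):
    rg = radius_of_gyration(truth_model, "B::CA")
    assert pm.rg_collapse_energy(truth_model, "B::CA", rg + 5.0) == 0.0
    assert pm.rg_collapse_energy(truth_model, "B::CA", rg - 1.0, rg_k=1.0) == \
        pytest.approx(1.0, rel=1e-9)
    # composition with radius_of_gyration for an arbitrary target
    target = rg * 0.5
    assert pm.rg_collapse_energy(truth_model, "B::CA", target, rg_k=2.0) == \
        pytest.approx(2.0 * (rg - target) ** 2, rel=1e-12)


def test_hbond_reward_geometry():
    # one amide H at ideal distance from a carbonyl O on another chain
    model = pm.StructureModel(
        ["A", "B"], [1, 1], ["ALA", "ALA"], ["O", "H"], ["O", "H"],
        [[0, 0, 0], [2.1, 0, 0]])
    assert hbond_energy(model, epsilon=1.0) == pytest.approx(-1.0)
    far = pm.StructureModel(
        ["A", "B"], [1, 1], ["ALA", "ALA"], ["O", "H"], ["O", "H"],
        [[0, 0, 0], [5.0, 0, 0]])
    assert hbond_energy(far) == 0.0


def test_total_energy_additivity(truth_model, label_sites, sb_params):
    site = next(iter(label_sites.values()))
    rst = DistanceRestraint(site=site, anchor_atoms=None, chain_id="B",
                            residue_number=60, atom_name="H",
                            target=15.0, lower=14.0, upper=16.0)
    energy = pm.EnergyModel(weights={"pre_restraints": 2.0,
                                     "mutagenesis_restraints": 1.0,
                                     "clash": 1.5, "rg_collapse": 0.7,
                                     "hbond": 0.0},
                            rg_target=5.0)
    total, terms = energy.total_energy(truth_model, [rst],
                                       collapse_selection="B::CA",
                                       rigid_chains=("A",))
    expect = (2.0 * pm.restraint_energy(rst.distance(truth_model), rst,
                                        energy.potential)
              + 1.5 * pm.clash_energy(truth_model, scale=energy.radii_scale,
                                      rigid_chains=("A",))
              + 0.7 * pm.rg_collapse_energy(truth_model, "B::CA", 5.0))
    assert total == pytest.approx(expect, rel=1e-9)
    assert all(v >= 0 for k, v in terms.items() if k != "hbond")


def test_negative_weights_rejected():
    with pytest.raises(ValueError):
        pm.EnergyModel(weights={"clash": -1.0})


# ---------------------------------------------------------------------------
# Metropolis rule (empirical acceptance frequencies)
# ---------------------------------------------------------------------------

def test_metropolis_acceptance_frequencies(rng):
    """Accept always for ΔE ≤ 0; with probability exp(−ΔE/T) otherwise."""
    t_red = 0.8
    for d_e in (-1.0, 0.0, 0.4, 1.6):
        p_expect = 1.0 if d_e <= 0 else float(np.exp(-d_e / t_red))
        n = 20_000
        acc = sum((d_e <= 0 or rng.random() < np.exp(-d_e / t_red))
                  for _ in range(n))
        p_hat = acc / n
        sigma = np.sqrt(max(p_expect * (1 - p_expect), 1e-12) / n)
        assert abs(p_hat - p_expect) <= max(3 * sigma, 1e-9)


def _quick_setup(toy_complex, label_sites, sb_params, seed=0, w=5.0):
    receptor, truth, free = toy_complex
    spec = pm.SyntheticComplexSpec()
    noise = pm.NoiseModel(gamma_noise_cv=0.0)
    profs = pm.simulate_pre(merge_models(receptor, truth), label_sites,
                            sb_params, noise, spec.peptide_residues(), "B",
                            seed=seed)
    policy = pm.RestraintPolicy()
    restraints = []
    for name, prof in profs.items():
        restraints += pm.generate_restraints(prof, sb_params, policy,
                                             label_sites[name], "B")
    energy = pm.EnergyModel(weights={"pre_restraints": w,
                                     "mutagenesis_restraints": w,
                                     "clash": 1.0, "rg_collapse": 0.0,
                                     "hbond": 0.0})
    return receptor, free, restraints, energy, profs


def test_sampler_deterministic_in_seed(toy_complex, label_sites, sb_params):
    receptor, free, restraints, energy, _ = _quick_setup(toy_complex,
                                                         label_sites, sb_params)
    cfg = pm.SamplerConfig(n_steps=2500, n_trajectories=1, seed=42,
                           predock_steps=300, snapshot_t_max=5.0,
                           snapshot_interval=20)
    ens1, log1 = pm.sample_complex(receptor, free, restraints, energy, cfg)
    ens2, log2 = pm.sample_complex(receptor, free, restraints, energy, cfg)
    assert len(ens1) == len(ens2)
    for a, b in zip(ens1, ens2):
        assert np.array_equal(a.coords, b.coords)
    cfg2 = pm.SamplerConfig(n_steps=2500, n_trajectories=1, seed=43,
                            predock_steps=300, snapshot_t_max=5.0,
                            snapshot_interval=20)
    ens3, _ = pm.sample_complex(receptor, free, restraints, energy, cfg2)
    assert not np.array_equal(ens1[-1].coords, ens3[-1].coords)


def test_clash_only_annealing_reduces_clashes(toy_complex):
    receptor, truth, free = toy_complex
    energy = pm.EnergyModel(weights={"pre_restraints": 0.0,
                                     "mutagenesis_restraints": 0.0,
                                     "clash": 1.0, "rg_collapse": 0.0,
                                     "hbond": 0.0})
    # start the peptide overlapping the receptor so clashes exist
    clashy = free.copy()
    clashy.coords = free.coords - free.coords.mean(axis=0) \
        + receptor.coords.mean(axis=0)
    start_model = merge_models(receptor, clashy)
    e0 = pm.clash_energy(start_model, scale=0.85, rigid_chains=("A",))
    assert e0 > 0
    cfg = pm.SamplerConfig(n_steps=3000, n_trajectories=1, seed=7,
                           predock_steps=0, n_cycles=1, clash_ramp_start=1.0,
                           snapshot_t_max=5.0)
    ens, _ = pm.sample_complex(receptor, clashy, [], energy, cfg)
    e_final = pm.clash_energy(ens[-1], scale=0.85, rigid_chains=("A",))
    assert e_final <= e0


def test_restraint_on_absent_atom_rejected(toy_complex, label_sites, sb_params):
    receptor, truth, free = toy_complex
    bad = DistanceRestraint(site=None, anchor_atoms=(("A", 360, "CB"),),
                            chain_id="B", residue_number=999, atom_name="H",
                            target=15.0, lower=14.0, upper=16.0)
    energy = pm.EnergyModel()
    with pytest.raises(ValueError, match="absent atom"):
        pm.sample_complex(receptor, free, [bad], energy,
                          pm.SamplerConfig(n_steps=10, n_trajectories=1))


def test_sampled_torsions_stay_in_allowed_basins(toy_complex, label_sites,
                                                 sb_params):
    from premodel.structures import phi_psi
    from premodel.modeling import PHI_BOUNDS, PSI_BOUNDS

    receptor, free, restraints, energy, _ = _quick_setup(toy_complex,
                                                         label_sites, sb_params)
    cfg = pm.SamplerConfig(n_steps=3000, n_trajectories=1, seed=5,
                           predock_steps=200, snapshot_t_max=5.0)
    ens, _ = pm.sample_complex(receptor, free, restraints, energy, cfg)
    for r, phi, psi in phi_psi(ens[-1], "B"):
        assert PHI_BOUNDS[0] - 1e-6 <= phi <= PHI_BOUNDS[1] + 1e-6
        assert PSI_BOUNDS[0] - 1e-6 <= psi <= PSI_BOUNDS[1] + 1e-6


# ---------------------------------------------------------------------------
# B-DNA trace and ternary protocol
# ---------------------------------------------------------------------------

def test_bform_dna_geometry():
    dna = build_bform_dna(10)
    strand = dna.coords[dna.chain_ids == "D"]
    order = np.argsort(dna.residue_numbers[dna.chain_ids == "D"])
    strand = strand[order]
    rises = np.diff(strand @ np.array([0.0, 0.0, 1.0]))
    assert np.allclose(np.abs(rises), 3.4, atol=1e-9)
    radii = np.linalg.norm(strand[:, :2], axis=1)
    assert np.allclose(radii, 9.4, atol=1e-9)


@pytest.fixture(scope="module")
def ternary_setup(truth_model):
    cfg = pm.TernaryConfig(rigid_segment=(51, 80), mobile_segment=(36, 50),
                           collapse_selection="B:38-42 D E",
                           n_structures=8, n_select=3, dna_n_bp=10)
    start = build_ternary_start(truth_model, cfg, seed=3,
                                sequence={r: "K" for r in range(36, 46)})
    return cfg, start


def test_ternary_start_adds_dna_and_mobile_residues(ternary_setup, truth_model):
    cfg, start = ternary_setup
    assert set(cfg.dna_chains) <= set(start.chain_ids)
    pep_res = start.residue_numbers[start.chain_ids == "B"]
    assert pep_res.min() == 36
    # toy mode keeps the receptor exactly where the binary model had it
    rec_idx = start.select("A::CA")
    rec_ref = truth_model.select("A::CA")
    assert np.allclose(start.coords[rec_idx], truth_model.coords[rec_ref])


def test_ternary_randomization_seeds_differ(truth_model):
    cfg = pm.TernaryConfig(rigid_segment=(51, 80), mobile_segment=(36, 50),
                           n_structures=2, n_select=1, dna_n_bp=8)
    s1 = build_ternary_start(truth_model, cfg, seed=1,
                             sequence={r: "K" for r in range(36, 46)})
    s2 = build_ternary_start(truth_model, cfg, seed=2,
                             sequence={r: "K" for r in range(36, 46)})
    mob1 = s1.coords[s1.select("B:36-45:CA")]
    mob2 = s2.coords[s2.select("B:36-45:CA")]
    assert not np.allclose(mob1, mob2)
    rig1 = s1.coords[s1.select("B:51-80:CA")]
    rig2 = s2.coords[s2.select("B:51-80:CA")]
    assert np.allclose(rig1, rig2)


def test_sample_ternary_contract(ternary_setup):
    cfg, start = ternary_setup
    rg0 = radius_of_gyration(start, cfg.collapse_selection)
    energy = pm.EnergyModel(weights={"pre_restraints": 0.0,
                                     "mutagenesis_restraints": 0.0,
                                     "clash": 1.0, "rg_collapse": 1.0,
                                     "hbond": 0.0},
                            rg_target=rg0 * 0.6)
    scfg = pm.SamplerConfig(n_steps=1200, n_trajectories=1, seed=11,
                            predock_steps=0)
    all_ens, energies, selected = sample_ternary(start, energy, cfg, scfg)
    assert len(all_ens) == cfg.n_structures
    assert len(selected) == cfg.n_select
    assert np.all(np.diff(energies) >= -1e-9)  # ranked by energy
    fixed = ~((start.chain_ids == "B") & (start.residue_numbers >= 36)
              & (start.residue_numbers <= 50))
    for m in all_ens:
        assert np.array_equal(m.coords[fixed], start.coords[fixed])


def test_collapse_term_compacts_selection(ternary_setup):
    cfg, start = ternary_setup
    rg0 = radius_of_gyration(start, cfg.collapse_selection)
    diffs = []
    for seed in range(3):
        scfg = pm.SamplerConfig(n_steps=900, n_trajectories=1, seed=seed,
                                predock_steps=0)
        on = pm.EnergyModel(weights={"pre_restraints": 0.0,
                                     "mutagenesis_restraints": 0.0,
                                     "clash": 1.0, "rg_collapse": 1.0,
                                     "hbond": 0.0}, rg_target=rg0 * 0.6)
        off = pm.EnergyModel(weights={"pre_restraints": 0.0,
                                      "mutagenesis_restraints": 0.0,
                                      "clash": 1.0, "rg_collapse": 0.0,
                                      "hbond": 0.0}, rg_target=rg0 * 0.6)
        _, _, sel_on = sample_ternary(start, on, cfg, scfg)
        _, _, sel_off = sample_ternary(start, off, cfg, scfg)
        rg_on = np.mean([radius_of_gyration(m, cfg.collapse_selection)
                         for m in sel_on])
        rg_off = np.mean([radius_of_gyration(m, cfg.collapse_selection)
                          for m in sel_off])
        diffs.append(rg_off - rg_on)
    assert np.mean(diffs) > 0
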