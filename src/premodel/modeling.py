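"""Restrained conformational sampling of a flexible peptide on a rigid domain.

The composite potential combines

* flat-bottom distance restraints (zero inside [lower, upper], harmonic
  outside with force constant k = 2.0 kcal·mol⁻¹·Å⁻², flat region 1 Å wide
  by default),
* a soft-sphere excluded-volume term,
* an optional one-sided radius-of-gyration "collapse" term that biases a
  selection (e.g. a lysine cluster plus the DNA) to stay compact.

Sampling is Metropolis Monte-Carlo with simulated annealing over a geometric
temperature ladder. Moves are backbone pivot torsions (φ/ψ) on the flexible
residues plus rigid-body rotations/translations of the whole peptide; the
receptor (and DNA, and any rigid peptide segment) never moves. This is a
deliberately coarse engine: it explores restraint-satisfying poses rather
than force-field energetics, so ensembles are validated by restraint
satisfaction and by back-calculated PRE correlation, not by their energies.

Peptide residues carry backbone N, H, CA, C, O plus a Cβ pseudo-side-chain;
the mutagenesis-derived restraint attaches between Cβ atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .pre_analysis import DistanceRestraint
from .structures import (ANG_C_N_CA, ANG_CA_C_N, ANG_N_CA_C, BOND_C_N,
                         BOND_CA_C, BOND_N_CA, Ensemble, StructureModel,
                         place_atom, radius_of_gyration)

__all__ = [
    "RestraintPotential",
    "SamplerConfig",
    "EnergyModel",
    "TernaryConfig",
    "restraint_energy",
    "clash_energy",
    "rg_collapse_energy",
    "sample_complex",
    "build_ternary_start",
    "sample_ternary",
    "build_bform_dna",
    "merge_models",
]

#: soft-sphere radii per element (Å)
DEFAULT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "H": 1.10, "S": 1.80,
                 "P": 1.80, "Zn": 1.39, "Mn": 1.39}

PEPTIDE_ATOMS = ("N", "H", "CA", "C", "O", "CB")

#: pivot proposals keep φ/ψ inside these broad basins (β + polyproline +
#: right-handed α); a knowledge-based prior standing in for the backbone
#: torsion potential the coarse model lacks
PHI_BOUNDS = (-160.0, -45.0)
PSI_BOUNDS = (-75.0, 170.0)


# ---------------------------------------------------------------------------
# potentials
# ---------------------------------------------------------------------------

@dataclass
class RestraintPotential:
    """Flat-bottom harmonic: zero on [lower, upper], k·Δ² outside."""

    flat_width: float = 1.0
    k: float = 2.0  # kcal·mol⁻¹·Å⁻²

    def __post_init__(self):
        if self.flat_width < 0:
            raise ValueError("flat_width must be >= 0")
        if self.k <= 0:
            raise ValueError("force constant must be positive")


def restraint_energy(d: float, restraint: DistanceRestraint,
                     pot: RestraintPotential | None = None) -> float:
    """Flat-bottom restraint energy at distance ``d`` (kcal/mol).

    Zero inside [lower, upper]; k·(d − upper)² above; k·(lower − d)² below.
    Continuous with zero slope at both boundaries.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    pot = pot or RestraintPotential()
    if d > restraint.upper:
        return pot.k * (d - restraint.upper) ** 2
    if d < restraint.lower:
        return pot.k * (restraint.lower - d) ** 2
    return 0.0


def _radii_for(model: StructureModel, radii: dict, scale: float) -> np.ndarray:
    table = {**DEFAULT_RADII, **(radii or {})}
    out = np.array([table.get(el, 1.7) for el in model.elements])
    return out * scale


def clash_energy(model: StructureModel, radii: dict | None = None,
                 k_rep: float = 1.0, scale: float = 0.85,
                 rigid_chains=()) -> float:
    """Soft-sphere overlap energy over non-bonded atom pairs.

    Pairs closer than the (scaled) radius sum contribute k_rep·(rsum − d)².
    Excluded: pairs within one residue, pairs in adjacent residues of the
    same chain, and pairs entirely inside the rigid chains (a constant).
    """
    r = _radii_for(model, radii, scale)
    rigid = np.isin(model.chain_ids, list(rigid_chains))
    n = len(model)
    same_chain = model.chain_ids[:, None] == model.chain_ids[None, :]
    res_sep = np.abs(model.residue_numbers[:, None] - model.residue_numbers[None, :])
    excluded = same_chain & (res_sep <= 1)
    excluded |= rigid[:, None] & rigid[None, :]
    iu = np.triu_indices(n, k=1)
    keep = ~excluded[iu]
    i_idx, j_idx = iu[0][keep], iu[1][keep]
    d = np.linalg.norm(model.coords[i_idx] - model.coords[j_idx], axis=1)
    rsum = r[i_idx] + r[j_idx]
    overlap = np.clip(rsum - d, 0.0, None)
    return float(k_rep * np.sum(overlap ** 2))


def hbond_energy(model: StructureModel, epsilon: float = 1.0, d0: float = 2.1,
                 width: float = 0.6) -> float:
    """Inter-chain backbone H-bond reward (negative energy, kcal/mol).

    Every amide H within ``d0 ± width`` of a carbonyl O on another chain
    contributes a smooth parabolic well of depth ``epsilon``; each donor or
    acceptor is credited at most once.
    """
    e = 0.0
    names = model.atom_names
    for a_name, b_name in (("H", "O"),):
        ai = np.nonzero(names == a_name)[0]
        bi = np.nonzero(names == b_name)[0]
        if not len(ai) or not len(bi):
            continue
        d = cdist(model.coords[ai], model.coords[bi])
        u = 1.0 - ((d - d0) / width) ** 2
        diff_chain = model.chain_ids[ai][:, None] != model.chain_ids[bi][None, :]
        u[(u <= 0) | ~diff_chain] = 0.0
        if u.any():
            e -= epsilon * float(np.sum(u.max(axis=1)))
    return e


def rg_collapse_energy(model: StructureModel, selection, rg_target: float,
                       rg_k: float = 1.0) -> float:
    """One-sided collapse: rg_k·(Rg − rg_target)² when Rg exceeds the target."""
    rg = radius_of_gyration(model, selection)
    return float(rg_k * (rg - rg_target) ** 2) if rg > rg_target else 0.0


@dataclass
class EnergyModel:
    """Weights and parameters of the composite potential."""

    weights: dict = field(default_factory=lambda: {
        "pre_restraints": 1.0, "mutagenesis_restraints": 1.0,
        "clash": 1.0, "rg_collapse": 0.0, "hbond": 0.0})
    radii: dict = field(default_factory=dict)
    radii_scale: float = 0.85
    clash_k: float = 1.0
    rg_target: float | None = None
    rg_k: float = 1.0
    #: inter-chain backbone H-bond well depth (kcal/mol); a smooth reward
    #: for amide-H···carbonyl-O pairs near 2.1 Å that favours flush
    #: β-augmentation geometry at the interface
    hbond_epsilon: float = 1.0
    hbond_d0: float = 2.1
    hbond_width: float = 0.6
    potential: RestraintPotential = field(default_factory=RestraintPotential)

    def __post_init__(self):
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("term weights must be >= 0")

    def total_energy(self, model: StructureModel, restraints=(),
                     collapse_selection=None, rigid_chains=()):
        """Reference (unvectorised) total energy; returns (total, terms)."""
        terms = {"pre_restraints": 0.0, "mutagenesis_restraints": 0.0,
                 "clash": 0.0, "rg_collapse": 0.0, "hbond": 0.0}
        for r in restraints:
            key = "mutagenesis_restraints" if r.source == "mutagenesis" else "pre_restraints"
            terms[key] += r.weight * restraint_energy(r.distance(model), r, self.potential)
        terms["clash"] = clash_energy(model, self.radii, self.clash_k,
                                      self.radii_scale, rigid_chains)
        if self.weights.get("hbond", 0.0) > 0 and self.hbond_epsilon > 0:
            terms["hbond"] = hbond_energy(model, self.hbond_epsilon,
                                          self.hbond_d0, self.hbond_width)
        if collapse_selection is not None and self.rg_target is not None:
            terms["rg_collapse"] = rg_collapse_energy(model, collapse_selection,
                                                      self.rg_target, self.rg_k)
        total = sum(self.weights.get(k, 0.0) * v for k, v in terms.items())
        return float(total), terms


# ---------------------------------------------------------------------------
# sampler configuration
# ---------------------------------------------------------------------------

@dataclass
class SamplerConfig:
    """Monte-Carlo / simulated-annealing settings.

    Temperatures are reduced units (energy scale kcal/mol); the default
    ladder anneals geometrically over 8 stages. Move probabilities must sum
    to 1; rigid-body moves are automatically disabled when the peptide is
    anchored (ternary mode).
    """

    n_steps: int = 50_000
    temperature_ladder: tuple = tuple(np.geomspace(5.0, 0.05, 10).round(4))
    p_pivot: float = 0.6
    p_rotate: float = 0.2
    p_translate: float = 0.2
    max_torsion_deg: float = 30.0
    max_rotate_deg: float = 15.0
    max_translate: float = 2.0
    #: move sizes shrink as sqrt(T/T_max) during annealing (floored at 0.15)
    scale_moves_with_t: bool = True
    #: excluded-volume weight is ramped geometrically from this fraction of
    #: its final value up to 1 across the ladder, so restraints can thread
    #: the chain early and sterics harden late (classic restrained-SA trick)
    clash_ramp_start: float = 0.01
    #: annealing cycles per trajectory; cycles after the first either reheat
    #: from the best state so far ("best") or restart from a new random
    #: placement ("fresh"), trading refinement depth for basin attempts
    n_cycles: int = 2
    restart_mode: str = "fresh"
    #: rigid-body-only pre-docking steps at the start of each cycle (soft
    #: sterics, restraints on): places the whole peptide in the
    #: data-consistent region before torsions anneal
    predock_steps: int = 3000
    predock_t: float = 2.0
    snapshot_interval: int = 50
    #: snapshots are only collected at reduced temperatures at or below this
    #: value (and with sterics fully on), so the selection pool holds
    #: converged conformers rather than mid-anneal states
    snapshot_t_max: float = 0.5
    n_trajectories: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if abs(self.p_pivot + self.p_rotate + self.p_translate - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")


# ---------------------------------------------------------------------------
# internal sampling machinery
# ---------------------------------------------------------------------------

def _rodrigues(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate row vectors ``v`` about unit ``axis`` by ``angle`` (radians)."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + np.outer(v @ axis, axis) * (1.0 - c)


class _System:
    """Precomputed index tables for fast energy evaluation.

    The full model is split into fixed atoms and moving atoms; restraint
    pseudo-positions anchored on fixed atoms are precomputed once.
    """

    def __init__(self, model: StructureModel, moving_mask: np.ndarray,
                 flexible_residues, peptide_chain: str, restraints,
                 energy: EnergyModel, collapse_selection=None,
                 pivot_direction: str = "C"):
        self.model = model
        self.moving = np.nonzero(moving_mask)[0]
        self.fixed = np.nonzero(~moving_mask)[0]
        self.energy = energy
        self.pot = energy.potential
        self.coords = model.coords.copy()
        radii = _radii_for(model, energy.radii, energy.radii_scale)
        self.r_moving = radii[self.moving]
        self.r_fixed = radii[self.fixed]

        # restraints → padded pseudo-position stacks for one vectorised pass;
        # an r⁻⁶ mean over a single point reduces to the plain distance, so
        # label-site fans and midpoint anchors share one code path
        moving_lookup = {int(g): l for l, g in enumerate(self.moving)}
        rows = []
        for r in restraints:
            idx = model.find_atom(r.chain_id, r.residue_number, r.atom_name)
            if idx is None:
                raise ValueError(f"restraint references absent atom "
                                 f"{r.chain_id}:{r.residue_number}:{r.atom_name}")
            a_pos = r.endpoint_a_positions(model)  # anchored on fixed receptor
            key = "mutagenesis_restraints" if r.source == "mutagenesis" else "pre_restraints"
            w = self.energy.weights.get(key, 0.0) * r.weight
            if w == 0.0:
                continue
            local = moving_lookup.get(int(idx))
            if local is None:
                raise ValueError("restraint endpoint atom is not a moving atom")
            rows.append((a_pos, local, r.lower, r.upper, w))
        if rows:
            p_max = max(len(a) for a, *_ in rows)
            self.rst_pts = np.full((len(rows), p_max, 3), 1e6)  # pad far away
            self.rst_mask = np.zeros((len(rows), p_max))
            for i, (a_pos, *_ ) in enumerate(rows):
                self.rst_pts[i, :len(a_pos)] = a_pos
                self.rst_mask[i, :len(a_pos)] = 1.0
            self.rst_npts = self.rst_mask.sum(axis=1)
            self.rst_local = np.array([r[1] for r in rows], dtype=int)
            self.rst_lower = np.array([r[2] for r in rows])
            self.rst_upper = np.array([r[3] for r in rows])
            self.rst_w = np.array([r[4] for r in rows])
        else:
            self.rst_pts = None

        # moving-moving clash radius matrix; excluded pairs (same/adjacent
        # residue, lower triangle) get zero contact radius
        mv = self.moving
        resnum = model.residue_numbers[mv]
        chain = model.chain_ids[mv]
        self.mm_rsum = self.r_moving[:, None] + self.r_moving[None, :]
        same_chain = chain[:, None] == chain[None, :]
        adjacent = same_chain & (np.abs(resnum[:, None] - resnum[None, :]) <= 1)
        self.mm_rsum[adjacent] = 0.0
        self.mm_rsum[np.tril_indices(len(mv))] = 0.0
        self.mm_rsum2 = self.mm_rsum ** 2
        resnum = model.residue_numbers
        chain = model.chain_ids

        # moving-fixed: exclude adjacent residues across the moving/fixed
        # boundary within the peptide chain (ternary anchor) by zeroing the
        # contact radius of excluded pairs
        self.mf_rsum = self.r_moving[:, None] + self.r_fixed[None, :]
        for a, ia in enumerate(self.moving):
            adj = ((chain[self.fixed] == chain[ia])
                   & (np.abs(resnum[self.fixed] - resnum[ia]) <= 1))
            self.mf_rsum[a, adj] = 0.0
        self.mf_rsum2 = self.mf_rsum ** 2
        self.fixed_coords = self.coords[self.fixed]
        self._fixed_t = self.fixed_coords.T.copy()
        self._fixed_sq = np.einsum("ij,ij->i", self.fixed_coords, self.fixed_coords)

        # inter-chain backbone H-bond partners (moving H vs fixed O and
        # moving O vs fixed H), different chains only
        self.hb_pairs = []
        if energy.weights.get("hbond", 0.0) > 0 and energy.hbond_epsilon > 0:
            names = model.atom_names
            chains = model.chain_ids
            for a_name, b_name in (("H", "O"), ("O", "H")):
                mv_sel = np.array([l for l, g in enumerate(self.moving)
                                   if names[g] == a_name], dtype=int)
                fx_sel = np.array([f for f, g in enumerate(self.fixed)
                                   if names[g] == b_name], dtype=int)
                if len(mv_sel) and len(fx_sel):
                    # exclude same-chain partners (intra-chain H-bonds are
                    # not part of this coarse reward)
                    mv_ch = chains[self.moving[mv_sel]]
                    fx_ch = chains[self.fixed[fx_sel]]
                    ok = mv_ch[:, None] != fx_ch[None, :]
                    self.hb_pairs.append((mv_sel, self.fixed_coords[fx_sel], ok))

        # collapse selection: split into fixed and moving parts
        self.collapse_fixed = self.collapse_moving_local = None
        if collapse_selection is not None and energy.rg_target is not None:
            sel = model.select(collapse_selection)
            self.collapse_fixed = self.coords[np.intersect1d(sel, self.fixed)]
            mv_sel = np.intersect1d(sel, self.moving)
            self.collapse_moving_local = np.searchsorted(self.moving, mv_sel)

        # torsion move table
        self.torsions = self._build_torsions(flexible_residues, peptide_chain,
                                             pivot_direction)

    # -- torsion table -------------------------------------------------------

    def _build_torsions(self, flexible_residues, chain, direction):
        model = self.model
        chain_mask = model.chain_ids == chain
        moving_set = set(self.moving.tolist())
        local = {g: l for l, g in enumerate(self.moving)}
        atom_of = {}
        for i in np.nonzero(chain_mask)[0]:
            atom_of[(int(model.residue_numbers[i]), model.atom_names[i])] = i
        torsions = []
        flex = sorted(int(r) for r in flexible_residues)
        chain_res = sorted({int(r) for r in model.residue_numbers[chain_mask]})
        for r in flex:
            n_i = atom_of.get((r, "N"))
            ca_i = atom_of.get((r, "CA"))
            c_i = atom_of.get((r, "C"))
            if n_i is None or ca_i is None or c_i is None:
                continue
            later = [atom_of[(rr, a)] for rr in chain_res if rr > r
                     for a in PEPTIDE_ATOMS if (rr, a) in atom_of]
            earlier = [atom_of[(rr, a)] for rr in chain_res if rr < r
                       for a in PEPTIDE_ATOMS if (rr, a) in atom_of]
            phi_c = [atom_of[(r, a)] for a in ("C", "O", "CB")
                     if (r, a) in atom_of] + later
            psi_c = ([atom_of[(r, "O")]] if (r, "O") in atom_of else []) + later
            phi_n = earlier + ([atom_of[(r, "H")]] if (r, "H") in atom_of else [])
            psi_n = earlier + [atom_of[(r, a)] for a in ("N", "H", "CB")
                               if (r, a) in atom_of]
            if direction == "C":
                phi_rot, psi_rot = phi_c, psi_c
            elif direction == "N":  # C-terminal anchor stays put
                phi_rot, psi_rot = phi_n, psi_n
            else:  # unanchored chain: rotate the smaller side (local moves)
                phi_rot = phi_c if len(phi_c) <= len(phi_n) else phi_n
                psi_rot = psi_c if len(psi_c) <= len(psi_n) else psi_n
            c_prev = atom_of.get((r - 1, "C"))
            n_next = atom_of.get((r + 1, "N"))
            phi_meas = ((c_prev, n_i, ca_i, c_i) if c_prev is not None else None)
            psi_meas = ((n_i, ca_i, c_i, n_next) if n_next is not None else None)
            for axis, rot, meas, bounds in (
                    ((n_i, ca_i), phi_rot, phi_meas, PHI_BOUNDS),
                    ((ca_i, c_i), psi_rot, psi_meas, PSI_BOUNDS)):
                rot = [i for i in rot if i in moving_set]
                if rot:
                    torsions.append((axis[0], axis[1],
                                     np.array([local[i] for i in rot], dtype=int),
                                     meas, bounds))
        if not torsions:
            raise ValueError("no torsion moves available for the flexible residues")
        return torsions

    # -- energy --------------------------------------------------------------

    def eval_energy(self, moving_coords: np.ndarray,
                    clash_scale: float = 1.0) -> float:
        e = 0.0
        w_clash = self.energy.weights.get("clash", 0.0) * clash_scale
        if w_clash > 0:
            d2 = cdist(moving_coords, moving_coords, "sqeuclidean")
            hit = d2 < self.mm_rsum2
            if hit.any():
                ov = self.mm_rsum[hit] - np.sqrt(d2[hit])
                e += w_clash * self.energy.clash_k * float(ov @ ov)
            if len(self.fixed):
                d2 = cdist(moving_coords, self.fixed_coords, "sqeuclidean")
                hit = d2 < self.mf_rsum2
                if hit.any():
                    ov = self.mf_rsum[hit] - np.sqrt(d2[hit])
                    e += w_clash * self.energy.clash_k * float(ov @ ov)
        w_hb = self.energy.weights.get("hbond", 0.0)
        if w_hb > 0 and self.hb_pairs:
            eps, d0, width = (self.energy.hbond_epsilon, self.energy.hbond_d0,
                              self.energy.hbond_width)
            for mv_sel, fx_coords, ok in self.hb_pairs:
                d = cdist(moving_coords[mv_sel], fx_coords)
                u = 1.0 - ((d - d0) / width) ** 2
                u[(u <= 0) | ~ok] = 0.0
                if u.any():
                    # at most one H-bond credited per donor/acceptor atom
                    e -= w_hb * eps * float(np.sum(u.max(axis=1)))
        if self.rst_pts is not None:
            b = moving_coords[self.rst_local]
            diff = self.rst_pts - b[:, None, :]
            d2 = np.einsum("ijk,ijk->ij", diff, diff)
            inv6 = (d2 * d2 * d2) ** -1 * self.rst_mask
            d_eff = (inv6.sum(axis=1) / self.rst_npts) ** (-1.0 / 6.0)
            over = np.clip(d_eff - self.rst_upper, 0.0, None)
            under = np.clip(self.rst_lower - d_eff, 0.0, None)
            viol = over + under
            if viol.any():
                e += self.pot.k * float(self.rst_w @ (viol * viol))
        if self.collapse_moving_local is not None:
            pts = np.vstack([self.collapse_fixed,
                             moving_coords[self.collapse_moving_local]])
            centroid = pts.mean(axis=0)
            rg = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
            if rg > self.energy.rg_target:
                e += (self.energy.weights.get("rg_collapse", 0.0) * self.energy.rg_k
                      * (rg - self.energy.rg_target) ** 2)
        return e

    # -- moves ---------------------------------------------------------------

    def propose(self, moving_coords, rng, cfg: SamplerConfig, allow_rigid: bool,
                scale: float = 1.0):
        """Return proposed moving-atom coordinates (input is never mutated)."""
        u = rng.random()
        if (not allow_rigid) or u < cfg.p_pivot:
            new = moving_coords.copy()
            ax_a, ax_b, rot_local, meas, bounds = \
                self.torsions[rng.integers(len(self.torsions))]
            angle = np.deg2rad(rng.normal(0.0, scale * cfg.max_torsion_deg / 2.0))
            # axis atoms may themselves be moving atoms → take current coords
            pa = self._current_pos(moving_coords, ax_a)
            pb = self._current_pos(moving_coords, ax_b)
            axis = pb - pa
            axis /= np.sqrt(axis @ axis)
            new[rot_local] = _rodrigues(moving_coords[rot_local] - pa, axis, angle) + pa
            if meas is not None:
                from .structures import dihedral
                pts = [self._current_pos(new, g) for g in meas]
                val = dihedral(*pts)
                if not (bounds[0] <= val <= bounds[1]):
                    return None  # outside the allowed backbone basin
        elif u < cfg.p_pivot + cfg.p_rotate:
            centroid = moving_coords.mean(axis=0)
            axis = rng.normal(size=3)
            axis /= np.sqrt(axis @ axis)
            angle = np.deg2rad(rng.normal(0.0, scale * cfg.max_rotate_deg / 2.0))
            new = _rodrigues(moving_coords - centroid, axis, angle) + centroid
        else:
            new = moving_coords + rng.normal(0.0, scale * cfg.max_translate / 2.0,
                                             size=3)
        return new

    def _current_pos(self, moving_coords, global_idx):
        local = np.searchsorted(self.moving, global_idx)
        if local < len(self.moving) and self.moving[local] == global_idx:
            return moving_coords[local]
        return self.coords[global_idx]


def _anneal(system: _System, moving_coords: np.ndarray, cfg: SamplerConfig,
            rng, allow_rigid: bool, collect_snapshots: bool = True,
            restart_fn=None):
    """Run one annealing trajectory; returns (snapshots, final, diagnostics).

    The trajectory consists of ``cfg.n_cycles`` annealing cycles over the
    temperature ladder; the first cycle ramps the excluded-volume weight
    (threading stage), later cycles reheat from the best state found so far
    with sterics fully on. Step counts are weighted towards the cold stages,
    where restraint refinement happens.
    """
    ladder = list(cfg.temperature_ladder)
    n_stages = len(ladder)
    # pre-docking steps come out of the overall step budget
    n_predock = cfg.predock_steps * max(1, cfg.n_cycles) if allow_rigid else 0
    budget = max(n_stages * max(1, cfg.n_cycles), cfg.n_steps - n_predock)
    # low-T stages get proportionally more steps (weight 1 → 2 across ladder)
    stage_w = np.linspace(1.0, 2.0, n_stages)
    stage_steps = np.maximum(1, np.round(
        stage_w / stage_w.sum() * budget / max(1, cfg.n_cycles))).astype(int)
    snapshots = []
    diagnostics = []
    accepted_since_snap = 0
    t_max = max(ladder)
    best = (np.inf, moving_coords.copy())
    start_coords = moving_coords.copy()
    for cycle in range(max(1, cfg.n_cycles)):
        ramp_on = n_stages > 1 and cfg.clash_ramp_start < 1.0
        if cycle == 0:
            clash_ramp = (np.geomspace(max(cfg.clash_ramp_start, 1e-6), 1.0,
                                       n_stages) if ramp_on else np.ones(n_stages))
        elif cfg.restart_mode == "fresh" and restart_fn is not None:
            moving_coords = restart_fn(rng)
            clash_ramp = (np.geomspace(max(cfg.clash_ramp_start, 1e-6), 1.0,
                                       n_stages) if ramp_on else np.ones(n_stages))
        else:
            clash_ramp = np.ones(n_stages)
            moving_coords = best[1].copy()
        if allow_rigid and cfg.predock_steps > 0 and (
                cycle == 0 or cfg.restart_mode == "fresh"):
            rigid_cfg = SamplerConfig(
                n_steps=1, p_pivot=0.0, p_rotate=0.5, p_translate=0.5,
                max_rotate_deg=cfg.max_rotate_deg * 2,
                max_translate=cfg.max_translate * 2, seed=0)
            e_cur = system.eval_energy(moving_coords, cfg.clash_ramp_start)
            for _ in range(cfg.predock_steps):
                proposal = system.propose(moving_coords, rng, rigid_cfg, True)
                if proposal is None:
                    continue
                e_new = system.eval_energy(proposal, cfg.clash_ramp_start)
                d_e = e_new - e_cur
                if d_e <= 0 or rng.random() < np.exp(-d_e / cfg.predock_t):
                    moving_coords = proposal
                    e_cur = e_new
        for stage, t_red in enumerate(ladder):
            clash_scale = float(clash_ramp[stage])
            e_cur = system.eval_energy(moving_coords, clash_scale)
            scale = (max(0.15, np.sqrt(t_red / t_max))
                     if cfg.scale_moves_with_t else 1.0)
            accepted_stage = 0
            for _ in range(int(stage_steps[stage])):
                proposal = system.propose(moving_coords, rng, cfg, allow_rigid, scale)
                if proposal is None:  # torsion left the allowed basin
                    continue
                e_new = system.eval_energy(proposal, clash_scale)
                d_e = e_new - e_cur
                if d_e <= 0 or rng.random() < np.exp(-d_e / t_red):
                    moving_coords = proposal
                    e_cur = e_new
                    accepted_stage += 1
                    accepted_since_snap += 1
                    if clash_scale >= 1.0 and e_cur < best[0]:
                        best = (e_cur, moving_coords.copy())
                    # snapshots only from cold, fully-steric stages, so the
                    # pool never contains threading or mid-anneal geometries
                    if (collect_snapshots and clash_scale >= 0.99
                            and t_red <= cfg.snapshot_t_max
                            and accepted_since_snap >= cfg.snapshot_interval):
                        snapshots.append((moving_coords.copy(), e_cur))
                        accepted_since_snap = 0
            if accepted_stage == 0:
                diagnostics.append(f"zero acceptance at reduced temperature {t_red}")
    if not np.isfinite(best[0]):
        best = (system.eval_energy(moving_coords), moving_coords)
    if collect_snapshots and not snapshots:
        snapshots.append((best[1].copy(), best[0]))
    return snapshots, best[::-1], diagnostics


def merge_models(*models: StructureModel, model_id: int = 1,
                 metadata: dict | None = None) -> StructureModel:
    """Concatenate models (e.g. receptor + peptide [+ DNA]) into one."""
    return StructureModel(
        np.concatenate([m.chain_ids for m in models]),
        np.concatenate([m.residue_numbers for m in models]),
        np.concatenate([m.residue_names for m in models]),
        np.concatenate([m.atom_names for m in models]),
        np.concatenate([m.elements for m in models]),
        np.vstack([m.coords for m in models]),
        model_id=model_id, metadata=metadata)


# ---------------------------------------------------------------------------
# binary complex sampling
# ---------------------------------------------------------------------------

def sample_complex(receptor: StructureModel, peptide: StructureModel,
                   restraints, energy: EnergyModel, cfg: SamplerConfig):
    """Annealed MC sampling of a fully flexible peptide on a rigid receptor.

    Runs ``cfg.n_trajectories`` independent trajectories (sub-seeded from
    ``cfg.seed``), each starting from a random rigid-body placement of the
    input peptide conformation. Snapshots are taken every
    ``cfg.snapshot_interval`` accepted moves and pooled across trajectories.

    Returns ``(ensemble, energy_log)`` where the log is a DataFrame with one
    row per snapshot (trajectory, snapshot index, energy). Identical seeds
    give identical trajectories.
    """
    peptide_chain = peptide.chain_ids[0]
    full = merge_models(receptor, peptide)
    moving_mask = full.chain_ids == peptide_chain
    flexible = sorted(set(peptide.residue_numbers.tolist()))
    system = _System(full, moving_mask, flexible, peptide_chain, restraints,
                     energy, pivot_direction="auto")
    rec_centroid = receptor.coords.mean(axis=0)
    rec_extent = float(np.max(np.linalg.norm(receptor.coords - rec_centroid, axis=1)))
    models = []
    log_rows = []
    all_diag = []
    template = full.coords[system.moving].copy()

    def random_placement(rng):
        # random rigid-body placement of the input conformation around the
        # receptor surface
        pep_centroid = template.mean(axis=0)
        pep_extent = float(np.max(np.linalg.norm(template - pep_centroid, axis=1)))
        rot = Rotation.random(random_state=np.random.RandomState(
            int(rng.integers(2 ** 31 - 1))))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        new_centroid = rec_centroid + direction * (rec_extent + 0.5 * pep_extent + 5.0)
        return rot.apply(template - pep_centroid) + new_centroid

    for traj in range(cfg.n_trajectories):
        rng = np.random.default_rng([int(cfg.seed), traj])
        start = random_placement(rng)
        snaps, _, diag = _anneal(system, start, cfg, rng, allow_rigid=True,
                                 restart_fn=random_placement)
        all_diag.extend(f"trajectory {traj}: {d}" for d in diag)
        for k, (coords, e) in enumerate(snaps):
            m = full.copy()
            m.coords[system.moving] = coords
            m.model_id = len(models) + 1
            m.metadata = {"energy": e, "trajectory": traj, "snapshot": k,
                          "seed": int(cfg.seed)}
            models.append(m)
            log_rows.append({"trajectory": traj, "snapshot": k, "energy": e})
    ensemble = Ensemble(models, validate=False)
    log = pd.DataFrame(log_rows)
    log.attrs["diagnostics"] = all_diag
    return ensemble, log


# ---------------------------------------------------------------------------
# ternary (peptide–domain–DNA) protocol
# ---------------------------------------------------------------------------

@dataclass
class TernaryConfig:
    """Ternary extension settings.

    The receptor and DNA backbones are fixed; the already-determined bound
    peptide segment (``rigid_segment``) moves with them as one rigid body;
    only ``mobile_segment`` torsions are sampled, under the collapse term on
    ``collapse_selection``.
    """

    template: StructureModel | None = None
    receptor_chain: str = "A"
    peptide_chain: str = "B"
    dna_chains: tuple = ("D", "E")
    rigid_segment: tuple = (51, 80)
    mobile_segment: tuple = (11, 45)
    collapse_selection: str = ""
    superpose_selection: str = ""
    n_structures: int = 120
    n_select: int = 20
    dna_n_bp: int = 12
    randomize_max_tries: int = 100

    def __post_init__(self):
        if not (self.n_select <= self.n_structures):
            raise ValueError("n_select must not exceed n_structures")
        if not (self.mobile_segment[1] < self.rigid_segment[0]
                or self.rigid_segment[1] < self.mobile_segment[0]):
            raise ValueError("rigid and mobile segments must be disjoint")


def build_bform_dna(n_bp: int = 12, center=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
                    chains=("D", "E")) -> StructureModel:
    """Ideal B-form phosphate-backbone trace (P atoms only).

    Two antiparallel strands, rise 3.4 Å, twist 36° per base pair, P atoms at
    9.4 Å radius; base identity alternates A/T. Coarse by design: the DNA is
    rigid scenery for the collapse term, not a nucleic-acid model.
    """
    rise, twist, radius = 3.4, np.deg2rad(36.0), 9.4
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    # orthonormal frame around the axis
    seed_vec = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed_vec, axis)) > 0.9:
        seed_vec = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, seed_vec)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    center = np.asarray(center, dtype=float)
    z0 = -(n_bp - 1) * rise / 2.0
    names, resnums, chain_ids, coords = [], [], [], []
    groove = np.deg2rad(154.0)  # strand-2 angular offset (minor groove)
    for i in range(n_bp):
        theta = i * twist
        z = z0 + i * rise
        p1 = center + radius * (np.cos(theta) * u + np.sin(theta) * v) + z * axis
        p2 = center + radius * (np.cos(theta + groove) * u
                                + np.sin(theta + groove) * v) + z * axis
        chain_ids += [chains[0]]
        resnums += [i + 1]
        names += ["DA" if i % 2 == 0 else "DT"]
        coords.append(p1)
        chain_ids += [chains[1]]
        resnums += [n_bp - i]
        names += ["DT" if i % 2 == 0 else "DA"]
        coords.append(p2)
    order = np.lexsort((resnums, chain_ids))
    return StructureModel(
        np.array(chain_ids)[order], np.array(resnums)[order],
        np.array(names)[order], np.array(["P"] * len(coords))[order],
        np.array(["P"] * len(coords))[order], np.array(coords)[order])


def _prepend_residues(peptide: StructureModel, new_resnums, sequence: dict,
                      rng, fixed_context: np.ndarray, radii_scale=0.85,
                      max_tries: int = 100) -> StructureModel:
    """Extend a peptide N-terminally with ideal-geometry residues.

    New residues are grown backwards from the current first residue with
    coil-like torsions, re-drawn (up to ``max_tries``) until the grown atoms
    neither clash with the context coordinates nor with the peptide.
    """
    from .structures import BOND_C_O, BOND_N_H, BOND_CA_CB, ANG_CA_C_O

    first = int(peptide.residue_numbers.min())
    chain = peptide.chain_ids[0]

    def backbone(resnum, atom):
        i = peptide.find_atom(chain, resnum, atom)
        return peptide.coords[i]

    # the junction residue is covalently bonded to the first grown residue
    # and must not count as clash context
    not_junction = peptide.residue_numbers != first
    context_all = np.vstack([fixed_context, peptide.coords[not_junction]])

    def grow_residue(resnum, n_r, ca_r, c_r, built, tries=40):
        """Sequential chain growth: redraw torsions until this residue fits."""
        for _ in range(tries):
            phi = rng.uniform(-150.0, -60.0)
            psi = rng.uniform(-60.0, 160.0)
            c_prev = place_atom(c_r, ca_r, n_r, BOND_C_N, ANG_C_N_CA, phi)
            ca_prev = place_atom(ca_r, n_r, c_prev, BOND_CA_C, ANG_CA_C_N, 180.0)
            n_prev = place_atom(n_r, c_prev, ca_prev, BOND_N_CA, ANG_N_CA_C, psi)
            o_prev = place_atom(n_prev, ca_prev, c_prev, BOND_C_O, ANG_CA_C_O,
                                psi + 180.0)
            uu = ca_prev - n_prev
            uu /= np.linalg.norm(uu)
            h_dir = -(uu + np.array([0.3, 0.3, 0.3]))
            h_prev = n_prev + BOND_N_H * h_dir / np.linalg.norm(h_dir)
            un = n_prev - ca_prev
            uc = c_prev - ca_prev
            un, uc = un / np.linalg.norm(un), uc / np.linalg.norm(uc)
            bisect = un + uc
            bisect /= np.linalg.norm(bisect)
            perp = np.cross(un, uc)
            perp /= np.linalg.norm(perp)
            cb_dir = (-bisect * np.sin(np.deg2rad(54.0))
                      + perp * np.cos(np.deg2rad(54.0)))
            cb_prev = ca_prev + BOND_CA_CB * cb_dir
            atoms = np.array([n_prev, h_prev, ca_prev, c_prev, o_prev, cb_prev])
            # new residue must clear the context (bonded neighbours excluded
            # by the 2.0 Å threshold being below bond-adjacent distances)
            if cdist(atoms, context_all).min() < 2.4:
                continue
            # self-avoidance against earlier-grown residues (the directly
            # bonded neighbour is exempt)
            if len(built) > 1 and cdist(atoms, np.vstack(built[:-1])).min() < 2.0:
                continue
            return atoms
        return None

    for attempt in range(max_tries):
        coords_new = []
        rows = []
        built = []
        n_r = backbone(first, "N")
        ca_r = backbone(first, "CA")
        c_r = backbone(first, "C")
        ok = True
        for resnum in sorted(new_resnums, reverse=True):
            atoms = grow_residue(resnum, n_r, ca_r, c_r, built)
            if atoms is None:
                ok = False
                break
            built.append(atoms)
            res1 = sequence.get(resnum, "A")
            for atom, pos in zip(("N", "H", "CA", "C", "O", "CB"), atoms):
                rows.append((chain, resnum, res1, atom))
                coords_new.append(pos)
            n_r, ca_r, c_r = atoms[0], atoms[2], atoms[3]
        if ok:
            new_xyz = np.array(coords_new)
            break
    else:
        raise RuntimeError(f"could not grow a clash-free N-terminal extension "
                           f"in {max_tries} tries")
    from .shift_analysis import AA1_TO_3
    order = np.argsort([r[1] for r in rows], kind="stable")
    ext = StructureModel(
        [rows[i][0] for i in order], [rows[i][1] for i in order],
        [AA1_TO_3.get(rows[i][2], rows[i][2]) for i in order],
        [rows[i][3] for i in order],
        [("N" if rows[i][3] in ("N",) else "H" if rows[i][3] == "H"
          else "O" if rows[i][3] == "O" else "C") for i in order],
        new_xyz[order])
    return merge_models(ext, peptide, model_id=peptide.model_id,
                        metadata=dict(peptide.metadata))


def build_ternary_start(binary_model: StructureModel, cfg: TernaryConfig,
                        seed: int = 0, sequence: dict | None = None) -> StructureModel:
    """Assemble the ternary starting structure.

    The binary-complex receptor is superposed onto the template receptor
    backbone, the template DNA is copied in, and any mobile-segment residues
    absent from the binary model are grown N-terminally with clash-free
    coil torsions.
    """
    from .structures import superpose

    rng = np.random.default_rng([int(seed), 9001])
    rec_mask = binary_model.chain_ids == cfg.receptor_chain
    if cfg.template is not None:
        sel = cfg.superpose_selection or f"{cfg.receptor_chain}::N,CA,C"
        tf, _ = superpose(binary_model, cfg.template, sel)
        placed = tf.apply_model(binary_model)
        dna_mask = np.isin(cfg.template.chain_ids, list(cfg.dna_chains))
        if not dna_mask.any():
            raise ValueError("template carries no DNA chains")
        dna = StructureModel(
            cfg.template.chain_ids[dna_mask], cfg.template.residue_numbers[dna_mask],
            cfg.template.residue_names[dna_mask], cfg.template.atom_names[dna_mask],
            cfg.template.elements[dna_mask], cfg.template.coords[dna_mask])
    else:
        # toy mode: ideal B-DNA placed on the far side of the receptor
        placed = binary_model.copy()
        rec_centroid = binary_model.coords[rec_mask].mean(axis=0)
        pep_mask = binary_model.chain_ids == cfg.peptide_chain
        away = rec_centroid - binary_model.coords[pep_mask].mean(axis=0)
        away /= np.linalg.norm(away)
        rec_extent = float(np.max(np.linalg.norm(
            binary_model.coords[rec_mask] - rec_centroid, axis=1)))
        center = rec_centroid + away * (rec_extent + 11.0)
        axis = np.cross(away, [0.0, 0.0, 1.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(away, [0.0, 1.0, 0.0])
        dna = build_bform_dna(cfg.dna_n_bp, center=center, axis=axis,
                              chains=cfg.dna_chains)
    full = merge_models(placed, dna, metadata={"seed": int(seed)})
    # grow missing mobile residues
    pep_mask = full.chain_ids == cfg.peptide_chain
    present = set(int(r) for r in full.residue_numbers[pep_mask])
    missing = [r for r in range(cfg.mobile_segment[0], cfg.mobile_segment[1] + 1)
               if r not in present]
    if missing:
        pep_idx = np.nonzero(pep_mask)[0]
        peptide = StructureModel(
            full.chain_ids[pep_idx], full.residue_numbers[pep_idx],
            full.residue_names[pep_idx], full.atom_names[pep_idx],
            full.elements[pep_idx], full.coords[pep_idx])
        context = full.coords[~pep_mask]
        peptide = _prepend_residues(peptide, missing, sequence or {}, rng,
                                    context, max_tries=cfg.randomize_max_tries)
        others_idx = np.nonzero(~pep_mask)[0]
        others = StructureModel(
            full.chain_ids[others_idx], full.residue_numbers[others_idx],
            full.residue_names[others_idx], full.atom_names[others_idx],
            full.elements[others_idx], full.coords[others_idx])
        full = merge_models(others, peptide, metadata={"seed": int(seed)})
    return full


def sample_ternary(start: StructureModel, energy: EnergyModel,
                   cfg: TernaryConfig, sampler_cfg: SamplerConfig):
    """Randomize-then-anneal protocol for the ternary complex.

    ``cfg.n_structures`` independent runs each randomize the mobile-segment
    torsions and anneal with only those torsions active (receptor, DNA and
    the rigid peptide segment never move). Returns
    ``(all_ensemble, energies, selected_ensemble)`` with structures ranked by
    final energy and the ``cfg.n_select`` lowest-energy subset.
    """
    pep = start.chain_ids == cfg.peptide_chain
    mobile_lo, mobile_hi = cfg.mobile_segment
    moving_mask = pep & (start.residue_numbers >= mobile_lo) \
        & (start.residue_numbers <= mobile_hi)
    if not moving_mask.any():
        raise ValueError("mobile segment absent from the start structure")
    flexible = sorted(set(int(r) for r in start.residue_numbers[moving_mask]))
    collapse = cfg.collapse_selection or None
    system = _System(start, moving_mask, flexible, cfg.peptide_chain,
                     restraints=(), energy=energy,
                     collapse_selection=collapse, pivot_direction="N")
    results = []
    for k in range(cfg.n_structures):
        rng = np.random.default_rng([int(sampler_cfg.seed), 77, k])
        coords = start.coords[system.moving].copy()
        # randomization stage: large random torsions, keep if not clashing badly
        for _ in range(cfg.randomize_max_tries):
            trial = coords.copy()
            rand_cfg = SamplerConfig(n_steps=1, p_pivot=1.0, p_rotate=0.0,
                                     p_translate=0.0, max_torsion_deg=120.0,
                                     seed=0)
            for _ in range(len(flexible)):
                nxt = system.propose(trial, rng, rand_cfg, allow_rigid=False)
                if nxt is not None:
                    trial = nxt
            if system.eval_energy(trial) < 1e3:
                coords = trial
                break
        else:
            raise RuntimeError("could not randomize the mobile segment without "
                               "irresolvable clashes")
        _, (final_coords, e_final), _ = _anneal(system, coords, sampler_cfg, rng,
                                                allow_rigid=False,
                                                collect_snapshots=False)
        m = start.copy()
        m.coords[system.moving] = final_coords
        m.model_id = k + 1
        m.metadata = {"energy": e_final, "run": k, "seed": int(sampler_cfg.seed)}
        results.append((e_final, m))
    order = np.argsort([e for e, _ in results], kind="stable")
    ranked = [results[i][1] for i in order]
    energies = [results[i][0] for i in order]
    for rank, m in enumerate(ranked):
        m.model_id = rank + 1
    all_ensemble = Ensemble(ranked, validate=False)
    selected = Ensemble(ranked[:cfg.n_select], validate=False)
    return all_ensemble, np.array(energies), selected
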