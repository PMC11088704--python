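"""Ground-truth toy complexes and simulated NMR observables.

Everything downstream of the experiment can be exercised without any
deposited data: a small β-sheet receptor with three cysteine-like label
sites, a 35-residue disordered peptide whose central segment docks as an
extra edge strand (the ground-truth pose), Γ2 profiles following the
r⁻⁶ Solomon–Bloembergen law with multiplicative Gaussian noise and an
exchange-broadened missing block, and free/bound shift tables with a
localised CSP hotspot plus a β-propensity segment.

Every generator is deterministic in its seed. Noise is multiplicative on Γ2
(PRE measurement errors grow with the rate itself).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pre_analysis import PREProfile, SBParameters, backcalc_profile
from .shift_analysis import AA1_TO_3, RandomCoilTable, ShiftTable
from .structures import (Ensemble, LabelSite, StructureModel, build_backbone,
                         superpose, write_structure)

__all__ = [
    "SyntheticComplexSpec",
    "NoiseModel",
    "make_toy_complex",
    "default_label_sites",
    "simulate_pre",
    "simulate_shifts",
    "write_fixtures",
    "peptide_from_torsions",
]

#: default peptide sequence, residues 46..80 — lysine cluster at the
#: N-terminus, V at 51, a VQ pair at 63-64 and an aromatic anchor at 58
DEFAULT_PEPTIDE_SEQ = "KKKSTVEDSLNKFRELIVQLTAEDASTNLEKSAQS"

STRAND_PHI, STRAND_PSI = -120.0, 130.0
SHEET_SPACING = 5.2  # Å between adjacent strands

DEFAULT_SHIFT_NOISE = {"H": 0.005, "N": 0.03, "CA": 0.05, "CB": 0.05}


@dataclass
class SyntheticComplexSpec:
    """Blueprint of the toy complex (sizes, numbering, seed)."""

    receptor_n_strands: int = 5
    strand_length: int = 8
    receptor_first_residue: int = 351
    receptor_chain: str = "A"
    label_sites: tuple = (360, 377, 390)
    peptide_length: int = 35
    peptide_first_residue: int = 46
    peptide_chain: str = "B"
    peptide_sequence: str = DEFAULT_PEPTIDE_SEQ
    bound_segment: tuple = (51, 66)
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.bound_segment
        first, last = self.peptide_first_residue, self.peptide_last_residue
        if not (first <= lo <= hi <= last):
            raise ValueError("bound_segment must lie within the peptide")
        rec_last = (self.receptor_first_residue
                    + self.receptor_n_strands * self.strand_length - 1)
        for s in self.label_sites:
            if not (self.receptor_first_residue <= s <= rec_last):
                raise ValueError(f"label site {s} not on the receptor")
        if len(self.peptide_sequence) != self.peptide_length:
            raise ValueError("peptide_sequence length mismatch")

    @property
    def peptide_last_residue(self) -> int:
        return self.peptide_first_residue + self.peptide_length - 1

    def peptide_residues(self):
        return list(range(self.peptide_first_residue, self.peptide_last_residue + 1))

    def residue_name(self, resnum: int) -> str:
        return self.peptide_sequence[resnum - self.peptide_first_residue]


@dataclass
class NoiseModel:
    """Measurement-noise settings for the simulated observables."""

    gamma_noise_cv: float = 0.10
    missing_residues: frozenset = frozenset(range(52, 58))
    gamma_max: float = 150.0  # s⁻¹ detection ceiling; faster-relaxing residues vanish
    shift_noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_SHIFT_NOISE))
    csp_amplitude_median: float = 0.08  # ppm, log-normal median of hotspot CSPs
    csp_amplitude_sigma: float = 0.5    # log-normal shape
    strand_fraction: float = 0.6        # fractional β population in the bound segment

    def __post_init__(self):
        if self.gamma_noise_cv < 0:
            raise ValueError("gamma_noise_cv must be >= 0")
        if any(v < 0 for v in self.shift_noise_sd.values()):
            raise ValueError("shift noise sd must be >= 0")


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def peptide_from_torsions(spec: SyntheticComplexSpec, phi, psi,
                          chain: str | None = None) -> StructureModel:
    """Build the toy peptide (N/H/CA/C/O/CB per residue) from φ/ψ lists."""
    bb = build_backbone(phi, psi)
    chain = chain or spec.peptide_chain
    chain_ids, resnums, resnames, atoms, elements, coords = [], [], [], [], [], []
    for i, resnum in enumerate(spec.peptide_residues()):
        res3 = AA1_TO_3.get(spec.residue_name(resnum), "ALA")
        for atom in ("N", "H", "CA", "C", "O", "CB"):
            chain_ids.append(chain)
            resnums.append(resnum)
            resnames.append(res3)
            atoms.append(atom)
            elements.append(atom[0] if atom[0] in "NHOC" else "C")
            coords.append(bb[atom][i])
    return StructureModel(chain_ids, resnums, resnames, atoms, elements,
                          np.array(coords))


def _build_receptor(spec: SyntheticComplexSpec) -> StructureModel:
    """Parallel β-sheet: n identical extended strands at 5 Å spacing.

    Residue names cycle through a fixed menu; label-site residues are CYS.
    """
    menu = ["THR", "ILE", "VAL", "GLU", "LEU", "SER", "LYS", "ALA"]
    n_res = spec.strand_length
    bb = build_backbone([STRAND_PHI] * n_res, [STRAND_PSI] * n_res)
    # strand axis: direction from first to last CA
    axis = bb["CA"][-1] - bb["CA"][0]
    axis /= np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    perp = np.cross(axis, ref)
    perp /= np.linalg.norm(perp)
    chain_ids, resnums, resnames, atoms, elements, coords = [], [], [], [], [], []
    resnum = spec.receptor_first_residue
    for s in range(spec.receptor_n_strands):
        offset = perp * (s * SHEET_SPACING)
        for i in range(n_res):
            res3 = "CYS" if resnum in spec.label_sites else menu[(s + i) % len(menu)]
            for atom in ("N", "H", "CA", "C", "O", "CB"):
                chain_ids.append(spec.receptor_chain)
                resnums.append(resnum)
                resnames.append(res3)
                atoms.append(atom)
                elements.append(atom[0])
                coords.append(bb[atom][i] + offset)
            resnum += 1
    return StructureModel(chain_ids, resnums, resnames, atoms, elements,
                          np.array(coords))


def _coil_torsions(rng, n):
    """Coil-like (φ, ψ) draws spanning the broad allowed basin."""
    phi = rng.uniform(-150.0, -60.0, size=n)
    psi = np.where(rng.random(n) < 0.6,
                   rng.uniform(90.0, 170.0, size=n),
                   rng.uniform(-60.0, 0.0, size=n))
    return phi, psi


def _peptide_clash(pep: StructureModel, receptor: StructureModel | None,
                   cutoff_self=1.8, cutoff_rec=2.6) -> bool:
    from scipy.spatial.distance import cdist

    d_self = cdist(pep.coords, pep.coords)
    sep = np.abs(pep.residue_numbers[:, None] - pep.residue_numbers[None, :])
    mask = sep >= 2
    if np.any(d_self[mask] < cutoff_self):
        return True
    if receptor is not None:
        if np.min(cdist(pep.coords, receptor.coords)) < cutoff_rec:
            return True
    return False


def make_toy_complex(spec: SyntheticComplexSpec, max_tries: int = 300):
    """Deterministic toy complex with a known bound pose.

    Returns ``(receptor, peptide_bound_truth, peptide_free)``. The bound
    segment is an extended strand docked along the receptor's edge strand
    (one sheet spacing outside it); flanking residues carry clash-free coil
    torsions. The free peptide is an independent self-avoiding coil.
    """
    rng = np.random.default_rng([int(spec.seed), 11])
    receptor = _build_receptor(spec)

    # target CA positions for the docked segment: edge-strand geometry moved
    # one spacing further out
    n_res = spec.strand_length
    bb = build_backbone([STRAND_PHI] * n_res, [STRAND_PSI] * n_res)
    axis = bb["CA"][-1] - bb["CA"][0]
    axis /= np.linalg.norm(axis)
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    edge_offset = perp * (spec.receptor_n_strands * SHEET_SPACING)

    lo, hi = spec.bound_segment
    residues = spec.peptide_residues()
    n_pep = len(residues)
    seg_idx = [i for i, r in enumerate(residues) if lo <= r <= hi]
    n_anchor = min(len(seg_idx), n_res)

    from .modeling import clash_energy, merge_models

    # the C-terminal n_anchor residues of the bound segment pair with the
    # docking strand; the taut extended remainder runs off the sheet corner
    anchor_idx = seg_idx[-n_anchor:]
    target = StructureModel(
        [spec.peptide_chain] * n_anchor,
        [residues[i] for i in anchor_idx],
        ["ALA"] * n_anchor, ["CA"] * n_anchor, ["C"] * n_anchor,
        bb["CA"][:n_anchor] + edge_offset)
    sel = (f"{spec.peptide_chain}:"
           f"{residues[anchor_idx[0]]}-{residues[anchor_idx[-1]]}:CA")

    def build_and_place(phi, psi):
        pep = peptide_from_torsions(spec, phi, psi)
        tf, _ = superpose(pep, target, sel)  # deterministic given segment torsions
        return tf.apply_model(pep)

    # coil flanks are resampled independently until the complete pose has
    # exactly zero soft-sphere overlap
    phi = np.empty(n_pep)
    psi = np.empty(n_pep)
    phi[:], psi[:] = _coil_torsions(rng, n_pep)
    phi[seg_idx] = STRAND_PHI
    psi[seg_idx] = STRAND_PSI
    n_flank = [i for i in range(n_pep) if i < seg_idx[0]]
    c_flank = [i for i in range(n_pep) if i > seg_idx[-1]]
    truth = None
    for _ in range(max_tries):
        pep = build_and_place(phi, psi)
        full = merge_models(receptor, pep)
        if clash_energy(full, rigid_chains=(spec.receptor_chain,)) == 0.0:
            truth = pep
            break
        # identify which flank(s) clash and redraw only those torsions
        from scipy.spatial.distance import cdist

        redrew = False
        for flank in (n_flank, c_flank):
            if not flank:
                continue
            flank_res = [residues[i] for i in flank]
            flank_idx = np.nonzero((full.chain_ids == spec.peptide_chain)
                                   & np.isin(full.residue_numbers, flank_res))[0]
            d = cdist(full.coords[flank_idx], full.coords)
            sep_ok = np.ones(d.shape, dtype=bool)
            for a, ia in enumerate(flank_idx):
                adjacent = ((full.chain_ids == full.chain_ids[ia])
                            & (np.abs(full.residue_numbers
                                      - full.residue_numbers[ia]) <= 1))
                sep_ok[a, adjacent] = False
            if np.any(d[sep_ok] < 3.0):
                cphi, cpsi = _coil_torsions(rng, len(flank))
                phi[flank] = cphi
                psi[flank] = cpsi
                redrew = True
        if not redrew:  # residual overlap not attributable to one flank
            for flank in (n_flank, c_flank):
                if flank:
                    cphi, cpsi = _coil_torsions(rng, len(flank))
                    phi[flank] = cphi
                    psi[flank] = cpsi
    if truth is None:
        raise RuntimeError(f"no clash-free bound pose found in {max_tries} tries")

    free = None
    for _ in range(max_tries):
        phi, psi = _coil_torsions(rng, n_pep)
        pep = peptide_from_torsions(spec, phi, psi)
        if clash_energy(pep) == 0.0:
            free = pep
            break
    if free is None:
        raise RuntimeError(f"no self-avoiding free coil found in {max_tries} tries")
    return receptor, truth, free


def default_label_sites(spec: SyntheticComplexSpec) -> dict:
    """Three spin-label sites on the receptor, keyed by name."""
    sites = {}
    for resnum in spec.label_sites:
        site = LabelSite(chain_id=spec.receptor_chain, residue_number=int(resnum))
        sites[site.name] = site
    return sites


def mutagenesis_restraint(truth_complex: StructureModel,
                          spec: SyntheticComplexSpec,
                          anchor_residues: tuple = (354, 356),
                          peptide_residue: int = 51,
                          halfwidth: float = 0.5):
    """Mutagenesis-style Cβ–Cβ anchor restraint with a ground-truth target.

    Emulates a contact known from mutagenesis: the restraint attaches the
    peptide residue's Cβ to the midpoint of two receptor Cβ atoms, with the
    target taken from the truth pose (± ``halfwidth``).
    """
    from .pre_analysis import DistanceRestraint

    anchors = tuple((spec.receptor_chain, int(r), "CB") for r in anchor_residues)
    rst = DistanceRestraint(
        site=None, anchor_atoms=anchors, chain_id=spec.peptide_chain,
        residue_number=int(peptide_residue), atom_name="CB",
        target=halfwidth * 2, lower=halfwidth, upper=halfwidth * 3,
        source="mutagenesis")
    d_true = rst.distance(truth_complex)
    rst.target, rst.lower, rst.upper = d_true, d_true - halfwidth, d_true + halfwidth
    return rst


def interface_contacts(receptor: StructureModel, peptide: StructureModel,
                       cutoff: float = 8.0) -> set:
    """Cβ–Cβ inter-chain contacts under ``cutoff`` Å: {(rec_res, pep_res)}."""
    from scipy.spatial.distance import cdist

    rec_cb = receptor.select("::CB")
    pep_cb = peptide.select("::CB")
    d = cdist(receptor.coords[rec_cb], peptide.coords[pep_cb])
    out = set()
    for i, j in zip(*np.nonzero(d < cutoff)):
        out.add((int(receptor.residue_numbers[rec_cb[i]]),
                 int(peptide.residue_numbers[pep_cb[j]])))
    return out


# ---------------------------------------------------------------------------
# simulated observables
# ---------------------------------------------------------------------------

def simulate_pre(truth: StructureModel, sites: dict, params: SBParameters,
                 noise: NoiseModel, residues, peptide_chain: str = "B",
                 seed: int = 0) -> dict:
    """Per-site Γ2 profiles from the ground-truth pose.

    Γ2 = backcalc × (1 + ε) with ε ~ N(0, cv); σ column is cv·Γ2. Residues in
    ``noise.missing_residues`` (exchange-broadened) are removed entirely, as
    are residues whose noiseless Γ2 exceeds ``noise.gamma_max`` (relaxed
    beyond detection — their signals vanish in the paramagnetic spectrum).
    """
    rng = np.random.default_rng([int(seed), 23])
    out = {}
    for name, site in sites.items():
        clean = backcalc_profile(truth, site, residues, params, peptide_chain)
        df = clean.df[clean.df["flag"] == "ok"].copy()
        df = df[~df["residue_number"].isin(list(noise.missing_residues))]
        # residues relaxing faster than the detection ceiling vanish from the
        # paramagnetic spectrum but stay in the table as broadened entries
        broadened = df["gamma2"] > noise.gamma_max
        df.loc[broadened, ["gamma2", "sigma"]] = np.nan
        df.loc[broadened, "flag"] = "missing_para"
        ok = ~broadened
        eps = rng.normal(0.0, noise.gamma_noise_cv, size=int(ok.sum())) \
            if noise.gamma_noise_cv > 0 else np.zeros(int(ok.sum()))
        df.loc[ok, "gamma2"] = df.loc[ok, "gamma2"].to_numpy() * (1.0 + eps)
        df.loc[ok, "sigma"] = np.abs(df.loc[ok, "gamma2"].to_numpy()) * noise.gamma_noise_cv
        out[name] = PREProfile(df.reset_index(drop=True), site=name)
    return out


def simulate_shifts(spec: SyntheticComplexSpec, rc: RandomCoilTable,
                    noise: NoiseModel, seed: int | None = None):
    """Free and bound shift tables with a CSP hotspot and a β-segment.

    Free state: random-coil shifts plus measurement noise. Bound state adds,
    inside the bound segment, (i) amide H/N perturbations whose composite
    CSP amplitude is log-normal around ``noise.csp_amplitude_median`` and
    (ii) fractional strand secondary shifts ``strand_fraction × full-strand
    reference`` on CA/CB/H. Residues in the missing set are dropped from the
    bound table (exchange broadening).
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng([int(seed), 37])
    lo, hi = spec.bound_segment
    # static per-residue amide-15N base (not in the random-coil table)
    residues = spec.peptide_residues()
    base_n = {r: 118.5 + rng.normal(0.0, 2.0) for r in residues}

    def draw_noise(nuc):
        sd = noise.shift_noise_sd.get(nuc, 0.0)
        return rng.normal(0.0, sd) if sd > 0 else 0.0

    free_rows, bound_rows = [], []
    for r in residues:
        res1 = spec.residue_name(r)
        in_segment = lo <= r <= hi
        # hotspot perturbation: split one composite amplitude between H and N
        if in_segment:
            amp = float(np.exp(np.log(noise.csp_amplitude_median)
                               + noise.csp_amplitude_sigma * rng.normal()))
            theta = rng.uniform(0.0, np.pi / 2.0)
            d_h = amp * np.cos(theta) * rng.choice([-1.0, 1.0])
            d_n = 6.0 * amp * np.sin(theta) * rng.choice([-1.0, 1.0])
        else:
            d_h = d_n = 0.0
        for nuc in ("H", "N", "CA", "CB"):
            if nuc == "N":
                base = base_n[r]
            else:
                nxt = spec.residue_name(r + 1) if r + 1 <= spec.peptide_last_residue else None
                base = rc.random_coil(res1, nuc, next_residue=nxt)
                if base is None:
                    continue
            free_val = base + draw_noise(nuc)
            bound_val = base + draw_noise(nuc)
            if in_segment:
                if nuc == "H":
                    bound_val += d_h
                elif nuc == "N":
                    bound_val += d_n
                if nuc in ("CA", "CB", "H"):
                    bound_val += noise.strand_fraction * rc.ref[("strand", nuc)]
            free_rows.append({"residue_number": r, "residue_name": res1,
                              "nucleus": nuc, "shift_ppm": free_val})
            if r not in noise.missing_residues:
                bound_rows.append({"residue_number": r, "residue_name": res1,
                                   "nucleus": nuc, "shift_ppm": bound_val})
    free = ShiftTable(pd.DataFrame(free_rows), state_label="free")
    bound = ShiftTable(pd.DataFrame(bound_rows), state_label="complexed")
    return free, bound


# ---------------------------------------------------------------------------
# fixture tree
# ---------------------------------------------------------------------------

def write_fixtures(outdir, spec: SyntheticComplexSpec | None = None,
                   noise: NoiseModel | None = None,
                   params: SBParameters | None = None) -> dict:
    """Write the complete worked-example input tree; returns the manifest.

    Emits receptor/peptide/truth PDB files, free+bound shift tables, per-site
    Γ2 tables and a pipeline config, plus a sha256 manifest. Bit-identical
    under the same spec seed.
    """
    from .modeling import merge_models

    spec = spec or SyntheticComplexSpec()
    noise = noise or NoiseModel()
    params = params or SBParameters()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    receptor, truth, free_pep = make_toy_complex(spec)
    sites = default_label_sites(spec)
    truth_complex = merge_models(receptor, truth)
    write_structure(Ensemble([receptor]), outdir / "receptor.pdb")
    write_structure(Ensemble([free_pep]), outdir / "peptide_free.pdb")
    write_structure(Ensemble([truth_complex]), outdir / "truth_complex.pdb")

    rc = RandomCoilTable.from_package()
    free_tab, bound_tab = simulate_shifts(spec, rc, noise)
    free_tab.to_tsv(outdir / "shifts_free.tsv")
    bound_tab.to_tsv(outdir / "shifts_bound.tsv")

    profiles = simulate_pre(truth_complex, sites, params, noise,
                            spec.peptide_residues(), spec.peptide_chain,
                            seed=spec.seed)
    for name, prof in profiles.items():
        prof.to_tsv(outdir / f"pre_{name}.tsv")

    from .pre_analysis import write_restraints_tsv
    write_restraints_tsv([mutagenesis_restraint(truth_complex, spec)],
                         outdir / "restraints_mutagenesis.tsv")

    config_lines = [
        "# premodel pipeline configuration (flat key = value)",
        f"seed = {spec.seed}",
        f"receptor_pdb = receptor.pdb",
        f"peptide_pdb = peptide_free.pdb",
        f"shifts_free = shifts_free.tsv",
        f"shifts_bound = shifts_bound.tsv",
        "pre_tables = " + ",".join(f"pre_{n}.tsv" for n in sorted(profiles)),
        "mutagenesis_restraints = restraints_mutagenesis.tsv",
        "label_sites = " + ",".join(
            f"{s.chain_id}:{s.residue_number}" for s in sites.values()),
        f"peptide_chain = {spec.peptide_chain}",
        f"receptor_chain = {spec.receptor_chain}",
        f"tau_c_ns = {params.tau_c}",
        f"field_mhz = {params.field}",
        f"spin_s = {params.spin_S}",
    ]
    (outdir / "config.txt").write_text("\n".join(config_lines) + "\n")

    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.tsv" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    with open(outdir / "manifest.tsv", "w") as fh:
        fh.write("file\tsha256\n")
        for name, digest in sorted(manifest.items()):
            fh.write(f"{name}\t{digest}\n")
    return manifest
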