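"""Paramagnetic relaxation enhancement: Γ2 rates, distances, restraints.

A paramagnetic tag (here an Mn²⁺-chelating maleimide on an engineered
cysteine) enhances the transverse relaxation of nearby nuclei. The excess
rate Γ2 = R2(paramagnetic) − R2(diamagnetic) reports on the electron–proton
distance r through the Solomon–Bloembergen relation

    Γ2 = K · r⁻⁶ · (4 τc + 3 τc / (1 + ω_H² τc²)),

with K assembled from fundamental constants and the electron spin quantum
number S (S = 5/2 for Mn²⁺). Because Γ2 ∝ r⁻⁶, the inversion to a distance
is analytic, and measurement noise propagates only weakly (r ∝ Γ2^(−1/6)).

Sign convention: Γ2 is defined as paramagnetic-minus-diamagnetic, i.e.
positive for paramagnetic broadening.

The flexible-tag geometry is handled by the
:class:`~premodel.structures.LabelSite` pseudo-position fan; every distance
involving a label site is an r⁻⁶ average over its pseudo-positions,
    r_eff = ( ⟨ r_k⁻⁶ ⟩_k )^(−1/6),
which is also how the experiment weights the tag conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import LabelSite, StructureModel

__all__ = [
    "RelaxationInput",
    "PREProfile",
    "SBParameters",
    "DistanceRestraint",
    "RestraintPolicy",
    "gamma2_from_rates",
    "gamma2_from_intensities",
    "sb_gamma",
    "sb_distance",
    "generate_restraints",
    "backcalc_profile",
    "r6_average",
    "write_restraints_tsv",
    "read_restraints_tsv",
    "write_restraints_xplor",
]

# fundamental constants (SI)
MU0_OVER_4PI = 1.0e-7            # T·m/A
GAMMA_H = 2.6752218744e8         # proton gyromagnetic ratio, rad·s⁻¹·T⁻¹
G_ELECTRON = 2.0023193           # free-electron g factor
MU_BOHR = 9.2740100783e-24       # Bohr magneton, J/T

ALLOWED_S = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5)


# ---------------------------------------------------------------------------
# parameters and data containers
# ---------------------------------------------------------------------------

@dataclass
class SBParameters:
    """Solomon–Bloembergen parameters.

    tau_c: effective electron–nucleus correlation time in ns (not measured in
    a typical PRE study; restraint distances depend on it only as τc^(1/6)).
    field: ¹H Larmor frequency in MHz. spin_S: electron spin quantum number
    (5/2 for Mn²⁺).
    """

    tau_c: float = 8.0
    field: float = 600.0
    spin_S: float = 2.5

    def __post_init__(self):
        if self.tau_c <= 0:
            raise ValueError("tau_c must be positive")
        if self.field <= 0:
            raise ValueError("field must be positive")
        if not any(abs(self.spin_S - s) < 1e-9 for s in ALLOWED_S):
            raise ValueError(f"spin_S must be one of {ALLOWED_S}")

    @property
    def omega_h(self) -> float:
        """¹H Larmor angular frequency, rad/s."""
        return 2.0 * np.pi * self.field * 1e6

    @property
    def k_constant(self) -> float:
        """Composite constant K in Å⁶·s⁻², such that Γ2 = K r⁻⁶ J(τc)."""
        k_si = (MU0_OVER_4PI ** 2 * GAMMA_H ** 2 * G_ELECTRON ** 2 * MU_BOHR ** 2
                * self.spin_S * (self.spin_S + 1.0)) / 15.0
        return k_si * 1e60  # m⁶ → Å⁶

    @property
    def spectral_term(self) -> float:
        """4τc + 3τc/(1+ω²τc²), seconds."""
        tau = self.tau_c * 1e-9
        return 4.0 * tau + 3.0 * tau / (1.0 + (self.omega_h * tau) ** 2)


class RelaxationInput:
    """Per-residue paramagnetic/diamagnetic observations.

    Either transverse rates (columns ``r2_para``, ``r2_dia`` with optional
    ``sigma_para``/``sigma_dia``, s⁻¹) or a two-point intensity pair
    (columns ``i_para``, ``i_dia`` with the relaxation delay ``delay_s``).
    NaN marks a residue missing in that state.
    """

    def __init__(self, df: pd.DataFrame, delay_s: float | None = None):
        self.df = df.copy().reset_index(drop=True)
        self.delay_s = delay_s
        if delay_s is not None and delay_s <= 0:
            raise ValueError("relaxation delay must be positive")
        for col in ("r2_para", "r2_dia"):
            if col in self.df and np.any(self.df[col].dropna() <= 0):
                raise ValueError(f"{col} must be positive")
        for col in ("i_para", "i_dia"):
            if col in self.df and np.any(self.df[col].dropna() <= 0):
                raise ValueError(f"{col} must be positive")


class PREProfile:
    """Per-residue Γ2 (s⁻¹) with uncertainties and missing-data flags."""

    def __init__(self, df: pd.DataFrame, site: str = ""):
        need = {"residue_number", "gamma2", "sigma", "flag"}
        if not need <= set(df.columns):
            raise ValueError(f"PREProfile needs columns {sorted(need)}")
        df = df.copy()
        defined = df["flag"] == "ok"
        if np.any(~np.isfinite(df.loc[defined, "gamma2"].astype(float))):
            raise ValueError("non-finite gamma2 on a defined residue")
        if np.any(df.loc[defined, "sigma"].astype(float) < 0):
            raise ValueError("negative gamma2 uncertainty")
        self.df = df.reset_index(drop=True)
        self.site = site

    def defined(self) -> pd.DataFrame:
        return self.df[self.df["flag"] == "ok"]

    def get(self, residue_number: int):
        hit = self.df[(self.df["residue_number"] == residue_number)
                      & (self.df["flag"] == "ok")]
        return float(hit["gamma2"].iloc[0]) if len(hit) else None

    @classmethod
    def from_tsv(cls, path, site: str = "") -> "PREProfile":
        return cls(pd.read_csv(path, sep="\t", comment="#"), site=site)

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Γ2 quantification
# ---------------------------------------------------------------------------

def gamma2_from_rates(inp: RelaxationInput, site: str = "") -> PREProfile:
    """Γ2 = R2(para) − R2(dia), uncertainties combined in quadrature.

    Residues measured in only one state are flagged missing instead of
    raising.
    """
    df = inp.df
    if "r2_para" not in df or "r2_dia" not in df:
        raise ValueError("rate columns r2_para/r2_dia required")
    rows = []
    for _, row in df.iterrows():
        para, dia = row.get("r2_para"), row.get("r2_dia")
        if pd.isna(para) or pd.isna(dia):
            flag = "missing_para" if pd.isna(para) else "missing_dia"
            rows.append({"residue_number": int(row["residue_number"]),
                         "gamma2": np.nan, "sigma": np.nan, "flag": flag})
            continue
        s_p = float(row.get("sigma_para", 0.0) or 0.0)
        s_d = float(row.get("sigma_dia", 0.0) or 0.0)
        rows.append({"residue_number": int(row["residue_number"]),
                     "gamma2": float(para) - float(dia),
                     "sigma": float(np.hypot(s_p, s_d)), "flag": "ok"})
    if not any(r["flag"] == "ok" for r in rows):
        raise ValueError("no residue with both rates measured")
    return PREProfile(pd.DataFrame(rows), site=site)


def gamma2_from_intensities(inp: RelaxationInput, site: str = "",
                            reference_residues=None) -> PREProfile:
    """Two-point Γ2 = −ln(I_para/I_dia)/Δt.

    If ``reference_residues`` (residues known to be unaffected by the label)
    are given, the intensity ratio is first normalised by its median over
    that set, absorbing concentration/gain differences between the two
    samples.
    """
    df = inp.df
    if inp.delay_s is None or "i_para" not in df or "i_dia" not in df:
        raise ValueError("intensity columns i_para/i_dia and delay_s required")
    ratio = df["i_para"].astype(float) / df["i_dia"].astype(float)
    if reference_residues is not None:
        ref_mask = df["residue_number"].isin(list(reference_residues))
        ref_ratio = ratio[ref_mask & ratio.notna()]
        if len(ref_ratio) == 0:
            raise ValueError("no usable reference residues for normalisation")
        ratio = ratio / float(np.median(ref_ratio))
    rows = []
    for (_, row), rat in zip(df.iterrows(), ratio):
        if pd.isna(rat):
            rows.append({"residue_number": int(row["residue_number"]),
                         "gamma2": np.nan, "sigma": np.nan, "flag": "missing_para"})
            continue
        if rat <= 0:
            raise ValueError(f"non-positive intensity ratio at residue "
                             f"{int(row['residue_number'])}")
        gamma2 = -np.log(rat) / inp.delay_s
        # two-point error propagation if intensity noise given
        s_i = float(row.get("sigma_i", 0.0) or 0.0)
        sigma = (s_i / inp.delay_s) * np.sqrt(1.0 / row["i_para"] ** 2
                                              + 1.0 / row["i_dia"] ** 2) if s_i else 0.0
        rows.append({"residue_number": int(row["residue_number"]),
                     "gamma2": float(gamma2), "sigma": float(sigma), "flag": "ok"})
    return PREProfile(pd.DataFrame(rows), site=site)


# ---------------------------------------------------------------------------
# Solomon–Bloembergen forward / inverse
# ---------------------------------------------------------------------------

def sb_gamma(r: float, params: SBParameters) -> float:
    """Γ2 (s⁻¹) at electron–proton distance r (Å). Strictly decreasing in r."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    out = params.k_constant * r ** -6.0 * params.spectral_term
    return float(out) if out.ndim == 0 else out


def sb_distance(gamma2: float, params: SBParameters) -> float:
    """Analytic inverse of :func:`sb_gamma`: r = (K·J(τc)/Γ2)^(1/6), Å."""
    gamma2 = np.asarray(gamma2, dtype=float)
    if np.any(gamma2 <= 0):
        raise ValueError("gamma2 must be positive to invert to a distance")
    out = (params.k_constant * params.spectral_term / gamma2) ** (1.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def r6_average(distances: np.ndarray) -> float:
    """Effective distance r_eff = (⟨r⁻⁶⟩)^(−1/6) over tag pseudo-positions."""
    d = np.asarray(distances, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distances must be positive")
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

@dataclass
class DistanceRestraint:
    """Flat-bottom distance restraint between a tag/anchor and a peptide atom.

    Endpoint A is either a spin-label site (distance evaluated as the r⁻⁶
    average over its pseudo-positions, matching the PRE forward model) or a
    list of (chain, residue, atom) anchors whose midpoint is used (the
    mutagenesis-derived restraint attaches to the midpoint of two receptor
    Cβ atoms). Endpoint B is a single peptide atom.
    """

    site: LabelSite | None
    anchor_atoms: tuple | None
    chain_id: str
    residue_number: int
    atom_name: str
    target: float
    lower: float
    upper: float
    source: str = "PRE"
    weight: float = 1.0

    def __post_init__(self):
        if not (0 < self.lower <= self.target <= self.upper):
            raise ValueError(f"invalid bounds {self.lower}/{self.target}/{self.upper}")

    def endpoint_a_positions(self, model: StructureModel) -> np.ndarray:
        if self.site is not None:
            return self.site.pseudo_positions(model)
        pts = []
        for chain, res, atom in self.anchor_atoms:
            i = model.find_atom(chain, res, atom)
            if i is None:
                raise ValueError(f"restraint anchor {chain}:{res}:{atom} not found")
            pts.append(model.coords[i])
        return np.mean(pts, axis=0)[None, :]

    def distance(self, model: StructureModel) -> float:
        """Model distance: r⁻⁶ average to a label site, plain to an anchor."""
        a = self.endpoint_a_positions(model)
        i = model.find_atom(self.chain_id, self.residue_number, self.atom_name)
        if i is None:
            raise ValueError(f"restraint atom {self.chain_id}:{self.residue_number}:"
                             f"{self.atom_name} not found")
        d = np.linalg.norm(a - model.coords[i], axis=1)
        return r6_average(d) if self.site is not None else float(d[0])


@dataclass
class RestraintPolicy:
    """Controls how a PRE profile is turned into restraints.

    threshold: Γ2 (s⁻¹) above which a residue yields a distance restraint;
    None → max(20 s⁻¹, 2× median of defined Γ2). min_halfwidth: floor on the
    half-width of the flat region (0.5 Å → total 1 Å flat bottom).
    lower_bound_only / broadened_upper: optional extra restraint classes for
    weak-PRE and beyond-detection residues.
    """

    threshold: float | None = None
    min_halfwidth: float = 0.5
    lower_bound_only: bool = False
    #: lower bound (Å) for weak-PRE residues; None → derived from the
    #: threshold as sb_distance(1.25 × threshold), i.e. the distance the
    #: sub-threshold Γ2 implies, with a 25% noise margin on Γ2
    weak_lower: float | None = None
    broadened_restraints: bool = False
    broadened_upper: float = 14.0

    def resolve_threshold(self, gamma2_values: np.ndarray) -> float:
        if self.threshold is not None:
            return float(self.threshold)
        med = float(np.median(gamma2_values))
        return max(20.0, 2.0 * med)


def generate_restraints(profile: PREProfile, params: SBParameters,
                        policy: RestraintPolicy, site: LabelSite,
                        peptide_chain: str, amide_atoms: dict | None = None):
    """Convert one site's Γ2 profile into flat-bottom distance restraints.

    Residues with Γ2 ≥ threshold get ``target = sb_distance(Γ2)`` with bounds
    from propagating ±σ(Γ2) (floored at ``min_halfwidth``). Restraints attach
    to the amide proton; pass ``amide_atoms[residue] = "N"`` for residues
    without an observable H (bounds are then widened by 1 Å). Optionally,
    weak residues give lower-bound-only restraints and exchange-broadened
    residues upper-bound-only restraints.
    """
    defined = profile.defined()
    if defined.empty:
        raise ValueError("PRE profile has no defined residues")
    gam = defined["gamma2"].to_numpy(dtype=float)
    pos = gam[gam > 0]
    if len(pos) == 0:
        raise ValueError("no positive gamma2 values to convert")
    threshold = policy.resolve_threshold(pos)
    amide_atoms = amide_atoms or {}
    out = []
    for _, row in defined.iterrows():
        resnum = int(row["residue_number"])
        g = float(row["gamma2"])
        sig = float(row["sigma"]) if np.isfinite(row["sigma"]) else 0.0
        atom = amide_atoms.get(resnum, "H")
        widen = 1.0 if atom == "N" else 0.0
        if g >= threshold:
            target = sb_distance(g, params)
            lo = sb_distance(g + sig, params) if g + sig > 0 else target
            hi = sb_distance(g - sig, params) if g - sig > 0 else target + 5.0
            half = max(policy.min_halfwidth, target - lo, hi - target)
            out.append(DistanceRestraint(
                site=site, anchor_atoms=None, chain_id=peptide_chain,
                residue_number=resnum, atom_name=atom,
                target=target, lower=target - half - widen,
                upper=target + half + widen, source="PRE"))
        elif policy.lower_bound_only and g < threshold:
            # a small Γ2 is information too: the residue must be far from
            # the tag (one-sided restraint, no upper limit)
            lower = (policy.weak_lower if policy.weak_lower is not None
                     else sb_distance(1.25 * threshold, params))
            out.append(DistanceRestraint(
                site=site, anchor_atoms=None, chain_id=peptide_chain,
                residue_number=resnum, atom_name=atom,
                target=lower, lower=lower, upper=np.inf,
                source="PRE_lower"))
    if policy.broadened_restraints:
        for _, row in profile.df[profile.df["flag"] == "missing_para"].iterrows():
            resnum = int(row["residue_number"])
            atom = amide_atoms.get(resnum, "H")
            out.append(DistanceRestraint(
                site=site, anchor_atoms=None, chain_id=peptide_chain,
                residue_number=resnum, atom_name=atom,
                target=policy.broadened_upper, lower=1.0,
                upper=policy.broadened_upper, source="PRE_upper"))
    return out


def backcalc_profile(model: StructureModel, site: LabelSite, residues,
                     params: SBParameters, chain_id: str) -> PREProfile:
    """Back-calculate a Γ2 profile from coordinates for one label site.

    Per residue, the amide proton (N fallback) distance to the tag is the
    r⁻⁶ average over the site's pseudo-positions; Γ2 = sb_gamma(r_eff).
    Residues with no amide atom are flagged, not dropped silently.
    """
    pseudo = site.pseudo_positions(model)
    rows = []
    for resnum in residues:
        idx = model.find_atom(chain_id, int(resnum), "H")
        if idx is None:
            idx = model.find_atom(chain_id, int(resnum), "N")
        if idx is None:
            rows.append({"residue_number": int(resnum), "gamma2": np.nan,
                         "sigma": np.nan, "flag": "no_amide"})
            continue
        d = np.linalg.norm(pseudo - model.coords[idx], axis=1)
        rows.append({"residue_number": int(resnum),
                     "gamma2": sb_gamma(r6_average(d), params),
                     "sigma": 0.0, "flag": "ok"})
    return PREProfile(pd.DataFrame(rows), site=site.name)


# ---------------------------------------------------------------------------
# restraint file I/O
# ---------------------------------------------------------------------------

def write_restraints_tsv(restraints, path, sites=None):
    rows = []
    for r in restraints:
        rows.append({
            "site": r.site.name if r.site else "",
            "anchor": ";".join(f"{c}:{n}:{a}" for c, n, a in (r.anchor_atoms or [])),
            "chain": r.chain_id, "residue": r.residue_number, "atom": r.atom_name,
            "target": round(r.target, 3), "lower": round(r.lower, 3),
            "upper": round(r.upper, 3), "source": r.source, "weight": r.weight,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path, sites: dict):
    """Read restraints written by :func:`write_restraints_tsv`.

    ``sites`` maps site names to :class:`LabelSite` objects (restraint files
    store only the site name).
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        site = sites.get(str(row["site"])) if str(row["site"]) else None
        anchor = None
        if str(row.get("anchor", "")):
            anchor = tuple(
                (c, int(n), a) for c, n, a in
                (part.split(":") for part in str(row["anchor"]).split(";")))
        out.append(DistanceRestraint(
            site=site, anchor_atoms=anchor, chain_id=str(row["chain"]),
            residue_number=int(row["residue"]), atom_name=str(row["atom"]),
            target=float(row["target"]), lower=float(row["lower"]),
            upper=float(row["upper"]), source=str(row["source"]),
            weight=float(row["weight"])))
    return out


def write_restraints_xplor(restraints, path):
    """Write an Xplor-style NOE-range assign table (interoperability export)."""
    lines = []
    for r in restraints:
        if r.site is not None:
            sel_a = (f"(segid LABL and resid {r.site.residue_number} "
                     f"and name {r.site.attachment_atom})")
        else:
            c, n, a = r.anchor_atoms[0]
            sel_a = f"(resid {n} and name {a})"
        sel_b = f"(resid {r.residue_number} and name {r.atom_name})"
        d_minus = r.target - r.lower
        d_plus = r.upper - r.target
        lines.append(f"assign {sel_a} {sel_b} {r.target:.2f} {d_minus:.2f} {d_plus:.2f}")
    Path_text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(Path_text)
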