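"""Coordinate data model, PDB ensemble I/O and structural statistics.

The in-memory model is deliberately small: a :class:`StructureModel` holds
parallel numpy arrays (one entry per atom), a :class:`Ensemble` is an ordered
list of models sharing one atom table. PDB reading/writing is delegated to
:mod:`biotite`; superposition uses the Kabsch algorithm via
:class:`scipy.spatial.transform.Rotation`.

Selections use a compact mini-language ``"chain:resid_range:atom_names"``:

* ``"A:46-80:CA"`` — chain A, residues 46..80, CA atoms only
* ``"B::"`` or ``"B"`` — every atom of chain B
* ``"::N,CA,C"`` — backbone N/CA/C of every chain
* ``"A:12,15,20-25:CB"`` — residue lists and ranges may be mixed

Several space-separated terms form a union: ``"A:1-10:CA B::P"``.
"""

from __future__ import annotations


from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "LabelSite",
    "Transform",
    "read_structure",
    "write_structure",
    "superpose",
    "pairwise_rmsd",
    "radius_of_gyration",
    "ramachandran_stats",
    "dihedral",
    "build_backbone",
]

RAMA_CLASSES = ("most_favored", "additional_allowed", "generously_allowed", "disallowed")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom: chain / author residue number / names / element / position (Å)."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {self.position}")
        object.__setattr__(self, "position", pos)


class StructureModel:
    """A single conformer: parallel per-atom arrays plus free-form metadata.

    Author residue numbering (1-based, as deposited) is kept verbatim.
    """

    def __init__(self, chain_ids, residue_numbers, residue_names, atom_names,
                 elements, coords, model_id: int = 1, metadata: dict | None = None,
                 validate: bool = True):
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.residue_numbers = np.asarray(residue_numbers, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U4")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.asarray(elements, dtype="U2")
        self.coords = np.ascontiguousarray(coords, dtype=float)
        self.model_id = int(model_id)
        self.metadata = dict(metadata or {})
        if validate:
            self._validate()

    # -- construction helpers ------------------------------------------------

    @classmethod
    def from_atoms(cls, atoms, model_id: int = 1, metadata: dict | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ValueError("StructureModel must contain at least one atom")
        return cls(
            [a.chain_id for a in atoms],
            [a.residue_number for a in atoms],
            [a.residue_name for a in atoms],
            [a.atom_name for a in atoms],
            [a.element for a in atoms],
            np.array([a.position for a in atoms], dtype=float),
            model_id=model_id, metadata=metadata,
        )

    def _validate(self):
        n = len(self.coords)
        if n == 0:
            raise ValueError("StructureModel must contain at least one atom")
        if self.coords.shape != (n, 3) or not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be a finite (n, 3) array")
        keys = list(zip(self.chain_ids, self.residue_numbers, self.atom_names))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate atom {dup} in model {self.model_id}")
        for ch in np.unique(self.chain_ids):
            resnum = self.residue_numbers[self.chain_ids == ch]
            if np.any(np.diff(resnum) < 0):
                raise ValueError(f"residue numbering not monotone in chain {ch}")

    # -- basic API -----------------------------------------------------------

    def __len__(self):
        return len(self.coords)

    def __iter__(self):
        for i in range(len(self)):
            yield AtomRecord(self.chain_ids[i], int(self.residue_numbers[i]),
                             self.residue_names[i], self.atom_names[i],
                             self.elements[i], self.coords[i].copy())

    def copy(self) -> "StructureModel":
        return StructureModel(self.chain_ids.copy(), self.residue_numbers.copy(),
                              self.residue_names.copy(), self.atom_names.copy(),
                              self.elements.copy(), self.coords.copy(),
                              self.model_id, dict(self.metadata), validate=False)

    def atom_key(self):
        """Ordered (chain, resid, atom) identity used for ensemble consistency."""
        return list(zip(self.chain_ids.tolist(), self.residue_numbers.tolist(),
                        self.atom_names.tolist()))

    # -- selections ----------------------------------------------------------

    def select(self, selection) -> np.ndarray:
        """Resolve a selection expression to an index array (see module docs)."""
        if selection is None:
            return np.arange(len(self))
        if isinstance(selection, np.ndarray) and selection.dtype != np.dtype("U"):
            return np.asarray(selection, dtype=int)
        mask = np.zeros(len(self), dtype=bool)
        for term in str(selection).split():
            mask |= self._select_term(term)
        return np.nonzero(mask)[0]

    def _select_term(self, term: str) -> np.ndarray:
        parts = (term.split(":") + ["", ""])[:3]
        chain, resid_spec, atom_spec = (p.strip() for p in parts)
        mask = np.ones(len(self), dtype=bool)
        if chain:
            mask &= self.chain_ids == chain
        if resid_spec:
            wanted = set()
            for piece in resid_spec.split(","):
                if "-" in piece[1:]:  # "46-80" range (author numbers may be negative)
                    lo, hi = piece[:1] + piece[1:].split("-", 1)[0], piece[1:].split("-", 1)[1]
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(piece))
            mask &= np.isin(self.residue_numbers, sorted(wanted))
        if atom_spec:
            names = [a.strip() for a in atom_spec.split(",") if a.strip()]
            mask &= np.isin(self.atom_names, names)
        return mask

    def find_atom(self, chain_id: str, residue_number: int, atom_name: str):
        """Index of one atom, or None if absent."""
        hit = np.nonzero((self.chain_ids == chain_id)
                         & (self.residue_numbers == int(residue_number))
                         & (self.atom_names == atom_name))[0]
        return int(hit[0]) if len(hit) else None

    def residue_ids(self, chain_id: str) -> np.ndarray:
        return np.unique(self.residue_numbers[self.chain_ids == chain_id])


class Ensemble:
    """Ordered conformers sharing one (chain, residue, atom) table."""

    def __init__(self, models, validate: bool = True):
        self.models = list(models)
        if not self.models:
            raise ValueError("Ensemble must contain at least one model")
        if validate:
            ref = self.models[0].atom_key()
            for m in self.models[1:]:
                key = m.atom_key()
                if key != ref:
                    bad = next((a for a, b in zip(ref, key) if a != b),
                               ref[min(len(key), len(ref) - 1)] if len(key) != len(ref) else None)
                    raise ValueError(
                        f"model {m.model_id} atom set differs from model "
                        f"{self.models[0].model_id} (first mismatch near {bad})")

    def __len__(self):
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i):
        return self.models[i]

    def coords_array(self) -> np.ndarray:
        """(n_models, n_atoms, 3) coordinate stack."""
        return np.stack([m.coords for m in self.models])


@dataclass
class LabelSite:
    """A cysteine spin-label attachment site on the rigid receptor.

    The paramagnetic tag is long and never observed directly; it is modelled
    as ``n_pseudo`` pseudo-positions fanned around the Cα→Cβ axis at
    ``centroid_offset`` Å from the attachment atom. Back-calculated PREs use
    r⁻⁶ averaging over these pseudo-positions.
    """

    chain_id: str
    residue_number: int
    attachment_atom: str = "CB"
    centroid_offset: float = 8.0
    n_pseudo: int = 3
    name: str = ""

    def __post_init__(self):
        if self.n_pseudo < 1:
            raise ValueError("n_pseudo must be >= 1")
        if self.centroid_offset < 0:
            raise ValueError("centroid_offset must be >= 0")
        if not self.name:
            self.name = f"{self.chain_id}{self.residue_number}"

    def pseudo_positions(self, model: StructureModel) -> np.ndarray:
        """(n_pseudo, 3) tag-center positions derived from local geometry."""
        i_cb = model.find_atom(self.chain_id, self.residue_number, self.attachment_atom)
        i_ca = model.find_atom(self.chain_id, self.residue_number, "CA")
        if i_cb is None or i_ca is None:
            raise ValueError(f"label site {self.name}: CA/{self.attachment_atom} not found")
        ca, cb = model.coords[i_ca], model.coords[i_cb]
        axis = cb - ca
        axis /= np.linalg.norm(axis)
        centroid = cb + self.centroid_offset * axis
        if self.n_pseudo == 1:
            return centroid[None, :]
        # fan: tilt the offset vector by 25 degrees and revolve around the axis
        perp = np.cross(axis, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(axis, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        tilt = Rotation.from_rotvec(np.deg2rad(25.0) * perp)
        arm = tilt.apply(self.centroid_offset * axis)
        out = []
        for k in range(self.n_pseudo):
            spin = Rotation.from_rotvec(2 * np.pi * k / self.n_pseudo * axis)
            out.append(cb + spin.apply(arm))
        return np.array(out)


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _from_atom_array(arr, model_id: int) -> StructureModel:
    return StructureModel(arr.chain_id, arr.res_id, arr.res_name, arr.atom_name,
                          np.char.capitalize(arr.element), arr.coord, model_id=model_id)


def read_structure(path, dialect: str = "pdb") -> Ensemble:
    """Read a PDB file (single-model or MODEL/ENDMDL ensemble) into an Ensemble.

    HETATM records (DNA, metals, ligands) are retained; alternate locations
    are resolved to the highest-occupancy conformer.
    """
    import biotite.structure.io.pdb as pdbio

    if dialect != "pdb":
        raise ValueError(f"unsupported dialect: {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    pdb_file = pdbio.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises on ragged models
        raise ValueError(f"inconsistent atom sets across models in {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValueError(f"no ATOM/HETATM records in {path}")
    models = [_from_atom_array(stack[i], model_id=i + 1)
              for i in range(stack.stack_depth())]
    return Ensemble(models)


def write_structure(ensemble: Ensemble, path) -> None:
    """Write an Ensemble as a (multi-)MODEL PDB file; coordinates at 3 dp."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdbio

    n_atoms = len(ensemble[0])
    stack = struc.AtomArrayStack(len(ensemble), n_atoms)
    first = ensemble[0]
    stack.chain_id = first.chain_ids.astype("U4")
    stack.res_id = first.residue_numbers
    stack.res_name = first.residue_names.astype("U5")
    stack.atom_name = first.atom_names.astype("U6")
    stack.element = np.char.upper(first.elements.astype("U2"))
    stack.hetero = np.isin(first.residue_names, ["DA", "DT", "DG", "DC", "ZN", "MN", "HOH"])
    stack.coord = ensemble.coords_array()
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass
class Transform:
    """Rigid transform x -> rotation @ (x - pivot) + shift."""

    rotation: np.ndarray
    pivot: np.ndarray
    shift: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords) - self.pivot) @ self.rotation.T + self.shift

    def apply_model(self, model: StructureModel) -> StructureModel:
        out = model.copy()
        out.coords = self.apply(model.coords)
        return out


def _check_not_collinear(x: np.ndarray):
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selection atoms are collinear; superposition is degenerate")


def superpose(mobile: StructureModel, reference: StructureModel, selection=None):
    """Least-squares (Kabsch) rigid fit of ``mobile`` onto ``reference``.

    Returns ``(transform, rmsd)`` where the RMSD is over the selection after
    the fit. The selection must resolve to >= 3 non-collinear atom pairs
    present in both models (matched by chain/residue/atom identity).
    """
    idx_m = mobile.select(selection)
    key_r = {k: i for i, k in enumerate(reference.atom_key())}
    pairs = [(i, key_r[k]) for i, k in
             ((i, (mobile.chain_ids[i], int(mobile.residue_numbers[i]), mobile.atom_names[i]))
              for i in idx_m) if k in key_r]
    if len(pairs) < 3:
        raise ValueError(f"superposition needs >=3 matched atoms, got {len(pairs)}")
    xm = mobile.coords[[p[0] for p in pairs]]
    xr = reference.coords[[p[1] for p in pairs]]
    _check_not_collinear(xm)
    _check_not_collinear(xr)
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    rot, _ = Rotation.align_vectors(xr - cr, xm - cm)
    tf = Transform(rotation=rot.as_matrix(), pivot=cm, shift=cr)
    rmsd = float(np.sqrt(np.mean(np.sum((tf.apply(xm) - xr) ** 2, axis=1))))
    return tf, rmsd


def pairwise_rmsd(ensemble: Ensemble, selection=None):
    """Mean ± sd of pairwise RMSD over all unordered model pairs.

    Each pair is first superposed on the same selection the RMSD is computed
    over. Returns ``(mean, sd, matrix)``.
    """
    n = len(ensemble)
    if n < 2:
        raise ValueError("pairwise RMSD needs an ensemble of >= 2 models")
    idx = ensemble[0].select(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    mat = np.zeros((n, n))
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            _, r = superpose(ensemble[j], ensemble[i], selection)
            mat[i, j] = mat[j, i] = r
            vals.append(r)
    vals = np.array(vals)
    return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0, mat


def radius_of_gyration(model: StructureModel, selection=None, weights=None) -> float:
    """Mass-weighted RMS distance of selected atoms from their weighted centroid."""
    idx = model.select(selection)
    if len(idx) == 0:
        raise ValueError("empty selection for radius of gyration")
    x = model.coords[idx]
    if weights is None:
        w = np.ones(len(idx))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
    centroid = np.average(x, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((x - centroid) ** 2, axis=1), weights=w)))


# ---------------------------------------------------------------------------
# dihedrals, Ramachandran statistics
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return float(np.degrees(np.arctan2(-np.dot(m1, n2), np.dot(n1, n2))))


def _load_rama_grid():
    """Rectangular φ/ψ region grid shipped as package data."""
    rows = []
    text = resources.files("premodel.data").joinpath("rama_regions.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cls, phi_lo, phi_hi, psi_lo, psi_hi = line.split("\t")
        rows.append((cls, float(phi_lo), float(phi_hi), float(psi_lo), float(psi_hi)))
    return rows


_RAMA_GRID = None


def classify_phi_psi(phi: float, psi: float) -> str:
    """Classify one (φ, ψ) pair against the shipped rectangular region grid."""
    global _RAMA_GRID
    if _RAMA_GRID is None:
        _RAMA_GRID = _load_rama_grid()
    for cls in RAMA_CLASSES[:3]:
        for c, plo, phi_hi, slo, shi in _RAMA_GRID:
            if c == cls and plo <= phi <= phi_hi and slo <= psi <= shi:
                return cls
    return "disallowed"


def phi_psi(model: StructureModel, chain_id: str):
    """(residue_number, φ, ψ) for internal residues with complete backbone."""
    out = []
    resids = model.residue_ids(chain_id)
    bb = {}
    for r in resids:
        trip = {a: model.find_atom(chain_id, int(r), a) for a in ("N", "CA", "C")}
        if all(v is not None for v in trip.values()):
            bb[int(r)] = {a: model.coords[i] for a, i in trip.items()}
    for r in sorted(bb):
        if r - 1 in bb and r + 1 in bb:
            phi = dihedral(bb[r - 1]["C"], bb[r]["N"], bb[r]["CA"], bb[r]["C"])
            psi = dihedral(bb[r]["N"], bb[r]["CA"], bb[r]["C"], bb[r + 1]["N"])
            out.append((r, phi, psi))
    return out


def ramachandran_stats(ensemble: Ensemble, chain_id: str) -> dict:
    """Fractions of internal residues per Ramachandran class over the ensemble.

    Regions are rectangles from the packaged grid (``data/rama_regions.tsv``);
    fractions sum to 1 over classified residues. Residues lacking backbone
    atoms are skipped.
    """
    counts = {c: 0 for c in RAMA_CLASSES}
    for model in ensemble:
        pp = phi_psi(model, chain_id)
        for _, phi, psi in pp:
            counts[classify_phi_psi(phi, psi)] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"no classifiable residues in chain {chain_id}")
    return {c: counts[c] / total for c in RAMA_CLASSES}


# ---------------------------------------------------------------------------
# ideal backbone construction (NeRF extension)
# ---------------------------------------------------------------------------

# standard peptide geometry (Å, degrees)
BOND_N_CA, BOND_CA_C, BOND_C_N = 1.458, 1.525, 1.329
BOND_C_O, BOND_N_H, BOND_CA_CB = 1.231, 1.020, 1.530
ANG_C_N_CA, ANG_N_CA_C, ANG_CA_C_N = 121.7, 111.0, 116.2
ANG_CA_C_O = 120.8


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given a-b-c with |cd| = bond, ∠bcd = angle, χ(a,b,c,d) = torsion.

    Natural-extension (NeRF) construction; angle/torsion in degrees.
    """
    ang, tor = np.deg2rad(angle), np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(ang),
                               np.sin(ang) * np.cos(tor),
                               np.sin(ang) * np.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray, omega: float = 180.0):
    """Build an ideal-geometry backbone from per-residue φ/ψ.

    Returns a dict with (n_res, 3) arrays for N, CA, C, O, H, CB. The first
    residue's φ and the last residue's ψ are applied but only affect
    H/O/CB placement.
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    n_res = len(phi)
    if len(psi) != n_res:
        raise ValueError("phi and psi must have equal length")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    # seed first residue in a canonical frame
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [BOND_N_CA, 0.0, 0.0]
    C[0] = place_atom(np.array([0.0, -1.0, 0.0]), N[0], CA[0], BOND_CA_C, ANG_N_CA_C, phi[0])
    for i in range(1, n_res):
        N[i] = place_atom(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANG_CA_C_N, psi[i - 1])
        CA[i] = place_atom(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANG_C_N_CA, omega)
        C[i] = place_atom(C[i - 1], N[i], CA[i], BOND_CA_C, ANG_N_CA_C, phi[i])
    O = np.zeros((n_res, 3))
    H = np.zeros((n_res, 3))
    CB = np.zeros((n_res, 3))
    for i in range(n_res):
        # carbonyl O anti to the next amide N
        O[i] = place_atom(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O, psi[i] + 180.0)
        # amide H in the peptide plane, opposite the bisector of C(-1)-N and CA-N
        if i > 0:
            u = C[i - 1] - N[i]
            v = CA[i] - N[i]
        else:
            u = np.array([-1.0, 1.0, 0.0])
            v = CA[i] - N[i]
        u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
        h_dir = -(u + v)
        H[i] = N[i] + BOND_N_H * h_dir / np.linalg.norm(h_dir)
        # tetrahedral CB off the N-CA-C frame
        u = N[i] - CA[i]
        v = C[i] - CA[i]
        u, v = u / np.linalg.norm(u), v / np.linalg.norm(v)
        bisect = (u + v)
        bisect /= np.linalg.norm(bisect)
        perp = np.cross(u, v)
        perp /= np.linalg.norm(perp)
        cb_dir = -bisect * np.sin(np.deg2rad(54.0)) + perp * np.cos(np.deg2rad(54.0))
        CB[i] = CA[i] + BOND_CA_CB * cb_dir / np.linalg.norm(cb_dir)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H, "CB": CB}
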