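"""Chemical-shift analysis: CSP mapping, secondary shifts, SSP profiling.

Chemical shift perturbation (CSP) locates a binding interface from the
composite amide shift change between free and complexed states,

    Δδ = sqrt(Δδ_H² + (Δδ_N/6)²),

where the 1/6 factor scales ¹⁵N changes onto the ¹H scale. Residues that can
be assigned in the free state but vanish in the complex are flagged as
exchange-broadened candidates rather than given a Δδ.

Secondary-structure propensity (SSP) turns secondary shifts (observed minus
sequence-corrected random coil) of Cα, Cβ and amide H into a windowed,
reference-normalised score: +1 for fully formed helix, −1 for fully formed
extended strand, 0 for random coil.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ShiftTable",
    "CSPProfile",
    "SSPProfile",
    "RandomCoilTable",
    "compute_csp",
    "secondary_shifts",
    "compute_ssp",
    "flag_missing",
    "read_nmrstar_shifts",
]

NUCLEI = ("H", "N", "CA", "CB", "C", "HA")

#: plausible ppm windows per nucleus (validation guard, generous on purpose)
PLAUSIBLE_PPM = {
    "H": (4.5, 12.5), "N": (95.0, 140.0), "CA": (38.0, 75.0),
    "CB": (8.0, 78.0), "C": (160.0, 190.0), "HA": (1.0, 7.5),
}

#: nucleus weights entering the SSP sums (amide H shifts are noisier and
#: more susceptible to ring currents / hydrogen bonding, hence down-weighted)
SSP_WEIGHTS = {"CA": 1.0, "CB": 1.0, "H": 0.3}

#: secondary shifts larger than this (ppm) are treated as outliers and
#: excluded from the SSP sums
SSP_OUTLIER_PPM = {"CA": 5.0, "CB": 5.0, "H": 1.5}

#: cap on |SSP| absorbing reference-table overshoot
SSP_CAP = 1.15

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------

class ShiftTable:
    """Per-residue, per-nucleus chemical shifts (ppm) for one sample state.

    Backed by a DataFrame with columns ``residue_number`` (int),
    ``residue_name`` (1-letter code), ``nucleus`` and ``shift_ppm``.
    """

    def __init__(self, df: pd.DataFrame, state_label: str = "", validate: bool = True):
        df = df.copy()
        df["residue_number"] = df["residue_number"].astype(int)
        df["shift_ppm"] = df["shift_ppm"].astype(float)
        self.df = df.reset_index(drop=True)
        self.state_label = state_label
        if validate:
            self._validate()

    def _validate(self):
        dup = self.df.duplicated(subset=["residue_number", "nucleus"])
        if dup.any():
            row = self.df[dup].iloc[0]
            raise ValueError(f"duplicate shift for residue {row.residue_number} "
                             f"nucleus {row.nucleus}")
        bad_nuc = set(self.df["nucleus"]) - set(NUCLEI)
        if bad_nuc:
            raise ValueError(f"unknown nuclei: {sorted(bad_nuc)}")
        for nuc, (lo, hi) in PLAUSIBLE_PPM.items():
            vals = self.df.loc[self.df["nucleus"] == nuc, "shift_ppm"]
            out = vals[(vals < lo) | (vals > hi)]
            if len(out):
                raise ValueError(
                    f"{self.state_label or 'table'}: {nuc} shift {out.iloc[0]:.2f} ppm "
                    f"outside plausible window [{lo}, {hi}]")

    # -- access --------------------------------------------------------------

    def get(self, residue_number: int, nucleus: str):
        hit = self.df[(self.df["residue_number"] == residue_number)
                      & (self.df["nucleus"] == nucleus)]
        return float(hit["shift_ppm"].iloc[0]) if len(hit) else None

    def residues(self, nuclei=None) -> np.ndarray:
        """Residue numbers carrying all of the given nuclei (default: any)."""
        if nuclei is None:
            return np.unique(self.df["residue_number"].to_numpy())
        ok = None
        for nuc in nuclei:
            have = set(self.df.loc[self.df["nucleus"] == nuc, "residue_number"])
            ok = have if ok is None else ok & have
        return np.array(sorted(ok or []), dtype=int)

    def residue_name(self, residue_number: int):
        hit = self.df[self.df["residue_number"] == residue_number]
        return str(hit["residue_name"].iloc[0]) if len(hit) else None

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path, state_label: str = "") -> "ShiftTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df[["residue_number", "residue_name", "nucleus", "shift_ppm"]],
                   state_label=state_label)

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


def read_nmrstar_shifts(path, state_label: str = "") -> ShiftTable:
    """Minimal NMR-STAR v3 reader for ``_Atom_chem_shift`` loops.

    Parses only the assigned-chemical-shift loop (sufficient to ingest BMRB
    entry files); all other content is ignored.
    """
    text = Path(path).read_text()
    rows = []
    for m in re.finditer(r"loop_(.*?)stop_", text, flags=re.S):
        body = m.group(1)
        tags = re.findall(r"_Atom_chem_shift\.(\S+)", body)
        if not tags:
            continue
        cols = {t: i for i, t in enumerate(tags)}
        need_res = "Comp_index_ID" if "Comp_index_ID" in cols else "Seq_ID"
        if need_res not in cols or "Atom_ID" not in cols or "Val" not in cols:
            continue
        data_part = body.split(f"_Atom_chem_shift.{tags[-1]}", 1)[1]
        for line in data_part.splitlines():
            fields = line.split()
            if len(fields) != len(tags):
                continue
            atom = fields[cols["Atom_ID"]]
            nuc = {"H": "H", "HN": "H", "N": "N", "CA": "CA", "CB": "CB",
                   "C": "C", "HA": "HA"}.get(atom)
            if nuc is None:
                continue
            res3 = fields[cols["Comp_ID"]].upper() if "Comp_ID" in cols else "ALA"
            rows.append({
                "residue_number": int(fields[cols[need_res]]),
                "residue_name": AA3_TO_1.get(res3, "X"),
                "nucleus": nuc,
                "shift_ppm": float(fields[cols["Val"]]),
            })
    if not rows:
        raise ValueError(f"no _Atom_chem_shift rows found in {path}")
    return ShiftTable(pd.DataFrame(rows), state_label=state_label)


# ---------------------------------------------------------------------------
# random-coil reference
# ---------------------------------------------------------------------------

@dataclass
class RandomCoilTable:
    """Random-coil shifts plus full-helix/full-strand reference deltas.

    ``rc[(residue_1letter, nucleus)]`` → ppm;
    ``ref[("helix"|"strand", nucleus)]`` → signed average secondary shift;
    ``corr[("prepro", nucleus)]`` → additive correction for residues
    preceding a proline.
    """

    rc: dict
    ref: dict
    corr: dict = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path_or_text) -> "RandomCoilTable":
        if isinstance(path_or_text, str) and "\n" in path_or_text:
            text = path_or_text
        else:
            text = Path(path_or_text).read_text()
        rc, ref, corr = {}, {}, {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            record, key, nucleus, value = line.split("\t")
            if record == "rc":
                rc[(key, nucleus)] = float(value)
            elif record == "ref":
                ref[(key, nucleus)] = float(value)
            elif record == "corr":
                corr[(key, nucleus)] = float(value)
        return cls(rc=rc, ref=ref, corr=corr)

    @classmethod
    def from_package(cls) -> "RandomCoilTable":
        text = resources.files("premodel.data").joinpath("random_coil.tsv").read_text()
        return cls.from_tsv(text)

    def random_coil(self, residue_name: str, nucleus: str, next_residue: str | None = None):
        """Random-coil shift with pre-proline neighbour correction applied."""
        val = self.rc.get((residue_name, nucleus))
        if val is None:
            return None
        if next_residue == "P":
            val += self.corr.get(("prepro", nucleus), 0.0)
        return val


# ---------------------------------------------------------------------------
# CSP
# ---------------------------------------------------------------------------

@dataclass
class CSPProfile:
    """Composite amide chemical shift changes with assignment flags."""

    df: pd.DataFrame  # residue_number, delta_ppm (NaN where undefined), flag

    def top_residues(self, n: int) -> np.ndarray:
        """Residue numbers of the n largest Δδ among fully assigned residues."""
        sub = self.df[self.df["flag"] == "assigned_both"]
        return sub.nlargest(n, "delta_ppm")["residue_number"].to_numpy()

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


def compute_csp(free: ShiftTable, complexed: ShiftTable) -> CSPProfile:
    """Composite CSP Δδ = sqrt(Δδ_H² + (Δδ_N/6)²) between two states.

    Residues with amide assignments in both states get a Δδ; residues
    assigned in only one state are flagged (``missing_in_complex`` marks
    exchange-broadening candidates).
    """
    free_res = set(free.residues(["H", "N"]).tolist())
    cplx_res = set(complexed.residues(["H", "N"]).tolist())
    if not free_res and not cplx_res:
        raise ValueError("no residues with amide H/N shifts in either table")
    if not (free_res & cplx_res):
        raise ValueError("no overlapping amide-assigned residues between states")
    rows = []
    for r in sorted(free_res | cplx_res):
        if r in free_res and r in cplx_res:
            d_h = complexed.get(r, "H") - free.get(r, "H")
            d_n = complexed.get(r, "N") - free.get(r, "N")
            delta = float(np.hypot(d_h, d_n / 6.0))
            rows.append({"residue_number": r, "delta_ppm": delta, "flag": "assigned_both"})
        elif r in free_res:
            rows.append({"residue_number": r, "delta_ppm": np.nan, "flag": "missing_in_complex"})
        else:
            rows.append({"residue_number": r, "delta_ppm": np.nan, "flag": "missing_in_free"})
    return CSPProfile(pd.DataFrame(rows))


def flag_missing(free: ShiftTable, complexed: ShiftTable) -> pd.DataFrame:
    """Residues amide-assigned in exactly one state.

    ``missing_in_complex`` entries are candidates for intermediate-timescale
    exchange broadening upon binding.
    """
    free_res = set(free.residues(["H", "N"]).tolist())
    cplx_res = set(complexed.residues(["H", "N"]).tolist())
    rows = [{"residue_number": r, "flag": "missing_in_complex"}
            for r in sorted(free_res - cplx_res)]
    rows += [{"residue_number": r, "flag": "missing_in_free"}
             for r in sorted(cplx_res - free_res)]
    return pd.DataFrame(rows, columns=["residue_number", "flag"])


# ---------------------------------------------------------------------------
# secondary shifts and SSP
# ---------------------------------------------------------------------------

def secondary_shifts(observed: ShiftTable, rc: RandomCoilTable) -> pd.DataFrame:
    """Δδ_sec = δ_obs − δ_rc with pre-proline neighbour correction.

    Returns a DataFrame (residue_number, residue_name, nucleus, delta_sec);
    residues whose type or nucleus is missing from the reference are omitted.
    """
    names = {int(r): observed.residue_name(int(r)) for r in observed.residues()}
    rows = []
    for _, row in observed.df.iterrows():
        resnum = int(row["residue_number"])
        res1 = str(row["residue_name"])
        if res1 not in {k[0] for k in rc.rc}:
            raise ValueError(f"unknown residue type {res1!r} at residue {resnum}")
        base = rc.random_coil(res1, row["nucleus"], next_residue=names.get(resnum + 1))
        if base is None:
            continue
        rows.append({"residue_number": resnum, "residue_name": res1,
                     "nucleus": row["nucleus"],
                     "delta_sec": float(row["shift_ppm"]) - base})
    return pd.DataFrame(rows, columns=["residue_number", "residue_name", "nucleus", "delta_sec"])


@dataclass
class SSPProfile:
    """Windowed secondary-structure propensity scores.

    Positive → helical propensity; negative → extended/β propensity;
    |score| ≈ 1 corresponds to fully formed secondary structure.
    """

    df: pd.DataFrame  # residue_number, ssp
    window: int
    nuclei_used: tuple

    def segment_mean(self, lo: int, hi: int) -> float:
        sub = self.df[(self.df["residue_number"] >= lo) & (self.df["residue_number"] <= hi)]
        return float(sub["ssp"].mean())

    def to_tsv(self, path):
        self.df.to_csv(path, sep="\t", index=False)


def compute_ssp(observed: ShiftTable, rc: RandomCoilTable, window: int = 5) -> SSPProfile:
    """Secondary-structure propensity from Cα/Cβ/amide-H secondary shifts.

    For each residue, secondary shifts of the surrounding odd ``window`` are
    sign-aligned (each nucleus multiplied by the sign of its full-helix
    reference so that helix-like deviations count positive), weighted by
    :data:`SSP_WEIGHTS`, and summed. The score is that sum divided by the
    matching weighted sum of reference magnitudes — full-helix magnitudes if
    the numerator is positive, full-strand magnitudes otherwise — so fully
    formed helix scores +1 and fully formed strand −1. Outlier shifts
    (|Δδ_sec| above :data:`SSP_OUTLIER_PPM`) are excluded; scores are capped
    at ±``SSP_CAP``.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and positive")
    sec = secondary_shifts(observed, rc)
    usable = sec[sec["nucleus"].isin(SSP_WEIGHTS)]
    if usable.empty:
        raise ValueError("no CA/CB/H secondary shifts available for SSP")
    by_res: dict[int, list] = {}
    for _, row in usable.iterrows():
        nuc = row["nucleus"]
        if abs(row["delta_sec"]) > SSP_OUTLIER_PPM[nuc]:
            continue
        by_res.setdefault(int(row["residue_number"]), []).append((nuc, row["delta_sec"]))
    half = window // 2
    out_rows = []
    for r in sorted(by_res):
        num = 0.0
        mag_h = 0.0
        mag_s = 0.0
        n_terms = 0
        for j in range(r - half, r + half + 1):
            for nuc, dsec in by_res.get(j, []):
                w = SSP_WEIGHTS[nuc]
                sign = np.sign(rc.ref[("helix", nuc)])
                num += w * sign * dsec
                mag_h += w * abs(rc.ref[("helix", nuc)])
                mag_s += w * abs(rc.ref[("strand", nuc)])
                n_terms += 1
        if n_terms == 0:
            continue
        denom = mag_h if num >= 0 else mag_s
        score = num / denom if denom > 0 else 0.0
        score = float(np.clip(score, -SSP_CAP, SSP_CAP))
        out_rows.append({"residue_number": r, "ssp": score})
    return SSPProfile(pd.DataFrame(out_rows, columns=["residue_number", "ssp"]),
                      window=window, nuclei_used=tuple(sorted(set(usable["nucleus"]))))
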