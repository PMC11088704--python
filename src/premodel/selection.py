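"""Conformer scoring against experimental PREs and ensemble reporting.

Each conformer is scored by the Pearson correlation R between its
back-calculated Γ2 values (pooled over all label sites) and the experimental
profile; the best-correlating n conformers represent the complex. Correlation
is computed per conformer — the reported mean ± sd over the selected subset
mirrors how NMR ensemble statistics tables quote it — with an optional
ensemble-averaged (r⁻⁶ over models) mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pre_analysis import SBParameters, backcalc_profile
from .structures import Ensemble, pairwise_rmsd, ramachandran_stats

__all__ = ["ConformerScore", "score_conformers", "select_top",
           "ensemble_report", "render_report_text"]


@dataclass
class ConformerScore:
    model_id: int
    correlation_R: float
    n_points: int
    restraint_violations: int = 0
    max_violation: float = 0.0
    total_energy: float = float("nan")

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("correlation undefined below 3 points")
        if not (-1.0 - 1e-9 <= self.correlation_R <= 1.0 + 1e-9):
            raise ValueError("correlation outside [-1, 1]")
        if self.restraint_violations < 0:
            raise ValueError("violation count must be >= 0")


def _pooled_experimental(experimental: dict):
    """[(site_name, residue, gamma2), ...] over all defined residues."""
    rows = []
    for name, prof in experimental.items():
        for _, row in prof.defined().iterrows():
            rows.append((name, int(row["residue_number"]), float(row["gamma2"])))
    return rows


def score_conformers(ensemble: Ensemble, experimental: dict, sites: dict,
                     params: SBParameters, peptide_chain: str = "B",
                     restraints=(), violation_tol: float = 0.0):
    """Per-conformer Pearson R between back-calculated and experimental Γ2.

    ``experimental`` maps site name → PREProfile, ``sites`` maps site name →
    LabelSite; residues are pooled across sites, missing pairs dropped
    pairwise. If restraints are given, per-conformer violation counts
    (distance outside bounds by more than ``violation_tol``) are recorded.
    """
    pooled = _pooled_experimental(experimental)
    if not pooled:
        raise ValueError("no experimental PRE points")
    scores = []
    for model in ensemble:
        back = {}
        for name, site in sites.items():
            residues = sorted({r for (s, r, _) in pooled if s == name})
            prof = backcalc_profile(model, site, residues, params, peptide_chain)
            for _, row in prof.defined().iterrows():
                back[(name, int(row["residue_number"]))] = float(row["gamma2"])
        x, y = [], []
        for name, res, g_exp in pooled:
            g_back = back.get((name, res))
            if g_back is not None:
                x.append(g_exp)
                y.append(g_back)
        if len(x) < 3:
            raise ValueError(f"conformer {model.model_id}: fewer than 3 usable "
                             "PRE points")
        r_corr = float(np.corrcoef(np.asarray(x), np.asarray(y))[0, 1])
        n_viol, max_viol = 0, 0.0
        for rst in restraints:
            d = rst.distance(model)
            excess = max(d - rst.upper, rst.lower - d, 0.0)
            if excess > violation_tol:
                n_viol += 1
                max_viol = max(max_viol, excess)
        scores.append(ConformerScore(
            model_id=model.model_id, correlation_R=r_corr, n_points=len(x),
            restraint_violations=n_viol, max_violation=max_viol,
            total_energy=float(model.metadata.get("energy", np.nan))))
    return scores


def filter_consistent(scores, min_pool: int = 20):
    """Restrict to restraint-consistent conformers before ranking by R.

    Keeps conformers with the smallest violation count q such that at least
    ``min_pool`` remain (q = 0 when enough violation-free conformers exist).
    A conformer must satisfy the distance restraints before its PRE
    correlation is meaningful; ranking unfiltered pools by R alone can
    prefer strained geometries that fit the noise.
    """
    if len(scores) <= min_pool:
        return list(scores)
    counts = sorted(s.restraint_violations for s in scores)
    q = counts[min_pool - 1]
    return [s for s in scores if s.restraint_violations <= q]


def select_top(scores, n: int):
    """Top-n conformers by correlation R.

    Ties break by fewer restraint violations, then lower energy, then lower
    model id; the result is independent of input ordering. Returns
    ``(model_ids, mean_R, sd_R, subset_scores)``.
    """
    if n > len(scores):
        raise ValueError(f"cannot select {n} of {len(scores)} conformers")
    def sort_key(s: ConformerScore):
        energy = s.total_energy if np.isfinite(s.total_energy) else np.inf
        return (-s.correlation_R, s.restraint_violations, energy, s.model_id)
    ranked = sorted(scores, key=sort_key)
    subset = ranked[:n]
    r_vals = np.array([s.correlation_R for s in subset])
    sd = float(r_vals.std(ddof=1)) if len(r_vals) > 1 else 0.0
    return [s.model_id for s in subset], float(r_vals.mean()), sd, subset


def ensemble_report(ensemble: Ensemble, restraints=(), scores=None,
                    subunit_chain: str = "B", rmsd_selection: str | None = None):
    """Table-style ensemble statistics.

    Restraint counts by source and by target-distance bin (short < 10 Å,
    medium 10–20 Å, long > 20 Å), pairwise Cα and backbone RMSD mean ± sd
    over the stated subunit, Ramachandran fractions, and the correlation
    summary when scores are given. Returns a nested dict; see
    :func:`render_report_text` for the human-readable rendering.
    """
    report: dict = {"n_conformers": len(ensemble)}

    by_source: dict = {}
    bins = {"short_lt10": 0, "medium_10_20": 0, "long_gt20": 0}
    for r in restraints:
        by_source[r.source] = by_source.get(r.source, 0) + 1
        if r.target < 10.0:
            bins["short_lt10"] += 1
        elif r.target <= 20.0:
            bins["medium_10_20"] += 1
        else:
            bins["long_gt20"] += 1
    report["restraints_total"] = len(list(restraints))
    report["restraints_by_source"] = by_source
    report["restraints_by_range"] = bins

    if len(ensemble) >= 2:
        ca_sel = rmsd_selection or f"{subunit_chain}::CA"
        bb_sel = (rmsd_selection.replace(":CA", ":N,CA,C")
                  if rmsd_selection else f"{subunit_chain}::N,CA,C")
        mean_ca, sd_ca, _ = pairwise_rmsd(ensemble, ca_sel)
        mean_bb, sd_bb, _ = pairwise_rmsd(ensemble, bb_sel)
        report["pairwise_rmsd"] = {"ca_mean": mean_ca, "ca_sd": sd_ca,
                                   "backbone_mean": mean_bb, "backbone_sd": sd_bb}
    report["ramachandran"] = ramachandran_stats(ensemble, subunit_chain)

    if scores:
        r_vals = np.array([s.correlation_R for s in scores])
        report["correlation"] = {
            "mean": float(r_vals.mean()),
            "sd": float(r_vals.std(ddof=1)) if len(r_vals) > 1 else 0.0,
            "n": len(r_vals)}
    return report


def render_report_text(report: dict) -> str:
    lines = ["Structure statistics", "=" * 40]
    lines.append(f"Number of conformers          {report['n_conformers']}")
    lines.append(f"Distance restraints (total)   {report['restraints_total']}")
    for src, n in sorted(report.get("restraints_by_source", {}).items()):
        lines.append(f"  {src:<27} {n}")
    rb = report.get("restraints_by_range", {})
    lines.append(f"  Short-range (<10 A)         {rb.get('short_lt10', 0)}")
    lines.append(f"  Medium-range (10-20 A)      {rb.get('medium_10_20', 0)}")
    lines.append(f"  Long-range (>20 A)          {rb.get('long_gt20', 0)}")
    if "correlation" in report:
        c = report["correlation"]
        lines.append("Correlation with experimental PRE "
                     f"{c['mean']:.2f} +/- {c['sd']:.2f} (n={c['n']})")
    if "pairwise_rmsd" in report:
        p = report["pairwise_rmsd"]
        lines.append("Average pairwise r.m.s. deviation (A)")
        lines.append(f"  CA only                     {p['ca_mean']:.2f} +/- {p['ca_sd']:.2f}")
        lines.append(f"  Backbone                    {p['backbone_mean']:.2f} "
                     f"+/- {p['backbone_sd']:.2f}")
    rama = report.get("ramachandran", {})
    if rama:
        lines.append("Ramachandran statistics (subunit)")
        for cls in ("most_favored", "additional_allowed",
                    "generously_allowed", "disallowed"):
            lines.append(f"  {cls:<27} {100.0 * rama.get(cls, 0.0):.1f}%")
    return "\n".join(lines) + "\n"


def report_to_tsv(report: dict, path):
    rows = []

    def walk(prefix, obj):
        if isinstance(obj, dict):
            for k, v in obj.items():
                walk(f"{prefix}.{k}" if prefix else str(k), v)
        else:
            rows.append({"key": prefix, "value": obj})

    walk("", report)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
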