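"""Comparison of heterogeneous depositions of the same protein.

Structures of one protein solved by different groups under different
conditions carry B-factors on incompatible absolute scales.  After
normalization (division by the selection average) their per-residue
profiles become directly comparable; together with per-residue RMSD
against a chosen reference this exposes whether conformational
variability between depositions tracks B-factor variability.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .bfactor_stats import aggregate_b, normalize_b
from .pdb_io import StructureModel, TemperatureSeries
from .superpose import align_series, displacement_profile

__all__ = ["summary_stats", "compare_set"]

_RESIDUE_KEY = ["chain", "resseq", "icode"]


def summary_stats(models: Sequence[StructureModel]) -> pd.DataFrame:
    """Per-structure header metadata: average B, Wilson B, R-work/R-free,
    cell parameters and temperature.  Absent fields are left blank (NaN)."""
    rows = []
    for m in models:
        try:
            b_avg = float(m.atoms[m.atoms["atom_class"] != "hydrogen"]["b"].mean())
        except Exception:
            b_avg = np.nan
        cell = m.cell or (np.nan,) * 6
        rows.append({
            "structure_id": m.structure_id,
            "b_avg": b_avg,
            "wilson_b": np.nan if m.wilson_b is None else m.wilson_b,
            "r_work": np.nan if m.r_work is None else m.r_work,
            "r_free": np.nan if m.r_free is None else m.r_free,
            "cell_a": cell[0], "cell_b": cell[1], "cell_c": cell[2],
            "cell_alpha": cell[3], "cell_beta": cell[4], "cell_gamma": cell[5],
            "temperature_K": np.nan if m.temperature_K is None else m.temperature_K,
            "n_atoms": len(m.atoms),
        })
    return pd.DataFrame(rows)


def compare_set(models: Sequence[StructureModel], reference_id: str,
                fit_selection: str = "calpha") -> Dict[str, pd.DataFrame]:
    """Raw/normalized B profiles and per-residue RMSD for a structure set.

    Every model is superposed onto the reference (Calpha fit by default);
    residues are compared over the intersection with the reference, and
    mismatched residue names are skipped.  Returns ``{"summary": ...,
    "profiles": ...}`` where profiles is a long frame with one row per
    (structure, selection, residue) carrying b_raw, b_norm and rmsd.
    """
    if len(models) < 2:
        raise ValueError("compare_set needs at least 2 structures")
    ids = [m.structure_id for m in models]
    if reference_id not in ids:
        raise ValueError(f"reference {reference_id!r} not among {ids}")

    # temperatures may be absent for deposited sets; superposition does not
    # need them, so fill a placeholder series temperature where missing
    work: List[StructureModel] = []
    for m in models:
        if m.temperature_K is None:
            m = replace(m, temperature_K=293.0)
        work.append(m)
    series = TemperatureSeries(models=work, reference_id=reference_id)
    aligned = align_series(series, fit_selection=fit_selection)
    ref = series.reference

    parts = []
    for (model, _tf), orig in zip(aligned, models):
        disp = displacement_profile(model, ref)
        for selection, dcol in (("calpha", "d_calpha"), ("side_chain", "d_side_chain")):
            prof = normalize_b(aggregate_b(orig, selection))
            d = prof.data.merge(disp[_RESIDUE_KEY + [dcol]], on=_RESIDUE_KEY, how="left")
            d = d.rename(columns={dcol: "rmsd"})
            d.insert(0, "selection", selection)
            d.insert(0, "structure_id", orig.structure_id)
            parts.append(d)
    profiles = pd.concat(parts, ignore_index=True)
    return {"summary": summary_stats(models), "profiles": profiles}
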