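"""Non-protein atoms across a temperature series.

Crystallographic waters evaporate from the model as temperature rises;
the ones that persist can be tracked by position after superposition.
This module counts waters per temperature, identifies conserved waters
(matched in every — or a configured fraction of — structures), and fits
the exponential thermal model to the mean B of waters, ions and ligand
atoms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pdb_io import StructureModel, TemperatureSeries
from .superpose import RigidTransform, align_series
from .thermal_models import ThermalFit, fit_exponential

__all__ = [
    "match_waters",
    "WaterMatchTable",
    "build_water_match_table",
    "water_census",
    "component_thermal_fit",
]

log = logging.getLogger(__name__)

COMPONENTS = ("conserved_water", "all_water", "ion", "ligand")


def _water_oxygens(model: StructureModel) -> pd.DataFrame:
    w = model.select("water")
    return w[w["element"] == "O"].reset_index(drop=True)


def match_waters(aligned_model: StructureModel, reference: StructureModel,
                 cutoff: float = 1.0) -> pd.DataFrame:
    """Mutual-nearest-neighbour pairing of water oxygens within ``cutoff``.

    Both structures must already be in the reference frame.  Pairs are
    accepted in ascending distance order (mutual nearest neighbours are
    one-to-one by construction; the ordering makes the result
    deterministic).  Returns a frame with reference water key, moving
    water key and the match distance; unmatched reference waters appear
    with NaN distance.
    """
    ref_w = _water_oxygens(reference)
    mov_w = _water_oxygens(aligned_model)
    ref_ids = list(zip(ref_w["chain"], ref_w["resseq"], ref_w["icode"]))
    out = pd.DataFrame({
        "ref_chain": ref_w["chain"], "ref_resseq": ref_w["resseq"],
        "ref_icode": ref_w["icode"],
        "mov_chain": pd.Series([None] * len(ref_w), dtype=object),
        "mov_resseq": pd.Series([np.nan] * len(ref_w)),
        "distance": np.nan,
    })
    if len(ref_w) == 0 or len(mov_w) == 0:
        return out
    ref_xyz = ref_w[["x", "y", "z"]].to_numpy(dtype=float)
    mov_xyz = mov_w[["x", "y", "z"]].to_numpy(dtype=float)
    t_ref = cKDTree(ref_xyz)
    t_mov = cKDTree(mov_xyz)
    d_rm, j_rm = t_mov.query(ref_xyz)        # nearest moving water per reference
    d_mr, j_mr = t_ref.query(mov_xyz)        # nearest reference water per moving
    mutual = [(d_rm[i], i, j_rm[i]) for i in range(len(ref_w))
              if d_rm[i] <= cutoff and j_mr[j_rm[i]] == i]
    for dist, i, j in sorted(mutual):
        out.loc[i, "mov_chain"] = mov_w.loc[j, "chain"]
        out.loc[i, "mov_resseq"] = mov_w.loc[j, "resseq"]
        out.loc[i, "distance"] = dist
    out.attrs["structure_id"] = aligned_model.structure_id
    return out


@dataclass
class WaterMatchTable:
    """Reference waters x structures: match distances and conserved flags.

    ``distances`` is indexed by the reference water key with one column
    per structure_id (NaN = unmatched); ``conserved`` flags reference
    waters matched in at least ``conserved_fraction`` of the structures.
    """

    distances: pd.DataFrame
    conserved: pd.Series
    matched_ids: Dict[str, pd.DataFrame]
    cutoff: float
    conserved_fraction: float


def build_water_match_table(series: TemperatureSeries,
                            aligned: Optional[List[Tuple[StructureModel, RigidTransform]]] = None,
                            cutoff: float = 1.0,
                            conserved_fraction: float = 1.0,
                            fit_selection: str = "calpha") -> WaterMatchTable:
    """Match every structure's waters against the reference after
    superposition and flag the conserved set."""
    if aligned is None:
        aligned = align_series(series, fit_selection=fit_selection)
    ref = series.reference
    dist_cols = {}
    matched_ids = {}
    for model, _tf in aligned:
        m = match_waters(model, ref, cutoff=cutoff)
        key = pd.MultiIndex.from_frame(m[["ref_chain", "ref_resseq", "ref_icode"]])
        dist_cols[model.structure_id] = pd.Series(m["distance"].to_numpy(), index=key)
        matched_ids[model.structure_id] = m
    distances = pd.DataFrame(dist_cols)
    frac = distances.notna().mean(axis=1)
    conserved = frac >= conserved_fraction
    return WaterMatchTable(distances=distances, conserved=conserved,
                           matched_ids=matched_ids, cutoff=cutoff,
                           conserved_fraction=conserved_fraction)


def water_census(series: TemperatureSeries) -> pd.DataFrame:
    """Water counts per temperature, averaged over replicates.

    Returns one row per temperature: mean number of water molecules and
    the water / amino-acid quotient.
    """
    rows = []
    for m in series.models:
        n_w = len(_water_oxygens(m))
        n_aa = m.n_amino_acids()
        rows.append({"structure_id": m.structure_id,
                     "temperature_K": m.temperature_K,
                     "n_waters": n_w,
                     "waters_per_residue": n_w / n_aa if n_aa else np.nan})
    per_structure = pd.DataFrame(rows)
    census = (per_structure.groupby("temperature_K", as_index=False)
              .agg(n_waters=("n_waters", "mean"),
                   waters_per_residue=("waters_per_residue", "mean"),
                   n_replicates=("structure_id", "size")))
    census.attrs["per_structure"] = per_structure
    return census


def component_thermal_fit(series: TemperatureSeries, component: str,
                          aligned: Optional[List[Tuple[StructureModel, RigidTransform]]] = None,
                          match_table: Optional[WaterMatchTable] = None,
                          cutoff: float = 1.0, conserved_fraction: float = 1.0,
                          fit_selection: str = "calpha") -> ThermalFit:
    """Exponential B(T) fit for one non-protein component.

    The per-structure response is the mean B over the component's atoms;
    for ``conserved_water`` only waters matched to the conserved
    reference set count.  Structures lacking the component are skipped
    with a warning; fewer than 3 remaining is an error.
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}; choose from {COMPONENTS}")
    if component == "conserved_water" and match_table is None:
        match_table = build_water_match_table(
            series, aligned=aligned, cutoff=cutoff,
            conserved_fraction=conserved_fraction, fit_selection=fit_selection)
    t_vals, y_vals = [], []
    for m in series.models:
        if component == "all_water":
            sub = _water_oxygens(m)
        elif component == "conserved_water":
            matches = match_table.matched_ids[m.structure_id]
            key = pd.MultiIndex.from_frame(
                matches[["ref_chain", "ref_resseq", "ref_icode"]])
            keep = matches[match_table.conserved.reindex(key).to_numpy()
                           & matches["distance"].notna().to_numpy()]
            waters = _water_oxygens(m).set_index(["chain", "resseq"])
            idx = pd.MultiIndex.from_arrays(
                [keep["mov_chain"], keep["mov_resseq"].astype(int)])
            sub = waters.loc[waters.index.intersection(idx)].reset_index()
        else:
            sub = m.select(component)
        if len(sub) == 0:
            warnings.warn(f"{m.structure_id}: no {component} atoms; structure skipped")
            continue
        t_vals.append(m.temperature_K)
        y_vals.append(float(sub["b"].mean()))
    if len(t_vals) < 3:
        raise ValueError(f"{component}: only {len(t_vals)} structures carry the component")
    return fit_exponential(np.array(t_vals), np.array(y_vals))
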