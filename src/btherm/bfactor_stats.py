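"""B-factor aggregation, Debye-Waller conversion and normalization.

The crystallographic B relates to the mean-square displacement through
B = 8 pi^2 <x^2>.  Normalized B-factors divide each observation by the
average over its selection, removing the per-dataset scale so profiles
collected on different crystals and instruments become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np
import pandas as pd

from .pdb_io import StructureModel

__all__ = ["EIGHT_PI_SQ", "b_to_msd", "msd_to_b", "BProfile", "aggregate_b", "normalize_b"]

EIGHT_PI_SQ = 8.0 * np.pi ** 2

#: selections aggregated per residue; the rest aggregate per atom
_RESIDUE_SELECTIONS = ("calpha", "side_chain")
_ATOM_SELECTIONS = ("water", "ligand", "ion")


def b_to_msd(b):
    """Mean-square displacement <x^2> = B / (8 pi^2), in Angstrom^2."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factor must be non-negative")
    out = b / EIGHT_PI_SQ
    return float(out) if out.ndim == 0 else out


def msd_to_b(x2):
    """Inverse Debye-Waller conversion: B = 8 pi^2 <x^2>."""
    x2 = np.asarray(x2, dtype=float)
    if np.any(x2 < 0):
        raise ValueError("mean-square displacement must be non-negative")
    out = EIGHT_PI_SQ * x2
    return float(out) if out.ndim == 0 else out


@dataclass
class BProfile:
    """Per-residue (or per-atom) raw and normalized B for one selection of
    one structure.

    ``data`` has columns chain, resseq, icode, resname, b_raw and, after
    :func:`normalize_b`, b_norm; ``b_avg`` is the unweighted mean of
    b_raw over the profile.
    """

    structure_id: str
    temperature_K: Optional[float]
    selection: str
    data: pd.DataFrame
    b_avg: float

    @property
    def normalized(self) -> bool:
        return "b_norm" in self.data.columns


def aggregate_b(model: StructureModel, selection: str, level: str = "per_residue",
                include_zero_occupancy: bool = False,
                ) -> Union[BProfile, float]:
    """Aggregate B-factors of one selection.

    Protein selections (``calpha``, ``side_chain``) aggregate per residue:
    the Calpha profile takes the Calpha atom's B, the side-chain profile
    the unweighted mean over the residue's side-chain heavy atoms
    (glycines are absent).  Water/ligand/ion profiles are per atom.
    ``level='per_structure'`` returns the scalar mean over the profile.
    Zero-occupancy atoms are excluded unless asked for.
    """
    if selection not in _RESIDUE_SELECTIONS + _ATOM_SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}")
    if level not in ("per_residue", "per_structure"):
        raise ValueError(f"unknown level {level!r}")
    df = model.select(selection)
    if not include_zero_occupancy:
        df = df[df["occ"] > 0]
    if len(df) == 0:
        raise ValueError(f"{model.structure_id}: selection {selection!r} is empty")
    if selection in _RESIDUE_SELECTIONS:
        data = (df.groupby(["chain", "resseq", "icode"], as_index=False)
                .agg(resname=("resname", "first"), b_raw=("b", "mean")))
    else:
        data = df[["chain", "resseq", "icode", "resname", "name", "b"]].rename(
            columns={"b": "b_raw"}).reset_index(drop=True)
    b_avg = float(data["b_raw"].mean())
    if level == "per_structure":
        return b_avg
    return BProfile(structure_id=model.structure_id,
                    temperature_K=model.temperature_K,
                    selection=selection, data=data, b_avg=b_avg)


def normalize_b(profile: BProfile) -> BProfile:
    """Fill ``b_norm = b_raw / b_avg``; the profile mean of b_norm is 1.

    Scale-invariant: multiplying every raw B by a positive constant leaves
    the normalized profile unchanged.
    """
    if not profile.b_avg > 0:
        raise ValueError(
            f"{profile.structure_id}/{profile.selection}: degenerate profile "
            f"(b_avg = {profile.b_avg})")
    data = profile.data.copy()
    data["b_norm"] = data["b_raw"] / profile.b_avg
    return replace(profile, data=data)
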