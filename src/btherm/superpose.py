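"""Least-squares rigid superposition and per-residue displacement profiles.

The Kabsch solver (SVD with the determinant correction restricting the
optimum to proper rotations) aligns each structure of a temperature
series onto a reference; displacement profiles then measure, residue by
residue, how far Calpha atoms and side chains have moved in the common
frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pdb_io import StructureModel, TemperatureSeries

__all__ = [
    "RigidTransform",
    "kabsch_fit",
    "align_series",
    "displacement_profile",
    "global_displacement",
]

log = logging.getLogger(__name__)

_RESIDUE_KEY = ["chain", "resseq", "icode"]
_ATOM_KEY = _RESIDUE_KEY + ["name"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_fit_atoms: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0, 0)


def kabsch_fit(moving_coords: np.ndarray, reference_coords: np.ndarray) -> RigidTransform:
    """Optimal proper rotation + translation mapping ``moving`` onto
    ``reference`` in the least-squares sense.

    Points are paired by index.  The reflection branch of the SVD optimum
    is excluded by flipping the sign of the smallest singular vector when
    needed, the standard determinant correction.
    """
    X = np.asarray(moving_coords, dtype=float)
    Y = np.asarray(reference_coords, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("coordinate sets must both be (N, 3)")
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs >= 3 paired atoms, got {n}")
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    Xc = X - mx
    Yc = Y - my
    C = Xc.T @ Yc
    U, S, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = (U @ D @ Vt).T
    t = my - R @ mx
    diff = Xc @ R.T - Yc
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd, n_fit_atoms=n)


def _matched_atoms(model: StructureModel, reference: StructureModel,
                   atom_classes: Sequence[str]) -> pd.DataFrame:
    """Inner join of heavy atoms on (chain, resseq, icode, name); rows where
    the residue name differs (mutations/renames) are dropped and logged."""
    a = model.select(*atom_classes)
    b = reference.select(*atom_classes)
    merged = a.merge(b, on=_ATOM_KEY, suffixes=("_mov", "_ref"))
    mism = merged["resname_mov"] != merged["resname_ref"]
    if mism.any():
        log.info("%s vs %s: dropping %d atoms with mismatched residue names",
                 model.structure_id, reference.structure_id, int(mism.sum()))
        merged = merged[~mism]
    return merged


def align_series(series: TemperatureSeries, fit_selection: str = "calpha",
                 ) -> List[Tuple[StructureModel, RigidTransform]]:
    """Superpose every model of the series onto the reference.

    ``fit_selection`` is the atom class the rotation is fitted on
    ("calpha" or "backbone"; backbone here means N/C/O + CA).  The
    returned models carry transformed coordinates; the reference maps to
    itself with the exact identity.
    """
    if fit_selection not in ("calpha", "backbone"):
        raise ValueError("fit_selection must be 'calpha' or 'backbone'")
    classes = ("calpha",) if fit_selection == "calpha" else ("calpha", "backbone")
    ref = series.reference
    out: List[Tuple[StructureModel, RigidTransform]] = []
    for model in series.models:
        if model.structure_id == series.reference_id:
            out.append((model, RigidTransform.identity()))
            continue
        matched = _matched_atoms(model, ref, classes)
        if len(matched) < 3:
            raise ValueError(
                f"{model.structure_id}: only {len(matched)} atoms match the "
                f"reference on selection {fit_selection!r}")
        tf = kabsch_fit(matched[["x_mov", "y_mov", "z_mov"]].to_numpy(),
                        matched[["x_ref", "y_ref", "z_ref"]].to_numpy())
        out.append((model.with_coords(tf.apply(model.coords())), tf))
    return out


def displacement_profile(aligned_model: StructureModel, reference: StructureModel,
                         ) -> pd.DataFrame:
    """Per-residue displacement of an aligned model relative to the reference.

    Returns a frame with one row per matched residue: ``d_calpha`` is the
    Euclidean distance between the paired Calpha atoms and
    ``d_side_chain`` the unweighted mean of per-atom distances over the
    residue's matched side-chain heavy atoms (NaN where the residue has
    none, e.g. glycine).  The model must already be in the reference frame.
    """
    parts = {}
    for col, classes in (("d_calpha", ("calpha",)),
                         ("d_side_chain", ("side_chain",))):
        m = _matched_atoms(aligned_model, reference, classes)
        if len(m) == 0:
            parts[col] = pd.DataFrame(columns=_RESIDUE_KEY + ["resname", col])
            continue
        d = np.sqrt(((m[["x_mov", "y_mov", "z_mov"]].to_numpy()
                      - m[["x_ref", "y_ref", "z_ref"]].to_numpy()) ** 2).sum(axis=1))
        m = m.assign(_d=d)
        parts[col] = (m.groupby(_RESIDUE_KEY, as_index=False)
                      .agg(**{col: ("_d", "mean"), "resname": ("resname_ref", "first")}))
    prof = parts["d_calpha"].merge(parts["d_side_chain"],
                                   on=_RESIDUE_KEY + ["resname"], how="outer")
    prof = prof.sort_values(_RESIDUE_KEY).reset_index(drop=True)
    prof.attrs["structure_id"] = aligned_model.structure_id
    prof.attrs["temperature_K"] = aligned_model.temperature_K
    return prof


def global_displacement(profile: pd.DataFrame,
                        residue_range: Optional[Tuple[int, int]] = None,
                        ) -> Tuple[float, float]:
    """Mean (d_calpha, d_side_chain) over residues in ``residue_range``
    (inclusive author numbering; None = all residues).  Residues lacking a
    value are excluded from that mean."""
    df = profile
    if residue_range is not None:
        lo, hi = residue_range
        df = df[(df["resseq"] >= lo) & (df["resseq"] <= hi)]
    if len(df) == 0:
        raise ValueError(f"no residues in range {residue_range}")
    return (float(df["d_calpha"].mean(skipna=True)),
            float(df["d_side_chain"].mean(skipna=True)))
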