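"""PDB-format structure I/O and atom classification.

Parsing and fixed-column formatting are delegated to :mod:`gemmi`; this
module adds the bookkeeping the analysis needs on top of it: alternate
location resolution, extraction of the data-collection temperature
(REMARK 200) and Wilson B (REMARK 3), and a deterministic partition of
atoms into the selections the downstream stages operate on (Calpha,
backbone, side chain, water, ion, ligand, hydrogen).

Atoms are held in a :class:`pandas.DataFrame` inside
:class:`StructureModel`; one row per atom after altloc resolution, keyed
by ``(chain, resseq, icode, name)``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "StructureModel",
    "TemperatureSeries",
    "classify_atom",
    "read_structure",
    "write_structure",
    "resolve_temperature",
    "read_series",
    "write_manifest",
]

# Residue-name vocabularies used by the classifier.
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}
WATER_RESIDUES = {"HOH", "WAT"}
# Monatomic ions deposited as single-atom HETATM residues.
ION_RESIDUES = {"CA", "MG", "NA", "K", "CL", "ZN", "MN", "FE", "CO", "NI", "CU", "CD", "BR", "IOD"}

ATOM_CLASSES = ("calpha", "backbone", "side_chain", "water", "ion", "ligand", "hydrogen")

_ATOM_COLUMNS = [
    "serial", "name", "altloc", "resname", "chain", "resseq", "icode",
    "element", "x", "y", "z", "occ", "b", "atom_class",
]

_RE_T200 = re.compile(r"REMARK 200\s+TEMPERATURE\s+\(KELVIN\)\s*:\s*([0-9.]+)")
_RE_WILSON = re.compile(r"REMARK   3\s+FROM WILSON PLOT\s+\(A\*\*2\)\s*:\s*([0-9.Ee+-]+)")
_RE_RWORK = re.compile(r"REMARK   3\s+R VALUE\s+\(WORKING SET\)\s*:\s*([0-9.]+)")
_RE_RFREE = re.compile(r"REMARK   3\s+FREE R VALUE\s+:\s*([0-9.]+)")


@dataclass(frozen=True)
class AtomRecord:
    """One atom after altloc resolution."""

    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_seq: int
    insertion_code: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float
    b_factor: float
    atom_class: str


@dataclass
class StructureModel:
    """One crystal structure: an atom table plus header metadata."""

    structure_id: str
    atoms: pd.DataFrame
    temperature_K: Optional[float] = None
    wilson_b: Optional[float] = None
    replicate_id: Optional[int] = None
    cell: Optional[Tuple[float, float, float, float, float, float]] = None
    r_work: Optional[float] = None
    r_free: Optional[float] = None
    spacegroup: Optional[str] = None

    def __post_init__(self) -> None:
        if self.temperature_K is not None and not self.temperature_K > 0:
            raise ValueError(f"{self.structure_id}: temperature_K must be > 0")

    # -- selection helpers -------------------------------------------------

    def select(self, *atom_classes: str) -> pd.DataFrame:
        """Rows of the given atom classes (hydrogens never included
        unless asked for explicitly)."""
        bad = set(atom_classes) - set(ATOM_CLASSES)
        if bad:
            raise ValueError(f"unknown atom class(es): {sorted(bad)}")
        return self.atoms[self.atoms["atom_class"].isin(atom_classes)]

    def coords(self, df: Optional[pd.DataFrame] = None) -> np.ndarray:
        df = self.atoms if df is None else df
        return df[["x", "y", "z"]].to_numpy(dtype=float)

    def n_amino_acids(self) -> int:
        prot = self.atoms[self.atoms["atom_class"].isin(("calpha", "backbone", "side_chain"))]
        return len(prot.groupby(["chain", "resseq", "icode"]).size())

    def iter_atoms(self) -> Iterable[AtomRecord]:
        for row in self.atoms.itertuples(index=False):
            yield AtomRecord(
                serial=int(row.serial), name=row.name, altloc=row.altloc,
                residue_name=row.resname, chain_id=row.chain,
                residue_seq=int(row.resseq), insertion_code=row.icode,
                element=row.element, x=row.x, y=row.y, z=row.z,
                occupancy=row.occ, b_factor=row.b, atom_class=row.atom_class,
            )

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        """Copy of this model with replaced coordinates (same atom order)."""
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = self.atoms.copy()
        atoms[["x", "y", "z"]] = xyz
        return replace(self, atoms=atoms)


@dataclass
class TemperatureSeries:
    """An ordered set of structures spanning data-collection temperatures."""

    models: List[StructureModel]
    reference_id: str

    def __post_init__(self) -> None:
        ids = [m.structure_id for m in self.models]
        if self.reference_id not in ids:
            raise ValueError(f"reference {self.reference_id!r} not in series {ids}")
        missing = [m.structure_id for m in self.models if m.temperature_K is None]
        if missing:
            raise ValueError(f"structures without temperature: {missing}")

    @property
    def reference(self) -> StructureModel:
        return next(m for m in self.models if m.structure_id == self.reference_id)

    def temperatures(self) -> np.ndarray:
        return np.array([m.temperature_K for m in self.models], dtype=float)

    def require_distinct_temperatures(self, n: int = 2) -> None:
        if len(set(self.temperatures().tolist())) < n:
            raise ValueError(f"series needs >= {n} distinct temperatures")


# ---------------------------------------------------------------------------
# classification


def classify_atom(residue_name: str, atom_name: str, element: str,
                  oxt_is_backbone: bool = True) -> str:
    """Deterministic atom classification.

    Amino-acid N/C/O (and OXT by default) are backbone, CA is its own
    class, remaining amino-acid heavy atoms are side chain.  Waters are
    recognised by residue name (HOH/WAT), single-atom ionic residues by a
    fixed vocabulary, any other het group is a ligand.  Hydrogen wins over
    everything: downstream selections never see it.
    """
    if not residue_name or not atom_name:
        raise ValueError("residue_name and atom_name must be non-empty")
    el = element.strip().upper()
    if el in ("H", "D"):
        return "hydrogen"
    rn = residue_name.strip().upper()
    an = atom_name.strip().upper()
    if rn in AMINO_ACIDS:
        if an == "CA":
            return "calpha"
        backbone = {"N", "C", "O"} | ({"OXT"} if oxt_is_backbone else set())
        return "backbone" if an in backbone else "side_chain"
    if rn in WATER_RESIDUES:
        return "water"
    if rn in ION_RESIDUES:
        return "ion"
    return "ligand"


# ---------------------------------------------------------------------------
# reading


def _parse_remarks(raw_remarks: Sequence[str]):
    temp = wilson = rwork = rfree = None
    for line in raw_remarks:
        if temp is None:
            m = _RE_T200.search(line)
            if m:
                try:
                    temp = float(m.group(1))
                except ValueError:
                    pass
                continue
        if wilson is None:
            m = _RE_WILSON.search(line)
            if m:
                try:
                    wilson = float(m.group(1))
                except ValueError:
                    pass
                continue
        if rwork is None:
            m = _RE_RWORK.search(line)
            if m:
                rwork = float(m.group(1))
                continue
        if rfree is None:
            m = _RE_RFREE.search(line)
            if m:
                rfree = float(m.group(1))
    return temp, wilson, rwork, rfree


def _resolve_altlocs(df: pd.DataFrame, policy: str) -> pd.DataFrame:
    """Collapse altloc groups to one row per (chain, resseq, icode, name)."""
    if policy not in ("highest_occupancy", "first"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    key = ["chain", "resseq", "icode", "name"]
    if not df.duplicated(key).any():
        return df
    if policy == "first":
        return df.drop_duplicates(key, keep="first").reset_index(drop=True)
    # highest occupancy; ties broken by lexicographically smallest altloc
    df = df.sort_values(key + ["occ", "altloc"],
                        ascending=[True, True, True, True, False, True],
                        kind="mergesort")
    out = df.drop_duplicates(key, keep="first")
    return out.sort_values("serial", kind="mergesort").reset_index(drop=True)


def read_structure(path: str | Path, altloc_policy: str = "highest_occupancy",
                   structure_id: Optional[str] = None,
                   oxt_is_backbone: bool = True) -> StructureModel:
    """Read one PDB file into a :class:`StructureModel`.

    Only the first MODEL of a multi-model file is used (a warning is
    issued for the rest).  Altloc groups are collapsed according to
    ``altloc_policy``; ``highest_occupancy`` keeps the highest-occupancy
    record (ties: lexicographically smallest altloc ID), ``first`` keeps
    the first record encountered.
    """
    path = Path(path)
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no coordinate records")
    if len(st) > 1:
        warnings.warn(f"{path}: {len(st)} MODELs present; only the first is read")
    rows = []
    serial = 0
    for chain in st[0]:
        for res in chain:
            for atom in res:
                serial += 1
                altloc = atom.altloc if atom.altloc != "\x00" else ""
                rows.append((
                    atom.serial or serial, atom.name, altloc, res.name.strip(),
                    chain.name, res.seqid.num, (res.seqid.icode or " ").strip(),
                    atom.element.name.upper(),
                    atom.pos.x, atom.pos.y, atom.pos.z,
                    round(float(atom.occ), 2), round(float(atom.b_iso), 2),
                    classify_atom(res.name, atom.name, atom.element.name,
                                  oxt_is_backbone=oxt_is_backbone),
                ))
    if not rows:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    df = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    df = _resolve_altlocs(df, altloc_policy)
    bad = df[(df.occ < 0) | (df.occ > 1) | (df.b < 0)]
    if len(bad):
        raise ValueError(f"{path}: {len(bad)} atoms with occupancy outside [0,1] or negative B")
    temp, wilson, rwork, rfree = _parse_remarks(st.raw_remarks)
    cell = None
    if st.cell and st.cell.a > 1.0:
        c = st.cell
        cell = (c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return StructureModel(
        structure_id=structure_id or path.stem.upper(),
        atoms=df, temperature_K=temp, wilson_b=wilson,
        cell=cell, r_work=rwork, r_free=rfree,
        spacegroup=st.spacegroup_hm or None,
    )


# ---------------------------------------------------------------------------
# writing


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-column PDB text (via gemmi).

    Emits REMARK 200 temperature and REMARK 3 Wilson-B lines when those
    metadata are present so a round trip preserves them.
    """
    df = model.atoms
    if len(df) == 0:
        raise ValueError("cannot write an empty structure")
    if (df[["x", "y", "z"]].abs() >= 1e4).any().any():
        raise ValueError("coordinate overflows the PDB fixed-width field")
    if (df["b"] >= 1e3).any():
        raise ValueError("B-factor overflows the PDB fixed-width field")

    st = gemmi.Structure()
    st.name = model.structure_id
    if model.cell is not None:
        st.cell = gemmi.UnitCell(*model.cell)
    if model.spacegroup:
        st.spacegroup_hm = model.spacegroup
    remarks = []
    if model.r_work is not None:
        remarks.append(f"REMARK   3   R VALUE            (WORKING SET) : {model.r_work:.3f}")
    if model.r_free is not None:
        remarks.append(f"REMARK   3   FREE R VALUE                     : {model.r_free:.3f}")
    if model.wilson_b is not None:
        remarks.append(f"REMARK   3   FROM WILSON PLOT           (A**2) : {model.wilson_b:.2f}")
    if model.temperature_K is not None:
        remarks.append(f"REMARK 200  TEMPERATURE           (KELVIN) : {model.temperature_K:g}")
    st.raw_remarks = remarks

    gm = gemmi.Model("1")
    for chain_id, chain_df in df.groupby("chain", sort=False):
        ch = gemmi.Chain(str(chain_id))
        for (resseq, icode, resname), res_df in chain_df.groupby(
                ["resseq", "icode", "resname"], sort=False):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(int(resseq), icode if icode else " ")
            res.het_flag = "A" if resname in AMINO_ACIDS else "H"
            for row in res_df.itertuples(index=False):
                a = gemmi.Atom()
                a.name = row.name
                if row.altloc:
                    a.altloc = row.altloc
                a.element = gemmi.Element(row.element.capitalize())
                a.pos = gemmi.Position(row.x, row.y, row.z)
                a.occ = float(row.occ)
                a.b_iso = float(row.b)
                res.add_atom(a)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    Path(path).write_text(st.make_pdb_string())


# ---------------------------------------------------------------------------
# temperature resolution and series manifests


def resolve_temperature(model: StructureModel,
                        override_table: Optional[Dict[str, float]] = None) -> float:
    """Data-collection temperature: override table wins over REMARK 200."""
    if override_table and model.structure_id in override_table:
        return float(override_table[model.structure_id])
    if model.temperature_K is not None:
        return float(model.temperature_K)
    raise ValueError(f"no temperature available for structure {model.structure_id!r}")


def read_series(manifest_path: str | Path, reference_id: Optional[str] = None,
                altloc_policy: str = "highest_occupancy",
                temperature_overrides: Optional[Dict[str, float]] = None,
                ) -> TemperatureSeries:
    """Load a temperature series from a TSV manifest.

    Columns: ``structure_id``, ``path``, ``temperature_K`` (blank = take
    from the file header), ``replicate_id``.  Relative paths are resolved
    against the manifest's directory.  The reference defaults to the first
    row.
    """
    manifest_path = Path(manifest_path)
    tab = pd.read_csv(manifest_path, sep="\t", dtype={"structure_id": str})
    required = {"structure_id", "path"}
    if not required.issubset(tab.columns):
        raise ValueError(f"{manifest_path}: manifest needs columns {sorted(required)}")
    models = []
    for i, row in tab.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_path.parent / p
        try:
            m = read_structure(p, altloc_policy=altloc_policy,
                               structure_id=row["structure_id"])
        except Exception as exc:
            raise ValueError(f"{manifest_path} line {i + 2}: {exc}") from exc
        if "temperature_K" in tab.columns and pd.notna(row.get("temperature_K")):
            m.temperature_K = float(row["temperature_K"])
        m.temperature_K = resolve_temperature(m, temperature_overrides)
        if "replicate_id" in tab.columns and pd.notna(row.get("replicate_id")):
            m.replicate_id = int(row["replicate_id"])
        models.append(m)
    if not models:
        raise ValueError(f"{manifest_path}: empty manifest")
    ref = reference_id or models[0].structure_id
    return TemperatureSeries(models=models, reference_id=ref)


def write_manifest(models: Sequence[StructureModel], paths: Sequence[str | Path],
                   out_path: str | Path) -> None:
    rows = [{
        "structure_id": m.structure_id,
        "path": str(p),
        "temperature_K": m.temperature_K,
        "replicate_id": m.replicate_id,
    } for m, p in zip(models, paths)]
    pd.DataFrame(rows).to_csv(out_path, sep="\t", index=False)
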