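"""Synthetic PDB ensembles with known ground truth.

The generator emulates a multi-temperature crystallographic study: a
series of structures of one protein collected at 9 temperatures (100 to
300 K in 25 K steps) in triplicate, where

* every residue's B-factor follows B(T) = B0_i * exp(k_i * T) with
  multiplicative noise,
* residues drift by a small temperature-proportional displacement
  delta_i * (T - Tmin) along a fixed per-residue direction,
* each replicate sits in its own rigid frame (a random proper rotation
  and translation, as independently mounted crystals would),
* waters are retained with a temperature-dependent probability p(T),

and the complete truth table (B0_i, k_i, delta_i, transforms, retention
schedule) is returned alongside, so every downstream stage can be
checked against known values.

The base chain is a coarse-grained poly-alanine-like model: a gently
coiled self-avoiding backbone (N, CA, C, O per residue) with one-atom
side chains (CB) on non-glycine positions, plus a six-atom ligand ring,
one calcium ion and a configurable number of waters.  Pseudo-bond
lengths are >= 2 Angstrom — the chain is a stand-in for the analysis
geometry (atom classes and positions), not for covalent stereochemistry.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .pdb_io import StructureModel, TemperatureSeries, classify_atom, write_manifest, write_structure

__all__ = [
    "TruthConfig",
    "SyntheticTruth",
    "generate_base_structure",
    "generate_ensemble",
    "DEFAULT_TEMPERATURES",
]

DEFAULT_TEMPERATURES = tuple(range(100, 301, 25))  # 9 temperatures, 25 K steps

_ATOM_COLUMNS = [
    "serial", "name", "altloc", "resname", "chain", "resseq", "icode",
    "element", "x", "y", "z", "occ", "b", "atom_class",
]


@dataclass
class TruthConfig:
    """Ground-truth distributions for :func:`generate_ensemble`.

    Defaults bracket the magnitudes seen in real multi-temperature
    protein series: zero-Kelvin B around 6 A^2, thermal constants around
    0.005 1/K, displacement coefficients of order 1e-3 A/K.
    """

    # per-residue zero-Kelvin B: log-normal(median, sigma of ln B)
    b0_median: float = 6.0
    b0_sigma_log: float = 0.4
    # side-chain atoms carry this multiple of the residue's B0
    sc_b0_factor: float = 1.3
    # thermal constant: "uniform" draws per residue, "fixed" shares one value
    k_mode: str = "uniform"
    k_range: Tuple[float, float] = (0.004, 0.006)
    k_fixed: float = 0.005
    # displacement coefficient delta_i (A/K): half-normal, or tied to
    # log10(B0) in planted mode (a positive control for the correlation
    # stage; its amplitude is set so the planted signal dominates the
    # displacement measurement noise floor)
    delta_mode: str = "independent"          # or "planted_logb0"
    delta_sd: float = 0.0015
    planted_slope: float = 0.01
    # noise
    coord_noise_sd: float = 0.05             # A, isotropic per atom
    b_noise_frac: float = 0.05               # multiplicative sd on B
    # replicate-frame rigid transforms
    identity_transforms: bool = False
    transform_max_angle_deg: float = 15.0
    transform_max_shift: float = 4.0
    # water retention p(T): linear from p_start at Tmin to p_end at Tmax
    retention_p_start: float = 1.0
    retention_p_end: float = 0.5
    # non-protein B parameters
    water_b0_median: float = 8.0
    water_b0_sigma_log: float = 0.3
    ion_b0: float = 4.0
    ligand_b0: float = 6.0
    nonprotein_k: float = 0.005

    def validate(self) -> None:
        if self.b0_median <= 0 or self.b0_sigma_log < 0:
            raise ValueError("B0 distribution parameters must be positive")
        if self.k_mode not in ("uniform", "fixed"):
            raise ValueError(f"unknown k_mode {self.k_mode!r}")
        if self.delta_mode not in ("independent", "planted_logb0"):
            raise ValueError(f"unknown delta_mode {self.delta_mode!r}")
        for p in (self.retention_p_start, self.retention_p_end):
            if not 0.0 <= p <= 1.0:
                raise ValueError("retention probabilities must lie in [0, 1]")
        if self.coord_noise_sd < 0 or self.b_noise_frac < 0:
            raise ValueError("noise levels must be non-negative")

    @staticmethod
    def noiseless(**overrides) -> "TruthConfig":
        """Convenience: no noise, identity frames, full water retention."""
        base = dict(coord_noise_sd=0.0, b_noise_frac=0.0,
                    identity_transforms=True,
                    retention_p_start=1.0, retention_p_end=1.0)
        base.update(overrides)
        return TruthConfig(**base)


@dataclass
class SyntheticTruth:
    """Ground truth paired with a generated ensemble."""

    residues: pd.DataFrame        # resseq, resname, b0, b0_side, k, delta, ux, uy, uz
    waters: pd.DataFrame          # resseq, b0
    nonprotein: Dict[str, float]  # ion_b0, ligand_b0, k
    transforms: pd.DataFrame      # replicate, r11..r33, t1..t3
    retention: pd.DataFrame       # temperature_K, p
    realized: pd.DataFrame        # structure_id, temperature_K, replicate, n_waters
    config: TruthConfig
    seed: int

    def transform_of(self, replicate: int) -> Tuple[np.ndarray, np.ndarray]:
        row = self.transforms[self.transforms["replicate"] == replicate].iloc[0]
        R = np.array([[row[f"r{i}{j}"] for j in (1, 2, 3)] for i in (1, 2, 3)])
        t = np.array([row.t1, row.t2, row.t3])
        return R, t

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.residues.to_csv(out / "truth_residues.tsv", sep="\t", index=False)
        self.waters.to_csv(out / "truth_waters.tsv", sep="\t", index=False)
        self.transforms.to_csv(out / "truth_transforms.tsv", sep="\t", index=False)
        self.retention.to_csv(out / "truth_retention.tsv", sep="\t", index=False)
        self.realized.to_csv(out / "truth_realized.tsv", sep="\t", index=False)
        meta = {"nonprotein": self.nonprotein, "seed": self.seed,
                "config": dataclasses.asdict(self.config)}
        (out / "truth_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, out_dir: str | Path) -> "SyntheticTruth":
        out = Path(out_dir)
        meta = json.loads((out / "truth_meta.json").read_text())
        cfg_d = meta["config"]
        cfg_d["k_range"] = tuple(cfg_d["k_range"])
        def _read(name):
            # round_trip float parsing keeps the truth table lossless
            return pd.read_csv(out / name, sep="\t", float_precision="round_trip")

        return cls(
            residues=_read("truth_residues.tsv"),
            waters=_read("truth_waters.tsv"),
            nonprotein=meta["nonprotein"],
            transforms=_read("truth_transforms.tsv"),
            retention=_read("truth_retention.tsv"),
            realized=_read("truth_realized.tsv"),
            config=TruthConfig(**cfg_d), seed=meta["seed"],
        )


# ---------------------------------------------------------------------------
# base geometry


def _chain_frames(n: int):
    """CA positions on a gentle coil plus local (tangent, radial, binormal)
    frames.  Curvature radius 25 A keeps the chain self-avoiding and far
    from collinear while local geometry stays near the straight-chain
    template."""
    R, alpha = 25.0, 0.12
    rise = np.sqrt(3.9 ** 2 - (R * alpha) ** 2)
    i = np.arange(n)
    phi = alpha * i
    ca = np.stack([R * np.cos(phi), R * np.sin(phi), rise * i], axis=1)
    e_r = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
    nxt = np.vstack([ca[1:], ca[-1] + (ca[-1] - ca[-2])])
    prv = np.vstack([ca[0] - (ca[1] - ca[0]), ca[:-1]])
    e_t = nxt - prv
    e_t /= np.linalg.norm(e_t, axis=1, keepdims=True)
    e_b = np.cross(e_t, e_r)
    e_b /= np.linalg.norm(e_b, axis=1, keepdims=True)
    return ca, e_t, e_r, e_b


def generate_base_structure(n_residues: int, seed: int = 0,
                            n_waters: Optional[int] = None,
                            glycine_every: int = 8) -> StructureModel:
    """Deterministic coarse-grained base structure.

    ``n_residues`` backbone+CB residues (every ``glycine_every``-th is
    glycine, contributing no side-chain atom), a six-atom benzamidine-like
    ring, one calcium ion and ``n_waters`` (default ``2 * n_residues``)
    waters placed at least 2.4 A from every other atom.
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    if n_waters is None:
        n_waters = 2 * n_residues
    rng = np.random.default_rng(seed)
    ca, e_t, e_r, e_b = _chain_frames(n_residues)

    rows = []
    serial = 0

    def add(name, resname, chain, resseq, element, pos, bval=10.0):
        nonlocal serial
        serial += 1
        rows.append((serial, name, "", resname, chain, resseq, "",
                     element, float(pos[0]), float(pos[1]), float(pos[2]),
                     1.0, bval, classify_atom(resname, name, element)))

    for idx in range(n_residues):
        resseq = idx + 1
        resname = "GLY" if (resseq % glycine_every == 3) else "ALA"
        n_pos = ca[idx] - 1.2 * e_t[idx] + 1.7 * e_b[idx]
        c_pos = ca[idx] + 1.2 * e_t[idx] - 1.7 * e_b[idx]
        o_pos = c_pos - 1.2 * e_b[idx] + 1.7 * e_r[idx]
        add("N", resname, "A", resseq, "N", n_pos)
        add("CA", resname, "A", resseq, "C", ca[idx])
        add("C", resname, "A", resseq, "C", c_pos)
        add("O", resname, "A", resseq, "O", o_pos)
        if resname != "GLY":
            add("CB", resname, "A", resseq, "C", ca[idx] - 2.2 * e_r[idx])

    # ligand ring: hexagon of radius 2.1 in the (t, b) plane, offset outward
    mid = n_residues // 2
    center = ca[mid] + 5.5 * e_r[mid]
    for j in range(6):
        ang = j * np.pi / 3
        pos = center + 2.1 * (np.cos(ang) * e_t[mid] + np.sin(ang) * e_b[mid])
        add("N1" if j == 0 else f"C{j}", "BEN", "L", 401, "N" if j == 0 else "C", pos)

    # one calcium ion, outward at a quarter of the chain
    q = n_residues // 4
    add("CA", "CA", "I", 301, "CA", ca[q] + 5.5 * e_r[q])

    protein_xyz = np.array([(r[8], r[9], r[10]) for r in rows])

    # waters: rejection-sampled in a shell around random chain positions
    placed = []
    attempts = 0
    while len(placed) < n_waters:
        attempts += 1
        if attempts > 200 * n_waters:
            raise RuntimeError("could not place the requested number of waters")
        anchor = ca[rng.integers(0, n_residues)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pos = anchor + direction * rng.uniform(4.0, 9.0)
        near = np.vstack([protein_xyz] + [np.asarray(placed)] if placed else [protein_xyz])
        if np.min(np.linalg.norm(near - pos, axis=1)) >= 2.4:
            placed.append(pos)
    for w, pos in enumerate(placed, start=1):
        add("O", "HOH", "S", w, "O", pos, bval=20.0)

    atoms = pd.DataFrame(rows, columns=_ATOM_COLUMNS)
    span = atoms[["x", "y", "z"]].agg(["min", "max"])
    cell = tuple(float(span.loc["max", c] - span.loc["min", c] + 20.0) for c in "xyz") + (90.0, 90.0, 90.0)
    return StructureModel(structure_id="BASE", atoms=atoms, cell=cell,
                          spacegroup="P 1")


# ---------------------------------------------------------------------------
# ensemble generation


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0.0, max_angle_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _quantize(atoms: pd.DataFrame) -> pd.DataFrame:
    """Apply PDB fixed-column precision (coords 1e-3 A, B and occupancy
    1e-2) so in-memory models match what a written file would read back."""
    atoms = atoms.copy()
    atoms[["x", "y", "z"]] = atoms[["x", "y", "z"]].round(3)
    atoms["b"] = atoms["b"].round(2)
    atoms["occ"] = atoms["occ"].round(2)
    return atoms


def generate_ensemble(base: StructureModel, truth_config: TruthConfig,
                      temperatures: Sequence[float] = DEFAULT_TEMPERATURES,
                      n_replicates: int = 3, seed: int = 0,
                      out_dir: Optional[str | Path] = None,
                      ) -> Tuple[TemperatureSeries, SyntheticTruth]:
    """Generate the temperature series and its truth table.

    Structure ids are ``S{T}R{rep}``; the reference is the first
    replicate at the lowest temperature.  When ``out_dir`` is given the
    structures are written as PDB files (with REMARK 200 temperature and
    REMARK 3 Wilson-B headers) together with a ``manifest.tsv`` and the
    truth table; the in-memory models are quantized to PDB precision
    either way, so results do not depend on whether files were written.
    """
    cfg = truth_config
    cfg.validate()
    temperatures = sorted(float(t) for t in temperatures)
    if len(set(temperatures)) < 3:
        raise ValueError("need >= 3 distinct temperatures")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    t_min, t_max = temperatures[0], temperatures[-1]
    rng = np.random.default_rng(seed)

    prot_mask = base.atoms["atom_class"].isin(("calpha", "backbone", "side_chain"))
    prot_res = sorted(base.atoms.loc[prot_mask, "resseq"].unique())
    n_res = len(prot_res)

    # --- truth draws (order fixed: residues, waters, transforms)
    b0 = cfg.b0_median * np.exp(rng.normal(0.0, cfg.b0_sigma_log, n_res))
    if cfg.k_mode == "fixed":
        k = np.full(n_res, cfg.k_fixed)
    else:
        k = rng.uniform(*cfg.k_range, n_res)
    if cfg.delta_mode == "independent":
        delta = np.abs(rng.normal(0.0, cfg.delta_sd, n_res))
    else:
        delta = cfg.planted_slope * np.maximum(np.log10(b0), 0.01)
    dirs = rng.normal(size=(n_res, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    resnames = (base.atoms.loc[prot_mask, ["resseq", "resname"]]
                .drop_duplicates().set_index("resseq")["resname"])
    residues = pd.DataFrame({
        "resseq": prot_res,
        "resname": [resnames[r] for r in prot_res],
        "b0": b0, "b0_side": b0 * cfg.sc_b0_factor, "k": k, "delta": delta,
        "ux": dirs[:, 0], "uy": dirs[:, 1], "uz": dirs[:, 2],
    })

    water_mask = base.atoms["atom_class"] == "water"
    water_res = base.atoms.loc[water_mask, "resseq"].to_numpy()
    water_b0 = cfg.water_b0_median * np.exp(
        rng.normal(0.0, cfg.water_b0_sigma_log, len(water_res)))
    # Each water carries a fixed order-parameter threshold u: it is present
    # in a structure at temperature T iff u <= p(T).  Marginally that is
    # Bernoulli(p(T)); across the series it makes water loss nested (the
    # same weakly-ordered waters disappear first, as in real crystals), so
    # the conserved set is the fraction surviving at the top temperature.
    water_u = rng.random(len(water_res))
    waters = pd.DataFrame({"resseq": water_res, "b0": water_b0,
                           "retention_threshold": water_u})

    transforms_rows = []
    transform_list: List[Tuple[np.ndarray, np.ndarray]] = []
    for rep in range(1, n_replicates + 1):
        if cfg.identity_transforms:
            R, tvec = np.eye(3), np.zeros(3)
        else:
            R = _random_rotation(rng, cfg.transform_max_angle_deg)
            tvec = rng.uniform(-cfg.transform_max_shift, cfg.transform_max_shift, 3)
        transform_list.append((R, tvec))
        row = {"replicate": rep}
        for i in range(3):
            for j in range(3):
                row[f"r{i + 1}{j + 1}"] = R[i, j]
        row.update(t1=tvec[0], t2=tvec[1], t3=tvec[2])
        transforms_rows.append(row)

    retention = pd.DataFrame({
        "temperature_K": temperatures,
        "p": [cfg.retention_p_start + (cfg.retention_p_end - cfg.retention_p_start)
              * (t - t_min) / max(t_max - t_min, 1e-12) for t in temperatures],
    })

    # per-atom truth lookups aligned with the base atom table
    res_idx = {r: i for i, r in enumerate(prot_res)}
    atom_b0 = np.zeros(len(base.atoms))
    atom_k = np.zeros(len(base.atoms))
    disp_vec = np.zeros((len(base.atoms), 3))
    for pos, row in enumerate(base.atoms.itertuples(index=False)):
        if row.atom_class in ("calpha", "backbone", "side_chain"):
            i = res_idx[row.resseq]
            atom_b0[pos] = b0[i] * (cfg.sc_b0_factor if row.atom_class == "side_chain" else 1.0)
            atom_k[pos] = k[i]
            disp_vec[pos] = delta[i] * dirs[i]
        elif row.atom_class == "water":
            atom_b0[pos] = water_b0[np.searchsorted(water_res, row.resseq)]
            atom_k[pos] = cfg.nonprotein_k
        elif row.atom_class == "ion":
            atom_b0[pos] = cfg.ion_b0
            atom_k[pos] = cfg.nonprotein_k
        else:
            atom_b0[pos] = cfg.ligand_b0
            atom_k[pos] = cfg.nonprotein_k

    base_xyz = base.coords()
    water_positions = np.flatnonzero(water_mask.to_numpy())
    p_by_t = dict(zip(retention["temperature_K"], retention["p"]))

    models: List[StructureModel] = []
    realized_rows = []
    for t_val in temperatures:
        for rep in range(1, n_replicates + 1):
            sid = f"S{int(t_val)}R{rep}"
            R, tvec = transform_list[rep - 1]
            xyz = base_xyz + disp_vec * (t_val - t_min)
            if cfg.coord_noise_sd > 0:
                xyz = xyz + rng.normal(0.0, cfg.coord_noise_sd, xyz.shape)
            xyz = xyz @ R.T + tvec
            bvals = atom_b0 * np.exp(atom_k * t_val)
            if cfg.b_noise_frac > 0:
                bvals = bvals * (1.0 + rng.normal(0.0, cfg.b_noise_frac, len(bvals)))
            bvals = np.maximum(bvals, 0.01)
            atoms = base.atoms.copy()
            atoms[["x", "y", "z"]] = xyz
            atoms["b"] = bvals
            p = p_by_t[t_val]
            keep = np.ones(len(atoms), dtype=bool)
            if p < 1.0:
                keep[water_positions[water_u > p]] = False
            atoms = _quantize(atoms[keep].reset_index(drop=True))
            n_wat = int((atoms["atom_class"] == "water").sum())
            wilson = round(float(atoms["b"].mean()), 2)
            models.append(StructureModel(
                structure_id=sid, atoms=atoms, temperature_K=float(t_val),
                wilson_b=wilson, replicate_id=rep, cell=base.cell,
                spacegroup=base.spacegroup))
            realized_rows.append({"structure_id": sid, "temperature_K": t_val,
                                  "replicate": rep, "n_waters": n_wat})

    truth = SyntheticTruth(
        residues=residues, waters=waters,
        nonprotein={"ion_b0": cfg.ion_b0, "ligand_b0": cfg.ligand_b0,
                    "k": cfg.nonprotein_k},
        transforms=pd.DataFrame(transforms_rows), retention=retention,
        realized=pd.DataFrame(realized_rows), config=cfg, seed=seed)

    series = TemperatureSeries(models=models, reference_id=models[0].structure_id)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        for m in models:
            p = out / f"{m.structure_id}.pdb"
            write_structure(m, p)
            paths.append(p.name)
        write_manifest(models, paths, out / "manifest.tsv")
        truth.save(out)
    return series, truth
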