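"""End-to-end analysis pipeline over a temperature-series manifest.

Stages: superposition onto the reference -> displacement profiles ->
B-factor aggregation/normalization -> global and per-residue thermal
fits -> water census and non-protein component fits -> cross-correlation
of B parameters with displacement constants -> ensemble comparison
tables.  Results are written as TSV files plus a plain-text run log.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .correlation import CorrelationResult, b_vs_plasticity, sequence_trend
from .ensemble_compare import compare_set, summary_stats
from .pdb_io import TemperatureSeries, read_series
from .superpose import align_series, displacement_profile, global_displacement
from .thermal_models import fit_linear, fit_profile_series, fits_to_tsv, global_b_fits
from .water_ligand import build_water_match_table, component_thermal_fit, water_census

__all__ = ["run_pipeline", "run_pipeline_on_series", "correlation_to_frame"]

log = logging.getLogger(__name__)

SELECTIONS = ("calpha", "side_chain")


def correlation_to_frame(results: Dict[str, CorrelationResult]) -> pd.DataFrame:
    rows = []
    for key, c in results.items():
        rows.append({"pair": key, "x": c.x_label, "y": c.y_label,
                     "x_transform": c.x_transform, "r": c.pearson_r,
                     "ci_low": c.r_ci95[0], "ci_high": c.r_ci95[1],
                     "p": c.p_two_tailed, "n": c.n})
    return pd.DataFrame(rows)


def _thermalfit_row(name, fit):
    if fit is None:
        return {"channel": name}
    return {"channel": name, "model_form": fit.model_form,
            "amplitude": fit.amplitude, "k": fit.k, "r": fit.pearson_r,
            "ci_low": fit.r_ci95[0], "ci_high": fit.r_ci95[1],
            "p": fit.p_two_tailed, "n": fit.n_points, "converged": fit.converged}


def run_pipeline_on_series(series: TemperatureSeries,
                           out_dir: Optional[str | Path] = None,
                           config: Optional[AnalysisConfig] = None,
                           ) -> Dict[str, object]:
    """Run every stage on an in-memory series; optionally write TSVs."""
    cfg = config or AnalysisConfig()
    results: Dict[str, object] = {}

    aligned = align_series(series, fit_selection=cfg.fit_selection)
    results["transforms"] = pd.DataFrame(
        [{"structure_id": m.structure_id, "temperature_K": m.temperature_K,
          "fit_rmsd": tf.rmsd, "n_fit_atoms": tf.n_fit_atoms}
         for m, tf in aligned])

    # global displacement means per structure + linear regression on T
    ref = series.reference
    disp_rows = []
    for model, _tf in aligned:
        prof = displacement_profile(model, ref)
        mean_ca, mean_sc = global_displacement(prof)
        disp_rows.append({"structure_id": model.structure_id,
                          "temperature_K": model.temperature_K,
                          "mean_d_calpha": mean_ca, "mean_d_side_chain": mean_sc})
    gd = pd.DataFrame(disp_rows)
    results["global_displacement"] = gd
    results["global_displacement_fits"] = {
        "calpha": fit_linear(gd["temperature_K"], gd["mean_d_calpha"]),
        "side_chain": fit_linear(gd["temperature_K"], gd["mean_d_side_chain"]),
    }

    # global B(T) fits: Wilson, side-chain average, Calpha average
    results["global_b_fits"] = global_b_fits(
        series, include_zero_occupancy=cfg.include_zero_occupancy)

    # per-residue fits
    fit_tables: Dict[tuple, pd.DataFrame] = {}
    for selection in SELECTIONS:
        for response, form in (("b_raw", "exponential"), ("b_norm", "exponential")):
            fit_tables[(selection, response)] = fit_profile_series(
                series, selection, response, model_form=form,
                min_coverage_fraction=cfg.min_coverage_fraction,
                tol=cfg.exp_tol, max_iter=cfg.exp_max_iter)
        dcol = "d_calpha" if selection == "calpha" else "d_side_chain"
        fit_tables[(selection, dcol)] = fit_profile_series(
            series, selection, dcol, model_form="linear",
            min_coverage_fraction=cfg.min_coverage_fraction, aligned=aligned)
    results["fit_tables"] = fit_tables

    # sequence trends of the per-residue thermal constants
    seq_trends: Dict[str, CorrelationResult] = {}
    for (selection, response), tab in fit_tables.items():
        conv = tab[tab["converged"]]
        if len(conv) >= 3 and np.ptp(conv["k"].to_numpy()) > 0:
            seq_trends[f"k_{response}_{selection}"] = sequence_trend(conv, "k")
    results["sequence_trends"] = seq_trends

    # correlation stage: B parameters vs displacement constants
    disp_fits = {s: fit_tables[(s, "d_calpha" if s == "calpha" else "d_side_chain")]
                 for s in SELECTIONS}
    b_fits = {s: fit_tables[(s, "b_raw")] for s in SELECTIONS}
    results["b_vs_plasticity"] = b_vs_plasticity(disp_fits, b_fits)

    # waters, ions, ligand
    results["water_census"] = water_census(series)
    match_table = build_water_match_table(
        series, aligned=aligned, cutoff=cfg.water_cutoff,
        conserved_fraction=cfg.conserved_fraction)
    results["water_match_table"] = match_table
    comp_fits = {}
    for component in ("all_water", "conserved_water", "ion", "ligand"):
        try:
            comp_fits[component] = component_thermal_fit(
                series, component, aligned=aligned, match_table=match_table,
                cutoff=cfg.water_cutoff, conserved_fraction=cfg.conserved_fraction)
        except ValueError as exc:
            log.warning("component %s skipped: %s", component, exc)
            comp_fits[component] = None
    results["component_fits"] = comp_fits

    # ensemble comparison of the whole set against the reference
    results["ensemble"] = compare_set(series.models, series.reference_id,
                                      fit_selection=cfg.fit_selection)

    if out_dir is not None:
        _write_results(results, series, cfg, Path(out_dir))
    return results


def _write_results(results, series, cfg, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results["transforms"].to_csv(out / "transforms.tsv", sep="\t", index=False)
    results["global_displacement"].to_csv(out / "global_displacement.tsv",
                                          sep="\t", index=False)
    glob_rows = [_thermalfit_row(f"displacement_{k}", f)
                 for k, f in results["global_displacement_fits"].items()]
    glob_rows += [_thermalfit_row(f"b_{k}", f)
                  for k, f in results["global_b_fits"].items()
                  if not isinstance(f, float)]
    gb = results["global_b_fits"]
    pd.DataFrame(glob_rows).to_csv(out / "global_fits.tsv", sep="\t", index=False)
    fits_to_tsv(results["fit_tables"], out / "per_residue_fits.tsv")
    correlation_to_frame(results["b_vs_plasticity"]).to_csv(
        out / "b_vs_plasticity.tsv", sep="\t", index=False)
    correlation_to_frame(results["sequence_trends"]).to_csv(
        out / "sequence_trends.tsv", sep="\t", index=False)
    results["water_census"].to_csv(out / "water_census.tsv", sep="\t", index=False)
    comp_rows = [_thermalfit_row(k, f) for k, f in results["component_fits"].items()]
    pd.DataFrame(comp_rows).to_csv(out / "component_fits.tsv", sep="\t", index=False)
    results["ensemble"]["summary"].to_csv(out / "ensemble_summary.tsv",
                                          sep="\t", index=False)
    results["ensemble"]["profiles"].to_csv(out / "ensemble_profiles.tsv",
                                           sep="\t", index=False)
    lines = [
        "btherm run log",
        f"n_structures = {len(series.models)}",
        f"reference = {series.reference_id}",
        f"temperatures = {sorted(set(series.temperatures().tolist()))}",
        f"mean_k (global B fits) = {gb['mean_k']:.6g}",
        f"mean_b0 (global B fits) = {gb['mean_b0']:.6g}",
        "config:",
    ]
    lines += [f"  {f.name} = {getattr(cfg, f.name)}"
              for f in dataclasses.fields(cfg)]
    (out / "run.log").write_text("\n".join(lines) + "\n")


def run_pipeline(manifest: str | Path, out_dir: str | Path,
                 config: Optional[AnalysisConfig] = None,
                 reference_id: Optional[str] = None) -> Dict[str, object]:
    """Load a manifest TSV and run the full analysis into ``out_dir``."""
    cfg = config or AnalysisConfig()
    series = read_series(manifest, reference_id=reference_id,
                         altloc_policy=cfg.altloc_policy,
                         temperature_overrides=cfg.temperature_overrides)
    return run_pipeline_on_series(series, out_dir=out_dir, config=cfg)
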