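"""Pearson correlation with Fisher-z confidence intervals, and the
cross-correlation stage relating B-factor parameters to temperature-induced
conformational change.

The central scientific question this stage answers: do residues whose
conformation responds more strongly to temperature also carry larger
zero-Kelvin B-factors (B0) or steeper B-factor thermal constants (Bk)?
Each pairing is summarised by a Pearson r with a 95% CI and a two-tailed
p-value; the B0 axis is log10-transformed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "fisher_ci",
    "pearson_p_value",
    "pearson",
    "b_vs_plasticity",
    "sequence_trend",
]

_RESIDUE_KEY = ["chain", "resseq", "icode"]


@dataclass(frozen=True)
class CorrelationResult:
    x_label: str
    y_label: str
    pearson_r: float
    r_ci95: Tuple[float, float]
    p_two_tailed: float
    n: int
    x_transform: str = "identity"


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """95% (by default) confidence interval for a correlation via the
    Fisher z-transform; requires n >= 4."""
    if n < 4:
        return (float("nan"), float("nan"))
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return (float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se)))


def pearson_p_value(r: float, n: int) -> float:
    """Two-tailed p for H0: rho = 0, from the t-distribution on n-2 df."""
    if n < 3 or abs(r) >= 1.0:
        return 0.0 if abs(r) >= 1.0 and n >= 3 else float("nan")
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * stats.t.sf(abs(t), n - 2))


def pearson(x, y, x_transform: str = "identity",
            x_label: str = "x", y_label: str = "y") -> CorrelationResult:
    """Product-moment correlation of paired samples.

    Pairs with a missing member are dropped.  ``x_transform='log10'``
    correlates against log10(x) and requires x > 0 on the retained pairs.
    Zero variance in either variable raises: the correlation is undefined.
    """
    if x_transform not in ("identity", "log10"):
        raise ValueError(f"unknown x_transform {x_transform!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x_transform == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 transform requires strictly positive x")
        x = np.log10(x)
    n = len(x)
    if n < 3:
        raise ValueError(f"correlation needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationResult(
        x_label=x_label, y_label=y_label, pearson_r=r,
        r_ci95=fisher_ci(r, n), p_two_tailed=pearson_p_value(r, n),
        n=n, x_transform=x_transform)


def b_vs_plasticity(displacement_fits: Mapping[str, pd.DataFrame],
                    b_fits: Mapping[str, pd.DataFrame],
                    ) -> Dict[str, CorrelationResult]:
    """The four B-vs-conformational-plasticity panels.

    ``displacement_fits`` and ``b_fits`` map selection ("calpha",
    "side_chain") to per-residue fit tables (as produced by
    :func:`btherm.thermal_models.fit_profile_series`): the former holds the
    linear displacement thermal constants (column ``k``), the latter the
    exponential B(T) parameters (columns ``amplitude`` = B0 and ``k`` = Bk).

    Pairings, per selection: B0 vs delta-k (B0 on a log10 axis) and
    Bk vs delta-k.  Residues missing from either table are dropped
    pairwise.  Keys: ``"b0_vs_dk_calpha"``, ``"bk_vs_dk_calpha"``,
    ``"b0_vs_dk_side_chain"``, ``"bk_vs_dk_side_chain"``.
    """
    out: Dict[str, CorrelationResult] = {}
    for selection in ("calpha", "side_chain"):
        disp = displacement_fits[selection]
        bfit = b_fits[selection]
        merged = disp.merge(bfit, on=_RESIDUE_KEY, suffixes=("_disp", "_b"))
        if len(merged) < 3:
            raise ValueError(
                f"{selection}: only {len(merged)} residues overlap between "
                "displacement and B-factor fit tables")
        dk = merged["k_disp"].to_numpy(dtype=float)
        out[f"b0_vs_dk_{selection}"] = pearson(
            merged["amplitude_b" if "amplitude_b" in merged else "amplitude"].to_numpy(dtype=float),
            dk, x_transform="log10",
            x_label=f"B0[{selection}]", y_label=f"delta_k[{selection}]")
        out[f"bk_vs_dk_{selection}"] = pearson(
            merged["k_b"].to_numpy(dtype=float), dk,
            x_label=f"Bk[{selection}]", y_label=f"delta_k[{selection}]")
    return out


def sequence_trend(per_residue_values: pd.Series | pd.DataFrame,
                   value_column: str | None = None) -> CorrelationResult:
    """Correlation of a per-residue quantity with its sequence position.

    Accepts a Series indexed by residue number, or a DataFrame with a
    ``resseq`` column and ``value_column``.
    """
    if isinstance(per_residue_values, pd.DataFrame):
        if value_column is None:
            raise ValueError("value_column required for DataFrame input")
        x = per_residue_values["resseq"].to_numpy(dtype=float)
        y = per_residue_values[value_column].to_numpy(dtype=float)
        y_label = value_column
    else:
        x = per_residue_values.index.to_numpy(dtype=float)
        y = per_residue_values.to_numpy(dtype=float)
        y_label = per_residue_values.name or "value"
    return pearson(x, y, x_label="resseq", y_label=str(y_label))
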