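"""Temperature-regression engine.

Two model forms describe how a response y (a displacement in Angstrom or
a B-factor in Angstrom^2) depends on the data-collection temperature T:

* linear:       y = a + k * T          (ordinary least squares)
* exponential:  y = A * exp(k * T)     (nonlinear least squares on the
                                        untransformed residuals)

For the exponential form, A is the amplitude extrapolated to zero Kelvin
(B0 when y is a B-factor) and k the thermal constant in 1/K.  The
nonlinear fit is seeded by OLS on (T, ln y) and refined by a damped
Gauss-Newton (Levenberg-Marquardt) iteration; points with y <= 0 are
dropped from the seed only, never from the objective.

Per-residue fits across a temperature series are solved in a single
vectorised pass (one Levenberg-Marquardt state per residue), which keeps
ensembles with hundreds of residues and dozens of structures cheap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bfactor_stats import aggregate_b, normalize_b
from .correlation import fisher_ci, pearson_p_value
from .pdb_io import StructureModel, TemperatureSeries
from .superpose import RigidTransform, align_series, displacement_profile

__all__ = [
    "ThermalFit",
    "fit_linear",
    "fit_exponential",
    "exp_fit_batch",
    "collect_response",
    "fit_profile_series",
    "global_b_fits",
    "fits_to_tsv",
]

log = logging.getLogger(__name__)

_RESIDUE_KEY = ["chain", "resseq", "icode"]
RESPONSES = ("b_raw", "b_norm", "d_calpha", "d_side_chain")


@dataclass(frozen=True)
class ThermalFit:
    """Result of one temperature regression."""

    model_form: str                      # "linear" or "exponential"
    amplitude: float                     # intercept (linear) or zero-Kelvin value
    k: float                             # thermal constant
    pearson_r: float
    r_ci95: Tuple[float, float]
    p_two_tailed: float
    n_points: int
    converged: bool

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        if self.model_form == "linear":
            return self.amplitude + self.k * t
        return self.amplitude * np.exp(self.k * t)


def _r_stats(x: np.ndarray, y: np.ndarray) -> Tuple[float, Tuple[float, float], float]:
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, (float("nan"), float("nan")), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, fisher_ci(r, n), pearson_p_value(r, n)


# ---------------------------------------------------------------------------
# scalar fits


def fit_linear(t: Sequence[float], y: Sequence[float]) -> ThermalFit:
    """Ordinary least squares of y on T.

    The Pearson r is that of (T, y); its CI comes from the Fisher
    z-transform and the two-tailed p from the t-distribution on n-2 df.
    A constant response is degenerate: slope 0, r reported as 0,
    ``converged`` False.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D of equal length")
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(t) < 2:
        raise ValueError("linear fit needs >= 2 points")
    if np.ptp(t) == 0:
        raise ValueError("singular design: all temperatures identical")
    tc = t - t.mean()
    slope = float((tc @ (y - y.mean())) / (tc @ tc))
    intercept = float(y.mean() - slope * t.mean())
    degenerate = np.ptp(y) == 0
    r, ci, p = _r_stats(t, y)
    return ThermalFit(model_form="linear", amplitude=intercept, k=slope,
                      pearson_r=r, r_ci95=ci, p_two_tailed=p,
                      n_points=len(t), converged=not degenerate)


def fit_exponential(t: Sequence[float], y: Sequence[float],
                    tol: float = 1e-10, max_iter: int = 200) -> ThermalFit:
    """Nonlinear least squares of y = A * exp(k*T).

    The reported Pearson r is between observed and model-predicted
    values (with CI and p as for the linear fit).  When no admissible
    log-seed exists (fewer than 2 points with y > 0) the fit is flagged
    not converged with NaN parameters.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("t and y must be 1-D of equal length")
    keep = np.isfinite(t) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if len(t) < 3 or len(set(t.tolist())) < 3:
        raise ValueError("exponential fit needs >= 3 points at >= 3 distinct temperatures")
    A, k, _, conv, nval = exp_fit_batch(t, y[None, :], tol=tol, max_iter=max_iter)
    A, k, conv = float(A[0]), float(k[0]), bool(conv[0])
    if not np.isfinite(A):
        return ThermalFit("exponential", float("nan"), float("nan"), 0.0,
                          (float("nan"),) * 2, float("nan"), len(t), False)
    pred = A * np.exp(k * t)
    r, ci, p = _r_stats(y, pred)
    return ThermalFit(model_form="exponential", amplitude=A, k=k,
                      pearson_r=r, r_ci95=ci, p_two_tailed=p,
                      n_points=int(nval[0]), converged=conv and A > 0)


# ---------------------------------------------------------------------------
# batched Levenberg-Marquardt core


def exp_fit_batch(t: np.ndarray, Y: np.ndarray, mask: Optional[np.ndarray] = None,
                  tol: float = 1e-10, max_iter: int = 200,
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``Y[i, j] ~ A[i] * exp(k[i] * t[j])`` for every row i at once.

    ``mask`` marks valid observations (missing residues in some
    structures); NaNs in Y are treated as missing as well.  Returns
    ``(A, k, loss, converged, n_valid)``.  Rows without an admissible
    seed (fewer than 2 positive observations at 2 distinct temperatures)
    come back NaN with ``converged`` False.

    The update is a damped Gauss-Newton step on the 2x2 normal equations,
    solved in closed form per row; the damping factor adapts per row
    (divide by 3 on an accepted step, multiply by 10 on a rejected one).
    Convergence: relative loss change below ``tol``.
    """
    t = np.asarray(t, dtype=float)
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    if t.shape != (n,):
        raise ValueError("t must match the second axis of Y")
    valid = np.isfinite(Y)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    W = valid.astype(float)
    Yw = np.where(valid, Y, 0.0)
    n_valid = valid.sum(axis=1)

    # --- log-linear seed on the positive observations
    pos = valid & (Y > 0)
    Wp = pos.astype(float)
    npos = Wp.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(pos, np.log(np.where(pos, Y, 1.0)), 0.0)
        st_ = Wp @ t
        stt = Wp @ (t * t)
        sl = L.sum(axis=1)
        slt = (L * t[None, :]).sum(axis=1)
        denom = npos * stt - st_ ** 2
        k = np.where(denom > 0, (npos * slt - st_ * sl) / np.where(denom > 0, denom, 1.0), 0.0)
        logA = np.where(npos > 0, (sl - k * st_) / np.where(npos > 0, npos, 1.0), np.nan)
    seedable = (npos >= 2) & (denom > 1e-12)
    A = np.where(seedable, np.exp(np.clip(logA, -300, 300)), np.nan)
    k = np.where(seedable, k, np.nan)

    def model(Av, kv):
        return Av[:, None] * np.exp(np.clip(kv[:, None] * t[None, :], -600, 600))

    def loss_of(Av, kv):
        r = np.where(valid, Yw - model(Av, kv), 0.0)
        return (r * r).sum(axis=1)

    loss = np.where(seedable, loss_of(np.where(seedable, A, 1.0),
                                      np.where(seedable, k, 0.0)), np.nan)
    lam = np.full(m, 1e-3)
    active = seedable & (n_valid >= 3)
    converged = np.zeros(m, dtype=bool)

    for _ in range(max_iter):
        if not active.any():
            break
        E = np.exp(np.clip(k[:, None] * t[None, :], -600, 600))
        F = A[:, None] * E
        R = np.where(valid, Yw - F, 0.0)
        J1 = np.where(valid, E, 0.0)                     # d f / d A
        J2 = np.where(valid, F * t[None, :], 0.0)        # d f / d k
        a11 = (J1 * J1).sum(axis=1)
        a12 = (J1 * J2).sum(axis=1)
        a22 = (J2 * J2).sum(axis=1)
        g1 = (J1 * R).sum(axis=1)
        g2 = (J2 * R).sum(axis=1)
        d11 = a11 * (1 + lam)
        d22 = a22 * (1 + lam)
        det = d11 * d22 - a12 * a12
        ok = np.abs(det) > 1e-300
        dA = np.where(ok, (d22 * g1 - a12 * g2) / np.where(ok, det, 1.0), 0.0)
        dk = np.where(ok, (d11 * g2 - a12 * g1) / np.where(ok, det, 1.0), 0.0)
        A_new = A + np.where(active, dA, 0.0)
        k_new = k + np.where(active, dk, 0.0)
        loss_new = loss_of(np.nan_to_num(A_new), np.nan_to_num(k_new))
        accept = active & (loss_new <= loss)
        improved = accept & (loss - loss_new <= tol * np.maximum(loss, 1e-300))
        A = np.where(accept, A_new, A)
        k = np.where(accept, k_new, k)
        lam = np.where(accept, np.maximum(lam / 3.0, 1e-12),
                       np.where(active, np.minimum(lam * 10.0, 1e12), lam))
        loss = np.where(accept, loss_new, loss)
        converged |= improved
        active &= ~improved
        # rows stuck at maximal damping cannot move: stop them, unconverged
        active &= ~(lam >= 1e12)

    return A, k, loss, converged, n_valid


# ---------------------------------------------------------------------------
# per-residue fits across a series


def collect_response(series: TemperatureSeries, selection: str, response: str,
                     aligned: Optional[List[Tuple[StructureModel, RigidTransform]]] = None,
                     fit_selection: str = "calpha",
                     include_zero_occupancy: bool = False) -> pd.DataFrame:
    """Long table of one response observed per residue per structure.

    Columns: chain, resseq, icode, resname, structure_id, temperature_K,
    value.  B-factor responses (``b_raw``, ``b_norm``) come from
    :mod:`btherm.bfactor_stats` on the stated selection; displacement
    responses (``d_calpha``, ``d_side_chain``) require superposition onto
    the series reference (``aligned`` may carry a precomputed alignment).
    """
    if response not in RESPONSES:
        raise ValueError(f"unknown response {response!r}")
    rows = []
    if response in ("b_raw", "b_norm"):
        for model in series.models:
            prof = aggregate_b(model, selection,
                               include_zero_occupancy=include_zero_occupancy)
            if response == "b_norm":
                prof = normalize_b(prof)
            d = prof.data[_RESIDUE_KEY + ["resname", response]].rename(columns={response: "value"})
            d["structure_id"] = model.structure_id
            d["temperature_K"] = model.temperature_K
            rows.append(d)
    else:
        if aligned is None:
            aligned = align_series(series, fit_selection=fit_selection)
        ref = series.reference
        for model, _tf in aligned:
            prof = displacement_profile(model, ref)
            d = prof[_RESIDUE_KEY + ["resname", response]].rename(columns={response: "value"})
            d = d.dropna(subset=["value"])
            d["structure_id"] = model.structure_id
            d["temperature_K"] = model.temperature_K
            rows.append(d)
    return pd.concat(rows, ignore_index=True)


def fit_profile_series(series: TemperatureSeries, selection: str, response: str,
                       model_form: str = "exponential",
                       min_coverage_fraction: float = 2.0 / 3.0,
                       aligned: Optional[List[Tuple[StructureModel, RigidTransform]]] = None,
                       tol: float = 1e-10, max_iter: int = 200,
                       long_table: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """One thermal fit per residue across the series.

    Replicates enter as separate fit points.  Residues present in fewer
    than ``min_coverage_fraction`` of the structures are omitted (and
    logged).  Returns a frame with columns chain, resseq, icode, resname,
    amplitude, k, r, ci_low, ci_high, p, n, converged.
    """
    if model_form not in ("linear", "exponential"):
        raise ValueError(f"unknown model_form {model_form!r}")
    if not series.models:
        raise ValueError("empty series")
    series.require_distinct_temperatures(2 if model_form == "linear" else 3)
    tab = long_table if long_table is not None else collect_response(
        series, selection, response, aligned=aligned)
    order = [m.structure_id for m in series.models]
    t_by_id = {m.structure_id: m.temperature_K for m in series.models}
    wide = tab.pivot_table(index=_RESIDUE_KEY + ["resname"], columns="structure_id",
                           values="value", aggfunc="first")
    wide = wide.reindex(columns=order)
    t = np.array([t_by_id[c] for c in wide.columns], dtype=float)
    Y = wide.to_numpy(dtype=float)
    valid = np.isfinite(Y)
    threshold = int(np.ceil(min_coverage_fraction * len(order)))
    covered = valid.sum(axis=1) >= threshold
    if (~covered).any():
        log.info("%s/%s: omitting %d residues below coverage threshold %d",
                 selection, response, int((~covered).sum()), threshold)
    wide = wide[covered]
    Y = Y[covered]
    valid = valid[covered]
    mres = len(wide)
    if mres == 0:
        raise ValueError("no residues meet the coverage threshold")

    if model_form == "linear":
        W = valid.astype(float)
        nv = W.sum(axis=1)
        Yw = np.where(valid, Y, 0.0)
        st_ = W @ t
        stt = W @ (t * t)
        sy = Yw.sum(axis=1)
        syt = (Yw * t[None, :]).sum(axis=1)
        denom = nv * stt - st_ ** 2
        k = (nv * syt - st_ * sy) / denom
        amp = (sy - k * st_) / nv
        pred = amp[:, None] + k[:, None] * t[None, :]
        conv = np.ptp(np.where(valid, Y, np.nan), axis=1) > 0
        robs = _masked_pearson(np.broadcast_to(t, Y.shape), Y, valid)
    else:
        amp, k, _, conv, nv = exp_fit_batch(t, Y, tol=tol, max_iter=max_iter)
        conv = conv & (amp > 0)
        pred = amp[:, None] * np.exp(np.clip(k[:, None] * t[None, :], -600, 600))
        robs = _masked_pearson(Y, pred, valid)

    nv = valid.sum(axis=1)
    ci_lo, ci_hi = _fisher_ci_vec(robs, nv)
    p = _pearson_p_vec(robs, nv)
    out = wide.index.to_frame(index=False)
    out["amplitude"] = amp
    out["k"] = k
    out["r"] = robs
    out["ci_low"] = ci_lo
    out["ci_high"] = ci_hi
    out["p"] = p
    out["n"] = nv
    out["converged"] = conv
    return out.reset_index(drop=True)


def _masked_pearson(X: np.ndarray, Y: np.ndarray, valid: np.ndarray) -> np.ndarray:
    W = valid.astype(float)
    nv = W.sum(axis=1)
    Xw = np.where(valid, X, 0.0)
    Yw = np.where(valid, Y, 0.0)
    mx = Xw.sum(axis=1) / nv
    my = Yw.sum(axis=1) / nv
    dx = np.where(valid, X - mx[:, None], 0.0)
    dy = np.where(valid, Y - my[:, None], 0.0)
    cov = (dx * dy).sum(axis=1)
    vx = (dx * dx).sum(axis=1)
    vy = (dy * dy).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    return np.where((vx > 0) & (vy > 0), r, 0.0)


def _fisher_ci_vec(r: np.ndarray, n: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
        se = 1.0 / np.sqrt(np.maximum(n - 3, 0))
    zc = stats.norm.ppf(0.975)
    lo = np.tanh(z - zc * se)
    hi = np.tanh(z + zc * se)
    bad = n < 4
    lo = np.where(bad, np.nan, lo)
    hi = np.where(bad, np.nan, hi)
    return lo, hi


def _pearson_p_vec(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt(np.maximum(n - 2, 0) / np.maximum(1 - r * r, 1e-300))
        p = 2 * stats.t.sf(np.abs(tstat), np.maximum(n - 2, 1))
    return np.where(n >= 3, p, np.nan)


# ---------------------------------------------------------------------------
# global (whole-structure) fits


def global_b_fits(series: TemperatureSeries,
                  include_zero_occupancy: bool = False) -> Dict[str, object]:
    """Exponential B(T) fits of the three whole-structure channels.

    Channels: the header Wilson B, the side-chain average B and the
    Calpha average B, each regressed on temperature across the series.
    Also reports the mean thermal constant and mean zero-Kelvin amplitude
    over the available channels.  A missing Wilson B skips that channel
    with a warning.
    """
    series.require_distinct_temperatures(3)
    t = series.temperatures()
    fits: Dict[str, object] = {}

    wilson = np.array([np.nan if m.wilson_b is None else m.wilson_b
                       for m in series.models], dtype=float)
    if np.isfinite(wilson).sum() >= 3:
        keep = np.isfinite(wilson)
        fits["wilson"] = fit_exponential(t[keep], wilson[keep])
    else:
        warnings.warn("Wilson B absent from the series headers; skipping that channel")
        fits["wilson"] = None

    for channel, selection in (("side_chain", "side_chain"), ("calpha", "calpha")):
        y = np.array([aggregate_b(m, selection, level="per_structure",
                                  include_zero_occupancy=include_zero_occupancy)
                      for m in series.models], dtype=float)
        fits[channel] = fit_exponential(t, y)

    present = [f for f in fits.values() if f is not None]
    fits["mean_k"] = float(np.mean([f.k for f in present]))
    fits["mean_b0"] = float(np.mean([f.amplitude for f in present]))
    return fits


def fits_to_tsv(fit_tables: Dict[Tuple[str, str], pd.DataFrame], path) -> None:
    """Export per-residue fit tables as one TSV: a row per
    (selection, response, residue)."""
    parts = []
    for (selection, response), df in fit_tables.items():
        d = df.copy()
        d.insert(0, "selection", selection)
        d.insert(1, "response", response)
        parts.append(d)
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False)
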