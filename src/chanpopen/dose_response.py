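"""Whole-cell concentration–response analysis.

Workflow for per-cell agonist dose–response data recorded with interleaved
saturating-glycine (10 mM) standards:

1. quality control — a cell is accepted only when the change between its
   first and last standard (run-down or run-up) is below 30%;
2. normalization — every response is divided by the temporally nearest
   standards, linearly interpolated across the application sequence;
3. Hill fitting per cell,

       y = y_max · [A]^nH / ([A]^nH + EC50^nH)

   by unweighted nonlinear least squares;
4. pooling — each cell's responses are rescaled by that cell's fitted
   y_max, pooled across cells and refitted for display;
5. relative efficacy — an agonist's fitted maximum on the normalized scale
   is its I_rel, the maximal response relative to glycine in the same cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "HillFit",
    "RundownResult",
    "CellFit",
    "hill_curve",
    "rundown_check",
    "normalize_to_standard",
    "fit_hill",
    "pool_and_refit",
    "relative_efficacy",
    "analyze_crc",
]

RUNDOWN_LIMIT_DEFAULT = 0.30
NH_BOUNDS = (0.2, 10.0)


def hill_curve(conc, y_max: float, ec50: float, n_h: float):
    """Hill equation y_max·[A]^nH/([A]^nH + EC50^nH)."""
    conc = np.asarray(conc, dtype=float)
    cn = np.power(conc, n_h)
    return y_max * cn / (cn + ec50**n_h)


@dataclass
class HillFit:
    """Hill-equation fit result with asymptotic parameter SDs.

    ``flags`` lists anomalies (non-convergence, boundary-pinned parameters,
    undefined covariance); an empty list means a clean fit.
    """

    y_max: float
    ec50: float
    n_h: float
    sd_y_max: float = np.nan
    sd_ec50: float = np.nan
    sd_n_h: float = np.nan
    flags: list[str] = field(default_factory=list)

    @property
    def converged(self) -> bool:
        return "no_convergence" not in self.flags

    def predict(self, conc):
        return hill_curve(conc, self.y_max, self.ec50, self.n_h)


@dataclass(frozen=True)
class RundownResult:
    passed: bool
    drift: float
    first_standard: float
    last_standard: float


def _standards(cell: pd.DataFrame) -> pd.DataFrame:
    std = cell[cell["is_standard"].astype(bool)].sort_values("order")
    if len(std) < 2:
        raise ValueError(
            f"cell {cell['cell_id'].iloc[0] if len(cell) else '?'} needs at least "
            "two standard applications (first and last)"
        )
    return std


def rundown_check(cell: pd.DataFrame, limit: float = RUNDOWN_LIMIT_DEFAULT) -> RundownResult:
    """Accept a cell when |last standard − first standard|/first < ``limit``."""
    std = _standards(cell)
    first = float(std["peak_current_nA"].iloc[0])
    last = float(std["peak_current_nA"].iloc[-1])
    if first <= 0:
        raise ValueError("first standard response must be positive")
    drift = abs(last - first) / first
    return RundownResult(passed=drift < limit, drift=drift,
                         first_standard=first, last_standard=last)


def normalize_to_standard(cell: pd.DataFrame) -> pd.DataFrame:
    """Divide each response by the interpolated 10 mM glycine standard.

    The standard current is interpolated linearly in application order
    between the bracketing standards, so slow run-down is divided out;
    standards themselves map to 1.0.  Returns a copy with a ``normalized``
    column.
    """
    std = _standards(cell)
    out = cell.sort_values("order").copy()
    ref = np.interp(
        out["order"].to_numpy(float),
        std["order"].to_numpy(float),
        std["peak_current_nA"].to_numpy(float),
    )
    if np.any(ref <= 0):
        raise ValueError("non-positive interpolated standard response")
    out["normalized"] = out["peak_current_nA"].to_numpy(float) / ref
    out.loc[out["is_standard"].astype(bool), "normalized"] = 1.0
    return out


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float]:
    """y_max = max response; EC50 = log-interpolated half-max conc; nH = 1.5."""
    y0 = float(resp.max())
    half = y0 / 2.0
    order = np.argsort(conc)
    c, r = conc[order], resp[order]
    idx = np.nonzero(r >= half)[0]
    if idx.size == 0 or idx[0] == 0:
        ec0 = float(np.sqrt(c[0] * c[-1]))
    else:
        i = idx[0]
        lo, hi = r[i - 1], r[i]
        t = (half - lo) / (hi - lo) if hi > lo else 0.5
        ec0 = float(10 ** (np.log10(c[i - 1]) + t * (np.log10(c[i]) - np.log10(c[i - 1]))))
    return y0, ec0, 1.5


def fit_hill(concs, responses) -> HillFit:
    """Unweighted nonlinear least-squares fit of the Hill equation.

    Requires at least three distinct concentrations.  Bounds keep the fit in
    a physically sensible region (nH in [0.2, 10], EC50 within two decades
    of the tested range); a parameter within 0.1% of a bound is flagged
    ``boundary`` rather than silently accepted.
    """
    conc = np.asarray(concs, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if conc.shape != resp.shape:
        raise ValueError("concentration and response arrays differ in length")
    if np.unique(conc).size < 3:
        raise ValueError("need at least three distinct concentrations")
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")

    p0 = _initial_guess(conc, resp)
    lower = [1e-12, conc.min() / 100.0, NH_BOUNDS[0]]
    upper = [np.inf, conc.max() * 100.0, NH_BOUNDS[1]]
    p0 = tuple(np.clip(p0, lower, upper))
    flags: list[str] = []
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                hill_curve, conc, resp, p0=p0, bounds=(lower, upper), maxfev=20000
            )
    except RuntimeError:
        flags.append("no_convergence")
        popt = np.asarray(p0, float)
        pcov = np.full((3, 3), np.nan)

    sds = np.sqrt(np.diag(pcov))
    if not np.all(np.isfinite(sds)):
        flags.append("covariance_undefined")
    for name, value, lo, hi in zip(
        ("ec50", "n_h"), popt[1:], lower[1:], upper[1:]
    ):
        if value <= lo * 1.001 or value >= hi * 0.999:
            flags.append(f"boundary:{name}")
    return HillFit(
        y_max=float(popt[0]), ec50=float(popt[1]), n_h=float(popt[2]),
        sd_y_max=float(sds[0]), sd_ec50=float(sds[1]), sd_n_h=float(sds[2]),
        flags=flags,
    )


@dataclass
class CellFit:
    """One cell's normalized responses for one agonist with its Hill fit."""

    cell_id: str
    concentrations: np.ndarray
    responses: np.ndarray  # normalized to the glycine standard
    fit: HillFit


def pool_and_refit(cells: list[CellFit]) -> tuple[HillFit, pd.DataFrame]:
    """Rescale by per-cell fitted maxima, pool and refit for display.

    Each cell's responses are divided by that cell's fitted y_max, removing
    cell-to-cell scale differences; the pooled points are refitted, and a
    per-concentration mean ± SE table is returned alongside.
    """
    if len(cells) < 1:
        raise ValueError("no fitted cells to pool")
    concs, resps = [], []
    for cf in cells:
        if cf.fit.y_max <= 0:
            raise ValueError(f"cell {cf.cell_id}: non-positive fitted maximum")
        concs.append(np.asarray(cf.concentrations, float))
        resps.append(np.asarray(cf.responses, float) / cf.fit.y_max)
    conc = np.concatenate(concs)
    resp = np.concatenate(resps)
    pooled = fit_hill(conc, resp)
    display = (
        pd.DataFrame({"concentration_uM": conc, "response": resp})
        .groupby("concentration_uM")["response"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    display["se"] = display["sd"] / np.sqrt(display["n"])
    return pooled, display


def relative_efficacy(cell: pd.DataFrame, agonist: str) -> float:
    """I_rel: the agonist's fitted maximum relative to the glycine standard.

    The cell's responses are first normalized to the interleaved 10 mM
    glycine standards, so the fitted y_max of the agonist's curve on that
    scale is directly I_ago/I_gly.
    """
    normalized = normalize_to_standard(cell)
    rows = normalized[
        (normalized["agonist"] == agonist) & (~normalized["is_standard"].astype(bool))
    ]
    if rows.empty:
        raise ValueError(f"cell has no test applications of {agonist!r}")
    fit = fit_hill(rows["concentration_uM"], rows["normalized"])
    return fit.y_max


def analyze_crc(
    dataset: pd.DataFrame, rundown_limit: float = RUNDOWN_LIMIT_DEFAULT
) -> dict:
    """Full dose–response analysis of a multi-cell dataset.

    Runs the run-down screen, normalizes accepted cells, fits the Hill
    equation per cell and agonist, and pools across cells.  Returns a dict
    with per-agonist summaries (I_rel, EC50, nH as mean ± SD over cells,
    pooled refit) plus the glycine maximal current and QC record.
    """
    qc: dict[str, RundownResult] = {}
    accepted: list[str] = []
    for cell_id, cell in dataset.groupby("cell_id"):
        result = rundown_check(cell, rundown_limit)
        qc[str(cell_id)] = result
        if result.passed:
            accepted.append(str(cell_id))
    if not accepted:
        raise ValueError("all cells failed the run-down screen")

    agonists = sorted(
        set(dataset.loc[~dataset["is_standard"].astype(bool), "agonist"])
    )
    per_agonist: dict[str, dict] = {}
    i_max_gly = [
        float(_standards(dataset[dataset["cell_id"] == c])["peak_current_nA"].iloc[0])
        for c in accepted
    ]
    for agonist in agonists:
        cell_fits: list[CellFit] = []
        for cell_id in accepted:
            cell = normalize_to_standard(dataset[dataset["cell_id"] == cell_id])
            rows = cell[(cell["agonist"] == agonist) & (~cell["is_standard"].astype(bool))]
            if rows["concentration_uM"].nunique() < 3:
                continue
            fit = fit_hill(rows["concentration_uM"], rows["normalized"])
            cell_fits.append(
                CellFit(
                    cell_id=str(cell_id),
                    concentrations=rows["concentration_uM"].to_numpy(float),
                    responses=rows["normalized"].to_numpy(float),
                    fit=fit,
                )
            )
        if not cell_fits:
            continue
        pooled, display = pool_and_refit(cell_fits)
        ec50s = np.array([cf.fit.ec50 for cf in cell_fits])
        nhs = np.array([cf.fit.n_h for cf in cell_fits])
        irels = np.array([cf.fit.y_max for cf in cell_fits])
        per_agonist[agonist] = {
            "n_cells": len(cell_fits),
            "i_rel_mean": float(irels.mean()),
            "i_rel_sd": float(irels.std(ddof=1)) if len(irels) > 1 else 0.0,
            "ec50_mean": float(ec50s.mean()),
            "ec50_sd": float(ec50s.std(ddof=1)) if len(ec50s) > 1 else 0.0,
            "n_h_mean": float(nhs.mean()),
            "n_h_sd": float(nhs.std(ddof=1)) if len(nhs) > 1 else 0.0,
            "pooled_fit": pooled,
            "display": display,
            "cell_fits": cell_fits,
        }
    return {
        "qc": qc,
        "accepted_cells": accepted,
        "i_max_glycine_nA": float(np.mean(i_max_gly)),
        "agonists": per_agonist,
    }
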