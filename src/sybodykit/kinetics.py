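"""1:1 biolayer-interferometry kinetics: closed-form model and global fit.

The reversible bimolecular model d[AB]/dt = kon*[A]*[B] - koff*[AB] with
[AB](0) = 0 and constant analyte concentration C has the closed forms

    association:   R(t) = Req * (1 - exp(-kobs * t)),
                   kobs = kon*C + koff,  Req = Rmax * C / (C + koff/kon)
    dissociation:  R(t) = R0 * exp(-koff * (t - t0))

in response units proportional to [AB].  ``global_fit`` shares a single
(kon, koff, Rmax) across all concentrations and both phases, minimizing the
summed squared residuals; an optional constant baseline per phase is the
only nuisance parameter (mass transport, drift and reference subtraction
are not modeled).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

ASSOCIATION = "association"
DISSOCIATION = "dissociation"

#: Default parameter bounds (configurable): kon in M^-1 s^-1, koff in s^-1.
KON_BOUNDS = (1e2, 1e9)
KOFF_BOUNDS = (1e-6, 1.0)


class KineticsError(ValueError):
    pass


class FitError(KineticsError):
    """Non-convergence; carries the best iterate for diagnostics."""

    def __init__(self, message: str, best: "KineticsFit | None" = None):
        super().__init__(message)
        self.best = best


def model_response(kon: float, koff: float, rmax: float, concentration: float,
                   times: Sequence[float], phase: str = ASSOCIATION,
                   r0: float | None = None, t0: float = 0.0) -> np.ndarray:
    """Closed-form 1:1 response at the given times (seconds).

    For the association phase, times are measured from injection (R=0 at
    t=t0).  For dissociation, ``r0`` is the response at the phase start
    ``t0`` and decays at rate koff.
    """
    if kon <= 0:
        raise KineticsError(f"kon must be > 0, got {kon}")
    if koff < 0:
        raise KineticsError(f"koff must be >= 0, got {koff}")
    if rmax <= 0:
        raise KineticsError(f"rmax must be > 0, got {rmax}")
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise KineticsError("negative times")
    if phase == ASSOCIATION:
        if concentration <= 0:
            raise KineticsError("concentration must be > 0")
        kobs = kon * concentration + koff
        req = rmax * kon * concentration / kobs
        return req * (1.0 - np.exp(-kobs * (t - t0)))
    if phase == DISSOCIATION:
        if r0 is None:
            raise KineticsError("dissociation needs the phase-start response r0")
        return r0 * np.exp(-koff * (t - t0))
    raise KineticsError(f"unknown phase {phase!r}")


def kd(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff / kon (molar)."""
    if kon <= 0:
        raise KineticsError(f"kon must be > 0, got {kon}")
    if koff < 0:
        raise KineticsError(f"koff must be >= 0, got {koff}")
    return koff / kon


@dataclass(frozen=True)
class KineticsFit:
    kon: float                    # M^-1 s^-1
    koff: float                   # s^-1
    rmax: float                   # response units
    rss: float
    n_points: int
    baselines: dict[str, float] = field(default_factory=dict)
    stderr: dict[str, float] = field(default_factory=dict)   # 1-sigma, log10 for rates
    warnings: tuple[str, ...] = ()

    @property
    def kd(self) -> float:
        return kd(self.kon, self.koff)

    def to_dict(self) -> dict:
        return {
            "kon_per_M_per_s": self.kon,
            "koff_per_s": self.koff,
            "KD_M": self.kd,
            "rmax": self.rmax,
            "rss": self.rss,
            "n_points": self.n_points,
            "baselines": dict(self.baselines),
            "stderr": dict(self.stderr),
            "warnings": list(self.warnings),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _split_curves(data: pd.DataFrame) -> list[dict]:
    """Per-concentration phase arrays with phase-start bookkeeping."""
    required = {"concentration", "phase", "time", "response"}
    missing = required - set(data.columns)
    if missing:
        raise KineticsError(f"sensorgram table missing columns: {sorted(missing)}")
    curves = []
    for conc, grp in data.groupby("concentration"):
        if conc <= 0:
            raise KineticsError(f"concentration must be > 0, got {conc}")
        assoc = grp[grp["phase"] == ASSOCIATION].sort_values("time")
        dissoc = grp[grp["phase"] == DISSOCIATION].sort_values("time")
        if assoc.empty:
            raise KineticsError(f"concentration {conc}: no association phase")
        t_a = assoc["time"].to_numpy(float)
        curves.append({
            "conc": float(conc),
            "t_assoc": t_a - t_a[0],
            "y_assoc": assoc["response"].to_numpy(float),
            "t_assoc_end": t_a[-1] - t_a[0],
            "t_dissoc": (dissoc["time"].to_numpy(float) - t_a[0]
                         if not dissoc.empty else np.empty(0)),
            "y_dissoc": dissoc["response"].to_numpy(float),
        })
    return curves


def _initial_guess(curves: list[dict]) -> tuple[float, float, float]:
    """kobs-vs-C regression seeds (kon, koff); Rmax from the top plateau."""
    kobs_est, concs, plateaus = [], [], []
    for c in curves:
        y, t = c["y_assoc"], c["t_assoc"]
        plateau = float(np.mean(y[int(0.9 * len(y)):])) if len(y) > 3 else float(y[-1])
        plateaus.append(plateau)
        concs.append(c["conc"])
        if plateau > 0:
            target = plateau * (1.0 - math.exp(-1.0))
            above = np.nonzero(y >= target)[0]
            if above.size and t[above[0]] > 0:
                kobs_est.append(1.0 / t[above[0]])
                continue
        kobs_est.append(np.nan)
    kobs = np.asarray(kobs_est)
    concs_a = np.asarray(concs)
    ok = np.isfinite(kobs)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(concs_a[ok], kobs[ok], 1)
    else:
        slope, intercept = np.nan, np.nan
    kon0 = slope if np.isfinite(slope) and slope > 0 else 1e5
    koff0 = intercept if np.isfinite(intercept) and intercept > 0 else 1e-3
    kon0 = float(np.clip(kon0, *KON_BOUNDS))
    koff0 = float(np.clip(koff0, *KOFF_BOUNDS))
    kd0 = koff0 / kon0
    top = int(np.argmax(concs_a))
    rmax0 = plateaus[top] * (concs_a[top] + kd0) / concs_a[top]
    if not (rmax0 > 0):
        rmax0 = max(float(np.max(np.concatenate([c["y_assoc"] for c in curves]))),
                    1e-3)
    return kon0, koff0, float(rmax0)


def _predict(curves: list[dict], kon: float, koff: float, rmax: float,
             b_assoc: float, b_dissoc: float) -> np.ndarray:
    parts = []
    for c in curves:
        kobs = kon * c["conc"] + koff
        req = rmax * kon * c["conc"] / kobs
        y_a = req * (1.0 - np.exp(-kobs * c["t_assoc"]))
        parts.append(y_a + b_assoc)
        if c["t_dissoc"].size:
            r0 = req * (1.0 - math.exp(-kobs * c["t_assoc_end"]))
            parts.append(r0 * np.exp(-koff * (c["t_dissoc"] - c["t_assoc_end"]))
                         + b_dissoc)
    return np.concatenate(parts)


def global_fit(data: pd.DataFrame, fit_baselines: bool = False,
               kon_bounds: tuple[float, float] = KON_BOUNDS,
               koff_bounds: tuple[float, float] = KOFF_BOUNDS) -> KineticsFit:
    """Global 1:1 fit: one (kon, koff, Rmax) shared across concentrations.

    ``data`` is a tidy sensorgram table (columns concentration, phase, time,
    response).  Unweighted least squares over both phases; rates are
    optimized in log10 space within bounds.  Deterministic given the data
    and the kobs-regression initialization.
    """
    curves = _split_curves(data)
    warnings: list[str] = []
    if len(curves) < 2:
        warnings.append(
            "single-concentration fit: kon and Rmax may be poorly constrained"
        )
    y_obs = np.concatenate(
        [np.concatenate([c["y_assoc"], c["y_dissoc"]]) for c in curves]
    )
    kon0, koff0, rmax0 = _initial_guess(curves)

    def unpack(x):
        kon = 10.0 ** x[0]
        koff = 10.0 ** x[1]
        rmax = x[2]
        b_a = x[3] if fit_baselines else 0.0
        b_d = x[4] if fit_baselines else 0.0
        return kon, koff, rmax, b_a, b_d

    def resid(x):
        return _predict(curves, *unpack(x)) - y_obs

    x0 = [math.log10(kon0), math.log10(koff0), rmax0]
    lo = [math.log10(kon_bounds[0]), math.log10(koff_bounds[0]), 1e-12]
    hi = [math.log10(kon_bounds[1]), math.log10(koff_bounds[1]), np.inf]
    if fit_baselines:
        x0 += [0.0, 0.0]
        lo += [-np.inf, -np.inf]
        hi += [np.inf, np.inf]
    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
    kon, koff, rmax, b_a, b_d = unpack(res.x)
    rss = float(2.0 * res.cost)
    n = y_obs.size

    # 1-sigma from local curvature (J'J), in the optimizer's parameter scale
    stderr: dict[str, float] = {}
    try:
        jtj = res.jac.T @ res.jac
        dof = max(n - res.x.size, 1)
        cov = np.linalg.inv(jtj) * (rss / dof)
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {"log10_kon": float(sd[0]), "log10_koff": float(sd[1]),
                  "rmax": float(sd[2])}
    except np.linalg.LinAlgError:
        warnings.append("singular curvature; no standard errors")

    if koff <= koff_bounds[0] * 1.05:
        warnings.append(
            f"koff at the lower bound ({koff_bounds[0]:g} /s): dissociation "
            "is flat over the observed window"
        )
    fit = KineticsFit(
        kon=kon, koff=koff, rmax=rmax, rss=rss, n_points=n,
        baselines={"association": b_a, "dissociation": b_d},
        stderr=stderr, warnings=tuple(warnings),
    )
    if not res.success:
        raise FitError(f"global fit did not converge: {res.message}", best=fit)
    return fit


def load_sensorgrams(path: str | Path) -> pd.DataFrame:
    """Read a sensorgram table (TSV/CSV with time, response, concentration,
    phase columns)."""
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep)
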