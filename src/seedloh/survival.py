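"""Single-hit multitarget survival model.

The classical radiobiological model in which a cell (here, a seedling)
dies once all N of its hypothetical targets are hit, each target being
inactivated independently with 1/e dose D0:

    S(D) = 1 − (1 − exp(−D / D0))^N

The low-dose plateau ends at the quasi-threshold ("shoulder") dose
Dq = D0·ln N, the quantity used to pick a mutagenesis dose that kills few
plants while still causing damage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SurvivalCurveFit",
    "survival_probability",
    "fit_multitarget",
    "shoulder_dose",
]


@dataclass(frozen=True)
class SurvivalCurveFit:
    """Fitted single-hit multitarget parameters."""

    D0: float
    N: float
    Dq: float
    residual_sse: float


def survival_probability(D, D0: float, N: float):
    """S(D) = 1 − (1 − e^{−D/D0})^N; scalar or array dose, in Gy."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be non-negative")
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if N < 1:
        raise ValueError("extrapolation number N must be >= 1")
    out = 1.0 - (1.0 - np.exp(-D / D0)) ** N
    return float(out) if out.ndim == 0 else out


def _initial_guess(dose: np.ndarray, frac: np.ndarray) -> tuple[float, float]:
    # Terminal slope of log-survival gives -1/D0; extrapolating that line
    # back to dose 0 gives log N.  Use the decaying part of the curve.
    ok = (frac > 0) & (frac < 1) & (dose > 0)
    if ok.sum() >= 2:
        d, f = dose[ok], np.log(frac[ok])
        # weight the tail: keep the half of the points at highest dose
        order = np.argsort(d)
        tail = order[len(order) // 2:] if len(order) > 3 else order
        slope, intercept = np.polyfit(d[tail], f[tail], 1)
        if slope < 0:
            D0 = -1.0 / slope
            N = max(1.0, float(np.exp(intercept)))
            return float(D0), N
    return float(max(dose.max(), 1.0) / 3.0), 5.0


def fit_multitarget(
    data: pd.DataFrame,
    *,
    init_D0: float | None = None,
    init_N: float | None = None,
) -> SurvivalCurveFit:
    """Least-squares fit of (D0, N) to per-dose survival fractions.

    ``data`` needs columns ``dose_gy, n_total, n_survived``.  The fit is
    unweighted on the linear survival scale with bounds D0 > 0, N >= 1.

    Raises
    ------
    ValueError
        With fewer than 3 distinct doses, or with degenerate (all-survive
        or all-die) data from which the parameters are not identifiable.
    """
    dose = np.asarray(data["dose_gy"], dtype=float)
    n_total = np.asarray(data["n_total"], dtype=float)
    n_survived = np.asarray(data["n_survived"], dtype=float)
    if len(np.unique(dose)) < 3:
        raise ValueError("need at least 3 distinct doses to fit the model")
    if np.any(n_total <= 0) or np.any(n_survived > n_total):
        raise ValueError("survivor counts must satisfy 0 <= n_survived <= n_total")
    frac = n_survived / n_total
    if np.all(frac == 1.0) or np.all(frac == 0.0):
        raise ValueError("all-survive or all-die data: parameters not identifiable")

    g0, g1 = _initial_guess(dose, frac)
    x0 = np.array([init_D0 if init_D0 is not None else g0,
                   init_N if init_N is not None else g1])

    def resid(theta: np.ndarray) -> np.ndarray:
        D0, N = theta
        return 1.0 - (1.0 - np.exp(-dose / D0)) ** N - frac

    sol = least_squares(
        resid, x0, bounds=([1e-9, 1.0], [np.inf, np.inf]), xtol=1e-14, ftol=1e-14
    )
    D0, N = map(float, sol.x)
    sse = float(np.sum(sol.fun**2))
    return SurvivalCurveFit(D0=D0, N=N, Dq=D0 * np.log(N), residual_sse=sse)


def shoulder_dose(fit: SurvivalCurveFit) -> float:
    """Quasi-threshold dose Dq = D0·ln N, in Gy."""
    return fit.D0 * float(np.log(fit.N))
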