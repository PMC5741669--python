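"""Least-squares estimation of respiratory-system mechanics.

Airway pressure is regressed on volume, flow, and a constant:

    Paw = E * V + R * V' + P0

per breath (default) or over the whole recording, by ordinary least squares.
Per-breath estimates are aggregated by median (default) or mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from varivent.simulator import BreathSignal

__all__ = ["MechanicsFit", "DegenerateFitError", "fit_equation_of_motion"]


class DegenerateFitError(ValueError):
    """Raised when the regressor matrix for a breath is rank-deficient."""


@dataclass(frozen=True)
class MechanicsFit:
    """Aggregated equation-of-motion fit with per-breath detail."""

    E_hat: float  # cmH2O/mL
    R_hat: float  # cmH2O/mL/s
    p0_hat: float  # cmH2O
    per_breath: tuple  # of (E, R, p0, r_squared)
    aggregation: str

    def to_dict(self) -> dict:
        return {
            "E_hat": self.E_hat,
            "R_hat": self.R_hat,
            "p0_hat": self.p0_hat,
            "aggregation": self.aggregation,
            "per_breath": [
                {"E": e, "R": r, "p0": p, "r_squared": r2} for e, r, p, r2 in self.per_breath
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _ols_breath(paw, flow, volume, breath_index: int):
    X = np.column_stack([volume, flow, np.ones_like(paw)])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateFitError(
            f"breath {breath_index}: regressor matrix (volume, flow, 1) is rank-deficient"
        )
    coef, _, _, _ = np.linalg.lstsq(X, paw, rcond=None)
    resid = paw - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((paw - paw.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(coef[0]), float(coef[1]), float(coef[2]), min(r2, 1.0)


def fit_equation_of_motion(
    signal: BreathSignal,
    per_breath: bool = True,
    aggregation: str = "median",
    window: str = "whole",
) -> MechanicsFit:
    """Estimate (E, R, P0) from a recorded or simulated signal.

    Parameters
    ----------
    signal : BreathSignal
        Must contain at least one complete breath with volume consistent
        with the integral of flow.
    per_breath : bool
        Fit each breath separately and aggregate; otherwise one global fit.
    aggregation : {"median", "mean"}
        How per-breath estimates are combined.
    window : {"whole", "inspiration"}
        Fit over the whole breath or the inspiratory limb only (flow > 0).

    Raises
    ------
    DegenerateFitError
        If volume and flow are collinear over a fit window, naming the breath.
    """
    if aggregation not in ("median", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if window not in ("whole", "inspiration"):
        raise ValueError(f"unknown window {window!r}")
    if signal.n_breaths < 1:
        raise ValueError("signal contains no complete breath")
    if not signal.check_volume_consistency(rtol=1e-3):
        raise ValueError("volume trace is not the integral of flow; signal inconsistent")

    results = []
    if per_breath:
        for i, (start, stop) in enumerate(signal.iter_breaths()):
            sl = slice(start, stop)
            paw, flow, vol = signal.paw[sl], signal.flow[sl], signal.volume[sl]
            vol = vol - vol[0]  # reference to end-expiratory volume: p0 = total PEEP
            if window == "inspiration":
                mask = flow > 0
                paw, flow, vol = paw[mask], flow[mask], vol[mask]
            results.append(_ols_breath(paw, flow, vol, i))
    else:
        paw, flow, vol = signal.paw, signal.flow, signal.volume
        if window == "inspiration":
            mask = flow > 0
            paw, flow, vol = paw[mask], flow[mask], vol[mask]
        results.append(_ols_breath(paw, flow, vol, 0))

    arr = np.asarray(results)
    agg = np.median if aggregation == "median" else np.mean
    return MechanicsFit(
        E_hat=float(agg(arr[:, 0])),
        R_hat=float(agg(arr[:, 1])),
        p0_hat=float(agg(arr[:, 2])),
        per_breath=tuple(map(tuple, results)),
        aggregation=aggregation,
    )
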