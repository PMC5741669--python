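"""Forward simulation of airway pressure from tidal-volume sequences.

The single-compartment linear model computes pressure directly from the
prescribed volume/flow waveforms:

    Paw(t) = E * V(t) + R * V'(t) + P0 + noise

An optional second compartment (with its own elastance/resistance) is
integrated breath-by-breath to emulate time-constant inhomogeneity; it exists
to stress the estimator and is never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

__all__ = ["LungModel", "BreathSignal", "simulate"]


@dataclass(frozen=True)
class LungModel:
    """Linear respiratory-system model parameters.

    E in cmH2O/mL, R in cmH2O/mL/s, p0 the end-expiratory pressure offset
    (equal to total PEEP). Providing (E2, R2) adds a second compartment in
    parallel with (E, R); the volume split between compartments then follows
    from the mechanics (steady-state fraction to compartment 2 is
    E/(E+E2)), so no explicit fraction parameter is accepted.
    """

    E: float
    R: float
    p0: float = 3.0
    E2: float | None = None
    R2: float | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError(f"E must be > 0, got {self.E}")
        if self.R <= 0:
            raise ValueError(f"R must be > 0, got {self.R}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if (self.E2 is None) != (self.R2 is None):
            raise ValueError("two-compartment model requires both E2 and R2")
        if self.E2 is not None and (self.E2 <= 0 or self.R2 <= 0):
            raise ValueError("E2 and R2 must be > 0")

    @property
    def two_compartment(self) -> bool:
        return self.E2 is not None


@dataclass
class BreathSignal:
    """Time-aligned airway pressure, flow, and volume for >= 1 breaths."""

    time: np.ndarray  # s, uniform grid
    paw: np.ndarray  # cmH2O
    flow: np.ndarray  # mL/s, inspiratory positive
    volume: np.ndarray  # mL, 0 at end-expiration
    breath_boundaries: np.ndarray  # sample index of each breath start, + end sentinel

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.paw) == len(self.flow) == len(self.volume) == n):
            raise ValueError("time, paw, flow, volume must have equal length")

    @property
    def sampling_hz(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    @property
    def n_breaths(self) -> int:
        return len(self.breath_boundaries) - 1

    def iter_breaths(self):
        """Yield (start, stop) sample-index pairs, one per breath."""
        b = self.breath_boundaries
        for i in range(len(b) - 1):
            yield int(b[i]), int(b[i + 1])

    def check_volume_consistency(self, rtol: float = 1e-6) -> bool:
        """Volume must be the cumulative trapezoid of flow within each breath."""
        for start, stop in self.iter_breaths():
            v = cumulative_trapezoid(self.flow[start:stop], self.time[start:stop], initial=0.0)
            v += self.volume[start]
            scale = max(np.abs(self.volume[start:stop]).max(), 1e-12)
            if np.abs(v - self.volume[start:stop]).max() > rtol * scale:
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "paw_cmH2O": self.paw,
                "flow_mL_s": self.flow,
                "vol_mL": self.volume,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, breath_boundaries=None) -> "BreathSignal":
        df = pd.read_csv(path)
        n = len(df)
        if breath_boundaries is None:
            breath_boundaries = np.array([0, n])
        return cls(
            time=df["time_s"].to_numpy(),
            paw=df["paw_cmH2O"].to_numpy(),
            flow=df["flow_mL_s"].to_numpy(),
            volume=df["vol_mL"].to_numpy(),
            breath_boundaries=np.asarray(breath_boundaries),
        )


def _two_compartment_pressure(flow, volume, dt, model: LungModel):
    """Integrate two parallel first-order compartments sharing airway pressure.

    Total flow is prescribed; the split between compartments follows from
    equal pressure at the common airway opening:
        Paw = E1*V1 + R1*V1' = E2*V2 + R2*V2',  V1' + V2' = flow.
    Solved with a semi-implicit Euler step on V1.
    """
    E1, R1 = model.E, model.R
    E2, R2 = model.E2, model.R2
    n = len(flow)
    v1 = np.zeros(n)
    paw = np.zeros(n)
    for k in range(1, n):
        # R1*V1' - R2*(flow - V1') = E2*V2 - E1*V1
        v2 = volume[k - 1] - v1[k - 1]
        rhs = E2 * v2 - E1 * v1[k - 1] + R2 * flow[k]
        dv1 = rhs / (R1 + R2)
        v1[k] = v1[k - 1] + dv1 * dt
        paw[k] = E1 * v1[k] + R1 * dv1
    paw[0] = paw[1] if n > 1 else 0.0
    return paw


def simulate(seq, model: LungModel, plan, sampling_hz: float = 1000.0, pause_s: float = 0.0) -> BreathSignal:
    """Simulate pressure/flow/volume traces for every breath of ``seq``.

    Expiration uses a passive RC profile with the model's own time constant
    R/E, so the noise-free single-compartment output satisfies the equation
    of motion at every sample.
    """
    from varivent.vtgen import build_breath_waveform

    values = np.asarray(seq.values if hasattr(seq, "values") else seq, dtype=float)
    if values.size == 0:
        raise ValueError("tidal-volume sequence is empty")

    tau = model.R / model.E
    chunks_flow, chunks_vol, boundaries = [], [], [0]
    for vt in values:
        breath = build_breath_waveform(
            float(vt),
            plan,
            sampling_hz=sampling_hz,
            expiration="exponential",
            expiratory_tau=tau,
            pause_s=pause_s,
        )
        chunks_flow.append(breath.flow)
        chunks_vol.append(breath.volume)
        boundaries.append(boundaries[-1] + len(breath.flow))

    flow = np.concatenate(chunks_flow)
    volume = np.concatenate(chunks_vol)
    n = len(flow)
    dt = 1.0 / sampling_hz
    time = np.arange(n) * dt

    if model.two_compartment:
        paw = np.zeros(n)
        for i in range(len(boundaries) - 1):
            s, e = boundaries[i], boundaries[i + 1]
            paw[s:e] = _two_compartment_pressure(flow[s:e], volume[s:e], dt, model)
        paw += model.p0
    else:
        paw = model.E * volume + model.R * flow + model.p0

    if model.noise_sd > 0:
        rng = np.random.default_rng(model.seed)
        paw = paw + rng.normal(0.0, model.noise_sd, size=n)

    return BreathSignal(
        time=time,
        paw=paw,
        flow=flow,
        volume=volume,
        breath_boundaries=np.asarray(boundaries),
    )
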