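"""Breath-to-breath variable tidal-volume sequences and ventilator waveforms.

Tidal volumes are drawn from a Gaussian centred on the nominal mean with a
standard deviation set by the target coefficient of variation (CV), clipped
to a configurable number of SDs and floored at a strictly positive fraction
of the mean so every breath is deliverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VentilationPlan", "VTSequence", "generate_vt_sequence", "build_breath_waveform"]

#: default body mass in kg (study cohort mean)
DEFAULT_BODY_MASS_KG = 0.437

#: default respiratory rate chosen so that VT x RR ~ 150 mL/min at 6 mL/kg
DEFAULT_RESP_RATE = 57.0


@dataclass(frozen=True)
class VentilationPlan:
    """Configuration for one variable-ventilation run.

    Parameters
    ----------
    mean_vt : float
        Nominal mean tidal volume in mL/kg body mass.
    cv_pct : float
        Target coefficient of variation of tidal volume, percent.
    n_breaths : int
        Number of breaths in the sequence.
    body_mass : float
        Animal body mass in kg; absolute volumes are ``mean_vt * body_mass``.
    peep : float
        Positive end-expiratory pressure, cmH2O.
    resp_rate : float
        Respiratory rate, breaths/min.
    ie_ratio : float
        Inspiratory:expiratory time ratio (I/E), dimensionless.
    seed : int
        Seed for the tidal-volume random draws.
    truncation_sd : float
        Number of SDs at which draws are clipped; ``inf`` disables clipping.
    positivity_floor : float
        Lower bound on volumes as a fraction of the mean.
    normalize_mean : bool
        Rescale the finished sequence so its sample mean equals the nominal
        mean exactly (the delivered mean tidal volume and minute ventilation
        are then held at their targets, as in the study tables). Rescaling
        leaves the coefficient of variation unchanged.
    """

    mean_vt: float = 6.0
    cv_pct: float = 0.0
    n_breaths: int = 1200
    body_mass: float = DEFAULT_BODY_MASS_KG
    peep: float = 3.0
    resp_rate: float = DEFAULT_RESP_RATE
    ie_ratio: float = 0.5
    seed: int = 0
    truncation_sd: float = 3.0
    positivity_floor: float = 0.1
    normalize_mean: bool = True

    def __post_init__(self) -> None:
        if self.mean_vt <= 0:
            raise ValueError(f"mean_vt must be > 0, got {self.mean_vt}")
        if self.cv_pct < 0:
            raise ValueError(f"cv_pct must be >= 0, got {self.cv_pct}")
        if self.n_breaths < 1:
            raise ValueError(f"n_breaths must be >= 1, got {self.n_breaths}")
        if self.body_mass <= 0:
            raise ValueError(f"body_mass must be > 0, got {self.body_mass}")
        if self.peep < 0:
            raise ValueError(f"peep must be >= 0, got {self.peep}")
        if self.resp_rate <= 0:
            raise ValueError(f"resp_rate must be > 0, got {self.resp_rate}")
        if self.ie_ratio <= 0:
            raise ValueError(f"ie_ratio must be > 0, got {self.ie_ratio}")
        if self.truncation_sd <= 0:
            raise ValueError(f"truncation_sd must be > 0, got {self.truncation_sd}")
        if not 0 <= self.positivity_floor < 1:
            raise ValueError("positivity_floor must be in [0, 1)")

    @property
    def mean_vt_abs(self) -> float:
        """Absolute mean tidal volume in mL."""
        return self.mean_vt * self.body_mass

    @property
    def breath_period(self) -> float:
        """Breath period in seconds."""
        return 60.0 / self.resp_rate


@dataclass(frozen=True)
class VTSequence:
    """A realized tidal-volume sequence with summary statistics."""

    values: np.ndarray  # mL, absolute
    realized_mean: float
    realized_cv_pct: float
    seed_used: int
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.values) <= 0):
            raise ValueError("all tidal volumes must be > 0")

    def __len__(self) -> int:
        return len(self.values)


def _summarize(values: np.ndarray) -> tuple[float, float]:
    mean = float(np.mean(values))
    cv = 100.0 * float(np.std(values, ddof=1)) / mean if len(values) > 1 else 0.0
    return mean, cv


def generate_vt_sequence(plan: VentilationPlan) -> VTSequence:
    """Draw a Gaussian tidal-volume sequence according to ``plan``.

    Draws are clipped at ``mean +/- truncation_sd * SD`` and floored at
    ``positivity_floor * mean``. If the floor censors more than 1% of draws
    a warning is recorded on the result (it is never an error).
    Identical plan and seed give a bit-identical sequence.
    """
    mean = plan.mean_vt_abs
    n = plan.n_breaths
    if plan.cv_pct == 0:
        values = np.full(n, mean)
        return VTSequence(values=values, realized_mean=mean, realized_cv_pct=0.0, seed_used=plan.seed)

    sd = mean * plan.cv_pct / 100.0
    rng = np.random.default_rng(plan.seed)
    raw = rng.normal(mean, sd, size=n)
    if np.isfinite(plan.truncation_sd):
        values = np.clip(raw, mean - plan.truncation_sd * sd, mean + plan.truncation_sd * sd)
    else:
        values = raw.copy()

    floor = plan.positivity_floor * mean
    if floor <= 0:
        # positivity must still hold: nudge nonpositive draws to a tiny volume
        floor = np.finfo(float).tiny
    censored = values < floor
    warnings: tuple[str, ...] = ()
    if censored.mean() > 0.01:
        warnings = (
            f"positivity floor censored {censored.mean():.1%} of draws "
            f"(cv_pct={plan.cv_pct}); realized CV will be attenuated",
        )
    values = np.maximum(values, floor)
    if plan.normalize_mean:
        values = values * (mean / values.mean())

    realized_mean, realized_cv = _summarize(values)
    return VTSequence(
        values=values,
        realized_mean=realized_mean,
        realized_cv_pct=realized_cv,
        seed_used=plan.seed,
        warnings=warnings,
    )


def build_breath_waveform(
    vt: float,
    plan: VentilationPlan,
    sampling_hz: float = 1000.0,
    expiration: str = "exponential",
    expiratory_tau: float | None = None,
    pause_s: float = 0.0,
):
    """Build one volume-controlled breath: constant inspiratory flow, passive expiration.

    Inspiratory flow is constant at ``vt / t_insp`` over the inspiratory
    fraction of the period; expiration is an exponential (default) or linear
    return to zero volume. The expiratory flow profile is rescaled so its
    discrete trapezoid integral returns the volume to 0 at end-expiration.

    An optional end-inspiratory pause of ``pause_s`` seconds (zero flow at
    full inflation) is carved out of the expiratory window.

    Returns
    -------
    BreathSignal
        Time, flow, and volume arrays for one breath; ``paw`` is all-NaN
        (pressure is produced by the simulator).
    """
    from varivent.simulator import BreathSignal

    if vt <= 0:
        raise ValueError(f"vt must be > 0, got {vt}")
    if sampling_hz <= 0:
        raise ValueError(f"sampling_hz must be > 0, got {sampling_hz}")
    if expiration not in ("exponential", "linear"):
        raise ValueError(f"unknown expiration profile {expiration!r}")

    period = plan.breath_period
    dt = 1.0 / sampling_hz
    n_total = int(round(period * sampling_hz))
    if n_total < 2:
        raise ValueError(
            f"breath period {period:.4g}s holds fewer than 2 samples at {sampling_hz} Hz"
        )
    t_insp = period * plan.ie_ratio / (1.0 + plan.ie_ratio)
    n_insp = max(int(round(t_insp * sampling_hz)), 1)
    n_exp = n_total - n_insp
    if n_exp < 1:
        raise ValueError("expiratory phase holds fewer than 1 sample; lower resp_rate or ie_ratio")

    # samples 0..n_insp carry constant inspiratory flow so the trapezoid
    # integral over the inspiratory window equals vt exactly
    time = np.arange(n_total) * dt
    flow = np.empty(n_total)
    flow[: n_insp + 1] = vt / (n_insp * dt)
    n_pause = int(round(pause_s * sampling_hz))
    flow[n_insp + 1 : n_insp + 1 + n_pause] = 0.0
    exp_start = n_insp + 1 + n_pause
    n_exp = n_total - exp_start
    if n_exp < 1:
        raise ValueError("expiratory phase holds fewer than 1 sample; lower resp_rate or ie_ratio")

    t_exp = (np.arange(n_exp) + 1) * dt
    if expiration == "exponential":
        tau = expiratory_tau if expiratory_tau is not None else (n_exp * dt) / 5.0
        shape = np.exp(-t_exp / tau)
    else:
        shape = 1.0 - t_exp / (n_exp * dt + dt)
    flow[exp_start:] = -shape

    from scipy.integrate import cumulative_trapezoid

    # rescale the expiratory limb so the trapezoid-integrated volume returns
    # to 0 at end-expiration; the transition trapezoid's inspiratory half is
    # fixed, so solve v_base + s * (v_full - v_base) = 0 for the scale s
    base = flow.copy()
    base[exp_start:] = 0.0
    v_base = cumulative_trapezoid(base, dx=dt, initial=0.0)[-1]
    v_full = cumulative_trapezoid(flow, dx=dt, initial=0.0)[-1]
    if v_full >= v_base:  # pragma: no cover - shapes above are strictly negative
        raise RuntimeError("expiratory profile does not expel volume")
    flow[exp_start:] *= v_base / (v_base - v_full)
    volume = cumulative_trapezoid(flow, dx=dt, initial=0.0)

    paw = np.full(n_total, np.nan)
    return BreathSignal(
        time=time,
        paw=paw,
        flow=flow,
        volume=volume,
        breath_boundaries=np.array([0, n_total]),
    )
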