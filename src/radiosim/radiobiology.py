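"""Linear-Quadratic cell killing and fractionation schedules.

Survival after a uniform dose D follows S(D) = exp(-(alpha D + beta D^2)).
Radiosensitivity varies over the cell cycle: S phase is the most
radioresistant proliferating phase and dormant (G0, hypoxic) cells are the
most resistant overall.  The phase-specific coefficients derive from the
proliferating-phase pair (alpha_p, beta_p) through the oxygen enhancement
ratio:

    alpha_G0 = alpha_p / OER          beta_G0 = beta_p / OER^2
    alpha_S  = 0.6 alpha_p + 0.4 alpha_G0
    beta_S   = 0.6 beta_p  + 0.4 beta_G0

Cells killed by a fraction are marked *lethally hit* at the administration
instant; they keep cycling rudimentarily and die through necrosis after two
further mitoses (mitotic catastrophe).  Terminally differentiated cells are
irradiated with the dormant-cell coefficients (non-cycling, most
radioresistant) and their killed part joins the necrotic pool directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

from .cytokinetics import HIT2, UNHIT, CompartmentState

__all__ = [
    "Radiosensitivity",
    "RTSchedule",
    "surviving_fraction",
    "derive_phase_sensitivities",
    "apply_irradiation",
    "make_schedule",
]


@dataclass(frozen=True)
class Radiosensitivity:
    """Phase-resolved LQ coefficients (Gy^-1 / Gy^-2)."""

    alpha_p: float
    beta_p: float
    alpha_s: float
    beta_s: float
    alpha_G0: float
    beta_G0: float
    OER: float = 1.0
    cell_kill_factor: float = 1.0  # multiplier on stem-cell kill probability

    @classmethod
    def from_alpha(cls, alpha_p: float, alpha_beta_ratio: float = 3.0,
                   OER: float = 1.0, cell_kill_factor: float = 1.0) -> "Radiosensitivity":
        """Build from alpha with beta slaved through the alpha/beta ratio."""
        beta_p = alpha_p / alpha_beta_ratio if alpha_beta_ratio else 0.0
        return derive_phase_sensitivities(alpha_p, beta_p, OER, cell_kill_factor)


@dataclass
class RTSchedule:
    """Ordered irradiation events: (time in hours since start, dose in Gy)."""

    events: List[Tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        if any(d <= 0 for _, d in self.events):
            raise ValueError("doses must be positive")

    def __len__(self) -> int:
        return len(self.events)

    def doses_in_hour(self, t: int) -> List[float]:
        """Doses administered within simulation hour [t, t+1)."""
        return [d for et, d in self.events if t <= et < t + 1]

    @property
    def total_dose(self) -> float:
        return sum(d for _, d in self.events)


def surviving_fraction(alpha: float, beta: float, dose: float) -> float:
    """LQ surviving fraction exp(-(alpha D + beta D^2))."""
    if dose < 0:
        raise ValueError("dose must be non-negative")
    if alpha < 0 or beta < 0:
        raise ValueError("LQ coefficients must be non-negative")
    return math.exp(-(alpha * dose + beta * dose * dose))


def derive_phase_sensitivities(alpha_p: float, beta_p: float, OER: float,
                               cell_kill_factor: float = 1.0) -> Radiosensitivity:
    """Phase-specific LQ coefficients from the proliferating-phase pair."""
    if OER < 1.0:
        raise ValueError("OER must be >= 1")
    alpha_G0 = alpha_p / OER
    beta_G0 = beta_p / OER**2
    return Radiosensitivity(
        alpha_p=alpha_p, beta_p=beta_p,
        alpha_s=0.6 * alpha_p + 0.4 * alpha_G0,
        beta_s=0.6 * beta_p + 0.4 * beta_G0,
        alpha_G0=alpha_G0, beta_G0=beta_G0,
        OER=OER, cell_kill_factor=cell_kill_factor,
    )


def apply_irradiation(
    state: CompartmentState,
    dose: float,
    rs: Radiosensitivity,
    rng: Optional[np.random.Generator] = None,
) -> dict:
    """Mark lethally hit cells in every GC for one dose fraction (in place).

    Per subclass the kill probability is 1 - S(D) with the coefficients of
    its phase (G1/G2/M: proliferating; S: S phase; G0 and DIFF: dormant),
    multiplied by ``cell_kill_factor`` for stem subclasses.  Killed cycling
    cells move unhit -> hit(2) within their phase position; killed DIFF
    cells join the necrotic pool.  Returns the per-pool kill counts.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    stochastic = state.params.stochastic
    if dose == 0:
        z = np.zeros(state.n)
        return {"cycling": z, "g0": z.copy(), "diff": z.copy()}

    def kill_p(alpha, beta):
        return 1.0 - surviving_fraction(alpha, beta, dose)

    p_prolif = kill_p(rs.alpha_p, rs.beta_p)
    p_s = kill_p(rs.alpha_s, rs.beta_s)
    p_g0 = kill_p(rs.alpha_G0, rs.beta_G0)
    phase_p = [p_prolif, p_s, p_prolif, p_prolif]   # G1, S, G2, M
    ckf = rs.cell_kill_factor

    def draw(arr, p):
        if stochastic:
            return rng.binomial(np.round(arr).astype(np.int64), p).astype(float)
        return arr * p

    hit_cycling = np.zeros(state.n)
    for ph, arr in enumerate(state.cycle):
        unhit = arr[:, :, UNHIT, :]
        killed = draw(unhit, phase_p[ph])
        killed[:, 0] = draw(unhit[:, 0], phase_p[ph] * ckf) if ckf != 1.0 else killed[:, 0]
        arr[:, :, UNHIT, :] -= killed
        arr[:, :, HIT2, :] += killed
        hit_cycling += killed.sum(axis=(1, 2))
    if state.hourly_g0:
        unhit = state.g0_age[:, :, UNHIT, :]
        killed = draw(unhit, p_g0)
        if ckf != 1.0:
            killed[:, 0] = draw(unhit[:, 0], p_g0 * ckf)
        state.g0_age[:, :, UNHIT, :] -= killed
        state.g0_age[:, :, HIT2, :] += killed
        hit_g0 = killed.sum(axis=(1, 2))
    else:
        unhit = state.g0[:, :, UNHIT]
        killed = draw(unhit, p_g0)
        if ckf != 1.0:
            killed[:, 0] = draw(unhit[:, 0], p_g0 * ckf)
        state.g0[:, :, UNHIT] -= killed
        state.g0[:, :, HIT2] += killed
        hit_g0 = killed.sum(axis=1)
    killed_diff = draw(state.diff, p_g0)
    state.diff -= killed_diff
    state.nec[:, 0] += killed_diff
    return {"cycling": hit_cycling, "g0": hit_g0, "diff": killed_diff}


def make_schedule(
    start_day: int = 0,
    n_fractions: int = 0,
    dose_per_fraction: float = 2.0,
    weekday_time: float = 8.0,
    skip_weekends: bool = True,
    start_weekday: int = 0,
) -> RTSchedule:
    """Daily fractionation schedule with an optional weekend pause.

    ``start_day`` is in simulation days, ``weekday_time`` the hour of
    administration within the day, ``start_weekday`` the weekday of
    simulation day 0 (0 = Monday).
    """
    if n_fractions < 0:
        raise ValueError("n_fractions must be >= 0")
    if n_fractions > 0 and dose_per_fraction <= 0:
        raise ValueError("dose per fraction must be positive")
    events = []
    day = start_day
    delivered = 0
    while delivered < n_fractions:
        weekday = (start_weekday + day) % 7
        if not (skip_weekends and weekday >= 5):
            events.append((24.0 * day + weekday_time, dose_per_fraction))
            delivered += 1
        day += 1
    return RTSchedule(events=events)
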