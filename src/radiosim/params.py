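"""Model parameters, derived phase durations and the analytic free-growth check.

The simulator describes a solid tumor as five interacting cell populations:
cancer stem cells (unlimited mitotic potential), LIMP cells (LImited Mitotic
Potential progenitors that differentiate terminally after ``N_LIMP`` further
mitoses), terminally differentiated (DIFF) cells, and the apoptotic and
necrotic remains of dead cells awaiting clearance.  All kinetic constants of
that description live in :class:`ModelParameters`; everything downstream
(cytokinetics, radiobiology, mesh, engine) consumes this object.

Times are hours, rates are per-hour fractions, lengths are millimetres.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import List, Tuple

__all__ = [
    "ModelParameters",
    "PhaseDurations",
    "ValidationReport",
    "phase_durations",
    "free_growth_lhs",
    "classify_growth_regime",
    "validate_parameters",
    "GROWING",
    "INDETERMINATE",
    "SELF_DIMINISHING",
]

#: Duration of mitosis, hours.  The hourly clock of the simulator is chosen
#: to match the shortest cell-cycle phase, so T_M is fixed.
T_M = 1.0

SELF_DIMINISHING = "self-diminishing"
INDETERMINATE = "indeterminate"
GROWING = "growing"


@dataclass(frozen=True)
class PhaseDurations:
    """Cell-cycle phase durations (hours) derived from the cycle time T_c.

    G1 and S each take 41 % of the non-mitotic cycle, G2 takes 18 %, and
    mitosis is pinned at 1 h, so T_G1 + T_S + T_G2 + T_M == T_c exactly.
    Durations are kept as real hours; the hourly engine realises a
    fractional duration with the exact mean by splitting entrants between
    the two adjacent integer residences.
    """

    T_G1: float
    T_S: float
    T_G2: float
    T_M: float = T_M

    @property
    def total(self) -> float:
        return self.T_G1 + self.T_S + self.T_G2 + self.T_M

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.T_G1, self.T_S, self.T_G2, self.T_M)


def phase_durations(T_c: float) -> PhaseDurations:
    """Split a cell-cycle duration into per-phase durations.

    Parameters
    ----------
    T_c : float
        Total cell-cycle duration in hours; must exceed the 1-h mitosis.

    Returns
    -------
    PhaseDurations
        ``T_G1 = T_S = 0.41 (T_c - 1)``, ``T_G2 = 0.18 (T_c - 1)``,
        ``T_M = 1``.
    """
    if not T_c > T_M:
        raise ValueError(f"T_c must exceed T_M = {T_M} h, got {T_c}")
    rest = T_c - T_M
    return PhaseDurations(0.41 * rest, 0.41 * rest, 0.18 * rest, T_M)


@dataclass
class ModelParameters:
    """Full kinetic parameter set of one (homogeneous) tumor region.

    Defaults correspond to a slowly proliferating, necrosis-free prostate
    adenocarcinoma profile (doubling time ~500 days, growth fraction ~1 %).
    Per-class values for LIMP cells default to the stem-cell values.
    """

    # --- phase / lifetime durations (hours) -------------------------------
    T_c: float = 31.0            # cell-cycle duration, stem cells
    T_c_limp: float | None = None   # LIMP cycle duration; None -> T_c
    T_G0: float = 373.0          # mean dormant-phase sojourn before necrosis
    T_G0_limp: float | None = None
    T_N: float = 186.0           # necrosis completion + lysis-removal time
    T_A: float = 17.0            # apoptosis completion + removal time

    # --- transition rates / fractions -------------------------------------
    R_A: float = 10.230e-4       # spontaneous apoptosis of living stem/LIMP, h^-1
    R_NDiff: float = 0.0         # necrosis rate of DIFF cells, h^-1
    R_ADiff: float = 2.591e-4    # apoptosis rate of DIFF cells, h^-1
    P_G0toG1: float = 1.0        # fraction of ending dormancies that re-enter G1
    P_sleep: float = 0.179       # fraction of newborn cells entering G0
    P_sym: float = 0.090         # fraction of stem divisions that are symmetric
    N_LIMP: int = 7              # mitoses a LIMP cell performs before DIFF

    # --- mesh / bookkeeping ------------------------------------------------
    cell_density: float = 1.0e6  # biological cells per mm^3
    voxel_edge: float = 1.0      # GC edge, mm
    margin_percent: float = 0.1  # allowed occupancy fluctuation around NBC
    color_criterion: float = 0.9  # dead fraction that paints a GC necrotic

    # --- run control --------------------------------------------------------
    mode: int = 1                # 1: free growth, 2: treatment response
    spatial_evolution: bool = True
    execution_time: float = 100.0  # days
    rng_seed: int = 0

    # --- numerics -----------------------------------------------------------
    #: "sojourn": dormancy ends at hazard 1/T_G0, endings split P_G0toG1 to
    #: G1 vs necrosis (matches the analytic free-growth condition).
    #: "hourly": fraction P_G0toG1 of the pool exits to G1 every hour and
    #: survivors necrose at the T_G0 wall (literal per-hour reading).
    g0_exit: str = "sojourn"
    stochastic: bool = False     # integer Monte-Carlo flows instead of fractional

    def __post_init__(self) -> None:
        if self.T_c_limp is None:
            self.T_c_limp = self.T_c
        if self.T_G0_limp is None:
            self.T_G0_limp = self.T_G0

    # -- derived -------------------------------------------------------------
    @property
    def NBC(self) -> float:
        """Nominal number of biological cells per geometrical cell."""
        return self.cell_density * self.voxel_edge**3

    def durations(self, limp: bool = False) -> PhaseDurations:
        return phase_durations(self.T_c_limp if limp else self.T_c)

    def replace(self, **kw) -> "ModelParameters":
        """Copy with selected fields overridden."""
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ValidationReport:
    ok: bool
    violations: List[Tuple[str, str]] = field(default_factory=list)
    growth_regime: str = INDETERMINATE
    lhs: float = float("nan")


def free_growth_lhs(params: ModelParameters, parse: str = "default") -> float:
    """Left-hand side of the analytic self-sustainment condition.

    A stem division yields on average ``1 + P_sym`` stem-fated daughters.
    Each daughter either cycles directly (probability ``1 - P_sleep``) or
    detours through dormancy, which it survives back into the cycle with
    probability ``P_G0toG1 / (T_G0 R_A + 1)`` (re-entry competing with
    apoptosis and necrosis at the dormancy-ending hazard ``1/T_G0``).
    Discounting one cycle of spontaneous apoptosis, the expected number of
    cycling stem cells replacing a single one is

        LHS = (1 + P_sym) [ (1 - P_sleep) + P_sleep P_G0toG1 / (T_G0 R_A + 1) ]
              exp(-R_A T_c)

    LHS > 1 means the stem compartment sustains itself.  ``parse="alt"``
    evaluates the variant ``1 + P_sym [...] exp(-R_A T_c)``.
    """
    bracket = (1.0 - params.P_sleep) + params.P_sleep * params.P_G0toG1 / (
        params.T_G0 * params.R_A + 1.0
    )
    decay = math.exp(-params.R_A * params.T_c)
    if parse == "default":
        return (1.0 + params.P_sym) * bracket * decay
    if parse == "alt":
        return 1.0 + params.P_sym * bracket * decay
    raise ValueError(f"unknown parse {parse!r}")


def classify_growth_regime(lhs: float) -> str:
    """Map the self-sustainment LHS onto a growth regime.

    Below 0.9 free growth cannot be sustained; above 1.1 it is ensured; the
    band in between must be resolved by simulation.
    """
    if lhs < 0:
        raise ValueError(f"LHS must be non-negative, got {lhs}")
    if lhs < 0.9:
        return SELF_DIMINISHING
    if lhs <= 1.1:
        return INDETERMINATE
    return GROWING


_RANGE_CHECKS = [
    # (field, low, high, inclusive-low, inclusive-high)
    ("R_A", 0.0, 1.0),
    ("R_NDiff", 0.0, 1.0),
    ("R_ADiff", 0.0, 1.0),
    ("P_G0toG1", 0.0, 1.0),
    ("P_sleep", 0.0, 1.0),
    ("P_sym", 0.0, 1.0),
    ("margin_percent", 0.0, 0.5),
    ("color_criterion", 0.9, 0.999),
]


def validate_parameters(params: ModelParameters) -> ValidationReport:
    """Range-check every field and embed the free-growth classification."""
    violations: List[Tuple[str, str]] = []
    for name, lo, hi in _RANGE_CHECKS:
        v = getattr(params, name)
        if not (lo <= v <= hi):
            violations.append((name, f"{v} outside [{lo}, {hi}]"))
    for name in ("T_c", "T_c_limp"):
        if not getattr(params, name) > T_M:
            violations.append((name, f"must exceed T_M = {T_M} h"))
    for name in ("T_G0", "T_G0_limp", "T_N", "T_A"):
        if not getattr(params, name) > 0:
            violations.append((name, "must be positive"))
    if params.N_LIMP < 1 or params.N_LIMP != int(params.N_LIMP):
        violations.append(("N_LIMP", "must be an integer >= 1"))
    if params.cell_density <= 0:
        violations.append(("cell_density", "must be positive"))
    if params.voxel_edge <= 0:
        violations.append(("voxel_edge", "must be positive"))
    if params.mode not in (1, 2):
        violations.append(("mode", "must be 1 (free growth) or 2 (treatment)"))
    if params.g0_exit not in ("sojourn", "hourly"):
        violations.append(("g0_exit", "must be 'sojourn' or 'hourly'"))

    try:
        lhs = free_growth_lhs(params)
        regime = classify_growth_regime(lhs)
    except ValueError:
        lhs, regime = float("nan"), INDETERMINATE
    return ValidationReport(ok=not violations, violations=violations,
                            growth_regime=regime, lhs=lhs)
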