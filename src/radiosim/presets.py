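"""Named virtual-tumor parameter sets.

Five "solution" profiles span the clinically reported range of prostate
tumor kinetics (doubling times from ~3 months to ~16 months, growth
fractions below 10 %, negligible necrosis), and seven "case" profiles are
single-parameter variations of the slowest-growing baseline used for
parametric exploration.  Radiosensitivity is expressed through the
proliferating-phase alpha (Gy^-1), a fixed alpha/beta ratio of 3 Gy and an
oxygen enhancement ratio applied to dormant cells.
"""

from __future__ import annotations

from .params import ModelParameters

__all__ = ["solution", "case", "SOLUTIONS", "CASES", "ALPHA_BETA_RATIO"]

ALPHA_BETA_RATIO = 3.0  # Gy, prostate adenocarcinoma

# kinetic parameters per named virtual tumor
SOLUTIONS: dict[str, dict] = {
    "solution-1": dict(T_c=31, T_G0=131, T_N=29, T_A=7, N_LIMP=8,
                       R_A=44.999e-4, R_NDiff=5.951e-4, R_ADiff=4.062e-4,
                       P_G0toG1=0.5, P_sleep=0.308, P_sym=0.474),
    "solution-2": dict(T_c=30, T_G0=113, T_N=98, T_A=16, N_LIMP=7,
                       R_A=5.425e-4, R_NDiff=2.775e-4, R_ADiff=16.102e-4,
                       P_G0toG1=0.5, P_sleep=0.255, P_sym=0.190),
    "solution-3": dict(T_c=31, T_G0=146, T_N=5, T_A=1, N_LIMP=9,
                       R_A=69.285e-4, R_NDiff=0.189e-4, R_ADiff=0.845e-4,
                       P_G0toG1=1.0, P_sleep=0.288, P_sym=0.453),
    "solution-4": dict(T_c=30, T_G0=109, T_N=143, T_A=4, N_LIMP=7,
                       R_A=46.744e-4, R_NDiff=0.600e-4, R_ADiff=1.102e-4,
                       P_G0toG1=1.0, P_sleep=0.289, P_sym=0.278),
    "solution-5": dict(T_c=31, T_G0=373, T_N=186, T_A=17, N_LIMP=7,
                       R_A=10.230e-4, R_NDiff=0.0, R_ADiff=2.591e-4,
                       P_G0toG1=1.0, P_sleep=0.179, P_sym=0.090),
}

#: (alpha_p in Gy^-1, OER) per solution, patient-1 adaptation
SOLUTION_RADIO: dict[str, tuple[float, float]] = {
    "solution-1": (10.068e-3, 1.960),
    "solution-2": (9.969e-3, 2.187),
    "solution-3": (25.998e-3, 2.989),
    "solution-4": (16.496e-3, 2.942),
    "solution-5": (9.336e-3, 2.388),
}

# single-parameter variations of the baseline (case-0 == solution-5 kinetics)
_CASE0 = dict(SOLUTIONS["solution-5"])
CASES: dict[str, dict] = {
    "case-0": dict(_CASE0),
    "case-1": dict(_CASE0, T_N=1, T_A=1),
    "case-2": dict(_CASE0, R_ADiff=0.0),
    "case-3": dict(_CASE0, P_sleep=0.060),
    "case-4": dict(_CASE0, P_sym=0.15),
    "case-5": dict(_CASE0),   # radiosensitivity change only (alpha)
    "case-6": dict(_CASE0),   # OER change only
}

#: (alpha_p in Gy^-1, OER) per case
CASE_RADIO: dict[str, tuple[float, float]] = {
    "case-0": (9.254e-3, 2.388),
    "case-1": (9.254e-3, 2.388),
    "case-2": (9.254e-3, 2.388),
    "case-3": (9.254e-3, 2.388),
    "case-4": (9.254e-3, 2.388),
    "case-5": (150.000e-3, 2.388),
    "case-6": (9.254e-3, 1.00),
}


def solution(name: str | int, **overrides) -> ModelParameters:
    """Parameter set of a named virtual tumor, e.g. ``solution(1)``."""
    key = name if isinstance(name, str) else f"solution-{name}"
    if key not in SOLUTIONS:
        raise KeyError(f"unknown solution {name!r}")
    return ModelParameters(**{**SOLUTIONS[key], **overrides})


def case(name: str | int, **overrides) -> ModelParameters:
    """Parameter set of a named exploratory case, e.g. ``case(0)``."""
    key = name if isinstance(name, str) else f"case-{name}"
    if key not in CASES:
        raise KeyError(f"unknown case {name!r}")
    return ModelParameters(**{**CASES[key], **overrides})


def radiosensitivity_of(name: str | int, kind: str = "solution") -> tuple[float, float]:
    """(alpha_p, OER) pair calibrated for a named virtual tumor."""
    key = name if isinstance(name, str) else f"{kind}-{name}"
    table = SOLUTION_RADIO if key.startswith("solution") else CASE_RADIO
    return table[key]
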