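"""Tumor definition and equilibrium-composition bootstrap.

Initialising every GC with an arbitrary cell mix produces an artificial
transient (typically an initial volume dip followed by regrowth).  The
bootstrap avoids that: a handful of independent GCs are seeded with a small
number of stem cells whose phase clocks are drawn at random, the cytokinetic
update alone is iterated until the category fractions stabilise, and the
stabilised composition and fitted exponential growth rate then initialise
the actual tumor mesh.  Parameter sets that cannot sustain growth are
reported as a convergence failure rather than producing a tumor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Set, Tuple

import numpy as np

from .cytokinetics import CompartmentState, step_compartments, summarize_state
from .mesh import TumorMesh
from .params import SELF_DIMINISHING, ModelParameters, classify_growth_regime, free_growth_lhs

__all__ = [
    "EquilibriumComposition",
    "TumorGeometry",
    "BootstrapError",
    "bootstrap_equilibrium",
    "build_geometry",
    "init_mesh",
]


class BootstrapError(RuntimeError):
    """The parameter set cannot create/sustain the initial tumor."""


@dataclass
class EquilibriumComposition:
    """Stabilised free-growth composition and kinetics.

    Fractions are percentages; ``gf + diff_frac + g0_frac == 100`` (living
    cells), ``dead_frac`` refers to the total population.  ``growth_rate``
    is per hour; ``doubling_time`` in days satisfies Td = ln2 / (24 rate).
    """

    gf: float
    stem_frac: float
    diff_frac: float
    g0_frac: float
    dead_frac: float
    growth_rate: float
    doubling_time: float
    converged: bool
    equilibrium_day: float
    n_gcs: int
    seed: Optional[int] = None
    #: detailed subclass fractions (category x phase), used to populate GCs
    detail: dict = field(default_factory=dict)


def bootstrap_equilibrium(
    params: ModelParameters,
    n_gcs: int = 10,
    seed_stem_count: float = 100.0,
    rng: Optional[np.random.Generator] = None,
    max_days: int = 3000,
    stability_tol: float = 0.01,
    window_days: int = 30,
    seed_g0_share: Optional[float] = None,
) -> EquilibriumComposition:
    """Grow stem-cell seeds to a stabilised free-growth composition.

    ``n_gcs`` independent GCs each start with ``seed_stem_count`` stem
    cells spread over the cycle phases with randomly drawn clocks (drawing
    differs per GC, which desynchronises them).  Equilibrium is declared
    when the cycling/differentiated/dormant/dead fractions each vary by
    less than ``stability_tol`` (relative) over a sliding ``window_days``
    window; the growth rate is an OLS log-linear fit of total cells over
    that window.

    Raises :class:`BootstrapError` for self-diminishing parameter sets or
    when no equilibrium emerges within ``max_days``.
    """
    lhs = free_growth_lhs(params)
    if classify_growth_regime(lhs) == SELF_DIMINISHING:
        raise BootstrapError(
            f"parameters cannot sustain free growth (self-sustainment LHS = {lhs:.3f} < 0.9); "
            "the initial tumor cannot be created")
    rng = rng or np.random.default_rng(params.rng_seed)
    state = CompartmentState(n_gcs, params)
    if seed_g0_share is None:
        seed_g0_share = 0.0
    state.seed_stem(seed_stem_count, rng, g0_share=seed_g0_share)

    hours = 24 * max_days
    window = 24 * window_days
    totals = np.empty(hours)
    fracs = np.empty((hours, 4))
    eq_at = None
    for t in range(hours):
        step_compartments(state, params, rng if params.stochastic else None)
        cyc = state.cycling().sum()
        g0 = state.dormant().sum()
        diff = state.diff.sum()
        dead = state.dead().sum()
        living = cyc + g0 + diff
        if living <= 0:
            raise BootstrapError("population went extinct during bootstrap")
        totals[t] = living + dead
        fracs[t] = (cyc / living, diff / living, g0 / living,
                    dead / (living + dead))
        # check stability once per simulated day
        if t >= window and (t + 1) % 24 == 0:
            win = fracs[t + 1 - window: t + 1]
            lo, hi = win.min(axis=0), win.max(axis=0)
            mid = 0.5 * (lo + hi)
            rel = np.where(mid > 1e-6, (hi - lo) / np.maximum(mid, 1e-300), 0.0)
            if (rel < stability_tol).all():
                eq_at = t + 1
                break
    if eq_at is None:
        raise BootstrapError(
            f"no equilibrium within {max_days} days (self-sustainment LHS = {lhs:.3f}); "
            "the parameter set is unable to create a stable initial tumor")

    y = np.log(totals[eq_at - window: eq_at])
    rate = float(np.polyfit(np.arange(window), y, 1)[0])
    if rate <= 0:
        raise BootstrapError(
            f"stabilised population is not growing (rate = {rate:.3e} /h)")
    comp = summarize_state(state)
    detail = _composition_detail(state)
    return EquilibriumComposition(
        gf=comp["gf"], stem_frac=comp["stem_frac"], diff_frac=comp["diff_frac"],
        g0_frac=comp["g0_frac"], dead_frac=comp["dead_frac"],
        growth_rate=rate, doubling_time=math.log(2) / rate / 24.0,
        converged=True, equilibrium_day=eq_at / 24.0, n_gcs=n_gcs,
        detail=detail,
    )


def _composition_detail(state: CompartmentState) -> dict:
    """Per-(category, phase) fractions of the total population."""
    total = state.total().sum()
    detail: dict = {"total": total, "phases": {}}
    for ph, name in enumerate(("G1", "S", "G2", "M")):
        arr = state.cycle[ph]
        detail["phases"][name] = arr.sum(axis=(0, 3)) / total   # (ncat, 3)
    if state.hourly_g0:
        detail["G0"] = state.g0_age.sum(axis=(0, 3)) / total
    else:
        detail["G0"] = state.g0.sum(axis=0) / total
    detail["DIFF"] = state.diff.sum() / total
    detail["APO"] = state.apo.sum() / total
    detail["NEC"] = state.nec.sum() / total
    return detail


@dataclass
class TumorGeometry:
    """Either a triaxial ellipsoid (diameters in mm, optional necrotic core
    in GCs) or an explicit voxel mask (set of occupied lattice sites)."""

    tumor_length: Optional[float] = None
    tumor_breadth: Optional[float] = None
    tumor_width: Optional[float] = None
    necrotic_length: Optional[float] = None
    necrotic_breadth: Optional[float] = None
    necrotic_width: Optional[float] = None
    mask: Optional[Set[Tuple[int, int, int]]] = None
    necrotic_mask: Optional[Set[Tuple[int, int, int]]] = None

    def __post_init__(self) -> None:
        if self.mask is None:
            ext = (self.tumor_length, self.tumor_breadth, self.tumor_width)
            if any(e is None or e <= 0 for e in ext):
                raise ValueError("ellipsoid geometry needs three positive diameters")


def build_geometry(
    geom: TumorGeometry,
    voxel_edge: float = 1.0,
    dims: Optional[Tuple[int, int, int]] = None,
) -> Tuple[Set[Tuple[int, int, int]], Set[Tuple[int, int, int]], Tuple[int, int, int]]:
    """Occupied and necrotic lattice sets for a geometry.

    For an ellipsoid, a GC is occupied iff its center ``(i + 0.5) edge``
    lies inside the ellipsoid with semi-axes of half the given diameters,
    centered in the returned lattice box.  Returns (occupied, necrotic,
    dims).
    """
    if geom.mask is not None:
        occupied = {tuple(map(int, c)) for c in geom.mask}
        necrotic = {tuple(map(int, c)) for c in (geom.necrotic_mask or set())}
        if not necrotic <= occupied:
            raise ValueError("necrotic core must lie inside the tumor mask")
        if dims is None:
            m = np.array(list(occupied))
            dims = tuple(int(v) + 1 for v in m.max(axis=0))
        for c in occupied:
            if not all(0 <= v < d for v, d in zip(c, dims)):
                raise ValueError(f"mask voxel {c} outside mesh dims {dims}")
        return occupied, necrotic, dims

    semi = np.array([geom.tumor_length, geom.tumor_breadth, geom.tumor_width]) / 2.0
    if (semi * 2 < voxel_edge).any():
        raise ValueError("tumor extents must be at least one voxel edge")
    n_gc = np.ceil(semi * 2 / voxel_edge).astype(int) + 2   # margin of 1 GC
    if dims is None:
        dims = tuple(int(v) for v in n_gc)
    center = np.array(dims) * voxel_edge / 2.0
    occupied = set()
    for i in range(dims[0]):
        for j in range(dims[1]):
            for k in range(dims[2]):
                c = (np.array([i, j, k]) + 0.5) * voxel_edge
                if (((c - center) / semi) ** 2).sum() <= 1.0:
                    occupied.add((i, j, k))
    necrotic: Set[Tuple[int, int, int]] = set()
    if geom.necrotic_length:
        nsemi = np.array([geom.necrotic_length, geom.necrotic_breadth,
                          geom.necrotic_width]) / 2.0 * voxel_edge
        for (i, j, k) in occupied:
            c = (np.array([i, j, k]) + 0.5) * voxel_edge
            if (((c - center) / nsemi) ** 2).sum() <= 1.0:
                necrotic.add((i, j, k))
    return occupied, necrotic, dims


def init_mesh(
    mesh: TumorMesh,
    eq: EquilibriumComposition,
    occupied: Set[Tuple[int, int, int]],
    rng: Optional[np.random.Generator] = None,
    necrotic: Optional[Set[Tuple[int, int, int]]] = None,
) -> TumorMesh:
    """Populate the occupied GCs with NBC cells at the equilibrium mix.

    Cycling cells are spread over G1/S/G2/M proportionally to the phase
    durations; each subclass's elapsed-time clock is drawn uniformly within
    the phase by the seeded generator (independently per GC).
    """
    if not eq.converged:
        raise ValueError("equilibrium composition did not converge")
    rng = rng or mesh.rng
    params = mesh.params
    nbc = mesh.NBC
    detail = eq.detail
    total_ref = detail["total"]
    necrotic = necrotic or set()

    stochastic = params.stochastic
    for coord in sorted(occupied):
        row = mesh.ensure_row(
            coord, region="necrotic" if coord in necrotic else "proliferating")
        st = mesh.state

        def place(arr_row, amt):
            """Spread a cohort over the residence slots: uniformly in the
            deterministic mode (the continuum limit of per-cell uniform
            clock draws), multinomially in the Monte-Carlo mode."""
            slots = arr_row.shape[-1]
            if stochastic:
                flat = rng.multinomial(int(round(amt)), np.full(slots, 1 / slots))
                arr_row[...] += flat
            else:
                arr_row[...] += amt / slots

        for ph, name in enumerate(("G1", "S", "G2", "M")):
            frac = detail["phases"][name]              # (ncat, 3)
            amt = nbc * frac
            slots = st.cycle[ph].shape[-1]
            st.cycle[ph][row] += amt[:, :, None] / slots
        g0_amt = nbc * detail["G0"]
        if st.hourly_g0:
            st.g0_age[row] += g0_amt[:, :, None] / st.g0_age.shape[-1]
        else:
            st.g0[row] += g0_amt
        st.diff[row] += nbc * detail["DIFF"]
        place(st.apo[row], nbc * detail["APO"])
        place(st.nec[row], nbc * detail["NEC"])
    return mesh
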