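"""Hourly cytokinetic update of the tumor cell populations.

Every geometrical cell (GC) of the mesh holds a :class:`CompartmentState`
row: cell counts partitioned by category (stem / LIMP with k remaining
mitoses / terminally differentiated / apoptotic / necrotic), cell-cycle
phase (G1, S, G2, M, G0) and radiation hit status (unhit, or lethally hit
with two or one mitoses left before necrotic death).  The update applied
each hour is:

1. spontaneous apoptosis drains every living stem/LIMP subclass (cycling
   and dormant, hit or not) at rate ``R_A``; differentiated cells drain at
   ``R_ADiff`` (apoptosis) and ``R_NDiff`` (necrosis);
2. the apoptotic and necrotic pools age and entries older than ``T_A`` /
   ``T_N`` leave the tumor (lysis products removed);
3. dormancies end (see ``g0_exit`` on :class:`~radiosim.params.ModelParameters`),
   re-entrants joining G1 and the remainder entering necrosis;
4. cycle phases advance along hourly delay lines; cohorts whose residence
   expired transition G1->S->G2->M, and cells completing M divide;
5. newborn stem/LIMP siblings are routed together either into G1 or (with
   probability ``P_sleep``) into G0; lethally hit cells cycle "rudimentarily"
   — their offspring skip G0 and, after the second post-hit mitosis, the
   whole progeny joins the necrotic pool.

Counts are real-valued fractional flows by default; with
``params.stochastic`` the same update draws integer binomial flows from a
seeded generator.

Fractional phase durations are realised with the exact mean residence:
entrants split between ``floor(T)`` and ``ceil(T)`` hour residences so the
cohort mean equals ``T``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .params import ModelParameters

__all__ = [
    "CompartmentState",
    "StepDeltas",
    "step_compartments",
    "mitosis_outcome",
    "summarize_state",
    "N_HIT",
    "UNHIT",
    "HIT2",
    "HIT1",
]

# hit-status axis
UNHIT, HIT2, HIT1 = 0, 1, 2
N_HIT = 3
# phase order along the cycle
PHASES = ("G1", "S", "G2", "M")


def _entry_split(T: float, slots: int) -> list[tuple[int, float]]:
    """(entry index, weight) pairs realising mean residence T in a delay line.

    A cohort placed at index ``i`` exits after ``slots - i`` shifts.
    """
    lo, hi = math.floor(T), math.ceil(T)
    lo = max(lo, 1)
    if hi <= lo:
        return [(slots - lo, 1.0)]
    f = T - math.floor(T)
    return [(slots - hi, f), (slots - lo, 1.0 - f)]


class CompartmentState:
    """Vectorised per-GC cell bookkeeping (leading axis = GC row).

    Array layout, with ``ncat = 1 + N_LIMP`` (index 0 = stem, index k =
    LIMP with k remaining mitoses) and 3 hit states:

    - ``cycle[ph]`` : (n, ncat, 3, slots_ph) hourly delay line of phase ph
    - ``g0``        : (n, ncat, 3) dormant pool  (sojourn mode)
    - ``g0_age``    : (n, ncat, 3, ceil(T_G0)) age-structured dormant pool
                      (hourly-exit mode only)
    - ``diff``      : (n,) terminally differentiated cells
    - ``apo``/``nec``: (n, ceil(T_A)) / (n, ceil(T_N)) dead-cell age rings
    """

    def __init__(self, n: int, params: ModelParameters):
        self.params = params
        #: bumped on every mutation; lets callers cache derived aggregates
        self.version = 0
        self.ncat = 1 + int(params.N_LIMP)
        d_stem = params.durations().as_tuple()
        d_limp = params.durations(limp=True).as_tuple()
        self.slots = [max(math.ceil(max(ds, dl)), 1)
                      for ds, dl in zip(d_stem, d_limp)]
        # per phase: entry plan for the stem class and the LIMP classes
        self.entry_stem = [_entry_split(d, s) for d, s in zip(d_stem, self.slots)]
        self.entry_limp = [_entry_split(d, s) for d, s in zip(d_limp, self.slots)]
        self.cycle: List[np.ndarray] = [
            np.zeros((n, self.ncat, N_HIT, s)) for s in self.slots
        ]
        self.hourly_g0 = params.g0_exit == "hourly"
        if self.hourly_g0:
            g0_slots = max(math.ceil(max(params.T_G0, params.T_G0_limp)), 1)
            self.g0_age = np.zeros((n, self.ncat, N_HIT, g0_slots))
        else:
            self.g0 = np.zeros((n, self.ncat, N_HIT))
        self.diff = np.zeros(n)
        self.apo = np.zeros((n, max(math.ceil(params.T_A), 1)))
        self.nec = np.zeros((n, max(math.ceil(params.T_N), 1)))

    # -- construction -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.diff.shape[0]

    def copy(self) -> "CompartmentState":
        new = CompartmentState.__new__(CompartmentState)
        new.__dict__.update(self.__dict__)
        new.cycle = [a.copy() for a in self.cycle]
        if self.hourly_g0:
            new.g0_age = self.g0_age.copy()
        else:
            new.g0 = self.g0.copy()
        new.diff = self.diff.copy()
        new.apo = self.apo.copy()
        new.nec = self.nec.copy()
        return new

    def seed_stem(self, count: float, rng: np.random.Generator,
                  g0_share: float = 0.0) -> None:
        """Seed every GC with stem cells spread over the cycle phases.

        Cells are distributed across G1/S/G2/M proportionally to the phase
        durations; within a phase the time already spent is drawn uniformly
        by placing the cohort at a random delay-line position (Monte-Carlo
        time initialisation, independent per GC).  ``g0_share`` optionally
        seeds that fraction directly into G0.
        """
        durs = self.params.durations().as_tuple()
        total = sum(durs)
        cycling = count * (1.0 - g0_share)
        if g0_share > 0:
            if self.hourly_g0:
                ages = rng.integers(0, self.g0_age.shape[-1], size=self.n)
                for g, a in enumerate(ages):
                    self.g0_age[g, 0, UNHIT, a] += count * g0_share
            else:
                self.g0[:, 0, UNHIT] += count * g0_share
        for ph, (dur, slots) in enumerate(zip(durs, self.slots)):
            amt = cycling * dur / total
            # uniform random position = uniform elapsed time in the phase
            pos = rng.integers(0, slots, size=self.n)
            for g in range(self.n):
                self.cycle[ph][g, 0, UNHIT, pos[g]] += amt

    # -- aggregates ----------------------------------------------------------
    def cycling(self) -> np.ndarray:
        return sum(a.sum(axis=(1, 2, 3)) for a in self.cycle)

    def dormant(self) -> np.ndarray:
        if self.hourly_g0:
            return self.g0_age.sum(axis=(1, 2, 3))
        return self.g0.sum(axis=(1, 2))

    def stem(self) -> np.ndarray:
        s = sum(a[:, 0].sum(axis=(1, 2)) for a in self.cycle)
        if self.hourly_g0:
            return s + self.g0_age[:, 0].sum(axis=(1, 2))
        return s + self.g0[:, 0].sum(axis=1)

    def limp(self) -> np.ndarray:
        s = sum(a[:, 1:].sum(axis=(1, 2, 3)) for a in self.cycle)
        if self.hourly_g0:
            return s + self.g0_age[:, 1:].sum(axis=(1, 2, 3))
        return s + self.g0[:, 1:].sum(axis=(1, 2))

    def living(self) -> np.ndarray:
        return self.cycling() + self.dormant() + self.diff

    def dead(self) -> np.ndarray:
        return self.apo.sum(axis=1) + self.nec.sum(axis=1)

    def total(self) -> np.ndarray:
        return self.living() + self.dead()

    # -- morphology support ---------------------------------------------------
    def _row_arrays(self):
        arrs = list(self.cycle) + [self.apo, self.nec]
        if self.hourly_g0:
            arrs.append(self.g0_age)
        else:
            arrs.append(self.g0)
        return arrs

    def transfer(self, src: int, dst: int, amount: float) -> None:
        """Move ``amount`` cells from GC row src to dst, proportionally
        drawn from every subclass of the source."""
        tot = float(self.total()[src])
        if amount <= 0 or tot <= 0:
            return
        f = min(amount / tot, 1.0)
        self.version += 1
        for a in self._row_arrays():
            moved = a[src] * f
            a[src] -= moved
            a[dst] += moved
        moved = self.diff[src] * f
        self.diff[src] -= moved
        self.diff[dst] += moved

    def move_all(self, src: int, dst: int) -> None:
        self.version += 1
        for a in self._row_arrays():
            a[dst] += a[src]
            a[src] = 0.0
        self.diff[dst] += self.diff[src]
        self.diff[src] = 0.0

    def append_rows(self, k: int) -> None:
        """Grow the state by k empty GC rows."""
        self.version += 1
        def grow(a):
            pad = np.zeros((k,) + a.shape[1:])
            return np.concatenate([a, pad], axis=0)
        self.cycle = [grow(a) for a in self.cycle]
        if self.hourly_g0:
            self.g0_age = grow(self.g0_age)
        else:
            self.g0 = grow(self.g0)
        self.diff = grow(self.diff)
        self.apo = grow(self.apo)
        self.nec = grow(self.nec)


@dataclass
class StepDeltas:
    """Per-GC audit trail of one hourly step (conservation check support).

    ``births`` is the net gain from mitosis (one per division).  The exact
    identity ``total_after = total_before + births - cleared_apoptotic -
    cleared_necrotic`` holds every step.
    """

    births: np.ndarray
    apoptotic_deaths: np.ndarray
    necrotic_deaths: np.ndarray
    cleared_apoptotic: np.ndarray
    cleared_necrotic: np.ndarray
    g0_reentries: np.ndarray
    differentiations: np.ndarray


def _binom(rng: np.random.Generator, n: np.ndarray, p: float) -> np.ndarray:
    """Binomial draw tolerant of float count arrays."""
    return rng.binomial(np.round(n).astype(np.int64), min(max(p, 0.0), 1.0)).astype(float)


def step_compartments(
    state: CompartmentState,
    params: Optional[ModelParameters] = None,
    rng: Optional[np.random.Generator] = None,
) -> StepDeltas:
    """Advance every GC of ``state`` by one hour, in place."""
    p = params or state.params
    state.version += 1
    stochastic = p.stochastic
    if stochastic and rng is None:
        raise ValueError("stochastic mode requires an rng")

    total_before = state.total()

    # --- 1. spontaneous death ------------------------------------------------
    if stochastic:
        ap_live = np.zeros(state.n)
        for a in state.cycle:
            d = _binom(rng, a, p.R_A)
            a -= d
            ap_live += d.sum(axis=(1, 2, 3))
        if state.hourly_g0:
            d = _binom(rng, state.g0_age, p.R_A)
            state.g0_age -= d
            ap_live += d.sum(axis=(1, 2, 3))
        else:
            d = _binom(rng, state.g0, p.R_A)
            state.g0 -= d
            ap_live += d.sum(axis=(1, 2))
        ap_diff = _binom(rng, state.diff, p.R_ADiff)
        nec_diff = _binom(rng, state.diff - ap_diff, p.R_NDiff)
    else:
        ap_live = p.R_A * (state.cycling() + state.dormant())
        for a in state.cycle:
            a *= (1.0 - p.R_A)
        if state.hourly_g0:
            state.g0_age *= (1.0 - p.R_A)
        else:
            state.g0 *= (1.0 - p.R_A)
        ap_diff = p.R_ADiff * state.diff
        nec_diff = p.R_NDiff * state.diff
    state.diff -= ap_diff + nec_diff

    # --- 2. dead-pool ageing and clearance ------------------------------------
    cleared_a = state.apo[:, -1].copy()
    cleared_n = state.nec[:, -1].copy()
    state.apo[:, 1:] = state.apo[:, :-1]
    state.apo[:, 0] = ap_live + ap_diff
    state.nec[:, 1:] = state.nec[:, :-1]
    nec_in = nec_diff

    # --- 3. dormancy endings ---------------------------------------------------
    if state.hourly_g0:
        # literal reading: a fraction P_G0toG1 of the pool re-enters each hour;
        # survivors necrose when their dormancy reaches the T_G0 wall
        if stochastic:
            exits = _binom(rng, state.g0_age, p.P_G0toG1)
        else:
            exits = p.P_G0toG1 * state.g0_age
        state.g0_age -= exits
        reenter = exits.sum(axis=3)                      # (n, ncat, 3)
        wall = state.g0_age[..., -1].copy()
        nec_in = nec_in + wall.sum(axis=(1, 2))
        state.g0_age[..., 1:] = state.g0_age[..., :-1]
        state.g0_age[..., 0] = 0.0
        nec_from_g0 = wall.sum(axis=(1, 2))
    else:
        # dormancy ends at hazard 1/T_G0; of the endings, P_G0toG1 re-enter G1
        # and the remainder dies through necrosis
        haz = np.empty(state.ncat)
        haz[0] = 1.0 / p.T_G0
        haz[1:] = 1.0 / p.T_G0_limp
        if stochastic:
            ended = np.stack(
                [_binom(rng, state.g0[:, c], haz[c]) for c in range(state.ncat)],
                axis=1,
            )
            reenter = _binom(rng, ended, p.P_G0toG1)
        else:
            ended = state.g0 * haz[None, :, None]
            reenter = p.P_G0toG1 * ended
        state.g0 -= ended
        to_nec = (ended - reenter).sum(axis=(1, 2))
        nec_in = nec_in + to_nec
        nec_from_g0 = to_nec

    # --- 4. cycle advance and mitosis ------------------------------------------
    outs = []
    for a in state.cycle:
        outs.append(a[..., -1].copy())
        a[..., 1:] = a[..., :-1]
        a[..., 0] = 0.0
    m_done = outs[3]                                     # (n, ncat, 3)
    divisions = m_done.sum(axis=(1, 2))

    newborn = np.zeros((state.n, state.ncat, N_HIT))
    diff_new = np.zeros(state.n)
    nec_mitotic = np.zeros(state.n)

    # unhit lineage-aware mitosis
    stem_u = m_done[:, 0, UNHIT]
    if stochastic:
        n_sym = _binom(rng, stem_u, p.P_sym)
    else:
        n_sym = p.P_sym * stem_u
    newborn[:, 0, UNHIT] += 2.0 * n_sym + (stem_u - n_sym)
    newborn[:, p.N_LIMP, UNHIT] += stem_u - n_sym
    limp1 = m_done[:, 1, UNHIT]
    diff_new += 2.0 * limp1
    for k in range(2, state.ncat):
        newborn[:, k - 1, UNHIT] += 2.0 * m_done[:, k, UNHIT]

    # rudimentary cycling of lethally hit cells: category is retained, the
    # second post-hit mitosis sends the whole progeny to necrosis
    newborn[:, :, HIT1] += 2.0 * m_done[:, :, HIT2]
    nec_mitotic += 2.0 * m_done[:, :, HIT1].sum(axis=1)
    nec_in = nec_in + nec_mitotic
    state.nec[:, 0] = nec_in

    # --- 5. newborn routing -------------------------------------------------
    state.diff += diff_new
    unhit_newborn = newborn[:, :, UNHIT]
    if stochastic:
        # sibling co-routing: the sleep decision is per division (both
        # daughters share it), so draw on division counts and double
        to_g0 = 2.0 * _binom(rng, unhit_newborn / 2.0, p.P_sleep)
        to_g0 = np.minimum(to_g0, unhit_newborn)
    else:
        to_g0 = p.P_sleep * unhit_newborn
    to_g1 = newborn.copy()
    to_g1[:, :, UNHIT] -= to_g0
    # dormancy re-entrants (hit ones resume the rudimentary cycle)
    to_g1 += reenter
    if state.hourly_g0:
        state.g0_age[:, :, UNHIT, 0] += to_g0
    else:
        state.g0[:, :, UNHIT] += to_g0

    def _enter(ph: int, amt: np.ndarray) -> None:
        """Place entrants (n, ncat, 3) into phase ph with exact mean residence."""
        arr = state.cycle[ph]
        plan_s, plan_l = state.entry_stem[ph], state.entry_limp[ph]
        for sl, plan in ((slice(0, 1), plan_s), (slice(1, None), plan_l)):
            sub = amt[:, sl]
            if stochastic and len(plan) > 1:
                (i_hi, f), (i_lo, _) = plan
                hi = _binom(rng, sub, f)
                arr[:, sl, :, i_hi] += hi
                arr[:, sl, :, i_lo] += sub - hi
            else:
                for idx, w in plan:
                    arr[:, sl, :, idx] += w * sub

    _enter(0, to_g1)          # newborns + dormancy re-entrants -> G1
    _enter(1, outs[0])        # G1 -> S
    _enter(2, outs[1])        # S -> G2
    _enter(3, outs[2])        # G2 -> M

    deltas = StepDeltas(
        births=divisions,
        apoptotic_deaths=ap_live + ap_diff,
        necrotic_deaths=nec_diff + nec_from_g0 + nec_mitotic,
        cleared_apoptotic=cleared_a,
        cleared_necrotic=cleared_n,
        g0_reentries=reenter.sum(axis=(1, 2)),
        differentiations=diff_new,
    )
    # conservation must hold exactly (within float rounding)
    total_after = state.total()
    expected = total_before + deltas.births - cleared_a - cleared_n
    if not np.allclose(total_after, expected, rtol=1e-9, atol=1e-6):
        raise RuntimeError("cell-number conservation violated in step")
    if any((a < -1e-9).any() for a in state._row_arrays()) or (state.diff < -1e-9).any():
        raise RuntimeError("negative compartment count")
    return deltas


def mitosis_outcome(
    category: str,
    count: float,
    hit_state: int,
    params: ModelParameters,
    rng: Optional[np.random.Generator] = None,
    limp_k: int = 0,
) -> dict:
    """Offspring allocation of one dividing subclass (reference semantics).

    Returns a dict with keys among ``stem``, ``limp``, ``diff``, ``necrotic``
    and the G0/G1 routing of the stem/LIMP newborns (``to_g0``, ``to_g1``).
    ``category`` is ``"STEM"`` or ``"LIMP"`` (with ``limp_k`` remaining
    mitoses).
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    out: dict = {"stem": 0.0, "limp": {}, "diff": 0.0, "necrotic": 0.0,
                 "to_g0": 0.0, "to_g1": 0.0}
    if hit_state == HIT1:
        out["necrotic"] = 2.0 * count
        return out
    if category == "STEM":
        if params.stochastic:
            n_sym = float(_binom(rng, np.asarray(count, dtype=float), params.P_sym))
        else:
            n_sym = params.P_sym * count
        out["stem"] = 2.0 * n_sym + (count - n_sym)
        if count - n_sym > 0:
            out["limp"][params.N_LIMP] = count - n_sym
        newborn = out["stem"] + (count - n_sym)
    elif category == "LIMP":
        if limp_k < 1:
            raise ValueError("limp_k must be >= 1")
        if limp_k == 1 and hit_state == UNHIT:
            out["diff"] = 2.0 * count
            return out
        out["limp"][limp_k if hit_state != UNHIT else limp_k - 1] = 2.0 * count
        newborn = 2.0 * count
    else:
        raise ValueError(f"unknown category {category!r}")
    if hit_state == UNHIT:
        if params.stochastic:
            slept = 2.0 * float(_binom(rng, np.asarray(newborn / 2.0), params.P_sleep))
        else:
            slept = params.P_sleep * newborn
        out["to_g0"] = slept
        out["to_g1"] = newborn - slept
    else:
        out["to_g1"] = newborn   # hit offspring skip dormancy
    return out


def summarize_state(state: CompartmentState, per_gc: bool = False) -> dict:
    """Composition fractions of the tumor (percentages).

    ``gf + diff_frac + g0_frac == 100`` exactly (fractions of living cells);
    ``dead_frac`` is referred to the total (living + dead) population.
    """
    cyc = state.cycling()
    g0 = state.dormant()
    diff = state.diff.copy()
    dead = state.dead()
    stem = state.stem()
    if not per_gc:
        cyc, g0, diff, dead, stem = (x.sum() for x in (cyc, g0, diff, dead, stem))
    living = cyc + g0 + diff
    total = living + dead
    if np.ndim(total) == 0:
        if total <= 0:
            raise ValueError("empty state has no composition")
        if living <= 0:
            raise ValueError("no living cells")
    return {
        "gf": 100.0 * cyc / living,
        "stem_frac": 100.0 * stem / living,
        "diff_frac": 100.0 * diff / living,
        "g0_frac": 100.0 * g0 / living,
        "dead_frac": 100.0 * dead / total,
    }
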