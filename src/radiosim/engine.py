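"""Hourly simulation loop: irradiation, cytokinetics, morphology, recording.

Each simulated hour consists of (a) marking lethally hit cells if a
radiotherapy fraction falls in this hour — marking happens at the
administration instant, before the biological update of the same hour;
(b) the first mesh scan (cytokinetic update of every GC); (c) the second
mesh scan (mechanical rebalancing and cohesion repair) when spatial
evolution is enabled; and (d) recording.  With spatial evolution disabled
the engine degenerates to a well-mixed, lattice-free ("0-D") mode in which
the tumor volume is total cells divided by the cell density — the mode the
bootstrap and the calibration runner use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

from .cytokinetics import step_compartments, summarize_state
from .mesh import TumorMesh, second_scan, tumor_volume
from .radiobiology import Radiosensitivity, RTSchedule, apply_irradiation

__all__ = ["SimulationOutput", "run_simulation", "volume_reduction"]


@dataclass
class SimulationOutput:
    """Recorded time series plus the event log of a run."""

    frame: pd.DataFrame
    events: List[dict] = field(default_factory=list)

    def volume_at(self, t_hours: float) -> float:
        f = self.frame
        idx = (f["t_hours"] - t_hours).abs().idxmin()
        return float(f.loc[idx, "volume_mm3"])


_COLUMNS = [
    "t_hours", "volume_mm3", "total", "stem", "limp", "diff",
    "g0", "apoptotic", "necrotic", "gf", "stem_frac", "diff_frac",
    "g0_frac", "dead_frac", "occupied_gcs",
]


def _record(mesh: TumorMesh, t: float, spatial: bool) -> list:
    st = mesh.state
    stem = st.stem().sum()
    limp = st.limp().sum()
    diff = st.diff.sum()
    g0 = st.dormant().sum()
    apo = st.apo.sum()
    nec = st.nec.sum()
    total = stem + limp + diff + apo + nec
    living = stem + limp + diff
    cyc = st.cycling().sum()
    occ = len(mesh.occupied_rows()) if spatial else int(total > 0)
    vol = tumor_volume(mesh) if spatial else total / mesh.params.cell_density
    return [t, vol, total, stem, limp, diff, g0, apo, nec,
            100 * cyc / living if living else 0.0,
            100 * stem / living if living else 0.0,
            100 * diff / living if living else 0.0,
            100 * g0 / living if living else 0.0,
            100 * (apo + nec) / total if total else 0.0,
            occ]


def run_simulation(
    mesh: TumorMesh,
    rs: Optional[Radiosensitivity] = None,
    schedule: Optional[RTSchedule] = None,
    t_end_hours: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    record_stride: int = 24,
) -> SimulationOutput:
    """Run the initialised mesh forward and record the time series.

    ``mode`` 1 (free growth) requires an empty schedule; ``mode`` 2 applies
    every (time, dose) event of ``schedule`` to all occupied GCs.  Recording
    happens at t = 0 and then every ``record_stride`` hours.
    """
    params = mesh.params
    schedule = schedule or RTSchedule()
    if params.mode == 1 and len(schedule):
        raise ValueError("mode 1 (free growth) cannot take a radiotherapy schedule")
    if len(schedule) and rs is None:
        raise ValueError("a schedule requires radiosensitivity coefficients")
    rng = rng or mesh.rng
    hours = int(t_end_hours if t_end_hours is not None
                else round(24 * params.execution_time))
    spatial = params.spatial_evolution

    rows = [_record(mesh, 0.0, spatial)]
    events: List[dict] = []
    for t in range(hours):
        for dose in schedule.doses_in_hour(t):
            kills = apply_irradiation(mesh.state, dose, rs, rng)
            events.append({
                "t_hours": t, "event": "irradiation", "dose_Gy": dose,
                "hit_cells": float(sum(v.sum() for v in kills.values())),
            })
        step_compartments(mesh.state, params, rng if params.stochastic else None)
        if spatial:
            n_fallback = len(mesh.fallback_log)
            second_scan(mesh)
            for e in mesh.fallback_log[n_fallback:]:
                events.append({"t_hours": t, **e})
        if (t + 1) % record_stride == 0 or t == hours - 1:
            rows.append(_record(mesh, float(t + 1), spatial))
    frame = pd.DataFrame(rows, columns=_COLUMNS)
    return SimulationOutput(frame=frame, events=events)


def volume_reduction(output: SimulationOutput, t0: float, t1: float) -> float:
    """Percent volume reduction between two recorded times.

    Positive for shrinkage; negative for (re)growth.
    """
    if not t0 < t1:
        raise ValueError("t0 must precede t1")
    v0 = output.volume_at(t0)
    v1 = output.volume_at(t1)
    if v0 <= 0:
        raise ValueError("volume at t0 is zero")
    return 100.0 * (v0 - v1) / v0
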