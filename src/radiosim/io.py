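"""Configuration files, mask and schedule formats, fixture generation.

Configs are flat YAML (or JSON) key/value files using the canonical input
parameter symbols (T_c, T_G0, ..., P_sym, N_LIMP, cell_density, voxel_edge,
margin_percent, color_criterion, mode, spatial_evolution, execution_time,
rng_seed) plus geometry, radiotherapy and output keys.  Masks are either
NIfTI label volumes (0 background, 1 tumor, 2 necrotic) or a plain CSV
voxel list ``x,y,z,label`` with 0-based indices, x fastest.  Schedules are
CSV with columns ``time_hours,dose_Gy``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .initialization import TumorGeometry
from .params import ModelParameters
from .radiobiology import RTSchedule, make_schedule
from . import presets

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_mask",
    "write_mask",
    "read_schedule",
    "write_schedule",
    "generate_fixture",
]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_GEOM_KEYS = {"tumor_length", "tumor_breadth", "tumor_width",
              "necrotic_length", "necrotic_breadth", "necrotic_width",
              "x_dim", "y_dim", "z_dim", "input_image", "image_filename"}
_RADIO_KEYS = {"alpha", "beta", "alpha_beta_ratio", "OER", "cell_kill_factor",
               "schedule_file", "n_fractions", "dose_per_fraction",
               "start_day", "weekday_time", "skip_weekends"}
_MISC_KEYS = {"output_directory", "record_stride"}
_ALL_KEYS = _PARAM_KEYS | _GEOM_KEYS | _RADIO_KEYS | _MISC_KEYS


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulation run."""

    params: ModelParameters
    geometry: Optional[TumorGeometry] = None
    dims: Optional[Tuple[int, int, int]] = None
    image_filename: Optional[str] = None
    alpha: Optional[float] = None
    alpha_beta_ratio: float = presets.ALPHA_BETA_RATIO
    OER: float = 1.0
    cell_kill_factor: float = 1.0
    schedule_file: Optional[str] = None
    n_fractions: int = 0
    dose_per_fraction: float = 2.0
    start_day: int = 0
    weekday_time: float = 8.0
    skip_weekends: bool = True
    output_directory: str = "."
    record_stride: int = 24

    def schedule(self, base: Optional[Path] = None) -> RTSchedule:
        if self.schedule_file:
            path = Path(self.schedule_file)
            if base and not path.is_absolute():
                path = base / path
            return read_schedule(path)
        if self.n_fractions:
            return make_schedule(self.start_day, self.n_fractions,
                                 self.dose_per_fraction, self.weekday_time,
                                 self.skip_weekends)
        return RTSchedule()

    def to_dict(self) -> dict:
        d = {}
        for k, v in self.params.to_dict().items():
            d[k] = v
        if self.geometry is not None and self.geometry.mask is None:
            for k in ("tumor_length", "tumor_breadth", "tumor_width",
                      "necrotic_length", "necrotic_breadth", "necrotic_width"):
                v = getattr(self.geometry, k)
                if v is not None:
                    d[k] = v
        if self.dims is not None:
            d["x_dim"], d["y_dim"], d["z_dim"] = self.dims
        d["input_image"] = self.image_filename is not None
        if self.image_filename:
            d["image_filename"] = self.image_filename
        for k in ("alpha", "alpha_beta_ratio", "OER", "cell_kill_factor",
                  "schedule_file", "n_fractions", "dose_per_fraction",
                  "start_day", "weekday_time", "skip_weekends",
                  "output_directory", "record_stride"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


class ConfigError(ValueError):
    pass


def load_config(path: str | Path) -> RunConfig:
    """Load and schema-validate a YAML/JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    unknown = set(data) - _ALL_KEYS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    missing = {"T_c"} - set(data)
    if missing:
        raise ConfigError(f"{path}: missing required keys {sorted(missing)}")

    pkw = {}
    for k in _PARAM_KEYS & set(data):
        v = data[k]
        f = {f.name: f for f in dataclasses.fields(ModelParameters)}[k]
        try:
            if k in ("N_LIMP", "mode", "rng_seed"):
                v = int(v)
            elif k == "spatial_evolution":
                v = bool(v)
            elif k == "stochastic":
                v = bool(v)
            elif k == "g0_exit":
                v = str(v)
            else:
                v = float(v)
        except (TypeError, ValueError):
            raise ConfigError(f"{path}: key {k} has invalid value {v!r}")
        pkw[k] = v
    params = ModelParameters(**pkw)

    geometry = None
    if data.get("input_image"):
        if "image_filename" not in data:
            raise ConfigError(f"{path}: input_image set but image_filename missing")
    elif "tumor_length" in data:
        geometry = TumorGeometry(
            tumor_length=float(data["tumor_length"]),
            tumor_breadth=float(data.get("tumor_breadth", data["tumor_length"])),
            tumor_width=float(data.get("tumor_width", data["tumor_length"])),
            necrotic_length=data.get("necrotic_length"),
            necrotic_breadth=data.get("necrotic_breadth"),
            necrotic_width=data.get("necrotic_width"),
        )
    dims = None
    if {"x_dim", "y_dim", "z_dim"} <= set(data):
        dims = (int(data["x_dim"]), int(data["y_dim"]), int(data["z_dim"]))
    kw = {}
    for k in ("alpha", "alpha_beta_ratio", "OER", "cell_kill_factor",
              "dose_per_fraction", "weekday_time"):
        if k in data:
            kw[k] = float(data[k])
    for k in ("n_fractions", "start_day", "record_stride"):
        if k in data:
            kw[k] = int(data[k])
    for k in ("schedule_file", "output_directory"):
        if k in data:
            kw[k] = str(data[k])
    if "skip_weekends" in data:
        kw["skip_weekends"] = bool(data["skip_weekends"])
    return RunConfig(params=params, geometry=geometry, dims=dims,
                     image_filename=data.get("image_filename"), **kw)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = cfg.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> Tuple[Set[tuple], Set[tuple], Tuple[int, int, int]]:
    """Read a label mask; returns (tumor voxels, necrotic voxels, dims)."""
    path = Path(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path)
        need = {"x", "y", "z", "label"}
        if not need <= set(df.columns):
            raise ConfigError(f"{path}: voxel list needs columns {sorted(need)}")
        tumor = {(int(r.x), int(r.y), int(r.z)) for r in df.itertuples() if r.label >= 1}
        nec = {(int(r.x), int(r.y), int(r.z)) for r in df.itertuples() if r.label == 2}
        dims = tuple(int(df[c].max()) + 1 for c in ("x", "y", "z"))
        return tumor, nec, dims
    import nibabel as nib
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    tumor = {tuple(map(int, c)) for c in np.argwhere(vol >= 1)}
    nec = {tuple(map(int, c)) for c in np.argwhere(vol == 2)}
    return tumor, nec, vol.shape


def write_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write a label volume as NIfTI or CSV voxel list, by extension."""
    path = Path(path)
    if path.suffix == ".csv":
        xs, ys, zs = np.nonzero(labels)
        df = pd.DataFrame({"x": xs, "y": ys, "z": zs,
                           "label": labels[xs, ys, zs]})
        df.to_csv(path, index=False)
        return
    import nibabel as nib
    nib.save(nib.Nifti1Image(labels.astype(np.int16), np.eye(4)), str(path))


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def read_schedule(path: str | Path) -> RTSchedule:
    df = pd.read_csv(path)
    if not {"time_hours", "dose_Gy"} <= set(df.columns):
        raise ConfigError(f"{path}: schedule needs columns time_hours,dose_Gy")
    events = [(float(t), float(d)) for t, d in
              sorted(zip(df["time_hours"], df["dose_Gy"]))]
    return RTSchedule(events=events)


def write_schedule(schedule: RTSchedule, path: str | Path) -> None:
    pd.DataFrame(schedule.events, columns=["time_hours", "dose_Gy"]).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def generate_fixture(kind: str, outdir: str | Path, seed: int = 0,
                     solution: str | int = 1, diameters: tuple = (10.0, 10.0, 10.0),
                     n_fractions: int = 30, dose: float = 2.0) -> dict:
    """Emit a runnable synthetic configuration (mask + schedule + params).

    ``ellipsoid-patient`` mimics an imaging-derived case: an ellipsoidal
    tumor mask, a weekday fractionation schedule and a parameter file
    prefilled from a named virtual-tumor solution.  ``toy-cube`` is a
    minimal cubic mask for smoke tests.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    if kind == "ellipsoid-patient":
        params = presets.solution(solution, rng_seed=int(rng.integers(2**31)),
                                  mode=2)
        alpha, oer = presets.radiosensitivity_of(
            solution if isinstance(solution, str) else f"solution-{solution}")
        geometry = TumorGeometry(*diameters)
        sched = make_schedule(0, n_fractions, dose, 8.0, True)
        cfg = RunConfig(params=params, geometry=geometry, alpha=alpha,
                        OER=oer, schedule_file="schedule.csv")
        write_schedule(sched, outdir / "schedule.csv")
        save_config(cfg, outdir / "config.yaml")
        return {"config": outdir / "config.yaml",
                "schedule": outdir / "schedule.csv"}
    if kind == "toy-cube":
        side = 3
        labels = np.zeros((side + 2,) * 3, dtype=np.int16)
        labels[1:side + 1, 1:side + 1, 1:side + 1] = 1
        write_mask(outdir / "mask.csv", labels)
        params = presets.case(0, rng_seed=int(rng.integers(2**31)))
        cfg = RunConfig(params=params, image_filename="mask.csv",
                        dims=labels.shape)
        save_config(cfg, outdir / "config.yaml")
        return {"config": outdir / "config.yaml", "mask": outdir / "mask.csv"}
    raise ValueError(f"unknown fixture kind {kind!r}")
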