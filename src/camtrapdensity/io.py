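"""Readers, writers, species-parameter configs, and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .detection import CameraDeployment, CameraGrid
from .events import LYCALOPEX_POOL, pool_species
from .movement import MovementParams, Trajectory

__all__ = [
    "load_species_params",
    "species_defaults",
    "read_photo_records",
    "write_photo_records",
    "read_deployments",
    "write_deployments",
    "write_trajectories",
    "RunManifest",
]

_PARAM_FIELDS = ("mean_step_m", "sd_step_m", "sd_turn_deg",
                 "steps_per_month", "home_range_km2")


def species_defaults() -> dict[str, MovementParams]:
    """The shipped per-species movement parameter defaults."""
    text = (resources.files("camtrapdensity") / "data" /
            "species_params.yaml").read_text()
    raw = yaml.safe_load(text)
    return {name: MovementParams(species_label=name, **vals)
            for name, vals in raw.items()}


def load_species_params(source: str | Path,
                        species: str | None = None) -> MovementParams:
    """Load movement parameters from a shipped species name or a YAML file.

    ``source`` may be a species label present in the shipped defaults, or
    a path to a YAML file containing either one parameter set (flat keys)
    or a mapping of species name -> parameter set (then ``species``
    selects the entry).
    """
    defaults = species_defaults()
    if isinstance(source, str) and source in defaults:
        return defaults[source]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a shipped species "
            f"({sorted(defaults)}) nor an existing file")
    raw = yaml.safe_load(path.read_text())
    if set(_PARAM_FIELDS) <= set(raw):
        label = raw.get("species_label", species or path.stem)
        return MovementParams(species_label=label,
                              **{k: raw[k] for k in _PARAM_FIELDS})
    if species is None or species not in raw:
        raise KeyError(f"species {species!r} not found in {path}")
    return MovementParams(species_label=species, **raw[species])


def read_photo_records(path, column_map: dict | None = None,
                       species_map: dict | None = LYCALOPEX_POOL,
                       deployments: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a photo-record CSV into the canonical schema.

    ``column_map`` maps canonical names (site, camera_id, species,
    timestamp) to the file's column names, adapting arbitrary deposits.
    Unparseable timestamps raise with the offending data row numbers
    (1-based, excluding the header); when ``deployments`` is given,
    records referencing unknown site/camera pairs raise a validation
    report listing them.
    """
    df = pd.read_csv(path)
    column_map = column_map or {}
    rename = {v: k for k, v in column_map.items()}
    df = df.rename(columns=rename)
    required = ["site", "camera_id", "species", "timestamp"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} "
                         f"(have {list(df.columns)})")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = ts.isna() & df["timestamp"].notna()
    if bad.any():
        rows = [int(i) + 1 for i in df.index[bad][:10]]
        raise ValueError(
            f"{path}: unparseable timestamp in data row(s) {rows} "
            f"(e.g. {df.loc[df.index[bad][0], 'timestamp']!r})")
    df["timestamp"] = ts
    if "individual_id" not in df.columns:
        df["individual_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    df = df[required + ["individual_id"]]
    if species_map:
        df = pool_species(df, species_map)
    if deployments is not None:
        known = set(zip(deployments["site"], deployments["camera_id"]))
        pairs = set(zip(df["site"], df["camera_id"]))
        unknown = sorted(pairs - known)
        if unknown:
            raise ValueError(
                f"{path}: records reference unknown site/camera pairs: "
                f"{unknown[:10]}")
    return df


def write_photo_records(records: pd.DataFrame, path) -> None:
    out = records.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_deployments(path) -> dict[str, CameraGrid]:
    """Read a deployment CSV into per-site camera grids.

    Columns: site, camera_id, x_m, y_m, facing_deg (blank = unknown,
    randomised at simulation time), active_start, active_end. Optional:
    detect_radius_m, sector_halfwidth_deg.
    """
    df = pd.read_csv(path)
    grids = {}
    for site, sub in df.groupby("site", sort=False):
        cams = []
        for row in sub.itertuples(index=False):
            facing = getattr(row, "facing_deg", None)
            if facing is not None and pd.isna(facing):
                facing = None
            kw = {}
            for opt in ("detect_radius_m", "sector_halfwidth_deg"):
                if opt in sub.columns and pd.notna(getattr(row, opt)):
                    kw[opt] = float(getattr(row, opt))
            cams.append(CameraDeployment(
                site=site, camera_id=str(row.camera_id),
                position=(float(row.x_m), float(row.y_m)),
                facing_deg=None if facing is None else float(facing),
                active_start=pd.Timestamp(row.active_start),
                active_end=pd.Timestamp(row.active_end), **kw))
        grids[site] = CameraGrid(site, tuple(cams))
    return grids


def write_deployments(grids: dict[str, CameraGrid], path) -> None:
    rows = []
    for grid in grids.values():
        for c in grid.cameras:
            rows.append({"site": c.site, "camera_id": c.camera_id,
                         "x_m": c.position[0], "y_m": c.position[1],
                         "facing_deg": c.facing_deg,
                         "active_start": c.active_start.isoformat(),
                         "active_end": c.active_end.isoformat()})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    """Trajectory CSV export: individual_id, step_index, x_m, y_m, timestamp."""
    frames = []
    for t in trajectories:
        frames.append(pd.DataFrame({
            "individual_id": t.individual_id,
            "step_index": range(len(t)),
            "x_m": t.positions[:, 0],
            "y_m": t.positions[:, 1],
            "timestamp": pd.Series(t.timestamps).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run an estimate bit-identically."""

    command: str
    config: dict
    seed: int
    package_version: str = ""
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    _t0: float = field(default_factory=time.perf_counter, repr=False)

    def add_input(self, name: str, path) -> None:
        self.input_digests[name] = _sha256(path)

    def record_stage(self, name: str, count: int | None = None) -> None:
        self.stage_seconds[name] = round(time.perf_counter() - self._t0, 3)
        self._t0 = time.perf_counter()
        if count is not None:
            self.stage_counts[name] = int(count)

    def write(self, path) -> None:
        d = {k: v for k, v in self.__dict__.items() if not k.startswith("_")}
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def read(cls, path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)
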