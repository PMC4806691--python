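"""Configuration files, canonical fixtures and delimited-table I/O.

A run is described by a single YAML document with one section per
ingredient (scene, source, leaf specs, sweep, TST parameters, optimizer).
Unknown keys are rejected — physics fields never default silently.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .leafgeom import LeafEndCurve, MachineScene, leaf_end
from .source_model import SourceDistribution
from .tst_core import TSTParams

__all__ = ["SceneConfig", "SourceConfig", "LeafConfig", "SweepConfig",
           "TSTConfig", "OptimizerConfig", "RunConfig", "load_config",
           "dump_config", "make_fixtures", "write_table", "read_table",
           "scene_from_config", "source_from_config", "leaf_from_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SceneConfig(_Strict):
    sad: float = Field(gt=0, description="source-to-axis distance (cm)")
    scd: float = Field(gt=0, description="source-to-collimator distance (cm)")
    fs: float = Field(gt=0, description="maximum square field side (cm)")
    lh: float = Field(gt=0, description="leaf height (cm)")
    rho: float = Field(gt=0, description="leaf density (g/cm^3)")
    mu_rho: float = Field(gt=0, description="mass attenuation coeff (cm^2/g)")
    sdd: float | None = None
    dh: float | None = None


class SourceConfig(_Strict):
    kind: str = "gaussian"
    fwhms: list[float] = [0.2]
    weights: list[float] = [1.0]
    centers: list[float] | None = None
    k_sigma: float = 3.0
    n_subsources: int = 100

    @field_validator("kind")
    @classmethod
    def _kind(cls, v):
        if v not in ("gaussian", "gaussian_mixture"):
            raise ValueError("kind must be gaussian or gaussian_mixture")
        return v


class LeafConfig(_Strict):
    family: str
    params: dict[str, object]
    label: str = ""


class SweepConfig(_Strict):
    t_w: float = -20.0
    t_p: float = 20.0
    n: int = Field(default=17, ge=2)


class TSTConfig(_Strict):
    e: float = Field(gt=0)
    l: float = Field(gt=0)


class OptimizerConfig(_Strict):
    family: str = "circular"
    objective: str = "mean"     # mean | std | a lambda in [0,1] as string
    method: str = "gradient"    # gradient | ga | multistart
    population: int = 80
    generations: int = 150
    n_starts: int = 20


class RunConfig(_Strict):
    scene: SceneConfig
    source: SourceConfig = SourceConfig()
    leaves: list[LeafConfig] = []
    sweep: SweepConfig = SweepConfig()
    tst: TSTConfig | None = None
    optimizer: OptimizerConfig | None = None
    seed: int = 0

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=False)


def scene_from_config(cfg: RunConfig) -> MachineScene:
    s = cfg.scene
    return MachineScene(sad=s.sad, scd=s.scd, fs=s.fs, lh=s.lh, rho=s.rho,
                        mu_rho=s.mu_rho, sdd=s.sdd, dh=s.dh)


def source_from_config(cfg: RunConfig) -> SourceDistribution:
    s = cfg.source
    return SourceDistribution(fwhms=tuple(s.fwhms), weights=tuple(s.weights),
                              centers=tuple(s.centers) if s.centers else None,
                              k_sigma=s.k_sigma)


def leaf_from_config(leaf: LeafConfig, lh: float) -> LeafEndCurve:
    return leaf_end(leaf.family, lh, **leaf.params)


def tst_from_config(cfg: RunConfig) -> TSTParams:
    if cfg.tst is None:
        raise ValueError("configuration has no tst section")
    return TSTParams(e=cfg.tst.e, l=cfg.tst.l)


# ---------------------------------------------------------------------------
# canonical fixtures
# ---------------------------------------------------------------------------

#: reference geometric model: 6 MV-class machine, tungsten leaves of 8 cm
#: height at SCD 46 cm, 40 cm maximum field, Gaussian 0.2 cm FWHM focal spot
TABLE2_SCENE = SceneConfig(sad=100.0, scd=46.0, fs=40.0, lh=8.0, rho=19.3,
                           mu_rho=0.05, sdd=33.9, dh=7.8)

#: calibrated TST parameters for the reference model
CANONICAL_TST = TSTConfig(e=0.152, l=1.174)

#: symmetric circular-arc radius family used for verification sweeps
RADIUS_FAMILY = (4.0, 6.0, 8.0, 10.0, 15.0, 20.0, 25.0)

#: published optimal designs for the reference model
OPTIMA = {
    "circular": {"R": 16.213, "d": -0.732},
    "elliptical": {"b": 0.728},
    "bezier": {"control": [[-1.594, 1.077], [0.814, 0.748]]},
}

#: clinical machine geometries (leaf material: tungsten alloy, 18 g/cm^3)
MACHINES = {
    "elekta_agility": SceneConfig(sad=100.0, scd=35.1, fs=40.0, lh=9.0,
                                  rho=18.0, mu_rho=0.05),
    "varian_millennium": SceneConfig(sad=100.0, scd=51.02, fs=40.0, lh=5.65,
                                     rho=18.0, mu_rho=0.05),
}


def make_fixtures(kind: str):
    """Canonical run configurations.

    ``table2_scene``: the reference geometric model; ``fig3_radius_family``:
    the circular-arc verification family; ``table5_optima``: the optimal
    designs of the four families (B-spline omitted: its published control
    values are incomplete); ``table6_machines``: Elekta Agility / Varian
    Millennium geometries.
    """
    if kind == "table2_scene":
        return RunConfig(scene=TABLE2_SCENE, tst=CANONICAL_TST)
    if kind == "fig3_radius_family":
        leaves = [LeafConfig(family="circular", params={"R": r, "d": 0.0},
                             label=f"R={r:g}") for r in RADIUS_FAMILY]
        return RunConfig(scene=TABLE2_SCENE, leaves=leaves, tst=CANONICAL_TST)
    if kind == "table5_optima":
        leaves = [LeafConfig(family=f, params=dict(p), label=f)
                  for f, p in OPTIMA.items()]
        return RunConfig(scene=TABLE2_SCENE, leaves=leaves, tst=CANONICAL_TST)
    if kind == "table6_machines":
        return {name: RunConfig(scene=sc) for name, sc in MACHINES.items()}
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# delimited tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a rectangular table as CSV with '#'-prefixed metadata lines.

    Column order and float formatting are deterministic and
    locale-independent.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a CSV written by :func:`write_table`; returns (frame, metadata)."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    return df, meta


def matrix_frame(matrix) -> pd.DataFrame:
    """PenumbraMatrix -> tidy frame (one row per curve, columns = positions)."""
    cols = {"curve": matrix.labels}
    for j, T in enumerate(matrix.positions):
        cols[f"T={T:g}"] = matrix.widths[:, j]
    return pd.DataFrame(cols)


def frame_matrix(df: pd.DataFrame):
    """Inverse of :func:`matrix_frame` (labels + positions + width array)."""
    labels = df["curve"].tolist()
    pos_cols = [c for c in df.columns if c.startswith("T=")]
    positions = np.array([float(c[2:]) for c in pos_cols])
    widths = df[pos_cols].to_numpy(dtype=float)
    return labels, positions, widths
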