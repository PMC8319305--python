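"""File formats and run configuration.

Cage series travel as tidy CSV, one row per collection, with run provenance
(arm, replicate, seed, release day, config hash) embedded as ``# key: value``
header comments.  Ground truth and analysis summaries are JSON; run
configuration is a single declarative YAML file validated before any
computation (unknown keys are rejected).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__ as _version
from .cage_sim import CageProtocol, DriveParams, LifeHistoryParams, ObservedCageSeries
from .synthetic import GroundTruth, StudyBundle

__all__ = [
    "write_series_csv",
    "read_series_csv",
    "write_bundle",
    "read_bundle",
    "RunConfig",
    "load_config",
    "config_hash",
]


def write_series_csv(series: ObservedCageSeries, path: Union[str, Path]) -> None:
    """Write one cage series with provenance header comments."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (("arm", series.arm), ("replicate", series.replicate),
                         ("seed", series.seed), ("release_day", series.release_day),
                         ("cagedrive_version", _version)):
            fh.write(f"# {key}: {val}\n")
        series.records.to_csv(fh, index=False)


def read_series_csv(path: Union[str, Path]) -> ObservedCageSeries:
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines(keepends=True)
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, val = line.lstrip("# ").partition(":")
        meta[key.strip()] = val.strip()
    try:
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
    except Exception as exc:
        raise ValueError(f"malformed cage CSV {path}: {exc}") from exc
    required = {"day", "eggs_total", "larvae_screened", "rfp_positive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def _maybe_int(s: Optional[str]) -> Optional[int]:
        return None if s in (None, "", "None") else int(s)

    return ObservedCageSeries(
        df, arm=meta.get("arm", "unknown"),
        replicate=int(meta.get("replicate", 0)),
        seed=_maybe_int(meta.get("seed")),
        release_day=_maybe_int(meta.get("release_day")),
    )


def write_bundle(bundle: StudyBundle, outdir: Union[str, Path]) -> Path:
    """Write a synthetic study: one CSV per cage, truth.json, protocol.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for arm, cages in bundle.cages.items():
        for s in cages:
            write_series_csv(s, outdir / f"cage_{arm}_{s.replicate}.csv")
    (outdir / "truth.json").write_text(
        json.dumps(bundle.truth.to_dict(), indent=2, default=str) + "\n")
    protocols = {arm: dataclasses.asdict(p) for arm, p in bundle.protocols.items()}
    for p in protocols.values():  # YAML-friendly: tuples -> lists
        p["release_events"] = [list(e) for e in p["release_events"]]
    (outdir / "protocol.yaml").write_text(yaml.safe_dump(protocols, sort_keys=False))
    return outdir


def read_bundle(indir: Union[str, Path]) -> StudyBundle:
    """Read back a bundle written by :func:`write_bundle` (lossless)."""
    indir = Path(indir)
    truth = GroundTruth.from_dict(json.loads((indir / "truth.json").read_text()))
    raw = yaml.safe_load((indir / "protocol.yaml").read_text())
    protocols = {}
    for arm, kw in raw.items():
        kw["release_events"] = tuple(tuple(e) for e in kw["release_events"])
        protocols[arm] = CageProtocol(**kw)
    cages: dict[str, list[ObservedCageSeries]] = {arm: [] for arm in protocols}
    for f in sorted(indir.glob("cage_*.csv")):
        s = read_series_csv(f)
        cages.setdefault(s.arm, []).append(s)
    for arm in cages:
        cages[arm].sort(key=lambda s: s.replicate)
    return StudyBundle(cages=cages, truth=truth, protocols=protocols)


# --------------------------------------------------------------------------
# run configuration


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolConfig(_Block):
    arm: str = "control"
    establishment_days: int = 21
    prerelease_end_day: int = 74
    restock_cap: int = 400
    collections_per_week: int = 2
    monitoring_end_day: int = 384
    larvae_screen_cap: int = 1000
    startup_pupae: int = 800
    establishment_pupae: int = 400
    supplement_prerelease: bool = True


class LifeHistoryConfig(_Block):
    lambda_eggs: float = 116.0
    p_lay: float = 0.14
    survival_model: str = "gompertz"
    median_lifespan_start: float = 6.0
    median_lifespan_end: float = 11.0
    senescence_shape: float = 0.45
    s_adult_start: float = 0.5 ** (1 / 6)
    s_adult_end: float = 0.5 ** (1 / 11)
    hatch_days: int = 2
    egg_to_pupa_days: int = 11
    pupa_to_adult_days: int = 2
    juvenile_survival: float = 0.8
    p_mate: float = 0.6
    female_survival_advantage: float = 1.0
    batch_dispersion: Optional[float] = None


class DriveConfig(_Block):
    h: float = 0.975
    rho: float = 0.5
    f_pat: float = 0.35
    f_mat: float = 0.5
    deposition_combine: str = "min"
    deposition_scope: str = "all_daughters"
    h_male: Optional[float] = None
    h_female: Optional[float] = None


class PriorsConfig(_Block):
    f_pat: tuple[float, float] = (0.0, 1.0)
    f_mat: tuple[float, float] = (0.0, 1.0)
    lambda_eggs: tuple[float, float] = (20.0, 300.0)
    p_lay: tuple[float, float] = (0.01, 0.5)
    rho: tuple[float, float] = (0.0, 1.0)


class RunConfig(_Block):
    """Declarative run configuration; schema-validated, unknown keys rejected."""

    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    life_history: LifeHistoryConfig = Field(default_factory=LifeHistoryConfig)
    drive: DriveConfig = Field(default_factory=DriveConfig)
    priors: PriorsConfig = Field(default_factory=PriorsConfig)
    seed: int = 0
    output_dir: str = "results"

    def build(self):
        """Instantiate (protocol, life-history, drive) domain objects."""
        from .cage_sim import study_protocol

        pkw = self.protocol.model_dump()
        arm = pkw.pop("arm")
        protocol = study_protocol(arm, **pkw)
        life = LifeHistoryParams(**self.life_history.model_dump())
        drive = DriveParams(**self.drive.model_dump())
        return protocol, life, drive


def load_config(path: Union[str, Path]) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a validated configuration, for provenance."""
    blob = json.dumps(cfg.model_dump(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
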