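"""Run configuration parsing/validation and result writers.

A run is described by a small JSON or YAML document validated against
:class:`RunConfig` (unknown keys are rejected).  Writers emit the tidy
trajectory CSV, a dose JSON, the Wolff–Chaikoff event log and a manifest
with the resolved configuration and solver statistics; repeated runs of a
deterministic scenario produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import replace
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .dosimetry import DoseResult
from .kinetics import ExposureScenario, Trajectory
from .parameters import (
    SUPPORTED_WEEKS,
    WC_DURATION_H,
    ModelParameters,
    load_parameters,
)


class SolverOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rtol: float = Field(1e-8, gt=0)
    method: str = "LSODA"


class WCOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    enabled: bool = True
    threshold_maternal_umol: Optional[float] = Field(None, gt=0)
    threshold_fetal_umol: Optional[float] = Field(None, gt=0)
    duration_h: float = Field(WC_DURATION_H, gt=0)


class RunConfig(BaseModel):
    """Validated description of one exposure simulation."""

    model_config = ConfigDict(extra="forbid")

    week: int
    activity_bq: float = Field(0.0, ge=0)
    stable_dose_mg: float = Field(0.0, ge=0)
    t_admin_radio_d: float = Field(0.0, ge=0)
    t_admin_stable_d: float = Field(0.0, ge=0)
    horizon_d: float = Field(100.0, gt=0)
    include_gamma: bool = True
    solver: SolverOptions = SolverOptions()
    wc: WCOptions = WCOptions()
    seed: Optional[int] = None  # only noisy-fit demos draw randomness

    def model_post_init(self, _ctx) -> None:
        if self.week not in SUPPORTED_WEEKS:
            raise ValueError(
                f"week must be one of {sorted(SUPPORTED_WEEKS)}, got {self.week}"
            )

    def scenario(self) -> ExposureScenario:
        return ExposureScenario(
            week=self.week,
            activity_bq=self.activity_bq,
            stable_dose_mg=self.stable_dose_mg,
            t_admin_radio_d=self.t_admin_radio_d,
            t_admin_stable_d=self.t_admin_stable_d,
            horizon_d=self.horizon_d,
            wc_enabled=self.wc.enabled,
        )

    def parameters(self) -> ModelParameters:
        params = load_parameters(self.week)
        overrides: dict = {"wc_duration_d": self.wc.duration_h / 24.0}
        if self.wc.threshold_maternal_umol is not None:
            overrides["wc_threshold_maternal_umol"] = self.wc.threshold_maternal_umol
        if self.wc.threshold_fetal_umol is not None:
            overrides["wc_threshold_fetal_umol"] = self.wc.threshold_fetal_umol
        return replace(params, **overrides)


def parse_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration."""
    path = Path(path)
    text = path.read_text()
    data = (
        json.loads(text)
        if path.suffix.lower() == ".json"
        else yaml.safe_load(text)
    )
    return RunConfig.model_validate(data)


def write_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def write_outputs(
    trajectory: Trajectory,
    dose_result: DoseResult,
    outdir: str | Path,
    *,
    config: RunConfig | None = None,
    fits: dict | None = None,
) -> dict[str, Path]:
    """Write trajectory/dose/event/manifest files; returns the paths."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    traj_path = outdir / "trajectory.csv"
    trajectory.to_frame().to_csv(traj_path, index=False, float_format="%.10g")
    paths["trajectory"] = traj_path

    dose_path = outdir / "dose.json"
    dose_path.write_text(
        json.dumps(dataclasses.asdict(dose_result), indent=2, sort_keys=True)
        + "\n"
    )
    paths["dose"] = dose_path

    events = [
        {
            "gland": ev.gland,
            "switch_on_min": ev.t_on_d * 1440.0,
            "switch_off_min": None if ev.t_off_d is None else ev.t_off_d * 1440.0,
        }
        for ev in trajectory.events
    ]
    events_path = outdir / "events.json"
    events_path.write_text(json.dumps(events, indent=2) + "\n")
    paths["events"] = events_path

    manifest = {
        "package_version": __version__,
        "config": None if config is None else config.model_dump(),
        "solver_stats": trajectory.solver_stats,
        "wc_events_min": events,
    }
    if fits:
        manifest["hill_fits"] = {
            name: dataclasses.asdict(fit) for name, fit in fits.items()
        }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = manifest_path
    return paths
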