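"""Schema-validated YAML configuration for the command-line interface.

Unknown keys are rejected; every tolerance default matches the library
defaults, so a minimal config (dataset + line) reproduces the standard
analysis exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .contours import DislocationLine
from .crystal import UnitCell, ZoneAxis
from .pipeline import AnalysisOptions

__all__ = ["AnalysisConfigModel", "SimulationSpecModel", "load_analysis_config",
           "load_simulation_spec"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class CellModel(_Strict):
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    label: str = ""


class LineModel(_Strict):
    points_nm: list[list[float]]
    positive_sense: int = 1

    @field_validator("points_nm")
    @classmethod
    def _check_points(cls, v):
        if len(v) < 2 or any(len(p) != 2 for p in v):
            raise ValueError("line needs >= 2 (x, y) points in nm")
        return v


class AnalysisConfigModel(_Strict):
    dataset: str
    line: LineModel
    output_dir: str = "sedlab-out"
    seed: int = 0
    aperture_radius: float = 0.02
    sample_fraction: float = 0.05
    cluster_tol: float = 0.012
    skip_centering: bool = False
    affine: list[list[float]] | None = None
    n_boot: int = 199
    zero_tol: float = 2.0
    invisibility_angle_tol: float = 10.0
    min_crossing_deg: float = 15.0
    screw_tol: float = 15.0
    edge_tol: float = 15.0
    handedness_align_tol: float = 20.0
    match_tol: float = 3.0
    cell: CellModel | None = None
    zone: list[int] | None = None
    candidate_zones: list[list[int]] = Field(default_factory=list)
    burgers_candidates: list[list[int]] | None = None

    def to_line(self) -> DislocationLine:
        return DislocationLine(np.asarray(self.line.points_nm, dtype=float),
                               positive_sense=self.line.positive_sense)

    def to_options(self) -> AnalysisOptions:
        cell = None
        if self.cell is not None:
            cell = UnitCell(self.cell.a, self.cell.b, self.cell.c,
                            self.cell.alpha, self.cell.beta, self.cell.gamma,
                            label=self.cell.label)
        return AnalysisOptions(
            aperture_radius=self.aperture_radius,
            sample_fraction=self.sample_fraction,
            cluster_tol=self.cluster_tol,
            seed=self.seed,
            skip_centering=self.skip_centering,
            affine=None if self.affine is None
            else np.asarray(self.affine, dtype=float),
            n_boot=self.n_boot,
            zero_tol=self.zero_tol,
            invisibility_angle_tol=self.invisibility_angle_tol,
            min_crossing_deg=self.min_crossing_deg,
            screw_tol=self.screw_tol,
            edge_tol=self.edge_tol,
            handedness_align_tol=self.handedness_align_tol,
            match_tol=self.match_tol,
            cell=cell,
            zone=None if self.zone is None else ZoneAxis(tuple(self.zone)),
            candidate_zones=[ZoneAxis(tuple(z)) for z in self.candidate_zones],
            burgers_candidates=None if self.burgers_candidates is None
            else [tuple(b) for b in self.burgers_candidates],
        )


class ReflectionModel(_Strict):
    k: list[float]
    width_nm: float = 16.0
    strength: float = 0.05
    hkl: list[int] | None = None


class SimulationSpecModel(_Strict):
    """YAML form of :class:`sedlab.simulate.SimulationSpec`.

    Either give a named ``fixture`` kind, or the explicit scene.
    """

    fixture: str | None = None
    seed: int = 0
    scan_shape: list[int] = Field(default_factory=lambda: [64, 64])
    scan_step: float = 4.0
    detector_shape: list[int] = Field(default_factory=lambda: [96, 96])
    detector_cal: float = 0.012
    rotation_offset: float = 0.0
    reflections: list[ReflectionModel] = Field(default_factory=list)
    line: LineModel | None = None
    A_true: float = 12.0
    B_true: float = 2.5
    C_true: float = 60.0
    handedness: int = 0
    twist_deg: float = 10.0
    artifact_row: int | None = None
    artifact_shift_px: float = 3.0
    dose: float | None = None
    kv: float = 300.0
    alpha_mrad: float = 0.8
    current_pa: float = 1.0
    dwell_ms: float = 1.0

    def to_spec(self):
        from .optics import AcquisitionGeometry
        from .simulate import Reflection, SimulationSpec, fixture_spec
        if self.fixture is not None:
            return fixture_spec(self.fixture, seed=self.seed)
        line = None
        if self.line is not None:
            line = DislocationLine(np.asarray(self.line.points_nm, float),
                                   positive_sense=self.line.positive_sense)
        return SimulationSpec(
            scan_shape=tuple(self.scan_shape),
            scan_step=self.scan_step,
            detector_shape=tuple(self.detector_shape),
            detector_cal=self.detector_cal,
            rotation_offset=self.rotation_offset,
            geometry=AcquisitionGeometry(self.kv, self.alpha_mrad,
                                         self.current_pa, self.dwell_ms),
            reflections=[Reflection(k=tuple(r.k), width_nm=r.width_nm,
                                    strength=r.strength,
                                    hkl=None if r.hkl is None
                                    else tuple(r.hkl))
                         for r in self.reflections],
            line=line,
            A_true=self.A_true, B_true=self.B_true, C_true=self.C_true,
            handedness=self.handedness, twist_deg=self.twist_deg,
            artifact_row=self.artifact_row,
            artifact_shift_px=self.artifact_shift_px,
            dose=self.dose, seed=self.seed,
        )


def load_analysis_config(path) -> AnalysisConfigModel:
    return AnalysisConfigModel.model_validate(
        yaml.safe_load(Path(path).read_text()))


def load_simulation_spec(path) -> SimulationSpecModel:
    return SimulationSpecModel.model_validate(
        yaml.safe_load(Path(path).read_text()))
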