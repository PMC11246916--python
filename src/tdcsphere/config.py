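"""Run configuration: a flat, fully serializable description of a simulation
or optimization run.  YAML is the native format; JSON is accepted.  Every
artifact directory receives a copy of the exact configuration used."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .montage import ElectrodeSpec, MontageSpec, enumerate_candidates
from .optimize import SolverSettings
from .phantom import PopulationSpec, default_head_spec


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    # phantom population
    outer_radius_mm: float = 92.0
    spongy_bone: bool = False
    n_models: int = 5
    thickness_cv: float = 0.08
    size_cv: float = 0.04
    seed: int = 0
    # solver / sampling
    h_mm: float = 2.0
    tol: float = 1e-6
    maxiter: int = 10000
    n_surface_points: int = 10000
    sampling_depth_mm: float = 1.0
    # stimulation
    current_mA: float = 2.0
    montages: list = field(default_factory=list)  # e.g. ["FCz-POz"]; empty = all candidates
    # electrode
    electrode_length_mm: float = 70.0
    electrode_width_mm: float = 50.0
    sponge_thickness_mm: float = 5.0
    rubber_thickness_mm: float = 1.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def electrode_spec(self) -> ElectrodeSpec:
        return ElectrodeSpec(
            length_mm=self.electrode_length_mm,
            width_mm=self.electrode_width_mm,
            sponge_below_mm=self.sponge_thickness_mm,
            sponge_above_mm=self.sponge_thickness_mm,
            rubber_thickness_mm=self.rubber_thickness_mm,
        )

    def solver_settings(self) -> SolverSettings:
        return SolverSettings(
            tol=self.tol,
            maxiter=self.maxiter,
            n_surface_points=self.n_surface_points,
            sampling_depth_mm=self.sampling_depth_mm,
            electrode=self.electrode_spec(),
        )

    def population_spec(self) -> PopulationSpec:
        return PopulationSpec(
            base=default_head_spec(self.outer_radius_mm, self.spongy_bone),
            n=self.n_models,
            thickness_cv=self.thickness_cv,
            size_cv=self.size_cv,
            seed=self.seed,
        )

    def montage_specs(self) -> list:
        if self.montages:
            out = []
            for name in self.montages:
                anode, cathode = name.split("-", 1)
                out.append(MontageSpec(anode, cathode, self.current_mA))
            return out
        return enumerate_candidates(self.electrode_spec(), self.current_mA)
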