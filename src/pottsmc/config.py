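"""Structured experiment configuration (YAML) and object builders.

One config file describes a full experiment: lattice block, cell-index/type
block, Hamiltonian block, dynamics block and experiment block.  Parsing and
serialization are lossless (the canonical dict is kept as written), all
referenced types and indices are validated on build, and a seed is mandatory
for stochastic experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dynamics import DynamicsParams
from .errors import ConfigurationError
from .hamiltonian import (
    ConstraintTerm,
    Hamiltonian,
    SurfaceConstraintParams,
    SurfaceEnergyMatrix,
    VolumeConstraintParams,
)
from .lattice import CellIndexModel, Configuration, Lattice, Neighborhood


def _neighborhood(block: Mapping[str, Any] | None) -> Neighborhood | None:
    if block is None:
        return None
    return Neighborhood(block.get("kind", "von_neumann"), int(block.get("order", 1)))


def _constraint(block: Mapping[str, Any], cls):
    per_type = {
        t: ConstraintTerm(float(v["target"]), float(v["strength"]))
        for t, v in block.get("per_type", {}).items()
    }
    return cls(per_type, include_medium=bool(block.get("include_medium", False)))


@dataclass
class ExperimentConfig:
    """A parsed experiment configuration; ``data`` is the canonical dict."""

    data: dict = field(default_factory=dict)

    # -- round-trip -------------------------------------------------------

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "ExperimentConfig":
        return cls(dict(data))

    def to_dict(self) -> dict:
        return dict(self.data)

    @classmethod
    def load(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # -- builders ---------------------------------------------------------

    def build_lattice(self) -> Lattice:
        block = self.data.get("lattice")
        if not block:
            raise ConfigurationError("config has no lattice block")
        return Lattice(
            block["dimensions"],
            boundary=block.get("boundary", "periodic"),
            copy_neighborhood=_neighborhood(block.get("copy_neighborhood")),
            interface_neighborhood=_neighborhood(block.get("interface_neighborhood")),
        )

    def build_cells(self) -> CellIndexModel:
        block = self.data.get("cells")
        if not block:
            raise ConfigurationError("config has no cells block")
        types = block.get("types")
        type_map = {int(k): str(v) for k, v in types.items()} if types else None
        return CellIndexModel(
            int(block["K"]),
            type_map=type_map,
            medium_type=block.get("medium_type", "medium"),
        )

    def build_hamiltonian(self, cells: CellIndexModel | None = None) -> Hamiltonian:
        cells = cells or self.build_cells()
        block = self.data.get("hamiltonian") or {}
        surface = None
        if "surface" in block and block["surface"] is not None:
            surface = SurfaceEnergyMatrix.from_dict(block["surface"])
        volume = None
        if "volume" in block and block["volume"] is not None:
            volume = _constraint(block["volume"], VolumeConstraintParams)
        surf_c = None
        if "surface_constraint" in block and block["surface_constraint"] is not None:
            surf_c = _constraint(block["surface_constraint"], SurfaceConstraintParams)
        return Hamiltonian(cells, surface=surface, volume=volume, surface_constraint=surf_c)

    def build_params(self, require_seed: bool = False) -> DynamicsParams:
        block = self.data.get("dynamics") or {}
        seed = block.get("seed")
        if require_seed and seed is None:
            raise ConfigurationError("a seed is mandatory for stochastic experiments")
        temperature = block.get("temperature", 1.0)
        if isinstance(temperature, str):
            if temperature not in ("inf", "+inf", "infinity"):
                raise ConfigurationError(f"unreadable temperature {temperature!r}")
            temperature = float("inf")
        return DynamicsParams(
            temperature=float(temperature),
            threshold=float(block.get("threshold", 0.0)),
            convention=block.get("convention", "shifted"),
            kernel=block.get("kernel", "modified"),
            seed=None if seed is None else int(seed),
        )

    def build_initial(
        self, lattice: Lattice | None = None, cells: CellIndexModel | None = None
    ) -> Configuration:
        from .experiments import generate_initial_config
        from .lattice import read_grid

        lattice = lattice or self.build_lattice()
        cells = cells or self.build_cells()
        block = (self.data.get("experiment") or {}).get("initial") or {}
        if "grid_file" in block:
            return read_grid(block["grid_file"])
        kind = block.get("kind", "equal_blocks")
        return generate_initial_config(
            kind,
            lattice,
            cells,
            seed=block.get("seed", (self.data.get("dynamics") or {}).get("seed")),
            index=int(block.get("index", 1)),
        )

    @property
    def experiment(self) -> dict:
        return dict(self.data.get("experiment") or {})
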