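"""The energy function H of a cellular Potts model and its single-site increments.

H is a sum of optional addends: the surface-interaction term (symmetric
coefficients J between cell types summed over interfaces), the quadratic
volume constraint, the quadratic surface constraint, and an arbitrary extra
term supplied as a callable.  The energy gain Delta-H of a proposed
single-site copy is evaluated incrementally — touching only the interfaces at
the target site and the two affected cells — and is bit-consistent with a
full recomputation up to additive floating-point tolerance; the full
recomputation is retained as a test oracle.

The medium (index 0) is excluded from the volume and surface constraints by
default, since the constraints are meant per biological cell; the
``include_medium`` flag restores full symmetry for theory experiments.
Energies are plain reals without a unit system — the temperature divides the
energy in the dynamics, so one of the two scales is redundant anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np


from .errors import ConfigurationError, MissingInteractionError
from .lattice import CellIndexModel, Configuration, cell_surface_length, interface_pairs

DELTA_TOLERANCE = 1e-9  # incremental-vs-full consistency contract


class SurfaceEnergyMatrix:
    """Symmetric surface-energy coefficients J(type, type).

    Construction accepts any mapping from (unordered) type pairs to reals;
    supplying both orientations of a pair with different values is an error.
    """

    def __init__(self, values: Mapping[tuple[str, str], float]) -> None:
        table: dict[frozenset[str] | str, float] = {}
        for (a, b), v in values.items():
            key = frozenset((a, b))
            v = float(v)
            if key in table and table[key] != v:
                raise ConfigurationError(
                    f"surface energy matrix not symmetric: J({a},{b}) given twice "
                    f"with values {table[key]} and {v}"
                )
            table[key] = v
        self._table = table

    def get(self, a: str, b: str) -> float:
        try:
            return self._table[frozenset((a, b))]
        except KeyError:
            raise MissingInteractionError(f"no surface energy for type pair ({a}, {b})")

    __call__ = get

    def validate_types(self, types: set[str]) -> None:
        for a in types:
            for b in types:
                self.get(a, b)

    def to_dict(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for key, v in self._table.items():
            pair = sorted(key)
            a, b = (pair[0], pair[-1])
            out.setdefault(a, {})[b] = v
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, Mapping[str, float]]) -> "SurfaceEnergyMatrix":
        return cls({(a, b): v for a, row in data.items() for b, v in row.items()})


@dataclass(frozen=True)
class ConstraintTerm:
    """Per-type target/strength pair of a quadratic constraint."""

    target: float
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0 or self.target < 0:
            raise ConfigurationError("constraint targets and strengths must be >= 0")


@dataclass(frozen=True)
class VolumeConstraintParams:
    """Per-cell-type target volume V_T and strength lambda_V."""

    per_type: Mapping[str, ConstraintTerm]
    include_medium: bool = False


@dataclass(frozen=True)
class SurfaceConstraintParams:
    """Per-cell-type target surface length S_T and strength lambda_S."""

    per_type: Mapping[str, ConstraintTerm]
    include_medium: bool = False


def _validate_constraint(
    params, cells: CellIndexModel, what: str
) -> None:
    needed = set(cells.type_set)
    if params.include_medium:
        needed.add(cells.medium_type)
    missing = needed - set(params.per_type)
    if missing:
        raise ConfigurationError(f"{what} constraint missing parameters for types {sorted(missing)}")


@dataclass
class Hamiltonian:
    """H = H_surface + H_volume + H_surface_constraint + H_extra (absent terms = 0).

    ``extra_term`` is a real-valued function of a configuration.  Because the
    locality probe can only exhibit witnesses, never prove locality, an extra
    term must self-declare its dependence range via ``extra_term_range``
    (an integer radius, or ``None`` for nonlocal).
    """

    cells: CellIndexModel
    surface: SurfaceEnergyMatrix | None = None
    volume: VolumeConstraintParams | None = None
    surface_constraint: SurfaceConstraintParams | None = None
    extra_term: Callable[[Configuration], float] | None = None
    extra_term_range: int | None = field(default=None)

    def __post_init__(self) -> None:
        if self.surface is not None:
            self.surface.validate_types(set(self.cells.type_set) | {self.cells.medium_type})
        if self.volume is not None:
            _validate_constraint(self.volume, self.cells, "volume")
        if self.surface_constraint is not None:
            _validate_constraint(self.surface_constraint, self.cells, "surface")

    # -- term energies ----------------------------------------------------

    def surface_energy(self, config: Configuration) -> float:
        """Surface-interaction term: sum of J(tau(eta_x), tau(eta_y)) over interfaces.

        Under fixed boundary, contacts with the frozen medium frame (one per
        out-of-bounds interface offset) are charged at J(type, medium); cells
        thus interact with the confining environment through the Hamiltonian.
        Medium-medium frame contacts contribute J(medium, medium) like any
        other pair.
        """
        if self.surface is None:
            raise ConfigurationError("Hamiltonian has no surface term")
        tau = self.cells.type_of
        vals = config.values
        total = 0.0
        for x, y in interface_pairs(config):
            total += self.surface.get(tau(int(vals[x])), tau(int(vals[y])))
        if config.lattice.boundary == "fixed":
            medium = self.cells.medium_type
            for x in np.nonzero(config.lattice.frame_deficit)[0]:
                total += config.lattice.frame_deficit[x] * self.surface.get(
                    tau(int(vals[x])), medium
                )
        return total

    def _constrained_indices(self, params) -> list[int]:
        start = 0 if params.include_medium else 1
        return list(range(start, self.cells.K + 1))

    def volume_energy(self, config: Configuration) -> float:
        """Quadratic volume constraint: sum_i lambda_V (V_i - V_T)^2."""
        if self.volume is None:
            raise ConfigurationError("Hamiltonian has no volume term")
        total = 0.0
        for i in self._constrained_indices(self.volume):
            term = self.volume.per_type[self.cells.type_of(i)]
            total += term.strength * (config.volume(i) - term.target) ** 2
        return total

    def surface_constraint_energy(self, config: Configuration) -> float:
        """Quadratic surface constraint: sum_i lambda_S (s_i - S_T)^2."""
        if self.surface_constraint is None:
            raise ConfigurationError("Hamiltonian has no surface-constraint term")
        total = 0.0
        for i in self._constrained_indices(self.surface_constraint):
            term = self.surface_constraint.per_type[self.cells.type_of(i)]
            total += term.strength * (cell_surface_length(config, i) - term.target) ** 2
        return total

    def energy(self, config: Configuration) -> float:
        """Total energy: the sum of all present addends (0 with none)."""
        total = 0.0
        if self.surface is not None:
            total += self.surface_energy(config)
        if self.volume is not None:
            total += self.volume_energy(config)
        if self.surface_constraint is not None:
            total += self.surface_constraint_energy(config)
        if self.extra_term is not None:
            total += float(self.extra_term(config))
        return total

    # -- incremental energy gain -----------------------------------------

    def delta(self, config: Configuration, site, new_index: int) -> float:
        """Energy gain of copying ``new_index`` onto ``site`` (incremental).

        Equals ``energy(trial) - energy(config)`` where the trial copies
        ``new_index`` onto the target, but touches only the interfaces at the
        target and the two affected cells.
        """
        lat = config.lattice
        x = lat._as_flat(site)
        new = self.cells.validate_index(new_index)
        vals = config.values
        old = int(vals[x])
        if new == old:
            return 0.0
        neigh = lat.interface_neighbor_array(x)
        neigh_vals = [int(vals[y]) for y in neigh]
        dH = 0.0
        if self.surface is not None:
            tau = self.cells.type_of
            t_old, t_new = tau(old), tau(new)
            for yv in neigh_vals:
                t_y = tau(yv)
                if yv != old:
                    dH -= self.surface.get(t_old, t_y)
                if yv != new:
                    dH += self.surface.get(t_new, t_y)
            deficit = int(lat.frame_deficit[x]) if lat.boundary == "fixed" else 0
            if deficit:
                medium = self.cells.medium_type
                dH += deficit * (
                    self.surface.get(t_new, medium) - self.surface.get(t_old, medium)
                )
        if self.volume is not None:
            lo = 0 if self.volume.include_medium else 1
            for idx, dv in ((old, -1), (new, +1)):
                if idx >= lo:
                    term = self.volume.per_type[self.cells.type_of(idx)]
                    v = config.volume(idx)
                    dH += term.strength * (
                        (v + dv - term.target) ** 2 - (v - term.target) ** 2
                    )
        if self.surface_constraint is not None:
            lo = 0 if self.surface_constraint.include_medium else 1
            affected = {old, new} | set(neigh_vals)
            for i in affected:
                if i < lo:
                    continue
                ds = self._local_surface_delta(old, new, neigh_vals, i)
                if ds == 0:
                    continue
                term = self.surface_constraint.per_type[self.cells.type_of(i)]
                s = cell_surface_length(config, i)
                dH += term.strength * (
                    (s + ds - term.target) ** 2 - (s - term.target) ** 2
                )
        if self.extra_term is not None:
            trial = config.with_site(x, new)
            dH += float(self.extra_term(trial)) - float(self.extra_term(config))
        return dH

    @staticmethod
    def _local_surface_delta(old: int, new: int, neigh_vals: list[int], i: int) -> int:
        """Change in s_i restricted to the interface pairs incident to the target."""
        before = sum(1 for yv in neigh_vals if yv != old and (old == i or yv == i))
        after = sum(1 for yv in neigh_vals if yv != new and (new == i or yv == i))
        return after - before

    def delta_full(self, config: Configuration, site, new_index: int) -> float:
        """Oracle: Delta-H by full recomputation on the trial configuration."""
        trial = config.with_site(site, new_index)
        return self.energy(trial) - self.energy(config)

    # -- locality declaration (consumed by the diagnostics probe) ---------

    def term_hamiltonians(self) -> dict[str, "Hamiltonian"]:
        """Single-term Hamiltonians for each present addend."""
        out: dict[str, Hamiltonian] = {}
        if self.surface is not None:
            out["surface"] = Hamiltonian(self.cells, surface=self.surface)
        if self.volume is not None:
            out["volume"] = Hamiltonian(self.cells, volume=self.volume)
        if self.surface_constraint is not None:
            out["surface_constraint"] = Hamiltonian(
                self.cells, surface_constraint=self.surface_constraint
            )
        if self.extra_term is not None:
            out["extra"] = Hamiltonian(
                self.cells,
                extra_term=self.extra_term,
                extra_term_range=self.extra_term_range,
            )
        return out


def zero_hamiltonian(cells: CellIndexModel) -> Hamiltonian:
    """H == 0: the voter-model limit where the energy never biases a copy."""
    return Hamiltonian(cells)


# -- operation-style module surface -----------------------------------------


def surface_energy(config: Configuration, spec: Hamiltonian) -> float:
    return spec.surface_energy(config)


def volume_energy(config: Configuration, spec: Hamiltonian) -> float:
    return spec.volume_energy(config)


def surface_constraint_energy(config: Configuration, spec: Hamiltonian) -> float:
    return spec.surface_constraint_energy(config)


def total_energy(config: Configuration, spec: Hamiltonian) -> float:
    return spec.energy(config)


def delta_energy(config: Configuration, spec: Hamiltonian, site, new_index: int) -> float:
    return spec.delta(config, site, new_index)
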