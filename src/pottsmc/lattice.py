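"""Lattice geometry, cell indexing, configurations and elementary observables.

A cellular Potts model lives on a finite regular lattice ``S`` whose sites
carry *cell indices* from ``Sigma = {0, 1, ..., K}``; index ``0`` denotes the
medium.  A *configuration* assigns one index to every site; the *cell* with
index ``i`` is the set of sites carrying ``i``.  This module provides the
lattice (with periodic or fixed boundary and configurable copy/interface
neighborhoods), the cell-index model with its type map ``tau``, configurations
with their elementary observables (volume, surface length, present indices),
plain-text grid serialization, and exhaustive state-space enumeration for the
exact Markov-chain analysis on tiny lattices.

Sites are 0-based coordinate tuples in row-major (raster) order; most
internals work on flattened (raster) site indices for speed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConfigurationError,
    LatticeBoundsError,
    StateSpaceCapExceeded,
    UnknownIndexError,
)

MEDIUM_INDEX = 0
MEDIUM_TYPE = "medium"

DEFAULT_STATE_CAP = 10**6


@dataclass(frozen=True)
class Neighborhood:
    """A translation-invariant neighborhood template.

    ``von_neumann`` of order ``r`` contains all offsets with L1 norm <= r,
    ``moore`` all offsets with Chebyshev norm <= r (the origin excluded).
    """

    kind: str = "von_neumann"
    order: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("von_neumann", "moore"):
            raise ConfigurationError(f"unknown neighborhood kind {self.kind!r}")
        if self.order < 1:
            raise ConfigurationError("neighborhood order must be >= 1")

    def offsets(self, ndim: int) -> list[tuple[int, ...]]:
        """Offsets in a deterministic (lexicographic) order."""
        r = self.order
        out = []
        for off in itertools.product(range(-r, r + 1), repeat=ndim):
            if all(o == 0 for o in off):
                continue
            if self.kind == "von_neumann" and sum(abs(o) for o in off) > r:
                continue
            out.append(off)
        return sorted(out)


class Lattice:
    """A finite d-dimensional regular lattice (d in {1, 2, 3}).

    Parameters
    ----------
    dimensions:
        Side lengths per axis; the total site count is their product (>= 2).
    boundary:
        ``"periodic"`` wraps every axis onto a torus; ``"fixed"`` truncates
        neighbor lists at the faces.
    copy_neighborhood:
        Neighborhood used when drawing the copy source of a Metropolis
        attempt.
    interface_neighborhood:
        Neighborhood defining interfaces (pairs of neighboring sites with
        different indices).  Defaults to the copy neighborhood; the two are
        independently configurable because published models differ here.

    Notes
    -----
    Offsets that wrap onto the same site (tiny periodic lattices) are
    deduplicated and the site itself is never its own neighbor, so neighbor
    lists always contain distinct other sites.
    """

    def __init__(
        self,
        dimensions: Sequence[int],
        boundary: str = "periodic",
        copy_neighborhood: Neighborhood | None = None,
        interface_neighborhood: Neighborhood | None = None,
    ) -> None:
        dims = tuple(int(d) for d in dimensions)
        if not dims or any(d < 1 for d in dims):
            raise ConfigurationError("dimensions must be positive integers")
        if len(dims) > 3:
            raise ConfigurationError("only 1-, 2- and 3-D lattices are supported")
        if int(np.prod(dims)) < 2:
            raise ConfigurationError("lattice must contain at least 2 sites")
        if boundary not in ("periodic", "fixed"):
            raise ConfigurationError(f"unknown boundary mode {boundary!r}")
        self.dimensions = dims
        self.boundary = boundary
        self.copy_neighborhood = copy_neighborhood or Neighborhood()
        self.interface_neighborhood = interface_neighborhood or self.copy_neighborhood
        self.n_sites = int(np.prod(dims))
        self._strides = tuple(
            int(np.prod(dims[i + 1 :], initial=1)) for i in range(len(dims))
        )
        self._copy_neighbors = self._build_neighbors(self.copy_neighborhood)
        self._interface_neighbors = self._build_neighbors(self.interface_neighborhood)
        self._interface_pair_array = self._build_pairs(self._interface_neighbors)
        self._frame_deficit = self._build_frame_deficit()
        if any(len(nb) == 0 for nb in self._copy_neighbors):
            raise ConfigurationError("every site must have at least one neighbor")

    # -- geometry ---------------------------------------------------------

    def _build_neighbors(self, hood: Neighborhood) -> list[np.ndarray]:
        dims = self.dimensions
        offsets = hood.offsets(len(dims))
        neighbors: list[np.ndarray] = []
        for flat in range(self.n_sites):
            coord = self.flat_to_site(flat)
            seen: list[int] = []
            for off in offsets:
                c = [a + b for a, b in zip(coord, off)]
                if self.boundary == "periodic":
                    c = [x % d for x, d in zip(c, dims)]
                elif any(x < 0 or x >= d for x, d in zip(c, dims)):
                    continue
                f = self.site_to_flat(tuple(c))
                if f != flat and f not in seen:
                    seen.append(f)
            neighbors.append(np.asarray(seen, dtype=np.int64))
        return neighbors

    def _build_frame_deficit(self) -> np.ndarray:
        """Per site: interface-neighborhood offsets that leave a fixed lattice.

        Under fixed boundary the confining environment is modeled as a frozen
        medium frame: each out-of-bounds interface offset is one contact with
        the frame, which the surface term charges at the cell-medium
        coefficient.  Zero everywhere on a torus.
        """
        deficit = np.zeros(self.n_sites, dtype=np.int64)
        if self.boundary == "fixed":
            dims = self.dimensions
            offsets = self.interface_neighborhood.offsets(len(dims))
            for flat in range(self.n_sites):
                coord = self.flat_to_site(flat)
                deficit[flat] = sum(
                    1
                    for off in offsets
                    if any(
                        x + o < 0 or x + o >= d for x, o, d in zip(coord, off, dims)
                    )
                )
        return deficit

    @property
    def frame_deficit(self) -> np.ndarray:
        return self._frame_deficit

    @staticmethod
    def _build_pairs(neighbors: list[np.ndarray]) -> np.ndarray:
        pairs = [
            (x, int(y))
            for x, nbrs in enumerate(neighbors)
            for y in nbrs
            if int(y) > x
        ]
        return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)

    def site_to_flat(self, site: tuple[int, ...]) -> int:
        return int(sum(c * s for c, s in zip(site, self._strides)))

    def flat_to_site(self, flat: int) -> tuple[int, ...]:
        return tuple(int(x) for x in np.unravel_index(flat, self.dimensions))

    def _as_flat(self, site) -> int:
        if isinstance(site, tuple):
            if len(site) != len(self.dimensions) or any(
                c < 0 or c >= d for c, d in zip(site, self.dimensions)
            ):
                raise LatticeBoundsError(f"site {site} outside lattice {self.dimensions}")
            return self.site_to_flat(site)
        flat = int(site)
        if flat < 0 or flat >= self.n_sites:
            raise LatticeBoundsError(f"site {flat} outside lattice of {self.n_sites} sites")
        return flat

    def neighbors(self, site, which: str = "copy"):
        """Neighbor list of ``site`` (deterministic order, symmetric relation).

        ``site`` may be a coordinate tuple or a flat raster index; the return
        type matches the input.  ``which`` selects the copy or interface
        neighborhood.
        """
        flat = self._as_flat(site)
        arr = (self._copy_neighbors if which == "copy" else self._interface_neighbors)[flat]
        if isinstance(site, tuple):
            return [self.flat_to_site(int(f)) for f in arr]
        return [int(f) for f in arr]

    def copy_neighbor_array(self, flat: int) -> np.ndarray:
        return self._copy_neighbors[flat]

    def interface_neighbor_array(self, flat: int) -> np.ndarray:
        return self._interface_neighbors[flat]

    @property
    def interface_pair_array(self) -> np.ndarray:
        """All unordered site pairs {x, y} with y in N_interface(x), as rows (x, y), x < y."""
        return self._interface_pair_array

    def degrees(self, which: str = "copy") -> np.ndarray:
        nbrs = self._copy_neighbors if which == "copy" else self._interface_neighbors
        return np.asarray([len(a) for a in nbrs], dtype=np.int64)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Lattice(dimensions={self.dimensions}, boundary={self.boundary!r}, "
            f"copy={self.copy_neighborhood}, interface={self.interface_neighborhood})"
        )


class CellIndexModel:
    """The cell-index set Sigma = {0, ..., K} with the type map tau.

    Index 0 is reserved for the medium and always maps to the medium type;
    indices 1..K are biological cells, each with a type from the type set
    Lambda that determines its interaction parameters.
    """

    def __init__(
        self,
        K: int,
        type_map: Mapping[int, str] | None = None,
        medium_type: str = MEDIUM_TYPE,
    ) -> None:
        if K < 1:
            raise ConfigurationError("K must be >= 1 (at least one cell)")
        self.K = int(K)
        self.medium_type = medium_type
        tmap = {0: medium_type}
        for i in range(1, self.K + 1):
            if type_map is not None and i in type_map:
                tmap[i] = str(type_map[i])
            elif type_map is not None:
                raise ConfigurationError(f"type_map missing cell index {i}")
            else:
                tmap[i] = "cell"
        if type_map is not None and any(i < 1 or i > self.K for i in type_map):
            raise ConfigurationError("type_map keys must lie in 1..K")
        if medium_type in set(tmap[i] for i in range(1, self.K + 1)):
            raise ConfigurationError("medium type label may not be reused for cells")
        self._type_map = tmap

    @property
    def indices(self) -> range:
        return range(self.K + 1)

    @property
    def type_set(self) -> frozenset[str]:
        """Lambda: the set of (non-medium) cell types."""
        return frozenset(self._type_map[i] for i in range(1, self.K + 1))

    def type_of(self, index: int) -> str:
        if index not in self._type_map:
            raise UnknownIndexError(f"cell index {index} outside Sigma = 0..{self.K}")
        return self._type_map[index]

    def validate_index(self, index: int) -> int:
        index = int(index)
        if index < 0 or index > self.K:
            raise UnknownIndexError(f"cell index {index} outside Sigma = 0..{self.K}")
        return index

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "medium_type": self.medium_type,
            "types": {i: self._type_map[i] for i in range(1, self.K + 1)},
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CellIndexModel(K={self.K}, types={dict(self._type_map)})"


class Configuration:
    """An assignment eta of a cell index to every lattice site.

    ``values`` is the flat (raster-order) integer array of cell indices; the
    ``grid`` property exposes it in lattice shape.  Per-index volumes are
    cached and maintained incrementally under single-site updates, which keeps
    the Metropolis inner loop and the volume-constraint energy cheap.
    """

    __slots__ = ("lattice", "cells", "values", "_volumes")

    def __init__(
        self,
        lattice: Lattice,
        cells: CellIndexModel,
        values: Iterable[int],
        _validate: bool = True,
    ) -> None:
        arr = np.asarray(values, dtype=np.int64).reshape(-1)
        if _validate:
            if arr.size != lattice.n_sites:
                raise ConfigurationError(
                    f"configuration has {arr.size} values for {lattice.n_sites} sites"
                )
            if arr.min(initial=0) < 0 or arr.max(initial=0) > cells.K:
                raise ConfigurationError("cell indices must lie in 0..K")
        self.lattice = lattice
        self.cells = cells
        self.values = arr
        self._volumes = np.bincount(arr, minlength=cells.K + 1)

    # -- mutation ---------------------------------------------------------

    def set_site(self, site, index: int) -> None:
        """In-place single-site update (keeps the volume cache consistent)."""
        flat = self.lattice._as_flat(site)
        index = self.cells.validate_index(index)
        old = int(self.values[flat])
        if old == index:
            return
        self.values[flat] = index
        self._volumes[old] -= 1
        self._volumes[index] += 1

    def copy(self) -> "Configuration":
        return Configuration(self.lattice, self.cells, self.values.copy(), _validate=False)

    def with_site(self, site, index: int) -> "Configuration":
        trial = self.copy()
        trial.set_site(site, index)
        return trial

    # -- observables ------------------------------------------------------

    @property
    def grid(self) -> np.ndarray:
        return self.values.reshape(self.lattice.dimensions)

    def volume(self, index: int) -> int:
        return int(self._volumes[self.cells.validate_index(index)])

    def volumes(self) -> np.ndarray:
        """Vector of volumes V_i for i = 0..K (sums to the site count)."""
        return self._volumes.copy()

    def surface_length(self, index: int) -> int:
        return cell_surface_length(self, index)

    def present_indices(self) -> frozenset[int]:
        return present_indices(self)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Configuration)
            and self.lattice.dimensions == other.lattice.dimensions
            and bool(np.array_equal(self.values, other.values))
        )

    def __hash__(self) -> int:
        return hash((self.lattice.dimensions, self.values.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Configuration({self.grid.tolist()})"


# -- elementary observables (module-level operation surface) ---------------


def neighbors(lattice: Lattice, site, which: str = "copy"):
    """Neighbor sites of ``site``; see :meth:`Lattice.neighbors`."""
    return lattice.neighbors(site, which=which)


def interface_pairs(config: Configuration) -> set[tuple[int, int]]:
    """All unordered interface pairs of the configuration.

    An interface is a pair of interface-neighborhood neighbors {x, y} whose
    sites carry different cell indices.  Pairs are returned as flat-index
    tuples (x, y) with x < y, so each unordered pair appears exactly once.
    """
    pairs = config.lattice.interface_pair_array
    vals = config.values
    if pairs.size == 0:
        return set()
    mask = vals[pairs[:, 0]] != vals[pairs[:, 1]]
    return {(int(x), int(y)) for x, y in pairs[mask]}


def cell_volume(config: Configuration, index: int) -> int:
    """V_i(eta): number of sites carrying ``index`` (Kronecker-delta sum)."""
    return config.volume(index)


def cell_surface_length(config: Configuration, index: int) -> int:
    """s_i(eta): number of interface pairs with at least one member in cell ``index``."""
    index = config.cells.validate_index(index)
    pairs = config.lattice.interface_pair_array
    if pairs.size == 0:
        return 0
    vals = config.values
    a = vals[pairs[:, 0]]
    b = vals[pairs[:, 1]]
    return int(np.sum((a != b) & ((a == index) | (b == index))))


def present_indices(config: Configuration) -> frozenset[int]:
    """The set A of cell indices with positive volume (always nonempty)."""
    return frozenset(int(i) for i in np.nonzero(config._volumes)[0])


# -- exhaustive state-space enumeration -------------------------------------


class StateSpace:
    """Bijection between 0..(K+1)^|S|-1 and the configuration space Omega.

    States are encoded base-(K+1) with raster site order (site 0 is the most
    significant digit).  Enumeration refuses to run above ``cap`` states so a
    careless model choice cannot trigger an exponential blow-up; the exact
    chain analysis is a tiny-lattice tool by design.
    """

    def __init__(
        self,
        lattice: Lattice,
        cells: CellIndexModel,
        cap: int = DEFAULT_STATE_CAP,
    ) -> None:
        self.lattice = lattice
        self.cells = cells
        self.base = cells.K + 1
        n_states = self.base**lattice.n_sites
        if n_states > cap:
            raise StateSpaceCapExceeded(
                f"state space has {n_states} = {self.base}^{lattice.n_sites} states, "
                f"above the cap of {cap}"
            )
        self.n_states = int(n_states)
        self._place = self.base ** np.arange(lattice.n_sites - 1, -1, -1, dtype=np.int64)

    def encode(self, config: Configuration | np.ndarray) -> int:
        vals = config.values if isinstance(config, Configuration) else np.asarray(config)
        return int(np.dot(vals.reshape(-1), self._place))

    def decode_values(self, code: int) -> np.ndarray:
        if code < 0 or code >= self.n_states:
            raise LatticeBoundsError(f"state code {code} outside 0..{self.n_states - 1}")
        digits = (code // self._place) % self.base
        return digits.astype(np.int64)

    def decode(self, code: int) -> Configuration:
        return Configuration(self.lattice, self.cells, self.decode_values(code), _validate=False)

    def constant_state(self, index: int) -> int:
        """Code of the constant-``index`` configuration (an absorbing state)."""
        index = self.cells.validate_index(index)
        return self.encode(np.full(self.lattice.n_sites, index, dtype=np.int64))

    def present_of(self, code: int) -> frozenset[int]:
        return frozenset(int(i) for i in np.unique(self.decode_values(code)))

    def __len__(self) -> int:
        return self.n_states


def enumerate_state_space(
    lattice: Lattice, cells: CellIndexModel, cap: int = DEFAULT_STATE_CAP
) -> StateSpace:
    """Enumerate Omega = Sigma^S; refuses above ``cap`` states."""
    return StateSpace(lattice, cells, cap=cap)


# -- plain-text grid serialization ------------------------------------------


def write_grid(config: Configuration, path: str | Path) -> None:
    """Write a configuration as a plain-text integer grid.

    Format: a header line ``# dims=AxBxC boundary=<mode> K=<K>`` followed by
    one row of space-separated integers per lattice row (a single row for
    1-D; 3-D grids are written as stacked rows of the last axis).
    """
    lat = config.lattice
    dims = "x".join(str(d) for d in lat.dimensions)
    rows = config.values.reshape(-1, lat.dimensions[-1])
    with open(path, "w") as fh:
        fh.write(f"# dims={dims} boundary={lat.boundary} K={config.cells.K}\n")
        for row in rows:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_grid(
    path: str | Path,
    copy_neighborhood: Neighborhood | None = None,
    interface_neighborhood: Neighborhood | None = None,
    type_map: Mapping[int, str] | None = None,
) -> Configuration:
    """Read a grid file written by :func:`write_grid` (round-trip identity).

    Neighborhoods and the type map are not part of the file format and may be
    supplied; they default to von Neumann order 1 and a single generic cell
    type.
    """
    with open(path) as fh:
        header = fh.readline().strip()
        body = [line.split() for line in fh if line.strip()]
    fields = dict(
        item.split("=", 1) for item in header.lstrip("#").split() if "=" in item
    )
    try:
        dims = tuple(int(d) for d in fields["dims"].split("x"))
        boundary = fields["boundary"]
        K = int(fields["K"])
    except KeyError as exc:
        raise ConfigurationError(f"grid header missing field: {exc}") from exc
    lattice = Lattice(
        dims,
        boundary=boundary,
        copy_neighborhood=copy_neighborhood,
        interface_neighborhood=interface_neighborhood,
    )
    cells = CellIndexModel(K, type_map=type_map)
    values = np.asarray([[int(v) for v in row] for row in body], dtype=np.int64)
    return Configuration(lattice, cells, values.reshape(-1))
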