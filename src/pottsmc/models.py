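"""Canonical tiny models used by the examples, tests and shipped configs.

These fix the study conditions for the exact-chain experiments:

* ``voter_ring`` — H == 0 on a 1-D periodic ring; the pure multi-type voter
  model whose absorption probabilities are the initial volume fractions.
* ``sorting_2x2`` — a 2x2 periodic lattice with medium plus two cells of
  types A and B under a differential-adhesion surface term (like-type contact
  cheaper than unlike-type) and optionally a weak volume constraint.  At 81
  states it is fully enumerable, yet shows every structural phenomenon:
  broken detailed balance, absorption, a primitive exit-time spectrum.
* ``sorting_demo_16`` — a 16x16 two-type cell-sorting demonstration for
  simulation only (far above the enumeration cap).

Parameter values are illustrative fixtures chosen to keep energy scales of
order one at T = 1 so that copy attempts are neither almost-always accepted
nor essentially frozen.
"""

from __future__ import annotations

from dataclasses import dataclass


from .dynamics import DynamicsParams
from .hamiltonian import (
    ConstraintTerm,
    Hamiltonian,
    SurfaceEnergyMatrix,
    VolumeConstraintParams,
)
from .lattice import MEDIUM_TYPE, CellIndexModel, Configuration, Lattice, Neighborhood


@dataclass
class Model:
    """A bundled lattice + cell model + Hamiltonian + dynamics parameters."""

    lattice: Lattice
    cells: CellIndexModel
    hamiltonian: Hamiltonian
    params: DynamicsParams

    def initial(self, kind: str, seed: int | None = None) -> Configuration:
        from .experiments import generate_initial_config

        return generate_initial_config(kind, self.lattice, self.cells, seed=seed)


def voter_ring(n: int = 4, K: int = 2, seed: int | None = None) -> Model:
    """H == 0 on an n-site periodic ring with K cells plus medium (voter limit).

    The copy neighborhood is von Neumann order 2; on the default 4-site ring
    that makes every pair of sites neighbors, so any two configurations with
    the same present indices are mutually reachable by single-site copies and
    the present-index sets are exactly the communication classes.  (With
    nearest-neighbor copying a 1-D ring conserves the cyclic order of cells
    and the class structure fragments; see the methods note.)
    """
    lattice = Lattice((n,), copy_neighborhood=Neighborhood("von_neumann", 2))
    cells = CellIndexModel(K)
    return Model(
        lattice,
        cells,
        Hamiltonian(cells),
        DynamicsParams(temperature=1.0, threshold=0.0, kernel="modified", seed=seed),
    )


def _sorting_surface(j_like: float, j_unlike: float, j_medium: float) -> SurfaceEnergyMatrix:
    return SurfaceEnergyMatrix(
        {
            ("A", "A"): j_like,
            ("B", "B"): j_like,
            ("A", "B"): j_unlike,
            ("A", MEDIUM_TYPE): j_medium,
            ("B", MEDIUM_TYPE): j_medium,
            (MEDIUM_TYPE, MEDIUM_TYPE): 0.0,
        }
    )


def sorting_2x2(
    volume: bool = True,
    temperature: float = 1.0,
    seed: int | None = None,
) -> Model:
    """2x2 periodic lattice, Sigma = {0, 1, 2} with types A and B.

    Differential adhesion: J(A,A) = J(B,B) = 1 < J(A,B) = 2, cell-medium
    contact J = 1.  With ``volume=True`` a weak volume constraint
    (V_T = 1, lambda_V = 0.5 per type) is added; the target is one site so a
    two-cell-plus-medium population fits the four sites.

    The Moore-order-1 neighborhood makes all four torus sites mutual
    neighbors, under which the present-index sets coincide exactly with the
    communication classes (the nearest-neighbor 2x2 torus degenerates to a
    4-cycle, where unreachable proper-coloring states fragment the classes).
    """
    lattice = Lattice((2, 2), copy_neighborhood=Neighborhood("moore", 1))
    cells = CellIndexModel(2, type_map={1: "A", 2: "B"})
    surface = _sorting_surface(1.0, 2.0, 1.0)
    vol = None
    if volume:
        vol = VolumeConstraintParams(
            {"A": ConstraintTerm(1.0, 0.5), "B": ConstraintTerm(1.0, 0.5)}
        )
    ham = Hamiltonian(cells, surface=surface, volume=vol)
    return Model(
        lattice,
        cells,
        ham,
        DynamicsParams(temperature=temperature, threshold=0.0, kernel="modified", seed=seed),
    )


def sorting_demo_16(temperature: float = 4.0, seed: int | None = None) -> Model:
    """16x16 two-type cell-sorting demonstration (simulation only).

    Eight cells of each of two types, GGH-style differential adhesion with
    target volume 16 per cell; illustrative parameter values.
    """
    lattice = Lattice((16, 16))
    K = 16
    type_map = {i: ("A" if i <= K // 2 else "B") for i in range(1, K + 1)}
    cells = CellIndexModel(K, type_map=type_map)
    surface = _sorting_surface(2.0, 11.0, 16.0)
    vol = VolumeConstraintParams(
        {"A": ConstraintTerm(16.0, 1.0), "B": ConstraintTerm(16.0, 1.0)}
    )
    ham = Hamiltonian(cells, surface=surface, volume=vol)
    return Model(
        lattice,
        cells,
        ham,
        DynamicsParams(temperature=temperature, threshold=0.0, kernel="modified", seed=seed),
    )
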