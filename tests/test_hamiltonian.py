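"""Energy terms, additivity, and incremental-vs-full Delta-H consistency."""

import numpy as np
import pytest

from pottsmc import (
    CellIndexModel,
    Configuration,
    ConstraintTerm,
    Hamiltonian,
    Lattice,
    SurfaceConstraintParams,
    SurfaceEnergyMatrix,
    VolumeConstraintParams,
)
from pottsmc.errors import ConfigurationError, MissingInteractionError


@pytest.fixture
def cellsAB():
    return CellIndexModel(2, type_map={1: "A", 2: "B"})


@pytest.fixture
def surfaceJ():
    return SurfaceEnergyMatrix(
        {
            ("A", "A"): 1.0,
            ("B", "B"): 1.0,
            ("A", "B"): 3.0,
            ("A", "medium"): 2.0,
            ("B", "medium"): 2.0,
            ("medium", "medium"): 0.0,
        }
    )


@pytest.fixture
def full_hamiltonian(cellsAB, surfaceJ):
    return Hamiltonian(
        cellsAB,
        surface=surfaceJ,
        volume=VolumeConstraintParams(
            {"A": ConstraintTerm(3.0, 0.5), "B": ConstraintTerm(3.0, 1.0)}
        ),
        surface_constraint=SurfaceConstraintParams(
            {"A": ConstraintTerm(4.0, 0.25), "B": ConstraintTerm(4.0, 0.25)}
        ),
    )


def random_config(cells, seed, lattice=None):
    lattice = lattice or Lattice((3, 3))
    rng = np.random.default_rng(seed)
    return Configuration(lattice, cells, rng.integers(0, cells.K + 1, size=lattice.n_sites))


class TestSurfaceEnergyMatrix:
    def test_symmetry_enforced(self):
        with pytest.raises(ConfigurationError):
            SurfaceEnergyMatrix({("A", "B"): 1.0, ("B", "A"): 2.0})

    def test_symmetric_lookup(self, surfaceJ):
        assert surfaceJ.get("A", "B") == surfaceJ.get("B", "A") == 3.0

    def test_missing_pair_raises(self, cellsAB, surfaceJ):
        ham = Hamiltonian(cellsAB, surface=surfaceJ)
        with pytest.raises(MissingInteractionError):
            surfaceJ.get("A", "C")
        with pytest.raises(MissingInteractionError):
            Hamiltonian(
                CellIndexModel(2, type_map={1: "A", 2: "C"}),
                surface=surfaceJ,
            )

    def test_dict_roundtrip(self, surfaceJ):
        again = SurfaceEnergyMatrix.from_dict(surfaceJ.to_dict())
        assert again.get("A", "medium") == 2.0


class TestTermEnergies:
    def test_constant_configuration_surface_energy_zero(self, cellsAB, surfaceJ):
        ham = Hamiltonian(cellsAB, surface=surfaceJ)
        config = Configuration(Lattice((4,)), cellsAB, [1] * 4)
        assert ham.surface_energy(config) == 0.0

    def test_two_arc_ring_counts_interfaces_times_coefficient(self, cellsAB, surfaceJ):
        ham = Hamiltonian(cellsAB, surface=surfaceJ)
        config = Configuration(Lattice((4,)), cellsAB, [1, 1, 2, 2])
        # two A|B interfaces at J(A,B) = 3
        assert ham.surface_energy(config) == pytest.approx(6.0)

    def test_zero_matrix_gives_zero(self, cellsAB):
        J0 = SurfaceEnergyMatrix(
            {(a, b): 0.0 for a in ("A", "B", "medium") for b in ("A", "B", "medium")}
        )
        ham = Hamiltonian(cellsAB, surface=J0)
        assert ham.surface_energy(random_config(cellsAB, 0)) == 0.0

    def test_volume_energy_quadratic_deviation(self, cellsAB):
        ham = Hamiltonian(
            cellsAB,
            volume=VolumeConstraintParams(
                {"A": ConstraintTerm(4.0, 0.5), "B": ConstraintTerm(4.0, 0.0)}
            ),
        )
        # cell 1 (type A) has volume 2, target 4, strength 0.5 -> 0.5 * 4 = 2
        config = Configuration(Lattice((4,)), cellsAB, [1, 1, 2, 2])
        assert ham.volume_energy(config) == pytest.approx(2.0)

    def test_volume_at_target_is_zero(self, cellsAB):
        ham = Hamiltonian(
            cellsAB,
            volume=VolumeConstraintParams(
                {"A": ConstraintTerm(4.0, 1.0), "B": ConstraintTerm(0.0, 1.0)}
            ),
        )
        config = Configuration(Lattice((4,)), cellsAB, [1, 1, 1, 1])
        assert ham.volume_energy(config) == 0.0

    def test_surface_constraint_formula(self, cellsAB):
        ham = Hamiltonian(
            cellsAB,
            surface_constraint=SurfaceConstraintParams(
                {"A": ConstraintTerm(4.0, 1.0), "B": ConstraintTerm(2.0, 0.0)}
            ),
        )
        # cell 1 has s = 2 on the two-arc ring, target 4, strength 1 -> 4
        config = Configuration(Lattice((4,)), cellsAB, [1, 1, 2, 2])
        assert ham.surface_constraint_energy(config) == pytest.approx(4.0)

    def test_fixed_boundary_charges_frozen_medium_frame(self, cellsAB, surfaceJ):
        # 3x3 fixed boundary, all-A configuration: no interior interfaces,
        # but 4 corners x 2 + 4 edge sites x 1 = 12 frame contacts at
        # J(A, medium) = 2
        ham = Hamiltonian(cellsAB, surface=surfaceJ)
        lat = Lattice((3, 3), boundary="fixed")
        config = Configuration(lat, cellsAB, [1] * 9)
        assert ham.surface_energy(config) == pytest.approx(24.0)
        # incremental delta stays consistent with full recomputation
        for site in (0, 4, 5):
            for new in (0, 2):
                assert ham.delta(config, site, new) == pytest.approx(
                    ham.delta_full(config, site, new), abs=1e-12
                )

    def test_medium_excluded_unless_flagged(self, cellsAB):
        per_type = {
            "A": ConstraintTerm(1.0, 1.0),
            "B": ConstraintTerm(1.0, 1.0),
            "medium": ConstraintTerm(0.0, 1.0),
        }
        config = Configuration(Lattice((4,)), cellsAB, [0, 0, 1, 2])
        excl = Hamiltonian(cellsAB, volume=VolumeConstraintParams(per_type))
        incl = Hamiltonian(
            cellsAB, volume=VolumeConstraintParams(per_type, include_medium=True)
        )
        assert excl.volume_energy(config) == pytest.approx(0.0)
        # medium has volume 2, target 0 -> adds 4
        assert incl.volume_energy(config) == pytest.approx(4.0)


class TestTotalEnergy:
    def test_empty_spec_is_zero(self, cellsAB):
        assert Hamiltonian(cellsAB).energy(random_config(cellsAB, 1)) == 0.0

    def test_single_term_equals_term(self, cellsAB, surfaceJ):
        ham = Hamiltonian(cellsAB, surface=surfaceJ)
        config = random_config(cellsAB, 2)
        assert ham.energy(config) == ham.surface_energy(config)

    @pytest.mark.parametrize("seed", range(5))
    def test_additivity(self, full_hamiltonian, cellsAB, seed):
        config = random_config(cellsAB, seed)
        total = (
            full_hamiltonian.surface_energy(config)
            + full_hamiltonian.volume_energy(config)
            + full_hamiltonian.surface_constraint_energy(config)
        )
        assert full_hamiltonian.energy(config) == pytest.approx(total, abs=1e-12)

    def test_translation_invariance_on_torus(self, full_hamiltonian, cellsAB):
        config = random_config(cellsAB, 3)
        grid = config.grid
        for shift in ((1, 0), (0, 2), (2, 1)):
            rolled = Configuration(
                config.lattice, cellsAB, np.roll(grid, shift, axis=(0, 1)).reshape(-1)
            )
            assert full_hamiltonian.energy(rolled) == pytest.approx(
                full_hamiltonian.energy(config), abs=1e-12
            )

    def test_relabeling_equivariance_within_type(self, surfaceJ):
        # two cells of the same type: swapping their indices changes nothing
        cells = CellIndexModel(2, type_map={1: "A", 2: "A"})
        ham = Hamiltonian(
            cells,
            surface=surfaceJ,
            volume=VolumeConstraintParams({"A": ConstraintTerm(2.0, 1.0)}),
        )
        config = random_config(cells, 4)
        swapped_values = np.select(
            [config.values == 1, config.values == 2],
            [2, 1],
            default=config.values,
        )
        swapped = Configuration(config.lattice, cells, swapped_values)
        assert ham.energy(swapped) == pytest.approx(ham.energy(config), abs=1e-12)


class TestDeltaEnergy:
    def test_noop_proposal_is_zero(self, full_hamiltonian, cellsAB):
        config = random_config(cellsAB, 5)
        site = 3
        assert full_hamiltonian.delta(config, site, int(config.values[site])) == 0.0

    def test_zero_hamiltonian_delta_zero(self, cellsAB):
        ham = Hamiltonian(cellsAB)
        config = random_config(cellsAB, 6)
        assert ham.delta(config, 0, 2) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_incremental_matches_full_recomputation(
        self, full_hamiltonian, cellsAB, seed
    ):
        rng = np.random.default_rng(seed)
        config = random_config(cellsAB, seed + 100)
        for _ in range(30):
            site = int(rng.integers(9))
            new = int(rng.integers(3))
            inc = full_hamiltonian.delta(config, site, new)
            full = full_hamiltonian.delta_full(config, site, new)
            assert inc == pytest.approx(full, abs=1e-9)

    def test_surface_only_delta_ignores_far_sites(self, cellsAB, surfaceJ):
        ham = Hamiltonian(cellsAB, surface=surfaceJ)
        lattice = Lattice((8,))
        base = Configuration(lattice, cellsAB, [1, 1, 1, 1, 2, 2, 2, 2])
        d0 = ham.delta(base, 0, 2)
        for far_site in (3, 4, 5):
            for new in (0, 1, 2):
                pert = base.with_site(far_site, new)
                assert ham.delta(pert, 0, 2) == pytest.approx(d0, abs=1e-12)

    def test_volume_delta_depends_on_far_site(self, cellsAB):
        ham = Hamiltonian(
            cellsAB,
            volume=VolumeConstraintParams(
                {"A": ConstraintTerm(4.0, 1.0), "B": ConstraintTerm(4.0, 1.0)}
            ),
        )
        lattice = Lattice((8,))
        base = Configuration(lattice, cellsAB, [1, 1, 1, 1, 2, 2, 2, 2])
        d0 = ham.delta(base, 0, 2)
        pert = base.with_site(4, 0)  # changes cell 2's volume far away
        assert ham.delta(pert, 0, 2) != pytest.approx(d0, abs=1e-12)

    def test_extra_term_enters_energy_and_delta(self, cellsAB):
        ham = Hamiltonian(
            cellsAB,
            extra_term=lambda c: float(c.volume(1) ** 2),
            extra_term_range=None,
        )
        config = random_config(cellsAB, 7)
        assert ham.energy(config) == config.volume(1) ** 2
        site = int(np.nonzero(config.values == 1)[0][0])
        inc = ham.delta(config, site, 0)
        assert inc == pytest.approx(ham.delta_full(config, site, 0), abs=1e-12)
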