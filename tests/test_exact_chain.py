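"""Exact chain analysis: kernel construction, classes, absorption, exit spectrum."""

import math
from dataclasses import replace

import numpy as np
import pytest

from pottsmc import (
    CellIndexModel,
    Configuration,
    ConstraintTerm,
    DynamicsParams,
    Hamiltonian,
    Lattice,
    StateSpace,
    SurfaceEnergyMatrix,
    VolumeConstraintParams,
    absorption_probabilities,
    build_transition_matrix,
    classify_states,
    exact_survival,
    exit_time_spectrum,
    gibbs_measure,
    stationary_distribution,
    stationary_distribution_basis,
    survival_curve,
    voter_transition_matrix,
    zero_hamiltonian,
)
from pottsmc.errors import InternalConsistencyError, PreconditionError
from pottsmc.exact_chain import absorption_by_truncated_sum
from pottsmc.models import sorting_2x2, voter_ring


@pytest.fixture(scope="module")
def sorting_chain():
    model = sorting_2x2()
    ss = StateSpace(model.lattice, model.cells)
    tm = build_transition_matrix(ss, model.hamiltonian, model.params)
    decomp = classify_states(tm)
    return model, ss, tm, decomp


@pytest.fixture(scope="module")
def voter_chain():
    model = voter_ring()
    ss = StateSpace(model.lattice, model.cells)
    tm = build_transition_matrix(ss, model.hamiltonian, model.params)
    decomp = classify_states(tm)
    return model, ss, tm, decomp


class TestBuildTransitionMatrix:
    def test_two_site_voter_kernel_matches_hand_enumeration(self):
        # 2 sites, Sigma = {0, 1}: from (0, 1) either site copies the other's
        # index with probability 1/2 each, so the state jumps to (0,0) or
        # (1,1); the constant states are absorbing.
        lat = Lattice((2,))
        cells = CellIndexModel(1)
        ss = StateSpace(lat, cells)
        tm = build_transition_matrix(
            ss, zero_hamiltonian(cells), DynamicsParams(temperature=math.inf)
        )
        expected = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.5, 0.0, 0.0, 0.5],
                [0.5, 0.0, 0.0, 0.5],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        assert np.abs(tm.P.toarray() - expected).max() == 0.0

    def test_rows_sum_to_one(self, sorting_chain):
        _, _, tm, _ = sorting_chain
        assert np.abs(tm.row_sums() - 1.0).max() < 1e-12

    def test_standard_kernel_rows_sum_to_one(self, sorting_chain):
        model, ss, _, _ = sorting_chain
        tm = build_transition_matrix(
            ss, model.hamiltonian, replace(model.params, kernel="standard")
        )
        assert np.abs(tm.row_sums() - 1.0).max() < 1e-12

    def test_constant_configuration_is_absorbing_row(self, sorting_chain):
        _, ss, tm, _ = sorting_chain
        P = tm.P.toarray()
        for k in range(3):
            s = ss.constant_state(k)
            row = np.zeros(ss.n_states)
            row[s] = 1.0
            assert np.abs(P[s] - row).max() == 0.0


class TestClassification:
    def test_absorbing_states_are_constant_configurations(self, sorting_chain):
        _, ss, _, decomp = sorting_chain
        assert len(decomp.absorbing_states) == 3
        assert decomp.absorbing_states == [ss.constant_state(k) for k in range(3)]

    def test_closed_iff_single_index(self, sorting_chain):
        _, _, _, decomp = sorting_chain
        for A in decomp.classes:
            assert decomp.is_closed(A) == (len(A) == 1)

    def test_class_partition_matches_sccs_on_81_state_chain(self, sorting_chain):
        # classify_states verifies the present-index partition against the
        # strongly-connected components and raises on mismatch, so success
        # plus the expected class census is the assertion
        _, _, _, decomp = sorting_chain
        assert len(decomp.classes) == 7
        sizes = {frozenset(A): len(s) for A, s in decomp.classes.items()}
        assert sizes[frozenset({0})] == 1
        assert sizes[frozenset({0, 1})] == 14
        assert sizes[frozenset({0, 1, 2})] == 36

    def test_transitions_only_into_subsets(self, sorting_chain):
        _, _, tm, decomp = sorting_chain
        coo = tm.P.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            if v > 0:
                assert decomp.labels[int(j)] <= decomp.labels[int(i)]

    def test_nearest_neighbor_ring_fragments_classes(self):
        # with nearest-neighbor copying a ring conserves the cyclic order of
        # cells and proper-coloring states are unreachable, so the
        # present-index sets are strictly coarser than the communication
        # classes; the mismatch must surface as an error, never be patched
        lat = Lattice((4,))
        cells = CellIndexModel(2)
        ss = StateSpace(lat, cells)
        tm = build_transition_matrix(ss, zero_hamiltonian(cells), DynamicsParams())
        with pytest.raises(InternalConsistencyError):
            classify_states(tm)


class TestAbsorption:
    def test_rows_sum_to_one(self, sorting_chain):
        _, _, tm, decomp = sorting_chain
        result = absorption_probabilities(tm, decomp)
        assert np.abs(result.row_sums() - 1.0).max() < 1e-10

    def test_absorbing_state_is_point_mass_on_itself(self, sorting_chain):
        _, ss, tm, decomp = sorting_chain
        result = absorption_probabilities(tm, decomp)
        pi = result.pi(ss.constant_state(2))
        assert pi.tolist() == [0.0, 0.0, 1.0]

    def test_voter_martingale_gives_initial_fractions(self, voter_chain):
        model, ss, tm, decomp = voter_chain
        result = absorption_probabilities(tm, decomp)
        config = Configuration(model.lattice, model.cells, [0, 1, 2, 2])
        pi = result.pi(ss.encode(config))
        assert np.abs(pi - np.array([0.25, 0.25, 0.5])).max() < 1e-10

    def test_linear_solve_agrees_with_truncated_sum(self, sorting_chain):
        _, _, tm, decomp = sorting_chain
        B = absorption_probabilities(tm, decomp).B
        B_sum = absorption_by_truncated_sum(tm, decomp, 10_000)
        assert np.abs(B - B_sum).max() < 1e-8

    def test_pi_vanishes_on_absent_indices(self, voter_chain):
        model, ss, tm, decomp = voter_chain
        result = absorption_probabilities(tm, decomp)
        config = Configuration(model.lattice, model.cells, [1, 1, 2, 2])
        pi = result.pi(ss.encode(config))
        assert pi[0] == 0.0
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestStationaryDistributions:
    def test_point_mass_basis_has_dimension_K_plus_1(self, sorting_chain):
        _, ss, tm, _ = sorting_chain
        basis = stationary_distribution_basis(tm)
        assert len(basis) == 3
        P = tm.P.toarray()
        for delta in basis:
            assert np.abs(delta @ P - delta).max() < 1e-12

    def test_convex_combinations_are_stationary(self, sorting_chain):
        _, _, tm, _ = sorting_chain
        basis = stationary_distribution_basis(tm)
        mix = 0.2 * basis[0] + 0.5 * basis[1] + 0.3 * basis[2]
        assert np.abs(mix @ tm.P.toarray() - mix).max() < 1e-12

    def test_standard_kernel_has_unique_gibbs_stationary_state(self, sorting_chain):
        model, ss, _, _ = sorting_chain
        tm = build_transition_matrix(
            ss, model.hamiltonian, replace(model.params, kernel="standard")
        )
        pi = stationary_distribution(tm)
        mu = gibbs_measure(model.hamiltonian, model.params.temperature, ss)
        assert np.abs(pi - mu.probabilities).max() < 1e-10

    def test_standard_kernel_at_infinite_temperature_is_uniform(self, sorting_chain):
        model, ss, _, _ = sorting_chain
        tm = build_transition_matrix(
            ss,
            model.hamiltonian,
            replace(model.params, kernel="standard", temperature=math.inf),
        )
        pi = stationary_distribution(tm)
        assert np.abs(pi - 1.0 / ss.n_states).max() < 1e-12


class TestExitTime:
    def test_survival_starts_at_one_and_decreases(self, sorting_chain):
        model, ss, tm, decomp = sorting_chain
        init = ss.encode(model.initial("single_site_cells"))
        curve = survival_curve(tm, decomp, init, 200)
        assert curve[0] == 1.0
        assert np.all(np.diff(curve) <= 0)
        assert np.all(curve > 0)
        assert exact_survival(tm, decomp, init, 0) == 1.0

    def test_initial_state_outside_class_rejected(self, sorting_chain):
        _, ss, tm, decomp = sorting_chain
        with pytest.raises(PreconditionError):
            survival_curve(tm, decomp, ss.constant_state(0), 10)

    def test_survival_ratio_converges_to_lambda1(self, sorting_chain):
        model, ss, tm, decomp = sorting_chain
        spectrum = exit_time_spectrum(tm, decomp)
        init = ss.encode(model.initial("single_site_cells"))
        curve = survival_curve(tm, decomp, init, 120)
        ratios = curve[1:] / curve[:-1]
        assert abs(ratios[100] - spectrum.lambda1) / spectrum.lambda1 < 1e-9

    def test_spectrum_properties(self, sorting_chain):
        _, _, tm, decomp = sorting_chain
        spectrum = exit_time_spectrum(tm, decomp)
        assert 0.0 < spectrum.lambda1 < 1.0
        assert spectrum.primitive
        assert spectrum.second_magnitude <= spectrum.lambda1
        assert spectrum.left is not None and spectrum.right is not None
        assert spectrum.left.min() > 0 and spectrum.right.min() > 0
        assert float(spectrum.left @ spectrum.right) == pytest.approx(1.0, abs=1e-10)

    def test_survival_over_lambda1_power_converges_to_constant(self, sorting_chain):
        model, ss, tm, decomp = sorting_chain
        spectrum = exit_time_spectrum(tm, decomp)
        init = ss.encode(model.initial("single_site_cells"))
        curve = survival_curve(tm, decomp, init, 120)
        scaled = curve / spectrum.lambda1 ** np.arange(121)
        assert scaled[120] > 0
        assert abs(scaled[120] - scaled[100]) < 1e-8 * scaled[120]

    def test_voter_spectrum(self, voter_chain):
        _, _, tm, decomp = voter_chain
        spectrum = exit_time_spectrum(tm, decomp)
        assert 0.0 < spectrum.lambda1 < 1.0 and spectrum.primitive


class TestVoterEquivalence:
    def test_modified_kernel_at_infinite_temperature_equals_voter(self, sorting_chain):
        model, ss, _, _ = sorting_chain
        tm = build_transition_matrix(
            ss, model.hamiltonian, replace(model.params, temperature=math.inf)
        )
        V = voter_transition_matrix(ss)
        assert np.abs((tm.P - V).toarray()).max() < 1e-14

    def test_zero_hamiltonian_equals_voter(self, voter_chain):
        model, ss, tm, _ = voter_chain
        V = voter_transition_matrix(ss)
        assert np.abs((tm.P - V).toarray()).max() < 1e-14


class TestRestrictionConsistency:
    def test_chain_restricted_to_class_equals_restricted_model(self):
        # dropping cell 2: the sub-block of the full kernel on configurations
        # using only indices {0, 1} must equal the kernel of the CPM built
        # with K = 1 and the same Hamiltonian parameters, entrywise
        full = sorting_2x2()
        ss_full = StateSpace(full.lattice, full.cells)
        tm_full = build_transition_matrix(ss_full, full.hamiltonian, full.params)

        cells_r = CellIndexModel(1, type_map={1: "A"})
        ham_r = Hamiltonian(
            cells_r,
            surface=full.hamiltonian.surface,
            volume=VolumeConstraintParams({"A": ConstraintTerm(1.0, 0.5)}),
        )
        ss_r = StateSpace(full.lattice, cells_r)
        tm_r = build_transition_matrix(ss_r, ham_r, full.params)

        sub_states = [
            s
            for s in range(ss_full.n_states)
            if ss_full.present_of(s) <= {0, 1}
        ]
        assert len(sub_states) == ss_r.n_states
        P_full = tm_full.P.toarray()
        P_r = tm_r.P.toarray()
        for a, sa in enumerate(sub_states):
            ra = ss_r.encode(ss_full.decode_values(sa))
            for b, sb in enumerate(sub_states):
                rb = ss_r.encode(ss_full.decode_values(sb))
                assert P_full[sa, sb] == pytest.approx(P_r[ra, rb], abs=1e-14)
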