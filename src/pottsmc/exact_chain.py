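"""Exact finite-Markov-chain analysis of CPMs on enumerated tiny state spaces.

On a lattice small enough to enumerate Omega = Sigma^S, the one-step kernel P
of either Metropolis variant can be assembled exactly.  For the modified
(CPM) kernel the communication classes are the sets Sigma_A of configurations
whose present-index set is exactly A; the K+1 constant configurations are the
absorbing states and every other state is transient.  This module constructs
P, verifies the class structure against a graph-theoretic strongly-connected-
component computation, solves for the absorption probabilities (the rows of
B = (I - Q)^(-1) R, which sum to one: absorption is almost sure), exhibits
the K+1-dimensional stationary simplex spanned by the point masses on the
constant configurations, and computes the Perron-Frobenius spectrum of the
substochastic restriction to the all-indices class, whose leading eigenvalue
lambda_1 makes the exit time (the first cell extinction) approximately
geometric with parameter 1 - lambda_1.

Dense linear algebra is used below ~2,000 states, sparse/iterative routines
above; every quantity is cross-checkable against Monte Carlo simulation via
the dynamics module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dynamics import DynamicsParams, acceptance_probability
from .errors import InternalConsistencyError, PreconditionError
from .hamiltonian import Hamiltonian
from .lattice import (  # noqa: F401  (re-exported: StateSpace lives with the lattice)
    CellIndexModel,
    Configuration,
    Lattice,
    StateSpace,
    enumerate_state_space,
)

DENSE_LIMIT = 2000
EIG_TOL = 1e-10


@dataclass
class TransitionMatrix:
    """Exact one-step kernel over an enumerated state space."""

    P: sp.csr_matrix
    state_space: StateSpace
    kernel: str
    params: DynamicsParams

    @property
    def n_states(self) -> int:
        return self.state_space.n_states

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.P.sum(axis=1)).ravel()

    def validate(self, tol: float = 1e-12) -> None:
        if np.max(np.abs(self.row_sums() - 1.0)) > tol:
            raise InternalConsistencyError("transition matrix rows do not sum to 1")
        if self.P.nnz and (self.P.data.min() < 0 or self.P.data.max() > 1 + tol):
            raise InternalConsistencyError("transition probabilities outside [0, 1]")


def build_transition_matrix(
    state_space: StateSpace, spec: Hamiltonian, params: DynamicsParams
) -> TransitionMatrix:
    """Aggregate the algorithm's proposal/acceptance probabilities per state pair.

    For the modified kernel,
    ``P(eta, zeta) = sum_{(x, y): copy gives zeta} 1/|S| * 1/|N(x)| * accept``,
    with all rejected and self-copy mass on the diagonal.  For the standard
    kernel the replacement index is uniform on Sigma instead of copied from a
    neighbor.
    """
    lat = state_space.lattice
    cells = state_space.cells
    n = lat.n_sites
    base = cells.K + 1
    place = state_space._place
    rows: list[int] = []
    cols: list[int] = []
    data: list[float] = []
    for code in range(state_space.n_states):
        config = state_space.decode(code)
        vals = config.values
        diag = 0.0
        off: dict[int, float] = {}
        for x in range(n):
            old = int(vals[x])
            if params.kernel == "modified":
                nbrs = lat.copy_neighbor_array(x)
                proposals = [(int(vals[y]), 1.0 / (n * len(nbrs))) for y in nbrs]
            else:
                proposals = [(k, 1.0 / (n * base)) for k in range(base)]
            for new, prob in proposals:
                if new == old:
                    diag += prob
                    continue
                dh = spec.delta(config, x, new)
                p_acc = acceptance_probability(dh, params)
                if p_acc > 0.0:
                    target = code + (new - old) * int(place[x])
                    off[target] = off.get(target, 0.0) + prob * p_acc
                diag += prob * (1.0 - p_acc)
        for target, prob in off.items():
            rows.append(code)
            cols.append(target)
            data.append(prob)
        if diag > 0.0:
            rows.append(code)
            cols.append(code)
            data.append(diag)
    P = sp.csr_matrix(
        (data, (rows, cols)), shape=(state_space.n_states, state_space.n_states)
    )
    tm = TransitionMatrix(P, state_space, params.kernel, params)
    tm.validate()
    return tm


def voter_transition_matrix(state_space: StateSpace) -> sp.csr_matrix:
    """The multi-type voter kernel, built directly (no Hamiltonian machinery).

    Each attempt picks a target site uniformly and adopts the index of a
    uniformly chosen copy-neighbor, always accepting.  This is the CPM limit
    at infinite temperature (or H == 0) and serves as an independent oracle
    for that equivalence.
    """
    lat = state_space.lattice
    n = lat.n_sites
    place = state_space._place
    rows, cols, data = [], [], []
    for code in range(state_space.n_states):
        vals = state_space.decode_values(code)
        acc: dict[int, float] = {}
        for x in range(n):
            nbrs = lat.copy_neighbor_array(x)
            w = 1.0 / (n * len(nbrs))
            for y in nbrs:
                target = code + (int(vals[y]) - int(vals[x])) * int(place[x])
                acc[target] = acc.get(target, 0.0) + w
        for target, prob in acc.items():
            rows.append(code)
            cols.append(target)
            data.append(prob)
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(state_space.n_states, state_space.n_states)
    )


@dataclass
class ClassDecomposition:
    """Partition of the state space into the present-index classes Sigma_A."""

    state_space: StateSpace
    labels: list[frozenset[int]]  # class label (present-index set) per state
    classes: dict[frozenset[int], list[int]]
    absorbing_states: list[int]  # constant configurations, ordered by index k
    transient_states: list[int]
    permutation: np.ndarray  # absorbing first, then transient

    def is_closed(self, A: frozenset[int]) -> bool:
        """A class Sigma_A is closed iff it consists of a single index."""
        return len(A) == 1

    def is_absorbing_state(self, state: int) -> bool:
        return state in set(self.absorbing_states)

    def block_form(self, P: sp.csr_matrix) -> tuple[np.ndarray, np.ndarray]:
        """(Q_transient_transient, R_transient_absorbing) dense blocks."""
        t = self.transient_states
        a = self.absorbing_states
        Pd = P.toarray()
        return Pd[np.ix_(t, t)], Pd[np.ix_(t, a)]


def classify_states(tm: TransitionMatrix) -> ClassDecomposition:
    """Communication classes by present-index sets, verified against SCCs.

    The label of a state is its present-index set A; the labelled partition
    must coincide with the strongly connected components of the positive-
    transition digraph, otherwise an internal consistency error is raised
    (degenerate kinetics such as T = 0 can break the class structure; that is
    surfaced, never silently patched).
    """
    ss = tm.state_space
    labels = [ss.present_of(code) for code in range(ss.n_states)]
    classes: dict[frozenset[int], list[int]] = {}
    for code, lab in enumerate(labels):
        classes.setdefault(lab, []).append(code)

    G = nx.DiGraph()
    G.add_nodes_from(range(ss.n_states))
    coo = tm.P.tocoo()
    G.add_edges_from(
        (int(i), int(j)) for i, j, v in zip(coo.row, coo.col, coo.data) if v > 0 and i != j
    )
    sccs = {frozenset(c) for c in nx.strongly_connected_components(G)}
    by_label = {frozenset(states) for states in classes.values()}
    if sccs != by_label:
        raise InternalConsistencyError(
            "present-index classes do not match the strongly connected components "
            f"({len(by_label)} index classes vs {len(sccs)} SCCs)"
        )

    absorbing = [ss.constant_state(k) for k in range(ss.cells.K + 1)]
    absorbing_set = set(absorbing)
    transient = [s for s in range(ss.n_states) if s not in absorbing_set]
    # within the transient block, order classes by decreasing |A| so the
    # substochastic block is lower triangular across classes
    transient.sort(key=lambda s: (-len(labels[s]), sorted(labels[s]), s))
    permutation = np.asarray(absorbing + transient, dtype=np.int64)
    return ClassDecomposition(ss, labels, classes, absorbing, transient, permutation)


@dataclass
class AbsorptionResult:
    """Absorption probabilities B and the limiting distribution weights pi_k."""

    B: np.ndarray  # transient x absorbing
    transient_states: list[int]
    absorbing_states: list[int]  # column j corresponds to constant-j configuration
    state_space: StateSpace

    def row_sums(self) -> np.ndarray:
        return self.B.sum(axis=1)

    def pi(self, state: int) -> np.ndarray:
        """Weights pi_k over the K+1 point measures delta_{eta_k}, for any start state."""
        K = self.state_space.cells.K
        out = np.zeros(K + 1)
        if state in self.absorbing_states:
            out[self.absorbing_states.index(state)] = 1.0
            return out
        r = self.transient_states.index(state)
        out[:] = self.B[r]
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "absorbing_states": self.absorbing_states,
            "transient_states": self.transient_states,
            "B": self.B.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def absorption_probabilities(
    tm: TransitionMatrix, decomposition: ClassDecomposition
) -> AbsorptionResult:
    """Solve (I - Q) B = R for the absorption probabilities.

    The linear solve is the production path; the truncated-sum limit
    ``sum_{m<n} Q^m R`` is kept as a test oracle.  Each row of B sums to 1:
    absorption is almost sure from every transient state.
    """
    Q, R = decomposition.block_form(tm.P)
    n_t = Q.shape[0]
    try:
        B = np.linalg.solve(np.eye(n_t) - Q, R)
    except np.linalg.LinAlgError as exc:
        raise InternalConsistencyError(
            "I - Q is singular: a transient class is closed (model/kernel inconsistency)"
        ) from exc
    return AbsorptionResult(
        B,
        decomposition.transient_states,
        decomposition.absorbing_states,
        tm.state_space,
    )


def absorption_by_truncated_sum(
    tm: TransitionMatrix, decomposition: ClassDecomposition, n_terms: int
) -> np.ndarray:
    """Oracle: B as the accumulated coupling block sum_{m<n} Q^m R."""
    Q, R = decomposition.block_form(tm.P)
    acc = np.zeros_like(R)
    term = R.copy()
    for _ in range(n_terms):
        acc += term
        term = Q @ term
    return acc


def stationary_distribution_basis(tm: TransitionMatrix) -> list[np.ndarray]:
    """Extreme points of the stationary simplex of the CPM kernel.

    The left eigenspace of eigenvalue 1 must have dimension exactly K+1 and
    is spanned by the point masses on the K+1 constant configurations; those
    point masses are returned.  A dimension mismatch raises a consistency
    error.
    """
    ss = tm.state_space
    K = ss.cells.K
    Pd = tm.P.toarray()
    eigvals = np.linalg.eigvals(Pd.T)
    dim = int(np.sum(np.abs(eigvals - 1.0) < 1e-8))
    if dim != K + 1:
        raise InternalConsistencyError(
            f"left eigenvalue-1 eigenspace has dimension {dim}, expected K+1 = {K + 1}"
        )
    basis = []
    for k in range(K + 1):
        delta = np.zeros(ss.n_states)
        delta[ss.constant_state(k)] = 1.0
        if np.max(np.abs(delta @ Pd - delta)) > EIG_TOL:
            raise InternalConsistencyError(
                f"point mass on constant-{k} configuration is not stationary"
            )
        basis.append(delta)
    return basis


def stationary_distribution(tm: TransitionMatrix) -> np.ndarray:
    """Unique stationary distribution of an irreducible kernel (standard Metropolis).

    Computed as the normalized left Perron eigenvector of P.
    """
    Pd = tm.P.toarray()
    w, V = np.linalg.eig(Pd.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[i] - 1.0) > 1e-8:
        raise InternalConsistencyError("no eigenvalue 1 found")
    v = np.real(V[:, i])
    v = v * np.sign(v.sum())
    if v.min() < -1e-10:
        raise InternalConsistencyError("stationary eigenvector is not nonnegative")
    v = np.clip(v, 0.0, None)
    return v / v.sum()


# -- exit time from the all-indices class -----------------------------------


def _all_indices_class(
    tm: TransitionMatrix, decomposition: ClassDecomposition
) -> tuple[list[int], np.ndarray]:
    ss = tm.state_space
    full = frozenset(range(ss.cells.K + 1))
    if full not in decomposition.classes:
        raise PreconditionError("no configuration contains all indices on this lattice")
    states = decomposition.classes[full]
    U = tm.P.toarray()[np.ix_(states, states)]
    return states, U


def exact_survival(
    tm: TransitionMatrix,
    decomposition: ClassDecomposition,
    initial_state: int,
    n: int,
) -> float:
    """P(exit time > n) from ``initial_state`` in the all-indices class Sigma_Sigma.

    Equals the row sum of the n-th power of the substochastic restriction;
    non-increasing in n and in (0, 1].
    """
    return float(survival_curve(tm, decomposition, initial_state, n)[n])


def survival_curve(
    tm: TransitionMatrix,
    decomposition: ClassDecomposition,
    initial_state: int,
    n_max: int,
) -> np.ndarray:
    """Exact survival function of the exit time for n = 0..n_max."""
    states, U = _all_indices_class(tm, decomposition)
    if initial_state not in states:
        raise PreconditionError(
            "initial state must lie in the all-indices class Sigma_Sigma"
        )
    v = np.zeros(len(states))
    v[states.index(initial_state)] = 1.0
    out = np.empty(n_max + 1)
    out[0] = 1.0
    for m in range(1, n_max + 1):
        v = v @ U
        out[m] = v.sum()
    return out


@dataclass
class ExitTimeSpectrum:
    """Perron-Frobenius data of the substochastic all-indices restriction.

    When the restriction is primitive (irreducible and aperiodic), lambda_1
    is the real leading eigenvalue in (0, 1), both Perron eigenvectors are
    strictly positive, and the exit time is approximately geometric with
    parameter 1 - lambda_1.  Non-primitivity is a reported state (the
    geometric claim is then inapplicable), not an error.
    """

    states: list[int]
    restriction: np.ndarray
    lambda1: float
    left: np.ndarray | None
    right: np.ndarray | None
    primitive: bool
    second_magnitude: float

    @property
    def geometric_parameter(self) -> float:
        return 1.0 - self.lambda1

    @property
    def geometric_applicable(self) -> bool:
        return self.primitive

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "states": self.states,
            "lambda1": self.lambda1,
            "geometric_parameter": self.geometric_parameter,
            "primitive": self.primitive,
            "second_magnitude": self.second_magnitude,
            "left": None if self.left is None else self.left.tolist(),
            "right": None if self.right is None else self.right.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def exit_time_spectrum(
    tm: TransitionMatrix, decomposition: ClassDecomposition
) -> ExitTimeSpectrum:
    """Leading eigenvalue and Perron eigenvectors of the Sigma_Sigma restriction."""
    states, U = _all_indices_class(tm, decomposition)
    G = nx.DiGraph()
    G.add_nodes_from(range(len(states)))
    nz = np.argwhere(U > 0)
    G.add_edges_from((int(i), int(j)) for i, j in nz)
    irreducible = nx.is_strongly_connected(G)
    primitive = irreducible and nx.is_aperiodic(G)

    if U.shape[0] <= DENSE_LIMIT:
        w, V = np.linalg.eig(U)
        wl, W = np.linalg.eig(U.T)
    else:  # pragma: no cover - exercised only on large enumerations
        k = min(6, U.shape[0] - 2)
        w, V = spla.eigs(sp.csr_matrix(U), k=k)
        wl, W = spla.eigs(sp.csr_matrix(U).T, k=k)
    order = np.argsort(-np.abs(w))
    lam1 = w[order[0]]
    second = float(np.abs(w[order[1]])) if len(w) > 1 else 0.0
    if abs(lam1.imag) > EIG_TOL:
        raise InternalConsistencyError("leading eigenvalue is not real")
    lam1 = float(lam1.real)

    left = right = None
    if primitive:
        right = np.real(V[:, order[0]])
        il = int(np.argmin(np.abs(wl - lam1)))
        left = np.real(W[:, il])
        right = right * np.sign(right[np.argmax(np.abs(right))])
        left = left * np.sign(left[np.argmax(np.abs(left))])
        if right.min() <= 0 or left.min() <= 0:
            raise InternalConsistencyError(
                "Perron eigenvectors of a primitive restriction must be positive"
            )
        # normalize: right sums to 1, inner product <left, right> = 1
        right = right / right.sum()
        left = left / float(left @ right)
    return ExitTimeSpectrum(states, U, lam1, left, right, primitive, second)
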