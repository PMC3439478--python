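"""Metropolis-type kinetics of the cellular Potts model.

The *modified* Metropolis kernel is the CPM definition: draw a target site
uniformly, draw the replacement index from a uniformly chosen copy-neighbor
of the target, and accept with probability 1 if the energy gain Delta-H lies
below the threshold Delta, else with a thresholded exponential of -Delta-H/T.
The *standard* Metropolis kernel draws the replacement index uniformly from
the whole index set Sigma instead; it is the equilibrium sampler of the Gibbs
measure and serves as the contrast for the diagnostics module.

At infinite temperature (or H == 0) every proposal is accepted and the
modified kernel reduces to the multi-type voter model, whose exact kernel the
analysis module constructs independently.

Time is counted in elementary copy attempts; one Monte Carlo step (MCS) is
|S| attempts and is reported alongside.  A single seeded generator with a
fixed draw order (target site, then neighbor/index, then acceptance uniform)
makes trajectories bit-reproducible.  No "no-extinction" patch rule is
implemented: faithfulness to the definition, including the consecutive
extinction of cells, is the point of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path


import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, PreconditionError
from .hamiltonian import Hamiltonian
from .lattice import Configuration

INF = math.inf


@dataclass(frozen=True)
class DynamicsParams:
    """Kinetic parameters of a CPM chain.

    temperature:
        T > 0 or +inf.  +inf accepts every proposal (voter limit); T -> 0 is
        handled as the limit: accept iff Delta-H < threshold.
    threshold:
        The transition threshold Delta (0 in the original model; small
        positive values appear in the literature).
    convention:
        ``"shifted"``: accept with exp(-(dH - Delta)/T), continuous at
        dH = Delta; ``"unshifted"``: min(1, exp(-dH/T)).  Both conventions
        circulate in the literature, neither is asserted as canonical.
    kernel:
        ``"modified"`` (the CPM) or ``"standard"`` (Gibbs sampler contrast).
    """

    temperature: float = 1.0
    threshold: float = 0.0
    convention: str = "shifted"
    kernel: str = "modified"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (self.temperature > 0 or self.temperature == INF) and self.temperature != 0.0:
            raise ConfigurationError("temperature must be positive, zero (limit) or +inf")
        if self.temperature < 0:
            raise ConfigurationError("temperature must be nonnegative")
        if self.convention not in ("shifted", "unshifted"):
            raise ConfigurationError(f"unknown acceptance convention {self.convention!r}")
        if self.kernel not in ("modified", "standard"):
            raise ConfigurationError(f"unknown kernel {self.kernel!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def with_seed(self, seed: int) -> "DynamicsParams":
        return replace(self, seed=seed)


def acceptance_probability(delta_h: float, params: DynamicsParams) -> float:
    """Probability of accepting a proposal with energy gain ``delta_h``.

    Always in [0, 1]: 1 below the threshold; above it a thresholded
    exponential (clamped at 1), with the T = 0 and T = +inf limits accepting
    never resp. always.
    """
    if delta_h < params.threshold:
        return 1.0
    T = params.temperature
    if T == INF:
        return 1.0
    if T == 0.0:
        return 0.0
    if params.convention == "shifted":
        p = math.exp(-(delta_h - params.threshold) / T)
    else:
        p = math.exp(-delta_h / T)
    return min(1.0, p)


@dataclass(frozen=True)
class ProposalRecord:
    """Bookkeeping for a single copy attempt."""

    target: int
    old_index: int
    new_index: int
    delta_h: float
    accept_prob: float
    accepted: bool


def attempt_copy(
    config: Configuration,
    spec: Hamiltonian,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> tuple[Configuration, bool, ProposalRecord]:
    """One elementary step of the modified Metropolis algorithm (in place).

    Draw order: target site, copy neighbor, acceptance uniform.  A proposal
    whose source index equals the target's is a no-op self-loop but still
    consumes one step (and all three draws).  Only transitions changing at
    most one site are possible.
    """
    lat = config.lattice
    x = int(rng.integers(lat.n_sites))
    nbrs = lat.copy_neighbor_array(x)
    y = int(nbrs[rng.integers(len(nbrs))])
    u = rng.random()
    old = int(config.values[x])
    new = int(config.values[y])
    if new == old:
        rec = ProposalRecord(x, old, new, 0.0, 1.0, True)
        return config, True, rec
    dh = spec.delta(config, x, new)
    p = acceptance_probability(dh, params)
    accepted = u < p
    if accepted:
        config.set_site(x, new)
    return config, accepted, ProposalRecord(x, old, new, dh, p, accepted)


def standard_metropolis_attempt(
    config: Configuration,
    spec: Hamiltonian,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> tuple[Configuration, bool, ProposalRecord]:
    """One step of the standard Metropolis algorithm (replacement index uniform on Sigma)."""
    lat = config.lattice
    x = int(rng.integers(lat.n_sites))
    new = int(rng.integers(config.cells.K + 1))
    u = rng.random()
    old = int(config.values[x])
    if new == old:
        return config, True, ProposalRecord(x, old, new, 0.0, 1.0, True)
    dh = spec.delta(config, x, new)
    p = acceptance_probability(dh, params)
    accepted = u < p
    if accepted:
        config.set_site(x, new)
    return config, accepted, ProposalRecord(x, old, new, dh, p, accepted)


def _stepper(params: DynamicsParams):
    return attempt_copy if params.kernel == "modified" else standard_metropolis_attempt


@dataclass
class TrajectoryRecord:
    """State summary at one recording point."""

    step: int
    mcs: float
    energy: float
    surviving_index_count: int
    volumes: np.ndarray
    snapshot: np.ndarray | None = None


@dataclass
class Trajectory:
    """Recorded summaries of a simulated chain plus its final configuration."""

    records: list[TrajectoryRecord]
    final: Configuration
    extinctions: list[tuple[int, int]] = field(default_factory=list)  # (step, index)
    params: DynamicsParams | None = None

    def to_frame(self) -> pd.DataFrame:
        K = len(self.records[0].volumes) - 1
        rows = []
        for r in self.records:
            row = {
                "step": r.step,
                "mcs": r.mcs,
                "energy": r.energy,
                "surviving_index_count": r.surviving_index_count,
            }
            row.update({f"volume_{i}": int(r.volumes[i]) for i in range(K + 1)})
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_chain(
    config0: Configuration,
    spec: Hamiltonian,
    params: DynamicsParams,
    n_steps: int,
    record_every: int | None = None,
    snapshot_every: int | None = None,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Simulate ``n_steps`` elementary attempts from ``config0``.

    Reproducible given the seed in ``params`` (or an explicit generator);
    records at the stated cadence (always including step 0 and the final
    step) and logs every extinction event with its step index.  The energy is
    tracked incrementally from accepted Delta-H values.
    """
    if n_steps < 0:
        raise PreconditionError("n_steps must be >= 0")
    rng = rng if rng is not None else params.rng()
    step_fn = _stepper(params)
    config = config0.copy()
    n = config.lattice.n_sites
    energy = spec.energy(config)
    alive = int(np.count_nonzero(config.volumes()))
    records: list[TrajectoryRecord] = []
    extinctions: list[tuple[int, int]] = []

    def record(step: int) -> None:
        snap = None
        if snapshot_every is not None and (step % snapshot_every == 0 or step == n_steps):
            snap = config.values.copy()
        records.append(
            TrajectoryRecord(step, step / n, energy, alive, config.volumes(), snap)
        )

    record(0)
    for step in range(1, n_steps + 1):
        _, accepted, rec = step_fn(config, spec, params, rng)
        if accepted and rec.new_index != rec.old_index:
            energy += rec.delta_h
            if config.volume(rec.old_index) == 0:
                alive -= 1
                extinctions.append((step, rec.old_index))
        if record_every is not None and step % record_every == 0:
            record(step)
        elif step == n_steps and (record_every is None or step % record_every != 0):
            record(step)
    return Trajectory(records, config, extinctions, params)


def sample_exit_time(
    config0: Configuration,
    spec: Hamiltonian,
    params: DynamicsParams,
    max_steps: int,
    rng: np.random.Generator | None = None,
) -> int | None:
    """First step at which a cell index goes extinct, or ``None`` if censored.

    ``config0`` must contain every index of Sigma (the chain starts in the
    all-indices communication class); the exit time is the step count of the
    first transition that shrinks the set of present indices.
    """
    if len(config0.present_indices()) != config0.cells.K + 1:
        raise PreconditionError(
            "initial configuration must contain every cell index of Sigma"
        )
    rng = rng if rng is not None else params.rng()
    step_fn = _stepper(params)
    config = config0.copy()
    for step in range(1, max_steps + 1):
        _, accepted, rec = step_fn(config, spec, params, rng)
        if (
            accepted
            and rec.new_index != rec.old_index
            and config.volume(rec.old_index) == 0
        ):
            return step
    return None


def rate_matrix_from_transition(P) -> sp.csr_matrix:
    """Continuous-time embedding Q = P - E of a row-stochastic kernel.

    Q has zero row sums and nonnegative off-diagonal entries equal to those
    of P; it generates the continuous-time chain whose jump chain (conditioned
    on leaving a state) has P's off-diagonal proportions, with exponential
    instead of constant holding times.
    """
    P = sp.csr_matrix(P, dtype=float)
    if P.shape[0] != P.shape[1]:
        raise ConfigurationError("transition matrix must be square")
    if P.nnz and P.data.min() < -1e-15:
        raise ConfigurationError("transition matrix entries must be nonnegative")
    rows = np.asarray(P.sum(axis=1)).ravel()
    if np.max(np.abs(rows - 1.0)) > 1e-9:
        raise ConfigurationError("transition matrix rows must sum to 1")
    return (P - sp.identity(P.shape[0], format="csr")).tocsr()
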