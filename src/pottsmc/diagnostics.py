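"""Equilibrium and structural diagnostics for CPM kernels.

Three questions from the theory are made executable here:

* Does a kernel satisfy detailed balance with respect to the Gibbs measure
  mu propto exp(-H/T)?  The standard Metropolis kernel does; the modified
  (CPM) kernel does not — and in fact admits *no* strictly positive
  reversible measure, witnessed by a one-way transition (a single-site cell
  can vanish but never reappear).
* Which Hamiltonian terms are local?  The locality probe perturbs
  configurations at increasing graph distance from a proposal's target site
  and records the largest distance at which the energy gain still responds.
  A dependence radius that stabilizes across lattice sizes indicates a
  finite-range term (the surface interaction); a radius that grows with the
  lattice exhibits nonlocality (the volume constraint), which is what blocks
  the extension of a CPM to unbounded lattices as an interacting particle
  system.

The probe is falsification-style: "local" verdicts mean no witness was found
up to the tested radius, while every "nonlocal" verdict carries a
reproducible witness perturbation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp

from .errors import ConfigurationError, PreconditionError
from .hamiltonian import Hamiltonian
from .lattice import Configuration, Lattice, Neighborhood, StateSpace

DB_TOLERANCE = 1e-12


@dataclass
class GibbsMeasure:
    """mu(eta) propto exp(-H(eta)/T) on an enumerated state space."""

    probabilities: np.ndarray
    temperature: float
    log_Z: float
    state_space: StateSpace

    def __post_init__(self) -> None:
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ConfigurationError("Gibbs probabilities must sum to 1")


def gibbs_measure(spec: Hamiltonian, T: float, state_space: StateSpace) -> GibbsMeasure:
    """The Gibbs measure of H at finite temperature T.

    Energies are shifted by their maximum before exponentiation to guard
    against overflow; the measure is invariant under the shift H -> H + c.
    """
    if not (0 < T < np.inf):
        raise PreconditionError("Gibbs measure requires finite positive temperature")
    energies = np.array(
        [spec.energy(state_space.decode(code)) for code in range(state_space.n_states)]
    )
    logw = -energies / T
    log_Z = float(logsumexp(logw))
    p = np.exp(logw - log_Z)
    return GibbsMeasure(p / p.sum(), T, log_Z, state_space)


@dataclass
class DetailedBalanceReport:
    """Maximum flow imbalance max |mu(eta) P(eta,zeta) - mu(zeta) P(zeta,eta)|."""

    max_violation: float
    pair: tuple[int, int]
    passed: bool
    tolerance: float = DB_TOLERANCE


def detailed_balance_check(
    P, mu: GibbsMeasure | np.ndarray, tol: float = DB_TOLERANCE
) -> DetailedBalanceReport:
    """Check mu(eta) P(eta,zeta) == mu(zeta) P(zeta,eta) over all pairs."""
    probs = mu.probabilities if isinstance(mu, GibbsMeasure) else np.asarray(mu)
    P = sp.csr_matrix(P, dtype=float)
    if P.shape[0] != probs.size:
        raise ConfigurationError("kernel and measure have mismatched dimensions")
    F = sp.diags(probs) @ P
    D = (F - F.T).tocoo()
    if D.nnz == 0:
        return DetailedBalanceReport(0.0, (0, 0), True, tol)
    k = int(np.argmax(np.abs(D.data)))
    viol = float(np.abs(D.data[k]))
    pair = (int(D.row[k]), int(D.col[k]))
    return DetailedBalanceReport(viol, pair, viol < tol, tol)


@dataclass
class ReversibilityWitness:
    """A one-way transition: P(eta, zeta) > 0 while P(zeta, eta) = 0.

    Its existence rules out any strictly positive reversible measure for P.
    For the CPM kernel the canonical witness is the deletion of a single-site
    cell.
    """

    source: int
    target: int
    forward_probability: float
    changed_site: int | None = None
    deleted_index: int | None = None


def reversibility_witness(
    P, state_space: StateSpace | None = None
) -> ReversibilityWitness | None:
    """Search for a one-way transition; ``None`` if every transition is two-way.

    With a state space supplied, the witness is annotated with the changed
    site and, when the transition deletes a cell, the deleted index.
    """
    P = sp.csr_matrix(P, dtype=float)
    Pt = P.T.tocsr()
    coo = P.tocoo()
    for i, j, v in zip(coo.row, coo.col, coo.data):
        if i == j or v <= 0:
            continue
        if Pt[int(i), int(j)] == 0:
            witness = ReversibilityWitness(int(i), int(j), float(v))
            if state_space is not None:
                a = state_space.decode_values(int(i))
                b = state_space.decode_values(int(j))
                diff = np.nonzero(a != b)[0]
                if diff.size == 1:
                    witness.changed_site = int(diff[0])
                    old = int(a[diff[0]])
                    if old not in set(int(x) for x in b):
                        witness.deleted_index = old
            return witness
    return None


# -- locality probe ---------------------------------------------------------


@dataclass
class PerturbationWitness:
    """A far-site perturbation that changed Delta-H of a fixed proposal."""

    lattice_size: int
    distance: int
    perturbed_site: int
    old_value: int
    new_value: int
    delta_h_base: float
    delta_h_perturbed: float

    def reproduce(self, term: Hamiltonian, base: Configuration, target: int, proposal: int) -> bool:
        """Re-evaluate both energy gains; True iff they match the record."""
        d0 = term.delta(base, target, proposal)
        pert = base.with_site(self.perturbed_site, self.new_value)
        d1 = term.delta(pert, target, proposal)
        return (
            abs(d0 - self.delta_h_base) < 1e-12
            and abs(d1 - self.delta_h_perturbed) < 1e-12
        )


@dataclass
class TermLocality:
    """Dependence-radius sweep result for one Hamiltonian term."""

    term: str
    radii: dict[int, int]  # lattice size -> largest distance with dependence
    verdict: str  # "local-with-range-R" or "nonlocal"
    range_estimate: int | None
    witnesses: list[PerturbationWitness] = field(default_factory=list)


@dataclass
class LocalityReport:
    """Per-term locality verdicts over a lattice-size sweep."""

    terms: dict[str, TermLocality]
    sizes: list[int]

    def summary(self) -> str:
        lines = ["term                radius-by-size                verdict"]
        for name, t in self.terms.items():
            radii = " ".join(f"{L}:{r}" for L, r in sorted(t.radii.items()))
            lines.append(f"{name:<19} {radii:<29} {t.verdict}")
        return "\n".join(lines)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "sizes": self.sizes,
            "terms": {
                name: {
                    "radii": {str(k): v for k, v in t.radii.items()},
                    "verdict": t.verdict,
                    "range_estimate": t.range_estimate,
                    "witnesses": [w.__dict__ for w in t.witnesses],
                }
                for name, t in self.terms.items()
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def _ring_distance_groups(lattice: Lattice) -> dict[int, list[int]]:
    """Graph distances from site 0 in the interface-neighborhood graph (BFS)."""
    n = lattice.n_sites
    dist = {0: 0}
    frontier = [0]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for x in frontier:
            for y in lattice.interface_neighbor_array(x):
                y = int(y)
                if y not in dist:
                    dist[y] = d
                    nxt.append(y)
        frontier = nxt
    groups: dict[int, list[int]] = {}
    for site, d in dist.items():
        if d > 0:
            groups.setdefault(d, []).append(site)
    return groups


def locality_probe(
    spec: Hamiltonian,
    lattice_size_sweep: Sequence[int] = tuple(range(4, 17, 4)),
    n_trials: int = 200,
    seed: int = 0,
    neighborhood: Neighborhood | None = None,
) -> LocalityReport:
    """Estimate the dependence radius of each Hamiltonian term by perturbation.

    For each 1-D periodic lattice size in the sweep, a fixed proposal (copy
    the clockwise-neighboring cell's index onto site 0) is evaluated on an
    equal-blocks two-cell configuration.  Sites at increasing graph distance
    r from the target are rewritten to random different indices (``n_trials``
    per (size, r) cell, seeded); the largest r at which any rewrite changes
    Delta-H is the term's dependence radius at that size.  A radius that
    grows from the smallest to the largest lattice yields the verdict
    "nonlocal"; a size-stable radius yields "local-with-range-R".
    """
    sizes = sorted(int(L) for L in lattice_size_sweep)
    if len(sizes) < 3:
        raise PreconditionError("locality probe needs a sweep of >= 3 lattice sizes")
    from .experiments import generate_initial_config  # local import: no module cycle

    hood = neighborhood or Neighborhood()
    terms = spec.term_hamiltonians()
    if not terms:
        terms = {"zero": Hamiltonian(spec.cells)}
    report: dict[str, TermLocality] = {}
    for name, term in terms.items():
        radii: dict[int, int] = {}
        witnesses: list[PerturbationWitness] = []
        for L in sizes:
            lattice = Lattice((L,), boundary="periodic", copy_neighborhood=hood)
            base = generate_initial_config("equal_blocks", lattice, spec.cells, seed=seed)
            target = 0
            # proposal: the index of the counter-clockwise neighbor (last block)
            proposal = int(base.values[L - 1])
            if proposal == int(base.values[0]):
                proposal = int(base.values[1])
            d0 = term.delta(base, target, proposal)
            rng = np.random.default_rng(seed + L)
            groups = _ring_distance_groups(lattice)
            r_dep = 0
            for r in sorted(groups):
                hit = None
                sites = groups[r]
                for _ in range(n_trials):
                    site = int(sites[rng.integers(len(sites))])
                    old = int(base.values[site])
                    new = int(rng.integers(spec.cells.K + 1))
                    if new == old:
                        new = (new + 1) % (spec.cells.K + 1)
                    pert = base.with_site(site, new)
                    d1 = term.delta(pert, target, proposal)
                    if abs(d1 - d0) > 1e-12:
                        hit = PerturbationWitness(L, r, site, old, new, d0, d1)
                        break
                if hit is not None:
                    r_dep = r
                    if L == sizes[-1] or r > 1:
                        witnesses.append(hit)
            radii[L] = r_dep
        growing = radii[sizes[-1]] > radii[sizes[0]]
        if growing:
            verdict, rng_est = "nonlocal", None
        else:
            rng_est = max(radii.values())
            verdict = f"local-with-range-{rng_est}"
        report[name] = TermLocality(name, radii, verdict, rng_est, witnesses)
    return LocalityReport(report, sizes)
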