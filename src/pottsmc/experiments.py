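"""Fixture generation and canned experiments.

The initial-configuration generators produce the standard starting states of
the theory experiments: constant configurations (absorbing states),
checkerboards and random tilings (mixed populations as in cell-sorting
studies), equal contiguous blocks (every cell present with equal volume) and
single-site cells (one lattice node per cell, the rest medium).

The survival-curve experiment turns the approximately-geometric exit-time law
into a table: empirical survival of the first-extinction time over many
replicates, side by side with the exact survival function and the leading
eigenvalue lambda_1 of the all-indices restriction whenever the state space
is small enough to enumerate, plus a geometric tail fit with Monte Carlo
standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsParams, Trajectory, sample_exit_time
from .errors import ConfigurationError, PreconditionError
from .exact_chain import (

    StateSpace,
    build_transition_matrix,
    classify_states,
    exit_time_spectrum,
    survival_curve,
)
from .hamiltonian import Hamiltonian
from .lattice import CellIndexModel, Configuration, Lattice

GENERATOR_KINDS = (
    "constant",
    "checkerboard",
    "random_uniform",
    "equal_blocks",
    "single_site_cells",
)


def generate_initial_config(
    kind: str,
    lattice: Lattice,
    cells: CellIndexModel,
    seed: int | None = None,
    index: int = 1,
) -> Configuration:
    """Deterministic (given seed) initial configurations for experiments.

    ``constant``: every site carries ``index``.
    ``checkerboard``: site (c_1, ..., c_d) carries 1 + (sum c_j mod K) — all
    cells present, maximally interleaved, no medium.
    ``random_uniform``: i.i.d. uniform over all of Sigma.
    ``equal_blocks``: contiguous raster blocks of equal volume (+-1 site) for
    indices 1..K, no medium.
    ``single_site_cells``: cells 1..K occupy one site each (raster order),
    the rest is medium.
    """
    n = lattice.n_sites
    K = cells.K
    if kind == "constant":
        values = np.full(n, cells.validate_index(index), dtype=np.int64)
    elif kind == "checkerboard":
        coords = np.stack(
            np.unravel_index(np.arange(n), lattice.dimensions), axis=1
        )
        values = 1 + (coords.sum(axis=1) % K)
    elif kind == "random_uniform":
        rng = np.random.default_rng(seed)
        values = rng.integers(0, K + 1, size=n)
    elif kind == "equal_blocks":
        if K > n:
            raise ConfigurationError(f"cannot place {K} cells on {n} sites")
        edges = np.linspace(0, n, K + 1).round().astype(int)
        values = np.empty(n, dtype=np.int64)
        for i in range(K):
            values[edges[i] : edges[i + 1]] = i + 1
    elif kind == "single_site_cells":
        if K > n:
            raise ConfigurationError(f"cannot place {K} single-site cells on {n} sites")
        values = np.zeros(n, dtype=np.int64)
        values[:K] = np.arange(1, K + 1)
    else:
        raise ConfigurationError(
            f"unknown generator kind {kind!r}; choose from {GENERATOR_KINDS}"
        )
    return Configuration(lattice, cells, values)


@dataclass
class SurvivalExperimentResult:
    """Empirical (and, when feasible, exact) survival of the first-extinction time."""

    table: pd.DataFrame  # columns: n, empirical_survival, se, [exact_survival]
    replicates: int
    censored: int
    tail_start: int
    tail_count: int
    geometric_parameter_hat: float | None
    geometric_parameter_se: float | None
    lambda1: float | None
    exact_geometric_parameter: float | None
    exit_times: np.ndarray

    def summary_dict(self) -> dict:
        return {
            "replicates": self.replicates,
            "censored": self.censored,
            "tail_start": self.tail_start,
            "tail_count": self.tail_count,
            "geometric_parameter_hat": self.geometric_parameter_hat,
            "geometric_parameter_se": self.geometric_parameter_se,
            "lambda1": self.lambda1,
            "exact_geometric_parameter": self.exact_geometric_parameter,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.summary_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def fit_geometric_tail(
    exit_times: np.ndarray, tail_start: int
) -> tuple[float | None, float | None, int]:
    """MLE of the geometric parameter from exit times beyond ``tail_start``.

    Conditional on tau > n0 the residual tau - n0 of a geometric law is again
    geometric on {1, 2, ...}; the MLE is 1/mean with delta-method standard
    error p * sqrt((1 - p)/m).
    """
    tail = exit_times[exit_times > tail_start] - tail_start
    m = tail.size
    if m < 2:
        return None, None, m
    p_hat = 1.0 / float(np.mean(tail))
    se = p_hat * np.sqrt((1.0 - p_hat) / m)
    return p_hat, se, m


def survival_curve_experiment(
    config0: Configuration,
    spec: Hamiltonian,
    params: DynamicsParams,
    replicates: int = 10_000,
    max_steps: int = 100_000,
    tail_start: int | None = None,
    exact: bool = True,
    seed: int | None = None,
    state_cap: int = 10**5,
) -> SurvivalExperimentResult:
    """Empirical exit-time survival versus the exact spectrum.

    Simulates ``replicates`` first-extinction times from ``config0``
    (censoring at ``max_steps`` is reported, censored runs are excluded from
    the tail fit) and, when the state space is enumerable under
    ``state_cap``, computes the exact survival function and lambda_1 for the
    same model.

    ``tail_start`` bounds the transient excluded from the geometric tail
    fit.  By default it is chosen from the exact analysis as the smallest n
    at which the exact survival ratio S(n+1)/S(n) is within 1% of lambda_1
    (a spectral-convergence diagnostic independent of the simulated data);
    without exact analysis it falls back to 50.
    """
    if len(config0.present_indices()) != config0.cells.K + 1:
        raise PreconditionError("survival experiment requires all indices present")
    rng = np.random.default_rng(seed if seed is not None else params.seed)
    times = []
    censored = 0
    for _ in range(replicates):
        t = sample_exit_time(config0, spec, params, max_steps, rng=rng)
        if t is None:
            censored += 1
        else:
            times.append(t)
    exit_times = np.asarray(times, dtype=np.int64)

    n_max = int(exit_times.max(initial=1))
    grid = np.arange(n_max + 1)
    emp = np.array([np.mean(exit_times > n) for n in grid]) if exit_times.size else np.ones(1)
    se = np.sqrt(emp * (1 - emp) / max(1, replicates))
    table = pd.DataFrame({"n": grid, "empirical_survival": emp, "se": se})

    lam1 = exact_p = None
    if exact:
        ss = StateSpace(config0.lattice, config0.cells, cap=state_cap)
        tm = build_transition_matrix(ss, spec, params)
        decomp = classify_states(tm)
        spectrum = exit_time_spectrum(tm, decomp)
        lam1 = spectrum.lambda1
        exact_p = spectrum.geometric_parameter
        curve = survival_curve(tm, decomp, ss.encode(config0), max(n_max, 200))
        table["exact_survival"] = curve[: n_max + 1]
        if tail_start is None:
            ratios = curve[1:] / np.where(curve[:-1] > 0, curve[:-1], 1.0)
            converged = np.abs(ratios - lam1) / lam1 < 1e-2
            tail_start = int(np.argmax(converged)) if converged.any() else 50
    if tail_start is None:
        tail_start = 50

    p_hat, p_se, m = fit_geometric_tail(exit_times, tail_start)
    return SurvivalExperimentResult(
        table=table,
        replicates=replicates,
        censored=censored,
        tail_start=tail_start,
        tail_count=m,
        geometric_parameter_hat=p_hat,
        geometric_parameter_se=p_se,
        lambda1=lam1,
        exact_geometric_parameter=exact_p,
        exit_times=exit_times,
    )


@dataclass
class RunSummary:
    """Per-run summary of a trajectory: extinctions, final class, series stats."""

    extinction_times: dict[int, int]
    final_class: frozenset[int]
    energy: dict[str, float]
    volumes_final: dict[int, int]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "extinction_times": {str(k): v for k, v in self.extinction_times.items()},
            "final_class": sorted(self.final_class),
            "energy": self.energy,
            "volumes_final": {str(k): v for k, v in self.volumes_final.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def summary_statistics(trajectory: Trajectory) -> RunSummary:
    """Extinction events, final communication class, and series summaries."""
    if not trajectory.records:
        raise PreconditionError("trajectory has no records")
    energies = np.array([r.energy for r in trajectory.records])
    final = trajectory.final
    return RunSummary(
        extinction_times={idx: step for step, idx in trajectory.extinctions},
        final_class=final.present_indices(),
        energy={
            "initial": float(energies[0]),
            "final": float(energies[-1]),
            "min": float(energies.min()),
            "max": float(energies.max()),
        },
        volumes_final={i: final.volume(i) for i in final.cells.indices},
    )


def plot_survival(result: SurvivalExperimentResult, path: str | Path) -> None:
    """Log-scale survival plot (empirical vs exact) written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    t = result.table
    ax.semilogy(t["n"], t["empirical_survival"], drawstyle="steps-post", label="empirical")
    if "exact_survival" in t:
        ax.semilogy(t["n"], t["exact_survival"], "--", label="exact")
    if result.lambda1 is not None:
        ax.set_title(f"lambda_1 = {result.lambda1:.6f}")
    ax.set_xlabel("step n")
    ax.set_ylabel("P(exit > n)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
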