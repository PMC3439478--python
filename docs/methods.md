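# Methods

## Model

A configuration η assigns to every site x of a finite regular lattice S a
cell index η(x) ∈ Σ = {0, 1, …, K}; index 0 is the medium and each index
i ≥ 1 is one biological cell of type τ(i).  A cell's *volume* V_i(η) is the
number of sites carrying i; its *surface length* s_i(η) is the number of
*interfaces* — unordered pairs of neighboring sites with different indices —
touching the cell.  The energy is

H(η) = Σ_{interfaces {x,y}} J(τ(η(x)), τ(η(y)))
     + Σ_{cells i} λ_V(τ(i)) · (V_i(η) − V_T(τ(i)))²
     + Σ_{cells i} λ_S(τ(i)) · (s_i(η) − S_T(τ(i)))²
     + H_extra(η),

with every addend optional.  J is symmetric and must cover all type pairs
including the medium type.  The medium is excluded from the volume and
surface constraints by default (the constraints model properties of
biological cells; constraining the medium is nonstandard); an
`include_medium` flag restores full symmetry for theory experiments, since
the printed form of the constraint's index range is ambiguous in parts of
the literature.  Energies carry no unit system: the temperature divides the
energy in the acceptance rule, so one of the two scales is redundant and can
be absorbed by rescaling.

### Dynamics

One elementary step of the *modified* Metropolis algorithm (the CPM):

1. draw a target site x uniformly on S;
2. draw a source y uniformly among the copy-neighbors N(x);
3. form the trial configuration by copying η(y) onto x and compute
   ΔH = H(trial) − H(η);
4. accept with probability 1 if ΔH < Δ (the transition threshold, default
   0), otherwise with an exponential acceptance probability.

The *standard* Metropolis kernel differs only in step 2: the replacement
index is drawn uniformly from all of Σ, ignoring the neighborhood.  It is
the classical equilibrium sampler whose reversible law is the Gibbs measure
μ ∝ exp(−H/T); the modified kernel is not reversible for any strictly
positive measure (see Diagnostics).

Because the exact exponential form of the acceptance probability is not
standardized, both circulating conventions are implemented:

* `shifted` (default): exp(−(ΔH − Δ)/T), continuous at ΔH = Δ where it
  equals 1;
* `unshifted`: min(1, exp(−ΔH/T)).

T = +∞ accepts every proposal — the chain is then the multi-type voter
model.  T = 0 is handled as the limit: accept iff ΔH < Δ.  T itself is a
technical parameter weighting the Hamiltonian's influence against the
uncontrolled voter-like part of the kinetics.

Time is counted in elementary attempts; one Monte Carlo step (MCS) equals
|S| attempts and is reported alongside for convention compatibility.  A
single seeded generator with a fixed draw order (site, then
neighbor/index, then acceptance uniform) makes every trajectory
bit-reproducible.  Deliberately, no "no-extinction" patch is offered: the
successive extinction of cells is a structural property of the model class,
and hiding it would misrepresent the dynamics this package exists to
exhibit.

### Lattice and neighborhoods

Lattices are 1-, 2- or 3-dimensional with periodic (torus) or fixed
boundary.  Under fixed boundary the confining environment is modeled as a
frozen medium frame: copy attempts never source from outside the lattice,
but the surface term charges each out-of-bounds interface offset at the
cell–medium coefficient, so cells interact with the wall through the
Hamiltonian.  The copy neighborhood (step 2) and the interface neighborhood
(the pairs entering the surface terms) are independently configurable von
Neumann or Moore templates of integer order, defaulting to von Neumann
order 1 for both, since published models differ here and nothing in the
model definition forces them to coincide.  On tiny periodic lattices,
offsets that wrap onto the same site are deduplicated and a site is never
its own neighbor.  Cell connectivity is *not* enforced: the definition
allows fragmented cells and no repair is attempted.

## Exact chain analysis

On lattices small enough to enumerate Ω = Σ^S (base-(K+1) encoding in
raster site order, refused above a configurable cap, default 10⁶ states),
the one-step kernel is assembled exactly:
P(η, ζ) = Σ_{(x,y) : copy gives ζ} (1/|S|)(1/|N(x)|) · accept(ΔH), with all
rejected and self-copy mass on the diagonal.  Structure exploited and
verified:

* Transitions never enlarge the set of present indices, so the
  present-index sets Σ_A (configurations whose present indices are exactly
  A) bound reachability; the K+1 constant configurations are the only
  absorbing states; every other state is transient.
* Absorption probabilities solve (I − Q̃)B = R̃, where Q̃ and R̃ are the
  transient–transient and transient–absorbing blocks.  The linear solve is
  the production path; the truncated power-series accumulation of the
  coupling block is retained as a test oracle.  Each row of B sums to one:
  absorption is almost sure from every start.
* The stationary set is the simplex spanned by the K+1 point masses on the
  constant configurations; the left eigenvalue-1 eigenspace is checked to
  have dimension exactly K+1.
* The restriction U of P to the all-indices class is substochastic; its
  spectral radius λ₁ ∈ (0, 1) governs the first-extinction (exit) time,
  whose law is approximately geometric with parameter 1 − λ₁.  Primitivity
  (strong connectivity plus aperiodicity of the positive-entry digraph) is
  verified, not assumed; when it fails the geometric claim is reported as
  inapplicable rather than forced, and the Perron eigenvectors (returned
  strictly positive, normalized to right-vector sum 1 and inner product
  ⟨left, right⟩ = 1) are omitted.  Dense eigensolvers are used below 2,000
  states, Arnoldi iteration above; eigen-tolerance 10⁻¹⁰.
* In the voter limit the number of sites carrying an index is a martingale,
  so the absorption probability of index k equals its initial volume
  fraction n_k/|S| — an independent closed form against which the linear
  solve and Monte Carlo runs are both checked.

### When present-index sets are not communication classes

The classical description of the CPM's class structure states that the sets
Σ_A are the communication classes of the kernel.  This presupposes that any
two configurations with the same present indices are mutually reachable by
single-site copies, which *fails* on the smallest nearest-neighbor
geometries:

* A configuration in which no two neighboring sites share an index (a
  proper coloring of the neighbor graph) has in-degree zero — entering it
  would require the final copy to duplicate a neighbor's index — so it
  cannot be reached from anywhere.  Such configurations exist whenever
  K + 1 reaches the chromatic number of the neighbor graph.
* With nearest-neighbor copying, a 1-D ring conserves the cyclic order of
  cell domains: two arrangements of the same cells in opposite order never
  communicate.  On the 4-site ring with three indices, Σ_{0,1,2} splits
  into two mirror-image components of 12 states plus 12 unreachable proper
  colorings.

`classify_states` therefore verifies the present-index partition against a
strongly-connected-component computation and raises an
`InternalConsistencyError` on mismatch instead of silently proceeding.  The
canonical tiny models avoid the degeneracy by using the complete neighbor
graph on their four sites (von Neumann order 2 on the 4-ring, Moore order 1
on the 2×2 torus), where the match is exact.  The absorption theory itself
(almost-sure absorption, B, the stationary simplex) does not depend on the
within-class structure and holds regardless.  T = 0 kinetics can break the
class structure in a second way (blocked uphill moves can close transient
sets) and is surfaced by the same check.

## Diagnostics

*Detailed balance* is checked as the maximal flow imbalance
max_{η,ζ} |μ(η)P(η,ζ) − μ(ζ)P(ζ,η)| with pass tolerance 10⁻¹²; exact
rational structure is not preserved in floating point, but the violations of
interest are O(1), many orders above the tolerance.  The *reversibility
witness* searches the kernel for a one-way transition (P(η,ζ) > 0,
P(ζ,η) = 0), which rules out any strictly positive reversible measure; for
the CPM kernel the canonical witness is the deletion of a single-site cell,
and the search annotates the witness with the deleted index.

The *locality probe* is empirical rather than symbolic because it must also
work for user-supplied extra terms: for each Hamiltonian term and each 1-D
periodic lattice size in a sweep (at least 3 sizes), a fixed copy proposal
is evaluated on an equal-blocks two-cell configuration, and sites at
increasing graph distance r from the target are rewritten to random
different indices (200 trials per size–radius cell, seeded).  The largest r
at which any rewrite changes ΔH is the term's dependence radius at that
size; a radius that grows from the smallest to the largest lattice yields
the verdict "nonlocal", a size-stable radius "local-with-range-R".  A
"local" verdict is falsificationist — no witness found up to the tested
radius — while every "nonlocal" verdict carries a reproducible witness
perturbation.  The surface term stabilizes at the interface-neighborhood
range; the volume constraint's radius grows like half the ring, which is
exactly the property that blocks extending a volume-constrained CPM to
unbounded lattices as an interacting particle system.  Extra terms must
self-declare a range (or nonlocality) because the probe can only exhibit
witnesses, never prove their absence.

## Canonical models and study conditions

`pottsmc.models` pins the conditions used by the tests, the shipped
configurations and the acceptance script:

* `voter_ring`: H ≡ 0 on a 4-site periodic ring, Σ = {0, 1, 2}; the pure
  voter limit with exact absorption fractions.
* `sorting_2x2`: 2×2 torus, medium plus one cell each of types A and B;
  differential adhesion J(A,A) = J(B,B) = 1 < J(A,B) = 2, cell–medium
  J = 1, volume constraint V_T = 1 (one site per cell fits the four-site
  lattice), λ_V = 0.5, T = 1, Δ = 0, shifted convention.  The parameters
  are illustrative fixtures keeping all energy scales of order one at
  T = 1, so copy attempts are neither almost-always accepted nor frozen;
  81 states make every exact computation instantaneous.
* `sorting_demo_16`: a 16×16 two-type cell-sorting demonstration
  (simulation only) with GGH-style coefficients; far above the enumeration
  cap, included to exercise the simulation path at realistic scale.

The survival experiment fits the geometric tail of simulated exit times by
conditional maximum likelihood: given a cutoff n₀, the residuals τ − n₀ of
a geometric law are again geometric, with MLE p̂ = 1/mean and delta-method
standard error p̂·sqrt((1 − p̂)/m).  The cutoff is chosen from the *exact*
analysis — the smallest n at which the exact survival ratio S(n+1)/S(n) is
within 1% of λ₁ — a spectral-convergence diagnostic computed before and
independently of the simulated data (fallback 50 when no exact analysis is
feasible).  For the canonical 2×2 model this gives n₀ = 6 with ≈ 230 of
10⁴ replicates in the tail and a fit bias an order of magnitude below one
standard error.

## What the fixtures do and do not show

The generators produce constant states, checkerboards, uniform random
tilings, equal contiguous blocks and single-site cells.  They realize the
initial conditions of the theory experiments exactly, but none of them
resembles a biological tissue snapshot: cells are few, tiny and often
fragmented, and lattices are orders of magnitude smaller than in production
CPM studies.  Passing tests therefore certify the *chain-theoretic*
properties of the implementation — absorption, spectra, reversibility,
locality — not the biological realism of any particular parameter set.
Conversely, those structural properties are lattice-size-independent
theorems, so verifying them exhaustively on 81-state models is evidence
about the mechanism itself, not merely about small systems.

## Numerical choices

* Incremental ΔH is the production path (touching only the target site's
  interfaces and the two affected cells); full recomputation is retained as
  an oracle, with agreement required to 10⁻⁹ absolute.
* Transition-matrix rows must sum to 1 within 10⁻¹²; absorption rows of B
  within 10⁻¹⁰; detailed-balance pass tolerance 10⁻¹²; Gibbs weights are
  computed with a max-shift before exponentiation (log-sum-exp for Z).
* Perron eigenvector sign is fixed by making the dominant component
  positive; degenerate (non-primitive) restrictions return no eigenvectors
  rather than arbitrary ones.
* The acceptance probability is clamped to [0, 1] (relevant for the
  unshifted convention with negative thresholds).
* Problem sizes: exact analysis runs on 81-state models; Monte Carlo
  cross-checks use 10⁴ replicates, which puts binomial three-sigma bands
  around ±1.5 percentage points — small enough to detect any structural
  error while keeping the full suite in a few seconds.

## Known limitations

* Exact analysis is exponential in the site count; it is a microscope for
  tiny systems, not a scalable solver.  The state-space cap refuses
  accidental blow-ups.
* The locality probe samples perturbations; it can miss dependence through
  measure-zero coincidences (e.g., a perturbation whose two energy effects
  cancel).  Witnesses, not verdicts of locality, are proofs.
* Hexagonal/irregular lattices, 4-D lattices, parallel checkerboard
  updating, kinetic ΔH extensions (chemotaxis, inertia), compartmentalized
  cells and hybrid intracellular couplings are out of scope.
* The prefactor of the geometric exit-time asymptotics is estimated
  numerically (as the limit of S(n)/λ₁ⁿ); no closed form is claimed.
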