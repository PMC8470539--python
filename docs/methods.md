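# Methods

## Model and conventions

A system is a symmetric, unweighted network of N nodes, each in one of Q
integer states. The package fits the maximum-entropy distribution
constrained to the per-state densities ⟨s_i⟩ and the per-edge-class
near-neighbor couple densities ⟨c_ij⟩, i.e. a Boltzmann distribution with a
Potts Hamiltonian. Three conventions are fixed once and recorded in every
parameter file:

* **Couple counting.** Each unordered edge is counted once; the state pair
  is folded into a symmetric matrix (c_ij = c_ji share the count for i ≠ j)
  and normalized by the class link count, so Σ_{i≤j} c_ij = 1. Since J is
  symmetric, ordered counting would add nothing; but h/J values are
  convention-dependent, so the convention is stated rather than implied.
* **Energy scale.** H is evaluated on densities (intensive), and the
  Boltzmann exponent is exactly −H. Under this scale a single node carries
  weight e^(−h_i/N), so the non-interacting start that reproduces the target
  densities is h_i(0) = −N ln⟨s_i⟩ — the same product model one would write
  with an extensive Hamiltonian and h_i = −ln⟨s_i⟩, reparameterized. This
  choice is what makes the Shannon–Fano boundary term of the entropy
  integral exact at the path start.
* **Flat ordering.** Parameter and observable vectors concatenate the
  s-block and then, per edge class, the upper triangle of the c-matrix
  row-major. Parameter files are portable across runs because this layout is
  frozen.

## Gauge fixing

The observables obey exact linear sum rules, so some parameter directions
change nothing (e.g. shifting all h by a constant adds a constant to H).
The trainer diagonalizes the observable covariance Σ of the training set and
treats eigendirections below a relative cutoff as gauge: residuals,
gradients and parameter updates are projected onto the informative
subspace, and χ² uses the pseudo-inverse of Σ there. Two thresholds are
used — a hard relative cutoff (1e−10) for exact dependencies, a
user-settable soft cutoff (default 1e−8) against near-singular sampling
noise — plus an absolute eigenvalue floor (1e−14): observables live in
[0, 1], so any genuine direction has variance far above round-off, and a
covariance whose spectrum sits entirely below the floor means the target is
deterministic and there is nothing to optimize.

## The χ² metric and convergence

χ² = rᵀ Σ_mean⁺ r with r the gauge-projected difference between target and
model observables and Σ_mean = Σ/N_train the covariance of the target
*mean*. Convergence is declared at χ²/dof below a threshold (default 1),
which under this metric is precisely "model and training observables are
compatible within the training set's stochastic accuracy". (The
per-configuration covariance without the 1/N_train factor would declare
victory at the non-interacting start for any moderately sized training set.)
The achievable floor is set by the Metropolis estimate of the model
observables, roughly N_train/N_kept in χ²/dof units, so N_kept should be at
least a few times N_train for tight fits.

## Optimization loop

Conjugate gradient (Polak–Ribière, restart every dof iterations or on loss
of descent) on the reweighted χ², with an analytic gradient: for a
Boltzmann family ∂⟨x_a⟩/∂θ_b = −Cov(x_a, x_b), so grad χ² = 2 C Σ_mean⁺ r
with C the importance-weighted model covariance — verified against central
finite differences in the tests. Each step starts from the Gauss–Newton
optimal length and backtracks (Armijo). Two safeguards keep importance
sampling honest: a trial step is accepted only while its effective-sample
ratio against the current anchor ensemble stays above η/2, and steps are
clipped to the hard-exclusion parameter box (below). When the ratio of the
current iterate falls below η (default 0.5), a fresh Metropolis run replaces
the anchor; the training log records the pre- and post-refresh ratios, so
the refresh criterion is auditable after the fact.

## Degenerate targets

* **Never-observed states** are removed from the fitting alphabet; the
  reported parameters pin their fields at 30·N (per-node weight e^(−30)),
  a numerically hard exclusion. Entropy is unaffected (0·ln 0 = 0).
* **Never-observed couple densities** (e.g. a perfectly alternating
  sequence has zero same-state temporal couples) are driven to a pinned
  coupling 30·n_links through a ramp prepended to the recorded path:
  the per-link exponent u is sampled with Metropolis up to u = 6 in steps of
  0.5, and beyond that the pinned densities decay exactly as e^(−u)
  (configurations with a single offending pair dominate), so the tail of the
  line integral is appended analytically without further sampling. This
  keeps thermodynamic integration valid for deterministic and periodic
  training data.
* All parameters are confined to the same ±30-per-unit box during
  optimization; beyond it models are numerically indistinguishable, and the
  bound prevents ill-conditioned directions (targets with densities of order
  1/N_train) from running away.

## Entropy by thermodynamic integration

S = S_SF + ⟨H⟩_final − ⟨H⟩_initial − ∫ x(θ)·dθ, with the line integral
discretized by the trapezoidal rule over the recorded path snapshots and
⟨H⟩ terms taken as θ·x at the endpoints (reweighted means during training,
exact closed form at the product-model start). Because
d ln Z/dθ_a = −⟨x_a⟩, this reproduces S = ⟨H⟩ + ln Z exactly in the
continuous-path limit; the requirement is only that the path start at the
non-interacting solution, whose entropy is exactly S_SF. Each accepted CG
step also records three interpolated snapshots (reweighted observables are
free), keeping the integral accurate through steep regions. On enumerable
test systems a 20-step path reproduces the exact −Σ P ln P to ~5e−5 on two
nodes and within 1e−2 per site on every system tested; fitted-path
estimates land within a few 1e−3 per site of the fitted model's exact
entropy. Reports always include per-site and ln Q-normalized values.

## Dynamical extension

T frames on a base network map to one configuration of a time-extended
network: spatial edges replicated per frame (one tied J_spatial — the
processes modeled are stationary, and untying would explode the parameter
count for single-sequence training), plus temporal edges joining each node
to itself at the next step (one J_temporal; the full symmetric Q×Q temporal
couple matrix is constrained, whose off-diagonal mass is the state-change
probability between consecutive frames). With several sequences, Σ is their
between-sequence covariance; a single sequence supplies pseudo-replicas
instead — every consecutive-frame window treated as a draw of a two-frame
extended system — which assumes stationarity and mild mixing of the
sequence. Dynamical entropy is the thermodynamic-integration entropy of the
extended model, reported per node per timestep and normalized by ln Q.

## Samplers

Single-site Metropolis: uniform random free node, uniform random different
allowed state, acceptance min(1, e^(−ΔH)); a sweep is one proposal per free
node; defaults burn-in 1000 sweeps, stride 10, 1000 kept configurations.
Per-node state alphabets implement both clamping (singleton alphabet) and
restricted-alphabet conditional sampling for inpainting. The inner loop is
JIT-compiled (numba); the chain is deterministic given the seed. Exact
enumeration (capped at 10⁶ states) provides probabilities, observables,
ln Z and entropy for small systems and serves as the oracle throughout the
test suite — detailed balance, total-variation agreement of the sampler,
conditional-marginal agreement, and the gauge invariance of probabilities
under uniform field shifts are all asserted against it.

## Synthetic-data generators

* **Potts ensembles** — i.i.d. draws from the enumerated table, or thinned
  Metropolis, from known parameters; the ground truth for all
  parameter-recovery tests.
* **Hopfield networks** — J = (1−ε/2)S + (ε/2)A, S symmetric / A
  antisymmetric with U[−1,1] off-diagonal entries, zero diagonal;
  synchronous threshold dynamics with the zero-input tie resolved by a fair
  coin. Dilution d removes unordered pairs with probability d (d → 0 fully
  connected); trajectories report detected recurrences (fixed point / cycle
  length). The entropy scan fits each single-neuron trajectory as its own
  one-node dynamical problem and averages.
* **Predator–prey lattice** — a three-state (empty/prey/predator)
  asynchronous agent model of this package's own design in the Wa-Tor
  family: prey move to random empty neighbors and breed into their vacated
  site; predators always eat an adjacent prey if present (resetting a
  starvation clock), otherwise move with the mobility probability, breed on
  moving, and die after a starvation horizon. Defaults (prey breed 0.35,
  predator breed 0.1, starvation 3, mobility 0.7, initial densities
  0.3/0.05) sit in the coexistence regime, where densities fluctuate around
  stable means; parameter sets outside it are detected and flagged as
  absorbing outcomes (prey saturation or extinction) rather than returned
  as steady states.
* **Synthetic tissue images** — a ground-truth grid drawn from a known
  4-state Potts model (background/green/red/blue) rendered as colored
  blocks with additive Gaussian noise. Default couplings encode a
  colocalization pattern (blue mildly self-clusters, is attracted to green
  and repelled by red; red otherwise nearly uncoupled), so hiding the blue
  class leaves genuine spatial evidence in the visible classes — the
  property the inpainting tests quantify as mean assigned probability at
  the true hidden cells exceeding their base rate. What these synthetic
  images do *not* emulate: single-cell segmentation, uneven illumination,
  color bleed-through, or registration errors of real fluorescence imaging;
  passing tests demonstrate the inference machinery, not robustness to
  microscopy artifacts.

## Single-configuration training

A single lattice configuration (one image) carries no between-sample
covariance; Σ is estimated from spatial sub-blocks of the grid treated as
pseudo-replicas, assuming approximate translation invariance — the same
assumption that makes one image a usable training set in the first place.

## Problem sizes in the test suite

Enumeration oracles run on systems of at most a few thousand states;
sampler/oracle total-variation checks use 1e5 kept samples on systems with
≤128 states, where the statistical floor of the total-variation distance
(~√(2K/πn)/2) sits safely below the 0.02 bound being asserted. The
parameter-recovery experiment uses 500 exact draws on a 2×3 open lattice;
the imaging suite uses 24×24 grids over 20 seeds; the Hopfield scan in the
test suite uses 2 realizations × 10 neurons per asymmetry value, and the
acceptance script the full 3 realizations × 20 neurons.

## Known limitations

* Observables are restricted to densities and near-neighbor couples; no
  triplet or long-range constraints.
* Metropolis is single-site; near phase transitions or with hard clamps the
  chain mixes slowly, and cluster updates are deliberately out of scope.
* The entropy estimate inherits Monte Carlo noise from the path; for
  near-deterministic targets the exclusion ramp contributes noise of a few
  1e−2 per pinned coordinate (total), which matters only for very small
  systems.
* Single-sequence and single-image covariance estimates rest on
  stationarity/translation-invariance assumptions stated above; strongly
  inhomogeneous data violates them.
* The gauge-projected parameters are the identifiable quantities; raw h and
  J values are only meaningful relative to one another, and the reporting
  tools say so.
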