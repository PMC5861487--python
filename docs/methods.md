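# Methods

## The dynamic interaction model

Each target protein i with candidate interactors j = 1..N_i is modelled by
the discrete-time linear update

    x_i[t+1] = x_i[t] + Σ_j a_ij x_j[t] − λ_i x_i[t] + k_i + ε_i[t]

on a uniform time grid.  The model is index-based: "t+1" means the next
grid point, so the grid step is the model's time unit.  Its assumptions
are strong and deliberate: linear coupling, first-order self-decay,
constant basal production, additive noise, and mRNA expression standing in
for protein level.  The parameters per target are the interaction
abilities a_ij (free sign and magnitude), the degradation λ_i ∈ [0, 1]
and the basal level k_i ≥ 0.

### Grid densification

Regeneration time courses are sampled at very few, irregular times
(e.g. 0, 0.25, 1, 3 days post injury).  Replicates are averaged per time
point (the ANOVA filter has already consumed replicate variance) and a
natural cubic spline through the averaged knots is evaluated on a uniform
grid of `m_points` times spanning exactly the observed range.  With only
two observed times the spline degenerates to linear interpolation.  The
default grid size is `max(4 × observed_times, N_max + 6)`, which
guarantees every target at least N_i + 2 equations with margin; it is
overridable, and the sizing rule is recorded in the run manifest.
Interpolated points are smoothness assumptions, not data: they stabilize
the regression but cannot add information beyond the knots.

### Constrained least squares

With θ_i = (a_i1..a_iN, 1−λ_i, k_i) and regression rows
φ_i[t] = (x_1[t], …, x_N[t], x_i[t], 1), stacking consecutive grid points
gives X_i = Φ_i θ_i + E_i with M−1 equations.  θ̂_i minimizes the residual
sum of squares subject to 1−λ_i ∈ [0, 1] and k_i ≥ 0 (degradation and
basal synthesis are physically non-negative; abilities stay free).  The
unconstrained solution is accepted when feasible; otherwise scipy's BVLS
active-set solver handles the bounds (trust-region fallback for systems
BVLS rejects).  A rank-deficient active design returns the minimum-norm
optimum flagged `degenerate` instead of raising — degenerate targets are
real in genomic data and must not abort a whole-network run.

### AIC model-order selection

Candidate order is selected by minimizing

    K_AIC(n) = log(RSS / n_eq) + 2 (n + 2) / n_eq,     n_eq = M − 1

with natural log, where n counts retained interactions and the +2 counts
the self/degradation and basal parameters.  Two numerical conventions
matter:

* **Equation count.** The residual vector has M−1 entries, so n_eq = M−1
  is used consistently in both the RSS average and the penalty.
* **RSS floor.** RSS/n_eq is floored at 1e−12 before the log so perfect
  (noiseless) fits score finitely; without the floor every noiseless
  comparison degenerates to −∞ ties.

The search is a nested scan: fit the full model once, rank interactors by
|a_ij| descending (ties broken by lexicographic id), refit the top-n
subset for n = 0..N_i, and keep the smallest n attaining the minimal
K_AIC.  This is O(N_i) fits per target; the exhaustive 2^N subset search
is kept as a test oracle, and on noiseless data the nested scan attains
its minimum (verified over hundreds of random targets).  Everything in
the inference path is deterministic; all ties break lexicographically.

An undirected edge {i, j} is retained when the i-regression keeps j *or*
the j-regression keeps i (union rule, the default).  A stricter "both"
rule is available; see the limitations section for the precision/recall
trade-off between them.

### Known limitation: AIC is a liberal filter

With penalty 2 per parameter, a single spurious regressor is retained
whenever its incremental fit statistic exceeds 2, which for an ideal
χ²₁-distributed statistic happens with probability ≈ 0.157 — regardless
of the noise scale, because the statistic is scale-free.  Two effects
push the realized false-positive rate higher: the magnitude ranking
tests, in effect, the *best-fitting* spurious candidate (the maximum of k
χ² draws: ≈ 0.40 for k = 3), and the union merge keeps an edge either
direction retains.  Measured on the synthetic benchmark (σ = 0.05, as
many spiked false edges as true ones, 30 seeds) this yields ≈ 93–94%
true-edge retention but only ≈ 27–33% spurious-edge rejection.  The
"both" merge flips the trade-off (≈ 81% rejection, ≈ 57% retention).
Exactly-noiseless data are the exception: there the RSS floor makes AIC
reject every spurious candidate, and recovery is exact.  Users who need
conservative networks should treat the refined edge set as a ranked
hypothesis list, not a validated interactome.

## Preprocessing

* **Percentile normalization** divides each sample column by its own
  q-th percentile (default q = 75), using linear interpolation between
  closest ranks (rank position (n−1)·q/100).  The operation is idempotent
  and scale-invariant per column; columns with non-positive percentile
  raise a degenerate-sample error naming the column.
* **ANOVA filter**: per protein, one-way fixed-effects ANOVA across
  time-point groups (replicates as observations, so every time point
  needs ≥ 2 replicates), Bonferroni-corrected against a family size that
  defaults to the number of proteins in that condition's matrix
  (per-condition families; overridable).  Zero-variance proteins get
  p = 1 — flat probes are excluded, never an error.  Under a simulated
  null the p-values are uniform (KS-checked in the suite).
* **Duplicate collapsing** operates on probe-level row arrays before the
  expression container is built (the container itself forbids duplicate
  ids): among rows sharing an id the smallest ANOVA p wins, ties to first
  occurrence.
* Platform-specific normalizations (GCRMA, vendor scaling) are upstream
  concerns; matrices from such platforms must arrive pre-normalized.

## Candidate construction

Human PPIs are projected through the zebrafish–human ortholog table:
edge (H1, H2) expands to every zebrafish pair (z_a, z_b) with z_a
orthologous to H1 and z_b to H2 (both orientations of the unordered
edge).  Many-to-many orthology expands to *all* pairs — no disambiguation
rule is imposed, because the dynamic-model pruning downstream is the
disambiguator.  Projected self-pairs are dropped: the model already has a
self term, and a self-interaction would alias with 1−λ_i.  Identifiers
are case-sensitive opaque strings throughout; no symbol cleaning is
attempted.  Edge provenance (which human edges produced a projected edge)
is carried for reporting only.

## Network comparison

Core proteins are the node-set intersection across all refined networks
(nodes are retained-edge endpoints only; isolated pool proteins are not
network nodes).  Each condition's core network is its edge set induced on
the core proteins — same nodes, different edges per condition.
Condition-specific proteins are the focal node set minus the union of all
other conditions' node sets, hence always disjoint from the core.  Hubs
are ranked by undirected degree, ties alphabetical.

## Synthetic benchmark protocol

The generator draws an Erdős–Rényi topology at the requested density;
every undirected true edge carries two independently drawn directed
abilities with magnitude uniform in [0.1, 0.5] and random sign.
Degradation, basal level and initial level are uniform in their ranges
(defaults [0, 0.3], [0, 1], [0.5, 1.5]).  The update matrix
W = I + A − diag(λ) must have spectral radius ≤ 1.05 (resampled up to 100
times, then an error) so simulated trajectories stay bounded; the bound
is a parameter because it interacts with the other ranges — at 20 nodes,
density 0.15 and the default ability range the radius is ≈ 1.4 unless
degradation is fast, so the recovery benchmarks draw λ ∈ [0.4, 0.8],
fast-turnover dynamics under which the default 1.05 bound is typically
satisfied on the first draw.

Simulation iterates the exact model on a uniform internal grid with
i.i.d. Gaussian process noise per node and step; design time points are
read off at the nearest grid point and independent Gaussian measurement
noise is added per replicate (both noises default to the model's σ,
separately overridable).  No non-negativity clipping is applied by
default — the model is linear, and clipping would bias recovery
benchmarks — though a clip option exists for realism demonstrations.
Spiked false-positive candidate edges are drawn uniformly from the absent
pairs; their true abilities are identically zero.

The recovery benchmarks use M uniform time points over [0, 3] dpi with 2
replicates, M = max(16, N_max + 6), and set the simulation grid and the
inference grid equal to the design grid.  This alignment is what
"identifiable design" means here: the model's discrete step is defined
relative to the data, and no off-knot spline values are fabricated — a
prerequisite for exact noiseless recovery.  What passing these benchmarks
does *not* show: real regeneration arrays have 4 irregular time points
(the generator emulates those too, for contract tests), platform-specific
noise, probe-level artifacts, and non-linear regulation; recovery rates
on the identifiable synthetic design are an upper bound on what such data
can support.

Problem sizes in the shipped benchmark runs — 20-node networks (12-node
for the exhaustive-oracle comparisons, whose cost is 2^N fits per
target), 30 seeds for stochastic rates, 200 targets for oracle
agreement, 5,000 proteins for the ANOVA null — keep the whole
reproduction script in the seconds-to-minutes range on one CPU while
giving stochastic estimates stable to a few percent across seeds.

## Design choices that were genuinely open

* **Constraint set**: only "constrained" least squares is inherent to the
  method; the bounds 1−λ ∈ [0, 1], k ≥ 0 encode non-negative degradation
  and synthesis while leaving abilities free.
* **Order search**: magnitude-ranked nested scan rather than exhaustive
  enumeration (intractable beyond ~20 candidates) or greedy stepwise
  regression (more fits, same liberal behavior).
* **Direction merge**: union by default — interaction "presence" in
  either direction's regression counts; "both" available.
* **Identifier join**: which human identifier type is matched against
  the ortholog table is configuration (column names), not code.
* **BioGRID deduplication** is purely by symbol pair, ignoring
  experimental system and publication multiplicity.
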