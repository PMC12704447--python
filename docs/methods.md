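# Methods

`chromvqa` models the ensemble of three-dimensional chromatin conformations
compatible with a (binary) Hi-C contact map, using a variational quantum
algorithm simulated exactly on a classical machine. This note records the
model, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Lattice encoding

A polymer of `N` beads (genomic bins) is threaded through a cubic lattice.
Bead 0 sits at the origin and bead 1 at `(1,1,1)/sqrt(3)`; every later bead
occupies one of the eight corners of a unit cube centred on its
predecessor, selected by three spin variables `(z_x, z_y, z_z) ∈ {-1,+1}`.
A conformation is therefore a spin string of length `3(N-2)`, in bijection
with a bitstring under `bit 1 ↔ spin +1` (qubit 0 = bead 2's x axis). Every
step has unit Euclidean norm, distances obey `D[i,j]² ≤ |i-j|²`, and no
physical length scale (nm) is assigned. The position of bead 0 is not
constrained by the closed-form prefix sum, which fixes only bead 1; the
origin is adopted as the natural convention.

Two beads are *in contact* when their Euclidean distance is at most the
contact radius `r = 1.5` lattice units and their sequence separation
exceeds `r` (so bonded and next-to-bonded neighbours never count). A
conformation *clashes* when any two beads come closer than 1/4; on this
lattice nonzero inter-bead distances are at least 1, so clashing is
equivalent to bead coincidence.

## Likelihood model

Given a binary contact map `π_c`, the likelihood of a conformation's
squared-distance matrix factorises over bead pairs at separation ≥ 2:

* contact pairs contribute the attractive propensity
  `f₊ = (1 − |D² − r²| / (sep² − r²)) ^ (sep²/D²)`, which peaks at
  `D = r` and collapses steeply as `D → 0` (the exponent doubles as a
  clash penalty);
* non-contact pairs contribute the neutral logistic propensity
  `f₋ = 1 − 1/(1 + e^{4(D² − r²)})`, flat except at or below the radius.

One subtlety worth recording: `f₊` *peaks* at `D = r` rather than
rewarding all distances below it. On the lattice the feasible `D²` values
are discrete, and for a pair at separation 2 the value nearest `r² = 2.25`
is `8/3` — a distance of 1.63, slightly outside the radius. The
maximum-likelihood conformations for a contact target are therefore those
placing contact pairs *near* the radius, not necessarily those whose
re-measured contact set reproduces the target exactly.

The log-likelihood drops its normalising constant, so values are
comparable only within a fixed `(N, π_c, r)`. Evaluation is in log space
with the attractive base clamped to `[1e-12, 1]` and `D²` floored at
`1e-9` inside the exponent: the raw expression is undefined at clashes
(negative base, infinite exponent) and `−∞` at `D² = sep²`, but the
optimiser needs finite values. The exponent `sep²/D²` was designed for
short polymers (N below ~150); an optional `exponent_cap` exists in
`ModelConfig` but is off by default. At `r = 1.5` the base is nonnegative
for every clash-free conformation, reaching zero exactly on straight
sub-chains (`D² = sep²`); the clamp is exercised only there and at
clashes.

The training objective over an ensemble of sampled conformations is

```
L(θ, α) = −(1 − α) · E_k[log L(D²_k)] − α · log L(E_k[D²_k]),   α ∈ [0, 1]
```

`α = 0` scores each conformation individually (single-cell / consensus
regime); `α = 1` scores the ensemble-mean squared-distance matrix
(bulk / population regime, a deconvolution reading of bulk Hi-C as an
average of single cells). The objective is affine in `α`.

### Clash handling during training

`aggregated_objective` by default scores *all* samples, clashes included.
Training, however, defaults to `TrainConfig(include_clashes=False)`:
clash-containing shots are dropped from the objective (exactly the filter
applied to the evaluation metrics), falling back to the inclusive cost
only when no shot survives. The reason is numerical: with the clamps
above, a single coincident contact pair contributes about `−1.1e11` to the
log-likelihood, nine to ten orders of magnitude beyond the likelihood
signal among clash-free conformations. A cost landscape with such cliffs
is untrainable for a derivative-free optimiser — in our experiments every
variant tried (trust-region restarts, log-compression of the cost, common
random numbers, simplex and line-search optimisers) stalled with residual
clash mass around `1e-3` and never optimised the likelihood ranking.
Filtering clash shots keeps the cost on the likelihood scale O(1–10); the
clash mass of trained distributions still shrinks because only clash-free
states earn reward. A known side effect at very small systems (N = 3): the
even-parity backtracking state can retain mass because nothing penalises
it directly.

## Ansatz and simulation

The generative model is a two-repetition real-amplitude circuit on
`3(N-2)` qubits: a layer of single-qubit y-rotations, then two repetitions
of (reverse-linear CNOT chain + rotation layer), giving `p = 9(N-2)`
parameters — 36 at N = 6 (12 qubits), 72 at N = 10 (24 qubits). RY and
CNOT have real entries, so the state has strictly real amplitudes; that
suffices because the objective Hamiltonian is diagonal in the measurement
basis.

Simulation is an exact statevector evolution (dense, `2^{3(N-2)}`
amplitudes) followed by a single multinomial draw of `ρ` shots —
distributionally identical to per-shot execution and far cheaper. The
default `ρ = 4096` is used both per objective evaluation and for final
ensembles. A `StateScoreCache` precomputes per-state distances and
log-likelihoods for universes up to `32768` states (N ≤ 7) and falls back
to lazy per-state evaluation above that.

## Optimisation

Parameters are initialised uniformly on `[0, 2π)` and optimised with
COBYLA, initial trust radius 0.7 rad and parameter tolerance 1e-3. A
single COBYLA run on the shot-noisy objective typically collapses its
trust region within ~150 evaluations; the engine therefore restarts from
the best parameters seen, at radii 0.3 then 0.1, until the evaluation
budget (default 2000) is spent, and reports the best-seen `θ*` rather
than the last iterate. Non-finite costs abort with a diagnostic. The
degenerate two-bead polymer returns its single fixed conformation without
building a circuit.

## Simulated targets and ground truth

For small `N` all `8^{N-2}` spin strings are enumerated (guarded at
N ≤ 10; N = 6 gives 4096 states, 2245 of them clash-free). Clash-free
states are partitioned into groups by identical contact set; a group's
contact set, materialised as a binary map, is one simulated Hi-C target.
The ground-truth vector `φ` holds every state's likelihood under a target;
its upper-`q` quantile (linear interpolation, ties at the threshold kept)
defines the "top" conformations for coverage (distinct sampled states in
the top set over top-set size) and empirical probability (shot mass at or
above the threshold).

## Evaluation metrics

* **Empirical entropy** of the sampled state distribution, bits.
* **Likelihood ratio by excitation level**: states ranked by `φ` into 20
  equal-occupancy bins (bin count is this package's choice); ratio of shot
  mass to uniform mass per bin.
* **Contact recovery**: ensemble-mean inferred contact probabilities
  (clash shots dropped) scored against the target by rank AUC
  (tie-averaged) and step-interpolated average precision over pairs at
  separation ≥ 2, plus mean/max inferred probability over the positives.
  The pair-level reading is used throughout; no class rebalancing is
  performed.
* **Dice–Sørensen variants**: weighted
  `DSI_w = 2Σππ̃ / Σ(π + π̃)` and maximum-threshold `DSI_m`, the best
  Dice over thresholds `t ∈ {0} ∪ {distinct π̃}` (including `t = 0` keeps
  the all-included candidate reachable when `π̃` is constant). Both are 1
  by convention when target and inference are empty.
* **Consensus scores**: scale-invariant RMSD
  `min_{s>0} sqrt(mean (s·D − D_target)²)` with the closed-form least-
  squares scale `s* = ΣD·Dt / ΣD²` (this closed form is the package's
  definition of scale invariance), and the Spearman rank correlation over
  upper-triangle distances.
* **Ensemble comparison**: Jensen–Shannon divergence (base 2, in [0, 1])
  between empirical distributions after mapping states to their discrete
  contact sets; a `state_key` hook accepts embedding-based groupings
  (e.g. a UMAP/KDE pipeline) but none ships. Paired F1 matches two sets of
  binary contact matrices by rectangular linear sum assignment maximising
  total F1 (upper-triangle entries; both-empty pairs score 1); duplicates
  are removed from the first set before matching.

## Landscape ruggedness

The empirical maximum information content `H_M` follows the
random-walk symbolisation recipe: `128p` uniform parameter samples set a
min–max normalisation of the cost; 64 random walks of `64p` steps each
produce normalised cost sequences; consecutive differences are symbolised
as `{-1, 0, +1}` against a sensitivity `ε`; the information content at
`ε` is the base-6 entropy of consecutive *unequal* symbol pairs, averaged
over walks; `H_M` maximises over an `ε` grid (zero plus 40 logarithmic
points spanning the observed difference magnitudes). Choices the source
procedure leaves open, fixed here: walk steps are uniform per-coordinate
perturbations of half-width π/20; normalised differences are rounded at
1e-12 before symbolisation so exactly-equal costs register as ties; and
the landscape is evaluated on the exact statevector expectation of the
(clash-filtered) training objective, the deterministic infinite-shot limit
of the trained cost.

## Problem sizes and runtime

The shipped benchmarks run at desk scale by design: training and trend
analyses use N = 6 (4096-state universe, 12 qubits), 4096 shots, five
optimiser seeds per condition, and full-size landscape analyses
(4608 samples + 147k walk evaluations at p = 36, a few minutes each).
Oracle-equivalence checks run at N ∈ {3, 4} where enumeration is exact and
instantaneous. The N = 10 instance (24 qubits, 16.7M states) is supported
by the same code paths behind the enumeration guard but is not exercised
in the default suite.

## What the synthetic benchmarks show — and do not

The simulated targets are *self-consistent*: the ground truth is defined
by the same likelihood the sampler optimises, so the benchmarks measure
the optimiser's and ansatz's ability to concentrate on high-likelihood
conformations, the directional effect of `α` (entropy, energy-level
enrichment, landscape ruggedness), and the correctness of the metric
stack — not the biological fidelity of the likelihood itself. Real
contact-frequency matrices enter only through the calibration rule
`π_c = 1 iff f/f_unit ≥ r^{-1/λ}` (with `f_unit` the smallest nonzero
adjacent-bin frequency) and its inverse `π̃ = min(1, (r/D)^{1/λ})`; the
power `λ` is dataset-dependent (1/3, 1/2, 2/3 are typical), matrices are
assumed cis-only and balanced upstream, and all-zero (unmappable) bins
are dropped with an index map retained. Known limitations: binary
contacts only (no probabilistic `π_c`), no excluded-volume enforcement
during decoding (clashes are detected, not forbidden), no device-noise
modelling, and single-polymer systems only.
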