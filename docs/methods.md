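# Methods

## Model

The core object is a synchronous Boolean network over `m` gene modules.
A module state vector `S(j) = (s_1(j), ..., s_m(j))` describes which
modules are ON at position `j` along the morphogen axis; positions are
read as pseudo-time in the direction of morphogen spread (anterior →
posterior by default; the posterior → anterior reading is available via
`GMNModel(..., reverse=True)` and, on typical data, collapses to the
all-OFF fixed point — a useful negative control).  Every module updates
simultaneously:

    s_i(j+1) = f_i(s_1(j), ..., s_m(j))

with `f_i` an AND/OR/NOT expression over a regulator subset.  A state
`S` with `step(S) = S` is a fixed point; cycles of length > 1 are also
detected and flagged, although spatial expression data, which pins the
terminal state, normally yields fixed points only.  The basin of an
attractor is the set of initial states whose trajectories reach it,
*including* the attractor's own states, so basin sizes always sum to
`2^m`.

Key modelling assumptions, and where they come from:

- **Binary module activity.** Individual genes are graded, but
  module-level activity (majority of binarized member genes) is treated
  as ON/OFF.  This is the empirical observation that motivates the
  Boolean treatment, not something the pipeline tests.
- **Stationarity in the source compartment.** The morphogen level is
  approximately constant inside its source compartment, so the terminal
  observed column is duplicated (label `B7*`-style) before inference.
  This single extra transition pins the terminal state as a fixed point
  of the observed dynamics.
- **Synchronous, deterministic updates.** One update per position
  interval; no asynchronous or probabilistic semantics.

## Conventions (deliberately literal, hence testable)

- Gene binarization: 1 iff the value **strictly** exceeds the gene's
  across-position mean.
- Module state: 1 iff **strictly more than half** of member genes are 1;
  exact ties are OFF.
- Bit-strings render module M1 leftmost, so `000000000111` means
  M10–M12 ON.  Internally states are packed into integers with M1 in the
  least-significant bit.
- Module labels: clusters are renumbered along the axis by the first
  position at which the cluster's mean profile exceeds its own mean
  (the ON-region start), ties broken by peak position, then by original
  cluster label.  Plain peak-argmax is ambiguous for plateau-shaped
  module profiles — with equal ON-level means, noise decides the argmax
  between adjacent modules — while the plateau start is stable.

## MRG screen

The published screening criterion ("g_k(j) ≥ 2 g_k(j+1), or
g_k(j) ≤ 2 g_k(j+1) in four consecutive intervals") is tautological as
printed, so the implemented reading is declared: a gene passes if some
window of `window_intervals` (default 4) consecutive intervals is
direction-consistent with a per-interval fold change ≥ `fold`
(default 2), computed on values + `eps`.  `fold=1` degrades to plain
monotonicity.  `eps` defaults to 1e-6 × the smallest positive value and
guards zeros; because the pseudo-count slightly deflates true ratios,
the fold comparison carries a 1e-5 relative slack so an exact 2-fold
change passes at `fold=2`.

A geometric consequence worth knowing: a 4-interval window spans 5 of
the 6–7 positions of a single section series, so a noise-free gene whose
profile is an interior band (high only on a mid-axis interval) cannot
pass — a monotone ≥ 2-fold run crosses the gene's mean only once.  On
real (noisy, asymmetric) profiles this is softened, but it means the
screen is a *gene-level* filter for morphogen responsiveness, not a
module-recovery step.  The noiseless end-to-end recovery demonstrations
therefore enter the pipeline at integration with an explicit gene list,
and the screen is validated on monotone, marker and background fixtures.

## Integration and batch adjustment

Batch adjustment is a per-gene offset removal on
`log2(value + pseudocount)` (default pseudocount 1.0, configurable):
each batch's mean deviation is removed and the gene's grand log-mean is
preserved.  This is the simplest model consistent with removing a
constant batch effect; it is not numerically identical to
regression-based tools.  Note that with a non-zero pseudocount a purely
multiplicative batch offset is no longer exactly additive on the log
scale; with `pseudocount=0` (all-positive data) the removal is exact.
The interleaving order of the two section series is user-supplied
configuration; when marker genes are named (*hh*-like, *ci*-like,
*dpp*-like) their integrated shapes are checked (terminal-exclusive /
terminal-excluded / interior peak) and deviations are warned about.

## Network inference

For each module, regulator subsets are searched in order of size
(0 … `max_indegree`), and within a size lexicographically; the first
subset on which no two observed transitions disagree is taken.  Unseen
truth-table rows are filled by the completion policy: `zero` (default —
unobserved input patterns leave the module inactive) or `majority`.
Many rule sets are typically consistent with a short sequence; this
deterministic selection makes results reproducible but means the
*rendered rules* are one canonical choice among equivalents, while the
reproduction of the observed sequence is a hard postcondition.
`max_indegree` defaults to `min(4, m)`: a 13-transition sequence cannot
meaningfully constrain larger in-degrees.  Inferred truth tables are
rendered as minimal sum-of-products expressions (Quine–McCluskey) in the
`targets, factors` dialect, which parses back truth-table-identically.

## Dynamics

The successor of all `2^m` states is built vectorized; each state's
eventual cycle is found by pointer doubling (`m` squarings reach ≥ `2^m`
steps, beyond any transient), cycles are walked explicitly, and basins
are counted by membership of the eventual state.  An independent
brute-force simulator (plain per-state stepping, written separately in
the test suite) certifies attractors, basins and tree membership
exhaustively for `m ≤ 4` and spot-checks 200 random 12-module networks.
Exhaustive enumeration is capped at `m = 24`.

The *major trajectory* is the update path from the first observed
column (the anterior-most state); on consistent data it reproduces all
observed states in order and ends in the "normal" attractor — defined
throughout as the attractor this trajectory reaches.

## Robustness studies

**Bit-flip perturbation.** `n_flips` (default 2) distinct uniformly
chosen cells of the observed columns are flipped (the duplicated
terminal column is excluded from the draw and re-synchronized), the
network is re-inferred and its attractor set compared with the
original's (exact set equality; cycles as state sets).  Reported over
`reps` replicates: the agreement percentage, mean basin sizes of the
original attractors over matching replicates, and a comparison of
trajectory overlap-ratio distributions.  The overlap ratio of an
initial state in the normal basin (major-path states excluded) is the
fraction of its trajectory's states lying on the major path.  The
comparison uses the two-sample Kolmogorov–Smirnov test by default (the
original analysis does not name its test, so the statistic choice is
ours and the p-value is not comparable); the perturbed vector is taken
from the first attractor-matching replicate.  Replicates whose
inference fails are recorded as non-matching, never fatal.

**Morphogen-production scan.** The contiguous ON run `[a, b]` of the
readout module (default M8, where Hh-pathway genes concentrate) is
modified per shift δ: production increase (δ > 0) widens the run away
from the source boundary (`a → a−δ`, clamped at the first position);
production decrease (δ < 0) switches off the `|δ|` run positions closest
to the boundary (`b → b−|δ|`), down to an all-OFF row with a warning.
This follows the verbal description of how gradient stretching/shrinkage
moves the readout's induction boundary; the exact published mapping from
production level to ON/OFF pattern is supplementary material we do not
redistribute, so the run-shift is a declared interpretation.  Each
scenario table is re-inferred and scored by the percentage of all `2^m`
states converging to the normal attractor of the *unmodified* analysis;
δ = 0 reproduces the baseline exactly.  A `mode="fixed"` variant keeps
the physiological network and instead restricts initial states to those
agreeing with the modified row at the first position.

## Synthetic data generator

The generator emulates the structure of position-resolved wing-disc
RNA-seq; its defaults are fixed study conditions:

| parameter | default | rationale |
|---|---|---|
| modules / positions | 12 / 13 (+ duplicated terminal) | matches the modular, 13-position design of the motivating data |
| ON runs | contiguous, starts strictly increasing | position-interval modules; peak-ordered so renumbering is the identity; terminal column `000000000111` echoes the posterior-compartment pattern; M8 ON just anterior to the source boundary |
| genes per module | 40 | enough for stable majority votes, small enough for fast clustering |
| `mu_on` / `mu_off` | 100 / 1 (FPKM-like) | a strongly expressed gene vs. background |
| off-run decay | 8-fold per position | ≥ 2-fold per interval (monotone for the screen) *and* steep enough that binarization recovers the run exactly: the nearest off-position value (`mu_off`) sits well below the gene mean (≈ `L·mu_on/13`) |
| noise | log-normal, σ = 0.2 (natural-log scale) | modest multiplicative measurement noise on positive data |
| batch offsets | 1.0, 1.6 | constant per-batch scale (library-size/batch effect) |
| batches | A: 6 positions, B: 7, staggered | the two interleaved section series |
| markers | *hh*/*ci*/*dpp*-like, noiseless fixed shapes | so integration-order validation is exact |
| background | 20 alternating non-monotone genes | must fail the screen |

The ground-truth network is the deterministic inference result on the
noiseless table; by the inference postcondition its trajectory from the
first column reproduces the table exactly, which makes the generator and
the pipeline mutually checking.

What the generator does **not** emulate: read-count noise (no negative
binomial), gene–gene correlation beyond module membership, asymmetric or
drifting profiles, spatial smoothing of the gradient, dropout.  Passing
tests therefore certify the *pipeline machinery* — screening logic,
binarization/majority conventions, inference determinism and
consistency, exact dynamics, reproducible robustness studies — not that
real tissue data will be as well-behaved.  In particular the synthetic
table's robustness numbers differ from the published study's (its
two-bit-flip attractor agreement is ~20–25%, against ~99.9% reported for
the original table): with only 13 transitions, re-inference is sensitive
to flips, and how sensitive depends on the table itself.  The published
rule/state tables are journal supplementary material and are not
redistributed; transcribing them into `data/published/` enables the
direct comparisons in the test suite.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng(seed)` local to
  each call; no global RNG state.  Same seed ⇒ byte-identical outputs.
- Screen: `eps > 0` required; fold comparison carries 1e-5 relative
  slack (above).
- Clustering: per-gene z-scores (zero-variance genes become all-zero
  profiles; undefined correlation distances are set to 1), SciPy
  `linkage`/`fcluster` with `maxclust=m`; deterministic.
- Ties: gene binarization at the mean → 0; module vote at exactly half
  → 0; inference subset ties → smallest, then lexicographic.
- `n_flips = 0` and δ = 0 are exact identities (used as test anchors).
- Problem sizes in the default test and acceptance runs: 12 modules /
  4096 states throughout; 1000 perturbation replicates in the
  acceptance script, 10–120 in unit tests; 200 random 12-module networks
  plus exhaustive `m ≤ 4` in the oracle-equivalence check; 20 replicate
  seeds in recovery-rate checks.

## Known limitations

- Rule rendering depends on sympy's canonical term ordering; it is
  deterministic for a given sympy version but the textual form (not the
  truth table) could differ across versions.
- The batch adjustment is a mean-offset model; systematic non-linear
  batch effects are out of scope.
- The screen's strict monotone window excludes noiseless interior-band
  genes (geometric argument above); callers wanting band genes retained
  should lower `window_intervals` or supply the gene list explicitly.
- Attractor enumeration is exhaustive only; no SAT/BDD symbolic mode, by
  design, since `m = 12` is the intended regime.
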