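# Methods

`rsnphi` quantifies integrated information and three reference measures
on small multivariate binary time-series of the kind produced by
region-level resting-state fMRI after binarization.  This note states
the models, the conventions that make the quantities well defined, the
defaults and why, and what the synthetic generator does and does not
emulate.

## From continuous signals to binary state sequences

Continuous region signals (time x region, sampling interval
`tr_seconds`, default 2.0 s) are linearly detrended and band-pass
filtered with a Butterworth filter, cutoffs 0.01–0.1 Hz.  The filter
order and phase handling are free choices; we use order 2 applied
forward–backward (`sosfiltfilt`), the common resting-state practice, so
the timing of threshold crossings is not shifted by filter phase.  Each
region is then z-scored against its own mean and standard deviation
(sample SD, `ddof=1`; binarization is insensitive to this choice) and
thresholded at zero: positive z-scores become 1 (above-baseline
activity), negative become 0.  An exact zero is a measure-zero boundary
event; it deterministically maps to 0 (configurable).  A network of
`N` regions then occupies one of `2**N` states per time point; states
are indexed little-endian, node 0 as the least significant bit.

Because one subject contributes only a few hundred time points against
32 states, series from several subjects are concatenated.  Every
concatenated series carries per-subject provenance segments, and all
transition counting excludes pairs that span a segment boundary:
adjacent samples from different subjects are not transitions of any
real dynamical system.  A compatibility flag re-includes them.

## Transition probability matrices

The state-by-state TPM is estimated by counting transitions `i -> j`
and dividing each row by the number of times state `i` appeared *and
transitioned onward* (a state seen only at the end of a segment
contributes nothing to its row).  Rows of states never observed to
transition have no empirical law; by default they are filled with the
uniform distribution (maximum entropy — it adds no spurious structure
and keeps every repertoire well defined), with `self`-loop and `error`
policies available.  The state-by-node form holds each node's marginal
ON-probability per current state; converting state-by-state ->
state-by-node -> state-by-state produces the unique conditionally
independent variant `B` of a TPM `A`, and the conditional-independence
diagnostic reports `D = ||A - B||_F / ||B||_F` (zero iff `A` already
factorizes over nodes).

### Markov-property test

The first-order assumption is probed with a contingency test seeded on
the most frequent state triple `(a, b, c)` with `b != c`.  Rows
enumerate every first state `x` observed before the bigram context:
the sequence count SC = #(x, b, c) and non-sequence count
NSC = #(x, b, e != c).  Under the Markov property P(c | b) cannot
depend on `x`, so the SC/NSC proportions are homogeneous across rows;
the chi-squared statistic (no continuity correction, no row pooling —
a warning is emitted when any expected count is below 5) has `H - 1`
degrees of freedom for `H` rows.  By construction the test only
detects first-order violations.  Calibration is conservative for short
sequences (empirical type-I rate ~0.03 at 1,500 points) and accurate
from roughly 3,000 points on; the calibration test therefore uses
chains of that length.  Only the single most frequent triple seeds the
test; combining several seed triples would be possible in principle
but multiplies the comparisons without changing what the test detects,
so it is left out.

## Integrated information (IIT 3.0)

All quantities are defined relative to a state-by-node TPM and a
current network state.  A subsystem is a node subset; nodes outside it
are background conditions, frozen at their current state when the
subsystem TPM is extracted.  The conventions are the canonical IIT 3.0
ones, stated here because the numbers are only meaningful relative to
them:

* **Priors.** Unconstrained distributions are uniform (maximum
  entropy).
* **Cause repertoires** factorize over mechanism elements: each
  mechanism node's likelihood over the purview's past states is
  marginalized over non-purview inputs *separately per node* (the
  "virtual elements" treatment), then the per-node likelihoods are
  multiplied and renormalized.  **Effect repertoires** factorize over
  purview elements: each purview node's next-state ON-probability is
  conditioned jointly on the mechanism state with all other inputs
  marginalized uniformly.
* **Small phi.** For a mechanism and direction, every purview is
  scored by the minimum, over all two-part factorizations of
  (mechanism, purview) in which each part is non-empty on at least one
  side, of the earth mover's distance (EMD) between the intact and the
  partitioned repertoire; the purview maximizing that minimum wins.
  The mechanism-level ground metric is the Hamming distance between
  purview states.
* **Concepts and big Phi.** A mechanism with positive small phi in
  both directions (tolerance 1e-10) contributes a concept.  Big Phi is
  the minimum over unidirectional cuts (sever all connections from one
  part to the other; severed inputs are marginalized uniformly) of the
  extended EMD between the intact and cut conceptual structures:
  concept mass (small phi) is transported between structures, with
  surplus mass moved to the null concept (the unconstrained
  repertoires); the ground distance between concepts is the sum of the
  Hamming-EMD between their cause repertoires and between their effect
  repertoires, each expanded to the full subsystem space (causes with
  the uniform distribution, effects with the subsystem's unconstrained
  effect marginals).
* **Ties** between purviews or partitions break toward the larger
  purview, then the lowest little-endian node mask, so repeated runs
  are bit-identical.
* **Degenerate conditioning.** Empirical TPMs contain zeros, so a
  mechanism state can have zero probability; its cause repertoire is
  then replaced by the uniform distribution and a fallback counter on
  the subsystem is incremented.

`phi_max` maximizes big Phi over candidate subsystems: `exhaustive`
mode scans every subset of two or more nodes, `full` mode (the
default) evaluates only the complete node set — in this analysis the
full set is where the maximum is found, and exhaustive search on five
nodes is roughly an order of magnitude more work.  The cost grows so
steeply with network size (all mechanisms x purviews x partitions x
cuts) that exhaustive mode warns beyond five nodes.

`mu_phi_max` summarizes a series: the TPM is estimated from the
series, big Phi^max is computed once per *distinct visited* state, and
the average weights each state by its occurrence frequency (state
counts, not transition counts).

### Earth mover's distance

The transportation problem is solved exactly by successive shortest
augmenting paths (Bellman–Ford with residual reverse edges), compiled
with numba; common mass is cancelled first so only the residual is
transported.  The solver agrees with an independent linear-programming
formulation to 1e-8 across randomized instances (tested), and results
are memoized because the same repertoire pairs recur across partitions
and cuts.

## Reference metrics

* **Phi\*** (lag `tau`, default 1 sample): the plug-in mutual
  information (natural log) between the whole system's lagged state
  pairs minus the sum of part MIs, minimized over all bipartitions
  into near-equal halves — the 10 splits of sizes 2|3 for five
  regions.  Lag pairs never span subject boundaries.  No bias
  correction by default; a Miller–Madow flag exists.  Note this plain
  MI difference can be negative: for strongly self-persistent nodes a
  misaligned split's part MIs can exceed the whole MI.  This plain
  MI-difference with the minimum rule is the definition implemented
  here; the mismatched-decoding variant found elsewhere in the
  literature is a different estimator and is deliberately not
  substituted for it.
* **Causal density**: least-squares VAR fits for orders 1..`p_max`
  (default 20); the order minimizes BIC by default (stronger
  overfitting penalty than AIC, which is available by flag).
  Concatenated series are fitted as separate trials sharing
  coefficients.  For each ordered pair `i -> j`, the conditional
  Granger statistic is `F = ln(sigma2_restricted / sigma2_full)` where
  the restricted model drops region i's lags while conditioning on all
  other regions; numerically negative ratios clamp to zero with a
  warning.  CD is the mean over all `N(N-1)` directed values (for an
  arithmetic mean this equals averaging the two directions first).
  Applying Gaussian-likelihood Granger causality to binarized series
  is an acknowledged approximation; it is kept so that all four
  metrics see exactly the same binary series as the integration
  analysis.
* **mu[rho]**: the mean Pearson correlation over the `N(N-1)/2`
  unordered pairs; exactly invariant under any common reordering of
  time points, which is why temporal controls cannot move it.

## Permutation controls

Spatial controls regroup regions: each control network draws its
regions from distinct source networks (regions may recur across
controls but never within one), preserving every region's marginal
series and destroying network composition.  Temporal controls permute
whole time points of the binarized series (the stated order of
operations), preserving state frequencies exactly while destroying the
transition structure — integration and causal density collapse,
correlation is untouched.

## Modulation analysis

For each network, a metric's condition means form
`M = [m_A, m_M, m_D, m_R]`; the magnitude is `|M|` and the awareness
similarity is the cosine of `M` with the fixed model vector
`E = [1, 0, -1, 1]` (decline into deep sedation, rebound in recovery).
Uncertainty comes from leave-one-subject-out concatenations: with `N`
subjects, `N` series each omitting one subject.  These resamples
overlap heavily, so their spread underestimates population spread; per
the emulated design the sample SD is read as a standard error and the
population SD reported as sample SD x sqrt(N).  Condition pairs are
compared with Welch's t-test (Welch–Satterthwaite degrees of freedom,
two-sided) and Benjamini–Hochberg controls the false discovery rate.
The BH family is genuinely ambiguous in the reference description;
the default family is *across networks within each condition pair*,
with *across pairs within each network* selectable — both are reported
with the family label.  Magnitude variability across networks is
`100 x (max - min) / max` percent (denominator `max` keeps it in
0–100; a mean-denominator variant exists).

## The synthetic cohort generator

Real resting-state network dynamics are unknown; the generator
therefore defines ground truth as an explicit state-by-state TPM per
network and condition, so estimation-recovery tests are exact.  The
TPM mixes an independent part (each node a two-state chain with
persistence `P(on|on) ~ U(0.6, 0.9)` and turn-on `P(on|off) ~
U(0.1, 0.4)`) with a synchronizing kernel (jump to all-ON with
probability `0.1 + 0.8 x fraction-active`, else all-OFF), weighted by
a coupling strength `c in [0, 1]`.  At `c = 0` the TPM factorizes
(zero conditional-independence distance, zero big Phi); raising `c`
raises both cross-node dependence and temporal structure — exactly the
properties integration and causal density respond to and temporal
shuffling destroys.

A cohort mirrors the emulated study design: 17 subjects x 4 conditions
(Awake, Mild, Deep, Recovery) x 11 named networks of 5 regions, 245
time points per subject at TR = 2 s — all configurable.  Sedation acts
multiplicatively on coupling through the per-condition profile
`[1, 0.7, 0.3, 1]`, scaled per network by a sensitivity in [0, 1]:
the frontoparietal and dorsal-attention analogues (sensitivity 1.0)
track the profile fully, the default-mode analogue partially (0.5,
with the lowest baseline coupling 0.35), and the sensory analogues
barely (0.1–0.25, with the sensorimotor analogues given the highest
baseline couplings 0.75–0.80).  These choices give the cohort the
qualitative structure the analysis is designed to detect — strongly
modulated higher-order analogues, high-magnitude but weakly modulated
sensory analogues — with one shared generative law per (network,
condition) and per-subject variation arising only from sampling.

What the generator does *not* emulate: haemodynamics (no HRF
convolution), head motion or physiological artifacts, inter-subject
differences in dynamics, spatial structure of any kind, and the
autocorrelated, non-Markovian character of real BOLD signals (the
generator is exactly first-order Markov, which is what makes the
diagnostics' null behavior testable).  Passing tests therefore
demonstrate correctness of the estimators and the direction of their
responses to coupling and shuffling — not that real fMRI satisfies the
model's assumptions; on real data the Markov and
conditional-independence diagnostics exist precisely to measure those
violations.  The BOLD-like generator (coupled AR(1) plus noise, slow
sinusoidal drift and linear trend) exists to exercise the
detrend/filter/binarize path, not to model physiology.

## Problem sizes

Integration metrics are exact but expensive: the engine's cost per
state grows as roughly `O(n 5^(3n))` bookkeeping, so one five-region
state evaluation takes tens of seconds while three-region states take
well under a second.  The test suite and the acceptance script
therefore run cohort-level analyses at three-region scale (8 subjects,
150 time points, all 11 networks) and demonstrate the five-region
computation on single states and on the estimation layer (50,000-step
recovery); these sizes are the package's reference configuration for
its own regression baselines.  Oracle-equivalence runs exhaustively at
two and three nodes against a brute-force enumeration oracle, and the
reducibility axiom (factorizable TPM implies zero Phi) is checked
exhaustively up to four nodes.

## Known limitations

* Big Phi beyond 5–6 nodes is computationally out of reach by design;
  no approximate or heuristic variant is provided.
* Mechanism-level-only summaries (sum or mean of small phi) can be
  assembled from `ConceptualStructure.total_phi` but are exploratory
  and unvalidated.
* Gaussian Granger causality on binary series, and plug-in MI without
  bias correction, are deliberate simplifications kept for
  comparability across metrics.
* The chi-squared Markov test is conservative on short series and
  detects only first-order violations.
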