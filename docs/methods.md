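# Methods

`slgraph` implements an electrode-level functional-connectivity analysis of
multichannel EEG contrasting two within-subject conditions (normal sleep,
NS, versus total sleep deprivation, TSD): synchronization-likelihood
connectivity, fixed-degree binary graphs with per-node clustering
coefficient and path length, spatial cluster-based permutation inference,
and a band-power mediation analysis addressing volume conduction.  A
synthetic-study generator with planted effects provides ground truth for
every stage.

## Band-pass filtering

Epochs are filtered into the five canonical bands (delta 1–4, theta 4–8,
alpha 8–13, beta 13–30, gamma 30–45 Hz) with a zero-phase FIR filter:
Hamming-window design, forward–backward application, transition width 25%
of the low band edge.  Zero-phase filtering avoids group-delay distortion
that would shift recurrence times in the SL computation.  The filter order
is capped at a third of the record length (with a warning) so that
forward–backward filtering remains applicable to short records; in that
case the transition band widens.

## Synchronization likelihood (SL)

SL measures generalized synchronization between two signals x and y.  Both
are time-delay embedded (dimension m, lag l).  For reference time i, the
candidate times j are those in the annulus w1 < |i − j| ≤ w2; the Theiler
window w1 excludes temporally adjacent, autocorrelated states, and w2
bounds the search range.  A per-signal, per-reference critical distance is
the Euclidean distance to the ⌈p_ref · n_candidates⌉-th nearest candidate,
so a fraction ≈ p_ref of candidates is *recurrent* (ties at the radius all
count, so the realized fraction can slightly exceed p_ref).  SL(i) is the
number of jointly recurrent candidates divided by the number of recurrent
candidates of the conditioning signal; the reported SL averages SL(i) over
all valid references and symmetrizes the two conditioning directions.  SL
is p_ref in expectation for independent stationary signals and exactly 1
for identical signals.

Embedding parameters follow a frequency-prior recipe from the band edges
(LF, HF) and sampling rate fs:

    lag = round(fs / (3 HF))          m  = floor(3 HF / LF) + 1
    w1  = 2 lag (m − 1)               w2 = w1 + floor(10 / p_ref)

w2 is capped at the embedding length.  The recipe targets ten expected
recurrences per reference; when an epoch is too short for that budget the
computation proceeds with a warning, and it errors only when the annulus
would hold fewer than max(10, ⌈1/p_ref⌉) candidates (below which the
expected recurrence count per reference drops under one and the conditional
likelihood becomes meaningless).  All four parameters are exposed in
`SLParams` and can be overridden.

Defaults: p_ref = 0.01; reference times are every valid embedding index (no
subsampling).  The inner loops are JIT-compiled; recurrences are stored as
packed 64-bit bitmaps and pair coincidences counted with popcounts, which
makes the all-pairs computation linear in memory and fast enough for
repeated whole-study simulation.  An exhaustive brute-force enumeration in
the test suite pins the kernel to the definition at 1e−12.

## Graphs and node metrics

Each SL matrix is thresholded to a binary graph by keeping the
floor(n·K/2) strongest off-diagonal values, fixing the mean degree at
(almost) K; ties at the threshold break deterministically by descending SL
then ascending (row, column).  K is kept small (5–8 at 61 channels) so only
the strongest connections survive; results are reported per K and never
pooled, with a per-band flag stating whether a cluster is significant for
every configured K.

Per node: clustering coefficient C = connected neighbour pairs / possible
neighbour pairs (C := 0 for degree < 2), and path length L = arithmetic
mean of shortest-path hop distances to all other nodes, with unreachable
nodes contributing ∞ — so L is ∞ for every node of a disconnected graph.
Aggregation across the design uses the harmonic mean (n / Σ 1/v, with
1/∞ := 0): epochs within a session first, sessions next, yielding one value
per subject, condition, node, band and K.  The harmonic mean stays finite
whenever any epoch is finite.  Two numerical choices: C values of exactly 0
are floored at 1e−6 before harmonic aggregation (the harmonic mean is
undefined at 0; the floor count is logged), and an aggregated cell that is
still ∞ (a node disconnected in *every* epoch of a condition) is capped at
1.5× the largest finite value in the table when the paired sample is built,
keeping t statistics finite while preserving the node's extremity (logged).

## Cluster-based permutation test

Node-wise paired t-tests (TSD − NS) are thresholded at the node-level alpha
(default 0.05, two-sided).  A significant node joins a cluster only if at
least two of its spatial neighbours are also significant; clusters are the
connected components of the electrode adjacency restricted to those
candidates, split by t-sign.  The electrode neighbour relation is Delaunay
triangulation of the 2-D layout by default (parameter-free); a Euclidean
distance cutoff is available as a sensitivity check.  The ≥2-neighbour
filter is applied in a single pass before component extraction.

The Monte-Carlo null swaps the NS/TSD labels of each subject with an
independent fair coin (equivalently, flips the sign of that subject's
difference) and records, per permutation, the maximum positive and maximum
negative summed cluster t.  Each observed cluster is compared with its own
tail's null at the per-tail alpha (default 0.025, i.e. a two-sided test at
0.05 family-wise), with the (+1)/(+1) Monte-Carlo correction so p is never
exactly 0.  Sign flips leave per-node sums of squares invariant, so the
whole permutation batch reduces to one matrix product; cluster forming runs
only for permutations with at least three supra-threshold nodes.

With n subjects there are only 2^n distinct sign patterns; the mass of
near-identity patterns bounds the attainable p from below (≈ (n+1)/2^n).
At 8 subjects this floor (~0.035) exceeds a 0.025 threshold, which is why
the planted-effect validation scenario uses 12 subjects.

## Mediation analysis

For each significant cluster, Welch band power (2-s Hamming windows, 50%
overlap; band power = mean in-band spectral density by default, integral
optional) is computed per electrode and epoch, averaged to session level,
and entered as mediator M between condition X (NS=0, TSD=1) and the
session-level graph metric Y:

* M1: M ~ X → a, s_a;  M2: Y ~ M + X → b, s_b, beta_with;  M3: Y ~ X →
  beta_without,

fitted as linear mixed models with random intercepts for subject, subject ×
experimental day, and electrode × subject (day defaults to the condition
label, one recording day per condition).  When a mixed fit is singular or
fails the model falls back to ordinary least squares and the result is
flagged as non-converged rather than dropped.  Mediation requires the four
classic criteria (X→M, X→Y, M→Y given X, and |beta_with| < |beta_without|)
and Sobel Z = a·b / √(b² s_a² + a² s_b²) significant at |Z| > 1.96; it is
labelled *partial* when X stays significant alongside M, *full* otherwise.

## Synthetic studies

The generator emulates the full design — subjects × {NS, TSD} × sessions ×
fixed-length epochs on a quasi-equidistant planar grid whose top third (by
the vertical coordinate, with a jitter-proof margin) is the designated
frontal region.  Per band, each channel mixes a field of latent band-limited
Gaussian sources (one per electrode site) with Gaussian spatial weights
(length scale 1.2 grid units), so inter-channel correlation decays smoothly
with distance, the way volume conduction spreads real scalp fields; the
shared field carries a per-band fraction of channel variance (coupling,
default 0.9), the rest being private narrowband noise, plus broadband 1/f
noise.  Band amplitudes follow a resting eyes-closed-like spectrum (delta
2.0, theta 1.5, alpha 2.0, beta 0.8, gamma 0.4).  Couplings get a
per-subject Gaussian perturbation (sd 0.05); every draw descends from one
mandatory seed, and identical seeds give bit-identical studies.

Under TSD the frontal channels' coupling shifts by a per-band delta and
their band power by a per-band factor, independently switchable so
connectivity effects with and without power changes can be planted.  The
defaults mirror the reference design (8 subjects, 5 sessions, 8 epochs of
8 s at 512 Hz, 61 channels) and plant a frontal alpha decoupling (−0.8), a
partial frontal theta decoupling (−0.6), an alpha power decrease (−30%) and
a theta power increase (+30%).  The alpha drop is near-total so local
cliques dissolve and C falls; the theta drop is deliberately partial so the
region stays weakly attached and its path lengths grow *without*
disconnecting the graph — a full detachment makes L infinite everywhere
(any unreachable node inflates every node's L) and destroys the spatial
contrast.

What the generator does not emulate: forward-modelled lead fields, ocular
and movement artifacts, non-stationarity within epochs, phase-coupled
oscillator dynamics, and electrode impedance drift.  Passing tests
therefore demonstrate that the statistical machinery recovers effects of
this linear-mixing form at the configured sizes, not that real sleep-
deprivation EEG would yield the same topographies.

## Validation scenarios and sizes

Repeated end-to-end runs use two frozen reduced designs (`slgraph.scenarios`):

* **null**: 8 subjects × 16 channels × 1 session × 4 epochs of 4 s at
  128 Hz, no planted effect, alpha band at K = 4; one run is one two-sided
  cluster test family (C and L).  200 runs check the empirical
  family-wise false-positive rate against the binomial band around 0.05.
* **effect**: 12 subjects × 25 channels × 2 sessions × 4 epochs of 4 s at
  128 Hz, frontal alpha delta −0.8 and theta delta −0.6 (no power change),
  K ∈ {7, 8}, 1000 permutations.  Recovery means: for every K, a
  significant majority-frontal cluster with negative summed t for alpha C
  and positive summed t for theta L.

The scenario sizes are the package's choice of smallest designs at which
the respective properties are statistically identifiable: 16 channels
suffice for a null rate, while topography recovery needs a two-row frontal
block (the ≥2-significant-neighbour rule excludes the corners of a single
row) and 12 subjects (sign-flip p floor, above).  Mediation logic is
validated on a direct linear simulator of the three-variable causal system
(known a, b, direct effect; random intercepts as in the analysis model)
rather than on full EEG runs, which isolates the regression/Sobel logic
from connectivity noise.

## Known limitations

* SL is strongly compressive at low coupling: with linear mixing, pair
  correlations below ~0.5 are barely distinguishable from chance at 512
  samples per epoch, so planted effects must act on strongly coupled pairs.
* The ∞-propagation rule for L makes whole-graph disconnection a global
  event; at small n and K the metric is dominated by connectivity noise
  unless the graph stays connected in the no-effect condition.
* The mixed-model solver occasionally reports boundary (singular) variance
  components on small synthetic data; results are then flagged rather than
  suppressed.
* The embedding-parameter recipe is a faithful reconstruction of the cited
  frequency-prior scheme, but no published SL values exist to pin the
  original implementation numerically.
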