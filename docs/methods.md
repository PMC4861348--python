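# Methods

This note documents the models, estimators and design choices behind
`spikepid`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and where the edges of validity are.

## Information measures on binned spike trains

Spike trains are reduced to binary series by half-open binning (a bin is 1
iff it contains at least one spike). All information quantities are
computed from plug-in (maximum-likelihood) joint state frequencies in base
2, with `0·log 0 := 0` and zero-mass conditioning states contributing
nothing. No bias correction is applied: estimation bias is handled at the
inference stage by comparing against surrogates computed with exactly the
same estimator, not by debiasing individual values.

Transfer entropy from source J to receiver I is the conditional mutual
information `MI(I_F; J_P | I_P)` between the source past and the receiver
future given the receiver's own immediately preceding state. The receiver
self-lag is one bin by default (exposed as a parameter); source delays are
enumerated per timescale and the per-pair TE is the **maximum over the
delay list**, with the arg-max delay stored and reused by every downstream
stage so the triad decomposition is tied to the same lags the pairwise
inference selected. Normalized TE divides by the receiver-future entropy
`H(I_F)` (defined as 0 when the receiver never or always fires) and is
clipped to [0, 1] against floating-point dust.

Two canonical timescales are provided: 1.6 ms bins with delays 1–4 bins
(interactions 1.6–6.4 ms) and 3.5 ms bins with delays 1–4 bins (3.5–14 ms),
overlapping ranges that bracket typical cortical synaptic delays of
1–20 ms. Both bin width and delay list are freely configurable.

## The partial information decomposition

For two sources the decomposition is computed bottom-up from the redundancy:
redundancy is the minimum information `I_min`, an expectation over receiver
future states of the smaller of the two source-specific informations, each
conditioned on the receiver past. Unique terms follow by subtracting
redundancy from the bivariate TEs, and synergy by subtracting everything
from the joint TE. With this redundancy measure all four terms are
nonnegative; values above −1e−9 that are negative only by round-off are
clamped to zero, while genuinely negative values (which would indicate a
bug) are surfaced unclamped so tests can catch them. Terms are reported
raw (bits) and normalized by `H(I_F)`.

Interaction information `II = MI(J_P; K_P | I_F) − MI(J_P; K_P)` is
included as the classical contrast: it conflates synergy (positive) and
redundancy (negative) into one signed number, and the worked examples in
the test suite demonstrate the cases it cannot resolve (simultaneous
synergy and redundancy; unique information).

Higher-order decompositions are out of scope (the lattice grows too fast);
instead the highest-order synergy for n inputs is bounded by the
information gain `TE({J_1..J_n}) − TE({J_1..J_{n−1}})`. Because TE is
monotone under added sources, the gain is nonnegative. The "which input is
added last" ambiguity is resolved by averaging over the n leave-one-out
exclusions — orderings *within* the remaining set cannot matter for TE, so
this is the only content the permutation average can have. Per receiver and
n, at most 100 input combinations are evaluated (all of them when there are
fewer); combinations are sampled without replacement, seeded. A consequence
of exclusion averaging worth knowing: a receiver driven by one perfect
source plus an irrelevant one has mean gain 0.5 bits, not 0, because the
exclusion of the informative source loses the full bit.

## Surrogate-based network inference

The null for a directed pair displaces every **source** spike independently
by a uniform offset in ±20 ms (window configurable; chosen to cover the
1–20 ms synaptic-delay range so surrogates destroy delay structure while
preserving spike count and slow rate fluctuations), then recomputes TE with
the identical max-over-delays selection. The empirical p-value is the
fraction of surrogates strictly exceeding the real TE, with no +1
correction, and the connection is kept when that fraction is below 0.001 —
with 5000 surrogates, exactly the fewer-than-5 rule. The defaults are 5000
surrogates for publication-scale runs; the CLI default is 200 (where the
threshold is equivalent to "no surrogate exceeds the real value") to keep
desk-scale runs fast.

Sub-network sampling (defaults: 500 sub-networks of 50 nodes with average
total degree within ±0.2 of 3, uniform node sampling with rejection, at
most 1e5 retries) equalizes size and density before degree statistics are
compared across recordings. Matched random ensembles place the same number
of directed non-self edges uniformly at random. TE weight distributions are
fitted with a log10-normal **mass** function over 100 logarithmically
spaced bins spanning the data range; the extra amplitude parameter absorbs
the bin width, and fits are unweighted nonlinear least squares.

## Degree and computation

Every receiver with in-degree d ≥ 2 contributes C(d, 2) triads. Synergy is
correlated with receiver in-degree (one point per triad) and with
transmitter out-degree (two points per triad — each transmitter is a
distinct data point). Pearson correlation is the default with Spearman as
an option; correlations are computed on the full inferred network by
default. Nulls permute the synergy column against the degree column; the
sign-skew test across recordings is the one-sided binomial tail
`P(X ≥ max(n_pos, n_neg))` at p = 1/2, with zero or undefined correlations
excluded. Per-degree profiles report median and quartiles and omit degrees
with fewer than 20 triads. Median information gain versus n is fitted with
`a·exp(b·n)` by nonlinear least squares, with a t-based 95% CI on b.

## The synthetic-data generator

The generator emulates the statistics of hour-scale culture recordings:
independent homogeneous Poisson background (default 2 Hz, near the ~2.1 Hz
average of the recordings this pipeline targets; any rate in the
0.03–10 Hz range works), optional network-wide binary common drive that
scales rates by 1±depth, pairwise couplings in which each source spike
induces a target spike at the stated delay with probability 0.5 (strong
enough to multiply delayed coincidence rates several-fold over an hour),
and planted three-neuron motifs.

A motif triad runs on a clock with one tick every `delay_bins + 1` bins; at
each tick a state tuple (i_F, i_P, j_P, k_P) is drawn i.i.d. from the
specified 16-state column and the four corresponding bins are forced. The
stride keeps consecutive ticks' forced bins disjoint, which is essential:
several columns (the self and hidden-self interactions) have a
deterministic self-copy transition, so a Markov realization would freeze in
one state — independent ticks are the only way a single recording can
realize those distributions. The cost of this design is that the planted
distribution is exact *at the motif clock* (receiver self-lag equal to the
motif delay, futures restricted to ticks — what `motif_observations`
evaluates); lagged rows taken at every bin mix in unforced bins and dilute
the motif. Recovery tests therefore measure the estimand the generator
actually plants. Printed motif columns are renormalized to sum to one
(their four-decimal entries are rounded; one column sums to 1.0002).

What the generator does **not** emulate: bursting, refractoriness,
non-stationarity, rate heterogeneity across neurons, and inhibition.
Passing recovery tests shows the estimators are correct on data satisfying
the pipeline's stationarity assumptions, not that real cultures satisfy
them.

## The feedforward model

Two layers of N binary neurons (N = 20 default, 40 supported), firing
probability `1/(1 + e^{−αI+β})` with α, β solved in closed form from
p(0) = 0.01 and p(I_con·N) = 0.5 (α ≈ 0.023, β ≈ 4.6 at N = 20,
I_con = 10). A fair binary signal b(t) stands in for unmodelled
network-wide activity; signal currents are set by inverting the sigmoid so
no-connectivity firing probabilities are graded linearly across each layer
(±0.4 span for inputs, ±0.2 for outputs, 1-based indices, first neuron
uncorrelated with b). 0.2·N² connections of I_con = 10 each link the
layers. Rewiring runs the network 500 times, scores every pair as
`S = A + a1·DegIn(o) + a2·DegOut(i) + a3·FR(o) + a4·FR(i)` (A = fraction of
runs with identical states; degrees and rates raw, measured on the current
statistics pass), moves the worst connection to the best vacancy — ties
broken uniformly at random, re-adding a just-removed connection allowed —
and repeats once per connection. Rule coefficients: Hebbian all zero;
degree-modified (0.05, −1.75) at N = 20 and (0.16, −0.3) at N = 40;
firing-rate-modified (0.35, 3.1). The staged lattice search that produced
such coefficients is implemented with 7 grid points per axis per stage,
three stages, each re-gridding around the incumbent at one third of the
span within the bounds (−3..3 for degree terms, −4..4 for rate terms); the
incumbent's objective is cached so the reported trace is non-increasing
even though the objective is stochastic.

Model-side PID uses structural triads (two connected inputs, one output)
with the receiver past taken as the previous run's output state — runs are
independent, so this conditions on nothing while matching the lagged form
used on spike trains. Connected-pair MI is reported raw and conditioned on
b; ensembles are compared with Mann-Whitney rank-sum tests under
Benjamini–Hochberg FDR control.

A documented caveat: under these printed score equations the positive
in-degree coefficient of the degree-modified rule is worth up to 1.0 score
units against an agreement swing of ~0.3, which drives a rich-get-richer
concentration of all connections into a few saturated output columns. The
expected qualitative contrasts that follow from the mechanics — Hebbian
maximizes unconditioned connected-pair MI; the degree-modified rule spreads
sources uniformly and yields the (in ≈ 0, out > 0) synergy-degree pattern —
reproduce robustly. The further expectation that the degree-modified rule
also maximizes b-conditioned MI does not hold in this implementation (the
saturated outputs transmit less per pair than a random network's); the
corresponding acceptance test documents this by failing, and the behaviour
is insensitive to degree normalization, layer size and coefficient sweeps.

## Numerical choices and degenerate inputs

- Bin counts tolerate 1e−9 relative float dust so an interval of exactly k
  bins yields k bins.
- Entropies of empty variable sets, overlapping MI argument sets, zero-mass
  specific-information events, empty observation tables, sub-size networks
  and nonpositive or degenerate weight samples all raise `ValueError`
  rather than returning NaN.
- Zero-variance correlation inputs return NaN and are excluded from skew
  counts.
- All randomness flows through `numpy.random.Generator` objects seeded per
  call; every CLI command takes `--seed` and reruns are bit-identical.

## Problem sizes used in the shipped tests

Worked-example decompositions are exact (16-state enumerations, checked
against an independent brute-force oracle to 1e−12). End-to-end recovery
uses hour-long synthetic recordings with 200 surrogates; model-ensemble
contrasts use 20 instances per rule with 200-run statistics passes and
2000-run analyses; estimator identities use 1000 random distributions.
These sizes were chosen so the full suite completes in a few minutes while
leaving sampling error well below the asserted tolerances.
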