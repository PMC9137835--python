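# Methods

## Model

The pipeline treats the nutritional profile of a full-fat larval meal as an
unknown function of three categorical rearing factors — species (TM, ZM),
substrate (carrot, cabbage, mixture of cabbage + carrot + flaxseed) and
harvest time (90, 97, 104 days) — observed at all 18 factor combinations
with replicate analytical determinations. Replicates are averaged to
condition means before modelling; the surrogate layer therefore models the
18-point mean surface, not replicate-level scatter.

Four perceptron surrogates share the same 8-dimensional input (one-hot
blocks of 2 + 3 + 3 indicators) and split the 23 responses by assay group:
proximate (6 outputs), amino acids (9), minerals (5), fatty acids (3).
Each surrogate is a single hidden layer,

    y = g(W2 · f(W1 x + b1) + b2),

with `f` drawn from {identity, logistic, tanh, exponential, softlog} and `g`
identity by default. `softlog` is a sign-symmetric logarithmic softening,
sign(x)·ln(1+|x|), provided as the "logarithmic" activation family; it is
not part of the default search set (identity, logistic, tanh). Inputs and
outputs are min-max scaled to [0, 1]; scaling is fitted on the training
partition and inverted exactly for reporting (degenerate variables map to
0.5 and invert to their minimum). The parameter count is
(8+1)·h + (h+1)·q — 156/189/145/87 for the four topologies of interest.

## Training and structure selection

Training minimizes the summed squared error (SOS) of the normalized outputs
with BFGS (scipy) and analytic backpropagation gradients, full batch,
gradient tolerance 1e-8, at most 500 iterations. Weights start from a seeded
uniform(−0.5, 0.5) draw; every fit is deterministic given its seed.

The topology search enumerates hidden sizes × hidden-activation families ×
seeded restarts, scores each fitted candidate by SOS on a held-out
validation subset of conditions (default split 70/15/15 at condition level,
seeded), and keeps the best. Validation scores closer than
`selection_tolerance` (default 1e-9 SOS) are treated as tied and resolved by
fewer parameters, then lower training SOS, then seed order — so among
exactly interpolating candidates the smallest adequate topology wins (this
is how a search over hidden sizes 7–12 settles on the 87-parameter 8-7-3
network for the three fatty-acid outputs). Reported r² values are
1 − SSE/SST per output in original units, and pooled across outputs in
normalized space for the "overall" figure; zero-variance outputs yield NaN
r² and are thereby flagged. The default restart budget (200 per candidate in
the search configuration; 10 in the pipeline configuration) is sized for
interactive runs; the CLI's `--paper-scale` raises it to 100,000.

## Connection-weight sensitivity

The relative influence of input i on output j is
RI_ij% = Σ_k w_ik·w_kj / Σ_i |Σ_k w_ik·w_kj| · 100, biases excluded,
computed on normalized-space weights. Two explicit numerical choices:

* **Denominator.** The default takes absolute values of the per-input inner
  sums, keeping each column bounded with Σ|RI| = 100. The literal variant
  without absolute values is available (`denominator="verbatim"`) but can
  divide by a near-zero signed sum and produce unbounded percentages.
* **Gauge.** Because every one-hot block sums to 1 for every design point,
  adding a constant to a block's input-to-hidden weights is
  function-preserving, and trained networks park intercept mass in indicator
  columns; raw connection weights then attribute influence to factors with
  no effect. RI is therefore computed by default with input-to-hidden
  weights centered within each factor block (the sum-to-zero gauge, the same
  identification used by ANOVA effect coding). This is an exact
  reparameterization of the same network, and for identity-activation
  networks it makes the RI proportions coincide with the identified
  least-squares effect contrasts. Centering is skipped for models without
  the 8-input block structure and for the verbatim denominator (whose signed
  sum is identically zero in the centered gauge).

## Multi-objective optimization

All 23 objectives are optimized simultaneously over the 18 conditions, 21
maximized, crude ash and n6/n3 minimized. Two routes return the
nondominated set: exhaustive enumeration (exact by construction on a finite
space) and an NSGA-II-style genetic algorithm — 3 integer genes, binary
tournament on (nondomination rank, crowding distance), uniform crossover
(rate 0.9), per-gene reset mutation (rate 1/3), population 20, 50
generations, with an archive of all evaluated points whose nondominated
subset is returned. The GA exists to mirror the published workflow; the
enumeration is the correctness oracle, and their set equality is asserted in
the tests across seeds and datasets.

With 23 objectives most candidate sets are mutually nondominated, so a
single recommendation is selected explicitly: objectives are normalized by
ideal/nadir over the front, and the member with the smallest Euclidean
distance to the ideal point wins; ties break by the count of objectives at
which a member is best, then by documented level order (TM, ZM | carrot,
cabbage, mixture | 90, 97, 104). The selection rule is a package decision —
a Pareto front alone does not single out a point.

## Synthetic data generator

The generator emulates the structure of the measured factorial dataset
without reproducing any measured values. Per response and species, condition
means are drawn inside plausible ranges shipped with the package
(`range_fixture.csv`; rows flagged `reported-range` carry published range
endpoints, rows flagged `synthetic-default` are plausible bands for
responses whose ranges were not printed numerically — the amino acids, crude
ash, Na and the two individual fatty acids). Factor effects are *additive*
(species + substrate + time main effects; substrate amplitude 20% and time
amplitude 12% of the narrower species range width), with two planted diet
effects: under the mixture substrate the C18:3n3 mean is ~10× the
carrot/cabbage baseline (capped to its band) and n6/n3 is drawn in
[1.95, 2.35] versus ≥6 without flaxseed. Replicate noise is additive
Gaussian with relative SD 3% (configurable; 0 gives exact replicates), and
the default 3 replicates per condition mirror standard triplicate assays.

Additivity is a deliberate choice: the 18-point design gives a 10-hidden-
neuron network only an 11-column adaptive basis, so exact interpolation of
an *arbitrary* 18-point table is not generically possible; reported
training r² of 1.000 in this kind of analysis implies near-main-effect
response structure, and the generator reproduces that regime honestly. An
`interaction_strength` knob (default 0) adds species × substrate wiggle for
stress testing. Consequently, passing tests demonstrate correct behaviour
on main-effect-structured data; they do not certify surrogate accuracy on
strongly interacting real data.

**Planted optimum.** For recovery tests the generator can make one chosen
condition strictly best in all 23 responses (per optimization direction):
factor effects are re-drawn so the planted level of each factor is best by a
margin (4% of the response range), over the *species-merged* range — merged
because the two species' published ranges can be disjoint (ZM's calcium
range lies entirely above TM's), which would make all-response dominance
impossible inside per-species bands. Planted condition means therefore
dominate exactly at the mean level; under replicate noise the planted point
may share the empirical front with neighbours, and the recovery criterion is
that the end-to-end pipeline's *recommendation* returns it.

## Problem sizes and numerical notes

Default problem sizes throughout (18 conditions × 3 replicates; restart
budgets of 2–100 per candidate in tests and the acceptance script; GA
population 20 × 50 generations) are chosen so a full pipeline run completes
in seconds to a few minutes on one core while every correctness property is
still exercised at full design-space scale — the design space itself is
never down-sampled. Degenerate inputs are handled explicitly: zero-variance
responses scale to the constant 0.5 and report NaN r²; an all-zero network
raises on RI computation; an empty Pareto front cannot yield a
recommendation. Dataset CSV round-trips are exact to 6 significant digits.

## Known limitations

* Connection-weight RI describes the fitted network, not causal effects;
  with 18 conditions and interpolating networks, influence estimates inherit
  fit non-uniqueness beyond what the gauge fixes (nonlinear networks can
  still distribute influence in compensating ways).
* The surrogate layer models condition means only; replicate-level
  uncertainty is not propagated into the Pareto front.
* The GA is redundant on an 18-point space (enumeration is exact and
  cheaper); it is included to mirror the published workflow and is only
  meaningful as a template for larger categorical design spaces.
* The distance-to-ideal recommendation depends on ideal/nadir normalization
  over the front; rescaling objectives by other conventions can change the
  recommended member of a large front.
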