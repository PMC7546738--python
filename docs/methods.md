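# Methods

This note records the models, numerical choices and limitations behind
each analysis, and what the synthetic data generator does and does not
emulate.

## The connectome graph model

A connectome is a directed graph over neurons with exactly one
aggregated edge per ordered pair; the edge weight is the number of
parallel synapses (the field's standard proxy for connection strength),
optionally broken down by brain region.  Autapses are rejected at load:
in dense EM reconstructions putative self-synapses fall below the false
positive rate of automated synapse detection, so connectivity tables
exclude them.  Each synapse is counted in exactly one region, as given
in the input; region labels are flat strings.  Loading is strict —
duplicate (pre, post) edge rows and edges referencing unknown body ids
are hard errors rather than silently merged, because dialect ambiguity
in flat-file exports is a real source of silent corruption.

Connection strengths are classified weak (1–2 synapses), medium (3–9)
and strong (≥10).  A reported strong connection certainly exists; weak
connections may be proofreading noise in either direction.

## Per-region statistics

`compartment_summary` reports N, L, ⟨k⟩ (distinct in- or out-partners,
a reciprocal partner counted once), the diameter D and mean hop
distance on the directed unweighted graph.  Distances are taken over
ordered pairs with a finite path; unreachable pairs are excluded and
their count is always reported, since dense neuropil graphs are usually
strongly connected but subsampled or thresholded ones need not be.  An
edge is reciprocal iff its reverse exists, and fracR is the fraction of
*edges* that are reciprocal (a fully bidirectional graph scores 1.0).

Path-length curves use N(N−1) — all ordered pairs — as the denominator
at every threshold, so unreached pairs are never counted as connected
and curves may saturate below 1.

## Strength distribution fit

The connection-strength model is a discrete power law with exponential
cutoff, P(k) ∝ k^(−γ)·e^(−k/κ), normalized on the fit range
(default k ∈ [1, 100]; weights outside the range are excluded and
counted).  The fit maximizes the exact discrete log-likelihood via its
sufficient statistics (Σ log k and Σ k over the histogram), optimized
by Nelder–Mead in (γ, log κ) with standard errors from the numerical
observed-information matrix (κ's error mapped back by the delta
method).  MLE is used rather than least squares on the log histogram
because the heavy tail makes histogram bins heteroscedastic; this is a
deliberate choice where the procedure was genuinely open.  A
single-valued sample is rejected as degenerate.  Calibration: refitting
10^6 draws from the generator at (γ=1.67, κ=42) recovers both
parameters well within the Monte-Carlo spread (±0.05 and ±3
respectively, checked across seeds).

## Completeness and accuracy arithmetic

With per-synapse trace probability c, an n-synapse connection appears
in the reconstruction with probability 1 − (1 − c)^n, assuming
independent misses — a 10-synapse connection survives 50% tracing with
probability 0.999.  `completeness_delta` compares two proofreading
states pair-by-pair; on a healthy trajectory nearly all changed pairs
increase and no new strong (≥10) connections appear.  Two-connection
accuracy uses (1 − precision)² for the probability that both synapses
of a 2-synapse pathway are false, again under independence.

## Motif detection

A type with ≥20 instances is reported as a clique when ≥90% of its
cells have bidirectional connections (weight ≥1 each way; the threshold
is a flag) to ≥90% of the *other* cells of the type.  Coverage and
strength are computed over all ordered pairs among all cells of the
type, so a report's `avg_strength · edges_present = total_synapses`
exactly.  Ordered pairs are used throughout (25 cells → 600 possible
edges).  Per-region cliques restrict edge weights to that region's
synapse counts first.  The random-wiring null probability of a complete
m-cell clique is p^(m(m−1)), reported as a base-10 logarithm; p = 0 is
an explicit error rather than −∞.

One-to-many (overseer) motifs: for a sparse type (≤2 cells) and an
abundant type (≥20 cells), the pair is reported when *every* sparse
cell reaches ≥90% of the abundant type's cells in the requested
direction(s).  The reciprocity census uses a degree-preserving
double-edge-swap null (10 swaps per edge per sample) because the
in/out-degree sequence is the natural thing to hold fixed; the z-score
is defined as 0 when the null is degenerate (e.g. a complete digraph,
which no swap can change).

## Boundary quality

A neuron crossing a region boundary n ≥ 1 times contributes n − 1
excess crossings; single crossings are inevitable wherever the boundary
is drawn and contribute nothing.  Crossings are counted on skeleton
*edges* whose endpoint labels are exactly the two regions — counting
per root-to-leaf path would double-count shared trunks.  Edges touching
a third region do not contribute, and an unlabeled endpoint adjacent to
one of the scored regions is an error (its crossing status is
ambiguous).  Boundary surface areas are an input measured upstream from
the volume segmentation; computing them from voxels is out of scope.

## Passive cable model

Each skeleton edge of length L with end radii r₁, r₂ is a truncated
cone: axial resistance Ra·L/(π·r₁·r₂), lateral membrane area
π·(r₁+r₂)·√(L²+(r₁−r₂)²) split half to each endpoint node, giving node
membrane conductance area/Rm and capacitance area·Cm.  Units: Ra in
Ω·m, Rm in Ω·m², Cm in F/m² (fixed at 0.01 — membrane capacitance is
set by membrane thickness and does not vary usefully between cells);
geometry in μm, API in ms and mV.

A synaptic input is a peak-normalized difference of exponentials
(default 1 nS peak, 0.1 ms rise, 1 ms fall) linearized to a current
source I(t) = g(t)·drive with drive = 60 mV; the g·V correction is
second-order while responses stay far from the reversal potential.
The "1 ms width" of a typical input is descriptive of this
biexponential, not an extra constraint.  Integration is backward Euler
— unconditionally stable on this symmetric positive-definite system —
with one sparse factorization reused across steps; defaults dt = 0.01
ms over 20 ms, and dt > τ_rise/5 is rejected.  Convergence: halving dt
moves peak amplitudes by <0.5% at the default geometry.  Checked
against closed forms: the single-compartment RC charging curve and the
sealed-end cylinder steady state cosh((l−x)/λ)/cosh(l/λ) both agree
within 1%.

Response summaries are (delay, amplitude) = (time of peak after input
onset, voltage at peak), ties broken earliest, onset defined as the
start of the conductance transient; an identically-zero trace reports
amplitude 0 with a NaN delay.  `compartment_matrices` averages
summaries over sampled (input-site, output-site) pairs per ordered
region pair, sampling without replacement with a seeded generator;
synapse positions map to skeletons by nearest node (Euclidean).  The
residual SDs of the matrix model and the single-scalar model are
computed over the same pairs with the same (population) denominator, so
matrix ≤ scalar holds as a variance-decomposition identity.  The
parameter sweep evaluates min/medium/max Ra ∈ {0.4, 1.6, 4.0} Ω·m ×
Rm ∈ {0.20, 0.83, 2.64} Ω·m² spanning the reported fly literature;
both axes are needed because the two resistances interact
non-linearly.  The published EPG-neuron residual improvements (0.446 →
0.045 ms, 0.168 → 0.021 mV) require that neuron's real skeleton; the
package asserts the qualitative content — clean within/cross-region
separation and a strictly smaller matrix residual — on its synthetic
3-compartment geometry.  No active conductances and no gap junctions
(undetectable in the source imaging) are modelled.

## Rent's rule

Per compartment, pins = neurons with at least one synapse (pre or
post) inside *and* at least one outside; computation = contained
presynaptic sites (T-bars), with PSD-count and unique-pair measures as
options.  The fit is OLS of log pins on log computation (a =
exp(intercept), b = slope), with per-point residuals reported so other
estimators can be compared; exponents are classified against the
inclusive packing range [0.5, 0.7].  The analysis driver demonstrates
the expected negative control: randomly wired connectomes carry no
packing pressure and fit below the packing range.

## CBLAST

Features concatenate the input and output profiles — the fraction of a
neuron's input (output) synapse weight exchanged with each current
cluster.  Clustering is agglomerative, average linkage, Euclidean,
cut at a user threshold (the single knob replacing the interactive
refinement of the original workflow); iteration refines
featurize → cluster → relabel until the *partition* (not the label
names) is stable, with non-convergence at max_iter returned as a flag,
not an error.

Initialization matters more than the clustering details.  A coarse
random initialization is information-free: when every cluster mixes the
true types, all types have the same expected profile over clusters, so
no featurization can separate them — this negative control is real,
not an implementation artifact.  The no-prior-knowledge start is
therefore a randomly permuted *singleton* assignment, whose features
are normalized adjacency rows.  From that start, synapse-weighted
profiles are fragile — the heavy-tailed strength distribution lets one
strong edge dominate a single neuron's profile — so the robust
bootstrap uses partner-count profiles (`weighted=False`); weighted
profiles remain the default once an assignment is coarse.  Documented
recovery conditions on the planted block model (4 types × 30 cells,
dense blocks at p = 0.6 vs background 0.02, background edges weak):
singleton start, count profiles, threshold 0.4 → ARI ≥ 0.9 across
seeds, and ground-truth initialization is a one-iteration fixed point
with weighted profiles.  The 2-D UMAP embedding is for plotting only.
Left/right homologue matching and morphological features are out of
scope.

## Synthetic data: what it does and does not emulate

`generate_connectome` produces an ellipsoid-body-like region by
default: 300 neurons, per-ordered-pair connection probability 0.19,
weights from the truncated power law (γ = 1.67, κ = 42, support 1–100),
and a reciprocity boost of 3.8 chosen so the reciprocal-edge fraction
approaches the ≈0.7 measured in that region.  Reciprocity is a
conditional boost with exact compensation — P(back | forward) is
multiplied by the boost and P(back | no forward) lowered so the
marginal stays exactly p — keeping edge density and reciprocity
independently controllable.  Edge synapses are split across regions by
a per-synapse categorical draw proportional to region volumes, and
per-neuron region counts are derived from those splits, so restricted
edge totals partition exactly.  Planted cliques use weights
1 + Poisson(mean − 1), preserving the weight ≥ 1 invariant while
targeting the requested mean.  The block-model generator draws weak
weights on low-probability background edges (high-probability blocks
get the full strength distribution), modelling the positive correlation
between connection probability and strength across type pairs.  All
generators are pure functions of (config, seed), with sub-streams
derived from the one seed by fixed offsets so adding a generator never
perturbs existing outputs.

Not emulated: dataset-scale counts (10⁷ synapses), realistic
morphology beyond region-labelled random binary arbors joined by thin
neurites, spatial synapse placement, type-specific wiring beyond the
block model, and truncation at a volume boundary.  Passing tests
therefore demonstrate correctness of the analyses under the stated
statistical structure, not agreement with any real brain's numbers:
dataset-level tables from the original study (region statistics,
detected clique census, path curves at scale, the EPG residuals) are
deliberately out of reach and are covered instead by oracle-equivalence
and planted-recovery tests.

## Problem sizes

Tests and the acceptance script run at desk scale by design: graphs of
30–300 neurons (oracle comparisons cap at 30, where dense all-pairs
references are exact), 10⁶-draw fits for the strength model, 200-segment
cables, and 120-neuron block models — sizes at which every check runs in
seconds while still exercising the asymptotics that matter (the fit's
Monte-Carlo spread, BFS path statistics, planted-structure recovery).
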