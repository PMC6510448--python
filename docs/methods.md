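# Methods

`epigrn` models a cell-fate decision circuit in which chromatin state gates
transcription: two self-activating, mutually inhibitory genes (gene 1 promotes
differentiation, gene 2 pluripotency), each under the control of its own
stochastic epigenetic-regulation (ER) system.  This note records the model
definitions, the numerical choices, and what the bundled synthetic systems do
and do not establish.

## The per-gene ER network

One gene's chromatin is a pool of Y modification sites, each methylated (M),
unmodified (U) or acetylated (A), together with two explicit enzyme pools:
histone demethylases (HDM, total e_HDM) and deacetylases (HDAC, total e_HDAC).
Sixteen mass-action channels act on the seven copy numbers
(M, U, A, HDM, HDM·M, HDAC, HDAC·A):

* enzymatic removal of marks as Michaelis–Menten triplets
  (bind / unbind / catalyse), in an unrecruited form and a form whose binding
  is recruited by the opposing mark (A recruits demethylation, channels 4–6;
  M recruits deacetylation, channels 12–14);
* non-enzymatic addition of marks, unrecruited (channels 7, 15) and recruited
  by like marks (M-recruited methylation, channel 8; A-recruited acetylation,
  channel 16).

Propensities are plain mass-action products of the listed factor species
(`c_k × Π counts`), with falling factorials for repeated factors.  Three
conservation laws hold exactly: sites (M+U+A+complexes = Y) and the two enzyme
totals.  Mutual reinforcement makes the network bistable for suitable rates,
with a high-acetylation *open* state and a high-methylation *closed* state.

**Observable convention.** The acetylation level of a gene counts *all*
acetylated sites, free or enzyme-bound: an HDAC-bound acetylated histone is
still acetylated.  This total is the slow observable of the system; defining
openness on free A alone would make threshold crossings fast-variable events
that no slow reduced description can reproduce.  A state is *open* when the
level exceeds 90% of Y, *closed* below 10%, and the promoter-accessibility
indicator is η = H(level − y0·Y) with y0 = 0.5 by default (configurable).

**Mean-field limit.** With sites far exceeding enzymes (Y ≫ Z), the enzyme
complexes sit at their Briggs–Haldane quasi-steady state and the site
fractions (m, u, a) follow a two-dimensional flow (u = 1 − m − a).  Stable
fixed points are found by relaxing an 11×11 lattice of initial fractions
under RK4, polishing with Newton, and merging duplicates within 1e-6 relative
distance.  One stable point classifies the regime as open (a ≥ y0) or closed;
two or more as bistable.  Scanning (e_HDM, e_HDAC) yields the regime phase
diagram over enzyme abundance.

## The GRN and its reduced dynamics

Monomers of gene i (scale S) dimerise and bind the e_i exposed sites of
promoters (scale E per promoter), activating their own gene and competitively
blocking the other's activator.  In the reduced description the generalized
coordinates q_i obey

    dq_i/dτ = R_i + (p∞i/p)·ω_i1 k_ii q_i² / (1 + Σ_j k_ij q_j²) − ω_i2 q_i,

with k_ij = β_ij/δ_ij and promoter accessibility p∞i/p = e_i/E the handle
through which ER acts.  Raw stochastic rates follow from the rescaled ones via
S and E (see `GRNParams`); dimerisation is folded into a single binding
reaction with propensity ∝ X(X−1).

Stable steady states are labelled by which genes are "on" (q ≥ 0.5):
PSS (pluripotency: gene 2 on), DSS (differentiation: gene 1 on), USS
(undecided: both off).  A single on/off split is used rather than separate
"small"/"order-one" bands because stable roots just inside a saddle-node can
sit anywhere below the activated branch; a total classification keeps the
phase-diagram region types well defined.  With the defaults
(R = 0.02, ω_i2 = 1, ω_11 = ω_21 = 4, self k = 4, cross k = 2 — the
cross-inhibition chosen as the smallest scanned value for which no stable
both-on state survives) the accessibility plane splits into exactly seven
regions: three monostable (U, P, D), three bistable (PU, UD, PD) and one
tristable wedge (PUD), with U at the origin, P and D at the single-gene
extremes and PD at full accessibility.

## Switching times and minimum action paths

Noise-induced transitions between the open and closed ER states have
exponentially distributed waiting times whose mean grows exponentially with
system size, τ_s = C·e^{Y·S}.  The exponent S is the Freidlin–Wentzell action
of the optimal fluctuation path on the chemical-Langevin approximation of the
reduced (m, a) dynamics: four effective slow channels (methylation,
demethylation, acetylation, deacetylation, enzymes at QSSA) give a drift b and
a diagonal diffusion D, and

    A[φ] = ½ ∫ (φ̇ − b)ᵀ D⁻¹ (φ̇ − b) dτ

is minimised over interior knots of a midpoint-discretised path (64 knots by
default; L-BFGS-B with an analytic gradient assembled from central-difference
field Jacobians) and over the transit time (golden-section on log T, warm
starts between T values).  D is floored at 1e-10 before inversion.  Halving
the knot spacing moves the exemplar actions by under 2%.

The prefactor C is not provided by the theory; it is estimated by regressing
ln τ̂ on Y from direct SSA switching along the standard system-size family
(`er_params_at_size`: bimolecular constants scaled down with Y, enzyme totals
scaled up, so the intensive law is fixed).  For size comparisons the
open/closed bands use nearest-count rounding of a fixed fraction (85%/15%)
rather than the strict 90%/10% rule, whose integer quantisation at Y = 10
would demand full acetylation.  The bundled scaling benchmark keeps Z/Y = 1/5
so enzyme counts stay integral across Y ∈ {10, 15, 20, 25}; its fitted slope
reproduces the independently minimised action to ~13%.

## Ensembles, clustering and sensitivity

Cofactor heterogeneity is represented by an ensemble of rate vectors
compatible with common reference trajectories: 10 realisations × 25 time
points of the acetylation level, started at the role-appropriate attractor
(open for the differentiation gene, closed for the pluripotency gene), and
summarised per time point by mean and SD over realisations.  ABC rejection
draws candidates from independent log-uniform priors (reference × [1/s, s];
the package default spread is 100, desk-scale analyses use s = 3) and accepts
when both summary statistics stay within ε_mean = 0.1·Y and ε_sd = 0.15·Y of
the reference at every time point (max-aggregated).  Candidates re-simulate
the identical observation protocol from the same initial state.

Bistable members get (τ+, τ−) from alternating first-passage measurements;
k-means (k = 3, 50 restarts, fixed seed) on standardised (log10 τ+, log10 τ−)
partitions the differentiation-gene ensemble, and clusters are named by
centroid geometry: red = fastest opening, blue = fastest closing of the
remainder, green = slow in both.  Two-sample Kolmogorov–Smirnov tests compare
per-parameter marginals between subensembles; raw p-values are reported (a
Benjamini–Hochberg column is available but off by default).  On regenerated
desk-scale ensembles the pipeline recovers the three-cluster geometry, and
flags larger unrecruited-demethylation binding (c1) in the red cluster — the
parameters that gate opening.

## The reprogramming probability Q

A DERS–PERS pair starts pluripotency-locked (D closed, P open).  Remodelling
to differentiation-primed (D open, P closed) needs one switch of each system,
via two routes (P closes first, or D opens first); holding times are
exponential with means (τ1±, τ2±), the systems are independent, simultaneous
switches are neglected, and a route is abandoned if its intermediate state
reverts first.  Each route density is therefore a competition-weighted
convolution of two exponentials, and the waiting-time PDF is their sum
normalised by the total direct-route probability Z (computed from
normalisation, never transcribed) — equivalently, the arrival-time law
conditioned on direct remodelling.  Q(τ_P) is the closed-form integral over
(0, τ_P]; degenerate equal-rate pairs use the τe^{−τ/τ0} limit through a
numerically stable exponential-difference kernel.  Two Monte-Carlo oracles
ship: the direct-route oracle (matching the closed form's conditioning) and a
full four-state first-passage simulation with back-switching, whose deviation
from the direct-route law quantifies the weight of indirect paths.  The
horizon defaults to the ensemble-mean DERS opening time and pairs classify as
differentiation-primed when Q ≥ T = 0.7.

## The hybrid (piecewise-deterministic) simulator

At the reference scales S ≫ E and Y ≫ Z, bound promoters and enzyme
complexes are fast; monomers are effectively deterministic.  The reduction:

* **Fast variables.** Promoter occupancies follow a reversible multi-class
  binding chain with product-form stationary law (multinomial weights ×
  ρ_j^{n_j}, ρ_j = η k_ij x_j²), sampled exactly by enumeration.  Enzyme
  complexes follow one-dimensional binding chains whose stationary laws are
  enumerated over 0..min(Z, substrate); substrate depletion (a complexed site
  is unavailable) is built in — at Y/Z = 3 the naive total-count binomial
  overestimates occupancy visibly — and the two chains' cross-recruitment is
  closed self-consistently (each chain reads the other's mean free marks,
  iterated to a fixed point before sampling).
* **Slow ER dynamics.** Six effective channels on the total mark counts
  (un/recruited methylation and acetylation, enzymatic removal at rate
  ∝ sampled complex count) are simulated by exact thinning: proposals from a
  constant bound with complexes replaced by their maxima, acceptance with
  freshly sampled complexes.
* **Monomers.** An RK4-integrated ODE with the sampled occupancies entering
  synthesis and binding-exchange terms, and accessibility gates
  η_i = H(level_i − y0·Y) recomputed from the live ER state.  Occupancies are
  redrawn every `resample_dt`; this interval must stay below the occupancy
  correlation time E/(δS) (≈ 0.03 at the defaults), otherwise the frozen
  samples inject spurious low-frequency noise — `HybridConfig.for_params`
  picks a safe value and the shipped default is 0.02.

Regulation is one-way (chromatin gates transcription; TFs never modify
chromatin), so the per-gene ER jump processes are generated first and the
monomer ODE is driven through the resulting η(t) — an exact scheduler for the
coupled PDMP.  Differentiation-time measurements run in chunks and stop as
soon as the criterion holds, restarting each chunk from the carried slow
state (exact, by the Markov property).

**Accuracy at the reference scales.** With Y/Z = 3 the timescale separation
is only moderate.  Openings and shallow excursions (including the η
threshold at y0 = 0.5) match the full model closely; *deep* closing passages
(to below 10% acetylation) run 1.2–1.7× slower in the reduced process even
though every conditional stationary statistic and the barrier committor
match — a path-correlation effect of the annealed fast-variable resampling
that faster binding kinetics do not remove.  Differentiation times, which
hinge on the shallow threshold, agree distributionally (two-sample KS
D ≈ 0.08 at n = 200 per arm); per-system deep-closing times should be taken
from the exact SSA when they are the quantity of interest.  The hybrid's
advantage is the event count: ~4–15× fewer stochastic events than the full
SSA on the bundled benchmarks.

## Differentiation criterion and intervention experiments

The differentiation time τ_D is the first entry into the differentiated
basin, operationalised as: gene-1 monomer count above half its DSS level
(computed at accessibility (1, 0)) while the gene-2 count stays below a tenth
of its PSS level, sustained for 5 time units.  Runs start pluripotency-locked
(gene-1 ER at its closed attractor, gene-2 ER open, GRN at the PSS); censored
runs report the horizon and are never averaged into statistics.

Reprogramming strategies scale the unrecruited-deacetylation catalysis
constant down and/or the unrecruited-demethylation catalysis constant up
(two-step: both, one-step: demethylation only).  The default factor is 4: at
the bundled parameter scale a ten-fold change destroys bistability outright,
and a four-fold change reproduces the intended blue→red cluster migration
while keeping the modified system bistable.  HDM/HDAC scans rerun τ_D over a
grid of enzyme abundances applied to both genes' ER systems, with the
baseline (Z, Z) always included.

## Synthetic reference systems

No published rate constants are available to this package; everything in
`data/reference_systems_synthetic.yaml` is a synthetic stand-in constructed
from qualitative requirements, at scales Y = 15, Z = 5, E = 3, S = 100:

* a near-symmetric bistable *reference* system that generates the ABC raw
  data;
* *ders1*, red-cluster-like (fast opening, slow closing: larger c1 and c15,
  smaller c11 and c16) and *ders2*, blue-cluster-like (mirrored biases);
* *pers1* (most opening-resistant) and *pers2* (readily opening), chosen so
  the closed→open action spread is over eight-fold across the DERS pair and
  about two-fold across the PERS pair — the qualitative variability structure
  the analyses presume.

Consequently the *absolute* action values, transition times and cluster sizes
produced here characterise these synthetic systems only; conclusions that
transfer are the structural ones (region counts and layout, cluster geometry,
direction of sensitivity biases, intervention effects, scaling laws).  The
generator also idealises real chromatin: sites are exchangeable (no spatial
neighbourhoods), only two eraser enzyme pools are explicit, and gene-gene
coupling runs solely through promoter accessibility.

## Determinism and seeds

Every stochastic entry point takes a seed; one master seed spawns independent
31-bit child streams (`spawn_seeds`) per run, and identical seeds reproduce
trajectories bit-for-bit.  Deterministic computations (phase diagrams, action
minimisation, closed-form Q) are seed-free.  Desk-scale problem sizes used by
the bundled experiments (ensemble 200 accepted sets with 60 clustered,
12–20 intervention runs per condition, 200-run equivalence benchmarks) are
package defaults chosen to characterise the synthetic systems well; all are
configurable.
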