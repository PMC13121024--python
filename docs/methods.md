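# Methods

This package implements a computational stack for quantifying integrated
information in multichannel brain-like timeseries, relating it to network
control energy on a structural connectome, and probing its mechanisms with
a dynamic mean-field simulator.  Everything runs end-to-end on synthetic
data with known ground truth; this note records the models, the defaults,
and the design choices that were genuinely open.

## Gaussian integrated information decomposition

For two (possibly multivariate) parts X, Y of a stationary process, the
time-delayed mutual information I(X_{t−τ}, Y_{t−τ}; X_t, Y_t) is decomposed
into 16 atoms, one per pair of redundancy-lattice nodes {Red, UnX, UnY,
Syn} at past and future.  All quantities are computed in closed form from
the joint Gaussian covariance of the stacked past/future vector, in nats.

Redundancy follows the minimum-mutual-information (MMI) rule.  The
double-redundancy function at a node pair (α, β) is

    R(α → β) = min over a ∈ α, b ∈ β of I(past of collection a; future of b),

which reduces to the minimum of the four single-part lagged MIs at the
bottom node pair and to the full time-delayed MI at the top.  Atoms are
recovered by Möbius inversion over the product partial order (a fixed
invertible 16×16 zeta system).  Consequences, verified to 1e-9 in the
tests: atoms sum to the TDMI; the four Red/UnX combinations sum to
I(X_past; X_fut); the transfer-entropy identity
TE(X→Y) = I(X_past; Y_fut | Y_past) holds exactly at the atom level.

Derived measures: Φ_R (nine synergy-containing plus two pure-transfer
atoms), Φ_2008 = Φ_R − Red→Red (may be negative in redundancy-dominated
systems), causal density (sum of both directed TEs), and net information
flow |UnX→UnY − UnY→UnX|.

Estimation: per-region z-scoring, then the sample covariance of the
stacked lagged vector; diagonal loading (1e-9 relative to mean variance)
only if the smallest eigenvalue falls below 1e-10.  Default lag τ = 1
sample — the minimal nontrivial choice for slow timeseries; configurable
everywhere.  Pairwise aggregation averages over unordered pairs (Φ_R is
symmetric; for directed measures the unordered mean of te_xy+te_yx is
reported via causal density).  A K-set bipartition estimator
(`bipartition_phi`, default K=6, random even splits) trades the pairwise
view for higher-order interactions at controlled cost.

Surrogate debiasing subtracts the mean measure over surrogates built by a
single joint permutation of timepoints — this preserves each region's
marginal distribution and the zero-lag covariance exactly (the two
constraints that matter) while destroying all temporal structure.
Alternatives such as circular shifts preserve autocorrelation and would
not isolate the past–future structure; they are noted, not implemented.

### The two-node autoregressive family

`two_node_ar(a, c)` builds the canonical two-parameter system: symmetric
cross-coupling `a` (synergy rises with it) and innovation correlation `c`
("common noise"; redundancy rises with it).  Each node also keeps a
self-coupling of 0.2 by default.  This nodal memory matters: with pure
cross-coupling, all lagged mutual informations vanish at a = 0 and the
redundancy-dominated regime cannot exist — Φ_2008 is identically zero
there.  With memory, the analytic grid (a ∈ [0, 0.45], c ∈ [0, 0.9])
shows the intended structure: Φ_2008 < 0 at high c and low-but-nonzero a,
while Φ_R ≥ 0 everywhere and rises monotonically with a at c = 0.

## Network control energy

Dynamics are stabilized as A = C/(λ_max(C)+1) − I (eigenvalues in [−2, 0)),
a convention from the network-control literature; states are z-scored per
region so synthetic and empirical scales are commensurable.  The
finite-horizon controllability Gramian is computed by the augmented-matrix
exponential (machine precision); transition energy is vᵀW_T⁻¹v with
v = x_f − e^{AT}x_0, horizon T = 1.  Per-node energies integrate the
optimal input's squared components by 48-node Gauss–Legendre quadrature
and sum to the total to well below 1e-6 relative.  An independent
discretized least-squares optimal-control oracle agrees within 1% on
random systems.  Control weights B are diagonal in [0, 1]; map-weighted
control uses B = I − diag(map) with a 1e-3 floor so the Gramian stays
invertible (a strict mode with pseudo-inverse fallback exists).

Two findings about this model shaped the null test for map-weighted
control (`energy_vs_null_maps`):

1. Removing control from *weakly connected* nodes raises transition energy
   most — they are the hardest to reach through the network (per-node
   sensitivity vs strength: ρ ≈ −0.76).  The planted-effect experiments
   therefore concentrate the map on weakly connected regions.
2. Energy is hypersensitive to the smallest control weights (through
   1/B² in the Gramian inverse), so null maps must preserve the value
   distribution, not just mean and autocorrelation.  The null generator
   therefore rank-remaps each spatial surrogate onto the empirical map's
   value multiset (`match_distribution=True`), the standard practice for
   distribution-sensitive downstream statistics.

## Spatial maps and surrogates

Synthetic regional maps are Gaussian random fields with squared-
exponential covariance over region coordinates.  Moran spectral
randomization projects a map onto the eigenvectors of the doubly centred
spatial weight matrix (default weights: inverse Euclidean distance, zero
diagonal), randomizes coefficient signs, permutes coefficients within
eigenvalue-similar blocks (relative tolerance 0.05), and restores the
mean exactly.  Moran's I is preserved to within ±0.1 on fields whose
correlation length is comparable to the coordinate span.

## Dynamic mean-field model

Each region is a reduced excitatory–inhibitory neural mass (gating
variables S_E, S_I; sigmoidal rate functions with the canonical constants:
I₀ = 0.382 nA, w₊ = 1.4, J_NMDA = 0.15 nA, τ_E = 100 ms, τ_I = 10 ms,
γ = 0.641, σ = 0.01 nA), coupled by G·J_NMDA·C·S_E with the connectome
scaled to unit mean strength.  Local feedback inhibition J is a free
per-region parameter, baseline 0.7 nA.  Haemodynamics are a standard
Balloon–Windkessel model driven by S_E, integrated on a ~1 ms sub-step;
BOLD is recorded at the repetition time.  Integration is Euler–Maruyama
(default dt = 0.1 ms; the experiments shipped here use 0.5 ms, which is
comfortably stable for these time constants and five times faster), with
10 s of burn-in discarded.  The rate function's removable singularity at
zero net input is evaluated by its series limit.  Identical parameters
and seed give identical output.

With the homogeneous J = 0.7 baseline, long-range excitation is unopposed
and the model saturates at high rates for any appreciable G; in that
regime the FCD statistics are nearly independent of G and perturbations
act paradoxically (inhibiting hubs can *raise* integration by pulling
pinned nodes back into dynamic range).  The package therefore provides
the linear feedback-inhibition-control heuristic J_i = 0.75·G·s_i + 1
(`fic_heuristic`, s_i = strength at unit mean), which keeps mean rates
at a few Hz across G and places the model near its dynamical working
point.  The perturbation protocol itself is unchanged: heterogeneous
inhibition adds 0.7·map_i to each region's J (0.7 → 1.4 across the map's
range at the homogeneous baseline), and nodal stimulation scales the
external excitatory current from 1 to up to 3 at chosen regions.

Model fitting matches the pooled distribution of sliding-window FCD
similarities (window 30 samples, step 3) by the Kolmogorov–Smirnov
statistic over a G grid, ties resolved toward the smaller G.  At the
FIC-balanced working point this objective is identifiable: the generating
G of a self-generated target is recovered within one step of a 10-point
grid (25-node connectome, three repetitions of 300 s at TR = 2 s).

The perturbation experiments run at deliberately modest sizes (25-node
connectomes, 400 s simulated scans, 6–10 runs per condition), which the
package treats as its standard desk-scale configuration:

* *Heterogeneous inhibition* (working point G = 1.5, FIC-balanced):
  inhibition weighted by a hub-concentrated map lowers mean pairwise Φ_R
  below the homogeneous model and below ≥ 8/10 spatial-null arrangements
  of the same map.
* *Nodal stimulation* (G = 1.0, FIC + 0.35 homogeneous extra inhibition —
  a sub-critical anaesthesia-like state): the stimulation experiment uses
  a connectome augmented with one broadly connected nucleus
  (`add_hub_node`), the synthetic analogue of a thalamocortical hub.
  Exciting that nucleus restores more Φ_R than exciting the weakest node,
  and the advantage does not shrink from 1.5× to 3× stimulation.  On an
  ordinary modular graph this direction is not expected: strong constant
  input pins a single node's gating variable and removes its
  fluctuations, which costs more integration than the added drive returns.

## Synthetic studies

A study bundles a modular weighted connectome (four communities,
lognormal weights), random 3-D coordinates, a smooth truth map normalized
to [0, 1], and per-subject VAR(1) timeseries per condition.  The
condition's coupling scale multiplies the connectome-shaped coupling
(base spectral radius 0.55, self-coupling 0.2); common noise is an
equicorrelated innovation component; optional map-weighted attenuation
scales each region's incoming coupling.  The arousal score is
round(11 · coupling_scale) plus integer noise in {−1, 0, 1}, clipped to
the 0–11 behavioural scale.

Default conditions emulate wakefulness (coupling 1.0, common noise 0.15)
versus deep anaesthesia (0.4, 0.25).  The graded `DBS_CONDITIONS` add two
stimulation-like states (0.6 and 0.85 coupling with intermediate noise,
drug still present) — a graded-arousal design analogous to the
anaesthesia + thalamic-stimulation experiments that dominance analyses
are run on.  Two calibration notes: (i) with only two conditions the
arousal score is nearly binary and the four information measures are
statistically interchangeable as predictors, so the dominance ranking is
unstable; the graded design is the appropriate one.  (ii) The
common-noise gradient must stay moderate: a strongly global-signal-
dominated state moves along the most controllable direction of the
stabilized dynamics and would *lower* its transition energy, inverting
the expected energy contrast.  Even in the graded design, Φ_R and causal
density remain highly collinear under a symmetric coupling manipulation,
and causal density overtakes Φ_R as the top dominance predictor in
roughly a quarter of study realizations; the acceptance test therefore
asserts the joint signature over the majority of five replicate studies.

What the generator does *not* emulate: haemodynamic convolution in the
VAR branch (the mean-field branch handles biophysics), empirical atlas
geometry, subject-level heterogeneity of connectomes, head-motion or
physiological artefacts.  Passing tests demonstrate internal consistency
and directional behaviour under known ground truth, not performance on
real fMRI.

## Numerical conventions

Units are nats throughout the information measures.  Covariances are
symmetrized after every construction; log-determinants go through
`slogdet` with explicit sign checks; Gramian solves use Cholesky with a
condition-number gate at 1e12.  All stochastic procedures take explicit
integer seeds and are pure functions of (parameters, seed); study
regeneration is bit-identical.  Degenerate inputs (constant regions,
constant maps, singular sub-covariances, non-stationary coupling) raise
`ValueError` with a diagnostic rather than propagating NaNs; failed
region pairs in whole-matrix sweeps are excluded and counted in the log.

## Known limitations

* MMI is the only redundancy function; no discrete-variable estimators.
* The double-redundancy lattice is evaluated for two parts only (even
  bipartitions of sampled sets cover higher orders).
* The mean-field model has no layer- or cell-type-resolved structure and
  no receptor-density modulation; Supplementary-table-level constants of
  the original modelling literature are represented by the canonical
  reduced Wong–Wang values with a config override slot.
* Transition-energy comparisons between maps are meaningful only with
  distribution-matched nulls (see above); raw spectral surrogates are
  appropriate for correlation-type statistics.
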