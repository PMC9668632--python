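# Methods

This note documents the models, procedures and numerical choices behind
`dfcstates`, and what the synthetic cohort generator does and does not
emulate.

## Problem setting

Resting-state fMRI signals, reduced by group ICA to a set of component
time-courses (here 47 signal components sampled at TR = 2.25 s, 255
volumes), exhibit time-varying functional connectivity (FC): the pairwise
correlation structure drifts among a small number of recurrent
whole-brain patterns ("connectivity states").  The package estimates
those states, summarizes how each participant moves through them, and
relates the temporal summaries and the connectivity itself to clinical
disability in a three-group design (healthy controls, patients without
disability, patients with mild-to-moderate disability by EDSS).

## Nuisance processing

Component time-courses pass through despike -> detrend -> optional
confound regression -> band-pass, in that order.

- **Despike** is MAD-based winsorization: samples farther than
  `c = 4` robust SDs (1.4826·MAD) from the per-component median are
  clipped to that threshold.  Constant series (MAD = 0) pass through.
- **Detrend** removes the least-squares line (intercept + slope) per
  component; it is an exact projection and therefore idempotent.
- **Confound regression** removes an intercept plus arbitrary confound
  columns by OLS; rank-deficient confound sets are reduced with a
  warning.  Also a projection.
- **Band-pass** is a 4th-order Butterworth applied forward-backward
  (`filtfilt`, zero phase, squared magnitude response), default band
  0.01-0.15 Hz, reflection padding of one window length (22 samples).
  A Butterworth filter is *not* a projection: reapplying the pipeline
  attenuates band-edge content again (about 10 % RMS on broadband noise,
  < 2 % for mid-band content).  Tests assert exact idempotence only for
  the projection steps.

## Connectivity

Static FC is the Pearson correlation over all timepoints; dynamic FC uses
sliding windows of w = 22 TR, slide 1 TR (234 windows of a 255-TR scan),
rectangular by default, with an optional Gaussian-convolved taper
(sigma = 3 TR).  Correlations are Fisher-Z transformed after clipping at
|r| = 1 - 1e-7 so values stay finite while preserving order.  FC matrices
are vectorized over the strict lower triangle in column-major order
(1081 pairs for 47 components); the pair ordering is fixed package-wide.

## State estimation

Windowed FC vectors from all participants are pooled and clustered with
L1 (city-block) k-means — the metric recommended for high-dimensional FC
data — using per-coordinate **median** centroid updates (the true L1
minimizer), k-means++-style distance-weighted seeding, and the best of
`n_init` restarts by total within-cluster L1 cost.  Emptied clusters are
re-seeded at the point farthest from its centroid.

The number of states is chosen by convergence of two criteria computed
over k = 2..10:

- **Elbow**: the cost curve (anchored at k = 1) is normalized by its
  first value and the k maximizing the consecutive drop ratio
  (f(k−1) − f(k)) / (f(k) − f(k+1)) is taken.  At the generative k the
  numerator is the last structural cost drop while the denominator is a
  pure noise split, so the ratio peaks there; the more common second
  difference of the cost curve is biased toward small k when cluster
  occupancies are unequal, because early splits always remove the most
  cost.  The denominator is floored at 1e-4 (normalized units) against
  division blow-ups on flat tails.
- **Dunn's index**: minimum between-cluster point distance over maximum
  within-cluster diameter (city-block; optionally on a stratified
  subsample to bound the O(n²) computation).

When the two disagree the elbow k is returned and a divergence flag is
recorded.  On slide-1 sliding-window data, consecutive windows share
w - 1 TRs and windows straddling a state switch interpolate continuously
between the two state centroids; the minimum inter-cluster point distance
is therefore dominated by these transition windows, and Dunn's index is
expected to be flat/noisy in this regime.  The elbow carries the
selection; the divergence flag makes the disagreement explicit rather
than hiding it.

After clustering, state identities are re-coded by descending total
window count over the whole cohort (ties to the lower original id), and
each participant's FC in a state is summarized by the coordinate-wise
median over the windows spent there; unvisited states propagate as
missing, never as zeros.

## Temporal metrics, modularity, ASOC

From the per-window state sequence: fraction time (occupancy
proportion), mean dwell time (mean run length), stickiness (count of
adjacent same-state window pairs), and transition counts between
distinct state pairs (ordered and unordered; group tests use the
unordered totals).  Two identities hold by construction and are tested:
stickiness + transitions = windows - 1, and per-state occupancy =
stickiness + number of runs.

State-wise average connectivity is the mean Fisher-Z over all pairs and
windows in the state.  Modularity Q is computed per participant per
state on the **median per-state FC matrix** with a community-Louvain
algorithm written for signed weighted graphs: positive and negative
layers contribute asymmetrically (Q = Q+/v+ − Q−/(v+ + v−)), gamma = 1,
10 seeded restarts with shuffled node order, best Q kept.  Alternative
negative-weight rules (absolute value, zero-clip) are selectable.

Across-state overall connectivity (ASOC) averages a participant's
windowed FC over all windows irrespective of state: one grand average,
one intra-network average per multi-component network (7 of the 8; the
basal-ganglia network has a single component and no intra pairs), one
inter-network average per network (pairs with exactly one member in the
network), plus all pairwise network-to-network averages.  The grand ASOC
equals the occupancy-weighted mean of per-state average connectivity —
the algebraic form of "time spent in high-connectivity states drives
overall connectivity".

## Clinical composites and the EDSS split

Raw test scores (30 measures: 16 visual-acuity readings, 2 motor timings,
fatigue, depression, 8 cognitive sub-tests, normalized brain volume,
lesion volume) are z-scored across patients (n−1 SD, missing values
excluded), averaged per domain with available-case deletion, and
impairment-coded: vision, cognition and brain volume are multiplied by
−1 so higher always means worse.  Patients are split at the lower/upper
30th nearest-rank percentiles of EDSS; patients whose score equals the
sample median exactly are excluded from both groups.  EDSS values are
validated to the 0-10 grid in 0.5 steps.

## Statistics

- **Mass-univariate group differences** (static FC per group pair;
  per-state median FC per group pair and state) use a two-sample
  permutation test: Welch T observed, label permutations for the null,
  add-one two-sided p = (1 + #{|T*| ≥ |T|})/(1 + n_perm).  Welch rather
  than Student because permutation inference is valid for either and
  Welch is robust to variance imbalance; default n_perm = 9999 (999 in
  the shipped desk-scale config), seeded.
- **FDR** is Benjamini-Hochberg, applied independently within declared
  families: 1081 tests per group pair for static FC; 1081 per group pair
  × state for dynamic FC; 1081 per state × clinical domain for
  correlations; 3 pairwise tests per measure × state for the rank
  post-hocs; 7 for the domain-score group tests.
- **Temporal metrics / ASOC** group effects: values are residualized on
  age (OLS), then a Kruskal-Wallis omnibus over the three groups with
  tie correction, then Dunn's pairwise Z tests (tie-corrected pooled-rank
  SE) with BH over the 3 pairs.  Dunn's tests are computed for all pairs;
  the omnibus decision is recorded alongside so gating is a reporting
  policy, not a data loss.
- **Brain-clinical correlations** use Spearman partial correlations
  controlling for age: all three variables rank-transformed, partial
  Pearson on the ranks, p from the t approximation with n − 3 df;
  missing data deleted pairwise per test.  Age control for the metric
  tests (residualize-then-rank) and for the correlations
  (rank-then-partial) are deliberately distinct code paths.
- Cohen's d uses the pooled SD with (n1−1, n2−1) weights.

## Synthetic cohort generator

The generator provides the study conditions for every test:

- **Latent states**: a first-order Markov chain over k = 5 states at TR
  resolution.  Self-transition probabilities (0.980, 0.975, 0.970,
  0.962, 0.950) imply expected dwell times of 50/40/33/26/20 TR and a
  stationary occupancy proportional to 1/(1 − p_stay), so state 1 is the
  most frequent and state 5 the least — the qualitative structure the
  analysis expects.  Window-level ground truth is the majority vote over
  each window's TR labels.
- **State centroids**: five network-structured correlation matrices over
  the 8-network, 47-component layout.  State 1 is globally weak, state 5
  globally hyperconnected (highest mean connectivity, lowest
  modularity), and states 2-4 carry distinct sensory / default-mode /
  attention motifs with anticorrelations.  Motif strengths were chosen
  so that the mutual city-block separations between state centroids
  (≈ 260-420 in Fisher-Z pair space) clearly exceed the per-window FC
  estimation noise of a 22-TR window (L1 deviation ≈ 200); weaker motifs
  leave states 2-4 unresolvable at this window length, which is a
  statement about w = 22 windows, not about the clustering.  Matrices
  are repaired to valid correlation matrices by eigenvalue clipping at
  zero and renormalization to unit diagonal.
- **Group effect**: the mild-disability group's state-5 self-transition
  probability is raised by 0.035, planting the "more time in the
  high-connectivity state" occupancy effect.
- **Clinical scores**: raw test scores are drawn on plausible scales
  with standardized subgroup mean differences per domain (defaults
  0.4-1.2 SD, largest for fatigue, matching the ordering of reported
  group differences), oriented so the impairment-coded composite is
  higher in the disability group.  EDSS is drawn on-grid: 0/1 for the
  no-disability group, 2-5.5 (median 2.5) for the mild group, and a
  median-tied block at 1.5 that the percentile split must exclude.  Age
  is drawn older in the disability group; missingness is injected at 5 %
  per cell.
- **Seeding**: one master seed fans out to per-participant seeds by a
  fixed stride (7919) modulo 2^31; all outputs are byte-identical under
  a fixed seed.

What the generator does **not** emulate: raw 4D fMRI volumes, head
motion, scanner noise spectra, ICA mixing or back-reconstruction,
spatial maps, hemodynamic autocorrelation within states, or realistic
inter-test correlation structure within clinical domains beyond the
shared group shift.  Passing tests therefore demonstrate that the
estimators recover the generative structure they target under the
assumed piecewise-stationary Gaussian model — not that they would behave
identically on real fMRI data.

## Problem sizes in tests and the acceptance script

The shipped analyses run at desk scale, chosen as the smallest sizes at
which each property is identifiable: cohorts of 12-40 participants for
clustering and recovery checks (the full 101+101 default is exercised by
the generator but not clustered in tests), 1000 simulated datasets with
n_perm = 999 for permutation calibration, 200 patients/group for clinical
effect-size recovery, 60 participants/group and 40 replicate cohorts for
the fraction-time power analysis.  The k-selection scan uses fewer
k-means restarts (4-5) than the final clustering (10-20).

## Known limitations

- The elbow criterion remains a heuristic on a noisy curve; the drop
  ratio is robust on the shipped fixtures, but at very small cohorts or
  with strongly hierarchical state geometries any single-number elbow
  can be ambiguous.
- Dunn's index is uninformative for slide-1 windowed FC (see above); it
  is reported for transparency and used only through the convergence
  flag.
- Louvain is a greedy heuristic; on 47-node FC graphs with 10 restarts
  it matches exhaustive modularity maxima on all small test instances,
  but global optimality is not guaranteed in general.
- Permutation p-values are conservative by the add-one rule; with
  n_perm = 999 the smallest attainable p is 1/1000.
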