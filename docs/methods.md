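# Methods

This note documents the models, estimators, conventions and numerical
choices behind `hyperconn`, and what the synthetic-data tests do and do not
establish about real recordings.

## Data model and preprocessing

The unit of analysis is a *trial*: for each of 26 ROIs per brain (13
anatomical labels × 2 hemispheres with fixed MNI centroids), a
3-dimensional current-density time series at 1024 Hz.  Trials shorter than
10 s are treated as unsuccessful and excluded.  Trials are trimmed to
their central 10 s (a 20 s trial loses its first and last 5 s) to isolate
steady task performance, then segmented into 2 s windows stepped by 1 s —
nine windows covering the trimmed trial exactly.

The segmentation step deserves a remark: a 2 s window with 0.5 s overlap
cannot produce nine segments over 10 s, while a 1 s step does.  The
explicit segment count is used throughout the averaging, so the step is
fixed at 1 s by default; it is configurable and logged.

Time-to-sample conversion floors start indices; windows are half-open
`[start, start + window)`.

## Lagged phase synchronization

Connectivity is restricted to the alpha band (8.5–12 Hz, inclusive
endpoints, eight 0.5 Hz bins at the 2 s window resolution).  Per segment
and bin, the Fourier coefficients of a ROI's three spatial dimensions form
a complex 3-vector, normalized to unit Euclidean norm so that only phase
information survives (zero-amplitude vectors are flagged and excluded).
Averaging outer products across segments yields normalized auto-spectral
(3×3 Hermitian, unit trace) and cross-spectral (3×3) covariance blocks;
for a pair these stack into a 6×6 Hermitian matrix `S`.

Dependence is quantified on the log-determinant scale:

    F_total = ln det(S_xx) + ln det(S_yy) − ln det(S)
    F_inst  = the same expression evaluated on Re(S)
    F_lag   = F_total − F_inst

each mapped monotonically to [0, 1] by `1 − exp(−F)`.  In the univariate
special case this reduces to the familiar forms: `1 − exp(−F_total)` is
the squared modulus of the phase coherence and the lagged component
becomes `Im(r)² / (1 − Re(r)²)`.  A purely real (zero-lag) coupling —
volume conduction's signature — is fully captured by `Re(S)` and
contributes nothing to `F_lag`; a quarter-cycle lag is almost entirely
imaginary and passes through.  The estimator is identical for intra- and
inter-brain pairs, so one common threshold can compare them directly.
Total and instantaneous components are retained (uncalibrated) as
diagnostics.

**Small-sample null calibration.**  With only nine segments the
determinant-based `F_lag` estimator overfits badly: its null expectation
is ≈ 1.40 nats for the default scheme (the overlap between windows
correlates the Fourier vectors and worsens the ≈ 0.95 nats expected for
nine independent draws).  Left uncorrected this would report null LPS
around 0.5.  The expected null `F_lag` is therefore estimated once per
segmentation scheme by a deterministic Monte-Carlo run (250 draws of
independent 3-D white-noise source pairs, segmented exactly like the data;
internal fixed seed; cached) and subtracted before the [0, 1] map.  The
per-bin calibration is frequency-independent for white sources and, by
direct experiment, insensitive to auto-covariance anisotropy, so one
calibration serves all bands.  Calibrated per-bin values may be slightly
negative under the null; the band average is taken over the signed values
and clipped to [0, 1] at the end, so null band-averaged LPS concentrates
at zero (measured mean ≈ 0.006 on independent sources) instead of
rectifying the per-bin noise.  Requesting `calibrate=False` reproduces the
uncorrected estimator.

Ill-conditioned covariances receive a relative diagonal ridge of 10⁻¹² ×
trace before determinant evaluation; at least six well-conditioned
segments are needed for the 6×6 determinant, and the default nine are
barely sufficient — which is precisely what the calibration absorbs.
Fourier windows are rectangular by default (a taper hook exists but is
off).

## Thresholding and network assembly

Each trial's full value set (325 values for a single brain, all 1326
jointly for a dyad) is thresholded at `median + MAD`, the MAD unscaled
(no 1.4826 normal-consistency factor); ties at the threshold become edges.
Thresholding is per trial by default; a pooled mode (one threshold per
session × condition over all trials' values) is available behind a config
flag.  Self-connections are stored as zeros and excluded from every count
and measure: all graph theory here is on simple graphs.  Hyperbrain
matrices are 52×52 with J1 (always the less experienced juggler) first;
the inter-brain block appears once as the J1-by-J2 matrix and its
transpose mirror.

A known degenerate regime: when most pair values are exactly zero (as
happens for the calibrated estimator on trials with little or no lagged
coupling), the median and MAD are both zero and the `≥` rule yields a
complete graph.  This is the faithful reading of the threshold definition;
analyses of sparse-coupling simulations should use the pooled mode or
inspect the recorded threshold.

## Graph measures and surrogate normalization

The characteristic path length `L` is the mean shortest-path distance over
ordered *reachable* pairs — thresholded networks can fragment, and
excluding unreachable pairs keeps the measure finite (an edgeless graph is
an error).  The mean clustering coefficient counts, per node, realized
neighbour links over possible ones, with degree-< 2 nodes contributing
zero.

Normalization references are degree-preserving surrogate ensembles
(default 100 each): *random* surrogates by Maslov–Sneppen double-edge
swaps, *lattice* surrogates by the same move accepted only when it lowers
a ring-distance cost (latticization).  On hyperbrain inputs swaps are
restricted to edge classes — intra-J1, intra-J2, inter — so the intra- and
inter-brain degree sequences are each preserved exactly; the inter block
is rewired as a bipartite graph.  For latticization the two 26-node
orderings are aligned on one ring, the natural extension of ring-distance
cost under the block constraint.  Each surrogate attempts 10 × (class edge
count) swaps; ensemble summaries are means (not medians) of `L` and `C`.
Blocks with fewer than two edges are copied with a warning.

Normalized measures use the ratio convention by default:

    G = mean(L_random) / L_observed        (1 = random-like efficiency)
    C = C_observed / mean(C_lattice)       (1 = lattice-like clustering)

clipped to [0, 1]; the word "inverse" in the efficiency definition is read
as this reversal (high G for short paths), not as an unbounded reciprocal.
An interpolation convention `(x − random) / (lattice − random)` is
selectable.  `SWI = G × C`, `D = edges / (n(n−1)/2)` (325 possible for 26
nodes, 1326 for 52), and `IIR = (intra_J1 + intra_J2) / inter` edges; a
zero inter-brain count flags IIR as undefined (NaN, excluded from
aggregation) rather than infinite.

## Asymmetry indices

`Lat_intra = (R − L)/(R + L)` over intra-brain edges with both endpoints
in the right (R) or left (L) hemisphere; inter-hemispheric edges classify
as neither and are excluded (a half/half split option exists for
sensitivity analysis).  `RA_intra` applies the same contrast to
fronto-limbic vs occipito-parietal endpoint classes.  The default class
map — fronto-limbic {SPFC, OFC, APFC, LPFC, ACC, INS, PHG},
occipito-parietal {SPL, IPC, PVC, FUS, PCC, SMA} — is an anatomical
judgement call (notably SMA, PCC, PHG, INS) and is therefore a config
file, not a constant.  Inter-brain variants classify each inter-brain edge
by its endpoint in the chosen juggler's brain, so every edge classifies.
When no edge classifies, indices return 0 with an explicit flag so session
aggregation stays total.

## Session statistics

The session (a unique dyad; seven in the reference design, three of them
skill-matched by the ≤ 3-years rule) is the experimental unit; the juggler
appearing in two sessions is treated as independent across them,
consistent with the reference degrees of freedom.  Per-trial metrics are
averaged within (session, condition, juggler-or-hyperbrain, measure)
cells, undefined values excluded with a warning.

All design factors have two levels, so the split-plot ANOVA is computed
exactly via per-session contrast scores: each within effect (and its
interaction with the between factor) is a one- or two-sample *t*-test on
the corresponding contrast with `F = t²` and its own error stratum.  With
unequal group sizes the within main effects weight group means equally
(Type-III convention); the decomposition reproduces a multistratum
reference fit on balanced designs exactly.  Sphericity corrections are
moot with 2-level factors.  Effect size is partial η² = F·df₁/(F·df₁ +
df₂) — which reproduces all four reported values (0.627, 0.626, 0.908,
0.915) from their (F, df) triples — and observed power is the
noncentral-F tail beyond the α = 0.05 critical value with λ = F·df₁, the
convention that reproduces the reported powers (e.g. 0.643 for
F(1,5) = 8.392).  Follow-up paired *t*-tests are Bonferroni-corrected
(capped at 1) with Cohen's d as mean difference over the SD of
differences; hyperbrain metrics are compared between matched and
unmatched groups by equal-variance independent *t*-tests, two-sided.

One reported inter-brain result (F(1,1) = 5.557, η² = 0.527) has
internally inconsistent degrees of freedom (the η² back-calculation
implies df₂ ≈ 5); it is not used as a reference value.

## The simulator: what it emulates, and what it does not

Latent per-ROI oscillators are band-pass filtered Gaussian noise
(Butterworth order 4, 8.5–12 Hz, zero-phase), unit variance — narrowband
but with non-degenerate phase, so LPS estimates have realistic variance.
Planted couplings form a forest of driver edges: a target's latent is
`s · delayed(source) + sqrt(1 − s²) · innovation` (variance-preserving),
lags rounded to integer samples with a warning.  Each ROI's 3-D moment is
a fixed random unit orientation (drawn once per session per ROI, seeded)
times its latent, plus isotropic broadband noise (default SD 0.1 relative
to unit signal).  Zero-lag mixing replaces each ROI's signal by
`(1 − m)·own + m·aggregate`, the aggregate being the sum of same-brain
ROIs rescaled to the ROI's own RMS; it never crosses brains.  One global
seed drives a per-(purpose, trial, ROI) stream hierarchy, so any trial is
regenerable in isolation and identical seeds give bit-identical data.

Driver edges compose: chains and shared sources induce dependence between
pairs that carry no direct edge, with effective correlation equal to the
product of chain coefficients to the deepest common ancestor and a single
relative lag.  The *derived* pairwise truth (`effective_lagged_pairs`)
classifies a dependent pair as lagged when its effective correlation is at
least 0.3 and its centre-frequency phase is at least 30° from the real
axis; recovery is scored against this derived set, not the raw edge list.

Scenario used for recovery scoring: a hub drives every other ROI, part at
zero lag and part at a quarter-cycle lag (default 34 of 51), creating two
phase classes whose 18 × 34 = 612 cross-class pairs are genuinely lagged
while within-class pairs are zero-lag coupled.  This stresses exactly the
property LPS claims: rejecting strong instantaneous coupling while
detecting lagged coupling at the same strength.  Recovery runs on full
20 s trials (19 segments): the steady-state trim exists for human
recordings, not for the simulator, and the larger segment count halves the
estimator's sampling noise.  With coupling strength 0.9 and noise SD 0.1,
median+MAD thresholding attains precision ≈ 1.0 and recall ≈ 0.98 over
ten trials.

What passing these tests shows: the estimator chain is internally
consistent — it suppresses instantaneous dependence (mixing-only trials:
mean lagged ≈ 0.002 with mean total synchronization ≈ 0.996), is unbiased
under independence, and recovers planted lagged structure through the full
threshold-and-graph chain.  What it does not show: performance under
realistic source leakage geometry (mixing here is uniform, not
lead-field-based), non-stationary or broadband dynamics, inaccurate
source reconstruction, or artifact residue — none of which the simulator
models.

## Problem sizes in the shipped checks

The acceptance script and test suite use: 20 mixing-only trials and 10
recovery trials at the defaults above; 100 random graphs (≤ 15 nodes)
against brute-force path/clustering oracles; 50 Watts–Strogatz seeds
(n = 26, k = 4, p = 0.15) with 8-surrogate ensembles for the small-world
separation; and 2000 null replications of the 2×2×2 mixed design for
type-I calibration (observed rate ≈ 4.9% at α = 5%).
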