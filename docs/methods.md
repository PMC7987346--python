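# Methods

`dgne` implements the population-level analyses used to characterize
synchronous activity in dentate gyrus (DG) granule cells recorded by
two-photon calcium imaging in head-fixed mice on a treadmill belt: detection
of synchronous *network events* (NEs) against shuffle nulls, NE orthogonality
and sub-ensemble structure, place/speed tuning, bulk medial-perforant-path
(MPP) input statistics, pupil-linked state statistics, and PCA-subspace
comparison of locomotion and immobility activity.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic tests do and do not establish.

## Inputs and conventions

A session is a bundle of per-frame channels at a common frame rate (15 Hz
default, 20-minute sessions): a binary event-onset raster (cells × frames),
optional ΔF/F traces, running speed (cm/s), belt position (cm on a 150 cm
circular belt), an optional bulk MPP fluorescence trace, and an optional
pupil-diameter trace with a blink mask.  Frames are 0-based; intervals are
half-open `[start, end)`.  ΔF/F is optional because public deposits of such
data often carry binarized traces only; stages that need ΔF/F fail fast with
a named error.

Behavioral states: running epochs are maximal intervals with speed ≥ 4 cm/s
lasting ≥ 2.5 s; immobility (rest) is speed < 4 cm/s.  Supra-threshold bouts
shorter than 2.5 s satisfy neither definition and are excluded from both
states by default (`rest_includes_short_bouts` folds them into rest instead).

## Network-event detection

Synchrony is counted in a moving 200 ms window — 3 frames at 15 Hz, the
center frame ± 1 — with multiple onsets of one cell inside a window counted
once (`window_counts`; edges use truncated windows).  Candidate events at
size *s* are maximal runs of frames whose count reaches *s*; runs merge into
a single event whose peak is the count argmax (earliest frame on ties, which
for an isolated synchronous column means the frame *before* the onset column,
since the count plateaus over three frames).  Members are all cells with an
onset within the run span ± half window.

The per-session size threshold comes from shuffled rasters (1000 shuffles by
default).  Three shuffle methods all conserve per-cell onset counts exactly:

1. `redistribute` — onset times redrawn uniformly per cell (default),
2. `trace_shift` — per-cell circular shifts (preserves within-cell
   inter-onset structure),
3. `state_constrained` — redistribution within run frames and within rest
   frames separately (preserves state-dependent rates).

Under the default `threshold_rule="ratio"` the threshold is the smallest *s*
at which the mean shuffled event count at ≥ *s* falls below `alpha = 0.001`
times the real event count at ≥ *s* (less than 0.1% of observed events
attributable to chance), or at which no real events remain.  An alternative
`per_shuffle` rule (fraction of shuffles containing any event of size ≥ *s*
below alpha) is available because the pooled-versus-per-shuffle reading of
the published rule is ambiguous.  The threshold scales with overall onset
density and rate heterogeneity: sparser sessions calibrate near 5 cells,
denser ones near 8–9.  Events smaller than the calibrated threshold are
undetectable *by construction*; recovery statements therefore apply to
planted events in the detectable size range.

State statistics report per-state counts and frequencies, duration-equalized
frequencies (the longer state truncated to the shorter's total duration by a
seeded contiguous subsample), the cumulative occurrence curve over session
time, and NE positions within rest periods ≥ 5 s normalized to period length.

## Orthogonality and sub-ensembles

Each NE is a binary participation vector over cells.  Similarity between NEs
is the cosine of their participation vectors (1 = identical membership, 0 =
disjoint).  The *orthogonal fraction* is the proportion of NE pairs with
similarity exactly 0; its null redraws each NE's participants uniformly
without replacement, preserving every NE's size (1000 draws; one-sided p for
greater orthogonality).  The size-preserving null is the natural chance model
for "how often would sparse events be disjoint anyway".

Sub-ensembles are found on the cells' participation row-vectors restricted to
NE-related activity.  The significance threshold is the 95th percentile of
pooled pairwise Pearson r values from 1000 row-wise permutations of the
participation matrix (each cell's participations reassigned to random NEs,
conserving per-cell counts).  Agglomeration uses a linkage tree
(standardized Euclidean distance, weighted average linkage, via scipy);
merges are applied in tree order and a merge is refused when the merged
cluster's own mean intra-r would fall below the threshold, freezing that
branch (`merge_stop_rule="cluster"`, the default).  A `"global"` variant
halts agglomeration when the pooled mean within-cluster r drops below the
threshold; it is more fragile because one early chance merge of two
uncorrelated cells can stop the procedure before genuine ensembles form.
Only clusters whose mean intra-r exceeds the threshold are reported.

A calibration caveat worth stating plainly: a 95th-percentile threshold on
*pairwise* r leaves ~5% of chance pairs eligible by construction, and the
linkage preferentially proposes exactly those pairs, so structureless data
yields a handful of small (2–3 cell) chance clusters rather than literally
zero.  The procedure controls the *strength* of reported clusters, not their
count; on planted data the genuine ensembles dominate and are recovered with
Jaccard ≥ 0.7.

## Spatial and speed tuning

Place coding uses the spatial tuning vector: the belt maps to the unit
circle (θ = 2π·pos/L); each running-epoch onset contributes a unit vector at
its θ weighted by the reciprocal occupancy time of its spatial bin (50 bins
of 3 cm by default), weights normalized to sum 1 so a perfectly concentrated
cell scores length 1 under any occupancy.  Only cells with ≥ 4 running
onsets are tested.  Significance: onset times redrawn uniformly over running
frames 1000 times; p is the fraction of null lengths exceeding the observed
length; place cells have p < 0.05.  The vector is exactly equivariant under
belt rotations.

Speed coding bins speed into 20 equal bins spanning [0, max]; the tuning
curve is the mean ΔF/F per bin over *all* frames (the lowest bin therefore
contains immobility frames — the printed procedure; a running-only variant
is a one-line restriction).  Candidacy requires Pearson r ≥ 0.9 between bin
centers and bin means; significance requires ≥ 95% of 1000 circular
time-shifts of the trace (≥ 5 s) to yield a smaller r.  Note that binned
means of a perfectly linear response differ from bin centers at order
(bin width)/n, so r → 1 only in the dense-sampling limit.

## Bulk MPP input

The bulk trace is converted to ΔF/F against a baseline defined as the
0.01 Hz zero-phase Butterworth low-pass of the raw trace.  Transients are
recovered by nonnegative sparse deconvolution under an exponential-decay
kernel (τ = 1.5 s default): FISTA on ½‖Ks − y‖² + λ‖s‖₁, s ≥ 0, with λ set
to 2.5 robust noise SDs per unit kernel norm (noise estimated from the
median absolute first difference), and the Lipschitz constant taken from the
kernel's DC gain.  Contiguous nonzero runs of the activity proxy collapse to
one event at the run argmax with the run's summed activity as amplitude;
amplitudes are reported normalized to the proxy's standard deviation (raw
ΔF/F-scale amplitudes are kept alongside).  On noiseless traces the
inversion is essentially exact; on pure noise the default floor admits
< 0.05 events/s.  "Large" events exceed mean + 2 SD of the session's event
amplitudes.

MPP–GC coupling during immobility is quantified by (i) the normalized
cross-correlation of the bulk ΔF/F with summed GC activity over rest frames
(positive lags = MPP leads), (ii) a bivariate Granger F-test (nested-AR OLS;
lag order by BIC up to 15; both directions computable), and (iii) the signed
delay from each NE to the nearest deconvolved MPP event (positive = MPP
leads).

## Pupil

Blink/saccade frames are bridged by linear interpolation (removal would
break the uniform time base the zero-phase filter and alignment need), then
a 4th-order zero-phase Butterworth low-pass at 4 Hz, resampling to 15 Hz
(polyphase, linear edge padding), and division by the mean (output mean
exactly 1).  State statistics report mean diameter and mean first-difference
rate of change (units 1/s) for entire locomotion episodes, entire immobility
periods, and the single frames of NE peaks; event-triggered averages drop
events whose window leaves the recording.

## Subspace similarity of locomotion and immobility activity

Rows of the ΔF/F matrix are z-scored once per session (constant rows
dropped with a warning, preserving cell alignment between state subsets).
PCA is by SVD with rows centered; eigenvector signs are fixed by making the
largest-magnitude loading positive; each basis is truncated at the smallest
component count explaining ≥ 50% of variance (k may differ between bases;
paired measures truncate to the smaller k).  X_run takes all running-epoch
columns; X_net takes 2 s windows centered on NE peaks (overlaps
deduplicated, edge windows clipped).

Measures, each comparing the NE basis V_net against the run basis V_run:

* projected variance ratio: trace(V_netᵀ C_run V_net) / trace(V_runᵀ C_run
  V_run), with C_run the covariance of X_run — invariant to rotations of
  V_net within its subspace;
* S_PCA = Σᵢ cos²θᵢ over the principal angles θᵢ (singular values of
  V_netᵀV_run), between 0 and k;
* EROS = Σᵢ wᵢ·|cosθᵢ| with *paired* component angles and weights wᵢ taken
  as the mean of the two bases' eigenvalue fractions, renormalized to sum 1
  (a two-matrix reduction of the corpus-level weighting in the original
  definition), between 0 and 1.

Three shuffle nulls randomize only the NE side (1000 shuffles; one-sided p =
fraction of shuffled values ≥ observed): (1) circular time shifts (≥ 5 s) of
each cell's concatenated immobility trace with the original NE windows
re-applied; (2) permutation of cell identities within each NE window
(conserves per-window totals); (3) permutation of each cell's window
segments across NEs (conserves per-cell participation).  Shuffles 2 and 3
operate on the block-structured concatenated NE matrix and use only
full-length windows.

Lap periodicity of the population code: the first five components' weight
series over running frames are resampled onto a 150-bin position grid per
complete lap (laps covering ≥ 80% of bins), concatenated, and
autocorrelated with the unbiased (overlap-corrected) normalization; the
peak near a lag of one lap (± 10%) averaged over components quantifies
spatial stability.  A CA1-like population (dense, strong place code) scores
near its ceiling; a DG-like population scores low.

## Synthetic sessions and what they show

The generator plants, per 200-cell 20-minute default session: alternating
rest/run bouts giving ~30–40 m of running; Poisson background onsets at
1/min/cell; 30 NEs inside rest epochs with sizes ~N(11, 2²) truncated at 8
cells (≈ 5.6% mean participation — published NE size distributions are
truncated at the per-session detection threshold, so planted sizes stay in
the detectable range); four sub-ensembles of 7 cells recruited at 0.9
participation by their designated NEs; 5% place cells (von Mises, κ = 4,
~25 extra in-field run onsets — κ chosen so detection is sensitive but not
trivial); 2% speed cells modeled as mildly rate-elevated (2× baseline,
slope 0.2/cm/s) *plus* a graded kernel-filtered ΔF/F component of
0.06 ΔF/F per cm/s, because the binned-ΔF/F r ≥ 0.9 criterion targets
continuous fluorescence modulation and a pure sparse-event model cannot
reach it at realistic granule-cell rates; ΔF/F via a single-exponential
kernel (τ = 1.5 s, GCaMP6s-like) with additive noise (SD 0.05); an MPP
trace with slow drift, small frequent run transients and large transients
leading each NE by 2 frames; and a pupil trace dilating during running,
constricting at rest, dipping by 0.15 at NEs, with sporadic blink frames.

For subspace analyses a separate factor-model builder creates
replay-positive sessions (NE windows re-express the run epochs' latent
factors) and replay-negative ones (NE windows of private/isotropic
activity); loadings are unit-norm per cell so similarity can only arise
from genuine cell-cell co-fluctuation, not variance profiles.

What passing tests show: the detectors recover exactly the structure they
were designed for, at calibrated false-positive rates, under a forward model
that matches the analyses' assumptions.  What they do not show: robustness
to motion artifacts, neuropil contamination, nonstationary baselines,
overlapping sources, non-Poisson background correlations, or real DG event
statistics — none of which the generator emulates.

## Numerical choices and degenerate inputs

Filters are Butterworth in second-order-section form with `sosfiltfilt`
(zero phase); filter order 4 for pupil, 2 for the very-low-cutoff MPP
baseline.  Tie-breaks: NE peak = earliest argmax; clusters ordered by size.
Pearson r between identical non-constant rows is treated as exactly 1;
constant rows are excluded from r pooling and from clustering.  Zero
participation columns cannot arise from valid NE sets and are excluded with
a warning from similarity.  Empty states, empty event sets, all-blink pupil
traces, too-short series for the requested Granger order, and fewer than
three complete laps all raise (or report) named errors rather than returning
silent zeros.  Master seeds expand to per-stage seeds by a fixed counter
scheme so any stage can be re-run in isolation.

## Problem sizes in the test suite

The shuffle-based batch calibrations in the acceptance tests use 200
shuffles (thresholds elsewhere default to 1000); recovery runs use batches
of 10 default-size sessions; the Poisson null calibration uses 100 seeded
200-cell sessions; subspace controls use 100-cell factor sessions with 20
NEs.  These sizes were chosen to estimate each rate with adequate precision
while keeping the full suite runnable on a single CPU.

## Known limitations

* The Dryad-deposit converter maps a plain binarized-trace matrix; the
  deposit's exact layout was not confirmed against the archive.
* The clustering null controls cluster strength, not cluster count (see
  above); reported cluster counts on weakly structured data include small
  chance pairs.
* Granger inference assumes approximately stationary series; the pipeline
  applies it to rest-frame concatenations without explicit stationarity
  checks.
* The object-displacement discrimination index is provided as a pure
  function of exploration times; behavioral video scoring is out of scope.
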