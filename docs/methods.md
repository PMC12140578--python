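# Methods

This note documents the models, estimators and design choices behind
`icnet`, and what the synthetic validation does and does not establish.

## Connectivity model

The pipeline quantifies functional coupling between cortical scouts with the
absolute imaginary part of coherency,

    IC_xy(f) = | Im( S_xy(f) / sqrt(S_xx(f) S_yy(f)) ) |,

where S_xx is the auto-spectral density of scout x and S_xy the
cross-spectral density. Coherency of two signals related by an
instantaneous, real, time-invariant mixing is real, so IC rejects volume
conduction and source leakage by construction; a non-zero imaginary part
requires a consistent non-zero phase lag. IC lies in [0, 1], is invariant
to per-scout amplitude rescaling, and is exactly zero on the diagonal.

**Spectral estimation.** Welch's method with 1-s windows (1 Hz resolution),
50 % overlap, per-window constant detrend and a periodic Hann taper, using
the S_xy = E[conj(X)·Y] convention (a pure delay of y by τ gives phase
−2πfτ). Windows from all eyes-closed segments of a recording are pooled
into one estimate; the window count is kept because the positive bias of
coherence-type estimators scales like 1/sqrt(n_windows). The taper and
detrend are our choices (the upstream processing chain this emulates does
not pin them down); both are standard and only affect leakage at the 1-Hz
bin scale.

**Band aggregation.** The alpha-band value of a pair is the arithmetic mean
of per-frequency IC over the bins with 8 ≤ f ≤ 12 Hz inclusive (five bins
at 1 Hz resolution), with the absolute value taken per bin *before*
averaging so each bin's contribution stays in [0, 1]. The alternative —
coherency of band-averaged spectra — would let opposite-phase bins cancel;
we document the choice and expose the band as a parameter. Bins where an
auto-spectrum vanishes are flagged undefined (NaN) and excluded from the
band mean.

**Noise ceiling.** Finite data give strictly positive IC even for
independent signals. `ic_noise_ceiling` estimates the null distribution of
band IC by running surrogate independent white-noise pairs through the
identical segmentation/Welch/IC/band path and returns its 99th percentile.
Observed band IC is treated as evidence of lagged coupling only above this
ceiling. The 99 % quantile (rather than 95 %) makes "fraction of pairs above
ceiling" a conservative detector with ~1 % expected false alarms.

## Preprocessing

Recordings pass through, in fixed order: (1) zero-phase band-pass
0.5–40 Hz (4th-order Butterworth, forward–backward, so cross-spectral phase
is untouched — any group delay would corrupt IC); (2) average reference
(subtract the instantaneous mean over scouts; idempotent and
difference-preserving); (3) segmentation into eyes-closed epochs from the
annotation track, trimming a 1-s guard from each interval boundary to
suppress eye-transition artifacts (configurable; segments shorter than one
spectral window after trimming are dropped with a warning). Eyes-closed
data are used because eyes-open alpha is suppressed by visual input.
Separate closed intervals are kept as separate epochs whose Welch windows
are pooled — an interpretation; concatenation would create artificial
discontinuities at the seams.

## Network metrics and change scores

Weighted node degree wND_i = Σ_{j≠i} IC_ij summarizes a scout's overall
coupling ("hub-ness"). wND values are z-scored across the recording's
scouts using the sample standard deviation (n−1; convention configurable);
a constant-wND recording is degenerate and recorded as missing rather than
aborting the study. Z-scores are averaged over the atlas's frontal region
sets — z first, then region averaging. The bundled 62-scout atlas mirrors
the Mindboggle/DKT cortical parcellation (31 regions per hemisphere); since
stimulation at F3/F4 affects a broad frontal territory, the frontal region
sets include the full frontal lobe of each hemisphere — superior/middle/
inferior frontal, precentral, paracentral, orbitofrontal — and the mapping
ships as an editable JSON data file, not code.

Change scores isolate the stimulation-specific effect:
wND change = (post − pre)_active − (post − pre)_sham per subject and
region; behavioral change = active − sham (behavior is measured once per
session, during stimulation). Subjects missing any study cell are excluded
with a logged reason.

## Statistics

**Edge test.** For each of the 1891 unordered scout pairs, a paired t
statistic is computed on the per-subject difference of raw IC changes
between conditions. The null is built by sign-flipping each subject's
difference vector: under H0 of no condition effect the difference is
symmetric about zero, so flips are exchangeable. One flip vector per
permutation is applied to all edges, preserving the between-edge
correlation structure. Monte-Carlo p-values (default 5000 draws) use the +1
correction, p = (1 + #{|t*| ≥ |t|})/(1 + n_perm), and are therefore valid
(never zero, minimum 1/(n_perm+1) — when FDR granularity matters, n_perm
must exceed m/(α·k) for the k-th smallest target). Correction is
Benjamini–Hochberg across all edges (Benjamini–Yekutieli by flag). Note BH
adjustment is *not* idempotent (p = [0.1, 0.5] → [0.2, 0.5] → [0.4, 0.5]);
the monotonicity of adjusted values in raw-p rank is the tested invariant.

**Baseline check.** Paired t tests compare active-pre vs sham-pre frontal
region means, mirroring the standard control for session baseline
differences.

**Brain–behavior models.** Per task and hemisphere, frontal wND change is
regressed on the fluency, originality and flexibility change scores with
backward elimination: start from the full OLS fit and repeatedly remove the
predictor with the largest p-value above the removal threshold (default
0.10, the common stepwise default; configurable). Reported are
unstandardized B, SE B, fully standardized β (equal to the slope after
z-scoring response and predictor; for a single predictor, to Pearson r),
model R², the F-test p, and the elimination trace. Follow-up simple
regressions are fit for each retained predictor.

## Synthetic data generator

The generator emulates the study design the pipeline targets: 40 subjects ×
{active, sham} × {pre, post}, 5-min resting-state recordings with
alternating 35-s eyes-open/closed blocks (defaults; all sizes are
parameters). Scout signals are sums of broadband Gaussian noise, an
independent narrowband alpha component per scout (an alpha rhythm with no
true coupling), and per-edge narrowband carriers: a coupled pair shares one
analytic carrier, the second scout receiving a copy rotated by the edge's
phase lag and diluted with an independent carrier so the shared fraction
equals the coupling strength. Oscillators are band-pass-filtered noise
rather than coupled ODEs because this gives direct, exact control of the
phase lag IC must detect. Source leakage is a fixed unit-diagonal mixing
matrix applied after coupling — precisely the confound IC claims to reject,
so a zero-lag-only world must yield null-level IC. Condition effects add
delta_coupling (times a per-subject uniform jitter in 1 ± 0.5, recorded as
ground truth) to the named edges in the active-post cell only. The paper
trail for effect sizes is empty, so the default delta (0.4) is chosen for
testability, not physiological realism.

Behavioral data: each subject answers 3 items per task per session from
item-parallel sets. Vocabularies hold 1000 candidate answers per item with
Zipf(1.4) population frequencies, 8 semantic clusters (cluster centers are
random unit vectors; token vectors scatter with norm 0.4 around them;
synonym surface forms share one canonical vector), and tilt-independent
rates of double listings, synonym aliases and common-use intrusions to
exercise the scoring rules. A subject's distinct answers are drawn *without
replacement*, which makes fluency independent of the coupling knobs by
construction. The `behavior_link` coefficient ρ shifts the active-session
answer-rarity tilt and cluster-switching rate by ρ·z + sqrt(1−ρ²)·ε, where
z is the subject's standardized injected connectivity change — so the
population correlation between connectivity change and the
originality/flexibility change scores is ρ up to sampling attenuation, and
exactly zero at ρ = 0. Fluency is never linked. The vocabulary size
matters: with a small vocabulary the population's own tilt flattens the
pooled frequency distribution and statistical-infrequency originality
degenerates; 1000 tokens keep the tail rare regardless of who samples it.

**What passing tests show — and don't.** The generator produces stationary
Gaussian band-limited signals with exact lags and linear instantaneous
leakage. Real EEG adds nonstationarity, artifacts, 1/f structure beyond the
modeled bands, finite-precision source reconstruction, and behavioral
answer pools that are open-ended rather than sampled from a fixed
vocabulary. Recovery and calibration results on synthetic studies therefore
validate the *estimators and inference machinery*, not the physiological
claims of any particular dataset.

## Validation problem sizes

The study-level validation uses reduced problem sizes chosen to keep the
whole suite at desk scale while leaving each test well-powered:

* null calibration: 500 replicate studies of 12 subjects × 10 scouts,
  30-s recordings at 100 Hz (7.5-s eye blocks), 500 permutations — pooled
  p-values are KS-uniform and the type-I rate at α = 0.05 is ~0.047
  (slightly conservative due to the +1 correction);
* effect recovery: 20 replicates of 40 subjects × 12 scouts with 3 injected
  edges (delta 0.4), 2000 permutations (FDR granularity requires
  min p = 1/2001 < 0.05·3/66);
* brain–behavior recovery: 20 replicates of 40 subjects regressing the
  ground-truth injected connectivity change on the scored behavioral
  changes — the response the `behavior_link` semantics are defined
  against; the EEG-measured response path is covered by the effect-recovery
  test.

## Numerical choices and degenerate inputs

Hermitian symmetry of the cross-spectral matrix is exact by construction
and the scout-diagonal is forced real. Band matrices are symmetrized
(averaged with their transpose) to remove float dust and the diagonal
zeroed. Zero-variance guards use relative tolerances (1e-12 of the data
scale): constant wND, constant paired differences, zero-variance
predictors. Permutation tie comparison uses |t*| ≥ |t| − 1e-12 so the
identity flip always counts. All randomness flows through numpy
`SeedSequence` spawning with a fixed layout (subject effects, behavior,
one stream per recording), making datasets bit-reproducible under a seed;
changing n_subjects changes the layout and hence all streams.

## Known limitations

* The pipeline starts from clean scout-level signals; bad-channel handling,
  ICA artifact removal and source reconstruction are upstream concerns.
* Only Welch spectra (no multitaper/wavelet), only IC (no directed
  measures), only wND (no other graph metrics).
* Statistical-infrequency originality is unstable in small samples; scores
  from few participants over-reward idiosyncratic answers.
* Backward elimination inherits the usual stepwise caveats (order effects,
  optimistic R²); the elimination trace is reported so final models can be
  audited.
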