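# Methods

`illusioneeg` re-implements, as a tested library, the EEG analysis chain of
a cross-linguistic auditory-illusion study design: five prior-congruence
conditions (congruent English **CEng**, congruent/illusory Italian
**CIta**, incongruent English **IEng**, incongruent Italian **IIta**,
scrambled words **SW**), event-related potential (ERP) statistics with
cluster-based permutation correction, topographic ANOVA, Morlet
time-frequency analysis, a beta/gamma Hilbert-envelope dominance index,
and a CSP → mutual-information → QDA decoder separating English from
Italian listening from spatial covariance structure.  Because raw
recordings for this paradigm are not publicly available, the package ships
a first-class synthetic-cohort generator whose statistical structure
matches what each analysis assumes, and every claim the test suite makes
is a claim about recovery of *injected* structure.

## Synthetic cohort model

A cohort is defined by `SimConfig`: by default 21 subjects, 64 channels
(idealized 10-20/10-10 positions on a unit disk, mastoids M1/M2 included),
1000 Hz, 100 trials split evenly over the five conditions in
subject-specific randomized order.  Each subject also gets a pair of long
"audiobook" recordings (default 11 min) used to train the decoder.

Signal model, all amplitudes in microvolts:

* **Background noise** — spatially correlated 1/f noise: independent
  spectrally shaped series (power ∝ f^−β, β = 1 by default) mixed through
  the Cholesky factor of a squared-exponential channel kernel
  (correlation length 0.35 disk units) and scaled to 10 µV RMS per
  channel.  The log-log spectral slope of a background-only recording
  matches −β within ±0.3 (tested).
* **ERP components** — N1 (negative, peak 110 ms, width 60 ms) and P2
  (positive, peak 200 ms, width 100 ms) half-cosine bumps time-locked to
  word onset, with a fronto-central Gaussian topography peaking at Cz.
  Half-cosines were chosen because their window means have a closed form,
  which the tests exploit.  Default P2 gains are CEng 1.0, CIta 3.2,
  IIta 5.4, SW 5.2, IEng 6.0 µV.  The *ordering* (IEng > CIta ≥ CEng,
  IIta > CIta, IIta < IEng) encodes the qualitative pattern the analyses
  must recover; the gap sizes were fixed at design time by a power
  analysis so that a 21-subject cohort recovers the ordering of
  grand-average P2 window means in ≈99% of replicates and the IEng-vs-CEng
  cluster in essentially all replicates.  They are therefore larger than a
  "slightly larger peak" — deliberately: the generator is a test harness,
  not a forward model of effect sizes.
* **Beta/gamma bursts** — amplitude-modulated carriers (21 Hz and 38 Hz)
  with raised-cosine ramps, phase-locked to word onset so that they
  survive trial averaging (the dominance index is computed on averaged
  ERPs).  Default dynamics: CEng beta-dominated throughout; CIta gamma
  0–250 ms then beta; IEng gamma 0–450 ms then beta; IIta/SW similar with
  later, weaker transitions.
* **Language covariance signature** — one broadband (4–30 Hz) source per
  language class, mixed with a lateralized Gaussian topography (left for
  English, right for Italian, 8 µV, small per-subject center jitter).
  Audiobook recordings carry their language's source continuously; main-
  task trials carry the signature of the *perceived* language during the
  audio span (CIta carries the Italian signature; all other conditions the
  English one, at condition-specific strength).  Classes differ only in
  stationary spatial covariance — exactly the structure CSP exploits —
  and not in stimulus-locked waveforms.
* **Trial timing** — audio duration uniform on 1–4.25 s, word onset lags
  music onset by 0–0.5 s, epochs beyond the audio end contain background
  noise only.
* **Ratings** — per-trial 3-point ratings drawn from condition-specific
  probability vectors (congruent/illusory conditions high, incongruent and
  scrambled low), which puts the Friedman statistic near its ceiling at
  n = 21, as in the motivating design.

Determinism: every random stream is derived from
`SeedSequence([seed, subject, purpose])`; identical config + seed
reproduce identical bytes (tested, including HDF5 output checksums).
`generate_epoch_cohort` is an epoch-level fast path that samples only the
epoch windows; it shares the trial model but uses separate noise streams,
so it matches the continuous path statistically, not sample-for-sample.

What the generator does **not** emulate: artifacts (blinks, EMG, line
noise), volume-conduction forward models, nonstationary noise, learning or
fatigue effects, and realistic inter-subject variability beyond source-
center jitter.  Passing tests therefore demonstrate correctness of the
analysis chain and its statistical calibration, not performance on real
EEG; in particular the decoder's ~99% synthetic LOSO accuracy reflects the
idealized covariance separation, and real-data accuracies will be far
lower.

## Preprocessing

Downsampling (polyphase, anti-aliased, events remapped), re-referencing to
the mastoid average, zero-phase windowed-sinc FIR band limiting (default
0–125 Hz; "0 Hz" edges are treated as pure low-pass), epoching by pure
indexing around event markers (out-of-bounds epochs dropped and counted),
baseline correction over −200–0 ms, and fixed 2.5-s segmentation for the
decoder path, which instead band-limits with a 4th-order Chebyshev type-I
low-pass at 40 Hz (0.5 dB design ripple; forward-backward application
doubles the ripple in dB but preserves phase).  All filtering is
zero-phase so component latencies are never shifted.  FIR order follows a
≈1 Hz transition width at 1000 Hz, scaled with rate.

## ERP statistics

ROI = {Fz, FCz, Cz, CPz, Pz}.  Waveforms are averaged over epochs within
subject × condition, then over ROI channels.  N1/P2 amplitudes are means
over the closed 100–150 / 150–250 ms windows.  Pointwise two-tailed t
tests support both paired (default for the within-subject design) and
independent variants.  The cluster permutation test forms clusters of
adjacent suprathreshold samples (p < 0.05 two-tailed forming threshold;
4-connectivity on time-frequency grids), uses cluster mass = Σt, and
builds the null from within-subject condition exchanges (sign flips),
enumerated exhaustively when 2^n ≤ n_perm.  Positive and negative clusters
are reported separately, but both are referred to a common two-tailed
max-statistic null (the larger of the maximal positive and maximal
|negative| mass per permutation); with per-tail nulls the familywise
type-I rate of "any significant cluster" sits at ≈2α, and the common null
restores calibration (verified empirically: null rejection rates fall in
[0.01, 0.10] at α = 0.05).  P-values use the ≥ convention with the
observed labeling included.

One-way repeated-measures ANOVA on window amplitudes uses the explicit
sums-of-squares decomposition with (k−1, (k−1)(n−1)) degrees of freedom
(cross-checked against pingouin).

TANOVA: per time point, each condition's grand-average map is normalized
by its global field power (RMS across channels); DISS between two maps is
the RMS across channels of their difference, generalized to >2 conditions
as the mean pairwise DISS.  The null shuffles condition labels within
subject; zero-GFP time points are excluded and flagged.

## Spectral analysis

Morlet wavelets (7 cycles, L2-normalized, truncated at ±3.5 σ_t) on a
2–80 Hz, 1 Hz grid; power is computed per trial and channel and averaged
over the ROI channels; per-frequency edge margins (half the wavelet
support) are flagged, and signals are reflection-padded before
convolution.  dB baselining is applied to trial-averaged power:
10·log₁₀(P / mean baseline P) per frequency, with the −200–0 ms window —
noting that in word-onset-aligned epochs the pre-onset span may contain
music, so it is a reference window rather than a true quiet baseline.
Band power is the mean over the band's frequency rows, bounds inclusive
(beta 13–30 Hz, gamma 30–50 Hz; high-beta 20–30 and low-gamma 30–50
presets are provided since either sub-band convention is defensible).

The dominance index divides the Hilbert envelope of the beta-filtered
grand-average ROI ERP by the gamma envelope (band filtering zero-phase
FIR, reflection-padded; edge margins flagged).  Runs where the ratio stays
on one side of 1 for at least 100 ms (half of a 200 ms inspection window)
are reported as beta-/gamma-dominated intervals; samples with ratio
exactly 1 break a run, zero-gamma samples are excluded.  The ratio is
computed on condition-averaged ERPs — averaging first, as the index is
defined — which is why the generator's bursts are phase-locked.

## Decoder

Per-segment channel covariances (ddof 1) are trace-normalized and
class-averaged; CSP solves the generalized eigenproblem (C_a, C_a + C_b),
so eigenvalue pairs satisfy λ_a + λ_b = 1, and components are ordered by
discriminability max(λ, 1−λ) (ties resolved toward the class-A-dominant
component).  Rank-deficient composite covariances receive a logged ridge.
Features are raw log variances of the filtered segments.  Mutual
information between each feature (equal-frequency binned into ⌈√n⌉ bins)
and the class label ranks features; ties break toward the lower index.
QDA uses class-specific covariances with optional shrinkage toward a
scaled identity; singular covariances trigger the minimal restoring
shrinkage, logged.

Evaluation is leave-one-subject-out: training subjects' segments are
pooled trial-wise, (n_components, k features, shrinkage) are chosen by
inner repeated class-stratified 10-fold accuracy over a small grid
(components ∈ {2,4,6,8}, k ∈ {2..components}, shrinkage ∈ {0, 0.01, 0.1}
by default; ties prefer the smaller model), the pipeline is refit on the
full pool and scored on the held-out subject.  All folds are seeded.
Inner folds stratify by class only; a subject-grouped variant was
considered and rejected for the default because pooled training is the
stated design.

Condition projection: main-task epochs are conformed to the 2.5-s training
length (cropped from word onset; shorter epochs reflect-padded), averaged
across subjects per stimulus (stimulus identity, not presentation index,
is the only defensible alignment under randomized order), **rescaled by
√n_subjects**, projected through the trained CSP-MI-QDA pipeline, and
summarized as per-condition class percentages.  The rescaling exists
because averaging n trials with independent noise divides variances by n,
which would shift every log-variance feature by −log n — far outside the
classifier's training support; multiplying the averaged trials by √n
restores the single-trial variance scale while leaving class-covariance
ratios untouched.

## Behavioral statistics

Trial ratings are aggregated to one value per subject × condition (mean by
default, median optionally).  The Friedman statistic uses mid-ranks with
the standard tie-correction factor and a χ²(k−1) reference (an exhaustive
or Monte-Carlo row-permutation option exists for small samples).  Pairwise
Wilcoxon signed-rank tests cover all 10 condition pairs with Bonferroni
correction (×10); zero differences are dropped and counted, the exact
null is enumerated over all 2^m sign patterns when m ≤ 12 non-zero
differences remain (this enumeration supports ties), and the tie-corrected
continuity-corrected normal approximation is used otherwise.

## Pipeline and reproducibility

`illusioneeg.pipeline.run_pipeline` executes simulate → preprocess → erp /
spectral / decode / behavior from one YAML-serializable configuration with
a single root seed expanded per stage.  Every output file is recorded in
`manifest.json` with a SHA-256 checksum; HDF5 files are written without
embedded timestamps, so a rerun with identical config + seed reproduces
identical checksums (tested), and an up-to-date simulate stage is skipped
on rerun.  BrainVision and EDF recordings can be imported through MNE's
readers into the same containers; the internal HDF5 layout
(`/data`, `/rate`, `/labels`, `/events`, `/meta`) is the native format.

## Test-scale conditions

The replicated statistical checks run at deliberately reduced scale so the
whole suite stays fast while preserving the structure that matters: 250 Hz
sampling, a 16-channel montage that always retains the five ROI channels
and both mastoids, 2-minute audiobooks, and 10–21 subjects depending on
the check (21 for ERP ordering/cluster recovery and all reported
grand-average quantities, 12 for decoding and calibration, 10 for
dominance replicates).  Calibration checks use 200 null cohorts; effect-
recovery checks use 50–100 replicates.  These sizes are the package's own
choice of test conditions and are stated alongside each result.

## Known limitations

* The generator's effect sizes are tuned for statistical recoverability,
  not biological realism; synthetic decoding accuracy in particular is
  near ceiling.
* The dominance rule's "selected time window" is read as 200 ms (minimum
  run = 100 ms); the parameter is exposed.
* Epoch windows are parameters: the component analyses default to
  −200–350 ms or −200–800 ms depending on the question, and the module
  does not resolve upstream ambiguities about which was used where.
* The Chebyshev ripple (0.5 dB), FIR transition width, and MI binning rule
  are fixed conventions; all are pluggable.
* EDF/BrainVision import is supported; EDF export is not.
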