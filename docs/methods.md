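# Methods

This note documents the models, parameter choices and numerical conventions
behind `elindex`, and what the synthetic validation does and does not show.

## Signal model and preprocessing

Input is a two-channel EEG recording — left central C3 (referenced to the
right earlobe, A2) and right central C4 (to A1) — in microvolts at a
sampling rate `fs` (default 200 Hz), with scored events (`normal`, `OSA`)
given as onset/duration annotations.  For each event a 20-s window
(`segment_s`) is cut per channel, starting at the annotation onset
(configurable offset).  Indexing is 0-based with half-open sample windows;
onsets convert to samples by `round(onset × fs)`.  Non-finite samples are a
hard error everywhere: entropy and energy are undefined on NaN and silent
imputation would fabricate symmetry.

**Low-pass filter.**  An order-8 Butterworth with 50 Hz cutoff removes
muscle artifact and mains interference.  The filter is *designed* on the
analog prototype — magnitude `(1 + (f/50)^16)^(−1/2)`, −3.01 dB at the
cutoff — and *applied* as the bilinear-transform digital SOS cascade run
forward-backward (`sosfiltfilt`).  Zero-phase application is standard in
EEG work because phase distortion would shift features differently per
band; the cost is an effectively squared magnitude response, which is
irrelevant here since both channels are filtered identically and every
downstream index is a within-comparison contrast.

**Band decomposition.**  Bands are δ 1–3, θ 4–7, α 8–13, β 14–30 Hz.
Dyadic DWT levels cannot match those edges, so the default backend is
wavelet-*packet* decomposition at depth `ceil(log2(fs/2 / 2))` (terminal
packets ≤ 2 Hz wide; depth 6 at 200 Hz), reconstructing each band from the
packets whose nominal frequency ranges intersect the band edges.  The
discrete Meyer wavelet (`dmey`) is the default family: with compact
Daubechies filters (db4/db8) packet aliasing leaves only 0.76–0.84 of a
10.5 Hz sinusoid's four-band energy in the α band, while `dmey` keeps
≥ 0.98 in every band and passes the ≥ 0.85 fidelity bound with a wide
margin.  An FIR band-pass filter-bank backend (`wavelet.backend: fir`) is
available as a cross-check.  Content in the 0–1 Hz and 30–50 Hz gaps is
discarded without renormalization — only the four bands are analyzed.
Packets straddling a boundary (e.g. 12.5–14.06 Hz) are included in every
band they intersect, so a small spectral sliver can be counted twice;
band energies are used only within-band, never summed across bands.

**Epoching.**  Each band signal is split into contiguous, non-overlapping
1-s epochs (200 samples); a 20-s segment yields exactly 20.  Lengths not
divisible by the epoch size are an error (no partial epochs), and
concatenation of the epochs reproduces the signal exactly.

## Features

**Fuzzy entropy** (complexity).  For an epoch of N samples,
`FE = ln φ^m − ln φ^(m+1)`, where φ^ℓ averages the pairwise similarities
`exp(−d^n / r)` of baseline-removed ℓ-length template vectors under the
Chebyshev distance.  Defaults m = 2, n = 2, r = 0.2·SD.

Conventions (configurable):

- `chen` (default): N−m template vectors for *both* φ^m and φ^(m+1), each
  vector's own mean removed.  Using the same vector count makes the two φ
  comparable and guarantees φ^(m+1) ≤ φ^m, hence FE ≥ 0.
- `paper_literal`: N−m+1 vectors for φ^m, N−m for φ^(m+1), whole-epoch mean
  removed (inert under Chebyshev distances but applied for fidelity).

The tolerance enters through the SD-normalized epoch: the kernel is
evaluated on `x / SD(x)` with `r = r_factor`.  For unit-SD signals this is
exactly the textbook definition with r = 0.2·SD, and it makes FE invariant
to positive rescaling of the epoch for *any* fuzzy power n.  (Plugging
r = 0.2·SD directly into `exp(−d^n/r)` is not scale invariant when n ≠ 1:
the kernel argument scales as c^(n−1).  Scale invariance is the property
that lets the laterality index ignore per-channel gain, so the normalized
form is the only self-consistent reading.)  The SD is the population SD
(divide by N), fixed so the brute-force oracle matches to 1e−10.  A
constant epoch returns FE = 0 by continuity — every distance is 0 and every
similarity 1 — without ever dividing by the zero SD.  `sd_scope: segment`
normalizes by the whole band signal's SD instead, trading epoch-wise scale
invariance for cross-epoch comparability.

The optimized path vectorizes the pairwise Chebyshev distances
(`scipy.spatial.distance.cdist`, ~0.6 ms per 200-sample epoch); an
independent pure-Python O(N²) enumeration lives in the test suite only.

**Energy** (strength).  `E = Σ y(s)²` over the epoch (µV²·samples); zero
iff the epoch is identically zero.  Both features are averaged over the 20
epochs of a segment to give per-(subject, channel, band, condition) values.

**Strength normalization.**  For presentation, energy is min-max normalized
to [0, 1] *within each (subject, condition) group* across the 8
channel×band cells.  This mirrors how normalized strength tables are
reported, but it is never fed into a laterality index: min-max with a
nonzero minimum destroys the ratio structure that makes LI_E
gain-invariant.  An all-equal group maps to 0.5 with a warning.  Because
the per-group extremes are pinned at exactly 0 and 1 for every subject,
paired tests on E_norm are degenerate, so the reporting layer tests
FE and raw E only.

## Laterality indices

`LI = scale·(Q_LH − Q_RH)/(Q_LH + Q_RH)` with scale = 1 by default.
Quantities must be nonnegative with a positive sum — a zero denominator is
an error, not a silent 0, so symmetry is never fabricated from empty
signals.  The ELI is the convex combination of per-quantity LIs; with one
pair and weight 1.0 it reduces *bit-identically* to LI (the implementation
literally multiplies by 1.0).  Weight vectors must lie in [0,1] and sum to
1 within 1e−12.  The λ-sweep `ELI(λ) = λ·LI_FE + (1−λ)·LI_E` is evaluated
on the inclusive grid 0:0.1:1 (11 points) by default; λ weights the
complexity index and 1−λ the strength index, so λ = 0 reproduces LI_E and
λ = 1 reproduces LI_FE.  No criterion for choosing λ is imposed — the
artifact exposes the sweep and the choice is the analyst's.

## Reporting layer

Summaries are mean ± sample SD (n−1).  Hypotheses are tested with
two-sided paired-samples t tests on per-subject averaged features — the
unit of analysis is the subject (n = cohort size), not the epoch, which
avoids pseudo-replication from the 20 correlated epochs per segment.
Axes: the 6 unordered band pairs per (channel, condition); C3 vs C4 per
(band, condition); normal vs OSA per (band, channel).  Degenerate cases:
identical samples give an undefined p (flagged, never significant);
zero-variance nonzero differences give t = ±∞, p = 0.  Significance is
annotated per cell at α = 0.05 with no correction by default, matching the
conventional table presentation; Holm's step-down correction is available
behind a config flag.

## Synthetic cohorts

Each subject's recording is broadband Gaussian noise (default SD 2 µV)
with one normal and one OSA segment summed in: per band, an
amplitude-scaled mixture `(1−c)·tone + c·band_noise`, where the tone sits
at the band midpoint (2, 5.5, 10.5, 22 Hz), the noise is white noise
FFT-masked to the exact band edges, and the mixture is normalized to unit
sample variance *before* amplitude scaling.  The normalization makes the
realized per-sample band variance exactly A², so the energy laterality has
the closed form `LI_E = (A_L² − A_R²)/(A_L² + A_R²)` — the generator emits
this as machine-checkable ground truth.  Default amplitudes (δ 40, θ 8,
α 20, β 15 µV) mimic the sleep-EEG strength hierarchy (δ strongest,
θ weakest).  A per-(subject, band) log-normal amplitude jitter (σ = 0.1)
adds between-subject variability; it is shared by both channels and both
conditions, so no laterality ground truth is perturbed.  All randomness
flows from one seed; identical specs are bit-identical.

**What the complexity knob can and cannot do.**  The mix parameter c moves
fuzzy entropy appreciably only in the β band (FE ≈ 0.71 at c = 0 vs 0.81
at c = 1 after decomposition).  In the narrow slow bands, band-limited
noise is locally as regular as the band-center tone at a 5 ms sampling
interval — FuzzyEn with m = 2 sees sample-scale irregularity, and a 1–3 Hz
process barely changes between samples — so δ/θ/α tone-vs-noise contrasts
are ≲ 0.02 and not reliably signed.  The monotonicity of FE in c is
therefore asserted (and exploited) in β only.  What *is* robust across all
bands is the complexity ordering δ < θ < α < β driven by band frequency
content, the ordering reported for real sleep EEG.

**Separation scenario.**  `make_eli_separation_scenario` builds a cohort
whose OSA segments carry left-dominant asymmetry in strength (C3 amplitude
×1.3 in every band) and/or complexity (C4 β mix dropped to 0), with normal
sleep symmetric.  Complexity is injected in β alone for the reason above,
and confining the spectral change to the topmost band keeps the slow
bands' spectra identical across channels — a tone-vs-noise difference in a
strong slow band would otherwise leak asymmetric energy into its weaker
neighbor's packets (δ→θ spill is ~3% of δ energy, comparable to θ's entire
energy) and contaminate LI_E.  On this scenario the β-band cohort-mean
ELI(OSA) exceeds ELI(normal) at every λ, while the strength-only variant
fails to separate at λ = 1 and the complexity-only variant at λ = 0 —
the qualitative argument for fusing both quantities, as a sign test.

**What passing does not show.**  The generator has stationary band
amplitudes, no sleep microstructure (spindles, K-complexes), no apnea
physiology (desaturation-coupled arousals), no artifacts beyond white
noise, and independent channels (no volume conduction).  Recovery of
injected asymmetries validates the pipeline's arithmetic and calibration,
not any clinical claim about apnea lateralization.

## Problem sizes and runtimes

Validation uses cohorts of 3–21 subjects: the bookkeeping check runs the
full 21-subject cohort (3360 epochs per condition), energy-laterality
recovery averages 20 four-subject cohorts, the separation scenarios run 21
subjects each, and the type-I calibration pools 416 null comparisons from
13 eight-subject cohorts (binomial 95% band at α = 0.05).  The complete
suite runs in about a minute on one core; fuzzy entropy dominates at
~0.6 ms per epoch.

## Known limitations

- EDF is read (via `mne`) but not written; synthetic cohorts are stored as
  CSV.  EDF+ annotation export is out of scope.
- Wavelet-packet band edges are nominal; packets straddling a printed edge
  are shared between bands (documented above).  The FIR backend gives
  hard-edged bands for sensitivity analysis.
- Fuzzy-entropy ground truth has no closed form; FE-based claims are
  validated qualitatively (orderings, sign tests), quantitatively only for
  energy.
- No artifact rejection beyond the 50 Hz low-pass, no re-referencing, no
  sleep staging: recordings are assumed pre-scored.
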