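# Methods

`nirsblock` analyses block-design continuous-wave fNIRS experiments of the
kind used to study fine motor control in virtual-reality training games:
dual-wavelength (760/850 nm) intensity recordings at 7.81 Hz over 30
source-detector channels (8 sources, 16 detectors, nominal 30 mm
separation) covering bilateral prefrontal cortex (PFC), premotor cortex
(PMC), supplementary motor area (SMA) and primary motor cortex (M1), while
subjects alternate 30 s gameplay blocks — with (wFC) and without (woFC) an
isometric pinch-force-control requirement at 70 ± 10% of maximum voluntary
contraction (MVC) — with 30 s rests. Because raw recordings from such
studies are rarely deposited, the package pairs the analysis chain with a
forward simulator so that every stage is validated by parameter recovery.

## Signal chain

1. **Channel pruning.** Channels whose raw intensity is too weak
   (mean < 1e-3 a.u.), saturated (mean > 1e7 a.u.) or unstable
   (SD/mean > 0.5) are masked, not deleted, keeping indexing aligned with
   the montage. The bounds are deliberately permissive — they catch dead
   channels, not subtle quality problems, which on real data require
   visual inspection.
2. **Optical density.** OD(t) = −ln(I(t)/Ī) per channel and wavelength,
   with Ī the trace's own temporal mean (natural-log convention; the
   extinction table is in matching natural-log units). All downstream
   quantities are therefore *changes* relative to the session mean.
3. **Wavelet motion correction.** Each OD trace is symmetrically padded,
   decomposed with a stationary (undecimated) Daubechies-2 transform to 4
   levels, and detail coefficients with |d| > 1.5 × IQR of their level are
   zeroed before reconstruction. This targets spikes and baseline steps;
   smooth hemodynamics and sinusoidal physiology pass through essentially
   unchanged (a pure tone's coefficient distribution has no tail beyond
   1.5 IQR). The `iqr_factor` trades aggressiveness against distortion.
4. **Band-pass.** Zero-phase (forward–backward) 3rd-order Butterworth,
   0.01–0.1 Hz, removing drift, Mayer waves (~0.1 Hz), respiration
   (~0.25 Hz) and cardiac pulsation (~1.1 Hz). The effective magnitude
   response is the square of the single-pass response; the measured gain
   is ~1.00 at 0.05 Hz and < 0.4% at 1.1 Hz.
5. **Modified Beer–Lambert.** Per sample and channel the 2×2 system
   ΔOD(λ) = ε(λ, chrom) · c · d · ppf is solved for (HbO, HbR), with the
   partial pathlength factor ppf = 1 and results reported as c·d·ppf in
   µM·mm — the natural unit when the true optical pathlength is unknown.
   The shipped extinction table is the standard hemoglobin compendium
   (base-10 values converted to natural-log 1/(µM·mm)); it is a versioned
   JSON file and can be swapped.

## Response estimation

The hemodynamic response to each condition is deconvolved by OLS with a
Gaussian basis: 41 Gaussians (SD 1 s, spacing 1 s) centred from −5 to 35 s
around block onset, one regressor per (condition, centre) formed by
summing the Gaussian over that condition's onsets. Rest is the implicit
baseline. Estimated curves are baseline-normalised (zero mean over −5..0 s)
and summarised per ROI as the mean over 10–35 s — the window where the
movement-evoked response plateaus — averaging unpruned channel curves
within the ROI first, then the window.

Two design choices matter numerically and were made after measuring their
effect on parameter recovery:

* **Drift basis.** Default is a discrete-cosine set with cutoff equal to
  the band-pass high-pass edge (0.01 Hz ≈ 100 s period), the fMRI
  convention. The band-pass removes the session-half envelope of the
  design (one condition occupies each half of the session); a low-order
  polynomial cannot absorb that removal and leaves a −2–3% bias on the
  second condition's amplitudes. A Legendre polynomial drift
  (`drift_basis="poly"`, order 3) is available for unfiltered,
  Homer-style fits.
* **Filter compensation.** Filtered data are missing exactly the
  component of the evoked signal that the filter removes — including
  ~4.5% of the 1/60 Hz block fundamental, which no drift basis can
  represent because it lives at the task frequency. The design therefore
  carries one nuisance column per condition: (I − F) applied to the
  condition's canonical block drive (double-gamma impulse response, peak
  6 s, undershoot 16 s, ratio 1/6, convolved with the block boxcars),
  where F is the same zero-phase filter. Its coefficient is discarded;
  curves are reconstructed from the task basis alone. Without this
  column the attenuation differs slightly between the first- and
  second-half conditions, leaving a systematic wFC−woFC offset
  (~+0.8 µM·mm under the null at default noise) that a paired test over
  12 subjects partially detects. Filtering the *regressors* instead is
  not an option: inside a 0.01–0.1 Hz band the 41 narrow Gaussians
  collapse to effective rank ≈ 10 per condition and the solve amplifies
  model mismatch catastrophically. The canonical drive assumes the
  double-gamma shape; on real data with atypical response shapes the
  compensation is approximate (it can be disabled via
  `GlmSpec(filter_compensation=False)`).

With both choices the zero-noise end-to-end bias of every ROI × condition
× chromophore amplitude is ≤ 1.3% (dominated by filter edge effects and
basis truncation beyond 35 s).

## Connectivity and network features

Per subject, condition and chromophore, Pearson correlations between the 8
ROI-averaged concentration series over the concatenated gameplay blocks of
that condition give an 8×8 matrix; Fisher z = atanh(r) with |r| clipped to
1 − 1e-7. Features over the 28 unique off-diagonal pairs: connection ratio
CR = fraction with |z| > 0.7, connection strength CS = mean |z|.
Zero-variance ROIs make their pairs undefined; undefined pairs leave both
numerator and denominator. Per-subject features feed the group tests;
group display matrices are the across-subject mean z back-transformed to r.
Whether to correlate continuous task-period series (default) or
trial-averaged response curves is an open choice in the field; the
functions accept any ROI-labelled series, so either can be supplied.

## Game metrics

Per gameplay loop: grasp count (fork pick-ups: one at loop start plus one
per force-window violation), pinch-force coefficient of variation (sample
SD with n−1 denominator over mean, using only samples while the fork is
held), and memory accuracy (correct feeds / total feeds). Subject scores
are means over loops.

## Group statistics

Mann-Whitney U for independent group comparisons (exact when combined
n ≤ 12 without ties, tie-corrected normal approximation with continuity
correction otherwise), Wilcoxon signed-rank for paired condition
comparisons (zeros dropped per Wilcoxon's original rule; exact for ≤ 15
nonzero untied differences), Spearman for score–response correlations; all
two-sided. Benjamini–Hochberg step-up at q = 0.05 within explicitly
declared families — one family per report table (e.g. the 8 ROI
comparisons of a group × chromophore table). Undefined tests (all-zero
differences, constant inputs) carry NaN p-values through reporting rather
than silently vanishing.

## The simulator

`simulate_recording` plants, per channel, ROI × condition amplitudes
(µM·mm) times the canonical block response, normalised so that the
baseline-corrected 10–35 s window mean of a single block equals exactly 1
— the amplitude parameter *is* the quantity the pipeline estimates. HbR
defaults to −HbO/3, the typical physiological ratio. Noise is added in OD
space per channel and wavelength: white sensor noise (SD 0.002), cardiac
(1.1 Hz, amp 0.010), respiratory (0.25 Hz, 0.005) and Mayer (0.1 Hz,
0.005) sinusoids with random phases, a random linear drift (±1e-5 OD/s),
and Poisson motion artifacts (0.5/min, exponential spikes of ~0.02 OD,
half leaving a baseline step). The clean concentrations go through the
same forward Beer–Lambert map the pipeline inverts and intensities are
I = exp(−OD) around unit baseline, keeping |ΔOD| ≪ 0.1 so the
log/exponential pair is well conditioned. Noise amplitudes were chosen
once to give single-subject ROI-mean errors of a few µM·mm on 40 µM·mm
responses — comparable to the standard errors in published group tables.
Between-subject variability is a lognormal gain (σ = 0.15, unit median)
multiplying all amplitudes of a subject; group-level tables report only
means and SEs, so this spread is a free, documented parameter rather than
a calibrated one.

The game simulator is an Ornstein-Uhlenbeck force trace around 70% MVC
(reversion 1/s, volatility 3.4 N/√s at 50 Hz); excursions beyond ±10% MVC
reset the fork and trigger a re-grasp after 0.5 s. The volatility default
was set once so the mean grasp count per loop (~5) matches the scale of
observed gameplay. Feeding errors are Bernoulli per item (default 0.2).

What the simulator does **not** emulate: wavelength-correlated physiology
(noise is independent per wavelength, so HbO/HbR crosstalk from systemic
signals is absent), superficial/scalp contamination, spatially correlated
noise across channels, subject motion coherent across the probe,
inter-trial response variability within a subject, and the full
grasp-release force dynamics (the simulated force COV only reflects hold
steadiness, so it is an order of magnitude smaller than COVs computed over
full grasp cycles on real force traces). Passing recovery tests therefore
demonstrates correctness of the computations under the stated generative
model, not robustness to everything real data can do.

## Validation experiments and problem sizes

`nirsblock.validation` packages three canned experiments, also re-run by
`scripts/acceptance.py`: a zero-noise end-to-end recovery run (one
subject), a detection study (50 replicates × 12 subjects, rM1 planted at
50 vs 25 µM·mm, paired Wilcoxon + BH over the 8-ROI HbO family), and a
null calibration (200 replicates × 12 subjects, equal amplitudes,
family-wise any-rejection rate; for the BH step-up under a global null
with independent p-values this equals the Simes level q = 0.05, slightly
conservative here because the n = 12 exact Wilcoxon p is discrete). The
replicate counts keep each experiment in the minutes range on one core
while leaving binomial standard errors of a few percent.

## Degenerate inputs and numerical conventions

Non-positive intensities, non-uniform time bases (> 1 ppm jitter),
overlapping events, unknown condition labels, all-pruned recordings,
singular extinction matrices (condition number > 1e12) and rank-deficient
designs raise descriptive errors. Fisher z clipping at |r| = 1 − 1e-7
bounds z at ~8.4. ROIs with all channels pruned are reported as missing
(NaN), never as zero. File round-trips preserve metadata exactly and data
to float precision (SNIRF bit-exact, CSV to 12 significant digits).

## Known limitations

The channel→ROI table of the default montage is a nominal reading of a
probe layout (the exact per-ROI channel counts are not enumerated in
text); it ships as a versioned JSON and is user-overridable. Optode
coordinates are informational. The filter-compensation column assumes a
canonical response shape. No short-separation regression or systemic
physiology modelling is included. Statistical families are a reporting
choice; alternative family definitions change adjusted p-values.
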