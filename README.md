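# nirsblock

Block-design fNIRS analysis for motor-control experiments, with a forward
simulator that makes every stage testable by parameter recovery.

The package targets studies in which subjects play a pinch-force-controlled
task in alternating 30 s gameplay/rest blocks — with (wFC) and without
(woFC) an isometric force-control requirement at 70 ± 10% of maximum
voluntary contraction — while a continuous-wave NIRS probe (760/850 nm,
7.81 Hz, 8 sources / 16 detectors / 30 channels) records over bilateral
prefrontal cortex, premotor cortex, supplementary motor area and primary
motor cortex. It implements the full chain from raw intensities to group
statistics:

* **Preprocessing** — channel pruning; optical density OD = −ln(I/Ī);
  stationary-wavelet motion correction (detail coefficients beyond
  1.5 × IQR zeroed); zero-phase Butterworth band-pass 0.01–0.1 Hz;
  modified Beer–Lambert inversion ΔOD(λ) = ε(λ,·)·c·d·ppf to HbO/HbR in
  µM·mm (ppf = 1).
* **Response estimation** — OLS deconvolution on a Gaussian basis (41
  Gaussians, SD 1 s, spacing 1 s, −5..35 s around onset), baseline
  normalisation over −5..0 s, and ROI block means over the 10–35 s window.
* **Connectivity** — 8×8 ROI Pearson/Fisher-z matrices per condition and
  chromophore; connection ratio CR = #{|z| > 0.7}/28 and connection
  strength CS = mean |z|.
* **Game metrics** — grasp count, pinch-force coefficient of variation
  (SD/mean), memory accuracy.
* **Group statistics** — Mann-Whitney U, Wilcoxon signed-rank, Spearman
  (exact small-sample branches), Benjamini–Hochberg FDR at q = 0.05 per
  table family, and report tables in the published layout.
* **Simulation** — a forward model planting known ROI amplitudes with
  physiological noise, drift, motion artifacts, and an
  Ornstein-Uhlenbeck pinch-force game model with known metric values.

The scientific model and the numerical choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a noiseless subject with a planted right-M1 HbO response of
50 µM·mm during wFC (40 µM·mm elsewhere, HbR = −HbO/3) and run the whole
chain (`examples/hrf_and_roi_means.py`):

```python
import nirsblock as nb

amp = nb.default_amplitudes(40.0)
amp.loc["rM1", "wFC"] = 50.0
truth = nb.SimulationTruth(amp_hbo=amp, noise=nb.NoiseSpec.silent(),
                           motion=nb.MotionSpec.none(), subject_gain_sd=0.0,
                           seed=1)
rec = nb.simulate_recording(nb.default_montage(), nb.default_paradigm(), truth)
ana = nb.analyze_subject(rec, nb.default_paradigm())
print(ana.roi_stats.mean_hbo.round(2))
```

prints the estimated ROI × condition HbO block means (µM·mm):

```
        wFC   woFC
lPFC  40.33  40.49
lPMC  40.33  40.49
lSMA  40.33  40.49
lM1   40.33  40.49
rPFC  40.33  40.49
rPMC  40.33  40.49
rSMA  40.33  40.49
rM1   50.43  40.51
```

Every planted amplitude is recovered within 1.3% through pruning, OD
conversion, wavelet correction, band-pass filtering, Beer–Lambert
inversion, GLM deconvolution and ROI windowing; the residual is filter
edge effect, not noise. Other scripts in `examples/` walk through
preprocessing against planted ground truth, connectivity features, game
scoring, and a full simulated two-group study with report tables.

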