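# hhtecg

Hilbert–Huang spectral features and a coupled classifier bank for multiclass
ECG arrhythmia recognition.

## The problem

Single-lead (MLII-style) ECG monitoring produces long, nonlinear and
non-stationary voltage series in which several arrhythmias — atrial premature
complexes (APC), atrial fibrillation (AFib), ventricular premature complexes
(VPC) and ventricular tachycardia (VT) — must be distinguished from normal
sinus rhythm (NSR).  Classical frequency-domain analysis (FFT/PSD) assumes
stationarity that arrhythmic ECG does not have.  This package implements a
recognition pipeline built on empirical mode decomposition (EMD) and the
Hilbert spectrum, which handle non-stationary signals natively, and is aimed
at signal-processing and machine-learning researchers who need a transparent,
fully testable reference implementation that runs without any external
database.

## The method

Each analysis frame (3 s at 360 Hz, long enough to contain a complete
symptomatic waveform) is processed as:

1. **Noise filtering** — 5th-order low-pass Butterworth at 16 Hz, applied
   forward–backward (zero phase, magnitude response squared).
2. **EMD** — sifting with cubic-spline envelopes through the local extrema
   decomposes the frame into intrinsic mode functions (IMFs) `s_j(t)` plus a
   monotonic residue `r(t)`, with `x(t) = Σ_j s_j(t) + r(t)` exact.  An IMF
   satisfies |#extrema − #zero-crossings| ≤ 1 and has near-zero envelope mean.
3. **Hilbert spectrum** — the analytic signal of each IMF gives instantaneous
   amplitude `a_j(t)` and frequency `ω_j(t)`; `H(ω, t) = a_j(t)` at
   `ω = ω_j(t)`, 0 otherwise.
4. **Marginal Hilbert spectrum** — `MHS(ω) = ∫ H(ω, t) dt`, the energy per
   frequency over the frame.
5. **Centroid features** — for each of the first three IMFs, the MHS-area
   centroid `(x̄, ȳ)` with `x̄ = Σ ω·MHS(ω) / Σ MHS(ω)` (mean frequency, Hz)
   and `ȳ = Σ MHS(ω) / T` (energy per second, "power"), forming a
   6-dimensional feature vector per frame.

Recognition couples four classifiers — a multilayer perceptron (one hidden
layer of 10 units), a boosted tree ensemble (100 cycles, 10-node trees), a
support vector machine (linear kernel, Platt-calibrated posteriors) and
Gaussian naive Bayes — under one-versus-one coding: `C(k, 2)` binary learners
whose pairwise posteriors are averaged into class scores summing to one.
Evaluation reports accuracy `(TP+TN)/(TP+FN+FP+TN)`, sensitivity
`TP/(TP+FN)`, specificity `1 − FP/(FP+TN)`, and trapezoid AUC over all ROC
cut-points, per symptom pair and per one-versus-rest class, with stratified
5-fold cross-validation.

Because annotated corpora are unbalanced and scarce, the package ships a
Gaussian feature simulator parameterized by the published per-class (μ, σ) of
the six features, and a template-based waveform generator for all five rhythm
classes, so the entire pipeline — featuring, training, scanning — runs and is
tested end to end with no downloads.

## Worked example

`examples/04_scan_record.py` trains a naive Bayes model on sliding-window
features of synthetic NSR and VT records and screens a fresh VT record with
3-s frames overlapping by 1 s:

```
scanned sim_vt_41: 14 frames

start_s  end_s  label  name
    0.0    3.0  5      VT
    2.0    5.0  5      VT
    ...
   26.0   29.0  5      VT

fraction of frames labelled VT: 1.00
```

Each row is one frame of the traceable annotation track: all 14 frames of the
ventricular-tachycardia record are recognized as class 5 (VT).
`examples/02_decompose_frame.py` shows the featuring stage on one normal
frame — mode centroid frequencies fall with mode order (8.09, 3.40, 0.98 Hz),
as expected since IMF1 carries the fastest oscillations (QRS complexes).
The other examples cover the feature simulator and the full pattern-pair
evaluation table.

The same workflow is available from the shell:

```bash
hhtecg simulate --per-class 1000 --seed 1 --out feat_sim.csv
hhtecg simulate-ecg --symptom 5 --duration 30 --seed 2 --out rec.csv
hhtecg train --method nb --in feat_sim.csv --out model.bin
hhtecg scan --record rec.csv --model model.bin --out trace.csv --plot
```

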