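# streambci

Analysis pipeline for a 3-class auditory brain–computer interface based on
**auditory stream segregation**: three interleaved musical-tone oddball
sequences (stimulus onset asynchrony 180 ms, deviant probability 0.1) are
perceived as three separate streams, and the listener's selective attention
to one stream is decoded from 64-channel EEG via the P300 evoked by attended
deviants.

The package is aimed at EEG/BCI researchers who want a tested, reusable
implementation of the full decoding chain, exercised end-to-end on a
synthetic EEG generator so that every stage is verifiable without access to
recordings.

## What it computes

1. **Stimulus model** — cyclically interleaved oddball streams; each
   stream's tone in each 540 ms cycle is a deviant with probability 0.1.
2. **Preprocessing** — zero-phase 2nd-order Butterworth bandpass (0.1–40 Hz
   for ERP averaging, 1–40 Hz for classification), epochs −100–500 ms with
   −50–0 ms baseline, rejection of epochs exceeding ±100 µV (EEG) or
   ±500 µV (EOG).
3. **ERP statistics** — condition averages and a pointwise two-sample
   Student's *t*-test (p < 0.01, uncorrected) between attended-deviant and
   concatenated nonattended-deviant responses.
4. **xDAWN spatial filtering** — per class (attended / nonattended), filters
   **u** maximizing the signal-to-signal-plus-noise ratio
   ρ(**u**) = (**u**ᵀΣ₁**u**)/(**u**ᵀΣₓ**u**) with Σ₁ = P₁ᵀD₁ᵀD₁P₁ and
   Σₓ = XᵀX, where P₁ is the least-squares evoked estimate from the Toeplitz
   design D₁ (overlap-aware); top 3 components per class.
5. **Riemannian classification** — super-trials X̃ᵢ = [P₁; Xᵢ], sample
   covariances Σ̃ᵢ = X̃ᵢX̃ᵢᵀ/(N−1), affine-invariant distance
   δ_R(Σ₁,Σ₂) = ‖log λ(Σ₁⁻¹Σ₂)‖₂, Fréchet mean, tangent-space vectorization
   vᵢ = upper(Σ_G^{−1/2} Log_{Σ_G}(Σ̃ᵢ) Σ_G^{−1/2}), logistic regression
   (or minimum-distance-to-mean as an alternative).
6. **Evaluation** — one binary "stream *n* attended" classifier per stream
   on the deviant-D_n epochs, stratified 10-fold cross-validation with all
   transforms refit per training fold, accuracy / Matthews correlation
   coefficient / averaged confusion matrices, and the Wolpaw information
   transfer rate.

## Worked example

Simulate a reduced synthetic session (1 block × 3 runs of 120 s) and decode
which stream was attended in each run:

```python
from streambci.evaluation import itr, report_table, format_report
from streambci.pipeline import SyntheticStudyConfig, simulate_and_decode

cfg = SyntheticStudyConfig(blocks=1, run_duration=120.0)
results = simulate_and_decode(seed=42, config=cfg, n_folds=5)
for s, r in results.items():
    print(f"stream {s}: {r.n_epochs} epochs, accuracy {r.accuracy:.2f}, MCC {r.mcc:.2f}")
print(format_report(report_table({"synthetic-01": results})))
rep = itr(3, 0.79, 7.42)
print(f"{rep.bits_per_selection:.4f} bits/selection, {rep.bits_per_min:.2f} bits/min")
```

prints

```
stream 1: 70 epochs, accuracy 1.00, MCC 1.00
stream 2: 50 epochs, accuracy 0.98, MCC 0.95
stream 3: 69 epochs, accuracy 0.99, MCC 0.97

              Stream 1      Stream 2      Stream 3       Average
              Accuracy  MCC Accuracy  MCC Accuracy  MCC Accuracy  MCC
synthetic-01      1.00 1.00     0.98 0.95     0.99 0.97     0.99 0.98
Grand Average     1.00 1.00     0.98 0.95     0.99 0.97     0.99 0.98

0.6335 bits/selection, 5.12 bits/min
```

Each row is one synthetic "subject"; accuracy is the cross-validated rate
of correctly deciding whether the given stream was the attended one, and
MCC the balanced version of the same decision (0 = chance, 1 = perfect).
The last line is the information transfer rate of a 3-class selection at
79 % accuracy once every 7.42 s.

A command-line interface mirrors the library
(`streambci simulate|preprocess|evaluate|itr --help`).

## Layout

- `src/streambci/synthetic_data.py` — stimulus sequences, ERP templates, EEG simulator
- `src/streambci/io_formats.py` — canonical HDF5 container, events CSV, BrainVision I/O
- `src/streambci/preprocessing.py` — filtering, epoching, artifact rejection
- `src/streambci/erp_stats.py` — condition averages, significance masks
- `src/streambci/xdawn.py` — SSNR-maximizing spatial filters
- `src/streambci/riemann.py` — SPD-manifold machinery (distance, mean, tangent space, MDM)
- `src/streambci/evaluation.py` — cross-validation, MCC, confusion matrices, ITR
- `src/streambci/pipeline.py` — session-level orchestration
- `docs/methods.md` — model, parameters, numerical choices, limitations
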