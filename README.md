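# wavemi

Decoding left- vs right-hand **motor imagery** from three-channel EEG
(electrodes C3, Cz, C4) with continuous-wavelet time-frequency images and a
shallow convolutional network, plus quantification of the
**event-related desynchronization (ERD)** signature those images encode.

Imagining a hand movement suppresses the sensorimotor **mu (8–13 Hz)** and
**beta (13–30 Hz)** rhythms over the contralateral motor cortex (left-hand
imagery quiets C4, right-hand imagery quiets C3). wavemi turns that
physiology into a classifier in three steps:

1. **Continuous wavelet transform.** Each channel's 2 s imagery interval is
   transformed with

   `CWT(ω, s) = (1/|s|) ∫ x(t) ψ((t − ω)/s) dt`

   using one of three mother wavelets: **Morlet**
   `ψ(t) = e^{2πit} e^{−t²/2σ²}`, **Mexican hat**
   `ψ(t) = (1 − t²/σ²) e^{−t²/2σ²}`, or the band-limited **Bump** wavelet,
   defined in the Fourier domain as
   `ψ̂(sw) = exp(1 − 1/(1 − (sw−μ)²/σ²))` on `[μ−σ, μ+σ]` and exactly zero
   elsewhere. The scale–frequency map is `s = f_c / f` with `f_c` the
   wavelet's peak frequency.
2. **Image construction.** Mu- and beta-band scalograms of the three
   electrodes are cropped to the quietest 0.5 s window (minimum summed
   mu power), resized with cubic splines (mu → 15 rows, beta → 16 rows,
   time → 32 columns) and stacked into a **93 × 32** image
   (3 electrodes × 31 rows); a mu-only variant keeps the native 26
   frequency rows per electrode (**78 × 32**). Images are min–max
   normalized to [0, 1] per trial.
3. **Shallow 1D-kernel CNN.** 30 kernels of size 93 × 3 span the whole
   frequency/electrode axis and slide only along time (stride 1) →
   30 feature maps of length 30 → ReLU → max-pool by 10 → 90 features →
   fully connected 2-class softmax. Training is seeded mini-batch gradient
   descent on cross-entropy, with analytically derived gradients.

The ERD statistic itself is `ERD/ERS(%) = 100·(P(j) − P_ref)/P_ref`, where
`P(j)` is the trial-averaged squared band-pass-filtered signal and `P_ref`
its mean over a pre-cue reference interval.

A **synthetic EEG generator** (mu/beta oscillators with controllable
contralateral amplitude attenuation over 1/f background noise) provides
labeled data with known ground truth, so the whole chain is testable
offline: an amplitude attenuation `a` must be recovered as a
`100·(a² − 1)` percent power change, and datasets with a built-in effect
must be decodable far above chance.

## Worked example

```bash
python examples/01_simulate_and_quantify_erd.py
```

```
analytic ground truth: {'contralateral': -75.0, 'ipsilateral': 0.0, 'Cz': 0.0}

recovered mu-band ERD over the central task interval (3.75-5.25 s):
  C3:   +0.00 %
  Cz:   +0.00 %
  C4:  -75.10 %
```

Fifty noise-free left-hand trials are simulated with the contralateral
amplitude halved during imagery; the ERD pipeline recovers the implied
−75 % mu-power change on C4 to within 0.1 percentage points while the
other channels stay flat. The other examples build the wavelet images
(`02`), train the CNN (`03`), and run repeated k-fold cross-validation
(`04`); on a synthetic set with attenuation 0.3 and moderate noise the
CV accuracy reaches 100 % against a 50 % chance level.

A thin CLI mirrors the stages:

```bash
wavemi simulate --n-trials 100 --seed 1 --out epochs.h5
wavemi transform --wavelet morlet --variant dual --in epochs.h5 --out images.h5
wavemi erd --band mu --in epochs.h5 --out erd.tsv
wavemi evaluate --k 10 --reps 10 --in epochs.h5 --report-out report.csv
wavemi run --out-dir results/   # full pipeline with defaults
```

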