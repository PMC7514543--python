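# Methods

## Signal model of the synthetic generator

Each trial is 8 s of three-channel EEG at 250 Hz (configurable), cue at
3 s, imagery analysed 0.5–2.5 s after the cue. Per channel the signal is

    x(t) = A_mu · e(t) · sin(2π f_mu t + φ1) + A_beta · e(t) · sin(2π f_beta t + φ2) + n(t)

with f_mu = 10 Hz, f_beta = 20 Hz, A_mu = 1, A_beta = 0.5 (arbitrary
units), phases drawn per channel from the seeded generator, and n(t)
Gaussian noise with a 1/f power spectrum scaled to standard deviation
`noise_sigma` (default 0.5). The envelope e(t) is 1 at baseline, drops to
the attenuation factor `a` during the task window on the channel
contralateral to the imagined hand (C4 for left, C3 for right), and rises
to `ers_rebound` afterwards; Cz receives a fraction `cz_mix` (default
0.25) of the lateralized effect. Transitions use 0.1 s cosine ramps — a
step modulation would splatter broadband energy into the beta band.
Defaults `a = 0.5` and `ers_rebound = 1` reflect that a clear ERD and no
marked mu-band ERS is the typical cued-imagery picture; the recovery
tests and the decoding study set `a` explicitly (0.5 and 0.3).

Because power scales with amplitude squared, the generator's analytic
ground truth is ERD% = 100·(a² − 1) contralaterally, 0 ipsilaterally.

What the generator does **not** emulate: volume conduction between
electrodes, ocular/muscular artifacts, non-stationary background spectra,
inter-subject and inter-trial variability of ERD depth and latency, or
phase coupling between bands. Passing tests therefore demonstrate that
the pipeline is correct and sensitive under the stated signal model, not
that any particular accuracy is attainable on recorded data.

## Continuous wavelet transform

The forward transform is taken literally from its defining integral:
normalization 1/|s| (not the more common 1/√|s|) and an unconjugated
kernel. For real signals both choices leave coefficient magnitudes —
which is all the scalogram stores — unchanged; complex coefficients are
retained on request for the inverse transform. Scale maps to frequency
through the wavelet peak frequency: Morlet f_c = 1 Hz at scale 1 (its
e^{2πit} carrier), Mexican hat f_c = √2/(2πσ), Bump f_c = μ/(2π).

Defaults: Morlet σ = 1 s, Mexican hat σ = 1, Bump μ = 5, σ = 0.6 (a
common pairing). All are configurable and recorded in artifact metadata.

Implementation: Morlet and Mexican hat rows are FFT convolutions of the
closed-form time kernel, truncated where the Gaussian envelope falls
below ~1e−14 of its peak (8σ per scale). The Bump wavelet is evaluated
natively in the spectral domain where it is defined; its time kernel
(needed only by the oracle) comes from trapezoid quadrature of the
inverse Fourier integral over the compact support, where the integrand's
vanishing endpoint derivatives make the rule spectrally accurate. The
signal is mirror-padded by one kernel support before convolution so the
0.5 s window selection downstream is not biased by wrap-around
transients. `cwt_oracle` recomputes single rows by a direct Riemann sum
(explicit dot product per shift) under identical boundary assumptions;
the fast path agrees with it to ~1e−10 relative, against a 1e−6 bound.

The inverse uses the discretized single-integral (delta) reconstruction:
complex coefficients summed over log-spaced scales with d(ln s) weights,
divided by K = ∫ψ̂(v)/v dv computed numerically. It recovers band-limited
signals with correlation > 0.95; exactness is not a goal.

## Image construction

Analysis grids: mu = 8.0–13.0 Hz in 0.2 Hz steps (26 bins), beta =
13–30 Hz in 37 linear bins, chosen to reproduce the 26×500 / 37×500 band
scalograms of a 2 s, 250 Hz interval. The quietest 0.5 s window is found
by an exhaustive stride-1 scan minimizing mu-band magnitude summed over
frequencies and electrodes (ties to the earliest start); beta reuses the
mu-selected window. Choosing the *minimum*-power window samples the
deepest ERD, which is the most class-informative segment. Both bands are
resized by separable not-a-knot cubic splines; the 15 + 16 row split is
the near-equal division of the printed 31-row electrode block, beta
keeping the extra row as the wider band. Stacking order is C3, Cz, C4
top-to-bottom, mu above beta, frequencies ascending — fixed and recorded
per row in `row_map`. Min–max normalization to [0, 1] is strictly
trial-local, so no statistics leak across cross-validation folds.
Magnitude (not squared magnitude) fills the image by default; a `power`
switch is provided.

## ERD/ERS quantification

Band-pass filtering uses a zero-phase forward–backward 4th-order
Butterworth (zero phase preserves ERD latency). The reference interval
defaults to the 1 s ending 0.5 s before the cue; trial-averaged power is
smoothed with a 0.25 s moving average before the percent change is
formed. Recovery tests average the curve over the central 1.5 s of the
task window (3.75–5.25 s) to stay clear of the modulation ramps.

## CNN and training

Softmax cross-entropy was chosen as the two-class loss; the optimizer is
plain seeded mini-batch gradient descent (learning rate 0.01, batch 50,
300 epochs by default), weights initialized zero-mean uniform scaled by
1/√fan-in. Convolution is implemented as correlation (no kernel flip),
the CNN convention. The kernel height binds to the input image height at
build time, so the mu-only variant gets 78-tall kernels automatically.
Max-pooling drops the trailing remainder (no padding); prediction ties
break toward class index 0 ('left'). All gradients are derived by hand
and checked against central finite differences (max relative error
~5e−10, bound 1e−4).

## Evaluation protocol

Default: 10 repetitions of stratified 10-fold cross-validation → 100
splits, each with a freshly initialized, freshly seeded CNN;
stratification guarantees both classes in every training fold. A
`shuffle` mode with independent 90/10 stratified splits is available as
the alternative reading of "repeated ten times". The reported std is the
population standard deviation over split accuracies. The acceptance
study uses 100 trials and 50 training epochs — enough for the separable
synthetic conditions to converge while keeping the full 100-split
protocol cheap; the label-permutation null uses 2 repetitions (20
splits), which bounds its standard error near 2 points, sufficient for a
±10 chance-level check.

## Numerical notes and edge cases

- Degenerate constant images normalize to all zeros with a warning.
- A frequency grid sparser than ~2 voices per octave triggers a
  reconstruction warning (not an error) in the inverse CWT.
- Frequencies above Nyquist, empty band selections, windows longer than
  the series, single-class training sets and non-finite inputs raise
  labeled `ValueError`s at the boundary they violate.
- Band extraction tolerates 1e−6 Hz of float fuzz at band edges so
  grids built by `linspace` include their nominal endpoints.
- HDF5 artifacts are written with `track_times=False`; identical inputs
  produce byte-identical files.

## Known limitations

- The headline accuracies reported for the public BCI competition
  recordings are out of scope here; they require those datasets, whose
  ingestion (`read_epochs(..., format='edf_gdf')`) is provided as an
  optional extra and not exercised by the test suite.
- The synthetic decoding task is easier than recorded EEG: with a clear
  built-in ERD the CV accuracy saturates at 100 %. The chance-level null
  and the ERD recovery bounds are the informative checks.
- Only the C3/Cz/C4 montage and two classes are supported, by design.
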