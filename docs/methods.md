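# Methods

This note documents the models, parameter choices and numerical conventions
behind `corrbci`, and what the synthetic-data experiments do and do not
demonstrate.

## Pipeline order

Stages run in a fixed order per modality:

1. baseline correction (per-channel mean subtraction),
2. Butterworth band-pass (EEG 1-25 Hz, fNIRS optical density 0.01-0.2 Hz;
   order 4),
3. modified Beer-Lambert conversion (fNIRS only; the HbO plane is carried
   forward),
4. per-channel z-normalization (population standard deviation),
5. window-average downsizing (0.096 s non-overlapping blocks),
6. correlation-based channel selection on the concatenated task epochs,
7. per-trial hemisphere-averaged feature extraction,
8. min-max feature normalization and set enumeration,
9. stratified 10-fold cross-validated classification.

Two orderings here were genuinely open and are package decisions: the
normalization step precedes downsizing, and downsizing precedes channel
selection (so correlation and features see the same ~10.4 Hz streams). A
causal (single-pass) filter variant is available (`zero_phase=False`); the
default is forward-backward filtering so trial epochs are not phase-shifted,
at the cost of the effective magnitude response being the squared
single-pass response.

## Channel selection

Within each hemisphere group the pairwise Pearson correlation matrix is
computed over the concatenation of all non-rest task windows. Channel score
is the mean **absolute** off-diagonal correlation; absolute value is used so
strong anticorrelation counts as association, consistent with the
conventional strength-of-association bins (|rho| in [0.1, 0.3) small,
[0.3, 0.5) medium, [0.5, 1.0] large; below 0.1 we label "negligible" — the
conventional table leaves that gap open). A signed-mean variant is exposed
(`score="signed"`). Ties are broken by ascending channel position for
determinism. Which "two intervals" the correlation should compare is not
pinned down by the method's original description; correlating channels over
the task-epoch concatenation is this package's documented reading.

Defaults keep k=3 EEG channels per hemisphere (6 of 21) and k=5 fNIRS
channels per hemisphere (10 of 34); both fully configurable.

## Modified Beer-Lambert law

`dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * d * DPF(lambda)`
is solved exactly as a 2x2 linear system per channel and sample. Default
constants (overridable): molar extinction coefficients in 1/(mM cm) —
760 nm: eps_HbO 0.1496, eps_HbR 0.3865; 850 nm: eps_HbO 0.2526, eps_HbR
0.1798 — source-detector separation d = 3.4 cm, and DPF = 6.0 at both
wavelengths. Concentration outputs are in mM. A singular extinction matrix
(proportional rows) is rejected at construction.

## Features and classification

The four statistics use population (1/N) moments: mean M; signed maximum P;
skewness SK = E[((X-mu)/sigma)^3]; kurtosis KR = E[((X-mu)/sigma)^4]
(non-excess; Gaussian data -> 3). Features are computed on each trial's task
window, on the spatial average of the selected channels of each hemisphere
(2 series per modality per trial; a pooled single-average option exists), so
a "two-feature" set carries 2 features x 2 hemispheres = 4 columns per
modality. Min-max normalization is fit on the full feature table before
cross-validation by default, mirroring the upstream protocol; this leaks
the column extrema across folds, so a fold-safe option
(`normalize_within_folds=True`) is provided and recorded in results.

Classifiers: kNN (Euclidean, majority vote, k=5 default), decision tree
(Gini, unlimited depth), and LDA for the two-class rest-vs-movement
protocol. Folds are stratified by class when every class has at least k
members, otherwise plain shuffled folds; all splits are seeded. Accuracy is
plain percent correct, averaged over folds; confusion matrices are summed
across folds.

## Synthetic sessions

The generator emulates the block design of a cued motor-task experiment:
each trial is 6 s rest + 6 s task; five classes (left/right hand, left/right
arm, rest) are balanced and seed-shuffled; the default session is one hour
(60 trials per class). Channels are split into hemisphere groups (21 lateral
10-20 EEG electrodes, 11 left / 10 right; 34 fNIRS channels, 17/17).

Planted channels (3 per hemisphere EEG, 5 per hemisphere fNIRS by default)
carry a lateralized response: left-hemisphere channels respond to
right-sided classes and vice versa. Classes are additionally coded by
temporal activation profile: hand gripping is sustained over the full 6 s
window (gain 1.0), an arm raise is modelled as a brief transient covering
the first third of the window at gain 0.8. The profile difference is what
makes the four movement classes mutually distinguishable in
hemisphere-averaged features: purely amplitude-coded classes cannot be
separated reliably at any SNR because the per-trial carrier energy is
itself random (multiplicative noise), whereas profile differences shift the
scale-free shape statistics (SK, KR) and the M/P balance.

- **EEG**: each hemisphere has one shared mu-band source (white noise
  band-passed to 8-12 Hz, unit variance); planted channels add
  `snr * envelope(t) * source(t)` on top of unit-variance white channel
  noise. `snr` is the amplitude ratio of the task component to the noise
  standard deviation during active windows.
- **fNIRS**: per hemisphere, the per-class activation boxcar is convolved
  with a canonical double-gamma hemodynamic response (difference of
  unit-scale gamma densities with modes at 6 s and 16 s, undershoot ratio
  1/6), normalized to unit RMS over its active windows and scaled by
  `snr * sigma_noise` (sigma = 1 uM). HbR mirrors HbO with ratio -0.3.
  Channel noise is white (1 uM) plus a slow sinusoidal drift per channel
  with frequency drawn from 0.003-0.015 Hz (vasomotor band) and random
  phase, amplitude 2 sigma. Per-channel drift frequencies keep noise
  channels mutually uncorrelated; a single session-wide drift frequency
  would correlate every channel pair (equal-frequency sinusoids correlate
  as the cosine of their phase difference) and make correlation ranking
  meaningless by construction.
- Concentrations (signal + noise + drift) are emitted as optical density at
  760/850 nm through the same forward Beer-Lambert relation the
  preprocessing inverts, so `mbll_convert` recovers the injected HbO/HbR
  series to numerical precision — this round trip is asserted in tests.

What the generator does **not** model: volume conduction and realistic EEG
forward physics, EOG/EMG artifacts, raw (pre-dOD) light intensities,
subject heterogeneity, non-stationary noise. Passing tests therefore show
that the pipeline recovers the structure this model plants — not that it
would reach the same numbers on human recordings.

Two emergent properties of the model are worth knowing when reading
results. First, with a 6 s task and a hemodynamic response peaking ~6-9 s
after onset, the fNIRS response to trial *i* peaks during trial *i+1*'s
windows; fNIRS features are therefore contaminated by the previous trial's
class, which caps fNIRS-only accuracy well below EEG at high SNR (the
rest-vs-movement LDA protocol, with longer effective separation, is much
cleaner). Second, the 0.096 s window averaging nearly cancels a ~10.4 Hz
oscillation (one block ~ one mu period), so only the low edge of the mu
band survives downsizing for EEG features — the faithful cost of the
rate-parity step.

## Problem sizes and tolerances

Tests and the acceptance script use 30-trials-per-class sessions (36 min) as
a scaled-down version of the one-hour default, and 12- or 3-trials-per-class
sessions for unit-level checks. Oracle agreement tolerances: 1e-12 for the
correlation core, 1e-10 relative for the Beer-Lambert round trip, 2% for
measured vs analytic filter passband gain, 2-5% for Monte-Carlo moment
checks. "High SNR" in classification sanity checks means snr=10; planted
recovery is checked at snr=2. Degenerate inputs (constant channels,
singular extinction, empty selections, windows outside the recording,
classes missing from a training fold) raise informative errors rather than
propagating NaNs.
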