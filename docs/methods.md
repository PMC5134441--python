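# Methods

## Problem and pipeline

The package classifies user intent — steady, grasp or release — from
multi-channel surface EMG, epoch by epoch, under an online constraint:
no decision may use future signal. The pipeline is

1. **Conditioning** — causal 6th-order Butterworth band-pass
   (10–450 Hz, implemented as a 3-pole-pair design so the total
   band-pass order is 6), optional second-order 60 Hz IIR notch
   (Q = 30), per-channel mean subtraction, full-wave rectification.
   All filters are forward-pass only; zero-phase filtering was rejected
   because it consumes future samples. Filters start from zero state,
   so tests discard a warm-up segment before measuring gains.
2. **Epoching** — 125 ms sliding windows with 100 ms overlap (25 ms
   hop). Trailing samples that do not fill a window are discarded.
3. **Features** — per channel and epoch: integrated absolute value
   (IAV), waveform length (WFL), variance (VAR, population normalizer),
   slope-sign changes (SSC), zero crossings (ZC), Wilson amplitude
   (WAMP, 5 mV threshold), three equal frequency bins over 10–450 Hz
   from a single unwindowed periodogram, and three amplitude-bin counts
   (0.66 V bins centered as a block on 0 V, edges ±0.33/±0.99 V,
   half-open on the right). ZC/SSC (and the spectral features) are
   computed on the centered *signed* signal — a rectified signal has no
   zero crossings, so the standard definitions require the signed
   waveform; rectification only matters for IAV, which is already an
   absolute-value sum. ZC/SSC count strict sign changes with exact
   zeros skipped, no hysteresis.
4. **Screening** — for every ordered pair of candidate features, the
   later-listed one is dropped when squared Pearson correlation exceeds
   0.9 on *every* channel. Zero-variance columns have undefined
   correlation and never trigger removal. The screen is fit on training
   folds only and the kept-feature list is frozen into the model. On
   both real and realistic synthetic data this removes VAR (amplitude-
   redundant with IAV), taking 7 × 12 = 84 dimensions to 77; the bigram
   variant (current ‖ previous epoch, first epoch self-duplicated so
   sequences keep their length) doubles this to 154.
5. **Labels** — per movement with kinematic times (t_g, t_r): release
   is the half-open interval [max(t_r − L, t_g), t_r) with
   L = 500 ms by default (truncated at t_g for short movements), grasp
   is [t_g − 500 ms, release start), everything else steady. An epoch
   takes the label of the interval containing its temporal center;
   the center rule with half-open intervals makes every epoch's label
   unique and boundary behavior well defined. The grasp lead stays at
   500 ms even when the release length is swept.
6. **Classifiers** — per-class Gaussian mixtures (EM, k-means++
   seeding, single initialization, tol 1e-6 relative log-likelihood,
   max 500 iterations, 0.05 added to every covariance diagonal at each
   M-step). The GMM classifier is the per-epoch maximum-likelihood
   label. The HMM uses those mixtures as emissions, a uniform initial
   distribution (the user may start in any state), and a transition
   matrix from pooled training-label bigram counts with Laplace
   pseudocount α = 1 (rows never cross trial boundaries; unvisited
   states fall back to uniform rows). Decoding is the forward
   recursion in the log domain; each epoch is labeled by the argmax of
   its normalized filtered posterior, not Viterbi, matching the
   epoch-by-epoch online framing. Ties everywhere break toward the
   fixed state order steady < grasp < release.
7. **Voting** — with n > 0 the output carries its previous label until
   the current and previous n raw labels unanimously agree on a
   different one; the first n epochs pass through unchanged.
8. **Evaluation** — trial-level K-fold cross-validation (default
   K = 10; folds are whole trials, so screening, EM and transition
   counts never see test epochs). Accuracy is pooled epoch accuracy per
   fold; mean and SD over folds are reported with per-trial accuracies
   for inspection. Confusion matrices are row-normalized percents with
   kinematic truth on rows; precision/recall/F are conventional, with
   undefined scores reported as NaN rather than zero. Sensitivity axes:
   mixture components 1–15, unigram/bigram, GMM/HMM, epoch length
   50–500 ms (overlap held at 80 % of the window), release-label length
   200–600 ms, voting depth 0–5.

## Synthetic study generator

Real recordings for this task are not publicly available, so
`semgrasp.simulate` generates trials with the statistical structure the
classifiers rely on. Surface EMG is modeled as amplitude-modulated
band-limited Gaussian noise — a standard second-order phenomenology —
rather than motor-unit simulation.

* **Sources and mixing.** Three sources: a flexor-like source
  (20–100 Hz carrier), an extensor-like source (120–350 Hz) and a
  broadband floor (10–450 Hz). Seven channels sit at equal angles
  around the forearm; flexor/extensor weights are Gaussian bumps of the
  angular distance to the source (spread 65°), the floor couples
  evenly. Electrode-band displacement is emulated by rotating the bump
  geometry (cw/ccw, ±14° ≈ 1 cm on a 25.7 cm forearm) or tilting
  per-source gains (up/down); datasets cycle the five placements.
* **Envelopes.** The flexor envelope rises 300 ms *before* the
  kinematic grasp stamp (anticipatory pre-shaping), holds through
  transport with ±15 % slow multiplicative jitter, and decays after
  release. The extensor keeps a weak stabilizing tone during transport
  and bursts briefly around the release stamp. Release activation is
  deliberately shorter and weaker than grasp activation, so the
  class imbalance and the difficulty of detecting release emerge in the
  synthetic study as they do physiologically.
* **Scales.** Active peaks reach roughly 0.5–1 V and the floor is
  0.04 V RMS, so both the 5 mV Wilson threshold and the ±0.33 V
  amplitude-bin edges discriminate. Source band separation makes
  spectral features carry state information beyond raw amplitude; the
  continuous envelope modulation gives IAV and VAR the tight quadratic
  relationship (R² > 0.9 on every channel) that the screening step is
  designed to catch, while keeping other feature pairs below the
  cutoff on at least one channel. This correlation structure was
  verified across independent seeds at the default dataset size
  (20 trials) before the defaults were frozen.
* **Determinism.** A trial is a pure function of (config, seed);
  datasets derive per-trial seeds from one master seed, so everything
  from signal samples to CV folds reproduces bit-identically.

What the generator does **not** emulate: inter-subject physiological
variability, electrode-skin impedance drift, motion artifacts, object
contact transients, fatigue, or pre-shaping motions mislabeled as
steady. Passing tests therefore demonstrate correctness of the
machinery and qualitative behavior (anticipation, release difficulty,
shift robustness), not expected accuracy on laboratory recordings.

## Numerical choices

* Mixture densities and the forward recursion run entirely in the log
  domain (log-sum-exp); filtered posteriors are renormalized every epoch, so
  only relative emission likelihoods matter and underflow cannot zero
  out all states.
* EM with a covariance floor: adding 0.05 to each covariance diagonal
  after the M-step means the M-step maximizes a floored objective, so
  the *raw* log-likelihood path may dip by ~1e-6 near convergence; with
  a negligible floor the path is monotone to 1e-9. Tests assert both
  regimes. Empty mixture components are re-seeded from the worst-fit
  point.
* K-means++ seeding consumes a generator derived from the fit seed;
  identical seeds give bit-identical fits.
* The amplitude-bin index uses a 1e-9 epsilon so nominal edge values
  (±0.33 V) land in the half-open bin they name despite binary
  rounding.
* Degenerate inputs fail loudly: epochs shorter than two samples,
  recordings shorter than one epoch or a filter warm-up, K larger than
  the class sample count, zero total movements for the truncation
  percentage.

## Problem sizes

The shipped experiments use 20-trial synthetic datasets (two movements
per trial, ~8–12 s at 960 Hz, ≈ 6 000 epochs) with 10-fold trial-level
CV and 5-component unigram HMMs — large enough for stable accuracy
estimates (fold SD ≈ 1–2 points) while keeping a full study run to a
couple of minutes on one CPU. Unit tests use 4–8-trial datasets and
1–2-component mixtures.

## Known limitations

* The forward decoder assumes conditionally independent emissions given
  the state; the bigram variant violates this by construction (adjacent
  observations share a sub-vector) and simply ignores it, as is common.
* Sweeping epoch length re-derives labels on a new grid, so accuracies
  across epoch sizes are computed over slightly different epoch counts.
* `correlation_screen` is greedy in the configured feature order; a
  different candidate order could keep a different (equivalent-size)
  feature set.
* The truncation percentage of generated datasets is 0 under the
  default transport durations (0.9–1.4 s, all longer than the 500 ms
  release window); short movements appear only when configured.
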