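# Methods

`navmem` re-implements, against synthetic data with known ground truth, an
analysis battery for intracranial EEG recorded during a virtual
treasure-hunt task: subjects navigate a 100 x 70 (virtual unit) rectangular
arena, encounter four treasure chests per trial (160 per 40-trial session;
100 reveal an object for 1500 ms, 60 are empty), and later place each
object's location from an elevated viewpoint at one of the arena's short
ends. The analyses ask whether low-theta (1-3 Hz) hippocampal power is
lateralized: elevated in the left hemisphere during successful memory
encoding and in the right during navigation.

## Task and behavior simulator

`synthetic.generate_session` draws, per trial, a pre-trial baseline epoch
(uniform 2-6 s), four navigation epochs (log-normal, median 6 s, sigma 0.4,
clipped to 2-20 s), and four chest events at uniform-random arena
positions. Exactly half the trials carry three objects and half carry two,
so a session meets the 100/60 object/empty totals exactly; the trial order
of the 3-object trials is shuffled by seed.

Ground-truth memory is drawn first (Bernoulli, p = 0.5 per object);
responses are generated conditional on it: remembered objects scatter
around the true location (per-axis SD 13 virtual units), forgotten objects
respond uniformly at random with probability 0.85 and with a 4x wider
scatter otherwise. Confidence (Yes / Maybe / No) degrades with realized
error through two soft thresholds (15 and 35 units, Gaussian slack SD 5).
These values were chosen once so that the simulated cohort reproduces the
task's published behavioral profile: mean normalized accuracy ~0.69,
accuracy increasing with confidence, and ~83% agreement between the planted
memory outcome and the analysis-side median-split label. Because the
behavioral label is re-derived downstream (median split plus confidence),
this agreement — not 100% — is the realistic ceiling on how cleanly neural
contrasts can be recovered.

## Recording simulator

`synthetic.generate_recording` builds microvolt traces per physical contact:

- **Background**: spectrally shaped white noise with amplitude proportional
  to f^(-k/2) (default exponent k = 2, RMS 10 uV, DC zeroed). A linear
  filter of Gaussian noise stays Gaussian, which matters for the kurtosis
  rejection stage below.
- **Oscillatory bursts**: Hann-windowed sinusoids at 3 Hz, random phase,
  2-6 cycles, Poisson-placed at 3 bursts/s within every baseline,
  navigation, and chest-display epoch, base amplitude 6 uV. Each
  hemisphere has one burst train, projected onto its contacts with a fixed
  per-contact gradient (uniform 0.5-1.5), so bipolar differencing
  attenuates but does not cancel the oscillation, while perfectly common
  signals (e.g. reference noise) cancel exactly. Burst amplitude is
  multiplied by a hemisphere-specific memory gain during encoding epochs
  whose item is (ground-truth) remembered, and by a navigation gain during
  navigation epochs; all gains default to 1 (null condition). The
  effects-on condition used throughout the analyses plants left memory
  gain 2 and right navigation gain 2.
- **Broadband high-frequency activity**: 40-100-Hz band-passed noise added
  during object displays, scaled by (hfa_item_gain - 1), emulating
  population-spiking increases during item viewing.
- **Line noise and artifacts**: a 60-Hz sinusoid with common phase but
  per-contact amplitude jitter (so the notch filter, not bipolar
  referencing, must remove it), and exponential-decay spikes (300 uV,
  20 ms) at 0.5 events/min per contact.

Two burst parameters deserve comment. Bursts of 1-3 cycles make clean
epochs heavy-tailed enough that the kurtosis criterion (threshold 5)
rejects 2-3% of artifact-free windows; 2-6-cycle bursts keep clean
rejection under 2% while preserving a narrowband spectral peak. The base
amplitude 6 uV places the gain-1 oscillation near the narrowband detector's
threshold, so detection is more prevalent for remembered (gain-2) than
forgotten spectra — the qualitative prevalence asymmetry the analyses test
— instead of saturating in both conditions. With these defaults the
overall event rejection fraction lands near 7%, matching the exclusion
rate reported for the real recordings.

What the generator does **not** emulate: volume conduction and realistic
electrode geometry, phase-amplitude coupling, non-stationary background
spectra, correlated artifacts across contacts, eye/muscle activity, and
any dependence of behavior on arena position. Passing tests therefore
show that the pipeline recovers effects of the planted form at realistic
SNR — not that it would be robust to every pathology of clinical iEEG.

## Preprocessing

Bipolar referencing pairs immediately adjacent contacts on each probe
(consecutive contact indices); the virtual channel is first minus second,
located at the pair midpoint, inheriting hemisphere/region labels when the
parents agree ("boundary" otherwise). Line noise is removed with a
4th-order Butterworth band-stop at 58-62 Hz applied forward-backward
(zero phase; the effective attenuation is doubled, acceptable since only a
stop band is required). Epochs carry a 3000-ms buffer on each side for
wavelet edge control; fixed 0-1500-ms windows for chest displays, full
variable-length spans (ragged) for navigation and baseline epochs.

Artifact rejection computes the plain (non-excess) kurtosis of the
unbuffered voltage trace per event x channel and excludes cells above 5;
Gaussian traces sit near 3, uniform near 1.8, spike-contaminated traces
far above. The convention is non-excess so the threshold 5 behaves as in
the artifact-rejection literature this rule comes from. Zero-variance
traces are excluded and logged. Rejection is per event x electrode rather
than whole-event, which preserves data on clean channels.

## Spectral estimation

Power comes from convolution with unit-energy complex Morlet wavelets
(wave number 5, i.e. five cycles under the Gaussian envelope, support
+-3.5 sigma_t) on 50 log-spaced frequencies from 1 to 200 Hz. The
convolution runs in 'same' mode so epochs may be shorter than the wavelet
(~8 s at 1 Hz); buffers are trimmed afterwards. With unit-energy
normalization the expected power approximates the local PSD, so a
power-law background yields a log-log spectral slope of about -k.

Raw power is averaged over the analysis window, natural-log transformed,
and z-scored across events separately per channel and frequency (and time
bin for binned analyses). The normalization set is the union of encoding,
navigation, and baseline events; empty-chest (no_item) events are
transformed with the same group statistics but excluded from computing
them. The z-score uses the population SD (ddof = 0), fixed by the anchor
case that a two-event group maps to exactly {-1, +1}. Bands: low theta
1-3 Hz, theta 3-10 Hz, HFA 40-100 Hz, closed intervals on the grid (3 Hz
belongs to both theta bands). Time-frequency binning uses fully contained
overlapping windows — floor((span - width)/step) + 1 of them — giving the
69-bin (100/50 ms over -1500..2000 ms) and 56-bin (500/100 ms over
-2250..3750 ms) layouts. Navigation-epoch analyses re-center z-power on
the mean of the pre-trial baseline events (mean subtraction only; the
baseline SD is not divided out).

## Group statistics

Per-electrode contrasts are differences of condition means of z-power
(remembered - forgotten; navigation - baseline; item - empty chest),
averaged over a subject's hippocampal electrodes within hemisphere to one
value per subject x hemisphere x band x contrast. Group inference is a
two-sided one-sample t against zero, Bonferroni-corrected across the six
band x hemisphere tests within each contrast family; no correction is
applied across analysis families.

The cluster-mass permutation test thresholds per-bin one-sample t maps at
the two-sided parametric p < 0.05 critical value, forms same-sign clusters
under 4-connectivity (1-D adjacency for time-only traces), and compares
each cluster's summed t against the maximum |mass| distribution obtained
by flipping each subject's whole map sign at random (1000 permutations,
+1-corrected p). Sign flips leave per-bin sums of squares unchanged, so
the null t maps need only flipped means — the permutation loop is a single
matrix product plus a stacked connected-component labeling, which is what
makes the 2000-dataset calibration suites affordable.

Vertex-map thresholds use the pooled sign-flip null: per permutation and
point, a uniformly random half (floor(n/2)) of subjects flip sign; the
2.5th/97.5th percentiles of the pooled null t are the significance bounds.
(The source wording is ambiguous between flipping half the subjects per
point and half of each subject's points; the former is implemented.)
Spatial aggregation assigns each target point the mean effect of a
subject's electrodes within radius (12.5 mm cortical, 3 mm hippocampal),
with optional 4-mm-FWHM Gaussian smoothing over a subject's assigned
points, and excludes points with fewer than five contributing subjects.

The lateralization ANOVA is a two-way fixed-effects model (hemisphere x
condition) on subject-level values with type-II sums of squares — robust
to the unbalanced hemisphere groups that arise when not every subject has
electrodes in both hemispheres — plus per-cell one-sample and pooled
two-sample post-hoc t tests. Variant forms replace the condition factor
with memory success or navigation state on condition-level means.

Narrowband detection fits log-power against log-frequency over 1-50 Hz by
IRLS with Tukey bisquare weights (c = 4.685, max 50 iterations, tol 1e-8)
and flags frequencies whose residual exceeds one SD of the residuals. The
fitted slope estimates minus the background exponent. The pipeline skips
this analysis when a scaled-down grid has fewer than 10 frequencies in
range. Within-subject SEMs remove each subject's mean (restoring the
grand mean) before computing per-condition SEMs.

## Decoding

An L2-regularized logistic regression (inverse strength C = 1, no internal
tuning, no class weighting — the median-split rule yields near-balanced
classes) predicts remembered vs forgotten from z-power at 10 log-spaced
frequencies in 1-10 Hz and/or 10 in 40-100 Hz per electrode, averaged over
0-1500 ms. Cross-validation leaves one session out (one trial out for
single-session subjects); AUC is computed on predictions pooled across
folds, which is stabler than per-fold AUC under leave-one-trial-out.
Events with any rejected cell are dropped row-wise. The shuffle null
permutes labels within subject (identity permutations resampled away) and
re-runs the full CV 100 times; the cohort p compares the true mean AUC to
the shuffled cohort means. The electrode sweep, per repetition, half-splits
the events, ranks electrodes by the maximum |two-sample t| across their
frequencies on the training half, and evaluates AUC on the held-out half
for the top N = 1..50 electrodes (half-split evaluation, not nested CV,
following the procedure's description).

## Scaled-down study conditions

Full 40-trial sessions (~25 min at 500 Hz) are used for design-count
checks; the statistical suites run on shortened sessions that preserve the
design ratios (10 trials, 40 chests, 25/15 object/empty) and a coarser
12-point 1-40-Hz grid, never a lower sampling rate. The planted-effect
recovery condition is 20 subjects x 10 seeds with left memory gain 2 and
right navigation gain 2, the cluster calibration uses 2000 null datasets
of 12 subjects x 20 x 20 bins at 250 permutations each, and chance-level
decoding uses 10 null subjects x 20 label permutations. These sizes are
the package's chosen desk-scale study conditions; the analysis drivers
under `analysis/` state the sizes they run at.

## Storage

Recordings persist as HDF5 (data matrix + montage table + ground-truth
sidecar JSON); session and response tables as TSV; power tensors as HDF5
with dimension labels and provenance; results as JSON/TSV. An EDF export
was considered and dropped — the environment provides no EDF writer — and
HDF5 keeps full float precision anyway.

## Known limitations

- The simulator's effects are multiplicative amplitude gains on a single
  3-Hz burst train per hemisphere; it cannot express frequency shifts,
  duration changes, or phase effects.
- Sessions are single-run; the leave-one-session-out branch of the CV is
  exercised only by tests that construct multi-session feature matrices.
- The spatial-aggregation stage operates on abstract 3-D point clouds; no
  anatomical surfaces or volumes are modeled.
- Wavelet power at 1 Hz inside a 1.5-s window is dominated by smoothing
  from neighboring epochs (the wavelet spans ~8 s); contrasts at the
  lowest grid frequencies therefore mix adjacent-epoch activity, exactly
  as in the real analysis.
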