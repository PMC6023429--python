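# Methods

`mwdiag` re-creates, at desk scale, a three-stage computer-aided diagnosis
platform for ultra-wideband microwave breast scanning: (1) acquisition of
multistatic backscattered signals, (2) signal processing that isolates the
tumour response, and (3) machine-learning diagnosis of the tumour as benign
or malignant.  Stage 1 is a synthetic generator standing in for full-wave
electromagnetic simulation; stages 2 and 3 are the methods under study.

## 1. Acquisition model

**Geometry.** Twelve point antennas sit on a planar ring (default radius
70 mm) around a circular breast cross-section (default radius 55 mm with a
2 mm skin shell), antenna *i* at polar angle *i*·30°.  A *channel* is an
unordered transmit–receive pair, monostatic pairs included:
n(n+1)/2 = 78 channels for n = 12.  The *channel angle* Z ∈ {0°, 30°, …,
180°} is the angular separation of the pair; a 12-ring has 12 channels at
each angle below 180° and 6 diametric ones.

**Pulse.** The interrogating waveform is a differentiated Gaussian whose
scale is set by the 6 GHz centre frequency (σ = 1/2πf_c ≈ 26.5 ps); its
spectral magnitude peaks exactly at f_c.  Records are sampled at 600 GHz.
The nominal pulse width t_p = 0.8 ns is a *windowing unit*, chosen so the
2.5·t_p tumour window downsampled to 30 GHz is exactly 60 samples; the spec
gives the window in pulse widths and the output in samples but not t_p
itself, which pins it uniquely.

**Echo model.** The generator replaces the field solver with a geometric
superposition per channel:

* *reference*: the antenna-coupling waveform — a direct Tx→Rx pulse through
  the immersion medium (ε_imm = 9, adipose-like), identical for channels of
  equal angle; monostatic channels get the self-coupling echo at zero delay;
* *skin artefact*: the entry-point reflection, at the time both antennas'
  ring–breast gap crossings sum to, with amplitude 12× the principal tumour
  echo (the stated world requires ≥ 10×).  A specular mid-point reflection
  was rejected: at this geometry it lands inside the tumour window for
  wide-angle pairs, contradicting the premise that windowing eliminates the
  skin response;
* *principal tumour echo*: a pulse copy at the three-media round-trip delay
  (section 2), amplitude `100 / path-length(mm)` — a simple monotone
  path-loss law;
* *spicule sub-echoes*: Poisson(round(10·s)) additional copies, delays
  uniform within ±1 pulse width of the principal echo, amplitudes uniform in
  [0.2, 0.8] of it.  The spiculation parameter s ∈ [0,1] encodes margin
  irregularity: benign tumours draw s ~ U[0, 0.25], malignant s ~ U[0.50,
  0.90], diameters U[6, 20] mm.  The sub-echo law is this package's own
  stylisation of "waveform distortion grows with spiculation": it makes the
  classes separable but overlapping (a benign tumour can draw up to ~3
  sub-echoes, a malignant one as few as ~4);
* *glandular clutter*: Poisson(20·gf) echoes from uniformly random interior
  scatterers (gf = glandular fraction; presets 1%, 5%, 27%), amplitudes
  uniform in [0.05, 0.5] of the principal echo;
* *noise*: white Gaussian, σ expressed relative to the principal-echo
  amplitude (default 0.05).

The default dataset design is 3 breasts (one per glandular preset) × 72
tumours (36 benign / 36 malignant, shapes shared across breasts) × 5
positions (breast centre plus four quadrant sites at half the interior
radius on the ±45° diagonals — the quadrant coordinates are unstated in the
source material, so this package fixes them once) = 1080 scans, 84,240
signals.  All randomness flows from one seed through `SeedSequence` spawns,
so a dataset is bit-reproducible.

**What the generator does *not* emulate:** dispersive (Debye) tissue
response, MRI-derived anatomy, antenna radiation patterns, 3-D propagation,
multiple scattering, and channel-angle-dependent phase distortion of the
tumour response.  A green diagnosis test therefore establishes that the
*pipeline machinery* (windowing, features, model families, voting, CV)
recovers a spiculation signal of the stated statistical shape — not that
real FDTD or clinical data would yield the same figures.

## 2. Tumour windowing (TW)

1. **Artefact removal** — pointwise subtraction of the per-channel
   reference.
2. **Delay prediction** — the round-trip delay Tx→tumour→Rx is computed on
   straight rays through three media (immersion, skin annulus, interior),
   each segment divided by c/√ε; segment lengths come from the two
   line–circle intersections.  The *true* tumour position from the scan
   metadata is used, mirroring the source study's idealised localisation.
3. **Windowing** — a 2.5·t_p slice (1200 samples at 600 GHz) starting
   0.75·t_p before the predicted arrival; the asymmetry leaves room for the
   trailing spicule sub-echoes.  Overruns are zero-padded with a logged
   warning; a delay beyond the record is an error.
4. **Alignment** — "peak energy" is read as the sample of maximum absolute
   amplitude (the simplest reading; an envelope-based alternative would
   behave differently for multi-lobe echoes).  The window is circularly
   shifted so the peak maps to a fixed index.  Near-ties (< 1e-9 relative)
   resolve to the earliest sample because the two lobes of a clean
   differentiated-Gaussian echo are exactly equal in magnitude.
5. **Downsampling** — zero-phase FIR anti-alias filtering at the 15 GHz
   output Nyquist, then decimation by 20 to 30 GHz; naive decimation would
   alias the upper band edge of the 6 GHz pulse.  A final output-rate shift
   pins the signature's peak at index 33 of 60 (chosen because the dominant
   aligned sample is expected in the low-30s of the signature), which also
   makes alignment idempotent.  Alignment is per-signal, each channel
   independently.

An all-zero window yields a zero signature flagged low-quality with the
alignment index at the window centre.

## 3. Feature extraction (FE)

Thirty descriptors per signal in four sub-groups: time-domain peak/area
statistics (#1–#19), autocorrelation peak statistics on the lag-0-normalised
sequence (#20–#24), the mean Welch PSD (#25; Hann window, segment 30, 50%
overlap — parameters unstated upstream, chosen for a 60-sample record), and
periodogram peak statistics (#26–#30; rectangular window, full record,
widths/separations in frequency bins).  Feature #6 ("root-mean-squared
error") is implemented as the RMS value of the signal since no reference
waveform is named; #13/#14 are read as the mean separation between
*consecutive peaks of the same polarity*, parallel to the per-polarity
structure of #11/#12.  Peaks everywhere are prominence-filtered local
extrema (threshold 5% of max |amplitude|, suppressing numerical ripple)
with FWHM by linear interpolation at half the prominence-referenced height.
Every feature depends only on its own signal — no cross-observation
statistic exists, so feature extraction cannot leak information across CV
folds.  Degenerate inputs (zero signal, empty peak sets) map to defined
zero defaults, never NaN.

The definitions are length-agnostic: FE mode applies them to raw
artefact-removed records at 600 GHz, TW+FE to 60-sample signatures at
30 GHz.

## 4. Diagnosis

**Observation unit.** Each (scan, channel) signature or feature vector is
one training row labelled with its scan's class; fusion to a scan-level
diagnosis happens only at prediction time.

**Forests.** scikit-learn random forests with bootstrap resampling
(≈ 1/3 of rows out-of-bag per tree) and `oob_score=True`; the OOB
misclassification rate is the model-selection criterion.  Hyperparameters
{number of trees, features per split, minimum leaf size} are tuned by a
small sequential model-based search: 5 seeded random initial points, then a
Gaussian-process (Matern 5/2) surrogate over the unit-scaled integer space
maximising expected improvement; ties break to fewer trees.  Default space
50–500 trees, 1–30 features, leaf 1–20, budget 30 evaluations (tests and
the acceptance driver shrink space and budget for runtime only).

**Model families.** EA(Z) trains on channels of exactly one angle (7
models); MA(0–U) pools all channels with angle ≤ U (6 models); EAC(0–U)
holds one EA member per angle ≤ U and fuses member decisions by unweighted
majority, ties to malignant (6 models).  Antenna grouping is applied
*inside* each EAC member before the member-level vote — the fusion order is
unstated upstream; this choice keeps each member a self-contained EA model.
The EAC ROC score is the mean of member fused scores, which preserves a
usable continuous sweep while the hard decision remains the member-majority
vote.

**Antenna grouping.** Channels are ranked by the two-leg Euclidean path
Tx→tumour→Rx (the physical signal path; it reduces to twice the
antenna–tumour distance for monostatic channels), ties broken
lexicographically by (tx, rx).  The fused score over the W closest voting
channels is the malignant fraction; the label threshold is 0.5 with ties to
malignant, favouring sensitivity in a screening context.  Note the ranking
uses the true tumour position — a clinical system would need a localisation
front-end here.

**Validation.** k = 5 stratified outer folds at *scan* level: all 78 rows
of a scan stay on one side of every split, and the leakage ban is asserted
programmatically on each run.  Hyperparameters are optimised inside each
training fold on OOB error alone (no inner CV loop is needed for forests);
reported performance is the mean test-fold AUC.

## 5. Evaluation

ROC curves sweep the decision threshold over all unique fused scores
(classify malignant at score ≥ threshold), prepending the above-maximum
threshold so curves run (0,0)→(1,1); AUC is trapezoidal and equals the
Mann–Whitney pairwise statistic (asserted in tests).  The operating
threshold maximises Youden's J = TPR − FPR, ties to the lower threshold.
Feature contributions are out-of-bag permutation importances (per tree: OOB
error increase under single-column shuffling, averaged, clipped at zero)
max-normalised to [0,1]; permutation on OOB rows is less biased than
impurity importances for correlated inputs.  In TW mode the map is per time
sample, in FE/TW+FE per feature.

## 6. Numerical choices and edge cases

* Units: mm, ns, GHz; c = 299.792458 mm/ns.
* Record length 4096 samples (≈ 6.8 ns) by default; tests use 2560
  (≈ 4.27 ns), the shortest record containing every tumour window at the
  default geometry.
* Delay computation raises on tumours outside the breast interior;
  proximity ranking merely warns for positions outside the ring (the
  ranking stays well defined).
* `%.17g` CSV floats with round-trip parsing give bit-exact table I/O;
  dataset containers are HDF5 with one group per scan.
* Determinism: identical `RunConfig`s reproduce prediction tables
  byte-for-byte; every output carries the config hash (output paths are
  excluded from the hash).

## 7. Known limitations

* The echo model's spicule law (Poisson rate 10·s, ±1 pulse-width spread)
  is a plausible but invented bridge between margin spiculation and
  waveform distortion; absolute AUCs on this generator do not transfer to
  FDTD or measured data, which is why performance checks are properties
  (orderings, nulls, monotonicity) rather than reproductions of the source
  figures.
* Channel-angle-dependent effects (phase rotation of the tumour response
  with bistatic angle) are not modelled, so EA-vs-MA contrasts here are
  weaker than in the source data.
* Monostatic self-coupling and skin reflection are stylised single echoes;
  no multiple reflections or antenna ringing.
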