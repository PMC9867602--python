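# Methods

`mesophot` analyzes paired recordings of mesoscale widefield cortical calcium
imaging (a 40-Hz H x W x T movie over a cortical mask) and striatal fiber
photometry (a ~1-kHz 465-nm calcium-dependent trace with a 405-nm isosbestic
control). Its goal is the multiscale question: how does distributed cortical
activity relate, pixel by pixel and motif by motif, to the bulk presynaptic
calcium signal recorded from corticostriatal axon terminals, and with what
time lag?

## Preprocessing

**Photometry dF/F.** Two baseline definitions are provided. The isosbestic
method fits the 405-nm channel to the 465-nm channel by ordinary least squares
and uses the fit as F0, making the result invariant to affine rescaling of the
control channel; it targets movement artifacts shared by both wavelengths. The
moving-average method uses a centered 10-s moving mean of the raw trace as F0;
windows shrink at the recording edges so F0 is defined everywhere. In both
cases the output is (F - F0)/F0. Descriptions of the moving-average method
sometimes stop at subtraction; we divide as well, for dimensional consistency
with the isosbestic method and the cortical dF/F, and expose the subtract-only
variant behind `divide=False`.

**Temporal filtering.** Both modalities pass through the same band-pass —
Chebyshev type I, order 2, 0.5 dB ripple, 0.1-12 Hz — applied
forward-backward (`sosfiltfilt`). Identical treatment means filtering cannot
introduce a relative lag between cortex and striatum, and zero phase preserves
absolute event times, which the lag maps depend on.

**Resampling.** Photometry is brought onto the widefield frame clock by a
zero-phase low-pass Chebyshev type I filter of order 8 (0.05 dB ripple, cutoff
0.8x the output Nyquist — the classic MATLAB `decimate` design) followed by
linear interpolation onto `t0 + k/fs_out`.

**Widefield.** Per-pixel dF/F against the 10-s moving-average baseline, then
spatial smoothing with a normalized 3-pixel disc (the full 3x3 neighborhood;
diagonal centers lie within the 1.5-pixel radius), then the shared band-pass.
This order is fixed and recorded in the output provenance. Unmasked pixels are
carried as zeros and excluded from all statistics. Stimulation artifacts
(one-frame full-field transients from visual stimuli) are removed on the raw
movie by per-pixel linear interpolation across each artifact run plus a
1-frame pad; runs touching the recording ends raise an error rather than
extrapolate.

## Correlation and lag maps

The full correlation map is the Pearson r of each masked pixel against the
(preprocessed, z-scored) photometry trace. The partial correlation map
controls for the global cortical signal (spatial mean over the mask) through
the closed form

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),

with pixels whose residual variance vanishes set to 0 and flagged. The lag map
evaluates, per pixel, the Pearson correlation at every integer-frame lag in
+/- `max_lag` (default 2 s), re-estimating mean and SD on the overlapping
segment at each lag so |r| <= 1 holds exactly; the signed maximum defines the
pixel's lag, and pixels whose peak falls below `r_threshold` (default 0.5) are
marked invalid and rendered gray. Negative lag means cortex leads. Lags are
integer frame multiples; no sub-sample interpolation is attempted. The peak
search uses signed r rather than |r| because the corticostriatal maps are
positive-correlation structures; anti-correlated peaks would be a biologically
distinct finding and should not silently flip the map.

## Convolutional motif discovery

Cortical motifs are found by convolutional (sequential) NMF on the rectified
dF/F matrix X (masked pixels x time; negative dF/F is clipped to zero since
the factorization requires nonnegativity):

    X ~ sum_k sum_l W[:, k, l] H[k, t - l],  W, H >= 0,

with K motifs of L frames (default L = 40, i.e. 1 s at 40 Hz). Updates are
multiplicative and are exact Lee-Seung steps on the linearized problem — the
H update treats the fixed W as a linear (block-Toeplitz) operator, the W
update treats the stacked, lag-shifted H as an ordinary NMF design matrix —
so at penalty weight lambda = 0 the squared-error objective is provably
non-increasing, which the test suite checks. A cross-factor orthogonality
penalty, lambda * sum_{k != k'} [(W (*) X) S H^T]_{kk'} with S a
(2L-1)-frame moving sum, discourages distinct motifs from explaining the same
data at nearby times. Each iteration costs two dense (P x T) x (KL) matrix
products, so a 5-minute 64 x 64 session fits in ~1.5 s/iteration on one core.
Motifs are max-normalized with scale absorbed into the loadings; motifs whose
loading energy is below 1e-6 of the strongest are kept in the returned set
but dropped from reports.

**Convergence matters for timing.** The multiplicative updates sharpen the
loadings slowly: at a few hundred iterations each motif occurrence is still
smeared over 2-3 adjacent frames, which biases the loading-photometry
cross-correlation peak 1-3 frames early (the photometry transient kernel's
heavy tail rewards early smear). Recovering planted coupling delays to
one-frame accuracy requires running the fit to ~600 iterations; the package
does not sharpen or deconvolve loadings post hoc.

**Lag semantics.** The loading-photometry cross-correlation reports the raw
lag between z-scored loadings and the z-scored trace. Because the striatal
trace is itself a convolution of event times with the indicator kinetics, this
lag includes the kernel's peak location after zero-phase filtering (about one
frame); no deconvolution is attempted.

## Evoked analysis

Epochs are cut around TTL event times with a 1-s pre-stimulus baseline;
windows that cross the recording edge are dropped and counted. Habituation is
the comparison of the average of the first 10 responses against the last 10,
with peak amplitude measured after subtracting each block's pre-window mean.
The activated area counts pixels whose trial-averaged post-stimulus peak
exceeds the baseline mean + 4 SD (per-pixel statistics; zero-variance pixels
fall back to the global baseline SD and warn). Whether the threshold applies
to the per-pixel peak or to any post-stimulus frame is configurable
(`mode="peak"` default, `mode="any"`); for the count statistic the two
coincide. Note the 4-SD bound keeps false positives near zero only when the
post-stimulus window is matched to the evoked transient (~0.25 s); a long
window accumulates peak-over-frames comparisons and the count's +-2-pixel
reproducibility degrades. Behavior (FaceMap-style motion) traces are smoothed
with a 1-s moving average and z-scored.

## Synthetic sessions

The generator emulates the recording regime the analysis assumes, not the
biology underneath it:

- **Motifs.** "ap_wave" is a bilateral pair of blobs travelling
  anterior-to-posterior over the motif's L frames (the "butterfly"
  sensorimotor pattern); "alm_visual" is a static, spatially disjoint
  ALM + visual-cortex pattern with a half-sine temporal envelope. Template
  maxima equal the configured amplitude (default 5 on a baseline of 100, i.e.
  a 5% dF/F transient, typical of mesoscale GCaMP).
- **Loadings** are homogeneous-Poisson event trains (default 0.2 events/s)
  thinned so instances never overlap themselves — the sparse,
  non-self-overlapping regime convolutional NMF assumes.
- **Photometry coupling.** Selected motifs add a transient to the 465 channel
  at each occurrence, delayed by a configurable corticostriatal delay and
  shaped by a causal single-exponential kernel with tau = 1 s (GCaMP6s-like
  off-kinetics; configurable). The 405 channel never sees motif activity.
- **Drift** is a slow sinusoid (default 2% of baseline, 120-s period) shared
  between the 465 and 405 channels, so isosbestic fitting has real structure
  to remove. Noise is white Gaussian per channel/pixel (defaults: widefield SD
  1.0 = 20% of motif amplitude; photometry SD 0.5 = 10% of transient weight).
- **Stimulation.** An optional block of n stimuli at fixed ISI (defaults 40 at
  10 s) adds an elliptical evoked response (~50 pixels at 64 x 64, 0.1-s rise,
  exponential decay) scaled by decay^trial, a matching photometry transient,
  and optionally a one-frame full-field artifact spike.
- **Determinism.** All randomness flows from one seed through five named
  sub-streams (loadings, widefield noise, 465 noise, 405 noise, uncoupled
  component) spawned in fixed order, so equal configs are bit-identical and
  changing one noise source never perturbs another.

What the generator does *not* emulate: hemodynamic absorption, vascular
anatomy, sensor nonlinearity, movement artifacts beyond shared drift, or a
realistic thalamic contribution to the striatal signal (an optional smoothed
uncoupled component exists but makes no claim of realism). A green
recovery test therefore establishes correctness of the analysis chain under
the stated generative assumptions, not robustness to real-data pathologies.

A caveat the synthetic world makes visible: when a travelling motif drives the
photometry, different footprint pixels activate at different times within the
motif, so per-pixel lags are genuinely dispersed around the planted coupling
delay (this is the anterior-to-posterior gradient the lag map is designed to
show). Statistics that summarize "the" lag of a region should use the median
over valid pixels, and zero-lag correlation maps resolve static footprints
much better than travelling ones.

## Numerical choices

- Population (1/N) SD everywhere a z-score or SD appears; constant traces
  z-score to zeros rather than erroring.
- Pearson accumulations run in float64 even when movie data is float32; the
  lag map's per-lag dot products use float32 BLAS (relative error ~1e-5,
  irrelevant at the 0.5 validity threshold and for integer-frame argmax).
- Long-session stacks are processed in 8-row chunks to bound peak memory;
  movies are float32 end to end.
- seq-NMF denominators carry an additive 1e-30 guard; fits run in the dtype of
  X (float64 in tests, float32 for long sessions).
- The moving-average dF/F window truncates (shrinks) at the edges; the
  band-pass uses `sosfiltfilt` default edge padding.
- SNR is the plain summed-squares ratio 10 log10(sum s^2 / sum n^2) — not a
  harmonic-distortion SNR.
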