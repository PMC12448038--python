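# Methods

This note documents the models, algorithms and numerical choices behind
`eegtelemetry`, and what the synthetic validation does and does not show.

## ADC front-end model

The acquisition chain is modelled as an ideal bipolar converter behind a
programmable gain amplifier (PGA): reference voltage `vref` (default
2.5 V), gain `g ∈ {1, 2, 4, 8}`, resolution `b` bits (native 24).  One
LSB is `(2·vref/g)/2^b` volts — 0.298 µV at gain 1 and 24 bits, 0.037 µV
at gain 8 — and the input range is ±`vref/g`.  Codes are signed
two's-complement centred on 0 V: EEG is a bipolar signal and the
symmetric input-range specification requires the signed reading; unsigned
code spans (0–65535 at 16 bits, etc.) are kept only as illustrations of
the number of codes.  Quantization rounds half away from zero so positive
and negative voltages are treated symmetrically; out-of-range voltages
saturate to full scale rather than erroring, as a real converter does.
Bit-depth reduction to 10/14/16 bits is a pure arithmetic right shift
(truncation, no dithering).  ADC noise (thermal noise, ENOB), analog
anti-aliasing and crosstalk are out of scope.

## Telemetry codec

The codec is closed-loop DPCM with a per-channel adaptive bit shift.

* **Differencing.** For each channel the encoder transmits
  `q = round(d / 2^s)` where `d` is the difference between the current
  24-bit code and the encoder's *own previous reconstruction*, `s` the
  channel's current shift, and `q` saturates to the signed
  `payload_bits`-wide symbol range.  Quantizing against the encoder's own
  reconstruction (not the true previous sample) is essential: it keeps
  the decoder bit-identical to the encoder and prevents quantization
  error from accumulating.  The per-sample error is at most `2^(s-1)`
  codes whenever no saturation occurs.
* **Shift selection.** Once per statistics window (1 s) each channel
  computes the population standard deviation σ of the *first differences*
  of the window (the quantity that must fit the symbol is a single signal
  change).  The shift is
  `s = clamp(bits_needed(round(f·σ)) − (payload_bits − 1), 0, max_shift)`
  with safety factor `f ≥ 1` (default 8) and `bits_needed(x) =
  ⌊log2 x⌋ + 1`.  Baseline allocation covers changes strictly below σ;
  `f = 8` buys exactly four extra high-order bits of headroom.  Larger
  shifts admit larger changes at coarser resolution; the `max_shift`
  clamp deliberately clips very large jumps (mostly artifacts).
* **Framing.** Every statistics window opens with a keyframe carrying the
  absolute per-channel reconstruction state and the freshly selected
  shifts; the window's samples follow as delta packets of 25 symbols per
  channel (ten delta packets per second at 250 Hz, so one lost packet
  costs ≤ 100 ms).  Shifts for window *k* come from window *k−1*; the
  first window uses its own statistics (the only look-ahead, confined to
  stream start).  Sequence numbers are unsigned 16-bit with wraparound.
* **Loss handling.** Samples covered by lost delta packets are filled by
  holding the last reconstructed value and flagged; reconstruction is
  exact again from the next received keyframe, which restores the
  absolute state.  Loss statistics come from sequence arithmetic; the
  monitor recommends lowering the payload depth or sampling rate when the
  loss fraction strictly exceeds a threshold (default 1%; the
  notification in the field appears around a few percent).
* **Wire format.** `DMP1` little-endian: per packet seq uint16, flags
  uint8, n_samples uint8, 24 shift bytes, then 24 × int32 (keyframe) or
  n×24 × int16 (deltas).  10/14-bit symbols are not bit-packed tighter
  than int16; entropy coding is out of scope.

## Filter bank

The validated menu is Butterworth throughout (the standard maximally
flat choice, which also makes "order" unambiguous): high-pass 0.8 Hz/2,
1.0 Hz/4, 1.7 Hz/4, 1.7 Hz/2; low-pass 45 Hz/4, 60 Hz/6; band-stop
46–54 Hz and 48–52 Hz at total order 6 or 4.  Band-stop order is the
*total* polynomial order (an order-6 band-stop is a 3rd-order prototype
mirrored).  The default chain is HP 1 Hz/4 → LP 45 Hz/4 → BS 46–54 Hz/6,
designed at the 500 Hz acquisition rate; with linear filters the chain
order only affects transients.  Application is causal per channel
(streaming semantics); forward–backward zero-phase filtering exists as an
offline option.  Stability (all poles strictly inside the unit circle) is
checked at design time for every menu member.  Decimation to 250 Hz
(every 2nd sample) or 167 Hz (every 3rd, the 500/3 mode) keeps index 0
and relies on the chain's low-pass (≤ 60 Hz, far below the decimated
Nyquist) for anti-aliasing; decimating unfiltered data warns.  A sweep
harness injects a 1–70 Hz linear chirp and reports the filtered/raw power
ratio along the sweep; with the default chain the 50 Hz ratio is the
notch depth (< 10⁻⁴ in power by design — the reference experiment shows
this only graphically, so the quantitative bound comes from the designed
response).

## Synthetic sessions

The generator emulates the alpha-blocking validation protocol: five
cycles of 2-minute eyes-closed / 2-minute eyes-open (20 min, starting
eyes-closed) on the 24-channel 10–20 montage, sampled at 250 Hz.  Signal
content per channel, all in µV at the scalp:

| component | default | where / when |
|---|---|---|
| pink (1/f) background | 10 µV RMS | all channels, always |
| alpha (~10 Hz, AM/FM-jittered) | 20 µV peak | POZ/O1/OZ/O2 (full), P3/PZ/P4 (half), eyes-closed |
| delta band-limited noise (0.5–4 Hz) | 15 µV RMS | FP1/FPZ/FP2, eyes-open |
| blinks (biphasic, ~300 ms, Poisson) | 100 µV peak, 0.25 /s | FP1/FPZ/FP2, eyes-open |
| mains sinusoid (50 Hz) | 0 µV (off) | all channels if enabled |

Amplitudes are physiologically plausible resting-EEG magnitudes chosen
once to give the cluster test high power at the standard epoch counts;
the half-amplitude parietal alpha makes the effect spatially clustered,
matching the occipito-parietal spread of real topographies.  The 2-D
montage positions are a schematic 10–20 layout shipped as a plain-text
fixture (the mastoids are drawn just inside the unit head circle so that
every channel has at least one neighbour under the default adjacency
radius).  Everything is drawn from a single seeded NumPy generator, so a
fixed seed reproduces a session bit for bit on any platform.

What the generator does *not* model: biophysical volume conduction
(sources appear only on their designated channels plus the shared pink
background, there is no realistic inter-channel covariance), artifact
taxonomies beyond blinks, non-stationary alpha reactivity, or
inter-subject variability.  Passing the recovery tests therefore shows
the pipeline detects a spatially clustered spectral contrast of realistic
magnitude under realistic noise — not that it reproduces any particular
human dataset.

## Analysis pipeline

1. **Channel exclusion.** A channel is dropped if flat (zero variance) or
   if its log-variance deviates from the across-channel median by more
   than 5 robust z-units (MAD-scaled).  The MAD scale is floored at 0.35
   natural-log units so that the legitimate factor-of-a-few spread of
   channel variances (alpha and blink topography) can never be flagged;
   visual inspection in the original workflow is not reproducible, so the
   rule is automated this way.
2. **Epoching.** Consecutive non-overlapping 30-s epochs within each
   condition block; partial tails discarded; epochs never span a
   condition boundary.  The default session yields 40 epochs (20 per
   condition).
3. **Spectra.** Multitaper FFT with DPSS tapers, half-bandwidth
   W = 1 Hz, `K = ⌊2TW⌋ − 1 = 59` tapers for T = 30 s; eigenspectra
   averaged with equal weights; one-sided density in µV²/Hz that
   integrates to the signal variance.  Band powers integrate bins with
   `lo ≤ f < hi` over Delta (1–4), Theta (4–8), Alpha (8–12) and Beta
   (12–30 Hz).
4. **Statistics.** Cellwise independent-samples pooled-variance t on
   log₁₀ power (EEG power is right-skewed; the log brings the groups
   close to the equal-variance Gaussian setting).  Cells with |t| above
   the two-sided critical value at `cluster_alpha` (default 0.01) are
   grouped into connected components — same channel & adjacent frequency
   bins, or adjacent channels & same bin, with channel adjacency =
   Euclidean distance ≤ 0.4 on the unit head plane.  Positive and
   negative clusters are formed separately; the cluster statistic is the
   sum of member t values.  Monte Carlo p-values compare each observed
   |statistic| against the permutation distribution of the maximum
   |cluster statistic| over both signs (group labels shuffled, default
   1000 permutations, `p = (1 + #{max ≥ obs}) / (n_perm + 1)` so p is
   never 0).  Testing is restricted to 1–30 Hz, the union of the bands.
   `cluster_alpha` (cluster-forming) and `cluster_sig_alpha`
   (significance, default 0.05) are deliberately separate knobs.
5. **Effective channels.** The union of channels in significant clusters,
   in montage order.
6. **End-to-end fidelity.** `compare_pipelines` correlates, across
   channels, the eyes-closed-minus-open alpha band-power difference of a
   clean recording with that of its processed (ADC → codec → filters)
   counterpart.

## Problem sizes used in the test suite

The statistical checks run at desk scale: type-I calibration uses 200
null simulations of 8-vs-8 synthetic spectra with 200 permutations each
(rate expected within 3 binomial standard errors of 0.05); power uses 50
seeded full sessions at the standard 20-vs-20 epoch counts with 199
permutations (the minimum attainable p, 1/200, lies below the 0.01
criterion); the end-to-end fidelity check uses one full session.  These
sizes keep the whole suite to minutes while leaving the Monte Carlo
error well inside the asserted tolerances.

## Known limitations

* The codec models the radio link only as an ordered lossy packet
  channel; no GATT/MTU framing, retransmission or jitter.
* Saturation clipping is the only artifact suppression in the codec; no
  dedicated artifact filter is implemented.
* The decoder infers the size of lost packets from the framing cadence
  (`samples_per_packet`); a lost keyframe therefore costs alignment until
  the next keyframe.
* Whether bit-depth requantization should be applied before differencing
  is left open in the source system; here `payload_bits` is the width of
  the difference symbol and no pre-requantization occurs.
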