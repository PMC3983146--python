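# Methods

This note documents the detector's model, its tunable parameters, the
synthetic data the test suite runs on, and the numerical and design
choices made where the design was genuinely open.

## Detection model

The detector assumes an HFO appears as a short-lived event with an
isolated spectral peak: energy standing out from the band-passed
background in time (Stage 1) *and* a high-frequency peak separated from
low-frequency activity by a spectral trough at every instant of the
event's core (Stage 2). Events that ring the filter without possessing an
isolated spectral peak — sharp interictal spikes, steps, pops — fail the
second condition even when they pass the first.

### Stage 1 parameters

| parameter | default | meaning |
| --- | --- | --- |
| band | 80–500 Hz | detection band; elliptic (Cauer) IIR band-pass |
| stopband attenuation | 60 dB | at and beyond 10 Hz outside the band edges |
| passband ripple | 0.5 dB | |
| transition width | 10 Hz | lower and upper |
| envelope threshold | mean + 3 SD | of the Hilbert envelope over the whole epoch |
| event bounds | crossings of θ/2 | half-threshold full width |
| minimum duration | >6 ms | strict inequality |
| merge gap | <10 ms | closer events merged, peak = larger envelope peak |
| peak rule | ≥6 peaks > mean + 2 SD | local maxima of the rectified filtered trace |

The filter order is the minimum meeting the constraints at the given
sampling rate (`scipy.signal.ellipord`; order 11 at 2000 Hz), verified
stable. Zero-phase filtering is forward–backward; the edge padding is
sized from the slowest pole's settle time (≈9700 samples at 2000 Hz for
the default design) because the sharp elliptic design places poles at
|p| ≈ 0.9993 and scipy's default padding would let edge transients bleed
far into the epoch. Statistics use the population SD (divisor N); with
≥10^5-sample epochs the distinction is irrelevant, fixing it makes runs
deterministic. All thresholds are relative to the data's own scale, so
detection is invariant under global amplitude scaling.

The "mean baseline signal" of the peak rule is read as the epoch-level
mean and SD of the rectified filtered trace — one consistent statistic
rather than a locally re-estimated baseline.

### Stage 2 parameters

| parameter | default | meaning |
| --- | --- | --- |
| analysis window | 1 s | raw (unfiltered) signal around the envelope peak |
| valid region | central 0.5 s | outer quarters absorb boundary effects |
| HiFP range | 60–500 Hz | lower edge avoids 50 Hz line hum |
| trough range | 40 Hz–HiFP | spectral argmin |
| trough depth | P(trough)/P(HiFP) < 0.8 | |
| peak height | P(HiFP)/P(LoFP) > 0.5 | |
| artifact bound | argmax > 500 Hz → reject | global argmax over [60, fs/2] |
| class split | 200 Hz | ripple below, fast ripple at or above |

The Stockwell transform uses the canonical frequency-dependent Gaussian
window σ(f) = 1/f, computed in the frequency domain on the full 1 Hz grid
(0–fs/2 for a 1 s window at integer fs). The zero-frequency row is the
window mean. Two identities anchor the implementation: the time-marginal
of S(τ, f) equals the window's Fourier spectrum (machine precision), and
tones localize to within 1 Hz.

Both ratio criteria are evaluated on **linear** power (µV²/Hz). Ratios of
dB values depend on the reference unit and can change sign; linear ratios
are scale-free and match the physical reading of a power ratio. A dB mode
remains switchable (`Stage2Params(ratio_domain="db")`) for comparison.

The FWHM support is the contiguous run around the envelope peak where the
envelope is at least half its peak *and* at least the Stage-1 threshold
(the intersection reading), clipped to the valid central half-second.
Acceptance requires every instantaneous spectrum in the support to pass;
the recorded rejection reason is that of the first failing instant, and
the characteristic HiFP/trough/LoFP triplet is taken at the envelope
peak. A monotone spectrum — trough coinciding with the HiFP — is recorded
as `no_trough`; a spectrum with no local maximum below the trough as
`no_lofp` (the HiFP/LoFP criterion is then undefined, and the event is
rejected). "Local maximum" means a strict one-bin neighbourhood maximum
on the 1 Hz grid, plateaus resolving to their highest-frequency bin.
Accepted events with HiFP below 80 Hz keep their true peak frequency and
fall in the ripple bin, so ripples and fast ripples partition all
accepted events.

### Baselines

The RMS detector band-passes 100–500 Hz, takes a 3 ms moving RMS,
thresholds at mean + 5 SD of the trace, applies the same >6 ms / <10 ms
duration and merge rules, and rejects events with fewer than 6 rectified
peaks above mean + 3 SD. The line-length detector band-passes 80–500 Hz
and replaces the RMS by the moving sum of absolute first differences
(offset-invariant by construction); no peak rule is described for it and
none is applied. The line-length window is not specified anywhere we
could find, so it defaults to 3 ms to parallel the RMS window
(configurable). "Five times the SD of the mean energy" is read as
threshold = mean + 5·SD of the feature trace, consistent with Stage 1's
formulation. Baseline events feed the half-maximum channel ranking
directly; they do not pass through Stage 2.

### Evaluation

The HFO area is { c : rate(c) > max rate / 2 } — strict, so a channel at
exactly half the maximum is excluded and the maximal channel is always
included. Sensitivity and specificity are integer percentages (half away
from zero; this rounding reproduces the published worked examples, e.g.
15/16 → 94). With an empty SOZ, sensitivity is undefined and reported as
None; with no negative channels the false-positive rate is taken as 0.
Confidence intervals are Clopper–Pearson (statsmodels `method="beta"`):
the published intervals match no single standard method across all rows,
so CIs are reported but not used as pass/fail quantities. A
Kittler–Illingworth minimum-error threshold on the rate histogram is
available as an alternative channel-selection rule
(`evaluation.kittler_area`) but is not scored.

## Synthetic data

The generator emulates the target recording conditions: multichannel
2000 Hz epochs (5 min by default) of 1/f background scaled to 20 µV RMS,
with per-channel Poisson event trains (dead time 200 ms, 0.6 s edge
margins) of:

* **HFO bursts** — Tukey(0.25)-windowed sinusoids, frequency uniform
  60–500 Hz, 6–12 cycles (duration floored at 6 ms), amplitude = SNR ×
  the 80–500 Hz band-limited background RMS (default SNR 8). The taper
  keeps spectral splatter below the >500 Hz artifact-rejection region.
* **Spikes (IES)** — a sharp cusp (τ = 2.5 ms) riding a Gaussian
  sharp-wave body (σ floored at 4 ms, 2.5× the cusp) with an
  opposite-polarity after-wave; total width 20–70 ms. The amplitude
  multiplier (5–20× background RMS) scales the cusp; the overall peak is
  ≈3.4× that, i.e. several hundred µV — the large-spike regime in which
  filter ringing produces "false ripples". The body keeps the
  instantaneous spectrum a smooth continuum falling from low to high
  frequency, so Stage 2 rejects these events for lack of a trough, which
  is the published phenomenology.
* **Artifacts** — 1–3-sample impulses or brief steps at 20–50× background
  RMS. The S-transform magnitude of an impulse grows ∝ f, so its
  instantaneous spectral peak falls above 500 Hz and the artifact bound
  rejects it.

Everything derives from one seed; generation is bit-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about clinical data: physiological (non-epileptic) HFOs,
state-dependent background (sleep spindles, alpha), electrode drift,
line hum, overlapping event morphologies, and spikes *with* genuine
superimposed oscillations in arbitrary phase relationships. Events are
non-overlapping within a channel by construction.

Two measured properties of the detector on this synthetic data are worth
recording. First, pure sinusoidal bursts below ~80 Hz cannot pass
Stage 1 — the band-pass removes them — so sub-80 Hz events are detected
only when harmonics or co-occurring broadband activity carry them through
Stage 1, after which Stage 2 accepts them with their true (sub-80) peak
frequency. The sensitivity property test therefore plants bursts in the
band interior (80–480 Hz), where event-level sensitivity and precision
exceed 0.9 at SNR 8; bursts within ~20 Hz of the 500 Hz edge can
additionally splatter past the artifact bound. Second, six-cycle bursts
at low frequencies sit near the ≥6-peak rule's limit (the Tukey taper
weakens edge cycles), so the shortest admissible events are detected with
reduced probability — a faithful property of the peak rule, not of the
implementation.

## Problem sizes

Unit tests run on 2–20 s single-channel epochs. The oracle-equivalence
check uses 100 random 2 s signals. Rejection-rate checks collect 100
Stage-1-passing candidates from 5-minute 4-channel recordings. The
end-to-end recovery study uses ten 60 s, 8-channel studies (two planted
channels at 10 HFOs/min, SNR 8, off-target 0.5/min) — one minute of data
suffices for stable channel ranking at these rates, and the acceptance
script repeats the same sizes.

## Known limitations

* EDF output is 16-bit; round-trip precision is bounded by the physical
  range over 2^16. The delimited text format round-trips to <1e-6 µV.
* The detector requires fs ≥ 2000 Hz and epochs ≥60 s (threshold
  statistics); it warns on common-reference montages rather than
  refusing, since the mathematics is montage-agnostic.
* Ripple/fast-ripple co-occurrence at one event is not modelled: an event
  is classed by its single characteristic HiFP.
* The S-transform's frequency smoothing (σ_f = f/2π) broadens spectral
  peaks relative to a same-resolution Fourier spectrum; its advantage is
  time localization and stable instantaneous estimates, not frequency
  sharpness. Peak frequencies of accepted events carry ~±(f/2π) Hz of
  systematic blur at high frequencies.
* Memory per validated event is one (fs/2+1) × fs power map (~16 MB at
  2000 Hz in float64), bounding throughput at roughly 10 events/s/core.
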