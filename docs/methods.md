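# Methods

This note documents the models, defaults and numerical conventions behind
`osstap`, and what the synthetic data can and cannot establish.

## Synthetic impaction sounds

A hammer blow is modelled as modal ringing: a sum of exponentially damped
sinusoids `a_i · exp(−t/τ_i) · sin(2π f_i t)`. The default eight modes sit at
0.4, 1.2, 2.9, 4.4, 8.7, 12, 16.5 and 19 kHz so that every analysed frequency
band contains energy; amplitudes decrease and decay rates increase with
frequency (τ from 30 ms down to 4 ms), as they do for flexural modes of
bone–implant constructs. Blows arrive at 1.0 ± 0.2 s (uniform jitter, enough
to keep bursts non-overlapping), on a Gaussian noise floor 50 dB below the
burst peak. Two lognormal jitters give blows individual character: a
whole-blow amplitude factor (σ = 0.15, varying hammer force — removed again
by energy normalization) and a per-mode factor (σ = 0.15) that is the sole
source of between-blow spectral variance. The per-mode σ was set so that the
fit-vs-fracture low-band effect lands at Cohen's d ≈ 1–2, the magnitude
class reported for real recordings, rather than the d ≈ 5 a nearly
deterministic spectrum would give.

Anchorage conditions act multiplicatively on modal power:

| parameter | default | meaning |
|---|---|---|
| `low_band_gain` (fracture) | 1.37 | power factor on modes < 2.5 kHz, calibrated on the noiseless modal model so the normalized low-band amplitude fraction rises by +0.062 over fit |
| `high_band_atten` (fracture) | 0.25 (−6 dB) | power factor on 15–20 kHz modes; the literature reports only a "sharp drop", so the magnitude is a package choice sized to make the high-frequency clusters detectable at four recordings per condition |
| fracture 8.5–8.9 kHz shift | −1 dB | the mid-frequency deficit that accompanies cortical cracking; renormalization alone (more mass below 2.5 kHz ⇒ less everywhere else) under-produces it at realistic variance |
| loose band shifts | +0.2 dB low, −0.2 dB at 2.9/4.4 kHz | the subtle loose→fit contrast: seating moves energy from the fundamental into the first two high bands, with amplitude ≤ 0.2 dB |

`modal_band_energy` gives the exact discrete energy of each mode via a
closed geometric-series form; it is the ground-truth oracle the tests
compare against direct summation (relative tolerance 10⁻⁶) and against the
sign of recovered band-power differences.

What the generator does **not** emulate: femur-specific modal structure
(a finite-element model would be needed), room reverberation, microphone
transfer functions, mode-frequency drift while the stem seats, and
specimen-level random effects (all blows of a condition share one modal
model up to iid jitter). Passing tests therefore demonstrate that the
pipeline recovers effects of the injected kind at realistic magnitudes and
sample sizes — not that real operating-room recordings would behave
identically.

## Segmentation

Spectral flux (positive frame-to-frame magnitude increase, Hann window,
frame 2048, hop 512) is peak-picked with a robust threshold
(median + 10·MAD-σ of the flux, 0.3 s refractory period). A flux frame only
localizes the attack to within one frame, so the detector first climbs to
the short-time-energy maximum inside that span (window 128, hop 32 samples)
and then back-tracks to the preceding local energy minimum — the last quiet
instant before the burst. On the synthetic benchmark this places onsets
within ~9 ms before to ~1 ms after the true burst start, and recall =
precision = 1.00 over 50 recordings × 30 blows.

Segments are cut to exactly `fft_length` samples (zero-padded at the
recording tail); the default `fft_length = 35280` (0.8 s at 44.1 kHz) gives
1.25 Hz bins so that the 20-bin cluster-merge gap equals 25 Hz. No analysis
window is applied: the transients are naturally time-limited and windowing
would only blur band edges. Total energy is Σx² of the un-padded content;
segments with energy strictly below 5 % of the median (median over all
segments of the recording, before any removal) are discarded — a segment at
exactly the threshold is kept. The normalized spectrum divides |FFT| by its
sum, making every retained spectrum sum to 1 (checked to 10⁻⁹) and the
pipeline invariant to any positive rescaling of the input.

## Spectral statistics

*Unit of observation.* The individual hammer blow, pooled across specimens
within a condition. This inherits pseudoreplication (blows from one
specimen are not independent); a hierarchical model is out of scope and the
group-level claims should be read accordingly.

*Band tests.* Band power is the sum of normalized amplitudes over bins with
`lo ≤ f ≤ hi` (inclusive edges). Δµ is the mean band power of the second
set minus the first, so "fit–fracture" positive means more energy in
fracture. The permutation test shuffles labels of the per-blow band powers
and compares |t| (equal-variance form); when C(n_A+n_B, n_A) ≤ n_perm all
splits are enumerated and p is exact (a 4-vs-4 design has 70 splits),
otherwise p uses the add-one convention (observed statistic counted in its
own null), so p is never 0. Cohen's d = Δµ / pooled SD (n−1 denominators).
|t| comparisons use a 10⁻¹² relative tolerance so splits that tie in exact
arithmetic are not separated by float rounding.

*Cluster test.* Bin-wise equal-variance t with df = n_A+n_B−2; bins with
two-tailed p < α (default 0.05) are supra-threshold. Same-sign
supra-threshold bins whose index gaps are ≤ `max_gap_bins` (default 20)
merge into one cluster; opposite signs never merge (a mixed-sign mass would
be uninterpretable). Cluster mass is Σ|t| over the supra-threshold member
bins only — gap bins contribute span but not mass. The family-wise null is
the maximum cluster mass per label permutation (0 when a permutation yields
no cluster), and corrected p-values again use add-one. Under the null the
probability of any significant cluster calibrates to ≈ 0.05 (slightly
conservative, as add-one implies); an effect injected into bins 800–1000 of
a 1200-bin grid is recovered as exactly one overlapping significant cluster
in ≥ 95 % of runs.

*KS test.* Each (blow, bin) normalized amplitude is one observation; the
two conditions' pooled samples (n = blows × bins each) enter
`scipy.stats.ks_2samp` with the asymptotic two-sided p. This pooled
definition is what makes the huge sample sizes — and the correspondingly
extreme p-values — possible; it treats bins as exchangeable observations
and is intended as a global screen, not a calibrated test.

## Micromotion

The torque protocol ramps 0 → +max → −max → 0 per cycle, each ramp in
`n_steps` increments; two cycles give 3·80·2 = 480 measurements per series
with each rotation-direction extreme reached twice. (The published protocol
description — "80 incremental steps" and "480 measurements per series" —
does not pin down the ramp layout uniquely; this decomposition satisfies
both counts and is the package's documented choice.) Torque amplitude is
3.5 Nm for loose/fit and 1.75 Nm for fracture specimens.

Normalized rotational stability is the least-squares slope of angle vs
torque over the full hysteresis loop of one series, averaged over the three
replicate series. Loading-only fitting would be an alternative reading; for
the linear synthetic model both coincide.

Cube pose: a gap sensor with unit normal n at cube point r (mm) reads
`n·(t + ω×r)` for small rigid displacements (t in µm, ω in mrad), giving a
9×6 least-squares system; the default 3-3-3 geometry (three sensors per
orthogonal face of a 20 mm cube, 6 mm in-face offsets) has rank 6. Readings
are quantized to the 0.1 µm sensor resolution, which bounds the Z-rotation
error by ≈ 0.05 µm / 6 mm ≈ 0.48 mdeg; recovery is exact without
quantization.

Relative micromotions interpolate the prosthesis compliance linearly in
marker height from (P_p, P_d) to the heights of B1 and B2 (extrapolation
allowed when a bone marker lies outside the prosthesis span). Marker
heights default to B1 = +45, B2 = −30, B3 = −80 mm about the lesser
trochanter; prosthesis markers default to P_p = +55 mm and a size-dependent
tip height (−45…−60 mm for stem sizes 4–7) — the tip heights are package
defaults, configurable per prosthesis.

Group simulation draws per-specimen rm1/rm2 from lognormals moment-matched
(σ² = ln(1+(sd/mean)²), µ = ln mean − σ²/2) to the benchmark group moments;
a lognormal is used because the loose group's sd exceeds its mean, which
would give a Gaussian substantial negative mass. rm1 and rm2 are drawn
independently. The five marker compliances are then constructed to be
exactly consistent with the drawn values (bone markers share a 0.5 mdeg/Nm
baseline), so the noiseless round trip recovers them to machine precision.
Note that with n = 4 specimens the hierarchy of group *sample* means
fracture < fit < loose is itself a stochastic event (the fit and fracture
rm2 distributions overlap); it holds in ≈ 90–97 % of simulated studies.

Group inference uses scipy's Kruskal–Wallis (midranks, tie correction,
χ² reference) plus exact two-sided Mann–Whitney pairwise tests. At
n = 4 + 4 the smallest attainable exact two-sided p is 2/70 ≈ 0.029, so the
pairwise p-values are reported for completeness rather than treated as a
benchmark.

## Reproducibility and problem sizes

Every generator and permutation test takes an explicit seed; the pipeline
splits one master seed into per-stage children via
`numpy.random.SeedSequence.spawn` and records all seeds, tunables and a
config hash in its manifest, so identical configurations reproduce all
tables byte-identically.

The shipped test suite and acceptance script run the statistical
simulations at deliberately modest sizes — 0.1 s analysis windows for the
calibration studies, 100 null simulations × 199 permutations for the
family-wise calibration, 50 runs for effect recovery, four recordings ×
10 blows per condition at the full 35 280-sample window for the
fingerprint — sizes at which the qualitative conclusions are already
stable. All defaults scale up: the pipeline's `n_perm` defaults are 10 000
(band) and 1 000 (cluster).

## Known limitations

- The acoustic generator is phenomenological, not a vibro-acoustic femur
  model; absolute cluster masses and KS statistics depend on its variance
  structure and should not be read as predictions for real recordings.
- Blow-level pooling inherits pseudoreplication from the study design.
- The high-frequency attenuation magnitude at fracture and the prosthesis
  tip-marker heights are package choices where the literature gives none.
- The cluster-forming threshold uses the equal-variance t; Welch would be
  preferable for strongly unequal group variances.
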