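# osstap

**O**rthopaedic **s**hort-**s**tem **t**apping **a**nd **p**rimary-stability
analysis: a Python toolkit for assessing how well an uncemented femoral short
stem is anchored in bone, from two complementary measurements:

1. **Impaction acoustics.** Every hammer blow that seats the stem emits a
   transient whose spectrum depends on the stem–bone coupling. The package
   segments recordings into individual blows (back-tracked spectral-flux
   onset detection), converts each blow to an energy-normalized single-sided
   amplitude spectrum `P1_norm = |FFT| / Σ|FFT|`, discards segments whose
   total energy falls below 5% of the median, and compares conditions with
   three tiers of statistics: global two-sample Kolmogorov–Smirnov tests on
   pooled bin amplitudes; band-wise permutation *t*-tests (Δµ, Cohen's *d*)
   on four canonical regions of interest (0–2.5, 2.7–3.1, 4.2–4.6,
   8.5–8.9 kHz); and a one-dimensional cluster-permutation test in which
   same-sign supra-threshold bins ≤ 20 bins (≈ 25 Hz) apart merge into
   clusters whose mass Σ|T| is tested against the permutation null of the
   maximum cluster mass (family-wise control).

2. **Torsional micromotion.** Torque sweeps (±3.5 Nm, 480 measurements per
   series) applied about the stem axis yield a normalized rotational
   stability (mdeg/Nm, the angle-vs-torque regression slope) at bone markers
   B1/B2/B3 and prosthesis markers P_p/P_d, with marker poses reconstructed
   from nine eddy-current gap sensors by a small-angle rigid-body
   least-squares fit. Relative micromotions rm1 = P_p − B1 and
   rm2 = P_d − B2 (prosthesis compliance linearly interpolated to the
   bone-marker heights) separate three anchorage states — *loose*, *fit*
   (optimal press-fit), and over-press-fit to cortical *fracture* — with the
   characteristic hierarchy fracture < fit < loose. Groups are compared with
   Kruskal–Wallis and exact Mann–Whitney tests.

Because no public recordings of stem impaction exist, the package ships a
first-class synthetic-data module (`osstap.synthetic`): blows are sums of
exponentially damped sinusoids whose modal powers encode each anchorage
condition (fracture boosts < 2.5 kHz power by ≈ +6 % of the spectral mass
and damps 15–20 kHz by −6 dB; loose differs from fit by ≤ 0.2 dB band
shifts), and micromotion groups are drawn from lognormals moment-matched to
the published benchmark. The intended users are biomechanics and surgical-
acoustics researchers who want a reproducible reference pipeline for
impact-sound stability monitoring.

## Worked example

```python
from osstap import synthetic, segmentation, spectral

sets = {}
for condition, seed in (("fit", 100), ("fracture", 200)):
    spectra = []
    for i in range(4):  # four simulated specimens, 10 blows each
        rec = synthetic.generate_impaction_recording(condition, n_blows=10, seed=seed + i)
        spectra.extend(segmentation.segment_recording(rec).spectra)
    sets[condition] = segmentation.SpectrumSet(condition, spectra)

low = spectral.band_permutation_test(sets["fit"], sets["fracture"],
                                     spectral.ROI_BANDS[0], n_perm=2000, seed=1)
print(f"low band (0-2.5 kHz): delta_mu = {low.delta_mu:+.3f}, "
      f"p = {low.p_value:.4f}, d = {low.cohens_d:+.2f}")

clusters = spectral.cluster_permutation_test(sets["fit"], sets["fracture"],
                                             n_perm=400, seed=2)
for c in clusters:
    if c.significant and c.freq_lo > 15000:
        print(f"cluster {c.freq_lo:.0f}-{c.freq_hi:.0f} Hz: "
              f"mass = {c.mass:.0f}, p = {c.p_corrected:.4f}, sign = {c.sign:+d}")
```

prints

```
low band (0-2.5 kHz): delta_mu = +0.062, p = 0.0005, d = +1.92
cluster 15819-17604 Hz: mass = 5697, p = 0.0025, sign = -1
cluster 18676-20655 Hz: mass = 5137, p = 0.0025, sign = -1
```

i.e. the fracture condition carries ≈ 6 % more of its spectral mass below
2.5 kHz (a large, significant effect) and shows two broad, strongly
significant high-frequency deficits above 15 kHz — the acoustic signature of
a cortical crack damping the stiff flexural modes.

The micromotion side, on the published per-specimen benchmark values:

```python
from osstap import micromotion
from osstap.datasets import metha_micromotion

df = metha_micromotion()
for cond, grp in df.groupby("condition", sort=False):
    mean, sd = micromotion.group_summary(grp["rm1_mdeg_per_nm"])
    print(f"{cond:9s} rm1 = {mean:7.2f} ± {sd:.2f} mdeg/Nm")
groups = {c: g["rm1_mdeg_per_nm"].to_numpy() for c, g in df.groupby("condition", sort=False)}
kw = micromotion.kruskal_wallis_with_pairwise(groups)
print(f"Kruskal-Wallis H = {kw.h_statistic:.3f}, p = {kw.p_value:.4f}")
```

```
loose     rm1 =  132.78 ± 171.40 mdeg/Nm
fit       rm1 =    4.42 ± 2.43 mdeg/Nm
fracture  rm1 =    1.67 ± 0.60 mdeg/Nm
Kruskal-Wallis H = 8.769, p = 0.0125
```

A command-line interface covers the same ground
(`osstap simulate | segment | spectra | micromotion | run-all`); for example

```bash
osstap simulate --condition fracture --blows 30 --seed 7 -o frac.wav
osstap run-all --seed 0 -o results/ --blows 10
```

writes the full results bundle (`ks.csv`, `bands.csv`, `clusters.csv`,
`table4.csv`, spectra and motion-graph plots, and a manifest that records
every tunable and seed; re-running the same configuration reproduces every
table byte-identically).

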