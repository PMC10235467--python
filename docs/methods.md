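# Methods

`lnvlight` analyzes two kinds of Drosophila data — patch-clamp voltage traces from
large ventral lateral neurons (l-LNvs) under timed light stimulation, and
TriKinetics activity-monitor records under a nighttime light-pulse protocol — and
ships synthetic generators that emulate the statistical structure both analyses
assume. Because the measurements this package targets are group summaries (firing
-frequency ratios, arousal percentages) rather than deposited raw recordings, the
package's validation strategy is *parameter recovery*: the generators take the
published group values as generative parameters and the analysis chain must recover
them end to end.

## Electrophysiology arm

### Sweep protocol and firing-frequency statistics

Each recording consists of five repeated sweeps: 50 s of darkness (baseline), 5 s of
monochromatic LED light (365, 405, 450 or 635 nm at 200 µW/cm²), then 95 s of
darkness. Spikes are counted in half-open 10-s bins aligned to the protocol; a spike
at exactly lights-on belongs to the light-on window.

The core statistic is the firing-frequency (FF) ratio

    FF ratio = (light-on count / 5 s) / (pre-light count / 50 s),

i.e. both numerator and denominator are converted to rates before dividing. The
source protocol descriptions can be read either as a count ratio or a rate ratio
over these unequal windows; a raw-count reading would halve all reported magnitudes
relative to the published group values (≈1–2 against ≈4-Hz baselines), so the rate
convention is adopted and declared here rather than inferred as fact. The analyzed
window is the first 105 s of the 150-s sweep (5 pre bins + light + 5 post bins); the
post-stimulus profile divides each 10-s post bin (as Hz) by the same baseline rate.
Per-cell values are means over that recording's five sweeps; group summaries are
mean ± SEM over cells. Cells with zero baseline spikes have an undefined ratio and
are excluded from aggregation with the exclusion counted — never given an infinite
ratio.

### Spike detection

Detection operates on the zero-phase high-pass-filtered trace (2nd-order
Butterworth, 50 Hz cutoff), which removes the resting potential, slow drift and the
DC depolarization step during the light without displacing spike peaks. The
threshold is 5 robust standard deviations of the filtered signal, with sigma
estimated as MAD/0.6745 (the standard robust convention in extracellular spike
sorting); one event is emitted per suprathreshold excursion at its peak sample, and
events closer than the 2-ms refractory floor are collapsed with a logged collision
warning. Clipped plateaus (≥ 5 ms flat at the trace extremes) are reported.
Constraints: the sampling rate must be ≥ 1 kHz to resolve the 2-ms waveform, and
the light-step amplitude must stay below the detection threshold (true at the
generator defaults: 5 mV step vs ≈10 mV threshold at 2 mV noise). On generator
output at default noise, detection sensitivity and precision both exceed 0.99.

### Synthetic traces

The generator is deliberately *not* a biophysical membrane model: the analysis
consumes only spike counts, and l-LNv firing is predominantly tonic at these rates,
so spikes are drawn from an inhomogeneous Poisson process with a 2-ms absolute
refractory period (thinning construction). The rate profile is

    r(t) = r_base                                   t < t_on
           r_base · k_λ                             t_on ≤ t < t_off
           r_base · (1 + (k_λ − 1) e^−(t−t_off)/τ_λ)  t ≥ t_off,

with τ_λ = 0 meaning an immediate return to baseline. With a 2-ms dead time the
realized stationary rate is r/(1 + r·τ_ref), a < 1% correction at 2–5 Hz, so the FF
estimator recovers k_λ essentially unbiased.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `baseline_rate` | per genotype, 2.4–5.2 Hz | tonic dark firing rate |
| `fold_change[λ]` | per genotype × wavelength table | light-on rate multiplier k_λ |
| `decay_tau[λ]` | control: 6/12/25/0 s (UV/violet/blue/red); mutants: 3/5/8/0 s | post-stimulus persistence |
| `refractory` | 2 ms | absolute dead time |
| `spike_amplitude` | 40 mV | biphasic 2-ms template height |
| `noise_sd` | 2 mV | Gaussian membrane noise |
| `depolarization_dc` | 5 mV | DC step during light |
| sampling rate | 10 kHz (floor 1 kHz) | trace resolution |

No quantitative decay constants are published; the τ_λ defaults are qualitative
reconstructions of the reported persistence ordering (blue ≈ 20–30 s in controls,
shorter for violet and UV, none for red; weaker in mutants) and are
config-overridable. They do not affect the FF ratio or baseline statistics, only
the post-stimulus profile. Each cell draws its recording time uniformly from
ZT0–16 with no time-of-day effect on rate, matching the absence of a baseline/ZT
correlation in the data being emulated; the pipeline reports the descriptive
baseline-vs-ZT Pearson correlation.

Determinism: every sweep's spikes and noise derive from
SHA-256(master seed | genotype | cell | sweep | stream), so cohorts are
byte-identical across reruns and platforms.

## Behavior arm

### Sleep and arousal scoring

Sleep uses the standard Drosophila criterion — a minute is asleep iff it lies in a
maximal run of ≥ 5 consecutive zero-count minutes (the source assay presupposes
sleep/wake without defining it; the field default is the least surprising choice
and is overridable). For each 5-min pulse (ZT18/19/20, three nights), a fly enters
the denominator iff the five minutes before onset are all zero, and is aroused iff
it registers ≥ 1 beam crossing within the pulse window (no post-pulse grace; a
window extension is a config option). Flies silent over the final 24 h are excluded
as dead. The total average is denominator-weighted
(Σ aroused / Σ asleep across the nine pulses); an unweighted mean-of-nine option
exists because the published aggregation convention is unstated. Per-night means
are reported for the night-consistency check.

### Synthetic monitor data

Each fly is an alternating renewal process. Sleep bouts are 5 min plus an
exponential tail (night mean 45 min, day mean 20 min), so every generated bout
satisfies the 5-min criterion; wake bouts are exponential (night 10 min, day
60 min, minimum 1 min) and every awake minute registers 1 + Poisson(mean − 1)
crossings (mean 2/min). Making awake minutes never silent is a deliberate
idealization: zero-count minutes then coincide exactly with sleep minutes, so the
analysis-side classifier and the generator agree on ground truth and arousal
recovery is unbiased. Real flies show quiet wakefulness; consequences for real data
are discussed under limitations.

At each pulse onset, a fly that slept through the preceding minute awakens with the
per-condition Bernoulli probability p_arousal (the generative analogue of the
published "% flies that awaken"); an aroused fly emits activity for a geometric
number of minutes (mean 10). A fly that sleeps through has its bout extended past
the pulse window — the literal reading of "otherwise its bout continues". Without
that extension, natural terminations of exponential bouts inside the 5-min window
(≈ 10% for 45-min bouts) would inflate recovered arousal by several percentage
points, more than the recovery tolerance for the weakest responders. Flies whose
sampled bout end coincides with the onset minute are likewise governed by the coin,
so pulse-window activity from a sleeping fly occurs exactly when the coin says so.

Cohorts default to 32 flies per condition (one full monitor; per-genotype counts
are not published) over 4 recorded days with pulses on nights 1–3, yielding ≈
230–260 scored pulse events per condition. Recordings start at ZT0 (lights-on
08:00 local); monitor files store local time and a ZT0 reference hour supplied as
sidecar metadata, since the 42-column dialect has no metadata block.

## Inference layer

Each pairwise comparison runs Anderson–Darling normality on both samples at
α = 0.05 (either failing routes to Mann–Whitney — the conservative reading of the
source's non-normal fallback); normal pairs take a two-sided F-test at α = 0.05 to
choose pooled vs Welch, then a one-tailed t. The published α of "0.5" is read as a
typo for 0.05. Mann–Whitney uses exact enumeration for group sizes ≤ 20 without
ties, otherwise the tie-corrected normal approximation. Tail directions are always
explicit configuration (light-response families test control > mutant), never
inferred from the data. Families are one per wavelength (ephys) or per
wavelength × intensity (behavior) — all control-vs-mutant comparisons annotated
together — and are BH-adjusted with rejection at q = 0.1 and tiers * < 0.1,
** < 0.05, *** < 0.01 (exclusive boundaries). The exact family boundaries used in
the source are unstated; per-panel families are this package's documented choice.

## Numerical and scale choices

- Rate profiles are sampled at 1 ms for thinning; segment boundaries land on the
  grid so light-window rates are exact.
- Spike times sit on the sample grid when rendered; detection recovers them within
  ±1 ms (one filtered-peak sample).
- Protocol binning uses half-open intervals throughout; ties at bin edges go to the
  later bin except lights-on, which claims its boundary spike.
- The replicate-heavy checks (20-replicate blue-light significance pattern,
  null-family false-discovery rate) run at reduced trace resolution (2.5 kHz) or at
  spike-train level; detection fidelity is validated separately at 10 kHz, and the
  statistics under test do not depend on trace resolution above the 1-kHz floor.
  Recovery checks for the headline quantities run at the full 10 kHz and the
  recorded cohort sizes.

## Limitations

- The generators emulate group-level statistical structure, not biophysics: no
  subthreshold dynamics, bursting, adaptation, or intensity–response curves.
  Passing recovery tests demonstrates that the analysis chain is unbiased and
  self-consistent under these conditions, not that it is robust to artifacts real
  rigs produce (electrode drift, seal loss, bursting cells).
- Quiet wakefulness is absent from the behavior generator; on real monitor data the
  5-min rule misclassifies some quiet-wake minutes as sleep, and the arousal
  denominator inherits that bias. The scoring rules themselves are the field
  standard and apply unchanged to real files.
- Between-fly and between-cell heterogeneity is not modeled (all cells of a
  genotype share one rate; all flies share one p_arousal), so simulated group SEMs
  reflect only counting noise and are smaller than published SEMs.
- Post-stimulus decay constants are qualitative reconstructions; the post-bin
  profile should not be read as a quantitative fit to the published decay data.
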