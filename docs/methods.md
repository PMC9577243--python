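# Methods

This note documents the models, defaults and numerical choices behind
`nirsnet`, and what the synthetic-data generator does and does not emulate.

## Experimental model

The package targets block-design fNIRS over both sensorimotor cortices:
24 source–detector channels (12 around C3, 12 around C4, 3 cm separation)
sampled at 10 Hz, four conditions (Rest, MV, MO, MOV), 10 s tasks followed
by rests drawn uniformly from 25–30 s, four sessions of ten tasks each.
Condition counts are balanced globally: a pool with total/4 blocks per
condition is shuffled with the seed and chunked into sessions (a design with
10 tasks per session cannot be balanced within sessions over 4 conditions;
global balance gives each condition exactly 10 occurrences). Sessions sit on
one continuous time axis separated by a 180 s gap, with 30 s of quiet before
each session's first onset.

The default montage fixes the right-hemisphere channel set
(S1–S5 × D1–D4, 12 channels) and seven homotopic pairs from the published
layout; the remaining left-hemisphere channels and pairs are completed by a
mirror map of the grid (S1→S7, S2→S6, S3→S8, S4→S10, S5→S9; D1→D5, D2→D7,
D3→D6, D4→D8), chosen to be consistent with all seven published pairs.
Montages are plain data and can be replaced wholesale.

## Forward model (synthetic subjects)

Each task block contributes a hemodynamic response: a canonical double-gamma
HRF (gamma shapes 6 and 16, undershoot ratio 1/6 — the community default,
as the source experiment does not state one) convolved with the 10 s task
boxcar and normalised to unit peak, scaled by the condition's per-hemisphere
peak amplitude. Default amplitudes (left, right, µMol/L):

| condition | left | right | rationale |
|---|---|---|---|
| Rest | 0 | 0 | contrast condition (enforced) |
| MV | 0.03 | 0.30 | vibrotactile: strong, highly asymmetric |
| MO | 0.08 | 0.15 | visual-only: weaker and less asymmetric |
| MOV | 0.05 | 0.30 | combined: strong, asymmetric |

Left-hand tasks drive the contralateral (right) hemisphere. Amplitudes were
fixed so that a 14-subject cohort reproduces the qualitative group-level
pattern reported for this paradigm — vibrotactile conditions significantly
stronger than MO at 5 s in most right-hemisphere channels, strong
lateralization for MV/MOV, weak for MO, none at Rest — and are exposed in
`SimulationConfig`. A per-subject gain (CV 0.2) and per-block jitter
(CV 0.1) model inter- and intra-subject variability; the ground-truth
manifest records the realised per-block, per-channel amplitude. HbR is
−1/3 of the HbO response plus independent noise at 30% amplitude.

Noise comprises cardiac (1.2 Hz, 0.05 µM), respiration (0.25 Hz, 0.03 µM)
and Mayer-wave (0.1 Hz, 0.02 µM) sinusoids with random phase per channel, a
linear drift (±0.05 µM over the recording), white noise (sd 0.05 µM), and a
spontaneous low-frequency oscillation — white noise low-passed at 0.08 Hz,
sd 0.1 µM. The LFO term matters: real resting HbO is dominated by slow
spontaneous fluctuations of the same order as evoked responses, and without
it the Rest condition's laterality index is governed by tiny filter-undershoot
residues of neighbouring task blocks rather than by physiological
variability, producing spurious group lateralization no real cohort would
show. All noise parameters are config-exposed; none is stated in the source
experiment beyond the component names.

Directed couplings (`receiver_t += gain · driver_{t−lag}`) provide
Granger-causality ground truth. Condition-tagged couplings act only inside
that condition's 20 s task windows, so the planted effect is
condition-specific after block averaging; untagged couplings act over the
whole series. Defaults plant 6 couplings under MV (5 right→left, 1
left→right, gains 0.7–0.9), 3 under MOV, 2 under MO and none under Rest,
mirroring the reported ordering (MV densest, right→left dominant, Rest
sparsest). A side effect worth knowing: a coupling into a left-hemisphere
channel adds activity there and *lowers* the LI of that homotopic pair —
cross-hemisphere drive and lateralization trade off, as they would in vivo.

The optical forward model inverts the modified Beer–Lambert law at 760 and
850 nm with DPF 6.0 and a standard molar-extinction table, so that
`intensity_to_od` followed by `od_to_hb` recovers the input concentrations
to < 1e−6 µM (verified round-trip). Wavelengths, DPF and the table are
config-exposed; the source experiment names none of them.

## Preprocessing

* OD conversion uses the stored per-trace reference intensity when present
  (the simulator writes one), else the per-trace mean — the continuous-wave
  convention.
* The Beer–Lambert inversion solves the 2×2 system per channel and sample;
  a singular extinction matrix (wavelengths that cannot separate HbO from
  HbR) is an error.
* The bandpass is a 4th-order Butterworth applied forward–backward
  (`sosfiltfilt`): zero phase, so filtered responses stay aligned with task
  onsets; the effective magnitude response is 8th order. Defaults 0.02–0.2 Hz.
* Epochs span [−5, 20] s around onset; baseline is the half-open [−5, 0) s
  window (the onset sample belongs to the task). Blocks whose window leaves
  the recording are dropped with a logged warning; retained + dropped always
  equals the schedule length.
* Block averages carry the pointwise across-block SD; grand averages the
  across-subject SD.

A caveat measured on zero-noise data: the block-repetition fundamental of
this design (one task per ~37 s ≈ 0.027 Hz) lies inside the high-pass
transition band, so the 0.02 Hz cut attenuates the response peak by ~8–11%.
Epoching, baseline correction and averaging alone recover the true peak
exactly; peak amplitudes read off filtered averages are systematically
~10% low. The tests assert exact recovery for the unfiltered path and a 15%
envelope for the filtered path.

## ROI analysis

The per-channel read-out is the block-average value at the sample nearest
5 s after onset (the most literal "amplitude at 5 s"; a window mean can be
substituted by averaging over `roi_task_mean`). Contrasts are unpaired
pooled-variance two-sample *t*-tests per channel, two-sided with the
direction reported, α = 0.05, no multiple-comparison correction across
channels (per-channel reporting convention; apply a correction downstream if
a family-wise guarantee is needed). The degenerate both-groups-constant,
equal-means case returns t = 0, p = 1 with a logged warning. HbR is carried
through preprocessing but excluded from all inference stages, since HbO is
the cleaner chromophore for these paradigms.

## Laterality index

LI = f·(RHi − LHi)/(|RHi| + |LHi|), f = 1, with RHi/LHi the mean HbO of a
homotopic pair's right/left channel over [0, 20] s post-onset (the window
excludes the pre-task baseline). |LI| ≤ |f| always; LI is scale-invariant
and antisymmetric under swapping hemispheres. The 0/0 case (no activation on
either side) maps to 0 — "no asymmetry" — with a logged warning. LI is
computed per subject from that subject's condition block average; the group
test is a one-sample *t* of the subjects' LIs against LI_TH = 0.2,
one-sided (greater), because the screening question is whether activation is
*more* right-lateralized than the conventional threshold; a two-sided switch
exists. Zero-variance-at-threshold is not significant by convention.

Note: in the source literature for this paradigm the abstract and results
disagree on whether MO produced one or two lateralized connections; the
pipeline reports whatever the data yield.

## Granger causality

For a directed pair y→x the restricted model regresses x on an intercept
and its own p lags, the full model adds y's q lags; both are ordinary least
squares on the same sample (t = order…n−1), so the restricted residual
variance cannot fall below the full one and G = ln(COV(ε_x)/COV(ε_yx)) ≥ 0
(clipped at 0 against rounding). COV(ε) is the biased 1/n residual variance
in both numerator and denominator — any consistent convention cancels. A
single joint order p = q is selected per directed pair by BIC on the full
model over 1…20 lags (2 s at 10 Hz), each candidate on its own aligned
sample, ties to the smaller order. The Durbin–Watson statistic of each fit
is available as a residual-autocorrelation diagnostic; fits are not rejected
on it. `gc_value` is verified against explicit normal-equation regression
(1e−8 on random instances), against `statsmodels`' Granger machinery, and
against the closed form G → ln(1 + c²σ_y²/σ_ε²) for a planted lag-1 system.

**GC input.** The network stage fits GC on each subject's per-condition
block average over [0, 20] s (201 samples), channel-wise z-scored (amplitude
scale carries no directed information). Crucially, these averages are built
from *unfiltered* epochs: a 10 Hz series band-limited to 0.2 Hz retains
essentially no innovation noise, both residual variances collapse toward
zero, and the log-ratio becomes arbitrarily large — measured on synthetic
Rest data, the filtered-input null had median G ≈ 0.5 and nearly every pair
"significant" at threshold 0.4, while the unfiltered-input null has median
G ≈ 0.06 and planted couplings stand out at G ≈ 0.6–0.8. Averaging ten
blocks already suppresses physiological noise, which is the filter's job
elsewhere in the chain.

The group network screens each of the 288 directed pairs with a one-sided
one-sample *t* of the subjects' G against the threshold (α = 0.05, no
multiplicity correction across pairs; a correction switch exists). Edge
counts partition exactly into left→right plus right→left and are
non-increasing in the threshold (nested selection); the default report uses
threshold 0.4 and sweeps 0.15–0.45 in steps of 0.05.

## Determinism and problem sizes

Every stochastic component is a pure function of its seed; per-subject seeds
are spawned from the cohort seed via `numpy` SeedSequence, and a pipeline
run with a fixed config and seed is byte-identical. The bundled validation
suite runs cohorts at the study scale (14 subjects, 4 sessions × 10 tasks,
~36 min of recording per subject) for end-to-end recovery, and reduced
cohorts (white-noise channels, 200 samples; 6 subjects × 20 seeds) for
network-direction recovery, sizes chosen to estimate each property with
comfortable margin on a single CPU.

## What the generator does not emulate

Motion artifacts, short-separation channels and superficial physiology,
optode-scalp coupling variation, 3-D probe geometry, inter-channel
correlated noise fields, non-stationary vigilance effects, and HbR dynamics
beyond a fixed ratio to HbO. Passing tests therefore demonstrate that the
analysis chain is correct and recovers known ground truth under realistic
noise — not that it is robust to every artifact class of real recordings.

## Known limitations

* The unpaired between-condition *t*-test follows the source convention even
  though conditions are within-subject; a paired design would be more
  powerful.
* Bivariate GC only: no conditional/multivariate or spectral variants, so
  common-input effects between channel pairs are not controlled.
* The 5 s read-out is a single sample of a filtered average and inherits the
  ~10% high-pass attenuation described above.
* SNIRF support targets the processed-hemoglobin profile this package
  writes; it is not a general SNIRF validator.
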