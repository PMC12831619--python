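# Methods

`neonirs` implements a complete analysis chain for sleeping-infant
fNIRS recorded with an 18-channel, two-hemisphere array (780/850 nm,
10 Hz, 2 cm source-detector separation), together with a synthetic-data
generator that makes every stage testable against known ground truth.
This note describes the models, the parameters that matter, and the
design choices made where the design was genuinely open.

## Probe model

The `bright18` layout places nine channels per hemisphere, partitioned
into frontal (channels 1, 2, 3, 8 left; 10, 11, 12, 17 right) and
temporal (4, 5, 6, 7, 9 left; 13, 14, 15, 16, 18 right) regions of
interest. Coordinates are synthetic: no published coordinate table
exists for this array, so positions are fabricated to honour the
array's topology and the 20 mm adjacency semantics — within-region
nearest neighbours sit at <= 20 mm, hemispheres are far apart (never
adjacent), and exactly one frontal-temporal channel pair per hemisphere
(1-4, 10-13) bridges the regions so the within-hemisphere adjacency
graph is connected. That bridge matters: frontal-temporal response
clusters are a real feature of this array, and a layout whose adjacency
respected region boundaries strictly could never produce them.

## Stimulus schedules

Three paradigms, in fixed session order:

- **social**: 16 auditory trials of 8 s, vocal (V) and nonvocal (N)
  sounds in the fixed pseudo-random order N,V,V,N,V,N,N,V,N,V,V,N,V,N,N,V,
  each trial preceded by a silent baseline jittered uniformly on
  [10, 12] s (seeded).
- **hand** (habituation and novelty detection): 25 spoken-sentence
  trials of 8 s, each preceded by a 10 s baseline, grouped into the
  five-trial epochs Fam1 (1-5), Fam2 (6-10), Fam3 (11-15), Nov (16-20),
  ReFam (21-25).
- **fc**: alternating 70 s social and 60 s nonsocial audio blocks, the
  pair repeated twice, 260 s total.

## Synthetic-data generator

Per-trial hemodynamics are a double-gamma HRF (peak 7 s, undershoot
ratio 1/6, both configurable) convolved with the trial's 8 s boxcar and
renormalised so the planted amplitude is the peak HbO excursion in uM.
HbR is -1/3 of HbO with a 0.5 s lag; only its sign and rough magnitude
matter downstream (contrast gating). Physiological noise comprises an
amplitude-modulated cardiac oscillation shared across coupled channels
(the signal the scalp coupling index detects), respiratory (~0.7 Hz)
and vasomotor (~0.1 Hz) sinusoids, per-channel 1/f drift band-limited
below 0.5 Hz, and white detector noise. Default amplitudes (cardiac
0.15, respiratory 0.2, vasomotor 0.3, drift 0.8, white 0.05 uM) put
spontaneous slow fluctuations on the same order as a ~1 uM evoked
response, the regime in which trial averaging and IQR-based wavelet
rejection are actually needed. Motion artifacts are Gaussian spikes
(<= 1 s support) and step-like baseline shifts. The forward model maps
(HbO, HbR) to two-wavelength optical density via the modified
Beer-Lambert law (standard tabulated extinction coefficients for
780/850 nm in (uM cm)^-1; DPF 5.22/4.23; d = 2 cm) and exponentiates to
detector intensity. Channels designated bad-coupling are rendered as
wavelength-independent noise, emulating a detached optode.

For the fc paradigm, four latent slow-band (0.01-0.08 Hz) region
signals carry a planted 4x4 correlation matrix. The latents are
synthesised in the frequency domain and QR-orthonormalised before
Cholesky mixing, so their sample correlation equals the planted matrix
exactly; narrow time-domain filters at this record length are dominated
by edge transients and only realise target correlations in expectation,
far too loosely for a 260 s record.

What the generator does **not** emulate: optical photon transport and
partial-volume effects, anatomical variability, state changes across
the session (sleep stages, arousals), serially correlated artifact
bursts, and — importantly — the residual global physiology that in real
data survives global signal regression. Consequences for interpreting
passing tests are noted per stage below.

## Channel quality (SCI / PSP)

Quality screening runs on raw intensity, before any correction. Per
non-overlapping 5 s window both wavelength signals are band-passed to
the infant cardiac band [1.5, 3.5] Hz and standardised; SCI is their
zero-lag Pearson correlation. PSP is the peak of the power spectrum of
their cross-correlation sequence, computed on lags |k| <= n/2 with
unbiased normalisation so a pure shared sinusoid yields PSP near 1.
A window passes at SCI >= 0.7 and PSP >= 0.1; a channel is flagged when
fewer than 70% of its windows pass; a dataset is excluded when more
than 40% of channels (more than 7 of 18) are flagged. Window overlap is
configurable; non-overlap is the default.

## Activation preprocessing

Chain order: intensity -> OD (-log10 against the temporal mean
reference) -> spline motion correction -> wavelet rejection ->
zero-phase low-pass (order-5 Butterworth, 0.6 Hz, forward-backward) ->
Beer-Lambert inversion -> epoching. Each stage can be bypassed for
ablation.

*Motion detection* uses a 1 s moving SD: samples where it exceeds 5x
the channel's median moving SD **and** an absolute floor of 0.01 OD are
flagged and dilated by half a window. The absolute floor exists because
the median-based threshold degenerates to zero on clean synthetic data;
gross motion in OD units is far above it, smooth hemodynamics far
below. *Spline correction* fits a smoothing spline (MATLAB-style
p = 0.99, i.e. lam = (1-p)/p) within each flagged segment, subtracts
it, re-anchors the segment to the preceding sample and shifts the
remainder to preserve continuity, so step artifacts are removed rather
than smoothed. *Wavelet rejection* (Daubechies-2) zeroes detail
coefficients outside [Q1 - 0.8 IQR, Q3 + 0.8 IQR] per level. The
decomposition depth is ceil(log2(fs / (2 f_c))) (= 4 at 10 Hz with the
0.6 Hz cutoff) so that detail bands lie entirely above the retained
hemodynamic band: deeper decompositions put evoked-response energy into
detail levels where the fence clips it, which measurably attenuates
recovered amplitudes. Levels with zero IQR (exactly flat baselines) are
skipped as degenerate.

*Epoching* cuts [-2, 18] s windows at trial onsets and subtracts the
[-2, 0] s pre-trial mean per trial and channel. The window was chosen
to contain the longest response offsets this kind of data shows
(~17 s post-stimulus) with margin. A trial is invalid if its epoch runs
past the recording or a motion segment overlaps it on more than half
the valid channels. A subject is valid for the social contrast with
>= 3 valid N and >= 3 valid V trials, and for habituation with >= 3
valid Fam1 and >= 3 valid Fam3 trials. Note that with 10-12 s
inter-trial baselines, consecutive responses overlap: the pre-trial
baseline is contaminated by the previous trial's tail, so
trial-averaged peaks underestimate planted amplitudes by design of the
paradigm, not through chain loss (the chain itself is verified lossless
on widely spaced trials).

## TFCE statistics

Subject-level difference maps (channel x time; trial-averaged response
for versus-baseline contrasts, difference of condition means for
condition contrasts) feed a one-sample t-map across subjects
(zero-variance elements capped at 1e6 and flagged). TFCE integrates
extent^E x height^H over supra-threshold components with E = 1, H = 2;
connectivity joins spatially adjacent channels (<= 20 mm) at the same
time sample and the same channel at adjacent samples. Because the
component structure is piecewise constant in the threshold, the
enhancement integral has a closed form between component-merge events;
it is evaluated exactly with an offset union-find (the dh -> 0 limit of
the stepped ladder — an evenly stepped ladder at dh = max/100 deviates
by up to ~2% from the fine-step limit, which exceeds the numerical
fidelity this implementation targets).

The null is sign-flipping of subject difference maps (exchangeable
under symmetric subject effects), 1000 permutations by default, with
per-element p = (1 + #{null >= observed}) / (1 + B). Significance is
Benjamini-Hochberg FDR at q = 0.025 per direction (the two directions
of each contrast are tested separately, each at 0.025, matching the
stated threshold without inventing a two-sided scheme), applied per
chromophore. Per channel, significant runs shorter than 1 s are deleted
as not robust. Condition-difference significance is gated: a channel
survives only if the favoured condition is itself significant against
baseline at that channel (N>V needs N>baseline; V>N needs V>baseline;
Fam1>Fam3 needs Fam1>baseline; Nov>Fam3 needs Nov>baseline). Cluster
time windows are the medians over member channels of first/last
significant samples — medians because fNIRS artifacts make extrema
unreliable — and a 4 s extraction window is centred on the midpoint,
from which per-subject ROI scalar means are extracted.

Design notes: pointwise permutation p-values with BH across elements
are used rather than max-statistic correction — a deliberate fidelity
choice to the described procedure; dh survives in `TfceParams` only as
the reference-ladder step used by the oracle tests.

## Functional connectivity

OD data are band-passed 0.009-3 Hz (zero-phase; the 3 Hz edge sits near
the 5 Hz Nyquist and the design stays stable there; filtfilt padding is
extended to ~3 periods of the 0.009 Hz edge because default padding is
far too short for a 110 s time constant), the across-channel global
mean is regressed out per channel, and a second band-pass restricts to
0.009-0.08 Hz. Motion censoring uses the global variance of temporal
derivatives (GVTD): threshold = median + 5 x 1.4826 MAD (a robust,
dependency-free stand-in for a mode-based baseline estimate), with 5 s
guards either side of each supra-threshold sample; subjects need
>= 120 s of valid data. Censored samples are dropped, not interpolated
(interpolation injects autocorrelation into r). ROI averages (LF, LT,
RF, RT; unflagged channels only) yield a 4x4 Pearson matrix per
chromophore, Fisher-z transformed with r clipped at 0.999999 so
degenerate perfect correlations stay finite. Inter-hemispheric pairs
are LF-RF, LT-RT, LF-RT, LT-RF; intra-hemispheric are LF-LT and RF-RT
(four ROIs admit only these two intra pairs). Cohort summaries: paired
t of inter vs intra means, repeated-measures ANOVA over the four inter
pairs with Greenhouse-Geisser correction and generalized eta squared,
and FDR-corrected post-hocs of the temporal pair against the others.

**Known limitation.** After global signal regression the four ROI
series sum to approximately zero, which forces their average pairwise
correlation toward -1/3: absolute post-GSR correlations in the
generator are shifted strongly negative relative to the planted matrix,
and the temporal-vs-between-region gap is compressed. Real recordings
do not show this because residual global physiology survives GSR and
channel-local variance is richer. The *ordering* of connections
(temporal > between-region > frontal inter-hemispheric) and the
inter > intra contrast are preserved and are what the analyses use;
recovery of the ordering is therefore verified at cohort level (means
over subjects), where it is stable, and absolute planted-value recovery
is verified before GSR.

## Cross-paradigm associations

Per-subject scalars — selectivity (N - V window mean; positive =
nonvocal-selective), habituation (Fam1 - Fam3 window mean; positive =
habituating), and connectivity summaries — join into one table keyed by
subject. Associations (selectivity-habituation; each activation metric
against overall inter-hemispheric connectivity and against the
regionally targeted pair) use Pearson r with a Fisher-z 95% CI
(atanh r +- 1.96/sqrt(n-3)) and a t-transform p with n-2 df. Regional
follow-ups are Bonferroni-adjusted within their family (m = pairs
tested per functional metric per chromophore; recorded in the output).
Missing data are handled complete-case per association, so each
association reports its own n.

## Numerical and reproducibility choices

- All randomness flows through seeds; cohorts derive per-subject seeds
  deterministically from a master seed (kept below 2^31).
- Degenerate inputs: zero-variance t capped at 1e6 and excluded from
  window medians; F = 0 when the effect sum of squares is zero; GG
  epsilon clamped to [1/(k-1), 1]; IQR = 0 wavelet levels skipped.
- Default problem sizes in the test suite and acceptance script
  (e.g. 30-subject cohorts, 1000 permutations, 100-200 Monte-Carlo
  seeds, reduced 6-channel grids for null calibration) were chosen to
  make the full verification cycle convenient on a single CPU while
  keeping every Monte-Carlo band meaningful.
- SNIRF (HDF5) is the interchange format for raw and simulated
  recordings; hemisphere/region labels are embedded so probe layouts
  round-trip.
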