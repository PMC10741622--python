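# Methods

`examcoh` re-implements, as a reusable and tested pipeline, an EEG
analysis of clinical decision making during a simulated board-style
standardized oral exam (SOE): two groups — experienced fellows and
novice residents, n = 8 each — wear a 14-channel headset through a
3-minute eyes-open baseline and an 18-minute exam (3 min reading a case
stem, 12 min of questioning on it, 3 min on a spontaneously presented
second case).  The analysis derives quantitative EEG features per task
segment, compares them between groups, and models behavioral outcomes
(checklist performance, NASA-TLX workload) from them.  Because no
public recording of such a study exists, the package ships a synthetic
cohort generator with controlled ground truth; every downstream stage
is validated against it.

## Acquisition model

Recordings are 14 channels of the 10-20 system (AF3, F7, F3, FC5, T7,
P7, O1, O2, P8, T8, FC6, F4, F8, AF4; mastoid referenced) at 256 Hz in
microvolts, band-limited to 0.2–45 Hz by the headset.  The channel
listing order above is canonical: feature vectors, the 91 channel-pair
indices and file channel order all refer to it.  Task segments are
delimited by markers ("eyes open", "reading", "answer 1", "answer 2"),
matched case-insensitively after whitespace normalization; each segment
runs from its marker to the next (or the end of the recording).

## Preprocessing

Each segment is cut into non-overlapping 1-second epochs (floor rule;
the tail is discarded).  An epoch is rejected when any channel exceeds
100 µV absolute deviation from its epoch mean, 200 µV peak-to-peak, or
is flat below 0.1 µV peak-to-peak.  The source study removed epochs
semi-automatically; these thresholds are standard quantitative-EEG
automation of that step, and a manual override hook
(`preprocess.override_mask`) reproduces the reviewer-in-the-loop part.
Rejection decisions use only the epoch's own samples, so the mask is
permutation-equivariant over epochs.  No interpolation or ICA is
applied; a participant losing more than half the epochs of a task is
flagged, never silently dropped.

## Spectral features

Per task segment, retained epochs are demeaned, Kaiser-windowed
(β = 8, sidelobes ≈ −58 dB) and Fourier transformed; 256-sample epochs
at 256 Hz give exactly 1 Hz resolution.

* **PSD** — one-sided, window-power corrected (µV²/Hz), averaged over
  epochs; the integral of the PSD of unit-variance white noise is 1
  within sampling error (Parseval).
* **Band power** — unweighted mean of PSD bins with lo ≤ f ≤ hi for
  delta 1–3, theta 4–7, alpha 8–12, beta 13–30 and gamma 31–45 Hz.
  Gamma is specified as ">30 Hz"; at 1 Hz resolution its first bin is
  31, and it is capped at 45 Hz by the acquisition passband.  Delta is
  computed but excluded from default group reports and model candidate
  sets, mirroring its absence from the study's tables.
* **Coherence** — magnitude-squared coherence per channel pair,
  γ²(f) = |Σₖ Xₖ(f) Ȳₖ(f)|² / (Σₖ|Xₖ|² · Σₖ|Yₖ|²), summed over retained
  epochs (Welch-style with zero overlap, since the protocol defines 1-s
  intervals), then band-averaged.  All 91 = C(14,2) pairs per task and
  band.  For K independent epochs the estimator has the known positive
  bias E[γ̂²] ≈ 1/K; with 180 baseline epochs the floor is ≈ 0.0056.

**Baseline correction** subtracts the same participant's eyes-open
baseline value from every band-aggregated feature (outputs may be
negative).  Subtracting per-frequency baseline spectra before band
aggregation is algebraically identical (the band mean is linear), so
only the feature-space path exists; subtracting baseline *samples*
recorded minutes earlier from task samples is ill-posed and not
implemented.  **Min-max scaling** then maps each feature column across
participants onto [0, 1]; a constant column becomes zeros with a
warning.  Scaling is per task by default; a pooled-across-tasks scope
is available (`normalization_scope="pooled_tasks"`).  Min-max scaling
is affine per column, so the group t statistics below are identical on
raw and normalized features.

## Behavioral instruments

Decision-making performance is a weighted checklist (items rated
No/Maybe/Yes = 0/1/2): score = Σ wᵢrᵢ / Σ 2wᵢ ∈ [0, 1]; weights default
to 1 when a form does not specify them.  Workload is the NASA-TLX
raw-sum ("RTLX") total of six 0–20 subscales, 0–120, rescaled to a 0–1
fraction.  Inter-rater reliability is ICC(2,1): the single-rater,
absolute-agreement intraclass correlation from the two-way
random-effects ANOVA, (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n),
with F = MSR/MSE on (n−1, (n−1)(k−1)) df — the form whose df pair is
(15, 15) at n = 16 subjects and k = 2 raters — and the standard F-based
confidence interval with Satterthwaite df.  The implementation is
checked against a brute-force ANOVA oracle and `pingouin`.

## Group statistics and models

Per-feature group comparisons are independent two-sample t tests,
pooled-variance by default: recomputing the published coherence
contrasts from their printed group summaries (means, SDs, n = 8/8)
under pooled df = 14 reproduces the printed p-values to within the
rounding of the inputs, so pooled is the faithful default; Welch is a
flag.  No multiplicity correction is applied by default (matching the
source analysis); Benjamini-Hochberg is available.  Significant
coherence rows are rendered in the study's table layout (3-decimal
p-values) and exported as a connectivity edge list.

Outcome models follow the study's recipe: candidate features
(reported bands only) are screened by Pearson correlation with the
outcome (p < 0.05); the Lasso selects among the screened set with the
penalty chosen by 5-fold cross-validated mean squared error over a
100-point log grid from λ_max down to 10⁻⁴λ_max (features standardized
within each training fold); an ordinary least-squares refit on the
selected columns reports coefficients, standard errors, p-values and
R².  These refit standard errors ignore the selection step — they are
descriptive, not selection-adjusted.  When the CV-minimum penalty
selects more features than n − 3 (easy at n = 16), the penalty is
raised to the smallest grid value whose support leaves the refit at
least two residual degrees of freedom, with a warning; an all-zero
selection yields the intercept-only model with R² = 0.

## The synthetic cohort generator

The generator's defaults are the study conditions: two groups of 8,
256 Hz, the 3/3/12/3-minute session plan, ~10% contaminated epochs, and
a designed-effect table holding the published group mean coherences for
the 16 significant (task, band, pair) contrasts — e.g. FC5–FC6 theta
while reading at 0.13 (experienced) vs 0.52 (novice).

**Background.**  Each channel is 1/f^α noise (α = 1) confined to the
0.2–45 Hz passband, scaled to 20 µV RMS — a minimal realistic resting
spectrum; posterior channels (P7, O1, O2, P8) add an independent
narrow-band 10 Hz alpha rhythm (6 µV RMS, 0.6 Hz Gaussian width).
Because each channel's rhythm is independent, it adds power but no
coherence.

**Designed coherence.**  Inside a coupled band, channel c's spectrum is
a power-preserving mixture

    X_c(f) = A(f) · [ √(1 − Σₖ ρ_ck) · ε_c(f) + Σₖ √ρ_ck · S_k(f) ]

with A(f) the common 1/f amplitude profile, ε_c private noise and S_k
unit-variance shared sources.  ρ_ck is the coherent fraction of
channel c's power carried by source k, so a pair coupled through k has
theoretical coherence exactly ρ_ck·ρ_dk at every in-band frequency —
the band mean equals the single design value — while the per-bin PSD
stays A(f)² regardless of coupling.  That last property is deliberate:
the study found expertise differences in coherence but not in power,
so connectivity structure must not leak into the PSD features (it also
keeps clean-epoch amplitudes independent of the effect table).  Shared
sources are ideal band-limited noise rather than filtered noise: a
filter rolloff would make the in-band coherent fraction frequency
dependent and bias the band mean low.  The symmetric split
ρ = √γ² realizes any target in [0, 1); a target of exactly 1 is
rejected (unattainable with nonzero private noise).

Two geometric details matter.  First, the coupled band extends two
1-Hz bins past the analysis band (clipped to the passband): the Kaiser
β = 8 analysis window has a ±2.7-bin main lobe, and without the guard
the smearing of uncorrelated out-of-band noise into edge bins dilutes
the designed value (about −7% of a 0.9 target with no guard).  The
guard's side effect is an attenuated echo of large effects in up to two
bins of the adjacent band of the same pair; when the same pair carries
designed effects in adjacent bands, each effect's extension is trimmed
out of the other's analysis bins.  Second, a channel serving several
same-band effects (O1 pairs with T8, FC6, F4 and AF4 in answer-2
gamma) cannot give each partner the full symmetric fraction: with
independent sources, Σₖ ρ_ck ≤ 1.  The published group values for that
hub sum to Σγ² = 1.41, which *no* independent-shared-source model can
realize.  The allocator rescales overloaded channels to a 0.97 load
cap, recovers what it can through slack on partner channels, and
records the realized products in `GroundTruth.coupling` — for the
novice answer-2 hub this lands near 0.22–0.27 instead of 0.30–0.46.
Group contrasts keep their designed direction and remain comfortably
detectable.

**Between-participant variability.**  Each participant's targets are
jittered by N(0, 0.05) (clipped to [0.005, 0.98]).  The published
group SDs (up to 0.36) describe between-subject heterogeneity much
larger than this; under those SDs several published rows would have
under 50% power at n = 8, so recovery checks operate at the published
mean differences with realistic-but-modest inter-individual spread.
Passing them shows the pipeline detects effects of the published
magnitude, not that the original cohort's heterogeneity was small.

**Artifacts.**  Round(rate × exam epochs) 1-s epochs of the three exam
segments (the baseline rest stays clean; the contaminations emulate
head/muscle movement during the exam) receive a 0.5-s raised-cosine
transient, ~500 µV peak (≈ 25× background SD) on every channel with
±20% per-channel scatter and random polarity, fully contained in the
epoch.  Contaminated indices are ground truth; the default detector
catches ≥ 95% of them and rejects ≈ 10% of exam epochs overall.

**Behavior.**  Outcomes are linear in named normalized features plus
N(0, 0.05) noise, clipped to [0, 1].  Defaults reproduce the published
group-level conditions: performance = 0.70 + 0.30·coh(answer 1, beta,
F7–F8) − 0.22·coh(reading, theta, FC5–FC6) gives ≈ 93% (experienced)
vs ≈ 54% (novice); the TLX model mirrors the published cognitive-load
coefficients on group-neutral features, giving similar load in both
groups near 0.6.  The checklist observed by each rater draws item
ratings from Binomial(2, performance) with a 10% per-item mis-scoring
probability per rater (0 yields ICC = 1 exactly); TLX subscales split
the total with zero-sum jitter.

**What the generator does not emulate:** volume conduction and
reference effects (correlated sensors from a single deep source),
ocular/EMG spectral structure (artifacts are broadband transients),
non-stationarity within segments, and the full between-subject
heterogeneity above.  Tests passing on this generator validate the
pipeline's estimators and statistics under known truth; they do not
certify performance on real recordings.

## Numerical and design notes

* Frequency-domain synthesis uses float32/complex64 (ample for
  simulation); analysis accumulates cross-spectra in complex128.
* Determinism: every stage is seeded; `simulate_recording` is
  bit-identical for fixed (seed, participant, group); the pipeline fans
  one master seed out to stage seeds by fixed offsets, and a full
  seeded run writes a byte-identical bundle on rerun.
* Coherence division guards: zero auto-spectra yield 0, and values are
  clipped into [0, 1] against rounding.
* EDF export uses 1-s records, 16-bit samples over the data's symmetric
  physical range (≤ 1 LSB round-trip error; a warning plus a recorded
  gain note if resolution would be coarser than the hardware's 0.51
  µV/LSB); markers travel as EDF+ annotations.  The XDF reader/writer
  covers the subset needed here (numeric EEG stream + string marker
  stream) and reports byte offsets on parse errors.  Fixture CSVs are
  written with `%.17g` and parsed with round-trip float precision, so
  they are diffable *and* exact.
* Validation studies (`examcoh.validation`) size their simulations to
  balance statistical resolution against runtime: 20 replicates for the
  coherence oracle, 50 full cohorts for effect recovery, 3 null cohorts
  (≈ 3800 tests) for the false-positive rate, 50 seeds for Lasso
  recovery.  The recovery criterion for OLS coefficients ("within 2
  standard errors") is a coverage event with ≈ 0.93 per-coefficient
  probability at the refit's residual df — its joint rate sits near
  0.8 by construction, independent of the noise level.

## Known limitations

* The naive post-Lasso standard errors and p-values are not
  selection-adjusted; with ~1500 candidate features and n = 16 the
  selected models fit almost perfectly (R² ≈ 1 on the synthetic
  cohort), which should be read as small-sample overfit, not signal.
* Printed-table recomputation can only cover statistics whose inputs
  the tables print; the published ICC (0.886) depends on unpublished
  per-rater scores and is therefore validated structurally (df, oracle
  agreement, perfect-agreement limit) rather than numerically.
* The hub-channel feasibility bound above means a small number of
  published mean coherences are reproduced in direction and
  significance but not magnitude.
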