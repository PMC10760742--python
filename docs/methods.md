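# Methods

This note documents the models, conventions and defaults behind
`fixent`, the choices made where the underlying definitions are open,
and what the synthetic-data tests do and do not establish.

## Signal model and canonical timebase

The unit of analysis is a labeled fixation: a maximal run of
fixation-labeled samples of horizontal gaze position (degrees of visual
angle), carried with up to 30 samples of surrounding signal per side.
All analysis happens on a canonical 250 Hz timebase (4 ms inter-sample
interval). Irregularly sampled recordings are linearly interpolated onto
the 4 ms grid (labels from the nearest original sample, ties toward the
earlier one); faster recordings are brought down by plain decimation
with **no anti-alias filter** — deliberate, because high-frequency
content (ocular microtremor, ~70–100 Hz) is one of the phenomena the
entropy measures must see, and a low-pass stage would erase it. Missing
position values are bridged by linear interpolation across gaps of at
most 3 samples; longer gaps stay missing.

## Screening

Rules apply in a fixed order and the first violation is recorded:
duration < 11 samples (entropy estimates need more than 10 points);
duration flagged by a generalized extreme Studentized deviate (GESD)
test (two-sided Rosner recursion, α = 0.05, max outliers = ⌈5 % of n⌉ —
conventional defaults, exposed in the API); fewer than 30 samples of
signal before the fixation; fewer than 30 after. The GESD threshold
reported is the largest retained duration; a profile whose entropies
later degenerate is dropped at profiling time rather than here.

Duration equalization across datasets band-filters to [20, 80] samples
and then removes segments one at a time — uniformly at random among the
above-pooled-median segments of the dataset with the largest median —
until a Kruskal–Wallis test across datasets exceeds α = 0.05, capped at
10,000 removals. The equality test, its level, and the thinning rule are
package choices (the procedure being emulated is described only as
random removal of higher-duration fixations until distributions no
longer differ); all randomness is driven by one seed and the result is
bit-reproducible.

## Phase-space reconstruction

`delay_embed` maps x(1..N) to L = N − (m−1)τ states
y(i) = (x(i), x(i+τ), …, x(i+(m−1)τ)), 0-based internally (published
state tables are 1-based; state i, coordinate j is `states[i-1, j-1]`).

The batch pipeline fixes τ = 1 and compares m = 1 against m = 2
(FuzzEn/SampEn) or embeds increments at m = 2 (IncrEn). The estimators
`estimate_tau_ami` and `estimate_m_fnn` serve the illustrative
single-fixation path only:

* **AMI lag**: histogram mutual information of (x(t), x(t+τ)) with a
  shared Freedman–Diaconis binning; the lag is the first local minimum
  of the curve, falling back — on monotonically decaying curves, common
  for short smooth fixations — to the first lag at which AMI drops to
  1/e of the lag-0 self-information, and finally to `max_tau` with a
  warning.
* **FNN dimension**: Kennel criterion with distance-ratio tolerance 15,
  loneliness tolerance 2 (in units of signal spread), and a 10 %
  false-neighbor threshold.

On the bundled 23-sample trace these defaults give τ = 4 and m = 3.
Note the bundled trace preserves a sign anomaly on sample 15 (printed
positive amid negatives in its source, with the source's own state
matrix disagreeing with itself about that sample's sign); the verbatim
trace is used for reproducing the published reconstruction, while the
estimator calibration uses the sign-corrected variant
(`SAMPLE_FIXATION_23_CLEAN`), since a single spurious sign flip
collapses histogram MI and inflates false-neighbor fractions.

## The entropy measures

Shared configuration (`EntropyConfig`): τ = 1; FuzzEn/SampEn base
dimension m = 1 (compared at m+1 = 2); IncrEn dimension 2; tolerance
r = 0.2·std(x) (population std); fuzzy membership exponent n = 2;
increment quantifying resolution qr = 4; 3×3 Poincaré grid; 4 SODP
sectors; natural logarithms (base 2 available). Degenerate inputs
(zero variance; empty match counts; all SODP points at the origin)
raise `MetricUndefined`; `profile_fixation` converts this to NaN and
marks the profile invalid, as does any value ≤ 0 or non-finite.

Conventions worth stating precisely:

* **FuzzEn** — both φ averages run over the same M = N − m·τ
  baseline-removed templates as proper means (outer 1/M, inner
  1/(M−1)), so identical templates give φᵐ = φᵐ⁺¹ = 1 and a linear ramp
  scores exactly 0. The membership function is exp(−(d/r)ⁿ): the
  distance enters scaled by the tolerance, which keeps the measure
  dimensionless and invariant under x → a·x + b (a > 0).
* **SampEn** — B counts unordered template pairs (Chebyshev distance
  ≤ r) over all N − (m−1)τ templates at dimension m; A over the
  N − m·τ templates at m+1. Every (m+1)-match is also an m-match, so
  A ≤ B and SampEn = −ln(A/B) ≥ 0. A = 0 or B = 0 leaves the metric
  undefined.
* **IncrEn** — the increment series is embedded at dimension m; each
  state contributes a word of (m−1) [sign, magnitude] pairs built from
  its adjacent coordinate changes, with magnitude
  q = min(qr, ⌊|Δ|·qr / std(υ)⌋) and q = 0 when std(υ) = 0. Word
  probabilities divide by the number of states (so they sum to one) and
  the Shannon entropy is normalized by m−1.
* **GridEn/GDR** — cells are half-open with the top/right edges closed,
  so the maximum point is counted exactly once. Because min-max
  normalization pins some coordinate to 0 and another to 1, any
  non-constant signal of N ≥ 3 occupies at least two cells; the
  one-cell limit (GridEn = 0, GDR = 1/9) is a statement about the
  distribution formula, not a reachable input.
* **PhasEn** — angles via atan2(Y, Z) mapped into (0, 2π] (non-positive
  results shifted by 2π); k equal sectors ((i−1)·2π/k, i·2π/k];
  exact-origin points dropped. The normalization 1/log k uses the same
  base as the entropy, so PhasEn ∈ [0, 1] in any base.
* **SpecEn** — one-sided spectrum, mean removed, DC bin excluded,
  Nyquist bin included for even N.

Every measure has an independent loop-based oracle in the test suite
(O(N²) double loops, dictionary word-counting, an O(N²)
DFT-by-definition); agreement is enforced to 1e−9 on 200 seeded
sequences of 12–80 samples spanning three amplitude scales.

## High/low analysis

Per metric and side, the 36 most extreme **valid** profiles form a page
(ties broken by ascending fixation id for determinism). Consensus
ratings are ingested as a single CSV (an optional multi-rater majority
mode is out of scope); a code occurring on ≥ 8 fixations of a page —
counted once per fixation however often it repeats on one — is
*characteristic* of that entropy extreme. The summary matrix lists only
(metric, side) rows with at least one characteristic code.

## Synthetic gaze generator

`make_fixation` composes, at 250 Hz: a baseline offset; linear drift;
a low-frequency "bump" sinusoid (default 3 Hz, 0.4°); band-limited
tremor in 70–100 Hz built from eight random-frequency, random-phase
sinusoids scaled to a target RMS (default 0.08°) — irregular by
construction, since physiological microtremor is not a pure tone; white
device noise (default 0.01° RMS, typical of a high-precision video
tracker); and optional onset/fragment events (logistic corrective
saccade of ~1°, decaying 30 Hz post-saccadic oscillation, 3° embedded
saccade fragment, isolated 2° spikes). Contexts are generated as
incoming/outgoing saccade tails; a flag truncates them to plant
missing-context rejections. A "normal" fixation keeps a slow ~0.3 deg/s
drift — real fixations are never flat — and only slopes ≥ 1 deg/s are
tagged as the drift pathology (default 3 deg/s, the scale at which
drift dominates the trace and may masquerade as smooth pursuit).

`make_dataset` allocates archetypes by largest-remainder stratification
(counts exact), jitters amplitudes ±20 %, draws durations uniformly in
[20, 80] samples and baselines in ±10°, and stitches fixations between
labeled saccade segments so the full CSV → extract → screen → profile
path is exercisable; re-extraction recovers the planted fixations
bit-for-bit.

Amplitudes and frequencies are artifact choices: they make each planted
pathology detectable against the modeled noise floor, and they are
*not* measurements of any particular tracker or population. Passing
discrimination tests therefore show that the measures separate these
idealized pathologies in the stated directions (tremor raises FuzzEn
and GridEn, bumps lower SpecEn, drift lowers PhasEn) — not that they
would achieve any particular effect size on real recordings, where
pathologies mix, amplitudes vary, and labels carry their own errors.
The generator also omits vertical/torsional components, microsaccades,
smooth pursuit, and blinks.

## Problem sizes

The bundled study sizes keep the full suite fast while leaving the
statistics decisive: 200 fixations per arm for the rank-test
discrimination checks (Mann–Whitney, α = 0.01), 900 fixations for the
high/low planted-code recovery, 200 sequences for oracle equivalence,
and 600/300/200 segments for three-dataset equalization.

## Known limitations

* Only the horizontal channel is modeled and analyzed.
* Event labels are taken as given; no classifier is included.
* The AMI/FNN estimators are calibrated on one short reference trace;
  on very short fixations their output is sensitive to binning and
  tolerances, which is why the batch pipeline pins τ and m instead.
* GESD assumes approximate normality of the duration distribution;
  with heavy-tailed durations its flag set is conservative.
* The equalization procedure is one member of a family of random
  thinning schemes; different schemes equalize to the same test verdict
  but different surviving multisets.
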