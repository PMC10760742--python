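# fixent

Entropy profiling of ocular fixation trajectories.

During a fixation the eye is never still: the recorded horizontal gaze
position carries slow drift, device noise, and sometimes pathology — a
mislabeled corrective saccade at onset, an embedded saccade fragment,
signal artifacts, low-frequency "bumpy" oscillations, or high-frequency
tremor. `fixent` quantifies the complexity of each fixation trajectory
with six entropy measures and provides the surrounding machinery a study
of such measures needs: recording canonicalization, fixation screening,
duration equalization across datasets, a seeded synthetic-gaze generator
with ground-truth pathology archetypes, and a high/low extreme-rank
analysis that relates entropy extremes to human rating codes.

It is written for eye-movement researchers who want to ask: *which
fixations in my dataset are complex, in what way, and what does that say
about their quality or classification?*

## The six measures

All operate on a fixation's horizontal position samples x(1..N) in
degrees of visual angle, typically 20–80 samples at 250 Hz. Several use
delay embedding: states y(i) = (x(i), x(i+τ), …, x(i+(m−1)τ)), giving
L = N − (m−1)τ states.

| Measure | Idea |
|---|---|
| **FuzzEn** | Fuzzy template self-similarity: baseline-removed m- and (m+1)-templates compared by Chebyshev distance through a graded membership exp(−(d/r)ⁿ); FuzzEn = ln φᵐ − ln φᵐ⁺¹. Sensitive to large state-to-state transitions. |
| **IncrEn** | Symbolic dynamics of the increment series υ(i) = x(i+1) − x(i): each embedded increment state is coded by the sign and std-scaled, resolution-limited magnitude of its adjacent coordinate changes; IncrEn is the Shannon entropy of the code words, normalized by m−1. |
| **SampEn** | −ln(A/B), where B counts template pairs within r = 0.2·std(x) at dimension m and A the same at m+1: the conditional probability that close templates stay close. |
| **GridEn / GDR** | The min-max-normalized Poincaré plot (x_i, x_{i+1}) is cut into a 3×3 grid; GridEn is the Shannon entropy of per-cell point frequencies, GDR the fraction of cells occupied. |
| **PhasEn** | The second-order difference plot (x_{n+1}−x_n, x_{n+2}−x_{n+1}) is cut into k = 4 equal 90° angular sectors; sector-wise cumulative slope angles form a distribution whose normalized Shannon entropy lies in [0, 1]. Low values flag one-directional drift. |
| **SpecEn** | Shannon entropy of the normalized one-sided FFT power spectrum (mean and DC removed). Low values flag narrowband (e.g. "bumpy") fixations. |

A fixation whose profile contains any value ≤ 0, NaN or ∞ is flagged
invalid and excluded from ranking.

## Worked example

The package bundles a 23-sample fixation trace
(`fixent.datasets.SAMPLE_FIXATION_23`). Reconstructing its phase space
with lag τ = 4 and embedding dimension m = 3:

```python
import numpy as np
from fixent import delay_embed, make_dataset, extract_fixations, \
    screen_fixations, profile_fixation, EntropyConfig
from fixent.datasets import SAMPLE_FIXATION_23

ps = delay_embed(SAMPLE_FIXATION_23, tau=4, m=3)
print(f"states: {ps.n_states}")
print(f"state 1: {ps.states[0]}")
print(f"state 9: {ps.states[8]}")
```

prints

```
states: 15
state 1: [-3.2406 -3.2388 -3.1842]
state 9: [-3.1842 -3.1871 -3.176 ]
```

— 23 samples leave 23 − (3−1)·4 = 15 states; the third coordinate of
state 1 equals the second of state 5 and the first of state 9 (the same
sample, x(9), seen through the lag-4 delay).

Entropy profiling of synthetic data with planted tremor:

```python
segs, rec = make_dataset(200, {"baseline": 0.5, "tremor": 0.5}, seed=7)
report = screen_fixations(extract_fixations(rec))
profiles = [profile_fixation(s, EntropyConfig()) for s in report.kept]
by_arm = {}
for seg, prof in zip(segs, profiles):
    if prof.valid:
        by_arm.setdefault(seg.archetype, []).append(prof.fuzz)
for arm, vals in sorted(by_arm.items()):
    print(f"{arm:>8}: n={len(vals)}, median FuzzEn={np.median(vals):.3f}")
```

```
baseline: n=97, median FuzzEn=1.355
  tremor: n=100, median FuzzEn=2.171
```

High-frequency tremor roughly doubles the fuzzy entropy relative to a
normal drift-plus-noise fixation — the signature by which noisy
fixations surface on the high-FuzzEn page of a high/low analysis.

## Command line

```sh
fixent simulate --n 500 --seed 7 --out synthetic.csv   # synthetic recording
fixent convert  --in raw.csv --isi 4 --out canon.csv   # canonical 250 Hz timebase
fixent screen   --in canon.csv --out screened.csv      # rejection report
fixent profile  --in canon.csv --out profiles.csv      # six entropies per fixation
fixent highlow  --profiles profiles.csv --ratings ratings.csv --out summary.csv
fixent embed    --in canon.csv --tau 1 --m 2 --out states.csv
```

Gaze CSVs use columns `t_ms,x_deg,label` (1 = fixation, 2 = saccade,
3 = post-saccadic oscillation, 0 = other); ratings CSVs use
`fixation_id,code` with the nine codes ST, ET, CS, PS, AR, SA, LD, BF, N.

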