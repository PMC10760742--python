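"""Seeded synthetic gaze data with ground-truth fixation archetypes.

The generator emulates 250 Hz horizontal gaze recordings: labeled
fixations of 20-80 samples embedded between saccades, with optional
pathologies layered on a white-noise baseline:

* ``drift``      — linear position drift (deg/s), the LD rating,
* ``bumpy``      — low-frequency (< 10 Hz) oscillation, the BF rating,
* ``tremor``     — band-limited high-frequency (~70-100 Hz) noise
                   emulating ocular microtremor, the N rating,
* ``corrective_saccade`` / ``pso`` — fast step or decaying oscillation
                   at fixation onset (CS / PS ratings),
* ``saccade_fragment`` — a logistic step inside the window (SA rating),
* ``artifact``   — isolated large spikes (AR rating).

A normal ("baseline") fixation is modeled as slow physiological drift
(~0.3 deg/s) over a white device-noise floor (~0.01 deg RMS, typical of
a good video-oculography tracker); pathology amplitudes and frequencies
are artifact choices documented in the methods note, sized to be visible
against that floor.  All randomness flows from the single seed passed
in; there is no hidden global state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from fixent.recording import (
    GazeRecording,
    LABEL_FIXATION,
    LABEL_SACCADE,
    CANONICAL_ISI_MS,
)
from fixent.screening import FixationSegment, CONTEXT_SAMPLES

SAMPLE_RATE_HZ = 250.0

#: Band edges for the tremor component, Hz (pre-decimation microtremor
#: band; representable below the 125 Hz Nyquist limit of 250 Hz data).
TREMOR_BAND_HZ = (70.0, 100.0)


@dataclass
class ArchetypeParams:
    """Generator knobs for one synthetic fixation; amplitudes in degrees."""

    baseline_deg: float = 0.0
    noise_sd_deg: float = 0.01
    drift_slope_deg_per_s: float = 0.0
    bump_freq_hz: float = 3.0
    bump_amp_deg: float = 0.0
    tremor_freq_hz: float = 85.0
    tremor_amp_deg: float = 0.0
    cs_amp_deg: float = 0.0
    pso_amp_deg: float = 0.0
    pso_decay: float = 0.85
    sacc_amp_deg: float = 0.0
    spike_amp_deg: float = 0.0
    spike_count: int = 0
    duration_samples: int = 60
    truncate_pre_context: bool = False
    truncate_post_context: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_deg", "bump_amp_deg", "tremor_amp_deg",
                     "cs_amp_deg", "pso_amp_deg", "sacc_amp_deg",
                     "spike_amp_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 11 <= self.duration_samples <= 300:
            raise ValueError("duration_samples out of supported range")

    def active_components(self) -> list[str]:
        tags = []
        # slow (< 1 deg/s) drift is part of normal fixation; only marked
        # drift earns the LD-style tag
        if abs(self.drift_slope_deg_per_s) >= 1.0:
            tags.append("drift")
        if self.bump_amp_deg > 0:
            tags.append("bumpy")
        if self.tremor_amp_deg > 0:
            tags.append("tremor")
        if self.cs_amp_deg > 0:
            tags.append("corrective_saccade")
        if self.pso_amp_deg > 0:
            tags.append("pso")
        if self.sacc_amp_deg > 0:
            tags.append("saccade_fragment")
        if self.spike_amp_deg > 0 and self.spike_count > 0:
            tags.append("artifact")
        return tags


def _logistic_step(n: int, width: float = 1.5) -> np.ndarray:
    """Monotone 0 -> 1 step over n samples (logistic profile)."""
    k = np.arange(n) - (n - 1) / 2
    return 1.0 / (1.0 + np.exp(-k / width))


def _tremor(n: int, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited irregular oscillation: superposed sinusoids with
    random frequencies in the tremor band and random phases, RMS ~ amp."""
    n_comp = 8
    t = np.arange(n) / SAMPLE_RATE_HZ
    freqs = rng.uniform(*TREMOR_BAND_HZ, size=n_comp)
    phases = rng.uniform(0, 2 * np.pi, size=n_comp)
    waves = np.sin(2 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])
    return amp * np.sqrt(2.0 / n_comp) * waves.sum(axis=0)


def make_fixation(params: ArchetypeParams) -> FixationSegment:
    """Generate one fixation trajectory with 30-sample saccade-tail
    contexts; fully determined by ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    d = params.duration_samples
    t = np.arange(d) / SAMPLE_RATE_HZ
    x = np.full(d, params.baseline_deg)
    x = x + params.drift_slope_deg_per_s * t
    if params.bump_amp_deg > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + params.bump_amp_deg * np.sin(2 * np.pi * params.bump_freq_hz * t + phase)
    if params.tremor_amp_deg > 0:
        x = x + _tremor(d, params.tremor_amp_deg, rng)
    if params.cs_amp_deg > 0:
        n_cs = min(6, d // 3)
        x[:n_cs] += params.cs_amp_deg * (1.0 - _logistic_step(n_cs, width=0.8))
    if params.pso_amp_deg > 0:
        n_pso = min(12, d // 2)
        osc = np.sin(2 * np.pi * 30.0 * t[:n_pso])
        x[:n_pso] += params.pso_amp_deg * params.pso_decay ** np.arange(n_pso) * osc
    if params.sacc_amp_deg > 0:
        mid = d // 2
        n_sacc = min(8, d - mid)
        x[mid:mid + n_sacc] += params.sacc_amp_deg * _logistic_step(n_sacc, width=0.8)
        x[mid + n_sacc:] += params.sacc_amp_deg
    if params.noise_sd_deg > 0:
        x = x + rng.normal(0.0, params.noise_sd_deg, size=d)
    if params.spike_amp_deg > 0 and params.spike_count > 0:
        pos = rng.choice(d, size=min(params.spike_count, d), replace=False)
        signs = rng.choice([-1.0, 1.0], size=len(pos))
        x[pos] += params.spike_amp_deg * signs

    # saccade-tail contexts: incoming saccade settling onto the fixation
    # start, outgoing saccade leaving the fixation end
    in_amp = rng.uniform(2.0, 6.0) * rng.choice([-1.0, 1.0])
    out_amp = rng.uniform(2.0, 6.0) * rng.choice([-1.0, 1.0])
    pre = x[0] + in_amp * (1.0 - _logistic_step(CONTEXT_SAMPLES, width=2.0))
    post = x[-1] + out_amp * _logistic_step(CONTEXT_SAMPLES, width=2.0)
    if params.noise_sd_deg > 0:
        pre = pre + rng.normal(0.0, params.noise_sd_deg, size=CONTEXT_SAMPLES)
        post = post + rng.normal(0.0, params.noise_sd_deg, size=CONTEXT_SAMPLES)

    tags = params.active_components()
    return FixationSegment(
        x=x,
        pre_context=None if params.truncate_pre_context else pre,
        post_context=None if params.truncate_post_context else post,
        dataset_id="synthetic",
        fixation_id=params.seed,
        archetype="+".join(tags) if tags else "baseline",
    )


#: Parameter templates per archetype name; nuisance parameters (duration,
#: baseline, amplitude jitter) are randomized per instance in make_dataset.
#: Every archetype keeps the slow (~0.3 deg/s) physiological drift of a
#: normal fixation; "drift" alone carries marked (3 deg/s) drift.
_SLOW_DRIFT = 0.3

ARCHETYPES: dict[str, dict] = {
    "baseline": {"drift_slope_deg_per_s": _SLOW_DRIFT},
    "drift": {"drift_slope_deg_per_s": 3.0},
    "bumpy": {"drift_slope_deg_per_s": _SLOW_DRIFT, "bump_amp_deg": 0.4,
              "bump_freq_hz": 3.0},
    "tremor": {"drift_slope_deg_per_s": _SLOW_DRIFT, "tremor_amp_deg": 0.08},
    "corrective_saccade": {"drift_slope_deg_per_s": _SLOW_DRIFT, "cs_amp_deg": 1.0},
    "pso": {"drift_slope_deg_per_s": _SLOW_DRIFT, "pso_amp_deg": 0.5},
    "saccade_fragment": {"drift_slope_deg_per_s": _SLOW_DRIFT, "sacc_amp_deg": 3.0},
    "artifact": {"drift_slope_deg_per_s": _SLOW_DRIFT, "spike_amp_deg": 2.0,
                 "spike_count": 2},
}


def _stratified_counts(n: int, mixture: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation of n across mixture proportions."""
    names = sorted(mixture)
    raw = {k: n * mixture[k] for k in names}
    counts = {k: int(np.floor(raw[k])) for k in names}
    short = n - sum(counts.values())
    by_rem = sorted(names, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_rem[:short]:
        counts[k] += 1
    return counts


def make_dataset(
    n: int,
    mixture: dict[str, float] | None = None,
    seed: int = 0,
    dataset_id: str = "synthetic",
    duration_range: tuple[int, int] = (20, 80),
    noise_sd_deg: float = 0.01,
) -> tuple[list[FixationSegment], GazeRecording]:
    """Generate ``n`` fixations from an archetype mixture plus the
    stitched labeled recording containing them.

    Allocation across archetypes is stratified (largest remainder), so
    mixture counts are exact.  The stitched recording alternates labeled
    saccade context and fixation samples; re-extracting it recovers the
    planted fixations and their contexts bit-for-bit.
    """
    mixture = mixture or {"baseline": 1.0}
    unknown = set(mixture) - set(ARCHETYPES)
    if unknown:
        raise ValueError(f"unknown archetype(s): {sorted(unknown)}")
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"mixture proportions must sum to 1 (got {total})")
    rng = np.random.default_rng(seed)
    counts = _stratified_counts(n, mixture)

    plan: list[str] = [name for name in sorted(counts) for _ in range(counts[name])]
    rng.shuffle(plan)

    segments: list[FixationSegment] = []
    for i, name in enumerate(plan):
        overrides = dict(ARCHETYPES[name])
        jitter = {k: v * rng.uniform(0.8, 1.2) for k, v in overrides.items()
                  if isinstance(v, float)}
        overrides.update(jitter)
        params = ArchetypeParams(
            baseline_deg=float(rng.uniform(-10.0, 10.0)),
            noise_sd_deg=noise_sd_deg,
            duration_samples=int(rng.integers(duration_range[0], duration_range[1] + 1)),
            seed=int(rng.integers(2 ** 31)),
            **overrides,
        )
        seg = make_fixation(params)
        seg = replace(seg, fixation_id=i, dataset_id=dataset_id)
        segments.append(seg)

    x_parts, label_parts = [], []
    for seg in segments:
        x_parts += [seg.pre_context, seg.x, seg.post_context]
        label_parts += [
            np.full(CONTEXT_SAMPLES, LABEL_SACCADE),
            np.full(seg.duration_samples, LABEL_FIXATION),
            np.full(CONTEXT_SAMPLES, LABEL_SACCADE),
        ]
    x_all = np.concatenate(x_parts) if x_parts else np.array([])
    labels = np.concatenate(label_parts).astype(int) if label_parts else np.array([], dtype=int)
    timestamps = CANONICAL_ISI_MS * np.arange(len(x_all))
    recording = GazeRecording(
        timestamps, x_all, labels,
        sample_rate_hz=SAMPLE_RATE_HZ, dataset_id=dataset_id,
    )
    return segments, recording
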