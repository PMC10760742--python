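"""Fixation extraction, quality screening and duration equalization.

Fixations are maximal runs of fixation-labeled samples.  Each is carried
with up to 30 samples of surrounding signal on either side ("context"),
used both for plotting and for the screening rule that rejects fixations
too close to a recording boundary.  Screening applies, in order:

1. minimum length (default 11 samples — entropy estimates need >10 points),
2. duration outliers per the generalized extreme Studentized deviate
   (GESD) test,
3. missing 30-sample pre-context,
4. missing 30-sample post-context.

Duration equalization band-filters every dataset to [20, 80] samples and
then randomly thins the long-duration tail of the larger datasets until a
Kruskal-Wallis test no longer distinguishes the duration distributions.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from fixent.recording import GazeRecording, LABEL_FIXATION

logger = logging.getLogger(__name__)

CONTEXT_SAMPLES = 30


class RejectionReason(str, enum.Enum):
    TOO_SHORT = "TOO_SHORT"
    DURATION_OUTLIER = "DURATION_OUTLIER"
    NO_PRE_CONTEXT = "NO_PRE_CONTEXT"
    NO_POST_CONTEXT = "NO_POST_CONTEXT"
    INVALID_ENTROPY = "INVALID_ENTROPY"
    OUT_OF_BAND = "OUT_OF_BAND"


@dataclass
class FixationSegment:
    """One labeled fixation plus its surrounding signal context.

    ``pre_context``/``post_context`` are ``None`` when fewer than 30
    samples of signal exist on that side.  ``archetype`` carries the
    generator's ground-truth tag for synthetic data.
    """

    x: np.ndarray
    pre_context: np.ndarray | None
    post_context: np.ndarray | None
    dataset_id: str = ""
    fixation_id: int = 0
    archetype: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.pre_context is not None:
            self.pre_context = np.asarray(self.pre_context, dtype=float)
        if self.post_context is not None:
            self.post_context = np.asarray(self.post_context, dtype=float)

    @property
    def duration_samples(self) -> int:
        return len(self.x)


@dataclass
class ScreeningReport:
    kept: list[FixationSegment] = field(default_factory=list)
    rejected: list[tuple[int, RejectionReason]] = field(default_factory=list)

    def rejection_counts(self) -> dict[RejectionReason, int]:
        counts: dict[RejectionReason, int] = {}
        for _, reason in self.rejected:
            counts[reason] = counts.get(reason, 0) + 1
        return counts


def extract_fixations(
    rec: GazeRecording, context: int = CONTEXT_SAMPLES
) -> list[FixationSegment]:
    """One segment per maximal run of fixation-labeled samples.

    A side lacking ``context`` samples in the recording has its context
    marked absent (``None``); screening later turns that into a rejection.
    """
    labels = rec.labels
    segments: list[FixationSegment] = []
    n = len(labels)
    i = 0
    fixation_id = 0
    while i < n:
        if labels[i] == LABEL_FIXATION:
            j = i
            while j < n and labels[j] == LABEL_FIXATION:
                j += 1
            pre = rec.x[i - context:i] if i >= context else None
            post = rec.x[j:j + context] if n - j >= context else None
            segments.append(
                FixationSegment(
                    x=rec.x[i:j].copy(),
                    pre_context=None if pre is None else pre.copy(),
                    post_context=None if post is None else post.copy(),
                    dataset_id=rec.dataset_id,
                    fixation_id=fixation_id,
                )
            )
            fixation_id += 1
            i = j
        else:
            i += 1
    return segments


def gesd_duration_outliers(
    durations,
    alpha: float = 0.05,
    max_outliers: int | None = None,
) -> tuple[np.ndarray, float]:
    """Rosner's generalized extreme Studentized deviate test.

    Iteratively removes the observation farthest from the running mean,
    comparing each studentized extreme R_i against its critical value
    lambda_i at level ``alpha``; the largest i with R_i > lambda_i fixes
    the number of outliers.  Returns a boolean flag mask aligned with the
    input and the largest unflagged duration as the retained-duration
    threshold (+inf when nothing is flagged).

    ``max_outliers`` defaults to ceil(5% of n).
    """
    durations = np.asarray(durations, dtype=float)
    n = len(durations)
    if n < 15:
        raise ValueError(f"GESD needs >= 15 observations, got {n}")
    if max_outliers is None:
        max_outliers = math.ceil(0.05 * n)
    if max_outliers < 1:
        raise ValueError("max_outliers must be >= 1")
    max_outliers = min(max_outliers, n - 2)

    if np.ptp(durations) == 0:
        return np.zeros(n, dtype=bool), np.inf

    remaining = list(range(n))
    removed: list[int] = []
    n_outliers = 0
    for i in range(1, max_outliers + 1):
        sub = durations[remaining]
        sd = sub.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(sub - sub.mean())
        k = int(np.argmax(dev))
        r_stat = dev[k] / sd
        n_i = len(sub)
        p = 1 - alpha / (2 * n_i)
        t = stats.t.ppf(p, n_i - 2)
        lam = (n_i - 1) * t / math.sqrt((n_i - 2 + t * t) * n_i)
        removed.append(remaining.pop(k))
        if r_stat > lam:
            n_outliers = i
    flags = np.zeros(n, dtype=bool)
    flags[removed[:n_outliers]] = True
    if n_outliers == 0:
        return flags, np.inf
    threshold = float(durations[~flags].max())
    return flags, threshold


def screen_fixations(
    segments: list[FixationSegment],
    min_len: int = 11,
    use_gesd: bool = True,
    gesd_alpha: float = 0.05,
) -> ScreeningReport:
    """Apply the rejection rules in order; first violated rule is recorded."""
    report = ScreeningReport()
    durations = np.array([s.duration_samples for s in segments])
    if use_gesd and len(segments) >= 15 and np.ptp(durations) > 0:
        gesd_flags, threshold = gesd_duration_outliers(durations, alpha=gesd_alpha)
        if gesd_flags.any():
            logger.info("GESD duration threshold: %g samples", threshold)
    else:
        gesd_flags = np.zeros(len(segments), dtype=bool)
    for seg, is_outlier in zip(segments, gesd_flags):
        if seg.duration_samples < min_len:
            report.rejected.append((seg.fixation_id, RejectionReason.TOO_SHORT))
        elif is_outlier:
            report.rejected.append((seg.fixation_id, RejectionReason.DURATION_OUTLIER))
        elif seg.pre_context is None or len(seg.pre_context) < CONTEXT_SAMPLES:
            report.rejected.append((seg.fixation_id, RejectionReason.NO_PRE_CONTEXT))
        elif seg.post_context is None or len(seg.post_context) < CONTEXT_SAMPLES:
            report.rejected.append((seg.fixation_id, RejectionReason.NO_POST_CONTEXT))
        else:
            report.kept.append(seg)
    counts = report.rejection_counts()
    if counts:
        logger.info(
            "screened %d fixations: kept %d, rejected %s",
            len(segments), len(report.kept),
            {k.value: v for k, v in counts.items()},
        )
    return report


def equalize_durations(
    datasets: dict[str, list[FixationSegment]],
    lo: int = 20,
    hi: int = 80,
    seed: int = 0,
    alpha: float = 0.05,
    max_iter: int = 10_000,
) -> dict[str, list[FixationSegment]]:
    """Band-filter durations to [lo, hi] and thin tails until comparable.

    After the band filter, segments are removed one at a time — uniformly
    at random among the above-pooled-median segments of the dataset with
    the largest median duration — until a Kruskal-Wallis test across
    datasets is non-significant at ``alpha`` (or ``max_iter`` removals).
    Surviving segments are returned unaltered; the procedure is
    bit-reproducible for a fixed seed.
    """
    if len(datasets) < 2:
        raise ValueError("equalization needs at least 2 datasets")
    rng = np.random.default_rng(seed)
    pools: dict[str, list[FixationSegment]] = {}
    for name, segs in datasets.items():
        kept = [s for s in segs if lo <= s.duration_samples <= hi]
        if not kept:
            raise ValueError(f"dataset {name!r} emptied by the [{lo}, {hi}] band filter")
        pools[name] = kept

    for _ in range(max_iter):
        groups = {k: np.array([s.duration_samples for s in v]) for k, v in pools.items()}
        if _all_identical(groups) or _kruskal_p(groups) > alpha:
            break
        pooled_median = np.median(np.concatenate(list(groups.values())))
        # thin the dataset with the largest median; ties -> alphabetical
        target = max(sorted(groups), key=lambda k: np.median(groups[k]))
        candidates = [
            i for i, s in enumerate(pools[target])
            if s.duration_samples > pooled_median
        ]
        if not candidates or len(pools[target]) <= 2:
            break
        drop = candidates[int(rng.integers(len(candidates)))]
        pools[target] = pools[target][:drop] + pools[target][drop + 1:]
    return pools


def _all_identical(groups: dict[str, np.ndarray]) -> bool:
    multisets = [tuple(sorted(v.tolist())) for v in groups.values()]
    return all(m == multisets[0] for m in multisets[1:])


def _kruskal_p(groups: dict[str, np.ndarray]) -> float:
    arrays = list(groups.values())
    try:
        return float(stats.kruskal(*arrays).pvalue)
    except ValueError:  # all values identical across groups
        return 1.0
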