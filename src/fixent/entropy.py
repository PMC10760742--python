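"""The six fixation-entropy measures and the Shannon core.

All six operate on the fixation samples only (context excluded) and share
a small configuration object.  Conventions:

* FuzzEn and SampEn compare template matches at a base dimension m
  (default 1) against dimension m+1, with tolerance r = r_coeff * std(x).
* IncrEn works on the first-difference ("increment") series, embedded at
  dimension ``incr_m`` (default 2); each state is symbolized by the sign
  and the std-scaled, resolution-limited magnitude of its adjacent
  coordinate changes.
* GridEn/GDR use the min-max-normalized Poincare plot on an
  ``grid_n`` x ``grid_n`` grid (default 3x3).
* PhasEn sums slope angles of the second-order difference plot over
  ``k_sectors`` equal angular sectors (default 4, i.e. quadrants) and is
  normalized to [0, 1].
* SpecEn is the Shannon entropy of the normalized one-sided power
  spectrum, mean and DC removed.

Degenerate inputs (zero variance, empty match counts) raise
:class:`MetricUndefined`; :func:`profile_fixation` converts that, and any
non-positive / non-finite value, into an invalid profile, mirroring the
screening rule that drops such fixations from analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from fixent.screening import FixationSegment


class MetricUndefined(ValueError):
    """An entropy is undefined for this input (degenerate signal)."""


@dataclass
class EntropyConfig:
    tau: int = 1
    m: int = 1              # FuzzEn/SampEn base dimension (compared at m+1)
    incr_m: int = 2         # IncrEn embedding dimension
    r_coeff: float = 0.2    # tolerance r = r_coeff * std(x)
    fuzzy_n: float = 2.0    # membership exponent
    qr: int = 4             # increment quantifying resolution
    grid_n: int = 3
    k_sectors: int = 4
    log_base: str = "e"     # "e" or "2"

    def __post_init__(self) -> None:
        if self.grid_n < 2 or self.k_sectors < 2:
            raise ValueError("grid_n and k_sectors must be >= 2")
        if min(self.tau, self.m, self.incr_m, self.qr) < 1 or self.r_coeff <= 0:
            raise ValueError("tau, m, incr_m, qr must be >= 1 and r_coeff > 0")
        if self.log_base not in ("e", "2"):
            raise ValueError("log_base must be 'e' or '2'")

    def log(self, v):
        return np.log(v) if self.log_base == "e" else np.log2(v)


@dataclass
class EntropyProfile:
    """The six entropy values (plus the grid fill rate) for one fixation.

    ``valid`` is False iff any value is <= 0, NaN or infinite; invalid
    profiles are excluded from ranking.
    """

    fixation_id: int
    fuzz: float = math.nan
    incr: float = math.nan
    samp: float = math.nan
    grid: float = math.nan
    gdr: float = math.nan
    phas: float = math.nan
    spec: float = math.nan
    dataset_id: str = ""
    duration: int = 0
    valid: bool = field(default=False)

    METRICS = ("fuzz", "incr", "samp", "grid", "gdr", "phas", "spec")

    def values(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.METRICS}

    def refresh_validity(self) -> None:
        vals = list(self.values().values())
        self.valid = all(np.isfinite(v) and v > 0 for v in vals)


def shannon(probs, log_base: str = "e") -> float:
    """-sum p*log(p) over a probability vector; zero terms contribute 0."""
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-8:
        raise ValueError(f"probabilities must sum to 1 (got {p.sum()!r})")
    p = p[p > 0]
    log = np.log if log_base == "e" else np.log2
    return float(-np.sum(p * log(p)))


def _templates(x: np.ndarray, m: int, tau: int, count: int) -> np.ndarray:
    """First ``count`` delay vectors of dimension m (rows)."""
    return np.column_stack([x[j * tau: j * tau + count] for j in range(m)])


def fuzzy_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Fuzzy entropy: graded template self-similarity across dimensions.

    Templates of length m and m+1 (window mean removed) are compared with
    Chebyshev distance; each pair's membership is exp(-(d/r)^n), a
    scale-consistent exponential fuzzy function with gradient n.  The
    entropy is log(phi_m) - log(phi_{m+1}), where phi averages membership
    over the M = N - m*tau template pairs at each dimension.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    m, tau, n_exp = cfg.m, cfg.tau, cfg.fuzzy_n
    if len(x) < m + 2:
        raise MetricUndefined(f"need N >= m+2 samples (N={len(x)})")
    sd = x.std()
    if sd == 0:
        raise MetricUndefined("zero-variance signal")
    r = cfg.r_coeff * sd
    big_m = len(x) - m * tau
    if big_m < 2:
        raise MetricUndefined("too short for template comparison")
    phis = []
    for dim in (m, m + 1):
        tpl = _templates(x, dim, tau, big_m)
        tpl = tpl - tpl.mean(axis=1, keepdims=True)
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
        memb = np.exp(-((d / r) ** n_exp))
        np.fill_diagonal(memb, 0.0)
        phis.append(memb.sum() / (big_m * (big_m - 1)))
    if phis[0] <= 0 or phis[1] <= 0:
        raise MetricUndefined("vanishing membership average")
    return float(cfg.log(phis[0]) - cfg.log(phis[1]))


def sample_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Sample entropy: -log of the conditional template-match probability.

    B counts unordered template pairs within tolerance r at dimension m
    (all N-(m-1)*tau templates), A the same at dimension m+1; the result
    is -log(A/B).  A or B of zero leaves the metric undefined.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    m, tau = cfg.m, cfg.tau
    if len(x) < m + 2:
        raise MetricUndefined(f"need N >= m+2 samples (N={len(x)})")
    sd = x.std()
    if sd == 0:
        raise MetricUndefined("zero-variance signal")
    r = cfg.r_coeff * sd
    counts = []
    for dim in (m, m + 1):
        n_tpl = len(x) - (dim - 1) * tau
        tpl = _templates(x, dim, tau, n_tpl)
        d = np.max(np.abs(tpl[:, None, :] - tpl[None, :, :]), axis=2)
        iu = np.triu_indices(n_tpl, k=1)
        counts.append(int(np.count_nonzero(d[iu] <= r)))
    b, a = counts
    if a == 0 or b == 0:
        raise MetricUndefined("no template matches within tolerance")
    return float(-cfg.log(a / b))


def increment_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Increment entropy: pattern entropy of symbolized increment states.

    The increment series v(i) = x(i+1) - x(i) is embedded at dimension
    ``incr_m``; each state's adjacent coordinate changes are coded as
    (sign, magnitude) pairs, the magnitude quantized to at most ``qr``
    levels relative to std(v).  Pattern probabilities (count / number of
    states) feed the Shannon formula, normalized by (incr_m - 1).
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    m = cfg.incr_m
    if m < 2:
        raise ValueError("incr_m must be >= 2 (state needs adjacent coordinates)")
    if len(x) < m + 2:
        raise MetricUndefined(f"need N >= incr_m+2 samples (N={len(x)})")
    v = np.diff(x)
    n_states = len(v) - m + 1
    if n_states < 1:
        raise MetricUndefined("too short for increment embedding")
    sigma = v.std()
    states = _templates(v, m, 1, n_states)
    changes = np.diff(states, axis=1)  # m-1 adjacent coordinate changes
    signs = np.sign(changes).astype(int)
    if sigma == 0:
        mags = np.zeros_like(signs)
    else:
        mags = np.minimum(cfg.qr, np.floor(np.abs(changes) * cfg.qr / sigma)).astype(int)
    words: dict[tuple, int] = {}
    for s_row, q_row in zip(signs, mags):
        key = tuple(zip(s_row.tolist(), q_row.tolist()))
        words[key] = words.get(key, 0) + 1
    probs = np.array(list(words.values()), dtype=float) / n_states
    return shannon(probs, cfg.log_base) / (m - 1)


def grid_entropy(x, cfg: EntropyConfig | None = None) -> tuple[float, float]:
    """Gridded-distribution entropy and fill rate of the Poincare plot.

    Returns ``(grid_en, gdr)``: the Shannon entropy of per-cell point
    frequencies on the min-max-normalized (x_i, x_{i+1}) plot gridded
    ``grid_n`` x ``grid_n``, and the fraction of cells containing at least
    one point.  Cells are half-open with the top/right edges closed.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise MetricUndefined("need at least 3 samples")
    rng = np.ptp(x)
    if rng == 0:
        raise MetricUndefined("zero-variance signal")
    xn = (x - x.min()) / rng
    n = cfg.grid_n
    col = np.minimum((xn[:-1] * n).astype(int), n - 1)
    row = np.minimum((xn[1:] * n).astype(int), n - 1)
    cells = row * n + col
    counts = np.bincount(cells, minlength=n * n)
    gdr = float(np.count_nonzero(counts)) / (n * n)
    probs = counts[counts > 0] / (len(x) - 1)
    return shannon(probs, cfg.log_base), gdr


def phase_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Phase entropy of the second-order difference plot (SODP).

    Plots consecutive increments (Z, Y) = (x_{n+1}-x_n, x_{n+2}-x_{n+1}),
    assigns each point the four-quadrant angle theta in (0, 2*pi],
    accumulates theta within ``k_sectors`` equal angular sectors, and
    returns the Shannon entropy of the sector-sum distribution normalized
    by log(k) so the result lies in [0, 1].  Points at the exact origin
    are dropped.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise MetricUndefined("need at least 4 samples")
    yy = x[2:] - x[1:-1]
    zz = x[1:-1] - x[:-2]
    keep = ~((yy == 0) & (zz == 0))
    yy, zz = yy[keep], zz[keep]
    if len(yy) == 0:
        raise MetricUndefined("all SODP points at the origin")
    theta = np.arctan2(yy, zz)
    theta = np.where(theta <= 0, theta + 2 * np.pi, theta)  # range (0, 2*pi]
    k = cfg.k_sectors
    width = 2 * np.pi / k
    sector = np.minimum(np.ceil(theta / width).astype(int) - 1, k - 1)
    sums = np.bincount(sector, weights=theta, minlength=k)
    probs = sums / sums.sum()
    return shannon(probs[probs > 0], cfg.log_base) / float(cfg.log(k))


def spectral_entropy(x, cfg: EntropyConfig | None = None) -> float:
    """Shannon entropy of the normalized one-sided power spectrum.

    The mean is removed, the DC bin excluded, and the remaining FFT power
    normalized to a probability distribution over frequency bins.
    """
    cfg = cfg or EntropyConfig()
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise MetricUndefined("need at least 4 samples")
    power = np.abs(np.fft.rfft(x - x.mean())) ** 2
    power = power[1:]  # exclude DC
    total = power.sum()
    if total == 0:
        raise MetricUndefined("zero-variance signal")
    probs = power / total
    return shannon(probs[probs > 0], cfg.log_base)


def profile_fixation(seg: FixationSegment, cfg: EntropyConfig | None = None) -> EntropyProfile:
    """Compute all six metrics on the fixation samples only.

    Metric-level degeneracy never raises: the offending value becomes NaN
    and the profile is marked invalid (the ''drop the whole fixation''
    rule for values <= 0, NaN or infinite).
    """
    cfg = cfg or EntropyConfig()
    prof = EntropyProfile(
        fixation_id=seg.fixation_id,
        dataset_id=seg.dataset_id,
        duration=seg.duration_samples,
    )
    x = seg.x

    def safe(fn):
        try:
            return fn(x, cfg)
        except MetricUndefined:
            return math.nan

    prof.fuzz = safe(fuzzy_entropy)
    prof.incr = safe(increment_entropy)
    prof.samp = safe(sample_entropy)
    try:
        prof.grid, prof.gdr = grid_entropy(x, cfg)
    except MetricUndefined:
        prof.grid = prof.gdr = math.nan
    prof.phas = safe(phase_entropy)
    prof.spec = safe(spectral_entropy)
    prof.refresh_validity()
    return prof
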