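"""Delay-embedding phase-space reconstruction and parameter estimation.

A scalar series x(1..N) embedded with lag tau and dimension m yields
L = N - (m-1)*tau states y(i) = (x(i), x(i+tau), ..., x(i+(m-1)*tau)).
The batch entropy pipeline fixes tau=1, m=2 (or m=1 with comparison at
m+1); average mutual information (AMI) and false-nearest-neighbor (FNN)
estimators are provided for the illustrative single-fixation path where
the embedding parameters are read off the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PhaseSpace:
    """L x m state matrix; rows are states, columns delayed coordinates."""

    states: np.ndarray
    tau: int
    m: int
    source_length: int

    @property
    def n_states(self) -> int:
        return self.states.shape[0]


def delay_embed(x, tau: int, m: int) -> PhaseSpace:
    """Embed ``x`` with lag ``tau`` and dimension ``m``.

    0-based internally: states[i, j] == x[i + j*tau].
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if tau < 1 or m < 1:
        raise ValueError("tau and m must be positive integers")
    length = n - (m - 1) * tau
    if length <= 0:
        raise ValueError(
            f"series of length {n} too short for embedding (tau={tau}, m={m})"
        )
    states = np.column_stack([x[j * tau: j * tau + length] for j in range(m)])
    return PhaseSpace(states=states, tau=tau, m=m, source_length=n)


def _mutual_information(x: np.ndarray, lag: int, bins: int) -> float:
    """Histogram estimate of I(x(t); x(t+lag)) in nats."""
    a, b = (x, x) if lag == 0 else (x[:-lag], x[lag:])
    joint, _, _ = np.histogram2d(a, b, bins=bins, range=[[x.min(), x.max()]] * 2)
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float(np.sum(p[nz] * np.log(p[nz] / outer[nz])))


def _default_ami_bins(x: np.ndarray) -> int:
    """Freedman-Diaconis bin count, floored at 2."""
    n = len(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if iqr == 0:
        return 2
    width = 2 * iqr / n ** (1 / 3)
    return max(2, int(np.ceil(np.ptp(x) / width)))


def estimate_tau_ami(x, max_tau: int = 10, bins: int | None = None) -> int:
    """First local minimum of lagged average mutual information.

    The AMI curve is evaluated over lag = 0..max_tau with a shared
    histogram binning (Freedman-Diaconis by default).  The first lag
    whose AMI is below both neighbors is returned; for monotonically
    decaying curves (common on short, smooth fixation traces) the
    fallback is the first lag where AMI drops to 1/e of the lag-0
    self-information.  If neither criterion fires, ``max_tau`` is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("mutual information undefined for a constant signal")
    if len(x) < 4 * max_tau:
        raise ValueError(f"need N >= 4*max_tau samples (N={len(x)}, max_tau={max_tau})")
    if bins is None:
        bins = _default_ami_bins(x)
    ami = np.array([_mutual_information(x, lag, bins) for lag in range(0, max_tau + 1)])
    for lag in range(1, max_tau):  # endpoint cannot be confirmed as a minimum
        if ami[lag] < ami[lag - 1] and ami[lag] <= ami[lag + 1]:
            return lag
    below = np.nonzero(ami[1:] <= ami[0] / np.e)[0]
    if len(below):
        return int(below[0]) + 1
    warnings.warn("AMI has no local minimum or 1/e drop up to max_tau; returning max_tau")
    return max_tau


def estimate_m_fnn(
    x,
    tau: int,
    max_m: int = 8,
    rtol: float = 15.0,
    atol: float = 2.0,
    threshold: float = 0.1,
) -> int:
    """Smallest embedding dimension with a false-nearest-neighbor fraction
    below ``threshold`` (Kennel criterion).

    A neighbor pair at dimension m is false when either the distance grows
    by more than ``rtol`` when the (m+1)-th coordinate is added, or the
    extended distance exceeds ``atol`` times the signal's spread
    ("loneliness" test).
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("FNN undefined for a constant signal")
    spread = x.std()
    fractions = []
    for m in range(1, max_m + 1):
        if len(x) - m * tau < 2:
            break
        frac = _fnn_fraction(x, tau, m, rtol, atol, spread)
        fractions.append(frac)
        if frac < threshold:
            return m
    logger.warning("FNN fraction never fell below %g (got %s)", threshold, fractions)
    return max_m


def _fnn_fraction(
    x: np.ndarray, tau: int, m: int, rtol: float, atol: float, spread: float
) -> float:
    ps = delay_embed(x, tau, m)
    # only states that can be extended to dimension m+1
    n_ext = len(x) - m * tau
    states = ps.states[:n_ext]
    if n_ext < 2:
        return 0.0
    diff = states[:, None, :] - states[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    nn = dist.argmin(axis=1)
    r_m = dist[np.arange(n_ext), nn]
    extra = np.abs(x[np.arange(n_ext) + m * tau] - x[nn + m * tau])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(r_m > 0, extra / r_m, np.inf)
    r_m1 = np.sqrt(r_m ** 2 + extra ** 2)
    false = (ratio > rtol) | (r_m1 / spread > atol)
    return float(false.mean())
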