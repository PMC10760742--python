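"""Independent naive reference implementations used only by the tests.

Every function here is written as a direct, loop-based transcription of
the defining formulas — no shared code with the package under test, no
vectorization tricks — so that agreement between package and oracle is
evidence of correctness rather than of shared bugs.
"""

from __future__ import annotations

import cmath
import math


def oracle_shannon(probs, base_e: bool = True) -> float:
    total = 0.0
    for p in probs:
        if p > 0:
            total -= p * (math.log(p) if base_e else math.log2(p))
    return total


def oracle_embed(x, tau: int, m: int):
    """Index-by-index delay embedding."""
    n = len(x)
    length = n - (m - 1) * tau
    return [[x[i + j * tau] for j in range(m)] for i in range(length)]


def oracle_fuzzy(x, m: int = 1, tau: int = 1, r_coeff: float = 0.2, n_exp: float = 2.0) -> float:
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_coeff * sd
    big_m = n - m * tau

    def phi(dim: int) -> float:
        templates = []
        for i in range(big_m):
            window = [x[i + j * tau] for j in range(dim)]
            mu = sum(window) / dim
            templates.append([v - mu for v in window])
        outer = 0.0
        for i in range(big_m):
            inner = 0.0
            for j in range(big_m):
                if j == i:
                    continue
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                inner += math.exp(-((d / r) ** n_exp))
            outer += inner / (big_m - 1)
        return outer / big_m

    return math.log(phi(m)) - math.log(phi(m + 1))


def oracle_sampen(x, m: int = 1, tau: int = 1, r_coeff: float = 0.2) -> float:
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_coeff * sd

    def count_pairs(dim: int) -> int:
        n_tpl = n - (dim - 1) * tau
        templates = [[x[i + j * tau] for j in range(dim)] for i in range(n_tpl)]
        c = 0
        for i in range(n_tpl):
            for j in range(i + 1, n_tpl):
                d = max(abs(a - b) for a, b in zip(templates[i], templates[j]))
                if d <= r:
                    c += 1
        return c

    b = count_pairs(m)
    a = count_pairs(m + 1)
    if a == 0 or b == 0:
        raise ValueError("no matches")
    return -math.log(a / b)


def oracle_incren(x, m: int = 2, qr: int = 4) -> float:
    v = [x[i + 1] - x[i] for i in range(len(x) - 1)]
    mean = sum(v) / len(v)
    sigma = math.sqrt(sum((u - mean) ** 2 for u in v) / len(v))
    n_states = len(v) - m + 1
    words: dict[str, int] = {}
    for i in range(n_states):
        state = v[i:i + m]
        key = ""
        for j in range(1, m):
            change = state[j] - state[j - 1]
            sign = 0 if change == 0 else (1 if change > 0 else -1)
            if sigma == 0:
                q = 0
            else:
                q = min(qr, int(math.floor(abs(change) * qr / sigma)))
            key += f"({sign},{q})"
        words[key] = words.get(key, 0) + 1
    probs = [c / n_states for c in words.values()]
    return oracle_shannon(probs) / (m - 1)


def oracle_griden(x, grid_n: int = 3) -> tuple[float, float]:
    lo, hi = min(x), max(x)
    xn = [(v - lo) / (hi - lo) for v in x]
    counts = [[0] * grid_n for _ in range(grid_n)]
    for i in range(len(x) - 1):
        col = min(int(xn[i] * grid_n), grid_n - 1)
        row = min(int(xn[i + 1] * grid_n), grid_n - 1)
        counts[row][col] += 1
    flat = [c for row in counts for c in row]
    filled = sum(1 for c in flat if c > 0)
    gdr = filled / (grid_n * grid_n)
    probs = [c / (len(x) - 1) for c in flat if c > 0]
    return oracle_shannon(probs), gdr


def oracle_phasen(x, k: int = 4) -> float:
    sums = [0.0] * k
    width = 2 * math.pi / k
    for i in range(len(x) - 2):
        z = x[i + 1] - x[i]
        y = x[i + 2] - x[i + 1]
        if y == 0 and z == 0:
            continue
        theta = math.atan2(y, z)
        if theta <= 0:
            theta += 2 * math.pi
        sector = min(k - 1, math.ceil(theta / width) - 1)
        sums[sector] += theta
    total = sum(sums)
    probs = [s / total for s in sums]
    return oracle_shannon(probs) / math.log(k)


def oracle_specen(x) -> float:
    """Shannon entropy of the one-sided power spectrum via an O(N^2)
    discrete Fourier transform written from the definition."""
    n = len(x)
    mean = sum(x) / n
    xm = [v - mean for v in x]
    powers = []
    for r in range(1, n // 2 + 1):
        f = sum(xm[k] * cmath.exp(-2j * math.pi * r * k / n) for k in range(n))
        powers.append(abs(f) ** 2)
    total = sum(powers)
    probs = [p / total for p in powers]
    return oracle_shannon(probs)


def oracle_gesd(values, alpha: float = 0.05, max_outliers: int = 10):
    """Rosner's recursion, transcribed from the published procedure:
    returns the indices of the confirmed outliers."""
    from scipy.stats import t as t_dist

    vals = list(values)
    n = len(vals)
    idx = list(range(n))
    removed = []
    statistics = []
    for i in range(1, max_outliers + 1):
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        sd = math.sqrt(var)
        if sd == 0:
            break
        k = max(range(len(vals)), key=lambda j: abs(vals[j] - mean))
        r_i = abs(vals[k] - mean) / sd
        n_i = n - i + 1
        p = 1 - alpha / (2 * n_i)
        t = t_dist.ppf(p, n_i - 2)
        lam = (n_i - 1) * t / math.sqrt((n_i - 2 + t * t) * n_i)
        statistics.append((r_i, lam))
        removed.append(idx[k])
        del vals[k], idx[k]
    n_out = 0
    for i, (r_i, lam) in enumerate(statistics, start=1):
        if r_i > lam:
            n_out = i
    return set(removed[:n_out])


def oracle_mi_curve(x, max_tau: int, bins: int):
    """Brute-force lagged mutual information curve (lags 0..max_tau)."""
    lo, hi = min(x), max(x)
    width = (hi - lo) / bins

    def bin_of(v):
        b = int((v - lo) / width) if width > 0 else 0
        return min(b, bins - 1)

    curve = []
    for lag in range(max_tau + 1):
        a = x if lag == 0 else x[:-lag]
        b = x if lag == 0 else x[lag:]
        joint: dict[tuple[int, int], int] = {}
        for u, v in zip(a, b):
            key = (bin_of(u), bin_of(v))
            joint[key] = joint.get(key, 0) + 1
        total = len(a)
        px: dict[int, float] = {}
        py: dict[int, float] = {}
        for (i, j), c in joint.items():
            px[i] = px.get(i, 0) + c / total
            py[j] = py.get(j, 0) + c / total
        mi = 0.0
        for (i, j), c in joint.items():
            p = c / total
            mi += p * math.log(p / (px[i] * py[j]))
        curve.append(mi)
    return curve
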