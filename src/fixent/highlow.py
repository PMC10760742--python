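"""High/low extreme-rank analysis of entropy profiles.

For each entropy metric, the 36 fixations with the highest and the 36
with the lowest values are assembled into "pages".  Human rating codes
(one consensus CSV of ``fixation_id,code`` rows) are attached to each
page; a code occurring on at least 8 fixations of a page is deemed
characteristic of that entropy extreme.  The summary matrix mirrors the
per-dataset (metric, side) x code count layout, populated only where the
threshold is met.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fixent.entropy import EntropyProfile
from fixent.screening import FixationSegment

#: Accepted rating codes: six misclassification codes (ST late start,
#: ET early end, CS corrective-saccade start, PS PSO start, AR artifact,
#: SA embedded saccade) and three descriptive codes (LD linear drift,
#: BF bumpy/low-frequency, N high-frequency noise).
RATING_CODES = ("ST", "ET", "CS", "PS", "AR", "SA", "LD", "BF", "N")

RANKED_METRICS = ("fuzz", "incr", "samp", "grid", "phas", "spec")

PAGE_SIZE = 36
CHARACTERISTIC_THRESHOLD = 8


class RatingFormatError(ValueError):
    """Ratings CSV carries an unknown code or malformed row."""


@dataclass
class HighLowSelection:
    metric: str
    side: str  # "high" | "low"
    fixation_ids: list[int]
    page_size: int = PAGE_SIZE


@dataclass
class HighLowReport:
    selections: dict[tuple[str, str], HighLowSelection]
    code_counts: dict[tuple[str, str], dict[str, int]]
    characteristic: dict[tuple[str, str], set[str]]
    threshold: int = CHARACTERISTIC_THRESHOLD

    def to_frame(self) -> pd.DataFrame:
        """Summary matrix: rows = (metric, side) with >=1 characteristic
        code, columns = rating codes, cells = counts meeting threshold."""
        rows = []
        for (metric, side), codes in sorted(self.characteristic.items()):
            if not codes:
                continue
            counts = self.code_counts[(metric, side)]
            row = {"metric": metric, "side": side}
            row.update({c: counts.get(c, 0) if c in codes else 0 for c in RATING_CODES})
            rows.append(row)
        return pd.DataFrame(rows, columns=["metric", "side", *RATING_CODES])


def rank_select(
    profiles: list[EntropyProfile],
    metric: str,
    side: str,
    page_size: int = PAGE_SIZE,
) -> HighLowSelection:
    """Deterministically select the ``page_size`` most extreme profiles.

    Ties are broken by ascending fixation_id; fewer than ``page_size``
    valid profiles returns them all.
    """
    if metric not in EntropyProfile.METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if side not in ("high", "low"):
        raise ValueError("side must be 'high' or 'low'")
    valid = [p for p in profiles if p.valid]
    sign = -1.0 if side == "high" else 1.0
    order = sorted(valid, key=lambda p: (sign * getattr(p, metric), p.fixation_id))
    return HighLowSelection(
        metric=metric,
        side=side,
        fixation_ids=[p.fixation_id for p in order[:page_size]],
        page_size=page_size,
    )


def load_ratings(path) -> dict[int, list[str]]:
    """Load a consensus ratings CSV (``fixation_id,code``) into a
    per-fixation code multiset; unknown codes raise with the row cited."""
    df = pd.read_csv(path, dtype={"code": str})
    if df.empty and len(df.columns) == 0:
        return {}
    for col in ("fixation_id", "code"):
        if col not in df.columns:
            raise RatingFormatError(f"{path}: missing column {col!r}")
    ratings: dict[int, list[str]] = {}
    for i, row in df.iterrows():
        code = str(row["code"]).strip()
        if code not in RATING_CODES:
            raise RatingFormatError(f"{path}: unknown code {code!r} at row {i + 2}")
        ratings.setdefault(int(row["fixation_id"]), []).append(code)
    return ratings


def page_code_counts(
    selection: HighLowSelection, ratings: dict[int, list[str]]
) -> dict[str, int]:
    """Fixation-level code counts for a page: a code repeated on one
    fixation counts once."""
    counts: dict[str, int] = {}
    for fid in selection.fixation_ids:
        for code in set(ratings.get(fid, ())):
            counts[code] = counts.get(code, 0) + 1
    return counts


def characteristic_codes(
    selection: HighLowSelection,
    ratings: dict[int, list[str]],
    threshold: int = CHARACTERISTIC_THRESHOLD,
) -> set[str]:
    """Codes occurring on >= threshold fixations of the page."""
    return {c for c, n in page_code_counts(selection, ratings).items() if n >= threshold}


def summarize(
    profiles: list[EntropyProfile],
    ratings: dict[int, list[str]],
    metrics=RANKED_METRICS,
    page_size: int = PAGE_SIZE,
    threshold: int = CHARACTERISTIC_THRESHOLD,
) -> HighLowReport:
    """Run the full high/low analysis over all metrics and both sides."""
    selections: dict[tuple[str, str], HighLowSelection] = {}
    code_counts: dict[tuple[str, str], dict[str, int]] = {}
    characteristic: dict[tuple[str, str], set[str]] = {}
    for metric in metrics:
        for side in ("high", "low"):
            sel = rank_select(profiles, metric, side, page_size)
            counts = page_code_counts(sel, ratings)
            selections[(metric, side)] = sel
            code_counts[(metric, side)] = counts
            characteristic[(metric, side)] = {
                c for c, n in counts.items() if n >= threshold
            }
    return HighLowReport(
        selections=selections,
        code_counts=code_counts,
        characteristic=characteristic,
        threshold=threshold,
    )


def render_page(
    selection: HighLowSelection,
    segments: dict[int, FixationSegment],
    profiles: dict[int, EntropyProfile] | None = None,
    path=None,
):
    """Render a 6x6 grid of fixation trajectories (fixation in red,
    context in grey), most extreme first; returns the figure, optionally
    saving it to ``path``."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    missing = [fid for fid in selection.fixation_ids if fid not in segments]
    if missing:
        raise ValueError(f"missing segments for fixation ids {missing}")
    ncols = nrows = int(np.ceil(np.sqrt(selection.page_size)))
    fig, axes = plt.subplots(nrows, ncols, figsize=(14, 14), squeeze=False)
    for ax in axes.ravel():
        ax.axis("off")
    for ax, fid in zip(axes.ravel(), selection.fixation_ids):
        seg = segments[fid]
        pre = seg.pre_context if seg.pre_context is not None else np.array([])
        post = seg.post_context if seg.post_context is not None else np.array([])
        t0 = len(pre)
        ax.plot(np.arange(len(pre)), pre, color="grey", lw=0.8)
        ax.plot(np.arange(t0, t0 + len(seg.x)), seg.x, color="red", lw=1.0)
        ax.plot(np.arange(t0 + len(seg.x), t0 + len(seg.x) + len(post)), post,
                color="grey", lw=0.8)
        title = f"#{fid}"
        if profiles and fid in profiles:
            title += f"  {getattr(profiles[fid], selection.metric):.3g}"
        ax.set_title(title, fontsize=7)
        ax.axis("on")
        ax.tick_params(labelsize=5)
    fig.suptitle(f"{selection.metric} — {selection.side} entropy page")
    if path is not None:
        fig.savefig(path, dpi=100)
        plt.close(fig)
    return fig
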