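"""Per-window nucleotide skews and GRINS calling.

GC skew is (G-C)/(G+C) and TA skew (T-A)/(T+A), computed per 150-nt window
on the same grid as the duplication scan.  A duplicated region whose mean
absolute GC and TA skews over its windows both exceed 0.15 is promoted to
a GRINS (genetic repeat of intense nucleotide skews) call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .io_formats import GeneClusterRecord
from .window_scan import DupRegion, ScanParams, Window, segment_windows


@dataclass(frozen=True)
class SkewProfile:
    windows: tuple[Window, ...]
    gc_skew: np.ndarray  # nan where undefined (no G or C in window)
    ta_skew: np.ndarray  # nan where undefined


@dataclass(frozen=True)
class GrinsCall:
    region: DupRegion
    mean_abs_gc: float  # nan when the region has no defined window
    mean_abs_ta: float
    passes: bool


def gc_skew(seq: str) -> float:
    """(#G - #C) / (#G + #C); nan when the window has no G or C."""
    if not seq:
        raise ValueError("empty sequence")
    g, c = seq.count("G"), seq.count("C")
    if g + c == 0:
        return float("nan")
    return (g - c) / (g + c)


def ta_skew(seq: str) -> float:
    """(#T - #A) / (#T + #A); nan when the window has no T or A."""
    if not seq:
        raise ValueError("empty sequence")
    t, a = seq.count("T"), seq.count("A")
    if t + a == 0:
        return float("nan")
    return (t - a) / (t + a)


def skew_profile(cluster: GeneClusterRecord, params: ScanParams) -> SkewProfile:
    """GC and TA skew per window, on the identical grid as the identity scan."""
    windows = segment_windows(cluster, params)
    gc = np.array([gc_skew(cluster.seq[w.start : w.end]) for w in windows])
    ta = np.array([ta_skew(cluster.seq[w.start : w.end]) for w in windows])
    return SkewProfile(tuple(windows), gc, ta)


def _region_mean_abs(
    region: DupRegion, windows: Sequence[Window], values: np.ndarray
) -> float:
    inside = [
        values[w.index]
        for w in windows
        if w.start >= region.start and w.end <= region.end
    ]
    inside = [v for v in inside if not np.isnan(v)]
    if not inside:
        return float("nan")
    return float(np.mean(np.abs(inside)))


def call_grins(
    dups: Sequence[DupRegion],
    skews: SkewProfile,
    skew_min: float = 0.15,
    rule: Literal["both", "either"] = "both",
) -> list[GrinsCall]:
    """Score each duplicated region's skew intensity and flag GRINS.

    mean_abs_gc/ta are window-level means of |skew| over the region's
    defined windows (window-level magnitudes, so alternating skews do not
    cancel).  Under rule "both" a region passes iff both means exceed
    skew_min; "either" requires one.  All regions are returned with their
    pass flag; filtering is the caller's choice.
    """
    calls = []
    for region in dups:
        mg = _region_mean_abs(region, skews.windows, skews.gc_skew)
        mt = _region_mean_abs(region, skews.windows, skews.ta_skew)
        if np.isnan(mg) or np.isnan(mt):
            warnings.warn(
                f"region [{region.start},{region.end}) has no window with "
                "defined skew; marked as failing",
                stacklevel=2,
            )
            passes = False
        elif rule == "both":
            passes = mg > skew_min and mt > skew_min
        elif rule == "either":
            passes = mg > skew_min or mt > skew_min
        else:
            raise ValueError(f"unknown rule {rule!r}")
        calls.append(GrinsCall(region, mg, mt, passes))
    return calls
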