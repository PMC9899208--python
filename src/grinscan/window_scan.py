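"""Sliding-window intra-cluster duplication scan.

The cluster is split into 150-nt fragments every 30 nt; every fragment is
globally aligned against every other fragment whose genomic interval does
not overlap its own, and the best percent identity per fragment is kept.
Stretches where the five-window sliding mean of that profile exceeds 80%
and which span at least 500 bp are called duplicated regions.  All
thresholds are parameters; the defaults are the reference values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from Bio import Align

from .io_formats import GeneClusterRecord, revcomp


@dataclass(frozen=True)
class ScanParams:
    """Parameters of the duplication scan.

    win_len/step define the fragment grid; id_min is the sliding-mean
    identity threshold (percent, strict >); run is the sliding-mean width
    in windows; min_region the minimum region span in bp; min_separation
    the extra gap (bp) required between partner windows beyond plain
    non-overlap.  fast switches to gap-free (Hamming) identity;
    prefilter_k skips alignment of window pairs sharing no k-mer
    (None disables the prefilter).
    """

    win_len: int = 150
    step: int = 30
    id_min: float = 80.0
    run: int = 5
    min_region: int = 500
    min_separation: int = 0
    revcomp: bool = False
    fast: bool = False
    prefilter_k: Optional[int] = 12

    def __post_init__(self) -> None:
        if self.win_len <= 0:
            raise ValueError("win_len must be positive")
        if not 0 < self.step <= self.win_len:
            raise ValueError("need 0 < step <= win_len")
        if not 0 < self.id_min <= 100:
            raise ValueError("need 0 < id_min <= 100")
        if self.run < 1:
            raise ValueError("run must be >= 1")
        if self.min_region < self.win_len:
            raise ValueError("min_region must be >= win_len")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class Window:
    index: int
    start: int
    end: int


@dataclass(frozen=True)
class IdentityProfile:
    """Per-window best intra-cluster identity (the duplication signal)."""

    windows: tuple[Window, ...]
    best_identity: np.ndarray  # percent, shape (n_windows,)
    best_partner: tuple[Optional[int], ...]  # partner window index or None


@dataclass(frozen=True)
class DupRegion:
    start: int
    end: int
    mean_identity: float
    n_windows: int

    @property
    def span(self) -> int:
        return self.end - self.start


def segment_windows(cluster: GeneClusterRecord, params: ScanParams) -> list[Window]:
    """Full-length windows at starts 0, step, 2*step, ...

    Count is floor((L - win_len)/step) + 1 for L >= win_len, else 0.
    """
    L = cluster.length
    if L < params.win_len:
        return []
    n = (L - params.win_len) // params.step + 1
    return [
        Window(i, i * params.step, i * params.step + params.win_len)
        for i in range(n)
    ]


def _make_aligner() -> Align.PairwiseAligner:
    # EDNAFULL-like scoring: substitution-only homologs align gap-free.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner

_ALIGNER = _make_aligner()


def _identity_from_alignment(row_a: str, row_b: str) -> float:
    ncols = len(row_a)
    ident = sum(
        1
        for x, y in zip(row_a, row_b)
        if x == y and x not in "-N"
    )
    return 100.0 * ident / ncols


def fragment_identity(a: str, b: str) -> float:
    """Percent identity of the global alignment of two fragments.

    identity = 100 * identical columns / alignment length; N never counts
    as a match.  Symmetric by construction of the scoring.
    """
    if not a or not b:
        raise ValueError("fragment_identity requires non-empty sequences")
    aln = _ALIGNER.align(a.upper(), b.upper())[0]
    return _identity_from_alignment(str(aln[0]), str(aln[1]))


def _hamming_identity(a: str, b: str) -> float:
    """Gap-free identity of equal-length fragments (fast mode)."""
    if len(a) != len(b):
        raise ValueError("fast mode requires equal-length fragments")
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "N")
    return 100.0 * ident / len(a)


def _candidate_pairs(
    frags: Sequence[str], k: Optional[int]
) -> Optional[set[tuple[int, int]]]:
    """Window pairs sharing at least one k-mer (None = all pairs)."""
    if k is None:
        return None
    index: dict[str, list[int]] = {}
    for i, frag in enumerate(frags):
        seen: set[str] = set()
        for off in range(len(frag) - k + 1):
            kmer = frag[off : off + k]
            if "N" in kmer or kmer in seen:
                continue
            seen.add(kmer)
            index.setdefault(kmer, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        if len(hits) < 2:
            continue
        for ai in range(len(hits)):
            for bi in range(ai + 1, len(hits)):
                pairs.add((hits[ai], hits[bi]))
    return pairs


def max_identity_profile(
    cluster: GeneClusterRecord, params: ScanParams
) -> IdentityProfile:
    """Best identity of every window against all eligible partner windows.

    A partner is eligible iff the two genomic intervals are separated by at
    least min_separation bp (0 = plain non-overlap).  Windows that are >50%
    N, or have no eligible partner, get best_identity 0 and no partner.
    With revcomp on, each pair is also compared against the partner's
    reverse complement.  Ties break to the lowest partner index.
    """
    windows = segment_windows(cluster, params)
    n = len(windows)
    best = np.zeros(n)
    partner: list[Optional[int]] = [None] * n
    if n == 0:
        return IdentityProfile(tuple(windows), best, tuple(partner))

    frags = [cluster.seq[w.start : w.end] for w in windows]
    masked = [f.count("N") > params.win_len / 2 for f in frags]
    has_partner = [False] * n

    candidates = _candidate_pairs(frags, params.prefilter_k)
    if params.revcomp and candidates is not None:
        rc_candidates = _candidate_pairs(
            frags + [revcomp(f) for f in frags], params.prefilter_k
        )
        for i, j in rc_candidates:
            if i < n <= j and j - n != i:
                candidates.add((min(i, j - n), max(i, j - n)))

    identity_fn = _hamming_identity if params.fast else fragment_identity

    for i in range(n):
        wi = windows[i]
        for j in range(i + 1, n):
            wj = windows[j]
            if wj.start - wi.end < params.min_separation:
                continue  # overlapping or too close
            if not has_partner[i]:
                has_partner[i] = True
            has_partner[j] = True
            if masked[i] or masked[j]:
                continue
            if candidates is not None and (i, j) not in candidates:
                continue
            ident = identity_fn(frags[i], frags[j])
            if params.revcomp:
                ident = max(ident, identity_fn(frags[i], revcomp(frags[j])))
            if ident > best[i]:
                best[i], partner[i] = ident, j
            if ident > best[j]:
                best[j], partner[j] = ident, i

    for i in range(n):
        if masked[i] or not has_partner[i]:
            best[i], partner[i] = 0.0, None
    return IdentityProfile(tuple(windows), best, tuple(partner))


def sliding_mean(values: np.ndarray, run: int) -> np.ndarray:
    """Centered sliding mean, truncated to available neighbours at edges."""
    n = len(values)
    half = run // 2
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + (run - half))
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out


def call_duplicated_regions(
    profile: IdentityProfile, params: ScanParams
) -> list[DupRegion]:
    """Call duplicated regions from the identity profile.

    Windows whose centered run-window sliding mean exceeds id_min are
    marked; maximal runs of marked windows become candidate regions (the
    union of their window intervals); regions spanning >= min_region bp are
    kept.  Overlapping candidates (possible because adjacent windows share
    sequence) are merged before the span filter.
    """
    n = len(profile.windows)
    if n == 0:
        return []
    smooth = sliding_mean(np.asarray(profile.best_identity, dtype=float), params.run)
    marked = smooth > params.id_min

    runs: list[tuple[int, int]] = []  # window index ranges, half-open
    i = 0
    while i < n:
        if marked[i]:
            j = i
            while j + 1 < n and marked[j + 1]:
                j += 1
            runs.append((i, j + 1))
            i = j + 1
        else:
            i += 1

    # merge runs whose base-pair unions overlap
    merged: list[tuple[int, int]] = []
    for lo, hi in runs:
        if merged and profile.windows[lo].start < profile.windows[merged[-1][1] - 1].end:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))

    regions = []
    for lo, hi in merged:
        start = profile.windows[lo].start
        end = profile.windows[hi - 1].end
        if end - start < params.min_region:
            continue
        members = profile.best_identity[lo:hi]
        regions.append(
            DupRegion(
                start=start,
                end=end,
                mean_identity=float(np.mean(members)),
                n_windows=hi - lo,
            )
        )
    return regions


def scan_duplications(
    cluster: GeneClusterRecord, params: ScanParams | None = None
) -> tuple[IdentityProfile, list[DupRegion]]:
    """Convenience: profile + region calls in one shot."""
    params = params or ScanParams()
    profile = max_identity_profile(cluster, params)
    return profile, call_duplicated_regions(profile, params)
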