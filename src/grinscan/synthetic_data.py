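"""Synthetic PKS-like clusters with known planted structure.

Generates multi-module cluster sequences with codon structure, then plants
duplicated regions at a controlled substitution rate, regions of controlled
GC/TA skew, and module families evolved along a known tree — so every
pipeline stage can be tested against ground truth without external data.
Every operation is a pure function of (inputs, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import skbio

from .io_formats import GeneClusterRecord, RegionAnnotation

BASES = np.array(list("ACGT"))
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_modules: int = 4
    module_len: int = 900  # bp, divisible by 3
    intermodule_len: int = 150
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.module_len < 300 or self.module_len % 3 != 0:
            raise ValueError("module_len must be >= 300 and divisible by 3")
        if not 0 < self.gc_content < 1:
            raise ValueError(
                "gc_content must be in (0, 1): stop-free codon sampling is "
                "infeasible at the boundaries"
            )
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")
        if self.intermodule_len < 0:
            raise ValueError("intermodule_len must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """A generated cluster plus the ground truth planted into it."""

    cluster: GeneClusterRecord
    regions: tuple[RegionAnnotation, ...]
    planted_dups: tuple[tuple[tuple[int, int], tuple[int, int], float], ...] = ()
    planted_skews: tuple[tuple[tuple[int, int], float, float], ...] = ()
    true_tree: Optional[skbio.TreeNode] = None

    def __post_init__(self) -> None:
        L = self.cluster.length
        for (s0, e0), (s1, e1), _ in self.planted_dups:
            if not (0 <= s0 < e0 <= L and 0 <= s1 < e1 <= L):
                raise ValueError("planted duplication outside cluster")
        for (s, e), _, _ in self.planted_skews:
            if not (0 <= s < e <= L):
                raise ValueError("planted skew interval outside cluster")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    return rng.choice(4, size=n, p=_base_probs(gc))


def _random_orf(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """Stop-free random codons at the target GC (stops rejection-sampled)."""
    out = []
    for _ in range(n_codons):
        codon = "".join(BASES[_random_bases(rng, 3, gc)])
        while codon in STOP_CODONS:
            codon = "".join(BASES[_random_bases(rng, 3, gc)])
        out.append(codon)
    return "".join(out)


def generate_cluster(cfg: GeneratorConfig) -> SyntheticTruth:
    """Alternating stop-free module ORFs and random intermodule spacers.

    Layout: spacer, module_1, spacer, ..., module_n, spacer; total length
    n*module_len + (n+1)*intermodule_len.  Deterministic given cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    parts: list[str] = []
    regions: list[RegionAnnotation] = []
    pos = 0
    for i in range(cfg.n_modules):
        spacer = "".join(BASES[_random_bases(rng, cfg.intermodule_len, cfg.gc_content)])
        parts.append(spacer)
        pos += cfg.intermodule_len
        orf = _random_orf(rng, cfg.module_len // 3, cfg.gc_content)
        parts.append(orf)
        regions.append(
            RegionAnnotation(
                name=f"module_{i + 1}",
                kind="module",
                domain_class="none",
                start=pos,
                end=pos + cfg.module_len,
            )
        )
        pos += cfg.module_len
    parts.append("".join(BASES[_random_bases(rng, cfg.intermodule_len, cfg.gc_content)]))
    cluster = GeneClusterRecord(
        id=f"synthetic_cluster_seed{cfg.seed}", seq="".join(parts), source="synthetic"
    )
    return SyntheticTruth(cluster=cluster, regions=tuple(regions))


def _substitute(
    rng: np.random.Generator, seq: str, sub_rate: float, frame: Optional[int]
) -> str:
    """Substitute each site w.p. sub_rate, always to a different base.

    With frame set, codons (in that frame) turned into stops by the
    substitutions are repaired by re-drawing one of their substituted
    positions, keeping the copy translatable.
    """
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < sub_rate
    idx = np.flatnonzero(hit)
    base_to_i = {b: i for i, b in enumerate(BASES)}
    for i in idx:
        old = base_to_i.get(arr[i], 0)
        arr[i] = BASES[(old + 1 + rng.integers(3)) % 4]
    if frame is not None:
        for c0 in range(frame, len(arr) - 2, 3):
            codon = "".join(arr[c0 : c0 + 3])
            attempts = 0
            while codon in STOP_CODONS and attempts < 50:
                subbed = [p for p in range(c0, c0 + 3) if hit[p]]
                p = subbed[rng.integers(len(subbed))] if subbed else c0 + 2
                old = base_to_i.get(seq[p], 0) if subbed else base_to_i[arr[p]]
                arr[p] = BASES[(old + 1 + rng.integers(3)) % 4]
                codon = "".join(arr[c0 : c0 + 3])
                attempts += 1
    return "".join(arr)


def plant_duplication(
    truth: SyntheticTruth,
    source: tuple[int, int],
    dest_start: int,
    sub_rate: float,
    seed: int,
    frame: Optional[int] = None,
) -> SyntheticTruth:
    """Overwrite the interval at dest_start with a diverged copy of source.

    Each copied site is substituted (always to a different base) with
    probability sub_rate, so the expected identity between source and copy
    is exactly 100*(1 - sub_rate).  Source and destination must not overlap.
    """
    s0, e0 = source
    L = truth.cluster.length
    length = e0 - s0
    s1, e1 = dest_start, dest_start + length
    if not (0 <= s0 < e0 <= L and 0 <= s1 < e1 <= L):
        raise ValueError("source or destination outside cluster")
    if s0 < e1 and s1 < e0:
        raise ValueError("source and destination overlap")
    if not 0 <= sub_rate < 0.5:
        raise ValueError("sub_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    copy = _substitute(rng, truth.cluster.seq[s0:e0], sub_rate, frame)
    seq = truth.cluster.seq[:s1] + copy + truth.cluster.seq[e1:]
    cluster = replace(truth.cluster, seq=seq)
    return replace(
        truth,
        cluster=cluster,
        planted_dups=truth.planted_dups
        + (((s0, e0), (s1, e1), 100.0 * (1 - sub_rate)),),
    )


def skew_base_probs(
    gc_target: float, ta_target: float, gc_content: float
) -> np.ndarray:
    """Base probabilities (A,C,G,T) realising the requested skews.

    Solves (pG-pC)/(pG+pC) = gc_target with pG+pC = gc_content, and
    likewise for T/A on the remaining mass.  Targets of magnitude 1 need a
    zero probability and are rejected (open domain).
    """
    if abs(gc_target) >= 1 or abs(ta_target) >= 1:
        raise ValueError("skew targets must have magnitude < 1")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")
    pG = gc_content * (1 + gc_target) / 2
    pC = gc_content * (1 - gc_target) / 2
    pT = (1 - gc_content) * (1 + ta_target) / 2
    pA = (1 - gc_content) * (1 - ta_target) / 2
    return np.array([pA, pC, pG, pT])


def plant_skew(
    truth: SyntheticTruth,
    interval: tuple[int, int],
    gc_target: float,
    ta_target: float,
    seed: int,
    gc_content: float = 0.5,
) -> SyntheticTruth:
    """Resequence an interval i.i.d. at base probabilities hitting the skews.

    Codon/ORF structure inside the interval is not preserved.
    """
    s, e = interval
    if not 0 <= s < e <= truth.cluster.length:
        raise ValueError("interval outside cluster")
    probs = skew_base_probs(gc_target, ta_target, gc_content)
    rng = np.random.default_rng(seed)
    new = "".join(BASES[rng.choice(4, size=e - s, p=probs)])
    seq = truth.cluster.seq[:s] + new + truth.cluster.seq[e:]
    return replace(
        truth,
        cluster=replace(truth.cluster, seq=seq),
        planted_skews=truth.planted_skews + (((s, e), gc_target, ta_target),),
    )


def flagship_cluster(seed: int = 3) -> SyntheticTruth:
    """The reference end-to-end fixture: one skewed and one neutral duplicate.

    A 12-module cluster in which module_2 is resequenced with strong GC and
    TA skews (targets 0.3, 0.3) and then tandem-duplicated at 95% identity,
    while module_8 is tandem-duplicated without any skew.  The duplication
    scan should find both tandem blocks and the GRINS rule should pass only
    the skewed one.  Tandem copies keep source and copy in phase on the
    default 30-bp window grid (the block length 900 is a step multiple).
    """
    cfg = GeneratorConfig(
        seed=seed, n_modules=12, module_len=900, intermodule_len=100
    )
    truth = generate_cluster(cfg)
    skewed = truth.regions[1]
    truth = plant_skew(truth, (skewed.start, skewed.end), 0.3, 0.3, seed=seed + 100)
    truth = plant_duplication(
        truth, (skewed.start, skewed.end), skewed.end, 0.05, seed=seed + 200
    )
    neutral = truth.regions[7]
    truth = plant_duplication(
        truth, (neutral.start, neutral.end), neutral.end, 0.05, seed=seed + 300
    )
    return truth


def evolve_on_tree(
    root_orf: str,
    tree: skbio.TreeNode,
    rate_scale: float = 1.0,
    seed: int = 0,
) -> dict[str, str]:
    """Evolve a sequence down a tree under the Jukes-Cantor process.

    Along a branch of length d (substitutions/site, scaled by rate_scale)
    each site substitutes independently with probability
    p = (3/4)(1 - exp(-4d/3)), uniformly to one of the other three bases;
    back-substitutions are therefore possible.  Returns leaf-name -> seq.
    """
    rng = np.random.default_rng(seed)
    base_to_i = {b: i for i, b in enumerate(BASES)}
    root = np.array([base_to_i[b] for b in root_orf.upper()])
    leaves: dict[str, str] = {}

    def descend(node: skbio.TreeNode, state: np.ndarray) -> None:
        if node.length:
            d = node.length * rate_scale
            p = 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))
            hit = rng.random(len(state)) < p
            shift = rng.integers(1, 4, size=int(hit.sum()))
            state = state.copy()
            state[hit] = (state[hit] + shift) % 4
        if node.is_tip():
            leaves[node.name] = "".join(BASES[state])
        else:
            for child in node.children:
                descend(child, state)

    descend(tree, root)
    return leaves
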