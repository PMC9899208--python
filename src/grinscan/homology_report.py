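"""Module/domain homology quantification.

All-vs-all percent identity matrices at nucleotide or protein level, ranked
homolog pairs, and flagging of truncated domains (members of a domain class
substantially shorter than the class median, the hallmark used to pair the
homologous modules carrying shortened ketoreductases).

Identity denominator is alignment length including gap columns — the most
conservative common convention; every report header states it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneClusterRecord, RegionAnnotation
from .phylo import _AA_ALIGNER, _translate_checked
from .window_scan import _ALIGNER, _identity_from_alignment


@dataclass(frozen=True)
class IdentityMatrix:
    labels: tuple[str, ...]
    level: Literal["nt", "aa"]
    values: np.ndarray  # percent, symmetric, diagonal 100

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class TruncationFlag:
    name: str
    domain_class: str
    aa_length: int
    reference_length: float  # median aa length of the class
    deficit: float
    flagged: bool


def _pair_identity(a: str, b: str, level: str) -> float:
    if level == "nt":
        aln = _ALIGNER.align(a, b)[0]
    else:
        aln = _AA_ALIGNER.align(a, b)[0]
    return _identity_from_alignment(str(aln[0]), str(aln[1]))


def identity_matrix(
    regions: Sequence[RegionAnnotation],
    cluster: GeneClusterRecord,
    level: Literal["nt", "aa"] = "nt",
) -> IdentityMatrix:
    """All-vs-all global-alignment percent identity between regions.

    nt level aligns the strand-corrected nucleotide sequences with the scan
    scoring; aa level translates each region (frame 0 after frame_offset)
    and aligns with BLOSUM62.  identity = 100 * identical columns /
    alignment length.
    """
    labels = tuple(r.name for r in regions)
    if len(set(labels)) != len(labels):
        raise ValueError("region names must be unique")
    seqs = []
    for r in regions:
        s = r.extract(cluster)[r.frame_offset :]
        if level == "aa":
            s = s[: len(s) - len(s) % 3]
            aa, _ = _translate_checked(s, r.name)
            s = aa
        seqs.append(s)
    n = len(regions)
    values = np.full((n, n), 100.0)
    for i, j in combinations(range(n), 2):
        values[i, j] = values[j, i] = _pair_identity(seqs[i], seqs[j], level)
    return IdentityMatrix(labels, level, values)


def top_homolog_pairs(
    m: IdentityMatrix, k: int = 1
) -> list[tuple[tuple[str, str], float]]:
    """Top-k off-diagonal pairs by identity, each unordered pair once.

    Ties rank lexicographically by pair label for determinism.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pairs = [
        (tuple(sorted((m.labels[i], m.labels[j]))), float(m.values[i, j]))
        for i, j in combinations(range(len(m.labels)), 2)
    ]
    pairs.sort(key=lambda x: (-x[1], x[0]))
    return pairs[:k]


def flag_truncated(
    domains: Sequence[tuple[str, str, int]],
    delta_min: int = 40,
) -> list[TruncationFlag]:
    """Flag domains >= delta_min residues shorter than their class median.

    domains: (name, domain_class, aa_length) triples, all one class.
    The median (not the mean) is the reference so the truncated members
    themselves cannot drag it down.  A single-member class has no reference
    and yields an empty result with a warning.
    """
    classes = {c for _, c, _ in domains}
    if len(classes) > 1:
        raise ValueError(f"domains span multiple classes: {sorted(classes)}")
    if len(domains) < 2:
        warnings.warn(
            "fewer than 2 domains in class: no reference length, no flags",
            stacklevel=2,
        )
        return []
    ref = float(np.median([ln for _, _, ln in domains]))
    flags = []
    for name, cls, ln in domains:
        deficit = ref - ln
        flags.append(
            TruncationFlag(
                name=name,
                domain_class=cls,
                aa_length=ln,
                reference_length=ref,
                deficit=deficit,
                flagged=deficit >= delta_min,
            )
        )
    return flags


def aa_lengths(
    regions: Sequence[RegionAnnotation], cluster: GeneClusterRecord
) -> list[tuple[str, str, int]]:
    """(name, domain_class, aa length) for each region, for flag_truncated."""
    out = []
    for r in regions:
        s = r.extract(cluster)[r.frame_offset :]
        out.append((r.name, r.domain_class, (len(s) - len(s) % 3) // 3))
    return out
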