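"""Module/domain phylogeny: codon-aware alignment, Jukes-Cantor distances,
neighbor-joining, and topology queries.

The tree is built from pairwise distances, so no joint multiple alignment
is required: each pair of coding sequences is aligned at the amino-acid
level (BLOSUM62) and the alignment is expanded back to codons, guaranteeing
gaps of length 0 mod 3.  Raw mismatch proportions (p-distances, pairwise
deletion of gap/N columns) are corrected with the Jukes-Cantor model
d = -(3/4) ln(1 - 4p/3) and fed to a canonical Saitou-Nei neighbor-joining
agglomeration.  Trees are unrooted; cherry and bipartition queries are
defined on the unrooted topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
import skbio
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

JC_SATURATION_CAP = 5.0


@dataclass(frozen=True)
class AlignedPair:
    label_a: str
    label_b: str
    cols_a: str
    cols_b: str

    def __post_init__(self) -> None:
        if len(self.cols_a) != len(self.cols_b):
            raise ValueError("aligned rows must have equal column counts")

    @property
    def comparable_sites(self) -> int:
        return sum(
            1
            for x, y in zip(self.cols_a, self.cols_b)
            if x not in "-N" and y not in "-N"
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distances in substitutions/site with ordered labels."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("diagonal must be zero")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def _make_aa_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner

_AA_ALIGNER = _make_aa_aligner()


def _translate_checked(nt: str, label: str) -> tuple[str, str]:
    """Translate in frame 0; a single trailing stop codon is stripped."""
    if len(nt) % 3 != 0:
        raise ValueError(f"{label}: length not divisible by 3")
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa, nt = aa[:-1], nt[:-3]
    if "*" in aa:
        raise ValueError(f"{label}: internal stop codon")
    return aa, nt


def codon_align_pair(
    nt_a: str, nt_b: str, label_a: str = "a", label_b: str = "b"
) -> AlignedPair:
    """Amino-acid-guided global codon alignment of two coding sequences.

    The translated sequences are globally aligned (BLOSUM62, gap open -11,
    extend -1) and each amino-acid column is expanded to its source codon;
    gaps expand to '---', so every nucleotide gap has length 0 mod 3.
    """
    nt_a, nt_b = nt_a.upper(), nt_b.upper()
    aa_a, nt_a = _translate_checked(nt_a, label_a)
    aa_b, nt_b = _translate_checked(nt_b, label_b)
    aln = _AA_ALIGNER.align(aa_a, aa_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    def expand(row: str, nt: str) -> str:
        out, pos = [], 0
        for ch in row:
            if ch == "-":
                out.append("---")
            else:
                out.append(nt[pos : pos + 3])
                pos += 3
        return "".join(out)

    return AlignedPair(label_a, label_b, expand(row_a, nt_a), expand(row_b, nt_b))


def p_distance(pair: AlignedPair) -> float:
    """Proportion of differing comparable sites (pairwise deletion)."""
    comparable = diffs = 0
    for x, y in zip(pair.cols_a, pair.cols_b):
        if x in "-N" or y in "-N":
            continue
        comparable += 1
        if x != y:
            diffs += 1
    if comparable == 0:
        raise ValueError(
            f"no comparable sites between {pair.label_a} and {pair.label_b}"
        )
    return diffs / comparable


def jc_distance(p: float, cap_saturated: bool = False) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3), substitutions/site.

    p >= 0.75 is outside the model (saturation); by default it raises, or
    with cap_saturated the distance is capped at JC_SATURATION_CAP.
    """
    if p < 0:
        raise ValueError("p must be >= 0")
    if p >= 0.75:
        if cap_saturated:
            return JC_SATURATION_CAP
        raise ValueError(f"p = {p} >= 0.75: Jukes-Cantor distance is saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_jc_matrix(
    seqs: Mapping[str, str],
    aligned: bool = False,
    cap_saturated: bool = False,
) -> DistanceMatrix:
    """JC distance matrix over labelled coding (or pre-aligned) sequences.

    With aligned=False each pair is codon-aligned first; with aligned=True
    the sequences are taken as rows of an existing alignment (equal length)
    and gap/N columns are dropped per pair.
    """
    labels = tuple(seqs.keys())
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two sequences")
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        a, b = seqs[labels[i]].upper(), seqs[labels[j]].upper()
        if aligned:
            pair = AlignedPair(labels[i], labels[j], a, b)
        else:
            pair = codon_align_pair(a, b, labels[i], labels[j])
        try:
            dij = jc_distance(p_distance(pair), cap_saturated=cap_saturated)
        except ValueError as exc:
            raise ValueError(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
        d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels, d)


def nj_tree(D: DistanceMatrix) -> skbio.TreeNode:
    """Neighbor-joining tree (Saitou-Nei) from a distance matrix.

    Repeatedly joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j
    (ties broken to the lowest index pair), with the standard branch-length
    and distance-update formulas.  Negative branch lengths are clamped to
    zero.  The result is unrooted: the returned root has degree 3 (degree 2
    for a two-leaf tree) and no length.
    """
    labels = list(D.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    nodes = [skbio.TreeNode(name=lab) for lab in labels]
    d = D.d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        parent = skbio.TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.empty((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    if len(nodes) == 2:
        nodes[0].length = nodes[1].length = d[0, 1] / 2
        return skbio.TreeNode(children=nodes)
    # three-point formulas for the final unrooted junction
    for k, (a, b) in enumerate([(1, 2), (0, 2), (0, 1)]):
        nodes[k].length = max((d[k, a] + d[k, b] - d[a, b]) / 2, 0.0)
    return skbio.TreeNode(children=nodes)


def _clade_leaf_sets(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Leaf-name set under every node (tips included)."""
    sets: set[frozenset[str]] = set()
    cache: dict[int, frozenset[str]] = {}
    for node in tree.postorder():
        if node.is_tip():
            s = frozenset([node.name])
        else:
            s = frozenset().union(*(cache[id(c)] for c in node.children))
        cache[id(node)] = s
        sets.add(s)
    return sets


def tree_splits(tree: skbio.TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology.

    Each split is canonicalised as the side not containing the
    lexicographically smallest leaf.
    """
    leaves = frozenset(t.name for t in tree.tips())
    anchor = min(leaves)
    splits = set()
    for s in _clade_leaf_sets(tree):
        side = leaves - s if anchor in s else s
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def is_sister_pair(tree: skbio.TreeNode, a: str, b: str) -> bool:
    """True iff leaves a and b form a cherry on the unrooted topology."""
    leaves = {t.name for t in tree.tips()}
    for lab in (a, b):
        if lab not in leaves:
            raise ValueError(f"unknown leaf label {lab!r}")
    if len(leaves) <= 3:
        return True
    pair = frozenset([a, b])
    rest = frozenset(leaves) - pair
    clades = _clade_leaf_sets(tree)
    return pair in clades or rest in clades


def split_consistent(
    tree: skbio.TreeNode, label_map: Mapping[str, str]
) -> bool:
    """True iff a single edge separates the two classes of label_map exactly."""
    leaves = {t.name for t in tree.tips()}
    missing = leaves - set(label_map)
    if missing:
        raise ValueError(f"leaves missing from label_map: {sorted(missing)}")
    classes: dict[str, set[str]] = {}
    for leaf in leaves:
        classes.setdefault(label_map[leaf], set()).add(leaf)
    if len(classes) != 2:
        raise ValueError(f"label_map must define exactly 2 classes, got {len(classes)}")
    side1, side2 = (frozenset(s) for s in classes.values())
    clades = _clade_leaf_sets(tree)
    return side1 in clades or side2 in clades
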