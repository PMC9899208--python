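"""Readers and writers for cluster sequences, region tables, calls and trees.

Internal coordinates are 0-based half-open everywhere.  Conversion to and
from 1-based inclusive coordinates happens only at the GFF3 boundary; BED
output is natively 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
import skbio

DOMAIN_CLASSES = ("KS", "AT", "DH", "ER", "KR", "ACP", "TE", "none")

_IUPAC_AMBIGUOUS = set("RYSWKMBDHV")


@dataclass(frozen=True)
class GeneClusterRecord:
    """A named nucleotide sequence (the cluster under analysis)."""

    id: str
    seq: str
    source: Literal["fasta", "genbank", "synthetic"] = "synthetic"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("cluster id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled module or domain interval on the cluster (0-based half-open)."""

    name: str
    kind: Literal["module", "domain"]
    domain_class: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("module", "domain"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(f"unknown domain_class {self.domain_class!r}")
        if (self.domain_class == "none") != (self.kind == "module"):
            raise ValueError(
                f"region {self.name!r}: domain_class must be 'none' iff kind is 'module'"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(f"region {self.name!r}: need 0 <= start < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"region {self.name!r}: bad strand {self.strand!r}")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"region {self.name!r}: bad frame_offset")

    def validate_against(self, cluster: GeneClusterRecord) -> None:
        if self.end > cluster.length:
            raise ValueError(
                f"region {self.name!r} [{self.start},{self.end}) exceeds "
                f"cluster length {cluster.length}"
            )

    def extract(self, cluster: GeneClusterRecord) -> str:
        """Strand-aware subsequence of the cluster."""
        sub = cluster.seq[self.start : self.end]
        if self.strand == "-":
            sub = revcomp(sub)
        return sub


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _normalize_seq(raw: str, context: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - set("ACGTN")
    if bad:
        non_acgtn = sum(seq.count(c) for c in bad)
        if non_acgtn / max(len(seq), 1) > 0.10:
            raise ValueError(
                f"{context}: >10% non-ACGTN characters — looks like an "
                "amino-acid sequence, not nucleotides"
            )
        amb = bad & _IUPAC_AMBIGUOUS
        if amb:
            warnings.warn(
                f"{context}: ambiguity codes {sorted(amb)} mapped to N",
                stacklevel=3,
            )
        for c in bad:
            seq = seq.replace(c, "N")
    return seq


def read_cluster(path: str | Path, format: str = "fasta") -> GeneClusterRecord:
    """Read the first nucleotide record of a FASTA or GenBank file.

    Lowercase is normalised to uppercase, U to T, and non-ACGTN IUPAC codes
    to N (with a warning).  A file whose first record is >10% non-ACGTN is
    rejected as protein.
    """
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise ValueError(f"{path}: no sequence records")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} records found; using the first only",
            stacklevel=2,
        )
    rec = records[0]
    seq = _normalize_seq(str(rec.seq), str(path))
    return GeneClusterRecord(id=rec.id, seq=seq, source=format)


def read_regions(
    path: str | Path,
    dialect: Literal["tsv", "gff3"],
    cluster: GeneClusterRecord,
) -> list[RegionAnnotation]:
    """Read module/domain annotations from a 6-column TSV or GFF3.

    The TSV dialect carries 0-based half-open coordinates directly
    (columns: name, kind, domain_class, start, end, strand); GFF3 is
    converted from its 1-based inclusive convention.  Output is sorted by
    start and validated against the cluster length.
    """
    regions: list[RegionAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "tsv":
                    name, kind, domain_class, start_s, end_s, strand = fields[:6]
                    start, end = int(start_s), int(end_s)
                elif dialect == "gff3":
                    # col3 feature type = kind, col9 attributes: Name=...;domain_class=...
                    if len(fields) < 9:
                        raise ValueError("GFF3 line has fewer than 9 columns")
                    kind = fields[2]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6]
                    attrs = dict(
                        kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                    )
                    name = attrs.get("Name", attrs.get("ID", f"region_{lineno}"))
                    domain_class = attrs.get("domain_class", "none")
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
                region = RegionAnnotation(
                    name=name,
                    kind=kind,  # type: ignore[arg-type]
                    domain_class=domain_class,
                    start=start,
                    end=end,
                    strand=strand,  # type: ignore[arg-type]
                )
                region.validate_against(cluster)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            regions.append(region)
    return sorted(regions, key=lambda r: (r.start, r.end, r.name))


def write_regions_tsv(regions: Iterable[RegionAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#name\tkind\tdomain_class\tstart\tend\tstrand\n")
        for r in regions:
            fh.write(
                f"{r.name}\t{r.kind}\t{r.domain_class}\t{r.start}\t{r.end}\t{r.strand}\n"
            )


@dataclass(frozen=True)
class ScoredInterval:
    """A generic half-open interval with a score, for BED6 output."""

    chrom: str
    start: int
    end: int
    name: str
    score: float  # percent identity or skew magnitude x100, caller's choice
    strand: str = "+"


def write_bed(calls: Sequence[ScoredInterval], path: str | Path) -> None:
    """Write BED6.  Scores are x10 (percent scale -> 0..1000), clamped."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for c in calls:
            if not 0 <= c.start < c.end:
                raise ValueError(f"bad interval [{c.start},{c.end})")
            score = int(round(c.score * 10))
            if not 0 <= score <= 1000:
                warnings.warn(
                    f"score {c.score} outside [0,100]; clamped", stacklevel=2
                )
                score = min(max(score, 0), 1000)
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.name}\t{score}\t{c.strand}\n")


def write_newick(tree: skbio.TreeNode, path: str | Path) -> None:
    """Serialise a tree to Newick with 6-significant-digit branch lengths."""
    labels = [t.name for t in tree.tips()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")
    clone = tree.copy()
    for node in clone.traverse():
        if node.length is not None:
            node.length = float(f"{node.length:.6g}")
    clone.write(str(path), format="newick")


def read_newick(path: str | Path) -> skbio.TreeNode:
    return skbio.TreeNode.read(str(path), format="newick")
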