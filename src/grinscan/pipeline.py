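"""Orchestration of the two analyses: the GRINS track and the module tree.

Both pipelines are deterministic: rerunning with an identical configuration
and inputs produces byte-identical artifacts.  A JSON manifest recording
all parameters and input digests is written alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from . import __version__
from .io_formats import GeneClusterRecord, ScoredInterval, write_bed, write_newick
from .phylo import (
    DistanceMatrix,
    is_sister_pair,
    nj_tree,
    pairwise_jc_matrix,
    split_consistent,
)
from .skew_grins import GrinsCall, SkewProfile, call_grins, skew_profile
from .window_scan import (
    DupRegion,
    IdentityProfile,
    ScanParams,
    call_duplicated_regions,
    max_identity_profile,
)

logger = logging.getLogger("grinscan")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; defaults are the reference parameters."""

    scan: ScanParams = field(default_factory=ScanParams)
    skew_min: float = 0.15
    rule: str = "both"
    aligned: bool = False
    cap_saturated: bool = False
    outdir: Optional[Path] = None
    seed: int = 0


@dataclass(frozen=True)
class GrinsResult:
    profile: IdentityProfile
    skews: SkewProfile
    dup_regions: list[DupRegion]
    grins_calls: list[GrinsCall]
    artifacts: dict[str, Path]


@dataclass(frozen=True)
class PhyloResult:
    matrix: DistanceMatrix
    tree: "object"  # skbio.TreeNode
    sister_answers: dict[tuple[str, str], bool]
    split_answer: Optional[bool]
    artifacts: dict[str, Path]


def _digest(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()


def _write_manifest(
    outdir: Path, cfg: RunConfig, inputs: dict[str, str], artifacts: dict[str, Path]
) -> Path:
    manifest = {
        "tool": "grinscan",
        "version": __version__,
        "parameters": {
            "scan": asdict(cfg.scan),
            "skew_min": cfg.skew_min,
            "rule": cfg.rule,
            "aligned": cfg.aligned,
            "cap_saturated": cfg.cap_saturated,
            "seed": cfg.seed,
        },
        "input_sha256": inputs,
        "artifacts": {k: str(v.name) for k, v in artifacts.items()},
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def run_grins_pipeline(
    cluster: GeneClusterRecord, cfg: RunConfig | None = None
) -> GrinsResult:
    """Duplication scan + skew profile + GRINS calls, with optional artifacts.

    A cluster shorter than one window yields empty outputs and a warning
    (not an error).  With cfg.outdir set, writes: the per-window identity
    profile (TSV), duplicated regions (BED6), all candidate GRINS with skew
    means (TSV), passing GRINS (BED6), and a run manifest (JSON).
    """
    cfg = cfg or RunConfig()
    if cluster.length < cfg.scan.win_len:
        warnings.warn(
            f"cluster {cluster.id!r} shorter than one window "
            f"({cluster.length} < {cfg.scan.win_len} bp): empty result",
            stacklevel=2,
        )
    logger.info("scanning %s (%d bp)", cluster.id, cluster.length)
    profile = max_identity_profile(cluster, cfg.scan)
    dups = call_duplicated_regions(profile, cfg.scan)
    skews = skew_profile(cluster, cfg.scan)
    calls = call_grins(dups, skews, skew_min=cfg.skew_min, rule=cfg.rule)
    logger.info(
        "%d windows, %d duplicated regions, %d GRINS",
        len(profile.windows),
        len(dups),
        sum(c.passes for c in calls),
    )

    artifacts: dict[str, Path] = {}
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        prof_path = outdir / "identity_profile.tsv"
        with open(prof_path, "w") as fh:
            fh.write("#window_index\tstart\tend\tbest_identity\tbest_partner_start\n")
            for w, ident, part in zip(
                profile.windows, profile.best_identity, profile.best_partner
            ):
                pstart = profile.windows[part].start if part is not None else "."
                fh.write(f"{w.index}\t{w.start}\t{w.end}\t{ident:.4f}\t{pstart}\n")
        artifacts["identity_profile"] = prof_path

        dup_path = outdir / "duplicated_regions.bed"
        write_bed(
            [
                ScoredInterval(
                    cluster.id, r.start, r.end, f"dup_{i + 1}", r.mean_identity
                )
                for i, r in enumerate(dups)
            ],
            dup_path,
        )
        artifacts["duplicated_regions"] = dup_path

        cand_path = outdir / "grins_candidates.tsv"
        with open(cand_path, "w") as fh:
            fh.write(
                "#start\tend\tmean_identity\tn_windows\tmean_abs_gc\t"
                "mean_abs_ta\tpasses\n"
            )
            for c in calls:
                fh.write(
                    f"{c.region.start}\t{c.region.end}\t"
                    f"{c.region.mean_identity:.4f}\t{c.region.n_windows}\t"
                    f"{c.mean_abs_gc:.4f}\t{c.mean_abs_ta:.4f}\t"
                    f"{str(c.passes).lower()}\n"
                )
        artifacts["grins_candidates"] = cand_path

        grins_path = outdir / "grins.bed"
        write_bed(
            [
                ScoredInterval(
                    cluster.id,
                    c.region.start,
                    c.region.end,
                    f"GRINS_{i + 1}",
                    c.region.mean_identity,
                )
                for i, c in enumerate([c for c in calls if c.passes])
            ],
            grins_path,
        )
        artifacts["grins"] = grins_path

        artifacts["manifest"] = _write_manifest(
            outdir, cfg, {"cluster": _digest(cluster.seq)}, artifacts
        )
    return GrinsResult(profile, skews, dups, calls, artifacts)


def run_phylo_pipeline(
    seqs: Mapping[str, str],
    cfg: RunConfig | None = None,
    query_sisters: Sequence[tuple[str, str]] = (),
    classes: Optional[Mapping[str, str]] = None,
) -> PhyloResult:
    """Pairwise JC distances -> NJ tree -> topology queries, with artifacts.

    seqs maps region names to coding nucleotide sequences (or rows of a
    pre-built alignment when cfg.aligned).  Saturated pairs (p >= 0.75)
    raise with the pair named unless cfg.cap_saturated.
    """
    cfg = cfg or RunConfig()
    if len(seqs) < 2:
        raise ValueError("need at least 2 region sequences")
    matrix = pairwise_jc_matrix(
        seqs, aligned=cfg.aligned, cap_saturated=cfg.cap_saturated
    )
    tree = nj_tree(matrix)
    sisters = {(a, b): is_sister_pair(tree, a, b) for a, b in query_sisters}
    split_answer = split_consistent(tree, classes) if classes else None

    artifacts: dict[str, Path] = {}
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)

        mat_path = outdir / "jc_distances.tsv"
        with open(mat_path, "w") as fh:
            fh.write("label\t" + "\t".join(matrix.labels) + "\n")
            for i, lab in enumerate(matrix.labels):
                row = "\t".join(f"{v:.6f}" for v in matrix.d[i])
                fh.write(f"{lab}\t{row}\n")
        artifacts["jc_distances"] = mat_path

        tree_path = outdir / "nj_tree.nwk"
        write_newick(tree, tree_path)
        artifacts["nj_tree"] = tree_path

        summary_path = outdir / "phylo_queries.tsv"
        with open(summary_path, "w") as fh:
            fh.write("#query\tanswer\n")
            for (a, b), ans in sisters.items():
                fh.write(f"sisters:{a},{b}\t{str(ans).lower()}\n")
            if split_answer is not None:
                fh.write(f"split_consistent\t{str(split_answer).lower()}\n")
        artifacts["phylo_queries"] = summary_path

        artifacts["manifest"] = _write_manifest(
            Path(cfg.outdir),
            cfg,
            {"sequences": _digest("".join(f">{k}\n{v}\n" for k, v in seqs.items()))},
            artifacts,
        )
    return PhyloResult(matrix, tree, sisters, split_answer, artifacts)
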