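"""File formats, configuration, and the end-to-end pipeline.

One TSV dialect is used throughout: tab-separated, UTF-8, LF line
endings, '#'-prefixed metadata lines, coordinates 1-based inclusive
(except the BED-like export, which is 0-based half-open with
``start0 = start_aa - 1`` and ``end0 = end_aa``).
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from ._streams import substream
from .allele_model import RepairOutcomeModel
from .depletion_scoring import GuideScore, score_guides
from .domain_scan import (
    RegionCall,
    ResidueTrack,
    call_regions,
    evaluate_calls,
    permutation_null,
)
from .errors import InputError, ParseError
from .guide_design import CodingSequence, GuideRecord, design_tiling_library
from .synthetic_screen import (
    REFERENCE,
    SCREENED,
    Sample,
    ScreenCounts,
    SimTruth,
    random_cds,
    simulate_screen,
)

logger = logging.getLogger(__name__)

LIBRARY_COLUMNS = [
    "guide_id", "gene", "protospacer", "strand",
    "pam_pos_nt", "cut_nt", "target_aa", "is_control",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file (upper-cased; RNA rejected)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ParseError(
                f"record {rec.id!r}: RNA alphabet (U) not accepted; supply DNA"
            )
        try:
            records.append(CodingSequence(id=rec.id, seq=seq))
        except InputError as exc:
            raise ParseError(f"record {rec.id!r}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


# --------------------------------------------------------------- library

def write_library(records: list[GuideRecord], path) -> None:
    rows = []
    for g in records:
        rows.append({
            "guide_id": g.guide_id,
            "gene": g.gene,
            "protospacer": g.protospacer,
            "strand": g.strand if g.strand is not None else "",
            "pam_pos_nt": "" if g.pam_pos_nt is None else g.pam_pos_nt,
            "cut_nt": "" if g.cut_nt is None else g.cut_nt,
            "target_aa": "" if g.target_aa is None else g.target_aa,
            "is_control": str(g.is_control),
        })
    df = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_library(path) -> list[GuideRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != LIBRARY_COLUMNS:
        raise ParseError(
            f"{path}: expected columns {LIBRARY_COLUMNS}, got {list(df.columns)}"
        )
    records = []
    for _, row in df.iterrows():
        is_control = row["is_control"] == "True"
        records.append(GuideRecord(
            guide_id=row["guide_id"],
            gene=row["gene"],
            protospacer=row["protospacer"],
            strand=row["strand"] or None,
            pam_pos_nt=None if row["pam_pos_nt"] == "" else int(row["pam_pos_nt"]),
            cut_nt=None if row["cut_nt"] == "" else int(row["cut_nt"]),
            target_aa=None if row["target_aa"] == "" else int(row["target_aa"]),
            is_control=is_control,
        ))
    return records


# ---------------------------------------------------------------- counts

def write_counts(counts: ScreenCounts, path) -> None:
    """Count TSV: two '#' metadata lines (condition, replicate), then the
    guide × sample matrix.  Canonical ordering round-trips byte-identically."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("#condition\t" + "\t".join(s.condition for s in counts.samples) + "\n")
        fh.write("#replicate\t" + "\t".join(str(s.replicate) for s in counts.samples) + "\n")
        fh.write("guide_id\t" + "\t".join(s.name for s in counts.samples) + "\n")
        for gid, row in zip(counts.guide_ids, counts.counts):
            fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_counts(path) -> ScreenCounts:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    meta = {}
    body_start = 0
    for i, ln in enumerate(lines):
        if ln.startswith("#"):
            key, *vals = ln[1:].split("\t")
            meta[key] = vals
            body_start = i + 1
        else:
            break
    for key in ("condition", "replicate"):
        if key not in meta:
            raise ParseError(f"{path}: missing '#{key}' metadata line")
    header = lines[body_start].split("\t")
    if header[0] != "guide_id":
        raise ParseError(f"{path}: first column must be guide_id")
    names = header[1:]
    conditions = meta["condition"]
    replicates = meta["replicate"]
    if not (len(names) == len(conditions) == len(replicates)):
        raise ParseError(f"{path}: sample metadata width mismatch")
    for c in conditions:
        if c not in (REFERENCE, SCREENED):
            raise ParseError(f"{path}: unknown condition label {c!r}")
    samples = [
        Sample(n, c, int(r)) for n, c, r in zip(names, conditions, replicates)
    ]
    guide_ids, rows = [], []
    for ln in lines[body_start + 1:]:
        parts = ln.split("\t")
        if len(parts) != len(names) + 1:
            raise ParseError(f"{path}: ragged row for {parts[0]!r}")
        guide_ids.append(parts[0])
        try:
            row = [int(v) for v in parts[1:]]
        except ValueError as exc:
            raise ParseError(
                f"{path}: non-integer count in row {parts[0]!r}"
            ) from exc
        if any(v < 0 for v in row):
            raise ParseError(f"{path}: negative count in row {parts[0]!r}")
        rows.append(row)
    if len(set(guide_ids)) != len(guide_ids):
        raise ParseError(f"{path}: duplicated guide_id")
    try:
        return ScreenCounts(guide_ids, samples, np.array(rows, dtype=np.int64))
    except InputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


# ------------------------------------------------------- scores / track

def write_scores(scores: list[GuideScore], path) -> None:
    df = pd.DataFrame(
        [(s.guide_id, s.lfc, s.z, s.n_replicates_used) for s in scores],
        columns=["guide_id", "lfc", "z", "n_replicates_used"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def read_scores(path) -> list[GuideScore]:
    df = pd.read_csv(path, sep="\t")
    return [
        GuideScore(r.guide_id, float(r.lfc), float(r.z),
                   int(r.n_replicates_used))
        for r in df.itertuples(index=False)
    ]


def write_track(track: ResidueTrack, path) -> None:
    df = pd.DataFrame({
        "residue": np.arange(1, track.protein_length + 1),
        "signal": track.signal,
        "support": track.support,
        "p_emp": (track.p_emp if track.p_emp is not None
                  else np.full(track.protein_length, np.nan)),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              na_rep="NA", lineterminator="\n")


def write_regions(calls: list[RegionCall], path) -> None:
    df = pd.DataFrame(
        [(c.start_aa, c.end_aa, c.score, c.p, c.rank) for c in calls],
        columns=["start_aa", "end_aa", "score", "p", "rank"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g",
              lineterminator="\n")


def read_regions(path) -> list[RegionCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        RegionCall(int(r.start_aa), int(r.end_aa), float(r.score),
                   float(r.p), int(r.rank))
        for r in df.itertuples(index=False)
    ]


def write_regions_bed(calls: list[RegionCall], path, chrom: str) -> None:
    """BED-like export: 0-based half-open (start0 = start_aa - 1, end0 = end_aa)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for c in calls:
            fh.write(
                f"{chrom}\t{c.start_aa - 1}\t{c.end_aa}\t"
                f"region_{c.rank}\t{c.score:.6g}\n"
            )


def write_truth(truth: SimTruth, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path, encoding="utf-8") as fh:
        return SimTruth.from_dict(json.load(fh))


# ---------------------------------------------------------------- config

class ModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_frameshift: float = Field(2.0 / 3.0, ge=0.0, le=1.0)
    p_inframe: float = Field(1.0 / 3.0, ge=0.0, le=1.0)
    ploidy: int = Field(2, ge=1)
    efficiency: float = Field(1.0, ge=0.0, le=1.0)
    log2_floor: float = -10.0

    def build(self) -> RepairOutcomeModel:
        return RepairOutcomeModel(
            self.p_frameshift, self.p_inframe, self.ploidy, self.efficiency
        )


class SimConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    domains: list[tuple[int, int, float]] = []
    s_scr: float = Field(0.3, ge=0.0, le=1.0)
    s_ref: float = Field(0.0, ge=0.0, le=1.0)
    t_pre: int = Field(21, ge=0)
    t_scr: int = Field(20, ge=0)
    coverage: int = Field(1000, ge=1)
    depth: int = Field(1_000_000, ge=1)
    bottleneck: Optional[int] = Field(None, ge=1)
    n_replicates: int = Field(2, ge=1)
    wright_fisher: bool = False

    def build_truth(self, protein_length: int, seed: int) -> SimTruth:
        return SimTruth(
            protein_length=protein_length,
            domains=[list(d) for d in self.domains],
            s_scr=self.s_scr,
            s_ref=self.s_ref,
            t_pre=self.t_pre,
            t_scr=self.t_scr,
            coverage=self.coverage,
            depth=self.depth,
            bottleneck=self.bottleneck,
            seed=seed,
        )


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    pseudocount: float = Field(0.5, gt=0.0)
    bandwidth: float = Field(5.0, gt=0.0)
    min_support: float = Field(0.25, ge=0.0)
    permutations: int = Field(1000, ge=1)
    alpha: float = Field(0.05, gt=0.0, le=1.0)
    min_len: int = Field(3, ge=1)
    max_gap: int = Field(2, ge=1)


class RunConfig(BaseModel):
    """Strict pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    gene: str = "SIMGENE"
    fasta: Optional[str] = None  # if unset, a random CDS is generated
    cds_length_nt: int = Field(2394, ge=3)
    flank_nt: int = Field(25, ge=0)
    n_controls: int = Field(99, ge=0)
    seed: int = 0
    model: ModelConfig = ModelConfig()
    sim: SimConfig = SimConfig()
    analysis: AnalysisConfig = AnalysisConfig()


def load_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic.ValidationError
        raise ParseError(f"{path}: {exc}") from exc


def load_sim_config(path) -> SimConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        return SimConfig.model_validate(data)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc


# -------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, out_dir) -> dict:
    """design → simulate → score → scan → evaluate, with a run manifest.

    All artifacts are deterministic functions of (config, seed); rerunning
    with the same inputs reproduces every output byte-identically.
    Returns a dict of artifact paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("library", "library.tsv"),
        ("counts", "counts.tsv"),
        ("truth", "truth.json"),
        ("scores", "scores.tsv"),
        ("track", "track.tsv"),
        ("regions", "regions.tsv"),
        ("regions_bed", "regions.bed"),
        ("metrics", "metrics.json"),
        ("manifest", "manifest.json"),
    ]}

    stage = "design"

    def _stage(name):
        nonlocal stage
        stage = name
        logger.info("stage %s", name)

    try:
        _stage("design")
        design_rng = substream(config.seed, "design")
        if config.fasta is not None:
            cds = read_fasta(config.fasta)[0]
        else:
            cds = random_cds(
                config.cds_length_nt // 3, config.flank_nt,
                design_rng, seq_id=config.gene,
            )
        library = design_tiling_library(
            cds, n_controls=config.n_controls, gene=config.gene,
            seed=int(design_rng.integers(2**31)),
        )
        write_library(library, paths["library"])

        _stage("simulate")
        truth = config.sim.build_truth(cds.protein_length, config.seed)
        counts = simulate_screen(
            library, truth,
            n_replicates=config.sim.n_replicates,
            model=config.model.build(),
            wright_fisher=config.sim.wright_fisher,
            rng=substream(config.seed, "sim"),
        )
        write_counts(counts, paths["counts"])
        write_truth(truth, paths["truth"])

        _stage("score")
        scores = score_guides(counts, library,
                              pseudocount=config.analysis.pseudocount)
        write_scores(scores, paths["scores"])

        _stage("scan")
        track = permutation_null(
            scores, library,
            B=config.analysis.permutations,
            bandwidth=config.analysis.bandwidth,
            min_support=config.analysis.min_support,
            protein_length=cds.protein_length,
            rng=substream(config.seed, "scan"),
        )
        write_track(track, paths["track"])
        calls = call_regions(
            track,
            alpha=config.analysis.alpha,
            min_len=config.analysis.min_len,
            max_gap=config.analysis.max_gap,
        )
        write_regions(calls, paths["regions"])
        write_regions_bed(calls, paths["regions_bed"], chrom=config.gene)

        _stage("evaluate")
        metrics = evaluate_calls(calls, truth)
        with open(paths["metrics"], "w", encoding="utf-8", newline="\n") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True,
                      default=float)
            fh.write("\n")
    except Exception as exc:
        from .errors import TileScanError

        raise TileScanError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "tilescan_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": ["design", "simulate", "score", "scan", "evaluate"],
        "artifacts": {k: p.name for k, p in paths.items()},
    }
    with open(paths["manifest"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
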