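"""Per-guide depletion scores and a gene-level permutation ranking.

Guide scoring follows the standard dropout-screen recipe: pseudocounted
read frequencies per sample, log2 fold-change of screened over reference
per replicate pair, centering on the median of the non-targeting
controls, and a robust z-score against the control distribution
(median/MAD with the 1.4826 normal-consistency factor).

Gene scoring is a deliberately simple median-z statistic with a
control-resampling permutation null and Benjamini–Hochberg FDR.  It is a
plumbing-grade stand-in for dedicated rankers such as MAGeCK's α-RRA,
good enough to consume simulated multi-gene screens — not a
re-implementation of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .guide_design import GuideRecord
from .synthetic_screen import REFERENCE, SCREENED, ScreenCounts

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # normal-consistency factor
MIN_CONTROLS_FOR_Z = 8
MIN_CONTROLS_FOR_PERMUTATION = 20


@dataclass(frozen=True)
class GuideScore:
    guide_id: str
    lfc: float
    z: float
    n_replicates_used: int


@dataclass(frozen=True)
class GeneScore:
    gene: str
    score: float  # median guide z
    p: float
    fdr: float
    n_guides: int
    flagged: bool  # fewer than 2 guides


def _median_mad(x: np.ndarray) -> tuple[float, float]:
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med, mad


def score_guides(
    counts: ScreenCounts,
    library: list[GuideRecord],
    pseudocount: float = 0.5,
) -> list[GuideScore]:
    """Control-anchored per-guide depletion scores.

    Per replicate pair: ``freq = (count + pc) / (colsum + pc * n_guides)``,
    raw lfc = log2(freq_scr / freq_ref), then centering on the median raw
    lfc of the control guides.  Per-guide lfc is the mean over replicate
    pairs, and z is the robust standardization against the control lfc
    distribution.  With no controls, centering/standardization falls back
    to all guides with a warning.
    """
    ref_cols = counts.columns(REFERENCE)
    scr_cols = counts.columns(SCREENED)
    if not ref_cols or not scr_cols:
        raise InputError("need at least one reference and one screened sample")
    id_to_record = {g.guide_id: g for g in library}
    missing = [gid for gid in counts.guide_ids if gid not in id_to_record]
    if missing:
        raise InputError(f"guides absent from library: {missing[:5]} ...")

    C = counts.counts.astype(float)
    colsum = C.sum(axis=0)
    if (colsum == 0).any():
        raise InputError("zero-depth sample column")
    n_guides = C.shape[0]
    freq = (C + pseudocount) / (colsum + pseudocount * n_guides)

    is_ctrl = np.array(
        [id_to_record[gid].is_control for gid in counts.guide_ids]
    )
    if not is_ctrl.any():
        logger.warning(
            "no control guides present; centering on all-guide median"
        )
    center_mask = is_ctrl if is_ctrl.any() else np.ones(n_guides, dtype=bool)

    # pair replicates by replicate index (sorted); unequal arms pair up to
    # the shorter one
    ref_sorted = sorted(ref_cols, key=lambda j: counts.samples[j].replicate)
    scr_sorted = sorted(scr_cols, key=lambda j: counts.samples[j].replicate)
    n_pairs = min(len(ref_sorted), len(scr_sorted))
    if len(ref_sorted) != len(scr_sorted):
        logger.warning(
            "unequal replicate counts (%d reference, %d screened); using %d pairs",
            len(ref_sorted), len(scr_sorted), n_pairs,
        )

    lfcs = np.zeros((n_guides, n_pairs))
    for k in range(n_pairs):
        raw = np.log2(freq[:, scr_sorted[k]] / freq[:, ref_sorted[k]])
        lfcs[:, k] = raw - np.median(raw[center_mask])
    lfc = lfcs.mean(axis=1)

    z_mask = is_ctrl
    if is_ctrl.sum() < MIN_CONTROLS_FOR_Z:
        if is_ctrl.any():
            logger.warning(
                "only %d control guides (< %d); z standardized on all guides",
                int(is_ctrl.sum()), MIN_CONTROLS_FOR_Z,
            )
        z_mask = np.ones(n_guides, dtype=bool)
    med, mad = _median_mad(lfc[z_mask])
    denom = max(MAD_SCALE * mad, 1e-12)  # keeps z finite (0) in the
    # degenerate all-identical case
    z = (lfc - med) / denom

    return [
        GuideScore(gid, float(lfc[i]), float(z[i]), n_pairs)
        for i, gid in enumerate(counts.guide_ids)
    ]


def score_genes(
    scores: list[GuideScore],
    library: list[GuideRecord],
    B: int = 1000,
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> list[GeneScore]:
    """Median-z gene ranking with a control-resampling null.

    For a gene with k guides, the null is B seeded draws of k-guide
    control sets; the one-sided (depletion) p-value is
    ``(1 + #{null median <= observed}) / (B + 1)``, BH-adjusted across
    genes.  Genes with fewer than 2 guides are scored but flagged.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed))
    )
    z_by_id = {s.guide_id: s.z for s in scores}
    ctrl_pool = np.array(
        [z_by_id[g.guide_id] for g in library
         if g.is_control and g.guide_id in z_by_id]
    )
    if len(ctrl_pool) < MIN_CONTROLS_FOR_PERMUTATION:
        raise InputError(
            f"gene-level permutation needs >= {MIN_CONTROLS_FOR_PERMUTATION} "
            f"control guides, found {len(ctrl_pool)}"
        )

    gene_z: dict[str, list[float]] = {}
    for g in library:
        if g.is_control or g.guide_id not in z_by_id:
            continue
        gene_z.setdefault(g.gene, []).append(z_by_id[g.guide_id])

    # one null ensemble per distinct guide count
    sizes = sorted({len(v) for v in gene_z.values()})
    null_by_size: dict[int, np.ndarray] = {}
    for k in sizes:
        draws = np.empty(B)
        for b in range(B):
            draws[b] = np.median(
                rng.choice(ctrl_pool, size=k, replace=False)
            )
        null_by_size[k] = draws

    genes = sorted(gene_z)
    obs = np.array([np.median(gene_z[g]) for g in genes])
    pvals = np.array(
        [
            (1.0 + (null_by_size[len(gene_z[g])] <= obs[i]).sum()) / (B + 1.0)
            for i, g in enumerate(genes)
        ]
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]

    results = [
        GeneScore(
            gene=g,
            score=float(obs[i]),
            p=float(pvals[i]),
            fdr=float(fdr[i]),
            n_guides=len(gene_z[g]),
            flagged=len(gene_z[g]) < 2,
        )
        for i, g in enumerate(genes)
    ]
    results.sort(key=lambda r: (r.score, r.gene))
    return results
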