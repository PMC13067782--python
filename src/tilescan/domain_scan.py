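"""Residue-level smoothing, permutation null, and region calling.

Guide depletion z-scores live at irregular residue positions (wherever an
NGG PAM put a cut site).  The scan projects them onto a per-residue track
with a Gaussian-kernel Nadaraya–Watson estimator, builds an empirical
null by shuffling scores over the fixed guide positions, BH-adjusts the
per-residue one-sided p-values, and merges significant residues into
called regions that can be compared across screens (consensus) or
against simulation ground truth (Jaccard recovery metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .guide_design import GuideRecord
from .depletion_scoring import GuideScore
from .synthetic_screen import SimTruth

DEFAULT_BANDWIDTH = 5.0
DEFAULT_MIN_SUPPORT = 0.25
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_LEN = 3
DEFAULT_MAX_GAP = 2


@dataclass
class ResidueTrack:
    """Per-residue smoothed signal with kernel support and optional p-values.

    ``signal``/``p_emp`` are NaN at residues whose support falls below the
    mask floor.
    """

    protein_length: int
    signal: np.ndarray
    support: np.ndarray
    p_emp: Optional[np.ndarray] = None


@dataclass(frozen=True)
class RegionCall:
    start_aa: int
    end_aa: int
    score: float  # mean smoothed signal over the region span
    p: float  # min BH-adjusted p within the region
    rank: int


def _positions_and_z(
    scores: list[GuideScore], library: list[GuideRecord]
) -> tuple[np.ndarray, np.ndarray]:
    aa_by_id = {
        g.guide_id: g.target_aa for g in library if not g.is_control
    }
    pos, z = [], []
    for s in scores:
        if s.guide_id in aa_by_id and np.isfinite(s.z):
            pos.append(aa_by_id[s.guide_id])
            z.append(s.z)
    if not pos:
        raise InputError("no scored targeting guides to smooth")
    return np.array(pos, dtype=float), np.array(z, dtype=float)


def _kernel_matrix(
    positions: np.ndarray, protein_length: int, bandwidth: float
) -> np.ndarray:
    if bandwidth <= 0:
        raise InputError("bandwidth must be > 0")
    residues = np.arange(1, protein_length + 1, dtype=float)
    u = (residues[:, None] - positions[None, :]) / bandwidth
    return np.exp(-0.5 * u**2)


def _infer_length(
    library: list[GuideRecord], protein_length: Optional[int]
) -> int:
    if protein_length is not None:
        return protein_length
    return max(g.target_aa for g in library if not g.is_control)


def smooth_track(
    scores: list[GuideScore],
    library: list[GuideRecord],
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_support: float = DEFAULT_MIN_SUPPORT,
    protein_length: Optional[int] = None,
) -> ResidueTrack:
    """Nadaraya–Watson smoothing of guide z-scores along the protein.

    ``signal(a) = sum_g K((a - aa_g)/h) z_g / sum_g K((a - aa_g)/h)`` with
    a Gaussian kernel; ``support(a)`` is the kernel mass and residues
    below ``min_support`` are masked to NaN.
    """
    L = _infer_length(library, protein_length)
    pos, z = _positions_and_z(scores, library)
    K = _kernel_matrix(pos, L, bandwidth)
    support = K.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        signal = (K @ z) / support
    signal = np.where(support >= min_support, signal, np.nan)
    return ResidueTrack(L, signal=signal, support=support)


def permutation_null(
    scores: list[GuideScore],
    library: list[GuideRecord],
    B: int = 1000,
    seed: int = 0,
    bandwidth: float = DEFAULT_BANDWIDTH,
    min_support: float = DEFAULT_MIN_SUPPORT,
    protein_length: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ResidueTrack:
    """Smoothed track with per-residue empirical p-values.

    The null shuffles the z-vector over the fixed guide positions
    (preserving spatial guide density) B times; one-sided depletion
    p-values are ``(1 + #{null signal <= observed}) / (B + 1)`` and are
    therefore bounded below by 1/(B+1).
    """
    if B < 1:
        raise InputError("B must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed))
    )
    L = _infer_length(library, protein_length)
    pos, z = _positions_and_z(scores, library)
    K = _kernel_matrix(pos, L, bandwidth)
    support = K.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        observed = (K @ z) / support
    exceed = np.zeros(L)
    for _ in range(B):
        null = (K @ rng.permutation(z)) / support
        exceed += null <= observed
    p = (1.0 + exceed) / (B + 1.0)
    mask = support >= min_support
    return ResidueTrack(
        L,
        signal=np.where(mask, observed, np.nan),
        support=support,
        p_emp=np.where(mask, p, np.nan),
    )


def merge_significant_residues(
    residues: list[int], max_gap: int
) -> list[tuple[int, int]]:
    """Merge sorted significant residues into runs.

    Two residues belong to the same run when their coordinate difference
    is at most ``max_gap`` (so max_gap=2 bridges one intervening
    non-significant residue).
    """
    if not residues:
        return []
    step = max(1, max_gap)
    runs = []
    start = prev = residues[0]
    for r in residues[1:]:
        if r - prev <= step:
            prev = r
        else:
            runs.append((start, prev))
            start = prev = r
    runs.append((start, prev))
    return runs


def call_regions(
    track: ResidueTrack,
    alpha: float = DEFAULT_ALPHA,
    min_len: int = DEFAULT_MIN_LEN,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[RegionCall]:
    """BH-threshold the per-residue p-values and merge into regions.

    Regions shorter than ``min_len`` are dropped; score is the mean
    smoothed signal over the span, region p the minimum adjusted p
    within, and rank orders by score ascending (most depleted first).
    An empty list (nothing significant) is a valid outcome.
    """
    if track.p_emp is None:
        raise InputError("track has no p_emp; run permutation_null first")
    supported = np.isfinite(track.p_emp)
    if not supported.any():
        return []
    padj_full = np.full(track.protein_length, np.nan)
    padj_full[supported] = multipletests(
        track.p_emp[supported], method="fdr_bh"
    )[1]
    sig = [
        a + 1
        for a in range(track.protein_length)
        if supported[a] and padj_full[a] <= alpha
    ]
    calls = []
    for start, end in merge_significant_residues(sig, max_gap):
        if end - start + 1 < min_len:
            continue
        span = slice(start - 1, end)
        calls.append(
            (
                float(np.nanmean(track.signal[span])),
                float(np.nanmin(padj_full[span])),
                start,
                end,
            )
        )
    calls.sort()  # score ascending = most depleted first
    return [
        RegionCall(start_aa=s, end_aa=e, score=sc, p=p, rank=i + 1)
        for i, (sc, p, s, e) in enumerate(calls)
    ]


def consensus(
    calls_per_screen: list[list[RegionCall]], mode: str = "intersect"
) -> list[RegionCall]:
    """Combine region calls across screens.

    ``intersect`` (default) keeps only interval intersections supported by
    every screen (pairwise overlap >= 1 residue); ``union`` merges all
    overlapping intervals from any screen.  Scores are averaged over the
    contributing calls; p is the most conservative (max) member p.
    """
    if len(calls_per_screen) < 2:
        raise InputError("consensus needs at least 2 call sets")
    if mode == "intersect":
        current = [
            ((c.start_aa, c.end_aa), [c.score], [c.p])
            for c in calls_per_screen[0]
        ]
        for calls in calls_per_screen[1:]:
            merged = []
            for (s0, e0), sc, ps in current:
                for c in calls:
                    s, e = max(s0, c.start_aa), min(e0, c.end_aa)
                    if s <= e:
                        merged.append(((s, e), sc + [c.score], ps + [c.p]))
            current = merged
        out = [
            (float(np.mean(sc)), float(max(ps)), s, e)
            for (s, e), sc, ps in current
        ]
    elif mode == "union":
        pool = sorted(
            (c.start_aa, c.end_aa, c.score, c.p)
            for calls in calls_per_screen
            for c in calls
        )
        out = []
        for s, e, sc, p in pool:
            if out and s <= out[-1][3] + 1:
                prev = out[-1]
                out[-1] = (
                    float(np.mean([prev[0], sc])),
                    float(max(prev[1], p)),
                    prev[2],
                    max(prev[3], e),
                )
            else:
                out.append((sc, p, s, e))
    else:
        raise InputError(f"unknown consensus mode {mode!r}")
    out.sort()
    return [
        RegionCall(start_aa=s, end_aa=e, score=sc, p=p, rank=i + 1)
        for i, (sc, p, s, e) in enumerate(out)
    ]


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard index of two 1-based inclusive residue intervals."""
    inter = min(a[1], b[1]) - max(a[0], b[0]) + 1
    if inter <= 0:
        return 0.0
    union = max(a[1], b[1]) - min(a[0], b[0]) + 1
    return inter / union


def evaluate_calls(calls: list[RegionCall], truth: SimTruth) -> dict:
    """Recovery metrics of region calls against simulation ground truth.

    Per truth domain: best-overlap Jaccard over all calls.  ``recall`` is
    the fraction of truth domains recovered at Jaccard >= 0.5;
    ``precision`` the fraction of calls overlapping any truth domain
    (NaN when there are no calls).
    """
    truth_ivs = [(d.start_aa, d.end_aa) for d in truth.domains]
    call_ivs = [(c.start_aa, c.end_aa) for c in calls]
    per_domain = [
        max((interval_jaccard(t, c) for c in call_ivs), default=0.0)
        for t in truth_ivs
    ]
    overlapping = [
        c for c in call_ivs
        if any(interval_jaccard(c, t) > 0 for t in truth_ivs)
    ]
    return {
        "per_domain_jaccard": per_domain,
        "mean_jaccard": float(np.mean(per_domain)) if per_domain else float("nan"),
        "recall": (
            float(np.mean([j >= 0.5 for j in per_domain]))
            if per_domain else float("nan")
        ),
        "precision": (
            len(overlapping) / len(call_ivs) if call_ivs else float("nan")
        ),
        "n_calls": len(call_ivs),
    }
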