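"""Forward simulator for pooled CRISPR tiling screens.

The generator reproduces the stages of an in vivo dropout screen with a
known implanted ground truth:

1. transduction at low MOI (one guide per cell) of ``coverage`` cells per
   guide, with per-allele repair outcomes drawn from the diploid
   :class:`~tilescan.allele_model.RepairOutcomeModel`;
2. in vitro pre-depletion culture for ``t_pre`` generations at the
   reference fitness deficit ``s_ref``;
3. a split into a screened arm (optional engraftment bottleneck, then
   ``t_scr`` generations at ``s_scr``) and a reference arm that stays in
   culture at ``s_ref``;
4. sequencing of each sample as one multinomial draw of ``depth`` reads
   over guides proportional to final cell abundances.

By default genotype-class frequencies are propagated deterministically in
expectation (stochasticity only at transduction, bottleneck, and
sequencing), which isolates the signal the downstream scan must detect.
A per-generation stochastic mode (Poisson branching with binomial
genotype splits — guide populations must be allowed to shrink or grow,
otherwise selection leaves no between-guide signal) is available via
``wright_fisher=True``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._streams import substream
from .allele_model import RepairOutcomeModel, loss_fraction
from .errors import InputError
from .guide_design import CodingSequence, GuideRecord, design_tiling_library

REFERENCE = "reference"
SCREENED = "screened"

_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in _STOPS
]

#: the five consensus regions reported for the integrin-β1 ectodomain scan,
#: reused here purely as implanted fixture coordinates (R1 = 153–171 is the
#: functionally critical one and gets the largest disruption probability)
ITGB1_REGIONS = [(153, 171), (248, 254), (280, 295), (305, 314), (359, 363)]
ITGB1_PROTEIN_LENGTH = 798


@dataclass(frozen=True)
class Domain:
    """An implanted functional region: in-frame disruption probability d
    applies to every residue in [start_aa, end_aa]."""

    start_aa: int
    end_aa: int
    d: float


@dataclass
class SimTruth:
    """Ground truth and conditions of one simulated screen."""

    protein_length: int
    domains: list[Domain]
    s_scr: float = 0.3
    s_ref: float = 0.0
    t_pre: int = 21
    t_scr: int = 20
    coverage: int = 1000
    depth: int = 1_000_000
    bottleneck: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.domains = [
            d if isinstance(d, Domain) else Domain(*d) for d in self.domains
        ]
        if self.protein_length < 1:
            raise InputError("protein_length must be >= 1")
        if self.coverage < 1 or self.depth < 1:
            raise InputError("coverage and depth must be >= 1")
        for dom in self.domains:
            if not 1 <= dom.start_aa <= dom.end_aa <= self.protein_length:
                raise InputError(f"domain {dom} outside protein 1..{self.protein_length}")
            if not 0.0 <= dom.d <= 1.0:
                raise InputError(f"domain d must be in [0,1], got {dom.d}")
        ordered = sorted(self.domains, key=lambda x: x.start_aa)
        for a, b in zip(ordered, ordered[1:]):
            if b.start_aa <= a.end_aa:
                raise InputError(f"domains {a} and {b} overlap")

    def d_at(self, aa: int) -> float:
        """Disruption probability at residue ``aa`` (0 outside domains)."""
        for dom in self.domains:
            if dom.start_aa <= aa <= dom.end_aa:
                return dom.d
        return 0.0

    def to_dict(self) -> dict:
        return {
            "protein_length": self.protein_length,
            "domains": [[d.start_aa, d.end_aa, d.d] for d in self.domains],
            "s_scr": self.s_scr,
            "s_ref": self.s_ref,
            "t_pre": self.t_pre,
            "t_scr": self.t_scr,
            "coverage": self.coverage,
            "depth": self.depth,
            "bottleneck": self.bottleneck,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SimTruth":
        return cls(**data)


@dataclass(frozen=True)
class Sample:
    name: str
    condition: str  # REFERENCE or SCREENED
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in (REFERENCE, SCREENED):
            raise InputError(f"unknown condition {self.condition!r}")


@dataclass
class ScreenCounts:
    """Guide × sample integer count matrix with sample metadata."""

    guide_ids: list[str]
    samples: list[Sample]
    counts: np.ndarray  # shape (n_guides, n_samples), int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.guide_ids), len(self.samples)):
            raise InputError("count matrix shape does not match metadata")
        if (self.counts < 0).any():
            raise InputError("counts must be non-negative")
        if len(set(self.guide_ids)) != len(self.guide_ids):
            raise InputError("duplicated guide_id in count matrix")

    def columns(self, condition: str) -> list[int]:
        return [
            j for j, s in enumerate(self.samples) if s.condition == condition
        ]


def random_cds(
    n_codons: int,
    flank_nt: int,
    rng: np.random.Generator,
    seq_id: str = "synthetic_cds",
) -> CodingSequence:
    """A random open reading frame (ATG + sense codons) with random flanks."""
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons - 1)
    seq = "ATG" + "".join(_SENSE_CODONS[k] for k in idx)
    bases = np.array(list("ACGT"))
    flank5 = "".join(bases[rng.integers(0, 4, size=flank_nt)])
    flank3 = "".join(bases[rng.integers(0, 4, size=flank_nt)])
    return CodingSequence(id=seq_id, seq=seq, flank5=flank5, flank3=flank3)


def _branching_propagate(
    rng: np.random.Generator,
    n_lof: np.ndarray,
    n_ok: np.ndarray,
    s: float,
    gens: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-generation stochastic reproduction (Poisson branching)."""
    for _ in range(gens):
        w_lof = n_lof * (1.0 - s)
        tot = w_lof + n_ok
        n_next = rng.poisson(tot)
        with np.errstate(invalid="ignore"):
            p_lof = np.where(tot > 0, w_lof / np.maximum(tot, 1e-300), 0.0)
        n_lof = rng.binomial(n_next, p_lof)
        n_ok = n_next - n_lof
    return n_lof.astype(float), n_ok.astype(float)


def simulate_screen(
    library: list[GuideRecord],
    truth: SimTruth,
    n_replicates: int = 2,
    model: Optional[RepairOutcomeModel] = None,
    wright_fisher: bool = False,
    rng: Optional[np.random.Generator] = None,
) -> ScreenCounts:
    """Simulate sequencing counts for a tiling library under ``truth``.

    Returns a :class:`ScreenCounts` with ``n_replicates`` reference
    columns followed by ``n_replicates`` screened columns; every column
    sums to ``truth.depth``.  Fully reproducible from ``truth.seed``.
    """
    model = model or RepairOutcomeModel()
    rng = rng if rng is not None else substream(truth.seed, "sim")
    if not library:
        raise InputError("empty guide library")
    for g in library:
        if not g.is_control and g.target_aa > truth.protein_length:
            raise InputError(
                f"guide {g.guide_id} targets residue {g.target_aa} beyond "
                f"protein length {truth.protein_length}"
            )

    f = np.array(
        [
            0.0 if g.is_control else loss_fraction(model, truth.d_at(g.target_aa))
            for g in library
        ]
    )
    n_guides = len(library)

    # one transduced pool per screen, pre-depleted in vitro, then split
    n_lof0 = rng.binomial(truth.coverage, f).astype(float)
    n_ok0 = truth.coverage - n_lof0
    if wright_fisher:
        n_lof0, n_ok0 = _branching_propagate(
            rng, n_lof0, n_ok0, truth.s_ref, truth.t_pre
        )
    else:
        n_lof0 = n_lof0 * (1.0 - truth.s_ref) ** truth.t_pre

    samples: list[Sample] = []
    cols: list[np.ndarray] = []
    for condition in (REFERENCE, SCREENED):
        s_cond = truth.s_scr if condition == SCREENED else truth.s_ref
        for rep in range(1, n_replicates + 1):
            n_lof, n_ok = n_lof0.copy(), n_ok0.copy()
            if condition == SCREENED and truth.bottleneck is not None:
                thin = truth.bottleneck / truth.coverage
                n_lof = rng.poisson(thin * n_lof).astype(float)
                n_ok = rng.poisson(thin * n_ok).astype(float)
            if wright_fisher:
                n_lof, n_ok = _branching_propagate(
                    rng, n_lof, n_ok, s_cond, truth.t_scr
                )
            else:
                n_lof = n_lof * (1.0 - s_cond) ** truth.t_scr
            abundance = n_lof + n_ok
            total = abundance.sum()
            if total <= 0:
                raise InputError(
                    f"population extinct in {condition} replicate {rep}"
                )
            counts = rng.multinomial(truth.depth, abundance / total)
            samples.append(Sample(f"{condition[:3]}_{rep}", condition, rep))
            cols.append(counts)

    return ScreenCounts(
        guide_ids=[g.guide_id for g in library],
        samples=samples,
        counts=np.column_stack(cols),
    )


@dataclass(frozen=True)
class FixtureBundle:
    cds: CodingSequence
    library: list[GuideRecord]
    truth: SimTruth


def make_itgb1_like_fixture(
    seed: int,
    d_max: float = 1.0,
    d_other: float = 0.99,
    coverage: int = 500,
    depth: int = 1_000_000,
    s_scr: float = 0.3,
    t_scr: int = 20,
) -> FixtureBundle:
    """Synthetic stand-in for the integrin-β1 tiling screen.

    Emits a seeded random 2394-nt CDS (798 residues), its saturating
    tiling library with 99 non-targeting controls, and a ground truth
    implanting the five consensus-region intervals, with the first
    (residues 153–171) assigned the largest disruption probability.  The
    CDS is synthetic — random codons, not the real gene.
    """
    rng = substream(seed, "fixture")
    cds = random_cds(ITGB1_PROTEIN_LENGTH, flank_nt=25, rng=rng, seq_id="ITGB1SIM")
    library = design_tiling_library(
        cds, n_controls=99, gene="ITGB1SIM", seed=int(rng.integers(2**31))
    )
    domains = [
        Domain(start, end, d_max if (start, end) == (153, 171) else d_other)
        for start, end in ITGB1_REGIONS
    ]
    truth = SimTruth(
        protein_length=ITGB1_PROTEIN_LENGTH,
        domains=domains,
        s_scr=s_scr,
        s_ref=0.0,
        t_pre=21,
        t_scr=t_scr,
        coverage=coverage,
        depth=depth,
        seed=seed,
    )
    return FixtureBundle(cds=cds, library=library, truth=truth)


def neutral_truth(
    protein_length: int,
    coverage: int = 500,
    depth: int = 1_000_000,
    seed: int = 0,
) -> SimTruth:
    """A fully neutral screen: no domains, no selection anywhere."""
    return SimTruth(
        protein_length=protein_length,
        domains=[],
        s_scr=0.0,
        s_ref=0.0,
        t_pre=0,
        t_scr=0,
        coverage=coverage,
        depth=depth,
        seed=seed,
    )


def make_gene_library(
    n_genes: int,
    guides_per_gene: int,
    n_controls: int,
    protein_length: int = 1000,
    seed: int = 0,
) -> list[GuideRecord]:
    """A schematic multi-gene library for gene-level scoring tests.

    Guides carry gene labels and arbitrary residue assignments; the
    protospacer content is a placeholder (gene-mode scoring never reads
    sequence).
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    records: list[GuideRecord] = []
    for gi in range(n_genes):
        gene = f"gene{gi:04d}"
        for k in range(guides_per_gene):
            aa = int(rng.integers(1, protein_length + 1))
            cut = (aa - 1) * 3 + 1
            records.append(
                GuideRecord(
                    guide_id=f"{gene}_g{k}",
                    gene=gene,
                    protospacer="A" * 20,
                    strand="+",
                    pam_pos_nt=cut + 3,
                    cut_nt=cut,
                    target_aa=aa,
                    is_control=False,
                )
            )
    for k in range(n_controls):
        records.append(
            GuideRecord(
                guide_id=f"control_{k:03d}",
                gene="control",
                protospacer="A" * 20,
                strand=None,
                pam_pos_nt=None,
                cut_nt=None,
                target_aa=None,
                is_control=True,
            )
        )
    return records
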