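"""Saturating sgRNA tiling-library design over a coding sequence.

A CRISPR tiling ("scanning") library targets every SpCas9 protospacer
adjacent motif (PAM, 5'-NGG-3') on both strands of a coding sequence, so
that Cas9 cut sites blanket the protein at near-codon resolution.  This
module enumerates those sites, extracts the 20-nt protospacers, records
the blunt cut position, and maps it onto 1-based residue coordinates.

Coordinate conventions (1-based, inclusive, on the coding strand):

* SpCas9 cuts bluntly 3 bp 5' of the PAM, i.e. between protospacer
  positions 17 and 18.  ``cut_nt`` is the first nucleotide 3' of the cut
  on the coding strand.
* ``pam_pos_nt`` is the leftmost coding-strand base of the PAM window.
  For a plus-strand guide (NGG starting at p) the cut falls at p - 3; for
  a minus-strand guide (plus-strand CCN starting at q) it falls at q + 6.
* The targeted residue is the one whose codon contains ``cut_nt``:
  ``target_aa = (cut_nt - 1) // 3 + 1``.

Protospacers that would run off the CDS ends are filled from the supplied
flanking context when available, otherwise the candidate is dropped and
logged.  Non-targeting controls are seeded random 20-mers with no match
anywhere in the CDS-plus-flank context on either strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError

logger = logging.getLogger(__name__)

_VALID_NT = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

PROTOSPACER_LEN = 20
#: distance from the PAM-proximal protospacer end to the blunt cut
CUT_OFFSET = 3

CONTROL_GENE = "control"


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_nt(seq: str, what: str) -> None:
    bad = set(seq) - _VALID_NT
    if bad:
        raise InputError(
            f"{what} contains non-ACGT characters: {sorted(bad)}"
        )


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding sequence with optional flanking context.

    ``seq`` must be a non-empty multiple of 3 over {A,C,G,T}; flanks are
    only used to complete protospacers that overhang the CDS ends.
    """

    id: str
    seq: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) == 0:
            raise InputError(f"CDS {self.id!r} is empty")
        if len(self.seq) % 3 != 0:
            raise InputError(
                f"CDS {self.id!r} length {len(self.seq)} is not a multiple of 3"
            )
        _check_nt(self.seq, f"CDS {self.id!r}")
        _check_nt(self.flank5, f"5' flank of {self.id!r}")
        _check_nt(self.flank3, f"3' flank of {self.id!r}")

    @property
    def protein_length(self) -> int:
        return len(self.seq) // 3


@dataclass(frozen=True)
class GuideRecord:
    """One sgRNA of a tiling library.

    Positional fields are ``None`` for non-targeting controls.
    """

    guide_id: str
    gene: str
    protospacer: str
    strand: Optional[str]  # '+' or '-' relative to the coding strand
    pam_pos_nt: Optional[int]
    cut_nt: Optional[int]
    target_aa: Optional[int]
    is_control: bool = False


@dataclass(frozen=True)
class PamSite:
    """A candidate NGG site (PAM window fully inside the CDS)."""

    strand: str
    pam_pos_nt: int  # leftmost coding-strand base of the PAM window
    cut_nt: int


@dataclass(frozen=True)
class LibraryPlan:
    """Arithmetic of a multi-gene library configuration.

    Used as a design-stage sanity check that an assembled library matches
    its plan (e.g. a cell-surface-proteome library of 5 guides per gene
    over 581 genes must emit 2905 targeting guides).
    """

    n_genes: int
    guides_per_gene: int
    n_controls: int = 0

    @property
    def n_targeting(self) -> int:
        return self.n_genes * self.guides_per_gene

    @property
    def n_total(self) -> int:
        return self.n_targeting + self.n_controls

    def check(self, library: list[GuideRecord]) -> None:
        """Raise :class:`InputError` unless ``library`` matches the plan."""
        targeting = [g for g in library if not g.is_control]
        controls = [g for g in library if g.is_control]
        genes = {g.gene for g in targeting}
        if len(targeting) != self.n_targeting:
            raise InputError(
                f"library has {len(targeting)} targeting guides, "
                f"plan requires {self.n_targeting}"
            )
        if len(genes) != self.n_genes:
            raise InputError(
                f"library covers {len(genes)} genes, plan requires {self.n_genes}"
            )
        if len(controls) != self.n_controls:
            raise InputError(
                f"library has {len(controls)} controls, plan requires {self.n_controls}"
            )


def map_cut_to_residue(cut_nt: int, cds_length: int) -> int:
    """Map a 1-based cut-site nucleotide coordinate to a 1-based residue index."""
    if not 1 <= cut_nt <= cds_length:
        raise InputError(
            f"cut_nt {cut_nt} outside CDS coordinates 1..{cds_length}"
        )
    return (cut_nt - 1) // 3 + 1


def enumerate_pam_sites(cds: CodingSequence) -> list[PamSite]:
    """All NGG PAM windows fully inside the CDS, both strands.

    Sites are returned regardless of whether the cut site or protospacer
    is realizable; :func:`design_tiling_library` applies those rules.
    """
    s = cds.seq
    L = len(s)
    sites: list[PamSite] = []
    for i in range(L - 2):  # 0-based PAM window i..i+2
        if s[i + 1 : i + 3] == "GG":
            sites.append(PamSite("+", pam_pos_nt=i + 1, cut_nt=i - 2))
        if s[i : i + 2] == "CC":
            sites.append(PamSite("-", pam_pos_nt=i + 1, cut_nt=i + 8 - 1))
    return sites


def _protospacer_for(cds: CodingSequence, site: PamSite) -> Optional[str]:
    """Extract the 20-nt protospacer for a site, or None if context is short."""
    ext = cds.flank5 + cds.seq + cds.flank3
    off = len(cds.flank5)
    i = site.pam_pos_nt - 1  # 0-based PAM window start in cds.seq
    if site.strand == "+":
        start, end = off + i - PROTOSPACER_LEN, off + i
        if start < 0:
            return None
        return ext[start:end]
    start, end = off + i + 3, off + i + 3 + PROTOSPACER_LEN
    if end > len(ext):
        return None
    return reverse_complement(ext[start:end])


def _random_controls(
    cds: CodingSequence, n_controls: int, rng: np.random.Generator
) -> list[str]:
    """Seeded random 20-mers with no exact match to the CDS context.

    Rejecting any occurrence on either strand is stronger than the minimal
    "no NGG-adjacent match" requirement but equally cheap and never wrong.
    """
    context = cds.flank5 + cds.seq + cds.flank3
    context_rc = reverse_complement(context)
    bases = np.array(list("ACGT"))
    out: list[str] = []
    attempts = 0
    while len(out) < n_controls:
        attempts += 1
        if attempts > 1000 * max(n_controls, 1):
            raise InputError("could not generate non-targeting controls")
        proto = "".join(bases[rng.integers(0, 4, size=PROTOSPACER_LEN)])
        if proto in context or proto in context_rc:
            continue
        out.append(proto)
    return out


def design_tiling_library(
    cds: CodingSequence,
    n_controls: int = 0,
    gene: Optional[str] = None,
    seed: int = 0,
    return_dropped: bool = False,
):
    """Enumerate the saturating tiling library of ``cds``.

    One :class:`GuideRecord` is emitted per NGG occurrence on either
    strand whose blunt cut site falls inside the CDS and whose
    protospacer can be completed (from the CDS or its flanks); candidates
    that cannot are dropped and logged.  ``n_controls`` non-targeting
    records with seeded random protospacers are appended.

    Returns the record list, or ``(records, dropped_sites)`` when
    ``return_dropped`` is true.  Targeting records are sorted by
    ``(cut_nt, strand)``; there are no duplicate ``(pam_pos_nt, strand)``
    pairs by construction.
    """
    gene = gene if gene is not None else cds.id
    L = len(cds.seq)
    records: list[GuideRecord] = []
    dropped: list[PamSite] = []
    for site in enumerate_pam_sites(cds):
        if not 1 <= site.cut_nt <= L:
            dropped.append(site)
            continue
        proto = _protospacer_for(cds, site)
        if proto is None:
            logger.info(
                "dropping %s-strand PAM at %d of %s: protospacer overhangs "
                "the CDS and no flank context is available",
                site.strand, site.pam_pos_nt, cds.id,
            )
            dropped.append(site)
            continue
        cut = site.cut_nt
        records.append(
            GuideRecord(
                guide_id=f"{gene}_{cut:04d}{site.strand}",
                gene=gene,
                protospacer=proto,
                strand=site.strand,
                pam_pos_nt=site.pam_pos_nt,
                cut_nt=cut,
                target_aa=map_cut_to_residue(cut, L),
                is_control=False,
            )
        )
    records.sort(key=lambda g: (g.cut_nt, g.strand))

    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed)))
    for k, proto in enumerate(_random_controls(cds, n_controls, rng)):
        records.append(
            GuideRecord(
                guide_id=f"{CONTROL_GENE}_{k:03d}",
                gene=CONTROL_GENE,
                protospacer=proto,
                strand=None,
                pam_pos_nt=None,
                cut_nt=None,
                target_aa=None,
                is_control=True,
            )
        )
    if return_dropped:
        return records, dropped
    return records
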