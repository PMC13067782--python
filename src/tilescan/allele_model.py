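"""Diploid repair-outcome model for Cas9 tiling screens.

After a Cas9 double-strand break, end-joining repair yields a frameshift
indel with probability ~2/3 and an in-frame indel with probability ~1/3.
A frameshift knocks the allele out regardless of position; an in-frame
indel knocks it out only with probability ``d``, the per-residue
disruption probability (d ≈ 0 in dispensable stretches, d → 1 in critical
functional regions).  A diploid cell loses all function only when *both*
alleles are knocked out, so with independent allele outcomes the
loss-of-function cell fraction is

    f(d) = [eff · (p_fs + p_if · d)] ** ploidy

which for the defaults spans 4/9 ≈ 44% at d = 0 up to 100% at d = 1.
Loss-of-function cells carry a per-generation fitness deficit ``s`` under
selection; the expected guide abundance after T generations, relative to
an unselected reference, is what a dropout screen measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InputError

DEFAULT_LOG2_FLOOR = -10.0


def _check_prob(x: float, name: str) -> None:
    if not 0.0 <= x <= 1.0:
        raise InputError(f"{name} must be in [0, 1], got {x}")


@dataclass(frozen=True)
class RepairOutcomeModel:
    """Per-allele edit-outcome probabilities.

    ``efficiency`` is the probability that an allele is cut and repaired
    at all; the default of 1 matches the idealized arithmetic in which
    every allele is edited.
    """

    p_frameshift: float = 2.0 / 3.0
    p_inframe: float = 1.0 / 3.0
    ploidy: int = 2
    efficiency: float = 1.0

    def __post_init__(self) -> None:
        _check_prob(self.p_frameshift, "p_frameshift")
        _check_prob(self.p_inframe, "p_inframe")
        _check_prob(self.efficiency, "efficiency")
        if abs(self.p_frameshift + self.p_inframe - 1.0) > 1e-9:
            raise InputError("p_frameshift + p_inframe must equal 1")
        if self.ploidy < 1:
            raise InputError("ploidy must be >= 1")


@dataclass(frozen=True)
class SelectionParams:
    """Per-generation fitness deficits and generation counts per condition.

    ``s_ref``/``T_ref`` describe the reference (in vitro) arm, ``s_scr``/
    ``T_scr`` the screened (in vivo) arm.  ``s`` is the relative fitness
    deficit of loss-of-function cells: their per-generation growth weight
    is ``1 - s`` against 1 for functional cells.
    """

    s_ref: float = 0.0
    s_scr: float = 0.0
    T_ref: int = 0
    T_scr: int = 0

    def __post_init__(self) -> None:
        _check_prob(self.s_ref, "s_ref")
        _check_prob(self.s_scr, "s_scr")
        if self.T_ref < 0 or self.T_scr < 0:
            raise InputError("generation counts must be >= 0")


def loss_fraction(model: RepairOutcomeModel, d: float) -> float:
    """Fraction of guide-receiving cells retaining zero functional alleles.

    Each allele is knocked out independently with probability
    ``efficiency * (p_frameshift + p_inframe * d)``; a cell is
    loss-of-function when every one of its ``ploidy`` alleles is.
    """
    _check_prob(d, "d")
    per_allele = model.efficiency * (model.p_frameshift + model.p_inframe * d)
    return per_allele**model.ploidy


def expected_abundance_ratio(
    f: float,
    sel: SelectionParams,
    log2_floor: float = DEFAULT_LOG2_FLOOR,
) -> tuple[float, float]:
    """Expected screened/reference abundance ratio and its log2.

    A guide's cell population is a mixture of a loss-of-function fraction
    ``f`` (growth weight ``(1-s)`` per generation) and a functional
    remainder (weight 1), so its relative abundance in condition c is
    ``A_c = f (1 - s_c)^{T_c} + (1 - f)``.  Normalization against the
    population mean happens downstream in scoring.  The log2 is floored
    at ``log2_floor`` when the ratio underflows to zero.
    """
    _check_prob(f, "f")
    a_scr = f * (1.0 - sel.s_scr) ** sel.T_scr + (1.0 - f)
    a_ref = f * (1.0 - sel.s_ref) ** sel.T_ref + (1.0 - f)
    if a_ref == 0.0:
        raise InputError("reference abundance is zero; nothing to compare")
    ratio = a_scr / a_ref
    if ratio <= 0.0:
        return ratio, log2_floor
    return ratio, max(math.log2(ratio), log2_floor)
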