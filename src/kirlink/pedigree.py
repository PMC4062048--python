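"""Mendelian consistency of copy-number calls in nuclear families.

A diploid copy-number total hides its split across the two haplotypes: a
KIR2DL5 total of 2 may be 1+1 or 2+0. A family's calls are Mendelian-
consistent when there exists one split per parent such that every child's
total is one maternal haplotype count plus one paternal haplotype count —
the same parental split must explain all siblings jointly, because the
parental haplotypes are fixed. De novo copy-number events are not modeled;
an inconsistency is reported, not explained away.

The module also checks the population co-segregation rules linking KIR2DL5
to KIR2DS3 and KIR2DS5: absence of both implies no KIR2DL5, presence of
both implies at least two copies. These hold as near-perfect linkage
disequilibrium expectations, so violations are warnings rather than errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .errors import InfeasibleGenotypeError

DEFAULT_PER_HAPLOTYPE_MAX = 2


@dataclass
class FamilyGenotypes:
    """Integer copy-number calls for one nuclear family.

    ``None`` for a parent means unknown; unknown parents are treated as
    unconstrained over all feasible totals. ``presence`` optionally maps an
    individual label (``mother``, ``father``, ``child<i>`` or a real id) to
    a (KIR2DS3 present, KIR2DS5 present) pair.
    """

    family_id: str
    mother_cn: int | None
    father_cn: int | None
    children_cn: list
    per_haplotype_max: int = DEFAULT_PER_HAPLOTYPE_MAX
    children_ids: list | None = None
    presence: dict | None = field(default=None)

    def __post_init__(self) -> None:
        if not self.children_cn:
            raise ValueError(f"family {self.family_id}: no children")
        ceiling = 2 * self.per_haplotype_max
        for label, cn in (("mother", self.mother_cn), ("father", self.father_cn)):
            if cn is not None and not 0 <= cn <= ceiling:
                raise InfeasibleGenotypeError(
                    f"family {self.family_id}: {label} copy number {cn} outside [0, {ceiling}]"
                )
        for i, cn in enumerate(self.children_cn):
            if cn is not None and not 0 <= cn <= ceiling:
                raise InfeasibleGenotypeError(
                    f"family {self.family_id}: child {i} copy number {cn} outside [0, {ceiling}]"
                )


@dataclass(frozen=True)
class MendelianWitness:
    """One haplotype assignment that explains every child."""

    mother_split: tuple
    father_split: tuple
    transmissions: tuple  # per child: (maternal haplotype count, paternal)


@dataclass(frozen=True)
class MendelianVerdict:
    consistent: bool
    witness: MendelianWitness | None = None
    violating_child: int | None = None


def enumerate_haplotype_splits(total_cn: int, per_haplotype_max: int = DEFAULT_PER_HAPLOTYPE_MAX):
    """All ordered (h1, h2) pairs with h1 + h2 == total_cn, each within
    [0, per_haplotype_max]."""
    ceiling = 2 * per_haplotype_max
    if not 0 <= total_cn <= ceiling:
        raise InfeasibleGenotypeError(
            f"total copy number {total_cn} outside diploid range [0, {ceiling}]"
        )
    return {
        (h1, total_cn - h1)
        for h1 in range(0, per_haplotype_max + 1)
        if 0 <= total_cn - h1 <= per_haplotype_max
    }


def _parent_splits(cn: int | None, hmax: int):
    """Candidate splits for a parent; unknown parents range over all totals."""
    totals = range(0, 2 * hmax + 1) if cn is None else [cn]
    out = set()
    for t in totals:
        out |= enumerate_haplotype_splits(t, hmax)
    return sorted(out)


def mendelian_consistent(fam: FamilyGenotypes) -> MendelianVerdict:
    """Search for parental haplotype splits explaining all children jointly.

    Returns a witness (the splits and each child's transmitted haplotype
    counts) when consistent. Otherwise reports the first child left
    unexplained by the configuration that explains the most children, which
    is the most useful single pointer for review.
    """
    hmax = fam.per_haplotype_max
    m_splits = _parent_splits(fam.mother_cn, hmax)
    f_splits = _parent_splits(fam.father_cn, hmax)
    children = fam.children_cn
    best_explained = -1
    best_unexplained_child = 0
    for ms, fs in itertools.product(m_splits, f_splits):
        trans = []
        explained = 0
        first_bad = None
        for idx, c in enumerate(children):
            if c is None:
                trans.append((None, None))
                explained += 1
                continue
            found = next(
                ((mh, fh) for mh in ms for fh in fs if mh + fh == c), None
            )
            if found is None:
                if first_bad is None:
                    first_bad = idx
                trans.append(None)
            else:
                trans.append(found)
                explained += 1
        if first_bad is None:
            return MendelianVerdict(
                consistent=True,
                witness=MendelianWitness(
                    mother_split=ms, father_split=fs, transmissions=tuple(trans)
                ),
            )
        if explained > best_explained:
            best_explained = explained
            best_unexplained_child = first_bad
    return MendelianVerdict(consistent=False, violating_child=best_unexplained_child)


@dataclass(frozen=True)
class CosegregationResult:
    consistent: bool
    warnings: tuple = ()


def cosegregation_check(
    cn_2dl5: int, present_2ds3: bool, present_2ds5: bool
) -> CosegregationResult:
    """Check a KIR2DL5 copy number against KIR2DS3/KIR2DS5 presence calls.

    Absence of both KIR2DS3 and KIR2DS5 implies KIR2DL5 absent; presence of
    both implies at least two KIR2DL5 copies. These are linkage-
    disequilibrium expectations, so a violation is flagged as a warning."""
    warnings = []
    if not present_2ds3 and not present_2ds5 and cn_2dl5 > 0:
        warnings.append(
            f"KIR2DL5 copy number {cn_2dl5} but both KIR2DS3 and KIR2DS5 absent"
        )
    if present_2ds3 and present_2ds5 and cn_2dl5 < 2:
        warnings.append(
            f"KIR2DL5 copy number {cn_2dl5} but both KIR2DS3 and KIR2DS5 present"
            " (expected at least 2 copies)"
        )
    return CosegregationResult(consistent=not warnings, warnings=tuple(warnings))
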