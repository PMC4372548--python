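"""Pedigree-aware genotype-pattern evaluation under a dominant model.

Carrier status is dosage >= 1 (heterozygous or homozygous alternate).  Three
tiers are evaluated per family:

* ``segregates_definite`` — every sequenced definite case and every sequenced
  obligate carrier carries the variant (the hard segregation filter);
* ``segregates_all_aneurysm`` — additionally every sequenced probable IA,
  possible IA, or AAA member carries it (optional prioritization tier A);
* ``absent_in_unaffected`` — no sequenced, screened-unaffected,
  non-obligate-carrier member carries it (optional tier B).

Under the default ``strict`` missing-genotype policy, a MISSING genotype in
any member whose carrier status a tier requires fails that tier and sets
``missing_genotype_involved``; the ``permissive`` policy skips such members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from famvar.cohort import (
    ANEURYSM_CLASSES,
    Individual,
    Pedigree,
    PhenotypeClass,
    VariantRecord,
)

MissingPolicy = Literal["strict", "permissive"]


@dataclass(frozen=True)
class SegregationResult:
    family_id: str
    variant_key: tuple
    segregates_definite: bool
    segregates_all_aneurysm: bool
    absent_in_unaffected: bool
    unaffected_carrier_count: int
    missing_genotype_involved: bool


def _is_required_definite(ind: Individual) -> bool:
    return ind.sequenced and (
        ind.phenotype_class is PhenotypeClass.DEFINITE_IA or ind.obligate_carrier
    )


def _is_secondary_aneurysm(ind: Individual) -> bool:
    return ind.sequenced and ind.phenotype_class in (
        PhenotypeClass.PROBABLE_IA,
        PhenotypeClass.POSSIBLE_IA,
        PhenotypeClass.AAA,
    )


def _is_countable_unaffected(ind: Individual) -> bool:
    return (
        ind.sequenced
        and ind.phenotype_class is PhenotypeClass.UNAFFECTED_SCREENED
        and not ind.obligate_carrier
    )


def _all_carry(
    variant: VariantRecord, members: Iterable[Individual], policy: MissingPolicy
) -> tuple[bool, bool]:
    """(all required members carry, a missing genotype was involved)."""
    missing = False
    ok = True
    for ind in members:
        carrier = variant.is_carrier(ind.individual_id)
        if carrier is None:
            missing = True
            if policy == "strict":
                ok = False
        elif not carrier:
            ok = False
    return ok, missing


def evaluate_family_segregation(
    variant: VariantRecord, pedigree: Pedigree, policy: MissingPolicy = "strict"
) -> SegregationResult:
    """Evaluate all segregation tiers of one variant within one family."""
    required = [i for i in pedigree if _is_required_definite(i)]
    if not any(
        i.sequenced and i.phenotype_class is PhenotypeClass.DEFINITE_IA
        for i in pedigree
    ):
        raise ValueError(
            f"family {pedigree.family_id}: no sequenced definite case; "
            f"segregation is undefined"
        )

    seg_def, miss_def = _all_carry(variant, required, policy)
    secondary = [i for i in pedigree if _is_secondary_aneurysm(i)]
    seg_sec, miss_sec = _all_carry(variant, secondary, policy)
    seg_all = seg_def and seg_sec

    unaffected = [i for i in pedigree if _is_countable_unaffected(i)]
    # An unaffected's missing genotype cannot establish carriage; it does not
    # fail tier B but is surfaced through the missing flag.
    count = sum(
        1 for i in unaffected if variant.is_carrier(i.individual_id) is True
    )
    miss_unaff = any(
        variant.is_carrier(i.individual_id) is None for i in unaffected
    )

    return SegregationResult(
        family_id=pedigree.family_id,
        variant_key=variant.key,
        segregates_definite=seg_def,
        segregates_all_aneurysm=seg_all,
        absent_in_unaffected=count == 0,
        unaffected_carrier_count=count,
        missing_genotype_involved=miss_def or (seg_def and miss_sec) or miss_unaff,
    )


def count_unaffected_carriers(
    variant: VariantRecord, cohort: Iterable[Pedigree]
) -> int:
    """Cohort-wide count of sequenced, screened-unaffected, non-obligate
    carriers of the variant (the candidate table's Unaff column)."""
    return sum(
        1
        for ped in cohort
        for ind in ped
        if _is_countable_unaffected(ind)
        and variant.is_carrier(ind.individual_id) is True
    )
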