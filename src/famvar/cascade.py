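"""Ordered biological filter cascade with attrition accounting.

Filters, applied in order:

1. autosomal;
2. functional consequence agreed by all three gene models;
3. consensus population allele frequency below the rarity threshold;
4. internal database: below 1% binned frequency and not monomorphic;
5. damaging by CADD plus one concordant protein-level predictor;
6. segregates with every sequenced definite case and obligate carrier in at
   least one family.

Filters 1–5 are pure per-variant predicates, so the stage-6 input set is
invariant to their application order; stage 6 is family-relative and comes
last.  Tiers A (all-aneurysm segregation) and B (absent in unaffecteds) are
recorded as annotations on the surviving candidates, never as filters, and
visual inspection is a manual-review status field that the pipeline never
auto-fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from famvar.annotation import (
    consensus_consequence,
    consensus_frequency,
    internal_db_pass,
    pathogenicity_pass,
)
from famvar.cohort import (
    AnnotationBundle,
    Pedigree,
    PhenotypeClass,
    VariantRecord,
    normalize_variant,
)
from famvar.segregation import (
    MissingPolicy,
    SegregationResult,
    count_unaffected_carriers,
    evaluate_family_segregation,
)

STAGE_ROWS = [
    "all_variants",
    "1_autosomal",
    "2_consequence",
    "3_rare",
    "4_internal_db",
    "5_damaging",
    "6_segregating",
    "inspection",
    "A_all_aneurysm",
    "B_not_in_unaffected",
]


@dataclass
class CascadeConfig:
    freq_threshold: float = 0.01
    cadd_threshold: float = 10.0
    splice_window_bp: int = 2
    indel_match_bp: int = 10
    missing_policy: MissingPolicy = "strict"
    unaffected_screen_age: int = 45

    def __post_init__(self) -> None:
        for name in ("freq_threshold", "cadd_threshold", "splice_window_bp",
                     "indel_match_bp", "unaffected_screen_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"CascadeConfig.{name} must be positive")


@dataclass
class CandidateRecord:
    variant: VariantRecord
    bundle: AnnotationBundle
    segregation: dict[str, SegregationResult]
    families_segregating: set[str]
    cross_family_definite: bool
    unaffected_carrier_count: int
    inspection_status: str = "unreviewed"  # {unreviewed, pass, fail}
    # linkage fields, filled by the linkage module
    max_window_lod: Optional[float] = None
    family_max_lod: Optional[float] = None
    within_max: bool = False
    go_terms: frozenset = frozenset()
    # expression fields, filled by the expression module
    logfc: Optional[float] = None
    fdr: Optional[float] = None
    expression_available: bool = False
    differentially_expressed: bool = False

    def __post_init__(self) -> None:
        if not self.families_segregating:
            raise ValueError(
                f"candidate {self.variant.key} has no segregating family"
            )

    @property
    def key(self):
        return self.variant.key

    @property
    def gene(self) -> Optional[str]:
        return self.bundle.gene

    @property
    def seg_all_aneurysm_any(self) -> bool:
        return any(
            self.segregation[f].segregates_all_aneurysm
            for f in self.families_segregating
        )

    @property
    def absent_in_unaffected_all(self) -> bool:
        return all(
            self.segregation[f].absent_in_unaffected
            for f in self.families_segregating
        )


def _definite_carrier_families(
    variant: VariantRecord, pedigrees: Mapping[str, Pedigree]
) -> set[str]:
    """Families in which >= 1 sequenced definite case carries the variant."""
    out = set()
    for fid, ped in pedigrees.items():
        for ind in ped:
            if (
                ind.sequenced
                and ind.phenotype_class is PhenotypeClass.DEFINITE_IA
                and variant.is_carrier(ind.individual_id) is True
            ):
                out.add(fid)
                break
    return out


def stage_pass(
    variant: VariantRecord, bundle: AnnotationBundle, stage: int, config: CascadeConfig
) -> bool:
    """Pure predicate for filter stages 1–5."""
    if stage == 1:
        return variant.is_autosomal
    if stage == 2:
        return consensus_consequence(bundle, config.splice_window_bp)
    if stage == 3:
        return consensus_frequency(bundle) < config.freq_threshold
    if stage == 4:
        return internal_db_pass(bundle)
    if stage == 5:
        return pathogenicity_pass(variant, bundle, config.cadd_threshold)
    raise ValueError(f"no pure predicate for stage {stage}")


def apply_cascade(
    variants: Sequence[VariantRecord],
    bundles: Mapping[tuple, AnnotationBundle],
    pedigrees: Mapping[str, Pedigree],
    config: CascadeConfig | None = None,
) -> tuple[list[CandidateRecord], pd.DataFrame]:
    """Run filters 1–6 and build the per-family attrition table.

    The per-family column at each stage counts the surviving variants carried
    by at least one sequenced definite case of that family; the stage-6 cell
    counts variants fully segregating in that family.  The "All" column is
    the size of the surviving set (stage 6: union over families).
    """
    config = config or CascadeConfig()
    families = sorted(pedigrees)
    counts = pd.DataFrame(0, index=STAGE_ROWS, columns=families + ["All"], dtype=int)

    carrier_fams = {v.key: _definite_carrier_families(v, pedigrees) for v in variants}

    surviving = [v for v in variants if carrier_fams[v.key]]
    _tally(counts, "all_variants", surviving, carrier_fams, families)

    stage_names = dict(
        zip(range(1, 6), STAGE_ROWS[1:6])
    )
    for stage in range(1, 6):
        surviving = [
            v for v in surviving if stage_pass(v, bundles[v.key], stage, config)
        ]
        _tally(counts, stage_names[stage], surviving, carrier_fams, families)

    candidates: list[CandidateRecord] = []
    pedigree_list = list(pedigrees.values())
    seg_fams_by_tier: dict[str, dict[tuple, set[str]]] = {
        "6_segregating": {},
        "A_all_aneurysm": {},
        "B_not_in_unaffected": {},
    }
    for v in surviving:
        seg = {
            fid: evaluate_family_segregation(v, ped, config.missing_policy)
            for fid, ped in pedigrees.items()
            if any(
                i.sequenced and i.phenotype_class is PhenotypeClass.DEFINITE_IA
                for i in ped
            )
        }
        seg_fams = {f for f, r in seg.items() if r.segregates_definite}
        seg_fams_by_tier["6_segregating"][v.key] = seg_fams
        seg_fams_by_tier["A_all_aneurysm"][v.key] = {
            f for f in seg_fams if seg[f].segregates_all_aneurysm
        }
        seg_fams_by_tier["B_not_in_unaffected"][v.key] = {
            f for f in seg_fams if seg[f].absent_in_unaffected
        }
        if not seg_fams:
            continue
        candidates.append(
            CandidateRecord(
                variant=v,
                bundle=bundles[v.key],
                segregation=seg,
                families_segregating=seg_fams,
                cross_family_definite=len(carrier_fams[v.key]) >= 2,
                unaffected_carrier_count=count_unaffected_carriers(v, pedigree_list),
            )
        )

    for row in ("6_segregating", "A_all_aneurysm", "B_not_in_unaffected"):
        fam_sets = seg_fams_by_tier[row]
        for fam in families:
            counts.loc[row, fam] = sum(1 for s in fam_sets.values() if fam in s)
        counts.loc[row, "All"] = sum(1 for s in fam_sets.values() if s)
    # inspection statuses start unreviewed, which does not remove candidates
    counts.loc["inspection"] = counts.loc["6_segregating"]
    return candidates, counts


def _tally(counts, row, surviving, carrier_fams, families) -> None:
    for fam in families:
        counts.loc[row, fam] = sum(1 for v in surviving if fam in carrier_fams[v.key])
    counts.loc[row, "All"] = len(surviving)


def attrition_counts(trace: pd.DataFrame) -> pd.DataFrame:
    """The per-stage, per-family attrition matrix (already in Table shape)."""
    return trace.copy()


def apply_inspection(
    candidates: Iterable[CandidateRecord], review_path: Path | str
) -> None:
    """Attach manual review statuses from a (chrom, pos, ref, alt, status) TSV.

    Review is advisory: statuses are recorded, candidates are never removed.
    """
    statuses: dict[tuple, str] = {}
    with open(review_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, pos, ref, alt, status = line.split("\t")[:5]
            if status not in ("pass", "fail"):
                raise ValueError(f"bad inspection status {status!r}")
            pos_i, ref, alt = normalize_variant(int(pos), ref, alt)
            statuses[(chrom.removeprefix("chr"), pos_i, ref, alt)] = status
    for cand in candidates:
        if cand.key in statuses:
            cand.inspection_status = statuses[cand.key]


def reconcile_indels(
    candidates: Sequence[CandidateRecord],
    comparison_set: Sequence[VariantRecord],
    config: CascadeConfig | None = None,
) -> dict[tuple, str]:
    """Compare candidate indels against an independently called dataset.

    Returns per candidate key one of ``confirmed_match`` (normalized
    chrom/pos/ref/alt agree exactly), ``nearby_mismatch_review`` (nearest
    comparison indel within ``indel_match_bp``, flagged for manual review),
    or ``absent``.  SNVs pass through untouched (not in the mapping).
    """
    config = config or CascadeConfig()
    exact = {v.key for v in comparison_set}
    by_chrom: dict[str, list[int]] = {}
    for v in comparison_set:
        if not v.is_snv:
            by_chrom.setdefault(v.chrom, []).append(v.pos)
    out: dict[tuple, str] = {}
    for cand in candidates:
        v = cand.variant
        if v.is_snv:
            continue
        if v.key in exact:
            out[v.key] = "confirmed_match"
        elif any(
            abs(p - v.pos) <= config.indel_match_bp
            for p in by_chrom.get(v.chrom, ())
        ):
            out[v.key] = "nearby_mismatch_review"
        else:
            out[v.key] = "absent"
    return out


def candidates_to_frame(candidates: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Flatten candidates into the report table (one row per segregating
    family, matching the published candidate-table layout)."""
    rows = []
    for c in candidates:
        for fam in sorted(c.families_segregating):
            seg = c.segregation[fam]
            rows.append(
                {
                    "chrom": c.variant.chrom,
                    "pos": c.variant.pos,
                    "ref": c.variant.ref,
                    "alt": c.variant.alt,
                    "gene": c.gene,
                    "alt_freq": consensus_frequency(c.bundle),
                    "polyphen": c.bundle.polyphen,
                    "sift": c.bundle.sift,
                    "sift_indel": c.bundle.sift_indel,
                    "ddig_in": c.bundle.ddig_in,
                    "cadd_c": c.bundle.cadd_c,
                    "lod": c.max_window_lod,
                    "family": fam,
                    "unaff": c.unaffected_carrier_count,
                    "seg_all_aneurysm": seg.segregates_all_aneurysm,
                    "cross_family": c.cross_family_definite,
                    "within_max_lod": c.within_max,
                    "inspection": c.inspection_status,
                    "go_terms": ",".join(sorted(c.go_terms)) or "NA",
                    "logfc": c.logfc,
                    "fdr": c.fdr,
                }
            )
    return pd.DataFrame(rows)
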