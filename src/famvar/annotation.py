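"""Harmonized annotation predicates for the biological filter cascade.

Each predicate is a pure function of a single variant and its annotation
bundle; repeated calls are identical and no predicate depends on other
variants.  Absent evidence never counts as damaging — a variant must show
positive evidence to pass.

Thresholds follow the conventions of the underlying study design: rare means
strictly below 1% consensus alternate-allele frequency, damaging by CADD
means a scaled C-score of 10 or greater (inclusive), and splicing means
within 2 bp of a splice junction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from famvar.cohort import AnnotationBundle, VariantRecord

#: GO terms hypothesized to be relevant to vascular wall integrity; used for
#: annotation only, never as a filter.
VASCULAR_GO_TERMS = frozenset(
    {
        "GO:0001944",  # vasculature development
        "GO:0001570",  # vasculogenesis
        "GO:0003018",  # vascular process in circulatory system
        "GO:0005581",  # collagen
        "GO:0005604",  # basement membrane
        "GO:0051541",  # elastin metabolic process
    }
)

SPLICE_WINDOW_BP = 2
CADD_DAMAGING_THRESHOLD = 10.0


@dataclass(frozen=True)
class PredicateResult:
    variant_key: tuple
    predicate: str
    passed: bool
    detail: str = ""


def consensus_consequence(
    bundle: AnnotationBundle, splice_window_bp: int = SPLICE_WINDOW_BP
) -> bool:
    """True iff all three gene models call the variant functional.

    Functional means nonsynonymous exonic, or splicing within
    ``splice_window_bp`` of a junction.  The intersection (not union) of the
    RefSeq, UCSC and Ensembl calls is required; a database with no call
    counts as non-qualifying.
    """
    for db in AnnotationBundle.DBS:
        call = bundle.consequence_by_db.get(db)
        if call == "nonsynonymous_exonic":
            continue
        if call == "splicing":
            if (
                bundle.splice_distance_bp is not None
                and bundle.splice_distance_bp <= splice_window_bp
            ):
                continue
            return False
        return False
    return True


def consensus_frequency(bundle: AnnotationBundle) -> float:
    """Consensus alternate-allele frequency across the two population databases.

    The smaller of the two frequencies when both are present; the single
    present value when only one is; 0 when the variant is in neither.
    """
    present = [f for f in (bundle.freq_1kg_ea, bundle.freq_esp_ea) if f is not None]
    return min(present) if present else 0.0


def internal_db_pass(bundle: AnnotationBundle) -> bool:
    """True iff the internal sequencing database does not flag the variant.

    Fails on an internal binned minor allele frequency of 1% or more, and on
    the monomorphic flag (identical non-reference genotype in every internal
    sample — a pipeline-artifact signature).
    """
    if bundle.internal_freq_bin == "ge_1pct":
        return False
    return not bundle.internal_monomorphic


def pathogenicity_pass(
    variant: VariantRecord,
    bundle: AnnotationBundle,
    cadd_threshold: float = CADD_DAMAGING_THRESHOLD,
) -> bool:
    """CADD-damaging plus at least one concordant protein-level prediction.

    SNVs need SIFT damaging or PolyPhen-2 possibly/probably damaging;
    frameshift indels need SIFT-INDEL damaging; non-frameshift indels need
    DDIG-in damaging.  Absent predictors never count as damaging.
    """
    if bundle.cadd_c is None or bundle.cadd_c < cadd_threshold:
        return False
    if variant.is_snv:
        return bundle.sift == "damaging" or bundle.polyphen in ("possibly", "probably")
    if variant.is_frameshift:
        return bundle.sift_indel == "damaging"
    return bundle.ddig_in == "damaging"


def go_tag(
    gene: Optional[str],
    go_map: Mapping[str, frozenset[str] | set[str]],
    vascular_terms: frozenset[str] = VASCULAR_GO_TERMS,
) -> frozenset[str]:
    """Vascular GO terms attached to a gene; annotation only, never a filter."""
    if gene is None:
        return frozenset()
    return frozenset(go_map.get(gene, frozenset())) & vascular_terms


def load_go_map(path) -> dict[str, frozenset[str]]:
    """Two-column TSV (gene, GO id); repeated genes accumulate terms."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return {g: frozenset(t) for g, t in out.items()}
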