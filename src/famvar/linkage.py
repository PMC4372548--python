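"""Parametric single-point pedigree LOD engine and linkage-support annotation.

The engine computes the two-point pedigree likelihood of marker data under an
autosomal dominant disease model.  Each individual's latent state is an
ordered pair of two-locus haplotypes (disease allele x marker allele); the
likelihood sums founder genotype priors, Mendelian transmission with
recombination fraction theta between the disease and marker locus, penetrance
terms, and marker observations.  Summation is by pedigree peeling — variable
elimination over the pedigree's factor graph — so the cost is linear in
family size for the tree-structured pedigrees this package targets, rather
than exponential as in naive enumeration.

LOD(theta) = log10 L(theta) - log10 L(theta = 1/2).

Affecteds-only coding follows the study convention: only definite cases and
obligate carriers contribute phenotype information; everyone else is coded
phenotype-unknown.  Obligate carriers are coded as disease-allele carriers
(affected under the (0, 1, 1) penetrance vector).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from famvar.cohort import FOUNDER, LodTrack, Pedigree, PhenotypeClass

LOD_TOLERANCE = 0.01
WINDOW_HALFWIDTH_BP = 5_000_000


@dataclass
class LinkageModel:
    """Autosomal dominant two-point linkage model.

    ``penetrances`` is (f0, f1, f2): probability of being affected given
    0/1/2 disease alleles.  The default (0, 1, 1) with affecteds-only coding
    makes "affected" equivalent to "carrier".
    """

    disease_allele_freq: float = 0.01
    penetrances: tuple[float, float, float] = (0.0, 1.0, 1.0)
    theta: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must be in (0, 1)")
        if not all(0.0 <= f <= 1.0 for f in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")
        if self.penetrances[1] < self.penetrances[0]:
            raise ValueError("dominant model requires f1 >= f0")
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must lie in [0, 0.5]")


@dataclass
class LinkageAnnotation:
    max_window_lod: Optional[float]
    family_max_lod: float
    within_max: bool
    window_halfwidth_bp: int = WINDOW_HALFWIDTH_BP
    tolerance: float = LOD_TOLERANCE


class MendelianInconsistencyError(ValueError):
    """Marker data impossible under Mendelian transmission at any theta."""


# ---------------------------------------------------------------------------
# Factor-graph peeling
# ---------------------------------------------------------------------------


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, variables: tuple[str, ...], table: np.ndarray):
        self.vars = variables
        self.table = table


def _eliminate(factors: list[_Factor], var: str) -> tuple[list[_Factor], float]:
    """Sum `var` out of the product of the factors that mention it.

    Contraction is delegated to einsum so large intermediates are never
    materialized.  Returns the remaining factor list and a log-scale
    correction from normalizing the new factor.
    """
    involved = [f for f in factors if var in f.vars]
    rest = [f for f in factors if var not in f.vars]
    order: dict[str, str] = {}

    def letter(v: str) -> str:
        if v not in order:
            order[v] = chr(ord("a") + len(order))
        return order[v]

    inputs = []
    for f in involved:
        inputs.append("".join(letter(v) for v in f.vars))
    out_vars = tuple(v for v in order if v != var)
    spec = ",".join(inputs) + "->" + "".join(order[v] for v in out_vars)
    table = np.einsum(spec, *[f.table for f in involved], optimize=True)
    scale = float(table.max()) if table.size else 0.0
    if scale <= 0.0:
        # zero-probability configuration; keep an exact zero factor
        return rest + [_Factor(out_vars, table)], 0.0
    rest.append(_Factor(out_vars, table / scale))
    return rest, math.log(scale)


def _log_likelihood(
    pedigree: Pedigree,
    marker_genotypes: Mapping[str, Optional[tuple[int, int]]],
    phenotype_code: Mapping[str, Optional[bool]],
    model: LinkageModel,
    theta: float,
    n_marker_alleles: int,
    marker_allele_freqs: Optional[Sequence[float]] = None,
    known_phase: Optional[tuple[str, int]] = None,
) -> float:
    """Natural-log pedigree likelihood; -inf when the data are impossible."""
    k = n_marker_alleles
    nh = 2 * k  # haplotype index: d * k + m
    ng = nh * nh  # ordered genotype (paternal hap, maternal hap)
    q = model.disease_allele_freq
    pd_ = np.array([1.0 - q, q])
    pm = (
        np.full(k, 1.0 / k)
        if marker_allele_freqs is None
        else np.asarray(marker_allele_freqs, dtype=float)
    )

    hap_d = np.repeat(np.arange(2), k)  # disease allele of each haplotype
    hap_m = np.tile(np.arange(k), 2)  # marker allele of each haplotype
    hap_prior = pd_[hap_d] * pm[hap_m]

    g_pat, g_mat = np.divmod(np.arange(ng), nh)

    # transmission: P(gamete hap | parent ordered genotype)
    trans = np.zeros((ng, nh))
    for g in range(ng):
        h1, h2 = g_pat[g], g_mat[g]
        for strand, other in ((h1, h2), (h2, h1)):
            non_rec = strand
            rec = hap_d[strand] * k + hap_m[other]
            trans[g, non_rec] += 0.5 * (1.0 - theta)
            trans[g, rec] += 0.5 * theta

    n_disease = hap_d[g_pat] + hap_d[g_mat]
    pen = np.asarray(model.penetrances)[n_disease]

    factors: list[_Factor] = []
    for iid in pedigree.members:
        ind = pedigree.members[iid]
        evidence = np.ones(ng)
        code = phenotype_code.get(iid)
        if code is True:
            evidence *= pen
        elif code is False:
            evidence *= 1.0 - pen
        obs = marker_genotypes.get(iid)
        if obs is not None:
            a, b = obs
            match = (
                ((hap_m[g_pat] == a) & (hap_m[g_mat] == b))
                | ((hap_m[g_pat] == b) & (hap_m[g_mat] == a))
            )
            evidence *= match
        if known_phase is not None and iid == known_phase[0]:
            # the individual is a known heterozygote whose disease allele
            # rides on the given marker allele (hypothetical-marker
            # construction); phase is not marginalized
            a0 = known_phase[1]
            pat_hit = (hap_d[g_pat] == 1) & (hap_m[g_pat] == a0) & (hap_d[g_mat] == 0)
            mat_hit = (hap_d[g_mat] == 1) & (hap_m[g_mat] == a0) & (hap_d[g_pat] == 0)
            evidence *= pat_hit | mat_hit
        if ind.is_founder:
            evidence = evidence * (hap_prior[g_pat] * hap_prior[g_mat])
            factors.append(_Factor((iid,), evidence))
        else:
            factors.append(_Factor((iid,), evidence))
            # child genotype factorizes over gametes: one factor per parent
            factors.append(_Factor((ind.father_id, iid), trans[:, g_pat]))
            factors.append(_Factor((ind.mother_id, iid), trans[:, g_mat]))

    # peel children before parents: reverse topological order keeps factor
    # scopes small on tree pedigrees
    log_scale = 0.0
    for iid in reversed(pedigree.topological_order()):
        factors, corr = _eliminate(factors, iid)
        log_scale += corr
    total = 1.0
    for f in factors:
        total *= float(f.table) if f.table.ndim == 0 else float(f.table.sum())
    if total <= 0.0:
        return -math.inf
    return math.log(total) + log_scale


def _affecteds_only_codes(
    pedigree: Pedigree, include_all_phenotypes: bool = False
) -> dict[str, Optional[bool]]:
    codes: dict[str, Optional[bool]] = {}
    for iid, ind in pedigree.members.items():
        if ind.phenotype_class is PhenotypeClass.DEFINITE_IA or ind.obligate_carrier:
            codes[iid] = True
        elif include_all_phenotypes and (
            ind.phenotype_class is PhenotypeClass.UNAFFECTED_SCREENED
        ):
            codes[iid] = False
        else:
            codes[iid] = None
    return codes


def pedigree_lod(
    pedigree: Pedigree,
    marker_genotypes: Mapping[str, tuple[int, int]],
    model: LinkageModel,
    theta: Optional[float] = None,
    n_marker_alleles: Optional[int] = None,
    marker_allele_freqs: Optional[Sequence[float]] = None,
    known_phase: Optional[tuple[str, int]] = None,
) -> float:
    """Two-point LOD score for one marker in one family.

    ``marker_genotypes`` maps individual id to an unordered allele pair
    (integers starting at 0); absent individuals are treated as untyped.
    Founder disease-marker phase is marginalized as usual; ``known_phase``
    (individual id, marker allele) instead conditions on that individual
    being a heterozygote whose disease allele rides on the given marker
    allele, which is how the hypothetical fully informative marker is
    defined.  Returns -inf when the marker data are Mendelian-inconsistent
    at the requested theta but consistent under free recombination; raises
    :class:`MendelianInconsistencyError` when impossible at any theta.
    """
    th = model.theta if theta is None else theta
    if not 0.0 <= th <= 0.5:
        raise ValueError("theta must lie in [0, 0.5]")
    if n_marker_alleles is None:
        observed = [a for g in marker_genotypes.values() if g for a in g]
        n_marker_alleles = (max(observed) + 1) if observed else 2
    codes = _affecteds_only_codes(pedigree)
    ll_half = _log_likelihood(
        pedigree, marker_genotypes, codes, model, 0.5,
        n_marker_alleles, marker_allele_freqs, known_phase,
    )
    if math.isinf(ll_half):
        raise MendelianInconsistencyError(
            f"family {pedigree.family_id}: marker genotypes are "
            f"Mendelian-inconsistent (zero likelihood at theta = 0.5)"
        )
    if th == 0.5:
        return 0.0
    ll = _log_likelihood(
        pedigree, marker_genotypes, codes, model, th,
        n_marker_alleles, marker_allele_freqs, known_phase,
    )
    if math.isinf(ll):
        return -math.inf
    return (ll - ll_half) / math.log(10.0)


# ---------------------------------------------------------------------------
# Maximum possible LOD (hypothetical fully informative marker)
# ---------------------------------------------------------------------------


def _included_members(pedigree: Pedigree) -> list[str]:
    return [
        iid
        for iid, ind in pedigree.members.items()
        if ind.phenotype_class is PhenotypeClass.DEFINITE_IA or ind.obligate_carrier
    ]


@dataclass(frozen=True)
class InformativeMarker:
    """A constructed fully informative marker with its disease linkage."""

    genotypes: dict[str, tuple[int, int]]
    n_alleles: int
    origin: Optional[str]  # founder who introduces the disease allele
    disease_allele: Optional[int]  # marker allele on the disease haplotype

    @property
    def known_phase(self) -> Optional[tuple[str, int]]:
        if self.origin is None or self.disease_allele is None:
            return None
        return (self.origin, self.disease_allele)


def fully_informative_marker(pedigree: Pedigree) -> InformativeMarker:
    """Construct a marker that co-segregates exactly with the disease allele.

    Founders receive unique allele pairs (so every meiosis is observable);
    the disease haplotype is gene-dropped deterministically from a single
    ancestral founder to every definite case and obligate carrier.  Observed
    genotypes cover the included (definite/obligate) members only.
    """
    included = _included_members(pedigree)
    founders = sorted(i.individual_id for i in pedigree.founders())
    alleles = {fid: (2 * i, 2 * i + 1) for i, fid in enumerate(founders)}
    n_alleles = 2 * len(founders)
    if not included:
        return InformativeMarker({}, max(n_alleles, 2), None, None)

    def covers(fid: str) -> int:
        desc = pedigree.descendants_of(fid) | {fid}
        return sum(1 for iid in included if iid in desc)

    # the disease founder: deterministically the first founder ancestral to
    # (or identical with) the largest number of included members
    origin = sorted(founders, key=lambda fid: (-covers(fid), fid))[0]
    origin_desc = pedigree.descendants_of(origin) | {origin}

    # carriers: included members reachable from the origin plus the connecting
    # path; the disease-linked marker allele is the origin's first allele
    carrier_path: set[str] = set()
    for iid in included:
        if iid not in origin_desc:
            continue
        node = iid
        while node != origin:
            carrier_path.add(node)
            ind = pedigree.members[node]
            parents_in = [
                p
                for p in (ind.father_id, ind.mother_id)
                if p != FOUNDER and p in origin_desc | {origin}
            ]
            node = sorted(parents_in)[0]
        carrier_path.add(origin)

    disease_allele = alleles[origin][0]
    genotype: dict[str, tuple[int, int]] = {}
    linked: dict[str, int] = {}  # carrier -> marker allele on disease haplotype
    for iid in pedigree.topological_order():
        ind = pedigree.members[iid]
        if ind.is_founder:
            genotype[iid] = alleles[iid]
            if iid == origin:
                linked[iid] = disease_allele
            continue
        inherited = []
        for pid in (ind.father_id, ind.mother_id):
            pg = genotype[pid]
            if iid in carrier_path and pid in carrier_path and pid in linked:
                inherited.append(linked[pid])
            else:
                # deterministically transmit the parent's non-disease allele
                non_disease = [a for a in pg if a != linked.get(pid, -1)]
                inherited.append(non_disease[0])
        genotype[iid] = (inherited[0], inherited[1])
        if iid in carrier_path:
            linked[iid] = disease_allele
    observed = {iid: genotype[iid] for iid in included}
    return InformativeMarker(
        observed, max(n_alleles, 2), origin, disease_allele
    )


def max_possible_lod(pedigree: Pedigree, model: LinkageModel) -> float:
    """LOD at theta = 0 for the constructed fully informative marker.

    Deterministic (no Monte Carlo): the marker's alleles co-segregate
    exactly with the modeled disease allele, and the disease-linked
    haplotype of the introducing founder is known by construction, which
    maximizes the attainable two-point LOD for the pedigree under the model
    (for a parent with two affected children each informative meiosis then
    contributes log10 2).
    """
    marker = fully_informative_marker(pedigree)
    if not marker.genotypes:
        return 0.0
    return pedigree_lod(
        pedigree,
        marker.genotypes,
        model,
        theta=0.0,
        n_marker_alleles=marker.n_alleles,
        known_phase=marker.known_phase,
    )


# ---------------------------------------------------------------------------
# Candidate annotation
# ---------------------------------------------------------------------------


def max_lod_in_window(
    chrom: str, pos: int, track: LodTrack, halfwidth_bp: int = WINDOW_HALFWIDTH_BP
) -> Optional[float]:
    """Highest LOD among track markers within the window centered on pos."""
    return track.max_in_window(chrom, pos, halfwidth_bp)


def flag_linkage_support(
    candidates,
    family_max: Mapping[str, float],
    tolerance: float = LOD_TOLERANCE,
) -> None:
    """Set within_max on candidates whose window LOD reaches the family's
    maximum possible LOD to within ``tolerance`` (inclusive boundary, with a
    1e-9 guard against floating-point false negatives).

    Candidates segregating in several families are flagged if any of those
    families supports them.  Mutates the candidates in place.
    """
    for cand in candidates:
        fams = sorted(cand.families_segregating)
        for fam in fams:
            if fam not in family_max:
                raise KeyError(f"no family maximum LOD supplied for family {fam!r}")
        best_fam = max(fams, key=lambda f: family_max[f])
        cand.family_max_lod = family_max[best_fam]
        if cand.max_window_lod is None:
            cand.within_max = False
            continue
        cand.within_max = any(
            family_max[f] - cand.max_window_lod <= tolerance + 1e-9 for f in fams
        )


def annotate_window_lod(candidates, track: LodTrack,
                        halfwidth_bp: int = WINDOW_HALFWIDTH_BP) -> None:
    for cand in candidates:
        cand.max_window_lod = max_lod_in_window(
            cand.variant.chrom, cand.variant.pos, track, halfwidth_bp
        )


def region_overlap(
    candidates, regions: Sequence[tuple[str, int, int, str]]
) -> dict[str, list]:
    """Per-region candidate lists; intervals are 1-based, inclusive at both
    ends.  ``regions`` entries are (chrom, start, end, name)."""
    out: dict[str, list] = {}
    for chrom, start, end, name in regions:
        if start > end:
            raise ValueError(f"region {name}: start {start} > end {end}")
        chrom = str(chrom).removeprefix("chr")
        out[name] = [
            c
            for c in candidates
            if c.variant.chrom == chrom and start <= c.variant.pos <= end
        ]
    return out


def load_regions(path) -> list[tuple[str, int, int, str]]:
    """BED-like TSV of (chrom, start, end, name), documented as 1-based
    inclusive (unlike standard BED)."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("chrom\t"):
                continue
            chrom, start, end, name = line.split("\t")[:4]
            regions.append((chrom, int(start), int(end), name))
    return regions


def bed_to_inclusive(chrom: str, start0: int, end0: int) -> tuple[str, int, int]:
    """Convert a standard half-open 0-based BED interval to the 1-based
    inclusive convention used throughout this package."""
    return chrom, start0 + 1, end0
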