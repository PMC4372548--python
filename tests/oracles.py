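"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written without reusing the package's
algorithmic machinery: the pedigree likelihood enumerates the full joint
genotype space by tensor broadcasting instead of peeling, the segregation
predicate walks the genotype table directly, the cascade oracle intersects
per-variant predicates re-stated from scratch, and the BH oracle follows the
step-up definition literally.
"""

from __future__ import annotations

import math

import numpy as np

from famvar.cohort import FOUNDER, Pedigree, PhenotypeClass


# ---------------------------------------------------------------------------
# Full-joint two-locus pedigree likelihood (feasible up to ~6 members, k=2)
# ---------------------------------------------------------------------------


def oracle_pedigree_lod(
    pedigree: Pedigree,
    marker_genotypes: dict[str, tuple[int, int]],
    disease_allele_freq: float,
    penetrances: tuple[float, float, float],
    theta: float,
    n_marker_alleles: int,
    known_phase: tuple[str, int] | None = None,
) -> float:
    """LOD via exhaustive summation over the joint genotype space."""
    ll = _oracle_loglike(
        pedigree, marker_genotypes, disease_allele_freq, penetrances,
        theta, n_marker_alleles, known_phase,
    )
    ll_half = _oracle_loglike(
        pedigree, marker_genotypes, disease_allele_freq, penetrances,
        0.5, n_marker_alleles, known_phase,
    )
    if ll == -math.inf:
        return -math.inf
    return (ll - ll_half) / math.log(10.0)


def _oracle_loglike(
    pedigree, marker_genotypes, q, penetrances, theta, k, known_phase
) -> float:
    haps = [(d, m) for d in (0, 1) for m in range(k)]
    states = [(h1, h2) for h1 in haps for h2 in haps]
    ns = len(states)

    def hap_prior(h):
        return (q if h[0] == 1 else 1.0 - q) / k

    def gamete_prob(parent_state, gamete, th):
        h1, h2 = parent_state
        p = 0.0
        for strand, other in ((h1, h2), (h2, h1)):
            if gamete == strand:
                p += 0.5 * (1.0 - th)
            if gamete == (strand[0], other[1]):
                p += 0.5 * th
        return p

    ids = list(pedigree.members)
    index = {iid: i for i, iid in enumerate(ids)}
    n = len(ids)
    shape = [1] * n

    def axis_shape(i):
        s = shape.copy()
        s[i] = ns
        return tuple(s)

    joint = np.ones((ns,) * n)
    for iid in ids:
        ind = pedigree.members[iid]
        vec = np.ones(ns)
        # phenotype (affecteds-only coding: definite or obligate = affected)
        affected = (
            ind.phenotype_class is PhenotypeClass.DEFINITE_IA
            or ind.obligate_carrier
        )
        for s, (h1, h2) in enumerate(states):
            nd = h1[0] + h2[0]
            if affected:
                vec[s] *= penetrances[nd]
            obs = marker_genotypes.get(iid)
            if obs is not None:
                if tuple(sorted((h1[1], h2[1]))) != tuple(sorted(obs)):
                    vec[s] = 0.0
            if known_phase is not None and iid == known_phase[0]:
                a0 = known_phase[1]
                good = (h1 == (1, a0) and h2[0] == 0) or (
                    h2 == (1, a0) and h1[0] == 0
                )
                if not good:
                    vec[s] = 0.0
            if ind.is_founder:
                vec[s] *= hap_prior(h1) * hap_prior(h2)
        joint *= vec.reshape(axis_shape(index[iid]))
        if not ind.is_founder:
            for parent, which in ((ind.father_id, 0), (ind.mother_id, 1)):
                mat = np.zeros((ns, ns))
                for ps in range(ns):
                    for cs, (c1, c2) in enumerate(states):
                        gamete = (c1, c2)[which]
                        mat[ps, cs] = gamete_prob(states[ps], gamete, theta)
                s = shape.copy()
                s[index[parent]] = ns
                s[index[iid]] = ns
                joint *= mat.reshape(tuple(s))
    total = float(joint.sum())
    return math.log(total) if total > 0 else -math.inf


# ---------------------------------------------------------------------------
# Segregation brute force
# ---------------------------------------------------------------------------


def oracle_segregates(variant, pedigree, tier: str) -> bool:
    """Direct genotype-table statement of the segregation tiers."""
    rows = [
        (
            ind.phenotype_class.value,
            ind.obligate_carrier,
            ind.sequenced,
            variant.genotypes.get(ind.individual_id),
        )
        for ind in pedigree
    ]
    if tier == "definite":
        needed = [
            g for ph, ob, seq, g in rows if seq and (ph == "DEFINITE_IA" or ob)
        ]
        return all(g is not None and g >= 1 for g in needed)
    if tier == "all_aneurysm":
        needed = [
            g
            for ph, ob, seq, g in rows
            if seq
            and (ph in ("DEFINITE_IA", "PROBABLE_IA", "POSSIBLE_IA", "AAA") or ob)
        ]
        return all(g is not None and g >= 1 for g in needed)
    if tier == "absent_in_unaffected":
        carriers = [
            g
            for ph, ob, seq, g in rows
            if seq and ph == "UNAFFECTED_SCREENED" and not ob
        ]
        return not any(g is not None and g >= 1 for g in carriers)
    raise ValueError(tier)


# ---------------------------------------------------------------------------
# Cascade predicate intersection, restated from scratch
# ---------------------------------------------------------------------------


def oracle_cascade_survivors(variants, bundles, pedigrees, freq_threshold=0.01,
                             cadd_threshold=10.0):
    """Keys of variants passing all six filters, via independent predicates."""
    out = []
    for v in variants:
        b = bundles[v.key]
        chrom_ok = v.chrom.isdigit() and 1 <= int(v.chrom) <= 22
        calls = [b.consequence_by_db.get(db) for db in ("RefSeq", "UCSC", "Ensembl")]
        conseq_ok = all(
            c == "nonsynonymous_exonic"
            or (
                c == "splicing"
                and b.splice_distance_bp is not None
                and b.splice_distance_bp <= 2
            )
            for c in calls
        )
        freqs = [f for f in (b.freq_1kg_ea, b.freq_esp_ea) if f is not None]
        freq_ok = (min(freqs) if freqs else 0.0) < freq_threshold
        internal_ok = b.internal_freq_bin != "ge_1pct" and not b.internal_monomorphic
        snv = len(v.ref) == 1 and len(v.alt) == 1
        fs = abs(len(v.ref) - len(v.alt)) % 3 != 0
        if snv:
            second = b.sift == "damaging" or b.polyphen in ("possibly", "probably")
        elif fs:
            second = b.sift_indel == "damaging"
        else:
            second = b.ddig_in == "damaging"
        damaging_ok = b.cadd_c is not None and b.cadd_c >= cadd_threshold and second
        seg_ok = any(
            oracle_segregates(v, ped, "definite") for ped in pedigrees.values()
        )
        if chrom_ok and conseq_ok and freq_ok and internal_ok and damaging_ok and seg_ok:
            out.append(v.key)
    return set(out)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up, literal definition
# ---------------------------------------------------------------------------


def oracle_bh(p):
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(running, 1.0)
    return adj
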