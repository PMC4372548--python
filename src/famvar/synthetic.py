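"""Synthetic cohorts with known truth labels for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
multiplex autosomal-dominant families in which one founder introduces a rare
causal allele that is gene-dropped through the pedigree, phenotypes assigned
by penetrance with an optional phenocopy rate (affected non-carriers — the
documented failure mode of strict segregation filtering), screened-unaffected
labels only for adequately aged members, background variants with
independently drawn annotation marginals, LOD tracks scored by the package's
own pedigree-likelihood engine, and negative-binomial count matrices with
planted fold changes.

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from famvar.cohort import (
    FOUNDER,
    AnnotationBundle,
    CountMatrix,
    Individual,
    LodTrack,
    Pedigree,
    PhenotypeClass,
    VariantRecord,
)
from famvar.linkage import LinkageModel, fully_informative_marker, pedigree_lod


@dataclass
class SimConfig:
    seed: int = 0
    # pedigree structure
    n_families: int = 7
    generations: int = 3
    children_per_couple: tuple[int, int] = (2, 3)  # inclusive range
    # dominant causal model
    penetrance: float = 1.0  # P(affected | carrier), f1 = f2
    phenocopy_rate: float = 0.0  # P(affected | non-carrier)
    disease_allele_freq: float = 0.01
    screening_age_threshold: int = 45
    # background variants: marginal pass-rates per cascade predicate, chosen
    # to mirror the attrition proportions typical of exome-wide filtering
    n_background_variants: int = 200
    p_autosomal: float = 0.98
    p_consequence: float = 0.30
    p_rare: float = 0.27
    p_internal: float = 0.82
    p_damaging: float = 0.47
    background_allele_freq: float = 0.25  # in-cohort founder allele frequency
    # count simulation (defaults mirror the expression arm of the study:
    # 44 aneurysm vs 16 control samples)
    n_genes: int = 2000
    n_aneurysm: int = 44
    n_control: int = 16
    dispersion: float = 0.1
    library_size_range: tuple[float, float] = (5e6, 2e7)
    planted_log2fc: tuple[float, ...] = ()
    n_planted: int = 0

    def __post_init__(self) -> None:
        for name in ("penetrance", "phenocopy_rate", "p_autosomal", "p_consequence",
                     "p_rare", "p_internal", "p_damaging", "background_allele_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SimConfig.{name}={v} outside [0, 1]")
        if self.n_families < 1 or self.generations < 1:
            raise ValueError("need at least one family and one generation")
        if self.children_per_couple[0] < 1:
            raise ValueError("couples must have at least one child")


@dataclass
class TruthLabels:
    causal_variant_by_family: dict[str, tuple] = field(default_factory=dict)
    carrier_status: dict[str, dict[str, bool]] = field(default_factory=dict)
    planted_de_genes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _grow_pedigree(fid: str, config: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Founder couple, descendant couples with married-in founder spouses."""
    ped = Pedigree(family_id=fid)
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{fid}_{counter[0]:03d}"

    def add(father: str, mother: str, sex: str) -> Individual:
        ind = Individual(
            individual_id=new_id(),
            family_id=fid,
            father_id=father,
            mother_id=mother,
            sex=sex,
        )
        ped.add(ind)
        return ind

    pat = add(FOUNDER, FOUNDER, "male")
    mat = add(FOUNDER, FOUNDER, "female")
    current = [(pat, mat)]
    for gen in range(1, config.generations):
        nxt = []
        for father, mother in current:
            lo, hi = config.children_per_couple
            n_children = int(rng.integers(lo, hi + 1))
            for _ in range(n_children):
                sex = "male" if rng.random() < 0.5 else "female"
                child = add(father.individual_id, mother.individual_id, sex)
                if gen < config.generations - 1:
                    spouse = add(FOUNDER, FOUNDER,
                                 "female" if sex == "male" else "male")
                    couple = (
                        (child, spouse) if sex == "male" else (spouse, child)
                    )
                    nxt.append(couple)
        current = nxt
    return ped


def _gene_drop(
    ped: Pedigree, founder_carriers: dict[str, int], rng: np.random.Generator
) -> dict[str, int]:
    """Drop allele dosages through the pedigree; founders from the given map."""
    dosage: dict[str, int] = {}
    for iid in ped.topological_order():
        ind = ped.members[iid]
        if ind.is_founder:
            dosage[iid] = founder_carriers.get(iid, 0)
        else:
            transmitted = 0
            for pid in (ind.father_id, ind.mother_id):
                d = dosage[pid]
                p_transmit = 0.0 if d == 0 else (0.5 if d == 1 else 1.0)
                transmitted += int(rng.random() < p_transmit)
            dosage[iid] = transmitted
    return dosage


def _assign_phenotypes(
    ped: Pedigree, carriers: dict[str, int], config: SimConfig,
    rng: np.random.Generator,
) -> None:
    gen_depth = {
        iid: len(ped.ancestors_of(iid)) for iid in ped.members
    }
    max_depth = max(gen_depth.values()) if gen_depth else 0
    for iid, ind in ped.members.items():
        carrier = carriers[iid] >= 1
        p_aff = config.penetrance if carrier else config.phenocopy_rate
        affected = rng.random() < p_aff
        # older generations have had MRA screening; youngest often has not
        age = int(rng.integers(70, 90)) if ind.is_founder else int(
            rng.integers(30, 80 - 12 * min(gen_depth[iid], 4))
        )
        if affected:
            ind.phenotype_class = PhenotypeClass.DEFINITE_IA
            ind.screening_age = None
        elif age >= config.screening_age_threshold and rng.random() < 0.8:
            ind.phenotype_class = PhenotypeClass.UNAFFECTED_SCREENED
            ind.screening_age = age
        else:
            ind.phenotype_class = PhenotypeClass.UNKNOWN
            ind.screening_age = None
    # structural obligate carriers: unaffected members on the transmission
    # path between an affected ancestor and an affected descendant
    for iid, ind in ped.members.items():
        if ind.phenotype_class is PhenotypeClass.DEFINITE_IA:
            continue
        ancestors = ped.ancestors_of(iid)
        descendants = ped.descendants_of(iid)
        aff = {
            j
            for j, o in ped.members.items()
            if o.phenotype_class is PhenotypeClass.DEFINITE_IA
        }
        if aff & ancestors and aff & descendants:
            ind.obligate_carrier = True
    # sequencing selection mirrors the study: affected members, obligate
    # carriers, and screened unaffecteds
    for ind in ped:
        ind.sequenced = (
            ind.phenotype_class is PhenotypeClass.DEFINITE_IA
            or ind.obligate_carrier
            or ind.phenotype_class is PhenotypeClass.UNAFFECTED_SCREENED
        )


def _causal_bundle(gene: str) -> AnnotationBundle:
    """Annotation profile that passes cascade predicates 2-5 by construction,
    so recovery tests isolate the segregation logic."""
    return AnnotationBundle(
        consequence_by_db={db: "nonsynonymous_exonic" for db in AnnotationBundle.DBS},
        freq_1kg_ea=None,
        freq_esp_ea=None,
        internal_freq_bin="absent",
        internal_monomorphic=False,
        cadd_c=25.0,
        sift="damaging",
        polyphen="probably",
        gene=gene,
    )


def _background_bundle(
    gene: str, config: SimConfig, rng: np.random.Generator
) -> tuple[AnnotationBundle, bool]:
    """Independent draws of each predicate's pass state at the configured
    marginal rates; returns the bundle and whether chrom should be autosomal."""
    autosomal = rng.random() < config.p_autosomal
    if rng.random() < config.p_consequence:
        conseq = {db: "nonsynonymous_exonic" for db in AnnotationBundle.DBS}
    else:
        conseq = {
            "RefSeq": "nonsynonymous_exonic",
            "UCSC": "nonsynonymous_exonic",
            "Ensembl": "other",
        }
    if rng.random() < config.p_rare:
        freq = float(rng.uniform(0.0, 0.009))
    else:
        freq = float(rng.uniform(0.011, 0.3))
    internal_ok = rng.random() < config.p_internal
    damaging = rng.random() < config.p_damaging
    bundle = AnnotationBundle(
        consequence_by_db=conseq,
        freq_1kg_ea=freq,
        freq_esp_ea=None,
        internal_freq_bin="absent" if internal_ok else "ge_1pct",
        internal_monomorphic=False,
        cadd_c=float(rng.uniform(10.0, 40.0)) if damaging else float(rng.uniform(0.0, 9.99)),
        sift="damaging" if damaging else "tolerated",
        polyphen=None,
        gene=gene,
    )
    return bundle, autosomal


def simulate_cohort(
    config: SimConfig,
) -> tuple[dict[str, Pedigree], list[VariantRecord], dict, TruthLabels]:
    """Simulate pedigrees, variants and annotation bundles with truth labels.

    Per family one causal founder variant is gene-dropped and guaranteed to
    pass annotation predicates; ``n_background_variants`` cohort-wide
    background variants draw their annotation pass states independently at
    the configured marginal rates.
    """
    rng = np.random.default_rng(config.seed)
    truth = TruthLabels()
    pedigrees: dict[str, Pedigree] = {}
    bundles: dict[tuple, AnnotationBundle] = {}
    variants: list[VariantRecord] = []

    for i in range(config.n_families):
        fid = f"F{i + 1:02d}"
        # redraw until the family has a sequenced definite case (penetrance
        # or phenocopy may otherwise leave a family uninformative)
        for _ in range(200):
            ped = _grow_pedigree(fid, config, rng)
            founders = sorted(f.individual_id for f in ped.founders())
            carriers = _gene_drop(ped, {founders[0]: 1}, rng)
            _assign_phenotypes(ped, carriers, config, rng)
            if any(
                m.sequenced and m.phenotype_class is PhenotypeClass.DEFINITE_IA
                for m in ped
            ):
                break
        pedigrees[fid] = ped
        truth.carrier_status[fid] = {k: v >= 1 for k, v in carriers.items()}

        chrom = str((i % 22) + 1)
        pos = 1_000_000 + i * 10_000_000
        gene = f"CAUSAL_{fid}"
        genotypes = {
            m.individual_id: carriers[m.individual_id]
            for m in ped
            if m.sequenced
        }
        causal = VariantRecord(
            chrom=chrom, pos=pos, ref="G", alt="A", genotypes=genotypes
        )
        variants.append(causal)
        bundles[causal.key] = _causal_bundle(gene)
        truth.causal_variant_by_family[fid] = causal.key

    # joint calling yields a genotype for every sequenced sample: the
    # family-private causal alleles are homozygous reference elsewhere
    all_sequenced = [
        m.individual_id for ped in pedigrees.values() for m in ped if m.sequenced
    ]
    for key in truth.causal_variant_by_family.values():
        rec = next(v for v in variants if v.key == key)
        for iid in all_sequenced:
            rec.genotypes.setdefault(iid, 0)

    # background variants shared across the cohort
    sequenced = [
        m.individual_id for ped in pedigrees.values() for m in ped if m.sequenced
    ]
    bases = ("A", "C", "G", "T")
    for b in range(config.n_background_variants):
        bundle, autosomal = _background_bundle(f"BG_{b:05d}", config, rng)
        chrom = str(int(rng.integers(1, 23))) if autosomal else "X"
        pos = int(rng.integers(1_000_000, 200_000_000))
        ref, alt = rng.choice(len(bases), size=2, replace=False)
        genotypes: dict[str, Optional[int]] = {}
        for ped in pedigrees.values():
            founder_dos = {
                f.individual_id: int(
                    (rng.random() < config.background_allele_freq)
                    + (rng.random() < config.background_allele_freq)
                )
                for f in ped.founders()
            }
            dosage = _gene_drop(ped, founder_dos, rng)
            for m in ped:
                if m.sequenced:
                    genotypes[m.individual_id] = dosage[m.individual_id]
        rec = VariantRecord(
            chrom=chrom, pos=pos, ref=bases[ref], alt=bases[alt],
            genotypes=genotypes,
        )
        if rec.key in bundles:
            continue
        variants.append(rec)
        bundles[rec.key] = bundle
    return pedigrees, variants, bundles, truth


# ---------------------------------------------------------------------------
# LOD track simulation
# ---------------------------------------------------------------------------


def simulate_marker_genotypes(
    ped: Pedigree,
    rng: np.random.Generator,
    n_alleles: int = 4,
) -> tuple[dict[str, tuple[int, int]], int]:
    """Random unlinked marker genotypes via gene dropping; observed for the
    included (definite/obligate) members only."""
    genotype: dict[str, tuple[int, int]] = {}
    for iid in ped.topological_order():
        ind = ped.members[iid]
        if ind.is_founder:
            genotype[iid] = (
                int(rng.integers(n_alleles)),
                int(rng.integers(n_alleles)),
            )
        else:
            pat = genotype[ind.father_id][int(rng.integers(2))]
            mat = genotype[ind.mother_id][int(rng.integers(2))]
            genotype[iid] = (pat, mat)
    included = [
        iid
        for iid, ind in ped.members.items()
        if ind.phenotype_class is PhenotypeClass.DEFINITE_IA or ind.obligate_carrier
    ]
    return {iid: genotype[iid] for iid in included}, n_alleles


def simulate_lod_track(
    pedigrees: dict[str, Pedigree],
    model: LinkageModel,
    config: SimConfig,
    causal_positions: Optional[dict[str, tuple]] = None,
    grid_bp: int = 5_000_000,
    chrom_length_bp: int = 200_000_000,
    linked_radius_bp: int = 2_000_000,
) -> LodTrack:
    """Marker grid scored by the pedigree-LOD engine, summed over families.

    Markers within ``linked_radius_bp`` of a family's causal locus are
    simulated under complete linkage for that family; all other markers are
    gene-dropped independently of disease (theta = 1/2 truth).
    """
    rng = np.random.default_rng(config.seed + 1)
    causal_positions = causal_positions or {}
    chroms = sorted({key[0] for key in causal_positions.values()}, key=int) or ["1"]
    markers = []
    for chrom in chroms:
        positions = sorted(
            set(range(grid_bp, chrom_length_bp, grid_bp))
            | {p for c, p in causal_positions.values() if c == chrom}
        )
        for pos in positions:
            total = 0.0
            for fid, ped in pedigrees.items():
                causal = causal_positions.get(fid)
                linked = (
                    causal is not None
                    and causal[0] == chrom
                    and abs(causal[1] - pos) <= linked_radius_bp
                )
                if linked:
                    marker = fully_informative_marker(ped)
                    if not marker.genotypes:
                        continue
                    total += pedigree_lod(
                        ped, marker.genotypes, model, theta=0.0,
                        n_marker_alleles=marker.n_alleles,
                        known_phase=marker.known_phase,
                    )
                else:
                    geno, k = simulate_marker_genotypes(ped, rng)
                    if not geno:
                        continue
                    total += pedigree_lod(
                        ped, geno, model, theta=0.0, n_marker_alleles=k
                    )
            markers.append((chrom, pos, total))
    return LodTrack(markers)


# ---------------------------------------------------------------------------
# Count matrix simulation
# ---------------------------------------------------------------------------


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthLabels]:
    """Negative-binomial gene x sample counts with planted group effects.

    counts_gs ~ NB(mean = library_size_s * relative_abundance_g *
    group_effect_gs, dispersion phi); planted genes carry the configured
    log2 fold changes (aneurysm over control).
    """
    rng = np.random.default_rng(config.seed + 2)
    G = config.n_genes
    n_a, n_c = config.n_aneurysm, config.n_control
    S = n_a + n_c
    samples = [f"IA{i + 1:03d}" for i in range(n_a)] + [
        f"CTRL{i + 1:03d}" for i in range(n_c)
    ]
    group = np.array(["aneurysm"] * n_a + ["control"] * n_c)
    rupture = np.where(
        group == "aneurysm",
        rng.choice(["ruptured", "unruptured"], size=S),
        "control",
    )
    meta = pd.DataFrame(
        {
            "group": group,
            "age": rng.integers(30, 75, size=S),
            "sex": rng.choice(["male", "female"], size=S),
            "rupture": rupture,
        },
        index=pd.Index(samples, name="sample"),
    )

    abundance = rng.lognormal(mean=np.log(50.0), sigma=1.5, size=G)
    abundance /= abundance.sum()
    lib = rng.uniform(*config.library_size_range, size=S)

    planted = list(config.planted_log2fc)
    if config.n_planted and not planted:
        planted = [2.0] * config.n_planted
    truth = TruthLabels()
    log2fc = np.zeros(G)
    for i, fc in enumerate(planted):
        log2fc[i] = fc
        truth.planted_de_genes[f"GENE{i + 1:05d}"] = fc

    mean = abundance[:, None] * lib[None, :]
    mean = mean * np.where(group[None, :] == "aneurysm", 2.0 ** log2fc[:, None], 1.0)
    phi = config.dispersion
    if phi <= 0:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / phi
        counts = rng.negative_binomial(r, r / (r + mean))
    genes = [f"GENE{i + 1:05d}" for i in range(G)]
    frame = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    return CountMatrix(frame, meta), truth


# ---------------------------------------------------------------------------
# Writers (same formats the loaders read)
# ---------------------------------------------------------------------------


def write_vcf(
    variants: list[VariantRecord], sample_ids: list[str], path: Path | str
) -> None:
    """Plain-text VCF 4.2 with GT-only genotype columns."""
    contigs = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in sorted(contigs, key=lambda c: (0, int(c)) if c.isdigit() else (1, c)):
            fh.write(f"##contig=<ID={c},length=250000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        ordered = sorted(
            variants,
            key=lambda v: (
                (0, int(v.chrom)) if v.chrom.isdigit() else (1, v.chrom),
                v.pos,
                v.alt,
            ),
        )
        for v in ordered:
            gts = []
            for s in sample_ids:
                d = v.genotypes.get(s)
                gts.append({None: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}[d])
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_annotations(bundles: dict[tuple, AnnotationBundle], path: Path | str) -> None:
    cols = [
        "chrom", "pos", "ref", "alt", "gene",
        "conseq_refseq", "conseq_ucsc", "conseq_ensembl", "splice_distance",
        "freq_1kg_ea", "freq_esp_ea", "internal_freq_bin",
        "internal_monomorphic", "cadd_c", "sift", "polyphen", "sift_indel",
        "ddig_in", "go_terms",
    ]

    def fmt(v) -> str:
        if v is None:
            return "."
        if isinstance(v, float):
            return f"{v:.6g}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for key in sorted(
            bundles,
            key=lambda k: ((0, int(k[0])) if k[0].isdigit() else (1, k[0]), k[1], k[3]),
        ):
            b = bundles[key]
            fh.write(
                "\t".join(
                    [
                        key[0], str(key[1]), key[2], key[3], fmt(b.gene),
                        b.consequence_by_db.get("RefSeq", "."),
                        b.consequence_by_db.get("UCSC", "."),
                        b.consequence_by_db.get("Ensembl", "."),
                        fmt(b.splice_distance_bp),
                        fmt(b.freq_1kg_ea), fmt(b.freq_esp_ea),
                        b.internal_freq_bin,
                        "1" if b.internal_monomorphic else "0",
                        fmt(b.cadd_c), fmt(b.sift), fmt(b.polyphen),
                        fmt(b.sift_indel), fmt(b.ddig_in),
                        ",".join(sorted(b.go_terms)) or ".",
                    ]
                )
                + "\n"
            )


def write_counts(matrix: CountMatrix, counts_path: Path | str, meta_path: Path | str) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.sample_meta.to_csv(meta_path, sep="\t")
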