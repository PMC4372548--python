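"""Domain types and file I/O for family exome cohorts.

Coordinates are 1-based VCF convention throughout; intervals are inclusive at
both ends.  Missing genotype is a first-class state (``None``), never silently
imputed.  Variants are reduced to their minimal anchored representation at
ingestion (shared suffix then shared prefix trimmed, position advanced) so
that downstream matching is representation-independent.

The extended PED dialect used here adds three columns to the standard six::

    family_id  individual_id  father_id  mother_id  sex  phenotype  screening_age  obligate  sequenced

where ``sex`` is 1/2/0, ``phenotype`` is one of DEFINITE_IA, PROBABLE_IA,
POSSIBLE_IA, AAA, UNAFFECTED_SCREENED, UNKNOWN, ``screening_age`` is an
integer or ``.``, and ``obligate``/``sequenced`` are 0/1.  Founder parents are
encoded as ``0``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

FOUNDER = "0"

#: Autosomes accepted by filter 1 of the cascade.
AUTOSOMES = {str(i) for i in range(1, 23)}


class PhenotypeClass(str, enum.Enum):
    DEFINITE_IA = "DEFINITE_IA"
    PROBABLE_IA = "PROBABLE_IA"
    POSSIBLE_IA = "POSSIBLE_IA"
    AAA = "AAA"
    UNAFFECTED_SCREENED = "UNAFFECTED_SCREENED"
    UNKNOWN = "UNKNOWN"


#: Phenotypes counted as "aneurysm" for the all-aneurysm segregation tier.
ANEURYSM_CLASSES = {
    PhenotypeClass.DEFINITE_IA,
    PhenotypeClass.PROBABLE_IA,
    PhenotypeClass.POSSIBLE_IA,
    PhenotypeClass.AAA,
}


@dataclass
class Individual:
    individual_id: str
    family_id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: str = "unknown"  # {male, female, unknown}
    phenotype_class: PhenotypeClass = PhenotypeClass.UNKNOWN
    obligate_carrier: bool = False
    screening_age: Optional[int] = None
    sequenced: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER

    def validate(self, min_screening_age: int = 45) -> None:
        if (self.father_id == FOUNDER) != (self.mother_id == FOUNDER):
            raise ValueError(
                f"{self.individual_id}: parents must be both founder-sentinel "
                f"or both present"
            )
        if self.phenotype_class is PhenotypeClass.UNAFFECTED_SCREENED:
            if self.screening_age is None or self.screening_age < min_screening_age:
                raise ValueError(
                    f"{self.individual_id}: UNAFFECTED_SCREENED requires "
                    f"screening_age >= {min_screening_age}"
                )


@dataclass
class Pedigree:
    """A single family: members keyed by individual id, with parent links."""

    family_id: str
    members: dict[str, Individual] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.members.values())

    def __len__(self) -> int:
        return len(self.members)

    def add(self, ind: Individual) -> None:
        self.members[ind.individual_id] = ind

    def validate(self, min_screening_age: int = 45, require_sequenced: bool = True) -> None:
        for ind in self:
            ind.validate(min_screening_age=min_screening_age)
            for pid in (ind.father_id, ind.mother_id):
                if pid != FOUNDER and pid not in self.members:
                    raise ValueError(
                        f"family {self.family_id}: parent {pid} of "
                        f"{ind.individual_id} not in pedigree"
                    )
        self._check_acyclic()
        if require_sequenced and not any(i.sequenced for i in self):
            raise ValueError(f"family {self.family_id}: no sequenced member")

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                raise ValueError(
                    f"family {self.family_id}: cycle in parent graph at {iid}"
                )
            if state.get(iid) == 2:
                return
            state[iid] = 1
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid != FOUNDER:
                    visit(pid)
            state[iid] = 2

        for iid in self.members:
            visit(iid)

    def founders(self) -> list[Individual]:
        return [i for i in self if i.is_founder]

    def sequenced_members(self) -> list[Individual]:
        return [i for i in self if i.sequenced]

    def children_of(self, iid: str) -> list[Individual]:
        return [i for i in self if iid in (i.father_id, i.mother_id)]

    def ancestors_of(self, iid: str) -> set[str]:
        out: set[str] = set()
        stack = [iid]
        while stack:
            ind = self.members[stack.pop()]
            for pid in (ind.father_id, ind.mother_id):
                if pid != FOUNDER and pid not in out:
                    out.add(pid)
                    stack.append(pid)
        return out

    def descendants_of(self, iid: str) -> set[str]:
        out: set[str] = set()
        stack = [iid]
        while stack:
            for child in self.children_of(stack.pop()):
                if child.individual_id not in out:
                    out.add(child.individual_id)
                    stack.append(child.individual_id)
        return out

    def topological_order(self) -> list[str]:
        """Member ids ordered so that parents precede children."""
        order: list[str] = []
        seen: set[str] = set()

        def visit(iid: str) -> None:
            if iid in seen:
                return
            seen.add(iid)
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid != FOUNDER:
                    visit(pid)
            order.append(iid)

        for iid in self.members:
            visit(iid)
        return order


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Reduce (pos, ref, alt) to the minimal anchored representation.

    Shared trailing bases are trimmed first, then shared leading bases (the
    position advances with each leading base removed); at least one base is
    always retained on each allele.  Full repeat-aware left-alignment would
    require the reference sequence, which is not an input here; anchor
    trimming is sufficient to make equivalent spellings of the same indel
    compare equal.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genotypes: dict[str, Optional[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chrom = self.chrom.removeprefix("chr")
        if self.alt == self.ref:
            raise ValueError(f"{self.chrom}:{self.pos} alt equals ref")
        self.pos, self.ref, self.alt = normalize_variant(self.pos, self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        return "INSERTION" if len(self.alt) > len(self.ref) else "DELETION"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"

    @property
    def is_frameshift(self) -> bool:
        return abs(len(self.alt) - len(self.ref)) % 3 != 0

    @property
    def is_autosomal(self) -> bool:
        return self.chrom in AUTOSOMES

    def dosage(self, individual_id: str) -> Optional[int]:
        return self.genotypes.get(individual_id)

    def is_carrier(self, individual_id: str) -> Optional[bool]:
        """Dominant-model carrier status; None when the genotype is missing."""
        d = self.genotypes.get(individual_id)
        return None if d is None else d >= 1


_ABSENT = None


@dataclass
class AnnotationBundle:
    """All externally computed scores and frequencies the cascade consumes.

    Every field defaults to "absent"; an unannotated variant is a bundle of
    absents.  Frequencies are alternate-allele fractions in [0, 1].
    """

    consequence_by_db: dict[str, str] = field(default_factory=dict)  # db -> class
    splice_distance_bp: Optional[int] = None
    freq_1kg_ea: Optional[float] = None
    freq_esp_ea: Optional[float] = None
    internal_freq_bin: str = "absent"  # {absent, lt_1pct, ge_1pct}
    internal_monomorphic: bool = False
    cadd_c: Optional[float] = None
    sift: Optional[str] = None  # {damaging, tolerated}
    polyphen: Optional[str] = None  # {probably, possibly, benign}
    sift_indel: Optional[str] = None  # {damaging, neutral}
    ddig_in: Optional[str] = None  # {damaging, neutral}
    gene: Optional[str] = None
    go_terms: frozenset[str] = frozenset()

    DBS = ("RefSeq", "UCSC", "Ensembl")

    def __post_init__(self) -> None:
        for f in (self.freq_1kg_ea, self.freq_esp_ea):
            if f is not None and not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} outside [0, 1]")
        if self.cadd_c is not None and self.cadd_c < 0:
            raise ValueError(f"CADD C-score {self.cadd_c} negative")
        if self.internal_freq_bin not in ("absent", "lt_1pct", "ge_1pct"):
            raise ValueError(f"bad internal_freq_bin {self.internal_freq_bin!r}")


class LodTrack:
    """Per-chromosome sorted marker positions with LOD values."""

    def __init__(self, markers: Iterable[tuple[str, int, float]] = ()):
        by_chrom: dict[str, list[tuple[int, float]]] = {}
        for chrom, pos, lod in markers:
            if not np.isfinite(lod):
                raise ValueError(f"non-finite LOD at {chrom}:{pos}")
            by_chrom.setdefault(str(chrom).removeprefix("chr"), []).append(
                (int(pos), float(lod))
            )
        self._pos: dict[str, np.ndarray] = {}
        self._lod: dict[str, np.ndarray] = {}
        for chrom, pairs in by_chrom.items():
            pairs.sort()
            self._pos[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            self._lod[chrom] = np.array([l for _, l in pairs], dtype=float)

    def __len__(self) -> int:
        return sum(len(v) for v in self._pos.values())

    def chromosomes(self) -> list[str]:
        return sorted(self._pos, key=_chrom_sort_key)

    def markers(self) -> list[tuple[str, int, float]]:
        out = []
        for chrom in self.chromosomes():
            out.extend(
                (chrom, int(p), float(l))
                for p, l in zip(self._pos[chrom], self._lod[chrom])
            )
        return out

    def max_in_window(self, chrom: str, pos: int, halfwidth_bp: int) -> Optional[float]:
        """Maximum LOD among markers with |marker - pos| <= halfwidth_bp."""
        chrom = str(chrom).removeprefix("chr")
        if chrom not in self._pos:
            return None
        positions = self._pos[chrom]
        lo = np.searchsorted(positions, pos - halfwidth_bp, side="left")
        hi = np.searchsorted(positions, pos + halfwidth_bp, side="right")
        if hi <= lo:
            return None
        return float(self._lod[chrom][lo:hi].max())


class CountMatrix:
    """Gene x sample integer counts with per-sample metadata.

    ``sample_meta`` must carry a ``group`` column ({aneurysm, control}) and
    may carry ``age``, ``sex`` and ``rupture`` ({ruptured, unruptured,
    control, unknown}).
    """

    def __init__(self, counts: pd.DataFrame, sample_meta: pd.DataFrame):
        counts = counts.copy()
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        if not np.allclose(counts.values, np.round(counts.values)):
            raise ValueError("non-integer counts")
        if "group" not in sample_meta.columns:
            raise ValueError("sample_meta lacks 'group' column")
        missing = [s for s in counts.columns if s not in sample_meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        self.counts = counts.astype(np.int64)
        self.sample_meta = sample_meta.loc[counts.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def values(self) -> np.ndarray:
        return self.counts.values

    def subset_genes(self, genes: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(genes)], self.sample_meta)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_SEX_IN = {"1": "male", "2": "female", "0": "unknown"}
_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}


def load_ped(path: Path | str, min_screening_age: int = 45) -> dict[str, Pedigree]:
    """Parse the extended PED dialect into pedigrees keyed by family id."""
    pedigrees: dict[str, Pedigree] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(fields)}"
                )
            fid, iid, fat, mot, sex, pheno, age, obligate, seq = fields
            try:
                phenotype = PhenotypeClass(pheno)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unknown phenotype class {pheno!r}"
                ) from exc
            if sex not in _SEX_IN:
                raise ValueError(f"{path}:{lineno}: bad sex code {sex!r}")
            ind = Individual(
                individual_id=iid,
                family_id=fid,
                father_id=fat,
                mother_id=mot,
                sex=_SEX_IN[sex],
                phenotype_class=phenotype,
                obligate_carrier=obligate == "1",
                screening_age=None if age == "." else int(age),
                sequenced=seq == "1",
            )
            pedigrees.setdefault(fid, Pedigree(family_id=fid)).add(ind)
    for ped in pedigrees.values():
        ped.validate(min_screening_age=min_screening_age, require_sequenced=False)
    return pedigrees


def write_ped(pedigrees: Mapping[str, Pedigree], path: Path | str) -> None:
    with open(path, "w") as fh:
        for fid in sorted(pedigrees):
            for iid in sorted(pedigrees[fid].members):
                i = pedigrees[fid].members[iid]
                fh.write(
                    "\t".join(
                        [
                            i.family_id,
                            i.individual_id,
                            i.father_id,
                            i.mother_id,
                            _SEX_OUT[i.sex],
                            i.phenotype_class.value,
                            "." if i.screening_age is None else str(i.screening_age),
                            "1" if i.obligate_carrier else "0",
                            "1" if i.sequenced else "0",
                        ]
                    )
                    + "\n"
                )


def load_cohort(
    vcf_path: Path | str, ped_path: Path | str
) -> tuple[dict[str, Pedigree], list[VariantRecord]]:
    """Load a multi-sample VCF plus extended PED into domain objects.

    Multiallelic sites are split into biallelic records; every record is
    normalized at construction.  Every VCF sample must appear in the PED
    (hard error naming the sample); every sequenced PED individual absent
    from the VCF gets an explicit MISSING fill.  Records are returned in
    deterministic (chrom, pos, ref, alt) order.
    """
    import pysam

    pedigrees = load_ped(ped_path)
    all_individuals = {
        iid: ind for ped in pedigrees.values() for iid, ind in ped.members.items()
    }
    with pysam.VariantFile(str(vcf_path)) as vcf:
        vcf_samples = list(vcf.header.samples)
        for sample in vcf_samples:
            if sample not in all_individuals:
                raise ValueError(
                    f"VCF sample {sample!r} absent from PED {ped_path}"
                )
        for ind in all_individuals.values():
            ind.sequenced = ind.individual_id in vcf_samples
        sequenced_ids = [i for i in all_individuals if all_individuals[i].sequenced]

        variants: list[VariantRecord] = []
        for rec in vcf:
            alts = rec.alts or ()
            for alt_index, alt in enumerate(alts, start=1):
                genotypes: dict[str, Optional[int]] = {}
                for sample in sequenced_ids:
                    gt = rec.samples[sample].get("GT") if sample in rec.samples else None
                    if gt is None or any(a is None for a in gt):
                        # half-missing calls (e.g. ./1) are flagged as MISSING,
                        # never guessed
                        genotypes[sample] = None
                    else:
                        genotypes[sample] = sum(1 for a in gt if a == alt_index)
                variants.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        genotypes=genotypes,
                    )
                )
    variants.sort(key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt))
    return pedigrees, variants


_CONSEQ_TOKENS = {"nonsynonymous_exonic", "splicing", "other", "."}


def _parse_score(token: str, column: str, lineno: int, allowed: set[str]):
    if token in ("", "."):
        return None
    if token not in allowed:
        raise ValueError(
            f"annotation line {lineno}, column {column!r}: "
            f"unparsable value {token!r}"
        )
    return token


def load_annotations(
    tsv_path: Path | str, variants: Sequence[VariantRecord]
) -> dict[tuple[str, int, str, str], AnnotationBundle]:
    """Join an annotation TSV onto variants by normalized (chrom,pos,ref,alt).

    Schema (tab-separated, header required): chrom pos ref alt gene
    conseq_refseq conseq_ucsc conseq_ensembl splice_distance freq_1kg_ea
    freq_esp_ea internal_freq_bin internal_monomorphic cadd_c sift polyphen
    sift_indel ddig_in go_terms.  ``.`` denotes absent.  Variants without a
    row receive a bundle of absents.
    """
    rows: dict[tuple[str, int, str, str], AnnotationBundle] = {}
    with open(tsv_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        required = ["chrom", "pos", "ref", "alt"]
        for col in required:
            if col not in idx:
                raise ValueError(f"{tsv_path}: missing column {col!r}")

        def get(fields: list[str], col: str) -> str:
            i = idx.get(col)
            return fields[i] if i is not None and i < len(fields) else "."

        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            pos, ref, alt = normalize_variant(
                int(get(fields, "pos")), get(fields, "ref"), get(fields, "alt")
            )
            key = (get(fields, "chrom").removeprefix("chr"), pos, ref, alt)
            if key in rows:
                raise ValueError(
                    f"{tsv_path}:{lineno}: duplicate annotation for "
                    f"{key[0]}:{key[1]} {key[2]}>{key[3]}"
                )

            def fnum(col: str) -> Optional[float]:
                token = get(fields, col)
                if token in ("", "."):
                    return None
                try:
                    return float(token)
                except ValueError as exc:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: column {col!r}: "
                        f"unparsable score {token!r}"
                    ) from exc

            conseq = {}
            for db, col in (
                ("RefSeq", "conseq_refseq"),
                ("UCSC", "conseq_ucsc"),
                ("Ensembl", "conseq_ensembl"),
            ):
                token = get(fields, col)
                if token not in _CONSEQ_TOKENS:
                    raise ValueError(
                        f"{tsv_path}:{lineno}: column {col!r}: "
                        f"unknown consequence {token!r}"
                    )
                if token != ".":
                    conseq[db] = token
            splice = fnum("splice_distance")
            go_token = get(fields, "go_terms")
            bundle = AnnotationBundle(
                consequence_by_db=conseq,
                splice_distance_bp=None if splice is None else int(splice),
                freq_1kg_ea=fnum("freq_1kg_ea"),
                freq_esp_ea=fnum("freq_esp_ea"),
                internal_freq_bin=(
                    get(fields, "internal_freq_bin")
                    if get(fields, "internal_freq_bin") != "."
                    else "absent"
                ),
                internal_monomorphic=get(fields, "internal_monomorphic") == "1",
                cadd_c=fnum("cadd_c"),
                sift=_parse_score(
                    get(fields, "sift"), "sift", lineno, {"damaging", "tolerated"}
                ),
                polyphen=_parse_score(
                    get(fields, "polyphen"),
                    "polyphen",
                    lineno,
                    {"probably", "possibly", "benign"},
                ),
                sift_indel=_parse_score(
                    get(fields, "sift_indel"),
                    "sift_indel",
                    lineno,
                    {"damaging", "neutral"},
                ),
                ddig_in=_parse_score(
                    get(fields, "ddig_in"), "ddig_in", lineno, {"damaging", "neutral"}
                ),
                gene=None if get(fields, "gene") in ("", ".") else get(fields, "gene"),
                go_terms=frozenset(
                    t for t in go_token.split(",") if t and t != "."
                ),
            )
            rows[key] = bundle
    return {v.key: rows.get(v.key, AnnotationBundle()) for v in variants}


def load_lod_track(path: Path | str) -> LodTrack:
    """Read a (chrom, pos, lod) TSV with header into a LodTrack."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return LodTrack(zip(df["chrom"], df["pos"], df["lod"]))


def write_lod_track(track: LodTrack, path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tlod\n")
        for chrom, pos, lod in track.markers():
            fh.write(f"{chrom}\t{pos}\t{lod:.6g}\n")


def load_counts(counts_path: Path | str, meta_path: Path | str) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts, meta)


# Candidate report column order mirrors the published candidate table.
CANDIDATE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "alt_freq",
    "polyphen",
    "sift",
    "sift_indel",
    "ddig_in",
    "cadd_c",
    "lod",
    "family",
    "unaff",
    "seg_all_aneurysm",
    "cross_family",
    "within_max_lod",
    "inspection",
    "go_terms",
    "logfc",
    "fdr",
]


def write_reports(
    candidates: pd.DataFrame,
    attrition: Mapping[str, pd.DataFrame],
    out_dir: Path | str,
) -> dict[str, Path]:
    """Write the candidate table and attrition tables as TSV.

    Output is byte-stable for fixed inputs: fixed column order, fixed float
    formatting, rows sorted by (chrom, pos, alt, family).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cand = candidates.copy()
    for col in CANDIDATE_COLUMNS:
        if col not in cand.columns:
            cand[col] = np.nan
    cand = cand[CANDIDATE_COLUMNS]
    if len(cand):
        cand = cand.sort_values(["chrom", "pos", "alt", "family"], kind="mergesort")
    cand_path = out / "candidates.tsv"
    cand.to_csv(cand_path, sep="\t", index=False, float_format="%.6g", na_rep="NA")
    paths["candidates"] = cand_path

    for name, table in attrition.items():
        p = out / f"attrition_{name.lower()}.tsv"
        table.to_csv(p, sep="\t", float_format="%.6g")
        paths[f"attrition_{name.lower()}"] = p
    return paths
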