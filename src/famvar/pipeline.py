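"""End-to-end orchestration: filter -> segregate -> linkage -> expression.

All analysis stages are deterministic; randomness enters only through the
synthetic module.  Re-running with identical configuration and inputs yields
byte-identical reports.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from famvar import cascade as cascade_mod
from famvar import cohort as cohort_mod
from famvar import expression as expr_mod
from famvar import linkage as linkage_mod
from famvar.annotation import go_tag, load_go_map
from famvar.cascade import CascadeConfig, candidates_to_frame
from famvar.expression import DEConfig
from famvar.linkage import LinkageModel

logger = logging.getLogger("famvar")


@dataclass
class PipelineConfig:
    vcf: Path
    ped: Path
    annotations: Path
    out_dir: Path
    lod_track: Optional[Path] = None
    family_max_lods: Optional[Path] = None  # TSV: family <tab> max_lod
    counts: Optional[Path] = None
    sample_meta: Optional[Path] = None
    go_map: Optional[Path] = None
    review: Optional[Path] = None
    regions: Optional[Path] = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    linkage_model: LinkageModel = field(default_factory=LinkageModel)
    window_halfwidth_bp: int = linkage_mod.WINDOW_HALFWIDTH_BP
    lod_tolerance: float = linkage_mod.LOD_TOLERANCE
    de: DEConfig = field(default_factory=DEConfig)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key in ("vcf", "ped", "annotations", "out_dir", "lod_track",
                    "family_max_lods", "counts", "sample_meta", "go_map",
                    "review", "regions"):
            if key in raw and raw[key] is not None:
                kwargs[key] = Path(raw[key])
        if "cascade" in raw:
            kwargs["cascade"] = CascadeConfig(**raw["cascade"])
        if "linkage_model" in raw:
            lm = dict(raw["linkage_model"])
            if "penetrances" in lm:
                lm["penetrances"] = tuple(lm["penetrances"])
            kwargs["linkage_model"] = LinkageModel(**lm)
        if "de" in raw:
            de = dict(raw["de"])
            if "covariates" in de:
                de["covariates"] = tuple(de["covariates"])
            kwargs["de"] = DEConfig(**de)
        for key in ("window_halfwidth_bp", "lod_tolerance"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


def _require(path: Optional[Path], what: str) -> Path:
    if path is None:
        raise FileNotFoundError(f"no {what} configured")
    if not Path(path).exists():
        raise FileNotFoundError(f"{what} not found: {path}")
    return Path(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full prioritization chain and write reports.

    Returns a summary dict with stage-wise counts, candidate data frame and
    written paths.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logger.info("loading cohort: %s + %s", config.vcf, config.ped)
    pedigrees, variants = cohort_mod.load_cohort(
        _require(config.vcf, "VCF"), _require(config.ped, "PED")
    )
    bundles = cohort_mod.load_annotations(
        _require(config.annotations, "annotation table"), variants
    )
    logger.info("loaded %d variants across %d families", len(variants), len(pedigrees))

    snvs = [v for v in variants if v.is_snv]
    indels = [v for v in variants if not v.is_snv]
    cand_snv, trace_snv = cascade_mod.apply_cascade(
        snvs, bundles, pedigrees, config.cascade
    )
    cand_indel, trace_indel = cascade_mod.apply_cascade(
        indels, bundles, pedigrees, config.cascade
    )
    candidates = cand_snv + cand_indel
    logger.info(
        "cascade: %d SNV + %d indel candidates", len(cand_snv), len(cand_indel)
    )

    if config.review is not None:
        cascade_mod.apply_inspection(candidates, _require(config.review, "review file"))

    if config.go_map is not None:
        go_map = load_go_map(_require(config.go_map, "GO map"))
        for cand in candidates:
            cand.go_terms = go_tag(cand.gene, go_map)

    if config.lod_track is not None:
        track = cohort_mod.load_lod_track(_require(config.lod_track, "LOD track"))
        linkage_mod.annotate_window_lod(candidates, track, config.window_halfwidth_bp)
        if config.family_max_lods is not None:
            fam_max = _load_family_max(_require(config.family_max_lods,
                                                "family maxima"))
        else:
            fam_max = {
                fid: linkage_mod.max_possible_lod(ped, config.linkage_model)
                for fid, ped in pedigrees.items()
            }
        linkage_mod.flag_linkage_support(candidates, fam_max, config.lod_tolerance)

    de_results = None
    if config.counts is not None and config.sample_meta is not None:
        matrix = cohort_mod.load_counts(
            _require(config.counts, "count matrix"),
            _require(config.sample_meta, "sample metadata"),
        )
        matrix = expr_mod.filter_low_counts(matrix, config.de)
        de_results = expr_mod.fit_nb_de(matrix, config.de)
        expr_mod.integrate_expression(
            candidates, de_results, config.de.fdr_threshold
        )
        de_results.to_csv(out_dir / "de_results.tsv", sep="\t",
                          float_format="%.6g", na_rep="NA")

    frame = candidates_to_frame(candidates)
    paths = cohort_mod.write_reports(
        frame, {"snv": trace_snv, "indel": trace_indel}, out_dir
    )

    region_counts = {}
    if config.regions is not None:
        regions = linkage_mod.load_regions(_require(config.regions, "regions file"))
        overlap = linkage_mod.region_overlap(candidates, regions)
        region_counts = {name: len(hits) for name, hits in overlap.items()}

    summary = {
        "n_variants": len(variants),
        "n_candidates": len(candidates),
        "n_candidates_snv": len(cand_snv),
        "n_candidates_indel": len(cand_indel),
        "n_within_max": sum(1 for c in candidates if c.within_max),
        "n_differentially_expressed": sum(
            1 for c in candidates if c.differentially_expressed
        ),
        "region_counts": region_counts,
        "attrition_snv": trace_snv,
        "attrition_indel": trace_indel,
        "candidates": frame,
        "paths": paths,
    }
    _write_log(summary, trace_snv, trace_indel, out_dir)
    return summary


def _load_family_max(path: Path) -> dict[str, float]:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("family\t"):
                continue
            fam, lod = line.split("\t")[:2]
            out[fam] = float(lod)
    return out


def _write_log(summary: dict, trace_snv, trace_indel, out_dir: Path) -> None:
    import famvar

    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(f"famvar version {famvar.__version__}\n")
        for key in ("n_variants", "n_candidates", "n_candidates_snv",
                    "n_candidates_indel", "n_within_max",
                    "n_differentially_expressed"):
            fh.write(f"{key}\t{summary[key]}\n")
        fh.write("\nSNV attrition:\n")
        fh.write(trace_snv.to_string())
        fh.write("\n\nIndel attrition:\n")
        fh.write(trace_indel.to_string())
        fh.write("\n")


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
    )
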