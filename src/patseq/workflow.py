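"""End-to-end pipeline orchestration with a single structured config.

Stages run in the order preprocess -> map -> build-pacs -> annotate ->
de(gene) -> de(pac) -> switch -> profile. Inputs may be raw FASTQ (quality
filter, poly(T) trim, exact mapping) or pre-mapped BED tag files. A JSON
manifest records package version, all parameters, per-stage counts and the
seed, and rerunning with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotationIndex, annotate_pacs, gene_counts, load_annotation
from .expression import DEOptions, de_test, estimate_size_factors
from .pac import PacParams, build_pacs
from .preprocess import GenomeIndex, PreprocessConfig, preprocess_sample, read_bed
from .profiles import region_profiles
from .switching import SwitchParams, detect_switching, events_table, switching_genes
from .util import read_fasta

log = logging.getLogger("patseq")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    genome: str = ""
    annotation: str = ""
    sample_sheet: str = ""
    input_dir: str = ""
    input_format: str = "bed"          # "bed" or "fastq"
    output_dir: str = "patseq_out"
    utr3_extension: int = 120
    gene_alpha: float = 0.01           # DE gene padj threshold
    pac_alpha: float = 0.05            # DE-PAC padj threshold
    comparisons: List[Tuple[str, str]] = field(default_factory=list)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pac: PacParams = field(default_factory=PacParams)
    switch: SwitchParams = field(default_factory=SwitchParams)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub_cls in (("preprocess", PreprocessConfig), ("pac", PacParams),
                             ("switch", SwitchParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub_cls(**kwargs[key])
        if "comparisons" in kwargs:
            kwargs["comparisons"] = [tuple(c) for c in kwargs["comparisons"]]
        return cls(**kwargs)

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d


def validate_config(config: RunConfig) -> List[str]:
    """Report-only validation: list every invariant violation found."""
    violations: List[str] = []
    for name in ("genome", "annotation", "sample_sheet"):
        path = getattr(config, name)
        if path and not os.path.exists(path):
            violations.append(f"{name} path does not exist: {path}")
    if config.input_format not in ("bed", "fastq"):
        violations.append(f"input_format must be 'bed' or 'fastq', got {config.input_format!r}")
    if not 0 < config.gene_alpha < 1:
        violations.append("gene_alpha must lie in (0, 1)")
    if not 0 < config.pac_alpha < 1:
        violations.append("pac_alpha must lie in (0, 1)")
    if config.utr3_extension < 0:
        violations.append("utr3_extension must be >= 0")
    violations += config.preprocess.validate()
    violations += [f"pac.{v}" for v in config.pac.validate()]
    violations += [f"switch.{v}" for v in config.switch.validate()]
    if config.sample_sheet and os.path.exists(config.sample_sheet):
        sheet = pd.read_csv(config.sample_sheet, sep="\t")
        if sheet["sample"].duplicated().any():
            violations.append("sample sheet contains duplicate sample ids")
        groups = set(sheet["group"])
        for a, b in config.comparisons:
            for g in (a, b):
                if g not in groups:
                    violations.append(f"comparison group {g!r} absent from sample sheet")
    return violations


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> Dict:
    """Execute the full pipeline; returns the manifest dict.

    All result tables are written as TSV under ``config.output_dir`` with a
    fixed float format, so identical configs and inputs give byte-identical
    outputs. Any stage failure aborts with the stage name; previously
    written outputs are marked stale in the manifest.
    """
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    outdir = config.output_dir
    os.makedirs(outdir, exist_ok=True)
    manifest: Dict = {
        "package_version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
        "status": "running",
    }
    sheet = pd.read_csv(config.sample_sheet, sep="\t")
    samples = list(sheet["sample"])
    stage = "load-inputs"
    try:
        genome = read_fasta(config.genome)

        # ---- preprocess / map / import ----
        stage = "preprocess"
        tag_frames, stage_counts = [], {}
        if config.input_format == "fastq":
            index = GenomeIndex(genome)
            for sample in samples:
                path = os.path.join(config.input_dir, f"{sample}.fastq")
                tags_s, counts = preprocess_sample(
                    path, genome, sample, config.preprocess, index=index)
                tag_frames.append(tags_s)
                stage_counts[sample] = {k: dict(v) for k, v in counts.items()}
        else:
            for sample in samples:
                path = os.path.join(config.input_dir, f"{sample}.bed")
                tags_s = read_bed(path, sample)
                tag_frames.append(tags_s)
                stage_counts[sample] = {"imported": len(tags_s)}
        tags = pd.concat(tag_frames, ignore_index=True)
        manifest["stages"]["preprocess"] = stage_counts
        log.info("preprocess: %d tags over %d samples", len(tags), len(samples))

        # ---- PAS / PAC ----
        stage = "build-pacs"
        params = config.pac
        tables = build_pacs(tags, genome, samples, params)
        pacs = tables["pacs"]
        manifest["stages"]["build_pacs"] = {
            "pas": len(tables["pas"]),
            "pas_ip_removed": len(tables["pas_ip_removed"]),
            "pacs_all": len(tables["pacs_all"]),
            "pacs_low_support": len(tables["pacs_low_support"]),
            "pacs": len(pacs),
        }
        log.info("build-pacs: %d PAS -> %d PACs", len(tables["pas"]), len(pacs))

        # ---- annotate ----
        stage = "annotate"
        models = load_annotation(config.annotation, extension=config.utr3_extension)
        ann_index = AnnotationIndex(models)
        annotated = annotate_pacs(pacs, ann_index)
        gene_matrix, intergenic = gene_counts(annotated, samples)
        manifest["stages"]["annotate"] = {
            "genes_with_pacs": int(gene_matrix.shape[0]),
            "intergenic_pacs": int(len(intergenic)),
            "region_counts": annotated["region"].value_counts().to_dict(),
        }
        _write_tsv(annotated, os.path.join(outdir, "pacs_annotated.tsv"))
        _write_tsv(gene_matrix.reset_index(), os.path.join(outdir, "gene_counts.tsv"))
        _write_pac_bed(annotated, os.path.join(outdir, "pacs.bed"))

        # ---- DE + switching per comparison ----
        pac_matrix = annotated.set_index("pac_id")[samples]
        groups = sheet.groupby("group")["sample"].apply(list).to_dict()
        for group_a, group_b in config.comparisons:
            comp = f"{group_a}_vs_{group_b}"
            stage = f"de-gene:{comp}"
            de_gene = de_test(gene_matrix, groups[group_a], groups[group_b],
                              alpha=config.gene_alpha)
            _write_tsv(de_gene.reset_index(), os.path.join(outdir, f"de_gene.{comp}.tsv"))
            stage = f"de-pac:{comp}"
            de_pac = de_test(pac_matrix, groups[group_a], groups[group_b],
                             alpha=config.pac_alpha)
            _write_tsv(de_pac.reset_index(), os.path.join(outdir, f"de_pac.{comp}.tsv"))
            stage = f"switch:{comp}"
            events = detect_switching(annotated, sheet, (group_a, group_b),
                                      config.switch, de_pac)
            _write_tsv(events_table(events), os.path.join(outdir, f"switch.{comp}.tsv"))
            manifest["stages"][comp] = {
                "de_genes": int(de_gene["significant"].sum()),
                "de_pacs": int(de_pac["significant"].sum()),
                "switch_pairs": int(sum(e.verdict for e in events)),
                "switch_genes": len(switching_genes(events)),
            }
            log.info("%s: %d DE genes, %d DE PACs, %d switching genes", comp,
                     manifest["stages"][comp]["de_genes"],
                     manifest["stages"][comp]["de_pacs"],
                     manifest["stages"][comp]["switch_genes"])

        # ---- composition profiles ----
        stage = "profile"
        profiles = region_profiles(annotated, genome)
        _write_tsv(profiles, os.path.join(outdir, "profiles.tsv"))
        manifest["stages"]["profile"] = {
            "regions": sorted(profiles["region"].unique().tolist()),
        }
    except Exception as exc:
        manifest["status"] = f"failed at {stage}"
        _write_manifest(manifest, outdir)
        raise StageError(stage, exc) from exc

    manifest["status"] = "complete"
    _write_manifest(manifest, outdir)
    return manifest


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def _write_pac_bed(annotated: pd.DataFrame, path: str) -> None:
    """PACs as BED6+: the representative position is the interval, the full
    member span and region ride along as extra columns."""
    with open(path, "w") as fh:
        for row in annotated.itertuples():
            gene = row.gene_id if row.gene_id is not None else "."
            fh.write(
                f"{row.chrom}\t{row.representative}\t{row.representative + 1}\t"
                f"{row.pac_id}\t{row.total}\t{row.strand}\t"
                f"{row.start}\t{row.end}\t{gene}\t{row.region}\n"
            )


def _write_manifest(manifest: Dict, outdir: str) -> None:
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
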