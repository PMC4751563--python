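"""End-to-end pipeline orchestration.

Stages run in dependency order: simulate -> map -> dedup -> coverage ->
circle models -> mosaic -> breakpoints.  Each stage writes its outputs
before the next starts and contributes counts to a machine-readable run
summary (total / mapped / deduplicated / Ty-mapping reads and percent
Ty, mirroring the standard per-sample accounting).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import breakpoints as bp
from . import circles as ci
from . import coverage as cov
from . import mosaic as mo
from . import synthetic as syn
from .genome import Genome, TyAnnotation, build_exclusion_set, load_annotations, write_annotations
from .mapping import (
    GenomeMapper,
    MapperConfig,
    Read,
    map_reads,
    read_fastq,
    records_to_tsv,
    remove_duplicates,
    write_fastq,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """One config to drive all stages; every analysis constant surfaces
    here with its standard default (142-nt k-mers/reads, 50-bp windows,
    10x50-bp flanks, 99.5% locus coverage, 10 bp / 30 kb inter-LTR band,
    1000-hit cap, Q20)."""

    out_dir: str = "tycircle_out"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "map", "coverage", "circles", "mosaic", "breakpoints"]
    )
    genome_fasta: str | None = None
    annotation_tsv: str | None = None
    reads_fastq: str | None = None
    exclusions_tsv: str | None = None
    scenarios: list[str] = field(default_factory=lambda: ["I", "V"])
    family: str = "Ty1"
    min_quality: int = 20
    mapper: MapperConfig = field(default_factory=MapperConfig)
    profile: cov.ProfileConfig = field(default_factory=cov.ProfileConfig)
    circle: ci.CircleModelConfig = field(default_factory=ci.CircleModelConfig)
    mosaic: mo.MosaicConfig = field(default_factory=mo.MosaicConfig)
    locus: cov.LocusCriteria = field(default_factory=cov.LocusCriteria)
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("mapper", MapperConfig),
            ("profile", cov.ProfileConfig),
            ("circle", ci.CircleModelConfig),
            ("mosaic", mo.MosaicConfig),
            ("locus", cov.LocusCriteria),
            ("synthetic", syn.SyntheticConfig),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "seed": config.synthetic.seed,
        "stages": {},
        "counts": {},
        "outputs": {},
    }
    genome: Genome | None = None
    annotations: list[TyAnnotation] | None = None
    reads: list[Read] | None = None
    records = None
    truth = None

    def done(stage: str, **outputs: str) -> None:
        summary["stages"][stage] = "completed"
        summary["outputs"].update(outputs)
        log.info("stage %s completed", stage)

    try:
        if "simulate" in config.stages:
            genome, annotations, truth = syn.build_genome(config.synthetic)
            rng = np.random.default_rng(config.synthetic.seed + 1)
            elements = [a for a in annotations if a.is_full_length]
            sources = []
            for scen in config.scenarios:
                for el in elements:
                    partner = None
                    if scen in ("VI", "VII"):
                        solos = [
                            a for a in annotations
                            if not a.is_full_length and a.chrom == el.chrom
                        ]
                        if not solos:
                            continue
                        partner = solos[0]
                    model, ctruth = syn.make_circle(
                        scen, el, genome, config.synthetic, rng, partner=partner
                    )
                    truth.circles.append(ctruth)
                    sources.append(syn.ReadSource(ctruth.circle_id, model.sequence, circular=True))
            reads, read_truth = syn.simulate_reads(sources, config.synthetic, rng)
            truth.reads = read_truth
            genome.to_fasta(out / "genome.fa")
            write_annotations(annotations, out / "annotations.tsv")
            write_fastq(reads, out / "reads.fastq")
            syn.write_truth(truth, out)
            summary["counts"]["simulated_reads"] = len(reads)
            done(
                "simulate",
                genome=str(out / "genome.fa"),
                annotations=str(out / "annotations.tsv"),
                reads=str(out / "reads.fastq"),
            )

        if genome is None:
            if not config.genome_fasta:
                raise PipelineError("no genome available: supply genome_fasta or enable simulate")
            genome = Genome.from_fasta(config.genome_fasta)
        if annotations is None:
            if not config.annotation_tsv:
                raise PipelineError("no annotations available: supply annotation_tsv or enable simulate")
            annotations = load_annotations(config.annotation_tsv, genome)
        if reads is None and {"map", "coverage", "mosaic", "breakpoints"} & set(config.stages):
            if not config.reads_fastq:
                raise PipelineError("no reads available: supply reads_fastq or enable simulate")
            reads = list(read_fastq(config.reads_fastq))

        if "map" in config.stages:
            records = map_reads(reads, genome, config.mapper)
            n_mapped = sum(r.mapped for r in records)
            records = remove_duplicates(records)
            dedup = [r for r in records if r.mapped]
            records_to_tsv(records, out / "placements.tsv")
            summary["counts"].update(
                total_reads=len(reads),
                mapped_reads=n_mapped,
                deduplicated_reads=len(dedup),
            )
            done("map", placements=str(out / "placements.tsv"))

        dedup_records = [r for r in (records or []) if r.mapped]

        if "coverage" in config.stages:
            if records is None:
                raise PipelineError("coverage stage requires mapping output (enable map)")
            track = cov.weighted_track(dedup_records, genome)
            track.to_bedgraph(out / "coverage.bedgraph")
            observed = cov.family_venn(dedup_records, annotations)
            expected, _ = cov.expected_family_coverage(
                annotations, genome, config.mapper, config.locus.kmer_len
            )
            cov.venn_table(observed, expected).to_csv(out / "family_venn.tsv", sep="\t")
            exclusions = build_exclusion_set(config.exclusions_tsv)
            feature_sets = {
                "Ty": [(a.chrom, a.start, a.end) for a in annotations],
                "genome": [(c, 0, genome.length(c)) for c in genome.names],
            }
            cov.coverage_distribution(track, feature_sets, exclusions).to_csv(
                out / "coverage_distribution.tsv", sep="\t"
            )
            elements = [a for a in annotations if a.is_full_length]
            profile = cov.element_profile(track, elements, config.profile)
            cov.profile_to_frame(profile).to_csv(out / "element_profile.tsv", sep="\t", index=False)
            flags = cov.locus_contribution(dedup_records, elements, genome, config.locus, track)
            flags.to_csv(out / "locus_contribution.tsv", sep="\t")
            by_chrom = cov._family_lookup(annotations)
            n_ty = sum(1 for r in dedup_records if cov.read_family_set(r, by_chrom))
            summary["counts"]["ty_mapping_reads"] = n_ty
            n_nuclear = len(dedup_records)
            summary["counts"]["percent_ty"] = 100.0 * n_ty / n_nuclear if n_nuclear else 0.0
            done(
                "coverage",
                coverage=str(out / "coverage.bedgraph"),
                family_venn=str(out / "family_venn.tsv"),
                element_profile=str(out / "element_profile.tsv"),
                locus_contribution=str(out / "locus_contribution.tsv"),
            )

        if "circles" in config.stages:
            elements = [a for a in annotations if a.is_full_length and a.family == config.family]
            models = [ci.one_ltr_circle(el, genome) for el in elements]
            models += [ci.two_ltr_circle(el, genome) for el in elements]
            models += ci.inter_ltr_circles(annotations, genome, config.circle)
            ci.write_circles_fasta(models, out / "circle_models.fa")
            profiles = ci.expected_circle_coverage(
                models, genome, elements, config.mapper, config.profile, config.circle.kmer_len
            )
            rows = []
            for scen, prof in profiles.items():
                frame = cov.profile_to_frame(prof)
                frame.insert(0, "scenario", scen.value)
                rows.append(frame)
            import pandas as pd

            pd.concat(rows).to_csv(out / "expected_profiles.tsv", sep="\t", index=False)
            summary["counts"]["circle_models"] = len(models)
            done(
                "circles",
                circle_models=str(out / "circle_models.fa"),
                expected_profiles=str(out / "expected_profiles.tsv"),
            )

        if "mosaic" in config.stages:
            if reads is None:
                raise PipelineError("mosaic stage requires reads")
            calls = mo.detect_mosaics(reads, annotations, genome, config.mosaic, config.family)
            mo.calls_to_frame(calls).to_csv(out / "mosaic_calls.tsv", sep="\t", index=False)
            summary["counts"]["mosaic_calls"] = len(calls)
            done("mosaic", mosaic_calls=str(out / "mosaic_calls.tsv"))

        if "breakpoints" in config.stages:
            if reads is None:
                raise PipelineError("breakpoints stage requires reads")
            libraries = bp.build_libraries(annotations, genome, config.family)
            calls = bp.call_breakpoints(reads, libraries, genome, config.mapper)
            calls = bp.quality_filter(calls, {r.read_id: r for r in reads}, config.min_quality)
            bp.calls_to_frame(calls, annotations).to_csv(
                out / "breakpoint_calls.tsv", sep="\t", index=False
            )
            summary["counts"]["breakpoint_calls"] = len(calls)
            done("breakpoints", breakpoint_calls=str(out / "breakpoint_calls.tsv"))
    except Exception as exc:
        stage = next(
            (s for s in config.stages if s not in summary["stages"]), "unknown"
        )
        summary["stages"][stage] = f"failed: {exc}"
        (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    summary["outputs"]["summary"] = str(out / "run_summary.json")
    return summary
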