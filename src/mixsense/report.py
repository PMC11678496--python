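"""Run configuration and the end-to-end evaluation pipeline.

A run is described by a manifest (YAML): one VCF per sample with its role
(``dna1``, ``dna2`` or ``mixture`` with a DNA1 fraction ``f1``), optional
per-base coverage tables, cutoff grids and probit options. ``run_evaluate``
executes the full workflow — read and normalize call sets, select and trim
informative pairs, tabulate detection rates and probit sensitivities over
the cutoff grid, count FP error alleles — and writes the tables plus a
run-metadata record to the output directory.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError
from .fp_errors import fp_grid
from .pairs import (
    DEFAULT_DP_MIN,
    MixtureDesign,
    select_nh_pairs,
    trim_pairs,
    write_pairs_tsv,
)
from .sensitivity import CutoffCondition, count_detected_variants, detection_table, sensitivity_grid
from .vcf_io import CallSet, DepthTable, read_callset, read_depth_table

logger = logging.getLogger(__name__)

DEFAULT_DP_CUTS = [10, 20, 30, 50]
DEFAULT_VAF_CUTS = [0.0, 0.01, 0.03, 0.05]


@dataclass
class SampleSpec:
    sample_id: str
    vcf: Path
    role: str  # dna1 | dna2 | mixture
    f1: float | None = None
    depth_table: Path | None = None


@dataclass
class RunConfig:
    """Validated run manifest: exactly one DNA1, one DNA2, unique mixture f1."""

    samples: list[SampleSpec]
    dp_cuts: list[int] = field(default_factory=lambda: list(DEFAULT_DP_CUTS))
    vaf_cuts: list[float] = field(default_factory=lambda: list(DEFAULT_VAF_CUTS))
    dp_min: int = DEFAULT_DP_MIN
    strict_depth: bool = False
    pass_only: bool = False
    probit_target: float = 0.95
    max_fit_evaf: float | None = None
    outdir: Path = Path("mixsense_out")
    seed: int = 0

    def __post_init__(self) -> None:
        roles = [s.role for s in self.samples]
        if roles.count("dna1") != 1 or roles.count("dna2") != 1:
            raise ConfigError("manifest must name exactly one dna1 and one dna2 sample")
        fracs = [s.f1 for s in self.samples if s.role == "mixture"]
        if any(f is None for f in fracs):
            raise ConfigError("every mixture sample needs an f1 (DNA1 fraction)")
        if len(set(fracs)) != len(fracs):
            raise ConfigError("mixture f1 values must be unique")
        if not fracs:
            raise ConfigError("manifest needs at least one mixture sample")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        path = Path(path)
        try:
            raw = yaml.safe_load(path.read_text())
        except Exception as exc:
            raise ConfigError(f"cannot parse manifest {path}: {exc}") from exc
        if not isinstance(raw, dict) or "samples" not in raw:
            raise ConfigError(f"manifest {path} must be a mapping with a 'samples' list")
        base = path.parent
        samples = []
        for entry in raw["samples"]:
            try:
                samples.append(
                    SampleSpec(
                        sample_id=entry["sample_id"],
                        vcf=base / entry["vcf"],
                        role=entry.get("role", "mixture"),
                        f1=entry.get("f1"),
                        depth_table=(base / entry["depth_table"])
                        if entry.get("depth_table") else None,
                    )
                )
            except KeyError as exc:
                raise ConfigError(f"manifest sample entry missing field {exc}") from exc
        kwargs: dict = {"samples": samples}
        for name in ("dp_cuts", "vaf_cuts", "dp_min", "strict_depth", "pass_only",
                     "probit_target", "max_fit_evaf", "seed"):
            if name in raw:
                kwargs[name] = raw[name]
        if "outdir" in raw:
            kwargs["outdir"] = base / raw["outdir"]
        kwargs.update({k: v for k, v in overrides.items() if v is not None})
        kwargs["outdir"] = Path(kwargs.get("outdir", Path("mixsense_out")))
        return cls(**kwargs)

    @property
    def design(self) -> MixtureDesign:
        mix = sorted(
            ((s.sample_id, float(s.f1)) for s in self.samples if s.role == "mixture"),
            key=lambda kv: kv[1],
        )
        return MixtureDesign(tuple(mix))

    def sample(self, role: str) -> SampleSpec:
        return next(s for s in self.samples if s.role == role)


@dataclass
class LoadedRun:
    config: RunConfig
    dna1: CallSet
    dna2: CallSet
    dna1_depths: DepthTable | None
    dna2_depths: DepthTable | None
    mixtures: dict[str, CallSet]
    mixture_depths: dict[str, DepthTable]


def load_run(config: RunConfig) -> LoadedRun:
    """Read every manifest sample's VCF (and coverage table, when given)."""

    def load(spec: SampleSpec) -> tuple[CallSet, DepthTable | None]:
        callset = read_callset(spec.vcf, spec.sample_id, pass_only=config.pass_only)
        depths = read_depth_table(spec.depth_table) if spec.depth_table else None
        logger.info("loaded %s: %d SNV records", spec.sample_id, len(callset))
        return callset, depths

    dna1, dna1_depths = load(config.sample("dna1"))
    dna2, dna2_depths = load(config.sample("dna2"))
    mixtures: dict[str, CallSet] = {}
    mixture_depths: dict[str, DepthTable] = {}
    for spec in config.samples:
        if spec.role != "mixture":
            continue
        callset, depths = load(spec)
        mixtures[spec.sample_id] = callset
        if depths is not None:
            mixture_depths[spec.sample_id] = depths
    return LoadedRun(config=config, dna1=dna1, dna2=dna2, dna1_depths=dna1_depths,
                     dna2_depths=dna2_depths, mixtures=mixtures, mixture_depths=mixture_depths)


def run_evaluate(config: RunConfig) -> dict[str, Path]:
    """Execute the full evaluation and write the report bundle.

    Returns a mapping of artifact name to written path: trimmed pairs,
    per-condition detection tables, the sensitivity grid, detected-variant
    counts, the FP grid with medians, and run metadata.
    """
    run = load_run(config)
    design = config.design
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    selected = select_nh_pairs(
        run.dna1, run.dna2, run.dna1_depths, run.dna2_depths,
        dp_min=config.dp_min, strict=config.strict_depth,
    )
    trimmed = trim_pairs(selected, run.mixtures, run.mixture_depths, design,
                         dp_min=config.dp_min, strict=config.strict_depth)
    logger.info("pairs: %d selected, %d after trimming", len(selected), len(trimmed))
    outputs["trimmed_pairs"] = outdir / "trimmed_pairs.tsv"
    write_pairs_tsv(trimmed, design, outputs["trimmed_pairs"])

    conditions = [CutoffCondition(dp, vaf) for dp in config.dp_cuts for vaf in config.vaf_cuts]
    detection_frames = []
    for cond in conditions:
        frame = detection_table(trimmed, cond).to_frame()
        frame.insert(0, "vaf_cut", cond.vaf_cut)
        frame.insert(0, "dp_cut", cond.dp_cut)
        detection_frames.append(frame)
    outputs["detection_tables"] = outdir / "detection_tables.tsv"
    pd.concat(detection_frames, ignore_index=True).to_csv(
        outputs["detection_tables"], sep="\t", index=False
    )

    sens = sensitivity_grid(trimmed, conditions, target=config.probit_target,
                            max_fit_evaf=config.max_fit_evaf)
    outputs["sensitivity"] = outdir / "sensitivity.tsv"
    sens.to_csv(outputs["sensitivity"], sep="\t", index=False)

    counts = count_detected_variants(trimmed, conditions)
    outputs["detected_counts"] = outdir / "detected_counts.tsv"
    counts.to_csv(outputs["detected_counts"], sep="\t", index=False)

    table = fp_grid(run.mixtures, run.dna1, run.dna2, config.dp_cuts, config.vaf_cuts)
    outputs["fp_counts"] = outdir / "fp_counts.tsv"
    table.counts.to_csv(outputs["fp_counts"], sep="\t", index=False)
    outputs["fp_medians"] = outdir / "fp_medians.tsv"
    medians = table.class_medians().merge(table.total_medians(), on=["dp_cut", "vaf_cut"])
    medians.to_csv(outputs["fp_medians"], sep="\t", index=False)

    metadata = {
        "mixsense_version": __version__,
        "n_pairs_selected": len(selected),
        "n_pairs_trimmed": len(trimmed),
        "design": {sid: f1 for sid, f1 in design.samples},
        "dp_cuts": config.dp_cuts,
        "vaf_cuts": [float(v) for v in config.vaf_cuts],
        "dp_min": config.dp_min,
        "strict_depth": config.strict_depth,
        "pass_only": config.pass_only,
        "probit_target": config.probit_target,
        "max_fit_evaf": config.max_fit_evaf,
        "seed": config.seed,
        "conventions": {
            "null_max_vaf": 0.05,
            "hom_min_vaf": 0.95,
            "quartiles": "type 7 (linear interpolation)",
            "unknown_depth": "retained unless strict_depth",
        },
    }
    outputs["metadata"] = outdir / "run_metadata.json"
    outputs["metadata"].write_text(json.dumps(metadata, indent=2) + "\n")
    return outputs
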