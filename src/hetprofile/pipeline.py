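"""End-to-end orchestration of the profiling and assay stages.

``run_profile_pipeline`` executes simulate/load -> M values -> median
normalization -> 500-bp binning -> class assignment -> per-condition
profiles -> differential report (plus subtelomeric series and the
cross-condition TE correlation), writes every report under the output
directory, and records a run manifest (config snapshot, input
checksums, library versions, seed, stage timestamps). Reports are
deterministic given config and seed; the manifest is sufficient to
re-execute the run bit-identically on the same inputs.

``run_assay_pipeline`` does the same for the wet-lab computations:
standard curves and ChIP-qPCR enrichment per condition, ddCt
expression, and the beta-gal / pigment genotype-class fold changes.
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay_quant import (
    beta_gal_summary,
    chip_qpcr_enrichment,
    ddct_expression,
    fit_input_standard_curve,
    genotype_fold_changes,
    pigment_summary,
)
from .class_profiles import (
    class_mean_profile,
    cross_condition_correlation,
    differential_profile,
    recenter_on_background,
    subtelomere_profile,
)
from .errors import ConfigError, DataError, HetprofileError
from .genome_partition import assign_bins, load_annotation, subtelomeric_windows
from .io import (
    read_csv_table,
    read_probe_tsv,
    sha256_file,
    write_annotation,
    write_bin_track,
    write_json,
    write_probe_signal,
    write_tsv,
)
from .signal_enrichment import bin_track, compute_m_values, normalize_track
from .synthetic_data import (
    CONDITIONS,
    MUTANT,
    WILD_TYPE,
    SimConfig,
    build_genome_annotation,
    compute_sim_truth,
    simulate_expression_table,
    simulate_probe_signal,
    simulate_qpcr_plate,
    simulate_reporter_tables,
)

log = logging.getLogger("hetprofile")


@dataclass
class PipelineConfig:
    """One run's inputs and knobs; exactly one of (sim | real inputs)."""

    sim: SimConfig | None = None
    # real-input mode
    probe_tsv: dict[str, str] | None = None  # condition -> path
    arm_table: str | None = None
    te_bed: str | None = None
    cluster_bed: str | None = None
    qpcr_csv: dict[str, str] | None = None  # condition -> plate CSV
    expression_csv: str | None = None
    beta_gal_csv: str | None = None
    pigment_csv: str | None = None
    # knobs
    bin_width: int = 500
    subtelomere_window: int = 50_000
    m_floor: float = 0.1
    min_bins: int = 5
    include_nonunique: bool = False
    # "euchromatin" recenters bin means on annotated background after the
    # per-sample median step; "median" leaves the median-centered scale as is
    normalization: str = "euchromatin"
    outdir: str = "hetprofile_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        has_real = self.probe_tsv is not None or self.qpcr_csv is not None \
            or self.beta_gal_csv is not None or self.pigment_csv is not None \
            or self.expression_csv is not None
        if self.sim is not None and has_real:
            raise ConfigError("config must provide either a sim block or real inputs, not both")
        if self.sim is None and not has_real:
            raise ConfigError("config provides neither a sim block nor real inputs")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML config. A ``sim:`` mapping overrides scalar fields of
        the default :class:`SimConfig` (``null_run: true`` starts from the
        zero-signal configuration); richer simulated genomes are built
        through the library API."""
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: invalid YAML ({exc})") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        sim_block = raw.pop("sim", None)
        sim = None
        if sim_block is not None:
            from .synthetic_data import null_config

            if not isinstance(sim_block, dict):
                raise ConfigError(f"{path}: sim block must be a mapping")
            sim_block = dict(sim_block)
            base = null_config() if sim_block.pop("null_run", False) else SimConfig()
            for key, val in sim_block.items():
                if not hasattr(base, key):
                    raise ConfigError(f"{path}: unknown sim parameter {key!r}")
                setattr(base, key, val)
            sim = base
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update(overrides)
        cfg = cls(sim=sim, **raw)
        if cfg.sim is not None:
            cfg.sim.seed = cfg.seed
        return cfg


@dataclass
class ProfileRunResult:
    profiles: dict
    differential: Any
    correlation: Any
    subtelomere: dict
    truth: Any = None
    manifest_path: Path | None = None


@dataclass
class AssayRunResult:
    enrichment: dict = field(default_factory=dict)
    expression: Any = None
    genotype_summaries: dict = field(default_factory=dict)
    report: dict = field(default_factory=dict)
    manifest_path: Path | None = None


def _setup_logging(level: str) -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s [%(levelname)s] %(message)s",
    )


def _manifest_base(config: PipelineConfig) -> dict:
    def encode(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): encode(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [encode(v) for v in obj]
        return obj

    checksums = {}
    for attr in ("arm_table", "te_bed", "cluster_bed", "expression_csv",
                 "beta_gal_csv", "pigment_csv"):
        p = getattr(config, attr)
        if p:
            checksums[attr] = sha256_file(p)
    for attr in ("probe_tsv", "qpcr_csv"):
        mapping = getattr(config, attr)
        if mapping:
            for cond, p in mapping.items():
                checksums[f"{attr}:{cond}"] = sha256_file(p)
    return {
        "config": encode(config),
        "input_checksums": checksums,
        "versions": {
            "hetprofile": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "seed": config.seed,
        "stages": {},
    }


class _RunWriter:
    """Tracks written outputs so a failed run leaves no partial files."""

    def __init__(self, outdir: str | Path):
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.written: list[Path] = []

    def track(self, *paths: Path) -> None:
        self.written.extend(paths)

    def cleanup(self) -> None:
        for p in self.written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass


def run_profile_pipeline(config: PipelineConfig) -> ProfileRunResult:
    """Execute the full enrichment-profiling chain and write all reports."""
    _setup_logging(config.log_level)
    manifest = _manifest_base(config)
    writer = _RunWriter(config.outdir)
    out = Path(config.outdir)
    stage = "setup"
    try:
        t0 = time.time()
        if config.sim is not None:
            stage = "simulate"
            log.info("[%s] building synthetic annotation and signal", stage)
            annotation = build_genome_annotation(config.sim)
            probes = {c: simulate_probe_signal(annotation, config.sim, c) for c in CONDITIONS}
            truth = compute_sim_truth(annotation, config.sim, bin_width=config.bin_width)
            paths = write_annotation(annotation, out / "annotation")
            writer.track(*paths.values())
            for cond, df in probes.items():
                paths = write_probe_signal(df, out / "signal", cond)
                writer.track(*paths.values())
            write_json(truth.to_dict(), out / "sim_truth.json")
            writer.track(out / "sim_truth.json")
        else:
            stage = "load"
            if not (config.arm_table and config.probe_tsv):
                raise ConfigError("real-input profiling needs arm_table and probe_tsv")
            log.info("[%s] loading annotation and probe tables", stage)
            annotation = load_annotation(
                config.arm_table, te_bed=config.te_bed, cluster_bed=config.cluster_bed
            )
            probes = {cond: read_probe_tsv(p) for cond, p in config.probe_tsv.items()}
            truth = None
        manifest["stages"][stage] = time.time() - t0

        conditions = sorted(probes)
        profiles, bins_by_cond, membership_by_cond = {}, {}, {}
        for cond in conditions:
            stage = f"enrichment:{cond}"
            t0 = time.time()
            log.info("[%s] M values -> normalize -> bin", stage)
            track = normalize_track(compute_m_values(probes[cond]))
            bins = bin_track(track, config.bin_width, config.include_nonunique)
            membership = assign_bins(bins, annotation, config.subtelomere_window)
            if config.normalization == "euchromatin":
                bins = recenter_on_background(bins, membership)
            elif config.normalization != "median":
                raise ConfigError(f"unknown normalization {config.normalization!r}")
            profiles[cond] = class_mean_profile(bins, membership, cond)
            bins_by_cond[cond] = bins
            membership_by_cond[cond] = membership
            p = out / f"profile_{cond}.tsv"
            write_tsv(profiles[cond].table, p)
            paths = write_bin_track(bins, out / "bins", cond)
            writer.track(p, *paths.values())
            manifest["stages"][stage] = time.time() - t0

        stage = "differential"
        t0 = time.time()
        if len(conditions) < 2:
            raise ConfigError("differential output needs two conditions")
        wt = profiles.get(WILD_TYPE, profiles[conditions[0]])
        mut = profiles.get(MUTANT, profiles[conditions[-1]])
        diff = differential_profile(wt, mut, m_floor=config.m_floor, min_bins=config.min_bins)
        write_tsv(diff.table, out / "differential.tsv")
        write_json(
            {
                "te_direction_counts": list(diff.te_direction_counts),
                "cluster_direction_counts": list(diff.cluster_direction_counts),
                "m_floor": diff.m_floor,
                "min_bins": diff.min_bins,
            },
            out / "differential_counts.json",
        )
        writer.track(out / "differential.tsv", out / "differential_counts.json")
        manifest["stages"][stage] = time.time() - t0

        stage = "correlation"
        t0 = time.time()
        try:
            corr = cross_condition_correlation(wt, mut)
            write_json(
                {"r_squared": corr.r_squared, "n_families": corr.n_families},
                out / "correlation.json",
            )
            writer.track(out / "correlation.json")
        except DataError:
            corr = None
        manifest["stages"][stage] = time.time() - t0

        stage = "subtelomere"
        t0 = time.time()
        windows = subtelomeric_windows(annotation, config.subtelomere_window)
        orientation = {n: a.telomere_at_start for n, a in annotation.arms.items()}
        subtel = {
            cond: subtelomere_profile(bins_by_cond[cond], windows, orientation)
            for cond in conditions
        }
        for cond, prof in subtel.items():
            frames = [
                df.assign(arm=arm) for arm, df in prof.series.items() if not df.empty
            ]
            if frames:
                write_tsv(pd.concat(frames, ignore_index=True), out / f"subtelomere_{cond}.tsv")
                writer.track(out / f"subtelomere_{cond}.tsv")
        manifest["stages"][stage] = time.time() - t0

        manifest["finished"] = datetime.datetime.now().isoformat()
        write_json(manifest, out / "manifest.json")
        return ProfileRunResult(
            profiles=profiles,
            differential=diff,
            correlation=corr,
            subtelomere=subtel,
            truth=truth,
            manifest_path=out / "manifest.json",
        )
    except HetprofileError as exc:
        writer.cleanup()
        raise type(exc)(f"stage {stage!r}: {exc}") from exc


def run_assay_pipeline(config: PipelineConfig) -> AssayRunResult:
    """Execute the assay computations and write one combined JSON report."""
    _setup_logging(config.log_level)
    manifest = _manifest_base(config)
    writer = _RunWriter(config.outdir)
    out = Path(config.outdir)
    result = AssayRunResult()
    report: dict = {}
    stage = "setup"
    try:
        # qPCR enrichment
        plates: dict[str, pd.DataFrame] = {}
        control_locus = None
        if config.sim is not None:
            stage = "simulate_qpcr"
            plates = {c: simulate_qpcr_plate(config.sim, c) for c in CONDITIONS}
            control_locus = config.sim.qpcr_control_locus
        elif config.qpcr_csv:
            stage = "load_qpcr"
            plates = {
                cond: read_csv_table(
                    p, {"locus", "role", "dilution_fraction", "ct", "replicate"}
                )
                for cond, p in config.qpcr_csv.items()
            }
            control_locus = "alpha_actinin"
        if plates:
            stage = "qpcr"
            report["qpcr"] = {}
            for cond, plate in plates.items():
                curves = {
                    locus: fit_input_standard_curve(plate, locus=locus)
                    for locus in sorted(plate["locus"].unique())
                }
                if control_locus not in curves:
                    raise DataError(f"plate {cond!r}: control locus {control_locus!r} missing")
                per_locus = {}
                for locus, curve in curves.items():
                    res = chip_qpcr_enrichment(plate, curve, curves[control_locus], plate)
                    per_locus[locus] = {
                        "relative_enrichment": res.relative_enrichment,
                        "enrichment_sem": res.enrichment_sem,
                        "pulldown_efficacy": res.pulldown_efficacy,
                        "slope": curve.slope,
                        "amplification_base": curve.base,
                        "r_squared": curve.r_squared,
                        "out_of_range": res.out_of_range,
                    }
                report["qpcr"][cond] = per_locus
                result.enrichment[cond] = per_locus

        # ddCt expression
        expr_table = None
        if config.sim is not None:
            stage = "simulate_expression"
            expr_table = simulate_expression_table(config.sim)
            target = config.sim.expression_target_locus
            control = config.sim.expression_control_locus
            reference = config.sim.expression_reference
        elif config.expression_csv:
            stage = "load_expression"
            expr_table = read_csv_table(config.expression_csv, {"sample", "locus", "ct", "replicate"})
            target, control, reference = "piwi", "RPL32", "control"
        if expr_table is not None:
            stage = "expression"
            expr = ddct_expression(expr_table, target, control, reference)
            result.expression = expr
            report["expression"] = expr.table.to_dict(orient="records")

        # reporter assays
        bg_table = pg_table = None
        control_class = "C"
        if config.sim is not None:
            stage = "simulate_reporters"
            tables = simulate_reporter_tables(config.sim)
            bg_table, pg_table = tables.beta_gal, tables.pigment
            control_class = config.sim.assay_control_class
        else:
            if config.beta_gal_csv:
                bg_table = read_csv_table(
                    config.beta_gal_csv, {"genotype_class", "replicate", "time_min", "od574"}
                )
            if config.pigment_csv:
                pg_table = read_csv_table(config.pigment_csv, {"genotype_class", "od480"})
        if bg_table is not None:
            stage = "beta_gal"
            summary = genotype_fold_changes(beta_gal_summary(bg_table), control_class)
            result.genotype_summaries["beta_gal"] = summary
            report["beta_gal"] = summary.table.to_dict(orient="records")
        if pg_table is not None:
            stage = "pigment"
            summary = genotype_fold_changes(pigment_summary(pg_table), control_class)
            result.genotype_summaries["pigment"] = summary
            report["pigment"] = summary.table.to_dict(orient="records")

        manifest["finished"] = datetime.datetime.now().isoformat()
        write_json(report, out / "assay_report.json")
        write_json(manifest, out / "assay_manifest.json")
        result.report = report
        result.manifest_path = out / "assay_manifest.json"
        return result
    except HetprofileError as exc:
        writer.cleanup()
        raise type(exc)(f"stage {stage!r}: {exc}") from exc
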