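"""End-to-end orchestration: config file in, fixed-dialect TSVs out.

``run_pipeline`` sequences the stages in analysis order (clean → impute →
normalize → filter → test → adjust → classify for AP-MS; load → subtract →
aggregate → compare for ChIP), writes every output atomically, and records a
manifest (config hash, seed, version, row counts) so a run can be reproduced
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import tempfile
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chip import (
    ProfileConfig,
    aggregate_profile,
    compare_occupancy,
    load_signal,
    normalize_subtract_input,
    read_annotations,
    read_chrom_sizes,
)
from .errors import PoldiffError, ValidationError
from .io import (
    clean_protein_table,
    read_run_design,
    read_spectral_counts,
    write_run_design,
    write_spectral_counts,
)
from .scoring import ScoringConfig, analyze_variant, build_display_matrix
from .simulate import (
    LEUKODYSTROPHY,
    TCS,
    ChipGenomeSpec,
    ChipOccupancySpec,
    ChipReadSpec,
    ComplexModel,
    Scenario,
    simulate_apms_dataset,
    simulate_chip_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger("poldiff")

_SCENARIOS = {"leukodystrophy": LEUKODYSTROPHY, "tcs": TCS}
_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    out_dir: Path = Path("poldiff_out")
    seed: int = 0
    log_level: str = "INFO"
    # AP-MS inputs (may be produced by mode=simulate)
    counts_path: Path | None = None
    design_path: Path | None = None
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    # ChIP inputs
    chip_wt_path: Path | None = None
    chip_mut_path: Path | None = None
    input_path: Path | None = None
    annotations_path: Path | None = None
    chrom_sizes_path: Path | None = None
    bin_width: int = 10
    scale_per_million: bool = True
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    # simulation parameters
    scenario: str = "leukodystrophy"
    n_replicates: int = 3
    chip_occupancy: ChipOccupancySpec = field(default_factory=ChipOccupancySpec)
    chip_genome: ChipGenomeSpec = field(default_factory=ChipGenomeSpec)
    chip_reads: ChipReadSpec = field(default_factory=ChipReadSpec)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        kwargs: dict = {}
        for key in ("out_dir", "seed", "log_level", "scenario", "n_replicates",
                    "bin_width", "scale_per_million"):
            if key in raw:
                kwargs[key] = raw[key]
        apms = raw.get("apms", {})
        if "counts" in apms:
            kwargs["counts_path"] = Path(apms["counts"])
        if "design" in apms:
            kwargs["design_path"] = Path(apms["design"])
        if "scoring" in apms:
            kwargs["scoring"] = ScoringConfig(**apms["scoring"])
        chip = raw.get("chip", {})
        for yaml_key, attr in (
            ("chip_wt", "chip_wt_path"),
            ("chip_mut", "chip_mut_path"),
            ("input", "input_path"),
            ("annotations", "annotations_path"),
            ("chrom_sizes", "chrom_sizes_path"),
        ):
            if yaml_key in chip:
                kwargs[attr] = Path(chip[yaml_key])
        if "profile" in chip:
            kwargs["profile"] = ProfileConfig(**chip["profile"])
        cfg = cls(**kwargs)
        cfg.out_dir = Path(cfg.out_dir)
        return cfg

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (where outputs land and
        how verbosely we log do not change what is computed)."""
        payload = asdict(self)
        payload.pop("out_dir", None)
        payload.pop("log_level", None)
        text = json.dumps(payload, default=str, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _atomic_write_df(df: pd.DataFrame, path: Path, **to_csv_kwargs) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp_", suffix=".tsv")
    try:
        with os.fdopen(fd, "w") as fh:
            df.to_csv(fh, sep="\t", index=False, **to_csv_kwargs)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _stage(name: str):
    """Decorator: prefix any pipeline error with the failing stage's name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except FileNotFoundError as exc:
                raise PoldiffError(f"[{name}] missing input file: {exc}") from exc
            except PoldiffError as exc:
                raise PoldiffError(f"[{name}] {exc}") from exc

        return inner

    return wrap


@_stage("simulate")
def _run_simulate(config: PipelineConfig, manifest: dict) -> PipelineConfig:
    sim_dir = config.out_dir / "sim"
    sim_dir.mkdir(parents=True, exist_ok=True)
    scenario = _SCENARIOS.get(config.scenario)
    if scenario is None:
        raise ValidationError(
            f"unknown scenario {config.scenario!r}; choose from {sorted(_SCENARIOS)}"
        )
    table, design = simulate_apms_dataset(
        ComplexModel(), scenario, n_replicates=config.n_replicates, seed=config.seed
    )
    counts_path = sim_dir / "counts.tsv"
    design_path = sim_dir / "design.tsv"
    write_spectral_counts(table, counts_path)
    write_run_design(design, design_path)
    chip = simulate_chip_dataset(
        config.chip_occupancy,
        config.chip_genome,
        config.chip_reads,
        seed=config.seed + 1,
        out_dir=sim_dir / "chip",
    )
    manifest["rows"]["sim/counts.tsv"] = len(table.data)
    manifest["rows"]["sim/design.tsv"] = len(design.data)
    logger.info("simulated AP-MS (%d count rows) and ChIP read sets", len(table.data))
    return replace(
        config,
        counts_path=counts_path,
        design_path=design_path,
        chip_wt_path=chip.chip_wt,
        chip_mut_path=chip.chip_mut,
        input_path=chip.input,
        annotations_path=chip.annotations_path,
        chrom_sizes_path=chip.chrom_sizes_path,
    )


@_stage("apms")
def _run_apms(config: PipelineConfig, manifest: dict) -> None:
    if config.counts_path is None or config.design_path is None:
        raise ValidationError("apms mode needs counts and design paths")
    raw = read_spectral_counts(config.counts_path, kind="raw")
    design = read_run_design(config.design_path)
    raw = clean_protein_table(raw)
    rng = np.random.default_rng(config.seed)
    all_rows = []
    results_by_variant = {}
    for variant in design.variants:
        summaries, results = analyze_variant(
            raw, design, variant, config.scoring, rng=rng
        )
        results_by_variant[variant] = results
        n_pairs = len(design.pairs(variant))
        for res in results:
            row = {"variant": variant, "protein_id": res.protein_id, "basis": res.basis}
            for i in range(n_pairs):
                row[f"ratio_{i + 1}"] = res.ratios[i]
            row.update(
                mean_ratio=res.mean_ratio,
                log2_mean_ratio=res.log2_mean_ratio,
                t=res.t_statistic,
                df=res.degrees_of_freedom,
                p_raw=res.p_raw,
                p_adjusted=res.p_adjusted,
                label=res.label,
            )
            all_rows.append(row)
        logger.info(
            "variant %s: %d high-confidence interactors, %d differential",
            variant,
            len(results),
            sum(r.label in ("decreased", "increased") for r in results),
        )
    out = config.out_dir
    res_df = pd.DataFrame(all_rows)
    _atomic_write_df(res_df, out / "differential_results.tsv", float_format=_FLOAT_FMT)
    heatmap, volcano = build_display_matrix(results_by_variant, config.scoring)
    _atomic_write_df(
        heatmap.reset_index(), out / "heatmap_matrix.tsv", float_format=_FLOAT_FMT
    )
    for variant in design.variants:
        sub = volcano[volcano["variant"] == variant]
        _atomic_write_df(
            sub, out / f"volcano_{variant}.tsv", float_format=_FLOAT_FMT
        )
        manifest["rows"][f"volcano_{variant}.tsv"] = len(sub)
    manifest["rows"]["differential_results.tsv"] = len(res_df)
    manifest["rows"]["heatmap_matrix.tsv"] = len(heatmap)


@_stage("chip")
def _run_chip(config: PipelineConfig, manifest: dict) -> None:
    needed = {
        "chip_wt": config.chip_wt_path,
        "chip_mut": config.chip_mut_path,
        "input": config.input_path,
        "annotations": config.annotations_path,
        "chrom_sizes": config.chrom_sizes_path,
    }
    missing = [k for k, v in needed.items() if v is None]
    if missing:
        raise ValidationError(f"chip mode needs paths for {missing}")
    sizes = read_chrom_sizes(config.chrom_sizes_path)
    annotations = read_annotations(config.annotations_path)
    input_sig = load_signal(config.input_path, config.bin_width, sizes)
    tracks = {}
    for cond, path in (("WT", config.chip_wt_path), ("MUT", config.chip_mut_path)):
        chip_sig = load_signal(path, config.bin_width, sizes)
        tracks[cond] = normalize_subtract_input(
            chip_sig, input_sig, scale_per_million=config.scale_per_million
        )
    classes = sorted({g.gene_class for g in annotations})
    out = config.out_dir
    comparison_rows = []
    for cls in classes:
        profiles = {}
        for cond in ("WT", "MUT"):
            prof = aggregate_profile(tracks[cond], annotations, cls, config.profile)
            profiles[cond] = prof
            df = pd.DataFrame(
                {
                    "window_index": np.arange(prof.config.n_windows),
                    "offset_bp": prof.offsets_bp(),
                    "mean_signal": prof.values,
                }
            )
            _atomic_write_df(
                df, out / f"profile_{cls}_{cond}.tsv", float_format=_FLOAT_FMT
            )
        comp = compare_occupancy(profiles["WT"], profiles["MUT"])
        comparison_rows.append(
            {
                "gene_class": cls,
                "n_genes": profiles["WT"].n_genes,
                "mean_wt": comp.mean_a,
                "mean_mut": comp.mean_b,
                "ratio_mut_wt": comp.ratio,
                "log2_ratio": comp.log2_ratio,
                "degenerate": comp.degenerate,
            }
        )
        logger.info("class %s: log2 MUT/WT occupancy = %.3f", cls, comp.log2_ratio)
    comp_df = pd.DataFrame(comparison_rows)
    _atomic_write_df(comp_df, out / "occupancy_comparison.tsv", float_format=_FLOAT_FMT)
    manifest["rows"]["occupancy_comparison.tsv"] = len(comp_df)


def run_pipeline(config: PipelineConfig, mode: str = "all") -> dict:
    """Run the requested stages; returns the manifest written to out_dir.

    Modes: ``simulate`` (write synthetic inputs), ``apms``, ``chip``, or
    ``all`` (simulate, then both analyses on the simulated inputs).
    Identical config + seed reproduce every output byte-for-byte.
    """
    if mode not in ("simulate", "apms", "chip", "all"):
        raise ValidationError(f"unknown mode {mode!r}")
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": mode,
        "version": __version__,
        "rows": {},
    }
    if mode in ("simulate", "all"):
        config = _run_simulate(config, manifest)
    if mode in ("apms", "all"):
        _run_apms(config, manifest)
    if mode in ("chip", "all"):
        _run_chip(config, manifest)
    manifest_path = config.out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
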