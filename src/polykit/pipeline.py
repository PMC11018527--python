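"""End-to-end orchestration: config in, per-stage outputs plus report out.

Stages run in dependency order (synteny -> hedetect -> popstats ->
exprbias).  Defaults mirror the published analysis parameters: 10-gene
HE windows with +/-1.5 and +/-0.5 balance thresholds, 100-kb/10-kb
diversity windows, 2-kb F_ST flanks, 20-kb scan windows, Bonferroni
alpha 0.0005 and a 21-year generation time.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, exprbias, hedetect, io, popstats, syntenyfrac
from .util import sha256_file


class PipelineError(RuntimeError):
    """A stage failed; message names the stage and the cause."""


@dataclass
class RunConfig:
    out_dir: str = "polykit_out"
    # inputs
    syntelogs: str | None = None
    coverage: dict = field(default_factory=dict)  # accession -> TSV path
    vcf: str | None = None
    popmap: str | None = None
    expression: str | None = None
    segments: str | None = None  # precomputed HE segments (optional)
    # stage toggles
    run_synteny: bool = True
    run_hedetect: bool = True
    run_popstats: bool = True
    run_exprbias: bool = True
    # parameters
    retention_window_genes: int = 100
    he_window_genes: int = 10
    he_min_windows: int = 5
    he_alpha: float = 0.0005
    pi_window_bp: int = 100_000
    pi_step_bp: int = 10_000
    tajima_window_bp: int = 100_000
    fst_flank_bp: int = 2000
    scan_window_bp: int = 20_000
    fold_threshold: float = 2.0
    generation_time_years: float = 21.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_inputs(config: RunConfig) -> list[str]:
    """Collect (not raise) input problems: missing files, schema and
    sample-name mismatches."""
    errors: list[str] = []
    paths = {"syntelogs": config.syntelogs, "vcf": config.vcf,
             "popmap": config.popmap, "expression": config.expression,
             "segments": config.segments}
    paths.update({f"coverage[{acc}]": p for acc, p in config.coverage.items()})
    for name, p in paths.items():
        if p is not None and not Path(p).exists():
            errors.append(f"{name}: file not found: {p}")
    if errors:
        return errors

    if config.syntelogs:
        df = io.read_syntelogs(config.syntelogs)
        missing = {"pair_id", "status", "chrom", "ancestral_index"} - set(df.columns)
        if missing:
            errors.append(f"syntelogs: missing columns {sorted(missing)}")
    for acc, p in config.coverage.items():
        df = io.read_tsv(p)
        missing = {"pair_id", "chrom", "ancestral_index", "cc_depth", "ee_depth"} - set(df.columns)
        if missing:
            errors.append(f"coverage[{acc}]: missing columns {sorted(missing)}")
    if config.vcf and config.popmap:
        g = io.read_vcf(config.vcf)
        popmap = io.read_popmap(config.popmap)
        for sample in popmap.labels:
            if sample not in g.samples:
                errors.append(f"popmap: sample {sample!r} not in VCF")
    if config.expression:
        df = io.read_tsv(config.expression)
        if "gene" not in df.columns:
            errors.append("expression: missing 'gene' column")
    return errors


def run_all(config: RunConfig) -> dict:
    """Execute enabled stages; returns the report (also written as JSON)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    problems = validate_inputs(config)
    if problems:
        raise PipelineError("input validation failed: " + "; ".join(problems))

    report: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in vars(config).items() if not isinstance(v, dict)},
        "inputs": _checksums(_input_paths(config)),
        "stages": {},
        "outputs": {},
    }
    segments = None
    syntelogs = io.read_syntelogs(config.syntelogs) if config.syntelogs else None

    if config.run_synteny:
        _timed(report, "synteny", lambda: _stage_synteny(config, syntelogs, out_dir, report))
    if config.run_hedetect:
        segments = _timed(
            report, "hedetect", lambda: _stage_hedetect(config, syntelogs, out_dir, report)
        )
    if config.run_popstats:
        _timed(report, "popstats", lambda: _stage_popstats(config, out_dir, report))
    if config.run_exprbias:
        _timed(
            report, "exprbias",
            lambda: _stage_exprbias(config, syntelogs, segments, out_dir, report),
        )

    report_path = out_dir / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report


def _timed(report, name, fn):
    start = time.monotonic()
    try:
        result = fn()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    report["stages"][name] = {"seconds": round(time.monotonic() - start, 3)}
    return result


def _stage_synteny(config, syntelogs, out_dir, report):
    if syntelogs is None:
        raise PipelineError("stage 'synteny' requires a syntelogs table")
    for side in ("cc", "ee"):
        track = syntenyfrac.retention_rate_track(
            syntelogs, side, window_genes=config.retention_window_genes
        )
        _emit(report, out_dir, f"retention_{side}.tsv", track)
    spectrum = syntenyfrac.deletion_run_spectrum(syntelogs)
    rows = [
        {"side": side, "run_length": k, "count": v}
        for side, hist in spectrum.items()
        for k, v in sorted(hist.items())
    ]
    _emit(report, out_dir, "deletion_runs.tsv",
          pd.DataFrame(rows, columns=["side", "run_length", "count"]))
    _emit(report, out_dir, "gap_profile.tsv", syntenyfrac.intergenic_gap_profile(syntelogs))


def _stage_hedetect(config, syntelogs, out_dir, report):
    if not config.coverage:
        raise PipelineError("stage 'hedetect' requires coverage tables")
    profiles = {acc: io.read_tsv(p) for acc, p in config.coverage.items()}
    all_segments = []
    for acc, profile in profiles.items():
        track = hedetect.windowed_balance(profile, window_genes=config.he_window_genes)
        all_segments.append(
            hedetect.segment_dosage(track, min_windows=config.he_min_windows, accession=acc, profile=profile)
        )
    segments = pd.concat(all_segments, ignore_index=True)
    _emit(report, out_dir, "segments.tsv", segments)
    tests = hedetect.test_segments(segments, profiles, alpha=config.he_alpha)
    _emit(report, out_dir, "he_tests.tsv", tests)
    if syntelogs is not None:
        bed = _segments_bed(segments, syntelogs)
        path = out_dir / "segments.bed"
        io.write_bed(bed, path)
        report["outputs"]["segments.bed"] = sha256_file(path)
    return segments


def _stage_popstats(config, out_dir, report):
    if not (config.vcf and config.popmap):
        raise PipelineError("stage 'popstats' requires a VCF and a population map")
    g = io.read_vcf(config.vcf)
    popmap = io.read_popmap(config.popmap)
    for label in ("wild", "cultivar"):
        samples = popmap.samples_with(label)
        if len(samples) < 2:
            continue
        pi_df, pi_mean = popstats.windowed_pi(
            g, samples, window_bp=config.pi_window_bp, step_bp=config.pi_step_bp
        )
        _emit(report, out_dir, f"pi_{label}.tsv", pi_df)
        td_df, td_mean = popstats.windowed_tajima_d(
            g, samples, window_bp=config.tajima_window_bp
        )
        _emit(report, out_dir, f"tajima_d_{label}.tsv", td_df)
        report["stages"].setdefault("popstats_means", {})[label] = {
            "pi": pi_mean, "tajima_d": td_mean
        }


def _stage_exprbias(config, syntelogs, segments, out_dir, report):
    if config.expression is None:
        raise PipelineError("stage 'exprbias' requires an expression table")
    if syntelogs is None:
        raise PipelineError("stage 'exprbias' requires a syntelogs table")
    if segments is None:
        if config.segments is None:
            raise PipelineError(
                "stage 'exprbias' requires HE segments: enable the hedetect "
                "stage or provide a precomputed segments table"
            )
        segments = io.read_tsv(config.segments)
    expr = io.read_tsv(config.expression)
    pairs, removal_log = hedetect.filter_he_pairs(syntelogs, segments)
    _emit(report, out_dir, "he_removed_pairs.tsv", removal_log)
    bias = exprbias.pair_bias(expr, pairs, fold_threshold=config.fold_threshold)
    _emit(report, out_dir, "pair_bias.tsv", bias)
    n_cc, n_ee, p = exprbias.global_dominance_test(bias)
    report["stages"]["exprbias_global"] = {"n_cc": n_cc, "n_ee": n_ee, "p_value": p}
    if (bias["family"] != "").any():
        _emit(report, out_dir, "family_mosaic.tsv", exprbias.family_mosaic_summary(bias))


def _segments_bed(segments, syntelogs):
    rows = []
    for _, seg in segments.iterrows():
        sub = syntelogs[
            (syntelogs["chrom"] == seg["chrom"])
            & (syntelogs["ancestral_index"] >= seg["start_gene"])
            & (syntelogs["ancestral_index"] < seg["end_gene"])
        ]
        if sub.empty:
            continue
        rows.append(
            {
                "chrom": seg["chrom"],
                "start": int(sub["cc_start"].min()) - 1,
                "end": int(sub["cc_end"].max()),
                "name": f"{seg['accession']}:{seg['dosage_class']}",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def _emit(report, out_dir, name, df):
    path = out_dir / name
    io.write_tsv(df, path)
    report["outputs"][name] = sha256_file(path)


def _input_paths(config) -> list[Path]:
    paths = [config.syntelogs, config.vcf, config.popmap, config.expression, config.segments]
    paths.extend(config.coverage.values())
    return [Path(p) for p in paths if p is not None]


def _checksums(paths) -> dict[str, str]:
    return {str(p): sha256_file(p) for p in paths}
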