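"""End-to-end run: locate -> cut -> call -> profile -> consequence ->
knockdown, with a reproducible report bundle.

Outputs are deterministic functions of the inputs and configuration: the
run log records every effective parameter (defaults included) plus a
configuration hash, and contains no timestamps, so re-running the same
configuration yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import io
from .consequence import cohort_consequences
from .errors import ConfigError
from .indelcall import ScoringScheme, call_cohort, summarize_cohort
from .knockdown import ddct_fold, densitometry_ratio, group_stats
from .profile import positional_profile, skew_statistic, window_fraction
from .refmodel import GuideRNA, locate_protospacer, parse_cloning_oligo, predict_cut_site


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a pipeline run; path fields are checked at run time."""

    ref_fasta: str
    clones_fasta: str
    guide: str | None = None            # raw protospacer, or use oligos
    oligo_top: str | None = None
    oligo_bottom: str | None = None
    guide_name: str = "guide"
    features_tsv: str | None = None
    ct_csv: str | None = None
    densitometry_csv: str | None = None
    pam: str = "NGG"
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    flank: int = 15
    offset_convention: str = "break-centric"
    large_threshold: int = 20
    control_group: str = "control"
    seed: int = 0
    outdir: str = "nhejscope_out"

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(self.match, self.mismatch, self.gap_open, self.gap_extend)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path, **overrides: Any) -> RunConfig:
    """Flat key-value YAML config; keyword overrides win over the file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)


def _resolve_guide(config: RunConfig) -> GuideRNA:
    if config.guide:
        return GuideRNA(config.guide_name, config.guide.upper(), source="raw")
    if config.oligo_top and config.oligo_bottom:
        return parse_cloning_oligo(
            config.oligo_top.upper(), config.oligo_bottom.upper(),
            name=config.guide_name,
        )
    raise ConfigError("provide either a raw guide or an oligo top/bottom pair")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write the report bundle into ``outdir``.

    Returns the in-memory report dict. Any stage error is re-raised wrapped
    with the stage name so failures are attributable.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise ConfigError(f"pipeline stage {name!r} failed: {exc}") from exc

    for attr in ("ref_fasta", "clones_fasta"):
        p = getattr(config, attr)
        if not Path(p).exists():
            raise ConfigError(f"{attr} path does not exist: {p}")

    ref = stage("load-reference", io.read_reference, config.ref_fasta, config.features_tsv)
    guide = stage("resolve-guide", _resolve_guide, config)
    match = stage("locate", locate_protospacer, guide, ref, config.pam)
    cut = predict_cut_site(match)

    clones = stage("load-clones", io.read_clones, config.clones_fasta)
    records = stage("call", call_cohort, ref, clones, config.scoring())
    summary = summarize_cohort(records)

    prof = stage(
        "profile", positional_profile, records, cut, config.flank,
        config.offset_convention,
    )
    windows = {
        "down_1_3": window_fraction(records, cut, (-1, -3)),
        "up_1_3": window_fraction(records, cut, (1, 3)),
    }
    skew = skew_statistic(records, cut, config.flank, config.large_threshold)

    cons_df, cons_fractions = stage("consequence", cohort_consequences, records, ref)

    report: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "guide": {
            "name": guide.name,
            "protospacer": guide.protospacer,
            "source": guide.source,
        },
        "match": {
            "target_interval": list(match.target_interval),
            "strand": match.strand,
            "pam_seq": match.pam_seq,
        },
        "cut_interbase": cut.interbase,
        "cohort": {
            "n_clones": summary.n_clones,
            "class_counts": summary.class_counts,
            "min_deletion": summary.min_deletion,
            "max_deletion": summary.max_deletion,
        },
        "windows": {
            k: {"window": list(w.window), "fraction": w.fraction,
                "n_touching": w.n_touching}
            for k, w in windows.items()
        },
        "skew": dataclasses.asdict(skew),
        "consequence_fractions": cons_fractions,
    }

    if config.ct_csv:
        table = stage("knockdown-load", io.read_ct_csv, config.ct_csv)
        folds = stage("knockdown", ddct_fold, table, config.control_group)
        gs = group_stats(
            [f.replicate_folds for f in folds], [f.group for f in folds]
        )
        report["knockdown"] = {
            "per_group": [dataclasses.asdict(f) for f in folds],
            "anova": dataclasses.asdict(gs.anova),
            "tukey": [dataclasses.asdict(t) for t in gs.tukey],
        }
    if config.densitometry_csv:
        dt = stage("densitometry-load", io.read_densitometry_csv, config.densitometry_csv)
        ratios, gs = stage("densitometry", densitometry_ratio, dt, config.control_group)
        report["densitometry"] = {
            "group_means": ratios.groupby("group")["normalized"].mean().to_dict(),
            "anova": dataclasses.asdict(gs.anova) if gs else None,
            "tukey": [dataclasses.asdict(t) for t in gs.tukey] if gs else None,
        }

    io.write_calls_tsv(outdir / "calls.tsv", records, cons_df)
    io.write_profile_tsv(outdir / "profile.tsv", prof)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log_lines = [f"nhejscope run  config_hash={config.config_hash()}"]
    for f in dataclasses.fields(RunConfig):
        log_lines.append(f"{f.name} = {getattr(config, f.name)!r}")
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return report
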