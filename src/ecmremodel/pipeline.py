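"""End-to-end orchestration: stacks in, scores / stats / phenotype calls out.

A :class:`RunConfig` fully determines a run: either a simulation preset
(with field count and seed) or input TIFF paths plus a channel map, the
thresholds on the 0-225 scale, segmentation parameters, the neutral margin,
and the statistics alphas.  Given the same config and seed the pipeline is
deterministic and its CSV outputs byte-identical; every output embeds a
hash of the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import scoring, stats
from .errors import ConfigError
from .layers import detect_layers, max_projection
from .scoring import (
    DEFAULT_NEUTRAL_MARGIN,
    classify_phenotype,
    score_stack,
    segment_cell_region,
)
from .simulate import SimulationParams, preset, simulate_matrix_stack
from .stacks import read_stack, rescale_to_225

log = logging.getLogger("ecmremodel")


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    # input: either a simulation preset ...
    preset: str | None = "null"
    n_fields: int = 5
    # ... or real stacks
    inputs: tuple[str, ...] = ()
    channel_map: dict | None = None
    condition: str = "untreated"
    # scale & thresholds (0-225 scale)
    rescale_mode: str = "fixed-range"
    rescale_lo: float = 0.0
    rescale_hi: float = 225.0
    positive_threshold: float = 90.0
    high_lo: float = 90.0
    high_hi: float = 225.0
    top_coverage: float = 0.20
    full_coverage: float = 0.995
    # segmentation
    min_blob_area: int = 30
    dilation_radius_um: float = 5.0
    buffer_um: float = 10.0
    # classification & statistics
    neutral_margin: float = DEFAULT_NEUTRAL_MARGIN
    alpha_significant: float = 0.01
    alpha_fdr: float = 0.05
    # reproducibility
    seed: int = 0
    out_dir: str = "ecmremodel_run"
    sim_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        for key in ("inputs",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)


def _field_stacks(config: RunConfig):
    """Yield (field_id, ScaledStack) pairs for every field of the run."""
    if config.inputs:
        for i, path in enumerate(config.inputs):
            raw = read_stack(path, config.channel_map)
            yield f"field_{i}", rescale_to_225(
                raw, config.rescale_mode, lo=config.rescale_lo, hi=config.rescale_hi
            )
    else:
        if config.preset is None:
            raise ConfigError("config needs either inputs or a simulation preset")
        for i in range(config.n_fields):
            params = preset(
                config.preset, seed=config.seed + i, **config.sim_overrides
            )
            stack, _ = simulate_matrix_stack(params)
            yield f"field_{i}", rescale_to_225(
                stack, config.rescale_mode, lo=config.rescale_lo, hi=config.rescale_hi
            )


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate/load -> layer -> segment -> score -> classify -> stats.

    Returns a bundle dict with the scores DataFrame, phenotype calls, the
    per-field layer partitions, and (when several conditions were scored
    previously) hooks for the stats stage; also writes ``scores.csv``,
    ``phenotypes.json`` and ``run.json`` under ``config.out_dir``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    rows = []
    calls = {}
    partitions = {}
    for field_id, scaled in _field_stacks(config):
        part = detect_layers(
            scaled,
            positive_threshold=config.positive_threshold,
            top_coverage=config.top_coverage,
            full_coverage=config.full_coverage,
        )
        region = segment_cell_region(
            max_projection(scaled, "nuclei"),
            pixel_size_um=scaled.pixel_size_um,
            min_blob_area=config.min_blob_area,
            dilation_radius_um=config.dilation_radius_um,
            buffer_um=config.buffer_um,
        )
        scores = score_stack(
            scaled, part, region, high_range=(config.high_lo, config.high_hi)
        )
        call = classify_phenotype(scores, config.neutral_margin)
        calls[field_id] = call
        partitions[field_id] = part
        log.info(
            "%s: span=%s bottom_fallback=%s cell_px=%d devoid_px=%d call=%s",
            field_id, part.span, part.bottom_fallback,
            int(region.cell_mask.sum()), int(region.devoid_mask.sum()), call.label,
        )
        for s in scores:
            rows.append(
                {
                    "field": field_id,
                    "condition": config.condition,
                    "layer": s.layer,
                    "channel": s.channel,
                    "ratio_cell": s.ratio_cell,
                    "ratio_devoid": s.ratio_devoid,
                    "score_percent": s.score_percent,
                    "n_high_cell": s.n_high_cell,
                    "n_low_cell": s.n_low_cell,
                    "n_high_devoid": s.n_high_devoid,
                    "n_low_devoid": s.n_low_devoid,
                    "smoothing_applied": s.smoothing_applied,
                    "phenotype_call": call.label,
                }
            )

    scores_df = pd.DataFrame(rows)
    _write_csv(scores_df, out_dir / "scores.csv", chash)
    with open(out_dir / "phenotypes.json", "w") as fh:
        json.dump(
            {
                "config_hash": chash,
                "seed": config.seed,
                "calls": {
                    k: {"label": c.label, "top_score": c.top_score, "margin": c.margin}
                    for k, c in calls.items()
                },
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    with open(out_dir / "run.json", "w") as fh:
        json.dump(
            {"config": dataclasses.asdict(config), "config_hash": chash},
            fh, indent=2, sort_keys=True, default=str,
        )
    return {
        "scores": scores_df,
        "calls": calls,
        "partitions": partitions,
        "config": config,
        "config_hash": chash,
        "out_dir": out_dir,
    }


def stats_from_scores(
    scores_df: pd.DataFrame,
    control: str = "untreated",
    alpha_sig: float = 0.01,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """ANOVA + BH over a tidy scores table with a ``condition`` column.

    Replicates are per-field scores averaged over matrix channels within a
    (field, condition, layer) cell.
    """
    per_field = (
        scores_df.groupby(["condition", "layer", "field"])["score_percent"]
        .mean()
        .reset_index()
    )
    groups = [
        stats.ConditionGroup(cond, layer, tuple(sub["score_percent"]))
        for (cond, layer), sub in per_field.groupby(["condition", "layer"])
    ]
    results = stats.compare_conditions(
        groups, control=control, alpha_sig=alpha_sig, alpha_fdr=alpha_fdr
    )
    return stats.results_table(results)


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def read_scores_csv(path) -> pd.DataFrame:
    """Read a scores/stats CSV written by this pipeline (hash comment line)."""
    return pd.read_csv(path, comment="#")
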