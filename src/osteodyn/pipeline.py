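"""End-to-end experiment driver: simulate → segment → track → indices → stats.

Runs a battery of named conditions (n movies each), computes per-cell
deformation indices and per-movie bone-resorbing indices, summarizes each
group as mean ± SD, and tests every condition against the untreated
reference with a two-tailed t test. All randomness derives from one base
seed, so a run is exactly reproducible; a manifest records the materialized
config, the seed and a checksum for every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import deformation as deform_mod
from . import resorption as resorb_mod
from . import stats as stats_mod
from .segment import SegmentationParams, segment_stack, track_cells
from .simulate import CONDITIONS, make_condition_config, simulate_timelapse

logger = logging.getLogger("osteodyn")

__all__ = ["RunConfig", "run_experiment", "movie_seed"]


@dataclass
class RunConfig:
    """Everything an end-to-end run needs, with defaults for every stage."""

    conditions: list[str] = field(
        default_factory=lambda: ["untreated", "ris_12h", "aln_12h", "mino_12h",
                                 "ris_24h", "aln_24h", "mino_24h"])
    n_movies: int = 3
    seed: int = 0
    output_dir: str = "results/run"
    # simulation overrides applied to every condition config (None = defaults)
    sim_overrides: dict = field(default_factory=dict)
    # segmentation
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    segment_channel: str = "reporter"
    # tracking / deformation / resorption
    min_iou: float = 0.3
    window: int = 5
    exclusion_ring: int = 2
    t_test_variant: str = "welch"
    reference: str = "untreated"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def _plain(obj):
            if isinstance(obj, dict):
                return {k: _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return _plain(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seg = d.get("segmentation")
        if isinstance(seg, dict):
            d["segmentation"] = SegmentationParams(**seg)
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def movie_seed(base_seed: int, condition_index: int, movie_index: int) -> int:
    """Stable per-movie seed derived from (base seed, condition, movie)."""
    ss = np.random.SeedSequence([base_seed, condition_index, movie_index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _analyze_movie(condition: str, movie: int, seed: int, cfg: RunConfig):
    """Simulate one movie and compute both indices on the segmented stack."""
    sim_cfg = make_condition_config(condition, seed, **cfg.sim_overrides)
    stack, _ = simulate_timelapse(sim_cfg)
    label_maps = segment_stack(stack, cfg.segment_channel, cfg.segmentation)
    tracks = track_cells(label_maps, min_iou=cfg.min_iou)

    cell_rows = []
    for tr in tracks:
        records = deform_mod.compute_track_deformation(tr, label_maps,
                                                       window=cfg.window)
        if not records:
            continue
        idx = np.array([r.index for r in records])
        cell_rows.append({
            "condition": condition, "movie": movie, "track_id": tr.track_id,
            "n_windows": len(records), "mean_index": float(idx.mean()),
        })

    res_records = resorb_mod.compute_stack_resorption(
        stack, label_maps, exclusion_ring=cfg.exclusion_ring)
    res_df = resorb_mod.records_to_dataframe(res_records)
    res_df.insert(0, "movie", movie)
    res_df.insert(0, "condition", condition)
    res_summary = resorb_mod.movie_summary(res_records)

    deform_mean = (float(np.mean([r["mean_index"] for r in cell_rows]))
                   if cell_rows else float("nan"))
    movie_row = {
        "condition": condition, "movie": movie, "seed": seed,
        "n_cells_tracked": len(cell_rows),
        "deformation_index": deform_mean,
        "resorption_index": res_summary["index_mean"],
    }
    return cell_rows, res_df, movie_row


def run_experiment(config: RunConfig) -> dict:
    """Run the full battery and write tables, summaries and a manifest.

    Returns a result bundle with the per-cell deformation table, the
    per-frame resorption table, the per-movie table, group summaries and
    the pairwise comparison tables (both movie-level metrics, plus
    cell-level deformation).
    """
    t0 = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    log_file = out / "run.log"
    fh = logging.FileHandler(log_file, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)

    unknown = [c for c in config.conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown conditions {unknown}; valid: {sorted(CONDITIONS)}")

    stage_times: dict[str, float] = {}
    cell_rows: list[dict] = []
    res_frames: list[pd.DataFrame] = []
    movie_rows: list[dict] = []
    try:
        for ci, condition in enumerate(config.conditions):
            t_cond = time.time()
            for m in range(config.n_movies):
                seed = movie_seed(config.seed, ci, m)
                logger.info("condition=%s movie=%d seed=%d", condition, m, seed)
                cells, res_df, movie_row = _analyze_movie(condition, m, seed, config)
                cell_rows.extend(cells)
                res_frames.append(res_df)
                movie_rows.append(movie_row)
            stage_times[condition] = time.time() - t_cond
    except Exception as exc:
        logger.error("stage failed for condition battery: %s", exc)
        raise
    finally:
        logger.removeHandler(fh)
        fh.close()

    cells_df = pd.DataFrame(cell_rows, columns=["condition", "movie", "track_id",
                                                "n_windows", "mean_index"])
    res_df = (pd.concat(res_frames, ignore_index=True)
              if res_frames else pd.DataFrame())
    movies_df = pd.DataFrame(movie_rows)

    # group summaries at movie level for both metrics
    summary_rows = []
    for metric in ("deformation_index", "resorption_index"):
        for condition in config.conditions:
            vals = movies_df.loc[movies_df.condition == condition, metric].dropna()
            s = stats_mod.summarize(vals, condition)
            summary_rows.append({"metric": metric, "group": condition,
                                 "n": s.n, "mean": s.mean, "sd": s.sd})
    summaries_df = pd.DataFrame(summary_rows)

    comparisons = []
    ref = config.reference
    if ref in config.conditions and config.n_movies >= 2:
        for metric in ("deformation_index", "resorption_index"):
            groups = {c: movies_df.loc[movies_df.condition == c, metric]
                      .dropna().tolist()
                      for c in config.conditions}
            tbl = stats_mod.comparison_table(groups, ref,
                                             variant=config.t_test_variant)
            tbl.insert(0, "metric", metric)
            tbl.insert(1, "level", "movie")
            comparisons.append(tbl)
    if ref in config.conditions and not cells_df.empty:
        groups = {c: cells_df.loc[cells_df.condition == c, "mean_index"].tolist()
                  for c in config.conditions}
        if all(len(v) >= 2 for v in groups.values()):
            tbl = stats_mod.comparison_table(groups, ref,
                                             variant=config.t_test_variant)
            tbl.insert(0, "metric", "deformation_index")
            tbl.insert(1, "level", "cell")
            comparisons.append(tbl)
    comparisons_df = (pd.concat(comparisons, ignore_index=True)
                      if comparisons else pd.DataFrame())

    files = {
        "cells.csv": cells_df,
        "resorption_frames.csv": res_df,
        "movies.csv": movies_df,
        "group_summaries.csv": summaries_df,
        "comparisons.csv": comparisons_df,
    }
    for name, df in files.items():
        df.to_csv(out / name, index=False, float_format="%.10g")

    manifest = {
        "config": config.to_dict(),
        "seed": config.seed,
        "outputs": {name: _sha256(out / name) for name in files},
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "total_seconds": round(time.time() - t0, 3),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "cells": cells_df,
        "resorption_frames": res_df,
        "movies": movies_df,
        "group_summaries": summaries_df,
        "comparisons": comparisons_df,
        "manifest": manifest,
        "output_dir": str(out),
    }
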