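"""End-to-end pipeline: config-driven harmonize -> vote -> sweep -> refine.

The run configuration is a YAML file describing the product rasters (path +
class codes), reference-sample inputs, census table, zone rasters, selection
rule and seed.  `run_pipeline` executes the whole chain and writes a
reproducible artifact bundle (vote and refined GeoTIFFs, sweep CSV in the
per-threshold schema, accuracy reports raw + design-adjusted, error-sample
points, area comparison CSVs, and a run log echoing the config and seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy, areas, consensus, sampling
from .grid import (ClassMap, LabelGrid, binarize, load_label_grid,
                   read_label_grid, resample_nearest, write_label_grid,
                   mapped_area)

__all__ = ["RunConfig", "load_config", "harmonize_products",
           "run_pipeline", "validate_only"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (see `load_config` for the YAML schema)."""

    products: list = field(default_factory=list)   # dicts: name, path, codes
    samples: dict = field(default_factory=dict)    # path, optional label_map
    census: dict = field(default_factory=dict)     # path, zone/area columns or total
    zones: dict = field(default_factory=dict)      # level -> zone raster path
    rule: str = "f1-then-bias"
    f1_tie_epsilon: float = 0.0
    nodata_policy: str = "zero-vote"
    seed: int = 0
    out_dir: str = "out"
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.products and len(self.products) < 2:
            raise ValueError("consensus runs need at least two products")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    cfg = RunConfig(
        products=raw.get("products", []),
        samples=raw.get("samples", {}),
        census=raw.get("census", {}),
        zones=raw.get("zones", {}),
        rule=raw.get("rule", "f1-then-bias"),
        f1_tie_epsilon=float(raw.get("f1_tie_epsilon", 0.0)),
        nodata_policy=raw.get("nodata_policy", "zero-vote"),
        seed=int(raw.get("seed", 0)),
        out_dir=raw.get("out_dir", "out"),
        raw=raw,
    )
    for entry in cfg.products:
        p = Path(entry["path"])
        if not p.exists():
            raise FileNotFoundError(f"product {entry.get('name', p)}: {p}")
    return cfg


def harmonize_products(cfg: RunConfig, target=None) -> dict:
    """Load every product, binarize by its class codes, align to one grid.

    The first product's grid (or an explicit ``target`` spec) is the analysis
    grid; others are nearest-resampled onto it.  A product entry may list a
    ``stack`` of paths composited by per-cell temporal majority before
    binarization-free use (the stack entries must already be binary).
    """
    from .grid import temporal_majority

    grids = {}
    for entry in cfg.products:
        name = entry.get("name", Path(entry["path"]).stem)
        if entry.get("stack"):
            parts = [load_label_grid(p) for p in entry["stack"]]
            g = temporal_majority(parts)
        else:
            raw, spec, _nodata = read_label_grid(entry["path"],
                                                 entry.get("band", 0))
            cm = ClassMap(name,
                          frozenset(entry.get("cropland_codes", [1])),
                          frozenset(entry.get("nodata_codes", [])))
            g = binarize(raw, spec, cm)
        grids[name] = g
    if not grids:
        raise ValueError("no products configured")
    names = list(grids)
    if target is None:
        target = grids[names[0]].spec
    for name in names:
        if not grids[name].spec.aligned(target):
            logger.info("resampling %s onto the analysis grid", name)
            grids[name] = resample_nearest(grids[name], target)
    return grids


def _load_samples(cfg: RunConfig) -> sampling.SamplePool:
    s = cfg.samples
    label_map = s.get("label_map")
    if label_map:
        label_map = {int(k): int(v) for k, v in label_map.items()}
    return sampling.read_pool_csv(s["path"], label_map)


def _load_census(cfg: RunConfig):
    """Returns (census DataFrame or None, census total)."""
    c = cfg.census
    if "path" in c:
        df = pd.read_csv(c["path"])
        zcol = c.get("zone_column", "zone")
        acol = c.get("area_column", "census_area_1e4ha")
        df = df.rename(columns={zcol: "zone", acol: "census_area_1e4ha"})
        total = float(c.get("total", df["census_area_1e4ha"].sum()))
        return df[["zone", "census_area_1e4ha"]], total
    return None, float(c.get("total", 0.0))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full refinement chain and write the artifact bundle.

    Stages: harmonize -> vote -> sweep -> select -> refined map -> accuracy
    reports (raw + adjusted, global + per-zone) -> area comparison.  Any
    stage failure aborts with the stage name; outputs written so far are
    listed in the run log as partial.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    stage = "init"
    try:
        stage = "harmonize"
        grids = harmonize_products(cfg)
        maps = list(grids.values())

        stage = "samples"
        pool = _load_samples(cfg)

        stage = "census"
        census_df, census_total = _load_census(cfg)

        stage = "vote"
        vote = consensus.vote_map(maps, cfg.nodata_policy)
        write_label_grid(_Votes(vote), out / "vote.tif")
        written.append("vote.tif")

        stage = "sweep"
        table = consensus.threshold_sweep(vote, pool, census_total)
        table.to_csv(out / "sweep.csv", index=False, float_format="%.10g")
        written.append("sweep.csv")

        stage = "select"
        t, row = consensus.select_threshold(table, cfg.rule, cfg.f1_tie_epsilon)
        refined = consensus.threshold_map(vote, t)
        write_label_grid(refined, out / "refined.tif")
        written.append("refined.tif")

        stage = "accuracy"
        cm = accuracy.confusion_from_samples(refined, pool)
        raw_metrics = accuracy.metrics(cm)
        design = accuracy.design_from_samples(refined, pool)
        valid_area = int(refined.valid.sum()) * refined.spec.pixel_size ** 2 / 1e8
        adj = accuracy.adjusted_estimates(design, valid_area)
        report = pd.DataFrame([{
            "map": "refined", "threshold": t, **raw_metrics.as_dict(),
            "TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn,
            "adjusted_OA": adj.oa, "adjusted_PA_cropland": adj.pa[1],
            "adjusted_UA_cropland": adj.ua[1],
            "adjusted_area_1e4ha": adj.area[1],
            "area_ci95_1e4ha": adj.ci95_area(1),
            "mapped_area_1e4ha": mapped_area(refined),
        }])
        report.to_csv(out / "metrics.csv", index=False, float_format="%.10g")
        written.append("metrics.csv")

        err = accuracy.error_samples(refined, pool)
        err.to_csv(out / "error_samples.csv", index=False)
        written.append("error_samples.csv")

        stage = "zones"
        zone_outputs = {}
        for level, zpath in cfg.zones.items():
            zarr = _zone_array(zpath, refined)
            pz = accuracy.per_zone_metrics(refined, pool, zarr)
            pz.to_csv(out / f"metrics_by_{level}.csv", index=False,
                      float_format="%.10g")
            written.append(f"metrics_by_{level}.csv")
            if census_df is not None:
                summary, per_zone = areas.compare_table(
                    {"refined": refined}, zarr, census_df,
                    exclude_zones=cfg.raw.get("exclude_zones", []))
                summary.to_csv(out / f"area_compare_{level}.csv", index=False,
                               float_format="%.10g")
                per_zone.to_csv(out / f"area_by_zone_{level}.csv", index=False,
                                float_format="%.10g")
                written.extend([f"area_compare_{level}.csv",
                                f"area_by_zone_{level}.csv"])
            zone_outputs[level] = pz

        stage = "log"
        log = {"seed": cfg.seed, "selected_threshold": t,
               "rule": cfg.rule, "written": written, "config": cfg.raw}
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
        written.append("run_log.json")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r} "
            f"(partial outputs: {written or 'none'}): {exc}") from exc
    return {"selected_threshold": t, "sweep": table, "metrics": report,
            "out_dir": str(out), "written": written}


class _Votes:
    """Adapter letting `write_label_grid` serialize a VoteGrid (uint8, 255)."""

    def __init__(self, vote):
        arr = vote.votes.astype(np.uint8).copy()
        arr[vote.nodata_mask] = 255
        self.labels = arr
        self.spec = vote.spec
        self.nodata_code = 255


def _zone_array(zpath, reference: LabelGrid) -> np.ndarray:
    """Load a zone raster as a raw integer array aligned with the maps."""
    if isinstance(zpath, (str, Path)):
        raw, spec, _ = read_label_grid(zpath)
        if spec.shape != reference.spec.shape:
            raise ValueError(f"zone raster {zpath} not aligned with analysis grid")
        return raw
    return np.asarray(zpath)


def validate_only(cfg: RunConfig, map_path) -> dict:
    """Accuracy report for one external binary map, without consensus.

    Scores a single map against the configured reference sample: raw metrics
    in the sweep-table schema, design-adjusted estimates, and the error
    samples.  This is how the individual input products are assessed.
    """
    grid = load_label_grid(map_path)
    pool = _load_samples(cfg)
    cm = accuracy.confusion_from_samples(grid, pool)
    m = accuracy.metrics(cm)
    design = accuracy.design_from_samples(grid, pool)
    valid_area = int(grid.valid.sum()) * grid.spec.pixel_size ** 2 / 1e8
    adj = accuracy.adjusted_estimates(design, valid_area)
    report = pd.DataFrame([{"map": Path(map_path).stem, **m.as_dict(),
                            "mapped_area_1e4ha": mapped_area(grid),
                            "adjusted_OA": adj.oa,
                            "adjusted_area_1e4ha": adj.area[1],
                            "area_ci95_1e4ha": adj.ci95_area(1)}])
    return {"metrics": report, "confusion": cm,
            "error_samples": accuracy.error_samples(grid, pool)}
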