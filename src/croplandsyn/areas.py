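"""Zonal cropland areas and agreement with census statistics.

Mapped areas are aggregated over an administrative-zone raster and compared
with census areas zone by zone.  Agreement is summarized by two statistics
computed against the 1:1 line:

* an agreement R^2 — one minus the ratio of squared mapped-vs-census
  differences to the census variance (a skill score against the census mean;
  it can be negative and equals 1 only for exact agreement).  This is *not*
  the squared Pearson correlation of an OLS fit; the Pearson r^2 is emitted
  alongside under its own name because axis labels reading "R^2" are
  ambiguous in practice.
* the RMSE of mapped vs census areas.

All areas are in 10^4 ha.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grid import LabelGrid

__all__ = ["zonal_area", "r2", "rmse", "compare_table"]


def zonal_area(grid: LabelGrid, zones) -> pd.Series:
    """Cropland area per zone id, in 10^4 ha.

    ``zones`` is an integer zone-id raster aligned with the map (array or
    grid-like with ``.labels``).  Nodata map cells contribute nothing.
    Returns a Series indexed by zone id covering every zone present.
    """
    zone_arr = zones.labels if hasattr(zones, "labels") else np.asarray(zones)
    if zone_arr.shape != grid.spec.shape:
        raise ValueError("zonal_area: zone raster not aligned with map grid")
    px_area = grid.spec.pixel_size ** 2 / 1e8
    ids = np.unique(zone_arr)
    ones = grid.ones
    counts = {int(z): int(ones[zone_arr == z].sum()) for z in ids}
    return pd.Series({z: c * px_area for z, c in counts.items()},
                     name="mapped_area_1e4ha").sort_index()


def r2(x, y) -> float:
    """Agreement R^2 of mapped areas x against census areas y (1:1 line).

    ``1 - sum((x-y)^2) / sum((y - mean(y))^2)``; requires non-constant y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(y) < 2:
        raise ValueError("need at least two zones")
    ss_res = np.sum((x - y) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("census areas are constant; agreement R^2 undefined")
    return float(1.0 - ss_res / ss_tot)


def rmse(x, y) -> float:
    """Root mean squared difference between mapped and census areas."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) == 0:
        raise ValueError("need at least one zone")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def compare_table(maps: dict, zones, census: pd.DataFrame,
                  exclude_zones=(),):
    """Census agreement of one or more maps at one administrative level.

    Parameters
    ----------
    maps
        Mapping of map name -> :class:`LabelGrid` (all on the zone grid).
    zones
        Zone-id raster aligned with the maps.
    census
        DataFrame with columns ``zone`` and ``census_area_1e4ha``.
    exclude_zones
        Zone ids left out of the statistics (configured exclusions such as
        administratively incomparable units); they still appear in the
        per-zone export, flagged.

    Returns ``(summary, per_zone)``: per-map R^2 (agreement and Pearson),
    RMSE and total bias; and a tidy per-zone table for scatter plots against
    the 1:1 line.  Zone ids present in the census but absent from the raster
    (or vice versa) are reported in the per-zone table with NaN, never
    silently dropped.
    """
    census = census.set_index("zone")["census_area_1e4ha"]
    per_zone_frames = []
    summary_rows = []
    for name, grid in maps.items():
        mapped = zonal_area(grid, zones)
        joined = pd.DataFrame({"mapped_area_1e4ha": mapped,
                               "census_area_1e4ha": census})
        joined.index.name = "zone"
        joined = joined.reset_index()
        joined["map"] = name
        joined["excluded"] = joined["zone"].isin(exclude_zones)
        joined["unmatched"] = joined[["mapped_area_1e4ha",
                                      "census_area_1e4ha"]].isna().any(axis=1)
        per_zone_frames.append(joined)
        use = joined[~joined["excluded"] & ~joined["unmatched"]]
        x = use["mapped_area_1e4ha"].to_numpy()
        y = use["census_area_1e4ha"].to_numpy()
        pearson = float(np.corrcoef(x, y)[0, 1] ** 2) if len(x) > 1 and \
            np.std(x) > 0 and np.std(y) > 0 else np.nan
        summary_rows.append({
            "map": name, "n_zones": len(use),
            "r2_agreement": r2(x, y), "r2_pearson": pearson,
            "rmse_1e4ha": rmse(x, y),
            "total_bias_1e4ha": float(np.sum(x - y)),
        })
    summary = pd.DataFrame(summary_rows)
    per_zone = pd.concat(per_zone_frames, ignore_index=True)
    return summary, per_zone
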