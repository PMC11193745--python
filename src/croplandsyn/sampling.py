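"""Reference-sample pools: multi-source merging and stratified random draws.

A :class:`SamplePool` is the validation currency of the pipeline: labeled
points (cropland 1 / non-cropland 0) with a source tag recording provenance
(e.g. an existing public validation library vs. a fresh stratified draw).
Pools from several sources are merged with near-duplicate removal; new
points are drawn by stratified random sampling with the strata defined by
the vote (consistency) map, the design used to densify samples inside the
maximum cropland extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import LabelGrid

__all__ = [
    "SamplePool",
    "merge_pools",
    "stratified_sample",
    "label_from_truth",
    "pool_summary",
    "read_pool_csv",
    "write_pool_csv",
]

_COLUMNS = ["x", "y", "label", "source"]


@dataclass
class SamplePool:
    """Labeled reference points with per-source provenance.

    ``df`` has columns ``x, y, label, source``; ``label`` may be a nullable
    integer (coordinates drawn before interpretation carry no label yet).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=_COLUMNS))
    crs_tag: str = "equal-area"

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"sample pool missing columns {missing}")
        extra = [c for c in self.df.columns if c not in _COLUMNS]
        self.df = self.df[_COLUMNS + extra].reset_index(drop=True)
        lab = self.df["label"]
        ok = lab.isna() | lab.isin([0, 1])
        if not ok.all():
            raise ValueError("sample labels must be 0, 1 or missing")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sources(self) -> pd.Series:
        """Point counts by source tag."""
        return self.df["source"].value_counts()

    @classmethod
    def from_arrays(cls, x, y, label=None, source: str = "unknown",
                    crs_tag: str = "equal-area") -> "SamplePool":
        x = np.asarray(x, dtype=float)
        n = len(x)
        lab = pd.array([pd.NA] * n, dtype="Int64") if label is None \
            else pd.array(np.asarray(label), dtype="Int64")
        src = [source] * n if isinstance(source, str) else list(source)
        return cls(pd.DataFrame({"x": x, "y": np.asarray(y, dtype=float),
                                 "label": lab, "source": src}), crs_tag)


def merge_pools(pools: list[SamplePool], dedup_tolerance: float) -> SamplePool:
    """Concatenate pools, removing near-duplicate points.

    Points are processed in pool order (the configured source-priority
    order); a point is dropped if an already-kept point lies within
    ``dedup_tolerance`` map units (Euclidean).  With no collisions the merge
    is a pure concatenation, so the paper-style bookkeeping (sum of
    per-source counts) holds exactly.
    """
    tags = {p.crs_tag for p in pools}
    if len(tags) > 1:
        raise ValueError(f"cannot merge pools with mixed CRS tags: {sorted(tags)}")
    df = pd.concat([p.df for p in pools], ignore_index=True)
    if len(df) == 0:
        return SamplePool(df, pools[0].crs_tag if pools else "equal-area")
    keep = np.ones(len(df), dtype=bool)
    if dedup_tolerance > 0 and len(df) > 1:
        xy = df[["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        # pairs come out with i < j; greedy first-kept-wins in row order
        for i, j in sorted(tree.query_pairs(dedup_tolerance)):
            if keep[i]:
                keep[j] = False
    return SamplePool(df.loc[keep].reset_index(drop=True),
                      pools[0].crs_tag if pools else "equal-area")


def _quotas(sizes: np.ndarray, n_total: int, allocation, min_per_stratum: int) -> np.ndarray:
    """Per-stratum quotas by largest-remainder rounding, floored at a minimum.

    ``allocation`` is 'proportional', 'equal', or a weight vector over the
    strata.  Quotas never exceed the stratum size; infeasible demands raise.
    """
    k = len(sizes)
    if isinstance(allocation, str):
        if allocation == "proportional":
            w = sizes / sizes.sum()
        elif allocation == "equal":
            w = np.full(k, 1.0 / k)
        else:
            raise ValueError(f"unknown allocation {allocation!r}")
    else:
        w = np.asarray(allocation, dtype=float)
        if len(w) != k or (w < 0).any() or w.sum() <= 0:
            raise ValueError("custom allocation weights invalid")
        w = w / w.sum()
    ideal = n_total * w
    q = np.floor(ideal).astype(np.int64)
    remainder = ideal - q
    short = n_total - q.sum()
    for idx in np.argsort(-remainder)[:short]:
        q[idx] += 1
    # enforce minimum, taking the excess from the largest quotas
    if min_per_stratum > 0:
        if min_per_stratum * k > n_total:
            raise ValueError("min_per_stratum infeasible for n_total")
        deficit = np.maximum(min_per_stratum - q, 0)
        q += deficit
        overshoot = q.sum() - n_total
        while overshoot > 0:
            idx = int(np.argmax(q))
            take = min(overshoot, q[idx] - min_per_stratum)
            if take <= 0:
                raise ValueError("cannot satisfy minima within n_total")
            q[idx] -= take
            overshoot -= take
    if (q > sizes).any():
        bad = int(np.argmax(q > sizes))
        raise ValueError(
            f"stratum {bad} smaller than its quota ({sizes[bad]} < {q[bad]})")
    return q


def stratified_sample(vote, n_total: int, allocation="proportional",
                      min_per_stratum: int = 0, restrict_to_extent: bool = True,
                      seed: int | None = None) -> SamplePool:
    """Draw point coordinates by stratified random sampling on vote strata.

    Strata are the distinct vote values of the consistency map (one stratum
    per value, the finest reading of vote-proportion strata); with
    ``restrict_to_extent`` the draw is confined to the maximum cropland
    extent (vote >= 1).  Cells are sampled uniformly without replacement
    within each stratum, quotas allocated by ``allocation`` with
    largest-remainder rounding and floored at ``min_per_stratum``; points sit
    at pixel centers so their labels are unambiguous.  Labels are left unset
    (interpretation happens downstream).  Deterministic under ``seed``.
    """
    votes = vote.votes if hasattr(vote, "votes") else vote.labels
    spec = vote.spec
    nodata = getattr(vote, "nodata_code", None)
    flat = np.asarray(votes).ravel()
    valid = np.ones(flat.shape, dtype=bool)
    if nodata is not None:
        valid &= flat != nodata
    if hasattr(vote, "nodata_mask"):
        valid &= ~np.asarray(vote.nodata_mask).ravel()
    if restrict_to_extent:
        valid &= flat >= 1
    strata_vals = np.unique(flat[valid])
    if len(strata_vals) == 0:
        raise ValueError("no valid cells to sample from")
    sizes = np.array([(valid & (flat == v)).sum() for v in strata_vals])
    q = _quotas(sizes, n_total, allocation, min_per_stratum)
    rng = np.random.default_rng(seed)
    rows, cols, strat = [], [], []
    for v, quota in zip(strata_vals, q):
        idx = np.flatnonzero(valid & (flat == v))
        pick = rng.choice(idx, size=int(quota), replace=False)
        rows.append(pick // spec.n_cols)
        cols.append(pick % spec.n_cols)
        strat.append(np.full(int(quota), v))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    x, y = spec.cell_center(rows, cols)
    pool = SamplePool.from_arrays(x, y, None, "stratified", spec.crs_tag)
    pool.df["stratum"] = np.concatenate(strat)
    return pool


def label_from_truth(pool: SamplePool, truth: LabelGrid) -> SamplePool:
    """Label points by point-in-pixel lookup on a truth grid (synthetic mode).

    Stands in for photo-interpretation of reference imagery; only meaningful
    where a truth raster exists.  Out-of-extent points are an error, not a
    silent drop.  Idempotent.
    """
    x = pool.df["x"].to_numpy(dtype=float)
    y = pool.df["y"].to_numpy(dtype=float)
    inside = truth.spec.contains(x, y)
    if not inside.all():
        raise ValueError(f"{int((~inside).sum())} points outside the truth extent")
    row, col = truth.spec.rowcol(x, y)
    lab = truth.labels[row, col]
    if (lab == truth.nodata_code).any():
        raise ValueError("points fall on nodata cells of the truth grid")
    df = pool.df.copy()
    df["label"] = pd.array(lab, dtype="Int64")
    return SamplePool(df, pool.crs_tag)


def pool_summary(pool: SamplePool, zones=None, zone_spec=None) -> pd.DataFrame:
    """Cross-tab of sample counts by zone and source, with label totals.

    Without ``zones`` a single "all" zone is reported.  The grand total
    always equals the pool size.  Row order: zones then a "total" row.
    """
    df = pool.df.copy()
    if zones is not None:
        zone_arr = zones.labels if hasattr(zones, "labels") else np.asarray(zones)
        spec = zone_spec if zone_spec is not None else zones.spec
        row, col = spec.rowcol(df["x"].to_numpy(float), df["y"].to_numpy(float))
        inside = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
        zid = np.full(len(df), -1, dtype=np.int64)
        zid[inside] = zone_arr[row[inside], col[inside]]
        df["zone"] = zid
    else:
        df["zone"] = "all"
    tab = df.pivot_table(index="zone", columns="source", values="x",
                         aggfunc="count", fill_value=0)
    tab["cropland"] = df[df["label"] == 1].groupby("zone").size().reindex(tab.index, fill_value=0)
    tab["non_cropland"] = df[df["label"] == 0].groupby("zone").size().reindex(tab.index, fill_value=0)
    tab["total"] = df.groupby("zone").size().reindex(tab.index, fill_value=0)
    total = tab.sum(axis=0)
    total.name = "total"
    out = pd.concat([tab, total.to_frame().T])
    out.columns.name = None
    return out


# ---------------------------------------------------------------------------
# CSV I/O (x, y, label, source); supports the deposited 0/10 label coding
# ---------------------------------------------------------------------------


def read_pool_csv(path, label_map: dict | None = None,
                  crs_tag: str = "equal-area") -> SamplePool:
    """Read a sample CSV.  ``label_map`` remaps foreign label codings, e.g.
    ``{0: 0, 10: 1}`` for archives that code cropland as 10."""
    df = pd.read_csv(path)
    if "source" not in df.columns:
        df["source"] = "unknown"
    if label_map:
        df["label"] = df["label"].map(label_map)
        if df["label"].isna().any():
            raise ValueError("label values outside the provided label_map")
    df["label"] = pd.array(df["label"], dtype="Int64")
    return SamplePool(df[_COLUMNS], crs_tag)


def write_pool_csv(pool: SamplePool, path) -> None:
    pool.df.to_csv(path, index=False)
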