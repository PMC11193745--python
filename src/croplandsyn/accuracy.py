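"""Accuracy assessment of binary cropland maps against reference samples.

Two layers of inference are provided:

* **Raw (sample-count) metrics** — the usual confusion-matrix scores for a
  binary classifier: overall accuracy, producer's accuracy (recall), user's
  accuracy (precision), F1 and the Matthews correlation coefficient, with
  omission error = 1 - PA and commission error = 1 - UA.

* **Design-based (stratified) estimates** — when the reference sample was
  drawn by stratified random sampling, raw counts are re-weighted by the
  strata's area proportions W_i to give unbiased accuracy and area estimates
  with standard errors, following the good-practice stratified estimators
  used for map accuracy and area assessment (Olofsson-style adjustment).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import LabelGrid

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "Stratum",
    "StratifiedDesign",
    "AdjustedEstimate",
    "confusion_from_samples",
    "metrics",
    "adjusted_estimates",
    "design_from_samples",
    "per_zone_metrics",
    "error_samples",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion matrix counts; positive class = cropland (1)."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_positives(self) -> int:
        return self.tp + self.fn

    @property
    def reference_negatives(self) -> int:
        return self.tn + self.fp

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass(frozen=True)
class MetricSet:
    """The five accuracy scores plus derived omission/commission errors."""

    oa: float
    pa: float
    ua: float
    f1: float
    mcc: float

    @property
    def oe(self) -> float:
        """Omission error, 1 - PA."""
        return 1.0 - self.pa

    @property
    def ce(self) -> float:
        """Commission error, 1 - UA."""
        return 1.0 - self.ua

    def as_dict(self) -> dict:
        return {"OA": self.oa, "PA": self.pa, "UA": self.ua,
                "OE": self.oe, "CE": self.ce, "F1": self.f1, "MCC": self.mcc}


def metrics(cm: ConfusionCounts) -> MetricSet:
    """Compute OA, PA, UA, F1 and MCC from confusion counts.

    Degenerate denominators follow the standard conventions: PA (UA) is 0
    when there are no reference positives (no mapped positives), F1 is 0 when
    PA + UA = 0, and MCC is 0 when any marginal of the confusion matrix is
    zero.  These keep threshold sweeps total at the all-0/all-1 extremes.
    """
    tp, fp, fn, tn = cm.tp, cm.fp, cm.fn, cm.tn
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    oa = (tp + tn) / n
    pa = tp / (tp + fn) if tp + fn > 0 else 0.0
    ua = tp / (tp + fp) if tp + fp > 0 else 0.0
    f1 = 2 * pa * ua / (pa + ua) if pa + ua > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        mcc = 0.0
    else:
        # products of counts overflow int64 for large n; go through floats
        mcc = (tp * tn - fp * fn) / math.sqrt(float(tp + fp) * float(tp + fn)
                                              * float(tn + fp) * float(tn + fn))
    return MetricSet(oa, pa, ua, f1, mcc)


# ---------------------------------------------------------------------------
# Sample-vs-map confusion
# ---------------------------------------------------------------------------


def _map_labels_at(grid: LabelGrid, x, y):
    """Map labels at sample points plus a usability mask.

    Points outside the extent or on nodata cells are flagged unusable (and
    counted in the log); everything else returns the point-in-pixel label.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    row, col = grid.spec.rowcol(x, y)
    inside = (row >= 0) & (row < grid.spec.n_rows) & (col >= 0) & (col < grid.spec.n_cols)
    labels = np.full(x.shape, grid.nodata_code, dtype=np.int64)
    labels[inside] = grid.labels[row[inside], col[inside]]
    usable = inside & (labels != grid.nodata_code)
    n_out = int((~inside).sum())
    n_nodata = int((inside & (labels == grid.nodata_code)).sum())
    if n_out or n_nodata:
        logger.info("dropped samples: %d outside extent, %d on nodata cells",
                    n_out, n_nodata)
    return labels, usable


def confusion_from_samples(grid: LabelGrid, samples) -> ConfusionCounts:
    """Tally the confusion matrix of a map against labeled reference points.

    ``samples`` is anything with ``x``, ``y`` and ``label`` columns/attributes
    (a :class:`~croplandsyn.sampling.SamplePool` or a DataFrame).  Reference
    label 1 = cropland.  Samples outside the extent or on nodata cells are
    dropped (logged), mirroring the usual silent cleaning step — but audited.
    """
    x, y, ref = _sample_xyl(samples)
    pred, usable = _map_labels_at(grid, x, y)
    if not usable.any():
        raise ValueError("no usable samples fall on valid map cells")
    ref = np.asarray(ref, dtype=np.int64)[usable]
    pred = pred[usable]
    tp = int(((ref == 1) & (pred == 1)).sum())
    fn = int(((ref == 1) & (pred == 0)).sum())
    fp = int(((ref == 0) & (pred == 1)).sum())
    tn = int(((ref == 0) & (pred == 0)).sum())
    return ConfusionCounts(tp, fp, fn, tn)


def _sample_xyl(samples):
    """Accept a SamplePool, DataFrame, or (x, y, label) triple."""
    if hasattr(samples, "df"):
        df = samples.df
        return df["x"].to_numpy(), df["y"].to_numpy(), df["label"].to_numpy()
    if isinstance(samples, pd.DataFrame):
        return samples["x"].to_numpy(), samples["y"].to_numpy(), samples["label"].to_numpy()
    x, y, label = samples
    return np.asarray(x), np.asarray(y), np.asarray(label)


# ---------------------------------------------------------------------------
# Design-based (stratified / Olofsson-style) estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Stratum:
    """One sampling stratum: its area weight and within-stratum sample counts.

    ``n_mr`` is the 2x2 within-stratum cross-tab ``n_mr[m][r]`` of sampled
    points with map class ``m`` and reference class ``r`` (classes 0/1).
    When strata are the map's own classes the map class is constant within a
    stratum and one row of ``n_mr`` is zero; vote-bin strata mix both.
    """

    stratum_id: int
    weight: float
    n_mr: tuple  # ((n00, n01), (n10, n11))

    @property
    def n(self) -> int:
        return int(sum(sum(row) for row in self.n_mr))

    def ref_count(self, r: int) -> int:
        return int(self.n_mr[0][r] + self.n_mr[1][r])

    def agree_count(self) -> int:
        return int(self.n_mr[0][0] + self.n_mr[1][1])


@dataclass(frozen=True)
class StratifiedDesign:
    strata: tuple

    def __post_init__(self) -> None:
        w = sum(s.weight for s in self.strata)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"stratum weights must sum to 1 (got {w!r})")
        for s in self.strata:
            if s.n < 2:
                raise ValueError(
                    f"stratum {s.stratum_id} has n={s.n} < 2; SE undefined")


@dataclass(frozen=True)
class AdjustedEstimate:
    """Design-based accuracy and area estimates with standard errors.

    Area proportions ``p_hat`` (index = class), mapped onto areas via
    ``total_area`` (10^4 ha).  ``ci95_*`` are half-widths (1.96 SE).
    """

    oa: float
    ua: dict
    pa: dict
    p_hat: dict
    se_p: dict
    area: dict
    se_area: dict
    total_area: float

    def ci95_area(self, cls: int) -> float:
        return 1.96 * self.se_area[cls]


def adjusted_estimates(design: StratifiedDesign, total_area: float) -> AdjustedEstimate:
    """Stratified (area-weighted) accuracy and area estimators.

    Cell proportions ``p_mr = sum_i W_i n_i,mr / n_i`` form the error matrix
    in area-proportion terms.  From it: adjusted OA = diagonal sum, adjusted
    UA_m = p_mm / p_m., adjusted PA_r = p_rr / p_.r, and the class-r area
    proportion ``p_.r`` with stratified standard error

        SE(p_.r) = sqrt( sum_i W_i^2 (q_ir)(1 - q_ir) / (n_i - 1) ),

    where ``q_ir = n_ir / n_i`` is the within-stratum reference-class share.
    Areas are ``p_.r * total_area`` with 95% CI half-width 1.96 SE.
    """
    p = np.zeros((2, 2))
    var = np.zeros(2)
    for s in design.strata:
        n_i = s.n
        for m in (0, 1):
            for r in (0, 1):
                p[m, r] += s.weight * s.n_mr[m][r] / n_i
        for r in (0, 1):
            q = s.ref_count(r) / n_i
            var[r] += s.weight ** 2 * q * (1.0 - q) / (n_i - 1)
    oa = p[0, 0] + p[1, 1]
    p_map = p.sum(axis=1)   # p_m.
    p_ref = p.sum(axis=0)   # p_.r
    ua = {m: (p[m, m] / p_map[m] if p_map[m] > 0 else 0.0) for m in (0, 1)}
    pa = {r: (p[r, r] / p_ref[r] if p_ref[r] > 0 else 0.0) for r in (0, 1)}
    se_p = {r: float(np.sqrt(var[r])) for r in (0, 1)}
    return AdjustedEstimate(
        oa=float(oa),
        ua=ua,
        pa=pa,
        p_hat={r: float(p_ref[r]) for r in (0, 1)},
        se_p=se_p,
        area={r: float(p_ref[r] * total_area) for r in (0, 1)},
        se_area={r: float(se_p[r] * total_area) for r in (0, 1)},
        total_area=float(total_area),
    )


def design_from_samples(grid: LabelGrid, samples, strata_grid: LabelGrid | None = None,
                        weights: dict | None = None) -> StratifiedDesign:
    """Build a :class:`StratifiedDesign` from a map, labeled points and strata.

    By default strata are the assessed map's own classes and weights are the
    map's class-area proportions; pass ``strata_grid`` (e.g. a vote raster
    stored as labels) and explicit ``weights`` for other designs.
    """
    x, y, ref = _sample_xyl(samples)
    pred, usable = _map_labels_at(grid, x, y)
    x, y = np.asarray(x, float)[usable], np.asarray(y, float)[usable]
    ref = np.asarray(ref, dtype=np.int64)[usable]
    pred = pred[usable]
    if strata_grid is None:
        strat = pred
        if weights is None:
            valid = grid.valid
            n_valid = int(valid.sum())
            weights = {0: int((grid.labels == 0).sum()) / n_valid,
                       1: int(grid.ones.sum()) / n_valid}
    else:
        row, col = strata_grid.spec.rowcol(x, y)
        strat = strata_grid.labels[row, col]
        if weights is None:
            vals, counts = np.unique(
                strata_grid.labels[strata_grid.valid], return_counts=True)
            weights = dict(zip(vals.tolist(), (counts / counts.sum()).tolist()))
    strata = []
    for sid, w in sorted(weights.items()):
        sel = strat == sid
        n_mr = tuple(
            tuple(int(((pred[sel] == m) & (ref[sel] == r)).sum()) for r in (0, 1))
            for m in (0, 1)
        )
        strata.append(Stratum(int(sid), float(w), n_mr))
    return StratifiedDesign(tuple(strata))


# ---------------------------------------------------------------------------
# Per-zone reporting and error-sample export
# ---------------------------------------------------------------------------


def per_zone_metrics(grid: LabelGrid, samples, zones: LabelGrid | np.ndarray | None,
                     zone_ids=None) -> pd.DataFrame:
    """Raw metrics per administrative zone.

    ``zones`` is a zone-id raster aligned with ``grid`` (a plain integer
    array or a grid-like object with ``.labels``).  Zones with no usable
    samples appear in the output flagged ``no_samples`` rather than being
    silently dropped.  Returns one row per zone plus confusion counts.
    """
    zone_arr = zones.labels if hasattr(zones, "labels") else np.asarray(zones)
    if zone_arr.shape != grid.spec.shape:
        raise ValueError("zone raster not aligned with map grid")
    x, y, ref = _sample_xyl(samples)
    pred, usable = _map_labels_at(grid, x, y)
    row, col = grid.spec.rowcol(np.asarray(x, float), np.asarray(y, float))
    zone_of = np.full(len(pred), -1, dtype=np.int64)
    zone_of[usable] = zone_arr[row[usable], col[usable]]
    ref = np.asarray(ref, dtype=np.int64)

    if zone_ids is None:
        zone_ids = np.unique(zone_arr)
    records = []
    for zid in zone_ids:
        sel = usable & (zone_of == zid)
        rec = {"zone": int(zid), "n_samples": int(sel.sum())}
        if not sel.any():
            rec.update({k: np.nan for k in
                        ("OA", "PA", "UA", "OE", "CE", "F1", "MCC")})
            rec["flag"] = "no_samples"
        else:
            r, p = ref[sel], pred[sel]
            cm = ConfusionCounts(int(((r == 1) & (p == 1)).sum()),
                                 int(((r == 0) & (p == 1)).sum()),
                                 int(((r == 1) & (p == 0)).sum()),
                                 int(((r == 0) & (p == 0)).sum()))
            rec.update(metrics(cm).as_dict())
            rec.update({"TP": cm.tp, "FP": cm.fp, "FN": cm.fn, "TN": cm.tn})
            rec["flag"] = ""
        records.append(rec)
    return pd.DataFrame.from_records(records)


def error_samples(grid: LabelGrid, samples) -> pd.DataFrame:
    """Misclassified reference points, tagged for spatial error inspection.

    Returns the usable samples the map gets wrong: reference non-cropland
    mapped as cropland -> ``commission`` (FP); reference cropland mapped as
    non-cropland -> ``omission`` (FN).  A perfect map yields an empty table.
    """
    x, y, ref = _sample_xyl(samples)
    pred, usable = _map_labels_at(grid, x, y)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ref = np.asarray(ref, dtype=np.int64)
    commission = usable & (ref == 0) & (pred == 1)
    omission = usable & (ref == 1) & (pred == 0)
    sel = commission | omission
    flag = np.where(commission[sel], "commission", "omission")
    return pd.DataFrame({"x": x[sel], "y": y[sel], "label": ref[sel],
                         "flag": flag})
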