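"""Consensus fusion of binary cropland maps by vote thresholding.

K co-registered binary maps are combined into a per-pixel *vote* (consistency)
map counting how many products call the pixel cropland (0..K).  Thresholding
the votes at t = 1..K yields a nested family of candidate maps — from the
union of all products (t = 1) down to their intersection (t = K).  Each
candidate is scored against an independent reference sample (accuracy
metrics) and against a census area total (bias), and the refined map is the
candidate selected by the highest-F1 / lowest-bias principle: a
self-adjusted consensus threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import accuracy
from .grid import GridSpec, LabelGrid, mapped_area

__all__ = [
    "VoteGrid",
    "vote_map",
    "threshold_map",
    "threshold_sweep",
    "select_threshold",
    "refine",
    "sweep_from_metrics",
    "SWEEP_COLUMNS",
]

#: Canonical column order of the per-threshold sweep table.
SWEEP_COLUMNS = ["threshold", "OA", "PA", "UA", "OE", "CE", "F1", "MCC",
                 "mapped_area_1e4ha", "census_bias_1e4ha"]


@dataclass
class VoteGrid:
    """Per-pixel count of maps voting cropland, 0..k_maps.

    ``nodata_mask`` marks cells with no usable observation (policy-dependent);
    votes there are 0 and excluded from thresholding.
    """

    spec: GridSpec
    votes: np.ndarray
    k_maps: int
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes)
        if self.votes.shape != self.spec.shape:
            raise ValueError("vote array shape mismatch with spec")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.spec.shape, dtype=bool)
        v = self.votes[~self.nodata_mask]
        if v.size and (v.min() < 0 or v.max() > self.k_maps):
            raise ValueError(f"votes outside 0..{self.k_maps}")

    def total_votes(self) -> int:
        return int(self.votes[~self.nodata_mask].sum())


def vote_map(maps: list[LabelGrid], nodata_policy: str = "zero-vote") -> VoteGrid:
    """Pixel-by-pixel vote count across >= 2 aligned binary maps.

    ``nodata_policy``:

    * ``zero-vote`` (default) — a product's nodata contributes no vote; a
      cell is flagged nodata only when *every* product is nodata there.
    * ``propagate`` — a cell nodata in *any* product is flagged nodata.

    Conservation holds under zero-vote: the vote total equals the sum of the
    products' cropland-pixel counts.
    """
    if len(maps) < 2:
        raise ValueError("vote_map needs at least two maps")
    spec = maps[0].spec
    for m in maps[1:]:
        if not spec.aligned(m.spec):
            raise ValueError("vote_map: input grids are not aligned")
    votes = np.zeros(spec.shape, dtype=np.int16)
    n_nodata = np.zeros(spec.shape, dtype=np.int16)
    for m in maps:
        votes += m.ones
        n_nodata += ~m.valid
    if nodata_policy == "zero-vote":
        mask = n_nodata == len(maps)
    elif nodata_policy == "propagate":
        mask = n_nodata > 0
    else:
        raise ValueError(f"unknown nodata_policy {nodata_policy!r}")
    votes[mask] = 0
    return VoteGrid(spec, votes, len(maps), mask)


def threshold_map(vote: VoteGrid, t: int, nodata_code: int = 255) -> LabelGrid:
    """Binary map labeling cells cropland where vote >= t.

    Thresholds are cumulative, so the maps are nested: every cropland cell at
    t+1 is cropland at t.  Nodata cells of the vote grid pass through.
    """
    if not 1 <= t <= vote.k_maps:
        raise ValueError(f"threshold {t} outside 1..{vote.k_maps}")
    out = (vote.votes >= t).astype(np.uint8)
    out[vote.nodata_mask] = nodata_code
    return LabelGrid(vote.spec, out, nodata_code)


def threshold_sweep(vote: VoteGrid, samples, census_total: float) -> pd.DataFrame:
    """Score every candidate threshold t = 1..K.

    For each t: build the threshold map, compute the accuracy metrics against
    the reference sample, the mapped cropland area (10^4 ha) and the census
    bias (mapped - census, positive = overestimate).  Returns the sweep table
    in the canonical column order.
    """
    if census_total < 0:
        raise ValueError("census_total must be non-negative")
    rows = []
    for t in range(1, vote.k_maps + 1):
        grid = threshold_map(vote, t)
        m = accuracy.metrics(accuracy.confusion_from_samples(grid, samples))
        area = mapped_area(grid)
        rows.append({"threshold": t, **m.as_dict(),
                     "mapped_area_1e4ha": area,
                     "census_bias_1e4ha": area - census_total})
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def sweep_from_metrics(f1, mapped_area_1e4ha=None, census_total: float = 0.0,
                       **extra_columns) -> pd.DataFrame:
    """Assemble a sweep table from externally computed per-threshold metrics.

    Lets precomputed published metric tables drive threshold selection; any
    metric column absent defaults to NaN.
    """
    f1 = list(f1)
    k = len(f1)
    df = pd.DataFrame({"threshold": np.arange(1, k + 1), "F1": f1})
    if mapped_area_1e4ha is not None:
        df["mapped_area_1e4ha"] = list(mapped_area_1e4ha)
        df["census_bias_1e4ha"] = df["mapped_area_1e4ha"] - census_total
    for name, vals in extra_columns.items():
        df[name] = list(vals)
    for col in SWEEP_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[SWEEP_COLUMNS]


def select_threshold(table: pd.DataFrame, rule: str = "f1-then-bias",
                     f1_tie_epsilon: float = 0.0):
    """Pick the consensus threshold from a sweep table.

    Rules (``census_bias`` means ``|census_bias_1e4ha|``; missing bias is
    treated as 0 so a pure-F1 table still selects):

    * ``f1-max`` — argmax F1; exact ties broken by smaller |bias|.
    * ``f1-then-bias`` (default) — among rows with F1 within
      ``f1_tie_epsilon`` of the maximum, pick the smallest |bias|.  With
      epsilon 0 this is the argmax-F1 rule with bias as tiebreak.
    * ``bias-then-f1`` — among rows with |bias| within ``f1_tie_epsilon``
      (same knob, bias units) of the minimum, pick the highest F1.

    Returns ``(t, row)`` for the winning threshold.
    """
    if len(table) == 0:
        raise ValueError("empty sweep table")
    df = table.reset_index(drop=True)
    bias = df["census_bias_1e4ha"].abs() if "census_bias_1e4ha" in df else \
        pd.Series(0.0, index=df.index)
    bias = bias.fillna(0.0)
    f1 = df["F1"].astype(float)
    if rule == "f1-max":
        best = f1.max()
        cand = df.index[f1 == best]
    elif rule == "f1-then-bias":
        best = f1.max()
        cand = df.index[f1 >= best - f1_tie_epsilon]
    elif rule == "bias-then-f1":
        least = bias.min()
        cand = df.index[bias <= least + f1_tie_epsilon]
        # among close-bias rows, maximize F1 (bias as final tiebreak)
        top = f1[cand].max()
        cand = [i for i in cand if f1[i] == top]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    winner = min(cand, key=lambda i: (bias[i], df.loc[i, "threshold"]))
    row = df.loc[winner]
    return int(row["threshold"]), row


def refine(maps: list[LabelGrid], samples, census_total: float,
           rule: str = "f1-then-bias", f1_tie_epsilon: float = 0.0,
           nodata_policy: str = "zero-vote"):
    """End-to-end self-adjusted threshold refinement.

    Composes vote_map -> threshold_sweep -> select_threshold -> threshold_map
    and returns ``(refined LabelGrid, sweep table, selected t)``.
    """
    vote = vote_map(maps, nodata_policy)
    table = threshold_sweep(vote, samples, census_total)
    t, _ = select_threshold(table, rule, f1_tie_epsilon)
    return threshold_map(vote, t), table, t
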