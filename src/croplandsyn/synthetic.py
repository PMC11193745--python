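"""Synthetic study scenes: truth, corrupted products, zones, census, samples.

The generator builds complete, statistically controlled test worlds shaped
like the real study setting: a spatially autocorrelated binary cropland
truth map (smoothed-noise random field thresholded at a target cropland
fraction, mimicking fragmented parcels), K product maps derived from the
truth by per-class corruption (omission flips on cropland, commission flips
on non-cropland, optionally spatially correlated), a rectangular-block
administrative zone partition with a coarser province grouping, and a census
table equal to the truth's zonal areas (optionally perturbed).

Everything is deterministic under a master seed: one `numpy` SeedSequence
spawns independent substreams for the truth, each product map, the census
noise and any sampling, so components can be varied independently.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridSpec, LabelGrid, DEFAULT_NODATA
from . import consensus, sampling, accuracy
from .areas import zonal_area

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "generate_truth",
    "corrupt_map",
    "generate_zones",
    "generate_scene",
    "parameter_recovery_suite",
]


@dataclass(frozen=True)
class SceneParams:
    """Knobs of a synthetic scene.

    Defaults emulate the study conditions: ten products on a 30 m grid,
    moderate per-product omission (0.2) and commission (0.1) error rates,
    fragmented truth patches (correlation length 3 px ~ 90 m), 30% cropland,
    and a 4x4 zone partition grouped into 4 provinces.
    """

    n_rows: int = 256
    n_cols: int = 256
    pixel_size: float = 30.0
    cropland_fraction: float = 0.30
    truth_correlation: float = 3.0     # Gaussian sigma, pixels
    k_maps: int = 10
    omission: tuple | float = 0.2      # per-map or scalar o_k
    commission: tuple | float = 0.1    # per-map or scalar c_k
    error_correlation: float = 0.0     # 0 = independent flips
    n_zones: int = 16
    census_noise_sd: float = 0.0       # multiplicative, on zonal census areas
    seed: int = 0
    crs_tag: str = "synthetic-equal-area"

    def __post_init__(self) -> None:
        if not 0.0 < self.cropland_fraction < 1.0:
            raise ValueError("cropland_fraction must be in (0, 1)")
        if self.k_maps < 2:
            raise ValueError("need at least two product maps")
        for r in (*self.omission_rates(), *self.commission_rates()):
            if not 0.0 <= r < 0.5:
                raise ValueError("error rates must be in [0, 0.5)")
        if self.n_zones > self.n_rows * self.n_cols:
            raise ValueError("more zones than cells")

    def omission_rates(self) -> tuple:
        o = self.omission
        return tuple(o) if np.iterable(o) else (float(o),) * self.k_maps

    def commission_rates(self) -> tuple:
        c = self.commission
        return tuple(c) if np.iterable(c) else (float(c),) * self.k_maps

    def grid_spec(self) -> GridSpec:
        return GridSpec(0.0, self.n_rows * self.pixel_size, self.pixel_size,
                        self.n_rows, self.n_cols, self.crs_tag)


@dataclass
class SyntheticScene:
    truth: LabelGrid
    products: list
    zones: np.ndarray            # zone-id raster, ids 1..n_zones
    provinces: np.ndarray        # coarser grouping raster
    census: pd.DataFrame         # columns: zone, census_area_1e4ha
    params: SceneParams

    @property
    def census_total(self) -> float:
        return float(self.census["census_area_1e4ha"].sum())


def _substreams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _smooth_field(rng, shape, correlation: float) -> np.ndarray:
    field = rng.standard_normal(shape)
    if correlation > 0:
        field = ndimage.gaussian_filter(field, sigma=correlation, mode="wrap")
    return field


def generate_truth(params: SceneParams, rng=None) -> LabelGrid:
    """Spatially autocorrelated binary truth at the target cropland fraction.

    A seeded Gaussian noise field is smoothed with a kernel of the stated
    correlation length and thresholded at the empirical quantile that yields
    ``cropland_fraction`` (exact to the grid's resolution, so the realized
    fraction is within half a percentage point).  Correlation length 0 gives
    an i.i.d. Bernoulli field.
    """
    if rng is None:
        rng = _substreams(params.seed, 1)[0]
    shape = (params.n_rows, params.n_cols)
    field = _smooth_field(rng, shape, params.truth_correlation)
    cut = np.quantile(field, 1.0 - params.cropland_fraction)
    labels = (field > cut).astype(np.uint8)
    return LabelGrid(params.grid_spec(), labels, DEFAULT_NODATA)


def corrupt_map(truth: LabelGrid, omission: float, commission: float,
                error_correlation: float = 0.0, seed=None, rng=None) -> LabelGrid:
    """Derive a product map from truth with stated class-conditional errors.

    Truth-cropland cells flip to 0 with probability ``omission``; truth
    non-cropland cells flip to 1 with probability ``commission`` — so the
    expected producer's accuracy against truth is 1 - omission and the flips
    are independent across maps.  With ``error_correlation`` > 0 the flips
    come from thresholding a smoothed field at the class-conditional
    quantile, producing spatially clumped errors at the same marginal rates.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = truth.labels.copy()
    is_one = truth.ones
    is_zero = truth.labels == 0
    if error_correlation > 0:
        field = _smooth_field(rng, truth.labels.shape, error_correlation)
        for mask, rate, new in ((is_one, omission, 0), (is_zero, commission, 1)):
            if rate > 0 and mask.any():
                cut = np.quantile(field[mask], rate)
                labels[mask & (field <= cut)] = new
    else:
        u = rng.random(truth.labels.shape)
        labels[is_one & (u < omission)] = 0
        labels[is_zero & (u < commission)] = 1
    return LabelGrid(truth.spec, labels, truth.nodata_code)


def generate_zones(params: SceneParams) -> tuple:
    """Rectangular-block partition into ``n_zones`` contiguous zones.

    Zones are blocks of a near-square r x c tiling (ids 1..n_zones); the
    block rows double as a coarser "province" grouping for multi-level
    comparisons.  Every cell belongs to exactly one zone.
    """
    n = params.n_zones
    rows_of = int(np.floor(np.sqrt(n)))
    while n % rows_of:
        rows_of -= 1
    cols_of = n // rows_of
    row_edges = np.linspace(0, params.n_rows, rows_of + 1).astype(int)
    col_edges = np.linspace(0, params.n_cols, cols_of + 1).astype(int)
    zones = np.zeros((params.n_rows, params.n_cols), dtype=np.int32)
    provinces = np.zeros_like(zones)
    zid = 0
    for i in range(rows_of):
        for j in range(cols_of):
            zid += 1
            zones[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = zid
            provinces[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = i + 1
    return zones, provinces


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Compose truth, K corrupted products, zones and census into a scene.

    The census equals the truth's zonal cropland areas times ``1 + eps`` with
    ``eps ~ N(0, census_noise_sd)`` per zone (default exact).
    """
    rngs = _substreams(params.seed, params.k_maps + 2)
    truth = generate_truth(params, rng=rngs[0])
    o = params.omission_rates()
    c = params.commission_rates()
    products = [
        corrupt_map(truth, o[k], c[k], params.error_correlation, rng=rngs[1 + k])
        for k in range(params.k_maps)
    ]
    zones, provinces = generate_zones(params)
    areas = zonal_area(truth, zones)
    census_rng = rngs[-1]
    eps = census_rng.normal(0.0, params.census_noise_sd, len(areas)) \
        if params.census_noise_sd > 0 else np.zeros(len(areas))
    census = pd.DataFrame({"zone": areas.index.to_numpy(),
                           "census_area_1e4ha": areas.to_numpy() * (1.0 + eps)})
    return SyntheticScene(truth, products, zones, provinces, census, params)


def parameter_recovery_suite(params: SceneParams, n_reps: int = 20,
                             n_samples: int = 2000, seed: int = 0,
                             rule: str = "f1-then-bias") -> pd.DataFrame:
    """Monte-Carlo harness: does consensus refinement beat single products?

    For each replicate: generate a scene, draw a stratified reference sample
    on the vote map and label it from truth, run the full refinement, and
    score refined map and every product against the *same* sample.  Records
    per-replicate refined F1, mean single-map F1, the selected threshold and
    the design-based cropland area estimate vs the truth area.
    """
    records = []
    for rep in range(n_reps):
        p = SceneParams(**{**asdict(params), "seed": seed + rep})
        scene = generate_scene(p)
        vote = consensus.vote_map(scene.products)
        pool = sampling.stratified_sample(vote, n_samples,
                                          restrict_to_extent=False,
                                          seed=seed + rep)
        pool = sampling.label_from_truth(pool, scene.truth)
        refined, table, t = consensus.refine(scene.products, pool,
                                             scene.census_total, rule)
        ref_f1 = accuracy.metrics(
            accuracy.confusion_from_samples(refined, pool)).f1
        map_f1 = [accuracy.metrics(
            accuracy.confusion_from_samples(m, pool)).f1
            for m in scene.products]
        design = accuracy.design_from_samples(refined, pool)
        total_area = scene.truth.spec.n_rows * scene.truth.spec.n_cols \
            * scene.truth.spec.pixel_size ** 2 / 1e8
        est = accuracy.adjusted_estimates(design, total_area)
        truth_area = float(scene.truth.ones.sum()) \
            * scene.truth.spec.pixel_size ** 2 / 1e8
        records.append({
            "rep": rep, "selected_t": t, "refined_f1": ref_f1,
            "mean_map_f1": float(np.mean(map_f1)),
            "max_map_f1": float(np.max(map_f1)),
            "adjusted_area_1e4ha": est.area[1],
            "area_ci95_1e4ha": est.ci95_area(1),
            "truth_area_1e4ha": truth_area,
        })
    return pd.DataFrame.from_records(records)
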