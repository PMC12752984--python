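"""Synthetic landscape generation for testing the valuation pipeline.

Real applications of the pipeline run on co-registered 30 m rasters of
terrain, soil, location and ecology indicators plus annual climate surfaces.
This module generates stand-ins with the statistical structure the analysis
assumes — spatially autocorrelated continuous fields inside calibrated value
bounds, contiguous categorical patch maps, Euclidean-distance/buffer-derived
locational layers, and overlay-style evaluation units — so every downstream
stage is exercisable without any external download.

Conventions: rasters are row-major float/int arrays with origin at the
top-left corner, on a projected metric grid (default 30 m cells); areas come
from cell counts (cell_size^2 / 10^4 hm^2 per cell) with no geodesic
correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from . import hefei2021

# 4-connectivity structuring element used for both unit components and
# neighbour finding, so "adjacent" means edge-sharing throughout.
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

#: Default five-ring labels for 500 m buffer classifications of distance
#: layers, best (nearest) first.
RING_LABELS_5 = ("Closer", "Close", "Moderate", "Far", "Farther")


# ---------------------------------------------------------------------------
# Grid and layer containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """A regular raster grid in projected metric coordinates.

    The origin is the top-left corner of the top-left cell; rows increase
    southwards.  ``cell_area_hm2`` is cell_size^2 / 10,000.
    """

    nrows: int
    ncols: int
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "EPSG:32650"

    def __post_init__(self) -> None:
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError(
                f"grid must have at least one row and column, got "
                f"{self.nrows}x{self.ncols}"
            )
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_hm2(self) -> float:
        return self.cell_size ** 2 / 1e4


@dataclass
class IndicatorLayer:
    """One gridded indicator: values plus a nodata mask on a common grid."""

    grid: GridSpec
    indicator_id: str
    values: np.ndarray
    nodata_mask: np.ndarray | None = None
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"{self.grid.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.grid.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.grid.shape:
                raise ValueError("nodata_mask shape does not match grid")
        if self.kind == "continuous" and not np.all(
            np.isfinite(self.values[~self.nodata_mask])
        ):
            raise ValueError(f"layer {self.indicator_id}: non-finite values")


@dataclass
class CategoricalLayer:
    """Integer class-id raster with a legend mapping ids to category names."""

    grid: GridSpec
    class_ids: np.ndarray
    legend: dict[int, str]

    def __post_init__(self) -> None:
        self.class_ids = np.asarray(self.class_ids, dtype=np.int64)
        if self.class_ids.shape != self.grid.shape:
            raise ValueError("class_ids shape does not match grid")
        present = set(np.unique(self.class_ids).tolist())
        missing = present - set(self.legend)
        if missing:
            raise ValueError(f"class ids {sorted(missing)} missing from legend")


@dataclass
class UnitMap:
    """Evaluation units from the overlay of land use, soil and admin layers.

    ``labels`` assigns each cell a unit id (0 = background / non-farmland);
    ``units`` is one row per unit with its region, soil and land-use ids and
    area in hm^2.
    """

    grid: GridSpec
    labels: np.ndarray
    units: pd.DataFrame  # columns: unit_id, region_id, soil_id, landuse_id, area_hm2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")
        ids = set(np.unique(self.labels).tolist()) - {0}
        table_ids = set(self.units["unit_id"].tolist())
        if ids != table_ids:
            raise ValueError("unit table does not match label raster")

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def total_area_hm2(self) -> float:
        return float(self.units["area_hm2"].sum())


# ---------------------------------------------------------------------------
# Field and patch generators
# ---------------------------------------------------------------------------

def generate_field(
    grid: GridSpec,
    lo: float,
    hi: float,
    corr_length: float = 300.0,
    seed: int | np.random.Generator = 0,
    indicator_id: str = "field",
) -> IndicatorLayer:
    """Generate a smooth random field with exact bounds [lo, hi].

    White noise is convolved with a Gaussian kernel of scale ``corr_length``
    (metres; truncated at 4 sigma), then affinely rescaled so the sample
    minimum equals ``lo`` and the maximum equals ``hi``.  ``corr_length = 0``
    yields rescaled white noise.  Deterministic per seed.
    """
    if lo >= hi:
        raise ValueError(f"lo must be below hi, got lo={lo}, hi={hi}")
    if corr_length < 0:
        raise ValueError(f"corr_length must be non-negative, got {corr_length}")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(grid.shape)
    if corr_length > 0:
        sigma = corr_length / grid.cell_size
        noise = ndimage.gaussian_filter(noise, sigma=sigma, truncate=4.0,
                                        mode="reflect")
    vmin, vmax = float(noise.min()), float(noise.max())
    if vmax > vmin:
        values = lo + (noise - vmin) * (hi - lo) / (vmax - vmin)
    else:
        # degenerate (e.g. 1x1 grid): no spread to rescale; use the midpoint
        values = np.full(grid.shape, 0.5 * (lo + hi))
    return IndicatorLayer(grid, indicator_id, values, kind="continuous")


def generate_categorical(
    grid: GridSpec,
    legend: Sequence[str],
    patch_scale: float = 300.0,
    seed: int | np.random.Generator = 0,
) -> CategoricalLayer:
    """Generate a contiguous-patch categorical map over the given legend.

    A smooth latent field is cut at equal quantiles into ``len(legend)``
    classes (ids 1..n in legend order), which produces contiguous patches at
    roughly equal area shares.  Deterministic per seed.
    """
    if len(legend) == 0:
        raise ValueError("legend must be non-empty")
    n = len(legend)
    legend_map = {i + 1: name for i, name in enumerate(legend)}
    if n == 1:
        return CategoricalLayer(grid, np.ones(grid.shape, dtype=int), legend_map)
    latent = generate_field(grid, 0.0, 1.0, patch_scale, seed, "latent").values
    edges = np.quantile(latent, np.linspace(0, 1, n + 1)[1:-1])
    class_ids = np.searchsorted(edges, latent, side="right") + 1
    return CategoricalLayer(grid, class_ids, legend_map)


# ---------------------------------------------------------------------------
# Locational derivations: Euclidean distance and buffer rings
# ---------------------------------------------------------------------------

def distance_transform(mask: CategoricalLayer, target_class: int) -> IndicatorLayer:
    """Per-cell Euclidean distance (m, centre-to-centre) to the nearest cell
    of ``target_class``; 0 on target cells."""
    target = mask.class_ids == target_class
    if not target.any():
        raise ValueError(
            f"target class {target_class} does not occur in the layer"
        )
    dist = ndimage.distance_transform_edt(
        ~target, sampling=mask.grid.cell_size
    )
    return IndicatorLayer(mask.grid, f"distance_to_{target_class}",
                          np.asarray(dist, dtype=float), kind="continuous")


def ring_classify(
    distance: IndicatorLayer,
    ring_width: float = 500.0,
    n_rings: int = 5,
    labels: Sequence[str] | None = None,
) -> CategoricalLayer:
    """Classify a distance surface into ``n_rings`` buffer rings.

    Ring k (1-based) covers distances in [(k-1)w, kw); everything at or
    beyond (n_rings-1)w collapses into the outermost ring.  With five rings
    the default labels are the nearest-is-best convenience scale
    ("Closer" ... "Farther").
    """
    if ring_width <= 0:
        raise ValueError("ring_width must be positive")
    if n_rings < 1:
        raise ValueError("n_rings must be at least 1")
    d = distance.values
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    rings = np.minimum(np.floor_divide(d, ring_width).astype(int) + 1, n_rings)
    if labels is None:
        labels = RING_LABELS_5 if n_rings == 5 else tuple(
            f"ring {k}" for k in range(1, n_rings + 1)
        )
    if len(labels) != n_rings:
        raise ValueError("labels length must equal n_rings")
    legend = {k + 1: lab for k, lab in enumerate(labels)}
    return CategoricalLayer(distance.grid, rings, legend)


# ---------------------------------------------------------------------------
# Evaluation units by overlay
# ---------------------------------------------------------------------------

def _check_shared_grid(*layers: CategoricalLayer) -> GridSpec:
    grids = {l.grid for l in layers}
    if len(grids) != 1:
        raise ValueError("layers must share a single GridSpec")
    return layers[0].grid


def build_evaluation_units(
    landuse: CategoricalLayer,
    soil: CategoricalLayer,
    admin: CategoricalLayer,
    min_area_hm2: float = 0.36,
    farmland_classes: Sequence[int] | None = None,
) -> UnitMap:
    """Overlay land use, soil and administrative layers into evaluation units.

    A unit is a 4-connected component of cells sharing an identical
    (landuse, soil, admin) triple, restricted to farmland cells
    (``farmland_classes`` of the land-use legend; default: all cells).
    Components smaller than ``min_area_hm2`` are merged into their largest
    edge-adjacent unit (sliver elimination); isolated slivers with no
    neighbour are kept.  Unit attributes after a merge are the absorbing
    unit's.
    """
    grid = _check_shared_grid(landuse, soil, admin)
    if farmland_classes is None:
        farm = np.ones(grid.shape, dtype=bool)
    else:
        farm = np.isin(landuse.class_ids, np.asarray(list(farmland_classes)))

    labels = np.zeros(grid.shape, dtype=np.int64)
    attrs: dict[int, tuple[int, int, int]] = {}  # unit -> (region, soil, landuse)
    next_id = 1
    triples = np.stack([landuse.class_ids, soil.class_ids, admin.class_ids])
    # label connected components separately within each distinct triple
    flat = (
        triples[0].astype(np.int64) * 10**12
        + triples[1].astype(np.int64) * 10**6
        + triples[2].astype(np.int64)
    )
    for code in np.unique(flat[farm]):
        comp, n = ndimage.label(farm & (flat == code), structure=_STRUCTURE_4)
        for k in range(1, n + 1):
            cells = comp == k
            labels[cells] = next_id
            r, c = np.argwhere(cells)[0]
            attrs[next_id] = (
                int(admin.class_ids[r, c]),
                int(soil.class_ids[r, c]),
                int(landuse.class_ids[r, c]),
            )
            next_id += 1

    labels = _eliminate_slivers(labels, attrs, grid, min_area_hm2)

    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    # compact ids to 1..n
    remap = {old: new for new, old in enumerate(ids, start=1)}
    compact = np.zeros_like(labels)
    for old, new in remap.items():
        compact[labels == old] = new
    units = pd.DataFrame(
        {
            "unit_id": [remap[i] for i in ids],
            "region_id": [attrs[i][0] for i in ids],
            "soil_id": [attrs[i][1] for i in ids],
            "landuse_id": [attrs[i][2] for i in ids],
            "area_hm2": counts * grid.cell_area_hm2,
        }
    ).sort_values("unit_id", ignore_index=True)
    return UnitMap(grid, compact, units)


def _eliminate_slivers(
    labels: np.ndarray,
    attrs: dict[int, tuple[int, int, int]],
    grid: GridSpec,
    min_area_hm2: float,
) -> np.ndarray:
    """Merge units below the area threshold into their largest neighbour."""
    if min_area_hm2 <= 0:
        return labels
    min_cells = min_area_hm2 / grid.cell_area_hm2
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        sizes = dict(zip(ids.tolist(), counts.tolist()))
        small = sorted(
            (i for i in sizes if sizes[i] < min_cells), key=lambda i: sizes[i]
        )
        merged_any = False
        for uid in small:
            cells = labels == uid
            halo = ndimage.binary_dilation(cells, structure=_STRUCTURE_4) & ~cells
            neighbours = np.unique(labels[halo])
            neighbours = neighbours[(neighbours > 0) & (neighbours != uid)]
            if neighbours.size == 0:
                continue  # isolated sliver: kept
            target = max(neighbours.tolist(), key=lambda i: sizes.get(i, 0))
            labels[cells] = target
            merged_any = True
            break  # sizes changed; recompute
        if not merged_any:
            return labels


# ---------------------------------------------------------------------------
# Full landscape bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandscapeConfig:
    """Study conditions for synthetic landscape generation.

    Numeric indicator ranges default to the calibrated value bounds of the
    Hefei membership functions, so generated layers span exactly the fitted
    domain of each scoring function.  The climate defaults (annual mean
    temperature 15-17 degC, annual precipitation 900-1100 mm) are plausible
    for a subtropical monsoon setting and are configuration, not calibrated
    constants.
    """

    grid: GridSpec = field(default_factory=lambda: GridSpec(100, 100))
    indicator_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=hefei2021.indicator_value_ranges
    )
    temperature_range_c: tuple[float, float] = (15.0, 17.0)
    precipitation_range_mm: tuple[float, float] = (900.0, 1100.0)
    corr_length_m: float = 300.0
    # 200 m patches make the triple overlay yield evaluation units of ~5 hm2
    # mean area on the default grid, matching the unit structure the method
    # assumes
    patch_scale_m: float = 200.0
    ring_width_m: float = 500.0
    n_rings: int = 5
    landuse_legend: tuple[str, ...] = ("farmland", "forest", "water", "builtup")
    farmland_classes: tuple[int, ...] = (1,)
    water_class: int = 3
    settlement_class: int = 4
    n_soil_classes: int = 4
    n_admin_regions: int = 3
    min_unit_area_hm2: float = 0.36


@dataclass
class Landscape:
    """Bundle of co-registered synthetic inputs for one pipeline run."""

    grid: GridSpec
    indicators: dict[str, IndicatorLayer | CategoricalLayer]
    temperature: IndicatorLayer
    precipitation: IndicatorLayer
    landuse: CategoricalLayer
    soil: CategoricalLayer
    admin: CategoricalLayer
    units: UnitMap


def generate_landscape(
    config: LandscapeConfig | None = None, seed: int = 0
) -> Landscape:
    """Generate a self-consistent synthetic landscape bundle.

    Produces the 16 indicator layers (ten continuous within their configured
    bounds; terrain/texture/ecology patch maps over their category scales;
    two distance-ring layers derived by Euclidean distance to synthetic water
    bodies and settlements), temperature and precipitation surfaces, the
    land-use/soil/admin overlay layers and the resulting evaluation units.
    Bit-identical for identical (config, seed); sub-layers draw from
    independent streams spawned from the one seed.
    """
    cfg = config or LandscapeConfig()
    grid = cfg.grid
    streams = iter(np.random.SeedSequence(seed).spawn(32))

    indicators: dict[str, IndicatorLayer | CategoricalLayer] = {}
    for iid, (lo, hi) in sorted(cfg.indicator_ranges.items()):
        indicators[iid] = generate_field(
            grid, lo, hi, cfg.corr_length_m,
            np.random.default_rng(next(streams)), iid,
        )
    for iid in ("I1", "I3", "I15", "I16"):
        cats = hefei2021.CONCEPTUAL_CATEGORIES[iid]
        layer = generate_categorical(
            grid, cats, cfg.patch_scale_m, np.random.default_rng(next(streams))
        )
        indicators[iid] = layer

    landuse = generate_categorical(
        grid, cfg.landuse_legend, cfg.patch_scale_m,
        np.random.default_rng(next(streams)),
    )
    # guarantee at least one farmland cell so the unit overlay is non-empty
    ids = landuse.class_ids
    if not np.isin(ids, np.asarray(cfg.farmland_classes)).any():
        rng = np.random.default_rng(next(streams))
        ids[int(rng.integers(grid.nrows)), int(rng.integers(grid.ncols))] = (
            cfg.farmland_classes[0]
        )
    landuse = CategoricalLayer(grid, ids, landuse.legend)

    # locational indicators from Euclidean distance to dedicated feature
    # masks (water bodies, settlements), classified into 500 m buffer rings
    for iid, feature in (("I13", "water"), ("I14", "settlement")):
        mask = generate_categorical(
            grid, ("other", feature), cfg.patch_scale_m,
            np.random.default_rng(next(streams)),
        )
        mids = mask.class_ids
        if not (mids == 2).any():
            rng = np.random.default_rng(next(streams))
            mids[int(rng.integers(grid.nrows)), int(rng.integers(grid.ncols))] = 2
            mask = CategoricalLayer(grid, mids, mask.legend)
        dist = distance_transform(mask, 2)
        rings = ring_classify(dist, cfg.ring_width_m, cfg.n_rings)
        indicators[iid] = rings

    temperature = generate_field(
        grid, *cfg.temperature_range_c, cfg.corr_length_m,
        np.random.default_rng(next(streams)), "T",
    )
    precipitation = generate_field(
        grid, *cfg.precipitation_range_mm, cfg.corr_length_m,
        np.random.default_rng(next(streams)), "R",
    )
    soil = generate_categorical(
        grid, tuple(f"soil {i}" for i in range(1, cfg.n_soil_classes + 1)),
        cfg.patch_scale_m, np.random.default_rng(next(streams)),
    )
    admin = generate_categorical(
        grid, tuple(f"region {i}" for i in range(1, cfg.n_admin_regions + 1)),
        cfg.patch_scale_m * 2, np.random.default_rng(next(streams)),
    )
    units = build_evaluation_units(
        landuse, soil, admin, cfg.min_unit_area_hm2, cfg.farmland_classes
    )
    return Landscape(
        grid=grid,
        indicators=indicators,
        temperature=temperature,
        precipitation=precipitation,
        landuse=landuse,
        soil=soil,
        admin=admin,
        units=units,
    )
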