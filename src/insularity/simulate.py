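"""Synthetic quartz-island archipelagos with known generating truth.

The generator emulates the statistical structure the analysis assumes: a
~47-island archipelago whose areas span ~2.5×10³–8.3×10⁶ m² (log-uniform,
with one island pinned at the maximum as the "mainland equivalent"),
terrain with ridge/slope/plain/valley/drainage structure, bright
low-NDVI island interiors inside a greener matrix whose density varies
per island, and negative-binomial richness driven by log-area, habitat
diversity and hump-shaped matrix-contrast / target-effect terms.

Communities are generated top-down from richness: the analysis consumes
only richness, so drawing counts first keeps the truth bookkeeping exact;
species identities are then filled in with a rank-decay occupancy weight,
giving nested composition.  Every generated bundle satisfies the upstream
type contracts (disjoint interiors, ≥ 1000 m² islands, binary incidence).

All randomness flows from one root seed through named ``SeedSequence``
children, so a bundle is reproducible field by field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon

from . import contrast as mc
from . import geometry as geo
from . import habitats as hab
from . import terrain as ter
from .raster import RasterGrid

__all__ = [
    "SimulationConfig",
    "SyntheticBundle",
    "generate_islands",
    "generate_terrain",
    "generate_imagery",
    "generate_communities",
    "generate_predictor_table",
    "generate_bundle",
    "nb_draw",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic archipelago.

    Areas, island count and imagery resolution reflect the study system
    this generator emulates; the effect sizes are simulation knobs chosen
    to produce strong area/habitat-diversity effects, hump-shaped matrix
    contrast and target effect, and a negligible nearest-neighbour
    distance effect.
    """

    seed: int = 0
    n_islands: int = 47
    n_unsampled: int = 10
    area_range: tuple[float, float] = (2.5e3, 8.3e6)
    min_island_area: float = 1000.0
    extent: float = 25_000.0
    cell_size: float = 2.0
    min_gap: float = 100.0

    # terrain
    terrain_relief: float = 12.0        # m, broad-scale relief amplitude
    terrain_scale: float = 2_000.0      # m, broad correlation length
    terrain_relief_fine: float = 1.5    # m, fine-scale roughness
    terrain_scale_fine: float = 120.0   # m
    island_relief: float = 8.0          # m, per-island ridge/valley template

    # imagery
    ndvi_matrix_mean: float = 0.35
    ndvi_matrix_sd: float = 0.05
    ndvi_island_mean: float = 0.08
    ndvi_island_sd: float = 0.03
    ndvi_scale: float = 60.0            # m, NDVI spatial correlation length
    matrix_density_range: tuple[float, float] = (0.3, 1.5)
    matrix_halo: float = 100.0          # m, reach of the per-island density halo

    # communities
    effects: dict = field(
        default_factory=lambda: {
            "beta0_gr": 3.7,
            "beta0_qs": 1.9,
            "beta_logA": 0.55,
            "beta_hdi": 0.4,
            "beta_mc": 0.15,
            "beta_mc2": -0.2,
            "beta_te": 0.15,
            "beta_te2": -0.3,
        }
    )
    theta: float = 6.0
    specialist_fraction: float = 0.15
    pool_size: int = 600
    occupancy_decay: float = 5.0

    def __post_init__(self) -> None:
        lo, hi = self.area_range
        if not (0 < lo < hi) or not math.isfinite(hi):
            raise ValueError("area_range must be finite with min < max")
        if self.n_islands < 2:
            raise ValueError("need at least 2 islands")
        if not (0 < self.specialist_fraction < 1):
            raise ValueError("specialist_fraction must be in (0, 1)")
        if self.theta <= 0:
            raise ValueError("theta must be positive")

    def rngs(self, *names: str) -> list[np.random.Generator]:
        """Named child generators derived from the root seed."""
        root = np.random.SeedSequence(self.seed)
        children = root.spawn(8)
        order = ("islands", "terrain", "imagery", "communities", "jenks", "extra1", "extra2", "extra3")
        table = dict(zip(order, children))
        return [np.random.Generator(np.random.PCG64(table[n])) for n in names]


@dataclass
class SyntheticBundle:
    archipelago: geo.Archipelago
    dem: RasterGrid
    red: RasterGrid
    nir: RasterGrid
    community: pd.DataFrame
    traits: pd.Series
    predictors: pd.DataFrame
    truth: dict


# --------------------------------------------------------------------------
# islands

def _blob(center: np.ndarray, target_area: float, rng: np.random.Generator) -> Polygon:
    """A convex-ish star-shaped polygon rescaled exactly to target_area."""
    n_vert = 24
    ang = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    wob = rng.normal(0, 1, n_vert)
    # circular smoothing keeps the radius function continuous at 2π
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 1.5) ** 2)
    kernel /= kernel.sum()
    wob = np.convolve(np.r_[wob[-4:], wob, wob[:4]], kernel, mode="same")[4:-4]
    radii = 1.0 + 0.35 * wob
    radii = np.maximum(radii, 0.3)
    pts = np.column_stack([np.cos(ang), np.sin(ang)]) * radii[:, None]
    poly = Polygon(pts).buffer(0)
    scale = math.sqrt(target_area / poly.area)
    pts = shapely.get_coordinates(poly) * scale + center
    return Polygon(pts)


def generate_islands(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> geo.Archipelago:
    """Rejection-place ``n_islands`` sampled + ``n_unsampled`` small
    unsampled islands with pairwise edge gaps ≥ ``min_gap``.

    Areas are log-uniform over ``area_range``; the first sampled island is
    pinned at the maximum area (the mainland equivalent).  Unsampled
    islands are log-uniform over [1000 m², 10⁵ m²] — the ≥ 1000 m² floor
    every catalogued island respects.
    """
    (rng,) = (rng,) if rng is not None else cfg.rngs("islands")
    lo, hi = cfg.area_range
    areas = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_islands))
    areas[0] = hi
    extra = np.exp(rng.uniform(np.log(max(cfg.min_island_area, 1.0)), np.log(1e5), cfg.n_unsampled))
    specs = [(f"isl_{i:03d}", a, True) for i, a in enumerate(areas)]
    specs += [(f"uns_{i:03d}", a, False) for i, a in enumerate(extra)]
    specs.sort(key=lambda t: -t[1])  # place big islands first

    placed: list[geo.IslandPolygon] = []
    placed_geoms: list[Polygon] = []
    for iid, area, sampled in specs:
        r_eq = math.sqrt(area / math.pi) * 1.5  # generous bounding radius
        ok = False
        for _ in range(4000):
            c = rng.uniform(r_eq, cfg.extent - r_eq, 2) if cfg.extent > 2 * r_eq else None
            if c is None:
                break
            poly = _blob(c, area, rng)
            x0, y0, x1, y1 = poly.bounds
            if x0 < 0 or y0 < 0 or x1 > cfg.extent or y1 > cfg.extent:
                continue
            if all(poly.distance(g) >= cfg.min_gap for g in placed_geoms):
                placed.append(geo.IslandPolygon(iid, poly, sampled))
                placed_geoms.append(poly)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place island {iid!r} (area {area:.3g} m²); "
                "increase extent or reduce n_islands/min_gap"
            )
    placed.sort(key=lambda i: i.id)
    return geo.Archipelago(placed, crs="synthetic-metric")


# --------------------------------------------------------------------------
# rasters

def _scene_grid(cfg: SimulationConfig) -> tuple[int, float]:
    n = int(round(cfg.extent / cfg.cell_size))
    return n, cfg.cell_size


def _correlated_field(n: int, sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance smoothed Gaussian random field."""
    white = rng.normal(0, 1, (n, n))
    if sigma_cells <= 0:
        return white
    f = ndimage.gaussian_filter(white, sigma_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else np.zeros_like(f)


def _island_window_mask(grid: RasterGrid, poly: Polygon, pad: float = 0.0):
    """(row slice, col slice, boolean mask) of cells whose centre is inside
    ``poly`` (dilated by ``pad``), restricted to the bounding window."""
    b = shapely.buffer(poly, pad) if pad > 0 else poly
    x0, y0, x1, y1 = b.bounds
    gx0, gy0, gx1, gy1 = grid.bounds
    win = grid.window(max(x0, gx0), max(y0, gy0), min(x1, gx1), min(y1, gy1))
    nrows, _ = grid.shape
    r0 = int(round((grid.bounds[3] - win.bounds[3]) / grid.cell))
    c0 = int(round((win.xll - grid.xll) / grid.cell))
    xs, ys = win.cell_centers()
    X, Y = np.meshgrid(xs, ys)
    m = shapely.contains_xy(b, X.ravel(), Y.ravel()).reshape(X.shape)
    return slice(r0, r0 + win.shape[0]), slice(c0, c0 + win.shape[1]), m


def generate_terrain(
    cfg: SimulationConfig, arch: geo.Archipelago, rng: np.random.Generator | None = None
) -> RasterGrid:
    """DEM = broad + fine smoothed Gaussian fields + a regional tilt +
    per-island tent templates (alternating ridge / valley through the
    island centroid) so the default habitat rules see several classes on
    large islands."""
    (rng,) = (rng,) if rng is not None else cfg.rngs("terrain")
    n, cell = _scene_grid(cfg)
    z = cfg.terrain_relief * _correlated_field(n, cfg.terrain_scale / cell, rng)
    z = z + cfg.terrain_relief_fine * _correlated_field(n, cfg.terrain_scale_fine / cell, rng)
    xs = (np.arange(n) + 0.5) * cell
    z = z + 0.002 * xs[None, :] + 100.0  # gentle regional tilt, positive datum
    grid = RasterGrid(z, 0.0, 0.0, cell, crs="synthetic-metric")

    if cfg.island_relief > 0:
        for k, isl in enumerate(arch):
            rs, cs, m = _island_window_mask(grid, isl.geometry)
            if not m.any():
                continue
            cx, cy = isl.geometry.centroid.x, isl.geometry.centroid.y
            theta = rng.uniform(0, np.pi)
            ux, uy = -math.sin(theta), math.cos(theta)  # ridge line direction normal
            half = 0.5 * math.sqrt(isl.geometry.area / math.pi)
            xs_w = grid.xll + (np.arange(cs.start, cs.stop) + 0.5) * cell
            ys_w = grid.yll + (grid.shape[0] - np.arange(rs.start, rs.stop) - 0.5) * cell
            X, Y = np.meshgrid(xs_w, ys_w)
            d = np.abs((X - cx) * ux + (Y - cy) * uy)
            tent = np.maximum(0.0, 1.0 - d / max(half, cell))
            sign = 1.0 if k % 2 == 0 else -1.0
            amp = cfg.island_relief * rng.uniform(0.6, 1.4)
            patch = grid.values[rs, cs]
            patch[m] += sign * amp * tent[m]
            grid.values[rs, cs] = patch
    return grid


def generate_imagery(
    cfg: SimulationConfig, arch: geo.Archipelago, rng: np.random.Generator | None = None
) -> tuple[RasterGrid, RasterGrid]:
    """Red/NIR bands back-solved from a target NDVI field: a green matrix
    with per-island density halos, and bright quartz-gravel island
    interiors with low NDVI."""
    (rng,) = (rng,) if rng is not None else cfg.rngs("imagery")
    n, cell = _scene_grid(cfg)
    noise = _correlated_field(n, cfg.ndvi_scale / cell, rng)
    ndvi = cfg.ndvi_matrix_mean + cfg.ndvi_matrix_sd * noise
    brightness = np.full((n, n), 0.5)
    grid = RasterGrid(ndvi, 0.0, 0.0, cell, crs="synthetic-metric")

    lo_m, hi_m = cfg.matrix_density_range
    multipliers = {}
    for isl in arch:
        multipliers[isl.id] = float(rng.uniform(lo_m, hi_m))
    # halos first (island interiors overwrite them afterwards)
    for isl in arch:
        rs, cs, m = _island_window_mask(grid, isl.geometry, pad=cfg.matrix_halo)
        patch = grid.values[rs, cs]
        patch[m] *= multipliers[isl.id]
        grid.values[rs, cs] = patch
    island_noise = _correlated_field(n, cfg.ndvi_scale / cell, rng)
    for isl in arch:
        rs, cs, m = _island_window_mask(grid, isl.geometry)
        patch = grid.values[rs, cs]
        patch[m] = cfg.ndvi_island_mean + cfg.ndvi_island_sd * island_noise[rs, cs][m]
        grid.values[rs, cs] = patch
        bpatch = brightness[rs, cs]
        bpatch[m] = 0.8  # quartz gravel is bright
        brightness[rs, cs] = bpatch

    ndvi_t = np.clip(grid.values, -0.95, 0.95)
    red = brightness * (1.0 - ndvi_t) / 2.0
    nir = brightness * (1.0 + ndvi_t) / 2.0
    red_g = RasterGrid(red, 0.0, 0.0, cell, crs="synthetic-metric")
    nir_g = RasterGrid(nir, 0.0, 0.0, cell, crs="synthetic-metric")
    red_g._matrix_multipliers = multipliers  # truth bookkeeping for tests
    return red_g, nir_g


# --------------------------------------------------------------------------
# communities

def nb_draw(mu: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """NB2 counts with mean ``mu`` and size ``theta`` (Poisson limit for
    very large theta)."""
    mu = np.asarray(mu, dtype=float)
    if theta >= 1e6:
        return rng.poisson(mu)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_communities(
    cfg: SimulationConfig,
    predictors: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Draw island communities from NB richness models on the predictors.

    ``predictors`` needs columns area_m2, hdi, matrix_contrast,
    target_effect (one row per sampled island).  Latent log-means:

        eta_GR = b0_gr + b_logA z(log10 A) + b_mc z(MC) + b_mc2 z(MC)^2
        eta_QS = b0_qs + b_logA z(log10 A) + b_hdi z(HDI)
                 + b_mc z(MC) + b_mc2 z(MC)^2 + b_te z(TE) + b_te2 z(TE)^2

    GR_i ~ NB(e^eta_GR, theta) generalists are then drawn without
    replacement from the generalist pool with rank-decay weights (nested
    composition), and likewise QS_i specialists from the specialist pool.
    Returns (community matrix, trait flags, truth record).
    """
    (rng,) = (rng,) if rng is not None else cfg.rngs("communities")
    e = cfg.effects
    ids = predictors["island_id"].astype(str).to_numpy()
    zA = _zscore(np.log10(predictors["area_m2"].to_numpy(dtype=float)))
    zH = _zscore(predictors["hdi"].to_numpy(dtype=float))
    zM = _zscore(predictors["matrix_contrast"].to_numpy(dtype=float))
    zT = _zscore(predictors["target_effect"].to_numpy(dtype=float))

    eta_gr = e["beta0_gr"] + e["beta_logA"] * zA + e["beta_mc"] * zM + e["beta_mc2"] * zM**2
    eta_qs = (
        e["beta0_qs"] + e["beta_logA"] * zA + e["beta_hdi"] * zH
        + e["beta_mc"] * zM + e["beta_mc2"] * zM**2
        + e["beta_te"] * zT + e["beta_te2"] * zT**2
    )
    gr = nb_draw(np.exp(eta_gr), cfg.theta, rng)
    qs = nb_draw(np.exp(eta_qs), cfg.theta, rng)

    n_spec = int(round(cfg.pool_size * cfg.specialist_fraction))
    n_gen = cfg.pool_size - n_spec
    if gr.max() > n_gen or qs.max() > n_spec:
        raise ValueError(
            f"drawn richness exceeds the species pool "
            f"(max GR {gr.max()} vs {n_gen}, max QS {qs.max()} vs {n_spec}); enlarge pool_size"
        )
    gen_ids = [f"gen_{i:04d}" for i in range(n_gen)]
    spec_ids = [f"spec_{i:04d}" for i in range(n_spec)]

    def weights(npool: int) -> np.ndarray:
        w = np.exp(-cfg.occupancy_decay * np.arange(npool) / npool)
        return w / w.sum()

    w_gen, w_spec = weights(n_gen), weights(n_spec)
    cm = pd.DataFrame(
        0, index=pd.Index(ids, name="island_id"), columns=gen_ids + spec_ids, dtype=int
    )
    for i, isl in enumerate(ids):
        if gr[i] > 0:
            chosen = rng.choice(n_gen, size=int(gr[i]), replace=False, p=w_gen)
            cm.loc[isl, [gen_ids[j] for j in chosen]] = 1
        if qs[i] > 0:
            chosen = rng.choice(n_spec, size=int(qs[i]), replace=False, p=w_spec)
            cm.loc[isl, [spec_ids[j] for j in chosen]] = 1
    traits = pd.Series(
        [False] * n_gen + [True] * n_spec, index=gen_ids + spec_ids, name="quartz_specialist"
    )
    truth = {
        "effects": dict(e),
        "theta": cfg.theta,
        "eta_gr": eta_gr.tolist(),
        "eta_qs": eta_qs.tolist(),
        "gr": gr.tolist(),
        "qs": qs.tolist(),
        "island_id": list(ids),
        "z_predictors": {"logA": zA.tolist(), "hdi": zH.tolist(), "mc": zM.tolist(), "te": zT.tolist()},
    }
    return cm, traits, truth


def generate_predictor_table(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Predictor-level shortcut for repeated simulation studies.

    Draws the five predictors directly from distributions matching the
    full raster scene — log-uniform areas, HDI and nearest-neighbour
    distance mildly correlated with area, a target effect built from a
    lognormal distance-to-main-island so its negative correlation with
    area is structural — skipping terrain/imagery synthesis.  Use
    :func:`generate_bundle` when the raster stages themselves are under
    test.
    """
    (rng,) = (rng,) if rng is not None else cfg.rngs("communities")
    lo, hi = cfg.area_range
    n = cfg.n_islands
    area = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    area[0] = hi
    zA = _zscore(np.log10(area))
    hdi = np.exp(0.18 + 0.08 * zA + 0.08 * rng.normal(size=n))
    dmi = np.exp(rng.normal(np.log(600.0), 0.9, n))
    dmi[0] = 0.0
    te = np.array([geo.target_effect(a, d) for a, d in zip(area, dmi)])
    nn = np.exp(rng.normal(np.log(150.0), 0.7, n))
    mcv = np.maximum(rng.normal(0.5, 0.15, n), 0.05)
    return pd.DataFrame(
        {
            "island_id": [f"isl_{i:03d}" for i in range(n)],
            "area_m2": area,
            "hdi": hdi,
            "nn_dist_m": nn,
            "dmi_m": dmi,
            "target_effect": te,
            "matrix_contrast": mcv,
        }
    )


# --------------------------------------------------------------------------
# the full loop

def generate_bundle(
    cfg: SimulationConfig,
    habitat_rules: hab.HabitatRules = hab.HabitatRules(),
    jenks_k: int = mc.DEFAULT_N_CLASSES,
    buffer_width: float = mc.DEFAULT_BUFFER_WIDTH,
) -> SyntheticBundle:
    """Generate a full synthetic scene and close the loop: the community
    model consumes predictors computed from the scene by the *real*
    predictor modules, not the generator's internal quantities."""
    rng_isl, rng_ter, rng_img, rng_com = cfg.rngs(
        "islands", "terrain", "imagery", "communities"
    )
    arch = generate_islands(cfg, rng_isl)
    dem = generate_terrain(cfg, arch, rng_ter)
    red, nir = generate_imagery(cfg, arch, rng_img)

    geom = geo.predictor_geometry_table(arch)
    stack = ter.terrain_derivatives(dem)
    het = hab.heterogeneity_table(arch.sampled(), stack, habitat_rules)
    ndvi = mc.compute_ndvi(red, nir)
    # root seed directly: keeps breaks identical to a separate
    # compute-predictors run with the same seed
    breaks = mc.scene_breaks(ndvi, jenks_k, seed=cfg.seed)
    cgrid = mc.classify_grid(ndvi, breaks)
    mctab = mc.matrix_contrast_table(cgrid, arch, width=buffer_width)
    predictors = geom.merge(het, on="island_id").merge(mctab, on="island_id")

    community, traits, truth = generate_communities(cfg, predictors, rng_com)
    return SyntheticBundle(
        archipelago=arch,
        dem=dem,
        red=red,
        nir=nir,
        community=community,
        traits=traits,
        predictors=predictors,
        truth=truth,
    )
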