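"""End-to-end orchestration: predictors → diversity → SAR → GLM chain.

A :class:`PipelineConfig` (usually loaded from YAML) either points at real
inputs — island polygons (GeoJSON), DEM and red/NIR rasters (ASCII grid),
community and trait CSVs — or carries a ``simulate`` block, in which case
the synthetic generator produces the same inputs in memory.  One root
seed drives every stochastic stage.

``run_pipeline`` writes predictors.csv, diversity.csv, sar_fits.csv,
glm_single.csv, glm_selection.csv, glm_final.csv and run.log into the
output directory.  Stage functions are public so subcommands and tests
can run them individually with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import contrast as mc
from . import geometry as geo
from . import glm
from . import habitats as hab
from . import io as gio
from . import sar
from . import simulate as sim
from . import terrain as ter
from .raster import read_ascii_grid

__all__ = ["PipelineConfig", "run_pipeline", "compute_predictors", "fit_glm_chain"]

log = logging.getLogger("insularity")

RESPONSE_FAMILIES = {"gr": "nb", "qs": "nb", "qs_pct": "binomial"}
PREDICTOR_COLUMNS = ["area_m2", "hdi", "nn_dist_m", "target_effect", "matrix_contrast"]


@dataclass
class PipelineConfig:
    """Paths + parameters for one pipeline run.

    Exactly one of (real input paths, ``simulate`` block) must be
    provided.  All thresholds must be positive.
    """

    out_dir: str = "insularity_out"
    seed: int = 0

    # real inputs
    polygons: str | None = None
    dem: str | None = None
    red: str | None = None
    nir: str | None = None
    ndvi: str | None = None          # precomputed NDVI, replaces red+nir
    community: str | None = None
    traits: str | None = None
    crs: str | None = None

    # synthetic block: overrides for SimulationConfig fields
    simulate: dict | None = None

    # parameters
    buffer_width: float = mc.DEFAULT_BUFFER_WIDTH
    jenks_k: int = mc.DEFAULT_N_CLASSES
    jenks_max_sample: int = 10_000
    vif_threshold: float = glm.VIF_THRESHOLD
    alpha: float = glm.ALPHA_SIG
    epsilon: float = geo.DEFAULT_EPSILON
    tpi_window: float = 50.0
    tpi_threshold: float = 0.5
    slope_threshold: float = 5.0
    drainage_threshold: float = 50.0
    min_patch_cells: int = 4
    mask_other_islands: bool = False
    overdispersion_ratio: float = 1.5
    responses: tuple[str, ...] = ("gr", "qs", "qs_pct")

    def __post_init__(self) -> None:
        for name in ("buffer_width", "vif_threshold", "alpha", "epsilon", "tpi_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        have_real = self.polygons is not None
        if have_real == (self.simulate is not None):
            raise ValueError("provide either real input paths or a 'simulate' block (exactly one)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "responses" in doc:
            doc["responses"] = tuple(doc["responses"])
        return cls(**doc)

    def habitat_rules(self) -> hab.HabitatRules:
        return hab.HabitatRules(
            tpi_threshold=self.tpi_threshold,
            slope_threshold=self.slope_threshold,
            drainage_threshold=self.drainage_threshold,
            min_patch_cells=self.min_patch_cells,
        )

    def simulation_config(self) -> sim.SimulationConfig:
        overrides = dict(self.simulate or {})
        overrides.setdefault("seed", self.seed)
        if "area_range" in overrides:
            overrides["area_range"] = tuple(overrides["area_range"])
        return sim.SimulationConfig(**overrides)


# --------------------------------------------------------------------------
# input loading

def _load_inputs(cfg: PipelineConfig):
    """Returns (archipelago, dem, ndvi_grid, community, traits)."""
    if cfg.simulate is not None:
        bundle = sim.generate_bundle(
            cfg.simulation_config(),
            habitat_rules=cfg.habitat_rules(),
            jenks_k=cfg.jenks_k,
            buffer_width=cfg.buffer_width,
        )
        ndvi = mc.compute_ndvi(bundle.red, bundle.nir)
        return bundle.archipelago, bundle.dem, ndvi, bundle.community, bundle.traits, bundle

    arch = gio.read_archipelago(cfg.polygons, crs=cfg.crs)
    dem = read_ascii_grid(cfg.dem, crs=arch.crs) if cfg.dem else None
    if cfg.ndvi:
        ndvi = read_ascii_grid(cfg.ndvi, crs=arch.crs)
    elif cfg.red and cfg.nir:
        red = read_ascii_grid(cfg.red, crs=arch.crs)
        nir = read_ascii_grid(cfg.nir, crs=arch.crs)
        ndvi = mc.compute_ndvi(red, nir)
    else:
        raise ValueError("need either an NDVI raster or red+nir rasters")
    if dem is not None and dem.cell != ndvi.cell:
        log.info("DEM cell %.3g m differs from imagery cell %.3g m", dem.cell, ndvi.cell)
    cm = pd.read_csv(cfg.community, index_col=0)
    traits_df = pd.read_csv(cfg.traits)
    traits = traits_df.set_index(traits_df.columns[0]).iloc[:, 0].astype(bool)
    return arch, dem, ndvi, cm, traits, None


# --------------------------------------------------------------------------
# stages

def compute_predictors(
    arch: geo.Archipelago,
    dem,
    ndvi,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """The five-predictor table for all sampled islands."""
    geom = geo.predictor_geometry_table(arch, epsilon=cfg.epsilon)
    stack = ter.terrain_derivatives(dem, tpi_window=cfg.tpi_window)
    het = hab.heterogeneity_table(arch.sampled(), stack, cfg.habitat_rules())
    breaks = mc.scene_breaks(ndvi, cfg.jenks_k, max_sample=cfg.jenks_max_sample, seed=cfg.seed)
    cgrid = mc.classify_grid(ndvi, breaks)
    mctab = mc.matrix_contrast_table(
        cgrid, arch, width=cfg.buffer_width, mask_other_islands=cfg.mask_other_islands
    )
    return geom.merge(het, on="island_id").merge(mctab, on="island_id")


def fit_sar_stage(predictors: pd.DataFrame, diversity: pd.DataFrame) -> pd.DataFrame:
    merged = predictors.merge(diversity.reset_index(), on="island_id")
    frames = []
    for response in ("gr", "qs"):
        fit = sar.fit_power_sar(merged["area_m2"], merged[response])
        frames.append(fit.to_frame(response))
    return pd.concat(frames, ignore_index=True)


def fit_glm_chain(
    predictors: pd.DataFrame,
    diversity: pd.DataFrame,
    cfg: PipelineConfig,
    response: str,
):
    """screen → standardize → scan → dredge → finalize for one response.

    Returns (scan table, selection table, final fit, screened flags)."""
    family = RESPONSE_FAMILIES[response]
    merged = predictors.merge(diversity.reset_index(), on="island_id")
    trials = None
    if response == "qs_pct":
        keep = merged["total_richness"] > 0
        merged = merged.loc[keep]
        y = merged["qs"].to_numpy()
        trials = merged["total_richness"].to_numpy()
    else:
        y = merged[response].to_numpy()

    pt = merged[PREDICTOR_COLUMNS].copy()
    screened, flags = glm.screen_transform(pt, alpha=cfg.alpha, on_domain_error="keep")
    z = glm.standardize(screened)

    scan = glm.single_predictor_scan(y, z, family, trials=trials, alpha=cfg.alpha)
    terms = glm.candidate_terms_from_scan(scan, alpha=cfg.alpha)
    table, best = glm.dredge_aicc(y, z, terms, family, trials=trials)
    final = glm.finalize_model(
        best, y, z, family, trials=trials, alpha=cfg.alpha,
        vif_threshold=cfg.vif_threshold, log=log.info,
    )
    return scan, table, final, flags


def _final_frame(final: glm.GLMFit, response: str, flags: dict) -> pd.DataFrame:
    rows = []
    for name in final.params.index:
        rows.append(
            {
                "response": response,
                "family": final.family,
                "term": name,
                "coef": final.params[name],
                "se": final.bse[name],
                "p_value": final.pvalues[name],
                "theta": final.theta if final.theta is not None else np.nan,
                "aicc": final.aicc,
                "pseudo_r2": final.pseudo_r2,
                "n": final.n,
                "transformed": ",".join(k for k, v in flags.items() if v),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write the result tables.

    Returns a dict with the in-memory tables and fits.  Any stage error
    propagates (no partial outputs are left behind on validation errors,
    which fire before writing starts)."""
    out = Path(cfg.out_dir)
    arch, dem, ndvi, cm, traits, bundle = _load_inputs(cfg)
    if dem is None:
        raise ValueError("pipeline needs a DEM (habitat diversity stage)")

    if bundle is not None:
        # generate_bundle already ran the predictor modules with this config
        predictors = bundle.predictors
    else:
        predictors = compute_predictors(arch, dem, ndvi, cfg)
    diversity = comm.compute_diversity(cm, traits)
    missing = set(predictors["island_id"]) - set(diversity.index.astype(str))
    if missing:
        raise ValueError(f"community matrix is missing sampled islands: {sorted(missing)}")

    sar_fits = fit_sar_stage(predictors, diversity)
    scans, selections, finals = [], [], []
    for response in cfg.responses:
        scan, table, final, flags = fit_glm_chain(predictors, diversity, cfg, response)
        scans.append(scan.assign(response=response))
        selections.append(table.assign(response=response))
        finals.append(_final_frame(final, response, flags))
    glm_single = pd.concat(scans, ignore_index=True)
    glm_selection = pd.concat(selections, ignore_index=True)
    glm_final = pd.concat(finals, ignore_index=True)

    out.mkdir(parents=True, exist_ok=True)
    predictors.to_csv(out / "predictors.csv", index=False)
    diversity.to_csv(out / "diversity.csv")
    sar_fits.to_csv(out / "sar_fits.csv", index=False)
    glm_single.to_csv(out / "glm_single.csv", index=False)
    glm_selection.to_csv(out / "glm_selection.csv", index=False)
    glm_final.to_csv(out / "glm_final.csv", index=False)
    totals = comm.archipelago_totals(cm, traits)
    with open(out / "run.log", "w") as fh:
        from . import __version__

        fh.write(f"insularity {__version__}\nseed {cfg.seed}\n")
        fh.write(f"islands sampled {len(arch.sampled())} / total {len(arch)}\n")
        fh.write(f"species total {totals[0]} specialists {totals[1]}\n")
        fh.write(f"responses {list(cfg.responses)}\n")
    return {
        "archipelago": arch,
        "predictors": predictors,
        "diversity": diversity,
        "sar_fits": sar_fits,
        "glm_single": glm_single,
        "glm_selection": glm_selection,
        "glm_final": glm_final,
        "totals": totals,
        "bundle": bundle,
    }
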