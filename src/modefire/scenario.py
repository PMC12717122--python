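"""A self-contained demonstration world for the full pipeline.

Builds a coarse global grid whose SLP/SST fields embed latent modes at
exactly the locations the shipped catalogue recipes look for them (the
SOI pressure dipole, the Indian-Ocean SST dipole, the tropical North
Atlantic box), plus a small continental fire grid whose counts respond
to those modes with known log-rate coefficients, seasonal shifts, and a
one-year-lagged effect. Running the index recipes and the association
model on this world recovers the prescribed structure, which is what the
smoke tests, the worked example and the pipeline driver exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .grids import GridSpec
from .synthetic import (EffectSpec, ModeSpec, ModeTruth, generate_fields,
                        generate_fire_counts, generate_mode_truth)

__all__ = ["DemoWorld", "build_demo_world", "box_loading", "seasonal_profile"]


def box_loading(grid: GridSpec, box, value: float,
                base: np.ndarray | None = None) -> np.ndarray:
    """Fill a lat-lon box of the loading pattern with ``value``."""
    out = np.zeros(grid.shape) if base is None else base
    lat_min, lat_max, lon_min, lon_max = box
    lon = ((grid.lon + 180.0) % 360.0) - 180.0
    lon_min = ((lon_min + 180.0) % 360.0) - 180.0
    lon_max = ((lon_max + 180.0) % 360.0) - 180.0
    in_lat = (grid.lat >= lat_min) & (grid.lat <= lat_max)
    if lon_min <= lon_max:
        in_lon = (lon >= lon_min) & (lon <= lon_max)
    else:
        in_lon = (lon >= lon_min) | (lon <= lon_max)
    out[np.ix_(in_lat, in_lon)] = value
    return out


def seasonal_profile(peak_month: int = 7, width: float = 2.0,
                     annual_total: float = 60.0) -> np.ndarray:
    """A unimodal 12-month rate profile (circular Gaussian bump)."""
    m = np.arange(1, 13)
    d = np.minimum(np.abs(m - peak_month), 12 - np.abs(m - peak_month))
    prof = np.exp(-0.5 * (d / width) ** 2)
    return prof / prof.sum() * annual_total


@dataclass
class DemoWorld:
    """Everything the pipeline needs, with the ground truth attached."""

    world_grid: GridSpec
    fire_grid: GridSpec
    truth: list[ModeTruth]
    effects: list[EffectSpec]
    slp: xr.DataArray
    sst: xr.DataArray
    fire_counts: xr.DataArray
    beta_maps: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def truth_record(self) -> dict:
        """JSON-serializable record of the prescribed structure."""
        return {
            "seed": self.seed,
            "modes": [
                {"mode_id": t.mode_id, "ar1": t.ar1} for t in self.truth
            ],
            "effects": [
                {"mode_id": e.mode_id, "lag": e.lag,
                 "season_shift": e.season_shift, "season_amp": e.season_amp,
                 "beta_mean": float(np.mean(e.beta))}
                for e in self.effects
            ],
        }


def build_demo_world(n_members: int = 25, n_years: int = 10, seed: int = 0,
                     noise_sd: float = 0.3,
                     enso_iod_corr: float = -0.61) -> DemoWorld:
    """Construct the demonstration ensemble.

    Three latent modes: ENSO (SOI pressure dipole, AR(1) 0.3), IOD
    (Indian-Ocean SST dipole) correlated with ENSO at ``enso_iod_corr``
    (the coupling the multimode regression must disentangle), and TNA
    (tropical North Atlantic SST box, AR(1) 0.5) acting on fires with a
    one-year lag. ENSO also shifts the fire season by +0.4 months per
    unit index in the cells it loads.
    """
    world = GridSpec(lat=np.arange(-85.0, 86.0, 10.0),
                     lon=np.arange(-175.0, 176.0, 10.0))
    fire_grid = GridSpec.regular(10, 15)

    # loadings at the catalogue recipe locations
    enso_slp = box_loading(world, (-5, 5, 90, 140), 1.0)
    enso_slp = box_loading(world, (-5, 5, -130, -80), -1.0, base=enso_slp)
    iod_sst = box_loading(world, (-10, 10, 50, 70), 1.0)
    iod_sst = box_loading(world, (-10, 0, 90, 110), -1.0, base=iod_sst)
    tna_sst = box_loading(world, (5, 25, -55, -15), 1.0)

    modes = [
        ModeSpec("ENSO", ar1=0.3, loading_slp=enso_slp),
        ModeSpec("IOD", ar1=0.2, loading_sst=iod_sst),
        ModeSpec("TNA", ar1=0.5, loading_sst=tna_sst),
    ]
    corr = np.eye(3)
    corr[0, 1] = corr[1, 0] = enso_iod_corr
    truth = generate_mode_truth(n_members, n_years, modes, seed=seed,
                                correlation=corr)
    slp, sst = generate_fields(truth, world, noise_sd=noise_sd, seed=seed + 1)

    # fire response: ENSO positive (La Nina side) over the western half,
    # lagged TNA over the southern rows, IOD nowhere (its apparent
    # single-mode effect must come only through the ENSO correlation)
    n_lat, n_lon = fire_grid.shape
    beta_enso = np.zeros(fire_grid.shape)
    beta_enso[:, : n_lon // 2] = 0.25
    beta_tna = np.zeros(fire_grid.shape)
    beta_tna[: n_lat // 2, :] = 0.2
    effects = [
        EffectSpec("ENSO", beta=beta_enso, season_shift=0.4),
        EffectSpec("TNA", beta=beta_tna, lag=1),
    ]
    profile = seasonal_profile()[:, None, None] * np.ones((1, n_lat, n_lon))
    counts = generate_fire_counts(truth, effects, profile, seed=seed + 2,
                                  grid=fire_grid)
    return DemoWorld(world_grid=world, fire_grid=fire_grid, truth=truth,
                     effects=effects, slp=slp, sst=sst, fire_counts=counts,
                     beta_maps={"ENSO": beta_enso, "TNA": beta_tna},
                     seed=seed)
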