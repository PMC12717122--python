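"""Association between annual fire counts and climate-mode indices.

The central object is :class:`FireModeModel`, built from a cube of fire
counts and a set of annual mode index series, in the fit/results idiom of
statistical modelling packages: ``model.fit("ENSO")`` runs the per-cell
ordinary-least-squares regression of annual counts on the (raw) index
value, pooling all member-years as exchangeable samples, and returns a
:class:`FireModeResults` carrying slope and p-value maps, the
false-discovery-rate significance mask (Benjamini-Hochberg step-up, the
Wilks field-significance procedure), areal-extent accounting, and
phase-conditional effect-ratio maps. ``model.fit_multimode([...])`` runs
the per-cell multiple regression of counts relative to the cell mean on
standardized indices, which disentangles correlated modes.

Free functions expose the individual pieces (``regress_cells``,
``field_significance``, ``aggregate_fires``, ``phase_ratio_map``,
``cross_phase_table``, ``climate_change_effect``) for use outside the
model object.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grids import coslat_weights
from .indices import (PHASE_NEGATIVE, PHASE_NEUTRAL, PHASE_POSITIVE,
                      standardize_series)

__all__ = [
    "FireModeModel",
    "FireModeResults",
    "MultiModeResults",
    "regress_cells",
    "field_significance",
    "aggregate_fires",
    "phase_ratio_map",
    "driver_phase_ratio",
    "cross_phase_table",
    "climate_change_effect",
]

_PHASE_NAMES = {PHASE_POSITIVE: "positive", PHASE_NEUTRAL: "neutral",
                PHASE_NEGATIVE: "negative"}


# ---------------------------------------------------------------------------
# building blocks

def regress_cells(x: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-cell OLS of Y on x with intercept.

    Parameters
    ----------
    x : (n,) predictor (shared across cells)
    Y : (n, m) responses, one column per cell

    Returns (slope, p) per cell, the two-sided p-value for slope = 0.
    Degenerate cells: a perfect fit gives p = 0; a constant response
    gives slope 0, p = 1.
    """
    x = np.asarray(x, float)
    Y = np.asarray(Y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired samples")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx <= 0:
        raise ValueError("predictor has zero variance")
    Yc = Y - Y.mean(axis=0)
    slope = xc @ Yc / sxx
    resid = Yc - np.outer(xc, slope)
    sse = np.einsum("ij,ij->j", resid, resid)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[(se == 0) & (slope != 0)] = 0.0
    p[(se == 0) & (slope == 0)] = 1.0
    return slope, p


def field_significance(p_values: np.ndarray, alpha_fdr: float = 0.01) -> np.ndarray:
    """Benjamini-Hochberg step-up over all analysed cells.

    Sort p ascending, find the largest k with p_(k) <= (k/N) * alpha_fdr,
    and reject every cell with p <= p_(k); an empty rejection set is
    allowed. NaN p-values are never rejected.
    """
    p = np.asarray(p_values, float)
    out = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    rej, *_ = multipletests(p[ok], alpha=alpha_fdr, method="fdr_bh")
    out[ok] = rej
    return out


def aggregate_fires(cube: xr.DataArray, factor: int) -> xr.DataArray:
    """Block-sum a fine-grid count cube to the analysis grid.

    ``factor`` must divide both grid dimensions exactly; totals are
    conserved exactly.
    """
    if cube.sizes["lat"] % factor or cube.sizes["lon"] % factor:
        raise ValueError(
            f"aggregation factor {factor} does not divide grid "
            f"{cube.sizes['lat']}x{cube.sizes['lon']}"
        )
    return cube.coarsen(lat=factor, lon=factor, boundary="exact").sum()


def _annualize(counts: xr.DataArray) -> xr.DataArray:
    return counts.sum("month") if "month" in counts.dims else counts


def phase_ratio_map(values: xr.DataArray, phases: xr.DataArray,
                    mask: xr.DataArray | None = None,
                    which: tuple[float, ...] = (PHASE_POSITIVE, PHASE_NEGATIVE),
                    ) -> xr.Dataset:
    """Per-cell ratio of the phase-conditional mean to the all-year mean.

    ``values`` is annual per (member, year, lat, lon) — fire counts or an
    annualized driver field; the ratio in each phase is the mean over
    member-years in that phase divided by the mean over all labelled
    member-years, so the phase-frequency-weighted sum of ratios over the
    three phases is exactly 1 at every cell with nonzero mean. Cells with
    zero all-year mean are NaN; an optional significance ``mask``
    restricts reporting.
    """
    values = _annualize(values)
    lab = phases.broadcast_like(values.isel(lat=0, lon=0, drop=True))
    labelled = np.isfinite(lab)
    vals = values.where(labelled)
    overall = vals.mean(("member", "year"), skipna=True)
    out = {}
    freqs = {}
    n_lab = int(labelled.sum())
    for ph in which:
        sel = lab == ph
        n_ph = int(sel.sum())
        if n_ph == 0:
            raise ValueError(f"no member-years in phase {_PHASE_NAMES.get(ph, ph)}")
        cond = vals.where(sel).mean(("member", "year"), skipna=True)
        ratio = (cond / overall.where(overall != 0)).rename("ratio")
        if mask is not None:
            ratio = ratio.where(mask)
        out[_PHASE_NAMES.get(ph, str(ph))] = ratio
        freqs[_PHASE_NAMES.get(ph, str(ph))] = n_ph / n_lab
    ds = xr.Dataset(out)
    ds.attrs["phase_frequency"] = freqs
    ds.attrs["n_labelled"] = n_lab
    return ds


def driver_phase_ratio(driver_annual: xr.DataArray, phases: xr.DataArray,
                       mask: xr.DataArray | None = None, **kw) -> xr.Dataset:
    """Phase-conditional ratio map for a driver field (VPD, precipitation,
    GPP, ...): identical machinery to the fire-count ratio map."""
    return phase_ratio_map(driver_annual, phases, mask=mask, **kw)


def cross_phase_table(totals: xr.DataArray, phases_a: xr.DataArray,
                      phases_b: Mapping[str, xr.DataArray],
                      a_name: str = "A") -> pd.DataFrame:
    """Conditional-effect table: percentage change of the mean annual total
    under each phase of mode(s) B, within each phase of mode A.

    ``totals`` is the domain total per (member, year). Rows are the
    positive/neutral/negative phases of A plus an "All Years" row whose
    baseline is the grand mean; columns give, for each B mode, the
    percentage deviation of the conditional mean from the row baseline in
    the positive and negative phases of B, with the conditional sample
    size. Empty conditional cells are reported as missing.
    """
    tot = totals.values.ravel()
    a = phases_a.broadcast_like(totals).values.ravel()
    rows = []
    row_specs = [(PHASE_POSITIVE, f"{a_name} positive"),
                 (PHASE_NEUTRAL, f"{a_name} neutral"),
                 (PHASE_NEGATIVE, f"{a_name} negative"),
                 (None, "All Years")]
    for a_phase, row_name in row_specs:
        in_row = np.isfinite(a) if a_phase is None else (a == a_phase)
        valid = in_row & np.isfinite(tot)
        if valid.sum() == 0:
            continue
        baseline = tot[valid].mean()
        row = {"row": row_name, "n_years": int(valid.sum()),
               "mean_total": baseline}
        for b_name, pb in phases_b.items():
            b = pb.broadcast_like(totals).values.ravel()
            for b_phase, b_lab in ((PHASE_POSITIVE, "positive"),
                                   (PHASE_NEGATIVE, "negative")):
                sel = valid & (b == b_phase)
                col = f"{b_name} {b_lab}"
                if sel.sum() == 0:
                    row[f"{col} %"] = np.nan
                    row[f"{col} n"] = 0
                else:
                    row[f"{col} %"] = 100.0 * (tot[sel].mean() / baseline - 1.0)
                    row[f"{col} n"] = int(sel.sum())
        rows.append(row)
    return pd.DataFrame(rows).set_index("row")


def climate_change_effect(results_recent: "FireModeResults",
                          results_future: "FireModeResults",
                          phases_recent: xr.DataArray,
                          phases_future: xr.DataArray) -> xr.Dataset:
    """Compare a mode's influence between two climate time slices.

    Returns per-cell, per-phase ``strengthening`` = future phase ratio /
    recent phase ratio, masked to cells significant in BOTH climates, and
    per-cell integer sign codes (``sign_recent``, ``sign_future``: +1
    significant-positive, -1 significant-negative, 0 not significant) from
    which extent-transition categories are read.
    """
    if (results_recent.slope.sizes != results_future.slope.sizes):
        raise ValueError("recent and future results are on different grids")
    rr = results_recent.phase_ratio_map(phases_recent, where_significant=False)
    rf = results_future.phase_ratio_map(phases_future, where_significant=False)
    both = results_recent.significant & results_future.significant
    strength = {}
    for ph in ("positive", "negative"):
        strength[f"strengthening_{ph}"] = (rf[ph] / rr[ph].where(rr[ph] != 0)).where(both)
    ds = xr.Dataset(strength)
    ds["sign_recent"] = results_recent.sign
    ds["sign_future"] = results_future.sign
    ds["significant_both"] = both
    return ds


def simulate_null_fdr(n_cells: int = 1000, n_reps: int = 1000,
                      n_years: int = 100, alpha_fdr: float = 0.01,
                      base_rate: float = 5.0, seed: int = 0) -> dict:
    """False-discovery behaviour of the field-significance procedure under
    a complete global null.

    Each replicate regresses Poisson annual counts (independent of the
    index) on a Gaussian index at every cell and applies the BH step-up;
    every rejection is then a false discovery. Returns the mean
    false-discovery proportion over replicates and its Monte-Carlo
    standard error.
    """
    rng = np.random.default_rng(seed)
    fdp = np.empty(n_reps)
    for r in range(n_reps):
        x = rng.standard_normal(n_years)
        Y = rng.poisson(base_rate, size=(n_years, n_cells)).astype(float)
        _, p = regress_cells(x, Y)
        rej = field_significance(p, alpha_fdr)
        fdp[r] = 1.0 if rej.any() else 0.0  # all rejections are false
    return {"mean_fdp": float(fdp.mean()),
            "mc_se": float(fdp.std(ddof=1) / np.sqrt(n_reps)),
            "n_reps": n_reps, "n_cells": n_cells, "n_years": n_years,
            "alpha_fdr": alpha_fdr}


# ---------------------------------------------------------------------------
# model / results objects

class FireModeModel:
    """Per-cell association model between annual fires and mode indices.

    Parameters
    ----------
    counts : DataArray (member, year[, month], lat, lon) of fire counts;
        a monthly cube is summed to annual internally (the monthly cube
        is kept for seasonality analyses elsewhere).
    indices : mapping mode name -> annual index series (member, year);
        NaN member-years (lagged or previous-year-window values) are
        dropped pairwise per mode.
    cell_area : optional (lat, lon) relative areas; defaults to
        cos(latitude).
    """

    def __init__(self, counts: xr.DataArray,
                 indices: Mapping[str, xr.DataArray],
                 cell_area: xr.DataArray | None = None):
        self.counts = counts
        self.annual = _annualize(counts)
        self.indices = dict(indices)
        if cell_area is None:
            cell_area = coslat_weights(counts["lat"]).broadcast_like(
                counts.isel({d: 0 for d in counts.dims if d not in ("lat", "lon")},
                            drop=True))
        self.cell_area = cell_area

    def _paired(self, mode_id: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.indices[mode_id]
        y = self.annual.transpose("member", "year", "lat", "lon")
        x = idx.broadcast_like(y.isel(lat=0, lon=0, drop=True))
        xv = x.values.reshape(-1)
        yv = y.values.reshape(xv.size, -1)
        ok = np.isfinite(xv)
        if ok.sum() < 3:
            raise ValueError(f"{mode_id}: fewer than 3 usable member-years")
        return xv[ok], yv[ok]

    def fit(self, mode_id: str, alpha_fdr: float = 0.01) -> "FireModeResults":
        """Single-mode per-cell OLS on the raw index value, with BH/Wilks
        field significance at ``alpha_fdr``."""
        x, Y = self._paired(mode_id)
        slope, p = regress_cells(x, Y)
        shape = (self.annual.sizes["lat"], self.annual.sizes["lon"])
        coords = {"lat": self.annual["lat"], "lon": self.annual["lon"]}
        slope_da = xr.DataArray(slope.reshape(shape), dims=("lat", "lon"), coords=coords)
        p_da = xr.DataArray(p.reshape(shape), dims=("lat", "lon"), coords=coords)
        sig = field_significance(p, alpha_fdr).reshape(shape)
        sig_da = xr.DataArray(sig, dims=("lat", "lon"), coords=coords)
        return FireModeResults(model=self, mode_id=mode_id, slope=slope_da,
                               p_value=p_da, significant=sig_da,
                               alpha_fdr=alpha_fdr, n_obs=x.size)

    def fit_multimode(self, mode_ids: list[str],
                      max_condition: float = 1e8) -> "MultiModeResults":
        """Per-cell multiple OLS of counts relative to the cell mean on
        standardized indices (plus intercept).

        Member-years with any missing index are dropped; the design
        condition number is reported, and rank deficiency is rejected
        with the offending index correlation.
        """
        y = self.annual.transpose("member", "year", "lat", "lon")
        cols = []
        for m in mode_ids:
            std = standardize_series(self.indices[m])
            cols.append(std.broadcast_like(y.isel(lat=0, lon=0, drop=True))
                        .values.reshape(-1))
        X = np.column_stack(cols)
        ok = np.all(np.isfinite(X), axis=1)
        X = X[ok]
        Yv = y.values.reshape(ok.size, -1)[ok]
        cell_mean = Yv.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(cell_mean > 0, Yv / cell_mean, np.nan)
        design = np.column_stack([np.ones(X.shape[0]), X])
        cond = np.linalg.cond(design)
        if cond > max_condition:
            corr = np.corrcoef(X, rowvar=False)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"design is rank-deficient (condition {cond:.3g}); worst index "
                f"correlation: {mode_ids[i]} vs {mode_ids[j]} r={corr[i, j]:.3f}")
        coef, *_ = np.linalg.lstsq(design, np.nan_to_num(rel), rcond=None)
        resid = np.nan_to_num(rel) - design @ coef
        dof = design.shape[0] - design.shape[1]
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        xtx_inv_diag = np.diag(np.linalg.inv(design.T @ design))
        se = np.sqrt(np.outer(xtx_inv_diag, sigma2))
        # restore NaN for zero-mean cells
        coef[:, ~(cell_mean > 0)] = np.nan
        se[:, ~(cell_mean > 0)] = np.nan
        shape = (len(mode_ids), y.sizes["lat"], y.sizes["lon"])
        coords = {"mode": list(mode_ids), "lat": y["lat"], "lon": y["lon"]}
        betas = xr.DataArray(coef[1:].reshape(shape), dims=("mode", "lat", "lon"),
                             coords=coords)
        bse = xr.DataArray(se[1:].reshape(shape), dims=("mode", "lat", "lon"),
                           coords=coords)
        return MultiModeResults(model=self, mode_ids=list(mode_ids),
                                coefficients=betas, stderr=bse,
                                condition_number=float(cond),
                                n_obs=int(ok.sum()))


@dataclass
class FireModeResults:
    """Results of a single-mode per-cell regression."""

    model: FireModeModel
    mode_id: str
    slope: xr.DataArray
    p_value: xr.DataArray
    significant: xr.DataArray
    alpha_fdr: float
    n_obs: int

    @property
    def sign(self) -> xr.DataArray:
        """+1 / -1 where significant (from the slope), 0 elsewhere."""
        s = xr.where(self.significant, np.sign(self.slope), 0.0)
        return s.rename("sign")

    def areal_extent(self) -> dict[str, float]:
        """Area-weighted percentages of the domain with a significant
        positive / negative association, and the remainder, summing to 100."""
        area = self.model.cell_area
        total = float(area.sum())
        pos = float(area.where(self.sign > 0, 0.0).sum()) / total * 100.0
        neg = float(area.where(self.sign < 0, 0.0).sum()) / total * 100.0
        return {"positive": pos, "negative": neg,
                "not_significant": 100.0 - pos - neg}

    def phase_ratio_map(self, phases: xr.DataArray,
                        where_significant: bool = True) -> xr.Dataset:
        mask = self.significant if where_significant else None
        return phase_ratio_map(self.model.annual, phases, mask=mask)

    def summary(self) -> str:
        ext = self.areal_extent()
        lines = [
            f"Fire-mode association: {self.mode_id}",
            f"  member-years pooled : {self.n_obs}",
            f"  cells analysed      : {self.p_value.size}",
            f"  FDR control level   : {self.alpha_fdr}",
            f"  significant cells   : {int(self.significant.sum())}",
            f"  area positive       : {ext['positive']:6.1f} %",
            f"  area negative       : {ext['negative']:6.1f} %",
            f"  area not significant: {ext['not_significant']:6.1f} %",
        ]
        return "\n".join(lines)


@dataclass
class MultiModeResults:
    """Results of the per-cell multiple regression on standardized indices."""

    model: FireModeModel
    mode_ids: list[str]
    coefficients: xr.DataArray  # (mode, lat, lon)
    stderr: xr.DataArray  # (mode, lat, lon) OLS standard errors
    condition_number: float
    n_obs: int
    extra: dict = dc_field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            "Multimode fire association (response: count / cell mean)",
            f"  modes            : {', '.join(self.mode_ids)}",
            f"  member-years     : {self.n_obs}",
            f"  condition number : {self.condition_number:.3g}",
        ]
        for m in self.mode_ids:
            c = self.coefficients.sel(mode=m)
            lines.append(f"  {m:>6}: median coef {float(c.median()):+.4f}, "
                         f"domain-mean coef {float(c.mean()):+.4f}")
        return "\n".join(lines)
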