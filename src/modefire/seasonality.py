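"""Fire-season timing statistics: circular mean phase, seasonal
concentration, and season length, overall and conditioned on mode phase.

The month-of-year is placed on the unit circle (January at angle 0,
theta_m = 2*pi*(m-1)/12) and each cell's 12-month count vector becomes a
resultant R = sum_m n_m * exp(i*theta_m). The seasonal concentration is
|R| / sum_m n_m — 0 for fires spread equally through the year, 1 for all
fires in a single month — and the mean phase is the resultant's angle in
month units. Cells with concentration below a cutoff (default 0.15) have
no distinct peak and are excluded from phase-shift maps.

Season length is defined against the climatological peak: the
ensemble-mean count of the maximum month at each cell sets the peak; each
member-year contributes the number of months whose counts strictly exceed
half that peak, and the length is the average over member-years
(optionally restricted to years in a given mode phase).

All statistics are rotation-equivariant (rotating the monthly profiles by
k months rotates the mean phase by k and changes nothing else) and scale
invariant, so the angle convention never affects phase differences.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .indices import PHASE_NEGATIVE, PHASE_POSITIVE

__all__ = [
    "mean_phase_and_concentration",
    "phase_shift_by_mode",
    "season_length",
    "circular_difference_months",
]

_THETA = 2.0 * np.pi * (np.arange(12)) / 12.0  # month m -> angle 2*pi*(m-1)/12


def mean_phase_and_concentration(monthly_counts) -> tuple:
    """Circular mean phase (months, in [0, 12)) and seasonal concentration.

    ``monthly_counts`` is a 12-vector, or an array/DataArray with a
    12-long ``month`` dimension (vectorized over all other dims). Phase 0
    corresponds to mid-January. Cells with zero total count are NaN.
    """
    if isinstance(monthly_counts, xr.DataArray):
        da = monthly_counts.transpose(..., "month")
        vals = da.values
        other_dims = [d for d in da.dims if d != "month"]
        coords = {d: da[d] for d in other_dims if d in da.coords}
    else:
        vals = np.asarray(monthly_counts, float)
        other_dims = None
        coords = None
    if vals.shape[-1] != 12:
        raise ValueError("monthly counts must have 12 months in the last axis")
    if np.any(vals < 0):
        raise ValueError("counts must be nonnegative")
    total = vals.sum(axis=-1)
    z = (vals * np.exp(1j * _THETA)).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(total > 0, np.abs(z) / total, np.nan)
        phase = np.where(total > 0, (np.angle(z) / (2 * np.pi) * 12.0) % 12.0, np.nan)
    # a zero resultant has no defined direction
    phase = np.where(np.abs(z) == 0, np.nan, phase)
    if other_dims is not None:
        phase = xr.DataArray(phase, dims=other_dims, coords=coords, name="mean_phase")
        conc = xr.DataArray(conc, dims=other_dims, coords=coords, name="concentration")
        return phase, conc
    if vals.ndim == 1:
        return float(phase), float(conc)
    return phase, conc


def circular_difference_months(a, b):
    """a - b on the 12-month circle, wrapped to (-6, +6]."""
    d = (np.asarray(a) - np.asarray(b)) % 12.0
    out = np.where(d > 6.0, d - 12.0, d)
    return out


def _composite_profile(cube: xr.DataArray, sel: xr.DataArray | None) -> xr.DataArray:
    """Summed monthly profile over (selected) member-years, per cell."""
    if sel is not None:
        cube = cube.where(sel.broadcast_like(cube.isel(month=0, lat=0, lon=0,
                                                       drop=True)))
    return cube.sum(("member", "year"), skipna=True)


def phase_shift_by_mode(cube: xr.DataArray, phases: xr.DataArray,
                        concentration_min: float = 0.15,
                        which: tuple = (PHASE_POSITIVE, PHASE_NEGATIVE),
                        ) -> xr.Dataset:
    """Circular shift of the fire-season mean phase in each mode phase.

    The mean phase is computed from composite (summed over years) monthly
    profiles: once over all labelled member-years and once per requested
    mode phase; the difference is wrapped to (-6, +6] months. Cells whose
    all-year concentration is below ``concentration_min`` have no distinct
    peak and are excluded (NaN).
    """
    lab = phases
    labelled = np.isfinite(lab)
    all_prof = _composite_profile(cube, labelled)
    phase_all, conc_all = mean_phase_and_concentration(all_prof)
    keep = conc_all >= concentration_min
    out = {"mean_phase": phase_all.where(keep),
           "concentration": conc_all}
    names = {PHASE_POSITIVE: "positive", PHASE_NEGATIVE: "negative"}
    for ph in which:
        sel = lab == ph
        if int(sel.sum()) == 0:
            shifted = xr.full_like(phase_all, np.nan)
        else:
            prof = _composite_profile(cube, sel)
            phase_ph, _ = mean_phase_and_concentration(prof)
            shifted = xr.DataArray(
                circular_difference_months(phase_ph.values, phase_all.values),
                dims=phase_all.dims, coords=phase_all.coords)
        out[f"shift_{names.get(ph, ph)}"] = shifted.where(keep)
    ds = xr.Dataset(out)
    ds.attrs["concentration_min"] = concentration_min
    return ds


def season_length(cube: xr.DataArray, phases: xr.DataArray | None = None,
                  phase: float | None = None) -> xr.DataArray:
    """Mean number of months per year exceeding half the climatological peak.

    The peak is the ensemble-mean monthly profile's maximum at each cell;
    a month counts toward the season when its count strictly exceeds half
    that peak. Restricting to a mode phase averages only over member-years
    with that label. Cells with zero peak are NaN.
    """
    clim = cube.mean(("member", "year"))
    peak = clim.max("month")
    half = peak / 2.0
    exceeds = (cube > half).sum("month")
    if phases is not None:
        if phase is None:
            sel = np.isfinite(phases)
        else:
            sel = phases == phase
        if int(sel.sum()) == 0:
            raise ValueError("no member-years in the requested phase")
        exceeds = exceeds.where(sel.broadcast_like(
            exceeds.isel(lat=0, lon=0, drop=True)))
    length = exceeds.mean(("member", "year"), skipna=True)
    return length.where(peak > 0).rename("season_length")
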