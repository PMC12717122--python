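"""Climate-mode index construction from monthly SLP/SST fields.

Implements the standard catalogue of mode recipes — box-difference
indices (equatorial SOI, Indian Ocean DMI), box-anomaly indices
(tropical North/South Atlantic), principal-component indices (PDO, NAO,
EA, AO, PNA, SAM) and the global-contrast AMO — together with annual
aggregation windows, one-year lagging, and the half-standard-deviation
phase classification used to composite fire years.

Conventions
-----------
* Fields are :class:`xarray.DataArray` with dims (member, time, lat, lon),
  a monthly datetime ``time`` axis and an optional boolean ``mask``
  coordinate on (lat, lon) marking valid (e.g. ocean) cells.
* Anomalies are taken per calendar month against the climatology pooled
  over all members and years of the field (time slices are processed
  separately upstream).
* Standardized anomalies divide by the pooled per-calendar-month SD.
* Area weighting is cos(latitude) for box means, sqrt(cos) applied to the
  data matrix for EOFs (so the covariance is cos-weighted).
* Annual index series are (member, year) arrays with ``year`` an ordinal
  0-based index within the time slice; window definitions that start in
  the previous calendar year leave the first year of each member NaN.
* Phase labels are +1 (positive), 0 (neutral), -1 (negative) floats with
  NaN for missing member-years.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from importlib import resources

import numpy as np
import xarray as xr
import yaml

from .grids import coslat_weights, normalize_longitudes

__all__ = [
    "ModeDefinition",
    "load_mode_catalogue",
    "monthly_anomaly",
    "standardized_anomaly",
    "box_mean",
    "box_index",
    "pc_index",
    "amo_index",
    "aggregate_annual",
    "lag_index",
    "classify_phase",
    "compute_mode_index",
    "standardize_series",
    "PHASE_POSITIVE",
    "PHASE_NEUTRAL",
    "PHASE_NEGATIVE",
]

PHASE_POSITIVE = 1.0
PHASE_NEUTRAL = 0.0
PHASE_NEGATIVE = -1.0

_WINDOWS = {
    "annual": {"months": (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12), "prev": ()},
    "NDJFM": {"months": (1, 2, 3), "prev": (11, 12)},
    "DJF": {"months": (1, 2), "prev": (12,)},
    "NDJ": {"months": (1,), "prev": (11, 12)},
    "JJA": {"months": (6, 7, 8), "prev": ()},
}


@dataclass
class ModeDefinition:
    """One mode recipe: which field, which method, which boxes/windows.

    method is one of ``box-difference`` (difference of two box series),
    ``box-anomaly`` (single box), ``pc-index`` (principal component over a
    region) or ``global-contrast`` (box minus rest-of-ocean, AMO style).
    ``standardization`` applies to box methods: ``per-box`` standardizes
    each box series before differencing (SOI), ``difference`` standardizes
    the differenced series (DMI), ``none`` leaves raw anomalies (TNA/TSA).
    ``djf_first`` triggers the PNA-style ordering where the DJF mean
    (starting in the previous year) is taken before the decomposition.
    """

    mode_id: str
    field: str  # "slp" | "sst"
    method: str
    boxes: list = dc_field(default_factory=list)  # [lat_min, lat_max, lon_min, lon_max]
    pc_rank: int = 1
    annual_window: str = "annual"
    standardization: str = "none"
    djf_first: bool = False
    sign_reference: dict | None = None  # {"box": [...], "sign": +1|-1}
    description: str = ""

    def __post_init__(self):
        if self.method not in {"box-difference", "box-anomaly", "pc-index",
                               "global-contrast"}:
            raise ValueError(f"unknown method {self.method!r}")
        if self.method != "pc-index" and self.pc_rank != 1:
            raise ValueError("pc_rank only applies to pc-index modes")
        if self.annual_window not in _WINDOWS and not self.djf_first:
            raise ValueError(f"unknown annual_window {self.annual_window!r}")


def load_mode_catalogue(path=None) -> dict[str, ModeDefinition]:
    """Load the shipped (or a user-supplied) YAML catalogue of mode recipes."""
    if path is None:
        text = resources.files("modefire").joinpath("catalogue/modes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    out = {}
    for mode_id, spec in raw["modes"].items():
        out[mode_id] = ModeDefinition(mode_id=mode_id, **spec)
    return out


# ---------------------------------------------------------------------------
# anomalies

def _check_month_coverage(field: xr.DataArray, basis: xr.DataArray) -> None:
    need = np.unique(field["time"].dt.month.values)
    have, counts = np.unique(basis["time"].dt.month.values, return_counts=True)
    missing = set(need.tolist()) - set(have.tolist())
    if missing:
        raise ValueError(f"calendar months {sorted(missing)} absent from climatology basis")
    if np.any(counts < 2):
        thin = have[counts < 2].tolist()
        raise ValueError(f"calendar months {thin} have fewer than 2 basis instances")


def monthly_anomaly(field: xr.DataArray, basis: xr.DataArray | None = None) -> xr.DataArray:
    """Anomaly per calendar month against the pooled member-year climatology.

    The per-calendar-month mean of the output (over the basis) is zero to
    numerical precision.
    """
    basis = field if basis is None else basis
    _check_month_coverage(field, basis)
    clim = basis.groupby("time.month").mean(("member", "time"))
    anom = (field.groupby("time.month") - clim)
    return anom.drop_vars("month", errors="ignore").rename(field.name)


def monthly_pooled_sd(anom: xr.DataArray) -> xr.DataArray:
    """Pooled per-cell, per-calendar-month standard deviation (ddof 0)."""
    return anom.groupby("time.month").std(("member", "time"))


def standardized_anomaly(field: xr.DataArray, basis: xr.DataArray | None = None) -> xr.DataArray:
    """Anomaly divided by its pooled per-calendar-month SD.

    Cells with zero variance in some month become NaN there (no
    information), and are skipped by downstream weighted means.
    """
    anom = monthly_anomaly(field, basis)
    sd = monthly_pooled_sd(anom).where(lambda s: s > 0)
    out = anom.groupby("time.month") / sd
    return out.drop_vars("month", errors="ignore").rename(field.name)


# ---------------------------------------------------------------------------
# box machinery

def _select_box(field: xr.DataArray, box) -> xr.DataArray:
    """Select a lat-lon box, handling antimeridian-crossing longitudes."""
    lat_min, lat_max, lon_min, lon_max = box
    field = normalize_longitudes(field)
    lon_min = ((lon_min + 180.0) % 360.0) - 180.0
    lon_max = ((lon_max + 180.0) % 360.0) - 180.0
    sub = field.sel(lat=slice(lat_min, lat_max))
    if lon_min <= lon_max:
        sub = sub.sel(lon=slice(lon_min, lon_max))
    else:  # wraps the antimeridian: union of the two segments
        sub = sub.where((sub["lon"] >= lon_min) | (sub["lon"] <= lon_max), drop=True)
    return sub


def _apply_mask(sub: xr.DataArray) -> xr.DataArray:
    if "mask" in sub.coords:
        sub = sub.where(sub["mask"])
    return sub


def box_mean(field: xr.DataArray, box) -> xr.DataArray:
    """cos(latitude)-weighted mean over the unmasked cells of a box."""
    sub = _apply_mask(_select_box(field, box))
    if sub.sizes.get("lat", 0) == 0 or sub.sizes.get("lon", 0) == 0:
        raise ValueError(f"box {box} selects no grid cells")
    if bool(sub.isnull().all()):
        raise ValueError(f"box {box} is fully masked")
    w = coslat_weights(sub["lat"])
    return sub.weighted(w).mean(("lat", "lon"), skipna=True)


def _standardize_monthly_series(series: xr.DataArray) -> xr.DataArray:
    """Standardize a (member, time) series per calendar month, pooled SD."""
    grouped = series.groupby("time.month")
    mean = grouped.mean(("member", "time"))
    sd = grouped.std(("member", "time")).where(lambda s: s > 0)
    out = (series.groupby("time.month") - mean).groupby("time.month") / sd
    return out.drop_vars("month", errors="ignore")


def box_index(defn: ModeDefinition, field: xr.DataArray) -> xr.DataArray:
    """Monthly box index: difference of two boxes or a single box anomaly.

    SOI-style recipes standardize each box's anomaly series before
    differencing; DMI-style recipes standardize the differenced series;
    plain box-anomaly indices (TNA/TSA) stay in physical units — the
    downstream regression is scale-free.
    """
    if defn.method not in {"box-difference", "box-anomaly"}:
        raise ValueError(f"{defn.mode_id}: box_index requires a box method, "
                         f"got {defn.method!r}")
    anom = monthly_anomaly(field)
    if defn.method == "box-anomaly":
        return box_mean(anom, defn.boxes[0]).rename(defn.mode_id)
    b1 = box_mean(anom, defn.boxes[0])
    b2 = box_mean(anom, defn.boxes[1])
    if defn.standardization == "per-box":
        idx = _standardize_monthly_series(b1) - _standardize_monthly_series(b2)
    elif defn.standardization == "difference":
        idx = _standardize_monthly_series(b1 - b2)
    else:
        idx = b1 - b2
    return idx.rename(defn.mode_id)


# ---------------------------------------------------------------------------
# PC / EOF indices

def _djf_prior_mean(anom: xr.DataArray) -> xr.DataArray:
    """Per member-year DJF mean (December of the previous calendar year);
    the first year of each member is NaN."""
    year = anom["time"].dt.year
    month = anom["time"].dt.month
    target = xr.where(month == 12, year + 1, year)
    in_win = (month == 12) | (month <= 2)
    sub = anom.where(in_win, drop=True)
    target = target.where(in_win, drop=True)
    grouped = sub.assign_coords(djf_year=target).groupby("djf_year").mean("time")
    counts = sub.assign_coords(djf_year=target).groupby("djf_year").count("time")
    grouped = grouped.where(counts == 3)
    years = np.unique(year.values)
    grouped = grouped.sel(djf_year=grouped["djf_year"].isin(years))
    return grouped.rename({"djf_year": "cal_year"})


def pc_index(defn: ModeDefinition, field: xr.DataArray,
             return_loading: bool = False):
    """Principal-component index over a region.

    Anomalies in the region are weighted by sqrt(cos latitude), all
    member-time samples are pooled, and the PC of rank ``pc_rank`` is
    extracted by SVD and standardized to unit variance. The sign is fixed
    so that regressing the field on the PC has the expected sign over the
    ``sign_reference`` box. For DJF-first recipes (PNA) the anomalies are
    averaged over DJF per member-year before the decomposition and the
    result is already an annual series.
    """
    if defn.method != "pc-index":
        raise ValueError(f"{defn.mode_id}: pc_index requires method 'pc-index'")
    anom = monthly_anomaly(field)
    sub = _apply_mask(_select_box(anom, defn.boxes[0]))
    if sub.sizes["lat"] * sub.sizes["lon"] < 2:
        raise ValueError(f"{defn.mode_id}: region has fewer than 2 cells")

    if defn.djf_first:
        sub = _djf_prior_mean(sub)
        sample_dims = ("member", "cal_year")
    else:
        sample_dims = ("member", "time")

    wsqrt = np.sqrt(coslat_weights(sub["lat"]))
    weighted = sub * wsqrt
    stacked = weighted.stack(sample=sample_dims, cell=("lat", "lon"))
    X = stacked.transpose("sample", "cell").values
    # cells valid where no sample is NaN among rows that are themselves valid
    row_ok = ~np.all(np.isnan(X), axis=1)
    cell_ok = ~np.any(np.isnan(X[row_ok]), axis=0)
    Xv = X[np.ix_(row_ok, cell_ok)]
    n_samp = Xv.shape[0]
    if n_samp <= defn.pc_rank:
        raise ValueError(f"{defn.mode_id}: {n_samp} samples insufficient for "
                         f"pc_rank {defn.pc_rank}")
    Xc = Xv - Xv.mean(axis=0)
    total_var = np.sum(Xc ** 2)
    if total_var <= 0:
        raise ValueError(f"{defn.mode_id}: degenerate (zero-variance) covariance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = defn.pc_rank - 1
    eigvals = s ** 2 / max(n_samp - 1, 1)
    tie = False
    if r + 1 < len(s) and eigvals[0] > 0:
        gap = abs(eigvals[r] - eigvals[r + 1]) / eigvals[0]
        tie = gap < 1e-6
    if r > 0 and eigvals[0] > 0:
        tie = tie or abs(eigvals[r - 1] - eigvals[r]) / eigvals[0] < 1e-6

    pc = U[:, r] * s[r]
    sd = pc.std()
    if sd <= 0:
        raise ValueError(f"{defn.mode_id}: PC {defn.pc_rank} has zero variance")
    pc = (pc - pc.mean()) / sd

    full = np.full(X.shape[0], np.nan)
    full[row_ok] = pc
    series = xr.DataArray(full, dims=("sample",),
                          coords={"sample": stacked["sample"]}).unstack("sample")
    series = series.rename(defn.mode_id)
    series.attrs["eigenvalue_tie"] = bool(tie)
    series.attrs["explained_variance_ratio"] = float(eigvals[r] / eigvals.sum())

    if defn.sign_reference is not None:
        ref = box_mean(anom if not defn.djf_first else _djf_prior_mean(anom),
                       defn.sign_reference["box"])
        a = series.values.ravel()
        b = ref.transpose(*series.dims).values.ravel()
        ok = ~(np.isnan(a) | np.isnan(b))
        slope_sign = np.sign(np.dot(a[ok] - a[ok].mean(), b[ok] - b[ok].mean()))
        if slope_sign != 0 and slope_sign != np.sign(defn.sign_reference["sign"]):
            series = -series
            series.attrs.update(eigenvalue_tie=bool(tie))

    if return_loading:
        loading = np.full(X.shape[1], np.nan)
        loading[cell_ok] = Vt[r]
        loading = xr.DataArray(loading, dims=("cell",),
                               coords={"cell": stacked["cell"]}).unstack("cell")
        return series, loading
    return series


# ---------------------------------------------------------------------------
# AMO-style global contrast

def amo_index(defn: ModeDefinition, sst: xr.DataArray) -> xr.DataArray:
    """Annual basin-contrast index: box anomaly minus the anomaly over all
    other unmasked ocean cells, area-weighted, annually averaged."""
    if defn.method != "global-contrast":
        raise ValueError(f"{defn.mode_id}: amo_index requires 'global-contrast'")
    anom = normalize_longitudes(monthly_anomaly(sst))
    box = defn.boxes[0]
    lat_min, lat_max, lon_min, lon_max = box
    lon_min = ((lon_min + 180.0) % 360.0) - 180.0
    lon_max = ((lon_max + 180.0) % 360.0) - 180.0
    in_lat = (anom["lat"] >= lat_min) & (anom["lat"] <= lat_max)
    if lon_min <= lon_max:
        in_lon = (anom["lon"] >= lon_min) & (anom["lon"] <= lon_max)
    else:
        in_lon = (anom["lon"] >= lon_min) | (anom["lon"] <= lon_max)
    in_box = in_lat & in_lon

    box_part = anom.where(in_box)
    rest = anom.where(~in_box)
    if "mask" in anom.coords:
        box_part = box_part.where(anom["mask"])
        rest = rest.where(anom["mask"])
    w = coslat_weights(anom["lat"]).broadcast_like(anom.isel(member=0, time=0))
    if bool(box_part.isnull().all()):
        raise ValueError(f"{defn.mode_id}: box contains no unmasked cells")
    if bool(rest.isnull().all()):
        raise ValueError(f"{defn.mode_id}: complement contains no unmasked cells")
    monthly = (box_part.weighted(w).mean(("lat", "lon"), skipna=True)
               - rest.weighted(w).mean(("lat", "lon"), skipna=True))
    return aggregate_annual(monthly.rename(defn.mode_id), "annual")


# ---------------------------------------------------------------------------
# annual aggregation, lag, phase

def _year_index(cal_years: np.ndarray, first_year: int) -> np.ndarray:
    return cal_years - first_year


def aggregate_annual(monthly: xr.DataArray, window: str) -> xr.DataArray:
    """Aggregate a monthly (member, time) index to (member, year).

    Windows that start in the previous calendar year (NDJFM, DJF, NDJ)
    leave the first year of each member NaN — never imputed. ``year`` in
    the output is ordinal within the time slice (0-based).
    """
    if "cal_year" in monthly.dims:  # already annual (DJF-first PC recipe)
        cal = monthly["cal_year"].values
        out = monthly.rename({"cal_year": "year"})
        return out.assign_coords(year=_year_index(cal, cal.min()))
    if window not in _WINDOWS:
        raise ValueError(f"unknown annual window {window!r}")
    spec = _WINDOWS[window]
    year = monthly["time"].dt.year
    month = monthly["time"].dt.month
    target = xr.where(month.isin(list(spec["prev"])), year + 1, year)
    in_win = month.isin(list(spec["months"]) + list(spec["prev"]))
    sub = monthly.where(in_win, drop=True)
    tgt = target.where(in_win, drop=True)
    sub = sub.assign_coords(agg_year=tgt)
    mean = sub.groupby("agg_year").mean("time")
    count = sub.groupby("agg_year").count("time")
    need = len(spec["months"]) + len(spec["prev"])
    mean = mean.where(count == need)
    cal_years = np.unique(year.values)
    mean = mean.sel(agg_year=mean["agg_year"].isin(cal_years))
    out = mean.rename({"agg_year": "year"})
    return out.assign_coords(year=_year_index(out["year"].values, cal_years.min()))


def lag_index(series: xr.DataArray, lag: int = 1) -> xr.DataArray:
    """Pair year-t analyses with the year-(t-lag) index value.

    The first ``lag`` years of each member become NaN; member boundaries
    never mix.
    """
    if lag not in (0, 1):
        raise ValueError("lag must be 0 or 1")
    if lag == 0:
        return series
    out = series.shift(year=lag)
    out.attrs = dict(series.attrs)
    out.attrs["lag"] = lag
    return out.rename(f"{series.name}+{lag}" if series.name else None)


def standardize_series(series: xr.DataArray) -> xr.DataArray:
    """Exact pooled standardization over non-missing member-years."""
    mean = series.mean(skipna=True)
    sd = series.std(skipna=True)
    if float(sd) == 0:
        raise ValueError("cannot standardize a constant series")
    out = (series - mean) / sd
    out.attrs = dict(series.attrs)
    return out


def classify_phase(series: xr.DataArray, threshold_sd: float = 0.5) -> xr.DataArray:
    """Half-standard-deviation phase labels.

    value > +threshold_sd * SD -> positive (+1); value < -threshold_sd *
    SD -> negative (-1); otherwise neutral (0), boundary equality
    included in neutral (strict inequalities). SD is pooled over all
    non-missing member-years. Missing values stay NaN.
    """
    vals = series.values
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError("all index values missing; cannot classify phases")
    sd = finite.std()
    thr = threshold_sd * sd
    lab = np.where(vals > thr, PHASE_POSITIVE,
                   np.where(vals < -thr, PHASE_NEGATIVE, PHASE_NEUTRAL))
    lab = np.where(np.isfinite(vals), lab, np.nan)
    out = xr.DataArray(lab, dims=series.dims, coords=series.coords,
                       name=f"{series.name}_phase" if series.name else "phase")
    out.attrs["sd_threshold"] = float(thr)
    out.attrs["threshold_sd"] = float(threshold_sd)
    return out


def compute_mode_index(defn: ModeDefinition, slp: xr.DataArray | None = None,
                       sst: xr.DataArray | None = None) -> xr.DataArray:
    """Full recipe: monthly index -> annual (member, year) series."""
    field = {"slp": slp, "sst": sst}[defn.field]
    if field is None:
        raise ValueError(f"{defn.mode_id} needs the {defn.field.upper()} field")
    if defn.method == "global-contrast":
        return amo_index(defn, field)
    if defn.method == "pc-index":
        return aggregate_annual(pc_index(defn, field), defn.annual_window)
    monthly = box_index(defn, field)
    return aggregate_annual(monthly, defn.annual_window)
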