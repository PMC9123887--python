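"""Covariate engineering for hourly detection records.

Cyclic forcings (moon fraction, tide height/flow/curvature-trend, hour of
day, civil daylength) plus daily environmental joins (SST inside and outside
the lagoon, their difference, chlorophyll) and the two pre-modelling screens:
a Spearman collinearity filter and the Kaiser–Meyer–Olkin sampling-adequacy
measure that gatekeeps the PCA used for deployment clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, ValidationError

SYNODIC_DAYS = 29.530588853
#: a well-catalogued new moon, used as the phase origin (UTC)
_REFERENCE_NEW_MOON = datetime(2000, 1, 6, 18, 14)

CYCLIC_VARIABLES = {"moon": 1.0, "hour": 24.0}


def moon_phase(t: datetime) -> float:
    """Fraction of the synodic cycle at ``t``: 0 = new moon, 0.5 = full moon.

    Uses the mean synodic month anchored at a reference new moon; the drift
    against a true ephemeris stays below ~0.02 cycle over the 2017–2019 span.
    """
    days = (t - _REFERENCE_NEW_MOON).total_seconds() / 86400.0
    return float(days / SYNODIC_DAYS % 1.0)


# ---------------------------------------------------------------------------
# solar geometry (NOAA equations; civil twilight = sun 6 deg below horizon)


def _solar_declination_eqtime(day_of_year: float) -> tuple[float, float]:
    """Return (declination rad, equation of time min) — NOAA approximation."""
    g = 2.0 * math.pi / 365.0 * (day_of_year - 1 + 0.5)
    decl = (
        0.006918
        - 0.399912 * math.cos(g)
        + 0.070257 * math.sin(g)
        - 0.006758 * math.cos(2 * g)
        + 0.000907 * math.sin(2 * g)
        - 0.002697 * math.cos(3 * g)
        + 0.00148 * math.sin(3 * g)
    )
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(g)
        - 0.032077 * math.sin(g)
        - 0.014615 * math.cos(2 * g)
        - 0.040849 * math.sin(2 * g)
    )
    return decl, eqtime


def daylength(d: date, lat: float, lon: float = 0.0) -> float:
    """Hours between civil dawn and civil dusk (solar zenith 96°).

    Only latitudes within ±60° are supported: there the civil day always
    both starts and ends, so the hour angle is well defined.
    """
    if abs(lat) >= 60.0:
        raise ValidationError(f"daylength: |lat| must be < 60 deg, got {lat}")
    doy = d.timetuple().tm_yday
    decl, _ = _solar_declination_eqtime(doy)
    phi = math.radians(lat)
    zenith = math.radians(96.0)
    cos_ha = (math.cos(zenith) - math.sin(phi) * math.sin(decl)) / (
        math.cos(phi) * math.cos(decl)
    )
    cos_ha = min(1.0, max(-1.0, cos_ha))
    ha = math.acos(cos_ha)
    return 2.0 * math.degrees(ha) / 15.0


# ---------------------------------------------------------------------------
# tide features


@dataclass(frozen=True)
class TideFeatures:
    tide_m: float
    flow_m: float
    dtide: float


def tide_features(series: pd.Series, t: datetime, window_h: float = 3.0) -> TideFeatures:
    """Height, 60-min change, and trend of the height's first derivative at ``t``.

    ``series`` is a height series indexed by datetime at ≤10-min resolution.
    ``tide_m`` is the height linearly interpolated at ``t``; ``flow_m`` is
    ``h(t) − h(t − 60 min)``; ``dtide`` is the slope of the first derivative
    of the least-squares cubic ``h(τ) = a0 + a1 τ + a2 τ² + a3 τ³`` fitted to
    the trailing ``window_h`` hours (τ in hours, origin at the window start),
    i.e. ``2 a2 + 6 a3 τ`` evaluated at the window end.
    """
    if not series.index.is_monotonic_increasing:
        series = series.sort_index()
    t0 = t - timedelta(hours=window_h)
    idx = series.index
    if len(series) == 0 or idx[0] > t0 or idx[-1] < t:
        raise CoverageError(
            f"tide series does not cover [{t0}, {t}]",
            missing_span=(t0, t),
        )
    lo_pos = max(idx.searchsorted(t0) - 1, 0)
    hi_pos = min(idx.searchsorted(t, side="right") + 1, len(idx))
    widx = idx[lo_pos:hi_pos]
    if len(widx) < 2 or widx[0] > t0 or widx[-1] < t:
        raise CoverageError(f"tide series does not cover [{t0}, {t}]", missing_span=(t0, t))
    step = (widx[1:] - widx[:-1]).max()
    if step > pd.Timedelta(minutes=10):
        gaps = widx[1:][(widx[1:] - widx[:-1]) > pd.Timedelta(minutes=10)]
        raise CoverageError(
            f"tide series has gaps coarser than 10 min in [{t0}, {t}] near {list(gaps[:3])}",
            missing_span=None,
        )

    def interp(at: datetime) -> float:
        pos = idx.searchsorted(at)
        if pos < len(idx) and idx[pos] == at:
            return float(series.iloc[pos])
        lo, hi = idx[pos - 1], idx[pos]
        w = (at - lo).total_seconds() / (hi - lo).total_seconds()
        return float((1 - w) * series.iloc[pos - 1] + w * series.iloc[pos])

    tide = interp(t)
    flow = tide - interp(t - timedelta(hours=1.0))

    mask = (idx >= t0) & (idx <= t)
    tau = np.array([(x - t0).total_seconds() / 3600.0 for x in idx[mask]])
    hgt = series.to_numpy(dtype=float)[mask]
    if len(tau) < 5:
        raise CoverageError(f"only {len(tau)} tide samples in trailing window before {t}")
    coef = np.polynomial.polynomial.polyfit(tau, hgt, 3)  # a0..a3
    dtide = float(2.0 * coef[2] + 6.0 * coef[3] * window_h)
    return TideFeatures(tide_m=tide, flow_m=flow, dtide=dtide)


# ---------------------------------------------------------------------------
# covariate assembly


def attach_cyclic(records, tide_series: pd.Series, lat: float, lon: float) -> None:
    """Fill moon / tide / hour / daylength covariates on records in place."""
    day_cache: dict[date, float] = {}
    for r in records:
        mid = r.hour_start + timedelta(minutes=30)
        tf = tide_features(tide_series, mid)
        d = r.hour_start.date()
        if d not in day_cache:
            day_cache[d] = daylength(d, lat, lon)
        r.covariates.update(
            moon=moon_phase(mid),
            tide=tf.tide_m,
            flow=tf.flow_m,
            dtide=tf.dtide,
            hour=r.hour_start.hour + 0.5,
            daylength=day_cache[d],
        )


def attach_environment(
    records,
    sst_table: pd.DataFrame,
    sst_bay_table: pd.DataFrame,
    chl_table: pd.DataFrame | None = None,
) -> None:
    """Join same-day SST (lagoon + bay), ΔSST and chlorophyll onto records.

    Tables have columns ``date`` and ``value``; the join is by calendar day
    with no interpolation.  A missing day raises a warning and leaves NaN
    (flagged, never imputed).
    """

    def as_map(table: pd.DataFrame) -> dict:
        t = table.copy()
        t["date"] = pd.to_datetime(t["date"]).dt.date
        return dict(zip(t["date"], t["value"].astype(float)))

    sst_map = as_map(sst_table)
    bay_map = as_map(sst_bay_table)
    chl_map = as_map(chl_table) if chl_table is not None else {}
    missing: set[date] = set()
    for r in records:
        d = r.hour_start.date()
        sst = sst_map.get(d, float("nan"))
        bay = bay_map.get(d, float("nan"))
        if d not in sst_map or d not in bay_map:
            missing.add(d)
        r.covariates.update(
            sst=sst,
            sst_bay=bay,
            delta_sst=sst - bay,
            chl=chl_map.get(d, float("nan")),
            chl_missing=d not in chl_map,
        )
    if missing:
        warnings.warn(f"SST tables miss {len(missing)} day(s), e.g. {sorted(missing)[:3]}")


def attach_static(records, schedule) -> None:
    """Copy per-deployment descriptors (depth, distances, bottom) to records."""
    by_id = {w.deployment_id: w for w in schedule}
    for r in records:
        w = by_id[r.deployment_id]
        r.covariates.update(
            depth=w.depth_m,
            distance=w.distance_km,
            coast=w.coast_km,
            mangrove=w.mangrove_km,
            bottom=w.bottom,
        )


# ---------------------------------------------------------------------------
# screens


@dataclass
class ScreeningResult:
    spearman_rho: pd.DataFrame
    spearman_p: pd.DataFrame
    retained: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped, retained partner, rho)


def spearman_screen(
    table: pd.DataFrame,
    cutoff: float = 0.7,
    priority: list[str] | None = None,
) -> ScreeningResult:
    """Greedy collinearity filter on Spearman rank correlations.

    Variables are visited in ``priority`` order (default: column order); a
    candidate is dropped when some already-retained variable correlates with
    it at ``|ρ| > cutoff``.  Pairs involving a constant column have undefined
    ρ (reported NaN) and never trigger a drop.
    """
    if len(table) < 3:
        raise ValidationError("spearman_screen needs at least 3 complete rows")
    cols = list(table.columns)
    arr = table.to_numpy(dtype=float)
    m = arr.shape[1]
    rho_mat = np.eye(m)
    p_mat = np.zeros((m, m))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(m):
            for j in range(i + 1, m):
                r = stats.spearmanr(arr[:, i], arr[:, j])
                rho_mat[i, j] = rho_mat[j, i] = r.statistic
                p_mat[i, j] = p_mat[j, i] = r.pvalue
    rho = pd.DataFrame(rho_mat, index=cols, columns=cols)
    pval = pd.DataFrame(p_mat, index=cols, columns=cols)

    order = [c for c in (priority or cols) if c in cols]
    order += [c for c in cols if c not in order]
    retained: list[str] = []
    dropped: list[tuple[str, str, float]] = []
    for c in order:
        partner = None
        for kept in retained:
            r = rho.loc[c, kept]
            if np.isfinite(r) and abs(r) > cutoff:
                partner = (kept, float(r))
                break
        if partner is None:
            retained.append(c)
        else:
            dropped.append((c, partner[0], partner[1]))
    return ScreeningResult(spearman_rho=rho, spearman_p=pval, retained=retained, dropped=dropped)


def kmo(table: pd.DataFrame) -> tuple[float, pd.Series]:
    """Kaiser–Meyer–Olkin sampling adequacy: overall and per variable.

    Overall KMO = Σr² / (Σr² + Σq²) over off-diagonal simple correlations r
    and partial correlations q (from the inverse correlation matrix).
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("kmo: need more rows than variables")
    R = np.corrcoef(X, rowvar=False)
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("kmo: correlation matrix is singular") from exc
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    np.fill_diagonal(Q, 1.0)
    mask = ~np.eye(R.shape[0], dtype=bool)
    r2 = (R**2)[mask]
    q2 = (Q**2)[mask]
    overall = float(r2.sum() / (r2.sum() + q2.sum()))
    per = pd.Series(
        ((R**2) * mask).sum(axis=1) / (((R**2) * mask).sum(axis=1) + ((Q**2) * mask).sum(axis=1)),
        index=table.columns,
    )
    return overall, per
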