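"""Outcome-parameter quantification for dynamic FDG brain PET.

Five parameters are computed per region and scan:

* ``CMRglu`` — cerebral metabolic rate of glucose via Patlak graphical
  analysis: ``CMRglu = Ki * Gly / LC * 100 / rho`` in umol/min/100 g, with
  ``Ki`` the net influx rate (min^-1), ``Gly`` glycemia (mmol/L == umol/mL),
  ``LC`` the lumped constant and ``rho`` the tissue density (g/mL).
* ``SUV`` — duration-weighted mean standardized uptake value over the late
  plateau of the tissue kinetics.
* ``SUVxGly`` — SUV multiplied by glycemia.
* ``SUVR_pons`` / ``SUVR_cerebellum`` — SUV normalized to a reference region.

plus the plasma exposure (AUC of the SUV-normalized input function over
0-60 min), which characterizes each scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ArterialInputFunction, ScanMeta, TimeActivityCurve
from .errors import ConfigError, InputError

#: Canonical outcome-parameter names, in reporting order.
PARAMETERS = ("CMRglu", "SUV", "SUVxGly", "SUVR_pons", "SUVR_cerebellum")

#: Region label used for per-scan (non-regional) quantities in long tables.
PLASMA_LABEL = "plasma"

#: Patlak points whose interpolated Cp falls below this fraction of the peak
#: plasma activity are dropped before fitting (division-by-zero guard).
CP_POSITIVITY_FLOOR = 1e-6


@dataclass(frozen=True)
class QuantConfig:
    """Tunable constants of the quantification step."""

    lumped_constant: float = 0.34
    t_star_min: float = 30.0
    plateau_window_min: tuple[float, float] = (30.0, 60.0)
    reference_regions: tuple[str, ...] = ("pons", "cerebellum")
    glycemia_source: str = "arterial"
    tissue_density_g_ml: float = 1.0

    def __post_init__(self):
        if not 0 < self.lumped_constant <= 1:
            raise ConfigError("lumped constant must be in (0, 1]")
        lo, hi = self.plateau_window_min
        if not lo < hi:
            raise ConfigError("plateau window must be an increasing interval")
        if self.glycemia_source not in ("arterial", "venous"):
            raise ConfigError("glycemia_source must be 'arterial' or 'venous'")
        if not self.tissue_density_g_ml > 0:
            raise ConfigError("tissue density must be positive")

    def glycemia(self, meta: ScanMeta) -> float:
        if self.glycemia_source == "arterial":
            return meta.glycemia_arterial_mmol_l
        if meta.glycemia_venous_mmol_l is None:
            raise InputError(
                f"scan {meta.subject_id}/{meta.session}: venous glycemia requested but absent"
            )
        return meta.glycemia_venous_mmol_l


@dataclass(frozen=True)
class PatlakPoints:
    """Patlak-transformed points: x = int_0^T Cp dt / Cp(T), y = Ct(T)/Cp(T)."""

    t_mid_min: np.ndarray
    x_min: np.ndarray
    y: np.ndarray


@dataclass(frozen=True)
class PatlakFit:
    """OLS fit of the Patlak plot; slope is the influx rate Ki."""

    ki_per_min: float
    intercept: float
    n_points: int
    r_squared: float
    t_star_min: float


@dataclass(frozen=True)
class QuantRecord:
    """All outcome parameters for one scan.

    ``values[region][parameter]`` holds the regional parameters; a reference
    region's ratio to itself is omitted rather than reported as 1.
    """

    subject_id: str
    session: str
    values: dict
    plasma_exposure_suv_min: float
    patlak: dict = field(default_factory=dict)


def integrate_trapezoid(times_min, values, t_end_min: float) -> float:
    """Trapezoidal AUC from 0 to ``t_end_min``.

    If the first sample is at t > 0, a leading segment rising linearly from
    (0, 0) to the first sample is included.  No extrapolation beyond the last
    sample is performed.
    """
    t = np.asarray(times_min, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != v.shape or t.size == 0:
        raise InputError("times and values must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    if t[0] < 0:
        raise InputError("times must be non-negative")
    if t_end_min < 0:
        raise InputError("t_end must be non-negative")
    if t_end_min > t[-1] + 1e-12:
        raise InputError(f"t_end={t_end_min} min beyond last sample at {t[-1]} min")
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    return float(_cumulative_integral(t, v, np.asarray([t_end_min]))[0])


def _cumulative_integral(t: np.ndarray, v: np.ndarray, t_query: np.ndarray) -> np.ndarray:
    """Exact int_0^tq of the piecewise-linear curve through (t, v), per query.

    Queries must lie within [t[0], t[-1]]; the curve integral is evaluated
    segment-exactly (trapezoid on full segments plus a partial trapezoid).
    """
    cum = np.concatenate([[0.0], np.cumsum(np.diff(t) * (v[:-1] + v[1:]) / 2.0)])
    idx = np.clip(np.searchsorted(t, t_query, side="right") - 1, 0, t.size - 2)
    t0, v0 = t[idx], v[idx]
    v_q = v0 + (t_query - t0) / (t[idx + 1] - t0) * (v[idx + 1] - v0)
    return cum[idx] + (t_query - t0) * (v0 + v_q) / 2.0


def normalize_to_suv(activity_kbq_ml, meta: ScanMeta):
    """Convert activity (kBq/mL) to SUV (g/mL): activity / (dose / weight)."""
    return np.asarray(activity_kbq_ml, dtype=float) / meta.suv_denominator_kbq_g


def plasma_exposure(aif: ArterialInputFunction, meta: ScanMeta,
                    t_end_min: float = 60.0) -> float:
    """AUC (0 to ``t_end_min``) of the SUV-normalized input function, SUV*min."""
    if aif.times_min[-1] < t_end_min - 1e-9:
        raise InputError(f"input function must span {t_end_min} min")
    suv = normalize_to_suv(aif.plasma_kbq_ml, meta)
    return integrate_trapezoid(aif.times_min, suv, t_end_min)


def suv_plateau(tac: TimeActivityCurve, meta: ScanMeta,
                cfg: QuantConfig = QuantConfig()) -> float:
    """Duration-weighted mean SUV over frames whose midpoints lie in the plateau window."""
    lo, hi = cfg.plateau_window_min
    mid = tac.schedule.midpoints_min
    in_window = (mid >= lo) & (mid <= hi)
    if not np.any(in_window):
        raise InputError(f"no frame midpoint inside plateau window [{lo}, {hi}] min")
    dur = tac.schedule.durations_s[in_window]
    act = tac.activity_kbq_ml[in_window]
    return float(normalize_to_suv(np.average(act, weights=dur), meta))


def patlak_points(tac: TimeActivityCurve, aif: ArterialInputFunction) -> PatlakPoints:
    """Patlak transform at frame midpoints, with Cp linearly interpolated."""
    t_mid = tac.schedule.midpoints_min
    t, cp = aif.times_min, aif.plasma_kbq_ml
    if t_mid[-1] > t[-1] + 1e-9:
        raise InputError("input function does not cover all frame midpoints")
    if t[0] > 0:  # leading rise from (0, 0), as in integrate_trapezoid
        t = np.concatenate([[0.0], t])
        cp = np.concatenate([[0.0], cp])
    cp_mid = np.interp(t_mid, t, cp)
    cum = _cumulative_integral(t, cp, t_mid)
    keep = cp_mid >= CP_POSITIVITY_FLOOR * float(np.max(cp))
    if not np.any(keep):
        raise InputError("all Patlak points dropped: plasma activity is ~0 at frame midpoints")
    return PatlakPoints(
        t_mid_min=t_mid[keep],
        x_min=cum[keep] / cp_mid[keep],
        y=tac.activity_kbq_ml[keep] / cp_mid[keep],
    )


def patlak_fit(points: PatlakPoints, cfg: QuantConfig = QuantConfig()) -> PatlakFit:
    """Ordinary least squares on Patlak points with frame midpoint >= t*."""
    sel = points.t_mid_min >= cfg.t_star_min - 1e-9
    x, y = points.x_min[sel], points.y[sel]
    if x.size < 3:
        raise InputError(f"Patlak fit needs >= 3 points at t >= {cfg.t_star_min} min, got {x.size}")
    if np.ptp(x) == 0:
        raise InputError("Patlak fit: zero variance in x")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot <= 1e-300 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
    return PatlakFit(
        ki_per_min=float(slope),
        intercept=float(intercept),
        n_points=int(x.size),
        r_squared=r2,
        t_star_min=cfg.t_star_min,
    )


def cmrglu(fit: PatlakFit, meta: ScanMeta, cfg: QuantConfig = QuantConfig()) -> float:
    """CMRglu (umol/min/100 g) = Ki * Gly / LC * 100 / density.

    Glycemia in mmol/L is numerically umol/mL, so Ki (mL plasma/min/mL
    tissue) * Gly gives umol/min/mL tissue; division by the lumped constant
    converts FDG flux to glucose flux and the factor 100/density converts to
    per-100 g of tissue.
    """
    gly = cfg.glycemia(meta)
    return fit.ki_per_min * gly / cfg.lumped_constant * 100.0 / cfg.tissue_density_g_ml


def quantify_scan(tacs: dict[str, TimeActivityCurve], aif: ArterialInputFunction,
                  meta: ScanMeta, cfg: QuantConfig = QuantConfig()) -> QuantRecord:
    """Compute all outcome parameters for one scan.

    ``tacs`` maps region label to its time-activity curve and must contain
    every reference region of ``cfg``.
    """
    for ref in cfg.reference_regions:
        if ref not in tacs:
            raise InputError(f"reference region {ref!r} missing from scan "
                             f"{meta.subject_id}/{meta.session}")
    gly = cfg.glycemia(meta)
    suvs = {r: suv_plateau(tac, meta, cfg) for r, tac in tacs.items()}
    fits = {r: patlak_fit(patlak_points(tac, aif), cfg) for r, tac in tacs.items()}
    values: dict[str, dict[str, float]] = {}
    for region in tacs:
        row = {
            "CMRglu": cmrglu(fits[region], meta, cfg),
            "SUV": suvs[region],
            "SUVxGly": suvs[region] * gly,
        }
        for ref in cfg.reference_regions:
            if region != ref:  # a reference region against itself is omitted
                row[f"SUVR_{ref}"] = suvs[region] / suvs[ref]
        values[region] = row
    return QuantRecord(
        subject_id=meta.subject_id,
        session=meta.session,
        values=values,
        plasma_exposure_suv_min=plasma_exposure(aif, meta),
        patlak=fits,
    )


def records_to_frame(records: list[QuantRecord]) -> pd.DataFrame:
    """Long-format table: subject_id, session, region, parameter, value."""
    rows = []
    for rec in records:
        for region, params in rec.values.items():
            for parameter, value in params.items():
                rows.append((rec.subject_id, rec.session, region, parameter, value))
        rows.append((rec.subject_id, rec.session, PLASMA_LABEL, "AUC_plasma",
                     rec.plasma_exposure_suv_min))
    return pd.DataFrame(rows, columns=["subject_id", "session", "region", "parameter", "value"])
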