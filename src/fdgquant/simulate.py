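"""Synthetic test-retest FDG study generator.

Generates complete studies — arterial input functions, regional tissue
curves, scan metadata and ground truth — with a known kinetic and variance
structure, so the quantification and repeatability pipeline can be tested
end to end without any acquired data.

The generative model, per subject ``i``, session ``s`` and region ``r``:

* a bolus-plus-tail arterial input function (gamma-variate bolus, two
  exponential tails), scaled so its SUV-normalized 0-60 min AUC hits a
  target plasma exposure, jittered per session by a lognormal factor
  (``global_scale_cv``);
* irreversible two-tissue-compartment kinetics driven by the session's
  input function; the regional trapping rate k3 is set from a reference
  influx-rate map, the subject effect ``exp(b_i)`` scales K1 (hence Ki);
* the session effect ``exp(e_is)`` multiplies the whole measured scan (a
  global, not regional, test-retest difference — reference-region ratios
  cancel it); a small regional residual ``exp(u_isr)`` mimics residual
  segmentation/repositioning differences;
* frame-binned values receive multiplicative Gaussian noise whose standard
  deviation scales with 1/sqrt(frame duration).

True influx rates are ``Ki(i,s,r) = ki_map[r] * exp(b_i) * exp(e_is)`` with
``b_i ~ N(0, sigma_inter^2)`` and ``e_is ~ N(0, sigma_intra^2)`` (log scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import fftconvolve

from .core import (
    DEFAULT_BLOOD_TIMES_MIN,
    ArterialInputFunction,
    FrameSchedule,
    ScanMeta,
    TimeActivityCurve,
)
from .errors import ConfigError, InputError

#: Dense simulation grid step (min); the forward-model accuracy contract.
MAX_GRID_STEP_MIN = 0.01

#: Default reference influx-rate map (min^-1).  Values chosen so that with
#: glycemia 4.5 mmol/L and lumped constant 0.34 the regional CMRglu means
#: span roughly 15-27 umol/min/100 g, lowest in the pons and highest in the
#: caudate/putamen/frontal regions.
DEFAULT_REGION_KI = {
    "pons": 0.0119,
    "occipital_cortex": 0.0128,
    "cortex": 0.0147,
    "globus_pallidum": 0.0147,
    "midbrain": 0.0154,
    "thalamus": 0.0156,
    "cerebellum": 0.0159,
    "caudate": 0.0188,
    "putamen": 0.0198,
    "frontal_cortex": 0.0199,
}


@dataclass(frozen=True)
class InputFunctionModel:
    """Parametric arterial input function: gamma-variate bolus + 2-exp tail.

    The continuous shape, for ``s = t - appearance_delay >= 0``::

        Cp(t) ~ amplitude * [ (s/sp)^shape * exp(shape * (1 - s/sp))
                              + ramp(s) * (f1*exp(-r1*s) + f2*exp(-r2*s)) ]

    with ``sp = bolus_shape / bolus_rate`` the bolus peak lag and
    ``ramp(s) = (1 - exp(-bolus_rate * s))^2`` a smooth onset of the tail.
    The absolute scale is set by ``target_exposure_suv_min``: the curve is
    scaled so its SUV-normalized AUC over 0-60 min equals that exposure.
    """

    appearance_delay_min: float = 0.25
    bolus_amplitude: float = 1.0
    bolus_shape: float = 3.0
    bolus_rate_per_min: float = 6.25
    tail_fractions: tuple[float, float] = (0.08, 0.15)
    tail_rates_per_min: tuple[float, float] = (0.01, 0.7)
    target_exposure_suv_min: float = 94.1

    def __post_init__(self):
        if self.bolus_rate_per_min <= 0 or any(r <= 0 for r in self.tail_rates_per_min):
            raise ConfigError("all input-function rates must be positive")
        if self.bolus_amplitude <= 0 or self.bolus_shape <= 0:
            raise ConfigError("bolus amplitude and shape must be positive")
        if any(f < 0 for f in self.tail_fractions):
            raise ConfigError("tail fractions must be non-negative")
        if self.appearance_delay_min < 0:
            raise ConfigError("appearance delay must be non-negative")

    def shape(self, t_min) -> np.ndarray:
        """Unitless continuous Cp shape; zero before the appearance delay."""
        t = np.asarray(t_min, dtype=float)
        s = t - self.appearance_delay_min
        s = np.where(s > 0, s, 0.0)
        sp = self.bolus_shape / self.bolus_rate_per_min
        with np.errstate(divide="ignore", invalid="ignore"):
            bolus = (s / sp) ** self.bolus_shape * np.exp(self.bolus_shape * (1.0 - s / sp))
        bolus = np.where(s > 0, bolus, 0.0)
        f1, f2 = self.tail_fractions
        r1, r2 = self.tail_rates_per_min
        ramp = (1.0 - np.exp(-self.bolus_rate_per_min * s)) ** 2
        tail = ramp * (f1 * np.exp(-r1 * s) + f2 * np.exp(-r2 * s))
        return self.bolus_amplitude * (bolus + np.where(s > 0, tail, 0.0))


@dataclass(frozen=True)
class KineticParams:
    """Irreversible two-tissue-compartment rate constants.

    K1 (mL plasma/min/mL tissue) is delivery, k2 (1/min) efflux from the
    free compartment, k3 (1/min) trapping, vB the blood-volume fraction.
    The net influx rate is ``Ki = K1*k3/(k2 + k3) < K1``; ``k3 = 0`` is
    allowed as the reversible (no-trapping) limit with Ki = 0.
    """

    k1: float
    k2: float
    k3: float
    vb: float = 0.0

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0 or self.k3 < 0:
            raise InputError("K1 and k2 must be positive and k3 non-negative")
        if not 0 <= self.vb < 1:
            raise InputError("blood-volume fraction must be in [0, 1)")

    @property
    def ki(self) -> float:
        return self.k1 * self.k3 / (self.k2 + self.k3)


def simulation_grid(t_end_min: float = 60.0, dt_min: float = MAX_GRID_STEP_MIN) -> np.ndarray:
    """Uniform dense time grid [0, t_end] used by the forward model."""
    n = int(round(t_end_min / dt_min))
    return np.linspace(0.0, t_end_min, n + 1)


def aif_on_grid(model: InputFunctionModel, t_grid_min: np.ndarray,
                dose_mbq: float, weight_kg: float,
                exposure_scale: float = 1.0) -> np.ndarray:
    """Continuous Cp (kBq/mL) on a dense grid, calibrated to the target exposure.

    The shape is scaled so the SUV-normalized AUC over the grid equals
    ``target_exposure_suv_min * exposure_scale`` given the injected dose and
    body weight.
    """
    if dose_mbq <= 0 or weight_kg <= 0:
        raise InputError("dose and weight must be positive")
    shape = model.shape(t_grid_min)
    auc_shape = float(np.trapezoid(shape, t_grid_min))
    suv_denom = dose_mbq * 1000.0 / (weight_kg * 1000.0)  # kBq per g
    scale = model.target_exposure_suv_min * exposure_scale * suv_denom / auc_shape
    return shape * scale


def simulate_aif(model: InputFunctionModel, sample_times_min,
                 dose_mbq: float, weight_kg: float,
                 exposure_scale: float = 1.0) -> ArterialInputFunction:
    """Sample the continuous input-function model on a blood-draw schedule."""
    t = np.asarray(sample_times_min, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise InputError("sample times must be a non-empty 1-D array")
    if np.any(t < 0):
        raise InputError("sample times must be non-negative")
    if np.any(np.diff(t) <= 0):
        raise InputError("sample times must be sorted strictly increasing")
    grid = simulation_grid(max(60.0, float(t[-1])))
    cp_grid = aif_on_grid(model, grid, dose_mbq, weight_kg, exposure_scale)
    cp = np.interp(t, grid, cp_grid)
    return ArterialInputFunction(times_min=t, plasma_kbq_ml=cp)


def tissue_curve(params: KineticParams, t_grid_min: np.ndarray,
                 cp_kbq_ml: np.ndarray) -> np.ndarray:
    """Forward model: continuous Ct on the dense grid of the input function.

    Solves ``dC1/dt = K1*Cp - (k2+k3)*C1``, ``dC2/dt = k3*C1`` by discrete
    (trapezoid-corrected FFT) convolution and returns
    ``Ct = (1-vB)*(C1+C2) + vB*Cp`` (plasma stands in for whole blood).
    """
    t = np.asarray(t_grid_min, dtype=float)
    cp = np.asarray(cp_kbq_ml, dtype=float)
    _check_grid(t, cp)
    c1, c2 = _compartments(np.array([params.k1]), np.array([params.k2]),
                           np.array([params.k3]), t, cp)
    ct = (1.0 - params.vb) * (c1[0] + c2[0]) + params.vb * cp
    return np.maximum(ct, 0.0)


def _check_grid(t: np.ndarray, cp: np.ndarray) -> float:
    if t.ndim != 1 or t.shape != cp.shape or t.size < 2:
        raise InputError("grid and Cp must be equal-length 1-D arrays")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ConfigError("the dense grid must be uniform")
    if dt[0] > MAX_GRID_STEP_MIN + 1e-12:
        raise ConfigError(
            f"grid step {dt[0]:.4g} min exceeds the accuracy contract of "
            f"{MAX_GRID_STEP_MIN} min"
        )
    return float(dt[0])


def _compartments(k1: np.ndarray, k2: np.ndarray, k3: np.ndarray,
                  t: np.ndarray, cp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized C1/C2 solutions for several parameter sets sharing one Cp."""
    dt = float(t[1] - t[0])
    n = t.size
    a = (k2 + k3)[:, None]
    kern = np.exp(-a * t[None, :])
    conv = fftconvolve(cp[None, :], kern, axes=1)[:, :n] * dt
    conv -= 0.5 * dt * (cp[0] * kern + kern[:, [0]] * cp[None, :])  # trapezoid ends
    c1 = k1[:, None] * conv
    np.maximum(c1, 0.0, out=c1)
    c2 = k3[:, None] * cumulative_trapezoid(c1, t, axis=1, initial=0.0)
    return c1, c2


def bin_to_frames(t_grid_min: np.ndarray, ct_kbq_ml: np.ndarray,
                  schedule: FrameSchedule, region: str = "region") -> TimeActivityCurve:
    """Duration-weighted frame averages of a dense tissue curve."""
    t = np.asarray(t_grid_min, dtype=float)
    ct = np.asarray(ct_kbq_ml, dtype=float)
    if schedule.span_s / 60.0 > t[-1] + 1e-9 or schedule.starts_s[0] / 60.0 < t[0] - 1e-9:
        raise InputError("frame schedule exceeds the span of the dense curve")
    cum = cumulative_trapezoid(ct, t, initial=0.0)
    starts = schedule.starts_s / 60.0
    ends = schedule.ends_s / 60.0
    i_start = np.interp(starts, t, cum)
    i_end = np.interp(ends, t, cum)
    mean = (i_end - i_start) / (ends - starts)
    return TimeActivityCurve(region=region, schedule=schedule,
                             activity_kbq_ml=np.maximum(mean, 0.0))


def add_measurement_noise(tac: TimeActivityCurve, noise_cv: float,
                          rng: np.random.Generator) -> TimeActivityCurve:
    """Multiplicative Gaussian frame noise, sd scaled by 1/sqrt(duration).

    ``noise_cv`` is the coefficient of variation of the *longest* frame;
    shorter frames get proportionally larger noise.  Values are clipped at 0.
    ``noise_cv = 0`` returns the input unchanged.
    """
    if noise_cv < 0:
        raise InputError("noise_cv must be non-negative")
    if noise_cv == 0:
        return tac
    dur = tac.schedule.durations_s
    sd = noise_cv * np.sqrt(dur.max() / dur)
    noisy = tac.activity_kbq_ml * (1.0 + sd * rng.standard_normal(dur.size))
    return replace(tac, activity_kbq_ml=np.maximum(noisy, 0.0))


@dataclass(frozen=True)
class StudyDesign:
    """All knobs of the synthetic study generator.

    Log-scale standard deviations (``sigma_*``) act multiplicatively:
    ``sigma_inter`` is the between-subject effect on Ki, ``sigma_intra`` the
    session (test-retest) effect applied as a *global* scan-scale factor, and
    ``sigma_region`` a per-region session residual (segmentation /
    repositioning differences) that survives reference-region normalization.
    ``global_scale_cv`` jitters the plasma exposure of each session.
    ``glycemia_icc`` splits the glycemia variance between a stable
    per-subject level and session-to-session fluctuation.
    """

    n_subjects: int = 6
    n_sessions: int = 2
    region_ki_map: dict = field(default_factory=lambda: dict(DEFAULT_REGION_KI))
    sigma_inter: float = 0.05
    sigma_intra: float = 0.18
    sigma_region: float = 0.06
    global_scale_cv: float = 0.145
    glycemia_mean: float = 4.5
    glycemia_sd: float = 0.7
    glycemia_icc: float = 0.75
    venous_slope: float = 0.972
    venous_resid_sd: float = 0.25
    dose_mean_mbq: float = 169.2
    dose_sd_mbq: float = 9.0
    weight_mean_kg: float = 5.8
    weight_sd_kg: float = 1.1
    noise_cv: float = 0.05
    rng_seed: int = 1234
    k1: float = 0.10
    k2: float = 0.13
    vb: float = 0.0
    aif_model: InputFunctionModel = field(default_factory=InputFunctionModel)
    frame_schedule: FrameSchedule = field(default_factory=FrameSchedule.default)
    blood_times_min: np.ndarray = field(
        default_factory=lambda: DEFAULT_BLOOD_TIMES_MIN.copy())

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.n_sessions not in (1, 2):
            raise ConfigError("n_sessions must be 1 (robustness group) or 2 (test-retest)")
        for name in ("sigma_inter", "sigma_intra", "sigma_region", "global_scale_cv",
                     "glycemia_sd", "venous_resid_sd", "dose_sd_mbq", "weight_sd_kg",
                     "noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 <= self.glycemia_icc <= 1:
            raise ConfigError("glycemia_icc must be in [0, 1]")
        for ref in ("pons", "cerebellum"):
            if ref not in self.region_ki_map:
                raise ConfigError(f"region_ki_map must include {ref!r}")
        for region, ki in self.region_ki_map.items():
            if not 0 < ki < self.k1:
                raise ConfigError(f"region {region!r}: reference Ki must be in (0, K1)")

    @property
    def session_labels(self) -> tuple[str, ...]:
        return ("test", "retest") if self.n_sessions == 2 else ("single",)

    def region_k3(self, region: str) -> float:
        """Trapping rate that yields the region's reference Ki at (k1, k2)."""
        ki = self.region_ki_map[region]
        return self.k2 * ki / (self.k1 - ki)


@dataclass(frozen=True)
class ScanRecord:
    """One simulated scan: metadata, sampled AIF and per-region TACs."""

    meta: ScanMeta
    aif: ArterialInputFunction
    tacs: dict


@dataclass(frozen=True)
class SimulatedStudy:
    """A full synthetic study plus its generating truth.

    ``truth`` has one row per (subject, session, region) with the realized
    kinetic parameters, true Ki and the subject/session effects.
    """

    design: StudyDesign
    scans: list
    truth: pd.DataFrame


def simulate_glycemia(design: StudyDesign, rng: np.random.Generator,
                      n: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` (arterial, venous) glycemia pairs from the design's marginal.

    Arterial ~ Normal(mean, sd) truncated above 0.5 mmol/L; venous is a
    linear response ``venous_slope * arterial`` plus Gaussian residual.
    """
    arterial = _truncated_normal(rng, design.glycemia_mean, design.glycemia_sd, 0.5, n)
    venous = design.venous_slope * arterial + rng.normal(0.0, design.venous_resid_sd, n)
    return arterial, np.maximum(venous, 0.1)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, n: int | None = None) -> np.ndarray | float:
    size = 1 if n is None else n
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = out <= lower
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    out = np.maximum(out, lower + 1e-9)
    return float(out[0]) if n is None else out


def _lognormal_scale(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal factor with the given coefficient of variation."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def simulate_study(design: StudyDesign) -> SimulatedStudy:
    """Generate a complete synthetic study, reproducible from ``rng_seed``.

    Draw order is fixed: per subject — subject effect, glycemia level; per
    session — session effect, exposure scale, dose, weight, glycemia pair;
    then per region (map order) — regional residual; then per region — frame
    noise.  Changing one design field therefore perturbs only the draws that
    depend on it structurally.
    """
    rng = np.random.default_rng(design.rng_seed)
    regions = list(design.region_ki_map)
    k3 = np.array([design.region_k3(r) for r in regions])
    k1_base = np.full(len(regions), design.k1)
    k2 = np.full(len(regions), design.k2)
    grid = simulation_grid()
    gly_level_sd = design.glycemia_sd * math.sqrt(design.glycemia_icc)
    gly_sess_sd = design.glycemia_sd * math.sqrt(1.0 - design.glycemia_icc)

    scans: list[ScanRecord] = []
    truth_rows = []
    for i in range(design.n_subjects):
        subject = f"m{i + 1:02d}"
        b_i = rng.normal(0.0, design.sigma_inter) if design.sigma_inter else 0.0
        gly_level = rng.normal(design.glycemia_mean, gly_level_sd)
        for session in design.session_labels:
            e_is = rng.normal(0.0, design.sigma_intra) if design.sigma_intra else 0.0
            c_is = _lognormal_scale(rng, design.global_scale_cv)
            dose = _truncated_normal(rng, design.dose_mean_mbq, design.dose_sd_mbq, 1.0)
            weight = _truncated_normal(rng, design.weight_mean_kg, design.weight_sd_kg, 0.5)
            arterial = _truncated_normal(rng, gly_level, gly_sess_sd, 0.5)
            venous = max(design.venous_slope * arterial
                         + rng.normal(0.0, design.venous_resid_sd), 0.1)
            u = (rng.normal(0.0, design.sigma_region, len(regions))
                 if design.sigma_region else np.zeros(len(regions)))

            cp_grid = aif_on_grid(design.aif_model, grid, dose, weight, c_is)
            aif = ArterialInputFunction(
                times_min=design.blood_times_min,
                plasma_kbq_ml=np.interp(design.blood_times_min, grid, cp_grid),
            )
            c1, c2 = _compartments(k1_base * math.exp(b_i), k2, k3, grid, cp_grid)
            ct = (1.0 - design.vb) * (c1 + c2) + design.vb * cp_grid[None, :]
            scan_scale = math.exp(e_is)

            meta = ScanMeta(
                subject_id=subject, session=session,
                injected_dose_mbq=dose, body_weight_kg=weight,
                glycemia_arterial_mmol_l=arterial, glycemia_venous_mmol_l=venous,
            )
            tacs = {}
            for j, region in enumerate(regions):
                measured = ct[j] * scan_scale * math.exp(u[j])
                tac = bin_to_frames(grid, measured, design.frame_schedule, region)
                tacs[region] = add_measurement_noise(tac, design.noise_cv, rng)
                truth_rows.append((
                    subject, session, region,
                    design.k1 * math.exp(b_i), design.k2, k3[j],
                    design.region_ki_map[region] * math.exp(b_i) * math.exp(e_is),
                    b_i, e_is,
                ))
            scans.append(ScanRecord(meta=meta, aif=aif, tacs=tacs))

    truth = pd.DataFrame(
        truth_rows,
        columns=["subject_id", "session", "region", "K1", "k2", "k3", "Ki",
                 "subject_effect", "session_effect"],
    )
    return SimulatedStudy(design=design, scans=scans, truth=truth)
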