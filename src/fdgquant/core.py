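"""Core data containers: frame schedules, input functions, tissue curves, scan metadata.

All activities are decay-corrected kBq/mL.  Frame times are kept in seconds
(the convention of scanner rebinning protocols), blood-sample times in decimal
minutes post-injection; converters are provided on the containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError

SESSIONS = ("test", "retest", "single")

#: Printed rebinning durations of the acquisition protocol (count, seconds).
#: The full printed sequence sums to 120 min; the emission scan lasts 60 min,
#: so the default schedule truncates the trailing 600 s frames at 3600 s,
#: yielding 21 frames.
PRINTED_FRAME_DURATIONS = ((4, 15), (4, 30), (2, 60), (5, 120), (3, 300), (9, 600))


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frame binning.

    Parameters
    ----------
    starts_s, ends_s:
        Frame start/end times in seconds.  Frames must be contiguous,
        strictly increasing, and start at 0.
    """

    starts_s: np.ndarray
    ends_s: np.ndarray

    def __post_init__(self):
        starts = np.asarray(self.starts_s, dtype=float)
        ends = np.asarray(self.ends_s, dtype=float)
        object.__setattr__(self, "starts_s", starts)
        object.__setattr__(self, "ends_s", ends)
        if starts.ndim != 1 or starts.shape != ends.shape or starts.size == 0:
            raise InputError("frame starts/ends must be equal-length 1-D arrays")
        if starts[0] != 0:
            raise InputError("first frame must start at 0 s")
        if np.any(ends <= starts):
            raise InputError("every frame must have positive duration")
        if np.any(starts[1:] != ends[:-1]):
            raise InputError("frames must be contiguous and non-overlapping")

    @classmethod
    def from_durations(cls, durations: "list[tuple[int, float]] | tuple",
                       max_end_s: float | None = None) -> "FrameSchedule":
        """Build a schedule from ``(count, duration_s)`` groups.

        ``max_end_s`` truncates the schedule: frames starting at or beyond it
        are dropped and a frame crossing it is clipped.
        """
        durs = []
        for count, dur in durations:
            durs.extend([float(dur)] * int(count))
        ends = np.cumsum(durs)
        starts = ends - np.asarray(durs)
        if max_end_s is not None:
            keep = starts < max_end_s
            starts, ends = starts[keep], np.minimum(ends[keep], max_end_s)
        return cls(starts, ends)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """21-frame schedule: printed durations truncated at 3600 s."""
        return cls.from_durations(PRINTED_FRAME_DURATIONS, max_end_s=3600.0)

    @property
    def n_frames(self) -> int:
        return int(self.starts_s.size)

    @property
    def durations_s(self) -> np.ndarray:
        return self.ends_s - self.starts_s

    @property
    def midpoints_min(self) -> np.ndarray:
        return (self.starts_s + self.ends_s) / 2.0 / 60.0

    @property
    def span_s(self) -> float:
        return float(self.ends_s[-1])


#: Default arterial blood-sampling schedule (minutes): a pre-injection sample,
#: every 15 s during the first 2 min, then 2.5, 3, 5, 10, 20, 40 and 60 min.
DEFAULT_BLOOD_TIMES_MIN = np.concatenate(
    [np.arange(0.0, 2.01, 0.25), [2.5, 3.0, 5.0, 10.0, 20.0, 40.0, 60.0]]
)


@dataclass(frozen=True)
class ArterialInputFunction:
    """Timed, decay-corrected plasma activity samples Cp(t).

    ``times_min`` must be strictly increasing and non-negative with at least
    4 samples, one of which is at >= 30 min (a Patlak fit window needs late
    plasma data).
    """

    times_min: np.ndarray
    plasma_kbq_ml: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        c = np.asarray(self.plasma_kbq_ml, dtype=float)
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "plasma_kbq_ml", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise InputError("times and activities must be equal-length 1-D arrays")
        if t.size < 4:
            raise InputError("an input function needs at least 4 samples")
        if np.any(np.diff(t) <= 0):
            raise InputError("sample times must be strictly increasing")
        if t[0] < 0:
            raise InputError("sample times must be non-negative")
        if np.any(c < 0):
            raise InputError("plasma activities must be non-negative")
        if t[-1] < 30.0:
            raise InputError("at least one plasma sample at >= 30 min is required")

    @property
    def n_samples(self) -> int:
        return int(self.times_min.size)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Frame-binned, decay-corrected tissue activity Ct for one region."""

    region: str
    schedule: FrameSchedule
    activity_kbq_ml: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.activity_kbq_ml, dtype=float)
        object.__setattr__(self, "activity_kbq_ml", a)
        if a.ndim != 1 or a.size != self.schedule.n_frames:
            raise InputError(
                f"region {self.region!r}: activity length {a.size} does not match "
                f"frame count {self.schedule.n_frames}"
            )
        if np.any(a < 0):
            raise InputError(f"region {self.region!r}: negative frame activity")


@dataclass(frozen=True)
class ScanMeta:
    """Per-scan metadata: dose, weight and glycemia normalizers."""

    subject_id: str
    session: str
    injected_dose_mbq: float
    body_weight_kg: float
    glycemia_arterial_mmol_l: float
    glycemia_venous_mmol_l: float | None = None

    def __post_init__(self):
        if self.session not in SESSIONS:
            raise InputError(f"unknown session label {self.session!r}; expected one of {SESSIONS}")
        if not self.injected_dose_mbq > 0:
            raise InputError("injected dose must be positive")
        if not self.body_weight_kg > 0:
            raise InputError("body weight must be positive")
        if not self.glycemia_arterial_mmol_l > 0:
            raise InputError("arterial glycemia must be positive")
        if self.glycemia_venous_mmol_l is not None and not self.glycemia_venous_mmol_l > 0:
            raise InputError("venous glycemia must be positive when present")

    @property
    def dose_kbq(self) -> float:
        return self.injected_dose_mbq * 1000.0

    @property
    def weight_g(self) -> float:
        return self.body_weight_kg * 1000.0

    @property
    def suv_denominator_kbq_g(self) -> float:
        """Injected activity per body mass, kBq/g: the SUV normalizer."""
        return self.dose_kbq / self.weight_g
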