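"""CSV interchange formats for studies (TAC, blood, metadata, truth tables).

Plain RFC-4180 CSV with "." decimals and fixed headers is the exchange
format; image-domain formats are out of scope.  All writers/readers
round-trip values at better than 1e-9 relative accuracy (floats are written
with 12 significant digits).

Schemas
-------
* TACs:  ``subject_id, session, region, frame_start_s, frame_end_s,
  activity_kbq_per_ml`` — one row per frame.
* Blood: ``subject_id, session, time_min, plasma_kbq_per_ml``.
* Meta:  ``subject_id, session, injected_dose_mbq, body_weight_kg,
  glycemia_arterial_mmol_l, glycemia_venous_mmol_l`` (venous may be blank).
* Truth: ``subject_id, session, region, K1, k2, k3, Ki, subject_effect,
  session_effect``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SESSIONS, ArterialInputFunction, FrameSchedule, ScanMeta, TimeActivityCurve
from .errors import FormatError, InputError
from .simulate import ScanRecord, SimulatedStudy

FLOAT_FMT = "%.12g"

TAC_COLUMNS = ["subject_id", "session", "region", "frame_start_s", "frame_end_s",
               "activity_kbq_per_ml"]
BLOOD_COLUMNS = ["subject_id", "session", "time_min", "plasma_kbq_per_ml"]
META_COLUMNS = ["subject_id", "session", "injected_dose_mbq", "body_weight_kg",
                "glycemia_arterial_mmol_l", "glycemia_venous_mmol_l"]


@dataclass(frozen=True)
class StudyBundle:
    """A consistent set of scans (+ optional simulation truth and provenance)."""

    scans: list
    truth: pd.DataFrame | None = None
    provenance: dict | None = None

    def scan_map(self) -> dict:
        return {(s.meta.subject_id, s.meta.session): s for s in self.scans}


def _require_columns(df: pd.DataFrame, expected: list[str], path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}; expected header {expected}")


def _check_sessions(df: pd.DataFrame, path) -> None:
    bad = df.loc[~df["session"].isin(SESSIONS)]
    if len(bad):
        row = int(bad.index[0]) + 2  # header is line 1
        raise FormatError(f"{path}:{row}: unknown session label {bad['session'].iloc[0]!r}")


def tacs_to_frame(scans: list[ScanRecord]) -> pd.DataFrame:
    rows = []
    for scan in scans:
        sid, sess = scan.meta.subject_id, scan.meta.session
        for region, tac in scan.tacs.items():
            for s, e, a in zip(tac.schedule.starts_s, tac.schedule.ends_s,
                               tac.activity_kbq_ml):
                rows.append((sid, sess, region, s, e, a))
    return pd.DataFrame(rows, columns=TAC_COLUMNS)


def blood_to_frame(scans: list[ScanRecord]) -> pd.DataFrame:
    rows = []
    for scan in scans:
        sid, sess = scan.meta.subject_id, scan.meta.session
        for t, c in zip(scan.aif.times_min, scan.aif.plasma_kbq_ml):
            rows.append((sid, sess, t, c))
    return pd.DataFrame(rows, columns=BLOOD_COLUMNS)


def meta_to_frame(scans: list[ScanRecord]) -> pd.DataFrame:
    rows = []
    for scan in scans:
        m = scan.meta
        rows.append((m.subject_id, m.session, m.injected_dose_mbq, m.body_weight_kg,
                     m.glycemia_arterial_mmol_l,
                     np.nan if m.glycemia_venous_mmol_l is None else m.glycemia_venous_mmol_l))
    return pd.DataFrame(rows, columns=META_COLUMNS)


def write_study(study: SimulatedStudy | StudyBundle, out_dir) -> dict[str, Path]:
    """Write tacs/blood/meta (and truth, when available) CSVs; returns paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scans = study.scans
    paths = {}
    for name, df in (("tacs", tacs_to_frame(scans)), ("blood", blood_to_frame(scans)),
                     ("meta", meta_to_frame(scans))):
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False, float_format=FLOAT_FMT)
    truth = getattr(study, "truth", None)
    if truth is not None:
        paths["truth"] = out / "truth.csv"
        truth.to_csv(paths["truth"], index=False, float_format=FLOAT_FMT)
    return paths


def read_tacs(path) -> dict:
    """Read a TAC table -> {(subject, session): {region: TimeActivityCurve}}.

    Frames of each (subject, session, region) must form a valid schedule
    (contiguous, starting at 0); violations are reported with the file row
    of the offending frame.
    """
    df = pd.read_csv(path)
    _require_columns(df, TAC_COLUMNS, path)
    _check_sessions(df, path)
    out: dict = {}
    for (sid, sess, region), grp in df.groupby(["subject_id", "session", "region"],
                                               sort=False):
        grp = grp.sort_values("frame_start_s")
        starts = grp["frame_start_s"].to_numpy(dtype=float)
        ends = grp["frame_end_s"].to_numpy(dtype=float)
        gap = np.nonzero(starts[1:] != ends[:-1])[0]
        if gap.size:
            row = int(grp.index[gap[0] + 1]) + 2
            raise FormatError(
                f"{path}:{row}: frame starting at {starts[gap[0] + 1]:g} s is not "
                f"contiguous with previous frame ending at {ends[gap[0]]:g} s "
                f"({sid}/{sess}/{region})")
        try:
            schedule = FrameSchedule(starts, ends)
            tac = TimeActivityCurve(region=str(region), schedule=schedule,
                                    activity_kbq_ml=grp["activity_kbq_per_ml"]
                                    .to_numpy(dtype=float))
        except InputError as exc:
            raise FormatError(f"{path}: {sid}/{sess}/{region}: {exc}") from exc
        out.setdefault((sid, sess), {})[str(region)] = tac
    return out


def read_blood(path) -> dict:
    """Read a blood table -> {(subject, session): ArterialInputFunction}."""
    df = pd.read_csv(path)
    _require_columns(df, BLOOD_COLUMNS, path)
    _check_sessions(df, path)
    if (df["time_min"] < 0).any():
        row = int(df.index[df["time_min"] < 0][0]) + 2
        raise FormatError(f"{path}:{row}: negative sample time")
    out = {}
    for (sid, sess), grp in df.groupby(["subject_id", "session"], sort=False):
        dup = grp["time_min"].duplicated()
        if dup.any():
            row = int(grp.index[dup][0]) + 2
            raise FormatError(f"{path}:{row}: duplicate sample time "
                              f"{grp.loc[dup, 'time_min'].iloc[0]:g} min ({sid}/{sess})")
        grp = grp.sort_values("time_min")
        try:
            out[(sid, sess)] = ArterialInputFunction(
                times_min=grp["time_min"].to_numpy(dtype=float),
                plasma_kbq_ml=grp["plasma_kbq_per_ml"].to_numpy(dtype=float))
        except InputError as exc:
            raise FormatError(f"{path}: {sid}/{sess}: {exc}") from exc
    return out


def read_meta(path) -> dict:
    """Read a metadata table -> {(subject, session): ScanMeta}."""
    df = pd.read_csv(path)
    _require_columns(df, META_COLUMNS, path)
    _check_sessions(df, path)
    out = {}
    for i, row in df.iterrows():
        venous = row["glycemia_venous_mmol_l"]
        try:
            meta = ScanMeta(
                subject_id=str(row["subject_id"]), session=str(row["session"]),
                injected_dose_mbq=float(row["injected_dose_mbq"]),
                body_weight_kg=float(row["body_weight_kg"]),
                glycemia_arterial_mmol_l=float(row["glycemia_arterial_mmol_l"]),
                glycemia_venous_mmol_l=None if pd.isna(venous) else float(venous))
        except InputError as exc:
            raise FormatError(f"{path}:{int(i) + 2}: {exc}") from exc
        key = (meta.subject_id, meta.session)
        if key in out:
            raise FormatError(f"{path}:{int(i) + 2}: duplicate scan {key}")
        out[key] = meta
    return out


def read_bundle(tac_path, blood_path, meta_path, truth_path=None) -> StudyBundle:
    """Assemble scans from the three tables, checking key consistency."""
    tacs = read_tacs(tac_path)
    blood = read_blood(blood_path)
    meta = read_meta(meta_path)
    missing_blood = set(tacs) - set(blood)
    missing_meta = set(tacs) - set(meta)
    if missing_blood or missing_meta:
        raise FormatError(
            f"scans without blood data: {sorted(missing_blood)}; "
            f"without metadata: {sorted(missing_meta)}")
    scans = [ScanRecord(meta=meta[key], aif=blood[key], tacs=tacs[key])
             for key in tacs]
    truth = pd.read_csv(truth_path) if truth_path is not None else None
    return StudyBundle(scans=scans, truth=truth)
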