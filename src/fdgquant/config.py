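"""YAML study configuration: design, quantification and robustness sections.

A config file mirrors :class:`~fdgquant.simulate.StudyDesign` and
:class:`~fdgquant.quantify.QuantConfig`::

    design:
      n_subjects: 6
      sigma_intra: 0.18
      region_ki_map: {pons: 0.0119, cerebellum: 0.0159, ...}
      aif_model: {bolus_rate_per_min: 6.25, ...}
      frame_durations: [[4, 15], [4, 30], [2, 60], [5, 120], [3, 300], [9, 600]]
      frame_max_end_s: 3600
      blood_times_min: [0.0, 0.25, ...]
    quantification:
      lumped_constant: 0.34
      t_star_min: 30
    robustness:
      n_subjects: 4

Omitted keys fall back to the package defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .core import FrameSchedule
from .errors import ConfigError
from .quantify import QuantConfig
from .simulate import InputFunctionModel, StudyDesign


def load_config(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return cfg


def _known_fields(cls, data: dict, where: str) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    return data


def design_from_config(cfg: dict, seed: int | None = None) -> StudyDesign:
    """Build a StudyDesign from the ``design`` section; ``seed`` overrides."""
    data = dict(cfg.get("design") or {})
    kwargs = {}
    if "aif_model" in data:
        model = _known_fields(InputFunctionModel, dict(data.pop("aif_model")),
                              "design.aif_model")
        model = {k: tuple(v) if isinstance(v, list) else v for k, v in model.items()}
        kwargs["aif_model"] = InputFunctionModel(**model)
    durations = data.pop("frame_durations", None)
    max_end = data.pop("frame_max_end_s", 3600.0)
    if durations is not None:
        kwargs["frame_schedule"] = FrameSchedule.from_durations(
            [tuple(d) for d in durations], max_end_s=max_end)
    if "blood_times_min" in data:
        kwargs["blood_times_min"] = np.asarray(data.pop("blood_times_min"), dtype=float)
    if "region_ki_map" in data:
        kwargs["region_ki_map"] = dict(data.pop("region_ki_map"))
    _known_fields(StudyDesign, data, "design")
    kwargs.update(data)
    if seed is not None:
        kwargs["rng_seed"] = int(seed)
    return StudyDesign(**kwargs)


def quant_from_config(cfg: dict) -> QuantConfig:
    data = dict(cfg.get("quantification") or {})
    for key in ("plateau_window_min", "reference_regions"):
        if key in data:
            data[key] = tuple(data[key])
    _known_fields(QuantConfig, data, "quantification")
    return QuantConfig(**data)


def config_hash(cfg: dict) -> str:
    """Stable sha256 of a canonical JSON rendering of the config."""
    canon = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()


def derive_seed(seed: int, stream: int) -> int:
    """Deterministic child seed (< 2**31) for an auxiliary random stream."""
    state = np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0]
    return int(state % (2**31))


def dump_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True), encoding="utf-8")
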