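"""End-to-end pipeline: simulate -> quantify -> repeatability -> robustness.

`run_pipeline` executes the stages in order, writes every intermediate and
final table as CSV plus a provenance record, and is byte-reproducible from
the configuration (including its seed): no timestamps enter the outputs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import config_hash, derive_seed, design_from_config, quant_from_config
from .errors import ConfigError, FdgQuantError, PipelineError
from .io import FLOAT_FMT, StudyBundle, write_study
from .quantify import QuantConfig, quantify_scan, records_to_frame
from .repeatability import parameter_correlations, repeatability_table, robustness_check
from .simulate import simulate_study

log = logging.getLogger("fdgquant")


def quantify_bundle(bundle: StudyBundle, qcfg: QuantConfig):
    """Quantify every scan of a bundle -> long-format table."""
    records = [quantify_scan(scan.tacs, scan.aif, scan.meta, qcfg)
               for scan in bundle.scans]
    return records_to_frame(records)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except FdgQuantError as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_pipeline(cfg: dict, out_dir, seed: int | None = None) -> Path:
    """Run the full synthetic study pipeline; returns the output directory.

    Outputs: study CSVs (tacs/blood/meta/truth), ``quant.csv`` (long format),
    ``repeatability.csv`` (one row per region x parameter), ``correlations.csv``,
    ``robustness*.csv`` when a robustness group is configured, and
    ``provenance.json`` (seed, config hash, versions).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = design_from_config(cfg, seed=seed)
    qcfg = quant_from_config(cfg)
    for ref in qcfg.reference_regions:
        if ref not in design.region_ki_map:
            raise ConfigError(f"reference region {ref!r} absent from design.region_ki_map")
    if design.n_sessions != 2:
        raise ConfigError("the pipeline's main group needs n_sessions = 2 (test-retest)")

    log.info("simulating test-retest study (%d subjects)", design.n_subjects)
    study = _stage("simulate")(simulate_study)(design)
    write_study(study, out / "study")

    log.info("quantifying %d scans", len(study.scans))
    quant = _stage("quantify")(quantify_bundle)(StudyBundle(scans=study.scans), qcfg)
    quant.to_csv(out / "quant.csv", index=False, float_format=FLOAT_FMT)

    log.info("computing repeatability statistics")
    table = _stage("repeatability")(repeatability_table)(quant)
    table.to_csv(out / "repeatability.csv", index=False, float_format=FLOAT_FMT)
    corr = _stage("repeatability")(parameter_correlations)(quant)
    corr.to_csv(out / "correlations.csv", index=False, float_format=FLOAT_FMT)

    rob_cfg = cfg.get("robustness") or {}
    if rob_cfg.get("n_subjects", 4) and rob_cfg.get("enabled", True):
        import dataclasses
        n_rob = int(rob_cfg.get("n_subjects", 4))
        rob_design = dataclasses.replace(
            design, n_subjects=n_rob, n_sessions=1,
            rng_seed=derive_seed(design.rng_seed, 1))
        log.info("simulating robustness group (%d subjects)", n_rob)
        rob_study = _stage("robustness")(simulate_study)(rob_design)
        write_study(rob_study, out / "robustness_study")
        rob_quant = _stage("robustness")(quantify_bundle)(
            StudyBundle(scans=rob_study.scans), qcfg)
        rob_quant.to_csv(out / "robustness_quant.csv", index=False, float_format=FLOAT_FMT)
        rob = _stage("robustness")(robustness_check)(table, rob_quant)
        rob.to_csv(out / "robustness.csv", index=False, float_format=FLOAT_FMT)

    provenance = {
        "seed": design.rng_seed,
        "config_sha256": config_hash(cfg),
        "fdgquant_version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True),
                                         encoding="utf-8")
    return out
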