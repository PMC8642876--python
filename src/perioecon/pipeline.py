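"""Config-driven pipeline: base case, sensitivity analyses, CEAC, microsim.

Analyses run in dependency order and write plain CSV/JSON outputs plus a
manifest (config hash, seed, package versions).  Reruns with the same
configuration and seed are byte-identical; no timestamps enter any output.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .config import load_config, parse_dsa_rows, parse_parameter_set, parse_psa_specs
from .econ import compute_ceac, default_wtp_grid, incremental_analysis, quadrant_probabilities
from .markov import arm_expected_values, run_stratum
from .params import validate_parameter_set
from .pooling import pool_one_year_probabilities, read_studies_csv, rescale_study_to_annual
from .sensitivity import run_one_way_dsa, run_psa, tornado_frame
from .synthetic import microsimulate_arm

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("perioecon")

_ANALYSES = ("base_case", "dsa", "psa", "ceac", "microsim", "pooling")


@dataclass
class RunConfig:
    """Everything one pipeline invocation needs."""

    parameter_file: str | Path
    analyses: tuple = ("base_case",)
    iterations: int = 1000
    seed: int = 2021
    wtp_max: float = 1000.0
    wtp_step: float = 10.0
    output_dir: str | Path = "outputs"
    microsim_n: int = 100_000
    rehab_mode: str = "partial_prosthesis"
    pooling_csv: str | Path | None = None
    pooling_model: str = "fixed_effect"

    def __post_init__(self) -> None:
        unknown = set(self.analyses) - set(_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        if "ceac" in self.analyses and "psa" not in self.analyses:
            raise ValueError("analysis 'ceac' requires 'psa' (add the psa section/analysis)")
        if "pooling" in self.analyses and self.pooling_csv is None:
            raise ValueError("analysis 'pooling' requires pooling_csv")


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_csv(path: Path, frame) -> None:
    # 6 significant digits keeps CSVs readable; JSON carries full precision
    frame.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested analyses and return the manifest dict."""
    doc = load_config(config.parameter_file)
    ps = parse_parameter_set(doc)
    issues = validate_parameter_set(ps)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        raise ValueError(f"parameter set failed validation: {[i.to_dict() for i in errors]}")
    for issue in issues:
        logger.warning("parameter warning: %s", issue.to_dict())

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []

    def record(name: str) -> Path:
        outputs.append(name)
        return outdir / name

    inputs = ps.to_model_inputs(rehab_mode=config.rehab_mode)
    arms = {}
    if "base_case" in config.analyses:
        logger.info("base case: rolling back the decision tree")
        for arm in ("SCT", "NO_SCT"):
            arms[arm] = arm_expected_values(inputs, arm)
            _write_json(record(f"arm_{arm}.json"), arms[arm].to_dict())
        for measure in ("effect", "qaly"):
            inc = incremental_analysis(arms["SCT"], arms["NO_SCT"], measure)
            _write_json(record(f"incremental_{measure}.json"), inc.to_dict())
        for status in ("FORMER", "CURRENT"):
            trace = run_stratum(inputs, status)
            _write_csv(record(f"trace_{status}.csv"), trace.to_frame())

    if "dsa" in config.analyses:
        rows = parse_dsa_rows(doc)
        if not rows:
            raise ValueError("analysis 'dsa' requires a dsa.rows config section")
        logger.info("one-way sensitivity analysis over %d rows", len(rows))
        results = run_one_way_dsa(ps, rows)
        _write_csv(record("tornado.csv"), tornado_frame(results))

    samples = None
    if "psa" in config.analyses:
        specs = parse_psa_specs(doc)
        if not specs:
            raise ValueError("analysis 'psa' requires a psa.distributions config section")
        iterations = config.iterations or int(doc.get("psa", {}).get("iterations", 1000))
        logger.info("PSA: %d Monte Carlo iterations, seed %d", iterations, config.seed)
        samples = run_psa(ps, specs, iterations=iterations, seed=config.seed)
        _write_csv(record("psa_samples.csv"), samples.to_frame())
        quadrants = {
            measure: quadrant_probabilities(samples, measure).to_dict()
            for measure in ("effect", "qaly")
        }
        _write_json(record("quadrants.json"), quadrants)

    if "ceac" in config.analyses:
        grid = default_wtp_grid(config.wtp_max, config.wtp_step)
        frames = []
        for measure in ("effect", "qaly"):
            curve = compute_ceac(samples, grid, measure)
            f = curve.to_frame()
            f.insert(1, "effect_measure", measure)
            frames.append(f)
        import pandas as pd

        _write_csv(record("ceac.csv"), pd.concat(frames, ignore_index=True))

    if "microsim" in config.analyses:
        summaries = {}
        for arm in ("SCT", "NO_SCT"):
            res = microsimulate_arm(inputs, arm, config.microsim_n, seed=config.seed)
            summaries[arm] = res.to_dict()
            _write_csv(record(f"microsim_{arm}.csv"), res.records)
        _write_json(record("microsim_summary.json"), summaries)

    if "pooling" in config.analyses:
        studies = [rescale_study_to_annual(s) for s in read_studies_csv(config.pooling_csv)]
        pooled = pool_one_year_probabilities(studies, model=config.pooling_model)
        _write_json(record("pooled_proportion.json"), pooled.to_dict())
        import pandas as pd

        _write_csv(
            record("pooling_weights.csv"),
            pd.DataFrame(
                {"label": [s.label for s in studies], "weight": pooled.weights}
            ),
        )

    config_hash = hashlib.sha256(Path(config.parameter_file).read_bytes()).hexdigest()
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config_sha256": config_hash,
        "seed": config.seed,
        "analyses": list(config.analyses),
        "rehab_mode": config.rehab_mode,
        "outputs": outputs,
    }
    _write_json(outdir / "manifest.json", manifest)
    return manifest
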