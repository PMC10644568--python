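"""End-to-end orchestration: cohort in, report directory out.

Stage order follows the study's analysis chain: feature extraction ->
normality gate -> group summaries and pairwise t-tests -> independence map
-> Fisher combinations -> GP classification (-> circuit fitting when raw
spectra are available).  On a stage failure the run aborts with the stage
name; artifacts from completed stages are preserved in the output directory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .circuit import fit_circuit, group_parameter_summary
from .cohort import CohortTable, TissueRecord, load_cohort_fixture
from .features import extract_features
from .gp import rmse_table
from .measurements import read_measurement_bundle
from .report import write_report
from .simulate import GROUP_CIRCUITS, default_group_configs, generate_cohort
from .stats import comparison_matrix, independence_map, normality_gate, summary_table

__all__ = ["RunConfig", "PipelineStageError", "run_full"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "fixture"                 # fixture | synthetic | bundles
    out_dir: str = "results/run"
    seed: int = 0
    bundles_dir: str | None = None        # input for mode="bundles"
    n_per_group: dict = field(
        default_factory=lambda: {"AN": 14, "FA": 4, "CA": 10}
    )
    run_stats: bool = True
    run_independence: bool = True
    run_gp: bool = True
    run_circuit_fit: bool = True          # only meaningful with raw spectra
    gp_kernels: tuple = ("matern52",)
    gp_subsets: tuple = (("Z",), ("K",), ("k",), ("%R",), ("Z", "K", "k", "%R"))
    test_convention: str = "published"

    def __post_init__(self) -> None:
        if self.mode not in ("fixture", "synthetic", "bundles"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "bundles" and not self.bundles_dir:
            raise ValueError("mode='bundles' requires bundles_dir")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        if isinstance(cfg.gp_subsets, list):
            cfg.gp_subsets = tuple(tuple(s) for s in cfg.gp_subsets)
        if isinstance(cfg.gp_kernels, list):
            cfg.gp_kernels = tuple(cfg.gp_kernels)
        return cfg


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc


def run_full(config: RunConfig) -> dict:
    """Execute all configured stages; returns the results dict written out."""
    results: dict = {"mode": config.mode, "seed": config.seed}
    measurements = None
    sample_groups: list[str] = []

    if config.mode == "fixture":
        cohort = _stage("load-fixture", load_cohort_fixture)
        results["notes"] = "bundled per-subject study cohort"
    elif config.mode == "synthetic":
        def make():
            ms, truth, circuits = generate_cohort(
                default_group_configs(), dict(config.n_per_group), seed=config.seed
            )
            return ms, truth, circuits

        measurements, truth, _ = _stage("simulate", make)
        sample_groups = [r.group for r in truth]
        cohort = _stage("extract", _extract_cohort, measurements, truth.records)
        results["notes"] = "synthetic cohort (features re-extracted from raw curves)"
    else:  # bundles
        def load_bundles():
            root = Path(config.bundles_dir)
            dirs = sorted(d for d in root.iterdir() if d.is_dir())
            if not dirs:
                raise FileNotFoundError(f"no bundle directories under {root}")
            ms, recs = [], []
            for d in dirs:
                m = read_measurement_bundle(d)
                group = _group_from_name(d.name)
                ms.append(m)
                fv = extract_features(m)
                recs.append(
                    TissueRecord(d.name, group, fv.Z_15k, fv.K, fv.k_stiff, fv.pctR)
                )
            return ms, recs

        measurements, recs = _stage("read-bundles", load_bundles)
        sample_groups = [r.group for r in recs]
        cohort = CohortTable(recs)
        results["notes"] = f"bundles from {config.bundles_dir}"

    results["cohort"] = cohort

    if config.run_stats:
        results["normality"] = _stage("normality-gate", normality_gate, cohort)
        results["summaries"] = _stage("group-summaries", summary_table, cohort)
        results["comparison"] = _stage(
            "comparison-matrix", comparison_matrix, cohort, config.test_convention
        )
    if config.run_independence:
        results["independence"] = _stage("independence-map", independence_map, cohort)
    if config.run_gp:
        results["rmse_table"] = _stage(
            "gp-classification",
            rmse_table,
            cohort,
            config.gp_kernels,
            config.gp_subsets,
            config.seed,
        )
    if config.run_circuit_fit and measurements is not None:
        def fit_all():
            fits = []
            for m, g in zip(measurements, sample_groups):
                fits.append(fit_circuit(m.impedance, GROUP_CIRCUITS[g], seed=config.seed))
            return group_parameter_summary(fits, sample_groups)

        results["circuit_summary"] = _stage("circuit-fit", fit_all)

    _stage("write-report", write_report, results, config.out_dir)
    return results


def _extract_cohort(measurements, truth_records) -> CohortTable:
    recs = []
    for m, t in zip(measurements, truth_records):
        fv = extract_features(m)
        recs.append(TissueRecord(t.subject_id, t.group, fv.Z_15k, fv.K, fv.k_stiff, fv.pctR))
    return CohortTable(recs)


def _group_from_name(name: str) -> str:
    for g in ("AN", "FA", "CA"):
        if name.upper().startswith(g):
            return g
    raise ValueError(
        f"cannot infer group from bundle directory name {name!r} "
        "(expected an AN*/FA*/CA* prefix)"
    )
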